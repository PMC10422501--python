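"""Per-frame visual feature extraction.

Two interchangeable providers implement the same contract:

``vgg16``
    A from-scratch numpy forward pass through the VGG16 architecture
    (13 conv layers in 5 blocks, 2x2 max-pooling between blocks, then two
    4096-unit fully connected layers).  Weights are drawn once from a seeded
    He-initialised random distribution: this is an architecture-only
    instantiation in the random-feature regime, which fixes every output
    shape (pool5 is 7x7x512, fc7 is 4096) and is fully deterministic, but
    carries no ImageNet semantics.  The weights identifier recorded in run
    metadata is ``vgg16-random-seed<seed>``.

``mock``
    A cheap pure function of ``(seed, image)``: the image is block-mean
    reduced to the 7x7 cell grid and the three colour channels are projected
    to C channels through a seeded random matrix followed by a ReLU.  Image
    structure survives the projection, so synthetic frames with
    class-dependent content stay class-informative downstream.

Both providers emit non-negative activations (post-ReLU), matching the
pool5 contract.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize

from .errors import DataError, ParameterError, StateError

POOL5_GRID = 7
POOL5_CHANNELS = 512
FC7_DIM = 4096
INPUT_SIZE = 224

#: mean RGB of the ImageNet training images, the canonical VGG centring offset
IMAGENET_MEAN_RGB = np.array([123.68, 116.779, 103.939], dtype=np.float32)

# (n_convs, out_channels) per block; every conv is 3x3 stride 1 same-padding
_VGG16_BLOCKS = ((2, 64), (2, 128), (3, 256), (3, 512), (3, 512))


def preprocess_frame(
    image: np.ndarray,
    size: int = INPUT_SIZE,
    subtract_mean: bool = True,
) -> np.ndarray:
    """Resize an RGB frame to the backbone input size and centre it.

    Bilinear resize straight to ``size`` x ``size`` (no centre crop), RGB
    channel order, float32, optionally minus the ImageNet mean.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ParameterError(
            f"expected an HxWx3 RGB image, got shape {image.shape}"
        )
    if image.shape[0] < 1 or image.shape[1] < 1:
        raise ParameterError("image has zero spatial extent")
    out = image.astype(np.float32)
    if out.shape[:2] != (size, size):
        out = resize(
            out, (size, size), order=1, preserve_range=True, anti_aliasing=False
        ).astype(np.float32)
    if subtract_mean:
        out = out - IMAGENET_MEAN_RGB
    return out


def _block_mean_grid(image: np.ndarray, grid: int) -> np.ndarray:
    """Average-pool an HxWx3 image onto a grid x grid x 3 cell grid."""
    h, w = image.shape[:2]
    rows = np.linspace(0, h, grid + 1).astype(int)
    cols = np.linspace(0, w, grid + 1).astype(int)
    out = np.empty((grid, grid, image.shape[2]), dtype=np.float64)
    for i in range(grid):
        r0, r1 = rows[i], max(rows[i + 1], rows[i] + 1)
        for j in range(grid):
            c0, c1 = cols[j], max(cols[j + 1], cols[j] + 1)
            out[i, j] = image[r0:r1, c0:c1].mean(axis=(0, 1))
    return out


class MockBackbone:
    """Deterministic, weight-free provider used by tests and fixtures.

    Output is a pure function of ``(seed, image content)``; no state is
    mutated between calls.
    """

    provider_name = "mock"

    def __init__(self, seed: int = 0, channels: int = POOL5_CHANNELS,
                 grid: int = POOL5_GRID):
        self.seed = seed
        self.channels = channels
        self.grid = grid
        rng = np.random.default_rng(seed)
        self._projection = rng.normal(0.0, 1.0, size=(3, channels))
        self._bias = rng.normal(0.0, 0.1, size=channels)
        self._fc_projection = rng.normal(
            0.0, 1.0, size=(grid * grid * 3, FC7_DIM)
        ) / np.sqrt(grid * grid * 3)

    @property
    def weights_id(self) -> str:
        return f"mock-seed{self.seed}"

    def extract_pool5(self, image: np.ndarray) -> np.ndarray:
        cells = _block_mean_grid(self._check(image), self.grid) / 255.0
        stack = np.maximum(cells @ self._projection + self._bias, 0.0)
        assert stack.shape == (self.grid, self.grid, self.channels)
        return stack

    def extract_fc7(self, image: np.ndarray) -> np.ndarray:
        cells = _block_mean_grid(self._check(image), self.grid) / 255.0
        return np.maximum(cells.ravel() @ self._fc_projection, 0.0)

    @staticmethod
    def _check(image: np.ndarray) -> np.ndarray:
        image = np.asarray(image, dtype=np.float64)
        if image.ndim != 3 or image.shape[-1] != 3:
            raise ParameterError(f"expected HxWx3 image, got {image.shape}")
        return image


def _conv3x3(x: np.ndarray, weight: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Same-padding 3x3 convolution via im2col + matmul.

    ``x`` is (H, W, C_in); ``weight`` is (3, 3, C_in, C_out).
    """
    h, w, c_in = x.shape
    c_out = weight.shape[-1]
    padded = np.pad(x, ((1, 1), (1, 1), (0, 0)))
    # gather the 9 shifted views: (H, W, 3, 3, C_in)
    cols = np.empty((h, w, 3, 3, c_in), dtype=np.float32)
    for di in range(3):
        for dj in range(3):
            cols[:, :, di, dj, :] = padded[di:di + h, dj:dj + w, :]
    out = cols.reshape(h * w, 9 * c_in) @ weight.reshape(9 * c_in, c_out)
    out += bias
    return np.maximum(out.reshape(h, w, c_out), 0.0, out=out.reshape(h, w, c_out))


def _maxpool2x2(x: np.ndarray) -> np.ndarray:
    h, w, c = x.shape
    return x.reshape(h // 2, 2, w // 2, 2, c).max(axis=(1, 3))


class NumpyVGG16:
    """VGG16 forward pass in numpy with seeded He-initialised weights.

    Exposes the pool5 activation stack (7x7x512) and the fc7 vector (4096).
    Weight tensors are built lazily on first use and cached on the instance;
    the fully connected block alone holds ~430 MB of float32 parameters.
    """

    provider_name = "vgg16"

    def __init__(self, seed: int = 0):
        self.seed = seed
        self._conv_weights: list[tuple[np.ndarray, np.ndarray]] | None = None
        self._fc_weights: list[tuple[np.ndarray, np.ndarray]] | None = None

    @property
    def weights_id(self) -> str:
        return f"vgg16-random-seed{self.seed}"

    def _ensure_conv(self) -> list[tuple[np.ndarray, np.ndarray]]:
        if self._conv_weights is None:
            rng = np.random.default_rng(self.seed)
            weights = []
            c_in = 3
            for n_convs, c_out in _VGG16_BLOCKS:
                for _ in range(n_convs):
                    fan_in = 9 * c_in
                    w = rng.standard_normal((3, 3, c_in, c_out), dtype=np.float32)
                    w *= np.sqrt(2.0 / fan_in)
                    b = np.zeros(c_out, dtype=np.float32)
                    weights.append((w, b))
                    c_in = c_out
            self._conv_weights = weights
        return self._conv_weights

    def _ensure_fc(self) -> list[tuple[np.ndarray, np.ndarray]]:
        if self._fc_weights is None:
            rng = np.random.default_rng(self.seed + 1)
            dims = [POOL5_GRID * POOL5_GRID * POOL5_CHANNELS, FC7_DIM, FC7_DIM]
            weights = []
            for d_in, d_out in zip(dims[:-1], dims[1:]):
                w = rng.standard_normal((d_in, d_out), dtype=np.float32)
                w *= np.sqrt(2.0 / d_in)
                weights.append((w, np.zeros(d_out, dtype=np.float32)))
            self._fc_weights = weights
        return self._fc_weights

    def extract_pool5(self, image: np.ndarray) -> np.ndarray:
        x = self._check_input(image)
        conv_weights = iter(self._ensure_conv())
        for n_convs, _ in _VGG16_BLOCKS:
            for _ in range(n_convs):
                w, b = next(conv_weights)
                x = _conv3x3(x, w, b)
            x = _maxpool2x2(x)
        assert x.shape == (POOL5_GRID, POOL5_GRID, POOL5_CHANNELS)
        return x.astype(np.float64)

    def extract_fc7(self, image: np.ndarray) -> np.ndarray:
        pool5 = self.extract_pool5(image).astype(np.float32)
        x = pool5.reshape(-1)
        for w, b in self._ensure_fc():
            x = np.maximum(x @ w + b, 0.0)
        assert x.shape == (FC7_DIM,)
        return x.astype(np.float64)

    @staticmethod
    def _check_input(image: np.ndarray) -> np.ndarray:
        image = np.asarray(image, dtype=np.float32)
        if image.shape != (INPUT_SIZE, INPUT_SIZE, 3):
            raise ParameterError(
                f"vgg16 expects a preprocessed {INPUT_SIZE}x{INPUT_SIZE}x3 "
                f"input, got {image.shape}; run preprocess_frame first"
            )
        if not np.all(np.isfinite(image)):
            raise DataError("non-finite values in backbone input")
        return image


_PROVIDERS = {"vgg16": NumpyVGG16, "mock": MockBackbone}


def get_backbone(provider: str, seed: int = 0, **kwargs):
    """Factory for ``backbone.provider`` config values (``vgg16`` or ``mock``)."""
    try:
        cls = _PROVIDERS[provider]
    except KeyError:
        raise StateError(
            f"unknown backbone provider {provider!r}; choose from {sorted(_PROVIDERS)}"
        ) from None
    return cls(seed=seed, **kwargs)
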