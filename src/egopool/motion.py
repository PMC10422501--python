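"""Dense optical flow and its colour-image encoding.

The motion stream renders each inter-frame displacement field as an RGB
"motion image": hue encodes flow direction (the full hue circle spans the
full angle circle), saturation encodes flow magnitude, and the brightness
channel is held at maximum.  The motion image is then fed to the same
backbone as an ordinary RGB frame, so appearance and motion share one
feature extractor.

Flow is estimated with the iterative Lucas-Kanade dense solver from
scikit-image with its published default parameters; the parameters used are
recorded in run metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import hsv2rgb, rgb2gray
from skimage.registration import optical_flow_ilk

from .errors import DataError, ParameterError

#: defaults of skimage.registration.optical_flow_ilk, echoed into metadata
FLOW_PARAMS = {"radius": 7, "num_warp": 10, "gaussian": False, "prefilter": False}


@dataclass
class FlowField:
    """Per-pixel displacement between two frames, in pixels per interval.

    ``u`` is the horizontal (column) displacement, ``v`` the vertical (row)
    displacement, both following image coordinates (v > 0 points down).
    """

    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64)
        self.v = np.asarray(self.v, dtype=np.float64)
        if self.u.shape != self.v.shape or self.u.ndim != 2:
            raise ParameterError(
                f"u and v must be equal-shape 2-D arrays, got {self.u.shape} "
                f"and {self.v.shape}"
            )

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)

    @property
    def angle(self) -> np.ndarray:
        """Flow direction in [0, 2*pi)."""
        return np.mod(np.arctan2(self.v, self.u), 2.0 * np.pi)


def estimate_flow(frame_a: np.ndarray, frame_b: np.ndarray, **params) -> FlowField:
    """Dense displacement field moving content of ``frame_a`` onto ``frame_b``.

    Frames are converted to grayscale internally.  A positive ``u`` at a
    pixel means the content there moved rightwards between the two frames.
    """
    frame_a = np.asarray(frame_a)
    frame_b = np.asarray(frame_b)
    if frame_a.shape != frame_b.shape:
        raise ParameterError(
            f"frame shapes differ: {frame_a.shape} vs {frame_b.shape}"
        )
    gray_a = rgb2gray(frame_a) if frame_a.ndim == 3 else frame_a.astype(np.float64)
    gray_b = rgb2gray(frame_b) if frame_b.ndim == 3 else frame_b.astype(np.float64)
    kwargs = {**FLOW_PARAMS, **params}
    # optical_flow_ilk(reference, moving) returns (row, col) displacement
    # such that moving[r + v, c + u] ~= reference[r, c]
    rows, cols = optical_flow_ilk(gray_a, gray_b, **kwargs)
    return FlowField(u=cols, v=rows)


def flow_to_image(
    flow: FlowField,
    magnitude_norm: str = "per_frame",
    cap: float | None = None,
) -> np.ndarray:
    """Render a flow field as an RGB uint8 motion image.

    Hue is the flow angle mapped linearly over the full hue circle,
    saturation is the flow magnitude normalised either to the per-frame
    maximum (``per_frame``) or against a fixed cap (``fixed``), and value is
    maximal everywhere.  Zero-magnitude flow therefore renders as pure
    white.  Under ``per_frame`` normalisation the image is invariant to a
    global positive rescaling of the field.
    """
    if not (np.all(np.isfinite(flow.u)) and np.all(np.isfinite(flow.v))):
        raise DataError("flow field contains non-finite values")
    magnitude = flow.magnitude
    if magnitude_norm == "per_frame":
        peak = magnitude.max()
        saturation = magnitude / peak if peak > 0 else np.zeros_like(magnitude)
    elif magnitude_norm == "fixed":
        if cap is None or cap <= 0:
            raise ParameterError("fixed magnitude_norm requires a positive cap")
        saturation = np.clip(magnitude / cap, 0.0, 1.0)
    else:
        raise ParameterError(
            f"magnitude_norm must be 'per_frame' or 'fixed', got {magnitude_norm!r}"
        )
    hue = flow.angle / (2.0 * np.pi)
    hsv = np.stack([hue, saturation, np.ones_like(hue)], axis=-1)
    rgb = hsv2rgb(hsv)
    return np.round(rgb * 255.0).astype(np.uint8)


def motion_image_sequence(
    sampled_frames: list[np.ndarray],
    magnitude_norm: str = "per_frame",
    cap: float | None = None,
    **flow_params,
) -> list[np.ndarray]:
    """Motion images between consecutive sampled frames, length-matched.

    With ``n`` input frames, ``n - 1`` flow fields exist; the final motion
    image is duplicated so both streams pool over identical temporal
    supports.  A single-frame clip yields one zero-flow (zero-saturation)
    image.
    """
    if not sampled_frames:
        raise ParameterError("motion_image_sequence needs at least one frame")
    if len(sampled_frames) == 1:
        shape = sampled_frames[0].shape[:2]
        zero = FlowField(u=np.zeros(shape), v=np.zeros(shape))
        return [flow_to_image(zero, magnitude_norm, cap)]
    images = [
        flow_to_image(
            estimate_flow(a, b, **flow_params), magnitude_norm, cap
        )
        for a, b in zip(sampled_frames[:-1], sampled_frames[1:])
    ]
    images.append(images[-1].copy())
    return images
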