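"""Regional mean/max spatial pooling of convolutional feature maps (MMSP).

The pool5 activation grid of a frame is summarised per channel over six
fixed regions of the 7x7 cell grid — the whole grid, a 3x3 centre, and four
overlapping 4x4 quadrants that share row/column 4:

====================  =====================
region                rows x cols (1-based,
                      inclusive)
====================  =====================
whole                 [1,7] x [1,7]
center                [3,5] x [3,5]
top_left              [1,4] x [1,4]
top_right             [1,4] x [4,7]
bottom_left           [4,7] x [1,4]
bottom_right          [4,7] x [4,7]
====================  =====================

The MMSP frame descriptor concatenates the six per-channel regional means
followed by the six per-channel regional maxima, in the region order above:
12 blocks of C channels, i.e. 6144 values for C = 512.

Two mean conventions are provided.  ``true_mean`` divides each regional sum
by the region's actual cell count (49, 9 or 16).  ``paper_literal``
reproduces the originally printed coefficients, which use 1/49 for the
whole grid and 1/9 for every sub-region — including the 16-cell quadrants,
where 1/9 is almost certainly a copy-through from the 9-cell centre but is
kept available for exact replication.  ``true_mean`` is the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

#: 1-based inclusive (row_lo, row_hi, col_lo, col_hi) on the 7x7 cell grid
REGION_BOUNDS: dict[str, tuple[int, int, int, int]] = {
    "whole": (1, 7, 1, 7),
    "center": (3, 5, 3, 5),
    "top_left": (1, 4, 1, 4),
    "top_right": (1, 4, 4, 7),
    "bottom_left": (4, 7, 1, 4),
    "bottom_right": (4, 7, 4, 7),
}

REGION_ORDER = tuple(REGION_BOUNDS)

#: printed averaging coefficients: 1/49 on the whole grid, 1/9 elsewhere
PAPER_COEFFICIENTS: dict[str, float] = {
    name: (1.0 / 49.0 if name == "whole" else 1.0 / 9.0) for name in REGION_ORDER
}

MEAN_MODES = ("true_mean", "paper_literal")


@dataclass(frozen=True)
class RegionSpec:
    """A named rectangular pooling region in 1-based inclusive grid indices."""

    name: str
    row_range: tuple[int, int]
    col_range: tuple[int, int]

    @classmethod
    def named(cls, name: str) -> "RegionSpec":
        try:
            r0, r1, c0, c1 = REGION_BOUNDS[name]
        except KeyError:
            raise ParameterError(
                f"unknown region {name!r}; choose from {list(REGION_ORDER)}"
            ) from None
        return cls(name=name, row_range=(r0, r1), col_range=(c0, c1))

    def slices(self) -> tuple[slice, slice]:
        """0-based half-open slices; the only place indexing conventions meet."""
        (r0, r1), (c0, c1) = self.row_range, self.col_range
        return slice(r0 - 1, r1), slice(c0 - 1, c1)

    @property
    def cell_count(self) -> int:
        return (self.row_range[1] - self.row_range[0] + 1) * (
            self.col_range[1] - self.col_range[0] + 1
        )

    def validate_against(self, stack: np.ndarray) -> None:
        h, w = stack.shape[:2]
        (r0, r1), (c0, c1) = self.row_range, self.col_range
        if not (1 <= r0 <= r1 <= h and 1 <= c0 <= c1 <= w):
            raise ParameterError(
                f"region {self.name!r} {self.row_range}x{self.col_range} is "
                f"outside a {h}x{w} grid"
            )


def _check_stack(stack: np.ndarray) -> np.ndarray:
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim != 3:
        raise ParameterError(
            f"feature-map stack must be (H_cells, W_cells, C), got {stack.shape}"
        )
    return stack


def region_mean(
    stack: np.ndarray, region: RegionSpec | str, mode: str = "true_mean"
) -> np.ndarray:
    """Per-channel mean of the stack's cells inside a region (length C)."""
    stack = _check_stack(stack)
    if isinstance(region, str):
        region = RegionSpec.named(region)
    region.validate_against(stack)
    if mode not in MEAN_MODES:
        raise ParameterError(f"mode must be one of {MEAN_MODES}, got {mode!r}")
    rows, cols = region.slices()
    total = stack[rows, cols].sum(axis=(0, 1))
    if mode == "true_mean":
        return total / region.cell_count
    coefficient = PAPER_COEFFICIENTS.get(region.name)
    if coefficient is None:
        raise ParameterError(
            f"paper_literal coefficients are defined only for the named "
            f"regions, not {region.name!r}"
        )
    return total * coefficient


def region_max(stack: np.ndarray, region: RegionSpec | str) -> np.ndarray:
    """Per-channel maximum of the stack's cells inside a region (length C)."""
    stack = _check_stack(stack)
    if isinstance(region, str):
        region = RegionSpec.named(region)
    region.validate_against(stack)
    rows, cols = region.slices()
    return stack[rows, cols].max(axis=(0, 1))


def mmsp(stack: np.ndarray, mode: str = "true_mean") -> np.ndarray:
    """MMSP frame descriptor: six regional means then six regional maxima.

    Output length is 12 * C (6144 for the 7x7x512 pool5 stack).
    """
    stack = _check_stack(stack)
    means = [region_mean(stack, name, mode) for name in REGION_ORDER]
    maxima = [region_max(stack, name) for name in REGION_ORDER]
    descriptor = np.concatenate(means + maxima)
    assert descriptor.shape == (12 * stack.shape[2],)
    return descriptor


def stack_pool5(stack: np.ndarray) -> np.ndarray:
    """Flatten the full activation grid into one vector (the fv-pool5 baseline).

    Row-major cell traversal: the value of cell (i, j) channel c lands at
    flat index ``(i * W + j) * C + c`` (0-based).  Length is H*W*C, i.e.
    25,088 for 7x7x512.  ``stack_pool5(s).reshape(s.shape)`` recovers ``s``.
    """
    stack = _check_stack(stack)
    return stack.reshape(-1)
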