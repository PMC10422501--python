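"""Aggregation of per-frame descriptors into a single clip descriptor.

The temporal pyramid max-mean (TPMM) pooling uses a two-level pyramid: an
element-wise maximum over all frames of the clip (the global level), then
element-wise means over the clip's first and second halves (the local
level).  The three pooled vectors are concatenated, so the clip descriptor
is three times the frame-descriptor length — 18,432 for 6144-dimensional
MMSP frames.  Plain max-only and mean-only pooling serve as baselines.

Clip descriptors are L2-normalised before classification.  When both the
appearance and the motion stream are used, each stream's descriptor is
normalised, the two are concatenated (early fusion, doubling the length)
and the fused vector is re-normalised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DataError, ParameterError

logger = logging.getLogger(__name__)

POOLING_TAGS = ("tpmm", "max", "mean")
MODALITY_TAGS = ("appearance", "motion", "fused")


@dataclass(frozen=True)
class ClipDescriptor:
    """A pooled per-clip feature vector with its provenance tags."""

    values: np.ndarray
    pooling_tag: str
    modality_tag: str
    n_frames_pooled: int

    def __post_init__(self) -> None:
        if self.pooling_tag not in POOLING_TAGS:
            raise ParameterError(f"unknown pooling_tag {self.pooling_tag!r}")
        if self.modality_tag not in MODALITY_TAGS:
            raise ParameterError(f"unknown modality_tag {self.modality_tag!r}")


def _as_matrix(frames) -> np.ndarray:
    """Stack a descriptor sequence into an (N, d) float matrix."""
    matrix = np.atleast_2d(np.asarray(frames, dtype=np.float64))
    if matrix.size == 0:
        raise ParameterError("descriptor sequence is empty")
    return matrix


def temporal_max(frames) -> np.ndarray:
    """Element-wise maximum across the frame descriptors."""
    return _as_matrix(frames).max(axis=0)


def temporal_mean(frames) -> np.ndarray:
    """Element-wise arithmetic mean across the frame descriptors."""
    return _as_matrix(frames).mean(axis=0)


def tpmm(frames) -> np.ndarray:
    """Two-level temporal pyramid: [max over all, mean 1st half, mean 2nd half].

    For N frames the first half is frames 1..floor(N/2) and the second half
    the remainder; each half's mean uses that half's actual frame count.  A
    single-frame clip reuses its one frame for both halves (logged).
    """
    matrix = _as_matrix(frames)
    n = matrix.shape[0]
    if n == 1:
        logger.info("tpmm on a single-frame clip: both halves reuse the frame")
        first, second = matrix, matrix
    else:
        half = n // 2
        first, second = matrix[:half], matrix[half:]
    return np.concatenate(
        [matrix.max(axis=0), first.mean(axis=0), second.mean(axis=0)]
    )


_POOLERS = {"tpmm": tpmm, "max": temporal_max, "mean": temporal_mean}


def l2_normalize(vector: np.ndarray) -> np.ndarray:
    """Scale to unit Euclidean norm; a zero vector passes through (logged)."""
    vector = np.asarray(vector, dtype=np.float64)
    if not np.all(np.isfinite(vector)):
        raise DataError("cannot normalize a vector with non-finite values")
    norm = np.linalg.norm(vector)
    if norm == 0.0:
        logger.warning("l2_normalize called on a zero vector; returned unchanged")
        return vector
    return vector / norm


def pool_clip(
    frames,
    pooling_tag: str = "tpmm",
    modality_tag: str = "appearance",
    normalize: bool = True,
) -> ClipDescriptor:
    """Pool a frame-descriptor sequence into a tagged clip descriptor."""
    if pooling_tag not in _POOLERS:
        raise ParameterError(
            f"pooling_tag must be one of {POOLING_TAGS}, got {pooling_tag!r}"
        )
    matrix = _as_matrix(frames)
    values = _POOLERS[pooling_tag](matrix)
    if normalize:
        values = l2_normalize(values)
    return ClipDescriptor(
        values=values,
        pooling_tag=pooling_tag,
        modality_tag=modality_tag,
        n_frames_pooled=matrix.shape[0],
    )


def fuse(appearance: ClipDescriptor, motion: ClipDescriptor) -> ClipDescriptor:
    """Early fusion: concatenate the two streams and re-normalise.

    Both inputs must use the same temporal pooling; the fused length is the
    sum of the two (double, for equal-dimensional streams).
    """
    if appearance.pooling_tag != motion.pooling_tag:
        raise ParameterError(
            f"pooling_tag mismatch: {appearance.pooling_tag!r} vs "
            f"{motion.pooling_tag!r}"
        )
    fused = np.concatenate([appearance.values, motion.values])
    return ClipDescriptor(
        values=l2_normalize(fused),
        pooling_tag=appearance.pooling_tag,
        modality_tag="fused",
        n_frames_pooled=appearance.n_frames_pooled,
    )
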