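"""Dataset manifest handling, frame reading/sampling and the feature cache.

A dataset is described by a plain CSV manifest with one row per pre-segmented
video clip::

    clip_id,path,subject_id,label,native_fps

``path`` points either at a directory of numbered PNG/JPEG frames (read in
lexicographic order) or at a video container (requires an imageio video
plugin).  ``native_fps`` is taken from the manifest rather than probed from
the container so that frame sampling is reproducible across codecs.

The :class:`FeatureCache` stores one ``.npz`` file per ``(clip_id,
stream_tag)`` pair so that expensive backbone passes run once per clip.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EmptyClipError, ParameterError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ("clip_id", "path", "subject_id", "label", "native_fps")

#: bumped whenever the on-disk cache layout changes
CACHE_FORMAT_VERSION = 1

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}


@dataclass(frozen=True)
class ClipRecord:
    """One pre-segmented video clip with its subject and activity annotation."""

    clip_id: str
    path: str
    subject_id: str
    label: str
    native_fps: float

    def __post_init__(self) -> None:
        if not self.native_fps > 0:
            raise ValidationError(
                f"clip {self.clip_id!r}: native_fps must be > 0, got {self.native_fps}"
            )


@dataclass(frozen=True)
class DatasetManifest:
    """Ordered clip records plus the derived class and subject sets.

    ``classes`` is the sorted distinct label list (this ordering is also the
    class order used by the classifier, including its tie-break rule);
    ``subjects`` keeps first-appearance order.
    """

    records: tuple[ClipRecord, ...]
    classes: tuple[str, ...]
    subjects: tuple[str, ...]

    @classmethod
    def from_records(cls, records: Sequence[ClipRecord]) -> "DatasetManifest":
        records = tuple(records)
        if not records:
            raise ValidationError("manifest contains no records")
        ids = [r.clip_id for r in records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate clip_id(s): {sorted(dupes)}")
        classes = tuple(sorted({r.label for r in records}))
        subjects = tuple(dict.fromkeys(r.subject_id for r in records))
        return cls(records=records, classes=classes, subjects=subjects)

    def __len__(self) -> int:
        return len(self.records)


def load_manifest(path: str | Path) -> DatasetManifest:
    """Read and validate a CSV manifest.  Row order is preserved."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    try:
        frame = pd.read_csv(path, dtype={"clip_id": str, "subject_id": str, "label": str})
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"manifest is empty: {path}") from exc
    for column in MANIFEST_COLUMNS:
        if column not in frame.columns:
            raise SchemaError(f"manifest {path} is missing required column {column!r}")
    if frame.empty:
        raise ValidationError(f"manifest has a header but no rows: {path}")
    records = [
        ClipRecord(
            clip_id=row.clip_id,
            path=str(row.path),
            subject_id=row.subject_id,
            label=row.label,
            native_fps=float(row.native_fps),
        )
        for row in frame.itertuples(index=False)
    ]
    return DatasetManifest.from_records(records)


def write_manifest(manifest: DatasetManifest, path: str | Path) -> Path:
    """Write a manifest back to CSV; inverse of :func:`load_manifest`."""
    path = Path(path)
    frame = pd.DataFrame([
        {
            "clip_id": r.clip_id,
            "path": r.path,
            "subject_id": r.subject_id,
            "label": r.label,
            "native_fps": r.native_fps,
        }
        for r in manifest.records
    ])
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    return path


def _as_rgb(image: np.ndarray) -> np.ndarray:
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    if image.shape[-1] == 4:  # drop alpha
        image = image[..., :3]
    return image


def read_frames(record: ClipRecord) -> list[np.ndarray]:
    """Decode all frames of a clip in temporal order as HxWx3 uint8 arrays."""
    import imageio.v3 as iio

    source = Path(record.path)
    if not source.exists():
        raise FileNotFoundError(f"clip {record.clip_id!r}: path does not exist: {source}")
    frames: list[np.ndarray] = []
    if source.is_dir():
        files = sorted(
            p for p in source.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
        )
        for file in files:
            try:
                frames.append(_as_rgb(np.asarray(iio.imread(file))))
            except Exception as exc:
                raise OSError(f"clip {record.clip_id!r}: cannot decode {file}") from exc
    else:
        try:
            for frame in iio.imiter(source):
                frames.append(_as_rgb(np.asarray(frame)))
        except Exception as exc:
            raise OSError(
                f"clip {record.clip_id!r}: cannot read container {source} "
                "(a video plugin such as ffmpeg may be required)"
            ) from exc
    if not frames:
        raise EmptyClipError(f"clip {record.clip_id!r}: no decodable frames in {source}")
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise ValidationError(
            f"clip {record.clip_id!r}: frames disagree on shape: {sorted(shapes)}"
        )
    return frames


def sample_frames(
    frames: Sequence[np.ndarray],
    native_fps: float,
    target_fps: float,
    offset: int = 0,
) -> list[np.ndarray]:
    """Down-sample a frame sequence to ``target_fps`` by stride sampling.

    The stride is ``k = round(native_fps / target_fps)`` and sampling starts
    at frame ``offset`` (0 by default), so the output length is
    ``ceil((n - offset) / k)``.  At least one frame is always returned.
    """
    if target_fps <= 0:
        raise ParameterError(f"target_fps must be > 0, got {target_fps}")
    if target_fps > native_fps:
        raise ParameterError(
            f"target_fps ({target_fps}) exceeds native_fps ({native_fps})"
        )
    if not frames:
        raise ParameterError("cannot sample an empty frame sequence")
    stride = max(1, round(native_fps / target_fps))
    offset = min(offset, len(frames) - 1)
    sampled = list(frames[offset::stride])
    assert len(sampled) == math.ceil((len(frames) - offset) / stride)
    return sampled


class CacheMiss:
    """Sentinel type distinguishing a missing cache entry from empty content."""

    def __bool__(self) -> bool:
        return False

    def __repr__(self) -> str:  # pragma: no cover
        return "<cache miss>"


MISS = CacheMiss()


def _safe_key(clip_id: str, stream_tag: str) -> str:
    safe = re.sub(r"[^A-Za-z0-9_.-]", "_", clip_id)
    return f"{safe}__{stream_tag}.npz"


class FeatureCache:
    """One ``.npz`` file per ``(clip_id, stream_tag)``, with a format version.

    Each file stores a single named array ``data`` plus ``format_version``.
    A repeated ``put`` with the same key overwrites the previous entry (the
    overwrite is logged).
    """

    def __init__(self, directory: str | Path):
        self.directory = Path(directory)
        self.directory.mkdir(parents=True, exist_ok=True)
        if not self.directory.is_dir():
            raise OSError(f"cache path is not a directory: {self.directory}")

    def _path(self, clip_id: str, stream_tag: str) -> Path:
        return self.directory / _safe_key(clip_id, stream_tag)

    def put(self, clip_id: str, stream_tag: str, descriptors: np.ndarray) -> Path:
        descriptors = np.asarray(descriptors)
        if not np.all(np.isfinite(descriptors)):
            raise ValidationError(
                f"refusing to cache non-finite values for ({clip_id!r}, {stream_tag!r})"
            )
        target = self._path(clip_id, stream_tag)
        if target.exists():
            logger.info("cache overwrite: %s / %s", clip_id, stream_tag)
        try:
            np.savez(
                target,
                data=descriptors,
                format_version=np.int64(CACHE_FORMAT_VERSION),
            )
        except OSError as exc:
            raise OSError(f"cache directory not writable: {self.directory}") from exc
        return target

    def get(self, clip_id: str, stream_tag: str) -> np.ndarray | CacheMiss:
        target = self._path(clip_id, stream_tag)
        if not target.exists():
            return MISS
        with np.load(target) as archive:
            version = int(archive["format_version"])
            if version != CACHE_FORMAT_VERSION:
                raise ValidationError(
                    f"cache entry {target} has format version {version}, "
                    f"expected {CACHE_FORMAT_VERSION}"
                )
            return archive["data"]

    def has(self, clip_id: str, stream_tag: str) -> bool:
        return self._path(clip_id, stream_tag).exists()
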