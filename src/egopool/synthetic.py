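"""Seeded synthetic fixtures: feature stacks, videos and whole datasets.

Every generator is a pure function of its spec and seed, so fixtures are
reproducible bit-for-bit and need no downloads.  Two kinds of material are
produced:

* **Feature stacks** emulating pool5 activation grids whose class signal is
  an additive bump confined to one of the named MMSP pooling regions, on a
  seeded subset of channels.  Because the discriminative signal lives in a
  pooling region (not in arbitrary cells), the spatial-pooling stage is
  precisely what makes the classes linearly separable downstream.
* **Videos** of a textured square moving over a textured background with
  known per-interval shifts, giving the flow estimator a ground truth.

:func:`gen_dataset` assembles a balanced manifest in either cached-stack
form (pooling-only path) or frames-on-disk form (full pipeline).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .manifest_io import ClipRecord, DatasetManifest, FeatureCache, write_manifest
from .spatial_pooling import REGION_ORDER, RegionSpec

#: cache tags under which raw activation stacks (not descriptors) are stored
STACK_TAGS = {"appearance": "appearance_stacks", "motion": "motion_stacks"}

_SIGNAL_REGION_CYCLE = ("center", "top_left", "top_right", "bottom_left", "bottom_right")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic dataset.

    The separability condition ``signal_strength > 3 * noise_sd`` holds for
    the defaults (3.0 vs 3 x 0.5), so the default spec is the "separable"
    preset; pass ``signal_strength=0`` for a pure-noise (chance-level) set.
    """

    seed: int = 0
    n_subjects: int = 3
    n_classes: int = 2
    clips_per_subject_class: int = 2
    n_frames: int = 8
    frame_size: int = 64
    grid: int = 7
    channels: int = 512
    signal_strength: float = 3.0
    noise_sd: float = 0.5
    baseline_level: float = 1.0
    signal_channel_fraction: float = 0.25
    motion_profile: str | tuple = "class_dependent"
    native_fps: float = 30.0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_classes", "clips_per_subject_class",
                     "n_frames", "frame_size", "grid", "channels"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be positive")

    def signal_region(self, class_index: int) -> RegionSpec:
        """The MMSP region carrying class ``class_index``'s activation bump."""
        if not 0 <= class_index < self.n_classes:
            raise ParameterError(
                f"class index {class_index} outside [0, {self.n_classes})"
            )
        name = _SIGNAL_REGION_CYCLE[class_index % len(_SIGNAL_REGION_CYCLE)]
        return RegionSpec.named(name)

    def signal_channels(self, class_index: int) -> np.ndarray:
        """Seeded channel subset carrying the bump; fixed per (spec, class)."""
        rng = np.random.default_rng([self.seed, 7919, class_index])
        count = max(1, int(round(self.signal_channel_fraction * self.channels)))
        return np.sort(rng.choice(self.channels, size=count, replace=False))

    def class_shift(self, class_index: int) -> tuple[int, int]:
        """Per-interval (dx, dy) pixel shift for the clip's moving shape."""
        profile = self.motion_profile
        if profile == "static":
            return (0, 0)
        if isinstance(profile, tuple) and profile[0] == "translate":
            return (int(profile[1]), int(profile[2]))
        if profile == "class_dependent":
            angle = 2.0 * math.pi * class_index / max(self.n_classes, 1)
            return (int(round(3 * math.cos(angle))), int(round(3 * math.sin(angle))))
        raise ParameterError(f"unknown motion_profile {self.motion_profile!r}")


def gen_feature_stack(
    spec: SyntheticSpec, class_index: int, seed: int
) -> np.ndarray:
    """One synthetic activation grid: baseline noise plus the class bump.

    Gaussian noise of scale ``noise_sd`` around ``baseline_level``
    everywhere, plus ``signal_strength`` added inside the class's signal
    region on the class's seeded channel subset.
    """
    region = spec.signal_region(class_index)
    channels = spec.signal_channels(class_index)
    rng = np.random.default_rng([spec.seed, seed])
    stack = spec.baseline_level + rng.normal(
        0.0, spec.noise_sd, size=(spec.grid, spec.grid, spec.channels)
    )
    rows, cols = region.slices()
    stack[rows, cols, channels] += spec.signal_strength
    return stack


def gen_feature_stack_sequence(
    spec: SyntheticSpec, class_index: int, seed: int
) -> np.ndarray:
    """A clip's worth of stacks: (n_frames, grid, grid, channels)."""
    return np.stack(
        [
            gen_feature_stack(spec, class_index, seed * 100003 + t)
            for t in range(spec.n_frames)
        ]
    )


def _texture(rng: np.random.Generator, height: int, width: int) -> np.ndarray:
    """Low-contrast RGB noise texture that gives the flow estimator gradients."""
    base = rng.integers(60, 190, size=(height, width, 3))
    return base.astype(np.uint8)


def gen_video(
    spec: SyntheticSpec, class_index: int, seed: int
) -> tuple[list[np.ndarray], list[tuple[int, int]]]:
    """Frames of a textured square moving with a known per-interval shift.

    Returns ``(frames, shifts)`` where ``shifts[t]`` is the ground-truth
    (dx, dy) displacement between frames t and t+1 (len = n_frames - 1).
    """
    size = spec.frame_size
    shape_size = max(8, size // 4)
    dx, dy = spec.class_shift(class_index)
    travel_x = dx * (spec.n_frames - 1)
    travel_y = dy * (spec.n_frames - 1)
    margin = 2
    x0 = margin if travel_x >= 0 else margin - travel_x
    y0 = margin if travel_y >= 0 else margin - travel_y
    x_end = x0 + travel_x if travel_x >= 0 else x0
    y_end = y0 + travel_y if travel_y >= 0 else y0
    if (max(x0, x_end) + shape_size + margin > size
            or max(y0, y_end) + shape_size + margin > size):
        raise ParameterError(
            f"frame_size {size} too small for a {shape_size}px shape moving "
            f"({dx},{dy})/frame over {spec.n_frames} frames"
        )
    rng = np.random.default_rng([spec.seed, 104729, seed])
    background = _texture(rng, size, size)
    patch = rng.integers(120, 255, size=(shape_size, shape_size, 3)).astype(np.uint8)
    frames = []
    for t in range(spec.n_frames):
        frame = background.copy()
        x = x0 + dx * t
        y = y0 + dy * t
        frame[y:y + shape_size, x:x + shape_size] = patch
        frames.append(frame)
    shifts = [(dx, dy)] * (spec.n_frames - 1)
    return frames, shifts


def gen_dataset(
    spec: SyntheticSpec,
    out_dir: str | Path,
    form: str = "stacks",
    shuffle_labels: bool = False,
) -> DatasetManifest:
    """Write a balanced synthetic dataset and its manifest to ``out_dir``.

    ``form="stacks"`` caches per-clip activation-stack sequences (appearance
    and motion streams) so the pooling-only path can run without a backbone;
    ``form="frames"`` writes PNG frame directories for the full pipeline.
    ``shuffle_labels`` applies a seeded label permutation after generation,
    producing a chance-level control set with identical marginals.
    """
    if form not in ("stacks", "frames"):
        raise ParameterError(f"form must be 'stacks' or 'frames', got {form!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cache = FeatureCache(out_dir / "cache") if form == "stacks" else None

    records: list[ClipRecord] = []
    clip_seed = 0
    for subject_index in range(spec.n_subjects):
        for class_index in range(spec.n_classes):
            for k in range(spec.clips_per_subject_class):
                clip_seed += 1
                clip_id = f"s{subject_index:02d}_c{class_index:02d}_k{k:02d}"
                if form == "stacks":
                    stacks = gen_feature_stack_sequence(spec, class_index, clip_seed)
                    cache.put(clip_id, STACK_TAGS["appearance"], stacks)
                    # motion stream gets its own independent draw of the same
                    # class-conditional stack distribution
                    motion = gen_feature_stack_sequence(
                        spec, class_index, clip_seed + 50021
                    )
                    cache.put(clip_id, STACK_TAGS["motion"], motion)
                    path = str(out_dir / "cache")
                else:
                    frames, _ = gen_video(spec, class_index, clip_seed)
                    clip_dir = out_dir / "clips" / clip_id
                    clip_dir.mkdir(parents=True, exist_ok=True)
                    import imageio.v3 as iio

                    for t, frame in enumerate(frames):
                        iio.imwrite(clip_dir / f"frame_{t:04d}.png", frame)
                    path = str(clip_dir)
                records.append(
                    ClipRecord(
                        clip_id=clip_id,
                        path=path,
                        subject_id=f"subj{subject_index:02d}",
                        label=f"class{class_index:02d}",
                        native_fps=spec.native_fps,
                    )
                )
    if shuffle_labels:
        # permute labels within each subject: per-subject class balance is
        # preserved, so every LOPO training fold stays exactly balanced and
        # the control really scores at binomial chance (an unstratified
        # permutation makes training majorities anti-correlated with the
        # held-out fold, the well-known pessimistic bias of leave-one-out
        # on null data)
        rng = np.random.default_rng([spec.seed, 15485863])
        shuffled: list[ClipRecord] = []
        for subject_index in range(spec.n_subjects):
            block = [
                r for r in records if r.subject_id == f"subj{subject_index:02d}"
            ]
            labels = [r.label for r in block]
            permutation = rng.permutation(len(labels))
            shuffled.extend(
                ClipRecord(
                    clip_id=r.clip_id,
                    path=r.path,
                    subject_id=r.subject_id,
                    label=labels[permutation[i]],
                    native_fps=r.native_fps,
                )
                for i, r in enumerate(block)
            )
        records = shuffled
    manifest = DatasetManifest.from_records(records)
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest
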