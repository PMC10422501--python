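"""End-to-end orchestration: frames -> descriptors -> clip vector -> LOPO.

The per-clip flow mirrors the two-stream design: sampled RGB frames feed
the backbone directly (appearance stream) while the motion stream first
renders inter-frame optical flow as colour motion images and feeds those to
the same backbone.  Each stream's per-frame MMSP descriptors are pooled
temporally into one clip vector; with both streams active the two vectors
are fused by concatenation.

Per-frame descriptors are cached per (clip, stream) so backbone passes run
once.  Clips whose cache already holds raw synthetic activation stacks
(see :mod:`egopool.synthetic`) skip the backbone and enter at the
spatial-pooling stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import backbone as backbone_mod
from .classify import EvaluationResult, lopo_evaluate
from .config import RunConfig
from .errors import ParameterError
from .manifest_io import (
    ClipRecord,
    DatasetManifest,
    FeatureCache,
    MISS,
    read_frames,
    sample_frames,
)
from .motion import motion_image_sequence
from .spatial_pooling import mmsp, stack_pool5
from .synthetic import STACK_TAGS
from .temporal_pooling import ClipDescriptor, fuse, l2_normalize, pool_clip

logger = logging.getLogger(__name__)


def _frame_vector(stack_or_image, config: RunConfig, provider) -> np.ndarray:
    """Backbone pass + frame-level encoding for one image."""
    if config.backbone_layer == "fc7":
        image = stack_or_image
        if provider.provider_name == "vgg16":
            image = backbone_mod.preprocess_frame(image)
        return l2_normalize(provider.extract_fc7(image))
    image = stack_or_image
    if provider.provider_name == "vgg16":
        image = backbone_mod.preprocess_frame(image)
    stack = provider.extract_pool5(image)
    return mmsp(stack, mode=config.spatial_mode)


def frame_descriptors(
    record: ClipRecord,
    stream: str,
    config: RunConfig,
    cache: FeatureCache | None = None,
    provider=None,
) -> np.ndarray:
    """Per-frame descriptor matrix (n_frames, d) for one clip and stream."""
    if stream not in ("appearance", "motion"):
        raise ParameterError(f"stream must be 'appearance' or 'motion', got {stream!r}")
    if cache is not None:
        cached = cache.get(record.clip_id, stream)
        if cached is not MISS:
            return cached
        stacks = cache.get(record.clip_id, STACK_TAGS[stream])
        if stacks is not MISS:
            matrix = np.vstack(
                [mmsp(stack, mode=config.spatial_mode) for stack in stacks]
            )
            cache.put(record.clip_id, stream, matrix)
            return matrix
    if provider is None:
        provider = backbone_mod.get_backbone(
            config.backbone_provider, seed=config.seed
        )
    frames = sample_frames(
        read_frames(record), record.native_fps, config.target_fps,
        offset=config.sample_offset,
    )
    if stream == "motion":
        frames = motion_image_sequence(
            frames, config.magnitude_norm, config.magnitude_cap
        )
    matrix = np.vstack([_frame_vector(f, config, provider) for f in frames])
    if cache is not None:
        cache.put(record.clip_id, stream, matrix)
    return matrix


def clip_descriptor(
    record: ClipRecord,
    config: RunConfig,
    cache: FeatureCache | None = None,
    provider=None,
) -> ClipDescriptor:
    """Pooled (and, for two streams, fused) descriptor for one clip."""
    streams = ("appearance", "motion") if config.streams == "both" else (config.streams,)
    per_modality_norm = config.normalization == "per_modality_then_fused"
    pooled = [
        pool_clip(
            frame_descriptors(record, stream, config, cache, provider),
            pooling_tag=config.temporal_pooling,
            modality_tag=stream,
            normalize=per_modality_norm or len(streams) == 1,
        )
        for stream in streams
    ]
    if len(pooled) == 1:
        descriptor = pooled[0]
        if not per_modality_norm:
            descriptor = ClipDescriptor(
                values=l2_normalize(descriptor.values),
                pooling_tag=descriptor.pooling_tag,
                modality_tag=descriptor.modality_tag,
                n_frames_pooled=descriptor.n_frames_pooled,
            )
        return descriptor
    return fuse(pooled[0], pooled[1])


@dataclass
class ExtractionSummary:
    extracted: list[str]
    skipped_cached: list[str]
    failed: dict[str, str]


def extract_manifest(
    manifest: DatasetManifest,
    config: RunConfig,
    cache: FeatureCache,
) -> ExtractionSummary:
    """Populate the cache with per-frame descriptors for every clip.

    Idempotent: clips with all requested streams already cached are
    skipped.  Per-clip failures are logged and collected, not fatal.
    """
    streams = ("appearance", "motion") if config.streams == "both" else (config.streams,)
    provider = backbone_mod.get_backbone(config.backbone_provider, seed=config.seed)
    summary = ExtractionSummary(extracted=[], skipped_cached=[], failed={})
    for record in manifest.records:
        if all(cache.has(record.clip_id, s) for s in streams):
            summary.skipped_cached.append(record.clip_id)
            continue
        try:
            for stream in streams:
                frame_descriptors(record, stream, config, cache, provider)
            summary.extracted.append(record.clip_id)
        except Exception as exc:
            logger.error("clip %r failed: %s", record.clip_id, exc)
            summary.failed[record.clip_id] = str(exc)
    return summary


def evaluate_manifest(
    manifest: DatasetManifest,
    config: RunConfig,
    cache: FeatureCache | None = None,
) -> EvaluationResult:
    """Compute clip descriptors (from cache where possible) and run LOPO."""
    provider = backbone_mod.get_backbone(config.backbone_provider, seed=config.seed)
    features = {
        record.clip_id: clip_descriptor(record, config, cache, provider).values
        for record in manifest.records
    }
    return lopo_evaluate(
        manifest, features, cost=config.svm_cost, seed=config.seed
    )


def run_metadata(config: RunConfig) -> dict:
    """Reproducibility block written into every results file."""
    from . import __version__
    from .motion import FLOW_PARAMS

    provider = backbone_mod.get_backbone(config.backbone_provider, seed=config.seed)
    return {
        "egopool_version": __version__,
        "config": config.to_dict(),
        "weights_id": provider.weights_id,
        "flow_params": dict(FLOW_PARAMS),
    }
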