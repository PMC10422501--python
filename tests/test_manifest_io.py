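import math

import numpy as np
import pytest

from egopool.errors import (
    EmptyClipError,
    ParameterError,
    SchemaError,
    ValidationError,
)
from egopool.manifest_io import (
    MISS,
    ClipRecord,
    DatasetManifest,
    FeatureCache,
    load_manifest,
    read_frames,
    sample_frames,
    write_manifest,
)


def _write_csv(path, rows):
    lines = ["clip_id,path,subject_id,label,native_fps"] + rows
    path.write_text("\n".join(lines) + "\n")
    return path


class TestLoadManifest:
    def test_counts_records_subjects_classes(self, tmp_path):
        path = _write_csv(tmp_path / "m.csv", [
            "a,/x,p1,eat,30",
            "b,/x,p1,read,30",
            "c,/x,p2,eat,30",
            "d,/x,p2,read,30",
        ])
        manifest = load_manifest(path)
        assert len(manifest) == 4
        assert manifest.subjects == ("p1", "p2")
        assert manifest.classes == ("eat", "read")

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("clip_id,path,subject_id,native_fps\na,/x,p1,30\n")
        with pytest.raises(SchemaError, match="label"):
            load_manifest(path)

    def test_duplicate_clip_id_rejected(self, tmp_path):
        path = _write_csv(tmp_path / "m.csv", ["a,/x,p1,eat,30", "a,/y,p2,read,30"])
        with pytest.raises(ValidationError, match="duplicate"):
            load_manifest(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("")
        with pytest.raises(ValidationError):
            load_manifest(path)

    def test_nonpositive_fps_rejected(self, tmp_path):
        path = _write_csv(tmp_path / "m.csv", ["a,/x,p1,eat,0"])
        with pytest.raises(ValidationError, match="native_fps"):
            load_manifest(path)

    def test_round_trip_preserves_all_fields(self, tmp_path):
        records = [
            ClipRecord("c1", "/data/c1", "s1", "wash", 30.0),
            ClipRecord("c2", "/data/c2", "s2", "read", 24.0),
        ]
        manifest = DatasetManifest.from_records(records)
        reloaded = load_manifest(write_manifest(manifest, tmp_path / "m.csv"))
        assert reloaded.records == manifest.records
        assert reloaded.classes == manifest.classes
        assert reloaded.subjects == manifest.subjects


class TestReadFrames:
    def test_directory_read_in_filename_order(self, tmp_path):
        import imageio.v3 as iio

        clip = tmp_path / "clip"
        clip.mkdir()
        for t in range(5):
            frame = np.full((8, 8, 3), t * 10, dtype=np.uint8)
            iio.imwrite(clip / f"frame_{t:03d}.png", frame)
        frames = read_frames(ClipRecord("c", str(clip), "s", "x", 30.0))
        assert len(frames) == 5
        assert [int(f[0, 0, 0]) for f in frames] == [0, 10, 20, 30, 40]

    def test_generated_clip_frame_count(self, tmp_path):
        from egopool import SyntheticSpec, gen_video
        import imageio.v3 as iio

        spec = SyntheticSpec(seed=3, n_frames=9, motion_profile="static")
        frames, _ = gen_video(spec, 0, seed=1)
        clip = tmp_path / "clip"
        clip.mkdir()
        for t, frame in enumerate(frames):
            iio.imwrite(clip / f"f{t:04d}.png", frame)
        assert len(read_frames(ClipRecord("c", str(clip), "s", "x", 30.0))) == 9

    def test_corrupt_file_raises_io_error(self, tmp_path):
        clip = tmp_path / "clip"
        clip.mkdir()
        (clip / "bad.png").write_bytes(b"not a png")
        with pytest.raises(OSError):
            read_frames(ClipRecord("c", str(clip), "s", "x", 30.0))

    def test_empty_directory_raises_empty_clip_error(self, tmp_path):
        clip = tmp_path / "clip"
        clip.mkdir()
        with pytest.raises(EmptyClipError):
            read_frames(ClipRecord("c", str(clip), "s", "x", 30.0))


class TestSampleFrames:
    def test_30fps_to_1fps_takes_every_30th(self):
        frames = list(range(90))
        assert sample_frames(frames, 30, 1) == [0, 30, 60]

    def test_30fps_to_10fps_yields_30_frames(self):
        assert len(sample_frames(list(range(90)), 30, 10)) == 30

    def test_single_frame_clip_survives(self):
        assert sample_frames(["only"], 30, 1) == ["only"]

    def test_target_above_native_rejected(self):
        with pytest.raises(ParameterError):
            sample_frames([1, 2, 3], 30, 60)

    @pytest.mark.parametrize("n,native,target", [
        (90, 30, 1), (91, 30, 1), (89, 30, 1), (90, 30, 10),
        (7, 24, 5), (1, 30, 1), (100, 25, 3),
    ])
    def test_output_length_is_ceil_n_over_stride(self, n, native, target):
        stride = max(1, round(native / target))
        assert len(sample_frames(list(range(n)), native, target)) == math.ceil(n / stride)


class TestFeatureCache:
    def test_put_get_round_trip_is_bit_exact(self, tmp_path, rng):
        cache = FeatureCache(tmp_path)
        array = rng.normal(size=(5, 12)).astype(np.float64)
        cache.put("clip1", "appearance", array)
        out = cache.get("clip1", "appearance")
        assert out.dtype == array.dtype
        assert np.array_equal(out, array)

    def test_unknown_key_is_a_miss_not_an_exception(self, tmp_path):
        cache = FeatureCache(tmp_path)
        result = cache.get("nope", "appearance")
        assert result is MISS
        assert not result

    def test_miss_is_distinguishable_from_empty_array(self, tmp_path):
        cache = FeatureCache(tmp_path)
        cache.put("clip1", "motion", np.zeros((0, 4)))
        stored = cache.get("clip1", "motion")
        assert stored is not MISS
        assert stored.shape == (0, 4)

    def test_second_put_wins(self, tmp_path):
        cache = FeatureCache(tmp_path)
        cache.put("c", "appearance", np.array([1.0]))
        cache.put("c", "appearance", np.array([2.0]))
        assert cache.get("c", "appearance")[0] == 2.0

    def test_non_finite_values_rejected(self, tmp_path):
        cache = FeatureCache(tmp_path)
        with pytest.raises(ValidationError):
            cache.put("c", "appearance", np.array([np.nan]))
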