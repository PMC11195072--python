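import numpy as np
import pandas as pd
import pytest

from mtscompare import (
    TimeSeriesDataset,
    apply_qc,
    compute_framewise_displacement,
    load_dataset,
    write_dataset,
)


def make_dataset(data, diagnoses=None, mean_fd=None, tr=2.0):
    n = data.shape[0]
    pids = [f"p{i}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "diagnosis": diagnoses or ["case" if i % 2 else "control" for i in range(n)],
            "age": 30.0,
            "sex": 0,
            "site": "s1",
            "mean_fd": mean_fd if mean_fd is not None else [0.1] * n,
        },
        index=pids,
    )
    return TimeSeriesDataset(
        data=data,
        region_labels=[f"r{j}" for j in range(data.shape[1])],
        participant_ids=pids,
        tr_seconds=tr,
        meta=meta,
    )


class TestFramewiseDisplacement:
    def test_zero_motion_gives_zero_fd(self):
        fd = compute_framewise_displacement(np.zeros((6, 10)))
        assert np.array_equal(fd, np.zeros(10))

    def test_single_translation_step(self):
        motion = np.zeros((6, 5))
        motion[0, 2:] = 1.0  # 1 mm x-translation between frames 1 and 2
        fd = compute_framewise_displacement(motion)
        assert fd[0] == 0.0
        assert fd[2] == pytest.approx(1.0)
        assert fd.sum() == pytest.approx(1.0)

    def test_rotation_converted_on_50mm_sphere(self):
        motion = np.zeros((6, 3))
        motion[3, 1:] = 0.02  # 0.02 rad pitch step
        fd = compute_framewise_displacement(motion, head_radius_mm=50.0)
        assert fd[1] == pytest.approx(1.0)

    def test_invariant_to_constant_offset(self, rng):
        motion = rng.normal(size=(6, 30))
        shifted = motion + rng.normal(size=(6, 1))
        np.testing.assert_allclose(
            compute_framewise_displacement(motion),
            compute_framewise_displacement(shifted),
            atol=1e-12,
        )

    @pytest.mark.parametrize("bad", [np.zeros((6, 1)), np.zeros((5, 10))])
    def test_rejects_malformed_motion(self, bad):
        with pytest.raises(ValueError):
            compute_framewise_displacement(bad)


class TestQC:
    def test_constant_zero_participant_excluded(self, rng):
        data = rng.normal(size=(4, 3, 50))
        data[1] = 0.0
        ds = make_dataset(data)
        kept, report = apply_qc(ds)
        assert report.excluded_constant == ["p1"]
        assert kept.n_participants == 3

    def test_fd_threshold_counts(self, rng):
        data = rng.normal(size=(4, 2, 50))
        ds = make_dataset(data, diagnoses=["control", "case", "control", "case"],
                          mean_fd=[0.5, 0.56, 0.6, 0.1])
        kept, report = apply_qc(ds, fd_threshold_mm=0.55)
        assert report.excluded_motion == ["p1", "p2"]
        assert kept.participant_ids == ["p0", "p3"]

    def test_class_wipeout_rejected(self, rng):
        data = rng.normal(size=(3, 2, 50))
        ds = make_dataset(data, diagnoses=["control", "case", "case"],
                          mean_fd=[0.1, 0.9, 0.9])
        with pytest.raises(ValueError, match="diagnosis class"):
            apply_qc(ds, fd_threshold_mm=0.55)

    def test_low_motion_keeps_everyone(self, rng):
        ds = make_dataset(rng.normal(size=(4, 2, 50)), mean_fd=[0.1] * 4)
        kept, report = apply_qc(ds, fd_threshold_mm=0.55)
        assert report.n_excluded == 0
        assert kept.n_participants == 4

    def test_idempotent(self, rng):
        data = rng.normal(size=(5, 2, 50))
        data[0] = 0.0
        ds = make_dataset(data, mean_fd=[0.1, 0.1, 0.9, 0.1, 0.1])
        once, _ = apply_qc(ds)
        twice, rep2 = apply_qc(once)
        assert twice.participant_ids == once.participant_ids
        assert rep2.n_excluded == 0
        np.testing.assert_array_equal(twice.data, once.data)

    def test_all_excluded_raises(self):
        ds = make_dataset(np.zeros((2, 2, 50)))
        with pytest.raises(ValueError, match="every participant"):
            apply_qc(ds)

    def test_missing_fd_retained_with_warning(self, rng, caplog):
        ds = make_dataset(rng.normal(size=(2, 2, 50)),
                          mean_fd=[np.nan, np.nan])
        with caplog.at_level("WARNING"):
            kept, _ = apply_qc(ds)
        assert kept.n_participants == 2


class TestDatasetInvariants:
    def test_duplicate_region_labels_rejected(self, rng):
        with pytest.raises(ValueError, match="unique"):
            TimeSeriesDataset(
                data=rng.normal(size=(1, 2, 10)),
                region_labels=["a", "a"],
                participant_ids=["p0"],
                tr_seconds=2.0,
                meta=pd.DataFrame({"diagnosis": ["case"]}, index=["p0"]),
            )

    def test_nonpositive_tr_rejected(self, rng):
        with pytest.raises(ValueError, match="tr_seconds"):
            TimeSeriesDataset(
                data=rng.normal(size=(1, 1, 10)),
                region_labels=["a"],
                participant_ids=["p0"],
                tr_seconds=0.0,
                meta=pd.DataFrame({"diagnosis": ["case"]}, index=["p0"]),
            )


class TestIO:
    def test_write_load_roundtrip_bitwise(self, rng, tmp_path):
        ds = make_dataset(rng.normal(size=(3, 4, 20)))
        manifest = write_dataset(ds, tmp_path)
        loaded = load_dataset(manifest, tr_seconds=2.0)
        np.testing.assert_array_equal(loaded.data, ds.data)
        assert loaded.region_labels == ds.region_labels
        assert loaded.participant_ids == ds.participant_ids

    def test_shape_passthrough(self, rng, tmp_path):
        ds = make_dataset(rng.normal(size=(2, 3, 5)))
        loaded = load_dataset(write_dataset(ds, tmp_path), tr_seconds=2.0)
        assert loaded.data.shape == (2, 3, 5)

    def test_columns_aligned_by_header_name(self, rng, tmp_path):
        ds = make_dataset(rng.normal(size=(2, 3, 8)))
        manifest = write_dataset(ds, tmp_path)
        # reorder the second participant's columns on disk
        f = tmp_path / "timeseries" / "p1.csv"
        df = pd.read_csv(f)
        df[df.columns[::-1]].to_csv(f, index=False)
        loaded = load_dataset(manifest, tr_seconds=2.0)
        np.testing.assert_allclose(loaded.data, ds.data)

    def test_missing_file_names_participant(self, rng, tmp_path):
        ds = make_dataset(rng.normal(size=(2, 2, 8)))
        manifest = write_dataset(ds, tmp_path)
        (tmp_path / "timeseries" / "p1.csv").unlink()
        with pytest.raises(FileNotFoundError, match="p1"):
            load_dataset(manifest, tr_seconds=2.0)

    def test_ragged_timepoints_rejected(self, rng, tmp_path):
        ds = make_dataset(rng.normal(size=(2, 2, 8)))
        manifest = write_dataset(ds, tmp_path)
        f = tmp_path / "timeseries" / "p1.csv"
        pd.read_csv(f).iloc[:5].to_csv(f, index=False)
        with pytest.raises(ValueError, match="p1"):
            load_dataset(manifest, tr_seconds=2.0)

    def test_duplicate_ids_rejected(self, rng, tmp_path):
        ds = make_dataset(rng.normal(size=(2, 2, 8)))
        manifest = write_dataset(ds, tmp_path)
        m = pd.read_csv(manifest)
        m.loc[1, "participant_id"] = "p0"
        m.to_csv(manifest, index=False)
        with pytest.raises(ValueError, match="duplicate"):
            load_dataset(manifest, tr_seconds=2.0)

    def test_non_numeric_cells_rejected(self, rng, tmp_path):
        ds = make_dataset(rng.normal(size=(2, 2, 8)))
        manifest = write_dataset(ds, tmp_path)
        f = tmp_path / "timeseries" / "p0.csv"
        df = pd.read_csv(f).astype(object)
        df.iloc[0, 0] = "oops"
        df.to_csv(f, index=False)
        with pytest.raises(ValueError, match="non-numeric"):
            load_dataset(manifest, tr_seconds=2.0)
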