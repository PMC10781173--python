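"""Synthetic EEG generator and the segmentation/splitting protocol."""

import numpy as np
import pytest

from stseize.features import build_feature_map
from stseize.synthdata import (
    EEGRecord,
    NoiseSpec,
    SeizureSpec,
    annotations_from_csv,
    annotations_to_csv,
    generate_record,
    record_from_npz,
    record_to_npz,
    segment_record,
    split_train_test,
)


class TestGenerateRecord:
    def test_no_seizures_empty_annotations(self):
        rec = generate_record(30, n_channels=4, seed=0)
        assert rec.annotations == ()
        ds = segment_record(rec)
        assert set(ds.labels) == {0}

    def test_seeded_bit_reproducibility(self):
        spec = SeizureSpec(n_seizures=1, duration_range_s=(10, 20), min_gap_s=5)
        a = generate_record(60, n_channels=3, seizures=spec, seed=9)
        b = generate_record(60, n_channels=3, seizures=spec, seed=9)
        np.testing.assert_array_equal(a.signal, b.signal)
        assert a.annotations == b.annotations
        c = generate_record(60, n_channels=3, seizures=spec, seed=10)
        assert not np.array_equal(a.signal, c.signal)

    def test_chbmit_like_defaults(self):
        rec = generate_record(10, seed=1)
        assert rec.n_channels == 23
        assert rec.fs == 256.0
        assert rec.channel_names[0] == "FP1-F7"

    def test_ictal_band_energy_dominates(self):
        """Mean 3-30 Hz energy inside seizures is >= 3x the interictal mean."""
        spec = SeizureSpec(times=((20.0, 50.0),))
        rec = generate_record(90, n_channels=4, seizures=spec, seed=4)
        ds = segment_record(rec)
        # 3-30 Hz spans the theta/alpha/beta columns (indices 2..7)
        energies = np.array([
            build_feature_map(ds.segments[i], rec.fs).values[:, 2:8].mean()
            for i in range(len(ds))
        ])
        ictal = energies[ds.labels == 1].mean()
        inter = energies[ds.labels == 0].mean()
        assert ictal >= 3.0 * inter

    def test_overlapping_seizures_rejected(self):
        spec = SeizureSpec(times=((10.0, 30.0), (25.0, 40.0)))
        with pytest.raises(ValueError, match="overlap"):
            generate_record(60, n_channels=2, seizures=spec, seed=0)

    def test_out_of_range_seizures_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            generate_record(30, n_channels=2, seizures=SeizureSpec(times=((10.0, 40.0),)), seed=0)

    def test_too_many_seizures_rejected(self):
        with pytest.raises(ValueError, match="cannot fit"):
            generate_record(60, n_channels=2, seizures=SeizureSpec(n_seizures=5), seed=0)


class TestSegmentRecord:
    def _record_with(self, duration, seizure):
        return generate_record(duration, n_channels=2,
                               seizures=SeizureSpec(times=(seizure,)), seed=3)

    def test_ten_second_seizure_gives_four_ictal_windows(self):
        rec = self._record_with(40, (12.0, 22.0))
        ds = segment_record(rec)
        ictal_starts = ds.start_times[ds.labels == 1]
        np.testing.assert_allclose(ictal_starts, [12.0, 14.0, 16.0, 18.0])

    def test_four_second_seizure_single_window(self):
        rec = self._record_with(30, (8.0, 12.0))
        ds = segment_record(rec)
        assert (ds.labels == 1).sum() == 1

    def test_boundary_straddling_windows_discarded(self):
        rec = self._record_with(40, (10.0, 20.0))
        ds = segment_record(rec)
        for s, label in zip(ds.start_times, ds.labels):
            if label == 1:
                assert s >= 10.0 and s + 4.0 <= 20.0
            else:
                assert s + 4.0 <= 10.0 or s >= 20.0

    def test_interictal_windows_non_overlapping(self):
        rec = generate_record(40, n_channels=2, seed=0)
        ds = segment_record(rec)
        assert np.all(np.diff(ds.start_times) >= 4.0)

    def test_balanced_mode_equal_classes(self):
        rec = self._record_with(120, (30.0, 50.0))
        ds = segment_record(rec, mode="balanced", seed=1)
        assert (ds.labels == 0).sum() == (ds.labels == 1).sum()

    def test_balanced_mode_seeded(self):
        rec = self._record_with(120, (30.0, 50.0))
        a = segment_record(rec, mode="balanced", seed=5)
        b = segment_record(rec, mode="balanced", seed=5)
        np.testing.assert_array_equal(a.start_times, b.start_times)

    def test_segments_are_4s(self):
        rec = generate_record(20, n_channels=2, seed=0)
        ds = segment_record(rec)
        assert ds.segments.shape[-1] == 1024


class TestSplit:
    def _dataset(self):
        rec = generate_record(
            420, n_channels=2,
            seizures=SeizureSpec(times=((100.0, 140.0), (250.0, 300.0))), seed=0,
        )
        return segment_record(rec)

    def test_three_to_one_ratio(self):
        ds = self._dataset()
        tr, te = split_train_test(ds, 0.75, seed=0)
        assert len(tr) == int(round(0.75 * len(ds)))
        assert len(tr) + len(te) == len(ds)

    def test_seeded_and_partition(self):
        ds = self._dataset()
        tr1, te1 = split_train_test(ds, 0.75, seed=2)
        tr2, te2 = split_train_test(ds, 0.75, seed=2)
        np.testing.assert_array_equal(tr1.start_times, tr2.start_times)
        union = np.sort(np.concatenate([tr1.start_times, te1.start_times]))
        np.testing.assert_array_equal(union, np.sort(ds.start_times))

    def test_invalid_ratio_and_size(self):
        ds = self._dataset()
        with pytest.raises(ValueError):
            split_train_test(ds, 1.5, 0)
        with pytest.raises(ValueError, match="small"):
            split_train_test(ds.subset(np.array([0])), 0.75, 0)


def test_annotation_and_npz_round_trip(tmp_path):
    spec = SeizureSpec(times=((5.0, 15.0),))
    rec = generate_record(30, n_channels=3, seizures=spec, seed=2)
    annotations_to_csv(rec.annotations, tmp_path / "ann.csv")
    assert annotations_from_csv(tmp_path / "ann.csv") == rec.annotations
    record_to_npz(rec, tmp_path / "rec.npz")
    rec2 = record_from_npz(tmp_path / "rec.npz")
    np.testing.assert_array_equal(rec.signal, rec2.signal)
    assert rec2.channel_names == rec.channel_names
    assert rec2.annotations == rec.annotations


def test_record_invariants():
    with pytest.raises(ValueError, match="offset"):
        EEGRecord(np.zeros((1, 256)), 256.0, ("a",), annotations=((0.5, 0.2),))
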