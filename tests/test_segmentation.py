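import numpy as np
import pytest

from seizpred.eeg_io import SeizureAnnotation
from seizpred.segmentation import (
    Label,
    balance_classes,
    extract_segments,
    label_periods,
    read_manifest,
    write_manifest,
)

H4 = 4 * 3600


def spans(intervals, label):
    return [(iv.start, iv.end) for iv in intervals if iv.label is label]


class TestLabelPeriods:
    def test_single_seizure_reference_case(self):
        # 10 h record, one seizure [18000, 18120)
        ivs = label_periods(36000, [SeizureAnnotation("r", 18000, 18120)])
        assert spans(ivs, Label.PREICTAL) == [(17100, 18000)]  # 15 min
        assert spans(ivs, Label.ICTAL) == [(18000, 18120)]
        assert spans(ivs, Label.INTERICTAL) == [(0, 3600), (32520, 36000)]

    def test_preictal_clipped_at_zero(self):
        ivs = label_periods(7200, [SeizureAnnotation("r", 600, 660)])
        assert spans(ivs, Label.PREICTAL) == [(0, 600)]

    def test_close_seizures_truncate_second_preictal(self):
        # onsets 500 s apart; first offset at 560 -> second preictal 440 s long
        anns = [SeizureAnnotation("r", 2000, 2060), SeizureAnnotation("r", 2500, 2550)]
        ivs = label_periods(36000, anns)
        pre = spans(ivs, Label.PREICTAL)
        assert (2060, 2500) in pre
        assert pre[0] == (1100, 2000)

    def test_postictal_excluded(self):
        ivs = label_periods(36000, [SeizureAnnotation("r", 18000, 18120)])
        excluded = spans(ivs, Label.EXCLUDED)
        # the 4 h after offset is neither interictal nor preictal
        assert any(s <= 18120 < 32520 <= e for s, e in excluded)

    def test_disjoint_cover(self):
        anns = [SeizureAnnotation("r", 5000, 5100), SeizureAnnotation("r", 20000, 20200)]
        ivs = label_periods(40000, anns)
        assert ivs[0].start == 0 and ivs[-1].end == 40000
        for a, b in zip(ivs, ivs[1:]):
            assert a.end == b.start

    def test_no_seizures_all_interictal(self):
        ivs = label_periods(1000, [])
        assert spans(ivs, Label.INTERICTAL) == [(0, 1000)]

    def test_negative_duration(self):
        with pytest.raises(ValueError):
            label_periods(-1, [])

    @pytest.mark.parametrize("trial", range(25))
    def test_bruteforce_rules_random_annotations(self, trial):
        rng = np.random.default_rng(trial)
        duration = 12 * 3600
        n = rng.integers(1, 4)
        onsets = np.sort(rng.uniform(0, duration - 400, n))
        anns = []
        last_end = 0.0
        for onset in onsets:
            onset = max(onset, last_end + 1.0)
            offset = onset + float(rng.uniform(20, 300))
            if offset >= duration:
                break
            anns.append(SeizureAnnotation("r", float(onset), float(offset)))
            last_end = offset
        if not anns:
            pytest.skip("degenerate draw")
        ivs = label_periods(duration, anns)
        # brute-force point check on a 10 s lattice
        for t in np.arange(5.0, duration, 10.0):
            lab = next(iv.label for iv in ivs if iv.start <= t < iv.end)
            in_ictal = any(a.onset <= t < a.offset for a in anns)
            interictal_ok = all(
                t <= a.onset - H4 or t >= a.offset + H4 for a in anns
            )
            if in_ictal:
                assert lab is Label.ICTAL
            elif lab is Label.INTERICTAL:
                assert interictal_ok
            if lab is Label.PREICTAL:
                assert not in_ictal
                nxt = min(a.onset for a in anns if a.onset > t)
                assert nxt - t <= 900
                assert not any(a.onset <= t or a.offset > nxt for a in anns if a.onset < nxt and a.offset > t)

    def test_preictal_minutes_bookkeeping(self):
        # 7 well-separated seizures -> 7 x 15 = 105 preictal minutes
        anns = [
            SeizureAnnotation("r", 10000 + i * 20000, 10060 + i * 20000)
            for i in range(7)
        ]
        ivs = label_periods(7 * 20000 + 20000, anns)
        total = sum(iv.duration for iv in ivs if iv.label is Label.PREICTAL)
        assert total == pytest.approx(105 * 60)


class TestExtractSegments:
    def _intervals(self, rid="recA"):
        return label_periods(36000, [SeizureAnnotation(rid, 18000, 18120)])

    def test_counts_3s(self, make_record):
        rec = make_record(n_channels=2, fs=256, duration=36000 / 100, record_id="recA")
        # use a lightweight record covering only the preictal interval
        rec = make_record(n_channels=2, fs=8, duration=36000, record_id="recA")
        segs = extract_segments(rec, self._intervals(), 3.0)
        pre = [s for s in segs if s.label is Label.PREICTAL]
        assert len(pre) == 300  # 900 / 3

    def test_counts_1s(self, make_record):
        rec = make_record(n_channels=1, fs=8, duration=36000, record_id="recA")
        segs = extract_segments(rec, self._intervals(), 1.0)
        pre = [s for s in segs if s.label is Label.PREICTAL]
        assert len(pre) == 900

    def test_partial_window_discarded(self, make_record):
        rec = make_record(n_channels=1, fs=8, duration=10, record_id="recA")
        from seizpred.segmentation import PeriodInterval

        iv = [PeriodInterval("recA", 0, 10, Label.INTERICTAL)]
        segs = extract_segments(rec, iv, 3.0)
        assert len(segs) == 3
        assert segs[-1].start == 6.0

    def test_floor_count_property(self, make_record):
        rec = make_record(n_channels=1, fs=8, duration=100, record_id="recA")
        from seizpred.segmentation import PeriodInterval

        for length in [7.0, 13.5, 99.0]:
            iv = [PeriodInterval("recA", 0, length, Label.INTERICTAL)]
            segs = extract_segments(rec, iv, 2.0)
            assert len(segs) == int(length // 2.0)

    def test_overlap(self, make_record):
        rec = make_record(n_channels=1, fs=8, duration=10, record_id="recA")
        from seizpred.segmentation import PeriodInterval

        iv = [PeriodInterval("recA", 0, 10, Label.INTERICTAL)]
        segs = extract_segments(rec, iv, 2.0, overlap_seconds=1.0)
        assert [s.start for s in segs] == [float(i) for i in range(9)]

    def test_segment_too_long_yields_empty(self, make_record):
        rec = make_record(n_channels=1, fs=8, duration=10, record_id="recA")
        from seizpred.segmentation import PeriodInterval

        iv = [PeriodInterval("recA", 0, 2, Label.PREICTAL)]
        assert extract_segments(rec, iv, 3.0) == []

    def test_data_slice_matches(self, make_record):
        rec = make_record(n_channels=2, fs=16, duration=30, record_id="recA", seed=5)
        from seizpred.segmentation import PeriodInterval

        iv = [PeriodInterval("recA", 4, 10, Label.PREICTAL)]
        segs = extract_segments(rec, iv, 2.0)
        np.testing.assert_array_equal(segs[0].data, rec.data[:, 64:96])


class TestBalance:
    def _segs(self, n_pre, n_inter, make_record):
        rec = make_record(n_channels=1, fs=8, duration=2 * (n_pre + n_inter) + 10)
        from seizpred.segmentation import PeriodInterval

        ivs = [
            PeriodInterval("recA", 0, 2 * n_pre, Label.PREICTAL),
            PeriodInterval("recA", 2 * n_pre, 2 * (n_pre + n_inter), Label.INTERICTAL),
        ]
        return extract_segments(rec, ivs, 2.0)

    def test_subsample_to_ratio(self, make_record):
        segs = self._segs(300, 2000, make_record)
        out = balance_classes(segs, seed=0)
        labels = [s.label for s in out]
        assert labels.count(Label.PREICTAL) == 300
        assert labels.count(Label.INTERICTAL) == 300

    def test_cannot_upsample(self, make_record):
        segs = self._segs(300, 200, make_record)
        out = balance_classes(segs, seed=0)
        labels = [s.label for s in out]
        assert labels.count(Label.PREICTAL) == 300
        assert labels.count(Label.INTERICTAL) == 200

    def test_deterministic(self, make_record):
        segs = self._segs(50, 400, make_record)
        a = balance_classes(segs, seed=7)
        b = balance_classes(segs, seed=7)
        assert [(s.record_id, s.start) for s in a] == [(s.record_id, s.start) for s in b]

    def test_seed_changes_selection(self, make_record):
        segs = self._segs(50, 400, make_record)
        a = balance_classes(segs, seed=1)
        b = balance_classes(segs, seed=2)
        assert [(s.start, s.label) for s in a] != [(s.start, s.label) for s in b]

    def test_missing_class(self, make_record):
        segs = [s for s in self._segs(10, 10, make_record) if s.label is Label.PREICTAL]
        with pytest.raises(ValueError, match="interictal"):
            balance_classes(segs, seed=0)


def test_manifest_round_trip(tmp_path, make_record):
    from seizpred.segmentation import PeriodInterval

    rec = make_record(n_channels=1, fs=8, duration=20, record_id="recA")
    ivs = [PeriodInterval("recA", 0, 20, Label.INTERICTAL)]
    segs = extract_segments(rec, ivs, 5.0)
    p = tmp_path / "m.csv"
    write_manifest(p, segs)
    rows = read_manifest(p)
    assert len(rows) == 4
    assert rows[0] == {
        "record_id": "recA",
        "start": 0.0,
        "duration": 5.0,
        "label": Label.INTERICTAL,
    }
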