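"""Timing decomposition: segmentation, gap splitting, onset residuals."""

from __future__ import annotations

import numpy as np
import pytest

from matrixlft import (
    item_times,
    participant_item_table,
    participant_lfts,
    residualize_onset,
    segment_by_rule,
)
from matrixlft.io_logs import SessionLog
from matrixlft.lft_extraction import ExtractionConfig

from conftest import make_item, make_log


class TestSegmentation:
    def test_clicks_project_to_rule_time_pairs(self, two_rule_item):
        log = make_log(two_rule_item, [("A", 5), ("A", 6), ("B", 10), ("B", 11)],
                       ("submit", 12))
        seq = segment_by_rule(log, two_rule_item)
        assert seq == [("rule1", 5), ("rule1", 6), ("rule2", 10), ("rule2", 11)]

    def test_instant_timeout_gives_empty_sequence(self, two_rule_item):
        log = make_log(two_rule_item, [], ("timeout", 90.0))
        assert segment_by_rule(log, two_rule_item) == []

    def test_order_preserved_across_rule_revisits(self, two_rule_item):
        log = make_log(two_rule_item, [("A", 3), ("B", 4), ("A", 8)], ("submit", 9))
        seq = segment_by_rule(log, two_rule_item)
        assert [r for r, _ in seq] == ["rule1", "rule2", "rule1"]
        assert [t for _, t in seq] == [3, 4, 8]


class TestItemTimes:
    def test_blocked_processing_decomposition(self, two_rule_item):
        log = make_log(two_rule_item, [("A", 5), ("A", 6), ("B", 10), ("B", 11)],
                       ("submit", 12))
        t = item_times(log, two_rule_item)
        assert t.tot == 12 and t.first_click == 5
        assert t.inter_gaps == (4,) and t.intra_gaps == (1, 1)
        assert t.inter == 4.0 and t.intra == 1.0

    @pytest.mark.parametrize(
        "denom, expected", [("transitions", 7 / 3), ("rules", 7 / 2), ("rules-1", 7.0)]
    )
    def test_alternating_clicks_are_all_interrule(self, two_rule_item, denom, expected):
        log = make_log(two_rule_item, [("A", 2), ("B", 5), ("A", 7), ("B", 9)],
                       ("submit", 10))
        t = item_times(log, two_rule_item, inter_denominator=denom)
        assert t.inter_gaps == (3, 2, 2) and t.intra_gaps == ()
        assert t.intra is None
        assert t.inter == pytest.approx(expected)

    def test_single_click_then_timeout(self, two_rule_item):
        log = make_log(two_rule_item, [("A", 8)], ("timeout", 90.0))
        t = item_times(log, two_rule_item)
        assert t.tot == 90.0 and t.first_click == 8
        assert t.inter is None and t.intra is None

    def test_decomposition_identity_on_simulated_items(self, cohort):
        """first_click + gaps + trailing == ToT for every simulated log."""
        sessions, _truth, bank = cohort
        specs = {it.item_id: it for it in bank}
        checked = 0
        for session in sessions:
            for log in session.item_logs:
                t = item_times(log, specs[log.item_id])
                if t.first_click is None:
                    continue
                last_click = log.clicks[-1].t
                total = (
                    t.first_click
                    + sum(t.inter_gaps)
                    + sum(t.intra_gaps)
                    + (t.tot - last_click)
                )
                assert abs(total - t.tot) < 1e-9
                checked += 1
                if checked >= 1000:
                    return
        assert checked > 0

    @pytest.mark.parametrize("s", [0.5, 2.0, 3.7])
    def test_scale_equivariance(self, two_rule_item, s):
        seq = [("A", 2), ("A", 4), ("B", 7)]
        log1 = make_log(two_rule_item, seq, ("submit", 9))
        log2 = make_log(two_rule_item, [(r, t * s) for r, t in seq], ("submit", 9 * s))
        t1 = item_times(log1, two_rule_item)
        t2 = item_times(log2, two_rule_item)
        assert t2.tot == pytest.approx(s * t1.tot)
        assert t2.first_click == pytest.approx(s * t1.first_click)
        assert t2.inter == pytest.approx(s * t1.inter)
        assert t2.intra == pytest.approx(s * t1.intra)


class TestOnsetResidualization:
    def test_zero_slope_leaves_first_click_unchanged(self):
        inter = np.array([1.0, -1.0, 1.0, -1.0])  # exactly uncorrelated
        first = np.array([1.0, 1.0, 2.0, 2.0])
        onset = residualize_onset(first, inter)
        assert np.max(np.abs(onset - first)) < 1e-10

    def test_perfect_collinearity_collapses_to_mean(self):
        inter = np.array([1.0, 2.0, 3.0, 4.0])
        first = 2.0 * inter
        onset = residualize_onset(first, inter)
        assert np.allclose(onset, first.mean(), atol=1e-12)

    def test_constant_predictor_degenerates_to_centring(self):
        first = np.array([3.0, 5.0, 7.0])
        with pytest.warns(UserWarning, match="zero variance"):
            onset = residualize_onset(first, np.ones(3))
        assert np.allclose(onset, first - first.mean() + first.mean())

    def test_residuals_orthogonal_to_interrule_predictor(self, cohort):
        sessions, _truth, bank = cohort
        table = participant_item_table(sessions, bank)
        ok = table.dropna(subset=["onset", "inter"])
        r = np.corrcoef(ok["onset"], ok["inter"])[0, 1]
        assert abs(r) < 1e-8

    def test_swapped_direction_returns_residualized_inter(self):
        rng = np.random.default_rng(0)
        inter = rng.normal(10, 2, 50)
        first = 5 + 0.8 * inter + rng.normal(0, 1, 50)
        onset = residualize_onset(first, inter, direction="inter_on_first")
        # residual of inter is uncorrelated with first_click
        assert abs(np.corrcoef(onset, first)[0, 1]) < 1e-8


class TestParticipantAggregation:
    def test_mean_over_items(self):
        spec1 = make_item(2, item_id="i1", position=1)
        spec2 = make_item(2, item_id="i2", position=2)
        logs = [
            make_log(spec1, [("A", 2), ("A", 3), ("B", 7)], ("submit", 8)),   # inter 4
            make_log(spec2, [("A", 1), ("A", 2), ("B", 8)], ("submit", 9)),   # inter 6
        ]
        extra = [
            make_log(spec1, [("A", 1), ("A", 2), ("B", 4)], ("submit", 5), "p2"),
            make_log(spec2, [("A", 1), ("A", 3), ("B", 5)], ("submit", 6), "p2"),
        ]
        sessions = [
            SessionLog("p1", tuple(logs)),
            SessionLog("p2", tuple(extra)),
        ]
        lfts = participant_lfts(sessions, [spec1, spec2])
        assert lfts.loc["p1", "inter"] == pytest.approx(5.0)
        assert lfts.loc["p1", "n_items"] == 2

    def test_cohort_lfts_positive_and_finite(self, cohort_features):
        features, _long, _truth = cohort_features
        for col in ("tot", "onset", "inter", "intra"):
            vals = features[col].dropna()
            assert len(vals) >= 195
            assert np.isfinite(vals).all() and (vals > 0).all()

    def test_extraction_config_round_trip(self):
        cfg = ExtractionConfig(inter_denominator="rules")
        assert cfg.inter_denominator == "rules"
        assert cfg.onset_direction == "first_on_inter"
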