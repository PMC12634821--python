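"""Metric scores, sigma estimation, ranking and the top-differential selection."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pepmatch as pm
from pepmatch.errors import DegenerateInputError
from pepmatch.scoring import SIGMA_FLOOR


class TestEstimateSigma:
    def test_two_point_hand_computation(self):
        assert pm.estimate_sigma([-1.0, 1.0]) == pytest.approx(math.sqrt(2))

    def test_degenerate_spread_clamped(self):
        assert pm.estimate_sigma([0.0, 0.0, 0.0]) == SIGMA_FLOOR

    def test_single_value_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            pm.estimate_sigma([1.0])

    def test_nans_excluded(self):
        assert pm.estimate_sigma([-1.0, float("nan"), 1.0]) == pytest.approx(
            math.sqrt(2)
        )

    def test_monte_carlo_standard_normal(self):
        rng = np.random.default_rng(41)
        assert pm.estimate_sigma(rng.normal(0, 1, 10_000)) == pytest.approx(
            1.0, abs=0.03
        )


class TestMetric1:
    @pytest.mark.parametrize("sigma", [0.1, 1.0, 10.0])
    def test_maximum_at_zero_delta(self, sigma):
        assert pm.metric1_score(0.0, sigma) == 10.0

    def test_value_at_one_sigma(self):
        assert pm.metric1_score(1.0, 1.0) == pytest.approx(10 * math.exp(-0.5))

    def test_far_tail_vanishes(self):
        assert pm.metric1_score(100.0, 1.0) < 1e-300

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(-50, 50), st.floats(0.01, 10))
    def test_even_in_delta(self, x, sigma):
        assert pm.metric1_score(x, sigma) == pytest.approx(
            pm.metric1_score(-x, sigma), rel=1e-12
        )


class TestMetric2:
    def test_half_maximum_at_center(self):
        assert pm.metric2_score(0.5) == pytest.approx(50.0, abs=1e-9)

    def test_value_at_zero_error(self):
        assert pm.metric2_score(0.0) == pytest.approx(99.3307, abs=1e-4)

    def test_value_at_tolerance_edge(self):
        assert pm.metric2_score(1.0) == pytest.approx(0.6693, abs=1e-4)

    def test_bounded_and_strictly_decreasing(self):
        grid = np.linspace(0, 5, 10_000)
        scores = pm.metric2_score(grid)
        assert np.all(scores <= 100.0)
        assert np.all(np.diff(scores) < 0)

    def test_absolute_value_default_vs_signed_flag(self):
        assert pm.metric2_score(-0.3) == pytest.approx(pm.metric2_score(0.3))
        assert pm.metric2_score(-0.3, signed=True) > 50.0


class TestMetric3:
    def test_half_maximum_at_center(self):
        assert pm.metric3_score(2.0) == pytest.approx(2.5, abs=1e-9)

    def test_high_intensity_approaches_maximum(self):
        assert pm.metric3_score(10.0) == pytest.approx(4.99832, abs=1e-4)

    def test_low_intensity_vanishes(self):
        assert pm.metric3_score(-10.0) == pytest.approx(0.0, abs=1e-4)

    def test_bounded_and_strictly_increasing(self):
        grid = np.linspace(-50, 50, 10_000)
        assert np.all(pm.metric3_score(grid) <= 5.0)
        # strict monotonicity checked where the sigmoid has not saturated
        # to its float limit
        unsat = np.linspace(-20, 20, 10_000)
        assert np.all(np.diff(pm.metric3_score(unsat)) > 0)


def make_candidates(rows):
    """rows: (peak_id, mz, accession, sequence, delta_mass, delta_fc, norm_int)"""
    df = pd.DataFrame(
        rows,
        columns=["peak_id", "mz", "accession", "sequence", "delta_mass",
                 "delta_fold_change", "maldi_intensity_norm"],
    )
    df["modification_annotation"] = ""
    df["maldi_intensity"] = 2.0 ** df["maldi_intensity_norm"]
    df["fold_change_maldi"] = 0.0
    return df


class TestScoreAndRank:
    def test_total_is_sum_and_bounded(self, config):
        cands = make_candidates([(0, 945.5, "A", "SEQK", 0.1, 0.2, 1.0)])
        scored = pm.score_and_rank(cands, sigma=1.0, config=config)
        row = scored.iloc[0]
        assert row["total_score"] == pytest.approx(
            row["metric1"] + row["metric2"] + row["metric3"]
        )
        assert 0 <= row["total_score"] <= 115

    def test_equal_totals_tie_broken_by_smaller_mass_error(self, config):
        from pepmatch.scoring import _rank_within

        df = pd.DataFrame({
            "peak_id": [0, 0],
            "total_score": [80.1, 80.1],
            "_abs_dm": [0.4, 0.2],
            "maldi_intensity": [1.0, 1.0],
            "accession": ["A", "B"],
            "sequence": ["AAAK", "BBBK"],
        })
        ranks = _rank_within(df, "peak_id")
        assert ranks.tolist() == [2, 1]

    def test_exact_total_tie_broken_by_abs_dm_then_accession(self, config):
        # identical scores on all metrics: tie falls through to accession
        cands = make_candidates([
            (0, 945.5, "B", "AAAK", 0.3, 0.1, 1.0),
            (0, 945.5, "A", "AAAK", 0.3, 0.1, 1.0),
        ])
        scored = pm.score_and_rank(cands, sigma=1.0, config=config)
        assert scored[scored["rank_within_peak"] == 1]["accession"].iloc[0] == "A"

    def test_single_candidate_rank_one_everywhere(self, config):
        cands = make_candidates([(0, 945.5, "A", "AAAK", 0.1, 0.1, 1.0)])
        scored = pm.score_and_rank(cands, sigma=1.0, config=config)
        assert scored["rank_within_peak"].iloc[0] == 1
        assert scored["rank_within_protein_group"].iloc[0] == 1

    def test_ranks_are_permutations_within_groups(self, config, default_run):
        scored, _ = default_run
        for _, grp in scored.scored.groupby("peak_id"):
            assert sorted(grp["rank_within_peak"]) == list(range(1, len(grp) + 1))
        for _, grp in scored.scored.groupby("accession"):
            assert sorted(grp["rank_within_protein_group"]) == list(
                range(1, len(grp) + 1)
            )

    def test_missing_delta_fc_scored_zero_and_flagged(self, config):
        cands = make_candidates([(0, 945.5, "A", "AAAK", 0.1, float("nan"), 1.0)])
        scored = pm.score_and_rank(cands, sigma=1.0, config=config)
        assert scored["metric1"].iloc[0] == 0.0
        assert bool(scored["metric1_unavailable"].iloc[0])

    def test_deterministic_under_row_shuffle(self, config):
        rng = np.random.default_rng(43)
        rows = [
            (int(i // 3), 900.0 + i, f"P{i % 7}", "AAAK",
             float(rng.uniform(-1, 1)), float(rng.normal()), float(rng.normal()))
            for i in range(60)
        ]
        a = pm.score_and_rank(make_candidates(rows), 1.0, config)
        shuffled = [rows[i] for i in rng.permutation(60)]
        b = pm.score_and_rank(make_candidates(shuffled), 1.0, config)
        cols = ["peak_id", "accession", "delta_mass", "rank_within_peak"]
        pd.testing.assert_frame_equal(
            a[cols].reset_index(drop=True), b[cols].reset_index(drop=True)
        )

    def test_planted_true_peptide_ranks_first(self, default_run):
        """On the default synthetic instance the planted peptide tops >= 90%
        of its peaks' candidate lists."""
        result, truth = default_run
        report = pm.evaluate_recovery(result.scored, truth, result.retained_peak_ids)
        assert report.top1_recovery >= 0.90


class TestMetric4:
    def make_scored(self, n_peaks, rng):
        rows = []
        for pid in range(n_peaks):
            rows.append({
                "peak_id": pid,
                "maldi_intensity_norm": float(rng.normal()),
                "fold_change_maldi": float(rng.normal(0, 1.5)),
            })
        return pd.DataFrame(rows)

    def test_selects_exactly_n(self):
        scored = self.make_scored(100, np.random.default_rng(47))
        sel = pm.metric4_top_differential(scored, n=10)
        assert len(sel.peak_ids) == 10
        assert len(set(sel.peak_ids)) == 10

    def test_fewer_eligible_than_n_returns_all(self):
        scored = self.make_scored(4, np.random.default_rng(53))
        sel = pm.metric4_top_differential(scored, n=10, abundance_fraction=1.0)
        assert len(sel.peak_ids) == 4

    def test_low_abundance_high_fc_peak_excluded(self):
        scored = pd.DataFrame({
            "peak_id": [0, 1, 2, 3],
            "maldi_intensity_norm": [2.0, 1.5, 1.0, -5.0],
            "fold_change_maldi": [0.5, 0.4, 0.3, 9.9],
        })
        sel = pm.metric4_top_differential(scored, n=2, abundance_fraction=0.5)
        assert 3 not in sel.peak_ids
        assert sel.peak_ids == [0, 1]

    def test_deterministic_selection(self):
        scored = self.make_scored(50, np.random.default_rng(59))
        a = pm.metric4_top_differential(scored, n=10)
        b = pm.metric4_top_differential(scored.sample(frac=1, random_state=0), n=10)
        assert a.peak_ids == b.peak_ids
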