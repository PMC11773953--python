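"""Validation ops: held-out rates, DEG tests, concordance, method comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mirtarget as mt
from mirtarget.datasets import published_concordance_entries
from mirtarget.validation import ConcordanceEntry, pairwise_overlap_matrix


def db(role, pairs, name="db"):
    return mt.InteractionDB(name, role, frozenset(pairs))


class TestValidationRate:
    def test_heldout_subset_of_training_validates_nothing(self):
        sig = {("m1", "G1"), ("m2", "G2")}
        held = db("validation", {("m1", "G1")})
        train = db("training", {("m1", "G1"), ("m9", "G9")})
        v = mt.validation_rate(sig, [held], [train])
        assert v.n_validated == 0
        assert v.rate_pct == 0.0

    def test_fully_confirmed_set_scores_100(self):
        sig = {("m1", "G1"), ("m2", "G2")}
        v = mt.validation_rate(sig, [db("validation", sig)], [db("training", set())])
        assert v.rate_pct == 100.0

    def test_percentage_to_two_decimals(self):
        sig = {("m", f"G{i}") for i in range(871)}
        confirmed = set(list(sorted(sig))[:28])
        v = mt.validation_rate(sig, [db("validation", confirmed)],
                               [db("training", set())])
        assert v.n_validated == 28
        assert v.rate_pct == 3.21

    def test_empty_significant_set_rejected(self):
        with pytest.raises(ValueError):
            mt.validation_rate(set(), [], [])

    def test_rate_monotone_in_validated_count(self):
        sig = {("m", f"G{i}") for i in range(50)}
        train = db("training", set())
        rates = []
        for k in (5, 10, 20):
            held = db("validation", set(list(sorted(sig))[:k]))
            rates.append(mt.validation_rate(sig, [held], [train]).rate_pct)
        assert rates == sorted(rates)


class TestDegTtest:
    def _dataset(self, control, treated, genes=None):
        genes = genes or [f"G{i}" for i in range(control.shape[1])]
        return mt.PerturbationDataset(
            mirna_id="mir-1",
            cohort_context="C01",
            control=pd.DataFrame(control, columns=genes),
            treated=pd.DataFrame(treated, columns=genes),
        )

    def test_null_experiment_deg_fraction_near_alpha(self):
        rng = np.random.default_rng(8)
        ds = self._dataset(rng.normal(5, 1, (20, 1000)), rng.normal(5, 1, (20, 1000)))
        deg = mt.deg_ttest(ds)
        frac = len(deg.degs()) / len(deg.table)
        assert 0.03 <= frac <= 0.07

    def test_large_shift_is_detected_with_direction(self):
        rng = np.random.default_rng(9)
        control = rng.normal(5, 0.5, (20, 10))
        treated = rng.normal(5, 0.5, (20, 10))
        treated[:, 0] += 5.0   # up-regulated target
        treated[:, 1] -= 5.0   # down-regulated target
        deg = mt.deg_ttest(self._dataset(control, treated))
        assert {"G0", "G1"} <= deg.degs()
        assert deg.direction_of("G0") == "up"
        assert deg.direction_of("G1") == "down"

    def test_direction_follows_sign_of_mean_difference(self):
        control = np.full((3, 1), 5.0) + [[0.0], [0.1], [-0.1]]
        treated = np.full((3, 1), 4.0) + [[0.0], [0.1], [-0.1]]
        deg = mt.deg_ttest(self._dataset(control, treated))
        assert deg.direction_of("G0") == "down"

    def test_constant_gene_excluded(self):
        rng = np.random.default_rng(10)
        control = rng.normal(5, 1, (10, 3))
        treated = rng.normal(5, 1, (10, 3))
        control[:, 2] = 4.0
        treated[:, 2] = 4.0
        deg = mt.deg_ttest(self._dataset(control, treated))
        assert "G2" in deg.excluded
        assert "G2" not in set(deg.table.index)

    def test_deg_sets_nest_across_alpha(self):
        rng = np.random.default_rng(11)
        control = rng.normal(5, 1, (15, 300))
        treated = rng.normal(5.2, 1, (15, 300))
        deg = mt.deg_ttest(self._dataset(control, treated))
        assert deg.degs(0.01) <= deg.degs(0.05)

    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(12)
        control = rng.normal(5, 1, (12, 5))
        treated = rng.normal(5, 2, (14, 5))
        deg = mt.deg_ttest(self._dataset(control, treated))
        t, p = stats.ttest_ind(treated[:, 0], control[:, 0], equal_var=False)
        assert deg.table.at["G0", "t"] == pytest.approx(t, abs=1e-12)
        assert deg.table.at["G0", "p"] == pytest.approx(p, abs=1e-12)


class TestOverlapStats:
    def test_integer_percentages(self):
        predicted = {f"P{i}" for i in range(569)}
        known = {f"K{i}" for i in range(3411)}
        degs = set(list(sorted(predicted))[:31]) | set(list(sorted(known))[:130])
        row = mt.overlap_stats(predicted, known, degs)
        assert (row.predicted_overlap, row.predicted_overlap_pct) == (31, 5)
        assert (row.known_overlap, row.known_overlap_pct) == (130, 4)

    def test_disjoint_sets_give_zero(self):
        row = mt.overlap_stats({"A"}, {"B"}, {"C"})
        assert row.predicted_overlap == row.known_overlap == 0
        assert row.predicted_overlap_pct == row.known_overlap_pct == 0

    def test_empty_source_rejected(self):
        with pytest.raises(ValueError):
            mt.overlap_stats(set(), {"B"}, {"C"})


class TestDirectionConcordance:
    def entry(self, direction, sign, perturbation="overexpression"):
        return ConcordanceEntry("mir-x", "G", "C01", direction, sign, perturbation)

    @pytest.mark.parametrize("direction, sign, expected", [
        ("up", "positive", True),
        ("up", "negative", False),
        ("down", "negative", True),
        ("down", "positive", False),
    ])
    def test_overexpression_rule(self, direction, sign, expected):
        assert self.entry(direction, sign).is_concordant() is expected

    @pytest.mark.parametrize("direction, sign, expected", [
        ("up", "negative", True),
        ("down", "positive", True),
        ("up", "positive", False),
    ])
    def test_knockdown_rule_is_mirrored(self, direction, sign, expected):
        assert self.entry(direction, sign, "knockdown").is_concordant() is expected

    def test_published_entries_summary(self):
        summary = mt.direction_concordance(published_concordance_entries())
        assert summary.total == 88
        assert summary.concordant == 41
        assert summary.percentage == 47

    def test_missing_sign_entries_skipped(self):
        entries = [self.entry("up", "positive"), self.entry("up", None)]
        summary = mt.direction_concordance(entries)
        assert summary.total == 1
        assert summary.n_skipped == 1

    def test_sign_reversal_complements_concordance(self):
        entries = published_concordance_entries()
        flipped = [
            ConcordanceEntry(
                e.mirna, e.gene, e.cohort_context, e.direction,
                "positive" if e.correlation_sign == "negative" else "negative",
                e.perturbation,
            )
            for e in entries
        ]
        a = mt.direction_concordance(entries)
        b = mt.direction_concordance(flipped)
        assert a.concordant + b.concordant == a.total


class TestPairedOverlapTtest:
    def test_identical_vectors_show_no_difference(self):
        assert mt.paired_overlap_ttest([5, 9, 2], [5, 9, 2]) == (0.0, 1.0)

    def test_hand_computed_constant_shift(self):
        # differences (1,2,3,4): mean 2.5, sd sqrt(5/3), t = 2.5/(sd/2)
        a = [2.0, 4.0, 6.0, 8.0]
        b = [1.0, 2.0, 3.0, 4.0]
        t, p = mt.paired_overlap_ttest(a, b)
        expected_t = 2.5 / (np.sqrt(5 / 3) / 2)
        assert t == pytest.approx(expected_t, abs=1e-12)
        st_t, st_p = stats.ttest_rel(a, b)
        assert (t, p) == pytest.approx((st_t, st_p), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mt.paired_overlap_ttest([1, 2], [1, 2, 3])

    def test_method_matrix_is_symmetric(self):
        rng = np.random.default_rng(13)
        percents = {m: rng.uniform(0, 30, size=9) for m in "ABCD"}
        mat = pairwise_overlap_matrix(percents)
        assert np.allclose(mat.to_numpy(), mat.to_numpy().T, equal_nan=True)
        assert np.isnan(np.diag(mat.to_numpy())).all()


class TestSelectMatchedPredictions:
    def test_full_selection_returns_everything(self):
        scores = {"G1": 0.5, "G2": 0.1}
        assert mt.select_matched_predictions(scores, 2) == {"G1", "G2"}

    def test_ties_break_lexicographically(self):
        scores = {"G1": 0.9, "G2": 0.5, "G3": 0.9}
        assert mt.select_matched_predictions(scores, 2) == {"G1", "G3"}

    def test_matches_bruteforce_sort(self):
        rng = np.random.default_rng(14)
        genes = [f"G{i:03d}" for i in range(40)]
        scores = dict(zip(genes, rng.choice([0.1, 0.5, 0.9], size=40)))
        for k in (1, 7, 20, 40):
            expected = set(
                [g for g, _ in sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))][:k]
            )
            assert mt.select_matched_predictions(scores, k) == expected

    def test_k_beyond_universe_rejected(self):
        with pytest.raises(ValueError):
            mt.select_matched_predictions({"G1": 1.0}, 2)
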