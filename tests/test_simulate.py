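"""Synthetic-data generator: planted signal, nulls, determinism, fixtures."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mirtarget as mt
from mirtarget import io as mio


def _panel_of(panels, cohort_id):
    return next(p for p in panels if p.cohort_id == cohort_id)


class TestSimulatePanels:
    def test_same_seed_reproduces_everything(self):
        config = mt.SimulationConfig(
            n_cohorts=3, n_mirnas=8, n_genes=20, samples_per_cohort=30, seed=5,
            n_planted_training=6, n_planted_heldout=3, n_planted_undiscovered=3,
        )
        p1, t1 = mt.simulate_panels(config)
        p2, t2 = mt.simulate_panels(config)
        assert t1 == t2
        for a, b in zip(p1, p2):
            pd.testing.assert_frame_equal(a.mirna, b.mirna)
            pd.testing.assert_frame_equal(a.genes, b.genes)

    def test_noise_free_planted_pair_has_near_perfect_correlation(self):
        config = mt.SimulationConfig(
            n_cohorts=2, n_mirnas=5, n_genes=10, samples_per_cohort=100,
            noise_sd=1e-9, dropout_prob=0.0, frac_active_cohorts=1.0,
            n_planted_training=5, n_planted_heldout=0, n_planted_undiscovered=0,
            baseline_range=(10.0, 12.0), seed=3,
        )
        panels, truth = mt.simulate_panels(config)
        for pair in truth.pairs:
            for cohort in pair.active_cohorts:
                panel = _panel_of(panels, cohort)
                r = mt.pearson_r(panel.mirna[pair.mirna], panel.genes[pair.gene])
                assert abs(r) > 0.99
                assert np.sign(r) == pair.sign

    def test_non_planted_pairs_are_null(self):
        # at n=500 a null Pearson r has sd ~ 1/sqrt(499); |r| < 0.2 is ~4.5 sd
        config = mt.SimulationConfig(
            n_cohorts=1, n_mirnas=10, n_genes=50, samples_per_cohort=500,
            dropout_prob=0.0, n_planted_training=0, n_planted_heldout=0,
            n_planted_undiscovered=0, seed=13,
        )
        panels, _ = mt.simulate_panels(config)
        table = mt.build_feature_table(panels, min_coexpressing=10)
        assert (table.values.abs() < 0.2).all().all()

    def test_null_pair_correlations_are_calibrated(self):
        """|r| exceeds the two-sided 5% critical value for ~5% of null pairs."""
        config = mt.SimulationConfig(
            n_cohorts=1, n_mirnas=30, n_genes=60, samples_per_cohort=120,
            dropout_prob=0.0, n_planted_training=0, n_planted_heldout=0,
            n_planted_undiscovered=0, seed=29,
        )
        panels, _ = mt.simulate_panels(config)
        table = mt.build_feature_table(panels, min_coexpressing=10)
        n = config.samples_per_cohort
        # r * sqrt(n-2) / sqrt(1-r^2) ~ t(n-2) under the null
        t_crit = stats.t.ppf(0.975, n - 2)
        r_crit = t_crit / np.sqrt(n - 2 + t_crit**2)
        frac = float((table.values.abs() > r_crit).mean().mean())
        assert table.n_pairs >= 1000
        assert 0.03 <= frac <= 0.07

    def test_planted_sign_recovery_on_clean_data(self):
        config = mt.SimulationConfig(
            n_cohorts=4, n_mirnas=10, n_genes=40, samples_per_cohort=100,
            dropout_prob=0.0, noise_sd=0.4, effect_size_range=(1.2, 2.0),
            n_planted_training=20, n_planted_heldout=0, n_planted_undiscovered=0,
            seed=17,
        )
        panels, truth = mt.simulate_panels(config)
        for pair in truth.pairs:
            for cohort in pair.active_cohorts:
                panel = _panel_of(panels, cohort)
                r = mt.pearson_r(panel.mirna[pair.mirna], panel.genes[pair.gene])
                assert np.sign(r) == pair.sign

    def test_matrices_are_nonnegative_and_share_samples(self, tiny_panels):
        panels, _ = tiny_panels
        for p in panels:
            assert (p.mirna.to_numpy() >= 0).all()
            assert (p.genes.to_numpy() >= 0).all()
            assert list(p.mirna.index) == list(p.genes.index)

    def test_dropout_introduces_zeros(self):
        config = mt.SimulationConfig(
            n_cohorts=1, n_mirnas=5, n_genes=20, samples_per_cohort=200,
            dropout_prob=0.3, n_planted_training=0, n_planted_heldout=0,
            n_planted_undiscovered=0, seed=2,
        )
        panels, _ = mt.simulate_panels(config)
        zero_frac = float((panels[0].genes.to_numpy() == 0).mean())
        assert 0.25 <= zero_frac <= 0.35

    def test_rejects_overfull_planting(self):
        with pytest.raises(ValueError, match="exceeds"):
            mt.SimulationConfig(n_mirnas=2, n_genes=2, n_planted_training=5,
                                n_planted_heldout=0, n_planted_undiscovered=0)

    @pytest.mark.parametrize("bad", [
        dict(n_cohorts=0), dict(dropout_prob=1.5), dict(noise_sd=-1),
        dict(effect_size_range=(2.0, 1.0)), dict(samples_per_cohort=1),
    ])
    def test_rejects_invalid_config(self, bad):
        with pytest.raises(ValueError):
            mt.SimulationConfig(**bad)

    def test_tiers_are_disjoint(self, study):
        _, _, truth = study
        training = truth.pairs_by_tier("training")
        heldout = truth.pairs_by_tier("heldout")
        undiscovered = truth.pairs_by_tier("undiscovered")
        assert not training & heldout
        assert not training & undiscovered
        assert not heldout & undiscovered


class TestSimulatePerturbation:
    @pytest.fixture()
    def truth(self, tiny_panels):
        return tiny_panels[1]

    def test_zero_shift_is_a_null_experiment(self, truth):
        mirna = truth.pairs[0].mirna
        cohort = sorted(truth.pairs[0].active_cohorts)[0]
        ds = mt.simulate_perturbation(truth, mirna, cohort, n_per_group=20,
                                      shift=0.0, seed=3)
        deg = mt.deg_ttest(ds)
        frac = len(deg.degs()) / len(deg.table)
        assert frac < 0.12  # ~alpha at 40 genes

    def test_strong_shift_makes_target_a_deg_with_planted_direction(self, truth):
        pair = truth.pairs[0]
        cohort = sorted(pair.active_cohorts)[0]
        ds = mt.simulate_perturbation(truth, pair.mirna, cohort, n_per_group=20,
                                      shift=5.0, noise_sd=0.5, seed=4)
        deg = mt.deg_ttest(ds)
        assert pair.gene in deg.degs()
        expected = "up" if pair.sign > 0 else "down"
        assert deg.direction_of(pair.gene) == expected

    def test_knockdown_mirrors_overexpression(self, truth):
        pair = truth.pairs[0]
        cohort = sorted(pair.active_cohorts)[0]
        over = mt.simulate_perturbation(truth, pair.mirna, cohort, shift=5.0, seed=5)
        down = mt.simulate_perturbation(truth, pair.mirna, cohort, shift=5.0, seed=5,
                                        perturbation="knockdown")
        d_over = mt.deg_ttest(over).direction_of(pair.gene)
        d_down = mt.deg_ttest(down).direction_of(pair.gene)
        assert {d_over, d_down} == {"up", "down"}

    def test_unknown_mirna_rejected(self, truth):
        with pytest.raises(KeyError):
            mt.simulate_perturbation(truth, "mir-none", truth.cohorts[0])


class TestWriteFixtures:
    def test_panels_round_trip(self, tiny_panels, tmp_path):
        panels, truth = tiny_panels
        ds = mt.simulate_perturbation(truth, truth.pairs[0].mirna,
                                      truth.cohorts[0], seed=1)
        mt.write_fixtures(panels, truth, [ds], tmp_path)
        back = mio.read_panels_dir(tmp_path / "panels")
        assert [p.cohort_id for p in back] == [p.cohort_id for p in panels]
        for a, b in zip(back, panels):
            pd.testing.assert_frame_equal(a.mirna, b.mirna)
            pd.testing.assert_frame_equal(a.genes, b.genes)

    def test_three_tier_database_files(self, tiny_panels, tmp_path):
        panels, truth = tiny_panels
        paths = mt.write_fixtures(panels, truth, [], tmp_path)
        assert len(paths["databases"]) == 3
        db = mt.load_interaction_db(str(tmp_path / "databases" / "training.tsv"),
                                    "training", "training")
        assert db.pairs == frozenset(truth.pairs_by_tier("training"))

    def test_empty_planting_gives_header_only_databases(self, tmp_path):
        config = mt.SimulationConfig(
            n_cohorts=1, n_mirnas=3, n_genes=5, samples_per_cohort=10,
            n_planted_training=0, n_planted_heldout=0, n_planted_undiscovered=0,
            seed=0,
        )
        panels, truth = mt.simulate_panels(config)
        mt.write_fixtures(panels, truth, [], tmp_path)
        lines = (tmp_path / "databases" / "training.tsv").read_text().splitlines()
        assert lines == ["mirna\tgene"]

    def test_fixture_bytes_are_deterministic(self, tmp_path):
        config = mt.SimulationConfig(
            n_cohorts=2, n_mirnas=4, n_genes=6, samples_per_cohort=12, seed=9,
            n_planted_training=3, n_planted_heldout=1, n_planted_undiscovered=1,
        )
        blobs = []
        for sub in ("a", "b"):
            panels, truth = mt.simulate_panels(config)
            paths = mt.write_fixtures(panels, truth, [], tmp_path / sub)
            blob = b"".join(
                open(p, "rb").read() for group in sorted(paths) for p in paths[group]
            )
            blobs.append(blob)
        assert blobs[0] == blobs[1]
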