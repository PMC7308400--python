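"""Tests for the NB/ZINB simulators, DE injection, depth pairs and
multi-type mixtures."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from rogue import (
    DepthPairSpec,
    MultitypeScenario,
    Platform,
    SimSpec,
    dropout_probability,
    inject_de_genes,
    simulate_depth_pair,
    simulate_multitype,
    simulate_nb,
    simulate_zinb,
)


class TestSimulateNB:
    def test_sample_means_track_latent_means(self):
        m, means = simulate_nb(SimSpec(n_genes=8000, n_cells=1000, seed=1))
        sample_means = m.values.mean(axis=1)
        slope = np.polyfit(means, sample_means, 1)[0]
        assert 0.98 <= slope <= 1.02

    def test_nb_moment_identity_on_high_expression_genes(self):
        r = 10.0
        m, means = simulate_nb(
            SimSpec(n_genes=4000, n_cells=2000, dispersion_r=r, seed=2)
        )
        top = means >= np.quantile(means, 0.9)
        emp_var = m.values[top].var(axis=1, ddof=1)
        expected = means[top] + means[top] ** 2 / r
        ratio = emp_var / expected
        assert abs(np.median(ratio) - 1.0) < 0.1

    def test_poisson_limit_at_large_dispersion(self):
        m, means = simulate_nb(
            SimSpec(n_genes=500, n_cells=4000, dispersion_r=1e6, seed=3)
        )
        high = means >= np.quantile(means, 0.8)
        ratio = m.values[high].var(axis=1, ddof=1) / m.values[high].mean(axis=1)
        assert abs(np.median(ratio) - 1.0) < 0.05

    def test_deterministic_given_seed(self):
        a, ma = simulate_nb(SimSpec(n_genes=300, n_cells=50, seed=9))
        b, mb = simulate_nb(SimSpec(n_genes=300, n_cells=50, seed=9))
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(ma, mb)

    @pytest.mark.parametrize("bad", [dict(n_genes=0), dict(n_cells=-1),
                                     dict(dispersion_r=0.0), dict(sigma=0.0)])
    def test_invalid_spec(self, bad):
        with pytest.raises(ValueError):
            SimSpec(**bad)


class TestSimulateZINB:
    def test_dropout_at_median_expression(self):
        # gamma0 = -1.5, gamma1 = 1/median(E), E = median(E):
        # P = sigm(-(-1.5 + 1)) = sigm(0.5)
        means = np.array([1.0, 2.0, 3.0])
        p = dropout_probability(means, gamma0=-1.5)
        assert p[1] == pytest.approx(expit(0.5))
        assert p[1] == pytest.approx(0.6225, abs=1e-4)

    def test_dropout_monotone_decreasing_and_vanishing(self):
        means = np.logspace(-2, 2, 50)
        p = dropout_probability(means, gamma0=-1.5, gamma1=0.5)
        assert (np.diff(p) < 0).all()
        assert dropout_probability(np.array([1e6]), gamma0=-1.5, gamma1=0.5)[0] < 1e-6

    def test_zero_excess_matches_dropout_probability(self):
        r = 10.0
        spec = SimSpec(n_genes=2000, n_cells=2000, dispersion_r=r, zinb=True, seed=4)
        m, p_drop = simulate_zinb(spec)
        # the generator draws means first, so the seed-4 stream head recovers them
        means = np.random.default_rng(4).lognormal(0, 2, 2000)
        nb_zero = (r / (r + means)) ** r
        expected = p_drop + (1 - p_drop) * nb_zero
        observed = (m.values == 0).mean(axis=1)
        se = np.sqrt(expected * (1 - expected) / m.n_cells)
        check = np.abs(observed - expected) <= 5 * se + 1e-9
        assert check.mean() > 0.99

    def test_requires_zinb_flag(self):
        with pytest.raises(ValueError, match="zinb=True"):
            simulate_zinb(SimSpec(n_genes=10, n_cells=10, seed=1))

    def test_gamma1_override_validation(self):
        with pytest.raises(ValueError, match="gamma1"):
            SimSpec(n_genes=10, n_cells=10, gamma1=-0.5)

    def test_platform_is_full_length(self):
        m, _ = simulate_zinb(SimSpec(n_genes=50, n_cells=30, zinb=True, seed=6))
        assert m.platform is Platform.FULL_LENGTH


class TestInjectDE:
    def _base(self):
        return simulate_nb(SimSpec(n_genes=1000, n_cells=400, seed=7))

    def test_unselected_entries_untouched(self):
        m, means = self._base()
        out, truth, affected = inject_de_genes(
            m, means, 0.05, 0.25, dispersion_r=10, seed=8
        )
        de_rows = truth.index[truth.fold_change != 1.0]
        keep_rows = ~np.isin(m.gene_ids, de_rows)
        keep_cols = ~np.isin(m.cell_ids, affected)
        assert np.array_equal(out.values[keep_rows], m.values[keep_rows])
        assert np.array_equal(out.values[:, keep_cols], m.values[:, keep_cols])

    def test_full_cell_fraction_fold_change_realized(self):
        # well-expressed base (all latent means = 20) so the empirical mean
        # ratio estimates the fold change tightly
        from conftest import make_matrix

        rng = np.random.default_rng(9)
        means = np.full(50, 20.0)
        m = make_matrix(rng.negative_binomial(10, 10 / 30, size=(50, 400)))
        out, truth, _ = inject_de_genes(
            m, means, 1 / m.n_genes, 1.0, dispersion_r=10,
            fc_mu=np.log(4.0), fc_sigma=0.0, seed=9,
        )
        gene = truth.index[truth.fold_change != 1.0][0]
        i = list(m.gene_ids).index(gene)
        realized = out.values[i].mean() / m.values[i].mean()
        assert realized == pytest.approx(4.0, rel=0.15)
        assert bool(truth.loc[gene, "is_de"])

    def test_small_fold_change_not_ground_truth_de(self):
        m, means = self._base()
        _, truth, _ = inject_de_genes(
            m, means, 1 / m.n_genes, 1.0, dispersion_r=10,
            fc_mu=np.log(1.2), fc_sigma=0.0, seed=10,
        )
        assert not truth.is_de.any()

    def test_dilution_by_cell_fraction_enters_truth_rule(self):
        # fc = 4 in 10% of cells gives realized ratio 1.3 < 1.5: not DE
        m, means = self._base()
        _, truth, _ = inject_de_genes(
            m, means, 1 / m.n_genes, 0.1, dispersion_r=10,
            fc_mu=np.log(4.0), fc_sigma=0.0, seed=11,
        )
        assert not truth.is_de.any()

    def test_byte_identical_truth_across_runs(self):
        m, means = self._base()
        _, t1, a1 = inject_de_genes(m, means, 0.1, 0.5, dispersion_r=10, seed=12)
        _, t2, a2 = inject_de_genes(m, means, 0.1, 0.5, dispersion_r=10, seed=12)
        pd.testing.assert_frame_equal(t1, t2)
        assert np.array_equal(a1, a2)

    def test_nothing_to_inject_errors(self):
        m, means = self._base()
        with pytest.raises(ValueError, match="no gene"):
            inject_de_genes(m, means, 1e-5, 0.5, dispersion_r=10, seed=13)


class TestDepthPair:
    def test_depth_ratio_of_totals(self):
        spec = DepthPairSpec(
            base=SimSpec(n_genes=3000, n_cells=300, seed=14), delta=10.0
        )
        m, labels = simulate_depth_pair(spec)
        totals = m.values.sum(axis=0)
        r1 = np.median(totals[(labels == "replicate1").to_numpy()])
        r2 = np.median(totals[(labels == "replicate2").to_numpy()])
        assert r2 / r1 == pytest.approx(10.0, rel=0.15)

    def test_unit_delta_replicates_indistinguishable(self):
        spec = DepthPairSpec(
            base=SimSpec(n_genes=3000, n_cells=300, seed=15), delta=1.0
        )
        m, labels = simulate_depth_pair(spec)
        totals = m.values.sum(axis=0)
        mask = (labels == "replicate1").to_numpy()
        _, p = stats.mannwhitneyu(totals[mask], totals[~mask])
        assert p > 0.05

    def test_invalid_delta(self):
        with pytest.raises(ValueError, match="delta"):
            DepthPairSpec(base=SimSpec(n_genes=10, n_cells=10), delta=0.0)


class TestMultitype:
    def test_three_type_scenario_shapes_and_truth(self):
        sc = MultitypeScenario(
            n_genes=2000, cells_per_type=(150, 150, 150),
            n_varied_major=100, n_varied_minor=20, seed=16,
        )
        m, labels, truth = simulate_multitype(sc)
        assert m.n_cells == 450
        assert set(labels) == {"A", "B", "C"}
        assert (truth["pair"] == "A|BC").sum() == 100
        assert (truth["pair"] == "B|C").sum() == 20
        m2, labels2, truth2 = simulate_multitype(sc)
        assert np.array_equal(m.values, m2.values)
        pd.testing.assert_frame_equal(truth, truth2)

    def test_zero_varied_genes_pooled_is_pure(self):
        from rogue import rogue_statistic, run_se_pipeline

        sc = MultitypeScenario(
            n_genes=3000, cells_per_type=(200, 200, 200),
            n_varied_major=0, n_varied_minor=0, seed=17,
        )
        m, labels, truth = simulate_multitype(sc)
        assert truth.empty
        profile, sig = run_se_pipeline(m)
        assert rogue_statistic(profile.loc[sig, "ds"], 45.0) >= 0.99

    def test_minority_mixture_scores_below_pure_types(self):
        from rogue import rogue_statistic, run_se_pipeline

        sc = MultitypeScenario(
            n_genes=5000, cells_per_type=(30, 970),  # ~1:32 minority mixture
            n_varied_major=50, n_varied_minor=0, seed=18,
        )
        m, labels, _ = simulate_multitype(sc)

        def score(mat):
            profile, sig = run_se_pipeline(mat)
            return rogue_statistic(profile.loc[sig, "ds"], 45.0)

        pooled = score(m)
        pure_a = score(m.subset_cells((labels == "A").to_numpy()))
        pure_b = score(m.subset_cells((labels == "B").to_numpy()))
        assert pooled < pure_a
        assert pooled < pure_b

    def test_varied_counts_exceeding_genes_error(self):
        with pytest.raises(ValueError, match="exceed"):
            MultitypeScenario(n_genes=100, n_varied_major=90, n_varied_minor=20)
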