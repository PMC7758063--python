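import numpy as np
import pandas as pd
import pytest

import stratsim as st
from stratsim.polygenic import gradient_correlation


def fabricated_sumstats(dataset, pvals, betas=None):
    n = dataset.n_variants
    betas = np.ones(n) if betas is None else np.asarray(betas, float)
    table = pd.DataFrame(
        {
            "variant": np.arange(n),
            "chrom": dataset.variants["chrom"],
            "pos": dataset.variants["pos"],
            "frequency": dataset.variants["frequency"],
            "beta": betas,
            "se": np.ones(n),
            "chi2": np.ones(n),
            "p": np.asarray(pvals, float),
            "skipped": np.zeros(n, dtype=bool),
        }
    )
    return st.SummaryStats(table, dataset.n_individuals, 0)


class TestAscertainment:
    def test_matches_brute_force_min_p_scan(self, dataset_factory):
        # 7 variants, 2 causal windows on one chromosome
        pos = np.array([10e3, 40e3, 55e3, 90e3, 160e3, 190e3, 230e3])
        ds = dataset_factory(np.ones((4, 7), dtype=np.int8), positions=pos)
        pvals = np.array([3e-4, 1e-5, 2e-2, 4e-4, 1e-6, 5e-5, 0.5])
        stats = fabricated_sumstats(ds, pvals)
        causal = np.array([2, 5])  # windows centered at 55 kb and 190 kb
        sel = st.ascertain_lead_snps(stats, causal, ds, p_threshold=5e-4)
        # brute force: each variant belongs to the nearest causal variant;
        # keep the min-p sub-threshold variant per window
        oracle = {}
        for v in range(7):
            w = causal[np.argmin(np.abs(pos[v] - pos[causal]))]
            if abs(pos[v] - pos[w]) <= 50e3 and pvals[v] < 5e-4:
                if w not in oracle or pvals[v] < pvals[oracle[w]]:
                    oracle[w] = v
        assert dict(zip(sel["window"], sel["variant"])) == oracle

    def test_window_without_subthreshold_variant_contributes_nothing(
        self, dataset_factory
    ):
        pos = np.array([10e3, 40e3, 160e3])
        ds = dataset_factory(np.ones((4, 3), dtype=np.int8), positions=pos)
        stats = fabricated_sumstats(ds, [0.9, 0.2, 1e-5])
        sel = st.ascertain_lead_snps(stats, np.array([0, 2]), ds)
        assert list(sel["window"]) == [2]

    def test_causal_mode_applies_same_threshold(self, dataset_factory):
        pos = np.array([10e3, 12e3])
        ds = dataset_factory(np.ones((4, 2), dtype=np.int8), positions=pos)
        stats = fabricated_sumstats(ds, [1e-5, 1e-6])
        sel = st.ascertain_lead_snps(stats, np.array([0]), ds, mode="causal")
        assert list(sel["variant"]) == [0]  # causal kept even if not min-p
        stats2 = fabricated_sumstats(ds, [0.1, 1e-6])
        sel2 = st.ascertain_lead_snps(stats2, np.array([0]), ds, mode="causal")
        assert len(sel2) == 0

    def test_tie_broken_by_position(self, dataset_factory):
        pos = np.array([10e3, 20e3, 30e3])
        ds = dataset_factory(np.ones((4, 3), dtype=np.int8), positions=pos)
        stats = fabricated_sumstats(ds, [1e-5, 1e-5, 1e-4])
        sel = st.ascertain_lead_snps(stats, np.array([1]), ds)
        assert list(sel["variant"]) == [0]


class TestComputePgs:
    def test_zero_effects_zero_scores(self, dataset_factory):
        ds = dataset_factory(np.ones((5, 3), dtype=np.int8))
        res = st.compute_pgs({0: 0.0, 2: 0.0}, ds, np.zeros(5))
        assert np.all(res.scores == 0)

    def test_single_unit_effect_returns_dosage(self, dataset_factory):
        D = np.array([[0], [1], [2]], dtype=np.int8)
        ds = dataset_factory(D)
        res = st.compute_pgs({0: 1.0}, ds, np.zeros(3))
        assert np.array_equal(res.scores, D[:, 0].astype(float))

    def test_hand_computed_dot_products(self, dataset_factory):
        D = np.array([[0, 1, 2], [2, 0, 1]], dtype=np.int8)
        ds = dataset_factory(D)
        res = st.compute_pgs({0: 0.5, 1: -1.0, 2: 2.0}, ds, np.zeros(2))
        assert res.scores == pytest.approx([0 * 0.5 - 1 + 4, 1.0 + 0 + 2.0])

    def test_absent_variants_counted(self, dataset_factory):
        D = np.array([[0, 1], [0, 2]], dtype=np.int8)
        ds = dataset_factory(D)
        res = st.compute_pgs({0: 1.0, 1: 1.0}, ds, np.zeros(2))
        assert res.n_missing == 1  # variant 0 absent in the test sample


class TestResidualMap:
    def test_perfect_score_gives_flat_zero_map(self):
        g = np.random.default_rng(0).normal(size=60)
        res = st.PGSResult(
            g.copy(), g, np.repeat(np.arange(6), 10), "causal", "gwas", 10, 0
        )
        m = st.residual_map(res, n_demes=6)
        assert np.allclose(m["mean_residual"], 0.0)

    def test_location_shift_equivariance(self):
        g = np.random.default_rng(1).normal(size=60)
        res = st.PGSResult(
            g + 2.5, g, np.repeat(np.arange(6), 10), "causal", "gwas", 10, 0
        )
        m = st.residual_map(res, n_demes=6)
        assert np.allclose(m["mean_residual"], 2.5)

    def test_empty_deme_is_missing_not_zero(self):
        res = st.PGSResult(
            np.ones(4), np.zeros(4), np.array([0, 0, 2, 2]), "causal", "gwas", 1, 0
        )
        m = st.residual_map(res, n_demes=3)
        assert np.isnan(m["mean_residual"][1])
        assert m["n"][1] == 0


class TestAccuracy:
    def test_perfect_and_independent(self):
        rng = np.random.default_rng(2)
        g = rng.normal(size=2000)
        assert st.prediction_accuracy(g, g) == pytest.approx(1.0)
        assert st.prediction_accuracy(rng.normal(size=2000), g) < 0.01

    def test_zero_variance_score_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert st.prediction_accuracy(np.ones(10), np.arange(10.0)) == 0.0


class TestReestimate:
    def test_same_cohort_disallowed(self, grid22_cohort):
        train, _ = st.split_train_test(grid22_cohort, 0.5, seed=1)
        sel = pd.DataFrame({"window": [0], "variant": [0]})
        with pytest.raises(ValueError, match="independence"):
            st.reestimate_effects(
                sel,
                train,
                phenotype=np.zeros(train.n_individuals),
                discovery_individuals=train.individual_index,
            )

    def test_unrelated_reestimates_unbiased(self, dataset_factory):
        rng = np.random.default_rng(3)
        beta_true = 0.6
        ests = []
        for s in range(60):
            D = rng.binomial(2, 0.4, size=(400, 1)).astype(np.int8)
            ds = dataset_factory(D)
            y = beta_true * D[:, 0] + rng.normal(size=400)
            sel = pd.DataFrame({"window": [0], "variant": [0]})
            eff = st.reestimate_effects(sel, ds, phenotype=y)
            ests.append(eff["beta"][0])
        mc_se = np.std(ests) / np.sqrt(len(ests))
        assert np.mean(ests) == pytest.approx(beta_true, abs=2 * mc_se + 1e-9)
        assert eff["source"][0] == "unrelated_reestimated"

    def test_sib_mode_runs_and_marks_source(self, grid22_cohort):
        arch, _ = st.heritable_trait(grid22_cohort, "none", h2=0.8, seed=9)
        sibs = st.mate_within_deme(grid22_cohort, 8, seed=10)
        sibs = st.sib_phenotypes(
            sibs, arch, st.EnvironmentSpec("none", np.sqrt(0.2)), seed=11
        )
        sel = pd.DataFrame(
            {"window": arch.causal_indices, "variant": arch.causal_indices}
        )
        eff = st.reestimate_effects(sel, sibs)
        assert (eff["source"] == "sib_reestimated").all()
        assert len(eff) == arch.n_causal


class TestGradientCorrelation:
    def test_detects_linear_gradient(self):
        m = pd.DataFrame(
            {"row": np.repeat(np.arange(6), 6), "mean_residual": np.repeat(np.arange(6.0), 6)}
        )
        assert gradient_correlation(m) == pytest.approx(1.0)

    def test_flat_map_gives_zero(self):
        m = pd.DataFrame(
            {"row": np.repeat(np.arange(6), 6), "mean_residual": np.zeros(36)}
        )
        assert gradient_correlation(m) == 0.0
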