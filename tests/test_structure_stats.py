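import numpy as np
import pytest
from scipy import stats as sps

import stratsim as st


def textbook_wc_fst(D, labels):
    """Independent Weir & Cockerham (1984) oracle, scalar loops.

    Transcribes the a/b/c variance components variant by variant and
    deme by deme, then takes the ratio of sums.
    """
    labels = np.asarray(labels)
    demes = sorted(set(labels.tolist()))
    r = len(demes)
    ni = np.array([np.sum(labels == d) for d in demes], dtype=float)
    nbar = ni.mean()
    nc = (r * nbar - sum(n * n for n in ni) / (r * nbar)) / (r - 1)
    A = B = C = 0.0
    for v in range(D.shape[1]):
        p_i, h_i = [], []
        for d in demes:
            sub = D[labels == d, v]
            p_i.append(sub.sum() / (2 * len(sub)))
            h_i.append(np.mean(sub == 1))
        p_i, h_i = np.array(p_i), np.array(h_i)
        pbar = (ni * p_i).sum() / (r * nbar)
        s2 = (ni * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (ni * h_i).sum() / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        A += a
        B += b
        C += hbar / 2
    return A / (A + B + C)


def greedy_prune_oracle(D, window, step, thr):
    """Reference pruning: full correlation matrix + the greedy rule."""
    m = D.shape[1]
    R2 = np.corrcoef(D.T) ** 2
    kept = []
    for v in range(m):
        ok = True
        for k in kept:
            if v - k < window and R2[k, v] > thr:
                ok = False
                break
        if ok:
            kept.append(v)
    return kept


class TestLdPrune:
    def test_perfectly_correlated_pair_keeps_one(self, dataset_factory):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 3, 40)
        ds = dataset_factory(np.column_stack([x, x]))
        vs = st.VariantSet(np.array([0, 1]), "common")
        kept = st.ld_prune(ds, vs)
        assert list(kept.indices) == [0]  # earlier variant retained

    def test_independent_variants_untouched(self, dataset_factory):
        rng = np.random.default_rng(1)
        D = rng.binomial(2, 0.5, size=(500, 8)).astype(np.int8)
        ds = dataset_factory(D)
        vs = st.VariantSet(np.arange(8), "common")
        R2 = np.corrcoef(D.T.astype(float)) ** 2
        assert (R2[np.triu_indices(8, 1)] < 0.1).all()  # setup sanity
        assert list(st.ld_prune(ds, vs).indices) == list(range(8))

    def test_matches_reference_greedy_on_correlated_toy(self, dataset_factory):
        rng = np.random.default_rng(2)
        base = rng.binomial(2, 0.4, size=(200, 3)).astype(float)
        cols = [base[:, 0]]
        for j, noise in [(0, 0.1), (1, 0.0), (1, 2.0), (2, 0.2), (0, 2.0)]:
            cols.append(base[:, j] + rng.normal(0, noise, 200))
        D = np.clip(np.round(np.column_stack(cols)), 0, 2).astype(np.int8)
        ds = dataset_factory(D)
        vs = st.VariantSet(np.arange(D.shape[1]), "common")
        kept = st.ld_prune(ds, vs, window_size=6, step=1, r2_threshold=0.1)
        oracle = greedy_prune_oracle(D.astype(float), 6, 1, 0.1)
        assert list(kept.indices) == oracle

    def test_no_retained_pair_violates_threshold(self, grid22_cohort):
        common = st.classify_variants(grid22_cohort, "common")
        kept = st.ld_prune(grid22_cohort, common)
        D = grid22_cohort.dosages(kept.indices).astype(float)
        order = {int(v): i for i, v in enumerate(common.indices)}
        chrom = grid22_cohort.variants["chrom"].to_numpy()
        for a in range(D.shape[1]):
            for b in range(a + 1, D.shape[1]):
                va, vb = int(kept.indices[a]), int(kept.indices[b])
                # windows are per chromosome, as in genomic LD pruning
                if chrom[va] == chrom[vb] and order[vb] - order[va] < 100:
                    r = np.corrcoef(D[:, a], D[:, b])[0, 1]
                    assert r * r <= 0.1 + 1e-9

    def test_empty_input_empty_output(self, grid22_cohort):
        out = st.ld_prune(
            grid22_cohort, st.VariantSet(np.array([], dtype=int), "common")
        )
        assert len(out) == 0


class TestWeirCockerham:
    def test_identical_demes_near_zero(self, dataset_factory):
        rng = np.random.default_rng(3)
        block = rng.binomial(2, 0.3, size=(50, 20)).astype(np.int8)
        D = np.vstack([block, block, block])  # three identical demes
        ds = dataset_factory(D, demes=np.repeat([0, 1, 2], 50))
        fst = st.weir_cockerham_fst(
            ds, st.VariantSet(np.arange(20), "common"), n_boot=100
        )
        assert abs(fst.fst) < 0.02

    def test_fixed_difference_approaches_one(self, dataset_factory):
        D = np.zeros((200, 10), dtype=np.int8)
        D[100:, :] = 2  # deme 1 fixed derived at every variant
        ds = dataset_factory(D, demes=np.repeat([0, 1], 100))
        fst = st.weir_cockerham_fst(
            ds, st.VariantSet(np.arange(10), "common"), n_boot=100
        )
        assert fst.fst > 0.98

    def test_matches_independent_textbook_oracle(self, dataset_factory):
        rng = np.random.default_rng(4)
        D = rng.integers(0, 3, size=(30, 5)).astype(np.int8)
        labels = np.repeat([0, 1, 2], 10)
        ds = dataset_factory(D, demes=labels)
        fst = st.weir_cockerham_fst(
            ds, st.VariantSet(np.arange(5), "any"), n_boot=50
        )
        assert fst.fst == pytest.approx(textbook_wc_fst(D, labels), abs=1e-12)

    def test_invariant_to_variant_order_and_deme_relabeling(self, dataset_factory):
        rng = np.random.default_rng(5)
        D = rng.integers(0, 3, size=(60, 12)).astype(np.int8)
        labels = np.repeat([0, 1, 2], 20)
        base = st.weir_cockerham_fst(
            dataset_factory(D, demes=labels), st.VariantSet(np.arange(12), "x"),
            n_boot=10,
        ).fst
        perm = np.random.default_rng(6).permutation(12)
        shuffled = st.weir_cockerham_fst(
            dataset_factory(D[:, perm], demes=labels),
            st.VariantSet(np.arange(12), "x"), n_boot=10,
        ).fst
        relabeled = st.weir_cockerham_fst(
            dataset_factory(D, demes=(2 - labels)), st.VariantSet(np.arange(12), "x"),
            n_boot=10,
        ).fst
        assert shuffled == pytest.approx(base, abs=1e-12)
        assert relabeled == pytest.approx(base, abs=1e-12)

    def test_monomorphic_only_signaled(self, dataset_factory):
        D = np.zeros((40, 3), dtype=np.int8)
        ds = dataset_factory(D, demes=np.repeat([0, 1], 20))
        with pytest.raises(ValueError):
            st.weir_cockerham_fst(ds, st.VariantSet(np.arange(3), "x"))

    def test_single_deme_rejected(self, dataset_factory):
        ds = dataset_factory(np.ones((10, 2), dtype=np.int8))
        with pytest.raises(ValueError):
            st.weir_cockerham_fst(ds, st.VariantSet(np.arange(2), "x"))


class TestGenomicInflation:
    def test_exact_null_quantile_grid_gives_one(self):
        n = 100_000
        grid = sps.chi2.ppf((np.arange(n) + 0.5) / n, df=1)
        for p in (0.5, 0.9, 0.999):
            assert st.genomic_inflation(grid, p).lambda_p == pytest.approx(1.0, abs=0.02)

    def test_scale_equivariance(self):
        n = 100_000
        grid = sps.chi2.ppf((np.arange(n) + 0.5) / n, df=1)
        for p in (0.5, 0.999):
            assert st.genomic_inflation(2 * grid, p).lambda_p == pytest.approx(
                2.0, abs=0.04
            )

    def test_uniform_pvalues_give_unit_lambda(self):
        rng = np.random.default_rng(7)
        stats = sps.chi2.ppf(1 - rng.uniform(size=20_000), df=1)
        assert st.genomic_inflation(stats, 0.5).lambda_p == pytest.approx(1.0, abs=0.05)

    def test_guards(self):
        with pytest.raises(ValueError):
            st.genomic_inflation(np.ones(5), 0.999)
        with pytest.raises(ValueError):
            st.genomic_inflation(np.ones(100), 1.5)
        with pytest.raises(ValueError):
            st.genomic_inflation(np.array([-1.0, 1.0, 2.0]), 0.5)


class TestRescaleLambda:
    def test_published_rescaling_inputs(self):
        # (N/N0)(lambda-1)+1 with lambda=12, 300k -> 9k
        assert st.rescale_lambda(12, 300_000, 9_000) == pytest.approx(1.33)

    def test_no_inflation_is_scale_free(self):
        assert st.rescale_lambda(1.0, 300_000, 9_000) == 1.0
        assert st.rescale_lambda(1.0, 10, 1_000_000) == 1.0

    def test_forward_inverse_consistency(self):
        lam9 = st.rescale_lambda(12, 300_000, 9_000)
        assert st.rescale_lambda(lam9, 9_000, 300_000) == pytest.approx(12.0)

    def test_guards(self):
        with pytest.raises(ValueError):
            st.rescale_lambda(-0.1, 10, 10)
        with pytest.raises(ValueError):
            st.rescale_lambda(1.2, 0, 10)


class TestLocationGwas:
    def test_unstructured_dosages_give_unit_lambda(self, dataset_factory):
        rng = np.random.default_rng(8)
        D = rng.binomial(2, 0.3, size=(400, 3000)).astype(np.int8)
        rows = rng.integers(0, 6, 400)
        ds = dataset_factory(D, demes=rows, rows=rows)
        lam = st.location_gwas_lambda(ds, st.VariantSet(np.arange(3000), "common"))
        assert lam.lambda_p == pytest.approx(1.0, abs=0.1)

    def test_structured_cohort_inflated_on_structure_axis(
        self, two_deme_structured_cohort
    ):
        ds = two_deme_structured_cohort
        common = st.classify_variants(ds, "common")
        lam_x = st.location_gwas_lambda(ds, common, axis="x")
        assert lam_x.lambda_p > 1.5  # strong two-deme structure

    def test_single_deme_rejected(self, panmictic_cohort):
        common = st.classify_variants(panmictic_cohort, "common")
        with pytest.raises(ValueError):
            st.location_gwas_lambda(panmictic_cohort, common, axis="y")
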