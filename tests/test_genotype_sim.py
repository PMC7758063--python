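import numpy as np
import pytest

import stratsim as st


class TestSimulateCohort:
    def test_fixed_seed_reproduces_cohort_exactly(self):
        dem = st.build_demography("recent", st.GridSpec(2, 2), 0.05)
        g = st.GenomeSpec(2, 100_000)
        a = st.simulate_cohort(dem, g, 10, seed=99)
        b = st.simulate_cohort(dem, g, 10, seed=99)
        assert a.variants.equals(b.variants)
        assert np.array_equal(a.dosages(), b.dosages())
        c = st.simulate_cohort(dem, g, 10, seed=100)
        assert not a.variants.equals(c.variants)

    def test_zero_mutation_rate_gives_zero_variants(self):
        dem = st.build_demography("recent", st.GridSpec(2, 2), 0.05)
        g = st.GenomeSpec(1, 100_000, mutation_rate=0.0)
        ds = st.simulate_cohort(dem, g, 5, seed=3)
        assert ds.n_variants == 0

    def test_segregating_sites_near_watterson_expectation(self):
        """Single-deme recent model is panmictic at Ne: Watterson oracle.

        E[S] = 4 Ne mu L * H_{n-1}; the observed count over 1.5 Mb with
        n=240 haplotypes must fall within 20%.
        """
        Ne, L, mu, n_ind = 10_000, 500_000, 1e-8, 120
        dem = st.build_demography("recent", st.GridSpec(1, 1), 0.0, deme_ne=Ne)
        ds = st.simulate_cohort(dem, st.GenomeSpec(3, L), n_ind, seed=21)
        harmonic = np.sum(1.0 / np.arange(1, 2 * n_ind))
        expected = 4 * Ne * mu * (3 * L) * harmonic
        assert ds.n_variants == pytest.approx(expected, rel=0.2)

    def test_dosage_matches_genealogy_haplotypes(self, grid22_cohort):
        ds = grid22_cohort
        idx = np.arange(0, ds.n_variants, 7)
        D = ds.dosages(idx)
        for c in range(ds.genome.n_chromosomes):
            H = ds.haplotypes(c)
            sl = ds._chrom_slices[c]
            on_c = (idx >= sl.start) & (idx < sl.stop)
            expect = (H[:, 0::2] + H[:, 1::2]).T[:, idx[on_c] - sl.start]
            assert np.array_equal(D[:, on_c], expect)

    def test_weighted_sampling_allocates_counts(self):
        geo = st.load_england_wales_fixture()
        dem = st.build_demography("recent", geo, 0.08)
        ds = st.simulate_cohort(
            dem,
            st.GenomeSpec(1, 50_000),
            n_per_deme=0,
            seed=4,
            sampling_weights=geo.sampling_weights,
            n_total=900,
        )
        counts = ds.samples["deme"].value_counts()
        cornwall = list(geo.deme_names).index("cornwall")
        assert ds.n_individuals == 900
        assert counts[cornwall] <= 3  # ~17/9000 scaled to 900

    def test_rare_variants_more_geographically_clustered_than_common(self):
        """Rare-variant carriers concentrate in fewer demes (recent model)."""
        dem = st.build_demography("recent", st.GridSpec(2, 2), 0.01)
        ds = st.simulate_cohort(dem, st.GenomeSpec(2, 400_000), 50, seed=31)
        demes = ds.deme_labels

        def mean_carrier_concentration(vs):
            out = []
            for sel, block in ds.iter_dosage_chunks(vs.indices):
                for j in range(block.shape[1]):
                    carriers = demes[block[:, j] > 0]
                    if len(carriers):
                        # fraction of carriers in their modal deme
                        _, cts = np.unique(carriers, return_counts=True)
                        out.append(cts.max() / cts.sum())
            return float(np.mean(out))

        rare = st.classify_variants(ds, "rare_mac")
        common = st.classify_variants(ds, "common")
        assert mean_carrier_concentration(rare) > mean_carrier_concentration(common)


class TestClassifyVariants:
    def test_class_boundaries(self, dataset_factory):
        n = 50  # 100 haplotypes
        D = np.zeros((n, 4), dtype=np.int8)
        D[:5, 0] = 2  # dac=10, maf=0.10 -> common
        D[:5, 1] = 1  # dac=5, maf=0.05 exactly -> NOT common (strict >)
        D[:2, 2] = 1  # dac=2 -> rare_mac; freq 0.02 not ultra-rare
        # dac=0 column 3: monomorphic, no class
        ds = dataset_factory(D)
        assert list(st.classify_variants(ds, "common").indices) == [0]
        assert list(st.classify_variants(ds, "rare_mac").indices) == [2]
        assert list(st.classify_variants(ds, "ultra_rare").indices) == []

    def test_rare_mac_is_folded_and_ultra_rare_is_derived(self, dataset_factory):
        n = 3000  # 6000 haplotypes
        D = np.zeros((n, 2), dtype=np.int8)
        D[0, 0] = 2; D[1, 0] = 1  # dac=3: rare_mac AND ultra-rare (5e-4)
        D[:, 1] = 2; D[0, 1] = 0; D[1, 1] = 1  # dac=5997, mac=3: rare_mac, not ultra-rare
        ds = dataset_factory(D)
        assert list(st.classify_variants(ds, "rare_mac").indices) == [0, 1]
        assert list(st.classify_variants(ds, "ultra_rare").indices) == [0]

    def test_unknown_class_rejected(self, grid22_cohort):
        with pytest.raises(ValueError):
            st.classify_variants(grid22_cohort, "private")


class TestSubsample:
    def test_identity_and_empty(self, grid22_cohort):
        vs = st.classify_variants(grid22_cohort, "common")
        assert np.array_equal(
            st.subsample_variants(vs, len(vs), 1).indices, vs.indices
        )
        assert len(st.subsample_variants(vs, 0, 1)) == 0
        with pytest.raises(ValueError):
            st.subsample_variants(vs, len(vs) + 1, 1)

    def test_two_seeds_overlap_near_hypergeometric(self, grid22_cohort):
        vs = st.classify_variants(grid22_cohort, "common")
        k = len(vs) // 2
        a = set(st.subsample_variants(vs, k, 1).indices)
        b = set(st.subsample_variants(vs, k, 2).indices)
        expected = k * k / len(vs)
        sd = np.sqrt(expected)  # loose hypergeometric scale
        assert abs(len(a & b) - expected) < 5 * sd


class TestSplit:
    def test_stratified_even_split(self, grid22_cohort):
        train, test = st.split_train_test(grid22_cohort, 0.5, seed=2)
        assert train.n_individuals == test.n_individuals == 40
        for ds in (train, test):
            assert (ds.samples["deme"].value_counts() == 10).all()
        # disjoint engine-level individuals
        assert not set(train.individual_index) & set(test.individual_index)

    def test_frequencies_recomputed_on_halves(self, grid22_cohort):
        train, _ = st.split_train_test(grid22_cohort, 0.5, seed=2)
        dac = train.dosages().sum(axis=0)
        assert np.array_equal(dac, train.variants["dac"].to_numpy())

    def test_degenerate_fractions_rejected(self, grid22_cohort):
        for f in (0.0, 1.0):
            with pytest.raises(ValueError):
                st.split_train_test(grid22_cohort, f, seed=2)


class TestVcfRoundTrip:
    def test_round_trip_reproduces_dosage(self, grid22_cohort, tmp_path):
        path = str(tmp_path / "cohort.vcf")
        st.export_vcf(grid22_cohort, path)
        back = st.import_vcf(path, genome=grid22_cohort.genome)
        assert back.n_variants == grid22_cohort.n_variants
        assert np.array_equal(back.dosages(), grid22_cohort.dosages())

    def test_gt_fields_match_haplotypes(self, grid22_cohort, tmp_path):
        path = str(tmp_path / "cohort.vcf")
        st.export_vcf(grid22_cohort, path)
        H = grid22_cohort.haplotypes(0)
        with open(path) as fh:
            lines = [l for l in fh if not l.startswith("#")]
        first = lines[0].rstrip("\n").split("\t")
        assert first[3] == "A" and first[4] == "T"
        gts = first[9:]
        expect = [f"{H[0, 2*i]}|{H[0, 2*i+1]}" for i in range(len(gts))]
        assert gts == expect

    def test_summary_tables_round_trip(self, grid22_cohort, tmp_path):
        import json

        prefix = str(tmp_path / "cohort")
        st.export_summary_tables(grid22_cohort, prefix)
        import pandas as pd

        samples = pd.read_csv(prefix + ".samples.tsv", sep="\t")
        variants = pd.read_csv(prefix + ".variants.tsv", sep="\t")
        meta = json.loads(open(prefix + ".meta.json").read())
        assert len(samples) == grid22_cohort.n_individuals
        assert len(variants) == grid22_cohort.n_variants
        assert meta["seed"] == 11 and "msprime" in meta["engine"]

    def test_empty_variants_gives_header_only(self, tmp_path):
        dem = st.build_demography("recent", st.GridSpec(1, 1), 0.0)
        ds = st.simulate_cohort(
            dem, st.GenomeSpec(1, 10_000, mutation_rate=0.0), 3, seed=1
        )
        path = str(tmp_path / "empty.vcf")
        st.export_vcf(ds, path)
        with open(path) as fh:
            assert all(l.startswith("#") for l in fh)
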