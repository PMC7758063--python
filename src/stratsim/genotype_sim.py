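"""Coalescent cohort simulation: the study's synthetic-data generator.

Cohorts are simulated with msprime over a :class:`~stratsim.demography.
DemographySpec`, one independent tree sequence per chromosome (derived
seeds), under an infinite-sites binary mutation model so every variant
is biallelic with known ancestral (0) and derived (1) alleles.  The
resulting :class:`GenotypeDataset` keeps the tree sequences as the
source of truth — genotypes and haplotypes are decoded on demand in
chunks, so very large cohorts never require materializing the full
genotype matrix — and exposes the genealogies for exact IBD extraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd
import msprime
import tskit

from .demography import DemographySpec, GridSpec

__all__ = [
    "GenomeSpec",
    "GenotypeDataset",
    "VariantSet",
    "simulate_cohort",
    "classify_variants",
    "subsample_variants",
    "split_train_test",
    "export_vcf",
    "import_vcf",
]


@dataclass(frozen=True)
class GenomeSpec:
    """Genome layout and per-bp rates.

    The calibration preset (10 x 1 Mb) matches the migration-rate
    calibration design; the main preset (20 x 10 Mb) matches the
    full-scale GWAS design.
    """

    n_chromosomes: int = 10
    chromosome_length: float = 1_000_000.0
    mutation_rate: float = 1e-8
    recombination_rate: float = 1e-8

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.chromosome_length <= 0:
            raise ValueError("genome must have >=1 chromosome of positive length")
        if self.mutation_rate < 0 or self.recombination_rate < 0:
            raise ValueError("rates must be non-negative")

    @classmethod
    def calibration(cls) -> "GenomeSpec":
        return cls(n_chromosomes=10, chromosome_length=1e6)

    @classmethod
    def main(cls) -> "GenomeSpec":
        return cls(n_chromosomes=20, chromosome_length=1e7)

    @property
    def total_length(self) -> float:
        return self.n_chromosomes * self.chromosome_length


@dataclass(frozen=True)
class VariantSet:
    """Indices into a dataset's variant table plus their class label."""

    indices: np.ndarray
    label: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "indices", np.asarray(self.indices, dtype=np.int64)
        )

    def __len__(self) -> int:
        return len(self.indices)


VARIANT_CLASSES = ("common", "rare_mac", "ultra_rare")


class GenotypeDataset:
    """A simulated cohort backed by per-chromosome tree sequences.

    Attributes
    ----------
    samples : pandas.DataFrame
        One row per diploid individual: ``individual``, ``deme``,
        ``row``, ``col``.
    variants : pandas.DataFrame
        One row per variant: ``chrom`` (0-based), ``pos`` (0-based bp
        within chromosome), ``dac`` (derived-allele count) and
        ``frequency`` (derived-allele frequency), computed on the
        individuals of this dataset.
    tree_sequences : list of tskit.TreeSequence or None
        Genealogy handles; ``None`` for datasets imported from VCF.
    """

    def __init__(
        self,
        samples: pd.DataFrame,
        variants: pd.DataFrame,
        tree_sequences: Optional[list[tskit.TreeSequence]],
        genome: GenomeSpec,
        individual_index: Optional[np.ndarray] = None,
        dosage_cache: Optional[np.ndarray] = None,
        metadata: Optional[dict] = None,
    ):
        self.samples = samples.reset_index(drop=True)
        self.variants = variants.reset_index(drop=True)
        self.tree_sequences = tree_sequences
        self.genome = genome
        # position of each individual's genotype columns in the engine output
        if individual_index is None:
            individual_index = np.arange(len(self.samples))
        self.individual_index = np.asarray(individual_index, dtype=np.int64)
        self._dosage_cache = dosage_cache
        self.metadata = dict(metadata or {})
        self._chrom_slices = self._compute_chrom_slices()

    def _compute_chrom_slices(self) -> list[slice]:
        chroms = self.variants["chrom"].to_numpy()
        slices = []
        for c in range(self.genome.n_chromosomes):
            idx = np.flatnonzero(chroms == c)
            if len(idx) == 0:
                slices.append(slice(0, 0))
            else:
                slices.append(slice(int(idx[0]), int(idx[-1]) + 1))
        return slices

    # -- basic properties --------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def deme_labels(self) -> np.ndarray:
        return self.samples["deme"].to_numpy()

    @property
    def has_genealogy(self) -> bool:
        return self.tree_sequences is not None

    # -- genotype access ---------------------------------------------------

    def _haplotype_columns(self) -> np.ndarray:
        """Haplotype (sample-node) columns for this dataset's individuals."""
        cols = np.empty(2 * len(self.individual_index), dtype=np.int64)
        cols[0::2] = 2 * self.individual_index
        cols[1::2] = 2 * self.individual_index + 1
        return cols

    def iter_dosage_chunks(
        self, indices: Optional[np.ndarray] = None, chunk: int = 8192
    ) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        """Yield ``(variant_indices, dosage)`` blocks in variant order.

        ``dosage`` has shape (n_individuals, block_size), int8, counting
        derived alleles.  Decoding streams through the tree sequences so
        memory stays bounded regardless of cohort size.
        """
        if self._dosage_cache is not None:
            if indices is None:
                indices = np.arange(self.n_variants)
            indices = np.asarray(indices)
            for s in range(0, len(indices), chunk):
                sel = indices[s : s + chunk]
                yield sel, self._dosage_cache[:, sel]
            return
        if self.tree_sequences is None:
            raise ValueError("dataset has neither genealogy nor cached genotypes")
        if indices is None:
            indices = np.arange(self.n_variants)
        indices = np.asarray(indices, dtype=np.int64)
        if len(indices) == 0:
            return
        if np.any(np.diff(indices) <= 0):
            raise ValueError("variant indices must be strictly increasing")
        hap_cols = self._haplotype_columns()
        n = self.n_individuals
        pos = 0  # cursor into `indices`
        for c, ts in enumerate(self.tree_sequences):
            sl = self._chrom_slices[c]
            # indices requested on this chromosome
            start = pos
            while pos < len(indices) and indices[pos] < sl.stop:
                pos += 1
            want = indices[start:pos]
            if len(want) == 0:
                continue
            # random-access decode of just the requested sites
            var = tskit.Variant(ts, samples=hap_cols)
            buf = np.empty((chunk, n), dtype=np.int8)
            out_idx = np.empty(chunk, dtype=np.int64)
            k = 0
            for vidx in want:
                var.decode(int(vidx - sl.start))
                g = var.genotypes
                np.add(g[0::2], g[1::2], out=buf[k], casting="unsafe")
                out_idx[k] = vidx
                k += 1
                if k == chunk:
                    yield out_idx.copy(), buf[:k].T.copy()
                    k = 0
            if k:
                yield out_idx[:k].copy(), buf[:k].T.copy()

    def iter_haplotype_chunks(
        self, indices: Optional[np.ndarray] = None, chunk: int = 8192
    ) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        """Yield ``(variant_indices, H)`` blocks with phased haplotypes.

        ``H`` has shape (2 * n_individuals, block_size), int8; rows 2i
        and 2i+1 are individual i's haplotypes.  Requires the genealogy.
        """
        if self.tree_sequences is None:
            raise ValueError("phased haplotypes require the genealogy")
        if indices is None:
            indices = np.arange(self.n_variants)
        indices = np.asarray(indices, dtype=np.int64)
        if len(indices) == 0:
            return
        if np.any(np.diff(indices) <= 0):
            raise ValueError("variant indices must be strictly increasing")
        hap_cols = self._haplotype_columns()
        pos = 0
        for c, ts in enumerate(self.tree_sequences):
            sl = self._chrom_slices[c]
            start = pos
            while pos < len(indices) and indices[pos] < sl.stop:
                pos += 1
            want = indices[start:pos]
            if len(want) == 0:
                continue
            var = tskit.Variant(ts, samples=hap_cols)
            buf = np.empty((chunk, len(hap_cols)), dtype=np.int8)
            out_idx = np.empty(chunk, dtype=np.int64)
            k = 0
            for vidx in want:
                var.decode(int(vidx - sl.start))
                buf[k] = var.genotypes
                out_idx[k] = vidx
                k += 1
                if k == chunk:
                    yield out_idx.copy(), buf[:k].T.copy()
                    k = 0
            if k:
                yield out_idx[:k].copy(), buf[:k].T.copy()

    def dosages(self, indices: Optional[np.ndarray] = None) -> np.ndarray:
        """Materialize an (n_individuals x n_variants) int8 dosage matrix."""
        if indices is None:
            indices = np.arange(self.n_variants)
        indices = np.asarray(indices, dtype=np.int64)
        out = np.empty((self.n_individuals, len(indices)), dtype=np.int8)
        lookup = {int(v): i for i, v in enumerate(indices)}
        order = np.sort(indices)
        for sel, block in self.iter_dosage_chunks(order):
            for j, v in enumerate(sel):
                out[:, lookup[int(v)]] = block[:, j]
        return out

    def haplotypes(self, chrom: int) -> np.ndarray:
        """Phased haplotype matrix for one chromosome.

        Returns an int8 array of shape (n_sites_on_chrom, 2 *
        n_individuals); columns 2i and 2i+1 are individual i's two
        haplotypes.
        """
        if self.tree_sequences is None:
            raise ValueError("haplotypes require the genealogy")
        ts = self.tree_sequences[chrom]
        hap_cols = self._haplotype_columns()
        sl = self._chrom_slices[chrom]
        H = np.empty((sl.stop - sl.start, len(hap_cols)), dtype=np.int8)
        var = tskit.Variant(ts, samples=hap_cols)
        for i in range(sl.stop - sl.start):
            var.decode(i)
            H[i] = var.genotypes
        return H

    # -- derived datasets --------------------------------------------------

    def subset_individuals(self, rows: np.ndarray) -> "GenotypeDataset":
        """New dataset restricted to a subset of individuals.

        Variant frequencies are recomputed on the subset, since variant
        classification is always relative to the analyzed sample.
        """
        rows = np.asarray(rows)
        sub_samples = self.samples.iloc[rows]
        sub_index = self.individual_index[rows]
        cache = self._dosage_cache[rows] if self._dosage_cache is not None else None
        ds = GenotypeDataset(
            sub_samples,
            self.variants.copy(),
            self.tree_sequences,
            self.genome,
            individual_index=sub_index,
            dosage_cache=cache,
            metadata=self.metadata,
        )
        dac = np.zeros(ds.n_variants, dtype=np.int64)
        for sel, block in ds.iter_dosage_chunks():
            dac[sel] = block.sum(axis=0, dtype=np.int64)
        ds.variants["dac"] = dac
        ds.variants["frequency"] = dac / (2 * ds.n_individuals)
        return ds


def _stable_hash(stream: str) -> int:
    """Process-independent 32-bit hash of a stage name."""
    import zlib

    return zlib.crc32(stream.encode())


def _derive_seeds(seed: int, n: int, stream: str) -> list[int]:
    """Deterministic per-stage engine seeds below 2**31."""
    ss = np.random.SeedSequence([seed, _stable_hash(stream)])
    return [int(s) % (2**31 - 1) + 1 for s in ss.generate_state(n, dtype=np.uint64)]


def _site_derived_counts(ts: tskit.TreeSequence, hap_cols: np.ndarray) -> np.ndarray:
    """Derived-allele count per site over the given haplotype columns.

    Fast path for infinite-sites data (one mutation per site) counts
    samples below each mutation on the local tree; datasets with
    recurrent mutation fall back to genotype decoding.
    """
    counts = np.zeros(ts.num_sites, dtype=np.int64)
    full = len(hap_cols) == ts.num_samples
    # infinite-sites data has exactly one mutation per site
    if full and ts.num_mutations == ts.num_sites:
        for tree in ts.trees():
            for site in tree.sites():
                counts[site.id] = tree.num_samples(site.mutations[0].node)
        return counts
    var = tskit.Variant(ts, samples=hap_cols)
    for sid in range(ts.num_sites):
        var.decode(sid)
        counts[sid] = int((var.genotypes > 0).sum())
    return counts


def simulate_cohort(
    demography: DemographySpec,
    genome: GenomeSpec,
    n_per_deme: int | Sequence[int],
    seed: int,
    sampling_weights: Optional[Sequence[float]] = None,
    n_total: Optional[int] = None,
) -> GenotypeDataset:
    """Simulate a diploid cohort over the given demography.

    Chromosomes are simulated as independent coalescent replicates with
    seeds derived deterministically from ``seed``; the whole cohort is
    reproducible byte-for-byte for a fixed seed.

    Parameters
    ----------
    n_per_deme
        Diploid individuals sampled from each deme (scalar or per-deme
        sequence).  Ignored if ``sampling_weights`` is given.
    sampling_weights, n_total
        Non-uniform sampling: ``n_total`` individuals allocated to
        demes proportionally to the weights (largest-remainder
        rounding), mimicking uneven biobank ascertainment.
    """
    if seed is None:
        raise ValueError("a seed is required")
    n_demes = demography.n_demes
    if sampling_weights is not None:
        if n_total is None:
            raise ValueError("n_total required with sampling_weights")
        w = np.asarray(sampling_weights, dtype=float)
        w = w / w.sum()
        raw = w * n_total
        counts = np.floor(raw).astype(int)
        rem = n_total - counts.sum()
        order = np.argsort(-(raw - counts))
        counts[order[:rem]] += 1
    elif np.isscalar(n_per_deme):
        if n_per_deme <= 0:
            raise ValueError("n_per_deme must be positive")
        counts = np.full(n_demes, int(n_per_deme))
    else:
        counts = np.asarray(n_per_deme, dtype=int)
        if len(counts) != n_demes or (counts < 0).any():
            raise ValueError("per-deme counts must cover every deme, >=0")

    try:
        ms_dem = demography.to_msprime()
    except Exception as err:  # engine/spec incompatibility must be loud
        raise ValueError(f"demography cannot be translated to the engine: {err}")
    sample_sets = {
        demography.deme_name(i): int(c) for i, c in enumerate(counts) if c > 0
    }
    anc_seeds = _derive_seeds(seed, genome.n_chromosomes, "ancestry")
    mut_seeds = _derive_seeds(seed, genome.n_chromosomes, "mutations")

    tslist = []
    var_frames = []
    for c in range(genome.n_chromosomes):
        ts = msprime.sim_ancestry(
            samples=sample_sets,
            demography=ms_dem,
            sequence_length=genome.chromosome_length,
            recombination_rate=genome.recombination_rate,
            random_seed=anc_seeds[c],
        )
        ts = msprime.sim_mutations(
            ts,
            rate=genome.mutation_rate,
            random_seed=mut_seeds[c],
            model=msprime.BinaryMutationModel(),
            discrete_genome=False,
        )
        tslist.append(ts)
        var_frames.append(
            pd.DataFrame(
                {
                    "chrom": np.full(ts.num_sites, c, dtype=np.int32),
                    "pos": ts.sites_position,
                }
            )
        )

    # sample table: msprime orders individuals by population block
    demes = np.repeat(np.arange(n_demes), counts)
    if isinstance(demography.geography, GridSpec):
        rows = demography.geography.rows[demes]
        cols = demography.geography.cols[demes]
    else:
        rows = demography.geography.rows[demes]
        cols = np.zeros_like(rows)
    samples = pd.DataFrame(
        {
            "individual": np.arange(len(demes)),
            "deme": demes,
            "row": rows,
            "col": cols,
        }
    )
    variants = (
        pd.concat(var_frames, ignore_index=True)
        if var_frames
        else pd.DataFrame({"chrom": [], "pos": []})
    )
    n_ind = len(demes)
    hap_cols = np.arange(2 * n_ind)
    dac = np.concatenate(
        [_site_derived_counts(ts, hap_cols) for ts in tslist]
    ) if len(variants) else np.array([], dtype=np.int64)
    variants["dac"] = dac
    variants["frequency"] = dac / (2 * n_ind) if n_ind else np.nan
    return GenotypeDataset(
        samples,
        variants,
        tslist,
        genome,
        metadata={"seed": seed, "model_kind": demography.model_kind},
    )


def classify_variants(dataset: GenotypeDataset, label: str) -> VariantSet:
    """Select variants of one frequency class, computed on this dataset.

    ``common``: minor-allele frequency strictly above 0.05.
    ``rare_mac``: minor-allele count in {2, 3, 4}.
    ``ultra_rare``: derived-allele frequency strictly below 0.001
    (and nonzero).
    """
    if dataset.n_variants == 0:
        raise ValueError("dataset has no variants")
    if label not in VARIANT_CLASSES:
        raise ValueError(f"unknown variant class {label!r}")
    dac = dataset.variants["dac"].to_numpy()
    n2 = 2 * dataset.n_individuals
    freq = dac / n2
    mac = np.minimum(dac, n2 - dac)
    if label == "common":
        mask = np.minimum(freq, 1 - freq) > 0.05
    elif label == "rare_mac":
        mask = (mac >= 2) & (mac <= 4)
    else:
        mask = (freq > 0) & (freq < 0.001)
    return VariantSet(np.flatnonzero(mask), label)


def subsample_variants(variant_set: VariantSet, k: int, seed: int) -> VariantSet:
    """Uniform subsample without replacement, deterministic per seed."""
    if k > len(variant_set):
        raise ValueError("cannot subsample more variants than available")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(variant_set), size=k, replace=False)
    return VariantSet(np.sort(variant_set.indices[pick]), variant_set.label)


def split_train_test(
    dataset: GenotypeDataset, fraction: float = 0.5, seed: int = 0
) -> tuple[GenotypeDataset, GenotypeDataset]:
    """Deme-stratified split into disjoint training and test datasets.

    Each deme contributes ``floor(n_deme * fraction)`` individuals to
    the training half (floor rule; the remainder goes to test), drawn
    at random per deme.  Both halves recompute variant frequencies on
    their own individuals.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    demes = dataset.deme_labels
    train_rows, test_rows = [], []
    for d in np.unique(demes):
        rows = np.flatnonzero(demes == d)
        n_train = int(np.floor(len(rows) * fraction))
        if n_train == 0 or n_train == len(rows):
            raise ValueError(f"deme {d} would leave an empty half")
        perm = rng.permutation(rows)
        train_rows.append(np.sort(perm[:n_train]))
        test_rows.append(np.sort(perm[n_train:]))
    train = dataset.subset_individuals(np.concatenate(train_rows))
    test = dataset.subset_individuals(np.concatenate(test_rows))
    return train, test


# -- VCF plumbing ----------------------------------------------------------


def _integer_positions(dataset: GenotypeDataset) -> np.ndarray:
    """1-based integer positions per variant, unique within chromosome.

    Continuous infinite-sites positions are floored to integers; ties
    are bumped to the next free position so the VCF stays valid.
    """
    out = np.zeros(dataset.n_variants, dtype=np.int64)
    for c in range(dataset.genome.n_chromosomes):
        sl = dataset._chrom_slices[c]
        pos = np.floor(dataset.variants["pos"].to_numpy()[sl]).astype(np.int64) + 1
        for i in range(1, len(pos)):
            if pos[i] <= pos[i - 1]:
                pos[i] = pos[i - 1] + 1
        out[sl] = pos
    return out


def export_vcf(dataset: GenotypeDataset, path: str) -> None:
    """Write the cohort as VCF 4.2 (ancestral allele REF=A, derived ALT=T).

    Genotypes are phased haplotype pairs, so importing the file
    reproduces the dosage matrix exactly.
    """
    ipos = _integer_positions(dataset)
    names = [f"ind{i}" for i in dataset.samples["individual"]]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##source=stratsim\n')
        for c in range(dataset.genome.n_chromosomes):
            fh.write(
                f"##contig=<ID=chr{c + 1},length={int(dataset.genome.chromosome_length) + dataset.n_variants}>\n"
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(names)
            + "\n"
        )
        gt_strings = np.array(["0|0", "0|1", "1|0", "1|1"])
        for c in range(dataset.genome.n_chromosomes):
            sl = dataset._chrom_slices[c]
            if sl.stop == sl.start:
                continue
            if dataset.tree_sequences is not None:
                H = dataset.haplotypes(c)
            else:
                D = dataset.dosages(np.arange(sl.start, sl.stop)).T
                # unphased cache: emit dosage as 0|0, 0|1, 1|1
                H = np.zeros((D.shape[0], 2 * D.shape[1]), dtype=np.int8)
                H[:, 0::2] = (D >= 1).astype(np.int8)
                H[:, 1::2] = (D == 2).astype(np.int8)
            codes = 2 * H[:, 0::2] + H[:, 1::2]
            for i in range(H.shape[0]):
                v = sl.start + i
                fields = gt_strings[codes[i]]
                fh.write(
                    f"chr{c + 1}\t{ipos[v]}\t.\tA\tT\t.\tPASS\t.\tGT\t"
                    + "\t".join(fields)
                    + "\n"
                )


def export_summary_tables(dataset: GenotypeDataset, prefix: str) -> None:
    """Write the sample table, variant table and run metadata.

    ``<prefix>.samples.tsv``, ``<prefix>.variants.tsv`` and
    ``<prefix>.meta.json`` (seeds, genome parameters, engine version).
    """
    import json

    dataset.samples.to_csv(f"{prefix}.samples.tsv", sep="\t", index=False)
    dataset.variants.to_csv(f"{prefix}.variants.tsv", sep="\t", index=False)
    meta = {
        **dataset.metadata,
        "n_individuals": dataset.n_individuals,
        "n_variants": dataset.n_variants,
        "n_chromosomes": dataset.genome.n_chromosomes,
        "chromosome_length": dataset.genome.chromosome_length,
        "mutation_rate": dataset.genome.mutation_rate,
        "recombination_rate": dataset.genome.recombination_rate,
        "engine": f"msprime {msprime.__version__}",
    }
    with open(f"{prefix}.meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def import_vcf(path: str, genome: Optional[GenomeSpec] = None) -> GenotypeDataset:
    """Read a VCF written by :func:`export_vcf` back into a dataset.

    The returned dataset carries a dense genotype cache instead of a
    genealogy; operations that need exact IBD will refuse it.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    n_ind = len(vcf.samples)
    chroms, positions, rows = [], [], []
    for rec in vcf:
        chroms.append(int(rec.CHROM.replace("chr", "")) - 1)
        positions.append(rec.POS - 1)
        gts = np.asarray(rec.genotype.array())[:, :2]
        rows.append(gts.sum(axis=1).astype(np.int8))
    dosage = (
        np.vstack(rows).T if rows else np.zeros((n_ind, 0), dtype=np.int8)
    )
    n_chrom = (max(chroms) + 1) if chroms else 1
    if genome is None:
        genome = GenomeSpec(
            n_chromosomes=n_chrom,
            chromosome_length=float(max(positions) + 1 if positions else 1),
        )
    dac = dosage.sum(axis=0, dtype=np.int64)
    variants = pd.DataFrame(
        {
            "chrom": np.asarray(chroms, dtype=np.int32),
            "pos": np.asarray(positions, dtype=float),
            "dac": dac,
            "frequency": dac / (2 * n_ind),
        }
    )
    samples = pd.DataFrame(
        {
            "individual": np.arange(n_ind),
            "deme": np.zeros(n_ind, dtype=int),
            "row": np.zeros(n_ind, dtype=int),
            "col": np.zeros(n_ind, dtype=int),
        }
    )
    return GenotypeDataset(
        samples, variants, None, genome, dosage_cache=dosage
    )
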