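"""Gene-burden simulation and the spatial Gini coefficient.

Genes follow a human-average layout: eight exons of 160 bp separated
by introns of 6,938 bp.  Introns never contribute to burden; they only
matter as recombining spacers, so genes simulated *without*
recombination omit them entirely and span just the 1,280 bp of exon.
Each gene is an independent coalescent replicate under the chosen
demography.

A gene's burden for an individual is the count of derived alleles at
exonic variants whose derived-allele frequency in the analyzed cohort
is below 0.001.  Geographic clustering of the total per-deme burden is
summarized by the Gini coefficient

    G = (n − y₁ − Σ_{1<i≤n} (yᵢ + yᵢ₋₁)) / n

with yᵢ the cumulative burden shares sorted increasing (y_n = 1):
G = 0 for a uniformly spread burden, (n−1)/n when one deme carries it
all.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

import numpy as np
import msprime

from .demography import DemographySpec
from .genotype_sim import _derive_seeds

__all__ = [
    "GeneModel",
    "GeneBlock",
    "BurdenResult",
    "simulate_genes",
    "match_variant_counts",
    "gene_burden",
    "burden_association",
    "gini_coefficient",
]


@dataclass(frozen=True)
class GeneModel:
    """Exon/intron layout of a simulated gene."""

    n_exons: int = 8
    exon_length: int = 160
    intron_length: int = 6_938
    recombination: bool = False
    recombination_rate: float = 1e-8
    mutation_rate: float = 1e-8

    def __post_init__(self) -> None:
        if self.n_exons < 1 or self.exon_length < 1 or self.intron_length < 0:
            raise ValueError("invalid gene layout")

    @property
    def total_exon_length(self) -> int:
        return self.n_exons * self.exon_length

    @property
    def simulated_length(self) -> int:
        """Simulated span: introns are omitted without recombination."""
        if not self.recombination:
            return self.total_exon_length
        return (
            self.n_exons * self.exon_length
            + (self.n_exons - 1) * self.intron_length
        )

    def exon_intervals(self) -> list[tuple[int, int]]:
        """Half-open exon intervals on the simulated coordinate system."""
        if not self.recombination:
            return [(0, self.total_exon_length)]
        out = []
        start = 0
        for _ in range(self.n_exons):
            out.append((start, start + self.exon_length))
            start += self.exon_length + self.intron_length
        return out


@dataclass
class GeneBlock:
    """Genotypes of one simulated gene.

    ``dosage`` is (n_individuals x n_variants) int8; ``positions`` are
    bp on the simulated span; ``exonic`` marks variants inside exons.
    """

    gene_id: int
    positions: np.ndarray
    exonic: np.ndarray
    dosage: np.ndarray

    @property
    def n_variants(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class BurdenResult:
    """Per-individual burden counts with per-deme totals and Gini."""

    counts: np.ndarray
    deme_totals: np.ndarray
    gini: float


def simulate_genes(
    demography: DemographySpec,
    gene_model: GeneModel,
    n_genes: int,
    n_per_deme: int,
    seed: int,
    model=None,
) -> Iterator[GeneBlock]:
    """Yield independent coalescent gene replicates.

    Each gene gets its own derived seed; a failure in the engine is
    re-raised with the gene index attached so long runs are debuggable.
    """
    if n_genes < 1:
        raise ValueError("need at least one gene")
    ms_dem = demography.to_msprime()
    sample_sets = {
        demography.deme_name(i): n_per_deme for i in range(demography.n_demes)
    }
    anc_seeds = _derive_seeds(seed, n_genes, "gene-ancestry")
    mut_seeds = _derive_seeds(seed, n_genes, "gene-mutations")
    L = gene_model.simulated_length
    r = gene_model.recombination_rate if gene_model.recombination else 0.0
    intervals = gene_model.exon_intervals()
    for g in range(n_genes):
        try:
            ts = msprime.sim_ancestry(
                samples=sample_sets,
                demography=ms_dem,
                sequence_length=L,
                recombination_rate=r,
                random_seed=anc_seeds[g],
                model=model,
            )
            ts = msprime.sim_mutations(
                ts,
                rate=gene_model.mutation_rate,
                random_seed=mut_seeds[g],
                model=msprime.BinaryMutationModel(),
                discrete_genome=False,
            )
        except Exception as err:
            raise RuntimeError(f"gene {g}: engine failure: {err}") from err
        pos = ts.sites_position
        exonic = np.zeros(len(pos), dtype=bool)
        for a, b in intervals:
            exonic |= (pos >= a) & (pos < b)
        n_ind = ts.num_samples // 2
        D = np.empty((len(pos), n_ind), dtype=np.int8)
        for i, v in enumerate(ts.variants()):
            gt = v.genotypes
            np.add(gt[0::2], gt[1::2], out=D[i], casting="unsafe")
        yield GeneBlock(g, pos, exonic, D.T)


def hybrid_wf_model(duration: float = 100.0) -> list:
    """Discrete-time Wright–Fisher for the recent structured phase.

    Generation-by-generation simulation batches the many migration
    events of the 100-generation structured epoch and hands the deep
    history to the standard coalescent; for deme sizes of 10,000 the
    two engines agree (the coalescent is the WF limit) and the hybrid
    is several-fold faster on large gene panels.
    """
    return [
        msprime.DiscreteTimeWrightFisher(duration=duration),
        msprime.StandardCoalescent(),
    ]


def simulate_gene_rare_counts(
    demography: DemographySpec,
    gene_model: GeneModel,
    n_genes: int,
    n_per_deme: int,
    seed: int,
    freq_threshold: float = 0.001,
    model=None,
) -> np.ndarray:
    """Rare exonic variant count per gene, without genotype decoding.

    Only derived-allele counts are needed to count rare variants, and
    for a non-recombining gene each site's count is the number of
    samples below its mutation on the single marginal tree; this skips
    the genotype matrix entirely and makes large gene panels cheap.
    Only defined for recombination-free gene models.
    """
    if gene_model.recombination:
        raise ValueError("fast counting requires a recombination-free gene model")
    ms_dem = demography.to_msprime()
    sample_sets = {
        demography.deme_name(i): n_per_deme for i in range(demography.n_demes)
    }
    anc_seed = _derive_seeds(seed, 1, "gene-ancestry")[0]
    mut_seeds = _derive_seeds(seed, n_genes, "gene-mutations")
    n_hap = 2 * n_per_deme * demography.n_demes
    out = np.zeros(n_genes, dtype=np.int64)
    replicates = msprime.sim_ancestry(
        samples=sample_sets,
        demography=ms_dem,
        sequence_length=gene_model.simulated_length,
        recombination_rate=0,
        random_seed=anc_seed,
        model=model,
        num_replicates=n_genes,
    )
    for g, ts in enumerate(replicates):
        ts = msprime.sim_mutations(
            ts,
            rate=gene_model.mutation_rate,
            random_seed=mut_seeds[g],
            model=msprime.BinaryMutationModel(),
            discrete_genome=False,
        )
        tree = ts.first()
        c = 0
        for site in ts.sites():
            dac = tree.num_samples(site.mutations[0].node)
            if 0 < dac / n_hap < freq_threshold:
                c += 1
        out[g] = c
    return out


def gene_burden(
    block: GeneBlock, freq_threshold: float = 0.001
) -> np.ndarray:
    """Per-individual count of rare derived alleles across the exons.

    Frequencies are computed in the analyzed sample; variants at or
    above the threshold (and intronic variants) are excluded.
    """
    if block.n_variants == 0:
        return np.zeros(block.dosage.shape[0], dtype=np.int64)
    n2 = 2 * block.dosage.shape[0]
    freq = block.dosage.sum(axis=0, dtype=np.int64) / n2
    keep = block.exonic & (freq < freq_threshold) & (freq > 0)
    return block.dosage[:, keep].sum(axis=1, dtype=np.int64)


def rare_exonic_count(block: GeneBlock, freq_threshold: float = 0.001) -> int:
    """Number of rare exonic variants in a gene block."""
    if block.n_variants == 0:
        return 0
    n2 = 2 * block.dosage.shape[0]
    freq = block.dosage.sum(axis=0, dtype=np.int64) / n2
    return int((block.exonic & (freq < freq_threshold) & (freq > 0)).sum())


def match_variant_counts(
    blocks: Sequence[GeneBlock],
    target_mean: float = 16.0,
    target_sd: float = 4.0,
    seed: int = 0,
    freq_threshold: float = 0.001,
) -> list[GeneBlock]:
    """Thin each gene's rare exonic variants to a sampled target count.

    Per gene a count is drawn from N(target_mean, target_sd²), rounded
    and floored at zero, and that many rare exonic variants are kept
    uniformly at random (carriers keep their deme labels — thinning is
    column selection only).  Matching the variant-count distribution
    between demographic models isolates the effect of history from the
    effect of variant number.  Genes with too few variants are flagged
    with a warning and keep everything they have.
    """
    rng = np.random.default_rng(seed)
    out = []
    short = 0
    for block in blocks:
        n2 = 2 * block.dosage.shape[0]
        freq = block.dosage.sum(axis=0, dtype=np.int64) / n2
        rare = np.flatnonzero(block.exonic & (freq < freq_threshold) & (freq > 0))
        other = np.setdiff1d(np.arange(block.n_variants), rare)
        want = max(int(round(rng.normal(target_mean, target_sd))), 0)
        if want > len(rare):
            short += 1
            keep_rare = rare
        else:
            keep_rare = np.sort(rng.choice(rare, size=want, replace=False))
        keep = np.sort(np.concatenate([keep_rare, other]))
        out.append(
            GeneBlock(
                block.gene_id,
                block.positions[keep],
                block.exonic[keep],
                block.dosage[:, keep],
            )
        )
    if short:
        warnings.warn(f"{short} genes had fewer rare variants than their target")
    return out


def burden_association(
    burdens: np.ndarray,
    phenotype: np.ndarray,
    covariates=None,
) -> tuple[float, float, float]:
    """Linear regression of phenotype on a gene's burden (+ covariates).

    Returns (beta, se, p); raises for a zero-variance burden so callers
    can skip the gene explicitly.
    """
    x = np.asarray(burdens, dtype=np.float64)
    y = np.asarray(phenotype, dtype=np.float64)
    if x.std() == 0:
        raise ValueError("burden is constant across individuals; gene skipped")
    from .association import _covariate_basis
    from scipy import stats as sps

    n = len(y)
    Q = _covariate_basis(n, covariates)
    k = Q.shape[1] - 1
    df = n - k - 2
    yr = y - Q @ (Q.T @ y)
    xr = x - Q @ (Q.T @ x)
    sxx = float(xr @ xr)
    if sxx <= 1e-12:
        raise ValueError("burden lies in the covariate span; gene skipped")
    b = float(yr @ xr) / sxx
    rss = float(yr @ yr) - b * float(yr @ xr)
    se = float(np.sqrt(max(rss, 0.0) / df / sxx))
    p = float(2.0 * sps.t.sf(abs(b) / se, df)) if se > 0 else 0.0
    return b, se, p


def gini_coefficient(deme_totals: np.ndarray) -> float:
    """Spatial concentration of burden across demes.

    Evaluates the cumulative-share form on burdens sorted increasing;
    the shares are normalized so y_n = 1, under which the formula is
    exactly 0 for a uniform distribution and (n−1)/n for a single-deme
    concentration.
    """
    t = np.asarray(deme_totals, dtype=np.float64)
    n = len(t)
    if n < 2:
        raise ValueError("Gini needs at least two demes")
    if (t < 0).any():
        raise ValueError("burdens must be non-negative")
    total = t.sum()
    if total == 0:
        raise ValueError("all-zero burden; Gini undefined")
    y = np.cumsum(np.sort(t)) / total
    return float((n - y[0] - (y[1:] + y[:-1]).sum()) / n)


def burden_result(
    counts: np.ndarray, deme_labels: np.ndarray, n_demes: Optional[int] = None
) -> BurdenResult:
    """Aggregate per-individual counts into deme totals and their Gini."""
    counts = np.asarray(counts)
    if n_demes is None:
        n_demes = int(np.max(deme_labels)) + 1
    totals = np.bincount(deme_labels, weights=counts, minlength=n_demes)
    return BurdenResult(counts, totals, gini_coefficient(totals))
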