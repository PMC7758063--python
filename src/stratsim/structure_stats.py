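"""Realized-structure statistics: LD pruning, Weir–Cockerham FST,
genomic inflation, and the birthplace-GWAS calibration.

FST uses the multi-population Weir & Cockerham (1984) variance
components with the ratio-of-averages convention: the among-deme
component ``a`` and the total ``a + b + c`` are each summed over
variants before the ratio is taken.  Confidence intervals come from a
block bootstrap over 1 Mb variant blocks, since single-variant FST
estimates are strongly autocorrelated through linkage.

Genomic inflation :math:`\\lambda_p` is the ratio of the observed
p-th percentile of the association test statistic to the p-th quantile
of :math:`\\chi^2_1`; the median (p=0.5) is the standard definition and
p=0.999 is the tail variant used to expose rare-variant stratification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps

from .genotype_sim import GenotypeDataset, VariantSet

__all__ = [
    "FstResult",
    "InflationResult",
    "ld_prune",
    "weir_cockerham_fst",
    "genomic_inflation",
    "rescale_lambda",
    "location_gwas_lambda",
]


@dataclass(frozen=True)
class FstResult:
    """Ratio-of-averages Weir–Cockerham FST with bootstrap CI."""

    fst: float
    ci_low: float
    ci_high: float
    n_variants: int


@dataclass(frozen=True)
class InflationResult:
    """Genomic inflation factor at one percentile."""

    lambda_p: float
    percentile: float
    n_tests: int


def ld_prune(
    dataset: GenotypeDataset,
    variants: VariantSet,
    window_size: int = 100,
    step: int = 10,
    r2_threshold: float = 0.1,
) -> VariantSet:
    """Greedy left-to-right LD pruning (window 100 variants, step 10, r² 0.1).

    Variants are scanned in genomic order; a variant is dropped when its
    squared genotype correlation with any retained variant in the
    trailing window exceeds the threshold, so the earlier variant is
    always the one retained.  After the scan no retained pair within a
    window violates the threshold.
    """
    idx = variants.indices
    if len(idx) == 0:
        return VariantSet(np.array([], dtype=np.int64), variants.label)
    n = dataset.n_individuals
    kept: list[int] = []
    # rolling buffer of centered dosage columns for retained variants
    buf_cols: list[np.ndarray] = []
    buf_ss: list[float] = []
    buf_order: list[int] = []  # position within `idx` of each retained variant
    chrom_of = dataset.variants["chrom"].to_numpy()
    order_pos = {int(v): i for i, v in enumerate(idx)}
    for sel, block in dataset.iter_dosage_chunks(idx):
        X = block.astype(np.float64)
        for j, v in enumerate(sel):
            i_ord = order_pos[int(v)]
            x = X[:, j] - X[:, j].mean()
            ssx = float(x @ x)
            # trailing window: retained variants within window_size-1
            # positions on the same chromosome
            while buf_order and (
                i_ord - buf_order[0] >= window_size
                or chrom_of[idx[buf_order[0]]] != chrom_of[v]
            ):
                buf_order.pop(0)
                buf_cols.pop(0)
                buf_ss.pop(0)
            drop = False
            if ssx <= 0:
                drop = True  # monomorphic in sample: nothing to retain
            else:
                for xk, ssk in zip(buf_cols, buf_ss):
                    num = float(xk @ x)
                    if num * num > r2_threshold * ssk * ssx:
                        drop = True
                        break
            if not drop:
                kept.append(int(v))
                buf_cols.append(x)
                buf_ss.append(ssx)
                buf_order.append(i_ord)
    return VariantSet(np.asarray(kept, dtype=np.int64), variants.label)


def _wc_components(
    D: np.ndarray, deme_ind: np.ndarray, n_per_deme: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir & Cockerham (1984) per-variant variance components.

    D is (variants x individuals) int dosage; ``deme_ind`` a dense
    (individuals x demes) 0/1 indicator.  Returns arrays (a, b, c).
    """
    r = deme_ind.shape[1]
    ni = n_per_deme.astype(np.float64)
    nbar = ni.mean()
    nc = (r * nbar - (ni**2).sum() / (r * nbar)) / (r - 1)
    Df = D.astype(np.float32)
    p = (Df @ deme_ind) / (2.0 * ni)  # per-deme derived frequency
    h = ((D == 1).astype(np.float32) @ deme_ind) / ni  # per-deme het freq
    p = p.astype(np.float64)
    h = h.astype(np.float64)
    pbar = (p * ni).sum(axis=1) / (r * nbar)
    s2 = (ni * (p - pbar[:, None]) ** 2).sum(axis=1) / ((r - 1) * nbar)
    hbar = (h * ni).sum(axis=1) / (r * nbar)
    pq = pbar * (1 - pbar)
    a = (nbar / nc) * (
        s2 - (pq - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pq - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def weir_cockerham_fst(
    dataset: GenotypeDataset,
    variants: VariantSet,
    deme_labels: Optional[np.ndarray] = None,
    block_bp: float = 1e6,
    n_boot: int = 1000,
    seed: int = 0,
) -> FstResult:
    """Mean FST across demes, ratio-of-averages, with block-bootstrap CI.

    Raises if fewer than two demes with at least two individuals each
    are present, or if every requested variant is monomorphic.
    """
    if deme_labels is None:
        deme_labels = dataset.deme_labels
    demes, counts = np.unique(deme_labels, return_counts=True)
    if len(demes) < 2 or (counts < 2).any():
        raise ValueError("FST needs >=2 demes with >=2 individuals each")
    dense = np.zeros((len(deme_labels), len(demes)), dtype=np.float32)
    for j, d in enumerate(demes):
        dense[deme_labels == d, j] = 1.0
    chrom = dataset.variants["chrom"].to_numpy()
    pos = dataset.variants["pos"].to_numpy()
    block_sums: dict[tuple[int, int], np.ndarray] = {}
    n_used = 0
    for sel, block in dataset.iter_dosage_chunks(variants.indices):
        dac = block.sum(axis=0, dtype=np.int64)
        poly = (dac > 0) & (dac < 2 * dataset.n_individuals)
        if not poly.any():
            continue
        D = block.T[poly]
        a, b, c = _wc_components(D, dense, counts)
        keys = [
            (int(chrom[v]), int(pos[v] // block_bp))
            for v in sel[poly]
        ]
        for k, av, tv in zip(keys, a, a + b + c):
            acc = block_sums.setdefault(k, np.zeros(2))
            acc[0] += av
            acc[1] += tv
        n_used += int(poly.sum())
    if n_used == 0:
        raise ValueError("all requested variants are monomorphic; FST undefined")
    blocks = np.array(list(block_sums.values()))
    tot = blocks.sum(axis=0)
    fst = tot[0] / tot[1]
    rng = np.random.default_rng(seed)
    nb = len(blocks)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        pick = rng.integers(0, nb, size=nb)
        s = blocks[pick].sum(axis=0)
        boots[i] = s[0] / s[1]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return FstResult(float(fst), float(lo), float(hi), n_used)


def genomic_inflation(test_stats: np.ndarray, percentile: float = 0.5) -> InflationResult:
    """λp: observed p-th percentile of χ² statistics over the null quantile."""
    stats = np.asarray(test_stats, dtype=np.float64)
    if not 0 < percentile < 1:
        raise ValueError("percentile must lie strictly in (0, 1)")
    if (stats < 0).any():
        raise ValueError("test statistics must be non-negative")
    if len(stats) < 1 / min(percentile, 1 - percentile):
        raise ValueError("too few tests to resolve the requested percentile")
    lam = np.quantile(stats, percentile) / sps.chi2.ppf(percentile, df=1)
    return InflationResult(float(lam), percentile, len(stats))


def rescale_lambda(lambda_obs: float, n0: float, n: float) -> float:
    """Rescale genomic inflation between sample sizes.

    Inflation minus one grows linearly with sample size:
    ``lambda_n = (n / n0) * (lambda_n0 - 1) + 1``.
    """
    if lambda_obs < 0:
        raise ValueError("lambda must be non-negative")
    if n0 <= 0 or n <= 0:
        raise ValueError("sample sizes must be positive")
    return (n / n0) * (lambda_obs - 1.0) + 1.0


def location_gwas_lambda(
    dataset: GenotypeDataset,
    variants: VariantSet,
    axis: str = "y",
    percentile: float = 0.5,
) -> InflationResult:
    """Genomic inflation of a GWAS on an individual's grid coordinate.

    The phenotype is the row (``axis="y"``, latitude) or column
    (``axis="x"``, longitude) coordinate of the sampled deme; each
    variant is tested by simple linear regression without covariates
    and λ is taken at ``percentile`` of the χ² (squared t) statistics.
    """
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    coord = dataset.samples["row" if axis == "y" else "col"].to_numpy(dtype=float)
    if np.ptp(coord) == 0:
        raise ValueError("all individuals share one coordinate; GWAS undefined")
    n = dataset.n_individuals
    y = coord - coord.mean()
    yss = float(y @ y)
    chi2 = np.empty(len(variants))
    k = 0
    for sel, block in dataset.iter_dosage_chunks(variants.indices):
        X = block.astype(np.float64)
        X -= X.mean(axis=0)
        sxx = (X * X).sum(axis=0)
        sxy = y @ X
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = sxy**2 / (sxx * yss)
        r2 = np.where(sxx > 0, r2, np.nan)
        t2 = (n - 2) * r2 / (1 - r2)
        chi2[k : k + len(sel)] = t2
        k += len(sel)
    chi2 = chi2[np.isfinite(chi2)]
    return genomic_inflation(chi2, percentile)
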