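"""Polygenic scores, residual-bias maps and the hybrid sib-reestimation
design.

A polygenic score is the dosage-weighted sum of estimated effects over
an ascertained variant set.  Because the cohort is simulated, every
individual's *true* genetic value g is known; the residual score
(score − g) isolates the part of the prediction that does not reflect
genetics — under residual stratification it recapitulates the spatial
environment, which the per-deme residual map makes visible.

Variant ascertainment mirrors clumping-and-thresholding: either the
causal variants themselves (when they pass the p-value threshold) or
the most significant SNP in a 100 kb window centered on each causal
variant ("lead SNPs").  Effects can be taken from the discovery GWAS
or reestimated in an independent second cohort of sib pairs or
unrelated individuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .association import SummaryStats, gwas_linear, sib_difference_scan
from .genotype_sim import GenotypeDataset, VariantSet
from .siblings import SibPairSet

__all__ = [
    "PGSResult",
    "ascertain_lead_snps",
    "compute_pgs",
    "residual_map",
    "prediction_accuracy",
    "reestimate_effects",
]


@dataclass(frozen=True)
class PGSResult:
    """Per-individual polygenic scores with their residuals.

    ``ascertainment`` is ``causal`` or ``lead_snp``; ``effect_source``
    one of ``gwas``, ``sib_reestimated``, ``unrelated_reestimated``.
    """

    scores: np.ndarray
    g: np.ndarray
    deme: np.ndarray
    ascertainment: str
    effect_source: str
    n_score_variants: int
    n_missing: int

    @property
    def residual(self) -> np.ndarray:
        return self.scores - self.g

    def accuracy(self) -> float:
        return prediction_accuracy(self.scores, self.g)


def ascertain_lead_snps(
    sumstats: SummaryStats,
    causal_variants: np.ndarray,
    dataset: GenotypeDataset,
    p_threshold: float = 5e-4,
    window_bp: float = 100_000.0,
    mode: str = "lead_snp",
) -> pd.DataFrame:
    """Clumping-and-thresholding ascertainment around causal variants.

    For each causal variant a window of ``window_bp`` is centered on
    it; every tested variant is assigned to its *nearest* causal
    variant so overlapping windows never claim the same SNP twice.

    ``mode="lead_snp"`` keeps the window's minimum-p variant when that
    p-value is below the threshold (position breaks ties);
    ``mode="causal"`` keeps the causal variant itself under the same
    threshold rule.  Windows with no sub-threshold variant contribute
    nothing.

    Returns a frame with columns ``window`` (causal variant index),
    ``variant`` (selected variant index) — one row per selected window.
    """
    if mode not in ("lead_snp", "causal"):
        raise ValueError(f"unknown ascertainment mode {mode!r}")
    causal_variants = np.asarray(causal_variants, dtype=np.int64)
    chrom = dataset.variants["chrom"].to_numpy()
    pos = dataset.variants["pos"].to_numpy()
    tab = sumstats.table[~sumstats.table["skipped"]]
    out_win, out_var = [], []
    half = window_bp / 2.0
    for c in np.unique(chrom[causal_variants]):
        caus_c = causal_variants[chrom[causal_variants] == c]
        caus_pos = pos[caus_c]
        t = tab[tab["chrom"] == c]
        if len(t) == 0:
            continue
        vpos = t["pos"].to_numpy()
        vidx = t["variant"].to_numpy()
        pval = t["p"].to_numpy()
        # nearest causal variant for every tested variant on the chromosome
        order = np.argsort(caus_pos)
        sorted_pos = caus_pos[order]
        ins = np.searchsorted(sorted_pos, vpos)
        ins = np.clip(ins, 1, len(sorted_pos) - 1) if len(sorted_pos) > 1 else np.zeros(
            len(vpos), dtype=int
        )
        if len(sorted_pos) > 1:
            left = sorted_pos[ins - 1]
            right = sorted_pos[ins]
            nearest = np.where(vpos - left <= right - vpos, ins - 1, ins)
        else:
            nearest = np.zeros(len(vpos), dtype=int)
        owner = caus_c[order][nearest]
        in_window = np.abs(vpos - pos[owner]) <= half
        for w in caus_c:
            if mode == "causal":
                hit = (vidx == w) & (pval < p_threshold)
                if hit.any():
                    out_win.append(int(w))
                    out_var.append(int(w))
                continue
            mask = (owner == w) & in_window & (pval < p_threshold)
            if not mask.any():
                continue
            sub_p = pval[mask]
            sub_v = vidx[mask]
            sub_pos = vpos[mask]
            best = np.lexsort((sub_pos, sub_p))[0]  # min p, then min position
            out_win.append(int(w))
            out_var.append(int(sub_v[best]))
    return pd.DataFrame({"window": out_win, "variant": out_var})


def compute_pgs(
    effects: pd.DataFrame | dict,
    test_dataset: GenotypeDataset,
    true_g: np.ndarray,
    ascertainment: str = "lead_snp",
    effect_source: str = "gwas",
) -> PGSResult:
    """Score every test individual: Σ β̂_k x_ik over selected variants.

    ``effects`` maps variant index to estimated effect (dict, or a
    frame with ``variant``/``beta`` columns).  Variants monomorphic in
    the test sample contribute zero automatically; their count is
    reported as ``n_missing``.
    """
    if isinstance(effects, pd.DataFrame):
        eff = dict(zip(effects["variant"].astype(int), effects["beta"].astype(float)))
    else:
        eff = {int(k): float(v) for k, v in effects.items()}
    true_g = np.asarray(true_g, dtype=np.float64)
    if len(true_g) != test_dataset.n_individuals:
        raise ValueError("true genetic values cover different individuals")
    idx = np.sort(np.fromiter(eff.keys(), dtype=np.int64))
    scores = np.zeros(test_dataset.n_individuals)
    n_missing = 0
    if len(idx):
        betas = np.array([eff[int(v)] for v in idx])
        X = test_dataset.dosages(idx).astype(np.float64)
        n_missing = int((X.sum(axis=0) == 0).sum())  # absent in test sample
        scores = X @ betas
    return PGSResult(
        scores,
        true_g,
        test_dataset.deme_labels,
        ascertainment,
        effect_source,
        len(idx),
        n_missing,
    )


def residual_map(
    result: PGSResult,
    geography=None,
    n_demes: Optional[int] = None,
) -> pd.DataFrame:
    """Mean residual polygenic score per deme in the test sample.

    Demes with no sampled individuals get NaN (missing, not zero).
    Returns columns ``deme``, ``row``, ``col``, ``mean_residual``, ``n``.
    """
    resid = result.residual
    demes = result.deme
    if n_demes is None:
        n_demes = (geography.n_demes if geography is not None else int(demes.max()) + 1)
    mean = np.full(n_demes, np.nan)
    count = np.zeros(n_demes, dtype=int)
    for d in range(n_demes):
        mask = demes == d
        count[d] = int(mask.sum())
        if count[d]:
            mean[d] = float(resid[mask].mean())
    if geography is not None:
        rows = np.asarray(geography.rows)
        cols = (
            geography.cols
            if hasattr(geography, "cols")
            else np.zeros(n_demes, dtype=int)
        )
    else:
        rows = np.zeros(n_demes, dtype=int)
        cols = np.zeros(n_demes, dtype=int)
    return pd.DataFrame(
        {
            "deme": np.arange(n_demes),
            "row": rows,
            "col": np.asarray(cols),
            "mean_residual": mean,
            "n": count,
        }
    )


def gradient_correlation(map_frame: pd.DataFrame) -> float:
    """Pearson correlation of per-deme mean residual with the row index.

    The north--south residual gradient statistic: near 0 for unbiased
    scores, large in magnitude when residual scores recapitulate a
    smooth environmental cline.
    """
    ok = map_frame["mean_residual"].notna()
    x = map_frame.loc[ok, "row"].to_numpy(dtype=float)
    y = map_frame.loc[ok, "mean_residual"].to_numpy(dtype=float)
    if len(x) < 3 or np.ptp(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def prediction_accuracy(scores: np.ndarray, g: np.ndarray) -> float:
    """Squared correlation between polygenic score and true genetic value."""
    scores = np.asarray(scores, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if len(scores) != len(g) or len(g) < 2:
        raise ValueError("need >=2 matched individuals")
    if np.std(scores) == 0 or np.std(g) == 0:
        warnings.warn("zero-variance input; accuracy defined as 0")
        return 0.0
    return float(np.corrcoef(scores, g)[0, 1] ** 2)


def reestimate_effects(
    selected: pd.DataFrame,
    second_cohort: GenotypeDataset | SibPairSet,
    phenotype: Optional[np.ndarray] = None,
    covariates=None,
    discovery_individuals: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Reestimate ascertained variants' effects in an independent cohort.

    ``second_cohort`` may be a :class:`SibPairSet` (sib-difference
    regression per variant; the pairs' ``delta_y`` is used) or a
    :class:`GenotypeDataset` of unrelated individuals (plain linear
    scan of ``phenotype``).  Ascertainment is left untouched: the
    variant list is exactly ``selected["variant"]``.  Variants
    monomorphic in the second cohort get effect 0 (flagged).

    ``discovery_individuals`` (engine-level individual ids of the
    discovery cohort) enables the independence guard; reestimating in
    a cohort overlapping the discovery sample is refused.
    """
    variant_idx = np.sort(np.unique(selected["variant"].to_numpy(dtype=np.int64)))
    if isinstance(second_cohort, SibPairSet):
        base = second_cohort.dataset
        cohort_ids = base.individual_index[
            np.unique(
                np.concatenate(
                    [second_cohort.pairs["parent1"], second_cohort.pairs["parent2"]]
                )
            )
        ]
    else:
        base = second_cohort
        cohort_ids = base.individual_index
    if discovery_individuals is not None:
        overlap = np.intersect1d(np.asarray(discovery_individuals), cohort_ids)
        if len(overlap):
            raise ValueError(
                f"second cohort shares {len(overlap)} individuals with the "
                "discovery cohort; reestimation requires independence"
            )
    if isinstance(second_cohort, SibPairSet):
        DX = second_cohort.delta_dosage(variant_idx).astype(np.float64)
        res = sib_difference_scan(DX, second_cohort.delta_y)
        beta = np.where(res["skipped"], 0.0, res["beta"]).astype(float)
        skipped = res["skipped"].to_numpy()
        source = "sib_reestimated"
    else:
        if phenotype is None:
            raise ValueError("unrelated-cohort reestimation needs a phenotype")
        stats = gwas_linear(
            second_cohort,
            phenotype,
            covariates=covariates,
            variants=VariantSet(variant_idx, "selected"),
        )
        beta = np.where(stats.table["skipped"], 0.0, stats.table["beta"]).astype(float)
        skipped = stats.table["skipped"].to_numpy()
        source = "unrelated_reestimated"
    return pd.DataFrame(
        {
            "variant": variant_idx,
            "beta": np.nan_to_num(beta),
            "skipped": skipped,
            "source": source,
        }
    )
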