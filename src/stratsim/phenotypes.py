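"""Phenotype simulation: structured environments and heritable traits.

Non-heritable phenotypes are pure environment, ``y_ij ~ N(mu_j,
sigma^2)`` for individual i in deme j.  Two spatial layouts are
supported: a *smooth* north--south gradient in which the deme means are
linear in the grid row with a total range of 2 sigma, and a *sharp*
local effect in which exactly one deme is shifted by 2 sigma.

Heritable traits use a frequency-dependent architecture: M causal
variants (one per 100 kb window), effects beta_k drawn with variance
proportional to [2 p_k (1 - p_k)]^alpha, and the frequency-independent
scale sigma_l^2 solved so the expected genetic variance sigma_g^2 =
sigma_l^2 * sum_k [2 p_k (1-p_k)]^(alpha+1) equals the target
heritability (h^2 = 0.8 over 2,000 causal variants at the default
scale, alpha = -0.4 as estimated for height).  For heritable traits the
environmental scale is sigma = sqrt(1 - h^2), so the structured shift
of 2 sigma is expressed relative to the residual standard deviation.

The true decomposition (genetic value, environmental mean, noise) is
retained in the returned :class:`PhenotypeSet`; downstream bias
analyses subtract the true genetic values rather than reconstructing
them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .genotype_sim import GenotypeDataset

__all__ = [
    "EnvironmentSpec",
    "TraitArchitecture",
    "PhenotypeSet",
    "make_environment",
    "select_causal_variants",
    "draw_effects",
    "assemble_phenotype",
    "simulate_trait",
]


@dataclass(frozen=True)
class EnvironmentSpec:
    """Spatially structured environment.

    ``smooth``: deme means linear in the row index, anchored at 0 in
    the northernmost row and reaching ``2 * noise_sd`` in the
    southernmost.  ``sharp``: mean ``2 * noise_sd`` in ``affected_deme``
    and 0 elsewhere.
    """

    kind: str
    noise_sd: float = 1.0
    affected_deme: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("smooth", "sharp", "none"):
            raise ValueError(f"unknown environment kind {self.kind!r}")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.kind == "sharp" and self.affected_deme is None:
            raise ValueError("sharp environment needs an affected deme")

    def deme_means(self, rows: np.ndarray, demes: np.ndarray) -> np.ndarray:
        """Environmental mean for each entry of (rows, demes)."""
        if self.kind == "none":
            return np.zeros(len(rows))
        if self.kind == "smooth":
            n_rows = int(rows.max()) + 1
            if n_rows == 1:
                return np.zeros(len(rows))
            return 2.0 * self.noise_sd * rows / (n_rows - 1)
        return np.where(demes == self.affected_deme, 2.0 * self.noise_sd, 0.0)


@dataclass(frozen=True)
class TraitArchitecture:
    """Causal variants and their true effects for a heritable trait."""

    causal_indices: np.ndarray
    betas: np.ndarray
    alpha: float
    h2: float
    sigma_l2: float

    @property
    def n_causal(self) -> int:
        return len(self.causal_indices)


@dataclass(frozen=True)
class PhenotypeSet:
    """Per-individual phenotype with its true decomposition.

    ``y = g + env_mean + noise`` holds exactly by construction.
    """

    y: np.ndarray
    g: np.ndarray
    env_mean: np.ndarray
    noise: np.ndarray
    deme: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "deme": self.deme,
                "y": self.y,
                "g": self.g,
                "env_mean": self.env_mean,
                "noise": self.noise,
            }
        )


def make_environment(
    spec: EnvironmentSpec, samples: pd.DataFrame, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-individual environmental means and noise.

    Returns ``(env_mean, noise)``; the phenotype contribution is their
    sum, kept separate so the decomposition can be stored.
    """
    rows = samples["row"].to_numpy()
    demes = samples["deme"].to_numpy()
    mu = spec.deme_means(rows, demes)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, spec.noise_sd, size=len(mu))
    return mu, noise


def select_causal_variants(
    dataset: GenotypeDataset, window_bp: float = 100_000.0, seed: int = 0
) -> np.ndarray:
    """One causal variant per 100 kb window, uniformly at random.

    Windows tile each chromosome half-open, [0, window), [window,
    2*window), ...; empty windows are skipped with a warning.  At the
    main 200 Mb preset this yields 2,000 causal variants.
    """
    rng = np.random.default_rng(seed)
    chrom = dataset.variants["chrom"].to_numpy()
    pos = dataset.variants["pos"].to_numpy()
    win = (pos // window_bp).astype(np.int64)
    chosen = []
    n_windows_expected = dataset.genome.n_chromosomes * int(
        np.ceil(dataset.genome.chromosome_length / window_bp)
    )
    seen = 0
    for c in range(dataset.genome.n_chromosomes):
        on_c = np.flatnonzero(chrom == c)
        for w in np.unique(win[on_c]):
            cand = on_c[win[on_c] == w]
            chosen.append(int(rng.choice(cand)))
            seen += 1
    if seen < n_windows_expected:
        warnings.warn(
            f"{n_windows_expected - seen} empty causal windows were skipped"
        )
    return np.sort(np.asarray(chosen, dtype=np.int64))


def draw_effects(
    freqs: np.ndarray, alpha: float, h2: float, seed: int
) -> tuple[np.ndarray, float]:
    """Draw causal effect sizes under the frequency-coupled model.

    ``Var(beta_k) = sigma_l^2 [2 p_k (1 - p_k)]^alpha`` with sigma_l^2
    solved so the expected genetic variance equals ``h2``.  Negative
    alpha makes rarer variants carry larger effects.
    """
    p = np.asarray(freqs, dtype=np.float64)
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("causal variant frequencies must lie strictly in (0, 1)")
    het = 2.0 * p * (1.0 - p)
    sigma_l2 = h2 / float((het ** (alpha + 1.0)).sum())
    rng = np.random.default_rng(seed)
    betas = rng.normal(0.0, np.sqrt(sigma_l2 * het**alpha))
    return betas, sigma_l2


def assemble_phenotype(
    g: np.ndarray,
    env_mean: np.ndarray,
    noise: np.ndarray,
    deme: np.ndarray,
) -> PhenotypeSet:
    """Combine components into a phenotype, storing the decomposition."""
    parts = [np.asarray(a, dtype=np.float64) for a in (g, env_mean, noise)]
    if len({len(a) for a in parts}) != 1 or len(parts[0]) != len(deme):
        raise ValueError("phenotype components cover different individuals")
    g, env_mean, noise = parts
    return PhenotypeSet(g + env_mean + noise, g, env_mean, noise, np.asarray(deme))


def simulate_trait(
    dataset: GenotypeDataset,
    architecture: Optional[TraitArchitecture],
    environment: EnvironmentSpec,
    seed: int,
) -> PhenotypeSet:
    """One phenotype realization for every individual in the dataset.

    With ``architecture=None`` the trait is non-heritable (h² = 0,
    Figure-2-style); otherwise genetic values are X_causal @ beta and
    the environment spec's noise sd should be sqrt(1 - h²).
    """
    if architecture is None:
        g = np.zeros(dataset.n_individuals)
    else:
        X = dataset.dosages(architecture.causal_indices).astype(np.float64)
        g = X @ architecture.betas
    mu, noise = make_environment(environment, dataset.samples, seed)
    return assemble_phenotype(g, mu, noise, dataset.deme_labels)


def heritable_trait(
    dataset: GenotypeDataset,
    environment_kind: str = "none",
    h2: float = 0.8,
    alpha: float = -0.4,
    window_bp: float = 100_000.0,
    affected_deme: Optional[int] = None,
    seed: int = 0,
) -> tuple[TraitArchitecture, PhenotypeSet]:
    """Convenience wrapper: pick causal variants, draw effects, simulate.

    The environmental noise sd is sqrt(1 - h²), and any structured
    shift (smooth/sharp) is 2x that residual scale.
    """
    causal = select_causal_variants(dataset, window_bp=window_bp, seed=seed)
    freqs = dataset.variants["frequency"].to_numpy()[causal]
    ok = (freqs > 0) & (freqs < 1)
    causal, freqs = causal[ok], freqs[ok]
    betas, sigma_l2 = draw_effects(freqs, alpha, h2, seed=seed + 1)
    arch = TraitArchitecture(causal, betas, alpha, h2, sigma_l2)
    env = EnvironmentSpec(
        environment_kind, noise_sd=float(np.sqrt(1.0 - h2)), affected_deme=affected_deme
    )
    phen = simulate_trait(dataset, arch, env, seed=seed + 2)
    return arch, phen
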