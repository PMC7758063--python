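"""Sibling pairs from structured within-deme matings.

Parents are drawn without replacement from the same deme (and are not
reused across pairs); each mating produces two children.  A child
receives, independently for every chromosome, one of the two
haplotypes of each parent — transmission without recombination, the
chromosome being the unit of segregation.  Because both sibs share a
deme, any deme-level environmental mean cancels exactly in their
phenotype difference, which is what the sibling-difference association
design exploits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .genotype_sim import GenotypeDataset
from .phenotypes import EnvironmentSpec, TraitArchitecture

__all__ = ["SibPairSet", "mate_within_deme", "sib_phenotypes"]


@dataclass
class SibPairSet:
    """Sibling pairs tied to the parental cohort they were bred from.

    ``pairs`` has one row per sib pair: ``pair``, ``deme``, ``parent1``
    and ``parent2`` (row positions in ``dataset.samples``).
    ``choices[p, s, c, j]`` in {0, 1} records which haplotype child s
    of pair p received from parent j on chromosome c.  Phenotypes
    (``y``, ``g``, ``noise``; shape (n_pairs, 2)) are attached by
    :func:`sib_phenotypes`.
    """

    dataset: GenotypeDataset
    pairs: pd.DataFrame
    choices: np.ndarray
    y: Optional[np.ndarray] = None
    g: Optional[np.ndarray] = None
    env_mean: Optional[np.ndarray] = None
    noise: Optional[np.ndarray] = None

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def delta_y(self) -> np.ndarray:
        if self.y is None:
            raise ValueError("phenotypes not yet attached; run sib_phenotypes")
        return self.y[:, 0] - self.y[:, 1]

    def parent_rows(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            self.pairs["parent1"].to_numpy(),
            self.pairs["parent2"].to_numpy(),
        )

    def child_dosages(self, variant_indices: np.ndarray) -> np.ndarray:
        """Dosage array of shape (n_pairs, 2, n_variants) for both sibs."""
        variant_indices = np.asarray(variant_indices, dtype=np.int64)
        p1, p2 = self.parent_rows()
        chrom_of = self.dataset.variants["chrom"].to_numpy()
        out = np.empty((self.n_pairs, 2, len(variant_indices)), dtype=np.int8)
        col_of = {int(v): i for i, v in enumerate(variant_indices)}
        for sel, H in self.dataset.iter_haplotype_chunks(variant_indices):
            # H: (2n x block); parent haplotype rows
            for j, v in enumerate(sel):
                c = int(chrom_of[v])
                col = col_of[int(v)]
                for s in (0, 1):
                    h1 = H[2 * p1 + self.choices[:, s, c, 0], j]
                    h2 = H[2 * p2 + self.choices[:, s, c, 1], j]
                    out[:, s, col] = h1 + h2
        return out

    def delta_dosage(self, variant_indices: np.ndarray) -> np.ndarray:
        """Between-sib dosage differences, shape (n_pairs, n_variants)."""
        d = self.child_dosages(variant_indices)
        return (d[:, 0, :] - d[:, 1, :]).astype(np.int8)

    def ibd_fraction_per_chromosome(self) -> np.ndarray:
        """Mendelian genome sharing per pair and chromosome.

        With whole-chromosome transmission each parent contributes a
        fully shared or fully unshared chromosome, so the fraction is
        0, 1/2 or 1; its expectation over pairs is 1/2.
        """
        same = self.choices[:, 0, :, :] == self.choices[:, 1, :, :]
        return same.mean(axis=2)


def mate_within_deme(
    dataset: GenotypeDataset, n_pairs_per_deme: int, seed: int
) -> SibPairSet:
    """Breed sib pairs by random within-deme matings.

    Each deme contributes ``n_pairs_per_deme`` pairs; the two parents
    of a pair are distinct individuals of that deme and no individual
    parents more than one pair.
    """
    if n_pairs_per_deme < 1:
        raise ValueError("need at least one pair per deme")
    if dataset.tree_sequences is None:
        raise ValueError("sibling breeding requires phased haplotypes")
    rng = np.random.default_rng(seed)
    demes = dataset.deme_labels
    rows_p1, rows_p2, deme_col = [], [], []
    for d in np.unique(demes):
        rows = np.flatnonzero(demes == d)
        if len(rows) < 2 * n_pairs_per_deme:
            raise ValueError(
                f"deme {d} has {len(rows)} individuals; "
                f"{2 * n_pairs_per_deme} parents needed"
            )
        perm = rng.permutation(rows)[: 2 * n_pairs_per_deme]
        rows_p1.append(perm[0::2])
        rows_p2.append(perm[1::2])
        deme_col.append(np.full(n_pairs_per_deme, d))
    p1 = np.concatenate(rows_p1)
    p2 = np.concatenate(rows_p2)
    pairs = pd.DataFrame(
        {
            "pair": np.arange(len(p1)),
            "deme": np.concatenate(deme_col),
            "parent1": p1,
            "parent2": p2,
        }
    )
    n_chrom = dataset.genome.n_chromosomes
    choices = rng.integers(0, 2, size=(len(p1), 2, n_chrom, 2), dtype=np.int8)
    return SibPairSet(dataset, pairs, choices)


def sib_phenotypes(
    sibs: SibPairSet,
    architecture: Optional[TraitArchitecture],
    environment: EnvironmentSpec,
    seed: int,
) -> SibPairSet:
    """Attach phenotypes to both children of every pair.

    Uses the same causal architecture (shared true effects) as the
    discovery trait; each sib gets the deme's environmental mean plus
    independent noise, so Δ(environmental mean) = 0 by construction.
    """
    n_pairs = sibs.n_pairs
    if architecture is None:
        g = np.zeros((n_pairs, 2))
    else:
        if architecture.causal_indices.max() >= sibs.dataset.n_variants:
            raise ValueError("architecture refers to variants outside the dataset")
        d = sibs.child_dosages(architecture.causal_indices).astype(np.float64)
        g = d @ architecture.betas
    deme = sibs.pairs["deme"].to_numpy()
    # environment evaluated at the pair's deme, shared by both sibs
    rows = _rows_for_demes(sibs.dataset, deme)
    mu = environment.deme_means(rows, deme)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, environment.noise_sd, size=(n_pairs, 2))
    y = g + mu[:, None] + noise
    sibs.y = y
    sibs.g = g
    sibs.env_mean = np.repeat(mu[:, None], 2, axis=1)
    sibs.noise = noise
    return sibs


def _rows_for_demes(dataset: GenotypeDataset, demes: np.ndarray) -> np.ndarray:
    """Grid row of each deme, looked up from the sample table."""
    mapping = (
        dataset.samples.drop_duplicates("deme").set_index("deme")["row"].to_dict()
    )
    return np.asarray([mapping[d] for d in demes])
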