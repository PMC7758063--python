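"""Stepping-stone demographic models on grid and adjacency geographies.

Three model kinds are supported, all with per-deme diploid size 10,000:

``perpetual``
    Symmetric stepping-stone structure extending indefinitely into the
    past (:math:`\\tau = \\infty`).
``recent``
    The same stepping stone, but all demes collapse into a single
    ancestral population :math:`\\tau = 100` generations ago.
``complex``
    Demes are created 100 generations ago by admixture between two
    source populations along a north--south ancestry cline; the sources
    exchange migrants at rate ``m1`` and may themselves descend from an
    older layered history (hunter-gatherer / early-farmer style).

Migration-rate semantics: a migration-matrix entry is the proportion of
a deme replaced per generation by migrants from one adjacent deme (the
matrix is symmetric, so the same proportion moves "in and out").  This
is also the backward-time lineage-migration rate passed to the
coalescent engine, which is the standard equivalence for conservative
migration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import msprime

__all__ = [
    "GridSpec",
    "AdjacencyGeography",
    "AdmixtureSpec",
    "DemographySpec",
    "build_grid_migration_matrix",
    "build_adjacency_migration_matrix",
    "assign_admixture_cline",
    "build_demography",
    "load_england_wales_fixture",
]

DEFAULT_DEME_NE = 10_000
DEFAULT_TAU = 100
#: Depth (generations) at which the perpetual model's structured phase is
#: truncated into a panmictic phase of the total metapopulation size.  At
#: the calibrated migration rates the slowest spatial relaxation time is
#: ~50 generations, so 1,000 generations is deep in the stationary regime;
#: pass ``horizon=None`` for the literal infinite-structure model.
DEFAULT_PERPETUAL_HORIZON = 1_000


@dataclass(frozen=True)
class GridSpec:
    """A rectangular lattice of demes; row 0 is the northernmost row."""

    n_rows: int = 6
    n_cols: int = 6

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")

    @property
    def n_demes(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def deme_ids(self) -> list[int]:
        return list(range(self.n_demes))

    def coordinates(self, deme: int) -> tuple[int, int]:
        """(row, col) of a deme; demes are numbered row-major from the north."""
        if not 0 <= deme < self.n_demes:
            raise ValueError(f"deme {deme} outside grid")
        return divmod(deme, self.n_cols)

    @property
    def rows(self) -> np.ndarray:
        """Row (latitude) index of every deme, shape (n_demes,)."""
        return np.repeat(np.arange(self.n_rows), self.n_cols)

    @property
    def cols(self) -> np.ndarray:
        """Column (longitude) index of every deme, shape (n_demes,)."""
        return np.tile(np.arange(self.n_cols), self.n_rows)

    def neighbors(self, deme: int) -> list[int]:
        """Rook (4-neighbor) adjacency on the lattice."""
        r, c = self.coordinates(deme)
        out = []
        if r > 0:
            out.append(deme - self.n_cols)
        if r < self.n_rows - 1:
            out.append(deme + self.n_cols)
        if c > 0:
            out.append(deme - 1)
        if c < self.n_cols - 1:
            out.append(deme + 1)
        return out


@dataclass(frozen=True)
class AdjacencyGeography:
    """An irregular geography given by an explicit deme adjacency list.

    Used for the England/Wales-style map.  ``row_index`` orders demes
    along the north--south axis (0 = northernmost band) so that clines
    and smooth environments remain definable; ``sampling_weights`` give
    relative cohort sampling probabilities per deme (non-uniform
    sampling mimics biobank ascertainment).
    """

    deme_names: tuple[str, ...]
    edges: tuple[tuple[int, int], ...]
    row_index: tuple[int, ...]
    sampling_weights: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        n = len(self.deme_names)
        for a, b in self.edges:
            if a == b:
                raise ValueError("self-adjacency is not allowed")
            if not (0 <= a < n and 0 <= b < n):
                raise ValueError("edge endpoint outside deme range")
        if len(self.row_index) != n:
            raise ValueError("row_index must cover every deme")
        if self.sampling_weights is not None and len(self.sampling_weights) != n:
            raise ValueError("sampling_weights must cover every deme")

    @property
    def n_demes(self) -> int:
        return len(self.deme_names)

    @property
    def rows(self) -> np.ndarray:
        return np.asarray(self.row_index)

    def degree(self) -> np.ndarray:
        deg = np.zeros(self.n_demes, dtype=int)
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg


def build_grid_migration_matrix(grid: GridSpec, m: float) -> np.ndarray:
    """Symmetric stepping-stone migration matrix for a lattice.

    Entry ``(i, j)`` is ``m`` when demes i and j are rook neighbors and
    zero otherwise.  Corner demes therefore have two nonzero entries,
    edge demes three and interior demes four.

    Parameters
    ----------
    grid
        Lattice geometry.
    m
        Per-generation proportion of a deme exchanged with each
        adjacent deme; must be non-negative.
    """
    if m < 0:
        raise ValueError("migration rate must be non-negative")
    M = np.zeros((grid.n_demes, grid.n_demes))
    for i in range(grid.n_demes):
        for j in grid.neighbors(i):
            M[i, j] = m
    return M


def build_adjacency_migration_matrix(
    adjacency: Sequence[tuple[int, int]], m: float, n_demes: Optional[int] = None
) -> np.ndarray:
    """Migration matrix from an explicit list of abutting deme pairs.

    The binary adjacency matrix (1 if two demes abut) is multiplied by
    the migration parameter ``m``.
    """
    if m < 0:
        raise ValueError("migration rate must be non-negative")
    if n_demes is None:
        n_demes = 1 + max((max(a, b) for a, b in adjacency), default=-1)
    M = np.zeros((n_demes, n_demes))
    for a, b in adjacency:
        if a == b:
            raise ValueError("self-adjacency is not allowed")
        M[a, b] = m
        M[b, a] = m
    return M


def assign_admixture_cline(
    grid: GridSpec | AdjacencyGeography, fraction_north: float, fraction_south: float
) -> np.ndarray:
    """Per-deme ancestry fractions interpolated linearly along rows.

    Returns the proportion of ancestry drawn from the northern source
    population for every deme; all demes in one row share a fraction.
    A single-row geography receives ``fraction_north`` everywhere.
    """
    for f in (fraction_north, fraction_south):
        if not 0 <= f <= 1:
            raise ValueError("admixture fractions must lie in [0, 1]")
    rows = grid.rows
    n_rows = int(rows.max()) + 1
    if n_rows == 1:
        return np.full(len(rows), float(fraction_north))
    row_frac = np.linspace(fraction_north, fraction_south, n_rows)
    return row_frac[rows]


@dataclass(frozen=True)
class AdmixtureSpec:
    """Two-source admixture creating the demes of the complex model.

    ``fractions[i]`` is the proportion of deme i's ancestry drawn from
    the northern source.  The sources exchange migrants at rate ``m1``
    between the admixture time and their own common origin.  When
    ``ancient_layers`` is true the sources themselves descend from a
    three-population hunter-gatherer / early-farmer style history whose
    split times, admixture times and proportions are configurable
    (none of them are calibrated quantities; only ``m1`` is).
    """

    fractions: tuple[float, ...]
    m1: float = 0.004
    admixture_time: float = 100.0
    source_ne: float = DEFAULT_DEME_NE
    source_split_time: float = 2_000.0
    ancient_layers: bool = False
    # WHG/EHG/EF-style layer parameters, used only if ancient_layers is set.
    layer_admixture_time: float = 250.0
    north_proportions: tuple[float, float, float] = (0.4, 0.4, 0.2)  # WHG, EHG, EF
    south_proportions: tuple[float, float, float] = (0.2, 0.0, 0.8)
    hg_split_time: float = 2_000.0
    root_time: float = 6_000.0

    def __post_init__(self) -> None:
        if not all(0 <= f <= 1 for f in self.fractions):
            raise ValueError("admixture fractions must lie in [0, 1]")
        diffs = np.diff(np.asarray(self.fractions, dtype=float))
        # fractions follow the north-south axis as a monotone cline
        if not (np.all(diffs <= 1e-12) or np.all(diffs >= -1e-12)):
            raise ValueError("admixture fractions must be monotone along the cline")


@dataclass(frozen=True)
class DemographySpec:
    """Declarative description of one of the three demographic models."""

    model_kind: str
    geography: GridSpec | AdjacencyGeography
    migration: np.ndarray
    deme_ne: float = DEFAULT_DEME_NE
    ancestral_ne: float = DEFAULT_DEME_NE
    collapse_time: Optional[float] = None
    admixture: Optional[AdmixtureSpec] = None
    perpetual_horizon: Optional[float] = DEFAULT_PERPETUAL_HORIZON

    def __post_init__(self) -> None:
        if self.model_kind not in ("perpetual", "recent", "complex"):
            raise ValueError(f"unknown model kind {self.model_kind!r}")
        if self.deme_ne <= 0 or self.ancestral_ne <= 0:
            raise ValueError("population sizes must be positive")
        M = np.asarray(self.migration)
        if M.shape != (self.n_demes, self.n_demes):
            raise ValueError("migration matrix shape does not match geography")
        if (M < 0).any() or not np.allclose(M, M.T):
            raise ValueError("migration matrix must be symmetric and non-negative")
        if np.diag(M).any():
            raise ValueError("migration matrix diagonal must be zero")
        if self.model_kind == "perpetual" and self.collapse_time is not None:
            raise ValueError("perpetual model has no collapse event")
        if self.model_kind == "recent" and self.collapse_time is None:
            raise ValueError("recent model requires a collapse time")
        if self.model_kind == "complex" and self.admixture is None:
            raise ValueError("complex model requires an AdmixtureSpec")

    @property
    def n_demes(self) -> int:
        return self.geography.n_demes

    def deme_name(self, i: int) -> str:
        return f"d{i}"

    def to_msprime(self) -> msprime.Demography:
        """Translate into an ``msprime.Demography``.

        The perpetual model's structured phase is truncated at
        ``perpetual_horizon`` generations, beyond which lineages
        coalesce panmictically at the total metapopulation size (the
        strong-migration limit); set the horizon to ``None`` for the
        literal infinite-structure model.
        """
        dem = msprime.Demography()
        n = self.n_demes
        for i in range(n):
            dem.add_population(name=self.deme_name(i), initial_size=self.deme_ne)
        M = np.asarray(self.migration)
        for i in range(n):
            for j in range(i + 1, n):
                if M[i, j] > 0:
                    dem.set_symmetric_migration_rate(
                        [self.deme_name(i), self.deme_name(j)], M[i, j]
                    )
        names = [self.deme_name(i) for i in range(n)]
        if self.model_kind == "recent":
            dem.add_population(name="anc", initial_size=self.ancestral_ne)
            dem.add_population_split(
                time=self.collapse_time, derived=names, ancestral="anc"
            )
        elif self.model_kind == "perpetual":
            if self.perpetual_horizon is not None:
                dem.add_population(name="deep", initial_size=self.deme_ne * n)
                dem.add_population_split(
                    time=self.perpetual_horizon, derived=names, ancestral="deep"
                )
        else:
            self._add_complex_history(dem, names)
        dem.sort_events()
        return dem

    def _add_complex_history(self, dem: msprime.Demography, names: list[str]) -> None:
        adx = self.admixture
        assert adx is not None
        if len(adx.fractions) != self.n_demes:
            raise ValueError("admixture fractions must cover every deme")
        dem.add_population(name="src_north", initial_size=adx.source_ne)
        dem.add_population(name="src_south", initial_size=adx.source_ne)
        dem.set_symmetric_migration_rate(["src_north", "src_south"], adx.m1)
        t = adx.admixture_time
        for name, f in zip(names, adx.fractions):
            if f >= 1.0:
                dem.add_population_split(time=t, derived=[name], ancestral="src_north")
            elif f <= 0.0:
                dem.add_population_split(time=t, derived=[name], ancestral="src_south")
            else:
                dem.add_admixture(
                    time=t,
                    derived=name,
                    ancestral=["src_north", "src_south"],
                    proportions=[f, 1.0 - f],
                )
        if not adx.ancient_layers:
            dem.add_population(name="root", initial_size=self.ancestral_ne)
            dem.add_population_split(
                time=adx.source_split_time,
                derived=["src_north", "src_south"],
                ancestral="root",
            )
            return
        # WHG/EHG/EF-style layered history behind the two sources.
        for name in ("WHG", "EHG", "EF"):
            dem.add_population(name=name, initial_size=adx.source_ne)
        for src, props in (
            ("src_north", adx.north_proportions),
            ("src_south", adx.south_proportions),
        ):
            anc = [a for a, p in zip(("WHG", "EHG", "EF"), props) if p > 0]
            prp = [p for p in props if p > 0]
            if abs(sum(prp) - 1) > 1e-9:
                raise ValueError("ancient-layer proportions must sum to 1")
            if len(anc) == 1:
                dem.add_population_split(
                    time=adx.layer_admixture_time, derived=[src], ancestral=anc[0]
                )
            else:
                dem.add_admixture(
                    time=adx.layer_admixture_time,
                    derived=src,
                    ancestral=anc,
                    proportions=prp,
                )
        dem.add_population(name="HG_anc", initial_size=adx.source_ne)
        dem.add_population_split(
            time=adx.hg_split_time, derived=["WHG", "EHG"], ancestral="HG_anc"
        )
        dem.add_population(name="root", initial_size=self.ancestral_ne)
        dem.add_population_split(
            time=adx.root_time, derived=["HG_anc", "EF"], ancestral="root"
        )

    # -- JSON round trip ---------------------------------------------------

    def to_json(self) -> str:
        d: dict = {
            "model_kind": self.model_kind,
            "deme_ne": self.deme_ne,
            "ancestral_ne": self.ancestral_ne,
            "collapse_time": self.collapse_time,
            "perpetual_horizon": self.perpetual_horizon,
            "migration": np.asarray(self.migration).tolist(),
        }
        if isinstance(self.geography, GridSpec):
            d["geography"] = {
                "type": "grid",
                "n_rows": self.geography.n_rows,
                "n_cols": self.geography.n_cols,
            }
        else:
            g = self.geography
            d["geography"] = {
                "type": "adjacency",
                "deme_names": list(g.deme_names),
                "edges": [list(e) for e in g.edges],
                "row_index": list(g.row_index),
                "sampling_weights": (
                    list(g.sampling_weights) if g.sampling_weights else None
                ),
            }
        if self.admixture is not None:
            a = self.admixture
            d["admixture"] = {
                "fractions": list(a.fractions),
                "m1": a.m1,
                "admixture_time": a.admixture_time,
                "source_ne": a.source_ne,
                "source_split_time": a.source_split_time,
                "ancient_layers": a.ancient_layers,
                "layer_admixture_time": a.layer_admixture_time,
                "north_proportions": list(a.north_proportions),
                "south_proportions": list(a.south_proportions),
                "hg_split_time": a.hg_split_time,
                "root_time": a.root_time,
            }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DemographySpec":
        d = json.loads(text)
        g = d["geography"]
        if g["type"] == "grid":
            geography: GridSpec | AdjacencyGeography = GridSpec(
                g["n_rows"], g["n_cols"]
            )
        else:
            geography = AdjacencyGeography(
                deme_names=tuple(g["deme_names"]),
                edges=tuple(tuple(e) for e in g["edges"]),
                row_index=tuple(g["row_index"]),
                sampling_weights=(
                    tuple(g["sampling_weights"]) if g.get("sampling_weights") else None
                ),
            )
        admixture = None
        if d.get("admixture") is not None:
            a = d["admixture"]
            admixture = AdmixtureSpec(
                fractions=tuple(a["fractions"]),
                m1=a["m1"],
                admixture_time=a["admixture_time"],
                source_ne=a["source_ne"],
                source_split_time=a["source_split_time"],
                ancient_layers=a["ancient_layers"],
                layer_admixture_time=a["layer_admixture_time"],
                north_proportions=tuple(a["north_proportions"]),
                south_proportions=tuple(a["south_proportions"]),
                hg_split_time=a["hg_split_time"],
                root_time=a["root_time"],
            )
        return cls(
            model_kind=d["model_kind"],
            geography=geography,
            migration=np.asarray(d["migration"]),
            deme_ne=d["deme_ne"],
            ancestral_ne=d["ancestral_ne"],
            collapse_time=d["collapse_time"],
            admixture=admixture,
            perpetual_horizon=d["perpetual_horizon"],
        )


def build_demography(
    kind: str,
    geography: GridSpec | AdjacencyGeography | None = None,
    m: float = 0.05,
    *,
    tau: float = DEFAULT_TAU,
    deme_ne: float = DEFAULT_DEME_NE,
    ancestral_ne: float = DEFAULT_DEME_NE,
    admixture: Optional[AdmixtureSpec] = None,
    fraction_north: float = 1.0,
    fraction_south: float = 0.0,
    m1: float = 0.004,
    perpetual_horizon: Optional[float] = DEFAULT_PERPETUAL_HORIZON,
) -> DemographySpec:
    """Build one of the three demographic models at migration rate ``m``.

    Parameters
    ----------
    kind
        ``"perpetual"``, ``"recent"`` or ``"complex"``.
    geography
        Defaults to the 6x6 grid.
    m
        Stepping-stone migration rate between adjacent demes (the
        complex model's ``m2``).
    tau
        Collapse time in generations for the recent model (default 100).
    admixture
        Full admixture specification for the complex model; if omitted
        one is built from the linear north--south cline
        ``fraction_north`` -> ``fraction_south`` with source migration
        ``m1``.
    perpetual_horizon
        Deep-history truncation for the perpetual model (see
        :meth:`DemographySpec.to_msprime`).
    """
    if geography is None:
        geography = GridSpec()
    if isinstance(geography, GridSpec):
        migration = build_grid_migration_matrix(geography, m)
    else:
        migration = build_adjacency_migration_matrix(
            geography.edges, m, n_demes=geography.n_demes
        )
    if kind == "perpetual":
        return DemographySpec(
            "perpetual", geography, migration, deme_ne, ancestral_ne,
            collapse_time=None, perpetual_horizon=perpetual_horizon,
        )
    if kind == "recent":
        return DemographySpec(
            "recent", geography, migration, deme_ne, ancestral_ne, collapse_time=tau
        )
    if kind == "complex":
        if admixture is None:
            fractions = tuple(
                assign_admixture_cline(geography, fraction_north, fraction_south)
            )
            admixture = AdmixtureSpec(fractions=fractions, m1=m1, admixture_time=tau)
        return DemographySpec(
            "complex", geography, migration, deme_ne, ancestral_ne,
            collapse_time=None, admixture=admixture,
        )
    raise ValueError(f"unknown model kind {kind!r}")


def load_england_wales_fixture() -> AdjacencyGeography:
    """Load the shipped synthetic 35-region England/Wales-style geography.

    The adjacency list, north--south banding and sampling weights are a
    synthetic stand-in for the NUTS2 map of England and Wales: 35
    contiguous regions with one far-south-western region ("cornwall")
    heavily down-weighted (17 expected samples against 250 under
    uniform sampling) to mimic uneven biobank ascertainment.
    """
    from importlib.resources import files

    text = (files("stratsim") / "data" / "england_wales_synthetic.json").read_text()
    d = json.loads(text)
    return AdjacencyGeography(
        deme_names=tuple(d["deme_names"]),
        edges=tuple(tuple(e) for e in d["edges"]),
        row_index=tuple(d["row_index"]),
        sampling_weights=tuple(d["sampling_weights"]),
    )
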