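"""Discrete-time demographic models with migration bands and population paths.

A model consists of a strictly increasing grid of coalescence times (years
before present), a binary population tree whose divergence events sit at
"half time-points" (midpoints between adjacent grid times), piecewise-constant
diploid effective sizes per population, and a set of *migration bands*: each
band is an instantaneous gene-flow opportunity from a forwards-in-time source
population into a destination population at a fixed half time-point, with a
prior probability ``p_M`` that a lineage traced backwards through the band
follows the migrant path.

The central derived object is the *population path*: the assignment of one
population to each grid time point for a lineage traced from the present (or
its sampling age) back to the root.  A lineage with no migrations follows the
divergence tree; each band it encounters may be taken (relabelling it to the
source population) or passed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "TimeGrid",
    "Population",
    "MigrationBand",
    "SampleConfig",
    "PopulationPath",
    "DemographicModel",
    "build_time_grid",
    "snap_to_half_time",
    "enumerate_paths",
    "scale_model",
    "ModelError",
]

#: default human generation time in years
GENERATION_TIME = 29.0


class ModelError(ValueError):
    """Raised for inconsistent or invalid demographic model input."""


@dataclass(frozen=True)
class TimeGrid:
    """Discrete coalescence times plus the half time-points between them.

    ``coal_times`` are K strictly increasing times in years before present,
    starting at 0.  ``half_times`` are the K-1 arithmetic midpoints of
    adjacent coalescence times; divergence and migration events live there.
    """

    coal_times: tuple[float, ...]
    half_times: tuple[float, ...]

    @property
    def K(self) -> int:
        return len(self.coal_times)

    def __post_init__(self):
        t = np.asarray(self.coal_times, dtype=float)
        if t.size < 2:
            raise ModelError("time grid needs at least 2 points")
        if t[0] != 0:
            raise ModelError("first grid time must be 0")
        if np.any(np.diff(t) <= 0):
            raise ModelError("grid times must be strictly increasing")


def build_time_grid(times: Sequence[float]) -> TimeGrid:
    """Build a :class:`TimeGrid` from coalescence times in years.

    Half time-points are the arithmetic midpoints of adjacent times.
    """
    t = tuple(float(x) for x in times)
    if len(t) < 2 or t[0] != 0 or any(b <= a for a, b in zip(t, t[1:])):
        raise ModelError(f"invalid time grid: {times!r}")
    half = tuple((a + b) / 2.0 for a, b in zip(t, t[1:]))
    return TimeGrid(coal_times=t, half_times=half)


#: the 20-point default grid, in years (denser near the present)
DEFAULT_GRID_KYA = (
    0, 100, 200, 300, 400, 450, 500, 550, 600, 700,
    950, 1200, 1450, 1700, 2000, 3000, 5000, 7000, 13000, 15000,
)


def default_time_grid() -> TimeGrid:
    return build_time_grid([x * 1000.0 for x in DEFAULT_GRID_KYA])


@dataclass(frozen=True)
class Population:
    """A population (branch of the divergence tree).

    ``parent`` is ``None`` only for the root.  ``divergence_time`` is the time
    (years) at which this population merges into its parent, rounded onto a
    half time-point by the model.  ``sizes`` is either a scalar diploid
    effective size, or a list of ``(start_year, N)`` pieces (piecewise
    constant, pieces apply from ``start_year`` backwards until the next
    piece).  Ghost populations carry no samples and may omit sizes: no
    coalescence is permitted within them.
    """

    name: str
    parent: Optional[str] = None
    divergence_time: Optional[float] = None
    sizes: object = None  # scalar or [(start_year, N), ...]
    is_ghost: bool = False


@dataclass(frozen=True)
class MigrationBand:
    """Instantaneous gene-flow opportunity ``source -> dest`` (forwards in time).

    Backwards in time, a lineage found in ``dest`` at the band's (half) time
    follows the migrant path with prior probability ``prior_rate`` and
    relabels to ``source``.
    """

    source: str
    dest: str
    time: float  # years; snapped to a half time-point by the model
    prior_rate: float = 0.01

    @property
    def name(self) -> str:
        return f"{self.source}->{self.dest}"


@dataclass(frozen=True)
class SampleConfig:
    """One sampled individual: diploid (two haploid lineages) or haploid."""

    sample_id: str
    population: str
    age: float = 0.0  # years before present
    ploidy: int = 2
    phased: bool = False

    @property
    def lineages(self) -> tuple[str, ...]:
        if self.ploidy == 1:
            return (self.sample_id,)
        return (f"{self.sample_id}_1", f"{self.sample_id}_2")


@dataclass(frozen=True)
class PopulationPath:
    """Population label (index) per grid time point for one lineage.

    ``band`` indexes the model's band list if the path takes a migration,
    else ``None``; ``band_j`` is the half-time index of that band (the
    migration happens between grid times ``band_j`` and ``band_j + 1``).
    """

    pops: tuple[int, ...]
    band: Optional[int] = None
    band_j: Optional[int] = None

    @property
    def is_migrant(self) -> bool:
        return self.band is not None


class DemographicModel:
    """Validated demographic model over a discrete time grid.

    Times are stored in years and converted to coalescent units through
    ``generation_time``.  All divergence, band and sampling times are snapped
    onto the grid at construction (divergence/band times to half time-points,
    sample ages to grid times), with ties broken toward the younger time.
    """

    def __init__(
        self,
        grid: TimeGrid,
        populations: Sequence[Population],
        bands: Sequence[MigrationBand] = (),
        samples: Sequence[SampleConfig] = (),
        generation_time: float = GENERATION_TIME,
        max_migrations: int = 1,
    ):
        self.grid = grid
        self.generation_time = float(generation_time)
        self.max_migrations = int(max_migrations)
        if self.generation_time <= 0:
            raise ModelError("generation_time must be positive")

        self.pop_names = [p.name for p in populations]
        if len(set(self.pop_names)) != len(self.pop_names):
            raise ModelError("duplicate population names")
        self.pop_index = {n: i for i, n in enumerate(self.pop_names)}

        roots = [p for p in populations if p.parent is None]
        if len(roots) != 1:
            raise ModelError(f"model must have exactly one root population, got {len(roots)}")
        self._root = roots[0].name

        # snap divergence times to half time-points
        self.populations: list[Population] = []
        for p in populations:
            if p.parent is None:
                self.populations.append(p)
                continue
            if p.parent not in self.pop_index:
                raise ModelError(f"unknown parent population {p.parent!r}")
            if p.divergence_time is None:
                raise ModelError(f"population {p.name!r} has a parent but no divergence_time")
            self.populations.append(
                replace(p, divergence_time=snap_to_half_time(self, p.divergence_time))
            )
        # half-time index of each population's merge into its parent (None for root)
        self._div_j: list[Optional[int]] = []
        for p in self.populations:
            if p.parent is None:
                self._div_j.append(None)
            else:
                self._div_j.append(self.grid.half_times.index(p.divergence_time))
        self._check_tree()

        # snap band times
        self.bands: list[MigrationBand] = []
        self._band_j: list[int] = []
        for b in bands:
            for nm in (b.source, b.dest):
                if nm not in self.pop_index:
                    raise ModelError(f"unknown population {nm!r} in band {b.name}")
            if not 0.0 < b.prior_rate < 1.0:
                raise ModelError(f"band {b.name}: prior_rate must be in (0,1)")
            snapped = snap_to_half_time(self, b.time)
            j = self.grid.half_times.index(snapped)
            for nm in (b.source, b.dest):
                dj = self._div_j[self.pop_index[nm]]
                if dj is not None and dj <= j:
                    raise ModelError(
                        f"band {b.name} at {snapped:g}y: population {nm!r} has already "
                        f"merged at {self.populations[self.pop_index[nm]].divergence_time:g}y"
                    )
            self.bands.append(replace(b, time=snapped))
            self._band_j.append(j)

        # snap sample ages to grid times
        self.samples: list[SampleConfig] = []
        for s in samples:
            if s.population not in self.pop_index:
                raise ModelError(f"sample {s.sample_id}: unknown population {s.population!r}")
            if self.populations[self.pop_index[s.population]].is_ghost:
                raise ModelError(f"sample {s.sample_id}: ghost populations carry no samples")
            if s.ploidy not in (1, 2):
                raise ModelError(f"sample {s.sample_id}: ploidy must be 1 or 2")
            if s.age < 0:
                raise ModelError(f"sample {s.sample_id}: negative age")
            # ages are kept as given; inference snaps them onto the grid
            # through age_index (nearest grid time, ties toward younger)
            self.samples.append(s)

        self._build_lineage_maps()
        self._build_size_table()
        self._build_paths()
        self._lineage_names = []
        self._lineage_pops = []
        self._lineage_ages = []
        for s in self.samples:
            self._lineage_names.extend(s.lineages)
            self._lineage_pops.extend([self.pop_index[s.population]] * s.ploidy)
            self._lineage_ages.extend([self.age_index(s.age)] * s.ploidy)
        self._coal_gens = np.asarray(self.grid.coal_times) / self.generation_time

    # ------------------------------------------------------------------ #

    @property
    def K(self) -> int:
        return self.grid.K

    @property
    def root(self) -> str:
        return self._root

    @property
    def lineage_names(self) -> list[str]:
        return self._lineage_names

    @property
    def lineage_pops(self) -> list[int]:
        return self._lineage_pops

    @property
    def lineage_ages(self) -> list[int]:
        """Grid time index of each haploid lineage's sampling age."""
        return self._lineage_ages

    def age_index(self, age_years: float) -> int:
        return int(np.argmin(np.abs(np.asarray(self.grid.coal_times) - age_years)))

    def _check_tree(self):
        for p, dj in zip(self.populations, self._div_j):
            if p.parent is None:
                continue
            pj = self._div_j[self.pop_index[p.parent]]
            if pj is not None and dj >= pj:
                raise ModelError(
                    f"population {p.name!r} diverges at/above its parent's own merge"
                )

    def _build_lineage_maps(self):
        """resident population-label map per grid time, for every population."""
        K, P = self.K, len(self.populations)
        m = np.empty((P, K), dtype=np.int32)
        for i, p in enumerate(self.populations):
            cur = i
            for t in range(K):
                while self._div_j[cur] is not None and t >= self._div_j[cur] + 1:
                    cur = self.pop_index[self.populations[cur].parent]
                m[i, t] = cur
        self._lineage_map = m
        if len(set(m[:, K - 1])) != 1:
            raise ModelError("model must coalesce to a single population by the oldest time")

    def _build_size_table(self):
        """diploid N per (population, interval); inf for ghosts (no coalescence)."""
        K = self.K
        N = np.full((len(self.populations), K - 1), np.inf)
        for i, p in enumerate(self.populations):
            if p.sizes is None:
                if not p.is_ghost:
                    raise ModelError(f"population {p.name!r} is not a ghost and needs sizes")
                continue
            if p.is_ghost:
                continue  # within-ghost coalescence disabled regardless
            if np.isscalar(p.sizes):
                if p.sizes <= 0:
                    raise ModelError(f"population {p.name!r}: non-positive size")
                N[i, :] = float(p.sizes)
            else:
                pieces = sorted((float(t0), float(n)) for t0, n in p.sizes)
                if pieces[0][0] > 0:
                    pieces.insert(0, (0.0, pieces[0][1]))
                for m in range(K - 1):
                    t0 = self.grid.coal_times[m]
                    n = [nn for (s0, nn) in pieces if s0 <= t0][-1]
                    if n <= 0:
                        raise ModelError(f"population {p.name!r}: non-positive size")
                    N[i, m] = n
        self._size = N

    def size_at(self, pop: int, interval: int) -> float:
        return float(self._size[pop, interval])

    def resident_map(self, pop: str | int) -> np.ndarray:
        i = pop if isinstance(pop, (int, np.integer)) else self.pop_index[pop]
        return self._lineage_map[i]

    def is_ghost(self, pop: int) -> bool:
        return self.populations[pop].is_ghost

    def _migrant_extension(self, base: np.ndarray, bi: int) -> Optional[np.ndarray]:
        """Path obtained from ``base`` by taking band ``bi``; None if unavailable."""
        b = self.bands[bi]
        j = self._band_j[bi]
        if base[j] != self.pop_index[b.dest]:
            return None
        out = base.copy()
        out[j + 1:] = self._lineage_map[self.pop_index[b.source], j + 1:]
        return out

    def _build_paths(self):
        """Enumerate population paths per (non-ghost) start population.

        Paths are stored in a single global table; ``path_ids_for(pop)`` gives
        the ids available to a lineage sampled in ``pop`` (resident first).
        """
        self.paths: list[PopulationPath] = []
        self._path_ids: dict[int, list[int]] = {}
        for i, p in enumerate(self.populations):
            if p.is_ghost:
                continue
            ids = []
            base = self._lineage_map[i]
            ids.append(len(self.paths))
            self.paths.append(PopulationPath(pops=tuple(int(x) for x in base)))
            if self.max_migrations >= 1:
                # one-migration paths; deeper recursion unsupported by default
                for bi in range(len(self.bands)):
                    ext = self._migrant_extension(base, bi)
                    if ext is not None:
                        ids.append(len(self.paths))
                        self.paths.append(
                            PopulationPath(
                                pops=tuple(int(x) for x in ext),
                                band=bi,
                                band_j=self._band_j[bi],
                            )
                        )
            self._path_ids[i] = ids

    @property
    def path_pops_matrix(self) -> np.ndarray:
        """(n_paths, K) population index per grid time, for label matching."""
        m = getattr(self, "_path_pops_matrix", None)
        if m is None:
            m = np.asarray([p.pops for p in self.paths], dtype=np.int64)
            self._path_pops_matrix = m
        return m

    def path_ids_for(self, pop: str | int) -> list[int]:
        i = pop if isinstance(pop, (int, np.integer)) else self.pop_index[pop]
        return self._path_ids[i]

    def resident_path_id(self, pop: str | int) -> int:
        return self.path_ids_for(pop)[0]

    @property
    def max_paths(self) -> int:
        """P: the maximum number of population paths available to any lineage."""
        return max((len(v) for v in self._path_ids.values()), default=1)

    # -- time unit helpers --------------------------------------------- #

    def gens(self, years: float) -> float:
        return years / self.generation_time

    def interval_gens(self, m: int) -> float:
        return (self.grid.coal_times[m + 1] - self.grid.coal_times[m]) / self.generation_time

    def time_gens(self, idx: int) -> float:
        return float(self._coal_gens[idx])

    def band_index(self, band: MigrationBand | str | int) -> int:
        if isinstance(band, (int, np.integer)):
            return int(band)
        name = band if isinstance(band, str) else band.name
        for i, b in enumerate(self.bands):
            if b.name == name:
                return i
        raise ModelError(f"band {name!r} not in model")


# ---------------------------------------------------------------------- #
# module-level operations
# ---------------------------------------------------------------------- #


def snap_to_half_time(model: "DemographicModel | TimeGrid", time: float) -> float:
    """Round ``time`` (years) to the nearest half time-point.

    Ties break toward the younger half time-point.  Times outside
    ``[0, oldest grid time]`` are rejected.
    """
    grid = model.grid if isinstance(model, DemographicModel) else model
    if time < 0 or time > grid.coal_times[-1]:
        raise ModelError(f"time {time:g} outside grid range [0, {grid.coal_times[-1]:g}]")
    half = np.asarray(grid.half_times)
    d = np.abs(half - time)
    return float(half[int(np.argmin(d))])  # argmin returns first (younger) on ties


def enumerate_paths(
    model: DemographicModel,
    start_pop: str,
    start_time: float = 0.0,
    max_migrations: Optional[int] = None,
) -> list[PopulationPath]:
    """All population paths for a lineage sampled in ``start_pop``.

    Only bands at or above ``start_time`` can be taken.  With no bands the
    single resident path (the divergence-tree lineage map) is returned.
    """
    if start_pop not in model.pop_index:
        raise ModelError(f"unknown population {start_pop!r}")
    i = model.pop_index[start_pop]
    if model.populations[i].is_ghost:
        raise ModelError(f"cannot start a sampled lineage in ghost population {start_pop!r}")
    if max_migrations is None:
        max_migrations = model.max_migrations
    a = model.age_index(start_time)
    out = [p for p in (model.paths[k] for k in model.path_ids_for(i))
           if max_migrations >= 1 or not p.is_migrant]
    return [p for p in out if not p.is_migrant or p.band_j >= a]


def scale_model(model: DemographicModel, factor: float) -> DemographicModel:
    """Return a copy with every population size multiplied by ``factor``."""
    if factor <= 0:
        raise ModelError("scale factor must be positive")
    pops = []
    for p in model.populations:
        if p.sizes is None:
            pops.append(p)
        elif np.isscalar(p.sizes):
            pops.append(replace(p, sizes=p.sizes * factor))
        else:
            pops.append(replace(p, sizes=[(t0, n * factor) for t0, n in p.sizes]))
    return DemographicModel(
        grid=model.grid,
        populations=pops,
        bands=list(model.bands),
        samples=list(model.samples),
        generation_time=model.generation_time,
        max_migrations=model.max_migrations,
    )
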