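"""Coalescent simulation with ground-truth migrant tracts.

Data sets are generated with msprime under the same demographic model used
for inference: the population tree with its piecewise-constant sizes, pulse
admixture at the migration-band times, and ancient sampling ages.  A census
recorded one generation above each pulse identifies, for every sampled
lineage and local tree, whether its ancestor at the pulse time sits in the
band's source population — that interval is then a *truth* migrant tract.

Mutations are dropped under a binary (ancestral/derived) model using a
synthetic piecewise mutation-rate map averaging 1.45e-8 per generation per
site; recombination uses a constant 5e-9 per bp per generation by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import msprime
import numpy as np

from .demography import DemographicModel, ModelError
from .io import CompressedAlignment, compress_alignment
from .presets import recent_introgression_model

__all__ = [
    "SimDataset",
    "synthetic_mutation_map",
    "simulate_dataset",
    "degrade",
    "dataset_to_alignment",
    "nea_to_hum_config",
    "simulate_nea_to_hum",
]

DEFAULT_RECOMB = 5e-9
DEFAULT_MU_MEAN = 1.45e-8
DEFAULT_GHOST_SIZE = 13_000


@dataclass
class SimDataset:
    """Simulated genotypes plus per-lineage truth migrant tracts."""

    alleles: np.ndarray        # (n_lineages, n_sites) int8 0/1/-1
    positions: np.ndarray      # (n_sites,) 0-based bp
    window_bp: int
    truth: dict[str, list[list[tuple[int, int]]]]  # band -> per-lineage tracts
    model: DemographicModel
    seed: int
    mu_map: tuple[np.ndarray, np.ndarray]  # (breaks, per-site rates)
    recomb_rate: float
    masks: Optional[dict] = None

    @property
    def lineage_names(self) -> list[str]:
        return self.model.lineage_names

    def truth_fraction(self, band: str, lineage: int) -> float:
        bp = sum(b - a for a, b in self.truth[band][lineage])
        return bp / self.window_bp


def synthetic_mutation_map(
    length_bp: int,
    rng: np.random.Generator,
    mean: float = DEFAULT_MU_MEAN,
    window_bp: int = 100_000,
    cv: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise mutation map with gamma-distributed window rates, rescaled
    so the length-weighted average equals ``mean`` exactly."""
    n = max(1, int(np.ceil(length_bp / window_bp)))
    breaks = np.minimum(np.arange(n + 1) * window_bp, length_bp).astype(float)
    shape = 1.0 / cv**2
    rates = rng.gamma(shape, mean / shape, size=n)
    widths = np.diff(breaks)
    rates *= mean / np.average(rates, weights=widths)
    return breaks[:-1], rates


def _msprime_demography(
    model: DemographicModel,
    ghost_size: float = DEFAULT_GHOST_SIZE,
    admixture: Optional[dict[str, float]] = None,
    growth: Optional[dict] = None,
) -> msprime.Demography:
    dem = msprime.Demography()
    gt = model.generation_time
    for i, p in enumerate(model.populations):
        if p.sizes is None:
            n0 = ghost_size
        elif np.isscalar(p.sizes):
            n0 = float(p.sizes)
        else:
            n0 = float(sorted(p.sizes)[0][1])
        dem.add_population(name=p.name, initial_size=n0)
    # piecewise size changes
    for p in model.populations:
        if p.sizes is None or np.isscalar(p.sizes):
            continue
        for t0, n in sorted(p.sizes)[1:]:
            dem.add_population_parameters_change(
                time=t0 / gt, population=p.name, initial_size=float(n)
            )
    # splits grouped by (parent, time)
    groups: dict[tuple[str, float], list[str]] = {}
    for p in model.populations:
        if p.parent is not None:
            groups.setdefault((p.parent, p.divergence_time), []).append(p.name)
    for (parent, t), derived in groups.items():
        dem.add_population_split(time=t / gt, derived=derived, ancestral=parent)
    # pulse admixture at band times (backwards: dest lineages move to source)
    if admixture:
        for name, prop in admixture.items():
            if prop <= 0:
                continue
            if not 0 < prop < 1:
                raise ModelError(f"admixture proportion for {name} must be in (0,1)")
            bi = model.band_index(name)
            b = model.bands[bi]
            dem.add_mass_migration(
                time=b.time / gt, source=b.dest, dest=b.source, proportion=prop
            )
    if growth:
        # recent exponential growth for one population (present size given)
        dem[growth["population"]].initial_size = growth["present_size"]
        dem[growth["population"]].growth_rate = growth["rate"]
        dem.add_population_parameters_change(
            time=growth["start"] / gt,
            population=growth["population"],
            initial_size=growth["base_size"],
            growth_rate=0.0,
        )
    # census one generation above each distinct pulse time, for truth tracts
    if admixture:
        for t in sorted({model.bands[model.band_index(n)].time
                         for n, p in admixture.items() if p > 0}):
            dem.add_census(time=t / gt + 1.0)
    dem.sort_events()
    return dem


def _extract_tracts(
    ts,
    n_lineages: int,
    events: list[tuple[str, float, int, Sequence[int]]],
) -> dict[str, list[list[tuple[int, int]]]]:
    """Per-lineage truth tracts from census nodes.

    ``events`` holds ``(band_name, census_time_gens, source_pop_id,
    recipient_lineage_rows)``; a tract covers the trees where the recipient
    lineage's ancestor at the census sits in the source population.
    """
    truth: dict[str, list[list[tuple[int, int]]]] = {
        name: [[] for _ in range(n_lineages)] for name, _, _, _ in events
    }
    node_time = ts.tables.nodes.time
    node_pop = ts.tables.nodes.population
    samples = list(ts.samples())
    for tree in ts.trees():
        left, right = int(tree.interval.left), int(tree.interval.right)
        for name, tc, src_id, rows in events:
            for li in rows:
                u = samples[li]
                while u != -1 and node_time[u] < tc - 1e-9:
                    u = tree.parent(u)
                if u == -1 or abs(node_time[u] - tc) > 1e-6:
                    continue
                if int(node_pop[u]) == src_id:
                    tr = truth[name][li]
                    if tr and tr[-1][1] == left:
                        tr[-1] = (tr[-1][0], right)
                    else:
                        tr.append((left, right))
    return truth


def simulate_dataset(
    model: DemographicModel,
    length_bp: int,
    admixture: Optional[dict[str, float]] = None,
    recomb_rate: float = DEFAULT_RECOMB,
    mu=None,
    seed: int = 1,
    ghost_size: float = DEFAULT_GHOST_SIZE,
    growth: Optional[dict] = None,
) -> SimDataset:
    """Structured-coalescent simulation under ``model`` with pulse admixture.

    ``admixture`` maps band names (e.g. ``"Afr->Nea"``) to pulse proportions;
    bands not listed (or at proportion 0) contribute no migrants and empty
    truth tracts.  ``mu`` is a scalar rate, a ``(breaks, rates)`` map, or
    None for a synthetic map averaging 1.45e-8.
    """
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    admixture = dict(admixture or {})
    for name in admixture:
        model.band_index(name)  # validates
    rng = np.random.default_rng(seed)
    if mu is None:
        mu_map = synthetic_mutation_map(length_bp, rng)
    elif np.isscalar(mu):
        mu_map = (np.array([0.0]), np.array([float(mu)]))
    else:
        mu_map = (np.asarray(mu[0], dtype=float), np.asarray(mu[1], dtype=float))

    demog = _msprime_demography(model, ghost_size, admixture, growth)
    gt = model.generation_time
    sample_sets = [
        msprime.SampleSet(1, population=s.population, time=s.age / gt,
                          ploidy=s.ploidy)
        for s in model.samples
    ]
    seeds = rng.integers(1, 2**31 - 1, size=2)
    ts = msprime.sim_ancestry(
        samples=sample_sets,
        demography=demog,
        sequence_length=length_bp,
        recombination_rate=recomb_rate,
        random_seed=int(seeds[0]),
    )
    breaks, rates = mu_map
    rate_map = msprime.RateMap(
        position=np.concatenate([breaks, [length_bp]]), rate=rates
    )
    mts = msprime.sim_mutations(
        ts, rate=rate_map, model=msprime.BinaryMutationModel(),
        random_seed=int(seeds[1]),
    )
    G = mts.genotype_matrix()  # (sites, lineages)
    pos = mts.sites_position.astype(np.int64)
    seg = (G.min(axis=1) == 0) & (G.max(axis=1) == 1)
    pop_id = {p.name: i for i, p in enumerate(demog.populations)}
    lin_pop = model.lineage_pops
    events = []
    for name, prop in admixture.items():
        if prop <= 0:
            continue
        b = model.bands[model.band_index(name)]
        rows = [i for i in range(len(lin_pop))
                if lin_pop[i] == model.pop_index[b.dest]]
        events.append((name, b.time / gt + 1.0, pop_id[b.source], rows))
    truth = _extract_tracts(ts, len(model.lineage_names), events)
    for name in admixture:
        truth.setdefault(name, [[] for _ in model.lineage_names])
    return SimDataset(
        alleles=G[seg].T.astype(np.int8),
        positions=pos[seg],
        window_bp=int(length_bp),
        truth=truth,
        model=model,
        seed=int(seed),
        mu_map=mu_map,
        recomb_rate=recomb_rate,
    )


def degrade(
    dataset: SimDataset,
    phase_randomize: bool = True,
    masks: Optional[dict] = None,
    seed: int = 0,
) -> SimDataset:
    """Apply phase randomization and/or BED-style missingness masks.

    Phase randomization swaps the two alleles of each unphased diploid at
    heterozygous sites with probability one half per site; the unordered
    genotype per site is invariant.  Masked intervals (per sample or
    lineage) are set missing at the covered variant sites and recorded so
    that compression marks invariant columns missing too.
    """
    rng = np.random.default_rng(seed)
    alleles = dataset.alleles.copy()
    if phase_randomize:
        i = 0
        for s in dataset.model.samples:
            if s.ploidy == 2 and not s.phased:
                h1, h2 = i, i + 1
                het = alleles[h1] != alleles[h2]
                flip = het & (rng.random(alleles.shape[1]) < 0.5)
                a1 = alleles[h1].copy()
                alleles[h1, flip] = alleles[h2, flip]
                alleles[h2, flip] = a1[flip]
            i += s.ploidy
    if masks:
        names = dataset.lineage_names
        by_sample = {s.sample_id: s for s in dataset.model.samples}
        for key, ivals in masks.items():
            rows = ([names.index(key)] if key in names
                    else [names.index(n) for n in by_sample[key].lineages])
            for a, b in ivals:
                hit = (dataset.positions >= a) & (dataset.positions < b)
                for r in rows:
                    alleles[r, hit] = -1
    merged_masks = dict(dataset.masks or {})
    for k, v in (masks or {}).items():
        merged_masks[k] = list(merged_masks.get(k, [])) + list(v)
    return replace(dataset, alleles=alleles, masks=merged_masks or None)


def dataset_to_alignment(dataset: SimDataset, compress: int = 10) -> CompressedAlignment:
    """Compress a simulated data set for inference (shares the true mutation
    map, as in a matched-model analysis)."""
    return compress_alignment(
        positions=dataset.positions,
        site_alleles=dataset.alleles,
        window_bp=dataset.window_bp,
        lineage_names=dataset.lineage_names,
        compress=compress,
        mu=dataset.mu_map,
        masks=dataset.masks,
        samples=dataset.model.samples,
    )


# ------------------------------------------------------------------ #
# recent (Nea->Hum) introgression preset
# ------------------------------------------------------------------ #

@dataclass(frozen=True)
class NeaToHumConfig:
    """Simulation preset for the recent Neanderthal-into-European pulse.

    Europeans split from Africans 100 kya with initial size 2,100 and grow
    exponentially at rate 0.002/generation from 42 kya to a present-day size
    of 37,236; 2% Neanderthal admixture enters Europeans at 50 kya.  An
    optional 5% human-into-Neanderthal pulse at 250 kya supports
    direction-confusion experiments.
    """

    n_afr_lineages: int = 86
    n_eur_lineages: int = 4
    eur_split: float = 100e3
    eur_base_size: float = 2_100
    growth_rate: float = 0.002
    growth_start: float = 42e3
    eur_present_size: float = 37_236
    admix_nea_eur: float = 0.02
    t_admix: float = 50e3
    hum_to_nea: float = 0.0
    t_hum_to_nea: float = 250e3

    def scaled_down(self, n_afr_lineages: int, n_eur_lineages: int) -> "NeaToHumConfig":
        """Fewer samples; every event time and proportion is preserved."""
        return replace(self, n_afr_lineages=n_afr_lineages,
                       n_eur_lineages=n_eur_lineages)


def nea_to_hum_config(
    n_afr_lineages: int = 86,
    n_eur_lineages: int = 4,
    include_hum_to_nea: bool = False,
) -> NeaToHumConfig:
    return NeaToHumConfig(
        n_afr_lineages=n_afr_lineages,
        n_eur_lineages=n_eur_lineages,
        hum_to_nea=0.05 if include_hum_to_nea else 0.0,
    )


def simulate_nea_to_hum(
    config: NeaToHumConfig,
    length_bp: int,
    seed: int = 1,
    mu=None,
    recomb_rate: float = DEFAULT_RECOMB,
) -> SimDataset:
    """Simulate the recent-introgression design (phased samples).

    The simulator models the European split and growth explicitly; the
    returned data set's ``model`` is the matched *inference* model, which
    keeps all humans in a single population on the coarse time grid with a
    Nea->Hum band at 50 kya.  Truth tracts are stored under the inference
    band names: ``Nea->Hum`` for the pulse into Europeans, ``Hum->Nea`` for
    the optional reverse pulse into Neanderthals.
    """
    if config.n_afr_lineages % 2 or config.n_eur_lineages % 2:
        raise ValueError("haploid lineage counts must be even (diploid samples)")
    n_afr = config.n_afr_lineages // 2
    n_eur = config.n_eur_lineages // 2
    inf_model = recent_introgression_model(n_afr=n_afr, n_eur=n_eur,
                                           t_mig=config.t_admix)
    gt = inf_model.generation_time
    rng = np.random.default_rng(seed)
    if mu is None:
        mu_map = synthetic_mutation_map(length_bp, rng)
    elif np.isscalar(mu):
        mu_map = (np.array([0.0]), np.array([float(mu)]))
    else:
        mu_map = (np.asarray(mu[0], dtype=float), np.asarray(mu[1], dtype=float))

    from .presets import AFR_SIZE, DEN_SIZES, HND_SIZE, NEADEN_SIZE, NEA_SIZES, ROOT_SIZE

    dem = msprime.Demography()
    dem.add_population(name="Afr", initial_size=AFR_SIZE)
    dem.add_population(name="Eur", initial_size=config.eur_present_size,
                       growth_rate=config.growth_rate)
    dem.add_population(name="Nea", initial_size=NEA_SIZES[0][1])
    dem.add_population(name="Den", initial_size=DEN_SIZES[0][1])
    dem.add_population(name="Chimp", initial_size=20_000)
    dem.add_population(name="NeaDen", initial_size=NEADEN_SIZE)
    dem.add_population(name="HND", initial_size=HND_SIZE)
    dem.add_population(name="Root", initial_size=ROOT_SIZE)
    for t0, n in NEA_SIZES[1:]:
        dem.add_population_parameters_change(time=t0 / gt, population="Nea",
                                             initial_size=n)
    for t0, n in DEN_SIZES[1:]:
        dem.add_population_parameters_change(time=t0 / gt, population="Den",
                                             initial_size=n)
    dem.add_population_parameters_change(
        time=config.growth_start / gt, population="Eur",
        initial_size=config.eur_base_size, growth_rate=0.0,
    )
    t_admix = config.t_admix / gt
    dem.add_mass_migration(time=t_admix, source="Eur", dest="Nea",
                           proportion=config.admix_nea_eur)
    dem.add_census(time=t_admix + 1.0)
    if config.hum_to_nea > 0:
        t_rev = config.t_hum_to_nea / gt
        dem.add_mass_migration(time=t_rev, source="Nea", dest="Afr",
                               proportion=config.hum_to_nea)
        dem.add_census(time=t_rev + 1.0)
    dem.add_population_split(time=config.eur_split / gt, derived=["Eur"],
                             ancestral="Afr")
    dem.add_population_split(time=415e3 / gt, derived=["Nea", "Den"],
                             ancestral="NeaDen")
    dem.add_population_split(time=575e3 / gt, derived=["Afr", "NeaDen"],
                             ancestral="HND")
    dem.add_population_split(time=6.0e6 / gt, derived=["HND", "Chimp"],
                             ancestral="Root")
    dem.sort_events()

    sample_sets = (
        [msprime.SampleSet(n_afr, population="Afr", ploidy=2)]
        + [msprime.SampleSet(n_eur, population="Eur", ploidy=2)]
        + [msprime.SampleSet(1, population="Nea", time=115e3 / gt, ploidy=2)]
        + [msprime.SampleSet(1, population="Nea", time=52e3 / gt, ploidy=2)]
        + [msprime.SampleSet(1, population="Chimp", ploidy=1)]
    )
    seeds = rng.integers(1, 2**31 - 1, size=2)
    ts = msprime.sim_ancestry(
        samples=sample_sets, demography=dem, sequence_length=length_bp,
        recombination_rate=recomb_rate, random_seed=int(seeds[0]),
    )
    breaks, rates = mu_map
    rate_map = msprime.RateMap(position=np.concatenate([breaks, [length_bp]]),
                               rate=rates)
    mts = msprime.sim_mutations(ts, rate=rate_map,
                                model=msprime.BinaryMutationModel(),
                                random_seed=int(seeds[1]))
    G = mts.genotype_matrix()
    pos = mts.sites_position.astype(np.int64)
    seg = (G.min(axis=1) == 0) & (G.max(axis=1) == 1)
    pop_id = {p.name: i for i, p in enumerate(dem.populations)}
    n_lin = len(inf_model.lineage_names)
    eur_rows = list(range(2 * n_afr, 2 * n_afr + 2 * n_eur))
    nea_rows = list(range(2 * (n_afr + n_eur), 2 * (n_afr + n_eur) + 4))
    events = [("Nea->Hum", t_admix + 1.0, pop_id["Nea"], eur_rows)]
    if config.hum_to_nea > 0:
        events.append(("Hum->Nea", config.t_hum_to_nea / gt + 1.0,
                       pop_id["Afr"], nea_rows))
    truth = _extract_tracts(ts, n_lin, events)
    truth.setdefault("Nea->Hum", [[] for _ in range(n_lin)])
    return SimDataset(
        alleles=G[seg].T.astype(np.int8),
        positions=pos[seg],
        window_bp=int(length_bp),
        truth=truth,
        model=inf_model,
        seed=int(seed),
        mu_map=mu_map,
        recomb_rate=recomb_rate,
    )
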