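"""Gibbs-style MCMC over ARGs: sequential initialization, leaf re-threading
sweeps, phase integration for unphased diploids, burn-in/thinning/migration
delay.

One iteration removes and re-threads every haploid lineage once (in input
order).  Migrant population paths are disabled for the first ``start_mig``
iterations so the chain can establish a sound ARG before exploring the
migration space.  Samples are retained every ``thin`` iterations after
``burnin``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from .arg import ARG, LocalTree, thread, unthread, validate_tree
from .demography import DemographicModel
from .threading import EmissionContext, sample_threading

__all__ = ["ChainConfig", "IterationResult", "initialize_arg", "run_chain", "resample_phase"]

#: default recombination rate, per bp per generation
DEFAULT_RECOMB_RATE = 5e-9


@dataclass
class ChainConfig:
    """MCMC schedule; the defaults mirror a standard production run."""

    n_iter: int = 2000
    burnin: int = 500
    thin: int = 20
    start_mig: int = 100
    seed: int = 0
    recomb_rate: float = DEFAULT_RECOMB_RATE

    def __post_init__(self):
        if self.n_iter <= 0 or self.thin <= 0 or self.burnin < 0 or self.start_mig < 0:
            raise ValueError("chain config values must be positive (burnin/start_mig >= 0)")
        if self.burnin > self.n_iter:
            raise ValueError("burnin must not exceed n_iter")


@dataclass
class IterationResult:
    iteration: int
    loglik: float
    migrant_columns: dict[str, int]
    sample: Optional[ARG] = None


def initialize_arg(
    ctx: EmissionContext,
    model: DemographicModel,
    rng: np.random.Generator,
    recomb_rate: float = DEFAULT_RECOMB_RATE,
) -> ARG:
    """Build a starting ARG by threading lineages one at a time, in input
    order, with migrant states disabled."""
    lineages = list(range(len(model.lineage_names)))
    ages = model.lineage_ages
    pops = model.lineage_pops
    first = lineages[0]
    tree0 = LocalTree.single_lineage(
        n_slots=len(lineages), leaf=first, age=ages[first],
        path_id=model.resident_path_id(pops[first]),
    )
    arg = ARG(ctx.L, [0], [tree0])
    for lin in lineages[1:]:
        pieces, _ = sample_threading(
            arg, model, ctx, lin, rng, recomb_rate, allow_migrant=False
        )
        arg = thread(arg, pieces, lineage=lin, age=ages[lin], model=model)
    return arg


def _migrant_column_counts(arg: ARG, model: DemographicModel) -> dict[str, int]:
    counts = {b.name: 0 for b in model.bands}
    for start, end, tree in arg.segments():
        for v in tree.crossing_nodes(model):
            bi = model.paths[int(tree.path[v])].band
            counts[model.bands[bi].name] += end - start
    return counts


def run_chain(
    ctx: EmissionContext,
    model: DemographicModel,
    config: ChainConfig,
    check: bool = False,
) -> Iterator[IterationResult]:
    """Run the sampler; yields one :class:`IterationResult` per iteration,
    with ``sample`` set on retained iterations.

    The emission context is copied: phase integration resamples the allele
    assignment of unphased diploids in place during their re-threading.
    ``check=True`` validates every local tree of every retained sample.
    """
    rng = np.random.default_rng(config.seed)
    ctx = EmissionContext(ctx.alleles.copy(), ctx.mu_eff, ctx.widths)
    lineages = list(range(len(model.lineage_names)))
    ages = model.lineage_ages
    unphased_pairs = _unphased_pairs(model)
    cache: dict = {}
    arg = initialize_arg(ctx, model, rng, config.recomb_rate)
    for it in range(1, config.n_iter + 1):
        allow_mig = it > config.start_mig and len(model.bands) > 0
        total_ll = 0.0
        for lin in lineages:
            partial, rec = unthread(arg, lin, model)
            pieces, ll = sample_threading(
                partial, model, ctx, lin, rng, config.recomb_rate,
                allow_migrant=allow_mig, state_cache=cache,
            )
            arg = thread(partial, pieces, lineage=lin, age=ages[lin], model=model)
            total_ll += ll
            if lin in unphased_pairs:
                resample_phase(arg, model, ctx, unphased_pairs[lin], rng)
        retained = it > config.burnin and (it - config.burnin) % config.thin == 0
        sample = None
        if retained:
            sample = arg
            if check:
                for _, _, tree in arg.segments():
                    bad = validate_tree(tree, model)
                    if bad:
                        raise AssertionError(f"invalid sampled tree: {bad}")
        yield IterationResult(
            iteration=it,
            loglik=total_ll,
            migrant_columns=_migrant_column_counts(arg, model) if model.bands else {},
            sample=sample,
        )


def _unphased_pairs(model: DemographicModel) -> dict[int, tuple[int, int]]:
    """lineage -> its individual's (h1, h2) pair, for unphased diploids."""
    out = {}
    i = 0
    for s in model.samples:
        if s.ploidy == 2 and not s.phased:
            out[i] = (i, i + 1)
            out[i + 1] = (i, i + 1)
        i += s.ploidy
    return out


def resample_phase(
    arg: ARG,
    model: DemographicModel,
    ctx: EmissionContext,
    pair: tuple[int, int],
    rng: np.random.Generator,
) -> int:
    """Resample the allele assignment of an unphased diploid at het sites.

    At each heterozygous column the two alleles are assigned to the
    individual's two lineages proportional to the emission likelihood under
    the current local tree.  Homozygous and missing columns are untouched.
    Returns the number of swapped columns.
    """
    from .threading import _tree_messages

    h1, h2 = pair
    a = ctx.alleles
    het = np.where((a[h1] != a[h2]) & (a[h1] >= 0) & (a[h2] >= 0))[0]
    if het.size == 0:
        return 0
    swapped = 0
    for start, end, tree in arg.segments():
        cols = het[(het >= start) & (het < end)]
        if cols.size == 0:
            continue
        sub = EmissionContext(
            np.ascontiguousarray(a[:, cols]), ctx.mu_eff[cols], ctx.widths[cols]
        )
        U, _ = _tree_messages(tree, model, sub)
        l_keep = U[tree.root][:, 0]
        sub.alleles[[h1, h2]] = sub.alleles[[h2, h1]]
        U, _ = _tree_messages(tree, model, sub)
        l_swap = U[tree.root][:, 0]
        tot = l_keep + l_swap
        p_swap = np.divide(l_swap, tot, out=np.full_like(tot, 0.5), where=tot > 0)
        do = rng.random(cols.size) < p_swap
        sw = cols[do]
        tmp = a[h1, sw].copy()
        a[h1, sw] = a[h2, sw]
        a[h2, sw] = tmp
        swapped += int(do.sum())
    return swapped
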