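"""From sampled ARGs to introgression posteriors, region calls and coverage.

For each migration band and diploid individual, the per-column posterior of
heterozygous (exactly one of the two lineages migrant) and homozygous (both)
introgression is the fraction of retained ARG samples in that configuration.
Regions are maximal runs of columns with ``P_any >= threshold`` (0.5 by
default), reported in base pairs with a zygosity label assigned by
bp-majority within the run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .arg import ARG, migrant_tracts
from .demography import DemographicModel

__all__ = [
    "PosteriorTrack",
    "RegionCall",
    "migrant_indicator",
    "posterior_tracks",
    "call_regions",
    "coverage",
    "frequency_classify",
]


@dataclass
class PosteriorTrack:
    """Per-column migration posteriors for one (band, individual)."""

    band: str
    individual: str
    p_any: np.ndarray
    p_het: np.ndarray
    p_hom: np.ndarray
    bp_starts: np.ndarray  # (L,) bp start per column
    bp_ends: np.ndarray    # (L,) bp end per column
    chrom: str = "chr"

    def __post_init__(self):
        if not np.allclose(self.p_any, self.p_het + self.p_hom):
            raise ValueError("posterior identity P_any = P_het + P_hom violated")


@dataclass
class RegionCall:
    """A thresholded introgression call, 0-based half-open in bp."""

    chrom: str
    start: int
    end: int
    band: str
    individual: str
    zygosity: str  # "het" | "hom"
    mean_posterior: float

    @property
    def length(self) -> int:
        return self.end - self.start


def migrant_indicator(arg: ARG, model: DemographicModel, band, lineage: int
                      ) -> np.ndarray:
    """Boolean per-column indicator: lineage's ancestry crosses the band."""
    out = np.zeros(arg.L, dtype=bool)
    for a, b in migrant_tracts(arg, model, band, lineage):
        out[a:b] = True
    return out


def posterior_tracks(
    samples: Sequence[ARG],
    model: DemographicModel,
    band,
    individual: str,
    bp_starts: np.ndarray,
    bp_ends: np.ndarray,
    chrom: str = "chr",
) -> PosteriorTrack:
    """Fraction of ARG samples with one (het) / two (hom) migrant lineages.

    Haploid individuals yield ``p_any == p_hom`` with ``p_het == 0``.
    """
    if len(samples) == 0:
        raise ValueError("need at least one ARG sample")
    bi = model.band_index(band)
    sample_cfg = {s.sample_id: s for s in model.samples}[individual]
    names = model.lineage_names
    lin = [names.index(x) for x in sample_cfg.lineages]
    L = samples[0].L
    n_het = np.zeros(L)
    n_hom = np.zeros(L)
    for arg in samples:
        ind = np.stack([migrant_indicator(arg, model, bi, l) for l in lin])
        count = ind.sum(axis=0)
        if sample_cfg.ploidy == 2:
            n_het += count == 1
            n_hom += count == 2
        else:
            n_hom += count == 1
    n = len(samples)
    return PosteriorTrack(
        band=model.bands[bi].name,
        individual=individual,
        p_any=(n_het + n_hom) / n,
        p_het=n_het / n,
        p_hom=n_hom / n,
        bp_starts=np.asarray(bp_starts),
        bp_ends=np.asarray(bp_ends),
        chrom=chrom,
    )


def call_regions(track: PosteriorTrack, threshold: float = 0.5,
                 merge_distance: int = 0) -> list[RegionCall]:
    """Maximal runs of columns with ``P_any >= threshold`` as bp intervals.

    The threshold is inclusive.  Zygosity is "hom" when homozygous posterior
    mass dominates heterozygous mass over the run (bp-weighted), else "het".
    Adjacent calls are not merged across sub-threshold gaps unless
    ``merge_distance > 0``.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    above = track.p_any >= threshold
    calls: list[RegionCall] = []
    L = len(above)
    i = 0
    while i < L:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < L and above[j + 1]:
            j += 1
        widths = track.bp_ends[i:j + 1] - track.bp_starts[i:j + 1]
        het_bp = float((track.p_het[i:j + 1] * widths).sum())
        hom_bp = float((track.p_hom[i:j + 1] * widths).sum())
        calls.append(RegionCall(
            chrom=track.chrom,
            start=int(track.bp_starts[i]),
            end=int(track.bp_ends[j]),
            band=track.band,
            individual=track.individual,
            zygosity="hom" if hom_bp >= het_bp else "het",
            mean_posterior=float((track.p_any[i:j + 1] * widths).sum()
                                 / widths.sum()),
        ))
        i = j + 1
    if merge_distance > 0 and calls:
        merged = [calls[0]]
        for c in calls[1:]:
            prev = merged[-1]
            if (c.start - prev.end <= merge_distance
                    and c.zygosity == prev.zygosity):
                merged[-1] = RegionCall(
                    prev.chrom, prev.start, c.end, prev.band, prev.individual,
                    prev.zygosity,
                    (prev.mean_posterior * prev.length
                     + c.mean_posterior * c.length) / (prev.length + c.length),
                )
            else:
                merged.append(c)
        calls = merged
    return calls


def coverage(het_bp: float, hom_bp: float, callable_bp: float) -> float:
    """Introgression coverage of a diploid: (het/2 + hom) / callable."""
    if callable_bp <= 0:
        raise ValueError("coverage undefined for zero callable bases")
    if het_bp + hom_bp > callable_bp:
        raise ValueError("called bases exceed callable bases")
    return (0.5 * het_bp + hom_bp) / callable_bp


def frequency_classify(
    calls_by_individual: dict[str, Iterable[RegionCall]],
    band: str,
) -> tuple[list[tuple[int, int, tuple[str, ...]]], dict[tuple[str, ...], float]]:
    """Joint zygosity of called regions across recipient individuals.

    Returns the atomic intervals (start, end, per-individual labels in the
    given order; labels from {"none", "het", "hom"}) covering every called
    base, plus bp-weighted fractions per joint category.  With two diploid
    recipients, the all-"hom" category is the "doubly homozygous" class
    (migrant on all four lineages).
    """
    inds = list(calls_by_individual)
    events: set[int] = set()
    per_ind: dict[str, list[RegionCall]] = {}
    for ind in inds:
        cs = [c for c in calls_by_individual[ind] if c.band == band]
        per_ind[ind] = cs
        for c in cs:
            events.add(c.start)
            events.add(c.end)
    bounds = sorted(events)
    atoms = []
    total = 0.0
    frac: dict[tuple[str, ...], float] = {}
    for a, b in zip(bounds, bounds[1:]):
        labels = []
        for ind in inds:
            lab = "none"
            for c in per_ind[ind]:
                if c.start <= a and c.end >= b:
                    lab = c.zygosity
                    break
            labels.append(lab)
        if all(l == "none" for l in labels):
            continue
        key = tuple(labels)
        atoms.append((a, b, key))
        frac[key] = frac.get(key, 0.0) + (b - a)
        total += b - a
    if total > 0:
        frac = {k: v / total for k, v in frac.items()}
    return atoms, frac
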