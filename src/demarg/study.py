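"""Scaled-down replications of the simulation study.

Each study simulates replicate windows under the deep-introgression (or
recent-introgression) design, runs the sampler on each, calls introgressed
regions at the 0.5 posterior threshold, and aggregates basewise true/false
positive rates against the simulator's truth tracts.  Problem sizes
(window length, replicate count, chain length) default to desk-scale values
chosen so a study completes in minutes on one core; rates are aggregated
basewise across replicates, as in a full-scale study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .calling import RegionCall, call_regions, posterior_tracks
from .demography import DemographicModel, scale_model
from .evaluate import intersect_intervals, merge_intervals, subtract_intervals, total_bp
from .presets import deep_introgression_model
from .sampler import ChainConfig, run_chain
from .simulate import (
    SimDataset,
    dataset_to_alignment,
    degrade,
    nea_to_hum_config,
    simulate_dataset,
    simulate_nea_to_hum,
)

__all__ = [
    "StudyConfig",
    "WindowResult",
    "StudyResult",
    "run_window",
    "deep_study",
    "direction_confusion_study",
    "doubly_homozygous_fraction",
    "DEFAULT_ADMIXTURE",
]

#: pulse proportions of the deep-introgression simulation design
DEFAULT_ADMIXTURE = {"Afr->Nea": 0.08, "Sup->Den": 0.04, "Sup->Afr": 0.005}


@dataclass
class StudyConfig:
    """Desk-scale study settings (a full-scale design uses 100 x 2 Mb windows
    and 2000-iteration chains)."""

    n_windows: int = 3
    window_bp: int = 40_000
    compress: int = 20
    n_iter: int = 50
    burnin: int = 20
    thin: int = 3
    start_mig: int = 10
    recomb_rate: float = 5e-9


@dataclass
class WindowResult:
    dataset: SimDataset
    calls: dict[tuple[str, str], list[RegionCall]]  # (band, individual) -> calls
    tracks: dict

    def call_intervals(self, band: str, individual: str):
        return [(c.start, c.end) for c in self.calls.get((band, individual), [])]


@dataclass
class StudyResult:
    windows: list[WindowResult]
    model: DemographicModel

    def _diploids(self):
        return [s for s in self.model.samples if s.ploidy == 2]

    def fp_windows(self, band: str) -> np.ndarray:
        """Per-(window, recipient individual) false-positive fractions; the
        replication unit for uncertainty at reduced scale."""
        lin_index = {n: i for i, n in enumerate(self.model.lineage_names)}
        dest = self.model.bands[self.model.band_index(band)].dest
        out = []
        for w in self.windows:
            for s in self._diploids():
                if s.population != dest:
                    continue
                lins = [lin_index[x] for x in s.lineages]
                truth = merge_intervals(
                    sum((w.dataset.truth.get(band, [[]] * len(lin_index))[l]
                         for l in lins), [])
                )
                fp = total_bp(subtract_intervals(
                    w.call_intervals(band, s.sample_id), truth))
                neg = w.dataset.window_bp - total_bp(truth)
                out.append(fp / neg if neg else np.nan)
        return np.asarray(out)

    def band_rates(self, band: str, recipients_only: bool = True):
        """Aggregate basewise TP/FP for one band across windows/individuals.

        TP requires the right band in the right individual; the FP
        denominator excludes each individual's own truth for that band.
        """
        lin_index = {n: i for i, n in enumerate(self.model.lineage_names)}
        tp = fp = truth_tot = neg_tot = 0
        for w in self.windows:
            win = w.dataset.window_bp
            for s in self._diploids():
                dest = self.model.bands[self.model.band_index(band)].dest
                if recipients_only and s.population != dest:
                    continue
                lins = [lin_index[x] for x in s.lineages]
                truth = merge_intervals(
                    sum((w.dataset.truth.get(band, [[]] * len(lin_index))[l]
                         for l in lins), [])
                )
                calls = w.call_intervals(band, s.sample_id)
                tp += total_bp(intersect_intervals(calls, truth))
                fp += total_bp(subtract_intervals(calls, truth))
                t = total_bp(truth)
                truth_tot += t
                neg_tot += win - t
        return {
            "tp_rate": tp / truth_tot if truth_tot else float("nan"),
            "fp_rate": fp / neg_tot if neg_tot else float("nan"),
            "tp_bp": tp, "fp_bp": fp,
            "truth_bp": truth_tot, "neg_bp": neg_tot,
        }


def run_window(
    dataset: SimDataset,
    cfg: StudyConfig,
    seed: int,
    model: Optional[DemographicModel] = None,
    check: bool = False,
) -> WindowResult:
    """Sample ARGs for one simulated window and call all (band, diploid)
    region sets at the 0.5 threshold."""
    model = model if model is not None else dataset.model
    aln = dataset_to_alignment(dataset, compress=cfg.compress)
    chain = ChainConfig(
        n_iter=cfg.n_iter, burnin=cfg.burnin, thin=cfg.thin,
        start_mig=cfg.start_mig, seed=seed, recomb_rate=cfg.recomb_rate,
    )
    samples = [r.sample for r in run_chain(aln.ctx, model, chain, check=check)
               if r.sample is not None]
    bp_starts = aln.starts
    bp_ends = np.append(aln.starts[1:], aln.window_bp)
    calls = {}
    tracks = {}
    for band in model.bands:
        for s in model.samples:
            if s.ploidy != 2:
                continue
            track = posterior_tracks(samples, model, band.name, s.sample_id,
                                     bp_starts, bp_ends)
            tracks[(band.name, s.sample_id)] = track
            calls[(band.name, s.sample_id)] = call_regions(track, 0.5)
    return WindowResult(dataset=dataset, calls=calls, tracks=tracks)


def deep_study(
    cfg: StudyConfig,
    seed: int,
    t_mig: float = 250e3,
    t_div: float = 1.0e6,
    admixture: Optional[dict[str, float]] = None,
    size_scale: float = 1.0,
    require_truth_band: Optional[str] = None,
    check: bool = False,
) -> StudyResult:
    """Replicate deep-introgression windows (Hum->Nea, Sup->Den, Sup->Afr
    pulses plus control bands) and aggregate basewise rates.

    ``admixture=None`` uses the standard pulse proportions; pass ``{}`` for
    the no-migration control used to estimate false positives.
    ``size_scale`` scales every population size in both the simulation and
    the inference model (0.75 approximates X-chromosome demography).
    """
    model = deep_introgression_model(t_mig=t_mig, t_div=t_div)
    if size_scale != 1.0:
        model = scale_model(model, size_scale)
    admixture = DEFAULT_ADMIXTURE if admixture is None else admixture
    rng = np.random.default_rng(seed)
    windows = []
    for i in range(cfg.n_windows):
        s2, s3 = (int(x) for x in rng.integers(1, 2**31 - 1, size=2))
        ds = _simulate_window(model, cfg, admixture, rng, require_truth_band)
        ds = degrade(ds, phase_randomize=True, seed=s2)
        windows.append(run_window(ds, cfg, seed=s3, check=check))
    return StudyResult(windows=windows, model=model)


def _simulate_window(model, cfg, admixture, rng, require_truth_band=None,
                     min_fraction=0.05, max_fraction=0.6, max_tries=600):
    """Draw a window; optionally condition on it containing *partial* truth
    tracts for one band.

    Conditioning on the presence of a truth tract does not bias basewise TP
    (which is measured on truth bases only) and makes small power studies
    far more efficient, since at a 40-100 kb scale most windows carry no
    migrant tract at all.  The upper bound on the tract fraction keeps the
    window geometry comparable to a full-length (megabase) design, where a
    deep tract essentially always has non-migrant flanks within the window;
    windows saturated edge-to-edge by a single tract are an artifact of
    short replicate windows.
    """
    for _ in range(max_tries):
        s1 = int(rng.integers(1, 2**31 - 1))
        ds = simulate_dataset(model, cfg.window_bp, admixture=admixture,
                              recomb_rate=cfg.recomb_rate, seed=s1)
        if require_truth_band is None:
            return ds
        per_lin = ds.truth.get(require_truth_band, [])
        union = merge_intervals(sum(per_lin, []))
        frac = total_bp(union) / ds.window_bp
        if union and min_fraction <= frac <= max_fraction:
            return ds
    raise RuntimeError(
        f"no window with partial {require_truth_band} truth in {max_tries} draws"
    )


def direction_confusion_study(
    cfg: StudyConfig,
    seed: int,
    n_afr_lineages: int = 4,
    n_eur_lineages: int = 2,
) -> dict:
    """Both-direction simulation, one-direction inference.

    Windows carry 2% Nea->Hum (into Europeans, 50 kya) and 5% Hum->Nea
    (250 kya); inference uses only the Nea->Hum band.  Returns the fraction
    of truly Hum->Nea bases (in any Neanderthal lineage) that are called as
    Nea->Hum introgression in at least one human individual.
    """
    config = nea_to_hum_config(n_afr_lineages=n_afr_lineages,
                               n_eur_lineages=n_eur_lineages,
                               include_hum_to_nea=True)
    rng = np.random.default_rng(seed)
    confused = truth_tot = 0
    tp = truth_fwd = 0
    for i in range(cfg.n_windows):
        s2 = int(rng.integers(1, 2**31 - 1))
        for _ in range(400):  # condition on carrying a reverse-pulse tract
            s1 = int(rng.integers(1, 2**31 - 1))
            ds = simulate_nea_to_hum(config, cfg.window_bp, seed=s1)
            if any(ds.truth.get("Hum->Nea", [[]])[li]
                   for li in range(len(ds.lineage_names))):
                break
        w = run_window(ds, cfg, seed=s2)
        model = ds.model
        lin_index = {n: i for i, n in enumerate(model.lineage_names)}
        nea_rows = [lin_index[x] for s in model.samples if s.population == "Nea"
                    for x in s.lineages]
        hum_calls = []
        for s in model.samples:
            if s.ploidy == 2 and s.population == "Hum":
                hum_calls += w.call_intervals("Nea->Hum", s.sample_id)
        rev_truth = merge_intervals(
            sum((ds.truth.get("Hum->Nea", [[]] * len(lin_index))[l]
                 for l in nea_rows), [])
        )
        confused += total_bp(intersect_intervals(hum_calls, rev_truth))
        truth_tot += total_bp(rev_truth)
        # forward-direction power bookkeeping on the same windows
        for s in model.samples:
            if s.ploidy != 2 or s.population != "Hum":
                continue
            lins = [lin_index[x] for x in s.lineages]
            tr = merge_intervals(
                sum((ds.truth["Nea->Hum"][l] for l in lins), [])
            )
            tp += total_bp(intersect_intervals(
                w.call_intervals("Nea->Hum", s.sample_id), tr))
            truth_fwd += total_bp(tr)
    return {
        "confusion_rate": confused / truth_tot if truth_tot else float("nan"),
        "reverse_truth_bp": truth_tot,
        "nea_to_hum_tp_rate": tp / truth_fwd if truth_fwd else float("nan"),
        "nea_to_hum_truth_bp": truth_fwd,
    }


def doubly_homozygous_fraction(result: StudyResult, band: str = "Afr->Nea") -> dict:
    """Fraction of called band bases that are homozygous in both Neanderthals.

    Mirrors the ascertained frequency-spectrum summary used to date the
    migration: introgressed regions are classified by joint zygosity across
    the two recipient diploids, and the all-homozygous (four migrant
    lineages) share of called bases is reported, bp-weighted.
    """
    from .calling import frequency_classify

    dest = result.model.bands[result.model.band_index(band)].dest
    recips = [s.sample_id for s in result.model.samples
              if s.ploidy == 2 and s.population == dest]
    total = 0.0
    dh = 0.0
    elements = []
    for w in result.windows:
        calls_by_ind = {r: w.calls.get((band, r), []) for r in recips}
        atoms, _ = frequency_classify(calls_by_ind, band)
        for a, b, labels in atoms:
            total += b - a
            elements.append((float(b - a), labels))
            if all(l == "hom" for l in labels):
                dh += b - a
    return {
        "fraction": dh / total if total else float("nan"),
        "called_bp": total,
        "elements": elements,
    }
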