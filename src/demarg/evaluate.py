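"""Basewise accuracy metrics, ROC/length summaries, and frequency-spectrum
dating of migration time.

True/false positive rates are computed per base pair and per (band,
individual): a called base is a true positive only when the same migration
band is truly introgressed in the same individual.  Masked bases are
unscorable and excluded from the false-positive denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "merge_intervals",
    "intersect_intervals",
    "subtract_intervals",
    "total_bp",
    "basewise_rates",
    "confusion_rate",
    "roc_curve",
    "length_distribution",
    "bootstrap_spectrum",
    "date_migration",
]

Interval = tuple[int, int]


def merge_intervals(ivals: Iterable[Interval]) -> list[Interval]:
    s = sorted((int(a), int(b)) for a, b in ivals if b > a)
    out: list[Interval] = []
    for a, b in s:
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def intersect_intervals(x: Iterable[Interval], y: Iterable[Interval]) -> list[Interval]:
    x, y = merge_intervals(x), merge_intervals(y)
    out, i, j = [], 0, 0
    while i < len(x) and j < len(y):
        a = max(x[i][0], y[j][0])
        b = min(x[i][1], y[j][1])
        if b > a:
            out.append((a, b))
        if x[i][1] <= y[j][1]:
            i += 1
        else:
            j += 1
    return out


def subtract_intervals(x: Iterable[Interval], y: Iterable[Interval]) -> list[Interval]:
    x, y = merge_intervals(x), merge_intervals(y)
    out = []
    j = 0
    for a, b in x:
        cur = a
        while j < len(y) and y[j][1] <= cur:
            j += 1
        k = j
        while k < len(y) and y[k][0] < b:
            if y[k][0] > cur:
                out.append((cur, y[k][0]))
            cur = max(cur, y[k][1])
            k += 1
        if cur < b:
            out.append((cur, b))
    return out


def total_bp(ivals: Iterable[Interval]) -> int:
    return sum(b - a for a, b in merge_intervals(ivals))


@dataclass
class BasewiseRates:
    tp_rate: float
    fp_rate: float
    truth_bp: int
    called_bp: int
    tp_bp: int
    fp_bp: int
    scorable_bp: int


def basewise_rates(
    calls: Iterable[Interval],
    truth: Iterable[Interval],
    window_bp: int,
    mask: Iterable[Interval] = (),
) -> BasewiseRates:
    """Basewise TP/FP for one (band, individual) over one window.

    TP rate = called∩truth / truth; FP rate = called outside truth / scorable
    non-truth bases (window minus truth minus mask).
    """
    calls = merge_intervals(calls)
    truth = merge_intervals(truth)
    mask = merge_intervals(mask)
    for a, b in calls + truth:
        if a < 0 or b > window_bp:
            raise ValueError("interval outside window")
    calls_s = subtract_intervals(calls, mask)
    truth_s = subtract_intervals(truth, mask)
    tp = total_bp(intersect_intervals(calls_s, truth_s))
    fp = total_bp(subtract_intervals(calls_s, truth_s))
    truth_bp = total_bp(truth_s)
    neg_bp = window_bp - total_bp(mask) - truth_bp
    return BasewiseRates(
        tp_rate=tp / truth_bp if truth_bp else 0.0,
        fp_rate=fp / neg_bp if neg_bp else 0.0,
        truth_bp=truth_bp,
        called_bp=total_bp(calls_s),
        tp_bp=tp,
        fp_bp=fp,
        scorable_bp=neg_bp,
    )


def confusion_rate(
    calls_other: Iterable[Interval],
    truth_this: Iterable[Interval],
) -> float:
    """Fraction of truly-introgressed bases (one band) called as another band."""
    truth = merge_intervals(truth_this)
    t = total_bp(truth)
    if t == 0:
        return 0.0
    return total_bp(intersect_intervals(calls_other, truth)) / t


def roc_curve(
    p_any: np.ndarray,
    truth_cols: np.ndarray,
    widths: np.ndarray,
    thresholds: Optional[Sequence[float]] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Basewise ROC from a posterior track and a truth indicator per column.

    Returns (thresholds, FPR, TPR); the point at threshold 0.5 matches
    :func:`basewise_rates` on the thresholded calls.
    """
    p_any = np.asarray(p_any, dtype=float)
    truth_cols = np.asarray(truth_cols, dtype=bool)
    widths = np.asarray(widths, dtype=float)
    if thresholds is None:
        thresholds = np.unique(np.concatenate([[0.0, 0.5, 1.0], np.unique(p_any)]))
    pos = float(widths[truth_cols].sum())
    neg = float(widths[~truth_cols].sum())
    tpr, fpr = [], []
    for t in thresholds:
        called = p_any >= t
        tpr.append(widths[called & truth_cols].sum() / pos if pos else 0.0)
        fpr.append(widths[called & ~truth_cols].sum() / neg if neg else 0.0)
    return np.asarray(thresholds), np.asarray(fpr), np.asarray(tpr)


@dataclass
class LengthDistribution:
    lengths: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.lengths.mean()) if len(self.lengths) else float("nan")


def length_distribution(
    regions: Iterable[Interval],
    bin_edges: Optional[np.ndarray] = None,
) -> LengthDistribution:
    """Lengths (bp) of a set of regions, binned for comparison with truth."""
    lengths = np.asarray([b - a for a, b in regions], dtype=float)
    if bin_edges is None:
        top = lengths.max() if len(lengths) else 1.0
        bin_edges = np.logspace(2, max(np.log10(top), 2.5), 20)
    counts, edges = np.histogram(lengths, bins=bin_edges)
    return LengthDistribution(lengths=lengths, bin_edges=edges, counts=counts)


# ------------------------------------------------------------------ #
# frequency-spectrum dating
# ------------------------------------------------------------------ #

def bootstrap_spectrum(
    elements: Sequence[tuple[float, tuple]],
    n_boot: int,
    rng: np.random.Generator,
    categories: Optional[Sequence[tuple]] = None,
    ci: float = 0.95,
) -> dict[tuple, tuple[float, float, float]]:
    """Bootstrap the bp-weighted category fractions of introgressed elements.

    ``elements`` is a list of ``(length_bp, category)``; resampling is over
    elements (with replacement).  Returns, per category, (point estimate,
    CI low, CI high).
    """
    elements = list(elements)
    if not elements:
        raise ValueError("no introgressed elements: spectrum undefined")
    if categories is None:
        categories = sorted({c for _, c in elements})
    lengths = np.asarray([l for l, _ in elements], dtype=float)
    cats = [c for _, c in elements]
    cat_idx = {c: i for i, c in enumerate(categories)}
    onehot = np.zeros((len(elements), len(categories)))
    for i, c in enumerate(cats):
        if c in cat_idx:
            onehot[i, cat_idx[c]] = 1.0
    point = (lengths[:, None] * onehot).sum(axis=0) / lengths.sum()
    boots = np.empty((n_boot, len(categories)))
    n = len(elements)
    for b in range(n_boot):
        pick = rng.integers(0, n, size=n)
        lw = lengths[pick]
        boots[b] = (lw[:, None] * onehot[pick]).sum(axis=0) / lw.sum()
    alpha = (1.0 - ci) / 2.0
    lo = np.quantile(boots, alpha, axis=0)
    hi = np.quantile(boots, 1.0 - alpha, axis=0)
    return {c: (float(point[i]), float(lo[i]), float(hi[i]))
            for i, c in enumerate(categories)}


def date_migration(
    observed_elements: Sequence[tuple[float, tuple]],
    simulated_elements: dict[float, Sequence[tuple[float, tuple]]],
    n_boot: int = 100,
    seed: int = 0,
    ci: float = 0.95,
) -> dict:
    """Accept candidate migration times whose ascertained frequency spectrum
    is consistent with the observed one.

    For the observed regions and for each candidate time's simulated,
    caller-ascertained regions, bootstrap confidence intervals of the
    bp-weighted category fractions are computed; a candidate is accepted iff
    its CI overlaps the observed CI in *every* category.
    """
    rng = np.random.default_rng(seed)
    cats = sorted({c for _, c in observed_elements}
                  | {c for els in simulated_elements.values() for _, c in els})
    obs = bootstrap_spectrum(observed_elements, n_boot, rng, categories=cats, ci=ci)
    result = {"observed": obs, "candidates": {}, "accepted": []}
    for t, els in sorted(simulated_elements.items()):
        spec = bootstrap_spectrum(els, n_boot, rng, categories=cats, ci=ci)
        ok = all(
            spec[c][1] <= obs[c][2] and obs[c][1] <= spec[c][2] for c in cats
        )
        result["candidates"][t] = {"spectrum": spec, "accepted": ok}
        if ok:
            result["accepted"].append(t)
    return result
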