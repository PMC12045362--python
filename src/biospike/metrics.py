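"""Spike-train evaluation: assignment matching, classification metrics,
timing bias/uncertainty, filtered correlation, robust summaries.

Matching follows the linear-assignment convention: imputed and ground-truth
spikes are paired uniquely, minimizing total |offset| subject to a matching
window ``max_dt`` (default 10 ms), with the cost of leaving a spike
unmatched set to max_dt / 2 so that no pair with |offset| > max_dt is ever
formed.  True positives are the matched imputed spikes; unmatched imputed
spikes are false positives and unmatched ground-truth spikes are false
negatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import linear_sum_assignment

from .cell import SpikeTrain

_BIG = 1e9


@dataclass
class MatchResult:
    """Unique imputed/truth pairs with signed offsets (imputed - truth)."""

    pairs: list          # (imputed time, truth time, signed offset s)
    n_tp: int
    n_fp: int
    n_fn: int
    max_dt: float


@dataclass
class MetricsReport:
    precision: float | None
    recall: float | None
    f_score: float | None
    accuracy: float | None
    bias_ms: float | None = None
    uncertainty_ms: float | None = None
    correlation_by_width: dict | None = None


def _times(train) -> np.ndarray:
    return train.times if isinstance(train, SpikeTrain) \
        else np.asarray(train, dtype=float)


def match_spikes(imputed, truth, max_dt: float = 0.010) -> MatchResult:
    """Minimum-total-|offset| unique matching within ``max_dt``.

    Solved as a rectangular assignment problem padded with per-spike
    unassignment slots of cost max_dt / 2: a pair forms only when its
    |offset| beats leaving both spikes unmatched, i.e. |offset| <= max_dt.
    """
    a = _times(imputed)
    b = _times(truth)
    n, m = a.size, b.size
    if n == 0 or m == 0:
        return MatchResult([], 0, n, m, max_dt)
    cost_un = max_dt / 2.0
    d = np.abs(a[:, None] - b[None, :])
    d[d > max_dt] = _BIG
    # square padded matrix: [[D, Ua], [Ub, 0]] with diagonal unassignment
    C = np.full((n + m, n + m), _BIG)
    C[:n, :m] = d
    C[n:, m:] = 0.0
    C[:n, m:][np.arange(n), np.arange(n)] = cost_un
    C[n:, :m][np.arange(m), np.arange(m)] = cost_un
    rows, cols = linear_sum_assignment(C)
    pairs = []
    for r, c in zip(rows, cols):
        if r < n and c < m and d[r, c] <= max_dt:
            pairs.append((float(a[r]), float(b[c]), float(a[r] - b[c])))
    pairs.sort()
    n_tp = len(pairs)
    return MatchResult(pairs, n_tp, n - n_tp, m - n_tp, max_dt)


def classification_metrics(match: MatchResult) -> MetricsReport:
    """Precision, recall, harmonic-mean F-score and Jaccard-style accuracy.

    0/0 cases are reported as None and should be excluded from
    aggregation.
    """
    tp, fp, fn = match.n_tp, match.n_fp, match.n_fn
    precision = tp / (tp + fp) if tp + fp > 0 else None
    recall = tp / (tp + fn) if tp + fn > 0 else None
    if precision is None or recall is None:
        f = None
    elif precision + recall == 0:
        f = 0.0
    else:
        f = 2 * precision * recall / (precision + recall)
    accuracy = tp / (tp + fp + fn) if tp + fp + fn > 0 else None
    return MetricsReport(precision=precision, recall=recall, f_score=f,
                         accuracy=accuracy)


def timing_stats(imputed, truth, window: float = 0.100,
                 mode: str = "nearest"):
    """Median signed offset (bias) and median |offset| (uncertainty), ms.

    Per-spike offsets are measured from each imputed spike either to its
    nearest ground-truth spike (``nearest``) or to its assignment-matched
    spike (``matched``), restricted to ``window``.  Positive = imputed
    later than truth.  Returns (bias_ms, uncertainty_ms, offsets_s).
    """
    a = _times(imputed)
    b = _times(truth)
    if mode == "matched":
        match = match_spikes(a, b, max_dt=window)
        offsets = np.array([p[2] for p in match.pairs])
    elif mode == "nearest":
        if a.size == 0 or b.size == 0:
            offsets = np.empty(0)
        else:
            idx = np.clip(np.searchsorted(b, a), 1, b.size - 1) \
                if b.size > 1 else np.zeros(a.size, int)
            lo = b[np.maximum(idx - 1, 0)] if b.size > 1 else b[idx]
            hi = b[idx]
            off = np.where(np.abs(a - lo) <= np.abs(a - hi),
                           a - lo, a - hi)
            offsets = off[np.abs(off) <= window]
    else:
        raise ValueError("mode must be 'matched' or 'nearest'")
    if offsets.size == 0:
        return None, None, offsets
    return (float(np.median(offsets)) * 1e3,
            float(np.median(np.abs(offsets))) * 1e3,
            offsets)


def bin_spikes(truth, n_bins: int, rate: float) -> np.ndarray:
    """Spike counts on a uniform grid of half-open bins [t, t+dt)."""
    b = _times(truth)
    idx = np.floor(b * rate).astype(int)
    idx = idx[(idx >= 0) & (idx < n_bins)]
    out = np.zeros(n_bins)
    np.add.at(out, idx, 1.0)
    return out


def filtered_correlation(prob: np.ndarray, truth, widths, rate: float):
    """Pearson r between Gaussian-smoothed spike probability and truth.

    Both signals are convolved with a Gaussian of SD = width (seconds) and
    correlated; a constant signal yields None for that width.
    """
    prob = np.asarray(prob, dtype=float)
    binned = truth if isinstance(truth, np.ndarray) \
        else bin_spikes(truth, prob.size, rate)
    if binned.size != prob.size:
        raise ValueError("probability and binned truth length mismatch")
    out = {}
    for w in widths:
        sd_bins = w * rate
        x = gaussian_filter1d(prob, sd_bins)
        y = gaussian_filter1d(binned, sd_bins)
        if np.std(x) == 0 or np.std(y) == 0:
            out[w] = None
        else:
            out[w] = float(np.corrcoef(x, y)[0, 1])
    return out


def robust_summary(values):
    """Median, IQR and MAD-based robust SD (MAD / 0.6745)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("robust_summary of empty input")
    med = float(np.median(v))
    q1, q3 = np.percentile(v, [25, 75])
    mad = float(np.median(np.abs(v - med)))
    return {"median": med, "iqr": float(q3 - q1),
            "robust_sd": mad / 0.6745}


def evaluate(imputed, truth, max_dt: float = 0.010,
             widths=(0.005, 0.010, 0.020, 0.050, 0.100),
             prob: np.ndarray | None = None,
             rate: float | None = None,
             timing_window: float = 0.100) -> MetricsReport:
    """Full evaluation of one imputed train against ground truth."""
    match = match_spikes(imputed, truth, max_dt=max_dt)
    rep = classification_metrics(match)
    rep.bias_ms, rep.uncertainty_ms, _ = timing_stats(
        imputed, truth, window=timing_window, mode="nearest")
    if prob is not None and rate is not None:
        rep.correlation_by_width = filtered_correlation(
            prob, truth, widths, rate)
    return rep
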