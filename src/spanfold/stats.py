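"""Evaluation metrics and large-sample test statistics.

Genome-scale comparisons involve samples of 10^6-10^7 windows, where exact
p-values underflow any floating representation; following common practice
for such scales, results are reported as standard-normal Z statistics
(positive = first sample larger), with one-sided thresholds and Bonferroni
correction expressed on the Z scale.  The Wilcoxon statistics accept binned
(value, count) input so that memory is O(#bins) regardless of n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata


class MetricError(ValueError):
    pass


@dataclass(frozen=True)
class BinaryConfusion:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise MetricError("negative confusion count")


def mcc(conf: BinaryConfusion) -> float:
    """Matthews correlation coefficient (TP*TN - FP*FN) / sqrt(product of margins)."""
    tp, tn, fp, fn = conf.tp, conf.tn, conf.fp, conf.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        raise MetricError("MCC undefined: a confusion-matrix margin is zero")
    return (tp * tn - fp * fn) / np.sqrt(float(denom))


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve by the rank formula; ties count half.

    Equals the probability that a random positive outranks a random negative.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise MetricError("ROC AUC needs both classes present")
    ranks = rankdata(scores)  # mid-ranks
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass(frozen=True)
class TestResult:
    """Normal-approximation test statistic.

    ``z`` is on the standard-normal scale; positive means the first sample
    (or the positive differences) dominates.  ``tie_corrected`` records
    whether the variance included the tie correction.
    """

    __test__ = False  # keep pytest from collecting this as a test class

    z: float
    n_a: int
    n_b: int
    tie_corrected: bool = True

    def one_sided_p(self) -> float:
        """P(Z >= z) for the upper tail (underflows to 0 for huge z)."""
        return float(norm.sf(self.z))

    @staticmethod
    def bonferroni_z(alpha: float, m: int) -> float:
        """Z threshold whose one-sided p equals alpha/m (Bonferroni)."""
        return float(norm.isf(alpha / m))


def _as_bins(values, counts=None):
    values = np.asarray(values, dtype=float)
    if counts is None:
        values, counts = np.unique(values, return_counts=True)
    else:
        counts = np.asarray(counts, dtype=float)
        order = np.argsort(values)
        values, counts = values[order], counts[order]
    return values, counts.astype(float)


def rank_sum_z(sample_a, sample_b, counts_a=None, counts_b=None) -> TestResult:
    """Wilcoxon/Mann-Whitney rank-sum Z with mid-ranks and tie correction.

    Either raw samples, or binned input: ``sample_a``/``sample_b`` as the two
    bin-value grids with ``counts_a``/``counts_b``.  The normal approximation
    is used without continuity correction; binned and raw paths agree exactly.
    """
    if counts_a is None and counts_b is None:
        va, ca = _as_bins(sample_a)
        vb, cb = _as_bins(sample_b)
    else:
        va, ca = _as_bins(sample_a, counts_a)
        vb, cb = _as_bins(sample_b, counts_b)
    n_a, n_b = ca.sum(), cb.sum()
    if n_a < 1 or n_b < 1:
        raise MetricError("both samples must be non-empty")
    grid = np.union1d(va, vb)
    ka = np.zeros(grid.size)
    kb = np.zeros(grid.size)
    ka[np.searchsorted(grid, va)] = ca
    kb[np.searchsorted(grid, vb)] = cb
    t = ka + kb
    n = n_a + n_b
    # mid-rank of each bin: (count below) + (t + 1)/2
    below = np.concatenate([[0.0], np.cumsum(t)[:-1]])
    midrank = below + (t + 1.0) / 2.0
    rank_sum_a = float((midrank * ka).sum())
    u = rank_sum_a - n_a * (n_a + 1.0) / 2.0
    mean_u = n_a * n_b / 2.0
    tie_term = float(((t**3 - t)).sum())
    var_u = n_a * n_b / 12.0 * ((n + 1.0) - tie_term / (n * (n - 1.0)))
    if var_u <= 0:
        raise MetricError("zero variance: all observations tied in one bin")
    z = (u - mean_u) / np.sqrt(var_u)
    return TestResult(z=float(z), n_a=int(n_a), n_b=int(n_b))


def signed_rank_z(differences) -> TestResult:
    """Wilcoxon signed-rank Z for paired differences.

    Zero differences are dropped (the convention used here); ties among
    |differences| get mid-ranks with the variance tie correction.  Positive
    z means positive differences dominate.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise MetricError("signed-rank test undefined: all differences zero")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mean_w = n * (n + 1.0) / 4.0
    _, t = np.unique(np.abs(d), return_counts=True)
    var_w = n * (n + 1.0) * (2.0 * n + 1.0) / 24.0 - float((t**3 - t).sum()) / 48.0
    if var_w <= 0:
        raise MetricError("zero variance in signed-rank test")
    z = (w_plus - mean_w) / np.sqrt(var_w)
    return TestResult(z=float(z), n_a=n, n_b=n)


@dataclass
class ProfileAggregate:
    """Positional mean profile across aligned series, anchored at ``anchor``.

    ``mu[i]`` is the mean over series covering offset positions; offsets with
    no coverage are NaN (missing).
    """

    mu: np.ndarray
    coverage: np.ndarray
    anchor: int


def positional_profile(aligned_series, anchor: int = 0) -> ProfileAggregate:
    """Mean per position across aligned per-position series.

    ``aligned_series`` is a sequence of 1-D arrays sharing a common anchor:
    index ``anchor`` of every series corresponds to offset 0.  Shorter series
    simply stop contributing (missing positions ignored).
    """
    series = [np.asarray(s, dtype=float) for s in aligned_series]
    if not series:
        raise MetricError("no series given")
    length = max(s.size for s in series)
    total = np.zeros(length)
    cover = np.zeros(length)
    for s in series:
        mask = ~np.isnan(s)
        total[: s.size][mask] += s[mask]
        cover[: s.size][mask] += 1
    mu = np.full(length, np.nan)
    np.divide(total, cover, out=mu, where=cover > 0)
    return ProfileAggregate(mu=mu, coverage=cover, anchor=anchor)


def log_relative(profile: ProfileAggregate, half_span: int = 300) -> np.ndarray:
    """log(mu(i) / mu_bar) with mu_bar the mean of mu over +-half_span of the anchor."""
    lo = max(0, profile.anchor - half_span)
    hi = min(profile.mu.size, profile.anchor + half_span + 1)
    window = profile.mu[lo:hi]
    mu_bar = float(np.nanmean(window))
    if not mu_bar > 0:
        raise MetricError("mean profile around the anchor is not positive")
    out = np.full(profile.mu.size, np.nan)
    ok = profile.mu > 0
    out[ok] = np.log(profile.mu[ok] / mu_bar)
    return out


def density_log_ratio(values_a, values_b, bins=50):
    """log(f_a(x)/f_b(x)) per bin from histogram densities.

    Empty bins get an add-half pseudocount before normalisation so the log
    ratio stays finite.  Returns ``(bin_centres, log_ratio)``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise MetricError("both samples must be non-empty")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    edges = np.histogram_bin_edges(np.concatenate([a, b]), bins=bins, range=(lo, hi))
    ca, _ = np.histogram(a, bins=edges)
    cb, _ = np.histogram(b, bins=edges)
    fa = (ca + 0.5) / (ca + 0.5).sum()
    fb = (cb + 0.5) / (cb + 0.5).sum()
    centres = 0.5 * (edges[:-1] + edges[1:])
    return centres, np.log(fa / fb)
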