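"""Small statistical kernels: AUC and the paired Wilcoxon signed-rank test.

Both are pinned-down primitives of the model-evaluation pipeline, so the
exact conventions matter: AUC uses the Mann-Whitney formulation with ties
counted one half; the signed-rank test drops zero differences, uses
mid-ranks for tied magnitudes, and switches from the exact sign-flip null
distribution to a normal approximation (with tie and continuity
corrections) above 25 nonzero pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["auc", "wilcoxon_signed_rank", "WilcoxonResult", "mean_ci"]

EXACT_LIMIT = 25  # nonzero pairs at or below which the exact null is used


def auc(scores, labels) -> float:
    """Area under the ROC curve via the rank-sum (Mann-Whitney) identity.

    Equals the probability that a uniformly random positive case receives a
    higher score than a random negative one, counting ties as 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = sps.rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass(frozen=True)
class WilcoxonResult:
    """Signed-rank statistic W (sum of positive ranks), two-sided p, and n."""

    statistic: float
    p_value: float
    n_nonzero: int
    method: str


def _exact_sign_flip_p(ranks: np.ndarray, w_obs: float) -> float:
    """Two-sided p over the 2^n equiprobable sign assignments.

    Mid-ranks are multiples of 1/2, so doubling makes every rank an integer
    and the distribution of 2*W is a subset-sum convolution.
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    n_all = counts.sum()
    w2 = int(np.rint(2 * w_obs))
    p_le = counts[: w2 + 1].sum() / n_all
    p_ge = counts[w2:].sum() / n_all
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(differences) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test on a vector of differences.

    Zero differences are discarded; with no nonzero pair left the test is
    degenerate and p = 1. For <= 25 nonzero pairs the two-sided p comes from
    the exact sign-flip distribution (ties handled by mid-ranks); above that
    a normal approximation with tie correction and a 0.5 continuity
    correction toward the mean is used.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0, "degenerate")
    ranks = sps.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= EXACT_LIMIT:
        return WilcoxonResult(w, _exact_sign_flip_p(ranks, w), n, "exact")
    mean = n * (n + 1) / 4
    # tie correction: subtract sum(t^3 - t)/48 from the null variance
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24 - ((tie_counts**3 - tie_counts).sum()) / 48
    dev = w - mean
    z = (dev - 0.5 * np.sign(dev)) / np.sqrt(var)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return WilcoxonResult(w, p, n, "normal")


def mean_ci(values, level: float = 0.95) -> tuple[float, float, float]:
    """Mean with a normal-theory t confidence interval (mean, lo, hi)."""
    v = np.asarray(values, dtype=float)
    m = float(v.mean())
    if v.size < 2:
        return m, m, m
    se = float(v.std(ddof=1) / np.sqrt(v.size))
    t = float(sps.t.ppf(0.5 + level / 2, v.size - 1))
    return m, m - t * se, m + t * se
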