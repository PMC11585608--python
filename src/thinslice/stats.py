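"""Diagnostic-accuracy statistics for reader-study style evaluations.

Implements the statistical toolkit used to compare image types in a
diagnostic study: confusion-matrix metrics reported on the 0-100 scale,
the McNemar test for paired sensitivity/specificity, the DeLong test for
correlated AUCs, a seeded permutation test for precision/F1, a one-sided
Wilcoxon non-inferiority test on 5-point Likert ratings (0.25-point
margin), a chi-square test for diagnostic-quality rates, and percentile
bootstrap confidence intervals.

The Wilcoxon signed-rank test uses an exact null distribution for
``n <= 25`` computed by dynamic programming over (doubled) midranks — so
the exact branch also covers tied magnitudes — and the normal
approximation with continuity correction above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

EXACT_WILCOXON_MAX_N = 25
EXACT_MCNEMAR_MAX_N = 25


# ---------------------------------------------------------------------------
# Confusion-matrix metrics
# ---------------------------------------------------------------------------


@dataclass
class ConfusionCounts:
    """tp/fp/tn/fn for one (reader, image type) classification task."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def round1(x: float) -> float:
    """Round to one decimal, half away from zero (table presentation)."""
    return float(np.sign(x) * np.floor(np.abs(x) * 10.0 + 0.5) / 10.0)


def diagnostic_metrics(c: ConfusionCounts) -> dict:
    """Accuracy, sensitivity, specificity, precision and F1 on the 0-100
    scale, one decimal.  A metric with a zero denominator is ``None`` and
    listed under ``undefined`` instead of raising."""
    out: dict = {"undefined": []}

    def pct(num, den, name):
        if den == 0:
            out["undefined"].append(name)
            return None
        return round1(100.0 * num / den)

    out["accuracy"] = pct(c.tp + c.tn, c.n, "accuracy")
    out["sensitivity"] = pct(c.tp, c.tp + c.fn, "sensitivity")
    out["specificity"] = pct(c.tn, c.tn + c.fp, "specificity")
    out["precision"] = pct(c.tp, c.tp + c.fp, "precision")
    if c.tp + c.fn == 0 or c.tp + c.fp == 0:
        out["undefined"].append("f1")
        out["f1"] = None
    else:
        sens = c.tp / (c.tp + c.fn)
        prec = c.tp / (c.tp + c.fp)
        out["f1"] = (
            round1(100.0 * 2 * prec * sens / (prec + sens)) if prec + sens > 0 else None
        )
        if out["f1"] is None:
            out["undefined"].append("f1")
    return out


def binary_stat(pred: np.ndarray, truth: np.ndarray, which: str) -> float:
    """Precision or F1 (as fractions) of binary predictions against truth;
    zero-denominator cases evaluate to 0."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    prec = tp / (tp + fp) if tp + fp else 0.0
    sens = tp / (tp + fn) if tp + fn else 0.0
    if which == "precision":
        return prec
    if which == "f1":
        return 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    raise ValueError(f"unknown statistic {which!r}")


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank (exact DP branch)
# ---------------------------------------------------------------------------


def _signed_rank_null_cdf(double_ranks: np.ndarray) -> np.ndarray:
    """Counts of each doubled rank-sum value over all 2^n sign choices."""
    total = int(double_ranks.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for dr in double_ranks:
        dr = int(dr)
        new = counts.copy()
        new[dr:] += counts[: total + 1 - dr]
        counts = new
    return counts


def wilcoxon_signed_rank(diffs, alternative: str = "two-sided") -> dict:
    """Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; tied magnitudes receive average ranks.
    Exact null distribution (all sign assignments) for ``n <= 25``,
    normal approximation with continuity correction otherwise.  Returns
    ``statistic`` (W+, the positive rank sum), ``p``, ``n`` (non-zero
    pairs) and ``degenerate`` (all differences zero -> p = 1).
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return {"statistic": 0.0, "p": 1.0, "n": 0, "degenerate": True}
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_WILCOXON_MAX_N:
        double_ranks = np.round(2 * ranks).astype(np.int64)
        counts = _signed_rank_null_cdf(double_ranks)
        total_assignments = counts.sum()  # == 2^n
        obs = int(round(2 * w_plus))
        p_ge = counts[obs:].sum() / total_assignments
        p_le = counts[: obs + 1].sum() / total_assignments
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_ge, p_le))
    else:
        mean = n * (n + 1) / 4.0
        # tie correction for the variance of the rank sum
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
            tie_counts**3 - tie_counts
        ) / 48.0
        sd = np.sqrt(var)
        if alternative == "greater":
            z = (w_plus - mean - 0.5) / sd
            p = sps.norm.sf(z)
        elif alternative == "less":
            z = (w_plus - mean + 0.5) / sd
            p = sps.norm.cdf(z)
        else:
            z = (w_plus - mean - np.sign(w_plus - mean) * 0.5) / sd
            p = 2.0 * sps.norm.sf(abs(z))
        p = float(min(1.0, p))
    return {"statistic": w_plus, "p": float(p), "n": n, "degenerate": False}


# ---------------------------------------------------------------------------
# McNemar
# ---------------------------------------------------------------------------


def mcnemar_test(b: int, c: int) -> dict:
    """McNemar test from the two discordant-pair counts.

    Exact two-sided binomial test when ``b + c < 25``; chi-square with
    continuity correction otherwise.  ``b + c == 0`` is degenerate
    (p = 1)."""
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return {"p": 1.0, "degenerate": True, "method": "degenerate"}
    if n < EXACT_MCNEMAR_MAX_N:
        k = min(b, c)
        p = min(1.0, 2.0 * float(sps.binom.cdf(k, n, 0.5)))
        method = "exact-binomial"
    else:
        chi2 = (abs(b - c) - 1.0) ** 2 / n
        p = float(sps.chi2.sf(chi2, df=1))
        method = "chi-square-cc"
    return {"p": p, "degenerate": False, "method": method}


# ---------------------------------------------------------------------------
# DeLong AUC comparison
# ---------------------------------------------------------------------------


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and the per-observation placement values (ties count 1/2)."""
    cmp = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (
        pos[:, None] == neg[None, :]
    )
    return float(cmp.mean()), cmp.mean(axis=1), cmp.mean(axis=0)


def delong_auc_test(scores_a, scores_b, labels) -> dict:
    """Paired DeLong test comparing two correlated ROC AUCs.

    ``scores_a``/``scores_b`` are continuous scores of the two methods on
    the same cases; ``labels`` are binary ground truth.  Returns both
    AUCs and the two-sided p-value for their difference.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels).astype(bool)
    if not (len(sa) == len(sb) == len(y)):
        raise ValueError("scores and labels must have equal length")
    if y.all() or (~y).all():
        raise ValueError("both classes must be present")
    m, n = int(y.sum()), int((~y).sum())
    auc_a, v10_a, v01_a = _placements(sa[y], sa[~y])
    auc_b, v10_b, v01_b = _placements(sb[y], sb[~y])
    v10 = np.stack([v10_a, v10_b])
    v01 = np.stack([v01_a, v01_b])
    s10 = np.cov(v10) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    delta = auc_a - auc_b
    if var <= 0:
        p = 1.0 if delta == 0 else 0.0
    else:
        z = delta / np.sqrt(var)
        p = float(2.0 * sps.norm.sf(abs(z)))
    return {"auc_a": auc_a, "auc_b": auc_b, "delta": delta, "p": p}


# ---------------------------------------------------------------------------
# Permutation test for precision / F1
# ---------------------------------------------------------------------------


def permutation_test_f1(
    pred_a,
    pred_b,
    truth,
    n_perm: int = 10_000,
    seed: int = 0,
    statistic: str = "f1",
) -> dict:
    """Paired permutation test on the difference of F1 (or precision).

    The null is built by independently swapping the two methods'
    predictions per case; ``p = (1 + #{|d_perm| >= |d_obs|}) / (1 + B)``.
    Seeded and reproducible.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    a = np.asarray(pred_a).astype(bool)
    b = np.asarray(pred_b).astype(bool)
    t = np.asarray(truth).astype(bool)
    if not (len(a) == len(b) == len(t)):
        raise ValueError("pred_a, pred_b and truth must have equal length")
    d_obs = binary_stat(a, t, statistic) - binary_stat(b, t, statistic)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        swap = rng.random(len(a)) < 0.5
        pa = np.where(swap, b, a)
        pb = np.where(swap, a, b)
        d = binary_stat(pa, t, statistic) - binary_stat(pb, t, statistic)
        if abs(d) >= abs(d_obs) - 1e-12:
            hits += 1
    return {"delta": d_obs, "p": (1 + hits) / (1 + n_perm)}


# ---------------------------------------------------------------------------
# Likert non-inferiority, diagnostic-rate chi-square, bootstrap
# ---------------------------------------------------------------------------


@dataclass
class PairedRatings:
    """Paired 5-point Likert scores for two image types on the same cases."""

    real: np.ndarray
    synth: np.ndarray

    def __post_init__(self) -> None:
        self.real = np.asarray(self.real)
        self.synth = np.asarray(self.synth)
        if self.real.shape != self.synth.shape:
            raise ValueError("paired ratings must have equal length")
        for arr in (self.real, self.synth):
            if not np.isin(arr, [1, 2, 3, 4, 5]).all():
                raise ValueError("Likert scores must be in {1,...,5}")


def likert_noninferiority(
    real, synth=None, margin: float = 0.25, alpha: float = 0.05
) -> dict:
    """One-sided Wilcoxon non-inferiority test on Likert ratings.

    Tests H0: synth is worse than real by at least ``margin`` points,
    via the signed-rank test on ``d_i = synth_i - real_i + margin``
    (alternative: positive shift).  Verdict "non-inferior" when
    ``p < alpha``.  Accepts a :class:`PairedRatings` in place of the two
    arrays."""
    if isinstance(real, PairedRatings) and synth is None:
        real, synth = real.real, real.synth
    real = np.asarray(real, dtype=float)
    synth = np.asarray(synth, dtype=float)
    if real.shape != synth.shape:
        raise ValueError("paired ratings must have equal length")
    d = synth - real + margin
    res = wilcoxon_signed_rank(d, alternative="greater")
    if res["degenerate"]:
        return {"p": 1.0, "verdict": "degenerate", "degenerate": True}
    verdict = "non-inferior" if res["p"] < alpha else "not established"
    return {"p": res["p"], "verdict": verdict, "degenerate": False}


def diagnostic_rate_chisq(counts_a, counts_b) -> dict:
    """Chi-square (Yates-corrected) on a 2x2 of (diagnostic,
    nondiagnostic) counts for two image types; falls back to Fisher's
    exact test (flagged) when any expected cell is below 1."""
    table = np.asarray([counts_a, counts_b], dtype=float)
    if table.shape != (2, 2) or table.min() < 0:
        raise ValueError("counts must be two (diagnostic, nondiagnostic) pairs")
    if table.sum(axis=1).min() <= 0:
        raise ValueError("each group needs a positive total")
    expected = sps.contingency.expected_freq(table)
    if expected.min() < 1:
        p = float(sps.fisher_exact(table.astype(int))[1])
        return {"p": p, "method": "fisher-exact", "small_sample": True}
    chi2, p, _, _ = sps.chi2_contingency(table, correction=True)
    return {"p": float(p), "chi2": float(chi2), "method": "chi-square-yates",
            "small_sample": False}


def bootstrap_ci(
    stat_fn, data, n_boot: int = 1000, seed: int = 0, level: float = 0.95
) -> tuple[float, float]:
    """Seeded percentile bootstrap CI of ``stat_fn`` over resampled data."""
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    data = np.asarray(data)
    if data.size == 0:
        raise ValueError("data must be non-empty")
    rng = np.random.default_rng(seed)
    n = len(data)
    stats = [stat_fn(data[rng.integers(0, n, size=n)]) for _ in range(n_boot)]
    lo = (1 - level) / 2 * 100
    return (
        float(np.percentile(stats, lo)),
        float(np.percentile(stats, 100 - lo)),
    )
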