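"""Group-comparison statistics used throughout the pipeline.

Two-group comparisons use the Mann-Whitney test with a Hodges-Lehmann
location-shift effect size and its distribution-free 95% CI; ratio
effects (e.g. "x times longer") are obtained on log-transformed values
and exponentiated.  Multi-group comparisons use one-way ANOVA followed
by a protected LSD post hoc with a compact letter display.  Pairwise
correlations select Pearson or Spearman automatically from Shapiro-Wilk
normality checks.  Multiple testing is Benjamini-Hochberg.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats

EXACT_MAX_PRODUCT = 400  # |x|*|y| above this -> normal approximation


@dataclass
class EffectEstimate:
    estimate: float
    ci95: Tuple[float, float]
    pvalue: float
    method: str
    n: Tuple[int, ...] = ()

    def __post_init__(self):
        lo, hi = self.ci95
        if not (lo <= self.estimate <= hi) and not any(
            math.isnan(v) for v in (lo, hi, self.estimate)
        ):
            raise ValueError("CI must contain the estimate")


# ----------------------------------------------------------------------
# Mann-Whitney


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U counting pairs where x < y (ties half)."""
    gt = sum(1.0 for a in x for b in y if a < b)
    ties = sum(0.5 for a in x for b in y if a == b)
    return gt + ties


def _exact_u_cdf_table(n1: int, n2: int) -> np.ndarray:
    """Null counts of U = #{(i,j): x_i < y_j} over all labelings (no ties).

    Standard recursion on the number of label arrangements with a given
    U; equivalent to full enumeration of all C(n1+n2, n1) labelings.
    """
    max_u = n1 * n2
    # f[k][u] = number of arrangements of k y's among ... use recursion
    # N(U; n1, n2) = N(U - n2; n1 - 1, n2) + N(U; n1, n2 - 1)
    table = {}

    def N(u, a, b):
        if u < 0 or u > a * b:
            return 0
        if a == 0 or b == 0:
            return 1 if u == 0 else 0
        key = (u, a, b)
        if key not in table:
            table[key] = N(u - b, a - 1, b) + N(u, a, b - 1)
        return table[key]

    return np.array([N(u, n1, n2) for u in range(max_u + 1)], dtype=float)


def _mw_pvalue(x: np.ndarray, y: np.ndarray) -> Tuple[float, str]:
    n1, n2 = len(x), len(y)
    u = _u_statistic(x, y)
    has_ties = len(np.unique(np.concatenate([x, y]))) < n1 + n2
    if not has_ties and n1 * n2 <= EXACT_MAX_PRODUCT:
        counts = _exact_u_cdf_table(n1, n2)
        total = counts.sum()
        u_int = int(round(u))
        # two-sided: double the smaller tail (U distribution is symmetric)
        lower = counts[: u_int + 1].sum() / total
        upper = counts[u_int:].sum() / total
        return min(1.0, 2 * min(lower, upper)), "exact"
    # normal approximation with tie correction
    allv = np.concatenate([x, y])
    _, tie_counts = np.unique(allv, return_counts=True)
    n = n1 + n2
    mu = n1 * n2 / 2.0
    tie_term = (tie_counts**3 - tie_counts).sum()
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return 1.0, "normal"
    z = (u - mu) / math.sqrt(sigma2)
    # continuity correction toward the mean
    zc = (abs(u - mu) - 0.5) / math.sqrt(sigma2)
    return float(2 * stats.norm.sf(max(zc, 0.0))), "normal"


def _hl_ci(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> Tuple[float, float]:
    """Distribution-free CI for the y - x location shift from ordered pairwise differences."""
    diffs = np.sort((y[None, :] - x[:, None]).ravel())
    n1, n2 = len(x), len(y)
    m = n1 * n2
    if not _has_ties(x, y) and m <= EXACT_MAX_PRODUCT:
        counts = _exact_u_cdf_table(n1, n2)
        cdf = np.cumsum(counts) / counts.sum()
        # largest k with P(U <= k - 1) <= alpha/2
        k = int(np.searchsorted(cdf, alpha / 2, side="right"))
    else:
        mu = m / 2.0
        sigma = math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
        k = int(math.floor(mu - stats.norm.ppf(1 - alpha / 2) * sigma))
    k = max(1, min(k, (m + 1) // 2))
    return float(diffs[k - 1]), float(diffs[m - k])


def _has_ties(x, y) -> bool:
    allv = np.concatenate([x, y])
    return len(np.unique(allv)) < len(allv)


def mann_whitney_effect(
    x: Sequence[float], y: Sequence[float], log_ratio: bool = False
) -> EffectEstimate:
    """Mann-Whitney test with Hodges-Lehmann effect size (y relative to x).

    Exact enumeration p-value for small tie-free samples, normal
    approximation with tie correction otherwise.  ``log_ratio=True``
    computes the effect on log-transformed values and exponentiates,
    yielding a multiplicative ("times longer") effect.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need at least 3 observations per group")
    if log_ratio:
        if (x <= 0).any() or (y <= 0).any():
            raise ValueError("log-ratio effect requires positive data")
        x, y = np.log(x), np.log(y)
    if len(np.unique(np.concatenate([x, y]))) == 1:
        warnings.warn("all observations tied; effect 0, p = 1")
        est, ci, p, method = 0.0, (0.0, 0.0), 1.0, "degenerate"
    else:
        p, method = _mw_pvalue(x, y)
        est = float(np.median((y[None, :] - x[:, None]).ravel()))
        ci = _hl_ci(x, y)
    if log_ratio:
        est, ci = math.exp(est), (math.exp(ci[0]), math.exp(ci[1]))
    return EffectEstimate(
        est, ci, p, f"mann-whitney/{method}" + ("/log-ratio" if log_ratio else ""),
        (len(x), len(y)),
    )


# ----------------------------------------------------------------------
# ANOVA + LSD


@dataclass
class AnovaLsdResult:
    f_statistic: float
    pvalue: float
    df_between: int
    df_within: int
    mse: float
    group_means: Dict[str, float]
    pairwise_p: Dict[Tuple[str, str], float]
    letters: Dict[str, str]


def _compact_letters(
    groups: List[str], means: Dict[str, float], different: set
) -> Dict[str, str]:
    """Greedy insert-absorb compact letter display, groups ordered by mean."""
    ordered = sorted(groups, key=lambda g: means[g])
    letter_sets: List[set] = []
    for g in ordered:
        placed = False
        for s in letter_sets:
            if all((min(g, h), max(g, h)) not in different for h in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    # absorb subsets
    letter_sets = [
        s for i, s in enumerate(letter_sets)
        if not any(s < t for j, t in enumerate(letter_sets) if i != j)
    ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for i, s in enumerate(letter_sets):
        for g in sorted(s, key=lambda g: means[g]):
            out[g] += alphabet[i]
    return out


def anova_lsd(groups: Dict[str, Sequence[float]], alpha: float = 0.05) -> AnovaLsdResult:
    """One-way ANOVA with protected LSD post hoc and letter display.

    LSD pairwise t-tests (pooled MSE) run only when the omnibus F is
    significant at ``alpha``; otherwise every group shares one letter.
    """
    if len(groups) < 3:
        raise ValueError("need at least 3 groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    k = len(arrays)
    ntot = sum(len(v) for v in arrays.values())
    grand = np.concatenate(list(arrays.values())).mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in arrays.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in arrays.values())
    dfb, dfw = k - 1, ntot - k
    msb = ss_between / dfb
    mse = ss_within / dfw
    F = msb / mse if mse > 0 else math.inf
    p = float(stats.f.sf(F, dfb, dfw)) if math.isfinite(F) else 0.0
    means = {g: float(v.mean()) for g, v in arrays.items()}
    pairwise: Dict[Tuple[str, str], float] = {}
    different = set()
    if p < alpha and mse > 0:
        for g, h in itertools.combinations(sorted(arrays), 2):
            vg, vh = arrays[g], arrays[h]
            se = math.sqrt(mse * (1 / len(vg) + 1 / len(vh)))
            t = (vg.mean() - vh.mean()) / se
            pp = float(2 * stats.t.sf(abs(t), dfw))
            pairwise[(g, h)] = pp
            if pp < alpha:
                different.add((g, h))
    letters = _compact_letters(list(arrays), means, different)
    return AnovaLsdResult(float(F), p, dfb, dfw, float(mse), means, pairwise, letters)


# ----------------------------------------------------------------------
# Correlation with automatic method selection


def correlate(
    x: Sequence[float], y: Sequence[float], normality_alpha: float = 0.05
) -> EffectEstimate:
    """Pearson when both variables pass Shapiro-Wilk, Spearman otherwise.

    The correlation significance threshold used downstream is 0.01; the
    returned p-value is unadjusted.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired samples of length >= 4")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("correlation undefined for constant input")
    normal = (
        stats.shapiro(x).pvalue >= normality_alpha
        and stats.shapiro(y).pvalue >= normality_alpha
    )
    if normal:
        r, p = stats.pearsonr(x, y)
        method = "pearson"
    else:
        r, p = stats.spearmanr(x, y)
        method = "spearman"
    r = float(r)
    # Fisher-z CI (approximate for Spearman)
    n = len(x)
    if abs(r) >= 1.0 or n <= 3:
        ci = (r, r)
    else:
        z = np.arctanh(r)
        se = 1 / math.sqrt(n - 3)
        ci = (float(np.tanh(z - 1.96 * se)), float(np.tanh(z + 1.96 * se)))
    return EffectEstimate(r, ci, float(p), method, (n,))


# ----------------------------------------------------------------------
# Multiple testing


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def shapiro_wilk(x: Sequence[float]) -> Tuple[float, float]:
    res = stats.shapiro(np.asarray(x, dtype=float))
    return float(res.statistic), float(res.pvalue)


def levene(*groups: Sequence[float]) -> Tuple[float, float]:
    res = stats.levene(*[np.asarray(g, dtype=float) for g in groups])
    return float(res.statistic), float(res.pvalue)
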