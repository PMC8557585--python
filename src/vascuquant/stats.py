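"""Rank-based statistics with exact small-sample behaviour.

The study compares 13 benign against 3 malignant nodules and correlates ten
sonographic with three histological vascularization parameters over n = 16
patients.  At that size asymptotic p-values are unreliable, so by default:

* the Wilcoxon rank-sum test enumerates all C(n1+n2, n1) group assignments of
  the pooled mid-ranks (tie-respecting permutation distribution) whenever
  n1 + n2 <= 20, falling back to the tie-corrected, continuity-corrected
  normal approximation above that;
* the Spearman p-value enumerates all n! rank permutations for n <= 8 and
  uses a seeded Monte-Carlo permutation distribution (10^5 draws) for
  8 < n <= 20, with the t-approximation available on request;
* the partial Spearman correlation rank-transforms every variable and applies
  the inverse-correlation-matrix formula, with a t-approximate p on
  n - 2 - #covariates degrees of freedom.

Two-sided p-values double the smaller tail (each tail including the observed
point) and cap at 1.  Pairs with a missing member are deleted pairwise and
counted in ``missing_excluded``.  No multiple-testing adjustment is applied
anywhere; all reported p-values are raw.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "group_summary",
    "wilcoxon_rank_sum",
    "spearman",
    "partial_spearman",
    "correlation_table",
]

#: fixed seed of the Monte-Carlo Spearman permutation distribution
SPEARMAN_MC_SEED = 20210
SPEARMAN_MC_DRAWS = 100_000
#: largest pooled sample enumerated exactly by the rank-sum test
WILCOXON_EXACT_LIMIT = 20
#: largest n enumerated fully (n! permutations) by the Spearman test
SPEARMAN_EXACT_LIMIT = 8
#: largest n handled by the Monte-Carlo permutation distribution
SPEARMAN_MC_LIMIT = 20
_EPS = 1e-12


@dataclass(frozen=True)
class StatResult:
    """One test or correlation outcome.

    ``statistic`` is the rank sum W for the Wilcoxon test and the correlation
    coefficient r for (partial) Spearman results; NaN when undefined.
    """

    statistic: float
    p_value: float
    method: str
    n_used: int
    missing_excluded: int = 0

    @property
    def undefined(self) -> bool:
        return math.isnan(self.statistic)


def _clean(values: Sequence[float]) -> np.ndarray:
    arr = np.asarray(values, dtype=np.float64)
    return arr[~np.isnan(arr)]


def group_summary(values: Sequence[float], labels: Sequence[str]
                  ) -> dict[str, dict[str, float]]:
    """Per-label {n, mean, sd, median, min, max} summaries.

    Missing (NaN) values are dropped per group; the sample SD uses the n-1
    denominator and is NaN for a single observation.  An empty group yields
    an all-NaN summary with n = 0.
    """
    frame = pd.DataFrame({"value": np.asarray(values, dtype=np.float64),
                          "label": list(labels)})
    out: dict[str, dict[str, float]] = {}
    for label, grp in frame.groupby("label", sort=True):
        v = grp["value"].dropna()
        if v.empty:
            out[str(label)] = {"n": 0, "mean": math.nan, "sd": math.nan,
                               "median": math.nan, "min": math.nan,
                               "max": math.nan}
            continue
        out[str(label)] = {
            "n": int(v.size),
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if v.size > 1 else math.nan,
            "median": float(v.median()),
            "min": float(v.min()),
            "max": float(v.max()),
        }
    return out


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum

def _rank_sum_exact_p(ranks: np.ndarray, n1: int, w_obs: float) -> float:
    """Two-sided exact p over all C(N, n1) assignments of the pooled ranks."""
    n = len(ranks)
    idx = np.fromiter(itertools.chain.from_iterable(
        itertools.combinations(range(n), n1)), dtype=np.intp)
    sums = ranks[idx.reshape(-1, n1)].sum(axis=1)
    total = len(sums)
    p_le = np.count_nonzero(sums <= w_obs + _EPS) / total
    p_ge = np.count_nonzero(sums >= w_obs - _EPS) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float],
                      mode: str = "auto") -> StatResult:
    """Two-sided Wilcoxon rank-sum test of two independent samples.

    The statistic is the sum of pooled mid-ranks of *x*.  ``mode`` is
    ``auto`` (exact when n1 + n2 <= 20), ``exact`` (full enumeration, ties
    respected) or ``normal`` (tie-corrected variance, continuity correction).
    """
    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")
    xa, ya = _clean(x), _clean(y)
    excluded = (len(np.atleast_1d(x)) - xa.size) + (len(np.atleast_1d(y)) - ya.size)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both samples must contain at least one value")
    n1, n2 = xa.size, ya.size
    pooled = np.concatenate([xa, ya])
    ranks = sps.rankdata(pooled)  # mid-ranks for ties
    w = float(ranks[:n1].sum())
    n = n1 + n2

    if mode == "exact" or (mode == "auto" and n <= WILCOXON_EXACT_LIMIT):
        p = _rank_sum_exact_p(ranks, n1, w)
        return StatResult(w, p, "wilcoxon_exact", n, excluded)

    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts ** 3 - counts).sum())) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # all observations tied
        return StatResult(w, 1.0, "wilcoxon_normal", n, excluded)
    z = (w - mu - 0.5 * np.sign(w - mu)) / math.sqrt(var)
    p = min(1.0, 2.0 * float(sps.norm.sf(abs(z))))
    return StatResult(w, p, "wilcoxon_normal", n, excluded)


# ---------------------------------------------------------------------------
# Spearman correlation

def _pairwise(x: Sequence[float], y: Sequence[float]
              ) -> tuple[np.ndarray, np.ndarray, int]:
    xa = np.asarray(x, dtype=np.float64)
    ya = np.asarray(y, dtype=np.float64)
    if xa.shape != ya.shape:
        raise ValueError("x and y must have the same length")
    keep = ~(np.isnan(xa) | np.isnan(ya))
    return xa[keep], ya[keep], int((~keep).sum())


def _rank_corr(xr: np.ndarray, yr: np.ndarray) -> float:
    """Pearson correlation of mid-ranks (= Spearman r with ties)."""
    xc = xr - xr.mean()
    yc = yr - yr.mean()
    denom = math.sqrt(float((xc ** 2).sum()) * float((yc ** 2).sum()))
    if denom == 0:
        return math.nan
    return float((xc * yc).sum()) / denom


def _perm_corrs(xr: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Correlations of xr against each permuted row of its partner ranks."""
    xc = xr - xr.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc ** 2).sum() * (pc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (pc @ xc) / denom


def spearman(x: Sequence[float], y: Sequence[float],
             mode: str = "auto") -> StatResult:
    """Two-sided Spearman rank correlation with a permutation p-value.

    ``mode``: ``auto`` (full n! enumeration for n <= 8, seeded Monte-Carlo
    for 8 < n <= 20, t-approximation beyond), ``exact`` (enumeration or
    Monte-Carlo as above) or ``t_approx``.  Zero rank variance in either
    variable leaves r undefined (NaN, method ``undefined``).
    """
    if mode not in ("auto", "exact", "t_approx"):
        raise ValueError(f"unknown mode {mode!r}")
    xa, ya, excluded = _pairwise(x, y)
    n = xa.size
    if n < 3:
        raise ValueError("Spearman correlation needs at least 3 complete pairs")
    xr = sps.rankdata(xa)
    yr = sps.rankdata(ya)
    r = _rank_corr(xr, yr)
    if math.isnan(r):
        return StatResult(math.nan, math.nan, "undefined", n, excluded)

    if mode == "t_approx" or (mode == "auto" and n > SPEARMAN_MC_LIMIT):
        t = r * math.sqrt((n - 2) / max(_EPS, 1.0 - r * r))
        p = min(1.0, 2.0 * float(sps.t.sf(abs(t), df=n - 2)))
        return StatResult(r, p, "spearman_t", n, excluded)

    if n <= SPEARMAN_EXACT_LIMIT:
        perms = np.array(list(itertools.permutations(yr)))
        corrs = _perm_corrs(xr, perms)
        p = float(np.count_nonzero(np.abs(corrs) >= abs(r) - _EPS)) / len(corrs)
        return StatResult(r, min(1.0, p), "spearman_exact", n, excluded)

    rng = np.random.default_rng(SPEARMAN_MC_SEED)
    perms = rng.permuted(np.tile(yr, (SPEARMAN_MC_DRAWS, 1)), axis=1)
    corrs = _perm_corrs(xr, perms)
    hits = int(np.count_nonzero(np.abs(corrs) >= abs(r) - _EPS))
    p = (hits + 1) / (SPEARMAN_MC_DRAWS + 1)
    return StatResult(r, min(1.0, p), "spearman_mc", n, excluded)


def partial_spearman(x: Sequence[float], y: Sequence[float],
                     covariates: Sequence[Sequence[float]] | Sequence[float]
                     ) -> StatResult:
    """Spearman correlation of x and y controlling for covariates.

    All variables are rank-transformed (mid-ranks) over complete cases; the
    partial Pearson correlation of the ranks is the correlation of the
    residuals of x-ranks and y-ranks after least-squares regression on the
    covariate ranks (equivalent to the inverse-correlation-matrix formula),
    and the p-value uses a t-approximation with n - 2 - k degrees of freedom
    (k covariates).  Zero residual rank variance (e.g. a covariate identical
    to x or y) leaves the result undefined.
    """
    xa = np.asarray(x, dtype=np.float64)
    ya = np.asarray(y, dtype=np.float64)
    cov = np.asarray(covariates, dtype=np.float64)
    if cov.ndim == 1:
        cov = cov[:, None]
    if cov.shape[0] != xa.size or ya.size != xa.size:
        raise ValueError("x, y and covariates must share the same length")
    k = cov.shape[1]
    keep = ~(np.isnan(xa) | np.isnan(ya) | np.isnan(cov).any(axis=1))
    excluded = int((~keep).sum())
    xa, ya, cov = xa[keep], ya[keep], cov[keep]
    n = xa.size
    if n < 4 + k:
        raise ValueError(f"partial correlation needs >= {4 + k} complete cases")
    data = np.column_stack([xa, ya, cov])
    ranks = np.apply_along_axis(sps.rankdata, 0, data)
    design = np.column_stack([np.ones(n), ranks[:, 2:]])
    resid_x = ranks[:, 0] - design @ np.linalg.lstsq(design, ranks[:, 0],
                                                     rcond=None)[0]
    resid_y = ranks[:, 1] - design @ np.linalg.lstsq(design, ranks[:, 1],
                                                     rcond=None)[0]
    var_x = float((resid_x ** 2).sum())
    var_y = float((resid_y ** 2).sum())
    scale = float((ranks[:, 0] ** 2).sum() + (ranks[:, 1] ** 2).sum())
    if var_x <= 1e-10 * scale or var_y <= 1e-10 * scale:
        return StatResult(math.nan, math.nan, "undefined", n, excluded)
    r = float((resid_x * resid_y).sum()) / math.sqrt(var_x * var_y)
    r = max(-1.0, min(1.0, r))
    df = n - 2 - k
    t = r * math.sqrt(df / max(_EPS, 1.0 - r * r))
    p = min(1.0, 2.0 * float(sps.t.sf(abs(t), df=df)))
    return StatResult(r, p, "partial_spearman", n, excluded)


# ---------------------------------------------------------------------------
# correlation table

def correlation_table(cohort: pd.DataFrame,
                      smi_params: Sequence[str],
                      cd34_params: Sequence[str],
                      mode: str = "auto"
                      ) -> dict[tuple[str, str], StatResult]:
    """Spearman correlation of every (SMI parameter, CD34 parameter) pair.

    Missing or undefined values are deleted pairwise per cell.  Cells with
    fewer than 3 complete pairs are flagged undefined rather than raising.
    """
    if cohort.empty:
        raise ValueError("empty cohort")
    table: dict[tuple[str, str], StatResult] = {}
    for sp in smi_params:
        for cp in cd34_params:
            xa, ya, excluded = _pairwise(cohort[sp].to_numpy(dtype=float),
                                         cohort[cp].to_numpy(dtype=float))
            if xa.size < 3:
                table[(sp, cp)] = StatResult(math.nan, math.nan, "undefined",
                                             xa.size, excluded)
            else:
                table[(sp, cp)] = spearman(xa, ya, mode=mode)
    return table


def correlation_frame(table: Mapping[tuple[str, str], StatResult]
                      ) -> pd.DataFrame:
    """Long-format DataFrame of a correlation table (one row per cell)."""
    rows = [{"smi_parameter": sp, "cd34_parameter": cp,
             "r": res.statistic, "p_value": res.p_value,
             "method": res.method, "n_used": res.n_used,
             "missing_excluded": res.missing_excluded}
            for (sp, cp), res in table.items()]
    return pd.DataFrame(rows)
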