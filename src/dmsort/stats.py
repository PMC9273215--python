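"""Distributional and comparative statistics for fitness tables.

Positional means with confidence ribbons, synonymous-vs-missense summaries,
tail (quantile) differences, two-sample Kolmogorov–Smirnov, Fisher's exact
test, Pearson correlation, and paired surface/function comparison by position.

Quantiles use linear interpolation between order statistics throughout.
Standard tests are delegated to scipy.stats; the test suite cross-checks them
against exhaustive enumeration oracles on small inputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "positional_mean",
    "distribution_summary",
    "tail_difference",
    "ks_two_sample",
    "fisher_exact_2x2",
    "pearson",
    "axis_difference",
]


class StatsError(ValueError):
    pass


def positional_mean(
    fitness_table: pd.DataFrame, confidence: float = 0.90
) -> pd.DataFrame:
    """Mean score per position over measured mutations, with a t-interval.

    Returns columns position, mean_score, n, ci_half_width (NaN for n=1).
    Positions with no measured variants are simply absent.
    """
    rows = []
    for pos, grp in fitness_table.dropna(subset=["score"]).groupby("position"):
        s = grp["score"].to_numpy(float)
        n = len(s)
        half = np.nan
        if n > 1:
            tcrit = sps.t.ppf(0.5 + confidence / 2, n - 1)
            half = tcrit * s.std(ddof=1) / np.sqrt(n)
        rows.append(
            {"position": pos, "mean_score": s.mean(), "n": n, "ci_half_width": half}
        )
    return pd.DataFrame(rows)


def distribution_summary(scores, percentiles=(10, 25, 50, 75, 90)) -> dict:
    """Median, sample SD and requested percentiles of a score vector."""
    s = np.asarray(scores, float)
    s = s[np.isfinite(s)]
    if len(s) == 0:
        raise StatsError("empty score vector")
    out = {
        "n": len(s),
        "median": float(np.median(s)),
        "sd": float(s.std(ddof=1)) if len(s) > 1 else 0.0,
    }
    for q in percentiles:
        out[f"p{q:g}"] = float(np.percentile(s, q))
    return out


def tail_difference(a, b, q: float = 0.10) -> tuple[float, float]:
    """|quantile difference| between two samples at both tails (q and 1-q)."""
    if not 0 < q <= 0.5:
        raise StatsError("q must lie in (0, 0.5]")
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise StatsError("both samples must be nonempty")
    low = abs(np.quantile(a, q) - np.quantile(b, q))
    high = abs(np.quantile(a, 1 - q) - np.quantile(b, 1 - q))
    return float(low), float(high)


def ks_two_sample(a, b, exact_limit: int = 10_000) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test.

    D is the sup-distance between ECDFs; the p-value is exact when
    n*m <= ``exact_limit`` and asymptotic otherwise.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise StatsError("both samples must be nonempty")
    method = "exact" if len(a) * len(b) <= exact_limit else "asymp"
    res = sps.ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)


def fisher_exact_2x2(table, alternative: str = "two-sided") -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table of nonnegative integers.

    Returns (sample odds ratio ad/bc, p).  The two-sided p sums all tables
    with fixed margins whose probability does not exceed the observed one;
    an infinite odds ratio (zero in b or c with nonzero a, d) is returned
    as inf.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any():
        raise StatsError("need a nonnegative 2x2 table")
    (a, b), (c, d) = t
    if b * c == 0:
        oddsratio = np.inf if a * d > 0 else np.nan
    else:
        oddsratio = a * d / (b * c)
    _, p = sps.fisher_exact(t, alternative=alternative)
    return float(oddsratio), float(p)


def pearson(a, b) -> tuple[float, float]:
    """Sample Pearson correlation with t-transform p-value."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) != len(b) or len(a) < 3:
        raise StatsError("need paired samples of length >= 3")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise StatsError("non-finite values")
    if a.std() == 0 or b.std() == 0:
        raise StatsError("zero variance: correlation undefined")
    res = sps.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


SIGN_CLASSES = {
    ("-", "-"): "both-",
    ("+", "+"): "both+",
    ("-", "+"): "surf-/func+",
    ("+", "-"): "surf+/func-",
}


def axis_difference(
    surface_table: pd.DataFrame,
    function_table: pd.DataFrame,
    neutral_halfwidth: tuple[float, float] = (0.0, 0.0),
) -> pd.DataFrame:
    """Paired per-position mean surface vs function scores with a sign class.

    A positional mean below ``-neutral_halfwidth`` for its axis counts as
    negative; anything at or above counts as positive (so a score of exactly
    0 on the boundary is positive).  ``neutral_halfwidth`` is typically 1 SD
    of the synonymous-score distribution per axis.
    """
    surf = positional_mean(surface_table).set_index("position")["mean_score"]
    func = positional_mean(function_table).set_index("position")["mean_score"]
    common = surf.index.intersection(func.index)
    if len(common) == 0:
        import warnings

        warnings.warn("no overlapping positions between axes")
        return pd.DataFrame(
            columns=["position", "mean_surface", "mean_function", "difference", "sign_class"]
        )
    hs, hf = neutral_halfwidth
    rows = []
    for pos in common:
        ms, mf = float(surf[pos]), float(func[pos])
        sign_s = "-" if ms < -hs else "+"
        sign_f = "-" if mf < -hf else "+"
        rows.append(
            {
                "position": pos,
                "mean_surface": ms,
                "mean_function": mf,
                "difference": ms - mf,
                "sign_class": SIGN_CLASSES[(sign_s, sign_f)],
            }
        )
    return pd.DataFrame(rows)
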