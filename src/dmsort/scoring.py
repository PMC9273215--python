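"""Enrichment-based fitness scoring across ordered sort bins.

Per variant and replicate, the log ratio of variant to wildtype counts is
regressed on the ordered bin coordinate by weighted least squares; the slope
is the fitness score.  Wildtype is the pool of synonymous control variants.
With variant counts ``c_t`` and pooled wildtype counts ``w_t`` in bin ``t``
(default coordinates 0..k-1):

    M_t = ln((c_t + 1/2) / (w_t + 1/2))
    V_t = 1/(c_t + 1/2) + 1/(w_t + 1/2)

and the WLS fit of M on t with weights 1/V gives the replicate score and its
standard error.  Replicates are combined by a random-effects (method-of-
moments, DerSimonian–Laird-style) meta-analysis: the between-replicate
variance ``sigma2_between`` is estimated from the Q statistic, truncated at
zero, and the combined score is the inverse-variance-weighted mean with
``se = (sum of weights)^{-1/2}``.

Positive scores mean enrichment toward the high bin relative to wildtype
(e.g. increased surface expression); negative scores mean depletion.  Scores
are natural-log based by default; ``log_base=10`` rescales.

The model/results pair wraps this pipeline:

>>> model = SortSeqEnrichment(table, design, sort_spec)
>>> res = model.fit()
>>> res.scores.head(); print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counts import VariantCountTable
from .design import LibraryDesign

__all__ = [
    "LogRatioSeries",
    "wildtype_counts",
    "log_ratio_series",
    "wls_slope",
    "combine_replicates",
    "score_experiment",
    "SortSeqEnrichment",
    "SortSeqEnrichmentResults",
]

PSEUDOCOUNT = 0.5


class ScoringError(ValueError):
    pass


@dataclass
class LogRatioSeries:
    """Per-bin log count-ratios and their variance weights for one variant."""

    variant: str
    t: np.ndarray  # ordered bin coordinates
    M: np.ndarray  # log ratio per bin
    V: np.ndarray  # variance per bin

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.M = np.asarray(self.M, float)
        self.V = np.asarray(self.V, float)
        if not (len(self.t) == len(self.M) == len(self.V)):
            raise ScoringError("t, M, V must have equal length")
        if (self.V <= 0).any():
            raise ScoringError("variances must be positive")


def wildtype_counts(table: VariantCountTable, design: LibraryDesign) -> pd.DataFrame:
    """Pooled synonymous-control counts per (replicate, bin) — the wildtype
    internal standard."""
    if not design.synonymous:
        raise ScoringError("design has no synonymous controls")
    syn_ids = {v.variant_id for v in design.synonymous}
    sub = table.df[table.df["variant"].isin(syn_ids)]
    return (
        sub.groupby(["replicate", "bin"])["count"].sum().rename("wt_count").reset_index()
    )


def log_ratio_series(
    c: np.ndarray, w: np.ndarray, t=None, variant: str = "", pseudocount=PSEUDOCOUNT
) -> LogRatioSeries:
    """Build the log-ratio series M_t, V_t from variant and wildtype counts."""
    c = np.asarray(c, float)
    w = np.asarray(w, float)
    if len(c) < 2:
        raise ScoringError("need at least two bins")
    M = np.log((c + pseudocount) / (w + pseudocount))
    V = 1.0 / (c + pseudocount) + 1.0 / (w + pseudocount)
    if t is None:
        t = np.arange(len(c), dtype=float)
    return LogRatioSeries(variant=variant, t=t, M=M, V=V)


def wls_slope(series: LogRatioSeries) -> tuple[float, float]:
    """Weighted least-squares slope of M on t (weights 1/V) and its SE.

    Closed-form weighted normal equations; the SE is the square root of the
    slope entry of (X' W X)^{-1}.
    """
    w = 1.0 / series.V
    x, y = series.t, series.M
    if len(np.unique(x)) < 2:
        raise ScoringError("all observations at a single coordinate")
    sw = w.sum()
    swx = (w * x).sum()
    swy = (w * y).sum()
    swxx = (w * x * x).sum()
    swxy = (w * x * y).sum()
    delta = sw * swxx - swx**2
    slope = (sw * swxy - swx * swy) / delta
    se = float(np.sqrt(sw / delta))
    return float(slope), se


def combine_replicates(scores, ses) -> tuple[float, float, float]:
    """Random-effects combination of replicate (score, se) pairs.

    Method-of-moments between-replicate variance, truncated at zero; a single
    replicate passes through with sigma2_between = 0.
    Returns (score, se, sigma2_between).
    """
    s = np.asarray(scores, float)
    e = np.asarray(ses, float)
    ok = np.isfinite(s) & np.isfinite(e)
    s, e = s[ok], e[ok]
    if len(s) == 0:
        raise ScoringError("no scored replicates")
    if len(s) == 1:
        return float(s[0]), float(e[0]), 0.0
    w = 1.0 / e**2
    ybar = (w * s).sum() / w.sum()
    q = (w * (s - ybar) ** 2).sum()
    c = w.sum() - (w**2).sum() / w.sum()
    sigma2 = max(0.0, (q - (len(s) - 1)) / c)
    wr = 1.0 / (e**2 + sigma2)
    score = (wr * s).sum() / wr.sum()
    se = 1.0 / np.sqrt(wr.sum())
    return float(score), float(se), float(sigma2)


def _replicate_scores(
    counts: pd.DataFrame,
    wt: pd.DataFrame,
    bin_labels,
    pseudocount: float,
    bin_coords=None,
) -> pd.DataFrame:
    """Vectorised per-replicate WLS slopes for every variant."""
    k = len(bin_labels)
    t = (
        np.arange(k, dtype=float)
        if bin_coords is None
        else np.asarray(bin_coords, float)
    )
    out = []
    for rep, grp in counts.groupby("replicate"):
        wide = grp.pivot_table(
            index="variant", columns="bin", values="count", aggfunc="sum"
        ).reindex(columns=bin_labels)
        wt_rep = (
            wt[wt["replicate"] == rep].set_index("bin")["wt_count"].reindex(bin_labels)
        )
        cmat = wide.to_numpy(float)
        wvec = wt_rep.to_numpy(float)
        scored = cmat.sum(axis=1) > 0  # absent in all bins of this replicate
        M = np.log((cmat + pseudocount) / (wvec + pseudocount))
        wgt = 1.0 / (1.0 / (cmat + pseudocount) + 1.0 / (wvec + pseudocount))
        sw = wgt.sum(axis=1)
        swx = (wgt * t).sum(axis=1)
        swy = (wgt * M).sum(axis=1)
        swxx = (wgt * t * t).sum(axis=1)
        swxy = (wgt * t * M).sum(axis=1)
        delta = sw * swxx - swx**2
        slope = (sw * swxy - swx * swy) / delta
        se = np.sqrt(sw / delta)
        out.append(
            pd.DataFrame(
                {
                    "variant": wide.index,
                    "replicate": rep,
                    "score": np.where(scored, slope, np.nan),
                    "se": np.where(scored, se, np.nan),
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def score_experiment(
    table: VariantCountTable,
    design: LibraryDesign,
    sort_spec,
    pseudocount: float = PSEUDOCOUNT,
    log_base: float | None = None,
    bin_coords=None,
) -> pd.DataFrame:
    """Full scoring pipeline; returns the per-variant fitness table.

    Variants with zero reads across all bins of a replicate are unscored for
    that replicate; variants unscored in every replicate are dropped.
    ``log_base=10`` rescales the natural-log slopes by 1/ln(10).
    """
    wt = wildtype_counts(table, design)
    reps = _replicate_scores(
        table.df, wt, sort_spec.bin_labels, pseudocount, bin_coords
    )
    combined = []
    for variant, grp in reps.groupby("variant", sort=False):
        s = grp["score"].to_numpy()
        e = grp["se"].to_numpy()
        n_obs = int(np.isfinite(s).sum())
        if n_obs == 0:
            continue
        score, se, sigma2 = combine_replicates(s, e)
        row = {
            "variant": variant,
            "score": score,
            "se": se,
            "sigma2_between": sigma2,
            "n_replicates_observed": n_obs,
        }
        for rep, sr, er in zip(grp["replicate"], s, e):
            row[f"score_rep{rep}"] = sr
            row[f"se_rep{rep}"] = er
        combined.append(row)
    scores = pd.DataFrame(combined)
    if scores.empty:
        raise ScoringError("no variant scored in any replicate")
    meta = design.to_frame()
    meta["variant"] = [v.variant_id for v in design.variants]
    scores = scores.merge(
        meta[["variant", "position", "wt_aa", "mut_aa", "kind"]], on="variant"
    )
    scores["axis"] = sort_spec.axis
    if log_base is not None and log_base != np.e:
        scale = 1.0 / np.log(log_base)
        for col in scores.columns:
            if col.startswith(("score", "se")):
                scores[col] = scores[col] * scale
        scores["sigma2_between"] = scores["sigma2_between"] * scale**2
    front = [
        "axis",
        "variant",
        "position",
        "wt_aa",
        "mut_aa",
        "kind",
        "score",
        "se",
        "sigma2_between",
        "n_replicates_observed",
    ]
    return scores[front + [c for c in scores.columns if c not in front]]


class SortSeqEnrichment:
    """Weighted-regression enrichment model for a sorted, sequenced library.

    Parameters
    ----------
    table : VariantCountTable
        Complete per-(replicate, bin) variant counts.
    design : LibraryDesign
        The programmed library; its synonymous controls define wildtype.
    sort_spec : SortSpec
        Ordered bin labels and replicate structure.
    pseudocount : float
        Added to every count before forming ratios (default 1/2).
    bin_coords : sequence, optional
        Explicit bin coordinates; default equally spaced 0..k-1.
    """

    def __init__(
        self,
        table: VariantCountTable,
        design: LibraryDesign,
        sort_spec,
        pseudocount: float = PSEUDOCOUNT,
        bin_coords=None,
    ):
        table.validate(sort_spec)
        if not design.synonymous:
            raise ScoringError("design has no synonymous controls")
        self.table = table
        self.design = design
        self.sort_spec = sort_spec
        self.pseudocount = pseudocount
        self.bin_coords = bin_coords

    @classmethod
    def from_simulation(cls, experiment, **kwargs) -> "SortSeqEnrichment":
        table = VariantCountTable.from_simulation(experiment)
        return cls(table, experiment.design, experiment.sort_spec, **kwargs)

    def fit(self, log_base: float | None = None) -> "SortSeqEnrichmentResults":
        scores = score_experiment(
            self.table,
            self.design,
            self.sort_spec,
            pseudocount=self.pseudocount,
            log_base=log_base,
            bin_coords=self.bin_coords,
        )
        return SortSeqEnrichmentResults(model=self, scores=scores)


@dataclass
class SortSeqEnrichmentResults:
    """Fitted per-variant fitness scores with uncertainties and diagnostics."""

    model: SortSeqEnrichment
    scores: pd.DataFrame

    @property
    def missense(self) -> pd.DataFrame:
        return self.scores[self.scores["kind"] == "missense"]

    @property
    def synonymous(self) -> pd.DataFrame:
        return self.scores[self.scores["kind"] == "synonymous"]

    def replicate_correlation(self) -> float:
        """Pearson correlation of per-replicate scores (first two replicates)."""
        cols = [c for c in self.scores.columns if c.startswith("score_rep")]
        if len(cols) < 2:
            raise ScoringError("need two replicates for a correlation")
        sub = self.scores[cols[:2]].dropna()
        return float(np.corrcoef(sub[cols[0]], sub[cols[1]])[0, 1])

    def positional_means(self):
        from .stats import positional_mean

        return positional_mean(self.scores)

    def summary(self) -> str:
        sc = self.scores
        mis, syn = self.missense, self.synonymous
        lines = [
            "Sort-seq enrichment fit",
            "=" * 48,
            f"axis: {self.model.sort_spec.axis}",
            f"bins: {', '.join(self.model.sort_spec.bin_labels)}",
            f"variants scored: {len(sc)} "
            f"({len(mis)} missense, {len(syn)} synonymous)",
            f"replicates: {self.model.sort_spec.n_replicates}",
        ]
        for name, grp in (("missense", mis), ("synonymous", syn)):
            if len(grp):
                lines.append(
                    f"{name:>10}: median {grp['score'].median():+.3f}  "
                    f"sd {grp['score'].std(ddof=1):.3f}  "
                    f"mean se {grp['se'].mean():.3f}"
                )
        try:
            lines.append(f"replicate Pearson r: {self.replicate_correlation():.3f}")
        except ScoringError:
            pass
        return "\n".join(lines)

    def plot_score_distribution(self, ax=None):
        """Overlaid synonymous vs missense score densities (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for name, grp, color in (
            ("missense", self.missense, "black"),
            ("synonymous", self.synonymous, "red"),
        ):
            if len(grp) > 1:
                grp["score"].plot.kde(ax=ax, label=name, color=color)
        ax.set_xlabel("fitness score (log enrichment slope)")
        ax.legend()
        return ax

    def write(self, path) -> None:
        self.scores.to_csv(path, sep="\t", index=False)
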