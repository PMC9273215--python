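"""Clinical variant mapping, neutral-band estimation and VUS classification.

Clinically annotated variants (ClinVar-style labels) are mapped onto library
coordinates — directly for the assayed gene, or through a homolog multiple
sequence alignment for related family members, recording whether the wildtype
residue matches.  The score distribution of expert-reviewed benign variants
defines a per-axis "neutral band" (10th–90th percentile by default); scores
below the band predict a loss phenotype for that axis, scores above predict a
gain, and multi-axis predictions are unioned.  Scores exactly on a boundary
stay inside the band (no call).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

from .stats import fisher_exact_2x2

__all__ = [
    "NeutralBand",
    "map_positions",
    "neutral_band",
    "classify_variants",
    "mechanism_summary",
    "read_clinical_table",
]

BENIGN_LABELS = {"benign", "likely_benign"}
PATHOGENIC_LABELS = {"pathogenic", "likely_pathogenic"}


class ClinicalInputError(ValueError):
    pass


@dataclass(frozen=True)
class NeutralBand:
    """Benign-set percentile bounds for one phenotype axis."""

    axis: str
    lower: float
    upper: float
    n_benign: int
    q_low: float = 10.0
    q_high: float = 90.0

    def __post_init__(self):
        if self.lower > self.upper:
            raise ClinicalInputError("band lower bound exceeds upper bound")


def map_positions(msa_path, source_id: str, target_id: str) -> pd.DataFrame:
    """Positional map between two sequences of an aligned FASTA.

    For every ungapped source position: the target position aligned in the
    same column (or NA at a target gap) and whether the wildtype residues
    match.  Returns columns source_pos, source_aa, target_pos, target_aa,
    wt_match.
    """
    records = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(msa_path), "fasta")}
    for rid in (source_id, target_id):
        if rid not in records:
            raise ClinicalInputError(f"{rid!r} not found in alignment")
    src, tgt = records[source_id], records[target_id]
    if len(src) != len(tgt):
        raise ClinicalInputError("aligned sequences differ in length")
    rows = []
    spos = tpos = 0
    for s_char, t_char in zip(src, tgt):
        s_gap, t_gap = s_char in "-.", t_char in "-."
        if not s_gap:
            spos += 1
        if not t_gap:
            tpos += 1
        if s_gap:
            continue
        rows.append(
            {
                "source_pos": spos,
                "source_aa": s_char,
                "target_pos": tpos if not t_gap else pd.NA,
                "target_aa": t_char if not t_gap else pd.NA,
                "wt_match": (s_char == t_char) if not t_gap else pd.NA,
            }
        )
    return pd.DataFrame(rows)


def read_clinical_table(path) -> pd.DataFrame:
    """Read a ClinVar-style TSV (position, wt_aa, mut_aa, label, source...)."""
    df = pd.read_csv(path, sep="\t")
    required = {"position", "wt_aa", "mut_aa", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ClinicalInputError(f"clinical table missing columns: {sorted(missing)}")
    return df


def _benign_scores(
    fitness_table: pd.DataFrame,
    clinical_table: pd.DataFrame,
    include_likely: bool = True,
    require_wt_match: bool = True,
) -> np.ndarray:
    labels = BENIGN_LABELS if include_likely else {"benign"}
    benign = clinical_table[clinical_table["label"].isin(labels)]
    if require_wt_match and "wt_match" in benign.columns:
        benign = benign[benign["wt_match"].fillna(True).astype(bool)]
    merged = benign.merge(
        fitness_table.dropna(subset=["score"]),
        on=["position", "mut_aa"],
        how="inner",
    )
    return merged["score"].to_numpy(float)


def neutral_band(
    fitness_table: pd.DataFrame,
    clinical_table: pd.DataFrame,
    axis: str,
    q_low: float = 10.0,
    q_high: float = 90.0,
    min_benign: int = 5,
    include_likely: bool = True,
) -> NeutralBand:
    """Percentile band of the expert-reviewed benign score distribution.

    Refuses (raises) when fewer than ``min_benign`` benign variants have
    scores on the axis — there is no silent default band.
    """
    if not 0 <= q_low <= q_high <= 100:
        raise ClinicalInputError("need 0 <= q_low <= q_high <= 100")
    scores = _benign_scores(fitness_table, clinical_table, include_likely)
    if len(scores) < min_benign:
        raise ClinicalInputError(
            f"only {len(scores)} scored benign variants; need >= {min_benign}"
        )
    lower, upper = np.percentile(scores, [q_low, q_high])
    return NeutralBand(
        axis=axis,
        lower=float(lower),
        upper=float(upper),
        n_benign=len(scores),
        q_low=q_low,
        q_high=q_high,
    )


def classify_variants(
    fitness_tables: dict[str, pd.DataFrame],
    bands: dict[str, NeutralBand],
    clinical_table: pd.DataFrame,
) -> pd.DataFrame:
    """Band-based phenotype prediction per clinical variant.

    Per axis: score strictly below the band predicts ``loss_of_<axis>``;
    strictly above predicts ``gain_of_<axis>``; inside (boundaries included)
    contributes no label.  Labels are unioned over axes.  An empty label set
    means band-consistent (benign-like).  Variants without a score on some
    axis are flagged ``incomplete``.
    """
    missing = set(fitness_tables) - set(bands)
    if missing:
        raise ClinicalInputError(f"no neutral band for axes: {sorted(missing)}")
    lookups = {
        axis: tbl.dropna(subset=["score"]).set_index(["position", "mut_aa"])["score"]
        for axis, tbl in fitness_tables.items()
    }
    rows = []
    for rec in clinical_table.itertuples():
        labels = []
        incomplete = False
        scores = {}
        for axis, lookup in lookups.items():
            key = (rec.position, rec.mut_aa)
            if key not in lookup.index:
                incomplete = True
                scores[axis] = np.nan
                continue
            score = float(np.atleast_1d(lookup.loc[key])[0])
            scores[axis] = score
            band = bands[axis]
            if score < band.lower:
                labels.append(f"loss_of_{axis}")
            elif score > band.upper:
                labels.append(f"gain_of_{axis}")
        row = {
            "position": rec.position,
            "wt_aa": rec.wt_aa,
            "mut_aa": rec.mut_aa,
            "label": rec.label,
            "predicted": ";".join(labels),
            "n_predicted": len(labels),
            "incomplete": incomplete,
        }
        for axis, s in scores.items():
            row[f"score_{axis}"] = s
        rows.append(row)
    return pd.DataFrame(rows)


def mechanism_summary(
    predictions: pd.DataFrame,
    group_col: str | None = None,
    label_a: str = "loss_of_surface",
    label_b: str = "loss_of_function",
    alternative: str = "greater",
) -> dict:
    """Prediction counts per label x clinical class, plus a 2x2 enrichment test.

    When ``group_col`` (a boolean column of ``predictions``, e.g. "measured
    here" vs "database-reported") is given, the 2x2 table crosses
    ``label_a``/``label_b`` prediction counts against the two groups and is
    tested with Fisher's exact test.
    """
    preds = predictions.copy()
    preds["labels"] = preds["predicted"].fillna("").map(
        lambda s: [x for x in s.split(";") if x]
    )
    counts = (
        preds.explode("labels")
        .dropna(subset=["labels"])
        .groupby(["label", "labels"])
        .size()
        .rename("n")
        .reset_index()
    )
    out = {"counts": counts, "table": None, "fisher": None}
    if group_col is not None and preds[group_col].nunique() == 2:
        groups = sorted(preds[group_col].unique())
        table = np.zeros((2, 2), dtype=int)
        for j, g in enumerate(groups):
            grp = preds[preds[group_col] == g]
            table[0, j] = grp["labels"].map(lambda L: label_a in L).sum()
            table[1, j] = grp["labels"].map(lambda L: label_b in L).sum()
        out["table"] = table
        if table.sum() > 0 and not (table.sum(axis=0) == 0).any():
            out["fisher"] = fisher_exact_2x2(table, alternative=alternative)
    return out
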