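"""Per-bin variant counting with programmed-codon filtering.

Only programmed (expected) codon substitutions are counted.  A read is
classified against the designed codon positions it covers:

* ``wildtype`` — matches the reference at every designed codon it spans;
* a variant id — carries exactly one programmed mutant codon and is
  reference-matching at every other designed codon it spans;
* ``unexpected`` — anything else: a non-programmed codon, more than one
  mutated designed codon, or an indel inside a designed codon.

Reads covering no designed codon are skipped (tallied separately).  SAM input
is handled through pysam; SEQ is already reported on the forward reference
strand, so no strand handling is needed for codon comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import LibraryDesign, choose_codon, load_codon_usage

__all__ = [
    "VariantCountTable",
    "DesignIndex",
    "reference_cds",
    "extract_programmed_codon",
    "classify_sam",
    "tabulate",
    "unexpected_expected_ratio",
    "coverage_report",
]

WILDTYPE = "wildtype"
UNEXPECTED = "unexpected"

COUNT_COLUMNS = [
    "axis",
    "replicate",
    "bin",
    "variant",
    "position",
    "wt_aa",
    "mut_aa",
    "mut_codon",
    "kind",
    "count",
]


class ManifestError(ValueError):
    pass


@dataclass
class VariantCountTable:
    """Zero-filled per-(replicate, bin) variant counts plus unexpected tallies."""

    df: pd.DataFrame  # COUNT_COLUMNS
    unexpected: pd.DataFrame  # axis, replicate, bin, unexpected_count

    def validate(self, sort_spec=None) -> None:
        if (self.df["count"] < 0).any():
            raise ValueError("negative counts")
        if sort_spec is not None:
            bad = set(self.df["bin"]) - set(sort_spec.bin_labels)
            if bad:
                raise ManifestError(f"bins not in sort spec: {sorted(bad)}")

    def write(self, counts_path, unexpected_path=None) -> None:
        self.df.to_csv(counts_path, sep="\t", index=False)
        if unexpected_path is not None:
            self.unexpected.to_csv(unexpected_path, sep="\t", index=False)

    @classmethod
    def read(cls, counts_path, unexpected_path=None) -> "VariantCountTable":
        df = pd.read_csv(counts_path, sep="\t")
        if unexpected_path is not None:
            unexpected = pd.read_csv(unexpected_path, sep="\t")
        else:
            unexpected = pd.DataFrame(
                columns=["axis", "replicate", "bin", "unexpected_count"]
            )
        return cls(df=df, unexpected=unexpected)

    @classmethod
    def from_simulation(cls, experiment) -> "VariantCountTable":
        df = experiment.counts[COUNT_COLUMNS].copy()
        unexpected = experiment.unexpected[
            ["axis", "replicate", "bin", "unexpected_count"]
        ].copy()
        return cls(df=df, unexpected=unexpected)


@dataclass
class DesignIndex:
    """Designed codon positions of a library laid out on a coding sequence.

    Residue ``p`` (1-based) occupies CDS bases ``3(p-1) .. 3p-1`` (0-based).
    """

    reference: str
    codon_start: dict[int, int]  # position -> 0-based CDS offset
    wt_codon: dict[int, str]
    programmed: dict[int, dict[str, str]]  # position -> mut_codon -> variant id

    @classmethod
    def from_design(cls, design: LibraryDesign, reference: str | None = None):
        if reference is None:
            reference = reference_cds(design)
        codon_start, wt, programmed = {}, {}, {}
        for v in design.variants:
            codon_start[v.position] = 3 * (v.position - 1)
            wt[v.position] = reference[3 * (v.position - 1) : 3 * v.position]
            programmed.setdefault(v.position, {})[v.mut_codon] = v.variant_id
        return cls(reference, codon_start, wt, programmed)


def reference_cds(design: LibraryDesign, codon_usage_table=None) -> str:
    """Build a full-length reference CDS consistent with the design.

    Designed positions use the design's wildtype codons; remaining positions
    take the highest-usage codon for the wildtype residue.
    """
    if codon_usage_table is None:
        codon_usage_table = load_codon_usage()
    by_pos = {v.position: v.wt_codon for v in design.variants}
    codons = []
    for pos, aa in enumerate(design.sequence, start=1):
        codons.append(by_pos.get(pos) or choose_codon(aa, codon_usage_table, mode="argmax"))
    return "".join(codons)


def extract_programmed_codon(read, index: DesignIndex) -> str | None:
    """Classify one aligned read; None means it covers no designed codon.

    Unaligned reads also return None (callers tally them as skipped).
    """
    if read.is_unmapped:
        return None
    ref_to_query = {
        rpos: qpos
        for qpos, rpos in read.get_aligned_pairs()
        if rpos is not None
    }
    start, end = read.reference_start, read.reference_end
    hits: list[str] = []
    n_covered = 0
    for pos, s in index.codon_start.items():
        if s + 3 <= start or s >= end:
            continue
        if s < start or s + 3 > end:
            continue  # codon only partially spanned: no call from this read
        qpos = [ref_to_query.get(r) for r in (s, s + 1, s + 2)]
        if any(q is None for q in qpos):
            return UNEXPECTED  # deletion inside a designed codon
        codon = "".join(read.query_sequence[q] for q in qpos)
        n_covered += 1
        if codon == index.wt_codon[pos]:
            continue
        variant = index.programmed.get(pos, {}).get(codon)
        if variant is None:
            return UNEXPECTED
        hits.append(variant)
    if n_covered == 0:
        return None
    if len(hits) > 1:
        return UNEXPECTED
    return hits[0] if hits else WILDTYPE


def classify_sam(sam_path, index: DesignIndex) -> tuple[list[str], int]:
    """Classify every read in a SAM file; returns (calls, n_skipped)."""
    import pysam

    calls, skipped = [], 0
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
        for read in fh:
            call = extract_programmed_codon(read, index)
            if call is None:
                skipped += 1
            else:
                calls.append(call)
    return calls, skipped


def tabulate(
    calls: pd.DataFrame, design: LibraryDesign, sort_spec
) -> VariantCountTable:
    """Aggregate per-read calls into a complete zero-filled count table.

    ``calls`` needs columns ``replicate``, ``bin`` and ``call`` (a variant id,
    ``"wildtype"`` or ``"unexpected"``).  Every (replicate, bin) cell of the
    sort spec is present in the output even when empty.
    """
    bad = set(calls["bin"]) - set(sort_spec.bin_labels)
    if bad:
        raise ManifestError(f"bins not in sort spec: {sorted(bad)}")
    meta = design.to_frame()
    meta["variant"] = [v.variant_id for v in design.variants]
    reps = range(1, sort_spec.n_replicates + 1)
    grid = pd.MultiIndex.from_product(
        [reps, sort_spec.bin_labels, meta["variant"]],
        names=["replicate", "bin", "variant"],
    ).to_frame(index=False)
    if len(calls):
        obs = (
            calls[~calls["call"].isin([WILDTYPE, UNEXPECTED])]
            .groupby(["replicate", "bin", "call"])
            .size()
            .rename("count")
            .reset_index()
            .rename(columns={"call": "variant"})
        )
        df = grid.merge(obs, on=["replicate", "bin", "variant"], how="left")
        df["count"] = df["count"].fillna(0).astype(int)
    else:
        df = grid.assign(count=0)
    df = df.merge(meta, on="variant", how="left")
    df["axis"] = sort_spec.axis
    unexp_grid = pd.MultiIndex.from_product(
        [reps, sort_spec.bin_labels], names=["replicate", "bin"]
    ).to_frame(index=False)
    if len(calls):
        unexp = (
            calls.assign(is_unexp=calls["call"] == UNEXPECTED)
            .groupby(["replicate", "bin"])["is_unexp"]
            .sum()
            .rename("unexpected_count")
            .reset_index()
        )
        unexp = unexp_grid.merge(unexp, on=["replicate", "bin"], how="left")
        unexp["unexpected_count"] = unexp["unexpected_count"].fillna(0).astype(int)
    else:
        unexp = unexp_grid.assign(unexpected_count=0)
    unexp["axis"] = sort_spec.axis
    table = VariantCountTable(df=df[COUNT_COLUMNS], unexpected=unexp)
    table.validate(sort_spec)
    return table


def unexpected_expected_ratio(table: VariantCountTable) -> pd.DataFrame:
    """Per-(replicate, bin) ratio of unexpected to expected (programmed) reads.

    Samples with zero expected reads yield NaN rather than an error.
    """
    expected = (
        table.df.groupby(["replicate", "bin"])["count"].sum().rename("expected")
    )
    out = table.unexpected.merge(expected.reset_index(), on=["replicate", "bin"])
    out["ratio"] = np.where(
        out["expected"] > 0, out["unexpected_count"] / out["expected"], np.nan
    )
    return out[["replicate", "bin", "unexpected_count", "expected", "ratio"]]


def coverage_report(
    table: VariantCountTable, design: LibraryDesign, threshold: int = 20
) -> dict:
    """Library coverage: detection and read-depth summary per variant.

    Detection pools counts over all samples (the sorted bins stand in for a
    baseline sample).
    """
    totals = table.df.groupby("variant")["count"].sum()
    ids = pd.Series([v.variant_id for v in design.variants])
    totals = totals.reindex(ids, fill_value=0)
    n = len(ids)
    return {
        "n_variants": n,
        "detected_fraction": float((totals > 0).sum() / n) if n else float("nan"),
        "above_threshold_fraction": float((totals > threshold).sum() / n)
        if n
        else float("nan"),
        "threshold": threshold,
        "median_count": float(totals.median()) if n else float("nan"),
    }
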