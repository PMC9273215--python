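"""Programmed saturation-mutagenesis library design.

A deep-mutational-scanning (DMS) library is defined by a protein sequence, a
range of mutable residues, and a programmed set of codon substitutions: every
wildtype amino acid in the range is replaced by the 19 other standard amino
acids, with codons drawn according to organismal codon-usage weights.
Synonymous (codon-only) substitutions at a subset of positions serve as the
internal wildtype benchmark against which enrichment scores are computed.

Coordinates are 1-based and ranges are closed intervals.  Alternate numbering
schemes that arise from engineered insertions (e.g. an epitope tag spliced
into a loop) are expressed as ``numbering_offsets`` — a list of
``(insertion_position, insertion_length)`` pairs — rather than by re-indexing
the sequence itself.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "AMINO_ACIDS",
    "CODON_TO_AA",
    "AA_TO_CODONS",
    "ProgrammedVariant",
    "LibraryDesign",
    "load_codon_usage",
    "choose_codon",
    "enumerate_missense",
    "add_synonymous_controls",
    "possible_missense_count",
    "renumber",
    "read_protein_fasta",
    "read_design",
    "write_design",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# 61 sense codons of the standard genetic code, via biopython.
CODON_TO_AA: dict[str, str] = dict(
    CodonTable.unambiguous_dna_by_id[1].forward_table
)
AA_TO_CODONS: dict[str, tuple[str, ...]] = {
    aa: tuple(sorted(c for c, a in CODON_TO_AA.items() if a == aa))
    for aa in AMINO_ACIDS
}


class CoordinateError(ValueError):
    """A residue position falls outside the sequence or inside an insertion."""


class AlphabetError(ValueError):
    """A sequence contains a non-standard or ambiguous residue."""


class DesignError(ValueError):
    """A library design request cannot be satisfied (e.g. no synonymous codon)."""


@dataclass(frozen=True)
class ProgrammedVariant:
    """A single programmed codon substitution.

    ``kind`` is ``"missense"`` when the encoded amino acid changes and
    ``"synonymous"`` when only the codon changes.
    """

    position: int  # 1-based residue index, native numbering
    wt_aa: str
    mut_aa: str
    wt_codon: str
    mut_codon: str
    kind: str

    def __post_init__(self):
        if CODON_TO_AA.get(self.mut_codon) != self.mut_aa:
            raise DesignError(
                f"mut_codon {self.mut_codon} does not encode {self.mut_aa}"
            )
        syn = self.mut_aa == self.wt_aa
        if syn != (self.kind == "synonymous") or (
            syn and self.mut_codon == self.wt_codon
        ):
            raise DesignError(
                f"kind {self.kind!r} inconsistent at position {self.position}"
            )

    @property
    def variant_id(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}.{self.mut_codon}"


@dataclass
class LibraryDesign:
    """An enumerated programmed variant library over a mutable residue range."""

    protein_id: str
    sequence: str
    mutable_range: tuple[int, int]
    variants: list[ProgrammedVariant] = field(default_factory=list)
    synonymous_positions: set[int] = field(default_factory=set)
    numbering_offsets: list[tuple[int, int]] = field(default_factory=list)

    def validate(self) -> None:
        lo, hi = self.mutable_range
        seen = set()
        for v in self.variants:
            if not lo <= v.position <= hi:
                raise CoordinateError(
                    f"variant position {v.position} outside range {lo}:{hi}"
                )
            key = (v.position, v.mut_aa, v.mut_codon)
            if key in seen:
                raise DesignError(f"duplicate programmed variant {key}")
            seen.add(key)
        if not self.synonymous_positions <= set(range(lo, hi + 1)):
            raise CoordinateError("synonymous positions outside mutable range")

    @property
    def missense(self) -> list[ProgrammedVariant]:
        return [v for v in self.variants if v.kind == "missense"]

    @property
    def synonymous(self) -> list[ProgrammedVariant]:
        return [v for v in self.variants if v.kind == "synonymous"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": [v.position for v in self.variants],
                "wt_aa": [v.wt_aa for v in self.variants],
                "mut_aa": [v.mut_aa for v in self.variants],
                "wt_codon": [v.wt_codon for v in self.variants],
                "mut_codon": [v.mut_codon for v in self.variants],
                "kind": [v.kind for v in self.variants],
            }
        )


def load_codon_usage(path=None) -> pd.DataFrame:
    """Load a codon-usage table (columns: codon, aa, weight).

    With no path, the bundled human usage table (per-amino-acid codon
    fractions) is returned.  All 61 sense codons must be present with
    nonnegative weights.
    """
    if path is None:
        ref = importlib.resources.files("dmsort") / "data" / "human_codon_usage.tsv"
        with importlib.resources.as_file(ref) as p:
            table = pd.read_csv(p, sep="\t")
    else:
        table = pd.read_csv(path, sep="\t")
    missing = set(CODON_TO_AA) - set(table["codon"])
    if missing:
        raise DesignError(f"usage table missing sense codons: {sorted(missing)}")
    if (table["weight"] < 0).any():
        raise DesignError("usage weights must be nonnegative")
    for codon, aa in zip(table["codon"], table["aa"]):
        if CODON_TO_AA.get(codon) != aa:
            raise DesignError(f"usage table misassigns {codon} to {aa}")
    return table


def _usage_map(usage: pd.DataFrame) -> dict[str, tuple[list[str], np.ndarray]]:
    out = {}
    for aa, grp in usage.groupby("aa"):
        out[aa] = (list(grp["codon"]), grp["weight"].to_numpy(float))
    return out


def choose_codon(
    target_aa: str,
    codon_usage_table: pd.DataFrame,
    rng_seed=None,
    mode: str = "sample",
    exclude: str | None = None,
) -> str:
    """Pick a codon for ``target_aa`` weighted by usage frequency.

    ``mode="sample"`` draws proportionally to weight (deterministic given
    ``rng_seed``); ``mode="argmax"`` always returns the highest-weight codon.
    ``exclude`` removes one codon from consideration (used for synonymous
    controls, which must differ from the wildtype codon).
    """
    if target_aa not in AA_TO_CODONS:
        raise AlphabetError(f"unknown amino acid {target_aa!r}")
    grp = codon_usage_table[codon_usage_table["aa"] == target_aa]
    codons = list(grp["codon"])
    weights = grp["weight"].to_numpy(float)
    if exclude is not None:
        keep = [i for i, c in enumerate(codons) if c != exclude]
        codons = [codons[i] for i in keep]
        weights = weights[keep]
    total = weights.sum()
    if len(codons) == 0 or total <= 0:
        raise DesignError(f"no usable codon weight for {target_aa}")
    if mode == "argmax":
        return codons[int(np.argmax(weights))]
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    return codons[rng.choice(len(codons), p=weights / total)]


def possible_missense_count(sequence_or_length) -> int:
    """Number of possible single-residue missense variants: 19 per position."""
    n = (
        sequence_or_length
        if isinstance(sequence_or_length, int)
        else len(str(sequence_or_length))
    )
    return 19 * n


def enumerate_missense(
    sequence: str,
    mutable_range: tuple[int, int],
    codon_usage_table: pd.DataFrame | None = None,
    rng_seed=None,
    mode: str = "sample",
    protein_id: str = "protein",
) -> LibraryDesign:
    """Enumerate the full missense library: 19 substitutions per position.

    Wildtype codons are assigned as the highest-usage codon for each wildtype
    residue (the protein input carries no DNA information); mutant codons are
    chosen by :func:`choose_codon`.
    """
    sequence = str(sequence).upper()
    bad = set(sequence) - set(AMINO_ACIDS)
    if bad:
        raise AlphabetError(f"non-standard residues in sequence: {sorted(bad)}")
    lo, hi = mutable_range
    if lo > hi:
        design = LibraryDesign(protein_id, sequence, (lo, hi))
        return design
    if lo < 1 or hi > len(sequence):
        raise CoordinateError(
            f"range {lo}:{hi} outside sequence of length {len(sequence)}"
        )
    if codon_usage_table is None:
        codon_usage_table = load_codon_usage()
    umap = _usage_map(codon_usage_table)
    rng = np.random.default_rng(rng_seed)
    variants = []
    for pos in range(lo, hi + 1):
        wt = sequence[pos - 1]
        codons, weights = umap[wt]
        wt_codon = codons[int(np.argmax(weights))]
        for mut in AMINO_ACIDS:
            if mut == wt:
                continue
            codons, weights = umap[mut]
            if mode == "argmax":
                mut_codon = codons[int(np.argmax(weights))]
            else:
                mut_codon = codons[rng.choice(len(codons), p=weights / weights.sum())]
            variants.append(
                ProgrammedVariant(pos, wt, mut, wt_codon, mut_codon, "missense")
            )
    design = LibraryDesign(protein_id, sequence, (lo, hi), variants)
    design.validate()
    return design


def add_synonymous_controls(
    design: LibraryDesign,
    positions,
    codon_usage_table: pd.DataFrame | None = None,
    rng_seed=None,
    mode: str = "sample",
) -> LibraryDesign:
    """Append one synonymous (codon-only) control variant per listed position.

    Positions whose wildtype residue is single-codon (M, W) cannot host a
    synonymous control and raise :class:`DesignError`.
    """
    if codon_usage_table is None:
        codon_usage_table = load_codon_usage()
    rng = np.random.default_rng(rng_seed)
    new = list(design.variants)
    syn_positions = set(design.synonymous_positions)
    for pos in positions:
        lo, hi = design.mutable_range
        if not lo <= pos <= hi:
            raise CoordinateError(f"synonymous position {pos} outside {lo}:{hi}")
        wt = design.sequence[pos - 1]
        if len(AA_TO_CODONS[wt]) < 2:
            raise DesignError(
                f"position {pos} ({wt}) has a single codon; no synonymous control"
            )
        wt_codon = choose_codon(wt, codon_usage_table, mode="argmax")
        mut_codon = choose_codon(
            wt, codon_usage_table, rng, mode=mode, exclude=wt_codon
        )
        new.append(ProgrammedVariant(pos, wt, wt, wt_codon, mut_codon, "synonymous"))
        syn_positions.add(pos)
    out = replace(design)
    out.variants = new
    out.synonymous_positions = syn_positions
    out.validate()
    return out


def renumber(position: int, numbering_offsets, inverse: bool = False) -> int:
    """Translate a residue position between native and insertion-bearing numbering.

    Forward: a native position is shifted by the summed lengths of insertions
    at or before it.  Inverse: positions that fall inside an inserted segment
    have no native equivalent and raise :class:`CoordinateError`.
    """
    if position < 1:
        raise CoordinateError("positions are 1-based")
    offsets = sorted(numbering_offsets)
    if not inverse:
        shift = sum(length for ins_pos, length in offsets if ins_pos <= position)
        return position + shift
    shift = 0
    for ins_pos, length in offsets:
        start = ins_pos + shift
        if position < start:
            break
        if position < start + length:
            raise CoordinateError(
                f"position {position} lies inside the insertion at {ins_pos}"
            )
        shift += length
    return position - shift


def read_protein_fasta(path) -> tuple[str, str]:
    """Return (id, sequence) of the first record in a protein FASTA file."""
    record = next(SeqIO.parse(path, "fasta"))
    return record.id, str(record.seq).upper()


def write_design(design: LibraryDesign, path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def read_design(
    path, protein_id: str = "protein", sequence: str | None = None
) -> LibraryDesign:
    """Rebuild a LibraryDesign from its TSV representation.

    If no sequence is given, a minimal one is reconstructed from the wildtype
    residues recorded in the table (non-mutated positions are filled with A).
    """
    df = pd.read_csv(path, sep="\t")
    lo, hi = int(df["position"].min()), int(df["position"].max())
    if sequence is None:
        seq = ["A"] * hi
        for pos, wt in zip(df["position"], df["wt_aa"]):
            seq[pos - 1] = wt
        sequence = "".join(seq)
    variants = [
        ProgrammedVariant(
            int(r.position), r.wt_aa, r.mut_aa, r.wt_codon, r.mut_codon, r.kind
        )
        for r in df.itertuples()
    ]
    syn = {v.position for v in variants if v.kind == "synonymous"}
    design = LibraryDesign(protein_id, sequence, (lo, hi), variants, syn)
    design.validate()
    return design
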