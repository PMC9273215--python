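"""Residue contact topology from multimeric structures.

Residues of a homotetrameric channel are classified by the noncovalent
contacts they make: ``intra_only`` (contacts only within their own chain),
``inter`` (at least one contact across chains), or ``none``.  A contact is any
heavy-atom pair within a distance cutoff (default 4.5 Å), excluding pairs of
sequence-adjacent residues on the same chain.  Contact maps from several
structure states (e.g. closed and forced-open) can be unioned.

PDB parsing goes through Bio.PDB; hydrogens are dropped and for alternate
locations the highest-occupancy conformer is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .stats import ks_two_sample

__all__ = [
    "ContactMap",
    "parse_structure",
    "compute_contacts",
    "fitness_by_contact_class",
]

INTRA_ONLY = "intra_only"
INTER = "inter"
NONE = "none"


@dataclass
class ContactMap:
    """Symmetric residue-pair contacts and the derived per-residue classes."""

    pairs: pd.DataFrame  # chain_i, pos_i, chain_j, pos_j, min_distance
    residue_class: dict[tuple[str, int], str] = field(default_factory=dict)

    def position_class(self) -> dict[int, str]:
        """Class per residue position, pooled over chains (a position is
        ``inter`` if any chain copy makes an inter-subunit contact)."""
        out: dict[int, str] = {}
        for (_, pos), cls in self.residue_class.items():
            prev = out.get(pos)
            if prev == INTER or cls == INTER:
                out[pos] = INTER
            elif prev == INTRA_ONLY or cls == INTRA_ONLY:
                out[pos] = INTRA_ONLY
            else:
                out[pos] = NONE
        return out

    def union(self, other: "ContactMap") -> "ContactMap":
        """Union of two contact maps (e.g. closed- and open-state structures)."""
        pairs = pd.concat([self.pairs, other.pairs], ignore_index=True)
        pairs = (
            pairs.groupby(["chain_i", "pos_i", "chain_j", "pos_j"], as_index=False)[
                "min_distance"
            ].min()
        )
        residues = set(self.residue_class) | set(other.residue_class)
        return ContactMap(pairs=pairs, residue_class=_classify(pairs, residues))


def parse_structure(pdb_file) -> pd.DataFrame:
    """Heavy-atom records from a PDB file.

    Returns a DataFrame with chain, position, resname, atom, element, x, y, z.
    Hydrogens are excluded; disordered atoms contribute their highest-occupancy
    conformer only.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("structure", str(pdb_file))
    model = next(structure.get_models())
    rows = []
    for chain in model:
        for residue in chain:
            if residue.id[0] != " ":  # skip HETATM / waters
                continue
            for atom in residue:
                # DisorderedAtom iterates as its highest-occupancy child
                if atom.element == "H":
                    continue
                x, y, z = atom.coord
                rows.append(
                    {
                        "chain": chain.id,
                        "position": residue.id[1],
                        "resname": residue.get_resname(),
                        "atom": atom.get_name(),
                        "element": atom.element,
                        "x": float(x),
                        "y": float(y),
                        "z": float(z),
                    }
                )
    return pd.DataFrame(rows)


def _classify(pairs: pd.DataFrame, residues) -> dict[tuple[str, int], str]:
    cls = {r: NONE for r in residues}
    for row in pairs.itertuples():
        i = (row.chain_i, row.pos_i)
        j = (row.chain_j, row.pos_j)
        kind = INTRA_ONLY if row.chain_i == row.chain_j else INTER
        for r in (i, j):
            if r not in cls:
                cls[r] = NONE
            if kind == INTER:
                cls[r] = INTER
            elif cls[r] != INTER:
                cls[r] = INTRA_ONLY
    return cls


def compute_contacts(
    atoms: pd.DataFrame, cutoff: float = 4.5, min_seq_separation: int = 2
) -> ContactMap:
    """Residue contacts: any heavy-atom pair within ``cutoff`` Å.

    Same-chain pairs closer than ``min_seq_separation`` in sequence (including
    a residue with itself) are excluded as covalent/adjacent.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if atoms.empty:
        return ContactMap(pairs=_empty_pairs(), residue_class={})
    xyz = atoms[["x", "y", "z"]].to_numpy(float)
    chains = atoms["chain"].to_numpy()
    positions = atoms["position"].to_numpy()
    tree = cKDTree(xyz)
    found: dict[tuple, float] = {}
    for i, j in tree.query_pairs(cutoff):
        ci, pi = chains[i], int(positions[i])
        cj, pj = chains[j], int(positions[j])
        if ci == cj and abs(pi - pj) < min_seq_separation:
            continue
        key = ((ci, pi), (cj, pj)) if (ci, pi) <= (cj, pj) else ((cj, pj), (ci, pi))
        d = float(np.linalg.norm(xyz[i] - xyz[j]))
        if key not in found or d < found[key]:
            found[key] = d
    pairs = pd.DataFrame(
        [
            {
                "chain_i": a[0],
                "pos_i": a[1],
                "chain_j": b[0],
                "pos_j": b[1],
                "min_distance": d,
            }
            for (a, b), d in sorted(found.items())
        ],
        columns=["chain_i", "pos_i", "chain_j", "pos_j", "min_distance"],
    )
    residues = {(c, int(p)) for c, p in zip(chains, positions)}
    return ContactMap(pairs=pairs, residue_class=_classify(pairs, residues))


def _empty_pairs() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["chain_i", "pos_i", "chain_j", "pos_j", "min_distance"]
    )


def fitness_by_contact_class(
    contact_map: ContactMap,
    fitness_table: pd.DataFrame,
    region_filter=None,
    position_offset: int = 0,
) -> dict:
    """Fitness score vectors stratified by contact class, with a KS comparison.

    ``position_offset`` maps structure numbering to library numbering
    (library position = structure position + offset); ``region_filter`` is an
    optional set of library positions (e.g. the cytoplasmic domain).
    Returns per-class score arrays and, when both are populated, the
    two-sample KS (D, p) between ``intra_only`` and ``inter``.
    """
    pos_class = {
        pos + position_offset: cls for pos, cls in contact_map.position_class().items()
    }
    sub = fitness_table.dropna(subset=["score"])
    if region_filter is not None:
        region = set(region_filter)
        sub = sub[sub["position"].isin(region)]
    by_class: dict[str, list[float]] = {INTRA_ONLY: [], INTER: [], NONE: []}
    for pos, score in zip(sub["position"], sub["score"]):
        cls = pos_class.get(int(pos))
        if cls is not None:
            by_class[cls].append(float(score))
    result = {cls: np.asarray(v, float) for cls, v in by_class.items()}
    out = {"scores": result, "ks_intra_vs_inter": None}
    if len(result[INTRA_ONLY]) and len(result[INTER]):
        out["ks_intra_vs_inter"] = ks_two_sample(result[INTRA_ONLY], result[INTER])
    else:
        import warnings

        warnings.warn("a contact class is empty; KS comparison skipped")
    return out
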