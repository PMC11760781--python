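"""Group-level Q-score averages.

Per-atom Q-scores become interpretable when averaged over chemically
meaningful groups: a residue's backbone vs its sidechain, a nucleotide's
phosphate / sugar / base moieties, or a whole saccharide or ligand.  All
group means are unweighted means over member atoms with a defined Q; empty
partitions (a glycine sidechain, a 5'-terminal phosphate) are simply absent
from the output rather than reported as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import AtomicModel
from .qscore import QScoreTable

__all__ = [
    "GroupQ",
    "residue_q",
    "nucleotide_q",
    "molecule_q",
    "all_groups",
    "BACKBONE_ATOMS",
    "PHOSPHATE_ATOMS",
    "SUGAR_ATOMS",
]

#: protein backbone atom names; CB belongs to the sidechain
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})
#: nucleotide phosphate moiety (O5' goes with the phosphate, O3' with the sugar)
PHOSPHATE_ATOMS = frozenset({"P", "OP1", "OP2", "OP3", "O5'"})
#: ribose/deoxyribose atoms
SUGAR_ATOMS = frozenset({"C1'", "C2'", "C3'", "C4'", "C5'", "O4'", "O3'", "O2'"})


@dataclass
class GroupQ:
    """Mean Q over one atom group of one residue."""

    chain: str
    res_seq: int
    res_name: str
    icode: str
    kind: str       # protein | nucleotide | saccharide | ligand | water
    partition: str  # backbone | sidechain | phosphate | sugar | base | whole
    q_mean: float
    n_atoms: int


def _group_entries(table: QScoreTable) -> dict:
    """residue_key -> list of defined AtomQ entries."""
    groups: dict = {}
    for e in table:
        if e.defined:
            groups.setdefault(e.atom.residue_key, []).append(e)
    return groups


def _mean_group(entries, kind, partition) -> GroupQ | None:
    if not entries:
        return None
    a = entries[0].atom
    q = float(np.mean([e.q for e in entries]))
    return GroupQ(a.chain, a.res_seq, a.res_name, a.icode, kind, partition, q, len(entries))


def residue_q(table: QScoreTable, model: AtomicModel) -> list:
    """Backbone / sidechain / whole-residue Q means for protein residues."""
    out: list = []
    for key, entries in _group_entries(table).items():
        if entries[0].atom.mol_class != "protein":
            continue
        backbone = [e for e in entries if e.atom.atom_name in BACKBONE_ATOMS]
        sidechain = [e for e in entries if e.atom.atom_name not in BACKBONE_ATOMS]
        for part, sel in (("backbone", backbone), ("sidechain", sidechain), ("whole", entries)):
            g = _mean_group(sel, "protein", part)
            if g is not None:
                out.append(g)
    return out


def nucleotide_q(table: QScoreTable, model: AtomicModel) -> list:
    """Phosphate / sugar / base / whole Q means for nucleic-acid residues."""
    out: list = []
    for key, entries in _group_entries(table).items():
        if entries[0].atom.mol_class != "nucleotide":
            continue
        phosphate = [e for e in entries if e.atom.atom_name in PHOSPHATE_ATOMS]
        sugar = [e for e in entries if e.atom.atom_name in SUGAR_ATOMS]
        base = [
            e
            for e in entries
            if e.atom.atom_name not in PHOSPHATE_ATOMS
            and e.atom.atom_name not in SUGAR_ATOMS
        ]
        for part, sel in (
            ("phosphate", phosphate),
            ("sugar", sugar),
            ("base", base),
            ("whole", entries),
        ):
            g = _mean_group(sel, "nucleotide", part)
            if g is not None:
                out.append(g)
    return out


def molecule_q(table: QScoreTable, model: AtomicModel) -> list:
    """Whole-molecule Q means for saccharides, ligands and waters."""
    out: list = []
    for key, entries in _group_entries(table).items():
        kind = entries[0].atom.mol_class
        if kind not in ("saccharide", "ligand", "water"):
            continue
        g = _mean_group(entries, kind, "whole")
        if g is not None:
            out.append(g)
    return out


def all_groups(table: QScoreTable, model: AtomicModel) -> list:
    """All group rows: protein residues, nucleotides and small molecules."""
    return residue_q(table, model) + nucleotide_q(table, model) + molecule_q(table, model)


def groups_frame(groups) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chain": [g.chain for g in groups],
            "resnum": [g.res_seq for g in groups],
            "resname": [g.res_name for g in groups],
            "kind": [g.kind for g in groups],
            "partition": [g.partition for g in groups],
            "q_mean": [g.q_mean for g in groups],
            "n_atoms": [g.n_atoms for g in groups],
        }
    )
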