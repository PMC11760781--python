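"""Atomic models: PDB/mmCIF reading, residue classification, B-factor output.

The container is a flat list of :class:`Atom` records rather than a deep
hierarchy — every consumer in this package iterates atoms and groups them by
residue keys, so a flat table with grouping helpers is the simpler surface.
Residues are classified into the molecule classes the scoring pipeline cares
about (protein / nucleotide / saccharide / ligand / water) from the chemical
component dictionary shipped with gemmi, with an override hook for
non-tabulated components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import gemmi
import numpy as np

from .errors import InputError, ModelFormatError

__all__ = [
    "Atom",
    "AtomicModel",
    "read_model",
    "write_model_with_bfactors",
    "classify_residue",
]

#: molecule classes used throughout the package
MOLECULE_CLASSES = ("protein", "nucleotide", "saccharide", "ligand", "water")

_KIND_TO_CLASS = {
    gemmi.ResidueKind.AA: "protein",
    gemmi.ResidueKind.AAD: "protein",
    gemmi.ResidueKind.PAA: "protein",
    gemmi.ResidueKind.MAA: "protein",
    gemmi.ResidueKind.RNA: "nucleotide",
    gemmi.ResidueKind.DNA: "nucleotide",
    gemmi.ResidueKind.PYR: "saccharide",
    gemmi.ResidueKind.KET: "saccharide",
    gemmi.ResidueKind.HOH: "water",
}


def classify_residue(res_name: str, overrides: dict | None = None) -> str:
    """Molecule class for a residue name.

    Lookup order: user overrides, then the chemical-component tables bundled
    with gemmi.  Anything unrecognised is treated as a ligand, which also
    covers ions and other single-atom entities.
    """
    name = res_name.strip().upper()
    if overrides and name in overrides:
        return overrides[name]
    info = gemmi.find_tabulated_residue(name)
    if info is not None and info.found():
        return _KIND_TO_CLASS.get(info.kind, "ligand")
    return "ligand"


@dataclass
class Atom:
    """One atom record; coordinates in world Å, B-factor in Å²."""

    chain: str
    res_name: str
    res_seq: int
    atom_name: str
    element: str
    xyz: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    b_factor: float = 0.0
    icode: str = ""
    mol_class: str = "ligand"
    hetero: bool = False

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=np.float64).reshape(3)
        if not np.all(np.isfinite(self.xyz)):
            raise ModelFormatError(
                f"atom {self.chain}/{self.res_seq}/{self.atom_name} has non-finite coordinates"
            )
        if not self.element:
            raise ModelFormatError(
                f"atom {self.chain}/{self.res_seq}/{self.atom_name} has empty element symbol"
            )

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    @property
    def residue_key(self) -> tuple:
        """(chain, res_seq, icode, res_name) — identifies the residue."""
        return (self.chain, self.res_seq, self.icode, self.res_name)


@dataclass
class AtomicModel:
    """Flat atomic model with residue-grouping helpers."""

    atoms: list

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)

    def coords(self, atoms: Iterable[Atom] | None = None) -> np.ndarray:
        sel = self.atoms if atoms is None else list(atoms)
        if not sel:
            return np.zeros((0, 3))
        return np.array([a.xyz for a in sel])

    def scoreable_atoms(self) -> list:
        """Atoms eligible for Q-scoring.

        Non-hydrogen, occupancy > 0, and one altloc per atom site: the
        highest-occupancy conformer (ties broken toward altloc 'A') so that
        the same density is never sampled twice.
        """
        best: dict = {}
        for atom in self.atoms:
            if atom.is_hydrogen or atom.occupancy <= 0:
                continue
            key = atom.residue_key + (atom.atom_name,)
            prev = best.get(key)
            if prev is None:
                best[key] = atom
                continue
            # higher occupancy wins; on a tie prefer the alphabetically
            # first altloc (blank sorts first and is already unique)
            if (atom.occupancy, prev.altloc or "A") > (prev.occupancy, atom.altloc or "A"):
                best[key] = atom
        # preserve file order
        chosen = set(id(a) for a in best.values())
        return [a for a in self.atoms if id(a) in chosen]

    def residues(self) -> "dict[tuple, list]":
        """Atoms grouped by residue, in file order."""
        groups: dict = {}
        for atom in self.atoms:
            groups.setdefault(atom.residue_key, []).append(atom)
        return groups

    def with_b_factors(self, b_factors: np.ndarray) -> "AtomicModel":
        """Copy of the model with per-atom B-factors replaced (file order)."""
        b = np.asarray(b_factors, dtype=np.float64)
        if b.shape != (len(self.atoms),):
            raise InputError(
                f"need {len(self.atoms)} B-factors, got shape {b.shape}"
            )
        return AtomicModel([replace(a, b_factor=float(v)) for a, v in zip(self.atoms, b)])


def _from_gemmi(structure: gemmi.Structure, overrides: dict | None) -> AtomicModel:
    atoms: list = []
    if len(structure) == 0:
        raise ModelFormatError(f"{structure.name!r}: no models in file")
    model = structure[0]
    for chain in model:
        for res in chain:
            mol_class = classify_residue(res.name, overrides)
            for at in res:
                atoms.append(
                    Atom(
                        chain=chain.name,
                        res_name=res.name,
                        res_seq=res.seqid.num,
                        icode=(res.seqid.icode or "").strip(),
                        atom_name=at.name,
                        element=at.element.name,
                        xyz=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=at.occ,
                        altloc=at.altloc if at.altloc != "\x00" else "",
                        b_factor=at.b_iso,
                        mol_class=mol_class,
                        hetero=res.het_flag == "H",
                    )
                )
    if not atoms:
        raise ModelFormatError(f"{structure.name!r}: no atoms in file")
    return AtomicModel(atoms)


def read_model(path, overrides: dict | None = None) -> AtomicModel:
    """Read an atomic model from PDB or mmCIF (format auto-detected)."""
    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise ModelFormatError(f"cannot parse coordinate file {path!r}: {exc}") from exc
    model = _from_gemmi(structure, overrides)
    if structure.input_format == gemmi.CoorFormat.Mmcif:
        _restore_full_precision_b(model, path)
    return model


def _restore_full_precision_b(model: AtomicModel, path) -> None:
    # gemmi's Atom.b_iso is float32; re-read the mmCIF B column so values
    # written at full double precision survive a round-trip
    try:
        block = gemmi.cif.read(str(path)).sole_block()
        col = block.find_loop("_atom_site.B_iso_or_equiv")
    except (RuntimeError, ValueError):
        return
    values = [v for v in col]
    if len(values) != len(model.atoms):
        return
    for atom, raw in zip(model.atoms, values):
        try:
            atom.b_factor = float(raw)
        except ValueError:
            pass


def _to_gemmi(model: AtomicModel, name: str = "qscore3d") -> gemmi.Structure:
    # gemmi's add_chain/add_residue copy their argument, so each chain and
    # residue is assembled completely before being added to its parent
    chain_order: list = []
    by_chain: dict = {}
    for atom in model.atoms:
        if atom.chain not in by_chain:
            by_chain[atom.chain] = []
            chain_order.append(atom.chain)
        by_chain[atom.chain].append(atom)

    st = gemmi.Structure()
    st.name = name
    gm = gemmi.Model("1")
    for chain_name in chain_order:
        ch = gemmi.Chain(chain_name)
        res = None
        res_id = None
        for atom in by_chain[chain_name]:
            key = (atom.res_seq, atom.icode, atom.res_name)
            if key != res_id:
                if res is not None:
                    ch.add_residue(res)
                res = gemmi.Residue()
                res.name = atom.res_name
                res.seqid = gemmi.SeqId(atom.res_seq, atom.icode or " ")
                res.het_flag = "H" if atom.hetero else "A"
                res_id = key
            ga = gemmi.Atom()
            ga.name = atom.atom_name
            ga.element = gemmi.Element(atom.element)
            ga.pos = gemmi.Position(*atom.xyz)
            ga.occ = atom.occupancy
            ga.b_iso = atom.b_factor
            if atom.altloc:
                ga.altloc = atom.altloc
            res.add_atom(ga)
        if res is not None:
            ch.add_residue(res)
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_model_with_bfactors(model: AtomicModel, path) -> None:
    """Write a model with its B-factor column populated.

    Format follows the extension: ``.pdb`` / ``.ent`` gives PDB (B printed to
    two decimals, values clamped to [0, 999.99] with a warning), anything
    else mmCIF with full-precision B values.
    """
    for atom in model.atoms:
        if not np.isfinite(atom.b_factor):
            raise InputError(
                f"atom {atom.chain}/{atom.res_seq}/{atom.atom_name} has non-finite B-factor"
            )
    suffix = str(path).lower()
    as_pdb = suffix.endswith((".pdb", ".ent"))
    out = model
    if as_pdb:
        bs = np.array([a.b_factor for a in model.atoms])
        clipped = np.clip(bs, 0.0, 999.99)
        if np.any(clipped != bs):
            warnings.warn(
                "B-factors outside [0, 999.99] clamped for PDB output", stacklevel=2
            )
        out = model.with_b_factors(clipped)
    st = _to_gemmi(out)
    if as_pdb:
        st.write_pdb(str(path))
        return
    doc = st.make_mmcif_document()
    block = doc.sole_block()
    col = block.find_loop("_atom_site.B_iso_or_equiv")
    for i, atom in enumerate(out.atoms):
        col[i] = repr(float(atom.b_factor))
    doc.write_file(str(path))
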