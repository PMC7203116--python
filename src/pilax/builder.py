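"""Filament model building and PDB coordinate I/O.

A filament is generated from a single rigid subunit by repeated application
of the screw operation (rotate by the twist about z, translate by the rise
along z). Subunit 0 is left untransformed; positive twist is
counterclockwise looking down +z (right-handed convention — projection data
cannot determine the hand, so this is a documented choice, not a result).

PDB reading and writing go through gemmi; one chain per subunit, chains
lettered A, B, C, ... in subunit-index order.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import gemmi
import numpy as np

from .lattice import HelicalSymmetry

CHARGE_CLASSES = {"acidic", "basic", "neutral", "n_terminus", "c_terminus"}

# Side-chain atoms carrying the formal charge, per residue type.
ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_ATOMS = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2")}

_CHAIN_IDS = string.ascii_uppercase + string.ascii_lowercase + string.digits


@dataclass
class Atom:
    """A single (heavy) atom with its residue context and charge class."""

    name: str
    element: str
    residue_name: str
    residue_seq: int
    position: np.ndarray  # shape (3,), Å
    charge_class: str = "neutral"

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("position must be finite")
        if self.residue_seq < 1:
            raise ValueError("residue_seq must be >= 1")
        if self.charge_class not in CHARGE_CLASSES:
            raise ValueError(f"unknown charge_class {self.charge_class!r}")


@dataclass
class SubunitModel:
    """One pilin subunit: an ordered list of atoms plus its sequence."""

    atoms: List[Atom]
    sequence: str = ""
    label: str = "subunit"

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("subunit must contain at least one atom")

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array, Å."""
        return np.array([a.position for a in self.atoms])

    def n_residues(self) -> int:
        return len({a.residue_seq for a in self.atoms})


@dataclass
class FilamentModel:
    """Ordered rigid copies of a subunit related by helical symmetry about z."""

    subunits: List[SubunitModel]
    symmetry: HelicalSymmetry
    start_index: int = 0
    axis: str = "z"

    def __post_init__(self) -> None:
        if not self.subunits:
            raise ValueError("filament must contain at least one subunit")

    @property
    def n_subunits(self) -> int:
        return len(self.subunits)

    @property
    def coords(self) -> np.ndarray:
        return np.vstack([s.coords for s in self.subunits])

    def subunit_coords(self, i: int) -> np.ndarray:
        return self.subunits[i].coords


def screw_transform(sym: HelicalSymmetry, i: int) -> tuple[np.ndarray, np.ndarray]:
    """Rotation matrix and translation of the i-th screw operation."""
    theta = math.radians(sym.signed_twist * i)
    c, s = math.cos(theta), math.sin(theta)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    trans = np.array([0.0, 0.0, sym.rise * i])
    return rot, trans


def _transformed_subunit(subunit: SubunitModel, sym: HelicalSymmetry, i: int) -> SubunitModel:
    rot, trans = screw_transform(sym, i)
    atoms = [
        Atom(
            name=a.name,
            element=a.element,
            residue_name=a.residue_name,
            residue_seq=a.residue_seq,
            position=rot @ a.position + trans,
            charge_class=a.charge_class,
        )
        for a in subunit.atoms
    ]
    return SubunitModel(atoms=atoms, sequence=subunit.sequence, label=subunit.label)


def build_filament(
    subunit: SubunitModel,
    sym: HelicalSymmetry,
    n: int,
    start_index: int = 0,
) -> FilamentModel:
    """Symmetry-expand *subunit* into an n-subunit filament.

    Subunit i is the base subunit rotated by i*twist about z and translated
    by i*rise along z, for i = start_index .. start_index + n - 1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    subunits = [
        _transformed_subunit(subunit, sym, i)
        for i in range(start_index, start_index + n)
    ]
    return FilamentModel(subunits=subunits, symmetry=sym, start_index=start_index)


def filament_diameter(filament: FilamentModel) -> float:
    """Filament diameter: twice the largest atomic radius from the z axis, Å."""
    xy = filament.coords[:, :2]
    return 2.0 * float(np.max(np.linalg.norm(xy, axis=1)))


def _charge_class_for(atom_name: str, residue_name: str, residue_seq: int,
                      first_seq: int, last_seq: int) -> str:
    if residue_seq == first_seq and atom_name == "N":
        return "n_terminus"
    if residue_seq == last_seq and atom_name in ("OXT", "O"):
        # Terminal carboxylate; plain backbone O only counts on the last residue.
        return "c_terminus"
    if atom_name in ACIDIC_ATOMS.get(residue_name, ()):
        return "acidic"
    if atom_name in BASIC_ATOMS.get(residue_name, ()):
        return "basic"
    return "neutral"


def annotate_charge_classes(subunit: SubunitModel) -> SubunitModel:
    """Assign charge classes from residue/atom names and chain termini (in place)."""
    seqs = [a.residue_seq for a in subunit.atoms]
    first_seq, last_seq = min(seqs), max(seqs)
    for a in subunit.atoms:
        a.charge_class = _charge_class_for(
            a.name, a.residue_name, a.residue_seq, first_seq, last_seq
        )
    return subunit


def read_model(path, sym: Optional[HelicalSymmetry] = None):
    """Read a PDB file into a FilamentModel (or SubunitModel if single-chain).

    Each chain becomes one subunit, in file order. Charge classes are
    derived from residue and atom names. Returns a :class:`SubunitModel`
    when the file holds a single chain, else a :class:`FilamentModel` (a
    symmetry must then be supplied or a placeholder is used for bookkeeping
    only).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"failed to parse {path}: {exc}") from exc
    structure.setup_entities()
    if len(structure) == 0:
        raise ValueError(f"{path} contains no models")
    model = structure[0]
    subunits: List[SubunitModel] = []
    for chain in model:
        atoms: List[Atom] = []
        seq_letters = []
        for residue in chain:
            info = gemmi.find_tabulated_residue(residue.name)
            seq_letters.append(info.one_letter_code.upper() if info else "X")
            for at in residue:
                atoms.append(
                    Atom(
                        name=at.name,
                        element=at.element.name,
                        residue_name=residue.name,
                        residue_seq=residue.seqid.num,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    )
                )
        if atoms:
            sub = SubunitModel(atoms=atoms, sequence="".join(seq_letters), label=chain.name)
            annotate_charge_classes(sub)
            subunits.append(sub)
    if not subunits:
        raise ValueError(f"{path} contains no chains with atoms")
    if len(subunits) == 1:
        return subunits[0]
    if sym is None:
        sym = HelicalSymmetry(rise=1.0, twist=360.0)  # placeholder bookkeeping symmetry
    return FilamentModel(subunits=subunits, symmetry=sym)


def write_model(filament, path) -> None:
    """Write a filament (or bare subunit) as a PDB file, one chain per subunit."""
    if isinstance(filament, SubunitModel):
        filament = FilamentModel(
            subunits=[filament], symmetry=HelicalSymmetry(rise=1.0, twist=360.0)
        )
    if filament.n_subunits == 0:
        raise ValueError("cannot write an empty filament")
    if filament.n_subunits > len(_CHAIN_IDS):
        raise ValueError(
            f"{filament.n_subunits} subunits exceed the {len(_CHAIN_IDS)}-chain "
            "PDB ID space; split the model or use multi-model output"
        )
    structure = gemmi.Structure()
    structure.name = "filament"
    model = gemmi.Model("1")
    for i, sub in enumerate(filament.subunits):
        chain = gemmi.Chain(_CHAIN_IDS[i])
        current_seq = None
        residue = None
        for a in sub.atoms:
            if a.residue_seq != current_seq:
                residue = gemmi.Residue()
                residue.name = a.residue_name
                residue.seqid = gemmi.SeqId(a.residue_seq, " ")
                chain.add_residue(residue)
                current_seq = a.residue_seq
            at = gemmi.Atom()
            at.name = a.name
            at.element = gemmi.Element(a.element)
            at.pos = gemmi.Position(*a.position)
            at.occ = 1.0
            at.b_iso = 0.0
            chain[-1].add_atom(at)
        model.add_chain(chain)
    structure.add_model(model)
    structure.setup_entities()
    doc = structure.make_pdb_string()
    Path(path).write_text(doc)
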