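"""Structural frames, role tagging and multi-model PDB I/O.

A :class:`Frame` is one snapshot of the region around a receptor binding
pocket: a list of atom records plus an ``(n, 3)`` coordinate array in Å.
Frame ensembles (e.g. trajectory snapshots) are stored on disk as
multi-model PDB files (``MODEL``/``ENDMDL`` records) read and written with
Biopython.

Functional roles (ligand hydroxyl oxygen, sodium-site carboxylate oxygens,
tyrosine phenol ring, ...) are decoupled from author-specific residue
numbering through a :class:`RoleMap`: a small config mapping each role to a
residue/atom selector, so Ballesteros–Weinstein positions such as D^2.50
can be bound to whatever residue number a given receptor uses.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import numpy as np
import yaml
from Bio.PDB import PDBIO, PDBParser
from Bio.PDB.StructureBuilder import StructureBuilder

__all__ = [
    "Atom",
    "Frame",
    "AtomSelector",
    "RoleMap",
    "RoleError",
    "read_frames",
    "write_frames",
]

WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3", "SOL"})


class RoleError(ValueError):
    """A required role is missing, ambiguous or unresolvable in a frame."""


@dataclasses.dataclass(frozen=True)
class Atom:
    """One atom record (coordinates live in the parent Frame)."""

    serial: int
    name: str
    resname: str
    resid: int
    chain: str
    element: str

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.resname, self.resid, self.chain)


def _guess_element(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    if len(stripped) >= 2 and stripped[:2].upper() in {"CL", "BR", "NA", "MG", "ZN", "FE"}:
        return stripped[:2].capitalize()
    return stripped[0].upper()


class Frame:
    """One structural snapshot: atoms + coordinates (Å)."""

    def __init__(self, atoms: Sequence[Atom], coords, index: int = 0):
        self.atoms: list[Atom] = list(atoms)
        coords = np.asarray(coords, dtype=float)
        if coords.size == 0:
            coords = coords.reshape(0, 3)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coords shape {coords.shape} does not match {len(self.atoms)} atoms"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("frame coordinates must be finite")
        self.coords = coords
        self.index = index

    def __len__(self) -> int:
        return len(self.atoms)

    def __repr__(self) -> str:  # pragma: no cover - repr cosmetics
        return f"Frame(index={self.index}, n_atoms={len(self)})"

    def indices_where(self, **fields) -> list[int]:
        """Indices of atoms whose record fields all match ``fields``."""
        out = []
        for i, a in enumerate(self.atoms):
            if all(getattr(a, k) == v for k, v in fields.items()):
                out.append(i)
        return out

    def with_coords(self, coords) -> "Frame":
        return Frame(self.atoms, coords, index=self.index)

    def transformed(self, rotation=None, translation=None) -> "Frame":
        """Apply a rigid-body motion ``x -> R x + t`` to every atom."""
        xyz = self.coords
        if rotation is not None:
            xyz = xyz @ np.asarray(rotation, float).T
        if translation is not None:
            xyz = xyz + np.asarray(translation, float)
        return self.with_coords(xyz)


@dataclasses.dataclass(frozen=True)
class AtomSelector:
    """Match atoms by residue name/number/chain and atom name set."""

    resname: str | None = None
    resid: int | None = None
    chain: str | None = None
    atoms: tuple[str, ...] | None = None

    def matches(self, atom: Atom) -> bool:
        if self.resname is not None and atom.resname != self.resname:
            return False
        if self.resid is not None and atom.resid != self.resid:
            return False
        if self.chain is not None and atom.chain != self.chain:
            return False
        if self.atoms is not None and atom.name not in self.atoms:
            return False
        return True

    @classmethod
    def from_dict(cls, d: Mapping) -> "AtomSelector":
        atoms = d.get("atoms")
        if atoms is None and "atom" in d:
            atoms = [d["atom"]]
        return cls(
            resname=d.get("resname"),
            resid=d.get("resid"),
            chain=d.get("chain"),
            atoms=tuple(atoms) if atoms is not None else None,
        )


class RoleMap:
    """Mapping role name -> :class:`AtomSelector`.

    Standard role names used by the pipeline:

    - ``ligand_hydroxyl``: the ligand benzyl-alcohol oxygen (single atom)
    - ``carboxylate``: sodium-site aspartate carboxylate oxygens (OD1/OD2)
    - ``water``: water oxygens
    - ``tyrosine_ring``: the 7.43 tyrosine phenol ring carbons
    - ``tyrosine_hydroxyl``: the 7.43 tyrosine OH oxygen
    - ``glutamine_amide``: the 2.60 glutamine amide N/O
    - ``ligand_ring``: the ligand phenyl ring used for stacking
    """

    def __init__(self, roles: Mapping[str, AtomSelector]):
        self.roles = dict(roles)

    @classmethod
    def default(cls) -> "RoleMap":
        """Role map matching the synthetic-frame naming convention."""
        return cls(
            {
                "ligand_hydroxyl": AtomSelector(resname="LIG", atoms=("O1",)),
                "carboxylate": AtomSelector(resname="ASP", resid=114, atoms=("OD1", "OD2")),
                "water": AtomSelector(resname="HOH", atoms=("O",)),
                "tyrosine_ring": AtomSelector(
                    resname="TYR", resid=326, atoms=("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
                ),
                "tyrosine_hydroxyl": AtomSelector(resname="TYR", resid=326, atoms=("OH",)),
                "glutamine_amide": AtomSelector(resname="GLN", resid=124, atoms=("NE2", "OE1")),
                "ligand_ring": AtomSelector(
                    resname="LIG", atoms=("C2", "C3", "C4", "C5", "C6", "C7")
                ),
            }
        )

    @classmethod
    def from_dict(cls, d: Mapping[str, Mapping]) -> "RoleMap":
        return cls({k: AtomSelector.from_dict(v) for k, v in d.items()})

    @classmethod
    def from_yaml(cls, path) -> "RoleMap":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def resolve(self, frame: Frame, role: str) -> list[int]:
        """All atom indices carrying ``role`` (possibly empty)."""
        try:
            sel = self.roles[role]
        except KeyError as exc:
            raise RoleError(f"role {role!r} is not defined in the role map") from exc
        return [i for i, a in enumerate(frame.atoms) if sel.matches(a)]

    def require(self, frame: Frame, role: str) -> list[int]:
        idx = self.resolve(frame, role)
        if not idx:
            raise RoleError(f"no atoms tagged for role {role!r} in frame {frame.index}")
        return idx

    def resolve_one(self, frame: Frame, role: str) -> int:
        idx = self.require(frame, role)
        if len(idx) > 1:
            raise RoleError(
                f"role {role!r} must be unique but matched {len(idx)} atoms "
                f"in frame {frame.index}"
            )
        return idx[0]


def _hetfield(resname: str) -> str:
    if resname in WATER_RESNAMES:
        return "W"
    if resname in {"ASP", "TYR", "GLN", "SER"} or len(resname) != 3:
        return " "
    # non-standard residues (e.g. the ligand) as HETATM
    if resname not in _STANDARD_AA:
        return f"H_{resname}"
    return " "


_STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


def write_frames(frames: Iterable[Frame], path) -> None:
    """Write an ensemble of frames as a multi-model PDB file."""
    from Bio.PDB.PDBExceptions import PDBConstructionWarning

    builder = StructureBuilder()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        builder.init_structure("frames")
        for m, frame in enumerate(frames):
            builder.init_model(m)
            current_chain = None
            current_res = None
            for atom, xyz in zip(frame.atoms, frame.coords):
                if atom.chain != current_chain:
                    builder.init_chain(atom.chain)
                    builder.init_seg("    ")
                    current_chain = atom.chain
                    current_res = None
                res_key = (atom.chain, atom.resname, atom.resid)
                if res_key != current_res:
                    builder.init_residue(
                        atom.resname, _hetfield(atom.resname), atom.resid, " "
                    )
                    current_res = res_key
                name = atom.name
                fullname = name if len(name) >= 4 else f" {name}".ljust(4)
                builder.init_atom(
                    name,
                    np.asarray(xyz, float),
                    0.0,
                    1.0,
                    " ",
                    fullname,
                    serial_number=atom.serial,
                    element=atom.element,
                )
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


def read_frames(path) -> list[Frame]:
    """Read a multi-model PDB file into a list of frames (one per MODEL)."""
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(Path(path).stem, str(path))
    frames = []
    for m, model in enumerate(structure):
        atoms: list[Atom] = []
        coords: list[np.ndarray] = []
        for chain in model:
            for residue in chain:
                _, resid, _ = residue.id
                for at in residue:
                    element = (at.element or "").strip() or _guess_element(at.get_name())
                    atoms.append(
                        Atom(
                            serial=int(at.serial_number or len(atoms) + 1),
                            name=at.get_name(),
                            resname=residue.get_resname().strip(),
                            resid=int(resid),
                            chain=chain.id,
                            element=element.capitalize()
                            if len(element) > 1
                            else element.upper(),
                        )
                    )
                    coords.append(at.coord)
        frames.append(Frame(atoms, np.asarray(coords, float), index=m))
    return frames
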