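"""Read, write and subset atomic structures.

Structures are held as a flat, ordered atom table (:class:`StructureModel`)
which every downstream geometry operation consumes.  File I/O is delegated
to :mod:`biotite`; this module owns the filtering conventions (waters out,
hydrogens out, one altloc per atom), ligand flagging, radius assignment and
subunit selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    EmptyModelError,
    EmptySelectionError,
    PartitionError,
    StructureParseError,
)

logger = logging.getLogger(__name__)

#: Sentinel meaning "radius not assigned yet".
RADIUS_UNSET = -1.0

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O", "SOL", "TIP", "TIP3", "TIP4"}

_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}


@dataclass
class Atom:
    """One heavy atom of a structure."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    altloc: str = ""
    occupancy: float = 1.0
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    radius: float = RADIUS_UNSET
    is_ligand: bool = False
    is_hydrogen: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.serial}")


@dataclass
class StructureModel:
    """Ordered atom collection with chain and ligand bookkeeping."""

    atoms: list[Atom]
    ligand_codes: frozenset[str] = frozenset()
    label: str = ""

    @property
    def chains(self) -> set[str]:
        return {a.chain_id for a in self.atoms}

    def __len__(self) -> int:
        return len(self.atoms)

    # -- dense views used by the geometry modules --------------------------
    def coords(self) -> np.ndarray:
        """(N, 3) float array of positions in Å."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    def ligand_mask(self) -> np.ndarray:
        return np.array([a.is_ligand for a in self.atoms], dtype=bool)

    def has_radii(self) -> bool:
        return len(self.atoms) > 0 and all(a.radius > 0 for a in self.atoms)

    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain_id, residue_seq, residue_name) triples."""
        seen: dict[tuple[str, int, str], None] = {}
        for a in self.atoms:
            seen.setdefault((a.chain_id, a.residue_seq, a.residue_name))
        return list(seen)


@dataclass(frozen=True)
class RadiusTable:
    """Van der Waals radii by element symbol (Å)."""

    radii: dict[str, float]
    default_radius: float = 1.70

    def __post_init__(self) -> None:
        for elem, r in self.radii.items():
            if not 0.5 < r < 3.0:
                raise ValueError(f"radius for {elem!r} out of range: {r}")
        if not 0.5 < self.default_radius < 3.0:
            raise ValueError(f"default radius out of range: {self.default_radius}")

    def lookup(self, element: str) -> float:
        elem = element.strip().upper()
        if elem in self.radii:
            return self.radii[elem]
        logger.warning("unknown element %r: using default radius %.2f Å",
                       element, self.default_radius)
        return self.default_radius


#: Bondi-style van der Waals set used by default.
DEFAULT_RADII = RadiusTable(
    radii={"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80,
           "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90},
    default_radius=1.70,
)


@dataclass(frozen=True)
class Subunit:
    """One named selection of a partition.

    ``chains`` selects all non-ligand atoms of those chains (optionally
    restricted by ``residue_ranges``).  Ligand atoms are only included when
    their residue code appears in ``ligand_codes``; specific copies can be
    pinned with ``ligand_ids`` as (chain_id, residue_seq) pairs.
    """

    name: str
    chains: frozenset[str]
    residue_ranges: tuple[tuple[int, int], ...] | None = None
    ligand_codes: frozenset[str] = frozenset()
    ligand_ids: tuple[tuple[str, int], ...] | None = None

    def matches(self, atom: Atom) -> bool:
        if atom.is_ligand:
            if atom.residue_name not in self.ligand_codes:
                return False
            if self.ligand_ids is not None:
                return (atom.chain_id, atom.residue_seq) in self.ligand_ids
            return atom.chain_id in self.chains
        if atom.chain_id not in self.chains:
            return False
        if self.residue_ranges is not None:
            return any(lo <= atom.residue_seq <= hi
                       for lo, hi in self.residue_ranges)
        return True


@dataclass(frozen=True)
class PartitionSpec:
    """Disjoint named subunits for interface analysis."""

    subunits: tuple[Subunit, ...]
    name: str = "partition"

    def validate(self, model: StructureModel) -> None:
        """Raise :class:`PartitionError` if subunits overlap on ``model``."""
        owner = np.full(len(model), -1, dtype=int)
        for i, sub in enumerate(self.subunits):
            for j, atom in enumerate(model.atoms):
                if sub.matches(atom):
                    if owner[j] >= 0:
                        raise PartitionError(
                            f"atom {atom.serial} matched by both "
                            f"{self.subunits[owner[j]].name!r} and {sub.name!r}")
                    owner[j] = i


def subunit_mask(model: StructureModel, sub: Subunit) -> np.ndarray:
    """Boolean membership array of ``sub`` over ``model``'s atom order."""
    return np.array([sub.matches(a) for a in model.atoms], dtype=bool)


# ---------------------------------------------------------------------------
# File I/O (biotite-backed)
# ---------------------------------------------------------------------------

def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".pdb", ".ent"}:
        return "pdb"
    if suffix in {".cif", ".mmcif"}:
        return "mmcif"
    # sniff: mmCIF files start with "data_"
    try:
        head = path.open("rt", errors="replace").read(2048)
    except OSError as exc:
        raise StructureParseError(f"cannot read {path}: {exc}") from exc
    return "mmcif" if head.lstrip().startswith("data_") else "pdb"


def _read_atom_array(path: Path, fmt: str):
    import biotite.structure.io.pdb as pdb
    import biotite.structure.io.pdbx as pdbx

    extra = ["occupancy"]
    try:
        if fmt == "pdb":
            pfile = pdb.PDBFile.read(str(path))
            return pdb.get_structure(pfile, model=1, altloc="occupancy",
                                     extra_fields=extra)
        cfile = pdbx.CIFFile.read(str(path))
        return pdbx.get_structure(cfile, model=1, altloc="occupancy",
                                  extra_fields=extra, use_author_fields=True)
    except Exception as exc:
        raise StructureParseError(f"failed to parse {path} as {fmt}: {exc}") from exc


def load_structure(path: str | Path,
                   format: str = "auto",
                   ligand_codes: Iterable[str] = (),
                   label: str = "") -> StructureModel:
    """Load a PDB or mmCIF file into a :class:`StructureModel`.

    Waters and hydrogens are removed and only the highest-occupancy altloc
    is kept per atom.  Radii are left unassigned (see :func:`assign_radii`).
    ``ligand_codes`` flags those residue names as ligand; without it, any
    non-water HETATM residue that is not a standard amino acid is flagged.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    fmt = format if format != "auto" else _detect_format(path)
    if fmt not in {"pdb", "mmcif"}:
        raise StructureParseError(f"unknown format {fmt!r}")

    arr = _read_atom_array(path, fmt)
    codes = frozenset(c.strip().upper() for c in ligand_codes)

    atoms: list[Atom] = []
    serial = 0
    for i in range(arr.array_length()):
        res_name = str(arr.res_name[i]).strip().upper()
        element = str(arr.element[i]).strip().upper()
        if res_name in _WATER_NAMES:
            continue
        if element in {"H", "D"}:
            continue
        hetero = bool(arr.hetero[i])
        if codes:
            is_ligand = res_name in codes
        else:
            is_ligand = hetero and res_name not in _AMINO_ACIDS
        serial += 1
        atoms.append(Atom(
            serial=serial,
            name=str(arr.atom_name[i]).strip(),
            element=element,
            residue_name=res_name,
            residue_seq=int(arr.res_id[i]),
            chain_id=str(arr.chain_id[i]).strip(),
            occupancy=float(arr.occupancy[i]) if "occupancy" in arr.get_annotation_categories() else 1.0,
            position=np.array(arr.coord[i], dtype=float),
            is_ligand=is_ligand,
        ))
    if not atoms:
        raise EmptyModelError(f"{path}: no atoms left after removing "
                              "waters/hydrogens")
    return StructureModel(atoms=atoms, ligand_codes=codes or frozenset(
        a.residue_name for a in atoms if a.is_ligand), label=label or path.stem)


def assign_radii(model: StructureModel,
                 table: RadiusTable = DEFAULT_RADII) -> StructureModel:
    """Return a copy of ``model`` with van der Waals radii set per element.

    Idempotent; unknown elements fall back to ``table.default_radius``
    with a logged warning.
    """
    if len(model) == 0:
        raise EmptyModelError("cannot assign radii to an empty model")
    new_atoms = [replace(a, radius=table.lookup(a.element),
                         position=a.position.copy())
                 for a in model.atoms]
    return StructureModel(atoms=new_atoms, ligand_codes=model.ligand_codes,
                          label=model.label)


def select(model: StructureModel, sub: Subunit) -> StructureModel:
    """Subset ``model`` to one subunit, preserving atom order and flags."""
    missing = sub.chains - model.chains
    if missing:
        raise EmptySelectionError(
            f"subunit {sub.name!r} names absent chains: {sorted(missing)}")
    picked = [replace(a, position=a.position.copy())
              for a in model.atoms if sub.matches(a)]
    if not picked:
        raise EmptySelectionError(f"subunit {sub.name!r} matched zero atoms")
    return StructureModel(atoms=picked, ligand_codes=model.ligand_codes,
                          label=f"{model.label}:{sub.name}")


def write_structure(model: StructureModel, path: str | Path,
                    format: str = "pdb") -> None:
    """Write ``model`` as PDB or mmCIF; ligand atoms become HETATM records."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb
    import biotite.structure.io.pdbx as pdbx

    if len(model) == 0:
        raise EmptyModelError("refusing to write an empty model")
    n = len(model)
    arr = struc.AtomArray(n)
    arr.coord = model.coords().astype(np.float32)
    arr.chain_id = np.array([a.chain_id for a in model.atoms], dtype="U4")
    arr.res_id = np.array([a.residue_seq for a in model.atoms], dtype=int)
    arr.res_name = np.array([a.residue_name for a in model.atoms], dtype="U5")
    arr.atom_name = np.array([a.name for a in model.atoms], dtype="U6")
    arr.element = np.array([a.element for a in model.atoms], dtype="U2")
    arr.hetero = model.ligand_mask()
    arr.set_annotation("occupancy",
                       np.array([a.occupancy for a in model.atoms], dtype=float))
    arr.set_annotation("b_factor", np.zeros(n, dtype=float))

    path = Path(path)
    try:
        if format == "pdb":
            pfile = pdb.PDBFile()
            pdb.set_structure(pfile, arr)
            pfile.write(str(path))
        elif format == "mmcif":
            cfile = pdbx.CIFFile()
            pdbx.set_structure(cfile, arr, data_block=model.label or "model")
            cfile.write(str(path))
        else:
            raise ValueError(f"unknown format {format!r}")
    except OSError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc
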