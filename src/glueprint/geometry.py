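"""Ligand/domain geometry: rigid superposition, ring planes, polar
contacts, and a bead-model hydrodynamic radius."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    CorrespondenceError,
    DegenerateGeometryError,
    LigandCountError,
    PreconditionError,
)
from .structure_io import Atom, StructureModel


@dataclass
class SuperpositionResult:
    rotation: np.ndarray       # 3x3, det = +1
    translation: np.ndarray    # 3-vector, Å
    rmsd: float
    n_atoms: int
    correspondence: list[tuple[str, str]] | None = None

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class PlaneFit:
    centroid: np.ndarray
    normal: np.ndarray
    planarity_rms: float
    atom_names: list[str] | None = None


@dataclass
class ContactRecord:
    kind: str                  # canonical_hbond | weak_hbond | ch_o_contact
    donor_atom: Atom
    acceptor_atom: Atom
    distance: float
    cis_trans: str             # cis | trans


@dataclass
class RhEstimate:
    rh: float                  # nm
    method: str
    n_beads: int


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of B onto A (Kabsch, proper
    rotation only) under a fixed index correspondence.

    Returns the transform T with ``T(B) ≈ A`` and the RMSD of the residual
    distances after applying it.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (N, 3)")
    n = len(a)
    if n < 3:
        raise DegenerateGeometryError("need at least 3 points")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    s = np.linalg.svd(a0, compute_uv=False)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise DegenerateGeometryError("reference points are collinear")
    h = b0.T @ a0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = ca - rot @ cb
    resid = a - (b @ rot.T + trans)
    rmsd = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd,
                               n_atoms=n)


def _ligand_copies(model: StructureModel, ligand_code: str):
    groups: dict[tuple[str, int], list[Atom]] = {}
    for a in model.atoms:
        if a.residue_name == ligand_code.upper():
            groups.setdefault((a.chain_id, a.residue_seq), []).append(a)
    return groups


def ligand_pair_rmsd(model: StructureModel, ligand_code: str) -> SuperpositionResult:
    """All-heavy-atom RMSD between the two copies of a ligand after optimal
    superposition, with atoms paired by name."""
    groups = _ligand_copies(model, ligand_code)
    if len(groups) != 2:
        raise LigandCountError(
            f"expected exactly 2 copies of {ligand_code!r}, found {len(groups)}")
    (key_a, atoms_a), (key_b, atoms_b) = sorted(groups.items())
    by_name_a = {a.name: a for a in atoms_a}
    by_name_b = {a.name: a for a in atoms_b}
    only_a = sorted(set(by_name_a) - set(by_name_b))
    only_b = sorted(set(by_name_b) - set(by_name_a))
    if only_a or only_b:
        raise CorrespondenceError(
            f"atom-name mismatch between copies {key_a} and {key_b}: "
            f"only in first: {only_a}; only in second: {only_b}")
    names = sorted(by_name_a)
    ca = np.array([by_name_a[n].position for n in names])
    cb = np.array([by_name_b[n].position for n in names])
    result = superpose(ca, cb)
    result.correspondence = [(n, n) for n in names]
    return result


def superpose_by_selection(model_a: StructureModel, model_b: StructureModel,
                           residues_a: list[tuple[str, int]],
                           residues_b: list[tuple[str, int]],
                           atom_name: str = "CA"
                           ) -> tuple[SuperpositionResult, StructureModel]:
    """Superpose ``model_b`` onto ``model_a`` on matched residues.

    ``residues_*`` are equal-length ordered lists of (chain_id, residue_seq);
    the correspondence uses one named atom (Cα by default) per residue.
    Returns the transform and the whole transformed copy of ``model_b``.
    """
    if len(residues_a) != len(residues_b):
        raise CorrespondenceError(
            f"selection lengths differ: {len(residues_a)} vs {len(residues_b)}")

    def _pick(model: StructureModel, residues, tag: str) -> np.ndarray:
        index = {(a.chain_id, a.residue_seq): a for a in model.atoms
                 if a.name == atom_name}
        missing = [r for r in residues if r not in index]
        if missing:
            raise CorrespondenceError(
                f"model {tag} lacks atom {atom_name!r} in residues: {missing}")
        return np.array([index[r].position for r in residues])

    coords_a = _pick(model_a, residues_a, "A")
    coords_b = _pick(model_b, residues_b, "B")
    result = superpose(coords_a, coords_b)
    moved = [replace(a, position=result.apply(a.position[None])[0])
             for a in model_b.atoms]
    transformed = StructureModel(atoms=moved, ligand_codes=model_b.ligand_codes,
                                 label=f"{model_b.label}:superposed")
    return result, transformed


# ---------------------------------------------------------------------------
# Ring planes
# ---------------------------------------------------------------------------

def best_fit_plane(coords: np.ndarray,
                   atom_names: list[str] | None = None) -> PlaneFit:
    """Least-squares plane through a point set (normal = smallest principal
    direction); raises on fewer than 3 or collinear points."""
    pts = np.asarray(coords, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise DegenerateGeometryError("need at least 3 points for a plane")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise DegenerateGeometryError("points are collinear")
    normal = vt[2]
    rms = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    return PlaneFit(centroid=centroid, normal=normal, planarity_rms=rms,
                    atom_names=atom_names)


def plane_angle(a: PlaneFit, b: PlaneFit) -> float:
    """Angle between two fitted planes, in degrees, folded to [0, 90]."""
    cosang = abs(float(np.dot(a.normal, b.normal)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def ring_plane(model: StructureModel, residue: tuple[str, int],
               atom_names: list[str]) -> PlaneFit:
    """Plane fit over named atoms of one residue (chain_id, residue_seq)."""
    chain, seq = residue
    index = {a.name: a for a in model.atoms
             if a.chain_id == chain and a.residue_seq == seq}
    missing = [n for n in atom_names if n not in index]
    if missing:
        raise CorrespondenceError(f"residue {residue} lacks atoms: {missing}")
    return best_fit_plane(np.array([index[n].position for n in atom_names]),
                          atom_names=list(atom_names))


# ---------------------------------------------------------------------------
# Polar contacts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContactCriteria:
    """Heavy-atom distance bands (Å); no angle terms since the models carry
    no hydrogens."""

    canonical_max: float = 3.5
    weak_max: float = 4.0
    ch_o_max: float = 3.7
    min_distance: float = 2.2   # below this it is a clash, not a bond


# Protein side-chain donor/acceptor atom names; backbone N donates and
# backbone O accepts for every residue.
_SIDECHAIN_DONORS = {
    "ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"}, "HIS": {"ND1", "NE2"},
    "TRP": {"NE1"}, "ASN": {"ND2"}, "GLN": {"NE2"}, "SER": {"OG"},
    "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
}
_SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "HIS": {"ND1", "NE2"}, "SER": {"OG"}, "THR": {"OG1"},
    "TYR": {"OH"}, "MET": {"SD"}, "CYS": {"SG"},
}


def _is_donor(atom: Atom) -> bool:
    if atom.is_ligand:
        return atom.element in {"N", "O"}
    if atom.name == "N":
        return True
    return atom.name in _SIDECHAIN_DONORS.get(atom.residue_name, set())


def _is_acceptor(atom: Atom) -> bool:
    if atom.is_ligand:
        return atom.element in {"N", "O"}
    if atom.name in {"O", "OXT"}:
        return True
    return atom.name in _SIDECHAIN_ACCEPTORS.get(atom.residue_name, set())


def find_polar_contacts(model: StructureModel,
                        selection_a: np.ndarray,
                        selection_b: np.ndarray,
                        criteria: ContactCriteria = ContactCriteria(),
                        protomer_of: dict[str, str] | None = None
                        ) -> list[ContactRecord]:
    """Geometric polar contacts between two atom selections.

    ``selection_a``/``selection_b`` are boolean masks over ``model``'s atom
    order.  Donor–acceptor pairs within ``canonical_max`` are canonical
    hydrogen bonds, within ``weak_max`` weak ones; carbon–oxygen pairs
    within ``ch_o_max`` are recorded as non-classical C–H···O contacts.
    ``cis_trans`` is "cis" when both atoms belong to the same protomer
    (same chain, or same ``protomer_of`` group when given).
    """
    sel_a = np.flatnonzero(np.asarray(selection_a, dtype=bool))
    sel_b = np.flatnonzero(np.asarray(selection_b, dtype=bool))
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise PreconditionError("empty contact selection")

    atoms = model.atoms
    coords = model.coords()
    tree_b = cKDTree(coords[sel_b])
    max_cut = max(criteria.weak_max, criteria.ch_o_max)

    def _group(atom: Atom) -> str:
        if protomer_of is not None:
            return protomer_of.get(atom.chain_id, atom.chain_id)
        return atom.chain_id

    records: list[ContactRecord] = []
    seen: set[tuple[int, int, str]] = set()
    for ia in sel_a:
        a = atoms[ia]
        for jb in tree_b.query_ball_point(coords[ia], max_cut):
            ib = sel_b[jb]
            if ib == ia:
                continue
            b = atoms[ib]
            d = float(np.linalg.norm(a.position - b.position))
            if d < criteria.min_distance:
                continue
            cis_trans = "cis" if _group(a) == _group(b) else "trans"
            pair_key = (min(ia, ib), max(ia, ib))

            kind = None
            donor, acceptor = None, None
            if d <= criteria.weak_max:
                if _is_donor(a) and _is_acceptor(b):
                    donor, acceptor = a, b
                elif _is_donor(b) and _is_acceptor(a):
                    donor, acceptor = b, a
                if donor is not None:
                    kind = ("canonical_hbond" if d <= criteria.canonical_max
                            else "weak_hbond")
            if kind is None and d <= criteria.ch_o_max:
                if a.element == "C" and b.element == "O":
                    donor, acceptor, kind = a, b, "ch_o_contact"
                elif b.element == "C" and a.element == "O":
                    donor, acceptor, kind = b, a, "ch_o_contact"
            if kind is None:
                continue
            if (*pair_key, kind) in seen:
                continue
            seen.add((*pair_key, kind))
            records.append(ContactRecord(kind=kind, donor_atom=donor,
                                         acceptor_atom=acceptor, distance=d,
                                         cis_trans=cis_trans))
    records.sort(key=lambda r: (r.distance, r.donor_atom.serial))
    return records


# ---------------------------------------------------------------------------
# Hydrodynamic radius
# ---------------------------------------------------------------------------

#: Default bead radius for one-residue beads (Å); roughly the Cα spacing.
RESIDUE_BEAD_RADIUS = 3.8
#: Hydration-shell increment added to every bead radius (Å).
HYDRATION_INCREMENT = 3.0


def kirkwood_rh(centers: np.ndarray, bead_radii: np.ndarray) -> float:
    """Kirkwood double-sum hydrodynamic radius (Å) of a rigid bead array:

        1/Rh = (1/N²) [ Σ_i 1/b_i  +  Σ_{i≠j} 1/r_ij ]

    Reduces to ``b`` for a single bead and to additive friction for far
    separated beads.  Vectorised; see tests for the brute-force oracle.
    """
    c = np.asarray(centers, dtype=float)
    b = np.asarray(bead_radii, dtype=float)
    n = len(c)
    if n == 0:
        raise ValueError("no beads")
    if n == 1:
        return float(b[0])
    diff = c[:, None, :] - c[None, :, :]
    r = np.sqrt(np.sum(diff ** 2, axis=-1))
    inv = np.zeros_like(r)
    off = ~np.eye(n, dtype=bool)
    inv[off] = 1.0 / r[off]
    total = float(np.sum(1.0 / b) + inv.sum())
    return float(n * n / total)


def coarse_grain_beads(model: StructureModel,
                       residue_bead_radius: float = RESIDUE_BEAD_RADIUS,
                       hydration: float = HYDRATION_INCREMENT
                       ) -> tuple[np.ndarray, np.ndarray]:
    """One bead per protein residue (heavy-atom centroid) plus one bead per
    ligand atom (its vdW radius); hydration increment added to all radii."""
    centers, radii = [], []
    groups: dict[tuple[str, int], list[Atom]] = {}
    for a in model.atoms:
        if a.is_ligand:
            centers.append(a.position)
            radii.append(a.radius + hydration)
        else:
            groups.setdefault((a.chain_id, a.residue_seq), []).append(a)
    for atoms in groups.values():
        centers.append(np.mean([a.position for a in atoms], axis=0))
        radii.append(residue_bead_radius + hydration)
    return np.array(centers), np.array(radii)


def predict_rh(model: StructureModel, method: str = "kirkwood_beads",
               residue_bead_radius: float = RESIDUE_BEAD_RADIUS,
               hydration: float = HYDRATION_INCREMENT) -> RhEstimate:
    """Structure-based hydrodynamic radius in nm.

    Coarse-grains the model to beads and evaluates the Kirkwood double sum;
    a single-bead model returns that bead's hydrated radius.
    """
    if method != "kirkwood_beads":
        raise ValueError(f"unknown method {method!r}")
    if not model.has_radii():
        raise PreconditionError("radii not assigned")
    centers, radii = coarse_grain_beads(model, residue_bead_radius, hydration)
    rh_angstrom = kirkwood_rh(centers, radii)
    return RhEstimate(rh=rh_angstrom / 10.0, method=method,
                      n_beads=len(centers))
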