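"""Synthetic structures with analytically known geometry.

Everything here exists so the surface/footprint/geometry pipeline can be
tested without external files: pseudo-atom sphere pairs with closed-form
buried areas, rigid duplicated ligands with a known transform, spiro-like
ring pairs at an exact dihedral, and mirror-symmetric toy complexes.

All generators are deterministic under a fixed seed; the oracles are pure
closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import Atom, PartitionSpec, StructureModel, Subunit


@dataclass(frozen=True)
class SpherePairSpec:
    r1: float
    r2: float
    separation: float
    probe: float = 1.4

    def __post_init__(self) -> None:
        if min(self.r1, self.r2, self.probe) <= 0 or self.separation < 0:
            raise ValueError("radii and probe must be positive, separation >= 0")


@dataclass(frozen=True)
class RigidDimerSpec:
    n_atoms: int
    rotation: np.ndarray
    translation: np.ndarray
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_atoms < 3:
            raise ValueError("need at least 3 atoms")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


def _pseudo_atom(serial: int, chain: str, pos, radius: float,
                 name: str | None = None, residue_name: str = "SPH",
                 residue_seq: int = 1, is_ligand: bool = False) -> Atom:
    return Atom(serial=serial, name=name or f"C{serial}", element="C",
                residue_name=residue_name, residue_seq=residue_seq,
                chain_id=chain, position=np.asarray(pos, dtype=float),
                radius=radius, is_ligand=is_ligand)


# ---------------------------------------------------------------------------
# Sphere pair + analytic buried-SASA oracle
# ---------------------------------------------------------------------------

def make_sphere_pair(spec: SpherePairSpec) -> StructureModel:
    """Two pseudo-atoms on the x axis (chains A and B) with explicit radii."""
    atoms = [
        _pseudo_atom(1, "A", [0.0, 0.0, 0.0], spec.r1),
        _pseudo_atom(2, "B", [spec.separation, 0.0, 0.0], spec.r2),
    ]
    return StructureModel(atoms=atoms, label="sphere_pair")


def sphere_pair_partition() -> PartitionSpec:
    return PartitionSpec(subunits=(
        Subunit(name="A", chains=frozenset({"A"})),
        Subunit(name="B", chains=frozenset({"B"})),
    ), name="sphere_pair")


def analytic_buried_sasa_sphere_pair(spec: SpherePairSpec) -> dict[str, float]:
    """Closed-form buried SASA of each expanded sphere of the pair.

    With expanded radii R_i = r_i + probe and separation d, the occluded
    area on sphere i is the spherical cap 2π R_i h_i with
    h_i = R_i − (d² + R_i² − R_j²)/(2d).  Disjoint spheres bury nothing;
    containment (d ≤ |R1−R2|, including the concentric d = 0 case) buries
    the smaller sphere completely and nothing of the larger.
    """
    R1, R2 = spec.r1 + spec.probe, spec.r2 + spec.probe
    d = spec.separation
    if d >= R1 + R2:
        buried = {"A": 0.0, "B": 0.0}
    elif d <= abs(R1 - R2):
        small, large = ("A", "B") if R1 <= R2 else ("B", "A")
        rs = min(R1, R2)
        buried = {small: 4.0 * np.pi * rs ** 2, large: 0.0}
    else:
        h1 = R1 - (d * d + R1 * R1 - R2 * R2) / (2.0 * d)
        h2 = R2 - (d * d + R2 * R2 - R1 * R1) / (2.0 * d)
        buried = {"A": 2.0 * np.pi * R1 * max(h1, 0.0),
                  "B": 2.0 * np.pi * R2 * max(h2, 0.0)}
    buried["total"] = buried["A"] + buried["B"]
    return buried


# ---------------------------------------------------------------------------
# Rigid ligand dimer
# ---------------------------------------------------------------------------

def make_rigid_dimer(spec: RigidDimerSpec) -> StructureModel:
    """Two copies of a random compact 'ligand': copy B = R·A + t + noise.

    Atom names match across copies so name-based correspondence works; the
    expected RMSD is derivable from the seeded noise.
    """
    rng = np.random.default_rng(spec.seed)
    base = rng.normal(scale=2.0, size=(spec.n_atoms, 3))
    rot = np.asarray(spec.rotation, dtype=float)
    trans = np.asarray(spec.translation, dtype=float)
    moved = base @ rot.T + trans
    if spec.noise_sigma > 0:
        moved = moved + rng.normal(scale=spec.noise_sigma,
                                   size=moved.shape)
    atoms = []
    serial = 0
    for chain, res_seq, coords in (("A", 1, base), ("B", 1, moved)):
        for i in range(spec.n_atoms):
            serial += 1
            atoms.append(_pseudo_atom(serial, chain, coords[i], 1.7,
                                      name=f"L{i+1}", residue_name="LIG",
                                      residue_seq=res_seq, is_ligand=True))
    return StructureModel(atoms=atoms, ligand_codes=frozenset({"LIG"}),
                          label="rigid_dimer")


def rotation_about_axis(axis, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about an arbitrary axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(t) * k + (1 - np.cos(t)) * (k @ k)


# ---------------------------------------------------------------------------
# Spiro-like ring pair
# ---------------------------------------------------------------------------

def make_ring_pair(dihedral_deg: float,
                   ring_sizes: tuple[int, int] = (5, 6)
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Two regular planar rings sharing one vertex at the origin, with the
    second ring's plane rotated about the x axis by exactly ``dihedral_deg``.

    Returns the two coordinate arrays; the exact inter-plane angle is the
    requested dihedral by construction.
    """
    if not 0.0 <= dihedral_deg <= 90.0:
        raise ValueError("dihedral must be in [0, 90] degrees")

    def _ring(n: int, edge: float = 1.5) -> np.ndarray:
        radius = edge / (2.0 * np.sin(np.pi / n))
        ang = 2.0 * np.pi * np.arange(n) / n
        pts = np.column_stack([radius * np.cos(ang), radius * np.sin(ang),
                               np.zeros(n)])
        return pts - pts[0]          # shared vertex at the origin

    ring_a = _ring(ring_sizes[0])
    # point-reflect the second ring so it extends away from the first, as a
    # real spiro junction does, then tilt its plane about x by the dihedral
    ring_b = -_ring(ring_sizes[1]) @ rotation_about_axis([1, 0, 0],
                                                         dihedral_deg).T
    return ring_a, ring_b


# ---------------------------------------------------------------------------
# Toy two-domain complex
# ---------------------------------------------------------------------------

def _slab(n: int, seed: int, spacing: float = 1.8,
          jitter: float = 0.1, layers: int = 2) -> np.ndarray:
    """n jittered lattice points forming a flat two-layer slab facing +x.

    A slab presents a broad planar face, so a dimer of two slabs buries a
    patch deep enough for the 2 Å interface rule to label a substantial
    footprint.  Spacing < 2 r keeps the SES a single body; the jitter is
    applied only in x so the y/z footprint stays exactly mirrorable.
    """
    rng = np.random.default_rng(seed)
    m = int(np.ceil(np.sqrt(n / layers) / 2.0)) + 2
    yz = np.array(np.meshgrid(np.arange(-m, m + 1), np.arange(-m, m + 1),
                              indexing="ij")).reshape(2, -1).T
    order = np.argsort(np.linalg.norm(yz, axis=1), kind="stable")
    pts = []
    for ix in range(layers):
        for yzi in yz[order]:
            pts.append([-ix * spacing, yzi[0] * spacing, yzi[1] * spacing])
    pts = np.array(pts[:n], dtype=float)
    pts[:, 0] += rng.uniform(-jitter, jitter, size=len(pts))
    return pts


def make_toy_complex(n_per_subunit: int = 30, gap: float = 1.0,
                     ligand_at_interface: bool = True, seed: int = 0,
                     radius: float = 1.7
                     ) -> tuple[StructureModel, PartitionSpec]:
    """Mirror-symmetric two-domain complex, optionally bridged by a pair of
    5-atom pseudo-ligands; returns the model plus its two-protomer
    partition.

    Subunit A occupies x < 0 and B is its exact mirror image through the
    x = 0 plane, with the facing van der Waals surfaces ``gap`` Å apart.
    """
    if n_per_subunit < 10:
        raise ValueError("n_per_subunit must be at least 10")
    blob = _slab(n_per_subunit, seed)
    shift = blob[:, 0].max() + radius + gap / 2.0
    blob_a = blob - np.array([shift, 0.0, 0.0])

    atoms: list[Atom] = []
    serial = 0
    for pos in blob_a:
        serial += 1
        atoms.append(_pseudo_atom(serial, "A", pos, radius,
                                  residue_name="DOM", residue_seq=serial))
    if ligand_at_interface:
        # 5 non-collinear atoms resting on the slab face near the mirror
        # plane; the zigzag keeps the copy superposable but not degenerate
        ztop = blob_a[:, 2].max() + radius
        lig_a = [np.array([-gap / 2.0 - 0.6 - 0.5 * (i % 2),
                           -3.2 + 1.6 * i,
                           ztop + 0.9 + 0.4 * (i % 3 == 0)])
                 for i in range(5)]
        for i, pos in enumerate(lig_a):
            serial += 1
            atoms.append(_pseudo_atom(serial, "A", pos, radius, name=f"L{i+1}",
                                      residue_name="LIG", residue_seq=9000,
                                      is_ligand=True))
    # mirror everything through x = 0 to get subunit B
    n_a = len(atoms)
    for a in atoms[:n_a]:
        serial += 1
        pos = a.position * np.array([-1.0, 1.0, 1.0])
        atoms.append(_pseudo_atom(serial, "B", pos, radius, name=a.name,
                                  residue_name=a.residue_name,
                                  residue_seq=a.residue_seq,
                                  is_ligand=a.is_ligand))
    model = StructureModel(atoms=atoms, ligand_codes=frozenset({"LIG"}),
                           label="toy_complex")
    partition = PartitionSpec(subunits=(
        Subunit(name="P1", chains=frozenset({"A"}),
                ligand_codes=frozenset({"LIG"})),
        Subunit(name="P2", chains=frozenset({"B"}),
                ligand_codes=frozenset({"LIG"})),
    ), name="toy")
    return model, partition
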