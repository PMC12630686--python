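"""Conveniences for analysing deposited glue-dimer models.

These helpers avoid hard-coding chain identifiers: the bridging ligand is
identified as the ligand residue code present in exactly two copies, and
each copy is assigned to the protein chain it touches most closely.  The
default protomer partition is then "one receptor chain + its ligand copy",
with any remaining chains (e.g. an adaptor subunit) left out unless
explicitly requested.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path

import numpy as np

from .errors import DegenerateGeometryError, LigandCountError
from .structure_io import (
    PartitionSpec,
    StructureModel,
    Subunit,
    assign_radii,
    load_structure,
    select,
)


def find_glue_ligand(model: StructureModel) -> str:
    """Residue code of the ligand present in exactly two copies (the
    largest such ligand when several qualify)."""
    copies: dict[str, set[tuple[str, int]]] = {}
    sizes: Counter[str] = Counter()
    for a in model.atoms:
        if a.is_ligand:
            copies.setdefault(a.residue_name, set()).add(
                (a.chain_id, a.residue_seq))
            sizes[a.residue_name] += 1
    paired = [code for code, ids in copies.items() if len(ids) == 2]
    if not paired:
        raise LigandCountError(
            f"no ligand code with exactly 2 copies among {dict(sizes)}")
    return max(paired, key=lambda c: sizes[c])


def ligand_copy_ids(model: StructureModel,
                    ligand_code: str) -> list[tuple[str, int]]:
    return sorted({(a.chain_id, a.residue_seq) for a in model.atoms
                   if a.residue_name == ligand_code})


def protomer_partition(model: StructureModel, ligand_code: str | None = None,
                       extra_chains_with: dict[str, int] | None = None
                       ) -> PartitionSpec:
    """Two-protomer partition: each ligand copy goes with its closest
    protein chain.

    ``extra_chains_with`` optionally maps additional chain IDs (e.g. an
    adaptor protein) to the protomer index (0 or 1) they should join.
    """
    code = ligand_code or find_glue_ligand(model)
    ids = ligand_copy_ids(model, code)
    if len(ids) != 2:
        raise LigandCountError(
            f"expected 2 copies of {code!r}, found {len(ids)}")

    protein_chains = sorted({a.chain_id for a in model.atoms
                             if not a.is_ligand})
    chain_coords = {c: np.array([a.position for a in model.atoms
                                 if a.chain_id == c and not a.is_ligand])
                    for c in protein_chains}

    def closest_chain(copy_id):
        lig = np.array([a.position for a in model.atoms
                        if (a.chain_id, a.residue_seq) == copy_id
                        and a.residue_name == code])
        best, best_d = None, np.inf
        for c, pts in chain_coords.items():
            d = min(np.linalg.norm(pts - p, axis=1).min() for p in lig)
            if d < best_d:
                best, best_d = c, d
        return best

    owners = [closest_chain(i) for i in ids]
    if owners[0] == owners[1]:
        raise LigandCountError(
            f"both ligand copies assigned to chain {owners[0]!r}")

    chain_sets = [{owners[k]} for k in range(2)]
    if extra_chains_with:
        for chain, k in extra_chains_with.items():
            chain_sets[k].add(chain)
    subunits = tuple(
        Subunit(name=f"protomer{k + 1}", chains=frozenset(chain_sets[k]),
                ligand_codes=frozenset({code}), ligand_ids=(ids[k],))
        for k in range(2))
    return PartitionSpec(subunits=subunits, name="protomers")


def deposited_report(path: str | Path, ligand_code: str | None = None,
                     grid_spacing: float = 0.5, probe: float = 1.4,
                     threshold: float = 2.0) -> dict:
    """End-to-end analysis of a deposited glue-dimer model.

    Returns buried SASA, protomer-1 footprint and its ligand share, the
    ligand-pair RMSD, the spiro inter-plane angle, and the bead-model
    hydrodynamic radius — everything needed to compare against published
    interface numbers.
    """
    from .footprint import (
        buried_sasa,
        decompose_footprint,
        footprint_area,
        label_interface_vertices,
    )
    from .geometry import best_fit_plane, ligand_pair_rmsd, plane_angle, predict_rh
    from .rings import find_spiro_ring_pair
    from .surface import SurfaceParams, compute_ses_mesh

    model = assign_radii(load_structure(path))
    code = ligand_code or find_glue_ligand(model)
    partition = protomer_partition(model, code)
    params = SurfaceParams(probe_radius=probe, grid_spacing=grid_spacing)

    bsasa = buried_sasa(model, partition, params)

    complex_mesh = compute_ses_mesh(model, params, attribute=False)
    sub = partition.subunits[0]
    sub_model = select(model, sub)
    sub_mesh = compute_ses_mesh(sub_model, params)
    labels = label_interface_vertices(sub_mesh, complex_mesh, threshold)
    fp_area = footprint_area(sub_mesh, labels)
    lig_area, prot_area = decompose_footprint(sub_mesh, labels, sub_model)

    rmsd = ligand_pair_rmsd(model, code)

    copy0 = ligand_copy_ids(model, code)[0]
    lig_atoms = [a for a in model.atoms
                 if (a.chain_id, a.residue_seq) == copy0
                 and a.residue_name == code]
    lig_coords = np.array([a.position for a in lig_atoms])
    try:
        ring5, ring6 = find_spiro_ring_pair(lig_coords)
        dihedral = plane_angle(best_fit_plane(lig_coords[ring5]),
                               best_fit_plane(lig_coords[ring6]))
    except DegenerateGeometryError:
        dihedral = None      # ligand has no spiro 5/6 ring pair

    rh = predict_rh(model)

    return {
        "ligand_code": code,
        "n_atoms": len(model),
        "buried_sasa_total_A2": bsasa["total"],
        "buried_sasa_per_protomer_A2": {
            s.name: bsasa[s.name] for s in partition.subunits},
        "footprint_protomer1_A2": fp_area,
        "footprint_ligand_A2": lig_area,
        "footprint_protein_A2": prot_area,
        "ligand_pair_rmsd_A": rmsd.rmsd,
        "ligand_pair_n_atoms": rmsd.n_atoms,
        "spiro_dihedral_deg": dihedral,
        "rh_nm": rh.rh,
        "rh_n_beads": rh.n_beads,
    }
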