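"""Buried surface areas and interface footprints.

A subunit's footprint is the part of its solvent-excluded surface that
disappears when the complex forms.  It is found by comparing the subunit's
SES mesh against the complex's SES mesh, both built in the same frame with
identical grid parameters: a subunit vertex farther than a threshold
(default 2.0 Å) from every complex-mesh vertex lies on surface that the
complex no longer exposes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import PartitionError, PreconditionError
from .structure_io import PartitionSpec, StructureModel, select, subunit_mask
from .surface import SurfaceParams, TriangleMesh, compute_sasa, compute_ses_mesh

#: Buried-SASA bands (Å²) used for interface classification.
CLASS_BANDS = {"transient_low": 800.0, "transient_high": 1200.0}


@dataclass
class FootprintResult:
    subunit_name: str
    interface_vertices: np.ndarray  # int indices into the subunit mesh
    footprint_area: float
    ligand_area: float
    protein_area: float
    buried_sasa_subunit: float
    threshold: float


@dataclass
class InterfaceSummary:
    total_buried_sasa: float
    footprints: list[FootprintResult]
    classification: str


def buried_sasa(complex_model: StructureModel, partition: PartitionSpec,
                params: SurfaceParams = SurfaceParams()) -> dict[str, float]:
    """SASA lost by each subunit upon complex formation.

    buried(S) = SASA(S alone) − SASA(S's atoms within the full complex).
    Returns per-subunit values plus a ``"total"`` key.
    """
    if not complex_model.has_radii():
        raise PreconditionError("radii not assigned")
    partition.validate(complex_model)
    complex_sasa = compute_sasa(complex_model, params)
    out: dict[str, float] = {}
    total = 0.0
    for sub in partition.subunits:
        alone = compute_sasa(select(complex_model, sub), params)
        mask = subunit_mask(complex_model, sub)
        in_complex = float(complex_sasa.per_atom_area[mask].sum())
        buried = alone.total - in_complex
        out[sub.name] = buried
        total += buried
    out["total"] = total
    return out


def label_interface_vertices(subunit_mesh: TriangleMesh,
                             complex_mesh: TriangleMesh,
                             threshold: float = 2.0) -> np.ndarray:
    """Boolean per-vertex labels: True where the subunit-mesh vertex is more
    than ``threshold`` Å from every complex-mesh vertex."""
    if len(complex_mesh.vertices) == 0:
        raise PreconditionError("complex mesh has no vertices")
    tree = cKDTree(complex_mesh.vertices)
    dist, _ = tree.query(subunit_mesh.vertices)
    return dist > threshold


def footprint_area(subunit_mesh: TriangleMesh, labels: np.ndarray) -> float:
    """Summed vertex area over interface-labeled vertices."""
    if subunit_mesh.vertex_area is None:
        raise PreconditionError("subunit mesh lacks vertex areas")
    return float(subunit_mesh.vertex_area[labels].sum())


def decompose_footprint(subunit_mesh: TriangleMesh, labels: np.ndarray,
                        model: StructureModel) -> tuple[float, float]:
    """(ligand_area, protein_area) split of the footprint by nearest-atom
    attribution; sums to the footprint area exactly."""
    if subunit_mesh.vertex_atom is None or subunit_mesh.vertex_area is None:
        raise PreconditionError("subunit mesh lacks vertex attribution")
    lig = model.ligand_mask()[subunit_mesh.vertex_atom]
    areas = subunit_mesh.vertex_area
    ligand_area = float(areas[labels & lig].sum())
    protein_area = float(areas[labels & ~lig].sum())
    return ligand_area, protein_area


def classify_interface(total_buried_sasa: float,
                       bands: dict[str, float] = CLASS_BANDS) -> str:
    """Label a buried-SASA total as below-transient / transient /
    obligate-range."""
    if total_buried_sasa < 0:
        raise ValueError("buried SASA cannot be negative")
    if total_buried_sasa < bands["transient_low"]:
        return "below-transient"
    if total_buried_sasa <= bands["transient_high"]:
        return "transient"
    return "obligate-range"


def analyze_interface(complex_model: StructureModel, partition: PartitionSpec,
                      params: SurfaceParams = SurfaceParams(),
                      threshold: float = 2.0) -> InterfaceSummary:
    """Full footprint + buried-SASA analysis for one partition.

    Builds the complex SES mesh once and one mesh per subunit (all with the
    same parameters and frame), labels interface vertices at ``threshold``,
    decomposes footprints into ligand/protein parts, and classifies the
    total buried SASA.
    """
    sasa = buried_sasa(complex_model, partition, params)
    complex_mesh = compute_ses_mesh(complex_model, params, attribute=False)
    results = []
    for sub in partition.subunits:
        sub_model = select(complex_model, sub)
        sub_mesh = compute_ses_mesh(sub_model, params)
        labels = label_interface_vertices(sub_mesh, complex_mesh, threshold)
        area = footprint_area(sub_mesh, labels)
        lig_area, prot_area = decompose_footprint(sub_mesh, labels, sub_model)
        results.append(FootprintResult(
            subunit_name=sub.name,
            interface_vertices=np.flatnonzero(labels),
            footprint_area=area,
            ligand_area=lig_area,
            protein_area=prot_area,
            buried_sasa_subunit=sasa[sub.name],
            threshold=threshold,
        ))
    return InterfaceSummary(total_buried_sasa=sasa["total"],
                            footprints=results,
                            classification=classify_interface(sasa["total"]))
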