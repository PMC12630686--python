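"""Distance-based bond perception and spiro ring detection.

Heavy-atom bond graphs are inferred from inter-atomic distances, which is
sufficient for ring perception on well-refined small molecules.  The main
consumer is the spiro-dihedral analysis: find a five- and a six-membered
ring sharing exactly one atom and measure the angle between their planes.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from .errors import DegenerateGeometryError

#: Generous upper bound for a heavy-atom covalent bond (Å); C–S is ~1.81.
BOND_CUTOFF = 1.85


def bond_graph(coords: np.ndarray, cutoff: float = BOND_CUTOFF) -> nx.Graph:
    """Graph with one node per atom and edges between atoms closer than
    ``cutoff`` (excluding self pairs)."""
    pts = np.asarray(coords, dtype=float)
    g = nx.Graph()
    g.add_nodes_from(range(len(pts)))
    from scipy.spatial import cKDTree
    tree = cKDTree(pts)
    for i, j in tree.query_pairs(cutoff):
        g.add_edge(int(i), int(j))
    return g


def find_spiro_ring_pair(coords: np.ndarray,
                         ring_sizes: tuple[int, int] = (5, 6),
                         cutoff: float = BOND_CUTOFF
                         ) -> tuple[list[int], list[int]]:
    """Indices of a spiro-linked ring pair (sizes ``ring_sizes``) sharing
    exactly one atom; raises when no such pair exists."""
    g = bond_graph(coords, cutoff)
    cycles = nx.minimum_cycle_basis(g)
    small = [c for c in cycles if len(c) == ring_sizes[0]]
    large = [c for c in cycles if len(c) == ring_sizes[1]]
    for a in small:
        for b in large:
            if len(set(a) & set(b)) == 1:
                return sorted(a), sorted(b)
    raise DegenerateGeometryError(
        f"no spiro-linked {ring_sizes[0]}/{ring_sizes[1]} ring pair found "
        f"(cycle sizes present: {sorted(len(c) for c in cycles)})")
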