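"""Randomized-MST haplotype networks and per-area haplotype pies.

The network's primary topology is one canonical minimum spanning tree over
the mutational-step matrix (Kruskal with deterministic lexicographic
tie-breaking). Because ties among equal-weight edges are common at barcode
scales, MSTs are recomputed under seeded random edge orderings; edges that
appear in some minimum tree but not the canonical one are emitted with
``alternative=True``. Every emitted spanning tree attains the global
minimum weight (a matroid property of MSTs), which is asserted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distances import HaplotypeTable
from .records import Dataset
from .spatial import GridSpec, Projection, bin_to_grid, project_coordinates


@dataclass(frozen=True)
class NetworkEdge:
    hap_a: str
    hap_b: str
    steps: int
    alternative: bool


@dataclass
class HaplotypeNetwork:
    nodes: list[tuple[str, int]]           # (haplotype_id, count)
    edges: list[NetworkEdge]

    @property
    def primary_edges(self) -> list[NetworkEdge]:
        return [e for e in self.edges if not e.alternative]

    @property
    def alternative_edges(self) -> list[NetworkEdge]:
        return [e for e in self.edges if e.alternative]

    def total_weight(self) -> int:
        return sum(e.steps for e in self.primary_edges)

    def to_dict(self) -> dict:
        return {
            "nodes": [{"haplotype_id": h, "count": c} for h, c in self.nodes],
            "edges": [{"hap_a": e.hap_a, "hap_b": e.hap_b, "steps": e.steps,
                       "alternative": e.alternative} for e in self.edges],
        }


def _mst_edges(ids: list[str], steps: np.ndarray,
               order: list[tuple[int, int]]) -> set[tuple[str, str]]:
    """Kruskal MST; ties among equal weights broken by position in ``order``."""
    ranked = sorted(range(len(order)), key=lambda t: (steps[order[t]], t))
    parent = list(range(len(ids)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree: set[tuple[str, str]] = set()
    for t in ranked:
        i, j = order[t]
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri
            tree.add(tuple(sorted((ids[i], ids[j]))))
            if len(tree) == len(ids) - 1:
                break
    return tree


def build_network(table: HaplotypeTable, steps: np.ndarray,
                  n_orders: int = 50, seed: int = 0) -> HaplotypeNetwork:
    """Minimum-spanning-tree haplotype network with alternative links.

    ``steps`` is the symmetric integer mutational-step matrix over the
    table's haplotypes. The canonical tree uses lexicographic edge-id
    tie-breaking; ``n_orders`` seeded random orderings collect tie-
    equivalent alternative edges.
    """
    ids = table.ids()
    k = len(ids)
    if k == 0:
        raise ValueError("empty haplotype table")
    counts = dict(zip(ids, table.counts()))
    if k == 1:
        return HaplotypeNetwork([(ids[0], counts[ids[0]])], [])
    if n_orders < 1:
        raise ValueError("n_orders must be >= 1")

    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    # canonical: lexicographic by (id_a, id_b) within each weight class
    canonical_order = sorted(pairs, key=lambda p: (ids[p[0]], ids[p[1]]))
    canonical = _mst_edges(ids, steps, canonical_order)
    if len(canonical) != k - 1:
        raise ValueError("steps matrix is disconnected")
    weight_of = {tuple(sorted((ids[i], ids[j]))): int(steps[i, j]) for i, j in pairs}
    min_weight = sum(weight_of[e] for e in canonical)

    rng = np.random.default_rng(seed)
    alternatives: set[tuple[str, str]] = set()
    for _ in range(n_orders):
        perm = [pairs[t] for t in rng.permutation(len(pairs))]
        tree = _mst_edges(ids, steps, perm)
        assert sum(weight_of[e] for e in tree) == min_weight
        alternatives |= tree - canonical

    edges = [NetworkEdge(a, b, weight_of[(a, b)], False)
             for a, b in sorted(canonical)]
    edges += [NetworkEdge(a, b, weight_of[(a, b)], True)
              for a, b in sorted(alternatives)]
    return HaplotypeNetwork([(h, counts[h]) for h in ids], edges)


@dataclass
class AreaPie:
    cell: tuple[int, int]
    centroid_lat: float
    centroid_lon: float
    n: int
    composition: dict[str, int]                       # haplotype_id -> count
    colors: dict[str, tuple[float, float, float]] = field(default_factory=dict)


def group_by_area(dataset: Dataset, table: HaplotypeTable,
                  color_assignment: dict[str, tuple[float, float, float]],
                  area_cell_km: float = 200.0,
                  projection: Projection | None = None) -> list[AreaPie]:
    """Aggregate records into grid-cell pies for the haplotype map.

    Each pie carries the cell's member centroid, total n (pie radius is
    drawn proportional to n), and the haplotype composition with its colors
    from the shared PCoA scheme.
    """
    membership = table.membership()
    points = project_coordinates(dataset, projection)
    cells = bin_to_grid(points, GridSpec(cell_size_km=area_cell_km))
    by_cell: dict[tuple[int, int], list[int]] = {}
    for i, c in enumerate(cells):
        by_cell.setdefault((int(c[0]), int(c[1])), []).append(i)
    pies: list[AreaPie] = []
    for cell in sorted(by_cell):
        idx = by_cell[cell]
        comp: dict[str, int] = {}
        for i in idx:
            hid = membership[dataset.records[i].specimen_id]
            comp[hid] = comp.get(hid, 0) + 1
        pies.append(AreaPie(
            cell=cell,
            centroid_lat=float(np.mean([dataset.records[i].latitude for i in idx])),
            centroid_lon=float(np.mean([dataset.records[i].longitude for i in idx])),
            n=len(idx),
            composition=comp,
            colors={h: color_assignment[h] for h in comp},
        ))
    return pies
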