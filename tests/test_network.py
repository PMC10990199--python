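from __future__ import annotations

import itertools

import numpy as np
import pytest

from haploatlas.distances import Haplotype, HaplotypeTable
from haploatlas.embedding import assign_colors, pcoa_embed
from haploatlas.distances import haplotype_distance_matrix
from haploatlas.network import build_network, group_by_area

from conftest import make_dataset


def _table(ids, counts=None):
    counts = counts or [1] * len(ids)
    haps = [Haplotype(h, "A", (f"{h}-m",), c) for h, c in zip(ids, counts)]
    return HaplotypeTable(haps, sum(counts))


def brute_force_mst_weight(steps: np.ndarray) -> int:
    """Exhaustive minimum over all spanning trees (edge-subset enumeration)."""
    k = len(steps)
    edges = [(i, j) for i in range(k) for j in range(i + 1, k)]
    best = None
    for subset in itertools.combinations(edges, k - 1):
        parent = list(range(k))

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        ok = True
        for i, j in subset:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[rj] = ri
        if not ok:
            continue
        w = sum(steps[i, j] for i, j in subset)
        best = w if best is None else min(best, w)
    return best


class TestBuildNetwork:
    def test_chain_topology_no_alternatives(self):
        steps = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]])
        net = build_network(_table(["A", "B", "C"]), steps)
        primary = {(e.hap_a, e.hap_b) for e in net.primary_edges}
        assert primary == {("A", "B"), ("B", "C")}
        assert not net.alternative_edges
        assert all(e.steps == steps[ord(e.hap_a) - 65, ord(e.hap_b) - 65]
                   for e in net.edges)

    def test_tied_triangle_flags_one_alternative(self):
        steps = np.ones((3, 3), dtype=int) - np.eye(3, dtype=int)
        net = build_network(_table(["A", "B", "C"]), steps, n_orders=50, seed=1)
        assert net.total_weight() == 2
        assert len(net.primary_edges) == 2
        assert len(net.alternative_edges) == 1

    def test_two_haplotypes_single_edge(self):
        steps = np.array([[0, 3], [3, 0]])
        net = build_network(_table(["A", "B"], [4, 2]), steps)
        assert [(e.hap_a, e.hap_b, e.steps) for e in net.edges] == [("A", "B", 3)]
        assert dict(net.nodes) == {"A": 4, "B": 2}

    def test_primary_edges_form_spanning_tree(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            k = int(rng.integers(3, 8))
            steps = rng.integers(1, 9, size=(k, k))
            steps = np.triu(steps, 1) + np.triu(steps, 1).T
            net = build_network(_table([f"H{i}" for i in range(k)]), steps,
                                n_orders=10, seed=3)
            assert len(net.primary_edges) == k - 1

    def test_weight_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            k = int(rng.integers(3, 7))
            steps = rng.integers(1, 6, size=(k, k))
            steps = np.triu(steps, 1) + np.triu(steps, 1).T
            net = build_network(_table([f"H{i}" for i in range(k)]), steps,
                                n_orders=5, seed=5)
            assert net.total_weight() == brute_force_mst_weight(steps)

    def test_deterministic_under_seed(self):
        steps = np.ones((4, 4), dtype=int) - np.eye(4, dtype=int)
        t = _table(["A", "B", "C", "D"])
        n1 = build_network(t, steps, n_orders=20, seed=9)
        n2 = build_network(t, steps, n_orders=20, seed=9)
        assert n1.to_dict() == n2.to_dict()


class TestGroupByArea:
    def _setup(self):
        rows = [
            ("S1", "Sp", 45.0, -100.0, "AAAA"),
            ("S2", "Sp", 45.0, -100.0, "AAAA"),
            ("S3", "Sp", 45.0, -100.0, "AAAT"),
            ("S4", "Sp", 45.0, -80.0, "TTTT"),
            ("S5", "Sp", 45.0, -80.0, "TTTT"),
        ]
        ds = make_dataset(rows)
        from haploatlas.distances import collapse_haplotypes
        table = collapse_haplotypes(ds)
        colors = assign_colors(pcoa_embed(haplotype_distance_matrix(table)))
        return ds, table, colors

    def test_compositions_partition_records(self):
        ds, table, colors = self._setup()
        pies = group_by_area(ds, table, colors, area_cell_km=200.0)
        assert len(pies) == 2
        assert sum(p.n for p in pies) == ds.n_records
        for p in pies:
            assert sum(p.composition.values()) == p.n

    def test_disjoint_haplotypes_disjoint_colors(self):
        ds, table, colors = self._setup()
        pies = sorted(group_by_area(ds, table, colors, area_cell_km=200.0),
                      key=lambda p: p.centroid_lon)
        west, east = pies
        assert set(west.composition) != set(east.composition)
        assert not set(west.composition) & set(east.composition)
        for p in pies:
            for hid in p.composition:
                assert p.colors[hid] == colors[hid]

    def test_single_cell_when_colocated(self):
        rows = [(f"S{i}", "Sp", 45.0, -100.0, "AAAA") for i in range(5)]
        ds = make_dataset(rows)
        from haploatlas.distances import collapse_haplotypes
        table = collapse_haplotypes(ds)
        colors = {"H1": (0.5, 0.5, 0.5)}
        pies = group_by_area(ds, table, colors)
        assert len(pies) == 1 and pies[0].n == 5
        assert pies[0].centroid_lat == pytest.approx(45.0)
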