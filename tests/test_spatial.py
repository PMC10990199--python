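from __future__ import annotations

import numpy as np
import pytest

from haploatlas.distances import distance_matrix
from haploatlas.spatial import (GridSpec, Projection, bin_to_grid,
                                dataset_projection, multiscale_gst,
                                project_coordinates, raw_gst)

from conftest import make_dataset


class TestProjection:
    def test_center_maps_to_origin(self):
        p = Projection(50.0, -100.0)
        x, y = p.forward(50.0, -100.0)
        assert abs(x) < 1e-9 and abs(y) < 1e-9

    def test_one_degree_latitude_is_111km(self):
        p = Projection(50.0, -100.0)
        x, y = p.forward(51.0, -100.0)
        dist = float(np.hypot(x, y))
        assert dist == pytest.approx(111.2, rel=0.01)

    def test_roundtrip(self):
        p = Projection(45.0, -75.0)
        lats = np.array([40.0, 45.0, 52.5, 60.0])
        lons = np.array([-90.0, -75.0, -60.0, -100.0])
        x, y = p.forward(lats, lons)
        lat2, lon2 = p.inverse(x, y)
        assert np.allclose(lat2, lats, atol=1e-8)
        assert np.allclose(lon2, lons, atol=1e-8)

    def test_antipodal_point_errors(self):
        p = Projection(0.0, 0.0)
        with pytest.raises(ValueError):
            p.forward(0.0, 180.0)

    def test_dataset_projection_centered_on_centroid(self, tiny_dataset):
        proj = dataset_projection(tiny_dataset)
        pts = project_coordinates(tiny_dataset, proj)
        assert np.allclose(pts.mean(axis=0), 0.0, atol=2.0)  # km


class TestGridBinning:
    @pytest.mark.parametrize("point,cell,offset,expected", [
        ((150.0, 250.0), 100.0, 0.0, (1, 2)),
        ((150.0, 250.0), 100.0, 0.5, (1, 2)),  # floor((150-50)/100)=1
        ((-10.0, 0.0), 100.0, 0.0, (-1, 0)),
    ])
    def test_floor_arithmetic(self, point, cell, offset, expected):
        grid = GridSpec(cell_size_km=cell, offset_fraction=offset)
        assert tuple(bin_to_grid(np.array([point]), grid)[0]) == expected

    def test_invalid_offsets_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(cell_size_km=100.0, offset_fraction=0.25)


def _two_cell_dataset(n_per_hap=5, d_sites=2, L=100, monomorphic_cells=True):
    """Two locations ~1000 km apart; haplotype layout per cell configurable."""
    h1 = "A" * L
    h2 = "T" * d_sites + "A" * (L - d_sites)
    rows = []
    locs = [(45.0, -100.0), (45.0, -87.3)]  # ~1000 km apart at 45N
    k = 0
    for c, (lat, lon) in enumerate(locs):
        if monomorphic_cells:
            seqs = [h1 if c == 0 else h2] * n_per_hap
        else:
            seqs = [h1, h2] * n_per_hap
        for s in seqs:
            k += 1
            rows.append((f"S{k:02d}", "Sp", lat, lon, s))
    return make_dataset(rows)


class TestRawGst:
    def test_fixed_cells_fully_differentiated(self):
        ds = _two_cell_dataset(n_per_hap=6, monomorphic_cells=True)
        dm = distance_matrix(ds)
        pts = project_coordinates(ds)
        grid = GridSpec(200.0)
        rep = raw_gst(dm, bin_to_grid(pts, grid), grid)
        assert rep.eligible
        assert rep.H_S == pytest.approx(0.0)
        assert rep.gst_raw == pytest.approx(1.0)

    def test_monomorphic_pool_defined_as_zero(self):
        rows = [(f"S{i:02d}", "Sp", 45.0 + (i % 4) * 3, -100.0, "A" * 50)
                for i in range(20)]
        ds = make_dataset(rows)
        dm = distance_matrix(ds)
        pts = project_coordinates(ds)
        grid = GridSpec(100.0)
        rep = raw_gst(dm, bin_to_grid(pts, grid), grid)
        assert rep.eligible and rep.gst_raw == 0.0

    def test_panmictic_two_cells_negative_raw(self):
        # each cell {h1:2, h2:2}: H_S = 2d/3, H_T = 4d/7, D_ST < 0
        ds = _two_cell_dataset(n_per_hap=2, monomorphic_cells=False)
        dm = distance_matrix(ds)
        pts = project_coordinates(ds)
        grid = GridSpec(300.0)
        rep = raw_gst(dm, bin_to_grid(pts, grid), grid, min_total=7)
        d = 2 / 100
        assert rep.H_S == pytest.approx(2 * d / 3)
        assert rep.H_T == pytest.approx(4 * d / 7)
        assert rep.D_ST < 0 and rep.gst_raw < 0
        assert -1.0 <= rep.gst_raw <= 1.0

    def test_eligibility_requires_two_cells_and_pool_size(self):
        ds = _two_cell_dataset(n_per_hap=6)  # 6 + 6 pooled
        dm = distance_matrix(ds)
        pts = project_coordinates(ds)
        grid = GridSpec(200.0)
        assign = bin_to_grid(pts, grid)
        assert raw_gst(dm, assign, grid, min_total=10).eligible
        # pooled specimens must strictly exceed min_total: 12 pooled fails at 12
        rep = raw_gst(dm, assign, grid, min_total=12)
        assert not rep.eligible and rep.gst_raw is None
        # one qualifying cell is never eligible
        rep1 = raw_gst(dm, assign, grid, min_per_cell=7, min_total=5)
        assert not rep1.eligible

    def test_translation_invariance(self):
        ds = _two_cell_dataset(n_per_hap=6)
        dm = distance_matrix(ds)
        pts = project_coordinates(ds)
        grid = GridSpec(150.0)
        a = raw_gst(dm, bin_to_grid(pts, grid), grid)
        shifted = pts + np.array([3 * 150.0, -7 * 150.0])
        b = raw_gst(dm, bin_to_grid(shifted, grid), grid)
        assert b.gst_raw == pytest.approx(a.gst_raw)
        assert b.H_T == pytest.approx(a.H_T)


class TestMultiscaleGst:
    def test_eight_replicates_for_structured_species(self):
        ds = _two_cell_dataset(n_per_hap=8)
        res = multiscale_gst(ds, distance_matrix(ds))
        assert res.status == "computed"
        assert len(res.replicates) == 8
        sizes = {r.grid.cell_size_km for r in res.replicates}
        offs = {r.grid.offset_fraction for r in res.replicates}
        assert sizes == {100.0, 200.0, 300.0, 400.0} and offs == {0.0, 0.5}
        assert res.gst_mean == pytest.approx(1.0)

    def test_single_haplotype_status(self):
        rows = [(f"S{i:02d}", "Sp", 45.0 + i * 0.01, -100.0, "ACGT" * 10)
                for i in range(20)]
        res = multiscale_gst(make_dataset(rows),
                             distance_matrix(make_dataset(rows)))
        assert res.status == "single_haplotype_zero"
        assert res.gst_mean == 0.0

    def test_negative_average_clamped_to_zero(self):
        ds = _two_cell_dataset(n_per_hap=3, monomorphic_cells=False)  # 12 total
        res = multiscale_gst(ds, distance_matrix(ds))
        raws = [r.gst_raw for r in res.replicates if r.eligible]
        assert raws and all(g < 0 for g in raws)
        assert res.gst_mean == 0.0 and res.status == "computed"

    def test_ineligible_when_one_location(self):
        rows = [(f"S{i:02d}", "Sp", 45.0, -100.0,
                 ("A" if i % 2 else "T") + "A" * 49) for i in range(20)]
        ds = make_dataset(rows)
        res = multiscale_gst(ds, distance_matrix(ds))
        assert res.status == "ineligible" and res.gst_mean is None
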