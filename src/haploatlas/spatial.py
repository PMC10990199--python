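"""Spatial genetic structure: equal-area projection, grid binning, G_ST.

G_ST follows Nei's decomposition of gene diversity applied to p-distances on
a geographic grid: H_T is the mean pairwise p-distance among all sequences
pooled from the qualifying grid cells, H_S is the unweighted mean over
qualifying cells of the within-cell mean pairwise p-distance, D_ST = H_T -
H_S, and G_ST = D_ST / H_T (in [-1, 1]).

Because a single grid is arbitrary in scale and placement, the statistic is
averaged over four cell sizes (100, 200, 300, 400 km) each at two grid
placements (cell centers vs cell vertices, i.e. a half-cell shift of the
origin on both planar axes), giving 8 replicates; the mean of the defined
replicate values is retained, and a negative mean — an artefact of low
sample size — is set to 0. A cell qualifies with at least 3 specimens;
a replicate is eligible with at least two qualifying cells holding more
than 10 pooled specimens. A species collapsing to a single haplotype has no
structure by definition and gets G_ST = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distances import DistanceMatrix
from .records import Dataset

EARTH_RADIUS_KM = 6371.0088

DEFAULT_CELL_SIZES = (100.0, 200.0, 300.0, 400.0)
DEFAULT_OFFSETS = (0.0, 0.5)


class ProjectionError(ValueError):
    pass


@dataclass(frozen=True)
class Projection:
    """Lambert azimuthal equal-area projection on a spherical Earth (km)."""

    center_lat: float
    center_lon: float

    def forward(self, lat, lon) -> tuple[np.ndarray, np.ndarray]:
        lat = np.radians(np.asarray(lat, dtype=float))
        lon = np.radians(np.asarray(lon, dtype=float))
        lat0 = np.radians(self.center_lat)
        lon0 = np.radians(self.center_lon)
        cosc = np.sin(lat0) * np.sin(lat) + np.cos(lat0) * np.cos(lat) * np.cos(lon - lon0)
        if np.any(cosc <= -1.0 + 1e-12):
            raise ProjectionError("point antipodal to projection center")
        k = np.sqrt(2.0 / (1.0 + cosc))
        x = EARTH_RADIUS_KM * k * np.cos(lat) * np.sin(lon - lon0)
        y = EARTH_RADIUS_KM * k * (np.cos(lat0) * np.sin(lat)
                                   - np.sin(lat0) * np.cos(lat) * np.cos(lon - lon0))
        return x, y

    def inverse(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        x = np.asarray(x, dtype=float) / EARTH_RADIUS_KM
        y = np.asarray(y, dtype=float) / EARTH_RADIUS_KM
        lat0 = np.radians(self.center_lat)
        lon0 = np.radians(self.center_lon)
        rho = np.hypot(x, y)
        c = 2.0 * np.arcsin(np.clip(rho / 2.0, -1.0, 1.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            lat = np.where(
                rho == 0, lat0,
                np.arcsin(np.cos(c) * np.sin(lat0)
                          + np.where(rho == 0, 0.0, y * np.sin(c) * np.cos(lat0)
                                     / np.where(rho == 0, 1.0, rho))))
            lon = lon0 + np.arctan2(
                x * np.sin(c),
                rho * np.cos(lat0) * np.cos(c) - y * np.sin(lat0) * np.sin(c))
        return np.degrees(lat), np.degrees(lon)


def dataset_projection(dataset: Dataset) -> Projection:
    """Projection centered on the dataset's spherical centroid."""
    lat = np.radians([r.latitude for r in dataset.records])
    lon = np.radians([r.longitude for r in dataset.records])
    v = np.array([np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon),
                  np.sin(lat)]).mean(axis=1)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ProjectionError("degenerate centroid (points cancel out)")
    v /= norm
    return Projection(center_lat=float(np.degrees(np.arcsin(v[2]))),
                      center_lon=float(np.degrees(np.arctan2(v[1], v[0]))))


def project_coordinates(dataset: Dataset,
                        projection: Projection | None = None) -> np.ndarray:
    """Planar (x, y) in km per record under the equal-area projection."""
    if projection is None:
        projection = dataset_projection(dataset)
    x, y = projection.forward([r.latitude for r in dataset.records],
                              [r.longitude for r in dataset.records])
    return np.column_stack([x, y])


@dataclass(frozen=True)
class GridSpec:
    cell_size_km: float
    offset_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be positive")
        if self.offset_fraction not in (0.0, 0.5):
            raise ValueError("offset_fraction must be 0 or 0.5")

    @property
    def offset_km(self) -> float:
        return self.offset_fraction * self.cell_size_km


def bin_to_grid(points: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Cell index (ix, iy) per point: floor((coordinate - offset) / cell_size)."""
    pts = np.asarray(points, dtype=float)
    return np.floor((pts - grid.offset_km) / grid.cell_size_km).astype(int)


@dataclass
class GstReplicate:
    grid: GridSpec
    eligible: bool
    H_T: float | None = None
    H_S: float | None = None
    D_ST: float | None = None
    gst_raw: float | None = None
    cells_used: list[tuple[tuple[int, int], int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "cell_size_km": self.grid.cell_size_km,
            "offset_fraction": self.grid.offset_fraction,
            "eligible": self.eligible,
            "H_T": self.H_T, "H_S": self.H_S, "D_ST": self.D_ST,
            "gst_raw": self.gst_raw,
            "cells_used": [{"cell": list(c), "n": n} for c, n in self.cells_used],
        }


@dataclass
class GstResult:
    replicates: list[GstReplicate]
    gst_mean: float | None
    status: str  # computed | single_haplotype_zero | ineligible

    def to_dict(self) -> dict:
        return {"status": self.status, "gst_mean": self.gst_mean,
                "replicates": [r.to_dict() for r in self.replicates]}


def _mean_pairwise(values: np.ndarray, idx: np.ndarray) -> float:
    sub = values[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return float(sub[iu].mean())


def raw_gst(dmat: DistanceMatrix, cell_assignment: np.ndarray,
            grid: GridSpec, min_per_cell: int = 3,
            min_total: int = 10) -> GstReplicate:
    """One-grid G_ST replicate with eligibility rules.

    Cells with >= ``min_per_cell`` specimens qualify; the replicate is
    eligible iff there are >= 2 qualifying cells whose pooled specimens
    exceed ``min_total``. If the pooled sample is monomorphic (H_T = 0),
    gst_raw is defined as 0.
    """
    dmat.require_complete("G_ST")
    cells = [(int(c[0]), int(c[1])) for c in np.asarray(cell_assignment)]
    by_cell: dict[tuple[int, int], list[int]] = {}
    for i, c in enumerate(cells):
        by_cell.setdefault(c, []).append(i)
    qualifying = {c: idx for c, idx in by_cell.items() if len(idx) >= min_per_cell}
    pooled = sorted(i for idx in qualifying.values() for i in idx)
    if len(qualifying) < 2 or len(pooled) <= min_total:
        return GstReplicate(grid=grid, eligible=False,
                            cells_used=sorted((c, len(i)) for c, i in qualifying.items()))
    H_T = _mean_pairwise(dmat.values, np.array(pooled))
    H_S = float(np.mean([_mean_pairwise(dmat.values, np.array(idx))
                         for idx in qualifying.values()]))
    D_ST = H_T - H_S
    gst = 0.0 if H_T == 0.0 else D_ST / H_T
    return GstReplicate(grid=grid, eligible=True, H_T=H_T, H_S=H_S,
                        D_ST=D_ST, gst_raw=gst,
                        cells_used=sorted((c, len(i)) for c, i in qualifying.items()))


def multiscale_gst(dataset: Dataset, dmat: DistanceMatrix,
                   cell_sizes: tuple[float, ...] = DEFAULT_CELL_SIZES,
                   offsets: tuple[float, ...] = DEFAULT_OFFSETS,
                   min_per_cell: int = 3, min_total: int = 10,
                   clamp_per_replicate: bool = False,
                   projection: Projection | None = None) -> GstResult:
    """Grid-averaged G_ST over all cell sizes and grid placements.

    Returns the average of the defined replicate values, clamped at 0 from
    below. By default negative replicates contribute their raw values to the
    mean and only the mean is clamped; ``clamp_per_replicate=True`` clamps
    each replicate first.
    """
    from .distances import collapse_haplotypes

    table = collapse_haplotypes(dataset, dmat)
    if table.n_haplotypes == 1:
        return GstResult([], 0.0, "single_haplotype_zero")

    points = project_coordinates(dataset, projection)
    replicates: list[GstReplicate] = []
    for size in cell_sizes:
        for off in offsets:
            grid = GridSpec(cell_size_km=size, offset_fraction=off)
            assign = bin_to_grid(points, grid)
            replicates.append(raw_gst(dmat, assign, grid,
                                      min_per_cell=min_per_cell,
                                      min_total=min_total))
    defined = [r.gst_raw for r in replicates if r.eligible]
    if not defined:
        return GstResult(replicates, None, "ineligible")
    if clamp_per_replicate:
        defined = [max(0.0, g) for g in defined]
    gst_mean = max(0.0, float(np.mean(defined)))
    return GstResult(replicates, gst_mean, "computed")
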