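"""PCoA embedding of haplotype distances and corner-colored-square color maps.

Haplotypes are embedded by classical principal coordinates analysis (double
centering of squared distances followed by eigendecomposition). The first
two axes are overlaid on a colored square whose corners are, by default,
white, yellow, blue and black — a palette chosen with the common forms of
color blindness in mind (the informative axis runs blue-yellow). Each
haplotype's color is the bilinear blend of the corner colors at its
min-max-scaled position, so color similarity tracks genetic similarity.

Negative eigenvalues (p-distance matrices are only near-Euclidean) are
dropped without Cailliez/Lingoes correction; at barcode scales the deficit
is visible in ``variance_explained`` rather than corrected away.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .distances import DistanceMatrix

#: Corner colors of the default square: keys are (u, v) corners of [0,1]^2.
DEFAULT_CORNERS: dict[tuple[int, int], tuple[float, float, float]] = {
    (0, 0): (1.0, 1.0, 1.0),  # white
    (1, 0): (1.0, 0.9, 0.0),  # yellow
    (0, 1): (0.0, 0.35, 1.0),  # blue
    (1, 1): (0.0, 0.0, 0.0),  # black
}


@dataclass
class Embedding:
    haplotype_ids: list[str]
    coords: np.ndarray            # (n, 2), first two PCoA axes
    eigenvalues: np.ndarray       # full spectrum, descending
    variance_explained: float     # fraction for axes 1-2 among positive axes
    full_coords: np.ndarray       # (n, rank) positive-eigenvalue axes


def pcoa_embed(dmat: DistanceMatrix) -> Embedding:
    """Classical PCoA of a haplotype p-distance matrix.

    One haplotype embeds at the origin; two haplotypes at distance d embed
    at +-d/2 on axis 1. Axes are ordered by descending eigenvalue and
    negative-eigenvalue axes are dropped.
    """
    dmat.require_complete("PCoA")
    n = dmat.n
    if n == 1:
        return Embedding(list(dmat.ids), np.zeros((1, 2)), np.zeros(0), 1.0,
                         np.zeros((1, 0)))
    D2 = np.asarray(dmat.values, dtype=float) ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = scipy.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-12, 1e-10 * abs(eigval[0])) if eigval.size else 0.0
    pos = eigval > tol
    full = eigvec[:, pos] * np.sqrt(eigval[pos])
    coords = np.zeros((n, 2))
    coords[:, :min(2, full.shape[1])] = full[:, :2]
    pos_sum = float(eigval[pos].sum())
    var12 = float(eigval[pos][:2].sum()) / pos_sum if pos_sum > 0 else 1.0
    return Embedding(list(dmat.ids), coords, eigval, var12, full)


def assign_colors(
    embedding: Embedding,
    corner_map: dict[tuple[int, int], tuple[float, float, float]] | None = None,
) -> dict[str, tuple[float, float, float]]:
    """Color each haplotype by bilinear interpolation over the corner square.

    Axes are min-max scaled independently to [0, 1]; a degenerate axis
    (zero range) is pinned to 0.5. Identical coordinates get identical
    colors.
    """
    corners = DEFAULT_CORNERS if corner_map is None else corner_map
    xy = embedding.coords
    scaled = np.empty_like(xy)
    for ax in range(2):
        lo, hi = xy[:, ax].min(), xy[:, ax].max()
        scaled[:, ax] = 0.5 if hi == lo else (xy[:, ax] - lo) / (hi - lo)
    c00 = np.array(corners[(0, 0)])
    c10 = np.array(corners[(1, 0)])
    c01 = np.array(corners[(0, 1)])
    c11 = np.array(corners[(1, 1)])
    out: dict[str, tuple[float, float, float]] = {}
    for hid, (u, v) in zip(embedding.haplotype_ids, scaled):
        rgb = ((1 - u) * (1 - v) * c00 + u * (1 - v) * c10
               + (1 - u) * v * c01 + u * v * c11)
        out[hid] = tuple(float(np.clip(x, 0.0, 1.0)) for x in rgb)
    return out
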