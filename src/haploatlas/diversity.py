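"""Per-species diversity indices and cross-species barcode-sharing detection.

Nucleotide diversity (pi) is the mean pairwise p-distance over specimens
(not unique haplotypes). Nei's haplotype diversity carries the N/(N-1)
small-sample correction: h = N/(N-1) * (1 - sum p_i^2). The nearest-neighbor
distance (NND) is the minimum p-distance from any focal specimen to any
heterospecific specimen; NND = 0 flags barcode sharing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distances import (DistanceError, DistanceMatrix, encode_sequences)
from .records import Dataset


@dataclass
class DiversitySummary:
    N: int
    H: int
    pi: float | None
    h: float | None
    max_intra: float | None
    nnd: float | None = None
    nn_species: str | None = None

    @property
    def shares_barcode(self) -> bool:
        return self.nnd == 0.0


def nucleotide_diversity(dmat: DistanceMatrix) -> float:
    """Mean of the N(N-1)/2 pairwise p-distances over specimens."""
    dmat.require_complete("nucleotide diversity")
    return dmat.mean_offdiag()


def max_intraspecific(dmat: DistanceMatrix) -> float:
    dmat.require_complete("maximum intraspecific distance")
    iu = np.triu_indices(dmat.n, k=1)
    return float(dmat.values[iu].max())


def haplotype_diversity(haplotype_counts: list[int], N: int | None = None) -> float:
    """Nei haplotype diversity h = N/(N-1) * (1 - sum p_i^2), clipped to [0, 1]."""
    counts = np.asarray(haplotype_counts, dtype=float)
    total = float(counts.sum()) if N is None else float(N)
    if N is not None and counts.sum() != N:
        raise ValueError("haplotype counts must sum to N")
    if total < 2:
        raise ValueError("h undefined for N < 2")
    p = counts / total
    h = total / (total - 1.0) * (1.0 - float(np.sum(p * p)))
    return float(np.clip(h, 0.0, 1.0))


def _cross_species_min(focal: Dataset, other: Dataset) -> float | None:
    """Minimum p-distance between any focal and any other-species specimen."""
    a = encode_sequences(focal.sequences())
    b = encode_sequences(other.sequences())
    best: float | None = None
    for i in range(a.shape[0]):
        valid = (a[i] != 255) & (b != 255)
        c = valid.sum(axis=1)
        d = ((a[i] != b) & valid).sum(axis=1)
        ok = c > 0
        if not ok.any():
            continue
        m = float((d[ok] / c[ok]).min())
        if best is None or m < best:
            best = m
        if best == 0.0:
            break
    return best


def nearest_neighbor(
    species_dataset: Dataset,
    other_species_datasets: dict[str, Dataset],
) -> tuple[float, str]:
    """Minimum p-distance from the focal species to any heterospecific specimen.

    Ties between species are broken alphabetically by species name. Raises
    :class:`DistanceError` if no cross-species pair is comparable.
    """
    if not other_species_datasets:
        raise ValueError("at least one other species required")
    best_d: float | None = None
    best_sp: str | None = None
    for sp in sorted(other_species_datasets):
        m = _cross_species_min(species_dataset, other_species_datasets[sp])
        if m is None:
            continue
        if best_d is None or m < best_d:
            best_d, best_sp = m, sp
    if best_d is None:
        raise DistanceError("no comparable cross-species pairs")
    return best_d, best_sp


def detect_barcode_sharing(
    all_species_datasets: dict[str, Dataset],
) -> list[tuple[str, str, int]]:
    """Species pairs sharing at least one identical barcode (zero p-distance).

    For each unordered pair the count is the number of haplotype pairs (one
    from each species) at zero p-distance under pairwise deletion, matching
    the haplotype-collapsing convention.
    """
    from .distances import collapse_haplotypes

    if len(all_species_datasets) < 2:
        raise ValueError("need at least 2 species")
    tables = {sp: collapse_haplotypes(ds) for sp, ds in all_species_datasets.items()}
    species = sorted(tables)
    out: list[tuple[str, str, int]] = []
    for i, sa in enumerate(species):
        for sb in species[i + 1:]:
            ra = encode_sequences(tables[sa].representatives())
            rb = encode_sequences(tables[sb].representatives())
            shared = 0
            for x in range(ra.shape[0]):
                valid = (ra[x] != 255) & (rb != 255)
                c = valid.sum(axis=1)
                d = ((ra[x] != rb) & valid).sum(axis=1)
                shared += int(np.sum((c > 0) & (d == 0)))
            if shared:
                out.append((sa, sb, shared))
    return out


def percent_coverage(n_covered: int, n_total: int) -> float:
    """Barcode coverage of a fauna as a percentage, rounded to whole percent."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * n_covered / n_total)
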