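"""Pairwise p-distances with pairwise deletion, and haplotype collapsing.

The p-distance between two aligned sequences is the proportion of differing
sites among the sites that are jointly unambiguous — any site carrying a
non-A/C/G/T symbol (IUPAC ambiguity code, 'N' or a gap) in either sequence
is deleted for that pair ("pairwise deletion"). Specimens are collapsed
into haplotypes by the transitive closure of the zero-p-distance relation:
a short, partially ambiguous sequence can therefore bridge two otherwise
distinct haplotypes; such bridge merges are counted and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .records import Dataset, normalize_sequence

logger = logging.getLogger(__name__)

_CODE = np.full(128, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i


class DistanceError(ValueError):
    """Raised when a pairwise distance is undefined (no jointly unambiguous sites)."""


def encode_sequences(sequences: list[str]) -> np.ndarray:
    """Encode sequences as a (n, L) uint8 array; 255 marks ambiguous/missing."""
    arr = np.frombuffer(
        "".join(normalize_sequence(s) for s in sequences).encode("ascii"),
        dtype=np.uint8,
    ).reshape(len(sequences), -1)
    return _CODE[arr]


def p_distance(seq_a: str, seq_b: str) -> tuple[float, int, int]:
    """p-distance with pairwise deletion.

    Returns ``(distance, compared_sites, diff_count)`` where sites ambiguous
    in either sequence are excluded. Raises :class:`DistanceError` if no
    site is jointly unambiguous.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal aligned length")
    enc = encode_sequences([seq_a, seq_b])
    a, b = enc[0], enc[1]
    valid = (a != 255) & (b != 255)
    compared = int(valid.sum())
    if compared == 0:
        raise DistanceError("no jointly unambiguous sites")
    diffs = int(((a != b) & valid).sum())
    return diffs / compared, compared, diffs


@dataclass
class DistanceMatrix:
    """Symmetric matrix of p-distances with per-pair compared-site counts."""

    ids: list[str]
    values: np.ndarray          # (n, n) float, p-distances in [0, 1]
    compared_sites: np.ndarray  # (n, n) int, jointly unambiguous sites per pair
    incomplete_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def complete(self) -> bool:
        return not self.incomplete_pairs

    def require_complete(self, context: str = "downstream analysis") -> None:
        if not self.complete:
            raise DistanceError(
                f"distance matrix incomplete (pairs with no comparable sites: "
                f"{self.incomplete_pairs[:5]}...); {context} blocked"
            )

    def submatrix(self, indices: np.ndarray) -> "DistanceMatrix":
        idx = np.asarray(indices)
        return DistanceMatrix(
            ids=[self.ids[i] for i in idx],
            values=self.values[np.ix_(idx, idx)],
            compared_sites=self.compared_sites[np.ix_(idx, idx)],
            incomplete_pairs=[
                (a, b) for a, b in self.incomplete_pairs
                if a in set(self.ids[i] for i in idx)
                and b in set(self.ids[i] for i in idx)
            ],
        )

    def mean_offdiag(self) -> float:
        """Mean of the n(n-1)/2 pairwise distances."""
        n = self.n
        if n < 2:
            raise DistanceError("need at least 2 sequences")
        iu = np.triu_indices(n, k=1)
        return float(self.values[iu].mean())


def distance_matrix(dataset: Dataset) -> DistanceMatrix:
    """Full pairwise p-distance matrix over a dataset's specimens.

    Pairs sharing no unambiguous site get distance NaN, are recorded in
    ``incomplete_pairs``, and block PCoA / G_ST downstream via
    :meth:`DistanceMatrix.require_complete`.
    """
    if dataset.n_records < 2:
        raise ValueError("need at least 2 records for a distance matrix")
    return matrix_from_sequences(dataset.sequences(), dataset.ids())


def matrix_from_sequences(sequences: list[str], ids: list[str]) -> DistanceMatrix:
    enc = encode_sequences(sequences)
    n = enc.shape[0]
    valid = enc != 255
    values = np.zeros((n, n), dtype=float)
    compared = np.zeros((n, n), dtype=np.int64)
    incomplete: list[tuple[str, str]] = []
    for i in range(n):
        v = valid[i] & valid[i + 1:]
        c = v.sum(axis=1)
        d = ((enc[i] != enc[i + 1:]) & v).sum(axis=1)
        compared[i, i + 1:] = compared[i + 1:, i] = c
        with np.errstate(invalid="ignore"):
            row = np.where(c > 0, d / np.maximum(c, 1), np.nan)
        values[i, i + 1:] = values[i + 1:, i] = row
        for j in np.nonzero(c == 0)[0]:
            incomplete.append((ids[i], ids[i + 1 + j]))
    if incomplete:
        logger.warning("%d specimen pairs share no unambiguous sites", len(incomplete))
    return DistanceMatrix(list(ids), values, compared, incomplete)


@dataclass(frozen=True)
class Haplotype:
    haplotype_id: str
    representative_sequence: str
    member_specimen_ids: tuple[str, ...]
    count: int


@dataclass
class HaplotypeTable:
    """Unique haplotypes with member specimens; counts sum to ``total_n``."""

    haplotypes: list[Haplotype]
    total_n: int

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def counts(self) -> list[int]:
        return [h.count for h in self.haplotypes]

    def representatives(self) -> list[str]:
        return [h.representative_sequence for h in self.haplotypes]

    def ids(self) -> list[str]:
        return [h.haplotype_id for h in self.haplotypes]

    def membership(self) -> dict[str, str]:
        """Map specimen_id -> haplotype_id."""
        return {m: h.haplotype_id for h in self.haplotypes
                for m in h.member_specimen_ids}

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(
            [{"haplotype_id": h.haplotype_id, "count": h.count,
              "member_ids": ",".join(h.member_specimen_ids),
              "representative": h.representative_sequence}
             for h in self.haplotypes]
        )


def collapse_haplotypes(dataset: Dataset,
                        dmat: DistanceMatrix | None = None) -> HaplotypeTable:
    """Group specimens into haplotypes by zero-p-distance connectivity.

    Uses the transitive closure of the d = 0 relation (union-find), so the
    grouping is deterministic and order-independent. The representative of
    each haplotype is the member with the most unambiguous sites, ties
    broken by lexicographic specimen id. Merges that rely on a bridging
    low-information sequence (members at d > 0 within one group) are logged.
    """
    if dmat is None:
        dmat = distance_matrix(dataset) if dataset.n_records >= 2 else None
    if dataset.n_records == 0:
        return HaplotypeTable([], 0)
    if dataset.n_records == 1:
        r = dataset.records[0]
        return HaplotypeTable(
            [Haplotype("H1", r.sequence, (r.specimen_id,), 1)], 1)
    dmat.require_complete("haplotype collapsing")

    n = dmat.n
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    zero = dmat.values == 0.0
    for i in range(n):
        for j in np.nonzero(zero[i, i + 1:])[0] + i + 1:
            ri, rj = find(i), find(int(j))
            if ri != rj:
                parent[rj] = ri

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    n_bridged = sum(
        1 for members in groups.values()
        if len(members) > 1
        and np.any(dmat.values[np.ix_(members, members)] > 0)
    )
    if n_bridged:
        logger.info("%d haplotype group(s) merged via low-information bridges",
                    n_bridged)

    recs = dataset.records
    raw = []
    for members in groups.values():
        rep = min(members,
                  key=lambda i: (-recs[i].n_unambiguous, recs[i].specimen_id))
        member_ids = tuple(sorted(recs[i].specimen_id for i in members))
        raw.append((recs[rep].sequence, member_ids))
    # stable haplotype ids: descending count, then first member id
    raw.sort(key=lambda t: (-len(t[1]), t[1][0]))
    haps = [Haplotype(f"H{k + 1}", seq, member_ids, len(member_ids))
            for k, (seq, member_ids) in enumerate(raw)]
    return HaplotypeTable(haps, dataset.n_records)


def mutational_steps(hap_a: str, hap_b: str) -> int:
    """Differing jointly unambiguous sites between two haplotype representatives."""
    _, _, diffs = p_distance(hap_a, hap_b)
    return diffs


def steps_matrix(table: HaplotypeTable) -> np.ndarray:
    """Integer mutational-step matrix over haplotype representatives."""
    reps = table.representatives()
    k = len(reps)
    steps = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            steps[i, j] = steps[j, i] = mutational_steps(reps[i], reps[j])
    return steps


def haplotype_distance_matrix(table: HaplotypeTable) -> DistanceMatrix:
    """p-distance matrix over haplotype representatives."""
    return matrix_from_sequences(table.representatives(), table.ids())
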