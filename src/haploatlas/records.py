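"""Reading, validating and filtering georeferenced barcode records.

A specimen record ties one aligned COI barcode sequence to a species label
and a geographic point. Sequences are expected pre-aligned (the COI barcode
is length-conserved in butterflies); unequal lengths are an input error, not
something this module repairs.

Metadata is tab-separated with a header row containing at least
``specimen_id``, ``species``, ``lat``, ``lon`` and optionally ``country``
(the dialect of BOLD-style TSV exports, without binding to them).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Unambiguous nucleotide symbols. Everything else (IUPAC ambiguity codes,
#: 'N', gaps) counts as ambiguous/missing for filtering and pairwise deletion.
UNAMBIGUOUS = frozenset("ACGT")

METADATA_COLUMNS = ("specimen_id", "species", "lat", "lon")


class RecordsError(ValueError):
    """Raised for unrecoverable input problems (duplicate ids, ragged alignment)."""


@dataclass(frozen=True)
class SpecimenRecord:
    """One barcode sequence tied to a species and a geographic point."""

    specimen_id: str
    species: str
    latitude: float
    longitude: float
    sequence: str
    country: str | None = None

    @property
    def n_unambiguous(self) -> int:
        """Number of A/C/G/T sites (case-insensitive, 'U' read as 'T')."""
        return sum(1 for c in normalize_sequence(self.sequence) if c in UNAMBIGUOUS)

    @property
    def georeferenced(self) -> bool:
        return -90.0 <= self.latitude <= 90.0 and -180.0 <= self.longitude <= 180.0


@dataclass
class Dataset:
    """A collection of specimen records sharing one alignment length."""

    records: list[SpecimenRecord]
    alignment_length: int
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.specimen_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise RecordsError(f"duplicate specimen ids: {dupes}")
        bad = [r.specimen_id for r in self.records
               if len(r.sequence) != self.alignment_length]
        if bad:
            raise RecordsError(
                f"sequences not matching alignment length {self.alignment_length}: {bad}"
            )

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def species_names(self) -> list[str]:
        return sorted({r.species for r in self.records})

    def species_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.species] = counts.get(r.species, 0) + 1
        return counts

    def subset(self, species: str) -> "Dataset":
        recs = [r for r in self.records if r.species == species]
        return Dataset(recs, self.alignment_length,
                       provenance=f"{self.provenance} [species={species}]")

    def partition_by_species(self) -> dict[str, "Dataset"]:
        return {sp: self.subset(sp) for sp in self.species_names}

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def ids(self) -> list[str]:
        return [r.specimen_id for r in self.records]


def normalize_sequence(seq: str) -> str:
    """Upper-case and map RNA 'U' to 'T'."""
    return seq.upper().replace("U", "T")


def read_records(
    fasta_source: str | Path,
    metadata_source: str | Path,
) -> tuple[Dataset, pd.DataFrame]:
    """Join FASTA sequences with TSV metadata into a :class:`Dataset`.

    Records present in only one source are reported in the returned report
    frame (columns ``specimen_id``, ``problem``), never silently dropped.
    Rows with malformed or out-of-range coordinates are excluded with a
    reason. Duplicate ids in either source and ragged alignment lengths
    raise :class:`RecordsError`.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_source), "fasta"):
        if rec.id in seqs:
            raise RecordsError(f"duplicate FASTA id: {rec.id}")
        seqs[rec.id] = normalize_sequence(str(rec.seq))

    meta = pd.read_csv(metadata_source, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise RecordsError(f"metadata missing required columns: {missing}")
    if meta["specimen_id"].duplicated().any():
        dupes = sorted(meta.loc[meta["specimen_id"].duplicated(), "specimen_id"])
        raise RecordsError(f"duplicate metadata ids: {dupes}")

    problems: list[dict[str, str]] = []
    meta_ids = set(meta["specimen_id"])
    for sid in sorted(set(seqs) - meta_ids):
        problems.append({"specimen_id": sid, "problem": "unmatched sequence"})
    for sid in sorted(meta_ids - set(seqs)):
        problems.append({"specimen_id": sid, "problem": "unmatched metadata"})

    records: list[SpecimenRecord] = []
    for row in meta.itertuples(index=False):
        sid = row.specimen_id
        if sid not in seqs:
            continue
        try:
            lat, lon = float(row.lat), float(row.lon)
        except (TypeError, ValueError):
            problems.append({"specimen_id": sid, "problem": "malformed coordinates"})
            continue
        if not -90.0 <= lat <= 90.0:
            problems.append({"specimen_id": sid, "problem": "latitude out of range"})
            continue
        if not -180.0 <= lon <= 180.0:
            problems.append({"specimen_id": sid, "problem": "longitude out of range"})
            continue
        country = getattr(row, "country", None)
        records.append(SpecimenRecord(
            specimen_id=sid, species=row.species, latitude=lat, longitude=lon,
            sequence=seqs[sid], country=None if pd.isna(country) else country,
        ))

    lengths = {len(r.sequence) for r in records}
    if len(lengths) > 1:
        by_len: dict[int, list[str]] = {}
        for r in records:
            by_len.setdefault(len(r.sequence), []).append(r.specimen_id)
        common = max(by_len, key=lambda k: len(by_len[k]))
        offenders = sorted(i for k, v in by_len.items() if k != common for i in v)
        raise RecordsError(f"ragged alignment lengths; offending ids: {offenders}")

    aln_len = lengths.pop() if lengths else 0
    report = pd.DataFrame(problems, columns=["specimen_id", "problem"])
    ds = Dataset(records, aln_len,
                 provenance=f"fasta={fasta_source} meta={metadata_source}")
    return ds, report


def filter_records(
    dataset: Dataset,
    min_unambiguous: int = 500,
) -> tuple[Dataset, pd.DataFrame]:
    """Keep records with >= ``min_unambiguous`` A/C/G/T sites and valid coordinates.

    Returns the filtered dataset and a rejection report with each removed
    record's unambiguous-site count and reason. Idempotent: filtering a
    filtered dataset changes nothing.
    """
    if min_unambiguous < 1:
        raise ValueError("min_unambiguous must be >= 1")
    kept: list[SpecimenRecord] = []
    rejected: list[dict] = []
    for r in dataset.records:
        n_ok = r.n_unambiguous
        if not r.georeferenced:
            rejected.append({"specimen_id": r.specimen_id,
                             "unambiguous_sites": n_ok,
                             "reason": "not georeferenced"})
        elif n_ok < min_unambiguous:
            rejected.append({"specimen_id": r.specimen_id,
                             "unambiguous_sites": n_ok,
                             "reason": f"fewer than {min_unambiguous} unambiguous sites"})
        else:
            kept.append(r)
    if not kept:
        logger.warning("no records left after filtering (of %d)", dataset.n_records)
    report = pd.DataFrame(rejected,
                          columns=["specimen_id", "unambiguous_sites", "reason"])
    out = Dataset(kept, dataset.alignment_length if kept else 0,
                  provenance=f"{dataset.provenance} [min_unambiguous={min_unambiguous}]")
    return out, report


def write_dataset(dataset: Dataset, fasta_path: str | Path,
                  meta_path: str | Path) -> None:
    """Write the FASTA + metadata TSV dialect that :func:`read_records` reads."""
    with open(fasta_path, "w") as fh:
        for r in dataset.records:
            fh.write(f">{r.specimen_id}\n{r.sequence}\n")
    rows = [{"specimen_id": r.specimen_id, "species": r.species,
             "lat": f"{r.latitude:.6f}", "lon": f"{r.longitude:.6f}",
             "country": r.country or ""} for r in dataset.records]
    pd.DataFrame(rows, columns=["specimen_id", "species", "lat", "lon", "country"]) \
        .to_csv(meta_path, sep="\t", index=False)
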