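from __future__ import annotations

import pytest

from haploatlas.records import Dataset, SpecimenRecord


def make_dataset(rows, provenance="test") -> Dataset:
    """rows: (specimen_id, species, lat, lon, sequence)."""
    recs = [SpecimenRecord(specimen_id=r[0], species=r[1], latitude=r[2],
                           longitude=r[3], sequence=r[4]) for r in rows]
    return Dataset(recs, len(rows[0][4]) if rows else 0, provenance=provenance)


@pytest.fixture
def tiny_dataset() -> Dataset:
    return make_dataset([
        ("S1", "Species a", 45.0, -75.0, "AAAA"),
        ("S2", "Species a", 45.1, -75.1, "AAAT"),
        ("S3", "Species a", 45.2, -75.2, "AATT"),
    ])


@pytest.fixture
def fasta_meta(tmp_path):
    """Minimal matching FASTA + metadata TSV on disk."""
    fasta = tmp_path / "seqs.fasta"
    meta = tmp_path / "meta.tsv"
    fasta.write_text(">S1\nACGTACGT\n>S2\nACGTACGA\n>S3\nACGTTCGT\n")
    meta.write_text(
        "specimen_id\tspecies\tlat\tlon\tcountry\n"
        "S1\tSpecies a\t45.0\t-75.0\tCanada\n"
        "S2\tSpecies a\t46.0\t-76.0\tCanada\n"
        "S3\tSpecies b\t47.0\t-77.0\tUSA\n")
    return fasta, meta
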