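"""Dataset I/O and sequence quality control.

Reads aligned CO1 barcode FASTA plus a tab-separated specimen metadata table
into :class:`SpecimenRecord` objects on a common coordinate frame (default
658 positions, 1-based inclusive), and applies the two standard library-audit
quality filters: a minimum count of unambiguous base pairs, and a stop-codon
screen that flags probable NUMTs (nuclear mitochondrial pseudogene copies,
typically betrayed by in-frame stop codons under the invertebrate
mitochondrial code).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

from barcode_audit.errors import ConfigurationError, DataError

log = logging.getLogger(__name__)

FRAME_LENGTH = 658

#: Valid region labels for the Last-Glacial-Maximum partition.
REGIONS = ("north_alpine", "mid_latitude", "south", "unknown")

IUPAC_NUCLEOTIDES = frozenset("ACGTRYSWKMBDHVN")
_VALID_CHARS = IUPAC_NUCLEOTIDES | {"-"}
_UNAMBIGUOUS = frozenset("ACGT")

#: Invertebrate mitochondrial genetic code (NCBI translation table 5).
INVERTEBRATE_MITO_TABLE = 5

_REQUIRED_COLUMNS = ("specimen_id", "species", "genus", "family", "region")


@dataclass
class SpecimenRecord:
    """One barcode sequence with its taxonomic and geographic labels."""

    specimen_id: str
    species: str
    genus: str
    family: str
    region: str = "unknown"
    country: str | None = None
    latitude: float | None = None
    longitude: float | None = None
    sequence: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.region not in REGIONS:
            raise DataError(
                f"specimen {self.specimen_id!r}: region {self.region!r} "
                f"not one of {REGIONS}"
            )
        bad = set(self.sequence) - _VALID_CHARS
        if bad:
            raise DataError(
                f"specimen {self.specimen_id!r}: illegal sequence "
                f"characters {sorted(bad)}"
            )

    @property
    def n_unambiguous(self) -> int:
        return count_unambiguous(self.sequence)


@dataclass
class QCReport:
    """Outcome of :func:`qc_filter`: kept ids, removed ids with reasons."""

    kept: list[str]
    removed: list[tuple[str, str]]  # (specimen_id, reason)
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts:
            self.counts = {}
            for _, reason in self.removed:
                self.counts[reason] = self.counts.get(reason, 0) + 1

    def to_frame(self) -> pd.DataFrame:
        rows = [{"specimen_id": s, "status": "kept", "reason": ""} for s in self.kept]
        rows += [
            {"specimen_id": s, "status": "removed", "reason": r}
            for s, r in self.removed
        ]
        return pd.DataFrame(rows, columns=["specimen_id", "status", "reason"])

    def summary(self) -> dict:
        return {
            "n_input": len(self.kept) + len(self.removed),
            "n_kept": len(self.kept),
            "n_removed": len(self.removed),
            "removed_by_reason": dict(self.counts),
        }


def count_unambiguous(sequence: str) -> int:
    """Number of positions that are exactly A, C, G or T.

    Ambiguity codes (N, R, Y, ...) and gaps do not count; this is the
    "unambiguous base pairs" statistic behind the minimum-length filter.
    """
    seq = sequence.upper()
    bad = set(seq) - _VALID_CHARS
    if bad:
        raise DataError(f"illegal sequence characters {sorted(bad)}")
    return sum(1 for c in seq if c in _UNAMBIGUOUS)


def _stop_codons(table_id: int = INVERTEBRATE_MITO_TABLE) -> frozenset[str]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    return frozenset(table.stop_codons)


def stop_codon_screen(
    sequence: str, table_id: int = INVERTEBRATE_MITO_TABLE
) -> tuple[int, int]:
    """Translate in all three frames; return (best_frame, stop_count).

    Gap characters are removed before framing.  Codons containing any
    ambiguous character are untranslatable and skipped — they never count as
    stops.  The best frame is the one with the fewest stop codons; ties go to
    the lowest frame index (1-based).
    """
    stops = _stop_codons(table_id)
    ungapped = sequence.upper().replace("-", "")
    if count_unambiguous(ungapped) == 0:
        raise DataError("sequence has no unambiguous bases; cannot screen frames")
    best_frame, best_count = 1, None
    for frame in (1, 2, 3):
        sub = ungapped[frame - 1 :]
        count = 0
        for i in range(0, len(sub) - 2, 3):
            codon = sub[i : i + 3]
            if all(c in _UNAMBIGUOUS for c in codon) and codon in stops:
                count += 1
        if best_count is None or count < best_count:
            best_frame, best_count = frame, count
    return best_frame, int(best_count)


def qc_filter(
    records: Sequence[SpecimenRecord], min_unambiguous: int = 500
) -> QCReport:
    """Apply the length filter, then the stop-codon (NUMT) screen.

    Records with fewer than ``min_unambiguous`` A/C/G/T positions are removed
    first (reason ``too_short``); of the remainder, records with at least one
    stop codon in their best reading frame are removed (reason
    ``stop_codon``).  Records whose sequence cannot be screened at all are
    removed with reason ``bad_characters``.
    """
    kept: list[str] = []
    removed: list[tuple[str, str]] = []
    for rec in records:
        try:
            n_ok = count_unambiguous(rec.sequence)
        except DataError:
            removed.append((rec.specimen_id, "bad_characters"))
            continue
        if n_ok < min_unambiguous:
            removed.append((rec.specimen_id, "too_short"))
            continue
        _, n_stops = stop_codon_screen(rec.sequence)
        if n_stops > 0:
            removed.append((rec.specimen_id, "stop_codon"))
        else:
            kept.append(rec.specimen_id)
    return QCReport(kept=kept, removed=removed)


def _as_optional_float(value) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return float(value)


def read_dataset(
    fasta_path: str | Path,
    metadata_path: str | Path,
    frame_length: int = FRAME_LENGTH,
    column_map: Mapping[str, str] | None = None,
) -> list[SpecimenRecord]:
    """Read a FASTA + TSV metadata pair into SpecimenRecords.

    Every FASTA id must appear in the metadata table.  Sequences shorter than
    the frame are padded with ``'-'`` according to the metadata ``offset``
    column (1-based position of the sequence's first base on the frame;
    default 1).  Metadata rows without a sequence are skipped with a warning.

    ``column_map`` maps the required logical names (``specimen_id``,
    ``species``, ``genus``, ``family``, ``region``, and optionally
    ``country``, ``latitude``, ``longitude``, ``offset``) to the actual
    column headers, accommodating BOLD-style exports.
    """
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if column_map:
        meta = meta.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in _REQUIRED_COLUMNS if c not in meta.columns]
    if missing:
        raise ConfigurationError(f"metadata is missing required columns: {missing}")
    if meta["specimen_id"].duplicated().any():
        dups = meta.loc[meta["specimen_id"].duplicated(), "specimen_id"].tolist()
        raise DataError(f"duplicate specimen ids in metadata: {dups}")
    meta = meta.set_index("specimen_id", drop=False)

    records: list[SpecimenRecord] = []
    seen: set[str] = set()
    for fasta_rec in SeqIO.parse(str(fasta_path), "fasta"):
        sid = fasta_rec.id
        if sid in seen:
            raise DataError(f"duplicate specimen id in FASTA: {sid!r}")
        seen.add(sid)
        if sid not in meta.index:
            raise DataError(f"FASTA record {sid!r} absent from metadata table")
        row = meta.loc[sid]
        seq = str(fasta_rec.seq).upper()
        offset = int(row["offset"]) if "offset" in meta.columns and not pd.isna(row.get("offset")) else 1
        if offset < 1:
            raise DataError(f"specimen {sid!r}: offset must be >= 1, got {offset}")
        if offset - 1 + len(seq) > frame_length:
            raise DataError(
                f"specimen {sid!r}: sequence of length {len(seq)} at offset "
                f"{offset} exceeds the {frame_length}-position frame"
            )
        padded = "-" * (offset - 1) + seq
        padded += "-" * (frame_length - len(padded))
        records.append(
            SpecimenRecord(
                specimen_id=sid,
                species=str(row["species"]),
                genus=str(row["genus"]),
                family=str(row["family"]),
                region=str(row["region"]),
                country=None if pd.isna(row.get("country")) else str(row.get("country")),
                latitude=_as_optional_float(row.get("latitude")),
                longitude=_as_optional_float(row.get("longitude")),
                sequence=padded,
            )
        )
    skipped = set(meta.index) - seen
    if skipped:
        log.warning(
            "%d metadata rows have no sequence and were skipped: %s",
            len(skipped), sorted(skipped)[:10],
        )
    return records


def write_dataset(
    records: Iterable[SpecimenRecord],
    fasta_path: str | Path,
    metadata_path: str | Path,
) -> None:
    """Write records back out as FASTA + TSV (full-frame sequences, offset 1)."""
    records = list(records)
    with open(fasta_path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.specimen_id}\n{rec.sequence}\n")
    rows = [
        {
            "specimen_id": r.specimen_id,
            "species": r.species,
            "genus": r.genus,
            "family": r.family,
            "region": r.region,
            "country": r.country if r.country is not None else "",
            "latitude": "" if r.latitude is None else repr(r.latitude),
            "longitude": "" if r.longitude is None else repr(r.longitude),
            "offset": 1,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(metadata_path, sep="\t", index=False)


def write_qc_report(report: QCReport, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
    report.to_frame().to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(report.summary(), fh, indent=2, sort_keys=True)
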