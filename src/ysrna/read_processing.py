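"""FASTQ/FASTA ingestion and HD-adapter trimming.

Trimming follows the exact-match recipe used for HD small-RNA libraries:
reads containing unassigned nucleotides (N) are excluded; the leftmost perfect
occurrence of the first 8 nt of the 3' adapter (TGGAATTC, i.e. UGGAAUUC after
DNA->RNA conversion) and everything after it is removed; then the 4 random HD
nucleotides are stripped positionally from each end of the remainder.  Reads
with no adapter hit, or whose remainder is too short to contain both HD
4-mers plus a minimal insert, are rejected.  Quality values are never used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from Bio import SeqIO

__all__ = [
    "TrimmedRead",
    "ReadFormatError",
    "DEFAULT_ADAPTER_PREFIX",
    "read_records",
    "trim_read",
    "process_reads",
    "process_file",
    "write_trimmed_fasta",
    "write_trim_report",
]

DEFAULT_ADAPTER_PREFIX = "UGGAAUUC"  # first 8 nt of the 3' adapter
STATUS_ACCEPTED = "accepted"
STATUS_REJECTED_N = "rejected_N"
STATUS_NO_ADAPTER = "rejected_no_adapter"
STATUS_SHORT = "rejected_short"


class ReadFormatError(ValueError):
    """Truncated or malformed FASTQ/FASTA record."""


@dataclass(frozen=True)
class TrimmedRead:
    read_id: str
    insert: str  # RNA alphabet; empty unless accepted
    raw_length: int
    status: str


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def read_records(path: str) -> Iterator[tuple[str, str]]:
    """Stream (id, RNA-alphabet sequence) from FASTQ or FASTA.

    The format is auto-detected from the first character ('@' FASTQ,
    '>' FASTA).  No alphabet filtering happens here; N handling is part of
    trimming so that rejection counts are reported.
    """
    with open(path) as fh:
        first = fh.read(1)
    if not first:
        return
    if first == "@":
        fmt = "fastq"
    elif first == ">":
        fmt = "fasta"
    else:
        raise ReadFormatError(f"unrecognized format (first character {first!r})")
    n_record = 0
    try:
        for n_record, rec in enumerate(SeqIO.parse(path, fmt), start=1):
            yield rec.id, _to_rna(str(rec.seq))
    except ValueError as exc:  # truncated/malformed record
        raise ReadFormatError(f"record {n_record + 1} in {path}: {exc}") from exc


def trim_read(
    raw: str,
    adapter_prefix: str = DEFAULT_ADAPTER_PREFIX,
    hd_len: int = 4,
    min_insert: int = 15,
    read_id: str = "",
) -> TrimmedRead:
    """Trim one raw read; all failure modes are statuses, not exceptions."""
    seq = _to_rna(raw)
    n = len(seq)
    if "N" in seq:
        return TrimmedRead(read_id, "", n, STATUS_REJECTED_N)
    idx = seq.find(adapter_prefix)
    if idx < 0:
        return TrimmedRead(read_id, "", n, STATUS_NO_ADAPTER)
    remainder = seq[:idx]
    if len(remainder) < min_insert + 2 * hd_len:
        return TrimmedRead(read_id, "", n, STATUS_SHORT)
    insert = remainder[hd_len : len(remainder) - hd_len]
    return TrimmedRead(read_id, insert, n, STATUS_ACCEPTED)


def process_reads(
    records: Iterable[tuple[str, str]],
    adapter_prefix: str = DEFAULT_ADAPTER_PREFIX,
    hd_len: int = 4,
    min_insert: int = 15,
) -> tuple[list[TrimmedRead], dict[str, int]]:
    """Trim a stream of (id, sequence); returns accepted reads and a report of
    counts by status (the report includes rejected categories)."""
    report = {
        STATUS_ACCEPTED: 0,
        STATUS_REJECTED_N: 0,
        STATUS_NO_ADAPTER: 0,
        STATUS_SHORT: 0,
    }
    accepted = []
    for read_id, seq in records:
        t = trim_read(seq, adapter_prefix, hd_len, min_insert, read_id=read_id)
        report[t.status] += 1
        if t.status == STATUS_ACCEPTED:
            accepted.append(t)
    return accepted, report


def process_file(
    path: str,
    adapter_prefix: str = DEFAULT_ADAPTER_PREFIX,
    hd_len: int = 4,
    min_insert: int = 15,
) -> tuple[list[TrimmedRead], dict[str, int]]:
    return process_reads(read_records(path), adapter_prefix, hd_len, min_insert)


def write_trimmed_fasta(reads: Iterable[TrimmedRead], path: str) -> None:
    with open(path, "w") as fh:
        for t in reads:
            if t.status == STATUS_ACCEPTED:
                fh.write(f">{t.read_id}\n{t.insert}\n")


def write_trim_report(report: dict[str, int], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("status\tcount\n")
        for status, count in report.items():
            fh.write(f"{status}\t{count}\n")
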