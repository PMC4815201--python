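"""Collapsed tag tables of counts, and a convenience read collapser.

A *tag* is a unique (pre-trimmed) read sequence carried with the number of
reads supporting it.  The canonical on-disk form is a two-column TSV
``sequence<TAB>count``; ``collapse_reads`` produces the same table from
FASTA/FASTQ when no upstream collapser was used.  Adapter trimming is out of
scope and assumed done upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence

from Bio import SeqIO

from .reference_db import InputError, normalize_sequence, _VALID_ALPHABET

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TagRecord:
    """A unique read sequence with its occurrence count (tag_size = len)."""

    sequence: str
    count: int

    @property
    def length(self) -> int:
        return len(self.sequence)


def read_tag_counts(path: str | Path) -> List[TagRecord]:
    """Read a ``sequence<TAB>count`` table (whitespace-delimited accepted).

    An optional header line is auto-detected by a non-numeric second field.
    Malformed lines are skipped with a warning; duplicate sequences are
    merged by summing counts; sequences with non-ACGT symbols (after U->T
    normalization) are excluded and counted in the log.

    Raises ``InputError`` when the file is missing or holds zero valid lines.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"tag table not found: {path}")

    merged: Dict[str, int] = {}
    n_bad_alpha = 0
    n_merged = 0
    first_data_line = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                log.warning("%s:%d: missing count field, line skipped", path, lineno)
                continue
            seq_raw, count_raw = fields[0], fields[1]
            try:
                count = int(count_raw)
            except ValueError:
                if first_data_line:
                    first_data_line = False  # header line
                    continue
                log.warning("%s:%d: non-integer count %r, line skipped", path, lineno, count_raw)
                continue
            first_data_line = False
            if count < 1:
                log.warning("%s:%d: non-positive count %d, line skipped", path, lineno, count)
                continue
            seq = normalize_sequence(seq_raw)
            if not seq or not set(seq) <= _VALID_ALPHABET:
                n_bad_alpha += 1
                continue
            if seq in merged:
                n_merged += 1
                merged[seq] += count
            else:
                merged[seq] = count

    if n_bad_alpha:
        log.warning("%s: %d sequences with non-ACGT symbols excluded", path, n_bad_alpha)
    if n_merged:
        log.info("%s: %d duplicate sequences merged by summing counts", path, n_merged)
    if not merged:
        raise InputError(f"tag table {path} holds zero valid lines")
    return [TagRecord(sequence=s, count=c) for s, c in merged.items()]


def collapse_reads(path: str | Path) -> List[TagRecord]:
    """Collapse pre-trimmed FASTA/FASTQ reads into unique tags with counts.

    The format is auto-detected from the first character ('>' FASTA,
    '@' FASTQ).  Reads with non-ACGT symbols are excluded (their number is
    logged); the total count of the returned tags equals the number of
    retained reads.  Output is sorted by descending count, then sequence.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"reads file not found: {path}")
    with open(path) as fh:
        first = fh.read(1)
    if first == ">":
        fmt = "fasta"
    elif first == "@":
        fmt = "fastq"
    else:
        raise InputError(f"{path}: not FASTA or FASTQ (starts with {first!r})")

    counts: Dict[str, int] = {}
    n_reads = 0
    n_bad = 0
    try:
        for rec in SeqIO.parse(str(path), fmt):
            n_reads += 1
            seq = normalize_sequence(str(rec.seq))
            if not seq or not set(seq) <= _VALID_ALPHABET:
                n_bad += 1
                continue
            counts[seq] = counts.get(seq, 0) + 1
    except (ValueError, OSError) as exc:
        raise InputError(f"could not parse {fmt} file {path}: {exc}") from exc

    if n_reads == 0:
        raise InputError(f"reads file {path} is empty")
    if n_bad:
        log.warning("%s: %d reads with non-ACGT symbols excluded", path, n_bad)
    tags = [TagRecord(sequence=s, count=c) for s, c in counts.items()]
    tags.sort(key=lambda t: (-t.count, t.sequence))
    return tags


def write_tag_counts(tags: Sequence[TagRecord], path: str | Path) -> None:
    """Write tags as ``sequence<TAB>count``, no header."""
    with open(path, "w") as fh:
        for t in tags:
            fh.write(f"{t.sequence}\t{t.count}\n")
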