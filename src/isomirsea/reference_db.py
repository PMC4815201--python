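"""Mature miRNA reference loading and the seed-sorted index.

References are read from a miRBase-style FASTA (``>hsa-miR-1244 ...``), the
RNA alphabet is normalized to DNA (U -> T), and each accepted record is filed
under its seed hexamer.  The index is the lookup structure the aligner probes
with tag substrings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set

from Bio import SeqIO

from .params import AlignmentParams

log = logging.getLogger(__name__)

_VALID_ALPHABET = frozenset("ACGT")


class InputError(ValueError):
    """Fatal problem with an input file or filter."""


@dataclass(frozen=True)
class MatureRecord:
    """One mature miRNA reference sequence.

    ``species_code`` is the miRBase prefix before the first ``-`` in the id
    (``hsa``, ``mml``, ...); ids without a dash get ``"unknown"``.  ``length``
    is the miR_size used by the alignment score.
    """

    id: str
    species_code: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class SeedIndex:
    """Hexamer-keyed grouping of mature records, per species set.

    Every record appears under exactly one key (its own seed); lookups of
    absent keys return the empty list.
    """

    mapping: Dict[str, List[MatureRecord]] = field(default_factory=dict)
    species_set: Set[str] = field(default_factory=set)
    seed_start: int = 2
    seed_end: int = 7

    def lookup(self, hexamer: str) -> List[MatureRecord]:
        return self.mapping.get(hexamer, [])

    @property
    def n_records(self) -> int:
        return sum(len(g) for g in self.mapping.values())


def species_code_of(name: str) -> str:
    return name.split("-", 1)[0] if "-" in name else "unknown"


def normalize_sequence(raw: str) -> str:
    """Uppercase and map the RNA alphabet onto DNA (U -> T)."""
    return raw.upper().replace("U", "T")


def load_mature_references(
    path: str | Path,
    species_filter: Optional[Iterable[str]] = None,
    min_length: int = 7,
) -> List[MatureRecord]:
    """Load mature references from FASTA, in file order.

    Records shorter than ``min_length`` (too short to contain the full seed)
    or containing symbols outside {A,C,G,T} after U->T normalization are
    skipped with a warning.  Duplicate ids keep the first occurrence.

    Raises
    ------
    InputError
        If the file is missing/empty/unparseable, or if ``species_filter``
        leaves zero records.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"reference FASTA not found: {path}")
    wanted = set(species_filter) if species_filter is not None else None

    records: List[MatureRecord] = []
    seen_ids: Set[str] = set()
    n_parsed = 0
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            n_parsed += 1
            name = rec.id
            seq = normalize_sequence(str(rec.seq))
            if name in seen_ids:
                log.warning("duplicate reference id %s: keeping first occurrence", name)
                continue
            if len(seq) < min_length:
                log.warning("reference %s shorter than the seed (%d nt): skipped", name, len(seq))
                continue
            if not set(seq) <= _VALID_ALPHABET:
                log.warning("reference %s contains non-ACGT symbols: skipped", name)
                continue
            code = species_code_of(name)
            if wanted is not None and code not in wanted:
                continue
            seen_ids.add(name)
            records.append(MatureRecord(id=name, species_code=code, sequence=seq))
    except (ValueError, OSError) as exc:  # Bio raises ValueError on bad FASTA
        raise InputError(f"could not parse reference FASTA {path}: {exc}") from exc

    if n_parsed == 0:
        raise InputError(f"reference FASTA {path} is empty or not FASTA")
    if not records:
        if wanted is not None:
            raise InputError(
                f"zero records after species filter {sorted(wanted)} in {path}"
            )
        raise InputError(f"zero usable records in {path}")
    return records


def extract_seed(record: MatureRecord, seed_start: int = 2, seed_end: int = 7) -> str:
    """Return the seed substring (1-based inclusive coordinates).

    Raises ``ValueError`` if the record is too short to contain the full
    seed; callers building the index treat that as a per-record rejection.
    """
    if seed_start < 1:
        raise ValueError("seed_start must be >= 1")
    if record.length < seed_end:
        raise ValueError(
            f"record {record.id} ({record.length} nt) shorter than seed_end {seed_end}"
        )
    return record.sequence[seed_start - 1 : seed_end]


def build_seed_index(
    records: Sequence[MatureRecord], params: AlignmentParams | None = None
) -> SeedIndex:
    """Group records by their seed hexamer, preserving input order.

    The groups partition the accepted records: the sum of group sizes equals
    the number of records long enough to carry the full seed.
    """
    params = params or AlignmentParams()
    if not records:
        raise InputError("cannot build a seed index from zero records")
    index = SeedIndex(seed_start=params.seed_start, seed_end=params.seed_end)
    for rec in records:
        try:
            key = extract_seed(rec, params.seed_start, params.seed_end)
        except ValueError:
            log.warning("record %s excluded from index (shorter than seed)", rec.id)
            continue
        index.mapping.setdefault(key, []).append(rec)
        index.species_set.add(rec.species_code)
    return index
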