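"""Synthetic references, tag corpora with truth labels, and the brute-force
alignment oracle.

The generator builds a mature reference set with controlled seed sharing and
derives tags from it by injecting the canonical isomiR variant classes
(5'-end shifts, 3'-end shifts, internal substitutions, and combinations),
plus two negative classes: ``seed_corrupt`` (a substitution inside the seed)
and ``no_seed`` (a random sequence carrying no reference seed in the search
window).  Each emitted tag carries a truth row — expected isomiR token and
expected interaction-site flags — computed from the construction parameters
by span arithmetic, deliberately not by calling the annotator, so the test
surface is not circular.

``brute_force_align`` is a direct, slice-based re-statement of the alignment
rules used as an independent oracle in tests: it enumerates every placement
of an exact seed copy in the search window and applies the mismatch-window,
truncation, minimum-length and identity rules literally.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .annotator import ISOMIR_TOKENS, SiteDefinitions
from .params import AlignmentParams
from .reference_db import MatureRecord
from .seed_aligner import (
    REASON_LOW_IDENTITY,
    REASON_MISMATCH_WINDOW,
    REASON_TOO_SHORT,
    Alignment,
    Rejection,
    align_score,
    mirtag_diff,
)
from .tag_io import TagRecord

_BASES = "ACGT"

NEGATIVE_TOKENS = ("seed_corrupt", "no_seed")
EXPECTED_DISCARD = "expected-discard"


@dataclass(frozen=True)
class InjectionSpec:
    """How many tags of one variant class to synthesise.

    ``token`` is a canonical isomiR token or one of the negative classes.
    End-shift magnitudes are drawn from ``five_p_range`` / ``three_p_range``
    (nonzero when the class requires that end to move); substitution
    positions are drawn uniformly over allowed non-seed positions that
    respect the mismatch window.  Read counts per tag are uniform over
    ``count_range``.
    """

    token: str
    n_tags: int = 20
    count_range: Tuple[int, int] = (1, 40)
    five_p_range: Tuple[int, int] = (-1, 4)
    three_p_range: Tuple[int, int] = (-4, 4)


@dataclass
class TruthRow:
    """Generation-time bookkeeping for one synthetic tag."""

    sequence: str
    count: int
    source_id: str
    seed_pos: int
    expected_token: str
    offset_conserved: Optional[bool]
    supplementary_conserved: Optional[bool]
    central_conserved: Optional[bool]
    d5: int = 0
    d3: int = 0
    snp_positions: Tuple[int, ...] = ()


def _random_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(length))


def generate_reference(
    n: int,
    length_range: Tuple[int, int] = (20, 24),
    species: str = "hsa",
    rng_seed: int = 0,
    n_shared_seed_pairs: int = 0,
    seed_start: int = 2,
    seed_end: int = 7,
) -> List[MatureRecord]:
    """Synthesise ``n`` mature records with distinct seeds (unless sharing
    is requested), reproducibly for a given ``rng_seed``.

    ``n_shared_seed_pairs`` records at the end reuse the seed of an earlier
    record, emulating miRNA families.  Fails when ``n`` exceeds the number
    of distinct seeds (4^seed_len).
    """
    seed_len = seed_end - seed_start + 1
    if n < 1:
        raise ValueError("n must be >= 1")
    if n - n_shared_seed_pairs > 4 ** seed_len:
        raise ValueError(f"cannot draw {n} distinct {seed_len}-mers")
    if length_range[0] < 16:
        raise ValueError("reference lengths must be >= 16")
    rng = random.Random(rng_seed)
    records: List[MatureRecord] = []
    used_seeds: Set[str] = set()
    n_distinct = n - n_shared_seed_pairs
    for i in range(n):
        length = rng.randint(*length_range)
        while True:
            seq = _random_seq(rng, length)
            seed = seq[seed_start - 1 : seed_end]
            if i < n_distinct:
                if seed not in used_seeds:
                    break
            else:
                donor = records[rng.randrange(len(records))]
                seq = (
                    seq[: seed_start - 1]
                    + donor.sequence[seed_start - 1 : seed_end]
                    + seq[seed_end:]
                )
                break
        used_seeds.add(seq[seed_start - 1 : seed_end])
        records.append(
            MatureRecord(
                id=f"{species}-miR-s{i + 1:04d}",
                species_code=species,
                sequence=seq,
            )
        )
    return records


def write_reference_fasta(records: Sequence[MatureRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id} synthetic\n{rec.sequence}\n")


def _parse_token(token: str) -> Tuple[bool, int, bool]:
    parts = token.split("-")
    has5 = "iso_5p" in parts
    has3 = "iso_3p" in parts
    n_snp = 1 if "iso_snp" in parts else 2 if "iso_multi_snp" in parts else 0
    return has5, n_snp, has3


def _truth_sites(
    mir_start: int, mir_end: int, snps: Sequence[int], defs: SiteDefinitions
) -> Tuple[bool, bool, bool]:
    """Independent span arithmetic for the expected site flags."""
    snpset = set(snps)

    def full(start: int, end: int) -> bool:
        return start >= mir_start and end <= mir_end and not snpset & set(range(start, end + 1))

    s, e = defs.supplementary_span
    best = run = 0
    for p in range(s, e + 1):
        ok = mir_start <= p <= mir_end and p not in snpset
        run = run + 1 if ok else 0
        best = max(best, run)
    return (
        full(defs.offset_pos, defs.offset_pos),
        best >= defs.supplementary_min_contiguous,
        full(*defs.central_span),
    )


def _window_hexamers(seq: str, params: AlignmentParams) -> List[str]:
    L = params.seed_len
    return [
        seq[s - 1 : s - 1 + L]
        for s in range(params.tag_search_min, params.tag_search_max + 1)
        if s - 1 + L <= len(seq)
    ]


def _make_in_spec_tag(
    rng: random.Random,
    records: Sequence[MatureRecord],
    spec: InjectionSpec,
    params: AlignmentParams,
    defs: SiteDefinitions,
) -> Tuple[str, MatureRecord, int, int, Tuple[int, ...]]:
    """Construct one tag of an in-spec class; returns (seq, source, d5, d3, snps)."""
    has5, n_snp, has3 = _parse_token(spec.token)
    for _ in range(500):
        mature = records[rng.randrange(len(records))]
        mir_len = mature.length
        d5 = 0
        if has5:
            lo = max(spec.five_p_range[0], -1)
            hi = min(spec.five_p_range[1], params.tag_search_max - params.seed_start)
            choices = [d for d in range(lo, hi + 1) if d != 0]
            d5 = rng.choice(choices)
        d3 = 0
        if has3:
            lo, hi = spec.three_p_range
            choices = [d for d in range(lo, hi + 1) if d != 0 and abs(d5 + d) <= params.max_len_diff]
            if not choices:
                continue
            d3 = rng.choice(choices)
        elif abs(d5) > params.max_len_diff:
            continue

        mir_start = 2 if d5 == -1 else 1
        mir_end = mir_len + min(d3, 0)
        if mir_end - mir_start + 1 < params.min_align_len:
            continue

        snps: Tuple[int, ...] = ()
        if n_snp:
            allowed = [
                p
                for p in range(mir_start, mir_end + 1)
                if not params.seed_start <= p <= params.seed_end
            ]
            if n_snp == 1:
                snps = (rng.choice(allowed),)
            else:
                pairs = [
                    (a, b)
                    for a in allowed
                    for b in allowed
                    if b - a > params.mismatch_window
                ]
                if not pairs:
                    continue
                snps = pairs[rng.randrange(len(pairs))]

        # build the tag sequence
        core = list(mature.sequence)
        for p in snps:
            core[p - 1] = rng.choice([b for b in _BASES if b != core[p - 1]])
        seq = "".join(core)
        if d5 == -1:
            seq = seq[1:]
        elif d5 > 0:
            seq = _random_seq(rng, d5) + seq
        if d3 < 0:
            seq = seq[:d3]
        elif d3 > 0:
            seq = seq + _random_seq(rng, d3)
        return seq, mature, d5, d3, snps
    raise RuntimeError(f"could not satisfy constraints for class {spec.token}")


def _make_negative_tag(
    rng: random.Random,
    records: Sequence[MatureRecord],
    token: str,
    params: AlignmentParams,
    all_seeds: Set[str],
) -> str:
    """Construct a tag guaranteed to carry no reference seed in the window."""
    for _ in range(2000):
        if token == "seed_corrupt":
            mature = records[rng.randrange(len(records))]
            core = list(mature.sequence)
            pos = rng.randint(params.seed_start, params.seed_end)
            core[pos - 1] = rng.choice([b for b in _BASES if b != core[pos - 1]])
            seq = "".join(core)
        else:  # no_seed
            seq = _random_seq(rng, rng.randint(18, 26))
        if not any(h in all_seeds for h in _window_hexamers(seq, params)):
            return seq
    raise RuntimeError(f"could not synthesise a {token} tag avoiding all seeds")


def generate_tags(
    records: Sequence[MatureRecord],
    specs: Sequence[InjectionSpec],
    rng_seed: int = 0,
    params: AlignmentParams | None = None,
    sites: SiteDefinitions | None = None,
) -> Tuple[List[TagRecord], List[TruthRow]]:
    """Synthesise a tag corpus with truth labels.

    Tags whose sequence collides with an earlier tag (from any spec) are
    dropped from the truth table; the tag table itself merges their counts.
    """
    if not records:
        raise ValueError("reference must be non-empty")
    params = params or AlignmentParams()
    sites = sites or SiteDefinitions()
    rng = random.Random(rng_seed)
    all_seeds = {
        rec.sequence[params.seed_start - 1 : params.seed_end] for rec in records
    }

    truth: Dict[str, TruthRow] = {}
    collided: Set[str] = set()
    counts: Dict[str, int] = {}
    order: List[str] = []

    for spec in specs:
        for _ in range(spec.n_tags):
            count = rng.randint(*spec.count_range)
            if spec.token in NEGATIVE_TOKENS:
                seq = _make_negative_tag(rng, records, spec.token, params, all_seeds)
                row = TruthRow(
                    sequence=seq, count=count, source_id="", seed_pos=0,
                    expected_token=EXPECTED_DISCARD,
                    offset_conserved=None, supplementary_conserved=None,
                    central_conserved=None,
                )
            else:
                seq, mature, d5, d3, snps = _make_in_spec_tag(
                    rng, records, spec, params, sites
                )
                mir_start = 2 if d5 == -1 else 1
                mir_end = mature.length + min(d3, 0)
                off, sup, cen = _truth_sites(mir_start, mir_end, snps, sites)
                row = TruthRow(
                    sequence=seq, count=count, source_id=mature.id,
                    seed_pos=params.seed_start + d5,
                    expected_token=spec.token,
                    offset_conserved=off, supplementary_conserved=sup,
                    central_conserved=cen, d5=d5, d3=d3, snp_positions=snps,
                )
            if seq in counts:
                counts[seq] += count
                collided.add(seq)
            else:
                counts[seq] = count
                order.append(seq)
                truth[seq] = row

    for seq in collided:
        truth.pop(seq, None)
    tags = [TagRecord(sequence=s, count=counts[s]) for s in order]
    return tags, [truth[s] for s in order if s in truth]


def default_corpus_specs(
    tags_per_class: int = 20, count_range: Tuple[int, int] = (1, 40)
) -> List[InjectionSpec]:
    """One spec per canonical isomiR token plus the two negative classes."""
    return [
        InjectionSpec(token=t, n_tags=tags_per_class, count_range=count_range)
        for t in (*ISOMIR_TOKENS, *NEGATIVE_TOKENS)
    ]


def write_truth_table(rows: Sequence[TruthRow], path: str | Path, rng_seed: int) -> None:
    def flag(x: Optional[bool]) -> str:
        return "-" if x is None else ("1" if x else "0")

    with open(path, "w") as fh:
        fh.write(f"# rng_seed={rng_seed}\n")
        fh.write(
            "#sequence\tcount\tsource_id\tseed_pos\texpected_token\t"
            "offset_conserved\tsupplementary_conserved\tcentral_conserved\t"
            "d5\td3\tsnp_positions\n"
        )
        for r in rows:
            snp = ";".join(map(str, r.snp_positions)) if r.snp_positions else "-"
            fh.write(
                f"{r.sequence}\t{r.count}\t{r.source_id or '-'}\t{r.seed_pos}\t"
                f"{r.expected_token}\t{flag(r.offset_conserved)}\t"
                f"{flag(r.supplementary_conserved)}\t{flag(r.central_conserved)}\t"
                f"{r.d5}\t{r.d3}\t{snp}\n"
            )


# ---------------------------------------------------------------------------
# brute-force oracle


def brute_force_align(
    tag: TagRecord | str, mature: MatureRecord, params: AlignmentParams | None = None
) -> Tuple[List[Alignment], List[Rejection]]:
    """Literal enumeration oracle for the alignment rules (test use only).

    For every search-window position where the tag holds an exact copy of
    the mature seed, the full ungapped pairing is materialised, mismatches
    collected by direct comparison, the third-mismatch truncation replayed,
    and the window / length / identity rules applied verbatim.
    """
    params = params or AlignmentParams()
    seq = tag.sequence if isinstance(tag, TagRecord) else tag
    mat = mature.sequence
    seed = mat[params.seed_start - 1 : params.seed_end]
    accepted: List[Alignment] = []
    rejections: List[Rejection] = []

    for s in range(params.tag_search_min, params.tag_search_max + 1):
        if s - 1 + len(seed) > len(seq):
            continue
        if seq[s - 1 : s - 1 + len(seed)] != seed:
            continue
        shift = s - params.seed_start
        paired = [
            (m, m + shift)
            for m in range(1, len(mat) + 1)
            if 1 <= m + shift <= len(seq)
        ]
        # replay the extension: 5' flank fully paired, 3' stops before the
        # mismatch that would exceed the budget
        kept_mm = [m for m, t in paired if m < params.seed_start and mat[m - 1] != seq[t - 1]]
        mir_end = params.seed_end
        for m, t in paired:
            if m <= params.seed_end:
                continue
            if mat[m - 1] != seq[t - 1]:
                if len(kept_mm) >= params.max_mismatches:
                    break
                kept_mm.append(m)
            mir_end = m
        mir_start = paired[0][0]

        reason = None
        if any(b - a <= params.mismatch_window for a, b in zip(kept_mm, kept_mm[1:])):
            reason = REASON_MISMATCH_WINDOW
        size = mir_end - mir_start + 1
        identity = (size - len(kept_mm)) / size * 100.0
        if reason is None and size < params.min_align_len:
            reason = REASON_TOO_SHORT
        if reason is None and identity < params.identity_min:
            reason = REASON_LOW_IDENTITY
        if reason is not None:
            rejections.append(Rejection(mature.id, s, reason))
            continue
        accepted.append(
            Alignment(
                mature_id=mature.id,
                species=mature.species_code,
                mir_size=len(mat),
                tag=seq,
                seed_pos_in_tag=s,
                offset_5p=s - params.seed_start,
                mir_start=mir_start,
                mir_end=mir_end,
                mismatch_positions=tuple(kept_mm),
                n_gaps=0,
                overhang_3p=len(seq) - (mir_end + shift),
                delta_3p=(len(seq) - shift) - len(mat),
                align_score=align_score(len(mat), size, 0),
                mirtag_diff=mirtag_diff(len(mat), len(seq)),
                identity_pct=identity,
            )
        )
    return accepted, rejections
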