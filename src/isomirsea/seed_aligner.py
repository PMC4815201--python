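"""Seed-anchored ungapped alignment of tags to mature miRNAs.

The algorithm anchors a mature miRNA inside a tag by an *exact* seed match
at a tag position compatible with miRNA structure, then extends without gaps
in both directions.  The 5' flank (mature positions before the seed reached
by the tag) is fully paired; the 3' extension records mismatches and stops
immediately before the (max_mismatches + 1)-th.  An extension is rejected
when two retained mismatches fall within the mismatch window, when the
aligned span is shorter than the minimum, or when percent identity over the
span falls below the threshold.

Coordinates: tag position i pairs with mature position i - seed_pos + seed_start
(1-based everywhere).  Accepted alignments carry two quality measures:

    align_score = (miR_size - (align_size - n_gaps)) / miR_size * 100
    miRtag_diff = miR_size - tag_size

Lower values of both indicate a tag closer to the full mature sequence.
n_gaps is always 0 in this ungapped mode; the symbol is kept in the formula
for a future gapped mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple, Union

from .params import AlignmentParams
from .reference_db import MatureRecord, SeedIndex
from .tag_io import TagRecord

# Rejection reasons, in decreasing "informativeness" for aggregate reporting:
# a window violation says more than a short span, which says more than a
# generic identity failure; "no_seed" is the fallback when nothing anchored.
REASON_MISMATCH_WINDOW = "mismatch_window"
REASON_TOO_SHORT = "too_short"
REASON_LOW_IDENTITY = "low_identity"
REASON_TOO_MANY_MISMATCHES = "too_many_mismatches"
REASON_NO_SEED = "no_seed"
REASON_PRIORITY = (
    REASON_MISMATCH_WINDOW,
    REASON_TOO_MANY_MISMATCHES,
    REASON_TOO_SHORT,
    REASON_LOW_IDENTITY,
    REASON_NO_SEED,
)


@dataclass(frozen=True)
class SeedAnchor:
    """A mature whose seed occurs exactly at ``seed_pos_in_tag`` (1-based)."""

    mature: MatureRecord
    seed_pos_in_tag: int


@dataclass(frozen=True)
class Rejection:
    """Typed per-anchor rejection."""

    mature_id: str
    seed_pos_in_tag: int
    reason: str


@dataclass(frozen=True)
class Alignment:
    """An accepted anchored ungapped alignment.

    ``offset_5p`` = seed_pos_in_tag - seed_start: positive values count tag
    nucleotides 5' of mature position 1 (5p additions); -1 means mature
    position 1 is unpaired (a one-nt 5p deletion).  ``delta_3p`` is the
    signed 3'-end length difference in mature coordinates (positive = tag
    reaches past the mature 3' end); ``overhang_3p`` counts tag nucleotides
    beyond the aligned span at the 3' side.  ``mismatch_positions`` are
    mature coordinates and never fall inside the seed.
    """

    mature_id: str
    species: str
    mir_size: int
    tag: str
    seed_pos_in_tag: int
    offset_5p: int
    mir_start: int
    mir_end: int
    mismatch_positions: Tuple[int, ...]
    n_gaps: int
    overhang_3p: int
    delta_3p: int
    align_score: float
    mirtag_diff: int
    identity_pct: float

    @property
    def align_size(self) -> int:
        return self.mir_end - self.mir_start + 1

    @property
    def tag_size(self) -> int:
        return len(self.tag)


def align_score(miR_size: int, align_size: int, n_gaps: int = 0) -> float:
    """Alignment quality in percent; lower is better (0 = full-length span)."""
    if miR_size <= 0:
        raise ValueError("miR_size must be positive")
    if align_size < 0 or n_gaps < 0:
        raise ValueError("align_size and n_gaps must be non-negative")
    return (miR_size - (align_size - n_gaps)) / miR_size * 100.0


def mirtag_diff(miR_size: int, tag_size: int) -> int:
    """Signed length difference miR_size - tag_size; small |value| = comparable lengths."""
    if miR_size <= 0 or tag_size <= 0:
        raise ValueError("sizes must be positive")
    return miR_size - tag_size


def _tag_sequence(tag: Union[TagRecord, str]) -> str:
    return tag.sequence if isinstance(tag, TagRecord) else tag


def find_seed_anchors(
    tag: Union[TagRecord, str], index: SeedIndex, params: AlignmentParams
) -> List[SeedAnchor]:
    """Locate all (mature, position) pairs whose seed occurs exactly in the tag
    within the structure-compatible search window.  An empty list means the
    tag carries no usable seed and is discarded as non-miRNA.
    """
    seq = _tag_sequence(tag)
    seed_len = params.seed_len
    anchors: List[SeedAnchor] = []
    for s in range(params.tag_search_min, params.tag_search_max + 1):
        if s + seed_len - 1 > len(seq):
            break
        window = seq[s - 1 : s - 1 + seed_len]
        for mature in index.lookup(window):
            anchors.append(SeedAnchor(mature=mature, seed_pos_in_tag=s))
    return anchors


def extend_ungapped(
    tag: Union[TagRecord, str],
    mature: MatureRecord,
    anchor: Union[SeedAnchor, int],
    params: AlignmentParams,
) -> Union[Alignment, Rejection]:
    """Extend an anchored seed match in both directions without gaps.

    Returns an :class:`Alignment` on success or a typed :class:`Rejection`.
    """
    seq = _tag_sequence(tag)
    seed_pos = anchor.seed_pos_in_tag if isinstance(anchor, SeedAnchor) else int(anchor)
    mat = mature.sequence
    mir_len = len(mat)
    tag_len = len(seq)
    shift = seed_pos - params.seed_start  # tag pos = mature pos + shift

    # 5' side: pair every mature position before the seed that the tag reaches.
    mir_start = max(1, 1 - shift)
    mismatches: List[int] = []
    for m in range(mir_start, params.seed_start):
        if seq[m + shift - 1] != mat[m - 1]:
            mismatches.append(m)

    # 3' side: extend past the seed, stopping just before a mismatch that
    # would exceed the retained-mismatch budget.
    mir_end = params.seed_end
    max_reach = min(mir_len, tag_len - shift)
    for m in range(params.seed_end + 1, max_reach + 1):
        if seq[m + shift - 1] != mat[m - 1]:
            if len(mismatches) >= params.max_mismatches:
                break
            mismatches.append(m)
        mir_end = m

    if len(mismatches) > params.max_mismatches:
        # only reachable with a 5' flank longer than the mismatch budget
        return Rejection(mature.id, seed_pos, REASON_TOO_MANY_MISMATCHES)

    for a, b in zip(mismatches, mismatches[1:]):
        if b - a <= params.mismatch_window:
            return Rejection(mature.id, seed_pos, REASON_MISMATCH_WINDOW)

    size = mir_end - mir_start + 1
    if size < params.min_align_len:
        return Rejection(mature.id, seed_pos, REASON_TOO_SHORT)

    identity = (size - len(mismatches)) / size * 100.0
    if identity < params.identity_min:
        return Rejection(mature.id, seed_pos, REASON_LOW_IDENTITY)

    return Alignment(
        mature_id=mature.id,
        species=mature.species_code,
        mir_size=mir_len,
        tag=seq,
        seed_pos_in_tag=seed_pos,
        offset_5p=seed_pos - params.seed_start,
        mir_start=mir_start,
        mir_end=mir_end,
        mismatch_positions=tuple(mismatches),
        n_gaps=0,
        overhang_3p=tag_len - (mir_end + shift),
        delta_3p=(tag_len - shift) - mir_len,
        align_score=align_score(mir_len, size, 0),
        mirtag_diff=mirtag_diff(mir_len, tag_len),
        identity_pct=identity,
    )


@dataclass
class TagAlignmentResult:
    """All accepted alignments for one tag plus per-anchor rejections."""

    alignments: List[Alignment]
    rejections: List[Rejection]

    @property
    def rejection_reason(self) -> str:
        """Most informative aggregate reason when no alignment was accepted."""
        if self.alignments:
            return ""
        reasons = {r.reason for r in self.rejections}
        for reason in REASON_PRIORITY:
            if reason in reasons:
                return reason
        return REASON_NO_SEED


def align_tag_detailed(
    tag: Union[TagRecord, str], index: SeedIndex, params: AlignmentParams
) -> TagAlignmentResult:
    """Run the full per-tag procedure, keeping rejection provenance."""
    anchors = find_seed_anchors(tag, index, params)
    seen: set = set()
    accepted: List[Alignment] = []
    rejections: List[Rejection] = []
    for anchor in anchors:
        key = (anchor.mature.id, anchor.seed_pos_in_tag)
        if key in seen:
            continue
        seen.add(key)
        result = extend_ungapped(tag, anchor.mature, anchor, params)
        if isinstance(result, Alignment):
            accepted.append(result)
        else:
            rejections.append(result)
    return TagAlignmentResult(alignments=accepted, rejections=rejections)


def align_tag(
    tag: Union[TagRecord, str], index: SeedIndex, params: AlignmentParams
) -> List[Alignment]:
    """Accepted alignments of one tag over all anchors (empty = discarded)."""
    return align_tag_detailed(tag, index, params).alignments


def align_all(
    tags: List[TagRecord], index: SeedIndex, params: AlignmentParams
) -> Dict[TagRecord, TagAlignmentResult]:
    """Align every tag; the mapping preserves tag order."""
    return {t: align_tag_detailed(t, index, params) for t in tags}
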