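"""Multi-mapping resolution: unique / ambiguous partition, score-based rescue,
and cross-species competition.

A tag with exactly one accepted alignment is *unique*; with several it is
*ambiguous* and rescue picks the candidate minimising
(align_score, |miRtag_diff|) — a tie on both measures across distinct mature
ids is refused (*ambiguous_unresolved*) rather than fabricating counts, while
a tie confined to one mature id (the same seed occurring twice in the tag) is
broken deterministically.  With a multi-species reference, a tag whose chosen
winner belongs to a non-focal species is excluded from the focal species'
expression tables but kept in tag-level outputs labelled with its winning
species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .seed_aligner import Alignment, TagAlignmentResult
from .tag_io import TagRecord

STATUS_UNIQUE = "unique"
STATUS_RESCUED = "rescued"
STATUS_AMBIGUOUS = "ambiguous_unresolved"
STATUS_DISCARDED = "discarded"
ALL_STATUSES = (STATUS_UNIQUE, STATUS_RESCUED, STATUS_AMBIGUOUS, STATUS_DISCARDED)


@dataclass
class Assignment:
    """Resolution outcome for one tag."""

    tag: TagRecord
    status: str
    alignment: Optional[Alignment] = None
    candidates: List[Alignment] = field(default_factory=list)
    candidate_count: int = 0
    family_count: int = 0
    second_best_gap: float = 0.0
    species_excluded: bool = False
    rejection_reason: str = ""

    @property
    def mature_id(self) -> Optional[str]:
        return self.alignment.mature_id if self.alignment is not None else None


def _sort_key(a: Alignment) -> Tuple[float, int, str, int]:
    return (a.align_score, abs(a.mirtag_diff), a.mature_id, a.seed_pos_in_tag)


def _anchor_seed(a: Alignment, seed_len: int) -> str:
    return a.tag[a.seed_pos_in_tag - 1 : a.seed_pos_in_tag - 1 + seed_len]


def _family_count(candidates: Sequence[Alignment], winner: Alignment, seed_len: int) -> int:
    """Distinct mature ids among candidates anchored by the winning seed."""
    seed = _anchor_seed(winner, seed_len)
    return len({c.mature_id for c in candidates if _anchor_seed(c, seed_len) == seed})


def partition_assignments(
    per_tag: Dict[TagRecord, List[Alignment]]
) -> Tuple[List[TagRecord], List[TagRecord], List[TagRecord]]:
    """Split tags into (unique, ambiguous, discarded) by alignment count."""
    unique: List[TagRecord] = []
    ambiguous: List[TagRecord] = []
    discarded: List[TagRecord] = []
    for tag, alns in per_tag.items():
        if not alns:
            discarded.append(tag)
        elif len(alns) == 1:
            unique.append(tag)
        else:
            ambiguous.append(tag)
    return unique, ambiguous, discarded


def rescue_ambiguous(
    tag: TagRecord, candidates: Sequence[Alignment], seed_len: int = 6
) -> Assignment:
    """Select a single miRNA for a multi-mapped tag by the two scores.

    Winner = minimal (align_score, |miRtag_diff|), with a deterministic id
    ordering as last resort; an exact tie on both scores across >= 2
    distinct mature ids is refused (status ``ambiguous_unresolved``).
    ``second_best_gap`` is the align_score distance from the winner to the
    next-best candidate (0 when tied).
    """
    if len(candidates) < 2:
        raise ValueError("rescue requires at least two candidates")
    ordered = sorted(candidates, key=_sort_key)
    best = ordered[0]
    best_measures = (best.align_score, abs(best.mirtag_diff))
    tied_ids = {
        c.mature_id
        for c in ordered
        if (c.align_score, abs(c.mirtag_diff)) == best_measures
    }
    resolved = len(tied_ids) == 1
    return Assignment(
        tag=tag,
        status=STATUS_RESCUED if resolved else STATUS_AMBIGUOUS,
        alignment=best if resolved else None,
        candidates=list(ordered),
        candidate_count=len(ordered),
        family_count=_family_count(ordered, best, seed_len),
        second_best_gap=(ordered[1].align_score - best.align_score) if resolved else 0.0,
    )


def apply_species_competition(
    assignments: Sequence[Assignment], focal_species: Optional[str]
) -> List[Assignment]:
    """Mark tags whose chosen winner is a non-focal species as excluded.

    Excluded tags stay in tag-level outputs labelled with the winning
    species; only the focal expression tables drop them.  With no focal
    species the call is a no-op.
    """
    if focal_species is None:
        return list(assignments)
    for a in assignments:
        if a.alignment is not None and a.alignment.species != focal_species:
            a.species_excluded = True
    return list(assignments)


def resolve_all(
    results: Dict[TagRecord, TagAlignmentResult],
    focal_species: Optional[str] = None,
    seed_len: int = 6,
) -> List[Assignment]:
    """Partition, rescue, and apply species competition over all tags.

    Every input tag ends in exactly one status; the returned order follows
    the input mapping.
    """
    assignments: List[Assignment] = []
    for tag, res in results.items():
        alns = res.alignments
        if not alns:
            assignments.append(
                Assignment(
                    tag=tag,
                    status=STATUS_DISCARDED,
                    rejection_reason=res.rejection_reason,
                )
            )
        elif len(alns) == 1:
            assignments.append(
                Assignment(
                    tag=tag,
                    status=STATUS_UNIQUE,
                    alignment=alns[0],
                    candidates=list(alns),
                    candidate_count=1,
                    family_count=_family_count(alns, alns[0], seed_len),
                )
            )
        else:
            assignments.append(rescue_ambiguous(tag, alns, seed_len))
    return apply_species_competition(assignments, focal_species)
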