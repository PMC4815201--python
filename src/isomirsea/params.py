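"""Run parameters for the seed-anchored alignment procedure.

All coordinates are 1-based and inclusive, following the standard miRNA
position convention (the seed is "nt 2-7" of the mature sequence).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Any, Mapping


@dataclass(frozen=True)
class AlignmentParams:
    """Tunable parameters of the alignment stage.

    Attributes
    ----------
    seed_start, seed_end:
        1-based mature-miRNA coordinates of the seed (default nt 2-7).
    tag_search_min, tag_search_max:
        1-based window of tag positions where a seed start is accepted.
        The default [1, 6] admits a single-nucleotide 5' deletion (seed at
        tag position 1) through a four-nucleotide 5' addition.
    min_align_len:
        Minimum accepted alignment span in nt.
    mismatch_window:
        Two retained mismatches whose mature coordinates are separated by
        at most this many nt cause the alignment to be discarded.
    max_mismatches:
        Mismatches retained before the 3' extension stops; the extension
        halts immediately before the (max_mismatches + 1)-th mismatch.
    identity_min:
        Minimum percent identity over the aligned span.
    max_len_diff:
        Reporting-stage cap on |miR_size - tag_size|; tags beyond it are
        flagged "f" (detected but filtered), never rejected at alignment.
    """

    seed_start: int = 2
    seed_end: int = 7
    tag_search_min: int = 1
    tag_search_max: int = 6
    min_align_len: int = 11
    mismatch_window: int = 10
    max_mismatches: int = 2
    identity_min: float = 80.0
    max_len_diff: int = 4

    def __post_init__(self) -> None:
        if self.seed_start < 1 or self.seed_end < self.seed_start:
            raise ValueError("seed span must satisfy 1 <= seed_start <= seed_end")
        if self.tag_search_min < 1:
            raise ValueError("tag_search_min must be >= 1")
        if self.tag_search_max < self.tag_search_min:
            raise ValueError("tag_search_max must be >= tag_search_min")
        if self.min_align_len < self.seed_len:
            raise ValueError("min_align_len must be >= seed length")
        if self.max_mismatches < 0 or self.mismatch_window < 0:
            raise ValueError("mismatch parameters must be non-negative")

    @property
    def seed_len(self) -> int:
        return self.seed_end - self.seed_start + 1

    def with_updates(self, **kwargs: Any) -> "AlignmentParams":
        return replace(self, **kwargs)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "AlignmentParams":
        """Build params from a config mapping, ignoring unknown keys."""
        known = {f for f in cls.__dataclass_fields__}  # noqa: C416
        return cls(**{k: v for k, v in mapping.items() if k in known})
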