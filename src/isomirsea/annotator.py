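"""isomiR classification and miRNA-mRNA interaction-site conservation.

An accepted alignment is labelled by which ends and internal positions
deviate from the mature sequence (iso_5p / iso_3p / iso_snp / iso_multi_snp
and their fixed-order combinations), and profiled for conservation of the
four interaction sites: seed (nt 2-7, exact by construction), offset (nt 8),
supplementary (nt 13-16, requiring a contiguous run of Watson-Crick pairs),
and central (nt 4-16).  Mature positions outside the aligned span cannot
pair and therefore break conservation of any site that needs them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

from .seed_aligner import Alignment

#: Canonical isomiR tokens in fixed report order.
ISOMIR_TOKENS: Tuple[str, ...] = (
    "mirna_exact",
    "iso_5p",
    "iso_snp",
    "iso_multi_snp",
    "iso_3p",
    "iso_5p-iso_snp",
    "iso_5p-iso_multi_snp",
    "iso_5p-iso_3p",
    "iso_snp-iso_3p",
    "iso_multi_snp-iso_3p",
    "iso_5p-iso_snp-iso_3p",
    "iso_5p-iso_multi_snp-iso_3p",
)

SITE_NAMES: Tuple[str, ...] = ("seed", "offset", "supplementary", "central")


@dataclass(frozen=True)
class SiteDefinitions:
    """1-based inclusive coordinates of the interaction sites."""

    seed_span: Tuple[int, int] = (2, 7)
    offset_pos: int = 8
    supplementary_span: Tuple[int, int] = (13, 16)
    central_span: Tuple[int, int] = (4, 16)
    supplementary_min_contiguous: int = 3


@dataclass(frozen=True)
class IsomirLabel:
    has_5p: bool
    has_3p: bool
    n_snp: int
    canonical: str

    @property
    def report_token(self) -> str:
        """Report alias: a pure 3p variant is written ``iso_3p-only``."""
        return "iso_3p-only" if self.canonical == "iso_3p" else self.canonical


@dataclass(frozen=True)
class SitesProfile:
    seed_conserved: bool
    offset_conserved: bool
    supplementary_conserved: bool
    central_conserved: bool

    @property
    def combo(self) -> str:
        flags = (
            self.seed_conserved,
            self.offset_conserved,
            self.supplementary_conserved,
            self.central_conserved,
        )
        names = [n for n, f in zip(SITE_NAMES, flags) if f]
        return "+".join(names) if names else "none"


def classify_isomir(a: Alignment) -> IsomirLabel:
    """Assign the canonical isomiR token of an accepted alignment.

    ``mirna_exact`` requires no end shifts, no mismatches, and a span
    covering the whole mature sequence; otherwise the token is the
    '-'-joined concatenation, in fixed order, of iso_5p, iso_snp /
    iso_multi_snp, iso_3p for whichever flags are set.
    """
    has_5p = a.offset_5p != 0
    has_3p = a.delta_3p != 0 or a.overhang_3p > 0
    n_snp = len(a.mismatch_positions)
    if not has_5p and not has_3p and n_snp == 0:
        # span completeness is implied by the flags; assert the contract
        assert a.mir_start == 1 and a.mir_end == a.mir_size and a.overhang_3p == 0
        return IsomirLabel(False, False, 0, "mirna_exact")
    parts = []
    if has_5p:
        parts.append("iso_5p")
    if n_snp == 1:
        parts.append("iso_snp")
    elif n_snp >= 2:
        parts.append("iso_multi_snp")
    if has_3p:
        parts.append("iso_3p")
    return IsomirLabel(has_5p, has_3p, n_snp, "-".join(parts))


def _span_conserved(a: Alignment, start: int, end: int) -> bool:
    if start < a.mir_start or end > a.mir_end:
        return False
    return not any(start <= p <= end for p in a.mismatch_positions)


def _longest_match_run(a: Alignment, start: int, end: int) -> int:
    best = run = 0
    for p in range(start, end + 1):
        aligned = a.mir_start <= p <= a.mir_end and p not in a.mismatch_positions
        run = run + 1 if aligned else 0
        best = max(best, run)
    return best


def annotate_sites(a: Alignment, defs: SiteDefinitions | None = None) -> SitesProfile:
    """Conservation profile of the four interaction sites.

    A site is conserved iff every position of its span is aligned and
    matching; the supplementary site instead requires the longest run of
    contiguous aligned matches within its span to reach
    ``supplementary_min_contiguous`` (contiguous Watson-Crick pairing is
    what matters there, not completeness).
    """
    defs = defs or SiteDefinitions()
    return SitesProfile(
        seed_conserved=_span_conserved(a, *defs.seed_span),
        offset_conserved=_span_conserved(a, defs.offset_pos, defs.offset_pos),
        supplementary_conserved=(
            _longest_match_run(a, *defs.supplementary_span)
            >= defs.supplementary_min_contiguous
        ),
        central_conserved=_span_conserved(a, *defs.central_span),
    )
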