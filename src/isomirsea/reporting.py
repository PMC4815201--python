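"""Pipeline orchestration and the nine output files.

The run proceeds in three blocks: (a) pre-processing — load the mature
reference, build the seed index, ingest the tag table (or collapse reads);
(b) alignment — seed search and ungapped extension per tag; (c) output —
resolution, annotation, and nine TSV reports:

    1 unique_tags.tsv              tag-level, single-miRNA tags
    2 ambiguous_tags.tsv           tag-level, multi-mapped tags (incl. unresolved)
    3 rescued_tags.tsv             tag-level, multi-mapped tags with a chosen winner
    4 discarded_tags.tsv           tag-level, tags with no accepted alignment
    5 mirna_expression_unique.tsv  miRNA-level, from unique tags
    6 mirna_expression_selected.tsv miRNA-level, from rescued tags
    7 isomir_summary.tsv           corpus-wide isomiR class breakdown
    8 sites_summary.tsv            corpus-wide interaction-site breakdown
    9 run_stats.tsv                per-stage accounting

Every file starts with a single '#'-prefixed header line.  Tag rows carry a
d/u/f status flag: detected, undetected (discarded), or detected but beyond
the |miRtag_diff| length filter.  The length filter is reporting-stage only:
flagged tags stay in the expression tables, so read counts are conserved
across the five accounting buckets (unique, rescued, ambiguous_unresolved,
discarded, species-excluded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .annotator import (
    ISOMIR_TOKENS,
    IsomirLabel,
    SiteDefinitions,
    SitesProfile,
    annotate_sites,
    classify_isomir,
)
from .params import AlignmentParams
from .reference_db import (
    InputError,
    MatureRecord,
    SeedIndex,
    build_seed_index,
    load_mature_references,
)
from .resolver import (
    STATUS_AMBIGUOUS,
    STATUS_DISCARDED,
    STATUS_RESCUED,
    STATUS_UNIQUE,
    Assignment,
    resolve_all,
)
from .seed_aligner import align_all
from .tag_io import TagRecord, collapse_reads, read_tag_counts

log = logging.getLogger(__name__)

OUTPUT_FILES = (
    "unique_tags.tsv",
    "ambiguous_tags.tsv",
    "rescued_tags.tsv",
    "discarded_tags.tsv",
    "mirna_expression_unique.tsv",
    "mirna_expression_selected.tsv",
    "isomir_summary.tsv",
    "sites_summary.tsv",
    "run_stats.tsv",
)

FLAG_DETECTED = "d"
FLAG_UNDETECTED = "u"
FLAG_FILTERED = "f"


class PipelineError(RuntimeError):
    """Fatal pipeline failure, tagged with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class AnnotatedAssignment:
    """Assignment plus isomiR label and sites profile of the chosen winner."""

    assignment: Assignment
    label: Optional[IsomirLabel] = None
    profile: Optional[SitesProfile] = None

    @property
    def flag(self) -> str:
        a = self.assignment
        if a.status == STATUS_DISCARDED:
            return FLAG_UNDETECTED
        best = a.alignment or (a.candidates[0] if a.candidates else None)
        if best is not None and abs(best.mirtag_diff) > self.max_len_diff:
            return FLAG_FILTERED
        return FLAG_DETECTED

    max_len_diff: int = 4


@dataclass
class ExpressionRow:
    """Per-miRNA aggregate over its supporting tags."""

    mirna_id: str
    species: str
    total_count: int = 0
    n_tags: int = 0
    class_counts: Dict[str, int] = field(default_factory=dict)
    offset_conserved_reads: int = 0
    supplementary_conserved_reads: int = 0
    central_conserved_reads: int = 0

    def class_count(self, token: str) -> int:
        return self.class_counts.get(token, 0)


@dataclass
class RunConfig:
    """Everything a run needs; ``tags_path`` or ``reads_path`` must be set."""

    mature_path: str
    tags_path: Optional[str] = None
    reads_path: Optional[str] = None
    out_dir: Optional[str] = None
    species: Optional[Sequence[str]] = None
    focal_species: Optional[str] = None
    params: AlignmentParams = field(default_factory=AlignmentParams)
    sites: SiteDefinitions = field(default_factory=SiteDefinitions)


@dataclass
class RunResult:
    references: List[MatureRecord]
    index: SeedIndex
    tags: List[TagRecord]
    annotated: List[AnnotatedAssignment]
    stats: Dict[str, int]


def annotate_assignments(
    assignments: Sequence[Assignment],
    sites: SiteDefinitions | None = None,
    max_len_diff: int = 4,
) -> List[AnnotatedAssignment]:
    sites = sites or SiteDefinitions()
    out: List[AnnotatedAssignment] = []
    for a in assignments:
        if a.alignment is not None:
            out.append(
                AnnotatedAssignment(
                    assignment=a,
                    label=classify_isomir(a.alignment),
                    profile=annotate_sites(a.alignment, sites),
                    max_len_diff=max_len_diff,
                )
            )
        else:
            out.append(AnnotatedAssignment(assignment=a, max_len_diff=max_len_diff))
    return out


def apply_length_filter(
    annotated: Sequence[AnnotatedAssignment], max_len_diff: int = 4
) -> Tuple[List[AnnotatedAssignment], List[AnnotatedAssignment]]:
    """Split assigned tags into (kept, flagged) by the |miRtag_diff| cap.

    Flagged tags (|miR_size - tag_size| > max_len_diff) are excluded from
    *filtered views* only; the raw reports keep them with flag "f".
    """
    kept: List[AnnotatedAssignment] = []
    flagged: List[AnnotatedAssignment] = []
    for ann in annotated:
        a = ann.assignment
        best = a.alignment or (a.candidates[0] if a.candidates else None)
        if best is not None and abs(best.mirtag_diff) > max_len_diff:
            flagged.append(ann)
        else:
            kept.append(ann)
    if flagged:
        log.info(
            "length filter (|miRtag_diff| > %d): %d tags flagged 'f'",
            max_len_diff,
            len(flagged),
        )
    return kept, flagged


def build_expression_tables(
    annotated: Sequence[AnnotatedAssignment], source: str
) -> List[ExpressionRow]:
    """Aggregate per-miRNA expression from ``unique`` or ``selected`` tags.

    ``selected`` means rescued multi-mapped tags.  Species-excluded tags are
    skipped.  Rows are sorted by descending total_count, then id; per-class
    percentages are recoverable as 100 * class_count / total_count.
    """
    if source not in ("unique", "selected"):
        raise ValueError("source must be 'unique' or 'selected'")
    status = STATUS_UNIQUE if source == "unique" else STATUS_RESCUED
    rows: Dict[str, ExpressionRow] = {}
    for ann in annotated:
        a = ann.assignment
        if a.status != status or a.species_excluded or a.alignment is None:
            continue
        aln = a.alignment
        row = rows.setdefault(
            aln.mature_id, ExpressionRow(mirna_id=aln.mature_id, species=aln.species)
        )
        row.total_count += a.tag.count
        row.n_tags += 1
        token = ann.label.canonical if ann.label else ""
        row.class_counts[token] = row.class_counts.get(token, 0) + a.tag.count
        if ann.profile:
            if ann.profile.offset_conserved:
                row.offset_conserved_reads += a.tag.count
            if ann.profile.supplementary_conserved:
                row.supplementary_conserved_reads += a.tag.count
            if ann.profile.central_conserved:
                row.central_conserved_reads += a.tag.count
    return sorted(rows.values(), key=lambda r: (-r.total_count, r.mirna_id))


def accounting(annotated: Sequence[AnnotatedAssignment]) -> Dict[str, int]:
    """Tag and read counts per accounting bucket.

    The five read buckets (unique, rescued, ambiguous_unresolved, discarded,
    species_excluded) partition the input reads exactly.
    """
    stats = {
        "n_tags": len(annotated),
        "n_reads": sum(a.assignment.tag.count for a in annotated),
    }
    for st in (STATUS_UNIQUE, STATUS_RESCUED, STATUS_AMBIGUOUS, STATUS_DISCARDED):
        sel = [a for a in annotated if a.assignment.status == st]
        kept = [a for a in sel if not a.assignment.species_excluded]
        stats[f"{st}_tags"] = len(kept)
        stats[f"{st}_reads"] = sum(a.assignment.tag.count for a in kept)
    excl = [a for a in annotated if a.assignment.species_excluded]
    stats["species_excluded_tags"] = len(excl)
    stats["species_excluded_reads"] = sum(a.assignment.tag.count for a in excl)
    stats["length_filtered_tags"] = sum(1 for a in annotated if a.flag == FLAG_FILTERED)
    return stats


# ---------------------------------------------------------------------------
# file writers


def _fmt(x) -> str:
    if isinstance(x, bool):
        return "1" if x else "0"
    if isinstance(x, float):
        return f"{x:.2f}"
    return str(x)


def _write_tsv(path: Path, columns: Sequence[str], rows: Sequence[Sequence]) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def _mm_str(positions: Sequence[int]) -> str:
    return ";".join(str(p) for p in positions) if positions else "-"


_TAG_COLUMNS = [
    "sequence", "count", "flag", "mature_id", "species", "isomir",
    "seed_pos", "offset_5p", "delta_3p", "overhang_3p", "mismatch_positions",
    "align_score", "mirtag_diff", "identity_pct",
    "seed_conserved", "offset_conserved", "supplementary_conserved",
    "central_conserved", "sites_combo",
]


def _tag_row(ann: AnnotatedAssignment) -> List:
    a = ann.assignment
    aln = a.alignment
    lab, prof = ann.label, ann.profile
    return [
        a.tag.sequence, a.tag.count, ann.flag, aln.mature_id, aln.species,
        lab.report_token, aln.seed_pos_in_tag, aln.offset_5p, aln.delta_3p,
        aln.overhang_3p, _mm_str(aln.mismatch_positions), aln.align_score,
        aln.mirtag_diff, aln.identity_pct, prof.seed_conserved,
        prof.offset_conserved, prof.supplementary_conserved,
        prof.central_conserved, prof.combo,
    ]


def _sorted_by_tag(anns: List[AnnotatedAssignment]) -> List[AnnotatedAssignment]:
    return sorted(anns, key=lambda x: (-x.assignment.tag.count, x.assignment.tag.sequence))


_EXPR_COLUMNS = [
    "mirna_id", "species", "total_count", "n_tags",
    *ISOMIR_TOKENS,
    "offset_conserved_reads", "supplementary_conserved_reads", "central_conserved_reads",
]


def _expr_rows(rows: Sequence[ExpressionRow]) -> List[List]:
    out = []
    for r in rows:
        out.append(
            [r.mirna_id, r.species, r.total_count, r.n_tags]
            + [r.class_count(t) for t in ISOMIR_TOKENS]
            + [r.offset_conserved_reads, r.supplementary_conserved_reads,
               r.central_conserved_reads]
        )
    return out


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Round-trip reader for the miRNA expression TSVs."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().lstrip("#").strip().split("\t")
    return pd.read_csv(path, sep="\t", skiprows=1, names=header)


def write_outputs(
    annotated: Sequence[AnnotatedAssignment],
    out_dir: str | Path,
    stats: Optional[Dict[str, int]] = None,
) -> Dict[str, Path]:
    """Write the nine report files; returns name -> path."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise PipelineError("output", f"output directory {out} not writable: {exc}")

    stats = dict(stats or accounting(annotated))
    by_status: Dict[str, List[AnnotatedAssignment]] = {}
    for ann in annotated:
        by_status.setdefault(ann.assignment.status, []).append(ann)

    paths: Dict[str, Path] = {}

    # 1: unique tags
    rows = [_tag_row(a) for a in _sorted_by_tag(by_status.get(STATUS_UNIQUE, []))]
    paths["unique_tags.tsv"] = out / "unique_tags.tsv"
    _write_tsv(paths["unique_tags.tsv"], _TAG_COLUMNS, rows)

    # 2: ambiguous tags = every multi-candidate tag, resolved or not
    amb_cols = [
        "sequence", "count", "flag", "resolved", "candidate_count",
        "family_count", "second_best_gap", "candidates",
    ]
    amb = [
        a for a in annotated
        if a.assignment.candidate_count >= 2
    ]
    amb_rows = []
    for ann in _sorted_by_tag(amb):
        a = ann.assignment
        cand = ";".join(
            f"{c.mature_id}:{c.align_score:.2f}:{c.mirtag_diff}" for c in a.candidates
        )
        amb_rows.append([
            a.tag.sequence, a.tag.count, ann.flag,
            "yes" if a.status == STATUS_RESCUED else "no",
            a.candidate_count, a.family_count, a.second_best_gap, cand,
        ])
    paths["ambiguous_tags.tsv"] = out / "ambiguous_tags.tsv"
    _write_tsv(paths["ambiguous_tags.tsv"], amb_cols, amb_rows)

    # 3: rescued tags
    resc_cols = _TAG_COLUMNS + ["candidate_count", "family_count", "second_best_gap"]
    resc_rows = [
        _tag_row(a) + [a.assignment.candidate_count, a.assignment.family_count,
                       a.assignment.second_best_gap]
        for a in _sorted_by_tag(by_status.get(STATUS_RESCUED, []))
    ]
    paths["rescued_tags.tsv"] = out / "rescued_tags.tsv"
    _write_tsv(paths["rescued_tags.tsv"], resc_cols, resc_rows)

    # 4: discarded tags
    disc_rows = [
        [a.assignment.tag.sequence, a.assignment.tag.count, FLAG_UNDETECTED,
         a.assignment.rejection_reason or "no_seed"]
        for a in _sorted_by_tag(by_status.get(STATUS_DISCARDED, []))
    ]
    paths["discarded_tags.tsv"] = out / "discarded_tags.tsv"
    _write_tsv(paths["discarded_tags.tsv"], ["sequence", "count", "flag", "reason"], disc_rows)

    # 5 & 6: expression tables
    for source, name in (("unique", "mirna_expression_unique.tsv"),
                         ("selected", "mirna_expression_selected.tsv")):
        table = build_expression_tables(annotated, source)
        paths[name] = out / name
        _write_tsv(paths[name], _EXPR_COLUMNS, _expr_rows(table))

    # 7: isomiR summary over unique + rescued tags (focal species only)
    assigned = [
        a for a in annotated
        if a.assignment.alignment is not None and not a.assignment.species_excluded
    ]
    total_reads = sum(a.assignment.tag.count for a in assigned)
    iso_counts: Dict[str, List[int]] = {}
    for ann in assigned:
        tok = ann.label.report_token
        entry = iso_counts.setdefault(tok, [0, 0])
        entry[0] += 1
        entry[1] += ann.assignment.tag.count
    iso_rows = [
        [tok, nt, nr, (100.0 * nr / total_reads) if total_reads else 0.0]
        for tok, (nt, nr) in sorted(iso_counts.items(), key=lambda kv: (-kv[1][1], kv[0]))
    ]
    paths["isomir_summary.tsv"] = out / "isomir_summary.tsv"
    _write_tsv(paths["isomir_summary.tsv"], ["isomir", "n_tags", "reads", "pct_reads"], iso_rows)

    # 8: interaction-sites summary
    site_counts: Dict[str, List[int]] = {}
    for ann in assigned:
        combo = ann.profile.combo
        entry = site_counts.setdefault(combo, [0, 0])
        entry[0] += 1
        entry[1] += ann.assignment.tag.count
    site_rows = [
        [combo, nt, nr, (100.0 * nr / total_reads) if total_reads else 0.0]
        for combo, (nt, nr) in sorted(site_counts.items(), key=lambda kv: (-kv[1][1], kv[0]))
    ]
    paths["sites_summary.tsv"] = out / "sites_summary.tsv"
    _write_tsv(paths["sites_summary.tsv"], ["sites_combo", "n_tags", "reads", "pct_reads"], site_rows)

    # 9: run stats
    stat_rows = [[k, v] for k, v in sorted(stats.items())]
    paths["run_stats.tsv"] = out / "run_stats.tsv"
    _write_tsv(paths["run_stats.tsv"], ["key", "value"], stat_rows)
    for k, v in sorted(stats.items()):
        log.info("run_stats %s=%s", k, v)
    return paths


def run_pipeline(config: RunConfig, write: bool = True) -> RunResult:
    """Execute blocks a -> b -> c; deterministic for identical inputs.

    Raises :class:`PipelineError` with a stage tag on any fatal error.
    """
    # block a: pre-processing
    try:
        references = load_mature_references(config.mature_path, config.species)
        index = build_seed_index(references, config.params)
        if config.tags_path:
            tags = read_tag_counts(config.tags_path)
        elif config.reads_path:
            tags = collapse_reads(config.reads_path)
        else:
            raise InputError("either tags_path or reads_path must be provided")
    except InputError as exc:
        raise PipelineError("pre-processing", str(exc)) from exc
    log.info("pre-processing: %d references, %d seed groups, %d tags",
             len(references), len(index.mapping), len(tags))

    # block b: alignment
    results = align_all(tags, index, config.params)
    n_hit = sum(1 for r in results.values() if r.alignments)
    log.info("alignment: %d/%d tags with >= 1 accepted alignment", n_hit, len(tags))

    # block c: resolution, annotation, output
    assignments = resolve_all(results, config.focal_species, config.params.seed_len)
    annotated = annotate_assignments(
        assignments, config.sites, config.params.max_len_diff
    )
    stats = accounting(annotated)
    stats["n_references"] = len(references)
    stats["n_seed_groups"] = len(index.mapping)
    if write:
        if not config.out_dir:
            raise PipelineError("output", "no output directory configured")
        write_outputs(annotated, config.out_dir, stats)
    return RunResult(references=references, index=index, tags=tags,
                     annotated=annotated, stats=stats)
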