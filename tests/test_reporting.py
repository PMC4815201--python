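"""Expression tables, the nine report files, length filter, and the pipeline."""

import hashlib
import random
from pathlib import Path

import pytest

from isomirsea import (
    MatureRecord,
    RunConfig,
    TagRecord,
    apply_length_filter,
    build_expression_tables,
    run_pipeline,
    write_tag_counts,
)
from isomirsea.reporting import (
    OUTPUT_FILES,
    PipelineError,
    accounting,
    annotate_assignments,
    read_expression_table,
    write_outputs,
)
from isomirsea.resolver import STATUS_UNIQUE, Assignment, resolve_all
from isomirsea.seed_aligner import align_all
from isomirsea.synthetic import (
    default_corpus_specs,
    generate_reference,
    generate_tags,
    write_reference_fasta,
)

from conftest import REF_SEQ, substitute, write_fasta


def _annotated_single(tag_seq, count, mature_seq=REF_SEQ, mature_id="hsa-a", pos=2):
    from isomirsea import AlignmentParams, extend_ungapped
    from isomirsea.seed_aligner import Alignment, SeedAnchor

    params = AlignmentParams()
    m = MatureRecord(mature_id, "hsa", mature_seq)
    aln = extend_ungapped(tag_seq, m, SeedAnchor(m, pos), params)
    assert isinstance(aln, Alignment)
    a = Assignment(
        tag=TagRecord(tag_seq, count), status=STATUS_UNIQUE, alignment=aln,
        candidates=[aln], candidate_count=1, family_count=1,
    )
    return annotate_assignments([a])[0]


class TestExpressionTables:
    def test_single_exact_tag_aggregates_to_one_row(self):
        ann = _annotated_single(REF_SEQ, 7)
        rows = build_expression_tables([ann], "unique")
        assert len(rows) == 1
        row = rows[0]
        assert row.total_count == 7 and row.n_tags == 1
        assert row.class_count("mirna_exact") == 7
        assert sum(row.class_counts.values()) == row.total_count

    def test_class_percentages_recoverable_from_counts(self):
        iso3 = _annotated_single(REF_SEQ[:-2], 3)  # iso_3p
        snp = _annotated_single(substitute(REF_SEQ, 12), 1)  # iso_snp
        rows = build_expression_tables([iso3, snp], "unique")
        row = rows[0]
        assert row.total_count == 4
        assert 100 * row.class_count("iso_3p") / row.total_count == 75.0
        assert 100 * row.class_count("iso_snp") / row.total_count == 25.0

    def test_no_assigned_tags_gives_empty_table(self):
        assert build_expression_tables([], "unique") == []
        assert build_expression_tables([], "selected") == []


class TestLengthFilter:
    def test_worked_example_tags_flagged_f(self):
        """A 26-nt mature with 21- and 20-nt tags: |miRtag_diff| = 5 and 6,
        both past the +/-4 cap, so both are detected but flagged."""
        mature_26 = REF_SEQ + "CGGA"
        t21 = _annotated_single(mature_26[:21], 1, mature_26, "hsa-long")
        t20 = _annotated_single(mature_26[:20], 1, mature_26, "hsa-long")
        t22 = _annotated_single(REF_SEQ, 1)
        assert t21.assignment.alignment.mirtag_diff == 5
        assert t20.assignment.alignment.mirtag_diff == 6
        kept, flagged = apply_length_filter([t21, t20, t22], max_len_diff=4)
        assert [a.assignment.tag.sequence for a in flagged] == [mature_26[:21], mature_26[:20]]
        assert [a.flag for a in flagged] == ["f", "f"]
        assert kept == [t22] and t22.flag == "d"

    def test_flagged_tags_stay_in_expression_tables(self):
        mature_26 = REF_SEQ + "CGGA"
        t21 = _annotated_single(mature_26[:21], 4, mature_26, "hsa-long")
        rows = build_expression_tables([t21], "unique")
        assert rows and rows[0].total_count == 4


class TestWriteOutputs:
    def test_empty_input_writes_nine_header_only_files(self, tmp_path):
        paths = write_outputs([], tmp_path)
        assert set(paths) == set(OUTPUT_FILES)
        for name, p in paths.items():
            lines = Path(p).read_text().splitlines()
            data = [l for l in lines if not l.startswith("#")]
            if name == "run_stats.tsv":
                assert any(l.startswith("n_tags\t0") for l in data)
            else:
                assert data == []

    def test_single_unique_tag_appears_in_tag_and_expression_files(self, tmp_path):
        ann = _annotated_single(REF_SEQ, 7)
        paths = write_outputs([ann], tmp_path)
        unique_rows = [
            l for l in Path(paths["unique_tags.tsv"]).read_text().splitlines()
            if not l.startswith("#")
        ]
        assert len(unique_rows) == 1 and unique_rows[0].startswith(REF_SEQ + "\t7\td")
        expr = read_expression_table(paths["mirna_expression_unique.tsv"])
        assert list(expr["mirna_id"]) == ["hsa-a"]
        assert list(expr["total_count"]) == [7]
        assert list(expr["mirna_exact"]) == [7]

    def test_expression_round_trip(self, tmp_path):
        anns = [
            _annotated_single(REF_SEQ, 7),
            _annotated_single(REF_SEQ[:-2], 3),
            _annotated_single(substitute(REF_SEQ, 12), 2),
        ]
        paths = write_outputs(anns, tmp_path)
        df = read_expression_table(paths["mirna_expression_unique.tsv"])
        rows = build_expression_tables(anns, "unique")
        assert list(df["mirna_id"]) == [r.mirna_id for r in rows]
        assert list(df["total_count"]) == [r.total_count for r in rows]
        assert list(df["iso_3p"]) == [r.class_count("iso_3p") for r in rows]


class TestPipeline:
    def _corpus(self, tmp_path, rng_seed=7):
        records = generate_reference(20, rng_seed=rng_seed)
        tags, _ = generate_tags(records, default_corpus_specs(5), rng_seed=rng_seed)
        ref = tmp_path / "ref.fa"
        tab = tmp_path / "tags.tsv"
        write_reference_fasta(records, ref)
        write_tag_counts(tags, tab)
        return ref, tab

    def test_minimal_fixture_produces_nine_files(self, tmp_path):
        ref = write_fasta(tmp_path / "ref.fa", [("hsa-a", REF_SEQ)])
        tab = tmp_path / "tags.tsv"
        tab.write_text(f"{REF_SEQ}\t5\n")
        out = tmp_path / "out"
        result = run_pipeline(RunConfig(mature_path=str(ref), tags_path=str(tab), out_dir=str(out)))
        assert sorted(p.name for p in out.iterdir()) == sorted(OUTPUT_FILES)
        assert result.stats["unique_tags"] == 1

    def test_missing_reference_fails_in_preprocessing(self, tmp_path):
        cfg = RunConfig(mature_path=str(tmp_path / "absent.fa"), tags_path="x", out_dir=str(tmp_path))
        with pytest.raises(PipelineError) as err:
            run_pipeline(cfg)
        assert err.value.stage == "pre-processing"

    def test_read_counts_are_conserved_across_buckets(self, tmp_path):
        ref, tab = self._corpus(tmp_path)
        result = run_pipeline(
            RunConfig(mature_path=str(ref), tags_path=str(tab), out_dir=str(tmp_path / "o"))
        )
        st = result.stats
        buckets = (
            st["unique_reads"] + st["rescued_reads"]
            + st["ambiguous_unresolved_reads"] + st["discarded_reads"]
            + st["species_excluded_reads"]
        )
        assert buckets == st["n_reads"]
        assert st["n_reads"] == sum(t.count for t in result.tags)

    def test_runs_are_byte_identical_even_with_shuffled_inputs(self, tmp_path):
        ref, tab = self._corpus(tmp_path)

        def run_into(out, ref_path, tab_path):
            run_pipeline(RunConfig(mature_path=str(ref_path), tags_path=str(tab_path), out_dir=str(out)))
            return {
                name: hashlib.sha256((Path(out) / name).read_bytes()).hexdigest()
                for name in OUTPUT_FILES
            }

        h1 = run_into(tmp_path / "o1", ref, tab)
        h2 = run_into(tmp_path / "o2", ref, tab)
        assert h1 == h2

        # shuffle both inputs: results must not depend on input order
        rng = random.Random(1)
        ref_lines = Path(ref).read_text().strip().split("\n")
        fasta_records = [(ref_lines[i], ref_lines[i + 1]) for i in range(0, len(ref_lines), 2)]
        rng.shuffle(fasta_records)
        ref2 = tmp_path / "ref_shuf.fa"
        ref2.write_text("".join(f"{h}\n{s}\n" for h, s in fasta_records))
        tab_lines = Path(tab).read_text().strip().split("\n")
        rng.shuffle(tab_lines)
        tab2 = tmp_path / "tags_shuf.tsv"
        tab2.write_text("\n".join(tab_lines) + "\n")
        h3 = run_into(tmp_path / "o3", ref2, tab2)
        assert h1 == h3

    def test_species_competition_removes_foreign_winners_from_expression(self, tmp_path):
        # an mml mature identical to the tag beats a shorter hsa mature
        hsa = REF_SEQ
        mml = REF_SEQ + "CG"
        ref = write_fasta(tmp_path / "ref.fa", [("hsa-a", hsa), ("mml-a", mml)])
        tab = tmp_path / "tags.tsv"
        tab.write_text(f"{mml}\t9\n{hsa}\t4\n")
        result = run_pipeline(
            RunConfig(
                mature_path=str(ref), tags_path=str(tab),
                out_dir=str(tmp_path / "o"), focal_species="hsa",
            )
        )
        st = result.stats
        assert st["species_excluded_reads"] == 9
        df = read_expression_table(tmp_path / "o" / "mirna_expression_unique.tsv")
        assert "mml-a" not in set(df["mirna_id"])


def test_accounting_counts_length_filtered_tags():
    mature_26 = REF_SEQ + "CGGA"
    anns = [
        _annotated_single(mature_26[:21], 1, mature_26, "hsa-long"),
        _annotated_single(REF_SEQ, 2),
    ]
    st = accounting(anns)
    assert st["length_filtered_tags"] == 1
    assert st["n_reads"] == 3
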