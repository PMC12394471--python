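"""GO transfer from tabular hits: parsing, filtering, collapse, summary I/O."""

import io
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from goforge.annotation import (AnnotationRecord, SearchParams, annotation_table,
                                collapse_annotations, filter_hits, parse_tabular,
                                queries_without_hits, read_summary,
                                run_or_load_search, transfer_annotations,
                                write_summary)
from goforge.decoration import parse_decoration
from goforge.errors import (ConfigurationError, InputError, TabularParseError)
from goforge.simulate import generate_queries_and_hits, generate_reference

ROW = "q1\ts1\t90.0\t100\t10\t0\t1\t100\t1\t100\t{ev}\t180.0\ts1 title"


def make_hit_row(qid, sid, evalue, bit=180.0, title=""):
    return (f"{qid}\t{sid}\t90.0\t100\t10\t0\t1\t100\t1\t100\t{evalue}\t{bit}"
            f"\t{title or sid + ' plain title'}")


class TestParseTabular:
    def test_parses_12_and_13_column_rows(self):
        hits = parse_tabular(ROW.format(ev="1e-20") + "\n"
                             + ROW.format(ev="1e-5").rsplit("\t", 1)[0] + "\n")
        assert len(hits) == 2
        assert hits[0].subject_title == "s1 title"
        assert hits[1].subject_title == ""

    def test_wrong_column_count_reports_line_number(self):
        with pytest.raises(TabularParseError, match="line 2"):
            parse_tabular(ROW.format(ev="1e-20") + "\nq1\ts1\tbroken\n")

    def test_bad_numeric_field_reports_line_number(self):
        with pytest.raises(TabularParseError, match="line 1"):
            parse_tabular(ROW.format(ev="not-a-number"))

    def test_negative_evalue_rejected(self):
        with pytest.raises(TabularParseError, match="negative"):
            parse_tabular(ROW.format(ev="-1e-5"))


class TestFilterHits:
    def test_cutoff_excludes_rows_above_threshold(self):
        text = "\n".join([make_hit_row("q1", "s1", "1e-20"),
                          make_hit_row("q1", "s2", "1e-3"),
                          make_hit_row("q2", "s1", "1e-8")])
        params = SearchParams(evalue_cutoff=1e-5, max_target_seqs=5)
        kept = filter_hits(parse_tabular(text), params)
        assert {(h.query_id, h.subject_id) for h in kept} \
            == {("q1", "s1"), ("q2", "s1")}

    def test_empty_stream_gives_empty_list(self):
        assert run_or_load_search(precomputed=io.StringIO("")) == []

    def test_max_target_seqs_keeps_best_subjects(self):
        text = "\n".join([make_hit_row("q1", "sB", "1e-10"),
                          make_hit_row("q1", "sA", "1e-30"),
                          make_hit_row("q1", "sA", "1e-12")])
        kept = filter_hits(parse_tabular(text), SearchParams(max_target_seqs=1))
        assert {h.subject_id for h in kept} == {"sA"}
        assert len(kept) == 2  # both rows of the winning subject survive

    def test_matches_brute_force_filter_on_planted_fixture(self):
        ref = generate_reference(n_genes=100, n_terms=25, seed=61)
        sim = generate_queries_and_hits(ref.truth, mutation_rate=0.01,
                                        n_decoys=80, seed=62)
        params = SearchParams(evalue_cutoff=1e-5, max_target_seqs=10)
        kept = filter_hits(parse_tabular(sim.hits_tsv), params)
        truth_rows = [l.split("\t") for l in sim.hits_tsv.splitlines()]
        expected = {(r[0], r[1], r[10]) for r in truth_rows
                    if float(r[10]) <= 1e-5}
        assert {(h.query_id, h.subject_id, f"{h.evalue:.3e}") for h in kept} \
            == expected

    def test_no_aligner_and_no_precomputed_is_config_error(self):
        with pytest.raises(ConfigurationError, match="not found"):
            run_or_load_search(queries="q.faa", reference="db",
                               binary="definitely-not-a-real-aligner")

    def test_invalid_params_rejected(self):
        with pytest.raises(InputError):
            SearchParams(evalue_cutoff=0.0)
        with pytest.raises(InputError):
            SearchParams(max_target_seqs=0)


class TestParseDecorationExamples:
    def test_single_term_grammar_instance(self):
        terms = parse_decoration("acc x GN=S TAX=9606 GO=GO:0003824!IEA!Function")
        assert len(terms) == 1 and terms[0].not_flag is False
        assert terms[0].go_id == "GO:0003824"

    def test_undecorated_title_gives_empty_list(self):
        assert parse_decoration("NP_1.1 hypothetical protein") == []

    def test_truncated_block_raises_with_title(self):
        with pytest.raises(TabularParseError, match="truncated"):
            parse_decoration("acc GN=S TAX=9606 GO=GO:0000001!IEA")

    def test_thousand_random_titles_invert_exactly(self):
        ref = generate_reference(n_genes=600, n_terms=40, seed=71,
                                 accessions_per_gene=(1, 2))
        sim = generate_queries_and_hits(ref.truth, seed=72,
                                        n_queries=1000)
        checked = 0
        by_acc = {r.accession: r for r in ref.truth.reference_records}
        for line in sim.hits_tsv.splitlines():
            cols = line.split("\t")
            rec = by_acc[cols[1]]
            got = {(t.go_id, t.evidence, t.category, t.not_flag)
                   for t in parse_decoration(cols[12])}
            expected = {(a.go_id, a.evidence, a.category, a.not_flag)
                        for a in rec.assignments}
            assert got == expected
            checked += 1
        assert checked == 1000


class TestTransferAnnotations:
    def test_not_qualified_terms_excluded(self):
        title = "s1 x GN=S TAX=9606 GO=GO:0000001!IEA!Process;GO:0000002!IDA!Function!NOT"
        hits = parse_tabular(make_hit_row("q1", "s1", "1e-20", title=title))
        records = transfer_annotations(hits)
        assert [r.go_id for r in records] == ["GO:0000001"]
        assert records[0].evalue == 1e-20
        assert records[0].source_symbol == "S"

    def test_empty_decoration_transfers_nothing(self):
        hits = parse_tabular(make_hit_row("q1", "s1", "1e-20"))
        assert transfer_annotations(hits) == []

    def test_count_equals_truth_minus_planted_not_terms(self):
        ref = generate_reference(n_genes=150, n_terms=30, seed=81)
        sim = generate_queries_and_hits(ref.truth, seed=82)
        hits = parse_tabular(sim.hits_tsv)
        records = transfer_annotations(hits)
        by_acc = {r.accession: r for r in ref.truth.reference_records}
        total = sum(len(by_acc[q.source_accession].assignments)
                    for q in ref.truth.query_records)
        planted_not = sum(
            sum(a.not_flag for a in by_acc[q.source_accession].assignments)
            for q in ref.truth.query_records)
        assert planted_not > 0  # the ~10% NOT rate actually planted some
        assert len(records) == total - planted_not


def rec(q, go, ev, bit=0.0, sid="", prov="similarity"):
    return AnnotationRecord(query_id=q, go_id=go, evidence="IEA",
                            category="Process", evalue=ev, bit_score=bit,
                            subject_id=sid, provenance=prov)


class TestCollapseAnnotations:
    def test_lowest_evalue_survives(self):
        out = collapse_annotations([rec("q", "GO:0000001", 1e-10),
                                    rec("q", "GO:0000001", 1e-20)])
        assert len(out) == 1 and out[0].evalue == 1e-20

    def test_tie_break_bit_score_then_subject(self):
        out = collapse_annotations([rec("q", "GO:0000001", 1e-10, bit=50, sid="sB"),
                                    rec("q", "GO:0000001", 1e-10, bit=90, sid="sC"),
                                    rec("q", "GO:0000001", 1e-10, bit=90, sid="sA")])
        assert out[0].bit_score == 90 and out[0].subject_id == "sA"

    def test_idempotent_on_unique_input(self):
        records = [rec("q1", "GO:0000001", 1e-10), rec("q2", "GO:0000002", 1e-9)]
        once = collapse_annotations(records)
        assert collapse_annotations(once) == once
        assert set(once) == set(records)

    def test_matches_group_by_min_oracle_on_random_records(self, rng):
        records = []
        for _ in range(5000):
            q = f"q{rng.integers(0, 60)}"
            go = f"GO:{int(rng.integers(1, 40)):07d}"
            ev = float(10.0 ** rng.uniform(-40, -2))
            records.append(rec(q, go, ev, bit=float(rng.integers(0, 500)),
                               sid=f"s{rng.integers(0, 30)}"))
        out = collapse_annotations(records)
        # brute-force scan per key
        oracle: dict = {}
        for r in records:
            key = (r.query_id, r.go_id)
            cur = oracle.get(key)
            if cur is None or (r.evalue, -r.bit_score, r.subject_id) < \
                    (cur.evalue, -cur.bit_score, cur.subject_id):
                oracle[key] = r
        assert {(r.query_id, r.go_id): r.evalue for r in out} \
            == {k: v.evalue for k, v in oracle.items()}

    @given(st.permutations(list(range(12))))
    def test_order_independent(self, perm):
        base = [rec(f"q{i % 3}", f"GO:{(i % 4) + 1:07d}", 10.0 ** -(i + 2),
                    bit=float(i), sid=f"s{i}") for i in range(12)]
        shuffled = [base[i] for i in perm]
        assert collapse_annotations(shuffled) == collapse_annotations(base)


class TestSummaryIO:
    def test_zero_records_header_only(self):
        buf = io.StringIO()
        assert write_summary([], buf) == 0
        assert buf.getvalue() == "#query_id\tsymbol\ttaxon\tgo_terms\n"

    def test_two_terms_one_row(self):
        buf = io.StringIO()
        n = write_summary([rec("q1", "GO:0000002", 1e-10),
                           rec("q1", "GO:0000001", 1e-20)], buf)
        assert n == 1
        body = buf.getvalue().splitlines()[1]
        assert body.count(";") == 1
        assert body.index("GO:0000001") < body.index("GO:0000002")

    def test_round_trip_reconstructs_every_field(self):
        ref = generate_reference(n_genes=80, n_terms=25, seed=91)
        sim = generate_queries_and_hits(ref.truth, seed=92)
        hits = filter_hits(parse_tabular(sim.hits_tsv), SearchParams())
        records = collapse_annotations(transfer_annotations(hits))
        buf = io.StringIO()
        write_summary(records, buf)
        back = read_summary(buf.getvalue())
        assert {(r.query_id, r.go_id, r.evidence, r.category, r.evalue)
                for r in back} \
            == {(r.query_id, r.go_id, r.evidence, r.category, r.evalue)
                for r in records}


class TestEndToEnd:
    def test_planted_homologs_fully_recovered(self):
        """Every non-NOT term of the source passes through at low mutation."""
        ref = generate_reference(n_genes=120, n_terms=30, seed=111)
        sim = generate_queries_and_hits(ref.truth, mutation_rate=0.02,
                                        n_decoys=100, seed=112)
        hits = filter_hits(parse_tabular(sim.hits_tsv),
                           SearchParams(evalue_cutoff=1e-5))
        records = collapse_annotations(transfer_annotations(hits))
        table = annotation_table(records)
        for qid, expected in ref.truth.expected_transfer_sets().items():
            assert table.get(qid, set()) == expected

    def test_output_never_violates_cutoff_or_not_rule(self):
        ref = generate_reference(n_genes=60, n_terms=25, seed=121)
        sim = generate_queries_and_hits(ref.truth, n_decoys=60, seed=122)
        params = SearchParams(evalue_cutoff=1e-5)
        hits = filter_hits(parse_tabular(sim.hits_tsv), params)
        records = collapse_annotations(transfer_annotations(hits))
        by_acc = {r.accession: r for r in ref.truth.reference_records}
        not_terms = {(q.query_id, a.go_id)
                     for q in ref.truth.query_records
                     for a in by_acc[q.source_accession].assignments
                     if a.not_flag}
        for r in records:
            assert r.evalue <= params.evalue_cutoff
            assert (r.query_id, r.go_id) not in not_terms

    def test_no_hit_queries_listed_for_domain_scan_routing(self):
        ref = generate_reference(n_genes=30, n_terms=20, seed=131)
        sim = generate_queries_and_hits(ref.truth, seed=132)
        # keep only half the hits below an artificially strict cutoff
        hits = filter_hits(parse_tabular(sim.hits_tsv),
                           SearchParams(evalue_cutoff=1e-25))
        all_ids = [q.query_id for q in ref.truth.query_records]
        missing = queries_without_hits(all_ids, hits)
        assert missing == set(all_ids) - {h.query_id for h in hits}
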