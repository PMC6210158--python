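"""Alignment records, I/O dialects, the seed-and-chain aligner, and the
best-hit query filter."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refgap.alignment import (
    RELAXED,
    STRICT,
    AlignParams,
    AlignmentRecord,
    align,
    best_hit_filter,
    read_alignments,
    revcomp,
    write_alignments,
)
from refgap.errors import ConfigError, ParseError, ValidationError
from refgap.simulate import SimulationConfig, random_sequence


def test_align_params_validation():
    with pytest.raises(ConfigError):
        AlignParams(min_match_len=10)
    with pytest.raises(ConfigError):
        AlignParams(min_match_len=100, min_cluster_len=50)


class TestAlignmentIO:
    def test_paf_identity(self, tmp_path):
        path = tmp_path / "a.paf"
        path.write_text("q\t100\t0\t50\t+\tt\t1000\t10\t60\t45\t50\t0\n")
        (rec,) = read_alignments(path, "paf")
        assert rec.identity == pytest.approx(0.90)
        assert (rec.query_start, rec.query_end) == (0, 50)
        assert (rec.target_start, rec.target_end) == (10, 60)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.paf"
        path.write_text("")
        assert read_alignments(path, "paf") == []

    def test_malformed_line_reports_number(self, tmp_path):
        path = tmp_path / "bad.paf"
        path.write_text("q\t100\t0\t50\t+\tt\t1000\t10\t60\t45\t50\t0\nbroken line\n")
        with pytest.raises(ParseError, match="2"):
            read_alignments(path, "paf")

    def test_coordinate_violation(self, tmp_path):
        path = tmp_path / "bad.paf"
        # query_end > query_length
        path.write_text("q\t40\t0\t50\t+\tt\t1000\t10\t60\t45\t50\t0\n")
        with pytest.raises(ValidationError):
            read_alignments(path, "paf")

    def test_coords_is_one_based_inclusive(self, tmp_path):
        path = tmp_path / "a.coords"
        path.write_text(
            "query\tqstart\tqend\ttarget\ttstart\ttend\tstrand\tmatches\tspan\tidentity\n"
            "q\t1\t50\tt\t11\t60\t+\t45\t50\t0.9\n"
        )
        (rec,) = read_alignments(path, "coords")
        assert (rec.query_start, rec.query_end) == (0, 50)
        assert (rec.target_start, rec.target_end) == (10, 60)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        rows=st.lists(
            st.tuples(
                st.integers(0, 500),  # qstart
                st.integers(1, 500),  # q span
                st.integers(0, 500),  # tstart
                st.integers(1, 500),  # t span extra
                st.integers(1, 400),  # matches
                st.sampled_from("+-"),
            ),
            min_size=0,
            max_size=8,
        ),
        dialect=st.sampled_from(["paf", "coords"]),
    )
    def test_round_trip(self, tmp_path_factory, rows, dialect):
        records = []
        for i, (qs, qspan, ts, tspan, matches, strand) in enumerate(rows):
            span = max(qspan, tspan, matches)
            records.append(
                AlignmentRecord(
                    query_id=f"q{i}", query_start=qs, query_end=qs + qspan,
                    target_id="t", target_start=ts, target_end=ts + tspan,
                    strand=strand, matches=min(matches, span), alignment_span=span,
                    query_length=qs + qspan + 5, target_length=ts + tspan + 5,
                )
            )
        path = tmp_path_factory.mktemp("rt") / f"a.{dialect}"
        write_alignments(path, records, dialect)
        back = read_alignments(path, dialect)
        fields = ("query_id", "query_start", "query_end", "target_id",
                  "target_start", "target_end", "strand", "matches", "alignment_span")
        assert [[getattr(r, f) for f in fields] for r in back] == [
            [getattr(r, f) for f in fields] for r in records
        ]


class TestAligner:
    def test_exact_copy_full_identity(self, rng):
        target = random_sequence(rng, 5000, 0.41)
        recs = align({"q": target}, {"t": target}, STRICT)
        assert len(recs) == 1
        rec = recs[0]
        assert rec.identity == 1.0
        assert (rec.query_start, rec.query_end) == (0, 5000)
        assert (rec.target_start, rec.target_end) == (0, 5000)
        assert rec.strand == "+"

    def test_random_gc_matched_query_finds_nothing(self, rng):
        target = random_sequence(rng, 5000, 0.41)
        query = random_sequence(rng, 5000, 0.41)
        assert align({"q": query}, {"t": target}, STRICT) == []

    def test_implanted_query_located(self, rng):
        query = random_sequence(rng, 2000, 0.41)
        target = random_sequence(rng, 1000, 0.41) + query + random_sequence(rng, 1000, 0.41)
        recs = align({"q": query}, {"t": target}, STRICT)
        assert len(recs) == 1
        assert recs[0].target_start == 1000
        assert recs[0].target_end == 3000

    def test_reverse_strand(self, rng):
        query = random_sequence(rng, 2000, 0.41)
        target = revcomp(query)
        (rec,) = align({"q": query}, {"t": target}, STRICT)
        assert rec.strand == "-"
        assert (rec.query_start, rec.query_end) == (0, 2000)
        assert rec.identity == 1.0

    def test_query_order_invariance(self, rng):
        target = {"t": random_sequence(rng, 20000, 0.41)}
        q1 = target["t"][2000:5000]
        q2 = target["t"][9000:14000]
        a = align({"a": q1, "b": q2}, target, STRICT)
        b = align({"b": q2, "a": q1}, target, STRICT)
        assert a == b

    def test_n_bases_never_seed(self):
        target = {"t": "N" * 5000}
        assert align({"q": "N" * 5000}, target, RELAXED) == []

    def test_empty_query_set(self, rng):
        assert align({}, {"t": random_sequence(rng, 1000, 0.5)}, STRICT) == []

    def test_substitutions_chain_across(self, rng):
        # one substitution every ~1 kb: a single chain spans the whole query
        from refgap.simulate import mutate_sequence

        target = random_sequence(rng, 20000, 0.41)
        query = mutate_sequence(target, 0.001, rng)
        recs = align({"q": query}, {"t": target}, STRICT)
        assert len(recs) == 1
        assert recs[0].identity >= 1 - 0.001 - 0.01
        span = recs[0].query_end - recs[0].query_start
        assert span >= 0.99 * len(query)

    def test_no_implant_assembly_coverage(self, rng):
        """>= 99% of non-novel contig bases align at near-backbone identity."""
        from refgap.discovery import unaligned_segments
        from refgap.simulate import (
            SimulationConfig, contigs_to_dict, simulate_assembly, simulate_reference,
        )

        cfg = SimulationConfig(seed=11, n_chromosomes=1, chrom_length=100_000,
                               n_novel_segments=0, include_decoy_implant=False)
        ref, cen, decoy = simulate_reference(cfg)
        contigs, truth = simulate_assembly(ref, cfg, "d0", cen, decoy)
        assert truth.implanted_segments == []
        cd = contigs_to_dict(contigs)
        recs = best_hit_filter(align(cd, ref, STRICT))
        assert all(r.identity >= 1 - cfg.divergence_rate - 0.01 for r in recs)
        total = sum(len(s) for s in cd.values())
        holes = unaligned_segments({c: len(s) for c, s in cd.items()}, recs, min_segment=1)
        uncovered = sum(e - s for ivs in holes.values() for s, e in ivs)
        assert uncovered <= 0.01 * total


def _rec(q, qs, qe, matches, target="t", ts=0, identity_span=None):
    span = identity_span or (qe - qs)
    return AlignmentRecord(
        query_id=q, query_start=qs, query_end=qe, target_id=target,
        target_start=ts, target_end=ts + (qe - qs), strand="+",
        matches=matches, alignment_span=max(span, matches),
        query_length=10_000, target_length=100_000,
    )


class TestBestHitFilter:
    def test_disjoint_records_both_kept(self):
        recs = [_rec("q", 0, 100, 90), _rec("q", 200, 300, 80)]
        assert best_hit_filter(recs) == sorted(recs, key=lambda r: r.query_start)

    def test_same_interval_higher_weight_wins(self):
        keep = _rec("q", 0, 100, 500, identity_span=500)
        drop = _rec("q", 0, 100, 400, identity_span=400)
        assert best_hit_filter([drop, keep]) == [keep]

    def test_idempotent(self, rng):
        recs = []
        for i in range(30):
            qs = int(rng.integers(0, 500))
            qe = qs + int(rng.integers(20, 200))
            recs.append(_rec("q", qs, qe, int(rng.integers(10, 300)), ts=int(rng.integers(0, 1000))))
        once = best_hit_filter(recs)
        assert best_hit_filter(once) == once

    def test_overlap_tolerance(self):
        # 10 bp of overlap is allowed, 11 is not
        a = _rec("q", 0, 100, 100)
        b = _rec("q", 90, 200, 110)
        assert best_hit_filter([a, b]) == [a, b]
        c = _rec("q", 89, 200, 111)
        assert best_hit_filter([a, c]) == [c]  # heavier of the two

    def test_keep_ties_retains_co_optimal_duplicates(self):
        a = _rec("q", 0, 100, 100, target="t1")
        b = _rec("q", 0, 100, 100, target="t2")
        default = best_hit_filter([a, b])
        assert len(default) == 1
        with_ties = best_hit_filter([a, b], keep_ties=True)
        assert sorted(r.target_id for r in with_ties) == ["t1", "t2"]
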