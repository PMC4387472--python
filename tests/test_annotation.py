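"""Curation stages: parsing, filtering, overlap resolution, chaining,
TSD detection, structure classes and content summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cennest import (
    CurationConfig,
    RawHit,
    SimConfig,
    classify_structure,
    curate_elements,
    detect_tsd,
    filter_hits,
    merge_fragments,
    parse_repeatmasker_out,
    resolve_overlaps,
    simulate_centromere,
    summarize_content,
)
from cennest.annotation_curation import Element, write_repeatmasker_out
from cennest.synthetic_centromere import ground_truth_hits
from cennest._util import union_length

RM_HEADER = "header line one\nheader line two\n\n"


def _write(tmp_path, body):
    p = tmp_path / "hits.out"
    p.write_text(RM_HEADER + body)
    return p


class TestRepeatMaskerParsing:
    def test_plus_strand_row(self, tmp_path):
        p = _write(tmp_path, "800 5.2 0.0 0.0 chr8 101 700 (1000) + RIRE3 LTR/Gypsy 51 650 (350) 1\n")
        (hit,) = parse_repeatmasker_out(p)
        assert (hit.qstart, hit.qend) == (100, 700)
        assert hit.strand == "+"
        assert (hit.cstart, hit.cend) == (50, 650)
        assert hit.score == 800 and hit.divergence == 5.2

    def test_minus_strand_parenthesized_consensus(self, tmp_path):
        # consensus columns for C strand are "(left) end begin":
        # (0) 646 1 means the hit covers consensus bases 1..646
        p = _write(tmp_path, "500 1.0 0.0 0.0 chr8 11 656 (0) C CRR1 LTR/Gypsy (0) 646 1 1\n")
        (hit,) = parse_repeatmasker_out(p)
        assert hit.strand == "-"
        assert (hit.cstart, hit.cend) == (0, 646)
        assert (hit.qstart, hit.qend) == (10, 656)

    def test_empty_body(self, tmp_path):
        assert parse_repeatmasker_out(_write(tmp_path, "")) == []

    def test_malformed_row_reports_line_number(self, tmp_path):
        p = _write(tmp_path, "not a valid row\n")
        with pytest.raises(ValueError, match="line 4"):
            parse_repeatmasker_out(p)

    def test_write_parse_roundtrip(self, tmp_path, small_truth):
        hits = ground_truth_hits(small_truth)
        clens = {f.name: f.length for f in small_truth.library}
        p = tmp_path / "rt.out"
        write_repeatmasker_out(hits, p, clens)
        back = parse_repeatmasker_out(p)
        assert [(h.qstart, h.qend, h.strand, h.family, h.cstart, h.cend) for h in back] == [
            (h.qstart, h.qend, h.strand, h.family, h.cstart, h.cend) for h in hits
        ]


@pytest.mark.parametrize(
    ("score", "length", "kept"),
    [
        (300, 60, False),  # score not strictly greater
        (301, 51, True),
        (1000, 50, False),  # length not strictly greater
        (299, 500, False),
        (301, 50, False),
    ],
)
def test_filter_is_strict(score, length, kept):
    hit = RawHit("q", 0, length, "+", "FAM", 0, length, score)
    assert (filter_hits([hit]) == [hit]) is kept


class TestResolveOverlaps:
    def test_disjoint_input_unchanged(self):
        hits = [
            RawHit("q", 0, 100, "+", "A", 0, 100, 500),
            RawHit("q", 200, 400, "+", "B", 0, 200, 700),
        ]
        assert resolve_overlaps(hits) == hits

    def test_lower_score_is_trimmed(self):
        a = RawHit("q", 0, 200, "+", "A", 0, 200, 800)
        b = RawHit("q", 180, 400, "+", "B", 0, 220, 400)
        out = resolve_overlaps([a, b])
        assert len(out) == 2
        trimmed = next(h for h in out if h.family == "B")
        assert (trimmed.qstart, trimmed.qend) == (200, 400)
        assert (trimmed.cstart, trimmed.cend) == (20, 220)

    def test_minus_strand_trim_clips_consensus_end(self):
        a = RawHit("q", 0, 200, "+", "A", 0, 200, 800)
        b = RawHit("q", 180, 400, "-", "B", 0, 220, 400)
        out = resolve_overlaps([a, b])
        trimmed = next(h for h in out if h.family == "B")
        # genomic left trim of a minus-strand hit removes consensus 3' end
        assert (trimmed.cstart, trimmed.cend) == (0, 200)

    def test_short_remainder_dropped(self):
        a = RawHit("q", 0, 300, "+", "A", 0, 300, 900)
        b = RawHit("q", 280, 340, "+", "B", 0, 60, 400)
        out = resolve_overlaps([a, b], min_length=50)
        assert [h.family for h in out] == ["A"]

    @given(
        st.lists(
            st.tuples(
                st.integers(0, 400), st.integers(60, 250), st.integers(301, 2000)
            ),
            min_size=1,
            max_size=8,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_union_coverage_preserved(self, raw):
        """Position-wise oracle: when no remainder is dropped, the output
        tiles exactly the union of the input intervals."""
        hits = [
            RawHit("q", s, s + ln, "+", f"F{i}", 0, ln, sc)
            for i, (s, ln, sc) in enumerate(raw)
        ]
        out = resolve_overlaps(hits, min_length=0)
        # disjointness
        ivs = sorted((h.qstart, h.qend) for h in out)
        for (s0, e0), (s1, e1) in zip(ivs, ivs[1:]):
            assert e0 <= s1
        assert sum(h.length for h in out) == union_length(
            [(h.qstart, h.qend) for h in hits]
        )


class TestMergeFragments:
    def test_single_hit_single_fragment(self, sim_library):
        fam = next(iter(sim_library))
        hit = RawHit("q", 1000, 2000, "+", fam.name, 0, 1000, 900)
        (el,) = merge_fragments([hit], sim_library)
        assert el.fragments == [(1000, 2000)]
        assert el.family == fam.name

    def test_host_split_by_interposed_element_is_rejoined(self, sim_library):
        host = next(f for f in sim_library if f.length > 7000)
        other = next(f for f in sim_library if f.name != host.name)
        hits = [
            RawHit("q", 0, 3000, "+", host.name, 0, 3000, 900),
            RawHit("q", 3000, 8000, "+", other.name, 0, 5000, 900),
            RawHit("q", 8000, 8000 + host.length - 3000, "+", host.name, 3000, host.length, 900),
        ]
        els = merge_fragments(hits, sim_library)
        assert len(els) == 2
        host_el = next(e for e in els if e.family == host.name)
        assert len(host_el.fragments) == 2
        assert host_el.consensus_fragments == [(0, 3000), (3000, host.length)]

    def test_never_chains_across_family_or_strand(self, sim_library):
        fam = next(iter(sim_library))
        hits = [
            RawHit("q", 0, 1000, "+", fam.name, 0, 1000, 900),
            RawHit("q", 1010, 2010, "-", fam.name, 1000, 2000, 900),
        ]
        assert len(merge_fragments(hits, sim_library)) == 2

    def test_large_uncovered_gap_not_chained(self, sim_library):
        fam = next(iter(sim_library))
        hits = [
            RawHit("q", 0, 1000, "+", fam.name, 0, 1000, 900),
            RawHit("q", 5000, 6000, "+", fam.name, 1000, 2000, 900),
        ]
        # 4 kb genomic gap with no intervening hits: two elements
        assert len(merge_fragments(hits, sim_library)) == 2


class TestDetectTsd:
    def test_planted_ccctt_duplication(self, toy_library):
        fam = toy_library["GYPSY1"]
        seq = "GATTC" * 30 + "CCCTT" + fam.consensus + "CCCTT" + "AGGTC" * 30
        start = 150 + 5
        el = Element("e1", "GYPSY1", "+", [(start, start + fam.length)], [(0, fam.length)])
        detect_tsd(el, seq, toy_library)
        assert el.tsd == "CCCTT"

    def test_random_flanks_no_tsd(self, toy_library):
        fam = toy_library["GYPSY1"]
        seq = "GATCA" * 30 + fam.consensus + "TTGCC" * 30
        el = Element("e1", "GYPSY1", "+", [(150, 150 + fam.length)], [(0, fam.length)])
        detect_tsd(el, seq, toy_library)
        assert el.tsd is None

    def test_element_at_sequence_edge_flagged(self, toy_library):
        fam = toy_library["GYPSY1"]
        el = Element("e1", "GYPSY1", "+", [(0, fam.length)], [(0, fam.length)])
        detect_tsd(el, fam.consensus + "A" * 50, toy_library)
        assert el.tsd is None and el.tsd_at_edge

    def test_zero_tsd_family_reports_absent(self, toy_library):
        fam = toy_library["HEL1"]
        seq = "AATCG" * 20 + fam.consensus + "GGTAC" * 20
        el = Element("e1", "HEL1", "+", [(100, 100 + fam.length)], [(0, fam.length)])
        detect_tsd(el, seq, toy_library)
        assert el.tsd is None and not el.tsd_at_edge


class TestClassifyStructure:
    def test_full_copy_is_intact(self, toy_library):
        fam = toy_library["GYPSY1"]
        el = Element("e", fam.name, "+", [(0, fam.length)], [(0, fam.length)])
        assert classify_structure(el, toy_library) == "intact"

    def test_single_ltr_is_solo(self, toy_library):
        el = Element("e", "GYPSY1", "+", [(0, 300)], [(0, 300)])
        assert classify_structure(el, toy_library) == "solo-LTR"

    def test_internal_fragment_is_truncated(self, toy_library):
        el = Element("e", "GYPSY1", "+", [(0, 200)], [(600, 800)])
        assert classify_structure(el, toy_library) == "truncated"

    def test_planted_structures_recovered(self, small_truth, small_elements):
        truth_struct = {ev.span: ev.structure for ev in small_truth.events}
        for el in small_elements:
            assert el.structure == truth_struct[el.span]


class TestSummarizeContent:
    def test_empty_elements_all_zero(self, sim_library):
        df = summarize_content([], 1000, sim_library)
        assert (df["copy_no"] == 0).all()
        assert (df["coverage_bp"] == 0).all()

    def test_subtotals_and_grand_total(self, small_elements, small_truth, sim_library):
        df = summarize_content(small_elements, len(small_truth.sequence), sim_library)
        class1 = df.loc["Ty1-copia":"other (Class I)", "copy_no"].sum()
        assert df.loc["Total Class I", "copy_no"] == class1
        assert (
            df.loc["Total TEs", "copy_no"]
            == df.loc["Total Class I", "copy_no"] + df.loc["Total Class II", "copy_no"]
        )
        assert df.loc["Total TEs", "copy_no"] == len(small_elements)
        cov_frac = df.loc["Total TEs", "content_pct"]
        assert cov_frac == pytest.approx(100 * small_truth.te_fraction)

    def test_planted_composition_recovered(self, small_truth, small_elements, sim_library):
        df = summarize_content(small_elements, len(small_truth.sequence), sim_library)
        from collections import Counter
        truth_counts = Counter(
            sim_library.bucket(ev.family) for ev in small_truth.events
        )
        for (cls, bucket), n in truth_counts.items():
            label = bucket if bucket != "other" else f"other (Class {cls})"
            assert df.loc[label, "copy_no"] == n


def test_roundtrip_recall_and_precision_on_simulation(small_truth, small_elements):
    from cennest.evaluation import element_recall_precision, tsd_recovery_rate

    recall, precision = element_recall_precision(small_elements, small_truth)
    assert recall == 1.0 and precision == 1.0
    assert tsd_recovery_rate(small_elements, small_truth) == 1.0


def test_no_base_claimed_twice_after_full_pipeline(sim_library):
    cfg = SimConfig(backbone_length=80_000, n_insertions=25, seed=17, nesting_bias=0.6)
    truth = simulate_centromere(sim_library, cfg)
    els = curate_elements(truth.sequence, ground_truth_hits(truth), sim_library)
    frags = sorted(f for el in els for f in el.fragments)
    for (s0, e0), (s1, e1) in zip(frags, frags[1:]):
        assert e0 <= s1
    assert sum(e - s for s, e in frags) <= len(truth.sequence)
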