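"""Curation of raw repeat hits into whole transposable elements.

The stages mirror how centromere repeat annotations are cleaned by hand:

1. parse RepeatMasker ``.out`` tables into strand-explicit hits,
2. drop weak hits (score and length cutoffs),
3. resolve overlaps between conflicting annotations (higher score wins),
4. chain consensus-colinear fragments of one element that were split apart
   by nested insertions,
5. detect target-site duplications (TSDs) at element boundaries,
6. classify each element as intact / solo-LTR / truncated, and
7. tabulate copy number, coverage and percent content per superfamily.

All genomic and consensus coordinates are 0-based half-open internally.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ._util import (
    covered_fraction,
    hamming,
    merge_intervals,
    round_half_up,
    union_length,
)
from .te_model import CLASS_I, CLASS_II, TAXONOMY, TELibrary

log = logging.getLogger(__name__)

Interval = tuple[int, int]


@dataclass(frozen=True)
class RawHit:
    """One repeat hit: a genomic interval matched to a family consensus.

    ``cstart``/``cend`` are consensus-forward coordinates regardless of
    strand; for minus-strand hits the genomic start corresponds to ``cend``.
    """

    query_id: str
    qstart: int
    qend: int
    strand: str  # '+' or '-'
    family: str
    cstart: int
    cend: int
    score: float
    divergence: float = 0.0

    def __post_init__(self) -> None:
        if self.qend <= self.qstart or self.cend <= self.cstart:
            raise ValueError(f"malformed hit intervals: {self}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.score < 0 or not 0 <= self.divergence <= 100:
            raise ValueError(f"score/divergence out of range: {self}")

    @property
    def length(self) -> int:
        return self.qend - self.qstart


@dataclass
class Element:
    """A curated element copy: one or more consensus-colinear fragments."""

    element_id: str
    family: str
    strand: str
    fragments: list[Interval]
    consensus_fragments: list[Interval]
    structure: str = "truncated"  # intact | solo-LTR | truncated
    tsd: str | None = None
    tsd_left: Interval | None = None
    tsd_right: Interval | None = None
    tsd_at_edge: bool = False
    host_id: str | None = None  # filled by the nesting stage
    layer: int | None = None

    @property
    def span(self) -> Interval:
        return self.fragments[0][0], self.fragments[-1][1]

    @property
    def block_length(self) -> int:
        s, e = self.span
        return e - s

    @property
    def covered_bp(self) -> int:
        return sum(e - s for s, e in self.fragments)


@dataclass
class CurationConfig:
    """Thresholds of the curation stages.

    The score/length cutoffs are the published filter (strictly greater
    than 300 / 50 bp); the remaining knobs formalise manual inspection and
    are deliberately exposed.
    """

    min_score: float = 300.0
    min_length: int = 50
    consensus_gap_tol: int = 50
    consensus_overlap_tol: int = 20
    small_gap_tol: int = 50
    intervening_cover_frac: float = 0.9
    tsd_search_slack: int = 3
    tsd_max_mismatch: int = 1
    intact_cov_frac: float = 0.8
    ltr_cov_frac: float = 0.8
    max_internal_frac: float = 0.1


# ---------------------------------------------------------------------------
# RepeatMasker .out dialect I/O
# ---------------------------------------------------------------------------

_RM_HEADER = (
    "   SW   perc perc perc  query     position in query          matching"
    "  repeat         position in repeat\n"
    "score   div. del. ins.  sequence  begin end     (left)   repeat"
    "  class/family    begin end (left)\n"
    "\n"
)


def parse_repeatmasker_out(path: str | Path) -> list[RawHit]:
    """Parse a RepeatMasker ``.out``-dialect table.

    Expects the usual 3 header lines followed by whitespace-separated rows.
    Minus-strand rows carry ``C`` in the strand column and give consensus
    coordinates as ``(left) end begin``; they are normalised here to
    consensus-forward 0-based half-open intervals.
    """
    hits: list[RawHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= 3 or not line.strip():
                continue
            parts = line.split()
            try:
                score = float(parts[0])
                div = float(parts[1])
                query = parts[4]
                qbegin, qend = int(parts[5]), int(parts[6])
                strand_col = parts[8]
                family = parts[9]
                if strand_col == "C":
                    strand = "-"
                    # (left) end begin
                    cend = int(parts[12])
                    cstart = int(parts[13]) - 1
                else:
                    strand = "+"
                    cstart = int(parts[11]) - 1
                    cend = int(parts[12])
                hits.append(
                    RawHit(
                        query_id=query,
                        qstart=qbegin - 1,
                        qend=qend,
                        strand=strand,
                        family=family,
                        cstart=cstart,
                        cend=cend,
                        score=score,
                        divergence=div,
                    )
                )
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed row at line {lineno}: {exc}") from exc
    return hits


def write_repeatmasker_out(
    hits: Sequence[RawHit],
    path: str | Path,
    consensus_lengths: dict[str, int] | None = None,
) -> None:
    """Write hits in the RepeatMasker ``.out`` dialect read by the parser."""
    consensus_lengths = consensus_lengths or {}
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for i, h in enumerate(hits, start=1):
            clen = consensus_lengths.get(h.family, h.cend)
            qleft = "(0)"
            if h.strand == "+":
                rcols = f"{h.cstart + 1} {h.cend} ({clen - h.cend})"
                strand = "+"
            else:
                rcols = f"({clen - h.cend}) {h.cend} {h.cstart + 1}"
                strand = "C"
            fh.write(
                f"{h.score:.0f} {h.divergence:.1f} 0.0 0.0 {h.query_id} "
                f"{h.qstart + 1} {h.qend} {qleft} {strand} {h.family} "
                f"Unknown {rcols} {i}\n"
            )


# ---------------------------------------------------------------------------
# Filtering and overlap resolution
# ---------------------------------------------------------------------------

def filter_hits(
    hits: Iterable[RawHit], min_score: float = 300, min_length: int = 50
) -> list[RawHit]:
    """Keep hits with score strictly greater than ``min_score`` and genomic
    length strictly greater than ``min_length``."""
    return [h for h in hits if h.score > min_score and h.length > min_length]


def _trim_hit(hit: RawHit, piece: Interval) -> RawHit:
    """Restrict a hit to a genomic sub-interval, trimming the consensus
    interval by the same amounts (colinear, indel-free approximation)."""
    ps, pe = piece
    lcut = ps - hit.qstart
    rcut = hit.qend - pe
    if hit.strand == "+":
        cstart, cend = hit.cstart + lcut, hit.cend - rcut
    else:
        cstart, cend = hit.cstart + rcut, hit.cend - lcut
    cstart = max(hit.cstart, min(cstart, hit.cend - 1))
    cend = min(hit.cend, max(cend, cstart + 1))
    return replace(hit, qstart=ps, qend=pe, cstart=cstart, cend=cend)


def resolve_overlaps(hits: Sequence[RawHit], min_length: int = 50) -> list[RawHit]:
    """Make hits pairwise disjoint on the query.

    Hits are processed by priority (higher score, then longer, then earlier
    start, then family name); lower-priority hits are trimmed to the bases
    not yet claimed.  Trimmed remainders shorter than ``min_length`` are
    dropped (pass 0 to keep everything).
    """
    order = sorted(hits, key=lambda h: (-h.score, -h.length, h.qstart, h.family))
    occupied: list[Interval] = []
    kept: list[RawHit] = []
    for hit in order:
        pieces = _subtract(hit.qstart, hit.qend, occupied)
        for ps, pe in pieces:
            if pe - ps < max(min_length, 1):
                if pe > ps:
                    log.debug("dropping %d bp remainder of %s hit", pe - ps, hit.family)
                continue
            kept.append(_trim_hit(hit, (ps, pe)))
        occupied = merge_intervals(occupied + [(hit.qstart, hit.qend)])
    kept.sort(key=lambda h: (h.query_id, h.qstart))
    return kept


def _subtract(start: int, end: int, ivs: Sequence[Interval]) -> list[Interval]:
    """Pieces of [start, end) not covered by the (disjoint, sorted) ivs."""
    pieces: list[Interval] = []
    cur = start
    for s, e in ivs:
        if e <= cur or s >= end:
            continue
        if s > cur:
            pieces.append((cur, min(s, end)))
        cur = max(cur, e)
        if cur >= end:
            break
    if cur < end:
        pieces.append((cur, end))
    return pieces


# ---------------------------------------------------------------------------
# Fragment chaining (defragmentation of nested-split elements)
# ---------------------------------------------------------------------------

def merge_fragments(
    hits: Sequence[RawHit],
    library: TELibrary,
    config: CurationConfig | None = None,
) -> list[Element]:
    """Chain overlap-resolved hits of one query into elements.

    Two same-family, same-strand hits are chained when their consensus
    intervals advance colinearly (gap within ``consensus_gap_tol``, overlap
    within ``consensus_overlap_tol``) and the genomic gap between them is
    either small (``small_gap_tol``) or almost fully covered by other hits —
    the signature of a host split open by nested insertions.
    """
    cfg = config or CurationConfig()
    all_ivs = [(h.qstart, h.qend) for h in hits]
    chains: list[list[RawHit]] = []
    open_by_group: dict[tuple[str, str], list[int]] = {}

    for hit in sorted(hits, key=lambda h: h.qstart):
        group = (hit.family, hit.strand)
        best: tuple[int, int, int] | None = None
        best_ci = -1
        for ci in open_by_group.get(group, []):
            tail = chains[ci][-1]
            if hit.qstart < tail.qend:
                continue
            if hit.strand == "+":
                d = hit.cstart - tail.cend
            else:
                d = tail.cstart - hit.cend
            if not (-cfg.consensus_overlap_tol <= d <= cfg.consensus_gap_tol):
                continue
            gap = (tail.qend, hit.qstart)
            gap_len = gap[1] - gap[0]
            if gap_len > cfg.small_gap_tol:
                chain_ivs = {(h.qstart, h.qend) for h in chains[ci]}
                others = [iv for iv in all_ivs if iv not in chain_ivs and iv != (hit.qstart, hit.qend)]
                if covered_fraction(gap, others) < cfg.intervening_cover_frac:
                    continue
            # nested same-family copies close LIFO (bracket-like), so among
            # equally colinear chains prefer the nearest, most recent tail
            key = (abs(d), gap_len, -ci)
            if best is None or key < best:
                best = key
                best_ci = ci
        if best is None:
            chains.append([hit])
            open_by_group.setdefault(group, []).append(len(chains) - 1)
        else:
            chains[best_ci].append(hit)

    elements: list[Element] = []
    chains.sort(key=lambda c: c[0].qstart)
    for i, chain in enumerate(chains):
        frags = [(h.qstart, h.qend) for h in chain]
        cons = [(h.cstart, h.cend) for h in chain]
        elements.append(
            Element(
                element_id=f"el{i:04d}",
                family=chain[0].family,
                strand=chain[0].strand,
                fragments=frags,
                consensus_fragments=cons,
            )
        )
    return elements


# ---------------------------------------------------------------------------
# TSD detection and structure classification
# ---------------------------------------------------------------------------

def detect_tsd(
    element: Element,
    sequence: str,
    library: TELibrary,
    config: CurationConfig | None = None,
) -> Element:
    """Search for a target-site duplication flanking the element block.

    Compares k-mers within ``tsd_search_slack`` bp of the outer block
    boundaries, k being the family's expected TSD length (scanning k in
    [4, 6] when the family is unknown; k = 0 means no TSD expected).
    The best pair with at most ``tsd_max_mismatch`` mismatches is recorded.
    """
    cfg = config or CurationConfig()
    fam = library[element.family] if element.family in library else None
    ks: Sequence[int]
    if fam is not None:
        if fam.tsd_length == 0:
            element.tsd = None
            return element
        ks = [fam.tsd_length]
    else:
        ks = range(6, 3, -1)

    start, end = element.span
    best: tuple[int, int, int, int, str] | None = None  # (mm, |dl|+|dr|, dl, dr, seq)
    slack = cfg.tsd_search_slack
    for k in ks:
        if start - k - slack < 0 or end + k + slack > len(sequence):
            element.tsd_at_edge = True
            continue
        for dl, dr in itertools.product(range(-slack, slack + 1), repeat=2):
            ls = start - k + dl
            rs = end + dr
            left = sequence[ls : ls + k]
            right = sequence[rs : rs + k]
            mm = hamming(left, right)
            if mm > cfg.tsd_max_mismatch:
                continue
            key = (mm, abs(dl) + abs(dr), dl, dr, left)
            if best is None or key[:2] < best[:2]:
                best = key
                best_iv = ((ls, ls + k), (rs, rs + k))
        if best is not None:
            break  # prefer the longest k that yields a hit
    if best is not None:
        element.tsd = best[4]
        element.tsd_left, element.tsd_right = best_iv
    else:
        element.tsd = None
    return element


def _covered_frac_of(span: Interval, cons_frags: Sequence[Interval]) -> float:
    return covered_fraction(span, cons_frags)


def classify_structure(
    element: Element,
    library: TELibrary,
    config: CurationConfig | None = None,
) -> str:
    """Classify an element as intact, solo-LTR or truncated.

    Intact requires near-complete consensus coverage including both terminal
    repeats; solo-LTR (Class I only) requires one well-covered LTR and a
    near-empty internal region.
    """
    cfg = config or CurationConfig()
    if element.family not in library:
        return "truncated"
    fam = library[element.family]
    cons = merge_intervals(element.consensus_fragments)
    total_cov = union_length(cons) / fam.length

    if fam.is_ltr:
        ltr5, ltr3 = fam.ltr_span
        cov5 = _covered_frac_of(ltr5, cons)
        cov3 = _covered_frac_of(ltr3, cons)
        internal = fam.internal_span
        cov_int = _covered_frac_of(internal, cons) if internal[1] > internal[0] else 0.0
        if total_cov >= cfg.intact_cov_frac and min(cov5, cov3) >= cfg.ltr_cov_frac:
            return "intact"
        if max(cov5, cov3) >= cfg.ltr_cov_frac and cov_int <= cfg.max_internal_frac:
            return "solo-LTR"
        return "truncated"

    if total_cov >= cfg.intact_cov_frac:
        if fam.tir_length:
            t = fam.tir_length
            tir5 = (0, t)
            tir3 = (fam.length - t, fam.length)
            if min(_covered_frac_of(tir5, cons), _covered_frac_of(tir3, cons)) < cfg.ltr_cov_frac:
                return "truncated"
        return "intact"
    return "truncated"


# ---------------------------------------------------------------------------
# Content summary (Table-1 style)
# ---------------------------------------------------------------------------

ROW_ORDER = (
    [(CLASS_I, b) for b in TAXONOMY[CLASS_I]]
    + ["Total Class I"]
    + [(CLASS_II, b) for b in TAXONOMY[CLASS_II]]
    + ["Total Class II", "Total TEs"]
)


def summarize_content(
    elements: Sequence[Element], sequence_length: int, library: TELibrary
) -> pd.DataFrame:
    """Per-superfamily copy number, coverage (bp) and content (% of sequence).

    A multi-fragment element counts as one copy; coverage sums fragment
    lengths.  Rows follow the conventional class/superfamily table order
    with class subtotals and a grand total.
    """
    counts: dict[tuple[str, str], int] = {}
    cover: dict[tuple[str, str], int] = {}
    for el in elements:
        key = library.bucket(el.family)
        counts[key] = counts.get(key, 0) + 1
        cover[key] = cover.get(key, 0) + el.covered_bp

    rows = []
    index = []
    subtotals = {CLASS_I: [0, 0], CLASS_II: [0, 0]}
    for key in ROW_ORDER:
        if key == "Total Class I":
            index.append(key)
            rows.append(subtotals[CLASS_I][:])
        elif key == "Total Class II":
            index.append(key)
            rows.append(subtotals[CLASS_II][:])
        elif key == "Total TEs":
            index.append(key)
            rows.append(
                [
                    subtotals[CLASS_I][0] + subtotals[CLASS_II][0],
                    subtotals[CLASS_I][1] + subtotals[CLASS_II][1],
                ]
            )
        else:
            cls, bucket = key
            n = counts.get(key, 0)
            bp = cover.get(key, 0)
            subtotals[cls][0] += n
            subtotals[cls][1] += bp
            index.append(f"{bucket} (Class {cls})" if bucket == "other" else bucket)
            rows.append([n, bp])

    df = pd.DataFrame(rows, index=index, columns=["copy_no", "coverage_bp"])
    df["content_pct"] = df["coverage_bp"] / sequence_length * 100.0
    return df


def class_ratio(class1_value: float, class2_value: float, ndigits: int = 2) -> float:
    """Class I : Class II ratio (copy number or coverage), rounded half-up."""
    if class2_value == 0:
        return math.inf
    return round_half_up(class1_value / class2_value, ndigits)


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

def curate_elements(
    sequence: str,
    hits: Sequence[RawHit],
    library: TELibrary,
    config: CurationConfig | None = None,
) -> list[Element]:
    """Full curation chain: filter, resolve, chain, TSD, structure class."""
    cfg = config or CurationConfig()
    kept = filter_hits(hits, cfg.min_score, cfg.min_length)
    flat = resolve_overlaps(kept, cfg.min_length)
    elements = merge_fragments(flat, library, cfg)
    for el in elements:
        detect_tsd(el, sequence, library, cfg)
        el.structure = classify_structure(el, library, cfg)
    return elements


def elements_to_dataframe(elements: Sequence[Element]) -> pd.DataFrame:
    rows = []
    for el in elements:
        rows.append(
            {
                "element_id": el.element_id,
                "family": el.family,
                "strand": el.strand,
                "start": el.span[0],
                "end": el.span[1],
                "n_fragments": len(el.fragments),
                "fragments": ";".join(f"{s}-{e}" for s, e in el.fragments),
                "consensus_fragments": ";".join(
                    f"{s}-{e}" for s, e in el.consensus_fragments
                ),
                "structure": el.structure,
                "tsd": el.tsd or "",
                "host_id": el.host_id or "",
                "layer": el.layer if el.layer is not None else "",
            }
        )
    return pd.DataFrame(rows)


def elements_to_gff3(elements: Sequence[Element], seqid: str) -> str:
    """GFF3 text with one feature per fragment (Parent = element id)."""
    lines = ["##gff-version 3"]
    for el in elements:
        s, e = el.span
        attrs = f"ID={el.element_id};Name={el.family};structure={el.structure}"
        if el.layer is not None:
            attrs += f";layer={el.layer}"
        if el.host_id:
            attrs += f";host={el.host_id}"
        lines.append(
            f"{seqid}\tcennest\ttransposable_element\t{s + 1}\t{e}\t.\t{el.strand}\t.\t{attrs}"
        )
        for j, (fs, fe) in enumerate(el.fragments):
            lines.append(
                f"{seqid}\tcennest\ttransposon_fragment\t{fs + 1}\t{fe}\t.\t{el.strand}\t.\t"
                f"ID={el.element_id}.f{j};Parent={el.element_id}"
            )
    return "\n".join(lines) + "\n"
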