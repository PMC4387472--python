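"""Orthologous vs lineage-specific transposon calling between two assemblies.

Orthology between centromere assemblies cannot rely on position alone —
coordinates drift with every insertion — so elements are compared inside
intervals bounded by conserved single-copy gene anchors.  Within each
inter-anchor gap, candidate pairs must share a family and are scored by
TSD sequence equality, element sequence identity and positional rank;
a greedy one-to-one matching yields shared (orthologous) pairs, and the
remainder are lineage-specific.  Elements outside the anchored interval are
excluded from the totals, mirroring the exclusion of regions without a
clearly orthologous counterpart.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import edlib
import pandas as pd

from ._util import hamming, revcomp, round_half_up
from .annotation_curation import Element
from .te_model import CLASS_I, TELibrary

log = logging.getLogger(__name__)

Interval = tuple[int, int]


@dataclass
class GeneAnchor:
    gene_id: str
    interval_a: Interval
    interval_b: Interval
    same_orientation: bool = True


@dataclass
class OrthologPair:
    id_a: str
    id_b: str
    family: str
    tsd_match: bool
    identity: float
    gap_index: int


@dataclass
class MatchResult:
    pairs: list[OrthologPair]
    unmatched_a: list[Element]
    unmatched_b: list[Element]
    excluded_a: list[Element] = field(default_factory=list)
    excluded_b: list[Element] = field(default_factory=list)


@dataclass
class MatchConfig:
    """Candidate thresholds and composite-score weights for ortholog calling.

    A candidate pair scores
    ``2*tsd_match + 2*flank_identity + identity - rank_penalty*|Δrank|``:
    TSD equality and shared flanking context dominate (orthologous
    insertions sit in the same target site, so both flanks align between
    assemblies), element identity separates real divergence, and the
    within-family positional-rank penalty keeps a marginally-higher
    identity from pairing an element with an independent younger insertion
    of the same family.  Candidates are rejected outright when both
    detected TSDs are present but disagree beyond one substitution
    (independent insertions duplicate different target sites) or when the
    flanks fail to align at ``min_flank_identity``.
    """

    min_identity: float = 0.90
    min_cov: float = 0.80  # minimum length ratio shorter/longer
    rank_penalty: float = 0.02
    reject_tsd_mismatch: bool = True
    flank_bp: int = 30
    min_flank_identity: float = 0.75


@dataclass
class ComparisonTable:
    """Shared/unshared tallies for one pairwise genome comparison."""

    shared: int
    unshared_a: int
    unshared_b: int
    unshared_retro_a: int | None = None
    unshared_retro_b: int | None = None

    @property
    def total_a(self) -> int:
        return self.shared + self.unshared_a

    @property
    def total_b(self) -> int:
        return self.shared + self.unshared_b

    @property
    def rate_a(self) -> float:
        return polymorphic_rate(self.unshared_a, self.total_a)

    @property
    def rate_b(self) -> float:
        return polymorphic_rate(self.unshared_b, self.total_b)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "total": [self.total_a, self.total_b],
                "shared": [self.shared, self.shared],
                "unshared": [self.unshared_a, self.unshared_b],
                "unshared_retro": [self.unshared_retro_a, self.unshared_retro_b],
                "polymorphic_rate_pct": [self.rate_a, self.rate_b],
            },
            index=["genome_A", "genome_B"],
        )


def polymorphic_rate(unshared: int, total: int) -> float:
    """Unshared / total as a percentage, rounded half-up to one decimal."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100.0 * unshared / total, 1)


# ---------------------------------------------------------------------------
# Gene anchors
# ---------------------------------------------------------------------------

def build_anchor_map(
    genes_a: Mapping[str, Interval], genes_b: Mapping[str, Interval]
) -> list[GeneAnchor]:
    """Colinear gene anchors shared by both assemblies.

    Shared gene ids are sorted by their coordinate in assembly A; anchors
    that cross (break colinearity) are removed by keeping the longest
    subsequence whose assembly-B coordinates also increase.
    """
    shared = sorted(set(genes_a) & set(genes_b), key=lambda g: genes_a[g][0])
    if len(shared) < 2:
        raise ValueError("need at least 2 shared gene anchors to compare")

    b_starts = [genes_b[g][0] for g in shared]
    # O(n^2) longest strictly increasing subsequence with earliest-index ties
    n = len(shared)
    best_len = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if b_starts[j] < b_starts[i] and best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j
    end = max(range(n), key=lambda i: (best_len[i], -i))
    keep_idx = []
    while end != -1:
        keep_idx.append(end)
        end = prev[end]
    keep_idx.reverse()
    dropped = n - len(keep_idx)
    if dropped:
        log.info("dropped %d crossing anchors", dropped)
    return [
        GeneAnchor(shared[i], tuple(genes_a[shared[i]]), tuple(genes_b[shared[i]]))
        for i in keep_idx
    ]


# ---------------------------------------------------------------------------
# Ortholog matching
# ---------------------------------------------------------------------------

def _element_sequence(el: Element, sequence: str) -> str:
    """Element sequence in consensus orientation (fragments concatenated)."""
    seq = "".join(sequence[s:e] for s, e in el.fragments)
    return revcomp(seq) if el.strand == "-" else seq


def _flank_sequence(el: Element, sequence: str, flank_bp: int) -> str:
    """Concatenated left+right flanks of the element block (genome strand)."""
    s, e = el.span
    return sequence[max(0, s - flank_bp) : s] + sequence[e : e + flank_bp]


def _flank_identity(ea: Element, eb: Element, seq_a: str, seq_b: str, flank_bp: int) -> float:
    fa = _flank_sequence(ea, seq_a, flank_bp)
    fb = _flank_sequence(eb, seq_b, flank_bp)
    if not fa or not fb:
        return 0.0
    res = edlib.align(fa, fb, mode="NW", task="distance")
    return 1.0 - res["editDistance"] / max(len(fa), len(fb))


def _midpoint(el: Element) -> int:
    s, e = el.span
    return (s + e) // 2


def _assign_gaps(
    elements: Sequence[Element], boundaries: list[int]
) -> tuple[dict[int, list[Element]], list[Element]]:
    by_gap: dict[int, list[Element]] = {}
    excluded: list[Element] = []
    for el in elements:
        m = _midpoint(el)
        if m < boundaries[0] or m >= boundaries[-1]:
            excluded.append(el)
            continue
        gi = bisect_right(boundaries, m) - 1
        by_gap.setdefault(gi, []).append(el)
    for els in by_gap.values():
        els.sort(key=lambda e: e.span[0])
    return by_gap, excluded


def match_orthologs(
    elements_a: Sequence[Element],
    elements_b: Sequence[Element],
    anchors: Sequence[GeneAnchor],
    sequence_a: str,
    sequence_b: str,
    config: MatchConfig | None = None,
) -> MatchResult:
    """One-to-one ortholog matching of elements between two assemblies.

    Within each inter-anchor gap, same-family candidates are scored by
    (TSD equality, sequence identity, positional-rank agreement) in that
    priority and matched greedily.  Identity is measured by aligning the
    shorter element sequence within the longer; candidates also need a
    length ratio of at least ``min_cov``.  Elements outside the anchored
    region are excluded from totals and reported separately.
    """
    cfg = config or MatchConfig()
    if len(anchors) < 2:
        raise ValueError("need at least 2 anchors")
    bounds_a = [(s + e) // 2 for s, e in (a.interval_a for a in anchors)]
    bounds_b = [(s + e) // 2 for s, e in (a.interval_b for a in anchors)]
    gaps_a, excluded_a = _assign_gaps(elements_a, bounds_a)
    gaps_b, excluded_b = _assign_gaps(elements_b, bounds_b)
    if excluded_a or excluded_b:
        log.info(
            "excluded %d/%d elements outside the anchored interval",
            len(excluded_a), len(excluded_b),
        )

    pairs: list[OrthologPair] = []
    matched_a: set[str] = set()
    matched_b: set[str] = set()
    for gi in sorted(set(gaps_a) | set(gaps_b)):
        cands = []
        els_a = gaps_a.get(gi, [])
        els_b = gaps_b.get(gi, [])
        # positional rank within (gap, family): same-family copies keep their
        # relative order across lineages, while gap-wide ranks shift whenever
        # a lineage-specific element lands in the gap
        rank_a: dict[str, int] = {}
        rank_b: dict[str, int] = {}
        for els, ranks in ((els_a, rank_a), (els_b, rank_b)):
            per_family: dict[str, int] = {}
            for el in els:
                ranks[el.element_id] = per_family.get(el.family, 0)
                per_family[el.family] = ranks[el.element_id] + 1
        for ea in els_a:
            seq_a_el = _element_sequence(ea, sequence_a)
            for eb in els_b:
                if ea.family != eb.family:
                    continue
                seq_b_el = _element_sequence(eb, sequence_b)
                short, long_ = sorted((seq_a_el, seq_b_el), key=len)
                if len(short) / len(long_) < cfg.min_cov:
                    continue
                res = edlib.align(short, long_, mode="HW", task="distance")
                identity = 1.0 - res["editDistance"] / len(short)
                if identity < cfg.min_identity:
                    continue
                tsd_eq = bool(ea.tsd and eb.tsd and ea.tsd == eb.tsd)
                if cfg.reject_tsd_mismatch and ea.tsd and eb.tsd and not tsd_eq:
                    # a single substitution in one flank should not disqualify
                    # an otherwise matching pair
                    if len(ea.tsd) != len(eb.tsd) or hamming(ea.tsd, eb.tsd) > 1:
                        continue
                flank_id = _flank_identity(ea, eb, sequence_a, sequence_b, cfg.flank_bp)
                if flank_id < cfg.min_flank_identity:
                    continue
                drank = abs(rank_a[ea.element_id] - rank_b[eb.element_id])
                score = (
                    2.0 * tsd_eq + 2.0 * flank_id + identity - cfg.rank_penalty * drank
                )
                cands.append((score, ea.element_id, eb.element_id, identity, tsd_eq))
        # best score first; deterministic tie-break on element ids
        cands.sort(key=lambda c: (-c[0], c[1], c[2]))
        for score, ida, idb, identity, tsd_eq in cands:
            if ida in matched_a or idb in matched_b:
                continue
            matched_a.add(ida)
            matched_b.add(idb)
            pairs.append(
                OrthologPair(
                    id_a=ida,
                    id_b=idb,
                    family=next(e.family for e in els_a if e.element_id == ida),
                    tsd_match=tsd_eq,
                    identity=identity,
                    gap_index=gi,
                )
            )

    unmatched_a = [
        el for els in gaps_a.values() for el in els if el.element_id not in matched_a
    ]
    unmatched_b = [
        el for els in gaps_b.values() for el in els if el.element_id not in matched_b
    ]
    return MatchResult(pairs, unmatched_a, unmatched_b, excluded_a, excluded_b)


def tabulate_comparison(
    pairs: Sequence[OrthologPair],
    unmatched_a: Sequence[Element],
    unmatched_b: Sequence[Element],
    library: TELibrary | None = None,
) -> ComparisonTable:
    """Shared/unshared totals and polymorphic rates for a matched pair of
    assemblies; with a library, also the retrotransposon subcount of the
    unshared elements."""
    retro_a = retro_b = None
    if library is not None:
        retro_a = sum(1 for el in unmatched_a if library[el.family].te_class == CLASS_I)
        retro_b = sum(1 for el in unmatched_b if library[el.family].te_class == CLASS_I)
    return ComparisonTable(
        shared=len(pairs),
        unshared_a=len(unmatched_a),
        unshared_b=len(unmatched_b),
        unshared_retro_a=retro_a,
        unshared_retro_b=retro_b,
    )
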