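"""Assignment of short reads to TE families by seed-and-extend search.

Reads (e.g. CENH3-ChIP sequences) are matched against the library with a
k-mer seed index over both strands, refined by containment alignment of the
read within each candidate consensus, and thresholded with a
Karlin-Altschul-style significance ``E = K * m * n * exp(-lambda * S)``.
The E-value parameters are configurable; only the thresholding behaviour
(default E < 1e-5) is contractual, since absolute E-values depend on the
search tool and database size.  A read counts toward its single best
family; equal-best ties are reported as ambiguous.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import pandas as pd
from Bio.SeqRecord import SeqRecord

from ._util import revcomp
from .te_model import TELibrary

log = logging.getLogger(__name__)


@dataclass
class KmerIndex:
    k: int
    library: TELibrary
    seeds: dict[str, set[tuple[str, str]]] = field(default_factory=dict)  # kmer -> {(family, strand)}
    total_bp: int = 0


@dataclass
class ScoringParams:
    """Alignment scoring and Karlin-Altschul significance parameters."""

    match: int = 1
    penalty: int = 3  # score cost per edit (mismatch or gap)
    ka_k: float = 0.1
    ka_lambda: float = 0.5


@dataclass
class ReadAssignment:
    read_id: str
    family: str | None
    status: str  # assigned | unassigned | ambiguous
    score: float = 0.0
    identity: float = 0.0
    evalue: float = math.inf
    candidates: tuple[str, ...] = ()


def index_library(library: TELibrary, k: int = 12) -> KmerIndex:
    """Seed index over all consensus sequences, both strands."""
    if len(library) == 0:
        raise ValueError("library is empty")
    shortest = min(f.length for f in library)
    if k > shortest:
        raise ValueError(f"k={k} exceeds shortest consensus length {shortest}")
    idx = KmerIndex(k=k, library=library)
    for fam in library:
        idx.total_bp += 2 * fam.length
        for strand, seq in (("+", fam.consensus), ("-", revcomp(fam.consensus))):
            for i in range(len(seq) - k + 1):
                idx.seeds.setdefault(seq[i : i + k], set()).add((fam.name, strand))
    return idx


def _score_read(
    read: str, fam_consensus: str, params: ScoringParams
) -> tuple[float, float]:
    """Containment-align the read within a consensus; return (score, identity)."""
    res = edlib.align(read, fam_consensus, mode="HW", task="distance")
    dist = res["editDistance"]
    if dist < 0:  # pragma: no cover - HW never fails outright
        return -math.inf, 0.0
    score = params.match * len(read) - params.penalty * dist
    identity = 1.0 - dist / len(read)
    return float(score), identity


def assign_reads(
    reads: Iterable[SeqRecord],
    index: KmerIndex,
    significance_threshold: float = 1e-5,
    params: ScoringParams | None = None,
) -> list[ReadAssignment]:
    """Assign each read to its best-scoring family.

    Seed hits nominate candidate (family, strand) pairs; each candidate is
    scored by containment alignment and the best is kept when its
    significance passes the threshold.  Reads whose two best families tie
    exactly are flagged ambiguous with both candidates recorded.
    """
    params = params or ScoringParams()
    k = index.k
    out: list[ReadAssignment] = []
    for rec in reads:
        seq = str(rec.seq).upper()
        if not seq:
            log.warning("skipping empty read %s", rec.id)
            continue
        if len(seq) < k:
            out.append(ReadAssignment(rec.id, None, "unassigned"))
            continue
        candidates: set[tuple[str, str]] = set()
        for i in range(len(seq) - k + 1):
            candidates |= index.seeds.get(seq[i : i + k], set())
        if not candidates:
            out.append(ReadAssignment(rec.id, None, "unassigned"))
            continue

        by_family: dict[str, tuple[float, float]] = {}
        for fam_name, strand in candidates:
            consensus = index.library[fam_name].consensus
            query = seq if strand == "+" else revcomp(seq)
            score, ident = _score_read(query, consensus, params)
            if fam_name not in by_family or score > by_family[fam_name][0]:
                by_family[fam_name] = (score, ident)

        ranked = sorted(by_family.items(), key=lambda kv: (-kv[1][0], kv[0]))
        best_fam, (best_score, best_ident) = ranked[0]
        evalue = (
            params.ka_k
            * len(seq)
            * index.total_bp
            * math.exp(-params.ka_lambda * best_score)
        )
        if evalue > significance_threshold:
            out.append(
                ReadAssignment(rec.id, None, "unassigned", best_score, best_ident, evalue)
            )
            continue
        tied = [f for f, (s, _) in ranked if s == best_score]
        if len(tied) > 1:
            out.append(
                ReadAssignment(
                    rec.id, None, "ambiguous", best_score, best_ident, evalue,
                    candidates=tuple(sorted(tied)),
                )
            )
            continue
        out.append(
            ReadAssignment(rec.id, best_fam, "assigned", best_score, best_ident, evalue)
        )
    return out


@dataclass
class FamilyReadCounts:
    counts: pd.Series  # per-family assigned read counts
    class_counts: dict[str, int]
    flagged: list[str]  # families exceeding the report threshold
    n_assigned: int
    n_unassigned: int
    n_ambiguous: int

    @property
    def class_fractions(self) -> dict[str, float]:
        total = sum(self.class_counts.values())
        if total == 0:
            return {c: 0.0 for c in self.class_counts}
        return {c: n / total for c, n in self.class_counts.items()}


def family_report(
    assignments: Sequence[ReadAssignment],
    library: TELibrary,
    min_reads: int = 5000,
) -> FamilyReadCounts:
    """Per-family read counts with class rollups.

    Families targeted by strictly more than ``min_reads`` assigned reads are
    flagged for reporting.
    """
    counts: dict[str, int] = {}
    n_un = n_amb = 0
    for a in assignments:
        if a.status == "assigned":
            counts[a.family] = counts.get(a.family, 0) + 1
        elif a.status == "ambiguous":
            n_amb += 1
        else:
            n_un += 1
    series = pd.Series(counts, dtype=int).sort_values(ascending=False)
    class_counts = {"I": 0, "II": 0}
    for fam, n in counts.items():
        class_counts[library[fam].te_class] += n
    flagged = sorted(f for f, n in counts.items() if n > min_reads)
    return FamilyReadCounts(
        counts=series,
        class_counts=class_counts,
        flagged=flagged,
        n_assigned=sum(counts.values()),
        n_unassigned=n_un,
        n_ambiguous=n_amb,
    )
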