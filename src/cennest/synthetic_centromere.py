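"""Synthetic centromere generator with a fully known insertion history.

The simulator emulates the structure of a transposon-dense centromere: a
plain backbone is populated by iterative insertions of Class I (LTR) and
Class II (TIR) element copies.  Each insertion duplicates the target-site
bases as a TSD, may land inside an earlier element (splitting it and
building multi-layer nested blocks), may be reduced to a solo LTR, and
accumulates age-proportional substitutions.  Because every event is logged
with its final projected coordinates, the output doubles as an exact oracle
for the curation, nesting, dating and comparison stages.

Insertions are simulated oldest-first; coordinates of all earlier events
are re-projected after every insertion, so the event log carries exact
final intervals.  The divergence model applies substitutions only (no
indels), keeping ground-truth coordinates valid after mutation.
"""

from __future__ import annotations

import copy as _copy
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import revcomp
from .annotation_curation import RawHit
from .te_model import CLASS_I, CLASS_II, TAXONOMY, TEFamily, TELibrary, library_from_families

log = logging.getLogger(__name__)

Interval = tuple[int, int]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# Configuration and ground-truth containers
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study conditions for one simulated centromere.

    ``mutation_rate_per_age_unit`` is substitutions/site per age unit; a
    copy of age rank ``r`` (1 = oldest) out of ``n`` insertions accumulates
    ``(n - r) * rate`` expected substitutions per site, so older copies look
    more diverged.  ``nesting_bias`` is the probability that a new insertion
    targets an existing element instead of backbone.  ``nesting_target``
    chooses the host among existing elements: "random" (uniform) or
    "newest" (always the latest element, producing a single deep chain).
    """

    backbone_length: int = 500_000
    n_insertions: int = 120
    family_weights: dict[str, float] | None = None  # None = uniform
    nesting_bias: float = 0.5
    mutation_rate_per_age_unit: float = 0.0
    solo_ltr_prob: float = 0.1
    seed: int = 0
    n_anchor_genes: int = 0
    anchor_length: int = 1000
    min_fragment_margin: int = 60
    nesting_target: str = "random"

    def validate(self) -> None:
        if self.backbone_length <= 0:
            raise ValueError("backbone_length must be positive")
        if self.n_insertions < 0:
            raise ValueError("n_insertions must be non-negative")
        for p in (self.nesting_bias, self.solo_ltr_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.mutation_rate_per_age_unit < 0:
            raise ValueError("mutation rate must be non-negative")
        if self.family_weights is not None:
            total = sum(self.family_weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("family_weights must sum to 1")
            if any(w < 0 for w in self.family_weights.values()):
                raise ValueError("family_weights must be non-negative")
        if self.nesting_target not in ("random", "newest"):
            raise ValueError("nesting_target must be 'random' or 'newest'")
        # a simulated centromere must stay well inside int coordinates
        if self.backbone_length + self.n_insertions * 100_000 > 2**53:
            raise ValueError("insertion budget exceeds coordinate range")


@dataclass
class InsertionEvent:
    """One logged insertion with exact final (projected) coordinates."""

    event_id: str
    family: str
    strand: str
    age_rank: int  # 1 = oldest
    lineage: str  # ancestral | lineageA | lineageB
    structure: str  # intact | solo-LTR
    tsd: str
    fragments: list[Interval]
    consensus_fragments: list[Interval]
    tsd_left: Interval | None
    tsd_right: Interval | None
    parent_id: str | None  # host event, None = backbone

    @property
    def span(self) -> Interval:
        return self.fragments[0][0], self.fragments[-1][1]


@dataclass
class GroundTruth:
    """Simulated sequence plus its complete event log."""

    seq_id: str
    sequence: str
    events: list[InsertionEvent]
    library: TELibrary
    config: SimConfig
    anchors: list[tuple[str, Interval]] = field(default_factory=list)
    lineage: str = "ancestral"
    _state: "_SimState | None" = None  # pre-mutation state, for lineage resumption

    @property
    def parent_map(self) -> dict[str, str | None]:
        return {ev.event_id: ev.parent_id for ev in self.events}

    @property
    def te_fraction(self) -> float:
        te_bp = sum(e - s for ev in self.events for s, e in ev.fragments)
        return te_bp / len(self.sequence) if self.sequence else 0.0

    def depth(self, event_id: str) -> int:
        d = 1
        pid = self.parent_map[event_id]
        while pid is not None:
            d += 1
            pid = self.parent_map[pid]
        return d

    def events_dataframe(self) -> pd.DataFrame:
        rows = []
        for ev in self.events:
            rows.append(
                {
                    "event_id": ev.event_id,
                    "family": ev.family,
                    "strand": ev.strand,
                    "age_rank": ev.age_rank,
                    "lineage": ev.lineage,
                    "structure": ev.structure,
                    "tsd": ev.tsd,
                    "start": ev.span[0],
                    "end": ev.span[1],
                    "fragments": ";".join(f"{s}-{e}" for s, e in ev.fragments),
                    "parent_id": ev.parent_id or "",
                    "layer": self.depth(ev.event_id),
                }
            )
        return pd.DataFrame(rows)

    def write_fasta(self, path: str | Path) -> None:
        SeqIO.write(
            [SeqRecord(Seq(self.sequence), id=self.seq_id, description="")],
            str(path),
            "fasta",
        )

    def to_gff3(self) -> str:
        lines = ["##gff-version 3"]
        for ev in self.events:
            for j, (s, e) in enumerate(ev.fragments):
                attrs = (
                    f"ID={ev.event_id}.f{j};event_id={ev.event_id};family={ev.family};"
                    f"layer={self.depth(ev.event_id)};lineage={ev.lineage}"
                )
                lines.append(
                    f"{self.seq_id}\tcennest-sim\ttransposon_fragment\t{s + 1}\t{e}\t.\t"
                    f"{ev.strand}\t.\t{attrs}"
                )
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Library simulation
# ---------------------------------------------------------------------------

# per-superfamily TSD lengths used by the simulated library (field-typical)
_TSD_BY_SUPERFAMILY = {
    "Ty1-copia": 5,
    "Ty3-gypsy": 5,
    "hAT": 8,
    "CACTA": 3,
    "Mutator": 9,
    "Harbinger": 3,
    "Helitron": 0,
    "MITE/Stowaway": 2,
    "MITE/Tourist": 3,
}

_MITE_BUCKETS = ("MITE/Stowaway", "MITE/Tourist")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def simulate_library(
    n_families: int,
    length_ranges: dict[str, tuple[int, int]] | None = None,
    seed: int = 0,
    ltr_length_range: tuple[int, int] = (250, 500),
    tir_length: int = 14,
) -> TELibrary:
    """Generate a random TE library with realistic structure.

    LTR families carry two identical LTR copies at the consensus ends; TIR
    families begin with a motif whose reverse complement ends the consensus.
    Superfamilies cycle through the taxonomy so every bucket is exercised.
    Deterministic given ``seed``.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    length_ranges = length_ranges or {CLASS_I: (3000, 8000), CLASS_II: (400, 2500)}
    mite_range = (150, 600)
    rng = np.random.default_rng(seed)

    class2_cycle = [b for b in TAXONOMY[CLASS_II] if b != "other"]
    fams: list[TEFamily] = []
    n_class1 = max(1, round(n_families * 0.5))
    for i in range(n_families):
        if i < n_class1:
            bucket = "Ty3-gypsy" if i % 2 == 0 else "Ty1-copia"
            lo, hi = length_ranges[CLASS_I]
            ltr_len = int(rng.integers(*ltr_length_range))
            if hi <= 2 * ltr_len:
                raise ValueError("Class I length range too small to hold two LTRs")
            total = int(rng.integers(max(lo, 2 * ltr_len + 200), hi))
            ltr = _random_seq(rng, ltr_len)
            internal = _random_seq(rng, total - 2 * ltr_len)
            fams.append(
                TEFamily(
                    name=f"RT{i:02d}",
                    te_class=CLASS_I,
                    superfamily=bucket,
                    consensus=ltr + internal + ltr,
                    ltr_span=((0, ltr_len), (total - ltr_len, total)),
                    tsd_length=_TSD_BY_SUPERFAMILY[bucket],
                )
            )
        else:
            bucket = class2_cycle[(i - n_class1) % len(class2_cycle)]
            lo, hi = mite_range if bucket in _MITE_BUCKETS else length_ranges[CLASS_II]
            total = int(rng.integers(lo, hi))
            if bucket == "Helitron":
                consensus = _random_seq(rng, total)
                tir = None
            else:
                tir5 = _random_seq(rng, tir_length)
                middle = _random_seq(rng, total - 2 * tir_length)
                consensus = tir5 + middle + revcomp(tir5)
                tir = tir_length
            fams.append(
                TEFamily(
                    name=f"DT{i:02d}",
                    te_class=CLASS_II,
                    superfamily=bucket,
                    consensus=consensus,
                    tir_length=tir,
                    tsd_length=_TSD_BY_SUPERFAMILY[bucket],
                )
            )
    return library_from_families(fams)


# ---------------------------------------------------------------------------
# Simulation state
# ---------------------------------------------------------------------------

@dataclass
class _Frag:
    start: int
    end: int
    cstart: int
    cend: int


@dataclass
class _Copy:
    event_id: str
    family: str
    strand: str
    rank: int
    lineage: str
    structure: str
    tsd: str
    frags: list[_Frag]
    tsd_left: list[int]
    tsd_right: list[int]
    parent: str | None


@dataclass
class _SimState:
    """Mutable pre-mutation simulation state (resumable across lineages)."""

    seq: str
    copies: list[_Copy]
    blocked: list[list[int]]  # TSD flanks + anchors: no cut may land here
    anchors: list[tuple[str, list[int]]]
    n_events: int = 0

    def clone(self) -> "_SimState":
        return _copy.deepcopy(self)


def _shift_interval(iv: list[int], x: int, delta: int) -> None:
    if iv[0] >= x:
        iv[0] += delta
        iv[1] += delta
    elif iv[1] > x:
        iv[1] += delta  # interval spans the cut; only blocked/anchor zones may


def _project_all(state: _SimState, x: int, delta: int, skip: _Frag | None) -> None:
    """Shift every tracked coordinate after an insertion of ``delta`` bp at ``x``."""
    for cp in state.copies:
        for fr in cp.frags:
            if fr is skip:
                continue
            if fr.start >= x:
                fr.start += delta
                fr.end += delta
            elif fr.end > x:
                raise AssertionError("only the host fragment may span the cut")
        for iv in (cp.tsd_left, cp.tsd_right):
            if iv:
                _shift_interval(iv, x, delta)
    for iv in state.blocked:
        _shift_interval(iv, x, delta)
    for _, iv in state.anchors:
        _shift_interval(iv, x, delta)


def _find_fragment(state: _SimState, x: int) -> tuple[_Copy, _Frag] | None:
    for cp in state.copies:
        for fr in cp.frags:
            if fr.start < x < fr.end:
                return cp, fr
    return None


def _in_blocked(state: _SimState, lo: int, hi: int) -> bool:
    return any(iv[0] < hi and lo < iv[1] for iv in state.blocked)


def _insert_one(
    state: _SimState,
    library: TELibrary,
    config: SimConfig,
    rng: np.random.Generator,
    lineage: str,
    rank: int,
    families: list[str],
    weights: np.ndarray,
) -> None:
    margin = config.min_fragment_margin
    fam = library[families[int(rng.choice(len(families), p=weights))]]
    t = fam.tsd_length

    solo = fam.is_ltr and rng.random() < config.solo_ltr_prob
    if solo:
        s5, e5 = fam.ltr_span[0]
        cons_iv = (s5, e5)
        structure = "solo-LTR"
    else:
        cons_iv = (0, fam.length)
        structure = "intact"
    copy_seq = fam.consensus[cons_iv[0] : cons_iv[1]]
    strand = "+" if rng.random() < 0.5 else "-"
    genomic = copy_seq if strand == "+" else revcomp(copy_seq)
    L = len(genomic)

    # --- choose the cut site ------------------------------------------------
    host: _Copy | None = None
    host_frag: _Frag | None = None
    eligible = [
        (cp, fr)
        for cp in state.copies
        for fr in cp.frags
        if fr.end - fr.start >= 2 * margin + 1
    ]
    if eligible and rng.random() < config.nesting_bias:
        if config.nesting_target == "newest":
            newest = state.copies[-1]
            pool = [(cp, fr) for cp, fr in eligible if cp is newest] or eligible
        else:
            pool = eligible
        lens = np.array([fr.end - fr.start - 2 * margin for _, fr in pool], dtype=float)
        host, host_frag = pool[int(rng.choice(len(pool), p=lens / lens.sum()))]
        x = int(rng.integers(host_frag.start + margin, host_frag.end - margin + 1))
    else:
        for _ in range(10_000):
            x = int(rng.integers(margin + t, len(state.seq) - margin))
            inside = _find_fragment(state, x)
            if inside is not None:
                continue
            if _in_blocked(state, x - t - 1, x + 1):
                continue
            host, host_frag = None, None
            break
        else:
            raise RuntimeError("could not place insertion outside blocked zones")

    # --- splice -------------------------------------------------------------
    tsd = state.seq[x - t : x] if t else ""
    insert_str = genomic + tsd
    delta = len(insert_str)
    state.seq = state.seq[:x] + insert_str + state.seq[x:]

    # split the host fragment at x, maintaining its consensus mapping
    if host_frag is not None:
        off = x - host_frag.start
        if host.strand == "+":
            left = _Frag(host_frag.start, x, host_frag.cstart, host_frag.cstart + off)
            right = _Frag(x, host_frag.end, host_frag.cstart + off, host_frag.cend)
        else:
            left = _Frag(host_frag.start, x, host_frag.cend - off, host_frag.cend)
            right = _Frag(x, host_frag.end, host_frag.cstart, host_frag.cend - off)
        idx = host.frags.index(host_frag)
        host.frags[idx : idx + 1] = [left, right]
        host_frag = right  # the piece that shifts with the insertion
        _project_all(state, x, delta, skip=None)
        # `right` starts exactly at x, so the generic shift already moved it
    else:
        _project_all(state, x, delta, skip=None)

    state.n_events += 1
    ev_id = f"ev{state.n_events:05d}"
    cp = _Copy(
        event_id=ev_id,
        family=fam.name,
        strand=strand,
        rank=rank,
        lineage=lineage,
        structure=structure,
        tsd=tsd,
        frags=[_Frag(x, x + L, cons_iv[0], cons_iv[1])],
        tsd_left=[x - t, x] if t else [],
        tsd_right=[x + L, x + L + t] if t else [],
        parent=host.event_id if host else None,
    )
    state.copies.append(cp)
    if t:
        # widen by t so a later cut cannot carve into either TSD copy
        state.blocked.append([x - 2 * t, x + t])
        state.blocked.append([x + L - t, x + L + 2 * t])


def _mutate(
    seq: str,
    copies: Sequence[_Copy],
    rate_for: dict[str, float],
    backbone_rate: float,
    rng: np.random.Generator,
) -> str:
    """Apply per-copy age-scaled substitutions (and optionally backbone ones)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    in_copy = np.zeros(arr.size, dtype=bool)
    for cp in copies:
        rate = rate_for.get(cp.event_id, 0.0)
        for fr in cp.frags:
            in_copy[fr.start : fr.end] = True
            if rate <= 0:
                continue
            n = fr.end - fr.start
            hits = np.nonzero(rng.random(n) < rate)[0]
            for h in hits:
                pos = fr.start + h
                choices = _BASES[_BASES != arr[pos]]
                arr[pos] = rng.choice(choices)
    if backbone_rate > 0:
        positions = np.nonzero((~in_copy) & (rng.random(arr.size) < backbone_rate))[0]
        for pos in positions:
            choices = _BASES[_BASES != arr[pos]]
            arr[pos] = rng.choice(choices)
    return arr.tobytes().decode()


def _finalize(
    state: _SimState,
    library: TELibrary,
    config: SimConfig,
    rng: np.random.Generator,
    seq_id: str,
    lineage: str,
    total_age: int,
    backbone_rate: float = 0.0,
) -> GroundTruth:
    rate_for = {
        cp.event_id: config.mutation_rate_per_age_unit * (total_age - cp.rank)
        for cp in state.copies
    }
    mutated = _mutate(state.seq, state.copies, rate_for, backbone_rate, rng)
    events = [
        InsertionEvent(
            event_id=cp.event_id,
            family=cp.family,
            strand=cp.strand,
            age_rank=cp.rank,
            lineage=cp.lineage,
            structure=cp.structure,
            tsd=cp.tsd,
            fragments=[(f.start, f.end) for f in cp.frags],
            consensus_fragments=[(f.cstart, f.cend) for f in cp.frags],
            tsd_left=tuple(cp.tsd_left) if cp.tsd_left else None,
            tsd_right=tuple(cp.tsd_right) if cp.tsd_right else None,
            parent_id=cp.parent,
        )
        for cp in state.copies
    ]
    truth = GroundTruth(
        seq_id=seq_id,
        sequence=mutated,
        events=events,
        library=library,
        config=config,
        anchors=[(gid, tuple(iv)) for gid, iv in state.anchors],
        lineage=lineage,
        _state=state,
    )
    log.info("%s: %d events, TE fraction %.1f%%", seq_id, len(events), 100 * truth.te_fraction)
    return truth


def simulate_centromere(library: TELibrary, config: SimConfig) -> GroundTruth:
    """Simulate one centromere-like sequence with a known insertion history."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    backbone = _random_seq(rng, config.backbone_length)
    state = _SimState(seq=backbone, copies=[], blocked=[], anchors=[])

    # anchor "genes": conserved backbone islands no insertion may cut
    if config.n_anchor_genes:
        step = config.backbone_length // (config.n_anchor_genes + 1)
        for i in range(config.n_anchor_genes):
            s = (i + 1) * step
            iv = [s, s + config.anchor_length]
            state.anchors.append((f"gene{i:03d}", iv))
            state.blocked.append(list(iv))

    families = sorted(f.name for f in library)
    if config.family_weights is None:
        weights = np.full(len(families), 1.0 / len(families))
    else:
        weights = np.array([config.family_weights.get(f, 0.0) for f in families])
        weights = weights / weights.sum()

    for i in range(config.n_insertions):
        _insert_one(state, library, config, rng, "ancestral", i + 1, families, weights)

    return _finalize(
        state, library, config, rng, seq_id=f"simcen_seed{config.seed}",
        lineage="ancestral", total_age=config.n_insertions,
    )


def diverge_pair(
    ancestor: GroundTruth,
    config_a: SimConfig,
    config_b: SimConfig,
) -> tuple[GroundTruth, GroundTruth, dict[str, str]]:
    """Evolve two descendant lineages from one simulated ancestor.

    Each lineage receives its own lineage-specific insertions (tagged
    ``lineageA``/``lineageB``) on a copy of the ancestral, pre-mutation
    state; substitutions are then applied with ages continuing from the
    ancestral ranks, plus uniform backbone divergence proportional to the
    lineage's elapsed age.  Ancestral insertions are never lost, so the
    ortholog map is the identity on ancestral event ids.
    """
    if ancestor._state is None:
        raise ValueError("ancestor GroundTruth lacks resumable state")
    n_anc = ancestor.config.n_insertions
    outputs = []
    for tag, cfg in (("lineageA", config_a), ("lineageB", config_b)):
        cfg.validate()
        rng = np.random.default_rng(cfg.seed)
        state = ancestor._state.clone()
        families = sorted(f.name for f in ancestor.library)
        if cfg.family_weights is None:
            weights = np.full(len(families), 1.0 / len(families))
        else:
            weights = np.array([cfg.family_weights.get(f, 0.0) for f in families])
            weights = weights / weights.sum()
        for i in range(cfg.n_insertions):
            _insert_one(
                state, ancestor.library, cfg, rng, tag, n_anc + i + 1, families, weights
            )
        truth = _finalize(
            state,
            ancestor.library,
            cfg,
            rng,
            seq_id=f"{ancestor.seq_id}_{tag}",
            lineage=tag,
            total_age=n_anc + cfg.n_insertions,
            backbone_rate=cfg.mutation_rate_per_age_unit * cfg.n_insertions,
        )
        outputs.append(truth)
    truth_a, truth_b = outputs
    ortholog_map = {
        ev.event_id: ev.event_id for ev in truth_a.events if ev.lineage == "ancestral"
    }
    return truth_a, truth_b, ortholog_map


# ---------------------------------------------------------------------------
# ChIP-style read simulation
# ---------------------------------------------------------------------------

def simulate_chip_reads(
    truth: GroundTruth,
    enrichment: dict[str, float],
    read_length: int = 100,
    n_reads: int = 10_000,
    seed: int = 0,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Sample reads with family-proportional enrichment.

    Read start positions are drawn with probability proportional to the
    enrichment weight of the element covering the read midpoint ("backbone"
    keys the weight of un-annotated sequence, default 1.0); the truth label
    of a read is the family at that same midpoint, so sampled weights and
    labels agree exactly.  Reads are reverse-complemented with probability
    0.5 and carry fixed base qualities.
    """
    if not enrichment:
        raise ValueError("enrichment mapping must not be empty")
    L = len(truth.sequence)
    if read_length > L:
        raise ValueError("read_length exceeds sequence length")
    rng = np.random.default_rng(seed)

    owner = np.full(L, -1, dtype=np.int32)  # index into truth.events
    for i, ev in enumerate(truth.events):
        for s, e in ev.fragments:
            owner[s:e] = i
    weights = np.full(L, float(enrichment.get("backbone", 1.0)))
    for i, ev in enumerate(truth.events):
        w = float(enrichment.get(ev.family, 0.0))
        for s, e in ev.fragments:
            weights[s:e] = w

    # weight each candidate start by the family at the read midpoint
    start_w = weights[read_length // 2 : read_length // 2 + (L - read_length + 1)].copy()
    total = start_w.sum()
    if total <= 0:
        raise ValueError("all enrichment weights are zero")
    starts = rng.choice(start_w.size, size=n_reads, p=start_w / total)

    records: list[SeqRecord] = []
    rows = []
    for i, s in enumerate(starts):
        s = int(s)
        frag = truth.sequence[s : s + read_length]
        flip = bool(rng.random() < 0.5)
        read_seq = revcomp(frag) if flip else frag
        rid = f"read{i:06d}"
        rec = SeqRecord(Seq(read_seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = [40] * read_length
        records.append(rec)
        mid = s + read_length // 2
        ev_idx = int(owner[mid])
        label = truth.events[ev_idx].family if ev_idx >= 0 else "backbone"
        fully_inside = False
        if ev_idx >= 0:
            fully_inside = any(
                fs <= s and s + read_length <= fe
                for fs, fe in truth.events[ev_idx].fragments
            )
        rows.append(
            {
                "read_id": rid,
                "start": s,
                "end": s + read_length,
                "reverse": flip,
                "label": label,
                "fully_inside": fully_inside,
            }
        )
    return records, pd.DataFrame(rows)


def write_fastq(records: Sequence[SeqRecord], path: str | Path) -> None:
    SeqIO.write(list(records), str(path), "fastq")


# ---------------------------------------------------------------------------
# Ground-truth-derived hits (perfect-annotation input for the curation stage)
# ---------------------------------------------------------------------------

def ground_truth_hits(truth: GroundTruth, score_per_bp: float = 10.0) -> list[RawHit]:
    """Emit one repeat hit per event fragment, as an idealised annotator would.

    Scores scale with fragment length; divergence mirrors the copy's
    simulated substitution rate.
    """
    n_total = max(ev.age_rank for ev in truth.events) if truth.events else 0
    hits: list[RawHit] = []
    for ev in truth.events:
        rate = truth.config.mutation_rate_per_age_unit * (n_total - ev.age_rank)
        for (s, e), (cs, ce) in zip(ev.fragments, ev.consensus_fragments):
            hits.append(
                RawHit(
                    query_id=truth.seq_id,
                    qstart=s,
                    qend=e,
                    strand=ev.strand,
                    family=ev.family,
                    cstart=cs,
                    cend=ce,
                    score=score_per_bp * (e - s),
                    divergence=min(100.0, 100.0 * rate),
                )
            )
    hits.sort(key=lambda h: h.qstart)
    return hits
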