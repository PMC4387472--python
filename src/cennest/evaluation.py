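"""Scoring of curated annotations against simulator ground truth.

These helpers compare a curated element set with the event log of a
:class:`~cennest.synthetic_centromere.GroundTruth`: element-level recall and
precision, nesting-forest agreement, TSD recovery, and ortholog-calling F1.
They are evaluation plumbing for synthetic benchmarks, not part of the
annotation pipeline itself.
"""

from __future__ import annotations

from typing import Sequence

from ._util import union_length
from .annotation_curation import Element
from .comparative import OrthologPair
from .synthetic_centromere import GroundTruth


def match_elements_to_events(
    elements: Sequence[Element], truth: GroundTruth, min_jaccard: float = 0.99
) -> dict[str, str]:
    """Map element ids to event ids by fragment-set Jaccard overlap."""
    mapping: dict[str, str] = {}
    for el in elements:
        el_ivs = el.fragments
        el_len = sum(e - s for s, e in el_ivs)
        best: tuple[float, str] | None = None
        for ev in truth.events:
            inter = 0
            for s, e in el_ivs:
                for ts, te in ev.fragments:
                    inter += max(0, min(e, te) - max(s, ts))
            if inter == 0:
                continue
            union = union_length(list(el_ivs) + list(ev.fragments))
            jac = inter / union if union else 0.0
            if best is None or jac > best[0]:
                best = (jac, ev.event_id)
        if best is not None and best[0] >= min_jaccard:
            mapping[el.element_id] = best[1]
    return mapping


def element_recall_precision(
    elements: Sequence[Element], truth: GroundTruth, min_jaccard: float = 0.99
) -> tuple[float, float]:
    """Event-level recall and element-level precision of a curated set."""
    mapping = match_elements_to_events(elements, truth, min_jaccard)
    recovered = set(mapping.values())
    recall = len(recovered) / len(truth.events) if truth.events else 1.0
    precision = len(mapping) / len(elements) if elements else 1.0
    return recall, precision


def forest_agreement(
    elements: Sequence[Element], truth: GroundTruth, min_jaccard: float = 0.99
) -> float:
    """Fraction of matched elements whose recovered host equals the planted
    parent (both mapped through the element/event correspondence)."""
    mapping = match_elements_to_events(elements, truth, min_jaccard)
    parent = truth.parent_map
    ok = total = 0
    for el in elements:
        if el.element_id not in mapping:
            continue
        total += 1
        truth_parent = parent[mapping[el.element_id]]
        found_parent = mapping.get(el.host_id) if el.host_id else None
        if truth_parent == found_parent:
            ok += 1
    return ok / total if total else 1.0


def tsd_recovery_rate(
    elements: Sequence[Element], truth: GroundTruth, min_jaccard: float = 0.99
) -> float:
    """Fraction of matched events with an expected TSD whose detected TSD
    sequence equals the planted one."""
    mapping = match_elements_to_events(elements, truth, min_jaccard)
    events = {ev.event_id: ev for ev in truth.events}
    ok = total = 0
    for el in elements:
        ev = events.get(mapping.get(el.element_id, ""))
        if ev is None or not ev.tsd:
            continue
        total += 1
        if el.tsd == ev.tsd:
            ok += 1
    return ok / total if total else 1.0


def ortholog_f1(
    pairs: Sequence[OrthologPair],
    elements_a: Sequence[Element],
    elements_b: Sequence[Element],
    truth_a: GroundTruth,
    truth_b: GroundTruth,
    ortholog_map: dict[str, str],
    comparable_a: set[str] | None = None,
    comparable_b: set[str] | None = None,
) -> float:
    """F1 of predicted ortholog pairs against the planted ortholog map.

    Predicted element-id pairs are translated to event-id pairs; the truth
    set is restricted to ancestral events whose copies fall in the
    comparable (anchored) region on both sides when those sets are given.
    """
    map_a = match_elements_to_events(elements_a, truth_a)
    map_b = match_elements_to_events(elements_b, truth_b)
    predicted = {
        (map_a[p.id_a], map_b[p.id_b])
        for p in pairs
        if p.id_a in map_a and p.id_b in map_b
    }
    truth_pairs = {
        (ea, eb)
        for ea, eb in ortholog_map.items()
        if (comparable_a is None or ea in comparable_a)
        and (comparable_b is None or eb in comparable_b)
    }
    tp = len(predicted & truth_pairs)
    fp = len(predicted - truth_pairs)
    fn = len(truth_pairs - predicted)
    if tp == 0:
        return 0.0
    return 2 * tp / (2 * tp + fp + fn)
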