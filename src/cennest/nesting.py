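"""Nesting forest reconstruction and nested-block statistics.

A transposon inserted into another transposon splits its host into
fragments; iterated insertions build multi-layer nested blocks.  Given
curated, defragmented elements, this module assigns each element to the
host whose inter-fragment gap contains it (smallest enclosing gap wins),
computes layer depths, extracts maximal nested blocks rooted at layer-1
hosts, and tabulates class-level insertion preferences.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from ._util import round_half_up
from .annotation_curation import Element
from .te_model import CLASS_I, TELibrary

log = logging.getLogger(__name__)


@dataclass
class NestNode:
    element_id: str
    host: str | None  # None = backbone
    children: list[str] = field(default_factory=list)
    layer: int = 1


@dataclass
class NestedBlock:
    """A layer-1 host together with everything nested inside it."""

    root_id: str
    member_ids: list[str]
    span: tuple[int, int]
    max_layer: int

    @property
    def size(self) -> int:
        return self.span[1] - self.span[0]


@dataclass
class InsertionGroupCounts:
    """Four-way split of TE-hosted insertions by (nested class -> host class)."""

    rna_into_rna: int = 0
    rna_into_dna: int = 0
    dna_into_rna: int = 0
    dna_into_dna: int = 0

    @property
    def total(self) -> int:
        return self.rna_into_rna + self.rna_into_dna + self.dna_into_rna + self.dna_into_dna

    @property
    def preference_ratio(self) -> float:
        return insertion_preference_ratio(self.rna_into_rna, self.rna_into_dna)

    def as_dict(self) -> dict[str, int]:
        return {
            "RNA->RNA": self.rna_into_rna,
            "RNA->DNA": self.rna_into_dna,
            "DNA->RNA": self.dna_into_rna,
            "DNA->DNA": self.dna_into_dna,
        }


def build_nesting_forest(elements: Sequence[Element]) -> dict[str, NestNode]:
    """Assign every element a host and a layer.

    Element B is nested in host A when B's block span lies inside the gap
    between two consecutive fragments of A; among multiple candidate hosts
    the smallest enclosing gap wins.  Elements with no host attach to the
    backbone (layer 1).  Mutates ``host_id``/``layer`` on the elements and
    returns the forest.
    """
    nodes = {el.element_id: NestNode(el.element_id, None) for el in elements}
    by_id = {el.element_id: el for el in elements}

    for el in elements:
        bs, be = el.span
        best: tuple[int, str] | None = None
        for other in elements:
            if other is el:
                continue
            frags = other.fragments
            for (s0, e0), (s1, e1) in zip(frags, frags[1:]):
                if e0 <= bs and be <= s1:
                    key = (s1 - e0, other.element_id)
                    if best is None or key < best:
                        best = key
        if best is None:
            # flag spans that overlap another element without clean containment
            for other in elements:
                if other is el:
                    continue
                os_, oe = other.span
                if bs < oe and os_ < be and not (os_ <= bs and be <= oe) and not (bs <= os_ and oe <= be):
                    log.warning(
                        "elements %s and %s overlap without containment",
                        el.element_id, other.element_id,
                    )
        else:
            nodes[el.element_id].host = best[1]
            nodes[best[1]].children.append(el.element_id)

    # layers by traversal from the roots
    for node in nodes.values():
        node.children.sort(key=lambda cid: by_id[cid].span[0])
    roots = [nid for nid, n in nodes.items() if n.host is None]
    stack = [(r, 1) for r in roots]
    seen = 0
    while stack:
        nid, layer = stack.pop()
        nodes[nid].layer = layer
        seen += 1
        stack.extend((c, layer + 1) for c in nodes[nid].children)
    if seen != len(nodes):  # pragma: no cover - containment is acyclic by construction
        raise RuntimeError("nesting forest contains a cycle")

    for el in elements:
        el.host_id = nodes[el.element_id].host
        el.layer = nodes[el.element_id].layer
    return nodes


def extract_blocks(
    forest: dict[str, NestNode],
    elements: Sequence[Element],
    sequence_length: int,
) -> tuple[list[NestedBlock], dict[str, float]]:
    """Maximal nested blocks and their summary statistics.

    A block is a layer-1 host with at least one nested descendant; its size
    is the genomic span of the root from first fragment start to last
    fragment end (which contains all nested content).  Density is blocks
    per Mb, reported to one decimal.
    """
    by_id = {el.element_id: el for el in elements}
    blocks: list[NestedBlock] = []
    for nid, node in forest.items():
        if node.host is not None or not node.children:
            continue
        members = [nid]
        max_layer = 1
        stack = list(node.children)
        while stack:
            cid = stack.pop()
            members.append(cid)
            max_layer = max(max_layer, forest[cid].layer)
            stack.extend(forest[cid].children)
        blocks.append(
            NestedBlock(
                root_id=nid,
                member_ids=sorted(members),
                span=by_id[nid].span,
                max_layer=max_layer,
            )
        )
    blocks.sort(key=lambda b: b.span[0])

    sizes = [b.size for b in blocks]
    summary = {
        "n_blocks": float(len(blocks)),
        "min_size": float(min(sizes)) if sizes else 0.0,
        "max_size": float(max(sizes)) if sizes else 0.0,
        "mean_size": float(sum(sizes) / len(sizes)) if sizes else 0.0,
        "density_per_mb": nested_block_density(len(blocks), sequence_length / 1e6),
    }
    return blocks, summary


def nested_block_density(n_blocks: int, sequence_mb: float) -> float:
    """Blocks per Mb, rounded half-up to one decimal."""
    if sequence_mb <= 0:
        raise ValueError("sequence length must be positive")
    return round_half_up(n_blocks / sequence_mb, 1)


def insertion_preference_ratio(n_rna_into_rna: int, n_rna_into_dna: int) -> float:
    """Ratio of RNA->RNA to RNA->DNA nested insertions, one decimal."""
    if n_rna_into_dna == 0:
        return math.inf
    return round_half_up(n_rna_into_rna / n_rna_into_dna, 1)


def classify_insertion_groups(
    forest: dict[str, NestNode],
    elements: Sequence[Element],
    library: TELibrary,
) -> InsertionGroupCounts:
    """Count TE-hosted insertions by nested-class -> immediate-host-class."""
    by_id = {el.element_id: el for el in elements}
    counts = InsertionGroupCounts()
    for el in elements:
        host = forest[el.element_id].host
        if host is None:
            continue
        nested_rna = library[el.family].te_class == CLASS_I
        host_rna = library[by_id[host].family].te_class == CLASS_I
        if nested_rna and host_rna:
            counts.rna_into_rna += 1
        elif nested_rna:
            counts.rna_into_dna += 1
        elif host_rna:
            counts.dna_into_rna += 1
        else:
            counts.dna_into_dna += 1
    return counts


def blocks_to_dataframe(blocks: Sequence[NestedBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "root_id": [b.root_id for b in blocks],
            "start": [b.span[0] for b in blocks],
            "end": [b.span[1] for b in blocks],
            "size_bp": [b.size for b in blocks],
            "n_members": [len(b.member_ids) for b in blocks],
            "max_layer": [b.max_layer for b in blocks],
            "members": [",".join(b.member_ids) for b in blocks],
        }
    )
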