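"""Windowed family-density tracks and gene/TE overlap classification."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gffutils
import pandas as pd

from ._util import overlap_length, union_length
from .annotation_curation import Element
from .te_model import TELibrary

log = logging.getLogger(__name__)

Interval = tuple[int, int]


@dataclass
class GeneModel:
    """A protein-coding gene model with derived intron intervals.

    All intervals are 0-based half-open on the chromosome.  Introns are the
    gaps between consecutive exons; UTRs are exonic sequence outside the CDS.
    """

    gene_id: str
    seqid: str
    strand: str
    start: int
    end: int
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    @property
    def introns(self) -> list[Interval]:
        ex = sorted(self.exons)
        return [(e0, s1) for (_, e0), (s1, _) in zip(ex, ex[1:]) if s1 > e0]

    @property
    def utrs(self) -> list[Interval]:
        return sorted(self.utr5 + self.utr3)


@dataclass
class GeneTEOverlap:
    gene_id: str
    element_id: str
    compartment: str  # CDS | intron | UTR
    superfamily: str
    te_class: str


def load_gene_models(gff3_path: str | Path) -> list[GeneModel]:
    """Read gene models (gene/mRNA/exon/CDS/UTR features) from GFF3."""
    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        gm = GeneModel(
            gene_id=gene.id,
            seqid=gene.seqid,
            strand=gene.strand,
            start=gene.start - 1,
            end=gene.end,
        )
        for feat in db.children(gene, order_by="start"):
            iv = (feat.start - 1, feat.end)
            if feat.featuretype == "exon":
                gm.exons.append(iv)
            elif feat.featuretype == "CDS":
                gm.cds.append(iv)
            elif feat.featuretype in ("five_prime_UTR", "5UTR"):
                gm.utr5.append(iv)
            elif feat.featuretype in ("three_prime_UTR", "3UTR"):
                gm.utr3.append(iv)
        genes.append(gm)
    return genes


def filter_te_coding_genes(
    genes: Sequence[GeneModel],
    elements: Sequence[Element],
    max_te_cds_frac: float = 0.5,
) -> list[GeneModel]:
    """Drop genes whose CDS is mostly transposon: they encode TE proteins,
    not true centromere genes, and are excluded before overlap analysis."""
    te_ivs = [f for el in elements for f in el.fragments]
    kept = []
    for g in genes:
        cds_len = union_length(g.cds)
        if cds_len == 0:
            kept.append(g)
            continue
        te_in_cds = sum(
            overlap_length(c, t) for c in g.cds for t in te_ivs
        )
        if te_in_cds / cds_len >= max_te_cds_frac:
            log.info("dropping TE-coding gene %s", g.gene_id)
            continue
        kept.append(g)
    return kept


# ---------------------------------------------------------------------------
# Window density tracks
# ---------------------------------------------------------------------------

def window_density(
    elements: Sequence[Element],
    chrom_length: int,
    window: int = 100_000,
) -> pd.DataFrame:
    """Per-window, per-family element counts (copy number track).

    Each element is assigned once, to the window containing its block
    midpoint, so window counts always sum to the element count.  The last
    partial window is kept.
    """
    n_windows = max(1, -(-chrom_length // window))
    families = sorted({el.family for el in elements})
    df = pd.DataFrame(
        0,
        index=pd.Index(
            [i * window for i in range(n_windows)], name="window_start"
        ),
        columns=families,
        dtype=int,
    )
    for el in elements:
        s, e = el.span
        mid = (s + e) // 2
        df.loc[min(mid // window, n_windows - 1) * window, el.family] += 1
    return df


def window_track_to_bedgraph(
    track: pd.DataFrame, seqid: str, family: str, window: int = 100_000
) -> str:
    lines = []
    for start, count in track[family].items():
        lines.append(f"{seqid}\t{start}\t{start + window}\t{count}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Gene / TE overlap classification
# ---------------------------------------------------------------------------

_PRECEDENCE = {"CDS": 0, "UTR": 1, "intron": 2}


def classify_gene_te_overlap(
    elements: Sequence[Element],
    genes: Sequence[GeneModel],
    library: TELibrary,
) -> tuple[list[GeneTEOverlap], pd.DataFrame]:
    """Classify gene-overlapping elements into CDS / UTR / intron.

    An element overlapping a gene is assigned the compartment with the
    largest base-pair overlap, with the precedence CDS > UTR > intron
    breaking ties.  Intergenic elements are excluded.  Returns the overlap
    records plus a per-superfamily summary with CDS/intron/UTR columns and
    an "all" total.
    """
    overlaps: list[GeneTEOverlap] = []
    for el in elements:
        span = el.span
        best: tuple[int, int, GeneModel, str] | None = None  # (-bp, precedence, ...)
        for g in genes:
            if span[1] <= g.start or g.end <= span[0]:
                continue
            for name, ivs in (("CDS", g.cds), ("UTR", g.utrs), ("intron", g.introns)):
                bp = sum(
                    overlap_length(f, iv) for f in el.fragments for iv in ivs
                )
                if bp <= 0:
                    continue
                key = (-bp, _PRECEDENCE[name], g, name)
                if best is None or key[:2] < best[:2]:
                    best = key
        if best is not None:
            cls, bucket = library.bucket(el.family)
            overlaps.append(
                GeneTEOverlap(
                    gene_id=best[2].gene_id,
                    element_id=el.element_id,
                    compartment=best[3],
                    superfamily=bucket,
                    te_class=cls,
                )
            )

    buckets = sorted({o.superfamily for o in overlaps})
    summary = pd.DataFrame(
        0, index=buckets + ["Total"], columns=["CDS", "intron", "UTR", "all"], dtype=int
    )
    for o in overlaps:
        summary.loc[o.superfamily, o.compartment] += 1
        summary.loc["Total", o.compartment] += 1
    summary["all"] = summary[["CDS", "intron", "UTR"]].sum(axis=1)
    return overlaps, summary


def compartment_fraction(count: int, total: int) -> float:
    """Percentage of gene-associated elements in one compartment, 1 decimal."""
    from ._util import round_half_up

    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100.0 * count / total, 1)
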