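"""Transposable-element library model and taxonomy.

A *TE library* is a set of family consensus sequences plus the structural
metadata the curation stages need: LTR coordinates for LTR retrotransposons,
TIR length for DNA transposons, and the expected target-site-duplication
(TSD) length for every family.  Families are bucketed into a fixed
superfamily taxonomy: Class I (retrotransposons) Ty1-copia / Ty3-gypsy /
other, and Class II (DNA transposons) hAT / CACTA / Mutator / Harbinger /
Helitron / MITE-Stowaway / MITE-Tourist / other.

Coordinates on the consensus are 0-based half-open throughout the package;
files in 1-based formats (GFF3, RepeatMasker tables) are converted at the
I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

CLASS_I = "I"
CLASS_II = "II"

#: Superfamily buckets, per TE class.  Every family maps to exactly one bucket.
TAXONOMY: dict[str, tuple[str, ...]] = {
    CLASS_I: ("Ty1-copia", "Ty3-gypsy", "other"),
    CLASS_II: (
        "hAT",
        "CACTA",
        "Mutator",
        "Harbinger",
        "Helitron",
        "MITE/Stowaway",
        "MITE/Tourist",
        "other",
    ),
}

# Canonical label -> (class, bucket).  Keys are lowercase; matching is
# case-insensitive.  Synonyms cover the common library spellings (MULE,
# PIF/Harbinger, Stow/Tourist shorthands, non-LTR retros).
_LABEL_MAP: dict[str, tuple[str, str]] = {
    "ty1-copia": (CLASS_I, "Ty1-copia"),
    "ty1/copia": (CLASS_I, "Ty1-copia"),
    "copia": (CLASS_I, "Ty1-copia"),
    "ty3-gypsy": (CLASS_I, "Ty3-gypsy"),
    "ty3/gypsy": (CLASS_I, "Ty3-gypsy"),
    "gypsy": (CLASS_I, "Ty3-gypsy"),
    "line": (CLASS_I, "other"),
    "sine": (CLASS_I, "other"),
    "hat": (CLASS_II, "hAT"),
    "cacta": (CLASS_II, "CACTA"),
    "en-spm": (CLASS_II, "CACTA"),
    "mutator": (CLASS_II, "Mutator"),
    "mule": (CLASS_II, "Mutator"),
    "mudr": (CLASS_II, "Mutator"),
    "harbinger": (CLASS_II, "Harbinger"),
    "pif/harbinger": (CLASS_II, "Harbinger"),
    "pif": (CLASS_II, "Harbinger"),
    "helitron": (CLASS_II, "Helitron"),
    "mite/stowaway": (CLASS_II, "MITE/Stowaway"),
    "mite/stow": (CLASS_II, "MITE/Stowaway"),
    "stowaway": (CLASS_II, "MITE/Stowaway"),
    "mite/tourist": (CLASS_II, "MITE/Tourist"),
    "tourist": (CLASS_II, "MITE/Tourist"),
    "tc1/mariner": (CLASS_II, "other"),
    "mariner": (CLASS_II, "other"),
}

_VALID_BASES = frozenset("ACGTN")


def classify_superfamily(raw_label: str, te_class: str | None = None) -> tuple[str, str]:
    """Map a raw superfamily label to a ``(te_class, bucket)`` pair.

    Case-insensitive and total: labels outside the taxonomy fall back to the
    "other" bucket of ``te_class`` (Class I when no class hint is given).
    """
    hit = _LABEL_MAP.get(raw_label.strip().lower())
    if hit is not None:
        if te_class is not None and hit[0] != te_class:
            # metadata class wins; e.g. a Class II library entry labelled
            # with a retro superfamily is an annotation slip
            log.warning(
                "superfamily %r implies class %s but metadata says %s; using %s/other",
                raw_label, hit[0], te_class, te_class,
            )
            return te_class, "other"
        return hit
    cls = te_class if te_class in (CLASS_I, CLASS_II) else CLASS_I
    log.warning("unknown superfamily %r -> class %s bucket 'other'", raw_label, cls)
    return cls, "other"


@dataclass
class TEFamily:
    """One library entry: consensus sequence plus structural metadata.

    ``ltr_span`` gives the 5' and 3' LTR intervals on the consensus
    (half-open); it is present only for LTR retrotransposons.  ``tir_length``
    is the terminal-inverted-repeat length of Class II families (absent for
    Helitrons, which also carry ``tsd_length`` 0).
    """

    name: str
    te_class: str
    superfamily: str
    consensus: str
    ltr_span: tuple[tuple[int, int], tuple[int, int]] | None = None
    tir_length: int | None = None
    tsd_length: int = 0

    def __post_init__(self) -> None:
        self.consensus = self.consensus.upper()
        self.validate()

    # -- derived accessors -------------------------------------------------
    @property
    def length(self) -> int:
        return len(self.consensus)

    @property
    def is_ltr(self) -> bool:
        return self.ltr_span is not None

    @property
    def internal_span(self) -> tuple[int, int] | None:
        """Consensus interval between the two LTRs (LTR families only)."""
        if self.ltr_span is None:
            return None
        return self.ltr_span[0][1], self.ltr_span[1][0]

    def validate(self) -> None:
        if not self.consensus:
            raise ValueError(f"family {self.name}: empty consensus")
        bad = set(self.consensus) - _VALID_BASES
        if bad:
            raise ValueError(f"family {self.name}: invalid bases {sorted(bad)}")
        if self.te_class not in TAXONOMY:
            raise ValueError(f"family {self.name}: te_class must be I or II")
        if self.superfamily not in TAXONOMY[self.te_class]:
            raise ValueError(
                f"family {self.name}: superfamily {self.superfamily!r} not in "
                f"class {self.te_class} taxonomy"
            )
        if not 0 <= self.tsd_length <= 20:
            raise ValueError(f"family {self.name}: tsd_length outside [0, 20]")
        if self.ltr_span is not None:
            if self.te_class != CLASS_I:
                raise ValueError(f"family {self.name}: ltr_span on a Class II family")
            (s5, e5), (s3, e3) = self.ltr_span
            if not (0 <= s5 < e5 <= s3 < e3 <= self.length):
                raise ValueError(f"family {self.name}: ltr_span outside consensus bounds")
            if e5 - s5 != e3 - s3:
                raise ValueError(f"family {self.name}: LTR intervals differ in length")
        if self.tir_length is not None:
            if self.te_class != CLASS_II:
                raise ValueError(f"family {self.name}: tir_length on a Class I family")
            if not 0 < self.tir_length <= self.length // 2:
                raise ValueError(f"family {self.name}: tir_length out of range")


@dataclass
class TELibrary:
    """A validated set of :class:`TEFamily`, keyed by family name."""

    families: dict[str, TEFamily] = field(default_factory=dict)

    def __iter__(self) -> Iterator[TEFamily]:
        return iter(self.families.values())

    def __len__(self) -> int:
        return len(self.families)

    def __contains__(self, name: str) -> bool:
        return name in self.families

    def __getitem__(self, name: str) -> TEFamily:
        return self.families[name]

    def add(self, fam: TEFamily) -> None:
        if fam.name in self.families:
            raise ValueError(f"duplicate family name {fam.name!r}")
        self.families[fam.name] = fam

    def bucket(self, name: str) -> tuple[str, str]:
        fam = self.families[name]
        return fam.te_class, fam.superfamily

    def bucket_sizes(self) -> dict[tuple[str, str], int]:
        sizes: dict[tuple[str, str], int] = {}
        for fam in self:
            key = (fam.te_class, fam.superfamily)
            sizes[key] = sizes.get(key, 0) + 1
        return sizes

    # -- I/O ---------------------------------------------------------------
    def write(self, fasta_path: str | Path, metadata_path: str | Path) -> None:
        records = [
            SeqRecord(Seq(f.consensus), id=f.name, description="") for f in self
        ]
        SeqIO.write(records, str(fasta_path), "fasta")
        rows = []
        for f in self:
            (s5, e5), (s3, e3) = f.ltr_span if f.ltr_span else ((None, None), (None, None))
            rows.append(
                {
                    "name": f.name,
                    "class": f.te_class,
                    "superfamily": f.superfamily,
                    "ltr5_start": s5,
                    "ltr5_end": e5,
                    "ltr3_start": s3,
                    "ltr3_end": e3,
                    "tir_length": f.tir_length,
                    "tsd_length": f.tsd_length,
                }
            )
        pd.DataFrame(rows).to_csv(metadata_path, sep="\t", index=False)


def load_te_library(fasta_path: str | Path, metadata_path: str | Path) -> TELibrary:
    """Load and validate a TE library from FASTA + tab-separated metadata.

    The metadata table has columns name, class, superfamily, ltr5_start,
    ltr5_end, ltr3_start, ltr3_end, tir_length, tsd_length; coordinates are
    0-based half-open on the consensus.  FASTA identifiers and metadata rows
    must match one-to-one; softmasked sequence is uppercased.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate family name {rec.id!r} in FASTA")
        seqs[rec.id] = str(rec.seq).upper()

    meta = pd.read_csv(metadata_path, sep="\t", dtype={"name": str})
    if meta["name"].duplicated().any():
        dup = meta.loc[meta["name"].duplicated(), "name"].iloc[0]
        raise ValueError(f"duplicate family name {dup!r} in metadata")
    names = set(meta["name"])
    if names != set(seqs):
        missing = sorted((names ^ set(seqs)))[:5]
        raise ValueError(f"FASTA/metadata identifiers differ (e.g. {missing})")

    lib = TELibrary()
    for _, row in meta.iterrows():
        te_class, bucket = classify_superfamily(str(row["superfamily"]), str(row["class"]))
        ltr_span = None
        if pd.notna(row["ltr5_start"]):
            ltr_span = (
                (int(row["ltr5_start"]), int(row["ltr5_end"])),
                (int(row["ltr3_start"]), int(row["ltr3_end"])),
            )
        tir = int(row["tir_length"]) if pd.notna(row["tir_length"]) else None
        lib.add(
            TEFamily(
                name=str(row["name"]),
                te_class=te_class,
                superfamily=bucket,
                consensus=seqs[str(row["name"])],
                ltr_span=ltr_span,
                tir_length=tir,
                tsd_length=int(row["tsd_length"]) if pd.notna(row["tsd_length"]) else 0,
            )
        )
    return lib


def library_from_families(families: Iterable[TEFamily]) -> TELibrary:
    lib = TELibrary()
    for fam in families:
        lib.add(fam)
    return lib


def class_of(library: TELibrary | Mapping[str, TEFamily], family: str) -> str:
    fam = library[family] if isinstance(library, TELibrary) else library[family]
    return fam.te_class
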