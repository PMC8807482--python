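"""Murine IGH germline mini-reference: segment model, loading, validation.

The package bundles a small synthetic heavy-chain locus (8 V including the
IGHV1-7 gene that dominates antigen-specific repertoires here, 4 D, 4 J) as a
FASTA file plus a TSV anchor table.  Anchors mark the first base of the
conserved CDR3-flanking codons: the V-gene cysteine (position 104 in IMGT
numbering) and the J-gene tryptophan/phenylalanine (position 118).  The CDR3
convention throughout the package includes both anchor codons.

All coordinates are 0-based, half-open.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import GermlineError

_NT = frozenset("ACGT")

#: Packaged synthetic mini-locus (not an IMGT extract; see docs/methods.md).
DEFAULT_FASTA = "igh_mini_synthetic.fasta"
DEFAULT_ANCHORS = "igh_mini_synthetic_anchors.tsv"


def translate(nt: str) -> str:
    """Translate a nucleotide string in frame; stop codons become ``*``.

    Raises ``ValueError`` on length not divisible by 3 or non-ACGT characters.
    """
    if len(nt) % 3 != 0:
        raise ValueError(f"length {len(nt)} is not a multiple of 3")
    s = nt.upper()
    bad = set(s) - _NT
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)}")
    if not s:
        return ""
    return str(Seq(s).translate())


@dataclass(frozen=True)
class GermlineSegment:
    """One germline gene segment.

    ``anchor`` is the 0-based position of the first base of the conserved CDR3
    anchor codon (Cys for V, Trp/Phe for J); ``None`` for D segments.
    """

    name: str
    family: str
    segment_class: str  # "V", "D" or "J"
    sequence: str
    anchor: Optional[int] = None

    def __post_init__(self) -> None:
        if self.segment_class not in ("V", "D", "J"):
            raise GermlineError(f"{self.name}: unknown segment class {self.segment_class!r}")
        if len(self.sequence) < 3 or set(self.sequence) - _NT:
            raise GermlineError(f"{self.name}: sequence must be >=3 nt over A/C/G/T")
        if self.segment_class in ("V", "J"):
            a = self.anchor
            if a is None or a < 0 or a + 3 > len(self.sequence):
                raise GermlineError(f"{self.name}: anchor {a} out of range")
            aa = translate(self.sequence[a : a + 3])
            if self.segment_class == "V" and aa != "C":
                raise GermlineError(f"{self.name}: V anchor codon translates to {aa}, expected C")
            if self.segment_class == "J" and aa not in ("W", "F"):
                raise GermlineError(f"{self.name}: J anchor codon translates to {aa}, expected W or F")
        elif self.anchor is not None:
            raise GermlineError(f"{self.name}: D segments carry no anchor")

    @property
    def gene(self) -> str:
        """Gene name without the allele suffix (``IGHV1-7*01`` -> ``IGHV1-7``)."""
        return self.name.split("*", 1)[0]


def family_of(name: str) -> str:
    """Gene family per IMGT-style naming: substring before the hyphen-number."""
    gene = name.split("*", 1)[0]
    return gene.split("-", 1)[0]


@dataclass
class GermlineReference:
    """Validated collection of V/D/J segments with unique names."""

    v_segments: List[GermlineSegment]
    d_segments: List[GermlineSegment]
    j_segments: List[GermlineSegment]
    version_tag: str = "bcrep-mini-synthetic-1"
    _by_name: Dict[str, GermlineSegment] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for segs, cls in ((self.v_segments, "V"), (self.d_segments, "D"), (self.j_segments, "J")):
            if not segs:
                raise GermlineError(f"reference has no {cls} segments")
            for s in segs:
                if s.segment_class != cls:
                    raise GermlineError(f"{s.name}: class {s.segment_class} in {cls} collection")
        self._by_name = {}
        for s in self.all_segments():
            if s.name in self._by_name:
                raise GermlineError(f"duplicate segment name {s.name!r}")
            self._by_name[s.name] = s

    def all_segments(self) -> Iterable[GermlineSegment]:
        yield from self.v_segments
        yield from self.d_segments
        yield from self.j_segments

    def __getitem__(self, name: str) -> GermlineSegment:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name


def _read_anchor_table(source) -> Dict[str, int]:
    df = pd.read_csv(source, sep="\t", dtype={"name": str, "class": str})
    for col in ("name", "class", "anchor"):
        if col not in df.columns:
            raise GermlineError(f"anchor table missing column {col!r}")
    return dict(zip(df["name"], df["anchor"].astype(int)))


def load_germline(fasta_source=None, anchor_table_source=None) -> GermlineReference:
    """Load a germline reference from FASTA + anchor-table TSV.

    FASTA records are named ``<name>|<class>|<family>``.  With no arguments the
    packaged synthetic mini-locus is loaded.
    """
    if fasta_source is None or anchor_table_source is None:
        if not (fasta_source is None and anchor_table_source is None):
            raise GermlineError("provide both FASTA and anchor table, or neither")
        data = importlib.resources.files("bcrep") / "data"
        fasta_source = str(data / DEFAULT_FASTA)
        anchor_table_source = str(data / DEFAULT_ANCHORS)
    anchors = _read_anchor_table(anchor_table_source)
    groups: Dict[str, List[GermlineSegment]] = {"V": [], "D": [], "J": []}
    seen = set()
    for rec in SeqIO.parse(str(fasta_source), "fasta"):
        parts = rec.id.split("|")
        if len(parts) != 3:
            raise GermlineError(f"FASTA record id {rec.id!r} is not '<name>|<class>|<family>'")
        name, cls, family = parts
        if name in seen:
            raise GermlineError(f"duplicate segment name {name!r}")
        seen.add(name)
        if cls not in groups:
            raise GermlineError(f"{name}: unknown segment class {cls!r}")
        anchor = anchors.get(name) if cls in ("V", "J") else None
        if cls in ("V", "J") and anchor is None:
            raise GermlineError(f"{name}: no anchor entry for {cls} segment")
        groups[cls].append(
            GermlineSegment(name=name, family=family, segment_class=cls,
                            sequence=str(rec.seq).upper(), anchor=anchor)
        )
    return GermlineReference(groups["V"], groups["D"], groups["J"])


def write_germline(reference: GermlineReference, fasta_path, anchor_path) -> None:
    """Write a reference back to FASTA + anchor TSV (inverse of :func:`load_germline`)."""
    records = [
        SeqRecord(Seq(s.sequence), id=f"{s.name}|{s.segment_class}|{s.family}", description="")
        for s in reference.all_segments()
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = [
        {"name": s.name, "class": s.segment_class, "anchor": s.anchor}
        for s in reference.all_segments()
        if s.segment_class in ("V", "J")
    ]
    pd.DataFrame(rows).to_csv(anchor_path, sep="\t", index=False)
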