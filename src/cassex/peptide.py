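"""Peptide properties of a translated cassette exon.

Translation handles exon phase (nucleotides carried over from the previous
exon are skipped) and profiles report the composition features relevant to
isoform non-equivalence: serine richness, charged-residue tallies under an
explicit charge convention (histidine counted positive by default), net
charge, and candidate phosphosite (S/T/Y) positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from collections import Counter

from Bio.Seq import Seq

from .errors import ValidationError
from .seqtools import normalize

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

DEFAULT_POSITIVE = frozenset("KRH")
DEFAULT_NEGATIVE = frozenset("DE")


@dataclass
class PeptideProfile:
    sequence: str
    length: int
    composition: dict[str, int]
    serine_count: int
    positive_count: int
    negative_count: int
    net_charge: int
    sty_positions: list[int] = field(default_factory=list)  # 1-based

    def __post_init__(self) -> None:
        if self.net_charge != self.positive_count - self.negative_count:
            raise ValidationError("net_charge != positive - negative")


def translate_segment(nt: str, phase: int = 0) -> str:
    """Translate a coding segment, skipping ``phase`` leading nucleotides.

    Only complete codons are translated; a trailing partial codon is
    dropped with a warning. An internal stop truncates translation with a
    warning (the stop is not included).
    """
    if phase not in (0, 1, 2):
        raise ValidationError("phase must be 0, 1 or 2")
    seq = normalize(nt)[phase:]
    if len(seq) < 3:
        raise ValidationError("fewer than 3 nt remain after phase skip")
    remainder = len(seq) % 3
    if remainder:
        warnings.warn(f"dropping trailing partial codon of {remainder} nt", stacklevel=2)
        seq = seq[: len(seq) - remainder]
    aa = str(Seq(seq).translate())
    if "*" in aa:
        warnings.warn("internal stop codon; translation truncated", stacklevel=2)
        aa = aa[: aa.index("*")]
    return aa


def profile_peptide(
    aa: str,
    positive_set: frozenset[str] | set[str] = DEFAULT_POSITIVE,
    negative_set: frozenset[str] | set[str] = DEFAULT_NEGATIVE,
) -> PeptideProfile:
    """Composition and charge profile of an amino-acid string.

    Unknown symbols are counted in ``composition`` but belong to no charge
    class.
    """
    seq = aa.upper().strip()
    if not seq:
        raise ValidationError("empty peptide")
    comp = dict(Counter(seq))
    positive = sum(comp.get(r, 0) for r in positive_set)
    negative = sum(comp.get(r, 0) for r in negative_set)
    return PeptideProfile(
        sequence=seq,
        length=len(seq),
        composition=comp,
        serine_count=comp.get("S", 0),
        positive_count=positive,
        negative_count=negative,
        net_charge=positive - negative,
        sty_positions=[i + 1 for i, c in enumerate(seq) if c in "STY"],
    )
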