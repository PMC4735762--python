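"""Small sequence utilities shared by every module.

One canonical alphabet: DNA upper case. RNA input (U) is folded to T at the
boundary; display layers may render U again. Non-ACGT symbols are kept as-is
(upper-cased) so downstream scoring can treat them as background and motif
matching can refuse them.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTRYKMBDHVN", "TGCAYRMKVHDBN")

DNA_BASES = ("A", "C", "G", "T")


def normalize(seq: str) -> str:
    """Upper-case and fold RNA U to DNA T. Other symbols pass through."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Render a DNA string in the RNA alphabet (T -> U), for display."""
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC-aware for the common ambiguity codes)."""
    return normalize(seq).translate(_COMPLEMENT)[::-1]
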