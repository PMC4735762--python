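"""Conservation profiling: Shannon entropy over protein alignments, and
exon/intron length architecture summaries across species groups.

Column entropy is H = -sum p_i log2 p_i over the residues observed at an
alignment column (gaps excluded, frequencies renormalised over residues),
in bits. Low H marks conserved positions, high H variable ones; for an
N-state alphabet H is bounded by log2 N (N = 20 for protein).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import ValidationError

GAP = "-"


@dataclass
class AlignedBlock:
    """An aligned block of equal-length protein sequences."""

    sequences: list[str]
    ids: list[str]
    groups: Optional[list[str]] = None

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ValidationError("alignment needs at least 2 rows")
        width = len(self.sequences[0])
        if any(len(s) != width for s in self.sequences):
            raise ValidationError("aligned rows have unequal lengths")
        if len(self.ids) != len(self.sequences):
            raise ValidationError("ids do not match sequences")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def width(self) -> int:
        return len(self.sequences[0])

    @classmethod
    def from_fasta(cls, path: str | Path, groups: Optional[Mapping[str, str]] = None) -> "AlignedBlock":
        records = list(SeqIO.parse(str(path), "fasta"))
        ids = [r.id for r in records]
        return cls(
            sequences=[str(r.seq) for r in records], ids=ids,
            groups=[groups.get(i, "") for i in ids] if groups else None,
        )


@dataclass
class EntropyProfile:
    per_column_H: list[float]      # NaN where masked/all-gap
    window: int
    smoothed_H: list[float]
    coverage: list[float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "column": np.arange(1, len(self.per_column_H) + 1),
            "H": self.per_column_H,
            "smoothed_H": self.smoothed_H,
            "coverage": self.coverage,
        })


@dataclass
class LengthSummary:
    """Mode/min/max of one (group, unit, index) length cell."""

    unit: str
    index: int
    group: str
    mode: int
    mode_fraction: float
    min: int
    max: int

    def __post_init__(self) -> None:
        if not self.min <= self.mode <= self.max:
            raise ValidationError("mode outside [min, max]")
        if not 0 < self.mode_fraction <= 1:
            raise ValidationError("mode_fraction outside (0, 1]")


def column_entropy(counts: Mapping[str, float] | Sequence[float], N: int = 20) -> float:
    """Shannon entropy (bits) of one column's residue counts.

    Gaps must already be excluded. An empty (all-gap) column is reported
    as missing (NaN), not zero.
    """
    values = list(counts.values()) if isinstance(counts, Mapping) else list(counts)
    total = float(sum(values))
    if total <= 0:
        return float("nan")
    H = 0.0
    for c in values:
        if c > 0:
            p = c / total
            H -= p * math.log2(p)
    if H > math.log2(N) + 1e-9:
        raise ValidationError(f"entropy {H:.4f} exceeds log2({N}); more states than N?")
    return H


def entropy_profile(block: AlignedBlock, window: int = 9, min_coverage: float = 0.5) -> EntropyProfile:
    """Per-column entropy with coverage masking and centred moving average.

    Columns whose non-gap fraction is below ``min_coverage`` are masked
    (NaN). ``window`` must be odd; the smoothed value at a column is the
    mean of unmasked values in the centred window (NaN when none).
    """
    if window < 1 or window % 2 == 0:
        raise ValidationError("window must be a positive odd integer")
    if window > block.width:
        raise ValidationError("window larger than alignment width")
    n_rows = len(block.sequences)
    H = np.full(block.width, np.nan)
    cov = np.zeros(block.width)
    for j in range(block.width):
        col = [s[j] for s in block.sequences]
        residues = [c for c in col if c != GAP and c != "."]
        cov[j] = len(residues) / n_rows
        if residues and cov[j] >= min_coverage:
            counts: dict[str, int] = {}
            for c in residues:
                counts[c] = counts.get(c, 0) + 1
            H[j] = column_entropy(counts)
    smoothed = (
        pd.Series(H).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )
    # columns that are themselves masked stay masked in the smoothed track
    smoothed = np.where(np.isnan(H), np.nan, smoothed)
    return EntropyProfile(
        per_column_H=H.tolist(), window=window, smoothed_H=smoothed.tolist(),
        coverage=cov.tolist(),
    )


def length_summaries(lengths: pd.DataFrame) -> list[LengthSummary]:
    """Summarise a (species, group, unit, index, length) table per cell.

    The mode is the most frequent length (smallest on ties);
    ``mode_fraction`` is the share of the cell's observations at the mode.
    """
    required = {"group", "unit", "index", "length"}
    missing = required - set(lengths.columns)
    if missing:
        raise ValidationError(f"length table missing columns: {sorted(missing)}")
    out = []
    for (group, unit, index), sub in lengths.groupby(["group", "unit", "index"], sort=True):
        vals = sub["length"].astype(int)
        vc = vals.value_counts()
        top = vc[vc == vc.max()]
        mode = int(min(top.index))
        out.append(LengthSummary(
            unit=str(unit), index=int(index), group=str(group), mode=mode,
            mode_fraction=float(vc.max() / len(vals)), min=int(vals.min()), max=int(vals.max()),
        ))
    return out


def length_summary_frame(summaries: Sequence[LengthSummary]) -> pd.DataFrame:
    return pd.DataFrame([
        dict(group=s.group, unit=s.unit, index=s.index, mode=s.mode,
             mode_fraction=s.mode_fraction, min=s.min, max=s.max)
        for s in summaries
    ])
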