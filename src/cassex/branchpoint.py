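"""Branchpoint-site detection: YURAY motifs, AG exclusion, distance windows.

The branchpoint signal in vertebrate introns is a degenerate 5-mer YURAY
(Y = pyrimidine, R = purine; DNA rendering [CT]T[AG]A[CT]) whose adenosine
attacks the donor site in the first splicing step. A genuine branchpoint
sits at a characteristic distance upstream of the intron's 3' end and is
not followed by a non-terminal AG: the first AG after the branchpoint is
generally used as the 3' splice site, so an intervening AG disqualifies a
candidate. Distance ``d_to3`` is measured from the first base of the motif
to the intron's 3' end (a motif occupying the last 5 nt has d_to3 = 5).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import EstimationError, ValidationError
from .seqtools import normalize

YURAY_RE = re.compile(r"(?=([CT]T[AG]A[CT]))")


@dataclass(frozen=True)
class MotifHit:
    """A YURAY occurrence at 0-based offset ``start`` within an intron."""

    start: int
    motif: str


@dataclass
class BranchpointHit:
    """A classified YURAY hit.

    ``is_candidate`` means no AG dinucleotide intervenes between the motif
    and the terminal 3'SS AG; ``in_opt_window`` is filled once a distance
    window is known.
    """

    hit: MotifHit
    d_to3: int
    intervening_ag: bool
    in_opt_window: bool = False

    @property
    def is_candidate(self) -> bool:
        return not self.intervening_ag


@dataclass
class OptWindow:
    """The distance window [lo, hi] that concentrates branchpoint distances."""

    lo: int
    hi: int
    coverage: float

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValidationError("window lo > hi")

    def __contains__(self, d: int) -> bool:
        return self.lo <= d <= self.hi

    @property
    def midpoint(self) -> float:
        return (self.lo + self.hi) / 2


def scan_yuray(intron_seq: str) -> list[MotifHit]:
    """All (overlapping) YURAY motif occurrences in an intron."""
    seq = normalize(intron_seq)
    return [MotifHit(start=m.start(), motif=m.group(1)) for m in YURAY_RE.finditer(seq)]


def classify_hits(intron_seq: str, hits: Sequence[MotifHit]) -> list[BranchpointHit]:
    """Attach d_to3 and the intervening-AG exclusion flag to each hit.

    The terminal AG (offsets L-2, L-1) is the 3'SS and never counts as
    intervening; an AG starting anywhere in [start+5, L-3] does. Introns
    not ending in AG are processed with a warning, treating the terminal
    dinucleotide as the 3'SS regardless.
    """
    seq = normalize(intron_seq)
    L = len(seq)
    if not seq.endswith("AG"):
        warnings.warn(f"intron does not end in AG (ends {seq[-2:]!r}); proceeding", stacklevel=2)
    out = []
    for h in hits:
        # search region for a non-3'SS AG: starts in [start+5, L-3]
        region = seq[h.start + 5 : L - 1]
        out.append(BranchpointHit(hit=h, d_to3=L - h.start, intervening_ag="AG" in region))
    return out


def scan_and_classify(intron_seq: str, min_intron_length: int = 0) -> list[BranchpointHit]:
    """scan_yuray + classify_hits; optionally skip short introns entirely."""
    seq = normalize(intron_seq)
    if len(seq) < max(5, min_intron_length):
        return []
    return classify_hits(seq, scan_yuray(seq))


def estimate_opt_window(
    d_values: Sequence[int], coverage_target: float = 0.75, bin: int = 1
) -> OptWindow:
    """Smallest contiguous integer window covering >= coverage_target of values.

    Ties on width are broken by the smaller lower bound. ``bin`` coarsens
    the candidate bounds to multiples of the bin width (default 1 = exact).
    """
    if len(d_values) == 0:
        raise EstimationError("no distance values supplied")
    if len(d_values) < 10:
        raise EstimationError("need at least 10 distance values")
    if not 0 < coverage_target <= 1:
        raise ValidationError("coverage_target must be in (0, 1]")
    d = np.sort(np.asarray(d_values, dtype=int))
    n = len(d)
    need = int(np.ceil(coverage_target * n))
    best: Optional[tuple[int, int, int]] = None  # (width, lo, count)
    # window covering `need` consecutive order statistics is optimal for its lo
    for i in range(0, n - need + 1):
        lo, hi = int(d[i]), int(d[i + need - 1])
        if bin > 1:
            lo = (lo // bin) * bin
            hi = ((hi + bin - 1) // bin) * bin
        width = hi - lo
        if best is None or (width, lo) < (best[0], best[1]):
            best = (width, lo, hi)
    width, lo, hi = best
    coverage = float(((d >= lo) & (d <= hi)).sum() / n)
    return OptWindow(lo=lo, hi=hi, coverage=coverage)


def call_strong_bps(
    intron_seq: str, window: OptWindow, min_intron_length: int = 0
) -> tuple[bool, Optional[BranchpointHit]]:
    """Does this intron carry a strong branchpoint in the optimal window?

    True iff at least one candidate hit (no intervening AG) falls inside
    the window. The best hit is the in-window candidate with d_to3 closest
    to the window midpoint, ties to the smaller d_to3.
    """
    bhits = scan_and_classify(intron_seq, min_intron_length=min_intron_length)
    in_window = []
    for bh in bhits:
        bh.in_opt_window = bh.d_to3 in window
        if bh.is_candidate and bh.in_opt_window:
            in_window.append(bh)
    if not in_window:
        return False, None
    best = min(in_window, key=lambda bh: (abs(bh.d_to3 - window.midpoint), bh.d_to3))
    return True, best


def hits_table(intron_id: str, intron_seq: str, window: Optional[OptWindow] = None) -> pd.DataFrame:
    """BED-like table of classified hits for one intron."""
    bhits = scan_and_classify(intron_seq)
    rows = []
    for bh in bhits:
        rows.append(dict(
            intron_id=intron_id, start=bh.hit.start, end=bh.hit.start + 5, motif=bh.hit.motif,
            d_to3=bh.d_to3, intervening_ag=bh.intervening_ag, candidate=bh.is_candidate,
            in_window=(bh.d_to3 in window) if window is not None else False,
        ))
    return pd.DataFrame(rows, columns=["intron_id", "start", "end", "motif", "d_to3",
                                       "intervening_ag", "candidate", "in_window"])


def distance_histogram(d_values: Sequence[int], max_d: int = 200) -> pd.DataFrame:
    """Histogram of candidate branchpoint distances (per-nt bins up to max_d)."""
    d = np.asarray(d_values, dtype=int)
    d = d[d <= max_d]
    counts = np.bincount(d, minlength=max_d + 1)
    return pd.DataFrame({"d_to3": np.arange(max_d + 1), "count": counts})
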