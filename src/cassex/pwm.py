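"""Position weight matrices for splice-site strength (PWMS) scoring.

A donor-site PWM is trained on a set of equal-length exon|intron junction
strings. Per-position log-odds are

    score(b, j) = log2( ((count(b, j) + c * q_b) / (n + c)) / q_b )

with background probability ``q_b`` and a background-scaled Laplace
pseudocount ``c``. A sequence's PWMS is the sum of its per-position lookups;
larger scores mean a stronger match to the splice-signal consensus. At
pseudocount 0 an unobserved base would be log2(0); those cells are floored
at ``SCORE_FLOOR`` to keep arithmetic finite while preserving ordering.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidBackgroundError, ShapeError, ValidationError
from .seqtools import DNA_BASES, normalize

SCORE_FLOOR = -30.0

_BASE_INDEX = {b: i for i, b in enumerate(DNA_BASES)}


@dataclass
class PWM:
    """A per-position log-odds matrix over {A, C, G, T}.

    ``counts`` may be None for matrices loaded from published score tables
    (scores given, training counts unavailable); count-based operations then
    raise.
    """

    position_labels: list[str]
    scores: np.ndarray                       # shape (4, width)
    counts: Optional[np.ndarray] = None      # shape (4, width)
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 1.0
    n_sequences: Optional[int] = None
    alphabet: tuple[str, ...] = DNA_BASES

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.scores.shape != (4, len(self.position_labels)):
            raise ShapeError("scores shape does not match position labels")
        if self.counts is not None:
            self.counts = np.asarray(self.counts, dtype=float)
            if self.counts.shape != self.scores.shape:
                raise ShapeError("counts shape does not match scores shape")

    @property
    def width(self) -> int:
        return len(self.position_labels)

    def frequencies(self) -> np.ndarray:
        """Pseudocounted per-position frequencies (columns sum to 1)."""
        if self.counts is None:
            raise ValidationError("PWM has no training counts")
        n = self.counts.sum(axis=0)
        return (self.counts + self.pseudocount * self.background[:, None]) / (n + self.pseudocount)

    # -- serialisation -----------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Scores as TSV (rows = bases) plus a JSON sidecar with metadata."""
        df = pd.DataFrame(self.scores, index=list(self.alphabet), columns=self.position_labels)
        df.to_csv(path, sep="\t", index_label="base", float_format="%.6g")
        sidecar = Path(str(path) + ".json")
        sidecar.write_text(json.dumps({
            "background": self.background.tolist(),
            "pseudocount": self.pseudocount,
            "n_sequences": self.n_sequences,
        }))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PWM":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.str.upper().str.replace("U", "T")
        df = df.loc[list(DNA_BASES)]
        meta = {}
        sidecar = Path(str(path) + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        return cls(
            position_labels=[str(c) for c in df.columns],
            scores=df.to_numpy(),
            background=np.asarray(meta.get("background", [0.25] * 4)),
            pseudocount=meta.get("pseudocount", 1.0),
            n_sequences=meta.get("n_sequences"),
        )


@dataclass
class PwmsResult:
    """A scored junction: total PWMS plus the per-position breakdown."""

    sequence: str
    score: float
    per_position_contributions: list[float]


@dataclass
class Consensus:
    sequence: str
    tie_positions: list[int]     # 0-based columns where the argmax was tied

    def __str__(self) -> str:
        return self.sequence


@dataclass
class PairedTestResult:
    """Classical paired t-test on score differences (two-sided).

    ``degenerate`` marks a zero-variance difference vector; the t statistic
    is then 0 (all differences zero) or signed infinity.
    """

    n_pairs: int
    mean_diff: float
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    degenerate: bool = False


def build_pwm(
    junctions: Sequence[str],
    position_labels: Optional[Sequence[str]] = None,
    background: str | Sequence[float] = "uniform",
    pseudocount: float = 1.0,
) -> PWM:
    """Train a PWM from equal-length junction strings.

    Ambiguity symbols (anything outside ACGT after U->T folding) contribute
    to no base's count. ``background`` is "uniform" or four probabilities
    in A, C, G, T order.
    """
    if len(junctions) < 2:
        raise ValidationError("need at least 2 junctions to build a PWM")
    seqs = [normalize(s) for s in junctions]
    width = len(seqs[0])
    if any(len(s) != width for s in seqs):
        raise ShapeError("junction strings have unequal lengths")
    if position_labels is None:
        position_labels = [str(i + 1) for i in range(width)]
    if len(position_labels) != width:
        raise ShapeError("position_labels length does not match junction width")

    if isinstance(background, str):
        if background != "uniform":
            raise InvalidBackgroundError(f"unknown background {background!r}")
        bg = np.full(4, 0.25)
    else:
        bg = np.asarray(background, dtype=float)
        if bg.shape != (4,) or not math.isclose(bg.sum(), 1.0, abs_tol=1e-6):
            raise InvalidBackgroundError("background must be 4 probabilities summing to 1")
    if np.any(bg <= 0):
        raise InvalidBackgroundError("background contains a zero entry")
    if pseudocount < 0:
        raise ValidationError("pseudocount must be non-negative")

    counts = np.zeros((4, width))
    for s in seqs:
        for j, b in enumerate(s):
            i = _BASE_INDEX.get(b)
            if i is not None:
                counts[i, j] += 1
    n = len(seqs)
    with np.errstate(divide="ignore"):
        freq = (counts + pseudocount * bg[:, None]) / (n + pseudocount)
        scores = np.log2(freq / bg[:, None])
    scores = np.maximum(scores, SCORE_FLOOR)
    return PWM(
        position_labels=list(position_labels), scores=scores, counts=counts,
        background=bg, pseudocount=pseudocount, n_sequences=n,
    )


def score_sequence(pwm: PWM, junction: str) -> PwmsResult:
    """PWMS of one junction: additive per-position log-odds lookup.

    Non-ACGT symbols contribute 0 at their position (background behaviour).
    """
    seq = normalize(junction)
    if len(seq) != pwm.width:
        raise ShapeError(f"junction length {len(seq)} != PWM width {pwm.width}")
    contribs = []
    for j, b in enumerate(seq):
        i = _BASE_INDEX.get(b)
        contribs.append(float(pwm.scores[i, j]) if i is not None else 0.0)
    return PwmsResult(sequence=seq, score=float(sum(contribs)), per_position_contributions=contribs)


def consensus(pwm: PWM, columns: Optional[slice] = None) -> Consensus:
    """Per-position argmax base; ties broken alphabetically and flagged."""
    scores = pwm.scores if columns is None else pwm.scores[:, columns]
    letters, ties = [], []
    for j in range(scores.shape[1]):
        col = scores[:, j]
        best = col.max()
        winners = [DNA_BASES[i] for i in range(4) if col[i] == best]
        letters.append(winners[0])
        if len(winners) > 1:
            ties.append(j)
    return Consensus(sequence="".join(letters), tie_positions=ties)


def max_score(pwm: PWM) -> float:
    """The best achievable PWMS: sum of per-position maxima."""
    return float(pwm.scores.max(axis=0).sum())


def column_information(pwm: PWM) -> np.ndarray:
    """Per-position information content I_j = 2 - H_j in bits.

    Computed from the pseudocounted column frequencies; this is the height
    scale of a sequence logo.
    """
    freq = pwm.frequencies()
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
    H = -plogp.sum(axis=0)
    return np.log2(4) - H


def logo_data(pwm: PWM) -> pd.DataFrame:
    """Per-position per-base letter heights (freq * column information)."""
    freq = pwm.frequencies()
    heights = freq * column_information(pwm)[None, :]
    return pd.DataFrame(heights, index=list(pwm.alphabet), columns=pwm.position_labels)


def paired_pwms_test(pairs: Sequence[tuple[float, float]]) -> PairedTestResult:
    """Paired two-sided t-test on (score_a - score_b) differences.

    Zero-variance differences are reported as degenerate rather than NaN:
    t = 0 (p = 1) when all differences are zero, signed infinity (p = 0)
    otherwise.
    """
    if len(pairs) < 2:
        raise ValidationError("need at least 2 pairs")
    a = np.asarray([p[0] for p in pairs], dtype=float)
    b = np.asarray([p[1] for p in pairs], dtype=float)
    diff = a - b
    n = len(diff)
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return PairedTestResult(n, 0.0, 0.0, n - 1, 1.0, degenerate=True)
        t = math.inf if mean > 0 else -math.inf
        return PairedTestResult(n, mean, t, n - 1, 0.0, degenerate=True)
    res = stats.ttest_rel(a, b)
    return PairedTestResult(
        n_pairs=n, mean_diff=mean, t_statistic=float(res.statistic),
        degrees_of_freedom=n - 1, p_value=float(res.pvalue),
    )


def read_junctions(path: str | Path) -> list[str]:
    """Junction strings from FASTA or plain one-per-line text."""
    text = Path(path).read_text()
    if text.lstrip().startswith(">"):
        from Bio import SeqIO
        return [normalize(str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    return [normalize(line.strip()) for line in text.splitlines() if line.strip()]
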