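"""Junction-level isoform evidence: retained vs skipped read counting.

For a cassette exon E flanked by exons U (upstream) and D (downstream),
the retained isoform contains the U-E and E-D junctions and the skipped
isoform the U-D junction. Transcript evidence (ESTs or RNA-seq reads) is
classified by exact matching of junction-spanning probe cores: a read
supports a junction iff it contains the probe segment covering at least
``min_overhang`` nt on each side of the junction point. PSI (percent
spliced in) is retained / (retained + skipped) with a Wilson 95% interval;
the long/short ratio is retained / skipped.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import stats

from .errors import ValidationError
from .seqtools import normalize, revcomp

log = logging.getLogger(__name__)

RETAINED = "retained"
SKIPPED = "skipped"
AMBIGUOUS = "ambiguous"
NONE = "none"


@dataclass
class ProbeSet:
    """Junction probes around a cassette exon, ``flank`` nt per side.

    ``retained_probes`` span the U-E and E-D junctions; ``skipped_probe``
    spans U-D (last ``flank`` nt of U followed by first ``flank`` nt of D).
    Each probe's junction point sits exactly at its midpoint.
    """

    retained_probes: list[str]
    skipped_probe: str
    flank: int

    def __post_init__(self) -> None:
        for p in [*self.retained_probes, self.skipped_probe]:
            if len(p) != 2 * self.flank:
                raise ValidationError("probe length != 2 * flank")


@dataclass
class IsoformCounts:
    retained: int
    skipped: int
    ambiguous: int
    total_scanned: int
    psi: Optional[float]
    psi_ci: Optional[tuple[float, float]]
    ratio_long_short: Optional[float]

    @property
    def unmatched(self) -> int:
        return self.total_scanned - self.retained - self.skipped - self.ambiguous


def wilson_interval(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion k/n."""
    if n == 0:
        raise ValidationError("Wilson interval undefined for n = 0")
    z = stats.norm.ppf(0.5 + confidence / 2)
    p = k / n
    denom = 1 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * ((p * (1 - p) / n + z * z / (4 * n * n)) ** 0.5) / denom
    return max(0.0, centre - half), min(1.0, centre + half)


def build_probes(e_up: str, e_cassette: str, e_down: str, flank: int = 20) -> ProbeSet:
    """Probes for the three junctions around a cassette exon."""
    e_up, e_cassette, e_down = normalize(e_up), normalize(e_cassette), normalize(e_down)
    for name, e in [("upstream", e_up), ("cassette", e_cassette), ("downstream", e_down)]:
        if len(e) < flank:
            raise ValidationError(f"{name} exon shorter ({len(e)} nt) than flank {flank}")
    return ProbeSet(
        retained_probes=[e_up[-flank:] + e_cassette[:flank], e_cassette[-flank:] + e_down[:flank]],
        skipped_probe=e_up[-flank:] + e_down[:flank],
        flank=flank,
    )


def _core(probe: str, flank: int, min_overhang: int) -> str:
    """The minimal junction-spanning window: min_overhang nt each side."""
    return probe[flank - min_overhang : flank + min_overhang]


def _contains(read: str, core: str, max_mismatches: int) -> bool:
    if max_mismatches == 0:
        return core in read
    w = len(core)
    for i in range(len(read) - w + 1):
        window = read[i : i + w]
        mism = sum(a != b for a, b in zip(window, core))
        if mism <= max_mismatches:
            return True
    return False


def classify_read(
    read: str,
    probes: ProbeSet,
    min_overhang: int = 8,
    strand_both: bool = True,
    max_mismatches: int = 0,
) -> str:
    """Classify one read as retained / skipped / ambiguous / none.

    A read supports a junction iff it contains the probe core covering at
    least ``min_overhang`` nt on each side of the junction point; a read
    matching both isoform classes is ambiguous. The reverse complement is
    also checked when ``strand_both``.
    """
    if min_overhang > probes.flank:
        raise ValidationError("min_overhang exceeds probe flank")
    seq = normalize(read)
    if len(seq) < 2 * min_overhang:
        raise ValidationError(f"read shorter than 2 * min_overhang ({2 * min_overhang})")
    orientations = [seq, revcomp(seq)] if strand_both else [seq]
    ret_cores = [_core(p, probes.flank, min_overhang) for p in probes.retained_probes]
    skip_core = _core(probes.skipped_probe, probes.flank, min_overhang)
    retained = skipped = False
    for s in orientations:
        retained = retained or any(_contains(s, c, max_mismatches) for c in ret_cores)
        skipped = skipped or _contains(s, skip_core, max_mismatches)
    if retained and skipped:
        return AMBIGUOUS
    if retained:
        return RETAINED
    if skipped:
        return SKIPPED
    return NONE


def count_support(
    reads: Iterable[str],
    probes: ProbeSet,
    min_overhang: int = 8,
    strand_both: bool = True,
    max_mismatches: int = 0,
    spanning_probs: Optional[tuple[float, float]] = None,
) -> IsoformCounts:
    """Aggregate classify_read over a stream of read sequences.

    With ``spanning_probs = (p_retained, p_skipped)`` — the per-read
    probabilities that a read from each isoform spans a junction of its
    class (see :func:`effective_spanning_probs`) — PSI is corrected for
    the retained isoform carrying two junctions (and for transcript-length
    differences): the raw junction-read proportion q = r/(r+s) estimates
    ``psi * p_r / (psi * p_r + (1-psi) * p_s)``, so psi and its CI are
    obtained by pushing q and its Wilson bounds through the inverse map.
    Without it PSI is the raw proportion, which overweights the retained
    isoform roughly two-fold.
    """
    tallies = {RETAINED: 0, SKIPPED: 0, AMBIGUOUS: 0, NONE: 0}
    total = 0
    for read in reads:
        total += 1
        try:
            tallies[classify_read(read, probes, min_overhang, strand_both, max_mismatches)] += 1
        except ValidationError as exc:
            log.warning("skipping unusable read: %s", exc)
    r, s = tallies[RETAINED], tallies[SKIPPED]
    psi = psi_ci = ratio = None
    if r + s > 0:
        q = r / (r + s)
        q_lo, q_hi = wilson_interval(r, r + s)
        if spanning_probs is not None:
            p_r, p_s = spanning_probs
            if p_r <= 0 or p_s <= 0:
                raise ValidationError("spanning probabilities must be positive")
            unmap = lambda x: x * p_s / (x * p_s + (1 - x) * p_r)  # noqa: E731
            psi, psi_ci = unmap(q), (unmap(q_lo), unmap(q_hi))
        else:
            psi, psi_ci = q, (q_lo, q_hi)
    if s > 0:
        ratio = r / s
    return IsoformCounts(
        retained=r, skipped=s, ambiguous=tallies[AMBIGUOUS], total_scanned=total,
        psi=psi, psi_ci=psi_ci, ratio_long_short=ratio,
    )


def effective_spanning_probs(
    retained_tx: str,
    skipped_tx: str,
    probes: ProbeSet,
    read_len: int,
    min_overhang: int = 8,
    max_mismatches: int = 0,
) -> tuple[float, float]:
    """Per-read junction-spanning probabilities for each isoform.

    Exact enumeration over uniform error-free read start positions on each
    transcript; the pair feeds :func:`count_support` as the effective-length
    correction (retained transcripts carry two junctions and are longer, so
    their reads hit a junction more often).
    """
    def frac(tx: str, want: str) -> float:
        tx = normalize(tx)
        n = len(tx) - read_len + 1
        if n <= 0:
            raise ValidationError("read_len exceeds transcript length")
        hits = sum(
            1 for i in range(n)
            if classify_read(tx[i : i + read_len], probes, min_overhang,
                             strand_both=False, max_mismatches=max_mismatches) == want
        )
        return hits / n

    return frac(retained_tx, RETAINED), frac(skipped_tx, SKIPPED)


def read_sequences(path: str | Path) -> Iterator[str]:
    """Sequences from FASTA or FASTQ, gzip-transparent, format by extension."""
    path = Path(path)
    name = path.name[:-3] if path.name.endswith(".gz") else path.name
    fmt = "fastq" if name.endswith((".fastq", ".fq")) else "fasta"
    opener = gzip.open if path.name.endswith(".gz") else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, fmt):
            yield str(rec.seq)


def write_probes_fasta(probes: ProbeSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(probes.retained_probes[0]), id="retained|up_cassette", description=""),
        SeqRecord(Seq(probes.retained_probes[1]), id="retained|cassette_down", description=""),
        SeqRecord(Seq(probes.skipped_probe), id="skipped|up_down", description=""),
    ]
    SeqIO.write(records, str(path), "fasta")


def counts_frame(counts: IsoformCounts):
    import pandas as pd

    return pd.DataFrame([{
        "retained": counts.retained, "skipped": counts.skipped,
        "ambiguous": counts.ambiguous, "total": counts.total_scanned,
        "psi": counts.psi,
        "psi_lo": counts.psi_ci[0] if counts.psi_ci else None,
        "psi_hi": counts.psi_ci[1] if counts.psi_ci else None,
        "ratio_long_short": counts.ratio_long_short,
    }])
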