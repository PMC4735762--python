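"""Synthetic gene models, junction sets and reads with recorded ground truth.

Every generator is seeded and emits a machine-readable :class:`TruthRecord`
alongside its data; tests read truth from the record, never re-derive it.
Gene models are built to the splicing grammar the analysis stages assume:
introns begin GT and end AG, donor sites carry requested +6 identities, and
branchpoint motifs (CTAAC) are planted at chosen distances from the intron
3' end, with accidental clean YURAY candidates purged from the scan window
by rejection sampling.

Background sequence is i.i.d. uniform over {A, C, G, T} by default; a
biased composition can be supplied. The read simulator models substitution
errors only (no indels).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError
from .genemodel import GeneModel
from .seqtools import DNA_BASES

_RETRY_CAP = 1000


@dataclass
class BpsPlan:
    """Plant one YURAY motif in intron ``intron_index`` at distance ``d_to3``.

    ``clean`` controls whether an AG is allowed between the motif and the
    terminal 3'SS AG (clean = no intervening AG = a genuine candidate).
    """

    intron_index: int
    d_to3: int
    clean: bool = True
    motif: str = "CTAAC"


@dataclass
class TruthRecord:
    """Ground truth emitted with every synthetic artefact."""

    seed: int
    pwm_truth: Optional[list[list[float]]] = None
    planted_bps: list[dict] = field(default_factory=list)
    plus6_config: Optional[tuple[str, str]] = None
    expected_call: Optional[str] = None
    psi_truth: Optional[float] = None
    read_params: Optional[dict] = None
    read_origins: Optional[list[str]] = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        data = json.loads(Path(path).read_text())
        if data.get("plus6_config"):
            data["plus6_config"] = tuple(data["plus6_config"])
        return cls(**data)


def _random_seq(rng: np.random.Generator, n: int, p: Optional[Sequence[float]] = None) -> str:
    if n <= 0:
        return ""
    return "".join(rng.choice(list(DNA_BASES), size=n, p=p))


def sample_donors(pwm_truth: np.ndarray, n: int, seed: int) -> list[str]:
    """Draw ``n`` junction strings by i.i.d. per-position sampling.

    ``pwm_truth`` is a (4, width) probability matrix in A, C, G, T row
    order; each column must sum to 1.
    """
    probs = np.asarray(pwm_truth, dtype=float)
    if probs.ndim != 2 or probs.shape[0] != 4:
        raise ConfigError("pwm_truth must be a (4, width) matrix")
    if not np.allclose(probs.sum(axis=0), 1.0, atol=1e-8):
        raise ConfigError("pwm_truth columns must sum to 1")
    rng = np.random.default_rng(seed)
    width = probs.shape[1]
    cols = [rng.choice(4, size=n, p=probs[:, j]) for j in range(width)]
    idx = np.stack(cols, axis=1)
    lookup = np.array(list(DNA_BASES))
    return ["".join(row) for row in lookup[idx]]


@dataclass
class GeneConfig:
    """Architecture of one synthetic multi-exon gene.

    ``donor_plus6`` gives the +6 identity of each intron's donor site (one
    base per intron). ``purge_window`` is the 3'-tail span kept free of
    accidental clean YURAY candidates (planted ones excepted).
    """

    exon_lengths: list[int]
    intron_lengths: list[int]
    donor_plus6: list[str]
    bps_plan: list[BpsPlan] = field(default_factory=list)
    gene_id: str = "synthetic_gene"
    species: str = "synthetic"
    purge_window: int = 50
    background: Optional[list[float]] = None

    def __post_init__(self) -> None:
        n_ex, n_in = len(self.exon_lengths), len(self.intron_lengths)
        if n_ex < 3:
            raise ConfigError("need at least 3 exons so a cassette exon exists")
        if n_in != n_ex - 1:
            raise ConfigError("need exactly exon_count - 1 introns")
        if len(self.donor_plus6) != n_in:
            raise ConfigError("need one donor +6 base per intron")
        if any(l < 12 for l in self.intron_lengths):
            raise ConfigError("introns must be at least 12 nt for the donor/acceptor grammar")
        for plan in self.bps_plan:
            if not 1 <= plan.intron_index <= n_in:
                raise ConfigError(f"bps plan targets nonexistent intron {plan.intron_index}")
            L = self.intron_lengths[plan.intron_index - 1]
            # motif must fit after the 6-nt donor head and before the terminal AG
            if plan.d_to3 < 7 or L - plan.d_to3 < 6:
                raise ConfigError(
                    f"motif at d_to3={plan.d_to3} does not fit in intron of length {L}"
                )


def _clean_yuray_ds(intron: str, window: int) -> set[int]:
    """d_to3 values of clean YURAY candidates within the 3'-tail window."""
    from .branchpoint import scan_and_classify

    return {
        bh.d_to3 for bh in scan_and_classify(intron)
        if bh.is_candidate and bh.d_to3 <= window
    }


def _build_intron(
    rng: np.random.Generator, length: int, plus6: str, plans: list[BpsPlan],
    purge_window: int, background: Optional[Sequence[float]],
) -> str:
    """One intron honouring the donor grammar and the branchpoint plan."""
    planted_ds = {p.d_to3 for p in plans if p.clean}
    for _ in range(_RETRY_CAP):
        head = "GTAAG" + plus6
        middle = _random_seq(rng, length - len(head) - 2, background)
        intron = head + middle + "AG"
        for plan in plans:
            pos = length - plan.d_to3
            intron = intron[:pos] + plan.motif + intron[pos + len(plan.motif):]
            if not plan.clean:
                # plant a disqualifying AG midway between motif end and the 3'SS
                lo, hi = pos + len(plan.motif), length - 3
                if hi <= lo:
                    raise ConfigError("no room for an intervening AG in decoy plan")
                mid = (lo + hi) // 2
                intron = intron[:mid] + "AG" + intron[mid + 2:]
        if intron[:2] != "GT" or intron[-2:] != "AG":
            continue
        found = _clean_yuray_ds(intron, purge_window)
        want = {d for d in planted_ds if d <= purge_window}
        if found == want:
            return intron
    raise ConfigError(f"could not satisfy branchpoint plan in {_RETRY_CAP} tries")


def synth_gene_model(config: GeneConfig, seed: int) -> tuple[GeneModel, TruthRecord]:
    """Generate a multi-exon gene with planted splice signals."""
    rng = np.random.default_rng(seed)
    bg = config.background
    parts: list[str] = []
    exons: list[tuple[int, int]] = []
    pos = 0
    plans_by_intron: dict[int, list[BpsPlan]] = {}
    for plan in config.bps_plan:
        plans_by_intron.setdefault(plan.intron_index, []).append(plan)
    for i, ex_len in enumerate(config.exon_lengths):
        exon = _random_seq(rng, ex_len, bg)
        exons.append((pos, pos + ex_len))
        parts.append(exon)
        pos += ex_len
        if i < len(config.intron_lengths):
            intron = _build_intron(
                rng, config.intron_lengths[i], config.donor_plus6[i],
                plans_by_intron.get(i + 1, []), config.purge_window, bg,
            )
            parts.append(intron)
            pos += len(intron)
    gm = GeneModel(
        gene_id=config.gene_id, species=config.species, strand="+",
        exons=exons, sequence="".join(parts),
    )
    truth = TruthRecord(
        seed=seed,
        planted_bps=[
            dict(intron_index=p.intron_index, start=config.intron_lengths[p.intron_index - 1] - p.d_to3,
                 motif=p.motif, d_to3=p.d_to3, clean=p.clean)
            for p in config.bps_plan
        ],
    )
    return gm, truth


def spliced_transcript(gm: GeneModel, drop_exon: Optional[int] = None) -> str:
    """Mature transcript sequence; ``drop_exon`` (1-based) skips that exon."""
    return "".join(
        gm.exon_seq(i) for i in range(1, gm.exon_count + 1) if i != drop_exon
    )


@dataclass
class SimRead:
    read_id: str
    seq: str
    origin: str  # retained | skipped


def synth_reads(
    gm: GeneModel,
    cassette_index: int,
    psi: float,
    n: int,
    read_len: int,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[SimRead], TruthRecord]:
    """Simulate junction evidence reads from the two isoforms.

    Each read comes from the retained transcript with probability ``psi``
    (else the skipped one), with a uniform start position and i.i.d.
    per-base substitution errors at ``error_rate``.
    """
    if not 0 <= psi <= 1:
        raise ConfigError("psi must be in [0, 1]")
    retained = spliced_transcript(gm)
    skipped = spliced_transcript(gm, drop_exon=cassette_index)
    if read_len > len(skipped):
        raise ConfigError("read_len exceeds the skipped transcript length")
    rng = np.random.default_rng(seed)
    bases = np.array(list(DNA_BASES))
    reads: list[SimRead] = []
    origins: list[str] = []
    for k in range(n):
        is_retained = rng.random() < psi
        template = retained if is_retained else skipped
        start = int(rng.integers(0, len(template) - read_len + 1))
        seq = list(template[start : start + read_len])
        if error_rate > 0:
            errs = rng.random(read_len) < error_rate
            for j in np.nonzero(errs)[0]:
                choices = [b for b in bases if b != seq[j]]
                seq[j] = choices[int(rng.integers(0, 3))]
        origin = "retained" if is_retained else "skipped"
        origins.append(origin)
        reads.append(SimRead(read_id=f"read{k:06d}|{origin}", seq="".join(seq), origin=origin))
    truth = TruthRecord(
        seed=seed, psi_truth=psi,
        read_params=dict(n=n, length=read_len, error_rate=error_rate),
        read_origins=origins,
    )
    return reads, truth


def write_fastq(reads: Sequence[SimRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


def write_fasta(reads: Sequence[SimRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id}\n{r.seq}\n")


# ---------------------------------------------------------------------------
# Species-like panel used by the pipeline tests and worked examples


PANEL_SPECS = [
    # name, group, (upstream +6, downstream +6), expected +6-rule call
    ("mammal_A", "mammal", ("T", "A"), "alternative_skipping"),
    ("mammal_B", "mammal", ("T", "A"), "alternative_skipping"),
    ("bird_skip", "bird", ("C", "A"), "alternative_skipping"),
    ("bird_noskip", "bird", ("A", "A"), "constitutive_retention"),
    ("fish", "fish", ("T", "C"), "constitutive_retention"),
]


def synth_panel(seed: int, exon_len: int = 60, intron_len: int = 120) -> list[tuple[str, str, GeneModel, TruthRecord]]:
    """A small vertebrate-like panel of 5-exon genes around a cassette exon 3.

    Every gene carries a strong branchpoint (clean CTAAC at d_to3 = 30) in
    the cassette exon's downstream intron — the branchpoint that serves
    both inclusion and skipping — so the skipping call is decided by the
    +6 donor configuration alone, as in the vertebrate panel it emulates.
    """
    out = []
    for k, (name, group, (up6, down6), expected) in enumerate(PANEL_SPECS):
        plus6 = ["T", up6, down6, "T"]
        plans = [BpsPlan(intron_index=3, d_to3=30, clean=True)]
        cfg = GeneConfig(
            exon_lengths=[exon_len] * 5, intron_lengths=[intron_len] * 4,
            donor_plus6=plus6, bps_plan=plans, gene_id=name, species=name,
        )
        gm, truth = synth_gene_model(cfg, seed=seed + 17 * k)
        truth.plus6_config = (up6, down6)
        truth.expected_call = expected
        out.append((name, group, gm, truth))
    return out
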