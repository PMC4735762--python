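"""End-to-end orchestration: extract -> score -> branchpoint -> predict -> evidence.

A run is described by a :class:`RunConfig` (usually loaded from YAML),
validated up front, and produces a run directory of TSV/JSON outputs plus a
plain-text log. Every tabular output carries a provenance comment line with
the config hash so reruns are auditable; given the same config and seed the
outputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .branchpoint import OptWindow, call_strong_bps
from .datasets import load_chr22_donor_pwm
from .errors import CassexError, ConfigError
from .genemodel import derive_introns, extract_donor_site, read_gene_model
from .isoform import build_probes, count_support, counts_frame, read_sequences
from .pwm import PWM
from .skipping import classify_panel, pair_from_donor_13mers

log = logging.getLogger(__name__)


class StageError(CassexError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class GeneInput:
    path: str
    format: str = "genbank"
    fasta: Optional[str] = None
    group: str = ""
    reads: Optional[str] = None
    transcript: Optional[str] = None


@dataclass
class RunConfig:
    """Validated description of one pipeline run."""

    out_dir: str
    genes: list[GeneInput]
    cassette_exon: int = 3
    seed: int = 0
    window_lo: int = 20
    window_hi: int = 40
    donor_exon_flank: int = 5
    donor_intron_flank: int = 8
    predictor_rule: str = "plus6"
    delta_threshold: float = 2.0
    evidence_flank: int = 20
    min_overhang: int = 8
    max_mismatches: int = 0
    pwm_path: Optional[str] = None

    def validate(self) -> None:
        if self.cassette_exon < 2:
            raise ConfigError("cassette_exon must be an internal exon (>= 2)")
        if not self.genes:
            raise ConfigError("no gene inputs configured")
        if self.window_lo > self.window_hi:
            raise ConfigError("window_lo > window_hi")
        if self.predictor_rule not in ("plus6", "pwms_delta"):
            raise ConfigError(f"unknown predictor rule {self.predictor_rule!r}")
        if not 0 <= self.max_mismatches <= 2:
            raise ConfigError("max_mismatches must be 0..2")
        for g in self.genes:
            if not Path(g.path).exists():
                raise ConfigError(f"gene input {g.path} does not exist")
            if g.format.startswith("gff3"):
                if g.fasta is None or not Path(g.fasta).exists():
                    raise ConfigError(f"gff3 input {g.path} needs an existing fasta")
            if g.reads is not None and not Path(g.reads).exists():
                raise ConfigError(f"reads file {g.reads} does not exist")
        if self.pwm_path is not None and not Path(self.pwm_path).exists():
            raise ConfigError(f"PWM file {self.pwm_path} does not exist")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        genes = [GeneInput(**g) for g in raw.pop("genes", [])]
        return cls(genes=genes, **raw)

    def config_hash(self) -> str:
        # hash the scientific parameters only, so reruns into a different
        # directory still produce byte-identical tables
        params = asdict(self)
        params.pop("out_dir")
        canon = json.dumps(params, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# cassex {__version__} config-hash {cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> Path:
    """Run every configured stage; returns the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    try:
        log.info("config hash %s, seed %d", cfg_hash, config.seed)
        pwm = PWM.from_tsv(config.pwm_path) if config.pwm_path else load_chr22_donor_pwm()
        window = OptWindow(lo=config.window_lo, hi=config.window_hi, coverage=1.0)
        c = config.cassette_exon

        summary: dict[str, dict] = {}
        panel_rows = []
        intron_rows = []
        evidence_frames = []
        for ginput in config.genes:
            t0 = time.monotonic()
            stage = f"extract:{ginput.path}"
            try:
                gm = read_gene_model(ginput.path, format=ginput.format,
                                     fasta=ginput.fasta, transcript=ginput.transcript)
            except CassexError as exc:
                raise StageError(stage, str(exc)) from exc
            if gm.exon_count < c + 1:
                raise StageError(stage, f"gene {gm.gene_id} has {gm.exon_count} exons; "
                                        f"cassette exon {c} needs at least {c + 1}")
            introns = derive_introns(gm)
            for rec in introns:
                intron_rows.append(dict(gene_id=gm.gene_id, intron_index=rec.index,
                                        length=rec.length, donor_dint=rec.donor_dinucleotide,
                                        acceptor_dint=rec.acceptor_dinucleotide))
            up = extract_donor_site(gm, c - 1, config.donor_exon_flank, config.donor_intron_flank)
            down = extract_donor_site(gm, c, config.donor_exon_flank, config.donor_intron_flank)
            pair = pair_from_donor_13mers(up.seq, down.seq, pwm=pwm)
            strong_up, _ = call_strong_bps(gm.intron_seq(c - 1), window)
            strong_down, best_down = call_strong_bps(gm.intron_seq(c), window)
            panel_rows.append((gm.gene_id, ginput.group, pair))
            entry = dict(
                group=ginput.group,
                upstream_donor=up.seq, downstream_donor=down.seq,
                upstream_plus6=pair.upstream_plus6, downstream_plus6=pair.downstream_plus6,
                upstream_pwms=pair.upstream_pwms, downstream_pwms=pair.downstream_pwms,
                strong_bps_upstream_intron=strong_up,
                strong_bps_downstream_intron=strong_down,
                best_bps_d_to3=best_down.d_to3 if best_down else None,
            )
            if ginput.reads:
                stage = f"evidence:{ginput.reads}"
                try:
                    probes = build_probes(gm.exon_seq(c - 1), gm.exon_seq(c), gm.exon_seq(c + 1),
                                          flank=config.evidence_flank)
                    counts = count_support(read_sequences(ginput.reads), probes,
                                           min_overhang=config.min_overhang,
                                           max_mismatches=config.max_mismatches)
                except CassexError as exc:
                    raise StageError(stage, str(exc)) from exc
                ef = counts_frame(counts)
                ef.insert(0, "gene_id", gm.gene_id)
                evidence_frames.append(ef)
                entry["isoform_counts"] = dict(
                    retained=counts.retained, skipped=counts.skipped,
                    ambiguous=counts.ambiguous, total=counts.total_scanned,
                    psi=counts.psi, psi_ci=counts.psi_ci,
                    ratio_long_short=counts.ratio_long_short,
                )
            summary[gm.gene_id] = entry
            log.info("gene %s done in %.2fs", gm.gene_id, time.monotonic() - t0)

        calls, tallies = classify_panel(panel_rows, rule=config.predictor_rule,
                                        delta_threshold=config.delta_threshold)
        for _, row in calls.iterrows():
            summary[row["species"]]["call"] = row["call"]
            summary[row["species"]]["rule"] = row["rule"]

        _write_tsv(pd.DataFrame(intron_rows), out / "introns.tsv", cfg_hash)
        _write_tsv(calls, out / "skipping_calls.tsv", cfg_hash)
        _write_tsv(tallies, out / "group_tallies.tsv", cfg_hash)
        if evidence_frames:
            _write_tsv(pd.concat(evidence_frames, ignore_index=True),
                       out / "isoform_evidence.tsv", cfg_hash)
        (out / "summary.json").write_text(json.dumps(
            {"config_hash": cfg_hash, "seed": config.seed, "genes": summary},
            indent=1, sort_keys=True,
        ))
        log.info("run complete")
        return out
    except Exception:
        failed_marker.write_text("pipeline failed; see run.log\n")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
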