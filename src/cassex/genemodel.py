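"""Gene-model I/O: annotated records in, introns and junction sequences out.

A :class:`GeneModel` holds one gene in *transcription orientation*: for
minus-strand annotations the region sequence is reverse-complemented and the
exon coordinates remapped at parse time, so that exon 1 is always the first
transcribed exon and plain slicing arithmetic applies everywhere downstream.

Coordinates are 0-based half-open internally; GenBank/GFF3 1-based inclusive
coordinates are converted at the boundary. Intron ``i`` lies between exon
``i`` and exon ``i+1`` (1-based), matching the conventional I_6/I_7 naming
for a cassette exon 7.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .errors import ParseError, TruncatedSiteError, UnsupportedFormatError, ValidationError
from .seqtools import normalize, revcomp


@dataclass
class GeneModel:
    """One gene's exon structure and region sequence, transcription-oriented.

    ``exons`` are ``(start, end)`` pairs, 0-based half-open, sorted in
    transcription order, non-overlapping, each with ``end > start``, all
    within ``sequence``. ``strand`` records the original genomic strand; the
    stored sequence is already reverse-complemented for ``-`` so exon order
    equals transcription order.
    """

    gene_id: str
    species: str
    strand: str
    exons: list[tuple[int, int]]
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = normalize(self.sequence)
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValidationError("gene model needs at least one exon")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise ValidationError(f"exon ({start},{end}) has end <= start")
            if start < 0 or end > len(self.sequence):
                raise ValidationError(
                    f"exon ({start},{end}) outside sequence of length {len(self.sequence)}"
                )
            if prev_end is not None and start < prev_end:
                raise ValidationError(
                    f"exons overlap or are unsorted near ({start},{end})"
                )
            prev_end = end

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    def exon_seq(self, i: int) -> str:
        """Sequence of exon ``i`` (1-based, transcription order)."""
        start, end = self.exons[i - 1]
        return self.sequence[start:end]

    def intron_span(self, i: int) -> tuple[int, int]:
        """0-based half-open span of intron ``i`` (between exons i and i+1)."""
        if not 1 <= i <= self.exon_count - 1:
            raise ValidationError(f"intron index {i} out of range for {self.exon_count} exons")
        return self.exons[i - 1][1], self.exons[i][0]

    def intron_seq(self, i: int) -> str:
        start, end = self.intron_span(i)
        return self.sequence[start:end]


@dataclass
class IntronRecord:
    """Intron ``index`` (1-based) with its sequence and boundary dinucleotides."""

    index: int
    seq: str
    length: int
    donor_dinucleotide: str
    acceptor_dinucleotide: str

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValidationError("intron index must be >= 1")
        if self.length != len(self.seq):
            raise ValidationError("intron length field disagrees with sequence")


@dataclass
class JunctionSeq:
    """A donor or acceptor junction window with explicit position labels.

    Donor positions run ``-exon_flank .. -1`` (exonic) then ``+1 ..
    +intron_flank`` (intronic); acceptors mirror this, intron side first.
    """

    kind: str
    exon_flank: int
    intron_flank: int
    seq: str
    positions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("donor", "acceptor"):
            raise ValidationError(f"junction kind must be donor/acceptor, got {self.kind!r}")
        if len(self.seq) != self.exon_flank + self.intron_flank:
            raise ValidationError("junction length != exon_flank + intron_flank")
        if not self.positions:
            self.positions = junction_position_labels(
                self.kind, self.exon_flank, self.intron_flank
            )


@dataclass
class AcceptorTail:
    """The 3' tail of an intron, flagged when shorter than requested."""

    seq: str
    requested: int
    truncated: bool


def junction_position_labels(kind: str, exon_flank: int, intron_flank: int) -> list[str]:
    exonic = [str(-i) for i in range(exon_flank, 0, -1)]
    intronic = [f"+{i}" for i in range(1, intron_flank + 1)]
    if kind == "donor":
        return exonic + intronic
    # acceptor: intron side first, counted back from the junction
    return [str(-i) for i in range(intron_flank, 0, -1)] + [f"+{i}" for i in range(1, exon_flank + 1)]


# ---------------------------------------------------------------------------
# Readers


def read_gene_model(
    path: str | Path,
    format: str = "genbank",
    fasta: str | Path | None = None,
    transcript: Optional[str] = None,
) -> GeneModel:
    """Parse one annotated gene into a :class:`GeneModel`.

    ``format`` is ``"genbank"`` (flat file with exon features, possibly under
    mRNA joins) or ``"gff3"`` (exon features with Parent attributes; requires
    ``fasta`` with the region sequence). When several transcripts are
    annotated the longest one (total exonic nt) is used unless ``transcript``
    names one explicitly.
    """
    if format == "genbank":
        return _read_genbank(Path(path), transcript)
    if format in ("gff3", "gff3+fasta"):
        if fasta is None:
            raise UnsupportedFormatError("gff3 input requires a companion FASTA path")
        return _read_gff3(Path(path), Path(fasta), transcript)
    raise UnsupportedFormatError(f"unknown gene-model format {format!r}")


def _orient(seq: str, exons: list[tuple[int, int]], strand: str) -> tuple[str, list[tuple[int, int]]]:
    """Map genomic-orientation exons to transcription orientation."""
    if strand == "+":
        return seq, sorted(exons)
    L = len(seq)
    flipped = sorted((L - end, L - start) for start, end in exons)
    return revcomp(seq), flipped


def _read_genbank(path: Path, transcript: Optional[str]) -> GeneModel:
    record = SeqIO.read(str(path), "genbank")
    species = record.annotations.get("organism", "") or ""
    gene_id = record.id or record.name

    # Transcript-level features (mRNA joins) take precedence; otherwise the
    # flat set of exon features defines a single transcript.
    mrnas = [f for f in record.features if f.type == "mRNA"]
    if mrnas:
        chosen = _pick_mrna(mrnas, transcript)
        parts = sorted(chosen.location.parts, key=lambda p: int(p.start))
        strand = "-" if chosen.location.strand == -1 else "+"
        exons = [(int(p.start), int(p.end)) for p in parts]
        tid = _feature_name(chosen)
        if tid:
            gene_id = tid
    else:
        exon_feats = [f for f in record.features if f.type == "exon"]
        if not exon_feats:
            raise ParseError(f"{path}: no exon or mRNA features found")
        strands = {f.location.strand for f in exon_feats}
        if len(strands) > 1:
            raise ParseError(f"{path}: exon features on mixed strands")
        strand = "-" if strands.pop() == -1 else "+"
        exons = sorted((int(f.location.start), int(f.location.end)) for f in exon_feats)
        for g in record.features:
            if g.type == "gene" and "gene" in g.qualifiers:
                gene_id = g.qualifiers["gene"][0]
                break
    _check_overlap(exons, str(path))
    seq, exons = _orient(str(record.seq), exons, strand)
    return GeneModel(gene_id=gene_id, species=species, strand=strand, exons=exons, sequence=seq)


def _feature_name(feat: SeqFeature) -> Optional[str]:
    for key in ("transcript_id", "gene", "locus_tag", "label"):
        if key in feat.qualifiers:
            return feat.qualifiers[key][0]
    return None


def _pick_mrna(mrnas: list[SeqFeature], transcript: Optional[str]) -> SeqFeature:
    if transcript is not None:
        for f in mrnas:
            if _feature_name(f) == transcript:
                return f
        raise ParseError(f"transcript {transcript!r} not found among mRNA features")
    return max(mrnas, key=lambda f: sum(len(p) for p in f.location.parts))


_GFF_COLS = 9


def _read_gff3(gff_path: Path, fasta_path: Path, transcript: Optional[str]) -> GeneModel:
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    by_parent: dict[str, list[tuple[int, int, str, str]]] = {}
    species = ""
    for line in gff_path.read_text().splitlines():
        if not line or line.startswith("#"):
            if line.startswith("#!species"):
                species = line.split(maxsplit=1)[1].strip()
            continue
        cols = line.split("\t")
        if len(cols) != _GFF_COLS:
            raise ParseError(f"{gff_path}: malformed GFF3 line: {line!r}")
        seqid, _, ftype, start, end, _, strand, _, attrs = cols
        if ftype != "exon":
            continue
        attr = dict(
            kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
        )
        parent = attr.get("Parent", attr.get("ID", "transcript"))
        # GFF3 is 1-based inclusive -> 0-based half-open
        by_parent.setdefault(parent, []).append((int(start) - 1, int(end), strand, seqid))
    if not by_parent:
        raise ParseError(f"{gff_path}: no exon features found")
    if transcript is not None:
        if transcript not in by_parent:
            raise ParseError(f"transcript {transcript!r} not found in GFF3 Parent attributes")
        parent = transcript
    else:
        parent = max(by_parent, key=lambda p: sum(e - s for s, e, *_ in by_parent[p]))
    rows = by_parent[parent]
    strands = {r[2] for r in rows}
    seqids = {r[3] for r in rows}
    if len(strands) > 1 or len(seqids) > 1:
        raise ParseError(f"{gff_path}: exons of {parent!r} span strands or sequences")
    seqid = seqids.pop()
    strand = strands.pop()
    if strand not in ("+", "-"):
        raise ParseError(f"{gff_path}: exon strand {strand!r} is not +/-")
    if seqid not in seqs:
        raise ParseError(f"sequence {seqid!r} not present in {fasta_path}")
    exons = sorted((s, e) for s, e, *_ in rows)
    _check_overlap(exons, str(gff_path))
    seq, exons = _orient(seqs[seqid], exons, strand)
    return GeneModel(gene_id=parent, species=species, strand=strand, exons=exons, sequence=seq)


def _check_overlap(exons: list[tuple[int, int]], source: str) -> None:
    prev = None
    for start, end in exons:
        if prev is not None and start < prev:
            raise ParseError(f"{source}: overlapping exon features at ({start},{end})")
        prev = end


# ---------------------------------------------------------------------------
# Writers


def write_genbank(gm: GeneModel, path: str | Path) -> None:
    """Write a GeneModel as a GenBank flat file (genomic orientation).

    Minus-strand models are reverse-complemented back so a re-read
    round-trips exons, strand and sequence exactly.
    """
    if gm.strand == "+":
        seq, exons, strand = gm.sequence, gm.exons, 1
    else:
        L = len(gm.sequence)
        seq = revcomp(gm.sequence)
        exons = sorted((L - e, L - s) for s, e in gm.exons)
        strand = -1
    record = SeqRecord(Seq(seq), id=gm.gene_id[:16] or "gene", name=re.sub(r"\W", "_", gm.gene_id)[:16] or "gene",
                       description=f"{gm.species} {gm.gene_id}".strip())
    record.annotations["molecule_type"] = "DNA"
    record.annotations["organism"] = gm.species
    for start, end in exons:
        record.features.append(
            SeqFeature(FeatureLocation(start, end, strand=strand), type="exon",
                       qualifiers={"gene": [gm.gene_id]})
        )
    SeqIO.write([record], str(path), "genbank")


def write_gff3(gm: GeneModel, gff_path: str | Path, fasta_path: str | Path) -> None:
    """Write a GeneModel as GFF3 + FASTA (genomic orientation)."""
    if gm.strand == "+":
        seq, exons = gm.sequence, gm.exons
    else:
        L = len(gm.sequence)
        seq = revcomp(gm.sequence)
        exons = sorted((L - e, L - s) for s, e in gm.exons)
    seqid = "region1"
    lines = ["##gff-version 3", f"#!species {gm.species}"]
    lines.append("\t".join([seqid, "cassex", "gene", "1", str(len(seq)), ".", gm.strand, ".",
                            f"ID=gene:{gm.gene_id}"]))
    lines.append("\t".join([seqid, "cassex", "mRNA", str(exons[0][0] + 1), str(exons[-1][1]), ".",
                            gm.strand, ".", f"ID={gm.gene_id};Parent=gene:{gm.gene_id}"]))
    for k, (start, end) in enumerate(exons, 1):
        lines.append("\t".join([seqid, "cassex", "exon", str(start + 1), str(end), ".", gm.strand,
                                ".", f"ID={gm.gene_id}.exon{k};Parent={gm.gene_id}"]))
    Path(gff_path).write_text("\n".join(lines) + "\n")
    SeqIO.write([SeqRecord(Seq(seq), id=seqid, description="")], str(fasta_path), "fasta")


# ---------------------------------------------------------------------------
# Derivations


def derive_introns(gm: GeneModel) -> list[IntronRecord]:
    """All introns of the model, in transcription order.

    Single-exon genes yield an empty list. A zero-length gap between
    adjacent exons is annotation nonsense and raises.
    """
    records = []
    for i in range(1, gm.exon_count):
        start, end = gm.intron_span(i)
        if end <= start:
            raise ValidationError(f"intron {i} has non-positive length (exons touch or overlap)")
        seq = gm.sequence[start:end]
        records.append(
            IntronRecord(index=i, seq=seq, length=len(seq),
                         donor_dinucleotide=seq[:2], acceptor_dinucleotide=seq[-2:])
        )
    return records


def reconstruct_span(gm: GeneModel) -> str:
    """Exons and introns re-concatenated; equals the annotated gene span."""
    first, last = gm.exons[0][0], gm.exons[-1][1]
    parts = []
    for i in range(1, gm.exon_count + 1):
        parts.append(gm.exon_seq(i))
        if i < gm.exon_count:
            parts.append(gm.intron_seq(i))
    assert "".join(parts) == gm.sequence[first:last]
    return "".join(parts)


def extract_donor_site(
    gm: GeneModel, intron_index: int, exon_flank: int = 5, intron_flank: int = 12
) -> JunctionSeq:
    """Donor (5'SS) window of intron ``intron_index``: exon tail + intron head."""
    exon = gm.exon_seq(intron_index)
    intron = gm.intron_seq(intron_index)
    if exon_flank > len(exon):
        raise TruncatedSiteError(
            f"exon {intron_index} has only {len(exon)} nt (< exon_flank {exon_flank})",
            available=len(exon),
        )
    if intron_flank > len(intron):
        raise TruncatedSiteError(
            f"intron {intron_index} has only {len(intron)} nt (< intron_flank {intron_flank})",
            available=len(intron),
        )
    seq = (exon[len(exon) - exon_flank:] if exon_flank else "") + intron[:intron_flank]
    return JunctionSeq(kind="donor", exon_flank=exon_flank, intron_flank=intron_flank, seq=seq)


def extract_acceptor_site(
    gm: GeneModel, intron_index: int, intron_flank: int = 12, exon_flank: int = 5
) -> JunctionSeq:
    """Acceptor (3'SS) window: intron tail + head of the next exon."""
    intron = gm.intron_seq(intron_index)
    exon = gm.exon_seq(intron_index + 1)
    if intron_flank > len(intron):
        raise TruncatedSiteError(
            f"intron {intron_index} has only {len(intron)} nt (< intron_flank {intron_flank})",
            available=len(intron),
        )
    if exon_flank > len(exon):
        raise TruncatedSiteError(
            f"exon {intron_index + 1} has only {len(exon)} nt (< exon_flank {exon_flank})",
            available=len(exon),
        )
    seq = intron[len(intron) - intron_flank:] + (exon[:exon_flank] if exon_flank else "")
    return JunctionSeq(kind="acceptor", exon_flank=exon_flank, intron_flank=intron_flank, seq=seq)


def extract_acceptor_tail(gm: GeneModel, intron_index: int, n: int) -> AcceptorTail:
    """Last ``min(n, length)`` nt of the intron, flagged when truncated."""
    intron = gm.intron_seq(intron_index)
    truncated = len(intron) < n
    return AcceptorTail(seq=intron[-n:] if n else "", requested=n, truncated=truncated)


# ---------------------------------------------------------------------------
# Tabular / FASTA exports


def intron_table(gms: Iterable[GeneModel]) -> pd.DataFrame:
    rows = []
    for gm in gms:
        for rec in derive_introns(gm):
            rows.append(
                dict(gene_id=gm.gene_id, intron_index=rec.index, length=rec.length,
                     donor_dint=rec.donor_dinucleotide, acceptor_dint=rec.acceptor_dinucleotide)
            )
    return pd.DataFrame(rows, columns=["gene_id", "intron_index", "length", "donor_dint", "acceptor_dint"])


def write_junction_fasta(gm: GeneModel, path: str | Path, exon_flank: int = 5, intron_flank: int = 12) -> int:
    """One FASTA record per donor junction, ID ``geneid|donor|intron_i``."""
    records = []
    for i in range(1, gm.exon_count):
        js = extract_donor_site(gm, i, exon_flank, intron_flank)
        records.append(SeqRecord(Seq(js.seq), id=f"{gm.gene_id}|donor|intron_{i}", description=""))
    SeqIO.write(records, str(path), "fasta")
    return len(records)
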