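"""Gene-model parsing, intron derivation and junction extraction."""

import numpy as np
import pytest

from cassex.errors import ParseError, TruncatedSiteError, ValidationError
from cassex.genemodel import (
    GeneModel,
    derive_introns,
    extract_acceptor_site,
    extract_acceptor_tail,
    extract_donor_site,
    read_gene_model,
    reconstruct_span,
    write_genbank,
    write_gff3,
)


def test_genbank_round_trip(toy_gene, tmp_path):
    path = tmp_path / "toy.gb"
    write_genbank(toy_gene, path)
    gm = read_gene_model(path, "genbank")
    assert gm.exons == toy_gene.exons
    assert gm.sequence == toy_gene.sequence
    assert gm.strand == "+"
    assert len(derive_introns(gm)) == 2


def test_minus_strand_annotation_gives_same_model(toy_gene, tmp_path):
    """A gene annotated on the minus strand of the reverse-complemented
    region parses to the identical transcription-oriented model."""
    minus = GeneModel(gene_id=toy_gene.gene_id, species=toy_gene.species, strand="-",
                      exons=toy_gene.exons, sequence=toy_gene.sequence)
    p_plus, p_minus = tmp_path / "p.gb", tmp_path / "m.gb"
    write_genbank(toy_gene, p_plus)
    write_genbank(minus, p_minus)
    # the minus-strand file holds the reverse-complemented genome
    assert read_gene_model(p_minus, "genbank").strand == "-"
    gm_p, gm_m = read_gene_model(p_plus, "genbank"), read_gene_model(p_minus, "genbank")
    assert gm_p.sequence == gm_m.sequence
    assert gm_p.exons == gm_m.exons
    assert extract_donor_site(gm_p, 1, 5, 8).seq == extract_donor_site(gm_m, 1, 5, 8).seq


def test_gff3_cross_format_oracle(toy_gene, tmp_path):
    """GFF3+FASTA and GenBank encodings of the same gene parse identically."""
    write_genbank(toy_gene, tmp_path / "g.gb")
    write_gff3(toy_gene, tmp_path / "g.gff3", tmp_path / "g.fa")
    a = read_gene_model(tmp_path / "g.gb", "genbank")
    b = read_gene_model(tmp_path / "g.gff3", "gff3", fasta=tmp_path / "g.fa")
    assert a.exons == b.exons
    assert a.sequence == b.sequence
    assert a.strand == b.strand


def test_multi_transcript_selection(tmp_path):
    from Bio.Seq import Seq
    from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    seq = "ACGT" * 30
    rec = SeqRecord(Seq(seq), id="multi", name="multi", description="")
    rec.annotations["molecule_type"] = "DNA"
    short = SeqFeature(CompoundLocation([FeatureLocation(0, 10, 1), FeatureLocation(50, 60, 1)]),
                       type="mRNA", qualifiers={"transcript_id": ["short"]})
    long = SeqFeature(CompoundLocation([FeatureLocation(0, 20, 1), FeatureLocation(40, 80, 1)]),
                      type="mRNA", qualifiers={"transcript_id": ["long"]})
    rec.features = [short, long]
    SeqIO.write([rec], str(tmp_path / "m.gb"), "genbank")
    assert read_gene_model(tmp_path / "m.gb", "genbank").exons == [(0, 20), (40, 80)]
    assert read_gene_model(tmp_path / "m.gb", "genbank", transcript="short").exons == [(0, 10), (50, 60)]
    with pytest.raises(ParseError):
        read_gene_model(tmp_path / "m.gb", "genbank", transcript="absent")


def test_intron_lengths_arithmetic(toy_gene):
    introns = derive_introns(toy_gene)
    assert [r.length for r in introns] == [10, 15]
    assert all(r.length == len(r.seq) for r in introns)


def test_adjacent_exons_rejected():
    with pytest.raises(ValidationError):
        derive_introns(GeneModel("g", "s", "+", [(0, 10), (10, 20)], "A" * 20))


def test_single_exon_gene_has_no_introns():
    assert derive_introns(GeneModel("g", "s", "+", [(0, 10)], "A" * 10)) == []


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_reconstruction_property_random_gene(seed):
    """Exons + introns re-concatenate to the annotated span (8-exon gene)."""
    rng = np.random.default_rng(seed)
    pos, exons = int(rng.integers(0, 5)), []
    for _ in range(8):
        length = int(rng.integers(5, 40))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(1, 30))
    seq = "".join(rng.choice(list("ACGT"), size=pos + 10))
    gm = GeneModel("rand", "s", "+", exons, seq)
    span = reconstruct_span(gm)
    assert span == seq[exons[0][0]:exons[-1][1]]


def test_donor_site_human_like_window():
    """Exon ending ...TCAAA followed by intron GTAAGTGA... yields the
    canonical 13-nt window at flanks (5, 8)."""
    exon = "GGGGGTCAAA"
    intron = "GTAAGTGAGCTTCCCCCCCCCCCCCCCAG"
    seq = exon + intron + "AAAAAAAAAA"
    gm = GeneModel("g", "s", "+", [(0, 10), (len(exon) + len(intron), len(seq))], seq)
    assert extract_donor_site(gm, 1, 5, 8).seq == "TCAAAGTAAGTGA"
    assert extract_donor_site(gm, 1, 0, 2).seq == "GT"
    js = extract_donor_site(gm, 1, 5, 12)
    assert js.positions == ["-5", "-4", "-3", "-2", "-1"] + [f"+{i}" for i in range(1, 13)]


@pytest.mark.parametrize("exon_flank,intron_flank", [(5, 12), (3, 6), (1, 1)])
def test_donor_site_matches_slicing_oracle(cassette_gene, exon_flank, intron_flank):
    gm, _ = cassette_gene
    for i in range(1, gm.exon_count):
        js = extract_donor_site(gm, i, exon_flank, intron_flank)
        end = gm.exons[i - 1][1]
        assert js.seq == gm.sequence[end - exon_flank : end + intron_flank]


def test_donor_flank_too_large_reports_available(toy_gene):
    with pytest.raises(TruncatedSiteError) as err:
        extract_donor_site(toy_gene, 1, exon_flank=11, intron_flank=2)
    assert err.value.available == 10


def test_acceptor_site_mirrors_donor(cassette_gene):
    gm, _ = cassette_gene
    js = extract_acceptor_site(gm, 1, intron_flank=12, exon_flank=5)
    start = gm.exons[1][0]
    assert js.seq == gm.sequence[start - 12 : start + 5]
    assert js.seq[10:12] == "AG"


def test_acceptor_tail_and_truncation(toy_gene, cassette_gene):
    gm, _ = cassette_gene
    tail = extract_acceptor_tail(gm, 1, 50)
    assert len(tail.seq) == 50 and not tail.truncated
    assert tail.seq.endswith("AG")
    short = extract_acceptor_tail(toy_gene, 1, 50)  # intron is 10 nt
    assert len(short.seq) == 10 and short.truncated
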