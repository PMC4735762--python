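import numpy as np
import pytest

from cassex.datasets import load_chr22_donor_pwm, load_usp4_e7_peptide, usp4_panel_rows
from cassex.genemodel import GeneModel
from cassex.simulate import BpsPlan, GeneConfig, synth_gene_model


@pytest.fixture(scope="session")
def chr22_pwm():
    """The bundled 13-column donor-site log-odds matrix."""
    return load_chr22_donor_pwm()


@pytest.fixture(scope="session")
def e7_peptide():
    return load_usp4_e7_peptide()


@pytest.fixture(scope="session")
def usp4_panel():
    return usp4_panel_rows()


@pytest.fixture
def toy_gene():
    """3 exons of 10 nt separated by 10- and 15-nt introns on a 60-nt region."""
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=60))
    return GeneModel(gene_id="toy", species="toyspecies", strand="+",
                     exons=[(0, 10), (20, 30), (45, 60)], sequence=seq)


@pytest.fixture
def cassette_gene():
    """5-exon synthetic gene with a clean branchpoint at d_to3 = 30 in intron 3."""
    cfg = GeneConfig(
        exon_lengths=[60] * 5, intron_lengths=[120] * 4,
        donor_plus6=["T", "T", "A", "T"],
        bps_plan=[BpsPlan(intron_index=3, d_to3=30, clean=True)],
        gene_id="cassette5", species="synthetic",
    )
    gm, truth = synth_gene_model(cfg, seed=11)
    return gm, truth
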