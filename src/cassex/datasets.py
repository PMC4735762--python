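"""Bundled reference data.

* ``load_chr22_donor_pwm`` — a published donor-site (5'SS) log-odds matrix
  trained on 15,770 exon-intron junctions of human chromosome 22, 13
  columns (5 exonic, -5..-1; 8 intronic, +1..+8). Shipped as scores only;
  the underlying counts were never published, so count-based operations on
  this matrix are unavailable.
* ``load_usp4_donor_panel`` — the 14-species vertebrate USP4 donor table
  around cassette exon 7: the 13-nt 5'SS_6 and 5'SS_7 windows plus their
  published PWMS values (reported as data; the published scores used a
  wider window than the 13 printed columns and are not recomputable from
  this matrix).
* ``load_usp4_e7_peptide`` — the human USP4 exon-7 peptide as published.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .pwm import PWM
from .skipping import DonorPair


def _data_path(name: str):
    return resources.files("cassex.data") / name


def load_chr22_donor_pwm() -> PWM:
    with resources.as_file(_data_path("chr22_donor_pwm.tsv")) as p:
        return PWM.from_tsv(p)


def load_usp4_donor_panel() -> pd.DataFrame:
    with resources.as_file(_data_path("usp4_donor_sites.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_usp4_e7_peptide() -> str:
    return _data_path("usp4_e7_peptide.txt").read_text().strip()


def usp4_panel_rows() -> list[tuple[str, str, DonorPair]]:
    """The USP4 panel as (species, group, DonorPair) rows for classify_panel."""
    df = load_usp4_donor_panel()
    rows = []
    for _, r in df.iterrows():
        rows.append((
            r["species"], r["group"],
            DonorPair(
                upstream_plus6=r["ss6"][10], downstream_plus6=r["ss7"][10],
                upstream_pwms=float(r["pwms6"]), downstream_pwms=float(r["pwms7"]),
                exon_present=bool(r["exon_present"]),
            ),
        ))
    return rows
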