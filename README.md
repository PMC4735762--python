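# cassex

Comparative splice-signal analysis of cassette exons.

Vertebrate genes sometimes keep an internal ("cassette") exon alternatively
spliced for hundreds of millions of years — the seventh exon of the
deubiquitinase gene USP4 is the canonical example, included or skipped in
therian mammals but constitutively retained in birds and fish. Whether such
an exon is skipped is largely written into its flanking *cis* splice
signals: the strengths of the two donor (5′) splice sites, the placement of
branchpoint motifs near the 3′ ends of the flanking introns, and — at the
finest grain — the identity of the sixth intronic nucleotide (+6) of each
donor. `cassex` implements that comparative framework as a tested,
composable pipeline for anyone studying exon-skipping architecture across
species: molecular evolution and RNA-splicing labs, primarily.

## What it computes

* **Donor-site PWM scoring** — position weight matrices over junction
  windows (5 exonic + 8 or 12 intronic nt), with per-position log-odds
  `score(b, j) = log2(((c_bj + κ·q_b)/(n + κ))/q_b)`, additive PWMS scores,
  consensus, information content (logo data), and a paired t-test for
  comparing matched site strengths. A published 13-column donor matrix
  trained on 15,770 human chromosome-22 junctions ships with the package.
* **Branchpoint detection** — degenerate YURAY (`[CT]T[AG]A[CT]`) motif
  scanning, the intervening-AG exclusion rule (the first AG after a genuine
  branchpoint is the 3′ splice site), distances `d_to3′` to the intron end,
  and estimation of the optimal-distance window (the smallest interval
  covering a target fraction of distances, canonically 20–40 nt).
* **Conservation profiling** — Shannon entropy `H = −Σ pᵢ log2 pᵢ` per
  alignment column (gaps excluded) with sliding-window smoothing, and
  exon/intron length-architecture summaries (mode, mode fraction, range)
  per clade.
* **Skipping prediction** — the +6 discriminant rule (strength order
  T > C ≥ A > G; skip iff the upstream donor's +6 is strong/neutral and the
  exon's own donor's +6 is weak) plus a secondary PWMS-difference rule.
* **Isoform evidence** — exact junction-spanning read counting (retained vs
  skipped), PSI with a Wilson 95% interval and an optional effective-length
  correction, and the long/short isoform ratio.
* **Peptide properties** — phase-aware translation of the cassette exon and
  composition/charge profiling (serine richness, K/R/H vs D/E tallies, net
  charge, S/T/Y positions).
* **Synthetic data** — seeded generators for gene models with planted donor
  +6 identities and branchpoints, junction sets drawn from a known
  probability matrix, and isoform reads at a chosen PSI, each with a
  machine-readable truth record.

## Worked example

```python
>>> from cassex.datasets import load_chr22_donor_pwm, load_usp4_e7_peptide
>>> from cassex import score_sequence, max_score, consensus, profile_peptide
>>> from cassex.skipping import DonorPair, predict_from_plus6
>>> pwm = load_chr22_donor_pwm()
>>> consensus(pwm, columns=slice(2, 11)).sequence     # positions -3..+6
'CAGGTAAGT'
>>> round(score_sequence(pwm, "TCAAAGTAAGTGA").score, 4)   # human upstream donor
9.0273
>>> round(max_score(pwm), 4)
14.3656
>>> predict_from_plus6(DonorPair("T", "A")).call      # therian configuration
'alternative_skipping'
>>> p = profile_peptide(load_usp4_e7_peptide())
>>> p.serine_count, p.positive_count, p.negative_count, p.net_charge
(16, 5, 1, 4)
```

The consensus is the canonical donor signal CAG|GTAAGT; 9.0273 is the
summed log-odds of the human upstream donor window over the bundled matrix
(out of a best achievable 14.3656); the T;A +6 configuration is the one
therian mammals maintain and predicts skipping; and the cassette-exon
peptide is serine-rich (16/48 residues) with five positive and one negative
residue, so skipping changes the protein's net charge by 4.

A full pipeline run (extract → score → branchpoint → predict → evidence)
is driven by a YAML config:

```bash
cassex simulate --seed 3 --plus6 T,T,A,T --bps 3:30 --out-prefix demo
cassex extract demo.gb --introns-out introns.tsv
cassex run config.yaml          # see cassex run --help
```

Each stage is also exposed as a library function and as its own subcommand
(`pwm-build`, `pwm-score`, `bps-scan`, `entropy`, `lengths`, `predict`,
`evidence`, `peptide`).

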