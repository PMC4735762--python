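# Methods

This note documents the models, conventions and design choices behind
`cassex`, in the spirit of a statistics package's methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Gene models and coordinates

A `GeneModel` stores one gene in transcription orientation: minus-strand
records are reverse-complemented and their exon coordinates remapped at
parse time, so that downstream arithmetic never branches on strand.
Internal coordinates are 0-based half-open; GenBank and GFF3 1-based
inclusive coordinates are converted at the I/O boundary only. Intron *i*
lies between exons *i* and *i+1* (1-based), so the donor of intron 6
("5′SS₆") is the site used by both isoforms of a cassette exon 7 and the
donor of intron 7 ("5′SS₇") is the exon's own. When a record annotates
several transcripts the longest (total exonic nt) is taken by default — an
artifact decision, since no selection rule is standard — overridable per
call. All input is folded to upper-case DNA (U→T); non-ACGT symbols are
carried through but never match motifs and score as background.

Junction windows default to 5 exonic + 12 intronic nt at extraction and 5 +
8 for scoring, matching the width of the bundled reference matrix; both are
parameters.

## Donor-site PWMs

Log-odds with a background-scaled Laplace pseudocount κ (default 1):

    score(b, j) = log2( ((count(b,j) + κ·q_b) / (n + κ)) / q_b )

Background q defaults to uniform 0.25 and can be estimated from supplied
sequences. At κ = 0 an unobserved base would give −∞; such cells are
floored at −30, which preserves ordering while keeping sums finite.
Ambiguity symbols contribute to no base's count when training and
contribute 0 when scoring. PWMS is the per-position sum; `max_score` is the
column-max sum; consensus argmax ties break alphabetically and are flagged.
Column information content is `2 − H` bits of the pseudocounted column
frequencies (the logo height scale).

The bundled chromosome-22 donor matrix is shipped as published scores
(13 columns); its training counts were never published, so count-based
operations on it raise. The published per-species PWMS values distributed
with the vertebrate panel were computed by the original authors over a
wider window than the 13 printed columns and therefore do not equal sums
over this matrix; they are carried as data, and this package's own sums
over the printed columns (e.g. 9.0273 for the human upstream donor,
column-max sum 14.3656) are what the tests assert.

The paired site-strength comparison is a classical two-sided paired t-test
(scipy). Zero-variance difference vectors — which scipy reports as NaN —
are returned explicitly as degenerate: t = 0, p = 1 when all differences
are zero, signed infinity otherwise.

## Branchpoints

Candidates are YURAY motifs, DNA rendering `[CT]T[AG]A[CT]`, scanned with
overlap. Distance `d_to3′` is counted from the motif's first base to the
intron's 3′ end, so a motif occupying the last five nucleotides has
`d_to3′ = 5`. A hit is disqualified when an AG dinucleotide starts anywhere
between the motif's end and the terminal 3′SS AG (offsets `[start+5, L−3]`;
the terminal AG at `L−2` never counts) — the first AG downstream of a
genuine branchpoint is generally used as the 3′ splice site. The degenerate
pattern itself cannot contain an internal AG start (asserted in tests), so
the exclusion scan safely begins at the motif end. Introns that do not end
in AG are processed with a warning rather than rejected, tolerating
annotation noise.

The optimal-distance window is the smallest contiguous integer interval
covering at least a target fraction of observed distances (default 0.75,
bracketing published calibrations of roughly 0.8 at 20–40 nt; ties on width
break toward the smaller lower bound). A strong-branchpoint call requires
at least one clean candidate inside the window; the best candidate is the
one nearest the window midpoint, ties toward the smaller distance. An
optional minimum intron length (off by default) excludes very short introns
from distribution estimates.

## Conservation and length architecture

Column entropy is `H = −Σ pᵢ log2 pᵢ` over residues observed at the column,
gaps excluded and frequencies renormalised; all-gap columns are missing
(NaN), not zero. Bits (log base 2) are used throughout; the profile's shape
is base-invariant. Columns with non-gap coverage below a threshold (default
0.5) are masked. Smoothing is a centred moving average with an odd window
(default 9 columns); masked columns stay masked. Length tables are
summarised per (clade, unit, index) cell by mode (smallest on ties), mode
fraction, and range.

## Skipping prediction

The +6 strengths are ordered T > C ≥ A > G (an empirical ranking of donor
+6 identities; note the reference matrix's +6 column orders G marginally
above A — the text ranking is used for the ordinal map, and nothing
downstream depends on the A/G order). The discriminant rule is
class-based, not ordinal: skip iff the upstream donor's +6 ∈ {T, C}
(strong/neutral) and the exon's own donor's +6 ∈ {A, G} (weak). A strict
"upstream stronger than downstream" comparison would mispredict the
T-vs-C configuration observed in fish, where both donors are
strong/neutral and the exon is retained; the class rule is the minimal one
consistent with every labelled vertebrate configuration. Exon loss is an
annotation fact, never inferred from sequence.

The secondary rule calls skipping when `PWMS_upstream − PWMS_downstream`
exceeds a threshold, default 2.0 — an artifact calibration chosen between
the smallest skipping-associated gap (≈ 2.77) and the largest
non-skipping gap (≈ 2.09) in the bundled vertebrate panel, exposed in
config and documented as such rather than a literature constant.

## Isoform evidence and PSI

Reads are classified by exact substring matching (optionally ≤ 2
mismatches via sliding Hamming comparison) of junction probe cores: a read
supports a junction iff it contains the probe segment covering at least
`min_overhang` nt (default 8) on each side of the junction point. Reads
matching both isoform classes are ambiguous; reverse complements are
checked by default. Matching is deliberately exact rather than
alignment-based: the operation is evidence counting, and exactness keeps
the oracle trivial.

The raw proportion `retained/(retained+skipped)` overweights the retained
isoform: it carries two junctions (and a longer transcript), so its reads
span a junction roughly twice as often. `count_support` therefore accepts
per-isoform junction-spanning probabilities (computed exactly by
enumerating error-free read start positions via
`effective_spanning_probs`) and applies the standard effective-length
correction; the raw proportion q estimates `ψ·p_r/(ψ·p_r + (1−ψ)·p_s)`, so
ψ and its interval are obtained by pushing q and its Wilson bounds through
the inverse map, which is monotone and hence coverage-preserving. Without
the correction the reported PSI is the raw proportion. The long/short
ratio is always the raw count ratio.

## Peptides

Translation uses the standard code on complete codons after skipping the
exon phase; trailing partial codons are dropped and internal stops truncate,
both with warnings. Charge profiling counts K/R/H positive and D/E negative
by default; histidine's inclusion is a visible parameter. The bundled
cassette-exon peptide is taken exactly as published (48 letters, although
the accompanying prose says 47 residues; only the internally consistent
serine and charge tallies are asserted anywhere).

## Synthetic data

Generators emulate the statistical structure the analyses assume: donor
sites begin GTAAG followed by a requested +6 base, introns begin GT and end
AG, branchpoint motifs (CTAAC) are planted at requested distances, and
accidental clean YURAY candidates within the scan window (default last 50
nt) are purged by rejection sampling (cap 1000 tries, then a configuration
error). Background sequence is i.i.d. uniform ACGT by default with an
optional biased composition. The read simulator draws each read from the
retained transcript with probability ψ, else the skipped one, with uniform
start and substitution-only errors; no indels, fragmentation or coverage
bias are modelled. Every generator emits a truth record and is
deterministic per seed.

What passing tests on this data do show: correctness of the motif/window
logic, unbiasedness and interval coverage of the PSI estimator under the
stated sampling model, and exact recovery of planted signals. What they do
not show: robustness to real annotation errors, non-uniform read coverage,
paralogous junction sequences, or genuine branchpoint sequence diversity
beyond the YURAY consensus.

## Problem sizes and numerical choices

Default test and acceptance problem sizes — 10,000 random introns for the
brute-force equivalence check, 5,000 junctions for probability-matrix
recovery (±0.02 per entry), 100 replicates of 2,000 reads for PSI interval
coverage, 1,000 distance draws for window recovery — were chosen as the
smallest sizes at which the corresponding statistical statements are
stable, and each completes in seconds on one CPU. Floating-point
comparisons in tests use absolute tolerances of 1e-4 for published
4-decimal quantities and 1e-9–1e-12 for identities.

## Known limitations

Branchpoint detection is motif-based (no energy or learned models) and the
polypyrimidine tract is not scored. The predictor models *cis* donor
signals only — no exonic enhancers/silencers or trans-acting factors. PWMs
are zeroth-order (no dependencies between positions). GFF3 support covers
the exon-with-Parent subset the pipeline needs, not the full
specification. Junction counting handles one cassette exon at a time.
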