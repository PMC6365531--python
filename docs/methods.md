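# Methods

This note documents the models, parameter choices and known limitations of
`ampseine`'s discovery cascade. Coordinates are 0-based half-open
everywhere in memory; conversion to 1-based inclusive coordinates happens
only in the GFF3 writer, so there is a single place where off-by-one
errors could arise.

## ORF discovery

Complete ORFs are runs from an ATG or GTG codon to the first in-frame stop
within the transcript. Nested ORFs sharing a stop are all emitted (one per
eligible start). Defaults: 20–100 residues inclusive (stop excluded),
sense strand only — the assumed input is a strand-specific RNA-seq
assembly; `strand_mode="both"` is available. GTG is translated as Val at
position 1 and is the only near-cognate start admitted: known amphibian
AMP precursors include Val-initiated sequences, while admitting further
near-cognate starts would multiply false candidates. Codons containing N
translate to X, and X is never a start residue.

## Profile-HMM screening

A family profile has M match states with 20-letter emissions, per-node
insert states and silent deletes; transition rows are stored per node as
(m→m, m→i, m→d, i→m, i→i, d→m, d→d). Scoring is uni-local: a path enters
any match state with probability 1/M and exits after any match state with
probability 1/M; flanking residues are emitted by the background and
cancel in the log-odds. X emits with log-odds 0 under both match and
background, so ambiguity neither creates nor destroys signal. Viterbi
maximises over paths and Forward sums over them, both in natural-log space
(reported in bits); both are verified against exhaustive path enumeration
for all models with ≤ 3 match states and peptides of ≤ 4 residues at 1e-9.

Significance: E = n_targets · P(S ≥ s). When a profile carries
forward-score tail statistics (tau, lambda), P is the exponential tail
exp(−lambda·(s − tau)), capped so E ≤ n_targets. `calibrate_profile` fits
(tau, lambda) once per model from 200 background peptides of length 50
(top-decile exponential tail), which keeps screening thousands of peptides
cheap; without statistics, a per-peptide null from 200 seeded shuffles of
the query is used. The screen threshold is E < 10⁻³ (strict inequality —
a threshold of 0 retains nothing). Background frequencies come from the
profile's COMPO line when present, else uniform 1/20.

The HMMER3/f ASCII dialect is the only profile format supported (binary
profiles are rejected); values are negative natural logs with `*` meaning
probability zero. Files written by this package are accepted by
independent HMMER3 parsers.

## Convertase-site splitting

A cleavage site is any Arg immediately preceded by Lys whose mature
fragment would be non-empty. The default rule cuts after the **last** K-R:
this is the single rule that reproduces all seven reference prepro/mature
boundaries, including the precursor with an additional KR near the
N-terminus (HP6); an `all` mode exposes every site for exploratory use.
Whether net positive mature charge should *filter* candidates (rather than
merely describe them) is left open; the pipeline reports charge but does
not filter on it.

## Physicochemical characterization

* **Net charge** is the formal count (K + R) − (D + E) with His and the
  termini excluded — the convention that reproduces the reference table's
  printed charges exactly. A pH-resolved charge is available separately.
* **Mass** is the sum of average (isotope-weighted) residue masses plus
  one water (18.02 Da), constants fixed in one table in code; values agree
  with the reference table within 0.1 Da.
* **pI** is the bisection root of the Henderson–Hasselbalch net charge on
  pH ∈ [0, 14] to |charge| < 1e-4 (≤ 100 iterations); when the charge
  never crosses zero the boundary is returned with a warning. Two pKa sets
  ship with the package: the default, `dtaselect` (N-term 8.0, C-term 3.1,
  C 8.5, D 4.4, E 4.4, H 6.5, K 10.0, R 12.0, Y 10.0), is the published
  set that reproduces the reference characterization table's pI values to
  ±0.05 across all seven peptides; `bjellqvist`, the set behind the ExPASy
  pI tools (with residue-specific terminal pKas), is provided and
  cross-checked against Biopython's implementation, but it deviates by up
  to ~0.26 pH units from three of the printed reference values, so it is
  not the default. Cysteines are treated as free thiols; disulfide-bonded
  (Rana-box) cysteines would not titrate, and no mass correction for
  disulfides is applied — both are documented approximations.

## Homology classification

Alignments use BLOSUM62 with affine gap costs: a gap of length g costs
open + g·extend (defaults 11/1, i.e. the first gapped column costs 12).
Traceback ties prefer diagonal, then up, then left, making alignments
deterministic. Identity and positivity are percentages over all aligned
columns — gap columns count in the denominator — where a positive column
scores > 0 in the substitution matrix. E-values are empirical: 200 seeded
shuffles of the subject, an exponential tail fitted to the top decile
(Karlin–Altschul theory is deliberately not assumed, keeping the statistic
self-contained and testable at desk scale; the E < 10⁻⁴ threshold
semantics are unchanged).

Classification: the best match is the lowest-E local full-precursor
alignment (ties by subject id); no match below E < 10⁻⁴ ⇒ *no_match*;
otherwise *known* when global precursor identity **and** positivity both
exceed 90%, else *novel*. Region identities (precursor/prepro/mature) come
from global alignments of the corresponding region pairs. The reference is
a user-supplied precursor FASTA split by the same last-KR rule — a
deliberate replacement of any remote database search, so results are
reproducible from local inputs.

## Expression quantification

Counts are normalized per sample to `count / sample_total × 10⁸`; the
scale is configurable (captions elsewhere sometimes describe such values
"per million" — the constant here follows the stated normalization rule,
and nothing downstream depends on its absolute size). Per feature and
group the summary is the median and MAD of normalized counts; "detected"
means at least one nonzero raw count in the group, inventing no threshold.

Treatment contrasts report the ratio of group medians (treated/control; a
feature absent from control but present after treatment is flagged
"appeared", 0/0 is "undefined") and a two-sided **exact mid-p rank-sum
test** at α = 0.05 with no multiplicity correction. The mid-p convention
(half weight on the observed U) is used because at n = 5 vs 5 the plain
exact test is so discrete that its attainable type-I error at 0.05 is only
8/252 ≈ 0.032 and midrank ties push the realized rate below 0.03, whereas
the mid-p variant attains 14/252 ≈ 0.056 — near-nominal calibration, which
the test suite verifies over 2,000 simulated null features. The exact null
distribution of U is computed from the classic count recurrence and
cached. No test is run with fewer than 3 samples per group (p is reported
as missing and the contrast is never significant).

## Gene models

The mapper assumes transcript and genome derive from the same population,
so near-exact identity is expected: exact k-mer seeding (k = 31, both
genome strands), merging of seeds into diagonal runs, and quadratic DP
chaining that maximises matched bases over colinear runs (overlaps, which
arise at ambiguous junctions, are counted once and trimmed from the later
run). Genome-side gaps ≥ 40 bp — the smallest credible spliceosomal
intron — open introns; smaller gaps are absorbed into exons as internal
indels. Exon junctions are then shifted by up to ±5 bp, when the moved
bases are identical on both sides (transcript sequence preserved), to
place introns at GT..AG; candidate shifts are tried closest-first with
ties leftmost on the + strand, and introns with no admissible canonical
placement keep their coordinates and are flagged. Minus-strand models
store transcript coordinates on the reverse-complemented transcript so
exons ascend on both axes, and donor/acceptor dinucleotides are reported
on the gene's strand. Transcripts matching several scaffolds produce
partial models per scaffold and are never stitched.

## Synthetic data

Generators are pure functions of spec + seed, and every generator returns
ground truth sufficient to score the downstream stage:

* **Precursor transcripts** — protein = start residue (M/V) + random
  neutral prepro + KR + mature with an exact planted count of basic and
  acidic residues (rejection-sampled to contain no internal K-R, so the
  last-KR split is unambiguous); back-translated with uniform synonymous
  codons (codon bias is irrelevant to every stage under test), embedded in
  random UTRs with an in-frame stop just upstream of the CDS so the
  planted ORF is also the maximal one. Defaults: mature 19–33 residues,
  net cationic.
* **Decoys** — i.i.d. uniform-base transcripts, rejection-sampled so none
  contains a complete 20–100 aa M/V-start ORF with a KR site and cationic
  mature part.
* **Toy profiles** — match state i emits its consensus residue with
  probability `conservation`, the rest uniform; m→m = 0.9. Deterministic.
* **Genomes** — 1–4 exons cut from a transcript, GT..AG introns ≥ 60 bp,
  random flanks; minus-strand genes are reverse-complemented into the
  scaffold.
* **Counts** — negative binomial with var = μ + dispersion·μ², defaults
  μ = 100, dispersion 0.1, two groups; a declared subset of features
  carries a fold effect.

What passing tests on these data do **not** show: recovery under
sequencing error, assembly fragmentation or polymorphism (the mapper's
exact seeding assumes near-identity), performance against real profile
libraries with informative insert states, or calibration under
correlated/compositional expression effects (a large planted fraction
shifts the totals that normalization divides by).

## Problem sizes in the test suite

The bundled verification runs at desk scale: 5 planted precursors among
500 decoys for end-to-end recovery, 50 synthetic single-gene genomes for
gene-model recovery, 2,000 null features for test calibration, exhaustive
oracles at ≤ 3 match states / ≤ 4 residues and alignment pairs ≤ 12
residues. These sizes exercise every code path while keeping the full
suite around half a minute.

## Known limitations

* Identity/positivity conventions (gap columns in the denominator) are one
  of several reasonable definitions; percentages from other aligners will
  differ on gapped alignments.
* The shuffle-null E-value is exchangeable for unrelated pairs, so its
  distribution under the null is approximately uniform — it separates true
  matches by tens of orders of magnitude but is not a calibrated tail
  probability beyond the fitted decile.
* The spliced mapper is not a general aligner: no mismatch tolerance
  within seeds, no splice-graph or isoform reasoning.
* pI and mass ignore disulfide bonds and post-translational modification.
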