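# Methods

`kunitzkit` reimplements, as a tested pipeline, the comparative analysis of
the Kunitz/BPTI gene family in the hard tick *Ixodes scapularis*: detecting
and classifying Kunitz domains from protein sequence, annotating their
protease-inhibitor and ion-channel functional sites, quantifying
stage-specific expression from EST libraries, building neighbor-joining
trees, and testing for positive selection with codon site models.  Every
stage can run offline on synthetic inputs whose statistical structure
matches the assumptions of the corresponding analysis.

## Domain detection and classification

A Kunitz/BPTI domain is identified purely by its six conserved cysteines
(disulfide-bonded 1-6, 2-4, 3-5) and the spacing between them.  The three
groups of tick single-domain proteins are defined by the spacings

| group | pattern |
|-------|---------|
| I   | C X(8) C X(15) C X(7) C X(12) C X(3) C (canonical, BPTI-like) |
| II  | C X(8) C X(18) C X(5) C X(12) C X(3) C |
| III | C X(5,6) C X(15) C X(8) C X(11) C X(3) C |

Detection scans windows of six consecutive cysteines left to right and
accepts a window whose spacing vector is within a per-gap tolerance
(default ±2) of any reference; accepted windows consume their cysteines
(greedy leftmost, so domains never overlap).  Classification assigns the
group minimizing the L1 distance between spacing vectors, requiring
distance ≤ 3 for a fuzzy match; exact matches are flagged, ties and larger
distances are `unclassified`.  The tolerance and L1 budget are deliberately
small — real tick sequences contain "exception" spacings, and a bounded
window keeps false merges rare while the flags make fuzzy calls auditable.
Note that group membership in the original analysis was ultimately a tree
clade; a pattern-only classifier can disagree on exception sequences, which
is why `exact_match` is carried through the output.

Multi-domain proteins are decomposed into single-domain segments spanning
from 5 residues before C1 through 2 residues after C6 (clamped at sequence
ends).  The margins are padding for the downstream motif checks; the P1
site needs only the residue after C2, so the margins are safe.  Architecture
labels (`One-KU` … `Seven-KU`) are derived from the domain count; more than
seven triggers a warning but still labels by count.  Signal-peptide status
is carried as input metadata and never predicted.  `domain_coding_length`
is the trivial 3 nt/residue arithmetic connecting the ~60-aa domain to its
~180-bp exon.

## Functional sites

* **P1 site** — the residue immediately after C2 (Lys15 in BPTI); it
  determines protease specificity.
* **Inhibitor motif** — trypsin inhibitors: P1 ∈ {K, R} followed by a small
  residue; chymotrypsin inhibitors: P1 ∈ {F, L, N, Y} followed by a small
  residue.  The "small" set is not enumerated in the source literature; we
  use the standard convention {G, A, S, C, T} and expose it as a parameter.
* **Channel-modulating elements** — a basic residue (R/K) close to a
  hydrophobic partner (L/Y/F) in the "base" of the fold.  The base is
  operationalized as [C4−3, C6]: the structural correlate (3₁₀ helix and
  β-turn) occupies the C-terminal third of the domain, and sequence
  coordinates for it are not published.  "Close" means within 6 positions —
  calibrated so that both published evidence pairs (R-34/F-28 and
  R-50/Y-44, each 6 apart) qualify; detection is monotone in the window.
  Sequences carrying Q in place of the basic residue are negative, matching
  the published negative examples.  Structural confirmation (helix/turn
  conformation) is out of scope; this is a sequence-level proxy.

## EST differential expression

For counts x_j in libraries of sizes N_j the heterogeneity statistic is

    R = Σ_j x_j ln( x_j / (N_j f) ),   f = Σ x_j / Σ N_j

with natural log and 0·ln 0 := 0.  R is a log-likelihood-ratio statistic:
0 under exact proportionality, x_j·ln(ΣN/N_j) when a gene is expressed in a
single library.  Because the statistic's reference method only states a
believability threshold, the calibration is defined explicitly here:
simulate `n_sim` (default 1000) null datasets in which each gene's total is
redistributed multinomially with probabilities N_j/ΣN, and report

    believability(c) = 100 · max(0, 1 − E[null genes with R ≥ c] / observed genes with R ≥ c)

(100 when no null exceedance is ever seen; 0 by convention when no observed
gene reaches the cutoff).  Significance uses R ≥ 9 and believability ≥ 99%.
Stage patterns over the four feeding stages (unfed, 6–12 h, 18–24 h, 72 h):
*pattern 1* is silence until the final stage; *pattern 2* starts at stage 2,
peaks strictly at stage 3 and collapses below 10% of the peak at stage 4
("decreases rapidly" quantified to match the observed 2/259; configurable).
Count tables are TSV with a mandatory `TOTAL` row because the library sizes
are not part of the per-gene table in the source data; this keeps the
artifact self-contained.

## Phylogenetics

Distances between aligned proteins are p-distances over pairwise-shared
ungapped columns (gaps and X excluded per pair), optionally
Poisson-corrected (d = −ln(1−p)); saturated pairs (p = 1) are an error
under the correction.  Neighbor joining follows the Saitou–Nei
rate-corrected criterion with two conventions chosen for determinism and
robustness: the minimal-Q pair is the lowest (i, j) in row-major order, and
a negative pendant branch is clamped to zero with the deficit transferred
to its sibling (preserving the pair's summed length).  The output is an
unrooted tree with a trifurcating root.  On additive matrices NJ provably
recovers the generating tree; the suite verifies this exactly and checks
the topology against an exhaustive least-squares oracle at 4–5 taxa and an
independent NJ implementation.  Bootstrap support is the Felsenstein column
bootstrap; replicates whose resampled distances are undefined are dropped
and support is relative to completed replicates.  The original study's
distance settings are unstated, so these defaults are documented rather
than claimed identical; Bayesian and ML tree inference are out of scope —
NJ supplies the topology the selection stage needs.

## Codon models and selection tests

The GY94 generator over the 61 sense codons assigns rate κ^(ts) · ω^(nonsyn)
· π_j to single-nucleotide changes and 0 otherwise, scaled to one expected
substitution per codon per unit branch length.  Codon frequencies come from
the alignment (equal, F1x4 or F3x4; F3x4 default).  Site models: M0 (one
ω), M1a (ω0 < 1, ω1 = 1), M2a (adds ω2 > 1), M3 (three free classes), M7
(Beta(p, q) discretized into 10 equal-probability categories by category
mean), M8 (M7 plus a class ω_s > 1).  Likelihoods use Felsenstein pruning
with per-node scaling; gap codons are fully ambiguous (partial likelihood 1
over all codons).  Since the generator is reversible, each class needs one
symmetric eigendecomposition, after which every branch's P(t) is cheap.

Fitting maximizes the mixture likelihood with bounded L-BFGS-B on
transformed parameters (κ ∈ [0.01, 100], ω ∈ [10⁻⁴, 50], proportions via
stick-breaking logits) and multiple starts with distinct initial ω
(default 3).  Branch lengths are optimized jointly under M0 and then held
fixed for the other models — this controls cost and mirrors common
practice; it is configurable.  Alternatives of nested pairs additionally
start from the null MLE embedded in their parameter space, which enforces
the nesting inequality; if an alternative still lands below its null
(the boundary case p₂ → 0 that a logistic transform cannot reach), the
exact boundary embedding is evaluated and kept when better.  Identical
sequences are flagged non-identifiable rather than rejected.

Nested pairs are compared by 2ΔL against chi-square: df 4 for M0 vs M3
(1% critical value 13.28), df 2 for M1a vs M2a and M7 vs M8 (critical
value 9.21).  These thresholds are conservative for the boundary mixture
null; the suite verifies the empirical type-I rate stays well under the
nominal level.  Tiny negative 2ΔL (> −10⁻⁶) is clamped to zero; anything
more negative is reported as an optimization failure.

Sites are assigned to classes by naive empirical Bayes (NEB) at the MLEs,
or Bayes empirical Bayes (BEB), which averages the per-site posterior over
a uniform discrete grid (10 points per free class parameter: the (p0, p1)
triangle and ω0 ∈ (0,1), ω2 ∈ (1,11) for M2a; p0, the beta shapes on a
geometric grid in [0.1, 10], and ω_s ∈ (1,11) for M8) with κ and branch
lengths fixed at their MLEs.  Sites with posterior mass > 0.95 on the
ω > 1 class are called positive.  BEB is noticeably more conservative than
NEB at the 0.95 threshold on simulated data — the grid forces prior mass
onto configurations with a smaller positive-class proportion — while the
ranking of sites is essentially shared; the suite therefore checks recall
against NEB and ranking for both.

The Nei–Gojobori counting method (equal pathway weighting, stop-codon
pathways excluded, Jukes–Cantor correction, synonymous-site fractions
computed over sense changes only) provides a model-free dN/dS cross-check;
it is never used as the estimator for the site models.

## Synthetic data

The generators invert the analyses they feed:

* **Proteins** — cysteines placed at exact group spacings; non-cysteine
  positions uniform over the 19 non-C residues; optional trypsin or
  chymotrypsin P1 motifs, channel-element pairs (or their Q-variant
  negatives), an 18-residue signal-peptide-like prefix, 8–15-residue
  linkers between 1–7 concatenated domains.
* **Codon alignments** — per site a class from the mixture, a root codon
  from π, and exact matrix-exponential transition sampling along each
  branch (so simulation and likelihood share the same P(t) by
  construction).  True site classes are returned for recovery tests.
* **EST counts** — null genes redistribute their totals multinomially by
  library size; differential genes follow a stage profile (default the
  mid-feeding burst shape 0/0.06/0.93/0.01); truth flags are returned.

One integer seed feeds named per-operation substreams, so adding a
generator never perturbs existing fixtures, and identical requests are
byte-identical.  What the generators do **not** emulate: realistic
signal-peptide composition, indels within domains, alignment error,
EST sampling biases beyond multinomial, or rate variation beyond the
site-class mixtures — so green tests demonstrate correctness of the
machinery under its own model, not robustness to real-data violations.

## Problem sizes and numerical choices

Simulation-based checks use deliberately modest sizes chosen as a
reasonable power/runtime trade-off: type-I calibration uses 100 replicates
of 5 taxa × 150 codons; M0 recovery 20 replicates of 8 taxa × 500 codons;
site-posterior recovery one 8-taxon × 600-codon alignment with 20% of sites
at ω = 5 on a tree of ~6 expected substitutions per codon (site posteriors
need divergence to accumulate per-site evidence).  Branch lengths for these
experiments are estimated under M0, not taken from the truth.  Degenerate
inputs are defined rather than left to chance: all-zero count vectors are
an error for R (0 for a whole matrix row in batch calls), equal-distance
NJ ties resolve to the lowest index pair, ω = 0 and identical-sequence
likelihoods are exact limits, and p ≥ 3/4 leaves the Jukes–Cantor
correction undefined (reported as NaN with proportions intact).

## Known limitations

* Group labels are spacing-based; clade-based labels can differ for
  exception sequences.
* The believability estimator is this package's explicit construction of a
  threshold that the source analysis states without procedural detail.
* BEB here integrates over class parameters only (not branch lengths or κ)
  and is conservative at high posterior thresholds.
* No saturation diagnostics; heavily saturated alignments will show it as
  poor model fit, not as a dedicated test.
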