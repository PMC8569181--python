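# Methods

## Coordinates, ordinals and the "ORF" unit

All intervals are stored 0-based half-open internally; GFF3 I/O converts
from/to 1-based inclusive, and every position shown to users is 1-based.
Within each replicon, CDS features (and only CDS — tRNA/rRNA are excluded,
and pseudogenes annotated as CDS are counted) are ranked by start, with ties
broken by end and then gene id, giving ordinals 0..N−1. These ordinals are
the "ORF" unit of both the cluster-adjacency rule and the 30-ORF
restriction–modification distance. Coverage of a homology hit is *query*
coverage (`aln_length/qlen`, or `qcovhsp/100` when supplied), matching the
qcovhsp convention of DIAMOND; a 12-column tabular file without `qlen` or
`qcovhsp` is rejected because query coverage is underivable from it.

## Cluster calling

A cluster type (dndCD, dndBCDE, dndFGH) is called when one assigned gene per
required family lies in a window of consecutive ordinals with at most
`max_gap` intervening non-member CDS (default 0: strictly adjacent). Member
order and strand are unconstrained — natural dnd operons occur in varied
configurations — and a window containing a family twice is invalid, so valid
windows can never nest and greedy left-to-right selection of non-overlapping
windows is canonical. Cluster types are called independently: the adjacent
C–D core inside a dndBCDE run is also reported as a dndCD call, which is the
reading under which dndCD occurrence is the modification system's minimal
core (always ≥ dndBCDE occurrence). On circular replicons the ordinal
sequence wraps and spans may cross the origin.

The restriction component dndFGH is "R-M linked" when a dndCD or dndBCDE
call lies on the same replicon with ordinal distance ≤ 30 between the
nearest span ends (adjacent spans are at distance 1; the boundary 30 is
inclusive; circular replicons take the shorter direction). Linkage is
reported as a separate per-genome flag rather than gating the dndFGH
presence flag, so users can apply either convention.

## Majority-rules prophage taxonomy

Each protein of a region votes through its best hit with bitscore ≥ 50;
equal-best hits to different families abstain. The vote denominator is the
full protein complement of the region (not just proteins with hits), so
poorly annotated regions stay unclassified. A family wins at vote fraction
≥ 0.5; with that threshold at most two families can reach it, and an exact
tie is deliberately left unclassified rather than broken arbitrarily. Note
one consequence: raising the bitscore bar usually cannot classify an
unclassified region, but it *can* break an exact 0.5/0.5 tie by silencing
one side; the property tests assert the monotone form away from the
boundary.

## Association statistics

Across taxa, each genus (default: ≥ 100 genomes) or species (≥ 30)
contributes one occurrence fraction per feature; dnd occurrence is regressed
on prophage occurrence by OLS and the Pearson r is tested against the t
distribution with n−2 df. The "significant negative" label requires all of
R² > 0.5, p < 0.001 and r < −0.7 — an intentionally conservative evidence
bar. R² equals r² for this simple regression, so the label is orientation-
symmetric; the slope is reported for the stated orientation.

Within a taxon, per-genome counts are ordinal, zero-inflated and heavily
tied, so association uses Kendall τ-b with tie correction. The two-sided
p-value is computed by exact enumeration over all permutations of one vector
for n ≤ 10 (tie structure is permutation-invariant, so the comparison on the
S statistic is exact) and otherwise by the tie-corrected normal
approximation for S with a ±1 continuity correction. Simulation places the
empirical type-I error at n = 200 within the 99% binomial interval of the
nominal 0.05. Raw p-values are reported; BH adjustment is available but off
by default, matching the practice of reporting per-(taxon, feature) raw
significance. A (taxon, feature) pair is flagged "statistically
unachievable" when the taxon has < 30 genomes or the feature (or prophage)
is entirely absent from it.

## PT motif accounting

The PT consensus GAAC/GTTC is a double-stranded pseudo-palindrome: every
reference-strand GAAC faces a GTTC on the complement. Motif totals are
therefore exposed under three conventions — per class on the reference
strand, per class over both strands, and one count per double-stranded pair
— and `convention_report` evaluates a set of modified-site counts under all
three, because published percentages do not always state their denominator.
The package's default reading takes per-class reference-strand totals, which
makes the GAAC and GTTC denominators independent. Frequencies are
`count/denominator × 10⁶` per nt; per-molecule counts use 2L nt for a
double-stranded molecule of length L. Site-to-gene mapping assigns a site to
*every* CDS whose interval contains it (overlapping genes each count it),
with boundary positions inclusive.

## Competition fitness model

The assay model: each day the mixed culture is diluted 1:D into fresh medium
and regrows to the same stationary density, so the total per-transfer
expansion equals D and a strain moving from fraction f_i to f_j over n
transfers realized `log2(f_j · Dⁿ / f_i)` doublings. W is the ratio of the
two strains' doublings (reference/test by default, so W > 1 reports a cost
of the test strain's modification). Under this model the published fraction
trajectory (52% → 48% → 31%) reproduces the published W values to < 0.3%,
which we take as validation of the full-regrowth assumption. Doublings are
interval-additive and W is label-swap antisymmetric (W(A,B)·W(B,A) = 1);
fractions of exactly 0 or 1 (extinction/fixation in the colony sample) are
errors rather than imputed.

## Synthetic data: what it emulates and what it does not

The panel generator plants dnd clusters as adjacent runs (shuffled member
order) at configurable prevalence (default 0.18 in a 500-genome genus, a
well-sampled-genus scale) and draws prophage counts from
`Poisson(λ · exp(β·I[dnd]))` with λ = 2 and β = −1.5 by default — the
simplest generative mechanism producing a negative rank correlation, chosen
as a modelling device rather than a mechanistic claim. Hit tables draw true
hits safely inside the detection thresholds (e ≤ 1e-12, qcov ≥ 0.6) and
decoys that fail at least one threshold, so planted-truth recovery is exact
by construction; this validates the filtering logic, not the behaviour on
borderline real alignments. Motif-planted sequences scrub accidental
GAAC/GTTC by iterative resampling so scans recover exactly the planted loci.
The competition generator inverts the doubling model for a target W
per-transfer (root-finding on the daily fraction map) and adds binomial
colony sampling (100 colonies/day by default). Consequently, passing tests
demonstrate correctness of the rules and estimators under the assumed
generative models — they say nothing about annotation quality, prophage
prediction accuracy, or phylogenetic non-independence in real panels
(phylogenetically corrected association tests are out of scope).

Every generator is a pure function of (parameters, seed); genome
materialisation uses a separate derived stream so truth tables are identical
whether or not full genome records are built (`include_genomes=False` is
used for 1,000-replicate calibration studies).

## Numerical choices and problem sizes

Detection tie-breaks: higher bitscore, then lower e-value, then
lexicographic family; output ordering is deterministic by (genome, replicon,
ordinal). The e-value threshold is strict (<) and coverage inclusive (≥), so
a hit at exactly 1e-10 is excluded and one at exactly 50% coverage is kept.
Zero-variance inputs yield `not_computable` results rather than NaN
surprises; a pooled t-test on constant equal samples returns p = 1, on
constant unequal samples raises. Calibration and recovery studies in the
test suite use 200–500 genomes per panel, 200–1,000 replicates, and toy
genomes of ≤ 50 genes against exhaustive oracles — sizes chosen so the whole
suite completes in a couple of minutes while keeping binomial confidence
intervals tight enough to be informative.

## Known limitations

* Detection starts from precomputed homology hits; running BLAST/DIAMOND and
  HMM-based detection are out of scope, as are prophage boundary prediction
  and phylogenetic tree construction.
* The within-taxon exact p-value enumerates n! permutations and is limited
  to n ≤ 10; beyond that the normal approximation is used.
* The dndCD-inside-dndBCDE reading and the exact-tie-unclassified rule are
  conventions where the underlying rules are ambiguous; both are exposed or
  documented rather than hidden.
* The modified-motif percentage analysis requires the target chromosome
  sequence; the package ships only the convention machinery and synthetic
  stand-ins, not reference genomes.
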