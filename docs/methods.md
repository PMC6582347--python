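# Methods

## Coordinates and orientation conventions

Genomic coordinates are 1-based and inclusive on the Watson reference
strand. Dyad-relative coordinates are signed integers with the dyad at 0, so
a nucleosome's protected span reads [−72, +72] and a region swap reads
"−45..−23 with 23..45". All per-gene analyses are *gene-oriented*: upstream
means towards the promoter. Particle tables on disk may carry tag totals in
genomic orientation (the default) or gene orientation; the reader flips the
upstream/downstream columns of Crick-strand genes at load time so that
in-memory records are always gene-oriented. Sequence windows around Crick
dyads are reverse complemented for the same reason. Tag totals are reals,
not integers, so depth-normalized tracks are accepted unchanged.

## Orientation calling

A side call compares one histone's upstream and downstream tag totals summed
over a 74-bp half-window on either side of the dyad: *asymmetric* towards
the larger side when it is ≥ `fold_asym` (default 2.0) times the smaller,
*symmetric* when the two are within `fold_sym` (default 1.3) of each other,
otherwise indeterminate. Both boundaries are inclusive ("at least 2-fold" is
≥, "within 1.3-fold" is ≤); ties therefore resolve towards a call rather
than towards indeterminacy. A (0, 0) pair is indeterminate; a single zero
with a nonzero partner is asymmetric, i.e. the ratio is treated as +∞ — the
choice is flagged in the output because zero-count halves are not otherwise
distinguishable from missing data.

A particle is an oriented hexasome when H2B is asymmetric and H4 symmetric,
a nucleosome when both are symmetric, and excluded when H4 is asymmetric
(strict mode, the default: an H4-asymmetric particle more plausibly reflects
a mispositioned or weakly positioned particle than dimer loss). Relaxed mode
skips the H4 condition entirely, which raises power at the cost of admitting
those artifacts; the adjacent-particle correlation analysis is meant to be
run in both modes. H2A and H3 totals are carried but unused by default; a
config switch makes H2A a second heterodimer reporter whose side call must
agree with H2B.

## Positional sequence statistics

Per-position symbol probabilities are computed over equal-length,
dyad-centred windows; windows containing N are dropped (and counted), not
imputed. A dinucleotide "at position i" starts at i (bases i and i+1), so
the dinucleotide grid is [−W, W−1]; this start-anchored convention is
recorded in output headers since the alternative (centre-anchored) is
equally defensible. Ratio profiles divide one class's distribution by
another's; 0/0 is flagged undefined and x/0 flagged infinite, and both are
excluded from testing.

The block t-tests tile positions ±1..±70 — the dyad base excluded — into 14
contiguous groups of 10, which makes the 14 × 10 grid exact within the 74-bp
half-window; each block's ratios are tested two-sided against 1.0 and
Bonferroni-corrected with factor 14 × (number of symbols) = 56 for
nucleotides. The factor is written into the result metadata so an auditor
can rescale to a different family definition (e.g. pooling mono- and
dinucleotide tests). A zero-variance block has p defined as 1 when its
common value is exactly 1 and 0 otherwise, with a degenerate flag — a
convention, applied only to pathological inputs. Association tests are plain
Pearson chi-squared without continuity correction; the per-gene-index test
compares each index's orientation counts against proportions pooled over all
three indices, so its null is composite and its p-values are conservative
rather than exactly uniform.

## Motif scanning and asymmetry

Scores are log2 odds against a background with a background-proportional
pseudocount (default 0.001): score(i, b) = log2((p + pc·bg_b)/((1+pc)·bg_b)).
The default background is uniform; a 0-order background estimated from the
scanned windows is available. The null distribution of a random background
word's score is computed exactly: for widths ≤ 10 by dictionary convolution
over the distinct attainable score sums (merged on a 1e-9 grid), beyond that
by a lattice DP with 10,000 bins. All score comparisons use a 1e-6 slack —
far above the ≤ width·5e-10 merge drift and far below the spacing of
distinct score levels — so hit p-values and thresholds are the exact tail
probabilities of the (possibly discretized) null. A requested significance
below the probability of the single best word returns the maximum score with
a warning.

Occurrences are counted per window (multiple hits per window allowed, both
strands when requested, default per-hit cutoff 1e-4 as the conventional
scanner default, exposed as a flag). A hit is upstream/downstream by the
side of the dyad its midpoint falls on; exact-centre midpoints are dropped
from both halves but reported. The up/down split is tested with the exact
two-sided binomial test (null 0.5, summing outcomes no more probable than
the observed one). A significantly asymmetric motif is *weak-binding* when
enriched on the dimer-absent half of the oriented set it was counted in and
*strong-binding* when enriched on the dimer-present half. De novo motif
discovery and motif–motif similarity filtering are out of scope: motifs
arrive as MEME-minimal PFMs and similarity-based exclusion is replaced by a
caller-supplied exclusion list.

## Sequence design

Chimeras are built by interchanging two equal-length, non-overlapping
regions, each replaced by the reverse complement of the other; the operation
is an involution and preserves length. Dinucleotide-level swaps are
expressed as lists of small interchanges with coordinates supplied by
config. Biasing-sequence design draws `n_candidates` (default 10,000)
region replacements independently per position from a supplied frequency
profile, scores each candidate's replaced region against the motif set on
both strands, ranks by best exact hit p-value with a lexicographic sequence
tie-break (so the ranking is independent of generation order), and retains
candidates with p < 1e-5. The full ranked table is returned; how many to
carry forward (e.g. two per motif) is left to the caller.

## Footprint model

Two empirical parameters: `nuc_half` (default 72 bp — taken directly as the
observed stall offset, with no claim about whether the enzyme stops at or
one base outside the 147-bp core) and `distal_unwrap` (default 40 bp, which
places the hexasome's dimer-distal stall at 72 − 40 = +32). Nucleosomes
protect [−nuc_half, +nuc_half]; hexasomes lose `distal_unwrap` on the
dimer-distal side; tetrasomes lose it on both sides and are labeled an
extrapolation of the model, since no tetrasome footprint was measured here.
ExoIII digests 3′→5′, so each strand's stall is the footprint edge first met
from that strand's 3′ end and the surviving 5′-labeled fragment runs from
the label to the stall (stall base included). Mixed populations contribute
their fraction at each footprint edge; digestion kinetics, partial-digestion
smearing and gel mobility are out of scope.

## Fluorescence and kinetics

The (ratio)_A efficiency is E = n_acc·(ε^A₆₁₀·F^A₅₁₀/F^A₆₁₀ − ε^A₅₁₀) /
(ε^D₅₁₀·d⁺) with n_acc = 2 by default (two acceptors per donor; a config
parameter). PIFE is (F^A/F^D) normalized to 1 at zero TF. The printed
acceptor-over-donor ratio runs opposite to the usual donor-enhancement
convention for a Cy3 PIFE reporter; the implementation computes it as
printed and offers an `invert` flag rather than silently resolving the
discrepancy.

The isotherm fit is unweighted least squares with data-driven initialization
(E₀ from the lowest concentration, E_F from the highest, S½ from the point
nearest half-signal) and covariance-based standard errors; an S½ outside the
measured range is flagged, not rejected.

Trace segmentation is a per-trace two-state Gaussian HMM fit by EM from a
deterministic quartile initialization and decoded by the most probable
path. This deliberately replaces a variational-Bayes HMM: the analysis is
explicitly two-state, so model selection over state count buys nothing, and
the scientific content downstream is the dwell-time statistics, not the
segmentation engine. Traces whose fitted means are closer than 0.1 FRET
units, or that never leave one decoded state, are flagged single-state and
excluded from dwell tabulation; traces are truncated at their photobleach
index first.

Dwells are run lengths × dt. The first and last dwell of every trace are
censored (their true extent is unobserved) and excluded from rate fits by
default; this is exposed as the `usable_*` accessors. Each state's usable
dwells are fit by least squares to N(t) = N_tot·(1 − exp(−k·t)) with the
empirical cumulative evaluated at every observed dwell (no histogram
binning); the MLE 1/mean is reported as a cross-check, and a fit is flagged
non-exponential when the sup deviation exceeds 10% of the sample or the two
estimators disagree by more than 50%. k_on is the slope of an unweighted,
unconstrained line through the unbound-state exit rates versus
concentration (the intercept is reported so a through-origin fit can be
judged); k_off is the mean of the bound-state exit rates with its standard
error. Dwells shorter than one frame (0.2 s at 5 Hz) are invisible, which
biases rates by a few percent at the rate scales studied here; no correction
is applied because the raw acquisition conditions are part of the model.

## Synthetic data: what it emulates and what it does not

The cohort generator lays out non-overlapping genes on one synthetic
chromosome, three particles per gene at 165-bp spacing, with i.i.d. uniform
sequence. Tag noise is Poisson per histone half (the source data state no
noise model; Poisson is the minimal counting model), with a
negative-binomial switch for overdispersion robustness checks. Hexasomes
get H2A/H2B means multiplied by the asymmetry factor (default 3) on the
dimer-present side; H4 is symmetric throughout. Crick genes store flipped
tag columns on disk so the reader's orientation conversion is exercised.
What is *not* emulated: MNase/ChIP-exo read-level biases, dyad-calling
error, linker variation, nucleosome-free regions and real genome
composition — so passing recovery tests demonstrates the correctness of the
classification and statistics code under the stated noise model, not
performance on real chromatin data.

The sequence-bias generator plants a C/G enrichment of `delta` (total
probability shifted, default 0.08) on the dimer-present half and the mirror
A/T enrichment on the absent half, plus an optional motif consensus inserted
at a uniform offset within one half. Traces are continuous-time two-state
telegraph processes (unbound→bound at k_on·[TF], bound→unbound at k_off)
sampled at the frame instants, with Gaussian observation noise (sd 0.1
about means 0.7/0.2) and exponential photobleaching (default 0.001 s⁻¹).
All generators are pure functions of spec + seed.

## Problem sizes used by the checks

The quantitative checks run at sizes chosen to give comfortable statistical
margins while staying quick on a laptop: orientation recovery on a
2001-particle cohort (667 genes, depth 500, asymmetry 3); composition-bias
detection on 1500 windows per class at delta 0.08; motif recovery on 400
windows at 30% insertion; kinetics on 200/70/16 traces at 3/10/100 nM, which
yields ≥ 700 usable dwells per state at every concentration under the 5 Hz /
400 s acquisition with photobleaching. The caller's rule-table equivalence is
exhaustive over all integer tag quadruples in [0, 20]⁴, and the PWM null DP
is checked against full enumeration for all widths ≤ 6.

## Known limitations

Genome-scale analyses (the published orientation-by-position and
adjacent-particle p-values, genome-wide ratio curves, discovered motifs)
require the original supplementary tables and reference genome; the package
ingests them when supplied but does not bundle them. The segmentation
assumes two Gaussian emission states and will mislabel multi-state or
drifting traces; the isotherm is strictly non-cooperative; the footprint
model is deterministic and ignores enzyme kinetics; PWM scanning uses a
0-order background only.
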