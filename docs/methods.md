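# Methods

This note documents the models, conventions and numerical choices behind the
package, what the synthetic-data generator does and does not emulate, and the
design decisions taken where more than one reasonable construction exists.

## Coordinates and interval algebra

All genomic coordinates are 0-based half-open (BED convention); 1-based
display is conversion-at-the-edge only. Annotation categories are normalized
`FeatureTrack`s: sorted, non-overlapping intervals with touching intervals
(end == start) merged, so every base is covered at most once and a track's
covered bp is an unambiguous exposure measure. Insertion "sites" reported by
callers are stored as 1-bp intervals at the reported TA position, giving
point calls and spans one uniform algebra. Strand is carried through I/O but
ignored by interval operations; strand policy is a motif-level concern.
Subtraction is exact set difference (bases in A and not B), used to build
intron-exclusive space so a site inside an exon of any transcript is never
counted intronic.

## Insertion-point convention and motif handling

Tc1 inserts at a TA dinucleotide; we store the 0-based coordinate of the T,
and flank extraction centers on the T|A boundary: column −1 of a flank matrix
is the T, column +1 the A, so the ±k matrix is symmetric around the
biologically defined duplication site. Sites within k of a contig edge are
excluded and counted rather than padded.

Motif scanning matches per-position IUPAC base sets at every offset (step 1,
overlapping matches all reported). Ambiguity codes in the *scanned sequence*
(assembly N runs) never match any motif position, including N — conservative
counting on real assemblies. The default genome-scan motif is the 8-mer
AYATATRT on the forward strand only: the motif is its own reverse complement,
so both-strand scanning is redundant; a `both_dedup` policy exists for
non-palindromic motifs and reports each genomic footprint once.

Consensus derivation thresholds per-position base frequencies: a base enters
the IUPAC set when its frequency ≥ 0.2 (default). At a ~50/50 position this
yields two-base codes (Y, R) while suppressing minor-allele noise; at
threshold > 0.25 a uniform position could produce an empty set, rendered N.
The center two positions are rendered as the invariant TA. The 0.2 default is
a package choice; recovery of a planted AYATATRT from ≥ 300 simulated sites
is exact in the seeded tests.

## Multi-caller consensus windows

Callers disagree on exact breakpoints, so agreement is assessed on windows:
nonreference calls on 1,000-bp windows, reference elements (which span
several kb) on 100,000-bp windows, with window index = floor(position /
window size) and spanning calls assigned to every window they touch. The two
window sets are pooled into one universe per strain, keyed by (kind,
chromosome, index) so a 1-kb and a 100-kb window with the same index never
collide. A caller contributing several calls to one window counts once;
"unique calls" for a strain means unique pooled windows. Support fractions
are reported as whole percents with half-up rounding.

Copy-number summaries pool the per-caller call counts with the
coverage-based estimate (element mean depth / genome mean depth) into
range/mean/median; the median of an even-length pool is the mean of the
middle two values, and display rounding is half-up (451.5 → 452). When a
caller provides no estimate (reference strains for callers that do not call
reference elements) the summary simply pools the available values.

## ddPCR model

λ = −ln((total − positives)/total) per well; a fully positive well is
saturated and rejected. Copy number is (λ_target/λ_reference) × D, with the
dilution factor D applied multiplicatively on the ratio — algebraically
equivalent to dividing reference positives by D before the Poisson step, but
a single formula. The 95% interval is a delta-method interval on log CN using
per-well Var(λ̂) = p/((1−p)n); simulated coverage of the interval is ≥ 90%
at the default design (λ_ref = 0.5, CN = 600, D = 100, 20,000 droplets).
Droplet gating (fluorescence thresholds) is out of scope; inputs are
already-classified counts.

## Enrichment statistics

Expected counts are proportional to exposure: category length in covered bp,
or the number of integration-motif sites per category. The contrast matters
because the A/T-rich Tc1 consensus is itself unevenly distributed: a category
can look enriched per bp yet be exactly as expected per available insertion
site. χ² goodness of fit uses df = k − 1 with no continuity correction
(expected cells < 5 warn rather than fail); the G-test is
2 Σ O ln(O/E) with margin-based E and zero cells contributing zero; Fisher's
exact test is two-sided by the point-probability rule; Holm–Bonferroni is the
step-down adjustment with monotonicity enforcement, capped at 1. One
adjustment family = the set of strains tested for one category system.
p-values are displayed capped at 1.

No spatial-autocorrelation correction is applied: Tc1 preferentially
transposes to sites near existing copies, which violates independence of
counts; this is acknowledged, not modeled.

## Nested ANOVA

The fitness design is strains (fixed treatments) / lines (random) / sublines
(one observation each), with unequal line and subline counts. Sums of squares
use the hierarchical-means decomposition; with groups i, subgroups j,
cell sizes n_ij, group totals N_i, grand total N, B = Σ b_i:

    n0′ = [N − Σ_i (Σ_j n_ij²)/N_i] / (B − a)
    nb0 = [Σ_i (Σ_j n_ij²)/N_i − (Σ n_ij²)/N] / (a − 1)
    n0  = [N − (Σ N_i²)/N] / (a − 1)

E[MS_lines] = σ²_e + n0′ σ²_line and E[MS_groups] = σ²_e + nb0 σ²_line +
n0 σ²_strain, so the strain test uses the synthesized denominator
c·MS_lines + (1−c)·MS_within with c = nb0/n0′ and Satterthwaite df; the
balanced case has c = 1 and F_s′ collapses to MS_groups/MS_lines exactly.
Both F_s (over within) and F_s′ are always reported, as the source tables
print both. Variance components are method-of-moments inversions of the
expected-MS equations and may be negative under sampling noise; they are
reported unclamped. Survivorship proportions are analyzed untransformed.
Worms dying before adulthood are absent records, not zeros.

Tukey–Kramer: q = |Δmean| / sqrt((MS_err/2)(1/n_i + 1/n_j)), p from the
studentized-range distribution with k groups and the error df. For nested
fitness traits the error term is the within-lines MS and df — the most
conservative reading of a 5% experiment-wise rate; one-way motility traits
use the residual MS.

## Molecular clock

t_generations = S / (2 μ L): the 2 accounts for substitutions accruing on
both lineages. Defaults μ = 4.32 × 10⁻⁸/site/generation and L = 13,794 bp
(the *C. elegans* mitochondrial genome length); the year is fixed at 365 days
(365.25 does not reproduce the three published dates as cleanly). Both L and
the year length are configurable. Display rounding is to the nearest year.

## Synthetic-data generator

The generator's defaults are the study conditions: genome AT fraction 0.64;
arm/core/tip at 45.7/47/7.3% laid out tip|arm|core|arm|tip per chromosome
(half of each arm/tip proportion per side); five chromatin states in 5-kb
i.i.d. blocks; gene models at regular spacing with 4 × 250-bp exons separated
by 400-bp introns; five callers at sensitivity 0.9, false-positive rate 0.05
per true insertion, jitter ≤ 100 bp, one caller (RetroSeq-like) not calling
reference elements; the nested phenotype design at 15 control / 20 treatment
lines × 5 sublines with productivity-scale effects (line and error variances
145 and 2,533, on the scale of the published productivity mean squares);
ddPCR wells at λ_ref = 0.5, D = 100, 20,000 droplets. The default simulated
genome is 3 × 1 Mb with 300 insertions — large enough to exercise every code
path while keeping the full test suite and the acceptance script to a few
minutes on one CPU; end-to-end enrichment-recovery runs use 3 × 3 Mb
(~2,400 motif sites) so that drawing 300 sites without replacement barely
depletes the biased category.

Insertions are sampled **without replacement from motif sites** with
per-category weight multipliers, because Tc1 targeting is strictly
TA-constrained; a `uniform_bp` mode exists to exercise the length-vs-motif
exposure contrast. Sampling without replacement means a planted w× bias
yields a slightly smaller realized rate ratio when the sampling fraction is
non-negligible (high-weight sites deplete first); at the 300-of-2,400 default
the residual attenuation is a few percent. Jitter is applied before
windowing so the 1,000-bp consensus logic is meaningfully stressed.

Limitations: bases are i.i.d. (no dinucleotide structure), so the clustering
of real integration-motif occurrences in an actual genome — where the
observed motif count exceeds the i.i.d. expectation — is not reproduced;
chromatin blocks are independent of gene models; caller errors are
independent across callers, whereas real callers share failure modes on
repetitive sequence. Passing tests therefore demonstrate correctness of the
statistical machinery and recoverability of planted effects, not performance
on real libraries.

## Numerical conventions

Display rounding is half-up throughout (Decimal-based, so 0.5 cases never
round to even). Degenerate inputs fail loudly: zero total variance,
saturated ddPCR wells, zero reference λ, empty flank matrices, degenerate
contingency margins and single-observation groups all raise with specific
messages rather than returning NaN.
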