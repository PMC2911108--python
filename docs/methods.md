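# Methods

## Read model and demultiplexing

Reads are fixed 42-cycle single-end sequences laid out as a 4-nt sample
index (cycles 1–4), an 18-nt universal primer (cycles 5–22) and the 20-nt
strain barcode (cycles 23–42). Internally all coordinates are 0-based
half-open; cycle *k* maps to position *k* − 1. The two universal primers
(`GAGGCAAGCTAAGATATC` for uptags, `CCAGTGTCGAAAAGTATC` for dntags) differ
at more than four positions, so a ≤ 2-mismatch match can only ever fit one
of them; the tie branch in the classifier is defensive.

Matching is deliberately asymmetric in stringency. The index is matched
exactly: indexes are drawn from a quaternary code of minimum pairwise
Hamming distance 2 (the parity code {x : Σ digits ≡ 0 mod 4}, size 64,
which is maximal — any 65 4-mers contain two sharing their first three
bases, hence at distance 1), so one sequencing error in the index can
never silently reassign a read; it simply matches no sample. The primer
region tolerates up to two mismatches, because it only has to identify the
tag class. The barcode is matched exactly against the catalog, because
barcodes are the quantified signal and fuzzy matching would cross-talk
between strains. Reads matching a barcode that is shared by more than one
(strain, tag-class) pair are discarded and counted under
`ambiguous_barcode`; reads shorter than 42 nt under `malformed`. Assigned
plus discarded always equals processed.

A barcode serving as the uptag of one gene and the dntag of another (or
reused within one strain) is excluded as ambiguous at the catalog level,
although the primer would in principle resolve the class: the
barcode→strain lookup stays a pure function of the barcode, which keeps
counting conservative and auditable.

## Growth model and GI score

A pool "generation" is one doubling of total culture mass; a strain with
relative fitness *f* (wild type 1) performs *f* doublings per pool
doubling, giving abundance fractions

p_i(g) = p_i(0)·2^(f_i·g) / Σ_j p_j(0)·2^(f_j·g).

Counts are normalized per tag class to 1,000,000 matched reads. The
growth-inhibition score is GI = Σ_g a_g·log₂(FC_g)/g with Σ a_g = 1, where
FC_g is the normalized control/treatment ratio at generation *g* after
adding a pseudocount of 1 to both raw counts. Scale factors are computed
from raw (un-pseudocounted) totals: the pseudocount exists only to avoid
division by zero and totals are dominated by real reads. Two designs are
built in: media comparisons sampled at g = 3, 4, 5 with a₃ = a₄ = a₅ = 1/3
(a₁ = a₂ = 0), and single-timepoint drug treatments at g = 5 where
GI = log₂(FC₅)/5.

Tags whose raw control reads fall below `min_control_reads = 12` at any
weighted generation are excluded (`insufficient_control_reads`). The
filter operates on raw counts — the conservative reading when the
sequencing depth is near the 1 M normalization target, where raw and
per-million counts coincide; the threshold and scale are parameters. A
strain's score is the mean of its defined tag scores; with one tag it is
that tag's score.

The pseudocount bounds measurable depletion: a strain with control count
*c* cannot exceed GI = log₂(c+1)/g even if fully depleted, so GI of
arrested strains is compressed below 1 for low-abundance strains. This is
visible in the auxotroph-recovery test and is a property of the estimator,
not a defect.

## Cutoffs, G-test, and hit calling

Per experiment, cutoffs derive from the combined strain GI distribution
(single- and dual-tag strains together): median + 3·NIQR for single-tag
genes; median + 2.5·NIQR on the averaged score *and* median + 2·NIQR per
tag for dual-tag genes. NIQR = IQR × 0.7413 with quartiles by linear
interpolation of order statistics; it equals σ for normal data, which the
oracle test verifies on exact normal quantiles.

The G-test is the likelihood-ratio statistic G = 2·Σ O·ln(O/E) on the 2×2
table (barcode reads vs all other reads, control vs treatment) built from
the final weighted generation's raw counts — the time point carrying the
fitness signal. Zero observed cells contribute zero; p is the upper
chi-square tail at 1 df; no Williams or continuity correction by default
(a Williams toggle exists). No multiple-testing correction is applied: the
fixed p < 0.005 cutoff is combined with the replication requirement
instead. A gene is a sensitive hit when it passes both the GI and p
filters in ≥ 2 of 3 experiments. Comparisons are inclusive (GI ≥ cutoff
passes). Note a degenerate corner: if an experiment's GI distribution is
exactly constant, NIQR = 0 and the inclusive GI filter passes everything —
the p filter is then the only guard; real count data never produces this.

Resistant mutants are reported as a ranking by ascending GI (ties by gene
id) with a descriptive flag at GI ≤ −0.5 (inclusive), not as a formal
multi-experiment test: enrichment of a resistant strain compresses every
other strain's apparent abundance, and the screen's own practice is
ranking plus inspection.

## QC statistics and clustering

Replicate correlation is Pearson r of log₁₀ normalized counts over
barcodes positive in both samples; the log scale matches how count scatter
spanning orders of magnitude is assessed (a raw-scale option exists).
Tag agreement correlates uptag- vs dntag-derived log₂ control/treatment
ratios over strains with both control tags ≥ 12 reads and both treatment
tags > 0. Spike-in linearity regresses log₁₀ normalized reads on log₁₀
spike-in cell ratio; proportional quantification gives slope 1.

Clustering is agglomerative average linkage on distance 1 − s with the
uncentered correlation s(x,y) = Σxᵢyᵢ/√(Σxᵢ²·Σyᵢ²) (correlation about
zero — profiles are similar when they deviate from "no fitness change" in
the same direction), run through scipy's linkage on the condensed distance
matrix and verified against a brute-force step-by-step agglomerator in the
tests. Zero-norm profiles get similarity 0 (distance 1). Missing GI values
are imputed as 0 — the neutral "no fitness change" value — before
clustering. Average linkage admits height inversions, so monotonic merge
heights are not asserted. Dendrograms export as Newick with branch length
= parent merge height minus child merge height.

## Simulator

The generator emulates the screen's stated conditions: ~2,500 strains,
initial abundances log-normal with σ = 1 (the real pool's dispersion is
not quantified; σ is configurable), 1–5 pool doublings, 10⁶ reads per tag
class per sample, spike-ins at cell ratios 1/200 … 1/20,000 added as
binomial draws with success probability ratio/(1 − Σ ratios) per library
read. Per-barcode amplification bias is a log-normal weight (default
σ = 0.5, a several-fold efficiency spread typical of PCR) drawn once per
barcode and shared across samples, as real PCR bias is — which is exactly
why it cancels in control/treatment ratios and why uptag/dntag agreement
works. Sequencing errors are substitution-only (uniform over the three
alternative bases), applied at FASTQ emission; indels are not modelled —
fixed-cycle short reads make them rare and they would only lower the match
rate, not change any contract. Qualities are a constant 'I'; the pipeline
never reads them. All randomness flows from one integer seed through
named numpy Generator streams, so every output is reproducible and
independent of evaluation order.

What the simulator does not emulate: lag/recovery phases, pharmacodynamic
dose response, cross-well contamination, quality-dependent error profiles,
or strain-specific PCR interactions. Passing recovery tests therefore
demonstrates the estimator's correctness under the stated sampling model,
not robustness to every artefact of real screens.

One measurable consequence of the error model: at per-base error 0.01 the
fraction of reads perfect at all 42 cycles is 0.99⁴² ≈ 0.66 — the
demultiplexer's ≤ 2-mismatch primer tolerance rescues part of the
remainder (binomial survival raises the assigned fraction to ≈ 0.78), so
the 0.66 figure is checked with the tolerance set to zero.

## Problem sizes and numerics

Tests and the acceptance script run counts-level simulations at the full
stated scale (2,500 strains, 10⁶ reads per tag class) because multinomial
sampling is cheap; FASTQ round-trips use 10⁵ reads, the scale at which the
binomial check on the perfect-match fraction is already decisive. Analytic
GI checks use noise-free count tables with equalized per-sample totals so
normalization is the identity and the unaffected strain's GI is exactly 0.
Quartiles use numpy's linear interpolation; G is clamped at 0 against
rounding; weights must sum to 1 within 1e−9; normalized tag-class totals
are verified to 1e−6 relative.
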