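# Methods

This note documents the models, rules and numerical choices implemented in
`oetomics`, including the places where a published description left the
design genuinely open and what this package chose.

## Stage axis and units

The seven developmental stages (FGO, MII, 1C, 2C, 4C, 8C, BL) carry no
physical time coordinate in the source data, so the default time grid is
the stage index 0..6. All rates are therefore "per stage transition":
a degradation rate k_d = 0.7 means the protein loses a factor e^0.7 per
stage step. A different grid (e.g. hours post-hCG) can be passed through
`StageSeries`; fitted parameters rescale accordingly.

## Missing values

Protein cells that are empty (or explicitly zero intensity) are "not
detected": below the sensitivity of label-free LC–MS/MS, not biologically
zero. Where an analysis needs complete trajectories (CV, clustering,
correlation), missing protein values are imputed at the global detected
minimum minus 1 log2 unit — "not detected = lowest abundance" without
−∞. The shift is configurable. FPKM layers keep explicit zeros as
measurements; they are log2(x + 1)-transformed where a log scale is
needed and a pseudocount of 0.1 is used in FPKM ratios (dormant-mRNA
rule) to avoid division by zero.

## Batch correction

LC–MS/MS batches differ by approximately additive offsets on the log2
scale. FGO samples present in every batch anchor the correction:
for proteins detected in the anchor stage of all batches, each batch is
summarized by the median (across proteins) of its per-protein mean anchor
intensity, and the offset is that median minus the reference batch's.
Offsets are subtracted from every sample of the batch; detection masks
are unchanged. Under a pure additive shift, the difference-of-medians and
the median-of-differences estimators coincide; difference of medians was
chosen as the more robust summary when the shift is only approximate.

## Replicate merging and gene universe

Stage values are means over replicates in which the protein was detected;
a stage is missing only if all replicates are. The four FGO runs are
first paired ((batch-1, batch-2), (batch-3, batch-3)) into two derived
replicates. The analysis universe keeps genes that are (i) detected in at
least one protein sample, (ii) not detected in exactly one derived FGO
replicate (an inconsistency suggesting an unreliable identification), and
(iii) detected (FPKM > 0) at one or more stages in RPF or mRNA. The
cross-batch consistency predicate is an operationalization — the exact
published rule is ambiguous — and is confined to `filter_gene_universe`
so alternatives can be swapped in.

## Dynamics

A gene is dynamic in a layer if the coefficient of variation (sample sd /
mean) of its log2 values across the seven stage means exceeds 0.2. RNA
layers restrict to genes expressed at FPKM ≥ 1 in at least one stage.
CV is computed on stage-averaged values (variance "across stages", not
across replicates). Trajectory clustering z-scores each gene's imputed
log2 trajectory (shape, not level, defines the groups), then runs
Euclidean K-means with k = 10 and 100 random restarts by default, keeping
the lowest within-cluster SSE; the restart stream is seeded and recorded.
Flat trajectories (zero variance) map to all-zero z-profiles. The
automated embryonic merge labels a cluster "embryonic" when its mean
detected trajectory stays below the detection floor (or is undetected) at
every pre-ZGA stage — before the 2-cell stage, where the major wave of
zygotic genome activation first produces embryonic proteins — and its
final-stage mean is above the floor; an explicit cluster→group mapping
can override the rule.

## Concordance

Gene-wise concordance is the Spearman correlation between the protein and
RPF (or mRNA) stage series, using average ranks for ties. By default
imputed protein values are included (the alternative, detected-stages
only, is available; genes with fewer than 3 usable stages are skipped and
counted). Bin boundaries follow the strict-inequality convention
high: r > 0.5, low: r < 0.2, medium: 0.2 ≤ r ≤ 0.5 — the boundary points
land in the middle bin. Change matrices are per-transition differences of
log2 values; lagged change correlation compares, across genes, protein
changes at one transition with RPF/mRNA changes at earlier transitions
(offset-1 and offset-2 diagonals = one- and two-stage lag).

IDRs are maximal runs of per-residue disorder score > 0.5 that are
strictly longer than 30 residues (a 30-residue run does not qualify),
reported in 1-based inclusive coordinates and written as BED-like 0-based
half-open intervals. Score computation itself is upstream of this
package; scores are consumed as input.

## Differential expression and attribution

DEP/DEG calls compare replicate log2 values of consecutive stages:
log2 fold change = difference of detected-replicate means; significance
by a classical equal-variance two-tailed Student's t-test (with n = 2 per
group, Welch's correction is unstable, and "Student's t-test" is read as
the pooled-variance form). Thresholds: |log2 fc| ≥ 1 and p < 0.05
(|log2 fc| ≥ 2 for cycloheximide experiments, where 24 h and 48 h
treatments may be pooled). Degenerate rows with zero variance in both
groups get p = 1 when means are equal and p = 0 otherwise; genes with
fewer than two detected replicates in a group are skipped and flagged.
No multiple-testing correction is applied — calls use raw p-values —
so DEP counts should be read as a screening statistic, not an FDR-
controlled discovery set.

Attribution scans, for each protein DEP at transition i, the mRNA and RPF
change tables over transitions i, i−1, i−2 (fewer at the series start).
A same-sign log2 change > 1 in the window assigns "mrna_contributed"
(checked first), else "rpf_only", else "unexplained". Requiring the same
sign operationalizes "corresponding changes"; opposite-sign changes do
not explain a protein change.

## Kinetic model

The mass-action balance dp/dt = α·r(t) − k_d·p(t) is solved exactly:
r(t) is piecewise-linear between stage time points, and within each
segment the integrating factor gives

p(t_k + τ) = p_k·e^(−k_d τ) + α[ r_k·τ·φ1(k_d τ) + b·τ²·φ2(k_d τ) ],

with b the segment slope, φ1(x) = (1−e^(−x))/x, φ2(x) = (x−1+e^(−x))/x²
(series expansions below |x| = 1e-4 for numerical stability). Fitting
minimizes Σᵢ (p(tᵢ) − p̂ᵢ)² over α, k_d ≥ 0 on the linear intensity scale
(2^log2; the balance is linear in abundance, and evaluation by rank
correlation is scale-robust). Missing observed stages are dropped from
the objective, not imputed. In P0+RPF mode p₀ is pinned to the observed
first-stage value (0 if undetected there); in RPF-only mode p₀ = 0.

Because the solution is linear in (p₀, α) for fixed k_d, the optimal
nonnegative α has a closed form per k_d. The optimizer profiles α over a
dense log-spaced k_d grid (0 plus 50 points spanning 1e-4..50 per-stage
units), refines the best three grid points by bounded scalar search, then
polishes (α, k_d) jointly with L-BFGS-B and re-profiles α at the final
k_d. The procedure is deterministic, its objective is never worse than
any grid point, and on noiseless synthetic genes it recovers parameters
to well under 1% relative error. Upper bounds (10⁶ in data-scaled units)
keep the search compact; fits ending on a bound are flagged. Genes whose
predicted series is constant have undefined rank correlation and are
excluded from medians (counted).

## Allele-specific analysis

Variant peptide windows span 30 residues each side of the variant
(61 aa), clipped — not padded — at protein termini: padded residues have
no biological meaning and variable-length windows are tolerated by
standard search engines. ASE is tested per embryo stage (1C..BL) by the
same equal-variance t-test with |log2 fc| > 1; a stage where one allele
is detected (≥ 2 replicates) and the other is entirely missing counts as
allele-specific (infinite fold change, p set to 0), since detection
asymmetry is itself the evidence. Stages with a single replicate are
skipped. Parent-of-origin categories are detection-pattern rules
(oocyte_specific, oocyte_embryonic, embryonic_maternal/paternal, none)
that operationalize descriptive heat-map groupings; they are exactly
recoverable on synthetic truth at zero noise.

## Synthetic-data generator

The generator emulates the study design: 7 stages; protein in three
batches (FGO replicated in all three, four FGO runs, blastocysts in batch
3) with additive log2 batch offsets (defaults 0, +0.7, −0.4); RPF/mRNA
with two replicates. Genes draw from nine trajectory classes (four
constitutive subgroups distinguished by their RPF behaviour, maternal,
OET-down, OET-up/dormant-driven, embryonic, and below-floor "low") with
per-class kinetic parameters and FPKM templates; per-gene parameters are
jittered log-normally (σ = 0.3 log2 units) around the class archetype,
and the jittered values are the ground truth. Protein trajectories are
forward-simulated through the kinetics module, log2-transformed,
replicated with lognormal measurement noise, shifted by batch offsets,
and masked below a detection floor (default 6.0 log2 units) applied to
the pre-offset noisy value — detection is decided by the measured amount,
not the batch-shifted record. Class counts use largest-remainder
apportionment (each within ±1 of n × proportion). One pseudo-random
stream per layer is split from the master seed.

Derived truth flags (dormant, FGO-originated, protein-dynamic, ASE
category) are computed from each gene's own sampled parameters at
generation time, so zero-noise recovery tests are exact even under
per-gene jitter. Absolute iBAQ scales are arbitrary (around 2^11 for
abundant classes); no public deposition was used for calibration.

What the generator does not emulate: peptide-level evidence and
share-of-intensity effects, correlated (non-additive) batch structure,
intensity-dependent missingness (the floor is sharp), biological
replicate variance distinct from measurement noise, and real gene-gene
correlation. Passing recovery tests therefore demonstrates correctness
of the estimators under the stated generative assumptions, not
performance on real LC–MS/MS data.

## Problem sizes

Default test and reproduction runs use bundles of 300–800 genes and
recovery experiments of 500 simulated genes — large enough for stable
medians and fractions while keeping a full pipeline run around a minute
on a single CPU. All simulations are seeded; the acceptance script
derives every stream from its `--seed` argument.
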