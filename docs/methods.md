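# Methods

This note documents the statistical models behind each pipeline stage, the
defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical choices that matter for
reproducibility.

## CRISPR resistance-screen analysis

**Model.** A pooled resistance screen compares sgRNA representation after
drug selection against a vehicle arm. Counts are scaled to reads per
million (RPM) within each sample; per sgRNA the enrichment is

    log2fc = log2((RPM_treated + pc) / (RPM_control + pc)),  pc = 1 RPM

with a pseudocount of 1 RPM on both sides to stabilize low counts. Because
the screen design has one sequencing sample per arm (no replicates), the
per-sgRNA p-value comes from an *empirical null*: the robust z-score
(median/MAD, scaled by 1.4826 for normal consistency) of each sgRNA's
log2fc against all sgRNAs in the same condition, converted through the
standard normal (two-sided by default; a one-sided enrichment option
exists). This assumes the vast majority of sgRNAs are inert, which holds
genome-wide; it cannot be applied to small focused libraries where many
guides are active.

**Gene rule.** Genes carried by 3–10 sgRNAs are eligible. An sgRNA passes
in a condition iff log2fc ≥ log2(fold_threshold) *and* p < p_threshold
(defaults: 2-fold, 0.05); a gene scores in a condition iff ≥ 2 of its
sgRNAs pass; the final call intersects the treated conditions (union mode
available). Raising the fold threshold or lowering the p threshold can
only remove hits (monotonicity, property-tested), and the vectorized
caller is verified identical to a nested-loop reference implementation on
random tables.

**Coverage.** `coverage_check` reports mean cells per sgRNA
(cells × infection rate / library size); pooled screens aim to keep this
above ~500 so multinomial sampling noise stays well below a 2-fold signal.

## Lipidomics

**Annotations.** Species are handled at summed-composition resolution:
class plus total acyl carbons and total double bonds (e.g. `PE C38:4`).
Chain counts are class-derived: 1 for CE/MAG/LPC/LPE/FFA, 3 for TAG, 2
otherwise.

**PUFA classification.** A species is PUFA-containing when its total
double-bond count *forces* a polyunsaturated chain under every possible
split across its chains: DB ≥ n_chains + 1 (pigeonhole — n_chains chains
can absorb at most one double bond each before some chain must carry two).
This is the weakest class-aware rule that never over-calls from a summed
composition; it reproduces the canonical examples (PE C38:4 and free
arachidonic acid C20:4 are PUFA; TAG C50:1 is not) and is verified against
exhaustive composition enumeration. It is deliberately conservative: a
TAG C52:3 *may* contain an 18:2 + 18:1 + 16:0 split but is not guaranteed
to, and is therefore classified SFA/MUFA-only. Stricter conventions can be
injected per class via `pufa_min_db_override`. Vinyl-ether double bonds of
plasmalogens (ePC/ePE) are *not* subtracted from DB before classification,
because summed-composition tables are ambiguous about whether they are
counted; users with chain-resolved knowledge should use the override.

**Normalization and testing.** Median normalization rescales every sample
to the grand median of sample medians (correcting loading/injection
differences); it assumes most species are unchanged between groups. Note
that rescaling one sample can move the grand-median target, so the
normalized table is invariant to per-sample rescaling only up to a single
global factor. Differential abundance per species is log2 of the group
mean over the reference mean, with a two-tailed pooled-variance Student
t-test on log2 abundances (log transform for variance stabilization; the
upstream intensity scale is multiplicative) and BH adjustment across
species within each group comparison. Species with zero mean on either
side are reported as not-detected and excluded from testing rather than
imputed.

**Class ratios and PCA.** `class_pufa_ratio` is the within-sample fraction
of class abundance carried by PUFA species — invariant to any per-sample
rescaling, hence robust to normalization choices. `pca_scores` takes the
SVD of a (median-centered by default) samples × features matrix and
reports scores plus variance fractions summing to 1.

## Dose–response

Dilution series are geometric: max, max/fold, …, max/fold^(n−1) (default
2-fold). Viabilities are raw signals divided by the mean vehicle signal;
values above 1 are kept (stimulation), values below 0 are floored at 0
before integration. The 4PL model

    v(c) = bottom + (top − bottom) / (1 + (c/EC50)^h)

is fit by bounded least squares with initialization top = max observed,
bottom = min observed, EC50 = geometric midpoint of the series, h = 1, and
EC50 bounded to [min_conc/4, max_conc × 4]; constant curves short-circuit
to the degenerate top = bottom fit, and optimizer failure returns the
initial iterate flagged unconverged.

The sensitivity score is the area under the viability curve over the
*log*-concentration axis. Because the series is geometric the grid is
uniform there, so the trapezoid rule reduces to the weighted mean
(½v₁ + v₂ + … + v_{n−1} + ½v_n)/(n−1): a flat curve at level v scores
exactly v, and a fully insensitive normalized curve scores 1. Whether
public AUC compendia use this exact axis convention is not knowable from
their documentation; the convention is stated here rather than claimed
equivalent.

Curve-shift testing (the re-sensitization readout) computes one AUC per
replicate (replicate j uses the j-th well at every concentration), reports
the mean AUC difference against the control curve, takes a two-sided
Student t-test on replicate-level AUCs, and BH-adjusts across a candidate
panel. Defining a "significant shift" via replicate AUCs is an
interpretive choice — AUC is the scalar that the ranking downstream
consumes — and is flagged as such.

## Lineage selectivity

Coverage filters run once each, compounds first: compounds profiled in
less than 2/3 of the cell-line collection are dropped, then lines profiled
on less than 50% of the *retained* compounds. The order matters only for
borderline cases and is fixed for determinism; the filter is idempotent.
Per compound, the flagged group is compared against all other lines with a
two-sided Mann–Whitney test (missing AUCs dropped pairwise, never
imputed), the effect is the difference of group means (medians behind a
flag), and p-values are BH-adjusted across compounds. Lineage ranking
sorts lineages (those with > 5 measured lines) ascending by mean AUC —
most sensitive first — with per-lineage Mann–Whitney tests against the
complement.

## Statistical primitives

* Student t: pooled-variance two-sample form (Welch behind a flag);
  zero-variance equal-mean input returns statistic 0, p 1.
* Mann–Whitney: exact p by full enumeration of the null when
  n₁ + n₂ ≤ 12 and the data are tie-free; otherwise the normal
  approximation with tie and continuity corrections. Ties always route to
  the approximation because exact enumeration assumes distinct ranks. The
  threshold trades enumeration cost against fidelity; at the boundary the
  two branches agree within 0.02 on tie-free data.
* BH: step-up adjusted values min_{j≥i} (m/j)·p_(j) capped at 1, returned
  in input order; verified against an O(m²) brute force and statsmodels.
* Two-sided p-values are doubled one-tail probabilities capped at 1.
* Robust z: (x − median)/(1.4826·MAD); zero MAD raises with instructions
  to fall back to a standard-deviation z-score.

## Synthetic data: what it emulates, and what it does not

All generators take a single integer seed and are byte-for-byte
reproducible; no global random state is touched.

**Screen counts.** Baseline sgRNA abundances are log-normal (σ = 0.5) to
mimic library skew; counts are negative binomial parameterized by mean m
and dispersion α with variance m + α·m² (α → 0 recovers Poisson; default
α = 0.05, a tight technical-replicate level). Defaults are a scaled-down
genome-wide screen: 1000 genes × 4 sgRNAs, depth 500 expected reads per
sgRNA (the representation floor a well-powered screen maintains), three
treated arms (`d4`/`d6`/`d8`) plus one vehicle arm. Planted resistance
genes (default 20) have 75% of their sgRNAs enriched 8-fold in every
treated arm, so the ≥ 2-passing-sgRNA rule is genuinely exercised against
inactive guides. Expected per-sample counts are renormalized so every
sample's expected total equals the configured depth — sequencing depth is
an instrument property, not a biology readout — which means planted guides
are fold-enriched *relative to the rest of the library* rather than in
absolute RPM; the median-centered empirical null is unaffected. Not
emulated: PCR jackpotting, guide-specific efficiency, cell-cycle/fitness
effects in the vehicle arm, or multi-infection — recovery results bound
what the hit caller can do under clean NB sampling, not under all real
failure modes.

**Lipidome.** Summed compositions are drawn per class on a carbon grid of
14–22 per chain with double-bond counts sampled under geometric decay
(weight ∝ exp(−0.6·DB)), making PUFA species ≈ 25% of the panel as in real
membranes where saturated/monounsaturated species dominate — this also
keeps the sample median anchored on unchanged species, the assumption
median normalization needs. Baselines are log-normal (σ = 1); noise is
Gaussian on the log2 scale (default sd 0.25); the planted effect (default
−2 log2) applies to every PUFA-classified species in non-reference groups.
Not emulated: class-correlated abundance structure, missingness at the
detection limit, or isotope/adduct artifacts.

**Viability.** 4PL signal plus homoscedastic Gaussian noise (default sd
0.02, four replicates) truncated at 0. The truncation introduces a small
positive bias only when the curve runs near 0 with large noise. Real
plates add edge effects and heteroscedastic noise near the top plateau;
neither is modeled.

**Sensitivity matrices.** Baseline AUCs are Gaussian (mean 0.85, sd 0.08)
clipped to [0, 1]; one randomly chosen compound's AUC is shifted by the
planted effect (default −0.4) in the single target lineage; missingness is
uniform at the configured fraction. Real compendia have structured
missingness (by screening wave) and correlated compound families; both are
absent.

**Xenograft volume.** The caliper formula V = L·W·W/2 (mm³) with the long
axis L ≥ W enforced.

## Problem sizes and determinism

The test suite and the acceptance script use the default simulation sizes
above (1000-gene screens, ~170-species lipidomes, 100-seed dose-response
sweeps, 50–200-compound matrices); the full suite runs in a few seconds on
one core. All Monte-Carlo assertions use fixed or argument-derived seeds;
hypothesis property tests run derandomized.

## Known limitations

* The empirical-null screen p-value is a design choice, not a
  reconstruction of any published tool's test; hit lists on real data will
  differ from replicate-based or rank-based callers near the threshold.
* The PUFA rule is guaranteed-minimal, not curated; chain-resolved data
  would reclassify some borderline summed compositions.
* Normalized AUC depends on the axis convention; comparisons across tools
  should re-derive AUC from the same curves.
* A broad planted depletion slightly shifts sample medians, so
  median-normalized null species sit marginally off zero; with the default
  ≈ 25% PUFA fraction this costs a few percent of false positives at
  q < 0.05 (visible in the worked example) and disappears under a null
  configuration.
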