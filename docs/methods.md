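# Methods

This note records the statistical procedures `ovisweep` implements, the
choices made where a convention had to be fixed, what the simulators do and
do not emulate, and the problem sizes the test suite runs at.

## Sweep scan

**Per-site F<sub>ST</sub>.** With pooled reference-allele frequencies
p_A, p_B and p̄ = (p_A + p_B)/2, total and mean subpopulation
heterozygosities are H_T = 2p̄(1−p̄) and
H_S = [2p_A(1−p_A) + 2p_B(1−p_B)]/2, and the site statistic is
(H_T − H_S)/H_T — the Nei/Hudson-style estimator on pooled proportions,
without finite-sample correction. It is exactly 0 at equal frequencies,
1 at a fixed difference, and defined as 0 when H_T = 0 (a site monomorphic
in both pools carries no differentiation signal). This estimator was chosen
because it needs only the pooled proportions the input carries; sample-size
corrected estimators (Weir–Cockerham) require per-pool depths that pooled
designs often lack.

**Windowing.** Windows of 50 kb slide in 25-kb steps from position 1 to the
last SNP of each chromosome; window F<sub>ST</sub> is the ratio of sums
Σ(H_T − H_S)/ΣH_T, not the mean of per-site ratios — the standard for
windowed F<sub>ST</sub>, since it weights sites by their informativeness.
Windows with fewer than `min_sites = 3` SNPs are retained but undefined:
sparse windows produce unstable ratios that distort the genome-wide moments.
Terminal partial windows are kept and flagged. Every interior site
contributes to exactly window/step windows.

**Pooled heterozygosity.** Per group, H = 2Σp Σq/(Σp + Σq)² over a window's
per-site major (p) and minor (q) allele frequencies, with major/minor
assigned per site within the group; 20-kb windows, 10-kb step. H is
computed per group (with a pooled-groups option), since diversity loss is a
property of the selected population.

**Standardization and calling.** Z = |x − μ|/σ with μ, σ the mean and
population-denominator standard deviation over all defined windows
genome-wide. The absolute value means unusually *low* windows also score
high; by default region calling is restricted to windows with x above the
genome-wide mean, because a sweep scan seeks elevated divergence (the
restriction is a flag). A spread below machine precision relative to the
mean is treated as a degenerate scan: all Z are set to 0 with a warning.
Significant windows (Z > 5 fixed, or the genome-wide top-5% quantile of Z)
that overlap or abut on one chromosome merge into a region spanning their
union; the region score is its maximum member Z. ΔAF = |p_A − p_B| is
reported per site with a genome-wide top-quantile threshold; no window
aggregation is applied to ΔAF. For the one-sided question "which tail",
high tails are used for the differentiation statistics; a low-H tail
(diversity loss) can be examined through the unrestricted mode.

**Coordinates.** 1-based inclusive internally (the VCF convention); BED
output converts to 0-based half-open. A gene annotates a region when the
intervals overlap by at least 1 bp.

## Marker statistics

Allele frequencies by gene counting: p = (2n_AA + n_Aa)/2N. HE = 1 − p² − q²,
PIC = HE − 2p²q², NE = 1/(p² + q²), all from unrounded p. Comparisons with
two-decimal published tables use round-half-away-from-zero (`round2`),
matching how such tables are typically produced; Python's built-in banker's
rounding differs at exact .xx5 boundaries.

The Hardy–Weinberg test is the chi-square goodness of fit of observed
genotype counts against (Np², 2Npq, Nq²) with p estimated from the data:
df = 3 − 1 − 1 = 1, no Yates continuity correction. Expected counts below 5
trigger a warning rather than a switch to an exact test, keeping the
procedure the plain chi-square law. Monomorphic markers are flagged
untestable.

One bundled table row (Small Tail Han at g.71833755T>C) prints PIC/HE/NE
values consistent with frequencies pre-rounded to 0.75/0.25 rather than the
unrounded 0.7539; the package always computes from unrounded counts, and
the reproduction checks exclude that row rather than guess at a rounding
pipeline.

## Linkage disequilibrium

Haplotype frequencies (f_AB, f_Ab, f_aB, f_ab) are estimated from unphased
two-locus genotypes by EM. All genotype classes except the double
heterozygote resolve to known haplotype counts; the E-step splits double
heterozygotes between AB/ab and Ab/aB in proportion to f_AB·f_ab vs
f_Ab·f_aB. Initialization is at linkage equilibrium (p₁p₂, …);
convergence when no frequency moves by more than 1e−8, capped at 1000
iterations (non-convergence warns and returns the last iterate). The
observed-data log-likelihood is recorded per iteration and is non-decreasing
— asserted in the tests. D = f_AB − p₁p₂; D′ = |D|/D_max with
D_max = min(p₁q₂, q₁p₂) for D > 0 and min(p₁p₂, q₁q₂) for D < 0;
r² = D²/(p₁q₁p₂q₂). Monomorphic loci yield a flagged undefined result.
Missing calls are dropped pairwise.

## Litter-size association

The model y_ijn = μ + P_i + G_j + I_PG + e_ijn (parity i = 1..3, genotype
j = 1..3) is fitted by OLS under the saturated cell-means parameterization —
one coefficient per non-empty (parity, genotype) cell, equivalent to the
interaction parameterization for every estimable quantity. MSE = SSE/df with
df = N − #cells. Records from the same ewe at different parities are treated
as independent: the model class has no ewe random effect, a known
limitation that understates SEs when between-ewe variance is appreciable.

Least-squares means: within parity, the LS mean of cell (i, j) is its cell
mean with SE = √(MSE/n_ij). The three-parity genotype average weights the
parity cells equally — estimate = mean of the three cell means,
SE = √(MSE·Σ1/n_ij)/3 — which is the marginal mean the interaction model
supports under unbalance (a pooled one-way average would re-weight by cell
size and confound parity with genotype). Empty cells are excluded from the
average with a warning and an `incomplete` flag.

LSD letters: all pairwise genotype differences within a comparison family
(one parity column, or the average column) are tested with
t = Δ/√(MSE(c₁+c₂)) against the residual-df t distribution, two-sided, no
multiplicity adjustment (that is what "least significant difference" means),
α = 0.05. Letters come from the insert-and-absorb algorithm, so two
genotypes share a letter exactly when their difference is non-significant;
'a' marks the group containing the largest mean.

## Expression

ΔCt = Ct(target) − Ct(reference gene) per replicate; ΔΔCt subtracts the
calibrator cell's mean ΔCt; fold = 2^−ΔΔCt. The default calibrator is a
*group within each tissue* (the comparison group), so per-tissue group
contrasts never depend on a global anchor; a global (tissue, group)
calibrator is available. Group comparisons are two-sided two-sample
t-tests, by default on ΔCt — the log₂ scale, where qPCR noise is closest to
Gaussian and where decisions coincide with fold-scale decisions as noise
vanishes — lettered at 0.05 (lowercase) and 0.01 (uppercase). Amplification
efficiency is assumed to be exactly 2 per cycle; no Pfaffl correction or
multi-reference normalization.

## Simulators

All generators are pure functions of (config, seed); a global seed fans out
to named child streams via `SeedSequence(entropy=seed, spawn_key=(hash(label),))`
so subsets of a run reproduce independently.

**Divergent pools.** Positions uniform without replacement, sorted; per
site an ancestral frequency from Uniform(0.05, 0.95); each group's
frequency an independent Beta draw with mean p and divergence F under the
Balding–Nichols parameterization (shapes p(1−F)/F, (1−p)(1−F)/F). Defaults:
10,000 sites on 5 Mb, F = 0.05 background, F = 0.5 in a 100-kb implant,
pools of 30 and 59 animals. This produces exchangeable, site-independent
frequencies with an interpretable divergence parameter. It does **not**
emulate linkage disequilibrium between sites, binomial sampling noise on
pool frequencies, sequencing depth variation, or selection dynamics over
time — so passing recovery tests demonstrate that the scan statistics find
localized divergence of this magnitude, not that they are robust to the
autocorrelation or noise structure of real pooled WGS.

**Genotype counts.** Multinomial over (p² + D, 2pq − 2D, q² + D); D = 0 is
HWE. The feasible D range is enforced with a helpful error.

**Litter sizes.** y = cell mean + Normal(0, σ²) with defaults μ = 2.3,
parity effects (−0.15, 0, +0.55), genotype effects (−0.1, +0.2, 0)
(heterozygote advantage), zero interactions, σ = 0.75 — the residual scale
implied by published SEs near 0.06 at cell sizes around 150. Litter size is
simulated continuous although it is an integer count, because the model
under test is the Gaussian fixed-effects model; integer rounding would only
add a discretization the model ignores anyway. Each simulated ewe keeps one
genotype across its three parities, but residuals are independent across
parities (no ewe-level random effect — matching the fitted model, not
biology).

**Ct tables.** Reference Ct ~ Normal(20, sd²); target = reference +
baseline ΔCt (5.0) + group shift + Normal(0, sd²) noise; 3 biological
replicates per tissue × group by default (the realistic, and admittedly
underpowered, scale of tissue-panel qPCR).

## Problem sizes and tolerances in the test suite

Window statistics are verified against brute-force interval oracles at
1e−12; OLS against a normal-equations solve at 1e−10; EM against phased
counting at 1e−6 where phase is unambiguous. Stochastic recovery checks run
at: 100 seeds × 10,000 sites for the sweep scan (top-quantile region must
overlap the implant in ≥95 seeds); 200 datasets × 1,800 records for
association (all nine cell LS means within 3 SE of truth in ≥95%); 200
seeds for the expression shift (−1.5 cycles, sd 0.2: the geometric-mean
fold must land in the analytically derived central-95% envelope
2^(1.5 ± 1.96·0.2√(2/3)) ≈ [2.27, 3.53] in ≥90% of seeds); 1,000 replicates
for the HWE type-I-error calibration (rejection rate in [0.03, 0.07] at
α = 0.05, n = 375). These sizes make each stochastic criterion's sampling
error small relative to its margin while keeping the default suite fast.

## Known limitations

- The F<sub>ST</sub> estimator has no finite-sample correction; very small
  pools bias it upward.
- No p-values are attached to sweep regions; the scan is an outlier method.
- The association model ignores repeated measures on ewes (above).
- LD EM assumes random mating within the sample; it is not an inference of
  phase for individuals.
- 2^−ΔΔCt assumes perfect primer efficiency.
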