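# Methods

## Data model

Every test consumes a *stratified genotype table*: non-negative integer
counts indexed by stratum (control = 0, case = 1) and by genotype class at
each of two diallelic loci, classes labelled by risk-allele count. A locus
with only two observed classes (e.g. the Hb locus in the malaria tables,
where no SS children appear) keeps its observed dimension; empty cells are
retained and enter every entropy sum under the `0·ln 0 = 0` convention.
Tables validate that both strata are non-empty, so the case fraction
`P_A = N_case/N` is always in (0, 1).

## The entropy metrics

All information quantities use the natural logarithm; this is what makes
`2·N·MI` a likelihood-ratio (G) statistic with a chi-squared reference, and
the identity `2·N·GenoCMI = Σ_d G_d` (the sum of the within-stratum G
statistics for independence) holds to floating-point precision and is
enforced by the test suite.

* **GenoMI**: plug-in MI between the flattened joint genotype and disease
  status; statistic `2·N·MI`.
* **GenoCMI**: `Σ_d (N_d/N)·MI_d` with `MI_d` the within-stratum genotype
  MI; statistic `2·N·CMI`. A stratum with fewer than two non-empty rows or
  columns contributes zero and is flagged in the result notes.
* **GameteCMI**: as GenoCMI but on the EM-estimated 2×2 gamete distribution
  per stratum; statistic `2·N·CMI`, 2 df (one per stratum). A stratum that
  is monomorphic at either locus, or whose EM is degenerate, contributes
  zero with a note.

### Degrees of freedom

For two fully observed loci the references are chi-squared(8) for both
GenoMI and GenoCMI, and chi-squared(2) for GameteCMI. For tables with a
structurally absent genotype class the two genotype metrics need a rule,
and the published worked examples force *different* rules:

* GenoMI on the 2×3 malaria-admission table reproduces its published
  p-value (1.84E-10) only with the **full-grid df = 8**; the
  observed-category rule (df = 5) gives 4.56E-12.
* GenoCMI on the same table reproduces its published 3.88E-3 only with the
  **structural df = 2(r−1)(c−1) = 4**; df = 8 gives 5.13E-2.

The package defaults are therefore per-metric (`geno_mi_test`:
`df_mode="fixed"`, `geno_cmi_test`: `df_mode="structural"`), with the other
convention available via `df_mode`.

### GameteCMI scaling

With unphased data the gamete frequencies are estimates, not counts, and
the scaled statistic can plausibly use N individuals (`2·N·CMI`) or 2N
gametes (`4·N·CMI`, the sum of per-stratum allelic G-tests). Simulation
decides: under the global null (1000 cases + 1000 controls, allele
frequencies 0.30/0.42), 5000 replicates of `2·N·CMI` have mean 2.00 and
pass a Kolmogorov–Smirnov test against chi-squared(2) (p ≈ 0.97), while
`4·N·CMI` has mean 3.84 and fails catastrophically. The individual-count
scaling is the default; `scale="gametes"` exposes the other.

### Published entries not derivable from their printed counts

The malaria-admission GenoMI/GenoCMI values and the Table-of-cancers
GenoMI values (GCC 3.88E-06, LC 5.11E-08, HCC 9.34E-07, BC 2.02E-01), the
GenoCMI values for LC (4.99E-02), HCC (5.69E-05) and BC (7.41E-02), and all
three GCC logistic benchmarks reproduce here to their printed three
significant figures. The remaining published entries for these tables do
not follow from the printed counts under either candidate convention; the
computed candidates are:

| table, metric | published | computed (default) | other candidate |
|---|---|---|---|
| admission, GameteCMI | 3.30E-05 | 4.44E-03 (2N) | 1.97E-05 (4N) |
| severe, GenoMI | 2.12E-07 | 1.61E-06 (df 8) | 7.08E-08 (df 5) |
| severe, GenoCMI | 1.17E-03 | 1.06E-03 (df 4) | 1.88E-02 (df 8) |
| severe, GameteCMI | 2.24E-06 | 3.98E-03 (2N) | 1.59E-05 (4N) |
| GCC, GenoCMI | 1.36E-03 | 2.29E-02 (df 8) | 1.36E-03 (df 4) |
| HCC, GameteCMI | 2.44E-04 | 4.21E-04 (2N) | 1.77E-07 (4N) |

Two observations: the published GCC GenoCMI value equals this package's
statistic at df = 4, inconsistent with the df = 8 that reproduces the other
three 3×3 tables — most plausibly a one-off df slip in the original
analysis; and the severe-malaria row reproduces under *no* convention while
the admission row from the same cohort reproduces exactly, suggesting the
original severe-malaria analysis used slightly different counts than were
printed. Since the published GameteCMI column matches neither scaling and
the 2N scaling is the one that is chi-squared(2) calibrated, the package
does not bend its conventions to those entries; the table above is the
authoritative cross-reference and is pinned by regression tests.

## Gamete-frequency EM

Only the double-heterozygote cell has ambiguous phase. Each iteration
splits that count between the coupling (AB/ab) and repulsion (Ab/aB)
configurations in proportion `h00·h11 : h01·h10` and renormalises gamete
counts; all other cells contribute fixed gametes. Details:

* Initialisation: linkage-equilibrium product of the observed allele
  frequencies — deterministic, no random restarts. The likelihood has a
  single free parameter (h11 on its Fréchet interval) once the allele
  margins are fixed, and the EM update conserves those margins exactly at
  every iteration, so the surface is well behaved.
* Stopping: max absolute frequency change < 1e-10 *or* log-likelihood
  change < 1e-10; cap 10 000 iterations (non-convergence is flagged, never
  raised). Because the stop is tolerance-based, EM-derived quantities repeat
  under count rescaling only to ~1e-6 relative, not to machine precision.
* Degeneracy: if every individual is doubly heterozygous the two phases tie
  for any h, the linkage-equilibrium point is stationary, and it is
  returned flagged `degenerate` rather than guessing a phase.
* Boundaries: a frequency that reaches 0 stays 0 (EM fixed point); final
  frequencies are clipped to [0, 1].
* The observed-data log-likelihood uses `P(double het) = 2(h00·h11 + h01·h10)`
  and the usual products elsewhere; a zero-probability cell with positive
  count yields −∞.

The unit tests check the EM against an independent grid-search maximizer of
the observed-data likelihood (1e-4 resolution) to 2e-4 per component, and
check monotonicity of the likelihood trace.

## Logistic benchmarks

Fits are maximum-likelihood logistic regressions on the count-weighted cell
design (statsmodels GLM, IRLS, tolerance 1e-10, 100 iterations max). The
1 df test is the squared z of the interaction coefficient under a chosen
coding (additive 0/1/2, dominant 0/1/1, recessive 0/0/1 at each locus,
interaction = product of scores); the factor test is the joint Wald test on
the (r−1)(c−1) interaction dummies of the saturated model. Likelihood-ratio
variants of both are available (`statistic="lr"`); on the malaria tables
the published factor-test values (8.63E-4 admission, 1.80E-4 severe)
correspond to the LR variant, while the GCC benchmarks match the Wald
variant — both are therefore kept, Wald as default. Non-convergence and
separation (any |coefficient| > 15 on the logit scale, e.g. induced by the
severe-malaria zero-case cell) are flagged and the p-value reported as NaN;
the Monte-Carlo harness counts such replicates separately instead of
treating them as rejections or silently dropping them. A `best_coded_1df_p`
helper returns the smallest p across the three codings, explicitly labelled
as uncorrected for model selection.

## Simulator

The population is HWE at each locus and linkage equilibrium between them
(defaults p_G = 0.30, p_H = 0.42); the penetrance is logistic,
`logit f_ij = β0 + ln(OR_G)·x_i + ln(OR_H)·x_j + ln(OR_GH)·x_i·x_j`, so the
OR parameters are exact odds ratios per score unit, and β0 is solved for a
target prevalence K by a bracketing root search on [−50, 50] (the map
β0 → prevalence is strictly increasing; achieved prevalence agrees with K
to 1e-8 across codings, ORs, and K down to 1e-4). Case and control tables
are two multinomial draws from the exact retrospective conditional laws
`P(cell|case) = P_ij f_ij / K` and `P(cell|control) = P_ij(1−f_ij)/(1−K)`.

Nine scenario presets cover: the global null; main effects at one or both
loci (OR 2.0 or 3.0); a rare disease (K = 1e-4) variant of each; a 1:2
case/control variant of each; and two power designs with a genuine
interaction OR, without and with a main effect. Default arm sizes are 1000
cases / 1000 controls (2000 controls for the 1:2 designs), α = 0.01, 1000
replicates. Per-replicate seeds spawn from the master seed by a counter
(`SeedSequence((seed, replicate))`), so the simulated tables are invariant
to which metrics are evaluated.

What the generator deliberately does **not** emulate: linkage
disequilibrium between or around the test loci, recombination history,
population structure, genotyping error, missingness, or covariates. Tests
passing under this generator therefore certify the statistics' behaviour
under the idealized two-unlinked-loci case-control design, not robustness
to those real-data complications. It also parameterizes penetrance directly
through the logistic model rather than through a forward population
simulation; power at a given OR_GH is meaningful relative to this
parameterization.

## Problem sizes and observed behaviour

The test suite runs the calibration checks at the sizes the corresponding
claims use: 1000-replicate type-I error (global-null GenoCMI lands within
3 binomial SE of the ~0.009–0.010 published band; additive OR_G = 2 drives
GenoMI rejection to 1.000), 5000-replicate KS calibration at N = 2000
(GenoCMI vs chi-squared(8), GameteCMI vs chi-squared(2), both comfortably
non-rejected at α = 0.01), and 600-replicate power bounds. Monte-Carlo
bounds are asserted with a 3-binomial-SE allowance; under this
parameterization the dominant×dominant power of GenoCMI at OR_GH = 2.0 is
0.799 ± 0.005 — right at the 80% figure it is checked against, with
GameteCMI at 0.84. The expected pathologies are reproduced, not hidden: the
harness asserts GameteCMI's *inflated* type-I error (> 0.02 at α = 0.01)
under dominant-dominant main effects of OR 3.0 at both loci, the one known
failure mode of the gamete-based approach.

## Known limitations

* Diallelic loci and a single pair per table; no multi-locus haplotypes,
  covariates, or multiple-testing machinery across SNP pairs.
* GameteCMI assumes random union of gametes (HWE within strata) for phase
  inference; strong within-stratum HWE violations would bias the EM.
* The chi-squared references are asymptotic; very sparse tables (expected
  cell counts ≪ 5) are better served by exact or permutation procedures,
  which are out of scope here.
* Separated logistic fits report NaN rather than a penalized estimate;
  Firth-type corrections are not implemented.
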