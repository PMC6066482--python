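# Methods

## Network construction

Voxel maps live on a shared integer grid (no spatial normalization is
performed; the generator produces data in a common space, and registration
of real images is out of scope).  For one edge and one group, the
streamline region is the set of voxels whose across-subject connective
values test above zero by a one-sample *t*:

* **One-sided.** Streamline values are non-negative, so the test is
  one-sided greater at α = 0.05; a two-sided test against zero would be
  degenerate on the left.
* **Zero variance.** A voxel constant across subjects has an undefined *t*;
  we take the limit: constant positive ⇒ included, constant zero ⇒
  excluded.
* **No voxel-level multiplicity correction** — the raw α = 0.05 voxel
  threshold is deliberate and documented, not an oversight.
* **Group-specific regions** are the default (each subject scored against
  their own group's region), matching the per-group region definition of
  the study design; because group-specific supports can in principle
  confound group comparisons, a pooled `union` region mode is provided and
  tested.

Edge strength is the arithmetic mean FA over the region's voxels, hence in
[0, 1].  An empty region yields an explicit undefined-strength flag (NaN
with a warning), never a silent zero.

## Edge-wise group comparison

The per-edge statistic is the *t* of the group coefficient in
`strength ~ group + age + cigarettes/day` (sign: abusers minus controls).
The permutation scheme permutes raw group labels with covariates fixed to
subjects and refits the full model each draw — the most literal reading of
a "permutation test based on covariate-adjusted two-sample t scores".
Freedman–Lane-style residual permutation is noted as an alternative, not
implemented.  Implementation detail: covariates are projected out of both
the strengths and the (permuted) group indicators once, and all B × 276
statistics are computed by a batched Frisch–Waugh identity, which makes
B = 10,000 draws a seconds-scale operation.

p-values use the add-one estimator (1 + #{|t*| ≥ |t|})/(B + 1), so p ≥
1/(B + 1) and is never zero.  Consequence: at the family-wise threshold
0.05/276 = 0.00018116, B must be at least ~5,600 for significance to be
attainable at all; with the study's B = 10,000 the attainable minimum is
1/10,001 ≈ 0.0001.  Reduced permutation counts (e.g. B = 1,000) are fine
for calibration experiments but cannot flag any edge at the corrected
threshold — the pipeline therefore keeps B = 10,000 even where other
Monte-Carlo loops are scaled down.  An exhaustive mode enumerates all
case/control assignments for small n and returns the exact p.

Family-wise control is Bonferroni only; selected Diff-connections are
ordered by |t| descending with lexicographic tie-break.

## Statistical genetics

* **HWE:** Pearson goodness-of-fit χ² with df 1 (allele frequency estimated
  from the data), no continuity correction; monomorphic markers are
  rejected rather than tested.
* **Case-control association:** genotypic χ² on the 2×3 table (df 2) and
  allelic χ² on the 2×2 allele table with A-count 2n_AA + n_AG (df 1), both
  without Yates correction — this convention reproduces the published
  statistics from the published counts to printed precision.  The odds
  ratio is for allele A, cases over controls (so an OR < 1 means the
  alternate allele is enriched in cases), with a Woolf log-SE interval at
  z = 1.96 and no small-sample correction.
* **LD:** haplotype frequencies for a SNP pair are estimated by EM.  Only
  double heterozygotes are phase-ambiguous; the E-step splits them between
  the cis and trans resolutions by their current relative likelihood.
  Defaults: tolerance 1e-8 on the max haplotype-frequency change, 1000
  iterations max (non-convergence is an error carrying the iteration
  count), initialization at linkage-equilibrium products.  D′ = |D|/D_max
  with the usual D-sign-dependent D_max, defined as 0 at D = 0; r² =
  D²/(p_A q_A p_B q_B).  The log-likelihood is non-decreasing across
  iterations (tested), and r² ≤ D′² always.
* **Screen:** additive dosage (count of the designated risk allele, 0/1/2).
  The pooled main-effect model omits the group term by default (a
  `main_with_group` option adds it); the interaction model contains both
  main effects plus dosage × group, tested by the Wald p of the product
  term; within-group models are fit per stratum, with monomorphic strata
  flagged NaN.  Recoding dosage to the other allele flips slopes' signs
  and leaves p-values unchanged (tested).

## Mediation

Model: `m ~ x + covs` gives a; `y ~ x + m + covs` gives (c′, b);
`y ~ x + covs` gives c.  With the same covariate set in all three fits the
identity c = c′ + a·b is exact (asserted to 1e-10).  The indirect-effect
interval is a bias-corrected (BC, no acceleration) percentile bootstrap:
subject rows are resampled jointly, a·b recomputed per resample (batched
normal equations via pseudo-inverse; a degenerate resample gets the
minimum-norm solution, inconsequential at the tail quantiles BC reads),
z₀ = Φ⁻¹(fraction of draws below the point estimate) with the fraction
clamped to (1/(B+1), B/(B+1)), endpoints Φ(2z₀ + z_{α/2}) and
Φ(2z₀ + z_{1−α/2}).  B defaults to 10,000; tests use smaller B.  If every
draw is identical the interval degenerates to a point with a warning.

Coverage behaviour, measured here: at a planted a·b = 0.3 (n = 200,
B = 2,000) the 95% interval covers in ≈94–96% of replicates; at the null
a·b = 0 coverage sits slightly below nominal (≈89–93%), the known mild
liberality of bias-corrected intervals for a product of coefficients at
the origin.  The significance rule (interval excludes zero) therefore runs
a little anticonservative at the null, exactly as the same rule does in
the standard PROCESS-style implementation this mirrors.

## Synthetic cohort generator

The generator emulates the statistical structure the analyses assume; it
is the test bed, not a simulator of raw diffusion images, tractography or
scanner artifacts.

* **Subjects.** Two groups (default 40/group for routine runs; the worked
  example uses 78/group, the imaging-cohort scale).  Age and cigarettes/day
  are drawn group-specifically (HA 36.2 ± 3.9 y, 26.0 ± 9.1 cig/day;
  HC 37.5 ± 5.0 y, 8.7 ± 9.8 cig/day, truncated at 0), so covariate
  adjustment is exercised non-trivially: smoking is strongly
  group-separated, which inflates the adjusted group-term SE by ~1.4×
  relative to an unadjusted comparison.  This collinearity is a feature of
  the addiction setting, and it is why planted effects must be large to
  survive family-wise correction at desk-scale n (below).
* **Genotypes.** Haplotype-based: two haplotypes per subject drawn
  independently from the block's haplotype distribution, so HWE holds per
  SNP by construction.  Within a block, adjacent SNPs share haplotype
  disequilibrium D = r·√(p₁q₁p₂q₂) (a Markov chain across the block), so
  the adjacent-pair haplotype correlation is exactly r and D′/r² truths
  are well defined; infeasible (r, MAF) combinations are rejected.
  Optional per-SNP missingness exercises the call-rate filter.
* **Voxel maps.** The grid is 14×14×14 with disjoint 2×2×2 regions placed
  on a lattice — the smallest even cube holding 343 ≥ 276 disjoint blocks,
  one per edge (a 12³ grid would hold only 216).  Within its region an
  edge's FA is baseline 0.5 plus, in SD units of the per-subject edge
  noise (0.03): the group effect for affected edges, an additive genotype
  slope (control-group slope β, case slope β + interaction), and noise;
  small voxel-level noise (0.01) is superimposed and values are clipped to
  [0, 1].  The dosage term is centered at its expected value 2·MAF so the
  genotype effect does not shift group means — the planted group contrast
  stays exactly the configured effect size while the per-allele slope (the
  mediation a path) is untouched.  Streamline values are positive inside
  the region and exactly zero outside.
* **Planted effects.** Defaults: ten VTA-linked edges at −2.5 SD (the real
  study reports widespread, strongly significant deficits concentrated on
  VTA-linked connections); genotype slope −1.0 SD per risk allele in
  controls with +1.0 interaction (case slope 0), mirroring the reported
  control-only dose effect.  The −2.5 SD magnitude follows from a power
  computation: after the ~1.4× covariate-collinearity inflation the
  effective standardized difference is ~1.8, giving per-edge power > 0.999
  at the 0.05/276 threshold with n = 40/group, so full recovery of all ten
  edges is the expected outcome rather than a coin flip.  Weaker settings
  (e.g. −1.5 SD) leave per-edge power near 0.5–0.8 and recovery becomes
  seed-dependent.
* **Cognition.** MoCA = intercept + group shift·1[HA] + c′·dosage +
  b·(mean strength over affected edges) + age term + noise.  Defaults
  b = 120 MoCA points per strength unit, c′ = −0.3, noise SD 2.0: the
  planted control-group indirect effect is a·b = (−1.0·0.03)·120 = −3.6
  MoCA points per risk allele, sized so the b path is detectable at
  cohort scale (t_b ≈ b·sd(m|x)·√n/σ ≈ 5 at n = 78) — the large-effect
  regime in which the group-asymmetric mediation pattern (flagged in
  controls, absent in abusers) is a reliable consequence of the design
  rather than a sampling accident.  A side effect of this regime is that
  the simulated group MoCA gap (~10 points) is wider than clinical
  cohorts show; the generator prioritizes a recoverable causal chain over
  matching every marginal moment.  BIS-11 and IGT scores are not
  generated: no in-scope analysis consumes them.
* **Determinism.** One seeded generator drives every draw; identical
  config + seed ⇒ bit-identical cohorts, and the pipeline's output files
  are byte-identical across reruns.

What passing tests show — and don't.  Recovery, calibration and coverage
results certify the statistical machinery on data satisfying the
generative assumptions (Gaussian noise, linear effects, disjoint edge
supports, HWE, no population stratification).  They do not certify
performance on real diffusion data, where regions overlap, FA noise is
spatially correlated, and genotype effects are orders of magnitude
smaller.

## Known limitations

* Freedman–Lane permutation (residualizing covariates before permuting) is
  not implemented; raw-label permutation is slightly conservative when
  covariates are strongly group-associated.
* The mediator in the mediation stage is the mean over Diff-connections
  selected from the same case-control contrast, as in the study design;
  the circularity of that selection is reproduced, not corrected.
* Only biallelic markers are supported; VNTR-type markers would need to be
  recoded as biallelic factors upstream.
* BC (not BCa) bootstrap: no acceleration correction, with the null-side
  liberality noted above.
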