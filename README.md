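# rewardnet

Structural reward-connectome analysis with imaging genetics, for studies of
heroin addiction: build an FA-weighted 24-node reward network from voxel
maps, find edges weakened in abusers by covariate-adjusted permutation
testing, screen candidate SNPs for main and gene × addiction effects on
network strength, run case-control genetic association, and test whether
network strength mediates the genotype → cognition association.  A
synthetic-cohort generator with planted, recoverable effects makes every
stage testable without subject data.

## The analysis

**Network.** Twelve reward-related regions per hemisphere (dlPFC, ACC, VTA,
OFC, INS, VStr, caudate, AMY, HIP, THA, putamen, pallidum) are the 24 nodes;
dlPFC/ACC/OFC/INS form the reward-control subnetwork, the subcortical rest
the reward-driving subnetwork.  For each of the 276 edges, the streamline
region is the voxel set where the group's probabilistic-streamline values
are significantly above zero (one-sample *t*, one-sided, *p* < 0.05), and a
subject's edge strength is the mean FA over that region.  Edges partition
into Control (28), Driving (120) and between-subnetwork BTN (128) classes.

**Edge statistics.** Each edge is compared between groups by the *t* of the
group term in `strength ~ group + age + cigarettes/day`.  The null is
10,000 label permutations with covariates kept attached to subjects;
two-sided *p* = (1 + #{|t*| ≥ |t|}) / (B + 1).  Diff-connections are edges
with *p* below the Bonferroni threshold 0.05/276 = 0.00018116.

**Genetics.** Per-SNP call-rate QC (> 0.98), Hardy–Weinberg χ² goodness of
fit (df 1), genotypic (df 2) and allelic (df 1) Pearson χ² without
continuity correction, the allele odds ratio with Woolf log-SE 95% CI, and
pairwise linkage disequilibrium (D, D′, r²) with haplotype frequencies
estimated by EM over double-heterozygote phase ambiguity.  The imaging
screen fits additive-dosage regressions of network strength with age and
smoking as covariates, pooled, by group, and with a dosage × group
interaction.

**Mediation.** Simple mediation, genotype dosage x → network strength m →
MoCA y, with covariates in both models: a from `m ~ x`, (c′, b) from
`y ~ x + m`, c from `y ~ x`.  The indirect effect a·b satisfies
c = c′ + a·b exactly; its 95% interval is a bias-corrected bootstrap over
subject resamples, and mediation is called significant when the interval
excludes zero.

## Worked example

The numbered scripts under `analysis/` run the study on a synthetic cohort
of 78 abusers and 78 controls (seed 1):

```
$ python analysis/01_simulate_cohort.py --seed 1
$ python analysis/02_build_network.py
$ python analysis/03_edge_differences.py --seed 1
10 of 276 edges significant at p < 0.00018116 (10000 permutations)
strongest group differences (all decreases in HA):
  ACC_L -- VTA_R: t = -10.64, p = 0.00010
  ...
against planted truth: sensitivity 1.00, false positives 0

$ python analysis/04_genetics.py
published rs279858 counts reanalysed:
  genotypic chi2 = 11.31 (p = 0.003)
  allelic chi2 = 11.28 (p = 0.00078)
  allele-A OR = 0.84 (95% CI 0.76-0.93)
  case freq(A) = 0.44; HWE p: cases 0.92, controls 0.42
screen on mean Diff-connection strength (10 edges):
  rs279858: main p = 3.6e-05, interaction p = 1.1e-28, HA p = 0.28, HC p = 3.9e-28

$ python analysis/05_mediation.py --seed 1
HC (n=78): a = -0.0291, b = 144.7, indirect = -4.214, 95% BC CI (-5.882, -2.725) -> significant
HA (n=78): a = 0.0016, b = 106.2, indirect = 0.175, 95% BC CI (-0.131, 0.522) -> not significant
```

The ten planted VTA-linked deficits are recovered exactly with no false
positives; the genotype's effect on network strength appears only in
controls (the interaction term), and consequently mediation of the
genotype → cognition path through network strength is flagged in controls
and not in abusers.

The same stages are available as a CLI (`rewardnet simulate`,
`build-network`, `compare-edges`, `assoc`, `ld`, `screen`, `mediate`,
`run-all`) over TSV interchange files; every output carries a provenance
header (version, config hash, seed) and reruns are byte-identical.

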