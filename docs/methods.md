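# Methods

## The statistic

Two genes A and B are represented by additive minor-allele dosage matrices
X (m x p) and Y (m x q).  Gene-gene **co-association** is measured by the
first canonical correlation between X and Y — the maximum over weight
vectors nu, omega of corr(X nu, Y omega) — or, to capture nonlinear
dependence, by its kernel counterpart computed from m x m Gram matrices
K_x, K_y.  The test contrasts this quantity between cases (kr_D) and
controls (kr_C): each is Fisher-transformed,

    kz = 1/2 [ log(1 + kr) - log(1 - kr) ],

the variance of each transformed coefficient is estimated by a bootstrap
over individuals, and

    U = (kz_D - kz_C) / sqrt( var(kz_D) + var(kz_C) )

is referred to N(0, 1), two-sided.  The null hypothesis is *no difference
in co-association between strata*; for two unlinked genes this coincides
with no gene-gene interaction.  A permutation alternative recomputes |U|
under random relabelings of case/control status (stratum sizes preserved)
and uses the add-one estimator (1 + #{|U*| >= |U|}) / (1 + n_perm).

## Kernels and regularization

Supported kernels: linear, polynomial, RBF `k(u,v) = exp(-sigma ||u-v||^2)`
(sigma is the direct multiplier, so bandwidth sweeps over
{0.05, 0.5, 5, 50} map one-to-one), sigmoid, identity-by-state, and
MAF-weighted IBS (weights 1/sqrt(MAF) — allele sharing at rare variants
counts more).  KCCU defaults to RBF with sigma = 0.5.

Kernel CCA is ill-posed when the Gram matrices are invertible (the optimum
is exactly 1), so the constraints are penalized quadratically:

    maximize a' K_x K_y b   s.t.   a'(K_x + eta I)^2 a = b'(K_y + eta I)^2 b = 1.

The default eta is `0.1 * m * mean(diag K)`, computed per side from the
uncentred kernel diagonal (for RBF this is simply 0.1 m).  In the linear-
kernel, eta -> 0 limit the solver reproduces classical CCA; this
equivalence is enforced by tests at 1e-4 over random full-rank fixtures.

**The linear (CCU) variant also runs through the regularized solver**, with
a linear kernel.  This is deliberate: the unregularized first canonical
correlation is a boundary statistic under the null (its population value
sits at 0, the edge of the parameter space), and the n-out-of-n bootstrap
of such maxima is known to overestimate the sampling variance — we measure
inflation factors of ~1.5-2, which makes the unregularized U markedly
conservative (sd(U) ~ 0.75, type I error ~0.01 at nominal 0.05).  It is
also how the linear statistic is computed in practice: the standard kernel
CCA software regularizes every kernel, including the linear one.  The
classical, unregularized CCA solver remains available (`kccu.cca_first`,
`bootstrap_var_z(engine="cca")`) for diagnostics and as the limit oracle.
Even with the default regularization the test remains somewhat
conservative under the null of these study conditions (sd(U) ~ 0.8,
empirical type I error ~0.01-0.03 at alpha = 0.05); this is a property of
bootstrap variances for near-degenerate correlation statistics, not a
coding artifact, and it is the main caveat when comparing against nominal
levels.

## Fast exact solver for repeated evaluation

Dosage rows over a gene take few distinct values (bounded by the number of
haplotype pairs segregating in the population), so a stratum is compressed
once into unique genotype patterns per gene plus joint-pattern counts.
The nonzero spectrum of the weighted centred Gram equals that of a u x u
matrix (u = number of unique patterns), and the cross-term reduces to the
count-normalized joint-pattern table, so each evaluation costs O(u^3)
instead of O(m^3).  A bootstrap resample of individuals is equivalent in
distribution to a multinomial redraw of the joint-pattern counts, which is
what makes B = 100-200 bootstrap replicates per stratum affordable at
m = 2500.  The path is exact up to the shared relative eigenvalue cutoff
(1e-6); agreement with the dense solver is enforced at 1e-6 in tests.

## Numerical choices

- Pseudo-inverse whitening with relative singular-value cutoff 1e-10 in
  classical CCA, so SNPs in perfect LD do not crash the solver.
- Correlations are clipped at 1 - 1e-12 (with a warning) before the Fisher
  transform; degenerate bootstrap resamples (a gene collapsing to a
  constant column) are redrawn, with a hard stop at 10 B redraws.
- Sign convention: r >= 0, first nonzero left-weight positive.
- Sub-seeds for the two strata's bootstrap streams are derived from the
  master seed plus a CRC of the stratum's data bytes, so exchanging the
  case and control strata reproduces each stratum's variance estimate and
  negates U bit-exactly.
- Rejection is counted as p <= alpha.

## The synthetic-data generator

The simulator emulates a two-unlinked-gene case-control design.  Each
region is a weighted haplotype pool; region 1 has 6 SNPs, region 2 has 7.
Pools are built from a first-order binary Markov chain over alleles, which
gives exact analytic control of per-SNP minor-allele frequency and
adjacent-pair r^2; the enumerated distribution is truncated to the most
frequent haplotypes (doubling the pool size until realized MAFs are within
0.02 and adjacent r^2 within 0.1 of their targets — the defaults settle at
32 haplotypes per region).  Default targets, chosen once as typical
gene-region values: region 1 MAF (0.35, 0.28, 0.22, 0.41, 0.17, 0.30) with
adjacent r^2 (0.55, 0.45, 0.35, 0.30, 0.50); region 2 MAF (0.24, 0.33,
0.19, 0.38, 0.27, 0.45, 0.21) with adjacent r^2 (0.50, 0.40, 0.35, 0.45,
0.30, 0.40).  Phased-haplotype text files can be supplied instead of the
synthetic pool.

Individuals are random unions of two haplotypes per region; disease status
is Bernoulli with the two-locus multiplicative penetrance

    P(disease | x1, x2) = f0 * r1^x1 * r2^x2 * theta^(x1 x2),

where x1, x2 are dosages at one causal SNP per region (defaults: the 2nd
SNP of region 1 and the central 4th SNP of region 2), f0 = 0.01 baseline
penetrance, r1 = r2 = 1.2 per-allele marginal effects, and theta the
interaction odds ratio (theta = 1 is the interaction null; at f0 = 0.01
risk ratios and odds ratios agree to well under 1%).  The causal columns
are deleted before testing, so the detectable signal is carried entirely by
LD between the causal SNPs and their surviving neighbours.  The penetrance
is clipped at 1 and f0 is rescaled (with a warning) if the parameter grid
would exceed it.

What the generator does **not** emulate: genotyping error and missingness,
population structure, long-range LD between the regions, more than two
causal loci, covariates.  Passing calibration/power tests therefore speak
to the statistic's behaviour under clean two-locus architectures, not to
robustness against those artifacts.

## Experiment protocol

For each (theta, causal-pair) cell one large population is simulated
(default 100k cases + 100k controls) and every replicate subsamples n/2
cases and n/2 controls from it, mirroring a generate-once design; a cell's
rejection rate at alpha = 0.05 is reported with its binomial standard
error, and null cells add a one-sample Kolmogorov-Smirnov p-value of the U
sample against N(0, 1).  All seeds derive deterministically from the master
seed and the cell coordinates, so any execution order and any subset of
cells reproduce identical numbers.  The desk-scale profile is 200
replicates with B = 100 bootstrap resamples per stratum and total sample
sizes 1000/3000/5000 via the pattern-compressed solver; replicate counts,
B, sample sizes and population size are all config fields.

## Known limitations

- Under the interaction null both statistics are conservative (see above);
  empirical type I error runs below the nominal 0.05, more so for the
  linear variant.
- Power at small interaction odds ratios (theta <= 1.2) is low at n = 1000
  under the default generator — expected for gene-based co-association
  differences driven only by LD leakage.
- Only the first (kernel) canonical pair feeds the statistic; subsequent
  pairs are exposed for diagnostics.
- No kernel-parameter learning: sigma and eta are user-supplied (defaults
  above); a bandwidth sweep is the recommended sensitivity analysis.
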