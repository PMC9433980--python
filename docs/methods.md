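# Methods

## Plasticity as a longitudinal trait

Let x_i = (x_i(t_1), …, x_i(t_T)) and y_i be one genotype's
replicate-averaged trajectories under control and stress. The stress
response is the signed difference z_i(t_k) = x_i(t_k) − y_i(t_k),
computed elementwise with no transformation: a genotype whose stress
trajectory tracks its control trajectory (z ≈ 0) is canalized; a large
positive z means stress suppresses growth strongly. Clonal replicates are
averaged arithmetically before differencing (the summary the measurement
design implies; replicate-level modelling is out of scope). Pipeline
files are written with 17-significant-digit floats and read back with
round-trip parsing so the identity x − y = z holds exactly on disk.

## Composite functional mapping

The scan models z_i as multivariate normal about a genotype-group mean
curve with a shared longitudinal covariance.

* **Mean curves** are logistic, μ(t) = a/(1 + b·e^(−rt)) with a, b, r > 0
  (asymptote in trait units, shape, per-day rate). Fitting is multi-start
  damped Gauss–Newton over a deterministic (b, r) seed grid with
  a₀ = 1.05·max(y); flat data yield a flagged degenerate fit.
* **Covariance** is stationary AR(1): Σ_kl = σ²ρ^|k−l| with σ² the
  marginal variance and ρ the lag-1 correlation. The inverse is
  tridiagonal, so log-likelihoods cost O(T) per individual. AR(1) is the
  standard parsimonious choice for short growth series; it cannot
  represent variance that grows with the mean (a real feature of growth
  data), which mainly costs power, not calibration, because significance
  is permutation-based.
* **Null model**: one curve for everyone, fitted by alternating
  generalized-least-squares curve fitting with ρ-profiled AR(1)
  estimation until the log-likelihood changes by < 1e-6.
* **Per-SNP scan**: group-specific logistic curves with the covariance
  held fixed at the null fit. With Σ fixed, the within-group scatter
  cancels from the likelihood ratio, which then depends on the data only
  through per-group mean vectors; every (SNP, group, permutation) fit
  becomes one row of a single batched Levenberg–Marquardt solve,
  warm-started at the null curve so LR ≥ 0 holds identically. Profiling
  the covariance once is a deliberate trade: per-SNP covariance
  re-estimation would change individual LR values slightly, but the
  permutation null uses the same statistic, so the test remains
  calibrated (verified empirically: genome-wide type-I error 0.05–0.06
  at α = 0.05 over 200 null simulations).
* **Thresholds**: phenotype labels are permuted (genotypes intact), the
  genome-wide maximum LR recorded per permutation, and the empirical
  (1−α) quantile taken as the critical value, separately per marker class
  (testcross and intercross markers segregate differently). GWAS SNPs are
  scanned with up to three genotype-group curves and no
  additive/dominance parameterization; groups smaller than 5 individuals
  skip the SNP.

## Effect curves

A fitted SNP's time-varying genetic effect is the genetic standard
deviation across its genotype groups,
g_s(t) = sqrt(Σ_j p_j (μ_j(t) − μ̄(t))²) with observed group frequencies
p_j — our concrete reading of "time-varying genetic standard deviation",
chosen because it is the square root of the between-group variance at
each time and reduces to half the group gap for two balanced groups. The
curve is smoothed once by least-squares projection onto Legendre
polynomials (order 4 by default; with T = 6 measurements at most order 5
is estimable) over the affine image of the time window on [−1, 1], and
resampled on a dense uniform grid (G = 30) that all downstream stages
share. Order 4 reproduces a growth-scale logistic to ~2.6% of range on a
30-point grid (order 5: 0.8%).

## Functional clustering and the module hierarchy

Effect curves are clustered with a Gaussian mixture whose component means
are Legendre curves and whose within-component covariance is AR(1) on the
dense grid (shared σ², ρ per component). EM uses kmeans++-style seeding
from a content-ordered RNG — initialization depends on the multiset of
curves, not their input order — with 10 restarts by default and a
relative log-likelihood tolerance of 1e-6 (500-iteration cap). Emptied
components are re-seeded from the worst-fit curve.

Model size is chosen by BIC with p_K = K(order + 3) + (K − 1) parameters;
ties go to the smaller K, and the K-sweep stops after three consecutive
BIC increases (the curve is near-convex in practice). Modules larger than
the Dunbar threshold (default 150, configurable; the literature gives no
exact number) are re-clustered recursively; a unit that BIC refuses to
split is force-split with K = 2, and any unit still oversized at the
depth cap (6) is chunked deterministically so the leaf-size invariant
holds unconditionally. With heavy-tailed curve noise the mixture can
split off small outlier groups, producing deep thin branches; this is
cosmetic — the partition and size invariants still hold.

## Quasi-dynamic network reconstruction

Each node (SNP effect curve, or module mean curve) follows

    dg_s/dt = Q_s(g_s(t)) + Σ_{s′∈R(s)} Q_{s←s′}(g_{s′}(t)),

with Q_s an order-3 Legendre polynomial in the node's own value (value
range mapped to [−1, 1]) and each dependent function an order-3 Legendre
polynomial in the regulator's value with no constant term (so a constant
regulator exerts no sustained forcing and the independent/dependent split
is identified at the parameter level).

**Regulator selection.** The node's smoothed derivative is regressed on
all other curves with the LASSO; the penalty is chosen by BIC along the
regularization path and the surviving set truncated to the `max_reg`
largest coefficients (default 5; ties broken by node id). Two numerical
choices matter. First, the regression is posed in the Legendre
coefficient space of the smoothed curves (modes weighted by their L2
norms, constant dropped): an order-p smooth of G points has only p + 1
degrees of freedom, and treating the G grid values as independent
observations makes BIC wildly anti-conservative — on a clean benchmark
(derivative = 0.8 × one candidate + noise σ = 0.01, ten candidates) the
time-domain variant recovers the exact support in ~1% of replicates, the
coefficient-space variant in 98%. Second, BIC uses a residual variance
estimated from the full OLS model, floored at 1% of the signal scale so
the criterion cannot chase numerically negligible residual structure.

**Fitting.** Parameters are initialized by linear least squares on the
derivative identity and refined by Nelder–Mead on the SSE between the
classical-RK4-integrated trajectory and the observed curve (step = grid
spacing; regulator curves evaluated at half-steps from their Legendre
representations; overflow is penalized). The initial value g_s(t_1) is
attributed entirely to the independent component — regulation accrues
over the observed window.

**Decomposition and edges.** Independent and per-regulator dependent
curves are accumulated from the same RK4 stage evaluations as the net
trajectory, so their sum equals the net trajectory to machine precision
(≤1e-8 is asserted; ~1e-13 is typical). An edge s′ → s is emitted when
the dependent component is not identically zero, with weight the
time-averaged |dependent component| and sign the sign of its time
average. Node roles: leaders have above-average out-degree and in-degree
at or below the 25th percentile; workers have only incoming links.

**Multilayer assembly.** Networks are built within sibling groups only:
the top layer over root-module mean curves, one layer per internal node
over its children's means, and one SNP-level layer per leaf. No edges
cross sibling groups — that restriction is what makes genome-scale
reconstruction tractable. A module is QTL-containing if any member SNP
passed the scan.

## Synthetic data

`simulate_population` emulates the clonal two-condition design: logistic
growth with control asymptote 30 cm (b = 9, r = 0.08/day), stress
reducing the asymptote by 30%, measurements at six 20-day intervals (a
14-point 5-day schedule is provided for mapping-population designs),
n = 100 genotypes, AR(1) measurement noise (σ² = 1, ρ = 0.5), genotypes
drawn at Hardy–Weinberg proportions from uniform MAFs on [0.1, 0.5].
Planted QTLs shift the stress asymptote per alternate allele, so adjacent
genotype groups separate in late-time plasticity by the planted amount.
What this does not emulate: linkage disequilibrium, population structure,
mean-dependent variance, or missing data patterns — passing tests
demonstrate statistical correctness under the stated model, not
robustness to those features.

`simulate_curve_clusters` draws effect curves around logistic cluster
means separated by a chosen multiple of the within-cluster AR(1) noise
scale.

`simulate_effect_system` integrates planted ODE systems with fine-step
RK4 (20–40 substeps per grid interval) and optional observation noise at
a given curve-level SNR. Two self-dynamics are supported: logistic (with
a weak cubic stabilizer that prevents runaway under sustained strong
inhibition and is negligible inside the growth range) and mean-reverting
λ(κ − g). The random 10-node generator used for recovery studies builds
a driven regulatory cascade: a three-node antisymmetric (stable
oscillatory) core, feed-forward couplings below it, per-node sinusoidal
intrinsic drives at distinct half-harmonic frequencies of the window
(cyclic effect components, as seen in real QTL effect curves), and
couplings centered below the trajectory mean so each edge carries
sustained signed forcing — with a per-node constant bias that cancels the
resulting offset at baseline, so equilibria stay put and the cascade does
not amplify.

## Known limitations

Support recovery and edge-sign identification in the quasi-dynamic model
are fundamentally hard at desk scale: with ~30 grid points, SNR ~10
observation noise, and smooth mutually coupled curves, every node's curve
is close to a linear combination of a few shared system modes, and an
exhaustive best-subset oracle — an upper bound on any penalized-regression
selector — recovers only about half of planted regulators across every
generator family we evaluated. Likewise, because the target trajectory
integrates its forcing, polynomial functions of the target's own value
can mimic much of a regulator's contribution to the derivative: only the
sum of components is well determined, and the per-edge decomposition
(hence the activation/inhibition call) is not identifiable in general.
Measured recovery rates are reported as-is by `scripts/acceptance.py`;
treat reconstructed edges as hypotheses for enrichment-style aggregate
analysis rather than as individually validated interactions. The
conservation property of the decomposition, by contrast, is exact and
always enforced.

## Problem sizes

The acceptance battery uses: 200 null and 200 power replicates at
n = 100, T = 6, a 20-SNP panel, 200 permutations; 20 clustering
replicates of 300 curves; 50 planted 10-node networks; and one
end-to-end GWAS-preset run (n = 100, m = 500, 200 permutations). These
sizes make the full battery a single-CPU job of some minutes while
keeping every estimate's Monte-Carlo error well below the margins being
tested.
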