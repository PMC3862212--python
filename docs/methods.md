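# Methods

## Model and assumptions

Counts are organized as K×S tables over CDR3 types for four sources:
WT-MC, WT-SC, MT-MC, MT-SC.  One frequency vector θ on the K-simplex is
assumed common to all samples and, under the null, to both cell
populations; a cross-subject homogeneity check on the least-distorted
source (WT-SC) motivates that pooling.  WT and MT-SC counts are
multinomial.  MT-MC counts are modeled hierarchically: independent Poisson
survivor counts `Z_{i,t} ~ Poisson(s_i θ_t f_i)` for the 6-TG bottleneck,
then `Y_i^mc | Z_i ~ DM(n_i^mc, φ Z_i)` for unequal clonal growth — the
Dirichlet weight of a clone is proportional to its founder count times a
Gamma(φ, 1) growth factor.  The DM family is closed under merging
categories (parameters add), so analyses at coarser type resolutions stay
inside the model.

Priors: flat Dirichlet(1,…,1) on θ.  For φ the default prior is
**log-uniform on [1e-4, 1e6]**.  A flat-on-φ prior truncated at a large
ceiling is offered (`phi_prior="flat"`) but not the default, for a reason
worth recording: as φ → ∞ the DM likelihood tends to a positive constant
(Z can absorb the observed proportions), so the marginal posterior mass of
the flat prior's tail grows linearly with the ceiling and, for weakly
informative data, swamps the φ-identified mode.  We verified this against
an exact small-instance posterior (K = 2, Z marginalized by truncated
summation): the sampler reproduces the exact posterior, and under the flat
prior that exact posterior concentrates near the ceiling even when the
data were generated at φ = 1.  The log-uniform (Jeffreys-type) prior for
this scale parameter restores data-driven inference: in simulations at
s·f = 10 the 90% posterior interval for φ covered the generating value in
29/30 replicates.

## Posterior computation

A Metropolis–Hastings block sampler targets p(z, θ, φ | y), conditioning on
the MT data only.  Per scan, in order:

- **Z block**: one symmetric ±1 Metropolis sweep over all (i, t).  Moves
  below the support floor (z ≥ 1 wherever y^mc ≥ 1) have zero target
  density and are auto-rejected; detailed balance holds coordinatewise.
  The acceptance ratio is evaluated from closed-form log-gamma differences,
  O(1) per coordinate.
- **θ block**: Dirichlet(c·θ) proposal with the asymmetric proposal
  densities in the ratio.  Because Σθ = 1 the Poisson means contribute
  Σ_t (Σ_i z_{i,t}) log θ_t, so the θ-target given (Z, SC counts) is
  Dirichlet-shaped; that conjugacy is used only as a test oracle, the
  update itself stays MH.
- **φ block**: Gaussian random walk on log φ (Jacobian included when the
  prior is flat on φ), truncated to the prior's support.

The θ and φ blocks repeat 5 and 2 cheap sub-moves per scan; the Z sweep
dominates the scan cost and the sub-moves cut the θ autocorrelation about
3.5-fold.  Proposal scales (c, initialized at 500·K, and the φ step,
initialized at 0.3) adapt toward 20–40% acceptance during burn-in only and
are frozen afterwards, preserving the invariant law of the saved draws.
Initialization: θ at pooled empirical frequencies (pseudocount 1),
z at max(1[y>0], round(s_i f_i θ̂)), φ at 1.  Defaults: 2000 burn-in scans,
10⁴ saved draws, thin 1.  The inner loops are numba-compiled; the
per-block Python functions are thin wrappers over the same kernels, so
there is one code path.  Correctness checks: conjugate-Dirichlet oracle
(no-MC data), truncated-Poisson oracle for Z, an exact φ posterior on a
small grid, and a Geweke-style successive-conditional comparison on a tiny
instance with φ held fixed — fixing φ keeps the comparison sharp, since
forward draws from the very diffuse φ prior would dominate the statistics
with uninformative extremes.

## The conditional predictive p-value

The pooled WT vector x (total m = 683 for the J-region data) is compared
with its posterior predictive law given the MT data: p_cp = P{p(X_rep|y) ≤
p(x|y) | y}, ties included.  One Multinomial(m, θ⁽ᵍ⁾) replicate is drawn
per saved θ draw, so the Monte Carlo size equals the saved-draw count; the
p-value lives on {0, 1/G, …, 1}.  The ordinate p(·|y) is evaluated
analytically after a method-of-moments Dirichlet approximation to p(θ|y):
per category α0_t = m_t(1−m_t)/v_t − 1 from the draw mean and variance,
aggregated by the mean-weighted average over non-degenerate categories and
capped at 1e8; α = m_t·α0.  The same fitted Dirichlet scores the observed
and every replicated vector, since all are ordinates of one fixed
conditional law.  On the packaged J-region data with the default
bottleneck metadata the full-scale pipeline gives p_cp ≈ 0.045, and the
value is stable (≈ 0.03–0.06) when the assumed expected survivor count
s·f is varied 3–30, so the borderline conclusion does not hinge on the
unpublished per-sample metadata.

## Baselines

**Fisher**: the K×2 table pools WT (MC+SC) against MT (MC+SC); the
conditional null given both margins is multivariate hypergeometric
(sampling and ordinates via scipy), with exact enumeration whenever the
margin-constrained table space has ≤ 1e6 tables and Monte Carlo (default
1e5 tables, ties included) otherwise.  **Likelihood ratio**: posterior
means stand in for MLEs (fit once under the null's common θ on all data,
once for the MT data alone, once for the WT data alone); the MT-MC
marginal likelihood is estimated by forward-simulating Z conditioned on a
nonempty bottleneck — the same convention the simulator uses; the
conditioning constant depends only on s_i·f_i and cancels from the ratio —
with a log-sum-exp average; Λ = 2(ℓ_alt − ℓ_null) is referred to χ² on
K−1 degrees of freedom (the alternative frees one extra simplex vector).
A negative or undefined Λ (a plug-in/simulation artifact) reports p = 1
with a warning.

## Synthetic data and operating characteristics

The generator draws the full hierarchy per sample; samples whose bottleneck
comes up empty are redrawn (an empty culture would never reach sequencing),
with redraws logged.  The J-matched configuration uses the six observed
per-sample sequencing depths; its frequency and overdispersion settings are
the posterior means from a fit to the J-region data (θ^mt, φ ≈ 0.45), with
the WT conjugate posterior mean as θ^wt under the alternative, and the
documented default bottleneck s = 1e6, f = 1e-5.  Since the study's own
per-sample bottleneck inputs and parameter settings were not published,
experiment reports flag the replication as approximate.  Reduced defaults
(R = 200 replicates, 2000 saved draws per replicate) keep experiment runs
at desk scale; the full-scale settings are R = 1000 and 10⁴ draws.

What the generator does *not* emulate: sequencing error, PCR amplification
noise, cross-subject frequency heterogeneity, or finer-than-configured type
resolution.  Passing operating-characteristics tests therefore demonstrate
properties of the method under its own sampling model, not robustness to
those artifacts.

A finding worth knowing when interpreting calibration runs: at the
J-region sample sizes the null law of p_cp is close to, but measurably not,
uniform — e.g. P(p ≤ 0.10) ≈ 0.11–0.12 — and the deviation persists in an
exact conjugate construction with no MCMC at all, so it is a finite-sample
property of the construction itself (the predictive law is wider than the
fixed-truth multinomial law of the observed WT vector).  It shrinks with
sequencing depth, consistently with the asymptotic uniformity result, and
a 500-replicate Kolmogorov–Smirnov test at the 1% level sits right at the
detection boundary for it.

## Numerical choices

All pmfs are computed via log-gamma; totals near 100 overflow raw
factorials.  DM parameters equal to zero follow the Γ→∞ limit (factor 1
when the count is zero, probability 0 otherwise).  Ordinate ties use a
1e-9 log-scale tolerance in the Fisher enumeration/Monte Carlo; the
predictive-ordinate comparison needs none because observed and replicated
ordinates share one code path.  The χ²-density level-set p-value h(v)
solves f(v′) = f(v) on the far side of the mode by bracketed bisection
(tolerance 1e-10); df ≤ 2 uses the monotone-density closed form
h(v) = P(U ≥ v), which for df = 2 is exp(−v/2).  Seeds: all randomness
flows through numpy Generators or the numba global RNG seeded once per
chain; fixed seeds give bit-identical draws.

## Known limitations

- φ inference depends on the prior when the data carry little
  overdispersion information (few samples, shallow sequencing); the
  diagnostics flag φ as unidentified when no MC data are present.
- The LR baseline's marginal-likelihood estimator uses prior sampling of
  Z and degrades when the assumed s·f is far from the data-compatible
  range; its p-value inherits plug-in noise of a few hundredths.
- The moment-matched Dirichlet is a single-precision summary of the θ
  posterior; heavy posterior tails (very small s·f with strong clonal
  spikes) are summarized, not represented.
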