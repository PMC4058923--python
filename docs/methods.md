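# Methods

## Model

`dynb` models one gene's read-count time course as a latent smooth
trajectory observed through overdispersed counting noise.

**Latent trajectory.** The expression level over time, f(t), carries a
Gaussian-process prior with squared-exponential covariance

    Cov(f(t_p), f(t_q)) = sigma1 * exp(-(t_p - t_q)^2 / (2 u^2 / sigma2)),

with mean level m. Per gene, m is the mid-range of the observed counts,
`(max(y) + min(y))/2`, the amplitude variance is `sigma1 = 500 * m`, and
the smoothness parameter is `sigma2 = 0.75` on a kernel time unit of
`u = 48 h`. With these values the correlation length is 48–68 h over a
72-h design: trajectories are smooth at the scale of the sampling grid,
values between design timepoints are pinned by interpolation, and the
amplitude prior is informative enough to charge all candidate time-warps a
comparable smoothness cost — which is what makes the discrete warp
identifiable (see below). A second amplitude parameter, theta1 = 10 ×
Stdev{y} (floored at 10 for constant genes), and a smoothness parameter
theta2 with a uniform prior on [0.5, 1] parameterize the kernel used by
the sampler's hyperparameter block.

**Observation model.** A count y_j(t_i) from replicate j at design time
t_i is negative binomial with mean `mu = s_{j,i} * f(t'_{j,i})` and
variance `sigma^2(mu)` from a pooled mean–variance polynomial (below);
s_{j,i} is the sample's size factor, and t' is the replicate's rescaled
time. The NB is moment-parameterized: success probability
`p = (sigma^2 - mu)/sigma^2` and size `r = mu^2/(sigma^2 - mu)`, which
requires strict overdispersion — guaranteed by the variance floor.
Trajectory values must be strictly positive at every evaluation point
(identity link); proposals violating this get log-likelihood −inf and are
rejected rather than clamped.

**Replicate time rescaling.** Biological replicates may differentiate at
different speeds. Replicate j observes the shared trajectory at effective
times `t' = k_j * t`, with k_j on a discrete grid defined by the time
difference Δ it induces at the last design timepoint T:
`Δ ∈ {−32, −28, …, +32} h` in 4-h steps at T = 72 h, i.e.
`k = 1 + Δ/T` with extreme factors 5/9 and 13/9. A designated reference
replicate is pinned at k = 1 for identifiability. The prior on Δ is a
discretized normal centered at zero delay with scale 8 h (two grid
steps, configurable, including an informative shifted variant): wide
enough for the data to dominate for genuinely delayed replicates
(tens of nats), narrow enough to resist the sub-nat pulls that arise when
a replicate's high-count draws sit a noise-sd off a rising curve, which
mimics a small shift.

## Normalization and the variance function

Size factors use the median-of-ratios estimator (per sample, the median
over genes of count / per-gene geometric mean, computed over genes nonzero
in every sample) and are rescaled to geometric mean 1 so that fits are
comparable across runs. The estimator assumes most genes are stable
across samples; panels in which a majority of genes change strongly over
time violate it, so the simulated panels keep induced genes a minority.

The variance polynomial `sigma^2(mu) = a0 + a1 mu + a2 mu^2` is fitted to
pooled (mean, unbiased variance) pairs of size-factor-normalized counts
across replicates, for every (gene, condition, timepoint) cell, by
non-negative least squares. Two estimator details matter in practice:

* **GLS weighting** (`weighted=True`): a 3-replicate variance estimate has
  sampling variance ≈ sigma^4, so squared residuals are weighted by
  1/sigma-hat^4 and the fit is iterated to convergence. Unweighted least
  squares lets high-mean cells pollute the linear coefficient by two
  orders of magnitude when means span 1–10^4. The unweighted variant
  remains the default switch position for compatibility, but the weighted
  fit is used and recommended throughout.
* **Outlier trimming**: cells whose variance exceeds 20× the first-pass
  fit (probability ~1e-9 under the NB with 3 replicates) are systematic
  effects — typically a replicate with shifted dynamics — and are dropped
  before the final fit; otherwise a single strongly delayed gene dominates
  the quadratic coefficient.

Evaluation floors the polynomial at `mu * 1.01` so sigma^2 > mu always
holds (epsilon = 0.01; near-Poisson floor).

## Posterior sampling

Each iteration composes four reversible Metropolis–Hastings kernels:

1. **theta2**: truncated-normal random walk on [0.5, 1] (sd 0.01), with
   the truncation normalizers in the acceptance ratio.
2. **Time shifts**: each non-reference replicate proposes ±4 h or stay
   with probability 1/3 each; outward proposals at the grid boundary carry
   zero prior mass and are rejected. Every 5th iteration, a realignment
   move additionally proposes an arbitrary grid shift for one replicate
   and redraws the trajectory at that replicate's exclusively-used
   evaluation points — points the new alignment uses are proposed at the
   replicate's own normalized counts with the NB scale, abandoned points
   at their conditional-prior mean — with the full proposal and
   conditional-prior ratios in the acceptance. Without this move a shift
   can only be accepted when the trajectory already fits the new
   alignment, which traps chains in local alignment modes.
3. **Global trajectory move**: preconditioned Crank–Nicolson (pCN) under
   the GP prior; prior-reversible, so acceptance is the likelihood ratio
   alone.
4. **Windowed trajectory move**: pCN within a random contiguous time
   window under the conditional GP prior given the rest of the curve.

pCN step sizes are drawn per move from small ladders
(global {0.002, 0.02, 0.1, 0.5}; window {0.01, 0.1, 0.5, 1.0}) so that
both low-expressed timepoints (tight likelihood) and high-expressed ones
mix without tuning. With time scaling the trajectory is represented on
the fixed union of all possible rescaled timepoints (69 points for the
default design and grid), so the state dimension never changes.

Chains are initialized at theta2 = 0.75, identity scaling, and a GP
interpolation of the pooled normalized counts ("empirical" init; the GP
prior mean is available as an option). Random-walk equilibration from the
prior mean takes many thousands of iterations for strongly induced genes,
so the data-driven start is the default. Defaults are 4 chains of 30 000
iterations with 10 000 burn-in, sized so that the Gelman–Rubin statistic
of the benchmark fit is below 1.1; convergence should be checked with
`DyNBResults.psrf` on any new data.

## Evidence, Bayes factors and the differential call

The marginal likelihood of a fit is the harmonic mean of posterior-sample
likelihoods, computed with a log-sum-exp transform; a bootstrap spread
over chain resamples is attached to every estimate because the estimator
is heavy-tailed. Differential dynamics between two conditions compares
M1 (one fit per condition) against M0 (a single fit pooling all
replicates of both conditions, each keeping its own size factors and —
when enabled — its own scaling factor, with one global reference):

    BF = exp(logML(c1) + logML(c2) − logML(pooled)),

and a gene is called differential when BF > 10 and the pseudocounted
posterior-mean trajectories differ more than two-fold at at least one
design timepoint, `max_t max(rho, 1/rho) > 2` with
`rho = (mean_c1 + 1)/(mean_c2 + 1)`. Genes with zero counts in all
samples of either condition are excluded from testing and flagged. No
multiple-testing correction is applied: the decision rule is the per-gene
BF/fold-change criterion.

Posterior trajectory summaries (mean and pointwise 95% band) interpolate
each stored trajectory sample onto a dense grid with shape-preserving
monotone cubic (PCHIP) interpolation — exact at the evaluation points.
(The GP conditional mean is unusable here: the near-singular kernel matrix
over closely spaced points filters out exactly the sharp-rise components
the likelihood pinned.)

## Synthetic data

The generator draws counts `y ~ NB(s * template(k t), sigma^2(.))` from
smooth parametric templates (flat, logistic induction/repression,
Gaussian transient), per-sample size factors log-uniform on [2/3, 3/2],
and a quadratic dispersion polynomial (default (0, 1, 0.05)).

* **Delayed-replicate benchmark** (`fig2_benchmark`): one condition,
  three replicates at {0, 12, 24, 48, 72} h; the benchmark gene follows
  an IL17A-like logistic induction (baseline 100, amplitude 1e4, midpoint
  56 h, slope 0.2/h) with replicate noise `sigma^2 = mu + 0.01 mu^2`
  (CV ≈ 10% when strongly expressed); replicate 1 is delayed with
  Δ = −24 h (k = 2/3), replicate 2 is the reference. A 300-gene
  background panel with exchangeable replicates (70% flat, 30% induced)
  lets size factors and the variance polynomial be estimated from data
  rather than supplied as ground truth. The amplitude 1e4 keeps the
  trajectory in the regime where the amplitude prior (500 × mid-range) is
  weaker than the NB likelihood at every timepoint; far above it the
  prior visibly shrinks the fitted curve (see limitations).
* **Null panel**: both conditions share each gene's template (30%
  induced), for Bayes-factor calibration.
* **Differential panel**: flat in one condition, ~100-fold induction in
  the other, on top of a non-differential background, for power checks.

What the generator does not emulate: per-gene dispersion variation
(a single polynomial generates and fits all genes), count outliers,
transcript-length or GC effects, correlated replicates, and any
read-level structure — simulation starts at the count matrix, matching
the model's data type. Passing tests therefore demonstrate internal
consistency and calibration under the model's own assumptions, not
robustness to real-data artifacts beyond those listed.

## Numerical choices

* Covariance jitter: 1e-6 × the kernel amplitude on diagonals; Cholesky
  retried with a larger ridge on failure.
* Acceptance ratios entirely in log space; the harmonic mean never
  exponentiates raw likelihoods.
* Equal prior model probabilities; no prior-odds knob.
* Per-gene fit seeds derive from a master seed and the gene id (CRC32),
  so genome-wide screens are reproducible and parallelizable.
* Test-suite problem sizes: calibration panels run 100 null and 20
  differential genes at 2 000 iterations/1 chain; recovery panels use
  2 000 simulated genes; the benchmark fit uses the full defaults.

## Design decisions on open points

* **Time-scaling convention**: effective time t' = k·t with
  Δ(T) = T(k − 1); the factor-inverse convention (t/k) is available via
  `convention="divide"` and reports the reciprocal factors for identical
  scaled times.
* **sigma1 rule**: `500 × (max + min)/2`, read as the amplitude variance;
  configurable via `default_priors(sigma1=...)`.
* **Stdev floor**: theta1 = 10 × max(Stdev{y}, 1) so constant genes keep a
  proper kernel.
* **theta1 scope**: the standard deviation is taken over all samples of
  the fit (not per condition).
* **M0 pooling**: 2M replicates of one process, per-replicate size
  factors and scaling factors, one global reference.
* **k in M1**: estimated per condition (each condition's fit carries its
  own replicate scaling factors).

## Known limitations

* The amplitude prior `sigma1 = 500 m` becomes *informative* for genes
  whose counts exceed ~10^4–10^5: the fitted trajectory is visibly shrunk
  toward the mid-range, and the time-difference posterior can shift by one
  grid step (shrinkage on a rising curve mimics a time shift). Raising
  `sigma1` removes the shrinkage but weakens warp identifiability; the
  default follows the balance described above.
* Credible bands are slightly anticonservative (~87% empirical coverage at
  a nominal 95% on the simulation panels), driven by the same prior
  shrinkage at trajectory extremes and finite chain length.
* The harmonic-mean evidence estimator is consistent but heavy-tailed;
  the reported bootstrap spread understates the true error when the
  likelihood has a long lower tail. Bayes factors near the decision
  threshold should be re-run with more chains.
* Accelerated replicates (positive Δ) are recovered with a mild bias
  toward identity (typically one to two grid steps at |Δ| = 16 h), because
  compression moves late observations into the interpolated interior where
  the trajectory is less constrained.
* The one-step shift walk alone mixes poorly across alignment modes; the
  realignment move is required. Disabling it (`k_realign=False`)
  reproduces the bare walk for diagnostic purposes only.
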