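# dynb

Bayesian analysis of **differential gene-expression dynamics** in
replicated RNA-seq time courses, with correction for replicate-specific
differentiation speed.

Timepoint-by-timepoint tests (DESeq-style) ignore the temporal correlation
of a time course and cannot tell a genuinely different response from one
that is merely *delayed* in one biological replicate — a common situation
in cell-differentiation experiments (e.g. T-helper-17 polarization), where
cultures from different donors progress at different speeds. `dynb`
addresses both problems with a single generative model per gene:

* a latent smooth expression trajectory f(t) with a Gaussian-process prior,
  `Cov(f(t_p), f(t_q)) = σ₁ exp(−½ σ₂ |t_p − t_q|²)` (distances in units of
  48 h);
* a negative-binomial observation model,
  `y_j(t_i) ~ NB(mean = s_{j,i} · f(t'_{j,i}), variance = σ²(mean))`, with
  median-of-ratios size factors s and a pooled quadratic mean–variance
  polynomial σ²(μ) = a₀ + a₁μ + a₂μ² shared across genes;
* a discrete per-replicate time rescaling `t' = k_j · t`, k on a grid of
  time differences Δ ∈ {−32, …, +32} h (4-h steps) at the last timepoint,
  with a reference replicate pinned at k = 1;
* MCMC posterior sampling of (f, θ₂, k), and model selection between
  shared dynamics (M0: one fit pooling both conditions) and
  condition-specific dynamics (M1: one fit per condition) by the Bayes
  factor `BF = p(y|M1)/p(y|M0)` from harmonic-mean marginal likelihoods.

A gene is called differential when **BF > 10** and the posterior-mean
trajectories differ more than **two-fold** at at least one timepoint.

## Worked example

Reproduce the delayed-replicate simulation benchmark: one strongly induced
IL17A-like gene measured in three replicates at {0, 12, 24, 48, 72} h,
where replicate 1 is a delayed version of the others — its nominal 72 h
sample reflects the 48 h state (Δ = −24 h, k = 2/3).

```python
from dynb import *
from dynb.model import DyNBModel

cm, sheet, truth = fig2_benchmark(seed=0)          # counts + design + ground truth
sf = estimate_size_factors(cm)                     # median-of-ratios
vf = fit_variance_function(cm, sheet, sf, weighted=True)
model = DyNBModel.from_dataframe(cm, sheet, "IL17A_like", "Th17", sf, vf,
                                 timescale=True, reference="r2")
result = model.fit(seed=0)
print(result.summary())
```

```
DyNB fit: gene IL17A_like
  replicates: r1, r2, r3  (reference: r2)
  timepoints (h): 0, 12, 24, 48, 72
  chains: 4 x 30000 iterations (burn-in 10000)
  acceptance rate: 0.576
  log marginal likelihood (harmonic mean): -103.057 (bootstrap se 0.110)
  PSRF (log-likelihood): 1.019
  posterior trajectory (normalized counts):
    time_h      mean     lower95    upper95
         0     110.9      95.0     129.4
        12     111.6      94.3     128.6
        24      99.9      84.5     117.4
        48    1489.1    1305.0    1664.7
        72    6804.1    6027.7    7583.5
  posterior-mode time difference at 72 h per replicate:
    r1: -24 h
    r2: +0 h
    r3: +4 h
```

The fit recovers the delay exactly: replicate 1's posterior-mode time
difference at nominal 72 h is **−24 h** (effective time 48 h), replicate 3
sits within one 4-h grid step of no delay, and the Gelman–Rubin statistic
(PSRF) near 1 confirms the four chains agree. The trajectory block is the
posterior mean and 95% credible band of the latent expression curve on the
size-factor-normalized count scale.

For a two-condition differential screen:

```python
from dynb.model import run_de_analysis
table, excluded, results = run_de_analysis(cm, sheet)  # per-gene log10 BF, FC, call
```

## Command line

```bash
dynb simulate --scenario fig2 --seed 0 --outdir sim/     # counts.tsv, samples.tsv, truth.json
dynb fit  --counts sim/counts.tsv --samples sim/samples.tsv \
          --condition Th17 --timescale --reference r2 --genes IL17A_like
dynb test --counts counts.tsv --samples samples.tsv --outdir out/   # results.tsv
```

Every run writes a `provenance.json` (config hash, seed, package version)
next to its outputs.

## Layout

| Module | Contents |
| --- | --- |
| `dynb.io` | count-matrix / sample-sheet / result-table TSV I/O and validation |
| `dynb.normalization` | size factors, pooled mean–variance polynomial |
| `dynb.model_core` | kernel, NB parameterization, time-scaling grid, priors, likelihood |
| `dynb.sampler` | MCMC kernels (pCN trajectory moves, shift walk, realignment), PSRF |
| `dynb.inference` | harmonic-mean evidence, Bayes factors, posterior summaries, calls |
| `dynb.model` | `DyNBModel` / `DyNBResults`, `compare_dynamics`, `run_de_analysis` |
| `dynb.synthetic` | simulation scenarios and ground-truth bookkeeping |
| `dynb.cli` | `dynb simulate | fit | test` |

See `docs/methods.md` for the full model description, estimator details,
design decisions and known limitations.
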