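"""Evidence estimation, Bayes factors and posterior summaries.

The marginal likelihood of a fit is estimated by the harmonic mean of the
posterior-sample likelihoods, computed entirely in log space.  Differential
dynamics between two conditions is quantified by the Bayes factor

    BF = p(y | M1) / p(y | M0),

where M1 fits one model per condition and M0 a single pooled model, and a
gene is called differential when BF > 10 (strong evidence) and the
posterior-mean trajectories differ more than two-fold at some timepoint.

The harmonic-mean estimator is simple but notoriously heavy-tailed; a
bootstrap spread over chain resamples is reported alongside every estimate
so its stability is visible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .model_core import KERNEL_TIME_SCALE_H
from .sampler import Chain

__all__ = [
    "log_marginal_likelihood",
    "bayes_factor",
    "log10_bayes_factor",
    "posterior_trajectory",
    "timescale_posterior",
    "fold_change",
    "call_differential",
    "DEResult",
]

#: strong-evidence threshold on the Bayes factor
BF_THRESHOLD = 10.0
#: fold-change threshold (at least one timepoint must exceed it)
FC_THRESHOLD = 2.0


@dataclass
class DEResult:
    """Differential-dynamics call for one gene."""

    gene_id: str
    log10_bf: float
    fold_changes: np.ndarray
    differential: bool
    times: np.ndarray
    delta_mode: dict = field(default_factory=dict)

    @property
    def max_abs_log2_fc(self) -> float:
        return float(np.max(np.abs(np.log2(self.fold_changes))))


def _pooled_logliks(chains) -> np.ndarray:
    if isinstance(chains, Chain):
        chains = [chains]
    lls = np.concatenate([c.post_burn_in(c.loglik) for c in chains])
    if lls.size == 0:
        raise ValueError("no post-burn-in samples")
    finite = np.isfinite(lls)
    if not finite.all():
        if not finite.any():
            raise ValueError("all stored log-likelihoods are -inf")
        warnings.warn(
            f"excluding {np.sum(~finite)} non-finite log-likelihood samples "
            "from the harmonic-mean estimate",
            RuntimeWarning,
        )
        lls = lls[finite]
    return lls


def log_marginal_likelihood(chains) -> float:
    """Harmonic-mean log evidence from one chain or a list of chains.

    log p(y) ≈ log n − logsumexp(−ℓ_i) over post-burn-in log-likelihoods
    ℓ_i; finite for arbitrary likelihood spread.
    """
    lls = _pooled_logliks(chains)
    return float(np.log(lls.size) - logsumexp(-lls))


def log_marginal_likelihood_bootstrap(chains, n_boot: int = 200, seed: int = 0):
    """Bootstrap standard error of the harmonic-mean log evidence."""
    lls = _pooled_logliks(chains)
    rng = np.random.default_rng(seed)
    est = np.empty(n_boot)
    for b in range(n_boot):
        res = rng.choice(lls, size=lls.size, replace=True)
        est[b] = np.log(res.size) - logsumexp(-res)
    return float(np.std(est, ddof=1))


def log10_bayes_factor(logml_c1: float, logml_c2: float, logml_pooled: float) -> float:
    """log10 BF of condition-specific (M1) over shared (M0) dynamics."""
    return (logml_c1 + logml_c2 - logml_pooled) / np.log(10.0)


def bayes_factor(logml_c1: float, logml_c2: float, logml_pooled: float) -> float:
    """BF = exp(logML(c1) + logML(c2) − logML(pooled)); may overflow to inf."""
    with np.errstate(over="ignore"):
        return float(np.exp(logml_c1 + logml_c2 - logml_pooled))


def posterior_trajectory(chains, grid, kernel_time_scale_h=KERNEL_TIME_SCALE_H):
    """Pointwise posterior mean and 95% credible band of f on a dense grid.

    Each stored f sample is carried onto ``grid`` by shape-preserving
    (monotone cubic) interpolation through its evaluation points — exact at
    the points themselves — and the band is the pointwise 2.5%/97.5%
    sample quantile.  Trajectories are on the size-factor-normalized count
    scale.
    """
    from scipy.interpolate import PchipInterpolator

    if isinstance(chains, Chain):
        chains = [chains]
    c0 = chains[0]
    grid = np.asarray(grid, dtype=float)
    lo_t, hi_t = c0.eval_times.min(), c0.eval_times.max()
    if grid.min() < lo_t - 1e-9 or grid.max() > hi_t + 1e-9:
        warnings.warn(
            f"trajectory grid [{grid.min()}, {grid.max()}] extrapolates beyond the "
            f"evaluated range [{lo_t}, {hi_t}]",
            RuntimeWarning,
        )
    samples = np.concatenate([c.post_burn_in(c.f) for c in chains], axis=0)
    if samples.shape[1] == 1:
        curves = np.repeat(samples, grid.size, axis=1)
    else:
        curves = PchipInterpolator(
            c0.eval_times, samples, axis=1, extrapolate=True
        )(grid)
    mean = curves.mean(axis=0)
    lower, upper = np.quantile(curves, [0.025, 0.975], axis=0)
    return mean, lower, upper


def timescale_posterior(chains, replicate: int):
    """Empirical posterior mass of the time difference Δ for one replicate.

    Returns (delta_grid, mass); mass sums to 1.  Requires a fit with time
    scaling enabled.
    """
    if isinstance(chains, Chain):
        chains = [chains]
    c0 = chains[0]
    if c0.grid is None:
        raise ValueError("time scaling was not enabled for this fit")
    deltas = np.concatenate([c.post_burn_in(c.deltas[:, replicate]) for c in chains])
    mass = np.array([np.mean(np.isclose(deltas, d)) for d in c0.grid.deltas])
    return c0.grid.deltas.copy(), mass


def delta_posterior_mode(chains, replicate: int) -> float:
    """Posterior-mode time difference (hours) for one replicate."""
    deltas, mass = timescale_posterior(chains, replicate)
    return float(deltas[int(np.argmax(mass))])


def fold_change(mean_c1, mean_c2) -> np.ndarray:
    """Per-timepoint fold change between posterior-mean trajectories.

    Pseudocounted and symmetric: max(rho, 1/rho) with
    rho = (mean_c1 + 1) / (mean_c2 + 1); always >= 1.
    """
    r = (np.asarray(mean_c1, float) + 1.0) / (np.asarray(mean_c2, float) + 1.0)
    return np.maximum(r, 1.0 / r)


def call_differential(bf: float, fcs) -> bool:
    """Strong evidence (BF > 10) plus > 2-fold change at >= 1 timepoint."""
    return bool(bf > BF_THRESHOLD and np.max(fcs) > FC_THRESHOLD)
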