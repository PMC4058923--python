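"""Model ingredients: GP prior, NB observation model, time scaling, priors.

The latent gene-expression trajectory f is a Gaussian-process realization on
the count scale, observed through a negative binomial whose mean is the
size-factor-scaled trajectory value and whose variance comes from the pooled
mean–variance polynomial.  Replicate-specific differentiation efficiency is
modelled by a discrete rescaling of the time axis: replicate j observes the
shared trajectory at effective times k_j * t, with a reference replicate
pinned at k = 1 for identifiability.

Kernel distances are measured in units of ``KERNEL_TIME_SCALE_H`` hours
(two days by default) so that the default smoothness prior
theta2 ~ U[0.5, 1] corresponds to length scales of 48-68 h over a 72-h
design: trajectories are genuinely smooth, values between design
timepoints are pinned by interpolation rather than free, and a one-step
(4 h) rescaling of a replicate's evaluation grid changes the likelihood
continuously.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "KernelHyperparams",
    "GPPriorSpec",
    "TimescaleGrid",
    "PriorSpec",
    "se_kernel",
    "gp_covariance",
    "nb_params_from_moments",
    "nb_log_pmf",
    "scaled_times",
    "timescale_grid",
    "joint_log_likelihood",
    "loglik_from_means",
    "match_times",
    "default_priors",
    "delay_prior",
    "KERNEL_TIME_SCALE_H",
]

#: hours per kernel time unit; see module docstring
KERNEL_TIME_SCALE_H = 48.0

#: relative jitter added to covariance diagonals
JITTER = 1e-6


@dataclass(frozen=True)
class KernelHyperparams:
    """Squared-exponential hyperparameters.

    theta1 : signal variance (count^2).
    theta2 : inverse squared length scale, per squared kernel time unit
        (days by default); the default prior is U[0.5, 1].
    """

    theta1: float
    theta2: float

    def __post_init__(self):
        if not (self.theta1 > 0 and self.theta2 > 0):
            raise ValueError("kernel hyperparameters must be positive")


@dataclass(frozen=True)
class GPPriorSpec:
    """GP prior on f: mean level m, signal variance sigma1, smoothness sigma2."""

    m: float
    sigma1: float
    sigma2: float = 0.75

    def __post_init__(self):
        if self.sigma1 <= 0:
            raise ValueError("sigma1 must be positive")
        if self.m < 0:
            raise ValueError("prior mean level must be non-negative for count data")


def se_kernel(tp, tq, theta: KernelHyperparams, time_scale_h: float = KERNEL_TIME_SCALE_H):
    """Squared-exponential covariance theta1 * exp(-theta2 * d^2 / 2).

    ``tp`` and ``tq`` are in hours; the distance d is measured in kernel
    time units (``time_scale_h`` hours each).
    """
    d = (np.asarray(tp, dtype=float) - np.asarray(tq, dtype=float)) / time_scale_h
    return theta.theta1 * np.exp(-0.5 * theta.theta2 * d * d)


def gp_covariance(
    times,
    theta: KernelHyperparams,
    jitter: float | None = None,
    time_scale_h: float = KERNEL_TIME_SCALE_H,
) -> np.ndarray:
    """Dense covariance matrix over a time grid (hours), plus diagonal jitter.

    The jitter defaults to ``JITTER * theta1`` and keeps the matrix positive
    definite when timepoints nearly coincide.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 1:
        raise ValueError("times must be a non-empty 1-D vector")
    if jitter is None:
        jitter = JITTER * theta.theta1
    d = (t[:, None] - t[None, :]) / time_scale_h
    K = theta.theta1 * np.exp(-0.5 * theta.theta2 * d * d)
    K[np.diag_indices_from(K)] += jitter
    return K


def nb_params_from_moments(mu: float, sigma2: float) -> tuple[float, float]:
    """Solve the NB (r, p) from mean and variance.

    p = (sigma2 - mu) / sigma2 and r = mu^2 / (sigma2 - mu); the resulting
    NB(r, p) (r failures, success probability p) has mean mu and variance
    sigma2.  Requires sigma2 > mu > 0 (strict overdispersion).
    """
    mu = float(mu)
    sigma2 = float(sigma2)
    if not mu > 0:
        raise ValueError("mu must be positive")
    if not sigma2 > mu:
        raise ValueError(
            f"variance {sigma2} must exceed mean {mu}; floor it via the variance function"
        )
    p = (sigma2 - mu) / sigma2
    r = mu * mu / (sigma2 - mu)
    return r, p


def nb_log_pmf(y, mu, sigma2):
    """Log pmf of the moment-parameterized negative binomial (vectorized).

    With r = mu^2/(sigma2-mu) and success probability p = (sigma2-mu)/sigma2:

        log P(y) = lgamma(y+r) - lgamma(r) - lgamma(y+1)
                   + r*log(mu/sigma2) + y*log((sigma2-mu)/sigma2)
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(mu <= 0) or np.any(sigma2 <= mu):
        raise ValueError("requires sigma2 > mu > 0")
    r = mu * mu / (sigma2 - mu)
    return (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1.0)
        + r * np.log(mu / sigma2)
        + y * np.log1p(-mu / sigma2)
    )


def scaled_times(times, k: float, convention: str = "multiply"):
    """Effective observation times of a replicate with scaling factor k.

    Under the default ``multiply`` convention the effective time is
    ``k * t``, so the time difference at the last design timepoint T is
    ``T * (k - 1)``.  ``divide`` gives ``t / k`` (the factor-inverse
    parameterization of the same family of warps).
    """
    t = np.asarray(times, dtype=float)
    if not k > 0:
        raise ValueError("time-scaling factor k must be positive")
    if convention == "multiply":
        return k * t
    if convention == "divide":
        return t / k
    raise ValueError(f"unknown timescale convention {convention!r}")


@dataclass(frozen=True)
class TimescaleGrid:
    """Discrete grid of allowed time rescalings.

    ``deltas`` are the time differences (hours) induced at the last design
    timepoint ``t_end``; ``ks`` are the matching scaling factors under the
    chosen convention.  The grid always contains the identity scaling.
    """

    t_end: float
    deltas: np.ndarray
    ks: np.ndarray
    step: float
    convention: str = "multiply"

    @property
    def n(self) -> int:
        return len(self.deltas)

    @property
    def identity_index(self) -> int:
        return int(np.argmin(np.abs(self.deltas)))

    def index_of_delta(self, delta: float) -> int:
        i = int(np.argmin(np.abs(self.deltas - delta)))
        if abs(self.deltas[i] - delta) > 1e-9:
            raise ValueError(f"delta {delta} is not on the grid")
        return i


def timescale_grid(
    t_end: float = 72.0,
    max_shift: float = 32.0,
    step: float = 4.0,
    convention: str = "multiply",
) -> TimescaleGrid:
    """Build the discrete scaling grid: Δ from −max_shift to +max_shift in steps.

    With the defaults (72, 32, 4) the grid has 17 points and extreme factors
    5/9 and 13/9.
    """
    if step <= 0 or max_shift <= 0:
        raise ValueError("step and max_shift must be positive")
    n_steps = max_shift / step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(f"step {step} does not divide max_shift {max_shift}")
    if not t_end > max_shift:
        raise ValueError("t_end must exceed max_shift")
    n_steps = int(round(n_steps))
    deltas = step * np.arange(-n_steps, n_steps + 1, dtype=float)
    k_mult = 1.0 + deltas / t_end
    if convention == "multiply":
        ks = k_mult
    elif convention == "divide":
        ks = 1.0 / k_mult
    else:
        raise ValueError(f"unknown timescale convention {convention!r}")
    return TimescaleGrid(float(t_end), deltas, ks, float(step), convention)


def delay_prior(grid: TimescaleGrid, mode_delta: float = 0.0, sd_h: float = 8.0) -> np.ndarray:
    """Discretized normal prior mass over the Δ grid.

    The default (mode 0, scale of two grid steps) is the symmetric prior
    centered at identity scaling; it resists the sub-nat likelihood pulls
    that arise when a replicate's high-count draws sit a noise-sd off a
    rising trajectory (which mimics a small time shift), while genuine
    delays — tens of nats — override it.  A nonzero mode gives an
    informative delay prior for designs where replicates are known to lag.
    """
    z = (grid.deltas - mode_delta) / sd_h
    mass = np.exp(-0.5 * z * z)
    return mass / mass.sum()


@dataclass
class PriorSpec:
    """Gene-specific priors and fixed hyperparameters.

    theta1 is fixed to 10 * Stdev{y}; theta2 gets a uniform prior on
    [0.5, 1].  The GP prior on f has mean level m = (max(y)+min(y))/2,
    signal variance sigma1 = 500 * m and smoothness sigma2 = 0.75.  The
    discrete time-scaling factor k has the prior mass ``k_prior_mass`` over
    the grid Δ values (symmetric and centered at zero delay by default).
    """

    theta1: float
    theta2_bounds: tuple[float, float]
    gp: GPPriorSpec
    k_prior_mass: np.ndarray | None = None
    grid: TimescaleGrid | None = None

    def __post_init__(self):
        lo, hi = self.theta2_bounds
        if not (0 < lo < hi):
            raise ValueError("invalid theta2 prior bounds")
        if self.k_prior_mass is not None:
            mass = np.asarray(self.k_prior_mass, dtype=float)
            if np.any(mass < 0) or abs(mass.sum() - 1.0) > 1e-9:
                raise ValueError("k prior mass must be a probability vector")
            self.k_prior_mass = mass


def default_priors(
    y,
    grid: TimescaleGrid | None = None,
    k_prior_sd_h: float = 8.0,
    k_prior_mode_h: float = 0.0,
    sigma1_scale: float = 500.0,
    sigma1: float | None = None,
    sigma2: float = 0.75,
    theta2_bounds: tuple[float, float] = (0.5, 1.0),
) -> PriorSpec:
    """Gene-specific default priors from the observed counts.

    theta1 = 10 * max(Stdev{y}, 1) (the floor guards constant genes);
    m = (max(y) + min(y)) / 2; the GP amplitude variance is
    sigma1 = sigma1_scale * m (500 times the mid-range by default).  This
    amplitude is deliberately informative: it regularizes all candidate
    time-warps with a comparable smoothness cost and pins the trajectory's
    interpolation between design timepoints, which is what makes the
    discrete warp identifiable.  Pass ``sigma1`` to override directly.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("empty count vector")
    sd = float(np.std(y, ddof=1)) if y.size > 1 else 0.0
    theta1 = 10.0 * max(sd, 1.0)
    m = float(y.max() + y.min()) / 2.0
    m = max(m, 1.0)  # keep the GP prior proper for all-zero genes
    if sigma1 is None:
        sigma1 = sigma1_scale * m
    k_mass = None
    if grid is not None:
        k_mass = delay_prior(grid, mode_delta=k_prior_mode_h, sd_h=k_prior_sd_h)
    return PriorSpec(
        theta1=theta1,
        theta2_bounds=theta2_bounds,
        gp=GPPriorSpec(m=m, sigma1=sigma1, sigma2=sigma2),
        k_prior_mass=k_mass,
        grid=grid,
    )


def loglik_from_means(y, mu, vf) -> float:
    """Joint NB log-likelihood of counts given per-observation means.

    ``y`` and ``mu`` are matched arrays; ``mu`` holds the size-factor-scaled
    trajectory values s_{j,i} * f(t'_{j,i}).  Returns −inf if any mean is
    non-positive (the identity link requires a strictly positive trajectory
    at every evaluation point).
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if y.shape != mu.shape:
        raise ValueError(f"count shape {y.shape} != mean shape {mu.shape}")
    if np.any(mu <= 0):
        return -np.inf
    var = vf(mu)
    return float(np.sum(nb_log_pmf(y, mu, var)))


def match_times(eval_times, wanted) -> np.ndarray:
    """Indices of ``wanted`` times within ``eval_times`` (tolerance 1e-6 h)."""
    eval_times = np.asarray(eval_times, dtype=float)
    wanted = np.asarray(wanted, dtype=float)
    idx = np.empty(wanted.shape, dtype=np.intp)
    flat = idx.ravel()
    for n, t in enumerate(wanted.ravel()):
        j = int(np.argmin(np.abs(eval_times - t)))
        if abs(eval_times[j] - t) > 1e-6:
            raise ValueError(f"time {t} h not on the evaluation grid")
        flat[n] = j
    return idx


def joint_log_likelihood(y, f, times, ks, sf, vf, eval_times=None,
                         convention: str = "multiply") -> float:
    """Time-scaled joint log-likelihood for one gene and one condition group.

    Parameters
    ----------
    y : (R, N) counts for R replicates at N design timepoints.
    f : latent trajectory values at ``eval_times`` (count scale).
    times : (N,) design timepoints in hours.
    ks : (R,) per-replicate time-scaling factors (reference has k = 1).
    sf : (R, N) per-sample size factors.
    vf : callable mean → variance (the pooled variance function).
    eval_times : grid on which ``f`` is tabulated; defaults to the sorted
        union of the replicates' scaled timepoints.

    The replicate-j observation at design time t_i is NB with mean
    ``sf[j, i] * f(scaled t_i)`` and variance from ``vf`` at that mean.
    """
    y = np.asarray(y, dtype=float)
    times = np.asarray(times, dtype=float)
    ks = np.asarray(ks, dtype=float)
    sf = np.asarray(sf, dtype=float)
    if y.ndim != 2 or y.shape != sf.shape or y.shape != (len(ks), len(times)):
        raise ValueError("inconsistent shapes for y, sf, ks, times")
    scaled = np.stack([scaled_times(times, k, convention) for k in ks])
    if eval_times is None:
        eval_times = np.unique(np.round(scaled.ravel(), 9))
    f = np.asarray(f, dtype=float)
    idx = match_times(eval_times, scaled)
    mu = sf * f[idx]
    return loglik_from_means(y, mu, vf)
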