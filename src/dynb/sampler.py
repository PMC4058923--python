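"""MCMC sampling of (f, theta2, k) and convergence diagnostics.

Each iteration composes four reversible Metropolis–Hastings kernels on the
target p(theta2) p(k) p(f) p(y | f, k):

* a truncated-normal random walk on theta2 over [0.5, 1] (the truncation
  normalizers enter the acceptance ratio — they do not cancel near the
  bounds);
* the discrete time-shift move: every non-reference replicate proposes one
  grid step up, one down, or stay, each with probability 1/3 (outward
  proposals at the grid boundary carry zero prior mass and are always
  rejected); periodically this is complemented by a realignment move that
  jointly proposes an arbitrary grid shift for one replicate and resamples
  the trajectory at that replicate's exclusively-used evaluation points
  from their conditional GP prior — the conditional-prior proposal cancels
  against the prior in the acceptance ratio, so the move is accepted on the
  shift prior and likelihood alone.  Without it, a shift move can only be
  accepted when the trajectory already fits the new alignment, which traps
  chains in local alignment modes;
* a global preconditioned Crank–Nicolson (pCN) move of the latent
  trajectory under its GP prior;
* a windowed pCN move that resamples a random contiguous time window of f
  from its conditional GP prior given the rest of the trajectory.

pCN moves are prior-reversible, so their acceptance ratio is the
likelihood ratio alone; this keeps the acceptance of trajectory updates
independent of the near-singular prior covariance that arises on the dense
union grid of rescaled timepoints.  Move scales (pCN beta) are drawn per
iteration from a small ladder, giving robust mixing for genes whose counts
span several orders of magnitude.  All ratios are computed in log space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import ndtr

from .model_core import (
    KERNEL_TIME_SCALE_H,
    KernelHyperparams,
    PriorSpec,
    TimescaleGrid,
    gp_covariance,
    loglik_from_means,
    match_times,
    scaled_times,
)

__all__ = ["MHConfig", "Chain", "GeneData", "run_mh", "run_chains", "k_move", "psrf"]

#: pCN step-size ladders; scales are drawn at random each move so that both
#: low-expressed timepoints (tight likelihood) and high-expressed ones mix
BETA_GLOBAL = (0.002, 0.02, 0.1, 0.5)
BETA_WINDOW = (0.01, 0.1, 0.5, 1.0)
#: every how many iterations the realignment move runs
REALIGN_EVERY = 5


@dataclass
class MHConfig:
    """Sampler settings.

    ``theta2_proposal_sd`` is the truncated-normal random-walk scale for
    the kernel hyperparameter (default 0.01); k moves are one grid step
    with probability 1/3 each way.  ``f_init`` chooses the trajectory
    initialization: ``empirical`` (GP interpolation of the pooled
    normalized counts; default) or ``prior_mean``.
    """

    n_iter: int = 30_000
    burn_in: int = 10_000
    n_chains: int = 4
    seed: int = 0
    theta2_proposal_sd: float = 0.01
    theta2_init: float = 0.75
    f_init: str = "empirical"  # or "prior_mean"
    delta_init: tuple | None = None  # per-replicate Δ (h); reference entry ignored
    k_realign: bool = True
    prior_only: bool = False

    def __post_init__(self):
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("require 0 <= burn_in < n_iter")
        if self.theta2_proposal_sd <= 0:
            raise ValueError("theta2 proposal sd must be positive")


@dataclass
class GeneData:
    """One gene's data for a single DyNB fit (one or a pooled condition group).

    counts, size_factors : (R, N) arrays over replicates × design timepoints.
    times : (N,) design timepoints (hours).
    reference : index of the replicate with k fixed to 1.
    """

    counts: np.ndarray
    size_factors: np.ndarray
    times: np.ndarray
    replicate_labels: list[str]
    reference: int = 0
    timescale: bool = False

    def __post_init__(self):
        self.counts = np.atleast_2d(np.asarray(self.counts, dtype=float))
        self.size_factors = np.atleast_2d(np.asarray(self.size_factors, dtype=float))
        self.times = np.asarray(self.times, dtype=float)
        if self.counts.shape != self.size_factors.shape:
            raise ValueError("counts and size factors must have matching shapes")
        if self.counts.shape[1] != self.times.size:
            raise ValueError("column count must equal the number of timepoints")
        if not 0 <= self.reference < self.counts.shape[0]:
            raise ValueError("reference replicate index out of range")

    @property
    def n_replicates(self) -> int:
        return self.counts.shape[0]


@dataclass
class Chain:
    """Accepted MCMC samples for one chain.

    ``f`` has shape (n_iter, G) over the evaluation grid ``eval_times``;
    ``deltas`` holds the per-replicate time differences at the last design
    timepoint (hours); ``loglik`` is the joint NB log-likelihood of the
    stored state (the quantity entering the harmonic-mean evidence).
    """

    f: np.ndarray
    theta2: np.ndarray
    deltas: np.ndarray
    loglik: np.ndarray
    eval_times: np.ndarray
    burn_in: int
    n_accepted: int
    priors: PriorSpec
    grid: TimescaleGrid | None
    reference: int
    replicate_labels: list[str]

    @property
    def n_iter(self) -> int:
        return len(self.theta2)

    @property
    def acceptance_rate(self) -> float:
        """Fraction of trajectory (pCN) proposals accepted."""
        return self.n_accepted / (2 * self.n_iter)

    def post_burn_in(self, arr: np.ndarray) -> np.ndarray:
        return arr[self.burn_in:]


def k_move(delta: float, grid: TimescaleGrid, rng: np.random.Generator) -> float:
    """Propose Δ ± one grid step or stay, each with probability 1/3.

    Off-grid results (outside the ± max shift) are returned as proposed;
    the acceptance step rejects them through the zero prior mass outside
    the grid.  The current Δ must itself lie on the grid.
    """
    grid.index_of_delta(delta)  # contract check
    return delta + grid.step * float(rng.integers(-1, 2))


def _truncnorm_logpdf(x: float, mean: float, sd: float, lo: float, hi: float) -> float:
    z = ndtr((hi - mean) / sd) - ndtr((lo - mean) / sd)
    return float(
        -0.5 * ((x - mean) / sd) ** 2 - np.log(sd) - 0.5 * np.log(2 * np.pi) - np.log(z)
    )


def _truncnorm_sample(mean: float, sd: float, lo: float, hi: float,
                      rng: np.random.Generator) -> float:
    for _ in range(1000):  # acceptance prob >= ~0.5 when mean is inside [lo, hi]
        x = mean + sd * rng.standard_normal()
        if lo <= x <= hi:
            return float(x)
    raise RuntimeError("truncated-normal rejection sampler failed; sd too large?")


def _eval_grid(data: GeneData, grid: TimescaleGrid | None):
    """Evaluation grid for f and per-(k, timepoint) index maps.

    With time scaling the grid is the sorted union of every possible scaled
    timepoint (all grid factors × all design times), so the dimension of f
    is fixed across iterations; without it, the design timepoints.
    """
    if data.timescale and grid is not None:
        all_times = np.concatenate(
            [scaled_times(data.times, 1.0 + d / grid.t_end) for d in grid.deltas]
        )
        eval_times = np.unique(np.round(all_times, 9))
        index_map = np.stack(
            [
                match_times(eval_times, scaled_times(data.times, 1.0 + d / grid.t_end))
                for d in grid.deltas
            ]
        )  # (n_grid, N)
        return eval_times, index_map
    eval_times = np.asarray(data.times, dtype=float)
    index_map = np.arange(eval_times.size, dtype=np.intp)[None, :]
    return eval_times, index_map


class _WindowMove:
    """Conditional-prior pCN resampling of a contiguous index window.

    For window W with complement O, the GP prior conditional is
    N(mu_c(f_O), K_c); the pCN update
    f*_W = mu_c + sqrt(1-beta^2) (f_W - mu_c) + beta L_c z
    preserves the full GP prior, so acceptance is the likelihood ratio.
    All solve factors depend only on the fixed prior covariance and are
    precomputed.
    """

    def __init__(self, K: np.ndarray, idx: np.ndarray):
        self.idx = idx
        n = K.shape[0]
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        self.other = np.where(~mask)[0]
        Koo = K[np.ix_(self.other, self.other)]
        Kwo = K[np.ix_(idx, self.other)]
        Kww = K[np.ix_(idx, idx)]
        if self.other.size:
            self.gain = Kwo @ np.linalg.inv(Koo)
            Kc = Kww - self.gain @ Kwo.T
        else:
            self.gain = np.zeros((idx.size, 0))
            Kc = Kww
        Kc = 0.5 * (Kc + Kc.T)
        Kc[np.diag_indices_from(Kc)] += 1e-12 * np.trace(Kc) / max(len(Kc), 1)
        self.chol = np.linalg.cholesky(Kc)

    def propose(self, f: np.ndarray, m: np.ndarray, beta: float,
                rng: np.random.Generator) -> np.ndarray:
        dev = f - m
        mu_c = self.gain @ dev[self.other]
        z = self.chol @ rng.standard_normal(self.idx.size)
        f_star = f.copy()
        f_star[self.idx] = (
            m[self.idx] + mu_c + np.sqrt(1.0 - beta * beta) * (dev[self.idx] - mu_c)
            + beta * z
        )
        return f_star


def _make_windows(eval_times: np.ndarray, K: np.ndarray) -> list[_WindowMove]:
    """Overlapping time windows covering the evaluation grid at two scales."""
    t0, t1 = eval_times.min(), eval_times.max()
    span = max(t1 - t0, 1.0)
    windows = []
    for width in (span / 3.0, span / 6.0):
        step = width / 2.0
        start = t0
        while start < t1 - 1e-9:
            idx = np.where((eval_times >= start - 1e-9) & (eval_times < start + width))[0]
            if idx.size and idx.size < eval_times.size:
                windows.append(_WindowMove(K, idx))
            start += step
    if not windows:  # degenerate tiny grids
        windows.append(_WindowMove(K, np.arange(eval_times.size)))
    return windows


def _realign_move(f, kidx, ll, j, ki_star, data, prior_cov, m_vec, index_map,
                  log_k_prior, loglik, vf, rng, prior_only):
    """Joint (time shift, trajectory) realignment proposal for replicate j.

    The evaluation points used exclusively by replicate j (in the current
    or proposed alignment) are redrawn: points the proposed alignment will
    use are centered at the replicate's own normalized counts with the NB
    scale, points it abandons at their conditional GP-prior mean.  The
    acceptance ratio carries the shift prior, the conditional-prior ratio
    of the redrawn block and the forward/reverse proposal densities, so
    the kernel is exact; the data-informed centering merely makes jumps
    into a distant, tight alignment basin acceptably probable.

    Returns (ll, f, kidx) on acceptance, (ll, None, None) otherwise.
    """
    G = f.size
    R = data.n_replicates
    used_other = np.zeros(G, dtype=bool)
    for o in range(R):
        if o != j:
            used_other[index_map[kidx[o]]] = True
    W = np.unique(np.concatenate([index_map[kidx[j]], index_map[ki_star]]))
    W = W[~used_other[W]]
    if W.size == 0:
        return ll, None, None
    O = np.setdiff1d(np.arange(G), W)
    dev = f - m_vec
    Kwo = prior_cov[np.ix_(W, O)]
    Koo = cho_factor(prior_cov[np.ix_(O, O)], lower=True)
    solve_ow = cho_solve(Koo, Kwo.T)
    cond_mean = m_vec[W] + Kwo @ cho_solve(Koo, dev[O])
    Kc = prior_cov[np.ix_(W, W)] - Kwo @ solve_ow
    Kc = 0.5 * (Kc + Kc.T)
    Kc[np.diag_indices_from(Kc)] += 1e-10 * max(np.trace(Kc), 1.0) / len(Kc)
    chol_c = np.linalg.cholesky(Kc)
    cond_sd = np.sqrt(np.diag(Kc))

    def centers(ki):
        c = cond_mean.copy()
        s = np.maximum(cond_sd.copy(), 1e-3)
        for i, w in enumerate(index_map[ki]):
            loc = np.where(W == w)[0]
            if loc.size:
                y = max(data.counts[j, i] / data.size_factors[j, i], 0.5)
                c[loc] = y
                s[loc] = max(
                    float(np.sqrt(vf(y))) / data.size_factors[j, i], 1e-3
                )
        return c, s

    def diag_logpdf(x, c, s):
        return float(
            -0.5 * np.sum(((x - c) / s) ** 2)
            - np.sum(np.log(s))
            - 0.5 * x.size * np.log(2 * np.pi)
        )

    def cond_logpdf(x):
        w = solve_triangular(chol_c, x - cond_mean, lower=True, check_finite=False)
        return float(
            -0.5 * (w @ w)
            - np.sum(np.log(np.diag(chol_c)))
            - 0.5 * x.size * np.log(2 * np.pi)
        )

    c_fwd, s_fwd = centers(ki_star)
    fW_star = c_fwd + s_fwd * rng.standard_normal(W.size)
    f_star = f.copy()
    f_star[W] = fW_star
    c_rev, s_rev = centers(kidx[j])
    kidx_star = kidx.copy()
    kidx_star[j] = ki_star
    ll_star = loglik(f_star, kidx_star)
    log_r = (
        float(log_k_prior[ki_star] - log_k_prior[kidx[j]])
        + (cond_logpdf(fW_star) - cond_logpdf(f[W]))
        + (ll_star - ll)
        + (diag_logpdf(f[W], c_rev, s_rev) - diag_logpdf(fW_star, c_fwd, s_fwd))
    )
    if np.log(rng.uniform()) < log_r:
        return ll_star, f_star, kidx_star
    return ll, None, None


def run_mh(
    data: GeneData,
    priors: PriorSpec,
    vf,
    cfg: MHConfig,
    grid: TimescaleGrid | None = None,
    rng: np.random.Generator | None = None,
    kernel_time_scale_h: float = KERNEL_TIME_SCALE_H,
) -> Chain:
    """Run one MCMC chain for a single DyNB fit.

    ``vf`` maps means to NB variances.  When ``data.timescale`` is False
    the k updates are skipped and all replicates keep k = 1.  With
    ``cfg.prior_only`` the likelihood term is dropped (for validating the
    sampler against the prior).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    timescale = data.timescale and grid is not None
    if data.timescale and grid is None:
        raise ValueError("time scaling requested but no grid supplied")
    eval_times, index_map = _eval_grid(data, grid)
    G = eval_times.size
    R = data.n_replicates
    lo, hi = priors.theta2_bounds

    if timescale:
        if priors.k_prior_mass is None or len(priors.k_prior_mass) != grid.n:
            raise ValueError("priors lack a k prior mass matching the grid")
        with np.errstate(divide="ignore"):
            log_k_prior = np.log(priors.k_prior_mass)

    # fixed GP prior on f (m, sigma1, sigma2) and precomputed move structures
    prior_cov = gp_covariance(
        eval_times,
        KernelHyperparams(priors.gp.sigma1, priors.gp.sigma2),
        time_scale_h=kernel_time_scale_h,
    )
    chol_prior = np.linalg.cholesky(prior_cov)
    m_vec = np.full(G, priors.gp.m)
    windows = _make_windows(eval_times, prior_cov)

    def loglik(f: np.ndarray, kidx: np.ndarray) -> float:
        if cfg.prior_only:
            return 0.0
        mu = data.size_factors * f[index_map[kidx]]  # (R, N)
        return loglik_from_means(data.counts, mu, vf)

    def rep_loglik(f: np.ndarray, j: int, ki: int) -> float:
        if cfg.prior_only:
            return 0.0
        mu = data.size_factors[j] * f[index_map[ki]]
        return loglik_from_means(data.counts[j], mu, vf)

    # initial state
    theta2 = float(np.clip(cfg.theta2_init, lo, hi))
    kidx = np.full(R, grid.identity_index if timescale else 0, dtype=np.intp)
    if timescale and cfg.delta_init is not None:
        for j, dv in enumerate(cfg.delta_init):
            if j != data.reference and dv is not None:
                kidx[j] = grid.index_of_delta(float(dv))
    if cfg.f_init == "prior_mean" or cfg.prior_only:
        f = m_vec.copy()
    elif cfg.f_init == "empirical":
        # GP interpolation through the pooled normalized counts, plus one
        # small prior-shaped jitter so chains start from distinct states
        ybar = (data.counts / data.size_factors).mean(axis=0)
        theta_p = KernelHyperparams(priors.gp.sigma1, priors.gp.sigma2)
        Ktt = gp_covariance(data.times, theta_p, time_scale_h=kernel_time_scale_h)
        dxt = (eval_times[:, None] - data.times[None, :]) / kernel_time_scale_h
        Kxt = priors.gp.sigma1 * np.exp(-0.5 * priors.gp.sigma2 * dxt * dxt)
        f = priors.gp.m + Kxt @ cho_solve(cho_factor(Ktt, lower=True), ybar - priors.gp.m)
        f = np.maximum(f, 1.0)
        f = np.maximum(f + 0.02 * (chol_prior @ rng.standard_normal(G)), 1.0)
    else:
        raise ValueError(f"unknown f_init {cfg.f_init!r}")
    ll = loglik(f, kidx)

    out_f = np.empty((cfg.n_iter, G))
    out_t2 = np.empty(cfg.n_iter)
    out_d = np.empty((cfg.n_iter, R))
    out_ll = np.empty(cfg.n_iter)
    n_acc = 0

    non_ref = [j for j in range(R) if j != data.reference]
    deltas_of = grid.deltas if timescale else None

    for it in range(cfg.n_iter):
        # --- theta2: truncated-normal random walk on its uniform prior
        t2_star = _truncnorm_sample(theta2, cfg.theta2_proposal_sd, lo, hi, rng)
        log_r = (
            _truncnorm_logpdf(theta2, t2_star, cfg.theta2_proposal_sd, lo, hi)
            - _truncnorm_logpdf(t2_star, theta2, cfg.theta2_proposal_sd, lo, hi)
        )
        if np.log(rng.uniform()) < log_r:
            theta2 = t2_star

        # --- k: one-step walk (plus a periodic realignment move below)
        if timescale:
            moves = rng.integers(-1, 2, size=R)
            moves[data.reference] = 0
            kidx_star = kidx + moves
            if np.all((kidx_star >= 0) & (kidx_star < grid.n)):
                ll_star = loglik(f, kidx_star)
                log_r = (
                    float(log_k_prior[kidx_star].sum() - log_k_prior[kidx].sum())
                    + ll_star - ll
                )
                if np.log(rng.uniform()) < log_r:
                    kidx, ll = kidx_star, ll_star
            # off-grid proposals are rejected outright (zero prior mass)

            if cfg.k_realign and it % REALIGN_EVERY == REALIGN_EVERY - 1:
                for j in non_ref:
                    ki_star = int(rng.integers(grid.n))  # symmetric global proposal
                    if ki_star == kidx[j]:
                        continue
                    self_ll, self_f, self_kidx = _realign_move(
                        f, kidx, ll, j, ki_star, data, prior_cov, m_vec,
                        index_map, log_k_prior, loglik, vf, rng, cfg.prior_only,
                    )
                    if self_f is not None:
                        f, kidx, ll = self_f, self_kidx, self_ll

        # --- f: global pCN move (prior-reversible; likelihood-ratio accept)
        beta = BETA_GLOBAL[rng.integers(len(BETA_GLOBAL))]
        z = chol_prior @ rng.standard_normal(G)
        f_star = m_vec + np.sqrt(1.0 - beta * beta) * (f - m_vec) + beta * z
        ll_star = loglik(f_star, kidx)
        if np.log(rng.uniform()) < ll_star - ll:
            f, ll = f_star, ll_star
            n_acc += 1

        # --- f: windowed conditional pCN move
        win = windows[rng.integers(len(windows))]
        beta = BETA_WINDOW[rng.integers(len(BETA_WINDOW))]
        f_star = win.propose(f, m_vec, beta, rng)
        ll_star = loglik(f_star, kidx)
        if np.log(rng.uniform()) < ll_star - ll:
            f, ll = f_star, ll_star
            n_acc += 1

        if np.isnan(ll):
            raise FloatingPointError(f"NaN log-likelihood at iteration {it}")

        out_f[it] = f
        out_t2[it] = theta2
        out_d[it] = deltas_of[kidx] if timescale else 0.0
        out_ll[it] = ll

    if n_acc == 0:
        warnings.warn(
            "no accepted trajectory moves in the whole chain; check the variance "
            "function and priors",
            RuntimeWarning,
        )
    return Chain(
        f=out_f,
        theta2=out_t2,
        deltas=out_d,
        loglik=out_ll,
        eval_times=eval_times,
        burn_in=cfg.burn_in,
        n_accepted=n_acc,
        priors=priors,
        grid=grid if timescale else None,
        reference=data.reference,
        replicate_labels=list(data.replicate_labels),
    )


def run_chains(
    data: GeneData,
    priors: PriorSpec,
    vf,
    cfg: MHConfig,
    grid: TimescaleGrid | None = None,
    kernel_time_scale_h: float = KERNEL_TIME_SCALE_H,
) -> list[Chain]:
    """Run ``cfg.n_chains`` independent chains with seeds spawned from ``cfg.seed``."""
    seqs = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    return [
        run_mh(data, priors, vf, cfg, grid=grid, rng=np.random.default_rng(s),
               kernel_time_scale_h=kernel_time_scale_h)
        for s in seqs
    ]


def psrf(traces) -> float:
    """Gelman–Rubin potential scale reduction factor of a scalar statistic.

    ``traces`` is a sequence of >= 2 equal-length 1-D arrays (post-burn-in
    samples per chain).  Returns sqrt(((n-1)/n * W + B/n) / W), the classic
    between/within variance ratio; identical chains give sqrt((n-1)/n) <= 1.
    """
    traces = [np.asarray(t, dtype=float) for t in traces]
    if len(traces) < 2:
        raise ValueError("PSRF needs at least 2 chains")
    n = len(traces[0])
    if any(len(t) != n for t in traces) or n < 2:
        raise ValueError("chains must have equal length >= 2")
    means = np.array([t.mean() for t in traces])
    W = float(np.mean([t.var(ddof=1) for t in traces]))
    B_over_n = float(means.var(ddof=1))
    if W == 0:
        return 1.0
    var_plus = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_plus / W))
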