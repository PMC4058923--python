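"""Library-size normalization and the pooled mean–variance function.

Size factors use the median-of-ratios estimator: each sample's factor is the
median, over genes, of the ratio of its count to the gene's geometric mean
across samples.  The negative-binomial variance is modelled as a quadratic
polynomial of the (normalized) mean, fitted by pooling replicate-level
sample means and variances across genes, conditions and timepoints —
genes expressed at a similar level are assumed to share a similar variance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .io import CountMatrix, SampleSheet

__all__ = [
    "SizeFactors",
    "VarianceFunction",
    "estimate_size_factors",
    "fit_variance_function",
]


class EstimationError(RuntimeError):
    pass


@dataclass
class SizeFactors:
    """Per-sample scaling factors, rescaled to geometric mean 1."""

    sample_ids: list[str]
    factors: np.ndarray

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if np.any(self.factors <= 0) or not np.all(np.isfinite(self.factors)):
            raise EstimationError("size factors must be positive and finite")

    def __getitem__(self, sample_id: str) -> float:
        return float(self.factors[self.sample_ids.index(sample_id)])

    def for_samples(self, sample_ids) -> np.ndarray:
        return np.array([self[s] for s in sample_ids])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dict(zip(self.sample_ids, self.factors.tolist())), fh, indent=1)


@dataclass
class VarianceFunction:
    """Quadratic mean–variance model sigma^2(mu) = a0 + a1*mu + a2*mu^2.

    Evaluation floors the polynomial at ``mu * (1 + epsilon)`` so that the
    variance strictly exceeds the mean everywhere; the negative-binomial
    moment parameterization requires sigma^2 > mu.
    """

    a0: float
    a1: float
    a2: float
    epsilon: float = 0.01

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise EstimationError("overdispersion floor epsilon must be positive")

    def __call__(self, mu):
        """Floored variance at mean ``mu`` (scalar or array, all > 0)."""
        mu = np.asarray(mu, dtype=float)
        if np.any(mu <= 0):
            raise ValueError("variance_at requires mu > 0")
        poly = self.a0 + self.a1 * mu + self.a2 * mu * mu
        return np.maximum(poly, mu * (1.0 + self.epsilon))

    @property
    def coefficients(self) -> tuple[float, float, float]:
        return (self.a0, self.a1, self.a2)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"a0": self.a0, "a1": self.a1, "a2": self.a2, "epsilon": self.epsilon},
                fh,
                indent=1,
            )


def variance_at(vf: VarianceFunction, mu):
    """Functional alias for ``vf(mu)``."""
    return vf(mu)


def estimate_size_factors(counts: CountMatrix) -> SizeFactors:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Only genes with a strictly positive geometric mean across samples (i.e.
    nonzero in every sample) enter the per-sample medians.
    """
    y = counts.counts.astype(float)
    with np.errstate(divide="ignore"):
        log_y = np.log(y)
    all_pos = np.all(y > 0, axis=1)
    if not np.any(all_pos):
        raise EstimationError(
            "no gene has nonzero counts in every sample; consider a pseudo-reference "
            "(e.g. geometric mean over nonzero samples) or filtering samples"
        )
    log_geo = log_y[all_pos].mean(axis=1)  # per-gene log geometric mean
    factors = np.median(np.exp(log_y[all_pos] - log_geo[:, None]), axis=0)
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean 1
    return SizeFactors(list(counts.sample_ids), factors)


def fit_variance_function(
    counts: CountMatrix,
    sheet: SampleSheet,
    sf: SizeFactors,
    epsilon: float = 0.01,
    weighted: bool = False,
) -> VarianceFunction:
    """Fit the pooled quadratic mean–variance polynomial.

    For every (gene, condition, timepoint) cell with >= 2 replicates, the
    sample mean and unbiased sample variance of size-factor-normalized
    counts across replicates are pooled, and ``a0 + a1*mu + a2*mu**2`` is
    fitted by least squares.

    Parameters
    ----------
    weighted : bool
        If True, weight squared residuals by 1/mu^2.  Recommended when
        means span several orders of magnitude, since the sampling noise of
        a replicate variance grows like sigma^4.
    """
    if counts.n_genes < 10:
        raise EstimationError("variance fitting needs at least 10 genes")
    order = {s: k for k, s in enumerate(counts.sample_ids)}
    norm = counts.counts.astype(float) / sf.for_samples(counts.sample_ids)[None, :]

    means, variances = [], []
    df = sheet.frame
    for (_, _), sub in df.groupby(["condition", "time_h"]):
        cols = [order[s] for s in sub["sample_id"]]
        if len(cols) < 2:
            continue
        block = norm[:, cols]
        means.append(block.mean(axis=1))
        variances.append(block.var(axis=1, ddof=1))
    if not means:
        raise EstimationError("no (condition, timepoint) cell has >= 2 replicates")
    mu = np.concatenate(means)
    v = np.concatenate(variances)
    keep = mu > 0
    mu, v = mu[keep], v[keep]
    if mu.size < 3:
        raise EstimationError(f"only {mu.size} pooled (mean, variance) points; need >= 3")

    # non-negative least squares: a count-variance polynomial with negative
    # coefficients can dip below the mean over whole count ranges, which the
    # floor then maps to near-Poisson noise — unstable on small panels
    def _fit(mu_, v_):
        X = np.column_stack([np.ones_like(mu_), mu_, mu_ * mu_])
        if not weighted:
            coef, _ = nnls(X, v_)
            return coef
        # iteratively reweighted GLS: a replicate variance estimate has
        # sampling variance ~ 2 sigma^4/(M-1), so squared residuals are
        # weighted by 1/sigma_hat^4, refitted to convergence
        coef = np.array([0.0, 1.0, 0.0])
        for _ in range(4):
            sig2 = np.maximum(X @ coef, mu_ * (1.0 + epsilon))
            w = 1.0 / sig2
            coef, _ = nnls(X * w[:, None], v_ * w)
        return coef

    # two-pass outlier trim: under the NB model a replicate variance is
    # ~ sigma^2 * chi2_{M-1}/(M-1); cells exceeding 20x the first-pass fit
    # (probability ~1e-9 at M=3) are systematic effects — e.g. a replicate
    # with shifted dynamics — not sampling noise, and would otherwise
    # dominate the regression
    coef = _fit(mu, v)
    fitted = np.maximum(coef[0] + coef[1] * mu + coef[2] * mu * mu, mu * (1.0 + epsilon))
    keep2 = v <= 20.0 * fitted
    if keep2.sum() >= 3 and keep2.sum() < mu.size:
        coef = _fit(mu[keep2], v[keep2])
    return VarianceFunction(float(coef[0]), float(coef[1]), float(coef[2]), epsilon)
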