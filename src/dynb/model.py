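"""Model/Results objects tying the pipeline together.

``DyNBModel`` holds one gene's counts for one condition group (or the
pooled two-condition group of the null model) together with the design,
size factors, variance function and priors; ``fit()`` runs the
Metropolis–Hastings sampler and returns a ``DyNBResults`` with the evidence
estimate, posterior trajectory, time-difference posteriors and diagnostics.

``compare_dynamics`` performs the model comparison for one gene — separate
fits per condition (M1) against a single pooled fit (M0) — and
``run_de_analysis`` maps it over all expressed genes of a count matrix.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from functools import cached_property

import numpy as np
import pandas as pd

from . import inference
from .io import CountMatrix, ResultTable, SampleSheet, expressed_genes
from .model_core import (
    KERNEL_TIME_SCALE_H,
    PriorSpec,
    TimescaleGrid,
    default_priors,
    timescale_grid,
)
from .normalization import SizeFactors, VarianceFunction
from .sampler import Chain, GeneData, MHConfig, psrf, run_chains

__all__ = ["DyNBModel", "DyNBResults", "compare_dynamics", "run_de_analysis"]


class DyNBModel:
    """A DyNB fit specification for one gene and one (possibly pooled) group.

    Parameters
    ----------
    counts : (R, N) int array
        Read counts for R replicates at the N design timepoints.
    times : (N,) array
        Design timepoints in hours.
    size_factors : (R, N) array
        Per-sample size factors, aligned with ``counts``.
    variance_fn : VarianceFunction
        Pooled mean–variance function shared across genes.
    timescale : bool
        Enable the discrete replicate time rescaling.
    reference : int or str
        Replicate (index or label) whose scaling is pinned at k = 1.
    grid : TimescaleGrid, optional
        Defaults to Δ ∈ ±32 h in 4 h steps at the last design timepoint.
    priors : PriorSpec, optional
        Defaults to the gene-specific rules (theta1 = 10·Stdev{y},
        m = mid-range, sigma1 = 500·m, sigma2 = 0.75, theta2 ~ U[0.5, 1]).
    """

    def __init__(
        self,
        counts,
        times,
        size_factors,
        variance_fn: VarianceFunction,
        replicate_labels=None,
        *,
        timescale: bool = False,
        reference=0,
        grid: TimescaleGrid | None = None,
        priors: PriorSpec | None = None,
        kernel_time_scale_h: float = KERNEL_TIME_SCALE_H,
        gene_id: str = "gene",
    ):
        counts = np.atleast_2d(np.asarray(counts))
        R = counts.shape[0]
        if replicate_labels is None:
            replicate_labels = [f"r{j + 1}" for j in range(R)]
        if isinstance(reference, str):
            reference = replicate_labels.index(reference)
        if timescale and grid is None:
            grid = timescale_grid(t_end=float(np.max(times)))
        if priors is None:
            priors = default_priors(counts, grid=grid)
        elif timescale and priors.k_prior_mass is None:
            raise ValueError("time scaling enabled but priors carry no k prior")
        self.data = GeneData(
            counts=counts,
            size_factors=size_factors,
            times=times,
            replicate_labels=list(replicate_labels),
            reference=reference,
            timescale=timescale,
        )
        self.variance_fn = variance_fn
        self.grid = grid if timescale else None
        self.priors = priors
        self.kernel_time_scale_h = kernel_time_scale_h
        self.gene_id = gene_id

    @classmethod
    def from_dataframe(
        cls,
        counts: CountMatrix,
        sheet: SampleSheet,
        gene_id: str,
        conditions,
        sf: SizeFactors,
        vf: VarianceFunction,
        **kwargs,
    ) -> "DyNBModel":
        """Build a model for one gene from a count matrix and sample sheet.

        ``conditions`` may be a single label (condition-specific fit) or a
        list of labels (pooled fit; replicates of all listed conditions are
        treated as replicates of one shared process, each keeping its own
        size factors and — when enabled — its own scaling factor).
        """
        if isinstance(conditions, str):
            conditions = [conditions]
        g = counts.gene_ids.index(gene_id)
        order = {s: k for k, s in enumerate(counts.sample_ids)}
        times = sheet.times(conditions[0])
        y_rows, s_rows, labels = [], [], []
        for cond in conditions:
            if not np.array_equal(sheet.times(cond), times):
                raise ValueError("pooled conditions must share a timepoint grid")
            for rep in sheet.replicates(cond):
                sub = sheet.samples_for(cond, rep)
                cols = [order[s] for s in sub["sample_id"]]
                y_rows.append(counts.counts[g, cols])
                s_rows.append(sf.for_samples(sub["sample_id"]))
                labels.append(f"{cond}:{rep}" if len(conditions) > 1 else rep)
        ref = kwargs.pop("reference", 0)
        if isinstance(ref, str) and ref not in labels and len(conditions) > 1:
            # a bare replicate label refers to the first condition's replicate
            ref = f"{conditions[0]}:{ref}"
        return cls(
            np.array(y_rows),
            times,
            np.array(s_rows),
            vf,
            replicate_labels=labels,
            reference=ref,
            gene_id=gene_id,
            **kwargs,
        )

    def fit(
        self,
        n_iter: int = 30_000,
        burn_in: int = 10_000,
        n_chains: int = 4,
        seed: int = 0,
        theta2_proposal_sd: float = 0.01,
    ) -> "DyNBResults":
        cfg = MHConfig(
            n_iter=n_iter,
            burn_in=burn_in,
            n_chains=n_chains,
            seed=seed,
            theta2_proposal_sd=theta2_proposal_sd,
        )
        chains = run_chains(
            self.data,
            self.priors,
            self.variance_fn,
            cfg,
            grid=self.grid,
            kernel_time_scale_h=self.kernel_time_scale_h,
        )
        return DyNBResults(self, chains, cfg)


@dataclass
class DyNBResults:
    """Posterior summaries and diagnostics of a DyNB fit."""

    model: DyNBModel
    chains: list[Chain]
    config: MHConfig

    @cached_property
    def log_marginal_likelihood(self) -> float:
        """Harmonic-mean log evidence pooled over chains."""
        return inference.log_marginal_likelihood(self.chains)

    @cached_property
    def log_marginal_likelihood_se(self) -> float:
        """Bootstrap spread of the harmonic-mean estimate (instability gauge)."""
        return inference.log_marginal_likelihood_bootstrap(self.chains)

    @property
    def acceptance_rate(self) -> float:
        return float(np.mean([c.acceptance_rate for c in self.chains]))

    def posterior_trajectory(self, grid=None):
        """(mean, lower95, upper95) of the latent trajectory on ``grid``."""
        if grid is None:
            t = self.model.data.times
            grid = np.linspace(t.min(), t.max(), 101)
        return inference.posterior_trajectory(
            self.chains, grid, self.model.kernel_time_scale_h
        )

    def _rep_index(self, replicate) -> int:
        if isinstance(replicate, str):
            return self.model.data.replicate_labels.index(replicate)
        return int(replicate)

    def timescale_posterior(self, replicate):
        """(delta_grid, posterior mass) of the time difference for a replicate."""
        return inference.timescale_posterior(self.chains, self._rep_index(replicate))

    def delta_mode(self, replicate) -> float:
        return inference.delta_posterior_mode(self.chains, self._rep_index(replicate))

    def delta_modes(self) -> dict:
        """Posterior-mode Δ (h) per replicate label (0 when scaling is off)."""
        labels = self.model.data.replicate_labels
        if self.model.grid is None:
            return {lab: 0.0 for lab in labels}
        return {lab: self.delta_mode(j) for j, lab in enumerate(labels)}

    def psrf(self, statistic: str = "loglik") -> float:
        """Gelman–Rubin PSRF of a scalar statistic across chains.

        ``statistic`` is one of ``loglik``, ``theta2``, ``f_last`` (the
        trajectory value at the last design timepoint) or ``f_mean``.
        """
        traces = []
        for c in self.chains:
            if statistic == "loglik":
                tr = c.post_burn_in(c.loglik)
            elif statistic == "theta2":
                tr = c.post_burn_in(c.theta2)
            elif statistic == "f_last":
                j = int(np.argmin(np.abs(c.eval_times - self.model.data.times.max())))
                tr = c.post_burn_in(c.f[:, j])
            elif statistic == "f_mean":
                tr = c.post_burn_in(c.f).mean(axis=1)
            else:
                raise ValueError(f"unknown statistic {statistic!r}")
            traces.append(tr)
        return psrf(traces)

    def summary(self) -> str:
        """Plain-text fit summary."""
        d = self.model.data
        mean, lo, hi = self.posterior_trajectory(d.times)
        lines = [
            f"DyNB fit: gene {self.model.gene_id}",
            f"  replicates: {', '.join(d.replicate_labels)}  "
            f"(reference: {d.replicate_labels[d.reference]})",
            f"  timepoints (h): {', '.join(f'{t:g}' for t in d.times)}",
            f"  chains: {len(self.chains)} x {self.config.n_iter} iterations "
            f"(burn-in {self.config.burn_in})",
            f"  acceptance rate: {self.acceptance_rate:.3f}",
            f"  log marginal likelihood (harmonic mean): "
            f"{self.log_marginal_likelihood:.3f} "
            f"(bootstrap se {self.log_marginal_likelihood_se:.3f})",
            (f"  PSRF (log-likelihood): {self.psrf('loglik'):.3f}"
             if len(self.chains) >= 2 else
             "  PSRF: n/a (single chain)"),
            "  posterior trajectory (normalized counts):",
            "    time_h      mean     lower95    upper95",
        ]
        for t, m, l, h in zip(d.times, mean, lo, hi):
            lines.append(f"    {t:6g} {m:9.1f} {l:9.1f} {h:9.1f}")
        if self.model.grid is not None:
            lines.append("  posterior-mode time difference at "
                         f"{d.times.max():g} h per replicate:")
            for lab, dm in self.delta_modes().items():
                lines.append(f"    {lab}: {dm:+g} h")
        return "\n".join(lines)


def _gene_seed(seed: int, gene_id: str, role: int) -> int:
    """Deterministic per-gene, per-fit seed below 2**31."""
    return (zlib.crc32(f"{seed}:{gene_id}:{role}".encode()) ^ seed) % (2**31)


def compare_dynamics(
    counts: CountMatrix,
    sheet: SampleSheet,
    gene_id: str,
    sf: SizeFactors,
    vf: VarianceFunction,
    *,
    conditions=None,
    timescale: bool = False,
    reference=0,
    n_iter: int = 30_000,
    burn_in: int = 10_000,
    n_chains: int = 4,
    seed: int = 0,
    return_fits: bool = False,
    **model_kwargs,
):
    """Bayes-factor comparison of condition-specific vs shared dynamics.

    Fits one DyNB model per condition (M1) and one pooled model over all
    replicates of both conditions (M0), estimates the three marginal
    likelihoods by the harmonic mean, and applies the BF > 10 &
    fold-change > 2 decision rule.
    """
    if conditions is None:
        conditions = sheet.conditions
    if len(conditions) != 2:
        raise ValueError("compare_dynamics requires exactly two conditions")
    fit_kw = dict(n_iter=n_iter, burn_in=burn_in, n_chains=n_chains)
    fits = {}
    for role, cond in enumerate(conditions):
        m = DyNBModel.from_dataframe(
            counts, sheet, gene_id, cond, sf, vf,
            timescale=timescale, reference=reference, **model_kwargs,
        )
        fits[cond] = m.fit(seed=_gene_seed(seed, gene_id, role), **fit_kw)
    m0 = DyNBModel.from_dataframe(
        counts, sheet, gene_id, list(conditions), sf, vf,
        timescale=timescale, reference=reference, **model_kwargs,
    )
    fits["pooled"] = m0.fit(seed=_gene_seed(seed, gene_id, 2), **fit_kw)

    log10_bf = inference.log10_bayes_factor(
        fits[conditions[0]].log_marginal_likelihood,
        fits[conditions[1]].log_marginal_likelihood,
        fits["pooled"].log_marginal_likelihood,
    )
    times = sheet.times(conditions[0])
    mean1, _, _ = fits[conditions[0]].posterior_trajectory(times)
    mean2, _, _ = fits[conditions[1]].posterior_trajectory(times)
    fcs = inference.fold_change(mean1, mean2)
    bf = 10.0 ** log10_bf
    delta_mode = {}
    if timescale:
        for cond in conditions:
            for lab, dm in fits[cond].delta_modes().items():
                delta_mode[f"{cond}:{lab}"] = dm
    result = inference.DEResult(
        gene_id=gene_id,
        log10_bf=float(log10_bf),
        fold_changes=fcs,
        differential=inference.call_differential(bf, fcs),
        times=times,
        delta_mode=delta_mode,
    )
    if return_fits:
        return result, fits
    return result


def run_de_analysis(
    counts: CountMatrix,
    sheet: SampleSheet,
    sf: SizeFactors | None = None,
    vf: VarianceFunction | None = None,
    *,
    genes=None,
    verbose: bool = False,
    **kwargs,
):
    """Genome-wide differential-dynamics screen.

    Estimates size factors and the variance function if not supplied,
    filters to expressed genes (>= 1 read in every condition; others are
    flagged and skipped), runs ``compare_dynamics`` per gene and assembles
    a :class:`ResultTable`.

    Returns (ResultTable, list of excluded gene ids, dict of DEResult).
    """
    from .normalization import estimate_size_factors, fit_variance_function

    if sf is None:
        sf = estimate_size_factors(counts)
    if vf is None:
        vf = fit_variance_function(counts, sheet, sf)
    mask = expressed_genes(counts, sheet)
    excluded = [g for g, keep in zip(counts.gene_ids, mask) if not keep]
    if genes is None:
        genes = [g for g, keep in zip(counts.gene_ids, mask) if keep]
    else:
        genes = [g for g in genes if mask[counts.gene_ids.index(g)]]
    rows = []
    results = {}
    for g in genes:
        res = compare_dynamics(counts, sheet, g, sf, vf, **kwargs)
        results[g] = res
        row = {
            "gene_id": g,
            "log10_bf": res.log10_bf,
            "max_abs_log2_fc": res.max_abs_log2_fc,
            "differential": res.differential,
        }
        for key, dm in res.delta_mode.items():
            row[f"delta_mode_h[{key}]"] = dm
        rows.append(row)
        if verbose:
            print(f"{g}: log10 BF = {res.log10_bf:.2f}, "
                  f"max |log2 FC| = {res.max_abs_log2_fc:.2f}, "
                  f"differential = {res.differential}")
    table = ResultTable(pd.DataFrame(rows))
    return table, excluded, results
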