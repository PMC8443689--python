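"""Posterior sampling of the single-pixel calibration likelihood.

An affine-invariant ensemble sampler (emcee) explores the global series
likelihood over log-transformed parameters with flat priors on the bounded
supports used by the MLE.  Affine invariance matters here: each dataset
mean pins E/phi, so the ADU factor and the per-level intensities ride a
strongly correlated likelihood ridge, and ensemble moves handle such
elongated posteriors without hand-tuned proposals.  Walkers start in a
small ball around the MLE; the first quarter of each chain is discarded as
burn-in by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import emcee
import numpy as np

from . import calibration_mle as cmle
from .calibration_mle import SeriesModel
from .simulator import SeriesDataset

__all__ = ["Chain", "sample_posterior", "summarize"]


@dataclass
class Chain:
    """Posterior draws: (n_steps, n_walkers, n_params) after burn-in removal
    on request; raw draws are stored and ``burn`` marks the cut."""

    draws: np.ndarray
    param_names: list[str]
    acceptance_rate: float
    seed: int
    burn: int = 0

    def flat(self, burn: int | None = None) -> np.ndarray:
        b = self.burn if burn is None else burn
        return self.draws[b:].reshape(-1, self.draws.shape[-1])


def sample_posterior(
    series: SeriesDataset,
    model: SeriesModel,
    darks=None,
    pixel: tuple[int, int] = (0, 0),
    n_walkers: int = 16,
    n_steps: int = 500,
    seed: int = 0,
    burn_frac: float = 0.25,
    mle_result=None,
) -> Chain:
    """Sample the posterior of one pixel's series-calibration parameters.

    The target density is the global log-likelihood (the NCH MAP objective
    for that scheme) over log-parameters; priors are flat inside the
    optimization bounds, so inference is likelihood-dominated.
    """
    model.check_series(series)
    dk = cmle._resolve_darks(series, darks)
    data = cmle._extract_pixel(series, dk, pixel)
    ndim = cmle.theta_dim(model, data)
    if n_walkers < 2 * ndim:
        raise ValueError(f"need n_walkers >= 2*ndim = {2 * ndim}")

    if mle_result is None:
        mle_result = cmle.fit(series, model, dk, pixel=pixel)
    theta_hat = np.asarray(mle_result.meta["theta"])

    def log_prob(th):
        return cmle.global_loglik(series, model, th, pixel=pixel, _data=data)

    rng = np.random.default_rng(seed)
    p0 = theta_hat + 1e-3 * rng.standard_normal((n_walkers, ndim))
    sampler = emcee.EnsembleSampler(n_walkers, ndim, log_prob)
    sampler.random_state = np.random.RandomState(seed).get_state()
    sampler.run_mcmc(p0, n_steps, progress=False)

    acc = float(np.mean(sampler.acceptance_fraction))
    if acc < 0.01:
        raise RuntimeError(
            f"all walkers stuck (acceptance {acc:.3f}); "
            "check the MLE starting point and parameter bounds"
        )
    _, names = cmle._named_estimates(model, data, theta_hat, series)
    return Chain(
        draws=sampler.get_chain(),
        param_names=names,
        acceptance_rate=acc,
        seed=seed,
        burn=int(burn_frac * n_steps),
    )


def split_rhat(chain_1d: np.ndarray) -> float:
    """Split-R-hat over walkers: each half-walker trace is one chain."""
    n, w = chain_1d.shape
    half = n // 2
    segs = np.concatenate([chain_1d[:half], chain_1d[half : 2 * half]], axis=1)  # (half, 2w)
    means = segs.mean(axis=0)
    varis = segs.var(axis=0, ddof=1)
    W = varis.mean()
    B = half * means.var(ddof=1)
    var_hat = (half - 1) / half * W + B / half
    return float(np.sqrt(var_hat / W)) if W > 0 else np.inf


def summarize(
    chain: Chain,
    credible: float = 0.95,
    rhat_threshold: float = 1.05,
    natural_scale: bool = True,
) -> dict:
    """Per-parameter posterior means, SDs, credible intervals, pairwise
    correlations, and split-R-hat convergence diagnostics.

    Draws are log-parameters (except NCH z terms); ``natural_scale``
    exponentiates before summarizing.  The phi-E correlations the noise
    model induces are reported explicitly under ``phi_E_correlations``.
    """
    flat = chain.flat()
    post = chain.draws[chain.burn :]
    names = chain.param_names
    if natural_scale:
        cols = [
            flat[:, j] if names[j].startswith("z") else np.exp(flat[:, j])
            for j in range(flat.shape[1])
        ]
        flat = np.column_stack(cols)

    alpha = (1 - credible) / 2
    summary = {"params": {}, "acceptance_rate": chain.acceptance_rate}
    warn = []
    for j, name in enumerate(names):
        r = split_rhat(post[:, :, j])
        if r > rhat_threshold:
            warn.append(name)
        x = flat[:, j]
        summary["params"][name] = {
            "mean": float(x.mean()),
            "sd": float(x.std(ddof=1)),
            "median": float(np.median(x)),
            "ci_low": float(np.quantile(x, alpha)),
            "ci_high": float(np.quantile(x, 1 - alpha)),
            "rhat": r,
        }
    corr = np.corrcoef(flat, rowvar=False)
    summary["correlations"] = {"names": names, "matrix": corr.tolist()}
    if "phi" in names:
        jphi = names.index("phi")
        summary["phi_E_correlations"] = {
            names[j]: float(corr[jphi, j]) for j in range(len(names)) if names[j].startswith("E")
        }
    summary["rhat_warnings"] = warn
    return summary
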