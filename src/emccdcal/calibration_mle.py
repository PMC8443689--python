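"""Global maximum-likelihood series calibration.

Several stacks are fit jointly by summing per-frame log-likelihoods under
the PGN/PN noise model, with parameters shared across stacks according to
one of four schemes:

- ``IS_ADU``   intensity series at unity gain: shared phi, per-level E,
  g fixed at 1 (the PN model) -- ADU calibration.
- ``IS_GAIN``  intensity series at an amplified set-point: shared g and
  phi, per-level E.
- ``GS_GAIN``  gain series: shared E and phi, per-set-point g.  A 1x stack,
  if present, enters with the PN model (g fixed at 1) and makes phi jointly
  identifiable; without one, phi must be supplied from an ADU calibration
  (at high gain the PG density depends on g and phi only through g/phi).
- ``GS_NCH``   non-centered hierarchical gain series: per-set-point
  intensities E_i = Ebar + sigma_Ebar * z_i with standard-normal z_i,
  optimized over the hyperparameters (a MAP objective) to absorb slow
  illumination drift between set-points.

The readout parameters S0 and sigma are always fixed from dark stacks
(per gain set-point, since real cameras show a gain-dependent offset).
Optimization is bounded quasi-Newton over log-transformed parameters with
multi-start initialization from the mean-variance estimates.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from . import noise_model as nm
from .calibration_mv import DarkParams, estimate_dark
from .results import CalibrationResult
from .simulator import SeriesDataset, nominal_gain

__all__ = [
    "Scheme",
    "SeriesModel",
    "global_loglik",
    "fit",
    "fit_region",
    "fit_gs_variants",
    "observed_information_se",
]

#: half-normal prior scale for the NCH relative illumination drift
_NCH_DRIFT_SCALE = 0.05

_LOG_BOUNDS = {
    "E": (np.log(1e-3), np.log(1e4)),
    "g": (np.log(1.0 + 1e-9), np.log(3000.0)),
    "phi": (np.log(0.1), np.log(100.0)),
}


class Scheme(str, enum.Enum):
    IS_ADU = "is-adu"
    IS_GAIN = "is-gain"
    GS_GAIN = "gs-gain"
    GS_NCH = "gs-nch"


@dataclass
class SeriesModel:
    """Parameter-sharing scheme plus fixed-value bookkeeping.

    ``fix_phi`` pins phi (needed for GS fits without a 1x stack);
    ``fix_sigma_E`` pins the NCH hyper-width (0 reduces NCH to GS_GAIN).
    """

    scheme: Scheme
    fix_phi: float | None = None
    fix_sigma_E: float | None = None
    include_unity_gain: bool = True

    def check_series(self, series: SeriesDataset) -> None:
        is_scheme = self.scheme in (Scheme.IS_ADU, Scheme.IS_GAIN)
        if is_scheme and series.series_axis != "intensity":
            raise ValueError(f"{self.scheme.value} requires an intensity series")
        if not is_scheme and series.series_axis != "gain":
            raise ValueError(f"{self.scheme.value} requires a gain series")


@dataclass
class _PixelData:
    """Per-dataset tabulated samples and dark-derived readout parameters."""

    samples: list[np.ndarray]
    gains_nominal: list[float]
    S0: list[float]
    sigma: list[float]
    # bincount tabulation per dataset: (lo, counts-per-value)
    tab: list[tuple[int, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for s in self.samples:
            s = np.asarray(s).astype(np.int64)
            lo = int(s.min())
            self.tab.append((lo, np.bincount(s - lo)))

    @property
    def n_datasets(self) -> int:
        return len(self.samples)


def _extract_pixel(
    series: SeriesDataset, darks: dict[str, DarkParams], pixel: tuple[int, int]
) -> _PixelData:
    r, c = pixel
    samples, gains, s0s, sigmas = [], [], [], []
    for stk in series.stacks:
        samples.append(stk.pixel(r, c))
        gains.append(nominal_gain(stk.gain_label))
        s0, sg = darks[stk.gain_label].at(r, c)
        s0s.append(s0)
        sigmas.append(sg)
    return _PixelData(samples, gains, s0s, sigmas)


def _dataset_loglik(tab: tuple[int, np.ndarray], params: nm.CameraParams) -> float:
    """Tabulated log-likelihood of one dataset under one parameter set.

    Parameter sets whose distribution cannot be evaluated on any plausible
    grid (see noise_model.MAX_GRID) floor every sample: they place the bulk
    of their mass far beyond the observed 16-bit counts.
    """
    lo, counts = tab
    try:
        pmf = nm.pgn_pdf(params)
    except nm.GridSizeError:
        return float(counts.sum()) * nm.LOG_FLOOR
    vals = np.arange(lo, lo + counts.size)
    lp = pmf.logpmf(vals)
    return float(np.dot(counts, lp))


# --- parameter packing ----------------------------------------------------
# theta layout per scheme (all free entries log-transformed except NCH z_i):
#   IS_ADU : [log phi, log E_1..M]
#   IS_GAIN: [log g, log phi, log E_1..M]
#   GS_GAIN: [log E, (log phi), log g_i for amplified datasets]
#   GS_NCH : [log Ebar, (log sigma_Ebar), (log phi), log g_i..., z_i...]


def _n_amplified(data: _PixelData) -> list[int]:
    return [i for i, g in enumerate(data.gains_nominal) if g > 1]


def theta_dim(model: SeriesModel, data: _PixelData) -> int:
    M = data.n_datasets
    amp = len(_n_amplified(data))
    if model.scheme == Scheme.IS_ADU:
        return 1 + M
    if model.scheme == Scheme.IS_GAIN:
        return 1 + int(model.fix_phi is None) + M
    free_phi = model.fix_phi is None
    if model.scheme == Scheme.GS_GAIN:
        return 1 + int(free_phi) + amp
    # GS_NCH
    free_sig = model.fix_sigma_E is None
    return 1 + int(free_sig) + int(free_phi) + amp + M


def _unpack(model: SeriesModel, data: _PixelData, theta: np.ndarray):
    """Return (per-dataset CameraParams list, log-prior term)."""
    M = data.n_datasets
    amp = _n_amplified(data)
    th = np.asarray(theta, dtype=float)
    prior = 0.0

    if model.scheme == Scheme.IS_ADU:
        phi = np.exp(th[0])
        Es = np.exp(th[1:])
        plist = [
            nm.CameraParams(E=Es[i], g=1.0, phi=phi, S0=data.S0[i], sigma=data.sigma[i])
            for i in range(M)
        ]
        return plist, prior
    if model.scheme == Scheme.IS_GAIN:
        g = np.exp(th[0])
        if model.fix_phi is None:
            phi, Es = np.exp(th[1]), np.exp(th[2:])
        else:
            phi, Es = model.fix_phi, np.exp(th[1:])
        plist = [
            nm.CameraParams(E=Es[i], g=g, phi=phi, S0=data.S0[i], sigma=data.sigma[i])
            for i in range(M)
        ]
        return plist, prior

    k = 0
    if model.scheme == Scheme.GS_GAIN:
        E = np.exp(th[k]); k += 1
        phi = model.fix_phi if model.fix_phi is not None else np.exp(th[k])
        if model.fix_phi is None:
            k += 1
        gs = dict(zip(amp, np.exp(th[k:])))
        Es = [E] * M
    else:  # GS_NCH
        Ebar = np.exp(th[k]); k += 1
        if model.fix_sigma_E is None:
            sigE = np.exp(th[k]); k += 1
        else:
            sigE = model.fix_sigma_E
        sigE = max(sigE, 1e-6 * Ebar)  # floor against the degenerate funnel
        phi = model.fix_phi if model.fix_phi is not None else np.exp(th[k])
        if model.fix_phi is None:
            k += 1
        gs = dict(zip(amp, np.exp(th[k : k + len(amp)])))
        z = th[k + len(amp) :]
        # clip rather than reject non-positive intensities so the objective
        # stays finite everywhere inside the box (L-BFGS-B line searches
        # misbehave on infinities); the likelihood itself repels E -> 0
        Es = [max(Ebar + sigE * z[i], 1e-9) for i in range(M)]
        prior = float(-0.5 * np.dot(z, z) - 0.5 * M * np.log(2 * np.pi))
        # weakly-informative half-normal prior on the relative illumination
        # drift sigma_E/Ebar (scale 5%): without it the non-centered MAP is
        # improper -- sigma_E -> inf with z -> 0 leaves the z-prior at its
        # maximum while freeing every E_i
        s = _NCH_DRIFT_SCALE * Ebar
        prior += float(0.5 * np.log(2 / np.pi) - np.log(s) - 0.5 * (sigE / s) ** 2)

    plist = []
    for i in range(M):
        g_i = 1.0 if i not in gs else gs[i]
        plist.append(
            nm.CameraParams(E=Es[i], g=g_i, phi=phi, S0=data.S0[i], sigma=data.sigma[i])
        )
    return plist, prior


def _in_bounds(model: SeriesModel, data: _PixelData, theta: np.ndarray) -> bool:
    for name, lo, hi, val in _bounds_iter(model, data, theta):
        if name == "z":
            if not (-20 < val < 20):
                return False
        elif not (lo <= val <= hi):
            return False
    return True


def _bounds_iter(model: SeriesModel, data: _PixelData, theta=None):
    """Yield (kind, lo, hi, value) per theta entry, in packing order."""
    M = data.n_datasets
    amp = len(_n_amplified(data))
    kinds: list[str] = []
    if model.scheme == Scheme.IS_ADU:
        kinds = ["phi"] + ["E"] * M
    elif model.scheme == Scheme.IS_GAIN:
        kinds = ["g"] + (["phi"] if model.fix_phi is None else []) + ["E"] * M
    elif model.scheme == Scheme.GS_GAIN:
        kinds = ["E"] + (["phi"] if model.fix_phi is None else []) + ["g"] * amp
    else:
        kinds = (
            ["E"]
            + (["sigE"] if model.fix_sigma_E is None else [])
            + (["phi"] if model.fix_phi is None else [])
            + ["g"] * amp
            + ["z"] * M
        )
    for i, kind in enumerate(kinds):
        if kind == "z":
            lo, hi = -20.0, 20.0
        elif kind == "sigE":
            lo, hi = np.log(1e-8), np.log(1e4)
        else:
            lo, hi = _LOG_BOUNDS[kind]
        val = theta[i] if theta is not None else None
        yield kind, lo, hi, val


def _bounds_list(model: SeriesModel, data: _PixelData):
    return [(lo, hi) for _, lo, hi, _ in _bounds_iter(model, data)]


def global_loglik(
    series: SeriesDataset,
    model: SeriesModel,
    theta: np.ndarray,
    darks: dict[str, DarkParams] | None = None,
    pixel: tuple[int, int] = (0, 0),
    _data: _PixelData | None = None,
) -> float:
    """Global log-likelihood (MAP objective for GS_NCH) at ``theta``.

    Out-of-bounds parameter vectors return -inf.  Datasets sharing an
    identical parameter set reuse a single pmf evaluation.
    """
    data = _data if _data is not None else _extract_pixel(series, _resolve_darks(series, darks), pixel)
    if len(theta) != theta_dim(model, data):
        raise ValueError(
            f"theta has dimension {len(theta)}, scheme {model.scheme.value} needs "
            f"{theta_dim(model, data)}"
        )
    if not _in_bounds(model, data, np.asarray(theta)):
        return -np.inf
    plist, prior = _unpack(model, data, theta)
    if plist is None:
        return -np.inf
    total = prior
    cache: dict[tuple, float] = {}
    for i, p in enumerate(plist):
        key = (p.E, p.g, p.phi, p.S0, p.sigma, data.tab[i][0], data.tab[i][1].size)
        if key in cache and np.array_equal(
            data.tab[i][1], data.tab[cache[key][1]][1]  # type: ignore[index]
        ):
            total += cache[key][0]  # type: ignore[index]
            continue
        ll = _dataset_loglik(data.tab[i], p)
        cache[key] = (ll, i)
        total += ll
    return float(total)


def _resolve_darks(series: SeriesDataset, darks) -> dict[str, DarkParams]:
    if darks is None:
        return {lbl: estimate_dark(stk) for lbl, stk in series.dark_stacks.items()}
    if isinstance(darks, DarkParams):
        return {stk.gain_label: darks for stk in series.stacks}
    return darks


def _moment_summaries(data: _PixelData):
    means = np.array([s.mean() for s in data.samples])
    varis = np.array([s.var(ddof=1) for s in data.samples])
    excess_m = np.maximum(means - np.array(data.S0), 1e-2)
    excess_v = np.maximum(varis - np.array(data.sigma) ** 2, 1e-2)
    return excess_m, excess_v


def _mv_init(model: SeriesModel, data: _PixelData, phi0: float | None = None) -> np.ndarray:
    """Initial theta from moment (mean-variance) estimates.

    For schemes where phi is a free parameter only weakly pinned by the
    moments (amplified IS, gain series at modest E), ``phi0`` supplies a
    trial value; the remaining parameters are derived from the sample
    moments conditional on it.
    """
    excess_m, excess_v = _moment_summaries(data)

    if model.scheme == Scheme.IS_ADU:
        # var - sigma^2 = <S - S0>/phi
        slope = float(np.dot(excess_m, excess_v) / np.dot(excess_m, excess_m))
        phi = phi0 if phi0 is not None else 1.0 / slope
        Es = excess_m * phi
        return np.concatenate([[np.log(phi)], np.log(np.maximum(Es, 1e-3))])
    if model.scheme == Scheme.IS_GAIN:
        # var - sigma^2 = 2 g <S - S0>/phi
        slope = float(np.dot(excess_m, excess_v) / np.dot(excess_m, excess_m))
        phi = model.fix_phi if model.fix_phi is not None else (phi0 if phi0 is not None else 1.0)
        g0 = max(slope * phi / 2.0, 1.0 + 1e-6)
        Es = excess_m * phi / g0
        head = [np.log(g0)] + ([np.log(phi)] if model.fix_phi is None else [])
        return np.concatenate([head, np.log(np.maximum(Es, 1e-3))])

    # gain series
    amp = _n_amplified(data)
    unity = [i for i in range(data.n_datasets) if i not in amp]
    if model.fix_phi is not None:
        phi = model.fix_phi
    elif phi0 is not None:
        phi = phi0
    elif unity:
        i0 = unity[0]
        phi = float(np.clip(excess_m[i0] / excess_v[i0], 0.11, 99.0))
    else:
        raise ValueError("GS calibration without a 1x dataset requires fix_phi")
    if unity:
        E0 = max(excess_m[unity[0]] * phi, 1e-2)
    else:
        E0 = max(2 * excess_m[amp[0]] ** 2 / excess_v[amp[0]], 1e-2)
    gs0 = np.maximum(excess_v[amp] * phi / (2 * excess_m[amp]), 1.0 + 1e-6)

    head = [np.log(E0)]
    if model.scheme == Scheme.GS_NCH and model.fix_sigma_E is None:
        head.append(np.log(max(0.01 * E0, 1e-6)))
    if model.fix_phi is None:
        head.append(np.log(phi))
    theta = np.concatenate([head, np.log(gs0)])
    if model.scheme == Scheme.GS_NCH:
        theta = np.concatenate([theta, np.zeros(data.n_datasets)])
    return theta


def _initial_thetas(model: SeriesModel, data: _PixelData, n_starts: int) -> list[np.ndarray]:
    """Multi-start initial points.

    IS_ADU's phi is well determined by the PTC slope, so starts are the
    moment init plus +/-25% log perturbations.  For the other schemes phi's
    moment estimate can be dominated by variance sampling noise, so starts
    sweep a log-spaced grid of trial phi values instead.
    """
    if model.scheme == Scheme.IS_ADU:
        theta0 = _mv_init(model, data)
        rng = np.random.default_rng(0)
        starts = [theta0]
        for _ in range(1, max(n_starts, 1)):
            starts.append(theta0 + rng.uniform(-np.log(1.25), np.log(1.25), theta0.size))
        return starts
    free_phi = model.scheme == Scheme.IS_GAIN or model.fix_phi is None
    if free_phi:
        phis = np.geomspace(0.5, 32.0, max(n_starts, 4))
        starts = [_mv_init(model, data, phi0=p) for p in phis]
        try:
            starts.append(_mv_init(model, data))
        except ValueError:
            pass
        return starts
    return [_mv_init(model, data)]


def fit(
    series: SeriesDataset,
    model: SeriesModel,
    darks: dict[str, DarkParams] | None = None,
    pixel: tuple[int, int] = (0, 0),
    n_starts: int = 3,
    tol: float = 1e-13,
    compute_se: bool = False,
) -> CalibrationResult:
    """Single-pixel global-MLE fit.

    Bounded L-BFGS-B over log-parameters, multi-start from the moment
    initialization plus +/-25% perturbations; the best optimum is kept and
    the pixel flagged multimodal if starts disagree by more than 1e-4 in
    log-likelihood.  Non-convergence is flagged, not raised.
    """
    model.check_series(series)
    dk = _resolve_darks(series, darks)
    data = _extract_pixel(series, dk, pixel)
    if model.scheme == Scheme.GS_GAIN and model.fix_phi is None:
        if not any(g == 1 for g in data.gains_nominal):
            raise ValueError("GS fit without a 1x dataset requires fix_phi")

    bounds = _bounds_list(model, data)
    blo = np.array([b[0] for b in bounds])
    bhi = np.array([b[1] for b in bounds])
    starts = [np.clip(th, blo, bhi) for th in _initial_thetas(model, data, n_starts)]
    theta0 = starts[0]

    def negll(th):
        v = global_loglik(series, model, th, pixel=pixel, _data=data)
        # keep the objective finite: L-BFGS-B line searches can accept an
        # infinite iterate and then fail in the gradient evaluation
        return 1e18 if not np.isfinite(v) else -v

    best = None
    optima = []
    for th0 in starts:
        res = optimize.minimize(
            negll,
            th0,
            method="L-BFGS-B",
            bounds=bounds,
            # the phi-E ridge is strongly correlated: a loose relative-ftol
            # stop would stall partway along it
            options={"ftol": tol, "gtol": 1e-9, "maxiter": 2000, "maxcor": 20},
        )
        optima.append(-res.fun)
        if best is None or res.fun < best.fun:
            best = res
    multimodal = bool(len(optima) > 1 and (max(optima) - sorted(optima)[-2]) > 1e-4)

    ll0 = -negll(theta0)
    estimates, names = _named_estimates(model, data, best.x, series)
    se = None
    if compute_se:
        se_vals = observed_information_se(negll, best.x, bounds)
        # delta method: theta entries are log-parameters (z entries excluded)
        se = {}
        for (kind, *_), nm_, th, s in zip(
            _bounds_iter(model, data, best.x), names, best.x, se_vals
        ):
            se[nm_] = float(s if kind == "z" else np.exp(th) * s)

    return CalibrationResult(
        method=f"mle-{model.scheme.value}",
        estimates=estimates,
        loglik=float(-best.fun),
        converged=bool(best.success and np.isfinite(best.fun)),
        se=se,
        meta={
            "scheme": model.scheme.value,
            "pixel": list(pixel),
            "theta": best.x.tolist(),
            "init_loglik": ll0,
            "multimodal": multimodal,
            "fixed": {
                "S0": data.S0,
                "sigma": data.sigma,
                "phi": model.fix_phi,
                "sigma_E": model.fix_sigma_E,
            },
            "n_frames": [len(s) for s in data.samples],
        },
    )


def _named_estimates(model: SeriesModel, data: _PixelData, theta, series):
    """Map theta to named natural-scale estimates (and the name list)."""
    names = []
    amp = _n_amplified(data)
    labels = [series.stacks[i].gain_label for i in range(data.n_datasets)]
    if model.scheme == Scheme.IS_ADU:
        names = ["phi"] + [f"E_level{i}" for i in range(data.n_datasets)]
    elif model.scheme == Scheme.IS_GAIN:
        names = ["g"] + (["phi"] if model.fix_phi is None else []) + [
            f"E_level{i}" for i in range(data.n_datasets)
        ]
    elif model.scheme == Scheme.GS_GAIN:
        names = ["E"] + (["phi"] if model.fix_phi is None else []) + [
            f"g_{labels[i]}" for i in amp
        ]
    else:
        names = (
            ["E_bar"]
            + (["sigma_E_bar"] if model.fix_sigma_E is None else [])
            + (["phi"] if model.fix_phi is None else [])
            + [f"g_{labels[i]}" for i in amp]
            + [f"z_{labels[i]}" for i in range(data.n_datasets)]
        )
    est = {}
    for (kind, *_), nm_, th in zip(_bounds_iter(model, data, theta), names, theta):
        est[nm_] = float(th if kind == "z" else np.exp(th))
    if model.scheme == Scheme.GS_NCH:
        sigE = est.get("sigma_E_bar", model.fix_sigma_E or 0.0)
        sigE = max(sigE, 1e-6 * est["E_bar"])
        for i in range(data.n_datasets):
            est[f"E_{labels[i]}"] = est["E_bar"] + sigE * est[f"z_{labels[i]}"]
    return est, names


def observed_information_se(negll, theta: np.ndarray, bounds, rel_step: float = 1e-4):
    """Standard errors from a central finite-difference Hessian of the
    negative log-likelihood (observed information) at the optimum."""
    n = theta.size
    h = np.maximum(np.abs(theta), 1.0) * rel_step
    H = np.empty((n, n))
    f0 = negll(theta)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            if i == j:
                H[i, i] = (negll(theta + ei) - 2 * f0 + negll(theta - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    negll(theta + ei + ej)
                    - negll(theta + ei - ej)
                    - negll(theta - ei + ej)
                    + negll(theta - ei - ej)
                ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(n, np.nan)
    return se


def fit_region(
    series: SeriesDataset,
    model: SeriesModel,
    darks: dict[str, DarkParams] | None = None,
    n_starts: int = 1,
) -> CalibrationResult:
    """Independent per-pixel fits over the full region; estimates become
    H x W maps and across-pixel summary statistics are reported."""
    H, W = series.stacks[0].shape
    dk = _resolve_darks(series, darks)
    maps: dict[str, np.ndarray] = {}
    lls = np.empty((H, W))
    conv = np.empty((H, W), dtype=bool)
    for r in range(H):
        for c in range(W):
            res = fit(series, model, dk, pixel=(r, c), n_starts=n_starts)
            for k, v in res.estimates.items():
                maps.setdefault(k, np.empty((H, W)))[r, c] = v
            lls[r, c] = res.loglik
            conv[r, c] = res.converged
    summary = {
        k: {"mean": float(v.mean()), "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0}
        for k, v in maps.items()
    }
    return CalibrationResult(
        method=f"mle-{model.scheme.value}",
        estimates=maps,
        loglik=lls,
        converged=conv,
        meta={"scheme": model.scheme.value, "n_pixels": H * W, "summary": summary},
    )


def fit_gs_variants(
    series: SeriesDataset,
    darks: dict[str, DarkParams] | None = None,
    include_unity_gain: bool = True,
    phi: float | None = None,
    pixel: tuple[int, int] = (0, 0),
    **kwargs,
) -> CalibrationResult:
    """GS_GAIN fit including or excluding the 1x dataset.

    Excluding it removes the PN self-consistency anchor, so phi must then be
    supplied externally (e.g. from an IS-ADU calibration).
    """
    sub = series
    if not include_unity_gain:
        keep = [s for s in series.stacks if nominal_gain(s.gain_label) > 1]
        if len(keep) == len(series.stacks):
            sub = series  # no 1x stack present; nothing to exclude
        else:
            sub = SeriesDataset(
                keep, "gain", {s.gain_label: series.dark_stacks[s.gain_label] for s in keep}
            )
        if phi is None:
            raise ValueError("excluding the 1x dataset requires an external phi")
    else:
        if not any(nominal_gain(s.gain_label) == 1 for s in series.stacks):
            raise ValueError("include_unity_gain=True but the series has no 1x stack")
    model = SeriesModel(Scheme.GS_GAIN, fix_phi=None if include_unity_gain else phi)
    res = fit(sub, model, darks, pixel=pixel, **kwargs)
    res.meta["include_unity_gain"] = include_unity_gain
    return res
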