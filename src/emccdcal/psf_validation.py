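"""Localization-based self-consistency validation of calibrations.

Fluorescent beads imaged at several gain set-points under constant
illumination provide an independent check of calibration quality: if the
per-set-point camera parameters are right, the photon flux recovered by
PSF fitting must not depend on the set-point.  The spread of the per-set-
point mean fluxes (``sigma_means``) therefore ranks candidate calibrations
-- smaller is more self-consistent.

Spots are fit per frame by maximum likelihood under the full PGN noise
model: the expected photon count of pixel (i, j) is background plus flux
times the exact integral of a unit 2-D Gaussian over the pixel square
(pixel (i, j) covers [i, i+1) x [j, j+1); positions are continuous in that
frame).  An optional second pass augments the PSF with an over-sampled
mean-residual template to compensate model mismatch.

Because every pixel carries its own expected photon count E, evaluating
the exact PGN pmf per pixel per optimizer step would be prohibitive; the
fit instead interpolates log p(S | E) from a table of pmfs evaluated on a
sqrt(E)-spaced grid of intensities (dense enough that the interpolation
error is far below the per-frame estimator noise; the exact objective
remains available for verification).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, stats

from . import noise_model as nm
from .noise_model import CameraParams
from .simulator import FrameStack, nominal_gain

__all__ = [
    "SpotFit",
    "ConsistencyReport",
    "integrated_gaussian_model",
    "PmfTable",
    "fit_spot",
    "fit_spot_residual_pass",
    "consistency_test",
    "scale_to_reference",
    "detect_spots",
]


@dataclass
class SpotFit:
    """Single-frame PSF fit: continuous position, width, integrated photon
    flux, flat background (photons/pixel), and the attained objective."""

    x: float
    y: float
    sigma_psf: float
    flux: float
    background: float
    loglik: float = np.nan
    converged: bool = True

    def __post_init__(self) -> None:
        if self.sigma_psf <= 0:
            raise ValueError("sigma_psf must be positive")
        if self.flux < 0 or self.background < 0:
            raise ValueError("flux and background must be non-negative")


def integrated_gaussian_model(
    x: float,
    y: float,
    sigma_psf: float,
    flux: float,
    background: float,
    roi: tuple[int, int],
    origin: tuple[int, int] = (0, 0),
) -> np.ndarray:
    """Expected photons per pixel for a pixel-integrated Gaussian spot.

    Pixel (i, j) of the ROI (row i, column j, offset by ``origin``) covers
    the unit square [i, i+1) x [j, j+1); its expectation is
    ``background + flux * [G(i+1) - G(i)] * [G(j+1) - G(j)]`` with G the
    1-D normal CDF centered on the spot coordinate -- the exact integral,
    not a point sample.
    """
    H, W = roi
    r0, c0 = origin
    rows = np.arange(r0, r0 + H)
    cols = np.arange(c0, c0 + W)
    ay = np.diff(stats.norm.cdf(np.append(rows, rows[-1] + 1), loc=y, scale=sigma_psf))
    ax = np.diff(stats.norm.cdf(np.append(cols, cols[-1] + 1), loc=x, scale=sigma_psf))
    return background + flux * np.outer(ay, ax)


class PmfTable:
    """log p(S | E) tabulated over a sqrt(E)-spaced intensity grid.

    One table serves every fit against a given (g, phi, S0, sigma) at a
    given count range.  Interpolation is linear in u = sqrt(E), where the
    log-likelihood curvature of a Poisson-type model is approximately
    constant, so a few hundred nodes hold the interpolation error to
    ~1e-2 nats even far from the optimum.
    """

    def __init__(
        self,
        camera: CameraParams,
        count_lo: int,
        count_hi: int,
        E_max: float,
        n_nodes: int = 160,
    ):
        self.camera = camera
        self.count_lo = count_lo
        self.grid_n = count_hi - count_lo + 1
        self.u_nodes = np.linspace(0.0, np.sqrt(E_max), n_nodes)
        self.E_nodes = self.u_nodes**2
        self.du = self.u_nodes[1] - self.u_nodes[0]
        vals = np.arange(count_lo, count_hi + 1)
        rows = []
        for E in self.E_nodes:
            p = camera.with_(E=float(E))
            lo = int(np.floor(p.S0 - 8 * p.sigma))
            hi = max(count_hi, nm.default_grid(p).last)
            pmf = nm.pgn_pdf(p, nm.CountGrid(min(lo, count_lo), hi - min(lo, count_lo) + 1))
            rows.append(pmf.logpmf(vals))
        self.logp = np.asarray(rows)  # (n_nodes, n_counts)

    def loglik_and_grad(self, counts: np.ndarray, E: np.ndarray):
        """Summed log-likelihood of integer ``counts`` at per-pixel ``E``,
        plus d(logp)/dE per pixel (consistent with the interpolant)."""
        idx = np.clip(counts.ravel() - self.count_lo, 0, self.grid_n - 1)
        u = np.sqrt(np.clip(E.ravel(), 0.0, self.E_nodes[-1]))
        k = np.clip((u / self.du).astype(np.int64), 0, len(self.u_nodes) - 2)
        frac = u / self.du - k
        f0 = self.logp[k, idx]
        f1 = self.logp[k + 1, idx]
        f = f0 + frac * (f1 - f0)
        # df/dE = (df/du) / (2 u); guard the u=0 node
        dfdE = (f1 - f0) / self.du / np.maximum(2 * u, 1e-6)
        return float(f.sum()), dfdE.reshape(E.shape)

    def exact_loglik(self, counts: np.ndarray, E: np.ndarray) -> float:
        """Exact per-pixel PGN log-likelihood (one pmf per pixel); the
        reference the tabulated objective is verified against."""
        total = 0.0
        for c, e in zip(counts.ravel(), E.ravel()):
            p = self.camera.with_(E=float(e))
            total += nm.log_likelihood([int(c)], p)
        return total


def _spot_negll_and_grad(theta, counts, table: PmfTable, origin, template=None):
    """Negative tabulated PGN log-likelihood of one ROI frame and its
    gradient in theta = (x, y, log sigma, log flux, log background)."""
    x, y = theta[0], theta[1]
    s, flux, bg = np.exp(theta[2]), np.exp(theta[3]), np.exp(theta[4])
    H, W = counts.shape
    r0, c0 = origin
    rows = np.arange(r0, r0 + H)
    cols = np.arange(c0, c0 + W)
    edge_y = np.append(rows, rows[-1] + 1)
    edge_x = np.append(cols, cols[-1] + 1)
    cy = stats.norm.cdf(edge_y, loc=y, scale=s)
    cx = stats.norm.cdf(edge_x, loc=x, scale=s)
    py = stats.norm.pdf(edge_y, loc=y, scale=s)
    px = stats.norm.pdf(edge_x, loc=x, scale=s)
    ay, ax = np.diff(cy), np.diff(cx)
    day_dy = -np.diff(py)
    dax_dx = -np.diff(px)
    # d/ds of CDF((t - mu)/s): -(t - mu)/s * pdf / s = -(t-mu) pdf / s^2
    day_ds = -np.diff((edge_y - y) * py) / s
    dax_ds = -np.diff((edge_x - x) * px) / s

    A = np.outer(ay, ax)
    mu = bg + flux * A
    if template is not None:
        mu = mu + flux * template
    mu = np.maximum(mu, 1e-12)
    ll, dfdE = table.loglik_and_grad(counts, mu)

    dmu_dx = flux * np.outer(ay, dax_dx)
    dmu_dy = flux * np.outer(day_dy, ax)
    dmu_ds = flux * (np.outer(day_ds, ax) + np.outer(ay, dax_ds))
    dA = flux * A if template is None else flux * (A + template)
    grad = np.array(
        [
            np.sum(dfdE * dmu_dx),
            np.sum(dfdE * dmu_dy),
            np.sum(dfdE * dmu_ds) * s,
            np.sum(dfdE * dA),          # d/d log flux
            np.sum(dfdE) * bg,          # d/d log bg
        ]
    )
    return -ll, -grad


def _init_from_roi(counts: np.ndarray, camera: CameraParams, origin, sigma_psf0: float) -> SpotFit:
    """Heuristic start: border-median background, photon-converted centroid."""
    H, W = counts.shape
    r0, c0 = origin
    border = np.concatenate([counts[0], counts[-1], counts[1:-1, 0], counts[1:-1, -1]])
    conv = camera.phi / camera.g  # photons per count above offset
    bg = max((np.median(border) - camera.S0) * conv, 0.05)
    img = np.maximum((counts - camera.S0) * conv - bg, 0.0)
    total = img.sum()
    if total <= 0:
        return SpotFit(c0 + W / 2, r0 + H / 2, sigma_psf0, 1.0, bg)
    ys, xs = np.mgrid[r0 : r0 + H, c0 : c0 + W]
    y0 = float((img * (ys + 0.5)).sum() / total)
    x0 = float((img * (xs + 0.5)).sum() / total)
    return SpotFit(x0, y0, sigma_psf0, max(total, 1.0), bg)


def fit_spot(
    frame: np.ndarray,
    camera: CameraParams,
    init: SpotFit | None = None,
    table: PmfTable | None = None,
    origin: tuple[int, int] = (0, 0),
    template: np.ndarray | None = None,
    E_max: float | None = None,
) -> SpotFit:
    """MLE fit of one spot in one ROI frame under the PGN noise model.

    ``camera`` carries the calibration under test (g, phi, S0, sigma); only
    the spot parameters are optimized.  A shared ``table`` makes repeated
    fits against the same calibration cheap.
    """
    counts = np.asarray(frame, dtype=np.int64)
    H, W = counts.shape
    if init is None:
        init = _init_from_roi(counts, camera, origin, sigma_psf0=1.3)
    if table is None:
        conv = camera.phi / camera.g
        if E_max is None:
            E_max = max((counts.max() - camera.S0) * conv * 3.0, 10.0)
        table = PmfTable(camera, int(counts.min()), int(counts.max()), E_max)

    theta0 = np.array(
        [init.x, init.y, np.log(init.sigma_psf), np.log(max(init.flux, 1e-2)),
         np.log(max(init.background, 1e-3))]
    )
    r0, c0 = origin
    bounds = [
        (c0 - 1.0, c0 + W + 1.0),
        (r0 - 1.0, r0 + H + 1.0),
        (np.log(0.3), np.log(max(H, W))),
        (np.log(1e-2), np.log(1e7)),
        (np.log(1e-3), np.log(1e5)),
    ]
    res = optimize.minimize(
        _spot_negll_and_grad,
        theta0,
        args=(counts, table, origin, template),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 300},
    )
    x, y = res.x[0], res.x[1]
    return SpotFit(
        x=float(x),
        y=float(y),
        sigma_psf=float(np.exp(res.x[2])),
        flux=float(np.exp(res.x[3])),
        background=float(np.exp(res.x[4])),
        loglik=float(-res.fun),
        converged=bool(res.success),
    )


def build_residual_template(
    frames: np.ndarray,
    camera: CameraParams,
    fits: list[SpotFit],
    roi_shape: tuple[int, int],
    origin: tuple[int, int] = (0, 0),
    oversample: int = 3,
) -> np.ndarray:
    """Mean over-sampled residual image in the spot frame of reference.

    Residuals (data minus fitted model, in photon units) are accumulated on
    an ``oversample``x grid aligned to each frame's fitted spot center, then
    normalized per unit flux so the refit can scale the template with flux.
    """
    H, W = roi_shape
    ov = oversample
    acc = np.zeros((H * ov, W * ov))
    wgt = np.zeros((H * ov, W * ov))
    conv = camera.phi / camera.g
    mean_flux = float(np.mean([f.flux for f in fits])) or 1.0
    cy, cx = H / 2.0, W / 2.0
    for frame, f in zip(frames, fits):
        model = integrated_gaussian_model(
            f.x, f.y, f.sigma_psf, f.flux, f.background, roi_shape, origin
        )
        resid = (np.asarray(frame, float) - camera.S0) * conv - model
        # shift into the spot frame: pixel centers relative to the fit center
        r0, c0 = origin
        ys = (np.arange(H) + r0 + 0.5 - f.y) * ov + H * ov / 2.0
        xs = (np.arange(W) + c0 + 0.5 - f.x) * ov + W * ov / 2.0
        iy = np.clip(np.round(ys).astype(int), 0, H * ov - 1)
        ix = np.clip(np.round(xs).astype(int), 0, W * ov - 1)
        acc[np.ix_(iy, ix)] += resid
        wgt[np.ix_(iy, ix)] += 1.0
    with np.errstate(invalid="ignore"):
        tmpl = np.where(wgt > 0, acc / np.maximum(wgt, 1), 0.0)
    return tmpl / mean_flux


def _resample_template(tmpl: np.ndarray, fit: SpotFit, roi_shape, origin, oversample=3):
    """Bilinear resample of the over-sampled template at this frame's
    pixel positions relative to the fitted center."""
    H, W = roi_shape
    ov = oversample
    r0, c0 = origin
    ys = (np.arange(H) + r0 + 0.5 - fit.y) * ov + H * ov / 2.0
    xs = (np.arange(W) + c0 + 0.5 - fit.x) * ov + W * ov / 2.0
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    return ndimage.map_coordinates(tmpl, [yy, xx], order=1, mode="constant")


def fit_spot_residual_pass(
    frames: np.ndarray,
    camera: CameraParams,
    first_pass: list[SpotFit],
    origin: tuple[int, int] = (0, 0),
    oversample: int = 3,
    table: PmfTable | None = None,
) -> list[SpotFit]:
    """Second-pass fits with the PSF augmented by the mean residual image.

    The template is scaled proportionally to flux during the refit.  With a
    correctly Gaussian PSF the template is ~0 and pass-2 reproduces pass-1;
    with a distorted PSF it compensates the flux bias of the mismatch.
    """
    frames = np.asarray(frames)
    roi_shape = frames.shape[1:]
    tmpl = build_residual_template(frames, camera, first_pass, roi_shape, origin, oversample)
    out = []
    for frame, f in zip(frames, first_pass):
        local = _resample_template(tmpl, f, roi_shape, origin, oversample)
        out.append(
            fit_spot(frame, camera, init=f, table=table, origin=origin, template=local)
        )
    return out


def detect_spots(stack: FrameStack, n_spots: int, min_sep: float = 6.0) -> list[tuple[float, float]]:
    """Rough (x, y) spot positions from the smoothed mean image."""
    mean_img = stack.counts.mean(axis=0)
    sm = ndimage.gaussian_filter(mean_img, 1.0)
    positions: list[tuple[float, float]] = []
    work = sm.copy()
    for _ in range(n_spots):
        r, c = np.unravel_index(np.argmax(work), work.shape)
        positions.append((c + 0.5, r + 0.5))
        rr, cc = np.mgrid[: work.shape[0], : work.shape[1]]
        work[(rr - r) ** 2 + (cc - c) ** 2 < min_sep**2] = -np.inf
    return positions


@dataclass
class ConsistencyReport:
    """Per-gain flux distributions and the sigma_means spread metric for
    one named calibration."""

    calibration: str
    per_gain_flux: dict[str, np.ndarray]
    means: dict[str, float] = field(default_factory=dict)
    sigma_means: float = np.nan
    sigma_means_excl_1x: float = np.nan
    scaled_means: dict[str, float] = field(default_factory=dict)
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.means:
            self.means = {k: float(np.mean(v)) for k, v in self.per_gain_flux.items()}
        vals = np.array(list(self.means.values()))
        if vals.size < 2:
            self.sigma_means = 0.0
            self.degenerate = True
        else:
            self.sigma_means = float(vals.std(ddof=1))
        non1x = [v for k, v in self.means.items() if nominal_gain(k) != 1]
        self.sigma_means_excl_1x = (
            float(np.std(non1x, ddof=1)) if len(non1x) >= 2 else 0.0
        )


def _roi_around(pos, half: int, shape) -> tuple[slice, slice, tuple[int, int]]:
    x, y = pos
    H, W = shape
    r = int(np.clip(round(y - 0.5), half, H - 1 - half))
    c = int(np.clip(round(x - 0.5), half, W - 1 - half))
    return slice(r - half, r + half + 1), slice(c - half, c + half + 1), (r - half, c - half)


def consistency_test(
    bead_stacks: dict[str, FrameStack],
    calibrations: dict[str, dict[str, CameraParams]],
    positions: list[tuple[float, float]] | None = None,
    n_spots: int | None = None,
    psf_sigma0: float = 1.3,
    residual_pass: bool = False,
    max_frames: int | None = None,
) -> dict[str, ConsistencyReport]:
    """Fit every bead in every frame at every gain set-point under each
    candidate calibration; aggregate per-set-point flux distributions and
    the sigma_means self-consistency metric (small = consistent).

    ``calibrations`` maps calibration name -> {gain label -> CameraParams}.
    """
    if len(bead_stacks) < 2:
        raise ValueError("consistency test needs >= 2 gain set-points")
    labels = list(bead_stacks)
    for name, cal in calibrations.items():
        missing = set(labels) - set(cal)
        if missing:
            raise ValueError(f"calibration {name!r} missing set-points {sorted(missing)}")
    if positions is None:
        ref = bead_stacks[labels[-1]]
        positions = detect_spots(ref, n_spots or 1)

    half = int(np.ceil(4 * psf_sigma0))
    reports = {}
    for name, cal in calibrations.items():
        per_gain: dict[str, list[float]] = {lbl: [] for lbl in labels}
        for lbl in labels:
            stack = bead_stacks[lbl]
            camera = cal[lbl]
            frames_all = stack.counts if max_frames is None else stack.counts[:max_frames]
            rois_all = []
            for pos in positions:
                rs, cs, origin = _roi_around(pos, half, stack.shape)
                rois_all.append((frames_all[:, rs, cs], origin))
            # one pmf table per (calibration, set-point) serves every bead
            lo = min(int(r.min()) for r, _ in rois_all)
            hi = max(int(r.max()) for r, _ in rois_all)
            conv = camera.phi / camera.g
            E_max = max((hi - camera.S0) * conv * 3.0, 10.0)
            table = PmfTable(camera, lo, hi, E_max)
            for rois, origin in rois_all:
                fits = [
                    fit_spot(f, camera, table=table, origin=origin) for f in rois
                ]
                if residual_pass:
                    fits = fit_spot_residual_pass(rois, camera, fits, origin, table=table)
                per_gain[lbl].extend(f.flux for f in fits)
        reports[name] = ConsistencyReport(
            calibration=name,
            per_gain_flux={k: np.asarray(v) for k, v in per_gain.items()},
        )
    return reports


def scale_to_reference(
    report: ConsistencyReport, reference_label: str = "1x"
) -> ConsistencyReport:
    """Scale per-set-point means to the reference set-point's mean."""
    if reference_label not in report.means:
        raise ValueError(f"reference set-point {reference_label!r} absent")
    ref = report.means[reference_label]
    report.scaled_means = {k: v / ref for k, v in report.means.items()}
    return report


def rank_calibrations(
    reports: dict[str, ConsistencyReport], exclude_1x: bool = False
) -> list[str]:
    """Calibration names ordered by sigma_means, most self-consistent first."""
    key = (lambda n: reports[n].sigma_means_excl_1x) if exclude_1x else (
        lambda n: reports[n].sigma_means
    )
    return sorted(reports, key=key)
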