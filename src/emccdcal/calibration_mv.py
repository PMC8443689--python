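"""Classical mean-variance (photon transfer curve) calibration.

The PTC relates signal mean to signal variance: with the gain register off
the shot-noise contribution is ``var = <S>/phi`` and with it on
``var = 2 g <S> / phi`` (the factor 2 is the excess noise of gamma
amplification), on top of a constant readout variance.  Fitting a straight
line to per-level (mean, variance) pairs therefore yields ``phi = 1/slope``
for an unamplified intensity series, or ``g = slope * phi / 2`` for an
amplified one.  Dark frames determine the readout offset and width.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .results import CalibrationResult
from .simulator import FrameStack, SeriesDataset, nominal_gain

__all__ = [
    "DarkParams",
    "PTCPoint",
    "estimate_dark",
    "ptc_fit",
    "adu_from_ptc",
    "gain_from_ptc",
    "calibrate_mv",
]


@dataclass
class DarkParams:
    """Per-pixel readout parameters from a dark stack (maps, shape H x W)."""

    S0: np.ndarray
    sigma: np.ndarray
    valid: np.ndarray = field(default=None)  # sigma > 0 flag

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.asarray(self.sigma) > 0

    def at(self, row: int, col: int) -> tuple[float, float]:
        return float(np.asarray(self.S0)[row, col]), float(np.asarray(self.sigma)[row, col])


@dataclass(frozen=True)
class PTCPoint:
    mean_counts: float
    var_counts: float

    def __post_init__(self) -> None:
        if self.var_counts <= 0:
            raise ValueError("var_counts must be positive")


def estimate_dark(dark: FrameStack) -> DarkParams:
    """Per-pixel sample mean and unbiased (n-1) standard deviation."""
    if dark.n_frames < 2:
        raise ValueError("dark estimation needs at least 2 frames")
    data = dark.counts.astype(float)
    return DarkParams(S0=data.mean(axis=0), sigma=data.std(axis=0, ddof=1))


def ptc_fit(
    points: list[PTCPoint],
    dark: tuple[float, float] | None = None,
    fix_intercept: bool = False,
) -> tuple[float, float, float]:
    """OLS fit of variance on mean: returns (slope, intercept, slope_se).

    By default the intercept is free; the dark-derived readout variance is a
    consistency diagnostic, not a constraint.  With ``fix_intercept`` the
    line is forced through ``intercept = sigma_dark**2``.
    """
    m = np.array([p.mean_counts for p in points])
    v = np.array([p.var_counts for p in points])
    if m.size < 2 or np.ptp(m) == 0:
        raise ValueError("need >= 2 PTC points with distinct means")
    if fix_intercept:
        if dark is None:
            raise ValueError("fix_intercept requires dark parameters")
        intercept = dark[1] ** 2
        slope = float(np.dot(m, v - intercept) / np.dot(m, m))
        resid = v - intercept - slope * m
        dof = max(m.size - 1, 1)
        slope_se = float(np.sqrt(resid @ resid / dof / np.dot(m, m)))
        return slope, intercept, slope_se
    X = np.column_stack([m, np.ones_like(m)])
    coef, *_ = np.linalg.lstsq(X, v, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    resid = v - X @ coef
    dof = max(m.size - 2, 1)
    s2 = resid @ resid / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    return slope, intercept, float(np.sqrt(cov[0, 0]))


def adu_from_ptc(slope: float, slope_se: float = 0.0) -> tuple[float, float]:
    """ADU conversion factor from an unamplified PTC slope: phi = 1/slope.
    The standard error propagates by the delta method, se = slope_se/slope^2."""
    if slope <= 0:
        raise ValueError("PTC slope must be positive")
    return 1.0 / slope, slope_se / slope**2


def gain_from_ptc(slope: float, phi: float, slope_se: float = 0.0) -> tuple[float, float]:
    """Gain from an amplified PTC slope and a known phi: g = slope * phi / 2."""
    if slope <= 0:
        raise ValueError("PTC slope must be positive")
    if phi <= 0:
        raise ValueError("phi must be positive")
    return slope * phi / 2.0, slope_se * phi / 2.0


def calibrate_mv(
    series: SeriesDataset,
    darks: DarkParams | None = None,
    phi: float | None = None,
    fix_intercept: bool = False,
) -> CalibrationResult:
    """Per-pixel mean-variance calibration of an intensity series.

    With the series gain at 1x the result is a per-pixel phi map; at an
    amplified set-point a per-pixel gain map is produced (requires ``phi``).
    Returns a CalibrationResult whose estimates are H x W arrays, plus
    across-pixel summary statistics.
    """
    if series.series_axis != "intensity":
        raise ValueError("mean-variance calibration applies to intensity series only")
    g_nom = nominal_gain(series.stacks[0].gain_label)
    if g_nom > 1 and phi is None:
        raise ValueError("gain calibration from an amplified series requires phi")
    if darks is None:
        darks = estimate_dark(series.dark_stacks[series.stacks[0].gain_label])

    H, W = series.stacks[0].shape
    # regress total variance on the dark-subtracted mean: the shot-noise
    # component is proportional to the signal above offset, so the free
    # intercept then estimates the readout variance directly
    means = np.stack(
        [s.counts.mean(axis=0, dtype=float) - np.asarray(darks.S0) for s in series.stacks]
    )
    varis = np.stack([s.counts.astype(float).var(axis=0, ddof=1) for s in series.stacks])

    est = np.empty((H, W))
    se = np.empty((H, W))
    intercepts = np.empty((H, W))
    for r in range(H):
        for c in range(W):
            pts = [PTCPoint(means[i, r, c], varis[i, r, c]) for i in range(means.shape[0])]
            slope, icpt, slope_se = ptc_fit(pts, dark=darks.at(r, c), fix_intercept=fix_intercept)
            if g_nom == 1:
                est[r, c], se[r, c] = adu_from_ptc(slope, slope_se)
            else:
                est[r, c], se[r, c] = gain_from_ptc(slope, phi, slope_se)
            intercepts[r, c] = icpt

    name = "phi" if g_nom == 1 else "g"
    dark_var = np.asarray(darks.sigma) ** 2
    return CalibrationResult(
        method="mv",
        estimates={name: est, "intercept": intercepts},
        loglik=None,
        converged=np.ones((H, W), dtype=bool),
        se={name: se},
        meta={
            "gain_label": series.stacks[0].gain_label,
            "n_pixels": H * W,
            "summary": {name: {"mean": float(est.mean()), "sd": float(est.std(ddof=1) if est.size > 1 else 0.0)}},
            "dark_variance_diagnostic": {
                "mean_intercept": float(intercepts.mean()),
                "mean_dark_variance": float(dark_var.mean()),
            },
            "fix_intercept": fix_intercept,
        },
    )
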