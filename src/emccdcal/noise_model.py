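"""Poisson-gamma-normal (PGN) noise model for electron-multiplying CCDs.

An EMCCD pixel converts photons to photoelectrons (Poisson, expectation
``E``), multiplies the charge through the electron-multiplying register
(modelled as a gamma distribution with shape ``n`` and scale ``g`` electrons
for ``n`` input electrons), and digitizes the result with an ADU conversion
factor ``phi`` photoelectrons per count plus normally distributed readout
noise (offset ``S0`` counts, width ``sigma`` counts).  The output pixel
value ``S`` is therefore distributed as the convolution of a Poisson-gamma
(PG) signal density with a normal readout kernel -- the PGN model.  With the
multiplication register disabled (``g = 1``) the signal is purely Poisson
and the model reduces to Poisson-normal (PN).

All probability mass functions here live on the integer count grid of the
digitizer.  Working directly in counts keeps the discrete FFT convolution
artifact-free; no continuous-approximation of the ADC is involved.  The
zero-photoelectron atom of the PG density (weight ``exp(-E)``) is never
placed on the pre-convolution grid -- it convolves analytically to
``exp(-E)`` times the readout kernel and is added after the FFT step.

Saturation/full-well effects, clock-induced charge, and dark current are not
modelled separately; the latter two are absorbed into ``E`` and ``S0``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal
from scipy import special, stats

__all__ = [
    "CameraParams",
    "CountGrid",
    "Pmf",
    "SignalDensity",
    "default_grid",
    "pg_pdf",
    "pn_pdf",
    "readout_kernel",
    "pgn_pdf",
    "brute_force_pgn",
    "log_likelihood",
    "pgn_moments",
]

#: log-probability assigned to samples that fall outside the evaluated grid
LOG_FLOOR = np.log(1e-300)

#: default tolerated truncation deficit of a Pmf's total mass
TRUNCATION_EPS = 1e-6

#: hard cap on evaluated grid length; parameters needing more are treated
#: as unsupportable by any 16-bit acquisition
MAX_GRID = 1 << 22


class GridSizeError(ValueError):
    """The requested parameters need a count grid larger than MAX_GRID."""


@dataclass(frozen=True)
class CameraParams:
    """Per-pixel camera model parameters.

    Parameters
    ----------
    E : float
        Expected photoelectrons per frame (>= 0).
    g : float
        Electron-multiplying gain (>= 1); ``g == 1`` selects the PN model.
    phi : float
        ADU conversion factor, photoelectrons per count (> 0).
    S0 : float
        Readout offset in counts.
    sigma : float
        Readout noise standard deviation in counts (> 0).
    """

    E: float
    g: float
    phi: float
    S0: float
    sigma: float

    def __post_init__(self) -> None:
        if self.E < 0:
            raise ValueError(f"E must be non-negative, got {self.E}")
        if self.g < 1:
            raise ValueError(f"g must be >= 1, got {self.g}")
        if self.phi <= 0:
            raise ValueError(f"phi must be positive, got {self.phi}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    def with_(self, **kwargs) -> "CameraParams":
        """Return a copy with the given fields replaced."""
        d = dict(E=self.E, g=self.g, phi=self.phi, S0=self.S0, sigma=self.sigma)
        d.update(kwargs)
        return CameraParams(**d)


@dataclass(frozen=True)
class CountGrid:
    """Contiguous integer count values ``origin, origin+1, ..., origin+n-1``."""

    origin: int
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("grid must contain at least one count value")

    @property
    def values(self) -> np.ndarray:
        return self.origin + np.arange(self.n)

    @property
    def last(self) -> int:
        return self.origin + self.n - 1

    def index_of(self, counts: np.ndarray) -> np.ndarray:
        return np.asarray(counts) - self.origin


@dataclass
class Pmf:
    """Probability mass on a :class:`CountGrid`.

    ``norm_deficit`` records how much mass the pre-normalization evaluation
    was missing (grid truncation diagnostic); the stored ``mass`` itself sums
    to <= 1 with deficit below the truncation tolerance.
    """

    grid: CountGrid
    mass: np.ndarray
    norm_deficit: float = 0.0

    def total(self) -> float:
        return float(self.mass.sum())

    def mean(self) -> float:
        return float(np.dot(self.grid.values, self.mass) / self.total())

    def var(self) -> float:
        m = self.mean()
        return float(np.dot((self.grid.values - m) ** 2, self.mass) / self.total())

    def skewness(self) -> float:
        m = self.mean()
        d = self.grid.values - m
        tot = self.total()
        mu2 = np.dot(d**2, self.mass) / tot
        mu3 = np.dot(d**3, self.mass) / tot
        return float(mu3 / mu2**1.5)

    def logpmf(self, counts: np.ndarray) -> np.ndarray:
        """Log mass at integer ``counts``; out-of-grid values get LOG_FLOOR."""
        counts = np.atleast_1d(np.asarray(counts, dtype=np.int64))
        idx = self.grid.index_of(counts)
        inside = (idx >= 0) & (idx < self.grid.n)
        out = np.full(counts.shape, LOG_FLOOR)
        with np.errstate(divide="ignore"):
            vals = np.log(self.mass[idx[inside]])
        out[inside] = np.maximum(vals, LOG_FLOOR)
        return out


@dataclass
class SignalDensity:
    """Pre-readout signal mass: a continuous part on the grid plus the
    zero-electron atom at signal 0 (carried separately until convolution)."""

    grid: CountGrid
    cont_mass: np.ndarray
    zero_weight: float
    norm_deficit: float = 0.0

    def total(self) -> float:
        return float(self.cont_mass.sum() + self.zero_weight)

    def mean(self) -> float:
        # atom sits at signal 0, contributes nothing to the first moment
        return float(np.dot(self.grid.values, self.cont_mass) / self.total())

    def var(self) -> float:
        m = self.mean()
        tot = self.total()
        second = np.dot(self.grid.values**2, self.cont_mass) / tot
        return float(second - m * m)


def pgn_moments(params: CameraParams) -> tuple[float, float]:
    """Closed-form mean and variance (counts, counts^2) of the full model.

    mean = S0 + g E / phi;  var = E/phi^2 + sigma^2 at g = 1 (PN) and
    2 g^2 E / phi^2 + sigma^2 at g > 1 (the gamma amplification model, whose
    excess noise factor is 2).
    """
    mean = params.S0 + params.g * params.E / params.phi
    if params.g == 1:
        var = params.E / params.phi**2 + params.sigma**2
    else:
        var = 2 * params.g**2 * params.E / params.phi**2 + params.sigma**2
    return mean, var


def default_grid(params: CameraParams, k_lo: float = 8.0, k_hi: float = 12.0) -> CountGrid:
    """Default output grid ``[floor(S0 - k_lo*sigma), ceil(mean + k_hi*std)]``."""
    mean, var = pgn_moments(params)
    lo = int(np.floor(params.S0 - k_lo * params.sigma))
    hi = int(np.ceil(mean + k_hi * np.sqrt(var)))
    n = hi - lo + 1
    if n > MAX_GRID:
        raise GridSizeError(f"grid of {n} counts exceeds MAX_GRID={MAX_GRID}")
    return CountGrid(lo, n)


def _signal_grid_for(out_grid: CountGrid, params: CameraParams) -> CountGrid:
    """Signal (counts-above-zero-offset) grid needed to fill ``out_grid``
    after convolution with the readout kernel."""
    ker_lo = int(np.floor(params.S0 - 8 * params.sigma))
    s_max = out_grid.last - ker_lo
    return CountGrid(0, max(s_max, 0) + 1)


def pg_pdf(params: CameraParams, grid: CountGrid | None = None) -> SignalDensity:
    """Poisson-gamma signal density on the integer count grid (counts above
    the offset), for ``g > 1``.

    The continuous part is evaluated in log space through the exponentially
    scaled modified Bessel function of the first kind, order 1, so that the
    large arguments reached at high gain do not overflow.  The
    zero-photoelectron delta term is returned as the scalar ``zero_weight``
    (= exp(-E)); the total (atom + continuous) mass is renormalized to 1 and
    the pre-normalization deficit recorded.
    """
    if params.g <= 1:
        raise ValueError("pg_pdf requires g > 1; use pn_pdf at g = 1")
    if grid is None:
        mean = params.g * params.E / params.phi
        std = np.sqrt(2 * params.g**2 * params.E) / params.phi
        grid = CountGrid(0, int(np.ceil(mean + 12 * std)) + 1)
    if grid.origin > 0:
        raise ValueError("PG signal grid must start at or below 0")

    s = grid.values.astype(float)
    E, g, phi = params.E, params.g, params.phi
    zero_weight = float(np.exp(-E))
    mass = np.zeros(grid.n)
    if E > 0:
        pos = s > 0
        sp = s[pos]
        x = 2.0 * np.sqrt(E * sp * phi / g)
        with np.errstate(divide="ignore"):
            log_i1 = np.log(special.i1e(x)) + x
        logq = 0.5 * (np.log(E * phi / g) - np.log(sp)) - sp * phi / g - E + log_i1
        mass[pos] = np.exp(logq)
        # s = 0 limit of the continuous part is (E phi / g) exp(-E); the
        # density has support only on [0, 0.5) of that unit bin, so the
        # midpoint sample carries half weight
        at0 = s == 0
        mass[at0] = 0.5 * E * phi / g * np.exp(-E)
    total = mass.sum() + zero_weight
    deficit = 1.0 - total
    mass /= total
    zero_weight /= total
    return SignalDensity(grid, mass, zero_weight, norm_deficit=float(deficit))


def pn_pdf(params: CameraParams, grid: CountGrid | None = None) -> Pmf:
    """Poisson signal mass on the integer count grid for ``g == 1``.

    The Poisson density is carried into count units through the gamma
    function, ``phi * E**(S phi) exp(-E) / Gamma(S phi + 1)``, evaluated at
    the integer count values and renormalized over the grid.  This form is
    smooth in ``phi`` (counts generally map to non-integer electron
    numbers), which the series MLE relies on; the renormalization absorbs
    the sampling residue of the continuous change of variables.
    """
    if params.g != 1:
        raise ValueError("pn_pdf requires g == 1")
    E, phi = params.E, params.phi
    if grid is None:
        mean = E / phi
        std = np.sqrt(E) / phi
        grid = CountGrid(0, int(np.ceil(mean + 12 * std)) + 2)
    if E == 0:
        mass = np.zeros(grid.n)
        idx = grid.index_of(0)
        if 0 <= idx < grid.n:
            mass[idx] = 1.0
        return Pmf(grid, mass, norm_deficit=0.0)

    s = grid.values.astype(float)
    mass = np.zeros(grid.n)
    nonneg = s >= 0
    x = s[nonneg] * phi
    logq = np.log(phi) + special.xlogy(x, E) - E - special.gammaln(x + 1.0)
    mass[nonneg] = np.exp(logq)
    deficit = 1.0 - mass.sum()
    mass /= mass.sum()
    return Pmf(grid, mass, norm_deficit=float(deficit))


def readout_kernel(params: CameraParams, grid: CountGrid | None = None) -> Pmf:
    """Discretized normal readout kernel N(S | S0, sigma) on integer counts,
    normalized over the grid.  The grid must span at least S0 +/- 6 sigma."""
    if grid is None:
        lo = int(np.floor(params.S0 - 8 * params.sigma))
        hi = int(np.ceil(params.S0 + 8 * params.sigma))
        grid = CountGrid(lo, hi - lo + 1)
    if grid.origin > params.S0 - 6 * params.sigma or grid.last < params.S0 + 6 * params.sigma:
        raise ValueError(
            "readout kernel grid must cover S0 +/- 6 sigma "
            f"(grid [{grid.origin}, {grid.last}], S0={params.S0}, sigma={params.sigma})"
        )
    dens = stats.norm.pdf(grid.values, loc=params.S0, scale=params.sigma)
    deficit = 1.0 - dens.sum()
    return Pmf(grid, dens / dens.sum(), norm_deficit=float(deficit))


def pgn_pdf(
    params: CameraParams,
    grid: CountGrid | None = None,
    *,
    k_lo: float = 8.0,
    k_hi: float = 12.0,
    eps: float = TRUNCATION_EPS,
) -> Pmf:
    """Full output-count pmf: PGN for ``g > 1``, PN for ``g == 1``.

    The continuous signal part is convolved with the readout kernel by a
    zero-padded (linear, hence wraparound-free) FFT convolution; the
    zero-electron atom is added afterwards as ``exp(-E)`` times the kernel.
    Raises if the requested grid truncates more than ``eps`` of the mass.
    """
    out = grid if grid is not None else default_grid(params, k_lo=k_lo, k_hi=k_hi)
    ker = readout_kernel(params)
    sig_grid = _signal_grid_for(out, params)

    if params.E == 0:
        # pure dark pixel: the signal is a point mass at 0
        mass = np.zeros(out.n)
        idx = ker.grid.index_of(out.values)
        inside = (idx >= 0) & (idx < ker.grid.n)
        mass[inside] = ker.mass[idx[inside]]
        pmf = Pmf(out, mass, norm_deficit=float(1.0 - mass.sum()))
    elif params.g == 1:
        sig = pn_pdf(params, sig_grid)
        conv = _signal.fftconvolve(sig.mass, ker.mass)
        pmf = _assemble(out, conv, ker, atom_weight=0.0, sig_deficit=sig.norm_deficit)
    else:
        sig = pg_pdf(params, sig_grid)
        conv = _signal.fftconvolve(sig.cont_mass, ker.mass)
        pmf = _assemble(out, conv, ker, atom_weight=sig.zero_weight, sig_deficit=sig.norm_deficit)

    if 1.0 - pmf.total() > eps:
        if grid is None:
            # widen the automatic grid once and retry
            return pgn_pdf(params, None, k_lo=k_lo + 4, k_hi=k_hi + 8, eps=eps)
        raise ValueError(
            f"grid truncates {1.0 - pmf.total():.3g} of the probability mass (> eps={eps})"
        )
    return pmf


def _assemble(
    out: CountGrid, conv: np.ndarray, ker: Pmf, atom_weight: float, sig_deficit: float
) -> Pmf:
    """Map a linear-convolution result (origin = kernel origin, signal origin
    0) onto the output grid and add the analytically convolved atom."""
    conv_origin = ker.grid.origin  # + signal grid origin, which is 0
    mass = np.zeros(out.n)
    idx = out.values - conv_origin
    inside = (idx >= 0) & (idx < conv.size)
    mass[inside] = conv[idx[inside]]
    if atom_weight:
        kidx = ker.grid.index_of(out.values)
        kin = (kidx >= 0) & (kidx < ker.grid.n)
        mass[kin] += atom_weight * ker.mass[kidx[kin]]
    np.clip(mass, 0.0, None, out=mass)
    return Pmf(out, mass, norm_deficit=float(sig_deficit))


def brute_force_pgn(
    S: int,
    params: CameraParams,
    n_max: int | None = None,
    grid: CountGrid | None = None,
) -> float:
    """Direct-summation oracle for the output-count pmf at a single value.

    Evaluates the Poisson-gamma series term by term with scipy's gamma
    density (no Bessel function) and convolves with the readout kernel by a
    plain dot product (no FFT).  Slow; intended for verification only.
    ``grid`` must match the grid of the pmf being checked, since the pmf is
    defined (renormalized) on its evaluation support.
    """
    if n_max is None:
        n_max = int(stats.poisson.isf(1e-13, max(params.E, 1e-12))) + 2
    if stats.poisson.sf(n_max, params.E) > 1e-12:
        raise ValueError("n_max leaves more than 1e-12 Poisson tail mass")

    out = grid if grid is not None else default_grid(params)
    ker_lo = int(np.floor(params.S0 - 8 * params.sigma))
    ker_hi = int(np.ceil(params.S0 + 8 * params.sigma))
    ker_vals = np.arange(ker_lo, ker_hi + 1)
    ker = stats.norm.pdf(ker_vals, loc=params.S0, scale=params.sigma)
    ker /= ker.sum()

    s_max = out.last - ker_lo
    s = np.arange(0, s_max + 1, dtype=float)

    if params.E == 0:
        q = np.zeros(s.size)
        atom = 1.0
    elif params.g == 1:
        # continuous Poisson density at s*phi electrons; identical to
        # gamma.pdf(E, a=s*phi+1) by the gamma-Poisson duality
        q = params.phi * stats.gamma.pdf(params.E, a=s * params.phi + 1.0, scale=1.0)
        atom = 0.0
    else:
        ns = np.arange(1, n_max + 1)
        pn = stats.poisson.pmf(ns, params.E)
        q = np.zeros(s.size)
        for n, p in zip(ns, pn):
            # gamma over electrons (shape n, scale g) evaluated at s*phi,
            # times phi for the change of variables to counts
            q += p * params.phi * stats.gamma.pdf(s * params.phi, a=n, scale=params.g)
        q[0] *= 0.5  # half bin at the support boundary, as in pg_pdf
        atom = stats.poisson.pmf(0, params.E)

    total = q.sum() + atom
    q /= total
    atom /= total

    # direct-summation convolution evaluated at the single requested count
    prob = 0.0
    for si, qv in enumerate(q):
        t = S - si  # kernel argument in absolute counts
        if qv and ker_lo <= t <= ker_hi:
            prob += qv * ker[t - ker_lo]
    if ker_lo <= S <= ker_hi:
        prob += atom * ker[S - ker_lo]
    return float(prob)


def log_likelihood(
    samples: np.ndarray, params: CameraParams, grid: CountGrid | None = None
) -> float:
    """Sum of log pmf values over integer count samples under one parameter
    set (one pmf evaluation total).  Samples outside the evaluated grid
    contribute the floor log-probability and trigger a warning."""
    samples = np.asarray(samples).ravel()
    if samples.size == 0:
        raise ValueError("log_likelihood requires at least one sample")
    pmf = pgn_pdf(params, grid)
    lp = pmf.logpmf(samples.astype(np.int64))
    n_clipped = int(np.count_nonzero(lp == LOG_FLOOR))
    if n_clipped:
        warnings.warn(
            f"{n_clipped} sample(s) outside the evaluated grid "
            f"[{pmf.grid.origin}, {pmf.grid.last}]; floored at log(1e-300)",
            stacklevel=2,
        )
    return float(lp.sum())


def tabulated_log_likelihood(samples: np.ndarray, pmf: Pmf) -> float:
    """log-likelihood of integer samples against an already-evaluated pmf,
    using a bincount tabulation (fast path for repeated optimizer calls)."""
    samples = np.asarray(samples).ravel().astype(np.int64)
    lo, hi = samples.min(), samples.max()
    counts = np.bincount(samples - lo, minlength=hi - lo + 1)
    vals = np.arange(lo, hi + 1)
    lp = pmf.logpmf(vals)
    return float(np.dot(counts, lp))
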