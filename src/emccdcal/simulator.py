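"""Synthetic EMCCD frame generator with known ground truth.

Every stack is produced by the same forward process the noise model
describes: photoelectrons ``n ~ Poisson(E)`` per frame, gamma amplification
``x ~ Gamma(shape=n, scale=g)`` electrons when the multiplying register is
on (``x = n`` at unity gain), ADC conversion ``x / phi`` counts, additive
normal readout noise ``(S0, sigma)``, rounding to the nearest integer, and
clipping to the 16-bit range.  Discretization happens only at the ADC, so
the simulator is the exact sampling counterpart of the likelihood.

Presets mirror the regimes the calibrations are designed around: a 25x
intensity series with four log-spaced levels, a gain series at a common
10-photoelectron illumination across set-points 1/5/25/100/300, and the
six-level acquisition layout used for ADU calibration (sigma = 10 counts,
S0 = 100 counts, phi = 3.5 e-/count, 5000 frames throughout).

Randomness: a master seed spawns one ``numpy.random.SeedSequence`` child
per stack, and region simulations spawn one grandchild per pixel, so every
pixel's sample stream is reproducible independently of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .noise_model import CameraParams

__all__ = [
    "FrameStack",
    "SeriesDataset",
    "gain_label",
    "nominal_gain",
    "simulate_pixel",
    "simulate_dark",
    "simulate_intensity_series",
    "simulate_gain_series",
    "simulate_sensor_region",
    "simulate_beads",
    "simulate_bernoulli_cascade",
    "PRESETS",
    "make_preset",
]

U16_MAX = 65535


@dataclass
class FrameStack:
    """N_frames x H x W stack of integer counts plus acquisition metadata."""

    counts: np.ndarray  # uint16, shape (N, H, W)
    gain_label: str = "unknown"
    illum_label: str = "unknown"
    truth: CameraParams | None = None
    n_clipped: int = 0

    def __post_init__(self) -> None:
        if self.counts.ndim != 3 or self.counts.shape[0] < 1:
            raise ValueError("counts must be (N >= 1, H, W)")

    @property
    def n_frames(self) -> int:
        return self.counts.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape[1:]

    def pixel(self, row: int = 0, col: int = 0) -> np.ndarray:
        return self.counts[:, row, col]


@dataclass
class SeriesDataset:
    """Ordered stacks sharing a series axis, with matching dark stacks.

    ``series_axis`` is "intensity" (shared gain, varying illumination) or
    "gain" (shared illumination, varying gain set-point).  ``dark_stacks``
    maps gain label -> dark FrameStack for that set-point.
    """

    stacks: list[FrameStack]
    series_axis: str
    dark_stacks: dict[str, FrameStack] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.series_axis not in ("intensity", "gain"):
            raise ValueError("series_axis must be 'intensity' or 'gain'")
        labels = {s.gain_label for s in self.stacks}
        if self.series_axis == "intensity" and len(labels) > 1:
            raise ValueError("intensity series must share one gain set-point")
        if self.series_axis == "gain":
            illum = {s.illum_label for s in self.stacks}
            if len(illum) > 1:
                raise ValueError("gain series must share one illumination level")
        missing = labels - set(self.dark_stacks)
        if missing:
            raise ValueError(f"missing dark stacks for gain set-points: {sorted(missing)}")


def gain_label(g: float) -> str:
    return f"{g:g}x"


def nominal_gain(label: str) -> float:
    if not label.endswith("x"):
        raise ValueError(f"cannot parse gain set-point label {label!r}")
    return float(label[:-1])


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _amplify(n: np.ndarray, g: float, rng: np.random.Generator) -> np.ndarray:
    """Electrons out of the multiplying register for ``n`` electrons in."""
    if g == 1:
        return n.astype(float)
    x = np.zeros(n.shape)
    pos = n > 0
    x[pos] = rng.standard_gamma(n[pos]) * g
    return x


def _digitize(x_electrons, params: CameraParams, rng) -> tuple[np.ndarray, int]:
    s = x_electrons / params.phi + rng.normal(params.S0, params.sigma, size=np.shape(x_electrons))
    s = np.rint(s)
    n_clipped = int(np.count_nonzero((s < 0) | (s > U16_MAX)))
    return np.clip(s, 0, U16_MAX).astype(np.uint16), n_clipped


def simulate_pixel(
    params: CameraParams, n_frames: int, seed, illum_label: str = "unknown"
) -> FrameStack:
    """Simulate one pixel for ``n_frames`` frames (a 1x1 region stack)."""
    rng = _rng(seed)
    n = rng.poisson(params.E, size=n_frames)
    x = _amplify(n, params.g, rng)
    counts, n_clip = _digitize(x, params, rng)
    return FrameStack(
        counts.reshape(n_frames, 1, 1),
        gain_label=gain_label(params.g),
        illum_label=illum_label,
        truth=params,
        n_clipped=n_clip,
    )


def simulate_dark(params: CameraParams, n_frames: int, seed) -> FrameStack:
    """Dark stack (shutter closed): the same pixel process with E = 0."""
    return simulate_pixel(params.with_(E=0.0), n_frames, seed, illum_label="dark")


def simulate_intensity_series(
    levels: np.ndarray,
    shared: CameraParams,
    n_frames: int,
    seed,
    n_dark_frames: int | None = None,
) -> SeriesDataset:
    """One stack per illumination level E, all sharing g/phi/S0/sigma, plus a
    dark stack at the common gain set-point."""
    levels = np.asarray(levels, dtype=float)
    if levels.size == 0 or np.any(levels <= 0):
        raise ValueError("intensity levels must be positive and non-empty")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(levels.size + 1)
    stacks = [
        simulate_pixel(
            shared.with_(E=float(E)),
            n_frames,
            np.random.default_rng(child),
            illum_label=f"level{i}",
        )
        for i, (E, child) in enumerate(zip(levels, children))
    ]
    dark = simulate_dark(shared, n_dark_frames or n_frames, np.random.default_rng(children[-1]))
    return SeriesDataset(stacks, "intensity", {stacks[0].gain_label: dark})


def simulate_gain_series(
    E: float,
    gains,
    phi: float,
    n_frames: int,
    seed,
    per_gain_offsets=None,
    per_gain_sigmas=None,
    S0: float = 100.0,
    sigma: float = 10.0,
    n_dark_frames: int | None = None,
) -> SeriesDataset:
    """One stack per gain set-point at a common illumination E, with a
    matching dark stack per set-point.  Offsets and readout widths may vary
    per set-point (real cameras show a gain-dependent offset)."""
    gains = list(gains)
    offsets = list(per_gain_offsets) if per_gain_offsets is not None else [S0] * len(gains)
    sigmas = list(per_gain_sigmas) if per_gain_sigmas is not None else [sigma] * len(gains)
    if not (len(gains) == len(offsets) == len(sigmas)):
        raise ValueError("gains, per_gain_offsets, per_gain_sigmas must have equal length")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * len(gains))
    stacks, darks = [], {}
    for i, (g, s0, sg) in enumerate(zip(gains, offsets, sigmas)):
        p = CameraParams(E=E, g=g, phi=phi, S0=s0, sigma=sg)
        stk = simulate_pixel(p, n_frames, np.random.default_rng(children[2 * i]), illum_label="common")
        stacks.append(stk)
        darks[stk.gain_label] = simulate_dark(
            p, n_dark_frames or n_frames, np.random.default_rng(children[2 * i + 1])
        )
    return SeriesDataset(stacks, "gain", darks)


def simulate_sensor_region(
    shape: tuple[int, int],
    flux_map,
    shared: CameraParams,
    n_frames: int,
    seed,
    illum_label: str = "region",
) -> FrameStack:
    """Independent-pixel region stack; ``flux_map`` holds per-pixel E values
    (a scalar gives a flat-top illumination profile)."""
    H, W = shape
    flux = np.broadcast_to(np.asarray(flux_map, dtype=float), (H, W))
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(H * W)
    counts = np.empty((n_frames, H, W), dtype=np.uint16)
    n_clip = 0
    for r in range(H):
        for c in range(W):
            rng = np.random.default_rng(children[r * W + c])
            n = rng.poisson(flux[r, c], size=n_frames)
            x = _amplify(n, shared.g, rng)
            s, k = _digitize(x, shared, rng)
            counts[:, r, c] = s
            n_clip += k
    return FrameStack(
        counts,
        gain_label=gain_label(shared.g),
        illum_label=illum_label,
        truth=shared,
        n_clipped=n_clip,
    )


def simulate_beads(
    positions,
    photon_fluxes,
    psf_sigma: float,
    background: float,
    camera: CameraParams,
    gains,
    n_frames: int,
    seed,
    shape: tuple[int, int] = (32, 32),
    per_gain_offsets=None,
) -> list[FrameStack]:
    """Bead movies at several gain set-points with flux held constant.

    Per pixel, the expected photon count is ``background`` plus each bead's
    flux times the exact integral of a unit 2-D Gaussian over the pixel
    area; that expectation then drives the PGN forward process at each gain
    set-point.  Beads must sit at least ``6 * psf_sigma`` from the border so
    no PSF mass is truncated.
    """
    from .psf_validation import integrated_gaussian_model

    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be positive")
    H, W = shape
    margin = 6 * psf_sigma
    for (x, y) in positions:
        if not (margin <= x <= W - margin and margin <= y <= H - margin):
            raise ValueError(f"bead at ({x}, {y}) closer than 6*psf_sigma to the border")
    expected = np.full((H, W), float(background))
    for (x, y), flux in zip(positions, photon_fluxes):
        expected += integrated_gaussian_model(x, y, psf_sigma, flux, 0.0, shape)

    gains = list(gains)
    offsets = list(per_gain_offsets) if per_gain_offsets is not None else [camera.S0] * len(gains)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(gains))
    stacks = []
    for g, s0, child in zip(gains, offsets, children):
        rng = np.random.default_rng(child)
        p = camera.with_(g=g, S0=s0)
        n = rng.poisson(expected, size=(n_frames, H, W))
        x = _amplify(n, g, rng)
        counts, n_clip = _digitize(x, p, rng)
        stacks.append(
            FrameStack(counts, gain_label=gain_label(g), illum_label="beads",
                       truth=p, n_clipped=n_clip)
        )
    return stacks


def simulate_bernoulli_cascade(
    E: float,
    n_stages: int,
    p_ionize: float,
    phi: float,
    S0: float,
    sigma: float,
    n_frames: int,
    seed,
) -> FrameStack:
    """Impact-ionization cascade simulator (illustrative mode).

    Each photoelectron passes through ``n_stages`` register stages; at each
    stage every electron independently spawns one more with probability
    ``p_ionize``, giving an effective gain ``(1 + p_ionize)^n_stages``.  At
    low effective gain the empirical excess noise factor of this process
    falls below the value 2 of the gamma approximation.
    """
    if n_stages < 1 or not (0 <= p_ionize < 1):
        raise ValueError("need n_stages >= 1 and 0 <= p_ionize < 1")
    rng = _rng(seed)
    n = rng.poisson(E, size=n_frames)
    for _ in range(n_stages):
        n = n + rng.binomial(n, p_ionize)
    g_eff = (1 + p_ionize) ** n_stages
    params = CameraParams(E=E, g=max(g_eff, 1.0), phi=phi, S0=S0, sigma=sigma)
    counts, n_clip = _digitize(n.astype(float), params, rng)
    return FrameStack(
        counts.reshape(n_frames, 1, 1),
        gain_label=f"cascade{g_eff:g}",
        illum_label="cascade",
        truth=params,
        n_clipped=n_clip,
    )


# --- presets -------------------------------------------------------------

_BASE = dict(phi=3.5, S0=100.0, sigma=10.0)


def make_preset(name: str, seed, n_frames: int | None = None):
    """Build one of the named study-condition datasets.

    - ``is-25x``: 25x gain, four log-spaced intensity levels, 5000 frames.
    - ``gs-10pe``: common E = 10 pe, gains 5/25/100/300, 5000 frames.
    - ``adu-series``: gain off, six log-spaced levels (5-500 pe), 5000 frames.
    - ``gain-series``: common E = 10 pe, gains 1/5/25/100/300, 5000 frames.
    """
    n = 5000 if n_frames is None else n_frames
    if name == "is-25x":
        shared = CameraParams(E=1.0, g=25.0, **_BASE)
        return simulate_intensity_series(np.geomspace(2.0, 50.0, 4), shared, n, seed)
    if name == "gs-10pe":
        return simulate_gain_series(10.0, [5.0, 25.0, 100.0, 300.0], 3.5, n, seed)
    if name == "adu-series":
        shared = CameraParams(E=1.0, g=1.0, **_BASE)
        return simulate_intensity_series(np.geomspace(5.0, 500.0, 6), shared, n, seed)
    if name == "gain-series":
        return simulate_gain_series(10.0, [1.0, 5.0, 25.0, 100.0, 300.0], 3.5, n, seed)
    raise ValueError(f"unknown preset {name!r}")


PRESETS = ("is-25x", "gs-10pe", "adu-series", "gain-series")
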