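"""PSF-fitting and self-consistency validation tests."""

import numpy as np
import pytest

from emccdcal import noise_model as nm
from emccdcal import simulator as sim
from emccdcal import psf_validation as pv

CAM = nm.CameraParams(E=1.0, g=1.0, phi=3.5, S0=100.0, sigma=10.0)


def test_integrated_gaussian_properties():
    flat = pv.integrated_gaussian_model(8.0, 8.0, 1.2, 0.0, 3.0, (16, 16))
    assert np.allclose(flat, 3.0)
    # spot at a pixel center: fourfold-symmetric expected image
    img = pv.integrated_gaussian_model(7.5, 7.5, 1.2, 1000.0, 0.0, (15, 15))
    assert np.allclose(img, img[::-1, :], rtol=1e-10)
    assert np.allclose(img, img[:, ::-1], rtol=1e-10)
    assert np.allclose(img, img.T, rtol=1e-10)
    # a 6-sigma ROI captures virtually all flux over the background
    roi = pv.integrated_gaussian_model(8.0, 8.0, 1.2, 1000.0, 2.0, (16, 16))
    assert abs(roi.sum() - (2.0 * 256 + 1000.0)) / 1000.0 < 3e-3


def test_tabulated_objective_matches_exact_pgn_loglik():
    """The fit objective is the noise-model log-likelihood summed over
    pixels; the interpolation table agrees with the exact evaluation."""
    camera = CAM.with_(g=25.0)
    stk = sim.simulate_beads([(8.0, 8.0)], [2500.0], 1.2, 5.0, camera.with_(g=1), [25], 1,
                             seed=3, shape=(16, 16))[0]
    roi = stk.counts[0]
    E = pv.integrated_gaussian_model(8.0, 8.0, 1.2, 2500.0, 5.0, (16, 16))
    table = pv.PmfTable(camera, int(roi.min()), int(roi.max()), float(E.max() * 3))
    ll_tab, _ = table.loglik_and_grad(roi.astype(np.int64), E)
    ll_exact = table.exact_loglik(roi.astype(np.int64), E)
    # exact path is itself a direct sum of noise_model log-likelihoods
    manual = sum(
        nm.log_likelihood([int(c)], camera.with_(E=float(e)))
        for c, e in zip(roi.ravel(), E.ravel())
    )
    assert ll_exact == pytest.approx(manual, rel=1e-12)
    assert abs(ll_tab - ll_exact) < 0.01 * roi.size  # interpolation residue


def test_flux_recovery_across_gains():
    """With the true calibration, mean recovered flux agrees with the
    simulated flux within 3 SE at every set-point."""
    stacks = sim.simulate_beads(
        [(10.0, 10.0)], [3000.0], 1.2, 5.0, CAM, [1, 25, 300], 25, seed=5
    )
    for stk in stacks:
        g = sim.nominal_gain(stk.gain_label)
        camera = CAM.with_(g=g)
        rs, cs, origin = pv._roi_around((10.0, 10.0), 5, stk.shape)
        rois = stk.counts[:, rs, cs]
        conv = camera.phi / camera.g
        table = pv.PmfTable(
            camera, int(rois.min()), int(rois.max()),
            max((float(rois.max()) - camera.S0) * conv * 3, 10.0),
        )
        flux = np.array(
            [pv.fit_spot(f, camera, table=table, origin=origin).flux for f in rois]
        )
        se = flux.std(ddof=1) / np.sqrt(len(flux))
        assert abs(flux.mean() - 3000.0) < 3 * se, stk.gain_label


def test_high_flux_near_deterministic_limit():
    """A noiseless expectation image rounded to counts is refit to within
    1% of the generating flux."""
    camera = CAM.with_(g=25.0)
    E = pv.integrated_gaussian_model(8.3, 7.6, 1.2, 50000.0, 10.0, (16, 16))
    counts = np.rint(camera.S0 + E * camera.g / camera.phi).astype(np.int64)
    fit = pv.fit_spot(counts, camera)
    assert abs(fit.flux - 50000.0) / 50000.0 < 0.01
    assert abs(fit.x - 8.3) < 0.05 and abs(fit.y - 7.6) < 0.05


def test_misspecified_gain_biases_flux():
    """Fitting with twice the true gain halves the recovered flux (flux and
    gain enter each pixel mean only as g*E/phi)."""
    stacks = sim.simulate_beads([(10.0, 10.0)], [3000.0], 1.2, 5.0, CAM, [25], 10, seed=6)
    stk = stacks[0]
    rs, cs, origin = pv._roi_around((10.0, 10.0), 5, stk.shape)
    rois = stk.counts[:, rs, cs]
    wrong = CAM.with_(g=50.0)
    flux = np.array([pv.fit_spot(f, wrong, origin=origin).flux for f in rois])
    assert abs(flux.mean() / 3000.0 - 0.5) < 0.05


def test_flux_invariant_to_common_offset_shift():
    stacks = sim.simulate_beads([(10.0, 10.0)], [3000.0], 1.2, 5.0, CAM, [25], 3, seed=8)
    stk = stacks[0]
    rs, cs, origin = pv._roi_around((10.0, 10.0), 5, stk.shape)
    camera = CAM.with_(g=25.0)
    for f0 in stk.counts[:, rs, cs]:
        a = pv.fit_spot(f0, camera, origin=origin)
        b = pv.fit_spot(f0 + 40, camera.with_(S0=camera.S0 + 40), origin=origin)
        assert b.flux == pytest.approx(a.flux, rel=1e-3)


def test_residual_pass_on_gaussian_spots_changes_nothing_much():
    """With a correct PSF model the residual template is noise-level and
    pass-2 fluxes reproduce pass-1 within Monte-Carlo error."""
    camera = CAM.with_(g=25.0)
    stacks = sim.simulate_beads([(10.0, 10.0)], [3000.0], 1.2, 5.0, CAM, [25], 15, seed=9)
    stk = stacks[0]
    rs, cs, origin = pv._roi_around((10.0, 10.0), 5, stk.shape)
    rois = stk.counts[:, rs, cs]
    fits1 = [pv.fit_spot(f, camera, origin=origin) for f in rois]
    fits2 = pv.fit_spot_residual_pass(rois, camera, fits1, origin=origin)
    m1 = np.mean([f.flux for f in fits1])
    m2 = np.mean([f.flux for f in fits2])
    assert abs(m2 - m1) / m1 < 0.02


def test_residual_pass_zero_residual_identity():
    """Zero-residual input produces an identically zero template."""
    camera = CAM.with_(g=25.0)
    fit = pv.SpotFit(x=5.5, y=5.5, sigma_psf=1.2, flux=3000.0, background=5.0)
    model = pv.integrated_gaussian_model(5.5, 5.5, 1.2, 3000.0, 5.0, (11, 11))
    counts = camera.S0 + model * camera.g / camera.phi  # exact expectation
    tmpl = pv.build_residual_template(counts[None], camera, [fit], (11, 11))
    assert np.allclose(tmpl, 0.0, atol=1e-9)


def test_residual_pass_reduces_bias_for_distorted_psf():
    """For a non-Gaussian (two-component) PSF the residual compensation
    moves the recovered flux toward the true photon count."""
    camera = CAM.with_(g=25.0)
    rng = np.random.default_rng(10)
    true_flux = 3000.0
    # mixture PSF: 70% sigma=1.0 core + 30% sigma=2.2 halo
    E = (
        pv.integrated_gaussian_model(8.0, 8.0, 1.0, 0.7 * true_flux, 5.0, (17, 17))
        + pv.integrated_gaussian_model(8.0, 8.0, 2.2, 0.3 * true_flux, 0.0, (17, 17))
    )
    frames = []
    for _ in range(20):
        n = rng.poisson(E)
        x = np.zeros_like(n, dtype=float)
        pos = n > 0
        x[pos] = rng.standard_gamma(n[pos]) * camera.g
        s = np.rint(x / camera.phi + rng.normal(camera.S0, camera.sigma, n.shape))
        frames.append(np.clip(s, 0, 65535).astype(np.int64))
    frames = np.asarray(frames)
    fits1 = [pv.fit_spot(f, camera) for f in frames]
    fits2 = pv.fit_spot_residual_pass(frames, camera, fits1)
    bias1 = abs(np.mean([f.flux for f in fits1]) - true_flux)
    bias2 = abs(np.mean([f.flux for f in fits2]) - true_flux)
    assert bias2 < bias1


def test_consistency_test_discriminates_and_scales():
    gains = [1, 25, 300]
    positions = [(10.0, 10.0), (22.0, 20.0)]
    stacks = sim.simulate_beads(positions, [3000.0, 2500.0], 1.2, 5.0, CAM, gains, 10, seed=11)
    bead_stacks = {s.gain_label: s for s in stacks}

    def calset(fs):
        return {sim.gain_label(g): CAM.with_(g=max(g * f, 1.0)) for g, f in zip(gains, fs)}

    cals = {"truth": calset([1, 1, 1]), "pert": calset([1, 1.2, 0.85])}
    reports = pv.consistency_test(bead_stacks, cals, positions=positions)
    assert reports["truth"].sigma_means < reports["pert"].sigma_means
    assert pv.rank_calibrations(reports)[0] == "truth"

    rep = pv.scale_to_reference(reports["truth"])
    assert rep.scaled_means["1x"] == 1.0
    for v in rep.scaled_means.values():
        assert abs(v - 1.0) < 0.05
    order = sorted(rep.means, key=lambda k: rep.means[k])
    order_scaled = sorted(rep.scaled_means, key=lambda k: rep.scaled_means[k])
    assert order == order_scaled
    with pytest.raises(ValueError, match="absent"):
        pv.scale_to_reference(reports["pert"], reference_label="77x")


def test_consistency_test_guards():
    stacks = sim.simulate_beads([(10.0, 10.0)], [3000.0], 1.2, 5.0, CAM, [25], 2, seed=12)
    one = {s.gain_label: s for s in stacks}
    with pytest.raises(ValueError, match=">= 2 gain set-points"):
        pv.consistency_test(one, {"truth": {"25x": CAM.with_(g=25)}})
    stacks = sim.simulate_beads([(10.0, 10.0)], [3000.0], 1.2, 5.0, CAM, [1, 25], 2, seed=13)
    two = {s.gain_label: s for s in stacks}
    with pytest.raises(ValueError, match="missing set-points"):
        pv.consistency_test(two, {"partial": {"25x": CAM.with_(g=25)}})


def test_degenerate_single_setpoint_report():
    rep = pv.ConsistencyReport("x", {"25x": np.array([3000.0, 2990.0])})
    assert rep.sigma_means == 0.0
    assert rep.degenerate
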