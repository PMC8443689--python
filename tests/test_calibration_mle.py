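"""Series-MLE tests: objective contracts, parameter recovery for every
sharing scheme, scheme-consistency reductions, and estimator invariances."""

import numpy as np
import pytest

from emccdcal import noise_model as nm
from emccdcal import simulator as sim
from emccdcal import calibration_mle as cm
from emccdcal.calibration_mle import Scheme, SeriesModel


def _data(series, pixel=(0, 0)):
    return cm._extract_pixel(series, cm._resolve_darks(series, None), pixel)


def test_single_dataset_objective_equals_noise_model_loglik():
    """A one-level IS_ADU objective is exactly the noise-model
    log-likelihood of that dataset."""
    shared = nm.CameraParams(E=1.0, g=1.0, phi=3.5, S0=100.0, sigma=10.0)
    ds = sim.simulate_intensity_series([50.0], shared, 400, seed=0)
    model = SeriesModel(Scheme.IS_ADU)
    data = _data(ds)
    theta = np.log([3.2, 45.0])
    ll = cm.global_loglik(ds, model, theta, _data=data)
    p = nm.CameraParams(E=45.0, g=1.0, phi=3.2, S0=data.S0[0], sigma=data.sigma[0])
    assert ll == pytest.approx(nm.log_likelihood(ds.stacks[0].pixel(), p), rel=1e-12)


def test_objective_additive_over_dataset_split():
    """Splitting one dataset into two halves with tied parameters leaves
    the global objective unchanged."""
    shared = nm.CameraParams(E=1.0, g=1.0, phi=3.5, S0=100.0, sigma=10.0)
    ds = sim.simulate_intensity_series([80.0], shared, 400, seed=1)
    stack = ds.stacks[0]
    halves = [
        sim.FrameStack(stack.counts[:200], "1x", "a"),
        sim.FrameStack(stack.counts[200:], "1x", "b"),
    ]
    split = sim.SeriesDataset(halves, "intensity", ds.dark_stacks)
    model = SeriesModel(Scheme.IS_ADU)
    ll_one = cm.global_loglik(ds, model, np.log([3.5, 80.0]), _data=_data(ds))
    ll_two = cm.global_loglik(split, model, np.log([3.5, 80.0, 80.0]), _data=_data(split))
    assert ll_one == pytest.approx(ll_two, rel=1e-12)


def test_truth_dominates_perturbed_gain(gain_series_small):
    """With 1500 frames per set-point the objective at truth beats +/-20%
    perturbations of the 25x gain."""
    model = SeriesModel(Scheme.GS_GAIN)
    data = _data(gain_series_small)
    th_true = np.log([10.0, 3.5, 5.0, 25.0, 100.0, 300.0])
    ll_true = cm.global_loglik(gain_series_small, model, th_true, _data=data)
    for f in (0.8, 1.2):
        th = th_true.copy()
        th[3] = np.log(25.0 * f)
        assert cm.global_loglik(gain_series_small, model, th, _data=data) < ll_true


def test_out_of_bounds_theta_is_rejected(gain_series_small):
    model = SeriesModel(Scheme.GS_GAIN)
    data = _data(gain_series_small)
    th = np.log([10.0, 3.5, 5.0, 25.0, 100.0, 300.0])
    bad = th.copy()
    bad[1] = np.log(1e5)  # phi far above its support
    assert cm.global_loglik(gain_series_small, model, bad, _data=data) == -np.inf
    with pytest.raises(ValueError, match="dimension"):
        cm.global_loglik(gain_series_small, model, th[:-1], _data=data)


def test_is_adu_recovery(adu_series):
    """ADU calibration recovers phi within 3 SE at the six-level design."""
    res = cm.fit(adu_series, SeriesModel(Scheme.IS_ADU), compute_se=True)
    assert res.converged
    assert abs(res["phi"] - 3.5) < 3 * res.se["phi"]
    # intensity levels recovered alongside
    for i, E in enumerate(np.geomspace(5, 500, 6)):
        assert abs(res[f"E_level{i}"] - E) / E < 0.2


def test_optimum_beats_moment_initialization(adu_series):
    res = cm.fit(adu_series, SeriesModel(Scheme.IS_ADU))
    assert res.loglik >= res.meta["init_loglik"] - 1e-6


def test_gs_gain_recovery(gain_series_small):
    """Gain-series MLE recovers the shared intensity and each set-point's
    gain within 3 SE."""
    res = cm.fit(gain_series_small, SeriesModel(Scheme.GS_GAIN), compute_se=True)
    assert res.converged
    assert abs(res["E"] - 10.0) < 3 * res.se["E"]
    for lbl, g in (("5x", 5.0), ("25x", 25.0), ("100x", 100.0), ("300x", 300.0)):
        assert abs(res[f"g_{lbl}"] - g) < 3 * res.se[f"g_{lbl}"]


def test_is_gain_and_gs_gain_agree(gain_series_small):
    """The two gain-calibration routes agree within combined SEs on data
    simulated from the exact model (phi fixed, as in the workflow where the
    ADU factor is calibrated first)."""
    shared = nm.CameraParams(E=1.0, g=25.0, phi=3.5, S0=100.0, sigma=10.0)
    is_ds = sim.simulate_intensity_series(np.geomspace(2, 60, 4), shared, 1500, seed=5)
    r_is = cm.fit(is_ds, SeriesModel(Scheme.IS_GAIN, fix_phi=3.5), compute_se=True)
    r_gs = cm.fit(gain_series_small, SeriesModel(Scheme.GS_GAIN), compute_se=True)
    diff = abs(r_is["g"] - r_gs["g_25x"])
    comb = np.hypot(r_is.se["g"], r_gs.se["g_25x"])
    assert diff < 3 * comb


def test_nch_with_zero_drift_reproduces_gs(gain_series_small):
    """Forcing the hierarchical width to zero makes the NCH fit reproduce
    GS_GAIN to optimizer tolerance."""
    r_gs = cm.fit(gain_series_small, SeriesModel(Scheme.GS_GAIN))
    r_nch = cm.fit(gain_series_small, SeriesModel(Scheme.GS_NCH, fix_sigma_E=0.0))
    assert r_nch["E_bar"] == pytest.approx(r_gs["E"], rel=1e-3)
    assert r_nch["phi"] == pytest.approx(r_gs["phi"], rel=1e-3)
    for lbl in ("5x", "25x", "100x", "300x"):
        assert r_nch[f"g_{lbl}"] == pytest.approx(r_gs[f"g_{lbl}"], rel=1e-3)


def test_nch_free_drift_stays_near_gs(gain_series_small):
    """With the drift hyperparameter free, the NCH fit still recovers the
    common intensity and gains (the drift prior keeps it proper)."""
    r = cm.fit(gain_series_small, SeriesModel(Scheme.GS_NCH))
    assert r.converged
    assert abs(r["E_bar"] - 10.0) < 1.0
    assert r["sigma_E_bar"] < 2.0
    assert abs(r["g_25x"] - 25.0) / 25.0 < 0.2


def test_gs_variants(gain_series_small):
    """Including the 1x dataset identifies phi jointly; excluding it
    requires an external phi but still recovers the gains."""
    r_in = cm.fit_gs_variants(gain_series_small, include_unity_gain=True)
    r_ex = cm.fit_gs_variants(gain_series_small, include_unity_gain=False, phi=3.5)
    assert "phi" in r_in.estimates and "phi" not in r_ex.estimates
    assert abs(r_in["g_25x"] - 25.0) / 25.0 < 0.2
    assert abs(r_ex["g_25x"] - 25.0) / 25.0 < 0.2
    with pytest.raises(ValueError, match="phi"):
        cm.fit_gs_variants(gain_series_small, include_unity_gain=False)
    no1x = sim.simulate_gain_series(10.0, [5, 25], 3.5, 100, seed=6)
    with pytest.raises(ValueError, match="no 1x"):
        cm.fit_gs_variants(no1x, include_unity_gain=True)


def test_scheme_series_compatibility(adu_series, gain_series_small):
    with pytest.raises(ValueError, match="intensity series"):
        cm.fit(gain_series_small, SeriesModel(Scheme.IS_ADU))
    with pytest.raises(ValueError, match="gain series"):
        cm.fit(adu_series, SeriesModel(Scheme.GS_GAIN))


def test_offset_shift_invariance():
    """Adding a constant to S0 and every count leaves E, g, phi unchanged."""
    ds = sim.simulate_gain_series(10.0, [1, 25], 3.5, 2000, seed=7)
    shift = 50
    shifted_stacks = [
        sim.FrameStack(s.counts + shift, s.gain_label, s.illum_label) for s in ds.stacks
    ]
    shifted_darks = {
        lbl: sim.FrameStack(d.counts + shift, d.gain_label, d.illum_label)
        for lbl, d in ds.dark_stacks.items()
    }
    shifted = sim.SeriesDataset(shifted_stacks, "gain", shifted_darks)
    r0 = cm.fit(ds, SeriesModel(Scheme.GS_GAIN))
    r1 = cm.fit(shifted, SeriesModel(Scheme.GS_GAIN))
    for k in ("E", "phi", "g_25x"):
        assert r1[k] == pytest.approx(r0[k], rel=1e-4)


def test_region_fit_matches_single_pixel():
    shared = nm.CameraParams(E=1.0, g=1.0, phi=3.5, S0=100.0, sigma=10.0)
    stacks = [
        sim.simulate_sensor_region((1, 2), E, shared, 800, seed=8 + i)
        for i, E in enumerate([50.0, 400.0])
    ]
    dark = sim.simulate_sensor_region((1, 2), 0.0, shared, 800, seed=20)
    dark.gain_label = "1x"
    ds = sim.SeriesDataset(stacks, "intensity", {"1x": dark})
    reg = cm.fit_region(ds, SeriesModel(Scheme.IS_ADU))
    single = cm.fit(ds, SeriesModel(Scheme.IS_ADU), pixel=(0, 1), n_starts=1)
    assert reg["phi"].shape == (1, 2)
    assert reg["phi"][0, 1] == pytest.approx(single["phi"], rel=1e-6)
    assert "summary" in reg.meta


def test_is_adu_estimator_is_unbiased_across_seeds():
    """Across 20 seeds at a reduced four-level design the mean phi estimate
    sits within 2 Monte-Carlo SEs of the true ADU factor."""
    shared = nm.CameraParams(E=1.0, g=1.0, phi=3.5, S0=100.0, sigma=10.0)
    phis = []
    for seed in range(20):
        ds = sim.simulate_intensity_series(
            np.geomspace(20, 800, 4), shared, 800, seed=100 + seed
        )
        phis.append(cm.fit(ds, SeriesModel(Scheme.IS_ADU), n_starts=1)["phi"])
    phis = np.array(phis)
    mcse = phis.std(ddof=1) / np.sqrt(len(phis))
    assert abs(phis.mean() - 3.5) < 2 * mcse
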