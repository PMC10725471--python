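"""Assay curve fits, Bliss synergy, SEC and depolarization quantification."""

import numpy as np
import pytest

from baxdm import assay_models as am
from baxdm import synthetic_data as syn
from baxdm.assay_models import (
    BindingIsotherm,
    DepolarizationTraces,
    DoseMatrix,
    MeltCurve,
    SECProfile,
)


# --------------------------------------------------------------------------
# fit_one_site


def test_noiseless_one_site_recovery():
    iso, _ = syn.gen_isotherm(kd_nm=100.0, b_max=1.0, baseline=0.0, noise_cv=0.0)
    fit = am.fit_one_site(iso)
    assert fit.converged
    assert fit.parameters["K_D"] == pytest.approx(100.0, rel=1e-6)
    assert fit.parameters["B_max"] == pytest.approx(1.0, rel=1e-6)


def test_one_site_grid_search_oracle_agreement():
    iso, _ = syn.gen_isotherm(kd_nm=560.0, noise_cv=0.03, seed=17)
    fit = am.fit_one_site(iso)
    # independent coarse-to-fine grid search over (K_D, B_max), baseline
    # solved in closed form per candidate
    L, y = iso.concentrations, iso.response
    best = (np.inf, None, None)
    for kd in np.geomspace(50, 5000, 4000):
        frac = L / (kd + L)
        # least squares in (B_max, baseline) is linear
        A = np.stack([frac, np.ones_like(frac)], axis=1)
        coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        rss = float(np.sum((A @ coef - y) ** 2))
        if rss < best[0]:
            best = (rss, kd, coef)
    assert fit.parameters["K_D"] == pytest.approx(best[1], rel=2e-3)


def test_one_site_zero_dynamic_range_flagged():
    conc = np.logspace(0, 3, 8)
    iso = BindingIsotherm(conc, np.ones_like(conc))
    fit = am.fit_one_site(iso)
    assert (not fit.converged) or abs(fit.parameters["B_max"]) < 1e-6


def test_one_site_requires_span_and_points():
    with pytest.raises(ValueError, match="5 titration"):
        am.fit_one_site(BindingIsotherm([1, 2, 3, 4], [0, 0.1, 0.2, 0.3]))
    with pytest.raises(ValueError, match="orders of magnitude"):
        am.fit_one_site(BindingIsotherm([1, 2, 4, 8, 16], [0, 0.1, 0.2, 0.3, 0.4]))


def test_kd_recovery_at_reported_wild_type_affinity():
    # median over seeded isotherms at 3% noise within 10% of truth
    kds = []
    for seed in range(25):
        iso, _ = syn.gen_isotherm(kd_nm=560.0, noise_cv=0.03, seed=seed)
        kds.append(am.fit_one_site(iso).parameters["K_D"])
    assert abs(np.median(kds) / 560.0 - 1.0) < 0.10


# --------------------------------------------------------------------------
# fit_competitive_4pl


def test_noiseless_4pl_exact_recovery():
    x = np.logspace(0, 5, 12)
    y = 0.0 + (100.0 - 0.0) / (1 + (x / 1000.0) ** 1.0)
    fit = am.fit_competitive_4pl(x, y, top_fixed=100.0, bottom_fixed=0.0)
    assert fit.converged
    assert fit.parameters["IC50"] == pytest.approx(1000.0, rel=1e-6)
    assert fit.parameters["hill"] == pytest.approx(1.0, rel=1e-6)


def test_4pl_flat_response_flagged_unidentifiable():
    x = np.logspace(0, 4, 10)
    fit = am.fit_competitive_4pl(x, np.full_like(x, 100.0), 100.0, 0.0)
    assert not fit.converged
    assert any("unidentifiable" in f for f in fit.flags)


def test_4pl_matches_grid_search_oracle():
    rng = np.random.default_rng(5)
    x = np.logspace(0.5, 4.5, 14)
    truth = 20.0 + (250.0 - 20.0) / (1 + (x / 800.0) ** 1.3)
    y = truth + rng.normal(0, 2.0, x.size)
    fit = am.fit_competitive_4pl(x, y, top_fixed=250.0, bottom_fixed=20.0)
    best = (np.inf, None)
    for ic50 in np.geomspace(100, 5000, 3000):
        for h in np.linspace(0.5, 2.5, 201):
            pred = 20.0 + 230.0 / (1 + (x / ic50) ** h)
            rss = float(np.sum((pred - y) ** 2))
            if rss < best[0]:
                best = (rss, ic50)
    assert fit.parameters["IC50"] == pytest.approx(best[1], rel=0.01)


# --------------------------------------------------------------------------
# melt curves


def test_noiseless_melt_recovers_planted_tm():
    # the 0-100% anchor rescaling leaves a small residual (the sigmoid is
    # not exactly 0 at the 74 C anchor), bounded well below 0.05 C here
    control, treated, truth = syn.gen_melt_curves(
        tm_control=62.0, delta_tm=4.5, noise_cv=0.0
    )
    fit_c = am.normalize_and_fit_melt(control)
    fit_t = am.normalize_and_fit_melt(treated)
    assert fit_c.parameters["Tm"] == pytest.approx(62.0, abs=0.05)
    assert fit_t.parameters["Tm"] == pytest.approx(57.5, abs=0.05)
    assert am.delta_tm(fit_t, fit_c) == pytest.approx(4.5, abs=0.05)


def test_normalization_maps_anchors_to_100_and_0():
    control, _, _ = syn.gen_melt_curves(noise_cv=0.02, gain=1500.0, seed=3)
    norm = am.normalize_melt(control)
    assert norm.signal[0] == pytest.approx(100.0)  # 25 C anchor
    assert norm.signal[-1] == pytest.approx(0.0)  # 74 C anchor


def test_identical_curves_give_zero_delta_tm():
    control, _, _ = syn.gen_melt_curves(noise_cv=0.0)
    fit = am.normalize_and_fit_melt(control)
    assert am.delta_tm(fit, fit) == pytest.approx(0.0)


def test_missing_anchor_raises():
    curve = MeltCurve(np.array([50.0, 60, 70]), np.array([90.0, 50, 10]),
                      anchors=(25.0, 74.0))
    with pytest.raises(ValueError, match="anchor"):
        am.normalize_and_fit_melt(curve)


def test_rising_melt_signal_is_flagged():
    temps = np.array([25.0, 50, 55, 60, 65, 74])
    signal = np.array([100.0, 20, 80, 15, 10, 0])
    fit = am.normalize_and_fit_melt(MeltCurve(temps, signal))
    assert any("non-monotone" in f for f in fit.flags)


def test_delta_tm_recovery_at_reported_destabilization():
    deltas = []
    for seed in range(25):
        control, treated, _ = syn.gen_melt_curves(
            tm_control=62.0, delta_tm=4.5, noise_cv=0.02, seed=seed
        )
        deltas.append(
            am.delta_tm(
                am.normalize_and_fit_melt(treated), am.normalize_and_fit_melt(control)
            )
        )
    assert abs(np.median(deltas) - 4.5) < 0.5


# --------------------------------------------------------------------------
# bliss synergy


def test_bliss_independent_surface_scores_zero():
    doses = np.array([0.0, 1, 10])
    fa = np.array([0.0, 0.5, 0.8])
    fb = np.array([0.0, 0.4, 0.6])
    effect = fa[:, None] + fb[None, :] - fa[:, None] * fb[None, :]
    result = am.bliss_synergy(DoseMatrix(doses, doses, effect))
    np.testing.assert_allclose(result.score, 0.0, atol=1e-12)
    assert result.summary == pytest.approx(0.0, abs=1e-12)


def test_bliss_excess_over_expectation():
    doses = np.array([0.0, 1.0])
    effect = np.array([[0.0, 0.4], [0.5, 0.8]])
    result = am.bliss_synergy(DoseMatrix(doses, doses, effect))
    assert result.expected[1, 1] == pytest.approx(0.7)
    assert result.score[1, 1] == pytest.approx(0.1)
    assert result.score[0, 0] == 0.0


def test_bliss_zero_dose_cells_score_zero():
    matrix, _ = syn.gen_dose_matrix(synergy_delta=0.2, noise_sd=0.0, seed=0)
    result = am.bliss_synergy(matrix)
    np.testing.assert_allclose(result.score[0, :], 0.0, atol=1e-12)
    np.testing.assert_allclose(result.score[:, 0], 0.0, atol=1e-12)


def test_effect_out_of_bounds_rejected():
    doses = np.array([0.0, 1.0])
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        DoseMatrix(doses, doses, np.array([[0.0, 0.2], [0.3, 1.4]]))


def test_planted_synergy_delta_recovered():
    matrix, truth = syn.gen_dose_matrix(synergy_delta=0.15, noise_sd=0.0, seed=1)
    result = am.bliss_synergy(matrix)
    assert result.summary == pytest.approx(0.15, abs=1e-9)


# --------------------------------------------------------------------------
# SEC


def _profile(**kv):
    labels = ["B2", "B1", "C1", "C2", "C3", "C4", "C5", "C6", "C7", "C8", "C9"]
    intensity = np.array([kv.get(l, 0.0) for l in labels])
    return SECProfile(labels, intensity)


def test_all_intensity_in_c4_is_pure_dimer():
    out = am.sec_quantify(_profile(C4=10.0))
    assert out["dimer_pct"] == pytest.approx(100.0)
    assert out["monomer_pct"] == pytest.approx(0.0)


def test_c6_splits_half_and_half():
    out = am.sec_quantify(_profile(C6=8.0))
    assert out["dimer_pct"] == pytest.approx(50.0)
    assert out["monomer_pct"] == pytest.approx(50.0)


def test_hand_evaluated_mixture():
    # C3=1, C6=2, C7=1: dimer = (1 + 1)/4, monomer = (1 + 1)/4
    out = am.sec_quantify(_profile(C3=1.0, C6=2.0, C7=1.0))
    assert out["dimer_pct"] == pytest.approx(50.0)
    assert out["monomer_pct"] == pytest.approx(50.0)


def test_windows_sum_to_100_when_all_intensity_inside():
    out = am.sec_quantify(_profile(C3=3.0, C5=1.0, C6=4.0, C8=2.0, B1=1.0))
    assert out["monomer_pct"] + out["dimer_pct"] + out["oligomer_pct"] == pytest.approx(100.0)


def test_zero_total_intensity_raises():
    with pytest.raises(ValueError, match="zero total"):
        am.sec_quantify(_profile())


def test_generated_profile_quantifies_near_planted_split():
    profile, _ = syn.gen_sec_profile(dimer_fraction=0.5, seed=0)
    out = am.sec_quantify(profile)
    assert out["dimer_pct"] == pytest.approx(50.0, abs=5.0)
    assert out["monomer_pct"] == pytest.approx(50.0, abs=5.0)


def test_pure_dimer_profile():
    profile, _ = syn.gen_sec_profile(dimer_fraction=1.0, seed=0)
    out = am.sec_quantify(profile)
    assert out["dimer_pct"] == pytest.approx(100.0, abs=1.0)


def test_mw_calibration_two_point_and_midpoint():
    # ovalbumin ~44 kDa, carbonic anhydrase ~29 kDa
    est = am.sec_mw_calibrate([(14.0, 44.0), (16.0, 29.0)])
    assert est(14.0) == pytest.approx((44.0, False))
    assert est(16.0)[0] == pytest.approx(29.0)
    mid, extrapolated = est(15.0)
    assert mid == pytest.approx(np.sqrt(44.0 * 29.0), rel=1e-9)  # geometric mean
    assert not extrapolated
    assert est(18.0)[1] is True


def test_mw_calibration_rejects_duplicates():
    with pytest.raises(ValueError, match="duplicate"):
        am.sec_mw_calibrate([(14.0, 44.0), (14.0, 29.0)])


# --------------------------------------------------------------------------
# depolarization


def _traces(sample):
    t = np.arange(0, 181, 15, dtype=float)
    dmso = np.full_like(t, 1000.0)
    cccp = np.full_like(t, 200.0)
    return DepolarizationTraces(t, {"s": sample(t, dmso, cccp)}, dmso, cccp)


def test_dmso_trace_maps_to_zero_percent():
    tr = _traces(lambda t, d, c: d.copy())
    assert am.depolarization_percent(tr)["s"]["percent"] == pytest.approx(0.0)


def test_cccp_trace_maps_to_100_percent():
    tr = _traces(lambda t, d, c: c.copy())
    assert am.depolarization_percent(tr)["s"]["percent"] == pytest.approx(100.0)


def test_midpoint_auc_maps_to_50_percent():
    tr = _traces(lambda t, d, c: (d + c) / 2)
    assert am.depolarization_percent(tr)["s"]["percent"] == pytest.approx(50.0)


def test_out_of_range_flagged_not_clipped():
    tr = _traces(lambda t, d, c: c - 100.0)  # deeper than CCCP
    out = am.depolarization_percent(tr)["s"]
    assert out["percent"] > 100.0
    assert out["out_of_range"]


def test_no_dynamic_range_raises():
    t = np.arange(0, 46, 15, dtype=float)
    flat = np.full_like(t, 500.0)
    with pytest.raises(ValueError, match="dynamic range"):
        am.depolarization_percent(
            DepolarizationTraces(t, {"s": flat}, flat.copy(), flat.copy())
        )


def test_depolarization_invariant_to_affine_gain():
    t = np.arange(0, 181, 15, dtype=float)
    rng = np.random.default_rng(2)
    dmso = 1000 + rng.normal(0, 5, t.size)
    cccp = 300 + rng.normal(0, 5, t.size)
    sample = 600 + rng.normal(0, 5, t.size)
    base = am.depolarization_percent(
        DepolarizationTraces(t, {"s": sample}, dmso, cccp)
    )["s"]["percent"]
    gained = am.depolarization_percent(
        DepolarizationTraces(
            t, {"s": 3.0 * sample + 50}, 3.0 * dmso + 50, 3.0 * cccp + 50
        )
    )["s"]["percent"]
    assert gained == pytest.approx(base, rel=1e-12)
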