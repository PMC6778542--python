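import numpy as np
import pytest

from raclmap.kinetics import (BiexpReference, FrameSchedule, KineticParams,
                              NoiseConfig, TimeActivityCurve, batch_bpnd,
                              default_schedule, logan_fit, read_tacs,
                              simulate_reference_tac, simulate_srtm_tac,
                              srtm_curve, srtm_curve_numeric, write_tacs)


def test_default_schedule_is_55_min_18_frames():
    sched = default_schedule()
    assert len(sched) == 18
    assert sched.total_duration == pytest.approx(55.0)


def test_schedule_validation():
    with pytest.raises(ValueError):
        FrameSchedule.from_durations([1.0, -2.0])
    with pytest.raises(ValueError):
        TimeActivityCurve(default_schedule(), np.ones(5))


def test_reference_peak_matches_calculus():
    # d/dt [A (e^{-l1 t} - e^{-l2 t})] = 0  =>  t = ln(l2/l1)/(l2-l1)
    ref = BiexpReference(30.0, 0.03, 0.6)
    expected = np.log(0.6 / 0.03) / (0.6 - 0.03)
    assert ref.peak_time == pytest.approx(expected, rel=1e-12)
    t = np.linspace(0.01, 20, 5000)
    assert abs(ref.peak_time - t[np.argmax(ref(t))]) < 0.01


def test_srtm_closed_form_matches_numeric_convolution():
    ref = BiexpReference(30.0, 0.03, 0.6)
    params = KineticParams(r1=0.9, k2=0.35, bp_nd=2.2)
    t = np.linspace(0.5, 55, 40)
    closed = srtm_curve(ref, params, t)
    numeric = srtm_curve_numeric(ref, params, t)
    assert np.allclose(closed, numeric, rtol=1e-4, atol=1e-4)


def test_zero_binding_equals_reference():
    ref = BiexpReference(30.0, 0.03, 0.6)
    sched = default_schedule()
    target = simulate_srtm_tac(ref, KineticParams(r1=1.0, k2=0.4, bp_nd=0.0),
                               sched)
    reference = simulate_reference_tac(sched, ref)
    assert np.allclose(target.activity, reference.activity, rtol=1e-10)


def test_logan_reference_against_itself_gives_zero_bp():
    sched = default_schedule()
    ref = simulate_reference_tac(sched, BiexpReference(30.0, 0.03, 0.6))
    for method in ("ols", "perpendicular"):
        res = logan_fit(ref, ref, method=method)
        assert res.slope == pytest.approx(1.0, abs=1e-10)
        assert res.bp_nd == pytest.approx(0.0, abs=1e-10)


def test_noiseless_round_trip_at_defaults():
    ref_curve = BiexpReference(30.0, 0.03, 0.6)
    sched = default_schedule()
    reference = simulate_reference_tac(sched, ref_curve)
    for bp in (0.1, 0.5, 1.0, 3.0):
        target = simulate_srtm_tac(ref_curve, KineticParams(bp_nd=bp), sched)
        res = logan_fit(target, reference)
        assert abs(res.bp_nd - bp) / bp < 0.02, (bp, res.bp_nd)


def test_coarse_frames_agree_with_dense_sampling_oracle():
    # the frame schedule itself introduces <0.5% of the Logan estimate:
    # 1-second frames (a near-continuous oracle) give nearly the same
    # slope as the 18-frame schedule
    ref_curve = BiexpReference(30.0, 0.03, 0.6)
    params = KineticParams(r1=1.0, k2=0.3, bp_nd=3.0)
    coarse = default_schedule()
    dense = FrameSchedule.from_durations([1.0 / 60] * (55 * 60))
    est = {}
    for name, sched in (("coarse", coarse), ("dense", dense)):
        ref = simulate_reference_tac(sched, ref_curve)
        tgt = simulate_srtm_tac(ref_curve, params, sched)
        est[name] = logan_fit(tgt, ref).bp_nd
    assert abs(est["coarse"] - est["dense"]) / est["dense"] < 0.005


def test_logan_dvr_scale_invariance():
    # multiplying both TACs by a constant leaves the slope unchanged
    ref_curve = BiexpReference(30.0, 0.03, 0.6)
    sched = default_schedule()
    ref = simulate_reference_tac(sched, ref_curve)
    tgt = simulate_srtm_tac(ref_curve, KineticParams(bp_nd=1.5), sched)
    base = logan_fit(tgt, ref).slope
    scaled = logan_fit(
        TimeActivityCurve(sched, tgt.activity * 7.3),
        TimeActivityCurve(sched, ref.activity * 7.3)).slope
    assert scaled == pytest.approx(base, rel=1e-10)


def test_tls_matches_ols_on_exact_line():
    sched = default_schedule()
    mid = sched.midpoint
    # synthetic exactly-linear Logan coordinates via constructed TACs is
    # awkward; test the regression property through identical results on
    # a TAC pair whose plot is nearly exactly linear (noiseless, late t*)
    ref_curve = BiexpReference(30.0, 0.03, 0.6)
    ref = simulate_reference_tac(sched, ref_curve)
    tgt = simulate_srtm_tac(ref_curve, KineticParams(bp_nd=0.3), sched)
    perp = logan_fit(tgt, ref, t_star=30.0, method="perpendicular")
    ols = logan_fit(tgt, ref, t_star=30.0, method="ols")
    assert perp.slope == pytest.approx(ols.slope, rel=1e-4)
    assert mid[mid >= 30.0].size == perp.n_points_used


def test_logan_error_cases():
    sched = default_schedule()
    ref_curve = BiexpReference(30.0, 0.03, 0.6)
    ref = simulate_reference_tac(sched, ref_curve)
    tgt = simulate_srtm_tac(ref_curve, KineticParams(bp_nd=1.0), sched)
    with pytest.raises(ValueError, match="method"):
        logan_fit(tgt, ref, method="ridge")
    with pytest.raises(ValueError, match="t_star"):
        logan_fit(tgt, ref, t_star=54.0)
    other = FrameSchedule.from_durations([5.0] * 11)
    with pytest.raises(ValueError, match="schedule"):
        logan_fit(tgt, simulate_reference_tac(other, ref_curve))
    bad = TimeActivityCurve(sched, np.zeros(18))
    with pytest.raises(ValueError, match="non-positive"):
        logan_fit(bad, ref)


def test_perpendicular_bias_not_worse_than_ols_under_noise():
    # calibrated noise (~10% CV in single-fit BP_ND); the perpendicular
    # estimator's median bias must not exceed OLS's in magnitude
    ref_curve = BiexpReference(30.0, 0.03, 0.6)
    sched = default_schedule()
    params = KineticParams(bp_nd=2.0)
    noise = NoiseConfig(sigma=1.6)
    errs = {"ols": [], "perpendicular": []}
    for seed in range(200):
        rng = np.random.default_rng(seed)
        ref = simulate_reference_tac(sched, ref_curve, noise, rng=rng)
        tgt = simulate_srtm_tac(ref_curve, params, sched, noise, rng=rng)
        for method in errs:
            errs[method].append(logan_fit(tgt, ref, method=method).bp_nd - 2.0)
    assert abs(np.median(errs["perpendicular"])) <= abs(np.median(errs["ols"])) + 1e-9


def test_write_read_tacs_round_trip(tmp_path):
    sched = default_schedule()
    ref_curve = BiexpReference(30.0, 0.03, 0.6)
    tacs = [simulate_reference_tac(sched, ref_curve),
            simulate_srtm_tac(ref_curve, KineticParams(bp_nd=1.0), sched,
                              region="Pt_L")]
    tacs[0] = TimeActivityCurve(sched, tacs[0].activity, region="cerebellum")
    path = tmp_path / "tacs.csv"
    write_tacs(tacs, path)
    back = read_tacs(path)
    assert [t.region for t in back] == ["cerebellum", "Pt_L"]
    for a, b in zip(tacs, back):
        assert np.allclose(a.activity, b.activity)
        assert np.allclose(a.schedule.duration, b.schedule.duration)


def test_batch_bpnd_records_failures_as_missing(caplog):
    sched = default_schedule()
    ref_curve = BiexpReference(30.0, 0.03, 0.6)
    ref = simulate_reference_tac(sched, ref_curve)
    good = simulate_srtm_tac(ref_curve, KineticParams(bp_nd=1.0), sched)
    bad = TimeActivityCurve(sched, np.zeros(18))
    table = batch_bpnd({"s1": {"Pt_L": good, "Cd_L": bad}}, {"s1": ref})
    assert len(table) == 2
    row_bad = table[table["region"] == "Cd"]
    assert row_bad["bp_nd"].isna().all()
    assert np.isfinite(table[table["region"] == "Pt"]["bp_nd"]).all()
    with pytest.raises(ValueError, match="reference"):
        batch_bpnd({"s2": {"Pt_L": good}}, {"s1": ref})
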