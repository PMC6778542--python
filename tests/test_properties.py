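"""Property-based invariants (hypothesis, derandomized for reproducibility)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from raclmap import fml_discrepancy, spearman
from raclmap.kinetics import (BiexpReference, KineticParams, default_schedule,
                              logan_fit, simulate_reference_tac,
                              simulate_srtm_tac)
from raclmap.kinetics import _tls_slope

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")


def _random_spd(rng, p):
    A = rng.standard_normal((p + 3, p))
    S = A.T @ A / (p + 3)
    return S + 0.1 * np.eye(p)


@given(st.integers(0, 10_000), st.integers(3, 8))
def test_fml_permutation_invariance(seed, p):
    rng = np.random.default_rng(seed)
    S = _random_spd(rng, p)
    sigma = _random_spd(rng, p)
    perm = rng.permutation(p)
    base = fml_discrepancy(S, None, sigma, None)
    permuted = fml_discrepancy(S[np.ix_(perm, perm)], None,
                               sigma[np.ix_(perm, perm)], None)
    assert permuted == pytest.approx(base, rel=1e-9, abs=1e-10)


@given(st.integers(0, 10_000))
def test_fml_nonnegative_and_zero_at_truth(seed):
    rng = np.random.default_rng(seed)
    S = _random_spd(rng, 5)
    sigma = _random_spd(rng, 5)
    assert fml_discrepancy(S, None, sigma, None) >= -1e-12
    assert fml_discrepancy(S, None, S, None) == pytest.approx(0.0, abs=1e-9)


@given(st.integers(0, 10_000))
def test_spearman_monotone_and_symmetry(seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(25)
    y = rng.standard_normal(25)
    rho, _ = spearman(x, y)
    assert spearman(y, x)[0] == pytest.approx(rho)
    assert spearman(np.expm1(x), y)[0] == pytest.approx(rho)
    assert spearman(-x, y)[0] == pytest.approx(-rho)
    assert -1.0 <= rho <= 1.0


@given(st.integers(0, 10_000))
def test_tls_slope_is_scale_consistent_and_bracketed(seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(30)
    beta = rng.uniform(0.2, 5.0)
    y = beta * x + 0.05 * rng.standard_normal(30)
    slope = _tls_slope(x, y)
    # joint rotation-free invariances: simultaneous scaling of both axes
    assert _tls_slope(3.0 * x, 3.0 * y) == pytest.approx(slope, rel=1e-9)
    # TLS slope magnitude lies between the OLS y-on-x slope and the
    # inverse of the OLS x-on-y slope (classical bracketing)
    b_yx = np.polyfit(x, y, 1)[0]
    b_inv = 1.0 / np.polyfit(y, x, 1)[0]
    lo, hi = sorted((b_yx, b_inv))
    assert lo - 1e-9 <= slope <= hi + 1e-9


@given(st.floats(0.05, 4.0), st.floats(0.25, 0.6))
def test_logan_bp_monotone_in_true_bp(bp, k2):
    # DVR estimate increases with true BP_ND and stays within 5% at the
    # package defaults for any efflux in the plausible range
    curve = BiexpReference(30.0, 0.03, 0.6)
    sched = default_schedule()
    ref = simulate_reference_tac(sched, curve)
    est = logan_fit(simulate_srtm_tac(curve, KineticParams(k2=k2, bp_nd=bp),
                                      sched), ref).bp_nd
    assert est == pytest.approx(bp, rel=0.08, abs=0.02)


@given(st.integers(0, 10_000))
def test_wide_long_round_trip_random(seed):
    from raclmap.regions import long_table, wide_table
    rng = np.random.default_rng(seed)
    rows = [(f"s{i}", r, h, float(rng.standard_normal()))
            for i in range(4) for r in ("Pt", "Hc") for h in ("L", "R")]
    long = pd.DataFrame(rows, columns=["subject_id", "region", "hemisphere",
                                       "bp_nd"])
    back = long_table(wide_table(long))
    merged = long.merge(back, on=["subject_id", "region", "hemisphere"],
                        suffixes=("", "_rt"))
    assert np.allclose(merged["bp_nd"], merged["bp_nd_rt"])
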