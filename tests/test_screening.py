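import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from raclmap import (compare_external_density, one_sample_t, screen_outliers,
                     skew_kurtosis, spearman)
from raclmap.screening import SUBSET_PRESETS, load_external_table, mahalanobis_d2


def test_one_sample_t_matches_scipy(rng):
    x = rng.normal(0.3, 1.0, 50)
    t, p, df = one_sample_t(x)
    ref = stats.ttest_1samp(x, 0.0)
    assert t == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue)
    assert df == 49


def test_spearman_matches_scipy_and_validates(rng):
    x = rng.normal(size=30)
    y = x + rng.normal(size=30)
    rho, p = spearman(x, y)
    ref = stats.spearmanr(x, y)
    assert rho == pytest.approx(ref.statistic)
    with pytest.raises(ValueError):
        spearman([1, 2, 3], [4, 5, 6])          # n < 4
    with pytest.raises(ValueError):
        spearman([1, 1, 1, 1], [1, 2, 3, 4])    # constant vector


def test_spearman_monotone_invariance(rng):
    x = rng.normal(size=40)
    y = rng.normal(size=40)
    rho, _ = spearman(x, y)
    rho2, _ = spearman(np.exp(x), y)            # strictly monotone transform
    assert rho2 == pytest.approx(rho)


def test_skew_kurtosis_flags():
    rng = np.random.default_rng(4)
    normal = rng.normal(size=2000)
    sk, ku, ok = skew_kurtosis(normal)
    assert ok and abs(sk) < 0.2 and abs(ku) < 0.5
    skewed = rng.exponential(size=2000) ** 2
    _, _, ok_bad = skew_kurtosis(skewed)
    assert not ok_bad


def test_screen_outliers_flags_planted_value(rng):
    data = pd.DataFrame(rng.normal(0, 1, size=(200, 4)),
                        columns=list("abcd"))
    data.loc[5, "a"] = 40.0
    screened, report = screen_outliers(data)
    assert np.isnan(screened.loc[5, "a"])
    assert report.univariate_excluded["a"] == 1
    n_removed = sum(report.univariate_excluded.values())
    assert report.fraction_missing == pytest.approx(n_removed / 800)
    # JSON export round-trips
    payload = json.loads(report.to_json())
    assert payload["univariate_excluded"]["a"] == 1


def test_screen_outliers_multivariate(rng):
    n = 300
    data = pd.DataFrame(rng.normal(0, 1, size=(n, 3)), columns=list("abc"))
    # a row extreme jointly but mild marginally
    data.loc[7] = [2.8, -2.8, 2.8]
    screened, report = screen_outliers(data, z_cut=3.29, maha_p=0.001)
    assert report.multivariate_excluded >= 1
    assert screened.loc[7].isna().all()


def test_screen_missing_fraction_warning(rng):
    data = pd.DataFrame(rng.normal(0, 1, size=(50, 2)), columns=["a", "b"])
    data.loc[0, "a"] = 100.0
    data.loc[1, "b"] = 100.0
    _, report = screen_outliers(data, max_missing_fraction=0.01)
    assert any("above" in w for w in report.warnings)


def test_mahalanobis_d2_oracle(rng):
    data = pd.DataFrame(rng.normal(size=(100, 2)), columns=["a", "b"])
    d2 = mahalanobis_d2(data)
    c = data - data.mean()
    S_inv = np.linalg.inv(data.cov().to_numpy())
    manual = np.einsum("ij,jk,ik->i", c.to_numpy(), S_inv, c.to_numpy())
    assert np.allclose(d2.to_numpy(), manual)


def test_external_density_comparison_presets():
    ext = load_external_table()
    assert {"region", "value"} <= set(ext.columns)
    bp = ext.rename(columns={"value": "bp_nd"}).copy()
    bp["bp_nd"] = bp["bp_nd"].rank()      # monotone in the external values
    rho, p, n = compare_external_density(bp, ext, region_subset="all")
    assert rho == pytest.approx(1.0)
    assert n == len(ext)
    rho_es, _, n_es = compare_external_density(bp, ext,
                                               region_subset="extrastriatal")
    excluded = SUBSET_PRESETS["extrastriatal"]["exclude"]
    assert n_es == len(ext[~ext["region"].isin(excluded)])


def test_external_density_requires_mapping_for_unknown_regions():
    ext = pd.DataFrame({"region": ["putamen"], "value": [20.0]})
    bp = pd.DataFrame({"region": ["Pt"], "bp_nd": [3.0]})
    with pytest.raises(ValueError, match="mapping"):
        compare_external_density(bp, ext)
    # with the mapping, too few regions for spearman -> its own error
    with pytest.raises(ValueError):
        compare_external_density(bp, ext, mapping={"putamen": "Pt"})
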