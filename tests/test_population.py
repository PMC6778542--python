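import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from raclmap import (KineticConfig, attach_tacs, batch_bpnd,
                     default_population, simulate_bp_table)
from raclmap.regions import HEMISPHERES


def test_default_population_structure():
    pop = default_population("anatomical")
    assert pop.n_subjects == 176
    assert len(pop.indicators) == 16
    assert set(pop.factor_corr.index) == {"Striatum", "Limbic", "Neocortex"}
    assert all(v == 0.9 for v in pop.first_order_loadings.values())
    # latent scale follows the reported precision of each latent mean
    assert pop.latent_sd["Pt"] == pytest.approx(0.020 * np.sqrt(176))


def test_functional_population_has_striatal_block_and_cross_loading():
    pop = default_population("functional")
    assert pop.striatal is not None
    assert pop.second_order_loadings["ACC"] == {"Limbic": 0.5,
                                                "Associative": 0.5}
    assert default_population("anatomical").striatal is None
    with pytest.raises(ValueError, match="model_id"):
        default_population("cortical")


def test_population_validation():
    pop = default_population("anatomical")
    bad = pop.factor_corr.copy()
    bad.iloc[0, 1] = 0.2     # asymmetric
    with pytest.raises(ValueError):
        replace(pop, factor_corr=bad)


def test_simulation_determinism_and_seed_sensitivity():
    pop = default_population("anatomical", n_subjects=20, seed=9)
    a = simulate_bp_table(pop).bp_table
    b = simulate_bp_table(pop).bp_table
    pd.testing.assert_frame_equal(a, b)
    c = simulate_bp_table(replace(pop, seed=10)).bp_table
    assert not np.allclose(a["bp_nd"], c["bp_nd"])


def test_subject_streams_stable_under_cohort_growth():
    # per-subject substreams: the first subjects' draws do not change when
    # the cohort grows
    small = simulate_bp_table(
        default_population("anatomical", n_subjects=5, seed=9)).bp_table
    large = simulate_bp_table(
        default_population("anatomical", n_subjects=8, seed=9)).bp_table
    merged = small.merge(large, on=["subject_id", "region", "hemisphere"],
                         suffixes=("_s", "_l"))
    assert len(merged) == len(small)
    assert np.allclose(merged["bp_nd_s"], merged["bp_nd_l"])


def test_empirical_moments_match_population(anatomical_cohort):
    ds = simulate_bp_table(
        default_population("anatomical", n_subjects=20000, seed=5))
    wide = ds.wide()
    implied = ds.params.implied_cov()
    emp = wide.cov().loc[implied.index, implied.columns]
    assert np.allclose(emp.to_numpy(), implied.to_numpy(), atol=0.06)
    mu = ds.params.implied_mean()
    assert np.allclose(wide.mean().loc[mu.index], mu, atol=0.03)


def test_neighbor_pairs_raise_residual_correlation(anatomical_cohort):
    # Hc_L and Amy_L share a residual covariance; their partialled
    # correlation (given factors) is positive in expectation
    implied = anatomical_cohort.params.implied_cov()
    pairs = dict(((a, b), v) for a, b, v
                 in anatomical_cohort.params.residual_cov_pairs)
    assert pairs[("Hc_L", "Amy_L")] > 0


def test_true_scores_align_with_observations(anatomical_cohort):
    # indicators correlate strongly with their generating region factor
    wide = anatomical_cohort.wide()
    ts = anatomical_cohort.true_scores
    r = np.corrcoef(wide["Pt_L"], ts.loc[wide.index, "Pt"])[0, 1]
    assert r > 0.8


def test_attach_tacs_round_trip_noiseless():
    ds = simulate_bp_table(default_population("anatomical", n_subjects=4,
                                              seed=3))
    tacs, refs = attach_tacs(ds, KineticConfig())
    bp = batch_bpnd(tacs, refs)
    merged = bp.merge(ds.bp_table, on=["subject_id", "region", "hemisphere"],
                      suffixes=("_est", "_true"))
    assert len(merged) == len(bp)
    rel = np.abs(merged["bp_nd_est"] - merged["bp_nd_true"]) / \
        np.maximum(merged["bp_nd_true"], 0.05)
    assert rel.max() < 0.02


def test_negative_bp_policy():
    ds = simulate_bp_table(default_population("anatomical", n_subjects=4,
                                              seed=3))
    tbl = ds.bp_table.copy()
    tbl.loc[tbl.index[0], "bp_nd"] = -0.2
    broken = replace(ds)
    broken.bp_table = tbl
    with pytest.raises(ValueError, match="negative"):
        attach_tacs(broken, KineticConfig(negative_bp="reject"))
    tacs, refs = attach_tacs(broken, KineticConfig(negative_bp="truncate"))
    bp = batch_bpnd(tacs, refs)
    row = bp.iloc[0]
    assert abs(row["bp_nd"]) < 0.02     # truncated to 0 binding


def test_striatal_block_jointly_correlated():
    ds = simulate_bp_table(default_population("functional", n_subjects=20000,
                                              seed=6))
    sw = ds.striatal_wide()
    assert set(sw.columns) == {"VST", "AST", "SMS"}
    ts = ds.true_scores
    # VST correlates with the Limbic factor per the generating matrix (0.27)
    r = np.corrcoef(sw["VST"], ts.loc[sw.index, "Limbic"])[0, 1]
    assert abs(r - ds.params.striatal.factor_corr.loc["VST", "Limbic"]) < 0.05
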