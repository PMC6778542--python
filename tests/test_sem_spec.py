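import pytest

from raclmap import (Constraint, ModelSpec, build_anatomical_spec,
                     build_functional_spec, build_one_factor_spec, count_df)
from raclmap.regions import NeighborPolicy


def test_reference_degrees_of_freedom():
    anat = build_anatomical_spec()
    func = build_functional_spec()
    assert count_df(anat) == 75
    assert count_df(build_one_factor_spec(anat)) == 86
    assert count_df(func) == 116
    assert count_df(build_one_factor_spec(func)) == 129


def test_df_without_residual_covariances():
    with pytest.warns(UserWarning, match="not 18"):
        bare = build_anatomical_spec(policy=NeighborPolicy())
    assert count_df(bare) == 93          # 75 + 18 restored moments


def test_mean_structure_does_not_change_df():
    # saturated mean structure: every added moment gets a free parameter
    anat = build_anatomical_spec(mean_structure=True)
    assert count_df(anat) == 75


def test_marker_scaling():
    anat = build_anatomical_spec()
    for f in anat.factors1:
        assert anat.marker_of(f) == f + "_L"
    # second-order markers: the first single-membership region
    assert anat.second_order["Striatum"]["Pt"] == 1.0
    func = build_functional_spec()
    # the ACC cross-loads, so it can never be a marker
    assert func.second_order["Limbic"]["ACC"] == "free"
    assert func.second_order["Associative"]["ACC"] == "free"


def test_parameter_names_count_matches_df():
    anat = build_anatomical_spec()
    p = len(anat.indicators)
    moments = p * (p + 1) // 2
    assert moments - len(anat.parameter_names()) == 75


def test_fix_constraint_increases_df():
    anat = build_anatomical_spec().standardized_second_order()
    fixed = anat.constrain(
        Constraint("fix", ("phi[Striatum,Limbic]",), value=1.0))
    assert count_df(fixed) == count_df(anat) + 1
    assert "phi[Striatum,Limbic]" not in fixed.parameter_names()
    assert "phi[Striatum,Limbic]" in fixed.parameter_names(
        ignore_constraints=True)


def test_equal_constraint_increases_df():
    anat = build_anatomical_spec().standardized_second_order()
    eq = anat.constrain(Constraint(
        "equal", ("phi[Striatum,Limbic]", "phi[Striatum,Neocortex]")))
    assert count_df(eq) == count_df(anat) + 1


def test_constraint_validation():
    with pytest.raises(ValueError):
        Constraint("fix", ("phi[a,b]",))                  # fix needs a value
    with pytest.raises(ValueError):
        Constraint("equal", ("phi[a,b]",))                # equal needs >= 2
    anat = build_anatomical_spec()
    with pytest.raises(ValueError, match="unknown parameter"):
        anat.constrain(Constraint("fix", ("lam9[nope]",), value=1.0))


def test_standardized_second_order_frees_loadings():
    std = build_anatomical_spec().standardized_second_order()
    assert std.std_second_order
    for g, loadings in std.second_order.items():
        assert all(v == "free" for v in loadings.values())
    # same df: fixed factor variances trade against freed marker loadings
    assert count_df(std) == 75


def test_serialization_round_trips():
    for spec in (build_anatomical_spec(mean_structure=True),
                 build_functional_spec().standardized_second_order()):
        for dump, load in ((spec.to_yaml, ModelSpec.from_yaml),
                           (spec.to_json, ModelSpec.from_json)):
            back = load(dump())
            assert back.indicators == spec.indicators
            assert back.first_order == spec.first_order
            assert back.second_order == spec.second_order
            assert back.mean_structure == spec.mean_structure
            assert count_df(back) == count_df(spec)


def test_spec_validation_errors():
    with pytest.raises(ValueError):
        ModelSpec(indicators=("a", "b"),
                  first_order={"F": {"a": 1.0, "c": "free"}},   # unknown ind
                  second_order={})
    with pytest.raises(ValueError):
        ModelSpec(indicators=("a", "b"),
                  first_order={"F": {"a": 1.0, "b": "free"}},
                  second_order={"G": {"H": 1.0}})               # unknown factor
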