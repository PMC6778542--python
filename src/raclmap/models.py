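"""Concrete factor-model specifications and the striatal-linkage analysis.

Four shipped specifications of regional [11C]raclopride BP_ND:

* **anatomical** — 16 hemispheric indicators, 8 first-order region factors,
  second-order Striatum {Pt, Cd}, Limbic {Hc, Amy}, Neocortex {FC, OC, TC,
  PC}; default residual-covariance policy gives df = 75.
* **anatomical one-factor** — same indicators, one general factor; df = 86.
* **functional** — 18 indicators, 9 first-order factors, second-order
  Limbic / Associative / Sensorimotor pathway factors with ACC
  cross-loading on Limbic and Associative; df = 116.
* **functional one-factor** — df = 129.

The striatal-linkage analysis extends the functional model with the three
observed striatal subdivisions (ventral, associative, sensorimotor; mean
of left and right) entering as single-indicator variables freely
correlated with the pathway factors and with each other, and reports both
raw and adjusted (partial) factor-striatum correlations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regions import (ANATOMICAL_FACTORS, ANATOMICAL_REGIONS,
                      DEFAULT_ANATOMICAL_POLICY, DEFAULT_FUNCTIONAL_POLICY,
                      FUNCTIONAL_FACTORS, FUNCTIONAL_REGIONS, HEMISPHERES,
                      STRIATAL_SUBDIVISIONS, NeighborPolicy, composite_scores,
                      indicator, wide_table)
from .sem import (FREE, Constraint, FactorModelResults, HierarchicalFactorModel,
                  ModelSpec, chi_square_diff, count_df)

logger = logging.getLogger(__name__)

__all__ = [
    "build_anatomical_spec", "build_one_factor_spec", "build_functional_spec",
    "striatal_linkage", "StriatalLinkageReport", "partial_correlation",
    "composite_scores",
]


def _hemispheric_first_order(regions) -> tuple[tuple[str, ...], dict]:
    indicators = tuple(indicator(r, h) for r in regions for h in HEMISPHERES)
    first_order = {r: {indicator(r, "L"): 1.0, indicator(r, "R"): FREE}
                   for r in regions}
    return indicators, first_order


def _second_order(groups: dict[str, tuple[str, ...]]) -> dict:
    """Marker-scaled second-order block; the marker of each factor is its
    first member that loads on no other factor (cross-loaders stay free)."""
    membership: dict[str, int] = {}
    for members in groups.values():
        for m in members:
            membership[m] = membership.get(m, 0) + 1
    out = {}
    for g, members in groups.items():
        marker = next(m for m in members if membership[m] == 1)
        out[g] = {m: (1.0 if m == marker else FREE) for m in members}
    return out


def build_anatomical_spec(policy: NeighborPolicy = DEFAULT_ANATOMICAL_POLICY,
                          mean_structure: bool = False) -> ModelSpec:
    """Hierarchical striatum / limbic / neocortex model (reference df = 75)."""
    indicators, first_order = _hemispheric_first_order(ANATOMICAL_REGIONS)
    pairs = tuple(policy.indicator_pairs())
    if len(pairs) != 18:
        warnings.warn(
            f"anatomical policy has {len(pairs)} residual covariances, not 18; "
            "df will differ from the reference value of 75", stacklevel=2)
    return ModelSpec(
        indicators=indicators,
        first_order=first_order,
        second_order=_second_order(ANATOMICAL_FACTORS),
        residual_cov_pairs=pairs,
        mean_structure=mean_structure,
        name="anatomical",
    )


def build_functional_spec(policy: NeighborPolicy = DEFAULT_FUNCTIONAL_POLICY,
                          mean_structure: bool = False) -> ModelSpec:
    """Hierarchical limbic / associative / sensorimotor model (reference df = 116)."""
    indicators, first_order = _hemispheric_first_order(FUNCTIONAL_REGIONS)
    pairs = tuple(policy.indicator_pairs())
    if len(pairs) != 6:
        warnings.warn(
            f"functional policy has {len(pairs)} residual covariances, not 6; "
            "df will differ from the reference value of 116", stacklevel=2)
    return ModelSpec(
        indicators=indicators,
        first_order=first_order,
        second_order=_second_order(FUNCTIONAL_FACTORS),
        residual_cov_pairs=pairs,
        mean_structure=mean_structure,
        name="functional",
    )


def build_one_factor_spec(base: ModelSpec) -> ModelSpec:
    """One-general-factor alternative with the same indicators and residual
    covariance policy as ``base`` (nested in the hierarchical model)."""
    first_order = {"General": {ind: (1.0 if i == 0 else FREE)
                               for i, ind in enumerate(base.indicators)}}
    return ModelSpec(
        indicators=base.indicators,
        first_order=first_order,
        second_order={},
        residual_cov_pairs=base.residual_cov_pairs,
        mean_structure=base.mean_structure,
        name=f"{base.name}-one-factor" if base.name else "one-factor",
    )


# --------------------------------------------------------------------------
# partial correlations
# --------------------------------------------------------------------------

def partial_correlation(corr: pd.DataFrame | np.ndarray, x, y, given) -> float:
    """Partial correlation of x and y given the variables in ``given``,
    computed by inverting the relevant submatrix of a correlation matrix."""
    if isinstance(corr, pd.DataFrame):
        labels = [x, y] + list(given)
        sub = corr.loc[labels, labels].to_numpy()
    else:
        labels = [x, y] + list(given)
        sub = np.asarray(corr)[np.ix_(labels, labels)]
    prec = np.linalg.inv(sub)
    return float(-prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1]))


# --------------------------------------------------------------------------
# striatal linkage
# --------------------------------------------------------------------------

def _extended_functional_spec(base: ModelSpec) -> ModelSpec:
    """Functional spec in standardized second-order mode, extended with the
    striatal subdivisions as unit-variance observed variables.

    Each striatal variable enters through a single-indicator chain with
    loading 1, zero residual and zero disturbance, so that the variable is
    identical to its pseudo second-order factor and the ``phi`` block is the
    joint correlation matrix of pathway factors and striatal subdivisions.
    The striatal columns must be z-scored (unit sample variance) before
    fitting.
    """
    std = base.standardized_second_order()
    indicators = tuple(std.indicators) + STRIATAL_SUBDIVISIONS
    first_order = {**{f: dict(l) for f, l in std.first_order.items()},
                   **{s: {s: 1.0} for s in STRIATAL_SUBDIVISIONS}}
    second_order = {**{g: dict(l) for g, l in std.second_order.items()},
                    **{s: {s: 1.0} for s in STRIATAL_SUBDIVISIONS}}
    constraints = list(std.constraints)
    for s in STRIATAL_SUBDIVISIONS:
        constraints += [Constraint("fix", (f"theta[{s}]",), 0.0),
                        Constraint("fix", (f"psi[{s}]",), 0.0)]
    return ModelSpec(
        indicators=indicators,
        first_order=first_order,
        second_order=second_order,
        residual_cov_pairs=std.residual_cov_pairs,
        mean_structure=False,
        std_second_order=True,
        constraints=tuple(constraints),
        name=f"{base.name}-striatal" if base.name else "striatal-linkage",
    )


@dataclass
class StriatalLinkageReport:
    """Raw and adjusted correlations between pathway factors and striatal
    subdivisions, with the underlying extended-model fit."""

    fit: FactorModelResults
    joint_correlation: pd.DataFrame      # factors x striatal variables, 6x6
    raw: pd.DataFrame                    # striatal target x pathway factor
    adjusted: pd.DataFrame               # adjusted for the other two targets
    equality_tests: pd.DataFrame | None = None

    def summary(self) -> str:
        lines = ["Striatal linkage (pathway factors vs striatal subdivisions)",
                 "=" * 64,
                 "Raw correlations:", self.raw.round(3).to_string(), "",
                 "Adjusted correlations (partial, given the other two striatal "
                 "subdivisions):", self.adjusted.round(3).to_string()]
        if self.equality_tests is not None and len(self.equality_tests):
            lines += ["", "Pairwise equality tests (delta chi-square):",
                      self.equality_tests.round(4).to_string(index=False)]
        return "\n".join(lines)


class StriatalLinkageAnalysis:
    """Joint model of the functional pathway factors and the observed
    striatal subdivisions, exposing raw/adjusted correlations and pairwise
    equality tests of the factor-striatum links."""

    def __init__(self, data: pd.DataFrame, striatal: pd.DataFrame,
                 base_spec: ModelSpec | None = None):
        base = base_spec if base_spec is not None else build_functional_spec()
        if "bp_nd" in data.columns:
            data = wide_table(data)
        if "bp_nd" in striatal.columns:
            striatal = striatal.pivot_table(index="subject_id", columns="region",
                                            values="bp_nd", aggfunc="first")
        missing = [s for s in STRIATAL_SUBDIVISIONS if s not in striatal.columns]
        if missing:
            raise ValueError(f"striatal table is missing subdivisions: {missing}")
        striatal = striatal[list(STRIATAL_SUBDIVISIONS)]
        if not data.index.equals(striatal.index):
            common = data.index.intersection(striatal.index)
            if len(common) < len(data.index) or len(common) < len(striatal.index):
                raise ValueError(
                    "striatal table and indicator data cover different subjects")
            striatal = striatal.loc[data.index]
        # z-score the striatal columns: their pseudo-factor variances are
        # fixed to 1 in the standardized extended model
        zs = (striatal - striatal.mean()) / striatal.std(ddof=1)
        self.data = pd.concat([data, zs], axis=1)
        self.spec = _extended_functional_spec(base)
        self.factors = base.factors2

    def fit(self, n_restarts: int = 2, rng=None,
            equality_tests: bool = False) -> StriatalLinkageReport:
        model = HierarchicalFactorModel(self.spec, data=self.data)
        res = model.fit(n_restarts=n_restarts, compute_se=False, rng=rng)
        labels = self.factors + list(STRIATAL_SUBDIVISIONS)
        joint = res.factor_correlations(order=2).loc[labels, labels]
        raw = joint.loc[list(STRIATAL_SUBDIVISIONS), self.factors].copy()
        adjusted = raw.copy()
        for s in STRIATAL_SUBDIVISIONS:
            others = [o for o in STRIATAL_SUBDIVISIONS if o != s]
            for f in self.factors:
                adjusted.loc[s, f] = partial_correlation(joint, s, f, others)
        eq = self._equality_tests(res, rng=rng) if equality_tests else None
        self._base_fit = res
        return StriatalLinkageReport(fit=res, joint_correlation=joint,
                                     raw=raw, adjusted=adjusted, equality_tests=eq)

    def equality_test(self, free_fit: FactorModelResults, striatal_target: str,
                      factor_a: str, factor_b: str, rng=None):
        """Delta chi-square test equating two factor-striatum correlations."""
        a = f"phi[{_phi_key(self.spec, striatal_target, factor_a)}]"
        b = f"phi[{_phi_key(self.spec, striatal_target, factor_b)}]"
        cons = self.spec.constrain(Constraint("equal", (a, b)))
        model = HierarchicalFactorModel(cons, data=self.data)
        res = model.fit(n_restarts=1, compute_se=False, rng=rng)
        return chi_square_diff(free_fit, res)

    def _equality_tests(self, free_fit: FactorModelResults, rng=None) -> pd.DataFrame:
        rows = []
        for s in STRIATAL_SUBDIVISIONS:
            for i, fa in enumerate(self.factors):
                for fb in self.factors[i + 1:]:
                    d, ddf, p = self.equality_test(free_fit, s, fa, fb, rng=rng)
                    rows.append((s, fa, fb, d, ddf, p))
        return pd.DataFrame(rows, columns=["striatal_target", "factor_a", "factor_b",
                                           "delta_chi2", "delta_df", "p"])


def _phi_key(spec: ModelSpec, a: str, b: str) -> str:
    """phi parameter names follow the factor order of the spec."""
    order = spec.factors2
    i, j = order.index(a), order.index(b)
    lo, hi = (a, b) if i < j else (b, a)
    return f"{lo},{hi}"


def striatal_linkage(data: pd.DataFrame, striatal: pd.DataFrame,
                     base_spec: ModelSpec | None = None,
                     equality_tests: bool = False,
                     n_restarts: int = 2, rng=None) -> StriatalLinkageReport:
    """Relate the functional pathway factors to striatal-subdivision BP_ND.

    Parameters
    ----------
    data : DataFrame
        Subject x indicator table (or long BP_ND table) for the functional
        model's 18 hemispheric indicators.
    striatal : DataFrame
        Subject x {VST, AST, SMS} bilateral-mean BP_ND (wide or long).
    equality_tests : bool
        Also run the pairwise delta chi-square tests equating each striatal
        target's three factor correlations (9 constrained refits).
    """
    analysis = StriatalLinkageAnalysis(data, striatal, base_spec=base_spec)
    return analysis.fit(n_restarts=n_restarts, rng=rng, equality_tests=equality_tests)
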