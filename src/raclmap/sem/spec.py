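"""Declarative specification of hierarchical confirmatory factor models.

A :class:`ModelSpec` describes a (possibly second-order) CFA with

* indicators loading on first-order factors (one loading per factor fixed
  to 1 for scaling — "marker" scaling),
* first-order factors loading on second-order factors (cross-loadings
  allowed, again marker-scaled),
* freely correlated second-order factors,
* selected pairs of residuals allowed to covary,
* an optional mean structure in which the scaling indicator's intercept is
  fixed to 0 so that the first-order latent mean takes the metric of its
  marker indicator.

Parameters are referred to by name throughout the package:

======================  =============================================
``lam1[Pt_R~Pt]``       first-order loading of indicator on factor
``lam2[Pt~Striatum]``   second-order loading
``phi[A,B]``            second-order factor (co)variance / correlation
``psi[Pt]``             first-order disturbance variance
``theta[Pt_L]``         residual variance
``theta[Pt_L,Cd_L]``    residual covariance
``alpha[Pt]``           first-order latent mean
``tau[Pt_R]``           indicator intercept
======================  =============================================

In *standardized second-order* mode (used for constraint tests on factor
correlations) the second-order factor variances are fixed to 1 and all
second-order loadings are free, so the ``phi`` off-diagonals are
correlations and can be fixed to a value or equated across pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import yaml

FREE = "free"


@dataclass(frozen=True)
class Constraint:
    """Fix a parameter to a value, or equate a set of parameters."""

    kind: str                  # 'fix' | 'equal'
    params: tuple[str, ...]
    value: float | None = None

    def __post_init__(self):
        if self.kind not in ("fix", "equal"):
            raise ValueError(f"unknown constraint kind {self.kind!r}")
        if self.kind == "fix" and (len(self.params) != 1 or self.value is None):
            raise ValueError("'fix' constraint takes one parameter and a value")
        if self.kind == "equal" and len(self.params) < 2:
            raise ValueError("'equal' constraint needs at least two parameters")


@dataclass(frozen=True)
class ModelSpec:
    """Hierarchical CFA structure; see module docstring for conventions.

    ``first_order`` maps factor -> {indicator: loading}, where a loading is
    either a fixed float or the string ``"free"``.  ``second_order`` maps
    second-order factor -> {first-order factor: loading}; an empty dict
    means a single-level model (the first-order factor covariance ``psi``
    then carries the factor variance).
    """

    indicators: tuple[str, ...]
    first_order: dict[str, dict[str, object]]
    second_order: dict[str, dict[str, object]] = field(default_factory=dict)
    residual_cov_pairs: tuple[tuple[str, str], ...] = ()
    mean_structure: bool = False
    std_second_order: bool = False
    constraints: tuple[Constraint, ...] = ()
    name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "indicators", tuple(self.indicators))
        object.__setattr__(self, "residual_cov_pairs",
                           tuple((a, b) for a, b in self.residual_cov_pairs))
        object.__setattr__(self, "constraints", tuple(self.constraints))
        self._validate()

    # -- structure ---------------------------------------------------------

    @property
    def factors1(self) -> list[str]:
        return list(self.first_order)

    @property
    def factors2(self) -> list[str]:
        return list(self.second_order)

    def factor_of(self, ind: str) -> str:
        for f, loadings in self.first_order.items():
            if ind in loadings:
                return f
        raise KeyError(ind)

    def marker_of(self, factor: str) -> str:
        """Scaling indicator (fixed nonzero loading) of a first-order factor."""
        fallback = None
        for ind, lo in self.first_order[factor].items():
            if lo != FREE and float(lo) == 1.0:
                return ind
            if lo != FREE and float(lo) != 0.0 and fallback is None:
                fallback = ind
        if fallback is not None:
            return fallback
        raise ValueError(f"factor {factor!r} has no fixed scaling loading")

    def _validate(self):
        seen: dict[str, str] = {}
        for f, loadings in self.first_order.items():
            if not loadings:
                raise ValueError(f"first-order factor {f!r} has no indicators")
            for ind in loadings:
                if ind not in self.indicators:
                    raise ValueError(f"unknown indicator {ind!r} in factor {f!r}")
                if ind in seen:
                    raise ValueError(
                        f"indicator {ind!r} loads on both {seen[ind]!r} and {f!r}; "
                        "each indicator must load on exactly one first-order factor")
                seen[ind] = f
        for ind in self.indicators:
            if ind not in seen:
                raise ValueError(f"indicator {ind!r} loads on no factor")
        for f, loadings in self.first_order.items():
            fixed = [v for v in loadings.values() if v != FREE]
            if not fixed:
                raise ValueError(f"first-order factor {f!r} needs one fixed scaling loading")
        for f2, loadings in self.second_order.items():
            for f1 in loadings:
                if f1 not in self.first_order:
                    raise ValueError(f"unknown first-order factor {f1!r} under {f2!r}")
            if not self.std_second_order:
                fixed = [v for v in loadings.values() if v != FREE]
                if not fixed:
                    raise ValueError(
                        f"second-order factor {f2!r} needs one fixed scaling loading "
                        "(or standardized mode)")
        for a, b in self.residual_cov_pairs:
            for ind in (a, b):
                if ind not in self.indicators:
                    raise ValueError(f"residual covariance names unknown indicator {ind!r}")
        valid = set(self.parameter_names(ignore_constraints=True))
        for c in self.constraints:
            for pname in c.params:
                if pname not in valid:
                    raise ValueError(f"constraint references unknown parameter {pname!r}")

    # -- parameter enumeration --------------------------------------------

    def parameter_names(self, ignore_constraints: bool = False) -> list[str]:
        """Names of structurally free parameters, before/after constraints."""
        names: list[str] = []
        for f, loadings in self.first_order.items():
            for ind, lo in loadings.items():
                if lo == FREE:
                    names.append(f"lam1[{ind}~{f}]")
        for f2, loadings in self.second_order.items():
            for f1, lo in loadings.items():
                if lo == FREE:
                    names.append(f"lam2[{f1}~{f2}]")
        f2s = self.factors2
        for i, a in enumerate(f2s):
            if not self.std_second_order:
                names.append(f"phi[{a},{a}]")
            for b in f2s[i + 1:]:
                names.append(f"phi[{a},{b}]")
        for f in self.first_order:
            names.append(f"psi[{f}]")
        for ind in self.indicators:
            names.append(f"theta[{ind}]")
        for a, b in self.residual_cov_pairs:
            names.append(f"theta[{a},{b}]")
        if self.mean_structure:
            for f in self.first_order:
                names.append(f"alpha[{f}]")
            markers = {self.marker_of(f) for f in self.first_order}
            for ind in self.indicators:
                if ind not in markers:
                    names.append(f"tau[{ind}]")
        if ignore_constraints:
            return names
        fixed = {c.params[0] for c in self.constraints if c.kind == "fix"}
        dropped = set()
        for c in self.constraints:
            if c.kind == "equal":
                dropped.update(c.params[1:])
        return [nm for nm in names if nm not in fixed and nm not in dropped]

    def n_free_parameters(self) -> int:
        return len(self.parameter_names())

    # -- transformations ---------------------------------------------------

    def standardized_second_order(self) -> "ModelSpec":
        """Equivalent re-parameterization with unit second-order variances.

        All second-order loadings become free and the ``phi`` block becomes a
        correlation matrix, enabling value/equality constraints on factor
        correlations.
        """
        if not self.second_order:
            raise ValueError("model has no second-order factors")
        so = {f2: {f1: FREE for f1 in loadings}
              for f2, loadings in self.second_order.items()}
        return replace(self, second_order=so, std_second_order=True)

    def constrain(self, *constraints: Constraint) -> "ModelSpec":
        return replace(self, constraints=self.constraints + tuple(constraints))

    def with_mean_structure(self, on: bool = True) -> "ModelSpec":
        return replace(self, mean_structure=on)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "indicators": list(self.indicators),
            "first_order": {f: dict(l) for f, l in self.first_order.items()},
            "second_order": {f: dict(l) for f, l in self.second_order.items()},
            "residual_cov_pairs": [list(p) for p in self.residual_cov_pairs],
            "mean_structure": self.mean_structure,
            "std_second_order": self.std_second_order,
            "constraints": [
                {"kind": c.kind, "params": list(c.params), "value": c.value}
                for c in self.constraints
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            indicators=tuple(d["indicators"]),
            first_order={f: dict(l) for f, l in d["first_order"].items()},
            second_order={f: dict(l) for f, l in d.get("second_order", {}).items()},
            residual_cov_pairs=tuple(tuple(p) for p in d.get("residual_cov_pairs", [])),
            mean_structure=d.get("mean_structure", False),
            std_second_order=d.get("std_second_order", False),
            constraints=tuple(
                Constraint(c["kind"], tuple(c["params"]), c.get("value"))
                for c in d.get("constraints", [])
            ),
            name=d.get("name", ""),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelSpec":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        return cls.from_dict(json.loads(text))


def count_df(spec: ModelSpec) -> int:
    """Degrees of freedom by the counting rule.

    Sample moments are p(p+1)/2 covariances (+ p means when the mean
    structure is on); free parameters are counted after constraints.
    """
    p = len(spec.indicators)
    moments = p * (p + 1) // 2
    if spec.mean_structure:
        moments += p
    df = moments - spec.n_free_parameters()
    if df < 0:
        raise ValueError(
            f"model not identified by counting rule: {spec.n_free_parameters()} free "
            f"parameters exceed {moments} sample moments")
    return df
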