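"""Model and Results objects for hierarchical CFA, plus fit indices.

:class:`HierarchicalFactorModel` is constructed from a spec and data
(subject x indicator table, a long BP_ND table, or precomputed moments);
``fit()`` returns a :class:`FactorModelResults` carrying estimates,
standard errors, chi-square, CFI, RMSEA with its 90% CI, the standardized
solution, factor correlations and latent means, and a ``summary()`` table.

Conventions (matching normal-theory ML as implemented in mainstream SEM
software): chi-square = (N - 1) * F_min; the CFI baseline is the
independence model (diagonal Sigma, free variances, free means when the
mean structure is on); RMSEA = sqrt(max(chi2 - df, 0) / (df (N - 1))) with
its CI from inverting the noncentral chi-square CDF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .engine import (ParamTable, fit_ml_raw, fml_discrepancy, implied_moments,
                     observed_information_cov)
from .spec import ModelSpec, count_df

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# fit indices
# --------------------------------------------------------------------------

def fit_indices(chi_square, df, n, chi_square_baseline, df_baseline):
    """(CFI, RMSEA) from model and independence-baseline chi-squares."""
    if df <= 0:
        raise ValueError("fit indices require df > 0")
    if n <= 1:
        raise ValueError("fit indices require n > 1")
    rmsea = float(np.sqrt(max(chi_square - df, 0.0) / (df * (n - 1))))
    num = max(chi_square - df, 0.0)
    den = max(chi_square_baseline - df_baseline, chi_square - df, 0.0)
    cfi = 1.0 if den == 0 else 1.0 - num / den
    return float(np.clip(cfi, 0.0, 1.0)), rmsea


def rmsea_ci(chi_square, df, n, level: float = 0.90):
    """Confidence interval for RMSEA by noncentral chi-square inversion.

    The upper bound solves P(chi2_df(lam) <= chi2_obs) = (1-level)/2 and the
    lower bound P = (1+level)/2; each bound is sqrt(lam / (df (n-1))),
    floored at 0 when the target probability cannot be bracketed.
    """
    if df <= 0:
        raise ValueError("rmsea_ci requires df > 0")
    scale = df * (n - 1)

    def solve(target):
        f = lambda lam: stats.ncx2.cdf(chi_square, df, lam) - target
        if f(1e-10) <= 0:       # even lam ~ 0 puts chi2_obs below the target quantile
            return 0.0
        hi = max(4.0 * chi_square, 10.0)
        while f(hi) > 0:
            hi *= 2
            if hi > 1e8:
                return 0.0
        return optimize.brentq(f, 1e-10, hi, xtol=1e-12)

    lam_lo = solve((1 + level) / 2)
    lam_hi = solve((1 - level) / 2)
    return float(np.sqrt(lam_lo / scale)), float(np.sqrt(lam_hi / scale))


def baseline_chi_square(S, n, mean_structure: bool = False):
    """Chi-square and df of the independence baseline (diagonal Sigma).

    The ML solution for a diagonal target is Sigma = diag(S) (means free and
    exactly fitted when present), so F_B = -ln|R| with R the sample
    correlation matrix; df_B = p(p-1)/2.
    """
    S = np.asarray(S, float)
    p = S.shape[0]
    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)
    sign, logdet_r = np.linalg.slogdet(R)
    if sign <= 0:
        raise np.linalg.LinAlgError("sample correlation matrix is not positive definite")
    return float(-(n - 1) * logdet_r), p * (p - 1) // 2


# --------------------------------------------------------------------------
# results object
# --------------------------------------------------------------------------

@dataclass
class FactorModelResults:
    """ML solution of a hierarchical factor model with fit statistics."""

    spec: ModelSpec
    params: pd.Series
    se: pd.Series | None
    chi_square: float
    df: int
    n: int
    fmin: float
    cfi: float
    rmsea: float
    rmsea_ci90: tuple[float, float]
    S: np.ndarray
    xbar: np.ndarray | None
    info: dict = field(default_factory=dict)
    _table: ParamTable | None = None
    _raw: np.ndarray | None = None

    # -- derived quantities ------------------------------------------------

    @property
    def p_value(self) -> float:
        return float(stats.chi2.sf(self.chi_square, self.df)) if self.df > 0 else 1.0

    def matrices(self) -> dict[str, np.ndarray]:
        return self._table.unpack(self._raw)

    def implied_moments(self):
        return implied_moments(self.matrices(), self.spec.mean_structure)

    def factor_covariance(self, order: int = 1) -> pd.DataFrame:
        """Estimated covariance matrix of first- or second-order factors."""
        m = self.matrices()
        if order == 2:
            if not self.spec.second_order:
                raise ValueError("model has no second-order factors")
            return pd.DataFrame(m["phi"], index=self.spec.factors2,
                                columns=self.spec.factors2)
        B = m["lam2"] @ m["phi"] @ m["lam2"].T + m["psi"] \
            if self.spec.second_order else m["psi"]
        return pd.DataFrame(B, index=self.spec.factors1, columns=self.spec.factors1)

    def factor_correlations(self, order: int = 2) -> pd.DataFrame:
        cov = self.factor_covariance(order).to_numpy()
        d = np.sqrt(np.diag(cov))
        corr = cov / np.outer(d, d)
        labels = self.spec.factors2 if order == 2 else self.spec.factors1
        return pd.DataFrame(corr, index=labels, columns=labels)

    def standardized_loadings(self) -> pd.DataFrame:
        """Completely standardized solution (correlation-metric loadings)."""
        m = self.matrices()
        sigma, _ = self.implied_moments()
        sd_y = np.sqrt(np.diag(sigma))
        B = self.factor_covariance(1).to_numpy()
        sd_f1 = np.sqrt(np.diag(B))
        rows = []
        for f in self.spec.factors1:
            jf = self.spec.factors1.index(f)
            for ind in self.spec.first_order[f]:
                i = list(self.spec.indicators).index(ind)
                lam = m["lam1"][i, jf]
                rows.append(("first", ind, f, lam * sd_f1[jf] / sd_y[i]))
        if self.spec.second_order:
            sd_f2 = np.sqrt(np.diag(m["phi"]))
            for g in self.spec.factors2:
                jg = self.spec.factors2.index(g)
                for f in self.spec.second_order[g]:
                    i = self.spec.factors1.index(f)
                    lam = m["lam2"][i, jg]
                    rows.append(("second", f, g, lam * sd_f2[jg] / sd_f1[i]))
        return pd.DataFrame(rows, columns=["order", "variable", "factor", "loading"])

    def latent_means(self) -> pd.DataFrame:
        """First-order latent means with standard errors."""
        if not self.spec.mean_structure:
            raise ValueError("latent means require the mean structure to be on "
                             "(fit the model with mean_structure=True)")
        rows = []
        for f in self.spec.factors1:
            nm = f"alpha[{f}]"
            se = float(self.se[nm]) if self.se is not None and nm in self.se else np.nan
            rows.append((f, float(self.params[nm]), se))
        return pd.DataFrame(rows, columns=["factor", "mean", "se"]).set_index("factor")

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        lines = [
            f"Hierarchical factor model: {self.spec.name or '(unnamed)'}",
            "=" * 64,
            f"  n = {self.n}, indicators = {len(self.spec.indicators)}, "
            f"free parameters = {self.spec.n_free_parameters()}",
            f"  chi-square({self.df}) = {self.chi_square:.1f}, p = {self.p_value:.4g}",
            f"  CFI = {self.cfi:.3f}   RMSEA = {self.rmsea:.3f} "
            f"(90% CI {self.rmsea_ci90[0]:.3f}, {self.rmsea_ci90[1]:.3f})",
        ]
        if self.spec.second_order:
            lines.append("")
            lines.append("Second-order factor correlations:")
            lines.append(self.factor_correlations(order=2).round(3).to_string())
        if self.spec.mean_structure:
            lines.append("")
            lines.append("Latent means (first-order factors):")
            lines.append(self.latent_means().round(3).to_string())
        if self.info.get("warnings"):
            lines.append("")
            for w in self.info["warnings"]:
                lines.append(f"  warning: {w}")
        return "\n".join(lines)

    def parameter_table(self) -> pd.DataFrame:
        df = pd.DataFrame({"estimate": self.params})
        if self.se is not None:
            df["se"] = self.se
            df["z"] = df["estimate"] / df["se"]
        return df

    def to_json_dict(self) -> dict:
        out = {
            "model": self.spec.name,
            "n": int(self.n),
            "chi_square": round(float(self.chi_square), 6),
            "df": int(self.df),
            "p_value": round(self.p_value, 6),
            "cfi": round(float(self.cfi), 6),
            "rmsea": round(float(self.rmsea), 6),
            "rmsea_ci90": [round(v, 6) for v in self.rmsea_ci90],
            "converged": bool(self.info.get("converged", True)),
            "warnings": list(self.info.get("warnings", [])),
            "parameters": {k: round(float(v), 8) for k, v in self.params.items()},
        }
        if self.se is not None:
            out["standard_errors"] = {k: round(float(v), 8) for k, v in self.se.items()}
        if self.spec.second_order:
            out["factor_correlations"] = {
                f"{a},{b}": round(float(self.factor_correlations(2).loc[a, b]), 6)
                for i, a in enumerate(self.spec.factors2)
                for b in self.spec.factors2[i + 1:]
            }
        if self.spec.mean_structure:
            lm = self.latent_means()
            out["latent_means"] = {
                f: {"mean": round(float(r["mean"]), 6), "se": round(float(r["se"]), 6)}
                for f, r in lm.iterrows()
            }
        return out


# --------------------------------------------------------------------------
# model object
# --------------------------------------------------------------------------

class HierarchicalFactorModel:
    """Second-order CFA fitted by normal-theory maximum likelihood.

    Parameters
    ----------
    spec : ModelSpec
        Model structure (use the builders in :mod:`raclmap.models` for the
        shipped anatomical / functional specifications).
    data : pandas.DataFrame, optional
        Subject x indicator table.  Rows with missing values on the model's
        indicators are removed listwise (count logged).
    cov, mean, nobs :
        Alternatively, precomputed sample moments (unbiased covariance).
    """

    def __init__(self, spec: ModelSpec, data: pd.DataFrame | None = None,
                 cov=None, mean=None, nobs: int | None = None):
        self.spec = spec
        inds = list(spec.indicators)
        if data is not None:
            missing = [c for c in inds if c not in data.columns]
            if missing:
                raise ValueError(f"data is missing indicator columns: {missing}")
            sub = data[inds]
            complete = sub.dropna()
            dropped = len(sub) - len(complete)
            if dropped:
                logger.info("listwise deletion removed %d of %d rows", dropped, len(sub))
            if len(complete) < len(inds) + 1:
                raise ValueError(
                    f"need at least {len(inds) + 1} complete rows, have {len(complete)}")
            self.S = complete.cov().to_numpy()
            self.xbar = complete.mean().to_numpy() if spec.mean_structure else None
            self.nobs = len(complete)
            self.n_dropped = dropped
        else:
            if cov is None or nobs is None:
                raise ValueError("provide either data or (cov, nobs)")
            self.S = np.asarray(cov, float)
            self.xbar = None if mean is None else np.asarray(mean, float)
            if spec.mean_structure and self.xbar is None:
                raise ValueError("mean structure requires a sample mean vector")
            self.nobs = int(nobs)
            self.n_dropped = 0
        sign, _ = np.linalg.slogdet(self.S)
        if sign <= 0:
            raise np.linalg.LinAlgError(
                "sample covariance is not positive definite; screen the data "
                "(collinear or constant indicators) before fitting")

    @classmethod
    def from_long(cls, spec: ModelSpec, long_df: pd.DataFrame) -> "HierarchicalFactorModel":
        """Build from a long BP_ND table (subject_id, region, hemisphere, bp_nd)."""
        from ..regions import wide_table
        return cls(spec, data=wide_table(long_df))

    def fit(self, n_restarts: int = 5, compute_se: bool = True,
            start: dict[str, float] | None = None, rng=None,
            rescale: bool = True) -> FactorModelResults:
        """Fit by ML.  ``rescale`` optimizes on unit-variance indicators for
        conditioning (F is invariant) and maps estimates back; it is turned
        off automatically when a constraint forbids it."""
        from .engine import _Objective, scale_factors

        d = np.sqrt(np.diag(self.S))
        sf = None
        if rescale:
            try:
                sf = scale_factors(self.spec, dict(zip(self.spec.indicators, d)))
            except ValueError as exc:
                logger.info("internal rescaling disabled: %s", exc)
        if sf is not None:
            S_fit = self.S / np.outer(d, d)
            xbar_fit = None if self.xbar is None else self.xbar / d
        else:
            S_fit, xbar_fit = self.S, self.xbar
        table, raw, fmin, info = fit_ml_raw(
            self.spec, S_fit, xbar_fit, self.nobs,
            n_restarts=n_restarts, start=start, rng=rng)
        cov_scale = np.ones(table.n_free)
        if sf is not None:
            natural = table.values(raw)
            cov_scale = np.array([sf[nm] for nm in table.names])
            raw_orig = table.pack({nm: natural[nm] * sf[nm] for nm in table.names})
            f_check, _ = _Objective(table, self.S, self.xbar)(raw_orig)
            if not np.isclose(f_check, fmin, rtol=1e-6, atol=1e-8):
                info["warnings"].append(
                    f"back-scaled solution F ({f_check:.8g}) differs from the "
                    f"rescaled optimum ({fmin:.8g})")
            se_table_args = (table, S_fit, xbar_fit, self.nobs, raw)
            raw = raw_orig
        else:
            se_table_args = (table, self.S, self.xbar, self.nobs, raw)
        chi2 = (self.nobs - 1) * fmin
        df = count_df(self.spec)
        chi2_b, df_b = baseline_chi_square(self.S, self.nobs, self.spec.mean_structure)
        if df > 0:
            cfi, rmsea = fit_indices(chi2, df, self.nobs, chi2_b, df_b)
            ci = rmsea_ci(chi2, df, self.nobs)
        else:
            cfi, rmsea, ci = 1.0, 0.0, (0.0, 0.0)
        params = table.values(raw)
        se = None
        if compute_se and table.n_free:
            cov = observed_information_cov(*se_table_args)
            se = pd.Series(np.sqrt(np.clip(np.diag(cov), 0, None)) * cov_scale,
                           index=table.names, name="se")
        return FactorModelResults(
            spec=self.spec, params=params, se=se, chi_square=float(chi2),
            df=df, n=self.nobs, fmin=fmin, cfi=cfi, rmsea=rmsea,
            rmsea_ci90=ci, S=self.S, xbar=self.xbar, info=info,
            _table=table, _raw=raw)


def fit_ml(spec: ModelSpec, data, n_restarts: int = 5, compute_se: bool = True,
           rng=None) -> FactorModelResults:
    """Convenience wrapper: fit ``spec`` to a wide table, a long BP_ND table,
    or a ``(S, xbar, n)`` moments tuple."""
    if isinstance(data, tuple):
        S, xbar, n = data
        model = HierarchicalFactorModel(spec, cov=S, mean=xbar, nobs=n)
    elif isinstance(data, pd.DataFrame) and "bp_nd" in getattr(data, "columns", []):
        model = HierarchicalFactorModel.from_long(spec, data)
    else:
        model = HierarchicalFactorModel(spec, data=data)
    return model.fit(n_restarts=n_restarts, compute_se=compute_se, rng=rng)


# --------------------------------------------------------------------------
# nested-model comparison
# --------------------------------------------------------------------------

def chi_square_diff(fit_free: FactorModelResults,
                    fit_constrained: FactorModelResults,
                    tol: float = 1e-3):
    """Likelihood-ratio test between nested covariance-structure fits.

    Nesting is checked by parameter-set inclusion: every free parameter of
    the constrained model must be free in the unconstrained model, given the
    same indicators and sample.  Returns (delta_chi2, delta_df, p).
    """
    a, b = fit_free, fit_constrained
    if tuple(a.spec.indicators) != tuple(b.spec.indicators):
        raise ValueError("models are fitted to different indicator sets")
    if a.n != b.n:
        raise ValueError("models are fitted to different samples")
    free_a = set(a.spec.parameter_names())
    free_b = set(b.spec.parameter_names())
    if not free_b <= free_a:
        raise ValueError(
            "constrained model is not nested in the free model "
            f"(extra free parameters: {sorted(free_b - free_a)})")
    delta_df = b.df - a.df
    if delta_df < 0:
        raise ValueError("constrained model has fewer df than the free model")
    delta = b.chi_square - a.chi_square
    if delta < -tol * (1 + abs(a.chi_square)):
        raise RuntimeError(
            f"constrained chi-square ({b.chi_square:.4f}) is below the free model's "
            f"({a.chi_square:.4f}); re-fit with more restarts")
    delta = max(delta, 0.0)
    if delta_df == 0:
        p = 1.0
    else:
        p = float(stats.chi2.sf(delta, delta_df))
    return float(delta), int(delta_df), p


def latent_means(fit: FactorModelResults) -> pd.DataFrame:
    """First-order latent means with SEs (requires mean structure)."""
    return fit.latent_means()
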