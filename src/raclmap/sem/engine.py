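"""Maximum-likelihood estimation of hierarchical factor models.

The implied moment structure of a second-order CFA is

    Sigma(theta) = Lam1 (Lam2 Phi Lam2' + Psi) Lam1' + Theta
    mu(theta)    = tau + Lam1 alpha            (mean structure only)

and the normal-theory ML discrepancy minimized here is

    F(theta) = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p
               + (xbar - mu)' Sigma^-1 (xbar - mu)

with chi-square = (n - 1) * F at the minimum.  Optimization runs on a
transformed parameter vector (log for variances, atanh for correlations
when the second-order block is standardized) with analytic gradients,
quasi-Newton (L-BFGS-B), a moment-based smart start and optional random
restarts.  Standard errors come from the inverse observed information,
cov(theta) = (2 / (n-1)) H^-1 with H the Hessian of F at the solution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .spec import FREE, ModelSpec

logger = logging.getLogger(__name__)

_PENALTY = 1e10
_VAR_FLOOR = 1e-6   # Heywood flag threshold on fitted variances


@dataclass
class _Entry:
    matrix: str          # 'lam1' | 'lam2' | 'phi' | 'psi' | 'theta' | 'alpha' | 'tau'
    i: int
    j: int
    pid: int             # index into the free-parameter vector
    transform: str       # 'id' | 'log' | 'atanh'


class ParamTable:
    """Maps the free-parameter vector onto the model matrices.

    Equality constraints share a parameter id; fixed parameters are folded
    into the matrix templates.  Transforms keep variances positive and
    standardized correlations inside (-1, 1).
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        p = len(spec.indicators)
        f1 = spec.factors1
        f2 = spec.factors2
        self.p, self.m1, self.m2 = p, len(f1), len(f2)
        self.ind_ix = {ind: i for i, ind in enumerate(spec.indicators)}
        self.f1_ix = {f: i for i, f in enumerate(f1)}
        self.f2_ix = {f: i for i, f in enumerate(f2)}

        self.templates = {
            "lam1": np.zeros((p, self.m1)),
            "lam2": np.zeros((self.m1, max(self.m2, 1))),
            "phi": np.zeros((max(self.m2, 1), max(self.m2, 1))),
            "psi": np.zeros((self.m1, self.m1)),
            "theta": np.zeros((p, p)),
            "alpha": np.zeros(self.m1),
            "tau": np.zeros(p),
        }

        fixed_vals = {c.params[0]: float(c.value)
                      for c in spec.constraints if c.kind == "fix"}
        alias: dict[str, str] = {}
        for c in spec.constraints:
            if c.kind == "equal":
                for nm in c.params[1:]:
                    alias[nm] = c.params[0]

        self.names: list[str] = []
        self._pid_of: dict[str, int] = {}
        self.entries: list[_Entry] = []

        def place(name, matrix, i, j, transform):
            if name in fixed_vals:
                self._set_fixed(matrix, i, j, fixed_vals[name], transform)
                return
            root = alias.get(name, name)
            if root in fixed_vals:
                self._set_fixed(matrix, i, j, fixed_vals[root], transform)
                return
            if root not in self._pid_of:
                self._pid_of[root] = len(self.names)
                self.names.append(root)
            self.entries.append(_Entry(matrix, i, j, self._pid_of[root], transform))

        for f, loadings in spec.first_order.items():
            jf = self.f1_ix[f]
            for ind, lo in loadings.items():
                i = self.ind_ix[ind]
                if lo == FREE:
                    place(f"lam1[{ind}~{f}]", "lam1", i, jf, "id")
                else:
                    self.templates["lam1"][i, jf] = float(lo)
        for g, loadings in spec.second_order.items():
            jg = self.f2_ix[g]
            for f, lo in loadings.items():
                i = self.f1_ix[f]
                if lo == FREE:
                    place(f"lam2[{f}~{g}]", "lam2", i, jg, "id")
                else:
                    self.templates["lam2"][i, jg] = float(lo)
        for a in f2:
            ia = self.f2_ix[a]
            if spec.std_second_order:
                self.templates["phi"][ia, ia] = 1.0
            else:
                place(f"phi[{a},{a}]", "phi", ia, ia, "log")
        corr_tf = "atanh" if spec.std_second_order else "id"
        for i, a in enumerate(f2):
            for b in f2[i + 1:]:
                place(f"phi[{a},{b}]", "phi", self.f2_ix[a], self.f2_ix[b], corr_tf)
        for f in f1:
            i = self.f1_ix[f]
            place(f"psi[{f}]", "psi", i, i, "log")
        for ind in spec.indicators:
            i = self.ind_ix[ind]
            place(f"theta[{ind}]", "theta", i, i, "log")
        for a, b in spec.residual_cov_pairs:
            place(f"theta[{a},{b}]", "theta", self.ind_ix[a], self.ind_ix[b], "id")
        if spec.mean_structure:
            markers = {spec.marker_of(f) for f in f1}
            for f in f1:
                place(f"alpha[{f}]", "alpha", self.f1_ix[f], 0, "id")
            for ind in spec.indicators:
                if ind not in markers:
                    place(f"tau[{ind}]", "tau", self.ind_ix[ind], 0, "id")

        self.n_free = len(self.names)

    def _set_fixed(self, matrix, i, j, value, transform):
        t = self.templates[matrix]
        if t.ndim == 1:
            t[i] = value
        else:
            t[i, j] = value
            if matrix in ("phi", "psi", "theta") and i != j:
                t[j, i] = value

    # -- raw <-> natural ---------------------------------------------------

    @staticmethod
    def _fwd(value, transform):
        if transform == "log":
            return np.log(max(value, 1e-12))
        if transform == "atanh":
            return np.arctanh(np.clip(value, -0.999999, 0.999999))
        return value

    @staticmethod
    def _inv(raw, transform):
        if transform == "log":
            return np.exp(raw)
        if transform == "atanh":
            return np.tanh(raw)
        return raw

    @staticmethod
    def _dinv(value, transform):
        """d(natural)/d(raw) expressed through the natural value."""
        if transform == "log":
            return value
        if transform == "atanh":
            return 1.0 - value ** 2
        return 1.0

    def pack(self, natural: dict[str, float]) -> np.ndarray:
        """Raw vector from a {name: natural value} mapping."""
        raw = np.zeros(self.n_free)
        tf = self._transform_of()
        for nm, v in natural.items():
            if nm in self._pid_of:
                raw[self._pid_of[nm]] = self._fwd(v, tf[nm])
        return raw

    def _transform_of(self) -> dict[str, str]:
        out = {}
        for e in self.entries:
            out[self.names[e.pid]] = e.transform
        return out

    def raw_bounds(self) -> list[tuple]:
        """Box bounds on the raw vector: log-variances are floored at the
        Heywood threshold (an exact-zero variance lies at -inf in log space
        and creates an unbounded flat valley); atanh-correlations are kept
        off +/-1.  Identity-transformed parameters are unbounded."""
        tf = self._transform_of()
        bounds = [(None, None)] * self.n_free
        for nm, pid in self._pid_of.items():
            if tf[nm] == "log":
                bounds[pid] = (math.log(_VAR_FLOOR), None)
            elif tf[nm] == "atanh":
                bounds[pid] = (-6.0, 6.0)
        return bounds

    def unpack(self, raw: np.ndarray) -> dict[str, np.ndarray]:
        """Model matrices from the raw parameter vector."""
        mats = {k: v.copy() for k, v in self.templates.items()}
        for e in self.entries:
            v = self._inv(raw[e.pid], e.transform)
            t = mats[e.matrix]
            if t.ndim == 1:
                t[e.i] = v
            else:
                t[e.i, e.j] = v
                if e.matrix in ("phi", "psi", "theta") and e.i != e.j:
                    t[e.j, e.i] = v
        return mats

    def values(self, raw: np.ndarray) -> pd.Series:
        tf = self._transform_of()
        return pd.Series({nm: self._inv(raw[self._pid_of[nm]], tf[nm])
                          for nm in self.names}, name="estimate")


def implied_moments(spec_or_table, theta=None):
    """Model-implied covariance matrix (and mean vector, if applicable).

    Accepts either ``(ModelSpec, {name: value} or raw vector)`` or a dict of
    assembled matrices.  Returns ``(Sigma, mu)`` with ``mu=None`` when the
    mean structure is off.
    """
    if isinstance(spec_or_table, ModelSpec):
        table = ParamTable(spec_or_table)
        if isinstance(theta, dict):
            raw = table.pack(theta)
        else:
            raw = np.asarray(theta, float)
            if raw.shape != (table.n_free,):
                raise ValueError(
                    f"theta has {raw.shape} entries, expected {table.n_free}")
        mats = table.unpack(raw)
        mean_on = spec_or_table.mean_structure
        has_so = bool(spec_or_table.second_order)
    else:
        mats = spec_or_table
        mean_on = theta if theta is not None else False
        has_so = mats["lam2"].any() or mats["phi"].any()
    lam1, lam2, phi, psi, theta_m = (mats["lam1"], mats["lam2"], mats["phi"],
                                     mats["psi"], mats["theta"])
    B = lam2 @ phi @ lam2.T + psi if has_so else psi
    sigma = lam1 @ B @ lam1.T + theta_m
    sigma = (sigma + sigma.T) / 2
    mu = mats["tau"] + lam1 @ mats["alpha"] if mean_on else None
    return sigma, mu


def fml_discrepancy(S, xbar, sigma, mu, p=None):
    """Normal-theory ML discrepancy between sample and implied moments.

    ``xbar`` and ``mu`` may both be None for covariance-only models.
    F >= 0, with equality iff Sigma = S (and mu = xbar).
    """
    S = np.asarray(S, float)
    sigma = np.asarray(sigma, float)
    p = p if p is not None else S.shape[0]
    sign_s, logdet_s = np.linalg.slogdet(S)
    if sign_s <= 0:
        raise np.linalg.LinAlgError("sample covariance matrix is not positive definite")
    c, low = linalg.cho_factor(sigma, lower=True)  # raises if Sigma not PD
    logdet_sig = 2 * np.sum(np.log(np.diag(c)))
    sig_inv = linalg.cho_solve((c, low), np.eye(p))
    F = logdet_sig + np.sum(S * sig_inv) - logdet_s - p
    if xbar is not None and mu is not None:
        d = np.asarray(xbar, float) - np.asarray(mu, float)
        F += d @ sig_inv @ d
    return float(F)


class _Objective:
    """F(theta) and its analytic gradient for a given (S, xbar)."""

    def __init__(self, table: ParamTable, S, xbar):
        self.table = table
        self.S = np.asarray(S, float)
        self.xbar = None if xbar is None else np.asarray(xbar, float)
        self.p = table.p
        sign, self.logdet_s = np.linalg.slogdet(self.S)
        if sign <= 0:
            raise np.linalg.LinAlgError("sample covariance matrix is not positive definite")
        self.mean_on = table.spec.mean_structure
        self.has_so = bool(table.spec.second_order)
        self.eye = np.eye(self.p)

    def __call__(self, raw):
        t = self.table
        mats = t.unpack(raw)
        lam1, lam2, phi, psi, theta = (mats["lam1"], mats["lam2"], mats["phi"],
                                       mats["psi"], mats["theta"])
        B = lam2 @ phi @ lam2.T + psi if self.has_so else psi
        sigma = lam1 @ B @ lam1.T + theta
        sigma = (sigma + sigma.T) / 2
        try:
            c, low = linalg.cho_factor(sigma, lower=True)
        except np.linalg.LinAlgError:
            return _PENALTY * (1.0 + float(np.sum(raw ** 2))), np.zeros(t.n_free)
        logdet_sig = 2 * np.sum(np.log(np.diag(c)))
        sig_inv = linalg.cho_solve((c, low), self.eye)
        if self.mean_on:
            mu = mats["tau"] + lam1 @ mats["alpha"]
            d = self.xbar - mu
            M = self.S + np.outer(d, d)
        else:
            d = None
            M = self.S
        F = logdet_sig + np.sum(self.S * sig_inv) - self.logdet_s - self.p
        if d is not None:
            F += d @ sig_inv @ d

        # gradient: dF/dSigma = Sinv - Sinv M Sinv
        G = sig_inv - sig_inv @ M @ sig_inv
        dlam1 = 2 * G @ lam1 @ B
        A1 = lam1.T @ G @ lam1
        grads = {"theta": G, "psi": A1}
        if self.has_so:
            grads["lam2"] = 2 * A1 @ lam2 @ phi
            grads["phi"] = lam2.T @ A1 @ lam2
        else:
            grads["lam2"] = np.zeros_like(lam2)
            grads["phi"] = np.zeros_like(phi)
        if d is not None:
            dmu = -2 * sig_inv @ d
            dlam1 = dlam1 + np.outer(dmu, mats["alpha"])
            grads["tau"] = dmu
            grads["alpha"] = lam1.T @ dmu
        grads["lam1"] = dlam1

        g = np.zeros(t.n_free)
        for e in t.entries:
            gm = grads.get(e.matrix)
            if gm is None:
                continue
            if gm.ndim == 1:
                val = gm[e.i]
            elif e.matrix in ("phi", "psi", "theta") and e.i != e.j:
                val = gm[e.i, e.j] + gm[e.j, e.i]
            else:
                val = gm[e.i, e.j]
            nat = t._inv(raw[e.pid], e.transform)
            g[e.pid] += val * t._dinv(nat, e.transform)
        return float(F), g


def smart_start(table: ParamTable, S, xbar) -> dict[str, float]:
    """Moment-based starting values on the natural scale."""
    spec = table.spec
    s_diag = np.diag(S)
    start: dict[str, float] = {}
    fvar = {}
    for f in spec.factors1:
        m = table.ind_ix[spec.marker_of(f)]
        fvar[f] = 0.7 * s_diag[m]
    for f, loadings in spec.first_order.items():
        m = table.ind_ix[spec.marker_of(f)]
        for ind, lo in loadings.items():
            if lo == FREE:
                i = table.ind_ix[ind]
                start[f"lam1[{ind}~{f}]"] = np.sqrt(max(s_diag[i] / s_diag[m], 1e-4))
    for g, loadings in spec.second_order.items():
        if spec.std_second_order:
            for f in loadings:
                start[f"lam2[{f}~{g}]"] = 0.7 * np.sqrt(fvar[f])
        else:
            marker_f = None
            for f, lo in loadings.items():
                if lo != FREE:
                    marker_f = f
            for f, lo in loadings.items():
                if lo == FREE:
                    start[f"lam2[{f}~{g}]"] = np.sqrt(max(fvar[f] / fvar[marker_f], 1e-4))
            start[f"phi[{g},{g}]"] = 0.5 * fvar[marker_f]
    f2 = spec.factors2
    for i, a in enumerate(f2):
        for b in f2[i + 1:]:
            if spec.std_second_order:
                start[f"phi[{a},{b}]"] = 0.3
            else:
                va = start.get(f"phi[{a},{a}]", 1.0)
                vb = start.get(f"phi[{b},{b}]", 1.0)
                start[f"phi[{a},{b}]"] = 0.3 * np.sqrt(va * vb)
    for f in spec.factors1:
        start[f"psi[{f}]"] = (0.5 if spec.second_order else 1.0) * fvar[f]
    for ind in spec.indicators:
        start[f"theta[{ind}]"] = 0.3 * s_diag[table.ind_ix[ind]]
    for a, b in spec.residual_cov_pairs:
        start[f"theta[{a},{b}]"] = 0.0
    if spec.mean_structure and xbar is not None:
        markers = {f: spec.marker_of(f) for f in spec.factors1}
        for f, m in markers.items():
            start[f"alpha[{f}]"] = xbar[table.ind_ix[m]]
        for ind in spec.indicators:
            if ind not in markers.values():
                f = spec.factor_of(ind)
                lam = start.get(f"lam1[{ind}~{f}]",
                                float(spec.first_order[f][ind])
                                if spec.first_order[f][ind] != FREE else 1.0)
                start[f"tau[{ind}]"] = (xbar[table.ind_ix[ind]]
                                        - lam * start[f"alpha[{f}]"])
    return start


def _minimize(obj: _Objective, raw0: np.ndarray, bounds=None):
    if bounds is not None:
        lo = np.array([-np.inf if b[0] is None else b[0] for b in bounds])
        hi = np.array([np.inf if b[1] is None else b[1] for b in bounds])
        raw0 = np.clip(raw0, lo, hi)
    res = optimize.minimize(
        obj, raw0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 20000, "maxfun": 60000, "ftol": 1e-13, "gtol": 1e-7},
    )
    return res


def fit_ml_raw(spec: ModelSpec, S, xbar, n, n_restarts: int = 5,
               start: dict[str, float] | None = None,
               restart_scale: float = 0.3,
               rng=None, agree_tol: float = 1e-4):
    """Minimize the ML discrepancy; returns (table, raw_hat, fmin, info).

    One moment-based start plus ``n_restarts`` randomly perturbed starts;
    the best solution is kept and disagreement beyond ``agree_tol`` in F
    across converged runs is logged in ``info['warnings']``.
    """
    table = ParamTable(spec)
    obj = _Objective(table, S, xbar)
    s0 = smart_start(table, S, xbar)
    if start:
        s0.update(start)
    raw0 = table.pack(s0)
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    bounds = table.raw_bounds()
    best = None
    fvals = []
    starts = [raw0] + [raw0 + restart_scale * rng.standard_normal(raw0.size)
                       for _ in range(n_restarts)]
    for k, r0 in enumerate(starts):
        res = _minimize(obj, r0, bounds)
        if res.fun >= _PENALTY:
            continue
        fvals.append(res.fun)
        if best is None or res.fun < best.fun:
            best = res
    info = {"warnings": [], "n_starts": len(starts), "n_converged": len(fvals)}
    if best is None:
        raise RuntimeError(
            "optimization failed to reach a positive-definite solution from "
            f"{len(starts)} starts; check data screening and model identification")
    if len(fvals) > 1 and (max(fvals) - min(fvals)) > agree_tol * (1 + abs(best.fun)):
        msg = (f"restarts disagree: F range [{min(fvals):.6g}, {max(fvals):.6g}]; "
               "possible local minima")
        logger.warning(msg)
        info["warnings"].append(msg)
    # polish: warm-restart from the incumbent when the line search or
    # iteration budget stopped L-BFGS-B short of its gradient tolerance
    for _ in range(2):
        if best.success or float(np.max(np.abs(best.jac))) < 1e-4:
            break
        res = _minimize(obj, best.x, bounds)
        if res.fun <= best.fun:
            best = res
    g = np.asarray(best.jac, float).copy()
    lo = np.array([-np.inf if b[0] is None else b[0] for b in bounds])
    hi = np.array([np.inf if b[1] is None else b[1] for b in bounds])
    g[(best.x <= lo + 1e-10) & (g > 0)] = 0.0
    g[(best.x >= hi - 1e-10) & (g < 0)] = 0.0
    gnorm = float(np.max(np.abs(g)))
    info["grad_max"] = gnorm
    info["converged"] = bool(best.success or gnorm < 5e-4)
    if not info["converged"]:
        info["warnings"].append(f"optimizer did not report convergence: {best.message}")
    # Heywood screening
    mats = table.unpack(best.x)
    for label, m in (("psi", mats["psi"]), ("theta", mats["theta"]), ("phi", mats["phi"])):
        dg = np.diag(m) if m.ndim == 2 else m
        for v, nm in zip(dg, _diag_names(table, label)):
            if nm is not None and v <= _VAR_FLOOR * 10:
                info["warnings"].append(f"Heywood case: variance {nm} at boundary ({v:.3g})")
    return table, best.x, float(best.fun), info


def _diag_names(table: ParamTable, label: str):
    spec = table.spec
    if label == "psi":
        return [f"psi[{f}]" for f in spec.factors1]
    if label == "theta":
        return [f"theta[{ind}]" for ind in spec.indicators]
    if label == "phi":
        return [f"phi[{g},{g}]" for g in spec.factors2] or [None]
    return []


def scale_factors(spec: ModelSpec, d: dict[str, float]) -> dict[str, float]:
    """Per-parameter back-transform factors after fitting on rescaled data.

    If each indicator i is divided by d_i before fitting, the natural
    estimate of every parameter in the original metric is the rescaled-fit
    estimate times the factor returned here (marker scaling propagates the
    marker indicator's d to its factor, and the marker first-order factor's
    d to its second-order factor; standardized second-order factors have
    unit scale).  The ML discrepancy itself is invariant.
    """
    m1_marker = {f: spec.marker_of(f) for f in spec.factors1}

    def e_of(g: str) -> float:
        if spec.std_second_order:
            return 1.0
        for f, lo in spec.second_order[g].items():
            if lo != FREE and float(lo) != 0.0:
                return d[m1_marker[f]]
        raise ValueError(f"second-order factor {g!r} has no fixed scaling loading")

    out: dict[str, float] = {}
    for name in spec.parameter_names(ignore_constraints=True):
        kind, _, body = name.partition("[")
        body = body[:-1]
        if kind == "lam1":
            ind, f = body.split("~")
            out[name] = d[ind] / d[m1_marker[f]]
        elif kind == "lam2":
            f, g = body.split("~")
            out[name] = d[m1_marker[f]] / e_of(g)
        elif kind == "phi":
            a, b = body.split(",")
            out[name] = e_of(a) * e_of(b)
        elif kind == "psi":
            out[name] = d[m1_marker[body]] ** 2
        elif kind == "theta":
            if "," in body:
                a, b = body.split(",")
                out[name] = d[a] * d[b]
            else:
                out[name] = d[body] ** 2
        elif kind == "alpha":
            out[name] = d[m1_marker[body]]
        elif kind == "tau":
            out[name] = d[body]
        else:  # pragma: no cover
            raise ValueError(f"unrecognized parameter name {name!r}")
    # equality constraints must bind parameters of identical scale for the
    # back-transform to be exact
    for c in spec.constraints:
        if c.kind == "equal":
            scales = {round(out.get(p, 1.0), 12) for p in c.params}
            if len(scales) > 1:
                raise ValueError(
                    f"equality constraint {c.params} mixes parameters of "
                    "different scale; fit without internal rescaling")
    return out


def observed_information_cov(table: ParamTable, S, xbar, n, raw_hat,
                             step: float = 1e-5) -> np.ndarray:
    """Covariance of the estimates from the observed information.

    H is the Hessian of F at the solution (central differences of the
    analytic gradient); cov = (2 / (n-1)) H^+.
    """
    obj = _Objective(table, S, xbar)
    k = raw_hat.size
    H = np.zeros((k, k))
    for i in range(k):
        e = np.zeros(k)
        e[i] = step
        _, gp = obj(raw_hat + e)
        _, gm = obj(raw_hat - e)
        H[i] = (gp - gm) / (2 * step)
    H = (H + H.T) / 2
    cov_raw = (2.0 / (n - 1)) * np.linalg.pinv(H)
    # delta method back to the natural scale
    tf = table._transform_of()
    vals = table.values(raw_hat)
    J = np.array([table._dinv(vals[nm], tf[nm]) for nm in table.names])
    return cov_raw * np.outer(J, J)
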