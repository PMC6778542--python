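"""Synthetic cohorts of regional BP_ND with known latent structure.

The generator draws subject-level data from the hierarchical factor model
that the analysis assumes: correlated second-order pathway factors drive
standardized first-order region factors, which drive the left/right
hemispheric indicators plus residual noise,

    z2 ~ N(0, Phi)                       (second-order, standardized)
    z1_f = l2_f' z2 + zeta_f             (first-order, standardized)
    y_ind = alpha_f + sd_f * lam_ind * z1_f + eps_ind   (BP_ND units)

so every indicator of region f has mean ``alpha_f`` (the latent mean), the
standardized first-order loading is ``lam_ind`` (around 0.9), and the
between-person scale is set per region by ``latent_sd``.  Defaults follow
the reported latent means, their standard-error scale (SD = SE * sqrt(176))
and the reported second-order factor correlations.

All randomness flows from one integer seed, expanded into per-subject
substreams with a fixed splitting rule so that any subject subset is
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .regions import (ANATOMICAL_FACTORS, ANATOMICAL_REGIONS,
                      DEFAULT_ANATOMICAL_POLICY, DEFAULT_FUNCTIONAL_POLICY,
                      FUNCTIONAL_FACTORS, FUNCTIONAL_REGIONS, HEMISPHERES,
                      STRIATAL_SUBDIVISIONS, NeighborPolicy, indicator,
                      long_table)

__all__ = ["PopulationParams", "StriatalPopulation", "CohortDataset",
           "default_population", "simulate_bp_table", "attach_tacs",
           "KineticConfig"]

_SQRT_N_REF = math.sqrt(176.0)   # reference cohort size behind the SE -> SD scale

#: Latent means and their reported SEs (anatomical model).
_ANATOMICAL_MEANS = {"Pt": 3.06, "Cd": 2.21, "Hc": 0.27, "Amy": 0.41,
                     "FC": 0.19, "OC": 0.24, "TC": 0.25, "PC": 0.20}
_ANATOMICAL_SES = {"Pt": 0.020, "Cd": 0.020, "Hc": 0.004, "Amy": 0.005,
                   "FC": 0.003, "OC": 0.003, "TC": 0.003, "PC": 0.003}
#: Second-order factor correlations (anatomical): Striatum-Limbic 0.53,
#: Striatum-Neocortex 0.30, Limbic-Neocortex 0.83.
_ANATOMICAL_CORR = pd.DataFrame(
    [[1.00, 0.53, 0.30],
     [0.53, 1.00, 0.83],
     [0.30, 0.83, 1.00]],
    index=["Striatum", "Limbic", "Neocortex"],
    columns=["Striatum", "Limbic", "Neocortex"])

#: Latent means and SEs (functional model).
_FUNCTIONAL_MEANS = {"Hc": 0.27, "Amy": 0.41, "OFC": 0.24, "ACC": 0.24,
                     "BA9": 0.09, "BA46": 0.17, "Precentral": 0.15,
                     "Postcentral": 0.11, "SuperiorParietal": 0.16}
_FUNCTIONAL_SES = {"Hc": 0.004, "Amy": 0.005, "OFC": 0.003, "ACC": 0.004,
                   "BA9": 0.003, "BA46": 0.003, "Precentral": 0.003,
                   "Postcentral": 0.003, "SuperiorParietal": 0.004}
#: Limbic-Associative 0.19, Limbic-Sensorimotor 0.62, Associative-Sensorimotor 0.66.
_FUNCTIONAL_CORR = pd.DataFrame(
    [[1.00, 0.19, 0.62],
     [0.19, 1.00, 0.66],
     [0.62, 0.66, 1.00]],
    index=["Limbic", "Associative", "Sensorimotor"],
    columns=["Limbic", "Associative", "Sensorimotor"])

#: Reported factor-striatum correlations (rows: VST, AST, SMS).
_STRIATAL_FACTOR_CORR = pd.DataFrame(
    [[0.27, -0.02, -0.05],
     [-0.14, 0.30, 0.01],
     [0.21, 0.10, 0.28]],
    index=["VST", "AST", "SMS"],
    columns=["Limbic", "Associative", "Sensorimotor"])


@dataclass(frozen=True)
class StriatalPopulation:
    """Generating parameters for the observed striatal subdivisions."""

    means: dict = field(default_factory=lambda: {"VST": 2.4, "AST": 2.8, "SMS": 2.6})
    sds: dict = field(default_factory=lambda: {"VST": 0.30, "AST": 0.30, "SMS": 0.30})
    factor_corr: pd.DataFrame = field(
        default_factory=lambda: _STRIATAL_FACTOR_CORR.copy())
    inter_corr: float = 0.40


@dataclass(frozen=True)
class PopulationParams:
    """Generating parameters for a synthetic BP_ND cohort.

    ``first_order_loadings`` and ``second_order_loadings`` are standardized;
    ``latent_sd`` carries the BP_ND-unit scale of each region factor, and
    ``residual_sd`` the indicator residual scale (defaults to
    ``latent_sd * sqrt(1 - loading^2)`` so indicators have unit standardized
    variance before residual covariances).
    """

    model_id: str
    latent_means: dict
    latent_sd: dict
    first_order_loadings: dict                 # indicator -> standardized loading
    second_order_loadings: dict                # first-order factor -> {factor2: loading}
    factor_corr: pd.DataFrame                  # second-order correlations
    residual_sd: dict                          # indicator -> SD (BP_ND units)
    residual_cov_pairs: tuple = ()             # (indicator, indicator, covariance)
    striatal: StriatalPopulation | None = None
    n_subjects: int = 176
    seed: int = 0

    def __post_init__(self):
        self.validate()

    # -- structure helpers -------------------------------------------------

    @property
    def regions(self) -> list[str]:
        return list(self.latent_means)

    @property
    def factors2(self) -> list[str]:
        return list(self.factor_corr.index)

    @property
    def indicators(self) -> list[str]:
        return list(self.first_order_loadings)

    def validate(self):
        phi = self.factor_corr.to_numpy()
        if not np.allclose(phi, phi.T):
            raise ValueError("factor_corr must be symmetric")
        if not np.allclose(np.diag(phi), 1.0):
            raise ValueError("factor_corr must have a unit diagonal")
        eig = np.linalg.eigvalsh(phi)
        if eig.min() < -1e-10:
            raise ValueError("factor_corr is not positive semi-definite "
                             f"(min eigenvalue {eig.min():.3g})")
        for ind, sd in self.residual_sd.items():
            if sd < 0:
                raise ValueError(f"residual_sd[{ind!r}] must be >= 0")
        for f, loads in self.second_order_loadings.items():
            l = np.array([loads.get(g, 0.0) for g in self.factors2])
            v = 1.0 - l @ phi @ l
            if v < -1e-10:
                raise ValueError(
                    f"second-order loadings of factor {f!r} imply negative "
                    f"disturbance variance ({v:.3g})")
        sigma = self.implied_cov().to_numpy()
        eig = np.linalg.eigvalsh(sigma)
        if eig.min() <= 0:
            raise ValueError(
                "implied indicator covariance matrix is not positive definite "
                f"(min eigenvalue {eig.min():.3g}); check the residual covariance "
                "pairs and loading pattern")

    # -- implied moments ---------------------------------------------------

    def _lambda2(self) -> np.ndarray:
        """Standardized second-order loading matrix (regions x factors)."""
        return np.array([[self.second_order_loadings[f].get(g, 0.0)
                          for g in self.factors2] for f in self.regions])

    def first_order_corr(self) -> pd.DataFrame:
        """Correlation matrix of the standardized first-order factors."""
        lam2 = self._lambda2()
        phi = self.factor_corr.to_numpy()
        C = lam2 @ phi @ lam2.T
        np.fill_diagonal(C, 1.0)
        return pd.DataFrame(C, index=self.regions, columns=self.regions)

    def implied_cov(self) -> pd.DataFrame:
        """Model-implied indicator covariance (BP_ND units)."""
        inds = self.indicators
        C1 = self.first_order_corr().to_numpy()
        fac_ix = {f: i for i, f in enumerate(self.regions)}
        lam = np.zeros((len(inds), len(self.regions)))
        for i, ind in enumerate(inds):
            f = _region_of(ind)
            lam[i, fac_ix[f]] = self.first_order_loadings[ind] * self.latent_sd[f]
        theta = np.diag([self.residual_sd[i] ** 2 for i in inds])
        ind_ix = {ind: i for i, ind in enumerate(inds)}
        for a, b, c in self.residual_cov_pairs:
            theta[ind_ix[a], ind_ix[b]] = c
            theta[ind_ix[b], ind_ix[a]] = c
        sigma = lam @ C1 @ lam.T + theta
        return pd.DataFrame(sigma, index=inds, columns=inds)

    def implied_mean(self) -> pd.Series:
        return pd.Series({ind: self.latent_means[_region_of(ind)]
                          for ind in self.indicators})


def _region_of(ind: str) -> str:
    region, _, hemi = ind.rpartition("_")
    return region if region else ind


def default_population(model_id: str, n_subjects: int = 176, seed: int = 0,
                       loading: float = 0.9,
                       residual_cov_scale: float = 0.1) -> PopulationParams:
    """Default generating parameters for the anatomical or functional cohort.

    Latent means follow the reported per-region values; between-person
    scale follows the reported SE of each latent mean (SD = SE * sqrt(176));
    standardized loadings default to 0.9 (the ACC cross-loads 0.5 on both
    the limbic and associative pathway factors); second-order factor
    correlations are 0.53 / 0.30 / 0.83 (anatomical) or 0.19 / 0.62 / 0.66
    (functional).  Residual covariances for the neighboring-region pairs
    default to ``residual_cov_scale`` times the product of the pair's
    residual SDs.
    """
    if model_id == "anatomical":
        means, ses, corr = _ANATOMICAL_MEANS, _ANATOMICAL_SES, _ANATOMICAL_CORR
        groups, policy = ANATOMICAL_FACTORS, DEFAULT_ANATOMICAL_POLICY
        striatal = None
    elif model_id == "functional":
        means, ses, corr = _FUNCTIONAL_MEANS, _FUNCTIONAL_SES, _FUNCTIONAL_CORR
        groups, policy = FUNCTIONAL_FACTORS, DEFAULT_FUNCTIONAL_POLICY
        striatal = StriatalPopulation()
    else:
        raise ValueError(f"unknown model_id {model_id!r}: "
                         "expected 'anatomical' or 'functional'")

    latent_sd = {r: ses[r] * _SQRT_N_REF for r in means}
    inds = [indicator(r, h) for r in means for h in HEMISPHERES]
    fo_loadings = {ind: loading for ind in inds}

    membership: dict[str, list[str]] = {}
    for g, members in groups.items():
        for m in members:
            membership.setdefault(m, []).append(g)
    so_loadings = {}
    for r in means:
        gs = membership[r]
        if len(gs) == 1:
            so_loadings[r] = {gs[0]: loading}
        else:
            # cross-loading region: split the variance between its pathways
            so_loadings[r] = {g: 0.5 for g in gs}

    residual_sd = {ind: latent_sd[_region_of(ind)] * math.sqrt(1 - loading ** 2)
                   for ind in inds}
    pairs = tuple(
        (a, b, residual_cov_scale * residual_sd[a] * residual_sd[b])
        for a, b in policy.indicator_pairs())

    return PopulationParams(
        model_id=model_id,
        latent_means=dict(means),
        latent_sd=latent_sd,
        first_order_loadings=fo_loadings,
        second_order_loadings=so_loadings,
        factor_corr=corr.copy(),
        residual_sd=residual_sd,
        residual_cov_pairs=pairs,
        striatal=striatal,
        n_subjects=n_subjects,
        seed=seed,
    )


# --------------------------------------------------------------------------
# simulation
# --------------------------------------------------------------------------

@dataclass
class CohortDataset:
    """Simulated cohort: long BP_ND table, latent true scores, parameters."""

    bp_table: pd.DataFrame         # subject_id, region, hemisphere, bp_nd
    true_scores: pd.DataFrame      # subject x (second-order + first-order factors)
    params: PopulationParams

    def wide(self) -> pd.DataFrame:
        from .regions import wide_table
        return wide_table(self.bp_table)

    def striatal_wide(self) -> pd.DataFrame:
        sub = self.bp_table[self.bp_table["hemisphere"] == "bilateral-mean"]
        return sub.pivot_table(index="subject_id", columns="region",
                               values="bp_nd", aggfunc="first")


def _subject_streams(seed: int, n: int):
    """Fixed splitting rule: per-subject child streams of one root seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_bp_table(params: PopulationParams) -> CohortDataset:
    """Draw a cohort from the hierarchical model implied by ``params``.

    Subjects are drawn independently from per-subject substreams of the
    root seed; second-order factors first, then first-order disturbances,
    then indicator residuals (with the configured neighbor covariances),
    then — for functional cohorts — the striatal subdivisions jointly with
    the second-order factors.
    """
    params.validate()
    regions = params.regions
    factors2 = params.factors2
    inds = params.indicators
    m2, m1, p = len(factors2), len(regions), len(inds)

    phi = params.factor_corr.to_numpy()
    lam2 = params._lambda2()
    psi_std = 1.0 - np.einsum("ij,jk,ik->i", lam2, phi, lam2)
    psi_std = np.clip(psi_std, 0.0, None)

    has_striatal = params.striatal is not None
    if has_striatal:
        ns = len(STRIATAL_SUBDIVISIONS)
        gamma = params.striatal.factor_corr.loc[
            list(STRIATAL_SUBDIVISIONS), factors2].to_numpy()
        s_corr = np.full((ns, ns), params.striatal.inter_corr)
        np.fill_diagonal(s_corr, 1.0)
        joint = np.block([[phi, gamma.T], [gamma, s_corr]])
        eig = np.linalg.eigvalsh(joint)
        if eig.min() <= 0:
            raise ValueError(
                "joint factor/striatal correlation matrix is not positive "
                f"definite (min eigenvalue {eig.min():.3g}); offending block: "
                "striatal factor_corr / inter_corr")
        chol_top = np.linalg.cholesky(joint)
        k_top = m2 + ns
    else:
        chol_top = np.linalg.cholesky(phi + 1e-12 * np.eye(m2))
        k_top = m2

    # residual covariance structure (joint normal residual draw)
    theta = np.diag([params.residual_sd[i] ** 2 for i in inds])
    ind_ix = {ind: i for i, ind in enumerate(inds)}
    for a, b, c in params.residual_cov_pairs:
        theta[ind_ix[a], ind_ix[b]] = c
        theta[ind_ix[b], ind_ix[a]] = c
    eigv = np.linalg.eigvalsh(theta)
    if eigv.min() < -1e-12:
        raise ValueError("residual covariance block is not positive semi-definite")
    chol_theta = np.linalg.cholesky(theta + 1e-12 * np.eye(p))

    lam_ind = np.array([params.first_order_loadings[i] for i in inds])
    fac_of = np.array([regions.index(_region_of(i)) for i in inds])
    sd_f = np.array([params.latent_sd[f] for f in regions])
    alpha = np.array([params.latent_means[f] for f in regions])

    rows = np.empty((params.n_subjects, p))
    striatal_rows = np.empty((params.n_subjects, 3)) if has_striatal else None
    scores = np.empty((params.n_subjects, m2 + m1))
    for s_ix, rng in enumerate(_subject_streams(params.seed, params.n_subjects)):
        top = chol_top @ rng.standard_normal(k_top)
        z2 = top[:m2]
        z1 = lam2 @ z2 + np.sqrt(psi_std) * rng.standard_normal(m1)
        eta = alpha + sd_f * z1
        eps = chol_theta @ rng.standard_normal(p)
        rows[s_ix] = alpha[fac_of] + sd_f[fac_of] * lam_ind * z1[fac_of] + eps
        scores[s_ix, :m2] = z2
        scores[s_ix, m2:] = eta
        if has_striatal:
            zs = top[m2:]
            mu_s = np.array([params.striatal.means[s] for s in STRIATAL_SUBDIVISIONS])
            sd_s = np.array([params.striatal.sds[s] for s in STRIATAL_SUBDIVISIONS])
            striatal_rows[s_ix] = mu_s + sd_s * zs

    subject_ids = [f"s{i:05d}" for i in range(params.n_subjects)]
    wide = pd.DataFrame(rows, index=pd.Index(subject_ids, name="subject_id"),
                        columns=inds)
    bp = long_table(wide)
    if has_striatal:
        srows = []
        for i, sid in enumerate(subject_ids):
            for j, s in enumerate(STRIATAL_SUBDIVISIONS):
                srows.append((sid, s, "bilateral-mean", striatal_rows[i, j]))
        bp = pd.concat([bp, pd.DataFrame(
            srows, columns=["subject_id", "region", "hemisphere", "bp_nd"])],
            ignore_index=True)
    true_scores = pd.DataFrame(
        scores, index=pd.Index(subject_ids, name="subject_id"),
        columns=factors2 + regions)
    return CohortDataset(bp_table=bp, true_scores=true_scores, params=params)


# --------------------------------------------------------------------------
# TAC attachment
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticConfig:
    """Reference-curve and noise settings for attaching TACs to a cohort."""

    r1: float = 1.0
    k2: float = 0.4
    ref_amplitude: float = 30.0
    ref_lam1: float = 0.03
    ref_lam2: float = 0.6
    noise_sigma: float = 0.0
    negative_bp: str = "reject"     # 'reject' | 'truncate'
    schedule_durations: tuple | None = None


def attach_tacs(dataset: CohortDataset, cfg: KineticConfig = KineticConfig()):
    """Generate SRTM TACs for every subject x hemispheric indicator.

    Returns ``(tac_set, references)`` in the shape expected by
    :func:`raclmap.kinetics.batch_bpnd`: nested dict subject -> indicator ->
    TAC, plus one shared (per-subject) cerebellar reference TAC.  Negative
    true BP_ND values are rejected or truncated to 0 per the config.
    """
    from .kinetics import (BiexpReference, FrameSchedule, KineticParams,
                           NoiseConfig, default_schedule, simulate_reference_tac,
                           simulate_srtm_tac)

    schedule = (FrameSchedule.from_durations(cfg.schedule_durations)
                if cfg.schedule_durations else default_schedule())
    curve = BiexpReference(cfg.ref_amplitude, cfg.ref_lam1, cfg.ref_lam2)
    noise = NoiseConfig(sigma=cfg.noise_sigma)

    hemispheric = dataset.bp_table[dataset.bp_table["hemisphere"].isin(HEMISPHERES)]
    subjects = list(dict.fromkeys(hemispheric["subject_id"]))
    streams = _subject_streams(int(dataset.params.seed) + 2 ** 20, len(subjects))

    tac_set: dict[str, dict] = {}
    references: dict[str, object] = {}
    for sid, rng in zip(subjects, streams):
        references[sid] = simulate_reference_tac(schedule, curve, noise, rng=rng)
        tac_set[sid] = {}
        sub = hemispheric[hemispheric["subject_id"] == sid]
        for _, row in sub.iterrows():
            bp = float(row["bp_nd"])
            if bp < 0:
                if cfg.negative_bp == "reject":
                    raise ValueError(
                        f"negative true BP_ND ({bp:.4f}) for subject {sid} region "
                        f"{row['region']}_{row['hemisphere']}; set "
                        "negative_bp='truncate' to clip at 0")
                bp = 0.0
            label = f"{row['region']}_{row['hemisphere']}"
            params = KineticParams(r1=cfg.r1, k2=cfg.k2, bp_nd=bp)
            tac_set[sid][label] = simulate_srtm_tac(
                curve, params, schedule, noise, rng=rng, region=label)
    return tac_set, references
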