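# Methods

Statistical conventions, parameter defaults and numerical design choices.
This documents *what the package computes* and *why each default is what
it is*, so results can be interpreted and reproduced without reading the
source.

## 1. Kinetic simulation and Logan quantification

### Reference curve

The cerebellar (reference-region) time–activity curve is a bi-exponential
input shape A·(e^(−λ₁t) − e^(−λ₂t)) with defaults A = 30 kBq/mL,
λ₁ = 0.03 /min, λ₂ = 0.6 /min — a bolus-like curve peaking at
ln(λ₂/λ₁)/(λ₂−λ₁) ≈ 5.3 min with slow washout, qualitatively matching
reported cerebellar [¹¹C]raclopride kinetics. Target curves follow the
simplified reference tissue model (SRTM):

    C_T(t) = R₁ C_R(t) + (k₂ − R₁ k₂a) · (C_R ⊛ e^(−k₂a t)),   k₂a = k₂/(1+BP_ND)

Because C_R is a sum of exponentials, the convolution is evaluated in
closed form, and *frame values are exact analytic frame averages*, not
midpoint samples (verified against numerical convolution to ≲1e−6).

### Frame schedule

The published acquisition is described only as "55-min, 18-frame". The
default schedule is 6×1, 4×2, 4×4, 4×6.25 min (fine early sampling,
coarser late frames — the standard pattern); it is configurable
everywhere a schedule is accepted.

### Logan analysis

Logan coordinates are built at frame midpoints with running trapezoid
integrals (plus the initial triangle from t = 0):
Y(T) = ∫₀ᵀC_T/C_T(T), X(T) = ∫₀ᵀC_R/C_T(T). Frames with midpoint
≥ t* enter the regression; slope = DVR, BP_ND = DVR − 1.

- **t\* = 18 min** (configurable): the paper does not state t*; 18 min
  leaves 7 late frames while staying past the quasi-equilibrium knee for
  BP_ND up to ~3.
- **Perpendicular regression** (default) is total least squares on the
  raw coordinates, via the closed-form dominant eigenvector of the 2×2
  centered scatter matrix: slope = (S_yy − S_xx + √((S_yy−S_xx)² +
  4S_xy²)) / (2S_xy). Both plot coordinates carry noise (both are
  divided by C_T(T)), which biases ordinary least squares downward;
  orthogonal regression reduces that attenuation. Under calibrated noise
  (σ = 1.6, ~10% CV in single-fit BP_ND) the perpendicular estimator's
  |median bias| is not larger than OLS's over 500 replicates.
- **Noise model**: zero-mean Gaussian per frame with standard deviation
  σ·√(C̄/Δt)-type scaling implemented as σ scaled by frame duration and
  activity floor ε; σ = 0 (noiseless) by default.
- **Simulation default k₂ = 0.4 /min**: the source publication does not
  report kinetic constants. At k₂ = 0.4 the noiseless round trip
  recovers BP_ND within ≤1.1% across the whole simulated range
  (0.05–3.06) at t* = 18. At slower efflux (k₂ = 0.3) the *asymptotic*
  Logan bias at BP_ND = 3 is ~2% even for near-continuous sampling —
  i.e., it is a property of the linear-phase approximation, not of the
  frame schedule (the 18-frame schedule agrees with a 1-second-frame
  oracle to <0.5%). Both values are inside the literature range for
  cerebellar raclopride efflux; the default favors the regime where the
  estimator is accurate.

Failures in batch quantification (non-positive activity, too few late
frames) are logged and recorded as missing, never silently dropped.

## 2. Synthetic population

`default_population(model_id)` returns the generating parameters for the
anatomical (8 regions × 2 hemispheres) or functional (9 × 2) cohort:

- **Latent region means**: the published latent mean estimates
  (anatomical: Pt 3.06, Cd 2.21, Amy 0.41, Hc 0.27, FC 0.19, TC 0.25,
  PC 0.20, OC 0.24; functional: Hc 0.27, Amy 0.41, OFC 0.24, ACC 0.24,
  BA9 0.09, BA46 0.17, Precentral 0.15, Postcentral 0.11, SupParietal
  0.16).
- **Latent SDs** (`latent_sd`): standardized loadings alone do not set a
  BP_ND-unit scale, so between-person SDs are derived from the published
  standard errors of the latent means: SD = SE·√176 (e.g. Pt:
  0.020·√176 ≈ 0.27).
- **Standardized loadings 0.9** for all indicators and single-membership
  second-order loadings (the paper reports loadings "around .90"); the
  ACC cross-loads 0.5 / 0.5 on the limbic and associative pathways.
- **Second-order factor correlations**: 0.53 / 0.30 / 0.83 (anatomical:
  striatum–limbic / striatum–neocortex / limbic–neocortex) and 0.19 /
  0.62 / 0.66 (functional), as published.
- **Residual covariances**: 0.1 × (product of the pair's residual SDs)
  for each configured neighboring pair — small positive local dependence;
  the magnitude is unspecified in the source and is configurable.
- **Neighbor policy** (anatomical default, 9 region pairs expanded
  per-hemisphere to 18 indicator pairs): Pt–Cd, Hc–Amy, Hc–TC, Amy–TC,
  FC–TC, FC–PC, TC–PC, TC–OC, PC–OC. Chosen for anatomical adjacency and
  because exactly 18 residual covariances give the reference df = 75.
  Functional default: Hc–Amy, BA9–BA46, Precentral–Postcentral (6 pairs,
  df = 116). Both configurable.
- **Striatal subdivisions** (functional cohorts only): VST/AST/SMS are
  drawn jointly with the second-order factors from the 6×6 correlation
  matrix whose factor–striatum block matches the published raw
  correlations (VST–limbic .27, AST–associative .30, SMS–sensorimotor
  .28, etc.).

Sampling is hierarchical per subject: second-order factors → first-order
disturbances → indicator residuals (with neighbor covariances via a
Cholesky factor). Each subject uses an independent child stream of the
root seed (`numpy.random.SeedSequence.spawn`), so cohorts are
reproducible and the first k subjects are invariant to cohort size.
Negative true BP_ND draws are rejected (error) or truncated to 0 per
configuration before TAC generation.

**Realism limits**: the generator is multivariate normal (no floor
effects, no partial-volume bias), TAC noise is Gaussian per frame, and
the reference curve is shared across subjects up to noise. These match
the modelling assumptions rather than raw PET physics, by design: the
package's purpose is evaluating the statistical chain under known truth.

## 3. Hierarchical factor models

Implied moments: Σ = Λ₁(Λ₂ΦΛ₂ᵀ + Ψ)Λ₁ᵀ + Θ; μ = τ + Λ₁α.

- **Scaling**: marker scaling by default — one loading per factor fixed
  to 1 (left-hemisphere indicator; first single-membership region for
  second-order factors), marker intercepts fixed to 0 so latent means
  are identified. `standardized_second_order()` re-parameterizes the
  second-order block with unit factor variances and free loadings (Φ
  becomes a correlation matrix) — an equivalent model (same χ²) used for
  correlation equality / fix-to-value constraint tests.
- **Estimation**: normal-theory ML, F = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p +
  dᵀΣ⁻¹d (d = x̄ − μ), minimized by L-BFGS-B with the *analytic*
  gradient (verified against finite differences). χ² = (N−1)·F — the
  convention that reproduces all four published RMSEA values from their
  printed (χ², df) pairs.
- **Parameterization**: variances are optimized on the log scale and
  bounded below at the Heywood floor (1e−6); correlations in
  standardized mode on the atanh scale (bounded ±6). The bounds remove
  the unbounded flat valley that a boundary (zero-variance) solution
  otherwise creates in log space.
- **Conditioning**: indicator variances span two orders of magnitude
  (putamen vs cortex), which stalls quasi-Newton optimization. Fits are
  performed on unit-variance-rescaled moments (F is scale-invariant for
  these models) and mapped back through exact per-parameter scale
  factors; standard errors are mapped with the same factors. Rescaling
  is disabled automatically when a constraint ties parameters whose
  scale factors differ.
- **Starts and restarts**: a moment-based smart start plus `n_restarts`
  random perturbations; disagreement across converged runs beyond 1e−4
  in F is reported. Non-converged best solutions are polished by warm
  restart; results carry a `converged` flag and Heywood warnings.
- **Fit indices**: CFI against the independence baseline (diagonal Σ,
  free variances and means), whose χ² has the closed form −(N−1)ln|R|;
  RMSEA = √(max(χ²−df,0)/(df(N−1))) with the 90% CI by inverting the
  noncentral χ² CDF (bisection on the noncentrality parameter).
  Good-fit bounds used for flagging: CFI ≥ 0.90, RMSEA ≤ 0.08.
- **Standard errors**: inverse observed information, cov(θ) =
  (2/(N−1))·H⁻¹ with H the central-difference Hessian of F built from
  the analytic gradient.
- **Missing data**: listwise deletion (matching the screening
  convention of treating excluded values as missing).
- **Δχ² tests**: `chi_square_diff` verifies nesting by parameter-set
  inclusion and returns (Δχ², Δdf, p). Calibration: for a generator with
  two second-order correlations exactly equal, the equality test rejects
  at 0.05 in ~7% of 500 replicates (n = 176).

## 4. Striatal linkage

The functional model is extended with the three observed striatal
subdivisions as single-indicator pseudo-factors (loading 1, zero residual
and disturbance variance, z-scored data) inside the standardized
second-order block, giving the joint 6×6 factor/striatum correlation
matrix in one ML fit. Reported per striatal target: raw correlations with
the three pathway factors, and *adjusted* correlations — partial
correlations given the other two striatal subdivisions, computed from the
joint estimated correlation matrix by precision-matrix inversion.
Pairwise equality of a target's factor correlations is tested by Δχ²
refits.

## 5. Screening and external comparison

- Univariate outliers: |z| > 3.29 set missing (single pass, statistics
  include candidate outliers). Multivariate: Mahalanobis D² above the
  χ²(p) 1−0.001 quantile flags the whole row. Screening warns—never
  silently proceeds—when more than the configured fraction (default 1%)
  of values is removed.
- Distribution checks: skewness and excess kurtosis flagged beyond ±1.5.
- External density comparison: Spearman correlation of group-mean BP_ND
  against a `(region, value)` table over preset subsets (`all`,
  `extrastriatal`, `extrastriatal_no_sfc`), with an explicit
  label-mapping step that errors on unmatched regions. The packaged
  `synthetic_postmortem_bmax.csv` is a *synthetic, clearly labelled
  stand-in* (the published post-mortem table is not redistributable);
  it exercises the machinery, not the published comparison.

## 6. Pipeline reproducibility

- One root seed drives everything (cohort, TAC noise via an offset
  stream, optimizer restarts); valid seeds are < 2³¹.
- Configs are YAML, validated by pydantic (strict: unknown keys are
  errors). Artifacts are stamped with the root seed and a SHA-256 hash
  of the canonical config (excluding the output directory); no artifact
  embeds a timestamp, so a rerun with the same config is byte-identical.
- Stage failures abort with the stage named; artifacts already produced
  are kept. Numerical failures (non-PD moments, non-convergence) are
  distinguished from configuration errors (CLI exit codes 2 vs 1).
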