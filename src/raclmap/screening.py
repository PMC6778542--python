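"""Data screening and cross-modality validation statistics.

Screening mirrors standard practice before normal-theory ML covariance
modelling: univariate outliers beyond +/- 3.29 SD are set missing per
variable, multivariate outliers are flagged by Mahalanobis distance
against the chi-square distribution at p < 0.001 over the indicator set of
the model about to be fitted, and skewness/kurtosis are checked against a
+/- 1.5 acceptability bound.

Cross-modality validation compares group-mean regional BP_ND against
external receptor-density tables (post-mortem autoradiography Bmax, or
BP_ND from a high-affinity ligand) by Spearman rank correlation over
explicit region mappings, with presets for including or excluding the
high-density striatal regions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["one_sample_t", "spearman", "screen_outliers", "skew_kurtosis",
           "compare_external_density", "load_external_table", "ScreeningReport"]


def one_sample_t(values, mu0: float = 0.0):
    """One-sample two-sided t test; returns (t, p, df)."""
    x = np.asarray(values, float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        raise ValueError("one_sample_t requires at least 2 values")
    if np.std(x, ddof=1) == 0:
        raise ValueError("one_sample_t requires nonzero variance")
    res = stats.ttest_1samp(x, mu0)
    return float(res.statistic), float(res.pvalue), int(x.size - 1)


def spearman(x, y):
    """Spearman rank correlation with average ranks for ties; p-value by the
    t approximation.  Returns (rho, p)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise ValueError("spearman requires at least 4 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("spearman is undefined for a constant vector")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def skew_kurtosis(values, bound: float = 1.5):
    """Sample skewness and excess kurtosis with an acceptability flag."""
    x = np.asarray(values, float)
    x = x[~np.isnan(x)]
    if x.size < 4:
        raise ValueError("skew_kurtosis requires at least 4 values")
    if np.std(x, ddof=1) == 0:
        raise ValueError("skew_kurtosis requires nonzero variance")
    skew = float(stats.skew(x))
    kurt = float(stats.kurtosis(x))      # excess (Fisher) kurtosis
    ok = abs(skew) <= bound and abs(kurt) <= bound
    return skew, kurt, ok


@dataclass
class ScreeningReport:
    """Outcome of outlier and distribution screening."""

    univariate_excluded: dict = field(default_factory=dict)   # variable -> count
    multivariate_excluded: int = 0
    skewness: dict = field(default_factory=dict)
    kurtosis: dict = field(default_factory=dict)
    distribution_flags: dict = field(default_factory=dict)    # variable -> ok?
    fraction_missing: float = 0.0
    warnings: list = field(default_factory=list)

    def to_json(self, **kw) -> str:
        return json.dumps({
            "univariate_excluded": self.univariate_excluded,
            "multivariate_excluded": self.multivariate_excluded,
            "skewness": {k: round(v, 6) for k, v in self.skewness.items()},
            "kurtosis": {k: round(v, 6) for k, v in self.kurtosis.items()},
            "distribution_flags": self.distribution_flags,
            "fraction_missing": round(self.fraction_missing, 6),
            "warnings": self.warnings,
        }, sort_keys=True, **kw)


def screen_outliers(data: pd.DataFrame, z_cut: float = 3.29,
                    maha_p: float = 0.001, columns=None,
                    max_missing_fraction: float = 0.01):
    """Univariate and multivariate outlier screening.

    Parameters
    ----------
    data : DataFrame
        Wide subject x variable table (use ``raclmap.regions.wide_table`` for
        long BP_ND tables).
    z_cut : float
        Per-variable z-score bound; values beyond it are set missing.
        Z-scores use each variable's own mean/SD including candidate
        outliers (single pass).
    maha_p : float
        Mahalanobis flagging threshold: subjects with D^2 above the
        chi-square(1 - maha_p) quantile over ``columns`` have their whole
        row set missing.
    columns :
        Indicator subset of the model about to be fitted (default: all).

    Returns
    -------
    (screened DataFrame, ScreeningReport)
    """
    cols = list(columns) if columns is not None else list(data.columns)
    if len(data) < 2:
        raise ValueError("screening requires at least 2 subjects")
    out = data.copy()
    report = ScreeningReport()

    for c in cols:
        x = out[c].astype(float)
        sd = x.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            report.warnings.append(f"variable {c} has zero variance; skipped")
            continue
        z = (x - x.mean()) / sd
        mask = z.abs() > z_cut
        report.univariate_excluded[c] = int(mask.sum())
        out.loc[mask, c] = np.nan
        sk, ku, ok = skew_kurtosis(x.dropna())
        report.skewness[c] = sk
        report.kurtosis[c] = ku
        report.distribution_flags[c] = bool(ok)

    complete = out[cols].dropna()
    if len(complete) > len(cols) + 1:
        S = complete.cov().to_numpy()
        try:
            S_inv = np.linalg.inv(S)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "covariance matrix over the screening columns is singular; "
                "screen a smaller variable subset") from exc
        centered = complete.to_numpy() - complete.mean().to_numpy()
        d2 = np.einsum("ij,jk,ik->i", centered, S_inv, centered)
        cut = stats.chi2.ppf(1 - maha_p, df=len(cols))
        flagged = complete.index[d2 > cut]
        report.multivariate_excluded = int(len(flagged))
        out.loc[flagged, cols] = np.nan

    n_cells = len(out) * len(cols)
    report.fraction_missing = float(out[cols].isna().sum().sum() / n_cells)
    if report.fraction_missing > max_missing_fraction:
        report.warnings.append(
            f"screening removed {report.fraction_missing:.2%} of values, above "
            f"the configured {max_missing_fraction:.2%} bound")
    return out, report


def mahalanobis_d2(data: pd.DataFrame) -> pd.Series:
    """Squared Mahalanobis distances of rows from the column means, using
    the sample covariance of the same data."""
    complete = data.dropna()
    S_inv = np.linalg.inv(complete.cov().to_numpy())
    centered = complete.to_numpy() - complete.mean().to_numpy()
    return pd.Series(np.einsum("ij,jk,ik->i", centered, S_inv, centered),
                     index=complete.index)


# --------------------------------------------------------------------------
# cross-modality comparison
# --------------------------------------------------------------------------

#: Region subsets for external-density comparisons.  The striatal/pallidal
#: regions dominate the dynamic range; the presets mirror correlations with
#: and without them, and without the superior frontal cortex (whose
#: autoradiographic value is a suspected overestimate).
SUBSET_PRESETS = {
    "all": None,
    "extrastriatal": {"exclude": ("Pt", "Cd", "NAc", "GP")},
    "extrastriatal_no_sfc": {"exclude": ("Pt", "Cd", "NAc", "GP", "SFC")},
}


def load_external_table(name: str = "synthetic_postmortem_bmax") -> pd.DataFrame:
    """Load a packaged external density table (columns region, value, source)."""
    with resources.files("raclmap.data").joinpath(f"{name}.csv").open() as fh:
        return pd.read_csv(fh)


def compare_external_density(bp_means: pd.DataFrame, external: pd.DataFrame,
                             region_subset="all",
                             mapping: dict[str, str] | None = None):
    """Spearman correlation of group-mean BP_ND against an external density
    table over a mapped region subset.

    Parameters
    ----------
    bp_means : DataFrame
        Columns ``region`` and ``bp_nd`` (group-level means).
    external : DataFrame
        Columns ``region`` and ``value`` (Bmax or external BP_ND).
    region_subset :
        A preset name from :data:`SUBSET_PRESETS`, or an explicit list of
        region labels.
    mapping : dict
        Optional external-label -> vocabulary-label mapping applied before
        matching.

    Returns
    -------
    (rho, p, n_regions)
    """
    ext = external.copy()
    if mapping:
        ext["region"] = ext["region"].map(lambda r: mapping.get(r, r))
    merged = bp_means.merge(ext, on="region", how="inner", suffixes=("", "_ext"))
    unmatched = sorted(set(ext["region"]) - set(bp_means["region"]))
    if unmatched:
        raise ValueError(
            f"external regions not found in the BP_ND table: {unmatched}; "
            "provide a mapping")
    if isinstance(region_subset, str):
        preset = SUBSET_PRESETS.get(region_subset)
        if region_subset not in SUBSET_PRESETS:
            raise ValueError(f"unknown subset preset {region_subset!r}; "
                             f"choose from {sorted(SUBSET_PRESETS)}")
        if preset is not None:
            merged = merged[~merged["region"].isin(preset["exclude"])]
    else:
        merged = merged[merged["region"].isin(list(region_subset))]
    if len(merged) < 4:
        raise ValueError(f"only {len(merged)} matched regions after mapping; "
                         "need at least 4")
    rho, p = spearman(merged["bp_nd"].to_numpy(), merged["value"].to_numpy())
    return rho, p, int(len(merged))
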