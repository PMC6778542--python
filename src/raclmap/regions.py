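"""Region vocabulary, pathway groupings, and residual-covariance policies.

The controlled vocabulary covers the regions entering the two hierarchical
factor models of regional [11C]raclopride BP_ND:

* the *anatomical* model — striatum (putamen, caudate), limbic system
  (hippocampus, amygdala) and neocortex (frontal, occipital, temporal,
  parietal composites), measured separately per hemisphere;
* the *functional* model — extrastriatal regions grouped by the
  dopaminergic corticostriatal loop they belong to (limbic, associative,
  sensorimotor), again per hemisphere.

Functional striatal subdivisions (ventral, associative, sensorimotor
striatum) are consumed as given labels; their delineation is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

HEMISPHERES = ("L", "R")

#: Controlled region vocabulary (bilateral unless noted).
REGIONS = (
    "Pt", "Cd",                    # striatum: putamen, caudate
    "Hc", "Amy",                   # limbic: hippocampus, amygdala
    "FC", "OC", "TC", "PC",        # neocortical lobar composites
    "OFC", "ACC", "BA9", "BA46",   # prefrontal / cingulate
    "Precentral", "Postcentral", "SuperiorParietal",
    "VST", "AST", "SMS",           # functional striatal subdivisions (bilateral mean)
)

ANATOMICAL_REGIONS = ("Pt", "Cd", "Hc", "Amy", "FC", "OC", "TC", "PC")
ANATOMICAL_FACTORS = {
    "Striatum": ("Pt", "Cd"),
    "Limbic": ("Hc", "Amy"),
    "Neocortex": ("FC", "OC", "TC", "PC"),
}

FUNCTIONAL_REGIONS = (
    "Hc", "Amy", "OFC", "ACC",
    "BA9", "BA46",
    "Precentral", "Postcentral", "SuperiorParietal",
)
#: Second-order pathway factors; ACC belongs to both the limbic and the
#: associative loop and therefore appears in both groups (cross-loading).
FUNCTIONAL_FACTORS = {
    "Limbic": ("Hc", "Amy", "OFC", "ACC"),
    "Associative": ("ACC", "BA9", "BA46"),
    "Sensorimotor": ("Precentral", "Postcentral", "SuperiorParietal"),
}

STRIATAL_SUBDIVISIONS = ("VST", "AST", "SMS")


def indicator(region: str, hemisphere: str) -> str:
    """Column label of one hemispheric indicator, e.g. ``Pt_L``."""
    if hemisphere not in HEMISPHERES:
        raise ValueError(f"hemisphere must be one of {HEMISPHERES}, got {hemisphere!r}")
    return f"{region}_{hemisphere}"


@dataclass(frozen=True)
class NeighborPolicy:
    """Pairs of regions whose hemispheric indicators may have correlated residuals.

    Pairs are given at the region level; they expand to one indicator pair
    per hemisphere (residual covariances are within-hemisphere, between
    neighboring areas).
    """

    region_pairs: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def indicator_pairs(self) -> list[tuple[str, str]]:
        out = []
        for a, b in self.region_pairs:
            for h in HEMISPHERES:
                out.append((indicator(a, h), indicator(b, h)))
        return out

    def __len__(self) -> int:
        return 2 * len(self.region_pairs)


#: Default anatomical policy: 9 anatomically adjacent pairs per hemisphere
#: (18 indicator pairs), yielding the reference model df of 75.
DEFAULT_ANATOMICAL_POLICY = NeighborPolicy((
    ("Pt", "Cd"),
    ("Hc", "Amy"), ("Hc", "TC"), ("Amy", "TC"),
    ("FC", "TC"), ("FC", "PC"), ("TC", "PC"), ("TC", "OC"), ("PC", "OC"),
))

#: Default functional policy: 3 adjacent pairs per hemisphere (6 indicator
#: pairs), yielding the reference model df of 116.
DEFAULT_FUNCTIONAL_POLICY = NeighborPolicy((
    ("Hc", "Amy"), ("BA9", "BA46"), ("Precentral", "Postcentral"),
))


def composite_scores(table, grouping: dict[str, list[str]]):
    """Unit-weighted composites of member regions, per subject and hemisphere.

    Parameters
    ----------
    table : pandas.DataFrame
        Long BP_ND table with columns subject_id, region, hemisphere, bp_nd.
    grouping : dict
        Maps composite label -> list of member region labels.

    Returns
    -------
    pandas.DataFrame
        Long table holding one row per subject x composite x hemisphere with
        the unweighted mean of the member values.
    """
    import pandas as pd

    frames = []
    for label, members in grouping.items():
        if not members:
            raise ValueError(f"composite group {label!r} has no member regions")
        sub = table[table["region"].isin(members)]
        missing = set(members) - set(sub["region"].unique())
        if missing:
            raise ValueError(f"composite group {label!r} missing regions: {sorted(missing)}")
        agg = (
            sub.groupby(["subject_id", "hemisphere"], sort=False)["bp_nd"]
            .mean()
            .reset_index()
        )
        agg["region"] = label
        frames.append(agg[["subject_id", "region", "hemisphere", "bp_nd"]])
    return pd.concat(frames, ignore_index=True)


def wide_table(table, regions=None, hemispheres=HEMISPHERES):
    """Pivot a long BP_ND table to subjects x indicators (``<region>_<hemi>``)."""
    import pandas as pd

    t = table
    if regions is not None:
        t = t[t["region"].isin(regions)]
    t = t[t["hemisphere"].isin(hemispheres)]
    wide = t.pivot_table(
        index="subject_id",
        columns=["region", "hemisphere"],
        values="bp_nd",
        aggfunc="first",
    )
    wide.columns = [f"{r}_{h}" for r, h in wide.columns]
    if regions is not None:
        order = [f"{r}_{h}" for r in regions for h in hemispheres]
        wide = wide[[c for c in order if c in wide.columns]]
    return wide


def long_table(wide) -> "pandas.DataFrame":
    """Inverse of :func:`wide_table`: indicators back to long format."""
    import pandas as pd

    rows = []
    for col in wide.columns:
        region, _, hemi = col.rpartition("_")
        for sid, val in wide[col].items():
            rows.append((sid, region, hemi, val))
    return pd.DataFrame(rows, columns=["subject_id", "region", "hemisphere", "bp_nd"])
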