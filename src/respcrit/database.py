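"""Loading, harmonising, filtering and analysing a Pcrit trait database.

The database is a delimited-text table with one row per Pcrit
determination (species, origin, acclimation, animal characteristics,
method, results, bibliography).  The pipeline:

1. load and validate rows (``load_database``);
2. convert every Pcrit to kPa and, where temperature and salinity permit,
   to mg/L (``harmonize_units``);
3. extract the unbiased 'control' subset: unfed/post-absorptive fish, no
   additional abiotic stressor, temperature acclimation longer than two
   days (``control_subset``);
4. analyses: climate-zone ANOVA with Sidak-adjusted pairwise comparisons,
   within-species respirometry-method t-tests, freshwater/seawater
   Mann-Whitney comparisons in both kPa and mg/L, and (stepwise) multiple
   linear regression of Pcrit on salinity, temperature, body mass and RMR.

Tables are pandas DataFrames throughout; every filter reports its
exclusions rather than dropping rows silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .units import OxygenQuantity, WaterConditions, convert_o2

__all__ = [
    "MANDATORY_FIELDS",
    "RESPIROMETRY_TYPES",
    "O2_DEPLETION_METHODS",
    "ControlSubset",
    "load_database",
    "harmonize_units",
    "control_subset",
    "assign_climate_zone",
    "zone_anova",
    "method_comparisons",
    "salinity_comparison",
    "pcrit_regression",
]

MANDATORY_FIELDS = ("species", "pcrit_value", "pcrit_unit", "trial_temperature")

RESPIROMETRY_TYPES = frozenset(
    {
        "closed_static_individual",
        "closed_static_grouped",
        "closed_flow_through",
        "intermittent_flow",
        "open_flow_through",
        "mesocosm",
        "opercular_mask",
    }
)
O2_DEPLETION_METHODS = frozenset({"fish_respiration", "n2_equilibration", "gas_mix"})

#: |latitude| cutoffs for tropical / subtropical / temperate; beyond is polar.
DEFAULT_ZONE_CUTOFFS = (23.44, 35.0, 66.56)


@dataclass
class ControlSubset:
    """The records passing the control-inclusion rules, plus the audit log."""

    records: pd.DataFrame
    exclusion_log: pd.DataFrame

    def __post_init__(self) -> None:
        assert len(self.records) + len(self.exclusion_log) >= len(self.records)


def load_database(
    path_or_buffer,
    column_map: dict | str | None = None,
    delimiter: str = ",",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a Pcrit database from delimited text.

    column_map maps file headers to schema names (dict, or path to a YAML
    file with one mapping).  Unknown columns are preserved as passthrough.
    Rows missing any mandatory field (species, pcrit_value, pcrit_unit,
    trial_temperature) or failing basic validation are rejected, each with
    a logged reason.

    Returns (records, report); the report has one row per rejected input
    row with its index and reason.
    """
    if isinstance(column_map, str):
        import yaml

        with open(column_map) as fh:
            column_map = yaml.safe_load(fh)
    df = pd.read_csv(path_or_buffer, delimiter=delimiter)
    if column_map:
        df = df.rename(columns=column_map)

    reasons = []
    keep = np.ones(len(df), dtype=bool)
    for i, row in df.iterrows():
        reason = None
        for f in MANDATORY_FIELDS:
            if f not in df.columns or pd.isna(row.get(f)):
                reason = f"missing_{f}"
                break
        if reason is None:
            try:
                v = float(row["pcrit_value"])
                if not v > 0:
                    reason = "nonpositive_pcrit"
            except (TypeError, ValueError):
                reason = "unparseable_pcrit"
        if reason is None and "latitude" in df.columns and pd.notna(row.get("latitude")):
            if abs(float(row["latitude"])) > 90:
                reason = "invalid_latitude"
        if (
            reason is None
            and "respirometry_type" in df.columns
            and pd.notna(row.get("respirometry_type"))
            and row["respirometry_type"] not in RESPIROMETRY_TYPES
        ):
            reason = "unknown_respirometry_type"
        if reason is not None:
            keep[df.index.get_loc(i)] = False
            reasons.append({"row": i, "reason": reason})
    report = pd.DataFrame(reasons, columns=["row", "reason"])
    return df[keep].reset_index(drop=True), report


def harmonize_units(records: pd.DataFrame) -> pd.DataFrame:
    """Attach kPa and (where possible) mg/L representations of Pcrit.

    Adds columns ``pcrit_kpa``, ``pcrit_mg_per_l``, ``conversion_flag``.
    Pressure-family values convert to kPa without conditions; % air
    saturation and concentration units need temperature (and use the
    row's salinity, defaulting to 0 when absent).  The mg/L representation
    needs both temperature and salinity; rows lacking salinity get
    ``conversion_flag='no_salinity'`` and an absent mg/L value.
    Idempotent: re-running recomputes the same columns.
    """
    out = records.copy()
    kpa = np.full(len(out), np.nan)
    mgl = np.full(len(out), np.nan)
    flags = np.array([""] * len(out), dtype=object)
    for k, (_, row) in enumerate(out.iterrows()):
        unit = row["pcrit_unit"]
        value = float(row["pcrit_value"])
        t = row.get("trial_temperature")
        s = row.get("salinity")
        has_sal = pd.notna(s)
        cond = None
        try:
            cond = WaterConditions(
                temperature=float(t), salinity=float(s) if has_sal else 0.0
            )
        except (TypeError, ValueError):
            pass
        q = OxygenQuantity(value, unit)
        try:
            # pressure-family conversions need no conditions; the rest do
            kpa[k] = convert_o2(q, "kPa", cond).value
        except ValueError:
            flags[k] = (
                "kpa_conversion_failed" if cond is not None else "conditions_out_of_range"
            )
            continue
        if cond is None:
            flags[k] = "conditions_out_of_range"
        elif has_sal:
            mgl[k] = convert_o2(OxygenQuantity(kpa[k], "kPa"), "mg_per_L", cond).value
        else:
            flags[k] = "no_salinity"
    out["pcrit_kpa"] = kpa
    out["pcrit_mg_per_l"] = mgl
    out["conversion_flag"] = flags
    return out


def control_subset(records: pd.DataFrame) -> ControlSubset:
    """Apply the three control-inclusion rules.

    Included iff fed_state in {unfed, post_absorptive} AND
    additional_stressor is False AND acclimation_days > 2 (strict).
    Rows with any of the three fields missing are excluded with reason
    ``missing_field``.  Nothing raises; everything is logged.
    """
    reasons = []
    keep = np.ones(len(records), dtype=bool)
    for k, (i, row) in enumerate(records.iterrows()):
        fed = row.get("fed_state")
        stressor = row.get("additional_stressor")
        acclim = row.get("acclimation_days")
        if pd.isna(fed) or pd.isna(stressor) or pd.isna(acclim):
            keep[k] = False
            reasons.append({"row": i, "reason": "missing_field"})
        elif fed not in ("unfed", "post_absorptive"):
            keep[k] = False
            reasons.append({"row": i, "reason": "fed"})
        elif bool(stressor):
            keep[k] = False
            reasons.append({"row": i, "reason": "stressor"})
        elif not float(acclim) > 2.0:
            keep[k] = False
            reasons.append({"row": i, "reason": "short_acclimation"})
    log = pd.DataFrame(reasons, columns=["row", "reason"])
    return ControlSubset(records=records[keep].reset_index(drop=True), exclusion_log=log)


def assign_climate_zone(
    latitude: float, cutoffs: tuple[float, float, float] = DEFAULT_ZONE_CUTOFFS
) -> str:
    """Climate zone from |latitude|: tropical / subtropical / temperate / polar.

    Default cutoffs are the astronomical tropic (23.44) and polar (66.56)
    circles with a conventional 35 degree subtropical bound.
    """
    if pd.isna(latitude):
        raise ValueError("latitude is missing")
    a = abs(float(latitude))
    if a > 90:
        raise ValueError(f"|latitude| must be <= 90, got {latitude}")
    t, st, te = cutoffs
    if a <= t:
        return "tropical"
    if a <= st:
        return "subtropical"
    if a <= te:
        return "temperate"
    return "polar"


def zone_anova(
    subset: pd.DataFrame,
    value_column: str = "pcrit_kpa",
    zone_column: str = "climate_zone",
    cutoffs: tuple[float, float, float] = DEFAULT_ZONE_CUTOFFS,
    alpha: float = 0.05,
) -> dict:
    """One-way ANOVA of Pcrit across climate zones with Sidak post hoc.

    Polar rows are excluded (historically too few to analyse).  Zones are
    taken from ``zone_column`` if present, otherwise derived from
    ``latitude``.  Pairwise comparisons use pooled-MSE t-tests with the
    Sidak adjustment p_adj = 1 - (1 - p)^m.
    """
    df = subset.copy()
    if zone_column not in df.columns:
        df[zone_column] = df["latitude"].map(lambda x: assign_climate_zone(x, cutoffs))
    df = df[df[zone_column] != "polar"]
    groups = {z: g[value_column].dropna().to_numpy() for z, g in df.groupby(zone_column)}
    sizes = {z: v.size for z, v in groups.items()}
    usable = {z: v for z, v in groups.items() if v.size >= 2}
    if len(usable) < 2:
        raise ValueError(f"need >= 2 zones with >= 2 records, group sizes: {sizes}")

    names = sorted(usable)
    arrays = [usable[z] for z in names]
    n_total = sum(a.size for a in arrays)
    k = len(arrays)
    df_between, df_within = k - 1, n_total - k
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    mse = ss_within / df_within
    if mse == 0.0:
        # degenerate all-equal-within case: no variance to explain
        f_stat = 0.0 if ss_between == 0.0 else math.inf
        p_value = 1.0 if ss_between == 0.0 else 0.0
    else:
        f_stat = (ss_between / df_between) / mse
        p_value = float(stats.f.sf(f_stat, df_between, df_within))

    m = k * (k - 1) // 2
    pairwise = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = arrays[i], arrays[j]
            se = math.sqrt(mse * (1.0 / a.size + 1.0 / b.size))
            diff = a.mean() - b.mean()
            t = diff / se if se > 0 else (0.0 if diff == 0 else math.copysign(math.inf, diff))
            p = 2.0 * stats.t.sf(abs(t), df_within)
            p_adj = 1.0 - (1.0 - p) ** m
            pairwise.append(
                {
                    "zone_a": names[i],
                    "zone_b": names[j],
                    "mean_a": a.mean(),
                    "mean_b": b.mean(),
                    "t": t,
                    "p": p,
                    "p_sidak": min(p_adj, 1.0),
                    "significant": p_adj < alpha,
                }
            )
    return {
        "F": float(f_stat),
        "p": float(p_value),
        "df": (df_between, df_within),
        "ms_between": ss_between / df_between,
        "ms_within": mse,
        "group_means": {z: float(usable[z].mean()) for z in names},
        "group_sizes": {z: int(usable[z].size) for z in names},
        "pairwise": pd.DataFrame(pairwise),
    }


def method_comparisons(
    subset: pd.DataFrame,
    value_column: str = "pcrit_kpa",
    min_per_method: int = 3,
) -> pd.DataFrame:
    """Within-species unpaired t-tests between respirometry types.

    For every species with at least two respirometry types each carrying
    more than two records, every method pair is compared with a Student's
    unpaired (pooled-variance) t-test.  Returns one row per comparison;
    empty (with a warning) when no species qualifies.
    """
    rows = []
    for species, g in subset.groupby("species"):
        counts = g.groupby("respirometry_type")[value_column].count()
        methods = counts[counts >= min_per_method].index.tolist()
        if len(methods) < 2:
            continue
        for i in range(len(methods)):
            for j in range(i + 1, len(methods)):
                a = g.loc[g["respirometry_type"] == methods[i], value_column].dropna()
                b = g.loc[g["respirometry_type"] == methods[j], value_column].dropna()
                t, p = stats.ttest_ind(a, b, equal_var=True)
                rows.append(
                    {
                        "species": species,
                        "method_a": methods[i],
                        "method_b": methods[j],
                        "n_a": len(a),
                        "n_b": len(b),
                        "t": float(t),
                        "df": len(a) + len(b) - 2,
                        "p": float(p),
                    }
                )
    if not rows:
        import warnings

        warnings.warn("no species has >= 2 respirometry types with enough records")
    return pd.DataFrame(
        rows, columns=["species", "method_a", "method_b", "n_a", "n_b", "t", "df", "p"]
    )


def salinity_comparison(
    subset: pd.DataFrame,
    freshwater_below: float = 10.0,
    value_columns: tuple[str, str] = ("pcrit_kpa", "pcrit_mg_per_l"),
) -> dict:
    """Mann-Whitney U comparison of freshwater vs seawater Pcrit.

    Run separately on the kPa and mg/L representations (the published
    contrast is significant in kPa and vanishes in mg/L, because the
    higher O2 solubility of fresh water offsets the partial-pressure
    difference).  Groups come from a ``water_type`` column if present,
    else from salinity (< ``freshwater_below`` PSU = freshwater).  The
    test uses the normal approximation with tie correction; z is derived
    from U.
    """
    if "water_type" in subset.columns:
        fw_mask = subset["water_type"] == "freshwater"
        sw_mask = subset["water_type"] == "seawater"
    else:
        fw_mask = subset["salinity"] < freshwater_below
        sw_mask = ~fw_mask
    out = {}
    for col in value_columns:
        fw = subset.loc[fw_mask, col].dropna().to_numpy()
        sw = subset.loc[sw_mask, col].dropna().to_numpy()
        if fw.size == 0 or sw.size == 0:
            raise ValueError(
                f"both groups must be non-empty for {col} (freshwater {fw.size}, "
                f"seawater {sw.size})"
            )
        res = stats.mannwhitneyu(fw, sw, alternative="two-sided", method="asymptotic")
        u = float(res.statistic)
        n1, n2 = fw.size, sw.size
        mu = n1 * n2 / 2.0
        combined = np.concatenate([fw, sw])
        _, tie_counts = np.unique(combined, return_counts=True)
        n = n1 + n2
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1.0))
        sigma = math.sqrt(n1 * n2 / 12.0 * (n + 1.0 - tie_term))
        z = (u - mu) / sigma
        out[col] = {
            "U": u,
            "z": float(z),
            "p": float(res.pvalue),
            "n_freshwater": int(n1),
            "n_seawater": int(n2),
            "median_freshwater": float(np.median(fw)),
            "median_seawater": float(np.median(sw)),
            "mean_freshwater": float(fw.mean()),
            "mean_seawater": float(sw.mean()),
            "percent_difference_of_means": float(
                (sw.mean() - fw.mean()) / sw.mean() * 100.0
            ),
        }
    return out


_PREDICTORS = ("salinity", "trial_temperature", "body_mass", "rmr")


def pcrit_regression(
    subset: pd.DataFrame,
    selection: str = "none",
    predictors: tuple[str, ...] = _PREDICTORS,
    value_column: str = "pcrit_kpa",
    enter_p: float = 0.05,
) -> dict:
    """(Stepwise) multiple linear regression of Pcrit on the trait covariates.

    ``selection='none'`` fits OLS on all predictors; ``'stepwise'`` runs
    forward selection, entering at each step the predictor with the
    smallest partial-F p-value below ``enter_p``.  Complete cases only.
    Reports unstandardised b, standardised beta, squared semipartial
    correlations sr^2, the intercept, adjusted r^2, F and degrees of
    freedom.  Constant predictors are excluded (logged); a design with
    condition number above 1e10 raises.
    """
    import statsmodels.api as sm

    if selection not in ("none", "stepwise"):
        raise ValueError(f"selection must be 'none' or 'stepwise', got {selection!r}")
    cols = [*predictors, value_column]
    data = subset[cols].dropna().astype(float)
    y = data[value_column].to_numpy()
    n = len(data)
    if n <= len(predictors) + 1:
        raise ValueError(f"too few complete cases ({n}) for {len(predictors)} predictors")

    excluded = []
    usable = []
    for p in predictors:
        if np.std(data[p].to_numpy()) == 0:
            excluded.append({"predictor": p, "reason": "constant"})
        else:
            usable.append(p)

    if selection == "stepwise":
        chosen: list[str] = []
        remaining = list(usable)
        while remaining:
            best = None
            for p in remaining:
                X = sm.add_constant(data[chosen + [p]].to_numpy())
                fit = sm.OLS(y, X).fit()
                p_val = fit.pvalues[-1]
                if best is None or p_val < best[0]:
                    best = (p_val, p)
            if best is None or best[0] >= enter_p:
                break
            chosen.append(best[1])
            remaining.remove(best[1])
            excluded = [e for e in excluded if e["predictor"] != best[1]]
        for p in remaining:
            excluded.append({"predictor": p, "reason": "not_selected"})
        selected = chosen
    else:
        selected = usable

    if not selected:
        raise ValueError("no predictors survived selection")
    X = sm.add_constant(data[selected].to_numpy())
    if np.linalg.cond(X) > 1e10:
        raise ValueError("design matrix is near-collinear (condition number > 1e10)")
    fit = sm.OLS(y, X).fit()

    sd_y = y.std(ddof=1)
    coef_rows = []
    for idx, p in enumerate(selected, start=1):
        b = fit.params[idx]
        beta = b * data[p].std(ddof=1) / sd_y
        t = fit.tvalues[idx]
        sr2 = t**2 * (1.0 - fit.rsquared) / fit.df_resid
        coef_rows.append(
            {"predictor": p, "b": float(b), "beta": float(beta), "sr2": float(sr2),
             "p": float(fit.pvalues[idx])}
        )
    return {
        "coefficients": pd.DataFrame(coef_rows),
        "intercept": float(fit.params[0]),
        "r_squared": float(fit.rsquared),
        "adjusted_r_squared": float(fit.rsquared_adj),
        "F": float(fit.fvalue),
        "df": (int(fit.df_model), int(fit.df_resid)),
        "p": float(fit.f_pvalue),
        "n": n,
        "selection": selection,
        "excluded": pd.DataFrame(excluded, columns=["predictor", "reason"]),
    }
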