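"""Cohort selection and per-woman ED history reconstruction.

The unit of analysis is the woman, not the visit: for each woman with at
least one aggression visit at age 15–70, every diagnosis and trauma reported
in any ED visit during the ``lookback_years`` preceding (and including) her
latest aggression visit is collapsed into a 29-dimensional binary indicator
vector (the *history*). A woman is WVV (victim of violence) when any of the
nine violence diagnosis codes appears in her history.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import yaml

from .categories import (
    CATEGORIES,
    TRAUMA_PLACE_CATEGORY,
    VIOLENCE_CATEGORIES,
    CategoryMapper,
    default_mapper,
)

__all__ = [
    "read_visits",
    "select_cohort",
    "build_history",
    "build_histories",
    "summarize_cohort",
    "summary_from_counts",
    "percentage",
    "prevalence_percent",
]

AGE_GROUP_EDGES = ((15, 24, "15-24"), (25, 34, "25-34"), (35, 54, "35-54"), (55, 70, "55-70"))


def _age_to_group(age: float) -> str | None:
    for lo, hi, label in AGE_GROUP_EDGES:
        if lo <= age <= hi:
            return label
    return None


def read_visits(path, column_map=None) -> pd.DataFrame:
    """Read a visit file (CSV, one row per ED visit).

    ``column_map`` may be a mapping or a YAML file path renaming foreign
    column names onto the expected schema (woman_id, visit_date, icd9_codes,
    trauma_place, aggression_flag, arrival, outcome, triage, and either
    age_at_visit or age_group, nationality, residence).
    """
    df = pd.read_csv(path, dtype={"icd9_codes": str}, keep_default_na=False)
    if column_map is not None:
        if not isinstance(column_map, dict):
            column_map = yaml.safe_load(open(column_map))
        df = df.rename(columns=column_map)
    df["visit_date"] = pd.to_datetime(df["visit_date"])
    if df["aggression_flag"].dtype == object:
        df["aggression_flag"] = df["aggression_flag"].isin([True, "True", "true", "1", 1])
    return df


def select_cohort(visits: pd.DataFrame, age_min: int = 15, age_max: int = 70) -> set[str]:
    """Women with >= 1 aggression visit at an eligible age.

    Age at the aggression visit is taken from ``age_at_visit`` when present,
    otherwise from ``age_group`` (whose four bands all lie within 15–70).
    """
    agg = visits[visits["aggression_flag"]]
    if agg.empty:
        return set()
    if "age_at_visit" in agg.columns:
        ok = agg[(agg["age_at_visit"] >= age_min) & (agg["age_at_visit"] <= age_max)]
    else:
        ok = agg[agg["age_group"].astype(str).isin([g for _, _, g in AGE_GROUP_EDGES])]
    return set(ok["woman_id"])


def _window_start(index_date: pd.Timestamp, lookback_years: int) -> pd.Timestamp:
    return index_date - pd.DateOffset(years=lookback_years)


def build_history(woman_visits: pd.DataFrame, lookback_years: int = 3,
                  mapper: CategoryMapper | None = None,
                  repeated_scope: str = "window") -> dict:
    """History of one woman: indicators over the closed look-back window
    ``[index − lookback, index]`` around her latest aggression visit.

    ``repeated_scope`` controls whether repeated aggression counts visits in
    the look-back window (default) or over the woman's whole record.
    """
    mapper = mapper or default_mapper()
    agg = woman_visits[woman_visits["aggression_flag"]]
    if agg.empty:
        raise ValueError("build_history requires at least one aggression visit")
    index_date = agg["visit_date"].max()
    start = _window_start(index_date, lookback_years)
    in_window = woman_visits[
        (woman_visits["visit_date"] >= start) & (woman_visits["visit_date"] <= index_date)
    ]

    ind = {c: False for c in CATEGORIES}
    for row in in_window.itertuples():
        if getattr(row, "outcome", None) == "left_without_visit":
            ind["missing_diagnosis"] = True
        else:
            raw = getattr(row, "icd9_codes", "") or ""
            for code in str(raw).split(";"):
                code = code.strip()
                if code:
                    ind[CATEGORIES[mapper.map_code(code)]] = True
        place = getattr(row, "trauma_place", "none")
        if not row.aggression_flag and place in TRAUMA_PLACE_CATEGORY:
            ind[TRAUMA_PLACE_CATEGORY[place]] = True

    scope = in_window if repeated_scope == "window" else woman_visits
    n_agg = int(scope["aggression_flag"].sum())
    ind["repeated_aggression"] = n_agg >= 2
    non_agg_trauma = scope[
        (~scope["aggression_flag"])
        & (scope["trauma_place"].isin(TRAUMA_PLACE_CATEGORY))
    ]

    index_row = agg.loc[agg["visit_date"].idxmax()]
    if "age_at_visit" in woman_visits.columns:
        age_group = _age_to_group(float(index_row["age_at_visit"]))
    else:
        age_group = str(index_row["age_group"])

    out = dict(ind)
    out.update(
        woman_id=index_row["woman_id"],
        index_date=index_date,
        age_group=age_group,
        nationality=str(index_row.get("nationality", "missing")),
        residence=str(index_row.get("residence", "outside")),
        wvv=any(ind[c] for c in VIOLENCE_CATEGORIES),
        repeated_aggression=ind["repeated_aggression"],
        repeated_other_trauma=len(non_agg_trauma) >= 2,
        n_aggression=n_agg,
    )
    return out


def build_histories(visits: pd.DataFrame, lookback_years: int = 3,
                    mapper: CategoryMapper | None = None,
                    age_min: int = 15, age_max: int = 70,
                    repeated_scope: str = "window") -> pd.DataFrame:
    """Select the cohort and build one history row per woman."""
    mapper = mapper or default_mapper()
    cohort = select_cohort(visits, age_min, age_max)
    rows = []
    for _, wv in visits[visits["woman_id"].isin(cohort)].groupby("woman_id", sort=True):
        rows.append(build_history(wv, lookback_years, mapper, repeated_scope))
    df = pd.DataFrame(rows)
    front = ["woman_id", "index_date", "age_group", "nationality", "residence",
             "wvv", "repeated_other_trauma", "n_aggression"]
    return df[front + [c for c in CATEGORIES]]


# ---------------------------------------------------------------------------
# summary table
# ---------------------------------------------------------------------------

def percentage(count: int, total: int) -> float:
    """100*count/total, rounded to 2 decimals half away from zero;
    0.0 when the denominator is zero."""
    if total == 0:
        return 0.0
    pct = Decimal(100 * count) / Decimal(total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def prevalence_percent(n_cases: int, n_total: int) -> float:
    """Prevalence as a percentage rounded to 2 decimals (e.g. 0.47)."""
    return percentage(n_cases, n_total)


def summary_from_counts(counts: dict, totals: dict | None = None) -> pd.DataFrame:
    """Turn nested counts {block: {stratum: {'wvv': n, 'other': n}}} into the
    summary table with percentages per column.

    ``totals`` gives the column denominators, either one ``{'wvv': n,
    'other': n}`` pair for all blocks or one per block name; without it the
    block column sums are used. An explicit total matters when a block omits
    a (e.g. missing-data) stratum, so its rows do not sum to the column N.
    """
    rows = []
    for block, strata in counts.items():
        if totals is None:
            tot = {col: sum(v[col] for v in strata.values()) for col in ("wvv", "other")}
        elif block in totals:
            tot = totals[block]
        elif "wvv" in totals:
            tot = totals
        else:
            tot = {col: sum(v[col] for v in strata.values()) for col in ("wvv", "other")}
        for stratum, v in strata.items():
            rows.append({
                "block": block,
                "stratum": stratum,
                "wvv_n": v["wvv"],
                "wvv_pct": percentage(v["wvv"], tot["wvv"]),
                "other_n": v["other"],
                "other_pct": percentage(v["other"], tot["other"]),
                "zero_denominator": tot["wvv"] == 0 or tot["other"] == 0,
            })
    return pd.DataFrame(rows)


def summarize_cohort(histories: pd.DataFrame, visits: pd.DataFrame | None = None) -> pd.DataFrame:
    """Cohort summary by WVV status: demographic blocks count women;
    arrival/outcome/triage blocks (when visits are given) count ED visits.
    Percentages use the column N (women or visits in that WVV group) as
    denominator."""
    counts: dict = {}
    totals: dict = {}
    wvv_mask = histories["wvv"].astype(bool)
    women_tot = {"wvv": int(wvv_mask.sum()), "other": int((~wvv_mask).sum())}

    def block_from(series: pd.Series, name: str, order=None) -> None:
        values = order or sorted(series.astype(str).unique())
        counts[name] = {
            str(v): {
                "wvv": int(((series.astype(str) == str(v)) & wvv_mask).sum()),
                "other": int(((series.astype(str) == str(v)) & ~wvv_mask).sum()),
            }
            for v in values
        }
        totals[name] = women_tot

    block_from(histories["age_group"], "age_group",
               order=[g for _, _, g in AGE_GROUP_EDGES])
    block_from(histories["nationality"], "nationality")
    block_from(histories["residence"], "residence")
    block_from(histories["repeated_aggression"].map({True: "yes", False: "no"}),
               "repeated_aggression", order=["no", "yes"])
    if "repeated_other_trauma" in histories.columns:
        block_from(histories["repeated_other_trauma"].map({True: "yes", False: "no"}),
                   "repeated_other_trauma", order=["no", "yes"])

    if visits is not None:
        wvv_women = set(histories.loc[wvv_mask, "woman_id"])
        vmask = visits["woman_id"].isin(set(histories["woman_id"]))
        v = visits[vmask]
        v_wvv = v["woman_id"].isin(wvv_women)
        visit_tot = {"wvv": int(v_wvv.sum()), "other": int((~v_wvv).sum())}
        for col in ("arrival", "outcome", "triage"):
            if col in v.columns:
                counts[col] = {
                    str(val): {
                        "wvv": int(((v[col].astype(str) == str(val)) & v_wvv).sum()),
                        "other": int(((v[col].astype(str) == str(val)) & ~v_wvv).sum()),
                    }
                    for val in sorted(v[col].astype(str).unique())
                }
                totals[col] = visit_tot
    return summary_from_counts(counts, totals)
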