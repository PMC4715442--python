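"""The staged analysis: exclusions -> age grouping -> per-item frequencies
-> parameter estimation -> trajectories -> diagnostics.

Stages are pure functions over pandas DataFrames so each is independently
testable; the CLI chains them.  Exclusion rules are applied in a fixed
order (uniform response pattern, then missing key variables, then the age
cap) with each row attributed to the first rule it trips, so the exclusion
report is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import ModelParams, crossing_point, expected_item_score
from .estimation import (
    CategoryCounts,
    ParamEstimate,
    aggregate_params,
    estimate_mle,
    estimate_ratio,
    loglinear_slope,
    parallelism_check,
    DEFAULT_PARALLEL_THRESHOLD,
)
from .scoring import NEGATIVE_ITEMS, item_columns, score_matrix
from .synthetic import DEFAULT_AGE_BINS, bin_label

__all__ = [
    "ExclusionReport",
    "TrajectoryTable",
    "DiagnosticsReport",
    "apply_exclusions",
    "assign_age_groups",
    "frequency_tables",
    "fit_all",
    "trajectory_compare",
    "run_diagnostics",
]


@dataclass(frozen=True)
class ExclusionReport:
    n_input: int
    n_uniform_pattern: int
    n_missing: int
    n_over_age: int
    n_retained: int

    def __post_init__(self) -> None:
        removed = self.n_uniform_pattern + self.n_missing + self.n_over_age
        assert removed + self.n_retained == self.n_input

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_uniform_pattern": self.n_uniform_pattern,
            "n_missing": self.n_missing,
            "n_over_age": self.n_over_age,
            "n_retained": self.n_retained,
        }


def apply_exclusions(
    df: pd.DataFrame, max_age: int = 89, require_sex: bool = False
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Remove suspect and incomplete rows, reporting per-rule counts.

    Rules, in order (a row is counted once, at the first rule it trips):

    1. uniform pattern — all 20 raw responses identical and equal to 0
       ("rarely" throughout) or 3 ("most" throughout);
    2. missing key variable — any missing item response or age (and sex,
       when ``require_sex``);
    3. age above ``max_age``.
    """
    if len(df) == 0:
        raise ValueError("empty input matrix")
    cols = item_columns()
    items = df[cols].to_numpy(dtype=float)

    complete = ~np.isnan(items).any(axis=1)
    uniform = np.zeros(len(df), dtype=bool)
    uniform[complete] = (items[complete] == 0).all(axis=1) | (
        items[complete] == 3
    ).all(axis=1)

    missing = ~complete | df["age"].isna().to_numpy()
    if require_sex:
        missing |= df["sex"].isna().to_numpy() | (df["sex"] == "").to_numpy()
    missing &= ~uniform

    over_age = (df["age"].to_numpy(dtype=float) > max_age) & ~uniform & ~missing

    keep = ~(uniform | missing | over_age)
    report = ExclusionReport(
        n_input=len(df),
        n_uniform_pattern=int(uniform.sum()),
        n_missing=int(missing.sum()),
        n_over_age=int(over_age.sum()),
        n_retained=int(keep.sum()),
    )
    return df.loc[keep].reset_index(drop=True), report


def assign_age_groups(
    ages, bins: tuple[tuple[int, int], ...] = DEFAULT_AGE_BINS
) -> pd.Series:
    """Map each age to its inclusive bin label; out-of-range ages raise.

    An age outside every bin after exclusions signals a config/data
    mismatch (e.g. the age cap and the last bin disagree).
    """
    ages = pd.Series(ages)
    sorted_bins = sorted(bins)
    for (_, hi1), (lo2, _) in zip(sorted_bins, sorted_bins[1:]):
        if lo2 <= hi1:
            raise ValueError("age bins overlap")
    edges = [lo for lo, _ in sorted_bins] + [sorted_bins[-1][1] + 1]
    labels = [bin_label(lo, hi) for lo, hi in sorted_bins]
    out = pd.cut(ages, bins=edges, labels=labels, right=False)
    # pd.cut leaves gaps between non-contiguous bins; re-check membership
    in_some_bin = pd.Series(False, index=ages.index)
    for lo, hi in sorted_bins:
        in_some_bin |= (ages >= lo) & (ages <= hi)
    if (~in_some_bin).any():
        bad = ages[~in_some_bin].iloc[0]
        raise ValueError(f"age {bad} falls outside all configured bins")
    return out.astype(str)


def frequency_tables(
    df: pd.DataFrame,
    bins: tuple[tuple[int, int], ...] = DEFAULT_AGE_BINS,
    items: tuple[int, ...] | None = None,
) -> dict[str, dict[int, CategoryCounts]]:
    """Exact counts of raw codes 0-3 per item per age group.

    Defaults to the 16 negative items; pass ``items`` to count others
    (positive items are counted in raw coding).  Groups with no rows get
    no entry and are flagged by the caller.
    """
    if items is None:
        items = tuple(sorted(NEGATIVE_ITEMS))
    for i in items:
        if f"item_{i}" not in df.columns:
            raise KeyError(f"unknown item id {i}")
    groups = assign_age_groups(df["age"], bins)
    out: dict[str, dict[int, CategoryCounts]] = {}
    for label in [bin_label(lo, hi) for lo, hi in sorted(bins)]:
        sub = df.loc[(groups == label).to_numpy()]
        if len(sub) == 0:
            continue
        out[label] = {}
        for i in items:
            vals = sub[f"item_{i}"].to_numpy(dtype=int)
            c = np.bincount(vals, minlength=4)
            out[label][i] = CategoryCounts(*(int(x) for x in c[:4]))
    return out


@dataclass
class TrajectoryTable:
    """Per-age-group, per-item fit results and score summaries.

    ``item_table`` has one row per (age_group, item): the item's mean
    Likert score, its four category counts and its (P, r) estimate.
    ``group_table`` has one row per age group: n, mean P and mean r over
    the defined item estimates, and the four mean totals.
    """

    item_table: pd.DataFrame
    group_table: pd.DataFrame
    estimator: str = "ratio"


def fit_all(
    df: pd.DataFrame,
    bins: tuple[tuple[int, int], ...] = DEFAULT_AGE_BINS,
    estimator: str = "ratio",
) -> TrajectoryTable:
    """Fit (P, r) to every group x negative-item table and summarize scores.

    Undefined estimates propagate into the tables as NaN rows (never
    exceptions) and are skipped when aggregating group means.
    """
    if estimator not in ("ratio", "mle"):
        raise ValueError(f"unknown estimator {estimator!r}")
    fit = estimate_ratio if estimator == "ratio" else estimate_mle

    scored = score_matrix(df)
    scored["age_group"] = assign_age_groups(scored["age"], bins)
    freqs = frequency_tables(df, bins)

    item_rows = []
    group_rows = []
    for label in [bin_label(lo, hi) for lo, hi in sorted(bins)]:
        sub = scored.loc[scored["age_group"] == label]
        if label not in freqs:
            group_rows.append({"age_group": label, "n": 0})
            continue
        estimates: list[ParamEstimate] = []
        for i, counts in freqs[label].items():
            est = fit(counts)
            estimates.append(est)
            mean_score = float(sub[f"item_{i}"].mean())
            item_rows.append(
                {
                    "age_group": label,
                    "item_id": i,
                    "mean_score": mean_score,
                    "n_rarely": counts.n_rarely,
                    "n_some": counts.n_some,
                    "n_much": counts.n_much,
                    "n_most": counts.n_most,
                    "method": estimator,
                    "P_hat": est.P_hat,
                    "r_hat": est.r_hat,
                    "n_total": est.n_total,
                    "defined": est.defined,
                }
            )
        mean_P, mean_r, skipped = aggregate_params(estimates)
        group_rows.append(
            {
                "age_group": label,
                "n": len(sub),
                "mean_P": mean_P,
                "mean_r": mean_r,
                "n_undefined_items": skipped,
                "mean_total_20": float(sub["total_20"].mean()),
                "mean_total_16": float(sub["total_16"].mean()),
                "mean_binary_total_20": float(sub["binary_total_20"].mean()),
                "mean_binary_total_16": float(sub["binary_total_16"].mean()),
            }
        )
    return TrajectoryTable(
        item_table=pd.DataFrame(item_rows),
        group_table=pd.DataFrame(group_rows),
        estimator=estimator,
    )


def _pooled_mean(gt: pd.DataFrame, labels: list[str], col: str) -> float:
    sub = gt.loc[gt["age_group"].isin(labels)]
    return float((sub[col] * sub["n"]).sum() / sub["n"].sum())


def trajectory_compare(
    table: TrajectoryTable,
    age_cap: int = 79,
    old_group: str = "70-79",
    mid_groups: tuple[str, ...] = ("30-39", "40-49", "50-59"),
) -> dict:
    """Likert-vs-binary trajectory summary.

    Restricts to groups whose upper bound is <= ``age_cap`` (the
    trajectory comparison is defined on ages 12-79 by default), then
    reports per-group empirical means, analytic expected 16-item totals
    16 P(3r^2+2r+1) (Likert) and 16 P(r^2+r+1) (binary) from the group
    mean parameters, and the ordering of the old group against the pooled
    middle groups under each scoring method.
    """
    gt = table.group_table.copy()
    if len(gt) < 2:
        raise ValueError("need at least 2 age groups")
    hi = gt["age_group"].str.split("-").str[1].astype(int)
    gt = gt.loc[hi <= age_cap].reset_index(drop=True)

    missing = [g for g in (old_group, *mid_groups) if g not in set(gt["age_group"])]
    if missing:
        raise ValueError(f"groups missing from table: {missing}")

    gt["expected_total_16_likert"] = 16.0 * gt.apply(
        lambda row: expected_item_score(
            ModelParams(row["mean_P"], row["mean_r"]), "likert"
        ),
        axis=1,
    )
    gt["expected_total_16_binary"] = 16.0 * gt.apply(
        lambda row: expected_item_score(
            ModelParams(row["mean_P"], row["mean_r"]), "binary"
        ),
        axis=1,
    )

    old = gt.loc[gt["age_group"] == old_group].iloc[0]
    mid_likert = _pooled_mean(gt, list(mid_groups), "mean_total_16")
    mid_binary = _pooled_mean(gt, list(mid_groups), "mean_binary_total_16")
    mid_likert20 = _pooled_mean(gt, list(mid_groups), "mean_total_20")
    mid_binary20 = _pooled_mean(gt, list(mid_groups), "mean_binary_total_20")

    return {
        "group_table": gt,
        "old_group": old_group,
        "mid_groups": list(mid_groups),
        "likert_old_minus_mid_16": float(old["mean_total_16"] - mid_likert),
        "binary_old_minus_mid_16": float(old["mean_binary_total_16"] - mid_binary),
        "likert_old_minus_mid_20": float(old["mean_total_20"] - mid_likert20),
        "binary_old_minus_mid_20": float(old["mean_binary_total_20"] - mid_binary20),
        "likert_old_higher": bool(old["mean_total_16"] > mid_likert),
        "binary_old_lower": bool(old["mean_binary_total_16"] < mid_binary),
    }


@dataclass
class DiagnosticsReport:
    """Per-group log-linear slopes, parallelism verdicts and crossing residuals."""

    slope_table: pd.DataFrame  # age_group, item_id, slope
    group_table: pd.DataFrame  # age_group, spread, sd, parallel, crossing x/y
    residual_table: pd.DataFrame  # age_group, item_id, residual

    def to_dict(self) -> dict:
        return {
            "slopes": self.slope_table.to_dict(orient="records"),
            "groups": self.group_table.to_dict(orient="records"),
            "residuals": self.residual_table.to_dict(orient="records"),
        }


def run_diagnostics(
    df: pd.DataFrame,
    bins: tuple[tuple[int, int], ...] = DEFAULT_AGE_BINS,
    parallel_threshold: float = DEFAULT_PARALLEL_THRESHOLD,
) -> DiagnosticsReport:
    """Model diagnostics per age group.

    For each group: the 16 items' log-linear slopes and the parallelism
    verdict; the crossing point implied by the group's mean r; and each
    item's rarely-to-some relative-frequency segment evaluated at the
    crossing abscissa minus the crossing ordinate.  On exact model
    frequencies with a common r all residuals are zero.
    """
    freqs = frequency_tables(df, bins)
    slope_rows, group_rows, resid_rows = [], [], []
    for label, by_item in freqs.items():
        counts_list = list(by_item.values())
        estimates = [estimate_ratio(c) for c in counts_list]
        try:
            _, mean_r, _ = aggregate_params(estimates)
        except ValueError:
            group_rows.append({"age_group": label, "insufficient_data": True})
            continue
        for i, c in by_item.items():
            slope_rows.append(
                {"age_group": label, "item_id": i, "slope": loglinear_slope(c)}
            )
        par = parallelism_check(counts_list, threshold=parallel_threshold)
        cp = crossing_point(mean_r) if mean_r > 0 else None
        if cp is not None:
            for i, c in by_item.items():
                n = c.n_total
                f0, f1 = c.n_rarely / n, c.n_some / n
                resid = (f0 + cp.x * (f1 - f0)) - cp.y
                resid_rows.append(
                    {"age_group": label, "item_id": i, "residual": resid}
                )
        group_rows.append(
            {
                "age_group": label,
                "mean_r": mean_r,
                "slope_spread": par.spread,
                "slope_sd": par.sd,
                "n_undefined_slopes": par.n_undefined,
                "parallel": par.parallel,
                "crossing_x": cp.x if cp else math.nan,
                "crossing_y": cp.y if cp else math.nan,
                "insufficient_data": False,
            }
        )
    return DiagnosticsReport(
        slope_table=pd.DataFrame(slope_rows),
        group_table=pd.DataFrame(group_rows),
        residual_table=pd.DataFrame(resid_rows),
    )
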