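"""Output surfaces: screening flow, cohort characteristics, marker usage
ranking, signal tables, risk-exposure tables, and pre/post-index
temporal distributions."""
from __future__ import annotations

import logging
import warnings
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .cohort import (OVERALL, ScreeningFlow, StudyConfig, _with_days,
                     constituent_ratio)
from .core import format_ratio

log = logging.getLogger("pssa.report")

__all__ = [
    "usage_table", "temporal_distribution", "plot_temporal",
    "results_tables", "CATEGORY_ORDER",
]

CATEGORY_ORDER = [OVERALL, "A12AA", "C01CA", "H02AB", "R06A"]


def usage_table(included: pd.DataFrame, orders: pd.DataFrame,
                config: StudyConfig,
                min_users: int | None = None) -> pd.DataFrame:
    """Per-drug usage ranking over the included cohort.

    Drops markers below the ``min_users`` floor (defaults to the study
    config's floor).  ``included`` must carry ``index_day`` from
    :func:`pssa.cohort.apply_exclusions`; same-day usage counts orders
    placed on the first index-drug day.
    """
    config.validate()
    if min_users is None:
        min_users = config.min_users_floor
    n_cohort = len(included)
    merged = _with_days(included, orders)
    merged = merged.merge(included[["admission_id", "index_day"]],
                          on="admission_id")
    catalog = config.marker_catalog
    mk = merged[merged["drug_name"].isin(set(catalog["drug_name"]))]

    has_hosp = "hospital_id" in included.columns
    rows = []
    for drug, grp in mk.groupby("drug_name"):
        users = grp["admission_id"].nunique()
        if users == 0 or users < min_users:
            continue
        same = grp.loc[grp["day_of_stay"] == grp["index_day"],
                       "admission_id"].nunique()
        inj = 100.0 * (grp["route"] == "injection").mean()
        row = {
            "drug_name": drug,
            "n_users": int(users),
            "pct_users": constituent_ratio(users, n_cohort),
            "n_same_day": int(same),
            "pct_same_day": constituent_ratio(same, users),
            "injection_pct": round(inj, 2),
        }
        if has_hosp:
            ids = set(grp["admission_id"])
            row["n_hospitals"] = int(
                included.loc[included["admission_id"].isin(ids),
                             "hospital_id"].nunique())
        rows.append(row)
    cols = ["rank", "drug_name"] + (["n_hospitals"] if has_hosp else []) + \
        ["n_users", "pct_users", "n_same_day", "pct_same_day",
         "injection_pct"]
    if not rows:
        return pd.DataFrame(columns=cols)
    table = pd.DataFrame(rows).sort_values(
        ["n_users", "drug_name"], ascending=[False, True],
        kind="mergesort").reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table[cols]


def temporal_distribution(sequences: pd.DataFrame, category: str,
                          washout: int = 30, mu: int = 30) -> pd.DataFrame:
    """Histogram of (first marker day - index day) for one marker or
    category, over offsets -washout..+mu (0 = same day)."""
    rows = sequences[sequences["marker"] == category]
    offsets = np.arange(-washout, mu + 1)
    if len(rows) == 0:
        warnings.warn(f"no sequences for {category!r}: empty histogram")
        counts = np.zeros(len(offsets), dtype=int)
    else:
        diff = (rows["marker_first_day"] - rows["index_day"]).to_numpy()
        diff = diff[(diff >= -washout) & (diff <= mu)]
        counts = np.bincount(diff + washout, minlength=len(offsets))
    return pd.DataFrame({"offset": offsets, "count": counts})


def plot_temporal(dist: pd.DataFrame, path: str | Path,
                  title: str = "", smooth: int = 0) -> Path:
    """Render a temporal distribution as a bar plot, optionally overlaying
    a moving-average smoother of the given (odd) width."""
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(dist["offset"], dist["count"], width=0.9, color="#4878a8")
    if smooth and smooth > 1:
        kernel = np.ones(smooth) / smooth
        ax.plot(dist["offset"],
                np.convolve(dist["count"], kernel, mode="same"),
                color="#c44e52", lw=1.5)
    ax.axvline(0, color="k", lw=0.8, ls="--")
    ax.set_xlabel("days from index order (0 = same day)")
    ax.set_ylabel("admissions")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path


def _attach_category(results: pd.DataFrame,
                     config: StudyConfig) -> pd.DataFrame:
    cat_map = config.marker_catalog.set_index("drug_name")["category"]
    out = results.copy()
    out["atc_category"] = out["marker"].map(
        lambda m: m if m in CATEGORY_ORDER else cat_map.get(m))
    out["is_category"] = out["marker"].isin(CATEGORY_ORDER)
    return out


def results_tables(results: pd.DataFrame, config: StudyConfig,
                   out_dir: str | Path,
                   flow: ScreeningFlow | None = None,
                   characteristics: pd.DataFrame | None = None,
                   usage: pd.DataFrame | None = None) -> dict[str, Path]:
    """Write the result tables (CSV plus a human-readable summary).

    Emits the full per-marker result table, the signal table grouped by
    ATC category with per-drug rows, and the risk-exposure (excess risk
    among exposed adjusted) table for the category-level signals.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    res = _attach_category(results, config)
    order = {c: i for i, c in enumerate(CATEGORY_ORDER)}
    res["_cat_rank"] = res["atc_category"].map(order).fillna(len(order))
    peak = res.groupby("marker")["n_index_to_marker"].transform("max")
    res["_marker_rank"] = -peak
    res = res.sort_values(
        ["_cat_rank", "is_category", "_marker_rank", "marker", "d"],
        ascending=[True, False, True, True, True],
        kind="mergesort").drop(columns=["_marker_rank"])

    full_cols = ["marker", "atc_category", "d", "n_index_to_marker",
                 "n_marker_to_index", "n_tie", "csr", "p", "nesr", "asr",
                 "asr_lower", "asr_upper", "signal", "eraea_count",
                 "eraea_pct"]
    files["results"] = out / "pssa_results.csv"
    res.reindex(columns=full_cols).to_csv(files["results"], index=False)

    sig = res.reindex(columns=["atc_category", "marker", "d",
                               "n_index_to_marker", "n_marker_to_index",
                               "n_tie", "csr", "asr", "asr_lower",
                               "asr_upper", "signal"]).copy()
    for col in ("csr", "asr", "asr_lower", "asr_upper"):
        sig[col + "_display"] = sig[col].map(format_ratio)
    files["table3"] = out / "table3_signals.csv"
    sig.to_csv(files["table3"], index=False)

    era = res[res["is_category"]].reindex(
        columns=["atc_category", "d", "n_index_to_marker", "asr",
                 "eraea_count", "eraea_pct", "n_index"])
    files["table4"] = out / "table4_eraea.csv"
    era.to_csv(files["table4"], index=False)

    if characteristics is not None:
        files["table1"] = out / "table1_characteristics.csv"
        characteristics.to_csv(files["table1"], index=False)
    if usage is not None:
        files["table2"] = out / "table2_usage.csv"
        usage.to_csv(files["table2"], index=False)
    if flow is not None:
        files["flow"] = out / "screening_flow.json"
        flow.to_json(files["flow"])

    lines = ["Sequence symmetry analysis results", "=" * 40, ""]
    if flow is not None:
        lines += [
            f"inpatients:        {flow.n_total_inpatients:>10,}",
            f"index users:       {flow.n_index_users:>10,}"
            f"  ({flow.index_user_pct}%)",
            f"included:          {flow.n_included:>10,}",
            f"excluded early/short stay: {flow.n_excluded_early_or_short:,}; "
            f"no marker: {flow.n_excluded_no_marker:,}; "
            f"repeat index use: {flow.n_excluded_repeat:,}", ""]
    show = res[res["is_category"]]
    if len(show):
        lines.append("Category-level signals:")
        for _, r in show.iterrows():
            lines.append(
                f"  {r['marker']:<8} d={r['d']:>2}  "
                f"{r['n_index_to_marker']:>6}/{r['n_marker_to_index']:<6} "
                f"aSR {format_ratio(r['asr'])} "
                f"({format_ratio(r['asr_lower'])}-"
                f"{format_ratio(r['asr_upper'])})"
                f"{'  *' if r['signal'] else ''}  "
                f"ERAEA {r['eraea_count']:,} ({r['eraea_pct']:.2f}%)")
    files["summary"] = out / "summary.txt"
    files["summary"].write_text("\n".join(lines) + "\n")
    log.info("wrote %d report files to %s", len(files), out)
    return files
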