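"""Cohort construction: inclusion/exclusion screening and first-order dates.

Reduces raw admission + drug-order tables to, per included admission, the
day-of-stay of the first index-drug order and the first marker-drug order
per marker (drug and ATC category) inside the washout-bounded observation
window.  Day-of-stay is 1-based: the admission day is day 1.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import ConfigurationError, DataIntegrityError

log = logging.getLogger("pssa.cohort")

__all__ = [
    "constituent_ratio",
    "DEFAULT_MARKER_CATALOG",
    "CATEGORY_PREFIXES",
    "OVERALL",
    "StudyConfig",
    "ScreeningFlow",
    "select_index_users",
    "apply_exclusions",
    "build_sequences",
    "marker_day_series",
    "characteristics_table",
]

#: ATC prefixes defining the marker categories (4 chars for the
#: antihistamine group, 5 for the others).
CATEGORY_PREFIXES = ("A12AA", "C01CA", "H02AB", "R06A")

#: Label for the pooled all-marker pseudo-category.
OVERALL = "Overall"

_CATALOG_ROWS = [
    # drug_name, atc_code
    ("dexamethasone", "H02AB02"),
    ("methylprednisolone", "H02AB04"),
    ("prednisolone", "H02AB06"),
    ("prednisone", "H02AB07"),
    ("hydrocortisone", "H02AB09"),
    ("calcium gluconate", "A12AA03"),
    ("dopamine", "C01CA04"),
    ("noradrenaline", "C01CA03"),
    ("phenylephrine", "C01CA06"),
    ("adrenaline", "C01CA24"),
    ("metaradrine", "C01CA09"),
    ("isoprenaline", "C01CA02"),
    ("dobutamine", "C01CA07"),
    ("methoxamedrine", "C01CA10"),
    ("promethazine", "R06AD02"),
    ("loratadine", "R06AX13"),
    ("desloratadine", "R06AX27"),
    ("diphenhydramine", "R06AA02"),
    ("chlorpheniramine", "R06AB04"),
    ("cetirizine", "R06AE07"),
    ("ebastine", "R06AX22"),
    ("dimenhydrinate", "R06AA52"),
]


def constituent_ratio(count: float, total: float, decimals: int = 2) -> float:
    """Constituent ratio in percent, rounded for display (the rounding used
    throughout the emitted tables)."""
    if total <= 0:
        return 0.0
    return round(100.0 * count / total, decimals)


def category_of(atc_code: str) -> str | None:
    for prefix in CATEGORY_PREFIXES:
        if atc_code.startswith(prefix):
            return prefix
    return None


def _default_catalog() -> pd.DataFrame:
    df = pd.DataFrame(_CATALOG_ROWS, columns=["drug_name", "atc_code"])
    df["category"] = df["atc_code"].map(category_of)
    return df


#: The 22 anti-allergic marker drugs, with ATC codes and category prefixes.
DEFAULT_MARKER_CATALOG = _default_catalog()


@dataclass
class StudyConfig:
    """Screening and analysis settings."""

    index_drug_name: str = "iodixanol"
    marker_catalog: pd.DataFrame = field(
        default_factory=lambda: DEFAULT_MARKER_CATALOG.copy())
    intervals_d: tuple[int, ...] = (3, 7, 28)
    washout_days: int = 30
    mu_days: int = 30        # last survey day after the index order
    min_stay_days: int = 3   # stays <= this are excluded
    index_min_day: int = 3   # index order must fall on day-of-stay >= this
    exclude_repeat_index: bool = False
    cross_admission_washout: bool = False  # documented divergence knob
    min_users_floor: int = 235

    def validate(self) -> None:
        if not self.index_drug_name:
            raise ConfigurationError("index_drug_name must be non-empty")
        required = {"drug_name", "atc_code", "category"}
        if not required <= set(self.marker_catalog.columns):
            raise ConfigurationError(
                f"marker_catalog must have columns {sorted(required)}")
        if self.index_drug_name in set(self.marker_catalog["drug_name"]):
            raise ConfigurationError(
                f"index drug {self.index_drug_name!r} may not appear in the "
                "marker catalog")
        if any(d < 1 for d in self.intervals_d):
            raise ConfigurationError("intervals_d must be >= 1 day")
        if max(self.intervals_d) > self.mu_days:
            raise ConfigurationError(
                "every interval must be <= mu_days (last survey day)")
        if self.washout_days <= max(self.intervals_d):
            raise ConfigurationError(
                "washout_days must exceed the largest interval")
        if self.min_stay_days < 1:
            raise ConfigurationError("min_stay_days must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "marker_catalog" in d:
            d["marker_catalog"] = pd.DataFrame(d["marker_catalog"])
            if "category" not in d["marker_catalog"].columns:
                d["marker_catalog"]["category"] = \
                    d["marker_catalog"]["atc_code"].map(category_of)
        if "intervals_d" in d:
            d["intervals_d"] = tuple(int(x) for x in d["intervals_d"])
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)


@dataclass
class ScreeningFlow:
    """Screening accounting (population flow chart).

    ``n_index_users == n_included + n_excluded_early_or_short +
    n_excluded_no_marker + n_excluded_repeat`` always holds.
    """

    n_total_inpatients: int = 0
    n_index_users: int = 0
    n_excluded_early_or_short: int = 0
    n_excluded_no_marker: int = 0
    n_excluded_repeat: int = 0
    n_included: int = 0

    @property
    def index_user_pct(self) -> float:
        if self.n_total_inpatients == 0:
            return 0.0
        return constituent_ratio(self.n_index_users, self.n_total_inpatients)

    def check_closure(self) -> None:
        total = (self.n_included + self.n_excluded_early_or_short
                 + self.n_excluded_no_marker + self.n_excluded_repeat)
        if total != self.n_index_users:
            raise DataIntegrityError(
                f"screening accounting broken: {total} != {self.n_index_users}")

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["index_user_pct"] = self.index_user_pct
        Path(path).write_text(json.dumps(d, indent=2) + "\n")


def _with_days(admissions: pd.DataFrame, orders: pd.DataFrame,
               require_known: bool = False) -> pd.DataFrame:
    """Join orders to the given admissions and add 1-based day-of-stay.

    Orders for admissions not in the given frame are dropped unless
    ``require_known`` is set, in which case they raise
    :class:`DataIntegrityError`.  Orders dated outside their admission
    always raise, naming the offending row.
    """
    adm = admissions[["admission_id", "admit_date", "discharge_date"]]
    merged = orders.merge(adm, on="admission_id", how="left", validate="m:1")
    orphan = merged["admit_date"].isna()
    if orphan.any():
        if require_known:
            i = int(np.flatnonzero(orphan.values)[0])
            raise DataIntegrityError(
                f"order row {i} references unknown admission "
                f"{merged['admission_id'].iloc[i]!r}")
        merged = merged[~orphan].reset_index(drop=True)
    day = (pd.to_datetime(merged["order_date"])
           - pd.to_datetime(merged["admit_date"])).dt.days + 1
    stay = (pd.to_datetime(merged["discharge_date"])
            - pd.to_datetime(merged["admit_date"])).dt.days + 1
    bad = (day < 1) | (day > stay)
    if bad.any():
        i = int(np.flatnonzero(bad.values)[0])
        raise DataIntegrityError(
            f"order row {i} ({merged['drug_name'].iloc[i]!r} for "
            f"{merged['admission_id'].iloc[i]!r}) is dated outside its "
            "admission")
    merged["day_of_stay"] = day.astype(np.int64)
    return merged


def _stay_length(admissions: pd.DataFrame) -> pd.Series:
    return ((pd.to_datetime(admissions["discharge_date"])
             - pd.to_datetime(admissions["admit_date"])).dt.days + 1)


def select_index_users(
    admissions: pd.DataFrame, orders: pd.DataFrame, config: StudyConfig,
) -> tuple[pd.DataFrame, ScreeningFlow]:
    """Admissions with at least one index-drug order, plus flow counts."""
    config.validate()
    flow = ScreeningFlow(n_total_inpatients=len(admissions))
    user_ids = orders.loc[orders["drug_name"] == config.index_drug_name,
                          "admission_id"].unique()
    users = admissions[admissions["admission_id"].isin(user_ids)].copy()
    flow.n_index_users = len(users)
    log.info("index users: %d of %d inpatients (%.2f%%)",
             flow.n_index_users, flow.n_total_inpatients, flow.index_user_pct)
    return users, flow


def apply_exclusions(
    index_users: pd.DataFrame, orders: pd.DataFrame, config: StudyConfig,
    flow: ScreeningFlow | None = None,
) -> tuple[pd.DataFrame, ScreeningFlow]:
    """Apply the new-user screening rules to index-user admissions.

    Excluded are admissions with (a) the first index order on a
    day-of-stay before ``index_min_day``, (b) a total stay of at most
    ``min_stay_days`` days, and (c) no marker-drug order inside the
    observation window ``[index - washout, index + mu]``.  The returned
    frame gains ``index_day`` and ``stay_length`` columns.
    """
    config.validate()
    if flow is None:
        flow = ScreeningFlow(n_index_users=len(index_users))
    if len(index_users) == 0:
        flow.check_closure()
        return index_users.assign(index_day=pd.Series(dtype=np.int64),
                                  stay_length=pd.Series(dtype=np.int64)), flow

    merged = _with_days(index_users, orders)
    idx_orders = merged[merged["drug_name"] == config.index_drug_name]
    first_index = idx_orders.groupby("admission_id")["day_of_stay"].min()
    n_index_orders = idx_orders.groupby("admission_id")["day_of_stay"].nunique()

    users = index_users.copy()
    users["stay_length"] = _stay_length(users).astype(np.int64)
    users["index_day"] = users["admission_id"].map(first_index)
    missing = users["index_day"].isna()
    if missing.any():
        raise DataIntegrityError(
            f"{int(missing.sum())} index-user admissions have no index order")
    users["index_day"] = users["index_day"].astype(np.int64)

    early = users["index_day"] < config.index_min_day
    short = users["stay_length"] <= config.min_stay_days
    drop_a = early | short
    flow.n_excluded_early_or_short = int(drop_a.sum())
    users = users[~drop_a]

    if config.exclude_repeat_index:
        repeat = users["admission_id"].map(n_index_orders).fillna(0) > 1
        flow.n_excluded_repeat = int(repeat.sum())
        users = users[~repeat]

    catalog_drugs = set(config.marker_catalog["drug_name"])
    mk = merged[merged["drug_name"].isin(catalog_drugs)][
        ["admission_id", "day_of_stay"]]
    mk = mk.merge(users[["admission_id", "index_day"]], on="admission_id")
    in_window = mk[
        (mk["day_of_stay"] >= mk["index_day"] - config.washout_days)
        & (mk["day_of_stay"] <= mk["index_day"] + config.mu_days)]
    with_marker = set(in_window["admission_id"])
    has_marker = users["admission_id"].isin(with_marker)
    flow.n_excluded_no_marker = int((~has_marker).sum())
    included = users[has_marker].reset_index(drop=True)

    flow.n_included = len(included)
    flow.check_closure()
    log.info("screening: %d users -> %d included "
             "(%d early/short, %d without marker, %d repeat)",
             flow.n_index_users, flow.n_included,
             flow.n_excluded_early_or_short, flow.n_excluded_no_marker,
             flow.n_excluded_repeat)
    return included, flow


def build_sequences(
    included: pd.DataFrame, orders: pd.DataFrame, config: StudyConfig,
) -> pd.DataFrame:
    """First index/marker order days per included admission.

    Returns a long-format frame with one row per (admission, marker):
    ``admission_id, index_day, stay_length, marker, marker_first_day``
    where ``marker`` runs over catalog drug names, ATC category prefixes,
    and the pooled label ``Overall``.  A marker never ordered inside the
    observation window contributes no row.
    """
    config.validate()
    cols = ["admission_id", "index_day", "stay_length", "marker",
            "marker_first_day"]
    if len(included) == 0:
        return pd.DataFrame(columns=cols)

    merged = _with_days(included, orders)
    catalog = config.marker_catalog
    mk = merged[merged["drug_name"].isin(set(catalog["drug_name"]))][
        ["admission_id", "drug_name", "day_of_stay"]]
    key = included[["admission_id", "index_day", "stay_length"]]
    mk = mk.merge(key, on="admission_id")
    mk = mk[(mk["day_of_stay"] >= mk["index_day"] - config.washout_days)
            & (mk["day_of_stay"] <= mk["index_day"] + config.mu_days)]
    mk["category"] = mk["drug_name"].map(
        catalog.set_index("drug_name")["category"])

    frames = []
    by_drug = mk.groupby(["admission_id", "drug_name"], as_index=False)[
        "day_of_stay"].min().rename(columns={"drug_name": "marker",
                                             "day_of_stay":
                                             "marker_first_day"})
    frames.append(by_drug)
    by_cat = mk.dropna(subset=["category"]).groupby(
        ["admission_id", "category"], as_index=False)["day_of_stay"].min()
    frames.append(by_cat.rename(columns={"category": "marker",
                                         "day_of_stay": "marker_first_day"}))
    overall = mk.groupby("admission_id", as_index=False)["day_of_stay"].min()
    overall["marker"] = OVERALL
    frames.append(overall.rename(columns={"day_of_stay": "marker_first_day"}))

    seq = pd.concat(frames, ignore_index=True).merge(key, on="admission_id")
    seq = seq[cols].sort_values(["admission_id", "marker"],
                                kind="mergesort").reset_index(drop=True)
    seq["marker_first_day"] = seq["marker_first_day"].astype(np.int64)
    return seq


def marker_day_series(
    admissions: pd.DataFrame, orders: pd.DataFrame, config: StudyConfig,
    max_day: int | None = None,
) -> dict[str, np.ndarray]:
    """Background marker-initiation series for the null-effect adjustment.

    For every marker (drug, category, and ``Overall``) counts, over ALL
    admissions in the database, how many first received that marker on
    each day-of-stay.  Index position ``n`` of each array is the count
    for day ``n`` (position 0 unused).
    """
    config.validate()
    if max_day is None:
        max_day = config.mu_days + max(config.intervals_d) + 1
    merged = _with_days(admissions, orders, require_known=True)
    catalog = config.marker_catalog
    mk = merged[merged["drug_name"].isin(set(catalog["drug_name"]))][
        ["admission_id", "drug_name", "day_of_stay"]].copy()
    mk["category"] = mk["drug_name"].map(
        catalog.set_index("drug_name")["category"])

    series: dict[str, np.ndarray] = {}

    def add(name: str, first_days: pd.Series) -> None:
        series[name] = np.bincount(
            first_days.to_numpy().clip(0, max_day + 1),
            minlength=max_day + 2)

    for drug, grp in mk.groupby("drug_name"):
        add(str(drug), grp.groupby("admission_id")["day_of_stay"].min())
    for cat, grp in mk.dropna(subset=["category"]).groupby("category"):
        add(str(cat), grp.groupby("admission_id")["day_of_stay"].min())
    add(OVERALL, mk.groupby("admission_id")["day_of_stay"].min())
    return series


_AGE_BANDS = [("<18", 0, 18), ("18-65", 18, 65), (">=65", 65, 200)]


def characteristics_table(included: pd.DataFrame,
                          top_dx: int = 5) -> pd.DataFrame:
    """Descriptive characteristics with constituent ratios and a two-sided
    Pearson chi-square (goodness of fit, equal shares) per category."""
    if len(included) == 0:
        raise ConfigurationError("characteristics_table requires a non-empty "
                                 "cohort")
    n = len(included)
    rows: list[dict] = []

    def block(category: str, levels: list[tuple[str, int]]) -> None:
        counts = [c for _, c in levels]
        if len(counts) < 2 or sum(counts) == 0:
            warnings.warn(f"chi-square skipped for {category!r}: "
                          "fewer than two cells")
            p = np.nan
        else:
            p = float(stats.chisquare(counts).pvalue)
        for i, (level, count) in enumerate(levels):
            rows.append({
                "category": category,
                "level": level,
                "count": int(count),
                "pct": constituent_ratio(count, n),
                "p_value": p if i == 0 else np.nan,
            })

    sex = included["sex"].value_counts()
    block("sex", [("M", int(sex.get("M", 0))), ("F", int(sex.get("F", 0)))])
    ages = included["age"].to_numpy()
    block("age", [(label, int(((ages >= lo) & (ages < hi)).sum()))
                  for label, lo, hi in _AGE_BANDS])
    dx = included["primary_dx"].value_counts().head(top_dx)
    block("primary_dx", [(str(k), int(v)) for k, v in dx.items()])
    surg = included["surgery_flag"].astype(bool)
    block("surgery", [("surgery", int(surg.sum())),
                      ("non-surgical", int((~surg).sum()))])
    alg = included["allergy_history_flag"].astype(bool)
    block("allergy_records", [("no history", int((~alg).sum())),
                              ("history", int(alg.sum()))])
    iod = included["iodixanol_allergy_flag"].astype(bool)
    block("iodixanol_allergy", [("documented", int(iod.sum())),
                                ("none", int((~iod).sum()))])
    return pd.DataFrame(rows)
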