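"""Synthetic inpatient admission and drug-order tables.

The generator emulates the temporal structure that sequence symmetry
analysis relies on: inpatient stays of variable length, an index contrast
agent (iodixanol by default) given once mid-stay to a fraction of
admissions, anti-allergic marker drugs ordered day by day under a
per-day Bernoulli hazard, optional same-day co-orders on the index day
(premedication), and a causal excess of marker orders in a short
reaction window after the index day.

Every marker order carries a ground-truth ``source`` tag
(``baseline`` | ``effect`` | ``same_day``; index orders are tagged
``index``) so downstream estimates can be checked against the
generator's own event log.  :func:`write_tables` persists the tag in a
``provenance.csv`` sidecar, keeping ``orders.csv`` on the plain schema.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError

__all__ = [
    "MarkerSpec",
    "SimulationConfig",
    "generate",
    "write_tables",
    "read_tables",
]

ADMISSION_COLUMNS = [
    "admission_id", "patient_id", "hospital_id", "admit_date",
    "discharge_date", "sex", "age", "primary_dx", "surgery_flag",
    "allergy_history_flag", "iodixanol_allergy_flag",
]
ORDER_COLUMNS = ["admission_id", "drug_name", "atc_code", "order_date", "route"]
PROVENANCE_COLUMNS = ["admission_id", "drug_name", "order_date", "source"]


@dataclass(frozen=True)
class MarkerSpec:
    """One marker drug: name, ATC code, baseline per-day order hazard."""

    name: str
    atc_code: str
    baseline_hazard: float
    injectable: bool = True


def _default_markers() -> list[MarkerSpec]:
    # One representative drug per anti-allergic category; hazards chosen so
    # that cohort usage shares roughly track the observed usage ranking
    # (glucocorticoid >> dopaminergic > antihistamine > calcium).
    return [
        MarkerSpec("dexamethasone", "H02AB02", 0.030),
        MarkerSpec("dopamine", "C01CA04", 0.012),
        MarkerSpec("promethazine", "R06AD02", 0.008),
        MarkerSpec("calcium gluconate", "A12AA03", 0.006),
        MarkerSpec("loratadine", "R06AX13", 0.002, injectable=False),
    ]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic inpatient cohort.

    Defaults reproduce the study conditions the pipeline was designed
    around: a 5.64% index-drug user share, stays averaging ~12 days, the
    index order concentrated in the first week of the stay, and a
    reaction window concentrated 1-3 days after the index order and
    tapering to day 7 (delayed hypersensitivity predominates; acute
    same-day treatment is modelled separately via ``p_same_day``).
    """

    n_admissions: int = 50_000
    seed: int = 0
    # stay length ~ 1 + NegBin(mean = mean_stay_days - 1, dispersion)
    mean_stay_days: float = 12.0
    stay_dispersion: float = 4.0
    max_stay_days: int = 90
    # index drug
    index_drug_name: str = "iodixanol"
    index_atc_code: str = "V08AB09"
    p_index_user: float = 0.0564
    index_day_mean_offset: float = 3.0  # day-of-stay = 1 + Poisson(offset), capped at stay
    p_repeat_index: float = 0.0
    # marker drugs
    marker_specs: list[MarkerSpec] = field(default_factory=_default_markers)
    p_same_day: float = 0.25
    effect_multiplier: float = 5.0
    reaction_lag_probs: dict[int, float] = field(default_factory=lambda: {
        1: 0.35, 2: 0.25, 3: 0.15, 4: 0.10, 5: 0.05, 6: 0.05, 7: 0.05})
    # demographics (constituent shares of the admitted population)
    p_male: float = 0.641
    age_band_probs: dict[str, float] = field(default_factory=lambda: {
        "<18": 0.0105, "18-65": 0.6216, ">=65": 0.3679})
    dx_probs: dict[str, float] = field(default_factory=lambda: {
        "I20-I25": 0.2871, "I60-I69": 0.1354, "K80-K87": 0.0504,
        "C15-C26": 0.0452, "Z40-Z54": 0.0415, "OTHER": 0.4404})
    p_surgery: float = 0.8075
    p_allergy_history: float = 0.0808
    p_iodixanol_allergy: float = 0.0003
    n_hospitals: int = 20
    start_date: str = "2015-01-01"
    calendar_span_days: int = 1095

    def validate(self) -> None:
        probs = {
            "p_index_user": self.p_index_user,
            "p_same_day": self.p_same_day,
            "p_repeat_index": self.p_repeat_index,
            "p_male": self.p_male,
            "p_surgery": self.p_surgery,
            "p_allergy_history": self.p_allergy_history,
            "p_iodixanol_allergy": self.p_iodixanol_allergy,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
        if self.n_admissions < 0:
            raise ConfigurationError("n_admissions must be >= 0")
        if self.mean_stay_days < 1.0:
            raise ConfigurationError("mean_stay_days must be >= 1 day")
        if self.stay_dispersion <= 0:
            raise ConfigurationError("stay_dispersion must be > 0")
        if self.effect_multiplier < 1.0:
            raise ConfigurationError("effect_multiplier must be >= 1")
        if self.index_day_mean_offset < 0:
            raise ConfigurationError("index_day_mean_offset must be >= 0")
        if not self.marker_specs:
            raise ConfigurationError("marker_specs must list at least one drug")
        for spec in self.marker_specs:
            if spec.baseline_hazard < 0:
                raise ConfigurationError(
                    f"baseline_hazard for {spec.name!r} must be >= 0")
        if not self.reaction_lag_probs:
            raise ConfigurationError("reaction_lag_probs must not be empty")
        for lag, w in self.reaction_lag_probs.items():
            if lag < 0 or w < 0:
                raise ConfigurationError(
                    "reaction_lag_probs requires lags >= 0 with weights >= 0")
        total = sum(self.reaction_lag_probs.values())
        if total <= 0:
            raise ConfigurationError("reaction_lag_probs weights sum to zero")
        for name in ("age_band_probs", "dx_probs"):
            d = getattr(self, name)
            if abs(sum(d.values()) - 1.0) > 1e-6:
                raise ConfigurationError(f"{name} must sum to 1")

    # ---- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["marker_specs"] = [dataclasses.asdict(m) for m in self.marker_specs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "marker_specs" in d:
            d["marker_specs"] = [
                m if isinstance(m, MarkerSpec) else MarkerSpec(**m)
                for m in d["marker_specs"]]
        if "reaction_lag_probs" in d:
            d["reaction_lag_probs"] = {
                int(k): float(v) for k, v in d["reaction_lag_probs"].items()}
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def generate(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one synthetic cohort.

    Returns ``(admissions, orders)``; ``orders`` carries an extra
    in-memory ``source`` column with the ground-truth provenance of each
    order.  Output is deterministic for a fixed config (including seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_admissions

    # --- stays and demographics --------------------------------------------
    r = config.stay_dispersion
    mean_extra = config.mean_stay_days - 1.0
    if mean_extra > 0:
        stay = 1 + rng.negative_binomial(r, r / (r + mean_extra), n)
    else:
        stay = np.ones(n, dtype=np.int64)
    stay = np.minimum(stay, config.max_stay_days).astype(np.int64)

    admit_offset = rng.integers(0, config.calendar_span_days, n)
    admit = np.datetime64(config.start_date) + admit_offset
    discharge = admit + (stay - 1)

    sex = np.where(rng.random(n) < config.p_male, "M", "F")
    bands = list(config.age_band_probs)
    band_idx = rng.choice(len(bands), n, p=list(config.age_band_probs.values()))
    age = np.empty(n, dtype=np.int64)
    lohi = {"<18": (1, 18), "18-65": (18, 65), ">=65": (65, 96)}
    for i, b in enumerate(bands):
        m = band_idx == i
        lo, hi = lohi.get(b, (18, 65))
        age[m] = rng.integers(lo, hi, m.sum())
    dx = rng.choice(list(config.dx_probs), n, p=list(config.dx_probs.values()))
    surgery = rng.random(n) < config.p_surgery
    allergy = rng.random(n) < config.p_allergy_history
    p_iod = (config.p_iodixanol_allergy / config.p_allergy_history
             if config.p_allergy_history > 0 else 0.0)
    iod_allergy = allergy & (rng.random(n) < min(p_iod, 1.0))
    hospital = rng.integers(1, config.n_hospitals + 1, n)

    adm_id = np.array([f"A{i:07d}" for i in range(1, n + 1)])
    admissions = pd.DataFrame({
        "admission_id": adm_id,
        "patient_id": np.array([f"P{i:07d}" for i in range(1, n + 1)]),
        "hospital_id": np.array([f"H{h:02d}" for h in hospital]),
        "admit_date": pd.to_datetime(admit).astype("datetime64[ns]"),
        "discharge_date": pd.to_datetime(discharge).astype("datetime64[ns]"),
        "sex": sex,
        "age": age,
        "primary_dx": dx,
        "surgery_flag": surgery,
        "allergy_history_flag": allergy,
        "iodixanol_allergy_flag": iod_allergy,
    })

    # --- index drug orders --------------------------------------------------
    is_user = rng.random(n) < config.p_index_user
    index_day = np.minimum(
        1 + rng.poisson(config.index_day_mean_offset, n), stay)
    index_day = np.where(is_user, index_day, 0)

    rows: list[tuple[np.ndarray, np.ndarray, str, str, str, str]] = []

    def emit(adm_idx: np.ndarray, day: np.ndarray, drug: str, atc: str,
             route: str, source: str) -> None:
        if len(adm_idx):
            rows.append((adm_idx, day, drug, atc, route, source))

    users = np.flatnonzero(is_user)
    emit(users, index_day[users], config.index_drug_name,
         config.index_atc_code, "injection", "index")
    if config.p_repeat_index > 0:
        can = users[(stay[users] > index_day[users])
                    & (rng.random(len(users)) < config.p_repeat_index)]
        if len(can):
            extra = index_day[can] + 1 + np.floor(
                rng.random(len(can)) * (stay[can] - index_day[can])
            ).astype(np.int64)
            emit(can, extra, config.index_drug_name, config.index_atc_code,
                 "injection", "index")

    # --- marker orders ------------------------------------------------------
    lmax = int(stay.max()) if n else 0
    day_grid = np.arange(1, lmax + 1)
    lags = np.array(sorted(config.reaction_lag_probs), dtype=np.int64)
    lag_w = np.array([config.reaction_lag_probs[int(j)] for j in lags])
    lag_w = lag_w / lag_w.sum()
    hazards = np.array([m.baseline_hazard for m in config.marker_specs])
    total_h = hazards.sum()

    for mi, spec in enumerate(config.marker_specs):
        route = "injection" if spec.injectable else "oral"
        if spec.baseline_hazard > 0 and lmax:
            hits = (rng.random((n, lmax)) < spec.baseline_hazard) \
                & (day_grid <= stay[:, None])
            adm_idx, day_idx = np.nonzero(hits)
            emit(adm_idx, day_idx + 1, spec.name, spec.atc_code, route,
                 "baseline")

        # causal excess: per-day hazard in the reaction window scales so the
        # window-average multiplier equals effect_multiplier
        if config.effect_multiplier > 1.0 and spec.baseline_hazard > 0:
            excess = (config.effect_multiplier - 1.0) * spec.baseline_hazard \
                * lag_w * len(lags)
            for j, pe in zip(lags, np.minimum(excess, 1.0)):
                d_eff = index_day + j
                ok = is_user & (d_eff <= stay) & (d_eff >= 1) \
                    & (rng.random(n) < pe)
                idx = np.flatnonzero(ok)
                emit(idx, d_eff[idx], spec.name, spec.atc_code, route,
                     "effect")

    # same-day co-order on the index day (premedication / acute treatment)
    if config.p_same_day > 0 and total_h > 0:
        chosen = users[rng.random(len(users)) < config.p_same_day]
        if len(chosen):
            which = rng.choice(len(config.marker_specs), len(chosen),
                               p=hazards / total_h)
            for mi, spec in enumerate(config.marker_specs):
                sel = chosen[which == mi]
                route = "injection" if spec.injectable else "oral"
                emit(sel, index_day[sel], spec.name, spec.atc_code, route,
                     "same_day")

    if rows:
        parts = []
        for adm_idx, day, drug, atc, route, source in rows:
            parts.append(pd.DataFrame({
                "admission_id": adm_id[adm_idx],
                "drug_name": drug,
                "atc_code": atc,
                "order_date": pd.to_datetime(
                    admit[adm_idx] + (day - 1)).astype("datetime64[ns]"),
                "route": route,
                "source": source,
            }))
        orders = pd.concat(parts, ignore_index=True)
        orders = orders.sort_values(
            ["admission_id", "order_date", "drug_name", "source"],
            kind="mergesort").reset_index(drop=True)
    else:
        orders = pd.DataFrame(columns=ORDER_COLUMNS + ["source"])
        orders["order_date"] = pd.to_datetime(orders["order_date"])
    return admissions, orders


def write_tables(admissions: pd.DataFrame, orders: pd.DataFrame,
                 path: str | Path) -> dict[str, Path]:
    """Write ``admissions.csv``, ``orders.csv`` and (when ground-truth
    tags are present) the ``provenance.csv`` sidecar under *path*."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    adm = admissions.copy()
    for col in ("admit_date", "discharge_date"):
        adm[col] = pd.to_datetime(adm[col]).dt.strftime("%Y-%m-%d")
    files["admissions"] = out / "admissions.csv"
    adm[ADMISSION_COLUMNS].to_csv(files["admissions"], index=False)

    ord_ = orders.copy()
    if len(ord_):
        ord_["order_date"] = pd.to_datetime(ord_["order_date"]).dt.strftime("%Y-%m-%d")
    files["orders"] = out / "orders.csv"
    ord_.reindex(columns=ORDER_COLUMNS).to_csv(files["orders"], index=False)

    if "source" in orders.columns:
        files["provenance"] = out / "provenance.csv"
        ord_.reindex(columns=PROVENANCE_COLUMNS).to_csv(
            files["provenance"], index=False)
    return files


def read_tables(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read tables written by :func:`write_tables`.

    Re-attaches the provenance ``source`` column when the sidecar is
    present and row-aligned with ``orders.csv``.
    """
    base = Path(path)
    adm_path = base / "admissions.csv"
    ord_path = base / "orders.csv"
    for p in (adm_path, ord_path):
        if not p.exists():
            raise FileNotFoundError(str(p))
    admissions = pd.read_csv(adm_path, parse_dates=["admit_date",
                                                    "discharge_date"])
    orders = pd.read_csv(ord_path, parse_dates=["order_date"])
    prov_path = base / "provenance.csv"
    if prov_path.exists():
        prov = pd.read_csv(prov_path, parse_dates=["order_date"])
        if len(prov) == len(orders) and \
                (prov["admission_id"].values == orders["admission_id"].values).all():
            orders = orders.assign(source=prov["source"].values)
    return admissions, orders
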