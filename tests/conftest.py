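"""Shared fixtures and independent brute-force oracles."""
from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from pssa import (MarkerSpec, SimulationConfig, StudyConfig,
                  apply_exclusions, build_sequences, generate,
                  marker_day_series, select_index_users)

BASE = dt.date(2020, 1, 1)


def _adm_row(aid, stay, hospital="H01", sex="M", age=50, dx="I20-I25"):
    return {
        "admission_id": aid, "patient_id": aid.replace("A", "P"),
        "hospital_id": hospital,
        "admit_date": pd.Timestamp(BASE),
        "discharge_date": pd.Timestamp(BASE + dt.timedelta(days=stay - 1)),
        "sex": sex, "age": age, "primary_dx": dx, "surgery_flag": True,
        "allergy_history_flag": False, "iodixanol_allergy_flag": False,
    }


def _order_row(aid, drug, atc, day, route="injection"):
    return {
        "admission_id": aid, "drug_name": drug, "atc_code": atc,
        "order_date": pd.Timestamp(BASE + dt.timedelta(days=day - 1)),
        "route": route,
    }


@pytest.fixture
def tiny_cohort():
    """Hand-built screening fixture with a known survivor set.

    index days / stays / marker days chosen to exercise every exclusion
    rule and every classification outcome at d=3.
    """
    spec = [
        # aid, stay, index_day (0 = none), marker days
        ("A001", 10, 1, [5]),        # index on day 1 -> excluded early
        ("A002", 10, 2, [5]),        # index on day 2 -> excluded early
        ("A003", 2, 1, [2]),         # early AND short
        ("A004", 3, 3, [2]),         # stay of 3 days -> excluded short
        ("A005", 4, 3, [4]),         # included, causal (+1)
        ("A006", 10, 4, [2]),        # included, noncausal (-2)
        ("A007", 12, 5, [5]),        # included, tie
        ("A008", 10, 3, []),         # no marker order -> excluded
        ("A009", 20, 6, [9, 13]),    # included, first marker day 9 (+3)
        ("A010", 10, 0, [2]),        # never got the index drug
        ("A011", 40, 3, [34]),       # marker at index+31 > mu -> excluded
    ]
    admissions = pd.DataFrame([_adm_row(a, s) for a, s, _, _ in spec])
    orders = []
    for aid, stay, iday, mdays in spec:
        if iday:
            orders.append(_order_row(aid, "iodixanol", "V08AB09", iday))
        for m in mdays:
            orders.append(_order_row(aid, "dexamethasone", "H02AB02", m))
    expected = {
        "users": {a for a, _, i, _ in spec if i},
        "included": {"A005", "A006", "A007", "A009"},
        "early_or_short": {"A001", "A002", "A003", "A004"},
        "no_marker": {"A008", "A011"},
    }
    return admissions, pd.DataFrame(orders), expected


@pytest.fixture(scope="session")
def study_config():
    return StudyConfig()


@pytest.fixture(scope="session")
def small_sim():
    """One mid-sized synthetic draw shared by read-only tests."""
    cfg = SimulationConfig(n_admissions=6000, seed=7)
    admissions, orders = generate(cfg)
    return cfg, admissions, orders


@pytest.fixture(scope="session")
def small_pipeline(small_sim):
    cfg, admissions, orders = small_sim
    sc = StudyConfig()
    users, flow = select_index_users(admissions, orders, sc)
    included, flow = apply_exclusions(users, orders, sc, flow)
    sequences = build_sequences(included, orders, sc)
    series = marker_day_series(admissions, orders, sc)
    return sc, admissions, orders, included, flow, sequences, series


# ---- Monte-Carlo study conditions (single-marker cohort at scale) ----------

MC_MARKER = MarkerSpec("dexamethasone", "H02AB02", 0.030)


def mc_config(seed: int, effect_multiplier: float = 1.0,
              n_admissions: int = 50_000) -> SimulationConfig:
    """Null / effect study conditions used in the calibration runs: one
    marker, no same-day co-orders, reaction window uniform on days 1-3."""
    return SimulationConfig(
        n_admissions=n_admissions, seed=seed,
        marker_specs=[MC_MARKER], p_same_day=0.0,
        effect_multiplier=effect_multiplier,
        reaction_lag_probs={1: 1 / 3, 2: 1 / 3, 3: 1 / 3},
    )


def run_chain(admissions, orders, config=None):
    """Raw tables -> (flow, sequences, background series)."""
    sc = config or StudyConfig()
    users, flow = select_index_users(admissions, orders, sc)
    included, flow = apply_exclusions(users, orders, sc, flow)
    sequences = build_sequences(included, orders, sc)
    series = marker_day_series(admissions, orders, sc)
    return flow, sequences, series


# ---- independent oracles ----------------------------------------------------

def brute_force_null_prob(i_series, m_series, mu: int, d: int) -> float:
    """Literal double-loop evaluation of the weighted null probability."""
    def M(n):
        # days are 1-based; position 0 of the series is unused
        return m_series[n] if 1 <= n < len(m_series) else 0.0

    num = den = 0.0
    for m in range(1, mu + 1):
        i_m = i_series[m] if m < len(i_series) else 0.0
        fwd = sum(M(n) for n in range(m + 1, m + d + 1))
        back = sum(M(n) for n in range(m - d, m))
        num += i_m * fwd
        den += i_m * (fwd + back)
    return num / den


def brute_force_sequences(admissions, orders, config):
    """Row-by-row scan computing first index/marker days per admission,
    independent of the pandas implementation.

    Returns {(admission_id, marker): first_day} for included admissions,
    marker running over drugs, ATC categories and 'Overall'.
    """
    cat_map = dict(zip(config.marker_catalog["drug_name"],
                       config.marker_catalog["category"]))
    stays, admits = {}, {}
    for row in admissions.itertuples():
        admits[row.admission_id] = row.admit_date.date()
        stays[row.admission_id] = (row.discharge_date.date()
                                   - row.admit_date.date()).days + 1
    per_adm: dict[str, list[tuple[str, int]]] = {}
    for row in orders.itertuples():
        if row.admission_id not in admits:
            continue
        day = (row.order_date.date() - admits[row.admission_id]).days + 1
        per_adm.setdefault(row.admission_id, []).append((row.drug_name, day))

    out = {}
    for aid, drug_days in per_adm.items():
        idx_days = [day for drug, day in drug_days
                    if drug == config.index_drug_name]
        if not idx_days:
            continue
        index_day = min(idx_days)
        if index_day < config.index_min_day:
            continue
        if stays[aid] <= config.min_stay_days:
            continue
        lo = index_day - config.washout_days
        hi = index_day + config.mu_days
        firsts: dict[str, int] = {}
        for drug, day in drug_days:
            if drug in cat_map and lo <= day <= hi:
                for key in (drug, cat_map[drug], "Overall"):
                    if key is not None:
                        firsts[key] = min(firsts.get(key, 10 ** 9), day)
        if not firsts:
            continue  # no marker inside the observation window
        for key, day in firsts.items():
            out[(aid, key)] = day
    return out
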