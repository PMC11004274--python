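"""The sequence symmetry statistic chain.

Four steps, per marker and interval ``d``:

1. classify each (index day, first marker day) pair as causal
   (marker starts 1..d days after the index drug), non-causal (marker
   starts 1..d days before), tie (same day) or out of window, and form
   the crude sequence ratio cSR = n_causal / n_noncausal;
2. compute the null-effect probability
   ``P = sum_m I_m F_m / sum_m I_m (B_m + F_m)`` with
   ``F_m = sum_{n=m+1}^{m+d} M_n`` and ``B_m = sum_{n=m-d}^{m-1} M_n``,
   weighting the background marker-initiation trend by the index-day
   distribution, and its Wald 95% bounds; the null-effect sequence
   ratio is the odds neSR = P / (1 - P);
3. the adjusted ratio aSR = cSR / neSR with its confidence interval
   (a lower bound above 1 flags a signal);
4. the excess risk among exposed adjusted,
   ERAEA = n_causal (aSR - 1) / aSR, as a count and as a percentage of
   all index-drug users.

Ties (same-day co-orders) are excluded from both cohorts by default and
reported separately.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import (DegenerateDistributionError, ParameterError,
                     UndefinedRatioError)

log = logging.getLogger("pssa.core")

__all__ = [
    "SequenceCounts", "NullEffectInputs", "StatConfig", "PssaResult",
    "classify_sequence", "count_sequences", "crude_sr", "null_effect_prob",
    "p_confidence_bounds", "ne_sr", "adjusted_sr", "eraea",
    "min_sample_size", "run_pssa", "run_all", "format_ratio",
]


@dataclass(frozen=True)
class SequenceCounts:
    """Causal / non-causal / tie / out-of-window tallies for one
    marker at one interval."""

    n_index_to_marker: int
    n_marker_to_index: int
    n_tie: int
    n_out_of_window: int
    d: int

    @property
    def n_classified(self) -> int:
        return self.n_index_to_marker + self.n_marker_to_index

    @property
    def total(self) -> int:
        return (self.n_index_to_marker + self.n_marker_to_index
                + self.n_tie + self.n_out_of_window)


@dataclass
class NullEffectInputs:
    """Per-day index (I_m) and marker (M_n) initiation counts.

    ``i_series[m]`` is the number of admissions first receiving the
    index drug on day-of-stay ``m``; ``m_series[n]`` the number first
    receiving the marker on day ``n`` (position 0 of both is unused).
    """

    i_series: np.ndarray
    m_series: np.ndarray
    mu: int
    d: int

    def validate(self) -> None:
        if self.d < 1:
            raise ParameterError(f"interval d must be >= 1, got {self.d}")
        if self.mu < 1:
            raise ParameterError(f"mu must be >= 1, got {self.mu}")
        for name in ("i_series", "m_series"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 1 or (arr < 0).any():
                raise ParameterError(f"{name} must be a 1-d non-negative "
                                     "array")
            setattr(self, name, arr)


@dataclass
class StatConfig:
    """Constants of the inferential formulas."""

    z_alpha2: float = 1.96       # two-sided 95% normal quantile
    pi_assumed: float = 0.0085   # assumed adverse-event incidence
    tolerance_error: float = (0.0036 + 0.0195) / 2

    def validate(self) -> None:
        if self.z_alpha2 <= 0:
            raise ParameterError("z_alpha2 must be > 0")
        if not 0.0 < self.pi_assumed < 1.0:
            raise ParameterError("pi_assumed must be in (0, 1)")
        if self.tolerance_error <= 0:
            raise ParameterError("tolerance_error must be > 0")


@dataclass
class PssaResult:
    marker: str
    d: int
    n_index_to_marker: int
    n_marker_to_index: int
    n_tie: int
    n_out_of_window: int
    csr: float
    p: float
    p_lower: float
    p_upper: float
    nesr: float
    nesr_lower: float
    nesr_upper: float
    asr: float
    asr_lower: float
    asr_upper: float
    signal: bool
    n_index: int
    eraea_count: int
    eraea_pct: float


def classify_sequence(index_day: int, marker_day: int, d: int) -> str:
    """Classify one admission's index/marker order pair at interval *d*."""
    if d < 1:
        raise ParameterError(f"interval d must be >= 1, got {d}")
    diff = marker_day - index_day
    if diff == 0:
        return "tie"
    if 0 < diff <= d:
        return "causal"
    if 0 < -diff <= d:
        return "noncausal"
    return "out_of_window"


def count_sequences(index_days: np.ndarray, marker_days: np.ndarray,
                    d: int, tie_policy: str = "exclude") -> SequenceCounts:
    """Vectorised tally over paired day arrays.

    ``tie_policy="causal"`` assigns same-day pairs to the causal cohort
    (sensitivity analysis); the default excludes them from both cohorts.
    """
    if d < 1:
        raise ParameterError(f"interval d must be >= 1, got {d}")
    if tie_policy not in ("exclude", "causal"):
        raise ParameterError(f"unknown tie_policy {tie_policy!r}")
    diff = np.asarray(marker_days) - np.asarray(index_days)
    tie = int((diff == 0).sum())
    causal = int(((diff > 0) & (diff <= d)).sum())
    noncausal = int(((diff < 0) & (diff >= -d)).sum())
    if tie_policy == "causal":
        causal, tie = causal + tie, 0
    out = int(len(diff) - causal - noncausal - tie)
    return SequenceCounts(causal, noncausal, tie, out, d)


def crude_sr(counts: SequenceCounts, continuity: bool = False) -> float:
    """cSR = n_index_to_marker / n_marker_to_index.

    With ``continuity=True`` a Haldane-style +0.5 is added to both
    counts when the denominator is zero.
    """
    num, den = counts.n_index_to_marker, counts.n_marker_to_index
    if den == 0:
        if not continuity:
            raise UndefinedRatioError(
                "no marker-to-index sequences: cSR undefined "
                "(pass continuity=True for a +0.5 correction)")
        return (num + 0.5) / 0.5
    return num / den


def null_effect_prob(inputs: NullEffectInputs) -> float:
    """Weighted probability that a marker start falls in the forward
    rather than the backward d-day window around the index day."""
    inputs.validate()
    mu, d = inputs.mu, inputs.d
    size = mu + d + 1
    I = np.zeros(size)
    I[:min(size, len(inputs.i_series))] = inputs.i_series[:size]
    M = np.zeros(size)
    M[:min(size, len(inputs.m_series))] = inputs.m_series[:size]
    if not I[1:mu + 1].any():
        raise DegenerateDistributionError("i_series has no mass on days "
                                          f"1..{mu}")
    cum = np.cumsum(M)  # cum[i] = sum_{n <= i} M_n
    m = np.arange(1, mu + 1)
    fwd = cum[np.minimum(m + d, size - 1)] - cum[m]
    back = cum[m - 1] - cum[np.maximum(m - d - 1, 0)]
    w = I[1:mu + 1]
    num = float(np.dot(w, fwd))
    den = float(np.dot(w, fwd + back))
    if den == 0:
        raise DegenerateDistributionError(
            "no marker starts fall in any survey window")
    return num / den


def p_confidence_bounds(p: float, n_eff: float, z: float = 1.96,
                        ) -> tuple[float, float]:
    """Wald binomial bounds ``p +/- z sqrt(p(1-p)/n)`` clamped to (0, 1).

    Warns when the large-sample guards (n > 200 and p*n > 15) fail.
    """
    if n_eff <= 0:
        raise ParameterError(f"n_eff must be > 0, got {n_eff}")
    if not 0.0 <= p <= 1.0:
        raise ParameterError(f"p must be in [0, 1], got {p}")
    if n_eff <= 200 or p * n_eff <= 15:
        warnings.warn("normal approximation guard failed "
                      f"(n={n_eff:g}, p*n={p * n_eff:.1f}); "
                      "bounds may be inaccurate")
    se = math.sqrt(p * (1.0 - p) / n_eff)
    eps = 1e-12
    return (min(max(p - z * se, eps), 1 - eps),
            min(max(p + z * se, eps), 1 - eps))


def ne_sr(p: float) -> float:
    """Odds transform: neSR = P / (1 - P)."""
    if not 0.0 < p < 1.0:
        raise ParameterError(f"P must lie strictly in (0, 1), got {p}")
    return p / (1.0 - p)


def adjusted_sr(csr: float, nesr_point: float,
                nesr_bounds: tuple[float, float] | None = None,
                ) -> tuple[float, float, float, bool]:
    """aSR = cSR / neSR with its interval and the signal flag.

    The interval divides cSR by the neSR bounds (upper bound of neSR
    gives the lower bound of aSR), so the uncertainty carried is that of
    the null-effect probability.
    """
    if nesr_point <= 0:
        raise ParameterError("neSR must be > 0")
    asr = csr / nesr_point
    if nesr_bounds is None:
        return asr, math.nan, math.nan, False
    lo_n, hi_n = nesr_bounds
    if lo_n <= 0 or hi_n <= 0:
        raise ParameterError("neSR bounds must be > 0")
    lo, hi = csr / hi_n, csr / lo_n
    return asr, lo, hi, lo > 1.0


def binomial_asr_bounds(counts: SequenceCounts, nesr_point: float,
                        alpha: float = 0.05) -> tuple[float, float]:
    """Alternative interval: exact (Clopper-Pearson) bounds on the causal
    proportion, odds-transformed and divided by the point neSR."""
    n = counts.n_classified
    if n == 0:
        raise ParameterError("no classified sequences")
    ci = sstats.binomtest(counts.n_index_to_marker, n).proportion_ci(
        confidence_level=1 - alpha, method="exact")
    eps = 1e-12
    lo_p = min(max(ci.low, eps), 1 - eps)
    hi_p = min(max(ci.high, eps), 1 - eps)
    return (ne_sr(lo_p) / nesr_point, ne_sr(hi_p) / nesr_point)


def eraea(n_index_to_marker: int, asr: float, n_index: int,
          ) -> tuple[int, float]:
    """Excess risk among exposed adjusted.

    ``count = n_index_to_marker (aSR - 1) / aSR`` rounded to the nearest
    integer (floored at zero for aSR < 1); ``pct`` is the count as a
    percentage of all index users, rounded to two decimals.
    """
    if n_index <= 0:
        raise ParameterError("n_index must be > 0")
    if asr <= 0:
        raise ParameterError("aSR must be > 0")
    if n_index_to_marker < 0:
        raise ParameterError("n_index_to_marker must be >= 0")
    raw = n_index_to_marker * (asr - 1.0) / asr
    count = max(int(round(raw)), 0)
    return count, round(100.0 * count / n_index, 2)


def min_sample_size(config: StatConfig) -> int:
    """Minimum cohort size ``ceil(z^2 pi (1 - pi) / E^2)`` (at least 1)."""
    config.validate()
    n = (config.z_alpha2 ** 2 * config.pi_assumed
         * (1.0 - config.pi_assumed) / config.tolerance_error ** 2)
    return max(math.ceil(n), 1)


def run_pssa(
    sequences: pd.DataFrame,
    marker: str,
    d: int,
    *,
    mu: int = 30,
    n_index: int | None = None,
    m_series: np.ndarray | None = None,
    stat: StatConfig | None = None,
    tie_policy: str = "exclude",
    ci_method: str = "paper",
    continuity: bool = False,
) -> PssaResult | None:
    """Full statistic chain for one marker at one interval.

    ``sequences`` is the long-format frame from
    :func:`pssa.cohort.build_sequences`.  ``m_series`` should be the
    background marker-initiation series over all admissions
    (:func:`pssa.cohort.marker_day_series`); without it the series is
    derived from the analysed cohort itself, which under-corrects when
    the causal effect is strong.  ``n_index`` defaults to the number of
    admissions in ``sequences``.

    Returns ``None`` (with a log entry) when the marker has no
    classified sequences.
    """
    stat = stat or StatConfig()
    stat.validate()
    if ci_method not in ("paper", "binomial"):
        raise ParameterError(f"unknown ci_method {ci_method!r}")
    rows = sequences[sequences["marker"] == marker]
    if len(rows) == 0:
        log.info("marker %r: no sequences, skipped", marker)
        return None
    counts = count_sequences(rows["index_day"].to_numpy(),
                             rows["marker_first_day"].to_numpy(),
                             d, tie_policy=tie_policy)
    if counts.n_classified == 0:
        log.info("marker %r at d=%d: no classified sequences, skipped",
                 marker, d)
        return None
    csr = crude_sr(counts, continuity=continuity)

    uniq = sequences[["admission_id", "index_day"]].drop_duplicates()
    i_series = np.bincount(uniq["index_day"].to_numpy(), minlength=mu + d + 2)
    if m_series is None:
        m_series = np.bincount(rows["marker_first_day"].to_numpy().clip(0),
                               minlength=mu + d + 2)
    inputs = NullEffectInputs(i_series=np.asarray(i_series, float),
                              m_series=np.asarray(m_series, float),
                              mu=mu, d=d)
    p = null_effect_prob(inputs)
    n_eff = counts.n_classified
    p_lo, p_hi = p_confidence_bounds(p, n_eff, stat.z_alpha2)
    nesr = ne_sr(p)
    nesr_lo, nesr_hi = ne_sr(p_lo), ne_sr(p_hi)
    asr, asr_lo, asr_hi, signal = adjusted_sr(csr, nesr, (nesr_lo, nesr_hi))
    if ci_method == "binomial":
        asr_lo, asr_hi = binomial_asr_bounds(counts, nesr)
        signal = asr_lo > 1.0
    if n_index is None:
        n_index = sequences["admission_id"].nunique()
    count, pct = eraea(counts.n_index_to_marker, asr, n_index)
    return PssaResult(
        marker=marker, d=d,
        n_index_to_marker=counts.n_index_to_marker,
        n_marker_to_index=counts.n_marker_to_index,
        n_tie=counts.n_tie, n_out_of_window=counts.n_out_of_window,
        csr=csr, p=p, p_lower=p_lo, p_upper=p_hi,
        nesr=nesr, nesr_lower=nesr_lo, nesr_upper=nesr_hi,
        asr=asr, asr_lower=asr_lo, asr_upper=asr_hi, signal=signal,
        n_index=n_index, eraea_count=count, eraea_pct=pct,
    )


def run_all(
    sequences: pd.DataFrame,
    markers: list[str] | None = None,
    intervals: tuple[int, ...] = (3, 7, 28),
    **kwargs,
) -> pd.DataFrame:
    """Run every marker at every interval; one result row each.

    ``kwargs`` are forwarded to :func:`run_pssa`; ``m_series`` may be a
    dict keyed by marker name.
    """
    if markers is None:
        markers = sorted(sequences["marker"].unique())
    m_series = kwargs.pop("m_series", None)
    out = []
    for marker in markers:
        ms = m_series.get(marker) if isinstance(m_series, dict) else m_series
        for d in intervals:
            try:
                res = run_pssa(sequences, marker, d, m_series=ms, **kwargs)
            except (UndefinedRatioError, DegenerateDistributionError) as exc:
                log.info("marker %r at d=%d skipped: %s", marker, d, exc)
                continue
            if res is not None:
                out.append(res.__dict__)
    return pd.DataFrame(out)


def format_ratio(x: float) -> str:
    """Display rounding used in the result tables: two decimals, three
    significant figures for values of 10 or more."""
    if not math.isfinite(x):
        return "nan"
    if abs(x) >= 10:
        return f"{float(f'{x:.3g}'):g}"
    return f"{x:.2f}"
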