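"""Statistic chain: classification, ratios, null-effect probability,
confidence bounds, excess-risk extrapolation, sample size."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pssa import (DegenerateDistributionError, NullEffectInputs,
                  ParameterError, SequenceCounts, StatConfig,
                  UndefinedRatioError, adjusted_sr, classify_sequence,
                  count_sequences, crude_sr, eraea, format_ratio,
                  min_sample_size, ne_sr, null_effect_prob,
                  p_confidence_bounds, run_pssa)

from conftest import brute_force_null_prob


@pytest.mark.parametrize("index_day, marker_day, d, expected", [
    (7, 9, 3, "causal"),          # +2 within d
    (7, 7, 3, "tie"),             # same day
    (7, 11, 3, "out_of_window"),  # +4 beyond d
    (9, 7, 3, "noncausal"),       # -2 within d
    (7, 10, 3, "causal"),         # boundary +d
    (10, 7, 3, "noncausal"),      # boundary -d
    (7, 3, 3, "out_of_window"),   # -4 beyond d
])
def test_sequence_classification(index_day, marker_day, d, expected):
    assert classify_sequence(index_day, marker_day, d) == expected


def test_nonpositive_interval_rejected():
    with pytest.raises(ParameterError):
        classify_sequence(5, 7, 0)
    with pytest.raises(ParameterError):
        count_sequences(np.array([5]), np.array([7]), -1)


@given(st.lists(st.tuples(st.integers(1, 40), st.integers(1, 40)),
                min_size=1, max_size=200),
       st.integers(1, 10))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_classification_is_an_exhaustive_partition(pairs, d):
    idx = np.array([a for a, _ in pairs])
    mk = np.array([b for _, b in pairs])
    counts = count_sequences(idx, mk, d)
    assert counts.total == len(pairs)
    by_scalar = [classify_sequence(a, b, d) for a, b in pairs]
    assert counts.n_index_to_marker == by_scalar.count("causal")
    assert counts.n_marker_to_index == by_scalar.count("noncausal")
    assert counts.n_tie == by_scalar.count("tie")


def test_tie_policy_causal_reassigns_ties():
    idx = np.array([5, 5, 5])
    mk = np.array([5, 6, 3])
    excl = count_sequences(idx, mk, 3)
    assert (excl.n_index_to_marker, excl.n_tie) == (1, 1)
    causal = count_sequences(idx, mk, 3, tie_policy="causal")
    assert (causal.n_index_to_marker, causal.n_tie) == (2, 0)


def test_crude_sr_values():
    # phenylephrine-style 3-day counts
    assert crude_sr(SequenceCounts(2363, 175, 0, 0, 3)) == \
        pytest.approx(13.5029, abs=1e-4)
    assert crude_sr(SequenceCounts(7, 7, 0, 0, 3)) == 1.0
    # pooled 3-day counts
    assert crude_sr(SequenceCounts(11913, 16019, 0, 0, 3)) == \
        pytest.approx(0.7437, abs=1e-4)


def test_crude_sr_zero_denominator():
    counts = SequenceCounts(5, 0, 0, 0, 3)
    with pytest.raises(UndefinedRatioError):
        crude_sr(counts)
    assert crude_sr(counts, continuity=True) == 11.0


def test_null_prob_symmetric_interior_case():
    """A single index day deep inside a uniform marker stream sees equal
    forward and backward mass: P = 1/2."""
    I = np.zeros(40)
    I[10] = 1
    M = np.ones(40)
    inputs = NullEffectInputs(I, M, mu=30, d=3)
    assert null_effect_prob(inputs) == pytest.approx(0.5)


def test_null_prob_one_sided_mass():
    I = np.zeros(40)
    I[5] = 10
    M = np.zeros(40)
    M[6:9] = 3.0  # all marker starts after the only index day
    assert null_effect_prob(NullEffectInputs(I, M, mu=30, d=7)) == 1.0


def test_null_prob_matches_brute_force_double_loop():
    rng = np.random.default_rng(42)
    for _ in range(25):
        I = rng.integers(0, 50, 40).astype(float)
        M = rng.integers(0, 50, 40).astype(float)
        d = int(rng.integers(1, 8))
        got = null_effect_prob(NullEffectInputs(I, M, mu=30, d=d))
        want = brute_force_null_prob(I, M, mu=30, d=d)
        assert got == pytest.approx(want, rel=1e-12)


def test_null_prob_degenerate_inputs():
    I = np.zeros(40)
    with pytest.raises(DegenerateDistributionError):
        null_effect_prob(NullEffectInputs(I, np.ones(40), mu=30, d=3))
    I[5] = 1
    with pytest.raises(DegenerateDistributionError):
        null_effect_prob(NullEffectInputs(I, np.zeros(40), mu=30, d=3))


def test_p_confidence_bounds_closed_form():
    lo, hi = p_confidence_bounds(0.5, 400, 1.96)
    assert (lo, hi) == (pytest.approx(0.451), pytest.approx(0.549))
    lo, hi = p_confidence_bounds(0.5, 400, 0.0)
    assert lo == hi == 0.5
    lo, hi = p_confidence_bounds(0.5, 1e12, 1.96)
    assert lo == pytest.approx(0.5, abs=1e-5)
    with pytest.raises(ParameterError):
        p_confidence_bounds(0.5, 0)


def test_p_confidence_guard_warns():
    with pytest.warns(UserWarning, match="guard"):
        p_confidence_bounds(0.5, 100, 1.96)


def test_ne_sr_odds_transform():
    assert ne_sr(0.5) == 1.0
    assert ne_sr(0.75) == pytest.approx(3.0)
    for p in (0.0, 1.0):
        with pytest.raises(ParameterError):
            ne_sr(p)


@given(st.floats(0.01, 0.98))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_ne_sr_strictly_increasing(p):
    assert ne_sr(p + 0.01) > ne_sr(p)


def test_adjusted_sr_values_and_interval():
    asr, lo, hi, signal = adjusted_sr(1.7, 1.7, (1.5, 1.9))
    assert asr == 1.0 and lo < 1.0 < hi and not signal
    # phenylephrine 3-day back-solve: cSR 13.5029 over neSR 0.625
    asr, *_ = adjusted_sr(13.5029, 0.625)
    assert format_ratio(asr) == "21.6"
    asr, lo, hi, signal = adjusted_sr(3.0, 1.2, (1.1, 1.3))
    assert lo < asr < hi and signal


@given(st.floats(0.05, 50), st.floats(0.02, 0.98))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_asr_nesr_product_recovers_csr(csr, p):
    nesr = ne_sr(p)
    asr, *_ = adjusted_sr(csr, nesr)
    assert asr * nesr == pytest.approx(csr, rel=1e-12)


def test_eraea_worked_examples():
    assert eraea(11913, 2.12, 209756) == (6294, 3.00)
    assert eraea(500, 1.0, 10_000) == (0, 0.0)
    count, _ = eraea(3777, 2.39, 209756)
    assert abs(count - 2198) <= 2  # printed value uses the unrounded aSR
    assert eraea(100, 0.5, 1000) == (0, 0.0)  # floored below the null
    with pytest.raises(ParameterError):
        eraea(10, 2.0, 0)


@given(st.integers(1, 10_000), st.floats(1.0, 30.0), st.floats(0.1, 5.0))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_eraea_monotone_in_asr(n_causal, asr, bump):
    low, _ = eraea(n_causal, asr, 10 ** 6)
    high, _ = eraea(n_causal, asr + bump, 10 ** 6)
    assert high >= low


def test_min_sample_size():
    assert min_sample_size(StatConfig()) == 243
    assert min_sample_size(StatConfig(pi_assumed=0.5,
                                      tolerance_error=0.05)) == 385
    assert min_sample_size(StatConfig(tolerance_error=1e6)) == 1
    with pytest.raises(ParameterError):
        min_sample_size(StatConfig(tolerance_error=0.0))


def test_run_pssa_conservation_and_identities(small_pipeline):
    sc, admissions, orders, included, flow, sequences, series = small_pipeline
    for marker in ("Overall", "H02AB", "dexamethasone"):
        rows = sequences[sequences["marker"] == marker]
        for d in (3, 7):
            res = run_pssa(sequences, marker, d, mu=sc.mu_days,
                           n_index=flow.n_index_users,
                           m_series=series[marker])
            total = (res.n_index_to_marker + res.n_marker_to_index
                     + res.n_tie + res.n_out_of_window)
            assert total == len(rows)
            assert res.asr * res.nesr == pytest.approx(res.csr, rel=1e-12)
            assert res.asr_lower <= res.asr <= res.asr_upper
            assert 0 < res.p < 1


def test_run_pssa_unknown_marker_returns_none(small_pipeline):
    *_, sequences, series = small_pipeline
    assert run_pssa(sequences, "no-such-drug", 3) is None


def test_run_pssa_binomial_interval_brackets_point(small_pipeline):
    sc, _, _, _, flow, sequences, series = small_pipeline
    res = run_pssa(sequences, "Overall", 7, mu=sc.mu_days,
                   n_index=flow.n_index_users, m_series=series["Overall"],
                   ci_method="binomial")
    assert res.asr_lower < res.asr < res.asr_upper


def test_format_ratio_display_rules():
    assert format_ratio(21.6046) == "21.6"
    assert format_ratio(2.115) == "2.12"
    assert format_ratio(0.9712) == "0.97"
    assert format_ratio(12.04) == "12"
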