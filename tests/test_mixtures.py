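"""Histogramming, static/dynamic mixture fits and the exchange-rate
amplitude identities, cross-checked against CTMC path statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from plate_smfret import mixtures as mx
from plate_smfret import simulate as sim
from plate_smfret.exceptions import ConfigurationError


# ------------------------------------------------------------- histograms
def test_histogram_single_value_one_bin():
    h = mx.build_histogram(np.array([0.5]))
    assert h.counts.sum() == 1
    assert (h.counts > 0).sum() == 1


def test_histogram_conserves_counts():
    rng = np.random.default_rng(0)
    values = rng.uniform(-0.3, 1.3, 1000)
    h = mx.build_histogram(values)
    in_range = ((values >= -0.1) & (values <= 1.1)).sum()
    # np.histogram half-open bins: right edge inclusive only for last bin
    assert abs(h.counts.sum() - in_range) <= 1
    assert h.n_out_of_range == len(values) - h.counts.sum()


def test_histogram_uniform_values_pass_chi2():
    from scipy import stats
    rng = np.random.default_rng(1)
    values = rng.uniform(-0.1, 1.1, 20000)
    h = mx.build_histogram(values)
    expected = h.n_bursts / len(h.counts)
    chi2 = ((h.counts - expected) ** 2 / expected).sum()
    assert stats.chi2.sf(chi2, len(h.counts) - 1) > 0.001


def test_histogram_rejects_bad_edges():
    with pytest.raises(ConfigurationError):
        mx.build_histogram(np.array([0.5]), edges=[0.0, 0.5, 0.4])


# ------------------------------------------------------------- static fits
def test_static_mixture_recovers_two_populations():
    rng = np.random.default_rng(2)
    values = np.concatenate([rng.normal(0.15, 0.05, 1000),
                             rng.normal(0.80, 0.05, 1000)])
    fit = mx.fit_static_mixture(mx.build_histogram(values), 2)
    assert fit.success
    means = fit.components["mean"].to_numpy()
    assert means[0] == pytest.approx(0.15, abs=0.01)
    assert means[1] == pytest.approx(0.80, abs=0.01)
    assert fit.components["amplitude"].sum() == pytest.approx(1.0)
    assert abs(fit.components["amplitude"].iloc[0] - 0.5) < 0.05


def test_static_single_component_amplitude_one():
    rng = np.random.default_rng(3)
    values = rng.normal(0.4, 0.06, 2000)
    fit = mx.fit_static_mixture(mx.build_histogram(values), 1)
    assert fit.components["amplitude"].iloc[0] == pytest.approx(1.0)
    assert fit.components["mean"].iloc[0] == pytest.approx(0.4, abs=0.01)


def test_static_components_ordered_by_mean():
    rng = np.random.default_rng(4)
    values = np.concatenate([rng.normal(0.7, 0.05, 800),
                             rng.normal(0.2, 0.05, 1200)])
    fit = mx.fit_static_mixture(mx.build_histogram(values), 2,
                                init_means=[0.8, 0.1])  # reversed init
    assert fit.components["mean"].is_monotonic_increasing


# --------------------------------------------------- dynamic amplitudes
@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.floats(0.01, 50.0), st.floats(0.01, 50.0), st.floats(0.05, 10.0))
def test_dynamic_amplitudes_sum_to_one(k_open, k_close, t):
    a_o, a_c, a_b = mx.dynamic_amplitudes(k_open, k_close, t)
    assert a_o >= 0 and a_c >= 0
    assert a_o + a_c + a_b == pytest.approx(1.0, abs=1e-12)


def test_occupancy_density_normalises_with_deltas():
    """Continuous density + no-switch end weights must integrate to 1."""
    for ko, kc, t in [(0.3, 0.3, 1.0), (1.5, 1.0, 1.0), (3.0, 0.5, 2.0)]:
        f = np.linspace(1e-6, 1 - 1e-6, 20001)
        cont = np.trapezoid(mx.occupancy_fraction_density(f, ko, kc, t), f)
        a_o, a_c, a_b = mx.dynamic_amplitudes(ko, kc, t)
        assert cont == pytest.approx(a_b, rel=1e-3)
        assert cont + a_o + a_c == pytest.approx(1.0, rel=1e-3)


def test_bridge_moments_match_monte_carlo():
    """Conditional bridge moments must agree with direct Gillespie path
    sampling of the two-state process (the Monte-Carlo moment oracle)."""
    ko, kc, t = 1.5, 1.0, 1.0
    rng = np.random.default_rng(5)
    p_open = ko / (ko + kc)
    fracs = []
    for _ in range(20000):
        s = 0 if rng.random() < p_open else 1
        tt, f_open, switched = 0.0, 0.0, False
        while tt < t:
            rate = (kc, ko)[s]
            dwell = rng.exponential(1.0 / rate)
            t1 = min(tt + dwell, t)
            if s == 0:
                f_open += t1 - tt
            if t1 < t:
                s = 1 - s
                switched = True
            tt = t1
        if switched:
            fracs.append(f_open / t)
    fracs = np.asarray(fracs)
    mean_b, var_b = mx.bridge_moments(ko, kc, t)
    assert fracs.mean() == pytest.approx(mean_b, abs=0.01)
    assert fracs.var() == pytest.approx(var_b, rel=0.05)


# ------------------------------------------------------------- dynamic fits
def test_dynamic_fit_recovers_rates(dynamic_well):
    """k_open=1.5/ms, k_close=1.0/ms at T=1 ms, ~3000 bursts: both rates
    recovered within 20%."""
    _, _, _, table = dynamic_well
    h = mx.build_histogram(table)
    fit = mx.fit_dynamic_three_gaussian(h, table["duration"].mean(),
                                        static_means_init=(0.15, 0.80))
    assert fit.k_open == pytest.approx(1.5, rel=0.20)
    assert fit.k_close == pytest.approx(1.0, rel=0.20)
    assert fit.components["amplitude"].sum() == pytest.approx(1.0, abs=1e-9)
    assert not fit.rates_upper_bound


@pytest.mark.parametrize("bridge", ["moments", "free"])
def test_dynamic_fit_gaussian_bridge_variants_run(dynamic_well, bridge):
    _, _, _, table = dynamic_well
    h = mx.build_histogram(table)
    fit = mx.fit_dynamic_three_gaussian(h, table["duration"].mean(),
                                        static_means_init=(0.15, 0.80),
                                        bridge=bridge)
    assert fit.success
    # Gaussian-bridge approximations are biased low but must stay in order
    assert 0.3 < fit.k_open < 2.0
    assert fit.components["amplitude"].sum() == pytest.approx(1.0, abs=1e-9)


def test_dynamic_fit_duration_averaging_fixes_exponential_transits():
    """With exponentially distributed transits the single-mean-duration
    model biases rates low; averaging over the empirical duration deciles
    recovers them."""
    cfg = sim.SimulationConfig(seed=13, duration=600.0, burst_rate=5.0,
                               transit_mean=1e-3,
                               states=((0.15, 0.5), (0.80, 0.5)),
                               k_open=1500.0, k_close=1000.0,
                               background_rates=(300.0, 300.0, 300.0))
    from plate_smfret import bursts as bp
    stream, _ = sim.simulate_two_state_bursts(cfg)
    table = bp.find_bursts(stream,
                           background_rates=bp.estimate_background(stream))
    h = mx.build_histogram(table)
    fit = mx.fit_dynamic_three_gaussian(
        h, table["duration"].mean(), static_means_init=(0.15, 0.80),
        durations_s=table["duration"].to_numpy())
    assert fit.k_open == pytest.approx(1.5, rel=0.15)
    assert fit.k_close == pytest.approx(1.0, rel=0.15)


def test_dynamic_static_limit_flags_upper_bound():
    """Without dynamics the bridge amplitude vanishes and the fit reduces
    to the static two-Gaussian description with rates as upper bounds."""
    rng = np.random.default_rng(6)
    values = np.concatenate([rng.normal(0.15, 0.05, 1500),
                             rng.normal(0.80, 0.05, 1500)])
    h = mx.build_histogram(values)
    fit = mx.fit_dynamic_three_gaussian(h, 1e-3,
                                        static_means_init=(0.15, 0.80))
    a = dict(zip(fit.components["label"], fit.components["amplitude"]))
    assert a["bridge"] < 0.05
    static = mx.fit_static_mixture(h, 2)
    means_d = sorted([a_ for l_, a_ in zip(fit.components["label"],
                                           fit.components["mean"])
                      if l_ != "bridge"])
    means_s = sorted(static.components["mean"])
    np.testing.assert_allclose(means_d, means_s, atol=0.02)


def test_dynamic_fit_rejects_bad_inputs(dynamic_well):
    _, _, _, table = dynamic_well
    h = mx.build_histogram(table)
    with pytest.raises(ConfigurationError):
        mx.fit_dynamic_three_gaussian(h, 0.0)
    with pytest.raises(ConfigurationError):
        mx.fit_dynamic_three_gaussian(h, 1e-3, bridge="nope")


# ------------------------------------------------ fraction above threshold
def test_fraction_above_threshold_binomial_sd():
    values = np.concatenate([np.full(400, 0.8), np.full(600, 0.1)])
    f, sd = mx.fraction_above_threshold(values, 0.4)
    assert f == pytest.approx(0.4)
    assert sd == pytest.approx(np.sqrt(0.4 * 0.6 / 1000), rel=1e-6)


def test_fraction_above_threshold_edges():
    values = np.full(100, 0.9)
    f, sd = mx.fraction_above_threshold(values, 0.4)
    assert (f, sd) == (1.0, 0.0)
    h = mx.build_histogram(values)
    assert mx.fraction_above_threshold(h, 2.0) == (0.0, 0.0)


def test_fraction_above_threshold_histogram_consistent():
    rng = np.random.default_rng(7)
    values = rng.uniform(0.0, 1.0, 5000)
    f_v, _ = mx.fraction_above_threshold(values, 0.4)
    f_h, _ = mx.fraction_above_threshold(mx.build_histogram(values), 0.4)
    assert f_h == pytest.approx(f_v, abs=0.01)
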