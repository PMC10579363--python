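"""LEM unfolding, chain-dimension analysis, speciation, six-state
competition with model selection, and dose-response fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from plate_smfret import equilibrium as eq
from plate_smfret import simulate as sim
from plate_smfret.exceptions import ConfigurationError


# ----------------------------------------------------------------- LEM
def test_lem_midpoint_and_limits():
    assert eq.lem_fraction_unfolded(3.16, 3.16, 8.5) == pytest.approx(0.5)
    assert eq.lem_fraction_unfolded(1e6, 3.16, 8.5) == pytest.approx(1.0)
    assert eq.lem_fraction_unfolded(0.0, 3.16, 8.5) < 0.01


def test_lem_scalar_oracle():
    """Independent evaluation of the closed form at c=2 M."""
    c_half, m, temp, c = 3.16, 8.5, 298.15, 2.0
    expected = 1.0 / (1.0 + np.exp(m * (c_half - c) / (8.314462618e-3 * temp)))
    assert eq.lem_fraction_unfolded(c, c_half, m, temp) == \
        pytest.approx(expected, rel=1e-12)


def _lem_table(noise, seed, n=96):
    rng = np.random.default_rng(seed)
    c = np.linspace(0.0, 6.0, n)
    f = eq.lem_fraction_unfolded(c, 3.16, 8.5)
    tab = pd.DataFrame({"denaturant_M": c,
                        "f_unfolded": np.clip(
                            f + noise * rng.standard_normal(n), 0, 1)})
    if noise > 0:
        tab["sd_f_unfolded"] = noise
    return tab


def test_lem_fit_noiseless_exact():
    fit = eq.fit_lem(_lem_table(0.0, 0))
    assert fit.c_half == pytest.approx(3.16, rel=1e-6)
    assert fit.m_value == pytest.approx(8.5, rel=1e-6)
    assert fit.dg_h2o == pytest.approx(fit.m_value * fit.c_half, rel=1e-10)


def test_lem_fit_recovery_with_noise():
    fit = eq.fit_lem(_lem_table(0.02, 1))
    assert fit.c_half == pytest.approx(3.16, rel=0.03)
    assert fit.m_value == pytest.approx(8.5, rel=0.03)
    assert fit.transition_in_range


def test_lem_subsampling_inflates_parameter_spread():
    """Dropping from 96 to 12 conditions must at least double the spread of
    the fitted midpoint and m-value over noise realisations."""
    sds = {}
    for n in (96, 12):
        c_halves, ms = [], []
        for seed in range(24):
            fit = eq.fit_lem(_lem_table(0.02, 100 + seed, n=n))
            c_halves.append(fit.c_half)
            ms.append(fit.m_value)
        sds[n] = (np.std(c_halves), np.std(ms))
    assert sds[12][0] >= 2.0 * sds[96][0]
    assert sds[12][1] >= 2.0 * sds[96][1]


def test_lem_flags_out_of_range_transition():
    tab = _lem_table(0.0, 0)
    tab = tab[tab["denaturant_M"] > 4.0].reset_index(drop=True)
    with pytest.warns(UserWarning):
        fit = eq.fit_lem(tab)
    assert not fit.transition_in_range


def test_lem_row_order_invariance():
    tab = _lem_table(0.02, 2)
    fit1 = eq.fit_lem(tab)
    fit2 = eq.fit_lem(tab.sample(frac=1.0, random_state=0)
                      .reset_index(drop=True))
    assert fit1.c_half == pytest.approx(fit2.c_half, rel=1e-6)


# ------------------------------------------------------- chain dimensions
def test_rg_inversion_round_trip():
    r0 = 5.4
    e = eq.mean_fret_gaussian_chain(2.38, r0)
    assert eq.fret_efficiency_to_rg(e, r0) == pytest.approx(2.38, abs=1e-4)


def test_mean_fret_monotone_in_rg():
    r0 = 5.4
    rgs = np.linspace(1.0, 6.0, 20)
    es = [eq.mean_fret_gaussian_chain(r, r0) for r in rgs]
    assert np.all(np.diff(es) < 0)


def test_gaussian_chain_integral_matches_monte_carlo():
    """Quadrature of the chain-averaged efficiency vs direct sampling of
    the end-to-end distribution (10^6 draws)."""
    rng = np.random.default_rng(8)
    rg, r0 = 2.38, 5.4
    sigma = np.sqrt(6.0 * rg ** 2 / 3.0)
    xyz = rng.normal(0.0, np.sqrt(6.0 * rg ** 2 / 3.0), size=(10 ** 6, 3))
    r = np.linalg.norm(xyz, axis=1)
    e_mc = float(np.mean(1.0 / (1.0 + (r / r0) ** 6)))
    e_quad = eq.mean_fret_gaussian_chain(rg, r0)
    assert e_quad == pytest.approx(e_mc, abs=1e-3)


def test_rg_inversion_rejects_invalid_e():
    with pytest.raises(ConfigurationError):
        eq.fret_efficiency_to_rg(1.2, 5.4)


def test_coil_globule_round_trip():
    truth = eq.ChainCompactionFit(rg_theta=2.38, eps0=2.0, eps1=-0.6)
    a = np.linspace(0.5, 3.0, 12)
    fit = eq.fit_coil_globule(pd.DataFrame({"activity": a,
                                            "rg_nm": truth.rg(a)}))
    assert fit.rg_theta == pytest.approx(2.38, abs=max(0.05,
                                                       2 * fit.rg_theta_stderr))
    expected_a = (eq.theta_interaction_energy(100, 0.2) - 2.0) / -0.6
    assert fit.transition_activity == pytest.approx(expected_a, abs=0.05)
    assert fit.compaction(fit.transition_activity) == pytest.approx(1.0,
                                                                    abs=0.01)


def test_coil_globule_flat_profile_flagged():
    a = np.linspace(0.5, 3.0, 8)
    with pytest.warns(UserWarning):
        fit = eq.fit_coil_globule(pd.DataFrame({"activity": a,
                                                "rg_nm": np.full(8, 2.5)}))
    assert not fit.transition_defined


# ------------------------------------------------------------- speciation
def test_speciation_limits():
    f = eq.speciation_fractions(0.0, 278e-12, 480e-9, 2.12, 1.19)
    assert f == (1.0, 0.0, 0.0)
    f = eq.speciation_fractions(278e-12, 278e-12, 1.0, 2.12, 1.19)
    assert f[0] == pytest.approx(0.5, abs=1e-6)
    assert f[1] == pytest.approx(0.5, abs=1e-6)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.floats(1e-12, 1e-3), st.floats(1e-12, 1e-3), st.floats(0.2, 6.0),
       st.floats(0.2, 6.0), st.floats(0.0, 1e-3))
def test_speciation_fractions_normalised(c1, c2, m, n, s):
    f = eq.speciation_fractions(s, c1, c2, m, n)
    assert all(fi >= 0 for fi in f)
    assert sum(f) == pytest.approx(1.0, abs=1e-9)


def test_fit_speciation_noiseless_exact():
    params = dict(c_half=278e-12, c_star_half=480e-9, hill_m=2.12,
                  hill_n=1.19)
    conc = np.logspace(-12, -5.4, 24)
    tab = sim.simulate_titration_table("speciation", params, conc, None)
    fit = eq.fit_speciation(tab)
    assert fit.c_half == pytest.approx(278e-12, rel=1e-4)
    assert fit.c_star_half == pytest.approx(480e-9, rel=1e-4)
    assert fit.hill_m == pytest.approx(2.12, rel=1e-4)
    assert fit.hill_n == pytest.approx(1.19, rel=1e-4)


def test_fit_speciation_with_counting_noise():
    params = dict(c_half=278e-12, c_star_half=480e-9, hill_m=2.12,
                  hill_n=1.19)
    conc = np.logspace(-12, -5.4, 24)
    tab = sim.simulate_titration_table("speciation", params, conc, 2000,
                                       seed=9)
    fit = eq.fit_speciation(tab)
    assert fit.c_half == pytest.approx(278e-12, rel=0.15)
    assert fit.c_star_half == pytest.approx(480e-9, rel=0.15)
    assert fit.hill_m == pytest.approx(2.12, rel=0.15)
    assert fit.hill_n == pytest.approx(1.19, rel=0.15)


# ------------------------------------------------------------- six-state
def _full_model(observable=("TSm", "TRqSm")):
    return eq.CompetitionModel(
        c_s_half=278e-12, c_s_star_half=480e-9, hill_m=2.12, hill_n=1.19,
        c_rp_half=425e-9, c_rq_half=237e-9, c_rr_half=278e-9,
        hill_p=4.9, hill_q=1.9, hill_r=3.0, observable=observable)


def test_six_state_reduces_to_speciation_at_zero_reca():
    model = _full_model()
    s = np.logspace(-12, -5, 20)
    fr = model.fractions(s, np.zeros_like(s))
    expected = np.stack(eq.speciation_fractions(
        s, model.c_s_half, model.c_s_star_half, model.hill_m, model.hill_n))
    np.testing.assert_allclose(fr[:3], expected, atol=1e-12)
    np.testing.assert_allclose(fr[3:], 0.0, atol=1e-12)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.floats(0, 1e-5), st.floats(0, 1e-5))
def test_six_state_fractions_normalised(s, r):
    fr = _full_model().fractions(s, r)
    assert np.all(fr >= 0)
    assert fr.sum() == pytest.approx(1.0, abs=1e-9)


def test_six_state_no_cooperativity_factorises():
    """With alpha = beta = 1 and equal RecA exponents, RecA binding is
    independent of SSB occupancy: the RecA-bound/unbound ratio is the same
    whatever the SSB state."""
    k_r = (300e-9) ** 2.0
    c = k_r ** (1 / 2.0)
    model = eq.CompetitionModel(
        c_s_half=1e-9, c_s_star_half=1e-7, hill_m=2.0, hill_n=1.0,
        c_rp_half=c, c_rq_half=c, c_rr_half=c,
        hill_p=2.0, hill_q=2.0, hill_r=2.0)
    assert model.alpha_coop == pytest.approx(1.0)
    assert model.beta_coop == pytest.approx(1.0)
    for s_conc, r_conc in [(1e-9, 2e-7), (5e-8, 5e-7), (1e-6, 1e-7)]:
        fr = dict(zip(eq.SIX_STATES, model.fractions(s_conc, r_conc)))
        ratio_t = fr["TRp"] / fr["T"]
        ratio_sm = fr["TRqSm"] / fr["TSm"]
        ratio_smn = fr["TRrSmn"] / fr["TSmn"]
        assert ratio_sm == pytest.approx(ratio_t, rel=1e-9)
        assert ratio_smn == pytest.approx(ratio_t, rel=1e-9)


def test_enumerate_configurations_counts():
    configs = eq.enumerate_configurations()
    assert len(configs) == 36
    assert all("TSm" in obs for _, obs in configs)
    ids = {(s, o) for s, o in configs}
    assert len(ids) == len(configs)


def _competition_table(seed, n_bursts=2000, observable=("TSm", "TRqSm")):
    gen = _full_model(observable)
    s_grid = np.logspace(-11, -6, 8)
    r_grid = np.logspace(-8.5, -5.5, 8)
    grid = np.array([(s, r) for s in s_grid for r in r_grid])
    f = gen.observable_fraction(grid[:, 0], grid[:, 1])
    rng = np.random.default_rng(seed)
    counts = rng.binomial(n_bursts, f)
    fo = counts / n_bursts
    sd = np.maximum(np.sqrt(fo * (1 - fo) / n_bursts), 1.0 / (2 * n_bursts))
    return pd.DataFrame({"SSB_M": grid[:, 0], "RecA_M": grid[:, 1],
                         "f_obs": fo, "sd_f_obs": sd})


def test_competition_selection_recovers_generating_configuration():
    spec = eq.SpeciationFit(c_half=278e-12, c_star_half=480e-9,
                            hill_m=2.12, hill_n=1.19)
    best, ranking = eq.fit_competition_model(_competition_table(10), spec)
    assert set(best.states) == set(eq.SIX_STATES)
    assert set(best.observable) == {"TSm", "TRqSm"}
    assert ranking.attrs["n_configurations"] == 36
    assert best.chi2_reduced == ranking["chi2_reduced"].min()
    assert best.c_rp_half == pytest.approx(425e-9, rel=0.35)
    assert best.c_rq_half == pytest.approx(237e-9, rel=0.35)


def test_competition_null_model_without_reca_dependence():
    """Data generated without any RecA effect must select a configuration
    with no RecA-bound states."""
    gen = eq.CompetitionModel(
        c_s_half=278e-12, c_s_star_half=480e-9, hill_m=2.12, hill_n=1.19,
        states=("T", "TSm", "TSmn"), observable=("TSm",))
    s_grid = np.logspace(-11, -6, 8)
    r_grid = np.logspace(-8.5, -5.5, 8)
    grid = np.array([(s, r) for s in s_grid for r in r_grid])
    f = gen.observable_fraction(grid[:, 0], grid[:, 1])
    rng = np.random.default_rng(11)
    fo = rng.binomial(2000, f) / 2000
    sd = np.maximum(np.sqrt(fo * (1 - fo) / 2000), 1.0 / 4000)
    tab = pd.DataFrame({"SSB_M": grid[:, 0], "RecA_M": grid[:, 1],
                        "f_obs": fo, "sd_f_obs": sd})
    spec = eq.SpeciationFit(c_half=278e-12, c_star_half=480e-9,
                            hill_m=2.12, hill_n=1.19)
    best, ranking = eq.fit_competition_model(tab, spec)
    # with no RecA dependence the mixed states add no explanatory power;
    # chi2_r tie-break must prefer the scheme with fewest free parameters
    top = ranking.iloc[0]
    close = ranking[ranking["chi2_reduced"] <
                    top["chi2_reduced"] * 1.05]
    assert close["n_free_params"].min() == top["n_free_params"]


def test_competition_row_order_invariance():
    spec = eq.SpeciationFit(c_half=278e-12, c_star_half=480e-9,
                            hill_m=2.12, hill_n=1.19)
    tab = _competition_table(12)
    best1, _ = eq.fit_competition_model(tab, spec)
    best2, _ = eq.fit_competition_model(
        tab.sample(frac=1.0, random_state=1).reset_index(drop=True), spec)
    assert best1.configuration_id == best2.configuration_id
    assert best1.chi2_reduced == pytest.approx(best2.chi2_reduced, rel=1e-6)


def test_parametric_bootstrap_ci_covers_truth():
    """Seeded parametric bootstrap of the LEM fit: the 68% interval covers
    the generating midpoint and roughly matches the covariance stderr."""
    params = dict(c_half=3.16, m_value=8.5)
    tab = sim.simulate_titration_table("lem", params,
                                       np.linspace(0, 6, 48), 1000, seed=15)
    fit = eq.fit_lem(tab)
    pred = np.stack([1 - eq.lem_fraction_unfolded(
        tab["denaturant_M"].to_numpy(), fit.c_half, fit.m_value),
        eq.lem_fraction_unfolded(
        tab["denaturant_M"].to_numpy(), fit.c_half, fit.m_value)], axis=1)
    ci = eq.parametric_bootstrap_ci(tab, eq.fit_lem, pred,
                                    ["c_half", "m_value"], n_boot=100,
                                    seed=16)
    lo, hi = ci["c_half"]
    assert lo < 3.16 < hi
    assert (hi - lo) / 2 == pytest.approx(fit.c_half_stderr, rel=0.6)
    # deterministic given the seed
    ci2 = eq.parametric_bootstrap_ci(tab, eq.fit_lem, pred,
                                     ["c_half", "m_value"], n_boot=100,
                                     seed=16)
    assert ci == ci2


# ------------------------------------------------------------ dose-response
def _dose_table(ec50=337e-6, h=1.5, noise=0.03, seed=13, n=12,
                c_max=3e-3):
    rng = np.random.default_rng(seed)
    c = np.logspace(np.log10(1e-6), np.log10(c_max), n)
    f = 0.2 + 0.6 * c ** h / (ec50 ** h + c ** h)
    return pd.DataFrame({"drug_M": c,
                         "f_folded": f * (1 + noise * rng.standard_normal(n)),
                         "sd_f_folded": np.full(n, 0.02)})


def test_dose_response_midpoint_identity():
    fit = eq.fit_dose_response(_dose_table(noise=0.0))
    mid = fit.predict(fit.ec50)
    assert mid == pytest.approx(0.5 * (fit.f_min + fit.f_max), rel=1e-6)


def test_dose_response_recovery():
    fit = eq.fit_dose_response(_dose_table())
    assert fit.ec50 == pytest.approx(337e-6, rel=0.15)
    assert fit.hill_slope == pytest.approx(1.5, rel=0.35)
    assert fit.excluded_points == []


def test_dose_response_exclusion_rule():
    tab = _dose_table(ec50=80e-6, seed=14)
    fit = eq.fit_dose_response(tab, exclusion_max=500e-6)
    n_over = int((tab["drug_M"] > 500e-6).sum())
    assert len(fit.excluded_points) == n_over
    assert all(c > 500e-6 for c, _ in fit.excluded_points)
    assert fit.ec50 == pytest.approx(80e-6, rel=0.20)


def test_dose_response_no_response_flagged():
    tab = _dose_table(noise=0.0)
    tab["f_folded"] = 0.5
    with pytest.warns(UserWarning):
        fit = eq.fit_dose_response(tab)
    assert fit.no_response
    assert np.isinf(fit.ec50)


def test_dose_response_needs_enough_points():
    with pytest.raises(ConfigurationError):
        eq.fit_dose_response(_dose_table(n=5))
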