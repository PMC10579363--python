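"""Equilibrium models fitted to per-well fractions.

Covers the thermodynamic and binding analyses that run on top of per-well
FRET populations:

* two-state denaturant unfolding by the linear extrapolation method (LEM),
  ``ΔG(c) = m·(c_1/2 − c)`` and ``ΔG_H2O = m·c_1/2``;
* unfolded-chain dimensions: numerically inverting the chain-averaged FRET
  efficiency for the radius of gyration, and a mean-field (Sanchez-type)
  coil–globule analysis with interaction energy linear in denaturant
  activity;
* Hill-type speciation of a two-mode ssDNA binder (SSB occluding 65 or 35
  nucleotides);
* competitive six-state SSB/RecA binding described by a partition function
  over states ``T, TS_m, TS_{m+n}, TR_p, TR_qS_m, TR_rS_{m+n}`` with
  model selection over state/observable configurations by reduced χ²;
* Hill dose–response curves yielding EC50 values, with an explicit
  concentration exclusion rule.

Statistical weights use half-occupancy concentrations: a state bound by i
ligands at dissociation constant K enters as ``(c/c_{1/2})^i`` with
``c_{1/2} = K^(1/i)``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .exceptions import ConfigurationError, FitError

__all__ = [
    "R_GAS_KJ",
    "lem_fraction_unfolded",
    "UnfoldingFit",
    "fit_lem",
    "mean_fret_gaussian_chain",
    "fret_efficiency_to_rg",
    "sanchez_expansion_factor",
    "ChainCompactionFit",
    "fit_coil_globule",
    "speciation_fractions",
    "SpeciationFit",
    "fit_speciation",
    "SIX_STATES",
    "six_state_fractions",
    "parametric_bootstrap_ci",
    "CompetitionModel",
    "enumerate_configurations",
    "fit_competition_model",
    "DoseResponseFit",
    "fit_dose_response",
]

#: gas constant in kJ mol^-1 K^-1
R_GAS_KJ = 8.314462618e-3


# ----------------------------------------------------------------------
# LEM unfolding
def lem_fraction_unfolded(c, c_half: float, m_value: float,
                          temperature: float = 298.15):
    """Fraction unfolded at denaturant concentration ``c`` (M).

    ``f_U = 1/(1 + exp(m·(c_1/2 − c)/(R·T)))`` with m in kJ·mol⁻¹·M⁻¹.
    """
    if temperature <= 0:
        raise ConfigurationError("temperature must be positive")
    c = np.asarray(c, float)
    out = 1.0 / (1.0 + np.exp(m_value * (c_half - c) / (R_GAS_KJ * temperature)))
    return float(out) if out.ndim == 0 else out


@dataclass
class UnfoldingFit:
    """LEM fit result; ``dg_h2o = m_value·c_half`` by construction."""

    c_half: float                       # M
    m_value: float                      # kJ mol^-1 M^-1
    temperature: float
    c_half_stderr: float = np.nan
    m_value_stderr: float = np.nan
    success: bool = True
    transition_in_range: bool = True
    fractions: pd.DataFrame | None = None

    @property
    def dg_h2o(self) -> float:
        """Zero-denaturant stability in kJ/mol."""
        return self.m_value * self.c_half

    @property
    def dg_h2o_stderr(self) -> float:
        return float(np.hypot(self.c_half * self.m_value_stderr,
                              self.m_value * self.c_half_stderr))


def fit_lem(fractions: pd.DataFrame, temperature: float = 298.15,
            concentration_column: str = "denaturant_M",
            fraction_column: str = "f_unfolded") -> UnfoldingFit:
    """Weighted least-squares LEM fit of an unfolding curve.

    ``fractions`` needs the concentration and fraction columns and may carry
    ``sd_<fraction_column>`` weights.  When an ``n_bursts`` column is
    present (counting statistics), the fit is iteratively reweighted with
    model-based binomial SDs — weights estimated from the observed
    fractions are correlated with their own noise and bias the slope.  A
    fit whose midpoint falls outside the probed range is flagged via
    ``transition_in_range=False``.
    """
    c = fractions[concentration_column].to_numpy(float)
    f = fractions[fraction_column].to_numpy(float)
    if c.size < 5:
        raise ConfigurationError("need at least 5 conditions")
    sd_col = "sd_" + fraction_column
    sigma = None
    if sd_col in fractions.columns:
        s = fractions[sd_col].to_numpy(float)
        if np.all(np.isfinite(s)) and np.all(s > 0):
            sigma = s
    n_counts = None
    if "n_bursts" in fractions.columns:
        n_arr = fractions["n_bursts"].to_numpy(float)
        if np.all(np.isfinite(n_arr)) and np.all(n_arr > 0):
            n_counts = n_arr

    def model(cc, c_half, m_value):
        return lem_fraction_unfolded(cc, c_half, m_value, temperature)

    c_init = float(np.interp(0.5, f, c)) if f[-1] > f[0] else float(np.median(c))
    popt, pcov = optimize.curve_fit(
        model, c, f, p0=[np.clip(c_init, c.min(), c.max()), 5.0],
        sigma=sigma, absolute_sigma=sigma is not None,
        bounds=([1e-6, 1e-3], [100.0, 1e3]), maxfev=10000)
    if n_counts is not None:
        for _ in range(2):
            fm = model(c, *popt)
            sigma = np.sqrt(np.maximum(fm * (1 - fm), 0.25 / n_counts)
                            / n_counts)
            popt, pcov = optimize.curve_fit(
                model, c, f, p0=popt, sigma=sigma, absolute_sigma=True,
                bounds=([1e-6, 1e-3], [100.0, 1e3]), maxfev=10000)
    perr = np.sqrt(np.diag(pcov))
    in_range = bool(c.min() <= popt[0] <= c.max())
    if not in_range:
        warnings.warn("fitted unfolding midpoint lies outside the probed range")
    return UnfoldingFit(c_half=float(popt[0]), m_value=float(popt[1]),
                        temperature=temperature,
                        c_half_stderr=float(perr[0]),
                        m_value_stderr=float(perr[1]),
                        transition_in_range=in_range,
                        fractions=fractions.copy())


# ----------------------------------------------------------------------
# unfolded-chain dimensions
def _gaussian_chain_pdf(r, rg):
    # end-to-end distance density of an ideal chain with <r^2> = 6 Rg^2
    msq = 6.0 * rg ** 2
    return (4.0 * np.pi * r ** 2 *
            (3.0 / (2.0 * np.pi * msq)) ** 1.5 *
            np.exp(-3.0 * r ** 2 / (2.0 * msq)))


def mean_fret_gaussian_chain(rg: float, r0: float, chain_pdf=None,
                             n_grid: int = 2000) -> float:
    """Chain-averaged FRET efficiency ``⟨E⟩ = ∫ P(r)·(1+(r/R0)⁶)⁻¹ dr``.

    ``chain_pdf(r, rg)`` defaults to the Gaussian-chain end-to-end density.
    """
    pdf = chain_pdf or _gaussian_chain_pdf
    r_max = 6.0 * np.sqrt(6.0) * rg
    r = np.linspace(1e-6, r_max, n_grid)
    p = pdf(r, rg)
    e = 1.0 / (1.0 + (r / r0) ** 6)
    norm = np.trapezoid(p, r)
    return float(np.trapezoid(p * e, r) / norm)


def fret_efficiency_to_rg(e_mean: float, r0: float, chain_pdf=None,
                          tol: float = 1e-6) -> float:
    """Invert the chain-averaged transfer efficiency for Rg (nm).

    Bisection on the monotone map Rg → ⟨E⟩ until ``|ΔE| < tol``.
    """
    if not 0.0 < e_mean < 1.0:
        raise ConfigurationError("mean efficiency must lie strictly in (0, 1)")
    lo, hi = 1e-3 * r0, 20.0 * r0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        e_mid = mean_fret_gaussian_chain(mid, r0, chain_pdf)
        if abs(e_mid - e_mean) < tol:
            return mid
        if e_mid > e_mean:     # chain too compact -> increase Rg
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def sanchez_expansion_factor(eps, n_monomers: int = 100,
                             phi_theta: float = 0.2):
    """Chain expansion factor α = Rg/Rg_Θ of the mean-field collapse model.

    The free energy per chain (units of kT) combines the elastic cost of
    swelling/compression with lattice-fluid mixing and a two-body attraction
    of dimensionless strength ``eps``:

        βF(α) = (3/2)·(α² − 1 − 2·ln α)
              + N·[ ((1−φ)/φ)·ln(1−φ) + 1 − eps·φ/2 ],   φ = φ_Θ/α³.

    The minimiser α*(eps) decreases monotonically with attraction; α* = 1
    defines the Θ point (eps_Θ ≈ 1 for small φ_Θ).
    """
    eps_arr = np.atleast_1d(np.asarray(eps, float))

    def free_energy(alpha, e):
        phi = np.clip(phi_theta / alpha ** 3, 1e-12, 0.999)
        elastic = 1.5 * (alpha ** 2 - 1.0 - 2.0 * np.log(alpha))
        mixing = ((1.0 - phi) / phi) * np.log1p(-phi) + 1.0
        return elastic + n_monomers * (mixing - 0.5 * e * phi)

    out = np.empty_like(eps_arr)
    for i, e in enumerate(eps_arr):
        res = optimize.minimize_scalar(free_energy, bounds=(0.2, 4.0),
                                       args=(e,), method="bounded",
                                       options={"xatol": 1e-8})
        out[i] = res.x
    return float(out[0]) if np.isscalar(eps) or np.ndim(eps) == 0 else out


def theta_interaction_energy(n_monomers: int = 100,
                             phi_theta: float = 0.2) -> float:
    """Attraction strength eps_Θ at which the chain is ideal (α* = 1)."""
    def g(e):
        return sanchez_expansion_factor(e, n_monomers, phi_theta) - 1.0
    return float(optimize.brentq(g, 0.0, 2.5, xtol=1e-8))


@dataclass
class ChainCompactionFit:
    """Coil–globule fit: Rg(a) = α*(eps0 + eps1·a)·Rg_Θ."""

    rg_theta: float                     # nm
    eps0: float
    eps1: float
    rg_theta_stderr: float = np.nan
    nu: float = 0.5
    n_monomers: int = 100
    phi_theta: float = 0.2
    transition_activity: float = np.nan  # activity where α crosses 1
    transition_defined: bool = True
    success: bool = True

    def compaction(self, activity):
        """α_c = Rg/Rg_Θ at the given denaturant activity."""
        return sanchez_expansion_factor(self.eps0 + self.eps1 *
                                        np.asarray(activity, float),
                                        self.n_monomers, self.phi_theta)

    def rg(self, activity):
        return self.rg_theta * self.compaction(activity)


def fit_coil_globule(data: pd.DataFrame, nu: float = 0.5,
                     n_monomers: int = 100, phi_theta: float = 0.2,
                     activity_column: str = "activity",
                     rg_column: str = "rg_nm") -> ChainCompactionFit:
    """Fit the mean-field coil–globule model to unfolded-state Rg values.

    Interaction energy is linear in denaturant activity, ``eps(a) = eps0 +
    eps1·a`` (denaturant weakens intrachain attraction, eps1 < 0 typically
    ... the sign is free).  Reports the Θ-state radius of gyration (the α=1
    point) and the activity where the chain crosses the Θ condition.  A flat
    Rg(a) profile leaves the transition undefined (flagged, not an error).
    """
    a = data[activity_column].to_numpy(float)
    rg = data[rg_column].to_numpy(float)
    if a.size < 5:
        raise ConfigurationError("need at least 5 unfolded-state conditions")

    def model(aa, rg_theta, eps0, eps1):
        return rg_theta * sanchez_expansion_factor(
            eps0 + eps1 * aa, n_monomers, phi_theta)

    span = rg.max() - rg.min()
    # the free-energy minimiser makes the objective multimodal in
    # (eps0, eps1); a deterministic multistart grid avoids local optima
    sign = -1.0 if rg[-1] >= rg[0] else 1.0
    best = None
    for e0 in (0.5, 1.0, 1.5, 2.0, 2.5):
        for e1 in (0.1, 0.3, 0.6, 1.0, 1.5):
            try:
                popt_i, pcov_i = optimize.curve_fit(
                    model, a, rg, p0=[float(np.mean(rg)), e0, sign * e1],
                    bounds=([1e-3, -10.0, -10.0], [1e3, 10.0, 10.0]),
                    maxfev=20000)
            except RuntimeError:
                continue
            ssr = float(np.sum((model(a, *popt_i) - rg) ** 2))
            if best is None or ssr < best[0]:
                best = (ssr, popt_i, pcov_i)
    if best is None:
        raise FitError("coil-globule fit did not converge from any start")
    _, popt, pcov = best
    perr = np.sqrt(np.diag(pcov))
    eps_theta = theta_interaction_energy(n_monomers, phi_theta)
    transition_defined = abs(popt[2]) > 1e-8 and span > 1e-9
    a_star = (eps_theta - popt[1]) / popt[2] if transition_defined else np.nan
    if not transition_defined:
        warnings.warn("Rg(a) is flat; coil-globule transition undefined")
    return ChainCompactionFit(
        rg_theta=float(popt[0]), eps0=float(popt[1]), eps1=float(popt[2]),
        rg_theta_stderr=float(perr[0]), nu=nu, n_monomers=n_monomers,
        phi_theta=phi_theta, transition_activity=float(a_star),
        transition_defined=bool(transition_defined))


# ----------------------------------------------------------------------
# SSB speciation (two binding modes)
def speciation_fractions(s_conc, c_half: float, c_star_half: float,
                         hill_m: float, hill_n: float):
    """State fractions (free, SSB_65, SSB_35) at SSB concentration ``s_conc``.

    Statistical weights ``1``, ``(S/c_1/2)^m`` and
    ``(S/c_1/2)^m·(S/c*_1/2)^n`` normalised to 1.
    """
    s = np.asarray(s_conc, float)
    if np.any(s < 0):
        raise ConfigurationError("concentration must be >= 0")
    with np.errstate(divide="ignore"):
        w65 = (s / c_half) ** hill_m
        w35 = w65 * (s / c_star_half) ** hill_n
    total = 1.0 + w65 + w35
    out = np.stack([np.ones_like(s) / total, w65 / total, w35 / total])
    if out.ndim == 1 or s.ndim == 0:
        return tuple(float(v) for v in out)
    return out


@dataclass
class SpeciationFit:
    """Two-mode Hill speciation fit (half-occupancy concentrations in M)."""

    c_half: float
    c_star_half: float
    hill_m: float
    hill_n: float
    c_half_stderr: float = np.nan
    c_star_half_stderr: float = np.nan
    hill_m_stderr: float = np.nan
    hill_n_stderr: float = np.nan
    chi2_reduced: float = np.nan
    success: bool = True

    def fractions(self, s_conc):
        return speciation_fractions(s_conc, self.c_half, self.c_star_half,
                                    self.hill_m, self.hill_n)


def fit_speciation(table: pd.DataFrame,
                   concentration_column: str = "SSB_M") -> SpeciationFit:
    """Simultaneous weighted fit of the three speciation curves.

    ``table`` needs columns ``f_free, f_65, f_35`` (+ optional ``sd_*``)
    versus SSB concentration.  Half-occupancy concentrations are fitted in
    log space (they span pM to µM); reported uncertainties are 68% CIs
    propagated back to linear concentration.
    """
    s = table[concentration_column].to_numpy(float)
    if s.size < 8:
        raise ConfigurationError("need at least 8 concentrations")
    fcols = ["f_free", "f_65", "f_35"]
    f_obs = table[fcols].to_numpy(float)
    sd = np.ones_like(f_obs)
    have_sd = all("sd_" + c in table.columns for c in fcols)
    if have_sd:
        sd_arr = table[["sd_" + c for c in fcols]].to_numpy(float)
        if np.all(np.isfinite(sd_arr)) and np.all(sd_arr > 0):
            sd = sd_arr

    pos = s[s > 0]
    p0 = [np.log10(np.median(pos)) - 1.0, np.log10(np.median(pos)) + 1.0,
          2.0, 1.0]

    def resid(theta):
        c1, c2 = 10.0 ** theta[0], 10.0 ** theta[1]
        model = np.stack(speciation_fractions(s, c1, c2, theta[2], theta[3]),
                         axis=-1)
        return ((model - f_obs) / sd).ravel()

    res = optimize.least_squares(
        resid, p0, bounds=([-14, -14, 0.1, 0.1], [0, 0, 10, 10]))
    dof = max(f_obs.size - 4, 1)
    chi2r = float(2 * res.cost / dof)
    jtj = res.jac.T @ res.jac
    try:
        cov = np.linalg.inv(jtj)
        if not have_sd:
            cov = cov * 2 * res.cost / dof
        perr = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        perr = np.full(4, np.nan)
    c1, c2 = 10.0 ** res.x[0], 10.0 ** res.x[1]
    ln10 = np.log(10.0)
    return SpeciationFit(
        c_half=float(c1), c_star_half=float(c2),
        hill_m=float(res.x[2]), hill_n=float(res.x[3]),
        c_half_stderr=float(ln10 * c1 * perr[0]),
        c_star_half_stderr=float(ln10 * c2 * perr[1]),
        hill_m_stderr=float(perr[2]), hill_n_stderr=float(perr[3]),
        chi2_reduced=chi2r, success=bool(res.success))


# ----------------------------------------------------------------------
# six-state competitive binding
SIX_STATES = ("T", "TSm", "TSmn", "TRp", "TRqSm", "TRrSmn")
_BASE_STATES = ("T", "TSm", "TSmn", "TRp")


@dataclass
class CompetitionModel:
    """Partition-function model of competitive SSB/RecA binding to ssDNA.

    All half-occupancy concentrations in M.  A state bound by i ligands at
    dissociation constant K enters the partition function with weight
    ``(c/c_{1/2})^i``, ``c_{1/2} = K^(1/i)``; the mixed-state constants
    relate to the bare RecA constant through the cooperativity factors
    ``alpha_coop`` and ``beta_coop`` (thermodynamic-square consistency is
    built into the weight construction).
    """

    c_s_half: float
    c_s_star_half: float
    hill_m: float
    hill_n: float
    c_rp_half: float = np.inf
    c_rq_half: float = np.inf
    c_rr_half: float = np.inf
    hill_p: float = 1.0
    hill_q: float = 1.0
    hill_r: float = 1.0
    states: tuple = SIX_STATES
    observable: tuple = ("TSm",)
    chi2_reduced: float = np.nan
    configuration_id: str = ""
    n_free_params: int = 0
    param_stderr: dict = field(default_factory=dict)

    def __post_init__(self):
        for c in (self.c_s_half, self.c_s_star_half, self.c_rp_half,
                  self.c_rq_half, self.c_rr_half):
            if not c > 0:
                raise ConfigurationError("half-occupancy concentrations must be > 0")
        if "TSm" not in self.states:
            raise ConfigurationError("state TSm must be part of the scheme")

    # equilibrium-constant view of the fitted half concentrations
    @property
    def k_r(self) -> float:
        return self.c_rp_half ** self.hill_p

    @property
    def alpha_coop(self) -> float:
        return self.c_rq_half ** self.hill_q / self.k_r

    @property
    def beta_coop(self) -> float:
        return self.c_rr_half ** self.hill_r / (self.alpha_coop * self.k_r)

    def weights(self, s_conc, r_conc) -> dict:
        s = np.asarray(s_conc, float)
        r = np.asarray(r_conc, float)
        with np.errstate(divide="ignore"):
            w_sm = (s / self.c_s_half) ** self.hill_m
            w_smn = w_sm * (s / self.c_s_star_half) ** self.hill_n
            w = {
                "T": np.ones_like(s * r),
                "TSm": w_sm,
                "TSmn": w_smn,
                "TRp": (r / self.c_rp_half) ** self.hill_p,
                "TRqSm": w_sm * (r / self.c_rq_half) ** self.hill_q,
                "TRrSmn": w_smn * (r / self.c_rr_half) ** self.hill_r,
            }
        return {k: (v if k in self.states else np.zeros_like(v))
                for k, v in w.items()}

    def fractions(self, s_conc, r_conc) -> np.ndarray:
        """Fractions of all six states (absent states are exactly 0).

        Returns shape ``(6,)`` for scalars, else ``(6, n)``.
        """
        w = self.weights(s_conc, r_conc)
        total = sum(w.values())
        return np.stack([w[k] / total for k in SIX_STATES])

    def observable_fraction(self, s_conc, r_conc):
        """Model prediction for f(E > threshold): sum over observable states."""
        fr = self.fractions(s_conc, r_conc)
        idx = [SIX_STATES.index(k) for k in self.observable]
        return fr[idx].sum(axis=0)


def six_state_fractions(s_conc, r_conc, model: CompetitionModel) -> np.ndarray:
    """Fractions of all six states at the given SSB/RecA concentrations.

    Convenience wrapper around :meth:`CompetitionModel.fractions`; states
    absent from the scheme get exactly zero.
    """
    return model.fractions(s_conc, r_conc)


def enumerate_configurations(optional_states=("TRqSm", "TRrSmn"),
                             always_observable=("TSm",)):
    """All (state subset, observable subset) model configurations.

    The four experimentally established states are always included; each
    subset of the optional mixed states defines a reaction scheme, and every
    subset of its non-empty-DNA states containing ``TSm`` is a candidate
    assignment to the high-FRET observable.  Returns a list of
    ``(states, observable)`` tuples; its length is the enumerated
    configuration count.
    """
    configs = []
    for k in range(len(optional_states) + 1):
        for extra in itertools.combinations(optional_states, k):
            states = tuple(s for s in SIX_STATES
                           if s in _BASE_STATES or s in extra)
            candidates = [s for s in states
                          if s != "T" and s not in always_observable]
            for j in range(len(candidates) + 1):
                for obs_extra in itertools.combinations(candidates, j):
                    observable = tuple(s for s in SIX_STATES
                                       if s in always_observable or
                                       s in obs_extra)
                    configs.append((states, observable))
    return configs


def _fit_one_configuration(s, r, f_obs, sd, speciation: SpeciationFit,
                           states, observable):
    r_states = [st for st in ("TRp", "TRqSm", "TRrSmn") if st in states]
    n_par = 2 * len(r_states)
    c_names = {"TRp": "c_rp_half", "TRqSm": "c_rq_half", "TRrSmn": "c_rr_half"}
    h_names = {"TRp": "hill_p", "TRqSm": "hill_q", "TRrSmn": "hill_r"}

    def build(theta):
        kw = dict(c_s_half=speciation.c_half,
                  c_s_star_half=speciation.c_star_half,
                  hill_m=speciation.hill_m, hill_n=speciation.hill_n,
                  states=states, observable=observable)
        for i, st in enumerate(r_states):
            kw[c_names[st]] = 10.0 ** theta[2 * i]
            kw[h_names[st]] = theta[2 * i + 1]
        return CompetitionModel(**kw)

    def resid(theta):
        return (build(theta).observable_fraction(s, r) - f_obs) / sd

    if n_par == 0:
        model = build([])
        res_vec = resid([])
        dof = max(f_obs.size - n_par, 1)
        chi2r = float((res_vec ** 2).sum() / dof)
        model.chi2_reduced = chi2r
        model.n_free_params = 0
        return model
    pos_r = r[r > 0]
    log_mid = np.log10(np.median(pos_r)) if pos_r.size else -6.0
    p0 = []
    for _ in r_states:
        p0 += [log_mid, 2.0]
    lo = [-12.0, 0.3] * len(r_states)
    hi = [0.0, 8.0] * len(r_states)
    res = optimize.least_squares(resid, p0, bounds=(lo, hi),
                                 xtol=1e-10, ftol=1e-10)
    dof = max(f_obs.size - n_par, 1)
    chi2r = float(2 * res.cost / dof)
    model = build(res.x)
    model.chi2_reduced = chi2r
    model.n_free_params = n_par
    try:
        cov = np.linalg.inv(res.jac.T @ res.jac)
        # ill-conditioned configurations can give tiny negative diagonals
        perr = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        ln10 = np.log(10.0)
        stderr = {}
        for i, st in enumerate(r_states):
            c_val = 10.0 ** res.x[2 * i]
            stderr[c_names[st]] = ln10 * c_val * perr[2 * i]
            stderr[h_names[st]] = perr[2 * i + 1]
        model.param_stderr = stderr
    except np.linalg.LinAlgError:
        pass
    return model


def fit_competition_model(table: pd.DataFrame, speciation: SpeciationFit,
                          configurations=None,
                          s_column: str = "SSB_M", r_column: str = "RecA_M",
                          f_column: str = "f_obs", sd_column: str | None = None):
    """Fit every state/observable configuration and rank by reduced χ².

    The SSB-only speciation parameters (c_S, c*_S, m, n) are held fixed; the
    RecA-related half concentrations and Hill exponents of each scheme are
    free.  Ties in χ²_r are broken toward fewer free parameters.  Returns
    ``(best_model, ranking)`` where ``ranking`` is a DataFrame over all
    enumerated configurations.
    """
    s = table[s_column].to_numpy(float)
    r = table[r_column].to_numpy(float)
    f_obs = table[f_column].to_numpy(float)
    sd_column = sd_column or ("sd_" + f_column if "sd_" + f_column
                              in table.columns else None)
    sd = np.ones_like(f_obs)
    if sd_column is not None:
        s_arr = table[sd_column].to_numpy(float)
        if np.all(np.isfinite(s_arr)) and np.all(s_arr > 0):
            sd = s_arr
    if configurations is None:
        configurations = enumerate_configurations()
    if f_obs.size < 16:
        warnings.warn("competition grid is small; model selection may be unstable")

    results, failures = [], []
    for states, observable in configurations:
        try:
            model = _fit_one_configuration(s, r, f_obs, sd, speciation,
                                           states, observable)
            model.configuration_id = (
                "states=" + "+".join(states) + "|obs=" + "+".join(observable))
            results.append(model)
        except Exception as exc:   # keep ranking robust to single failures
            failures.append((states, observable, exc))
    if not results:
        raise FitError(f"all {len(configurations)} configuration fits failed")

    results.sort(key=lambda m: (m.chi2_reduced, m.n_free_params))
    ranking = pd.DataFrame({
        "configuration_id": [m.configuration_id for m in results],
        "states": ["+".join(m.states) for m in results],
        "observable": ["+".join(m.observable) for m in results],
        "n_free_params": [m.n_free_params for m in results],
        "chi2_reduced": [m.chi2_reduced for m in results],
    })
    ranking.attrs["n_configurations"] = len(configurations)
    ranking.attrs["n_failed"] = len(failures)
    return results[0], ranking


# ----------------------------------------------------------------------
# parametric bootstrap for fraction-table fits
def parametric_bootstrap_ci(table: pd.DataFrame, fitter, predicted,
                            params, n_boot: int = 200, seed: int = 0,
                            level: float = 0.68) -> dict:
    """Seeded parametric-bootstrap confidence intervals for any fit on a
    fraction table with counting statistics.

    ``predicted`` is an array (n_rows, n_states) of model fractions from
    the point fit; each bootstrap replicate redraws per-row multinomial
    counts from it using the table's ``n_bursts``, rebuilds the fraction
    columns in ``table`` order, refits with ``fitter(table)`` and collects
    the attributes named in ``params``.  Returns
    ``{param: (lower, upper)}`` central intervals at the given level —
    a complement to the covariance-based 68% CIs of the point fits.
    """
    if "n_bursts" not in table.columns:
        raise ConfigurationError("bootstrap needs an n_bursts column")
    predicted = np.atleast_2d(np.asarray(predicted, float))
    if predicted.shape[0] != len(table):
        predicted = predicted.T
    frac_cols = [c for c in table.columns
                 if c.startswith("f_") and not c.startswith("f_obs")] or \
        [c for c in table.columns if c == "f_obs"]
    if predicted.shape[1] != len(frac_cols):
        raise ConfigurationError(
            f"predicted fractions have {predicted.shape[1]} states but the "
            f"table has columns {frac_cols}")
    rng = np.random.default_rng(seed)
    n_arr = table["n_bursts"].to_numpy(float).astype(int)
    draws = {p: [] for p in params}
    for _ in range(n_boot):
        boot = table.copy()
        for i in range(len(table)):
            row_p = np.clip(predicted[i], 0.0, None)
            if len(frac_cols) == 1:   # binomial observable
                k = rng.binomial(n_arr[i], min(row_p[0], 1.0))
                fo = k / n_arr[i]
                boot.iloc[i, boot.columns.get_loc(frac_cols[0])] = fo
                sd_col = "sd_" + frac_cols[0]
                if sd_col in boot.columns:
                    boot.iloc[i, boot.columns.get_loc(sd_col)] = max(
                        np.sqrt(fo * (1 - fo) / n_arr[i]),
                        1.0 / (2 * n_arr[i]))
            else:
                counts = rng.multinomial(n_arr[i], row_p / row_p.sum())
                for j, c in enumerate(frac_cols):
                    fo = counts[j] / n_arr[i]
                    boot.iloc[i, boot.columns.get_loc(c)] = fo
                    sd_col = "sd_" + c
                    if sd_col in boot.columns:
                        boot.iloc[i, boot.columns.get_loc(sd_col)] = max(
                            np.sqrt(fo * (1 - fo) / n_arr[i]),
                            1.0 / (2 * n_arr[i]))
        fit = fitter(boot)
        for p in params:
            draws[p].append(getattr(fit, p))
    alpha = (1.0 - level) / 2.0
    return {p: (float(np.quantile(v, alpha)),
                float(np.quantile(v, 1.0 - alpha)))
            for p, v in draws.items()}


# ----------------------------------------------------------------------
# dose-response screening
@dataclass
class DoseResponseFit:
    """Hill dose–response fit; EC50 in M."""

    ec50: float
    hill_slope: float
    f_min: float
    f_max: float
    ec50_stderr: float = np.nan
    hill_slope_stderr: float = np.nan
    excluded_points: list = field(default_factory=list)
    no_response: bool = False
    success: bool = True

    def predict(self, c):
        c = np.asarray(c, float)
        h = self.hill_slope
        return self.f_min + (self.f_max - self.f_min) * \
            c ** h / (self.ec50 ** h + c ** h)


def fit_dose_response(table: pd.DataFrame, exclusion_max: float | None = None,
                      concentration_column: str = "drug_M",
                      fraction_column: str = "f_folded") -> DoseResponseFit:
    """Weighted Hill fit of fraction folded versus drug concentration.

    Points with concentration above ``exclusion_max`` are dropped before the
    fit and listed in ``excluded_points`` with the reason (mirrors screening
    practice of excluding the range where compound fluorescence interferes
    with detection).  A curve with no resolvable response (span within twice
    the mean counting SD) is flagged and its EC50 reported as unbounded.
    """
    c_all = table[concentration_column].to_numpy(float)
    f_all = table[fraction_column].to_numpy(float)
    excluded = []
    keep = np.ones(c_all.size, bool)
    if exclusion_max is not None:
        over = c_all > exclusion_max
        for cc in c_all[over]:
            excluded.append((float(cc),
                             f"concentration above exclusion_max={exclusion_max:g}"))
        keep &= ~over
    c, f = c_all[keep], f_all[keep]
    if c.size < 6:
        raise ConfigurationError("need at least 6 concentrations after exclusion")
    sd_col = "sd_" + fraction_column
    sigma = None
    if sd_col in table.columns:
        s = table.loc[keep, sd_col].to_numpy(float)
        if np.all(np.isfinite(s)) and np.all(s > 0):
            sigma = s

    span = f.max() - f.min()
    noise = 2.0 * float(np.mean(sigma)) if sigma is not None else 0.02
    if span <= noise:
        warnings.warn("no resolvable dose response; EC50 unbounded")
        return DoseResponseFit(ec50=np.inf, hill_slope=np.nan,
                               f_min=float(f.mean()), f_max=float(f.mean()),
                               excluded_points=excluded, no_response=True,
                               success=False)

    def model(cc, log_ec50, h, f_min, f_max):
        ec50 = 10.0 ** log_ec50
        return f_min + (f_max - f_min) * cc ** h / (ec50 ** h + cc ** h)

    pos = c[c > 0]
    p0 = [np.log10(np.median(pos)), 1.0, float(f.min()), float(f.max())]
    popt, pcov = optimize.curve_fit(
        model, c, f, p0=p0, sigma=sigma, absolute_sigma=sigma is not None,
        bounds=([-12, 0.2, -0.2, -0.2], [0, 8, 1.2, 1.2]), maxfev=20000)
    perr = np.sqrt(np.diag(pcov))
    ec50 = 10.0 ** popt[0]
    return DoseResponseFit(
        ec50=float(ec50), hill_slope=float(popt[1]),
        f_min=float(popt[2]), f_max=float(popt[3]),
        ec50_stderr=float(np.log(10.0) * ec50 * perr[0]),
        hill_slope_stderr=float(perr[1]),
        excluded_points=excluded)
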