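"""Salt dependence of hairpin opening/closing kinetics.

The opening rate of a DNA hairpin falls linearly with salt,
``k_open(c) = k⁰_open + m_open·c``.  The closing rate is modelled as a
pseudo-bimolecular annealing reaction between the two complementary stem
halves held together by the single-stranded loop: the effective rate is
``k_close(c) = k′_close · [A]``, where the *apparent local concentration*
[A] of one stem end around the other is the inverse of the spherical volume
spanned by the root-mean-square end-to-end distance R of the loop,

    [A] = 1 / (N_A · 4/3·π·R³).

R comes from the worm-like chain (WLC) with contour length ``l_c`` and an
ionic-strength dependent persistence length ``l_p(I)``:

    R² = 2·l_p·l_c − 2·l_p²·(1 − exp(−l_c/l_p)).

Salt screens the backbone charge, lowering ``l_p``, shrinking the loop and
raising [A] — reproducing the upward curvature of the closing rate.
Rates are carried in 1/ms throughout this module; conversions happen only at
its boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.constants import Avogadro

from .exceptions import ConfigurationError

__all__ = [
    "wlc_end_to_end",
    "apparent_local_concentration",
    "persistence_length",
    "HairpinKineticsModel",
    "fit_hairpin_salt_dependence",
    "bootstrap_condition_sampling",
]

#: defaults for the dT21 loop of the hpT5 hairpin
DEFAULT_CONTOUR_NM = 14.2
DEFAULT_LP_ZERO_NM = 2.09    # persistence length at zero added salt
DEFAULT_LP_INF_NM = 0.75     # persistence length at infinite salt
DEFAULT_I_SCALE_M = 0.3      # screening decay scale of l_p(I)
DEFAULT_BUFFER_I_M = 0.01    # ionic-strength contribution of the buffer


def wlc_end_to_end(l_p: float, l_c: float) -> float:
    """Root-mean-square end-to-end distance of a worm-like chain (nm)."""
    if l_p <= 0 or l_c <= 0:
        raise ConfigurationError("persistence and contour length must be positive")
    r2 = 2.0 * l_p * l_c - 2.0 * l_p ** 2 * (1.0 - np.exp(-l_c / l_p))
    return float(np.sqrt(r2))


def apparent_local_concentration(r_nm) -> float:
    """Effective molar concentration of one chain end around the other.

    One molecule in the sphere of radius ``r_nm``: ``1/(N_A·(4/3)πR³)``,
    volume converted from nm³ to litres (1 nm³ = 1e-24 L).
    """
    r_nm = np.asarray(r_nm, float)
    if np.any(r_nm <= 0):
        raise ConfigurationError("distance must be positive")
    volume_l = (4.0 / 3.0) * np.pi * r_nm ** 3 * 1e-24
    out = 1.0 / (Avogadro * volume_l)
    return float(out) if out.ndim == 0 else out


def persistence_length(ionic_strength, l_p_zero: float = DEFAULT_LP_ZERO_NM,
                       l_p_inf: float = DEFAULT_LP_INF_NM,
                       i_scale: float = DEFAULT_I_SCALE_M):
    """Ionic-strength dependent ssDNA persistence length (nm).

    Monotone interpolation ``l_p(I) = l_p_inf + (l_p_zero−l_p_inf)·exp(−I/I_s)``
    between the zero-salt and high-salt limits; any alternative form can be
    passed to the fitting routines via ``lp_of_ionic_strength``.
    """
    ionic_strength = np.asarray(ionic_strength, float)
    if np.any(ionic_strength < 0):
        raise ConfigurationError("ionic strength must be >= 0")
    if not l_p_inf < l_p_zero:
        raise ConfigurationError("l_p_inf must be below l_p_zero")
    out = l_p_inf + (l_p_zero - l_p_inf) * np.exp(-ionic_strength / i_scale)
    return float(out) if out.ndim == 0 else out


@dataclass
class HairpinKineticsModel:
    """Fitted salt-dependence model of hairpin kinetics.

    Opening: ``k_open(c) = k_open_0 + m_open·c`` (1/ms).  Closing:
    ``k_close(c) = k_close_prime·[A](l_p(I(c)))`` with ``k_close_prime`` in
    1/(s·M), converted to 1/ms at the boundary.
    """

    k_open_0: float                      # 1/ms
    m_open: float                        # 1/(ms·M)
    k_close_prime: float                 # 1/(s·M)
    k_open_0_stderr: float = np.nan
    m_open_stderr: float = np.nan
    k_close_prime_stderr: float = np.nan
    l_c: float = DEFAULT_CONTOUR_NM      # nm
    l_p_zero: float = DEFAULT_LP_ZERO_NM
    l_p_inf: float = DEFAULT_LP_INF_NM
    i_scale: float = DEFAULT_I_SCALE_M   # M
    buffer_ionic_strength: float = DEFAULT_BUFFER_I_M  # M

    def __post_init__(self):
        if not self.l_p_inf < self.l_p_zero:
            raise ConfigurationError("l_p_inf must be below l_p_zero")
        if self.l_c <= 0 or self.k_close_prime <= 0:
            raise ConfigurationError("l_c and k_close_prime must be positive")

    def ionic_strength(self, salt_m):
        """Map [NaCl] to ionic strength (adds the buffer contribution)."""
        return np.asarray(salt_m, float) + self.buffer_ionic_strength

    def local_concentration(self, salt_m):
        lp = persistence_length(self.ionic_strength(salt_m), self.l_p_zero,
                                self.l_p_inf, self.i_scale)
        r = np.sqrt(2.0 * lp * self.l_c -
                    2.0 * lp ** 2 * (1.0 - np.exp(-self.l_c / lp)))
        return apparent_local_concentration(r)

    def k_open(self, salt_m):
        """Opening rate in 1/ms."""
        return self.k_open_0 + self.m_open * np.asarray(salt_m, float)

    def k_close(self, salt_m):
        """Closing rate in 1/ms."""
        return self.k_close_prime * self.local_concentration(salt_m) * 1e-3

    def closing_rate_bounds(self):
        """(lower, upper) closing-rate bounds in 1/ms from the l_p limits."""
        bounds = []
        for lp in (self.l_p_zero, self.l_p_inf):
            r = wlc_end_to_end(lp, self.l_c)
            bounds.append(self.k_close_prime *
                          apparent_local_concentration(r) * 1e-3)
        return min(bounds), max(bounds)


def _weights(err):
    err = np.asarray(err, float) if err is not None else None
    if err is None or not np.all(np.isfinite(err)) or np.any(err <= 0):
        return None
    return err


def fit_hairpin_salt_dependence(rates: pd.DataFrame,
                                l_c: float = DEFAULT_CONTOUR_NM,
                                l_p_zero: float = DEFAULT_LP_ZERO_NM,
                                l_p_inf: float = DEFAULT_LP_INF_NM,
                                i_scale: float = DEFAULT_I_SCALE_M,
                                buffer_ionic_strength: float = DEFAULT_BUFFER_I_M,
                                ) -> HairpinKineticsModel:
    """Fit the salt dependence of opening and closing rates.

    ``rates`` needs columns ``salt_M``, ``k_open``, ``k_close`` (1/ms) and
    optionally ``k_open_err``/``k_close_err`` for weighting.  The opening
    rate is fitted by weighted linear least squares; the closing rate by
    weighted least squares for the single bimolecular constant
    ``k_close_prime`` against the WLC local-concentration curve.
    Uncertainties are 68% CIs from the fit covariance.
    """
    needed = {"salt_M", "k_open", "k_close"}
    if not needed <= set(rates.columns):
        raise ConfigurationError(f"rate table needs columns {sorted(needed)}")
    ok = np.isfinite(rates["k_open"]) & np.isfinite(rates["k_close"])
    rt = rates.loc[ok]
    if len(rt) < 5:
        raise ConfigurationError("need at least 5 conditions with finite rates")
    c = rt["salt_M"].to_numpy(float)

    sig_o = _weights(rt["k_open_err"]) if "k_open_err" in rt else None
    popt, pcov = np.polyfit(c, rt["k_open"].to_numpy(float), 1,
                            w=None if sig_o is None else 1.0 / sig_o,
                            cov="unscaled" if sig_o is not None else True)
    m_open, k0 = popt
    m_err, k0_err = np.sqrt(np.diag(pcov))

    proto = HairpinKineticsModel(
        k_open_0=float(k0), m_open=float(m_open), k_close_prime=1.0,
        l_c=l_c, l_p_zero=l_p_zero, l_p_inf=l_p_inf, i_scale=i_scale,
        buffer_ionic_strength=buffer_ionic_strength)
    conc_local = proto.local_concentration(c)          # M

    def closing_model(cc, k_prime):
        return k_prime * proto.local_concentration(cc) * 1e-3

    sig_c = _weights(rt["k_close_err"]) if "k_close_err" in rt else None
    k_init = max(float(np.mean(rt["k_close"].to_numpy(float) /
                               (conc_local * 1e-3))), 1e-6)
    kopt, kcov = optimize.curve_fit(
        closing_model, c, rt["k_close"].to_numpy(float), p0=[k_init],
        sigma=sig_c, absolute_sigma=sig_c is not None,
        bounds=(0.0, np.inf))

    return HairpinKineticsModel(
        k_open_0=float(k0), m_open=float(m_open),
        k_close_prime=float(kopt[0]),
        k_open_0_stderr=float(k0_err), m_open_stderr=float(m_err),
        k_close_prime_stderr=float(np.sqrt(kcov[0, 0])),
        l_c=l_c, l_p_zero=l_p_zero, l_p_inf=l_p_inf, i_scale=i_scale,
        buffer_ionic_strength=buffer_ionic_strength)


def bootstrap_condition_sampling(rates: pd.DataFrame, n_conditions,
                                 n_boot: int = 200, seed: int = 0):
    """Sampling-density analysis of the linear opening-rate fit.

    For each requested number of conditions, ``n_boot`` subsamples (without
    replacement) of the rate table are drawn and the linear opening model is
    refitted; the spread (SD) of the zero-salt intercept across replicates
    quantifies how accuracy improves with sampling density.  Deterministic
    given ``seed``.  Returns a float for scalar ``n_conditions``, otherwise a
    :class:`pandas.Series` indexed by n.
    """
    scalar = np.isscalar(n_conditions)
    ns = [int(n_conditions)] if scalar else [int(n) for n in n_conditions]
    if n_boot < 100:
        raise ConfigurationError("n_boot must be >= 100")
    ok = np.isfinite(rates["k_open"])
    c = rates.loc[ok, "salt_M"].to_numpy(float)
    k = rates.loc[ok, "k_open"].to_numpy(float)
    rng = np.random.default_rng(seed)
    out = {}
    for n in ns:
        if n < 3:
            raise ConfigurationError("need at least 3 conditions per subsample")
        if n > c.size:
            raise ConfigurationError(f"only {c.size} conditions available")
        intercepts = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.choice(c.size, size=n, replace=False)
            slope, icpt = np.polyfit(c[idx], k[idx], 1)
            intercepts[b] = icpt
        out[n] = float(np.std(intercepts, ddof=1))
    if scalar:
        return out[ns[0]]
    return pd.Series(out, name="sd_k_open_0").rename_axis("n_conditions")
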