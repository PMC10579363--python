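"""Proximity ratio, stoichiometry and FRET correction factors.

Implements the standard PIE/ALEX correction chain: apparent values

    E_app = b_DA / (b_DA + b_DD)
    S_app = (b_DD + b_DA) / (b_DD + b_DA + b_AA)

from background-corrected counts; correction factors

``alpha_leak``
    donor spectral leakage into the acceptor channel,
``delta_dir``
    acceptor direct excitation by the donor laser,
``gamma``
    detection-efficiency / quantum-yield ratio of acceptor vs donor,
``beta``
    acceptor/donor excitation ratio;

and the corrected estimators

    F_AD   = b_DA − α·b_DD − δ·b_AA
    E_corr = F_AD / (γ·b_DD + F_AD)
    S_corr = (γ·b_DD + F_AD) / (γ·b_DD + F_AD + b_AA/β)

α and δ are measured on the donor-only and acceptor-only populations; γ and β
come from the classic two-population method — for leakage/direct-excitation
corrected values, ``1/S = 1 + γβ + (1−γ)β·E`` is linear in E, so a line
through the centroids of two double-labelled populations of distinct E yields
both factors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import CalibrationError

__all__ = [
    "CorrectionSet",
    "proximity_values",
    "derive_correction_set",
    "apply_correction_set",
]


@dataclass(frozen=True)
class CorrectionSet:
    """Detection/excitation correction factors for one well or plate."""

    alpha_leak: float = 0.0
    delta_dir: float = 0.0
    gamma: float = 1.0
    beta: float = 1.0
    source: str = "fixed"

    def __post_init__(self):
        if not (0 <= self.alpha_leak < 1 and 0 <= self.delta_dir < 1):
            raise CalibrationError("alpha_leak and delta_dir must lie in [0, 1)")
        if self.gamma <= 0 or self.beta <= 0:
            raise CalibrationError("gamma and beta must be positive")

    @classmethod
    def identity(cls) -> "CorrectionSet":
        return cls()

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CorrectionSet":
        with open(path) as fh:
            return cls(**json.load(fh))


def proximity_values(table: pd.DataFrame) -> pd.DataFrame:
    """Attach apparent FRET efficiency and stoichiometry columns.

    ``E_app = b_DA/(b_DA+b_DD)``; ``S_app = (b_DD+b_DA)/(b_DD+b_DA+b_AA)``.
    Values with non-positive denominator are NaN (flagged, not errors).
    """
    out = table.copy()
    out.attrs = dict(table.attrs)
    if len(table) == 0:
        out["E_app"] = pd.Series(dtype=float)
        out["S_app"] = pd.Series(dtype=float)
        return out
    b_dd = table["b_DD"].to_numpy(float)
    b_da = table["b_DA"].to_numpy(float)
    b_aa = table["b_AA"].to_numpy(float)
    den_e = b_da + b_dd
    den_s = den_e + b_aa
    with np.errstate(divide="ignore", invalid="ignore"):
        out["E_app"] = np.where(den_e > 0, b_da / den_e, np.nan)
        out["S_app"] = np.where(den_s > 0, den_e / den_s, np.nan)
    return out


def _gaussian_mean(values: np.ndarray, n_min: int = 10) -> float:
    """Population centre by a robust Gaussian estimate.

    Sigma-clipped normal MLE (3 iterations at 3 robust SDs) — equivalent to a
    Gaussian fit of the main mode, resistant to outlier bursts.
    """
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return np.nan
    if v.size < n_min:
        return float(np.mean(v))
    centre = np.median(v)
    scale = 1.4826 * np.median(np.abs(v - centre)) + 1e-12
    for _ in range(3):
        sel = v[np.abs(v - centre) <= 3.0 * scale]
        if sel.size < 3:
            break
        centre, sd = stats.norm.fit(sel)
        scale = sd + 1e-12
    return float(centre)


def _clip_mask(values: np.ndarray, n_sigma: float = 3.0) -> np.ndarray:
    """Membership mask of the main mode (robust sigma clip around the
    Gaussian centre); used so flux-weighted centroids resist outliers."""
    v = np.asarray(values, float)
    centre = _gaussian_mean(v)
    scale = 1.4826 * np.median(np.abs(v - centre)) + 1e-12
    return np.isfinite(v) & (np.abs(v - centre) <= n_sigma * scale)


def derive_correction_set(tables, s_donor_only: float = 0.9,
                          s_acceptor_only: float = 0.2,
                          s_double=(0.25, 0.8),
                          min_population: int = 10) -> CorrectionSet:
    """Derive all four correction factors from a calibration measurement.

    Requires donor-only bursts (``S_app > s_donor_only``), acceptor-only
    bursts (``S_app < s_acceptor_only``) and two double-labelled populations
    of distinct mean E (|ΔE| ≥ 0.1) in the stoichiometry band ``s_double``.

    α = Ē_DO/(1−Ē_DO) from the donor-only E centroid; δ = S̄_AO/(1−S̄_AO)
    from the acceptor-only S centroid; γ and β from the line through the two
    double-labelled centroids in (E, 1/S) space after α/δ correction.
    """
    if isinstance(tables, pd.DataFrame):
        table = tables
    else:
        table = pd.concat(list(tables), ignore_index=True)
    if "E_app" not in table.columns:
        table = proximity_values(table)

    s_app = table["S_app"].to_numpy(float)
    e_app = table["E_app"].to_numpy(float)

    do = table.loc[s_app > s_donor_only]
    ao = table.loc[s_app < s_acceptor_only]
    if len(do) < min_population:
        raise CalibrationError("no identifiable donor-only population")
    if len(ao) < min_population:
        raise CalibrationError("no identifiable acceptor-only population")
    # flux-weighted centroids over the sigma-clipped main mode: the ratio of
    # summed counts is unbiased at the population level, unlike the mean of
    # per-burst ratios
    m_do = _clip_mask(do["E_app"].to_numpy(float))
    e_do = (do["b_DA"].to_numpy(float)[m_do].sum() /
            max(do["b_DA"].to_numpy(float)[m_do].sum() +
                do["b_DD"].to_numpy(float)[m_do].sum(), 1e-12))
    alpha = max(e_do / (1.0 - e_do), 0.0)
    m_ao = _clip_mask(ao["S_app"].to_numpy(float))
    dex_ao = (ao["b_DD"].to_numpy(float)[m_ao].sum() +
              ao["b_DA"].to_numpy(float)[m_ao].sum())
    s_ao = dex_ao / max(dex_ao + ao["b_AA"].to_numpy(float)[m_ao].sum(), 1e-12)
    delta = max(s_ao / (1.0 - s_ao), 0.0)

    dl = table.loc[(s_app >= s_double[0]) & (s_app <= s_double[1])].copy()
    if len(dl) < 2 * min_population:
        raise CalibrationError("insufficient double-labelled bursts")
    b_dd = dl["b_DD"].to_numpy(float)
    b_da = dl["b_DA"].to_numpy(float)
    b_aa = dl["b_AA"].to_numpy(float)
    f_ad = b_da - alpha * b_dd - delta * b_aa
    with np.errstate(divide="ignore", invalid="ignore"):
        e_pr = f_ad / (f_ad + b_dd)
        s_pr = (b_dd + f_ad) / (b_dd + f_ad + b_aa)
    ok = np.isfinite(e_pr) & np.isfinite(s_pr) & (s_pr > 0)
    e_pr, s_pr = e_pr[ok], s_pr[ok]

    # deterministic 1-D two-means split on E
    c_lo, c_hi = np.percentile(e_pr, [25, 75])
    for _ in range(25):
        assign = np.abs(e_pr - c_lo) <= np.abs(e_pr - c_hi)
        new_lo, new_hi = e_pr[assign].mean(), e_pr[~assign].mean()
        if np.isclose(new_lo, c_lo) and np.isclose(new_hi, c_hi):
            break
        c_lo, c_hi = new_lo, new_hi
    pops = [assign, ~assign]
    if min(p.sum() for p in pops) < min_population:
        raise CalibrationError("two double-labelled populations not resolvable")
    gauss_means = [_gaussian_mean(e_pr[p]) for p in pops]
    if abs(gauss_means[0] - gauss_means[1]) < 0.1:
        raise CalibrationError(
            f"double-labelled populations indistinguishable (dE = "
            f"{abs(gauss_means[0] - gauss_means[1]):.3f} < 0.1)")
    b_dd_ok, b_aa_ok, f_ad_ok = b_dd[ok], b_aa[ok], f_ad[ok]
    e_means, inv_s = [], []
    for p in pops:
        idx = np.flatnonzero(p)
        sel = idx[_clip_mask(e_pr[idx])]
        f_sum = f_ad_ok[sel].sum()
        d_sum = b_dd_ok[sel].sum()
        a_sum = b_aa_ok[sel].sum()
        e_means.append(f_sum / (f_sum + d_sum))
        inv_s.append((d_sum + f_sum + a_sum) / (d_sum + f_sum))

    slope = (inv_s[1] - inv_s[0]) / (e_means[1] - e_means[0])
    intercept = inv_s[0] - slope * e_means[0]
    beta = intercept + slope - 1.0
    if beta <= 0:
        raise CalibrationError("two-population regression gave non-positive beta")
    gamma = (intercept - 1.0) / beta
    if gamma <= 0:
        raise CalibrationError("two-population regression gave non-positive gamma")
    return CorrectionSet(alpha_leak=alpha, delta_dir=delta, gamma=gamma,
                         beta=beta, source="derived-from-calibration")


def apply_correction_set(table: pd.DataFrame, corr: CorrectionSet) -> pd.DataFrame:
    """Attach fully corrected ``E_corr``/``S_corr`` columns.

    Degenerate denominators give NaN and set the ``corr_undefined`` flag.
    With identity corrections ``E_corr`` equals ``E_app`` exactly.
    """
    out = table.copy()
    out.attrs = dict(table.attrs)
    out.attrs["corrections"] = asdict(corr)
    if len(table) == 0:
        out["E_corr"] = pd.Series(dtype=float)
        out["S_corr"] = pd.Series(dtype=float)
        out["corr_undefined"] = pd.Series(dtype=bool)
        return out
    b_dd = table["b_DD"].to_numpy(float)
    b_da = table["b_DA"].to_numpy(float)
    b_aa = table["b_AA"].to_numpy(float)
    f_ad = b_da - corr.alpha_leak * b_dd - corr.delta_dir * b_aa
    den_e = corr.gamma * b_dd + f_ad
    den_s = den_e + b_aa / corr.beta
    with np.errstate(divide="ignore", invalid="ignore"):
        e_corr = np.where(den_e != 0, f_ad / den_e, np.nan)
        s_corr = np.where(den_s != 0, den_e / den_s, np.nan)
    out["E_corr"] = e_corr
    out["S_corr"] = s_corr
    out["corr_undefined"] = ~(np.isfinite(e_corr) & np.isfinite(s_corr))
    return out
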