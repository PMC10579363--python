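"""Burst identification and per-burst scores on PIE photon streams.

Bursts are found with the standard all-photon sliding-window search: a photon
is *in burst* when at least ``min_rate_photons`` photons (itself included)
fall within a centred time window of length ``window`` around it; runs of
consecutive in-burst photons form candidate bursts, and candidates with fewer
than ``min_total_photons`` photons are discarded.  A burst spans its first to
last in-burst photon, its duration floored at one clock tick.

Burst tables are plain :class:`pandas.DataFrame` objects (one row per burst)
with search provenance in ``df.attrs`` — serialisable as TSV + JSON sidecar.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd

from .corrections import proximity_values
from .exceptions import ConfigurationError
from .photons import AA, DA, DD, PhotonStream

__all__ = [
    "estimate_background",
    "find_bursts",
    "filter_bursts",
    "bva_scores",
    "write_burst_table",
    "read_burst_table",
]


def estimate_background(stream: PhotonStream, method: str = "out_of_burst",
                        window: float = 500e-6, min_rate_photons: int = 10,
                        tail_quantile: float = 0.8):
    """Per-channel background rates in photons/s.

    ``method="out_of_burst"`` runs a coarse burst search and estimates rates
    from the photons outside bursts (default); ``method="delay_tail"`` fits
    the exponential tail of the inter-photon-delay distribution (delays above
    ``tail_quantile``), whose MLE rate is ``1/mean(delay - threshold)``;
    ``method="mean"`` uses whole-trace mean rates.  Streams with fewer than
    100 photons fall back to whole-trace means with a warning.
    """
    if len(stream) == 0:
        return np.zeros(3)
    counts = stream.counts_per_channel().astype(float)
    duration = max(stream.duration, float(stream.timestamps[-1]) * stream.clock_period)
    mean_rates = counts / duration
    if len(stream) < 100:
        warnings.warn("fewer than 100 photons; using whole-trace mean rates")
        return mean_rates
    if method == "mean":
        return mean_rates

    if method == "delay_tail":
        t = stream.times
        delays = np.diff(t)
        thr = np.quantile(delays, tail_quantile)
        tail = delays[delays >= thr]
        total_rate = 1.0 / np.mean(tail - thr) if tail.size else 0.0
        return total_rate * counts / counts.sum()

    if method == "out_of_burst":
        mask = _in_burst_mask(stream.timestamps, stream.clock_period,
                              window, min_rate_photons)
        out = ~mask
        # time not covered by bursts
        t = stream.times
        burst_time = 0.0
        for i0, i1 in _runs(mask):
            burst_time += t[i1] - t[i0]
        free = max(duration - burst_time, 1e-12)
        ch = stream.channel[out]
        rates = np.bincount(ch, minlength=3)[:3] / free
        return rates.astype(float)

    raise ConfigurationError(f"unknown background method: {method!r}")


def _in_burst_mask(timestamps: np.ndarray, clock_period: float,
                   window: float, min_rate_photons: int) -> np.ndarray:
    """Sliding-window criterion: >= m photons within +-window/2 of each photon."""
    half = window / (2.0 * clock_period)
    t = timestamps.astype(np.float64)
    left = np.searchsorted(t, t - half, side="left")
    right = np.searchsorted(t, t + half, side="right")
    return (right - left) >= min_rate_photons


def _runs(mask: np.ndarray):
    """(start, stop) index pairs (inclusive) of True runs in mask."""
    if mask.size == 0:
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1)
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        stops = np.r_[stops, mask.size - 1]
    return list(zip(starts, stops))


def find_bursts(stream: PhotonStream, window: float = 500e-6,
                min_rate_photons: int = 10, min_total_photons: int = 50,
                background_rates=None) -> pd.DataFrame:
    """All-photon sliding-window burst search.

    Returns a burst table with raw per-channel counts ``n_DD/n_DA/n_AA``,
    background-corrected counts ``b_*`` (``b_X = n_X − rate_X·T``; may be
    negative, deliberately not clipped so E/S estimators stay unbiased), the
    apparent proximity ratio ``E_app`` and stoichiometry ``S_app``.
    """
    if window <= 0:
        raise ConfigurationError("window must be positive")
    if min_rate_photons < 1 or min_total_photons < 1:
        raise ConfigurationError("photon thresholds must be >= 1")
    if background_rates is None:
        background_rates = np.zeros(3)
    background_rates = np.asarray(background_rates, float)

    cols = ["start_index", "stop_index", "t_start", "duration",
            "n_DD", "n_DA", "n_AA", "b_DD", "b_DA", "b_AA"]
    rows = []
    if len(stream) > 0:
        mask = _in_burst_mask(stream.timestamps, stream.clock_period,
                              window, min_rate_photons)
        t = stream.timestamps
        ch = stream.channel
        for i0, i1 in _runs(mask):
            n_tot = i1 - i0 + 1
            if n_tot < min_total_photons:
                continue
            dur_ticks = max(int(t[i1] - t[i0]), 1)  # floor one tick
            dur = dur_ticks * stream.clock_period
            seg = ch[i0:i1 + 1]
            n = np.bincount(seg, minlength=3)[:3]
            b = n - background_rates * dur
            rows.append((i0, i1, t[i0] * stream.clock_period, dur,
                         *n.tolist(), *b.tolist()))

    table = pd.DataFrame(rows, columns=cols)
    for c in ("start_index", "stop_index", "n_DD", "n_DA", "n_AA"):
        table[c] = table[c].astype(np.int64) if len(table) else table[c]
    table = proximity_values(table)
    table.attrs["search"] = {
        "window_s": window, "min_rate_photons": int(min_rate_photons),
        "min_total_photons": int(min_total_photons),
        "background_rates": background_rates.tolist(),
    }
    table.attrs["well_id"] = stream.well_id
    return table


def filter_bursts(table: pd.DataFrame, s_range=(0.25, 0.75),
                  brightness_ratio_range=(0.0, np.inf),
                  min_photons: int = 0, use_corrected: bool = False) -> pd.DataFrame:
    """Stoichiometry / brightness-ratio / photon-count species filter.

    Keeps bursts whose stoichiometry (``S_corr`` when ``use_corrected`` and
    available, else ``S_app``) lies in ``s_range``, whose donor/acceptor
    brightness ratio ``(b_DD + b_DA)/b_AA`` lies in
    ``brightness_ratio_range``, and with at least ``min_photons`` raw photons.
    Filter values are recorded in ``attrs['filter']``.
    """
    lo, hi = s_range
    if not (0 <= lo < hi <= 1):
        raise ConfigurationError("s_range must satisfy 0 <= lo < hi <= 1")
    s_col = "S_corr" if (use_corrected and "S_corr" in table.columns) else "S_app"
    s = table[s_col].to_numpy(float) if len(table) else np.empty(0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = ((table["b_DD"] + table["b_DA"]) /
                 table["b_AA"]).to_numpy(float) if len(table) else np.empty(0)
    n_tot = (table[["n_DD", "n_DA", "n_AA"]].sum(axis=1).to_numpy()
             if len(table) else np.empty(0))
    keep = ((s >= lo) & (s <= hi) &
            (ratio >= brightness_ratio_range[0]) &
            (ratio <= brightness_ratio_range[1]) &
            (n_tot >= min_photons))
    out = table.loc[keep].reset_index(drop=True)
    out.attrs = dict(table.attrs)
    out.attrs["filter"] = {
        "s_range": [float(lo), float(hi)], "s_column": s_col,
        "brightness_ratio_range": [float(brightness_ratio_range[0]),
                                   float(brightness_ratio_range[1])],
        "min_photons": int(min_photons),
    }
    if len(out) == 0 and len(table) > 0:
        warnings.warn("species filter removed every burst")
    return out


def bva_scores(table: pd.DataFrame, stream: PhotonStream,
               photons_per_window: int = 5) -> pd.DataFrame:
    """Burst-variance (FRET fluctuation) analysis.

    For each burst the proximity ratio is computed over consecutive
    non-overlapping windows of ``photons_per_window`` donor-excitation
    photons (DD+DA only, standard for proximity-ratio fluctuation analysis).
    Returns per burst the mean windowed proximity ratio, the SD across
    windows, the binomial shot-noise limit ``sqrt(Ē(1−Ē)/n)`` and a
    ``dynamic`` flag (SD above the limit).  Bursts too short for a single
    window get NaN scores and ``undefined=True`` — flagged, never dropped.
    """
    n_win = int(photons_per_window)
    if n_win < 2:
        raise ConfigurationError("photons_per_window must be >= 2")
    ch = stream.channel
    out = {"pr_mean": [], "pr_sd": [], "shot_noise_sd": [],
           "dynamic": [], "undefined": []}
    for i0, i1 in zip(table["start_index"], table["stop_index"]):
        seg = ch[int(i0):int(i1) + 1]
        dex = seg[seg != AA]
        n_full = dex.size // n_win
        if n_full < 1:
            for k in ("pr_mean", "pr_sd", "shot_noise_sd"):
                out[k].append(np.nan)
            out["dynamic"].append(False)
            out["undefined"].append(True)
            continue
        w = (dex[:n_full * n_win] == DA).reshape(n_full, n_win)
        pr = w.mean(axis=1)
        e_bar = float(pr.mean())
        sd = float(pr.std(ddof=0))
        limit = np.sqrt(max(e_bar * (1.0 - e_bar), 0.0) / n_win)
        out["pr_mean"].append(e_bar)
        out["pr_sd"].append(sd)
        out["shot_noise_sd"].append(limit)
        out["dynamic"].append(sd > limit)
        out["undefined"].append(False)
    res = pd.DataFrame(out, index=table.index)
    res.attrs["photons_per_window"] = n_win
    return res


def write_burst_table(table: pd.DataFrame, tsv_path, provenance_path=None) -> None:
    """Write a burst table as TSV plus a JSON provenance sidecar."""
    table.to_csv(tsv_path, sep="\t", index=False)
    if provenance_path is not None:
        with open(provenance_path, "w") as fh:
            json.dump(table.attrs, fh, indent=2, default=str)


def read_burst_table(tsv_path, provenance_path=None) -> pd.DataFrame:
    table = pd.read_csv(tsv_path, sep="\t")
    if provenance_path is not None:
        with open(provenance_path) as fh:
            table.attrs.update(json.load(fh))
    return table
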