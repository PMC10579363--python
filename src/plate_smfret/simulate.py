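"""Synthetic photon-stream and titration-table generator with known ground truth.

The generator emulates the statistical structure that diffusion-based confocal
smFRET analysis assumes: single molecules traverse the observation volume in
~1 ms transits, emitting photons at a constant brightness while inside
(flat-top intensity profile), on top of uncorrelated Poisson background in all
three PIE channels.  During a transit a two-state molecule may interconvert
between its conformations; the state trajectory is simulated exactly as a
continuous-time Markov chain (Gillespie), and photons are split between donor
and acceptor channels according to the instantaneous FRET efficiency.

Detection imperfections (donor leakage α, acceptor direct excitation δ,
detection-efficiency ratio γ, excitation ratio β) are part of the forward
model so the correction-factor pipeline can be validated by round trip:
per state with efficiency E the channel intensities during transit are

    r_DD = Λ·(1 − E)
    r_AA = f_AA·γ·β·Λ            (acceptor-excitation probe; PIE)
    r_DA = Λ·(γ·E + α·(1 − E)) + δ·r_AA

with Λ the configured brightness and f_AA the PIE acceptor-direct fraction.
With α=δ=0 and γ=β=1 this reduces to the ideal binomial photon partitioning
by E.  Note β here absorbs the PIE duty-cycle factor f_AA when f_AA ≠ 1.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict, replace
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, LayoutError
from .photons import AA, DA, DD, PhotonStream

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_two_state_bursts",
    "simulate_plate_run",
    "simulate_titration_table",
    "well_seed",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of one simulated well.

    ``states`` lists the FRET states as ``(E_true, occupancy)`` pairs.  When
    the interconversion rates ``k_open`` (closed→open) and ``k_close``
    (open→closed) are nonzero, exactly two states must be given, the first
    being the *open* state; the static occupancies are then superseded by the
    equilibrium occupancy ``k_open/(k_open+k_close)``.
    """

    seed: int = 0
    duration: float = 60.0                      # s
    background_rates: tuple = (1000.0, 1000.0, 1000.0)  # photons/s (DD, DA, AA)
    burst_rate: float = 1.1                     # bursts/s (~1300 per 20 min)
    transit_mean: float = 1.0e-3                # s, mean transit duration T
    fixed_transit: bool = False                 # fixed duration instead of exponential
    brightness: float = 1.0e5                   # photons/s during transit
    states: tuple = ((0.15, 0.5), (0.80, 0.5))  # (E_true, occupancy)
    k_open: float = 0.0                         # 1/s, closed -> open
    k_close: float = 0.0                        # 1/s, open -> closed
    pie_fraction_aa: float = 1.0                # AA intensity fraction for double-labelled
    donor_only_fraction: float = 0.0
    acceptor_only_fraction: float = 0.0
    # detection imperfections (ground truth for the correction pipeline)
    alpha: float = 0.0                          # donor leakage into DA
    delta: float = 0.0                          # acceptor direct excitation
    gamma: float = 1.0                          # detection/quantum-yield ratio
    beta: float = 1.0                           # excitation ratio
    clock_period: float = 12.5e-9               # s per tick

    def __post_init__(self):
        rates = [self.duration, self.burst_rate, self.transit_mean,
                 self.brightness, self.k_open, self.k_close,
                 self.pie_fraction_aa, self.alpha, self.delta,
                 *self.background_rates]
        if not all(np.isfinite(rates)) or any(r < 0 for r in rates):
            raise ConfigurationError("rates and durations must be finite and >= 0")
        if self.gamma <= 0 or self.beta <= 0:
            raise ConfigurationError("gamma and beta must be positive")
        if not self.states:
            raise ConfigurationError("at least one FRET state required")
        occ = np.array([o for _, o in self.states], float)
        es = np.array([e for e, _ in self.states], float)
        if np.any(es < 0) or np.any(es > 1):
            raise ConfigurationError("state efficiencies must lie in [0, 1]")
        if abs(occ.sum() - 1.0) > 1e-9:
            raise ConfigurationError("state occupancies must sum to 1")
        if (self.k_open + self.k_close) > 0 and len(self.states) != 2:
            raise ConfigurationError("dynamic simulation requires exactly two states")
        if not (0 <= self.donor_only_fraction <= 1 and
                0 <= self.acceptor_only_fraction <= 1 and
                self.donor_only_fraction + self.acceptor_only_fraction <= 1):
            raise ConfigurationError("species fractions must lie in [0, 1] and sum <= 1")


@dataclass
class GroundTruth:
    """Per-burst truth recorded by the simulator (the oracle for recovery tests).

    ``per_burst`` columns: ``t_start``, ``transit`` (s), ``species``
    (double / donor_only / acceptor_only), ``n_switches``, one ``frac_state{i}``
    occupancy-fraction column per state, and ``e_true`` (time-averaged E).
    """

    per_burst: pd.DataFrame
    config: SimulationConfig

    def to_json(self, path) -> None:
        payload = {
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(self.config).items()},
            "per_burst": self.per_burst.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _channel_rates(cfg: SimulationConfig, e_true: float, species: str):
    """Mean detected intensities (r_DD, r_DA, r_AA) during transit."""
    lam = cfg.brightness
    if species == "donor_only":
        return lam, cfg.alpha * lam, 0.0
    if species == "acceptor_only":
        r_aa = cfg.pie_fraction_aa * cfg.gamma * cfg.beta * lam
        return 0.0, cfg.delta * r_aa, r_aa
    r_aa = cfg.pie_fraction_aa * cfg.gamma * cfg.beta * lam
    r_dd = lam * (1.0 - e_true)
    r_da = lam * (cfg.gamma * e_true + cfg.alpha * (1.0 - e_true)) + cfg.delta * r_aa
    return r_dd, r_da, r_aa


def _gillespie_trajectory(rng, state0: int, transit: float, k_open: float,
                          k_close: float):
    """Exact two-state CTMC path within one transit.

    Returns (segments, n_switches) with segments a list of
    (t0, t1, state_index); state 0 is open (leaves at rate k_close),
    state 1 closed (leaves at rate k_open).
    """
    out_rate = (k_close, k_open)
    t, s = 0.0, state0
    segments = []
    n_switch = 0
    while t < transit:
        rate = out_rate[s]
        dwell = rng.exponential(1.0 / rate) if rate > 0 else np.inf
        t1 = min(t + dwell, transit)
        segments.append((t, t1, s))
        if t1 < transit:
            s = 1 - s
            n_switch += 1
        t = t1
    return segments, n_switch


def simulate_two_state_bursts(config: SimulationConfig):
    """Simulate one well and return ``(PhotonStream, GroundTruth)``.

    Burst start times form a Poisson process at ``burst_rate``; transit
    durations are exponential with mean ``transit_mean`` (or fixed when
    ``fixed_transit``).  Within each transit the conformational trajectory is
    simulated exactly and photons are generated as piecewise-homogeneous
    Poisson processes per channel; Poisson background spans the full
    acquisition.  Identical ``(config, seed)`` reproduce the stream
    bit-for-bit.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    dynamic = (cfg.k_open + cfg.k_close) > 0
    es = np.array([e for e, _ in cfg.states], float)
    occ = np.array([o for _, o in cfg.states], float)
    if dynamic:
        p_open = cfg.k_open / (cfg.k_open + cfg.k_close)
        occ = np.array([p_open, 1.0 - p_open])

    n_bursts = rng.poisson(cfg.burst_rate * cfg.duration)
    t_starts = np.sort(rng.uniform(0.0, cfg.duration, n_bursts))
    if cfg.fixed_transit:
        transits = np.full(n_bursts, cfg.transit_mean)
    else:
        transits = rng.exponential(cfg.transit_mean, n_bursts)

    p_do, p_ao = cfg.donor_only_fraction, cfg.acceptor_only_fraction
    species_idx = rng.choice(3, size=n_bursts, p=[1.0 - p_do - p_ao, p_do, p_ao])
    species_names = np.array(["double", "donor_only", "acceptor_only"])

    times_parts, chan_parts = [], []
    records = []
    n_states = len(cfg.states)
    for i in range(n_bursts):
        t0, transit = t_starts[i], transits[i]
        sp = species_names[species_idx[i]]
        frac = np.zeros(n_states)
        n_switch = 0
        if sp == "double":
            if dynamic:
                s0 = 0 if rng.random() < occ[0] else 1
                segments, n_switch = _gillespie_trajectory(
                    rng, s0, transit, cfg.k_open, cfg.k_close)
            else:
                s0 = rng.choice(n_states, p=occ)
                segments = [(0.0, transit, s0)]
            for a, b, s in segments:
                frac[s] += (b - a) / transit if transit > 0 else 0.0
            e_true = float(frac @ es)
        else:
            segments = [(0.0, transit, -1)]
            e_true = np.nan

        for a, b, s in segments:
            e_seg = es[s] if s >= 0 else 0.0
            rates = _channel_rates(cfg, e_seg, sp)
            dt = b - a
            for ch, r in zip((DD, DA, AA), rates):
                n = rng.poisson(r * dt)
                if n:
                    times_parts.append(t0 + a + rng.uniform(0.0, dt, n))
                    chan_parts.append(np.full(n, ch, dtype=np.int8))
        rec = {"t_start": t0, "transit": transit, "species": sp,
               "n_switches": n_switch, "e_true": e_true}
        rec.update({f"frac_state{j}": frac[j] for j in range(n_states)})
        records.append(rec)

    # Poisson background over the full acquisition, per channel
    for ch, r in zip((DD, DA, AA), cfg.background_rates):
        n = rng.poisson(r * cfg.duration)
        if n:
            times_parts.append(rng.uniform(0.0, cfg.duration, n))
            chan_parts.append(np.full(n, ch, dtype=np.int8))

    if times_parts:
        times = np.concatenate(times_parts)
        chans = np.concatenate(chan_parts)
        order = np.argsort(times, kind="stable")
        times, chans = times[order], chans[order]
        ticks = np.floor(times / cfg.clock_period).astype(np.int64)
        # enforce strictly increasing ticks with minimal forward bumps
        n = ticks.size
        ticks = np.maximum.accumulate(ticks - np.arange(n)) + np.arange(n)
    else:
        ticks = np.empty(0, dtype=np.int64)
        chans = np.empty(0, dtype=np.int8)

    stream = PhotonStream(ticks, chans, clock_period=cfg.clock_period,
                          duration=cfg.duration)
    cols = ["t_start", "transit", "species", "n_switches"] + \
        [f"frac_state{j}" for j in range(n_states)] + ["e_true"]
    truth = GroundTruth(pd.DataFrame(records, columns=cols), cfg)
    return stream, truth


def well_seed(master_seed: int, well_id: str) -> int:
    """Deterministic, order-independent per-well seed (< 2**31)."""
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(well_id.encode())])
    return int(ss.generate_state(1, np.uint32)[0] % (2 ** 31))


def simulate_plate_run(layout: pd.DataFrame,
                       config_for: Callable[[pd.Series], SimulationConfig],
                       master_seed: int = 0) -> dict:
    """Simulate every well of a plate.

    ``layout`` must carry a ``well_id`` column; ``config_for`` maps a layout
    row (with its condition variables) to a :class:`SimulationConfig`.  Each
    well gets a seed derived deterministically from ``(master_seed, well_id)``,
    so results are independent of processing order.

    Returns ``{well_id: (PhotonStream, GroundTruth)}``.
    """
    if "well_id" not in layout.columns:
        raise LayoutError("layout must have a well_id column")
    out = {}
    for _, row in layout.iterrows():
        wid = str(row["well_id"])
        try:
            cfg = config_for(row)
        except KeyError as exc:
            raise LayoutError(f"missing condition variable for well {wid}: {exc}")
        cfg = replace(cfg, seed=well_seed(master_seed, wid))
        stream, truth = simulate_two_state_bursts(cfg)
        stream.well_id = wid
        out[wid] = (stream, truth)
    return out


def _model_fractions(model_kind: str, params: Mapping, conc_row) -> np.ndarray:
    from . import equilibrium as eq

    if model_kind == "speciation":
        return np.array(eq.speciation_fractions(
            float(conc_row), params["c_half"], params["c_star_half"],
            params["hill_m"], params["hill_n"]))
    if model_kind == "six_state":
        s_conc, r_conc = float(conc_row[0]), float(conc_row[1])
        model = params["model"] if "model" in params else eq.CompetitionModel(**params)
        return model.fractions(s_conc, r_conc)
    if model_kind == "lem":
        f_u = eq.lem_fraction_unfolded(
            float(conc_row), params["c_half"], params["m_value"],
            params.get("temperature", 298.15))
        return np.array([1.0 - f_u, f_u])
    if model_kind == "dose_response":
        c, ec50, h = float(conc_row), params["ec50"], params["hill_slope"]
        f = params["f_min"] + (params["f_max"] - params["f_min"]) * \
            c ** h / (ec50 ** h + c ** h)
        return np.array([1.0 - f, f])
    raise ConfigurationError(f"unknown model_kind: {model_kind!r}")


_FRACTION_COLUMNS = {
    "speciation": ["f_free", "f_65", "f_35"],
    "lem": ["f_folded", "f_unfolded"],
    "dose_response": ["f_open", "f_folded"],
}


def simulate_titration_table(model_kind: str, params: Mapping,
                             concentrations, n_bursts_per_well=None,
                             seed: int = 0) -> pd.DataFrame:
    """Per-well fraction table with multinomial counting noise.

    For each concentration the state fractions of the chosen equilibrium
    model are computed, ``n_bursts_per_well`` bursts are assigned to states
    by a multinomial draw, and the observed fractions plus their binomial
    counting SD are tabulated.  ``n_bursts_per_well=None`` gives the
    noiseless analytic table (SD column set to 0).  The exact generating
    parameters are carried in ``df.attrs``.
    """
    rng = np.random.default_rng(seed)
    if model_kind == "six_state":
        conc = np.atleast_2d(np.asarray(concentrations, float))
        conc_cols = {"SSB_M": conc[:, 0], "RecA_M": conc[:, 1]}
        from . import equilibrium as eq
        frac_cols = list(eq.SIX_STATES)
        rows_iter = list(conc)
    else:
        conc = np.asarray(concentrations, float).ravel()
        name = {"speciation": "SSB_M", "lem": "denaturant_M",
                "dose_response": "drug_M"}.get(model_kind)
        if name is None:
            raise ConfigurationError(f"unknown model_kind: {model_kind!r}")
        conc_cols = {name: conc}
        frac_cols = _FRACTION_COLUMNS[model_kind]
        rows_iter = list(conc)

    frac_rows, sd_rows = [], []
    for row in rows_iter:
        f = _model_fractions(model_kind, params, row)
        if n_bursts_per_well is None:
            frac_rows.append(f)
            sd_rows.append(np.zeros_like(f))
        else:
            n = int(n_bursts_per_well)
            counts = rng.multinomial(n, f / f.sum())
            fh = counts / n
            sd = np.sqrt(np.maximum(fh * (1 - fh), 0.0) / n)
            sd_rows.append(np.maximum(sd, 1.0 / (2 * n)))
            frac_rows.append(fh)

    df = pd.DataFrame(conc_cols)
    fr = np.asarray(frac_rows)
    for j, c in enumerate(frac_cols):
        df[c] = fr[:, j]
        df["sd_" + c] = np.asarray(sd_rows)[:, j]
    df["n_bursts"] = np.nan if n_bursts_per_well is None else int(n_bursts_per_well)
    df.attrs["model_kind"] = model_kind
    df.attrs["params"] = dict(params)
    df.attrs["seed"] = seed
    return df
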