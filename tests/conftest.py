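import numpy as np
import pytest

from plate_smfret import bursts as bp
from plate_smfret import simulate as sim


@pytest.fixture(scope="session")
def static_two_pop():
    """Static two-population well (no dynamics, no detection artefacts)."""
    cfg = sim.SimulationConfig(
        seed=11, duration=120.0, burst_rate=5.0,
        states=((0.15, 0.5), (0.80, 0.5)),
        background_rates=(300.0, 300.0, 300.0))
    stream, truth = sim.simulate_two_state_bursts(cfg)
    return cfg, stream, truth


@pytest.fixture(scope="session")
def static_burst_table(static_two_pop):
    _, stream, _ = static_two_pop
    bg = bp.estimate_background(stream)
    return bp.find_bursts(stream, background_rates=bg)


@pytest.fixture(scope="session")
def calibration_well():
    """Dual-population well with donor-only/acceptor-only species and known
    non-trivial correction factors (the correction-factor ground truth)."""
    cfg = sim.SimulationConfig(
        seed=21, duration=180.0, burst_rate=5.0,
        states=((0.15, 0.5), (0.80, 0.5)),
        donor_only_fraction=0.15, acceptor_only_fraction=0.15,
        alpha=0.05, delta=0.06, gamma=0.9, beta=1.1,
        background_rates=(300.0, 300.0, 300.0))
    stream, truth = sim.simulate_two_state_bursts(cfg)
    bg = bp.estimate_background(stream)
    table = bp.find_bursts(stream, background_rates=bg)
    return cfg, table


@pytest.fixture(scope="session")
def dynamic_well():
    """Two-state interconverting well, k_open=1.5/ms, k_close=1.0/ms, T=1 ms."""
    cfg = sim.SimulationConfig(
        seed=31, duration=600.0, burst_rate=5.0, fixed_transit=True,
        transit_mean=1e-3, states=((0.15, 0.5), (0.80, 0.5)),
        k_open=1500.0, k_close=1000.0,
        background_rates=(300.0, 300.0, 300.0))
    stream, truth = sim.simulate_two_state_bursts(cfg)
    bg = bp.estimate_background(stream)
    table = bp.find_bursts(stream, background_rates=bg)
    return cfg, stream, truth, table


def random_stream(rng, n_photons, duration=1.0, clock_period=12.5e-9):
    """Unstructured random photon stream (for oracle comparisons)."""
    from plate_smfret.photons import PhotonStream
    ticks = np.sort(rng.integers(0, int(duration / clock_period),
                                 size=n_photons))
    n = ticks.size
    ticks = np.maximum.accumulate(ticks - np.arange(n)) + np.arange(n)
    chan = rng.integers(0, 3, size=n_photons).astype(np.int8)
    return PhotonStream(ticks, chan, clock_period=clock_period,
                        duration=duration)


def brute_force_burst_search(stream, window, min_rate_photons,
                             min_total_photons):
    """Independent O(n^2) implementation of the all-photon sliding-window
    burst criterion; returns a list of (start_index, stop_index) pairs."""
    t = stream.timestamps.astype(float) * stream.clock_period
    n = t.size
    in_burst = np.zeros(n, dtype=bool)
    half = window / 2.0
    for i in range(n):
        count = 0
        for j in range(n):
            if abs(t[j] - t[i]) <= half:
                count += 1
        in_burst[i] = count >= min_rate_photons
    bursts = []
    i = 0
    while i < n:
        if in_burst[i]:
            j = i
            while j + 1 < n and in_burst[j + 1]:
                j += 1
            if j - i + 1 >= min_total_photons:
                bursts.append((i, j))
            i = j + 1
        else:
            i += 1
    return bursts


def brute_force_burst_search_fast(stream, window, min_rate_photons,
                                  min_total_photons):
    """Matrix-form O(n^2) oracle (same criterion, vectorised) for larger
    streams where the double loop would dominate the test budget."""
    t = stream.timestamps.astype(float) * stream.clock_period
    half = window / 2.0
    counts = (np.abs(t[:, None] - t[None, :]) <= half).sum(axis=1)
    in_burst = counts >= min_rate_photons
    bursts = []
    i, n = 0, t.size
    while i < n:
        if in_burst[i]:
            j = i
            while j + 1 < n and in_burst[j + 1]:
                j += 1
            if j - i + 1 >= min_total_photons:
                bursts.append((i, j))
            i = j + 1
        else:
            i += 1
    return bursts
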