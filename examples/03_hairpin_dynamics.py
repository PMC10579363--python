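"""Millisecond hairpin kinetics: from photon bursts to salt-dependence models.

Part 1 simulates a well of two-state molecules interconverting during their
~1-ms transits (k_open=1.5/ms, k_close=1.0/ms), detects the bridge
population, and extracts both rates from the dynamic histogram fit.

Part 2 fits the salt dependence of a full 96-condition rate table generated
from the hairpin model (linear opening; closing driven by the worm-like-chain
apparent local concentration of the stem ends) and runs the bootstrap
sampling-density analysis.
"""

import numpy as np
import pandas as pd

from plate_smfret import bursts as bp
from plate_smfret import kinetics as kin
from plate_smfret import mixtures as mx
from plate_smfret import simulate as sim

cfg = sim.SimulationConfig(seed=3, duration=300.0, burst_rate=5.0,
                           fixed_transit=True, transit_mean=1e-3,
                           states=((0.15, 0.5), (0.80, 0.5)),
                           k_open=1500.0, k_close=1000.0,
                           background_rates=(300.0, 300.0, 300.0))
stream, _ = sim.simulate_two_state_bursts(cfg)
table = bp.find_bursts(stream,
                       background_rates=bp.estimate_background(stream))
fit = mx.fit_dynamic_three_gaussian(mx.build_histogram(table),
                                    table["duration"].mean(),
                                    static_means_init=(0.15, 0.80))
print(f"{len(table)} bursts; recovered k_open = {fit.k_open:.2f}/ms "
      f"(truth 1.50), k_close = {fit.k_close:.2f}/ms (truth 1.00)")
a = dict(zip(fit.components["label"], fit.components["amplitude"]))
print(f"population amplitudes: open {a['open']:.2f}, "
      f"bridge {a['bridge']:.2f} (molecules switching mid-transit), "
      f"closed {a['closed']:.2f}")

# --- salt dependence ------------------------------------------------------
truth = kin.HairpinKineticsModel(k_open_0=1.89, m_open=-1.31,
                                 k_close_prime=0.305e6)
rng = np.random.default_rng(4)
salt = np.linspace(0.1, 1.0, 96)
rates = pd.DataFrame({
    "salt_M": salt,
    "k_open": truth.k_open(salt) * (1 + 0.05 * rng.standard_normal(96)),
    "k_open_err": 0.05 * truth.k_open(salt),
    "k_close": truth.k_close(salt) * (1 + 0.05 * rng.standard_normal(96)),
    "k_close_err": 0.05 * truth.k_close(salt),
})
model = kin.fit_hairpin_salt_dependence(rates)
lo, hi = model.closing_rate_bounds()
print(f"\nopening: k0 = {model.k_open_0:.2f}/ms (truth 1.89), "
      f"slope = {model.m_open:.2f}/ms/M (truth -1.31)")
print(f"closing: k' = {model.k_close_prime / 1e6:.3f}x10^6 /s/M "
      f"(truth 0.305); bounds from the persistence-length limits: "
      f"[{lo:.2f}, {hi:.2f}]/ms")
sd = kin.bootstrap_condition_sampling(rates, [5, 70], n_boot=300, seed=5)
print(f"bootstrap SD of k0: {sd.loc[5]:.3f} at 5 conditions vs "
      f"{sd.loc[70]:.3f} at 70 — dense sampling pays off "
      f"{sd.loc[5] / sd.loc[70]:.0f}-fold")
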