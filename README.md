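# plate-smfret

Analysis stack for **multiwell-plate confocal single-molecule FRET (smFRET)
screening** with pulsed-interleaved excitation (PIE): from raw time-tagged
photon streams per well, through burst search and FRET corrections, to the
kinetic, thermodynamic, competitive-binding and dose–response models that
turn a 96-well gradient into molecular parameters.

Diffusion-based smFRET detects single molecules as millisecond photon
*bursts* while they cross a confocal volume. Per burst, PIE channel counts
(DD: donor-excited donor emission, DA: FRET-sensitized acceptor emission,
AA: acceptor-excited acceptor emission) yield the FRET efficiency
`E = F_DA/(F_DA + F_DD)` and stoichiometry
`S = (F_DD + F_DA)/(F_DD + F_DA + F_AA)` after the standard corrections
(donor leakage α, acceptor direct excitation δ, detection ratio γ,
excitation ratio β). A plate of wells, each a different condition
([NaCl], [GdmCl], [SSB], [RecA], [drug]), then feeds plate-level models:

- **two-state millisecond kinetics** from the dynamic E-histogram: molecules
  that switch conformation mid-transit form a *bridge* population whose
  amplitude `A_B = 1 − p_O·e^(−k_close·T) − p_C·e^(−k_open·T)` encodes the
  exchange rates;
- **hairpin salt dependence**: linear opening `k_open(c) = k⁰ + m·c`;
  closing driven by the worm-like-chain apparent local concentration
  `[A] = 1/(N_A·(4/3)πR³)` with
  `R² = 2·l_p·l_c − 2·l_p²·(1 − e^(−l_c/l_p))` and a salt-dependent
  persistence length `l_p(I)`;
- **equilibrium unfolding** by the linear extrapolation method (LEM),
  `f_U = 1/(1 + e^{m([D]_1/2 − [D])/RT})`, `ΔG_H2O = m·[D]_1/2`, plus a
  mean-field coil–globule (Sanchez-type) analysis of unfolded-chain
  dimensions;
- **competitive binding**: partition-function speciation of two SSB binding
  modes and a six-state SSB/RecA competition scheme, with model selection
  over state/observable configurations by reduced χ²;
- **dose–response screening**: Hill fits yielding EC50, with explicit
  concentration exclusion rules.

A first-class synthetic-data module simulates the whole measurement
(diffusing bursts with exact Gillespie two-state trajectories, binomial
photon partitioning by E(t), PIE acceptor-direct counts, Poisson background,
per-plate condition gradients) with full ground truth, so every stage of the
stack is testable without an instrument.

## Worked example

```python
from plate_smfret import simulate as sim, bursts as bp, mixtures as mx

cfg = sim.SimulationConfig(seed=3, duration=300.0, burst_rate=5.0,
                           fixed_transit=True, transit_mean=1e-3,
                           states=((0.15, 0.5), (0.80, 0.5)),
                           k_open=1500.0, k_close=1000.0,
                           background_rates=(300.0, 300.0, 300.0))
stream, _ = sim.simulate_two_state_bursts(cfg)
table = bp.find_bursts(stream, background_rates=bp.estimate_background(stream))
fit = mx.fit_dynamic_three_gaussian(mx.build_histogram(table),
                                    table["duration"].mean(),
                                    static_means_init=(0.15, 0.80))
print(len(table), round(fit.k_open, 2), round(fit.k_close, 2))
```

prints

```
1417 1.54 0.94
```

i.e. 1417 detected bursts, and opening/closing rates of 1.54 and 0.94 per
millisecond recovered from the histogram alone — within a few percent of the
simulated truth (1.50, 1.00). The scripts in `examples/` walk through each
capability the same way (burst search, correction-factor derivation, hairpin
salt models, LEM unfolding and chain dimensions, SSB/RecA competition,
dose–response screening, the full plate pipeline) and print the numbers next
to their generating truths.

A thin CLI mirrors the library for shell use:
`plate-smfret simulate|bursts|correct|run|fit-hairpin|fit-unfolding|fit-binding|fit-competition|fit-dose`
(see `plate-smfret --help`).

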