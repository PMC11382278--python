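# Desk-scale surrogate of the dopaquinone + hydroxide rate-limiting step:
# a one-dimensional Marcus-like pair of harmonic diabats, calibrated to the
# gas-phase reference energetics, sampled over 51 lambda frames, and
# converted to pH-dependent kinetics with the experimental pKa values.

system:
  kind: marcus
  k1: 200.0        # kcal/mol/A^2
  k2: 200.0
  x1: 0.0          # A
  x2: 1.0
  delta_e: 0.0     # bare diabatic asymmetry, kcal/mol (alpha comes from calibration)
  mass: 12.0       # amu
  # association analogue of the explicit-system restraints: a flat-bottom
  # window spanning the reactive range of the coordinate plus a soft
  # positional restraint (force constants as in the reference protocol)
  restraints:
    - kind: flat_bottom_distance
      force_constant: 10.0   # kcal/mol/A^2; zero inside [-0.5, 1.5] A
      lo: -0.5
      hi: 1.5
    - kind: positional
      force_constant: 0.1
      target: 0.5

evb:
  targets:
    dg_act_gas: 1.28      # kcal/mol
    dg_rxn_gas: -47.04

schedule:
  n_lambda: 51
  n_steps: 10000    # per frame (production scale-down of 0.1 ns/frame)
  dt: 1.0           # fs
  temperature: 310.0
  friction: 0.2     # fs^-1
  n_replicas: 3
  seed: 2024
  stride: 10
  burn_in_frac: 0.2

kinetics:
  pKa_water: 15.7
  pKa_amine: 8.11
  pH: 7.4
  temperature: 310.15
  kT: 0.617               # conventional rounded kT at 37 degC; or "physical"
  rate_constant: 2.56e-7  # experimental, s^-1

profile:
  bin_width: 2.0          # energy-gap bin width, kcal/mol
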