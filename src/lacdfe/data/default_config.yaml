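# Default model configuration for the lac-operon DFE pipeline.
#
# Units: concentrations in nM, time in minutes, fitness in benefit units
# (nM lactose metabolized per minute).  These values are package defaults
# chosen for biological plausibility; they are NOT a published calibration.
fixed:
  kd1: 0.02        # LacZ degradation/dilution rate (1/min)
  kd2: 0.02        # LacY degradation/dilution rate (1/min)
  kd3: 0.02        # LacI degradation/dilution rate (1/min)
  K: 100.0         # LacI-lactose binding half-saturation (nM)
  k1: 60.0         # maximal lactose influx per LacY (1/min)
  k2: 1.0e+5       # influx half-saturation w.r.t. external lactose (nM)
  k3: 60.0         # maximal lactose metabolism per LacZ (1/min)
  k4: 500.0        # metabolism half-saturation w.r.t. internal lactose (nM)
  lac_out: 1.0e+5  # constant external lactose (nM); high-lactose environment
cost:
  alpha: 300.0     # cost per protein molecule per unit time
  # per-protein factors = (length relative to LacZ) x degradation constant
  # LacZ 1023 aa, LacY 417 aa, LacI 360 aa
  alpha_z: 0.02
  alpha_y: 0.008152492668621702
  alpha_i: 0.007038123167155425
mutable:
  bas1: {min: 0.001, max: 1.0}     # basal lac-promoter activity (nM/min)
  bas2: {min: 0.01, max: 20.0}     # basal lacI-promoter activity (nM/min)
  Ky:   {min: 1.0, max: 2000.0}    # maximal-activity numerator (nM^2/min)
  Kmy:  {min: 1.0, max: 200.0}     # promoter-activity half-saturation (nM)
  Kt:   {min: 0.05, max: 1.5}      # LacY/LacZ translational capacity (-)
kernel:
  cv: 0.1
  out_of_range_policy: resample
  distribution: normal
solver:
  rtol: 1.0e-9
  max_newton: 80
  fallback_horizon: 1.0e+5
experiment:
  fractions: [0.001, 0.1, 0.5]
  count: 100
  target_tolerance: 0.01
  n_mutations: 10000
  n_backgrounds: 4000
  neutral_epsilon: 0.0
  fmax_starts: 32
  seed: 0
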