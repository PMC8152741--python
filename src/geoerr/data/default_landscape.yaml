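# Default 15-metal urban soil-survey parameterization.
#
# Per metal: published descriptive statistics of XRF analytical assay errors
# (mean and standard deviation in ppm, three-parameter log-normal offset
# delta in ppm), a varimax-rotated 4-factor loading row describing the
# correlation structure among metal errors, and a maximum-permissible-level
# (MPL) threshold in ppm for exceedance counting.
#
# factor_rho: simultaneous-autoregressive spatial autocorrelation parameters
# for the four tract-level factor-score surfaces.
grid: {rows: 3, cols: 19}          # 57 tracts
samples_per_tract: 58              # mean of a truncated Poisson, min 5
factor_rho: [0.264, 0.435, 0.527, 0.484]
value_coupling: 0.5
value_noise_sd: 0.3
metals:
  As: {mean: 15.65,  sd: 10.02, delta: -5.8,  mpl: 4.5,    loadings: [0.193, 0.203, 0.957, 0.026]}
  Cr: {mean: 106.98, sd: 9.13,  delta: -29.4, mpl: 3.8,    loadings: [0.893, 0.367, 0.207, 0.077]}
  Co: {mean: 140.88, sd: 15.83, delta: 75.6,  mpl: 24.0,   loadings: [0.416, 0.835, 0.273, 0.071]}
  Cu: {mean: 55.30,  sd: 4.94,  delta: -26.9, mpl: 3.5,    loadings: [0.960, 0.157, 0.178, -0.027]}
  Fe: {mean: 375.82, sd: 42.74, delta: 283.6, mpl: 22979.0, loadings: [0.392, 0.847, 0.266, 0.058]}
  Pb: {mean: 19.31,  sd: 12.81, delta: -6.8,  mpl: 55.0,   loadings: [0.188, 0.199, 0.959, 0.028]}
  Mn: {mean: 136.31, sd: 13.19, delta: -16.7, mpl: 200.0,  loadings: [0.520, 0.694, 0.304, 0.125]}
  Hg: {mean: 10.46,  sd: 0.86,  delta: -5.0,  mpl: 1.9,    loadings: [0.944, 0.192, 0.205, -0.010]}
  Mo: {mean: 4.29,   sd: 0.31,  delta: 138.2, mpl: 253.0,  loadings: [0.191, 0.119, 0.085, 0.958]}
  Ni: {mean: 72.86,  sd: 5.64,  delta: -24.7, mpl: 2.6,    loadings: [0.942, 0.244, 0.165, -0.013]}
  Rb: {mean: 4.77,   sd: 0.53,  delta: 8.1,   mpl: 68.0,   loadings: [-0.419, 0.779, 0.042, -0.073]}
  Se: {mean: 7.52,   sd: 0.73,  delta: -4.3,  mpl: 0.11,   loadings: [0.852, 0.202, 0.441, 0.009]}
  Sr: {mean: 8.32,   sd: 1.64,  delta: -4.5,  mpl: 175.0,  loadings: [0.892, -0.286, 0.100, -0.073]}
  Zn: {mean: 40.90,  sd: 10.39, delta: -25.0, mpl: 16.0,   loadings: [0.640, 0.212, 0.702, -0.053]}
  Zr: {mean: 15.78,  sd: 1.70,  delta: 0.0,   mpl: 267.0,  loadings: [-0.242, -0.047, -0.056, 0.952]}
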