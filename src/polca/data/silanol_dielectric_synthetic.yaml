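# SYNTHETIC / RECONSTRUCTED inputs for the dielectric-constant correction
# of the two liquid silanols.
#
# eps_inf is the squared sodium-D refractive index (literature n_D values).
# The dipole ratio mu_liq / mu_model is NOT a primary measurement: the
# per-compound liquid and model dipole moments live in supplementary
# tabulations that are not shipped with this package, so the ratio here is
# back-derived from the published (uncorrected, corrected) dielectric pairs
# and serves only to demonstrate and regression-test the correction formula,
# not as an independent prediction.
trimethylsilanol:
  n_d: 1.3880
  eps_simul: 2.85
  mu_ratio: 1.4544166
  eps_corrected_published: 5.84
  eps_experimental: 7.17
triethylsilanol:
  n_d: 1.4330
  eps_simul: 1.39
  mu_ratio: 0.9955142
  eps_corrected_published: 2.44
  eps_experimental: 2.66
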