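# Tuned excitable healthy exemplar: a single stable focus close to the
# Hopf bifurcation; small cytokine-A pulses are amplified ~450-fold
# relative to the same pulse against linear clearance alone, and the
# system always returns to the same homeostatic point.
# Provenance: search_regimes(DEFAULT_BOUNDS, n_samples=5000, seed=0)
# oscillatory sample index 3214, with the A-channel rates (qmax_A,
# uptake_A, clearance_A) scaled by 0.0218 to move the equilibrium just
# to the stable side of the Hopf point (leading Re = -0.021).
production_A:
  max_rate: 0.0072556098801412556
  activator_dissociation: []
  inhibitor_dissociation:
  - 2.1779040353271486
  basal_rate: 7.255609880141256e-07
  hill: 1.0
production_B:
  max_rate: 17.282454622469615
  activator_dissociation:
  - 0.08874863425717554
  inhibitor_dissociation: []
  basal_rate: 0.0017282454622469616
  hill: 1.0
receptor_A:
  total_receptors: 1.0
  ligand_dissociation: 0.06649305347572912
  internalization_rate_bound: 3.327692402532568
  internalization_rate_free: 0.01
  recovery_rate: 0.10756928217382848
  uptake_normalization: 0.6023245806374252
receptor_B:
  total_receptors: 1.0
  ligand_dissociation: 2.798081876311647
  internalization_rate_bound: 0.600149725997211
  internalization_rate_free: 0.01
  recovery_rate: 0.6627665319904231
  uptake_normalization: 5.818533091379865
linear_clearance_A: 0.03992286107166514
linear_clearance_B: 0.03652033080244226
self_activation_A: false
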