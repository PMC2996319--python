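# Pure oscillatory exemplar: a single unstable equilibrium surrounded by
# a stable limit cycle; no stable equilibrium anywhere.
# Provenance: search_regimes(DEFAULT_BOUNDS, n_samples=5000, seed=0),
# sample index 3214, the largest-margin oscillatory hit.
production_A:
  max_rate: 0.3328261412908833
  activator_dissociation: []
  inhibitor_dissociation:
  - 2.1779040353271486
  basal_rate: 3.3282614129088326e-05
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
  uptake_normalization: 27.629567919147945
receptor_B:
  total_receptors: 1.0
  ligand_dissociation: 2.798081876311647
  internalization_rate_bound: 0.600149725997211
  internalization_rate_free: 0.01
  recovery_rate: 0.6627665319904231
  uptake_normalization: 5.818533091379865
linear_clearance_A: 1.8313239023699606
linear_clearance_B: 0.03652033080244226
self_activation_A: false
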