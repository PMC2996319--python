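# Monostable homeostasis exemplar: exactly one equilibrium, stable.
# Provenance: search_regimes(DEFAULT_BOUNDS, n_samples=5000, seed=0),
# sample index 2772, selected among monostable hits for an interior
# equilibrium (both concentrations > 0.2) with the largest stability
# margin (3.04) and a non-monotone A-uptake (ki_bound_A >> kr_A).
production_A:
  max_rate: 7.9831964195879985
  activator_dissociation: []
  inhibitor_dissociation:
  - 1.2109605219336537
  basal_rate: 0.0007983196419587998
  hill: 1.0
production_B:
  max_rate: 2.0261286679047354
  activator_dissociation:
  - 4.855504729908306
  inhibitor_dissociation: []
  basal_rate: 0.00020261286679047356
  hill: 1.0
receptor_A:
  total_receptors: 1.0
  ligand_dissociation: 2.947079201571537
  internalization_rate_bound: 2.2384544132387845
  internalization_rate_free: 0.01
  recovery_rate: 1.4925392890455662
  uptake_normalization: 0.9654893270883289
receptor_B:
  total_receptors: 1.0
  ligand_dissociation: 8.430691958528728
  internalization_rate_bound: 7.672720380522903
  internalization_rate_free: 0.01
  recovery_rate: 10.515341536981538
  uptake_normalization: 8.398738708214372
linear_clearance_A: 2.9823808983234295
linear_clearance_B: 2.2084821799589514
self_activation_A: false
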