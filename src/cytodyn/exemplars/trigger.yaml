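# Bistable trigger exemplar: three equilibria, two stable (H1 low/H3
# high) separated by a saddle.  An A-pulse (amplitude >= 0.02, duration
# 5) switches H1 -> H3; a B-pulse switches H3 -> H1.
# Provenance: search_regimes(DEFAULT_BOUNDS, n_samples=5000, seed=0),
# sample index 395, the largest-margin trigger hit whose two stable
# states are ordered low/low vs high/high in both cytokines.
production_A:
  max_rate: 0.17001846324365044
  activator_dissociation: []
  inhibitor_dissociation:
  - 0.15927316028845284
  basal_rate: 1.7001846324365046e-05
  hill: 1.0
production_B:
  max_rate: 6.5361554655036995
  activator_dissociation:
  - 2.1205849658175158
  inhibitor_dissociation: []
  basal_rate: 0.00065361554655037
  hill: 1.0
receptor_A:
  total_receptors: 1.0
  ligand_dissociation: 0.15104817814385174
  internalization_rate_bound: 23.73075847112558
  internalization_rate_free: 0.01
  recovery_rate: 1.0980000011340911
  uptake_normalization: 14.669116502824156
receptor_B:
  total_receptors: 1.0
  ligand_dissociation: 6.170764019740275
  internalization_rate_bound: 15.952481157981477
  internalization_rate_free: 0.01
  recovery_rate: 31.460709220673547
  uptake_normalization: 0.052530519110282635
linear_clearance_A: 0.683311856314885
linear_clearance_B: 2.4038515151078252
self_activation_A: false
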