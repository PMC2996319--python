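# Coexisting regime exemplar: a stable node at high concentrations
# together with a limit cycle around an unstable focus at low
# concentrations (saddle in between).  A-pulses of amplitude 0.1
# (duration 5) applied on-cycle escape to the stable point at any phase.
# Provenance: random search for the stable+saddle+unstable-focus
# skeleton (log-uniform prior with both receptor channels in the
# internalization-dominant regime, numpy Generator seed 23, sample 2700
# of 4000), then continuation in the B-channel time scale (qmax_B,
# uptake_B, clearance_B scaled by 7.0) into the middle of the window in
# which the cycle exists (window approx. [5.5, 8.2]).
production_A:
  max_rate: 0.6168038724427439
  activator_dissociation: []
  inhibitor_dissociation:
  - 0.3694416630141815
  basal_rate: 6.16803872442744e-05
  hill: 1.0
production_B:
  max_rate: 3.8412835799316816
  activator_dissociation:
  - 0.035022007961469405
  inhibitor_dissociation: []
  basal_rate: 0.00038412835799316817
  hill: 1.0
receptor_A:
  total_receptors: 1.0
  ligand_dissociation: 0.7341083945065726
  internalization_rate_bound: 17.112767231330636
  internalization_rate_free: 0.01
  recovery_rate: 0.3394329976790658
  uptake_normalization: 8.979428188329079
receptor_B:
  total_receptors: 1.0
  ligand_dissociation: 0.859760549415012
  internalization_rate_bound: 45.21016839418925
  internalization_rate_free: 0.01
  recovery_rate: 0.1640000682360274
  uptake_normalization: 8.495862335647983
linear_clearance_A: 0.018311381715814635
linear_clearance_B: 0.32018124550232197
self_activation_A: false
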