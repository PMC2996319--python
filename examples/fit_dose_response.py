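"""Calibrate a production law to a noisy synthetic dose-response table.

Generates a dose-response table (output cytokine concentration vs input
cytokine dose) with 10% multiplicative noise from known ground-truth
parameters, then recovers the maximal production rate and the activation
constant by box-constrained multi-start least squares.
"""

from cytodyn import ProductionParams, fit_dose_response, generate_dose_response_fixture

table, truth, _ = generate_dose_response_fixture(
    "monotone-saturating", n_points=12, noise_cv=0.10, seed=42
)
print("dose-response table (input, output):")
for _, row in table.iterrows():
    print(f"  {row.input_conc:8.3f}  {row.output_conc:8.2f}")

guess = ProductionParams(
    max_rate=40.0, activator_dissociation=(0.2,), basal_rate=truth.basal_rate
)
fit = fit_dose_response(
    table, ["max_rate", "activator_dissociation"], production=guess, seed=0
)
print(f"converged: {fit.success} ({fit.n_starts_converged} starts)")
print(f"max_rate:  true {truth.max_rate:.1f}   fitted {fit.production.max_rate:.1f}")
print(f"K_act:     true {truth.activator_dissociation[0]:.3f}   "
      f"fitted {fit.production.activator_dissociation[0]:.3f}")
# at 10% noise on 12 doses the maximal rate is typically recovered to
# within a few percent of the truth.
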