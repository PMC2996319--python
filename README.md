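# cytodyn

Phase-plane analysis and simulation of a two-population cytokine
interaction model of tissue immune homeostasis.

Inflamed and healthy tissue states can be understood as dynamical
regimes of interacting immune cell populations: one population secretes
cytokine A and is inhibited by cytokine B, the other secretes B in an
A-dependent manner.  Homeostasis is the intersection of the two
populations' dose-dependent production curves (the nullclines of a
planar ODE system); pathology corresponds to extra stable intersections
(a bistable "trigger" — chronically inflamed lesions next to
symptomless skin) or to loss of stability (sustained cytokine
oscillations).  `cytodyn` implements the model, finds and classifies
its homeostatic equilibria, detects limit cycles, simulates pulse
perturbation protocols, and searches parameter space for the regimes.
It is aimed at systems immunologists and modelers who want a concrete,
testable caricature of chronic inflammation dynamics.

## The model

Extracellular concentrations $A$, $B$ obey

$$\dot A = q_A\,\frac{K_B}{K_B + B} + q_A^0 - u_A(A) - \lambda_A A,
\qquad
\dot B = q_B\,\frac{A}{K_A + A} + q_B^0 - u_B(B) - \lambda_B B .$$

Production is a basal rate plus a maximal rate modulated by
Michaelis–Menten activation ($c/(K+c)$) and inhibition ($K/(K+c)$)
factors.  Removal combines first-order clearance $\lambda c$ (capillary
exchange plus linearized protease degradation) with receptor-mediated
uptake

$$u(c) = u_0 R\,\frac{c}{K_d + c}\,\phi(c)^2,
\qquad
\phi(c) = \frac{k_r}{k_r + k_i^{\text{free}}(1-b) + k_i^{\text{bound}} b},
\quad b = \frac{c}{K_d+c},$$

where $\phi$ is the steady-state fraction of receptors on the cell
surface under internalization and recycling.  When bound receptors
internalize much faster than they recover ($k_i^{\text{bound}} \gg
k_r$), uptake is **non-monotone** in concentration — it rises, peaks,
and declines as the surface receptor pool collapses.  This single
nonlinearity is what lets two coupled populations produce three
qualitatively different regimes:

* **stable homeostasis** — one intersection, globally attracting;
  small external cytokine pulses are amplified up to two orders of
  magnitude and then decay back;
* **bistable trigger** — three intersections (stable low H1, saddle
  H2, stable high H3); pulses of A switch H1→H3, pulses of B switch
  H3→H1;
* **oscillations** — a limit cycle, either as the only attractor or
  coexisting with a stable point that a well-timed small pulse can
  return the system to.

Across large random parameter sweeps the number of *stable* levels is
only ever 0, 1 or 2.

## Worked example

Five exemplar parameter sets, one per regime, ship with the package
(`cytodyn.list_exemplars()`).  Classifying the trigger exemplar and
switching it between its homeostatic levels
(`python examples/trigger_switching.py`, condensed):

```python
import cytodyn as cd

p = cd.load_exemplar("trigger")
for e in cd.find_equilibria(p):
    print(e.state.conc_A, e.state.conc_B, e.stability)
```

```
H1: A=0.0047  B=0.0063  stable-node
H2: A=0.0264  B=0.0335  saddle
H3: A=0.0456  B=0.0573  stable-node
regime: bistable-trigger
A-pulse from H1 settles at: H3
B-pulse from H3 settles at: H1
sub-threshold A-pulse from H1 settles at: H1
```

The two stable states are the low (perilesional) and high (lesional)
cytokine levels; an A-pulse of amplitude 0.05 for 5 time units flips
the tissue to the inflamed level, a B-pulse flips it back, and pulses
below the threshold (≈0.015) relax harmlessly to where they started.
The other scripts in `examples/` demonstrate impulse amplification in a
healthy system (ratio ≈ 455 for a 10⁻⁴-amplitude pulse), limit-cycle
detection and pulse-driven escape from oscillation, parameter-space
sweeps, and dose-response calibration.

The same operations are available from the shell:

```bash
cytodyn equilibria --exemplar trigger --out out/
cytodyn classify   --exemplar oscillatory_pure --out out/
cytodyn sweep      --n-samples 1000 --seed 0 --out sweep/
```

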