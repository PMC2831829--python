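# Methods

## The model

`casprd` simulates apoptosis execution in a cytosol where the trigger — mitochondrial
outer-membrane permeabilisation (MOMP) — does not happen everywhere at once but sweeps
across the cell as a slow wave. The question the model answers is whether that spatial
anisotropy survives into effector-caspase activity, or whether free diffusion of the
signalling proteins erases it first.

The cell is abstracted as a 1D cytosolic segment of length L = 30 μm (a typical HeLa
end-to-end distance) discretised into N = 300 nodes. Every species n obeys

    ∂c_n/∂t = D_n ∂²c_n/∂x² + R_n(c) + I_n(x, t),

with zero-flux (reflecting) boundaries at both ends: nothing enters or leaves the cell,
so transport conserves total protein.

**Reaction term.** R_n are mass-action rates of a ~20-species caspase network: the
apoptosome with bound procaspase-9 autoprocesses caspase-9 to its p35/p12 form and
activates procaspases-3 and -7; caspase-3 feeds back on caspase-9 (producing the
p35/p10 form, which escapes XIAP) and autoprocesses procaspase-3; XIAP binds and
inhibits caspase-9 (p35/p12) and caspases-3/-7; caspase-3 cleaves XIAP into BIR1-2 and
BIR3-RING fragments that retain their binding arms; Smac neutralises XIAP and both
fragments; XIAP-bound caspases are ubiquitinated and degraded at an enhanced rate (the
XIAP form is recycled, giving sub-stoichiometric inhibition); effector-caspase activity
progressively shuts down protein synthesis and proteasomal degradation (their rate
constants are scaled by the local *uncleaved* substrate fraction — the simplest
monotone coupling). Cleavage of a 1 μM effector-caspase substrate (a stand-in for a
cytosolic FRET probe) is the model output.

**Inputs.** MOMP is not modelled mechanistically. Two pseudo-reactions deliver the
released factors with first-order saturation kinetics, C_max·(1 − e^(−k·(t − t_on(x)))):
the apoptosome-formation trigger (C_max = 0.05 μM, k = 0.01 s⁻¹) and Smac
(C_max = 0.45 μM, k = 0.004 s⁻¹ — locally slower, as observed experimentally). The
onset time is position-dependent, t_on(x) = x / v_wave with v_wave = 0.1 μm/s, so the
far end of a 30 μm cell is triggered exactly 5 min after the near end.

**Diffusion.** Each species gets D from the Stokes-Einstein relation anchored to
cytosolic GFP, D = 24·(27/M)^(1/3) μm²/s with M in kDa (Stokes radius ∝ M^(1/3) for
globular proteins). A 216 kDa complex gets exactly 12 μm²/s; the ~700 kDa apoptosome
~8.1 μm²/s. Scenario variants can divide every D by an impairment factor (a "100-fold
reduced diffusivity" = factor 100; `inf` gives the exact diffusion-free limit) or set
D = 0 for all apoptosome-containing species (`immobile_apoptosome`).

## Parameterisation

The printed sources for this network give its topology but not the full rate-constant
tables, so the shipped default model (`data/reference_model.yaml`) is a labelled
**reconstruction**: association constants near the diffusion limit (1 μM⁻¹s⁻¹),
nanomolar-scale XIAP:caspase and sub-nanomolar Smac:XIAP dissociation, effector
substrate cleavage at kcat/Km ≈ 2×10⁵ M⁻¹s⁻¹, ~3 h constitutive protein half-lives,
and HeLa-scale pools (procaspase-3 0.2 μM, procaspase-7 0.045 μM, XIAP 0.25 μM,
Smac 0.45 μM, apoptosome sites 0.05 μM). Constants were balanced so the whole-cell
behaviour matches the published phenotype of this network: a MOMP-to-half-maximal-
cleavage lag of ~6 min governed by the XIAP/Smac switch, execution that completes
within the hour, and a reaction-limited (not input-limited) lag so that globally
accelerated kinetics genuinely compress it. Every number is overridable through the
model file; nothing in the code depends on the defaults.

Caveat inherited from the sources: minor bookkeeping choices (e.g. that caspase-9
p35/p10 is not XIAP-inhibitable) follow the topology wording and may differ from the
original tables in detail.

## Numerics

* **Method of lines.** Node-major state ordering makes the Jacobian banded with
  half-width n_species (reactions couple species within a node; diffusion couples a
  species across neighbouring nodes). Integration uses adaptive-step LSODA with an
  analytic banded Jacobian assembled per step; the derivative of the
  synthesis/degradation impairment factor is omitted from the Jacobian (preconditioner
  only — the solution is unaffected). Default tolerances rtol 1e-6, atol 1e-9 μM;
  tightening both 10× moves delay metrics by < 0.001 s.
* **Diffusion stencil.** Vertex-centred grid spanning [0, L] (spacing L/(N−1)) so the
  near/far read-outs sit exactly on the cell ends; zero flux by ghost-node reflection.
  cos(πx/L) is an exact eigenvector of the discrete operator, and the node-weighted
  (trapezoidal, half-weight end nodes) mass change is zero to machine precision for
  any field. Grid-doubling (N = 600) changes delay metrics by < 0.001%.
* **Onset regularisation.** The ideal travelling source switches on with a rate kink
  at every node (one per second at default settings), which collapses the integrator's
  step size. The solver replaces the elapsed time since onset with the softplus
  s(Δt) = τ·ln(1 + e^(Δt/τ)), τ = 1 s (the wave's one-cell crossing time), and starts
  integration at −10τ so every node receives the identical regularised tail. This
  keeps the source an exact function of Δt only, so the travelling wave remains a pure
  time shift: the D = 0 spatial run agrees with the time-shifted single-point ODE to
  ~1e-5 in cleavage fraction, and end-to-end delays are unchanged (the shift is common
  to both ends). τ is a solver argument; τ = 0 restores the ideal switch.
* **Positivity.** Rate laws evaluate concentrations floored at zero, so solver
  excursions below zero (≲ 1e-8 μM) cannot feed back as spurious production; saved
  fields are floored at zero after verifying no excursion exceeds a 1e-6 μM guard.
* **Metrics.** Cleavage fraction = cleaved/(cleaved+uncleaved) per node; crossing
  times are linearly interpolated between saves (save-grid independent); onset = 1%
  and half-maximal = 50% by convention, both configurable. End-to-end delay =
  far-end minus near-end crossing time; variant deltas subtract the unperturbed
  reference delay (negative = reduced anisotropy). Near/far kinetics within 10 s of
  each other are reported as "superimposed" (the synchrony tolerance — a reported
  judgement, not a hard-coded cut).

## Behaviour of the reference model

At reference diffusivities the 300 s input anisotropy is erased: near/far half-max
cleavage times differ by < 0.01 s. Impairing diffusion 10-fold leaves the half-max
delay inside the synchrony band (it can dip a few seconds *negative* — the reflecting
far boundary accumulates in-diffusing actives, the same mechanism that makes far-end
activity earlier than the diffusion-free case); ~100-fold impairment produces clear
asynchrony (onset delay ~130 s, half-max ~90 s); 10⁴-fold approaches the exact
diffusion-free limit of 300 s. Because of the small sub-tolerance dip, monotonicity of
the sweep is asserted within the 10 s synchrony tolerance. Feedback knockouts slow
execution overall and *reduce* anisotropy slightly (longer lag → more time to mix);
10× accelerated kinetics and apoptosome immobilisation *increase* it at intermediate
impairment, their combination more than either alone. Variant sign checks are scored
at 100- and 1000-fold impairment, where delays exceed the synchrony tolerance but the
reference has not yet saturated at the no-diffusion limit.

## Dimension check

The 1D abstraction is bounded by comparing single-species diffusion in a slab (input
at the left boundary) against a sphere with synchronous surface input, reduced to its
radial coordinate via a conservative finite-volume discretisation (the innermost shell
face has zero area — no centre singularity). The radial solver reproduces the
closed-form series for a constant-surface-concentration sphere to 0.01%. With matched
D = 24 μm²/s, travel distance 15 μm and input kinetics k = 0.01 s⁻¹ — the regime of
the execution model, where local delivery (τ ≈ 100 s) is much slower than diffusive
equilibration (R²/D ≈ 10 s) — arrival times at the 50% threshold differ by at most
~4% over the full depth range, supporting the 1D reduction. With threshold crossing in
the diffusion-limited regime (fast inputs) the geometries genuinely diverge; the check
is specific to slow, saturating inputs.

## What the defaults do and do not show

The default scenario encodes the study conditions (30 μm cell, 300 nodes, 0.1 μm/s
wave, GFP-anchored diffusivities) — it is an idealised, deterministic, 1D cell. It
ignores macromolecular crowding beyond the cytosolic GFP anchor, treats onset times as
strictly position-determined (no biological variability), and has no organelle
geometry; passing tests demonstrate properties of this idealisation, not of any
particular cell line's measured kinetics. Problem sizes in the test-suite and the
acceptance script (300-node grids, 1–3.6 ks horizons, single-scale variant runs)
were chosen as the smallest that leave all reported metrics grid- and
tolerance-converged.
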