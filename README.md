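# casprd — reaction–diffusion modelling of apoptosis execution

During apoptosis, mitochondrial outer-membrane permeabilisation (MOMP) can sweep
across a cell as a slow wave (~0.1 μm/s), releasing cytochrome-c and Smac with a
delay of minutes between the two cell ends. `casprd` asks what happens to that
spatial anisotropy downstream: it couples the mass-action caspase-activation
network of apoptosis execution (apoptosome/caspase-9 → caspases-3/-7, under XIAP
control with Smac antagonism) to Fickian diffusion along a 1D model cell, and
measures whether effector-caspase substrate cleavage stays anisotropic or becomes
spatially homogeneous. It is a tool for systems biologists studying spatiotemporal
signalling: reference simulations, diffusivity-impairment sweeps, network-variant
comparisons (feedback knockouts, globally accelerated kinetics, apoptosome
immobilisation) and a 1D-versus-3D geometry error estimate.

## Model

Every species n follows, on 0 ≤ x ≤ L (L = 30 μm, N = 300 nodes),

    ∂c_n/∂t = D_n ∂²c_n/∂x² + R_n(c) + I_n(x, t),      ∂c_n/∂x = 0 at x = 0, L

* **R_n** — mass-action kinetics of the ~20-species execution network
  (caspase-9 autoprocessing, effector activation, caspase-3 feedbacks, XIAP
  binding/cleavage, Smac neutralisation, ubiquitination-enhanced degradation,
  caspase-dependent impairment of synthesis/degradation; substrate cleavage is
  the output).
* **D_n** — Stokes-Einstein from molecular mass, anchored to cytosolic GFP:
  D = 24·(27 kDa / M)^(1/3) μm²/s.
* **I_n** — travelling-wave inputs: the apoptosome trigger and Smac are
  delivered with first-order saturation kinetics starting at
  t_on(x) = x / v_wave (v_wave = 0.1 μm/s → the far end lags by 5 min).

Space is discretised (method of lines) and integrated with an adaptive stiff
solver using an analytic banded Jacobian. The read-out is the **end-to-end
delay**: far-end minus near-end time of crossing a cleavage threshold (1% =
onset, 50% = half-maximal). See `docs/methods.md` for assumptions, parameter
provenance (the default model file is a labelled reconstruction) and numerics.

## Worked example

```python
import numpy as np
from casprd import SpatialGrid, build_reference_network
from casprd.config import default_model_parameters, wave_inputs_from_parameters
from casprd.metrics import diffusivity_sweep

params = default_model_parameters()
network = build_reference_network(params)
inputs = wave_inputs_from_parameters(params)
grid = SpatialGrid(length=30.0, n_nodes=300)

table = diffusivity_sweep(
    network, grid, inputs,
    scales=[1, 100, np.inf],      # reference, 100-fold impaired, no diffusion
    thresholds=(0.01, 0.5),
)
cols = ["scale", "threshold", "near_time_s", "far_time_s", "delay_s"]
print(table[cols].round({"near_time_s": 1, "far_time_s": 1, "delay_s": 1})
      .to_string(index=False))
```

prints

```
 scale  threshold  near_time_s  far_time_s  delay_s
   1.0       0.01        380.5       380.5     -0.0
   1.0       0.50        530.2       530.2     -0.0
 100.0       0.01        292.5       425.9    133.4
 100.0       0.50        463.8       552.8     89.0
   inf       0.01        215.6       515.6    300.0
   inf       0.50        363.6       663.6    300.0
```

Reading: although MOMP reaches the far end 300 s after the near end, at
physiological diffusivities (scale 1) substrate cleavage crosses both the 1%
and 50% thresholds *simultaneously* at the two ends — diffusion has erased the
anisotropy. Impairing every diffusion coefficient 100-fold lets asynchrony
reappear (133 s at onset, 89 s at half-max), and with diffusion off the full
300 s input delay is recovered exactly. The same sweep is available from the
shell (`casprd sweep --scales 1,100,10000`), along with `casprd run`
(kymograph-style cleavage heatmaps), `casprd variants` (delay deltas of
feedback knockouts, 10× kinetics and immobile apoptosomes versus the
reference) and `casprd dimcheck` (slab-versus-sphere arrival times).

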