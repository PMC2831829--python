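"""Spatial grid, diffusivity assignment, MOMP-wave inputs and the discrete
diffusion operator.

The cell is modelled as a 1D cytosolic domain of length ``L`` (default 30 μm,
the average end-to-end length of a HeLa cell) discretised into ``n_nodes``
equally spaced nodes. Proteins diffuse along this axis following Fick's
second law with zero-flux (reflecting) boundaries, so total protein content
in the domain is conserved by transport.

Diffusion coefficients are assigned per species from molecular mass via the
Stokes-Einstein relation, anchored to GFP (27 kDa, 24 μm²/s in cytosol):

    D(M) = D_GFP * (M_GFP / M)**(1/3)

Mitochondrial outer-membrane permeabilisation (MOMP) is not modelled
mechanistically; it enters as a travelling wave of onset times. Each released
factor (the cytochrome-c-dependent apoptosome-formation trigger, and Smac)
is delivered at every position by a first-order exponential saturation
function starting at the local onset time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpatialGrid",
    "WaveInput",
    "stokes_einstein_diffusivity",
    "momp_onset_time",
    "wave_input_value",
    "wave_input_rate",
    "diffusion_operator",
]

#: Reference diffusion coefficient of cytosolic GFP, μm²/s.
D_GFP = 24.0
#: Molecular mass of GFP, kDa.
M_GFP = 27.0


def stokes_einstein_diffusivity(
    mass: float, reference_D: float = D_GFP, reference_mass: float = M_GFP
) -> float:
    """Diffusion coefficient (μm²/s) of a globular protein of ``mass`` kDa.

    Stokes-Einstein gives D ∝ 1/radius, and for globular proteins the Stokes
    radius scales with the cube root of the mass, hence
    ``D = reference_D * (reference_mass / mass)**(1/3)``. The default anchor
    is GFP (27 kDa → 24 μm²/s in cellular cytosol), so a 216 kDa complex
    (8 × 27) diffuses at exactly half the GFP rate.

    Raises
    ------
    ValueError
        If ``mass`` is not strictly positive.
    """
    mass = float(mass)
    if not mass > 0.0:
        raise ValueError(f"molecular mass must be > 0 kDa, got {mass}")
    return reference_D * (reference_mass / mass) ** (1.0 / 3.0)


@dataclass(frozen=True)
class SpatialGrid:
    """Uniform 1D node-centred grid spanning ``[0, length]``.

    Nodes sit at ``x_i = i * spacing`` with ``spacing = length / (n_nodes-1)``,
    so the first and last node lie exactly on the near (x=0) and far (x=L)
    cell ends where the anisotropy read-outs are taken.
    """

    length: float = 30.0  # μm
    n_nodes: int = 300

    def __post_init__(self) -> None:
        if not self.length > 0:
            raise ValueError(f"grid length must be > 0 μm, got {self.length}")
        if self.n_nodes < 3:
            raise ValueError(f"need at least 3 nodes, got {self.n_nodes}")

    @property
    def spacing(self) -> float:
        """Node spacing Δx in μm."""
        return self.length / (self.n_nodes - 1)

    @property
    def coordinates(self) -> np.ndarray:
        """Node positions in μm, strictly increasing from 0 to L."""
        return np.linspace(0.0, self.length, self.n_nodes)

    @property
    def node_weights(self) -> np.ndarray:
        """Quadrature weights (μm) defining discrete mass ``Σ w_i c_i``.

        Trapezoidal weights: boundary nodes own a half cell. The diffusion
        operator conserves this discrete mass to machine precision.
        """
        w = np.full(self.n_nodes, self.spacing)
        w[0] = w[-1] = 0.5 * self.spacing
        return w


@dataclass(frozen=True)
class WaveInput:
    """A travelling-wave delivery of one mitochondrially released factor.

    After the MOMP wave passes position ``x`` (at ``momp_onset_time``), the
    cumulative locally delivered amount rises as a first-order exponential
    saturation ``amplitude * (1 - exp(-saturation_rate * (t - t_onset)))``.
    The instantaneous source term used in the PDE right-hand side is the time
    derivative of this curve.

    Parameters
    ----------
    target_species:
        Name of the network species receiving the influx.
    amplitude:
        Total deliverable amount C_max, μM.
    saturation_rate:
        First-order rate k of the local saturation kinetics, 1/s. Smac
        release proceeds with slower local kinetics than cytochrome-c-induced
        apoptosome formation, so the Smac input uses a smaller rate.
    wave_velocity:
        End-to-end propagation velocity of the MOMP wave, μm/s.
    origin:
        Wave origin x₀ in μm (default 0, the near end).
    """

    target_species: str
    amplitude: float
    saturation_rate: float
    wave_velocity: float = 0.1
    origin: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("input amplitude must be >= 0 μM")
        if not self.saturation_rate > 0:
            raise ValueError("saturation rate must be > 0 /s")
        if not self.wave_velocity > 0:
            raise ValueError("wave velocity must be > 0 μm/s")


def momp_onset_time(x, wave: WaveInput, grid: SpatialGrid | None = None):
    """Local MOMP onset time t_MOMP(x) = (x - x₀) / v_wave in seconds.

    Zero at the wave origin and linear in distance; with the default
    v = 0.1 μm/s over a 30 μm cell the far end is triggered 300 s (5 min)
    after the near end. If ``grid`` is given, ``x`` must lie inside it.
    """
    x = np.asarray(x, dtype=float)
    if grid is not None and (np.any(x < 0.0) or np.any(x > grid.length)):
        raise ValueError(f"position {x} outside the modelled domain [0, {grid.length}] μm")
    t = (x - wave.origin) / wave.wave_velocity
    return float(t) if t.ndim == 0 else t


def wave_input_value(x, t, wave: WaveInput, grid: SpatialGrid | None = None):
    """Cumulative delivered amount (μM) at position ``x`` and time ``t``.

    Zero before the local onset, then ``C_max (1 - exp(-k Δt))``; monotone
    non-decreasing in t and bounded by the amplitude.
    """
    dt = np.asarray(t, dtype=float) - momp_onset_time(x, wave, grid)
    value = wave.amplitude * -np.expm1(-wave.saturation_rate * np.maximum(dt, 0.0))
    return float(value) if value.ndim == 0 else value


def wave_input_rate(x, t, wave: WaveInput, grid: SpatialGrid | None = None):
    """Instantaneous influx rate (μM/s): time derivative of the cumulative curve."""
    dt = np.asarray(t, dtype=float) - momp_onset_time(x, wave, grid)
    rate = np.where(
        dt >= 0.0,
        wave.amplitude * wave.saturation_rate * np.exp(-wave.saturation_rate * np.maximum(dt, 0.0)),
        0.0,
    )
    return float(rate) if rate.ndim == 0 else rate


def diffusion_operator(field: np.ndarray, D: float, grid: SpatialGrid) -> np.ndarray:
    """Apply the discrete Neumann Laplacian: returns D ∂²c/∂x² per node (μM/s).

    Zero-flux boundaries are realised by ghost-node reflection (c[-1] = c[1]
    and c[N] = c[N-2]), which makes the node sum of the returned rates vanish
    identically — the discrete counterpart of mass conservation in a closed
    cell.
    """
    field = np.asarray(field, dtype=float)
    if field.shape[-1] != grid.n_nodes:
        raise ValueError(
            f"field has {field.shape[-1]} nodes, grid has {grid.n_nodes}"
        )
    if D < 0:
        raise ValueError("diffusion coefficient must be >= 0")
    out = np.empty_like(field)
    inv_h2 = D / grid.spacing**2
    out[..., 1:-1] = (field[..., :-2] - 2.0 * field[..., 1:-1] + field[..., 2:]) * inv_h2
    # reflecting ghosts: the boundary flux contribution cancels exactly
    out[..., 0] = 2.0 * (field[..., 1] - field[..., 0]) * inv_h2
    out[..., -1] = 2.0 * (field[..., -2] - field[..., -1]) * inv_h2
    return out
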