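"""Method-of-lines integration of the reaction-diffusion system.

Each species n obeys

    ∂c_n/∂t = D_n ∂²c_n/∂x² + R_n(c) + I_n(x, t)

on 0 ≤ x ≤ L with zero-flux boundaries: R_n are the mass-action network
rates, I_n the travelling-wave MOMP input sources, and D_n the
Stokes-Einstein diffusivities (0 for immobilised species, divided by the
scenario's impairment factor otherwise). Space is discretised on the grid
nodes, yielding a stiff ODE system of size n_nodes × n_species that is
integrated with an adaptive-step stiff solver (LSODA) exploiting the banded
Jacobian structure of the node-major state ordering.

``simulate_local_ode`` integrates the same chemistry at a single point —
the diffusion-free reference model, and the oracle for the D=0 limit of the
spatial simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .network import CLEAVAGE_IMPAIRED_TAGS, ReactionNetwork
from .transport import SpatialGrid, WaveInput, momp_onset_time

__all__ = ["ConcentrationField", "IntegrationError", "simulate", "simulate_local_ode"]

DEFAULT_RTOL = 1.0e-6
DEFAULT_ATOL = 1.0e-9  # μM
DEFAULT_SAVE_INTERVAL = 1.0  # s
#: Temporal width (s) of the smooth onset regularisation of the wave source.
DEFAULT_ONSET_SMOOTHING = 1.0
#: Positivity safeguard: solver excursions below zero larger than this (μM)
#: abort the run; smaller ones are floored to zero in the saved field.
POSITIVITY_GUARD = 1.0e-6


def _enforce_positivity(values: np.ndarray, what: str) -> np.ndarray:
    low = float(values.min(initial=0.0))
    if low < -POSITIVITY_GUARD:
        raise IntegrationError(
            f"{what}: concentration excursion to {low:.3g} μM exceeds the "
            f"positivity guard ({-POSITIVITY_GUARD:g} μM); tighten tolerances"
        )
    return np.maximum(values, 0.0)


def _source_rate(dt: np.ndarray, amp: float, k: float, tau: float) -> np.ndarray:
    """Influx rate of the saturating wave source with a C¹ onset.

    The ideal source switches on with a derivative kink at dt = 0, which an
    adaptive integrator resolves by collapsing its step at every node's
    onset. Replacing the elapsed time since onset by the softplus
    s(dt) = τ·ln(1+exp(dt/τ)) — whose derivative, the logistic σ(dt/τ),
    replaces the Heaviside — makes the rate amp·k·exp(−k·s)·σ smooth in
    time while keeping the delivered amount, the saturation limit and —
    because s depends on dt only — the exact node-to-node time shifts of
    the travelling wave. Integration starts at −10τ (see the solvers) so
    every node receives the full regularised tail. τ (default 1 s, the time
    the wave needs to cross one grid cell) is far below every reported
    delay scale; τ = 0 recovers the ideal switch.
    """
    if tau <= 0.0:
        return np.where(dt >= 0.0, amp * k * np.exp(-k * np.maximum(dt, 0.0)), 0.0)
    z = dt / tau
    s = tau * np.logaddexp(0.0, z)  # softplus, overflow-safe
    with np.errstate(over="ignore"):
        sigma = 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))
    return amp * k * np.exp(-k * s) * sigma


class IntegrationError(RuntimeError):
    """The stiff integrator failed to reach the requested end time."""


@dataclass(frozen=True)
class ConcentrationField:
    """c_n(x, t) for every species on the grid at the saved time points.

    ``values`` has shape (n_species, n_nodes, n_times), μM. Time points are
    strictly increasing; concentrations are non-negative up to integration
    tolerance.
    """

    species_names: tuple[str, ...]
    node_coordinates: np.ndarray  # μm, (n_nodes,)
    time_points: np.ndarray  # s, (n_times,)
    values: np.ndarray  # μM, (n_species, n_nodes, n_times)

    def __post_init__(self) -> None:
        if self.values.shape != (
            len(self.species_names),
            len(self.node_coordinates),
            len(self.time_points),
        ):
            raise ValueError("values shape inconsistent with coordinates")
        if np.any(np.diff(self.time_points) <= 0):
            raise ValueError("time points must be strictly increasing")

    def get(self, species: str) -> np.ndarray:
        """Concentration of one species, shape (n_nodes, n_times)."""
        return self.values[self.species_names.index(species)]

    def to_dataframe(self) -> pd.DataFrame:
        """Long-form table (species, x_um, t_s, value_uM)."""
        n_s, n_x, n_t = self.values.shape
        return pd.DataFrame(
            {
                "species": np.repeat(self.species_names, n_x * n_t),
                "x_um": np.tile(np.repeat(self.node_coordinates, n_t), n_s),
                "t_s": np.tile(self.time_points, n_s * n_x),
                "value_uM": self.values.ravel(),
            }
        )

    def save(self, path: str | Path) -> None:
        """Self-describing array container: one array per species plus the
        coordinate vectors."""
        arrays = {f"c::{name}": self.get(name) for name in self.species_names}
        np.savez_compressed(path, x_um=self.node_coordinates, t_s=self.time_points, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "ConcentrationField":
        with np.load(path) as data:
            names = tuple(k[3:] for k in data.files if k.startswith("c::"))
            return cls(
                species_names=names,
                node_coordinates=data["x_um"],
                time_points=data["t_s"],
                values=np.stack([data[f"c::{n}"] for n in names]),
            )


def _banded_jacobian_builder(
    network: ReactionNetwork, n_x: int, diff_coeff: np.ndarray
):
    """Analytic Jacobian of the method-of-lines RHS in LAPACK banded storage.

    With node-major state ordering the Jacobian is banded with half-width
    n_species: mass-action blocks are node-local and diffusion couples the
    same species at neighbouring nodes. The derivative of the
    cleavage-impairment factor with respect to the substrate pair is
    neglected (the affected rates are small); LSODA only uses the Jacobian
    as a Newton preconditioner, so this does not change the solution.
    """
    n_s = network.n_species
    n = n_x * n_s
    S = network.stoichiometry_matrix
    # distinct reactants with multiplicities + net-change rows, per reaction
    entries = []
    for j, rxn in enumerate(network.reactions):
        mult: dict[str, int] = {}
        for name, stoich in rxn.reactants:
            mult[name] = mult.get(name, 0) + stoich
        distinct = [(network.species_index(nm), m) for nm, m in mult.items()]
        rows = [(r, S[r, j]) for r in np.flatnonzero(S[:, j])]
        entries.append((rxn.rate_constant, distinct, rows, rxn.tag in CLEAVAGE_IMPAIRED_TAGS))

    # static diffusion contribution
    ab0 = np.zeros((2 * n_s + 1, n))
    for s in range(n_s):
        d = diff_coeff[s, 0]
        ab0[n_s, s::n_s] += -2.0 * d  # diagonal
        upper = ab0[0, n_s + s :: n_s]  # rows n → cols n+1
        upper += d
        upper[0] = 2.0 * d
        lower = ab0[2 * n_s, s::n_s][: n_x - 1]  # rows n → cols n-1
        lower += d
        lower[-1] = 2.0 * d

    def jac(t: float, y: np.ndarray) -> np.ndarray:
        c = np.maximum(y.reshape(n_x, n_s), 0.0)
        phi = network.uncleaved_fraction(c)
        ab = ab0.copy()
        for k, distinct, rows, impaired in entries:
            for i, m in distinct:
                dv = np.full(n_x, float(k) * m)
                if m > 1:
                    dv *= c[:, i] ** (m - 1)
                for o, mo in distinct:
                    if o != i:
                        dv *= c[:, o] ** mo
                if impaired:
                    dv = dv * phi
                for r, sigma in rows:
                    ab[n_s + r - i, i::n_s] += sigma * dv
        return ab

    return jac


def _save_times(t_end: float, save_interval: float) -> np.ndarray:
    times = np.arange(0.0, t_end + 0.5 * save_interval, save_interval)
    if times[-1] < t_end:
        times = np.append(times, t_end)
    return times


def _input_tables(
    inputs: Sequence[WaveInput], network: ReactionNetwork, x: np.ndarray
) -> list[tuple[int, float, float, np.ndarray]]:
    tables = []
    for inp in inputs:
        idx = network.species_index(inp.target_species)
        t_on = (np.asarray(x, dtype=float) - inp.origin) / inp.wave_velocity
        tables.append((idx, inp.amplitude, inp.saturation_rate, t_on))
    return tables


def _check_finite(dydt: np.ndarray, t: float, y: np.ndarray) -> None:
    if not np.all(np.isfinite(dydt)):
        bad = int(np.flatnonzero(~np.isfinite(dydt))[0])
        raise IntegrationError(
            f"non-finite right-hand side at t={t:.3f} s (state component {bad}; "
            f"state min {np.nanmin(y):.3g}, max {np.nanmax(y):.3g} μM)"
        )


def simulate(
    network: ReactionNetwork,
    grid: SpatialGrid,
    inputs: Sequence[WaveInput],
    t_end: float,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    save_interval: float = DEFAULT_SAVE_INTERVAL,
    onset_smoothing: float = DEFAULT_ONSET_SMOOTHING,
    initial_state: np.ndarray | None = None,
) -> ConcentrationField:
    """Integrate the full reaction-diffusion system and return c_n(x, t).

    Diffusivities come from the network (Stokes-Einstein over the recorded
    impairment scale; immobilised species get D = 0). The initial condition
    is spatially uniform at the network's initial concentrations unless an
    explicit ``initial_state`` of shape (n_species, n_nodes) is given.
    Raises :class:`IntegrationError` if the stiff solver does not converge,
    with the time reached in the message.
    """
    if not t_end > 0:
        raise ValueError("t_end must be > 0 s")
    n_s, n_x = network.n_species, grid.n_nodes
    x = grid.coordinates
    D = network.diffusivities()  # μm²/s, (n_s,)
    diff_coeff = (D / grid.spacing**2)[:, None]
    S_T = network.stoichiometry_matrix.T  # (n_r, n_s)
    inp_tables = _input_tables(inputs, network, x)

    if initial_state is None:
        y0 = np.tile(network.initial_concentrations(), (n_x, 1)).ravel()
    else:
        initial_state = np.asarray(initial_state, dtype=float)
        if initial_state.shape != (n_s, n_x):
            raise ValueError(
                f"initial_state must have shape {(n_s, n_x)}, got {initial_state.shape}"
            )
        y0 = initial_state.T.ravel()

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        c = y.reshape(n_x, n_s)
        dydt = network.reaction_velocities(c) @ S_T  # (n_x, n_s)
        # Neumann Laplacian via ghost-node reflection, all species at once
        cT = c.T  # (n_s, n_x) view
        lap = np.empty_like(cT)
        lap[:, 1:-1] = cT[:, :-2] - 2.0 * cT[:, 1:-1] + cT[:, 2:]
        lap[:, 0] = 2.0 * (cT[:, 1] - cT[:, 0])
        lap[:, -1] = 2.0 * (cT[:, -2] - cT[:, -1])
        dydt += (diff_coeff * lap).T
        for idx, amp, k, t_on in inp_tables:
            dydt[:, idx] += _source_rate(t - t_on, amp, k, onset_smoothing)
        dydt = dydt.ravel()
        _check_finite(dydt, t, y)
        return dydt

    times = _save_times(t_end, save_interval)
    t0 = -10.0 * onset_smoothing if inputs else 0.0  # pre-roll of the onset tail
    sol = solve_ivp(
        rhs,
        (t0, float(t_end)),
        y0,
        method="LSODA",
        t_eval=times,
        rtol=rtol,
        atol=atol,
        jac=_banded_jacobian_builder(network, n_x, diff_coeff),
        lband=n_s,
        uband=n_s,
    )
    if not sol.success:
        t_reached = sol.t[-1] if sol.t.size else 0.0
        raise IntegrationError(
            f"stiff integration failed at t≈{t_reached:.1f} s of {t_end} s: "
            f"{sol.message} (consider loosening tolerances or reducing stiffness "
            f"via smaller rate/diffusivity contrasts)"
        )
    values = sol.y.reshape(n_x, n_s, times.size).transpose(1, 0, 2)
    values = _enforce_positivity(values, "spatial simulation")
    return ConcentrationField(
        species_names=network.species_names,
        node_coordinates=x,
        time_points=times,
        values=values,
    )


def simulate_local_ode(
    network: ReactionNetwork,
    inputs: Sequence[WaveInput],
    t_end: float,
    x: float = 0.0,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    save_interval: float = DEFAULT_SAVE_INTERVAL,
    onset_smoothing: float = DEFAULT_ONSET_SMOOTHING,
) -> ConcentrationField:
    """Integrate the reaction + input system at a single point.

    This is the diffusion-free whole-cell ODE model: the wave inputs are
    evaluated at the fixed position ``x`` (their local onset time is
    t_MOMP(x)). Returns a one-node :class:`ConcentrationField`.
    """
    if not t_end > 0:
        raise ValueError("t_end must be > 0 s")
    n_s = network.n_species
    S_T = network.stoichiometry_matrix.T
    onset = [(network.species_index(i.target_species), i.amplitude, i.saturation_rate,
              momp_onset_time(x, i)) for i in inputs]

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        dydt = network.reaction_velocities(y) @ S_T
        for idx, amp, k, t_on in onset:
            dydt[idx] += float(_source_rate(np.float64(t - t_on), amp, k, onset_smoothing))
        _check_finite(dydt, t, y)
        return dydt

    times = _save_times(t_end, save_interval)
    t0 = -10.0 * onset_smoothing if inputs else 0.0
    sol = solve_ivp(
        rhs,
        (t0, float(t_end)),
        network.initial_concentrations(),
        method="LSODA",
        t_eval=times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        t_reached = sol.t[-1] if sol.t.size else 0.0
        raise IntegrationError(
            f"local ODE integration failed at t≈{t_reached:.1f} s of {t_end} s: {sol.message}"
        )
    return ConcentrationField(
        species_names=network.species_names,
        node_coordinates=np.array([float(x)]),
        time_points=times,
        values=_enforce_positivity(sol.y[:, None, :], "local ODE"),
    )
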