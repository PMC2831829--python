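"""Shared fixtures: the packaged reference model and cached expensive runs."""

from __future__ import annotations

import numpy as np
import pytest

from casprd import SpatialGrid, apply_variant, build_reference_network
from casprd.config import default_model_parameters, wave_inputs_from_parameters
from casprd.metrics import diffusivity_sweep
from casprd.network import ProteinSpecies, Reaction, ReactionNetwork
from casprd.solver import simulate, simulate_local_ode

#: Decade impairment grid used throughout, plus the exact no-diffusion limit.
DECADE_SCALES = (1.0, 10.0, 100.0, 1000.0, 10000.0)


@pytest.fixture(scope="session")
def reference_params() -> dict:
    return default_model_parameters()


@pytest.fixture(scope="session")
def reference_network(reference_params):
    return build_reference_network(reference_params)


@pytest.fixture(scope="session")
def wave_inputs(reference_params):
    return wave_inputs_from_parameters(reference_params)


@pytest.fixture(scope="session")
def grid300() -> SpatialGrid:
    return SpatialGrid(length=30.0, n_nodes=300)


@pytest.fixture(scope="session")
def toy_binding_network() -> ReactionNetwork:
    """Reversible A + B ⇌ C with an A ⇌ ∅ synthesis/turnover pair, plus an
    output substrate cleaved by C. Small enough for hand calculation."""
    return ReactionNetwork(
        species=(
            ProteinSpecies("A", mass=27.0, initial_concentration=1.0),
            ProteinSpecies("B", mass=54.0, initial_concentration=2.0),
            ProteinSpecies("C", mass=81.0),
            ProteinSpecies("S", mass=40.0, initial_concentration=1.0),
            ProteinSpecies("Sc", mass=20.0),
        ),
        reactions=(
            Reaction((("A", 1), ("B", 1)), (("C", 1),), 0.5, "xiap_binding"),
            Reaction((("C", 1),), (("A", 1), ("B", 1)), 0.1, "xiap_unbinding"),
            Reaction((), (("A", 1),), 0.02, "synthesis"),
            Reaction((("A", 1),), (), 0.01, "turnover"),
            Reaction((("C", 1), ("S", 1)), (("C", 1), ("Sc", 1)), 0.3, "substrate_cleavage"),
        ),
        substrate_pair=("S", "Sc"),
    )


@pytest.fixture(scope="session")
def reference_local_course(reference_network, wave_inputs):
    """Diffusion-free whole-cell time course at the wave origin."""
    return simulate_local_ode(
        reference_network, wave_inputs, t_end=1800.0, x=0.0, save_interval=1.0
    )


@pytest.fixture(scope="session")
def reference_field(reference_network, wave_inputs, grid300):
    """Reference-diffusivity spatial run, past half-maximal cleavage."""
    return simulate(reference_network, grid300, wave_inputs, 1200.0, save_interval=2.0)


@pytest.fixture(scope="session")
def no_diffusion_field(reference_network, wave_inputs, grid300):
    """Full spatial run with every diffusivity exactly zero."""
    frozen = apply_variant(reference_network, "diffusivity_scale:inf")
    return simulate(frozen, grid300, wave_inputs, 1800.0, save_interval=1.0)


@pytest.fixture(scope="session")
def reference_sweep(reference_network, wave_inputs, grid300):
    """Reference delays over the decade impairment grid and the D=0 limit."""
    return diffusivity_sweep(
        reference_network,
        grid300,
        wave_inputs,
        scales=list(DECADE_SCALES) + [np.inf],
        thresholds=(0.01, 0.5),
        t_end=3600.0,
        scenario_id="reference",
    )


def variant_sweep(network, wave_inputs, grid, variants, scales):
    return diffusivity_sweep(
        apply_variant(network, variants),
        grid,
        wave_inputs,
        scales=scales,
        thresholds=(0.01, 0.5),
        t_end=3600.0,
        scenario_id="+".join(variants),
    )
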