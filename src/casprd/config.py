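"""Plain-text model and scenario descriptions.

Two YAML documents drive every computation:

* the **model file** — species (name, mass, initial concentration,
  apoptosome flag), mass-action reactions (reactants, products, rate
  constant, mechanistic tag), the travelling-wave input functions, and the
  substrate/cleaved-substrate output pair. The packaged default
  (``data/reference_model.yaml``) is the reconstructed HeLa execution
  network.
* the **scenario file** — grid geometry, variant toggles, diffusivity
  scales, cleavage thresholds, integration horizon and tolerances, and the
  output directory.

Both round-trip exactly: saving a loaded document reproduces it
byte-for-byte, and an exported scenario re-run yields identical results.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import yaml

from .network import (
    ConfigurationError,
    ProteinSpecies,
    Reaction,
    ReactionNetwork,
    ScenarioVariant,
)
from .transport import SpatialGrid, WaveInput

__all__ = [
    "ScenarioConfig",
    "default_model_parameters",
    "load_model_file",
    "save_model_file",
    "network_from_parameters",
    "wave_inputs_from_parameters",
    "load_config",
    "save_config",
]

_MODEL_KEYS = {"name", "description", "output", "species", "reactions", "inputs"}
_SPECIES_KEYS = {"name", "mass_kDa", "init_uM", "diffusible", "apoptosome_containing"}
_REACTION_KEYS = {"reactants", "products", "k", "tag"}
_INPUT_KEYS = {
    "target",
    "amplitude_uM",
    "saturation_rate_per_s",
    "wave_velocity_um_per_s",
    "origin_um",
}


def _check_keys(entry: Mapping, allowed: set, required: set, what: str) -> None:
    unknown = set(entry) - allowed
    if unknown:
        raise ConfigurationError(f"unknown key(s) in {what}: {', '.join(sorted(unknown))}")
    missing = required - set(entry)
    if missing:
        raise ConfigurationError(f"missing key(s) in {what}: {', '.join(sorted(missing))}")


# ---------------------------------------------------------------------------
# model description
# ---------------------------------------------------------------------------


def default_model_parameters() -> dict:
    """The packaged reconstructed HeLa execution model, parsed."""
    text = (
        importlib.resources.files("casprd") / "data" / "reference_model.yaml"
    ).read_text()
    return yaml.safe_load(text)


def load_model_file(path: str | Path) -> dict:
    """Load and structurally validate a model description."""
    params = yaml.safe_load(Path(path).read_text())
    validate_model_parameters(params)
    return params


def validate_model_parameters(params: Mapping) -> None:
    if not isinstance(params, Mapping):
        raise ConfigurationError("model file must contain a mapping at top level")
    _check_keys(params, _MODEL_KEYS, {"species", "reactions"}, "model file")
    for sp in params["species"]:
        _check_keys(sp, _SPECIES_KEYS, {"name", "mass_kDa", "init_uM"}, f"species {sp.get('name', '?')!r}")
    for rxn in params["reactions"]:
        tag = rxn.get("tag", "?")
        _check_keys(rxn, _REACTION_KEYS, {"reactants", "products", "tag"}, f"reaction {tag!r}")
        if "k" not in rxn:
            raise ConfigurationError(f"reaction tagged {tag!r} has no rate constant 'k'")
    for inp in params.get("inputs", ()):
        _check_keys(
            inp,
            _INPUT_KEYS,
            {"target", "amplitude_uM", "saturation_rate_per_s"},
            f"input for {inp.get('target', '?')!r}",
        )


def save_model_file(params: Mapping, path: str | Path) -> None:
    """Write a model description in the canonical form (byte-exact round-trip)."""
    Path(path).write_text(_canonical_yaml(params))


def _canonical_yaml(obj: Any) -> str:
    return yaml.safe_dump(obj, sort_keys=False, default_flow_style=False, width=100)


def network_from_parameters(params: Mapping) -> ReactionNetwork:
    """Materialise a :class:`ReactionNetwork` from a parsed model description."""
    validate_model_parameters(params)
    species = tuple(
        ProteinSpecies(
            name=sp["name"],
            mass=float(sp["mass_kDa"]),
            initial_concentration=float(sp["init_uM"]),
            diffusible=bool(sp.get("diffusible", True)),
            apoptosome_containing=bool(sp.get("apoptosome_containing", False)),
        )
        for sp in params["species"]
    )
    reactions = tuple(
        Reaction(
            reactants=tuple((n, int(s)) for n, s in (rxn["reactants"] or {}).items()),
            products=tuple((n, int(s)) for n, s in (rxn["products"] or {}).items()),
            rate_constant=float(rxn["k"]),
            tag=str(rxn["tag"]),
        )
        for rxn in params["reactions"]
    )
    output = params.get("output", {})
    pair = (output.get("substrate", "substrate"), output.get("cleaved", "substrate_cleaved"))
    return ReactionNetwork(species=species, reactions=reactions, substrate_pair=pair)


def wave_inputs_from_parameters(params: Mapping) -> list[WaveInput]:
    """The travelling-wave input functions declared in a model description."""
    return [
        WaveInput(
            target_species=inp["target"],
            amplitude=float(inp["amplitude_uM"]),
            saturation_rate=float(inp["saturation_rate_per_s"]),
            wave_velocity=float(inp.get("wave_velocity_um_per_s", 0.1)),
            origin=float(inp.get("origin_um", 0.0)),
        )
        for inp in params.get("inputs", ())
    ]


# ---------------------------------------------------------------------------
# scenario description
# ---------------------------------------------------------------------------


@dataclass
class ScenarioConfig:
    """A fully resolved, serialisable simulation scenario.

    ``diffusivity_scales`` are fold-*reductions* (scale 100 = 100-fold
    impaired diffusion); the diffusion-free limit is requested through the
    explicit ``no_diffusion`` flag, never through a scale of 0 or infinity.
    """

    scenario_id: str = "reference"
    model_file: str | None = None  # None → packaged reconstructed default
    length_um: float = 30.0
    n_nodes: int = 300
    variants: list[str] = field(default_factory=list)
    diffusivity_scales: list[float] = field(default_factory=lambda: [1.0])
    no_diffusion: bool = False
    thresholds: list[float] = field(default_factory=lambda: [0.01, 0.5])
    t_end_s: float = 3600.0
    save_interval_s: float = 1.0
    rtol: float = 1.0e-6
    atol_uM: float = 1.0e-9
    output_dir: str = "results"

    def __post_init__(self) -> None:
        for scale in self.diffusivity_scales:
            if not scale > 0:
                raise ConfigurationError(
                    "diffusivity scale must be > 0; use 'no_diffusion: true' "
                    "for the diffusion-free limit"
                )
        for thr in self.thresholds:
            if not 0.0 < thr < 1.0:
                raise ConfigurationError(f"cleavage threshold must lie in (0, 1), got {thr}")
        for v in self.variants:
            ScenarioVariant.parse(v)  # raises on unknown variant names
        if not self.t_end_s > 0:
            raise ConfigurationError("t_end_s must be > 0")

    # -- resolved objects ---------------------------------------------

    @property
    def grid(self) -> SpatialGrid:
        return SpatialGrid(length=self.length_um, n_nodes=self.n_nodes)

    def model_parameters(self) -> dict:
        if self.model_file is None:
            return default_model_parameters()
        return load_model_file(self.model_file)

    def base_network(self) -> ReactionNetwork:
        """The scenario's network with variant toggles (but no diffusivity
        scale) applied."""
        from .network import apply_variant

        return apply_variant(network_from_parameters(self.model_parameters()), self.variants)

    def wave_inputs(self) -> list[WaveInput]:
        return wave_inputs_from_parameters(self.model_parameters())


def load_config(path: str | Path) -> ScenarioConfig:
    """Load a scenario file, rejecting unknown keys and resolving defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, Mapping):
        raise ConfigurationError("scenario file must contain a mapping at top level")
    allowed = set(ScenarioConfig.__dataclass_fields__)
    _check_keys(raw, allowed, set(), "scenario file")
    return ScenarioConfig(**raw)


def save_config(config: ScenarioConfig, path: str | Path) -> None:
    """Write a scenario in canonical form; ``load_config`` restores it exactly."""
    Path(path).write_text(_canonical_yaml(asdict(config)))
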