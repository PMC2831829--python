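"""The apoptosis-execution reaction network.

Species and mass-action reactions describing caspase activation downstream
of mitochondrial outer-membrane permeabilisation (MOMP), following the
established execution-network topology for HeLa cells:

* cytochrome-c-dependent apoptosome formation and Smac release enter as
  external inputs (pseudo-reactions; see :mod:`casprd.transport`),
* apoptosome-bound procaspase-9 autoprocesses to its p35/p12 form and
  activates procaspases-3 and -7,
* active caspase-3 processes caspase-9 to the p35/p10 form (positive
  feedback) and autoprocesses procaspase-3,
* XIAP inhibits caspase-9 (p35/p12) and caspases-3/-7 by stoichiometric
  binding; caspase-3 cleaves XIAP into BIR1-2 and BIR3-RING fragments that
  retain their respective binding roles; Smac neutralises XIAP and both
  fragments,
* XIAP-bound caspases are ubiquitinated and degraded at an enhanced rate,
* effector-caspase activity progressively impairs protein synthesis and
  proteasomal degradation,
* cleavage of an effector-caspase substrate (a FRET-probe analogue) is the
  model output.

The shipped default parameter set (``data/reference_model.yaml``) is a
*reconstruction*: rate constants and initial concentrations are assembled
from the published kinetics of the underlying whole-cell ODE model of
apoptosis execution and from typical in-vitro caspase/XIAP kinetics; every
value can be overridden through the model file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .transport import stokes_einstein_diffusivity

__all__ = [
    "ProteinSpecies",
    "Reaction",
    "ReactionNetwork",
    "ScenarioVariant",
    "ConfigurationError",
    "build_reference_network",
    "mass_action_rates",
    "apply_variant",
]

#: Reaction tags whose rates are scaled by the local uncleaved-substrate
#: fraction, implementing effector-caspase-dependent impairment of protein
#: synthesis and proteasomal degradation.
CLEAVAGE_IMPAIRED_TAGS = frozenset({"synthesis", "turnover", "ubiquitin_degradation"})

#: Tags that every complete execution model must carry (variant toggles and
#: the output read-out address reactions through them).
REQUIRED_TAGS = (
    "c9_autoprocessing",
    "c3_feedback_on_c9",
    "effector_activation",
    "c3_autoprocessing",
    "xiap_binding",
    "xiap_cleavage",
    "smac_binding",
    "ubiquitin_degradation",
    "substrate_cleavage",
    "synthesis",
    "turnover",
)


class ConfigurationError(ValueError):
    """A model or scenario description is incomplete or inconsistent."""


@dataclass(frozen=True)
class ProteinSpecies:
    """One diffusible (or immobilised) protein or protein complex.

    ``mass`` (kDa) sets the diffusion coefficient through the
    Stokes-Einstein rule; ``apoptosome_containing`` marks the species whose
    mobility the apoptosome-immobilisation variant removes.
    """

    name: str
    mass: float  # kDa
    initial_concentration: float = 0.0  # μM
    diffusible: bool = True
    apoptosome_containing: bool = False

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise ValueError(f"species {self.name!r}: mass must be > 0 kDa")
        if self.initial_concentration < 0:
            raise ValueError(f"species {self.name!r}: initial concentration must be >= 0 μM")


@dataclass(frozen=True)
class Reaction:
    """An irreversible mass-action reaction.

    ``rate_constant`` units follow the reaction order: μM/s (order 0),
    1/s (order 1), 1/(μM·s) (order 2), … ``tag`` names the mechanistic role
    and is how variant toggles and modifiers address groups of reactions.
    Reactions whose tag is in :data:`CLEAVAGE_IMPAIRED_TAGS` have their
    velocity multiplied by the local uncleaved-substrate fraction.
    """

    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate_constant: float
    tag: str

    def __post_init__(self) -> None:
        if self.rate_constant < 0:
            raise ValueError(f"reaction {self.tag!r}: rate constant must be >= 0")
        for name, stoich in (*self.reactants, *self.products):
            if not (isinstance(stoich, (int, np.integer)) and stoich > 0):
                raise ValueError(
                    f"reaction {self.tag!r}: stoichiometry of {name!r} must be a positive integer"
                )

    @property
    def order(self) -> int:
        return sum(s for _, s in self.reactants)


@dataclass(frozen=True)
class ScenarioVariant:
    """A perturbation of the reference model.

    kind ∈ {``no_c3_to_c9_feedback``, ``no_c3_autoprocessing``,
    ``rate_scale``, ``immobile_apoptosome``, ``diffusivity_scale``};
    ``value`` is the fold-factor for the two scaling kinds (ignored
    otherwise). ``diffusivity_scale`` records a *reduction*: every diffusion
    coefficient is divided by the factor, so scale 100 means 100-fold
    impaired diffusivity.
    """

    kind: str
    value: float | None = None

    _KNOWN = (
        "no_c3_to_c9_feedback",
        "no_c3_autoprocessing",
        "rate_scale",
        "immobile_apoptosome",
        "diffusivity_scale",
    )

    def __post_init__(self) -> None:
        if self.kind not in self._KNOWN:
            raise ConfigurationError(
                f"unknown variant {self.kind!r}; known variants: {', '.join(self._KNOWN)}"
            )
        if self.kind in ("rate_scale", "diffusivity_scale"):
            if self.value is None or not self.value > 0:
                raise ConfigurationError(f"variant {self.kind!r} needs a positive fold-factor")

    @classmethod
    def parse(cls, text: str) -> "ScenarioVariant":
        """Parse ``"rate_scale:10"`` / ``"immobile_apoptosome"`` style strings."""
        kind, _, value = text.partition(":")
        return cls(kind.strip(), float(value) if value else None)


_KNOCKOUT_TAGS = {
    "no_c3_to_c9_feedback": "c3_feedback_on_c9",
    "no_c3_autoprocessing": "c3_autoprocessing",
}


@dataclass(frozen=True)
class ReactionNetwork:
    """Immutable species + reaction container with vectorised kinetics.

    ``substrate_pair`` names the (uncleaved, cleaved) output species;
    ``diffusivity_scale`` is the fold-reduction of all diffusion
    coefficients requested by scenario variants (applied by the transport
    layer, 1 = reference).
    """

    species: tuple[ProteinSpecies, ...]
    reactions: tuple[Reaction, ...]
    substrate_pair: tuple[str, str] = ("substrate", "substrate_cleaved")
    diffusivity_scale: float = 1.0

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate species names in network")
        index = {n: i for i, n in enumerate(names)}
        for rxn in self.reactions:
            for name, _ in (*rxn.reactants, *rxn.products):
                if name not in index:
                    raise ConfigurationError(
                        f"reaction {rxn.tag!r} references unknown species {name!r}"
                    )
        for name in self.substrate_pair:
            if name not in index:
                raise ConfigurationError(f"substrate species {name!r} not in network")
        object.__setattr__(self, "_index", index)
        object.__setattr__(self, "_tables", self._build_tables())

    # -- structure -----------------------------------------------------

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def species_index(self, name: str) -> int:
        return self._index[name]

    def reactions_tagged(self, tag: str) -> tuple[Reaction, ...]:
        return tuple(r for r in self.reactions if r.tag == tag)

    @property
    def stoichiometry_matrix(self) -> np.ndarray:
        """Net stoichiometry, shape (n_species, n_reactions)."""
        return self._tables["S"].copy()

    def masses(self) -> np.ndarray:
        return np.array([s.mass for s in self.species])

    def diffusivities(self) -> np.ndarray:
        """Per-species diffusion coefficients (μm²/s).

        Stokes-Einstein from mass, divided by the recorded diffusivity
        impairment; immobilised species get exactly 0.
        """
        D = np.array(
            [
                stokes_einstein_diffusivity(s.mass) / self.diffusivity_scale
                if s.diffusible
                else 0.0
                for s in self.species
            ]
        )
        return D

    def initial_concentrations(self) -> np.ndarray:
        return np.array([s.initial_concentration for s in self.species])

    # -- kinetics ------------------------------------------------------

    def _build_tables(self) -> dict:
        n_s, n_r = len(self.species), len(self.reactions)
        S = np.zeros((n_s, n_r))
        for j, rxn in enumerate(self.reactions):
            for name, stoich in rxn.reactants:
                S[self._index[name], j] -= stoich
            for name, stoich in rxn.products:
                S[self._index[name], j] += stoich
        k = np.array([r.rate_constant for r in self.reactions])
        reactant_idx = [
            np.array([self._index[n] for n, s in r.reactants for _ in range(s)], dtype=np.intp)
            for r in self.reactions
        ]
        impaired = np.array([r.tag in CLEAVAGE_IMPAIRED_TAGS for r in self.reactions])
        sub = np.array([self._index[n] for n in self.substrate_pair], dtype=np.intp)
        return {"S": S, "k": k, "reactant_idx": reactant_idx, "impaired": impaired, "sub": sub}

    def uncleaved_fraction(self, concentrations: np.ndarray) -> np.ndarray:
        """Local fraction of output substrate still uncleaved (1 where no
        substrate is present); modulates synthesis/degradation reactions."""
        c = np.asarray(concentrations, dtype=float)
        u, v = c[..., self._tables["sub"][0]], c[..., self._tables["sub"][1]]
        total = u + v
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0.0, u / np.where(total > 0.0, total, 1.0), 1.0)
        return np.clip(frac, 0.0, 1.0)

    def reaction_velocities(self, concentrations: np.ndarray) -> np.ndarray:
        """Mass-action velocity of each reaction (μM/s).

        ``concentrations`` may be a vector (n_species,) or an array
        (..., n_species); velocities are computed elementwise over leading
        axes. Concentrations are floored at zero inside the rate law so a
        solver excursion below zero cannot feed back as spurious production.
        """
        c = np.asarray(concentrations, dtype=float)
        if c.shape[-1] != len(self.species):
            raise ValueError(
                f"expected {len(self.species)} concentrations, got {c.shape[-1]}"
            )
        cpos = np.maximum(c, 0.0)
        t = self._tables
        vel = np.empty(c.shape[:-1] + (len(self.reactions),))
        for j, idx in enumerate(t["reactant_idx"]):
            v = np.full(c.shape[:-1], t["k"][j])
            for i in idx:
                v = v * cpos[..., i]
            vel[..., j] = v
        if t["impaired"].any():
            vel[..., t["impaired"]] *= self.uncleaved_fraction(c)[..., None]
        return vel

    def rates(self, concentrations: np.ndarray) -> np.ndarray:
        """Net per-species rate of change dC/dt (μM/s), diffusion excluded."""
        c = np.asarray(concentrations, dtype=float)
        if np.any(c < 0.0) and np.min(c) < -1e-6:
            raise ValueError(f"negative concentration in rate evaluation: min {np.min(c):.3g} μM")
        vel = self.reaction_velocities(c)
        return vel @ self._tables["S"].T

    # -- transformations ----------------------------------------------

    def with_species(self, species: Iterable[ProteinSpecies]) -> "ReactionNetwork":
        return replace(self, species=tuple(species))

    def with_reactions(self, reactions: Iterable[Reaction]) -> "ReactionNetwork":
        return replace(self, reactions=tuple(reactions))


def mass_action_rates(network: ReactionNetwork, concentrations: np.ndarray) -> np.ndarray:
    """Per-species concentration change rate (μM/s) from mass-action kinetics.

    Equals stoichiometry-matrix × reaction-velocity vector; no diffusion.
    Raises :class:`ValueError` for (materially) negative concentrations.
    """
    return network.rates(concentrations)


def apply_variant(
    network: ReactionNetwork,
    variant: ScenarioVariant | str | Sequence[ScenarioVariant | str],
) -> ReactionNetwork:
    """Return a new network with the perturbation(s) applied.

    Knockouts remove exactly the reactions carrying the targeted tag;
    ``rate_scale`` multiplies every rate constant; ``immobile_apoptosome``
    clears ``diffusible`` on apoptosome-containing species only;
    ``diffusivity_scale`` records the fold-impairment for the transport
    layer. The input network is never modified. Knockouts are idempotent.
    """
    if isinstance(variant, (list, tuple)):
        for v in variant:
            network = apply_variant(network, v)
        return network
    if isinstance(variant, str):
        variant = ScenarioVariant.parse(variant)

    if variant.kind in _KNOCKOUT_TAGS:
        tag = _KNOCKOUT_TAGS[variant.kind]
        return network.with_reactions(r for r in network.reactions if r.tag != tag)
    if variant.kind == "rate_scale":
        return network.with_reactions(
            replace(r, rate_constant=r.rate_constant * variant.value) for r in network.reactions
        )
    if variant.kind == "immobile_apoptosome":
        return network.with_species(
            replace(s, diffusible=False) if s.apoptosome_containing else s
            for s in network.species
        )
    if variant.kind == "diffusivity_scale":
        return replace(network, diffusivity_scale=network.diffusivity_scale * variant.value)
    raise ConfigurationError(f"unknown variant {variant.kind!r}")  # pragma: no cover


def build_reference_network(params: Mapping | None = None) -> ReactionNetwork:
    """Build the reference HeLa execution network from a parameter mapping.

    ``params`` is the parsed model description (see
    :func:`casprd.config.load_model_file`); ``None`` loads the packaged
    reconstructed default set. The mapping must provide a rate constant for
    every declared reaction and an initial concentration for every species;
    a missing rate constant raises :class:`ConfigurationError` naming the
    reaction tag.
    """
    from . import config  # deferred: config imports this module's types

    if params is None:
        params = config.default_model_parameters()
    return config.network_from_parameters(params)
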