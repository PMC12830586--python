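"""Declarative ODE clock models.

A model is a set of named species, named rate parameters, and one
right-hand-side expression per species written in terms of both.  Models are
plain JSON on disk, so the engine is agnostic to the particular clock
parameterization: the bundled reduced model can be swapped for a full
published parameterization (e.g. the detailed Kim–Forger mammalian clock)
by supplying a file in the same format.

Tagged roles connect generic species/rates to the biology the pipeline
measures:

``per2_mrna``
    the E-box read-out whose peak defines the phase of the clock,
``bmal1_mrna``
    the antiphase positive-limb transcript; its peak anchors circadian time 0,
``bmal1_clock_unphospho``
    nuclear BMAL1:CLOCK not yet phosphorylated at the activating site,
``phospho_bmal1_clock_nuclear``
    the transcriptionally active phosphorylated BMAL1:CLOCK pool,
``k_phos``
    the rate constant converting the former into the latter — the single
    parameter that synchronization protocols modulate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import sympy as sp

from .errors import ModelDefinitionError

__all__ = ["ClockModel", "load_model", "save_model", "default_model"]

_REQUIRED_SPECIES_TAGS = (
    "per2_mrna",
    "bmal1_mrna",
    "bmal1_clock_unphospho",
    "phospho_bmal1_clock_nuclear",
)


@dataclass
class ClockModel:
    """An ODE clock model compiled from a declarative definition.

    Parameters
    ----------
    name : str
        Human-readable identifier.
    species : sequence of str
        Ordered state variable names (arbitrary concentration units).
    parameters : mapping str -> float
        Rate constants (per hour, or per hour per concentration unit).
    odes : mapping str -> str
        One expression per species giving d(species)/dt in terms of species
        and parameter names.
    tagged_species : mapping role -> species name
    tagged_rates : mapping role -> parameter name; must contain ``k_phos``.
    initial_state : optional mapping str -> float
        A state from which integration converges onto the limit cycle.
    """

    name: str
    species: tuple[str, ...]
    parameters: dict[str, float]
    odes: dict[str, str]
    tagged_species: dict[str, str]
    tagged_rates: dict[str, str]
    initial_state: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.species = tuple(self.species)
        if len(set(self.species)) != len(self.species):
            raise ModelDefinitionError("duplicate species names")
        missing = [s for s in self.species if s not in self.odes]
        if missing:
            raise ModelDefinitionError(f"no ODE expression for species {missing}")
        for role in _REQUIRED_SPECIES_TAGS:
            target = self.tagged_species.get(role)
            if target not in self.species:
                raise ModelDefinitionError(
                    f"species tag {role!r} -> {target!r} does not resolve to a declared species"
                )
        kp = self.tagged_rates.get("k_phos")
        if kp not in self.parameters:
            raise ModelDefinitionError(
                f"rate tag 'k_phos' -> {kp!r} does not resolve to a declared parameter"
            )
        self._param_names = tuple(self.parameters)
        self._compile()

    def _compile(self) -> None:
        sym_y = sp.symbols(self.species)
        sym_p = sp.symbols(self._param_names)
        local = dict(zip(self.species, sym_y)) | dict(zip(self._param_names, sym_p))
        exprs = []
        for s in self.species:
            try:
                exprs.append(sp.sympify(self.odes[s], locals=local))
            except (sp.SympifyError, TypeError) as e:
                raise ModelDefinitionError(f"cannot parse ODE for {s!r}: {e}") from e
            free = exprs[-1].free_symbols - set(sym_y) - set(sym_p)
            if free:
                raise ModelDefinitionError(f"undeclared symbols {free} in ODE for {s!r}")
        self._rhs_fn: Callable = sp.lambdify((sym_y, sym_p), exprs, modules="math")

    # -- runtime interface -------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def k_phos_name(self) -> str:
        return self.tagged_rates["k_phos"]

    @property
    def k_phos_index(self) -> int:
        return self._param_names.index(self.k_phos_name)

    def species_index(self, role_or_name: str) -> int:
        name = self.tagged_species.get(role_or_name, role_or_name)
        try:
            return self.species.index(name)
        except ValueError:
            raise KeyError(f"unknown species or role {role_or_name!r}") from None

    def param_vector(self, overrides: Mapping[str, float] | None = None) -> np.ndarray:
        p = dict(self.parameters)
        if overrides:
            unknown = set(overrides) - set(p)
            if unknown:
                raise ModelDefinitionError(f"unknown parameters {unknown}")
            p.update(overrides)
        return np.array([p[k] for k in self._param_names], dtype=float)

    def rhs(self, params: np.ndarray) -> Callable[[float, np.ndarray], list]:
        """Autonomous right-hand side f(t, y) for a fixed parameter vector."""
        fn = self._rhs_fn
        pl = list(params)
        return lambda t, y: fn(y, pl)

    def default_initial_state(self) -> np.ndarray:
        if self.initial_state:
            return np.array([self.initial_state.get(s, 0.1) for s in self.species])
        return np.full(self.n_species, 0.5)

    def with_parameters(self, **overrides: float) -> "ClockModel":
        p = dict(self.parameters)
        p.update(overrides)
        return ClockModel(
            name=self.name,
            species=self.species,
            parameters=p,
            odes=dict(self.odes),
            tagged_species=dict(self.tagged_species),
            tagged_rates=dict(self.tagged_rates),
            initial_state=dict(self.initial_state),
        )


def load_model(path: str | Path) -> ClockModel:
    """Load a model from its JSON definition file."""
    raw = json.loads(Path(path).read_text())
    try:
        return ClockModel(
            name=raw.get("name", Path(path).stem),
            species=tuple(raw["species"]),
            parameters={k: float(v) for k, v in raw["parameters"].items()},
            odes=dict(raw["odes"]),
            tagged_species=dict(raw["tags"]["species"]),
            tagged_rates=dict(raw["tags"]["rates"]),
            initial_state={k: float(v) for k, v in raw.get("initial_state", {}).items()},
        )
    except KeyError as e:
        raise ModelDefinitionError(f"model file missing section {e}") from e


def save_model(model: ClockModel, path: str | Path) -> None:
    doc = {
        "name": model.name,
        "species": list(model.species),
        "parameters": model.parameters,
        "odes": model.odes,
        "tags": {"species": model.tagged_species, "rates": model.tagged_rates},
        "initial_state": model.initial_state,
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def default_model() -> ClockModel:
    """The bundled reduced clock model (7 states, ~23.5 h limit cycle).

    Interlocked negative/positive feedback in the style of the reduced
    mammalian clock model of Becker-Weimann et al. (Biophys J 2004): nuclear
    PER2/CRY represses its own E-box transcription (driven by active
    BMAL1:CLOCK) and activates Bmal1 transcription, producing the observed
    Per2/Bmal1 antiphase.  Relative to that published parameter set the
    nuclear activation (phosphorylation) step ``k_phos`` is faster (0.3/h),
    which leaves the period and amplitudes essentially unchanged but makes
    the maximal phospho-BMAL1:CLOCK induction insensitive to the duration of
    a transient rate increase — the behaviour reported for the detailed
    model this pipeline is built to exercise.
    """
    species = (
        "Per2_mRNA",       # E-box driven Per2/Cry transcript
        "PERCRY_c",        # cytoplasmic PER2/CRY protein complex
        "PERCRY_n",        # nuclear PER2/CRY (repressor / Bmal1 activator)
        "Bmal1_mRNA",
        "BMAL1_c",         # cytoplasmic BMAL1 (CLOCK implicit, non-limiting)
        "BMALCLOCK_n",     # nuclear BMAL1:CLOCK, not phosphorylated
        "pBMALCLOCK_n",    # phosphorylated, transcriptionally active BMAL1:CLOCK
    )
    parameters = {
        "v1b": 9.0, "k1b": 1.0, "k1i": 0.56, "c_act": 0.01, "p_hill": 8.0, "k1d": 0.12,
        "k2b": 0.3, "q_hill": 2.0, "k2d": 0.05, "k2t": 0.24, "k3t": 0.02, "k3d": 0.12,
        "v4b": 3.6, "k4b": 2.16, "r_hill": 3.0, "k4d": 0.75,
        "k5b": 0.24, "k5d": 0.06, "k5t": 0.45, "k6t": 0.06, "k6d": 0.12,
        "k_phos": 0.3, "k_dephos": 0.003, "k7d": 0.09,
    }
    odes = {
        "Per2_mRNA": (
            "v1b*(pBMALCLOCK_n + c_act)"
            "/(k1b*(1 + (PERCRY_n/k1i)**p_hill) + pBMALCLOCK_n + c_act)"
            " - k1d*Per2_mRNA"
        ),
        "PERCRY_c": "k2b*Per2_mRNA**q_hill - k2d*PERCRY_c - k2t*PERCRY_c + k3t*PERCRY_n",
        "PERCRY_n": "k2t*PERCRY_c - k3t*PERCRY_n - k3d*PERCRY_n",
        "Bmal1_mRNA": "v4b*PERCRY_n**r_hill/(k4b**r_hill + PERCRY_n**r_hill) - k4d*Bmal1_mRNA",
        "BMAL1_c": "k5b*Bmal1_mRNA - k5d*BMAL1_c - k5t*BMAL1_c + k6t*BMALCLOCK_n",
        "BMALCLOCK_n": (
            "k5t*BMAL1_c - k6t*BMALCLOCK_n - k6d*BMALCLOCK_n"
            " + k_dephos*pBMALCLOCK_n - k_phos*BMALCLOCK_n"
        ),
        "pBMALCLOCK_n": "k_phos*BMALCLOCK_n - k_dephos*pBMALCLOCK_n - k7d*pBMALCLOCK_n",
    }
    tagged_species = {
        "per2_mrna": "Per2_mRNA",
        "bmal1_mrna": "Bmal1_mRNA",
        "bmal1_clock_unphospho": "BMALCLOCK_n",
        "phospho_bmal1_clock_nuclear": "pBMALCLOCK_n",
    }
    tagged_rates = {"k_phos": "k_phos"}
    initial_state = {
        "Per2_mRNA": 0.2, "PERCRY_c": 0.2, "PERCRY_n": 2.0, "Bmal1_mRNA": 0.5,
        "BMAL1_c": 2.0, "BMALCLOCK_n": 1.0, "pBMALCLOCK_n": 1.0,
    }
    return ClockModel(
        name="reduced-bmal1-phospho-clock",
        species=species,
        parameters=parameters,
        odes=odes,
        tagged_species=tagged_species,
        tagged_rates=tagged_rates,
        initial_state=initial_state,
    )
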