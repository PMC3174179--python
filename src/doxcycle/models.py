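"""Model library: build the doxorubicin bioactivation model variants.

Two families of models are supported, both built from the shipped constant
tables (``doxcycle/data/*.yaml``):

* the cell-free (*in vitro*) model — 9 species, reactions R1–R6, with an
  optional enzymatic SOD dismutation term, at low (100 µM) or high (500 µM)
  initial NADPH;
* the cellular (*in vivo*) models — 10 species, reactions R1–R8, specific
  to the doxorubicin-resistant EU1-Res or doxorubicin-sensitive EU3-Sens
  ALL line, at a 10 µM or 100 nM extracellular doxorubicin dose.

EU3-Sens constants are the EU1-Res constants scaled by measured fold
changes (CPR content, basal NADPH, NOX rate ``k4``, G6PD supply ``k8``);
``k2 = k1`` always.  Pharmacological interventions (e.g. the G6PD inhibitor
DHEA) scale a single rate constant by ``1 - fraction``.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Any, Mapping

import yaml

from .network import ConfigurationError, Reaction, ReactionNetwork

__all__ = [
    "CellLineProfile",
    "KineticModel",
    "ScenarioConfig",
    "apply_intervention",
    "build_invitro_model",
    "build_invivo_model",
    "build_model",
    "cell_line_profile",
    "load_table",
    "surface_factor",
    "total_doxorubicin",
]

CELL_LINES = ("EU1-Res", "EU3-Sens")
#: intervention target aliases: drug name -> rate constant
INTERVENTION_ALIASES = {"DHEA": "k8"}


def load_table(name: str) -> dict[str, Any]:
    """Load a shipped constants table (``"invitro"`` or ``"invivo"``)."""
    ref = resources.files("doxcycle.data").joinpath(f"{name}.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def surface_factor(table: dict[str, Any] | None = None) -> float:
    """Aggregate membrane surface factor A (product of the shipped terms)."""
    table = table or load_table("invivo")
    return math.prod(table["surface_factor_terms"])


@dataclass(frozen=True)
class CellLineProfile:
    """Fold-change multipliers of a cell line relative to EU1-Res."""

    label: str
    cpr: float = 1.0
    nadph: float = 1.0
    k4: float = 1.0
    k6: float = 1.0
    k8: float = 1.0

    def __post_init__(self) -> None:
        for name in ("cpr", "nadph", "k4", "k6", "k8"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(
                    f"profile {self.label}: multiplier {name} must be > 0"
                )


def cell_line_profile(cell_line: str) -> CellLineProfile:
    """Fold-change profile for a supported cell line.

    EU1-Res is the all-ones reference.  EU3-Sens multipliers are derived as
    (printed EU3 value) / (printed EU1 value) from the shipped table, so
    scaling EU1-Res constants by the profile reproduces the printed EU3
    values exactly.  The SOD multiplier is 1 (no measured difference).
    """
    if cell_line == "EU1-Res":
        return CellLineProfile("EU1-Res")
    if cell_line == "EU3-Sens":
        t = load_table("invivo")
        eu3 = t["eu3_measured"]
        return CellLineProfile(
            "EU3-Sens",
            cpr=eu3["CPR_red"] / t["initial_conditions_eu1"]["CPR_red"],
            nadph=eu3["NADPH"] / t["initial_conditions_eu1"]["NADPH"],
            k4=eu3["k4"] / t["parameters_eu1"]["k4"],
            k6=1.0,
            k8=eu3["k8"] / t["parameters_eu1"]["k8"],
        )
    raise ConfigurationError(f"unknown cell line {cell_line!r}")


@dataclass
class ScenarioConfig:
    """Declarative description of one model variant / treatment condition.

    Parameters
    ----------
    kind : {"invitro", "invivo"}
    cell_line : {"EU1-Res", "EU3-Sens"}
        Cellular models only.
    dose : {"high", "low"}
        Extracellular doxorubicin condition, 10 µM or 100 nM (cellular).
    nadph0 : {"low", "high"}
        Initial NADPH, 100 µM or 500 µM (cell-free).
    sod : bool
        Add the enzymatic SOD dismutation term (cell-free).
    interventions : list of (target, fraction)
        Each scales the target constant by ``1 - fraction``; drug aliases
        (``"DHEA"`` → ``k8``) are resolved at build time.
    oxygen_clamp : bool
        Hold O2 at its initial value (cellular; default dynamic).
    r4_dox_modulation : bool
        Multiply the NOX rate by ``[In_Dox_q]/([In_Dox_q]+K)`` (cellular;
        default on).  ``"table-literal"`` behaviour = False.
    rho : float
        Cell-to-medium volume fraction coupling uptake: the extracellular
        pool depletes at k7*A*[Ex] while the (1000x smaller) cytosolic
        pool gains 1/rho of that molar flux.  Default 1e-3 (1e9 cells/L at
        ~1 pL per lymphoblast).
    overrides : dict
        Optional explicit overrides of parameters / initial conditions.
    """

    kind: str = "invivo"
    cell_line: str = "EU1-Res"
    dose: str = "high"
    nadph0: str = "low"
    sod: bool = False
    sod_conc: float | None = None
    interventions: list[tuple[str, float]] = field(default_factory=list)
    oxygen_clamp: bool = False
    r4_dox_modulation: bool = True
    rho: float = 1e-3
    overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("invitro", "invivo"):
            raise ConfigurationError(f"unknown model kind {self.kind!r}")
        if self.kind == "invivo" and self.cell_line not in CELL_LINES:
            raise ConfigurationError(f"unknown cell line {self.cell_line!r}")
        if self.dose not in ("high", "low"):
            raise ConfigurationError(f"unknown dose condition {self.dose!r}")
        if self.nadph0 not in ("low", "high"):
            raise ConfigurationError(f"unknown NADPH condition {self.nadph0!r}")
        if self.rho <= 0:
            raise ConfigurationError("rho must be > 0")
        for target, fraction in self.interventions:
            if not 0.0 <= fraction <= 1.0:
                raise ConfigurationError(
                    f"intervention on {target}: fraction {fraction} outside [0, 1]"
                )

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["interventions"] = [list(iv) for iv in self.interventions]
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ScenarioConfig":
        d = dict(d)
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown scenario fields {sorted(unknown)}")
        d["interventions"] = [tuple(iv) for iv in d.get("interventions", [])]
        return cls(**d)


@dataclass
class KineticModel:
    """A built model: network, initial state, parameters and provenance."""

    network: ReactionNetwork
    initial_state: dict[str, float]
    parameters: dict[str, float]
    scenario: ScenarioConfig

    @property
    def species(self) -> tuple[str, ...]:
        return self.network.species

    def with_parameter(self, name: str, value: float) -> "KineticModel":
        """Rebuild this model with one rate constant replaced (``k2`` stays
        tied to ``k1``)."""
        scenario = copy.deepcopy(self.scenario)
        scenario.overrides = dict(scenario.overrides)
        scenario.overrides[name] = value
        return build_model(scenario)


def _resolve_interventions(
    params: dict[str, float], scenario: ScenarioConfig
) -> dict[str, float]:
    params = dict(params)
    for target, fraction in scenario.interventions:
        key = INTERVENTION_ALIASES.get(target, target)
        if key not in params:
            raise ConfigurationError(f"intervention target {target!r} unknown")
        params[key] *= 1.0 - fraction
    return params


def _apply_overrides(
    params: dict[str, float], y0: dict[str, float], scenario: ScenarioConfig
) -> None:
    for key, value in scenario.overrides.items():
        if key in params:
            params[key] = value
        elif key in y0:
            y0[key] = value
        else:
            raise ConfigurationError(f"override target {key!r} unknown")


def build_invitro_model(scenario: ScenarioConfig) -> KineticModel:
    """Cell-free model: 9 species, R1–R6 (+ optional SOD term)."""
    if scenario.kind != "invitro":
        raise ConfigurationError("scenario kind must be 'invitro'")
    t = load_table("invitro")
    y0 = dict(t["initial_conditions"])
    if scenario.nadph0 == "high":
        y0["NADPH"] = t["nadph_high"]
    params = dict(t["parameters"])
    params["k2"] = params["k1"]
    params = _resolve_interventions(params, scenario)
    _apply_overrides(params, y0, scenario)
    params["k2"] = params["k1"]  # tied under every construction path

    reactions = [
        Reaction("R1", "bimolecular", ("CPR_red", "Dox_q"),
                 {"CPR_red": -1, "Dox_q": -1, "CPR_ox": 1, "Dox_sq": 1},
                 {"k": params["k1"]}),
        Reaction("R2", "bimolecular", ("CPR_ox", "NADPH"),
                 {"CPR_ox": -1, "NADPH": -1, "CPR_red": 1, "NADP": 1},
                 {"k": params["k2"]}),
        Reaction("R3", "bimolecular", ("O2", "Dox_sq"),
                 {"O2": -1, "Dox_sq": -1, "O2minus": 1, "Dox_q": 1},
                 {"k": params["k3"]}),
        Reaction("R4", "bimolecular", ("NADPH", "O2"),
                 {"NADPH": -1, "O2": -1, "NADP": 1, "O2minus": 1},
                 {"k": params["k4"]}),
        Reaction("R5", "bimolecular", ("O2minus", "Dox_q"),
                 {"O2minus": -1, "Dox_q": -1, "Dox_sq": 1, "O2": 1},
                 {"k": params["k5"]}),
        # spontaneous dismutation: modelled as a terminal superoxide sink
        # (no O2 returned) so that high NADPH can competitively deplete the
        # assay's O2 pool — the prerequisite for the reductive-conversion
        # switch; the enzymatic SOD term below does regenerate O2.
        Reaction("R6", "bimolecular", ("O2minus", "O2minus"),
                 {"O2minus": -2, "H2O2": 1},
                 {"k": params["k6"]}),
    ]
    if scenario.sod:
        sod_conc = scenario.sod_conc
        if sod_conc is None:
            sod_conc = t["sod_condition"]["sod_conc"]
        k_sod = params.get("k_sod", t["sod_condition"]["k_sod"])
        params["k_sod"] = k_sod
        params["sod_conc"] = sod_conc
        # enzymatic dismutation, first order in O2-; per catalytic
        # encounter O2- -> 1/2 H2O2 + 1/2 O2 (linear law reuses the
        # permeation kind with [SOD] as the constant prefactor)
        reactions.append(
            Reaction("Rsod", "permeation", ("O2minus",),
                     {"O2minus": -1, "H2O2": 0.5, "O2": 0.5},
                     {"k": k_sod, "area": sod_conc})
        )
    network = ReactionNetwork(tuple(t["initial_conditions"]), tuple(reactions))
    return KineticModel(network, y0, params, scenario)


def build_invivo_model(scenario: ScenarioConfig) -> KineticModel:
    """Cellular model: 10 species, R1–R8, cell-line and dose specific."""
    if scenario.kind != "invivo":
        raise ConfigurationError("scenario kind must be 'invivo'")
    t = load_table("invivo")
    profile = cell_line_profile(scenario.cell_line)

    y0 = dict(t["initial_conditions_eu1"])
    y0["CPR_red"] *= profile.cpr
    y0["NADPH"] *= profile.nadph
    y0["Ex_Dox_q"] = t["doses"][scenario.dose]
    y0["NADP"] = t["nadp_ratio"] * y0["NADPH"]

    params = dict(t["parameters_eu1"])
    params["k2"] = params["k1"]
    params["k4"] *= profile.k4
    params["k6"] *= profile.k6
    params["k8"] *= profile.k8
    if scenario.dose not in t["k7_by_dose"]:
        raise ConfigurationError(f"no k7 entry for dose {scenario.dose!r}")
    params["k7"] = t["k7_by_dose"][scenario.dose]
    params["A"] = surface_factor(t)
    params = _resolve_interventions(params, scenario)
    _apply_overrides(params, y0, scenario)
    params["k2"] = params["k1"]
    if "NADPH" in scenario.overrides and "NADP" not in scenario.overrides:
        y0["NADP"] = t["nadp_ratio"] * y0["NADPH"]

    r4_modifier = None
    if scenario.r4_dox_modulation:
        r4_modifier = ("In_Dox_q", t["r4_dox_modulation_K"])

    reactions = (
        Reaction("R1", "bimolecular", ("CPR_red", "In_Dox_q"),
                 {"CPR_red": -1, "In_Dox_q": -1, "CPR_ox": 1, "In_Dox_sq": 1},
                 {"k": params["k1"]}),
        Reaction("R2", "bimolecular", ("CPR_ox", "NADPH"),
                 {"CPR_ox": -1, "NADPH": -1, "CPR_red": 1, "NADP": 1},
                 {"k": params["k2"]}),
        Reaction("R3", "bimolecular", ("O2", "In_Dox_sq"),
                 {"O2": -1, "In_Dox_sq": -1, "O2minus": 1, "In_Dox_q": 1},
                 {"k": params["k3"]}),
        Reaction("R4", "bimolecular", ("NADPH", "O2"),
                 {"NADPH": -1, "O2": -1, "NADP": 1, "O2minus": 1},
                 {"k": params["k4"]}, modifier=r4_modifier),
        Reaction("R5", "bimolecular", ("O2minus", "In_Dox_q"),
                 {"O2minus": -1, "In_Dox_q": -1, "In_Dox_sq": 1, "O2": 1},
                 {"k": params["k5"]}),
        Reaction("R6", "bimolecular", ("O2minus", "O2minus"),
                 {"O2minus": -2, "H2O2": 1, "O2": 1},
                 {"k": params["k6"]}),
        # uptake: rate k7*A*[Ex] is referenced to the medium volume (it is
        # the extracellular depletion rate); the cytosol, occupying a
        # volume fraction rho of the culture, concentrates the same molar
        # flux 1/rho-fold
        Reaction("R7", "permeation", ("Ex_Dox_q",),
                 {"Ex_Dox_q": -1.0, "In_Dox_q": 1.0 / scenario.rho},
                 {"k": params["k7"], "area": params["A"]}),
        Reaction("R8", "saturable_supply", ("NADP",),
                 {"NADP": -1, "NADPH": 1},
                 {"vmax": params["k8"], "km": params["k9"]}),
    )
    clamped = frozenset({"O2"}) if scenario.oxygen_clamp else frozenset()
    network = ReactionNetwork(
        tuple(t["initial_conditions_eu1"]), reactions, clamped
    )
    return KineticModel(network, y0, params, scenario)


def total_doxorubicin(model: KineticModel, state: Mapping[str, float]) -> float:
    """Conserved total drug (M, medium-referenced).

    Cell-free: Dox_q + Dox_sq.  Cellular: Ex_Dox_q + rho*(In_Dox_q +
    In_Dox_sq), because intracellular concentrations are referenced to the
    rho-fold smaller cytosolic volume.
    """
    if model.scenario.kind == "invitro":
        return state["Dox_q"] + state["Dox_sq"]
    rho = model.scenario.rho
    return state["Ex_Dox_q"] + rho * (state["In_Dox_q"] + state["In_Dox_sq"])


def build_model(scenario: ScenarioConfig) -> KineticModel:
    """Dispatch on scenario kind."""
    if scenario.kind == "invitro":
        return build_invitro_model(scenario)
    return build_invivo_model(scenario)


def apply_intervention(
    model: KineticModel, target: str, fraction: float
) -> KineticModel:
    """Return a copy of *model* with *target* scaled by ``1 - fraction``.

    *target* may be a rate-constant name (``"k8"``) or a drug alias
    (``"DHEA"``).  The original model is untouched.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ConfigurationError(f"fraction {fraction} outside [0, 1]")
    key = INTERVENTION_ALIASES.get(target, target)
    if key not in model.parameters:
        raise ConfigurationError(f"intervention target {target!r} unknown")
    scenario = copy.deepcopy(model.scenario)
    scenario.interventions = list(scenario.interventions) + [(key, fraction)]
    return build_model(scenario)
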