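"""Downstream analyses: metabolic-mode classification, intervention flux
comparison, and local sensitivity analysis.

*Metabolic mode.*  A trajectory is classified as *reductive conversion*
(net transformation of quinone doxorubicin into its semiquinone, the
toxicity-associated mode) when the fractional loss of quinone relative to
the most quinone ever available along the trajectory exceeds a threshold
(default 0.2); otherwise as *redox cycling* (futile re-oxidation with zero
net transformation, the ROS-producing mode).

*Intervention fluxes.*  For the 2x2 grid of cell line x dose, the
time-integrated semiquinone-formation flux (reaction R1) and the
NADPH-dependent superoxide flux (reaction R4) over the 60-min treatment
are compared with and without an intervention (default: the G6PD inhibitor
DHEA, 20% inhibition of k8).

*Sensitivity.*  Normalized local sensitivity coefficients by central
difference: each quantity x (a rate constant or an initial concentration)
is perturbed to x(1 ± delta) one at a time and

    S_i = [O(x(1+delta)) - O(x(1-delta))] / O(x) / (2 delta)

is reported for the 60-min readouts: quinone accumulation, NADPH depletion
and cumulative superoxide production.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .models import KineticModel, ScenarioConfig, build_model
from .simulate import compute_observables, integrate, integrated_flux
from .timecourse import TimeCourse, TimeCourseError

__all__ = [
    "FluxComparison",
    "SensitivityReport",
    "classify_metabolic_mode",
    "compare_intervention_fluxes",
    "sensitivity_scan",
]

#: default perturbed quantities: NOX, SOD and G6PD rate constants plus the
#: NADPH, CPR and O2 initial concentrations
DEFAULT_SENSITIVITY_QUANTITIES = ("k8", "k6", "k4", "NADPH", "CPR_red", "O2")
SENSITIVITY_READOUTS = ("quinone_accumulation", "nadph_depletion",
                        "superoxide_production")

#: dense grid (minutes) used for flux integrals and endpoint readouts
DENSE_GRID_MIN = np.linspace(0.0, 60.0, 241)

MODE_REDUCTIVE = "reductive_conversion"
MODE_REDOX = "redox_cycling"


def classify_metabolic_mode(
    tc: TimeCourse, threshold: float = 0.2
) -> str:
    """Classify a trajectory as reductive conversion or redox cycling.

    Uses the quinone series (``Dox_q`` or ``In_Dox_q``): the mode is
    reductive conversion when ``1 - q(end)/max(q)`` exceeds *threshold*.
    Invariant to uniform rescaling of concentration units.
    """
    name = "Dox_q" if "Dox_q" in tc.series else "In_Dox_q"
    if name not in tc.series:
        raise TimeCourseError("trajectory lacks a quinone doxorubicin series")
    q = tc.series[name]
    peak = float(np.max(q))
    if peak <= 0.0:
        return MODE_REDOX
    transformed = 1.0 - float(q[-1]) / peak
    return MODE_REDUCTIVE if transformed > threshold else MODE_REDOX


@dataclass
class FluxComparison:
    """Control vs intervention time-integrated fluxes for one condition."""

    cell_line: str
    dose: str
    intervention: str
    semiquinone_control: float
    semiquinone_intervention: float
    superoxide_control: float
    superoxide_intervention: float

    def ratio(self, which: str) -> float:
        """Intervention/control flux ratio; requires control > 0."""
        ctrl, trt = {
            "semiquinone": (self.semiquinone_control,
                            self.semiquinone_intervention),
            "superoxide": (self.superoxide_control,
                           self.superoxide_intervention),
        }[which]
        if ctrl <= 0.0:
            raise ZeroDivisionError(f"{which} control flux is zero")
        return trt / ctrl


def _window_fluxes(model: KineticModel,
                   window_min: tuple[float, float]) -> tuple[float, float]:
    tc = integrate(model, DENSE_GRID_MIN)
    semi = integrated_flux(model, tc, "R1", window_min)
    supo = integrated_flux(model, tc, "R4", window_min)
    return semi, supo


def compare_intervention_fluxes(
    cell_lines: Sequence[str] = ("EU1-Res", "EU3-Sens"),
    doses: Sequence[str] = ("high", "low"),
    target: str = "DHEA",
    fraction: float = 0.2,
    window_min: tuple[float, float] = (0.0, 60.0),
    scenario_options: Mapping[str, object] | None = None,
) -> list[FluxComparison]:
    """Control/intervention flux pairs over the cell line x dose grid."""
    options = dict(scenario_options or {})
    out: list[FluxComparison] = []
    for cell_line in cell_lines:
        for dose in doses:
            control = build_model(ScenarioConfig(
                kind="invivo", cell_line=cell_line, dose=dose, **options))
            treated = build_model(ScenarioConfig(
                kind="invivo", cell_line=cell_line, dose=dose,
                interventions=[(target, fraction)], **options))
            semi_c, supo_c = _window_fluxes(control, window_min)
            semi_t, supo_t = _window_fluxes(treated, window_min)
            out.append(FluxComparison(
                cell_line, dose, f"{target}:{fraction:g}",
                semi_c, semi_t, supo_c, supo_t))
    return out


@dataclass
class SensitivityReport:
    """Normalized sensitivity coefficients, quantity x readout."""

    delta: float
    coefficients: dict[str, dict[str, float]] = field(default_factory=dict)
    #: readouts whose baseline was ~0, where S_i is undefined
    undefined: list[tuple[str, str]] = field(default_factory=list)


def _endpoint_readouts(model: KineticModel) -> dict[str, float]:
    tc = integrate(model, DENSE_GRID_MIN)
    obs = compute_observables(model, tc,
                              ("quinone_dox", "nadph", "superoxide_signal"))
    nadph0 = tc.series["NADPH"][0]
    return {
        "quinone_accumulation": float(obs.series["quinone_dox"][-1]),
        "nadph_depletion": float(nadph0 * (1.0 - obs.series["nadph"][-1])),
        "superoxide_production": float(obs.series["superoxide_signal"][-1]),
    }


def _perturbed(model: KineticModel, quantity: str, factor: float) -> KineticModel:
    scenario = model.scenario
    if quantity in model.initial_state and quantity not in model.parameters:
        base = model.initial_state[quantity]
    elif quantity in model.parameters:
        base = model.parameters[quantity]
    else:
        raise TimeCourseError(f"unknown sensitivity quantity {quantity!r}")
    sc = copy.deepcopy(scenario)
    sc.overrides = dict(sc.overrides)
    sc.overrides[quantity] = base * factor
    return build_model(sc)


def sensitivity_scan(
    model: KineticModel | None = None,
    quantities: Sequence[str] = DEFAULT_SENSITIVITY_QUANTITIES,
    delta: float = 0.10,
) -> SensitivityReport:
    """Central-difference normalized sensitivities of the 60-min readouts.

    Defaults to the EU1-Res model at the 10 µM dose.  A readout whose
    baseline magnitude is ~0 yields an undefined coefficient, flagged in
    the report rather than reported as a number.
    """
    if model is None:
        model = build_model(ScenarioConfig(
            kind="invivo", cell_line="EU1-Res", dose="high"))
    if not 0.0 < delta < 1.0:
        raise ValueError("delta must be in (0, 1)")
    baseline = _endpoint_readouts(model)
    report = SensitivityReport(delta=delta)
    for q in quantities:
        up = _endpoint_readouts(_perturbed(model, q, 1.0 + delta))
        dn = _endpoint_readouts(_perturbed(model, q, 1.0 - delta))
        row: dict[str, float] = {}
        for readout in SENSITIVITY_READOUTS:
            base = baseline[readout]
            if not math.isfinite(base) or abs(base) < 1e-300:
                report.undefined.append((q, readout))
                continue
            row[readout] = (up[readout] - dn[readout]) / base / (2.0 * delta)
        report.coefficients[q] = row
    return report
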