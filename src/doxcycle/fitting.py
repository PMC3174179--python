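"""Least-squares time-course fitting of single rate constants.

The cost function is the plain sum of squared residuals

    U = sum_j sum_k (y_exp[j, t_k] - y_model[j, t_k])^2

over observable series *j* and grid points *t_k*, optionally after
max-normalizing each series (both data and prediction).  Each unknown rate
constant is fitted *independently* by deterministic bounded scalar
minimization of U (golden-section/parabolic, in log10 parameter space,
because the constants span many decades), against the one dataset that
informs it:

in vitro (11-point grid, 0–20 min, normalized quinone dox + NADPH)
    ``k1`` from the redox-cycling condition (100 µM NADPH),
    ``k4`` from the reductive-conversion condition (500 µM NADPH),
    ``k5`` from the SOD-induced redox-cycling condition;
in vivo (7-point grid, 0–60 min, EU1-Res at 10 µM only)
    ``k7`` from raw extracellular doxorubicin depletion,
    ``k8`` from max-normalized NADPH depletion.

``k2`` stays tied to ``k1`` throughout; EU3-Sens constants are derived by
fold-change scaling, never fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .models import KineticModel, ScenarioConfig, build_model
from .simulate import compute_observables, integrate, max_normalize
from .timecourse import TimeCourse, TimeCourseError

__all__ = [
    "FitResult",
    "FitSpec",
    "GRID_INVITRO_MIN",
    "GRID_INVIVO_MIN",
    "cost_U",
    "fit_parameter",
    "run_invitro_pipeline",
    "run_invivo_pipeline",
    "run_paper_fit_pipeline",
]

#: fitting grids (minutes): 11 points for the cell-free assays,
#: 7 points for the cellular readouts
GRID_INVITRO_MIN = np.arange(0.0, 21.0, 2.0)
GRID_INVIVO_MIN = np.arange(0.0, 61.0, 10.0)

#: relative parameter-change convergence tolerance
REL_XTOL = 1e-6


@dataclass
class FitSpec:
    """One single-parameter fit: scenario, dataset, observables, bounds."""

    target: str
    scenario: ScenarioConfig
    dataset: TimeCourse
    observables: tuple[str, ...]
    normalize: bool = True
    initial_guess: float | None = None
    bounds: tuple[float, float] | None = None

    def resolved_guess(self) -> float:
        if self.initial_guess is not None:
            return float(self.initial_guess)
        base = build_model(self.scenario).parameters[self.target]
        return 10.0 * base  # default: one decade above the tabulated scale

    def resolved_bounds(self) -> tuple[float, float]:
        if self.bounds is not None:
            lo, hi = self.bounds
        else:
            g = self.resolved_guess()
            lo, hi = 1e-3 * g, 1e3 * g
        if not lo < hi or lo <= 0:
            raise ValueError(f"invalid bounds ({lo}, {hi})")
        return float(lo), float(hi)


@dataclass
class FitResult:
    """Outcome of one bounded scalar minimization."""

    target: str
    value: float
    cost: float
    n_evaluations: int
    converged: bool
    provenance: str = ""
    #: best-so-far cost after each accepted improvement (non-increasing)
    accepted_costs: list[float] = field(default_factory=list)


def cost_U(
    prediction: TimeCourse,
    data: TimeCourse,
    series: Sequence[str] | None = None,
    normalize: bool = True,
) -> float:
    """Sum of squared residuals between data and prediction.

    Both inputs must share the fitting grid.  With ``normalize=True`` each
    series (data and prediction alike) is scaled to its own maximum first,
    which makes U invariant to rescaling a dataset by a positive constant.
    NaNs in the data are rejected with the series name and time index.
    """
    if series is None:
        series = sorted(set(prediction.series) & set(data.series))
        if not series:
            raise TimeCourseError("no shared series between data and prediction")
    if prediction.t_min.shape != data.t_min.shape or not np.allclose(
        prediction.t_min, data.t_min
    ):
        raise TimeCourseError("data and prediction grids differ")
    total = 0.0
    for name in series:
        y_exp = data.series[name]
        bad = np.flatnonzero(~np.isfinite(y_exp))
        if bad.size:
            raise TimeCourseError(
                f"series {name!r}: non-finite data at time index {bad[0]}"
            )
        y_mod = prediction.series[name]
        if normalize:
            y_exp = max_normalize(y_exp)
            y_mod = max_normalize(y_mod)
        total += float(np.sum((y_exp - y_mod) ** 2))
    return total


def fit_parameter(spec: FitSpec) -> FitResult:
    """Fit one rate constant by bounded scalar minimization of U.

    Deterministic given the spec (no randomness).  The search runs in
    log10 space over the resolved bounds; convergence is a relative
    parameter change below 1e-6.  On non-convergence the best value found
    is retained and the result flagged.
    """
    lo, hi = spec.resolved_bounds()
    grid = spec.dataset.t_min
    evals = {"n": 0}
    accepted: list[float] = []

    def objective(x: float) -> float:
        evals["n"] += 1
        model = build_model_with(spec.scenario, spec.target, 10.0**x)
        tc = integrate(model, grid)
        pred = compute_observables(
            model, tc, spec.observables, normalize=spec.normalize
        )
        u = cost_U(pred, spec.dataset, spec.observables, normalize=spec.normalize)
        if not accepted or u < accepted[-1]:
            accepted.append(u)
        return u

    res = minimize_scalar(
        objective,
        bounds=(np.log10(lo), np.log10(hi)),
        method="bounded",
        options={"xatol": REL_XTOL / np.log(10.0) / 2.0, "maxiter": 200},
    )
    return FitResult(
        target=spec.target,
        value=float(10.0**res.x),
        cost=float(res.fun),
        n_evaluations=evals["n"],
        converged=bool(res.success),
        provenance=f"{spec.scenario.kind}:{spec.target}",
        accepted_costs=accepted,
    )


def build_model_with(
    scenario: ScenarioConfig, target: str, value: float
) -> KineticModel:
    """Build the scenario's model with one rate constant overridden."""
    base = build_model(scenario)
    return base.with_parameter(target, value)


# -- staged pipelines -------------------------------------------------------

INVITRO_STAGES = (
    # (target, dataset key, scenario kwargs, observables)
    ("k1", "redox_cycling", {"nadph0": "low"}, ("quinone_dox", "nadph")),
    ("k4", "reductive_conversion", {"nadph0": "high"}, ("quinone_dox", "nadph")),
    ("k5", "sod_redox_cycling", {"nadph0": "high", "sod": True},
     ("quinone_dox", "nadph")),
)

INVIVO_STAGES = (
    ("k7", "extracellular_depletion", ("extracellular_dox",), False),
    ("k8", "nadph_depletion", ("nadph",), True),
)


def run_invitro_pipeline(
    datasets: Mapping[str, TimeCourse],
    initial_guesses: Mapping[str, float] | None = None,
) -> list[FitResult]:
    """Staged cell-free fits: k1, then k4, then k5, each on its own dataset.

    Fitted values are carried forward into later stages (k2 stays tied to
    k1).  A missing stage dataset aborts the pipeline; results obtained so
    far are returned with the failure recorded.
    """
    initial_guesses = dict(initial_guesses or {})
    carried: dict[str, float] = {}
    results: list[FitResult] = []
    for target, key, scen_kwargs, observables in INVITRO_STAGES:
        if key not in datasets:
            results.append(FitResult(target, float("nan"), float("nan"), 0,
                                     False, provenance=f"missing dataset {key!r}"))
            break
        scenario = ScenarioConfig(kind="invitro", overrides=dict(carried),
                                  **scen_kwargs)
        spec = FitSpec(target, scenario, datasets[key], observables,
                       normalize=True, initial_guess=initial_guesses.get(target))
        result = fit_parameter(spec)
        result.provenance = f"invitro:{target}<-{key}"
        results.append(result)
        carried[target] = result.value
    return results


def run_invivo_pipeline(
    datasets: Mapping[str, TimeCourse],
    initial_guesses: Mapping[str, float] | None = None,
    dose: str = "high",
) -> list[FitResult]:
    """Staged cellular fits on EU1-Res at 10 µM: k7 (raw extracellular
    depletion), then k8 (max-normalized NADPH depletion)."""
    initial_guesses = dict(initial_guesses or {})
    carried: dict[str, float] = {}
    results: list[FitResult] = []
    for target, key, observables, normalize in INVIVO_STAGES:
        if key not in datasets:
            results.append(FitResult(target, float("nan"), float("nan"), 0,
                                     False, provenance=f"missing dataset {key!r}"))
            break
        scenario = ScenarioConfig(kind="invivo", cell_line="EU1-Res",
                                  dose=dose, overrides=dict(carried))
        spec = FitSpec(target, scenario, datasets[key], observables,
                       normalize=normalize,
                       initial_guess=initial_guesses.get(target))
        result = fit_parameter(spec)
        result.provenance = f"invivo:{target}<-{key}"
        results.append(result)
        carried[target] = result.value
    return results


def run_paper_fit_pipeline(
    kind: str,
    datasets: Mapping[str, TimeCourse],
    initial_guesses: Mapping[str, float] | None = None,
) -> list[FitResult]:
    """Dispatch to the staged in vitro or in vivo fitting workflow."""
    if kind == "invitro":
        return run_invitro_pipeline(datasets, initial_guesses)
    if kind == "invivo":
        return run_invivo_pipeline(datasets, initial_guesses)
    raise ValueError(f"unknown pipeline kind {kind!r}")
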