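"""Seeded pseudo-experimental datasets for the fitting and analysis stages.

The generator integrates a model, maps the trajectory to the plate-reader
style observables, and adds seeded additive Gaussian noise (sigma expressed
as a fraction of each series' maximum) to a configurable number of
replicates — emulating triplicate absorbance/fluorescence time courses:

* cell-free datasets: normalized quinone doxorubicin and NADPH on the
  11-point 0–20 min grid, clipped to [0, 1.05] like a normalized assay;
* cellular datasets: quinone accumulation, NADPH fraction, cumulative
  superoxide signal and extracellular doxorubicin on the 7-point
  0–60 min grid.

Negative noisy values are clipped at 0 (absorbance cannot be negative);
the number of clipped points is recorded.  Identical seeds give
bit-identical datasets.  The generating parameters are recorded verbatim
so recovery tests can close the loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .fitting import GRID_INVITRO_MIN, GRID_INVIVO_MIN
from .models import ScenarioConfig, build_model
from .simulate import compute_observables, integrate
from .timecourse import SeriesMeta, TimeCourse, replicate_mean

__all__ = [
    "NoiseModel",
    "SyntheticDataset",
    "generate_invitro_dataset",
    "generate_invivo_dataset",
    "pipeline_datasets",
]

INVITRO_OBSERVABLES = ("quinone_dox", "nadph")
INVIVO_OBSERVABLES = (
    "quinone_dox", "nadph", "superoxide_signal", "extracellular_dox",
)
#: normalized cell-free assay range
INVITRO_CLIP = (0.0, 1.05)


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise: sigma as a fraction of each series' max."""

    sigma: float = 0.02
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class SyntheticDataset:
    """Replicated noisy observables plus the generating ground truth."""

    scenario: ScenarioConfig
    noise: NoiseModel
    truth: TimeCourse
    replicates: dict[int, TimeCourse]
    generating_parameters: dict[str, float]
    n_clipped: int = 0
    meta: dict[str, str] = field(default_factory=dict)

    def mean(self) -> TimeCourse:
        """Pointwise replicate mean (what the fitting stages consume)."""
        return replicate_mean(self.replicates)


def _generate(
    scenario: ScenarioConfig,
    noise: NoiseModel,
    grid_min: np.ndarray,
    observables: tuple[str, ...],
    normalize: bool,
    clip: tuple[float, float] | None,
) -> SyntheticDataset:
    model = build_model(scenario)
    tc = integrate(model, grid_min)
    truth = compute_observables(model, tc, observables, normalize=normalize)
    rng = np.random.default_rng(noise.seed)
    reps: dict[int, TimeCourse] = {}
    n_clipped = 0
    for r in range(noise.replicates):
        series = {}
        for name in observables:
            clean = truth.series[name]
            scale = noise.sigma * (np.max(np.abs(clean)) or 1.0)
            noisy = clean + rng.normal(0.0, scale, size=clean.shape) \
                if noise.sigma > 0 else clean.copy()
            lo, hi = clip if clip is not None else (0.0, np.inf)
            clipped = np.clip(noisy, lo, hi)
            n_clipped += int(np.sum(clipped != noisy))
            series[name] = clipped
        reps[r] = TimeCourse(grid_min.copy(), series, dict(truth.meta))
    return SyntheticDataset(
        scenario=scenario,
        noise=noise,
        truth=truth,
        replicates=reps,
        generating_parameters=dict(model.parameters),
        n_clipped=n_clipped,
    )


def generate_invitro_dataset(
    scenario: ScenarioConfig, noise: NoiseModel = NoiseModel()
) -> SyntheticDataset:
    """Cell-free dataset: normalized doxorubicin and NADPH, 11-point grid."""
    if scenario.kind != "invitro":
        raise ValueError("scenario kind must be 'invitro'")
    return _generate(scenario, noise, GRID_INVITRO_MIN,
                     INVITRO_OBSERVABLES, normalize=True, clip=INVITRO_CLIP)


def generate_invivo_dataset(
    scenario: ScenarioConfig, noise: NoiseModel = NoiseModel()
) -> SyntheticDataset:
    """Cellular dataset: quinone, NADPH fraction, cumulative superoxide
    signal and extracellular doxorubicin on the 7-point grid."""
    if scenario.kind != "invivo":
        raise ValueError("scenario kind must be 'invivo'")
    return _generate(scenario, noise, GRID_INVIVO_MIN,
                     INVIVO_OBSERVABLES, normalize=False, clip=(0.0, np.inf))


def pipeline_datasets(kind: str, noise: NoiseModel = NoiseModel(sigma=0.0)) \
        -> dict[str, TimeCourse]:
    """Generate the full set of stage datasets for a fitting pipeline.

    Returns replicate means keyed the way the pipelines expect.
    """
    if kind == "invitro":
        specs = {
            "redox_cycling": ScenarioConfig(kind="invitro", nadph0="low"),
            "reductive_conversion": ScenarioConfig(kind="invitro", nadph0="high"),
            "sod_redox_cycling": ScenarioConfig(kind="invitro", nadph0="high",
                                                sod=True),
        }
        return {
            key: generate_invitro_dataset(sc, noise).mean()
            for key, sc in specs.items()
        }
    if kind == "invivo":
        sc = ScenarioConfig(kind="invivo", cell_line="EU1-Res", dose="high")
        ds = generate_invivo_dataset(sc, noise)
        mean = ds.mean()
        return {
            "extracellular_depletion": mean.subset(["extracellular_dox"]),
            "nadph_depletion": mean.subset(["nadph"]),
        }
    raise ValueError(f"unknown pipeline kind {kind!r}")
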