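"""Synthetic data with the statistical structure the analysis assumes.

Raw measurements for this system exist only as published figures, so every
pipeline stage is validated on generated data instead: bulk mRNA time
courses (closed-form induction trajectory plus multiplicative Gaussian
measurement noise, in replicate) and single-cell flow snapshots (independent
populations per replicate from the stochastic accumulation model).

The strain presets encode truth parameters reverse-engineered from the
published summary statistics — onset times, steady states and half-times of
the bulk fits, and the mean activation times / expression rates of the
single-cell fits.  They reproduce those printed summaries by construction;
they are not claimed to equal the unpublished fitted parameter sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .flow_sim import CellSnapshot, FlowParams, sample_population
from .kinetics import KineticParams, TimeCourse, predict_mrna

__all__ = ["ScenarioSpec", "make_mrna_dataset", "make_flow_dataset", "strain_presets"]


@dataclass(frozen=True)
class ScenarioSpec:
    """Ground-truth parameters and sampling plan for one synthetic strain."""

    strain_label: str
    kinetic_truth: KineticParams
    flow_truth: FlowParams
    mrna_noise_cv: float = 0.05
    n_replicates: int = 3
    mrna_times: tuple = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0)
    mrna_time_unit: str = "hours"
    flow_times: tuple = (0.0, 2.0, 4.0, 6.0)
    n_cells: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mrna_noise_cv < 0:
            raise ValueError("mrna_noise_cv must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


def make_mrna_dataset(spec: ScenarioSpec) -> TimeCourse:
    """Replicate bulk mRNA measurements from the closed-form trajectory.

    Each measurement is ``M(t) * (1 + eta)`` with
    ``eta ~ Normal(0, cv^2)``, clipped at zero — multiplicative error, since
    expression ratios are positive with scale-dependent scatter.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng([spec.seed, 0])
    times = np.asarray(spec.mrna_times, dtype=float)
    clean = predict_mrna(spec.kinetic_truth, times)
    noise = rng.normal(0.0, spec.mrna_noise_cv, size=(spec.n_replicates, times.size))
    values = np.clip(clean[None, :] * (1.0 + noise), 0.0, None)
    return TimeCourse(times, values, label=spec.strain_label, time_unit=spec.mrna_time_unit)


def make_flow_dataset(spec: ScenarioSpec) -> list[CellSnapshot]:
    """Replicate single-cell snapshot sets from the accumulation model.

    Each replicate is an independent population (its own derived seed)
    observed at every snapshot time; samples are labelled
    ``"<strain>/repN"``.
    """
    snaps: list[CellSnapshot] = []
    for r in range(spec.n_replicates):
        snaps.extend(
            sample_population(
                spec.flow_truth,
                spec.n_cells,
                spec.flow_times,
                seed=np.random.default_rng([spec.seed, 1, r]).integers(2**31),
                sample=f"{spec.strain_label}/rep{r + 1}",
            )
        )
    return snaps


def _kinetics_from_summary(onset_min: float, steady: float, act_to_half_min: float) -> KineticParams:
    """Invert the summary metrics: delta = ln2/half-lag, alpha = steady*delta.

    Times are given in minutes (the bulk-fit convention).
    """
    delta = math.log(2.0) / act_to_half_min
    return KineticParams(onset_time=onset_min, production_rate=steady * delta, degradation_rate=delta)


def strain_presets(seed: int = 0) -> list[ScenarioSpec]:
    """Three documented presets spanning the phenotype range.

    - ``wild_type``: onset 204.8 min, steady state 0.9, activation-to-half
      29.5 min; mean single-cell activation 4.2 h at 2.2 counts/h.
    - ``deletion``: onset 214.1 min, steady state 0.7, activation-to-half
      148.3 min; mean activation 6.5 h at 1.3 counts/h.
    - ``unacetylatable``: onset 191.3 min, steady state 0.8,
      activation-to-half 184.2 min; mean activation 5.5 h at 2.1 counts/h.

    Gamma shapes are fixed at 4 (moderate cell-to-cell variability,
    CV = 1/2) with scales set from the target means; background noise is
    Normal(0.1, 0.05^2) counts.
    """
    noise = dict(noise_mean=0.1, noise_var=0.05**2)
    mrna_times_min = tuple(60.0 * t for t in (0, 2, 4, 6, 8, 10, 12, 14))
    presets = [
        ScenarioSpec(
            strain_label="wild_type",
            kinetic_truth=_kinetics_from_summary(204.8, 0.9, 29.5),
            flow_truth=FlowParams(k_t=4.0, theta_t=4.2 / 4.0, k_x=4.0, theta_x=2.2 / 4.0, **noise),
            mrna_times=mrna_times_min,
            mrna_time_unit="minutes",
            seed=seed,
        ),
        ScenarioSpec(
            strain_label="deletion",
            kinetic_truth=_kinetics_from_summary(214.1, 0.7, 148.3),
            flow_truth=FlowParams(k_t=4.0, theta_t=6.5 / 4.0, k_x=4.0, theta_x=1.3 / 4.0, **noise),
            mrna_times=mrna_times_min,
            mrna_time_unit="minutes",
            seed=seed + 1,
        ),
        ScenarioSpec(
            strain_label="unacetylatable",
            kinetic_truth=_kinetics_from_summary(191.3, 0.8, 184.2),
            flow_truth=FlowParams(k_t=4.0, theta_t=5.5 / 4.0, k_x=4.0, theta_x=2.1 / 4.0, **noise),
            mrna_times=mrna_times_min,
            mrna_time_unit="minutes",
            seed=seed + 2,
        ),
    ]
    return presets
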