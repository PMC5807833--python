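"""Study-shaped synthetic datasets for estimator and VPC testing.

No individual-animal concentration data are deposited with the source study,
so this module generates datasets with the same design — ZDF (diabetic) and
control rats, a single 0.8 mmol/kg IV methionine bolus at t=0, plasma
methionine and homocysteine sampled at 0, 10, 30, 60, 120, 210, 300 and
420 min — under any population model, with log-normal inter-individual
variability and combined residual error.  Output uses the same NONMEM-style
CSV dialect the estimator reads (:mod:`metcycle.estimate`).

The source study dosed a mixture of unlabelled and d4-labelled methionine;
here the dose is modelled as a single total-methionine bolus (the isotope
distinction only served the assay).  The t=0 sample is emitted as a pre-dose
record by default (prediction zero, observed value pure additive noise);
set ``t0_predose=False`` to sample just after the bolus instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .estimate import _ANALYTE_CMT, DATASET_COLUMNS
from .model_core import PopulationModel, build_rate_matrix, concentrations, \
    individual_pars, solve_multidose
from .simulate import draw_individual, subject_rng

__all__ = ["StudyDesign", "default_design", "generate_study"]

#: published sampling schedule, minutes post-dose
SAMPLING_TIMES_MIN = (0.0, 10.0, 30.0, 60.0, 120.0, 210.0, 300.0, 420.0)
STUDY_DOSE = 0.8  # mmol/kg, single IV bolus


@dataclass(frozen=True)
class StudyDesign:
    """Single-dose study layout (times entered in minutes, used in hours)."""

    n_per_group: int = 8
    dose: float = STUDY_DOSE
    times_min: tuple[float, ...] = SAMPLING_TIMES_MIN
    analytes: tuple[str, ...] = ("met", "hcy")
    t0_predose: bool = True

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.dose <= 0:
            raise ValueError("dose must be positive")
        t = self.times_min
        if len(set(t)) != len(t) or any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("sampling times must be unique and ascending")
        if t[0] != 0:
            raise ValueError("first sampling time must be 0")
        bad = [a for a in self.analytes if a not in _ANALYTE_CMT]
        if bad:
            raise ValueError(f"unknown analytes {bad}")

    @property
    def times_h(self) -> np.ndarray:
        return np.asarray(self.times_min, dtype=float) / 60.0


def default_design() -> StudyDesign:
    """The source-study design: 0.8 mmol/kg IV, 8 sampling times, both
    analytes (last sample at 420 min = 7.0 h)."""
    return StudyDesign()


def generate_study(design: StudyDesign, pop: PopulationModel, seed: int,
                   groups: Sequence[int] = (0, 1)) -> pd.DataFrame:
    """Generate a complete study table under ``pop``.

    Per subject: draw the random effects, solve the noise-free kinetics at
    the design times, apply the combined error model per analyte record, and
    emit one dose record plus one observation record per time and analyte.
    Subject IDs run 1..n over groups in the given order; each subject's
    random stream is derived deterministically from (seed, group, index).
    """
    times = design.times_h
    rows: list[dict] = []
    sid = 0
    for g in groups:
        if g not in (0, 1):
            raise ValueError("groups must be 0 or 1")
        for i in range(design.n_per_group):
            sid += 1
            rng = subject_rng(seed, g, i)
            fx = draw_individual(pop, g, rng)
            p = individual_pars(pop, fx)
            traj = solve_multidose(build_rate_matrix(p), [(0.0, design.dose)],
                                   times, post_dose=not design.t0_predose)
            series = dict(zip(("met", "hcy"), concentrations(traj, p)))
            obs = {a: _noisy(series[a], pop, rng) for a in design.analytes}
            # record order: pre-dose t=0 samples, the bolus, then the rest
            if design.t0_predose:
                for a in design.analytes:
                    rows.append(_obs_row(sid, g, 0.0, a, obs[a][0]))
            rows.append({"ID": sid, "TIME": 0.0, "AMT": design.dose,
                         "CMT": 2, "EVID": 1, "DV": np.nan, "MDV": 1, "ZDF": g})
            start = 1 if design.t0_predose else 0
            for k in range(start, times.size):
                for a in design.analytes:
                    rows.append(_obs_row(sid, g, float(times[k]), a, obs[a][k]))
    return pd.DataFrame(rows, columns=list(DATASET_COLUMNS))


def _noisy(clean: np.ndarray, pop: PopulationModel,
           rng: np.random.Generator) -> np.ndarray:
    ep = rng.normal(0.0, pop.sigma_prop, clean.shape) if pop.sigma_prop > 0 else 0.0
    ea = rng.normal(0.0, pop.sigma_add, clean.shape) if pop.sigma_add > 0 else 0.0
    return clean * (1.0 + ep) + ea


def _obs_row(sid: int, g: int, t: float, analyte: str, dv: float) -> dict:
    return {"ID": sid, "TIME": t, "AMT": np.nan, "CMT": _ANALYTE_CMT[analyte],
            "EVID": 0, "DV": float(dv), "MDV": 0, "ZDF": g}
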