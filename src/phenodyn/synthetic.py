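"""Synthetic flow-cytometry-style frequency datasets.

The generator emulates the two experimental designs of the study
system: an untreated control sampled at 48, 72 and 96 h post-seeding,
and a repeated-cisplatin design sampled at days 1, 4, 11 and 14 with
two 72 h therapy pulses (starting 24 h post-seeding) separated by a
7-day drug holiday.  Observations are noisy ADRN frequencies: the true
trajectory is simulated, additive Gaussian noise (default sd 0.02) is
applied to the ADRN frequency, the result is clipped to [0.001, 0.999]
and the MES frequency is set to its complement -- mirroring gated
live-cell percentages, which are complementary by construction.
Replicates differ only through noise; everything is reproducible from
the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .calibrate import (
    FrequencyDataset,
    concat_datasets,
    extract_off_therapy,
    growth_rate_from_doubling,
)
from .models import (
    UNTREATED,
    ContractError,
    ModelId,
    ModelParams,
    PhenotypeState,
    TreatmentSchedule,
)
from .simulate import simulate

__all__ = [
    "DesignLabel",
    "SamplingDesign",
    "GeneratorConfig",
    "make_design",
    "generate",
    "reference_scenarios",
    "untreated_calibration_dataset",
    "DEFAULT_NOISE_SD",
    "R_DEFAULT",
]

DEFAULT_NOISE_SD = 0.02

#: intrinsic growth rate from the 27 h SK-N-BE(2) doubling time
R_DEFAULT = growth_rate_from_doubling(27.0)


class DesignLabel(Enum):
    CONTROL = "CONTROL"
    TREATMENT = "TREATMENT"


@dataclass(frozen=True)
class SamplingDesign:
    """Sampling times, therapy schedule and replicate count of one experiment."""

    label: DesignLabel
    times: Tuple[float, ...]
    schedule: TreatmentSchedule
    n_replicates: int = 2

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ContractError("need at least one replicate")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ContractError("design times must be strictly increasing")

    @property
    def condition(self) -> str:
        return "UNTREATED" if not self.schedule.on_intervals else "TREATED"


def make_design(label: DesignLabel | str, n_replicates: int = 2) -> SamplingDesign:
    """Preset sampling designs.

    CONTROL: samples at 48, 72, 96 h, no therapy.
    TREATMENT: samples at 24, 96, 264, 336 h (days 1, 4, 11, 14);
    therapy on during [24, 96) and [264, 336) -- two 72 h pulses
    separated by a 168 h holiday.
    """
    if isinstance(label, str):
        try:
            label = DesignLabel(label.upper())
        except ValueError:
            raise ContractError(f"unknown design label {label!r}") from None
    if label is DesignLabel.CONTROL:
        return SamplingDesign(
            label=label,
            times=(48.0, 72.0, 96.0),
            schedule=UNTREATED,
            n_replicates=n_replicates,
        )
    if label is DesignLabel.TREATMENT:
        return SamplingDesign(
            label=label,
            times=(24.0, 96.0, 264.0, 336.0),
            schedule=TreatmentSchedule(((24.0, 96.0), (264.0, 336.0))),
            n_replicates=n_replicates,
        )
    raise ContractError(f"unknown design label {label!r}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything needed to draw one synthetic dataset."""

    model: ModelId
    params: ModelParams
    design: SamplingDesign
    x0: PhenotypeState
    noise_sd: float
    seed: int

    def __post_init__(self):
        if not 0.0 <= self.noise_sd < 0.2:
            raise ContractError(
                f"noise_sd={self.noise_sd} outside [0, 0.2): frequencies "
                "would no longer be informative"
            )
        if self.seed is None:
            raise ContractError("a seed is mandatory")


def generate(config: GeneratorConfig) -> FrequencyDataset:
    """Simulate the configured model and add per-observation noise.

    The trajectory starts at the design's first sampling time from
    ``config.x0``; for each replicate and time an independent Gaussian
    perturbation (sd ``noise_sd``) is added to the true ADRN frequency,
    clipped to [0.001, 0.999], and the MES frequency is set to the
    complement.
    """
    design = config.design
    times = list(design.times)
    traj = simulate(
        config.model,
        config.params,
        design.schedule,
        config.x0,
        times[0],
        times,
    )
    truth = traj.adrn
    rng = np.random.default_rng(config.seed)
    rows = []
    for rep in range(1, design.n_replicates + 1):
        eps = rng.normal(0.0, config.noise_sd, size=len(times)) if config.noise_sd else 0.0
        xa = np.clip(truth + eps, 0.001, 0.999)
        for t, a in zip(times, xa):
            rows.append(
                {
                    "time_h": t,
                    "replicate": f"r{rep}",
                    "freq_adrn": float(a),
                    "freq_mes": float(1.0 - a),
                }
            )
    return FrequencyDataset(
        pd.DataFrame(rows), condition=design.condition, schedule=design.schedule
    )


def reference_scenarios(
    seed: int = 0, noise_sd: float = DEFAULT_NOISE_SD
) -> Dict[str, GeneratorConfig]:
    """Ready-made generator configs at the study's fitted parameter regime.

    Scenarios (all rates per hour; see the methods note for the unit
    convention):

    * ``untreated-baseline`` -- control design, r = ln(2)/27,
      alpha = 0.484, beta = 1.00.
    * ``untreated-with-transitions`` -- as above plus the negligible
      background transition rates tau1 = 7.36e-14, tau2 = 1.64e-5.
    * ``treated-cell-type`` -- treatment design, gamma = 0.01.
    * ``treated-cell-state`` -- as above plus zeta = 3.15e-4.

    The initial frequencies -- (0.85, 0.15) for the control design and
    (0.70, 0.30) at treatment start -- are generator choices consistent
    with an ADRN-dominated baseline population, not measured data.
    """
    base = dict(r=R_DEFAULT, alpha=0.484, beta=1.00)
    control = make_design(DesignLabel.CONTROL)
    treatment = make_design(DesignLabel.TREATMENT)
    x0_control = PhenotypeState(0.85, 0.15)
    x0_treat = PhenotypeState(0.70, 0.30)
    return {
        "untreated-baseline": GeneratorConfig(
            model=ModelId.BASELINE,
            params=ModelParams(**base),
            design=control,
            x0=x0_control,
            noise_sd=noise_sd,
            seed=seed,
        ),
        "untreated-with-transitions": GeneratorConfig(
            model=ModelId.BASELINE_TRANSITIONS,
            params=ModelParams(**base, tau1=7.36e-14, tau2=1.64e-5),
            design=control,
            x0=x0_control,
            noise_sd=noise_sd,
            seed=seed,
        ),
        "treated-cell-type": GeneratorConfig(
            model=ModelId.CELLTYPE_THERAPY,
            params=ModelParams(**base, gamma=0.01),
            design=treatment,
            x0=x0_treat,
            noise_sd=noise_sd,
            seed=seed,
        ),
        "treated-cell-state": GeneratorConfig(
            model=ModelId.CELLSTATE_THERAPY,
            params=ModelParams(**base, gamma=0.01, zeta=3.15e-4),
            design=treatment,
            x0=x0_treat,
            noise_sd=noise_sd,
            seed=seed,
        ),
    }


def untreated_calibration_dataset(
    seed: int, noise_sd: float = DEFAULT_NOISE_SD
) -> FrequencyDataset:
    """Pooled untreated calibration data: control + off-therapy segments.

    Mirrors the calibration protocol for the baseline models: the
    untreated control series is pooled with the drug-holiday segment
    (96 -> 264 h) extracted from a treated-cell-type dataset generated
    at the same untreated parameters.  Both sub-datasets share the
    untreated replicator dynamics on every fitted interval, so the
    result is an UNTREATED dataset with an empty schedule.
    """
    children = np.random.SeedSequence(seed).generate_state(2) & 0x7FFFFFFF
    scen = reference_scenarios(noise_sd=noise_sd)
    control = generate(replace(scen["untreated-baseline"], seed=int(children[0])))
    treated = generate(replace(scen["treated-cell-type"], seed=int(children[1])))
    holiday = extract_off_therapy(treated)
    # disambiguate replicate labels before pooling
    ctrl_frame = control.frame.copy()
    ctrl_frame["replicate"] = "ctrl/" + ctrl_frame["replicate"]
    hol_frame = holiday.frame.copy()
    hol_frame["replicate"] = "hol/" + hol_frame["replicate"]
    control = FrequencyDataset(ctrl_frame, condition="UNTREATED", schedule=UNTREATED)
    holiday = FrequencyDataset(hol_frame, condition="UNTREATED", schedule=UNTREATED)
    return concat_datasets((control, holiday), condition="UNTREATED")
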