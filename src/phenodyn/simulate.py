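"""Numerical integration of the replicator models with on/off therapy.

Trajectories are integrated piecewise between treatment switch points
(no adaptive step ever straddles an on/off boundary), with LSODA at
rtol 1e-8 / atol 1e-10.  Frequencies are never renormalized: drift off
the simplex beyond 1e-6 is reported as an error, not silently fixed.
"""

from __future__ import annotations

from bisect import insort
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .models import (
    SIMPLEX_STATE_ATOL,
    UNTREATED,
    ContractError,
    ModelId,
    ModelParams,
    PhenotypeState,
    TreatmentSchedule,
    growth_field,
    rhs,
)

__all__ = [
    "IntegrationError",
    "ConvergenceError",
    "Trajectory",
    "simulate",
    "equilibrium_frequency",
]

_RTOL = 1e-8
_ATOL = 1e-10


class IntegrationError(RuntimeError):
    """The ODE integrator failed or the trajectory left the simplex."""

    def __init__(self, message: str, t: float | None = None):
        super().__init__(message)
        self.t = t


class ConvergenceError(RuntimeError):
    """A long-run simulation did not reach a near-stationary state."""


@dataclass(frozen=True)
class Trajectory:
    """A simulated frequency trajectory evaluated at sampling times."""

    times: Tuple[float, ...]
    states: Tuple[PhenotypeState, ...]
    model: ModelId
    params: ModelParams
    schedule: TreatmentSchedule

    def __post_init__(self):
        if len(self.times) != len(self.states):
            raise ContractError("times and states must align")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ContractError("trajectory times must be strictly increasing")

    @property
    def adrn(self) -> np.ndarray:
        return np.array([s.xA for s in self.states])

    @property
    def mes(self) -> np.ndarray:
        return np.array([s.xM for s in self.states])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_h": self.times, "freq_adrn": self.adrn, "freq_mes": self.mes}
        )


def simulate(
    model: ModelId,
    params: ModelParams,
    schedule: TreatmentSchedule,
    x0: PhenotypeState,
    t0: float,
    eval_times: Sequence[float],
) -> Trajectory:
    """Integrate *model* from (t0, x0) and evaluate at *eval_times*.

    eval_times must be >= t0 and strictly increasing.  Every schedule
    boundary inside the horizon becomes a forced mesh point, so the
    piecewise-constant therapy forcing is exact.  Deterministic for
    fixed inputs.
    """
    eval_times = [float(t) for t in eval_times]
    if not eval_times:
        raise ContractError("eval_times must be non-empty")
    if eval_times[0] < t0:
        raise ContractError("eval_times must be >= t0")
    if any(b <= a for a, b in zip(eval_times, eval_times[1:])):
        raise ContractError("eval_times must be strictly increasing")
    params.validate_for(model)

    t_end = eval_times[-1]
    # piecewise mesh: t0, every switch point in (t0, t_end), t_end
    mesh = [t0]
    for b in schedule.boundaries():
        if t0 < b < t_end:
            insort(mesh, b)
    if t_end > t0:
        mesh.append(t_end)

    wanted = list(eval_times)
    out_t: list[float] = []
    out_y: list[Tuple[float, float]] = []
    if wanted and wanted[0] == t0:
        out_t.append(t0)
        out_y.append((x0.xA, x0.xM))
        wanted = wanted[1:]

    y = (x0.xA, x0.xM)
    for ta, tb in zip(mesh, mesh[1:]):
        therapy_on = schedule.is_on(0.5 * (ta + tb))
        field = growth_field(model, params, therapy_on)
        seg_eval = [t for t in wanted if ta < t <= tb]
        t_eval = sorted(set(seg_eval + [tb]))
        sol = solve_ivp(
            field,
            (ta, tb),
            y,
            method="LSODA",
            rtol=_RTOL,
            atol=_ATOL,
            t_eval=t_eval,
            dense_output=False,
        )
        if not sol.success:
            raise IntegrationError(
                f"integrator failed in [{ta}, {tb}]: {sol.message}", t=tb
            )
        for i, t in enumerate(sol.t):
            if t in seg_eval:
                out_t.append(t)
                out_y.append((sol.y[0][i], sol.y[1][i]))
        y = (sol.y[0][-1], sol.y[1][-1])
        wanted = [t for t in wanted if t > tb]

    states = []
    for t, (xA, xM) in zip(out_t, out_y):
        if abs(xA + xM - 1.0) > SIMPLEX_STATE_ATOL:
            raise IntegrationError(
                f"trajectory drifted off the simplex at t={t}: "
                f"xA+xM={xA + xM}",
                t=t,
            )
        states.append(PhenotypeState(xA, xM, _atol=SIMPLEX_STATE_ATOL))
    return Trajectory(tuple(out_t), tuple(states), model, params, schedule)


def equilibrium_frequency(
    model: ModelId,
    params: ModelParams,
    x0: PhenotypeState,
    horizon: float,
    schedule: TreatmentSchedule = UNTREATED,
    deriv_tol: float = 1e-10,
) -> PhenotypeState:
    """Long-run state after *horizon* hours; errors if not stationary.

    The end state must satisfy max(|dxA/dt|, |dxM/dt|) < *deriv_tol*,
    otherwise a ConvergenceError is raised (pick a longer horizon).
    """
    traj = simulate(model, params, schedule, x0, 0.0, [horizon])
    end = traj.states[-1]
    dxA, dxM = rhs(model, horizon, end, params, schedule)
    if max(abs(dxA), abs(dxM)) >= deriv_tol:
        raise ConvergenceError(
            f"state not stationary after {horizon} h: |dx/dt|="
            f"{max(abs(dxA), abs(dxM)):.3e} >= {deriv_tol}"
        )
    return end
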