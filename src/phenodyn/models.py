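"""Replicator-dynamics vector fields for ADRN/MES phenotype frequencies.

Two neuroblastoma phenotypes compete in frequency space: the
therapy-sensitive adrenergic (ADRN) phenotype and the therapy-resistant
mesenchymal (MES) phenotype.  Four nested models share the replicator
structure dx_i/dt = x_i [f_i(x) - phi(x)] with logistic-style fitnesses

    f_A = r (1 - x_A - alpha * x_M)        (ADRN)
    f_M = r (1 - beta * x_A - x_M)         (MES)

and differ in the extra terms they carry:

* ``BASELINE`` -- pure frequency-dependent competition, no switching.
* ``BASELINE_TRANSITIONS`` -- adds background ADRN<->MES transition
  terms (-tau1*xA + tau2*xM inside the ADRN bracket, opposite sign for
  MES).
* ``CELLTYPE_THERAPY`` -- adds a therapy-induced per-capita death rate
  gamma(t) to ADRN cells while therapy is on (cell *type* hypothesis:
  no inter-conversion, differential survival only).
* ``CELLSTATE_THERAPY`` -- additionally lets ADRN cells switch to the
  MES state at rate zeta(t) while therapy is on (cell *state*
  hypothesis); the switched mass appears as an influx +zeta(t)*xA in
  the MES equation.

The mean fitness phi is defined so that the two-phenotype simplex
(xA + xM = 1) is exactly conserved by every model: phi includes the
therapy death term and the background transition terms, but for
``CELLSTATE_THERAPY`` it *excludes* the -zeta part of the ADRN bracket,
so the -zeta*xA outflux and the +zeta*xA influx cancel in the sum of
derivatives.  The observable is a frequency pair summing to one; any
non-conserving convention would contradict the data.

All rates are per hour internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Callable, Iterable, Tuple

__all__ = [
    "SimplexError",
    "ContractError",
    "ModelId",
    "PhenotypeState",
    "ModelParams",
    "TreatmentSchedule",
    "UNTREATED",
    "per_capita_growth",
    "mean_fitness",
    "rhs",
    "growth_field",
]

#: tolerance for the simplex constraint at explicit construction
SIMPLEX_CONSTRUCT_ATOL = 1e-9
#: tolerance for states produced by numerical integration
SIMPLEX_STATE_ATOL = 1e-6


class SimplexError(ValueError):
    """A frequency pair violates the simplex constraint xA + xM = 1."""


class ContractError(ValueError):
    """An argument violates an interface contract (unknown model, bad rates...)."""


class ModelId(Enum):
    """The four replicator models, each mapping to exactly one vector field."""

    BASELINE = "baseline"
    BASELINE_TRANSITIONS = "baseline_transitions"
    CELLTYPE_THERAPY = "celltype_therapy"
    CELLSTATE_THERAPY = "cellstate_therapy"


#: parameter names each model is allowed to use (others must be zero)
_USED_PARAMS = {
    ModelId.BASELINE: frozenset({"r", "alpha", "beta"}),
    ModelId.BASELINE_TRANSITIONS: frozenset({"r", "alpha", "beta", "tau1", "tau2"}),
    ModelId.CELLTYPE_THERAPY: frozenset({"r", "alpha", "beta", "gamma"}),
    ModelId.CELLSTATE_THERAPY: frozenset({"r", "alpha", "beta", "gamma", "zeta"}),
}

PARAM_NAMES = ("r", "alpha", "beta", "tau1", "tau2", "gamma", "zeta")


class PhenotypeState:
    """A point on the 1-simplex: (ADRN frequency, MES frequency).

    Both components must be non-negative and sum to one within
    ``SIMPLEX_CONSTRUCT_ATOL``.  Instances are immutable.
    """

    __slots__ = ("xA", "xM")

    def __init__(self, xA: float, xM: float, *, _atol: float = SIMPLEX_CONSTRUCT_ATOL):
        xA = float(xA)
        xM = float(xM)
        if not (math.isfinite(xA) and math.isfinite(xM)):
            raise SimplexError(f"non-finite frequencies ({xA}, {xM})")
        if xA < -_atol or xM < -_atol:
            raise SimplexError(f"negative frequency in ({xA}, {xM})")
        # roundoff-scale negatives (e.g. -1e-19 at a fixation boundary) are zero
        xA = max(xA, 0.0)
        xM = max(xM, 0.0)
        if abs(xA + xM - 1.0) > _atol:
            raise SimplexError(
                f"frequencies ({xA}, {xM}) sum to {xA + xM}, not 1 within {_atol}"
            )
        object.__setattr__(self, "xA", xA)
        object.__setattr__(self, "xM", xM)

    @classmethod
    def from_adrn(cls, xA: float) -> "PhenotypeState":
        """Build a state from the ADRN frequency alone (MES = 1 - ADRN)."""
        return cls(float(xA), 1.0 - float(xA))

    def __setattr__(self, name, value):  # immutability
        raise AttributeError("PhenotypeState is immutable")

    def __iter__(self):
        yield self.xA
        yield self.xM

    def __eq__(self, other):
        return (
            isinstance(other, PhenotypeState)
            and self.xA == other.xA
            and self.xM == other.xM
        )

    def __hash__(self):
        return hash((self.xA, self.xM))

    def __repr__(self):
        return f"PhenotypeState(xA={self.xA!r}, xM={self.xM!r})"


@dataclass(frozen=True)
class ModelParams:
    """All rate parameters of the four models, per hour.

    Parameters
    ----------
    r : float
        Intrinsic growth rate (>0), typically ln(2)/doubling-time.
    alpha : float
        Frequency effect of MES on ADRN fitness (dimensionless, >=0).
    beta : float
        Frequency effect of ADRN on MES fitness (dimensionless, >=0).
    tau1, tau2 : float
        Background ADRN->MES and MES->ADRN transition rates (>=0);
        only ``BASELINE_TRANSITIONS`` may use them.
    gamma : float
        Therapy-induced ADRN death rate while therapy is on (>=0).
    zeta : float
        Therapy-induced ADRN->MES switching rate while therapy is on
        (>=0); only ``CELLSTATE_THERAPY`` may use it.
    """

    r: float
    alpha: float = 0.0
    beta: float = 0.0
    tau1: float = 0.0
    tau2: float = 0.0
    gamma: float = 0.0
    zeta: float = 0.0

    def __post_init__(self):
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ContractError(f"parameter {name}={v} is not finite")
            if v < 0.0:
                raise ContractError(f"parameter {name}={v} is negative")
        if self.r <= 0.0:
            raise ContractError(f"growth rate r={self.r} must be positive")

    def validate_for(self, model: ModelId) -> None:
        """Raise ContractError if a rate unused by *model* is non-zero."""
        used = _USED_PARAMS.get(model)
        if used is None:
            raise ContractError(f"unknown model id: {model!r}")
        for name in PARAM_NAMES:
            if name not in used and getattr(self, name) != 0.0:
                raise ContractError(
                    f"parameter {name}={getattr(self, name)} must be zero "
                    f"for model {model.value}"
                )

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in PARAM_NAMES}


@dataclass(frozen=True)
class TreatmentSchedule:
    """Piecewise-constant therapy forcing: ordered half-open on-intervals.

    Each interval is ``[start, end)`` in hours post-seeding: at
    ``t == end`` therapy is already off.  An empty sequence denotes the
    untreated condition.
    """

    on_intervals: Tuple[Tuple[float, float], ...] = ()

    def __post_init__(self):
        ivs = tuple((float(a), float(b)) for a, b in self.on_intervals)
        object.__setattr__(self, "on_intervals", ivs)
        prev_end = -math.inf
        for start, end in ivs:
            if not (math.isfinite(start) and math.isfinite(end)):
                raise ContractError("schedule interval bounds must be finite")
            if end <= start:
                raise ContractError(f"interval ({start}, {end}) has end <= start")
            if start < prev_end:
                raise ContractError("schedule intervals overlap or are unordered")
            prev_end = end

    def is_on(self, t: float) -> bool:
        """True iff therapy is on at time *t* (half-open interval convention)."""
        return any(start <= t < end for start, end in self.on_intervals)

    def boundaries(self) -> Tuple[float, ...]:
        """All on/off switch times, sorted ascending."""
        pts = sorted({b for iv in self.on_intervals for b in iv})
        return tuple(pts)

    @property
    def total_on_time(self) -> float:
        return sum(end - start for start, end in self.on_intervals)


#: the untreated condition (no therapy intervals)
UNTREATED = TreatmentSchedule(())


def _growth_terms(
    model: ModelId, xA: float, xM: float, p: ModelParams, therapy_on: bool
) -> Tuple[float, float]:
    """Per-capita bracket terms (gA, gM), excluding phi; no validation."""
    gA = p.r * (1.0 - xA - p.alpha * xM)
    gM = p.r * (1.0 - p.beta * xA - xM)
    if model is ModelId.BASELINE_TRANSITIONS:
        flux = -p.tau1 * xA + p.tau2 * xM
        gA += flux
        gM -= flux
    elif model is ModelId.CELLTYPE_THERAPY:
        if therapy_on:
            gA -= p.gamma
    elif model is ModelId.CELLSTATE_THERAPY:
        if therapy_on:
            gA -= p.gamma + p.zeta
    elif model is not ModelId.BASELINE:
        raise ContractError(f"unknown model id: {model!r}")
    return gA, gM


def per_capita_growth(
    model: ModelId,
    state: PhenotypeState,
    params: ModelParams,
    therapy_on: bool = False,
) -> Tuple[float, float]:
    """Per-capita growth terms (gA, gM) of each phenotype, excluding phi.

    Returns the full bracketed term of each replicator equation: the
    logistic fitness, plus the background transition terms for
    ``BASELINE_TRANSITIONS``, minus gamma (and zeta, for
    ``CELLSTATE_THERAPY``) while therapy is on.  The +zeta*xA influx to
    MES is *not* part of the per-capita term; :func:`rhs` adds it.
    """
    if not isinstance(state, PhenotypeState):
        raise SimplexError("state must be a PhenotypeState on the simplex")
    if not isinstance(model, ModelId):
        raise ContractError(f"unknown model id: {model!r}")
    params.validate_for(model)
    return _growth_terms(model, state.xA, state.xM, params, therapy_on)


def mean_fitness(
    state: PhenotypeState, gA: float, gM: float, zeta_correction: float = 0.0
) -> float:
    """Population-mean fitness phi(x) = xA * gA' + xM * gM.

    ``zeta_correction`` adds the switching rate back to the ADRN term
    (gA' = gA + zeta_correction) for the cell-state model under
    therapy, so that phi weighs the ADRN fitness *without* the -zeta
    outflux and the switching flux cancels exactly in the simplex sum.
    For every other model pass the default 0.
    """
    if not isinstance(state, PhenotypeState):
        raise SimplexError("state must be a PhenotypeState on the simplex")
    return state.xA * (gA + zeta_correction) + state.xM * gM


def rhs(
    model: ModelId,
    t: float,
    state: PhenotypeState,
    params: ModelParams,
    schedule: TreatmentSchedule = UNTREATED,
) -> Tuple[float, float]:
    """Time derivatives (dxA/dt, dxM/dt) at time *t* under *schedule*.

    The two derivatives sum to zero (simplex conservation) for every
    model, state and parameter set.
    """
    therapy_on = schedule.is_on(t)
    gA, gM = per_capita_growth(model, state, params, therapy_on)
    zc = (
        params.zeta
        if (model is ModelId.CELLSTATE_THERAPY and therapy_on)
        else 0.0
    )
    phi = mean_fitness(state, gA, gM, zc)
    dxA = state.xA * (gA - phi)
    dxM = state.xM * (gM - phi) + zc * state.xA
    return dxA, dxM


def growth_field(
    model: ModelId, params: ModelParams, therapy_on: bool
) -> Callable[[float, Iterable[float]], Tuple[float, float]]:
    """Unvalidated vector field f(t, y) for the integrator.

    Therapy on/off is frozen (the simulator integrates piecewise
    between schedule boundaries), and the state is taken as raw floats
    so intermediate integrator evaluations slightly off the simplex do
    not raise.
    """
    params.validate_for(model)
    zc = params.zeta if (model is ModelId.CELLSTATE_THERAPY and therapy_on) else 0.0

    def field(t: float, y) -> Tuple[float, float]:
        xA, xM = y[0], y[1]
        gA, gM = _growth_terms(model, xA, xM, params, therapy_on)
        phi = xA * (gA + zc) + xM * gM
        return (xA * (gA - phi), xM * (gM - phi) + zc * xA)

    return field
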