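"""Bounded Levenberg-Marquardt calibration of the replicator models.

Each replicate series is simulated from its own first observation
(initial conditions are data, not free parameters); residuals are the
differences (predicted - observed) of BOTH phenotype frequencies at
every subsequent observation time, concatenated across replicates in
deterministic (replicate, time, phenotype) order.  Minimization uses
MINPACK's Levenberg-Marquardt through lmfit, which honors box bounds
via a smooth parameter transformation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, Mapping, Optional, Tuple

import lmfit
import numpy as np
import pandas as pd

from .models import (
    UNTREATED,
    ContractError,
    ModelId,
    ModelParams,
    PhenotypeState,
    TreatmentSchedule,
    PARAM_NAMES,
)
from .simulate import simulate

__all__ = [
    "FrequencyDataset",
    "FitSpec",
    "FitResult",
    "growth_rate_from_doubling",
    "residual_vector",
    "fit",
    "extract_off_therapy",
    "concat_datasets",
    "DEFAULT_START",
    "DEFAULT_BOUNDS",
]

REQUIRED_COLUMNS = ("time_h", "replicate", "freq_adrn", "freq_mes")

#: default starting values for free parameters
DEFAULT_START: Dict[str, float] = {
    "alpha": 0.5,
    "beta": 1.0,
    "tau1": 0.0,
    "tau2": 0.0,
    "gamma": 0.005,
    "zeta": 0.0,
}

#: default box bounds: interaction coefficients capped at 1, rates non-negative
DEFAULT_BOUNDS: Dict[str, Tuple[float, float]] = {
    "alpha": (0.0, 1.0),
    "beta": (0.0, 1.0),
    "tau1": (0.0, math.inf),
    "tau2": (0.0, math.inf),
    "gamma": (0.0, math.inf),
    "zeta": (0.0, math.inf),
}


def growth_rate_from_doubling(doubling_time: float) -> float:
    """Intrinsic growth rate r = ln(2) / doubling_time (per hour).

    The SK-N-BE(2) doubling time of 27 h gives r ~= 0.026/hour.
    """
    if not doubling_time > 0:
        raise ValueError(f"doubling time must be positive, got {doubling_time}")
    return math.log(2.0) / float(doubling_time)


@dataclass
class FrequencyDataset:
    """Replicate-labelled phenotype frequencies at sampling times.

    Parameters
    ----------
    frame : pandas.DataFrame
        Columns ``time_h`` (hours post-seeding), ``replicate``
        (identifier), ``freq_adrn``, ``freq_mes``.
    condition : str
        ``"UNTREATED"`` or ``"TREATED"``.
    schedule : TreatmentSchedule
        Therapy forcing; must be empty for the untreated condition.
    """

    frame: pd.DataFrame
    condition: str = "UNTREATED"
    schedule: TreatmentSchedule = field(default_factory=TreatmentSchedule)

    def __post_init__(self):
        if self.condition not in ("UNTREATED", "TREATED"):
            raise ContractError(f"unknown condition {self.condition!r}")
        missing = [c for c in REQUIRED_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ContractError(f"dataset missing columns: {missing}")
        df = self.frame.copy()
        df["time_h"] = df["time_h"].astype(float)
        df["replicate"] = df["replicate"].astype(str)
        bad = df.index[
            (df["freq_adrn"] + df["freq_mes"] - 1.0).abs() > 1e-6
        ].tolist()
        if bad:
            raise ContractError(
                f"rows {bad} violate freq_adrn + freq_mes = 1 (tol 1e-6)"
            )
        if ((df["freq_adrn"] < 0) | (df["freq_mes"] < 0)).any():
            raise ContractError("negative frequencies in dataset")
        for rep, grp in df.groupby("replicate"):
            if grp["time_h"].nunique() < 2:
                raise ContractError(
                    f"replicate {rep!r} has fewer than 2 distinct times"
                )
        df = df.sort_values(["replicate", "time_h"], kind="mergesort")
        self.frame = df.reset_index(drop=True)
        # per-replicate (times, xA, xM) arrays; the frame is treated as
        # immutable after construction, so cache for the fitting loop
        self._series_arrays = {
            rep: (
                grp["time_h"].to_numpy(dtype=float),
                grp["freq_adrn"].to_numpy(dtype=float),
                grp["freq_mes"].to_numpy(dtype=float),
            )
            for rep, grp in self.frame.groupby("replicate", sort=True)
        }

    @property
    def replicates(self) -> Tuple[str, ...]:
        return tuple(sorted(self._series_arrays))

    @property
    def n_records(self) -> int:
        return len(self.frame)

    def replicate_series(self, rep: str) -> pd.DataFrame:
        grp = self.frame[self.frame["replicate"] == rep]
        return grp.sort_values("time_h")


def concat_datasets(
    datasets: Tuple[FrequencyDataset, ...],
    condition: str = "UNTREATED",
    schedule: TreatmentSchedule = UNTREATED,
) -> FrequencyDataset:
    """Pool datasets; replicate labels must already be distinct across inputs."""
    frames = [d.frame for d in datasets]
    labels = [lab for d in datasets for lab in d.replicates]
    if len(set(labels)) != len(labels):
        raise ContractError("replicate labels collide across pooled datasets")
    return FrequencyDataset(
        pd.concat(frames, ignore_index=True), condition=condition, schedule=schedule
    )


def extract_off_therapy(data: FrequencyDataset) -> FrequencyDataset:
    """Observation runs whose between-sample intervals carry no therapy.

    For each replicate, maximal runs of consecutive sampling times are
    kept when every inter-observation interval [t_i, t_{i+1}) is
    disjoint from all therapy on-intervals (schedule lookup).  Runs
    with at least two observations become new replicate series labelled
    ``"<rep>/off<k>"``; the result is an untreated dataset with an
    empty schedule, suitable for fitting the baseline models.
    """
    ivs = data.schedule.on_intervals
    rows = []
    for rep in data.replicates:
        series = data.replicate_series(rep)
        times = series["time_h"].tolist()
        run: list[int] = [0]
        runs: list[list[int]] = []
        for i in range(len(times) - 1):
            a, b = times[i], times[i + 1]
            off = all(not (a < end and start < b) for start, end in ivs)
            if off:
                run.append(i + 1)
            else:
                runs.append(run)
                run = [i + 1]
        runs.append(run)
        for k, idx in enumerate(r for r in runs if len(r) >= 2):
            sub = series.iloc[idx].copy()
            sub["replicate"] = f"{rep}/off{k}"
            rows.append(sub)
    if not rows:
        raise ContractError("no off-therapy segment with >= 2 observations")
    frame = pd.concat(rows, ignore_index=True)
    return FrequencyDataset(frame, condition="UNTREATED", schedule=UNTREATED)


@dataclass(frozen=True)
class FitSpec:
    """What to fit: model, free/fixed parameters, bounds and starts.

    ``residual_mode`` is ``"both"`` (default: residuals on both
    phenotype frequencies, as both fitted curves are reported) or
    ``"adrn"`` (ADRN-only; the two frequencies are complementary, so
    this halves n without changing the optimum on clean data).
    ``n_restarts`` > 0 enables multi-start with jittered initial
    values for noisy data.
    """

    model: ModelId
    free: Tuple[str, ...]
    fixed: Mapping[str, float]
    bounds: Mapping[str, Tuple[float, float]] = field(default_factory=dict)
    start: Mapping[str, float] = field(default_factory=dict)
    residual_mode: str = "both"
    n_restarts: int = 0

    def __post_init__(self):
        object.__setattr__(self, "free", tuple(self.free))
        object.__setattr__(self, "fixed", dict(self.fixed))
        object.__setattr__(self, "bounds", dict(self.bounds))
        object.__setattr__(self, "start", dict(self.start))
        overlap = set(self.free) & set(self.fixed)
        if overlap:
            raise ContractError(f"parameters both free and fixed: {sorted(overlap)}")
        unknown = (set(self.free) | set(self.fixed)) - set(PARAM_NAMES)
        if unknown:
            raise ContractError(f"unknown parameter names: {sorted(unknown)}")
        if self.residual_mode not in ("both", "adrn"):
            raise ContractError(f"unknown residual_mode {self.residual_mode!r}")
        for name in self.free:
            lo, hi = self.bound_for(name)
            s = self.start_for(name)
            if not lo <= s <= hi:
                raise ContractError(
                    f"start {name}={s} outside bounds [{lo}, {hi}]"
                )

    def bound_for(self, name: str) -> Tuple[float, float]:
        return tuple(self.bounds.get(name, DEFAULT_BOUNDS.get(name, (0.0, math.inf))))

    def start_for(self, name: str) -> float:
        return float(self.start.get(name, DEFAULT_START.get(name, 0.0)))

    def build_params(self, free_values: Mapping[str, float]) -> ModelParams:
        values = {name: 0.0 for name in PARAM_NAMES}
        values.update(self.fixed)
        values.update({k: free_values[k] for k in self.free})
        return ModelParams(**values)


@dataclass(frozen=True)
class FitResult:
    """Estimates and goodness-of-fit of one least-squares calibration."""

    model: ModelId
    estimates: Dict[str, float]
    rss: float
    n_obs: int
    k: int
    r2: float
    aic: float
    converged: bool
    n_iter: int

    def to_dict(self) -> dict:
        return {
            "model": self.model.value,
            "estimates": dict(self.estimates),
            "rss": self.rss,
            "n_obs": self.n_obs,
            "k": self.k,
            "r2": self.r2,
            "aic": self.aic,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        return cls(
            model=ModelId(d["model"]),
            estimates=dict(d["estimates"]),
            rss=float(d["rss"]),
            n_obs=int(d["n_obs"]),
            k=int(d["k"]),
            r2=float(d["r2"]),
            aic=float(d["aic"]),
            converged=bool(d["converged"]),
            n_iter=int(d["n_iter"]),
        )


def _predicted_and_observed(
    model: ModelId,
    params: ModelParams,
    data: FrequencyDataset,
    mode: str = "both",
) -> Tuple[np.ndarray, np.ndarray]:
    """Model predictions and observations at all post-initial times.

    Deterministic (replicate, time, phenotype) ordering; each replicate
    series is simulated from its own first observation.
    """
    preds: list[float] = []
    obs: list[float] = []
    for rep in data.replicates:
        times, xa, xm = data._series_arrays[rep]
        x0 = PhenotypeState(xa[0], xm[0], _atol=1e-6)
        traj = simulate(model, params, data.schedule, x0, times[0], list(times[1:]))
        for j, state in enumerate(traj.states):
            preds.append(state.xA)
            obs.append(xa[j + 1])
            if mode == "both":
                preds.append(state.xM)
                obs.append(xm[j + 1])
    return np.asarray(preds), np.asarray(obs)


def residual_vector(
    model: ModelId,
    params: ModelParams,
    data: FrequencyDataset,
    mode: str = "both",
) -> np.ndarray:
    """Concatenated (predicted - observed) frequency residuals."""
    preds, obs = _predicted_and_observed(model, params, data, mode)
    return preds - obs


def _finish(
    spec: FitSpec,
    data: FrequencyDataset,
    estimates: Dict[str, float],
    rss: float,
    n_obs: int,
    k: int,
    converged: bool,
    n_iter: int,
) -> FitResult:
    from .selection import aic as aic_fn, r_squared  # local to avoid cycle

    params = spec.build_params(estimates)
    preds, obs = _predicted_and_observed(spec.model, params, data, spec.residual_mode)
    if rss == 0.0:
        r2, aic_value = 1.0, -math.inf
    else:
        r2 = r_squared(obs, preds)
        aic_value = aic_fn(rss, n_obs, k)
    return FitResult(
        model=spec.model,
        estimates={name: float(params.as_dict()[name]) for name in PARAM_NAMES},
        rss=float(rss),
        n_obs=int(n_obs),
        k=int(k),
        r2=float(r2),
        aic=float(aic_value),
        converged=bool(converged),
        n_iter=int(n_iter),
    )


def _jittered_starts(spec: FitSpec, rng: np.random.Generator) -> Dict[str, float]:
    start = {}
    for name in spec.free:
        lo, hi = spec.bound_for(name)
        s = spec.start_for(name)
        width = (hi - lo) if math.isfinite(hi - lo) else max(1.0, abs(s))
        start[name] = float(np.clip(s + rng.normal(0.0, 0.2 * width), lo, hi))
    return start


def _interior_start(value: float, lo: float, hi: float) -> float:
    """Nudge a start value strictly inside its bounds.

    MINPACK's bounded-LM parameter transformation has zero gradient
    exactly at a bound, which freezes any parameter started there;
    a 1e-6-scale nudge restores a usable Jacobian without measurably
    moving the start.
    """
    span = hi - lo
    eps = 1e-6 * (span if math.isfinite(span) else 1.0)
    upper = hi - eps if math.isfinite(hi) else hi
    return min(max(value, lo + eps), upper)


def _single_fit(spec: FitSpec, data: FrequencyDataset) -> FitResult:
    pars = lmfit.Parameters()
    for name in spec.free:
        lo, hi = spec.bound_for(name)
        start = _interior_start(spec.start_for(name), lo, hi)
        pars.add(name, value=start, min=lo, max=hi, vary=True)

    def objective(p: lmfit.Parameters) -> np.ndarray:
        values = {name: p[name].value for name in spec.free}
        params = spec.build_params(values)
        return residual_vector(spec.model, params, data, spec.residual_mode)

    # reference RSS at the literal (un-nudged) starting values
    literal_start = {name: spec.start_for(name) for name in spec.free}
    start_res = residual_vector(
        spec.model, spec.build_params(literal_start), data, spec.residual_mode
    )
    start_rss = float(np.sum(start_res**2))
    minner = lmfit.Minimizer(objective, pars)
    # epsfcn keeps finite-difference steps (~sqrt(epsfcn)) well above the
    # ODE integrator's 1e-8 relative noise floor; the MINPACK default
    # would differentiate integrator noise and stall at the start point
    # cap at 500 LM iterations; each iteration costs about k+1 evaluations
    out = minner.minimize(
        method="leastsq", xtol=1e-10, ftol=1e-10, gtol=1e-10,
        max_nfev=500 * (len(spec.free) + 1), epsfcn=1e-8,
    )
    estimates = {name: float(out.params[name].value) for name in spec.free}
    rss = float(np.sum(np.asarray(out.residual) ** 2))
    converged = bool(out.success)
    # objective decrease relative to the literal start; LM occasionally
    # exits (slightly) above it after wandering a flat ridge
    if rss > start_rss:
        estimates = literal_start
        rss = start_rss
        converged = False
    return _finish(
        spec, data, estimates, rss, len(start_res), len(spec.free),
        converged, int(out.nfev),
    )


def fit(spec: FitSpec, data: FrequencyDataset, seed: int = 0) -> FitResult:
    """Minimize the residual sum of squares over the free parameters.

    With no free parameters the RSS of the fixed parameter set is
    evaluated and returned with k = 0.  Non-convergence is flagged on
    the result (``converged=False``), never silently ignored.  The
    *seed* only matters when ``spec.n_restarts`` > 0 (jittered
    multi-start); the best-RSS restart wins.
    """
    if not spec.free:
        params = spec.build_params({})
        res = residual_vector(spec.model, params, data, spec.residual_mode)
        return _finish(
            spec, data, {}, float(np.sum(res**2)), len(res), 0, True, 0
        )

    best = _single_fit(spec, data)
    if spec.n_restarts > 0:
        rng = np.random.default_rng(seed)
        for _ in range(spec.n_restarts):
            restarted = replace(
                spec, start=_jittered_starts(spec, rng), n_restarts=0
            )
            cand = _single_fit(restarted, data)
            if cand.rss < best.rss:
                best = cand
    return best
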