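"""Goodness-of-fit statistics, AIC ranking, and the fixed-zeta sweep.

The discriminating question is whether therapy response is driven by
differential survival of distinct cell types (gamma only) or by
facultative ADRN->MES state switching (gamma + zeta).  Fits are ranked
by the least-squares Akaike information criterion

    AIC = n * ln(RSS / n) + 2k

with n the length of the residual vector and k the number of free
parameters; R^2 is pooled over all residual entries (both phenotypes,
all replicates) against the mean of the pooled observations.  The
fixed-zeta sweep profiles the fit quality as the switching rate is
forced upward from zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .calibrate import FitResult, FitSpec, FrequencyDataset, fit
from .models import ContractError, ModelId

__all__ = [
    "r_squared",
    "aic",
    "ModelComparison",
    "compare",
    "SweepResult",
    "zeta_sweep",
    "default_zeta_grid",
]


def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination 1 - RSS/TSS over pooled entries."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be equal-length 1-d")
    if obs.size < 2:
        raise ValueError("need at least 2 observations")
    tss = float(np.sum((obs - obs.mean()) ** 2))
    if tss == 0.0:
        raise ValueError("zero total sum of squares: observations all identical")
    rss = float(np.sum((pred - obs) ** 2))
    return 1.0 - rss / tss


def aic(rss: float, n_obs: int, k: int) -> float:
    """Least-squares AIC: n * ln(RSS/n) + 2k (no small-sample correction)."""
    if rss < 0:
        raise ValueError(f"negative RSS {rss}")
    if rss == 0:
        raise ValueError(
            "RSS is exactly zero (perfect fit); AIC diverges to -inf -- "
            "report the fit as perfect instead of an AIC value"
        )
    if n_obs <= 0:
        raise ValueError(f"n_obs must be positive, got {n_obs}")
    if k < 0:
        raise ValueError(f"k must be non-negative, got {k}")
    return n_obs * math.log(rss / n_obs) + 2 * k


@dataclass(frozen=True)
class ModelComparison:
    """Competing fits ranked by ascending AIC."""

    entries: Tuple[Tuple[str, FitResult], ...]  # ranked, best first
    best_by_aic: str

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, res in self.entries:
            rows.append(
                {
                    "label": label,
                    "model": res.model.value,
                    "k": res.k,
                    "rss": res.rss,
                    "r2": res.r2,
                    "aic": res.aic,
                }
            )
        return pd.DataFrame(rows)


def compare(entries: Sequence[Tuple[str, FitResult]]) -> ModelComparison:
    """Rank fits by AIC (ascending); ties broken by smaller k, then input order.

    All entries must come from the same dataset and residual layout
    (checked via the residual-vector length n_obs).
    """
    entries = list(entries)
    if not entries:
        raise ContractError("compare() needs at least one fit")
    n_set = {res.n_obs for _, res in entries}
    if len(n_set) > 1:
        raise ContractError(
            f"fits were computed on different residual layouts (n_obs={sorted(n_set)})"
        )
    ranked = sorted(
        enumerate(entries), key=lambda item: (item[1][1].aic, item[1][1].k, item[0])
    )
    ordered = tuple(entry for _, entry in ranked)
    return ModelComparison(entries=ordered, best_by_aic=ordered[0][0])


def default_zeta_grid(
    lo: float = 0.0, hi: float = 0.02, n_points: int = 21
) -> Tuple[float, ...]:
    """Linearly spaced switching-rate grid, default 21 points on [0, 0.02]."""
    return tuple(np.linspace(lo, hi, n_points))


@dataclass(frozen=True)
class SweepResult:
    """Per-grid-point fits of the cell-state model with zeta held fixed."""

    zeta_grid: Tuple[float, ...]
    fits: Tuple[Optional[FitResult], ...]  # None marks a failed grid point

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for z, res in zip(self.zeta_grid, self.fits):
            if res is None:
                rows.append(
                    {"zeta": z, "gamma_hat": np.nan, "rss": np.nan,
                     "r2": np.nan, "aic": np.nan}
                )
            else:
                rows.append(
                    {"zeta": z, "gamma_hat": res.estimates["gamma"],
                     "rss": res.rss, "r2": res.r2, "aic": res.aic}
                )
        return pd.DataFrame(rows)


def zeta_sweep(
    data: FrequencyDataset,
    grid: Sequence[float],
    base_spec: FitSpec,
) -> SweepResult:
    """Profile the fit over a grid of fixed switching rates zeta.

    *base_spec* must target ``CELLSTATE_THERAPY`` with zeta not free;
    at each grid point zeta is pinned and the remaining free
    parameters (typically gamma alone) are refitted.  A failed fit at
    one grid point is recorded as None and does not abort the sweep.
    """
    grid = tuple(float(z) for z in grid)
    if not grid:
        raise ContractError("empty zeta grid")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ContractError("zeta grid must be strictly increasing")
    if base_spec.model is not ModelId.CELLSTATE_THERAPY:
        raise ContractError("zeta sweep requires the cell-state therapy model")
    if "zeta" in base_spec.free:
        raise ContractError("move zeta from free to fixed for the sweep")

    fits: list[Optional[FitResult]] = []
    for z in grid:
        spec = replace(base_spec, fixed={**base_spec.fixed, "zeta": z})
        try:
            fits.append(fit(spec, data))
        except Exception:
            fits.append(None)
    return SweepResult(zeta_grid=grid, fits=tuple(fits))
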