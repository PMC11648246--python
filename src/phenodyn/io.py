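"""CSV / JSON / YAML readers and writers for datasets, fits and specs."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .calibrate import FitResult, FitSpec, FrequencyDataset
from .models import ContractError, ModelId, TreatmentSchedule, UNTREATED

__all__ = [
    "ParseError",
    "read_frequency_csv",
    "write_frequency_csv",
    "read_fit_json",
    "write_fit_json",
    "schedule_from_pairs",
    "read_fit_spec",
]

CSV_COLUMNS = ("time_h", "replicate", "freq_adrn", "freq_mes", "condition")


class ParseError(ValueError):
    """A file does not match the documented schema."""


def schedule_from_pairs(pairs: Optional[Sequence[Sequence[float]]]) -> TreatmentSchedule:
    if not pairs:
        return UNTREATED
    return TreatmentSchedule(tuple((float(a), float(b)) for a, b in pairs))


def read_frequency_csv(
    path: str | Path, schedule: TreatmentSchedule = UNTREATED
) -> FrequencyDataset:
    """Read a frequency dataset.

    Schema: ``time_h`` (float, hours post-seeding), ``replicate``
    (string), ``freq_adrn``, ``freq_mes`` (floats summing to 1 within
    1e-6 per row), ``condition`` (UNTREATED or TREATED, constant).
    The therapy schedule is not stored in the CSV and is supplied
    separately (config or CLI flag).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed file
        raise ParseError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    for col in ("time_h", "freq_adrn", "freq_mes"):
        try:
            df[col] = df[col].astype(float)
        except (TypeError, ValueError) as exc:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()].tolist()
            raise ParseError(
                f"{path}: non-numeric {col} at data rows {bad}"
            ) from exc
    bad = df.index[(df["freq_adrn"] + df["freq_mes"] - 1.0).abs() > 1e-6].tolist()
    if bad:
        raise ParseError(
            f"{path}: freq_adrn + freq_mes != 1 (tol 1e-6) at data rows {bad}"
        )
    conditions = set(df["condition"].astype(str).unique())
    if len(conditions) != 1:
        raise ParseError(f"{path}: mixed conditions {sorted(conditions)}")
    condition = conditions.pop()
    try:
        return FrequencyDataset(
            df[list(CSV_COLUMNS[:4])], condition=condition, schedule=schedule
        )
    except ContractError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_frequency_csv(data: FrequencyDataset, path: str | Path) -> None:
    df = data.frame.copy()
    df["condition"] = data.condition
    df.to_csv(path, index=False, columns=list(CSV_COLUMNS))


def write_fit_json(result: FitResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), indent=2) + "\n")


def read_fit_json(path: str | Path) -> FitResult:
    try:
        return FitResult.from_dict(json.loads(Path(path).read_text()))
    except (KeyError, ValueError) as exc:
        raise ParseError(f"{path}: not a valid fit result ({exc})") from exc


def read_fit_spec(path: str | Path) -> tuple[FitSpec, TreatmentSchedule]:
    """Load a fit specification from YAML/JSON.

    Keys: ``model`` (one of the four model ids), ``free`` (list),
    ``fixed`` (mapping), optional ``bounds`` (mapping name ->
    [low, high]), ``start`` (mapping), ``residual_mode``,
    ``n_restarts`` and ``schedule`` (list of [start, end] on-intervals,
    hours).
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: fit spec must be a mapping")
    try:
        model = ModelId(raw["model"])
        spec = FitSpec(
            model=model,
            free=tuple(raw.get("free", ())),
            fixed=dict(raw.get("fixed", {})),
            bounds={k: tuple(v) for k, v in dict(raw.get("bounds", {})).items()},
            start=dict(raw.get("start", {})),
            residual_mode=raw.get("residual_mode", "both"),
            n_restarts=int(raw.get("n_restarts", 0)),
        )
    except (KeyError, ValueError, ContractError) as exc:
        raise ParseError(f"{path}: invalid fit spec ({exc})") from exc
    schedule = schedule_from_pairs(raw.get("schedule"))
    return spec, schedule
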