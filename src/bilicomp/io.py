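"""File formats: measurement/estimate CSV tables, model JSON, config files.

CSV dialect: comma-separated, UTF-8, header required, '.' decimal separator,
full float precision on write (so read → write → read round-trips exactly).
Lines starting with ``#`` are provenance comments and are skipped on read.

Measurement CSV schema::

    sample_id,bilirubin_mgdl,hemoglobin_gdl,replicate,r465,r590[,strip_ok]

Rows with ``strip_ok`` false (an operator flagged an abnormal or incompletely
saturated strip) are excluded on read with a logged count — on the bench such
tests are repeated, so they never enter the analysis.

Simulator configs are flat ``key = value`` files whose keys are exactly the
:class:`~bilicomp.optical.OpticalParams` field names.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .compensation import BilirubinEstimate, CalibrationCurve, CompensationModel
from .exceptions import DomainError, ParseError
from .optical import Measurement, OpticalParams

__all__ = [
    "MeasurementTable",
    "read_measurements",
    "write_measurements",
    "read_estimates",
    "write_estimates",
    "read_config",
    "load_model",
]

logger = logging.getLogger("bilicomp")

MEASUREMENT_COLUMNS = ("sample_id", "bilirubin_mgdl", "hemoglobin_gdl", "replicate", "r465", "r590")
ESTIMATE_COLUMNS = MEASUREMENT_COLUMNS + ("estimate_mgdl", "compensated", "flags")

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


@dataclass(frozen=True)
class MeasurementTable:
    """Validated measurement rows plus exclusion bookkeeping."""

    rows: tuple[Measurement, ...]
    n_excluded: int = 0

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)


def _parse_bool(value, path: Path, row: int) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ParseError(f"{path}: row {row}, column 'strip_ok': not a boolean: {value!r}")


def read_measurements(path: str | Path) -> MeasurementTable:
    """Read and validate a measurement CSV.

    Raises :class:`ParseError` naming the offending row and column for a
    missing column, a non-numeric cell, or a duplicate (sample_id, replicate)
    key.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"{path}: cannot read CSV: {exc}")
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s): {', '.join(missing)}")

    numeric = {"bilirubin_mgdl": float, "hemoglobin_gdl": float, "replicate": int,
               "r465": float, "r590": float}
    parsed: dict[str, list] = {c: [] for c in df.columns}
    for idx, row in df.iterrows():
        rownum = idx + 2  # 1-based, plus header line
        for col, caster in numeric.items():
            try:
                parsed[col].append(caster(row[col]))
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: row {rownum}, column {col!r}: not numeric: {row[col]!r}"
                )
        parsed["sample_id"].append(str(row["sample_id"]))
        if "strip_ok" in df.columns:
            parsed["strip_ok"].append(_parse_bool(row["strip_ok"], path, rownum))

    keys = list(zip(parsed["sample_id"], parsed["replicate"]))
    seen: set = set()
    for rownum, key in enumerate(keys, start=2):
        if key in seen:
            raise ParseError(
                f"{path}: row {rownum}: duplicate (sample_id, replicate) key {key}"
            )
        seen.add(key)

    strip_ok = parsed.get("strip_ok", [True] * len(keys))
    rows = []
    n_excluded = 0
    for i in range(len(keys)):
        if not strip_ok[i]:
            n_excluded += 1
            continue
        rows.append(
            Measurement(
                sample_id=parsed["sample_id"][i],
                bilirubin_nominal=parsed["bilirubin_mgdl"][i],
                hemoglobin_nominal=parsed["hemoglobin_gdl"][i],
                replicate=parsed["replicate"][i],
                r465=parsed["r465"][i],
                r590=parsed["r590"][i],
            )
        )
    logger.info(
        "read %d measurement rows from %s (%d excluded via strip_ok)",
        len(rows), path, n_excluded,
    )
    return MeasurementTable(rows=tuple(rows), n_excluded=n_excluded)


def write_measurements(
    measurements: Sequence[Measurement] | MeasurementTable,
    path: str | Path,
    provenance: Mapping[str, object] | None = None,
) -> None:
    """Write measurements as CSV, optionally with ``# key = value`` header lines."""
    path = Path(path)
    rows = list(measurements)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key} = {value}\n")
        fh.write(",".join(MEASUREMENT_COLUMNS) + ",strip_ok\n")
        for m in rows:
            fh.write(
                f"{m.sample_id},{m.bilirubin_nominal!r},{m.hemoglobin_nominal!r},"
                f"{m.replicate},{m.r465!r},{m.r590!r},{str(m.strip_ok).lower()}\n"
            )
    logger.info("wrote %d measurement rows to %s", len(rows), path)


def write_estimates(estimates: Sequence[BilirubinEstimate], path: str | Path) -> None:
    """Write bilirubin estimates as CSV (flags are ';'-joined)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(ESTIMATE_COLUMNS) + "\n")
        for e in estimates:
            fh.write(
                f"{e.sample_id},{e.bilirubin_nominal!r},{e.hemoglobin_nominal!r},"
                f"{e.replicate},{e.r465!r},{e.r590!r},{e.estimate_mgdl!r},"
                f"{str(e.compensated).lower()},{';'.join(e.flags)}\n"
            )
    logger.info("wrote %d estimates to %s", len(estimates), path)


def read_estimates(path: str | Path) -> list[BilirubinEstimate]:
    """Read an estimates CSV written by :func:`write_estimates`."""
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"{path}: cannot read CSV: {exc}")
    missing = [c for c in ESTIMATE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s): {', '.join(missing)}")
    out = []
    for idx, row in df.iterrows():
        try:
            out.append(
                BilirubinEstimate(
                    sample_id=str(row["sample_id"]),
                    replicate=int(row["replicate"]),
                    bilirubin_nominal=float(row["bilirubin_mgdl"]),
                    hemoglobin_nominal=float(row["hemoglobin_gdl"]),
                    r465=float(row["r465"]),
                    r590=float(row["r590"]),
                    estimate_mgdl=float(row["estimate_mgdl"]),
                    compensated=_parse_bool(row["compensated"], path, idx + 2),
                    flags=tuple(f for f in str(row["flags"]).split(";") if f),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: row {idx + 2}: {exc}")
    logger.info("read %d estimates from %s", len(out), path)
    return out


def read_config(path: str | Path) -> OpticalParams:
    """Parse a flat ``key = value`` simulator config into OpticalParams.

    Keys must be OpticalParams field names; unset fields keep their
    defaults.  ``#`` starts a comment; blank lines are ignored.
    """
    path = Path(path)
    known = {f.name: f.type for f in fields(OpticalParams)}
    overrides: dict[str, object] = {}
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParseError(f"{path}: line {lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in known:
            raise ParseError(
                f"{path}: line {lineno}: unknown parameter {key!r} "
                f"(valid: {', '.join(sorted(known))})"
            )
        if key == "interference_mode":
            overrides[key] = value
        elif key == "seed":
            try:
                overrides[key] = int(value)
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: seed must be an integer")
        else:
            try:
                overrides[key] = float(value)
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: {key} must be numeric")
    try:
        return OpticalParams(**overrides)
    except DomainError as exc:
        raise ParseError(f"{path}: invalid parameter values: {exc}")


def load_model(path: str | Path) -> CalibrationCurve | CompensationModel:
    """Load a model JSON file, dispatching on its ``model`` discriminator."""
    d = json.loads(Path(path).read_text())
    kind = d.get("model")
    if kind == "calibration":
        return CalibrationCurve.from_dict(d)
    if kind == "compensation":
        return CompensationModel.from_dict(d)
    raise ParseError(f"{path}: unknown model kind {kind!r}")
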