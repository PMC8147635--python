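"""Reading and writing cohorts, feature tables, and configs.

The canonical cohort dialect is one row per participant: metadata and
covariate columns first, then the 6912 conductivity values in sensor-major,
cycle-middle, temperature-minor order.  A leading line ``bp_dialect,<name>``
declares the dialect version so malformed or foreign files fail loudly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

#: tensor axes: temperature step x measurement cycle x sensor
N_TEMP = 64
N_CYCLE = 36
N_SENSOR = 3
N_VALUES = N_TEMP * N_CYCLE * N_SENSOR  # 6912

N_FEATURES = 19

COHORT_DIALECT = "bp-cohort-v1"
FEATURE_DIALECT = "bp-feature-v1"

LABELS = ("positive", "negative", "unknown")


class MalformedInputError(ValueError):
    """A file violated the declared dialect (shape, type, or range)."""


@dataclass
class CovariateProfile:
    """Per-participant clinical covariates.

    Missing values are encoded as ``nan`` (age, pack-years) or ``None``
    (sex, toombak use); downstream regression drops incomplete cases
    listwise.
    """

    age: float = float("nan")
    sex: str | None = None            # "male" / "female"
    toombak_use: bool | None = None
    smoking_packyears: float = float("nan")

    def is_complete(self) -> bool:
        return (
            np.isfinite(self.age)
            and self.sex in ("male", "female")
            and self.toombak_use is not None
            and np.isfinite(self.smoking_packyears)
        )


@dataclass
class SensorTensor:
    """One participant's raw e-nose measurement.

    ``values[t, c, s]`` is the conductivity at temperature step ``t``
    (0..63, one heat/cool ramp between 260 and 340 degC), measurement cycle
    ``c`` (0..35) and sensor ``s`` (0..2).
    """

    participant_id: str
    values: np.ndarray
    device_id: str = "257"
    order_index: int = 0
    label: str = "unknown"
    covariates: CovariateProfile = field(default_factory=CovariateProfile)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_TEMP, N_CYCLE, N_SENSOR):
            raise MalformedInputError(
                f"participant {self.participant_id!r}: expected "
                f"{N_TEMP}x{N_CYCLE}x{N_SENSOR} values, got shape "
                f"{self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise MalformedInputError(
                f"participant {self.participant_id!r}: non-finite values"
            )
        if self.label not in LABELS:
            raise MalformedInputError(
                f"participant {self.participant_id!r}: label {self.label!r} "
                f"not in {LABELS}"
            )


@dataclass
class FeatureVector:
    """The 19-element compressed breathprint, each value in [-1, 1]."""

    participant_id: str
    features: np.ndarray
    label: str = "unknown"

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape != (N_FEATURES,):
            raise MalformedInputError(
                f"participant {self.participant_id!r}: expected "
                f"{N_FEATURES} features, got {self.features.shape}"
            )
        if np.any(np.abs(self.features) > 1 + 1e-12):
            raise MalformedInputError(
                f"participant {self.participant_id!r}: feature outside [-1, 1]"
            )


# ---------------------------------------------------------------------------
# column layout

_META_COLS = [
    "participant_id",
    "device_id",
    "order_index",
    "label",
    "age",
    "sex",
    "toombak_use",
    "smoking_packyears",
]


def value_columns() -> list[str]:
    """Names of the 6912 value columns, sensor-major / cycle / temperature."""
    return [
        f"s{s}c{c:02d}t{t:02d}"
        for s in range(N_SENSOR)
        for c in range(N_CYCLE)
        for t in range(N_TEMP)
    ]


def _flatten_values(values: np.ndarray) -> np.ndarray:
    # [t, c, s] -> sensor-major, cycle-middle, temperature-minor
    return np.transpose(values, (2, 1, 0)).reshape(-1)


def _unflatten_values(flat: np.ndarray) -> np.ndarray:
    return np.transpose(flat.reshape(N_SENSOR, N_CYCLE, N_TEMP), (2, 1, 0))


# ---------------------------------------------------------------------------
# cohort dialect


def write_cohort_csv(path: str | Path, cohort: Sequence[SensorTensor]) -> None:
    """Write a cohort in the canonical dialect (bit-exact round trip)."""
    rows = []
    for t in cohort:
        cov = t.covariates
        row: dict[str, object] = {
            "participant_id": t.participant_id,
            "device_id": t.device_id,
            "order_index": t.order_index,
            "label": t.label,
            "age": cov.age,
            "sex": "" if cov.sex is None else cov.sex,
            "toombak_use": "" if cov.toombak_use is None else ("yes" if cov.toombak_use else "no"),
            "smoking_packyears": cov.smoking_packyears,
        }
        row.update(zip(value_columns(), _flatten_values(t.values)))
        rows.append(row)
    frame = pd.DataFrame(rows, columns=_META_COLS + value_columns())
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"bp_dialect,{COHORT_DIALECT}\n")
        frame.to_csv(fh, index=False, lineterminator="\n")


def _read_dialect_line(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline().strip()
    parts = first.split(",")
    if len(parts) >= 2 and parts[0] == "bp_dialect":
        return parts[1]
    return ""


def read_cohort_csv(path: str | Path, best_effort: bool = False) -> list[SensorTensor]:
    """Read a cohort CSV.

    In strict mode the file must declare the canonical dialect.  With
    ``best_effort=True`` any table holding 6912 numeric value columns per
    row is accepted; unknown headers are warned about and id/label columns
    are picked up when recognizably named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = _read_dialect_line(path)
    if dialect != COHORT_DIALECT and not best_effort:
        raise MalformedInputError(
            f"{path}: expected dialect {COHORT_DIALECT!r}, found {dialect!r} "
            "(pass best_effort=True to attempt a tolerant import)"
        )
    skip = 1 if dialect else 0
    frame = pd.read_csv(
        path,
        skiprows=skip,
        dtype={"participant_id": str, "device_id": str},
        float_precision="round_trip",
    )
    if dialect == COHORT_DIALECT:
        missing = [c for c in _META_COLS if c not in frame.columns]
        if missing:
            raise MalformedInputError(f"{path}: missing columns {missing}")
        vcols = value_columns()
        extra = [c for c in frame.columns if c not in _META_COLS + vcols]
        if extra or len(frame.columns) != len(_META_COLS) + N_VALUES:
            raise MalformedInputError(
                f"{path}: wrong cell count per participant "
                f"({len(frame.columns)} columns; unknown: {extra[:5]})"
            )
        return _records_from_frame(frame, vcols, path)
    return _best_effort_cohort(frame, path)


def _records_from_frame(frame: pd.DataFrame, vcols: list[str], path: Path) -> list[SensorTensor]:
    records = []
    values = frame[vcols]
    numeric = values.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & values.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise MalformedInputError(
            f"{path}: non-numeric cell at data row {r + 1}, column {vcols[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise MalformedInputError(
            f"{path}: empty cell at data row {r + 1}, column {vcols[c]!r}"
        )
    for i, row in frame.iterrows():
        tb = row["toombak_use"]
        cov = CovariateProfile(
            age=float(row["age"]) if pd.notna(row["age"]) else float("nan"),
            sex=row["sex"] if isinstance(row["sex"], str) and row["sex"] else None,
            toombak_use=None if pd.isna(tb) or tb == "" else tb == "yes",
            smoking_packyears=(
                float(row["smoking_packyears"])
                if pd.notna(row["smoking_packyears"])
                else float("nan")
            ),
        )
        try:
            records.append(
                SensorTensor(
                    participant_id=str(row["participant_id"]),
                    values=_unflatten_values(numeric.iloc[i].to_numpy(dtype=float)),
                    device_id=str(row["device_id"]),
                    order_index=int(row["order_index"]),
                    label=str(row["label"]),
                    covariates=cov,
                )
            )
        except MalformedInputError as exc:
            raise MalformedInputError(f"{path}: {exc}") from exc
    _check_order_index(records)
    return records


def _best_effort_cohort(frame: pd.DataFrame, path: Path) -> list[SensorTensor]:
    numeric = frame.select_dtypes(include=[np.number])
    # columns that are fully numeric and not obviously metadata
    meta_like = {"order_index", "age", "smoking_packyears"}
    candidates = [c for c in numeric.columns if c not in meta_like]
    if len(candidates) < N_VALUES:
        raise MalformedInputError(
            f"{path}: best-effort import needs {N_VALUES} numeric value "
            f"columns, found {len(candidates)}"
        )
    if len(candidates) > N_VALUES:
        warnings.warn(
            f"{path}: {len(candidates) - N_VALUES} surplus numeric columns; "
            "using the last 6912 in file order",
            stacklevel=2,
        )
        candidates = candidates[-N_VALUES:]
    unknown = [c for c in frame.columns if c not in candidates and c not in _META_COLS]
    if unknown:
        warnings.warn(f"{path}: unknown headers {unknown[:8]}", stacklevel=2)
    records = []
    for i in range(len(frame)):
        pid = (
            str(frame.iloc[i]["participant_id"])
            if "participant_id" in frame.columns
            else f"row{i}"
        )
        label = str(frame.iloc[i]["label"]) if "label" in frame.columns else "unknown"
        if label not in LABELS:
            label = "unknown"
        records.append(
            SensorTensor(
                participant_id=pid,
                values=_unflatten_values(frame.iloc[i][candidates].to_numpy(dtype=float)),
                device_id=str(frame.iloc[i].get("device_id", "unknown")),
                order_index=int(frame.iloc[i].get("order_index", i)),
                label=label,
            )
        )
    return records


def _check_order_index(cohort: Sequence[SensorTensor]) -> None:
    idx = [t.order_index for t in cohort]
    if len(set(idx)) != len(idx):
        raise MalformedInputError("order_index values are not unique within the cohort")


# ---------------------------------------------------------------------------
# feature dialect


def write_feature_csv(path: str | Path, vectors: Sequence[FeatureVector]) -> None:
    cols = ["participant_id", "label"] + [f"f{i:02d}" for i in range(N_FEATURES)]
    rows = []
    for v in vectors:
        row: dict[str, object] = {"participant_id": v.participant_id, "label": v.label}
        row.update({f"f{i:02d}": v.features[i] for i in range(N_FEATURES)})
        rows.append(row)
    frame = pd.DataFrame(rows, columns=cols)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"bp_dialect,{FEATURE_DIALECT}\n")
        frame.to_csv(fh, index=False, lineterminator="\n")


def read_feature_csv(path: str | Path) -> list[FeatureVector]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = _read_dialect_line(path)
    if dialect != FEATURE_DIALECT:
        raise MalformedInputError(
            f"{path}: expected dialect {FEATURE_DIALECT!r}, found {dialect!r}"
        )
    frame = pd.read_csv(
        path, skiprows=1, dtype={"participant_id": str}, float_precision="round_trip"
    )
    fcols = [f"f{i:02d}" for i in range(N_FEATURES)]
    expected = ["participant_id", "label"] + fcols
    if list(frame.columns) != expected:
        raise MalformedInputError(
            f"{path}: expected columns {expected[:3]}...f18, got "
            f"{len(frame.columns)} columns"
        )
    out = []
    for i, row in frame.iterrows():
        feats = row[fcols].to_numpy(dtype=float)
        if np.any(np.abs(feats) > 1 + 1e-12):
            raise MalformedInputError(
                f"{path}: data row {i + 1}: feature value outside [-1, 1]"
            )
        out.append(
            FeatureVector(
                participant_id=str(row["participant_id"]),
                features=feats,
                label=str(row["label"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# configs


def load_yaml_config(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def dump_yaml_config(path: str | Path, cfg: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
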