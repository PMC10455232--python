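"""Catheterisation-trace and clinical-record data model and on-disk formats.

A catheterisation trace is the time series logged during one intermittent
catheterisation: time since catheter insertion (s), cumulative drained urine
(measured as mass on a precision scale, converted 1 g = 1 mL), and
intra-catheter pressure (cmH2O, corrected for atmospheric pressure, so
suction is negative).  Traces are stored as plain CSV with a header row;
column names are remappable through a small dialect mapping so vendor
exports can be read without rewriting them.

Cumulative mass from a weighing scale is noisy and can decrease by fractions
of a gram between samples; the reader repairs this with a running maximum so
that the derived flowrate is non-negative by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, FormatError

logger = logging.getLogger(__name__)

DEVICES = ("MHZC", "CEC")
VISITS = (1, 2)

#: default trace CSV dialect: logical field -> column name
DEFAULT_DIALECT: dict[str, str] = {
    "time": "time_s",
    "volume": "volume_ml",
    "mass": "mass_g",
    "pressure": "pressure_cmh2o",
}

#: gaps in the time base longer than this (s) are flagged as dropouts
DROPOUT_GAP_S = 2.0

# urine density taken as 1.000 g/mL for the mass -> volume conversion
MASS_TO_VOLUME_ML_PER_G = 1.0


def repair_monotone(values: np.ndarray) -> tuple[np.ndarray, int]:
    """Running-maximum repair of a cumulative series.

    Returns the repaired array and the number of samples that were raised.
    Idempotent, and never decreases any sample.
    """
    arr = np.asarray(values, dtype=float)
    repaired = np.maximum.accumulate(arr)
    n_repaired = int(np.sum(repaired > arr))
    return repaired, n_repaired


@dataclass(frozen=True)
class ProfileTrace:
    """One catheterisation's sampled time series.

    t is seconds from catheter insertion (strictly increasing), v cumulative
    drained volume (mL, non-decreasing), p intra-catheter pressure (cmH2O,
    suction negative).
    """

    subject_id: str
    device: str
    visit: int
    t: np.ndarray
    v: np.ndarray
    p: np.ndarray
    sampling_rate_nominal: float = 2.5
    dropout_gaps: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.v, dtype=float)
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "v", v)
        object.__setattr__(self, "p", p)
        if self.device not in DEVICES:
            raise DataError(f"unknown device {self.device!r}; expected one of {DEVICES}")
        if self.visit not in VISITS:
            raise DataError(f"visit must be 1 or 2, got {self.visit!r}")
        if not (len(t) == len(v) == len(p)):
            raise DataError("t, v, p must have equal length")
        if len(t) < 2:
            raise DataError(f"trace needs at least 2 samples, got {len(t)}")
        dt = np.diff(t)
        if not np.all(dt > 0):
            raise DataError("timestamps must be strictly increasing")
        if np.any(np.diff(v) < 0):
            raise DataError("cumulative volume must be non-decreasing (apply repair_monotone first)")
        if np.any(v < 0):
            raise DataError("cumulative volume must be non-negative")
        # ~2.5 Hz loggers should produce median intervals around 0.4 s
        if abs(self.sampling_rate_nominal - 2.5) < 0.5:
            med = float(np.median(dt))
            if not (0.2 <= med <= 0.8):
                raise DataError(
                    f"median sampling interval {med:.3f} s inconsistent with "
                    f"nominal {self.sampling_rate_nominal} Hz logging"
                )
        gaps = tuple(float(g) for g in dt[dt > DROPOUT_GAP_S])
        if gaps and not self.dropout_gaps:
            object.__setattr__(self, "dropout_gaps", gaps)
            logger.warning(
                "trace %s/%s/v%s: %d dropout gap(s) > %.1f s flagged (not interpolated)",
                self.subject_id, self.device, self.visit, len(gaps), DROPOUT_GAP_S,
            )

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def v_total(self) -> float:
        """Total catheterised volume (mL)."""
        return float(self.v[-1])


@dataclass(frozen=True)
class CatheterSpec:
    """Geometry of a catheter's drainage zone."""

    device: str
    n_holes: int
    hole_area: float  # mm^2 per hole
    zone_length: float = 0.0  # mm


#: micro-hole zone catheter: 120 micro-holes of 0.13 mm^2 over a 60 mm zone
MHZC_SPEC = CatheterSpec(device="MHZC", n_holes=120, hole_area=0.13, zone_length=60.0)
#: conventional eyelet catheter: two ~5 mm^2 eyelets at the tip
CEC_SPEC = CatheterSpec(device="CEC", n_holes=2, hole_area=5.0, zone_length=0.0)


def total_drainage_area(spec: CatheterSpec) -> float:
    """Total drainage surface area (mm^2) = n_holes x hole_area."""
    if spec.n_holes <= 0 or spec.hole_area <= 0:
        raise DataError("catheter spec needs n_holes > 0 and hole_area > 0")
    return spec.n_holes * spec.hole_area


DIPSTICK_CATEGORIES = (
    "negative",
    "non-haemolysed 10 (+/-)",
    "haemolysed 10 (+/-)",
    "haemolysed 25 (1+)",
    "haemolysed 80 (2+)",
    "non-haemolysed 80 (2+)",
    "haemolysed 200 (3+)",
)

MEDICAL_HISTORIES = ("neurogenic", "non-neurogenic")


@dataclass(frozen=True)
class ClinicalRecord:
    """Per subject-visit clinical measurements outside the trace."""

    subject_id: str
    visit: int
    device: str
    prevoid_scan: tuple[float, float, float]
    postvoid_scan: tuple[float, float, float]
    dipstick: str
    medical_history: str = "non-neurogenic"

    def __post_init__(self) -> None:
        for name in ("prevoid_scan", "postvoid_scan"):
            trip = tuple(float(x) for x in getattr(self, name))
            if len(trip) != 3:
                raise DataError(f"{name} must have exactly 3 entries, got {len(trip)}")
            if any(x < 0 for x in trip):
                raise DataError(f"{name} volumes must be non-negative")
            object.__setattr__(self, name, trip)
        if self.dipstick not in DIPSTICK_CATEGORIES:
            raise DataError(
                f"unknown dipstick category {self.dipstick!r}; "
                f"expected one of {DIPSTICK_CATEGORIES}"
            )
        if self.medical_history not in MEDICAL_HISTORIES:
            raise DataError(f"unknown medical history {self.medical_history!r}")
        if self.device not in DEVICES:
            raise DataError(f"unknown device {self.device!r}")
        if self.visit not in VISITS:
            raise DataError(f"visit must be 1 or 2, got {self.visit!r}")


# ---------------------------------------------------------------------------
# trace CSV


def _resolve_dialect(dialect: Mapping[str, str] | None) -> dict[str, str]:
    d = dict(DEFAULT_DIALECT)
    if dialect:
        unknown = set(dialect) - set(DEFAULT_DIALECT)
        if unknown:
            raise ConfigError(f"unknown dialect keys: {sorted(unknown)}")
        d.update(dialect)
    return d


def _read_header_meta(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
    return meta


def read_trace(path: str | Path, dialect: Mapping[str, str] | None = None) -> ProfileTrace:
    """Read a trace CSV, convert mass to volume, and apply monotone repair.

    The file is a comma-separated table with a header row; `#`-prefixed lines
    before the header carry metadata (subject_id, device, visit,
    sampling_rate_hz).  Either a volume column or a mass column must be
    present; mass is converted at 1 g = 1 mL.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"trace file not found: {path}")
    d = _resolve_dialect(dialect)
    meta = _read_header_meta(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # malformed CSV
        raise FormatError(f"cannot parse trace CSV {path}: {exc}") from exc

    if d["time"] not in df.columns:
        raise FormatError(f"{path}: missing time column {d['time']!r}")
    if d["pressure"] not in df.columns:
        raise FormatError(f"{path}: missing pressure column {d['pressure']!r}")
    if d["volume"] in df.columns:
        cum = df[d["volume"]].to_numpy(float)
    elif d["mass"] in df.columns:
        cum = df[d["mass"]].to_numpy(float) * MASS_TO_VOLUME_ML_PER_G
    else:
        raise FormatError(
            f"{path}: need a {d['volume']!r} or {d['mass']!r} column"
        )
    if len(df) < 2:
        raise DataError(f"{path}: trace needs at least 2 samples, got {len(df)}")

    t = df[d["time"]].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise DataError(f"{path}: timestamps not strictly increasing")
    v, n_repaired = repair_monotone(cum)
    if n_repaired:
        logger.info("%s: monotone repair raised %d of %d samples", path.name, n_repaired, len(v))
    return ProfileTrace(
        subject_id=meta.get("subject_id", path.stem),
        device=meta.get("device", "CEC"),
        visit=int(meta.get("visit", 1)),
        t=t,
        v=v,
        p=df[d["pressure"]].to_numpy(float),
        sampling_rate_nominal=float(meta.get("sampling_rate_hz", 2.5)),
    )


def write_trace(trace: ProfileTrace, path: str | Path) -> Path:
    """Write a trace to CSV (round-trips through read_trace)."""
    path = Path(path)
    df = pd.DataFrame(
        {"time_s": trace.t, "volume_ml": trace.v, "pressure_cmh2o": trace.p}
    )
    with open(path, "w") as fh:
        fh.write(f"# subject_id = {trace.subject_id}\n")
        fh.write(f"# device = {trace.device}\n")
        fh.write(f"# visit = {trace.visit}\n")
        fh.write(f"# sampling_rate_hz = {trace.sampling_rate_nominal}\n")
        df.to_csv(fh, index=False, float_format="%.17g")
    return path


# ---------------------------------------------------------------------------
# clinical-record CSV

_RECORD_COLUMNS = [
    "subject_id", "visit", "device",
    "prevoid_1", "prevoid_2", "prevoid_3",
    "postvoid_1", "postvoid_2", "postvoid_3",
    "dipstick", "medical_history",
]


def read_records(path: str | Path) -> list[ClinicalRecord]:
    """Read the clinical-record CSV (one row per subject-visit)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"record file not found: {path}")
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing record columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ClinicalRecord(
                subject_id=str(row.subject_id),
                visit=int(row.visit),
                device=str(row.device),
                prevoid_scan=(row.prevoid_1, row.prevoid_2, row.prevoid_3),
                postvoid_scan=(row.postvoid_1, row.postvoid_2, row.postvoid_3),
                dipstick=str(row.dipstick),
                medical_history=str(row.medical_history),
            )
        )
    return out


def write_records(records: Iterable[ClinicalRecord], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for r in records:
        rows.append(
            {
                "subject_id": r.subject_id,
                "visit": r.visit,
                "device": r.device,
                "prevoid_1": r.prevoid_scan[0],
                "prevoid_2": r.prevoid_scan[1],
                "prevoid_3": r.prevoid_scan[2],
                "postvoid_1": r.postvoid_scan[0],
                "postvoid_2": r.postvoid_scan[1],
                "postvoid_3": r.postvoid_scan[2],
                "dipstick": r.dipstick,
                "medical_history": r.medical_history,
            }
        )
    pd.DataFrame(rows, columns=_RECORD_COLUMNS).to_csv(path, index=False)
    return path
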