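"""Reading and writing gas-exchange time series and light-response tables.

Traces and tables are delimited text (comma or tab, auto-sniffed). Column
names follow common LI-6800 text-export headers by default but every
required column can be remapped through a *dialect* mapping, since
instrument export schemas vary between firmware versions.

Units are normalised on read: pressure to Pa (kPa auto-detected by a
magnitude threshold of 2000), temperature to K (degrees C detected below
200). Elapsed time is re-zeroed to the first log, because all downstream
arithmetic needs only inter-log intervals.
"""

from __future__ import annotations

import dataclasses
import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, ValidationError

#: canonical trace columns (internal names)
TRACE_COLUMNS = (
    "t_s",      # elapsed time, s
    "pfd_in",   # incident photon flux density, umol m-2 s-1
    "co2_s",    # sample-cell CO2 mole fraction, umol mol-1
    "h2o_s",    # sample-cell H2O mole fraction, mmol mol-1
    "a_raw",    # steady-state-equation net assimilation, umol m-2 s-1
    "e_raw",    # steady-state-equation transpiration, mol m-2 s-1
    "ci",       # intercellular CO2, umol mol-1
    "gsw",      # stomatal conductance to water vapour, mol m-2 s-1
    "p_air",    # cuvette pressure, Pa
    "t_air",    # cuvette air temperature, K
    "flow",     # air flow, umol s-1
    "s_leaf",   # enclosed leaf area, m2
)

#: default LI-6800-style export headers -> canonical names
DEFAULT_TRACE_DIALECT: dict[str, str] = {
    "t_s": "elapsed",
    "pfd_in": "Qin",
    "co2_s": "CO2_s",
    "h2o_s": "H2O_s",
    "a_raw": "A",
    "e_raw": "E",
    "ci": "Ci",
    "gsw": "gsw",
    "p_air": "Pa",
    "t_air": "Tair",
    "flow": "Flow",
    "s_leaf": "S",
}

LIGHT_RESPONSE_COLUMNS = ("pfd_in", "a", "ci", "gsw")
DEFAULT_LIGHT_RESPONSE_DIALECT: dict[str, str] = {
    "pfd_in": "Qin",
    "a": "A",
    "ci": "Ci",
    "gsw": "gsw",
}

#: pressures below this magnitude are assumed to be kPa and converted to Pa
PRESSURE_KPA_THRESHOLD = 2000.0
#: temperatures below this magnitude are assumed to be deg C and converted to K
TEMPERATURE_C_THRESHOLD = 200.0


@dataclass(frozen=True)
class TraceMeta:
    """Identity of one measured leaf/condition."""

    species: str = ""
    o2: float = 0.21          # O2 mole fraction, 0.21 or 0.02
    regime: str = ""          # e.g. "step6", "step30", "step300", "lrc"
    replicate: int = 0

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GasExchangeTrace:
    """Ordered per-log gas-exchange records for one leaf and condition.

    ``data`` holds one row per 2-Hz log with the canonical columns of
    :data:`TRACE_COLUMNS`; the dynamics module appends ``a_dyn``/``e_dyn``.
    """

    data: pd.DataFrame
    meta: TraceMeta = field(default_factory=TraceMeta)

    def __post_init__(self) -> None:
        if len(self.data) == 0:
            raise ValidationError("trace must contain at least one record")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def t(self) -> np.ndarray:
        return self.data["t_s"].to_numpy()

    @property
    def duration(self) -> float:
        t = self.t
        return float(t[-1] - t[0])


@dataclass
class LightResponseTable:
    """Steady-state light-response rows (one per PFD level)."""

    data: pd.DataFrame
    meta: TraceMeta = field(default_factory=TraceMeta)

    @property
    def levels(self) -> np.ndarray:
        return self.data["pfd_in"].to_numpy()

    def at_level(self, pfd: float) -> pd.Series:
        rows = self.data[np.isclose(self.data["pfd_in"], pfd)]
        if len(rows) == 0:
            raise ValidationError(f"light-response table has no {pfd} PFD level")
        return rows.iloc[0]


@dataclass(frozen=True)
class LightRegime:
    """Commanded light program for a fluctuating-light run.

    The treatment alternates between ``high_pfd`` and ``low_pfd`` every
    ``step_s`` seconds for ``total_s`` seconds, after acclimation at
    ``acclimation_pfd``. ``total_s`` need not be divisible by the full
    cycle; segmentation truncates any trailing partial step.
    """

    step_s: float
    acclimation_pfd: float = 150.0
    high_pfd: float = 800.0
    low_pfd: float = 100.0
    total_s: float = 3600.0
    first_phase: str = "high"
    log_hz: float = 2.0

    def __post_init__(self) -> None:
        if self.step_s <= 0:
            raise ValidationError("step_s must be positive")
        if self.first_phase not in ("high", "low"):
            raise ValidationError("first_phase must be 'high' or 'low'")

    def phase_at(self, t_s) -> np.ndarray:
        """Commanded phase ('high'/'low') at treatment time(s) ``t_s``."""
        k = np.floor(np.asarray(t_s, dtype=float) / self.step_s).astype(int)
        even_is_high = self.first_phase == "high"
        return np.where((k % 2 == 0) == even_is_high, "high", "low")

    def pfd_at(self, t_s) -> np.ndarray:
        return np.where(self.phase_at(t_s) == "high", self.high_pfd, self.low_pfd)


#: the three step durations used in the fluctuating-light treatments
STANDARD_REGIMES: dict[str, LightRegime] = {
    "step6": LightRegime(step_s=6.0),
    "step30": LightRegime(step_s=30.0),
    "step300": LightRegime(step_s=300.0),
}

#: theoretical maximum quantum yields of CO2 fixation (CO2/photon) by pathway
PHI_MAX_BY_SUBTYPE: dict[str, float] = {
    "none": 0.111,            # C3
    "NADP-ME": 0.064,
    "NAD-ME": 0.064,
    "NADP-ME-PEPCK": 0.075,   # mixed subtype, lower energy requirement
}


@dataclass(frozen=True)
class SpeciesConfig:
    """Species identity plus the constants needed for quantum yields."""

    name: str
    genus: str
    pathway: str                  # "C3" or "C4"
    subtype: str = "none"         # C4 decarboxylase subtype, "none" for C3
    phi_max: float | None = None  # theoretical max CO2/photon; default by subtype
    l_abs_red: float = 0.85       # absorptance at the 625 nm source band
    l_abs_blue: float = 0.85      # absorptance at the 475 nm source band

    def __post_init__(self) -> None:
        if self.pathway not in ("C3", "C4"):
            raise ValidationError(f"unknown pathway {self.pathway!r}")
        if self.phi_max is None:
            key = "none" if self.pathway == "C3" else self.subtype
            if key not in PHI_MAX_BY_SUBTYPE:
                raise ValidationError(f"no default phi_max for subtype {key!r}")
            object.__setattr__(self, "phi_max", PHI_MAX_BY_SUBTYPE[key])
        for v in (self.l_abs_red, self.l_abs_blue):
            if not 0 < v <= 1:
                raise ValidationError("absorptance must be in (0, 1]")


# ---------------------------------------------------------------------------
# unit normalisation

def normalize_pressure(p) -> np.ndarray:
    """Return pressure in Pa; values below the kPa threshold are scaled."""
    p = np.asarray(p, dtype=float)
    return np.where(np.abs(p) < PRESSURE_KPA_THRESHOLD, p * 1e3, p)


def normalize_temperature(t) -> np.ndarray:
    """Return temperature in K; values below the C threshold are shifted."""
    t = np.asarray(t, dtype=float)
    return np.where(t < TEMPERATURE_C_THRESHOLD, t + 273.15, t)


# ---------------------------------------------------------------------------
# readers / writers

def _read_delimited(path) -> tuple[pd.DataFrame, dict]:
    """Read a comma/tab file, returning the frame and `# key: value` metadata."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    meta: dict[str, str] = {}
    lines = path.read_text().splitlines()
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        body_start += 1
        stripped = line.lstrip("#").strip()
        if ":" in stripped:
            k, v = stripped.split(":", 1)
            meta[k.strip()] = v.strip()
    body = "\n".join(lines[body_start:])
    if not body.strip():
        raise FormatError(f"{path}: no tabular content")
    sep = "\t" if "\t" in body.splitlines()[0] else ","
    frame = pd.read_csv(_stdio.StringIO(body), sep=sep)
    return frame, meta


def _meta_from_header(meta: dict) -> TraceMeta:
    return TraceMeta(
        species=meta.get("species", ""),
        o2=float(meta.get("o2", 0.21)),
        regime=meta.get("regime", ""),
        replicate=int(meta.get("replicate", 0)),
    )


def _apply_dialect(frame: pd.DataFrame, required: Sequence[str],
                   dialect: Mapping[str, str], path) -> pd.DataFrame:
    rename = {}
    for canonical in required:
        source = dialect.get(canonical, canonical)
        if source in frame.columns:
            rename[source] = canonical
        elif canonical in frame.columns:
            continue
        else:
            raise FormatError(
                f"{path}: missing required column {source!r} (for {canonical!r})")
    return frame.rename(columns=rename)


def read_trace(path, dialect: Mapping[str, str] | None = None,
               meta: TraceMeta | None = None) -> GasExchangeTrace:
    """Read a gas-exchange time series.

    Raises :class:`FormatError` for unresolvable columns and
    :class:`DataError` (with the offending 1-based data row) when the time
    column is not strictly increasing or a physical invariant is violated.
    """
    frame, header_meta = _read_delimited(path)
    dialect = {**DEFAULT_TRACE_DIALECT, **(dialect or {})}
    frame = _apply_dialect(frame, TRACE_COLUMNS, dialect, path)
    frame = frame[list(TRACE_COLUMNS) +
                  [c for c in ("a_dyn", "e_dyn") if c in frame.columns]]
    frame = frame.astype(float).reset_index(drop=True)

    t = frame["t_s"].to_numpy()
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise DataError(
            f"{path}: time not strictly increasing at row {bad[0] + 2}")
    for col in ("s_leaf", "p_air", "t_air", "flow"):
        if (frame[col] <= 0).any():
            row = int(frame.index[frame[col] <= 0][0]) + 1
            raise DataError(f"{path}: non-positive {col} at row {row}")

    frame["t_s"] = t - t[0]
    frame["p_air"] = normalize_pressure(frame["p_air"])
    frame["t_air"] = normalize_temperature(frame["t_air"])
    return GasExchangeTrace(frame, meta or _meta_from_header(header_meta))


def read_light_response(path, dialect: Mapping[str, str] | None = None,
                        meta: TraceMeta | None = None) -> LightResponseTable:
    """Read a steady-state light-response table.

    Verifies that PFD levels are unique and that the 800 and 100 reference
    levels (used to anchor the fluctuating-light comparison) are present.
    """
    frame, header_meta = _read_delimited(path)
    dialect = {**DEFAULT_LIGHT_RESPONSE_DIALECT, **(dialect or {})}
    frame = _apply_dialect(frame, LIGHT_RESPONSE_COLUMNS, dialect, path)
    frame = frame[list(LIGHT_RESPONSE_COLUMNS)].astype(float)

    levels = frame["pfd_in"].to_numpy()
    if len(np.unique(levels)) != len(levels):
        raise ValidationError(f"{path}: duplicated PFD level")
    for needed in (800.0, 100.0):
        if not np.isclose(levels, needed).any():
            raise ValidationError(f"{path}: required PFD level {needed:g} absent")
    return LightResponseTable(frame.reset_index(drop=True),
                              meta or _meta_from_header(header_meta))


def _meta_header(meta: TraceMeta) -> str:
    return "".join(f"# {k}: {v}\n" for k, v in meta.as_dict().items())


def write_trace(trace: GasExchangeTrace, path, sep: str = ",") -> Path:
    """Write a trace with its metadata as leading `# key: value` lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_meta_header(trace.meta))
        trace.data.to_csv(fh, sep=sep, index=False)
    return path


def write_light_response(table: LightResponseTable, path, sep: str = ",") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_meta_header(table.meta))
        table.data.to_csv(fh, sep=sep, index=False)
    return path


def write_tidy(tables: Mapping[str, pd.DataFrame], out_dir,
               sep: str = ",") -> list[Path]:
    """Write one delimited file per result table, deterministic column order.

    Empty tables produce header-only files; everything round-trips through
    :func:`pandas.read_csv`.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    paths = []
    for name, frame in tables.items():
        path = out_dir / f"{name}.csv"
        frame.to_csv(path, sep=sep, index=False)
        paths.append(path)
    return paths
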