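"""Impact-kinematics I/O, filtering, differentiation, and resampling.

A :class:`KinematicsRecord` holds one impact's 6-DOF headform kinematics in
a headform-fixed frame: three linear-acceleration channels (g) and three
angular-velocity channels (rad/s) on a uniform time grid in milliseconds.
The canonical analysis grid is 600 samples spanning 30 ms at 0.05 ms, so
that three concatenated directional curves give 1800 correlation samples.

Angular acceleration is never read from file; it is derived from the
(optionally filtered) angular velocity by finite differences so its
provenance is single-sourced.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import signal

from .errors import DataError, FormatError, ParameterError

#: canonical analysis grid: 600 samples at 0.05 ms covering [0, 30) ms
CANONICAL_N = 600
CANONICAL_DURATION_MS = 30.0
CANONICAL_DT_MS = CANONICAL_DURATION_MS / CANONICAL_N

LOCATIONS = ("XRot", "YRot", "ZRot")

DEFAULT_COORD_NOTE = (
    "Headform-fixed Cartesian frame, origin at the headform centre of "
    "gravity: X posterior->anterior, Y right->left, Z inferior->superior."
)

#: SAE channel-frequency-class presets, mapped to the -3 dB frequency (Hz)
#: of the phaseless low-pass implemented here.  Provided as a convenience
#: alternative to a literal Hz cutoff.
CFC_PRESETS_HZ = {
    "CFC60": 100.0,
    "CFC180": 300.0,
    "CFC600": 1000.0,
    "CFC1000": 1650.0,
}

#: standard gravity, used for unit conversion m/s^2 -> g
G0 = 9.80665

_COLUMNS = ("t", "ax", "ay", "az", "wx", "wy", "wz")


@dataclass
class KinematicsRecord:
    """One impact's kinematics time histories.

    Attributes
    ----------
    helmet_id : str
        Short helmet identifier (e.g. ``"HelmetA"``).
    location : str
        Impact location, one of ``XRot``, ``YRot``, ``ZRot``.
    t : ndarray, shape (n,)
        Time samples in ms, uniform step.
    lin_acc : ndarray, shape (n, 3)
        Linear acceleration in g, columns x/y/z.
    ang_vel : ndarray, shape (n, 3)
        Angular velocity in rad/s.
    ang_acc : ndarray, shape (n, 3) or None
        Angular acceleration in rad/s²; derived, absent on load.
    """

    helmet_id: str
    location: str
    t: np.ndarray
    lin_acc: np.ndarray
    ang_vel: np.ndarray
    ang_acc: np.ndarray | None = None
    coord_note: str = DEFAULT_COORD_NOTE

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.lin_acc = np.asarray(self.lin_acc, dtype=float)
        self.ang_vel = np.asarray(self.ang_vel, dtype=float)
        if self.ang_acc is not None:
            self.ang_acc = np.asarray(self.ang_acc, dtype=float)
        self.validate()

    @property
    def n(self) -> int:
        return self.t.size

    @property
    def dt_ms(self) -> float:
        return float(self.t[1] - self.t[0])

    def validate(self) -> None:
        n = self.t.size
        if n < 2:
            raise DataError("record needs at least 2 time samples")
        steps = np.diff(self.t)
        if np.any(steps <= 0):
            raise DataError("time vector must be strictly increasing")
        if np.max(np.abs(steps - steps[0])) > 1e-9:
            raise DataError("time step not uniform to within 1e-9 ms")
        for name in ("lin_acc", "ang_vel", "ang_acc"):
            arr = getattr(self, name)
            if arr is None:
                continue
            if arr.shape != (n, 3):
                raise DataError(f"{name} must have shape ({n}, 3), got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise DataError(f"non-finite values in {name}")
        if not np.all(np.isfinite(self.t)):
            raise DataError("non-finite values in t")

    def is_canonical(self) -> bool:
        grid = canonical_grid()
        return self.n == CANONICAL_N and np.array_equal(self.t, grid)

    def resultant(self, which: str) -> np.ndarray:
        """Euclidean norm over axes of one channel group ('lin_acc',
        'ang_vel' or 'ang_acc')."""
        arr = getattr(self, which)
        if arr is None:
            raise DataError(f"{which} not present on record")
        return np.linalg.norm(arr, axis=1)


def canonical_grid(n: int = CANONICAL_N,
                   duration_ms: float = CANONICAL_DURATION_MS) -> np.ndarray:
    """Time samples k * duration/n for k = 0..n-1, in ms."""
    return np.arange(n) * (duration_ms / n)


# ---------------------------------------------------------------------------
# reading / writing


def _parse_id_from_name(path: Path) -> tuple[str | None, str | None]:
    stem = path.stem
    m = re.match(r"(?P<helmet>.+?)[_\-](?P<loc>XRot|YRot|ZRot)", stem)
    if m:
        return m.group("helmet"), m.group("loc")
    return None, None


def _load_sidecar(path: Path) -> dict:
    side = path.with_suffix(path.suffix + ".meta")
    if side.exists():
        loaded = yaml.safe_load(side.read_text())
        return loaded or {}
    return {}


def read_kinematics(path: str | Path, dialect: Mapping | None = None) -> KinematicsRecord:
    """Read a delimited-text kinematics table into a validated record.

    The file must carry a header naming columns ``t ax ay az wx wy wz``;
    comma or tab delimiter is autodetected and lines starting with ``#``
    are ignored.  Units are declared in *dialect* (or a ``<file>.meta``
    sidecar): ``time_unit`` in {ms, s}, ``lin_acc_unit`` in {g, m/s2},
    ``ang_vel_unit`` in {rad/s, deg/s}.  Defaults: ms, g, rad/s.
    """
    path = Path(path)
    cfg = dict(_load_sidecar(path))
    if dialect:
        cfg.update(dialect)

    try:
        with open(path) as fh:
            first = fh.readline()
            while first.startswith("#"):
                first = fh.readline()
        sep = "\t" if first.count("\t") >= first.count(",") else ","
        df = pd.read_csv(path, sep=sep, comment="#",
                         float_precision="round_trip")
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    except Exception as exc:  # noqa: BLE001 - surface as format error
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    df.columns = [str(c).strip() for c in df.columns]
    for col in _COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing column {col}")

    data = df[list(_COLUMNS)].to_numpy(dtype=float)
    if np.isnan(data).any():
        row = int(np.argwhere(np.isnan(data).any(axis=1))[0, 0])
        raise DataError(f"NaN value at data row {row}")

    t = data[:, 0]
    if np.any(np.diff(t) <= 0):
        raise DataError("non-monotone time column")

    time_unit = cfg.get("time_unit", "ms")
    if time_unit == "s":
        t = t * 1000.0
    elif time_unit != "ms":
        raise ParameterError(f"unknown time_unit {time_unit!r}")

    lin = data[:, 1:4]
    lin_unit = cfg.get("lin_acc_unit", "g")
    if lin_unit in ("m/s2", "m/s^2"):
        lin = lin / G0
    elif lin_unit != "g":
        raise ParameterError(f"unknown lin_acc_unit {lin_unit!r}")

    ang = data[:, 4:7]
    ang_unit = cfg.get("ang_vel_unit", "rad/s")
    if ang_unit == "deg/s":
        ang = np.deg2rad(ang)
    elif ang_unit != "rad/s":
        raise ParameterError(f"unknown ang_vel_unit {ang_unit!r}")

    helmet, loc = _parse_id_from_name(path)
    helmet_id = cfg.get("helmet_id", helmet)
    location = cfg.get("location", loc)
    if helmet_id is None or location is None:
        raise FormatError(
            f"helmet_id/location not derivable from {path.name}; "
            "provide them in the dialect or a sidecar file"
        )
    if location not in LOCATIONS:
        raise DataError(f"unknown location {location!r}; expected one of {LOCATIONS}")

    return KinematicsRecord(
        helmet_id=str(helmet_id), location=str(location),
        t=t, lin_acc=lin, ang_vel=ang,
        coord_note=cfg.get("coord_note", DEFAULT_COORD_NOTE),
    )


def write_kinematics(record: KinematicsRecord, path: str | Path,
                     header_comment: str | None = None) -> None:
    """Write a record to delimited text in canonical units (ms, g, rad/s).

    Values are printed with 17 significant digits so a read round-trips
    bit-identically.
    """
    path = Path(path)
    buf = io.StringIO()
    if header_comment:
        for line in header_comment.splitlines():
            buf.write(f"# {line}\n")
    buf.write(",".join(_COLUMNS) + "\n")
    cols = np.column_stack([record.t, record.lin_acc, record.ang_vel])
    for row in cols:
        buf.write(",".join(f"{v:.17g}" for v in row) + "\n")
    path.write_text(buf.getvalue())


def write_manifest(records: Mapping[tuple[str, str], str | Path],
                   path: str | Path) -> None:
    """Write an ensemble manifest: helmet_id, location, file path (CSV)."""
    rows = [{"helmet_id": h, "location": l, "path": str(p)}
            for (h, l), p in sorted(records.items())]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_manifest(path: str | Path) -> dict[tuple[str, str], Path]:
    df = pd.read_csv(path)
    for col in ("helmet_id", "location", "path"):
        if col not in df.columns:
            raise FormatError(f"missing column {col}")
    base = Path(path).parent
    out: dict[tuple[str, str], Path] = {}
    for _, row in df.iterrows():
        key = (str(row["helmet_id"]), str(row["location"]))
        if key in out:
            raise DataError(f"duplicate manifest entry for {key}")
        p = Path(row["path"])
        out[key] = p if p.is_absolute() else base / p
    return out


# ---------------------------------------------------------------------------
# signal conditioning


def cfc_filter(series: np.ndarray, dt_ms: float, cutoff_hz: float = 1000.0) -> np.ndarray:
    """Phaseless low-pass: 2-pole Butterworth applied forward and backward.

    Four poles total; unit gain at DC; zero phase lag.  At ``cutoff_hz`` the
    two passes give an amplitude ratio of 1/2 (each pass is the -3 dB
    point).  Endpoints are handled by reflective (even) padding of at least
    four filter time constants.

    ``series`` may be 1-D or 2-D (filtered along axis 0).
    """
    series = np.asarray(series, dtype=float)
    fs = 1000.0 / dt_ms
    nyq = fs / 2.0
    if isinstance(cutoff_hz, str):
        try:
            cutoff_hz = CFC_PRESETS_HZ[cutoff_hz]
        except KeyError:
            raise ParameterError(
                f"unknown CFC preset {cutoff_hz!r}; known: {sorted(CFC_PRESETS_HZ)}")
    if not 0 < cutoff_hz < nyq:
        raise ParameterError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyq:.1f} Hz)")
    b, a = signal.butter(2, cutoff_hz, fs=fs)
    # >= 4 time constants of the analogue prototype, tau = 1/(2 pi fc)
    padlen = int(np.ceil(4.0 * fs / (2.0 * np.pi * cutoff_hz)))
    padlen = min(max(padlen, 12), series.shape[0] - 1)
    return signal.filtfilt(b, a, series, axis=0, padtype="even", padlen=padlen)


def differentiate(series: np.ndarray, dt_ms: float) -> np.ndarray:
    """Time derivative: central differences interior, one-sided at the ends.

    Output units are input units per *second* (the ms grid is converted).
    Works on 1-D series or (n, 3) multi-axis series (axis 0 is time).
    """
    series = np.asarray(series, dtype=float)
    if series.shape[0] < 3:
        raise DataError("differentiate requires at least 3 samples")
    return np.gradient(series, dt_ms / 1000.0, axis=0, edge_order=2)


def resample_to_grid(record: KinematicsRecord, n: int = CANONICAL_N,
                     duration_ms: float = CANONICAL_DURATION_MS) -> KinematicsRecord:
    """Linear interpolation of a record onto the canonical uniform grid.

    The grid is ``k * duration/n`` for ``k = 0..n-1``.  Idempotent: a record
    already on the grid is returned unchanged (bitwise-identical arrays).
    """
    grid = canonical_grid(n, duration_ms)
    if record.n == n and np.array_equal(record.t, grid):
        return record
    if record.t[0] > grid[0] + 1e-12 or record.t[-1] < grid[-1] - 1e-12:
        raise DataError(
            f"record [{record.t[0]}, {record.t[-1]}] ms does not cover the "
            f"requested grid [0, {grid[-1]}] ms")

    def interp(arr: np.ndarray) -> np.ndarray:
        return np.column_stack([np.interp(grid, record.t, arr[:, j]) for j in range(3)])

    return replace(
        record, t=grid,
        lin_acc=interp(record.lin_acc),
        ang_vel=interp(record.ang_vel),
        ang_acc=None if record.ang_acc is None else interp(record.ang_acc),
    )


def derive_angular_acceleration(record: KinematicsRecord, *,
                                filter_first: bool = True,
                                cutoff_hz: float = 1000.0) -> KinematicsRecord:
    """Return a copy with ``ang_acc`` derived from angular velocity.

    With ``filter_first`` (default) the angular velocity is low-pass
    filtered before differencing, and the filtered velocity replaces the
    stored one so all angular metrics see consistent signals.
    """
    wv = record.ang_vel
    if filter_first:
        wv = cfc_filter(wv, record.dt_ms, cutoff_hz)
    acc = differentiate(wv, record.dt_ms)
    return replace(record, ang_vel=wv, ang_acc=acc)


def prepare_record(record: KinematicsRecord, *, filter_first: bool = True,
                   cutoff_hz: float = 1000.0,
                   filter_linear: bool = True) -> KinematicsRecord:
    """Resample to the canonical grid, filter, and derive angular acceleration."""
    rec = resample_to_grid(record)
    if filter_linear:
        rec = replace(rec, lin_acc=cfc_filter(rec.lin_acc, rec.dt_ms, cutoff_hz))
    return derive_angular_acceleration(rec, filter_first=filter_first,
                                       cutoff_hz=cutoff_hz)
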