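"""Kinematic head-injury metrics: PLA, HIC, PAA, PAV, BrIC, UBrIC, DAMAGE.

All seven metrics are functionals of one impact's 6-DOF head kinematics:

* PLA — peak resultant linear acceleration, g.
* HIC — Head Injury Criterion, max over windows (t2-t1) <= 15 ms of
  (t2-t1) * [mean a over the window]^2.5, with a(t) the resultant linear
  acceleration in g and time in seconds.
* PAA / PAV — peak resultant angular acceleration (reported in krad/s²)
  and angular velocity (rad/s).
* BrIC — root-sum-square of per-axis peak angular velocities normalised
  by critical values (66.2, 59.1, 44.2) rad/s.
* UBrIC — combines per-axis peak angular velocity and acceleration,
  each normalised by its critical value; the exponent r sits outside the
  axis sum (an ``original_form`` switch restores the per-term r-norm of
  the criterion's source publication).
* DAMAGE — β times the peak displacement norm of a 3-DOF coupled
  mass–spring–damper driven by the angular-acceleration vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .errors import DataError, NumericalError, ParameterError
from .kinio import KinematicsRecord

KINEMATIC_METRICS = ("PLA", "HIC", "PAA", "PAV", "BrIC", "UBrIC", "DAMAGE")
STRAIN_METRICS = ("MPS", "MTON", "MTPN", "MTOS", "MTPS")


def _default_damage_mass() -> np.ndarray:
    return np.eye(3)


def _default_damage_stiffness() -> np.ndarray:
    # Transcribed from the DAMAGE criterion's source publication; exercised
    # only for realistic-magnitude outputs, never for closed-form checks.
    return np.array([
        [32142.0, 0.0, 1636.3],
        [0.0, 23493.0, 0.0],
        [1636.3, 0.0, 16935.0],
    ])


def _default_damage_damping() -> np.ndarray:
    return 5.9148e-3 * _default_damage_stiffness()


@dataclass
class MetricConstants:
    """Critical values and model constants for the kinematic metrics.

    Angular-velocity criticals are rad/s; UBrIC acceleration criticals are
    krad/s²; the HIC window is ms.  The DAMAGE matrices follow the
    mass-normalised convention of the criterion's source (mass identity,
    stiffness-proportional damping); β is its displacement-to-strain scale.
    """

    bric_critical: tuple[float, float, float] = (66.2, 59.1, 44.2)
    ubric_w_critical: tuple[float, float, float] = (211.0, 171.0, 115.0)
    ubric_a_critical: tuple[float, float, float] = (20.0, 10.3, 7.76)
    ubric_r: float = 2.0
    hic_window_ms: float = 15.0
    damage_beta: float = 2.9903
    damage_mass: np.ndarray = field(default_factory=_default_damage_mass)
    damage_stiffness: np.ndarray = field(default_factory=_default_damage_stiffness)
    damage_damping: np.ndarray = field(default_factory=_default_damage_damping)

    def __post_init__(self) -> None:
        self.damage_mass = np.asarray(self.damage_mass, dtype=float)
        self.damage_stiffness = np.asarray(self.damage_stiffness, dtype=float)
        self.damage_damping = np.asarray(self.damage_damping, dtype=float)


DEFAULT_CONSTANTS = MetricConstants()


class HICResult(NamedTuple):
    value: float
    t1_ms: float
    t2_ms: float


class DamageResult(NamedTuple):
    value: float
    t_ms: np.ndarray
    delta: np.ndarray  # (n, 3) displacement history


def pla(record: KinematicsRecord) -> float:
    """Peak resultant linear acceleration in g."""
    return float(np.max(record.resultant("lin_acc")))


def hic(record: KinematicsRecord,
        constants: MetricConstants = DEFAULT_CONSTANTS) -> HICResult:
    """HIC over all sample-pair windows up to the configured length.

    Trapezoidal integration of the resultant acceleration (g) against time
    in seconds; returns the maximum and its optimizing window.  An all-zero
    signal yields 0.
    """
    a = record.resultant("lin_acc")
    t = record.t / 1000.0  # s
    n = t.size
    # cumulative trapezoid -> window integral as a difference
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (a[1:] + a[:-1]) * np.diff(t))])
    dt = t[1] - t[0]
    max_lag = max(1, int(np.floor(constants.hic_window_ms / 1000.0 / dt + 1e-12)))
    max_lag = min(max_lag, n - 1)

    best, best_i, best_lag = 0.0, 0, 1
    for lag in range(1, max_lag + 1):
        width = t[lag:] - t[:-lag]
        mean_a = (cum[lag:] - cum[:-lag]) / width
        vals = width * mean_a ** 2.5
        i = int(np.argmax(vals))
        if vals[i] > best:
            best, best_i, best_lag = float(vals[i]), i, lag
    return HICResult(best, record.t[best_i], record.t[best_i + best_lag])


def pav(record: KinematicsRecord) -> float:
    """Peak resultant angular velocity, rad/s."""
    return float(np.max(record.resultant("ang_vel")))


def paa(record: KinematicsRecord) -> float:
    """Peak resultant angular acceleration, reported in krad/s²."""
    return float(np.max(record.resultant("ang_acc"))) / 1000.0


def _axis_peaks(arr: np.ndarray) -> np.ndarray:
    """Per-axis maxima of absolute value (peaks may occur at different times)."""
    return np.max(np.abs(arr), axis=0)


def bric(record: KinematicsRecord,
         constants: MetricConstants = DEFAULT_CONSTANTS) -> float:
    w = _axis_peaks(record.ang_vel)
    wc = np.asarray(constants.bric_critical)
    return float(np.sqrt(np.sum((w / wc) ** 2)))


def _ubric_terms(w_star: np.ndarray, a_star: np.ndarray) -> np.ndarray:
    """Per-axis bracket w* + (a* - w*) exp(-a*/w*), with the analytic
    w* -> 0 limit (term -> 0)."""
    terms = np.zeros_like(w_star)
    pos = w_star > 0
    terms[pos] = (w_star[pos]
                  + (a_star[pos] - w_star[pos]) * np.exp(-a_star[pos] / w_star[pos]))
    return terms


def ubric(record: KinematicsRecord,
          constants: MetricConstants = DEFAULT_CONSTANTS, *,
          original_form: bool = False) -> float:
    """UBrIC from per-axis peak angular velocity and acceleration.

    Default is the printed form {sum_i bracket_i}^r; ``original_form``
    computes {sum_i bracket_i^r}^(1/r) instead.
    """
    if record.ang_acc is None:
        raise DataError("ang_acc required for UBrIC; derive it first")
    w = _axis_peaks(record.ang_vel) / np.asarray(constants.ubric_w_critical)
    a = (_axis_peaks(record.ang_acc) / 1000.0) / np.asarray(constants.ubric_a_critical)
    terms = _ubric_terms(w, a)
    r = constants.ubric_r
    if original_form:
        return float(np.sum(terms ** r) ** (1.0 / r))
    return float(np.sum(terms) ** r)


def damage(record: KinematicsRecord,
           constants: MetricConstants = DEFAULT_CONSTANTS) -> DamageResult:
    """DAMAGE: β · max_t ||δ(t)|| for M δ̈ + C δ̇ + K δ = −M α(t).

    Integrated from rest with classical Runge–Kutta at the kinematics time
    step, the forcing linearly interpolated at half steps.  The sign of the
    forcing does not affect max ||δ||.
    """
    if record.ang_acc is None:
        raise DataError("ang_acc required for DAMAGE; derive it first")
    M = constants.damage_mass
    C = constants.damage_damping
    K = constants.damage_stiffness
    try:
        eig = np.linalg.eigvalsh(0.5 * (M + M.T))
    except np.linalg.LinAlgError as exc:
        raise ParameterError(f"invalid mass matrix: {exc}") from exc
    if np.any(eig <= 0):
        raise ParameterError("DAMAGE mass matrix must be positive definite")

    Minv = np.linalg.inv(M)
    A_cd = Minv @ C
    A_k = Minv @ K
    alpha = record.ang_acc  # rad/s^2
    t = record.t / 1000.0
    h = t[1] - t[0]
    n = t.size

    # forcing at half steps by linear interpolation
    f = -alpha
    f_mid = 0.5 * (f[:-1] + f[1:])

    def deriv(d: np.ndarray, v: np.ndarray, fk: np.ndarray):
        return v, fk - A_cd @ v - A_k @ d

    delta = np.zeros((n, 3))
    d = np.zeros(3)
    v = np.zeros(3)
    for k in range(n - 1):
        k1d, k1v = deriv(d, v, f[k])
        k2d, k2v = deriv(d + 0.5 * h * k1d, v + 0.5 * h * k1v, f_mid[k])
        k3d, k3v = deriv(d + 0.5 * h * k2d, v + 0.5 * h * k2v, f_mid[k])
        k4d, k4v = deriv(d + h * k3d, v + h * k3v, f[k + 1])
        d = d + (h / 6.0) * (k1d + 2 * k2d + 2 * k3d + k4d)
        v = v + (h / 6.0) * (k1v + 2 * k2v + 2 * k3v + k4v)
        delta[k + 1] = d

    norms = np.linalg.norm(delta, axis=1)
    # static-deflection scale: ||K^-1 M alpha_max||
    static = np.max(np.abs(f)) * np.linalg.norm(np.linalg.inv(A_k), 2)
    if not np.all(np.isfinite(norms)) or norms.max() > 1e6 * max(static, 1e-300):
        raise NumericalError(
            "DAMAGE integration unstable (norm growth > 1e6); use a smaller step")
    return DamageResult(float(constants.damage_beta * norms.max()), record.t, delta)


def compute_metrics(record: KinematicsRecord,
                    constants: MetricConstants = DEFAULT_CONSTANTS) -> dict[str, float]:
    """All seven kinematic metrics for one prepared record."""
    return {
        "PLA": pla(record),
        "HIC": hic(record, constants).value,
        "PAA": paa(record),
        "PAV": pav(record),
        "BrIC": bric(record, constants),
        "UBrIC": ubric(record, constants),
        "DAMAGE": damage(record, constants).value,
    }


def metric_table(records: Iterable[KinematicsRecord],
                 constants: MetricConstants = DEFAULT_CONSTANTS) -> pd.DataFrame:
    """One row of the seven kinematic metrics per (helmet, location).

    Records must already be prepared (canonical grid, ang_acc derived).
    Duplicate (helmet, location) keys are a data error.
    """
    rows = {}
    for rec in records:
        key = (rec.helmet_id, rec.location)
        if key in rows:
            raise DataError(f"duplicate (helmet, location) pair {key}")
        rows[key] = compute_metrics(rec, constants)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index = pd.MultiIndex.from_tuples(df.index, names=["helmet_id", "location"])
    return df.sort_index()


def location_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-location mean, SD, min, max of each metric column.

    SD is the sample standard deviation (ddof=1); a single record per
    location reports SD 0.
    """
    grouped = table.groupby(level="location")
    sd = grouped.std(ddof=1).fillna(0.0)
    out = pd.concat(
        {"mean": grouped.mean(), "sd": sd, "min": grouped.min(), "max": grouped.max()},
        names=["stat"],
    )
    return out.swaplevel().sort_index()
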