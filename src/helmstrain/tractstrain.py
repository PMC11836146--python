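"""White-matter tract-related strain from element deformation histories.

Each finite element carries a deformation-gradient history F(t) (3x3,
F(0)=I, det F > 0) and, for white-matter elements, a reference fiber unit
vector a0.  From these we compute:

* MPS  — peak largest eigenvalue of the Green–Lagrange strain
  E = (FᵀF − I)/2, over all brain elements;
* MTON — peak normal strain along the (real-time, deformed) fiber
  direction â(t) = F a0 / ||F a0||, clamped at 0 (tensile convention);
* MTPN — peak of the larger principal strain in the plane
  perpendicular to â(t);
* MTOS — peak shear strain coupling the fiber axis to its
  perpendicular plane, sqrt(E'₁₂² + E'₁₃²) in a frame with e₁ = â;
* MTPS — peak maximal shear within the perpendicular plane,
  (λ⊥max − λ⊥min)/2.

Shear components follow the tensor (half-engineering) convention; a flag
doubles them for engineering-shear reporting.  All four tract measures are
invariant to the arbitrary in-plane basis and to rigid rotations applied
to both F and a0.

Per-element time peaks go into a :class:`StrainPeakTable` (a pandas
DataFrame) and per-simulation summaries are 95th-percentile values over
the metric's eligible element set: the whole brain for MPS, white matter
only for the tract measures.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

from .errors import DataError, FormatError, NumericalError, ParameterError

#: controlled region vocabulary
REGIONS = ("brain", "white_matter", "corpus_callosum", "cerebellum_wm", "other")
#: regions whose elements carry fibers and enter tract-strain summaries
WM_REGIONS = frozenset({"white_matter", "corpus_callosum", "cerebellum_wm"})

TRACT_METRICS = ("MTON", "MTPN", "MTOS", "MTPS")
ALL_STRAIN_METRICS = ("MPS",) + TRACT_METRICS


def green_lagrange(F: np.ndarray) -> np.ndarray:
    """E = (FᵀF − I)/2 for an array of 3x3 deformation gradients.

    Accepts any leading batch shape; exactly symmetric by construction.
    """
    F = np.asarray(F, dtype=float)
    C = np.einsum("...ji,...jk->...ik", F, F)
    E = 0.5 * (C - np.eye(3))
    return 0.5 * (E + np.swapaxes(E, -1, -2))


def principal_strain(E: np.ndarray) -> np.ndarray:
    """Largest eigenvalue of each symmetric strain tensor in a batch."""
    return np.linalg.eigvalsh(E)[..., -1]


def mps_history(E_series: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-time largest principal strain and its time maximum."""
    hist = principal_strain(E_series)
    return hist, float(np.max(hist))


def realtime_fiber_direction(F: np.ndarray, a0: np.ndarray) -> np.ndarray:
    """Deformed fiber direction â = F a0 / ||F a0|| (batched)."""
    v = np.einsum("...ij,...j->...i", np.asarray(F, float), np.asarray(a0, float))
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(norm < 1e-12):
        raise NumericalError("deformed fiber has vanishing length")
    return v / norm


def _perpendicular_basis(e1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal pair spanning the plane perpendicular to e1.

    e2 ∝ e1 × c with c the canonical axis least aligned with e1;
    e3 = e1 × e2.  The tract measures are invariant to this choice.
    """
    e1 = np.asarray(e1, dtype=float)
    idx = np.argmin(np.abs(e1), axis=-1)
    c = np.eye(3)[idx]
    e2 = np.cross(e1, c)
    e2 = e2 / np.linalg.norm(e2, axis=-1, keepdims=True)
    e3 = np.cross(e1, e2)
    return e2, e3


def tract_strain_histories(F_series: np.ndarray, a0: np.ndarray, *,
                           reference_fiber: bool = False,
                           engineering_shear: bool = False) -> dict[str, np.ndarray]:
    """Four tract-strain series for one or more elements.

    ``F_series`` has shape (..., n_t, 3, 3) and ``a0`` shape (..., 3).
    Returns arrays of shape (..., n_t) under keys ``ton`` (signed normal
    strain along the fiber), ``tpn`` (larger perpendicular principal
    strain), ``tos`` (along-fiber shear), ``tps`` (perpendicular maximal
    shear).  With ``reference_fiber`` the undeformed a0 replaces â(t).
    """
    F_series = np.asarray(F_series, dtype=float)
    a0 = np.asarray(a0, dtype=float)
    if not np.allclose(np.linalg.norm(a0, axis=-1), 1.0, atol=1e-9):
        raise DataError("fiber vectors must be unit length")
    E = green_lagrange(F_series)
    if reference_fiber:
        e1 = np.broadcast_to(a0[..., None, :], E.shape[:-1]).copy()
    else:
        e1 = realtime_fiber_direction(F_series, a0[..., None, :])
    e2, e3 = _perpendicular_basis(e1)

    def quad(u, v):
        return np.einsum("...i,...ij,...j->...", u, E, v)

    e11 = quad(e1, e1)
    e22 = quad(e2, e2)
    e33 = quad(e3, e3)
    e23 = quad(e2, e3)
    e12 = quad(e1, e2)
    e13 = quad(e1, e3)

    mean = 0.5 * (e22 + e33)
    rad = np.sqrt((0.5 * (e22 - e33)) ** 2 + e23 ** 2)
    shear_scale = 2.0 if engineering_shear else 1.0
    return {
        "ton": e11,
        "tpn": mean + rad,
        "tos": shear_scale * np.sqrt(e12 ** 2 + e13 ** 2),
        "tps": shear_scale * rad,
    }


def accumulate_peaks(histories: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Time-accumulated maxima of metric histories (last axis is time).

    MTON is the positive part of the peak *signed* along-fiber strain.
    """
    out = {}
    for name, series in histories.items():
        peak = np.max(series, axis=-1)
        if name == "ton":
            peak = np.maximum(peak, 0.0)
        out[name] = peak
    return out


def percentile_summary(values: np.ndarray, q: float = 95.0,
                       mask: np.ndarray | None = None) -> float:
    """Linear-interpolation percentile of a (masked) element field."""
    values = np.asarray(values, dtype=float)
    if mask is not None:
        values = values[np.asarray(mask, bool)]
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise DataError("empty element set for percentile summary")
    return float(np.percentile(values, q, method="linear"))


def compute_peak_table(F: np.ndarray, regions: Sequence[str],
                       fibers: np.ndarray | None,
                       element_ids: Sequence[int] | None = None, *,
                       reference_fiber: bool = False,
                       engineering_shear: bool = False) -> pd.DataFrame:
    """Per-element strain peaks for one impact simulation.

    Parameters
    ----------
    F : ndarray, shape (n_elem, n_t, 3, 3)
        Deformation-gradient histories, F(0) = I.
    regions : sequence of str, length n_elem
        Region labels from the controlled vocabulary.
    fibers : ndarray, shape (n_wm, 3) or None
        Unit fiber vectors for the white-matter elements, in element order.
    element_ids : optional explicit ids (default 0..n_elem-1).

    Returns a StrainPeakTable: DataFrame indexed by element_id with columns
    region, valid, MPS, MTON, MTPN, MTOS, MTPS (tract columns NaN for
    non-WM elements).  Elements with det F <= 0 at any time are flagged
    invalid and excluded from summaries.
    """
    F = np.asarray(F, dtype=float)
    n_elem, n_t = F.shape[0], F.shape[1]
    regions = np.asarray([str(r) for r in regions])
    if regions.shape[0] != n_elem:
        raise DataError("regions length does not match number of elements")
    unknown = set(regions) - set(REGIONS)
    if unknown:
        raise DataError(f"unknown region labels {sorted(unknown)}; known: {REGIONS}")
    if element_ids is None:
        element_ids = np.arange(n_elem)
    element_ids = np.asarray(element_ids)

    valid = np.all(np.linalg.det(F) > 0, axis=1)

    E = green_lagrange(F)
    mps_peak = np.max(principal_strain(E), axis=-1)

    is_wm = np.isin(regions, list(WM_REGIONS))
    n_wm = int(is_wm.sum())
    tract = {m: np.full(n_elem, np.nan) for m in TRACT_METRICS}
    if n_wm:
        if fibers is None:
            raise DataError("fibers required for white-matter elements")
        fibers = np.asarray(fibers, dtype=float)
        if fibers.shape != (n_wm, 3):
            raise DataError(
                f"fibers shape {fibers.shape} != ({n_wm}, 3) white-matter elements")
        hist = tract_strain_histories(
            F[is_wm], fibers, reference_fiber=reference_fiber,
            engineering_shear=engineering_shear)
        peaks = accumulate_peaks(hist)
        tract["MTON"][is_wm] = peaks["ton"]
        tract["MTPN"][is_wm] = peaks["tpn"]
        tract["MTOS"][is_wm] = peaks["tos"]
        tract["MTPS"][is_wm] = peaks["tps"]

    df = pd.DataFrame({"region": regions, "valid": valid, "MPS": mps_peak, **tract},
                      index=pd.Index(element_ids, name="element_id"))
    return df


def summarize_peaks(table: pd.DataFrame, q: float = 95.0) -> dict[str, float]:
    """Per-simulation percentile summaries: MPS over all valid brain
    elements, tract metrics over valid white-matter elements."""
    valid = table["valid"].to_numpy(bool)
    out = {"MPS": percentile_summary(table["MPS"].to_numpy(), q, mask=valid)}
    wm = valid & table["region"].isin(WM_REGIONS).to_numpy()
    for m in TRACT_METRICS:
        out[m] = percentile_summary(table[m].to_numpy(), q, mask=wm)
    return out


def region_restrict(table: pd.DataFrame, region: str) -> pd.DataFrame:
    """Rows of a StrainPeakTable belonging to one region label."""
    if region not in REGIONS:
        raise ParameterError(f"unknown region {region!r}; known labels: {REGIONS}")
    return table[table["region"] == region]


def invalid_element_count(table: pd.DataFrame) -> int:
    return int((~table["valid"]).sum())


# ---------------------------------------------------------------------------
# portable array container (HDF5 layout: /time, /elements/{F,fiber,region,id})


def write_strain_container(path, time_ms: np.ndarray, F: np.ndarray,
                           regions: Sequence[str], fibers: np.ndarray | None,
                           element_ids: Sequence[int] | None = None,
                           attrs: Mapping[str, str] | None = None) -> None:
    """Write one impact's FE-like output to an HDF5 container.

    Layout: ``/time`` (ms), ``/elements/F`` (n_elem, n_t, 3, 3),
    ``/elements/region`` (labels), ``/elements/fiber`` (n_wm, 3; white-
    matter elements in element order), ``/elements/id``.
    """
    F = np.asarray(F, dtype=float)
    if element_ids is None:
        element_ids = np.arange(F.shape[0])
    with h5py.File(path, "w") as h5:
        h5.create_dataset("time", data=np.asarray(time_ms, float))
        g = h5.create_group("elements")
        g.create_dataset("F", data=F, compression="gzip", compression_opts=1)
        g.create_dataset("region",
                         data=np.asarray([str(r) for r in regions], dtype="S32"))
        if fibers is not None:
            g.create_dataset("fiber", data=np.asarray(fibers, float))
        g.create_dataset("id", data=np.asarray(element_ids, dtype=np.int64))
        for k, v in (attrs or {}).items():
            h5.attrs[k] = v


def read_strain_container(path) -> dict:
    """Read a container written by :func:`write_strain_container`."""
    with h5py.File(path, "r") as h5:
        if "time" not in h5 or "elements" not in h5:
            raise FormatError(
                f"{path}: not a strain container (missing /time or /elements)")
        g = h5["elements"]
        out = {
            "time_ms": np.asarray(h5["time"]),
            "F": np.asarray(g["F"]),
            "regions": [s.decode() for s in np.asarray(g["region"])],
            "fibers": np.asarray(g["fiber"]) if "fiber" in g else None,
            "element_ids": np.asarray(g["id"]),
            "attrs": dict(h5.attrs),
        }
    return out
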