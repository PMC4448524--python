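"""Per-frame geometric metrics.

Centers of mass, minimum-image distances, gyration radius/diameter, optimal
superposition (orientation) angles between protein copies, molecular dipole
vectors, and translational diffusion coefficients from mean-squared
displacement.

Conventions
-----------
Inter-chain center-of-mass distances use the minimum-image convention under
the cubic box; intra-chain geometry (gyration, dipoles, superposition) uses
whole-molecule coordinates, so chains must be kept whole across the periodic
boundary (the synthetic generator and the readers guarantee this).  The
orientation angle between two copies is the rotation angle of the optimal
(Kabsch) superposition after centering both on their centers of mass:
0° for identical orientations, 180° for a perfect C2-symmetric dimer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import ANG2_PER_NS_TO_M2_PER_S, ANGSTROM, AVOGADRO, E_ANGSTROM_TO_DEBYE

__all__ = [
    "PairSeries",
    "DiffusionEstimate",
    "center_of_mass",
    "pbc_displacement",
    "pbc_distance",
    "gyration_radius",
    "gyration_diameter",
    "orientation_angle",
    "dipole_moment",
    "vector_angle",
    "unwrap_series",
    "msd",
    "msd_diffusion",
    "brownian_length",
    "box_concentration",
]


@dataclass
class PairSeries:
    """Per-frame metrics for one chain pair.

    All arrays share the frame count; angles are degrees in [0, 180],
    ``dipole_angle`` is NaN when the topology carries no charges.
    """

    chain_pair: tuple[str, str]
    times: np.ndarray  # ns
    com_distance: np.ndarray  # Å
    orientation_angle: np.ndarray  # deg
    dipole_angle: np.ndarray  # deg
    n_contacts: np.ndarray  # atoms

    def __post_init__(self):
        n = len(self.times)
        for name in ("com_distance", "orientation_angle", "dipole_angle", "n_contacts"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match frame count")


@dataclass
class DiffusionEstimate:
    """Translational diffusion coefficient from an MSD fit."""

    D_trans: float  # m²/s
    fit_window: tuple[float, float]  # ns (lag-time bounds used for the fit)
    fit_quality: float  # R² of the linear fit, in [0, 1]


def center_of_mass(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Mass-weighted mean position. ``coords`` may be (n, 3) or (frames, n, 3)."""
    coords = np.asarray(coords, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if coords.shape[-2] == 0:
        raise ValueError("empty atom selection")
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    return np.einsum("...ij,i->...j", coords, masses) / masses.sum()


def pbc_displacement(a: np.ndarray, b: np.ndarray, box_edge: float) -> np.ndarray:
    """Minimum-image displacement b − a in a cubic box."""
    if box_edge <= 0:
        raise ValueError("box_edge must be positive")
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    return d - box_edge * np.round(d / box_edge)


def pbc_distance(a: np.ndarray, b: np.ndarray, box_edge: float) -> float | np.ndarray:
    """Minimum-image Euclidean distance (≤ box_edge·√3/2)."""
    return np.linalg.norm(pbc_displacement(a, b, box_edge), axis=-1)


def gyration_radius(coords: np.ndarray, masses: np.ndarray) -> float:
    """Mass-weighted radius of gyration about the center of mass."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] == 0:
        raise ValueError("empty atom selection")
    masses = np.asarray(masses, dtype=float)
    com = center_of_mass(coords, masses)
    sq = np.sum((coords - com) ** 2, axis=1)
    return float(np.sqrt(np.sum(masses * sq) / masses.sum()))


def gyration_diameter(coords: np.ndarray, masses: np.ndarray) -> float:
    """Twice the radius of gyration — the expected center-of-mass distance
    of a maximally compact dimer of identical globular proteins."""
    return 2.0 * gyration_radius(coords, masses)


def orientation_angle(
    coords_ref: np.ndarray,
    coords_other: np.ndarray,
    masses: np.ndarray | None = None,
) -> float:
    """Total rotation angle (degrees) of the optimal superposition taking one
    COM-centered copy onto the other.

    Both copies are centered on their (mass-weighted) centers of mass, the
    optimal rotation is found by Kabsch superposition, and the returned angle
    is θ = arccos((trace(R) − 1)/2) ∈ [0, 180].  180° corresponds to a perfect
    dimer of C2 symmetry.
    """
    a = np.asarray(coords_ref, dtype=float)
    b = np.asarray(coords_other, dtype=float)
    if a.shape != b.shape:
        raise ValueError("copies must have identical atom counts (1:1 correspondence)")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 atoms to define an orientation")
    w = np.ones(a.shape[0]) if masses is None else np.asarray(masses, dtype=float)
    a = a - center_of_mass(a, w)
    b = b - center_of_mass(b, w)
    # degenerate (collinear) coordinates leave the rotation under-determined
    if np.linalg.matrix_rank(a, tol=1e-8) < 2 or np.linalg.matrix_rank(b, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) coordinates")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # align_vectors warns on exact fits
        rot, _ = Rotation.align_vectors(b, a, weights=w)
    return float(np.degrees(rot.magnitude()))


def dipole_moment(coords: np.ndarray, charges: np.ndarray) -> np.ndarray:
    """Molecular dipole vector Σ qᵢ(rᵢ − r̄) in Debye (1 e·Å = 4.80320 D).

    The reference point r̄ is the coordinate centroid; for a net-neutral
    charge set the dipole is independent of it.  A net charge above 0.01 e
    triggers an origin-dependence warning; an all-zero charge set warns and
    returns the zero vector.
    """
    coords = np.asarray(coords, dtype=float)
    charges = np.asarray(charges, dtype=float)
    if coords.shape[0] == 0:
        raise ValueError("empty atom selection")
    if np.all(charges == 0):
        warnings.warn("all charges are zero; dipole is the zero vector")
        return np.zeros(3)
    net = charges.sum()
    if abs(net) > 0.01:
        warnings.warn(
            f"net charge {net:.3f} e: dipole moment depends on the reference point"
        )
    ref = coords.mean(axis=0)
    return (charges[:, None] * (coords - ref)).sum(axis=0) * E_ANGSTROM_TO_DEBYE


def vector_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two vectors in degrees, in [0, 180]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("zero vector has no direction")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def unwrap_series(points: np.ndarray, box_edge: float) -> np.ndarray:
    """Remove periodic jumps from a wrapped per-frame position series.

    Successive displacements larger than half the box edge along any axis are
    interpreted as boundary crossings; the returned series is continuous.
    """
    points = np.asarray(points, dtype=float)
    steps = np.diff(points, axis=0)
    steps -= box_edge * np.round(steps / box_edge)
    return np.concatenate([points[:1], points[:1] + np.cumsum(steps, axis=0)])


def msd(series: np.ndarray) -> np.ndarray:
    """Time-origin-averaged mean-squared displacement over all lags.

    FFT-based (autocorrelation) algorithm, O(N log N); returns MSD(τ) for
    lags 0 … N−1 in the squared units of the input.
    """
    r = np.asarray(series, dtype=float)
    n = r.shape[0]
    sq = np.sum(r**2, axis=1)
    # S2 via FFT autocorrelation per coordinate
    nfft = 1 << (2 * n - 1).bit_length()
    fts = np.fft.rfft(r, n=nfft, axis=0)
    acf = np.fft.irfft(fts * np.conj(fts), n=nfft, axis=0)[:n].sum(axis=1)
    counts = n - np.arange(n)
    s2 = acf / counts
    # S1 recursion
    sumsq = np.concatenate([[0.0], sq]).cumsum()
    s1 = np.empty(n)
    total = 2.0 * sq.sum()
    for m in range(n):
        if m > 0:
            total -= sq[m - 1] + sq[n - m]
        s1[m] = total / (n - m)
    return s1 - 2.0 * s2


def msd_diffusion(
    com_series: np.ndarray | list[np.ndarray],
    frame_times: np.ndarray,
    fit_window: tuple[float, float] | None = None,
) -> DiffusionEstimate:
    """Translational diffusion coefficient from the MSD of unwrapped
    center-of-mass series: MSD(τ) = 6 D τ, so D = slope/6.

    ``com_series`` is one (frames, 3) series or a list/stack of several
    (independent chains or replicas); their MSD curves are averaged before
    the fit, which tightens the estimate considerably — time-averaged MSD
    of a single finite walk carries O(√(τ/T)) relative noise at lag τ.
    For the same reason the default fit window uses short lags, 0.5–5% of
    the analyzed span (falling back to 1–10% when that holds fewer than 10
    lag points).  Input coordinates are Å and times ns; D is returned in
    m²/s.  A negative fitted slope is clamped to zero with a warning.
    """
    arr = np.asarray(com_series, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("com_series must be (frames, 3) or (series, frames, 3)")
    frame_times = np.asarray(frame_times, dtype=float)
    dt = np.diff(frame_times)
    if np.any(dt <= 0):
        raise ValueError("frame_times must be strictly increasing")
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("msd_diffusion requires uniform frame spacing")
    n = arr.shape[1]
    lags = np.arange(n) * dt[0]
    span = lags[-1]
    if fit_window is None:
        fit_window = (0.005 * span, 0.05 * span)
        if np.sum((lags >= fit_window[0]) & (lags <= fit_window[1]) & (lags > 0)) < 10:
            fit_window = (0.01 * span, 0.1 * span)
    lo, hi = fit_window
    sel = (lags >= lo) & (lags <= hi) & (lags > 0)
    if sel.sum() < 10:
        raise ValueError("need at least 10 lag points inside the fit window")
    curve = np.mean([msd(s) for s in arr], axis=0)
    x, y = lags[sel], curve[sel]
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
    if slope < 0:
        warnings.warn("negative MSD slope; D clamped to 0")
        slope = 0.0
    d = slope / 6.0 * ANG2_PER_NS_TO_M2_PER_S
    return DiffusionEstimate(D_trans=d, fit_window=(lo, hi), fit_quality=float(np.clip(r2, 0, 1)))


def brownian_length(D: float, t: float) -> float:
    """RMS displacement √(6 D t) of 3D Brownian motion, in Å (D in m²/s, t in s)."""
    if D < 0 or t < 0:
        raise ValueError("D and t must be non-negative")
    return float(np.sqrt(6.0 * D * t) / ANGSTROM)


def box_concentration(n_copies: int, box_edge: float) -> float:
    """Molar concentration (mM) of ``n_copies`` solutes in a cubic box."""
    if n_copies < 1 or box_edge <= 0:
        raise ValueError("need n_copies ≥ 1 and box_edge > 0")
    volume_l = (box_edge * ANGSTROM) ** 3 * 1e3  # m³ → L
    return n_copies / (AVOGADRO * volume_l) * 1e3  # M → mM
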