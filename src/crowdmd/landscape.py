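"""PCA conformational reference frames and log-probability landscapes.

A reference frame is built by principal component analysis of the covariance
matrix of Cα positions over a structural ensemble (default residue range
2–70, the well-ordered core of a ~76-residue ubiquitin-like protein,
excluding the flexible tail).  Trajectory snapshots are superposed onto the
ensemble mean and projected on the leading eigenvectors; the resulting 2D
point cloud is binned and converted to a free-energy-like landscape
−k_BT ln(N_i/N_0), zero at the most populated bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .constants import R_KCAL
from .io import Topology, Trajectory

__all__ = [
    "PCAFrame",
    "LandscapeGrid",
    "extract_ca",
    "build_pca_frame",
    "project",
    "log_prob_landscape",
    "save_pca_frame",
    "load_pca_frame",
    "DEFAULT_RESIDUE_RANGE",
]

DEFAULT_RESIDUE_RANGE = (2, 70)


@dataclass
class PCAFrame:
    """PCA reference frame over range-Cα coordinates.

    Eigenvectors are columns of a (3m × k) orthonormal matrix, eigenvalues
    (Å²) sorted descending; ``variance_fractions`` are eigenvalue/trace.
    """

    residue_range: tuple[int, int]
    mean_coords: np.ndarray  # (m, 3) Å
    eigenvectors: np.ndarray  # (3m, k), orthonormal columns
    eigenvalues: np.ndarray  # (k,), Å², non-increasing
    variance_fractions: np.ndarray  # (k,)

    @property
    def n_residues(self) -> int:
        return self.mean_coords.shape[0]


@dataclass
class LandscapeGrid:
    """Binned −k_BT ln(N_i/N_0) landscape over the first two PCs.

    ``values`` is NaN on empty bins; the minimum over occupied bins is
    exactly 0 (at every most-populated bin)."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    values: np.ndarray  # kcal/mol
    temperature: float

    def to_frame(self) -> pd.DataFrame:
        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        xx, yy = np.meshgrid(xc, yc, indexing="ij")
        return pd.DataFrame(
            {
                "pc1_bin_center": xx.ravel(),
                "pc2_bin_center": yy.ravel(),
                "count": self.counts.ravel().astype(int),
                "value_kcal_mol": self.values.ravel(),
            }
        )


def extract_ca(
    topology: Topology,
    coords: np.ndarray,
    residue_range: tuple[int, int] = DEFAULT_RESIDUE_RANGE,
    chain_id: str | None = None,
) -> np.ndarray:
    """Cα coordinates for the inclusive residue range, in residue order;
    errors name the first residue missing a Cα."""
    lo, hi = residue_range
    mask = topology.ca_mask(chain_id)
    out = []
    for res in range(lo, hi + 1):
        sel = mask & (topology.residue_indices == res)
        idx = np.flatnonzero(sel)
        if idx.size == 0:
            raise ValueError(f"residue {res} has no CA atom in the selection")
        out.append(coords[idx[0]])
    return np.array(out)


def _kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rigidly superpose ``mobile`` onto ``target`` (least-squares)."""
    mc = mobile - mobile.mean(axis=0)
    tc = target - target.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rot, _ = Rotation.align_vectors(tc, mc)
    return rot.apply(mc) + target.mean(axis=0)


def build_pca_frame(
    ensemble: list[np.ndarray],
    residue_range: tuple[int, int] = DEFAULT_RESIDUE_RANGE,
    tol: float = 1e-6,
    max_iter: int = 10,
) -> PCAFrame:
    """PCA frame from an ensemble of range-Cα coordinate sets.

    Each ensemble member is an (m, 3) Cα array for the residue range (use
    :func:`extract_ca` to pull them from structures).  All members are
    iteratively superposed onto the running mean (converged when the mean
    shifts by < ``tol`` Å, at most ``max_iter`` passes, removing input-order
    dependence), the covariance of the flattened 3m coordinates is
    eigendecomposed, and variance fractions are eigenvalue/trace.
    """
    if len(ensemble) < 2:
        raise ValueError("need at least 2 structures to build a PCA frame")
    m = ensemble[0].shape[0]
    arrs = []
    for i, a in enumerate(ensemble):
        a = np.asarray(a, dtype=float)
        if a.shape != (m, 3):
            raise ValueError(f"ensemble member {i} has shape {a.shape}, expected {(m, 3)}")
        arrs.append(a - a.mean(axis=0))
    mean = arrs[0].copy()
    for _ in range(max_iter):
        aligned = [_kabsch_superpose(a, mean) for a in arrs]
        new_mean = np.mean(aligned, axis=0)
        shift = float(np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1))))
        mean = new_mean
        arrs = aligned
        if shift < tol:
            break
    flat = np.array([a.ravel() for a in arrs])  # (n, 3m)
    centered = flat - mean.ravel()
    cov = centered.T @ centered / len(arrs)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    trace = evals.sum()
    if trace <= 1e-12:
        raise ValueError("degenerate ensemble: all structures identical")
    fractions = evals / trace
    return PCAFrame(
        residue_range=residue_range,
        mean_coords=mean,
        eigenvectors=evecs,
        eigenvalues=evals,
        variance_fractions=fractions,
    )


def project(
    frame: PCAFrame,
    snapshots: np.ndarray | list[np.ndarray],
    n_components: int = 2,
) -> np.ndarray:
    """Project snapshots on the PCA frame.

    Each snapshot (an (m, 3) range-Cα array, or a (frames, m, 3) stack) is
    rigidly superposed onto the frame mean and its centered flattened
    coordinates are dotted with the leading eigenvectors.  The projection is
    invariant to any rigid transform applied to the input.
    """
    arr = np.asarray(snapshots, dtype=float)
    single = arr.ndim == 2
    if single:
        arr = arr[None]
    m = frame.n_residues
    if arr.shape[1:] != (m, 3):
        raise ValueError(f"snapshots must be (..., {m}, 3)")
    out = np.empty((arr.shape[0], n_components))
    vecs = frame.eigenvectors[:, :n_components]
    mean_flat = frame.mean_coords.ravel()
    for i, snap in enumerate(arr):
        aligned = _kabsch_superpose(snap, frame.mean_coords)
        out[i] = (aligned.ravel() - mean_flat) @ vecs
    return out[0] if single else out


def log_prob_landscape(
    points: np.ndarray,
    bins: int = 40,
    temperature: float = 300.0,
    pad_fraction: float = 0.05,
    extent: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> LandscapeGrid:
    """Binned −k_BT ln(N_i/N_0) landscape (kcal/mol) over 2D projections.

    N_0 is the maximum bin count, so the most populated bin(s) sit exactly
    at zero; empty bins are masked (NaN).  The grid spans the data range
    padded by ``pad_fraction`` unless an explicit extent is given.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 1:
        raise ValueError("points must be a non-empty (n, 2) array")
    if extent is None:
        spans = []
        for k in range(2):
            lo, hi = pts[:, k].min(), pts[:, k].max()
            pad = (hi - lo) * pad_fraction or 0.5
            spans.append((lo - pad, hi + pad))
        extent = (spans[0], spans[1])
    counts, xe, ye = np.histogram2d(pts[:, 0], pts[:, 1], bins=bins, range=extent)
    n0 = counts.max()
    kbt = R_KCAL * temperature  # kcal/mol
    with np.errstate(divide="ignore"):
        values = np.where(counts > 0, -kbt * np.log(counts / n0), np.nan)
    return LandscapeGrid(xe, ye, counts, values, temperature)


# ---------------------------------------------------------------------------
# Plain-text serialization of PCA frames
# ---------------------------------------------------------------------------

def save_pca_frame(frame: PCAFrame, path, n_components: int | None = 10) -> None:
    """Serialize a PCAFrame to a documented plain-text file.

    The full eigenvalue spectrum is kept (so variance fractions survive the
    round trip) but only the leading ``n_components`` eigenvectors are
    stored — projections use the first two, and storing all 3m columns is
    pointless bulk.  Pass ``None`` to keep every eigenvector.
    """
    path = Path(path)
    k = frame.eigenvalues.size if n_components is None else min(
        n_components, frame.eigenvalues.size
    )
    lines = [
        "# crowdmd PCA frame v1",
        f"residue_range {frame.residue_range[0]} {frame.residue_range[1]}",
        f"n_residues {frame.n_residues}",
        f"n_components {k}",
        "mean_coords",
    ]
    for xyz in frame.mean_coords:
        lines.append(" ".join(f"{v:.8f}" for v in xyz))
    lines.append("eigenvalues")
    lines.append(" ".join(f"{v:.10e}" for v in frame.eigenvalues))
    lines.append("eigenvectors")
    for col in frame.eigenvectors.T[:k]:
        lines.append(" ".join(f"{v:.10e}" for v in col))
    path.write_text("\n".join(lines) + "\n")


def load_pca_frame(path) -> PCAFrame:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("# crowdmd PCA frame"):
        raise ValueError("not a crowdmd PCA frame file")
    rr = tuple(int(t) for t in lines[1].split()[1:3])
    m = int(lines[2].split()[1])
    k = int(lines[3].split()[1])
    idx = lines.index("mean_coords") + 1
    mean = np.array([[float(v) for v in lines[idx + i].split()] for i in range(m)])
    idx = lines.index("eigenvalues") + 1
    evals = np.array([float(v) for v in lines[idx].split()])
    idx = lines.index("eigenvectors") + 1
    evecs = np.array(
        [[float(v) for v in lines[idx + i].split()] for i in range(k)]
    ).T
    fractions = evals / evals.sum()
    return PCAFrame(rr, mean, evecs, evals[:k], fractions[:k])
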