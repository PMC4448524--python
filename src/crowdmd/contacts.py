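"""Heavy-atom intermolecular contacts and per-residue contact profiles.

A contact count between two protein copies tallies the heavy (non-hydrogen)
atoms of each copy that lie within a cutoff (default 4 Å) of any heavy atom
of the other — atoms, not atom pairs, each side counted once.  Per-residue
profiles attribute each counted atom to its residue and accumulate over
frames (and average over replicas), giving the interface fingerprint that
can be compared against reference profiles (e.g. crystallographic-dimer
contacts or NMR chemical-shift perturbations supplied as tables).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import pearsonr

from .io import Topology, Trajectory, WATER_RESNAMES

__all__ = [
    "ContactProfile",
    "contact_flags",
    "count_contacts",
    "contact_matrix",
    "residue_contact_profile",
    "average_profiles",
    "running_residue_average",
    "compare_profiles",
    "interfacial_water_count",
    "DEFAULT_CUTOFF",
]

DEFAULT_CUTOFF = 4.0  # Å, heavy-atom contact cutoff


@dataclass
class ContactProfile:
    """Per-residue contact counts for one protein (or averaged over copies).

    ``counts[i]`` is the number of times an atom of residue
    ``residue_indices[i]`` was within the contact cutoff of the partner,
    accumulated over frames; ``n_frames`` allows per-frame normalization.
    """

    residue_indices: np.ndarray  # 1-based
    counts: np.ndarray  # ≥ 0, float once replica-averaged
    chain_scope: str = "all"
    n_frames: int = 1
    residue_names: np.ndarray | None = None

    def __post_init__(self):
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.residue_indices.shape != self.counts.shape:
            raise ValueError("residue_indices and counts must align")
        if np.any(self.counts < 0):
            raise ValueError("contact counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"residue_index": self.residue_indices, "count": self.counts}
        )
        if self.residue_names is not None:
            df.insert(1, "residue_name", self.residue_names)
        df["per_frame"] = self.counts / max(self.n_frames, 1)
        return df


def _minimum_image(coords: np.ndarray, box_edge: float | None) -> np.ndarray:
    if box_edge is None:
        return coords
    return np.mod(coords, box_edge)


def contact_flags(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
    box_edge: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks over the two coordinate sets marking atoms within
    ``cutoff`` of any atom of the other set (minimum image when a box is
    given)."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("both selections need at least one atom")
    if box_edge is not None:
        a = _minimum_image(a, box_edge)
        b = _minimum_image(b, box_edge)
        tree_a = cKDTree(a, boxsize=box_edge)
        tree_b = cKDTree(b, boxsize=box_edge)
    else:
        tree_a = cKDTree(a)
        tree_b = cKDTree(b)
    flags_a = np.array([len(nb) > 0 for nb in tree_b.query_ball_point(a, cutoff)])
    flags_b = np.array([len(nb) > 0 for nb in tree_a.query_ball_point(b, cutoff)])
    return flags_a, flags_b


def count_contacts(
    topology: Topology,
    coords: np.ndarray,
    chain_a: str,
    chain_b: str,
    cutoff: float = DEFAULT_CUTOFF,
    box_edge: float | None = None,
    count_pairs: bool = False,
) -> int:
    """Heavy-atom contact count between two chains for one frame.

    Default convention counts *atoms* on both sides (an atom of A within
    ``cutoff`` of any heavy atom of B contributes 1, and symmetrically);
    ``count_pairs=True`` switches to counting atom pairs for sensitivity
    checks.
    """
    mask_a = topology.chain_mask(chain_a) & topology.heavy
    mask_b = topology.chain_mask(chain_b) & topology.heavy
    if not mask_a.any() or not mask_b.any():
        raise ValueError("both chains need at least one heavy atom")
    a, b = coords[mask_a], coords[mask_b]
    if count_pairs:
        if box_edge is not None:
            ta = cKDTree(_minimum_image(a, box_edge), boxsize=box_edge)
            tb = cKDTree(_minimum_image(b, box_edge), boxsize=box_edge)
        else:
            ta, tb = cKDTree(a), cKDTree(b)
        return int(ta.count_neighbors(tb, cutoff))
    fa, fb = contact_flags(a, b, cutoff, box_edge)
    return int(fa.sum() + fb.sum())


def contact_matrix(
    topology: Topology,
    coords: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
    box_edge: float | None = None,
) -> np.ndarray:
    """Symmetric chains × chains matrix of heavy-atom contact counts."""
    chains = topology.chains
    n = len(chains)
    mat = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            c = count_contacts(topology, coords, chains[i], chains[j], cutoff, box_edge)
            mat[i, j] = mat[j, i] = c
    return mat


def residue_contact_profile(
    trajectory: Trajectory,
    chain_pairs: list[tuple[str, str]] | None = None,
    cutoff: float = DEFAULT_CUTOFF,
) -> ContactProfile:
    """Number of times each residue is involved in a contact, accumulated
    over frames and chain pairs.

    Every residue owning a counted atom increments by the number of its
    counted atoms, so the profile total over residues equals the summed
    contact counts.  All chains are assumed to be copies of the same protein
    (identical residue numbering); the profile is reported on that shared
    numbering with scope "all".
    """
    top = trajectory.topology
    if chain_pairs is None:
        chains = top.chains
        chain_pairs = [
            (chains[i], chains[j])
            for i in range(len(chains))
            for j in range(i + 1, len(chains))
        ]
    for pair in chain_pairs:
        for c in pair:
            if c not in top.chains:
                raise KeyError(f"unknown chain id {c!r}")
    residues = np.unique(top.residue_indices[top.heavy])
    res_pos = {r: i for i, r in enumerate(residues)}
    counts = np.zeros(len(residues))
    names = np.empty(len(residues), dtype=object)
    for r in residues:
        names[res_pos[r]] = top.residue_names[top.residue_indices == r][0]
    for f in range(trajectory.n_frames):
        coords = trajectory.coords[f]
        for ca, cb in chain_pairs:
            mask_a = top.chain_mask(ca) & top.heavy
            mask_b = top.chain_mask(cb) & top.heavy
            fa, fb = contact_flags(
                coords[mask_a], coords[mask_b], cutoff, trajectory.box_edge
            )
            for mask, flags in ((mask_a, fa), (mask_b, fb)):
                for r in top.residue_indices[mask][flags]:
                    counts[res_pos[r]] += 1
    return ContactProfile(
        residues, counts, "all", trajectory.n_frames, residue_names=names
    )


def average_profiles(profiles: list[ContactProfile]) -> ContactProfile:
    """Average replica profiles (e.g. across independent simulations)."""
    if not profiles:
        raise ValueError("no profiles to average")
    ref = profiles[0]
    for p in profiles[1:]:
        if not np.array_equal(p.residue_indices, ref.residue_indices):
            raise ValueError("profiles cover different residue sets")
    counts = np.mean([p.counts for p in profiles], axis=0)
    return ContactProfile(
        ref.residue_indices.copy(),
        counts,
        ref.chain_scope,
        ref.n_frames,
        residue_names=ref.residue_names,
    )


def running_residue_average(profile: ContactProfile, window: int = 5) -> ContactProfile:
    """Centered moving mean over the residue axis (window truncated at the
    termini), the smoothing used for interface-profile overlays."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    smoothed = (
        pd.Series(profile.counts)
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return ContactProfile(
        profile.residue_indices.copy(),
        smoothed,
        profile.chain_scope,
        profile.n_frames,
        residue_names=profile.residue_names,
    )


def compare_profiles(
    profile_md: ContactProfile, profile_ref: ContactProfile
) -> dict[str, float]:
    """Pearson correlation and peak overlap between two residue profiles.

    ``peak_overlap`` is the Jaccard index of the residue sets above each
    profile's own 75th percentile.  A zero-variance profile makes the
    correlation undefined (NaN, flagged by ``r_defined``).
    """
    a, b = profile_md.counts, profile_ref.counts
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("zero-variance profile: Pearson correlation undefined")
        r = float("nan")
    else:
        r = float(pearsonr(a, b).statistic)
    peaks_a = set(profile_md.residue_indices[a > np.percentile(a, 75)])
    peaks_b = set(profile_ref.residue_indices[b > np.percentile(b, 75)])
    union = peaks_a | peaks_b
    overlap = len(peaks_a & peaks_b) / len(union) if union else 0.0
    return {"pearson_r": r, "peak_overlap": overlap, "r_defined": float(not np.isnan(r))}


def interfacial_water_count(
    topology: Topology,
    coords: np.ndarray,
    chain_a: str,
    chain_b: str,
    cutoff: float = DEFAULT_CUTOFF,
    water_resnames=WATER_RESNAMES,
    box_edge: float | None = None,
) -> int:
    """Water oxygens bridging the two chains: within ``cutoff`` of a heavy
    atom of A *and* of a heavy atom of B.  Returns 0 (with a warning) when
    the topology holds no waters."""
    oxygen = np.array(
        [str(n).upper().startswith("O") for n in topology.atom_names]
    )
    wmask = topology.water_mask(water_resnames) & oxygen
    if not wmask.any():
        warnings.warn("no water molecules in topology")
        return 0
    mask_a = topology.chain_mask(chain_a) & topology.heavy & ~topology.water_mask(water_resnames)
    mask_b = topology.chain_mask(chain_b) & topology.heavy & ~topology.water_mask(water_resnames)
    waters = coords[wmask]
    if box_edge is not None:
        ta = cKDTree(_minimum_image(coords[mask_a], box_edge), boxsize=box_edge)
        tb = cKDTree(_minimum_image(coords[mask_b], box_edge), boxsize=box_edge)
        waters = _minimum_image(waters, box_edge)
    else:
        ta = cKDTree(coords[mask_a])
        tb = cKDTree(coords[mask_b])
    near_a = np.array([len(nb) > 0 for nb in ta.query_ball_point(waters, cutoff)])
    near_b = np.array([len(nb) > 0 for nb in tb.query_ball_point(waters, cutoff)])
    return int(np.sum(near_a & near_b))
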