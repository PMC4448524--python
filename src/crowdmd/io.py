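"""Structure / trajectory / table I/O and the internal data model.

The data model is deliberately small: a :class:`Topology` is an ordered list
of :class:`Atom` records (chains → residues → atoms), and a
:class:`Trajectory` is a ``frames × atoms × 3`` coordinate array in Å over a
fixed topology, optionally inside a periodic cubic box.

Multi-model PDB is the one mandatory trajectory dialect (MODEL/ENDMDL blocks
become frames); charges enter only through PQR files or the synthetic
generator — plain PDB yields zero charges.  Coordinates keep PDB conventions:
1-based residue indices, Å units, no implicit wrapping on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import ATOMIC_MASSES, DEFAULT_MASS

__all__ = [
    "Atom",
    "Topology",
    "Trajectory",
    "ParseError",
    "IntegrityError",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "write_table",
    "read_table",
    "DEFAULT_FRAME_DT_NS",
]

#: Default frame spacing (ns) assumed when a trajectory file carries no times.
DEFAULT_FRAME_DT_NS = 0.1

WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3", "TIP", "SOL"})


class ParseError(ValueError):
    """A record that does not parse under the named standard."""


class IntegrityError(ValueError):
    """Structurally valid input that violates a data-model invariant."""


def _element_from_name(atom_name: str) -> str:
    """Best-effort element from an atom name (first alphabetic character,
    honouring two-letter elements written flush-left like 'NA', 'CL')."""
    stripped = atom_name.strip()
    alpha = "".join(c for c in stripped if c.isalpha())
    if not alpha:
        return "X"
    two = alpha[:2].upper()
    if two in ("NA", "CL", "FE", "ZN", "MG") and len(stripped) <= 2:
        return two
    return alpha[0].upper()


@dataclass(frozen=True)
class Atom:
    """One atom record; ``(chain_id, residue_index, atom_name)`` is the
    unique key within a topology."""

    chain_id: str
    residue_index: int  # 1-based, PDB numbering preserved verbatim
    residue_name: str
    atom_name: str
    element: str
    mass: float
    charge: float = 0.0

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


class Topology:
    """Ordered atom list plus cached per-atom numpy views.

    Atom order is stable and identical across every frame of any trajectory
    built on the topology.
    """

    def __init__(self, atoms: Sequence[Atom]):
        if not atoms:
            raise IntegrityError("topology must contain at least one atom")
        self.atoms: tuple[Atom, ...] = tuple(atoms)
        seen: set[tuple[str, int, str]] = set()
        for a in self.atoms:
            key = (a.chain_id, a.residue_index, a.atom_name)
            if key in seen:
                raise IntegrityError(f"duplicate atom key {key}")
            seen.add(key)
        # first-appearance chain order
        chains: list[str] = []
        for a in self.atoms:
            if a.chain_id not in chains:
                chains.append(a.chain_id)
        self.chains: tuple[str, ...] = tuple(chains)
        self._chain_ids = np.array([a.chain_id for a in self.atoms])
        self.masses = np.array([a.mass for a in self.atoms], dtype=float)
        self.charges = np.array([a.charge for a in self.atoms], dtype=float)
        self.heavy = np.array([a.is_heavy for a in self.atoms], dtype=bool)
        self.residue_indices = np.array(
            [a.residue_index for a in self.atoms], dtype=int
        )
        self.residue_names = np.array([a.residue_name for a in self.atoms])
        self.atom_names = np.array([a.atom_name for a in self.atoms])

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def chain_mask(self, chain_id: str) -> np.ndarray:
        if chain_id not in self.chains:
            raise KeyError(f"unknown chain id {chain_id!r}")
        return self._chain_ids == chain_id

    def ca_mask(self, chain_id: str | None = None) -> np.ndarray:
        mask = self.atom_names == "CA"
        if chain_id is not None:
            mask &= self.chain_mask(chain_id)
        return mask

    def water_mask(self, resnames: Iterable[str] = WATER_RESNAMES) -> np.ndarray:
        return np.isin(self.residue_names, list(resnames))

    def with_charges(self, charges: np.ndarray) -> "Topology":
        charges = np.asarray(charges, dtype=float)
        if charges.shape != (self.n_atoms,):
            raise IntegrityError("charge array length does not match atom count")
        return Topology(
            [
                Atom(a.chain_id, a.residue_index, a.residue_name, a.atom_name,
                     a.element, a.mass, q)
                for a, q in zip(self.atoms, charges)
            ]
        )


@dataclass
class Trajectory:
    """Frames × atoms × 3 coordinates (Å) over a fixed topology."""

    topology: Topology
    coords: np.ndarray  # (n_frames, n_atoms, 3), Å
    frame_times: np.ndarray  # ns, strictly increasing
    box_edge: float | None = None  # cubic box edge, Å

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise IntegrityError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise IntegrityError(
                f"coordinate rows per frame ({self.coords.shape[1]}) do not "
                f"match topology atom count ({self.topology.n_atoms})"
            )
        if not np.all(np.isfinite(self.coords)):
            raise IntegrityError("coordinates contain non-finite values")
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frame_times.shape != (self.coords.shape[0],):
            raise IntegrityError("frame_times length does not match frame count")
        if self.n_frames > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise IntegrityError("frame_times must be strictly increasing")
        if self.box_edge is not None and self.box_edge <= 0:
            raise IntegrityError("box_edge must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]


# ---------------------------------------------------------------------------
# PDB / PQR parsing
# ---------------------------------------------------------------------------

def _parse_pdb_atom_line(line: str, lineno: int) -> tuple[Atom, np.ndarray]:
    if len(line.rstrip("\n")) < 54:
        raise ParseError(f"line {lineno}: ATOM record shorter than 54 columns")
    try:
        atom_name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip() or "A"
        resid = int(line[22:26])
        xyz = np.array(
            [float(line[30:38]), float(line[38:46]), float(line[46:54])]
        )
    except ValueError as exc:
        raise ParseError(f"line {lineno}: malformed ATOM record ({exc})") from exc
    element = line[76:78].strip().upper() if len(line) >= 78 else ""
    if not element:
        element = _element_from_name(atom_name)
    mass = ATOMIC_MASSES.get(element, DEFAULT_MASS)
    return Atom(chain, resid, resname, atom_name, element, mass, 0.0), xyz


def _parse_pqr_atom_line(line: str, lineno: int) -> tuple[Atom, np.ndarray]:
    tokens = line.split()
    # ATOM serial name resname [chain] resid x y z charge radius
    if len(tokens) == 11:
        _, _, name, resname, chain, resid_s = tokens[:6]
        rest = tokens[6:]
    elif len(tokens) == 10:
        _, _, name, resname, resid_s = tokens[:5]
        chain = "A"
        rest = tokens[5:]
    else:
        raise ParseError(
            f"line {lineno}: PQR ATOM record has {len(tokens)} fields, "
            "expected 10 or 11"
        )
    try:
        resid = int(resid_s)
        x, y, z, charge, _radius = (float(t) for t in rest)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: malformed PQR record ({exc})") from exc
    element = _element_from_name(name)
    mass = ATOMIC_MASSES.get(element, DEFAULT_MASS)
    return Atom(chain, resid, resname, name, element, mass, charge), np.array(
        [x, y, z]
    )


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = path.suffix.lower().lstrip(".")
    return suffix if suffix in ("pdb", "pqr") else "pdb"


def read_structure(path, fmt: str | None = None) -> tuple[Topology, np.ndarray]:
    """Read a single-snapshot PDB or PQR file.

    Returns ``(topology, coords)``; charges are populated only for PQR
    (plain PDB atoms carry zero charge).  If the file has several MODEL
    blocks only the first is returned.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    parse = _parse_pqr_atom_line if fmt == "pqr" else _parse_pdb_atom_line
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM"):
                atom, xyz = parse(line, lineno)
                atoms.append(atom)
                coords.append(xyz)
            elif rec == "ENDMDL":
                break
    if not atoms:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    return Topology(atoms), np.array(coords)


def read_trajectory(
    path,
    topology: Topology | None = None,
    frame_dt: float = DEFAULT_FRAME_DT_NS,
    box_edge: float | None = None,
) -> Trajectory:
    """Read a multi-model PDB as a trajectory.

    MODEL/ENDMDL blocks become frames in file order; a file without MODEL
    records yields one frame.  Frame times are ``frame_dt``-spaced (the file
    format carries none).  ``box_edge`` falls back to the CRYST1 record.
    """
    path = Path(path)
    frames: list[np.ndarray] = []
    current: list[np.ndarray] = []
    atoms: list[Atom] = []
    first_frame = True
    cryst_edge: float | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "CRYST1":
                try:
                    a, b, c = float(line[6:15]), float(line[15:24]), float(line[24:33])
                    if abs(a - b) < 1e-6 and abs(a - c) < 1e-6:
                        cryst_edge = a
                except ValueError:
                    pass
            elif rec in ("ATOM", "HETATM"):
                atom, xyz = _parse_pdb_atom_line(line, lineno)
                if first_frame:
                    atoms.append(atom)
                current.append(xyz)
            elif rec in ("ENDMDL", "END"):
                if current:
                    frames.append(np.array(current))
                    current = []
                    first_frame = False
    if current:
        frames.append(np.array(current))
    if not frames:
        raise ParseError(f"{path}: no coordinate records found")
    top = topology if topology is not None else Topology(atoms)
    for i, fr in enumerate(frames):
        if fr.shape[0] != top.n_atoms:
            raise IntegrityError(
                f"frame {i}: {fr.shape[0]} atoms, topology has {top.n_atoms}"
            )
    times = np.arange(len(frames)) * frame_dt
    return Trajectory(
        top,
        np.stack(frames),
        times,
        box_edge if box_edge is not None else cryst_edge,
    )


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _pdb_atom_line(i: int, a: Atom, xyz: np.ndarray) -> str:
    name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name:<3s}"
    return (
        f"ATOM  {min(i, 99999):5d} {name:<4.4s} {a.residue_name:<3.3s} "
        f"{a.chain_id[:1]}{a.residue_index:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {a.element:>2.2s}"
    )


def write_structure(topology: Topology, coords: np.ndarray, path, fmt=None) -> None:
    """Write a single snapshot as PDB or PQR (PQR keeps the charges)."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    coords = np.asarray(coords, dtype=float)
    lines: list[str] = []
    for i, (a, xyz) in enumerate(zip(topology.atoms, coords), start=1):
        if fmt == "pqr":
            lines.append(
                f"ATOM  {i:5d} {a.atom_name:<4s} {a.residue_name:<3s} "
                f"{a.chain_id[:1]} {a.residue_index:4d} "
                f"{xyz[0]:10.4f} {xyz[1]:10.4f} {xyz[2]:10.4f} "
                f"{a.charge:8.4f} {1.5:7.4f}"
            )
        else:
            lines.append(_pdb_atom_line(i, a, xyz))
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as multi-model PDB (one MODEL block per frame)."""
    path = Path(path)
    lines: list[str] = []
    if traj.box_edge is not None:
        e = traj.box_edge
        lines.append(
            f"CRYST1{e:9.3f}{e:9.3f}{e:9.3f}  90.00  90.00  90.00 P 1           1"
        )
    for f in range(traj.n_frames):
        lines.append(f"MODEL     {f + 1:4d}")
        for i, a in enumerate(traj.topology.atoms):
            lines.append(_pdb_atom_line(i + 1, a, traj.coords[f, i]))
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def write_table(records, path, float_format: str = "%.6g") -> None:
    """Write tabular records as CSV (header row, '.' decimal).

    ``records`` is a DataFrame or an iterable of uniform dicts; an empty
    record set is an error, never an empty file.  Output is bit-stable for
    identical inputs.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(list(records))
    if df.empty:
        raise ValueError("refusing to write an empty table")
    df.to_csv(path, index=False, float_format=float_format)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
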