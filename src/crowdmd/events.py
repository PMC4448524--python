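"""Binding/dissociation event detection and oligomer-state classification.

A pair of protein copies is called *bound* when its heavy-atom contact count
stays at or above a threshold (default 10 atoms) for a minimum persistence
time (default 5 ns) — bound dimers show contact plateaus of order 10² atoms,
so the threshold is conservative.  Binding *completes* when the
center-of-mass distance closes to within 10% of the configured gyration
diameter (a maximally compact dimer) or when the contact count plateaus.

Per-frame oligomeric state comes from the inter-chain contact graph: chains
are nodes, pairs with at least ``threshold`` contact atoms are edges, and
connected components are labelled monomer / dimer / linear-trimer (3 chains,
2 edges — a chain in the middle) / compact-trimer (3 chains, all 3 edges) /
n-mer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .geometry import PairSeries

__all__ = [
    "Event",
    "OligomerState",
    "detect_events",
    "classify_frame",
    "state_timeline",
    "DEFAULT_C_ON",
    "DEFAULT_C_OFF",
    "DEFAULT_PERSISTENCE_NS",
]

DEFAULT_C_ON = 10  # contact atoms that define "bound"
DEFAULT_C_OFF = 0  # contact atoms that define "unbound"
DEFAULT_PERSISTENCE_NS = 5.0


@dataclass(frozen=True)
class Event:
    kind: str  # "bind" | "unbind"
    chain_pair: tuple[str, str]
    onset_time: float  # ns
    completion_time: float  # ns, ≥ onset_time
    peak_contacts: int


@dataclass(frozen=True)
class OligomerState:
    """Partition of the chains into contact-graph connected components."""

    frame_index: int
    components: tuple[frozenset, ...]
    labels: tuple[str, ...]  # one per component

    @property
    def summary(self) -> str:
        """Order-independent label of the whole frame, e.g. 'dimer+monomer'."""
        return "+".join(sorted(self.labels))


def _sustained_run_start(flags: np.ndarray, min_len: int, start: int) -> int | None:
    """First index ≥ start opening a True run of at least ``min_len`` frames."""
    i = start
    n = len(flags)
    while i < n:
        if flags[i]:
            j = i
            while j < n and flags[j]:
                j += 1
            if j - i >= min_len:
                return i
            i = j
        else:
            i += 1
    return None


def detect_events(
    series: PairSeries,
    c_on: int = DEFAULT_C_ON,
    c_off: int = DEFAULT_C_OFF,
    persistence_ns: float = DEFAULT_PERSISTENCE_NS,
    gyration_diameter: float = 23.4,
    plateau_tol: float = 0.05,
) -> list[Event]:
    """Detect alternating bind/unbind events in a pair's contact series.

    Bind onset is the first frame of a run with ``n_contacts ≥ c_on``
    sustained for at least ``persistence_ns``; completion is the first
    subsequent frame where the COM distance is within 10% of
    ``gyration_diameter`` or where the rolling-mean contact count changes by
    less than ``plateau_tol`` over a persistence window.  Unbinding requires
    ``n_contacts ≤ c_off`` sustained for the same persistence.
    """
    times = np.asarray(series.times, dtype=float)
    if times.size < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("series needs ≥ 2 frames with monotone times")
    dt = float(np.median(np.diff(times)))
    k = max(1, int(round(persistence_ns / dt)))
    if k > times.size:
        raise ValueError("persistence window longer than the trajectory")
    contacts = np.asarray(series.n_contacts, dtype=float)
    dist = np.asarray(series.com_distance, dtype=float)

    events: list[Event] = []
    i = 0
    bound = False
    bind_onset_idx = 0
    while i < times.size:
        if not bound:
            onset = _sustained_run_start(contacts >= c_on, k, i)
            if onset is None:
                break
            completion = _find_completion(
                contacts, dist, onset, k, gyration_diameter, plateau_tol
            )
            # peak over the bound stretch (until unbind or end; filled later)
            bind_onset_idx = onset
            events.append(
                Event(
                    "bind",
                    series.chain_pair,
                    float(times[onset]),
                    float(times[completion]),
                    0,
                )
            )
            bound = True
            i = onset + 1
        else:
            off = _sustained_run_start(contacts <= c_off, k, i)
            end = off if off is not None else times.size
            peak = int(contacts[bind_onset_idx:end].max())
            events[-1] = Event(
                events[-1].kind,
                events[-1].chain_pair,
                events[-1].onset_time,
                events[-1].completion_time,
                peak,
            )
            if off is None:
                break
            events.append(
                Event(
                    "unbind",
                    series.chain_pair,
                    float(times[off]),
                    float(times[off]),
                    peak,
                )
            )
            bound = False
            i = off + 1
    return events


def _find_completion(
    contacts: np.ndarray,
    dist: np.ndarray,
    onset: int,
    k: int,
    gyration_diameter: float,
    plateau_tol: float,
) -> int:
    n = contacts.size
    rolling = pd.Series(contacts).rolling(k, min_periods=1).mean().to_numpy()
    for j in range(onset, n):
        if dist[j] <= 1.1 * gyration_diameter:
            return j
        if j >= onset + k:
            prev, cur = rolling[j - k], rolling[j]
            if prev > 0 and abs(cur - prev) / prev < plateau_tol:
                return j
    return n - 1


def classify_frame(
    contact_matrix: np.ndarray,
    chain_ids: tuple[str, ...] | None = None,
    threshold: int = 1,
    frame_index: int = 0,
) -> OligomerState:
    """Oligomer state of one frame from the chains × chains contact matrix."""
    mat = np.asarray(contact_matrix)
    n = mat.shape[0]
    if mat.shape != (n, n):
        raise ValueError("contact matrix must be square")
    if not np.array_equal(mat, mat.T):
        raise ValueError("contact matrix must be symmetric")
    if np.any(np.diag(mat) != 0):
        raise ValueError("contact matrix must have zero diagonal")
    ids = chain_ids if chain_ids is not None else tuple(str(i) for i in range(n))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if mat[i, j] >= threshold:
                g.add_edge(i, j)
    comps, labels = [], []
    for comp in sorted(nx.connected_components(g), key=lambda c: sorted(c)):
        size = len(comp)
        edges = g.subgraph(comp).number_of_edges()
        if size == 1:
            label = "monomer"
        elif size == 2:
            label = "dimer"
        elif size == 3:
            label = "linear-trimer" if edges == 2 else "compact-trimer"
        else:
            label = f"{size}-mer"
        comps.append(frozenset(ids[i] for i in comp))
        labels.append(label)
    return OligomerState(frame_index, tuple(comps), tuple(labels))


def state_timeline(
    contact_matrices: list[np.ndarray] | np.ndarray,
    chain_ids: tuple[str, ...] | None = None,
    threshold: int = 1,
) -> tuple[list[OligomerState], pd.DataFrame]:
    """Per-frame oligomer states and the matrix counting transitions between
    frame-summary labels (rows: from, columns: to)."""
    states = [
        classify_frame(m, chain_ids, threshold, frame_index=f)
        for f, m in enumerate(contact_matrices)
    ]
    labels = [s.summary for s in states]
    uniq = sorted(set(labels))
    trans = pd.DataFrame(0, index=uniq, columns=uniq, dtype=int)
    for a, b in zip(labels[:-1], labels[1:]):
        if a != b:
            trans.loc[a, b] += 1
    return states, trans
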