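"""End-to-end analysis and simulation drivers with reproducible outputs.

`run_simulate` writes a synthetic trajectory (multi-model PDB + PQR charges
+ JSON ground-truth sidecar); `run_analyze` reads a topology and trajectory
and emits per-pair metric CSVs, residue contact profiles, the event table,
the oligomer-state timeline, per-chain diffusion estimates and a JSON
summary.  Every run directory gets a manifest (config hash, seed, package
version) and a run log; identical config + inputs give byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import contacts as contacts_mod
from . import events as events_mod
from . import geometry as geom
from . import landscape as landscape_mod
from .io import (
    DEFAULT_FRAME_DT_NS,
    Topology,
    Trajectory,
    read_structure,
    read_trajectory,
    write_structure,
    write_table,
    write_trajectory,
)
from .synthetic import BindingScript, SyntheticSpec, generate

log = logging.getLogger("crowdmd")

__all__ = ["RunConfig", "run_simulate", "run_analyze", "compute_pair_series"]


@dataclass
class RunConfig:
    """Configuration shared by the pipeline stages; every default is
    overridable from a YAML config file or CLI flags (flags win)."""

    trajectory: str | None = None
    topology: str | None = None
    charges: str | None = None  # PQR supplying partial charges
    box_edge: float | None = None
    frame_dt: float = DEFAULT_FRAME_DT_NS
    contact_cutoff: float = contacts_mod.DEFAULT_CUTOFF
    c_on: int = events_mod.DEFAULT_C_ON
    c_off: int = events_mod.DEFAULT_C_OFF
    persistence_ns: float = events_mod.DEFAULT_PERSISTENCE_NS
    residue_range: tuple[int, int] = landscape_mod.DEFAULT_RESIDUE_RANGE
    temperature: float = 300.0
    dielectric: float = 78.0
    pca_frame: str | None = None  # serialized PCAFrame to project on
    out_dir: str = "crowdmd_out"
    seed: int = 0
    simulate: dict = field(default_factory=dict)  # SyntheticSpec overrides

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        if isinstance(cfg.residue_range, list):
            cfg.residue_range = tuple(cfg.residue_range)
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _setup_run_dir(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(asdict(config), sort_keys=True))
    for h in list(log.handlers):
        if isinstance(h, logging.FileHandler):
            log.removeHandler(h)
            h.close()
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    return out


def _write_manifest(out: Path, config: RunConfig, outputs: list[str]) -> None:
    manifest = {
        "package": "crowdmd",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "outputs": sorted(outputs),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def compute_pair_series(
    traj: Trajectory, cutoff: float | None = None
) -> dict[tuple[str, str], geom.PairSeries]:
    """Per-frame COM distance, orientation angle, dipole angle and contact
    count for every chain pair.

    Dipole angles are NaN (with one warning) when the topology carries no
    charges — dipoles need force-field or PQR charges.
    """
    top = traj.topology
    cutoff = contacts_mod.DEFAULT_CUTOFF if cutoff is None else cutoff
    chains = top.chains
    pairs = [
        (chains[i], chains[j])
        for i in range(len(chains))
        for j in range(i + 1, len(chains))
    ]
    have_charges = bool(np.any(top.charges != 0))
    if not have_charges:
        warnings.warn("topology has no partial charges; dipole angles will be NaN")
    masks = {c: top.chain_mask(c) for c in chains}
    heavy_masks = {c: masks[c] & top.heavy for c in chains}
    out: dict[tuple[str, str], geom.PairSeries] = {}
    for ca, cb in pairs:
        n = traj.n_frames
        dist = np.empty(n)
        ori = np.empty(n)
        dip = np.full(n, np.nan)
        ncon = np.zeros(n, dtype=int)
        for f in range(n):
            xyz = traj.coords[f]
            com_a = geom.center_of_mass(xyz[masks[ca]], top.masses[masks[ca]])
            com_b = geom.center_of_mass(xyz[masks[cb]], top.masses[masks[cb]])
            if traj.box_edge is not None:
                dist[f] = geom.pbc_distance(com_a, com_b, traj.box_edge)
            else:
                dist[f] = np.linalg.norm(com_b - com_a)
            ori[f] = geom.orientation_angle(
                xyz[heavy_masks[ca]], xyz[heavy_masks[cb]],
                top.masses[heavy_masks[ca]],
            )
            if have_charges:
                mu_a = geom.dipole_moment(xyz[masks[ca]], top.charges[masks[ca]])
                mu_b = geom.dipole_moment(xyz[masks[cb]], top.charges[masks[cb]])
                dip[f] = geom.vector_angle(mu_a, mu_b)
            ncon[f] = contacts_mod.count_contacts(
                top, xyz, ca, cb, cutoff, traj.box_edge
            )
        out[(ca, cb)] = geom.PairSeries(
            (ca, cb), traj.frame_times.copy(), dist, ori, dip, ncon
        )
    return out


def _pair_series_frame(series: geom.PairSeries) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_ns": series.times,
            "com_distance_A": series.com_distance,
            "orientation_deg": series.orientation_angle,
            "dipole_angle_deg": series.dipole_angle,
            "n_contacts": series.n_contacts,
        }
    )


def _load_inputs(config: RunConfig) -> Trajectory:
    if config.trajectory is None:
        raise ValueError("config.trajectory is required for analysis")
    topology = None
    if config.topology is not None:
        topology, _ = read_structure(config.topology)
    traj = read_trajectory(
        config.trajectory,
        topology=topology,
        frame_dt=config.frame_dt,
        box_edge=config.box_edge,
    )
    if config.charges is not None:
        charge_top, _ = read_structure(config.charges, fmt="pqr")
        traj = Trajectory(
            _apply_charges(traj.topology, charge_top),
            traj.coords,
            traj.frame_times,
            traj.box_edge,
        )
    return traj


def _apply_charges(topology: Topology, charge_top: Topology) -> Topology:
    """Map charges onto the topology by (residue_index, atom_name).

    A charge file covering one template copy is applied to every chain, so
    multi-copy systems need only one PQR.
    """
    lookup = {
        (a.residue_index, a.atom_name): a.charge for a in charge_top.atoms
    }
    charges = np.array(
        [
            lookup.get((a.residue_index, a.atom_name), a.charge)
            for a in topology.atoms
        ]
    )
    return topology.with_charges(charges)


def run_analyze(config: RunConfig) -> Path:
    """Run the full analysis pipeline; returns the output directory."""
    out = _setup_run_dir(config)
    outputs: list[str] = []
    t0 = time.time()
    traj = _load_inputs(config)
    top = traj.topology
    log.info("loaded trajectory: %d frames, %d atoms, %d chains",
             traj.n_frames, top.n_atoms, len(top.chains))

    # stage 1: pair series
    series = compute_pair_series(traj, config.contact_cutoff)
    for (ca, cb), s in series.items():
        name = f"pair_{ca}{cb}.csv"
        write_table(_pair_series_frame(s), out / name)
        outputs.append(name)
    log.info("pair series done (%.1f s)", time.time() - t0)

    # stage 2: contact profile
    profile = contacts_mod.residue_contact_profile(traj, cutoff=config.contact_cutoff)
    smoothed = contacts_mod.running_residue_average(profile)
    df = profile.to_frame()
    df["running_avg"] = smoothed.counts
    write_table(df, out / "contact_profile.csv")
    outputs.append("contact_profile.csv")

    # stage 3: events + oligomer states
    gyr = geom.gyration_diameter(
        traj.coords[0][top.chain_mask(top.chains[0])],
        top.masses[top.chain_mask(top.chains[0])],
    )
    all_events = []
    for s in series.values():
        all_events.extend(
            events_mod.detect_events(
                s, config.c_on, config.c_off, config.persistence_ns, gyr
            )
        )
    if all_events:
        ev_df = pd.DataFrame(
            {
                "kind": [e.kind for e in all_events],
                "chain_a": [e.chain_pair[0] for e in all_events],
                "chain_b": [e.chain_pair[1] for e in all_events],
                "onset_ns": [e.onset_time for e in all_events],
                "completion_ns": [e.completion_time for e in all_events],
                "peak_contacts": [e.peak_contacts for e in all_events],
            }
        ).sort_values(["onset_ns", "chain_a"], kind="stable")
        write_table(ev_df, out / "events.csv")
        outputs.append("events.csv")
    mats = [
        np.array(
            [
                [
                    0 if i == j else s_lookup(series, top.chains[i], top.chains[j]).n_contacts[f]
                    for j in range(len(top.chains))
                ]
                for i in range(len(top.chains))
            ]
        )
        for f in range(traj.n_frames)
    ]
    states, transitions = events_mod.state_timeline(mats, top.chains)
    timeline = pd.DataFrame(
        {
            "time_ns": traj.frame_times,
            "state": [st.summary for st in states],
        }
    )
    write_table(timeline, out / "state_timeline.csv")
    outputs.append("state_timeline.csv")
    transitions.to_csv(out / "state_transitions.csv")
    outputs.append("state_transitions.csv")
    log.info("events/states done (%.1f s)", time.time() - t0)

    # stage 4: per-chain diffusion
    diffusion = {}
    for c in top.chains:
        mask = top.chain_mask(c)
        coms = np.array(
            [
                geom.center_of_mass(traj.coords[f][mask], top.masses[mask])
                for f in range(traj.n_frames)
            ]
        )
        if traj.box_edge is not None:
            coms = geom.unwrap_series(coms, traj.box_edge)
        try:
            est = geom.msd_diffusion(coms, traj.frame_times)
            diffusion[c] = {
                "D_m2_per_s": est.D_trans,
                "fit_window_ns": list(est.fit_window),
                "fit_quality": est.fit_quality,
            }
        except ValueError as exc:
            log.warning("diffusion fit skipped for chain %s: %s", c, exc)

    # stage 5: optional landscape
    if config.pca_frame is not None:
        frame = landscape_mod.load_pca_frame(config.pca_frame)
        points = []
        for f in range(traj.n_frames):
            ca_xyz = landscape_mod.extract_ca(
                top, traj.coords[f], frame.residue_range, top.chains[0]
            )
            points.append(landscape_mod.project(frame, ca_xyz))
        grid = landscape_mod.log_prob_landscape(
            np.array(points), temperature=config.temperature
        )
        write_table(grid.to_frame(), out / "landscape.csv")
        outputs.append("landscape.csv")

    summary = {
        "n_frames": traj.n_frames,
        "n_chains": len(top.chains),
        "box_edge_A": traj.box_edge,
        "box_concentration_mM": (
            geom.box_concentration(len(top.chains), traj.box_edge)
            if traj.box_edge
            else None
        ),
        "gyration_diameter_A": gyr,
        "diffusion_per_chain": diffusion,
        "n_bind_events": sum(1 for e in all_events if e.kind == "bind"),
        "n_unbind_events": sum(1 for e in all_events if e.kind == "unbind"),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    outputs.append("summary.json")
    _write_manifest(out, config, outputs)
    log.info("analysis complete (%.1f s)", time.time() - t0)
    return out


def s_lookup(series, a, b):
    return series.get((a, b)) or series[(b, a)]


def run_simulate(config: RunConfig) -> Path:
    """Generate a synthetic trajectory and write trajectory + charges +
    ground-truth sidecar into the output directory."""
    out = _setup_run_dir(config)
    sim = dict(config.simulate)
    script = tuple(
        BindingScript(tuple(s["pair"]), s["bind_time"], s.get("approach_speed", 1.0))
        for s in sim.pop("script", [])
    )
    spec = SyntheticSpec(seed=config.seed, script=script, **sim)
    t0 = time.time()
    traj, truth = generate(spec)
    write_trajectory(traj, out / "trajectory.pdb")
    # single template copy carries the charges
    first = traj.topology.chain_mask(traj.topology.chains[0])
    template_atoms = [a for a, m in zip(traj.topology.atoms, first) if m]
    write_structure(
        Topology(template_atoms), traj.coords[0][first], out / "template.pqr", fmt="pqr"
    )
    truth["spec"] = {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in asdict(spec).items() if k != "script"}
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2, default=str) + "\n")
    _write_manifest(out, config, ["trajectory.pdb", "template.pqr", "ground_truth.json"])
    log.info("simulation complete (%.1f s): %d frames", time.time() - t0, traj.n_frames)
    return out
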