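#!/usr/bin/env python
"""Simulate the study system: three protein copies at ~5 mM in a periodic
100 Å box, freely diffusing, with one scripted binding event at 20 ns.

Writes trajectory.pdb / template.pqr / ground_truth.json under
scratch/encounter_run (trajectory files are bulky and regenerable, so they
live outside results/).  The downstream drivers (02, 03) read these files
or regenerate them if absent.
"""

import json
from pathlib import Path

from crowdmd.pipeline import RunConfig, run_simulate

SCRATCH = Path(__file__).resolve().parent.parent / "scratch" / "encounter_run"

SIM_SPEC = dict(
    n_copies=3,
    n_residues=35,  # reduced copy size keeps the multi-model PDB manageable
    dipole_target=250.0,
    n_steps=600,  # 60 ns of 0.1 ns snapshots
    min_separation=40.0,
    script=[dict(pair=["A", "B"], bind_time=20.0, approach_speed=2.0)],
)


def simulate(out_dir: Path = SCRATCH, seed: int = 2024) -> Path:
    cfg = RunConfig(out_dir=str(out_dir), seed=seed, simulate=dict(SIM_SPEC))
    return run_simulate(cfg)


if __name__ == "__main__":
    out = simulate()
    truth = json.loads((out / "ground_truth.json").read_text())
    print(f"wrote {out}")
    print(f"  copies: {truth['n_copies']}, box {truth['box_edge_A']} Å, "
          f"{truth['n_steps']} steps of {truth['dt_ns']} ns")
    print(f"  true D_trans: {truth['D_trans_m2_per_s']:.1e} m²/s, "
          f"dipole {truth['dipole_debye']} D")
    for e in truth["events"]:
        print(f"  scripted binding {e['pair']}: scheduled {e['bind_time_ns']} ns, "
              f"docked at {e['dock_time_ns']} ns")
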