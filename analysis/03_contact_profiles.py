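#!/usr/bin/env python
"""Per-residue contact profiles across replica simulations.

Runs two short replicas of the scripted-binding system with different
seeds, accumulates the per-residue heavy-atom contact profile of each,
averages them, smooths with the 5-residue running mean, and compares the
replicas (Pearson r and peak overlap).  Tables go to
results/contact_profiles/.
"""

from pathlib import Path

import pandas as pd

from crowdmd import contacts as ct
from crowdmd.io import write_table
from crowdmd.synthetic import BindingScript, SyntheticSpec, generate

RESULTS = Path(__file__).resolve().parent.parent / "results" / "contact_profiles"

SPEC = dict(
    n_copies=3, n_residues=35, dipole_target=250.0, n_steps=400,
    min_separation=40.0,
    script=(BindingScript(("A", "B"), 10.0, approach_speed=2.0),),
)


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    profiles = []
    for seed in (1, 2):
        traj, _ = generate(SyntheticSpec(seed=seed, **SPEC))
        profiles.append(ct.residue_contact_profile(traj))
    avg = ct.average_profiles(profiles)
    smooth = ct.running_residue_average(avg, window=5)
    df = avg.to_frame()
    df["running_avg"] = smooth.counts
    write_table(df, RESULTS / "profile_replica_average.csv")
    comparison = ct.compare_profiles(profiles[0], profiles[1])
    write_table([comparison], RESULTS / "replica_comparison.csv")
    top5 = df.nlargest(5, "count")
    print(f"wrote {RESULTS}")
    print("  most contacted residues (replica average):")
    for _, row in top5.iterrows():
        print(f"    residue {int(row.residue_index):3d}: "
              f"{row['count']:.1f} contact counts")
    print(f"  replica agreement: Pearson r = {comparison['pearson_r']:.3f}, "
          f"peak overlap = {comparison['peak_overlap']:.2f}")


if __name__ == "__main__":
    main()
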