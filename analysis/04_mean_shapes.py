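#!/usr/bin/env python
"""Compute the four normative mean shapes by generalized Procrustes analysis.

One GPA mean per sex x cluster cell, on unit-centroid-size superimposed
configurations.  Writes results/mean_shape_<sex>_c<i>.json and prints the
pairwise Procrustes distances between the four means.
"""

import json
from itertools import combinations
from pathlib import Path

import pandas as pd

from cephalomorph import gpa_mean, procrustes_distance, read_landmarks

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    specimens = {lm.specimen_id: lm for lm in read_landmarks(ROOT / "cohort.csv")}
    assignments = pd.read_csv(ROOT / "cluster_assignments.csv", dtype={"specimen_id": str})

    means = {}
    for (sex, cluster), sub in assignments.groupby(["sex", "cluster"]):
        members = [specimens[sid] for sid in sub["specimen_id"]]
        ens = gpa_mean(members, group_label=f"{sex}/c{cluster + 1}")
        means[ens.group_label] = ens
        (ROOT / f"mean_shape_{sex}_c{cluster + 1}.json").write_text(
            json.dumps(
                {
                    "group": ens.group_label,
                    "coordinate_frame": "gpa_unit",
                    "n_specimens": len(members),
                    "iterations": ens.iterations,
                    "converged": ens.converged,
                    "points": ens.mean_shape.points.tolist(),
                },
                indent=1,
            )
        )
        print(f"{ens.group_label}: GPA mean of {len(members)} specimens "
              f"({ens.iterations} iterations, converged={ens.converged})")

    print("\npairwise Procrustes distances between the four mean shapes:")
    for a, b in combinations(sorted(means), 2):
        d = procrustes_distance(means[a].mean_shape, means[b].mean_shape)
        print(f"  {a} vs {b}: {d:.5f}")


if __name__ == "__main__":
    main()
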