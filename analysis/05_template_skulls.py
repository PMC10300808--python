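#!/usr/bin/env python
"""Create the four normative template skulls by thin-plate-spline morphing.

One synthetic template mesh per sex (a landmark-annotated hull surface of
that sex's normative scaffold, standing in for a CT-derived skull polygon
model) is morphed onto each of its sex's two cluster mean shapes.  Writes
results/template_<sex>_c<i>.ply and reports the landmark misfit after
morphing (which is zero up to numerics: the TPS interpolates the
landmarks).
"""

import json
from pathlib import Path

import numpy as np

from cephalomorph import (
    SEX_PROPORTION_MEANS,
    Shape,
    align_pair,
    generate_toy_mesh,
    morph_template,
    realize_proportions,
    write_mesh,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    for sex in ("male", "female"):
        template_lm = realize_proportions(
            SEX_PROPORTION_MEANS[sex], specimen_id=f"{sex}-template", sex=sex
        )
        template = generate_toy_mesh(template_lm, subdivisions=2)
        for c in (1, 2):
            data = json.loads((ROOT / f"mean_shape_{sex}_c{c}.json").read_text())
            mean = Shape(np.asarray(data["points"]))
            morphed = morph_template(template, target_mean=mean)
            record = write_mesh(morphed, ROOT / f"template_{sex}_c{c}.ply")

            T, _ = align_pair(mean.points, template_lm.points, allow_scale=True)
            rms = np.sqrt(
                ((morphed.landmark_points() - T.apply(mean.points)) ** 2).sum() / 18
            )
            print(f"{sex} cluster {c}: {record.vertex_count} vertices, "
                  f"{record.face_count} faces -> {record.path.name}; "
                  f"landmark misfit RMS {rms:.2e} mm")


if __name__ == "__main__":
    main()
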