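"""End-to-end analysis: validation → proportions → statistics → clustering
→ mean shapes → template morphing.

The workflow mirrors a normative 3D-cephalometry study: per-specimen
distances and proportions, a per-sex normality screen, a sex comparison
with BH-adjusted Welch tests, k-means sub-phenotyping within each sex, a
per-cluster comparison (again BH-adjusted within its own 8-test table —
correction is never pooled across tables), a generalized Procrustes mean
shape per sex x cluster cell, and optionally thin-plate-spline morphs of
annotated template meshes onto those means.  Everything is a pure function
of (inputs, config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .clustering import ClusterModel, elbow_curve, kmeans_fit, label_phenotypes
from .landmarks import (
    PROPORTION_CODES,
    PROPORTION_SPEC_NOTES,
    LandmarkSet,
    LandmarkValidationError,
    ProportionVector,
    compute_distances,
    compute_proportions,
    validate_landmark_set,
)
from .mesh_io import write_mesh
from .registration import Shape, ShapeEnsemble, gpa_mean
from .stats import GroupComparisonTable, compare_groups, normality_report
from .tps import TriangleMesh, morph_template

logger = logging.getLogger("cephalomorph")

__all__ = ["AnalysisConfig", "AnalysisReport", "run_full_analysis", "make_templates"]


@dataclass
class AnalysisConfig:
    group_variable: str = "sex"
    k: int = 2
    alpha: float = 0.05
    scaling: str = "zscore"
    seed: int = 0
    n_init: int = 20
    tps_lambda: float = 0.0
    elbow_k_max: int = 6
    gpa_tol: float = 1e-8
    gpa_max_iter: int = 100

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class AnalysisReport:
    config: AnalysisConfig
    proportions: pd.DataFrame                      # per-specimen P01..P08 + sex
    normality: pd.DataFrame
    sex_comparison: GroupComparisonTable
    cluster_models: dict[str, ClusterModel]        # per sex
    cluster_comparisons: dict[str, GroupComparisonTable]
    cluster_mean_props: dict[str, list[ProportionVector]]
    elbow: dict[str, object]
    mean_shapes: dict[str, ShapeEnsemble]          # "male/c1", "male/c2", ...
    dropped: list[tuple[str, str]] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def _measure(specimens: Sequence[LandmarkSet]) -> pd.DataFrame:
    rows = []
    for lm in specimens:
        props = compute_proportions(compute_distances(lm))
        row = {"specimen_id": lm.specimen_id, "sex": lm.sex}
        row.update(props.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def _props_of(df: pd.DataFrame) -> list[ProportionVector]:
    return [
        ProportionVector.from_mapping(row[list(PROPORTION_CODES)])
        for _, row in df.iterrows()
    ]


def run_full_analysis(
    specimens: Sequence[LandmarkSet],
    config: AnalysisConfig | None = None,
) -> AnalysisReport:
    """Run the full landmark → report analysis on validated specimens.

    Specimens failing landmark validation are dropped with a logged
    reason, never imputed.  Requires at least two specimens per sex group.
    """
    config = config or AnalysisConfig()
    valid: list[LandmarkSet] = []
    dropped: list[tuple[str, str]] = []
    for lm in specimens:
        try:
            record = {name: lm.points[i] for i, name in enumerate(lm.names)}
            valid.append(
                validate_landmark_set(
                    record, specimen_id=lm.specimen_id, sex=lm.sex, age_years=lm.age_years
                )
            )
        except LandmarkValidationError as exc:
            logger.warning("dropping specimen %s: %s", lm.specimen_id, exc)
            dropped.append((lm.specimen_id, str(exc)))

    sexes = sorted({lm.sex for lm in valid})
    for sex in sexes:
        n = sum(lm.sex == sex for lm in valid)
        if n < 2:
            raise ValueError(f"group {sex!r} has {n} specimen(s); need at least 2")
    if len(sexes) != 2:
        raise ValueError(f"expected exactly 2 sex groups, found {sexes}")

    df = _measure(valid)
    groups = {sex: _props_of(df[df.sex == sex]) for sex in sexes}

    normality = normality_report(groups, alpha=config.alpha)
    sex_cmp = compare_groups(
        groups[sexes[0]], groups[sexes[1]],
        alpha=config.alpha, label_a=sexes[0], label_b=sexes[1],
    )

    cluster_models: dict[str, ClusterModel] = {}
    cluster_cmps: dict[str, GroupComparisonTable] = {}
    cluster_means: dict[str, list[ProportionVector]] = {}
    elbows: dict[str, object] = {}
    mean_shapes: dict[str, ShapeEnsemble] = {}
    for sex in sexes:
        props = groups[sex]
        k_max = min(config.elbow_k_max, len(props) - 1)
        elbows[sex] = elbow_curve(
            props, k_max=k_max, scaling=config.scaling,
            seed=config.seed, n_init=config.n_init,
        )
        model = kmeans_fit(
            props, k=config.k, scaling=config.scaling,
            seed=config.seed, n_init=config.n_init,
        )
        means = model.cluster_mean_proportions(props)
        model = label_phenotypes(model, means) if config.k == 2 else model
        cluster_models[sex] = model
        cluster_means[sex] = means

        sex_lms = [lm for lm in valid if lm.sex == sex]
        if config.k == 2:
            in_c = [
                [lm for lm, a in zip(sex_lms, model.assignments) if a == c]
                for c in range(2)
            ]
            if all(len(c) >= 2 for c in in_c):
                cluster_cmps[sex] = compare_groups(
                    [compute_proportions(compute_distances(lm)) for lm in in_c[0]],
                    [compute_proportions(compute_distances(lm)) for lm in in_c[1]],
                    alpha=config.alpha,
                    label_a=f"{sex}/c1", label_b=f"{sex}/c2",
                )
        for c in range(config.k):
            members = [lm for lm, a in zip(sex_lms, model.assignments) if a == c]
            if len(members) >= 2:
                mean_shapes[f"{sex}/c{c + 1}"] = gpa_mean(
                    members, tol=config.gpa_tol, max_iter=config.gpa_max_iter,
                    group_label=f"{sex}/c{c + 1}",
                )

    provenance = {
        "package_version": __version__,
        "seed": config.seed,
        "k": config.k,
        "alpha": config.alpha,
        "feature_scaling": config.scaling,
        "n_init": config.n_init,
        "tps_lambda": config.tps_lambda,
        "proportion_spec_notes": dict(PROPORTION_SPEC_NOTES),
        "bh_scope": "within each 8-test comparison table",
        "n_specimens": len(valid),
        "n_dropped": len(dropped),
    }
    return AnalysisReport(
        config=config,
        proportions=df,
        normality=normality,
        sex_comparison=sex_cmp,
        cluster_models=cluster_models,
        cluster_comparisons=cluster_cmps,
        cluster_mean_props=cluster_means,
        elbow=elbows,
        mean_shapes=mean_shapes,
        dropped=dropped,
        provenance=provenance,
    )


def make_templates(
    report: AnalysisReport,
    male_mesh: TriangleMesh,
    female_mesh: TriangleMesh,
) -> dict[str, TriangleMesh]:
    """Morph each sex's template mesh onto that sex's two cluster means."""
    meshes = {"male": male_mesh, "female": female_mesh}
    out: dict[str, TriangleMesh] = {}
    for key, ensemble in report.mean_shapes.items():
        sex = key.split("/")[0]
        if sex not in meshes:
            continue
        out[key] = morph_template(
            meshes[sex],
            target_mean=ensemble.mean_shape,
            lam=report.config.tps_lambda,
        )
    if len(out) != 4:
        raise ValueError(
            f"expected 4 template morphs (2 sexes x 2 clusters), produced {len(out)}"
        )
    return out


def write_report(report: AnalysisReport, out_dir: "str | Path") -> None:
    """Serialize every report artifact to CSV/JSON under ``out_dir``.

    Output is deterministic for a fixed report (stable column order, no
    timestamps), so identical configs and seeds give byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.proportions.to_csv(out / "proportions.csv", index=False)
    report.normality.to_csv(out / "normality.csv", index=False)
    report.sex_comparison.table.to_csv(out / "sex_comparison.csv")
    for sex, cmp_table in report.cluster_comparisons.items():
        cmp_table.table.to_csv(out / f"cluster_comparison_{sex}.csv")
    for sex, model in report.cluster_models.items():
        (out / f"cluster_model_{sex}.json").write_text(
            json.dumps(model.to_dict(), indent=1)
        )
    for key, ensemble in report.mean_shapes.items():
        (out / f"mean_shape_{key.replace('/', '_')}.json").write_text(
            json.dumps(
                {
                    "group": key,
                    "coordinate_frame": "gpa_unit",
                    "iterations": ensemble.iterations,
                    "converged": ensemble.converged,
                    "points": ensemble.mean_shape.points.tolist(),
                },
                indent=1,
            )
        )
    elbow_rows = []
    for sex, curve in report.elbow.items():
        for k, wss in zip(curve.k_values, curve.wss_values):
            elbow_rows.append({"sex": sex, "k": k, "wss": wss, "suggested_k": curve.suggested_k})
    pd.DataFrame(elbow_rows).to_csv(out / "elbow.csv", index=False)
    (out / "provenance.json").write_text(json.dumps(report.provenance, indent=1))
    if report.dropped:
        pd.DataFrame(report.dropped, columns=["specimen_id", "reason"]).to_csv(
            out / "dropped.csv", index=False
        )


def write_template_meshes(
    templates: dict[str, TriangleMesh], out_dir: "str | Path", format: str = "ply_ascii"
) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for key, mesh in templates.items():
        suffix = "ply" if format.startswith("ply") else "stl"
        path = out / f"template_{key.replace('/', '_')}.{suffix}"
        write_mesh(mesh, path, format=format)
        paths.append(path)
    return paths
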