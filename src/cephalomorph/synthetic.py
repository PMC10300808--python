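"""Synthetic landmark cohorts with controlled proportion structure.

The study design this package serves — normative 3D cephalometry on CBCT
landmark data — rests on cohorts that are not publicly deposited, so every
pipeline stage is exercised on synthetic skulls instead.  The generator
inverts the measurement model: given a target vector of the eight
proportions, it constructs a bilaterally symmetric 18-landmark scaffold
whose defined distances attain exactly the implied ratios, then adds
per-landmark isotropic Gaussian digitisation noise and an arbitrary
similarity transform (pose and size) per specimen.

Not every proportion is free: with the default definitions, fixing P01–P06
determines V1, V3, V4, H2, H3 and Z1 relative to H1, which forces the
realized P08 = H1/H3 = P02/P01 and P07 = V3/H1 = P01/P04.  Targets for
P07/P08 that disagree with those identities cannot be honoured; precedence
is P01–P06 over P08 over P07, and the realized values are always reported
back.

Calibration constants below are normative proportion means for an adult
Eurasian cohort (46 male, 44 female), by sex and by the two sub-phenotype
clusters found within each sex.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .landmarks import (
    LANDMARK_NAMES,
    PROPORTION_CODES,
    LandmarkSet,
    ProportionVector,
    validate_landmark_set,
)
from .tps import TriangleMesh

__all__ = [
    "SEX_PROPORTION_MEANS",
    "CLUSTER_PROPORTION_MEANS",
    "GroupSpec",
    "CohortSpec",
    "SyntheticCohort",
    "RealizationError",
    "realize_proportions",
    "realized_proportion_targets",
    "generate_cohort",
    "generate_toy_mesh",
    "sex_cohort_spec",
    "cluster_cohort_spec",
]

#: Normative proportion means by sex (adult Eurasian reference cohort).
SEX_PROPORTION_MEANS: dict[str, dict[str, float]] = {
    "female": {"P01": 1.08, "P02": 1.877, "P03": 1.04, "P04": 0.962,
               "P05": 4.851, "P06": 1.806, "P07": 1.816, "P08": 1.738},
    "male": {"P01": 1.115, "P02": 2.008, "P03": 1.082, "P04": 0.986,
             "P05": 5.293, "P06": 1.874, "P07": 1.785, "P08": 1.802},
}

#: Normative proportion means for the two sub-phenotype clusters per sex.
#: Cluster 1 of each sex is the dolichofacial (larger P01) phenotype.
CLUSTER_PROPORTION_MEANS: dict[str, dict[str, dict[str, float]]] = {
    "male": {
        "m1": {"P01": 1.178, "P02": 2.146, "P03": 1.136, "P04": 0.94,
               "P05": 5.535, "P06": 1.977, "P07": 1.643, "P08": 1.823},
        "m2": {"P01": 1.071, "P02": 1.912, "P03": 1.043, "P04": 1.019,
               "P05": 5.123, "P06": 1.802, "P07": 1.884, "P08": 1.786},
    },
    "female": {
        "f1": {"P01": 1.164, "P02": 2.001, "P03": 1.092, "P04": 0.921,
               "P05": 4.979, "P06": 1.9, "P07": 1.67, "P08": 1.746},
        "f2": {"P01": 1.034, "P02": 1.791, "P03": 1.003, "P04": 0.989,
               "P05": 4.763, "P06": 1.742, "P07": 1.917, "P08": 1.733},
    },
}

#: Scaffold version tag: the relative placements of the landmarks that are
#: not pinned by the eight distances are arbitrary but frozen, because GPA
#: mean shapes depend on all 18 points.
SCAFFOLD_VERSION = "scaffold-v1"

# fixed scaffold positions in units of V1: (x lateral, y anterior, z up)
_SCAFFOLD_FREE = {
    "IF r": (0.12, 0.02, -0.02),
    "IF l": (-0.12, 0.02, -0.02),
    "LIbl": (0.0, 0.02, -0.80),
    "LoMdbrbl r": (0.28, -0.07, -0.72),
    "LoMdbrbl l": (-0.28, -0.07, -0.72),
    "Pom r": (0.35, -0.45, -0.95),
    "Pom l": (-0.35, -0.45, -0.95),
}
_FOS_YZ = (0.0, -0.05)      # y, z of the fronto-orbital pair, units of V1
_CO_YZ = (-0.55, -0.35)     # y, z of the condyle pair
_UPM_YZ = (-0.05, -0.55)    # y, z of the upper-molar pair
_SPA_Y = 0.15               # anterior offset of spina nasalis anterior


class RealizationError(ValueError):
    """Target proportions admit no valid scaffold geometry."""


def _targets_dict(targets: "ProportionVector | Mapping[str, float]") -> dict[str, float]:
    if isinstance(targets, ProportionVector):
        return targets.as_dict()
    return {code: float(targets[code]) for code in PROPORTION_CODES}


def _derived_distances(targets: Mapping[str, float], base_scale_mm: float) -> dict[str, float]:
    t = dict(targets)
    if any(t[c] <= 0 for c in PROPORTION_CODES):
        raise RealizationError("all target proportions must be positive")
    if base_scale_mm <= 0:
        raise RealizationError("base_scale_mm must be positive")
    H1 = float(base_scale_mm)
    V1 = t["P01"] * H1
    return {
        "H1": H1,
        "V1": V1,
        "H3": V1 / t["P02"],
        "H2": V1 / t["P03"],
        "V3": V1 / t["P04"],
        "V4": V1 / t["P05"],
        "Z1": V1 / t["P06"],
    }


def realized_proportion_targets(
    targets: "ProportionVector | Mapping[str, float]",
) -> ProportionVector:
    """The proportions the scaffold will actually attain.

    P01–P06 are honoured exactly; the geometry then forces
    P07 = P01/P04 and P08 = P02/P01 regardless of their requested values.
    """
    t = _targets_dict(targets)
    out = dict(t)
    out["P07"] = t["P01"] / t["P04"]
    out["P08"] = t["P02"] / t["P01"]
    return ProportionVector.from_mapping(out)


def realize_proportions(
    targets: "ProportionVector | Mapping[str, float]",
    base_scale_mm: float = 100.0,
    specimen_id: str = "synthetic",
    sex: str = "unknown",
) -> LandmarkSet:
    """Construct a canonical 18-landmark configuration attaining the targets.

    The configuration is bilaterally symmetric (midline in the x = 0
    plane, paired landmarks mirrored in x) and places exactly the defining
    landmark pairs at the derived distances: H1 fixes the fronto-orbital
    width at ``base_scale_mm``; V1, V3, V4, H2, H3 and Z1 follow from
    P01–P06.  Raises :class:`RealizationError` when a derived distance is
    non-positive or the sphere constraints for the inferior orbital edge
    admit no intersection.
    """
    t = _targets_dict(targets)
    d = _derived_distances(t, base_scale_mm)
    V1 = d["V1"]

    pts: dict[str, np.ndarray] = {}
    pts["N"] = np.zeros(3)
    pts["Po"] = np.array([0.0, 0.0, -V1])

    # spina nasalis anterior: on the midline at distance V3 from pogonion,
    # pushed anteriorly by a fixed fraction of V1
    y_s = _SPA_Y * V1
    if d["V3"] <= y_s:
        raise RealizationError(
            f"V3 = {d['V3']:.3f} mm too small for the scaffold's anterior offset"
        )
    pts["SPA"] = np.array([0.0, y_s, -V1 + np.sqrt(d["V3"] ** 2 - y_s**2)])

    pts["FOS r"] = np.array([d["H1"] / 2, _FOS_YZ[0] * V1, _FOS_YZ[1] * V1])
    pts["FOS l"] = pts["FOS r"] * np.array([-1.0, 1.0, 1.0])
    pts["Co r"] = np.array([d["H2"] / 2, _CO_YZ[0] * V1, _CO_YZ[1] * V1])
    pts["Co l"] = pts["Co r"] * np.array([-1.0, 1.0, 1.0])
    pts["UpMdbrbl r"] = np.array([d["H3"] / 2, _UPM_YZ[0] * V1, _UPM_YZ[1] * V1])
    pts["UpMdbrbl l"] = pts["UpMdbrbl r"] * np.array([-1.0, 1.0, 1.0])

    # inferior orbital edge right: intersection of the sphere of radius V4
    # about FOS r with the sphere of radius Z1 about Co r
    f, c = pts["FOS r"], pts["Co r"]
    sep = c - f
    dist_fc = float(np.linalg.norm(sep))
    V4, Z1 = d["V4"], d["Z1"]
    if not (abs(V4 - Z1) < dist_fc < V4 + Z1):
        raise RealizationError(
            "inferior orbital edge unrealizable: need |V4 - Z1| < |FOS r - Co r| < V4 + Z1, "
            f"got V4={V4:.2f}, Z1={Z1:.2f}, separation={dist_fc:.2f} mm"
        )
    u = sep / dist_fc
    a = (V4**2 - Z1**2 + dist_fc**2) / (2 * dist_fc)
    h_sq = V4**2 - a**2
    if h_sq <= 0:
        raise RealizationError("inferior orbital edge unrealizable: degenerate sphere intersection")
    e = np.array([0.0, 1.0, 0.0])
    w = e - (e @ u) * u
    if np.linalg.norm(w) < 1e-12:
        e = np.array([0.0, 0.0, 1.0])
        w = e - (e @ u) * u
    w /= np.linalg.norm(w)
    pts["IOE r"] = f + a * u + np.sqrt(h_sq) * w
    pts["IOE l"] = pts["IOE r"] * np.array([-1.0, 1.0, 1.0])

    for name, rel in _SCAFFOLD_FREE.items():
        pts[name] = np.array(rel) * V1

    return validate_landmark_set(
        {name: pts[name] for name in LANDMARK_NAMES},
        specimen_id=specimen_id,
        sex=sex,
    )


@dataclass(frozen=True)
class GroupSpec:
    """One homogeneous cohort group (a sex, or a cluster within a sex)."""

    label: str
    n: int
    proportion_targets: "ProportionVector | dict[str, float]"
    sex: str = "unknown"
    base_scale_mm: float = 100.0
    noise_sd_mm: float = 0.5
    pose: str = "canonical"  # canonical | random_similarity
    true_cluster: "int | None" = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size n must be >= 1")
        if self.noise_sd_mm < 0:
            raise ValueError("noise_sd_mm must be non-negative")
        if self.pose not in ("canonical", "random_similarity"):
            raise ValueError(f"unknown pose {self.pose!r}")


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple[GroupSpec, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))


@dataclass
class SyntheticCohort:
    specimens: list[LandmarkSet]
    group_labels: list[str]
    true_clusters: list["int | None"]
    spec: CohortSpec

    def by_sex(self, sex: str) -> list[LandmarkSet]:
        return [s for s in self.specimens if s.sex == sex]


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform rotation via a normalised random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a cohort: canonical realization + noise + optional pose.

    Per specimen: the group's canonical scaffold, plus i.i.d. Gaussian
    displacement of every coordinate (sd = noise_sd_mm), then — if pose is
    random_similarity — a Haar-uniform rotation, a uniform translation in
    ±500 mm per axis and a uniform scale in [0.8, 1.25].  Fully
    reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    specimens: list[LandmarkSet] = []
    labels: list[str] = []
    clusters: list[int | None] = []
    for group in spec.groups:
        canonical = realize_proportions(
            group.proportion_targets,
            base_scale_mm=group.base_scale_mm,
            sex=group.sex,
        )
        for i in range(group.n):
            pts = canonical.points.copy()
            if group.noise_sd_mm > 0:
                pts = pts + rng.normal(scale=group.noise_sd_mm, size=pts.shape)
            if group.pose == "random_similarity":
                R = _random_rotation(rng)
                scale = rng.uniform(0.8, 1.25)
                trans = rng.uniform(-500.0, 500.0, size=3)
                pts = scale * pts @ R.T + trans
            specimens.append(
                LandmarkSet(
                    specimen_id=f"{group.label}-{i:03d}",
                    points=pts,
                    sex=group.sex,
                )
            )
            labels.append(group.label)
            clusters.append(group.true_cluster)
    return SyntheticCohort(
        specimens=specimens, group_labels=labels, true_clusters=clusters, spec=spec
    )


def sex_cohort_spec(
    seed: int = 0,
    n_male: int = 46,
    n_female: int = 44,
    noise_sd_mm: float = 0.5,
    pose: str = "random_similarity",
) -> CohortSpec:
    """Two sex groups at the normative sex-mean proportion calibrations."""
    return CohortSpec(
        groups=(
            GroupSpec(
                label="male", n=n_male, sex="male",
                proportion_targets=dict(SEX_PROPORTION_MEANS["male"]),
                noise_sd_mm=noise_sd_mm, pose=pose,
            ),
            GroupSpec(
                label="female", n=n_female, sex="female",
                proportion_targets=dict(SEX_PROPORTION_MEANS["female"]),
                noise_sd_mm=noise_sd_mm, pose=pose,
            ),
        ),
        seed=seed,
    )


def cluster_cohort_spec(
    seed: int = 0,
    n_male: int = 46,
    n_female: int = 44,
    noise_sd_mm: float = 0.5,
    pose: str = "random_similarity",
) -> CohortSpec:
    """Two sexes x two sub-phenotype clusters at the cluster calibrations.

    Each sex is split evenly between its two clusters (per-cluster counts
    are a package choice; the reference cohort reports only sex totals).
    """
    groups = []
    for sex, n_total in (("male", n_male), ("female", n_female)):
        half = n_total // 2
        sizes = (half, n_total - half)
        for ci, (label, targets) in enumerate(CLUSTER_PROPORTION_MEANS[sex].items()):
            groups.append(
                GroupSpec(
                    label=label, n=sizes[ci], sex=sex,
                    proportion_targets=dict(targets),
                    noise_sd_mm=noise_sd_mm, pose=pose,
                    true_cluster=ci,
                )
            )
    return CohortSpec(groups=tuple(groups), seed=seed)


def generate_toy_mesh(lm: LandmarkSet, subdivisions: int = 1, inflate: float = 1.05) -> TriangleMesh:
    """A closed hull-based surface around a landmark cloud, for morph tests.

    The convex hull of the landmarks is inflated slightly about its
    centroid (so landmarks sit near, not on, the surface) and subdivided
    for vertex density; the landmark map carries the landmarks as free 3D
    points.
    """
    import trimesh

    hull = trimesh.Trimesh(vertices=lm.points.copy()).convex_hull
    centroid = hull.vertices.mean(axis=0)
    vertices = centroid + (hull.vertices - centroid) * inflate
    mesh = trimesh.Trimesh(vertices=vertices, faces=hull.faces.copy(), process=False)
    for _ in range(max(0, subdivisions)):
        mesh = mesh.subdivide()
    landmark_map = {
        name: lm.points[i].copy() for i, name in enumerate(LANDMARK_NAMES)
    }
    return TriangleMesh(
        vertices=np.asarray(mesh.vertices, dtype=float),
        faces=np.asarray(mesh.faces, dtype=np.int64),
        landmark_map=landmark_map,
    )
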