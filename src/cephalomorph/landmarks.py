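"""The 18-landmark cephalometric scheme: validation, distances and proportions.

The scheme digitises 18 named skeletal landmarks on each skull (nasion,
paired fronto-orbital and orbital points, spina nasalis anterior, dental
bone-level points, condyles, pogonion and the posterior-inferior mandibular
points).  From these, eight inter-landmark distances are measured — four
"vertical" (V1–V4), three "horizontal" (H1–H3) and one oblique (Z1) — and
eight dimensionless proportions P01–P08 are formed as ratios of those
distances.  The proportions are the feature space for all downstream
statistics and clustering: being ratios, they are invariant under similarity
transforms (position, orientation, uniform scale) of the skull.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "LANDMARK_NAMES",
    "DISTANCE_DEFINITIONS",
    "DEFAULT_PROPORTION_SPEC",
    "LandmarkSet",
    "DistanceVector",
    "ProportionVector",
    "LandmarkValidationError",
    "ProportionSpecError",
    "validate_landmark_set",
    "compute_distances",
    "compute_proportions",
]

#: Canonical landmark codes in their fixed scheme order (1–18).
LANDMARK_NAMES: tuple[str, ...] = (
    "N",            # 1  nasion
    "FOS r",        # 2  fronto-orbital suture right
    "FOS l",        # 3  fronto-orbital suture left
    "IOE r",        # 4  inferior orbital edge right
    "IOE l",        # 5  inferior orbital edge left
    "IF r",         # 6  incisura frontalis right
    "IF l",         # 7  incisura frontalis left
    "SPA",          # 8  spina nasalis anterior
    "UpMdbrbl r",   # 9  upper first molar distobuccal root bone level right
    "UpMdbrbl l",   # 10 upper first molar distobuccal root bone level left
    "LIbl",         # 11 lower incisor bone level
    "LoMdbrbl r",   # 12 lower first molar distal root bone level right
    "LoMdbrbl l",   # 13 lower first molar distal root bone level left
    "Co r",         # 14 condyle right
    "Co l",         # 15 condyle left
    "Po",           # 16 pogonion
    "Pom r",        # 17 posterior inferior mandibular point right
    "Pom l",        # 18 posterior inferior mandibular point left
)

_INDEX = {name: i for i, name in enumerate(LANDMARK_NAMES)}

#: Distance code -> (landmark a, landmark b).  All bilateral distances use
#: either midline points or right-side pairs; H1–H3 span the two sides.
DISTANCE_DEFINITIONS: dict[str, tuple[str, str]] = {
    "V1": ("N", "Po"),
    "V2": ("N", "SPA"),
    "V3": ("SPA", "Po"),
    "V4": ("FOS r", "IOE r"),
    "H1": ("FOS r", "FOS l"),
    "H2": ("Co r", "Co l"),
    "H3": ("UpMdbrbl r", "UpMdbrbl l"),
    "Z1": ("IOE r", "Co r"),
}

_MEASURED_DISTANCES = ("V1", "V2", "V3", "V4", "H1", "H2", "H3", "Z1")

#: Default proportion definitions, P-code -> (numerator, denominator).
#: Two entries deviate from a literal reading of the published abbreviation
#: table and are flagged in :data:`PROPORTION_SPEC_NOTES`:
#: P05 is defined as V1/V4 (the ratio is printed as "V1/V6" in the source
#: abbreviation table but no V6 distance is defined anywhere; V4 is the only
#: vertical distance otherwise unused and the only one of the right
#: magnitude), and P07 is the ratio V3/H1 (printed with a dash, but a
#: literal difference would not be scale-invariant and would contradict the
#: dimensionless use of the proportions).
DEFAULT_PROPORTION_SPEC: dict[str, tuple[str, str]] = {
    "P01": ("V1", "H1"),
    "P02": ("V1", "H3"),
    "P03": ("V1", "H2"),
    "P04": ("V1", "V3"),
    "P05": ("V1", "V4"),
    "P06": ("V1", "Z1"),
    "P07": ("V3", "H1"),
    "P08": ("H1", "H3"),
}

PROPORTION_CODES = tuple(DEFAULT_PROPORTION_SPEC)

#: Metadata echoed into reports wherever the default spec is used.
PROPORTION_SPEC_NOTES: dict[str, str] = {
    "P05": "defined as V1/V4; the source abbreviation 'V1/V6' references an undefined distance",
    "P07": "interpreted as the ratio V3/H1; a literal difference is not scale-invariant",
}


class LandmarkValidationError(ValueError):
    """A candidate landmark record violates the 18-landmark scheme."""


class ProportionSpecError(ValueError):
    """A proportion definition references an unknown distance code."""


@dataclass(frozen=True)
class LandmarkSet:
    """One skull's 18 named 3D landmarks, in millimetres, in scheme order."""

    specimen_id: str
    points: np.ndarray  # (18, 3) float64
    sex: str = "unknown"  # female | male | unknown
    age_years: float | None = None

    names: tuple[str, ...] = field(default=LANDMARK_NAMES, repr=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (18, 3):
            raise LandmarkValidationError(
                f"expected 18 x 3 coordinates, got shape {pts.shape}"
            )
        object.__setattr__(self, "points", pts)

    def point(self, name: str) -> np.ndarray:
        return self.points[_INDEX[name]]

    def with_points(self, points: np.ndarray) -> "LandmarkSet":
        return LandmarkSet(
            specimen_id=self.specimen_id,
            points=np.asarray(points, dtype=float),
            sex=self.sex,
            age_years=self.age_years,
        )


@dataclass(frozen=True)
class DistanceVector:
    """The eight defined inter-landmark distances of one skull, in mm."""

    V1: float
    V2: float
    V3: float
    V4: float
    H1: float
    H2: float
    H3: float
    Z1: float

    def as_dict(self) -> dict[str, float]:
        return {code: getattr(self, code) for code in _MEASURED_DISTANCES}


@dataclass(frozen=True)
class ProportionVector:
    """The eight dimensionless shape proportions P01–P08 of one skull."""

    P01: float
    P02: float
    P03: float
    P04: float
    P05: float
    P06: float
    P07: float
    P08: float

    def as_dict(self) -> dict[str, float]:
        return {code: getattr(self, code) for code in PROPORTION_CODES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, code) for code in PROPORTION_CODES])

    @classmethod
    def from_mapping(cls, values: Mapping[str, float]) -> "ProportionVector":
        return cls(**{code: float(values[code]) for code in PROPORTION_CODES})


def _normalize_name(name: str) -> str:
    """Map a raw landmark label onto its canonical code (case/space tolerant)."""
    key = " ".join(str(name).split())
    lookup = {n.lower(): n for n in LANDMARK_NAMES}
    try:
        return lookup[key.lower()]
    except KeyError:
        raise LandmarkValidationError(
            f"unknown landmark code {name!r}; valid codes: {', '.join(LANDMARK_NAMES)}"
        ) from None


def validate_landmark_set(
    raw: Mapping[str, Sequence[float]] | Sequence[tuple[str, Sequence[float]]],
    *,
    specimen_id: str = "",
    sex: str = "unknown",
    age_years: float | None = None,
) -> LandmarkSet:
    """Validate a raw name->(x, y, z) record and return a canonical LandmarkSet.

    The record may list landmarks in any order; the result is always in the
    fixed scheme order 1–18.  Raises :class:`LandmarkValidationError` for a
    missing or duplicate landmark, a non-finite coordinate, or two exactly
    coincident landmarks, naming the offender.
    """
    items = list(raw.items()) if isinstance(raw, Mapping) else list(raw)
    seen: dict[str, np.ndarray] = {}
    for name, xyz in items:
        code = _normalize_name(name)
        if code in seen:
            raise LandmarkValidationError(f"duplicate landmark: {code}")
        arr = np.asarray(xyz, dtype=float)
        if arr.shape != (3,):
            raise LandmarkValidationError(
                f"landmark {code}: expected 3 coordinates, got {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise LandmarkValidationError(f"non-finite coordinate at landmark {code}")
        seen[code] = arr

    missing = [n for n in LANDMARK_NAMES if n not in seen]
    if missing:
        raise LandmarkValidationError(
            "missing landmark" + ("s" if len(missing) > 1 else "")
            + ": " + ", ".join(missing)
        )

    pts = np.stack([seen[n] for n in LANDMARK_NAMES])
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    iu = np.triu_indices(18, k=1)
    zero = np.nonzero(dist[iu] == 0.0)[0]
    if zero.size:
        i, j = iu[0][zero[0]], iu[1][zero[0]]
        raise LandmarkValidationError(
            f"coincident landmarks: {LANDMARK_NAMES[i]} and {LANDMARK_NAMES[j]}"
        )

    if sex not in ("female", "male", "unknown"):
        raise LandmarkValidationError(f"sex must be female/male/unknown, got {sex!r}")
    if age_years is not None and (not math.isfinite(age_years) or age_years < 0):
        raise LandmarkValidationError(f"age_years must be non-negative, got {age_years}")

    return LandmarkSet(specimen_id=specimen_id, points=pts, sex=sex, age_years=age_years)


def compute_distances(lm: LandmarkSet) -> DistanceVector:
    """Measure the eight defined Euclidean inter-landmark distances."""
    values = {
        code: float(np.linalg.norm(lm.point(a) - lm.point(b)))
        for code, (a, b) in DISTANCE_DEFINITIONS.items()
    }
    return DistanceVector(**values)


def compute_proportions(
    d: DistanceVector,
    spec: Mapping[str, tuple[str, str]] | None = None,
) -> ProportionVector:
    """Form the eight proportions from a distance vector.

    ``spec`` maps each P-code to a (numerator, denominator) pair of distance
    codes; the default is :data:`DEFAULT_PROPORTION_SPEC`.
    """
    spec = dict(DEFAULT_PROPORTION_SPEC) if spec is None else dict(spec)
    dist = d.as_dict()
    values: dict[str, float] = {}
    for code in PROPORTION_CODES:
        if code not in spec:
            raise ProportionSpecError(f"proportion spec missing {code}")
        num, den = spec[code]
        for ref in (num, den):
            if ref not in dist:
                raise ProportionSpecError(
                    f"proportion {code} references undefined distance {ref!r}"
                )
        values[code] = dist[num] / dist[den]
    return ProportionVector(**values)


def measure_proportions(lm: LandmarkSet) -> ProportionVector:
    """Convenience: distances then default proportions in one call."""
    return compute_proportions(compute_distances(lm))
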