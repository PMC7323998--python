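"""Embryo frame geometry and composable spatial regions.

The embryo is described in a right-handed physical frame (micrometres):
``axis_ap`` (+x, anterior), ``axis_ml`` (+y, towards the tracked eye, i.e.
lateral) and ``axis_dv`` (+z, dorsal).  The eye is a sphere; the lens sits at
its distal pole, so the proximodistal unit vector is
``u = (lens_center - eye_center) / R``.  "Proximal" and "distal" refer to the
two hemispheres either side of the equatorial plane through the eye centre,
perpendicular to ``u`` (brain-facing vs lens-facing).

Regions are pure, deterministic predicates over (N, 3) point arrays and can
be composed with union / intersection / complement; they are what cell
selection at a reference timepoint and in-region counting operate on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "EmbryoModel",
    "Region",
    "HalfSpace",
    "Sphere",
    "SphericalShell",
    "Box",
    "Union",
    "Intersection",
    "Complement",
    "default_embryo_model",
    "region_from_dict",
]


class GeometryError(ValueError):
    """Raised for invalid embryo geometry (e.g. lens off the eye surface)."""


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise GeometryError("zero vector cannot be normalised")
    return v / n


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------


class Region:
    """Base class: a pure boolean predicate over points in embryo space."""

    def contains(self, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return self.contains(pts)

    def __and__(self, other: "Region") -> "Region":
        return Intersection([self, other])

    def __or__(self, other: "Region") -> "Region":
        return Union([self, other])

    def __invert__(self) -> "Region":
        return Complement(self)


@dataclass(frozen=True)
class HalfSpace(Region):
    """Points p with (p - point) . normal >= offset."""

    point: tuple[float, float, float]
    normal: tuple[float, float, float]
    offset: float = 0.0

    def contains(self, points: np.ndarray) -> np.ndarray:
        n = _unit(np.asarray(self.normal, float))
        return (points - np.asarray(self.point, float)) @ n >= self.offset


@dataclass(frozen=True)
class Sphere(Region):
    center: tuple[float, float, float]
    radius: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(points - np.asarray(self.center, float), axis=-1)
        return d <= self.radius


@dataclass(frozen=True)
class SphericalShell(Region):
    """|‖p − center‖ − radius| <= thickness: a band around a sphere surface."""

    center: tuple[float, float, float]
    radius: float
    thickness: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(points - np.asarray(self.center, float), axis=-1)
        return np.abs(d - self.radius) <= self.thickness


@dataclass(frozen=True)
class Box(Region):
    """Axis-aligned box [lo, hi] per coordinate."""

    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    def contains(self, points: np.ndarray) -> np.ndarray:
        lo = np.asarray(self.lo, float)
        hi = np.asarray(self.hi, float)
        return np.all((points >= lo) & (points <= hi), axis=-1)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        lo = np.asarray(self.lo, float)
        hi = np.asarray(self.hi, float)
        return rng.uniform(lo, hi, size=(n, 3))


@dataclass(frozen=True)
class Union(Region):
    parts: Sequence[Region]

    def contains(self, points: np.ndarray) -> np.ndarray:
        out = np.zeros(len(points), dtype=bool)
        for p in self.parts:
            out |= p.contains(points)
        return out


@dataclass(frozen=True)
class Intersection(Region):
    parts: Sequence[Region]

    def contains(self, points: np.ndarray) -> np.ndarray:
        out = np.ones(len(points), dtype=bool)
        for p in self.parts:
            out &= p.contains(points)
        return out


@dataclass(frozen=True)
class Complement(Region):
    part: Region

    def contains(self, points: np.ndarray) -> np.ndarray:
        return ~self.part.contains(points)


_REGION_TYPES = {
    "half_space": HalfSpace,
    "sphere": Sphere,
    "spherical_shell": SphericalShell,
    "box": Box,
}


def region_from_dict(spec: dict) -> Region:
    """Build a Region from a JSON-style dict: {"type": ..., params...}.

    Combinators: {"type": "union"/"intersection", "parts": [...]} and
    {"type": "complement", "part": {...}}.
    """
    spec = dict(spec)
    kind = spec.pop("type")
    if kind == "union":
        return Union([region_from_dict(p) for p in spec["parts"]])
    if kind == "intersection":
        return Intersection([region_from_dict(p) for p in spec["parts"]])
    if kind == "complement":
        return Complement(region_from_dict(spec["part"]))
    try:
        cls = _REGION_TYPES[kind]
    except KeyError:
        raise ValueError(f"unknown region type {kind!r}") from None
    for key in ("point", "normal", "center", "lo", "hi"):
        if key in spec:
            spec[key] = tuple(float(x) for x in spec[key])
    return cls(**spec)


# ---------------------------------------------------------------------------
# Embryo model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EmbryoModel:
    """Geometry of the embryo frame around one eye.

    ``origin_zone_1nc`` is the lateral stripe at the border of the neural keel
    where the first (early) neural-crest wave delaminates;
    ``origin_zone_2nc`` is the mediodorsal zone at the diencephalon /
    mesencephalon level where the second wave forms.  ``cluster_center`` is
    the periocular point near the dorsal eye rim where the second wave
    transiently clusters before dissolving into the eye.
    """

    eye_center: np.ndarray
    eye_radius: float
    lens_center: np.ndarray
    axis_ap: np.ndarray
    axis_ml: np.ndarray
    axis_dv: np.ndarray
    origin_zone_1nc: Box
    origin_zone_2nc: Box
    cluster_center: np.ndarray

    def __post_init__(self) -> None:
        for name in ("axis_ap", "axis_ml", "axis_dv"):
            object.__setattr__(self, name, _unit(getattr(self, name)))
        object.__setattr__(self, "eye_center", np.asarray(self.eye_center, float))
        object.__setattr__(self, "lens_center", np.asarray(self.lens_center, float))
        object.__setattr__(self, "cluster_center", np.asarray(self.cluster_center, float))
        A = np.stack([self.axis_ap, self.axis_ml, self.axis_dv])
        if not np.allclose(A @ A.T, np.eye(3), atol=1e-8):
            raise GeometryError("embryo axes must be orthonormal")
        d = np.linalg.norm(self.lens_center - self.eye_center)
        if not np.isclose(d, self.eye_radius, rtol=1e-6, atol=1e-6):
            raise GeometryError(
                f"lens_center must lie on the eye sphere: |lens-eye| = {d:.3f}, "
                f"radius = {self.eye_radius:.3f}"
            )

    @property
    def u(self) -> np.ndarray:
        """Proximodistal unit vector (eye centre → lens pole)."""
        return _unit(self.lens_center - self.eye_center)

    # convenience regions -------------------------------------------------
    def eye_shell(self, shell_um: float) -> SphericalShell:
        return SphericalShell(tuple(self.eye_center), self.eye_radius, shell_um)

    def distal_half(self, margin_um: float = 0.0) -> HalfSpace:
        return HalfSpace(tuple(self.eye_center), tuple(self.u), margin_um)

    def proximal_half(self, margin_um: float = 0.0) -> HalfSpace:
        return HalfSpace(tuple(self.eye_center), tuple(-self.u), margin_um)

    def pd_coordinate(self, points: np.ndarray) -> np.ndarray:
        """Signed proximodistal coordinate (p - eye_center) . u in μm."""
        pts = np.atleast_2d(np.asarray(points, float))
        return (pts - self.eye_center) @ self.u


def default_embryo_model(
    eye_radius: float = 40.0,
    eye_center: Sequence[float] = (0.0, 70.0, 0.0),
    mirrored: bool = False,
) -> EmbryoModel:
    """Construct the default embryo geometry.

    The eye sits lateral to the midline plane (y = 0); its lens pole points
    further laterally, so u ≈ +axis_ml (flipped for a mirrored embryo on the
    other body side).  The early-wave origin stripe lies between midline and
    eye; the second-wave origin zone lies mediodorsally, anterior and close
    to the midline, at the level of the diencephalon / mesencephalon.
    """
    s = -1.0 if mirrored else 1.0
    c = np.asarray(eye_center, float) * np.array([1.0, s, 1.0])
    ml = np.array([0.0, s, 0.0])
    lens = c + eye_radius * ml
    R = eye_radius

    def ybounds(a: float, b: float) -> tuple[float, float]:
        lo, hi = (a * s, b * s) if s > 0 else (b * s, a * s)
        return lo, hi

    y1 = ybounds(10.0, 28.0)
    y2 = ybounds(2.0, 16.0)
    zone1 = Box((-60.0, y1[0], -10.0), (40.0, y1[1], 30.0))
    zone2 = Box((10.0, y2[0], 25.0), (50.0, y2[1], 45.0))
    cluster_dir = _unit(np.array([0.0, 0.35 * s, 0.95]))
    cluster = c + 1.30 * R * cluster_dir
    return EmbryoModel(
        eye_center=c,
        eye_radius=R,
        lens_center=lens,
        axis_ap=np.array([1.0, 0.0, 0.0]),
        axis_ml=ml,
        axis_dv=np.array([0.0, 0.0, 1.0]),
        origin_zone_1nc=zone1,
        origin_zone_2nc=zone2,
        cluster_center=cluster,
    )
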