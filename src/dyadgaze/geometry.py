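"""3D gaze geometry for face-to-face interaction.

All coordinates live in a fixed right-handed world frame in centimetres:
origin at the table-centre camera rig, y pointing up, z toward the
participant's side of the table. A person's *facial plane* is the plane
through their left-eye, right-eye and mouth landmarks; where an
interlocutor's gaze ray pierces that plane determines what they look at.
Gaze is classified by the distance from the (binocular-averaged)
intersection point to the partner's eye and mouth landmarks: within
6.3 cm of either eye landmark counts as gaze to the eye area.

The module exposes a scalar, dataclass-based API mirroring these concepts,
plus vectorised ``*_arrays`` routines operating on ``(n, 3)`` stacks that
the stream-level pipeline uses (one facial plane, ray pair and label per
video frame).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError, DegenerateGeometryError

__all__ = [
    "PARALLEL_TOL",
    "ON_PLANE_TOL",
    "DEFAULT_EYE_RADIUS_CM",
    "DEFAULT_MOUTH_RADIUS_CM",
    "GazeLabel",
    "LandmarkSet",
    "FacialPlane",
    "GazeRay",
    "IntersectionPoint",
    "AOISpec",
    "default_eye_aoi",
    "default_mouth_aoi",
    "as_point",
    "estimate_facial_plane",
    "intersect_ray_plane",
    "binocular_intersection",
    "classify_gaze",
    "angular_error",
    "project_to_plane_coords",
    "planes_from_landmark_arrays",
    "intersect_ray_plane_arrays",
    "classify_point_arrays",
]

#: |direction . normal| below this counts as a ray parallel to the plane.
PARALLEL_TOL = 1e-8
#: cm; maximum out-of-plane residual for a point considered on-plane.
ON_PLANE_TOL = 1e-6
#: cm^2; landmark triangles thinner than this are degenerate.
_MIN_TRIANGLE_AREA = 1e-8

DEFAULT_EYE_RADIUS_CM = 6.3
DEFAULT_MOUTH_RADIUS_CM = 6.3


class GazeLabel(IntEnum):
    """Per-frame area-of-interest label for gaze on the partner's face."""

    EYE = 0
    MOUTH = 1
    OTHER = 2
    MISSING = 3


def as_point(p, name: str = "point") -> np.ndarray:
    """Coerce ``p`` to a finite ``(3,)`` float array (a Point3)."""
    arr = np.asarray(p, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"{name} must have exactly 3 coordinates, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} has non-finite coordinates: {arr}")
    return arr


def _unit(v: np.ndarray, name: str = "vector") -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0.0 or not np.isfinite(n):
        raise DegenerateGeometryError(f"{name} has zero or non-finite length")
    return v / n


@dataclass(frozen=True)
class LandmarkSet:
    """The facial landmarks defining one person's facial plane.

    ``left_eye``/``right_eye`` are named from the *owner's* perspective.
    The three defining landmarks must form a proper triangle.
    """

    left_eye: np.ndarray
    right_eye: np.ndarray
    mouth: np.ndarray
    nose: Optional[np.ndarray] = None

    def __post_init__(self):
        object.__setattr__(self, "left_eye", as_point(self.left_eye, "left_eye"))
        object.__setattr__(self, "right_eye", as_point(self.right_eye, "right_eye"))
        object.__setattr__(self, "mouth", as_point(self.mouth, "mouth"))
        if self.nose is not None:
            object.__setattr__(self, "nose", as_point(self.nose, "nose"))
        area = 0.5 * np.linalg.norm(
            np.cross(self.right_eye - self.left_eye, self.mouth - self.left_eye)
        )
        if area <= _MIN_TRIANGLE_AREA:
            raise DegenerateGeometryError(
                "left_eye, right_eye and mouth are collinear or coincident "
                f"(triangle area {area:.3g} cm^2): {self.left_eye}, "
                f"{self.right_eye}, {self.mouth}"
            )

    def get(self, name: str) -> np.ndarray:
        value = getattr(self, name)
        if value is None:
            raise KeyError(f"landmark {name!r} not present")
        return value

    @property
    def centroid(self) -> np.ndarray:
        return (self.left_eye + self.right_eye + self.mouth) / 3.0


@dataclass(frozen=True)
class FacialPlane:
    """A facial plane with an orthonormal in-plane basis.

    ``origin`` is the centroid of the defining landmarks; ``u_axis`` follows
    the owner's left-eye-to-right-eye direction, ``v_axis = normal x u_axis``.
    """

    origin: np.ndarray
    normal: np.ndarray
    u_axis: np.ndarray
    v_axis: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "origin", as_point(self.origin, "origin"))
        for name in ("normal", "u_axis", "v_axis"):
            v = np.asarray(getattr(self, name), dtype=float)
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise DegenerateGeometryError(f"{name} is not a unit vector: {v}")
            object.__setattr__(self, name, v)
        for a, b in (("normal", "u_axis"), ("normal", "v_axis"), ("u_axis", "v_axis")):
            if abs(float(np.dot(getattr(self, a), getattr(self, b)))) > 1e-9:
                raise DegenerateGeometryError(f"{a} and {b} are not orthogonal")


@dataclass(frozen=True)
class GazeRay:
    """A gaze ray: eye centre plus a unit direction."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "origin", as_point(self.origin, "ray origin"))
        d = np.asarray(self.direction, dtype=float)
        if d.shape != (3,) or not np.all(np.isfinite(d)):
            raise DegenerateGeometryError(f"ray direction must be a finite 3-vector, got {d}")
        object.__setattr__(self, "direction", _unit(d, "ray direction"))


@dataclass(frozen=True)
class IntersectionPoint:
    """Where a gaze ray meets a facial plane.

    ``valid`` is False for parallel rays and intersections behind the eye;
    ``ray_parameter`` is the distance (cm) along the ray when valid.
    """

    point: np.ndarray
    valid: bool
    ray_parameter: float

    @staticmethod
    def invalid() -> "IntersectionPoint":
        return IntersectionPoint(np.full(3, np.nan), False, math.nan)


@dataclass(frozen=True)
class AOISpec:
    """A distance-rule area of interest: discs of ``radius`` centred on the
    named landmarks; a point is inside when its minimum 3D Euclidean distance
    to any named landmark is <= radius (boundary inclusive)."""

    name: str
    landmark_names: tuple
    radius: float

    def __post_init__(self):
        object.__setattr__(self, "landmark_names", tuple(self.landmark_names))
        if not self.landmark_names:
            raise ConfigurationError(f"AOI {self.name!r}: landmark_names must be non-empty")
        allowed = {"left_eye", "right_eye", "mouth", "nose"}
        bad = set(self.landmark_names) - allowed
        if bad:
            raise ConfigurationError(f"AOI {self.name!r}: unknown landmarks {sorted(bad)}")
        if not (self.radius > 0):
            raise ConfigurationError(
                f"AOI {self.name!r}: radius must be positive, got {self.radius}"
            )


def default_eye_aoi(radius: float = DEFAULT_EYE_RADIUS_CM) -> AOISpec:
    return AOISpec("eye", ("left_eye", "right_eye"), radius)


def default_mouth_aoi(radius: float = DEFAULT_MOUTH_RADIUS_CM) -> AOISpec:
    return AOISpec("mouth", ("mouth",), radius)


# ---------------------------------------------------------------------------
# scalar operations
# ---------------------------------------------------------------------------

def estimate_facial_plane(landmarks: LandmarkSet, toward=None) -> FacialPlane:
    """Fit the facial plane through the three defining landmarks.

    Parameters
    ----------
    landmarks
        The owner's landmark set.
    toward
        Optional point (typically the observing partner's eye midpoint).
        When given, the normal is flipped to point toward it, so successive
        frames share a consistent orientation and (u, v) handedness.
    """
    origin = landmarks.centroid
    e1 = landmarks.right_eye - landmarks.left_eye
    e2 = landmarks.mouth - landmarks.left_eye
    n = np.cross(e1, e2)
    nn = np.linalg.norm(n)
    if 0.5 * nn <= _MIN_TRIANGLE_AREA:
        raise DegenerateGeometryError(
            f"collinear landmarks cannot define a plane: {landmarks.left_eye}, "
            f"{landmarks.right_eye}, {landmarks.mouth}"
        )
    normal = n / nn
    if toward is not None:
        toward = as_point(toward, "toward")
        if float(np.dot(normal, toward - origin)) < 0.0:
            normal = -normal
    u = e1 - np.dot(e1, normal) * normal
    u = _unit(u, "u_axis")
    v = np.cross(normal, u)
    return FacialPlane(origin, normal, u, v)


def intersect_ray_plane(ray: GazeRay, plane: FacialPlane) -> IntersectionPoint:
    """Solve ``origin + t * direction`` on the plane.

    Invalid (never raises) when the ray is parallel to the plane
    (|normal . direction| <= PARALLEL_TOL) or the solution lies behind the
    eye (t <= 0).
    """
    denom = float(np.dot(plane.normal, ray.direction))
    if abs(denom) <= PARALLEL_TOL:
        return IntersectionPoint.invalid()
    t = float(np.dot(plane.normal, plane.origin - ray.origin)) / denom
    if t <= 0.0:
        return IntersectionPoint.invalid()
    return IntersectionPoint(ray.origin + t * ray.direction, True, t)


def binocular_intersection(
    left: Optional[GazeRay], right: Optional[GazeRay], plane: FacialPlane
) -> IntersectionPoint:
    """Average the left- and right-eye intersections with the partner's plane.

    Midpoint when both rays hit; the single valid point when only one does
    (one-eye fallback); invalid when neither does.
    """
    hits = []
    for ray in (left, right):
        if ray is None:
            continue
        p = intersect_ray_plane(ray, plane)
        if p.valid:
            hits.append(p)
    if not hits:
        return IntersectionPoint.invalid()
    if len(hits) == 1:
        return hits[0]
    point = 0.5 * (hits[0].point + hits[1].point)
    t = 0.5 * (hits[0].ray_parameter + hits[1].ray_parameter)
    return IntersectionPoint(point, True, t)


def classify_gaze(
    intersection: IntersectionPoint,
    target_landmarks: LandmarkSet,
    eye_aoi: Optional[AOISpec] = None,
    mouth_aoi: Optional[AOISpec] = None,
) -> GazeLabel:
    """Label the gaze point on the partner's face: EYE, MOUTH, OTHER or MISSING.

    The eye test (min distance to either eye landmark <= radius, inclusive)
    takes precedence over the mouth test where the discs overlap.
    """
    eye_aoi = eye_aoi if eye_aoi is not None else default_eye_aoi()
    mouth_aoi = mouth_aoi if mouth_aoi is not None else default_mouth_aoi()
    if not intersection.valid:
        return GazeLabel.MISSING
    point = intersection.point

    def min_dist(aoi: AOISpec) -> float:
        return min(
            float(np.linalg.norm(point - target_landmarks.get(name)))
            for name in aoi.landmark_names
        )

    if min_dist(eye_aoi) <= eye_aoi.radius:
        return GazeLabel.EYE
    if min_dist(mouth_aoi) <= mouth_aoi.radius:
        return GazeLabel.MOUTH
    return GazeLabel.OTHER


def angular_error(ray: GazeRay, target) -> float:
    """Angle in degrees between the ray direction and the origin-to-target
    direction; 0 for a perfect fixation, up to 180 for the opposite way."""
    target = as_point(target, "target")
    offset = target - ray.origin
    norm = np.linalg.norm(offset)
    if norm <= 1e-12:
        raise DegenerateGeometryError("target coincides with the ray origin")
    cosang = float(np.dot(ray.direction, offset / norm))
    return math.degrees(math.acos(min(1.0, max(-1.0, cosang))))


def project_to_plane_coords(
    intersection: IntersectionPoint, plane: FacialPlane
) -> Optional[tuple]:
    """In-plane (u, v) coordinates of a valid intersection, in cm.

    Returns None for an invalid intersection. The reconstruction
    ``origin + u*u_axis + v*v_axis`` recovers the point to ON_PLANE_TOL.
    """
    if not intersection.valid:
        return None
    rel = intersection.point - plane.origin
    return (float(np.dot(rel, plane.u_axis)), float(np.dot(rel, plane.v_axis)))


# ---------------------------------------------------------------------------
# vectorised operations (one row per frame)
# ---------------------------------------------------------------------------

def planes_from_landmark_arrays(left, right, mouth, toward=None):
    """Vectorised facial-plane estimation.

    Parameters are ``(n, 3)`` stacks of landmark positions; ``toward`` is an
    optional ``(n, 3)`` stack of observer positions used to orient normals.

    Returns
    -------
    dict with ``origin``, ``normal``, ``u_axis``, ``v_axis`` of shape
    ``(n, 3)`` and a boolean ``degenerate`` mask (rows with collinear
    landmarks; their basis vectors are NaN rather than raising, so a single
    bad video frame does not abort a stream).
    """
    left = np.atleast_2d(np.asarray(left, dtype=float))
    right = np.atleast_2d(np.asarray(right, dtype=float))
    mouth = np.atleast_2d(np.asarray(mouth, dtype=float))
    origin = (left + right + mouth) / 3.0
    e1 = right - left
    n = np.cross(e1, mouth - left)
    nn = np.linalg.norm(n, axis=1)
    degenerate = (0.5 * nn <= _MIN_TRIANGLE_AREA) | ~np.isfinite(nn)
    safe = np.where(degenerate, np.nan, nn)
    normal = n / safe[:, None]
    if toward is not None:
        toward = np.atleast_2d(np.asarray(toward, dtype=float))
        flip = np.einsum("ij,ij->i", normal, toward - origin) < 0.0
        normal = np.where(flip[:, None], -normal, normal)
    u = e1 - np.einsum("ij,ij->i", e1, normal)[:, None] * normal
    un = np.linalg.norm(u, axis=1)
    u = u / np.where(un == 0, np.nan, un)[:, None]
    v = np.cross(normal, u)
    return {"origin": origin, "normal": normal, "u_axis": u, "v_axis": v,
            "degenerate": degenerate}


def intersect_ray_plane_arrays(ray_origin, ray_direction, plane_origin, plane_normal):
    """Vectorised ray/plane intersection over ``(n, 3)`` stacks.

    Returns ``(point, t, valid)``; rows are invalid for NaN rays, parallel
    geometry, or intersections at t <= 0 (behind the eye).
    """
    ray_origin = np.atleast_2d(np.asarray(ray_origin, dtype=float))
    ray_direction = np.atleast_2d(np.asarray(ray_direction, dtype=float))
    plane_origin = np.atleast_2d(np.asarray(plane_origin, dtype=float))
    plane_normal = np.atleast_2d(np.asarray(plane_normal, dtype=float))
    denom = np.einsum("ij,ij->i", plane_normal, ray_direction)
    num = np.einsum("ij,ij->i", plane_normal, plane_origin - ray_origin)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / denom
    valid = np.isfinite(t) & (np.abs(denom) > PARALLEL_TOL) & (t > 0.0)
    t = np.where(valid, t, np.nan)
    point = ray_origin + t[:, None] * ray_direction
    return point, t, valid


def classify_point_arrays(
    points,
    invalid,
    left_eye,
    right_eye,
    mouth,
    eye_radius: float = DEFAULT_EYE_RADIUS_CM,
    mouth_radius: float = DEFAULT_MOUTH_RADIUS_CM,
):
    """Vectorised AOI classification of gaze points on the partner's face.

    ``points`` and the landmark stacks are ``(n, 3)``; ``invalid`` marks
    frames with no usable intersection. Returns an int8 array of
    :class:`GazeLabel` values.
    """
    if not (eye_radius > 0) or not (mouth_radius > 0):
        raise ConfigurationError("AOI radii must be positive")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    invalid = np.atleast_1d(np.asarray(invalid, dtype=bool))
    d_le = np.linalg.norm(points - left_eye, axis=1)
    d_re = np.linalg.norm(points - right_eye, axis=1)
    d_mo = np.linalg.norm(points - mouth, axis=1)
    labels = np.full(points.shape[0], int(GazeLabel.OTHER), dtype=np.int8)
    with np.errstate(invalid="ignore"):
        eye_hit = np.fmin(d_le, d_re) <= eye_radius
        mouth_hit = d_mo <= mouth_radius
    labels[mouth_hit] = int(GazeLabel.MOUTH)
    labels[eye_hit] = int(GazeLabel.EYE)  # eye test takes precedence
    labels[invalid | ~np.isfinite(points).all(axis=1)] = int(GazeLabel.MISSING)
    return labels
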