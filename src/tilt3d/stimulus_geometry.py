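"""Viewing and projective geometry of planar random-dot stimuli.

Planar surfaces are described by tilt (the direction the plane is oriented in
depth, measured as a rotation about the line of sight: 0° = right-near,
90° = top-near, 270° = bottom-near), slant (how much the plane is oriented in
depth), and distance along the line of sight.  The observer fixates a target
on the screen plane; stimuli may be rendered nearer or farther than fixation,
which shifts their horizontal disparity pedestal.

Coordinate frame: cyclopean eye at the origin, +z along the line of sight to
the fixation target, +x rightward, +y upward.  The screen plane sits at the
fixation distance.  Angles are degrees unless noted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ViewingGeometry",
    "SurfacePose",
    "CueCondition",
    "Eye",
    "DotField",
    "disparity_pedestal",
    "plane_depth_along_tilt",
    "projected_dot_axes",
    "generate_dot_field",
    "PIXELS_PER_DEGREE",
]

#: Display-only conversion factor (projector pixels per degree of visual
#: angle); derived from a 0.45° dot spanning 7.3 pixels.
PIXELS_PER_DEGREE = 7.3 / 0.45


@dataclass(frozen=True)
class ViewingGeometry:
    """Observer/display parameters.

    fixation_distance : cm from the cyclopean eye to the fixation target
        (and to the screen).
    interocular_separation : cm between the two eyes' optical centers.
    screen_field : angular extent of the projected area, (width, height) deg.
    envelope_diameter : diameter of the circular stimulus envelope, deg.
    baseline_dot_size : angular diameter of an unforeshortened dot, deg.
    """

    fixation_distance: float = 57.0
    interocular_separation: float = 3.0
    screen_field: tuple[float, float] = (70.0, 43.0)
    envelope_diameter: float = 20.0
    baseline_dot_size: float = 0.35

    def __post_init__(self) -> None:
        if self.fixation_distance <= 0 or self.interocular_separation <= 0:
            raise ValueError("viewing distances/separations must be positive")
        if self.envelope_diameter <= 0 or self.baseline_dot_size <= 0:
            raise ValueError("angular sizes must be positive")
        if self.envelope_diameter >= min(self.screen_field):
            raise ValueError("stimulus envelope must fit within the screen field")

    def vergence(self, distance: float) -> float:
        """Binocular vergence angle (deg) when fixating at `distance` cm."""
        if distance <= 0:
            raise ValueError("distance must be positive")
        half = self.interocular_separation / 2.0
        return 2.0 * np.degrees(np.arctan2(half, distance))


@dataclass(frozen=True)
class SurfacePose:
    """Tilt (deg, stored modulo 360), slant (deg, [0, 90)), distance (cm)."""

    tilt: float
    slant: float
    distance: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "tilt", float(self.tilt) % 360.0)
        if not 0.0 <= self.slant < 90.0:
            raise ValueError("slant must lie in [0, 90) degrees")
        if self.distance <= 0:
            raise ValueError("distance must be positive")


class CueCondition(str, Enum):
    COMBINED = "combined"
    STEREO = "stereo"
    PERSPECTIVE = "perspective"


class Eye(str, Enum):
    BOTH = "both"
    LEFT = "left"
    RIGHT = "right"


def disparity_pedestal(distance: float, geom: ViewingGeometry) -> float:
    """Horizontal disparity pedestal (deg) of a stimulus at `distance` cm.

    The pedestal is the vergence angle at the fixation distance minus the
    vergence angle at the stimulus distance, so stimuli nearer than fixation
    carry negative pedestals (they demand more convergence than the eyes
    provide) and farther stimuli positive ones.  Exact arctangent geometry is
    used rather than the small-angle approximation.
    """
    if distance <= 0:
        raise ValueError("stimulus distance must be positive")
    return geom.vergence(geom.fixation_distance) - geom.vergence(distance)


def _plane_unit_normal(pose: SurfacePose) -> np.ndarray:
    """Unit normal of the slanted plane (z-component positive).

    Slant rotates the frontoparallel normal (0, 0, 1) about the in-plane
    axis perpendicular to the tilt direction, so the normal acquires a
    component along the tilt direction (cos t, sin t, 0).
    """
    t = np.radians(pose.tilt)
    s = np.radians(pose.slant)
    return np.array(
        [np.sin(s) * np.cos(t), np.sin(s) * np.sin(t), np.cos(s)]
    )


def _ray_plane_depth(direction: np.ndarray, pose: SurfacePose) -> float:
    """z-depth (cm) where a cyclopean ray meets the plane; NaN if none."""
    n = _plane_unit_normal(pose)
    p0 = np.array([0.0, 0.0, pose.distance])
    denom = float(direction @ n)
    if denom * (p0 @ n) <= 0 or abs(denom) < 1e-12:
        return float("nan")
    lam = float(p0 @ n) / denom
    if lam <= 0:
        return float("nan")
    return lam * float(direction[2])


def plane_depth_along_tilt(
    eccentricity: float, pose: SurfacePose, geom: ViewingGeometry
) -> float:
    """Depth (cm, along +z) where an eccentric cyclopean ray meets the plane.

    `eccentricity` is the signed visual angle from the line of sight measured
    along the tilt direction; positive = toward the plane's near side.  For a
    plane at distance d with slant S the closed form is
    ``d / (1 + tan(ecc) * tan(S))``.
    """
    if abs(eccentricity) >= 90.0:
        raise ValueError("eccentricity must lie within ±90 degrees")
    e = np.radians(eccentricity)
    denom = 1.0 + np.tan(e) * np.tan(np.radians(pose.slant))
    if denom <= 0:
        raise ValueError("ray does not intersect the plane (diverging geometry)")
    return pose.distance / denom


def projected_dot_axes(
    eccentricity: float, pose: SurfacePose, geom: ViewingGeometry
) -> tuple[float, float]:
    """Projected (major, minor) angular axes (deg) of a dot on the tilt axis.

    Dots are scaled so that their on-screen size depends only on slant, not on
    the plane's distance: the baseline dot size is referenced to the fixation
    distance and scaled by fixation_distance / (distance along the ray to the
    dot).  The minor axis is foreshortened by the cosine of the local slant
    relative to the line of sight, which is the surface slant reduced by the
    eccentricity on the near side and increased on the far side.  A local
    slant of 90° or more projects to a degenerate (zero-width) dot.
    """
    z = plane_depth_along_tilt(eccentricity, pose, geom)
    ray_range = z / np.cos(np.radians(eccentricity))
    major = geom.baseline_dot_size * geom.fixation_distance / ray_range
    local_slant = pose.slant - eccentricity
    if abs(local_slant) >= 90.0:
        minor = 0.0
    else:
        minor = major * np.cos(np.radians(local_slant))
    return float(major), float(minor)


@dataclass
class DotField:
    """A rendered random-dot plane.

    Per-dot arrays: world positions (cm) on the plane, per-eye screen
    positions (deg of visual angle from each eye's line of sight), and the
    projected major/minor angular axes (deg).  Stereo-cue stimuli render
    every dot circular at the baseline size; perspective-cue stimuli are
    combined-cue renderings delivered to one eye only.
    """

    cue_condition: CueCondition
    stimulated_eye: Eye
    pose: SurfacePose
    geom: ViewingGeometry
    world_xyz: np.ndarray  # (n, 3) cm
    left_screen: np.ndarray  # (n, 2) deg; NaN if eye not stimulated
    right_screen: np.ndarray  # (n, 2) deg
    axes: np.ndarray  # (n, 2) major/minor deg

    def __post_init__(self) -> None:
        n = self.world_xyz.shape[0]
        for arr, width in ((self.left_screen, 2), (self.right_screen, 2), (self.axes, 2)):
            if arr.shape != (n, width):
                raise ValueError("per-dot arrays must share the dot count")
        if self.cue_condition is CueCondition.PERSPECTIVE and self.stimulated_eye is Eye.BOTH:
            raise ValueError("perspective stimuli are monocular")

    @property
    def n_dots(self) -> int:
        return self.world_xyz.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """One row per dot: world x/y/z (cm), per-eye screen x/y, axes (deg)."""
        return pd.DataFrame(
            {
                "world_x_cm": self.world_xyz[:, 0],
                "world_y_cm": self.world_xyz[:, 1],
                "world_z_cm": self.world_xyz[:, 2],
                "left_x_deg": self.left_screen[:, 0],
                "left_y_deg": self.left_screen[:, 1],
                "right_x_deg": self.right_screen[:, 0],
                "right_y_deg": self.right_screen[:, 1],
                "major_deg": self.axes[:, 0],
                "minor_deg": self.axes[:, 1],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def descriptor(self) -> dict:
        """Compact JSON-serializable stimulus descriptor (no per-dot data)."""
        return {
            "cue_condition": self.cue_condition.value,
            "stimulated_eye": self.stimulated_eye.value,
            "tilt_deg": self.pose.tilt,
            "slant_deg": self.pose.slant,
            "distance_cm": self.pose.distance,
            "n_dots": int(self.n_dots),
            "envelope_deg": self.geom.envelope_diameter,
            "baseline_dot_deg": self.geom.baseline_dot_size,
            "pixels_per_degree": PIXELS_PER_DEGREE,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.descriptor(), fh, indent=2)


def _eye_positions(geom: ViewingGeometry) -> dict[Eye, np.ndarray]:
    half = geom.interocular_separation / 2.0
    return {
        Eye.LEFT: np.array([-half, 0.0, 0.0]),
        Eye.RIGHT: np.array([half, 0.0, 0.0]),
    }

def _screen_angles(points: np.ndarray, eye_pos: np.ndarray) -> np.ndarray:
    """Angular screen coordinates (deg) of world points as seen from an eye."""
    rel = points - eye_pos
    x = np.degrees(np.arctan2(rel[:, 0], rel[:, 2]))
    y = np.degrees(np.arctan2(rel[:, 1], rel[:, 2]))
    return np.column_stack([x, y])


def _sample_envelope_directions(
    n: int, geom: ViewingGeometry, rng: np.random.Generator
) -> np.ndarray:
    """Unit ray directions uniform on screen within the circular envelope.

    Rejection sampling in the angular disc (area-uniform on screen, to a
    flat-screen approximation that is exact for the tangent-plane mapping
    used throughout).
    """
    radius = geom.envelope_diameter / 2.0
    out = np.empty((0, 2))
    while out.shape[0] < n:
        cand = rng.uniform(-radius, radius, size=(2 * n, 2))
        keep = cand[np.hypot(cand[:, 0], cand[:, 1]) <= radius]
        out = np.vstack([out, keep])
    ang = np.radians(out[:n])
    dirs = np.column_stack(
        [np.tan(ang[:, 0]), np.tan(ang[:, 1]), np.ones(n)]
    )
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def _plane_basis(pose: SurfacePose) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(u, v, p0): in-plane orthonormal basis and the plane's on-axis point.

    u points along the tilt direction within the plane (toward the near
    side), v along the slant rotation axis.
    """
    t = np.radians(pose.tilt)
    s = np.radians(pose.slant)
    # In-plane vector along the tilt direction, rotated toward the observer.
    u = np.array([np.cos(s) * np.cos(t), np.cos(s) * np.sin(t), -np.sin(s)])
    v = np.array([-np.sin(t), np.cos(t), 0.0])
    p0 = np.array([0.0, 0.0, pose.distance])
    return u, v, p0


def _world_dots_uniform_on_plane(
    n: int, pose: SurfacePose, geom: ViewingGeometry, rng: np.random.Generator
) -> np.ndarray:
    """Dots uniform on the plane patch whose projection fills the envelope.

    Rejection sampling: draw uniformly on the in-plane disc large enough to
    cover the envelope's pre-image, keep dots whose cyclopean projection
    falls inside the circular screen envelope.
    """
    u, v, p0 = _plane_basis(pose)
    radius_ang = np.radians(geom.envelope_diameter / 2.0)
    # Generous world-radius bound: envelope half-angle at the farthest
    # intersection depth, inflated for slant-induced stretch.
    denom = max(1.0 - np.tan(radius_ang) * np.tan(np.radians(pose.slant)), 0.05)
    r_max = pose.distance / denom * np.tan(radius_ang) / max(np.cos(np.radians(pose.slant)), 0.05)
    out = np.empty((0, 3))
    while out.shape[0] < n:
        m = 4 * n
        ab = rng.uniform(-r_max, r_max, size=(m, 2))
        ab = ab[np.hypot(ab[:, 0], ab[:, 1]) <= r_max]
        pts = p0 + ab[:, :1] * u + ab[:, 1:] * v
        pts = pts[pts[:, 2] > 1.0]  # keep in front of the observer
        ang = np.degrees(
            np.arctan2(np.hypot(pts[:, 0], pts[:, 1]), pts[:, 2])
        )
        out = np.vstack([out, pts[ang <= geom.envelope_diameter / 2.0]])
    return out[:n]


def _perspective_axes(points: np.ndarray, pose: SurfacePose, geom: ViewingGeometry) -> np.ndarray:
    """Projected (major, minor) axes for world dots with full perspective.

    Major axis: baseline scaled by fixation distance over the cyclopean ray
    range (distance compensation referenced to fixation).  Minor axis:
    foreshortened by the cosine of the angle between the plane normal and the
    line of sight to the dot.
    """
    rng_cm = np.linalg.norm(points, axis=1)
    major = geom.baseline_dot_size * geom.fixation_distance / rng_cm
    n = _plane_unit_normal(pose)
    cosang = np.abs(points @ n) / rng_cm
    minor = major * cosang
    return np.column_stack([major, minor])


def generate_dot_field(
    pose: SurfacePose,
    cue: CueCondition | str,
    n_dots: int,
    eye: Eye | str = Eye.BOTH,
    seed: Optional[int] = None,
    geom: Optional[ViewingGeometry] = None,
) -> DotField:
    """Construct a random-dot plane for one cue condition.

    combined
        Dots uniform on the plane in the world; both eyes see full
        perspective projections (density gradients, foreshortening, scaling).
    stereo
        Dots uniform on the screen, ray-traced onto the plane; every dot is
        rendered circular at the baseline size so only binocular disparity
        signals the plane's pose.
    perspective
        The combined-cue rendering delivered to a single eye.
    """
    cue = CueCondition(cue)
    eye = Eye(eye)
    geom = geom or ViewingGeometry()
    if n_dots < 1:
        raise ValueError("n_dots must be at least 1")
    if cue is CueCondition.PERSPECTIVE and eye is Eye.BOTH:
        raise ValueError("perspective stimuli require a single stimulated eye")
    if cue is not CueCondition.PERSPECTIVE:
        eye = Eye.BOTH
    if seed is None:
        raise ValueError("a seed is required for reproducible dot placement")
    rng = np.random.default_rng(seed)
    eyes = _eye_positions(geom)

    if cue is CueCondition.STEREO:
        dirs = _sample_envelope_directions(n_dots, geom, rng)
        depths = np.array([_ray_plane_depth(d, pose) for d in dirs])
        ok = np.isfinite(depths) & (depths > 0)
        # Redraw rays that miss the plane (possible at extreme slants).
        while not ok.all():
            redo = int((~ok).sum())
            nd = _sample_envelope_directions(redo, geom, rng)
            ndep = np.array([_ray_plane_depth(d, pose) for d in nd])
            dirs[~ok] = nd
            depths[~ok] = ndep
            ok = np.isfinite(depths) & (depths > 0)
        points = dirs * (depths / dirs[:, 2])[:, None]
        axes = np.full((n_dots, 2), geom.baseline_dot_size)
    else:
        points = _world_dots_uniform_on_plane(n_dots, pose, geom, rng)
        axes = _perspective_axes(points, pose, geom)

    left = _screen_angles(points, eyes[Eye.LEFT])
    right = _screen_angles(points, eyes[Eye.RIGHT])
    if cue is CueCondition.PERSPECTIVE:
        if eye is Eye.LEFT:
            right = np.full_like(right, np.nan)
        else:
            left = np.full_like(left, np.nan)

    return DotField(
        cue_condition=cue,
        stimulated_eye=eye,
        pose=pose,
        geom=geom,
        world_xyz=points,
        left_screen=left,
        right_screen=right,
        axes=axes,
    )
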