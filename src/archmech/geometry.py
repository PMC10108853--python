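"""Planar reconstruction of fascicle architecture from segmented ultrasound.

All geometry is 2D, in the scan plane: x runs along the muscle's line of
action (proximal positive), y is depth with superficial positive.  Two input
routes are supported, matching how vastus lateralis architecture is measured
in practice:

* dual-probe scans: aponeurosis and fascicle point lists segmented in each
  probe's local frame, fused into the distal probe's frame by rigid
  transforms, with the fascicle linearly extrapolated to the superficial
  aponeurosis;
* panoramic scans: dominant fascicle-fragment orientations in the deep and
  superficial regions, joined into a composite fascicle by an
  orientation-interpolating spline between the aponeuroses.

Lines are fitted to segmented points by total least squares (principal axis),
which is robust to segmentation jitter in either coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class GeometryError(ValueError):
    """Degenerate or inconsistent geometric configuration."""


class ReconstructionError(ValueError):
    """No valid fascicle reconstruction exists for the given inputs."""


@dataclass
class ProbeFrame:
    """Rigid placement of one probe's image frame in the common (muscle) frame.

    ``rotation_deg`` includes the deliberate 5 deg inter-probe angulation of
    the dual-transducer holder.  Local coordinates map to common coordinates
    as ``R(rotation) @ p + origin``.
    """

    probe_id: str
    origin: tuple[float, float] = (0.0, 0.0)
    rotation_deg: float = 0.0
    field_width: float = 60.0
    field_depth: float = 40.0

    def __post_init__(self) -> None:
        if self.field_width <= 0 or self.field_depth <= 0:
            raise ValueError("probe field dimensions must be positive")

    def _rot(self) -> np.ndarray:
        c, s = np.cos(np.radians(self.rotation_deg)), np.sin(np.radians(self.rotation_deg))
        return np.array([[c, -s], [s, c]])

    def to_common(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self._rot().T + np.asarray(self.origin)

    def to_local(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return (pts - np.asarray(self.origin)) @ self._rot()


@dataclass
class ArchitectureMeasure:
    """Fascicle length, pennation and thickness for one condition.

    Conditions follow the three standard measurement set-ups: panoramic scan
    at rest with the knee extended (REST_0), dual-probe scan at rest at 60 deg
    flexion (REST_60) and during MVC at 60 deg (MVC_60).
    """

    condition: str
    fascicle_length: float
    pennation: float
    thickness: float

    def __post_init__(self) -> None:
        if self.fascicle_length <= 0 or self.thickness <= 0:
            raise ValueError("fascicle length and thickness must be positive")
        if not 0.0 < self.pennation < 90.0:
            raise ValueError("pennation must lie in (0, 90) degrees")


def fit_line_tls(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares line through >= 2 points.

    Returns (centroid, unit direction); the direction is the principal axis
    of the point cloud, oriented toward positive x (or positive y if
    vertical).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise GeometryError("line fit needs at least two 2-D points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # principal axis via the larger eigenvector of the 2x2 scatter matrix
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    direction = v[:, int(np.argmax(w))]
    if w.max() <= 1e-24:
        raise GeometryError("points are coincident; no line defined")
    if direction[0] < 0 or (direction[0] == 0 and direction[1] < 0):
        direction = -direction
    return centroid, direction


def fuse_probe_frames(
    segments: dict[str, list[np.ndarray]],
    frames: dict[str, ProbeFrame],
) -> dict[str, list[np.ndarray]]:
    """Express per-probe segmented point lists in the distal probe's frame.

    ``segments`` maps probe_id -> list of (n, 2) local-coordinate arrays;
    ``frames`` maps probe_id -> ProbeFrame.  The distal probe is the
    reference; rigid transforms preserve all lengths and angles.
    """
    if "distal" not in frames:
        raise GeometryError("a 'distal' reference frame is required")
    ref = frames["distal"]
    fused: dict[str, list[np.ndarray]] = {}
    for probe_id, seg_list in segments.items():
        if probe_id not in frames:
            raise GeometryError(f"no frame provided for probe {probe_id!r}")
        frame = frames[probe_id]
        fused[probe_id] = [ref.to_local(frame.to_common(s)) for s in seg_list]
    return fused


def _intersect_ray_line(
    start: np.ndarray, direction: np.ndarray, line_point: np.ndarray, line_dir: np.ndarray
) -> tuple[np.ndarray, float]:
    """Intersection of the ray start + t*direction (t >= 0) with a line."""
    mat = np.column_stack([direction, -line_dir])
    det = np.linalg.det(mat)
    if abs(det) < 1e-12:
        raise GeometryError("fascicle and aponeurosis lines are parallel")
    t, _ = np.linalg.solve(mat, line_point - start)
    if t < 0:
        raise GeometryError(
            "aponeurosis intersection lies behind the fascicle's deep insertion"
        )
    return start + t * direction, float(t)


def extrapolate_fascicle_length(
    fascicle: np.ndarray,
    superficial: np.ndarray,
    deep: np.ndarray,
) -> tuple[float, float]:
    """Fascicle length (mm) and pennation (deg) by linear extrapolation.

    The fascicle's visible segment is extended from its deep insertion (the
    point nearest the deep aponeurosis, i.e. lowest y) to the total-least-
    squares line of the superficial aponeurosis; length is the distance from
    insertion to intersection; pennation is the acute angle between the
    fascicle and the deep aponeurosis lines.
    """
    f_pts = np.asarray(fascicle, dtype=float)
    _, f_dir = fit_line_tls(f_pts)
    s_pt, s_dir = fit_line_tls(superficial)
    d_pt, d_dir = fit_line_tls(deep)

    # deep insertion: the fascicle endpoint nearest the deep aponeurosis line
    # (frame-independent, unlike any global axis convention)
    d_normal = np.array([-d_dir[1], d_dir[0]])
    dists = np.abs((f_pts - d_pt) @ d_normal)
    deep_insertion = f_pts[int(np.argmin(dists))]
    # orient the fascicle direction so the ray reaches the superficial line
    try:
        intersection, t = _intersect_ray_line(deep_insertion, f_dir, s_pt, s_dir)
    except GeometryError as err:
        if "parallel" in str(err):
            raise
        intersection, t = _intersect_ray_line(deep_insertion, -f_dir, s_pt, s_dir)
        f_dir = -f_dir
    length = float(np.linalg.norm(intersection - deep_insertion))
    cosang = abs(float(np.dot(f_dir, d_dir)))
    pennation = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return length, pennation


def shortest_candidate_length(candidates: list[float]) -> float:
    """The retained fascicle length is the shortest valid candidate.

    When a fascicle is extrapolated to superficial-aponeurosis lines from
    more than one field of view, the reconstruction keeping the fascicle
    shortest is used.
    """
    valid = [c for c in candidates if np.isfinite(c) and c > 0]
    if not valid:
        raise ReconstructionError("no finite positive candidate length")
    return float(min(valid))


def muscle_thickness(
    superficial: np.ndarray,
    deep: np.ndarray,
    roi: tuple[float, float],
    n_samples: int = 101,
) -> float:
    """Mean perpendicular distance between the aponeuroses across the ROI.

    Sampled uniformly along the deep aponeurosis between the ROI's x limits.
    """
    x0, x1 = roi
    if not x1 > x0:
        raise ValueError("region of interest must have positive width")
    s_pt, s_dir = fit_line_tls(superficial)
    d_pt, d_dir = fit_line_tls(deep)
    if abs(d_dir[0]) < 1e-12:
        raise GeometryError("deep aponeurosis is vertical; cannot span the ROI")
    xs = np.linspace(x0, x1, n_samples)
    base = d_pt[None, :] + ((xs - d_pt[0]) / d_dir[0])[:, None] * d_dir[None, :]
    normal = np.array([-s_dir[1], s_dir[0]])
    dists = (base - s_pt) @ normal
    if dists.max() > 1e-9 and dists.min() < -1e-9:
        raise GeometryError("aponeuroses cross inside the region of interest")
    return float(np.mean(np.abs(dists)))


def _dominant_orientation(fragments: np.ndarray | list[float]) -> float:
    """Dominant fascicle orientation (deg) as the mean fragment angle."""
    angles = np.asarray(fragments, dtype=float)
    if angles.size == 0:
        raise ReconstructionError("at least one fragment orientation is required")
    return float(np.mean(angles))


def composite_fascicle_curve(
    theta_deep_deg: float,
    theta_sup_deg: float,
    thickness: float,
    n_points: int = 2001,
) -> tuple[np.ndarray, float]:
    """Composite fascicle as an orientation-interpolating spline.

    The curve starts at the deep aponeurosis with inclination
    ``theta_deep_deg`` and reaches the superficial aponeurosis with
    inclination ``theta_sup_deg``; between them the inclination varies
    linearly with depth (a Hermite-style constraint: end tangents equal the
    regional dominant orientations).  Returns the sampled (x, y) polyline and
    its arc length.  For equal angles this reduces exactly to a straight
    fascicle of length thickness / sin(theta).
    """
    th_d = np.radians(theta_deep_deg)
    th_s = np.radians(theta_sup_deg)
    if not (0 < th_d < np.pi / 2 and 0 < th_s < np.pi / 2):
        raise ReconstructionError(
            "fragment orientations must lie strictly between 0 and 90 deg"
        )
    y = np.linspace(0.0, thickness, n_points)
    phi = th_d + (th_s - th_d) * (y / thickness)
    # dx/dy = cot(phi); ds/dy = 1/sin(phi)
    dxdy = 1.0 / np.tan(phi)
    x = np.concatenate([[0.0], np.cumsum((dxdy[1:] + dxdy[:-1]) / 2 * np.diff(y))])
    dsdy = 1.0 / np.sin(phi)
    arc = float(np.trapezoid(dsdy, y))
    return np.column_stack([x, y]), arc


def composite_fascicle_panoramic(
    superficial_fragments: np.ndarray | list[float],
    deep_fragments: np.ndarray | list[float],
    superficial_apo: np.ndarray,
    deep_apo: np.ndarray,
    roi: tuple[float, float],
    n_points: int = 2001,
) -> ArchitectureMeasure:
    """Reconstruct architecture from a panoramic scan's fragment orientations.

    Fragment orientations are given in degrees relative to the x axis; the
    deep aponeurosis line defines the pennation reference.  Thickness is the
    mean inter-aponeurosis distance over the ROI; fascicle length is the arc
    length of the composite curve anchored between the aponeuroses.
    """
    thickness = muscle_thickness(superficial_apo, deep_apo, roi)
    d_pt, d_dir = fit_line_tls(deep_apo)
    apo_angle = float(np.degrees(np.arctan2(d_dir[1], d_dir[0])))
    th_deep = _dominant_orientation(deep_fragments) - apo_angle
    th_sup = _dominant_orientation(superficial_fragments) - apo_angle
    _, arc = composite_fascicle_curve(th_deep, th_sup, thickness, n_points)
    return ArchitectureMeasure(
        condition="REST_0",
        fascicle_length=arc,
        pennation=th_deep,
        thickness=thickness,
    )
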