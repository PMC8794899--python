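"""Cochlear point-cloud geometry.

Canonical-frame alignment of lateral-wall point clouds, angular unwrapping,
spline fitting with arc length, and extraction of the basal-turn landmark
distances (A, B, H) from geometry.

Canonical frame
---------------
* the modiolar (spiral) axis is the z-axis,
* the basal turn (first 360 deg from the round window) lies in the
  xy-plane (total-least-squares plane of the basal-turn points),
* the round window (RW) sits at angular coordinate 0, on the +x side,
* the trajectory winds counter-clockwise in xy, so the unwrapped angle
  theta increases from 0 at the RW toward the apex (typically up to
  ~900 deg for 2.5 turns).

Points are expected in trajectory order starting at the RW (the order in
which a rater would click them, or the order the synthetic generator
emits). Units are mm and degrees throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.interpolate import CubicSpline, PchipInterpolator
from scipy.optimize import brentq

__all__ = [
    "GeometryError",
    "AlignmentError",
    "OrderingError",
    "InsufficientDataError",
    "MeasurementError",
    "LateralWallPointCloud",
    "RigidTransform",
    "AlignedCochlea",
    "SplineCurve",
    "align_to_modiolar_frame",
    "unwrap_angles",
    "angular_bin_average",
    "fit_lateral_wall_spline",
    "arc_length",
    "measure_A",
    "measure_B",
    "measure_H",
    "extract_lateral_wall",
]


class GeometryError(ValueError):
    pass


class AlignmentError(GeometryError):
    """Axis/plane estimation failed (degenerate cloud)."""


class OrderingError(GeometryError):
    """Point sequence does not wind monotonically around the axis."""


class InsufficientDataError(GeometryError):
    pass


class MeasurementError(GeometryError):
    pass


@dataclass(frozen=True)
class LateralWallPointCloud:
    """Ordered lateral-wall points with a marked round-window point.

    ``points`` is an (n, 3) float array in mm, in trajectory order from
    base to apex; ``rw_index`` marks the round-window point (normally 0).
    """

    points: np.ndarray
    rw_index: int = 0
    side: str = "right"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if len(pts) < 4:
            raise InsufficientDataError("need at least 4 points")
        if not np.all(np.isfinite(pts)):
            raise ValueError("points must be finite")
        if not 0 <= self.rw_index < len(pts):
            raise ValueError("rw_index out of range")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        d = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(d < 1e-9):
            raise ValueError("duplicate points (within 1e-9 mm)")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class RigidTransform:
    """x -> rotation @ x + translation, with det(rotation) = +1."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3, translation length 3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation determinant must be +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self.compose(other)).apply == self.apply(other.apply(x))."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass(frozen=True)
class AlignedCochlea:
    """A point cloud expressed in the canonical modiolar frame."""

    cloud: LateralWallPointCloud
    transform: RigidTransform = field(default_factory=RigidTransform.identity)


def _tls_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares plane: (centroid, unit normal)."""
    c = points.mean(axis=0)
    q = points - c
    _, s, vt = np.linalg.svd(q, full_matrices=False)
    if len(points) < 3 or s[1] < 1e-9 * max(s[0], 1e-300):
        raise AlignmentError("degenerate (collinear) point cloud")
    return c, vt[2]


def _rotation_aligning(v: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector v onto unit vector target."""
    v = v / np.linalg.norm(v)
    target = target / np.linalg.norm(target)
    c = float(np.dot(v, target))
    if c > 1.0 - 1e-14:
        return np.eye(3)
    if c < -1.0 + 1e-14:
        # 180 deg: rotate about any axis perpendicular to v
        axis = np.cross(v, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(v, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return _rodrigues(axis, np.pi)
    axis = np.cross(v, target)
    angle = np.arctan2(np.linalg.norm(axis), c)
    return _rodrigues(axis / np.linalg.norm(axis), angle)


def _rodrigues(axis: np.ndarray, angle: float) -> np.ndarray:
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _rotz(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _unwrap_deg(pts_xy: np.ndarray, center: np.ndarray) -> np.ndarray:
    ang = np.degrees(np.arctan2(pts_xy[:, 1] - center[1],
                                pts_xy[:, 0] - center[0]))
    return np.degrees(np.unwrap(np.radians(ang)))


def _spiral_center(pts: np.ndarray, center0: np.ndarray,
                   n_iter: int = 12) -> np.ndarray:
    """Spiral axis position in xy by Gauss-Newton radius-profile fitting.

    Models the radius about a candidate center as a smooth low-order
    polynomial of the unwrapped angle and updates the center along the
    radial residuals (a center offset epsilon shows up as a
    -epsilon*cos(theta - phi) radius error, exactly the direction the
    update resolves). Unbiased for decaying spirals, where per-turn
    circle fits are systematically offset.
    """
    center = np.asarray(center0, dtype=float)
    for _ in range(n_iter):
        dx = pts[:, 0] - center[0]
        dy = pts[:, 1] - center[1]
        r = np.hypot(dx, dy)
        theta = np.degrees(np.unwrap(np.arctan2(dy, dx)))
        s = (theta - theta[0]) / max(np.ptp(theta), 1.0)
        design = np.column_stack([np.ones_like(s), s, s ** 2, s ** 3])
        beta, *_ = np.linalg.lstsq(design, r, rcond=None)
        resid = r - design @ beta
        J = np.column_stack([-dx / r, -dy / r])
        step, *_ = np.linalg.lstsq(J, -resid, rcond=None)
        norm = np.linalg.norm(step)
        if norm > 1.0:  # damp: keep the center inside the spiral
            step = step / norm
        center = center + step
        if np.linalg.norm(step) < 1e-12:
            break
    return center


def _residual_tilt(pts: np.ndarray, theta_deg: np.ndarray) -> np.ndarray:
    """Small residual tilt (a, b) of the spiral axis w.r.t. z.

    A small rotation of the true axis away from z adds ``a*x + b*y`` to
    every z-coordinate on top of the smooth axial rise z(theta). Regressing
    z on a flexible monotone-capable trend in theta plus x and y separates
    the two: the x/y coefficients are the tilt. Unlike a best-fit plane of
    the basal turn, this is unbiased for pitched spirals (a helix's
    best-fit plane is genuinely tilted relative to its axis). The trend
    uses a linear-hinge basis so piecewise-linear pitch profiles are
    representable exactly; the hinge spacing (~1/8 of the extent) is well
    below one turn, so the basis cannot absorb the period-360 tilt term.
    """
    th = (theta_deg - theta_deg[0]) / max(np.ptp(theta_deg), 1.0)
    hinges = [np.maximum(th - k / 8.0, 0.0) for k in range(8)]
    design = np.column_stack([np.ones_like(th), *hinges,
                              pts[:, 0], pts[:, 1]])
    coef, *_ = np.linalg.lstsq(design, pts[:, 2], rcond=None)
    return coef[-2:]


def align_to_modiolar_frame(cloud: LateralWallPointCloud,
                            max_iter: int = 10,
                            tol: float = 1e-10) -> AlignedCochlea:
    """Rigidly align a lateral-wall cloud to the canonical modiolar frame.

    Fixed-point iteration: (1) the total-least-squares plane of all points
    seeds the axis direction; (2) the axis position is the mean of
    per-turn least-squares circle centers; (3) the axis direction is
    refined by the detrended-tilt regression (axial rise modelled as a
    smooth function of the winding angle; leftover x/y dependence of z is
    tilt); (4) the frame is rotated about z so the RW lies at angle 0 and
    shifted so the basal-turn (first 360 deg) mean height is z = 0. The
    z-sign is chosen so the ordered trajectory winds counter-clockwise
    (theta increasing apically).

    The modiolar axis maps exactly onto z; for a pitched spiral the
    basal-turn best-fit plane is then within the pitch-induced tilt of
    the xy-plane (a property of the anatomy, not an alignment error).
    """
    pts0 = cloud.points
    if len(pts0) < 10:
        raise InsufficientDataError("alignment needs at least 10 points")
    # start at RW so the basal-turn window is well defined
    if cloud.rw_index != 0:
        pts0 = np.roll(pts0, -cloud.rw_index, axis=0)

    _, normal = _tls_plane(pts0)
    R = _rotation_aligning(normal, np.array([0.0, 0.0, 1.0]))
    t = np.zeros(3)
    pts = pts0 @ R.T

    for _ in range(max_iter):
        center_xy = _spiral_center(pts, pts[:, :2].mean(axis=0))
        theta = _unwrap_deg(pts[:, :2], center_xy)
        if theta[-1] < theta[0]:
            # flip the frame (rotate pi about x) so winding becomes CCW
            F = np.diag([1.0, -1.0, -1.0])
            R, t, pts = F @ R, F @ t, pts @ F.T
            center_xy = center_xy * np.array([1.0, -1.0])
            theta = _unwrap_deg(pts[:, :2], center_xy)
        theta = theta - theta[0]
        if theta[-1] <= 360.0:
            raise AlignmentError("cloud must span more than one full turn")

        centered = pts - np.array([center_xy[0], center_xy[1], 0.0])
        a, b = _residual_tilt(centered, theta)
        n_axis = np.array([-a, -b, 1.0])
        n_axis /= np.linalg.norm(n_axis)
        R_fix = _rotation_aligning(n_axis, np.array([0.0, 0.0, 1.0]))
        R, t, pts = R_fix @ R, R_fix @ t, pts @ R_fix.T

        center_xy = _spiral_center(pts, pts[:, :2].mean(axis=0))
        theta = _unwrap_deg(pts[:, :2], center_xy)
        theta = theta - theta[0]
        z0 = pts[theta <= 360.0, 2].mean()
        shift = np.array([center_xy[0], center_xy[1], z0])
        t, pts = t - shift, pts - shift
        # RW to angle zero
        phi = np.arctan2(pts[0, 1], pts[0, 0])
        Rz = _rotz(-phi)
        R, t, pts = Rz @ R, Rz @ t, pts @ Rz.T

        tilt = float(np.hypot(a, b))
        if tilt < tol and np.linalg.norm(shift) < 1e-8 and abs(phi) < 1e-10:
            break

    transform = RigidTransform(R, t)
    aligned_cloud = LateralWallPointCloud(pts, rw_index=0, side=cloud.side)
    return AlignedCochlea(cloud=aligned_cloud, transform=transform)


def unwrap_angles(aligned, strict: bool = True) -> np.ndarray:
    """Continuous unwrapped angles (deg) along the ordered trajectory.

    0 at the round window, strictly increasing toward the apex. Accepts an
    :class:`AlignedCochlea` or a plain (n, 3) array in canonical pose.
    ``strict=False`` skips the monotonicity check (noisy dense clouds
    wobble locally; binning restores monotone order).
    """
    pts = aligned.cloud.points if isinstance(aligned, AlignedCochlea) \
        else np.atleast_2d(np.asarray(aligned, dtype=float))
    if len(pts) == 1:
        return np.zeros(1)
    theta = _unwrap_deg(pts[:, :2], np.zeros(2))
    theta = theta - theta[0]
    if strict and np.any(np.diff(theta) <= 0):
        raise OrderingError(
            "projected angles are not strictly increasing along the "
            "trajectory (self-crossing or unordered points)"
        )
    return theta


def angular_bin_average(aligned: AlignedCochlea,
                        width_deg: float = 15.0) -> AlignedCochlea:
    """Average points within angular windows of ``width_deg``.

    Densely sampled, jittery clouds (hundreds of points with measurement
    noise comparable to the point spacing) make an interpolating spline
    chase the noise and inflate the arc length; window-averaging first
    restores a smooth trajectory. Averaging along a curved arc pulls the
    mean toward the chord, so the in-plane radius of each bin mean is
    re-expanded by the arc-to-chord factor (hw / sin(hw) for angular
    half-width hw) - exact for circular arcs, a second-order correction
    for slowly decaying spirals. The RW stays the first point.
    """
    theta = unwrap_angles(aligned, strict=False)
    pts = aligned.cloud.points
    bins = np.floor(theta / width_deg).astype(int)
    out = []
    for b in np.unique(bins):
        sel = bins == b
        mean = pts[sel].mean(axis=0)
        hw = 0.5 * np.radians(np.ptp(theta[sel]))
        if hw > 1e-9:
            mean[:2] *= hw / np.sin(hw)
        out.append(mean)
    cloud = LateralWallPointCloud(np.array(out), rw_index=0,
                                  side=aligned.cloud.side)
    return AlignedCochlea(cloud=cloud, transform=aligned.transform)


_GL_NODES, _GL_WEIGHTS = leggauss(8)


class SplineCurve:
    """Interpolating cubic 3D spline with an angular coordinate map.

    Parameterised by cumulative chordal length t; exposes theta(t) and its
    inverse via monotone (PCHIP) interpolation of the unwrapped angles at
    the knots. Arc lengths are computed by per-piece Gauss-Legendre
    quadrature of |C'(t)| (absolute error far below 1e-6 mm).

    ``length_scale`` (default 1) is a multiplicative arc-length debias
    applied by the denoised fitting path: residual knot noise inflates
    chord lengths by a known moment term which is subtracted as a global
    relative factor.
    """

    length_scale: float = 1.0

    def __init__(self, points: np.ndarray, theta_deg: np.ndarray) -> None:
        points = np.asarray(points, dtype=float)
        theta_deg = np.asarray(theta_deg, dtype=float)
        if len(points) < 4:
            raise InsufficientDataError("spline needs at least 4 points")
        chord = np.linalg.norm(np.diff(points, axis=0), axis=1)
        if np.any(chord <= 0):
            raise ValueError("coincident consecutive points")
        t = np.concatenate([[0.0], np.cumsum(chord)])
        self.t = t
        self.knot_theta = theta_deg
        self.spline = CubicSpline(t, points, axis=0)
        self._deriv = self.spline.derivative()
        if np.any(np.diff(theta_deg) <= 0):
            raise OrderingError("knot angles must be strictly increasing")
        self._theta_of_t = PchipInterpolator(t, theta_deg)
        self._t_of_theta = PchipInterpolator(theta_deg, t)

    # -- coordinate maps -------------------------------------------------
    @property
    def theta_range(self) -> tuple[float, float]:
        return float(self.knot_theta[0]), float(self.knot_theta[-1])

    def t_of_theta(self, theta_deg) -> np.ndarray:
        lo, hi = self.theta_range
        theta = np.asarray(theta_deg, dtype=float)
        if np.any(theta < lo - 1e-9) or np.any(theta > hi + 1e-9):
            raise MeasurementError(
                f"theta outside curve range [{lo:.1f}, {hi:.1f}] deg")
        return self._t_of_theta(np.clip(theta, lo, hi))

    def theta_of_t(self, t) -> np.ndarray:
        return self._theta_of_t(t)

    def point_at_theta(self, theta_deg) -> np.ndarray:
        return self.spline(self.t_of_theta(theta_deg))

    def __call__(self, t) -> np.ndarray:
        return self.spline(t)

    # -- arc length ------------------------------------------------------
    def _speed(self, t) -> np.ndarray:
        return np.linalg.norm(self._deriv(t), axis=-1)

    def arc_length_t(self, t0: float, t1: float) -> float:
        """Arc length between curve parameters t0 <= t1."""
        if t1 < t0:
            raise ValueError("t1 must be >= t0")
        knots = self.t
        # piece boundaries intersected with [t0, t1]
        edges = knots[(knots > t0) & (knots < t1)]
        bounds = np.concatenate([[t0], edges, [t1]])
        a, b = bounds[:-1], bounds[1:]
        mid = 0.5 * (a + b)
        half = 0.5 * (b - a)
        # (pieces, nodes) evaluation grid
        ts = mid[:, None] + half[:, None] * _GL_NODES[None, :]
        speeds = self._speed(ts.ravel()).reshape(ts.shape)
        raw = float(np.sum(half[:, None] * _GL_WEIGHTS[None, :] * speeds))
        return raw * self.length_scale

    def arc_length(self, theta_start: float, theta_end: float) -> float:
        """Arc length (mm) between two unwrapped angles (degrees)."""
        if theta_end < theta_start:
            raise MeasurementError("theta_start must be <= theta_end")
        t0 = float(self.t_of_theta(theta_start))
        t1 = float(self.t_of_theta(theta_end))
        return self.arc_length_t(t0, t1)

    def total_arc_length(self) -> float:
        return self.arc_length_t(float(self.t[0]), float(self.t[-1]))


def _order_endpoint(pts: np.ndarray, idx: np.ndarray,
                    at_idx: float) -> tuple[np.ndarray, float]:
    """Local-linear endpoint estimate in trajectory order.

    Fits position against the sample index over the first/last few points
    and predicts at the end index; returns the prediction and its leverage
    (prediction variance in units of the per-point noise variance). Using
    trajectory order avoids the angle-sorting scramble near the apex,
    where angular noise exceeds the angular point spacing.
    """
    x = idx - idx.mean()
    design = np.column_stack([np.ones_like(x, dtype=float), x])
    beta, *_ = np.linalg.lstsq(design, pts[idx], rcond=None)
    x0 = at_idx - idx.mean()
    leverage = 1.0 / len(idx) + x0 ** 2 / (x ** 2).sum()
    return beta[0] + beta[1] * x0, float(leverage)


def _denoised_spline(aligned: AlignedCochlea, window_mm: float,
                     end_fit_points: int) -> SplineCurve:
    """Noise-robust spline for dense jittery clouds.

    Points are averaged in windows of ~``window_mm`` of projected arc
    length (windows widen angularly toward the small-radius apex), each
    mean re-expanded by the exact discrete arc-to-chord factor; the two
    curve endpoints are local-linear predictions in trajectory order; and
    the arc length is debiased by the moment term 3*var/L that residual
    knot noise adds per segment, with the per-point noise variance
    estimated from within-window quadratic-fit residuals.
    """
    pts_in = aligned.cloud.points
    n = len(pts_in)
    theta_in = unwrap_angles(aligned, strict=False)
    m_end = min(end_fit_points, n)
    p_start, lev_start = _order_endpoint(pts_in, np.arange(m_end), 0)
    p_end, lev_end = _order_endpoint(pts_in, np.arange(n - m_end, n), n - 1)

    order = np.argsort(theta_in, kind="stable")
    theta, pts = theta_in[order], pts_in[order]
    radius = np.hypot(pts[:, 0], pts[:, 1])
    ds = np.radians(np.diff(theta)) * 0.5 * (radius[:-1] + radius[1:])
    s = np.concatenate([[0.0], np.cumsum(ds)])
    bins = np.floor(s / window_mm).astype(int)

    knot_theta, knot_pts, leverages = [], [], []
    resid_sq, resid_df = 0.0, 0
    for b in np.unique(bins):
        sel = bins == b
        m = int(sel.sum())
        mean = pts[sel].mean(axis=0)
        if m >= 5:
            x = theta[sel] - theta[sel].mean()
            design = np.column_stack([np.ones_like(x), x, x ** 2])
            _, res, *_ = np.linalg.lstsq(design, pts[sel], rcond=None)
            if len(res):
                resid_sq += float(res.sum())
                resid_df += 3 * (m - 3)
        # exact discrete arc-to-chord correction: the mean of points on an
        # arc lies inside it by the resultant length of their unit vectors
        resultant = np.abs(np.exp(1j * np.radians(theta[sel])).mean())
        if resultant > 0.1:
            mean[:2] /= resultant
        knot_theta.append(theta[sel].mean())
        knot_pts.append(mean)
        leverages.append(1.0 / m)

    def _local_angle(p: np.ndarray, near: float) -> float:
        phi = np.degrees(np.arctan2(p[1], p[0]))
        return near + (phi - near + 180.0) % 360.0 - 180.0

    th_start = min(_local_angle(p_start, knot_theta[0]),
                   knot_theta[0] - 1e-6)
    th_end = max(_local_angle(p_end, knot_theta[-1]),
                 knot_theta[-1] + 1e-6)
    knot_theta = np.r_[th_start, knot_theta, th_end] - th_start
    knot_pts = np.vstack([p_start, knot_pts, p_end])
    leverages = np.r_[lev_start, leverages, lev_end]

    curve = SplineCurve(knot_pts, knot_theta)
    sigma2 = resid_sq / resid_df if resid_df else 0.0
    if sigma2 > 0:
        seg = np.linalg.norm(np.diff(knot_pts, axis=0), axis=1)
        var = sigma2 * leverages
        inflation = float((1.5 * (var[:-1] + var[1:]) / seg).sum())
        raw = curve.total_arc_length()
        curve.length_scale = max(1.0 - inflation / raw, 0.0)
    return curve


def fit_lateral_wall_spline(aligned: AlignedCochlea,
                            denoise_window_mm: float | None = None,
                            end_fit_points: int = 8) -> SplineCurve:
    """Interpolating cubic spline through the ordered lateral-wall points.

    For sparse, clean clouds (manually clicked points) the spline
    interpolates the points directly, ordered by unwrapped angle (input
    order resolves ties). For dense clouds with click/segmentation jitter
    pass ``denoise_window_mm`` (~1 mm): points are then window-averaged
    along the trajectory before interpolation and the arc length is
    debiased for residual noise (see :func:`_denoised_spline`).
    """
    if denoise_window_mm is not None:
        return _denoised_spline(aligned, denoise_window_mm, end_fit_points)
    theta = unwrap_angles(aligned)
    order = np.argsort(theta, kind="stable")
    return SplineCurve(aligned.cloud.points[order], theta[order])


def arc_length(curve: SplineCurve, theta_start: float,
               theta_end: float) -> float:
    """Module-level convenience wrapper over :meth:`SplineCurve.arc_length`."""
    return curve.arc_length(theta_start, theta_end)


def _polar_angle_crossing(curve: SplineCurve, target_deg: float) -> np.ndarray:
    """Point on the curve where the xy polar angle equals target (deg).

    Searches near theta = target using the angular map, solving on the
    actual spline so interpolation between knots is honoured.
    """
    lo, hi = curve.theta_range
    if target_deg < lo + 1e-9 or target_deg > hi - 1e-9:
        raise MeasurementError(
            f"polar angle {target_deg} deg not covered by the curve")
    span = 60.0
    t_lo = float(curve.t_of_theta(max(lo, target_deg - span)))
    t_hi = float(curve.t_of_theta(min(hi, target_deg + span)))

    def wrapped_diff(t: float) -> float:
        p = curve(t)
        phi = np.degrees(np.arctan2(p[1], p[0]))
        return (phi - target_deg + 180.0) % 360.0 - 180.0

    f_lo, f_hi = wrapped_diff(t_lo), wrapped_diff(t_hi)
    if f_lo * f_hi > 0:
        raise MeasurementError(
            f"could not bracket the wall at polar angle {target_deg} deg")
    t_star = brentq(wrapped_diff, t_lo, t_hi, xtol=1e-10)
    return curve(t_star)


def measure_A(aligned: AlignedCochlea, curve: SplineCurve | None = None) -> float:
    """A-value: RW to the opposite lateral wall through the modiolus (mm).

    Measured in the xy-projection of the canonical frame: the RW sits at
    polar angle 0 and the ray through the modiolar axis meets the far
    basal-turn wall at polar angle 180 deg.
    """
    if curve is None:
        curve = fit_lateral_wall_spline(aligned)
    rw = curve(float(curve.t[0]))
    far = _polar_angle_crossing(curve, 180.0)
    return float(np.linalg.norm(rw[:2] - far[:2]))


def measure_B(aligned: AlignedCochlea, curve: SplineCurve | None = None) -> float:
    """B-value: wall-to-wall basal-turn chord perpendicular to A (mm)."""
    if curve is None:
        curve = fit_lateral_wall_spline(aligned)
    p1 = _polar_angle_crossing(curve, 90.0)
    p2 = _polar_angle_crossing(curve, 270.0)
    return float(np.linalg.norm(p1[:2] - p2[:2]))


def measure_H(aligned: AlignedCochlea, curve: SplineCurve | None = None,
              n_samples: int = 2000) -> float:
    """H-value: axial extent (max z - min z) of the wall trajectory (mm)."""
    if curve is None:
        curve = fit_lateral_wall_spline(aligned)
    lo, hi = curve.theta_range
    if hi - lo < 540.0:
        warnings.warn("cloud spans < 1.5 turns; apex (H) poorly defined",
                      stacklevel=2)
    ts = np.linspace(float(curve.t[0]), float(curve.t[-1]), n_samples)
    z = curve(ts)[:, 2]
    return float(z.max() - z.min())


def extract_lateral_wall(points: np.ndarray, spacing: float,
                         bin_width_deg: float = 12.0,
                         gap_factor: float = 2.2,
                         max_step_mm: float = 1.8) -> np.ndarray:
    """Pick lateral-wall points from a segmented duct-boundary cloud.

    Emulates a rater clicking the outer (lateral) wall on a thresholded 3D
    model (canonical pose assumed, round window near polar angle 0):

    1. points are binned by wrapped polar angle about the modiolar axis;
    2. within each bin, the duct's crossings of that angular half-plane
       (one per turn) are separated by single-linkage clustering in the
       (radius, z) section at ``gap_factor * spacing`` reach;
    3. each crossing contributes one wall candidate: the average of its
       near-outermost points (within half a voxel of the cluster's
       maximum radius);
    4. candidates are chained into the wall trajectory by spatial
       continuity, starting from the basal (largest-radius) candidate
       near angle 0 and always stepping to the nearest unused candidate
       in the next bin; the chain stops when no candidate lies within
       ``max_step_mm``.

    Returns wall points ordered base to apex. Boundary voxel centers sit
    inside the true wall, so the resulting duct length is biased slightly
    short - the voxel-resolution underestimation that motivates the 10/9
    correction.
    """
    from scipy.sparse.csgraph import connected_components
    from scipy.spatial import cKDTree

    pts = np.asarray(points, dtype=float)
    r = np.hypot(pts[:, 0], pts[:, 1])
    phi = np.degrees(np.arctan2(pts[:, 1], pts[:, 0])) % 360.0
    n_bins = int(round(360.0 / bin_width_deg))
    candidates: list[list[np.ndarray]] = [[] for _ in range(n_bins)]
    for b in range(n_bins):
        sel = (phi >= b * bin_width_deg) & (phi < (b + 1) * bin_width_deg)
        if not sel.any():
            continue
        idx = np.where(sel)[0]
        rz = np.column_stack([r[idx], pts[idx, 2]])
        tree = cKDTree(rz)
        graph = tree.sparse_distance_matrix(tree, gap_factor * spacing,
                                            output_type="coo_matrix")
        _, labels = connected_components(graph, directed=False)
        for lab in np.unique(labels):
            grp = idx[labels == lab]
            rmax = r[grp].max()
            top = grp[r[grp] >= rmax - 0.5 * spacing]
            candidates[b].append(pts[top].mean(axis=0))

    if not candidates[0]:
        raise MeasurementError("no boundary points near the round window")
    # start basally: the largest-radius candidate in the first bin
    start = int(np.argmax([np.hypot(p[0], p[1]) for p in candidates[0]]))
    current = candidates[0].pop(start)
    chain = [current]
    b = 0
    while True:
        b = (b + 1) % n_bins
        pool = candidates[b]
        if not pool:
            break
        dists = [np.linalg.norm(p - current) for p in pool]
        j = int(np.argmin(dists))
        if dists[j] > max_step_mm:
            break
        current = pool.pop(j)
        chain.append(current)
    return np.array(chain)
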