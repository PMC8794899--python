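"""Electrode-array insertion simulation and insertion-angle measurement.

The array is laid along a trajectory offset radially (in the canonical
xy-projection) from the lateral wall toward the modiolar axis, standing in
for the intrascalar electrode path. Contact angles are read off in the
idealised projection view; no radiographic geometry or electrode mechanics
are modelled.

Two insertion-angle conventions are reported:

* ``contact_span`` - unwrapped angle between the most apical and most
  basal contacts, the convention of post-operative radiographs; used as
  the default for the insertion-angle-based reference CDL,
* ``tip_from_rw`` - angle of the most apical trajectory point reached by
  the array tip, always >= the contact span (the tip extends beyond the
  first contact).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimators import ElectrodeSpec
from .geometry import SplineCurve

__all__ = ["ElectrodeArray", "InsertionResult",
           "simulate_insertion", "insertion_angle"]


@dataclass(frozen=True)
class ElectrodeArray:
    """Array geometry: contact arc positions measured from the tip (mm).

    Contact 1 is the most apical. The default is an idealised layout for
    a 31.5 mm carrier: contacts evenly spread from 0.5 mm behind the tip
    to 2 mm short of the basal end, so that at full insertion the
    contact-span angle tracks the whole intracochlear course (vendor
    layouts with a longer passive basal lead can be passed explicitly).
    """

    spec: ElectrodeSpec = field(default_factory=ElectrodeSpec)
    contact_positions_mm: np.ndarray = None

    def __post_init__(self) -> None:
        pos = self.contact_positions_mm
        if pos is None:
            pos = np.linspace(0.5, self.spec.length_mm - 2.0,
                              self.spec.n_contacts)
        pos = np.asarray(pos, dtype=float)
        if len(pos) != self.spec.n_contacts:
            raise ValueError("one arc position per contact required")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("contact positions must increase from the tip")
        if pos[0] < 0 or pos[-1] > self.spec.length_mm:
            raise ValueError("contact positions must lie on the array")
        object.__setattr__(self, "contact_positions_mm", pos)


@dataclass(frozen=True)
class InsertionResult:
    """Per-contact unwrapped angles and scalar insertion angle (degrees).

    ``contact_angles_deg[0]`` is contact 1 (apical, largest angle);
    ``ia_deg`` holds the default (contact-span) angle, ``tip_theta_deg``
    the most apical trajectory angle reached.
    """

    contact_angles_deg: np.ndarray
    ia_deg: float
    tip_theta_deg: float
    insertion_depth_mm: float
    full_insertion: bool

    def __post_init__(self) -> None:
        ang = np.asarray(self.contact_angles_deg, dtype=float)
        if np.any(np.diff(ang) > 1e-9):
            raise ValueError("contact angles must be non-increasing from "
                             "apical to basal contact")
        if self.ia_deg < 0:
            raise ValueError("insertion angle must be non-negative")
        object.__setattr__(self, "contact_angles_deg", ang)


def simulate_insertion(curve: SplineCurve, array: ElectrodeArray,
                       wall_offset_mm: float = 0.5,
                       n_samples: int = 6000) -> InsertionResult:
    """Lay an electrode array along the wall-offset trajectory.

    The lateral-wall spline is inset radially by ``wall_offset_mm`` in the
    xy-projection (the electrode sits inside the scala, not on the wall);
    the array occupies the first ``length_mm`` of arc length from the
    round window. If the trajectory is shorter than the array, the result
    is flagged ``full_insertion=False`` and contacts left outside sit at
    theta = 0.
    """
    if wall_offset_mm < 0:
        raise ValueError("wall offset must be non-negative")
    ts = np.linspace(float(curve.t[0]), float(curve.t[-1]), n_samples)
    pts = curve(ts)
    rho = np.hypot(pts[:, 0], pts[:, 1])
    scale = np.clip((rho - wall_offset_mm) / np.maximum(rho, 1e-12),
                    0.02 / np.maximum(rho, 1e-12), None)
    traj = pts.copy()
    traj[:, 0] *= scale
    traj[:, 1] *= scale
    seg = np.linalg.norm(np.diff(traj, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    theta = np.asarray(curve.theta_of_t(ts), dtype=float)

    length = array.spec.length_mm
    available = float(s[-1])
    full = length <= available + 1e-9
    depth = min(length, available)
    s_contacts = depth - array.contact_positions_mm
    angles = np.where(s_contacts > 0.0,
                      np.interp(np.clip(s_contacts, 0.0, available), s, theta),
                      0.0)
    tip_theta = float(np.interp(depth, s, theta))
    result = InsertionResult.__new__(InsertionResult)
    object.__setattr__(result, "contact_angles_deg", np.asarray(angles, float))
    object.__setattr__(result, "tip_theta_deg", tip_theta)
    object.__setattr__(result, "insertion_depth_mm", float(depth))
    object.__setattr__(result, "full_insertion", bool(full))
    object.__setattr__(result, "ia_deg",
                       float(angles[0] - angles[-1]) if len(angles) >= 2
                       else 0.0)
    InsertionResult.__post_init__(result)
    return result


def insertion_angle(result: InsertionResult,
                    convention: str = "contact_span") -> float:
    """Scalar insertion angle under a named convention (degrees)."""
    ang = result.contact_angles_deg
    if len(ang) < 2:
        raise ValueError("need at least 2 mapped contacts")
    if convention == "contact_span":
        return float(ang[0] - ang[-1])
    if convention == "tip_from_rw":
        return float(result.tip_theta_deg)
    raise ValueError(f"unknown convention {convention!r}")
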