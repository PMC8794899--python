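"""Formula-based cochlear duct length (CDL) estimators.

Implements the three closed-form CDL relations used in pre-operative
cochlear-implant planning, all operating on basal-turn landmark distances
measured in mm:

* the Escude A-value relation  ``LW = 2.62 * A * ln(1 + theta/235)``,
  with ``theta`` in **degrees** (the constant 235 is degree-valued; feeding
  radians silently inflates the result),
* its full-insertion short form ``LW = 2.62 * A * 1.57`` (``theta = 900``,
  i.e. 2.5 turns taken as 100% cochlear coverage),
* the elliptic-circular approximation from A- and B-values scaled by a
  percentage-of-basal-turn-length (pBTL) profile,

plus the organ-of-Corti (x0.9) and resolution (x10/9) corrections and the
coverage / insertion-angle / reference-CDL triplet for a given electrode:

* ``CC(%)  = length_mm / CDL * 100``
* ``IA(deg) = CC * 900 / 100``
* ``CDL    = length_mm * 900 / IA``  (the insertion-angle-based reference)

All lengths are mm, all angles degrees.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Union

__all__ = [
    "FULL_COCHLEA_ANGLE_DEG",
    "ESCUDE_ANGLE_SCALE_DEG",
    "ESCUDE_FACTOR",
    "OC_FACTOR",
    "RESOLUTION_FACTOR",
    "ElectrodeSpec",
    "BasalTurnMetrics",
    "PBTLProfile",
    "CDLEstimate",
    "CoveragePrediction",
    "escude_log_term",
    "cdl_escude",
    "cdl_escude_full",
    "cdl_elliptic",
    "to_organ_of_corti",
    "apply_resolution_correction",
    "predict_cc",
    "predict_ia",
    "cdl_reference_from_ia",
]

#: Angular extent taken as 100% cochlear coverage (2.5 turns).
FULL_COCHLEA_ANGLE_DEG = 900.0
#: Degree-valued constant inside the Escude logarithm.
ESCUDE_ANGLE_SCALE_DEG = 235.0
ESCUDE_FACTOR = 2.62
#: Printed truncation of ln(1 + 900/235) used by the short-form relation.
ESCUDE_PRINTED_CONSTANT = 1.57
#: Lateral wall -> organ of Corti scale factor.
OC_FACTOR = 0.9
#: Resolution correction compensating voxel-scale underestimation.
RESOLUTION_FACTOR = 10.0 / 9.0


class EstimatorDomainError(ValueError):
    """Raised when an estimator input is outside its mathematical domain."""


@dataclass(frozen=True)
class ElectrodeSpec:
    """Physical electrode array description.

    Defaults describe a 31.5 mm straight array with 12 contacts.
    """

    length_mm: float = 31.5
    n_contacts: int = 12
    name: str = "flex-31.5"

    def __post_init__(self) -> None:
        if self.length_mm <= 0:
            raise ValueError("electrode length must be positive")
        if self.n_contacts < 2:
            raise ValueError("electrode needs at least 2 contacts")


@dataclass(frozen=True)
class BasalTurnMetrics:
    """Basal-turn landmark distances for one specimen/modality/rater.

    A : basal-turn diameter, round window to opposite lateral wall through
        the modiolus (mm).
    B : basal-turn width, wall-to-wall chord perpendicular to A (mm).
    H : cochlear height base-to-apex along the modiolar axis (mm).
    """

    A_mm: float
    B_mm: float
    H_mm: float = float("nan")
    modality: str = "synthetic"
    rater_id: str = ""
    specimen_id: str = ""

    def __post_init__(self) -> None:
        if not (self.A_mm > self.B_mm > 0):
            warnings.warn(
                f"unusual basal-turn metrics: expected A > B > 0, got "
                f"A={self.A_mm}, B={self.B_mm}",
                stacklevel=2,
            )
        if not (5.0 < self.A_mm < 13.0):
            warnings.warn(
                f"A-value {self.A_mm} mm outside the (5, 13) mm sanity window",
                stacklevel=2,
            )


class PBTLProfile:
    """Percentage-of-basal-turn-length profile pBTL(theta).

    A positive, non-decreasing scale factor with pBTL(360 deg) = 1: the
    elliptic-circular bracket is a basal-turn length and the profile
    extrapolates it to a partial or full duct length.

    The default profile reuses the Escude angular-length shape normalised
    to 1 at 360 deg, ``ln(1 + theta/235) / ln(1 + 360/235)``. It is marked
    ``approximation=True``: the clinical software's tabulated profile is
    proprietary and any other callable may be injected instead.
    """

    def __init__(self, func: Callable[[float], float], name: str,
                 approximation: bool = False) -> None:
        self._func = func
        self.name = name
        self.approximation = approximation

    def __call__(self, theta_deg: float) -> float:
        value = float(self._func(theta_deg))
        if not value > 0:
            raise EstimatorDomainError(
                f"pBTL({theta_deg}) = {value}; profile must be positive"
            )
        return value

    @classmethod
    def escude_shape(cls) -> "PBTLProfile":
        denom = math.log1p(360.0 / ESCUDE_ANGLE_SCALE_DEG)
        return cls(
            lambda theta: math.log1p(theta / ESCUDE_ANGLE_SCALE_DEG) / denom,
            name="escude-shape-normalized",
            approximation=True,
        )

    @classmethod
    def unity(cls) -> "PBTLProfile":
        """pBTL identically 1: the bracket itself (basal-turn length)."""
        return cls(lambda theta: 1.0, name="unity")


@dataclass(frozen=True)
class CDLEstimate:
    """A CDL value tagged with how it was obtained.

    ``surface`` distinguishes lateral-wall from organ-of-Corti lengths so
    that estimates on different reference surfaces are never silently
    compared; applying the 0.9 factor records itself in ``corrections``.
    """

    value_mm: float
    method: str  # spline3D | A_value | elliptic_SW | reference
    theta_deg: float
    surface: str = "lateral_wall"  # or organ_of_corti
    corrections: frozenset = field(default_factory=frozenset)
    provenance: object = None

    def __post_init__(self) -> None:
        if not self.value_mm > 0:
            raise ValueError("CDL estimate must be positive")
        if self.surface == "organ_of_corti" and "oc_0.9" not in self.corrections:
            raise ValueError(
                "organ_of_corti surface requires the oc_0.9 correction record"
            )


@dataclass(frozen=True)
class CoveragePrediction:
    """Predicted cochlear coverage and insertion angle for an electrode."""

    cc_percent: float
    ia_deg: float
    electrode: ElectrodeSpec
    cdl_used: CDLEstimate | None = None


def _as_value(cdl: Union[CDLEstimate, float]) -> float:
    return cdl.value_mm if isinstance(cdl, CDLEstimate) else float(cdl)


def escude_log_term(theta_deg: float) -> float:
    """The angular term ln(1 + theta/235) of the Escude relation."""
    if theta_deg < 0:
        raise EstimatorDomainError("theta must be non-negative")
    return math.log1p(theta_deg / ESCUDE_ANGLE_SCALE_DEG)


def cdl_escude(A_mm: float, theta_deg: float) -> CDLEstimate:
    """Lateral-wall length from the A-value up to insertion angle theta.

    ``LW = 2.62 * A * ln(1 + theta/235)``, theta in degrees.
    """
    if not A_mm > 0:
        raise EstimatorDomainError("A-value must be positive")
    value = ESCUDE_FACTOR * A_mm * escude_log_term(theta_deg)
    if theta_deg == 0:
        # length of an empty angular interval; bypass positivity guard
        est = CDLEstimate.__new__(CDLEstimate)
        object.__setattr__(est, "value_mm", 0.0)
        object.__setattr__(est, "method", "A_value")
        object.__setattr__(est, "theta_deg", 0.0)
        object.__setattr__(est, "surface", "lateral_wall")
        object.__setattr__(est, "corrections", frozenset())
        object.__setattr__(est, "provenance", None)
        return est
    return CDLEstimate(value_mm=value, method="A_value", theta_deg=theta_deg)


def cdl_escude_full(A_mm: float, mode: str = "exact",
                    theta_full_deg: float = FULL_COCHLEA_ANGLE_DEG) -> CDLEstimate:
    """Full-cochlea (theta = 900 deg) A-value length.

    ``mode='exact'`` uses the exact logarithm and equals
    ``cdl_escude(A, 900)``; ``mode='printed_constant'`` reproduces the
    truncated published constant 1.57.
    """
    if not A_mm > 0:
        raise EstimatorDomainError("A-value must be positive")
    if mode == "exact":
        return cdl_escude(A_mm, theta_full_deg)
    if mode == "printed_constant":
        value = ESCUDE_FACTOR * A_mm * ESCUDE_PRINTED_CONSTANT
        return CDLEstimate(value_mm=value, method="A_value",
                           theta_deg=theta_full_deg)
    raise ValueError(f"unknown mode {mode!r}")


def elliptic_bracket(A_mm: float, B_mm: float) -> float:
    """Basal-turn length bracket of the elliptic-circular approximation.

    ``1.18(A-0.7) + 2.69(B-0.7) - sqrt(0.72 (A-0.7)(B-0.7))``
    """
    if not (A_mm > 0.7 and B_mm > 0.7):
        raise EstimatorDomainError(
            "elliptic-circular approximation requires A > 0.7 and B > 0.7 mm"
        )
    a = A_mm - 0.7
    b = B_mm - 0.7
    return 1.18 * a + 2.69 * b - math.sqrt(0.72 * a * b)


def cdl_elliptic(metrics: BasalTurnMetrics,
                 theta_deg: float = FULL_COCHLEA_ANGLE_DEG,
                 profile: Optional[PBTLProfile] = None) -> CDLEstimate:
    """Lateral-wall CDL from A and B values (elliptic-circular form).

    ``CDL_LW = pBTL(theta) * bracket(A, B)``. With the default profile the
    theta-dependence follows the normalised Escude shape (pBTL(360) = 1).
    """
    if profile is None:
        profile = PBTLProfile.escude_shape()
    value = profile(theta_deg) * elliptic_bracket(metrics.A_mm, metrics.B_mm)
    return CDLEstimate(value_mm=value, method="elliptic_SW",
                       theta_deg=theta_deg, provenance=metrics)


def to_organ_of_corti(est: CDLEstimate) -> CDLEstimate:
    """Rescale a lateral-wall length to the organ of Corti (x 0.9)."""
    if est.surface != "lateral_wall":
        raise ValueError("organ-of-Corti factor applies to lateral-wall "
                         "estimates only (already applied?)")
    return replace(est,
                   value_mm=est.value_mm * OC_FACTOR,
                   surface="organ_of_corti",
                   corrections=est.corrections | {"oc_0.9"})


def apply_resolution_correction(est: CDLEstimate) -> CDLEstimate:
    """Compensate voxel-resolution underestimation (x 10/9)."""
    if "res_10_9" in est.corrections:
        raise ValueError("resolution correction already applied")
    return replace(est,
                   value_mm=est.value_mm * RESOLUTION_FACTOR,
                   corrections=est.corrections | {"res_10_9"})


def predict_cc(cdl: Union[CDLEstimate, float],
               electrode: ElectrodeSpec = ElectrodeSpec(),
               theta_full_deg: float = FULL_COCHLEA_ANGLE_DEG) -> CoveragePrediction:
    """Cochlear coverage of an electrode: CC(%) = length / CDL * 100."""
    value = _as_value(cdl)
    if not value > 0:
        raise EstimatorDomainError("CDL must be positive")
    cc = electrode.length_mm / value * 100.0
    return CoveragePrediction(
        cc_percent=cc,
        ia_deg=predict_ia(cc, theta_full_deg),
        electrode=electrode,
        cdl_used=cdl if isinstance(cdl, CDLEstimate) else None,
    )


def predict_ia(cc_percent: float,
               theta_full_deg: float = FULL_COCHLEA_ANGLE_DEG) -> float:
    """Insertion angle predicted from coverage: IA = CC * 900 / 100."""
    if not cc_percent > 0:
        raise EstimatorDomainError("coverage must be positive")
    return cc_percent * theta_full_deg / 100.0


def cdl_reference_from_ia(ia_deg: float,
                          electrode: ElectrodeSpec = ElectrodeSpec(),
                          theta_full_deg: float = FULL_COCHLEA_ANGLE_DEG) -> CDLEstimate:
    """Insertion-angle-based reference CDL: CDL = length * 900 / IA.

    Inverts the coverage relations for the measured insertion angle of a
    fully inserted array of known length.
    """
    if not ia_deg > 0:
        raise EstimatorDomainError("insertion angle must be positive")
    value = electrode.length_mm * theta_full_deg / ia_deg
    return CDLEstimate(value_mm=value, method="reference", theta_deg=ia_deg)
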