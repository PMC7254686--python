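"""Dimensionless numbers and closed-form trackway speed predictors.

The Froude number Fr = U^2 / (g h) equalises the centripetal-to-gravitational
force ratio; geometrically similar animals moving at equal Fr move in a
dynamically similar way, which is what licenses transferring empirical
speed-stride relations across body sizes.  Two classical predictors are
implemented:

* the walking-speed predictor U = 0.25 g^0.5 l_stride^1.67 h^-1.17
  (Alexander's dinosaur-footprint formula, fitted across extant mammals and
  birds), appropriate while the gait is pendular;
* the fast-gait predictor U = [g h (l_stride / 1.8 h)^2.56]^0.5
  (Thulborn & Wade), advocated for relative stride lengths above 2.9.

For the intermediate (trotting) band the recommended estimate is the mean of
the two.  The piecewise dispatcher applies the literature band boundaries on
relative stride length lambda = l_stride / h: lambda < 2.0 walking,
2.0 <= lambda < 2.9 trot, lambda >= 2.9 run.  Boundary points belong to the
faster gait.  The exponents and coefficients are fixed constants of the
named models, not fitting parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

from .io import SpeciesProfile

__all__ = [
    "FroudeResult",
    "RelativeStride",
    "froude",
    "relative_stride",
    "alexander_speed",
    "thulborn_wade_speed",
    "trot_speed",
    "froude_model_speed",
    "hip_from_footlength",
    "WALK_TROT_LAMBDA",
    "TROT_RUN_LAMBDA",
]

#: Relative stride length at the walk -> bouncing-gait transition.
WALK_TROT_LAMBDA = 2.0
#: Relative stride length at the trot -> run/gallop transition.
TROT_RUN_LAMBDA = 2.9


class DomainError(ValueError):
    """A physical input is outside its admissible domain."""


@dataclass(frozen=True)
class FroudeResult:
    """Froude number with the speed and hip height it was computed from."""

    fr: float
    u: float
    h: float

    def __float__(self) -> float:
        return self.fr


@dataclass(frozen=True)
class RelativeStride:
    """Dimensionless stride ratio lambda = l_stride / h."""

    value: float

    def __float__(self) -> float:
        return self.value


def _check_profile(profile: SpeciesProfile) -> None:
    if profile.h <= 0:
        raise DomainError(f"hip height must be positive, got {profile.h}")
    if profile.g <= 0:
        raise DomainError(f"g must be positive, got {profile.g}")


def froude(u: float, profile: SpeciesProfile) -> FroudeResult:
    """Froude number Fr = u^2 / (g h) for speed ``u`` (m/s)."""
    _check_profile(profile)
    if u < 0:
        raise DomainError(f"speed must be non-negative, got {u}")
    return FroudeResult(fr=u * u / (profile.g * profile.h), u=u, h=profile.h)


def relative_stride(l_stride: float, profile: SpeciesProfile) -> RelativeStride:
    """Relative stride length lambda = l_stride / h (dimensionless)."""
    _check_profile(profile)
    if l_stride <= 0:
        raise DomainError(f"l_stride must be positive, got {l_stride}")
    return RelativeStride(value=l_stride / profile.h)


def alexander_speed(l_stride: float, profile: SpeciesProfile) -> float:
    """Walking-speed predictor U = 0.25 g^0.5 l_stride^1.67 h^-1.17 (m/s)."""
    _check_profile(profile)
    if l_stride <= 0:
        raise DomainError(f"l_stride must be positive, got {l_stride}")
    return 0.25 * profile.g**0.5 * l_stride**1.67 * profile.h**-1.17


def thulborn_wade_speed(l_stride: float, profile: SpeciesProfile) -> float:
    """Fast-gait predictor U = sqrt(g h (l_stride / 1.8 h)^2.56) (m/s)."""
    _check_profile(profile)
    if l_stride <= 0:
        raise DomainError(f"l_stride must be positive, got {l_stride}")
    return math.sqrt(
        profile.g * profile.h * (l_stride / (1.8 * profile.h)) ** 2.56
    )


def trot_speed(l_stride: float, profile: SpeciesProfile) -> float:
    """Trot-band speed: mean of the walking and fast-gait predictors (m/s)."""
    return 0.5 * (
        alexander_speed(l_stride, profile)
        + thulborn_wade_speed(l_stride, profile)
    )


def froude_model_speed(
    l_stride: float,
    profile: SpeciesProfile,
    *,
    walk_trot: float = WALK_TROT_LAMBDA,
    trot_run: float = TROT_RUN_LAMBDA,
) -> Tuple[float, str]:
    """Piecewise general-model speed with its gait band.

    Dispatches on relative stride lambda: below ``walk_trot`` the walking
    predictor (band ``"walk"``), between the thresholds the mean-of-two trot
    estimate (band ``"trot"``), at or above ``trot_run`` the fast-gait
    predictor (band ``"run"``).  A boundary point goes to the faster band.
    No smoothing is applied at the boundaries; the piecewise recipe is
    applied as published, so the function is discontinuous there.
    """
    if not walk_trot < trot_run:
        raise DomainError(
            f"thresholds must increase, got ({walk_trot}, {trot_run})"
        )
    lam = relative_stride(l_stride, profile).value
    if lam < walk_trot:
        return alexander_speed(l_stride, profile), "walk"
    if lam < trot_run:
        return trot_speed(l_stride, profile), "trot"
    return thulborn_wade_speed(l_stride, profile), "run"


def hip_from_footlength(foot_length: float, factor: float = 4.0) -> float:
    """Estimate functional hip height as ``factor`` x foot length (m).

    The conventional proxy multiplies footprint length by 4; postural
    uncertainty means such estimates can be off by a factor of 1.5 or more,
    which propagates directly into every speed estimate.
    """
    if foot_length <= 0:
        raise DomainError(f"foot_length must be positive, got {foot_length}")
    if factor <= 0:
        raise DomainError(f"factor must be positive, got {factor}")
    return factor * foot_length
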