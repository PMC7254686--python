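"""Gait classification from stride length, and ambiguity quantification.

Two classification schemes are provided.  The *relative-stride* scheme uses
the literature band boundaries on lambda = l_stride / h (walk below 2.0,
trot to 2.9, run above) and always yields a single label.  The
*species-ranges* scheme asks which calibrated gaits' observed stride-length
ranges contain the trackway's stride; because real gaits overlap in stride
length around the transitions, a stride can fall inside two ranges at once
— such trackways are flagged ambiguous, and the fraction of ambiguous
trackways in a cohort quantifies how much information stride length alone
carries about gait.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

from .calibration import LinearGaitModel, predict_with_interval
from .io import SpeciesProfile, TrackwayRecord
from .speed_models import (
    TROT_RUN_LAMBDA,
    WALK_TROT_LAMBDA,
    DomainError,
    relative_stride,
)

__all__ = [
    "GaitClassification",
    "classify_relative_stride",
    "classify_species_ranges",
    "unclassifiable_fraction",
]


@dataclass(frozen=True)
class GaitClassification:
    """Assigned gait(s) for one trackway with an ambiguity flag.

    ``gaits`` is a non-empty tuple of labels; ``ambiguous`` is true exactly
    when more than one gait matched.  ``lam`` carries the relative stride
    when the relative-stride method was used.  ``out_of_range`` marks a
    stride length outside every calibrated range (the nearest range's gait
    is then reported, never silently clamped).
    """

    trackway_id: str
    method: str
    gaits: Tuple[str, ...]
    ambiguous: bool
    lam: Optional[float] = None
    out_of_range: bool = False
    thresholds: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if not self.gaits:
            raise ValueError("a classification must name at least one gait")
        if self.ambiguous != (len(self.gaits) > 1):
            raise ValueError("ambiguous flag inconsistent with gait count")


def classify_relative_stride(
    l_stride: float,
    profile: SpeciesProfile,
    thresholds: Tuple[float, float] = (WALK_TROT_LAMBDA, TROT_RUN_LAMBDA),
    trackway_id: str = "",
) -> GaitClassification:
    """Single-gait call from the relative stride length.

    Half-open bands: lambda < thresholds[0] -> walk, thresholds[0] <=
    lambda < thresholds[1] -> trot, lambda >= thresholds[1] -> run.  A
    boundary point goes to the faster gait (once lambda *reaches* 2.0 the
    gait has shifted).  Never ambiguous.
    """
    walk_trot, trot_run = thresholds
    if not walk_trot < trot_run:
        raise DomainError(f"thresholds must increase, got {thresholds}")
    lam = relative_stride(l_stride, profile).value
    if lam < walk_trot:
        gait = "walk"
    elif lam < trot_run:
        gait = "trot"
    else:
        gait = "run"
    return GaitClassification(
        trackway_id=trackway_id,
        method="relative_stride",
        gaits=(gait,),
        ambiguous=False,
        lam=lam,
        thresholds=(walk_trot, trot_run),
    )


def _speed_interval_match(
    model: LinearGaitModel, l_stride: float, level: float
) -> bool:
    lo, hi = sorted(model.u_range)
    _, plo, phi = predict_with_interval(model, l_stride, level)
    return plo <= hi and lo <= phi


def classify_species_ranges(
    l_stride: float,
    models: Sequence[LinearGaitModel],
    trackway_id: str = "",
    *,
    mode: str = "stride_range",
    level: float = 0.95,
) -> GaitClassification:
    """Gait call from the calibrated per-gait stride-length ranges.

    Default mode ``"stride_range"`` matches every gait whose observed
    training stride range [l_min, l_max] contains ``l_stride`` (inclusive).
    Two or more matches -> ambiguous.  No match -> the gait whose range is
    nearest, flagged ``out_of_range``.

    Mode ``"speed_interval"`` instead matches a gait when the t-based
    prediction interval at ``l_stride`` under that gait's model intersects
    the gait's fitted speed range over its observed strides — a looser,
    speed-space notion of compatibility.
    """
    if not models:
        raise ValueError("need at least one fitted gait model")
    if mode not in ("stride_range", "speed_interval"):
        raise ValueError(f"unknown mode {mode!r}")
    if l_stride <= 0:
        raise DomainError(f"l_stride must be positive, got {l_stride}")

    if mode == "stride_range":
        matches = [
            m.gait for m in models if m.l_range[0] <= l_stride <= m.l_range[1]
        ]
    else:
        matches = [
            m.gait for m in models if _speed_interval_match(m, l_stride, level)
        ]

    if matches:
        return GaitClassification(
            trackway_id=trackway_id,
            method="species_ranges",
            gaits=tuple(matches),
            ambiguous=len(matches) > 1,
        )
    # Out of every range: report the nearest, never clamp silently.
    def distance(m: LinearGaitModel) -> float:
        lo, hi = m.l_range
        return lo - l_stride if l_stride < lo else l_stride - hi

    nearest = min(models, key=distance)
    return GaitClassification(
        trackway_id=trackway_id,
        method="species_ranges",
        gaits=(nearest.gait,),
        ambiguous=False,
        out_of_range=True,
    )


def unclassifiable_fraction(
    records: Sequence[TrackwayRecord],
    models: Sequence[LinearGaitModel],
    *,
    mode: str = "stride_range",
) -> float:
    """Fraction of trackways whose range-based gait call is ambiguous.

    This is the share of a cohort that could not be assigned a single gait
    from stride length alone, because its stride falls in the overlap of
    two calibrated gaits' ranges.
    """
    if not records:
        raise ValueError("need at least one trackway record")
    flags = [
        classify_species_ranges(r.l_stride, models, r.id, mode=mode).ambiguous
        for r in records
    ]
    return sum(flags) / len(flags)
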