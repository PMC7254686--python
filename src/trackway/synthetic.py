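"""Seeded generator of matched video-speed + trackway datasets.

Emulates the structure of a field campaign in which each trackway carries a
photograph-derived mean stride length, a gait label, and a simultaneous
video-derived ground-truth speed.  Each gait has a linear speed-stride
relation with Gaussian residual scatter; the generator truths default to
the calibrated per-gait regressions of the Svalbard rock ptarmigan study
system (slopes 3.20 / 2.34 / 4.29 (m/s)/m for walking, grounded running and
aerial running) with sample sizes 48 / 56 / 61 and a 50-trackway hold-out.

Stride lengths are drawn uniformly over each gait's observed range by
default (the least-assumption choice; a truncated normal is available).
Residual SDs are back-calculated from published prediction-interval
half-widths divided by 1.96 — an acknowledged approximation, since a
prediction-interval half-width also carries fit uncertainty and slightly
exceeds the residual SD.

The generator is statistical, not physical: it does not model snow
compliance, footprint formation, sex or ontogeny structure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .io import GAITS, TrackwayRecord

__all__ = [
    "GaitGeneratorSpec",
    "default_specs",
    "generate",
    "generate_holdout",
    "DEFAULT_HOLDOUT_SIZE",
]

DEFAULT_HOLDOUT_SIZE = 50


class GeneratorConfigError(ValueError):
    """A generator spec violates its invariants."""


@dataclass(frozen=True)
class GaitGeneratorSpec:
    """Ground-truth generating process for one gait.

    ``u_measured = slope * l + intercept + N(0, residual_sd)`` with stride
    lengths ``l`` drawn from ``stride_distribution`` over ``l_range``.
    """

    gait: str
    slope: float
    intercept: float
    residual_sd: float
    l_range: Tuple[float, float]
    n: int
    stride_distribution: str = "uniform"

    def __post_init__(self) -> None:
        lo, hi = self.l_range
        if not lo < hi:
            raise GeneratorConfigError(
                f"gait {self.gait!r}: l_range must satisfy min < max, got "
                f"{self.l_range}"
            )
        if lo <= 0:
            raise GeneratorConfigError(
                f"gait {self.gait!r}: stride lengths must be positive"
            )
        if self.residual_sd < 0:
            raise GeneratorConfigError(
                f"gait {self.gait!r}: residual_sd must be >= 0"
            )
        if self.n < 1:
            raise GeneratorConfigError(f"gait {self.gait!r}: n must be >= 1")
        if self.stride_distribution not in ("uniform", "truncated-normal"):
            raise GeneratorConfigError(
                f"gait {self.gait!r}: unknown stride_distribution "
                f"{self.stride_distribution!r}"
            )


def default_specs() -> List[GaitGeneratorSpec]:
    """The three study-condition gait specs.

    Slopes/intercepts are the calibrated per-gait regressions; stride
    ranges invert the published predicted-speed endpoints through each
    equation (walking 0.49-0.80 m/s -> 0.225-0.322 m; grounded running
    1.07-1.36 m/s -> 0.312-0.436 m; aerial running 1.57-2.74 m/s ->
    0.373-0.646 m); residual SDs are prediction-interval half-widths / 1.96
    (approximate — see module docstring); n = 48 / 56 / 61.
    """
    return [
        GaitGeneratorSpec(
            gait="walking",
            slope=3.20,
            intercept=-0.23,
            residual_sd=0.092,
            l_range=(0.225, 0.322),
            n=48,
        ),
        GaitGeneratorSpec(
            gait="grounded_running",
            slope=2.34,
            intercept=0.34,
            residual_sd=0.168,
            l_range=(0.312, 0.436),
            n=56,
        ),
        GaitGeneratorSpec(
            gait="aerial_running",
            slope=4.29,
            intercept=-0.03,
            residual_sd=0.180,
            l_range=(0.373, 0.646),
            n=61,
        ),
    ]


def _draw_strides(
    spec: GaitGeneratorSpec, rng: np.random.Generator, size: int
) -> np.ndarray:
    lo, hi = spec.l_range
    if spec.stride_distribution == "uniform":
        return rng.uniform(lo, hi, size=size)
    # truncated normal centred mid-range with SD a quarter of the range
    mid, sd = 0.5 * (lo + hi), 0.25 * (hi - lo)
    a, b = (lo - mid) / sd, (hi - mid) / sd
    return stats.truncnorm.rvs(a, b, loc=mid, scale=sd, size=size, random_state=rng)


def _spawn(seed: int, n_children: int) -> list[np.random.Generator]:
    # Splittable streams: one child per gait, so adding a gait does not
    # reshuffle the draws of the others.
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n_children)]


def generate(
    specs: Sequence[GaitGeneratorSpec],
    seed: int,
    measurement_sd: float = 0.0,
    id_prefix: str = "syn",
) -> List[TrackwayRecord]:
    """Generate one matched training dataset, deterministic given ``seed``.

    For each spec, draws ``spec.n`` stride lengths, sets the ground-truth
    speed from the gait's linear relation plus Gaussian residual noise, then
    perturbs the *recorded* stride length by ``N(0, measurement_sd)`` to
    mimic photograph-measurement error (the speed is computed from the true
    stride — the camera measures speed independently of the photograph).
    """
    if measurement_sd < 0:
        raise GeneratorConfigError("measurement_sd must be >= 0")
    rngs = _spawn(seed, len(specs))
    records: List[TrackwayRecord] = []
    for spec, rng in zip(specs, rngs):
        l_true = _draw_strides(spec, rng, spec.n)
        u = spec.slope * l_true + spec.intercept + rng.normal(
            0.0, spec.residual_sd, size=spec.n
        )
        # speeds and recorded strides are physical quantities: redraw the
        # rare noise draws that would push them non-positive (negligible
        # truncation at the default noise levels, ~5 SD from zero)
        while np.any(bad := u <= 0):
            u[bad] = spec.slope * l_true[bad] + spec.intercept + rng.normal(
                0.0, spec.residual_sd, size=int(bad.sum())
            )
        l_rec = l_true + rng.normal(0.0, measurement_sd, size=spec.n)
        while np.any(bad := l_rec <= 0):
            l_rec[bad] = l_true[bad] + rng.normal(
                0.0, measurement_sd, size=int(bad.sum())
            )
        for i in range(spec.n):
            records.append(
                TrackwayRecord(
                    id=f"{id_prefix}-{spec.gait}-{i:03d}",
                    l_stride=float(l_rec[i]),
                    n_strides_measured=1,
                    gait=spec.gait,
                    u_measured=float(u[i]),
                )
            )
    return records


def generate_holdout(
    specs: Sequence[GaitGeneratorSpec],
    seed: int,
    size: int = DEFAULT_HOLDOUT_SIZE,
    measurement_sd: float = 0.0,
) -> List[TrackwayRecord]:
    """Generate a hold-out cohort mixed across gaits proportionally to n.

    Gait counts are multinomial with probabilities proportional to each
    spec's sample size; every record keeps its gait label and ground-truth
    speed for error evaluation.
    """
    if size < 1:
        raise GeneratorConfigError("size must be >= 1")
    ss = np.random.SeedSequence(seed)
    alloc_rng = np.random.default_rng(ss.spawn(1)[0])
    probs = np.array([s.n for s in specs], dtype=float)
    probs /= probs.sum()
    counts = alloc_rng.multinomial(size, probs)
    sized = [replace(spec, n=int(c)) for spec, c in zip(specs, counts) if c > 0]
    # offset the child seed so hold-out draws differ from a training set
    # generated with the same top-level seed
    child_seed = int(np.random.default_rng(ss).integers(0, 2**31 - 1))
    return generate(sized, child_seed, measurement_sd, id_prefix="hold")
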