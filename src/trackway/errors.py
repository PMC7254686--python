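"""Ground-truth percent-error computation and per-model summaries.

The signed percent error of a prediction against a video-measured speed is
100 * (predicted - measured) / measured: negative values are
underestimates.  Summaries report the mean of absolute errors (the headline
accuracy figure), the signed mean (bias), spread, range, and a decadal
histogram with bin edges anchored at multiples of 10 percent
(closed-left / open-right).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

__all__ = ["ErrorSummary", "percent_error", "summarize_errors"]

BIN_WIDTH = 10.0  # percent


def percent_error(predicted: float, measured: float) -> float:
    """Signed percent error 100 * (predicted - measured) / measured.

    Negative = the model underestimates the measured speed.
    """
    if not (measured > 0 and math.isfinite(measured)):
        raise ValueError(f"measured speed must be positive, got {measured}")
    if not math.isfinite(predicted):
        raise ValueError(f"predicted speed must be finite, got {predicted}")
    return 100.0 * (predicted - measured) / measured


@dataclass(frozen=True)
class ErrorSummary:
    """Signed percent errors for one (model, gait) cell with summaries.

    ``bins`` is a list of ``(left_edge, count)`` pairs of width-10 bins
    covering the observed error range; counts sum to ``len(errors)``.
    ``mean_abs``/``sd`` summarise the absolute errors; ``mean_signed``/
    ``sd_signed`` the signed ones (bias and spread); ``min``/``max`` are the
    signed extremes.
    """

    model: str
    gait: str
    errors: Tuple[float, ...]
    mean_abs: float
    sd: float
    mean_signed: float
    sd_signed: float
    min: float
    max: float
    bins: Tuple[Tuple[float, int], ...]


def _decadal_bins(errors: np.ndarray) -> List[Tuple[float, int]]:
    lo = BIN_WIDTH * math.floor(errors.min() / BIN_WIDTH)
    hi = BIN_WIDTH * (math.floor(errors.max() / BIN_WIDTH) + 1)
    edges = np.arange(lo, hi + BIN_WIDTH / 2, BIN_WIDTH)
    # closed-left / open-right, so a value on an edge counts rightwards
    idx = np.floor(errors / BIN_WIDTH).astype(int)
    offset = int(round(lo / BIN_WIDTH))
    counts = np.bincount(idx - offset, minlength=len(edges) - 1)
    return [(float(edges[i]), int(counts[i])) for i in range(len(edges) - 1)]


def summarize_errors(
    pairs: Sequence[Tuple[float, float]], model: str, gait: str = "all"
) -> ErrorSummary:
    """Summarise signed percent errors of (predicted, measured) speed pairs.

    ``ddof=0`` standard deviations (population form) are used; with a
    single pair both SDs are 0.
    """
    if not pairs:
        raise ValueError("need at least one (predicted, measured) pair")
    errs = np.array([percent_error(p, m) for p, m in pairs], dtype=float)
    abs_errs = np.abs(errs)
    return ErrorSummary(
        model=model,
        gait=gait,
        errors=tuple(float(e) for e in errs),
        mean_abs=float(abs_errs.mean()),
        sd=float(abs_errs.std(ddof=0)),
        mean_signed=float(errs.mean()),
        sd_signed=float(errs.std(ddof=0)),
        min=float(errs.min()),
        max=float(errs.max()),
        bins=tuple(_decadal_bins(errs)),
    )
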