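"""Per-gait linear calibration of speed on stride length.

Fits ordinary least squares of measured speed U (m/s) on stride length
l_stride (m), one model per gait, never pooled: the incremental change of
speed with stride length differs between walking, grounded running and
aerial running, so a pooled slope would be biologically meaningless.
Prediction intervals are the two-sided t-based intervals for a single new
observation, accounting for both residual scatter and fit uncertainty at
the predictor value; they widen hyperbolically away from the mean training
stride length.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .io import GAITS, TrackwayRecord, normalize_gait

logger = logging.getLogger(__name__)

__all__ = [
    "LinearGaitModel",
    "InsufficientDataError",
    "DegenerateDesignError",
    "fit_gait_model",
    "predict_with_interval",
    "residual_normality",
    "save_models",
    "load_models",
]


class InsufficientDataError(ValueError):
    """Fewer than three usable (l_stride, u_measured) pairs for a gait."""


class DegenerateDesignError(ValueError):
    """Zero variance in the predictor (or in residuals where needed)."""


@dataclass(frozen=True)
class LinearGaitModel:
    """A fitted speed-stride regression for one gait.

    slope is in (m/s)/m, intercept in m/s.  ``residual_sd`` is the root
    mean squared error with n-2 degrees of freedom.  ``l_range`` is the
    observed (min, max) stride length of the training data, used for
    range-based gait classification.  ``l_mean`` and ``sxx`` (the centred
    sum of squares of the predictor) are retained for prediction intervals.
    """

    gait: str
    slope: float
    intercept: float
    n: int
    residual_sd: float
    r2: float
    f_stat: float
    l_range: Tuple[float, float]
    l_mean: float
    sxx: float

    @property
    def df(self) -> Tuple[int, int]:
        """Regression degrees of freedom (1, n - 2)."""
        return (1, self.n - 2)

    def predict(self, l_stride: float) -> float:
        """Point prediction slope * l_stride + intercept (m/s)."""
        return self.slope * l_stride + self.intercept

    @property
    def u_range(self) -> Tuple[float, float]:
        """Fitted speed range over the observed stride range (m/s)."""
        lo, hi = self.l_range
        return (self.predict(lo), self.predict(hi))


def _usable(records: Iterable[TrackwayRecord], gait: str) -> list[TrackwayRecord]:
    gait = normalize_gait(gait)
    selected = [r for r in records if r.gait == gait]
    usable = [r for r in selected if r.u_measured is not None]
    dropped = len(selected) - len(usable)
    if dropped:
        logger.info(
            "gait %s: excluded %d record(s) without measured speed", gait, dropped
        )
    return usable


def fit_gait_model(
    records: Sequence[TrackwayRecord], gait: str
) -> LinearGaitModel:
    """OLS fit of u_measured on l_stride for records of one gait.

    Requires at least three records carrying both a stride length and a
    measured speed for the gait.  Records without ``u_measured`` are
    excluded with a logged count.  No weighting by the number of strides
    averaged is applied.
    """
    usable = _usable(records, gait)
    if len(usable) < 3:
        raise InsufficientDataError(
            f"gait {gait!r}: need >= 3 records with l_stride and u_measured, "
            f"got {len(usable)}"
        )
    x = np.array([r.l_stride for r in usable], dtype=float)
    y = np.array([r.u_measured for r in usable], dtype=float)
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise DegenerateDesignError(
            f"gait {gait!r}: zero variance in l_stride; slope is unidentifiable"
        )
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    n = len(usable)
    residual_sd = float(np.sqrt(fit.ssr / (n - 2)))
    # snap floating-noise residuals of an exact linear fit to zero
    if residual_sd <= 1e-12 * max(1.0, float(np.abs(y).max())):
        residual_sd = 0.0
    return LinearGaitModel(
        gait=normalize_gait(gait),
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        n=n,
        residual_sd=residual_sd,
        r2=float(fit.rsquared),
        f_stat=float(fit.fvalue),
        l_range=(float(x.min()), float(x.max())),
        l_mean=float(x.mean()),
        sxx=sxx,
    )


def predict_with_interval(
    model: LinearGaitModel, l_stride: float, level: float = 0.95
) -> Tuple[float, float, float]:
    """Point prediction with a two-sided prediction interval for a new
    observation at ``l_stride``.

    The half-width is t_{1-(1-level)/2, n-2} * s * sqrt(1 + 1/n +
    (l - l_mean)^2 / Sxx): residual variance plus the fit uncertainty of the
    regression line at ``l_stride``.  Defaults to 95% coverage.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    point = model.predict(l_stride)
    if model.residual_sd == 0.0:
        return point, point, point
    se = model.residual_sd * math.sqrt(
        1.0 + 1.0 / model.n + (l_stride - model.l_mean) ** 2 / model.sxx
    )
    t = float(stats.t.ppf(0.5 + level / 2.0, model.n - 2))
    return point, point - t * se, point + t * se


def residual_normality(
    model: LinearGaitModel, records: Sequence[TrackwayRecord]
) -> Tuple[float, float]:
    """Shapiro-Wilk test of the regression residuals.

    Returns ``(W, p)``.  The residuals are recomputed from the records the
    model was fitted on; a p above the conventional 0.05 supports the
    Gaussian-residual assumption behind the t-based prediction intervals.
    """
    usable = _usable(records, model.gait)
    if len(usable) < 3:
        raise InsufficientDataError(
            f"gait {model.gait!r}: need >= 3 records for a residual check"
        )
    resid = np.array(
        [r.u_measured - model.predict(r.l_stride) for r in usable], dtype=float
    )
    if np.ptp(resid) <= 1e-12 * max(1.0, float(np.abs(resid).max())):
        raise DegenerateDesignError(
            f"gait {model.gait!r}: residuals have zero variance; the "
            "Shapiro-Wilk statistic is undefined"
        )
    w, p = stats.shapiro(resid)
    return float(w), float(p)


# ---------------------------------------------------------------------------
# Plain-text model persistence (reloadable by the predict CLI subcommand)

_MODEL_FIELDS = (
    "gait",
    "slope",
    "intercept",
    "n",
    "residual_sd",
    "r2",
    "f_stat",
    "l_min",
    "l_max",
    "l_mean",
    "sxx",
)


def save_models(models: Sequence[LinearGaitModel], path: str | Path) -> None:
    """Write fitted models to a plain-text key-value file, one block per gait."""
    lines = []
    for m in models:
        lines.append(f"gait: {m.gait}")
        lines.append(f"slope: {m.slope!r}")
        lines.append(f"intercept: {m.intercept!r}")
        lines.append(f"n: {m.n}")
        lines.append(f"residual_sd: {m.residual_sd!r}")
        lines.append(f"r2: {m.r2!r}")
        lines.append(f"f_stat: {m.f_stat!r}")
        lines.append(f"l_min: {m.l_range[0]!r}")
        lines.append(f"l_max: {m.l_range[1]!r}")
        lines.append(f"l_mean: {m.l_mean!r}")
        lines.append(f"sxx: {m.sxx!r}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def load_models(path: str | Path) -> list[LinearGaitModel]:
    """Reload models written by :func:`save_models`."""
    blocks: list[dict] = []
    current: dict = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            if current:
                blocks.append(current)
                current = {}
            continue
        key, _, value = line.partition(":")
        current[key.strip()] = value.strip()
    if current:
        blocks.append(current)
    models = []
    for b in blocks:
        missing = [k for k in _MODEL_FIELDS if k not in b]
        if missing:
            raise ValueError(f"model file {path}: missing fields {missing}")
        models.append(
            LinearGaitModel(
                gait=normalize_gait(b["gait"]),
                slope=float(b["slope"]),
                intercept=float(b["intercept"]),
                n=int(b["n"]),
                residual_sd=float(b["residual_sd"]),
                r2=float(b["r2"]),
                f_stat=float(b["f_stat"]),
                l_range=(float(b["l_min"]), float(b["l_max"])),
                l_mean=float(b["l_mean"]),
                sxx=float(b["sxx"]),
            )
        )
    return models


def fit_all_gaits(records: Sequence[TrackwayRecord]) -> list[LinearGaitModel]:
    """Fit one model per gait present with enough data, in canonical order."""
    models = []
    for gait in GAITS:
        try:
            models.append(fit_gait_model(records, gait))
        except InsufficientDataError:
            logger.info("gait %s: skipped (insufficient data)", gait)
    return models
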