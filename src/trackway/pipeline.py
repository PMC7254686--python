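"""Glue between the library and the tabular CSV workflow.

Turns trackway records plus a chosen model into :class:`PredictionRow`
objects ready for :func:`trackway.io.write_predictions`: species-calibrated
per-gait predictions carry prediction intervals, the general Froude-based
predictors carry their gait band, and percent errors are filled in wherever
a ground-truth speed is present.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .calibration import LinearGaitModel, predict_with_interval
from .errors import percent_error
from .io import PredictionRow, SpeciesProfile, TrackwayRecord
from .speed_models import (
    alexander_speed,
    froude_model_speed,
    thulborn_wade_speed,
)

__all__ = ["MODEL_NAMES", "predict_records"]

MODEL_NAMES = ("species", "alexander", "thulborn-wade", "froude-piecewise")


def _species_prediction(
    rec: TrackwayRecord,
    models: Sequence[LinearGaitModel],
    level: float,
) -> Optional[PredictionRow]:
    by_gait = {m.gait: m for m in models}
    model = by_gait.get(rec.gait) if rec.gait else None
    if model is None:
        return None
    point, lo, hi = predict_with_interval(model, rec.l_stride, level)
    return PredictionRow(
        trackway_id=rec.id,
        model="species",
        u_pred=point,
        lower=lo,
        upper=hi,
        gait_call=rec.gait,
    )


def predict_records(
    records: Sequence[TrackwayRecord],
    model: str,
    *,
    profile: Optional[SpeciesProfile] = None,
    gait_models: Optional[Sequence[LinearGaitModel]] = None,
    level: float = 0.95,
) -> list[PredictionRow]:
    """Predict speed for every record under one named model.

    ``model`` is one of ``species`` (requires ``gait_models`` and per-record
    gait labels; records without a usable gait are skipped), ``alexander``,
    ``thulborn-wade`` or ``froude-piecewise`` (require ``profile``).
    Records with a measured speed get a signed percent error.
    """
    if model not in MODEL_NAMES:
        raise ValueError(f"unknown model {model!r}; choose from {MODEL_NAMES}")
    rows: list[PredictionRow] = []
    for rec in records:
        if model == "species":
            if gait_models is None:
                raise ValueError("species model requires fitted gait_models")
            row = _species_prediction(rec, gait_models, level)
            if row is None:
                continue
        else:
            if profile is None:
                raise ValueError(f"{model} model requires a SpeciesProfile")
            if model == "alexander":
                u, band = alexander_speed(rec.l_stride, profile), None
            elif model == "thulborn-wade":
                u, band = thulborn_wade_speed(rec.l_stride, profile), None
            else:
                u, band = froude_model_speed(rec.l_stride, profile)
            row = PredictionRow(
                trackway_id=rec.id, model=model, u_pred=u, gait_call=band
            )
        if rec.u_measured is not None:
            row = PredictionRow(
                trackway_id=row.trackway_id,
                model=row.model,
                u_pred=row.u_pred,
                lower=row.lower,
                upper=row.upper,
                gait_call=row.gait_call,
                percent_error=percent_error(row.u_pred, rec.u_measured),
            )
        rows.append(row)
    return rows
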