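"""Domain types and tabular I/O for matched trackway/video datasets.

A *trackway* is a sequence of footprints; the quantity measured from a
trackway photograph is the mean stride length (distance between successive
placements of the same foot, in metres).  When a video of the trackmaker was
recorded as the tracks were made, the record also carries the ground-truth
speed in m/s.  All units are SI (metres, m/s); no unit auto-detection is
performed.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Controlled vocabulary of gait labels, slow to fast.
GAITS = ("walking", "grounded_running", "aerial_running")

#: Input aliases normalised on read.  "trot" is the intermediate gait of the
#: general Froude-based scheme; for species-specific analyses it maps onto
#: the grounded run (the bouncing gait without an aerial phase used by many
#: birds).
GAIT_ALIASES = {
    "trot": "grounded_running",
    "trotting": "grounded_running",
    "walk": "walking",
    "grounded running": "grounded_running",
    "aerial running": "aerial_running",
    "run": "aerial_running",
    "running": "aerial_running",
}

#: Functional hip height of a male Svalbard rock ptarmigan, metres
#: (literature morphometric value; hip height does not change seasonally).
DEFAULT_HIP_HEIGHT = 0.1727

#: Standard gravitational acceleration, m/s^2.
DEFAULT_G = 9.81


class TrackwayError(Exception):
    """Base class for trackway I/O and validation errors."""


class TrackwayParseError(TrackwayError):
    """A CSV cell could not be parsed; names the offending row and column."""


def normalize_gait(label: str) -> str:
    """Map an input gait label onto the controlled vocabulary.

    Raises :class:`TrackwayError` for labels outside the vocabulary and its
    aliases.  Alias normalisation (e.g. ``trot`` -> ``grounded_running``) is
    logged so that downstream species-specific analyses are traceable.
    """
    key = label.strip().lower()
    if key in GAITS:
        return key
    if key in GAIT_ALIASES:
        canonical = GAIT_ALIASES[key]
        logger.info("gait label %r normalised to %r", label, canonical)
        return canonical
    raise TrackwayError(
        f"unknown gait label {label!r}; allowed labels are {GAITS} "
        f"(aliases: {sorted(GAIT_ALIASES)})"
    )


@dataclass(frozen=True)
class TrackwayRecord:
    """One trackway: mean stride length plus optional gait / measured speed.

    Parameters
    ----------
    id : str
        Opaque identifier of the trackway.
    l_stride : float
        Mean stride length in metres, averaged over ``n_strides_measured``
        individual strides (typically 1-5 measured from a photograph).
    n_strides_measured : int
        Number of strides the mean was taken over.
    gait : str, optional
        One of ``walking``, ``grounded_running``, ``aerial_running``.
    u_measured : float, optional
        Ground-truth speed in m/s from a simultaneous video recording.
    """

    id: str
    l_stride: float
    n_strides_measured: int = 1
    gait: Optional[str] = None
    u_measured: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.l_stride > 0 and math.isfinite(self.l_stride)):
            raise TrackwayError(
                f"trackway {self.id!r}: l_stride must be positive and finite, "
                f"got {self.l_stride}"
            )
        if self.u_measured is not None and not (
            self.u_measured > 0 and math.isfinite(self.u_measured)
        ):
            raise TrackwayError(
                f"trackway {self.id!r}: u_measured must be positive, got "
                f"{self.u_measured}"
            )
        if self.n_strides_measured < 1:
            raise TrackwayError(
                f"trackway {self.id!r}: n_strides_measured must be >= 1"
            )
        if self.n_strides_measured > 5:
            warnings.warn(
                f"trackway {self.id!r}: {self.n_strides_measured} strides "
                "averaged; field protocols typically use 1-5",
                stacklevel=2,
            )
        if self.gait is not None:
            object.__setattr__(self, "gait", normalize_gait(self.gait))


@dataclass(frozen=True)
class SpeciesProfile:
    """Morphometric profile of the trackmaker species.

    ``h`` is the functional hip height in metres — the vertical distance from
    the ground to the hip during stance.  It is the body-size scale in the
    Froude number and in both general speed predictors.  ``g`` is the local
    gravitational acceleration in m/s^2.
    """

    species: str = "Lagopus muta hyperborea"
    h: float = DEFAULT_HIP_HEIGHT
    g: float = DEFAULT_G

    def __post_init__(self) -> None:
        if not (self.h > 0 and math.isfinite(self.h)):
            raise TrackwayError(f"hip height must be positive, got {self.h}")
        if not (self.g > 0 and math.isfinite(self.g)):
            raise TrackwayError(f"g must be positive, got {self.g}")

    @classmethod
    def from_file(cls, path: str | Path) -> "SpeciesProfile":
        """Load a profile from a YAML/key-value config (species, h, g)."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        kwargs = {k: data[k] for k in ("species", "h", "g") if k in data}
        for key in ("h", "g"):
            if key in kwargs:
                kwargs[key] = float(kwargs[key])
        return cls(**kwargs)


@dataclass(frozen=True)
class PredictionRow:
    """One (trackway, model) prediction for the output CSV."""

    trackway_id: str
    model: str
    u_pred: float
    lower: Optional[float] = None
    upper: Optional[float] = None
    gait_call: Optional[str] = None
    percent_error: Optional[float] = None


_REQUIRED_COLUMNS = ("id", "l_stride")
_OPTIONAL_COLUMNS = ("n_strides", "gait", "u_measured")


def _parse_float(value, row_label, column: str) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    text = str(value).strip()
    if text == "":
        return None
    try:
        return float(text)
    except ValueError:
        raise TrackwayParseError(
            f"row {row_label}: malformed numeric value {text!r} in column "
            f"{column!r}"
        ) from None


def read_trackways(
    path: str | Path, *, errors: str = "raise"
) -> list[TrackwayRecord] | tuple[list[TrackwayRecord], list[tuple[int, str]]]:
    """Read trackway records from a CSV file.

    The file must have a header naming at least ``id`` and ``l_stride``;
    ``n_strides``, ``gait`` and ``u_measured`` are optional and parsed as
    absent when blank.  Units are metres and m/s throughout.

    With ``errors="raise"`` (default) the first malformed cell aborts the
    read with a :class:`TrackwayParseError` naming the row and column.  With
    ``errors="collect"`` the function returns ``(records, bad_rows)`` where
    ``bad_rows`` is a list of ``(row_number, message)`` pairs, so that every
    data row is accounted for: ``len(records) + len(bad_rows)`` equals the
    number of data rows.
    """
    if errors not in ("raise", "collect"):
        raise ValueError("errors must be 'raise' or 'collect'")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrackwayError(f"CSV {path} is missing required columns {missing}")

    records: list[TrackwayRecord] = []
    bad_rows: list[tuple[int, str]] = []
    for i, row in df.iterrows():
        row_number = int(i) + 2  # 1-based file line, after the header
        try:
            l_stride = _parse_float(row["l_stride"], row_number, "l_stride")
            if l_stride is None:
                raise TrackwayParseError(
                    f"row {row_number}: column 'l_stride' is empty"
                )
            n_strides = None
            if "n_strides" in df.columns:
                n_val = _parse_float(row["n_strides"], row_number, "n_strides")
                n_strides = int(n_val) if n_val is not None else None
            gait = None
            if "gait" in df.columns and str(row["gait"]).strip() != "":
                gait = str(row["gait"]).strip()
            u_measured = None
            if "u_measured" in df.columns:
                u_measured = _parse_float(
                    row["u_measured"], row_number, "u_measured"
                )
            records.append(
                TrackwayRecord(
                    id=str(row["id"]),
                    l_stride=l_stride,
                    n_strides_measured=n_strides if n_strides else 1,
                    gait=gait,
                    u_measured=u_measured,
                )
            )
        except (TrackwayParseError, TrackwayError) as exc:
            if errors == "raise":
                raise
            bad_rows.append((row_number, str(exc)))
    if errors == "collect":
        return records, bad_rows
    return records


def write_trackways(records: Iterable[TrackwayRecord], path: str | Path) -> None:
    """Write trackway records to CSV in the standard input schema.

    Floats are rendered with ``repr`` precision so that identical record
    lists produce byte-identical files.
    """
    rows = []
    for rec in records:
        rows.append(
            {
                "id": rec.id,
                "l_stride": repr(float(rec.l_stride)),
                "n_strides": rec.n_strides_measured,
                "gait": rec.gait if rec.gait is not None else "",
                "u_measured": ""
                if rec.u_measured is None
                else repr(float(rec.u_measured)),
            }
        )
    pd.DataFrame(
        rows, columns=["id", "l_stride", "n_strides", "gait", "u_measured"]
    ).to_csv(path, index=False)


def write_predictions(
    records: Sequence[PredictionRow], path: str | Path
) -> None:
    """Write per-(trackway, model) predictions to CSV.

    One row per pair; numeric fields round-trip through
    :func:`read_predictions` to at least 6 significant figures.
    """
    rows = []
    for rec in records:
        rows.append(
            {
                "trackway_id": rec.trackway_id,
                "model": rec.model,
                "u_pred": repr(float(rec.u_pred)),
                "lower": "" if rec.lower is None else repr(float(rec.lower)),
                "upper": "" if rec.upper is None else repr(float(rec.upper)),
                "gait_call": rec.gait_call or "",
                "percent_error": ""
                if rec.percent_error is None
                else repr(float(rec.percent_error)),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "trackway_id",
            "model",
            "u_pred",
            "lower",
            "upper",
            "gait_call",
            "percent_error",
        ],
    ).to_csv(path, index=False)


def read_predictions(path: str | Path) -> list[PredictionRow]:
    """Read back a predictions CSV written by :func:`write_predictions`."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = []
    for i, row in df.iterrows():
        label = int(i) + 2

        def opt(col: str) -> Optional[float]:
            return _parse_float(row[col], label, col)

        u_pred = opt("u_pred")
        if u_pred is None:
            raise TrackwayParseError(f"row {label}: column 'u_pred' is empty")
        out.append(
            PredictionRow(
                trackway_id=str(row["trackway_id"]),
                model=str(row["model"]),
                u_pred=u_pred,
                lower=opt("lower"),
                upper=opt("upper"),
                gait_call=str(row["gait_call"]) or None,
                percent_error=opt("percent_error"),
            )
        )
    return out
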