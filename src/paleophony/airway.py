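"""Airway geometry: calibrated polyline measurements and pathway records.

Airway lengths are measured on lateral-view images as piecewise-linear
landmark chains (polylines) calibrated against a scale bar.  The measurement
convention is that every airway starts at the internal naris (choana): open
routes run to the anterior opening of the passage or the posterior extremity
of the external naris, closed routes to the closed extremity of a
diverticulum.  Those endpoint semantics are documentation-level conventions;
this module validates lengths, labels and calibration, not anatomy.

Polylines are normally 2-D lateral-view projections.  Points with a third
coordinate (midline curves traced through a CT volume) are accepted by the
same segment-sum rule and flagged in the log.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegeneratePathError,
    InvalidCalibrationError,
    InvalidPathwayError,
)

logger = logging.getLogger(__name__)

#: Taxonomic comparison groups used throughout the analysis.
GROUPS = ("lambeosaurine", "saurolophine", "non_hadrosaurid")

#: Ontogenetic stages.
STAGES = ("juvenile", "subadult", "adult")

#: Recognized airflow routes.
ROUTES = (
    "primary",
    "anterodorsal",
    "anteroventral",
    "lateral_diverticulum",
    "median_chamber",
)

#: Routes modeled as closed-ended tubes by default (part of the hypertrophied
#: lambeosaurine nasal cavity; all other routes are open-ended).
CLOSED_ROUTES = frozenset({"lateral_diverticulum", "median_chamber"})

END_CONDITIONS = ("open", "closed")

#: Column order of the canonical airway table.
AIRWAY_COLUMNS = [
    "specimen_id",
    "taxon",
    "group",
    "stage",
    "route",
    "end_condition",
    "length_m",
]


@dataclass(frozen=True)
class ScaleCalibration:
    """Scale-bar calibration: ``pixels_per_bar`` px span a bar of
    ``bar_length`` meters."""

    pixels_per_bar: float
    bar_length: float

    def __post_init__(self) -> None:
        if not (self.pixels_per_bar > 0 and self.bar_length > 0):
            raise InvalidCalibrationError(
                "calibration requires strictly positive bar pixels and length, "
                f"got {self.pixels_per_bar} px / {self.bar_length} m"
            )

    @property
    def meters_per_pixel(self) -> float:
        return self.bar_length / self.pixels_per_bar


def calibrate_scale(bar_pixels: float, bar_meters: float) -> float:
    """Meters-per-pixel factor from a measured scale bar.

    >>> calibrate_scale(100, 0.10)
    0.001
    """
    return ScaleCalibration(bar_pixels, bar_meters).meters_per_pixel


@dataclass(frozen=True)
class Polyline:
    """Ordered landmark chain in pixel units (2-D, optionally 3-D)."""

    points: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        pts = tuple(tuple(float(c) for c in p) for p in self.points)
        if len(pts) < 2:
            raise DegeneratePathError(
                f"polyline needs at least 2 points, got {len(pts)}"
            )
        dims = {len(p) for p in pts}
        if len(dims) != 1 or next(iter(dims)) not in (2, 3):
            raise DegeneratePathError(
                "polyline points must be uniformly 2-D or 3-D"
            )
        if next(iter(dims)) == 3:
            logger.info("3-D polyline accepted (%d points); lateral-view "
                        "2-D projection is the standard input", len(pts))
        object.__setattr__(self, "points", pts)

    @property
    def pixel_length(self) -> float:
        arr = np.asarray(self.points, dtype=float)
        return float(np.linalg.norm(np.diff(arr, axis=0), axis=1).sum())


def polyline_length(path: Polyline | Sequence[Sequence[float]],
                    scale: float) -> float:
    """Calibrated length in meters: ``scale × Σ‖p_{i+1} − p_i‖``.

    ``scale`` is the meters-per-pixel factor from :func:`calibrate_scale`.
    """
    if not isinstance(path, Polyline):
        path = Polyline(tuple(tuple(p) for p in path))
    if not scale > 0:
        raise InvalidCalibrationError(f"scale must be positive, got {scale}")
    return scale * path.pixel_length


@dataclass(frozen=True)
class AirwayPathway:
    """One measured breathing route with its tube end condition.

    ``end_condition`` defaults per route: diverticulum and median-chamber
    routes are closed-ended, all others open-ended.  An explicit override is
    accepted but logged, since it departs from the modeling convention.
    """

    specimen_id: str
    taxon: str
    group: str
    stage: str
    route: str
    end_condition: str
    length_m: float

    def __post_init__(self) -> None:
        for field, value, allowed in (
            ("group", self.group, GROUPS),
            ("stage", self.stage, STAGES),
            ("route", self.route, ROUTES),
            ("end_condition", self.end_condition, END_CONDITIONS),
        ):
            if value not in allowed:
                raise InvalidPathwayError(
                    f"unknown {field} {value!r}; expected one of {allowed}"
                )
        if not self.specimen_id or not self.taxon:
            raise InvalidPathwayError("specimen_id and taxon are required")
        if not (isinstance(self.length_m, (int, float))
                and math.isfinite(self.length_m) and self.length_m > 0):
            raise InvalidPathwayError(
                f"length must be a positive finite number, got {self.length_m}"
            )
        expected = "closed" if self.route in CLOSED_ROUTES else "open"
        if self.end_condition != expected:
            logger.warning(
                "pathway %s/%s: end_condition %s overrides the default %s "
                "for route %s",
                self.specimen_id, self.route, self.end_condition, expected,
                self.route,
            )


def default_end_condition(route: str) -> str:
    """Modeling default: closed for diverticulum/median-chamber, else open."""
    if route not in ROUTES:
        raise InvalidPathwayError(f"unknown route {route!r}")
    return "closed" if route in CLOSED_ROUTES else "open"


def build_pathway(
    specimen_id: str,
    taxon: str,
    group: str,
    stage: str,
    route: str,
    end_condition: str | None = None,
    *,
    length_m: float | None = None,
    path: Polyline | Sequence[Sequence[float]] | None = None,
    scale: float | None = None,
) -> AirwayPathway:
    """Validated pathway from explicit length or a calibrated polyline.

    Exactly one of ``length_m`` or ``(path, scale)`` must be supplied.
    """
    if (length_m is None) == (path is None):
        raise InvalidPathwayError(
            "provide exactly one of length_m or (path, scale)"
        )
    if length_m is None:
        if scale is None:
            raise InvalidPathwayError("a polyline input requires a scale")
        length_m = polyline_length(path, scale)
    if end_condition is None:
        end_condition = default_end_condition(route)
    return AirwayPathway(
        specimen_id=str(specimen_id),
        taxon=str(taxon),
        group=group,
        stage=stage,
        route=route,
        end_condition=end_condition,
        length_m=float(length_m),
    )


# ---------------------------------------------------------------------------
# Text I/O

def read_landmark_file(path: str | Path) -> tuple[Polyline, ScaleCalibration]:
    """Read a landmark file: one ``x,y`` point per line, plus one sidecar
    calibration line ``bar: <pixels>,<meters>``.

    Lines starting with ``#`` are comments.
    """
    points: list[tuple[float, ...]] = []
    calibration: ScaleCalibration | None = None
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.lower().startswith("bar:"):
            try:
                px, m = (float(v) for v in line[4:].split(","))
            except ValueError as exc:
                raise InvalidCalibrationError(
                    f"{path}:{lineno}: malformed calibration line {line!r}"
                ) from exc
            calibration = ScaleCalibration(px, m)
            continue
        try:
            points.append(tuple(float(v) for v in line.split(",")))
        except ValueError as exc:
            raise DegeneratePathError(
                f"{path}:{lineno}: malformed point {line!r}"
            ) from exc
    if calibration is None:
        raise InvalidCalibrationError(
            f"{path}: no 'bar: <pixels>,<meters>' calibration line"
        )
    return Polyline(tuple(points)), calibration


def read_airway_table(path: str | Path) -> list[AirwayPathway]:
    """Read the canonical airway table (delimited text, header required)."""
    df = pd.read_csv(path, comment="#")
    missing = set(AIRWAY_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidPathwayError(
            f"{path}: airway table missing columns {sorted(missing)}"
        )
    return [
        AirwayPathway(
            specimen_id=str(r.specimen_id),
            taxon=str(r.taxon),
            group=r.group,
            stage=r.stage,
            route=r.route,
            end_condition=r.end_condition,
            length_m=float(r.length_m),
        )
        for r in df.itertuples(index=False)
    ]


def pathways_to_frame(pathways: Iterable[AirwayPathway]) -> pd.DataFrame:
    """Airway records as a DataFrame in canonical column order."""
    return pd.DataFrame(
        [[getattr(p, c) for c in AIRWAY_COLUMNS] for p in pathways],
        columns=AIRWAY_COLUMNS,
    )


def write_airway_table(pathways: Iterable[AirwayPathway],
                       path: str | Path,
                       header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        pathways_to_frame(pathways).to_csv(fh, index=False)
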