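"""Sensory-discriminative pain scores over a body-grid scope.

Four measures are computed from a pain map restricted to a scope:

* ``pains``    -- pain area and intensity number summation: the cumulative
  sum of cell intensities over the scope (unnormalized).
* ``avg_pain`` -- mean intensity of the painful cells (1-3 scale); defined
  as 0 when no cell in scope is painful, so longitudinal series stay total.
* ``max_pain`` -- highest intensity present (0 if none).
* ``area_pct`` -- percent of the scope's cells that are painful, 0-100;
  the denominator is always the scope's own cell count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import BodyAtlas, scope_cells
from .errors import PainsGridError, ScopeError
from .io import PainMap, VisitScales, painmaps_to_frame, scales_to_frame

logger = logging.getLogger(__name__)

#: map-derived measures present in every cohort series
MAP_MEASURES = ("pains", "avg_pain", "max_pain", "area_pct")
#: scalar-scale measures merged in from the visit table
SCALE_MEASURES = ("vas", "panas_pos", "panas_neg")
ALL_MEASURES = MAP_MEASURES + SCALE_MEASURES


@dataclass
class ScoreRecord:
    """Scores for one patient-visit over one scope."""

    patient_id: str
    day: int
    scope: str
    pains: float
    avg_pain: float
    max_pain: int
    area_pct: float
    n_painful: int
    n_scope: int

    @property
    def pains_normalized(self) -> float:
        """PAINS rescaled to [0, 1] by its scope maximum ``3 * n_scope``."""
        return self.pains / (3.0 * self.n_scope)


def score(painmap: PainMap, atlas: BodyAtlas, scope="full") -> ScoreRecord:
    """Score a single pain map over a scope; cells outside scope are ignored."""
    in_scope = scope_cells(atlas, scope)
    if not in_scope:
        raise ScopeError(f"scope {scope!r} contains no cells")
    intensities = [i for c, i in painmap.marks.items() if c in in_scope]
    n_painful = len(intensities)
    pains = float(sum(intensities))
    return ScoreRecord(
        patient_id=painmap.patient_id,
        day=painmap.day,
        scope=_scope_label(scope),
        pains=pains,
        avg_pain=pains / n_painful if n_painful else 0.0,
        max_pain=int(max(intensities)) if n_painful else 0,
        area_pct=100.0 * n_painful / len(in_scope),
        n_painful=n_painful,
        n_scope=len(in_scope),
    )


def score_series(
    painmaps: list[PainMap],
    scales: list[VisitScales] | None,
    atlas: BodyAtlas,
    scope="full",
) -> pd.DataFrame:
    """Build an aligned longitudinal cohort series of scores and scales.

    Returns a tidy DataFrame with one row per (patient_id, day) and columns
    ``pains, avg_pain, max_pain, area_pct, n_painful, vas, panas_pos,
    panas_neg``.  Visits that appear in the scales table with no pain-map
    rows are pain-free: their map scores are zero.  Visits with a map but no
    scales carry NaN scale values.
    """
    in_scope = scope_cells(atlas, scope)
    if not in_scope:
        raise ScopeError(f"scope {scope!r} contains no cells")
    n_scope = len(in_scope)

    marks = painmaps_to_frame(painmaps)
    visits = marks[["patient_id", "day"]].drop_duplicates()
    if scales:
        sc = scales_to_frame(scales)
        visits = pd.concat([visits, sc[["patient_id", "day"]]]).drop_duplicates()
    else:
        sc = None
    visits = visits.sort_values(["patient_id", "day"]).reset_index(drop=True)

    if len(marks):
        marks = marks.loc[marks["cell_id"].isin(in_scope)]
    if len(marks):
        agg = marks.groupby(["patient_id", "day"]).agg(
            pains=("intensity", "sum"),
            max_pain=("intensity", "max"),
            n_painful=("intensity", "size"),
        )
        series = visits.join(agg, on=["patient_id", "day"])
    else:
        series = visits.assign(pains=np.nan, max_pain=np.nan, n_painful=np.nan)
    series[["pains", "max_pain", "n_painful"]] = (
        series[["pains", "max_pain", "n_painful"]].fillna(0)
    )
    n_painful = series["n_painful"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        avg = np.where(n_painful > 0, series["pains"].to_numpy(float) / n_painful, 0.0)
    series["avg_pain"] = avg
    series["area_pct"] = 100.0 * series["n_painful"] / n_scope
    series["pains"] = series["pains"].astype(float)
    series["max_pain"] = series["max_pain"].astype(int)
    series["n_painful"] = series["n_painful"].astype(int)

    if sc is not None:
        series = series.merge(sc, on=["patient_id", "day"], how="left")
    else:
        series[["vas", "panas_pos", "panas_neg"]] = np.nan
    cols = ["patient_id", "day", *MAP_MEASURES, "n_painful", *SCALE_MEASURES]
    return series[cols]


def delta_change(
    series: pd.DataFrame, day_from: int, day_to: int, measure: str = "pains"
) -> pd.Series:
    """Per-patient change ``value(day_to) - value(day_from)`` of one measure.

    Patients missing either visit are dropped with a logged warning.
    """
    if measure not in series.columns:
        raise PainsGridError(
            f"unknown measure {measure!r}; available: "
            f"{', '.join(c for c in series.columns if c not in ('patient_id', 'day'))}"
        )
    wide = series.pivot(index="patient_id", columns="day", values=measure)
    for day in (day_from, day_to):
        if day not in wide.columns:
            raise PainsGridError(f"no visits at day {day} in series")
    delta = wide[day_to] - wide[day_from]
    dropped = delta.index[delta.isna()].tolist()
    if dropped:
        logger.warning(
            "delta_change(%s, %d->%d): dropping patients missing a visit: %s",
            measure, day_from, day_to, dropped,
        )
    return delta.dropna().rename(f"delta_{measure}")


def write_scores(records: list[ScoreRecord], path) -> None:
    """Write score records to CSV (one row per patient-visit-scope)."""
    pd.DataFrame([vars(r) for r in records])[
        ["patient_id", "day", "scope", "pains", "avg_pain", "max_pain",
         "area_pct", "n_painful", "n_scope"]
    ].to_csv(path, index=False)


def _scope_label(scope) -> str:
    if isinstance(scope, str):
        return scope
    return "&".join(str(s) for s in scope)
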