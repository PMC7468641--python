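"""Cohort pain epicenter and per-patient spread (scatter score) analysis.

The *epicenter* is the cell marked painful in the largest number of
patient-visits across a cohort.  A patient's *scatter score* is the
intensity-weighted mean grid distance of their painful cells from the
epicenter -- zero when all pain sits on the epicenter itself, growing as
pain spreads away from it.  Distances are Euclidean on the (row, col) chart
of the epicenter's body segment; cells on another segment chart have no
shared coordinate frame and receive a fixed penalty distance (by default
the larger of the two charts' diagonals).

The scatter-score formula is this package's reconstruction of a
spread-from-epicenter statistic: the weighted mean was chosen for its
translation invariance within a chart and its invariance to uniform
intensity rescaling.

The chronicity association tests whether patients with longer pain history
show larger baseline spread, via Pearson correlation / OLS of scatter score
on pain duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import BodyAtlas, scope_cells
from .errors import DegenerateInputError, EmptyCohortError, ScopeError
from .io import PainMap, PatientMeta, meta_to_frame, painmaps_to_frame


@dataclass
class EpicenterResult:
    """The cohort's most frequently marked cell."""

    epicenter_cell: int
    frequency: int          # patient-visits marking the cell
    runner_up_margin: int   # frequency minus the next-most-marked cell's


@dataclass
class ScatterScore:
    """Intensity-weighted mean grid distance of one map's pain from a cell."""

    patient_id: str
    day: int
    score: float


def grid_distances(atlas: BodyAtlas, ref_cell: int,
                   segment_penalty: float | None = None) -> pd.Series:
    """Distance from every atlas cell to ``ref_cell``.

    Euclidean on (row, col) for cells sharing the reference cell's segment
    chart; ``segment_penalty`` for all other cells (default: the larger
    chart diagonal of the two segments involved).
    """
    ref = atlas.cell(ref_cell)
    cells = atlas.cells
    same = (cells["segment"] == ref["segment"]).to_numpy()
    d = np.empty(len(cells))
    dr = cells["row"].to_numpy(float) - float(ref["row"])
    dc = cells["col"].to_numpy(float) - float(ref["col"])
    d[same] = np.hypot(dr[same], dc[same])
    if (~same).any():
        ref_diag = atlas.segment_diagonal(ref["segment"])
        if segment_penalty is not None:
            d[~same] = segment_penalty
        else:
            for seg in cells.loc[~same, "segment"].unique():
                m = (~same) & (cells["segment"] == seg).to_numpy()
                d[m] = max(ref_diag, atlas.segment_diagonal(seg))
    return pd.Series(d, index=cells["cell_id"].to_numpy())


def find_epicenter(painmaps: list[PainMap], atlas: BodyAtlas,
                   scope="full") -> EpicenterResult:
    """Cell painful in the most patient-visits, within a scope.

    Ties are broken by larger total intensity sum, then by smaller cell_id,
    so the result is deterministic.
    """
    in_scope = scope_cells(atlas, scope)
    marks = painmaps_to_frame(painmaps)
    if len(marks):
        marks = marks.loc[marks["cell_id"].isin(in_scope)]
    if not len(marks):
        raise EmptyCohortError(f"no painful cells in scope {scope!r}")
    per_cell = marks.groupby("cell_id").agg(
        frequency=("intensity", "size"),
        intensity_sum=("intensity", "sum"),
    ).reset_index()
    per_cell = per_cell.sort_values(
        ["frequency", "intensity_sum", "cell_id"],
        ascending=[False, False, True],
    ).reset_index(drop=True)
    top = per_cell.iloc[0]
    runner = int(per_cell["frequency"].iloc[1]) if len(per_cell) > 1 else 0
    return EpicenterResult(
        epicenter_cell=int(top["cell_id"]),
        frequency=int(top["frequency"]),
        runner_up_margin=int(top["frequency"]) - runner,
    )


def scatter_score(painmap: PainMap, epicenter_cell: int, atlas: BodyAtlas,
                  segment_penalty: float | None = None) -> ScatterScore:
    """Intensity-weighted mean grid distance of painful cells from the epicenter.

    ``score = sum_c w_c d(c, epicenter) / sum_c w_c`` with ``w_c`` the cell's
    intensity; an empty map scores 0 by convention.
    """
    if not painmap.marks:
        return ScatterScore(painmap.patient_id, painmap.day, 0.0)
    d = grid_distances(atlas, epicenter_cell, segment_penalty=segment_penalty)
    cells = np.fromiter(painmap.marks.keys(), dtype=int)
    weights = np.fromiter(painmap.marks.values(), dtype=float)
    missing = set(cells.tolist()) - set(d.index.tolist())
    if missing:
        raise ScopeError(f"painmap references cells not in atlas: {sorted(missing)}")
    dist = d.loc[cells].to_numpy()
    return ScatterScore(
        painmap.patient_id,
        painmap.day,
        float(np.average(dist, weights=weights)),
    )


def scatter_scores_at_baseline(
    painmaps: list[PainMap], atlas: BodyAtlas, scope="full",
    baseline_day: int = 0, epicenter_cell: int | None = None,
) -> pd.DataFrame:
    """Per-patient baseline scatter scores (epicenter found on baseline maps).

    Returns a DataFrame ``patient_id, scatter`` plus the epicenter cell used
    (in ``df.attrs['epicenter_cell']``).
    """
    base = [m for m in painmaps if m.day == baseline_day]
    if epicenter_cell is None:
        epicenter_cell = find_epicenter(base, atlas, scope).epicenter_cell
    in_scope = scope_cells(atlas, scope)
    rows = []
    for m in base:
        clipped = PainMap(m.patient_id, m.day,
                          {c: i for c, i in m.marks.items() if c in in_scope})
        rows.append(
            {"patient_id": m.patient_id,
             "scatter": scatter_score(clipped, epicenter_cell, atlas).score}
        )
    out = pd.DataFrame(rows, columns=["patient_id", "scatter"])
    out.attrs["epicenter_cell"] = epicenter_cell
    return out


def chronicity_association(
    scatter: pd.DataFrame, meta: list[PatientMeta] | pd.DataFrame
) -> dict[str, float]:
    """Pearson association between pain duration and baseline scatter score.

    Returns ``{r, p, slope, intercept, n}`` from an OLS fit of scatter on
    duration; ``p`` is the two-sided t-test p-value of the correlation.
    """
    meta_df = meta if isinstance(meta, pd.DataFrame) else meta_to_frame(meta)
    joined = scatter.merge(meta_df, on="patient_id").dropna(
        subset=["scatter", "pain_duration_years"]
    )
    if len(joined) < 3:
        raise DegenerateInputError(
            f"need >= 3 patients with duration and scatter; got {len(joined)}"
        )
    x = joined["pain_duration_years"].to_numpy(float)
    y = joined["scatter"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError(
            "zero variance in duration or scatter score; correlation undefined"
        )
    fit = stats.linregress(x, y)
    return {
        "r": float(fit.rvalue),
        "p": float(fit.pvalue),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "n": int(len(joined)),
    }
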