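"""Read, write and validate longitudinal pain-map and scale observations.

All tables are long-format (tidy) CSV:

* ``painmaps.csv`` -- ``patient_id,day,cell_id,intensity`` with one row per
  painful cell per visit; intensity is 1 (mild), 2 (moderate) or 3 (severe).
* ``scales.csv``   -- ``patient_id,day,vas,panas_pos,panas_neg``.
* ``meta.csv``     -- ``patient_id,arm,pain_duration_years``.

``day`` is the integer study day (0 = baseline).  Missing visits are simply
absent rows; a visit present in the scales table but with no pain-map rows
is a legal pain-free visit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .atlas import BodyAtlas
from .errors import DataValidationError

ARMS = ("active", "sham")
INTENSITY_LABELS = {1: "mild", 2: "moderate", 3: "severe"}


@dataclass
class PainMap:
    """One patient-visit assignment of intensities to cells (sparse)."""

    patient_id: str
    day: int
    marks: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {c: i for c, i in self.marks.items() if i not in (1, 2, 3)}
        if bad:
            raise DataValidationError(
                f"intensities must be 1, 2 or 3; got {bad} "
                f"for patient {self.patient_id} day {self.day}"
            )

    @property
    def n_marks(self) -> int:
        return len(self.marks)


@dataclass
class VisitScales:
    """Per-visit scalar scales: VAS pain (0-10) and PANAS mood subscales."""

    patient_id: str
    day: int
    vas: float
    panas_pos: float
    panas_neg: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.vas <= 10.0:
            raise DataValidationError(
                f"vas must lie in [0, 10]; got {self.vas} "
                f"for patient {self.patient_id} day {self.day}"
            )


@dataclass
class PatientMeta:
    """Per-patient trial metadata: treatment arm and pain chronicity."""

    patient_id: str
    arm: str
    pain_duration_years: float

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise DataValidationError(
                f"arm must be one of {ARMS}; got {self.arm!r} "
                f"for patient {self.patient_id}"
            )
        if not self.pain_duration_years >= 0:
            raise DataValidationError(
                f"pain_duration_years must be finite and >= 0; got "
                f"{self.pain_duration_years} for patient {self.patient_id}"
            )


# -- painmaps ----------------------------------------------------------------

def painmaps_from_frame(df: pd.DataFrame, atlas: BodyAtlas) -> list[PainMap]:
    """Validate a long-format mark table and group it into PainMap objects.

    Rows with intensity 0 are treated as explicit "no pain here" and dropped.
    """
    required = ["patient_id", "day", "cell_id", "intensity"]
    _check_columns(df, required, "painmaps")
    df = df.copy()
    df["patient_id"] = df["patient_id"].astype(str)
    for col in ("day", "cell_id", "intensity"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(int)

    dup = df.duplicated(subset=["patient_id", "day", "cell_id"], keep=False)
    if dup.any():
        first = df.loc[dup].iloc[0]
        raise DataValidationError(
            "duplicate mark for patient "
            f"{first['patient_id']!r} day {first['day']} cell {first['cell_id']}"
        )
    bad = ~df["intensity"].isin([0, 1, 2, 3])
    if bad.any():
        idx = df.index[bad][0]
        raise DataValidationError(
            f"row {idx}: intensity {df.loc[idx, 'intensity']} outside {{1,2,3}}"
        )
    known = set(atlas.cell_ids.tolist())
    unknown = set(df["cell_id"]) - known
    if unknown:
        raise DataValidationError(
            f"cell_id(s) not in atlas: {sorted(unknown)[:10]}"
        )
    df = df.loc[df["intensity"] > 0]
    maps = [
        PainMap(patient_id=pid, day=int(day),
                marks=dict(zip(g["cell_id"].tolist(), g["intensity"].tolist())))
        for (pid, day), g in df.groupby(["patient_id", "day"], sort=True)
    ]
    return maps


def read_painmaps(path, atlas: BodyAtlas) -> list[PainMap]:
    """Read ``painmaps.csv`` and return one PainMap per (patient, day)."""
    df = pd.read_csv(path)
    return painmaps_from_frame(df, atlas)


def painmaps_to_frame(painmaps: list[PainMap]) -> pd.DataFrame:
    rows = [
        {"patient_id": m.patient_id, "day": m.day, "cell_id": c, "intensity": i}
        for m in painmaps
        for c, i in sorted(m.marks.items())
    ]
    return pd.DataFrame(rows, columns=["patient_id", "day", "cell_id", "intensity"])


def write_painmaps(painmaps: list[PainMap], path) -> None:
    painmaps_to_frame(painmaps).to_csv(path, index=False)


# -- scales and metadata ------------------------------------------------------

def scales_from_frame(df: pd.DataFrame) -> list[VisitScales]:
    required = ["patient_id", "day", "vas", "panas_pos", "panas_neg"]
    _check_columns(df, required, "scales")
    out = []
    for idx, row in df.iterrows():
        try:
            out.append(
                VisitScales(
                    patient_id=str(row["patient_id"]),
                    day=int(row["day"]),
                    vas=float(row["vas"]),
                    panas_pos=float(row["panas_pos"]),
                    panas_neg=float(row["panas_neg"]),
                )
            )
        except DataValidationError as err:
            raise DataValidationError(f"scales row {idx}: {err}") from None
    dup = df.duplicated(subset=["patient_id", "day"], keep=False)
    if dup.any():
        first = df.loc[dup].iloc[0]
        raise DataValidationError(
            f"duplicate scales row for patient {first['patient_id']!r} "
            f"day {first['day']}"
        )
    return out


def read_scales(path) -> list[VisitScales]:
    return scales_from_frame(pd.read_csv(path))


def scales_to_frame(scales: list[VisitScales]) -> pd.DataFrame:
    return pd.DataFrame(
        [vars(s) for s in scales],
        columns=["patient_id", "day", "vas", "panas_pos", "panas_neg"],
    )


def write_scales(scales: list[VisitScales], path) -> None:
    scales_to_frame(scales).to_csv(path, index=False)


def meta_from_frame(df: pd.DataFrame) -> list[PatientMeta]:
    required = ["patient_id", "arm", "pain_duration_years"]
    _check_columns(df, required, "meta")
    out = []
    for idx, row in df.iterrows():
        try:
            out.append(
                PatientMeta(
                    patient_id=str(row["patient_id"]),
                    arm=str(row["arm"]),
                    pain_duration_years=float(row["pain_duration_years"]),
                )
            )
        except DataValidationError as err:
            raise DataValidationError(f"meta row {idx}: {err}") from None
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise DataValidationError(f"duplicate meta row for patient {dup!r}")
    return out


def read_meta(path) -> list[PatientMeta]:
    return meta_from_frame(pd.read_csv(path))


def meta_to_frame(meta: list[PatientMeta]) -> pd.DataFrame:
    return pd.DataFrame(
        [vars(m) for m in meta],
        columns=["patient_id", "arm", "pain_duration_years"],
    )


def write_meta(meta: list[PatientMeta], path) -> None:
    meta_to_frame(meta).to_csv(path, index=False)


def _check_columns(df: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataValidationError(
            f"{name} table missing column(s): {', '.join(missing)}"
        )
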