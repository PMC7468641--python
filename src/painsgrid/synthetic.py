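"""Seeded synthetic longitudinal trial cohorts for validating the pipeline.

The generator emulates a small two-arm neuromodulation trial in chronic
craniofacial pain: each patient carries a latent *sensory severity* state
``S_t`` (stationary AR(1) over study days) and an independent latent *mood*
state ``M_t``.  The treatment shifts the active arm's sensory state
downward after the stimulation week.  Observables are built so that the
hypothesized measurement structure is true by construction:

* pain maps derive from ``S_t`` alone -- cells are painful with probability
  decaying as a Gaussian kernel around an epicenter cell, with kernel width
  ``sigma0 + spread_slope * duration`` (spread grows with chronicity) and
  overall marking probability rising with ``S_t``; cell intensities (1-3)
  increase stochastically with ``S_t``;
* VAS mixes the sensory state with mood (``beta_mood_vas``) plus noise, so
  mood contaminates VAS but never the map-derived measures;
* PANAS subscales are noisy readouts of mood only.

``treatment_delta`` is the standardized one-month treatment effect: the
active-arm downshift equals ``treatment_delta`` times the null standard
deviation of the latent change from baseline to the last visit,
``sqrt(2 (1 - phi^D))`` for an AR(1) with unit variance and span ``D`` days.
The two-arm comparison of latent deltas therefore has Cohen's d equal to
``treatment_delta`` exactly, and map-derived measures inherit it up to the
(small) map sampling noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .atlas import BodyAtlas, build_default_atlas
from .epicenter import grid_distances
from .errors import DataValidationError
from .io import PainMap, PatientMeta, VisitScales

DEFAULT_VISIT_DAYS = (0, 1, 2, 3, 4, 5, 12, 33)


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for a synthetic trial cohort.

    Defaults emulate a 24-patient, two-arm, ~40-day trial with baseline,
    five stimulation days, a 1-week and a 1-month follow-up.
    """

    n_patients: int = 24
    active_fraction: float = 0.5
    visit_days: tuple[int, ...] = DEFAULT_VISIT_DAYS
    treatment_end_day: int = 5      # shift applies to visits after this day

    # latent dynamics (daily AR(1) coefficients, unit stationary variance)
    phi_sensory: float = 0.9
    phi_mood: float = 0.4
    sensory_offset_sd: float = 0.8  # stable per-patient severity shift
    treatment_delta: float = 0.6    # standardized 1-month effect, active arm

    # spatial pain-map model
    epicenter_cell: int | None = None   # default: centroid cell of right jaw
    sigma0: float = 2.0                 # kernel width at zero duration, cells
    spread_slope: float = 0.25          # d(sigma)/d(duration), cells per year
    duration_range_years: tuple[float, float] = (2.0, 10.0)
    p_max: float = 0.6                  # peak marking probability at S = 0
    area_gain: float = 0.5              # log marking-probability gain per unit S
    intensity_base: float = 2.0         # mean cell intensity at S = 0
    intensity_slope: float = 0.4        # d(mean intensity)/dS
    intensity_noise_sd: float = 0.15    # per-cell intensity jitter

    # scalar scales
    vas_baseline: float = 5.0
    vas_gain: float = 0.05              # sensory loading on VAS
    beta_mood_vas: float = 1.2          # mood loading on VAS
    vas_noise_sd: float = 0.5
    vas_offset_sd: float = 0.2          # stable per-patient VAS shift
    panas_pos_baseline: float = 28.0
    panas_neg_baseline: float = 18.0
    panas_gain: float = 3.0             # mood loading on PANAS subscales
    panas_noise_sd: float = 3.0

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise DataValidationError("n_patients must be >= 2")
        if not 0 < self.active_fraction < 1:
            raise DataValidationError("active_fraction must lie in (0, 1)")
        days = tuple(self.visit_days)
        if len(days) < 1 or days[0] != 0 or any(
            b <= a for a, b in zip(days, days[1:])
        ):
            raise DataValidationError(
                "visit_days must be strictly increasing and start at 0"
            )
        for name in ("phi_sensory", "phi_mood"):
            if not abs(getattr(self, name)) < 1:
                raise DataValidationError(f"|{name}| must be < 1")
        for name in ("sigma0", "p_max", "intensity_noise_sd", "vas_noise_sd",
                     "panas_noise_sd", "panas_gain"):
            if not getattr(self, name) > 0:
                raise DataValidationError(f"{name} must be > 0")
        if not 0 < self.p_max <= 1:
            raise DataValidationError("p_max must lie in (0, 1]")
        if self.spread_slope < 0 or self.vas_offset_sd < 0:
            raise DataValidationError("spread_slope and vas_offset_sd must be >= 0")
        lo, hi = self.duration_range_years
        if not (0 <= lo <= hi):
            raise DataValidationError("duration_range_years must satisfy 0 <= lo <= hi")


@dataclass
class SimulatedCohort:
    """Synthetic observations plus the generating latent states."""

    painmaps: list[PainMap]
    scales: list[VisitScales]
    meta: list[PatientMeta]
    latent: pd.DataFrame      # patient_id, day, sensory, mood, sigma
    config: SimConfig
    atlas: BodyAtlas = field(repr=False, default=None)


def default_epicenter(atlas: BodyAtlas) -> int:
    """Centroid cell of the right jaw region (a TMD-like epicenter)."""
    rid = atlas.region_id("jaw", "right")
    sub = atlas.cells.loc[atlas.cells["region_id"] == rid]
    center = sub[["row", "col"]].mean()
    d2 = (sub["row"] - center["row"]) ** 2 + (sub["col"] - center["col"]) ** 2
    return int(sub.loc[d2.idxmin(), "cell_id"])


def _ar1_paths(rng: np.random.Generator, n: int, days: np.ndarray,
               phi: float) -> np.ndarray:
    """Stationary unit-variance AR(1) sampled at (possibly irregular) days."""
    out = np.empty((n, len(days)))
    out[:, 0] = rng.standard_normal(n)
    for j in range(1, len(days)):
        a = phi ** (days[j] - days[j - 1])
        out[:, j] = a * out[:, j - 1] + math.sqrt(1 - a * a) * rng.standard_normal(n)
    return out


def delta_sd(phi: float, span_days: int) -> float:
    """Null SD of the change over ``span_days`` of a unit-variance AR(1)."""
    return math.sqrt(2.0 * (1.0 - phi ** span_days))


def simulate_cohort(config: SimConfig, atlas: BodyAtlas | None = None) -> SimulatedCohort:
    """Generate one synthetic cohort; fully reproducible from ``config.seed``."""
    if atlas is None:
        atlas = build_default_atlas()
    rng = np.random.default_rng(config.seed)
    days = np.asarray(config.visit_days, dtype=int)
    n, v = config.n_patients, len(days)
    width = len(str(n))
    patients = [f"p{i + 1:0{width}d}" for i in range(n)]
    n_active = round(n * config.active_fraction)
    arms = np.array(["active"] * n_active + ["sham"] * (n - n_active))

    lo, hi = config.duration_range_years
    durations = rng.uniform(lo, hi, size=n)

    offsets = config.sensory_offset_sd * rng.standard_normal(n)
    sensory = offsets[:, None] + _ar1_paths(rng, n, days, config.phi_sensory)
    mood = _ar1_paths(rng, n, days, config.phi_mood)
    # downshift sized so the active-vs-sham latent delta (last visit minus
    # baseline; the stable offset cancels) has Cohen's d = treatment_delta
    shift = config.treatment_delta * delta_sd(config.phi_sensory, int(days[-1] - days[0]))
    post = days > config.treatment_end_day
    sensory = sensory - shift * np.outer(arms == "active", post)

    # ---- pain maps -------------------------------------------------------
    epicenter = (config.epicenter_cell if config.epicenter_cell is not None
                 else default_epicenter(atlas))
    d2 = grid_distances(atlas, epicenter).to_numpy() ** 2     # per cell
    cell_ids = atlas.cell_ids
    sigma_pat = config.sigma0 + config.spread_slope * durations
    # marking probability: Gaussian kernel in distance, scaled up/down by S
    # (severity widens the marked patch; probabilities cap per cell at 1)
    gain = config.p_max * np.exp(config.area_gain * sensory)
    kernel = np.exp(-d2[None, None, :] / (2.0 * sigma_pat[:, None, None] ** 2))
    prob = np.minimum(gain[:, :, None] * kernel, 1.0)
    painful = rng.random((n, v, len(cell_ids))) < prob

    mu = (config.intensity_base
          + config.intensity_slope * sensory[:, :, None]
          + config.intensity_noise_sd * rng.standard_normal(painful.shape))
    mu = np.clip(mu, 1.0, 3.0)
    base = np.floor(mu)
    intensity = (base + (rng.random(painful.shape) < (mu - base))).astype(int)
    intensity = np.minimum(intensity, 3)

    painmaps = []
    for i, pid in enumerate(patients):
        for j, day in enumerate(days):
            idx = np.flatnonzero(painful[i, j])
            marks = dict(zip(cell_ids[idx].tolist(), intensity[i, j, idx].tolist()))
            painmaps.append(PainMap(patient_id=pid, day=int(day), marks=marks))

    # ---- scalar scales ---------------------------------------------------
    vas_offset = config.vas_offset_sd * rng.standard_normal(n)
    vas = np.clip(
        config.vas_baseline
        + config.vas_gain * sensory
        + config.beta_mood_vas * mood
        + vas_offset[:, None]
        + config.vas_noise_sd * rng.standard_normal((n, v)),
        0.0, 10.0,
    )
    pos = np.clip(
        config.panas_pos_baseline - config.panas_gain * mood
        + config.panas_noise_sd * rng.standard_normal((n, v)),
        10.0, 50.0,
    )
    neg = np.clip(
        config.panas_neg_baseline + config.panas_gain * mood
        + config.panas_noise_sd * rng.standard_normal((n, v)),
        10.0, 50.0,
    )
    scales = [
        VisitScales(patient_id=patients[i], day=int(days[j]),
                    vas=round(float(vas[i, j]), 3),
                    panas_pos=round(float(pos[i, j]), 3),
                    panas_neg=round(float(neg[i, j]), 3))
        for i in range(n) for j in range(v)
    ]
    meta = [
        PatientMeta(patient_id=patients[i], arm=str(arms[i]),
                    pain_duration_years=round(float(durations[i]), 3))
        for i in range(n)
    ]
    latent = pd.DataFrame(
        {
            "patient_id": np.repeat(patients, v),
            "day": np.tile(days, n),
            "sensory": sensory.ravel(),
            "mood": mood.ravel(),
            "sigma": np.repeat(sigma_pat, v),
        }
    )
    return SimulatedCohort(painmaps=painmaps, scales=scales, meta=meta,
                           latent=latent, config=config, atlas=atlas)


def simulate_ar1_series(n_patients: int, n_days: int, phi: float,
                        seed: int | None = None,
                        measure: str = "value") -> pd.DataFrame:
    """Dense daily AR(1) panel for calibrating the reliability engine.

    Returns a tidy series (``patient_id, day, <measure>``) of stationary
    unit-variance AR(1) paths, whose pooled lag-L autocorrelation is
    ``phi**L`` by construction.
    """
    rng = np.random.default_rng(seed)
    days = np.arange(n_days)
    paths = _ar1_paths(rng, n_patients, days, phi)
    width = len(str(n_patients))
    return pd.DataFrame(
        {
            "patient_id": np.repeat(
                [f"p{i + 1:0{width}d}" for i in range(n_patients)], n_days
            ),
            "day": np.tile(days, n_patients),
            measure: paths.ravel(),
        }
    )


# ---- bundled deterministic fixtures ---------------------------------------

FIXTURE_NAMES = ("tiny", "trial_like")
_TRIAL_LIKE_SEED = 20200819


def make_fixture(name: str, atlas: BodyAtlas | None = None) -> dict[str, pd.DataFrame]:
    """Small deterministic datasets for examples and tests.

    ``tiny``: 2 patients, 3 visits, 5 painful cells total (hand-written).
    ``trial_like``: the default 24-patient 8-visit cohort at a fixed seed.
    Regenerating with the same name yields identical tables.
    """
    from .io import meta_to_frame, painmaps_to_frame, scales_to_frame

    if atlas is None:
        atlas = build_default_atlas()
    if name == "tiny":
        jaw_r = atlas.region_id("jaw", "right")
        cells = atlas.cells.loc[
            atlas.cells["region_id"] == jaw_r, "cell_id"
        ].tolist()[:3]
        c1, c2, c3 = cells
        painmaps = pd.DataFrame(
            [
                ("p1", 0, c1, 2), ("p1", 0, c2, 1),
                ("p1", 5, c1, 3),
                ("p2", 0, c3, 1),
                ("p2", 33, c1, 2),
            ],
            columns=["patient_id", "day", "cell_id", "intensity"],
        )
        scales = pd.DataFrame(
            [
                ("p1", 0, 6.0, 25.0, 20.0), ("p1", 5, 4.0, 28.0, 18.0),
                ("p1", 33, 3.0, 30.0, 15.0),
                ("p2", 0, 5.0, 27.0, 19.0), ("p2", 5, 5.5, 26.0, 21.0),
                ("p2", 33, 4.5, 29.0, 17.0),
            ],
            columns=["patient_id", "day", "vas", "panas_pos", "panas_neg"],
        )
        meta = pd.DataFrame(
            [("p1", "active", 8.0), ("p2", "sham", 3.5)],
            columns=["patient_id", "arm", "pain_duration_years"],
        )
        return {"painmaps": painmaps, "scales": scales, "meta": meta}
    if name == "trial_like":
        cohort = simulate_cohort(replace(SimConfig(), seed=_TRIAL_LIKE_SEED), atlas)
        return {
            "painmaps": painmaps_to_frame(cohort.painmaps),
            "scales": scales_to_frame(cohort.scales),
            "meta": meta_to_frame(cohort.meta),
        }
    raise DataValidationError(
        f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
    )
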