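"""Test-retest reliability as lag autocorrelation of a longitudinal measure.

For a lag of ``L`` days, every pair of visits of the same patient whose
study days differ by exactly ``L`` contributes one (earlier, later) point;
pairs are pooled across patients and the Pearson correlation of the pooled
points is the lag-``L`` autocorrelation.  Pooling across patients (rather
than averaging per-patient correlations) is required for small cohorts with
sparse visit schedules, where individual patients rarely have enough pairs
at any one lag.  Lags with fewer than 3 pairs, or with a constant measure,
are omitted: Pearson on two points is identically +/-1.

A cubic smoothing spline (smoothing parameter by generalized
cross-validation, weights proportional to pair counts) summarizes the trend
of reliability with lag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .errors import DegenerateInputError, PainsGridError

logger = logging.getLogger(__name__)

MIN_PAIRS_PER_LAG = 3


@dataclass
class ReliabilityCurve:
    """Lag autocorrelations of one measure (raw and optionally smoothed)."""

    measure: str
    lags: np.ndarray          # strictly increasing, only retained lags
    r: np.ndarray             # Pearson r per lag, in [-1, 1]
    n_pairs: np.ndarray       # pooled pair count per lag
    smoothed: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"measure": self.measure, "lag": self.lags,
             "r": self.r, "n_pairs": self.n_pairs}
        )
        df["smoothed"] = self.smoothed if self.smoothed is not None else np.nan
        return df

    def mean_r(self, min_lag: int = 2) -> float:
        """Mean raw autocorrelation over lags >= ``min_lag``."""
        keep = self.lags >= min_lag
        if not keep.any():
            raise DegenerateInputError(
                f"no retained lags >= {min_lag} for measure {self.measure!r}"
            )
        return float(self.r[keep].mean())


def pair_table(series: pd.DataFrame, measure: str, max_lag: int) -> pd.DataFrame:
    """All within-patient visit pairs with day difference in ``1..max_lag``.

    Returns columns ``patient_id, lag, x, y`` where x is the earlier visit's
    value.  This is the pooled-pair construction every autocorrelation is
    computed from.
    """
    if measure not in series.columns:
        raise PainsGridError(f"unknown measure {measure!r} in series")
    df = series[["patient_id", "day", measure]].dropna(subset=[measure])
    left = df.rename(columns={"day": "day_x", measure: "x"})
    right = df.rename(columns={"day": "day_y", measure: "y"})
    pairs = left.merge(right, on="patient_id")
    pairs["lag"] = pairs["day_y"] - pairs["day_x"]
    pairs = pairs.loc[(pairs["lag"] >= 1) & (pairs["lag"] <= max_lag)]
    return pairs[["patient_id", "lag", "x", "y"]].reset_index(drop=True)


def _pearson_by_lag(pairs: pd.DataFrame,
                    weights: np.ndarray | None = None) -> pd.DataFrame:
    """Per-lag (weighted) Pearson r and pair counts, vectorized.

    ``weights`` are per-pair multiplicities (used by the patient bootstrap);
    counts always refer to the weighted total.
    """
    w = np.ones(len(pairs)) if weights is None else np.asarray(weights, float)
    d = pairs.assign(
        w=w,
        wx=w * pairs["x"], wy=w * pairs["y"],
        wxx=w * pairs["x"] ** 2, wyy=w * pairs["y"] ** 2,
        wxy=w * pairs["x"] * pairs["y"],
    )
    g = d.groupby("lag")[["w", "wx", "wy", "wxx", "wyy", "wxy"]].sum()
    n = g["w"]
    sxx = n * g["wxx"] - g["wx"] ** 2
    syy = n * g["wyy"] - g["wy"] ** 2
    sxy = n * g["wxy"] - g["wx"] * g["wy"]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = sxy / np.sqrt(sxx * syy)
    return pd.DataFrame({"lag": g.index, "r": r.to_numpy(),
                         "n_pairs": n.to_numpy()}).reset_index(drop=True)


def lag_autocorrelation(series: pd.DataFrame, measure: str,
                        max_lag: int = 40) -> ReliabilityCurve:
    """Pooled lag-1..max_lag Pearson autocorrelations of one measure."""
    pairs = pair_table(series, measure, max_lag)
    if not len(pairs):
        raise DegenerateInputError(
            f"no within-patient visit pairs at lags 1..{max_lag}"
        )
    stats_df = _pearson_by_lag(pairs)
    few = stats_df["n_pairs"] < MIN_PAIRS_PER_LAG
    undefined = stats_df["r"].isna() & ~few
    if undefined.any():
        logger.warning(
            "measure %r constant at lag(s) %s; omitted",
            measure, stats_df.loc[undefined, "lag"].tolist(),
        )
    keep = stats_df.loc[~few & ~stats_df["r"].isna()]
    return ReliabilityCurve(
        measure=measure,
        lags=keep["lag"].to_numpy(int),
        r=keep["r"].to_numpy(float),
        n_pairs=keep["n_pairs"].to_numpy(int),
    )


def smooth_curve(curve: ReliabilityCurve) -> ReliabilityCurve:
    """Fit a GCV cubic smoothing spline of r on lag, weighted by pair count.

    Smoothed values are clipped to [-1, 1].  Requires at least 4 retained
    lags; use the raw curve below that.
    """
    if len(curve.lags) < 4:
        raise DegenerateInputError(
            f"smoothing needs >= 4 retained lags, got {len(curve.lags)}; "
            "use the raw curve"
        )
    spline = make_smoothing_spline(
        curve.lags.astype(float), curve.r, w=curve.n_pairs.astype(float)
    )
    smoothed = np.clip(spline(curve.lags.astype(float)), -1.0, 1.0)
    return replace(curve, smoothed=smoothed)


@dataclass
class ReliabilityComparison:
    """Reliability curves for several measures plus a long-lag summary."""

    curves: dict[str, ReliabilityCurve]
    summary: pd.DataFrame              # measure, mean_r (lags > 1)
    diff: float                        # mean_r[measures[0]] - mean_r[measures[1]]
    ci_low: float
    ci_high: float
    n_boot: int


def compare_reliability(
    series: pd.DataFrame,
    measures: list[str],
    max_lag: int = 40,
    n_boot: int = 1000,
    seed: int | None = None,
    min_lag_summary: int = 2,
) -> ReliabilityComparison:
    """Compare long-lag (> 1 day) reliability across measures.

    The summary statistic per measure is the mean raw autocorrelation over
    retained lags >= 2.  The difference between the first two measures gets
    a percentile bootstrap CI from patient-level resampling (each resampled
    patient contributes all its pooled pairs with multiplicity).
    """
    if len(measures) < 2:
        raise PainsGridError("need at least two measures to compare")
    curves, tables = {}, {}
    for m in measures:
        curves[m] = lag_autocorrelation(series, m, max_lag)
        tables[m] = pair_table(series, m, max_lag)
    summary = pd.DataFrame(
        {"measure": measures,
         "mean_r": [curves[m].mean_r(min_lag_summary) for m in measures]}
    )

    m0, m1 = measures[0], measures[1]
    diff = float(summary.loc[0, "mean_r"] - summary.loc[1, "mean_r"])
    rng = np.random.default_rng(seed)
    patients = series["patient_id"].unique()
    boots = np.empty(n_boot)
    for b in range(n_boot):
        draw = rng.choice(patients, size=len(patients), replace=True)
        mult = pd.Series(draw).value_counts()
        vals = []
        for m in (m0, m1):
            t = tables[m]
            w = t["patient_id"].map(mult).fillna(0).to_numpy(float)
            st = _pearson_by_lag(t, weights=w)
            keep = (
                (st["lag"] >= min_lag_summary)
                & (st["n_pairs"] >= MIN_PAIRS_PER_LAG)
                & st["r"].notna()
            )
            vals.append(st.loc[keep, "r"].mean() if keep.any() else np.nan)
        boots[b] = vals[0] - vals[1]
    boots = boots[~np.isnan(boots)]
    lo, hi = np.percentile(boots, [2.5, 97.5]) if len(boots) else (np.nan, np.nan)
    return ReliabilityComparison(
        curves=curves, summary=summary, diff=diff,
        ci_low=float(lo), ci_high=float(hi), n_boot=n_boot,
    )


def curves_to_frame(curves: dict[str, ReliabilityCurve]) -> pd.DataFrame:
    return pd.concat([c.to_frame() for c in curves.values()], ignore_index=True)
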