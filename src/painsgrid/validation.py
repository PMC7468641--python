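"""Measure-validation statistics: PCA clustering, effect sizes, power.

* :func:`pca_measures` decomposes the correlation matrix of per-patient
  baseline measures (map scores are on scales hundreds of times larger than
  a 0-10 VAS, so variables are z-scored first).  Loadings are reported in
  the factor-analysis convention ``eigenvector * sqrt(eigenvalue)``, i.e.
  the correlation of each variable with each component, so values above
  0.70 mark variables that a component essentially carries.
* :func:`cohens_d` is the pooled-SD standardized mean difference between
  treatment arms of a per-patient delta (follow-up minus baseline).
* :func:`sample_size` inverts a two-sample comparison for the per-group n
  at a target power, by normal approximation or by exact noncentral-t
  search (the t method is conservative: never smaller than the normal one).
* :func:`rm_corr` is a repeated-measures correlation: within-patient
  centering removes stable between-patient differences, then pooled Pearson
  measures whether two scales co-vary over time inside patients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .errors import DegenerateInputError, PainsGridError
from .scoring import ALL_MEASURES, MAP_MEASURES


@dataclass
class PCAResult:
    """Correlation-matrix PCA of a variables table."""

    variables: list[str]
    loadings: pd.DataFrame            # variables x components, sqrt(eigval)-scaled
    explained_variance: np.ndarray    # eigenvalues of the correlation matrix
    explained_variance_ratio: np.ndarray
    scores: pd.DataFrame              # observations x components


@dataclass
class EffectSizeResult:
    """Pooled-SD Cohen's d between two arms of a delta measure."""

    measure: str
    scope: str
    d: float
    mean_active: float
    mean_sham: float
    pooled_sd: float
    n_active: int
    n_sham: int


@dataclass
class PowerResult:
    """Per-group sample size for a two-sided two-sample comparison."""

    d: float
    alpha: float
    power: float
    method: str          # "normal" or "t"
    n_per_group: int


def pca_measures(table: pd.DataFrame, variables: list[str] | None = None) -> PCAResult:
    """PCA of the correlation structure among per-patient measures.

    ``table`` holds one row per patient; non-numeric columns (for example
    ``patient_id``) are ignored unless listed explicitly.  Components are
    signed so that the PAINS loading on PC1 and the VAS loading on PC2 are
    positive (falling back to largest-|loading| positive).
    """
    if variables is None:
        variables = [
            c for c in table.columns
            if c not in ("patient_id", "day") and pd.api.types.is_numeric_dtype(table[c])
        ]
    X = table[variables].to_numpy(float)
    if len(X) < 3:
        raise DegenerateInputError(f"PCA needs >= 3 patients, got {len(X)}")
    sd = X.std(axis=0, ddof=1)
    constant = [v for v, s in zip(variables, sd) if not s > 0]
    if constant:
        raise DegenerateInputError(
            f"constant column(s) make the correlation matrix singular: "
            f"{', '.join(constant)}"
        )
    Z = (X - X.mean(axis=0)) / sd

    pca = PCA(n_components=len(variables))
    score_arr = pca.fit_transform(Z)
    eigval = pca.explained_variance_          # eigenvalues of corr matrix (ddof=1)
    loadings = pca.components_.T * np.sqrt(np.maximum(eigval, 0.0))

    comp_names = [f"PC{k + 1}" for k in range(len(variables))]
    L = pd.DataFrame(loadings, index=variables, columns=comp_names)
    scores = pd.DataFrame(score_arr, columns=comp_names, index=table.index)
    for k, name in enumerate(comp_names):
        anchor = None
        if k == 0 and "pains" in variables:
            anchor = "pains"
        elif k == 1 and "vas" in variables:
            anchor = "vas"
        pivot = L[name].loc[anchor] if anchor else L[name].iloc[L[name].abs().argmax()]
        if pivot < 0:
            L[name] *= -1
            scores[name] *= -1
    return PCAResult(
        variables=list(variables),
        loadings=L,
        explained_variance=eigval,
        explained_variance_ratio=pca.explained_variance_ratio_,
        scores=scores,
    )


def pca_structure_matches(
    result: PCAResult,
    map_measures: tuple[str, ...] = MAP_MEASURES,
    panas_measures: tuple[str, ...] = ("panas_pos", "panas_neg"),
    vas: str = "vas",
) -> bool:
    """Whether the loadings show the map-vs-mood two-component structure.

    True when (a) PC1 is dominated by the map-derived measures -- their
    summed squared PC1 loadings exceed those of VAS and PANAS combined --
    and (b) VAS loads more strongly (absolute value) on whichever of the
    first two components carries PANAS than on the other: the map measures
    cluster on the leading component while VAS travels with mood.
    """
    L = result.loadings
    map_pc1 = float((L.loc[list(map_measures), "PC1"] ** 2).sum())
    other_pc1 = float((L.loc[[vas, *panas_measures], "PC1"] ** 2).sum())
    panas_abs = L.loc[list(panas_measures), ["PC1", "PC2"]].abs().mean()
    mood_pc = panas_abs.idxmax()
    map_pc = "PC1" if mood_pc == "PC2" else "PC2"
    vas_with_mood = abs(L.loc[vas, mood_pc]) > abs(L.loc[vas, map_pc])
    return map_pc1 > other_pc1 and vas_with_mood


def baseline_table(series: pd.DataFrame, day: int = 0,
                   measures: tuple[str, ...] = ALL_MEASURES) -> pd.DataFrame:
    """One row per patient of measure values at the baseline visit."""
    base = series.loc[series["day"] == day, ["patient_id", *measures]]
    if base.empty:
        raise PainsGridError(f"no visits at day {day} in series")
    return base.reset_index(drop=True)


def cohens_d(delta_active, delta_sham, measure: str = "",
             scope: str = "") -> EffectSizeResult:
    """Pooled-SD Cohen's d of active vs sham per-patient deltas.

    ``d = (mean_active - mean_sham) / sd_pooled`` with
    ``sd_pooled = sqrt(((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2))``.
    """
    a = np.asarray(delta_active, float)
    s = np.asarray(delta_sham, float)
    if len(a) < 2 or len(s) < 2:
        raise DegenerateInputError(
            f"need >= 2 patients per arm; got {len(a)} active, {len(s)} sham"
        )
    va, vs = a.var(ddof=1), s.var(ddof=1)
    pooled = math.sqrt(((len(a) - 1) * va + (len(s) - 1) * vs)
                       / (len(a) + len(s) - 2))
    if not pooled > 0:
        raise DegenerateInputError("zero pooled SD; effect size undefined")
    return EffectSizeResult(
        measure=measure, scope=scope,
        d=float((a.mean() - s.mean()) / pooled),
        mean_active=float(a.mean()), mean_sham=float(s.mean()),
        pooled_sd=float(pooled), n_active=len(a), n_sham=len(s),
    )


def two_sample_t_power(n_per_group: int, d: float, alpha: float = 0.05) -> float:
    """Exact power of a two-sided two-sample t-test at per-group size n.

    Noncentrality ``d * sqrt(n/2)``, ``2n - 2`` degrees of freedom.
    """
    df = 2 * n_per_group - 2
    nc = abs(d) * math.sqrt(n_per_group / 2.0)
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float(1 - stats.nct.cdf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


def normal_approx_power(n_per_group: int, d: float, alpha: float = 0.05) -> float:
    """Normal-approximation power of the same two-sided comparison."""
    za = stats.norm.ppf(1 - alpha / 2)
    shift = abs(d) * math.sqrt(n_per_group / 2.0)
    return float(stats.norm.cdf(shift - za) + stats.norm.cdf(-shift - za))


def sample_size(d: float, power: float = 0.80, alpha: float = 0.05,
                method: str = "normal") -> PowerResult:
    """Smallest per-group n detecting standardized effect ``d``.

    ``method="normal"``: closed form
    ``n = ceil(2 (z_{1-alpha/2} + z_{power})^2 / d^2)``.
    ``method="t"``: smallest integer n whose exact two-sample t-test power
    (noncentrality ``d sqrt(n/2)``, df ``2n - 2``) reaches the target.
    """
    if not d > 0:
        raise DegenerateInputError("d must be > 0: a null effect needs infinite n")
    if not 0 < power < 1 or not 0 < alpha < 1:
        raise PainsGridError("power and alpha must lie strictly in (0, 1)")
    if method not in ("normal", "t"):
        raise PainsGridError(f"method must be 'normal' or 't', got {method!r}")
    z = stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)
    n_normal = max(2, math.ceil(2 * z ** 2 / d ** 2))
    if method == "normal":
        n = n_normal
    else:
        n = max(2, n_normal)  # t power < normal power, so start at normal n
        while two_sample_t_power(n, d, alpha) < power:
            n += 1
    return PowerResult(d=d, alpha=alpha, power=power, method=method, n_per_group=n)


def rm_corr(series: pd.DataFrame, x: str, y: str) -> dict[str, float]:
    """Repeated-measures correlation between two longitudinal measures.

    Visits with both values present are centered within patient, then pooled
    Pearson is computed across all centered pairs.  The two-sided p-value
    uses ``df = N - k - 1`` (N pooled visits, k patients), accounting for
    the per-patient means removed.
    """
    df = series[["patient_id", x, y]].dropna()
    counts = df.groupby("patient_id").size()
    df = df[df["patient_id"].isin(counts.index[counts >= 2])]
    if df["patient_id"].nunique() < 2:
        raise DegenerateInputError(
            "repeated-measures correlation needs >= 2 patients with >= 2 visits"
        )
    centered = df[[x, y]] - df.groupby("patient_id")[[x, y]].transform("mean")
    xs = centered[x].to_numpy(float)
    ys = centered[y].to_numpy(float)
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise DegenerateInputError("a measure is constant within all patients")
    r = float(np.corrcoef(xs, ys)[0, 1])
    dof = len(df) - df["patient_id"].nunique() - 1
    if dof < 1:
        raise DegenerateInputError("not enough visits for a p-value")
    t = r * math.sqrt(dof / max(1e-300, 1 - r ** 2))
    p = float(2 * stats.t.sf(abs(t), dof))
    return {"r": r, "p": p, "dof": dof, "n": len(df)}
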