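"""Design-weighted descriptive analysis of complex-survey data.

Covers the descriptive layer of the workflow: design-weighted prevalence
with Taylor-linearized (stratified between-PSU) variances and logit-scale
confidence intervals; weighted cross-tabulations tested with the
second-order (Satterthwaite) Rao–Scott correction of the Pearson chi-square
on an F reference distribution; and a principal-component media-exposure
index cut into weighted tertiles.

All functions take a records DataFrame with columns ``weight, stratum_id,
psu_id`` plus the outcome/factor columns they are pointed at.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

__all__ = [
    "SurveyEstimate",
    "CrosstabResult",
    "MediaExposureIndex",
    "weighted_prevalence",
    "weighted_crosstab",
    "media_exposure_index",
    "weighted_quantile",
]


@dataclass(frozen=True)
class SurveyEstimate:
    """Design-based proportion estimate with 95% confidence interval."""

    point: float
    se: float
    ci_low: float
    ci_high: float
    design_df: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.point + 1e-12 and self.point - 1e-12 <= self.ci_high <= 1.0):
            raise ValueError("need 0 <= ci_low <= point <= ci_high <= 1")


@dataclass(frozen=True)
class CrosstabResult:
    """Weighted outcome percentage per factor level with a design-corrected test."""

    levels: tuple[str, ...]
    weighted_percent: dict[str, float]
    unweighted_n: dict[str, int]
    F_stat: float
    p_value: float
    df1: float
    df2: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level": list(self.levels),
                "weighted_percent": [self.weighted_percent[lv] for lv in self.levels],
                "unweighted_n": [self.unweighted_n[lv] for lv in self.levels],
            }
        )


@dataclass(frozen=True)
class MediaExposureIndex:
    """First-principal-component exposure score cut into weighted tertiles."""

    categories: pd.Series  # per-record in {"low", "mid", "high"}
    scores: pd.Series
    loadings: pd.Series
    explained_share: float


def _design_columns(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    for col in ("weight", "stratum_id", "psu_id"):
        if col not in records.columns:
            raise ValueError(f"records missing design column {col!r}")
    w = records["weight"].to_numpy(dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    return w, records["stratum_id"].to_numpy(), records["psu_id"].to_numpy()


def _check_psu_counts(strata: np.ndarray, psus: np.ndarray) -> int:
    """Design degrees of freedom (#PSUs − #strata); errors on singleton PSUs."""
    tab = pd.DataFrame({"s": strata, "p": psus}).drop_duplicates()
    counts = tab.groupby("s")["p"].nunique()
    single = counts[counts < 2]
    if len(single) > 0:
        raise ValueError(
            f"stratum/strata {list(single.index)!r} contain a single PSU; "
            "variance is inestimable — collapse strata before estimation"
        )
    return int(counts.sum() - len(counts))


def _linearized_cov(scores: np.ndarray, strata: np.ndarray, psus: np.ndarray) -> np.ndarray:
    """Stratified with-replacement between-PSU covariance of estimator scores.

    ``scores`` is (n, d); returns the (d, d) covariance estimate
    sum_h n_h/(n_h-1) sum_j (t_hj - tbar_h)(t_hj - tbar_h)'
    over PSU totals t_hj of the linearized scores.
    """
    df = pd.DataFrame(scores)
    df["_s"] = strata
    df["_p"] = psus
    totals = df.groupby(["_s", "_p"], sort=False).sum()
    d = scores.shape[1]
    V = np.zeros((d, d))
    for _, g in totals.groupby(level=0, sort=False):
        t = g.to_numpy(dtype=float)
        nh = t.shape[0]
        dev = t - t.mean(axis=0)
        V += nh / (nh - 1) * dev.T @ dev
    return V


def weighted_prevalence(records: pd.DataFrame, outcome: str = "outcome",
                        ci_method: str = "logit") -> SurveyEstimate:
    """Design-weighted prevalence of a binary outcome.

    Point estimate is the ratio estimator ``sum(w*y)/sum(w)``; its variance
    comes from Taylor linearization with stratified between-PSU totals, and
    the 95% interval is formed on the logit scale and back-transformed
    (``ci_method="wald"`` gives a clipped symmetric interval instead).
    """
    w, strata, psus = _design_columns(records)
    y = records[outcome].to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError(f"outcome {outcome!r} must be binary 0/1")
    ddf = _check_psu_counts(strata, psus)
    W = w.sum()
    p = float(w @ y / W)
    z = (w * (y - p) / W)[:, None]
    var = float(_linearized_cov(z, strata, psus)[0, 0])
    se = float(np.sqrt(max(var, 0.0)))
    tcrit = stats.t.ppf(0.975, ddf) if ddf > 0 else np.nan
    if se == 0.0 or p in (0.0, 1.0) or ci_method == "wald":
        lo = max(0.0, p - tcrit * se) if np.isfinite(tcrit) else p
        hi = min(1.0, p + tcrit * se) if np.isfinite(tcrit) else p
    elif ci_method == "logit":
        se_logit = se / (p * (1.0 - p))
        lo = float(expit(logit(p) - tcrit * se_logit))
        hi = float(expit(logit(p) + tcrit * se_logit))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return SurveyEstimate(point=p, se=se, ci_low=lo, ci_high=hi, design_df=ddf)


def weighted_crosstab(records: pd.DataFrame, outcome: str = "outcome",
                      factor: str = "factor") -> CrosstabResult:
    """Weighted outcome percentage by factor level with a Rao–Scott test.

    The association test is the Pearson chi-square computed from weighted
    cell proportions, corrected by the second-order (Satterthwaite)
    Rao–Scott adjustment: generalized design effects are the eigenvalues of
    ``V0^{-1} V`` where ``V`` is the linearized design covariance of the
    independence residuals and ``V0`` their multinomial covariance.  The
    corrected statistic is referred to an F distribution with
    Satterthwaite-adjusted degrees of freedom (the complex-survey software
    default).  Empty factor levels are dropped with a warning.
    """
    w, strata, psus = _design_columns(records)
    ddf = _check_psu_counts(strata, psus)
    fac = records[factor].astype(str)
    out = records[outcome]
    levels = [lv for lv in pd.unique(fac)]
    counts = fac.value_counts()
    empty = [lv for lv in levels if counts.get(lv, 0) == 0]
    if empty:
        warnings.warn(f"dropping empty factor levels {empty}")
        levels = [lv for lv in levels if lv not in empty]
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} needs >= 2 observed levels")
    out_levels = sorted(pd.unique(out))
    R, Cc = len(levels), len(out_levels)
    n = len(records)
    W = w.sum()

    Ir = np.stack([(fac == lv).to_numpy(dtype=float) for lv in levels], axis=1)  # (n, R)
    Ic = np.stack([(out == lv).to_numpy(dtype=float) for lv in out_levels], axis=1)  # (n, C)
    p_rc = (Ir * w[:, None]).T @ Ic / W  # (R, C)
    p_r = p_rc.sum(axis=1)
    p_c = p_rc.sum(axis=0)

    resid = p_rc - np.outer(p_r, p_c)
    with np.errstate(divide="ignore", invalid="ignore"):
        X2 = float(n * np.nansum(resid**2 / np.outer(p_r, p_c)))
    d = (R - 1) * (Cc - 1)

    # linearized scores of the independence residuals, first (R-1)(C-1) cells
    scores = np.empty((n, d))
    k = 0
    for r in range(R - 1):
        for c in range(Cc - 1):
            s = (
                (Ir[:, r] * Ic[:, c] - p_rc[r, c])
                - p_c[c] * (Ir[:, r] - p_r[r])
                - p_r[r] * (Ic[:, c] - p_c[c])
            )
            scores[:, k] = w * s / W
            k += 1
    V = _linearized_cov(scores, strata, psus)
    Ar = np.diag(p_r[:-1]) - np.outer(p_r[:-1], p_r[:-1])
    Bc = np.diag(p_c[:-1]) - np.outer(p_c[:-1], p_c[:-1])
    V0 = np.kron(Ar, Bc) / n
    try:
        delta = np.linalg.eigvals(np.linalg.solve(V0, V))
    except np.linalg.LinAlgError:
        delta = np.linalg.eigvals(np.linalg.pinv(V0) @ V)
    delta = np.real(delta)
    delta = np.clip(delta, 1e-12, None)
    dbar = float(delta.mean())
    a2 = float(delta.var() / dbar**2)

    F = X2 / (dbar * d)
    df1 = d / (1.0 + a2)
    df2 = df1 * max(ddf, 1)
    p_value = float(stats.f.sf(F, df1, df2))

    wpct, un = {}, {}
    positive = (out == out_levels[-1]).to_numpy(dtype=float) if Cc == 2 else None
    for r, lv in enumerate(levels):
        mask = Ir[:, r] > 0
        if positive is not None:
            wpct[lv] = float(100.0 * (w[mask] @ positive[mask]) / w[mask].sum())
        else:
            wpct[lv] = float("nan")
        un[lv] = int(mask.sum())
    return CrosstabResult(
        levels=tuple(levels), weighted_percent=wpct, unweighted_n=un,
        F_stat=float(F), p_value=p_value, df1=float(df1), df2=float(df2),
    )


def weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    """Smallest value whose cumulative weight share reaches ``q``."""
    order = np.argsort(values, kind="stable")
    v = np.asarray(values, dtype=float)[order]
    cw = np.cumsum(np.asarray(weights, dtype=float)[order])
    return float(v[np.searchsorted(cw / cw[-1], q, side="left")])


def media_exposure_index(records: pd.DataFrame, item_names: list[str],
                         weight: str = "weight") -> MediaExposureIndex:
    """Composite exposure index from ordinal media items via PCA.

    Items (e.g. frequency of television, radio, newspaper use coded 0–2)
    are standardized; the first principal component of their correlation
    matrix is oriented so that higher exposure scores higher (loading sum
    non-negative), and scores are cut at weighted tertiles into
    low/mid/high with boundary ties going to the lower category.
    Zero-variance items are excluded with a warning.
    """
    if len(item_names) < 3:
        raise ValueError("need at least 3 items for the exposure index")
    X = records[item_names].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not np.all(keep):
        dropped = [nm for nm, k in zip(item_names, keep) if not k]
        warnings.warn(f"excluding zero-variance items {dropped}")
    items = [nm for nm, k in zip(item_names, keep) if k]
    if len(items) < 2:
        raise ValueError("fewer than 2 items with variance; index undefined")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    corr = np.corrcoef(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    lead = evecs[:, -1]
    if lead.sum() < 0:
        lead = -lead
    scores = Z @ lead
    w = records[weight].to_numpy(dtype=float) if weight in records.columns else np.ones(len(records))
    q1 = weighted_quantile(scores, w, 1.0 / 3.0)
    q2 = weighted_quantile(scores, w, 2.0 / 3.0)
    cats = np.where(scores <= q1, "low", np.where(scores <= q2, "mid", "high"))
    return MediaExposureIndex(
        categories=pd.Series(cats, index=records.index, name="media_exposure"),
        scores=pd.Series(scores, index=records.index, name="media_score"),
        loadings=pd.Series(lead, index=items, name="loading"),
        explained_share=float(evals[-1] / evals.sum()),
    )
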