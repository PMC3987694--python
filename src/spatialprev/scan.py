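"""Bernoulli spatial scan statistics for area-level case/control data.

Implements Kulldorff-style circular-window scanning: for every area taken as
a window centre, nested windows grow outward over areas ordered by
great-circle distance, and each window is scored by the Bernoulli
log-likelihood ratio comparing the case rate inside against outside.  The
most likely cluster is the globally maximizing window; inference is by Monte
Carlo randomization conditional on the total case count and the per-area
at-risk totals, and secondary clusters are reported greedily subject to a
no-overlap rule.

High- and low-rate scans are separate one-sided analyses: a window whose
rate sits on the wrong side of the overall rate scores zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .geo import AreaMap, distance_matrix

__all__ = [
    "AreaCaseData",
    "Cluster",
    "window_sequence",
    "bernoulli_llr",
    "relative_risk",
    "scan",
    "monte_carlo_pvalues",
    "secondary_clusters",
]


@dataclass(frozen=True)
class AreaCaseData:
    """Per-area case counts and at-risk totals.

    ``cases[i]`` individuals with the outcome out of ``totals[i]`` at risk in
    area ``area_ids[i]``; the scan conditions on ``C = sum(cases)`` and the
    totals.
    """

    area_ids: tuple[str, ...]
    cases: np.ndarray
    totals: np.ndarray

    def __post_init__(self) -> None:
        cases = np.asarray(self.cases, dtype=np.int64)
        totals = np.asarray(self.totals, dtype=np.int64)
        if cases.shape != (len(self.area_ids),) or totals.shape != cases.shape:
            raise ValueError("cases/totals must be 1-d, one entry per area")
        if np.any(cases < 0) or np.any(totals < cases):
            raise ValueError("need 0 <= cases <= totals per area")
        object.__setattr__(self, "cases", cases)
        object.__setattr__(self, "totals", totals)

    @property
    def C(self) -> int:
        return int(self.cases.sum())

    @property
    def N(self) -> int:
        return int(self.totals.sum())

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "AreaCaseData":
        """Build from a frame with columns ``id, cases, total``."""
        missing = {"id", "cases", "total"} - set(df.columns)
        if missing:
            raise ValueError(f"missing columns {sorted(missing)}")
        return cls(
            area_ids=tuple(str(a) for a in df["id"]),
            cases=df["cases"].to_numpy(),
            totals=df["total"].to_numpy(),
        )

    @classmethod
    def read_csv(cls, path) -> "AreaCaseData":
        return cls.from_dataframe(pd.read_csv(path, dtype={"id": str}))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.area_ids, "cases": self.cases, "total": self.totals})

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass(frozen=True)
class Cluster:
    """One scan window: member areas, score and Monte Carlo significance."""

    center_area: str
    member_areas: tuple[str, ...]
    observed: int
    expected: float
    llr: float
    relative_risk: float
    direction: str
    p_value: float | None = None
    rank: int | None = None


def bernoulli_llr(c, n, C, N, direction: str = "high"):
    """Bernoulli scan log-likelihood ratio for a window.

    ``c`` cases among ``n`` at risk inside the window, against overall
    totals ``C`` of ``N``.  The statistic is the log ratio of the maximized
    two-rate likelihood to the single-rate null, with the convention
    ``0·log 0 = 0``; it is set to zero when the window rate is not on the
    requested side (``direction`` in ``{"high", "low"}``) of the overall
    rate ``C/N``, and when the window covers everything (``n == N``).

    Accepts scalars or broadcastable arrays.
    """
    c = np.asarray(c, dtype=float)
    n = np.asarray(n, dtype=float)
    Cf, Nf = float(C), float(N)
    if direction not in ("high", "low"):
        raise ValueError(f"direction must be 'high' or 'low', got {direction!r}")
    co = Cf - c  # cases outside
    no = Nf - n  # at risk outside
    with np.errstate(divide="ignore", invalid="ignore"):
        ll_in = xlogy(c, c / n) + xlogy(n - c, (n - c) / n)
        ll_out = np.where(no > 0, xlogy(co, co / np.where(no > 0, no, 1.0))
                          + xlogy(no - co, (no - co) / np.where(no > 0, no, 1.0)), 0.0)
    ll_null = xlogy(Cf, Cf / Nf) + xlogy(Nf - Cf, (Nf - Cf) / Nf)
    llr = ll_in + ll_out - ll_null
    rate_in = np.where(n > 0, c / np.where(n > 0, n, 1.0), 0.0)
    overall = Cf / Nf
    if direction == "high":
        onesided = rate_in > overall
    else:
        onesided = rate_in < overall
    llr = np.where(onesided & (n < Nf), np.maximum(llr, 0.0), 0.0)
    return float(llr) if llr.ndim == 0 else llr


def relative_risk(c, n, C, N) -> float:
    """Scan relative risk: observed/expected inside over observed/expected outside.

    ``RR = (c/E) / ((C−c)/(C−E))`` with ``E = n·C/N``.  Returns ``inf`` when
    all cases fall inside the window; raises when the expectation is zero.
    """
    E = n * C / N
    if E == 0:
        raise ValueError("expected count is zero; relative risk undefined")
    if C - c <= 0:
        return float("inf")
    if C - E <= 0:
        return float("inf")
    return float((c / E) / ((C - c) / (C - E)))


def window_sequence(center: str, area_map: AreaMap, data: AreaCaseData,
                    max_fraction: float = 0.5,
                    dist: np.ndarray | None = None) -> list[tuple[str, ...]]:
    """Nested circular windows centred on ``center``.

    Areas are sorted by great-circle distance from the centre (ties broken
    by position in ``area_map.area_ids``); windows are the nested prefixes
    whose cumulative at-risk total stays within ``max_fraction`` of the
    overall total.  The centre-only window is always included.
    """
    if not 0 < max_fraction <= 0.5:
        raise ValueError("max_fraction must be in (0, 0.5]")
    if dist is None:
        dist = distance_matrix(area_map)
    order, caps = _center_order(area_map, data, max_fraction, dist)
    ci = area_map.index[center]
    o = order[ci]
    n_win = max(1, caps[ci])
    return [tuple(area_map.area_ids[j] for j in o[: m + 1]) for m in range(n_win)]


def _center_order(area_map: AreaMap, data: AreaCaseData, max_fraction: float,
                  dist: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-centre distance ordering and prefix caps.

    Returns ``order`` (n×n; row i = area indices sorted by distance from i,
    ties by index) and ``caps`` (number of admissible prefixes per centre,
    at least 1 so the centre itself is always a window).
    """
    n = area_map.n_areas
    idx = np.arange(n)
    order = np.empty((n, n), dtype=np.int64)
    for i in range(n):
        order[i] = np.lexsort((idx, dist[i]))
    totals_sorted = data.totals[order]
    cum_n = np.cumsum(totals_sorted, axis=1)
    caps = (cum_n <= max_fraction * data.N).sum(axis=1)
    return order, np.maximum(caps, 1)


def _align(data: AreaCaseData, area_map: AreaMap) -> AreaCaseData:
    """Reorder ``data`` to the map's area order, requiring identical id sets."""
    if tuple(data.area_ids) == tuple(area_map.area_ids):
        return data
    pos = {a: i for i, a in enumerate(data.area_ids)}
    missing = [a for a in area_map.area_ids if a not in pos]
    extra = [a for a in data.area_ids if a not in set(area_map.area_ids)]
    if missing or extra:
        raise ValueError(f"case data / map mismatch: missing {missing}, extra {extra}")
    take = np.array([pos[a] for a in area_map.area_ids])
    return AreaCaseData(area_map.area_ids, data.cases[take], data.totals[take])


def scan(data: AreaCaseData, area_map: AreaMap, direction: str = "high",
         max_fraction: float = 0.5) -> list[Cluster]:
    """Score every circular window from every centre; return per-centre best
    windows ranked by log-likelihood ratio (descending, llr > 0 only).

    The rank-1 cluster is the most likely cluster.  Ranks are attached;
    p-values are left unset (see :func:`monte_carlo_pvalues`).
    """
    data = _align(data, area_map)
    if data.C < 1:
        return []
    dist = distance_matrix(area_map)
    order, caps = _center_order(area_map, data, max_fraction, dist)
    llr_mat, cum_c, cum_n = _scan_matrix(data.cases, data.totals, order, caps,
                                         data.C, data.N, direction)
    clusters: list[Cluster] = []
    best_per_center = llr_mat.max(axis=1)
    for i in np.argsort(-best_per_center, kind="stable"):
        if best_per_center[i] <= 0:
            continue
        m = int(np.argmax(llr_mat[i]))
        members = tuple(area_map.area_ids[j] for j in order[i, : m + 1])
        c = int(cum_c[i, m])
        n = int(cum_n[i, m])
        clusters.append(
            Cluster(
                center_area=area_map.area_ids[i],
                member_areas=members,
                observed=c,
                expected=n * data.C / data.N,
                llr=float(llr_mat[i, m]),
                relative_risk=relative_risk(c, n, data.C, data.N),
                direction=direction,
            )
        )
    return [replace(cl, rank=r + 1) for r, cl in enumerate(clusters)]


def _scan_matrix(cases: np.ndarray, totals: np.ndarray, order: np.ndarray,
                 caps: np.ndarray, C: int, N: int, direction: str):
    """LLR over all (centre, prefix) windows; inadmissible prefixes are -inf."""
    cum_c = np.cumsum(cases[order], axis=1).astype(float)
    cum_n = np.cumsum(totals[order], axis=1).astype(float)
    llr = bernoulli_llr(cum_c, cum_n, C, N, direction)
    n_areas = order.shape[0]
    mask = np.arange(n_areas)[None, :] >= caps[:, None]
    llr = np.where(mask, -np.inf, llr)
    return llr, cum_c, cum_n


def _null_max_llrs(data: AreaCaseData, order: np.ndarray, caps: np.ndarray,
                   direction: str, replications: int, rng: np.random.Generator,
                   batch: int = 200) -> np.ndarray:
    """Distribution of the maximum LLR under case redistribution.

    Each replicate deals the ``C`` cases across the ``N`` at-risk individuals
    without replacement, holding every area total fixed (multivariate
    hypergeometric), then rescans.
    """
    C, N = data.C, data.N
    out = np.empty(replications)
    done = 0
    while done < replications:
        b = min(batch, replications - done)
        sim = np.stack([rng.multivariate_hypergeometric(data.totals, C) for _ in range(b)])
        cum_c = np.cumsum(sim[:, order], axis=2).astype(float)  # (b, n, n)
        cum_n = np.cumsum(data.totals[order], axis=1).astype(float)  # (n, n)
        llr = bernoulli_llr(cum_c, cum_n[None, :, :], C, N, direction)
        mask = np.arange(order.shape[0])[None, :] >= caps[:, None]
        llr = np.where(mask[None, :, :], -np.inf, llr)
        out[done : done + b] = llr.reshape(b, -1).max(axis=1)
        done += b
    return out


def monte_carlo_pvalues(data: AreaCaseData, area_map: AreaMap, direction: str = "high",
                        max_fraction: float = 0.5, replications: int = 999,
                        seed: int | None = None) -> list[Cluster]:
    """Scan and attach Monte Carlo p-values to every candidate cluster.

    Each candidate's LLR is referred to the null distribution of the
    *maximum* LLR over ``replications`` case-redistribution replicates, so
    reported p-values account for the multiplicity of windows;
    ``p = (1 + #{replicate max >= llr}) / (1 + replications)``.
    Deterministic given ``seed``.
    """
    if replications < 1:
        raise ValueError("replications must be >= 1")
    data = _align(data, area_map)
    clusters = scan(data, area_map, direction, max_fraction)
    if not clusters:
        return []
    rng = np.random.default_rng(seed)
    dist = distance_matrix(area_map)
    order, caps = _center_order(area_map, data, max_fraction, dist)
    null_max = _null_max_llrs(data, order, caps, direction, replications, rng)
    out = []
    for cl in clusters:
        p = (1.0 + np.sum(null_max >= cl.llr - 1e-12)) / (1.0 + replications)
        out.append(replace(cl, p_value=float(p)))
    return out


def secondary_clusters(ranked: list[Cluster], significance_level: float = 0.05) -> list[Cluster]:
    """Greedy non-overlapping cluster report.

    Walk candidates in LLR order, skip any sharing an area with an already
    reported cluster, and stop reporting once p exceeds
    ``significance_level``.  Candidates without p-values are rejected.
    """
    reported: list[Cluster] = []
    covered: set[str] = set()
    for cl in ranked:
        if cl.p_value is None:
            raise ValueError("candidates need Monte Carlo p-values first")
        if covered & set(cl.member_areas):
            continue
        if cl.p_value > significance_level:
            break
        reported.append(replace(cl, rank=len(reported) + 1))
        covered |= set(cl.member_areas)
    return reported


def clusters_to_dataframe(clusters: list[Cluster]) -> pd.DataFrame:
    """Cluster report table: one row per reported cluster."""
    rows = []
    for cl in clusters:
        rows.append(
            {
                "rank": cl.rank,
                "direction": cl.direction,
                "center": cl.center_area,
                "n_areas": len(cl.member_areas),
                "observed": cl.observed,
                "expected": round(cl.expected, 2),
                "relative_risk": round(cl.relative_risk, 4) if np.isfinite(cl.relative_risk) else np.inf,
                "llr": round(cl.llr, 4),
                "p_value": cl.p_value,
                "members": ";".join(cl.member_areas),
            }
        )
    return pd.DataFrame(rows)
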