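"""DHS-like synthetic survey generator with known spatial and covariate effects.

The restricted microdata this package's methods were designed for cannot be
redistributed, so every downstream stage is exercised on data generated
here: a two-stage stratified cluster sample (strata = region × urban/rural,
primary sampling units nested in areas) of respondents whose binary outcome
follows a hierarchical spatial logistic model

    logit p_i = beta0 + x_i' beta + f_s(area_i) + f_u(area_i)

with f_s an intrinsic CAR (ICAR) field on the area graph and f_u iid
Gaussian area noise.  The generating parameters travel with the data as a
:class:`TruthSet`, giving every estimator a ground truth to be checked
against.

Default design: 4 PSUs per area, 25 respondents per PSU, 8 regions —
roughly one fifth the size of a national DHS round over ~47 areas, keeping
full pipelines runnable in seconds while preserving the design structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .geo import AreaMap, structure_matrix
from .scan import AreaCaseData

__all__ = [
    "TruthSet",
    "make_lattice_map",
    "simulate_icar_field",
    "simulate_survey",
    "aggregate_to_areas",
    "default_factor_spec",
    "default_truth",
]

#: Default categorical covariate distributions (level -> sampling probability).
#: First level of each factor is the reference.
DEFAULT_FACTOR_SPEC: dict[str, dict[str, float]] = {
    "age_group": {"15-24": 0.40, "25-34": 0.32, "35-49": 0.28},
    "education": {"none": 0.15, "primary": 0.55, "secondary+": 0.30},
}


def default_factor_spec() -> dict[str, dict[str, float]]:
    return {f: dict(levels) for f, levels in DEFAULT_FACTOR_SPEC.items()}


@dataclass(frozen=True)
class TruthSet:
    """Generating parameters of the hierarchical spatial logistic model.

    ``beta`` maps factor -> {non-reference level -> log-odds coefficient};
    the reference level of each factor implicitly carries 0.  ``f_s`` must
    sum to zero within every connected component of the area graph.
    """

    beta0: float
    beta: dict[str, dict[str, float]]
    f_s: np.ndarray
    f_u: np.ndarray
    tau_s: float | None = None
    tau_u: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "f_s", np.asarray(self.f_s, dtype=float))
        object.__setattr__(self, "f_u", np.asarray(self.f_u, dtype=float))
        for tau, name in ((self.tau_s, "tau_s"), (self.tau_u, "tau_u")):
            if tau is not None and tau <= 0:
                raise ValueError(f"{name} must be positive")

    def linear_effect(self, factor: str, level: str) -> float:
        levels = self.beta.get(factor, {})
        return float(levels.get(level, 0.0))


def make_lattice_map(rows: int, cols: int, spacing_deg: float = 0.5,
                     origin: tuple[float, float] = (36.0, -1.0)) -> AreaMap:
    """Rook-adjacency lattice of ``rows × cols`` areas.

    Pseudo-centroids are laid out on a regular grid of ``spacing_deg``
    degrees starting at ``origin`` (lon, lat), so great-circle distances
    behave like a planar grid at small extents.  Area ids are ``a00, a01,
    ...`` in row-major order.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    width = max(2, len(str(rows * cols - 1)))
    ids = [f"a{i:0{width}d}" for i in range(rows * cols)]
    lon0, lat0 = origin
    cent = np.array(
        [(lon0 + c * spacing_deg, lat0 + r * spacing_deg) for r in range(rows) for c in range(cols)]
    )
    nbrs: dict[str, set[str]] = {a: set() for a in ids}
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            if c + 1 < cols:
                j = i + 1
                nbrs[ids[i]].add(ids[j])
                nbrs[ids[j]].add(ids[i])
            if r + 1 < rows:
                j = i + cols
                nbrs[ids[i]].add(ids[j])
                nbrs[ids[j]].add(ids[i])
    return AreaMap(tuple(ids), cent, {a: frozenset(s) for a, s in nbrs.items()})


def simulate_icar_field(area_map: AreaMap, tau_s: float,
                        seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Draw one realization of the ICAR field with precision ``tau_s``.

    Sampling uses the spectral pseudo-inverse of the structure matrix Q:
    coordinates along null directions (one per graph component) are fixed
    at zero, each remaining eigen-coordinate is Gaussian with variance
    1/(tau_s * eigenvalue), and the draw is re-centred to sum to zero
    within every component.  Single-area components get exactly 0.
    """
    if tau_s <= 0:
        raise ValueError("tau_s must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sm = structure_matrix(area_map)
    evals, evecs = np.linalg.eigh(sm.Q)
    tol = 1e-8 * max(evals.max(), 1.0)
    keep = evals > tol
    z = rng.standard_normal(keep.sum())
    f = evecs[:, keep] @ (z / np.sqrt(tau_s * evals[keep]))
    for g in range(sm.n_components):
        mask = sm.component_labels == g
        f[mask] -= f[mask].mean()
    return f


def default_truth(area_map: AreaMap, beta0: float = -1.0,
                  beta: dict[str, dict[str, float]] | None = None,
                  tau_s: float = 2.0, tau_u: float = 10.0,
                  seed: int | np.random.Generator | None = None) -> TruthSet:
    """Draw a :class:`TruthSet` with ICAR ``f_s`` and iid ``f_u`` realized
    on ``area_map``.

    Defaults give a baseline outcome probability around 0.27 at the
    reference covariate pattern, a rising age gradient and a falling
    education gradient — the qualitative pattern of a high-prevalence
    traditional practice — with moderately strong spatial structure
    (tau_s = 2) and weak unstructured noise (tau_u = 10).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if beta is None:
        beta = {
            "age_group": {"25-34": 0.5, "35-49": 1.0},
            "education": {"primary": -0.4, "secondary+": -0.9},
        }
    f_s = simulate_icar_field(area_map, tau_s, rng)
    f_u = rng.standard_normal(area_map.n_areas) / np.sqrt(tau_u)
    return TruthSet(beta0=beta0, beta=beta, f_s=f_s, f_u=f_u, tau_s=tau_s, tau_u=tau_u)


def simulate_survey(area_map: AreaMap, truth: TruthSet,
                    design: dict | None = None,
                    factor_spec: dict[str, dict[str, float]] | None = None,
                    seed: int | np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate a two-stage stratified cluster sample of survey records.

    Areas are partitioned into contiguous regions; each area contributes
    ``psus_per_area`` primary sampling units (enumeration areas), each PSU
    is labelled urban or rural, and strata are region × urban/rural.  Every
    PSU yields ``respondents_per_psu`` respondents with covariates drawn
    from ``factor_spec``, outcome from the truth's logistic model, and a
    design weight (constant within PSU, lognormal dispersion
    ``weight_dispersion``) normalized to mean 1.

    Returns a DataFrame with columns ``outcome, weight, stratum_id, psu_id,
    area_id`` plus one column per factor.  Deterministic given ``seed``.
    """
    design = {**{"n_regions": 8, "psus_per_area": 4, "respondents_per_psu": 25,
                 "weight_dispersion": 0.2, "urban_fraction": 0.3}, **(design or {})}
    factor_spec = factor_spec if factor_spec is not None else default_factor_spec()
    for fac, levels in truth.beta.items():
        if fac not in factor_spec:
            raise ValueError(f"truth.beta names unknown factor {fac!r}")
        unknown = set(levels) - set(factor_spec[fac])
        if unknown:
            raise ValueError(f"truth.beta for {fac!r} names unknown levels {sorted(unknown)}")
    A = area_map.n_areas
    if len(truth.f_s) != A or len(truth.f_u) != A:
        raise ValueError("truth f_s/f_u length must equal the number of areas")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    n_regions = min(int(design["n_regions"]), A)
    region_of_area = np.concatenate(
        [np.full(len(chunk), g) for g, chunk in enumerate(np.array_split(np.arange(A), n_regions))]
    )
    ppa = int(design["psus_per_area"])
    rpp = int(design["respondents_per_psu"])
    wd = float(design["weight_dispersion"])
    uf = float(design["urban_fraction"])

    rows_area, rows_psu, rows_stratum, psu_weight = [], [], [], []
    for ai, area in enumerate(area_map.area_ids):
        for p in range(ppa):
            urban = rng.random() < uf
            stratum = f"R{region_of_area[ai]}:{'U' if urban else 'R'}"
            psu = f"{area}-psu{p}"
            w = float(np.exp(rng.normal(0.0, wd))) if wd > 0 else 1.0
            rows_area.append(ai)
            rows_psu.append(psu)
            rows_stratum.append(stratum)
            psu_weight.append(w)

    # collapse any region whose urban or rural stratum holds a single PSU
    # into one region-wide stratum, so the between-PSU variance estimator is
    # defined (standard survey practice)
    counts = pd.Series(rows_stratum).value_counts()
    collapse_regions = {s.split(":")[0] for s in counts.index[counts < 2]}
    rows_stratum = [s.split(":")[0] if s.split(":")[0] in collapse_regions else s
                    for s in rows_stratum]

    n_psus = len(rows_psu)
    n = n_psus * rpp
    area_idx = np.repeat(rows_area, rpp)
    psu_id = np.repeat(rows_psu, rpp)
    stratum_id = np.repeat(rows_stratum, rpp)
    weight = np.repeat(psu_weight, rpp)
    weight = weight / weight.mean()

    eta = truth.beta0 + truth.f_s[area_idx] + truth.f_u[area_idx]
    factors: dict[str, np.ndarray] = {}
    for fac, levels in factor_spec.items():
        names = list(levels)
        probs = np.array(list(levels.values()), dtype=float)
        probs = probs / probs.sum()
        draw = rng.choice(len(names), size=n, p=probs)
        factors[fac] = np.array(names, dtype=object)[draw]
        coef = np.array([truth.linear_effect(fac, lv) for lv in names])
        eta = eta + coef[draw]
    y = (rng.random(n) < expit(eta)).astype(np.int64)

    return pd.DataFrame(
        {
            "outcome": y,
            "weight": weight,
            "stratum_id": stratum_id,
            "psu_id": psu_id,
            "area_id": np.array(area_map.area_ids, dtype=object)[area_idx],
            **factors,
        }
    )


def _largest_remainder(values: np.ndarray, target: int) -> np.ndarray:
    """Round non-negative reals to integers summing to ``target``.

    Floors first, then hands the remaining units to the largest fractional
    remainders (ties by index order).
    """
    floors = np.floor(values).astype(np.int64)
    short = int(target - floors.sum())
    if short < 0:
        raise ValueError("target below the sum of floors")
    rema = values - floors
    order = np.lexsort((np.arange(len(values)), -rema))
    out = floors.copy()
    out[order[:short]] += 1
    return out


def aggregate_to_areas(records: pd.DataFrame, area_ids=None,
                       use_weights: bool = False) -> AreaCaseData:
    """Aggregate respondent records to per-area case/total counts.

    Unweighted (default): plain counts.  Weighted: per-area weighted sums
    are scaled so the overall total matches the unweighted respondent count,
    then rounded to integers by largest remainder (the scan statistic needs
    integer cases); the rounding preserves overall totals and never lets an
    area's cases exceed its total.  Areas with no records are retained with
    zero counts.
    """
    if area_ids is None:
        area_ids = tuple(pd.unique(records["area_id"]))
    area_ids = tuple(str(a) for a in area_ids)
    pos = {a: i for i, a in enumerate(area_ids)}
    unknown = set(records["area_id"].astype(str)) - set(area_ids)
    if unknown:
        raise ValueError(f"records reference unknown areas {sorted(unknown)}")
    ai = records["area_id"].astype(str).map(pos).to_numpy()
    y = records["outcome"].to_numpy()
    A = len(area_ids)
    if not use_weights:
        totals = np.bincount(ai, minlength=A)
        cases = np.bincount(ai, weights=y, minlength=A).astype(np.int64)
        return AreaCaseData(area_ids, cases, totals)

    w = records["weight"].to_numpy(dtype=float)
    scale = len(records) / w.sum()
    wt = np.bincount(ai, weights=w, minlength=A) * scale
    wc = np.bincount(ai, weights=w * y, minlength=A) * scale
    totals = _largest_remainder(wt, len(records))
    cases = _largest_remainder(wc, int(round(wc.sum())))
    # rounding can nudge an area's cases past its rounded total; push the
    # excess to areas with slack, preferring the largest fractional remainders
    excess = cases - totals
    if np.any(excess > 0):
        overflow = int(excess[excess > 0].sum())
        cases = np.minimum(cases, totals)
        slack = totals - cases
        order = np.lexsort((np.arange(A), -(wc - np.floor(wc))))
        for i in order:
            if overflow == 0:
                break
            give = int(min(overflow, slack[i]))
            cases[i] += give
            overflow -= give
    return AreaCaseData(area_ids, cases, totals)
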