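"""Hierarchical spatial logistic regression (BYM-type) fitted by MCMC.

The model family for a binary outcome observed on areas is

    Y_i ~ Bernoulli(p_i),    logit p_i = beta0 + x_i' beta + f_s(a_i) + f_u(a_i)

with ``f_u`` iid Gaussian area effects (precision ``tau_u``) and ``f_s`` an
intrinsic CAR (ICAR) Gaussian Markov random field on the area adjacency
graph (precision ``tau_s``).  Four nested variants are distinguished by
which area effects are present:

    Model 1 — neither (ordinary Bayesian logistic regression)
    Model 2 — unstructured only
    Model 3 — structured only
    Model 4 — both (the full convolution model)

Fixed effects get near-flat Gaussian priors (precision ``tau_beta``);
precisions get vague Gamma priors.  The posterior is explored by
Metropolis-within-Gibbs: adaptive random-walk updates for ``beta0`` and
``beta``, single-site random walks for the area effects with hard per-
component sum-to-zero re-centering of ``f_s`` (deficit folded into
``beta0``), and conjugate Gamma draws for the precisions.  Model choice is
by the deviance information criterion (DIC); smaller is better.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .geo import AreaMap, StructureMatrix, structure_matrix

__all__ = [
    "ModelSpec",
    "PosteriorSample",
    "PosteriorSamples",
    "FitResult",
    "build_design_matrix",
    "log_posterior",
    "fit_model",
    "compute_dic",
    "tau_u_conditional",
    "tau_s_conditional",
    "draw_precision",
    "select_best_model",
    "odds_ratio_table",
    "posterior_prevalence_map",
]

RESERVED_COLUMNS = ("outcome", "weight", "stratum_id", "psu_id", "area_id")

#: model number -> (include_structured, include_unstructured)
MODEL_NUMBERS = {1: (False, False), 2: (False, True), 3: (True, False), 4: (True, True)}


@dataclass(frozen=True)
class ModelSpec:
    """Which area effects are present, and the prior hyperparameters.

    ``prior_a``/``prior_b`` are the shape/rate of the vague Gamma prior
    shared by ``tau_s`` and ``tau_u``; ``beta_prior_precision`` is the
    Gaussian precision of the (near-flat) fixed-effect priors.
    """

    include_structured: bool
    include_unstructured: bool
    prior_a: float = 0.5
    prior_b: float = 0.0005
    beta_prior_precision: float = 1e-4
    reference_levels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if min(self.prior_a, self.prior_b, self.beta_prior_precision) <= 0:
            raise ValueError("prior_a, prior_b and beta_prior_precision must be positive")

    @classmethod
    def from_number(cls, number: int, **kwargs) -> "ModelSpec":
        try:
            s, u = MODEL_NUMBERS[number]
        except KeyError:
            raise ValueError(f"model number must be 1-4, got {number}") from None
        return cls(include_structured=s, include_unstructured=u, **kwargs)

    @property
    def number(self) -> int:
        for k, su in MODEL_NUMBERS.items():
            if su == (self.include_structured, self.include_unstructured):
                return k
        raise AssertionError

    @property
    def n_random_components(self) -> int:
        return int(self.include_structured) + int(self.include_unstructured)


@dataclass
class PosteriorSample:
    """One point in the latent field: fixed effects, area effects, precisions."""

    beta0: float
    beta: np.ndarray
    f_s: np.ndarray | None = None
    f_u: np.ndarray | None = None
    tau_s: float | None = None
    tau_u: float | None = None


@dataclass
class PosteriorSamples:
    """Stored MCMC draws as stacked arrays (one row per kept iteration)."""

    beta0: np.ndarray
    beta: np.ndarray
    f_s: np.ndarray | None
    f_u: np.ndarray | None
    tau_s: np.ndarray | None
    tau_u: np.ndarray | None
    deviance: np.ndarray

    def __len__(self) -> int:
        return len(self.beta0)

    def __getitem__(self, i: int) -> PosteriorSample:
        return PosteriorSample(
            beta0=float(self.beta0[i]),
            beta=self.beta[i],
            f_s=None if self.f_s is None else self.f_s[i],
            f_u=None if self.f_u is None else self.f_u[i],
            tau_s=None if self.tau_s is None else float(self.tau_s[i]),
            tau_u=None if self.tau_u is None else float(self.tau_u[i]),
        )


@dataclass
class FitResult:
    """Posterior samples plus summaries, DIC/pD and run diagnostics."""

    spec: ModelSpec
    samples: PosteriorSamples
    summaries: pd.DataFrame
    dic: float
    pd: float
    acceptance_rates: dict[str, float]
    seed: int
    column_names: list[str]
    area_ids: tuple[str, ...]
    factor_spec: dict[str, list[str]]
    reference_levels: dict[str, str]

    def save(self, outdir) -> Path:
        """Serialize samples, summaries and metadata to a directory."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cols = {"beta0": self.samples.beta0}
        for j, nm in enumerate(self.column_names):
            cols[f"b:{nm}"] = self.samples.beta[:, j]
        if self.samples.f_s is not None:
            for j, a in enumerate(self.area_ids):
                cols[f"fs:{a}"] = self.samples.f_s[:, j]
            cols["tau_s"] = self.samples.tau_s
        if self.samples.f_u is not None:
            for j, a in enumerate(self.area_ids):
                cols[f"fu:{a}"] = self.samples.f_u[:, j]
            cols["tau_u"] = self.samples.tau_u
        cols["deviance"] = self.samples.deviance
        pd.DataFrame(cols).to_csv(outdir / "samples.csv", index=False)
        self.summaries.to_csv(outdir / "summary.csv")
        meta = {
            "model_number": self.spec.number,
            "dic": self.dic,
            "pd": self.pd,
            "acceptance_rates": self.acceptance_rates,
            "seed": self.seed,
            "prior_a": self.spec.prior_a,
            "prior_b": self.spec.prior_b,
            "beta_prior_precision": self.spec.beta_prior_precision,
            "column_names": self.column_names,
            "area_ids": list(self.area_ids),
            "factor_spec": self.factor_spec,
            "reference_levels": self.reference_levels,
        }
        (outdir / "meta.json").write_text(json.dumps(meta, indent=2))
        return outdir

    @classmethod
    def load(cls, fitdir) -> "FitResult":
        fitdir = Path(fitdir)
        meta = json.loads((fitdir / "meta.json").read_text())
        df = pd.read_csv(fitdir / "samples.csv")
        area_ids = tuple(meta["area_ids"])
        spec = ModelSpec.from_number(
            meta["model_number"],
            prior_a=meta["prior_a"], prior_b=meta["prior_b"],
            beta_prior_precision=meta["beta_prior_precision"],
            reference_levels=meta["reference_levels"],
        )
        beta = np.column_stack([df[f"b:{nm}"] for nm in meta["column_names"]]) \
            if meta["column_names"] else np.empty((len(df), 0))
        f_s = tau_s = f_u = tau_u = None
        if spec.include_structured:
            f_s = np.column_stack([df[f"fs:{a}"] for a in area_ids])
            tau_s = df["tau_s"].to_numpy()
        if spec.include_unstructured:
            f_u = np.column_stack([df[f"fu:{a}"] for a in area_ids])
            tau_u = df["tau_u"].to_numpy()
        samples = PosteriorSamples(
            beta0=df["beta0"].to_numpy(), beta=beta, f_s=f_s, f_u=f_u,
            tau_s=tau_s, tau_u=tau_u, deviance=df["deviance"].to_numpy(),
        )
        return cls(
            spec=spec, samples=samples,
            summaries=pd.read_csv(fitdir / "summary.csv", index_col=0),
            dic=meta["dic"], pd=meta["pd"],
            acceptance_rates=meta["acceptance_rates"], seed=meta["seed"],
            column_names=meta["column_names"], area_ids=area_ids,
            factor_spec=meta["factor_spec"], reference_levels=meta["reference_levels"],
        )


def _factor_levels(factor_spec) -> dict[str, list[str]]:
    """Normalize a factor spec (levels list or level->prob dict) to lists."""
    return {f: list(levels) for f, levels in factor_spec.items()}


def infer_factor_spec(records: pd.DataFrame) -> dict[str, list[str]]:
    """Treat every non-design column as a factor, levels in appearance order."""
    return {
        c: [str(v) for v in pd.unique(records[c].astype(str))]
        for c in records.columns
        if c not in RESERVED_COLUMNS
    }


def build_design_matrix(records: pd.DataFrame, factor_spec,
                        reference_levels: dict[str, str] | None = None):
    """Dummy-coded (treatment) design matrix, reference column dropped.

    The intercept is *not* included (``beta0`` is handled separately).
    Column names are ``factor=level``.  Records carrying a level absent
    from ``factor_spec`` are rejected.
    """
    factor_spec = _factor_levels(factor_spec)
    reference_levels = reference_levels or {}
    cols, names = [], []
    for fac, levels in factor_spec.items():
        vals = records[fac].astype(str)
        unseen = set(vals.unique()) - set(levels)
        if unseen:
            raise ValueError(f"factor {fac!r} has undeclared levels {sorted(unseen)}")
        ref = reference_levels.get(fac, levels[0])
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} not a level of {fac!r}")
        for lv in levels:
            if lv == ref:
                continue
            cols.append((vals == lv).to_numpy(dtype=float))
            names.append(f"{fac}={lv}")
    X = np.column_stack(cols) if cols else np.empty((len(records), 0))
    return X, names


@dataclass
class ModelData:
    """Outcome, design matrix and area index, plus the cell aggregation.

    The Bernoulli likelihood depends on records only through their linear
    predictor, so records sharing (area, covariate pattern) are collapsed
    to cells with a trial count and a success count; every likelihood
    evaluation is then O(#cells) rather than O(n).
    """

    y: np.ndarray
    X: np.ndarray
    area_idx: np.ndarray
    n_areas: int
    cell_X: np.ndarray = field(init=False)
    cell_area: np.ndarray = field(init=False)
    cell_n: np.ndarray = field(init=False)
    cell_y: np.ndarray = field(init=False)
    area_cells: list = field(init=False)
    col_cells: list = field(init=False)

    def __post_init__(self) -> None:
        key = np.column_stack([self.area_idx.astype(float), self.X])
        uniq, inv = np.unique(key, axis=0, return_inverse=True)
        m = len(uniq)
        self.cell_area = uniq[:, 0].astype(np.int64)
        self.cell_X = uniq[:, 1:]
        self.cell_n = np.bincount(inv, minlength=m).astype(float)
        self.cell_y = np.bincount(inv, weights=self.y, minlength=m)
        self.area_cells = [np.where(self.cell_area == a)[0] for a in range(self.n_areas)]
        self.col_cells = [np.where(self.cell_X[:, j] != 0)[0] for j in range(self.X.shape[1])]

    @property
    def n(self) -> int:
        return len(self.y)

    def loglik(self, eta: np.ndarray) -> float:
        """Bernoulli log-likelihood from cell-level linear predictors."""
        return float(self.cell_y @ eta - self.cell_n @ np.logaddexp(0.0, eta))


def prepare_model_data(records: pd.DataFrame, area_map: AreaMap, factor_spec=None,
                       reference_levels: dict[str, str] | None = None):
    """Records -> (ModelData, column names, resolved factor spec)."""
    factor_spec = _factor_levels(factor_spec) if factor_spec is not None else infer_factor_spec(records)
    X, names = build_design_matrix(records, factor_spec, reference_levels)
    idx = area_map.index
    unknown = set(records["area_id"].astype(str)) - set(area_map.area_ids)
    if unknown:
        raise ValueError(f"records reference areas not in the map: {sorted(unknown)}")
    area_idx = records["area_id"].astype(str).map(idx).to_numpy(dtype=np.int64)
    y = records["outcome"].to_numpy(dtype=float)
    data = ModelData(y=y, X=X, area_idx=area_idx, n_areas=area_map.n_areas)
    return data, names, factor_spec


def log_posterior(sample: PosteriorSample, data: ModelData, spec: ModelSpec,
                  structure: StructureMatrix) -> float:
    """Unnormalized log posterior density of one latent-field point.

    Bernoulli log-likelihood + Gaussian prior on (beta0, beta) + iid-normal
    density of f_u + ICAR log-kernel of f_s (exponent (n_areas − k)/2 on
    tau_s, quadratic form over neighbour differences) + Gamma densities of
    the precisions; additive constants are dropped.
    """
    A = structure.Q.shape[0]
    if spec.include_structured and (sample.f_s is None or sample.tau_s is None):
        raise ValueError("spec includes f_s but the sample lacks f_s/tau_s")
    if spec.include_unstructured and (sample.f_u is None or sample.tau_u is None):
        raise ValueError("spec includes f_u but the sample lacks f_u/tau_u")
    eta = sample.beta0 + data.cell_X @ sample.beta
    if spec.include_structured:
        eta = eta + sample.f_s[data.cell_area]
    if spec.include_unstructured:
        eta = eta + sample.f_u[data.cell_area]
    lp = data.loglik(eta)
    lp += -0.5 * spec.beta_prior_precision * (sample.beta0**2 + float(sample.beta @ sample.beta))
    if spec.include_unstructured:
        lp += 0.5 * A * np.log(sample.tau_u) - 0.5 * sample.tau_u * float(sample.f_u @ sample.f_u)
        lp += (spec.prior_a - 1.0) * np.log(sample.tau_u) - spec.prior_b * sample.tau_u
    if spec.include_structured:
        quad = float(sample.f_s @ structure.Q @ sample.f_s)  # == sum over edges of squared differences
        k = structure.n_components
        lp += 0.5 * (A - k) * np.log(sample.tau_s) - 0.5 * sample.tau_s * quad
        lp += (spec.prior_a - 1.0) * np.log(sample.tau_s) - spec.prior_b * sample.tau_s
    if not np.isfinite(lp):
        raise FloatingPointError(f"non-finite log posterior (loglik/prior overflow): {lp}")
    return lp


def tau_u_conditional(f_u: np.ndarray, prior_a: float, prior_b: float) -> tuple[float, float]:
    """Gamma full conditional (shape, rate) of the iid-effect precision:
    ``Gamma(a + m/2, b + sum(f_u^2)/2)`` for ``m`` areas."""
    f_u = np.asarray(f_u, dtype=float)
    return prior_a + len(f_u) / 2.0, prior_b + 0.5 * float(f_u @ f_u)


def tau_s_conditional(f_s: np.ndarray, structure: StructureMatrix,
                      prior_a: float, prior_b: float) -> tuple[float, float]:
    """Gamma full conditional (shape, rate) of the ICAR precision:
    ``Gamma(a + (m − k)/2, b + sum over edges (f_i − f_j)^2 / 2)``."""
    f_s = np.asarray(f_s, dtype=float)
    m = len(f_s)
    quad = float(f_s @ structure.Q @ f_s)
    return prior_a + (m - structure.n_components) / 2.0, prior_b + 0.5 * quad


def draw_precision(rng: np.random.Generator, shape: float, rate: float) -> float:
    """One Gamma(shape, rate) draw (numpy parameterizes by scale = 1/rate)."""
    return float(rng.gamma(shape, 1.0 / rate))


class _Adapter:
    """Robbins–Monro style scale adaptation toward a target acceptance rate.

    Active only during burn-in; frozen afterwards so the chain keeps
    detailed balance.
    """

    def __init__(self, n: int, scale: float = 0.3, target: float = 0.35, window: int = 100):
        self.scales = np.full(n, scale)
        self.acc = np.zeros(n)
        self.att = np.zeros(n)
        self.total_acc = np.zeros(n)
        self.total_att = np.zeros(n)
        self.target = target
        self.window = window

    def record(self, i: int, accepted: bool) -> None:
        self.att[i] += 1
        self.total_att[i] += 1
        if accepted:
            self.acc[i] += 1
            self.total_acc[i] += 1

    def maybe_adapt(self) -> None:
        ready = self.att >= self.window
        if np.any(ready):
            rate = np.where(ready, self.acc / np.maximum(self.att, 1), self.target)
            self.scales = np.clip(self.scales * np.exp(rate - self.target), 1e-3, 50.0)
            self.acc[ready] = 0
            self.att[ready] = 0

    def rate(self) -> float:
        tot = self.total_att.sum()
        return float(self.total_acc.sum() / tot) if tot else float("nan")


def fit_model(records: pd.DataFrame, area_map: AreaMap, spec: ModelSpec,
              factor_spec=None, mcmc: dict | None = None) -> FitResult:
    """Fit one of Models 1–4 by Metropolis-within-Gibbs MCMC.

    ``mcmc`` keys: ``iterations`` (default 20000), ``burn_in`` (5000),
    ``thin`` (5) and ``seed`` (required).  Random-walk scales adapt during
    burn-in toward ~35% acceptance and are then frozen.  ``f_s`` is re-
    centred to zero within every graph component after each sweep with the
    deficit absorbed into ``beta0``; the precisions are drawn from their
    conjugate Gamma full conditionals.  Deterministic given the seed.
    """
    mcmc = {**{"iterations": 20000, "burn_in": 5000, "thin": 5, "seed": None}, **(mcmc or {})}
    if mcmc["seed"] is None:
        raise ValueError("mcmc['seed'] is required for reproducibility")
    iterations, burn_in, thin = int(mcmc["iterations"]), int(mcmc["burn_in"]), int(mcmc["thin"])
    if iterations <= burn_in:
        raise ValueError("iterations must exceed burn_in")
    seed = int(mcmc["seed"])
    rng = np.random.default_rng(seed)

    data, names, resolved_spec = prepare_model_data(
        records, area_map, factor_spec, spec.reference_levels
    )
    sm = structure_matrix(area_map)
    A, k = area_map.n_areas, sm.n_components
    if spec.include_structured and len(area_map.edges()) == 0:
        raise ValueError("structured effect requested on an edgeless graph; "
                         "the ICAR prior is vacuous — use Model 1 or 2")
    nbr_idx = [np.array([area_map.index[b] for b in area_map.neighbors[a]], dtype=np.int64)
               for a in area_map.area_ids]
    comp_masks = [sm.component_labels == g for g in range(k)]
    comp_sizes = np.array([m.sum() for m in comp_masks], dtype=float)

    p = data.X.shape[1]
    pooled = np.clip(data.y.mean(), 1e-3, 1 - 1e-3)
    beta0 = float(np.log(pooled / (1 - pooled)))
    beta = np.zeros(p)
    f_s = np.zeros(A)
    f_u = np.zeros(A)
    tau_s = tau_u = 1.0
    tb = spec.beta_prior_precision

    cell_fs = lambda: f_s[data.cell_area]
    eta = beta0 + data.cell_X @ beta
    if spec.include_structured:
        eta = eta + cell_fs()
    if spec.include_unstructured:
        eta = eta + f_u[data.cell_area]
    ll = data.loglik(eta)

    ad_b0 = _Adapter(1, scale=0.1)
    ad_b = _Adapter(p, scale=0.1)
    ad_fs = _Adapter(1, scale=0.3)
    ad_fu = _Adapter(1, scale=0.3)

    n_keep = (iterations - burn_in + thin - 1) // thin
    S_beta0 = np.empty(n_keep)
    S_beta = np.empty((n_keep, p))
    S_fs = np.empty((n_keep, A)) if spec.include_structured else None
    S_fu = np.empty((n_keep, A)) if spec.include_unstructured else None
    S_ts = np.empty(n_keep) if spec.include_structured else None
    S_tu = np.empty(n_keep) if spec.include_unstructured else None
    S_dev = np.empty(n_keep)
    stored = 0

    softplus = lambda x: np.logaddexp(0.0, x)

    for it in range(iterations):
        adapting = it < burn_in

        # --- beta0 ---
        delta = rng.normal(0.0, ad_b0.scales[0])
        new_eta = eta + delta
        new_ll = data.loglik(new_eta)
        dprior = -0.5 * tb * ((beta0 + delta) ** 2 - beta0**2)
        if np.log(rng.random()) < new_ll - ll + dprior:
            beta0 += delta
            eta, ll = new_eta, new_ll
            ad_b0.record(0, True)
        else:
            ad_b0.record(0, False)

        # --- beta, one coordinate at a time (dummy columns: only cells with
        #     a nonzero entry move) ---
        for j in range(p):
            aff = data.col_cells[j]
            delta = rng.normal(0.0, ad_b.scales[j])
            de = delta * data.cell_X[aff, j]
            old = eta[aff]
            new = old + de
            dll = float(data.cell_y[aff] @ de - data.cell_n[aff] @ (softplus(new) - softplus(old)))
            dprior = -0.5 * tb * ((beta[j] + delta) ** 2 - beta[j] ** 2)
            if np.log(rng.random()) < dll + dprior:
                beta[j] += delta
                eta[aff] = new
                ll += dll
                ad_b.record(j, True)
            else:
                ad_b.record(j, False)

        # --- unstructured effects ---
        if spec.include_unstructured:
            s = ad_fu.scales[0]
            for a in range(A):
                cells = data.area_cells[a]
                delta = rng.normal(0.0, s)
                old = eta[cells]
                new = old + delta
                dll = float(data.cell_y[cells].sum() * delta
                            - data.cell_n[cells] @ (softplus(new) - softplus(old)))
                dprior = -0.5 * tau_u * ((f_u[a] + delta) ** 2 - f_u[a] ** 2)
                if np.log(rng.random()) < dll + dprior:
                    f_u[a] += delta
                    eta[cells] = new
                    ll += dll
                    ad_fu.record(0, True)
                else:
                    ad_fu.record(0, False)
            tau_u = draw_precision(rng, *tau_u_conditional(f_u, spec.prior_a, spec.prior_b))

        # --- structured effects ---
        if spec.include_structured:
            s = ad_fs.scales[0]
            for a in range(A):
                nb = nbr_idx[a]
                cells = data.area_cells[a]
                delta = rng.normal(0.0, s)
                old = eta[cells]
                new = old + delta
                dll = float(data.cell_y[cells].sum() * delta
                            - data.cell_n[cells] @ (softplus(new) - softplus(old)))
                if len(nb):
                    diffs = f_s[a] - f_s[nb]
                    dprior = -0.5 * tau_s * float(np.sum((diffs + delta) ** 2 - diffs**2))
                else:
                    dprior = 0.0
                if np.log(rng.random()) < dll + dprior:
                    f_s[a] += delta
                    eta[cells] = new
                    ll += dll
                    ad_fs.record(0, True)
                else:
                    ad_fs.record(0, False)
            # hard sum-to-zero constraint per component; the removed level
            # shifts into the intercept (area-count-weighted mean)
            means = np.array([f_s[m].mean() for m in comp_masks])
            for g, m in enumerate(comp_masks):
                f_s[m] -= means[g]
            beta0 += float(comp_sizes @ means / A)
            eta = beta0 + data.cell_X @ beta + cell_fs()
            if spec.include_unstructured:
                eta = eta + f_u[data.cell_area]
            ll = data.loglik(eta)
            tau_s = draw_precision(rng, *tau_s_conditional(f_s, sm, spec.prior_a, spec.prior_b))

        if adapting:
            for ad in (ad_b0, ad_b, ad_fs, ad_fu):
                ad.maybe_adapt()

        if not np.isfinite(ll):
            raise FloatingPointError(
                f"MCMC diverged at iteration {it}: non-finite log-likelihood "
                f"(beta0={beta0:.3g}, |beta|max={np.abs(beta).max() if p else 0:.3g})"
            )

        if it >= burn_in and (it - burn_in) % thin == 0:
            S_beta0[stored] = beta0
            S_beta[stored] = beta
            if S_fs is not None:
                S_fs[stored] = f_s
                S_ts[stored] = tau_s
            if S_fu is not None:
                S_fu[stored] = f_u
                S_tu[stored] = tau_u
            S_dev[stored] = -2.0 * ll
            stored += 1

    samples = PosteriorSamples(
        beta0=S_beta0[:stored], beta=S_beta[:stored],
        f_s=None if S_fs is None else S_fs[:stored],
        f_u=None if S_fu is None else S_fu[:stored],
        tau_s=None if S_ts is None else S_ts[:stored],
        tau_u=None if S_tu is None else S_tu[:stored],
        deviance=S_dev[:stored],
    )

    # DIC: plug the posterior means of the linear-predictor parameters in
    eta_hat = samples.beta0.mean() + data.cell_X @ samples.beta.mean(axis=0)
    if samples.f_s is not None:
        eta_hat = eta_hat + samples.f_s.mean(axis=0)[data.cell_area]
    if samples.f_u is not None:
        eta_hat = eta_hat + samples.f_u.mean(axis=0)[data.cell_area]
    dic, p_d = compute_dic(samples.deviance, -2.0 * data.loglik(eta_hat))

    summaries = _summarize(samples, names, area_map.area_ids)
    acceptance = {
        "beta0": ad_b0.rate(), "beta": ad_b.rate(),
        "f_s": ad_fs.rate(), "f_u": ad_fu.rate(),
    }
    resolved_refs = {
        f: (spec.reference_levels or {}).get(f, levels[0])
        for f, levels in resolved_spec.items()
    }
    return FitResult(
        spec=spec, samples=samples, summaries=summaries, dic=dic, pd=p_d,
        acceptance_rates=acceptance, seed=seed, column_names=names,
        area_ids=area_map.area_ids, factor_spec=resolved_spec,
        reference_levels=resolved_refs,
    )


def _summarize(samples: PosteriorSamples, names: list[str], area_ids) -> pd.DataFrame:
    rows = {}

    def add(name, x):
        rows[name] = {
            "mean": np.mean(x), "sd": np.std(x, ddof=1) if len(x) > 1 else 0.0,
            "q025": np.percentile(x, 2.5), "median": np.percentile(x, 50),
            "q975": np.percentile(x, 97.5),
        }

    add("beta0", samples.beta0)
    for j, nm in enumerate(names):
        add(nm, samples.beta[:, j])
    if samples.tau_s is not None:
        add("tau_s", samples.tau_s)
        for j, a in enumerate(area_ids):
            add(f"f_s[{a}]", samples.f_s[:, j])
    if samples.tau_u is not None:
        add("tau_u", samples.tau_u)
        for j, a in enumerate(area_ids):
            add(f"f_u[{a}]", samples.f_u[:, j])
    return pd.DataFrame(rows).T


def compute_dic(deviances: np.ndarray, deviance_at_mean: float) -> tuple[float, float]:
    """DIC and effective parameter count from stored deviances.

    ``pD = mean(D) − D(posterior mean)``; ``DIC = mean(D) + pD``.  A
    negative pD signals a poorly behaved posterior and is logged as a
    warning rather than raised.
    """
    deviances = np.asarray(deviances, dtype=float)
    dbar = float(deviances.mean())
    p_d = dbar - float(deviance_at_mean)
    if p_d < 0:
        warnings.warn(f"negative pD ({p_d:.3f}); DIC may be unreliable")
    return dbar + p_d, p_d


def select_best_model(fits: dict) -> object:
    """Model key with the smallest DIC.

    Values may be :class:`FitResult` objects or bare DIC numbers.  Exact
    ties break toward the model with fewer random-effect components, then
    toward the earlier key in sorted order.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fitted models to compare")

    def dic_of(v):
        return v.dic if isinstance(v, FitResult) else float(v)

    def components_of(key, v):
        if isinstance(v, FitResult):
            return v.spec.n_random_components
        try:
            return {1: 0, 2: 1, 3: 1, 4: 2}[int(key)]
        except (ValueError, TypeError, KeyError):
            return 0

    keys = sorted(fits, key=lambda k: str(k))
    best = min(keys, key=lambda k: (dic_of(fits[k]), components_of(k, fits[k]), str(k)))
    return best


def odds_ratio_table(fit: FitResult) -> pd.DataFrame:
    """Posterior odds ratios with 95% credible intervals per coefficient.

    The point estimate is the exponentiated posterior median; interval
    endpoints are the exponentiated 2.5/97.5 posterior percentiles.
    Reference levels appear as rows with OR fixed at 1.
    """
    rows = []
    by_name = {nm: j for j, nm in enumerate(fit.column_names)}
    for fac, levels in fit.factor_spec.items():
        ref = fit.reference_levels.get(fac, levels[0])
        for lv in levels:
            if lv == ref:
                rows.append({"factor": fac, "level": lv, "reference": True,
                             "or": 1.0, "or_low": 1.0, "or_high": 1.0})
            else:
                b = fit.samples.beta[:, by_name[f"{fac}={lv}"]]
                rows.append({
                    "factor": fac, "level": lv, "reference": False,
                    "or": float(np.exp(np.percentile(b, 50))),
                    "or_low": float(np.exp(np.percentile(b, 2.5))),
                    "or_high": float(np.exp(np.percentile(b, 97.5))),
                })
    return pd.DataFrame(rows)


def posterior_prevalence_map(fit: FitResult, records: pd.DataFrame, area_map: AreaMap,
                             summary_set=("mean", "median", "q025", "q975"),
                             chunk: int = 500) -> pd.DataFrame:
    """Per-area posterior prevalence summaries for choropleth mapping.

    For each stored posterior draw, an area's prevalence is the average of
    ``expit(linear predictor)`` over that area's observed records; the
    requested summaries are then taken across draws.  Areas with no records
    are evaluated at the reference covariate pattern and flagged.
    """
    X, names = build_design_matrix(records, fit.factor_spec, fit.reference_levels)
    if names != fit.column_names:
        raise ValueError("records are incompatible with the fitted design")
    idx = area_map.index
    area_idx = records["area_id"].astype(str).map(idx).to_numpy(dtype=np.int64)
    A = area_map.n_areas
    key = np.column_stack([area_idx.astype(float), X])
    uniq, inv = np.unique(key, axis=0, return_inverse=True)
    cell_area = uniq[:, 0].astype(np.int64)
    cell_X = uniq[:, 1:]
    cell_n = np.bincount(inv, minlength=len(uniq)).astype(float)
    area_tot = np.bincount(cell_area, weights=cell_n, minlength=A)
    empty = area_tot == 0

    S = len(fit.samples)
    acc = {k: [] for k in summary_set}
    prev = np.empty((S, A))
    for lo in range(0, S, chunk):
        hi = min(lo + chunk, S)
        eta = fit.samples.beta0[lo:hi, None] + fit.samples.beta[lo:hi] @ cell_X.T
        if fit.samples.f_s is not None:
            eta = eta + fit.samples.f_s[lo:hi][:, cell_area]
        if fit.samples.f_u is not None:
            eta = eta + fit.samples.f_u[lo:hi][:, cell_area]
        pcell = expit(eta) * cell_n
        for s in range(hi - lo):
            prev[lo + s] = np.bincount(cell_area, weights=pcell[s], minlength=A)
        prev[lo:hi, ~empty] /= area_tot[~empty]
        if np.any(empty):
            eta0 = np.tile(fit.samples.beta0[lo:hi, None], (1, int(empty.sum())))
            cols = np.where(empty)[0]
            if fit.samples.f_s is not None:
                eta0 = eta0 + fit.samples.f_s[lo:hi][:, cols]
            if fit.samples.f_u is not None:
                eta0 = eta0 + fit.samples.f_u[lo:hi][:, cols]
            prev[lo:hi][:, cols] = expit(eta0)

    fns = {"mean": lambda x: x.mean(axis=0),
           "median": lambda x: np.percentile(x, 50, axis=0),
           "q025": lambda x: np.percentile(x, 2.5, axis=0),
           "q975": lambda x: np.percentile(x, 97.5, axis=0)}
    out = {k: fns[k](prev) for k in summary_set}
    out["no_records"] = empty
    return pd.DataFrame(out, index=list(area_map.area_ids))
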