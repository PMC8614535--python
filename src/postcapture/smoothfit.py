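"""Additive mixed model of a log movement metric with by-method time smooths.

Model for one response (log distance-to-COG or log step):

    y = X_f beta + sum_m f_m(t) 1[method = m] + b_animal + b_site + eps

* ``f_m``: penalized cubic B-spline (P-spline) of days since capture, one
  per capture method, second-difference penalty, basis dimension k, with a
  sum-to-zero constraint over that method's observed t values (so f_m = 0 is
  "average behaviour" and the plotted curve is centred on zero);
* fixed effects: intercept, log home-range size, and an optional subset of
  {method, sex, age} main effects with two-way interactions;
* random intercepts for individual and study site, represented as
  ridge-penalized indicator blocks (variance component sigma^2/lambda);
* smoothing parameters and variance components chosen by Gaussian REML.

The REML criterion (up to a constant) for penalty S_lambda = sum lambda_j S_j:

    2 V = D_p/phi + log|X'X + S_lambda| - log|S_lambda|_+ - M_p log(phi)
          + n log(2 pi phi),

with D_p = ||y - X beta||^2 + beta' S_lambda beta, M_p the dimension of the
total penalty null space, and phi profiled as D_p / (n - M_p).  Pointwise
smooth standard errors come from the Bayesian coefficient covariance
phi (X'X + S_lambda)^{-1}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve, null_space
from scipy.optimize import minimize

from .config import AGE_CLASSES, METHODS, SEXES

__all__ = [
    "ModelSpec",
    "SmoothModel",
    "fit_model",
    "candidate_models",
    "aicc",
    "aicc_weights",
    "select_model",
    "IdentifiabilityError",
    "SmallSampleError",
]

MAIN_TERMS = ("method", "sex", "age")
INTERACTIONS = ("method:sex", "method:age", "sex:age")
_FACTOR_COLUMNS = {"method": "method", "sex": "sex", "age": "age_class"}
_FACTOR_LEVELS = {"method": METHODS, "sex": SEXES, "age": AGE_CLASSES}


class IdentifiabilityError(ValueError):
    """Design is rank deficient; the message names the offending term."""


class SmallSampleError(ValueError):
    """AICc undefined: n - k - 1 <= 0."""


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model structure.

    The by-method smooth of days since capture and the log home-range
    covariate are always present; ``fixed_terms`` selects additional factor
    main effects and two-way interactions (an interaction is only legal
    alongside both its main effects).
    """

    response: str
    fixed_terms: tuple[str, ...] = ()
    k: int = 10
    covariates: tuple[str, ...] = ("log_hr",)
    random_terms: tuple[str, ...] = ("animal", "site")

    def __post_init__(self) -> None:
        for t in self.fixed_terms:
            if t not in MAIN_TERMS + INTERACTIONS:
                raise ValueError(f"unknown fixed term {t!r}")
        for t in self.fixed_terms:
            if ":" in t:
                a, b = t.split(":")
                if a not in self.fixed_terms or b not in self.fixed_terms:
                    raise ValueError(f"interaction {t!r} requires both main effects")

    @property
    def label(self) -> str:
        return "+".join(self.fixed_terms) if self.fixed_terms else "(none)"


@dataclass
class _PenaltyBlock:
    name: str
    sl: slice
    S: np.ndarray  # dense penalty on the block's columns
    rank: int
    logdet_plus: float  # log pseudo-determinant of S (unit lambda)


@dataclass
class _SmoothInfo:
    method: str
    knots: np.ndarray
    Z: np.ndarray  # constraint null-space basis, k x (k-1)
    sl: slice
    t_min: float
    t_max: float


@dataclass
class SmoothModel:
    """A fitted penalized-spline mixed model."""

    spec: ModelSpec
    beta: np.ndarray
    cov: np.ndarray  # Bayesian coefficient covariance phi * (X'X + S)^-1
    phi: float  # residual variance
    lambdas: dict[str, float]
    variance_components: dict[str, float]
    edf: dict[str, float]  # effective df per penalized block
    fixed_names: list[str]
    fixed_slice: slice
    smooths: dict[str, _SmoothInfo]
    random_levels: dict[str, list]
    n_obs: int
    loglik: float
    methods: tuple[str, ...] = field(default_factory=tuple)

    @property
    def n_fixed(self) -> int:
        return len(self.fixed_names)

    @property
    def edf_smooths(self) -> float:
        return float(sum(v for k, v in self.edf.items() if k.startswith("s(")))

    @property
    def k_params(self) -> float:
        """Parameter count used by AICc: fixed coefficients + variance
        components (animal, site, residual) + effective df of the smooths."""
        n_vc = len(self.spec.random_terms) + 1
        return self.n_fixed + n_vc + self.edf_smooths


def _bspline_basis(x: np.ndarray, lo: float, hi: float, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Cubic B-spline basis with k functions on capture-weighted knots.

    Interior knots are quadratically warped towards t = 0: post-release
    disturbances decay fastest immediately after capture, so resolution is
    allocated where the curvature lives (a k=10 warped basis represents a
    3-day exponential decay better than a uniform k=15 one).
    """
    nseg = k - 3
    if hi <= lo:
        hi = lo + 1.0
    u = np.linspace(0.0, 1.0, nseg + 1)
    inner = lo + (hi - lo) * u * u
    pre = inner[0] - (inner[1] - inner[0]) * np.arange(3, 0, -1)
    post = inner[-1] + (inner[-1] - inner[-2]) * np.arange(1, 4)
    knots = np.concatenate([pre, inner, post])
    xc = np.clip(np.asarray(x, dtype=float), lo, hi)
    B = BSpline.design_matrix(xc, knots, 3).toarray()
    return B, knots


def _difference_penalty(k: int) -> np.ndarray:
    D = np.diff(np.eye(k), n=2, axis=0)
    return D.T @ D


def _dummies(values: pd.Series, levels: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded indicators for the levels present (first = reference)."""
    present = [lv for lv in levels if (values == lv).any()]
    cols, names = [], []
    for lv in present[1:]:
        cols.append((values == lv).to_numpy(dtype=float))
        names.append(lv)
    if cols:
        return np.column_stack(cols), names
    return np.empty((len(values), 0)), names


def _build_fixed(records: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    n = len(records)
    columns: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["(intercept)"]
    term_spans: list[tuple[str, int, int]] = [("(intercept)", 0, 1)]
    for cov in spec.covariates:
        columns.append(records[cov].to_numpy(dtype=float))
        names.append(cov)
        term_spans.append((cov, len(names) - 1, len(names)))
    factor_parts: dict[str, tuple[np.ndarray, list[str]]] = {}
    for term in MAIN_TERMS:
        if term in spec.fixed_terms:
            block, lv_names = _dummies(
                records[_FACTOR_COLUMNS[term]], _FACTOR_LEVELS[term]
            )
            if not lv_names:
                raise IdentifiabilityError(
                    f"fixed term {term!r} has a single observed level; not estimable"
                )
            factor_parts[term] = (block, lv_names)
            start = len(names)
            for j, lv in enumerate(lv_names):
                columns.append(block[:, j])
                names.append(f"{term}[{lv}]")
            term_spans.append((term, start, len(names)))
    for term in INTERACTIONS:
        if term in spec.fixed_terms:
            a, b = term.split(":")
            block_a, names_a = factor_parts[a]
            block_b, names_b = factor_parts[b]
            start = len(names)
            for ia, la in enumerate(names_a):
                for ib, lb in enumerate(names_b):
                    columns.append(block_a[:, ia] * block_b[:, ib])
                    names.append(f"{a}[{la}]:{b}[{lb}]")
            term_spans.append((term, start, len(names)))
    X = np.column_stack(columns)
    # incremental rank check names the first unidentifiable term
    rank_prev = 0
    for term, start, stop in term_spans:
        sub = X[:, :stop]
        rank = np.linalg.matrix_rank(sub.T @ sub)
        if rank < rank_prev + (stop - start):
            raise IdentifiabilityError(
                f"fixed term {term!r} is not identifiable with these data"
            )
        rank_prev = rank
    return X, names


def _prepare(records: pd.DataFrame, spec: ModelSpec):
    data = records.dropna(subset=[spec.response]).reset_index(drop=True)
    if data["animal_id"].nunique() < 2:
        raise ValueError("fit_model requires records from at least 2 animals")
    y = data[spec.response].to_numpy(dtype=float)
    n = len(data)

    X_fixed, fixed_names = _build_fixed(data, spec)
    p_fixed = X_fixed.shape[1]

    methods_present = tuple(m for m in METHODS if (data["method"] == m).any())
    blocks: list[_PenaltyBlock] = []
    smooths: dict[str, _SmoothInfo] = {}
    parts = [X_fixed]
    col = p_fixed
    S_raw = _difference_penalty(spec.k)
    for m in methods_present:
        mask = (data["method"] == m).to_numpy()
        t = data.loc[mask, "t_days"].to_numpy(dtype=float)
        if len(np.unique(t)) < spec.k:
            raise ValueError(
                f"method {m!r} has fewer than k={spec.k} distinct days since capture"
            )
        lo, hi = 0.0, float(t.max())
        B_obs, knots = _bspline_basis(t, lo, hi, spec.k)
        c = B_obs.mean(axis=0)
        Z = null_space(c[None, :])
        Xm = np.zeros((n, spec.k - 1))
        Xm[mask] = B_obs @ Z
        S = Z.T @ S_raw @ Z
        eig = np.linalg.eigvalsh(S)
        tol = eig.max() * 1e-9
        pos = eig[eig > tol]
        sl = slice(col, col + spec.k - 1)
        blocks.append(_PenaltyBlock(f"s({m})", sl, S, len(pos), float(np.log(pos).sum())))
        smooths[m] = _SmoothInfo(m, knots, Z, sl, lo, hi)
        parts.append(Xm)
        col += spec.k - 1

    random_levels: dict[str, list] = {}
    id_col = {"animal": "animal_id", "site": "site_id"}
    for rt in spec.random_terms:
        levels = sorted(data[id_col[rt]].unique())
        random_levels[rt] = levels
        idx = data[id_col[rt]].map({lv: i for i, lv in enumerate(levels)}).to_numpy()
        Zr = np.zeros((n, len(levels)))
        Zr[np.arange(n), idx] = 1.0
        sl = slice(col, col + len(levels))
        blocks.append(_PenaltyBlock(rt, sl, np.eye(len(levels)), len(levels), 0.0))
        parts.append(Zr)
        col += len(levels)

    X = np.concatenate(parts, axis=1)
    return data, y, X, fixed_names, slice(0, p_fixed), blocks, smooths, random_levels, methods_present


def _assemble(XtX: np.ndarray, blocks: list[_PenaltyBlock], rho: np.ndarray) -> tuple[np.ndarray, float, int]:
    A = XtX.copy()
    logdet_S = 0.0
    total_rank = 0
    for blk, r in zip(blocks, rho):
        lam = math.exp(r)
        A[blk.sl, blk.sl] += lam * blk.S
        logdet_S += blk.rank * r + blk.logdet_plus
        total_rank += blk.rank
    return A, logdet_S, total_rank


def _chol(A: np.ndarray):
    jitter = 0.0
    base = np.trace(A) / A.shape[0]
    for _ in range(6):
        try:
            return cho_factor(A + jitter * np.eye(A.shape[0]), lower=True)
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10.0, base * 1e-10)
    raise np.linalg.LinAlgError("penalized normal equations are not positive definite")


def _reml_value(rho, XtX, Xty, yty, blocks, n, p) -> float:
    A, logdet_S, total_rank = _assemble(XtX, blocks, np.asarray(rho))
    cf = _chol(A)
    beta = cho_solve(cf, Xty)
    Dp = max(yty - float(Xty @ beta), 1e-300)
    Mp = p - total_rank
    phi = Dp / (n - Mp)
    logdet_A = 2.0 * float(np.log(np.diag(cf[0])).sum())
    crit = (n - Mp) + logdet_A - logdet_S - Mp * math.log(phi) + n * math.log(2 * math.pi * phi)
    return 0.5 * crit


def fit_model(
    records: pd.DataFrame,
    spec: ModelSpec,
    lambdas: dict[str, float] | None = None,
) -> SmoothModel:
    """Fit the penalized-spline mixed model.

    ``records`` needs columns animal_id, site_id, method, sex, age_class,
    t_days, log_hr and the response; rows with a missing response (the first
    fix of each animal for the step metric) are dropped.  Smoothing
    parameters are selected by REML unless ``lambdas`` pins them (keys:
    ``s(<method>)``, ``animal``, ``site``).
    """
    (
        data,
        y,
        X,
        fixed_names,
        fixed_slice,
        blocks,
        smooths,
        random_levels,
        methods_present,
    ) = _prepare(records, spec)
    n, p = X.shape
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    if lambdas is None:
        x0 = np.zeros(len(blocks))
        res = minimize(
            _reml_value,
            x0,
            args=(XtX, Xty, yty, blocks, n, p),
            method="L-BFGS-B",
            bounds=[(-18.0, 18.0)] * len(blocks),
            options={"maxiter": 200},
        )
        rho = res.x
    else:
        rho = np.array([math.log(lambdas[blk.name]) for blk in blocks])

    A, _, total_rank = _assemble(XtX, blocks, rho)
    cf = _chol(A)
    beta = cho_solve(cf, Xty)
    Ainv = cho_solve(cf, np.eye(p))
    Dp = max(yty - float(Xty @ beta), 1e-300)
    Mp = p - total_rank
    phi = Dp / (n - Mp)
    cov = phi * Ainv

    F = Ainv @ XtX
    edf = {blk.name: float(np.trace(F[blk.sl, blk.sl])) for blk in blocks}
    lam = {blk.name: float(math.exp(r)) for blk, r in zip(blocks, rho)}
    vc = {blk.name: phi / lam[blk.name] for blk in blocks if blk.name in ("animal", "site")}
    vc["residual"] = phi

    rss = yty - 2.0 * float(beta @ Xty) + float(beta @ (XtX @ beta))
    rss = max(rss, 1e-300)
    loglik = -0.5 * (n * math.log(2 * math.pi * phi) + rss / phi)

    return SmoothModel(
        spec=spec,
        beta=beta,
        cov=cov,
        phi=phi,
        lambdas=lam,
        variance_components=vc,
        edf=edf,
        fixed_names=fixed_names,
        fixed_slice=fixed_slice,
        smooths=smooths,
        random_levels=random_levels,
        n_obs=n,
        loglik=loglik,
        methods=methods_present,
    )


def evaluate_smooth(
    model: SmoothModel, method: str, t_grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Centred smooth f_m(t) and pointwise SE on a grid.

    The sum-to-zero constraint is built into the basis, so the weighted mean
    of f over the method's observed t values is zero by construction.
    """
    if method not in model.smooths:
        raise KeyError(f"method {method!r} not in fitted model (have {list(model.smooths)})")
    info = model.smooths[method]
    t = np.asarray(t_grid, dtype=float)
    B = BSpline.design_matrix(np.clip(t, info.t_min, info.t_max), info.knots, 3).toarray()
    Xg = B @ info.Z
    beta_s = model.beta[info.sl]
    V = model.cov[info.sl, info.sl]
    f = Xg @ beta_s
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xg, V, Xg), 0.0))
    return f, se


def fixed_coefficient(model: SmoothModel, name: str) -> tuple[float, float]:
    """Point estimate and SE of a named fixed coefficient (e.g. 'log_hr')."""
    idx = model.fixed_names.index(name)
    return float(model.beta[idx]), float(math.sqrt(model.cov[idx, idx]))


def candidate_models(
    records: pd.DataFrame, response: str = "log_d_cog", k: int = 10
) -> list[ModelSpec]:
    """The hierarchical candidate set of fixed-term structures.

    All candidates carry the by-method smooth, the log home-range covariate
    and both random intercepts; fixed factor structures are the empty set,
    each single main effect, each pair of mains, and each pair with its own
    two-way interaction (interactions never appear without both mains).
    """
    sets: list[tuple[str, ...]] = [()]
    sets += [(t,) for t in MAIN_TERMS]
    pairs = [("method", "sex"), ("method", "age"), ("sex", "age")]
    sets += [p for p in pairs]
    sets += [p + (f"{p[0]}:{p[1]}",) for p in pairs]
    return [ModelSpec(response=response, fixed_terms=s, k=k) for s in sets]


def fit_candidates(
    records: pd.DataFrame, response: str = "log_d_cog", k: int = 10
) -> tuple[list[ModelSpec], list[SmoothModel]]:
    """Fit the whole candidate set, skipping unidentifiable structures.

    Sparse factor combinations (e.g. a method represented by one sex only)
    make some interaction candidates rank deficient; those are dropped from
    the comparison with a warning rather than failing the run.
    """
    import logging

    specs_out, models = [], []
    for spec in candidate_models(records, response=response, k=k):
        try:
            models.append(fit_model(records, spec))
            specs_out.append(spec)
        except IdentifiabilityError as exc:
            logging.getLogger(__name__).warning("skipping candidate %s: %s", spec.label, exc)
    if not models:
        raise IdentifiabilityError("no candidate model is identifiable with these data")
    return specs_out, models


def aicc_value(loglik: float, k: float, n: int) -> float:
    """AICc = -2 logLik + 2k + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        raise SmallSampleError(f"AICc undefined for n={n}, k={k:.2f}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def aicc(model: SmoothModel) -> float:
    """AICc of a fitted model, with k = fixed coefficients + variance
    components + total effective df of the smooths."""
    return aicc_value(model.loglik, model.k_params, model.n_obs)


def aicc_weights(aiccs: np.ndarray) -> np.ndarray:
    a = np.asarray(aiccs, dtype=float)
    delta = a - a.min()
    w = np.exp(-0.5 * delta)
    return w / w.sum()


def select_model(models: list[SmoothModel]) -> tuple[SmoothModel, np.ndarray]:
    """Minimum-AICc model (ties broken by smaller parameter count) and the
    Akaike weights of the whole candidate set."""
    if not models:
        raise ValueError("select_model needs at least one fitted model")
    scores = np.array([aicc(m) for m in models])
    weights = aicc_weights(scores)
    order = sorted(range(len(models)), key=lambda i: (scores[i], models[i].k_params))
    return models[order[0]], weights
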