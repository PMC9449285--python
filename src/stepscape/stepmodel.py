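"""Random-intercept additive model of daily steps on land-use exposure.

The model for user *u* on day *d* is

    y_{u,d} = beta_{0,u} + beta_1 SEX_u + beta_2 AGE_u
              + sum_k s_k(x_{u,d,k}) + eps_{u,d}

    eps_{u,d}   ~ N(0, sigma2_L1)          (day-level residual)
    beta_{0,u}  ~ N(alpha, sigma2_L2)      (user-level random intercept)
    x_{u,d,k}   = ln(LANDUSE_{u,d,k} + 1)

with one smooth s_k per reclassified land-use type, SEX coded 1 for female
and 0 for male, and AGE coded {10, 20, 30, 40, 50, 60} by age decade.

Each s_k is a penalized cubic B-spline (second-order difference penalty,
basis dimension 10 by default) under a sum-to-zero constraint over the
training data, so ``alpha`` is the identifiable grand intercept.  The random
intercept is the standard variance-component construction: ridge-penalized
user indicator columns, whose smoothing parameter is sigma2_L1/sigma2_L2.
All smoothing parameters and both variances are selected jointly by
restricted maximum likelihood (REML); per-smooth p-values are approximate
Wald-type tests on the penalized coefficients at the effective degrees of
freedom.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve, eigh, null_space
from scipy.stats import chi2

from .exposure import AGE_VALUES, TYPES

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "StepModelFit",
    "transform_exposure",
    "fit",
    "predict_fixed",
    "smooth_curve",
    "save_fit",
    "load_fit",
]


def transform_exposure(counts) -> np.ndarray:
    """Exposure index x = ln(count + 1), elementwise.

    Accepts a scalar, array, or an exposure-record row/table slice of the 8
    count columns.  Negative counts are a domain error.
    """
    arr = np.asarray(counts, dtype=float)
    if np.any(arr < 0):
        raise ValueError("exposure counts must be nonnegative")
    return np.log1p(arr)


@dataclass
class ModelConfig:
    """Tunable choices for the additive model fit."""

    basis_dim: int = 10                    # B-spline basis functions per smooth
    degree: int = 3                        # cubic
    smooth_types: tuple = tuple(TYPES)     # land-use types given a smooth
    linear_terms: frozenset = frozenset()  # types fitted as unpenalized linear terms
    include_sex_age: bool = True
    include_random_intercept: bool = True
    reml_bounds: tuple = (-18.0, 25.0)     # bounds on log smoothing parameters


@dataclass
class SmoothTerm:
    """One fitted (or dropped) smooth."""

    name: str
    kind: str                  # "spline" | "linear" | "dropped"
    sl: slice | None = None    # columns in the design matrix
    knots: np.ndarray | None = None
    degree: int = 3
    Z: np.ndarray | None = None            # constraint null-space transform
    x_min: float = 0.0
    x_max: float = 0.0
    x_mean: float = 0.0        # centering offset for linear terms
    penalty_rank: int = 0
    edf: float = 0.0
    p_value: float = float("nan")
    significant: bool = False

    def basis(self, x: np.ndarray) -> np.ndarray:
        """Constrained basis evaluated at x (natural spline extrapolation)."""
        if self.kind == "dropped":
            return np.zeros((len(x), 0))
        if self.kind == "linear":
            return (x - self.x_mean)[:, None]
        B = BSpline.design_matrix(x, self.knots, self.degree, extrapolate=True).toarray()
        return B @ self.Z


def _bspline_knots(x_min: float, x_max: float, nb: int, degree: int) -> np.ndarray:
    nseg = nb - degree
    if nseg < 1:
        raise ValueError(f"basis_dim must exceed degree, got {nb} <= {degree}")
    dx = (x_max - x_min) / nseg
    return x_min + dx * np.arange(-degree, nseg + degree + 1)


@dataclass
class StepModelFit:
    """A fitted step-count model (coefficients, variances, diagnostics)."""

    config: ModelConfig
    terms: list                       # SmoothTerm per land-use type in smooth_types
    beta: np.ndarray
    cov: np.ndarray                   # Bayesian posterior covariance of beta
    alpha: float
    beta_sex: float | None
    beta_age: float | None
    sigma2_l1: float
    sigma2_l2: float
    lambdas: dict
    users: list
    user_intercepts: dict             # uuid -> alpha + b_u
    deviance_explained: float
    edf_total: float
    n_obs: int
    fixed_slices: dict = field(default_factory=dict)
    random_slice: slice | None = None

    # -- fixed-effects prediction ------------------------------------------
    def predict_fixed(self, records: pd.DataFrame) -> np.ndarray:
        """alpha + sum_k s_k(x_k); sex, age, and user intercepts ignored.

        ``records`` is an exposure table carrying the 8 count columns.
        Values of x outside the training range use the spline's natural
        extrapolation (a warning is logged).
        """
        yhat = np.full(len(records), self.alpha, dtype=float)
        n_out = 0
        for term in self.terms:
            if term.kind == "dropped":
                continue
            x = transform_exposure(records[term.name].to_numpy(float))
            n_out += int(((x < term.x_min) | (x > term.x_max)).sum())
            yhat += term.basis(x) @ self.beta[term.sl]
        if n_out:
            logger.warning(
                "predict_fixed: %d exposure values outside the training range "
                "were extrapolated", n_out
            )
        return yhat

    def smooth_curve(self, name: str, x_grid) -> pd.DataFrame:
        """s_k on a grid with pointwise 95% intervals from the coefficient
        covariance."""
        term = next((t for t in self.terms if t.name == name), None)
        if term is None:
            raise ValueError(f"no smooth for land-use type {name!r}")
        x = np.asarray(x_grid, dtype=float)
        if term.kind == "dropped":
            z = np.zeros_like(x)
            return pd.DataFrame({"x": x, "estimate": z, "se": z, "lo": z, "hi": z})
        B = term.basis(x)
        est = B @ self.beta[term.sl]
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", B, self.cov[term.sl, term.sl], B), 0.0))
        return pd.DataFrame(
            {"x": x, "estimate": est, "se": se, "lo": est - 1.96 * se, "hi": est + 1.96 * se}
        )


def _design(records: pd.DataFrame, config: ModelConfig):
    """Build the design matrix, penalty blocks, and term bookkeeping."""
    n = len(records)
    cols: list[np.ndarray] = []
    col_names: list[str] = []
    penalties = []  # (slice, S, rank, logdet_plus)
    fixed_slices = {}
    n_unpenalized = 0

    cols.append(np.ones((n, 1)))
    col_names.append("intercept")
    fixed_slices["intercept"] = slice(0, 1)
    n_unpenalized += 1
    pos = 1

    if config.include_sex_age:
        sex = records["sex"].map({"male": 0.0, "female": 1.0}).to_numpy(float)
        age = records["age_group"].map(AGE_VALUES).to_numpy(float)
        if np.isnan(sex).any() or np.isnan(age).any():
            raise ValueError("model data contain missing sex or age; split_model_data first")
        cols.append(sex[:, None])
        fixed_slices["sex"] = slice(pos, pos + 1)
        pos += 1
        cols.append(age[:, None])
        fixed_slices["age"] = slice(pos, pos + 1)
        pos += 1
        col_names += ["sex", "age"]
        n_unpenalized += 2

    terms: list[SmoothTerm] = []
    for name in config.smooth_types:
        x = transform_exposure(records[name].to_numpy(float))
        x_min, x_max = float(x.min()), float(x.max())
        if x_max - x_min < 1e-8:
            terms.append(SmoothTerm(name, "dropped", x_min=x_min, x_max=x_max))
            logger.warning("smooth for %r dropped: exposure index is constant", name)
            continue
        if name in config.linear_terms:
            xm = float(x.mean())
            cols.append((x - xm)[:, None])
            terms.append(
                SmoothTerm(name, "linear", sl=slice(pos, pos + 1),
                           x_min=x_min, x_max=x_max, x_mean=xm)
            )
            pos += 1
            n_unpenalized += 1
            continue
        nb = config.basis_dim
        knots = _bspline_knots(x_min, x_max, nb, config.degree)
        B = BSpline.design_matrix(x, knots, config.degree, extrapolate=True).toarray()
        Z = null_space(B.mean(axis=0, keepdims=True))      # sum-to-zero over data
        Bc = B @ Z
        D2 = np.diff(np.eye(nb), n=2, axis=0)
        Sc = Z.T @ (D2.T @ D2) @ Z
        w = eigh(Sc, eigvals_only=True)
        rank = int((w > w.max() * 1e-9).sum())
        logdet_plus = float(np.log(w[w > w.max() * 1e-9]).sum())
        sl = slice(pos, pos + Bc.shape[1])
        cols.append(Bc)
        penalties.append((sl, Sc, rank, logdet_plus, f"s({name})"))
        terms.append(
            SmoothTerm(name, "spline", sl=sl, knots=knots, degree=config.degree,
                       Z=Z, x_min=x_min, x_max=x_max, penalty_rank=rank)
        )
        pos += Bc.shape[1]
        n_unpenalized += Bc.shape[1] - rank   # penalty null space (the linear trend)

    users: list = []
    random_slice = None
    if config.include_random_intercept:
        uid, uniq = pd.factorize(records["uuid"])
        users = [str(u) for u in uniq]
        m = len(users)
        U = np.zeros((n, m))
        U[np.arange(n), uid] = 1.0
        sl = slice(pos, pos + m)
        cols.append(U)
        penalties.append((sl, np.eye(m), m, 0.0, "user"))
        random_slice = sl
        pos += m

    X = np.hstack(cols)
    return X, penalties, terms, fixed_slices, random_slice, users, n_unpenalized


def _check_rank(records: pd.DataFrame, config: ModelConfig) -> None:
    """Fail early, with names, when parametric columns are collinear."""
    bad = []
    if config.include_sex_age:
        sex = records["sex"].map({"male": 0.0, "female": 1.0}).to_numpy(float)
        age = records["age_group"].map(AGE_VALUES).to_numpy(float)
        if np.nanstd(sex) == 0:
            bad.append("sex")
        if np.nanstd(age) == 0:
            bad.append("age")
    if bad:
        raise ValueError(
            "design is rank deficient: column(s) "
            + ", ".join(bad)
            + " are constant and collinear with the intercept"
        )


def fit(records: pd.DataFrame, config: ModelConfig | None = None) -> StepModelFit:
    """REML fit of the random-intercept additive step model.

    ``records`` is the model-building exposure table (observed steps plus
    known sex and age): columns ``uuid, date, steps, sex, age_group`` and
    the 8 count columns.
    """
    config = config or ModelConfig()
    if records["uuid"].nunique() < 2:
        raise ValueError("fit requires records from at least 2 users")
    _check_rank(records, config)

    y = records["steps"].to_numpy(float)
    n = len(y)
    X, penalties, terms, fixed_slices, random_slice, users, n_unpen = _design(records, config)
    p = X.shape[1]
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    n_mp = n - n_unpen
    if n_mp <= 0:
        raise ValueError("more unpenalized coefficients than observations")

    def assemble(rho: np.ndarray) -> np.ndarray:
        A = XtX.copy()
        for (sl, S, _, _, _), r in zip(penalties, rho):
            A[sl, sl] += np.exp(r) * S
        return A

    def nreml(rho: np.ndarray) -> float:
        A = assemble(rho)
        try:
            c, low = cho_factor(A, lower=True)
        except np.linalg.LinAlgError:
            return 1e12
        beta = cho_solve((c, low), Xty)
        D = max(yty - beta @ Xty, 1e-300)
        sig2 = D / n_mp
        logdet_A = 2.0 * float(np.log(np.diag(c)).sum())
        logdet_S = sum(
            rank * r + ld for (_, _, rank, ld, _), r in zip(penalties, rho)
        )
        return 0.5 * (n_mp * (np.log(2.0 * np.pi * sig2) + 1.0) + logdet_A - logdet_S)

    if penalties:
        rho0 = np.array(
            [np.log(max(np.trace(XtX[sl, sl]), 1e-8) / max(np.trace(S), 1e-8))
             for sl, S, _, _, _ in penalties]
        )
        lo, hi = config.reml_bounds
        rho0 = np.clip(rho0, lo + 1.0, hi - 1.0)
        res = optimize.minimize(
            nreml, rho0, method="L-BFGS-B",
            bounds=[config.reml_bounds] * len(penalties),
            options={"maxiter": 200},
        )
        rho = res.x
    else:
        rho = np.zeros(0)

    A = assemble(rho)
    c, low = cho_factor(A, lower=True)
    beta = cho_solve((c, low), Xty)
    Ainv = cho_solve((c, low), np.eye(p))
    D = max(yty - beta @ Xty, 1e-300)
    sigma2_l1 = D / n_mp
    cov = Ainv * sigma2_l1

    fitted = X @ beta
    rss = float(((y - fitted) ** 2).sum())
    null_dev = float(((y - y.mean()) ** 2).sum())
    dev_expl = 1.0 - rss / null_dev if null_dev > 0 else 0.0

    edf_col = np.sum(Ainv * XtX, axis=1)  # diag(Ainv @ XtX)
    lambdas = {label: float(np.exp(r)) for (_, _, _, _, label), r in zip(penalties, rho)}

    sigma2_l2 = 0.0
    user_intercepts: dict[str, float] = {}
    alpha = float(beta[fixed_slices["intercept"]][0])
    if random_slice is not None:
        sigma2_l2 = sigma2_l1 / lambdas["user"]
        b = beta[random_slice]
        user_intercepts = {u: alpha + float(bu) for u, bu in zip(users, b)}

    # per-smooth effective df and approximate Wald p-values
    for term in terms:
        if term.kind == "dropped":
            continue
        sl = term.sl
        term.edf = float(edf_col[sl].sum())
        bk = beta[sl]
        Vk = cov[sl, sl]
        if Vk.shape[0] == 1:
            stat = float(bk[0] ** 2 / max(Vk[0, 0], 1e-300))
            df = 1
        else:
            w, vecs = eigh(Vk)
            order = np.argsort(w)[::-1]
            df = int(min(len(bk), max(1, round(term.edf))))
            w_k, v_k = w[order[:df]], vecs[:, order[:df]]
            w_k = np.maximum(w_k, w_k.max() * 1e-12)
            proj = v_k.T @ bk
            stat = float(proj @ (proj / w_k))
        term.p_value = float(chi2.sf(stat, df=df))
        term.significant = term.p_value < 0.05

    beta_sex = float(beta[fixed_slices["sex"]][0]) if "sex" in fixed_slices else None
    beta_age = float(beta[fixed_slices["age"]][0]) if "age" in fixed_slices else None

    return StepModelFit(
        config=config,
        terms=terms,
        beta=beta,
        cov=cov,
        alpha=alpha,
        beta_sex=beta_sex,
        beta_age=beta_age,
        sigma2_l1=float(sigma2_l1),
        sigma2_l2=float(sigma2_l2),
        lambdas=lambdas,
        users=users,
        user_intercepts=user_intercepts,
        deviance_explained=float(dev_expl),
        edf_total=float(edf_col.sum()),
        n_obs=n,
        fixed_slices=fixed_slices,
        random_slice=random_slice,
    )


def predict_fixed(fit_: StepModelFit, records: pd.DataFrame) -> np.ndarray:
    """Module-level alias for :meth:`StepModelFit.predict_fixed`."""
    if not isinstance(fit_, StepModelFit):
        raise ValueError("predict_fixed requires a fitted StepModelFit")
    return fit_.predict_fixed(records)


def smooth_curve(fit_: StepModelFit, name: str, x_grid) -> pd.DataFrame:
    """Module-level alias for :meth:`StepModelFit.smooth_curve`."""
    return fit_.smooth_curve(name, x_grid)


# -- serialization ---------------------------------------------------------

def save_fit(fit_: StepModelFit, path) -> None:
    """Write a fitted model to a self-describing JSON file."""
    d = {
        "config": {
            "basis_dim": fit_.config.basis_dim,
            "degree": fit_.config.degree,
            "smooth_types": list(fit_.config.smooth_types),
            "linear_terms": sorted(fit_.config.linear_terms),
            "include_sex_age": fit_.config.include_sex_age,
            "include_random_intercept": fit_.config.include_random_intercept,
        },
        "alpha": fit_.alpha,
        "beta_sex": fit_.beta_sex,
        "beta_age": fit_.beta_age,
        "sigma2_l1": fit_.sigma2_l1,
        "sigma2_l2": fit_.sigma2_l2,
        "lambdas": fit_.lambdas,
        "deviance_explained": fit_.deviance_explained,
        "edf_total": fit_.edf_total,
        "n_obs": fit_.n_obs,
        "beta": fit_.beta.tolist(),
        "cov": fit_.cov.tolist(),
        "users": fit_.users,
        "user_intercepts": fit_.user_intercepts,
        "terms": [
            {
                "name": t.name,
                "kind": t.kind,
                "start": t.sl.start if t.sl else None,
                "stop": t.sl.stop if t.sl else None,
                "knots": t.knots.tolist() if t.knots is not None else None,
                "degree": t.degree,
                "Z": t.Z.tolist() if t.Z is not None else None,
                "x_min": t.x_min,
                "x_max": t.x_max,
                "x_mean": t.x_mean,
                "penalty_rank": t.penalty_rank,
                "edf": t.edf,
                "p_value": t.p_value,
                "significant": t.significant,
            }
            for t in fit_.terms
        ],
    }
    with open(path, "w") as fh:
        json.dump(d, fh)


def load_fit(path) -> StepModelFit:
    """Read a model written by :func:`save_fit`."""
    with open(path) as fh:
        d = json.load(fh)
    cfg = ModelConfig(
        basis_dim=d["config"]["basis_dim"],
        degree=d["config"]["degree"],
        smooth_types=tuple(d["config"]["smooth_types"]),
        linear_terms=frozenset(d["config"]["linear_terms"]),
        include_sex_age=d["config"]["include_sex_age"],
        include_random_intercept=d["config"]["include_random_intercept"],
    )
    terms = []
    for t in d["terms"]:
        terms.append(
            SmoothTerm(
                name=t["name"],
                kind=t["kind"],
                sl=slice(t["start"], t["stop"]) if t["start"] is not None else None,
                knots=np.asarray(t["knots"]) if t["knots"] is not None else None,
                degree=t["degree"],
                Z=np.asarray(t["Z"]) if t["Z"] is not None else None,
                x_min=t["x_min"],
                x_max=t["x_max"],
                x_mean=t["x_mean"],
                penalty_rank=t["penalty_rank"],
                edf=t["edf"],
                p_value=t["p_value"],
                significant=t["significant"],
            )
        )
    return StepModelFit(
        config=cfg,
        terms=terms,
        beta=np.asarray(d["beta"]),
        cov=np.asarray(d["cov"]),
        alpha=d["alpha"],
        beta_sex=d["beta_sex"],
        beta_age=d["beta_age"],
        sigma2_l1=d["sigma2_l1"],
        sigma2_l2=d["sigma2_l2"],
        lambdas=d["lambdas"],
        users=d["users"],
        user_intercepts=d["user_intercepts"],
        deviance_explained=d["deviance_explained"],
        edf_total=d["edf_total"],
        n_obs=d["n_obs"],
    )
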