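"""Weighted regression machinery for the trio analysis.

Three model families are fit here, all with survey weights and
heteroskedasticity- or cluster-robust sandwich variance:

* **phenotypic**: WLS of an offspring outcome on both parents'
  self-reported BMI plus covariates (no offspring PGI, following standard
  practice for purely phenotypic models);
* **mr**: instrumental-variables two-stage least squares, instrumenting
  parental self-reported BMI with the parental polygenic indices while
  conditioning on the offspring PGI (which blocks the direct-transmission
  path) and covariates; a duo variant drops the father's terms;
* **pgi**: WLS of the outcome on mother's, father's and child's PGIs
  simultaneously, separating indirect (parental) from direct (child)
  genetic effects, with the mother/child coefficient ratio and its
  delta-method SE.

Covariates follow the analysis convention: child sex, age at assessment as
a 2-df natural cubic spline, maternal age at birth, maternal education
years, social-class indicators, and 10 principal-component columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ModelResult",
    "natural_spline_basis",
    "fit_wls",
    "fit_iv2sls",
    "first_stage_partial_F",
    "fit_phenotypic_model",
    "fit_trio_mr",
    "fit_pgi_model",
    "fit_lpm",
    "covariate_frame",
]

log = logging.getLogger(__name__)


@dataclass
class ModelResult:
    """Fitted coefficients with robust variance and diagnostics."""

    params: pd.Series
    cov: pd.DataFrame
    nobs: int
    model: str = "wls"
    first_stage_F: dict = field(default_factory=dict)
    dropped: list = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        zq = stats.norm.ppf(0.5 + level / 2)
        se = self.se
        return pd.DataFrame({"low": self.params - zq * se,
                             "high": self.params + zq * se})

    def tidy(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame({
            "term": self.params.index,
            "estimate": self.params.to_numpy(),
            "se": self.se.to_numpy(),
            "ci_low": ci["low"].to_numpy(),
            "ci_high": ci["high"].to_numpy(),
            "n": self.nobs,
            "model": self.model,
        })


# ---------------------------------------------------------------------------
# Natural cubic spline basis
# ---------------------------------------------------------------------------

def natural_spline_basis(x, df: int = 2, knots=None):
    """Natural cubic spline basis (without intercept), ``df`` columns.

    Boundary knots sit at the min/max of ``x`` and ``df - 1`` interior
    knots at quantiles (the median for df=2). Using the truncated-power
    construction with knots xi_1 < ... < xi_K and
    ``d_k(x) = ((x - xi_k)_+^3 - (x - xi_K)_+^3) / (xi_K - xi_k)``,
    the basis is ``x, d_1 - d_{K-1}, ..., d_{K-2} - d_{K-1}`` — linear
    beyond the boundary knots (second and third derivatives vanish there).
    Returns ``(basis, knots)`` so a basis is reproducible at new points.
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        uniq = np.unique(x)
        if len(uniq) < 3:
            raise ValueError("need at least 3 distinct values to place knots")
        qs = np.linspace(0, 1, df + 1)[1:-1]
        interior = np.quantile(x, qs)
        knots = np.concatenate([[uniq[0]], np.atleast_1d(interior), [uniq[-1]]])
        knots = np.unique(knots)
        if len(knots) < 3:
            raise ValueError("degenerate knot sequence")
    knots = np.asarray(knots, dtype=float)
    K = len(knots)

    def d(k):
        return (np.clip(x - knots[k], 0, None) ** 3
                - np.clip(x - knots[K - 1], 0, None) ** 3) \
            / (knots[K - 1] - knots[k])

    cols = [x]
    dlast = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - dlast)
    # K knots always yield K - 1 basis columns (df columns when knots were
    # auto-placed from df)
    return np.column_stack(cols), knots


# ---------------------------------------------------------------------------
# WLS / 2SLS core
# ---------------------------------------------------------------------------

def _drop_collinear(X: pd.DataFrame, tol: float = 1e-8):
    """Remove linearly dependent columns, keeping the earliest occurrence.

    Greedy Gram-Schmidt in column order: a column is dropped when its
    residual after projection onto the already-kept columns is numerically
    null relative to its own scale."""
    A = X.to_numpy(dtype=float)
    n, k = A.shape
    if k == 0:
        return X, []
    kept: list[int] = []
    Q = np.empty((n, 0))
    for j in range(k):
        col = A[:, j]
        resid = col - Q @ (Q.T @ col) if Q.shape[1] else col.copy()
        norm = np.linalg.norm(resid)
        if norm > tol * max(np.linalg.norm(col), 1.0):
            kept.append(j)
            Q = np.column_stack([Q, resid / norm])
    dropped = [str(X.columns[j]) for j in range(k) if j not in kept]
    if dropped:
        log.warning("dropping collinear columns: %s", dropped)
    return X.iloc[:, kept], dropped


def _sandwich(A_inv: np.ndarray, scores: np.ndarray, n: int, k: int,
              cluster=None) -> np.ndarray:
    """Robust covariance: HC1-style, or cluster-summed scores (CR1)."""
    if cluster is None:
        meat = scores.T @ scores
        factor = n / max(n - k, 1)
    else:
        cl = pd.Series(np.asarray(cluster))
        grouped = pd.DataFrame(scores).groupby(cl.to_numpy()).sum().to_numpy()
        meat = grouped.T @ grouped
        G = grouped.shape[0]
        factor = (G / max(G - 1, 1)) * ((n - 1) / max(n - k, 1))
    return factor * A_inv @ meat @ A_inv


def fit_wls(y, X: pd.DataFrame, weights=None, cluster=None,
            model: str = "wls") -> ModelResult:
    """Weighted least squares with robust (sandwich) variance.

    Minimizes ``sum_i w_i (y_i - x_i' beta)^2``. Collinear columns are
    dropped with a logged warning. The default variance is an HC1-style
    sandwich with small-sample factor ``n/(n-k)``; when ``cluster`` ids are
    given, score contributions are summed within cluster (CR1).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be > 0")
    Xd, dropped = _drop_collinear(X)
    k = Xd.shape[1]
    if k == 0:
        raise ValueError("design matrix has no usable columns")
    sw = np.sqrt(w)
    Xw = Xd.to_numpy(dtype=float) * sw[:, None]
    yw = y * sw
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    A = Xw.T @ Xw
    try:
        A_inv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"rank-deficient design after dropping {dropped}") from exc
    resid = y - Xd.to_numpy(dtype=float) @ beta
    scores = Xd.to_numpy(dtype=float) * (w * resid)[:, None]
    cov = _sandwich(A_inv, scores, n, k, cluster)
    idx = Xd.columns
    return ModelResult(params=pd.Series(beta, index=idx),
                       cov=pd.DataFrame(cov, index=idx, columns=idx),
                       nobs=n, model=model, dropped=dropped)


def first_stage_partial_F(endog_j, instruments: pd.DataFrame,
                          exog: pd.DataFrame, weights=None) -> float:
    """Partial F for the excluded instruments in one first-stage regression.

    ``F = ((RSS_restricted - RSS_full) / q) / (RSS_full / (n - k_full))``
    from the weighted regression of the endogenous regressor on
    ``[instruments, exog]`` (full) versus ``exog`` alone (restricted).
    """
    q = instruments.shape[1]
    if q == 0:
        raise ValueError("no excluded instruments (q = 0)")
    y = np.asarray(endog_j, dtype=float)
    n = len(y)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    sw = np.sqrt(w)

    def rss(Xf):
        A = Xf.to_numpy(dtype=float) * sw[:, None]
        b, *_ = np.linalg.lstsq(A, y * sw, rcond=None)
        r = y * sw - A @ b
        return float(r @ r), A.shape[1]

    full = pd.concat([instruments, exog], axis=1)
    rss_f, k_full = rss(full)
    rss_r, _ = rss(exog) if exog.shape[1] else (float((y * sw) @ (y * sw)), 0)
    if rss_f <= 0:
        raise ValueError("zero first-stage residual variance")
    return ((rss_r - rss_f) / q) / (rss_f / (n - k_full))


def fit_iv2sls(y, endog: pd.DataFrame, instruments: pd.DataFrame,
               exog: pd.DataFrame, weights=None, cluster=None,
               model: str = "mr") -> ModelResult:
    """Weighted IV-2SLS with robust variance and first-stage diagnostics.

    With weighted design ``X = [endog, exog]`` and instrument set
    ``Z = [instruments, exog]``, the estimator projects X onto the column
    space of Z in the weighted metric and solves
    ``beta = (Xhat' X)^{-1} Xhat' y`` — identical to replacing the
    endogenous columns by their weighted first-stage fitted values. The
    sandwich uses second-stage residuals ``y - X beta`` (not residuals from
    the fitted-X design). Per-endogenous first-stage partial F statistics
    are attached.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if instruments.shape[1] < endog.shape[1]:
        raise ValueError("under-identified: fewer instruments than "
                         "endogenous regressors")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be > 0")
    exog_d, dropped = _drop_collinear(exog) if exog.shape[1] else (exog, [])
    X = pd.concat([endog, exog_d], axis=1)
    Z = pd.concat([instruments, exog_d], axis=1)
    sw = np.sqrt(w)
    Xw = X.to_numpy(dtype=float) * sw[:, None]
    Zw = Z.to_numpy(dtype=float) * sw[:, None]
    yw = y * sw
    # first stage: project Xw on col(Zw)
    gamma, *_ = np.linalg.lstsq(Zw, Xw, rcond=None)
    Xhat = Zw @ gamma
    A = Xhat.T @ Xw          # equals Xhat'Xhat up to numerical error
    try:
        A_inv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular 2SLS normal equations "
                         "(weak or collinear instruments)") from exc
    beta = A_inv @ (Xhat.T @ yw)
    resid_w = yw - Xw @ beta
    scores = Xhat * resid_w[:, None]
    k = X.shape[1]
    cov = _sandwich(A_inv, scores, n, k, cluster)
    f_stats = {}
    for col in endog.columns:
        f_stats[str(col)] = first_stage_partial_F(
            endog[col], instruments, exog_d, weights=w)
        if f_stats[str(col)] < 1e-6:
            raise ValueError(f"near-singular first stage for {col!r} "
                             f"(F = {f_stats[str(col)]:.2e})")
    idx = X.columns
    return ModelResult(params=pd.Series(beta, index=idx),
                       cov=pd.DataFrame(cov, index=idx, columns=idx),
                       nobs=n, model=model, first_stage_F=f_stats,
                       dropped=dropped)


# ---------------------------------------------------------------------------
# Cohort-level model builders
# ---------------------------------------------------------------------------

_CLASS_BASE = "managerial"
_PC_COLS = [f"pc{j}" for j in range(1, 11)]


def _age_tag(age: float) -> str:
    return f"{age:g}".replace(".", "_")


def covariate_frame(df: pd.DataFrame, age: float | None = None,
                    spline_knots=None) -> pd.DataFrame:
    """Assemble the standard covariate design: intercept, child sex, age
    spline (2 natural-spline columns, omitted when ``age`` is None, e.g.
    for birthweight), maternal age, maternal education, social-class
    indicators (base category 'managerial'), and 10 PCs."""
    out = pd.DataFrame(index=df.index)
    out["const"] = 1.0
    out["child_sex"] = df["child_sex"].astype(float)
    if age is not None:
        ages = df[f"age_{_age_tag(age)}"].to_numpy(dtype=float)
        basis, _ = natural_spline_basis(ages, df=2, knots=spline_knots)
        out["age_ns1"] = basis[:, 0]
        out["age_ns2"] = basis[:, 1]
    out["maternal_age"] = df["maternal_age"].astype(float)
    out["maternal_edu"] = df["maternal_edu"].astype(float)
    for cat in sorted(df["social_class"].unique()):
        if cat == _CLASS_BASE:
            continue
        out[f"class_{cat}"] = (df["social_class"] == cat).astype(float)
    for pc in _PC_COLS:
        if pc in df.columns:
            out[pc] = df[pc].astype(float)
    return out


def _analysis_subset(df: pd.DataFrame, needed: list[str],
                     age: float | None) -> pd.DataFrame:
    """Regression-specific complete cases; restrict to sweep participants."""
    sub = df
    if age is not None:
        part = f"part_{_age_tag(age)}"
        if part in df.columns:
            sub = sub[sub[part].astype(bool)]
    sub = sub.dropna(subset=[c for c in needed if c in sub.columns])
    if len(sub) == 0:
        raise ValueError("no complete cases for this model")
    return sub


def _weights_cluster(df, weight_col, cluster_col):
    w = df[weight_col].to_numpy(dtype=float) if weight_col else None
    cl = df[cluster_col].to_numpy() if cluster_col else None
    return w, cl


def fit_phenotypic_model(df: pd.DataFrame, outcome: str,
                         age: float | None = None, weight_col: str | None = None,
                         cluster_col: str | None = None) -> ModelResult:
    """Phenotypic multivariable WLS: outcome on both parents' self-reported
    BMI plus covariates, without the child PGI."""
    needed = [outcome, "bmi_mother_self", "bmi_father_self"]
    sub = _analysis_subset(df, needed, age)
    X = pd.concat([sub[["bmi_mother_self", "bmi_father_self"]],
                   covariate_frame(sub, age)], axis=1)
    w, cl = _weights_cluster(sub, weight_col, cluster_col)
    return fit_wls(sub[outcome], X, weights=w, cluster=cl, model="phenotypic")


def fit_trio_mr(df: pd.DataFrame, outcome: str, age: float | None = None,
                drop_father: bool = False, weight_col: str | None = None,
                cluster_col: str | None = None) -> ModelResult:
    """Trio (or duo) MR: parental self-reported BMI instrumented by the
    parental PGIs, conditioning on the child PGI and covariates.

    ``drop_father=True`` is the mother-offspring duo sensitivity model:
    father's BMI and PGI are omitted entirely, which leaves the estimator
    exposed to collider/assortment bias whenever the father has a nonzero
    nurture effect.
    """
    endog_cols = ["bmi_mother_self"] + ([] if drop_father else ["bmi_father_self"])
    inst_cols = ["pgi_mother"] + ([] if drop_father else ["pgi_father"])
    needed = [outcome, "pgi_child"] + endog_cols + inst_cols
    sub = _analysis_subset(df, needed, age)
    exog = pd.concat([sub[["pgi_child"]], covariate_frame(sub, age)], axis=1)
    w, cl = _weights_cluster(sub, weight_col, cluster_col)
    return fit_iv2sls(sub[outcome], sub[endog_cols], sub[inst_cols], exog,
                      weights=w, cluster=cl,
                      model="mr_duo" if drop_father else "mr")


def fit_pgi_model(df: pd.DataFrame, outcome: str, age: float | None = None,
                  weight_col: str | None = None,
                  cluster_col: str | None = None) -> ModelResult:
    """Three-PGI decomposition: outcome on mother's, father's and child's
    standardized PGIs plus covariates.

    ``extra['ratio_mother_child']`` is the mother/child coefficient ratio
    (indirect relative to direct genetic effect) with a delta-method SE;
    it is ``None`` when the child coefficient is numerically zero.
    """
    pgi_cols = ["pgi_mother", "pgi_father", "pgi_child"]
    sub = _analysis_subset(df, [outcome] + pgi_cols, age)
    X = pd.concat([sub[pgi_cols], covariate_frame(sub, age)], axis=1)
    w, cl = _weights_cluster(sub, weight_col, cluster_col)
    res = fit_wls(sub[outcome], X, weights=w, cluster=cl, model="pgi")
    a = res.params["pgi_mother"]
    b = res.params["pgi_child"]
    if abs(b) < 1e-10:
        res.extra["ratio_mother_child"] = None
        res.extra["ratio_se"] = None
    else:
        r = a / b
        va = res.cov.loc["pgi_mother", "pgi_mother"]
        vb = res.cov.loc["pgi_child", "pgi_child"]
        cab = res.cov.loc["pgi_mother", "pgi_child"]
        var_r = r ** 2 * (va / a ** 2 + vb / b ** 2 - 2 * cab / (a * b)) \
            if a != 0 else va / b ** 2
        res.extra["ratio_mother_child"] = float(r)
        res.extra["ratio_se"] = float(np.sqrt(max(var_r, 0.0)))
    return res


def fit_lpm(df: pd.DataFrame, outcome: str, age: float | None = None,
            mode: str = "phenotypic", weight_col: str | None = None,
            cluster_col: str | None = None) -> ModelResult:
    """Linear probability model for a dichotomized outcome.

    Same machinery as the phenotypic / MR fits; coefficients are
    probability differences per kg/m^2 of parental BMI.
    """
    vals = df[outcome].dropna().unique()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"outcome {outcome!r} must be binary 0/1")
    if mode == "phenotypic":
        res = fit_phenotypic_model(df, outcome, age, weight_col, cluster_col)
    elif mode == "mr":
        res = fit_trio_mr(df, outcome, age, weight_col=weight_col,
                          cluster_col=cluster_col)
    else:
        raise ValueError("mode must be 'phenotypic' or 'mr'")
    res.model = f"lpm_{mode}"
    return res
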