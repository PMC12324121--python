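"""Non-response weighting, survey rescaling bootstrap, and estimate contrasts.

Selection into a genotyped subsample (or continued participation) is rarely
random; inverse-probability weights from a logistic response model, combined
with the recruitment (design) weights, reweight responders back toward the
full cohort. Confidence intervals for contrasts between estimators fitted on
the same sample use the Rao-Wu rescaling bootstrap: within each stratum with
``n_h`` primary sampling units, ``n_h - 1`` clusters are resampled with
replacement per replicate and weights rescaled by ``n_h / (n_h - 1)`` times
the resampling multiplicity, which is valid under stratified multistage
designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WeightSet",
    "BootstrapResult",
    "logistic_fit",
    "estimate_response_weights",
    "rao_wu_bootstrap",
    "diff_z_test",
]


@dataclass
class WeightSet:
    """Design weights, estimated response probabilities, combined weights.

    ``combined`` is ``design / p_hat`` renormalized to mean 1 among
    responders (NaN for non-responders)."""

    design: np.ndarray
    p_hat: np.ndarray
    combined: np.ndarray
    normalization: float
    coef: pd.Series = field(default=None)


@dataclass
class BootstrapResult:
    """Replicate estimates of a scalar contrast with a percentile CI."""

    replicates: np.ndarray
    estimate: float
    ci_low: float
    ci_high: float
    se: float
    B: int
    n_strata: int
    seed: int | None = None


def logistic_fit(X: np.ndarray, y: np.ndarray, max_iter: int = 100,
                 tol: float = 1e-10) -> np.ndarray:
    """Unpenalized logistic regression by iteratively reweighted least
    squares. Raises on (quasi-)complete separation, which shows up as
    diverging coefficients / vanishing working weights."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        W = p * (1 - p)
        if np.max(np.abs(beta)) > 1e3 or np.all(W < 1e-10):
            raise ValueError("perfect separation in the response model; "
                             "reduce the covariate set")
        grad = X.T @ (y - p)
        H = (X * W[:, None]).T @ X
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(len(beta)), grad)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular response-model design") from exc
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            return beta
    if np.max(np.abs(beta)) > 1e3:
        raise ValueError("perfect separation in the response model; "
                         "reduce the covariate set")
    return beta


def estimate_response_weights(covariates: pd.DataFrame, response,
                              design_weights, p_floor: float = 0.02
                              ) -> WeightSet:
    """Inverse-probability non-response weights.

    Fits a logistic model of the boolean ``response`` flag on the baseline
    ``covariates`` (an intercept is added), floors the fitted probabilities
    at ``p_floor``, forms ``design / p_hat``, and renormalizes to mean 1
    among responders.
    """
    response = np.asarray(response, dtype=bool)
    design = np.asarray(design_weights, dtype=float)
    if np.any(design <= 0):
        raise ValueError("design weights must be > 0")
    if covariates.isna().any().any():
        raise ValueError("baseline covariates must be complete")
    X = np.column_stack([np.ones(len(response)),
                         covariates.to_numpy(dtype=float)])
    if response.all() or (~response).all():
        p_hat = np.full(len(response), response.mean())
        coef = pd.Series(0.0, index=["const"] + list(covariates.columns))
    else:
        beta = logistic_fit(X, response.astype(float))
        p_hat = 1.0 / (1.0 + np.exp(-np.clip(X @ beta, -35, 35)))
        coef = pd.Series(beta, index=["const"] + list(covariates.columns))
    p_hat = np.clip(p_hat, p_floor, 1.0)
    combined = np.where(response, design / p_hat, np.nan)
    norm = np.nanmean(combined)
    combined = combined / norm
    return WeightSet(design=design, p_hat=p_hat, combined=combined,
                     normalization=float(norm), coef=coef)


def rao_wu_bootstrap(weights, strata, clusters, contrast_fn, B: int = 500,
                     seed: int | None = None) -> BootstrapResult:
    """Rao-Wu rescaling bootstrap over primary sampling units.

    Per replicate and stratum with ``n_h`` clusters, ``n_h - 1`` clusters
    are drawn with replacement and each unit's weight is multiplied by
    ``n_h / (n_h - 1)`` times its cluster's resampling multiplicity (so
    replicate weights are unbiased for the originals). ``contrast_fn``
    receives the replicate weight vector and returns a scalar; the CI is
    the percentile interval of the replicates (endpoints are order
    statistics).
    """
    weights = np.asarray(weights, dtype=float)
    strata = np.asarray(strata)
    clusters = np.asarray(clusters)
    rng = np.random.default_rng(seed)
    strat_ids = np.unique(strata)
    layout = []
    for s in strat_ids:
        in_s = strata == s
        cl_ids = np.unique(clusters[in_s])
        if len(cl_ids) < 2:
            raise ValueError(f"stratum {s!r} has a single cluster; the "
                             "Rao-Wu bootstrap needs >= 2 PSUs per stratum")
        # map each unit to a within-stratum cluster index
        cl_index = {c: i for i, c in enumerate(cl_ids)}
        unit_cl = np.array([cl_index[c] for c in clusters[in_s]])
        layout.append((np.flatnonzero(in_s), unit_cl, len(cl_ids)))

    estimate = float(contrast_fn(weights))
    reps = np.empty(B)
    for b in range(B):
        mult = np.ones(len(weights))
        for idx, unit_cl, n_h in layout:
            draws = rng.integers(0, n_h, size=n_h - 1)
            counts = np.bincount(draws, minlength=n_h)
            mult[idx] = counts[unit_cl] * (n_h / (n_h - 1))
        reps[b] = contrast_fn(weights * mult)
    lo, hi = np.quantile(reps, [0.025, 0.975], method="closest_observation")
    return BootstrapResult(replicates=reps, estimate=estimate,
                           ci_low=float(lo), ci_high=float(hi),
                           se=float(np.std(reps, ddof=1)), B=B,
                           n_strata=len(strat_ids), seed=seed)


def diff_z_test(est1: float, se1: float, est2: float, se2: float,
                cov: float = 0.0) -> tuple[float, float]:
    """Two-sided z-test for ``est1 - est2``.

    ``z = (est1 - est2) / sqrt(se1^2 + se2^2 - 2 cov)``. When the two
    estimates come from the same sample and no covariance is supplied, the
    test ignores their (typically positive) correlation and is
    conservative for the difference; pass a bootstrap covariance when
    available.
    """
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be > 0")
    var = se1 ** 2 + se2 ** 2 - 2.0 * cov
    if var <= 0:
        raise ValueError("non-positive variance of the difference")
    z = (est1 - est2) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)
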