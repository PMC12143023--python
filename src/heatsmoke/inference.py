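"""Conditional-logistic interaction model and additive-interaction measures.

Fits, by full Newton–Raphson on the exact conditional likelihood, the
matched-set model

    logit Pr(case) = b0_i + bH * xHEAT + bS * xSMOKE + bHS * xHEAT * xSMOKE

where ``b0_i`` is the stratum intercept eliminated by conditioning on one
case per stratum.  From a converged fit it derives, at a smoke increment
``delta`` (ug/m3):

* OR01 = exp(bH)                 — extreme heat alone
* OR10 = exp(bS * delta)         — wildfire smoke alone
* OR11 = exp(bH + bS*delta + bHS*delta) — joint exposure
* multiplicative interaction = OR11 / (OR01 * OR10) = exp(bHS * delta)
* RERI = OR11 - OR10 - OR01 + 1  — relative excess risk due to interaction
* AP   = RERI / OR11             — attributable proportion due to interaction

Confidence intervals for the multiplicative measure are Wald on ``bHS``;
RERI and AP use the delta method (gradient of the measure with respect to
the three coefficients propagated through the fit covariance).  P-values
are two-sided normal, with the one-sided (synergy > 0) value also emitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StratumStructureError",
    "DegenerateDesignError",
    "SingularHessianError",
    "NonConvergedError",
    "FitResult",
    "EstimateCI",
    "InteractionEstimates",
    "conditional_loglik",
    "fit_clogit",
    "interaction_measures",
]

_TERMS = ("x_heat", "x_smoke", "x_heat:x_smoke")


class StratumStructureError(ValueError):
    """A stratum does not contain exactly one case row."""


class DegenerateDesignError(ValueError):
    """No informative stratum (all exposures constant within every stratum)."""


class SingularHessianError(np.linalg.LinAlgError):
    """The observed information is singular; names the collinear term."""


class NonConvergedError(RuntimeError):
    """Interaction measures were requested from a non-converged fit."""


@dataclass
class FitResult:
    beta: np.ndarray  # (bH, bS, bHS)
    covariance: np.ndarray  # 3x3 inverse observed information
    loglik: float
    converged: bool
    n_strata_used: int
    n_strata_dropped_noninformative: int
    n_iter: int = 0
    message: str = ""

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))


@dataclass
class EstimateCI:
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_two_sided: float
    p_one_sided: float


@dataclass
class InteractionEstimates:
    or01: EstimateCI
    or10: EstimateCI
    or11: EstimateCI
    multiplicative: EstimateCI
    reri: EstimateCI
    ap: EstimateCI
    delta: float = 1.0
    p_value_convention: str = "two-sided normal (one-sided also reported)"


def _pack(design: pd.DataFrame):
    """Sort a long design table into contiguous stratum blocks.

    Returns (X, starts, sizes, case_pos) where X is the n x 3 design matrix
    in sorted row order, ``starts``/``sizes`` delimit strata, and
    ``case_pos`` is the row index of each stratum's case.
    """
    df = design.sort_values("stratum_id", kind="stable")
    sid = df["stratum_id"].to_numpy()
    xh = df["x_heat"].to_numpy(dtype=float)
    xs = df["x_smoke"].to_numpy(dtype=float)
    X = np.column_stack([xh, xs, xh * xs])
    is_case = df["is_case"].to_numpy(dtype=bool)

    boundaries = np.flatnonzero(np.r_[True, sid[1:] != sid[:-1]])
    sizes = np.diff(np.r_[boundaries, len(sid)])
    cases_per = np.add.reduceat(is_case.astype(int), boundaries)
    if (cases_per != 1).any():
        bad = sid[boundaries[cases_per != 1]][:5]
        raise StratumStructureError(
            f"strata without exactly one case row: {bad.tolist()}"
        )
    case_pos = np.flatnonzero(is_case)
    return X, boundaries, sizes, case_pos, is_case


def _informative_mask(X: np.ndarray, starts: np.ndarray) -> np.ndarray:
    """Strata where (x_heat, x_smoke) is not identical across all rows."""
    mins = np.minimum.reduceat(X[:, :2], starts, axis=0)
    maxs = np.maximum.reduceat(X[:, :2], starts, axis=0)
    return (maxs != mins).any(axis=1)


def _loglik_parts(beta: np.ndarray, X: np.ndarray, starts: np.ndarray,
                  case_pos: np.ndarray):
    """Exact conditional log-likelihood with analytic gradient and Hessian.

    Per stratum: ll = eta_case - log sum_rows exp(eta_row); the gradient is
    x_case - E_w[x] and the Hessian is -Cov_w(x), with weights w the
    within-stratum softmax of eta.
    """
    eta = X @ beta
    m = np.maximum.reduceat(eta, starts)
    m_rep = np.repeat(m, np.diff(np.r_[starts, len(eta)]))
    ex = np.exp(eta - m_rep)
    denom = np.add.reduceat(ex, starts)
    ll = float(np.sum(eta[case_pos] - m - np.log(denom)))

    w = ex / np.repeat(denom, np.diff(np.r_[starts, len(eta)]))
    wX = w[:, None] * X
    Ex = np.add.reduceat(wX, starts, axis=0)  # (n_strata, 3)
    grad = X[case_pos].sum(axis=0) - Ex.sum(axis=0)

    # sum over strata of E[x x^T] - E[x] E[x]^T
    Exx = np.einsum("ij,ik->jk", wX, X)
    hess = -(Exx - Ex.T @ Ex)
    return ll, grad, hess


def conditional_loglik(beta, strata: pd.DataFrame):
    """Exact conditional log-likelihood of a design table at ``beta``.

    ``strata`` is a long design table with columns ``stratum_id, is_case,
    x_heat, x_smoke`` (one case per stratum).  Returns
    ``(loglik, gradient, hessian)``.  Strata whose rows all share identical
    exposures contribute a constant ``log(1/m)`` and zero gradient.
    """
    beta = np.asarray(beta, dtype=float)
    X, starts, sizes, case_pos, _ = _pack(strata)
    return _loglik_parts(beta, X, starts, case_pos)


def fit_clogit(
    strata: pd.DataFrame,
    max_iter: int = 50,
    grad_tol: float = 1e-8,
    rel_ll_tol: float = 1e-10,
    beta_bound: float = 30.0,
) -> FitResult:
    """Newton–Raphson maximization of the exact conditional likelihood.

    Starts at beta = 0 with step-halving on any log-likelihood decrease.
    Non-informative strata (constant exposures within the stratum) are
    dropped and counted.  Monotone likelihoods (complete or quasi-complete
    separation) are flagged as a non-converged result with a diagnostic
    message rather than allowed to diverge silently.
    """
    X, starts, sizes, case_pos, is_case = _pack(strata)
    keep = _informative_mask(X, starts)
    n_dropped = int((~keep).sum())
    if not keep.any():
        raise DegenerateDesignError(
            "all strata are non-informative (constant exposures within "
            "every stratum); the conditional likelihood carries no "
            "information about the coefficients"
        )
    if n_dropped:
        row_keep = np.repeat(keep, sizes)
        X = X[row_keep]
        is_case = is_case[row_keep]
        sizes = sizes[keep]
        starts = np.r_[0, np.cumsum(sizes)[:-1]]
        case_pos = np.flatnonzero(is_case)

    # structural identifiability: every term must vary within some stratum
    Xall = np.column_stack([X[:, 0], X[:, 1], X[:, 0] * X[:, 1]])
    col_varies = (
        np.maximum.reduceat(Xall, starts, axis=0)
        != np.minimum.reduceat(Xall, starts, axis=0)
    ).any(axis=0)
    if not col_varies.all():
        term = _TERMS[int(np.argmin(col_varies))]
        raise SingularHessianError(
            f"term has no within-stratum variation (structurally collinear "
            f"with the stratum intercepts): {term}"
        )

    beta = np.zeros(3)
    ll, grad, hess = _loglik_parts(beta, X, starts, case_pos)
    n_iter = 0
    converged = False
    message = ""
    for n_iter in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-hess, grad)
            if not np.all(np.isfinite(step)):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            if n_iter == 1:
                eigval, eigvec = np.linalg.eigh(-hess)
                term = _TERMS[int(np.argmax(np.abs(eigvec[:, np.argmin(eigval)])))]
                raise SingularHessianError(
                    f"singular observed information; collinear term: {term}"
                )
            # curvature vanished along the ascent path: monotone likelihood
            message = (
                "monotone likelihood: complete or quasi-complete separation "
                "suspected (information lost along the ascent path)"
            )
            break
        new_beta = beta + step
        new_ll, new_grad, new_hess = _loglik_parts(new_beta, X, starts, case_pos)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_hess = _loglik_parts(new_beta, X, starts, case_pos)
            halvings += 1
        rel_change = abs(new_ll - ll) / (abs(ll) + 1e-12)
        beta, grad, hess = new_beta, new_grad, new_hess
        ll_prev, ll = ll, new_ll
        if np.max(np.abs(beta)) > beta_bound:
            message = (
                "monotone likelihood: complete or quasi-complete separation "
                "suspected (coefficient escaping to infinity)"
            )
            break
        if np.max(np.abs(grad)) < grad_tol or rel_change < rel_ll_tol:
            converged = True
            break
    else:
        message = f"no convergence in {max_iter} iterations"

    # quasi-complete separation often satisfies the gradient tolerance at an
    # absurdly large coefficient (the softmax saturates); a log-odds ratio
    # beyond ~10 (OR > 2e4) is a monotone-likelihood signature, not a fit
    if converged and np.max(np.abs(beta)) > 10.0:
        converged = False
        message = (
            "monotone likelihood: complete or quasi-complete separation "
            f"suspected (|beta| = {np.max(np.abs(beta)):.1f})"
        )

    if converged:
        try:
            cov = np.linalg.inv(-hess)
        except np.linalg.LinAlgError:
            eigval, eigvec = np.linalg.eigh(-hess)
            term = _TERMS[int(np.argmax(np.abs(eigvec[:, np.argmin(eigval)])))]
            raise SingularHessianError(
                f"singular observed information at the optimum; collinear "
                f"term: {term}"
            )
    else:
        cov = np.full((3, 3), np.nan)
    return FitResult(
        beta=beta,
        covariance=cov,
        loglik=ll,
        converged=converged,
        n_strata_used=len(sizes),
        n_strata_dropped_noninformative=n_dropped,
        n_iter=n_iter,
        message=message,
    )


def _zstat(est: float, se: float) -> float:
    if se > 0:
        return est / se
    return 0.0 if est == 0 else float(np.inf) * (1 if est > 0 else -1)


def _wald(est_log: float, se_log: float, z: float = 1.959963984540054) -> EstimateCI:
    """CI and p for a log-scale estimate reported as a ratio."""
    zstat = _zstat(est_log, se_log)
    with np.errstate(over="ignore"):  # an unbounded CI limit serializes as inf
        lo, hi = np.exp(est_log - z * se_log), np.exp(est_log + z * se_log)
    return EstimateCI(
        estimate=float(np.exp(est_log)),
        se=float(se_log),
        ci_low=float(lo),
        ci_high=float(hi),
        p_two_sided=float(2 * stats.norm.sf(abs(zstat))),
        p_one_sided=float(stats.norm.sf(zstat)),
    )


def _linear(est: float, se: float, z: float = 1.959963984540054) -> EstimateCI:
    zstat = _zstat(est, se)
    return EstimateCI(
        estimate=float(est),
        se=float(se),
        ci_low=float(est - z * se),
        ci_high=float(est + z * se),
        p_two_sided=float(2 * stats.norm.sf(abs(zstat))),
        p_one_sided=float(stats.norm.sf(zstat)),
    )


def interaction_measures(fit: FitResult, delta: float = 1.0) -> InteractionEstimates:
    """Multiplicative and additive interaction measures from a converged fit.

    ``delta`` is the wildfire-smoke increment (ug/m3) defining the joint
    contrast; the primary analysis uses 1 ug/m3.  RERI and AP confidence
    intervals propagate the fit covariance through the measures' gradients
    (delta method); AP's interval is computed on AP's own gradient, not
    back-transformed from RERI.
    """
    if not fit.converged:
        raise NonConvergedError(
            f"refusing to compute interaction measures: {fit.message or 'fit did not converge'}"
        )
    bH, bS, bHS = fit.beta
    cov = fit.covariance

    a01 = np.array([1.0, 0.0, 0.0])
    a10 = np.array([0.0, delta, 0.0])
    a11 = np.array([1.0, delta, delta])
    amul = np.array([0.0, 0.0, delta])

    or01 = float(np.exp(a01 @ fit.beta))
    or10 = float(np.exp(a10 @ fit.beta))
    or11 = float(np.exp(a11 @ fit.beta))
    reri = or11 - or10 - or01 + 1.0
    ap = reri / or11

    # gradients with respect to (bH, bS, bHS)
    g_reri = or11 * a11 - or10 * a10 - or01 * a01
    se_reri = float(np.sqrt(g_reri @ cov @ g_reri))
    g_or11 = or11 * a11
    g_ap = (g_reri * or11 - reri * g_or11) / or11**2
    se_ap = float(np.sqrt(g_ap @ cov @ g_ap))

    return InteractionEstimates(
        or01=_wald(float(a01 @ fit.beta), float(np.sqrt(a01 @ cov @ a01))),
        or10=_wald(float(a10 @ fit.beta), float(np.sqrt(a10 @ cov @ a10))),
        or11=_wald(float(a11 @ fit.beta), float(np.sqrt(a11 @ cov @ a11))),
        multiplicative=_wald(float(amul @ fit.beta), float(np.sqrt(amul @ cov @ amul))),
        reri=_linear(reri, se_reri),
        ap=_linear(ap, se_ap),
        delta=delta,
    )
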