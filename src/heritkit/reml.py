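"""Multi-component restricted maximum likelihood for the MVN mixed model.

Model: ``y ~ N(X b, V)`` with ``V = sum_c sigma2_c K_c + sigma2_e I`` where
the K_c are kinship matrices.  The restricted log-likelihood (constants
dropped) is

    L_R = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ],
    P   = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1.

The score for variance parameter c (with K = I for the residual) is
``-1/2 [tr(P K_c) - y' P K_c P y]`` and the average-information matrix has
entries ``AI_cd = 1/2 y' P K_c P K_d P y``.  The optimizer takes AI steps
with step-halving, falling back to EM updates when an AI proposal leaves the
feasible region or fails to improve the likelihood.  Standard errors come
from the inverse AI matrix at the optimum.

Variance parameters are constrained non-negative by default (a small
positive floor keeps V positive definite); an unconstrained mode exists
because bounded fits distort the null distribution of likelihood-ratio
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .grm import KinshipMatrix


class REMLNumericalError(RuntimeError):
    """V became non-positive-definite along the accepted iteration path."""

    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []


@dataclass
class MixedModelSpec:
    """Phenotype, fixed-effect design and kinship components for one fit.

    ``y``, ``X`` and all component matrices must share one sample order;
    assembly from id-keyed containers is the caller's job (see
    :mod:`heritkit.herit_models`).
    """

    y: np.ndarray
    X: np.ndarray
    components: list[KinshipMatrix]
    constraint: bool = True

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=np.float64))
        n = self.y.size
        if self.X.shape[0] != n:
            raise ValueError("X rows do not match y length")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("fixed-effect design X is rank deficient")
        for K in self.components:
            if K.values.shape[0] != n:
                raise ValueError("component dimension does not match y")


@dataclass
class REMLFit:
    """Variance-component estimates with curvature-based standard errors."""

    sigma2: np.ndarray          # per-component variances, residual last
    se: np.ndarray
    loglik_restricted: float
    n_iter: int
    converged: bool
    fixed_effects: np.ndarray
    vc_cov: np.ndarray          # covariance of sigma2 (inverse AI)
    trace: list = field(default_factory=list)

    @property
    def sigma2_genetic(self) -> np.ndarray:
        return self.sigma2[:-1]

    @property
    def sigma2_residual(self) -> float:
        return float(self.sigma2[-1])


def _chol_V(theta, Ks, n):
    V = theta[-1] * np.eye(n)
    for t, K in zip(theta[:-1], Ks):
        V += t * K
    if not np.isfinite(V).all():
        raise np.linalg.LinAlgError("non-finite V")
    try:
        c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(str(exc)) from exc
    return c, low


def _loglik_only(theta, Ks, y, X):
    """Restricted log-likelihood via Cholesky solves on vectors only (no
    n x n inverse) — cheap enough for line searches."""
    n = y.size
    c, low = _chol_V(theta, Ks, n)
    logdet_V = 2.0 * np.log(np.diag(c)).sum()
    ViX = linalg.cho_solve((c, low), X, check_finite=False)
    Viy = linalg.cho_solve((c, low), y, check_finite=False)
    XtViX = X.T @ ViX
    cx = linalg.cho_factor(XtViX, check_finite=False)
    logdet_X = 2.0 * np.log(np.diag(cx[0])).sum()
    beta = linalg.cho_solve(cx, X.T @ Viy, check_finite=False)
    ypy = float(y @ Viy) - float((X.T @ Viy) @ beta)
    return -0.5 * (logdet_V + logdet_X + ypy)


def _reml_pieces(theta, Ks, y, X):
    """Full V^-1-based quantities for one parameter point.

    Returns (loglik, P, Py, beta) or raises np.linalg.LinAlgError when V is
    not positive definite.
    """
    n = y.size
    c, low = _chol_V(theta, Ks, n)
    logdet_V = 2.0 * np.log(np.diag(c)).sum()
    Vinv = linalg.cho_solve((c, low), np.eye(n), check_finite=False)
    W = Vinv @ X
    XtViX = X.T @ W
    cx = linalg.cho_factor(XtViX, check_finite=False)
    logdet_X = 2.0 * np.log(np.diag(cx[0])).sum()
    beta = linalg.cho_solve(cx, W.T @ y, check_finite=False)
    P = Vinv - W @ linalg.cho_solve(cx, W.T, check_finite=False)
    P = 0.5 * (P + P.T)
    Py = P @ y
    loglik = -0.5 * (logdet_V + logdet_X + float(y @ Py))
    return loglik, P, Py, beta


def _score_ai(theta, Ks, y, P, Py):
    """Analytic score vector and average-information matrix."""
    n = y.size
    C = len(Ks)
    PKPy = []
    for K in Ks:
        PKPy.append(P @ (K @ Py))
    PKPy.append(P @ Py)  # residual component, K = I
    score = np.empty(C + 1)
    for c in range(C):
        tr_PK = float(np.sum(P * Ks[c]))  # tr(P K), both symmetric
        score[c] = -0.5 * (tr_PK - float(Py @ (Ks[c] @ Py)))
    score[C] = -0.5 * (np.trace(P) - float(Py @ Py))
    AI = np.empty((C + 1, C + 1))
    KPy_list = [K @ Py for K in Ks] + [Py]
    for c in range(C + 1):
        for d in range(c, C + 1):
            AI[c, d] = AI[d, c] = 0.5 * float(KPy_list[c] @ PKPy[d])
    return score, AI


def _em_step(theta, Ks, y, P, Py):
    """One EM-REML update; always stays in the interior for PSD components."""
    n = y.size
    new = theta.copy()
    for c, K in enumerate(Ks):
        tr_PK = float(np.sum(P * K))
        new[c] = theta[c] + theta[c] ** 2 * (float(Py @ (K @ Py)) - tr_PK) / n
    new[-1] = theta[-1] + theta[-1] ** 2 * (float(Py @ Py) - np.trace(P)) / n
    return new


def fit_reml(spec: MixedModelSpec, tol: float = 1e-6,
             max_iter: int = 100, init: np.ndarray | None = None) -> REMLFit:
    """Fit variance components by AI-REML with EM fallback.

    Starts all components at ``var(y) / (C + 1)`` (or ``init`` when given),
    takes one EM step for stability, then AI updates with step-halving.
    Convergence is declared when the relative change of the restricted
    log-likelihood drops below ``tol``.  Non-convergence at ``max_iter``
    yields a flagged fit rather than an exception.
    """
    y, X = spec.y, spec.X
    Ks = [K.values for K in spec.components]
    C = len(Ks)
    n = y.size
    if n < C + 1 + X.shape[1] + 2:
        raise ValueError("too few samples for the number of parameters")
    vp = float(np.var(y, ddof=1))
    floor = 1e-6 * vp
    if init is not None:
        theta = np.asarray(init, dtype=np.float64).copy()
        if theta.size != C + 1:
            raise ValueError("init length must be n_components + 1")
        if spec.constraint:
            theta = np.maximum(theta, floor)
    else:
        theta = np.full(C + 1, vp / (C + 1))
    trace = []

    try:
        loglik, P, Py, beta = _reml_pieces(theta, Ks, y, X)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - start point is PD
        raise REMLNumericalError("V not positive definite at start", trace) from exc
    trace.append((0, loglik, theta.copy()))

    # one EM step first: robust far from the optimum
    theta_new = _em_step(theta, Ks, y, P, Py)
    if spec.constraint:
        theta_new = np.maximum(theta_new, floor)
    try:
        ll_new, P, Py, beta = _reml_pieces(theta_new, Ks, y, X)
        theta, loglik = theta_new, ll_new
    except np.linalg.LinAlgError:
        pass  # keep the starting point
    trace.append((1, loglik, theta.copy()))

    converged = False
    it = 1
    for it in range(2, max_iter + 1):
        score, AI = _score_ai(theta, Ks, y, P, Py)
        # active set: parameters pinned at the floor whose score points
        # further out stay frozen; the AI system is solved on the rest
        if spec.constraint:
            free = ~((theta <= floor * (1 + 1e-9)) & (score < 0))
        else:
            free = np.ones(theta.size, dtype=bool)
        delta = np.zeros(theta.size)
        if free.any():
            sub = np.ix_(free, free)
            try:
                delta[free] = np.linalg.solve(AI[sub], score[free])
            except np.linalg.LinAlgError:
                delta[free] = np.linalg.lstsq(AI[sub], score[free],
                                              rcond=None)[0]
        else:
            converged = True
            break

        # line search evaluates the cheap likelihood only
        cand, ll_cand = None, -np.inf
        step = 1.0
        for _ in range(8):
            trial = theta + step * delta
            if spec.constraint:
                trial = np.maximum(trial, floor)
            try:
                ll_trial = _loglik_only(trial, Ks, y, X)
            except np.linalg.LinAlgError:
                step *= 0.5
                continue
            if ll_trial >= loglik - 1e-10:
                cand, ll_cand = trial, ll_trial
                break
            step *= 0.5
        if cand is None:
            # AI direction failed entirely: fall back to EM
            cand = _em_step(theta, Ks, y, P, Py)
            if spec.constraint:
                cand = np.maximum(cand, floor)
            try:
                ll_cand = _loglik_only(cand, Ks, y, X)
            except np.linalg.LinAlgError as exc:
                raise REMLNumericalError(
                    "V not positive definite on EM fallback", trace) from exc
            if ll_cand < loglik - 1e-8:
                break  # no direction improves: current point is the optimum

        rel_change = abs(ll_cand - loglik) / (abs(loglik) + 1.0)
        param_change = np.max(np.abs(cand - theta)) / max(vp, 1e-12)
        try:
            _, P, Py, beta = _reml_pieces(cand, Ks, y, X)
        except np.linalg.LinAlgError as exc:
            raise REMLNumericalError(
                "V not positive definite at accepted point", trace) from exc
        theta, loglik = cand, ll_cand
        trace.append((it, loglik, theta.copy()))
        if rel_change < tol or param_change < 1e-8:
            converged = True
            break

    score, AI = _score_ai(theta, Ks, y, P, Py)
    try:
        vc_cov = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        vc_cov = np.linalg.pinv(AI)
    se = np.sqrt(np.maximum(np.diag(vc_cov), 0.0))
    return REMLFit(sigma2=theta, se=se, loglik_restricted=loglik,
                   n_iter=it, converged=converged, fixed_effects=beta,
                   vc_cov=vc_cov, trace=trace)


def restricted_loglik(theta, Ks, y, X) -> float:
    """Restricted log-likelihood at an arbitrary parameter point.

    Exposed for oracle-style grid evaluation and finite-difference checks.
    """
    theta = np.asarray(theta, dtype=np.float64)
    Kvals = [K.values if isinstance(K, KinshipMatrix) else np.asarray(K)
             for K in Ks]
    ll, _, _, _ = _reml_pieces(theta, Kvals, np.asarray(y, float),
                               np.atleast_2d(np.asarray(X, float)))
    return ll


def reml_score(theta, Ks, y, X) -> np.ndarray:
    """Analytic score vector at an arbitrary parameter point."""
    theta = np.asarray(theta, dtype=np.float64)
    Kvals = [K.values if isinstance(K, KinshipMatrix) else np.asarray(K)
             for K in Ks]
    y = np.asarray(y, float)
    _, P, Py, _ = _reml_pieces(theta, Kvals, y, np.atleast_2d(np.asarray(X, float)))
    score, _ = _score_ai(theta, Kvals, y, P, Py)
    return score


def lrt(fit_full: REMLFit, fit_null: REMLFit, df: int = 1,
        boundary_mixture: bool = False) -> float:
    """Likelihood-ratio p-value for nested REML fits.

    The statistic ``2 (L_full - L_null)`` is clamped at zero and referred to
    a chi-square with ``df`` degrees of freedom.  With
    ``boundary_mixture=True`` a 50:50 mixture of a point mass at zero and
    chi-square(df) is used instead, appropriate when the tested variance sits
    on the boundary of its parameter space; the plain chi-square is the
    default (conservative under the boundary).
    """
    stat = 2.0 * (fit_full.loglik_restricted - fit_null.loglik_restricted)
    if stat < -1e-3:
        import warnings
        warnings.warn(
            f"full-model log-likelihood below null by {-stat / 2:.3g}; "
            "optimizer likely failed, consider refitting", RuntimeWarning)
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df))
    if boundary_mixture:
        p = 0.5 * p if stat > 0 else 1.0
    return min(p, 1.0)


def h2_from_fit(fit: REMLFit) -> tuple[np.ndarray, np.ndarray]:
    """Variance proportions per genetic component with delta-method s.e.

    Proportion c is ``sigma2_c / sum(sigma2)``; the gradient
    ``d h_c / d theta_d = (delta_cd S - theta_c) / S^2`` propagates the
    variance-component covariance matrix.
    """
    theta = fit.sigma2
    S = float(theta.sum())
    if S <= 0:
        raise ValueError("total variance is non-positive; proportions undefined")
    C = theta.size - 1
    props = theta[:C] / S
    se = np.empty(C)
    for c in range(C):
        g = -theta[c] / S ** 2 * np.ones(theta.size)
        g[c] += 1.0 / S
        se[c] = np.sqrt(max(float(g @ fit.vc_cov @ g), 0.0))
    return props, se
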