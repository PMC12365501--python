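"""Per-protein REML estimation with ridge-as-random-effects and Huber
robustification.

The model is ``y = X beta + Z u + eps`` with ``u ~ N(0, sigma^2 D)`` and
``D = blockdiag(gamma_b I_qb)``: each block's variance is parameterized as
a ratio ``gamma_b = sigma_b^2 / sigma^2`` relative to the residual
variance.  Ridge-penalized terms are ordinary blocks of ``Z``; the implied
ridge penalty is ``lambda_b = 1 / gamma_b``, estimated by REML rather than
by cross-validation.

Estimation profiles ``sigma^2`` out of the restricted likelihood and
optimizes the log variance ratios with a bounded derivative-free search
(Brent for a single ratio, cyclic coordinate descent otherwise);
coefficients, BLUPs and their covariance come from the Henderson
mixed-model equations at the optimum.  Outliers are handled by iterated
Huber weighting of the observations (M-estimation), with the robust scale
re-estimated from the median absolute deviation each iteration.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .design import DesignMatrices, FitOptions, ModelSpec
from .errors import SingularFitError

_LOG_FLOOR_MARGIN = 1.0 + 1e-6  # "at the floor" tolerance on ratio scale


@dataclass
class ProteinFit:
    """Result of one per-protein mixed-model fit.

    ``coef`` stacks the fixed-effect estimates (BLUEs) and the penalized /
    random-effect predictions (BLUPs) in ``coef_names`` order.
    ``vcov_unscaled`` is the inverse of the mixed-model-equations
    coefficient matrix: multiplied by ``sigma2`` it gives the covariance
    of the fixed effects and the prediction error covariance of the BLUPs.
    ``varcomps`` maps each block label to its estimated variance ratio
    sigma_b^2/sigma^2.  ``df_res`` is the effective residual degrees of
    freedom (sum of weights minus the trace of the weighted hat matrix).
    """

    coef: np.ndarray
    coef_names: list
    vcov_unscaled: np.ndarray
    sigma2: float
    varcomps: dict
    df_res: float
    n_obs: int
    weights: np.ndarray
    status: str = "ok"
    message: str = ""
    reml_converged: bool = True
    singular_blocks: list = field(default_factory=list)
    dropped_reference: set = field(default_factory=set)

    def coef_by_name(self) -> dict:
        return dict(zip(self.coef_names, self.coef))


class _RemlProblem:
    """Sufficient statistics of one weighted REML problem.

    Caches ``A = T' W T``, ``rhs = T' W y`` and ``y' W y`` for
    ``T = [X | Z]`` so every criterion evaluation is a single Cholesky of
    the penalized coefficient matrix.
    """

    def __init__(self, y, dm: DesignMatrices, weights):
        self.y = np.asarray(y, float)
        self.w = np.ones_like(self.y) if weights is None \
            else np.asarray(weights, float)
        if (self.w < 0).any():
            raise ValueError("weights must be nonnegative")
        self.dm = dm
        self.T = dm.T
        Tw = self.T * self.w[:, None]
        self.A = Tw.T @ self.T
        self.rhs = Tw.T @ self.y
        self.yWy = float(np.dot(self.w * self.y, self.y))
        self.n = dm.n_obs
        self.p = dm.p_fixed
        # slices of the penalized columns and their sizes, in block order
        self.slices, self.q = [], []
        pos = self.p
        for b in dm.blocks:
            qb = b.matrix.shape[1]
            self.slices.append(slice(pos, pos + qb))
            self.q.append(qb)
            pos += qb
        self.dim = pos
        self.labels = [b.label for b in dm.blocks]

    def pen_vector(self, ratios: np.ndarray) -> np.ndarray:
        pen = np.zeros(self.dim)
        for sl, g in zip(self.slices, ratios):
            pen[sl] = 1.0 / g
        return pen

    def chol(self, ratios: np.ndarray):
        C = self.A.copy()
        idx = np.arange(self.dim)
        d = np.zeros(self.dim)
        for sl, g in zip(self.slices, ratios):
            d[sl] = 1.0 / g
        C[idx, idx] += d
        try:
            L = np.linalg.cholesky(C)
        except np.linalg.LinAlgError as exc:
            raise SingularFitError(
                f"mixed-model equations singular: {exc}"
            ) from exc
        return C, L

    def solve(self, ratios: np.ndarray):
        C, L = self.chol(ratios)
        z = np.linalg.solve(L, self.rhs)
        sol = np.linalg.solve(L.T, z)
        logdetC = 2.0 * float(np.sum(np.log(np.diag(L))))
        yPy = max(self.yWy - float(self.rhs @ sol), 1e-300)
        return C, L, sol, logdetC, yPy

    def criterion(self, log_ratios: np.ndarray) -> float:
        ratios = np.exp(np.asarray(log_ratios, float))
        try:
            _, _, _, logdetC, yPy = self.solve(ratios)
        except SingularFitError:
            return np.inf
        logdetD = float(np.dot(self.q, np.asarray(log_ratios, float)))
        return (self.n - self.p) * np.log(yPy) + logdetC + logdetD

    def criterion_and_grad(self, log_ratios: np.ndarray):
        """Profiled criterion with its analytic gradient in log ratios.

        d f / d theta_b = q_b - e^{-theta_b} [ (n-p) ||u_b||^2 / yPy
        + tr(C^-1)_bb ]: the stationary point is the classic REML
        fixed-point condition for each variance ratio.
        """
        logr = np.asarray(log_ratios, float)
        ratios = np.exp(logr)
        try:
            _, L, sol, logdetC, yPy = self.solve(ratios)
        except SingularFitError:
            return np.inf, np.zeros_like(logr)
        f = (self.n - self.p) * np.log(yPy) + logdetC \
            + float(np.dot(self.q, logr))
        Linv = np.linalg.inv(L)
        diag_cinv = np.einsum("ij,ij->j", Linv, Linv)
        grad = np.empty(len(self.labels))
        for b, sl in enumerate(self.slices):
            u2 = float(np.dot(sol[sl], sol[sl]))
            tr = float(np.sum(diag_cinv[sl]))
            grad[b] = self.q[b] - np.exp(-logr[b]) * (
                (self.n - self.p) * u2 / yPy + tr
            )
        return f, grad


def reml_criterion(y, dm: DesignMatrices, weights, ratios: dict) -> float:
    """Minus twice the profiled restricted log-likelihood, up to a
    constant not depending on the variance ratios.

    Exposed so the attained optimum can be probed against arbitrary
    ratio values.
    """
    prob = _RemlProblem(y, dm, weights)
    logr = np.log([ratios[lab] for lab in prob.labels])
    return prob.criterion(logr)


def effective_df(cinv: np.ndarray, pen: np.ndarray, sum_w: float,
                 n_obs: int) -> float:
    """Effective residual df: sum of weights minus the hat-matrix trace.

    For the weighted mixed-model fit the trace of the hat matrix equals
    ``(p + q) - trace(C^-1 diag(pen))``; an unshrunk block contributes its
    full column count, a block shrunk to nothing contributes ~0, so plain
    regression recovers ``n - p`` exactly.  Clipped to ``[1, n_obs - 1]``.
    """
    tr_hat = len(pen) - float(np.sum(np.diag(cinv) * pen))
    return float(np.clip(sum_w - tr_hat, 1.0, max(n_obs - 1.0, 1.0)))


def _optimize_ratios(prob, free: list, lo: float, hi: float,
                     opts: FitOptions, x0: np.ndarray | None):
    """Minimize the profiled REML criterion over the free log ratios.

    Bounded L-BFGS with the analytic gradient, warm started from ``x0``
    when the robustness loop refits; a bounded Brent search seeds the
    single-ratio case when no warm start is available (the profiled
    criterion can have a boundary optimum that gradient descent from an
    arbitrary start would miss).
    """
    nfree = len(free)
    if nfree == 0:
        return np.array([]), True

    if x0 is None and nfree == 1:
        res0 = minimize_scalar(lambda v: prob.criterion(np.array([v])),
                               bounds=(lo, hi), method="bounded",
                               options={"xatol": 1e-4,
                                        "maxiter": opts.max_reml_iter})
        x0 = np.array([res0.x])
    x0 = np.zeros(nfree) if x0 is None else np.clip(x0, lo, hi)
    res = minimize(prob.criterion_and_grad, x0=x0, jac=True,
                   method="L-BFGS-B", bounds=[(lo, hi)] * nfree,
                   options={"maxiter": opts.max_reml_iter,
                            "ftol": 1e-14, "gtol": 1e-10})
    x, f = np.clip(res.x, lo, hi), res.fun
    # guard against a poor line search: never return worse than the start
    f0 = prob.criterion(x0)
    if f0 < f:
        x, f = x0, f0
    x = _newton_polish(prob, x, lo, hi)
    return x, bool(res.success)


def _newton_polish(prob, x: np.ndarray, lo: float, hi: float,
                   max_iter: int = 6) -> np.ndarray:
    """Drive the analytic gradient to ~0 for interior coordinates.

    Quasi-Newton methods stop on flat stretches of the profiled
    criterion well before the gradient vanishes; a few Newton steps with
    a finite-difference Jacobian of the exact gradient recover the
    stationary point to near machine precision, which the closed-form
    equivalences (OLS, ANOVA estimators) rely on.
    """
    h = 1e-5
    _, g = prob.criterion_and_grad(x)
    for _ in range(max_iter):
        interior = (x > lo + 1e-8) & (x < hi - 1e-8)
        gi = g[interior]
        if gi.size == 0 or np.max(np.abs(gi)) < 1e-10:
            break
        idx = np.flatnonzero(interior)
        J = np.empty((len(idx), len(idx)))
        for c, j in enumerate(idx):
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            _, gp = prob.criterion_and_grad(xp)
            _, gm = prob.criterion_and_grad(xm)
            J[:, c] = (gp[idx] - gm[idx]) / (2 * h)
        try:
            step = np.linalg.solve(J, gi)
        except np.linalg.LinAlgError:
            break
        step = np.clip(step, -1.0, 1.0)
        xn = x.copy()
        xn[idx] = np.clip(x[idx] - step, lo, hi)
        fn, gn = prob.criterion_and_grad(xn)
        # the criterion itself is only reproducible to ~1e-10, so step
        # acceptance must go by the (analytic) gradient norm
        if not np.isfinite(fn) or \
                np.max(np.abs(gn[idx])) >= np.max(np.abs(gi)):
            break
        x, g = xn, gn
    return x


def fit_reml(
    y,
    dm: DesignMatrices,
    weights=None,
    opts: FitOptions | None = None,
    pin_ratios: dict | None = None,
    start_ratios: dict | None = None,
) -> ProteinFit:
    """REML fit of the mixed model for one response vector.

    Variance ratios are optimized on log scale within
    ``[varcomp_floor, varcomp_ceiling]``; ratios listed in ``pin_ratios``
    are held fixed (used to impose a known ridge penalty);
    ``start_ratios`` warm-starts the search.  The fit is deterministic
    given its inputs.
    """
    opts = opts or FitOptions()
    prob = _RemlProblem(y, dm, weights)
    pin_ratios = dict(pin_ratios or {})
    free = [i for i, lab in enumerate(prob.labels) if lab not in pin_ratios]
    lo, hi = np.log(opts.varcomp_floor), np.log(opts.varcomp_ceiling)

    logr = np.zeros(len(prob.labels))
    for i, lab in enumerate(prob.labels):
        if lab in pin_ratios:
            logr[i] = np.log(pin_ratios[lab])

    converged = True
    if free:
        if prob.n <= prob.p:
            raise SingularFitError(
                f"cannot estimate variance components with "
                f"n={prob.n} <= p={prob.p}"
            )
        fixed_logr = logr.copy()
        x0 = None
        if start_ratios:
            x0 = np.array([np.log(start_ratios.get(prob.labels[i], 1.0))
                           for i in free])

        def full_from_free(log_free):
            lr = fixed_logr.copy()
            lr[free] = np.atleast_1d(log_free)
            return lr

        class _SubProblem:
            """View of the problem over the free coordinates only."""
            labels = [prob.labels[i] for i in free]

            @staticmethod
            def criterion(log_free):
                return prob.criterion(full_from_free(log_free))

            @staticmethod
            def criterion_and_grad(log_free):
                f, g = prob.criterion_and_grad(full_from_free(log_free))
                return f, g[free]

        x_opt, converged = _optimize_ratios(_SubProblem(),
                                            list(range(len(free))),
                                            lo, hi, opts, x0)
        logr = full_from_free(x_opt)

    ratios = np.exp(logr)
    C, L, sol, _, yPy = prob.solve(ratios)
    Linv = np.linalg.inv(L)
    cinv = Linv.T @ Linv
    cinv = (cinv + cinv.T) / 2.0
    dof = prob.n - prob.p
    sigma2 = yPy / dof if dof > 0 else np.nan
    pen = prob.pen_vector(ratios)
    df_res = effective_df(cinv, pen, float(np.sum(prob.w)), prob.n)
    ratio_map = dict(zip(prob.labels, (float(g) for g in ratios)))
    singular = [lab for lab, g in ratio_map.items()
                if lab not in pin_ratios
                and g <= opts.varcomp_floor * _LOG_FLOOR_MARGIN]
    return ProteinFit(
        coef=sol, coef_names=list(dm.coef_names), vcov_unscaled=cinv,
        sigma2=float(sigma2), varcomps=ratio_map, df_res=df_res, n_obs=prob.n,
        weights=prob.w, status="ok",
        message="" if converged else "REML iteration limit reached",
        reml_converged=converged, singular_blocks=singular,
        dropped_reference=set(dm.dropped_reference),
    )


def huber_weights(resid: np.ndarray, k: float) -> np.ndarray:
    """min(1, k/|r/s|) with s the MAD-based robust scale of the residuals."""
    med = np.median(resid)
    scale = 1.4826 * np.median(np.abs(resid - med))
    if scale <= 0:
        return np.ones_like(resid)
    std = np.abs(resid) / scale
    with np.errstate(divide="ignore"):
        w = np.minimum(1.0, k / std)
    w[std == 0] = 1.0
    return w


def fit_robust_ridge(
    y,
    dm: DesignMatrices,
    spec: ModelSpec | None = None,
    opts: FitOptions | None = None,
    robust: bool | None = None,
    pin_ratios: dict | None = None,
) -> ProteinFit:
    """Robust (Huber IRLS) ridge REML fit.

    Each iteration refits the REML model under the current observation
    weights, standardizes the conditional residuals by a MAD-based robust
    scale, and recomputes Huber weights; iteration stops when the largest
    coefficient change drops below ``irls_tol``.  When all standardized
    residuals sit inside the Huber identity region the weights are all one
    and the result coincides with the plain REML fit.  With ``robust``
    off this is a single REML fit.
    """
    if robust is None:
        robust = spec.robust if spec is not None else True
    opts = opts or (spec.options if spec is not None else FitOptions())
    y = np.asarray(y, float)
    T = dm.T
    fit = fit_reml(y, dm, weights=None, opts=opts, pin_ratios=pin_ratios)
    if not robust:
        return fit
    for _ in range(opts.max_irls_iter):
        resid = y - T @ fit.coef
        w_new = huber_weights(resid, opts.huber_k)
        if np.allclose(w_new, fit.weights, atol=1e-12):
            break
        new = fit_reml(y, dm, weights=w_new, opts=opts,
                       pin_ratios=pin_ratios, start_ratios=fit.varcomps)
        delta = float(np.max(np.abs(new.coef - fit.coef)))
        fit = new
        if delta < opts.irls_tol:
            break
    return fit
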