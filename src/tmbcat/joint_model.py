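"""Joint modeling of tumor response and time-to-event endpoints.

The two immunotherapy endpoints of one patient are linked through
correlated patient-level random effects:

* response submodel: ``R_i ~ Bernoulli(expit(b0 + b1*tmb_i + u_i))``
* hazard submodel:   ``h_i(t) = h0(t) * exp(alpha*tmb_i + v_i)`` (Cox,
  Breslow ties, Breslow baseline)
* ``(u_i, v_i)`` bivariate normal with covariance ``Sigma``.

Because each patient contributes a single Bernoulli draw and a single
(possibly censored) time, the full bivariate pair is weakly identified;
the default parameterization shares one effect, ``v_i = gamma * u_i``
with ``u_i ~ N(0, sigma_u^2)`` and ``gamma`` estimated (``rho`` is then
``sign(gamma)``).  The full bivariate structure remains available via
``FitOptions(random_effects="bivariate")``.

Estimation maximizes the Laplace-approximate marginal likelihood: an
inner damped-Newton solve yields the posterior modes of the random
effects for the penalized joint log-likelihood (logistic log-likelihood
+ Cox partial log-likelihood with Breslow ties + Gaussian penalty), and
the outer quasi-Newton loop updates fixed effects, loading and
log-variance against that profile plus the curvature (log-determinant)
adjustment — the REML-type correction that also keeps the loading
identified.  A parsimony rule collapses the random-effect structure to
the variance floor when its likelihood gain is smaller than its
parameter count.

The per-patient joint favorable-prognosis probability
``Pr(R_i = 1, T_i* > T0)`` is exposed in three modes:

``integrate``
    marginal over the random-effect distribution by Gauss-Hermite
    quadrature; a deterministic function of TMB, guaranteed in [0, 1].
``plugin``
    the literal product of the two component probabilities at the
    empirical-Bayes modes times the random-effect density factor; may
    exceed 1 and is intended for rank-based metrics only.
``eb``
    product of the two component probabilities at the empirical-Bayes
    modes (no density factor); patient-specific, in [0, 1].  This is the
    pipeline default: it carries the patient's own endpoint information,
    which between-group testing requires.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .data_model import Cohort, PatientRecord

__all__ = [
    "FitOptions",
    "JointModelFit",
    "JointProbability",
    "JointModelError",
    "SeparationError",
    "fit_joint_model",
    "joint_probability",
    "joint_probabilities",
]


class JointModelError(RuntimeError):
    """Raised when the joint model cannot be fitted."""


class SeparationError(JointModelError):
    """Complete separation in the response submodel."""


@dataclass(frozen=True)
class FitOptions:
    """Fitting options for :func:`fit_joint_model`.

    tol: relative-change tolerance for the outer variance-component loop.
    ridge_floor: lower bound on the random-effect variance(s).
    random_effects: "shared" (default, v = gamma*u), "bivariate", "none".
    """

    tol: float = 1e-6
    max_iter: int = 200
    ridge_floor: float = 1e-6
    random_effects: str = "shared"
    sigma0: float = 0.25
    quad_nodes: int = 15
    warn_small_n: int = 20
    #: collapse the random-effect structure to the variance floor when its
    #: marginal log-likelihood gain is below one point per extra parameter
    #: (AIC-style parsimony; set to None to disable)
    parsimony: bool = True

    def __post_init__(self) -> None:
        if self.random_effects not in ("shared", "bivariate", "none"):
            raise ValueError(f"unknown random_effects {self.random_effects!r}")


# --------------------------------------------------------------------------
# Cox partial-likelihood machinery (Breslow ties), O(n log n) per evaluation
# --------------------------------------------------------------------------
class _CoxCache:
    """Precomputed ordering/tie structure for repeated partial-likelihood
    evaluations on fixed ``(T, delta)``."""

    def __init__(self, T: np.ndarray, delta: np.ndarray):
        self.order = np.argsort(T, kind="stable")
        self.T_sorted = T[self.order]
        self.delta_sorted = delta[self.order]
        self.uniq_times, self.group_start = np.unique(self.T_sorted, return_index=True)
        self.pos_group = np.searchsorted(self.uniq_times, self.T_sorted)
        self.d = np.add.reduceat(self.delta_sorted, self.group_start)
        self.n = len(T)

    def parts(self, psi: np.ndarray):
        """Return (loglik, grad wrt psi, exp(psi)*H, curvature diag Q,
        baseline increments) in original patient order."""
        psi_s = np.clip(psi[self.order], -40.0, 40.0)
        w = np.exp(psi_s)
        s0_pos = np.cumsum(w[::-1])[::-1]
        s0 = s0_pos[self.group_start]  # risk-set sum at each unique time
        with np.errstate(divide="ignore"):
            log_s0 = np.log(s0)
        ll = float(self.delta_sorted @ psi_s - self.d @ log_s0)
        h = np.where(self.d > 0, self.d / s0, 0.0)  # Breslow increments
        H_i = np.cumsum(h)[self.pos_group]
        G_i = np.cumsum(np.where(self.d > 0, self.d / s0**2, 0.0))[self.pos_group]
        grad_s = self.delta_sorted - w * H_i
        Q_s = np.clip(w * H_i - w**2 * G_i, 0.0, None)  # info diag, psd

        inv = np.empty_like(self.order)
        inv[self.order] = np.arange(self.n)
        return ll, grad_s[inv], (w * H_i)[inv], Q_s[inv], h

    def baseline(self, psi: np.ndarray):
        """Breslow baseline cumulative hazard step function."""
        _, _, _, _, h = self.parts(psi)
        mask = self.d > 0
        return self.uniq_times[mask], np.cumsum(h[mask])


@dataclass
class BaselineHazard:
    """Step-function baseline cumulative hazard H0 (Breslow estimator)."""

    times: np.ndarray
    values: np.ndarray  # cumulative, same length as times

    def __call__(self, t: float | np.ndarray, warn_beyond: bool = False):
        t = np.asarray(t, dtype=float)
        if warn_beyond and np.any(t > self.times[-1]):
            warnings.warn(
                "T0 beyond the last observed event time; using the last "
                "baseline-hazard step",
                stacklevel=3,
            )
        idx = np.searchsorted(self.times, t, side="right")
        vals = np.concatenate([[0.0], self.values])
        return vals[idx]


@dataclass
class JointModelFit:
    """Fitted joint response/survival model.

    ``beta`` holds (intercept, TMB slope) of the response submodel;
    ``alpha`` the hazard-submodel TMB coefficient; ``gamma`` the shared
    random-effect loading (``v = gamma * u``); ``Sigma`` the implied 2x2
    random-effect covariance.  ``u_hat``/``v_hat`` are empirical-Bayes
    posterior modes per patient.
    """

    beta: np.ndarray
    alpha: float
    gamma: float
    Sigma: np.ndarray
    u_hat: np.ndarray
    v_hat: np.ndarray
    H0: BaselineHazard
    converged: bool
    loglik: float
    loglik_trace: np.ndarray
    n_iter: int
    ids: np.ndarray
    tmb: np.ndarray
    T_median: float
    random_effects: str
    method: str = "naive"
    quad_nodes: int = 15

    @property
    def sigma_u2(self) -> float:
        return float(self.Sigma[0, 0])

    @property
    def rho(self) -> float:
        su, sv = np.sqrt(self.Sigma[0, 0]), np.sqrt(self.Sigma[1, 1])
        if su * sv < 1e-12:
            return 0.0
        return float(self.Sigma[0, 1] / (su * sv))

    def linear_predictors(self, tmb, u=None, v=None):
        tmb = np.asarray(tmb, dtype=float)
        u = 0.0 if u is None else u
        v = 0.0 if v is None else v
        eta = self.beta[0] + self.beta[1] * tmb + u
        psi = self.alpha * tmb + v
        return eta, psi

    def index_of(self, patient_id: str) -> int:
        hits = np.nonzero(self.ids == patient_id)[0]
        if len(hits) == 0:
            raise JointModelError(
                f"patient {patient_id!r} was not in the fitted cohort; "
                "plugin/eb probabilities need the fitted empirical-Bayes effects"
            )
        return int(hits[0])

    # serialization --------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "beta": self.beta.tolist(),
            "alpha": self.alpha,
            "gamma": self.gamma,
            "Sigma": self.Sigma.tolist(),
            "u_hat": self.u_hat.tolist(),
            "v_hat": self.v_hat.tolist(),
            "H0_times": self.H0.times.tolist(),
            "H0_values": self.H0.values.tolist(),
            "converged": self.converged,
            "loglik": self.loglik,
            "n_iter": self.n_iter,
            "ids": self.ids.tolist(),
            "tmb": self.tmb.tolist(),
            "T_median": self.T_median,
            "random_effects": self.random_effects,
            "method": self.method,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "JointModelFit":
        return cls(
            beta=np.asarray(d["beta"], dtype=float),
            alpha=float(d["alpha"]),
            gamma=float(d["gamma"]),
            Sigma=np.asarray(d["Sigma"], dtype=float),
            u_hat=np.asarray(d["u_hat"], dtype=float),
            v_hat=np.asarray(d["v_hat"], dtype=float),
            H0=BaselineHazard(
                np.asarray(d["H0_times"], dtype=float),
                np.asarray(d["H0_values"], dtype=float),
            ),
            converged=bool(d["converged"]),
            loglik=float(d["loglik"]),
            loglik_trace=np.array([]),
            n_iter=int(d["n_iter"]),
            ids=np.asarray(d["ids"], dtype=object),
            tmb=np.asarray(d["tmb"], dtype=float),
            T_median=float(d["T_median"]),
            random_effects=str(d["random_effects"]),
            method=str(d["method"]),
        )

    @classmethod
    def load(cls, path) -> "JointModelFit":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class JointProbability:
    """Per-patient joint favorable-prognosis probability.

    ``p`` is the scalar joint probability; ``p_R``/``p_T`` the component
    (response / survival-past-T0) probabilities used by the weighted
    two-dimensional form ``[w1*p_R, w2*p_T]``.
    """

    p: float
    p_R: float
    p_T: float
    T0: float
    mode: str
    weights: tuple[float, float] = (1.0, 1.0)

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.weights[0] * self.p_R, self.weights[1] * self.p_T])


# --------------------------------------------------------------------------
# penalized likelihood pieces
# --------------------------------------------------------------------------
def _pen_loglik_shared(a, x, R, cox: _CoxCache, b0, b1, al, ga, sig2):
    """Penalized joint log-likelihood and parts, as a function of the
    shared random effects ``a`` (fixed effects held fixed)."""
    eta = b0 + b1 * x + a
    psi = al * x + ga * a
    ll_R = float(R @ eta - np.logaddexp(0.0, eta).sum())
    mu = expit(eta)
    ll_T, g_psi, _, Q, _ = cox.parts(psi)
    pen = 0.5 * float(a @ a) / sig2
    grad = (R - mu) + ga * g_psi - a / sig2
    hess_diag = mu * (1 - mu) + ga**2 * Q + 1.0 / sig2
    return ll_R + ll_T - pen, grad, hess_diag, mu, Q


def _solve_modes_shared(x, R, cox, b0, b1, al, ga, sig2, a0, tol=1e-9, max_iter=100):
    """Posterior modes of the shared random effects by damped Newton with
    the diagonal curvature (the objective is strictly concave in ``a``)."""
    a = a0.copy()
    f, g, h, mu, Q = _pen_loglik_shared(a, x, R, cox, b0, b1, al, ga, sig2)
    for _ in range(max_iter):
        if np.max(np.abs(g)) < tol * (1 + abs(f)):
            break
        step = g / h
        t = 1.0
        for _ in range(30):
            f_new, g_new, h_new, mu, Q = _pen_loglik_shared(
                a + t * step, x, R, cox, b0, b1, al, ga, sig2
            )
            if f_new >= f - 1e-12:
                break
            t *= 0.5
        a = a + t * step
        f, g, h = f_new, g_new, h_new
    return a, f, h, mu, Q


def _laplace_nll_shared(phi, x, R, cox, state):
    """Negative Laplace-approximate marginal log-likelihood.

    ``phi = (b0, b1, alpha, gamma, log sigma_u^2)``; the random-effect
    modes are profiled out by an inner Newton solve (warm-started via
    ``state``).  The Laplace curvature term -(1/2) sum log(1 +
    sigma^2 * (W_i + gamma^2 Q_i)) keeps the loading identified (the
    penalized likelihood alone is unbounded along gamma -> inf, u -> 0).
    """
    b0, b1, al, ga, ls2 = phi
    sig2 = np.exp(ls2)
    a, f, h, mu, Q = _solve_modes_shared(
        x, R, cox, b0, b1, al, ga, sig2, state["a"]
    )
    state["a"] = a
    lap = -0.5 * float(np.sum(np.log1p(sig2 * (mu * (1 - mu) + ga**2 * Q))))
    return -(f + lap)


def _pen_loglik_biv(u, v, x, R, cox: _CoxCache, b0, b1, al, P):
    eta = b0 + b1 * x + u
    psi = al * x + v
    ll_R = float(R @ eta - np.logaddexp(0.0, eta).sum())
    mu = expit(eta)
    ll_T, g_psi, _, Q, _ = cox.parts(psi)
    pen = 0.5 * float(P[0, 0] * (u @ u) + 2 * P[0, 1] * (u @ v) + P[1, 1] * (v @ v))
    g_u = (R - mu) - P[0, 0] * u - P[0, 1] * v
    g_v = g_psi - P[0, 1] * u - P[1, 1] * v
    W = mu * (1 - mu)
    return ll_R + ll_T - pen, g_u, g_v, W, Q


def _solve_modes_biv(x, R, cox, b0, b1, al, P, u0, v0, tol=1e-9, max_iter=100):
    """Posterior modes of (u_i, v_i) by damped Newton on per-patient
    2x2 curvature blocks."""
    u, v = u0.copy(), v0.copy()
    f, g_u, g_v, W, Q = _pen_loglik_biv(u, v, x, R, cox, b0, b1, al, P)
    for _ in range(max_iter):
        if max(np.max(np.abs(g_u)), np.max(np.abs(g_v))) < tol * (1 + abs(f)):
            break
        m00 = W + P[0, 0]
        m01 = P[0, 1]
        m11 = Q + P[1, 1]
        det = m00 * m11 - m01**2
        du = (m11 * g_u - m01 * g_v) / det
        dv = (m00 * g_v - m01 * g_u) / det
        t = 1.0
        for _ in range(30):
            f_new, gu_new, gv_new, W, Q = _pen_loglik_biv(
                u + t * du, v + t * dv, x, R, cox, b0, b1, al, P
            )
            if f_new >= f - 1e-12:
                break
            t *= 0.5
        u, v = u + t * du, v + t * dv
        f, g_u, g_v = f_new, gu_new, gv_new
    return u, v, f, W, Q


def _laplace_nll_biv(phi, x, R, cox, state):
    """Negative Laplace marginal log-likelihood for the bivariate option.

    ``phi = (b0, b1, alpha, log su2, log sv2, atanh rho)``.
    """
    b0, b1, al, lsu, lsv, zr = phi
    su2, sv2 = np.exp(lsu), np.exp(lsv)
    rho = np.tanh(zr)
    S = np.array(
        [[su2, rho * np.sqrt(su2 * sv2)], [rho * np.sqrt(su2 * sv2), sv2]]
    )
    P = np.linalg.inv(S)
    u, v, f, W, Q = _solve_modes_biv(
        x, R, cox, b0, b1, al, P, state["u"], state["v"]
    )
    state["u"], state["v"] = u, v
    # det(I + Sigma H_i) with H_i = diag(W_i, Q_i)
    det = (1 + S[0, 0] * W) * (1 + S[1, 1] * Q) - S[0, 1] ** 2 * W * Q
    lap = -0.5 * float(np.sum(np.log(np.clip(det, 1e-300, None))))
    return -(f + lap)


def _nll_fixed(theta, x, R, cox: _CoxCache):
    b0, b1, al = theta
    eta = b0 + b1 * x
    psi = al * x
    ll_R = float(R @ eta - np.logaddexp(0.0, eta).sum())
    mu = expit(eta)
    ll_T, g_psi, _, _, _ = cox.parts(psi)
    gR = R - mu
    return -(ll_R + ll_T), np.array([-gR.sum(), -(gR @ x), -(g_psi @ x)])


def _check_inputs(cohort: Cohort, options: FitOptions) -> None:
    R, delta, x = cohort.R, cohort.delta, cohort.tmb
    if cohort.n < options.warn_small_n:
        warnings.warn(
            f"n = {cohort.n} < {options.warn_small_n}: joint-model estimates "
            "will be unstable",
            stacklevel=3,
        )
    if delta.sum() < 1:
        raise JointModelError("at least one observed event is required")
    if R.min() == R.max():
        raise SeparationError(
            "all responses identical: the response submodel is completely "
            "separated; consider a penalized (e.g. Firth) analysis"
        )
    if x[R == 0].max() < x[R == 1].min() or x[R == 1].max() < x[R == 0].min():
        raise SeparationError(
            "TMB perfectly separates responders from non-responders; the "
            "logistic MLE diverges — consider a penalized analysis"
        )


def fit_joint_model(cohort: Cohort, options: FitOptions | None = None) -> JointModelFit:
    """Fit the joint response/survival mixed model by penalized likelihood.

    The outer loop updates the variance component(s) from the posterior
    modes plus the curvature of the penalized log-likelihood (EM-type)
    until the relative change drops below ``options.tol``; the inner step
    maximizes the penalized joint log-likelihood over fixed effects and
    random effects (L-BFGS with analytic gradients, warm-started).
    """
    options = options or FitOptions()
    _check_inputs(cohort, options)
    x, R = cohort.tmb, cohort.R
    n = cohort.n
    cox = _CoxCache(cohort.T, cohort.delta)

    b0_init = float(np.clip(np.log(R.mean() / (1 - R.mean())), -5, 5))
    lbfgs_opts = {"maxiter": 2000, "maxcor": 12, "ftol": 1e-14, "gtol": 1e-9}

    if options.random_effects == "none":
        theta = np.array([b0_init, 0.0, 0.0])
        res = minimize(
            _nll_fixed, theta, args=(x, R, cox), jac=True, method="L-BFGS-B",
            options=lbfgs_opts,
        )
        theta = res.x
        psi = theta[2] * x
        t_ev, H_ev = cox.baseline(psi)
        return JointModelFit(
            beta=theta[:2].copy(),
            alpha=float(theta[2]),
            gamma=0.0,
            Sigma=np.zeros((2, 2)),
            u_hat=np.zeros(n),
            v_hat=np.zeros(n),
            H0=BaselineHazard(t_ev, H_ev),
            converged=bool(res.success),
            loglik=float(-res.fun),
            loglik_trace=np.array([-res.fun]),
            n_iter=1,
            ids=cohort.ids,
            tmb=x.copy(),
            T_median=float(np.median(cohort.T)),
            random_effects="none",
            quad_nodes=options.quad_nodes,
        )

    # warm start from the fixed-effects-only fit; the sign of the residual
    # cross-correlation seeds the loading (the likelihood is bimodal in the
    # sign of the endpoint correlation)
    res0 = minimize(
        _nll_fixed, np.array([b0_init, 0.0, 0.0]), args=(x, R, cox),
        jac=True, method="L-BFGS-B", options=lbfgs_opts,
    )
    b0, b1, al = res0.x
    mu0 = expit(b0 + b1 * x)
    _, g_psi0, wH0, _, _ = cox.parts(al * x)
    r_R = R - mu0
    r_T = cohort.delta - wH0  # martingale residuals
    with np.errstate(invalid="ignore"):
        c = np.corrcoef(r_R, r_T)[0, 1]
    ga0 = float(np.clip(np.nan_to_num(c) * 2.0, -2.0, 2.0))
    start = np.array([b0, b1, al, ga0])
    ll_fixed = float(-res0.fun)

    if options.random_effects == "shared":
        fit = _fit_shared(cohort, options, x, R, cox, start, lbfgs_opts)
        n_extra = 2  # gamma, sigma_u^2
    else:
        fit = _fit_bivariate(cohort, options, x, R, cox, start, lbfgs_opts)
        n_extra = 3  # sigma_u^2, sigma_v^2, rho
    if options.parsimony and fit.loglik - ll_fixed < n_extra:
        # heterogeneity not supported by the data: report the
        # fixed-effects solution with the variance at the ridge floor
        t_ev, H_ev = cox.baseline(al * x)
        fit.beta = np.array([b0, b1])
        fit.alpha = float(al)
        fit.gamma = 0.0
        fit.Sigma = options.ridge_floor * np.eye(2)
        fit.u_hat = np.zeros(cohort.n)
        fit.v_hat = np.zeros(cohort.n)
        fit.H0 = BaselineHazard(t_ev, H_ev)
        fit.loglik = ll_fixed
        fit.loglik_trace = np.append(fit.loglik_trace, ll_fixed) \
            if fit.loglik_trace[-1] <= ll_fixed else np.array([ll_fixed])
        fit.converged = bool(res0.success)
    return fit


def _fit_shared(cohort, options, x, R, cox, start, lbfgs_opts):
    n = cohort.n
    state = {"a": np.zeros(n)}
    phi0 = np.array([*start, np.log(options.sigma0)])
    trace: list[float] = []

    def cb(phi):
        trace.append(-_laplace_nll_shared(phi, x, R, cox, state))

    res = minimize(
        _laplace_nll_shared,
        phi0,
        args=(x, R, cox, state),
        method="L-BFGS-B",
        bounds=[(-30, 30), (-10, 10), (-10, 10), (-25, 25),
                (np.log(options.ridge_floor), np.log(100.0))],
        callback=cb,
        options={
            "maxiter": options.max_iter,
            "ftol": options.tol * 1e-3,
            "gtol": options.tol,
            "eps": 1e-6,
        },
    )
    phi = res.x
    b0, b1, al, ga, ls2 = phi
    sig2 = float(np.exp(ls2))
    if abs(b1) >= 10 or abs(b0) >= 30:
        raise SeparationError(
            "response-submodel coefficients diverged (quasi-separation); "
            "consider a penalized analysis"
        )
    final_nll = _laplace_nll_shared(phi, x, R, cox, state)
    trace.append(-final_nll)
    a = state["a"]
    if not res.success:
        warnings.warn(
            f"joint-model optimization did not converge: {res.message}",
            stacklevel=3,
        )
    if sig2 <= options.ridge_floor * (1 + 1e-8):
        ga = 0.0  # loading unidentified at the variance floor
    Sigma = sig2 * np.array([[1.0, ga], [ga, ga**2]])
    t_ev, H_ev = cox.baseline(al * x + ga * a)
    return JointModelFit(
        beta=np.array([b0, b1]),
        alpha=float(al),
        gamma=float(ga),
        Sigma=Sigma,
        u_hat=a.copy(),
        v_hat=ga * a,
        H0=BaselineHazard(t_ev, H_ev),
        converged=bool(res.success),
        loglik=float(-final_nll),
        loglik_trace=np.asarray(trace),
        n_iter=int(res.nit),
        ids=cohort.ids,
        tmb=x.copy(),
        T_median=float(np.median(cohort.T)),
        random_effects="shared",
        quad_nodes=options.quad_nodes,
    )


def _fit_bivariate(cohort, options, x, R, cox, start, lbfgs_opts):
    n = cohort.n
    state = {"u": np.zeros(n), "v": np.zeros(n)}
    rho0 = float(np.clip(start[3] / 2.0, -0.9, 0.9))
    phi0 = np.array(
        [start[0], start[1], start[2],
         np.log(options.sigma0), np.log(options.sigma0), np.arctanh(rho0)]
    )
    trace: list[float] = []

    def cb(phi):
        trace.append(-_laplace_nll_biv(phi, x, R, cox, state))

    res = minimize(
        _laplace_nll_biv,
        phi0,
        args=(x, R, cox, state),
        method="L-BFGS-B",
        bounds=[(-30, 30), (-10, 10), (-10, 10),
                (np.log(options.ridge_floor), np.log(100.0)),
                (np.log(options.ridge_floor), np.log(100.0)),
                (-5, 5)],
        callback=cb,
        options={
            "maxiter": options.max_iter,
            "ftol": options.tol * 1e-3,
            "gtol": options.tol,
            "eps": 1e-6,
        },
    )
    phi = res.x
    b0, b1, al, lsu, lsv, zr = phi
    if abs(b1) >= 10 or abs(b0) >= 30:
        raise SeparationError(
            "response-submodel coefficients diverged (quasi-separation); "
            "consider a penalized analysis"
        )
    final_nll = _laplace_nll_biv(phi, x, R, cox, state)
    trace.append(-final_nll)
    su2, sv2 = float(np.exp(lsu)), float(np.exp(lsv))
    rho = float(np.tanh(zr))
    Sigma = np.array(
        [[su2, rho * np.sqrt(su2 * sv2)], [rho * np.sqrt(su2 * sv2), sv2]]
    )
    u, v = state["u"], state["v"]
    if not res.success:
        warnings.warn(
            f"joint-model optimization did not converge: {res.message}",
            stacklevel=3,
        )
    t_ev, H_ev = cox.baseline(al * x + v)
    return JointModelFit(
        beta=np.array([b0, b1]),
        alpha=float(al),
        gamma=float("nan"),
        Sigma=Sigma,
        u_hat=u.copy(),
        v_hat=v.copy(),
        H0=BaselineHazard(t_ev, H_ev),
        converged=bool(res.success),
        loglik=float(-final_nll),
        loglik_trace=np.asarray(trace),
        n_iter=int(res.nit),
        ids=cohort.ids,
        tmb=x.copy(),
        T_median=float(np.median(cohort.T)),
        random_effects="bivariate",
        quad_nodes=options.quad_nodes,
    )


# --------------------------------------------------------------------------
# joint probabilities
# --------------------------------------------------------------------------
def _gh_nodes(k: int):
    z, w = np.polynomial.hermite.hermgauss(k)
    return z * np.sqrt(2.0), w / np.sqrt(np.pi)


def _integrate_p(fit: JointModelFit, tmb: np.ndarray, H0_T0: float):
    """Marginal Pr(R=1, T*>T0 | tmb) over the random-effect law (GH)."""
    b0, b1 = fit.beta
    al = fit.alpha
    tmb = np.atleast_1d(np.asarray(tmb, dtype=float))
    if fit.random_effects == "bivariate" and fit.Sigma[0, 0] > 1e-10:
        z, w = _gh_nodes(fit.quad_nodes)
        L = np.linalg.cholesky(fit.Sigma + 1e-12 * np.eye(2))
        Z1, Z2 = np.meshgrid(z, z, indexing="ij")
        U = L[0, 0] * Z1
        V = L[1, 0] * Z1 + L[1, 1] * Z2
        W = np.outer(w, w)
        pr = expit(b0 + b1 * tmb[:, None, None] + U[None])
        st = np.exp(-H0_T0 * np.exp(al * tmb[:, None, None] + V[None]))
        p = np.tensordot(pr * st, W, axes=([1, 2], [0, 1]))
        p_R = np.tensordot(pr, W, axes=([1, 2], [0, 1]))
        p_T = np.tensordot(st, W, axes=([1, 2], [0, 1]))
        return p, p_R, p_T
    su = np.sqrt(max(fit.Sigma[0, 0], 0.0))
    if su < 1e-8:
        pr = expit(b0 + b1 * tmb)
        st = np.exp(-H0_T0 * np.exp(al * tmb))
        return pr * st, pr, st
    z, w = _gh_nodes(fit.quad_nodes)
    u = su * z
    v = fit.gamma * u
    pr = expit(b0 + b1 * tmb[:, None] + u[None, :])
    st = np.exp(-H0_T0 * np.exp(al * tmb[:, None] + v[None, :]))
    return (pr * st) @ w, pr @ w, st @ w


def _re_density(fit: JointModelFit, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Random-effect density factor of the literal plugin formula.

    For the shared parameterization the joint law of (u, v) is singular,
    so the density of the free coordinate u is used.
    """
    if fit.random_effects == "none":
        return np.ones_like(u)
    if fit.random_effects == "shared":
        s2 = max(fit.Sigma[0, 0], 1e-12)
        return np.exp(-0.5 * u**2 / s2) / np.sqrt(2 * np.pi * s2)
    S = fit.Sigma + 1e-12 * np.eye(2)
    P = np.linalg.inv(S)
    det = np.linalg.det(S)
    q = P[0, 0] * u**2 + 2 * P[0, 1] * u * v + P[1, 1] * v**2
    return np.exp(-0.5 * q) / (2 * np.pi * np.sqrt(det))


def joint_probability(
    fit: JointModelFit,
    patient: PatientRecord,
    T0: float | None = None,
    mode: str = "integrate",
    weights: tuple[float, float] = (1.0, 1.0),
) -> JointProbability:
    """Joint probability of response and surviving past ``T0`` for one patient.

    ``T0`` defaults to the median observed follow-up of the fitted cohort.
    See the module docstring for the three modes.
    """
    if T0 is None:
        T0 = fit.T_median
    if T0 < 0:
        raise ValueError("T0 must be >= 0")
    H0_T0 = float(fit.H0(T0, warn_beyond=True))
    if mode == "integrate":
        p, p_R, p_T = _integrate_p(fit, np.array([patient.tmb]), H0_T0)
        return JointProbability(float(p[0]), float(p_R[0]), float(p_T[0]), T0, mode, weights)
    if mode in ("plugin", "eb"):
        i = fit.index_of(patient.id)
        u, v = fit.u_hat[i], fit.v_hat[i]
        eta, psi = fit.linear_predictors(patient.tmb, u, v)
        p_R = float(expit(eta))
        p_T = float(np.exp(-H0_T0 * np.exp(psi)))
        p = p_R * p_T
        if mode == "plugin":
            p *= float(_re_density(fit, np.array([u]), np.array([v]))[0])
        return JointProbability(p, p_R, p_T, T0, mode, weights)
    raise ValueError(f"unknown mode {mode!r}")


def joint_probabilities(
    fit: JointModelFit,
    cohort: Cohort | None = None,
    T0: float | None = None,
    mode: str = "eb",
    weights: tuple[float, float] = (1.0, 1.0),
):
    """Vectorized per-patient joint probabilities.

    When ``cohort`` is omitted, the probabilities are computed for the
    fitted cohort itself (required for ``plugin``/``eb`` modes).  Returns
    a DataFrame with columns ``id, p, p_R, p_T``.
    """
    import pandas as pd

    if T0 is None:
        T0 = fit.T_median
    H0_T0 = float(fit.H0(T0, warn_beyond=True))
    if mode == "integrate":
        tmb = fit.tmb if cohort is None else cohort.tmb
        ids = fit.ids if cohort is None else cohort.ids
        p, p_R, p_T = _integrate_p(fit, tmb, H0_T0)
    elif mode in ("plugin", "eb"):
        if cohort is None:
            idx = np.arange(len(fit.ids))
            ids = fit.ids
            tmb = fit.tmb
        else:
            idx = np.array([fit.index_of(i) for i in cohort.ids])
            ids = cohort.ids
            tmb = cohort.tmb
        u, v = fit.u_hat[idx], fit.v_hat[idx]
        eta, psi = fit.linear_predictors(tmb, u, v)
        p_R = expit(eta)
        p_T = np.exp(-H0_T0 * np.exp(np.clip(psi, -500, 500)))
        p = p_R * p_T
        if mode == "plugin":
            p = p * _re_density(fit, u, v)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(
        {
            "id": ids,
            "p": p,
            "p_R": weights[0] * p_R,
            "p_T": weights[1] * p_T,
        }
    )
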