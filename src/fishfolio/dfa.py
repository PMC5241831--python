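"""Dynamic factor analysis for multivariate annual time series.

The model explains n observed series with m << n shared latent trends that
evolve as independent random walks:

    state:        x_t = x_{t-1} + w_t,   w_t ~ N(0, Q),  Q = I (fixed)
    observation:  y_t = Z x_t + v_t,     v_t ~ N(0, R),  R diagonal

with the initial state pinned at x_0 = 0 (zero variance).  Fixing Q to the
identity and pinning x_0 makes the model estimable; z-scoring each observed
series beforehand makes the fixed process-error scale meaningful.  The free
parameters are the factor loadings Z (n x m) and the diagonal observation
variances R — either a single shared variance ("diagonal and equal") or one
per series ("diagonal and unequal").

Estimation is maximum likelihood by EM: the E-step runs a Kalman filter and
fixed-interval (RTS) smoother, the M-step updates Z and R in closed form.
Remaining rotational indeterminacy is removed during estimation by the
standard constraint that the upper triangle of the first m rows of Z is zero;
a varimax rotation (plus a sign convention) is applied afterwards for
reporting only.  Candidate structures (number of trends, R structure) are
compared by AIC = -2 logL + 2k.

The filter uses the information-form measurement update, so each step costs
O(n m^2) rather than O(n^3); with diagonal R this is exact, not an
approximation.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ingest import Panel

_MONOTONE_TOL = 1e-9  # permitted floating-point backsliding of the EM logL trace
_R_FLOOR = 1e-10


@dataclasses.dataclass
class DFAModelSpec:
    """A candidate model structure: trend count and observation-error form."""

    m: int = 1
    r_structure: str = "diagonal_equal"  # or "diagonal_unequal"
    max_iter: int = 2000
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r_structure not in ("diagonal_equal", "diagonal_unequal"):
            raise ValueError(f"unknown r_structure {self.r_structure!r}")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


@dataclasses.dataclass
class ZScoredPanel:
    """Row-standardized observations with back-transform metadata."""

    values: np.ndarray  # n x T, each row mean 0 / sd 1
    means: np.ndarray
    sds: np.ndarray
    entity_ids: list | None = None
    years: np.ndarray | None = None

    @property
    def n_series(self) -> int:
        return self.values.shape[0]

    @property
    def n_years(self) -> int:
        return self.values.shape[1]


@dataclasses.dataclass
class DFAFit:
    """A fitted DFA: loadings, observation variances, smoothed trends."""

    Z: np.ndarray  # n x m
    R: np.ndarray  # length-n diagonal of the observation covariance
    states: np.ndarray  # m x T smoothed trends E[x_t | y_{1:T}]
    state_covs: np.ndarray  # T x m x m smoothed covariances
    logL: float
    n_params: int
    aic: float
    converged: bool
    iterations: int
    spec: DFAModelSpec
    loglik_trace: np.ndarray
    y: np.ndarray | None = None  # the observations the fit was made on
    rotated: bool = False

    @property
    def m(self) -> int:
        return self.Z.shape[1]

    @property
    def n_series(self) -> int:
        return self.Z.shape[0]


# ---------------------------------------------------------------------------
# standardization


def zscore(panel: Panel) -> ZScoredPanel:
    """Standardize each row of a panel to mean 0 and sd 1 (ddof=1).

    Raises on constant rows, naming the entity — a constant series carries no
    trend information and would divide by zero.
    """
    values = np.asarray(panel.values, dtype=float)
    means = values.mean(axis=1)
    sds = values.std(axis=1, ddof=1)
    flat = np.flatnonzero(sds <= 0)
    if flat.size:
        names = [panel.entity_ids[i] for i in flat[:5]]
        raise ValueError(f"constant series cannot be z-scored: {names}")
    z = (values - means[:, None]) / sds[:, None]
    return ZScoredPanel(
        values=z, means=means, sds=sds, entity_ids=list(panel.entity_ids), years=panel.years
    )


def _as_matrix(y) -> np.ndarray:
    if isinstance(y, ZScoredPanel):
        return y.values
    return np.asarray(y, dtype=float)


# ---------------------------------------------------------------------------
# likelihood: brute-force oracle and Kalman recursion


def loglik_oracle(y, Z, R) -> float:
    """Log-likelihood by brute force on the stacked observation vector.

    With x_0 = 0 and Q = I the latent trend at time t (t = 1..T) is a sum of
    t innovations, so the stacked vector (y_1', ..., y_T')' is zero-mean
    Gaussian with Cov(y_t, y_s) = Z min(t, s) Z' + delta_ts R.  Evaluating
    that dense multivariate normal is quadratic-memory and serves as the
    independent check on the Kalman recursion for small instances.
    """
    y = _as_matrix(y)
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    n, T = y.shape
    Rdiag = np.diag(np.asarray(R, dtype=float)) if np.ndim(R) <= 1 else np.asarray(R, float)
    ZZt = Z @ Z.T
    cov = np.empty((n * T, n * T))
    for t in range(T):
        for s in range(T):
            cov[t * n:(t + 1) * n, s * n:(s + 1) * n] = (min(t, s) + 1) * ZZt
        cov[t * n:(t + 1) * n, t * n:(t + 1) * n] += Rdiag
    stacked = y.T.reshape(-1)
    try:
        return float(stats.multivariate_normal(mean=np.zeros(n * T), cov=cov).logpdf(stacked))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate input
        raise ValueError("singular stacked covariance") from exc


def _inv_pd(M: np.ndarray) -> np.ndarray:
    """Inverse of a tiny positive-definite matrix (explicit for m <= 2)."""
    if M.shape[0] == 1:
        return np.array([[1.0 / M[0, 0]]])
    if M.shape[0] == 2:
        a, b, c, d = M[0, 0], M[0, 1], M[1, 0], M[1, 1]
        det = a * d - b * c
        return np.array([[d, -b], [-c, a]]) / det
    return np.linalg.inv(M)


def _logdet_pd(M: np.ndarray) -> float:
    if M.shape[0] == 1:
        return math.log(M[0, 0])
    if M.shape[0] == 2:
        return math.log(M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0])
    return float(np.linalg.slogdet(M)[1])


def _kalman_pass(y: np.ndarray, Z: np.ndarray, Rdiag: np.ndarray):
    """Filter + RTS smoother for the random-walk DFA.

    Returns (logL, smoothed means m x T, smoothed covariances T x m x m).
    Measurement updates use the information form, exact for diagonal R:
        P_filt = (P_pred^{-1} + Z' R^{-1} Z)^{-1}
    with the matched Woodbury identities for |F| and the innovation
    quadratic form, so no n x n matrix is ever formed and the recursion is
    purely m-dimensional: all n-dimensional contractions (Z'R^{-1}y,
    y'R^{-1}y, Z'R^{-1}Z) are precomputed once per call.
    """
    n, T = y.shape
    m = Z.shape[1]
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(Z)) and np.all(np.isfinite(Rdiag))):
        raise ValueError("non-finite input to Kalman recursion")
    Rinv = 1.0 / Rdiag
    A = Z.T * Rinv  # m x n, equals Z' R^{-1}
    AZ = A @ Z  # Z' R^{-1} Z, m x m
    Ay = A @ y  # m x T
    yRy = np.einsum("it,it->t", y * Rinv[:, None], y)
    # constant part: n T log(2 pi) and T sum(log r) of the |F| terms
    logL = -0.5 * (n * T * math.log(2.0 * math.pi) + T * float(np.sum(np.log(Rdiag))))
    if m == 1:
        return _pass_scalar(float(AZ[0, 0]), Ay[0], yRy, logL)

    xf = np.empty((T, m))
    Pf = np.empty((T, m, m))
    xp = np.empty((T, m))
    Pp = np.empty((T, m, m))
    x_pred = np.zeros(m)
    P_pred = np.eye(m)  # x_0 = 0 exactly, so P_{1|0} = Q = I
    eye = np.eye(m)

    for t in range(T):
        P_pred_inv = _inv_pd(P_pred)
        C = P_pred_inv + AZ
        Cinv = _inv_pd(C)
        ay = Ay[:, t]
        av = ay - AZ @ x_pred  # Z' R^{-1} (y_t - Z x_pred)
        # v'F^{-1}v = v'R^{-1}v - av'C^{-1}av, expanding v'R^{-1}v without v
        quad = (
            yRy[t] - 2.0 * float(x_pred @ ay) + float(x_pred @ AZ @ x_pred)
            - float(av @ Cinv @ av)
        )
        logL += -0.5 * (_logdet_pd(P_pred) + _logdet_pd(C) + quad)

        x_filt = Cinv @ (P_pred_inv @ x_pred + ay)
        xp[t], Pp[t] = x_pred, P_pred
        xf[t], Pf[t] = x_filt, Cinv
        x_pred = x_filt
        P_pred = Cinv + eye  # random walk: transition I, Q = I

    xs = np.empty((T, m))
    Ps = np.empty((T, m, m))
    xs[-1], Ps[-1] = xf[-1], Pf[-1]
    for t in range(T - 2, -1, -1):
        J = Pf[t] @ _inv_pd(Pp[t + 1])
        xs[t] = xf[t] + J @ (xs[t + 1] - xp[t + 1])
        Ps[t] = Pf[t] + J @ (Ps[t + 1] - Pp[t + 1]) @ J.T
    return float(logL), xs.T.copy(), Ps


def _pass_scalar(a: float, ay: np.ndarray, yRy: np.ndarray, logL: float):
    """Single-trend (m = 1) recursion in plain floats; hot path of the EM."""
    T = ay.shape[0]
    ay_l = ay.tolist()
    yRy_l = yRy.tolist()
    xf = [0.0] * T
    pf = [0.0] * T
    xp = [0.0] * T
    pp = [0.0] * T
    x_pred, P_pred = 0.0, 1.0
    log = math.log
    for t in range(T):
        c = 1.0 / P_pred + a
        av = ay_l[t] - a * x_pred
        quad = yRy_l[t] - 2.0 * x_pred * ay_l[t] + a * x_pred * x_pred - av * av / c
        logL += -0.5 * (log(P_pred) + log(c) + quad)
        P_filt = 1.0 / c
        x_filt = P_filt * (x_pred / P_pred + ay_l[t])
        xp[t], pp[t] = x_pred, P_pred
        xf[t], pf[t] = x_filt, P_filt
        x_pred = x_filt
        P_pred = P_filt + 1.0
    xs = [0.0] * T
    ps = [0.0] * T
    xs[-1], ps[-1] = xf[-1], pf[-1]
    for t in range(T - 2, -1, -1):
        J = pf[t] / pp[t + 1]
        xs[t] = xf[t] + J * (xs[t + 1] - xp[t + 1])
        ps[t] = pf[t] + J * (ps[t + 1] - pp[t + 1]) * J
    return float(logL), np.asarray(xs)[None, :], np.asarray(ps)[:, None, None]


def kalman_loglik(y, Z, R):
    """Exact log-likelihood and smoothed states for given (Z, R).

    Parameters
    ----------
    y : ZScoredPanel or array (n x T)
    Z : array (n x m)
    R : length-n array (diagonal) or scalar shared variance

    Returns
    -------
    (logL, states, state_covs)
        ``states`` is m x T (smoothed means), ``state_covs`` T x m x m.
    """
    y = _as_matrix(y)
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] != y.shape[0]:
        Z = Z.reshape(y.shape[0], -1)
    Rdiag = np.broadcast_to(np.atleast_1d(np.asarray(R, dtype=float)), (y.shape[0],)).copy()
    return _kalman_pass(y, Z, Rdiag)


# ---------------------------------------------------------------------------
# EM estimation


def _free_mask(n: int, m: int) -> np.ndarray:
    """Identifiability pattern: Z[i, j] fixed at 0 for j > i within the first m rows."""
    mask = np.ones((n, m), dtype=bool)
    for i in range(min(n, m)):
        mask[i, i + 1:] = False
    return mask


def n_free_params(n: int, m: int, r_structure: str) -> int:
    z_free = n * m - m * (m - 1) // 2
    return z_free + (1 if r_structure == "diagonal_equal" else n)


def _init_params(y: np.ndarray, m: int):
    """Deterministic start: principal directions for Z, half the variance for R."""
    n, T = y.shape
    cov = (y @ y.T) / (T - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1][:m]
    Z0 = eigvec[:, order]  # columns already unit norm
    # fixed sign convention so the start is reproducible across LAPACK builds
    for j in range(m):
        if Z0[np.argmax(np.abs(Z0[:, j])), j] < 0:
            Z0[:, j] = -Z0[:, j]
    Z0 = Z0 * _free_mask(n, m)  # zero the constrained entries
    R0 = np.full(n, 0.5 * float(np.mean(np.var(y, axis=1, ddof=1))))
    return Z0, R0


def em_fit(y, spec: DFAModelSpec) -> DFAFit:
    """Fit the DFA by EM with closed-form M-steps for Z and R.

    The E-step is the Kalman smoother; with Q and x_0 fixed only the
    smoothed first and second moments of x_t are needed.  Z rows update by
    generalized least squares restricted to the free (unconstrained) entries;
    R updates from the expected squared residuals.  The log-likelihood is
    non-decreasing across iterations (asserted); iteration stops when the
    improvement drops below ``spec.tol`` or at ``spec.max_iter``.
    """
    yv = _as_matrix(y)
    n, T = yv.shape
    m = spec.m
    if n <= m:
        raise ValueError(f"need more series than trends (n={n}, m={m})")
    mask = _free_mask(n, m)
    Z, Rdiag = _init_params(yv, m)

    trace = []
    converged = False
    states = covs = None
    for it in range(spec.max_iter):
        logL, states, covs = _kalman_pass(yv, Z, Rdiag)
        if trace:
            drop = trace[-1] - logL
            assert drop <= _MONOTONE_TOL, (
                f"EM log-likelihood decreased by {drop:.3e} at iteration {it}"
            )
            if logL - trace[-1] < spec.tol:
                trace.append(logL)
                converged = True
                break
        trace.append(logL)

        # E-step sufficient statistics
        S11 = covs.sum(axis=0) + states @ states.T  # sum E[x_t x_t'],  m x m
        Sxy = states @ yv.T  # m x n

        # M-step: Z rows on their free entries
        Znew = np.zeros_like(Z)
        for i in range(n):
            f = mask[i]
            Znew[i, f] = np.linalg.solve(S11[np.ix_(f, f)], Sxy[f, i])
        Z = Znew

        # M-step: R from expected residuals under the new Z
        resid = yv - Z @ states
        quad = np.einsum("im,tmk,ik->i", Z, covs, Z)
        r_ii = (np.sum(resid**2, axis=1) + quad) / T
        if spec.r_structure == "diagonal_equal":
            Rdiag = np.full(n, max(float(np.mean(r_ii)), _R_FLOOR))
        else:
            Rdiag = np.maximum(r_ii, _R_FLOOR)
    else:
        # final evaluation at the last parameter values
        logL, states, covs = _kalman_pass(yv, Z, Rdiag)
        assert trace[-1] - logL <= _MONOTONE_TOL
        trace.append(logL)

    if not converged:
        warnings.warn(
            f"EM did not converge within {spec.max_iter} iterations "
            f"(last improvement {trace[-1] - trace[-2]:.2e})",
            RuntimeWarning,
        )
    k = n_free_params(n, m, spec.r_structure)
    logL = trace[-1]
    return DFAFit(
        Z=Z,
        R=Rdiag,
        states=states,
        state_covs=covs,
        logL=logL,
        n_params=k,
        aic=-2.0 * logL + 2.0 * k,
        converged=converged,
        iterations=len(trace) - 1,
        spec=spec,
        loglik_trace=np.asarray(trace),
        y=yv,
    )


def select_model(y, candidates: Sequence[DFAModelSpec]):
    """Fit each candidate structure and pick the minimum-AIC model.

    Ties (within 1e-9) break toward fewer parameters.  Returns the winning
    fit and a table with one row per candidate (m, r_structure, logL, k,
    AIC, converged, iterations).
    """
    if not candidates:
        raise ValueError("need at least one candidate model")
    fits, rows = [], []
    for spec in candidates:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                fit = em_fit(y, spec)
        except Exception as exc:  # noqa: BLE001 - candidate failure is recorded
            rows.append(
                {"m": spec.m, "r_structure": spec.r_structure, "logL": np.nan,
                 "n_params": np.nan, "aic": np.nan, "converged": False,
                 "iterations": 0, "error": str(exc)}
            )
            fits.append(None)
            continue
        fits.append(fit)
        rows.append(
            {"m": spec.m, "r_structure": spec.r_structure, "logL": fit.logL,
             "n_params": fit.n_params, "aic": fit.aic, "converged": fit.converged,
             "iterations": fit.iterations, "error": ""}
        )
    table = pd.DataFrame(rows)
    ok = [f for f in fits if f is not None]
    if not ok:
        raise RuntimeError("all candidate models failed to fit")
    best = min(ok, key=lambda f: (round(f.aic / 1e-9) * 1e-9, f.n_params))
    return best, table


# ---------------------------------------------------------------------------
# reporting transforms


def rotate_and_align(fit: DFAFit, rotate: bool = True) -> DFAFit:
    """Varimax-rotate the loadings (m >= 2) and fix trend signs.

    The random-walk prior on x_t is isotropic (Q = I, x_0 = 0), so any
    orthogonal rotation H applied as (Z H, H' x) leaves the likelihood
    unchanged; varimax simply picks the most interpretable member of that
    equivalence class.  Each trend is then sign-flipped so the sum of its
    loadings is non-negative.  AIC and logL are carried over unchanged.
    """
    Z = fit.Z.copy()
    states = fit.states.copy()
    covs = fit.state_covs.copy()
    if rotate and fit.m >= 2:
        from statsmodels.multivariate.factor_rotation import rotate_factors

        Zrot, H = rotate_factors(Z, "varimax")
        Z = Zrot
        states = H.T @ states
        covs = np.einsum("ji,tjk,kl->til", H, covs, H)
    signs = np.where(Z.sum(axis=0) >= 0, 1.0, -1.0)
    Z = Z * signs
    states = states * signs[:, None]
    return dataclasses.replace(fit, Z=Z, states=states, state_covs=covs, rotated=True)


def trend_covariate_corr(trend, covariate) -> float:
    """Pearson correlation between an extracted trend and an annual covariate."""
    trend = np.asarray(trend, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if trend.shape != covariate.shape:
        raise ValueError("trend and covariate must have equal length")
    if np.std(trend) == 0 or np.std(covariate) == 0:
        raise ValueError("zero-variance input to correlation")
    return float(stats.pearsonr(trend, covariate)[0])
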