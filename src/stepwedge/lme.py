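"""Maximum-likelihood engine for the nested-intercept linear mixed model.

The marginal model is Gaussian with mean X beta and a block-diagonal
covariance, one block per cluster:

    V_k = sigma_gamma^2 * J  +  blockdiag over participants of
          [ sigma_h^2 * J_n  +  R ]

where J is the all-ones matrix and R is the within-participant residual
covariance — sigma^2 * I under compound symmetry (CS) or
R[a, b] = sigma^2 * rho^|t_a - t_b| under AR(1).

Fixed effects are profiled out by generalized least squares: for a given
set of variance parameters theta,

    beta(theta)  = (X' V^-1 X)^-1 X' V^-1 y,
    loglik(theta) = exact Gaussian log-density at (beta(theta), theta),

computed blockwise with one Cholesky factorization per distinct cluster
covariance pattern (balanced designs share a single factorization across
clusters). The outer maximization over theta runs unconstrained on
transformed parameters (log SDs, atanh rho).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, qr
from scipy.optimize import minimize

from .scenarios import VarianceComponents

__all__ = [
    "FitResult",
    "cluster_block_covariance",
    "profiled_loglik",
    "fit_ml",
    "fitted_values",
]

LOG2PI = math.log(2.0 * math.pi)

# Unconstrained-scale bounds: log-SD in [-8, 8], atanh(rho) in [-5, 5]
# (|rho| < 0.9999). Solutions pinned at a lower SD bound are effectively
# zero-variance fits and are reported, not errored.
_SD_LOG_BOUNDS = (-8.0, 8.0)
_RHO_ATANH_BOUNDS = (-5.0, 5.0)


# ---------------------------------------------------------------------------
# covariance construction
# ---------------------------------------------------------------------------

def _check_structure(structure: str) -> str:
    s = structure.upper().replace("(1)", "1")
    if s not in ("CS", "AR1"):
        raise ValueError(f"unknown covariance structure {structure!r}; use 'CS' or 'AR1'")
    return s


def _pattern_covariance(
    vc: VarianceComponents, same_subject: np.ndarray, lag: np.ndarray, structure: str
) -> np.ndarray:
    """Covariance for one cluster given its subject/lag pattern matrices."""
    if structure == "AR1":
        R = (vc.sigma**2) * np.power(vc.rho, lag)
    else:
        R = (vc.sigma**2) * np.eye(lag.shape[0])
    return vc.sigma_gamma**2 + same_subject * (vc.sigma_h**2 + R)


def cluster_block_covariance(
    varcomp: VarianceComponents, m: int, n: int, structure: str = "CS"
) -> np.ndarray:
    """Marginal covariance of one cluster's m*n stacked observations.

    Rows are ordered participant-major with each participant's n
    observations in time order (time steps 1..n, equally spaced).
    """
    if m < 1 or n < 1:
        raise ValueError("m and n must be >= 1")
    structure = _check_structure(structure)
    subj = np.repeat(np.arange(m), n)
    t = np.tile(np.arange(n), m)
    same = (subj[:, None] == subj[None, :]).astype(float)
    lag = np.abs(t[:, None] - t[None, :])
    return _pattern_covariance(varcomp, same, lag, structure)


# ---------------------------------------------------------------------------
# data layout: group clusters by covariance pattern
# ---------------------------------------------------------------------------

class _LikelihoodData:
    """Pre-extracted arrays for repeated likelihood evaluations.

    Sorts rows cluster-by-cluster (subjects contiguous, time-ordered),
    groups clusters that share a covariance pattern — identical within-
    cluster subject layout and time vector — and stacks each group's
    [X | y] into a 3-D array so one Cholesky serves the whole group.
    """

    def __init__(self, X, y, clusters, subjects, times, names=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        clusters = np.asarray(clusters)
        subjects = np.asarray(subjects)
        times = np.asarray(times, dtype=float)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("X must be 2-D with one row per element of y")
        self.names = list(names) if names is not None else [
            f"b{j}" for j in range(X.shape[1])
        ]
        _check_full_rank(X, self.names)

        order = np.lexsort((times, subjects, clusters))
        self.order = order
        X, y = X[order], y[order]
        clusters, subjects, times = clusters[order], subjects[order], times[order]
        self.X, self.y = X, y
        self.clusters, self.subjects, self.times = clusters, subjects, times
        self.n_obs, self.p = X.shape

        W = np.hstack([X, y[:, None]])  # augmented [X | y]
        self.groups = []
        by_pattern: dict = {}
        for c in pd.unique(clusters):
            idx = np.flatnonzero(clusters == c)
            subj_codes = pd.factorize(subjects[idx])[0]
            key = (tuple(subj_codes), tuple(times[idx]))
            by_pattern.setdefault(key, []).append(idx)
        for (subj_codes, t_vals), idx_list in by_pattern.items():
            sc = np.asarray(subj_codes)
            tv = np.asarray(t_vals)
            Wstack = np.stack([W[idx] for idx in idx_list])
            balanced = _balanced_layout(sc, tv)
            if balanced is not None:
                m, times1 = balanced
                self.groups.append(("balanced", (m, times1), Wstack, idx_list))
            else:
                same = (sc[:, None] == sc[None, :]).astype(float)
                lag = np.abs(tv[:, None] - tv[None, :])
                self.groups.append(("generic", (same, lag), Wstack, idx_list))

    def accumulate(self, vc: VarianceComponents, structure: str):
        """Return (XtViX, XtViy, ytViy, logdet) over all clusters."""
        p = self.p
        A = np.zeros((p + 1, p + 1))
        logdet = 0.0
        for kind, pattern, Wstack, idx_list in self.groups:
            n_c = Wstack.shape[0]
            if kind == "balanced":
                a, ld = _balanced_accumulate(vc, pattern, Wstack, structure)
                A += a
                logdet += n_c * ld
            else:
                same, lag = pattern
                V = _pattern_covariance(vc, same, lag, structure)
                c, low = cho_factor(V, lower=True, check_finite=False)
                b = Wstack.shape[1]
                flat = Wstack.transpose(1, 0, 2).reshape(b, n_c * (p + 1))
                Vi_flat = cho_solve((c, low), flat, check_finite=False)
                ViW = Vi_flat.reshape(b, n_c, p + 1).transpose(1, 0, 2)
                A += np.einsum("cbi,cbj->ij", Wstack, ViW)
                logdet += 2.0 * n_c * float(np.sum(np.log(np.diag(c))))
        return A[:p, :p], A[:p, p], A[p, p], logdet


def _balanced_layout(subj_codes: np.ndarray, times: np.ndarray):
    """Detect a subject-major balanced cluster: m subjects x one shared
    time vector. Returns (m, times_of_one_subject) or None."""
    counts = np.bincount(subj_codes)
    if counts.size == 0 or not np.all(counts == counts[0]):
        return None
    m, n = counts.size, int(counts[0])
    if not np.array_equal(subj_codes, np.repeat(np.arange(m), n)):
        return None
    t1 = times[:n]
    if not np.array_equal(times, np.tile(t1, m)):
        return None
    return m, t1


def _balanced_accumulate(vc, pattern, Wstack, structure):
    """W' V^-1 W and logdet for clusters of m identical subject blocks.

    V = I_m (x) A + sigma_gamma^2 * 1 1', with A the n x n within-subject
    covariance (participant intercept + residual). Sherman-Morrison gives
    V^-1 = D^-1 - c (D^-1 1)(D^-1 1)' with D = I_m (x) A and
    c = sigma_gamma^2 / (1 + sigma_gamma^2 m 1'A^-1 1), so all dense work
    happens at the n x n scale.
    """
    m, t1 = pattern
    n = len(t1)
    lag = np.abs(t1[:, None] - t1[None, :])
    if structure == "AR1":
        R = (vc.sigma**2) * np.power(vc.rho, lag)
    else:
        R = (vc.sigma**2) * np.eye(n)
    A_n = vc.sigma_h**2 + R
    c, low = cho_factor(A_n, lower=True, check_finite=False)
    logdet_A = 2.0 * float(np.sum(np.log(np.diag(c))))
    g = cho_solve((c, low), np.ones(n), check_finite=False)  # A^-1 1
    s = float(np.sum(g))
    denom = 1.0 + vc.sigma_gamma**2 * m * s
    cc = vc.sigma_gamma**2 / denom
    logdet = m * logdet_A + math.log(denom)

    n_c, b, q = Wstack.shape
    Wm = Wstack.reshape(n_c, m, n, q)
    Ai = cho_solve((c, low), np.eye(n), check_finite=False)
    DW = Wm.reshape(n_c * m, n, q)
    DW = (Ai @ DW).reshape(n_c, m, n, q)  # batched A^-1 W
    qvec = np.tensordot(Wm, g, axes=([2], [0])).sum(axis=1)  # (n_c, q): 1' D^-1 W
    ViW = DW - cc * g[None, None, :, None] * qvec[:, None, None, :]
    Acc = Wstack.reshape(-1, q).T @ ViW.reshape(-1, q)
    return Acc, logdet


def _check_full_rank(X: np.ndarray, names) -> None:
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # name the trailing pivot columns as the aliased set
        _, _, piv = qr(X, mode="economic", pivoting=True)
        aliased = sorted(names[j] for j in piv[r:])
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {r} < {X.shape[1]} columns); "
            f"aliased columns: {aliased}"
        )


# ---------------------------------------------------------------------------
# profiled likelihood
# ---------------------------------------------------------------------------

def _profiled_core(data: _LikelihoodData, vc: VarianceComponents, structure: str):
    XtViX, XtViy, ytViy, logdet = data.accumulate(vc, structure)
    try:
        beta = np.linalg.solve(XtViX, XtViy)
        vcov = np.linalg.inv(XtViX)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(f"normal equations singular: {e}") from e
    quad = ytViy - beta @ XtViy  # (y - Xb)' V^-1 (y - Xb) at the GLS beta
    loglik = -0.5 * (data.n_obs * LOG2PI + logdet + quad)
    return loglik, beta, vcov


def profiled_loglik(
    theta: VarianceComponents,
    X,
    y,
    clusters,
    subjects,
    times,
    structure: str = "CS",
    names=None,
):
    """Profile the fixed effects out of the Gaussian log-likelihood.

    Returns ``(loglik, beta_hat, vcov_beta)`` where beta_hat is the GLS
    estimate at the given variance parameters, loglik the exact Gaussian
    log-density at (beta_hat, theta), and vcov_beta = (X' V^-1 X)^-1.
    """
    structure = _check_structure(structure)
    data = _LikelihoodData(X, y, clusters, subjects, times, names)
    return _profiled_core(data, theta, structure)


# ---------------------------------------------------------------------------
# fit result
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """One maximum-likelihood fit of a mean model x covariance structure."""

    beta: pd.Series
    vcov_beta: pd.DataFrame
    varcomp: VarianceComponents
    loglik: float
    bic: float
    n_obs: int
    n_params: int
    converged: bool
    structure: str
    formulation: str | None = None
    message: str = ""
    n_evals: int = 0

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov_beta)), index=self.beta.index)

    def to_row(self) -> pd.Series:
        """Flat summary row (estimates, SEs, variance components, fit stats)."""
        out = {}
        for name, est in self.beta.items():
            out[f"beta_{name}"] = est
            out[f"se_{name}"] = self.se[name]
        out.update(
            sigma_gamma=self.varcomp.sigma_gamma,
            sigma_h=self.varcomp.sigma_h,
            sigma=self.varcomp.sigma,
            rho=self.varcomp.rho if self.structure == "AR1" else np.nan,
            loglik=self.loglik,
            bic=self.bic,
            n_obs=self.n_obs,
            n_params=self.n_params,
            converged=self.converged,
            structure=self.structure,
            formulation=self.formulation,
        )
        return pd.Series(out)


# ---------------------------------------------------------------------------
# outer optimization
# ---------------------------------------------------------------------------

def _pack(vc: VarianceComponents, ar1: bool) -> np.ndarray:
    z = [
        math.log(max(vc.sigma_gamma, 1e-3)),
        math.log(max(vc.sigma_h, 1e-3)),
        math.log(max(vc.sigma, 1e-3)),
    ]
    if ar1:
        z.append(math.atanh(np.clip(vc.rho, -0.999, 0.999)))
    return np.asarray(z)


def _unpack(z: np.ndarray, ar1: bool) -> VarianceComponents:
    rho = math.tanh(z[3]) if ar1 else 0.0
    return VarianceComponents(
        sigma_gamma=math.exp(z[0]), sigma_h=math.exp(z[1]), sigma=math.exp(z[2]), rho=rho
    )


def _moment_start(data: _LikelihoodData) -> VarianceComponents:
    """Method-of-moments variance decomposition of OLS residuals."""
    X, y = data.X, data.y
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta_ols
    df = pd.DataFrame(
        {"c": data.clusters, "s": data.subjects, "t": data.times, "r": r}
    )
    within = df.groupby("s")["r"].var().mean()  # ~ sigma^2
    subj_means = df.groupby("s")["r"].mean()
    clus_of_subj = df.groupby("s")["c"].first()
    clus_means = subj_means.groupby(clus_of_subj).mean()
    var_subj = subj_means.var()
    var_clus = clus_means.var()
    n_per = df.groupby("s")["t"].count().mean()
    sigma2 = max(within, 1e-2)
    sh2 = max(var_subj - var_clus - sigma2 / n_per, 1e-2)
    sg2 = max(var_clus, 1e-2)
    # pooled lag-1 autocorrelation of within-subject centred residuals
    rc = df["r"] - df.groupby("s")["r"].transform("mean")
    num = den = 0.0
    for _, g in df.assign(rc=rc).groupby("s"):
        v = g.sort_values("t")["rc"].to_numpy()
        num += float(v[:-1] @ v[1:])
        den += float(v @ v)
    rho = float(np.clip(num / den if den > 0 else 0.0, -0.95, 0.95))
    return VarianceComponents(math.sqrt(sg2), math.sqrt(sh2), math.sqrt(sigma2), rho)


def fit_ml(
    X,
    y,
    clusters,
    subjects,
    times,
    structure: str = "CS",
    start: VarianceComponents | None = None,
    names=None,
    formulation: str | None = None,
) -> FitResult:
    """Maximize the profiled log-likelihood over the variance parameters.

    Optimization runs on transformed parameters (log SDs; atanh rho under
    AR(1)) with L-BFGS-B and a Nelder-Mead polish on non-convergence, plus
    a method-of-moments restart if the first start fails. Deterministic
    given the data and starting values. BIC counts the fixed effects plus
    3 (CS) or 4 (AR1) variance parameters.
    """
    structure = _check_structure(structure)
    ar1 = structure == "AR1"
    data = _LikelihoodData(X, y, clusters, subjects, times, names)

    evals = [0]

    def negll(z):
        evals[0] += 1
        try:
            ll, _, _ = _profiled_core(data, _unpack(z, ar1), structure)
        except np.linalg.LinAlgError:
            return 1e12
        return -ll

    bounds = [_SD_LOG_BOUNDS] * 3 + ([_RHO_ATANH_BOUNDS] if ar1 else [])

    starts = []
    if start is not None:
        starts.append(start)
    else:
        starts.append(_moment_start(data))
        starts.append(VarianceComponents(1.0, 1.0, max(float(np.std(data.y)), 0.1), 0.0))

    best = None
    for s_i, vc0 in enumerate(starts):
        z0 = _pack(vc0, ar1)
        res = minimize(
            negll,
            z0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-11, "gtol": 1e-6, "maxiter": 500},
        )
        ok = res.success
        if not ok:
            # derivative-free polish from wherever L-BFGS-B stopped
            res2 = minimize(
                negll,
                res.x,
                method="Nelder-Mead",
                options={"fatol": 1e-7, "xatol": 1e-7, "maxiter": 2000},
            )
            if res2.fun <= res.fun:
                res = res2
            ok = res.success or res2.success
        if best is None or res.fun < best[0].fun - 1e-9:
            best = (res, ok)
        if ok and s_i == 0:
            break  # first start converged; no need for restarts

    res, converged = best
    vc_hat = _unpack(res.x, ar1)
    loglik, beta, vcov = _profiled_core(data, vc_hat, structure)
    n_params = data.p + (4 if ar1 else 3)
    bic = -2.0 * loglik + n_params * math.log(data.n_obs)
    return FitResult(
        beta=pd.Series(beta, index=data.names),
        vcov_beta=pd.DataFrame(vcov, index=data.names, columns=data.names),
        varcomp=vc_hat,
        loglik=float(loglik),
        bic=float(bic),
        n_obs=data.n_obs,
        n_params=n_params,
        converged=bool(converged),
        structure=structure,
        formulation=formulation,
        message=str(getattr(res, "message", "")),
        n_evals=evals[0],
    )


# ---------------------------------------------------------------------------
# fitted values (marginal or BLUP-inclusive)
# ---------------------------------------------------------------------------

def fitted_values(
    fit: FitResult,
    X,
    y,
    clusters,
    subjects,
    times,
    conditional: bool = True,
) -> np.ndarray:
    """Marginal (X beta) or conditional fitted values, in caller row order.

    Conditional values add the empirical best linear unbiased predictions
    of the random intercepts at the ML variance estimates: with
    r_k = y_k - X_k beta_hat the marginal residual of cluster k,
    gamma_hat_k = sigma_gamma^2 * 1' V_k^-1 r_k and, for participant i,
    h_hat_i = sigma_h^2 * (sum of V_k^-1 r_k over that participant's rows).
    """
    data = _LikelihoodData(X, y, clusters, subjects, times, names=list(fit.beta.index))
    beta = fit.beta.to_numpy()
    fitted_sorted = data.X @ beta
    if conditional:
        vc = fit.varcomp
        resid = data.y - fitted_sorted
        adj = np.zeros_like(resid)
        for kind, pattern, _, idx_list in data.groups:
            if kind == "balanced":
                m, t1 = pattern
                sc = np.repeat(np.arange(m), len(t1))
                tv = np.tile(t1, m)
                same = (sc[:, None] == sc[None, :]).astype(float)
                lag = np.abs(tv[:, None] - tv[None, :])
            else:
                same, lag = pattern
            V = _pattern_covariance(vc, same, lag, fit.structure)
            c = cho_factor(V, lower=True, check_finite=False)
            for idx in idx_list:  # idx: positions within the sorted arrays
                r_k = resid[idx]
                Vir = cho_solve(c, r_k, check_finite=False)
                gamma_hat = vc.sigma_gamma**2 * float(np.sum(Vir))
                subj_codes = pd.factorize(data.subjects[idx])[0]
                h_sums = np.bincount(subj_codes, weights=Vir)
                h_hat = vc.sigma_h**2 * h_sums[subj_codes]
                adj[idx] = gamma_hat + h_hat
        fitted_sorted = fitted_sorted + adj
    out = np.empty_like(fitted_sorted)
    out[data.order] = fitted_sorted
    return out
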