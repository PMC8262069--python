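"""Multi-kernel linear mixed models fitted by restricted maximum likelihood.

The model is y = X b + sum_k u_k + e with u_k ~ MVN(0, K_k s2_k) over the
phenotyped subset of a shared animal index and e ~ MVN(0, I s2_E). Variance
components are estimated by average-information (AI) REML with EM-REML
fallback steps whenever an AI update would leave the feasible region or
decrease the restricted likelihood; standard errors come from the inverse AI
matrix. BLUPs are computed for every animal in the kernel index, phenotyped
or not, via u_k = s2_k K_k[:, obs] P y.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from scipy.linalg.lapack import dpotri

from epiblup.kernels import KernelSet

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class MixedModelSpec:
    """Response, fixed-effect design and kernels for one single-trait model.

    ``obs_indices[i]`` maps phenotype record i to its row in the shared
    kernel animal index; the residual covariance is I * s2_E.
    """

    y: np.ndarray
    X: np.ndarray
    kernels: KernelSet
    obs_indices: np.ndarray
    x_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.obs_indices = np.asarray(self.obs_indices, dtype=int)
        n = self.y.size
        if self.X.shape[0] != n or self.obs_indices.size != n:
            raise ValueError("y, X and obs_indices must agree on record count")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("fixed-effect design X is rank deficient")
        if len(self.kernels):
            n_idx = len(self.kernels.animal_ids)
            if self.obs_indices.min() < 0 or self.obs_indices.max() >= n_idx:
                raise ValueError("obs_indices out of kernel index range")
            if np.unique(self.obs_indices).size != n:
                raise ValueError("each record must map to exactly one animal")

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def kernel_names(self) -> list[str]:
        return list(self.kernels.keys())

    def obs_kernels(self) -> list[np.ndarray]:
        """Kernel blocks restricted to phenotyped records."""
        ix = self.obs_indices
        return [k.matrix[np.ix_(ix, ix)] for k in self.kernels.values()]


@dataclass
class FitResult:
    varcomps: dict[str, tuple[float, float]]
    beta: np.ndarray
    beta_se: np.ndarray
    blups: dict[str, np.ndarray]
    residuals: np.ndarray
    loglik_restricted: float
    aic: float
    ai_covariance: np.ndarray
    converged: bool
    n_iter: int
    final_gradient_norm: float
    boundary: dict[str, bool]
    x_names: list[str] | None = None
    design_meta: object = None
    _spec: MixedModelSpec | None = field(default=None, repr=False)
    _Py: np.ndarray | None = field(default=None, repr=False)

    @property
    def sigma2(self) -> dict[str, float]:
        return {k: v[0] for k, v in self.varcomps.items()}

    def total_variance(self) -> float:
        return float(sum(v[0] for v in self.varcomps.values()))


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------


def _factor_V(Gs: list[np.ndarray], sigmas: np.ndarray, n: int):
    V = np.eye(n) * sigmas[-1]
    for G, s in zip(Gs, sigmas[:-1]):
        if s != 0.0:
            V += s * G
    try:
        c = cho_factor(V, lower=True, check_finite=False)
    except LinAlgError:
        jitter = 1e-8 * np.mean(np.diag(V))
        logger.warning("V factorization failed; adding jitter %.3g", jitter)
        V[np.diag_indices_from(V)] += jitter
        try:
            c = cho_factor(V, lower=True, check_finite=False)
        except LinAlgError as exc:
            cond = np.linalg.cond(V)
            raise LinAlgError(
                f"V is singular even after jitter (condition number {cond:.3g})"
            ) from exc
    logdet_V = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    return V, c, logdet_V


def _profile_fixed(c, logdet_V, y, X):
    """Profile fixed effects out of the likelihood given a factorized V."""
    ViY = cho_solve(c, np.column_stack([y, X]), check_finite=False)
    Viy, ViX = ViY[:, 0], ViY[:, 1:]
    C = X.T @ ViX  # X' V^-1 X
    cc = cho_factor(C, lower=True, check_finite=False)
    logdet_C = 2.0 * float(np.sum(np.log(np.diag(cc[0]))))
    beta = cho_solve(cc, X.T @ Viy, check_finite=False)
    Py = Viy - ViX @ beta
    n, p = X.shape
    yPy = float(y @ Py)
    ll = -0.5 * ((n - p) * _LOG2PI + logdet_V + logdet_C + yPy)
    return ll, beta, Py, ViX, cc


def restricted_loglik(spec: MixedModelSpec, sigmas) -> float:
    """Restricted log-likelihood of y under the given variance components,
    fixed effects profiled out."""
    sigmas = np.asarray(sigmas, dtype=float)
    if sigmas.size != len(spec.kernels) + 1:
        raise ValueError(
            f"expected {len(spec.kernels) + 1} variance components "
            f"(kernels + residual), got {sigmas.size}"
        )
    if np.any(sigmas < 0) or sigmas[-1] <= 0:
        raise ValueError("variance components must be >= 0 with residual > 0")
    _, c, logdet_V = _factor_V(spec.obs_kernels(), sigmas, spec.n_obs)
    ll, *_ = _profile_fixed(c, logdet_V, spec.y, spec.X)
    return ll


def _reml_state(y, X, Gs, sigmas):
    """Loglik, gradient, AI matrix and EM ingredients at one parameter point."""
    n = y.size
    _, c, logdet_V = _factor_V(Gs, sigmas, n)
    ll, beta, Py, ViX, cc = _profile_fixed(c, logdet_V, y, X)
    # explicit V^-1 for exact traces (dpotri reuses the Cholesky factor)
    Vinv, info = dpotri(c[0], lower=True)
    if info != 0:
        raise LinAlgError(f"dpotri failed with info={info}")
    Vinv = np.tril(Vinv) + np.tril(Vinv, -1).T
    Cinv_XtVi = cho_solve(cc, ViX.T, check_finite=False)  # C^-1 X' V^-1

    n_par = len(Gs) + 1
    grad = np.empty(n_par)
    yPGPy = np.empty(n_par)
    trPG = np.empty(n_par)
    t_vecs = []
    for k in range(n_par):
        G = Gs[k] if k < len(Gs) else None
        if G is None:
            tr_ViG = float(np.trace(Vinv))
            corr = float(np.einsum("ij,ji->", Cinv_XtVi, ViX))
            t = Py.copy()
        else:
            tr_ViG = float(np.einsum("ij,ji->", Vinv, G))
            GViX = G @ ViX
            corr = float(np.einsum("ij,ji->", Cinv_XtVi, GViX))
            t = G @ Py
        trPG[k] = tr_ViG - corr
        yPGPy[k] = float(t @ Py)
        grad[k] = -0.5 * (trPG[k] - yPGPy[k])
        t_vecs.append(t)

    AI = np.empty((n_par, n_par))
    Pt = []
    for t in t_vecs:
        Pt.append(Vinv @ t - ViX @ (Cinv_XtVi @ t))
    for k in range(n_par):
        for l in range(k, n_par):
            AI[k, l] = AI[l, k] = 0.5 * float(t_vecs[k] @ Pt[l])
    return {
        "ll": ll,
        "beta": beta,
        "Py": Py,
        "grad": grad,
        "AI": AI,
        "yPGPy": yPGPy,
        "trPG": trPG,
        "cc": cc,
    }


def _loglik_cheap(y, X, Gs, sigmas) -> float:
    _, c, logdet_V = _factor_V(Gs, sigmas, y.size)
    ll, *_ = _profile_fixed(c, logdet_V, y, X)
    return ll


def _em_step(sigmas: np.ndarray, state: dict, n: int) -> np.ndarray:
    """EM-REML update; stays positive and never decreases the likelihood."""
    new = sigmas.copy()
    for k in range(sigmas.size):
        new[k] = sigmas[k] + sigmas[k] ** 2 * (
            state["yPGPy"][k] - state["trPG"][k]
        ) / n
    return new


def fit_reml(
    spec: MixedModelSpec,
    max_iter: int = 200,
    tol_loglik: float = 1e-8,
    tol_param: float = 1e-6,
    algorithm: str = "ai",
    start: np.ndarray | None = None,
    verbose: bool = False,
) -> FitResult:
    """Estimate variance components, fixed effects and BLUPs by REML.

    ``algorithm='ai'`` uses average-information updates with step halving and
    EM fallback (the default); ``'em'`` uses pure EM-REML. The fit is
    deterministic given its inputs.
    """
    if algorithm not in ("ai", "em"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    y, X = spec.y, spec.X
    n, p = X.shape
    Gs = spec.obs_kernels()
    n_k = len(Gs)
    n_par = n_k + 1
    if n <= p + n_k:
        warnings.warn(
            f"only {n} records for {p} fixed effects and {n_k} kernels; "
            "variance components may not be identifiable",
            stacklevel=2,
        )

    vary = float(np.var(y, ddof=1)) if n > 1 else 1.0
    floor = max(1e-10 * vary, 1e-300)
    sigmas = start.astype(float).copy() if start is not None else np.full(
        n_par, vary / n_par
    )
    sigmas = np.maximum(sigmas, floor)

    state = _reml_state(y, X, Gs, sigmas)
    ll = state["ll"]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        accepted = False
        if algorithm == "ai":
            # active-set AI step: components pinned at the zero boundary with
            # a negative gradient are frozen out of the update
            grad, AI = state["grad"], state["AI"]
            frozen = (sigmas <= 10 * floor) & (grad < 0)
            frozen[-1] = False
            act = np.flatnonzero(~frozen)
            delta = np.zeros(n_par)
            try:
                delta[act] = np.linalg.solve(AI[np.ix_(act, act)], grad[act])
            except np.linalg.LinAlgError:
                delta[act] = np.linalg.lstsq(
                    AI[np.ix_(act, act)], grad[act], rcond=None
                )[0]
            candidates = []
            # scale the step to stop exactly at the nearest zero boundary,
            # pinning the binding component there
            neg = np.flatnonzero(delta < 0)
            if neg.size and np.any(sigmas[neg] + delta[neg] < floor):
                alpha = float(np.min((sigmas[neg] - floor) / -delta[neg]))
                if 0 < alpha < 1:
                    bound = sigmas + alpha * delta
                    candidates.append(np.maximum(bound, floor))
            # the AI matrix is PSD, so some fraction of the Newton step is an
            # ascent direction; halve deep before giving up to EM
            for s in (1.0, 0.5, 0.25, 0.125, 2**-4, 2**-5, 2**-6, 2**-8, 2**-10):
                candidates.append(sigmas + s * delta)
            for cand in candidates:
                if np.any(cand[:-1] < 0) or cand[-1] <= 0:
                    continue
                cand = np.maximum(cand, floor)
                try:
                    cand_ll = _loglik_cheap(y, X, Gs, cand)
                except LinAlgError:
                    cand_ll = -np.inf
                if cand_ll >= ll - 1e-10:
                    new_sigmas, new_ll, accepted = cand, cand_ll, True
                    break
        if not accepted:
            cand = np.maximum(_em_step(sigmas, state, n), floor)
            new_sigmas = cand
            new_ll = _loglik_cheap(y, X, Gs, cand)
        if verbose:
            logger.info("iter %d: loglik %.8f sigmas %s", it, new_ll, new_sigmas)
        d_ll = new_ll - ll
        d_par = np.max(np.abs(new_sigmas - sigmas)) / max(np.sum(sigmas), floor)
        sigmas, ll = new_sigmas, new_ll
        state = _reml_state(y, X, Gs, sigmas)
        if abs(d_ll) < tol_loglik * (1.0 + abs(ll)) and d_par < tol_param:
            # guard against EM plateaus: a free component with a sizeable
            # scaled gradient means the optimum is not reached yet
            scaled_grad = np.abs(state["grad"]) * np.maximum(sigmas, floor)
            at_floor = sigmas <= 10 * floor
            if np.max(np.where(at_floor, 0.0, scaled_grad)) < 1e-4 * (1 + abs(ll)):
                converged = True
                break
    if not converged:
        logger.warning(
            "REML did not converge in %d iterations (gradient norm %.3g)",
            max_iter,
            float(np.linalg.norm(state["grad"])),
        )

    total = float(np.sum(sigmas))
    boundary_flags = [s <= max(1e-6 * total, 2 * floor) for s in sigmas]

    # SEs from the inverse AI matrix; invalid on the zero boundary
    try:
        ai_cov = np.linalg.inv(state["AI"])
    except np.linalg.LinAlgError:
        ai_cov = np.linalg.pinv(state["AI"])
    ses = np.sqrt(np.maximum(np.diag(ai_cov), 0.0))
    for k, b in enumerate(boundary_flags):
        if b:
            ses[k] = np.nan
            ai_cov[k, :] = np.nan
            ai_cov[:, k] = np.nan

    names = spec.kernel_names + ["residual"]
    varcomps = {nm: (float(sigmas[k]), float(ses[k])) for k, nm in enumerate(names)}

    beta = state["beta"]
    beta_cov = cho_solve(state["cc"], np.eye(p), check_finite=False)
    beta_se = np.sqrt(np.diag(beta_cov))

    Py = state["Py"]
    blups: dict[str, np.ndarray] = {}
    for k, (nm, kern) in enumerate(spec.kernels.items()):
        blups[nm] = sigmas[k] * (kern.matrix[:, spec.obs_indices] @ Py)
    fitted = X @ beta
    for k, nm in enumerate(spec.kernel_names):
        fitted = fitted + blups[nm][spec.obs_indices]
    residuals = y - fitted

    aic = -2.0 * ll + 2.0 * n_par
    return FitResult(
        varcomps=varcomps,
        beta=beta,
        beta_se=beta_se,
        blups=blups,
        residuals=residuals,
        loglik_restricted=float(ll),
        aic=float(aic),
        ai_covariance=ai_cov,
        converged=converged,
        n_iter=it,
        final_gradient_norm=float(np.linalg.norm(state["grad"])),
        boundary=dict(zip(names, boundary_flags)),
        x_names=spec.x_names,
        _spec=spec,
        _Py=Py,
    )


def aic(fit: FitResult) -> float:
    """AIC = -2 * restricted loglik + 2 * (number of variance components)."""
    return fit.aic


def variance_proportions(fit: FitResult) -> dict[str, tuple[float, float]]:
    """Each component's share of total variance, with delta-method SEs."""
    names = list(fit.varcomps)
    s = np.array([fit.varcomps[nm][0] for nm in names])
    total = float(s.sum())
    if total <= 0:
        raise ValueError("total estimated variance is not positive")
    props = s / total
    cov = fit.ai_covariance
    out: dict[str, tuple[float, float]] = {}
    for k, nm in enumerate(names):
        grad = -s[k] / total**2 * np.ones(len(names))
        grad[k] += 1.0 / total
        var = float(grad @ np.nan_to_num(cov, nan=0.0) @ grad)
        se = np.nan if np.isnan(cov[k, k]) else float(np.sqrt(max(var, 0.0)))
        out[nm] = (float(props[k]), se)
    return out


def predict_unphenotyped(fit: FitResult, target_ids: list[str]) -> dict[str, np.ndarray]:
    """BLUP extrapolation to arbitrary animals in the kernel index.

    Returns per-kernel genetic values plus their sum under key ``'total'``;
    phenotyped animals get exactly their in-fit BLUPs.
    """
    spec = fit._spec
    if spec is None or fit._Py is None:
        raise ValueError("fit does not carry prediction state")
    index = {a: i for i, a in enumerate(spec.kernels.animal_ids)}
    missing = [t for t in target_ids if t not in index]
    if missing:
        raise KeyError(f"animal {missing[0]!r} absent from the kernel index")
    rows = np.asarray([index[t] for t in target_ids])
    out: dict[str, np.ndarray] = {}
    total = np.zeros(rows.size)
    for k, (nm, kern) in enumerate(spec.kernels.items()):
        s2 = fit.varcomps[nm][0]
        u = s2 * (kern.matrix[np.ix_(rows, spec.obs_indices)] @ fit._Py)
        out[nm] = u
        total += u
    out["total"] = total
    return out
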