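"""Gaussian-mixture clustering with EM, MDL model-order selection and
agglomerative component merging.

The clustering starts from an initial component count c0, runs EM to an
MDL-change tolerance, records the converged MDL value, merges the pair of
components whose pooling raises the description length least, and repeats
down to a single component.  The component count with the smallest recorded
MDL wins, and samples are labelled by maximum likelihood under that model.

The description length of a model with c components on N samples in M
dimensions is

    MDL(c, Omega) = -sum_i log sum_k pi_k N(z_i; mu_k, Sigma_k)
                    + 0.5 * nu * log(N*M),

with nu = c*(M + M*(M+1)/2 + 1) - 1 free parameters (means, symmetric
covariances and priors, minus one for the prior sum constraint); natural
logarithms throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["GMMParams", "ClusterResult", "mdl_value", "em_fit", "merge_step",
           "gmm_cluster", "ml_classify", "em_epsilon", "n_free_params"]

_COV_COND_LIMIT = 1e10
_COV_RIDGE = 1e-8
_EMPTY_MASS = 1e-10
# Component covariance eigenvalues are floored at this fraction of the
# data's pooled per-dimension variance: prevents the classic likelihood
# blow-up of a component collapsing onto one sample, while staying far
# below any genuine between-cluster separation.
_COV_FLOOR_FRAC = 0.01


@dataclass
class GMMParams:
    """Mixture parameters: prior weights, component means and covariances."""

    pi: np.ndarray  # (c,)
    mu: np.ndarray  # (c, M)
    Sigma: np.ndarray  # (c, M, M)

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=float))
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        if self.Sigma.ndim == 2:
            self.Sigma = self.Sigma[None]
        if not math.isclose(self.pi.sum(), 1.0, abs_tol=1e-8):
            raise ValueError("component priors must sum to 1")
        if np.any(self.pi < 0):
            raise ValueError("component priors must be nonnegative")

    @property
    def c(self) -> int:
        return len(self.pi)

    @property
    def M(self) -> int:
        return self.mu.shape[1]


@dataclass
class ClusterResult:
    """Outcome of MDL-guided agglomerative GMM clustering."""

    c_hat: int
    omega_hat: GMMParams
    labels: np.ndarray  # 1-based component assignments
    mdl_by_c: dict[int, float]
    trace: list[dict] = field(default_factory=list)


def n_free_params(c: int, M: int) -> int:
    """Continuously valued parameters of a c-component full-covariance GMM."""
    return c * (M + M * (M + 1) // 2 + 1) - 1


def em_epsilon(N: int, M: int) -> float:
    """EM convergence tolerance on the MDL change:
    0.01 * (1 + M + (M+1)M/2) * log(N*M)."""
    return 0.01 * (1 + M + (M + 1) * M / 2) * math.log(N * M)


def _pooled_floor(Z: np.ndarray) -> float:
    """Covariance-eigenvalue floor derived from the data's pooled variance."""
    v = float(np.mean(np.var(Z, axis=0)))
    return max(_COV_FLOOR_FRAC * v, 1e-30)


def _regularize(Sigma: np.ndarray, floor: float = 0.0) -> np.ndarray:
    """Floor a covariance's eigenvalues and ridge it if ill-conditioned."""
    S = (Sigma + Sigma.T) / 2
    ev = np.linalg.eigvalsh(S)
    lift = 0.0
    if ev[0] < floor:
        lift = floor - ev[0]
    elif ev[0] <= 0 or ev[-1] / max(ev[0], 1e-300) > _COV_COND_LIMIT:
        ridge = _COV_RIDGE * max(np.trace(S) / S.shape[0], 1e-30)
        target = ev[-1] / _COV_COND_LIMIT if ev[-1] > 0 else ridge
        lift = max(ridge, target - min(ev[0], 0.0))
    if lift > 0:
        S = S + lift * np.eye(S.shape[0])
    return S


def _log_gauss(Z: np.ndarray, mu: np.ndarray, Sigma: np.ndarray,
               floor: float = 0.0) -> np.ndarray:
    M = Z.shape[1]
    S = _regularize(Sigma, floor)
    chol = np.linalg.cholesky(S)
    sol = np.linalg.solve(chol, (Z - mu).T)
    maha = np.sum(sol**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (M * math.log(2 * math.pi) + logdet + maha)


def _log_joint(Z: np.ndarray, omega: GMMParams, floor: float = 0.0) -> np.ndarray:
    """log(pi_k) + log N(z_i; ...) as an (N, c) matrix."""
    out = np.full((Z.shape[0], omega.c), -np.inf)
    for k in range(omega.c):
        if omega.pi[k] > 0:
            out[:, k] = math.log(omega.pi[k]) + _log_gauss(Z, omega.mu[k], omega.Sigma[k], floor)
    return out


def mdl_value(Z: np.ndarray, omega: GMMParams) -> float:
    """Description length of the mixture on the data (natural log)."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    N, M = Z.shape
    lj = _log_joint(Z, omega, _pooled_floor(Z))
    mx = lj.max(axis=1)
    loglik = np.sum(mx + np.log(np.sum(np.exp(lj - mx[:, None]), axis=1)))
    nu = n_free_params(omega.c, M)
    return -loglik + 0.5 * nu * math.log(N * M)


def em_fit(Z: np.ndarray, omega_init: GMMParams, epsilon: float | None = None,
           max_iters: int = 500, trace: list | None = None) -> GMMParams:
    """EM updates until the MDL change drops below the tolerance.

    Components whose responsibility mass collapses are removed (c is
    decremented) and priors renormalized.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    N, M = Z.shape
    if epsilon is None:
        epsilon = em_epsilon(N, M)
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    floor = _pooled_floor(Z)
    pi = omega_init.pi.copy()
    mu = omega_init.mu.copy()
    Sig = np.array([_regularize(S, floor) for S in omega_init.Sigma])
    omega = GMMParams(pi, mu, Sig)
    prev = mdl_value(Z, omega)
    for _ in range(max_iters):
        lj = _log_joint(Z, omega, floor)
        mx = lj.max(axis=1)
        lse = mx + np.log(np.sum(np.exp(lj - mx[:, None]), axis=1))
        R = np.exp(lj - lse[:, None])  # responsibilities (N, c)
        mass = R.sum(axis=0)
        keep = mass > _EMPTY_MASS
        if not np.all(keep):
            R = R[:, keep]
            mass = mass[keep]
        c = R.shape[1]
        pi = mass / N
        mu = (R.T @ Z) / mass[:, None]
        Sig = np.empty((c, M, M))
        for k in range(c):
            d = Z - mu[k]
            Sig[k] = _regularize((R[:, k][:, None] * d).T @ d / mass[k], floor)
        omega = GMMParams(pi, mu, Sig)
        cur = mdl_value(Z, omega)
        if trace is not None:
            trace.append({"c": c, "mdl": cur})
        if abs(prev - cur) < epsilon:
            break
        prev = cur
    return omega


def _pool(pi_k, mu_k, S_k, pi_l, mu_l, S_l):
    pi_m = pi_k + pi_l
    wk, wl = pi_k / pi_m, pi_l / pi_m
    mu_m = wk * mu_k + wl * mu_l
    dk, dl = (mu_k - mu_m)[:, None], (mu_l - mu_m)[:, None]
    S_m = wk * (S_k + dk @ dk.T) + wl * (S_l + dl @ dl.T)
    return pi_m, mu_m, S_m


def merge_step(Z: np.ndarray, omega: GMMParams) -> GMMParams:
    """Merge the pair of components with the smallest description-length
    increase upper bound

        d(k,l) = N*pi_k/2 * log(|S_m|/|S_k|) + N*pi_l/2 * log(|S_m|/|S_l|),

    where S_m is the moment-matched pooled covariance.  Returns a model with
    one component fewer, to seed the next EM run.
    """
    if omega.c < 2:
        raise ValueError("need at least 2 components to merge")
    Zm = np.atleast_2d(Z)
    N = Zm.shape[0]
    floor = _pooled_floor(Zm)

    def logdet(S):
        return float(np.linalg.slogdet(_regularize(S, floor))[1])

    best, best_pair, best_merged = np.inf, None, None
    for k in range(omega.c):
        for l in range(k + 1, omega.c):
            pi_m, mu_m, S_m = _pool(omega.pi[k], omega.mu[k], omega.Sigma[k],
                                    omega.pi[l], omega.mu[l], omega.Sigma[l])
            d = (N * omega.pi[k] / 2) * (logdet(S_m) - logdet(omega.Sigma[k])) \
                + (N * omega.pi[l] / 2) * (logdet(S_m) - logdet(omega.Sigma[l]))
            if d < best:
                best, best_pair, best_merged = d, (k, l), (pi_m, mu_m, S_m)
    k, l = best_pair
    keep = [i for i in range(omega.c) if i not in (k, l)]
    pi = np.append(omega.pi[keep], best_merged[0])
    mu = np.vstack([omega.mu[keep], best_merged[1]]) if keep else best_merged[1][None]
    Sig = np.concatenate([omega.Sigma[keep], best_merged[2][None]]) if keep \
        else best_merged[2][None]
    return GMMParams(pi / pi.sum(), mu, Sig)


def _init_params(Z: np.ndarray, c0: int) -> GMMParams:
    """Deterministic k-means-style seeding: centers by farthest-point
    traversal, then one hard assignment; each component takes its cluster's
    moments (pooled covariance fallback for clusters too small to estimate
    one).  Sharp initial covariances keep the early EM steps making enough
    MDL progress to clear the convergence tolerance."""
    N, M = Z.shape
    centroid = Z.mean(axis=0)
    first = int(np.argmax(np.sum((Z - centroid) ** 2, axis=1)))
    centers = [first]
    while len(centers) < c0:
        d2 = np.min([np.sum((Z - Z[c]) ** 2, axis=1) for c in centers], axis=0)
        centers.append(int(np.argmax(d2)))
    pooled = np.cov(Z.T, bias=True).reshape(M, M)
    pooled = pooled + 1e-6 * max(np.trace(pooled), 1e-12) * np.eye(M)
    d2 = np.stack([np.sum((Z - Z[c]) ** 2, axis=1) for c in centers])
    assign = np.argmin(d2, axis=0)
    pi = np.empty(c0)
    mu = np.empty((c0, M))
    Sig = np.empty((c0, M, M))
    for k in range(c0):
        members = Z[assign == k]
        pi[k] = max(len(members), 1) / N
        mu[k] = members.mean(axis=0) if len(members) else Z[centers[k]]
        if len(members) > M:
            S = np.cov(members.T, bias=True).reshape(M, M)
            Sig[k] = S + 1e-6 * max(np.trace(S), np.trace(pooled) * 1e-3, 1e-12) * np.eye(M)
        else:
            Sig[k] = pooled
    return GMMParams(pi / pi.sum(), mu, Sig)


def gmm_cluster(Z: np.ndarray, c0: int = 2) -> ClusterResult:
    """Agglomerative GMM clustering with MDL model-order selection.

    Fits EM at c0 components, then repeatedly merges and refits down to one
    component, recording the converged MDL at each count; the count with the
    minimum MDL is selected and samples are labelled by maximum likelihood.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    N = Z.shape[0]
    if c0 < 1:
        raise ValueError("c0 must be >= 1")
    c0 = min(c0, N)
    trace: list[dict] = []
    omega = em_fit(Z, _init_params(Z, c0), trace=trace)
    mdl_by_c = {omega.c: mdl_value(Z, omega)}
    models = {omega.c: omega}
    while omega.c > 1:
        omega = em_fit(Z, merge_step(Z, omega), trace=trace)
        val = mdl_value(Z, omega)
        if omega.c not in mdl_by_c or val < mdl_by_c[omega.c]:
            mdl_by_c[omega.c] = val
            models[omega.c] = omega
    c_hat = min(mdl_by_c, key=lambda c: (mdl_by_c[c], c))
    best = models[c_hat]
    labels = ml_classify(Z, best)
    return ClusterResult(c_hat=c_hat, omega_hat=best, labels=labels,
                         mdl_by_c=mdl_by_c, trace=trace)


def ml_classify(Z: np.ndarray, omega: GMMParams) -> np.ndarray:
    """1-based maximum-likelihood component assignment
    (argmax_k pi_k N(z; mu_k, Sigma_k); ties go to the lowest index)."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    lj = _log_joint(Z, omega)
    return np.argmax(lj, axis=1) + 1
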