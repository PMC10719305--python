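"""Sparse finite mixture of accelerated failure time (AFT) regressions.

Model. Log survival time y = log t follows, within latent component k of K,
a normal linear model y = beta0_k + x' beta_k + sigma_k eps. With
right-censoring indicator delta (1 = event observed) the observed-data
likelihood contribution of subject i is

    sum_k pi_k f_k(y_i)^delta_i S_k(y_i)^(1 - delta_i),

where f_k and S_k are the normal density and survival function at the
component's linear predictor. Component-specific coefficient vectors are
typically sparse: a gene may affect survival in one subpopulation only.

Estimation. An EM algorithm with two nested expectations: the outer E-step
computes posterior component memberships tau_ik from the censoring-aware
likelihood; the inner E-step replaces each censored outcome by its truncated
-normal first and second conditional moments, after which the M-step is a
penalized weighted least-squares problem per component. Sparsity comes from
the SCAD penalty, handled by local quadratic approximation (LQA) with hard
zeroing; coefficients that hit zero stay excluded for the remainder of that
EM run. Per-component tuning parameters are chosen by a component-wise BIC
with effective sample size sum_i tau_ik, and the number of components by an
overall BIC over the tuned fits.

The mixing-proportion update maximizes the full penalized expected
log-likelihood (a one-dimensional root-find on the simplex Lagrange
multiplier), so the penalized observed log-likelihood is non-decreasing
across EM iterations by the usual MM/ECM argument.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp
from scipy.stats import norm
from sklearn.cluster import KMeans

from .survival_data import SurvivalDataset

logger = logging.getLogger(__name__)

__all__ = [
    "MixtureAFTModel",
    "PenaltyConfig",
    "FitResult",
    "OrderSelection",
    "DegenerateComponentError",
    "component_loglik",
    "mixture_loglik",
    "penalized_loglik",
    "scad",
    "scad_deriv",
    "e_step",
    "censored_moments",
    "m_step",
    "fit_em",
    "tune_lambdas",
    "select_order",
    "classify",
    "active_genes",
    "default_lambda_grid",
]

ZERO_THRESHOLD = 1e-8


class DegenerateComponentError(RuntimeError):
    """A mixture component collapsed below the effective-weight floor."""


@dataclass
class MixtureAFTModel:
    """Parameters of a K-component mixture of log-normal AFT regressions."""

    K: int
    pi: np.ndarray       # (K,) mixing proportions
    beta0: np.ndarray    # (K,) intercepts
    beta: np.ndarray     # (K, p) coefficients
    sigma: np.ndarray    # (K,) scales
    gene_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.beta0 = np.asarray(self.beta0, dtype=float)
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not self.gene_names:
            self.gene_names = [f"g{j + 1:03d}" for j in range(self.beta.shape[1])]

    @property
    def p(self) -> int:
        return self.beta.shape[1]

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        """n x K matrix of component means."""
        return self.beta0[None, :] + X @ self.beta.T


@dataclass
class PenaltyConfig:
    """SCAD penalty configuration; one tuning parameter per component."""

    lam: np.ndarray
    a: float = 3.7
    penalize_intercept: bool = False

    def __post_init__(self) -> None:
        self.lam = np.atleast_1d(np.asarray(self.lam, dtype=float))
        if self.a <= 2:
            raise ValueError("SCAD shape parameter a must exceed 2")
        if (self.lam < 0).any():
            raise ValueError("lambda must be nonnegative")


@dataclass
class FitResult:
    model: MixtureAFTModel
    tau: np.ndarray
    loglik_trace: np.ndarray
    bic: float
    converged: bool
    n_iter: int
    active: list[list[str]]
    penalty: PenaltyConfig | None = None
    loglik: float = np.nan


@dataclass
class OrderSelection:
    K_values: list[int]
    bic_per_K: list[float]
    best_K: int
    fits: dict[int, FitResult]
    errors: dict[int, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# likelihood pieces

def component_loglik(y, delta, mu, sigma):
    """Censoring-aware normal log-likelihood, elementwise.

    delta = 1: log normal density at y; delta = 0: log upper-tail probability
    (computed in log space, so deep right tails stay finite).
    """
    y = np.asarray(y, dtype=float)
    delta = np.asarray(delta)
    if np.any(np.asarray(sigma) <= 0):
        raise ValueError("sigma must be positive")
    z = (y - mu) / sigma
    dens = norm.logpdf(z) - np.log(sigma)
    surv = norm.logsf(z)
    return np.where(delta == 1, dens, surv)


def _loglik_matrix(dataset: SurvivalDataset, model: MixtureAFTModel) -> np.ndarray:
    mu = model.linear_predictor(dataset.X)
    return component_loglik(dataset.y[:, None], dataset.delta[:, None],
                            mu, model.sigma[None, :])


def mixture_loglik(dataset: SurvivalDataset, model: MixtureAFTModel) -> float:
    """Observed-data log-likelihood, via log-sum-exp over components."""
    ll = _loglik_matrix(dataset, model)
    return float(logsumexp(ll + np.log(model.pi)[None, :], axis=1).sum())


def scad(theta, lam, a: float = 3.7):
    """SCAD penalty value, elementwise.

    Linear (lam |theta|) up to lam, concave quadratic up to a*lam, then the
    constant lam^2 (a + 1)/2.
    """
    t = np.abs(np.asarray(theta, dtype=float))
    lam = float(lam)
    if lam == 0.0:
        return np.zeros_like(t) if t.ndim else 0.0
    mid = (2 * a * lam * t - t**2 - lam**2) / (2 * (a - 1))
    out = np.where(t <= lam, lam * t,
                   np.where(t <= a * lam, mid, lam**2 * (a + 1) / 2))
    return out if out.ndim else float(out)


def scad_deriv(theta, lam, a: float = 3.7):
    """Derivative of the SCAD penalty with respect to |theta| (|theta| > 0)."""
    t = np.abs(np.asarray(theta, dtype=float))
    lam = float(lam)
    if lam == 0.0:
        return np.zeros_like(t) if t.ndim else 0.0
    out = np.where(t <= lam, lam,
                   np.where(t <= a * lam, np.maximum(a * lam - t, 0.0) / (a - 1), 0.0))
    return out if out.ndim else float(out)


def _penalty_value(model: MixtureAFTModel, penalty: PenaltyConfig) -> float:
    tot = 0.0
    for k in range(model.K):
        pk = float(np.sum(scad(model.beta[k], penalty.lam[k], penalty.a)))
        if penalty.penalize_intercept:
            pk += float(scad(model.beta0[k], penalty.lam[k], penalty.a))
        tot += model.pi[k] * pk
    return tot


def penalized_loglik(dataset: SurvivalDataset, model: MixtureAFTModel,
                     penalty: PenaltyConfig) -> float:
    """mixture_loglik minus n * sum_k pi_k * SCAD(beta_k)."""
    return mixture_loglik(dataset, model) - dataset.n * _penalty_value(model, penalty)


def e_step(dataset: SurvivalDataset, model: MixtureAFTModel) -> np.ndarray:
    """Posterior membership probabilities tau (n x K), computed in log space."""
    logp = _loglik_matrix(dataset, model) + np.log(model.pi)[None, :]
    bad = ~np.isfinite(logp).any(axis=1)
    if bad.any():
        raise ValueError(f"zero likelihood under every component for "
                         f"observations {np.flatnonzero(bad).tolist()}")
    return np.exp(logp - logsumexp(logp, axis=1, keepdims=True))


def censored_moments(y, mu, sigma):
    """Conditional moments of a normal outcome known to exceed y.

    Returns (m1, m2) with m1 = E[Y | Y > y] = mu + sigma * h(z) and
    m2 = E[Y^2 | Y > y] = mu^2 + sigma^2 + (y + mu) * sigma * h(z), where
    h(z) = phi(z)/Phibar(z) is the normal hazard at z = (y - mu)/sigma,
    evaluated via log densities so large z stays stable.
    """
    y = np.asarray(y, dtype=float)
    if np.any(np.asarray(sigma) <= 0):
        raise ValueError("sigma must be positive")
    z = (y - mu) / sigma
    h = np.exp(norm.logpdf(z) - norm.logsf(z))
    m1 = mu + sigma * h
    m2 = mu**2 + sigma**2 + (y + mu) * sigma * h
    return m1, m2


# ---------------------------------------------------------------------------
# M-step

def _pseudo_outcomes(y, delta, mu, sigma):
    """Event outcomes as-is; censored replaced by truncated-normal moments."""
    m1, m2 = censored_moments(y, mu, sigma)
    t1 = np.where(delta == 1, y, m1)
    t2 = np.where(delta == 1, y**2, m2)
    return t1, t2


def _solve_penalized_wls(A, w, t1, ridge_diag):
    """Maximize the weighted quadratic with an added ridge from LQA."""
    Aw = A * w[:, None]
    H = A.T @ Aw
    H[np.diag_indices_from(H)] += ridge_diag
    # tiny absolute jitter guards rank deficiency without moving the solution
    H[np.diag_indices_from(H)] += 1e-10 * (np.trace(H) / H.shape[0] + 1.0) * 1e-2
    return np.linalg.solve(H, Aw.T @ t1)


def m_step(
    dataset: SurvivalDataset,
    tau: np.ndarray,
    penalty: PenaltyConfig,
    current: MixtureAFTModel,
    active_mask: np.ndarray | None = None,
    sigma_floor: float | None = None,
    min_component_weight: float = 5.0,
    n_lqa: int = 3,
    zero_threshold: float = ZERO_THRESHOLD,
    ridge_eps: float = 0.0,
    sigma_collapse: float | None = None,
):
    """One ECM step: update pi, then (beta0, beta) by SCAD-penalized WLS
    with LQA, then sigma from the tau-weighted second moments.

    ``active_mask`` (K x p bool) marks coefficients still in play; entries
    hard-zeroed here are switched off in the returned mask. Components whose
    effective weight sum_i tau_ik falls below ``min_component_weight`` raise
    :class:`DegenerateComponentError`; so does a fitted scale below
    ``sigma_collapse`` (when set) — a sign the component is interpolating its
    own events and spiking the likelihood. ``ridge_eps`` adds a relative
    ridge to the normal equations (used by the unpenalized warm-up in high
    dimensions).
    """
    X, y, delta = dataset.X, dataset.y, dataset.delta
    n, p = X.shape
    K = current.K
    if active_mask is None:
        active_mask = np.ones((K, p), dtype=bool)
    active_mask = active_mask.copy()
    if sigma_floor is None:
        sigma_floor = 1e-4 * float(np.std(y))

    n_k = tau.sum(axis=0)
    low = n_k < min_component_weight
    if low.any():
        raise DegenerateComponentError(
            f"component(s) {np.flatnonzero(low).tolist()} have effective weight "
            f"{n_k[low].round(2).tolist()} < {min_component_weight}"
        )

    # pi update: maximize sum_k n_k log pi_k - n pi_k P_k on the simplex.
    P = np.array([
        float(np.sum(scad(current.beta[k], penalty.lam[k], penalty.a)))
        + (float(scad(current.beta0[k], penalty.lam[k], penalty.a))
           if penalty.penalize_intercept else 0.0)
        for k in range(K)
    ])
    if np.all(P * n < 1e-12):
        pi = n_k / n
    else:
        nP = n * P
        lo = -nP.min() + max(1e-9, 1e-12 * nP.min())

        def excess(c):
            return np.sum(n_k / (c + nP)) - 1.0

        hi = n_k.sum() + nP.max() + 1.0
        while excess(hi) > 0:
            hi *= 2
        c = brentq(excess, lo, hi, xtol=1e-12, rtol=1e-14)
        pi = n_k / (c + nP)
        pi = np.maximum(pi, 1e-12)
        pi = pi / pi.sum()

    beta0 = current.beta0.copy()
    beta = current.beta.copy()
    sigma = current.sigma.copy()
    mu_cur = current.linear_predictor(X)

    for k in range(K):
        w = tau[:, k]
        t1, t2 = _pseudo_outcomes(y, delta, mu_cur[:, k], current.sigma[k])
        cols = np.flatnonzero(active_mask[k])
        b = np.concatenate(([beta0[k]], beta[k, cols]))
        A = np.column_stack([np.ones(n), X[:, cols]])
        lam_k, a = penalty.lam[k], penalty.a
        for _ in range(max(n_lqa, 1)):
            if lam_k > 0 and len(b) > 0:
                # LQA curvature p'(|b|)/|b|; floored at the zero threshold so
                # an exactly-zero coefficient gets the infinite-curvature
                # limit (it stays at zero) rather than a free re-entry
                absb = np.maximum(np.abs(b), zero_threshold)
                d = scad_deriv(absb, lam_k, a) / absb
                if not penalty.penalize_intercept:
                    d[0] = 0.0
                ridge = current.sigma[k] ** 2 * n * pi[k] * d
            else:
                ridge = np.zeros(len(b))
            if ridge_eps > 0:
                ridge = ridge + ridge_eps * np.sum(w) * np.ones(len(b))
            b = _solve_penalized_wls(A, w, t1, ridge)
            if lam_k > 0:
                small = np.abs(b) < zero_threshold
                small[0] = False  # the intercept column always stays in the design
                if small.any():
                    keep = ~small
                    b = b[keep]
                    A = A[:, keep]
                    # map dropped columns (excluding intercept slot) back
                    dropped = cols[small[1:][: len(cols)]] if len(cols) else []
                    slope_keep = keep[1:]
                    cols = cols[slope_keep]
                    active_mask[k, dropped] = False
        beta0[k] = b[0]
        beta[k, :] = 0.0
        beta[k, cols] = b[1:]
        mu_new = A @ b
        ss = np.sum(w * (t2 - 2.0 * mu_new * t1 + mu_new**2))
        sigma_raw = np.sqrt(max(ss / n_k[k], 0.0))
        if sigma_collapse is not None and sigma_raw < sigma_collapse:
            raise DegenerateComponentError(
                f"component {k}: fitted scale {sigma_raw:.3g} below collapse "
                f"floor {sigma_collapse:.3g}"
            )
        sigma[k] = max(sigma_raw, sigma_floor)

    model = MixtureAFTModel(K=K, pi=pi, beta0=beta0, beta=beta, sigma=sigma,
                            gene_names=current.gene_names)
    return model, active_mask


# ---------------------------------------------------------------------------
# EM driver

def _standardize(X):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd, mu, sd


def _destandardize(model: MixtureAFTModel, mu: np.ndarray, sd: np.ndarray):
    beta = model.beta / sd[None, :]
    beta0 = model.beta0 - beta @ mu
    return MixtureAFTModel(K=model.K, pi=model.pi, beta0=beta0, beta=beta,
                           sigma=model.sigma, gene_names=model.gene_names)


def _ridge_wls(A, w, t1, eps=1e-4):
    Aw = A * w[:, None]
    H = A.T @ Aw
    scale = np.trace(H) / H.shape[0]
    H[np.diag_indices_from(H)] += eps * max(scale, 1e-12)
    return np.linalg.solve(H, Aw.T @ t1)


def _initial_taus(dataset: SurvivalDataset, K: int, n_starts: int, rng):
    """Membership initializations: residual-partition starts plus random ones."""
    n, p = dataset.X.shape
    taus = []
    n_resid = (n_starts + 1) // 2
    # pooled ridge fit on standardized X; partition its residuals
    A = np.column_stack([np.ones(n), dataset.X])
    b = _ridge_wls(A, np.ones(n), dataset.y, eps=1e-2)
    resid = dataset.y - A @ b
    for s in range(n_resid):
        km = KMeans(n_clusters=K, n_init=3,
                    random_state=int(rng.integers(2**31 - 1)))
        lab = km.fit_predict(resid[:, None] + (0.0 if s == 0 else
                                               0.1 * np.std(resid) * rng.standard_normal((n, 1))))
        tau = np.full((n, K), 0.1 / max(K - 1, 1))
        tau[np.arange(n), lab] = 0.9
        tau /= tau.sum(axis=1, keepdims=True)
        taus.append(tau)
    while len(taus) < n_starts:
        tau = rng.dirichlet(np.full(K, 2.0), size=n)
        taus.append(tau)
    return taus


def _init_model_from_tau(dataset, tau, gene_names, sigma_floor):
    n, p = dataset.X.shape
    K = tau.shape[1]
    A = np.column_stack([np.ones(n), dataset.X])
    beta0 = np.zeros(K)
    beta = np.zeros((K, p))
    sigma = np.zeros(K)
    for k in range(K):
        b = _ridge_wls(A, tau[:, k], dataset.y, eps=1e-2)
        beta0[k], beta[k] = b[0], b[1:]
        resid = dataset.y - A @ b
        nk = tau[:, k].sum()
        sigma[k] = max(np.sqrt(np.sum(tau[:, k] * resid**2) / max(nk, 1.0)),
                       sigma_floor)
    pi = tau.mean(axis=0)
    return MixtureAFTModel(K=K, pi=pi, beta0=beta0, beta=beta, sigma=sigma,
                           gene_names=gene_names)


def fit_em(
    dataset: SurvivalDataset,
    K: int,
    penalty: PenaltyConfig | None = None,
    init: np.ndarray | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
    n_starts: int = 10,
    seed: int = 0,
    min_component_weight: float = 5.0,
    warmup_iter: int = 10,
    standardize: bool = True,
    refit_support: bool = True,
) -> FitResult:
    """Best-of-``n_starts`` penalized EM fit of a K-component mixture AFT.

    Each start runs a short unpenalized warm-up (part of initialization, not
    recorded in the trace) before the penalized EM, whose penalized observed
    log-likelihood trace is non-decreasing. With ``refit_support`` (the
    default) the winning start's model is polished by an unpenalized EM
    restricted to the selected supports, removing the penalty's shrinkage
    bias from the reported coefficients, scales and mixing proportions.
    Covariates are standardized internally (the tuning parameters act on
    that scale) and coefficients are reported on the original scale.
    Components are relabeled so Component 1 has the shortest fitted mean
    survival.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if penalty is None:
        penalty = PenaltyConfig(lam=np.zeros(K))
    if len(penalty.lam) != K:
        raise ValueError("penalty.lam length must equal K")
    X0 = dataset.X
    if standardize:
        Xs, x_mu, x_sd = _standardize(X0)
        work = SurvivalDataset(X=Xs, y=dataset.y, delta=dataset.delta,
                               gene_names=dataset.gene_names,
                               sample_ids=dataset.sample_ids)
    else:
        work = dataset
    sigma_floor = 1e-4 * float(np.std(work.y))
    rng = np.random.default_rng(seed)
    if init is not None:
        # caller-provided memberships join the generated starts
        taus = [np.asarray(init, dtype=float)]
        if n_starts > 1:
            taus += _initial_taus(work, K, n_starts - 1, rng)
    else:
        taus = _initial_taus(work, K, n_starts, rng)

    best = None
    for tau0 in taus:
        try:
            result = _run_one_start(work, K, penalty, tau0, max_iter, tol,
                                    min_component_weight, warmup_iter, sigma_floor)
        except DegenerateComponentError as err:
            logger.debug("start discarded: %s", err)
            continue
        if best is None or result[-1] > best[-1]:
            best = result
    if best is None:
        raise DegenerateComponentError(
            f"all {len(taus)} starts degenerate for K={K}")
    model_s, tau, trace, converged, n_iter, pll = best

    if refit_support and np.any(penalty.lam > 0):
        model_s, tau = _polish_support(work, model_s, tol, sigma_floor,
                                       min_component_weight)

    model = _destandardize(model_s, x_mu, x_sd) if standardize else model_s
    # relabel: Component 1 = shortest fitted mean survival (most aggressive)
    order = np.argsort(model.linear_predictor(X0).mean(axis=0), kind="stable")
    model = MixtureAFTModel(K=K, pi=model.pi[order], beta0=model.beta0[order],
                            beta=model.beta[order], sigma=model.sigma[order],
                            gene_names=model.gene_names)
    tau = tau[:, order]

    ll = mixture_loglik(dataset, model)
    active = [
        [g for g, b in zip(model.gene_names, model.beta[k])
         if abs(b) > ZERO_THRESHOLD]
        for k in range(K)
    ]
    df = sum(len(a) for a in active) + K + K + (K - 1)
    bic = -2.0 * ll + df * np.log(dataset.n)
    return FitResult(model=model, tau=tau, loglik_trace=np.asarray(trace),
                     bic=float(bic), converged=converged, n_iter=n_iter,
                     active=active, penalty=penalty, loglik=float(ll))


def _refit_masked(work, model, mask, tol, sigma_floor, min_component_weight,
                  max_iter: int = 200):
    """Unpenalized EM with the active sets frozen at ``mask``."""
    no_pen = PenaltyConfig(lam=np.zeros(model.K))
    ll_prev = -np.inf
    tau = e_step(work, model)
    for _ in range(max_iter):
        tau = e_step(work, model)
        model, _ = m_step(work, tau, no_pen, model, active_mask=mask,
                          sigma_floor=sigma_floor,
                          min_component_weight=min_component_weight, n_lqa=1)
        ll = mixture_loglik(work, model)
        if np.isfinite(ll_prev) and abs(ll - ll_prev) < tol * (abs(ll) + 1.0):
            break
        ll_prev = ll
    return model, e_step(work, model), ll


def _support_edits(work, model, tau, mask, threshold):
    """One backward/forward sweep of the supports under fixed memberships.

    Working Wald statistics decide drops, working score statistics decide
    re-admissions; ``threshold`` is the squared-statistic cost of one
    coefficient (log n + log p, the extended-BIC price). Censored
    observations carry their truncated-normal information factor so the
    imputed pseudo-outcomes do not overstate precision.
    """
    X, y, delta = work.X, work.y, work.delta
    n, p = X.shape
    new_mask = mask.copy()
    for k in range(model.K):
        w = tau[:, k]
        mu = model.beta0[k] + X @ model.beta[k]
        t1, _ = _pseudo_outcomes(y, delta, mu, model.sigma[k])
        z = (y - mu) / model.sigma[k]
        h = np.exp(norm.logpdf(z) - norm.logsf(z))
        info_factor = np.where(delta == 1, 1.0, np.clip(1.0 - h * (h - z), 0.0, 1.0))
        wi = w * info_factor
        s2 = model.sigma[k] ** 2
        cols = np.flatnonzero(new_mask[k])
        # backward: Wald statistics from the restricted weighted fit
        if len(cols):
            A = np.column_stack([np.ones(n), X[:, cols]])
            H = (A * wi[:, None]).T @ A
            H[np.diag_indices_from(H)] += 1e-8 * np.trace(H) / H.shape[0]
            cov = s2 * np.linalg.inv(H)
            b = np.concatenate(([model.beta0[k]], model.beta[k, cols]))
            wald = b[1:] ** 2 / np.maximum(np.diag(cov)[1:], 1e-300)
            drop = cols[wald < threshold]
            new_mask[k, drop] = False
        # forward: score statistics of excluded genes against the residual
        r = t1 - mu
        for j in np.flatnonzero(~new_mask[k]):
            xj = X[:, j]
            num = float(np.sum(w * xj * r)) ** 2
            den = s2 * float(np.sum(wi * xj**2))
            if den > 0 and num / den > threshold:
                new_mask[k, j] = True
    return new_mask


def _polish_support(work, model_s, tol, sigma_floor, min_component_weight,
                    max_cycles: int = 3):
    """Post-selection polish: unpenalized refit plus support editing.

    Alternates an unpenalized EM on the frozen supports (removing SCAD
    shrinkage) with extended-BIC-guided backward/forward edits of the
    supports (pruning coefficients whose deviance contribution does not
    cover the log n + log p price of a parameter, re-admitting excluded
    genes that do). Falls back to the input model if a cycle degenerates.
    """
    n, p = work.X.shape
    threshold = np.log(n) + np.log(max(p, 2))
    mask = np.abs(model_s.beta) > ZERO_THRESHOLD
    model, tau = model_s, e_step(work, model_s)
    try:
        model, tau, _ = _refit_masked(work, model, mask, tol, sigma_floor,
                                      min_component_weight)
        for _ in range(max_cycles):
            new_mask = _support_edits(work, model, tau, mask, threshold)
            if (new_mask == mask).all():
                break
            mask = new_mask
            model.beta[~mask] = 0.0
            model, tau, _ = _refit_masked(work, model, mask, tol, sigma_floor,
                                          min_component_weight)
        return model, tau
    except DegenerateComponentError:
        return model_s, e_step(work, model_s)


def _run_one_start(work, K, penalty, tau0, max_iter, tol,
                   min_component_weight, warmup_iter, sigma_floor):
    no_pen = PenaltyConfig(lam=np.zeros(K), a=penalty.a,
                           penalize_intercept=penalty.penalize_intercept)
    # warm-up: ridge-stabilized, with a conservative scale floor, so no
    # component can interpolate its events before the penalty takes over
    warm_floor = max(sigma_floor, 0.05 * float(np.std(work.y)))
    model = _init_model_from_tau(work, tau0, work.gene_names, warm_floor)
    tau = tau0
    for _ in range(warmup_iter):
        tau = e_step(work, model)
        model, _ = m_step(work, tau, no_pen, model, sigma_floor=warm_floor,
                          min_component_weight=min_component_weight, n_lqa=1,
                          ridge_eps=0.1)
    # an interpolating component shows up as a collapsing scale; treat a
    # scale below 2% of the marginal log-time spread as degenerate
    sigma_collapse = 0.02 * float(np.std(work.y))
    active_mask = np.ones((K, work.p), dtype=bool)
    trace = []
    converged = False
    pll_prev = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        tau = e_step(work, model)
        model, active_mask = m_step(work, tau, penalty, model,
                                    active_mask=active_mask,
                                    sigma_floor=sigma_floor,
                                    min_component_weight=min_component_weight,
                                    sigma_collapse=sigma_collapse)
        pll = penalized_loglik(work, model, penalty)
        trace.append(pll)
        if np.isfinite(pll_prev) and abs(pll - pll_prev) < tol * (abs(pll) + 1.0):
            converged = True
            break
        pll_prev = pll
    tau = e_step(work, model)
    # a converged component carrying more free parameters than its effective
    # sample size can support is an overfit attractor, not a subpopulation
    n_k = tau.sum(axis=0)
    n_active = (np.abs(model.beta) > ZERO_THRESHOLD).sum(axis=1)
    over = n_active + 2 > 0.9 * n_k
    if over.any():
        raise DegenerateComponentError(
            f"component(s) {np.flatnonzero(over).tolist()} ended with "
            f"{(n_active[over] + 2).tolist()} free parameters vs effective "
            f"weight {n_k[over].round(1).tolist()}"
        )
    return model, tau, trace, converged, it, trace[-1]


# ---------------------------------------------------------------------------
# tuning and order selection

def default_lambda_grid(n_points: int = 12, lo: float = 0.02, hi: float = 0.6):
    """Log-spaced SCAD tuning grid on the standardized-covariate scale.

    The lower end stops at 0.02: far below that, a near-unpenalized component
    in p ~ n data is rejected by the degeneracy guards anyway, and the grid
    stays small enough that every point affords an independent multi-start
    fit.
    """
    return np.geomspace(lo, hi, n_points)


def _component_refit(work, tau, model, k, lam, a, n_iter=15,
                     zero_threshold=ZERO_THRESHOLD):
    """Refit component k's coefficients at penalty lam with tau and scale fixed.

    Starts from the unpenalized ridge solution of the component's pseudo-data
    so every coefficient can re-enter regardless of the anchor's zeros.
    Holding the memberships and the scale at their anchor values keeps the
    per-lambda refits comparable — the component-wise BIC then ranks penalty
    levels on identical weighted data — and denies a dense refit the
    shrinking-scale likelihood spike.
    """
    X, y, delta = work.X, work.y, work.delta
    n, p = X.shape
    w = tau[:, k]
    pi_k = model.pi[k]
    A_full = np.column_stack([np.ones(n), X])
    beta0_k, beta_k, sigma_k = model.beta0[k], model.beta[k].copy(), model.sigma[k]
    b = None
    for _ in range(n_iter):
        mu = beta0_k + X @ beta_k
        t1, _ = _pseudo_outcomes(y, delta, mu, sigma_k)
        if b is None:
            b = _ridge_wls(A_full, w, t1, eps=1e-3)
        if lam > 0:
            absb = np.maximum(np.abs(b), zero_threshold)
            d = scad_deriv(absb, lam, a) / absb
            d[0] = 0.0
            ridge = sigma_k**2 * n * pi_k * d
        else:
            ridge = np.zeros(len(b))
        b = _solve_penalized_wls(A_full, w, t1, ridge)
        b[1:][np.abs(b[1:]) < zero_threshold] = 0.0
        beta0_k, beta_k = b[0], b[1:]
    return beta0_k, beta_k, sigma_k


def _componentwise_bic(dataset: SurvivalDataset, fit: FitResult) -> np.ndarray:
    """BIC_k = -2 l_k + df_k log(n_k) per component of a fitted mixture.

    l_k is the tau-weighted censoring-aware component log-likelihood,
    n_k = sum_i tau_ik the effective component size, and df_k counts the
    active coefficients plus intercept and scale.
    """
    model = fit.model
    ll = _loglik_matrix(dataset, model)
    out = np.empty(model.K)
    for k in range(model.K):
        n_k = float(fit.tau[:, k].sum())
        l_k = float(np.sum(fit.tau[:, k] * ll[:, k]))
        df_k = int(np.sum(np.abs(model.beta[k]) > ZERO_THRESHOLD)) + 2
        out[k] = -2.0 * l_k + df_k * np.log(max(n_k, 2.0))
    return out


def tune_lambdas(
    dataset: SurvivalDataset,
    K: int,
    lambda_grid: np.ndarray | None = None,
    a: float = 3.7,
    seed: int = 0,
    n_starts: int = 5,
    max_iter: int = 200,
    min_component_weight: float = 5.0,
    return_path: bool = False,
):
    """Data-adaptive component-wise BIC choice of the K tuning parameters.

    Two stages. First a common penalty level is scanned over the grid
    (independent multi-start fits, each also offered the previous grid
    point's memberships as a warm start) and the overall-BIC minimizer
    becomes the anchor fit. Second, holding the other components' penalties
    at the anchor level, each component's penalty is varied over the grid in
    EM fits warm-started from the anchor memberships — warm starting pins
    the component identities, which is what makes a per-component penalty
    well defined — and the component-wise BIC_k = -2 l_k + df_k log(n_k)
    picks lambda_k. Returns the penalty, and with ``return_path`` also the
    scan diagnostics and the anchor memberships (callers should warm-start
    the final fit from them so component k keeps its identity).
    """
    if lambda_grid is None:
        lambda_grid = default_lambda_grid()
    lambda_grid = np.unique(np.asarray(lambda_grid, dtype=float))
    if lambda_grid.size == 0:
        raise ValueError("lambda grid is empty")
    if np.all(lambda_grid == 0):
        logger.warning("lambda grid contains only 0: no selection performed")
        pen = PenaltyConfig(lam=np.zeros(K), a=a)
        return (pen, {}) if return_path else pen
    grid = np.array(sorted(lambda_grid[lambda_grid > 0], reverse=True))

    # stage 1: common-penalty scan by overall BIC
    tau_warm = None
    anchor = None
    anchor_lam = None
    scan_bic = {}
    failures = 0
    for lam in grid:
        try:
            fit = fit_em(dataset, K, PenaltyConfig(lam=np.full(K, lam), a=a),
                         init=tau_warm, n_starts=n_starts, seed=seed,
                         max_iter=max_iter,
                         min_component_weight=min_component_weight)
        except DegenerateComponentError as err:
            logger.debug("no fit at common lambda=%.4g: %s", lam, err)
            failures += 1
            if failures >= 2:
                break
            continue
        failures = 0
        tau_warm = fit.tau
        scan_bic[float(lam)] = fit.bic
        if anchor is None or fit.bic < anchor.bic:
            anchor, anchor_lam = fit, float(lam)
    if anchor is None:
        raise DegenerateComponentError(
            f"no non-degenerate fit on the penalty grid for K={K}")

    # stage 2: component-wise refinement against the anchor memberships.
    # tau and sigma stay at anchor values so the per-lambda refits are a
    # clean penalized-regression model selection on identical weighted data.
    Xs, x_mu, x_sd = _standardize(dataset.X)
    work = SurvivalDataset(X=Xs, y=dataset.y, delta=dataset.delta,
                           gene_names=dataset.gene_names,
                           sample_ids=dataset.sample_ids)
    model_s = MixtureAFTModel(
        K=K, pi=anchor.model.pi,
        beta0=anchor.model.beta0 + anchor.model.beta @ x_mu,
        beta=anchor.model.beta * x_sd[None, :],
        sigma=anchor.model.sigma, gene_names=dataset.gene_names,
    )
    tau = anchor.tau
    chosen = np.full(K, anchor_lam)
    comp_path: dict[int, dict[float, float]] = {}
    # With K > 1 the refinement only explores penalties at or above the
    # anchor: below it, a component refit against soft memberships can
    # absorb observations that really belong to another component
    # (misassignment is irreducible under overlap), and the component-wise
    # criterion would reward that spurious densification. A single
    # component has no contamination, so the full grid is searched.
    grid_k = grid if K == 1 else grid[grid >= anchor_lam - 1e-12]
    for k in range(K):
        n_k = float(tau[:, k].sum())
        bic_k_path = {}
        best_bic_k, best_lam = np.inf, anchor_lam
        for lam in grid_k:
            b0, bk, sk = _component_refit(work, tau, model_s, k, lam, a)
            mu = b0 + work.X @ bk
            l_k = float(np.sum(tau[:, k] * component_loglik(
                work.y, work.delta, mu, sk)))
            df_k = int(np.sum(np.abs(bk) > ZERO_THRESHOLD)) + 2
            bic_k = -2.0 * l_k + df_k * np.log(max(n_k, 2.0))
            bic_k_path[float(lam)] = bic_k
            if bic_k < best_bic_k - 1e-12:
                best_bic_k, best_lam = bic_k, float(lam)
        chosen[k] = best_lam
        comp_path[k] = bic_k_path
    pen = PenaltyConfig(lam=chosen, a=a)
    if return_path:
        return pen, {"common_bic": scan_bic, "anchor_lambda": anchor_lam,
                     "component_bic": comp_path, "anchor_tau": anchor.tau,
                     "anchor_fit": anchor}
    return pen


def fit_tuned(
    dataset: SurvivalDataset,
    K: int,
    lambda_grid: np.ndarray | None = None,
    a: float = 3.7,
    seed: int = 0,
    n_starts: int = 5,
    max_iter: int = 200,
    min_component_weight: float = 5.0,
) -> FitResult:
    """Tune the penalties component-wise, refit, and keep the BIC-best model.

    Both the anchor fit (common penalty, overall-BIC optimum of the scan)
    and the refit at the component-wise tuned penalties are candidates; the
    one with the lower overall BIC is returned. This guards against the
    occasional tuned refit that wanders out of the anchor's basin.
    """
    pen, info = tune_lambdas(dataset, K, lambda_grid=lambda_grid, a=a,
                             seed=seed, n_starts=n_starts, max_iter=max_iter,
                             min_component_weight=min_component_weight,
                             return_path=True)
    anchor: FitResult = info["anchor_fit"]

    # candidate contest judged by an extended BIC: with p comparable to the
    # effective per-component sample size, the plain BIC under-charges
    # spurious coefficients, so each active coefficient additionally pays
    # log(p) (the gamma = 0.5 extended-BIC surcharge for 2 * 0.5 * log p)
    p = dataset.p
    log_p = np.log(max(p, 2))

    def ebic(fit: FitResult) -> float:
        n_active = sum(len(acts) for acts in fit.active)
        return fit.bic + n_active * log_p

    best = anchor
    candidates = []
    if not np.allclose(pen.lam, info["anchor_lambda"]):
        candidates.append(pen.lam)
    if K > 1:
        # scale-balanced penalties: the LQA curvature of the penalty scales
        # with sigma_k^2, so a common lambda under-shrinks low-noise
        # components; lambda_k ~ 1/sigma_k^2 (geometric mean preserved)
        # equalizes the effective shrinkage across components
        s2 = anchor.model.sigma ** 2
        bal = info["anchor_lambda"] * np.exp(np.mean(np.log(s2))) / s2
        bal = np.clip(bal, 0.0, 10.0)
        for scale in (0.7, 1.0, 1.4):
            candidates.append(scale * bal)
    for lam_vec in candidates:
        try:
            # warm start only: fresh starts under asymmetric penalties can
            # converge with permuted component meanings, which would make
            # the per-component penalty assignment incoherent
            trial = fit_em(dataset, K, PenaltyConfig(lam=lam_vec, a=a),
                           init=info["anchor_tau"], n_starts=1,
                           seed=seed, max_iter=max_iter,
                           min_component_weight=min_component_weight)
        except DegenerateComponentError:
            continue
        if ebic(trial) < ebic(best):
            best = trial
    return best


def select_order(
    dataset: SurvivalDataset,
    K_range=(1, 2, 3),
    lambda_grid: np.ndarray | None = None,
    a: float = 3.7,
    seed: int = 0,
    n_starts: int = 5,
    max_iter: int = 200,
    min_component_weight: float = 5.0,
    tune: bool = True,
) -> OrderSelection:
    """Fit each K with tuned penalties and pick the overall-BIC minimizer.

    Overall BIC counts active coefficients plus K intercepts, K scales and
    K - 1 free mixing proportions. Failed fits are recorded and skipped.
    """
    K_values = sorted(set(int(k) for k in K_range))
    fits: dict[int, FitResult] = {}
    errors: dict[int, str] = {}
    bics = []
    for K in K_values:
        try:
            if tune:
                fit = fit_tuned(dataset, K, lambda_grid=lambda_grid, a=a,
                                seed=seed, n_starts=n_starts,
                                max_iter=max_iter,
                                min_component_weight=min_component_weight)
            else:
                fit = fit_em(dataset, K, PenaltyConfig(lam=np.zeros(K), a=a),
                             n_starts=n_starts, seed=seed, max_iter=max_iter,
                             min_component_weight=min_component_weight)
        except (DegenerateComponentError, ValueError, RuntimeError) as err:
            errors[K] = str(err)
            bics.append(np.nan)
            continue
        fits[K] = fit
        bics.append(fit.bic)
    ok = [i for i, b in enumerate(bics) if np.isfinite(b)]
    if not ok:
        raise RuntimeError(f"no successful fit in K_range {K_values}: {errors}")
    best_K = K_values[min(ok, key=lambda i: bics[i])]
    return OrderSelection(K_values=K_values, bic_per_K=bics, best_K=best_K,
                          fits=fits, errors=errors)


# ---------------------------------------------------------------------------
# reporting

def classify(fit: FitResult, sample_ids=None, delta=None):
    """MAP component labels (1-based) and a per-sample posterior table.

    Ties go to the lower component index. The table carries the posterior
    probability of Component 1 (the shorter-survival component), suitable for
    plotting separated by vital status.
    """
    import pandas as pd

    tau = fit.tau
    labels = np.argmax(tau, axis=1) + 1  # argmax takes the first max: low index
    n, K = tau.shape
    data = {"sample_id": sample_ids if sample_ids is not None else
            [f"s{i + 1:04d}" for i in range(n)]}
    if delta is not None:
        data["delta"] = np.asarray(delta, dtype=int)
    for k in range(K):
        data[f"tau_{k + 1}"] = tau[:, k]
    data["map_label"] = labels
    return labels, pd.DataFrame(data)


def active_genes(model: MixtureAFTModel, component: int,
                 zero_threshold: float = ZERO_THRESHOLD) -> set[str]:
    """Genes with |beta| above ``zero_threshold`` in the given 1-based component."""
    if not 1 <= component <= model.K:
        raise ValueError(f"component must be in 1..{model.K}")
    b = model.beta[component - 1]
    return {g for g, bj in zip(model.gene_names, b) if abs(bj) > zero_threshold}
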