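"""Preliminary heterogeneity diagnostics for right-censored survival times.

Kaplan-Meier estimation, inverse-probability-of-censoring (IPC) weights, a
censoring-aware kernel density of log survival time, and a BIC scan over
univariate Gaussian mixtures fitted to the log times. A multimodal weighted
density and a mixture winning the BIC scan are the classic first hints that
covariate effects on survival differ across latent subpopulations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

logger = logging.getLogger(__name__)

__all__ = [
    "StepFunction",
    "BicScan",
    "kaplan_meier",
    "ipc_weights",
    "weighted_log_density",
    "gaussian_mixture_bic_scan",
]


@dataclass
class StepFunction:
    """Right-continuous survival step function S(t).

    ``times`` are the distinct event times; ``values`` the step heights just
    after each time. S(t) = 1 before the first event time.
    """

    times: np.ndarray
    values: np.ndarray

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx < 0, 1.0, self.values[np.clip(idx, 0, len(self.values) - 1)])
        return out if out.ndim else float(out)

    def before(self, t) -> np.ndarray:
        """Left limit S(t-)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="left") - 1
        out = np.where(idx < 0, 1.0, self.values[np.clip(idx, 0, len(self.values) - 1)])
        return out if out.ndim else float(out)


@dataclass
class BicScan:
    K_values: list[int]
    bic: list[float]
    loglik: list[float]
    best_K: int


def _product_limit(times: np.ndarray, events: np.ndarray, others: np.ndarray) -> StepFunction:
    """Product-limit estimate treating ``events`` as the event of interest.

    At tied times the "other" outcome does not leave the risk set before the
    events at that time are counted, i.e. events precede the competing
    removals. (For the censoring-distribution estimate the roles flip and the
    same rule makes deaths precede censorings at ties.)
    """
    order = np.argsort(times, kind="stable")
    t, e, o = times[order], events[order], others[order]
    uniq = np.unique(t[e == 1])
    n = len(t)
    surv = np.empty(len(uniq))
    s = 1.0
    for i, u in enumerate(uniq):
        at_risk = np.sum(t >= u)
        d = np.sum((t == u) & (e == 1))
        # removals of the other kind at u stay in the risk set for events at u
        s *= 1.0 - d / at_risk
        surv[i] = s
    return StepFunction(times=uniq, values=surv)


def kaplan_meier(times, delta) -> StepFunction:
    """Kaplan-Meier product-limit estimator of the survival function.

    Ties are grouped; at a tied time events precede censorings, so subjects
    censored at an event time remain in that time's risk set.
    """
    times = np.asarray(times, dtype=float)
    delta = np.asarray(delta, dtype=int)
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    if not np.isin(delta, (0, 1)).all():
        raise ValueError("delta must be 0/1")
    if delta.sum() == 0:
        raise ValueError("no events: Kaplan-Meier estimate undefined")
    return _product_limit(times, delta, 1 - delta)


def ipc_weights(times, delta) -> np.ndarray:
    """Inverse-probability-of-censoring weights w_i = delta_i / G(t_i-).

    G is the Kaplan-Meier estimate of the censoring distribution (status
    flipped: censorings are the events). Censored subjects receive weight 0.
    Weights are returned raw, not renormalized. If G(t_i-) = 0 for an event
    (event beyond the last censoring support) the weight is set to the largest
    finite weight observed, with a warning.
    """
    times = np.asarray(times, dtype=float)
    delta = np.asarray(delta, dtype=int)
    if delta.sum() == 0:
        raise ValueError("no events: IPC weights undefined")
    w = np.zeros(len(times), dtype=float)
    ev = delta == 1
    if (delta == 0).sum() == 0:
        w[ev] = 1.0
        return w
    # censoring-distribution estimate: censorings are events, deaths compete
    G = _product_limit(times, 1 - delta, delta)
    g_minus = np.asarray(G.before(times[ev]), dtype=float)
    with np.errstate(divide="ignore"):
        wi = np.where(g_minus > 0, 1.0 / g_minus, np.inf)
    if np.isinf(wi).any():
        finite = wi[np.isfinite(wi)]
        cap = float(finite.max()) if len(finite) else 1.0
        logger.warning("G(t-)=0 for %d events; weights capped at %.3g",
                       int(np.isinf(wi).sum()), cap)
        wi = np.where(np.isinf(wi), cap, wi)
    w[ev] = wi
    return w


def weighted_log_density(times, delta, bandwidth: float, grid_size: int = 512):
    """IPC-weighted Gaussian-kernel density of log survival time.

    Returns (grid, density). The density is evaluated on ``grid_size`` points
    spanning the event log-times +/- 3 bandwidths; the IPC weights over events
    are normalized to sum to one so the curve integrates to ~1.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    times = np.asarray(times, dtype=float)
    delta = np.asarray(delta, dtype=int)
    if delta.sum() < 2:
        raise ValueError("need at least 2 events for a density estimate")
    y = np.log(times[delta == 1])
    w = ipc_weights(times, delta)[delta == 1]
    w = w / w.sum()
    grid = np.linspace(y.min() - 3 * bandwidth, y.max() + 3 * bandwidth, grid_size)
    z = (grid[:, None] - y[None, :]) / bandwidth
    dens = (norm.pdf(z) * w[None, :]).sum(axis=1) / bandwidth
    return grid, dens


def _fit_gmm_1d(y2d, K, means_init, weights_init, precisions_init, seed):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gm = GaussianMixture(
            n_components=K, covariance_type="full", n_init=1,
            means_init=means_init, weights_init=weights_init,
            precisions_init=precisions_init,
            reg_covar=1e-12, max_iter=500, tol=1e-7, random_state=seed,
        )
        gm.fit(y2d)
    return gm


def gaussian_mixture_bic_scan(y, K_max: int = 5, n_starts: int = 10,
                              seed: int = 0) -> BicScan:
    """Scan K = 1..K_max univariate Gaussian mixtures and pick the lowest BIC.

    For each K the best of ``n_starts`` EM fits is kept; one extra start is
    initialized from the previous K's solution with its widest component
    duplicated (nested initialization), which makes the maximized
    log-likelihood non-decreasing in K. Starts whose smallest fitted standard
    deviation falls below 1e-4 * sd(y) are discarded as degenerate. BIC uses
    q = 3K - 1 free parameters (K means, K variances, K - 1 weights).
    """
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if K_max < 1:
        raise ValueError("K_max must be >= 1")
    if n <= 3 * K_max:
        raise ValueError("need more than 3*K_max observations")
    y2d = np.sort(y)[:, None]  # sorting makes the scan permutation-invariant
    sd_floor = 1e-4 * float(np.std(y))
    rng = np.random.default_rng(seed)
    K_values, bics, logliks = [], [], []
    prev_best = None
    for K in range(1, K_max + 1):
        best = None
        candidates = [(None, None, None, int(rng.integers(2**31 - 1)))
                      for _ in range(n_starts)]
        if prev_best is not None:
            # nested start: split the widest component of the (K-1)-solution
            means = prev_best.means_.ravel()
            weights = prev_best.weights_.copy()
            covs = prev_best.covariances_.ravel()
            j = int(np.argmax(covs))
            means_init = np.append(means, means[j])[:, None]
            weights_init = np.append(weights, weights[j] / 2)
            weights_init[j] /= 2
            weights_init /= weights_init.sum()
            prec_init = (1.0 / np.append(covs, covs[j])).reshape(K, 1, 1)
            candidates.append((means_init, weights_init, prec_init,
                               int(rng.integers(2**31 - 1))))
        for means_init, weights_init, prec_init, s in candidates:
            gm = _fit_gmm_1d(y2d, K, means_init, weights_init, prec_init, s)
            if np.sqrt(gm.covariances_.ravel().min()) < sd_floor:
                continue
            ll = float(gm.score(y2d) * n)
            if best is None or ll > best_ll:
                best, best_ll = gm, ll
        if best is None:
            raise RuntimeError(f"all starts degenerate for K={K}")
        q = 3 * K - 1
        K_values.append(K)
        logliks.append(best_ll)
        bics.append(-2.0 * best_ll + q * np.log(n))
        prev_best = best
    best_K = K_values[int(np.argmin(bics))]
    return BicScan(K_values=K_values, bic=bics, loglik=logliks, best_K=best_K)
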