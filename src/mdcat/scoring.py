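"""Latent-trait estimation under the correlated-factor normal prior.

The operational estimator is the posterior mode (MAP) with standard errors
from expected Fisher information plus prior precision, both evaluated at
the mode:

    posterior_info = Sigma^{-1} + sum_j I_j(theta_hat),
    se_f = sqrt([posterior_info^{-1}]_{ff}).

EAP (posterior mean by quasi-Monte-Carlo integration) is provided as a
cross-check, not as the engine's estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .bank import ItemBank, N_FACTORS
from .grm import BankMatrices, THETA_CLAMP

GRAD_TOL = 1e-6


class ConvergenceError(RuntimeError):
    """MAP optimiser failed; ``best`` carries the best iterate found."""

    def __init__(self, message: str, best: "LatentState"):
        super().__init__(message)
        self.best = best


@dataclass
class LatentState:
    """Current estimate of the four traits with uncertainty.

    ``info`` is the posterior precision (prior precision plus accumulated
    expected item information, evaluated at ``theta``).
    """

    theta: np.ndarray
    se: np.ndarray
    info: np.ndarray
    n_items: int

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        self.info = np.asarray(self.info, dtype=float)


def posterior_se(info: np.ndarray) -> np.ndarray:
    """Per-trait SEs: sqrt of the diagonal of the inverse posterior precision."""
    cov = np.linalg.inv(info)
    return np.sqrt(np.clip(np.diag(cov), 0.0, None))


def _responses_to_arrays(
    responses: Mapping[str, int], mats: BankMatrices
) -> tuple[np.ndarray, np.ndarray]:
    idx, cats = [], []
    for item_id, x in responses.items():
        if x is None or (isinstance(x, float) and pd.isna(x)):
            continue
        idx.append(mats.item_ids.index(item_id))
        cats.append(int(x))
    return np.asarray(idx, dtype=np.int64), np.asarray(cats, dtype=np.int64)


def map_estimate(
    responses: Mapping[str, int],
    bank: ItemBank,
    sigma: np.ndarray | None = None,
    start: np.ndarray | None = None,
    mats: BankMatrices | None = None,
) -> LatentState:
    """Posterior mode of theta given one person's responses.

    With zero responses, returns the prior mean (theta = 0, SE = 1).  The
    optimiser is quasi-Newton from the warm start (default 0), with two
    random restarts before declaring failure; convergence means gradient
    infinity-norm below 1e-6.
    """
    mats = mats or BankMatrices(bank)
    sigma = bank.sigma if sigma is None else np.asarray(sigma, dtype=float)
    prior_prec = np.linalg.inv(sigma)
    idx, cats = _responses_to_arrays(responses, mats)
    return _map_from_arrays(idx, cats, mats, prior_prec, start)


def _map_from_arrays(
    idx: np.ndarray,
    cats: np.ndarray,
    mats: BankMatrices,
    prior_prec: np.ndarray,
    start: np.ndarray | None = None,
) -> LatentState:
    """MAP on pre-extracted (item-index, category) arrays — the CAT hot path."""
    if len(idx) == 0:
        sigma = np.linalg.inv(prior_prec)
        return LatentState(
            theta=np.zeros(N_FACTORS),
            se=np.sqrt(np.diag(sigma)),
            info=prior_prec.copy(),
            n_items=0,
        )

    def objective(theta: np.ndarray):
        ll, grad = mats.loglik_and_grad(idx, cats, theta)
        val = -ll + 0.5 * theta @ prior_prec @ theta
        return val, -grad + prior_prec @ theta

    def projected_gnorm(x: np.ndarray, grad: np.ndarray) -> float:
        # outward components at active bounds do not count
        at_lo = (x <= -THETA_CLAMP + 1e-12) & (grad > 0)
        at_hi = (x >= THETA_CLAMP - 1e-12) & (grad < 0)
        return float(np.max(np.abs(np.where(at_lo | at_hi, 0.0, grad))))

    def newton_polish(x: np.ndarray) -> np.ndarray:
        # the log-posterior is strictly concave, so guarded Newton converges
        x = np.clip(x, -THETA_CLAMP, THETA_CLAMP)
        val, grad = objective(x)
        for _ in range(50):
            if projected_gnorm(x, grad) < GRAD_TOL:
                break
            _, _, ll_hess = mats.loglik_grad_hess(idx, cats, x)
            hess = -ll_hess + prior_prec  # positive definite
            step = np.linalg.solve(hess, -grad)
            t = 1.0
            while t > 1e-6:
                x_new = np.clip(x + t * step, -THETA_CLAMP, THETA_CLAMP)
                val_new, grad_new = objective(x_new)
                if val_new <= val + 1e-12:
                    x, val, grad = x_new, val_new, grad_new
                    break
                t *= 0.5
            else:
                break
        return x

    x0 = np.zeros(N_FACTORS) if start is None else np.clip(np.asarray(start, float), -6, 6)
    best = None
    starts = [x0]
    rng = np.random.default_rng(12345)  # deterministic restart points
    starts += [rng.uniform(-2, 2, size=N_FACTORS) for _ in range(2)]
    for x_init in starts:
        res = minimize(
            objective,
            x_init,
            jac=True,
            method="L-BFGS-B",
            bounds=[(-THETA_CLAMP, THETA_CLAMP)] * N_FACTORS,
            options={"maxiter": 200, "ftol": 1e-14, "gtol": 1e-9},
        )
        if best is None or res.fun < best.fun:
            best = res
        x_hat = res.x
        if projected_gnorm(x_hat, objective(x_hat)[1]) >= GRAD_TOL:
            x_hat = newton_polish(x_hat)
        if projected_gnorm(x_hat, objective(x_hat)[1]) < GRAD_TOL:
            return _finalize_state(x_hat, idx, mats, prior_prec, len(idx))

    state = _finalize_state(best.x, idx, mats, prior_prec, len(idx))
    raise ConvergenceError(
        f"MAP optimiser did not reach gradient norm < {GRAD_TOL} after restarts", state
    )


def _finalize_state(
    theta: np.ndarray,
    idx: np.ndarray,
    mats: BankMatrices,
    prior_prec: np.ndarray,
    n_items: int,
) -> LatentState:
    theta = np.clip(theta, -THETA_CLAMP, THETA_CLAMP)
    info = prior_prec.copy()
    infos = mats.scalar_info_all(theta)
    for j in idx:
        f = mats.factors[j]
        info[f, f] += infos[j]
    return LatentState(theta=theta, se=posterior_se(info), info=info, n_items=n_items)


def map_batch(
    x_matrix: np.ndarray,
    bank: ItemBank,
    sigma: np.ndarray | None = None,
    mats: BankMatrices | None = None,
) -> np.ndarray:
    """Row-wise MAP over an integer matrix with -1/NaN = missing; (n, 4) thetas."""
    mats = mats or BankMatrices(bank)
    sigma = bank.sigma if sigma is None else np.asarray(sigma, dtype=float)
    prior_prec = np.linalg.inv(sigma)
    x = np.asarray(x_matrix, dtype=float)
    out = np.zeros((x.shape[0], N_FACTORS))
    for p in range(x.shape[0]):
        obs = np.flatnonzero(~np.isnan(x[p]) & (x[p] >= 0))
        state = _map_from_arrays(obs, x[p, obs].astype(np.int64), mats, prior_prec)
        out[p] = state.theta
    return out


def eap_estimate(
    responses: Mapping[str, int],
    bank: ItemBank,
    sigma: np.ndarray | None = None,
    n_qmc: int = 2000,
    seed: int = 0,
) -> LatentState:
    """Posterior mean/SD by quasi-Monte-Carlo integration (scoring cross-check).

    Nodes are drawn from the prior N(0, Sigma) via a low-discrepancy
    sequence; weights are proportional to the person's likelihood at each
    node.  Requires ``n_qmc >= 1000`` for a stable quadrature.
    """
    from .calibration import qmc_nodes  # lazy: calibration imports scoring

    if n_qmc < 1000:
        raise ValueError("n_qmc must be >= 1000")
    sigma = bank.sigma if sigma is None else np.asarray(sigma, dtype=float)
    mats = BankMatrices(bank)
    idx, cats = _responses_to_arrays(responses, mats)
    nodes, _ = qmc_nodes(n_qmc, sigma, seed)
    if len(idx) == 0:
        logw = np.zeros(n_qmc)
    else:
        z = mats.slopes[idx][None, :, None] * nodes[:, mats.factors[idx]][:, :, None]
        from scipy.special import expit

        cum = expit(z + mats.d_pad[idx][None])
        full = np.concatenate(
            [np.ones((n_qmc, len(idx), 1)), cum, np.zeros((n_qmc, len(idx), 1))], axis=2
        )
        p = full[:, :, :-1] - full[:, :, 1:]
        px = np.maximum(p[:, np.arange(len(idx)), cats], 1e-300)
        logw = np.log(px).sum(axis=1)
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    mean = w @ nodes
    centred = nodes - mean
    cov = (centred * w[:, None]).T @ centred
    cov = 0.5 * (cov + cov.T) + 1e-10 * np.eye(N_FACTORS)
    return LatentState(
        theta=mean,
        se=np.sqrt(np.diag(cov)),
        info=np.linalg.inv(cov),
        n_items=int(len(idx)),
    )
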