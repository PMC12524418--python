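"""Marginal-maximum-likelihood calibration of the four-factor GRM.

The fitter is an EM algorithm with quasi-Monte-Carlo integration
(full-information item factor analysis):

* E-step: posterior weights of each person over a fixed low-discrepancy
  node set drawn from N(0, Sigma) (scrambled Halton, inverse-normal
  transform, Cholesky correlation);
* M-step: per-item weighted ordinal-logistic maximisation (quasi-Newton in
  an unconstrained parameterisation that enforces slope positivity and
  intercept ordering), followed by the multivariate-normal update of the
  latent covariance from posterior second moments, rescaled to unit
  diagonal with a compensating likelihood-invariant rescale of the slopes;
* safeguarded Ramsay-style extrapolation of the item parameters between
  iterations.

Local-independence diagnostics use the Q3 statistic: Pearson correlations
of item residuals after conditioning on per-person MAP trait estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp, ndtri
from scipy.stats import qmc

from .bank import Item, ItemBank, ResponseMatrix, N_FACTORS, FACTOR_NAMES
from .grm import BankMatrices, PROB_FLOOR
from .scoring import map_batch

Q3_FLAG_THRESHOLD = 0.50


def qmc_nodes(n: int, sigma: np.ndarray, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Low-discrepancy nodes from N(0, Sigma) with equal weights 1/n.

    A scrambled Halton sequence in [0,1)^4 is pushed through the
    inverse-normal transform and the Cholesky factor of ``sigma``.
    """
    if n < 100:
        raise ValueError("n must be >= 100")
    sigma = np.asarray(sigma, dtype=float)
    ev = np.linalg.eigvalsh(sigma)
    if ev.min() <= 0:
        raise ValueError(f"sigma must be positive definite; smallest eigenvalue {ev.min():.3e}")
    u = qmc.Halton(d=sigma.shape[0], scramble=True, seed=seed).random(n)
    z = ndtri(np.clip(u, 1e-12, 1 - 1e-12))
    chol = np.linalg.cholesky(sigma)
    return z @ chol.T, np.full(n, 1.0 / n)


@dataclass
class CalibrationSettings:
    """Tuning knobs of the EM fitter.

    ``n_qmc`` defaults to 5000 nodes; ``tol`` is the maximum absolute
    parameter change declaring convergence; ``ramsay`` toggles the
    safeguarded acceleration; ``estimate_sigma=False`` keeps the latent
    correlation matrix fixed at its starting value.
    """

    n_qmc: int = 5000
    max_iter: int = 500
    tol: float = 1e-4
    seed: int = 0
    ramsay: bool = True
    estimate_sigma: bool = True
    sigma_start: np.ndarray | None = None


@dataclass
class FitResult:
    bank: ItemBank
    n_iterations: int
    loglik: float
    converged: bool
    loglik_trace: list[float] = field(default_factory=list)
    category_maps: dict[str, dict[int, int]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# per-item M-step machinery
# ---------------------------------------------------------------------------

def _params_to_c(a: float, d: np.ndarray) -> np.ndarray:
    gaps = -np.diff(d)
    return np.concatenate([[np.log(a), d[0]], np.log(np.maximum(gaps, 1e-8))])


def _c_to_params(c: np.ndarray) -> tuple[float, np.ndarray]:
    a = float(np.exp(np.clip(c[0], -10, 10)))
    gaps = np.exp(np.clip(c[2:], -20, 20))
    d = c[1] - np.concatenate([[0.0], np.cumsum(gaps)])
    return a, d


def _neg_expected_ll(c: np.ndarray, theta_f: np.ndarray, counts: np.ndarray):
    """Negative weighted complete-data log-likelihood of one item + gradient.

    ``counts[q, k]`` is the posterior-expected number of responses in
    category k located at node coordinate ``theta_f[q]``.
    """
    a, d = _c_to_params(c)
    z = a * theta_f[:, None] + d
    cum = expit(z)
    n = len(theta_f)
    full = np.concatenate([np.ones((n, 1)), cum, np.zeros((n, 1))], axis=1)
    p = np.maximum(full[:, :-1] - full[:, 1:], 1e-12)
    obj = float(np.sum(counts * np.log(p)))
    # dobj/dcum_k (k = 1..K-1): from the two adjacent categories
    ratio = counts / p
    dcum = (ratio[:, 1:] - ratio[:, :-1]) * cum * (1.0 - cum)
    grad_d = dcum.sum(axis=0)
    grad_a = float(np.sum(dcum * theta_f[:, None]))
    # chain rule into c = (log a, d_1, log gaps)
    k1 = len(d)
    grad_c = np.empty(1 + k1)
    grad_c[0] = grad_a * a
    grad_c[1] = grad_d.sum()
    for i in range(1, k1):
        gap = d[i - 1] - d[i]
        grad_c[1 + i] = -grad_d[i:].sum() * gap
    return -obj, -grad_c


def _mstep_item(c0: np.ndarray, theta_f: np.ndarray, counts: np.ndarray) -> np.ndarray:
    res = minimize(
        _neg_expected_ll,
        c0,
        args=(theta_f, counts),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 100, "ftol": 1e-12},
    )
    return res.x


# ---------------------------------------------------------------------------
# the fitter
# ---------------------------------------------------------------------------

def _prepare_data(
    responses: ResponseMatrix, structure: Mapping[str, int]
) -> tuple[np.ndarray, list[str], np.ndarray, list[int], dict[str, dict[int, int]]]:
    item_ids = [c for c in responses.item_ids if c in structure]
    if not item_ids:
        raise ValueError("no response columns match the structure map")
    x = responses.data[item_ids].to_numpy(dtype=float)
    x = np.where(np.isnan(x), -1, x).astype(np.int64)
    factors = np.array([structure[i] for i in item_ids], dtype=np.int64)
    n_cats: list[int] = []
    remaps: dict[str, dict[int, int]] = {}
    for j, iid in enumerate(item_ids):
        obs = np.unique(x[x[:, j] >= 0, j])
        if len(obs) < 2:
            raise ValueError(f"item {iid}: fewer than 2 observed categories")
        if len(obs) != obs[-1] + 1:
            remap = {int(o): k for k, o in enumerate(obs)}
            remaps[iid] = remap
            col = x[:, j]
            for old, new in remap.items():
                col[col == old] = new
            warnings.warn(
                f"item {iid}: empty categories collapsed, remap {remap}", stacklevel=2
            )
        n_cats.append(len(obs))
    return x, item_ids, factors, n_cats, remaps


def fit_grm(
    responses: ResponseMatrix,
    structure: Mapping[str, int],
    settings: CalibrationSettings | None = None,
) -> FitResult:
    """Fit the four-factor GRM to a response matrix.

    ``structure`` maps item id -> factor index (simple structure).  Missing
    responses contribute nothing to their person's E-step terms
    (full-information treatment).  Returns estimated slopes, intercepts and
    the latent correlation matrix in a new :class:`ItemBank`.
    """
    settings = settings or CalibrationSettings()
    x, item_ids, factors, n_cats, remaps = _prepare_data(responses, structure)
    n_persons, n_items = x.shape
    if n_persons < 100:
        warnings.warn(
            f"calibration with n={n_persons} persons is below the recommended 100",
            stacklevel=2,
        )

    # fixed base nodes in z-space; theta nodes re-mapped as sigma updates.
    # The base set is affinely standardised to exact zero mean and identity
    # covariance: otherwise its small sampling bias re-enters the latent
    # covariance update every sweep and the slopes drift instead of converging.
    u = qmc.Halton(d=N_FACTORS, scramble=True, seed=settings.seed).random(settings.n_qmc)
    z_base = ndtri(np.clip(u, 1e-12, 1 - 1e-12))
    z_base = z_base - z_base.mean(axis=0)
    z_base = z_base @ np.linalg.inv(np.linalg.cholesky(np.cov(z_base.T, bias=True))).T

    sigma = (
        np.eye(N_FACTORS)
        if settings.sigma_start is None
        else np.asarray(settings.sigma_start, dtype=float).copy()
    )

    # starting values: unit slopes, intercepts from marginal cumulative logits
    a = np.ones(n_items)
    d_list: list[np.ndarray] = []
    onehots: list[np.ndarray] = []
    obs_masks: list[np.ndarray] = []
    for j in range(n_items):
        obs = x[:, j] >= 0
        obs_masks.append(obs)
        k = n_cats[j]
        counts = np.bincount(x[obs, j], minlength=k).astype(float)
        p_ge = 1.0 - np.cumsum(counts)[:-1] / counts.sum()
        p_ge = np.clip(p_ge, 1e-3, 1 - 1e-3)
        d0 = np.log(p_ge / (1 - p_ge))
        d0 = np.minimum.accumulate(d0 - 1e-6 * np.arange(k - 1))  # enforce strict order
        d_list.append(d0)
        oh = np.zeros((n_persons, k))
        oh[obs, x[obs, j]] = 1.0
        onehots.append(oh)

    def pack(a_vec, d_vecs):
        return np.concatenate([_params_to_c(a_vec[j], d_vecs[j]) for j in range(n_items)])

    def unpack(cvec):
        a_out = np.empty(n_items)
        d_out = []
        pos = 0
        for j in range(n_items):
            ln = 1 + n_cats[j] - 1
            aj, dj = _c_to_params(cvec[pos : pos + ln])
            a_out[j] = aj
            d_out.append(dj)
            pos += ln
        return a_out, d_out

    def observed_loglik_and_weights(a_vec, d_vecs, sigma_mat):
        chol = np.linalg.cholesky(sigma_mat)
        nodes = z_base @ chol.T
        log_l = np.zeros((n_persons, settings.n_qmc))
        node_f = nodes[:, factors]  # (n_qmc, n_items)
        for j in range(n_items):
            zj = a_vec[j] * node_f[:, j][:, None] + d_vecs[j]
            cum = expit(zj)
            full = np.concatenate(
                [np.ones((settings.n_qmc, 1)), cum, np.zeros((settings.n_qmc, 1))], axis=1
            )
            logp = np.log(np.maximum(full[:, :-1] - full[:, 1:], PROB_FLOOR))
            obs = obs_masks[j]
            log_l[obs] += logp[:, x[obs, j]].T
        per_person = logsumexp(log_l, axis=1) - np.log(settings.n_qmc)
        w = np.exp(log_l - per_person[:, None] - np.log(settings.n_qmc))
        return float(per_person.sum()), w, nodes

    c_curr = pack(a, d_list)
    c_prev = None
    c_prev_step = None
    fallback_c = None
    skip_accel = 0
    trace: list[float] = []
    converged = False
    n_iter = 0

    for it in range(1, settings.max_iter + 1):
        n_iter = it
        a, d_list = unpack(c_curr)
        ll, w, nodes = observed_loglik_and_weights(a, d_list, sigma)

        # safeguard: a Ramsay step that dropped the likelihood is rolled back
        if trace and ll < trace[-1] - 1e-3 and fallback_c is not None:
            c_curr = fallback_c
            fallback_c = None
            skip_accel = 2
            a, d_list = unpack(c_curr)
            ll, w, nodes = observed_loglik_and_weights(a, d_list, sigma)
        trace.append(ll)

        # M-step: items
        node_f = nodes[:, factors]
        c_new_parts = []
        pos = 0
        for j in range(n_items):
            ln = n_cats[j]
            counts = w[obs_masks[j]].T @ onehots[j][obs_masks[j]]
            c_new_parts.append(_mstep_item(c_curr[pos : pos + ln], node_f[:, j], counts))
            pos += ln
        c_new = np.concatenate(c_new_parts)
        a_new, d_new = unpack(c_new)

        # M-step: latent covariance from posterior second moments
        sigma_new = sigma
        if settings.estimate_sigma:
            col_w = w.sum(axis=0)
            s_mat = (nodes * col_w[:, None]).T @ nodes / n_persons
            scale = np.sqrt(np.diag(s_mat))
            sigma_new = s_mat / np.outer(scale, scale)
            sigma_new = 0.5 * (sigma_new + sigma_new.T)
            # identification: rescale slopes so the likelihood is unchanged
            a_new = a_new * scale[factors]
            c_new_parts = []
            d_tmp = []
            for j in range(n_items):
                d_tmp.append(d_new[j])
                c_new_parts.append(_params_to_c(a_new[j], d_new[j]))
            c_new = np.concatenate(c_new_parts)
            d_new = d_tmp

        delta = max(
            float(np.max(np.abs(a_new - a))),
            max(float(np.max(np.abs(d_new[j] - d_list[j]))) for j in range(n_items)),
            float(np.max(np.abs(sigma_new - sigma))),
        )

        sigma = sigma_new
        c_unaccel = c_new

        # Ramsay-style extrapolation of item parameters
        accelerated = False
        if settings.ramsay and skip_accel == 0 and c_prev is not None:
            step = c_new - c_curr
            if c_prev_step is not None:
                denom = np.linalg.norm(c_prev_step)
                r = np.linalg.norm(step) / denom if denom > 0 else np.inf
                if 0.0 < r < 1.0:
                    mult = min(r / (1.0 - r), 5.0)
                    c_new = c_new + mult * step
                    accelerated = True
            c_prev_step = step
        elif c_prev is not None:
            c_prev_step = c_new - c_curr
        if skip_accel > 0:
            skip_accel -= 1

        fallback_c = c_unaccel if accelerated else None
        c_prev = c_curr
        c_curr = c_new

        if delta < settings.tol:
            converged = True
            # one final evaluation at the accepted parameters
            a, d_list = unpack(c_unaccel)
            c_curr = c_unaccel
            ll, _, _ = observed_loglik_and_weights(a, d_list, sigma)
            trace.append(ll)
            break

    a, d_list = unpack(c_curr)
    items = []
    for j, iid in enumerate(item_ids):
        items.append(
            Item(id=iid, factor=int(factors[j]), slope=float(a[j]), intercepts=tuple(d_list[j]))
        )
    bank = ItemBank(
        items=items, sigma=sigma, factor_names=FACTOR_NAMES, require_all_factors=False
    )
    return FitResult(
        bank=bank,
        n_iterations=n_iter,
        loglik=trace[-1],
        converged=converged,
        loglik_trace=trace,
        category_maps=remaps,
    )


# ---------------------------------------------------------------------------
# local independence
# ---------------------------------------------------------------------------

@dataclass
class Q3Result:
    matrix: pd.DataFrame
    flags: list[tuple[str, str, float]]
    threshold: float = Q3_FLAG_THRESHOLD


def q3_local_dependence(
    responses: ResponseMatrix,
    fit: FitResult | ItemBank,
    threshold: float = Q3_FLAG_THRESHOLD,
) -> Q3Result:
    """Q3 residual-correlation screen for local dependence.

    Residuals are ``x_pj - E[X_j | theta_hat_p]`` with per-person MAP trait
    estimates; Q3 is the Pearson correlation matrix of residual columns.
    Pairs with ``|Q3| >= threshold`` (default 0.50) are flagged for review;
    flagging is report-only.  Degenerate zero-variance residual columns
    yield NaN entries.
    """
    bank = fit.bank if isinstance(fit, FitResult) else fit
    item_ids = [c for c in responses.item_ids if c in bank.item_ids]
    x = responses.data[item_ids].to_numpy(dtype=float)
    x_full = _align_for_map(bank, item_ids, x)
    mats = BankMatrices(bank)
    thetas = map_batch(x_full, bank, mats=mats)
    cols = [bank.index_of(i) for i in item_ids]
    expected = np.empty_like(x)
    kmax = mats.kmax
    karange = np.arange(kmax)
    for p in range(x.shape[0]):
        probs = mats.cat_probs(thetas[p])  # (J, kmax)
        expected[p] = (probs[cols] * karange).sum(axis=1)
    resid = np.where(np.isnan(x), np.nan, x - expected)
    frame = pd.DataFrame(resid, columns=item_ids)
    q3 = frame.corr()
    np.fill_diagonal(q3.values, np.nan)
    flags = []
    for i in range(len(item_ids)):
        for j in range(i + 1, len(item_ids)):
            v = q3.iloc[i, j]
            if not np.isnan(v) and abs(v) >= threshold:
                flags.append((item_ids[i], item_ids[j], float(v)))
    return Q3Result(matrix=q3, flags=flags, threshold=threshold)


def _align_for_map(bank: ItemBank, item_ids: list[str], x: np.ndarray) -> np.ndarray:
    full = np.full((x.shape[0], len(bank)), np.nan)
    for k, iid in enumerate(item_ids):
        full[:, bank.index_of(iid)] = x[:, k]
    return full
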