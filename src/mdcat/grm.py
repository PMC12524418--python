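"""Graded-response-model mathematics.

Category probabilities, expected Fisher information, log-likelihoods,
response simulation and item characteristic curves, for simple-structure
multidimensional GRMs.  All functions accept a 4-vector ``theta`` on the
standard-normal latent metric; values are clamped to [-6, 6] before use.

``BankMatrices`` packs a bank into flat arrays for the vectorised hot paths
used by the scorer and the adaptive engine.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .bank import Item, ItemBank, N_FACTORS

THETA_CLAMP = 6.0
PROB_FLOOR = 1e-300
#: Sentinel for padded intercept slots; expit underflows to exactly 0.
_NEG_BIG = -1e30


def clamp_theta(theta) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    return np.clip(theta, -THETA_CLAMP, THETA_CLAMP)


def _cum_probs(item: Item, theta_f: np.ndarray) -> np.ndarray:
    """P(X >= k | theta) for k = 1..K-1; shape (..., K-1)."""
    d = np.asarray(item.intercepts)
    z = item.slope * np.asarray(theta_f)[..., None] + d
    return expit(z)


def category_prob(item: Item, theta) -> np.ndarray:
    """Probability of each of the K categories at ``theta``.

    P(X = k) = P(X >= k) - P(X >= k+1) with P(X >= 0) = 1, P(X >= K) = 0.
    Entries are non-negative and sum to 1 to machine precision.
    """
    theta = clamp_theta(theta)
    cum = _cum_probs(item, theta[item.factor])
    full = np.concatenate([[1.0], np.atleast_1d(cum.squeeze()), [0.0]])
    return full[:-1] - full[1:]


def category_prob_curve(item: Item, theta_f: np.ndarray) -> np.ndarray:
    """Category probabilities along the item's own factor; shape (n, K)."""
    theta_f = np.clip(np.asarray(theta_f, dtype=float), -THETA_CLAMP, THETA_CLAMP)
    cum = _cum_probs(item, theta_f)
    n = cum.shape[0]
    full = np.concatenate([np.ones((n, 1)), cum, np.zeros((n, 1))], axis=1)
    return full[:, :-1] - full[:, 1:]


def scalar_information(item: Item, theta_f: float) -> float:
    """Expected Fisher information along the item's own factor.

    I(theta) = sum_k (dP_k/dtheta)^2 / P_k with dP_k/dtheta =
    a * (g_k - g_{k+1}), g_k = P*_k (1 - P*_k) and g_0 = g_K = 0.
    """
    tf = float(np.clip(theta_f, -THETA_CLAMP, THETA_CLAMP))
    cum = _cum_probs(item, np.array(tf)).ravel()
    full = np.concatenate([[1.0], cum, [0.0]])
    g = full * (1.0 - full)
    p = full[:-1] - full[1:]
    dp = item.slope * (g[:-1] - g[1:])
    return float(np.sum(dp * dp / np.maximum(p, PROB_FLOOR)))


def item_information(item: Item, theta) -> np.ndarray:
    """4x4 expected Fisher information matrix of one item at ``theta``.

    Rank <= 1 under simple structure: the only nonzero entry sits at
    (factor, factor).
    """
    theta = clamp_theta(theta)
    info = np.zeros((N_FACTORS, N_FACTORS))
    info[item.factor, item.factor] = scalar_information(item, theta[item.factor])
    return info


def log_likelihood(responses: Mapping[str, int], bank: ItemBank, theta) -> float:
    """Log-likelihood of one person's responses at ``theta``.

    Missing items are simply absent from ``responses``.  Each category
    probability is floored at 1e-300, so the result is finite.
    """
    clean = {k: v for k, v in responses.items() if v is not None and not pd.isna(v)}
    if not clean:
        raise ValueError("cannot compute a likelihood from an all-missing response vector")
    theta = clamp_theta(theta)
    total = 0.0
    for item_id, x in clean.items():
        p = category_prob(bank[item_id], theta)
        total += float(np.log(max(p[int(x)], PROB_FLOOR)))
    return total


def simulate_response(item: Item, theta, rng) -> int:
    """Draw one category from the model at ``theta`` (seeded, reproducible)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    p = np.maximum(category_prob(item, theta), 0.0)
    p = p / p.sum()
    return int(rng.choice(item.n_categories, p=p))


def icc_table(item: Item, grid: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Item characteristic curves along the item's factor.

    Returns ``(grid, probs)`` with ``probs[i, k] = P(X = k | grid[i])``,
    off-factor coordinates held at 0.  Default grid: [-4, 4] step 0.05.
    """
    if grid is None:
        grid = np.round(np.arange(-4.0, 4.0 + 1e-9, 0.05), 10)
    grid = np.asarray(grid, dtype=float)
    return grid, category_prob_curve(item, grid)


def icc_long_frame(items: Sequence[Item], grid: np.ndarray | None = None) -> pd.DataFrame:
    """Long-format ICC table (item, theta, category, probability) for export."""
    rows = []
    for item in items:
        g, probs = icc_table(item, grid)
        for k in range(item.n_categories):
            rows.append(
                pd.DataFrame(
                    {
                        "item": item.id,
                        "theta": g,
                        "category": k,
                        "probability": probs[:, k],
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


class BankMatrices:
    """Flat-array view of a bank for vectorised likelihood/information work.

    Intercepts are right-padded with a large negative sentinel so that the
    padded cumulative probabilities underflow to exactly 0 and padded
    categories carry zero probability.
    """

    def __init__(self, bank: ItemBank):
        self.bank = bank
        self.n_items = len(bank)
        self.item_ids = bank.item_ids
        self.slopes = np.array([it.slope for it in bank], dtype=float)
        self.factors = np.array([it.factor for it in bank], dtype=np.int64)
        self.n_cats = np.array([it.n_categories for it in bank], dtype=np.int64)
        kmax = int(self.n_cats.max())
        self.kmax = kmax
        self.d_pad = np.full((self.n_items, kmax - 1), _NEG_BIG)
        for j, it in enumerate(bank):
            self.d_pad[j, : it.n_categories - 1] = it.intercepts
        self.exposure_weights = np.array([it.exposure_weight for it in bank], dtype=float)

    # -- vectorised model quantities --------------------------------------
    def cum_probs(self, theta: np.ndarray) -> np.ndarray:
        """P(X_j >= k) for all items; shape (J, kmax-1), 0 on padded slots."""
        z = self.slopes[:, None] * theta[self.factors][:, None] + self.d_pad
        return expit(z)

    def cat_probs(self, theta: np.ndarray) -> np.ndarray:
        """Category probabilities for all items; shape (J, kmax)."""
        cum = self.cum_probs(theta)
        j = self.n_items
        full = np.concatenate([np.ones((j, 1)), cum, np.zeros((j, 1))], axis=1)
        return full[:, :-1] - full[:, 1:]

    def loglik_and_grad(
        self, idx: np.ndarray, cats: np.ndarray, theta: np.ndarray
    ) -> tuple[float, np.ndarray]:
        """Log-likelihood and its 4-gradient for responses ``cats`` to items ``idx``."""
        theta = np.clip(theta, -THETA_CLAMP, THETA_CLAMP)
        a = self.slopes[idx]
        f = self.factors[idx]
        z = a[:, None] * theta[f][:, None] + self.d_pad[idx]
        cum = expit(z)
        n = len(idx)
        full = np.concatenate([np.ones((n, 1)), cum, np.zeros((n, 1))], axis=1)
        p = full[:, :-1] - full[:, 1:]
        g = full * (1.0 - full)
        rows = np.arange(n)
        px = np.maximum(p[rows, cats], PROB_FLOOR)
        ll = float(np.sum(np.log(px)))
        dpx = a * (g[rows, cats] - g[rows, cats + 1])
        coef = dpx / px
        grad = np.zeros(N_FACTORS)
        np.add.at(grad, f, coef)
        return ll, grad

    def loglik_grad_hess(
        self, idx: np.ndarray, cats: np.ndarray, theta: np.ndarray
    ) -> tuple[float, np.ndarray, np.ndarray]:
        """Log-likelihood, gradient and observed Hessian (4x4, diagonal under
        simple structure) for one person's responses."""
        theta = np.clip(theta, -THETA_CLAMP, THETA_CLAMP)
        a = self.slopes[idx]
        f = self.factors[idx]
        z = a[:, None] * theta[f][:, None] + self.d_pad[idx]
        cum = expit(z)
        n = len(idx)
        full = np.concatenate([np.ones((n, 1)), cum, np.zeros((n, 1))], axis=1)
        p = full[:, :-1] - full[:, 1:]
        g = full * (1.0 - full)  # d cum / dz
        gp = g * (1.0 - 2.0 * full)  # d^2 cum / dz^2
        rows = np.arange(n)
        px = np.maximum(p[rows, cats], PROB_FLOOR)
        ll = float(np.sum(np.log(px)))
        dpx = a * (g[rows, cats] - g[rows, cats + 1])
        d2px = a * a * (gp[rows, cats] - gp[rows, cats + 1])
        coef = dpx / px
        curv = d2px / px - coef**2  # d^2 log p / d theta_f^2, always <= 0
        grad = np.zeros(N_FACTORS)
        np.add.at(grad, f, coef)
        hess = np.zeros((N_FACTORS, N_FACTORS))
        np.add.at(hess, (f, f), curv)
        return ll, grad, hess

    def scalar_info_all(self, theta: np.ndarray) -> np.ndarray:
        """Expected information of every item along its own factor; shape (J,)."""
        theta = np.clip(theta, -THETA_CLAMP, THETA_CLAMP)
        cum = self.cum_probs(theta)
        j = self.n_items
        full = np.concatenate([np.ones((j, 1)), cum, np.zeros((j, 1))], axis=1)
        g = full * (1.0 - full)
        p = full[:, :-1] - full[:, 1:]
        dp = self.slopes[:, None] * (g[:, :-1] - g[:, 1:])
        with np.errstate(invalid="ignore", divide="ignore"):
            terms = np.where(p > PROB_FLOOR, dp * dp / np.maximum(p, PROB_FLOOR), 0.0)
        return terms.sum(axis=1)

    def simulate_matrix(self, thetas: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Simulate an (n_persons, J) integer response matrix from the model."""
        thetas = np.asarray(thetas, dtype=float)
        n = thetas.shape[0]
        out = np.empty((n, self.n_items), dtype=np.int64)
        u = rng.random((n, self.n_items))
        for j in range(self.n_items):
            item_theta = np.clip(thetas[:, self.factors[j]], -THETA_CLAMP, THETA_CLAMP)
            z = self.slopes[j] * item_theta[:, None] + self.d_pad[j]
            cum = expit(z)  # (n, kmax-1), zero on pads
            # X = #{k : u < P(X >= k)} computed via cumulative comparison
            out[:, j] = (u[:, j][:, None] < cum).sum(axis=1)
        return out
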