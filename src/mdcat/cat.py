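"""The adaptive administration loop.

One session runs: start item -> administer -> re-score (MAP) -> stopping
check -> select next item -> administer -> ...  Selection rules:

* ``DP`` (default): maximise det(Sigma^-1 + sum_administered I_i(theta_hat)
  + I_j(theta_hat)) — determinant rule on the prior-augmented posterior
  information;
* ``D``: same without the prior precision term;
* ``KL`` / ``KLn``: integrated Kullback-Leibler divergence between the
  response distributions at theta_hat and at nearby trait values, over a
  delta-box (KLn scales delta with sqrt(n administered));
* ``random``: uniform draw.

Stopping combines trait-specific SE thresholds, a Delta-theta stability
clause and hard length limits.  The shipped default configuration is:
start item demo18, DP rule, SE thresholds 0.45 (demoralization,
depression) / 0.50 (anxiety, irritability), Delta-theta 0.01, length 4-25.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import yaml

from .bank import ItemBank, N_FACTORS
from .grm import BankMatrices
from .scoring import LatentState, _map_from_arrays

SELECTION_RULES = ("DP", "D", "KL", "KLn", "random")
STOP_REASONS = ("se_met", "delta_theta", "max_items", "bank_exhausted")

#: Final configuration: SE 0.45 for demoralization and depression,
#: 0.50 for anxiety and irritability, in canonical factor order.
DEFAULT_SE_THRESHOLDS = (0.45, 0.50, 0.50, 0.45)


class CatSessionError(RuntimeError):
    """Answer-provider failure; ``session`` carries the partial session."""

    def __init__(self, message: str, session: "CatSession"):
        super().__init__(message)
        self.session = session


@dataclass
class CatConfig:
    """Administration settings (defaults = the shipped final configuration)."""

    start_item_id: str = "demo18"
    selection_rule: str = "DP"
    se_thresholds: tuple[float, float, float, float] = DEFAULT_SE_THRESHOLDS
    delta_theta_stop: float = 0.01
    min_items: int = 4
    max_items: int = 25
    exposure_pool: int = 1  # randomesque candidate-pool size; 1 = off
    use_exposure_weights: bool = True
    kl_delta: float = 0.1
    kl_grid_points: int = 11
    adaptive_start: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.selection_rule not in SELECTION_RULES:
            raise ValueError(
                f"selection_rule must be one of {SELECTION_RULES}, got {self.selection_rule!r}"
            )
        thr = tuple(float(t) for t in self.se_thresholds)
        if len(thr) != N_FACTORS or any(not (0 < t <= 1) for t in thr):
            raise ValueError("se_thresholds must be 4 values in (0, 1]")
        self.se_thresholds = thr
        if not (1 <= self.min_items <= self.max_items):
            raise ValueError("need 1 <= min_items <= max_items")
        if self.delta_theta_stop < 0:
            raise ValueError("delta_theta_stop must be >= 0 (0 disables the clause)")
        if self.kl_delta <= 0:
            raise ValueError("kl_delta must be > 0")
        if self.exposure_pool < 1:
            raise ValueError("exposure_pool must be >= 1")

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["se_thresholds"] = list(self.se_thresholds)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "CatConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown CatConfig fields: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "CatConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML superset covers JSON
        return cls.from_dict(data or {})


@dataclass
class CatSession:
    """Record of one adaptive administration."""

    items: list[str] = field(default_factory=list)
    responses: list[int] = field(default_factory=list)
    trajectory: list[LatentState] = field(default_factory=list)
    stop_reason: str | None = None

    @property
    def final(self) -> LatentState:
        return self.trajectory[-1]

    @property
    def n_items(self) -> int:
        return len(self.items)

    def to_dict(self) -> dict:
        return {
            "items": list(self.items),
            "responses": list(self.responses),
            "stop_reason": self.stop_reason,
            "trajectory": [
                {
                    "theta": s.theta.tolist(),
                    "se": s.se.tolist(),
                    "n_items": s.n_items,
                }
                for s in self.trajectory
            ],
        }


def start_item(config: CatConfig, bank: ItemBank, mats: BankMatrices | None = None) -> str:
    """First item of a session.

    Default: the configured fixed start (``demo18``).  With
    ``adaptive_start``, the item maximising the DP determinant at the prior
    mean theta = 0 is used instead.
    """
    if config.adaptive_start:
        mats = mats or BankMatrices(bank)
        prior_prec = np.linalg.inv(bank.sigma)
        infos = mats.scalar_info_all(np.zeros(N_FACTORS))
        best, best_det = None, -np.inf
        for j in range(mats.n_items):
            m = prior_prec.copy()
            m[mats.factors[j], mats.factors[j]] += infos[j]
            det = np.linalg.det(m)
            if det > best_det:
                best, best_det = j, det
        return mats.item_ids[best]
    if config.start_item_id not in bank.item_ids:
        raise KeyError(f"start item {config.start_item_id!r} not in bank")
    return config.start_item_id


def _kl_scores(
    mats: BankMatrices, candidates: np.ndarray, theta: np.ndarray, delta: float, n_grid: int
) -> np.ndarray:
    """Integrated KL index per candidate.

    Under simple structure the integrand varies only along the candidate's
    own factor, so the 4-dim box integral reduces to a 1-dim grid average
    times the box volume (2*delta)^4; the volume is common to all
    candidates at a given step and kept only for units.
    """
    probs_here = mats.cat_probs(theta)  # (J, kmax)
    logp_here = np.log(np.maximum(probs_here, 1e-300))
    scores = np.empty(len(candidates))
    offsets = np.linspace(-delta, delta, n_grid)
    for i, j in enumerate(candidates):
        f = mats.factors[j]
        grid = np.clip(theta[f] + offsets, -6.0, 6.0)
        z = mats.slopes[j] * grid[:, None] + mats.d_pad[j]
        from scipy.special import expit

        cum = expit(z)
        full = np.concatenate([np.ones((n_grid, 1)), cum, np.zeros((n_grid, 1))], axis=1)
        p_grid = np.maximum(full[:, :-1] - full[:, 1:], 1e-300)
        kl = np.sum(probs_here[j] * (logp_here[j] - np.log(p_grid)), axis=1)
        scores[i] = kl.mean() * (2.0 * delta) ** 4
    return scores


def select_next(
    state: LatentState,
    bank: ItemBank,
    administered: Sequence[str],
    config: CatConfig,
    rng: np.random.Generator | None = None,
    mats: BankMatrices | None = None,
) -> str:
    """Pick the next item among unadministered candidates.

    Exposure control is randomesque: after ranking (scores multiplied by
    per-item exposure weights when enabled), one of the top
    ``exposure_pool`` candidates is drawn uniformly.  Ties break on the
    lowest bank index, so selection is deterministic given the seed.
    """
    mats = mats or BankMatrices(bank)
    admin_idx = [mats.item_ids.index(i) for i in administered]
    candidates = np.array(
        [j for j in range(mats.n_items) if j not in set(admin_idx)], dtype=np.int64
    )
    if len(candidates) == 0:
        raise LookupError("no unadministered items remain; the session must stop")
    rng = rng or np.random.default_rng(config.seed)
    theta = state.theta

    if config.selection_rule == "random":
        return mats.item_ids[int(rng.choice(candidates))]

    if config.selection_rule in ("DP", "D"):
        infos = mats.scalar_info_all(theta)
        if config.selection_rule == "DP":
            base = state.info.copy()  # prior precision + administered info at theta_hat
        else:
            base = np.zeros((N_FACTORS, N_FACTORS))
            for j in admin_idx:
                base[mats.factors[j], mats.factors[j]] += infos[j]
        mstack = np.broadcast_to(base, (len(candidates), N_FACTORS, N_FACTORS)).copy()
        ff = mats.factors[candidates]
        mstack[np.arange(len(candidates)), ff, ff] += infos[candidates]
        scores = np.linalg.det(mstack)
    else:  # KL / KLn
        delta = config.kl_delta
        if config.selection_rule == "KLn":
            delta = delta * np.sqrt(max(len(administered), 1))
        scores = _kl_scores(mats, candidates, theta, delta, config.kl_grid_points)

    if config.use_exposure_weights:
        scores = scores * mats.exposure_weights[candidates]

    # stable ranking: descending score, ascending bank index on ties
    order = np.lexsort((candidates, -scores))
    pool = candidates[order[: min(config.exposure_pool, len(candidates))]]
    pick = pool[0] if len(pool) == 1 else pool[int(rng.integers(len(pool)))]
    return mats.item_ids[int(pick)]


def should_stop(
    state: LatentState,
    config: CatConfig,
    n_administered: int,
    theta_history: Sequence[np.ndarray],
) -> tuple[bool, str | None]:
    """Evaluate the stopping rules after ``n_administered`` items.

    Stop iff (n >= min_items AND [all four SEs at/below their thresholds OR
    the max coordinate change of theta_hat since the previous item is
    strictly below delta_theta_stop]) OR n >= max_items.  The precision
    clause wins ties.
    """
    if n_administered >= config.min_items:
        if np.all(state.se <= np.asarray(config.se_thresholds)):
            return True, "se_met"
        if config.delta_theta_stop > 0 and len(theta_history) >= 2:
            change = np.max(np.abs(theta_history[-1] - theta_history[-2]))
            if change < config.delta_theta_stop:
                return True, "delta_theta"
    if n_administered >= config.max_items:
        return True, "max_items"
    return False, None


def run_session(
    answer_provider: Callable[[str], int],
    bank: ItemBank,
    config: CatConfig | None = None,
    rng: np.random.Generator | None = None,
    mats: BankMatrices | None = None,
) -> CatSession:
    """Run one adaptive session, querying ``answer_provider(item_id)``.

    The trait estimate is refreshed by MAP after every response; the
    trajectory records the prior state first, then one state per item.
    """
    config = config or CatConfig()
    mats = mats or BankMatrices(bank)
    rng = rng or np.random.default_rng(config.seed)
    prior_prec = np.linalg.inv(bank.sigma)

    session = CatSession()
    state = _map_from_arrays(
        np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64), mats, prior_prec
    )
    session.trajectory.append(state)
    idx_list: list[int] = []
    cat_list: list[int] = []
    next_id = start_item(config, bank, mats)

    while True:
        j = mats.item_ids.index(next_id)
        try:
            x = int(answer_provider(next_id))
        except Exception as exc:
            raise CatSessionError(f"answer provider failed on {next_id!r}: {exc}", session)
        if not (0 <= x < mats.n_cats[j]):
            raise CatSessionError(
                f"invalid category {x} for item {next_id!r} (0..{mats.n_cats[j] - 1})", session
            )
        session.items.append(next_id)
        session.responses.append(x)
        idx_list.append(j)
        cat_list.append(x)
        state = _map_from_arrays(
            np.asarray(idx_list), np.asarray(cat_list), mats, prior_prec, start=state.theta
        )
        session.trajectory.append(state)

        stop, reason = should_stop(
            state, config, len(idx_list), [s.theta for s in session.trajectory]
        )
        if stop:
            session.stop_reason = reason
            break
        try:
            next_id = select_next(state, bank, session.items, config, rng=rng, mats=mats)
        except LookupError:
            session.stop_reason = "bank_exhausted"
            break
    return session


def simulate_session(
    true_theta: np.ndarray,
    bank: ItemBank,
    config: CatConfig | None = None,
    seed: int | np.random.Generator | None = None,
    mats: BankMatrices | None = None,
) -> CatSession:
    """Adaptive session for a virtual respondent with known traits.

    One seeded generator drives both the model response draws and any
    exposure/selection randomness, so a (true_theta, seed) pair replays
    bit-identically.
    """
    mats = mats or BankMatrices(bank)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    true_theta = np.asarray(true_theta, dtype=float)

    def provider(item_id: str) -> int:
        j = mats.item_ids.index(item_id)
        tf = float(np.clip(true_theta[mats.factors[j]], -6, 6))
        from scipy.special import expit

        cum = expit(mats.slopes[j] * tf + mats.d_pad[j])
        return int((rng.random() < cum).sum())

    return run_session(provider, bank, config, rng=rng, mats=mats)


def save_session(session: CatSession, path: str | Path) -> None:
    Path(path).write_text(json.dumps(session.to_dict(), indent=2) + "\n")
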