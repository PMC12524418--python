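"""Item banks, calibrated item parameters and response matrices.

The measurement model is a multidimensional graded response model (GRM)
with simple structure: every item loads on exactly one of four correlated
latent traits (demoralization, anxiety, irritability, depression).  An item
with K ordered categories 0..K-1 is parameterised by a positive slope ``a``
and K-1 strictly decreasing intercepts ``d`` on the logistic metric,

    P(X >= k | theta) = logistic(a * theta_f + d_k),   k = 1..K-1,

where ``theta_f`` is the trait the item measures.  Banks serialise to a
canonical JSON schema; responses travel as wide CSV (one row per person,
one column per item, empty cell = missing).
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical factor order used throughout the package.
FACTOR_NAMES: tuple[str, str, str, str] = (
    "demoralization",
    "anxiety",
    "irritability",
    "depression",
)

N_FACTORS = 4


class BankValidationError(ValueError):
    """An item bank violates a structural invariant."""


class ResponseValidationError(ValueError):
    """A response matrix is inconsistent with its bank."""


@dataclass(frozen=True)
class Item:
    """A single graded-response item.

    Parameters
    ----------
    id
        Unique label within the bank (convention: ``demo1..demo24``,
        ``anx1..anx6``, ``irr1..irr5``, ``phq_a..phq_i``).
    factor
        Index of the trait the item loads on, 0..3 in :data:`FACTOR_NAMES`
        order.
    slope
        Discrimination ``a`` > 0 on the logistic metric (no 1.7 constant).
    intercepts
        Strictly decreasing category-boundary intercepts ``d_1 > ... >
        d_{K-1}``; the number of response categories is ``len(intercepts)+1``.
    text
        Optional display stem shown during administration.
    alias
        Optional free-text source-scale name (e.g. the originating
        questionnaire's own item number).
    exposure_weight
        Positive multiplier applied to selection-rule scores; 1 = neutral.
    """

    id: str
    factor: int
    slope: float
    intercepts: tuple[float, ...]
    text: str | None = None
    alias: str | None = None
    exposure_weight: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "intercepts", tuple(float(d) for d in self.intercepts))
        object.__setattr__(self, "slope", float(self.slope))
        self.validate()

    @property
    def n_categories(self) -> int:
        return len(self.intercepts) + 1

    def validate(self) -> None:
        if not self.id:
            raise BankValidationError("item id must be a non-empty string")
        if not (0 <= int(self.factor) < N_FACTORS):
            raise BankValidationError(
                f"item {self.id}: factor must be in 0..{N_FACTORS - 1}, got {self.factor}"
            )
        if not (math.isfinite(self.slope) and self.slope > 0):
            raise BankValidationError(f"item {self.id}: slope must be positive, got {self.slope}")
        d = np.asarray(self.intercepts, dtype=float)
        if d.size < 1 or not np.all(np.isfinite(d)):
            raise BankValidationError(f"item {self.id}: needs >= 1 finite intercept")
        if not np.all(np.diff(d) < 0):
            raise BankValidationError(
                f"item {self.id}: intercepts strictly decreasing required, got {tuple(d)}"
            )
        if not (math.isfinite(self.exposure_weight) and self.exposure_weight > 0):
            raise BankValidationError(
                f"item {self.id}: exposure_weight must be positive, got {self.exposure_weight}"
            )


@dataclass(eq=False)
class ItemBank:
    """An ordered collection of items plus the factor-correlation prior.

    ``sigma`` is the 4x4 latent correlation matrix used both as the scoring
    prior and as the population model for simulated respondents.
    """

    items: list[Item]
    sigma: np.ndarray
    factor_names: tuple[str, ...] = FACTOR_NAMES
    #: Calibration of a partial bank (e.g. a single instrument) may leave
    #: factors without items; ordinary banks require all four covered.
    require_all_factors: bool = True

    def __post_init__(self) -> None:
        self.items = list(self.items)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.factor_names = tuple(self.factor_names)
        self.validate()

    # -- structural checks -------------------------------------------------
    def validate(self) -> None:
        if len(self.factor_names) != N_FACTORS:
            raise BankValidationError("factor_names must have exactly 4 entries")
        ids = [it.id for it in self.items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise BankValidationError(f"duplicate item ids: {dupes}")
        present = {it.factor for it in self.items}
        if self.require_all_factors and present != set(range(N_FACTORS)):
            missing = sorted(set(range(N_FACTORS)) - present)
            raise BankValidationError(f"no items for factor index(es) {missing}")
        s = self.sigma
        if s.shape != (N_FACTORS, N_FACTORS):
            raise BankValidationError(f"sigma must be 4x4, got {s.shape}")
        if not np.allclose(s, s.T, atol=1e-10):
            raise BankValidationError("sigma must be symmetric")
        if not np.allclose(np.diag(s), 1.0, atol=1e-10):
            raise BankValidationError("sigma must have unit diagonal")
        ev = np.linalg.eigvalsh(s)
        if ev.min() <= 1e-10:
            raise BankValidationError(
                f"sigma must be positive definite; smallest eigenvalue {ev.min():.3e}"
            )
        for it in self.items:
            it.validate()

    # -- convenience accessors --------------------------------------------
    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    @property
    def item_ids(self) -> list[str]:
        return [it.id for it in self.items]

    def __getitem__(self, item_id: str) -> Item:
        for it in self.items:
            if it.id == item_id:
                return it
        raise KeyError(item_id)

    def index_of(self, item_id: str) -> int:
        for i, it in enumerate(self.items):
            if it.id == item_id:
                return i
        raise KeyError(item_id)

    def items_for_factor(self, factor: int) -> list[Item]:
        return [it for it in self.items if it.factor == factor]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ItemBank):
            return NotImplemented
        return (
            self.factor_names == other.factor_names
            and np.array_equal(self.sigma, other.sigma)
            and self.items == other.items
        )

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        items = []
        for it in self.items:
            rec: dict = {
                "id": it.id,
                "text": it.text,
                "factor": int(it.factor),
                "n_categories": it.n_categories,
                "slope": it.slope,
                "intercepts": list(it.intercepts),
                "exposure_weight": it.exposure_weight,
            }
            if it.alias is not None:
                rec["alias"] = it.alias
            items.append(rec)
        return {
            "factor_names": list(self.factor_names),
            "sigma": [list(row) for row in self.sigma.tolist()],
            "items": items,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ItemBank":
        try:
            factor_names = tuple(data["factor_names"])
            sigma = np.asarray(data["sigma"], dtype=float)
            raw_items = data["items"]
        except KeyError as exc:  # pragma: no cover - message matters, not path
            raise BankValidationError(f"bank file missing required field {exc}") from exc
        items = []
        for rec in raw_items:
            try:
                n_cat = rec.get("n_categories")
                item = Item(
                    id=rec["id"],
                    factor=int(rec["factor"]),
                    slope=float(rec["slope"]),
                    intercepts=tuple(float(d) for d in rec["intercepts"]),
                    text=rec.get("text"),
                    alias=rec.get("alias"),
                    exposure_weight=float(rec.get("exposure_weight", 1.0)),
                )
            except KeyError as exc:
                raise BankValidationError(
                    f"item record {rec.get('id', '<no id>')} missing field {exc}"
                ) from exc
            if n_cat is not None and int(n_cat) != item.n_categories:
                raise BankValidationError(
                    f"item {item.id}: n_categories={n_cat} does not match "
                    f"{len(item.intercepts)} intercepts + 1"
                )
            items.append(item)
        return cls(items=items, sigma=sigma, factor_names=factor_names)


def save_bank(bank: ItemBank, path: str | Path) -> None:
    """Write ``bank`` as canonical JSON (stable key order, 2-space indent).

    Two saves of equal banks produce byte-identical files, and
    ``load_bank(save_bank(b)) == b`` exactly (JSON float repr round-trips).
    """
    payload = json.dumps(bank.to_dict(), indent=2) + "\n"
    Path(path).write_text(payload)


def load_bank(path: str | Path) -> ItemBank:
    """Load and validate an item bank from its JSON schema."""
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise BankValidationError(f"bank file {path} is not valid JSON: {exc}") from exc
    return ItemBank.from_dict(data)


@dataclass
class ResponseMatrix:
    """Persons x items ordinal responses with explicit missingness.

    Backed by a float DataFrame (person ids as index, item ids as columns);
    missing cells are NaN, never 0.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)

    @property
    def person_ids(self) -> list:
        return list(self.data.index)

    @property
    def item_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_persons(self) -> int:
        return len(self.data)

    def responses_for(self, person_id) -> dict[str, int]:
        """Non-missing responses of one person as ``{item_id: category}``."""
        row = self.data.loc[person_id]
        return {c: int(v) for c, v in row.items() if not pd.isna(v)}

    def validate(self, bank: ItemBank) -> None:
        unknown = [c for c in self.data.columns if c not in bank.item_ids]
        if unknown:
            raise ResponseValidationError(f"response columns not in bank: {unknown}")
        for col in self.data.columns:
            n_cat = bank[col].n_categories
            vals = self.data[col].dropna()
            bad = vals[(vals < 0) | (vals >= n_cat) | (vals != np.floor(vals))]
            if len(bad):
                person, value = bad.index[0], bad.iloc[0]
                raise ResponseValidationError(
                    f"person {person!r}, item {col!r}: value {value!r} outside "
                    f"categories 0..{n_cat - 1}"
                )

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        # keep integer rendering for non-missing cells
        out = out.astype("Int64")
        out.to_csv(path, index_label="person_id")

    @classmethod
    def from_arrays(
        cls,
        values: np.ndarray,
        item_ids: Sequence[str],
        person_ids: Sequence | None = None,
    ) -> "ResponseMatrix":
        values = np.asarray(values, dtype=float)
        if person_ids is None:
            person_ids = [f"p{i + 1}" for i in range(values.shape[0])]
        return cls(pd.DataFrame(values, index=list(person_ids), columns=list(item_ids)))


def load_responses(path: str | Path, bank: ItemBank) -> ResponseMatrix:
    """Read a wide response CSV and validate it against ``bank``.

    First column = person id; empty cells become missing (NaN).
    """
    try:
        df = pd.read_csv(path, index_col=0)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ResponseValidationError(f"cannot parse response CSV {path}: {exc}") from exc
    rm = ResponseMatrix(df)
    rm.validate(bank)
    return rm


def save_responses(rm: ResponseMatrix, path: str | Path) -> None:
    rm.to_csv(path)
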