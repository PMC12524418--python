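import numpy as np
import pytest

from mdcat import ItemBank, Item, make_synthetic_bank
from mdcat.grm import BankMatrices


@pytest.fixture(scope="session")
def default_bank() -> ItemBank:
    """The default 44-item synthetic bank (24/6/5/9, published correlations)."""
    return make_synthetic_bank(seed=20240101)


@pytest.fixture(scope="session")
def default_mats(default_bank) -> BankMatrices:
    return BankMatrices(default_bank)


def _minimal_items():
    """One weakly informative item per factor, used to pad toy banks."""
    return [
        Item(id=f"pad{f}", factor=f, slope=0.5, intercepts=(0.0,))
        for f in range(4)
    ]


@pytest.fixture
def toy_bank_2f() -> ItemBank:
    """Toy bank whose informative items sit on factors 0 and 1 only.

    Sigma is block-diagonal (r=0.5 between factors 0-1, identity elsewhere),
    so the MAP of (theta_0, theta_1) decouples from the untouched factors
    and a 2-d grid search is a valid oracle.
    """
    sigma = np.eye(4)
    sigma[0, 1] = sigma[1, 0] = 0.5
    items = [
        Item(id="f0a", factor=0, slope=1.8, intercepts=(1.2, 0.0, -1.2)),
        Item(id="f0b", factor=0, slope=1.2, intercepts=(0.8, -0.6)),
        Item(id="f0c", factor=0, slope=2.2, intercepts=(0.5,)),
        Item(id="f1a", factor=1, slope=1.5, intercepts=(1.0, -0.3, -1.5)),
        Item(id="f1b", factor=1, slope=2.0, intercepts=(0.2, -0.9)),
        Item(id="f1c", factor=1, slope=1.0, intercepts=(-0.4,)),
        Item(id="pad2", factor=2, slope=0.5, intercepts=(0.0,)),
        Item(id="pad3", factor=3, slope=0.5, intercepts=(0.0,)),
    ]
    return ItemBank(items=items, sigma=sigma)


@pytest.fixture
def small_bank() -> ItemBank:
    """10-item, 4-factor toy bank for selection-rule oracles."""
    rng = np.random.default_rng(99)
    items = []
    for j in range(10):
        f = j % 4
        a = float(rng.uniform(1.0, 2.5))
        b = np.sort(rng.normal(0.2, 1.0, size=3))
        items.append(Item(id=f"t{j}", factor=f, slope=a, intercepts=tuple(-a * b)))
    sigma = np.array(
        [
            [1.0, 0.671, 0.526, 0.93],
            [0.671, 1.0, 0.759, 0.60],
            [0.526, 0.759, 1.0, 0.498],
            [0.93, 0.60, 0.498, 1.0],
        ]
    )
    return ItemBank(items=items, sigma=sigma)
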