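import numpy as np
import pytest

from phenomask import Category, SheetRecipe, generate_sheet


SMALL_COUNTS = {Category.BUD: 3, Category.FLOWER: 3,
                Category.IMMATURE_FRUIT: 2, Category.MATURE_FRUIT: 2}


@pytest.fixture(scope="session")
def small_recipe() -> SheetRecipe:
    """A quick-to-render sheet with a few organs of every category."""
    return SheetRecipe(width=600, height=600, counts=dict(SMALL_COUNTS), seed=11)


@pytest.fixture(scope="session")
def small_sheet(small_recipe):
    """(image, ground truth) pair rendered once per session."""
    return generate_sheet(small_recipe)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


def make_square(x: int, y: int, side: int):
    """Axis-aligned square polygon with exact pixel area side**2."""
    return [(x, y), (x + side, y), (x + side, y + side), (x, y + side)]
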