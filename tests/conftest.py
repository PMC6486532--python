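import numpy as np
import pandas as pd
import pytest

from irtmarkov import (
    DiaryDataset,
    ItemSpec,
    PopulationParams,
    SubjectEffects,
    sample_subject_effects,
)
from irtmarkov.simulate import simulate_dataset


@pytest.fixture
def item3() -> ItemSpec:
    """Symmetric 3-category item used in hand-computed examples."""
    return ItemSpec(item_id=1, n_categories=3, a=1.0, b=(-1.0, 1.0))


@pytest.fixture
def small_items() -> tuple[ItemSpec, ...]:
    return (
        ItemSpec(1, 5, 1.8, (-1.5, -0.3, 0.8, 2.0)),
        ItemSpec(2, 4, 1.2, (-1.0, 0.4, 1.6)),
        ItemSpec(3, 5, 2.3, (-0.8, 0.2, 1.2, 2.2)),
    )


@pytest.fixture
def small_pop(small_items) -> PopulationParams:
    return PopulationParams(
        items=small_items, slope_mean=0.2, slope_sd=0.1, met0=2.0, met_iiv_sd=0.3
    )


def complete_design(n_subjects: int, n_days: int) -> pd.DataFrame:
    return pd.concat(
        [
            pd.DataFrame({"subject_id": s + 1, "day": np.arange(1, n_days + 1)})
            for s in range(n_subjects)
        ],
        ignore_index=True,
    )


@pytest.fixture
def tiny_dataset(small_pop) -> DiaryDataset:
    """3 subjects x 3 items x 20 complete days."""
    eff = sample_subject_effects(small_pop, 3, seed=5)
    ds = simulate_dataset(small_pop, eff, complete_design(3, 20), seed=7)
    ds.true_effects = eff
    return ds


def random_item(rng, K=None) -> ItemSpec:
    K = K if K is not None else int(rng.integers(4, 6))
    a = float(rng.uniform(0.5, 3.0))
    b = np.sort(rng.uniform(-3, 3, K - 1))
    return ItemSpec(item_id=1, n_categories=K, a=a, b=tuple(b))
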