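import numpy as np
import pytest

from endoflow import reference, simulate
from endoflow.gating import EventSample, PloidyCounts, SampleMeta


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def mixture_sample(rng):
    """5000 events from a 2C/4C/8C mixture (0.6/0.3/0.1), CV 3 %, no debris."""
    return simulate.simulate_events(
        [0.6, 0.3, 0.1], anchor_position=200.0, cv_percent=3.0,
        debris_fraction=0.0, n=5000, rng=rng,
        meta=SampleMeta(species="P. murinii", organ="root", individual="r1"),
    )


@pytest.fixture
def gs_table():
    return reference.genome_size_table()


@pytest.fixture
def prop_table():
    return reference.class_proportion_table()


@pytest.fixture
def param_table():
    return reference.endopoly_param_table()


def counts_from_row(row) -> PloidyCounts:
    """Fractional PloidyCounts from one published mean-proportion row."""
    return PloidyCounts.from_proportions(
        {c: float(row[f"{c}C"]) for c in reference.C_LEVELS if row[f"{c}C"] > 0},
        meta=SampleMeta(species=row["species"], organ=row["organ"]),
    )


def random_counts(rng, max_k: int = 5) -> PloidyCounts:
    """A random non-degenerate ploidy-count record for property tests."""
    k = rng.integers(1, max_k + 1)
    counts = {2 * 2**i: float(rng.integers(1, 500)) for i in range(k + 1)}
    return PloidyCounts(counts)
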