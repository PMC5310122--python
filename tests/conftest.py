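import numpy as np
import pytest

from coldqtl import MarkerMap, build_marker_map, make_f1, make_parents


@pytest.fixture
def small_map() -> MarkerMap:
    """4 chromosomes x 25 markers, yeast-like recombination rate."""
    return build_marker_map([1_000_000] * 4, 25, 380.0, seed=11)


@pytest.fixture
def tiny_map() -> MarkerMap:
    """One chromosome, 10 markers on a fixed grid (deterministic geometry)."""
    pos = np.arange(1, 11) * 100_000 - 50_000
    return MarkerMap(("chrA",), np.array([1_000_000]), (pos,), (pos * 380.0 / 1e6,),
                     np.array([380.0]))


@pytest.fixture
def parents(small_map):
    return make_parents(small_map)


@pytest.fixture
def f1(small_map):
    return make_f1(small_map, 50)
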