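import numpy as np
import pytest

from colocpcc import ChannelPair, SquarePairSpec, ThresholdPair, make_square_pair


@pytest.fixture(scope="session")
def square80():
    """1000x1000 pair of 80x80 squares at 0.8 with 25% overlap."""
    return make_square_pair(SquarePairSpec(side=80))


@pytest.fixture(scope="session")
def thr01():
    return ThresholdPair(green=0.1, red=0.1)


def naive_pcc(pair: ChannelPair, thresholds: ThresholdPair, criterion: str) -> float:
    """Double-loop Pearson over predicate-selected pixels.

    Deliberately naive and independent of the library's vectorised path:
    explicit per-pixel predicate, explicit two-pass mean/sum accumulation.
    """
    g_sel, r_sel = [], []
    for g, r in zip(pair.green.ravel(), pair.red.ravel()):
        if criterion == "all":
            keep = True
        elif criterion == "and":
            keep = g > thresholds.green and r > thresholds.red
        else:
            keep = g > thresholds.green or r > thresholds.red
        if keep:
            g_sel.append(g)
            r_sel.append(r)
    mg = sum(g_sel) / len(g_sel)
    mr = sum(r_sel) / len(r_sel)
    num = sum((g - mg) * (r - mr) for g, r in zip(g_sel, r_sel))
    den = (
        sum((g - mg) ** 2 for g in g_sel) * sum((r - mr) ** 2 for r in r_sel)
    ) ** 0.5
    return num / den


@pytest.fixture(scope="session")
def random_pair_factory():
    def make(seed: int, shape=(16, 16), high=20):
        rng = np.random.default_rng(seed)
        return ChannelPair(
            green=rng.integers(0, high, size=shape).astype(float),
            red=rng.integers(0, high, size=shape).astype(float),
        )

    return make
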