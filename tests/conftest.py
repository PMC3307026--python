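import pytest

from causalsig.ternary import Margins


@pytest.fixture
def small_margins():
    """q = (2, 1, 2), n = (1, 1, 3): 20 rearrangements, fully enumerable."""
    return Margins(2, 1, 2, 1, 1, 3)


def all_margin_pairs(t_values):
    """Every (q, n) composition pair for each ground-set size in t_values."""
    for t in t_values:
        comps = [(a, b, t - a - b) for a in range(t + 1) for b in range(t - a + 1)]
        for q in comps:
            for n in comps:
                yield Margins(*q, *n)
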