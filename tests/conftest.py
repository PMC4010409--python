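import numpy as np
import pytest
from hypothesis import settings as _hsettings

from ratesweep import Alignment, ClockTree

_hsettings.register_profile("repro", derandomize=True, deadline=None)
_hsettings.load_profile("repro")


def make_tree(parent, ages, labels=None):
    n = (len(parent) + 1) // 2
    labels = labels or [f"t{i}|0" for i in range(n)]
    return ClockTree(labels, np.asarray(parent), np.asarray(ages, dtype=float))


def make_alignment(seqs, ages=None, labels=None):
    labels = labels or [f"t{i}|0" for i in range(len(seqs))]
    ages = np.zeros(len(seqs)) if ages is None else np.asarray(ages, float)
    return Alignment.from_sequences(labels, seqs, ages)


@pytest.fixture
def tree3():
    # ((t0:1, t1:1):1, t2:2); all tips contemporaneous, root age 2
    return make_tree([3, 3, 4, 4, -1], [0, 0, 0, 1, 2])


@pytest.fixture
def tree4():
    # balanced 4-tip clock tree, root age 3
    return make_tree([4, 4, 5, 5, 6, 6, -1], [0, 0, 0, 0, 1, 2, 3])


@pytest.fixture
def tree5_serial():
    # 5 tips with staggered sampling ages
    parent = [5, 5, 6, 7, 8, 6, 7, 8, -1]
    ages = [0, 0, 1, 2, 5, 1.5, 3, 6, 9]
    return make_tree(parent, ages, labels=[f"t{i}|{a}" for i, a in
                                           enumerate([0, 0, 1, 2, 5])])


@pytest.fixture
def aln4():
    return make_alignment(["ACGTAC", "ACGTCC", "AGGTAT", "ACGAAC"])


def tiny_trees():
    """(name, tree) pairs covering 2-5 tips, serial and contemporaneous."""
    return [
        ("two", make_tree([2, 2, -1], [0, 0, 1.5])),
        ("three", make_tree([3, 3, 4, 4, -1], [0, 0, 0, 1, 2])),
        ("four", make_tree([4, 4, 5, 5, 6, 6, -1], [0, 0, 0, 0, 1, 2, 3])),
        ("five_serial", make_tree(
            [5, 5, 6, 7, 8, 6, 7, 8, -1], [0, 0, 1, 2, 5, 1.5, 3, 6, 9],
            labels=[f"t{i}|{a}" for i, a in enumerate([0, 0, 1, 2, 5])])),
    ]
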