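"""Shared fixtures: tiny contiguous barcode designs whose full allele
space is enumerable, and editing parameters with tightly bounded details,
so the brute-force oracle stays small."""

import numpy as np
import pytest

from gestaltree import BarcodeDesign, EditingParams
from gestaltree.editing import TrimMeans
from gestaltree.oracle import enumerate_allele_space
from gestaltree.trees import LineageTree, Node


def make_design(n_targets: int, width: int = 3, cut_offset: int = 1) -> BarcodeDesign:
    return BarcodeDesign(
        sequence=("ACGT" * (n_targets * width))[: n_targets * width],
        targets=tuple((i * width, (i + 1) * width) for i in range(n_targets)),
        cut_positions=tuple(i * width + cut_offset for i in range(n_targets)),
    )


def make_params(n_targets: int, **kwargs) -> EditingParams:
    defaults = dict(
        clock_rate=1.0,
        cut_rates=(1.0,) * n_targets,
        double_cut_weight=0.4,
        long_trim_left=0.3,
        long_trim_right=0.3,
        trim_means=TrimMeans(1.0, 0.5, 1.0, 0.5),
        insert_mean=0.5,
        max_insert_len=1,
    )
    defaults.update(kwargs)
    return EditingParams(**defaults)


@pytest.fixture(scope="session")
def design2():
    return make_design(2)


@pytest.fixture(scope="session")
def design3():
    return make_design(3)


@pytest.fixture(scope="session")
def params2():
    return make_params(2)


@pytest.fixture(scope="session")
def params3():
    return make_params(3, cut_rates=(1.0, 0.8, 1.2))


@pytest.fixture(scope="session")
def space2(design2, params2):
    return enumerate_allele_space(design2, params2)


@pytest.fixture(scope="session")
def space3(design3, params3):
    return enumerate_allele_space(design3, params3)


def cherry_tree(t: float = 0.6, labels=("a", "b")) -> LineageTree:
    root = Node(time=0.0)
    root.add_child(Node(labels[0], t))
    root.add_child(Node(labels[1], t))
    return LineageTree(root)


def three_leaf_tree(split: float = 0.3, tip: float = 0.8) -> LineageTree:
    root = Node(time=0.0)
    anc = root.add_child(Node(time=split))
    root.add_child(Node("c", tip))
    anc.add_child(Node("a", tip))
    anc.add_child(Node("b", tip))
    return LineageTree(root)


def caterpillar(n: int, step: float = 0.1) -> LineageTree:
    """Fully imbalanced n-tip tree."""
    root = Node(time=0.0)
    node = root
    tip_time = step * (n - 1)
    for i in range(n - 1):
        node.add_child(Node(f"t{i}", tip_time))
        if i < n - 2:
            node = node.add_child(Node(time=step * (i + 1)))
        else:
            node.add_child(Node(f"t{n - 1}", tip_time))
    return LineageTree(root)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
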