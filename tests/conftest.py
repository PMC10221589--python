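"""Shared fixtures: tiny synthetic datasets reused across test modules.

Everything is generated at test time with fixed seeds; the heavier
datasets are session-scoped so training-based tests share them.
"""

from __future__ import annotations

import numpy as np
import pytest

import liverscan as ls
from liverscan.hierarchy import GROUP1_LABELS

SUBJECTS = ["subjA", "subjB", "subjC", "subjD", "subjE"]
TRAIN_SUBJECTS = tuple(SUBJECTS[:3])
TEST_SUBJECTS = tuple(SUBJECTS[3:])


@pytest.fixture(scope="session")
def separable_specs():
    return ls.default_spec_set(ambiguity_overlap=0.0, seed=0)


@pytest.fixture(scope="session")
def overlap_specs():
    return ls.overlap_spec_set(0.6, seed=0)


@pytest.fixture(scope="session")
def small_dataset(separable_specs):
    """8 samples per class, 5 subjects: enough to train every stage."""
    return ls.generate_samples(separable_specs, 8, SUBJECTS, seed=11)


@pytest.fixture(scope="session")
def group1_overlap_dataset(overlap_specs):
    """Group-1-only frames with engineered ambiguity."""
    g1 = {k: v for k, v in overlap_specs.items() if k in GROUP1_LABELS}
    return ls.generate_samples(g1, 40, SUBJECTS, seed=2)


@pytest.fixture(scope="session")
def trained_hierarchy(small_dataset):
    from liverscan.hierarchy import HierarchyConfig, train_hierarchy

    train = [s for s in small_dataset if s.subject_id in TRAIN_SUBJECTS]
    return train_hierarchy(train, HierarchyConfig(seed=7))


def random_mask(rng: np.random.Generator, h: int = 12, w: int = 12):
    """A random non-degenerate binary mask."""
    from liverscan import BinaryMask

    n = int(rng.integers(1, h * w // 2))
    xs = rng.integers(0, w, size=n)
    ys = rng.integers(0, h, size=n)
    return BinaryMask(frozenset(zip(xs.tolist(), ys.tolist())), height=h, width=w)
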