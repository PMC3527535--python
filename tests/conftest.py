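"""Shared fixtures: bundled natives, toy systems, seeded RNGs."""

from __future__ import annotations

import numpy as np
import pytest

from knotfold import designer
from knotfold.designer import NativeSpec, _finalize
from knotfold.lattice import LatticeConformation, compute_contacts


@pytest.fixture(scope="session")
def protein_k():
    return designer.load_native("K")


@pytest.fixture(scope="session")
def protein_u():
    return designer.load_native("U")


@pytest.fixture(scope="session")
def toy_native8():
    """8-bead cube: a small foldable native with 4 contacts."""
    pos = np.array(
        [[0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
         [0, 1, 2], [1, 1, 2], [1, 0, 2], [0, 0, 2]]
    )
    conf = LatticeConformation(pos)
    spec = NativeSpec(8, len(compute_contacts(conf)), "unknot")
    return _finalize(pos, spec)


@pytest.fixture(scope="session")
def toy_native4():
    """The U-shaped 4-mer: the smallest chain with one contact."""
    pos = np.array([[0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]])
    conf = LatticeConformation(pos)
    spec = NativeSpec(4, 1, "unknot")
    return _finalize(pos, spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)


def straight_rod(n: int) -> LatticeConformation:
    pos = np.zeros((n, 3), dtype=np.int64)
    pos[:, 0] = np.arange(n)
    return LatticeConformation(pos)


@pytest.fixture()
def rod10():
    return straight_rod(10)
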