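"""Bundled fixtures: canonical lattice knot polygons and designed natives.

The polygon files hold one ``x y z`` integer vertex per line; the edge from
the last vertex back to the first is implicit.  Native structures are
stored in the plain-text conformation format of :mod:`knotfold.lattice`
with a JSON sidecar recording the design specification, search seed and
verification report.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np

__all__ = ["load_polygon", "polygon_names", "fixture_path"]

_POLYGONS = {
    "trefoil": "lattice_trefoil_24.txt",
    "figure_eight": "lattice_fig8_30.txt",
}


def polygon_names() -> list[str]:
    return sorted(_POLYGONS)


def fixture_path(filename: str):
    return resources.files(__package__) / filename


def load_polygon(name: str) -> np.ndarray:
    """Load a bundled closed lattice polygon by name (e.g. 'trefoil')."""
    if name not in _POLYGONS:
        raise KeyError(f"unknown polygon {name!r}; available: {polygon_names()}")
    text = fixture_path(_POLYGONS[name]).read_text()
    return np.array([line.split() for line in text.splitlines() if line.strip()],
                    dtype=np.int64)


def load_sidecar(name: str) -> dict:
    """Load the JSON sidecar of a designed native structure ('K' or 'U')."""
    return json.loads(fixture_path(f"protein_{name}.json").read_text())
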