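"""Go energetics and the Metropolis acceptance rule.

The energy of a conformation is the contact Hamiltonian

    H = sum_{i<j} epsilon * Delta(i, j),

where Delta(i, j) is 1 when beads i and j form a native contact and 0
otherwise, and epsilon (< 0, by default -1) is the uniform interaction
energy per native contact.  Non-native contacts are sterically allowed but
energetically neutral.  Temperature is measured in units of |epsilon|/k_B
with k_B = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lattice import ContactMap, LatticeConformation, compute_contacts, validate_contact_map

__all__ = ["GoEnergyModel", "energy", "metropolis_accept"]


@dataclass(frozen=True)
class GoEnergyModel:
    native_map: ContactMap
    epsilon: float = -1.0

    def __post_init__(self):
        if self.epsilon >= 0:
            raise ValueError("epsilon must be negative (native contacts are favourable)")
        object.__setattr__(self, "native_map", validate_contact_map(self.native_map))

    @property
    def n_native(self) -> int:
        return len(self.native_map)


def energy(conf: LatticeConformation, model: GoEnergyModel) -> float:
    """epsilon times the number of formed native contacts."""
    return model.epsilon * len(compute_contacts(conf) & model.native_map)


def metropolis_accept(delta_e: float, temperature: float, rng: np.random.Generator) -> bool:
    """Accept with probability min(1, exp(-dE / T)); T in epsilon/k_B units."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if delta_e <= 0:
        return True
    return rng.random() < np.exp(-delta_e / temperature)
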