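"""Grantham physicochemical distance model.

The model places each amino acid in a three-dimensional space of
composition (c, the atomic weight ratio of noncarbon elements in end
groups), polarity (p) and molecular volume (v).  The distance between two
residues is

    D(a, b) = rho * sqrt(alpha*(c_a-c_b)**2 + beta*(p_a-p_b)**2 + gamma*(v_a-v_b)**2)

with the classical weights alpha=1.833, beta=0.1018, gamma=0.000399 and the
scale rho chosen so that the mean over all 190 unordered residue pairs is
100.  This metric underlies both Grantham Variation (GV) and Grantham
Deviation (GD) used for missense grading.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import sqrt

__all__ = [
    "AMINO_ACIDS",
    "GRANTHAM_PROPERTIES",
    "GranthamModel",
    "DEFAULT_MODEL",
    "grantham_distance",
    "mean_pairwise_distance",
]

#: Classical composition / polarity / volume values for the 20 standard
#: amino acids (one-letter codes).
GRANTHAM_PROPERTIES: dict[str, tuple[float, float, float]] = {
    "S": (1.42, 9.2, 32.0),
    "R": (0.65, 10.5, 124.0),
    "L": (0.00, 4.9, 111.0),
    "P": (0.39, 8.0, 32.5),
    "T": (0.71, 8.6, 61.0),
    "A": (0.00, 8.1, 31.0),
    "V": (0.00, 5.9, 84.0),
    "G": (0.74, 9.0, 3.0),
    "I": (0.00, 5.2, 111.0),
    "F": (0.00, 5.2, 132.0),
    "Y": (0.20, 6.2, 136.0),
    "C": (2.75, 5.5, 55.0),
    "H": (0.58, 10.4, 96.0),
    "Q": (0.89, 10.5, 85.0),
    "N": (1.33, 11.6, 56.0),
    "K": (0.33, 11.3, 119.0),
    "D": (1.38, 13.0, 54.0),
    "E": (0.92, 12.3, 83.0),
    "M": (0.00, 5.7, 105.0),
    "W": (0.13, 5.4, 170.0),
}

AMINO_ACIDS: tuple[str, ...] = tuple(sorted(GRANTHAM_PROPERTIES))

ALPHA = 1.833
BETA = 0.1018
GAMMA = 0.000399


@dataclass(frozen=True)
class GranthamModel:
    """Physicochemical distance model with overridable constants.

    ``rho`` may be given explicitly; when ``None`` it is derived so that
    the mean unscaled distance over the 190 unordered pairs equals 100.
    """

    properties: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(GRANTHAM_PROPERTIES)
    )
    alpha: float = ALPHA
    beta: float = BETA
    gamma: float = GAMMA
    rho: float | None = None

    def __post_init__(self) -> None:
        if self.rho is None:
            mean = sum(
                self._unscaled(a, b) for a, b in combinations(sorted(self.properties), 2)
            ) / (len(self.properties) * (len(self.properties) - 1) / 2)
            object.__setattr__(self, "rho", 100.0 / mean)

    def _unscaled(self, aa1: str, aa2: str) -> float:
        c1, p1, v1 = self.properties[aa1]
        c2, p2, v2 = self.properties[aa2]
        return sqrt(
            self.alpha * (c1 - c2) ** 2
            + self.beta * (p1 - p2) ** 2
            + self.gamma * (v1 - v2) ** 2
        )

    def distance(self, aa1: str, aa2: str) -> float:
        """Scaled Grantham distance between two standard residues."""
        for aa in (aa1, aa2):
            if aa not in self.properties:
                raise ValueError(f"non-standard amino acid {aa!r}")
        return self.rho * self._unscaled(aa1, aa2)


DEFAULT_MODEL = GranthamModel()


def grantham_distance(aa1: str, aa2: str, model: GranthamModel = DEFAULT_MODEL) -> float:
    """Grantham distance between two amino acids (one-letter codes)."""
    return model.distance(aa1, aa2)


def mean_pairwise_distance(model: GranthamModel = DEFAULT_MODEL) -> float:
    """Mean distance over all unordered pairs of the model's residues."""
    pairs = list(combinations(sorted(model.properties), 2))
    return sum(model.distance(a, b) for a, b in pairs) / len(pairs)
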