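"""Query shape features: radius of gyration, sphericity, tail detection.

These features drive the query-adaptive weighting of the combined
all-atom / backbone distance. The all-atom surface discriminates better for
proteins with long tails, the backbone surface for near-spherical proteins;
the weights below encode exactly that.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import pi, sqrt
from typing import Callable

import numpy as np

from .structures import AtomSet

__all__ = [
    "ShapeFeatures",
    "radius_of_gyration",
    "sphericity",
    "tail_residue_count",
    "query_weights",
    "SPHERICITY_THRESHOLD",
    "TAIL_RESIDUE_THRESHOLD",
]

#: Finite atom-size correction used in the radius of gyration (Angstrom).
DEFAULT_ATOM_RADIUS = 1.5

#: Queries with sphericity above this are treated as spherical.
SPHERICITY_THRESHOLD = 0.15

#: Queries with more tail residues than this are treated as tailed.
TAIL_RESIDUE_THRESHOLD = 3


@dataclass
class ShapeFeatures:
    """Per-protein scalar shape summary."""

    rg: float  # radius of gyration, Angstrom
    sphericity: float
    tail_residues: int
    n_residues: int

    def __post_init__(self):
        if self.rg <= 0:
            raise ValueError("radius of gyration must be positive")
        if not 0 <= self.tail_residues <= self.n_residues:
            raise ValueError("tail_residues out of range")


def radius_of_gyration(
    atoms: AtomSet | np.ndarray, atom_radius: float = DEFAULT_ATOM_RADIUS
) -> float:
    """Radius of gyration with a finite atom-radius term added in quadrature.

    rg = sqrt( mean ||x_j - cog||^2 + R^2 ), unweighted over atoms, where R
    approximates the atom radius (1.5 A by default).
    """
    coords = atoms.coords if isinstance(atoms, AtomSet) else np.asarray(atoms, float)
    if atom_radius < 0:
        raise ValueError("atom_radius must be non-negative")
    cog = coords.mean(axis=0)
    msd = float(np.mean(np.sum((coords - cog) ** 2, axis=1)))
    return sqrt(msd + atom_radius**2)


def _sphericity_default(rg: float, rs: float) -> float:
    # a uniform solid ball of radius RS has rg = sqrt(3/5) RS, so the score
    # is 0 for a ball, < 0 for elongated shapes, > 0 for compact ones
    return 1.0 - rg / (sqrt(3.0 / 5.0) * rs)


def sphericity(
    atoms: AtomSet | np.ndarray,
    surface_volume: float,
    atom_radius: float = DEFAULT_ATOM_RADIUS,
    formula: Callable[[float, float], float] = _sphericity_default,
) -> float:
    """How compactly the shape fits a sphere of equal volume.

    ``surface_volume`` is the volume enclosed by the all-atom
    solvent-excluded surface (filled voxel count times voxel volume, A^3).
    RS is the radius of the equal-volume sphere. The comparison of the
    measured radius of gyration against that of a uniform ball of radius RS
    is pluggable via ``formula`` (signature ``(rg, rs) -> float``).
    """
    if surface_volume <= 0:
        raise ValueError("surface_volume must be positive")
    rg = radius_of_gyration(atoms, atom_radius)
    rs = (3.0 * surface_volume / (4.0 * pi)) ** (1.0 / 3.0)
    return float(formula(rg, rs))


def tail_residue_count(
    ca_positions: np.ndarray,
    rg: float | None = None,
    cog: np.ndarray | None = None,
) -> int:
    """Count residues in tail-like regions.

    A tail is a maximal run of consecutive residues, longer than three, all
    lying farther than twice the radius of gyration from the centre of
    gravity. Returns the total residue count over all such runs.

    ``rg`` and ``cog`` default to values computed from the C-alpha positions
    themselves (rg includes the 1.5 A atom-radius term).
    """
    pos = np.asarray(ca_positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 3 or len(pos) == 0:
        raise ValueError("ca_positions must be a non-empty (n, 3) array")
    if cog is None:
        cog = pos.mean(axis=0)
    if rg is None:
        rg = radius_of_gyration(pos)
    if rg <= 0:
        raise ValueError("rg must be positive")

    far = np.linalg.norm(pos - cog, axis=1) > 2.0 * rg
    total = 0
    run = 0
    for flag in np.append(far, False):  # sentinel closes a trailing run
        if flag:
            run += 1
        else:
            if run > TAIL_RESIDUE_THRESHOLD:
                total += run
            run = 0
    return total


def query_weights(
    features: ShapeFeatures, w_pair: tuple[float, float] = (0.3, 0.7)
) -> tuple[float, float]:
    """Weights (w_S for the all-atom surface, w_B for the backbone surface).

    Tailed queries favour the all-atom surface (0.7/0.3); spherical queries
    favour the backbone surface (0.3/0.7); everything else uses the fixed
    0.4/0.6 split.
    """
    w_low, w_high = w_pair
    if abs(w_low + w_high - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    if features.tail_residues > TAIL_RESIDUE_THRESHOLD:
        return (w_high, w_low)
    if features.sphericity > SPHERICITY_THRESHOLD:
        return (w_low, w_high)
    return (0.4, 0.6)
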