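"""Solvent-accessible surface area and buried dimer interface area.

SASA is computed with the Shrake–Rupley rolling-probe method: each heavy
atom's van der Waals sphere is inflated by the probe radius (water, 1.4 Å)
and sampled on a deterministic Fibonacci lattice; the exposed fraction of
sample points times the inflated-sphere area is the atom's accessible area.

The buried interface between two chains follows the ½ΔSASA convention used
by interface servers such as PISA:

    area = (SASA_A + SASA_B − SASA_AB) / 2

which for the loosest PPX dimer (the long-linker Deinococcus radiodurans
enzyme) is on the order of 1.1 × 10³ Å², while compact short-linker dimers
bury substantially more.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structio import Atom

__all__ = ["SasaResult", "InterfaceResult", "sasa", "interface_area", "VDW_RADII"]

# Bondi van der Waals radii (Å); hydrogens are excluded before computation
VDW_RADII: dict[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "SE": 1.90,
}
DEFAULT_RADIUS = 1.70
DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960


@dataclass(frozen=True)
class SasaResult:
    per_atom_area: np.ndarray  # Å² per atom
    probe_radius: float
    n_points: int

    @property
    def total(self) -> float:
        # fsum: exact, order-independent — keeps interface_area symmetric in
        # the chain order to the last bit
        return math.fsum(self.per_atom_area)


@dataclass(frozen=True)
class InterfaceResult:
    area: float     # Å², buried interface (½ΔSASA, clamped at 0)
    sasa_A: float
    sasa_B: float
    sasa_AB: float


def fibonacci_sphere(n: int) -> np.ndarray:
    """n points quasi-uniformly distributed on the unit sphere (golden-angle
    spiral); deterministic, no RNG."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / phi
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _radii_for(atoms: Sequence[Atom]) -> np.ndarray:
    radii = np.empty(len(atoms))
    for k, atom in enumerate(atoms):
        r = VDW_RADII.get(atom.element)
        if r is None:
            warnings.warn(
                f"no vdW radius for element {atom.element!r}; using {DEFAULT_RADIUS} Å",
                stacklevel=3,
            )
            r = DEFAULT_RADIUS
        radii[k] = r
    return radii


def sasa(
    atoms: Sequence[Atom],
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> SasaResult:
    """Shrake–Rupley solvent-accessible surface area over heavy atoms.

    Hydrogens must already be excluded (raise rather than silently drop, so
    that implicit- vs explicit-hydrogen conventions never mix).
    """
    if len(atoms) == 0:
        raise ValueError("sasa: no atoms given")
    if any(not a.is_heavy for a in atoms):
        raise ValueError("sasa: hydrogen atoms present; exclude them first")
    coords = np.vstack([a.coords for a in atoms])
    if not np.all(np.isfinite(coords)):
        raise ValueError("sasa: non-finite coordinates")

    radii = _radii_for(atoms) + probe
    sphere = fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * radii.max()

    per_atom = np.zeros(len(atoms))
    for i in range(len(atoms)):
        pts = coords[i] + radii[i] * sphere
        neighbors = [j for j in tree.query_ball_point(coords[i], max_reach) if j != i]
        if neighbors:
            nb_coords = coords[neighbors]
            nb_radii = radii[np.asarray(neighbors)]
            d2 = ((pts[:, None, :] - nb_coords[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nb_radii**2)[None, :]).any(axis=1)
            exposed_frac = 1.0 - buried.mean()
        else:
            exposed_frac = 1.0
        per_atom[i] = exposed_frac * 4.0 * np.pi * radii[i] ** 2
    return SasaResult(per_atom_area=per_atom, probe_radius=probe, n_points=n_points)


def interface_area(
    chain_a: Sequence[Atom],
    chain_b: Sequence[Atom],
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> InterfaceResult:
    """Buried interface area between two chains: ½(SASA_A + SASA_B − SASA_AB).

    Symmetric in the chain order by construction; clamped at zero against
    sampling noise. Near-duplicate atoms across the chains (inter-chain
    distance < 0.1 Å) draw a warning since they usually indicate a symmetry
    copy pasted onto itself.
    """
    if len(chain_a) == 0 or len(chain_b) == 0:
        raise ValueError("interface_area: both chains must be non-empty")
    ca = np.vstack([a.coords for a in chain_a])
    cb = np.vstack([a.coords for a in chain_b])
    dmin = cKDTree(ca).query(cb, k=1)[0].min()
    if dmin < 0.1:
        warnings.warn(
            f"overlapping atoms across chains (min distance {dmin:.3f} Å)",
            stacklevel=2,
        )
    sasa_a = sasa(chain_a, probe, n_points).total
    sasa_b = sasa(chain_b, probe, n_points).total
    sasa_ab = sasa(list(chain_a) + list(chain_b), probe, n_points).total
    area = max(0.0, (sasa_a + sasa_b - sasa_ab) / 2.0)
    return InterfaceResult(area=area, sasa_A=sasa_a, sasa_B=sasa_b, sasa_AB=sasa_ab)
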