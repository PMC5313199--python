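"""Surface-atom group definition and the dynamic contact-pair list.

The ambiguity restraint acts between two fixed groups of solvent-exposed
heavy atoms, one per binding partner, chosen once from the starting
conformation: an atom belongs to a group if its solvent-accessible
surface area (SASA), computed on the *isolated* partner with a 1.5 Å
probe, is at least 10 Å².  At every dynamics step the restraint sums
only over receptor–ligand surface-atom pairs currently closer than a
10 Å cutoff; that pair list is the only dynamic part.

SASA is evaluated by deterministic sphere-point sampling (Shrake–Rupley
with a fixed Fibonacci lattice), so results are reproducible bit-for-bit
for a given lattice size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .system_model import MolecularSystem

__all__ = [
    "SurfaceGroups",
    "ContactPairList",
    "atom_sasa",
    "select_surface_atoms",
    "build_contact_pairs",
]

DEFAULT_MIN_AREA = 10.0   # Å²
DEFAULT_PROBE = 1.5       # Å
DEFAULT_CUTOFF = 10.0     # Å
DEFAULT_N_POINTS = 960


@dataclass(frozen=True)
class SurfaceGroups:
    """Fixed surface-atom groups (global atom indices) and their areas."""

    receptor_atoms: np.ndarray
    ligand_atoms: np.ndarray
    areas: dict  # global atom index -> SASA (Å²) on the isolated partner
    min_area: float = DEFAULT_MIN_AREA

    def __post_init__(self):
        object.__setattr__(self, "receptor_atoms",
                           np.asarray(self.receptor_atoms, dtype=int))
        object.__setattr__(self, "ligand_atoms",
                           np.asarray(self.ligand_atoms, dtype=int))
        if self.receptor_atoms.size < 1 or self.ligand_atoms.size < 1:
            raise ValueError("surface groups must be non-empty on both partners")

    @property
    def n_r(self) -> int:
        return self.receptor_atoms.size

    @property
    def n_l(self) -> int:
        return self.ligand_atoms.size


@dataclass(frozen=True)
class ContactPairList:
    """Receptor–ligand surface pairs within the cutoff at one frame.

    ``receptor_idx``/``ligand_idx`` hold global atom indices; ``distances``
    the corresponding separations (all strictly below ``cutoff``).
    ``n_full`` is N_r·N_l, the unrestricted group-pair count used by the
    "full" normalization mode of the weighted mean distance.
    """

    receptor_idx: np.ndarray
    ligand_idx: np.ndarray
    distances: np.ndarray
    cutoff: float
    n_full: int

    @property
    def n_pairs(self) -> int:
        return self.distances.size

    def __len__(self) -> int:
        return self.distances.size


def fibonacci_sphere(n: int) -> np.ndarray:
    """n deterministic, nearly uniform unit vectors (Fibonacci lattice)."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def atom_sasa(coords, radii, probe: float = DEFAULT_PROBE,
              n_sphere_points: int = DEFAULT_N_POINTS) -> np.ndarray:
    """Per-atom solvent-accessible surface area, Å².

    Shrake–Rupley style: for each atom, points on a sphere of radius
    r_i + probe are tested for burial inside any neighbour sphere
    r_j + probe; the accessible fraction times the sphere area is the
    atom's SASA.  The point lattice is a fixed Fibonacci spiral, so the
    result is deterministic for a given ``n_sphere_points``.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if probe <= 0:
        raise ValueError("probe radius must be positive")
    if n_sphere_points < 92:
        raise ValueError("n_sphere_points must be at least 92")
    n = len(coords)
    if n == 0:
        return np.zeros(0)

    ext = radii + probe
    unit = fibonacci_sphere(n_sphere_points)
    areas = np.empty(n)

    tree = cKDTree(coords)
    max_ext = ext.max()
    for i in range(n):
        neighbors = [j for j in tree.query_ball_point(coords[i], ext[i] + max_ext)
                     if j != i]
        if neighbors:
            d = np.linalg.norm(coords[neighbors] - coords[i], axis=1)
            if np.any(d == 0.0):
                raise ValueError(f"coincident atom centers (atom {i}); SASA undefined")
            keep = d < ext[i] + ext[neighbors]
            neighbors = np.asarray(neighbors)[keep]
        if len(neighbors) == 0:
            areas[i] = 4.0 * np.pi * ext[i] ** 2
            continue
        pts = coords[i] + ext[i] * unit
        buried = np.zeros(n_sphere_points, dtype=bool)
        for j in neighbors:
            buried |= np.einsum(
                "ij,ij->i", pts - coords[j], pts - coords[j]) < ext[j] ** 2
        areas[i] = 4.0 * np.pi * ext[i] ** 2 * (1.0 - buried.mean())
    return areas


def select_surface_atoms(system: MolecularSystem,
                         min_area: float = DEFAULT_MIN_AREA,
                         probe: float = DEFAULT_PROBE,
                         n_sphere_points: int = DEFAULT_N_POINTS) -> SurfaceGroups:
    """Pick the surface heavy atoms of each *isolated* partner.

    Each partner's SASA is computed with the other partner absent, so the
    interface atoms of a bound starting pose still count as surface.
    Hydrogens are excluded throughout.  The selection is made once, from
    the system's starting coordinates, and held fixed for the whole run.
    """
    if min_area < 0:
        raise ValueError("min_area must be non-negative")
    heavy = system.heavy_mask()
    coords = system.coords
    radii = system.radii

    groups, areas = [], {}
    for part in (system.receptor_idx, system.ligand_idx):
        idx = part[heavy[part]]
        if idx.size == 0:
            raise ValueError("partner has no heavy atoms")
        a = atom_sasa(coords[idx], radii[idx], probe, n_sphere_points)
        sel = idx[a >= min_area]
        areas.update({int(i): float(v) for i, v in zip(idx, a)})
        if sel.size == 0:
            raise ValueError(
                f"empty surface selection (min_area={min_area} Å²); "
                "reduce the area threshold")
        groups.append(sel)
    return SurfaceGroups(groups[0], groups[1], areas, min_area)


def build_contact_pairs(groups: SurfaceGroups, coords,
                        cutoff: float = DEFAULT_CUTOFF) -> ContactPairList:
    """All receptor×ligand surface pairs strictly closer than ``cutoff``.

    Rebuilt from the current coordinates at every step.  An empty list is
    a valid result (the dissociation guard takes over downstream).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    coords = np.asarray(coords, dtype=float)
    d = cdist(coords[groups.receptor_atoms], coords[groups.ligand_atoms])
    ri, li = np.nonzero(d < cutoff)
    return ContactPairList(
        receptor_idx=groups.receptor_atoms[ri],
        ligand_idx=groups.ligand_atoms[li],
        distances=d[ri, li],
        cutoff=float(cutoff),
        n_full=groups.n_r * groups.n_l,
    )
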