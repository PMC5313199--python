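"""Molecular-system representation and structure/trajectory I/O.

A :class:`MolecularSystem` is an ordered list of atoms partitioned into a
receptor and a ligand index set.  Coordinates are in Å throughout.  PDB
reading/writing is delegated to :mod:`biotite`; the multi-frame XYZ
trajectory format used for replica output is written directly (it is a
three-line-header text format).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AtomRecord",
    "MolecularSystem",
    "read_pdb",
    "write_pdb",
    "write_xyz_trajectory",
    "read_xyz_trajectory",
    "vdw_radius",
    "atomic_mass",
]

# Bondi van der Waals radii, Å.
_BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
}
_DEFAULT_RADIUS = 1.70

_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "SE": 78.971,
}
_DEFAULT_MASS = 12.011


def vdw_radius(element: str) -> float:
    """Bondi van der Waals radius in Å; unknown elements get 1.7 Å."""
    key = element.strip().upper()
    if key not in _BONDI_RADII:
        warnings.warn(f"unknown element {element!r}: using vdW radius {_DEFAULT_RADIUS} Å")
        return _DEFAULT_RADIUS
    return _BONDI_RADII[key]


def atomic_mass(element: str) -> float:
    key = element.strip().upper()
    return _MASSES.get(key, _DEFAULT_MASS)


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, coordinates (Å), vdW radius (Å), mass (amu)."""

    serial: int
    name: str
    resname: str
    chain: str
    resid: int
    element: str
    coord: np.ndarray
    radius: float
    mass: float

    def __post_init__(self):
        coord = np.asarray(self.coord, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise ValueError(f"atom {self.serial}: coordinate must be a finite 3-vector")
        object.__setattr__(self, "coord", coord)
        if self.radius <= 0:
            raise ValueError(f"atom {self.serial}: radius must be positive")
        if self.mass <= 0:
            raise ValueError(f"atom {self.serial}: mass must be positive")

    @property
    def is_heavy(self) -> bool:
        return self.element.strip().upper() != "H"


@dataclass
class MolecularSystem:
    """Ordered atoms plus a disjoint receptor/ligand partition.

    ``receptor_idx`` and ``ligand_idx`` are sorted integer arrays that
    together cover every atom exactly once; both must be non-empty.
    """

    atoms: list[AtomRecord]
    receptor_idx: np.ndarray
    ligand_idx: np.ndarray
    _coords: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        n = len(self.atoms)
        rec = np.asarray(sorted(int(i) for i in self.receptor_idx), dtype=int)
        lig = np.asarray(sorted(int(i) for i in self.ligand_idx), dtype=int)
        if rec.size == 0 or lig.size == 0:
            raise ValueError("receptor and ligand index sets must both be non-empty")
        if np.intersect1d(rec, lig).size:
            raise ValueError("receptor and ligand index sets overlap")
        covered = np.union1d(rec, lig)
        if covered.size != n or covered[0] != 0 or covered[-1] != n - 1:
            raise ValueError("receptor ∪ ligand must cover all atoms exactly")
        self.receptor_idx = rec
        self.ligand_idx = lig
        if self._coords is None:
            self._coords = np.array([a.coord for a in self.atoms], dtype=float)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """Starting coordinates, shape (n_atoms, 3), Å."""
        return self._coords

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def heavy_mask(self) -> np.ndarray:
        return np.array([a.is_heavy for a in self.atoms], dtype=bool)

    def with_coords(self, coords: np.ndarray) -> "MolecularSystem":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError("coordinate frame has wrong shape")
        atoms = [replace(a, coord=c) for a, c in zip(self.atoms, coords)]
        return MolecularSystem(atoms, self.receptor_idx, self.ligand_idx, coords.copy())


class PDBParseError(ValueError):
    pass


def read_pdb(path, receptor_chains=None, ligand_chains=None) -> MolecularSystem:
    """Read a PDB file into a :class:`MolecularSystem`.

    By default the first chain encountered is the receptor and every other
    chain is the ligand; pass ``receptor_chains`` / ``ligand_chains``
    (iterables of chain IDs) to override.  Van der Waals radii come from
    the Bondi table, masses from standard atomic weights.
    """
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(model=1)
    except Exception as exc:  # re-raise with file context
        raise PDBParseError(f"cannot parse PDB file {path}: {exc}") from exc
    if arr.array_length() == 0:
        raise PDBParseError(f"{path}: no atoms")

    chains = list(dict.fromkeys(arr.chain_id))
    if receptor_chains is None:
        receptor_chains = {chains[0]}
    else:
        receptor_chains = set(receptor_chains)
    if ligand_chains is None:
        ligand_chains = set(chains) - receptor_chains
    else:
        ligand_chains = set(ligand_chains)
    if not receptor_chains or not ligand_chains:
        raise ValueError("receptor/ligand chain selection is empty")

    atoms, rec_idx, lig_idx = [], [], []
    for i in range(arr.array_length()):
        element = str(arr.element[i]).strip() or "C"
        chain = str(arr.chain_id[i])
        atoms.append(AtomRecord(
            serial=i + 1,
            name=str(arr.atom_name[i]),
            resname=str(arr.res_name[i]),
            chain=chain,
            resid=int(arr.res_id[i]),
            element=element,
            coord=np.asarray(arr.coord[i], dtype=float),
            radius=vdw_radius(element),
            mass=atomic_mass(element),
        ))
        if chain in receptor_chains:
            rec_idx.append(i)
        elif chain in ligand_chains:
            lig_idx.append(i)
        else:
            raise ValueError(f"chain {chain!r} assigned to neither receptor nor ligand")
    return MolecularSystem(atoms, np.array(rec_idx), np.array(lig_idx))


def write_pdb(system: MolecularSystem, coords, path) -> None:
    """Write one frame of a system as a standard PDB file.

    Occupancy/B-factor columns are 1.00/0.00.  Round-trips through
    :func:`read_pdb` at the format's 1e-3 Å precision.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    coords = np.asarray(coords, dtype=float)
    if coords.shape != (system.n_atoms, 3):
        raise ValueError(
            f"frame has {coords.shape} coordinates; system has {system.n_atoms} atoms")
    if np.any(np.abs(coords) >= 10000):
        raise ValueError("coordinates overflow fixed PDB columns (|x| >= 10000 Å)")

    arr = struc.AtomArray(system.n_atoms)
    arr.coord = coords
    for i, a in enumerate(system.atoms):
        arr.chain_id[i] = a.chain
        arr.res_id[i] = a.resid
        arr.res_name[i] = a.resname
        arr.atom_name[i] = a.name
        arr.element[i] = a.element
        arr.hetero[i] = False
    arr.set_annotation("occupancy", np.ones(system.n_atoms))
    arr.set_annotation("b_factor", np.zeros(system.n_atoms))
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def write_xyz_trajectory(store, replica: int, path) -> None:
    """Write one replica's frames from a trajectory store as multi-frame XYZ.

    The comment line of each block carries the step number and the bias
    energy of the frame.  An empty store produces an empty file and a
    warning.
    """
    frames = store.frames[replica]  # KeyError/IndexError for unknown replica
    records = store.records[replica]
    elements = store.elements
    with open(path, "w") as fh:
        if not frames:
            warnings.warn(f"replica {replica}: no frames recorded; writing empty file")
            return
        for frame, rec in zip(frames, records):
            fh.write(f"{len(frame)}\n")
            fh.write(f"step={rec['step']} bias={rec['bias'] + rec['guard']:.6f}\n")
            for el, (x, y, z) in zip(elements, frame):
                fh.write(f"{el:<2s} {x:15.8f} {y:15.8f} {z:15.8f}\n")


def read_xyz_trajectory(path):
    """Read a multi-frame XYZ file; returns (frames, comments)."""
    frames, comments = [], []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i])
        comments.append(lines[i + 1])
        block = lines[i + 2:i + 2 + n]
        coords = np.array([[float(v) for v in ln.split()[1:4]] for ln in block])
        frames.append(coords)
        i += 2 + n
    return frames, comments
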