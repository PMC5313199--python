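"""Synthetic desk-scale fixtures: sticky-shell docking systems, an
analytic harmonic pair, and mini PDB files.

The sticky-shell system emulates the failure mode the docking method is
built to escape: a bead receptor shell carrying one deep *native* site
and several shallower *decoy* (sticky) sites, with the ligand started
antipodal to the native site.  Plain Langevin dynamics tends to trap at
the first decoy on its way around the shell; the replica-exchange bias
lets the ligand detach slightly and slide.  Every generated system ships
with a grid-scan certificate that the declared native pose is the global
minimum of the receptor–ligand interaction over a placement scan.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ambiguity_bias import BiasWindow, bias_energy
from .surface_selection import SurfaceGroups, fibonacci_sphere
from .system_model import AtomRecord, MolecularSystem, write_pdb
from .toy_engine import RestraintSet, ToyForceField, cross_interaction_energy
from .units import KB

__all__ = [
    "ToyDockingSystem",
    "HarmonicPairSystem",
    "make_sticky_receptor",
    "make_harmonic_pair_system",
    "make_mini_pdb_fixture",
]


@dataclass
class ToyDockingSystem:
    """A sticky-shell receptor + bead ligand with a certified native pose."""

    system: MolecularSystem
    ff: ToyForceField
    restraints: RestraintSet
    native_pose: np.ndarray      # full-frame coordinates of the native complex
    native_site: int             # receptor bead index of the native site
    decoy_sites: list
    bead_radius: float
    metadata: dict = field(default_factory=dict)

    @property
    def bead_diameter(self) -> float:
        return 2.0 * self.bead_radius


def _tangent_polygon(center, normal, n_beads, side):
    """n beads in a regular polygon (or single bead) tangent to ``normal``."""
    normal = normal / np.linalg.norm(normal)
    if n_beads == 1:
        return center[None, :]
    # orthonormal tangent frame
    ref = np.array([1.0, 0.0, 0.0])
    if abs(normal @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    t1 = np.cross(normal, ref)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(normal, t1)
    if n_beads == 2:
        offsets = np.array([[-side / 2], [side / 2]]) * t1[None, :]
        return center + offsets
    circum = side / (2.0 * np.sin(np.pi / n_beads))
    ang = 2.0 * np.pi * np.arange(n_beads) / n_beads
    return center + circum * (np.cos(ang)[:, None] * t1 + np.sin(ang)[:, None] * t2)


def _grid_scan(system, ff, ligand_rel, directions, radii):
    """Scan rigid ligand placements; return (best_energy, best_center, table)."""
    best_e, best_center = np.inf, None
    coords = system.coords.copy()
    for u in directions:
        for r in radii:
            center = u * r
            coords[system.ligand_idx] = center + ligand_rel
            e = cross_interaction_energy(system, ff, coords)
            if e < best_e:
                best_e, best_center = e, center.copy()
    return best_e, best_center


def _relax_ligand(system, ff, coords):
    """Minimize cross-LJ + bond energy over the ligand coordinates."""
    from scipy.optimize import minimize

    from .toy_engine import RestraintSet as _RS
    from .toy_engine import compute_energy_forces as _cef

    lig = system.ligand_idx
    empty = _RS()
    base = coords.copy()

    def fun(x):
        frame = base.copy()
        frame[lig] = x.reshape(-1, 3)
        e, f, _ = _cef(system, ff, empty, None, frame)
        return e, -f[lig].ravel()

    res = minimize(fun, coords[lig].ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": 500})
    return res.x.reshape(-1, 3)


def make_sticky_receptor(n_receptor_beads: int = 64, n_ligand_beads: int = 1,
                         n_decoys: int = 4, native_depth: float = 15.0,
                         decoy_depth: float = 6.0, base_depth: float = 0.5,
                         sigma: float = 3.0, shell_radius: float = 5.0,
                         bond_k: float = 20.0, restraint_k: float = 0.5,
                         core_depth: float = 0.05, seed: int = 0,
                         certify: bool = True,
                         n_scan_directions: int = 256) -> ToyDockingSystem:
    """Build a sticky-shell docking system with a certified native site.

    Receptor beads sit on a Fibonacci lattice over a sphere of
    ``shell_radius`` Å (positionally restrained, ``restraint_k``
    kcal/mol/Å², mirroring the receptor backbone restraint used to keep
    binding partners folded).  The native site (LJ depth
    ``native_depth``) and ``n_decoys`` decoys (depth ``decoy_depth``)
    are placed at maximally spread beads by farthest-point selection;
    all remaining beads get ``base_depth``.  The ligand is a bonded
    bead polygon started antipodal to the native site.  ``seed`` only
    jitters bead positions by ±0.05 Å so replicate systems differ
    slightly; the construction is otherwise deterministic.

    The default bead density (64 beads on a 5 Å shell, spacing ≈ 2.2 Å
    < σ) makes the shell impenetrable to the ligand, and the interior is
    filled with inert core beads (LJ depth ``core_depth``) so that the
    hollow centre — which the long attractive LJ tails would otherwise
    turn into a spurious global minimum — is sterically excluded, as in
    a real protein.  Core beads are buried and therefore drop out of
    the surface groups via the SASA selection.  The grid-scan
    certificate includes interior placements to verify all this.
    """
    if not native_depth > decoy_depth > 0:
        raise ValueError("need native_depth > decoy_depth > 0")
    if n_decoys < 1:
        raise ValueError("need at least one decoy site")
    if n_decoys + 1 > n_receptor_beads:
        raise ValueError("more sites than receptor beads")

    rng = np.random.default_rng(seed)
    units = fibonacci_sphere(n_receptor_beads)
    rec_coords = units * shell_radius
    rec_coords = rec_coords + rng.uniform(-0.05, 0.05, rec_coords.shape)
    units = rec_coords / np.linalg.norm(rec_coords, axis=1)[:, None]

    # inert core filling: inner shell(s) + centre bead, spaced like the
    # outer shell so the interior is sterically excluded
    spacing = np.sqrt(4.0 * np.pi * shell_radius ** 2 / n_receptor_beads)
    core_coords = [np.zeros((1, 3))]
    r_inner = shell_radius - 0.8 * sigma
    while r_inner > 0.6 * spacing:
        n_inner = max(4, int(round(4.0 * np.pi * r_inner ** 2 / spacing ** 2)))
        core_coords.append(fibonacci_sphere(n_inner) * r_inner)
        r_inner -= 0.8 * sigma
    core_coords = np.vstack(core_coords)
    n_core = len(core_coords)

    # farthest-point site selection: native first (bead nearest +z), then
    # decoys maximizing the minimum angular distance to chosen sites
    native_site = int(np.argmax(units[:, 2]))
    sites = [native_site]
    for _ in range(n_decoys):
        cosmax = np.max(units @ units[sites].T, axis=1)
        cosmax[sites] = 2.0
        sites.append(int(np.argmin(cosmax)))
    decoy_sites = sites[1:]

    min_cos = max(units[a] @ units[b]
                  for i, a in enumerate(sites) for b in sites[i + 1:])
    min_chord = shell_radius * np.sqrt(max(0.0, 2.0 - 2.0 * min_cos))
    if min_chord < 2.0 * sigma:
        raise ValueError(
            f"sites too crowded: minimum separation {min_chord:.2f} Å "
            f"< 2σ = {2 * sigma:.2f} Å; reduce n_decoys")

    eps = np.full(n_receptor_beads + n_core, base_depth)
    eps[decoy_sites] = decoy_depth
    eps[native_site] = native_depth
    eps[n_receptor_beads:] = core_depth

    contact = 2.0 ** (1.0 / 6.0) * sigma
    native_dir = units[native_site]
    start_dir = -native_dir
    lig_start = _tangent_polygon(start_dir * (shell_radius + contact),
                                 start_dir, n_ligand_beads, sigma)
    lig_native = _tangent_polygon(native_dir * (shell_radius + contact),
                                  native_dir, n_ligand_beads, sigma)

    atoms = []
    all_rec = np.vstack([rec_coords, core_coords])
    for i, c in enumerate(all_rec):
        resname = "REC" if i < n_receptor_beads else "COR"
        atoms.append(AtomRecord(i + 1, "C", resname, "A", i + 1, "C", c,
                                sigma / 2.0, 12.011))
    n_r = len(all_rec)
    for i, c in enumerate(lig_start):
        atoms.append(AtomRecord(n_r + i + 1, "C", "LIG", "B", i + 1, "C", c,
                                sigma / 2.0, 12.011))
    system = MolecularSystem(atoms, np.arange(n_r),
                             np.arange(n_r, n_r + n_ligand_beads))

    bonds = []
    lig_idx = system.ligand_idx
    for a in range(n_ligand_beads):
        for b in range(a + 1, n_ligand_beads):
            r0 = float(np.linalg.norm(lig_start[a] - lig_start[b]))
            bonds.append((int(lig_idx[a]), int(lig_idx[b]), r0, bond_k))
    ff = ToyForceField(sigma=sigma, eps_cross=eps, eps_intra_ligand=0.0,
                       bonds=bonds)
    restraints = RestraintSet(
        positional=[(int(i), all_rec[i].copy(), restraint_k)
                    for i in range(n_r)])

    # the declared native pose is the relaxed bottom of the native basin:
    # start from the constructed tangent pose atop the native bead (or from
    # the best nearby grid placement when certifying) and minimize
    native_pose = system.coords.copy()
    native_pose[system.ligand_idx] = lig_native
    native_pose[system.ligand_idx] = _relax_ligand(system, ff, native_pose)

    metadata = {"seed": seed, "native_depth": native_depth,
                "decoy_depth": decoy_depth, "base_depth": base_depth,
                "sigma": sigma, "shell_radius": shell_radius}
    toy = ToyDockingSystem(system, ff, restraints, native_pose, native_site,
                           decoy_sites, sigma / 2.0, metadata)
    if certify:
        lig_rel = lig_native - lig_native.mean(axis=0)
        dirs = np.vstack([fibonacci_sphere(n_scan_directions), units])
        radii = np.concatenate([
            shell_radius + contact + np.array([-0.5, 0.0, 0.5]),
            [0.35 * shell_radius, 0.6 * shell_radius],  # interior must be worse
        ])
        best_e, best_center = _grid_scan(system, ff, lig_rel, dirs, radii)
        # re-relax from the grid optimum: the declared native pose is the
        # bottom of the basin the scan found
        probe_pose = system.coords.copy()
        probe_pose[system.ligand_idx] = best_center + lig_rel
        relaxed = _relax_ligand(system, ff, probe_pose)
        native_pose[system.ligand_idx] = relaxed
        toy.native_pose = native_pose
        native_center = relaxed.mean(axis=0)
        dist = float(np.linalg.norm(best_center - native_center))
        on_native_site = bool(
            np.linalg.norm(native_center - units[native_site]
                           * (shell_radius + contact)) <= 2.0 * sigma)
        metadata["certificate"] = {
            "n_placements": len(dirs) * len(radii),
            "best_energy": best_e,
            "distance_to_native": dist,
            "certified": dist <= sigma / 2.0 and on_native_site,
        }
        if not metadata["certificate"]["certified"]:
            raise ValueError(
                f"native pose failed grid-scan certification: global "
                f"minimum {dist:.2f} Å from declared pose"
                + ("" if on_native_site else
                   " (global minimum not at the native site)"))
    return toy


@dataclass
class HarmonicPairSystem:
    """One fixed bead + one on-axis mobile bead with a harmonic separation.

    Base potential U(r) = ½ k_base (r − x0)²; the exact stationary
    densities under any bias window (including the dissociation guard
    beyond the cutoff) come from 1-D quadrature via :meth:`density`.
    """

    system: MolecularSystem
    ff: ToyForceField
    restraints: RestraintSet
    groups: SurfaceGroups
    frozen_dof: np.ndarray
    k_base: float
    x0: float
    temperature: float
    cutoff: float = 10.0
    guard_k: float = 2.5

    def potential(self, r, window: BiasWindow | None = None):
        r = np.asarray(r, dtype=float)
        u = 0.5 * self.k_base * (r - self.x0) ** 2
        if window is not None:
            b = np.where(
                r < self.cutoff,
                np.array([bias_energy(v, window) for v in np.atleast_1d(r)]),
                self.guard_k * (r - self.cutoff) ** 2)
            u = u + b
        return u

    def density(self, window: BiasWindow | None = None, r_max: float = 16.0,
                n_grid: int = 8001):
        """Normalized stationary density p(r) on a grid; returns (r, p, cdf).

        ``cdf`` is a callable (vectorized linear interpolation) suitable
        for Kolmogorov–Smirnov comparison against sampled separations.
        """
        from scipy.integrate import cumulative_trapezoid
        from scipy.interpolate import interp1d

        r = np.linspace(1e-3, r_max, n_grid)
        beta = 1.0 / (KB * self.temperature)
        u = self.potential(r, window)
        w = np.exp(-beta * (u - u.min()))
        cum = cumulative_trapezoid(w, r, initial=0.0)
        z = cum[-1]
        p = w / z
        cdf = interp1d(r, cum / z, bounds_error=False, fill_value=(0.0, 1.0))
        return r, p, cdf

    def separations(self, frames) -> np.ndarray:
        return np.array([np.linalg.norm(f[1] - f[0]) for f in frames])


def make_harmonic_pair_system(k_base: float = 1.0, x0: float = 6.0,
                              temperature: float = 300.0,
                              cutoff: float = 10.0,
                              guard_k: float = 2.5) -> HarmonicPairSystem:
    """Analytic detailed-balance fixture for the replica-exchange module.

    Bead 0 (receptor) is fully frozen at the origin; bead 1 (ligand)
    moves along +x only, so the separation coordinate is literally the
    bead's x position and all stationary densities are exact 1-D
    Boltzmann factors.
    """
    if k_base <= 0:
        raise ValueError("k_base must be positive")
    atoms = [
        AtomRecord(1, "C", "REC", "A", 1, "C", np.zeros(3), 1.5, 12.011),
        AtomRecord(2, "C", "LIG", "B", 1, "C", np.array([x0, 0.0, 0.0]),
                   1.5, 12.011),
    ]
    system = MolecularSystem(atoms, np.array([0]), np.array([1]))
    ff = ToyForceField(sigma=1.0, eps_cross=np.zeros(1))
    restraints = RestraintSet(pair_distance=[(0, 1, x0, k_base / 2.0)])
    groups = SurfaceGroups(np.array([0]), np.array([1]),
                           {0: 4 * np.pi * 3.0 ** 2, 1: 4 * np.pi * 3.0 ** 2})
    frozen = np.array([[True, True, True], [False, True, True]])
    return HarmonicPairSystem(system, ff, restraints, groups, frozen,
                              k_base, x0, temperature, cutoff, guard_k)


def make_mini_pdb_fixture(n_atoms_per_chain: int = 3, seed: int = 0) -> str:
    """Two-chain PDB text with known coordinates, for I/O round-trip tests."""
    if n_atoms_per_chain < 3:
        raise ValueError("need at least 3 atoms per chain")
    rng = np.random.default_rng(seed)
    elements = ["C", "N", "O"]
    atoms = []
    n = n_atoms_per_chain
    coords = np.round(rng.uniform(-20.0, 20.0, (2 * n, 3)), 3)
    for i in range(2 * n):
        chain = "A" if i < n else "B"
        el = elements[i % 3]
        atoms.append(AtomRecord(i + 1, el, "TOY", chain, (i % n) + 1, el,
                                coords[i], 1.7, 12.0))
    system = MolecularSystem(atoms, np.arange(n), np.arange(n, 2 * n))
    with tempfile.NamedTemporaryFile("r", suffix=".pdb", delete=False) as fh:
        path = fh.name
    write_pdb(system, coords, path)
    text = Path(path).read_text()
    Path(path).unlink()
    return text
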