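"""Result metrics: ligand RMSD, near-native fractions, clustering, energies.

The central quantity is RMSD_lig: the receptor of each frame is first
superposed onto the reference receptor (Kabsch), and the ligand RMSD is
then measured against the reference ligand *without* re-fitting the
ligand — so it reports the displacement of the ligand relative to the
binding site, not internal ligand deformation alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .toy_engine import cross_interaction_energy

__all__ = [
    "RmsdSeries",
    "kabsch_superpose",
    "ligand_rmsd",
    "near_native_fraction",
    "leader_cluster",
    "interaction_energy_series",
    "first_passage",
]


@dataclass
class RmsdSeries:
    """Per-frame ligand RMSD values (Å) with their frame steps."""

    values: np.ndarray
    steps: np.ndarray = None
    replica: int | None = None
    selection: str = "all"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("RMSD values must be non-negative")
        if self.steps is None:
            self.steps = np.arange(len(self.values))
        else:
            self.steps = np.asarray(self.steps)

    def __len__(self):
        return len(self.values)


def kabsch_superpose(mobile, reference, selection=None):
    """Optimal rigid superposition of ``mobile[selection]`` onto reference.

    Returns (rotation (3,3), translation (3,), rmsd) such that
    ``mobile @ R.T + t`` minimizes the RMSD of the selected atoms.  The
    rotation is proper (det +1); degenerate (collinear) selections are
    rejected.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if selection is None:
        sel_m, sel_r = mobile, reference
    else:
        selection = np.asarray(selection)
        sel_m, sel_r = mobile[selection], reference[selection]
    if len(sel_m) < 3:
        raise ValueError("need at least 3 atoms for superposition")

    cm, cr = sel_m.mean(axis=0), sel_r.mean(axis=0)
    pm, pr = sel_m - cm, sel_r - cr
    # collinearity check: rank of the centered selection
    if np.linalg.matrix_rank(pm, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) selection")

    h = pm.T @ pr
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = cr - rot @ cm
    moved = sel_m @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - sel_r) ** 2, axis=1))))
    return rot, trans, rmsd


def ligand_rmsd(frame, reference, receptor_sel, ligand_sel,
                return_aligned: bool = False):
    """RMSD_lig (Å): receptor-superposed ligand RMSD, no ligand re-fit."""
    frame = np.asarray(frame, dtype=float)
    reference = np.asarray(reference, dtype=float)
    rot, trans, _ = kabsch_superpose(frame, reference, receptor_sel)
    lig = frame[ligand_sel] @ rot.T + trans
    diff = lig - reference[ligand_sel]
    rmsd = float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))
    if return_aligned:
        return rmsd, lig
    return rmsd


def near_native_fraction(series: RmsdSeries, threshold: float,
                         frame_window=None) -> float:
    """Fraction of frames with RMSD_lig strictly below ``threshold``.

    ``frame_window`` is a (start, stop) index pair restricting the series
    (half-open, as in array slicing); the full series by default.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    values = series.values
    if frame_window is not None:
        start, stop = frame_window
        values = values[start:stop]
    if len(values) == 0:
        raise ValueError("empty frame window")
    return float(np.mean(values < threshold))


def leader_cluster(frames, reference, receptor_sel, ligand_sel,
                   radius: float = 4.0):
    """Leader clustering of frames by pairwise ligand RMSD.

    Frames are receptor-superposed onto the reference once; the metric
    between two frames is then the plain RMSD between their aligned
    ligand coordinates.  In frame order, each frame joins the first
    cluster whose *leader* (founding frame) is within ``radius``, else
    founds a new cluster.  Returns (assignments, sizes) with cluster
    labels relabelled so that sizes are descending.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    aligned = []
    for f in frames:
        _, lig = ligand_rmsd(f, reference, receptor_sel, ligand_sel,
                             return_aligned=True)
        aligned.append(lig)

    leaders, raw = [], []
    for lig in aligned:
        for ci, leader in enumerate(leaders):
            d = float(np.sqrt(np.mean(np.sum((lig - leader) ** 2, axis=1))))
            if d < radius:
                raw.append(ci)
                break
        else:
            leaders.append(lig)
            raw.append(len(leaders) - 1)

    raw = np.asarray(raw)
    counts = np.bincount(raw)
    order = np.argsort(-counts, kind="stable")
    relabel = np.empty_like(order)
    relabel[order] = np.arange(len(order))
    return relabel[raw], np.sort(counts)[::-1]


def interaction_energy_series(frames, system, ff) -> np.ndarray:
    """Receptor–ligand non-bonded energy (kcal/mol) per frame, no cutoff.

    Cross terms only: intra-partner energies, restraints and bias are all
    excluded, so the series is comparable across replicas.
    """
    return np.array([cross_interaction_energy(system, ff, f) for f in frames])


def first_passage(series: RmsdSeries, threshold: float):
    """Index of the first frame with RMSD_lig < threshold, or None."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    below = np.nonzero(series.values < threshold)[0]
    return int(below[0]) if below.size else None
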