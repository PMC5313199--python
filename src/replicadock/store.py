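"""Per-replica trajectory, diagnostics and exchange bookkeeping."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExchangeRecord", "TrajectoryStore"]


@dataclass(frozen=True)
class ExchangeRecord:
    """One neighbour-swap attempt: Δ is the dimensionless Metropolis exponent."""

    step: int
    pair: tuple
    delta: float
    accepted: bool

    def __post_init__(self):
        if not np.isfinite(self.delta):
            raise ValueError("exchange delta must be finite")


@dataclass
class TrajectoryStore:
    """Frames + per-frame energy records per replica slot, plus exchange log.

    ``frames[r]`` is a list of (n_atoms, 3) arrays for replica slot r;
    ``records[r]`` the matching per-frame dicts (step, total, pair, bond,
    positional, pair_distance, bias, guard, interaction, d_ave12,
    n_pairs, guard_active).  ``exchanges`` is the flat list of
    :class:`ExchangeRecord`; ``elements`` the per-atom element symbols
    for trajectory output.
    """

    n_replicas: int
    elements: list
    exchange_interval: int
    record_every: int
    frames: list = field(default_factory=list)
    records: list = field(default_factory=list)
    exchanges: list = field(default_factory=list)

    def __post_init__(self):
        if not self.frames:
            self.frames = [[] for _ in range(self.n_replicas)]
        if not self.records:
            self.records = [[] for _ in range(self.n_replicas)]

    def n_frames(self, replica: int) -> int:
        return len(self.frames[replica])

    def diagnostics_frame(self) -> pd.DataFrame:
        """All per-frame records as one tidy DataFrame."""
        rows = []
        for r in range(self.n_replicas):
            for rec in self.records[r]:
                rows.append({"replica": r, **rec})
        return pd.DataFrame(rows)

    def exchange_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"step": e.step, "replica_i": e.pair[0], "replica_j": e.pair[1],
             "delta": e.delta, "accepted": e.accepted}
            for e in self.exchanges
        ])
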