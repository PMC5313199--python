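"""Run configuration: TOML loading, defaults, validation.

A run is described by flat key groups mirroring the module surfaces:

    [system]    pdb = "complex.pdb" | toy = "sticky"  (+ generator params)
    [surface]   min_area, probe, cutoff, n_sphere_points
    [bias]      exponent, k_f, ladder, normalization, guard_trigger
    [engine]    dt, gamma, temperature
    [remd]      n_steps, exchange_interval, record_every, seed
    [analysis]  thresholds, cluster_radius, success_threshold
    [benchmark] seeds, n_replicas

Defaults follow the published protocol where one exists (k_f 2.5,
cutoff 10 Å, probe 1.5 Å, min area 10 Å², T 300 K, γ 0.1 ps⁻¹); the
rest are the package's own desk-scale choices.
"""

from __future__ import annotations

import copy
import tomllib
from dataclasses import dataclass, field

from .ambiguity_bias import LADDER_PRESETS, BiasWindow, ReplicaLadder

__all__ = ["RunConfig", "DEFAULTS", "load_config"]

DEFAULTS = {
    "system": {"toy": "sticky", "n_receptor_beads": 64, "n_ligand_beads": 1,
               "n_decoys": 4, "native_depth": 15.0, "decoy_depth": 6.0,
               "base_depth": 0.5, "sigma": 3.0, "shell_radius": 5.0,
               "seed": 0, "pdb": None},
    "surface": {"min_area": 10.0, "probe": 1.5, "cutoff": 10.0,
                "n_sphere_points": 960},
    "bias": {"exponent": 12, "k_f": 2.5, "ladder": "toy4",
             "normalization": "restricted", "guard_trigger": "empty_pairs"},
    "engine": {"dt": 0.01, "gamma": 0.1, "temperature": 300.0},
    "remd": {"n_steps": 5000, "exchange_interval": 250, "record_every": 10,
             "seed": 1},
    "analysis": {"thresholds": [2.0, 4.0], "cluster_radius": 4.0,
                 "success_threshold": None},
    "benchmark": {"seeds": [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]},
}

_RANGES = {
    ("surface", "min_area"): (0.0, None),
    ("surface", "probe"): (1e-9, None),
    ("surface", "cutoff"): (1e-9, None),
    ("surface", "n_sphere_points"): (92, None),
    ("bias", "k_f"): (0.0, None),
    ("engine", "dt"): (1e-12, None),
    ("engine", "gamma"): (0.0, None),
    ("engine", "temperature"): (1e-9, None),
    ("remd", "n_steps"): (1, None),
    ("remd", "exchange_interval"): (1, None),
    ("remd", "record_every"): (1, None),
}


@dataclass
class RunConfig:
    """Validated run configuration; ``groups`` holds the merged key groups."""

    groups: dict = field(default_factory=dict)

    def __post_init__(self):
        merged = copy.deepcopy(DEFAULTS)
        for g, kv in self.groups.items():
            if g not in merged:
                raise ValueError(f"unknown config group [{g}]")
            for k, v in kv.items():
                if k not in merged[g]:
                    raise ValueError(f"unknown config key {g}.{k}")
                merged[g][k] = v
        for (g, k), (lo, hi) in _RANGES.items():
            v = merged[g][k]
            if lo is not None and v < lo:
                raise ValueError(f"{g}.{k} = {v} below minimum {lo}")
            if hi is not None and v > hi:
                raise ValueError(f"{g}.{k} = {v} above maximum {hi}")
        if merged["bias"]["exponent"] not in (6, 12):
            raise ValueError("bias.exponent must be 6 or 12")
        self.groups = merged
        self.ladder()  # validate early

    def __getitem__(self, group):
        return self.groups[group]

    def ladder(self) -> ReplicaLadder:
        """Resolve bias.ladder: preset name or inline [[d_low, d_up], ...]."""
        choice = self.groups["bias"]["ladder"]
        if choice is None:
            raise ValueError("missing config key bias.ladder")
        if isinstance(choice, str):
            if choice not in LADDER_PRESETS:
                raise ValueError(
                    f"unknown ladder preset {choice!r}; "
                    f"choose from {sorted(LADDER_PRESETS)}")
            return LADDER_PRESETS[choice]
        k_f = self.groups["bias"]["k_f"]
        return ReplicaLadder(tuple(BiasWindow(lo, up, k_f)
                                   for lo, up in choice))

    def to_dict(self) -> dict:
        return copy.deepcopy(self.groups)


def load_config(path) -> RunConfig:
    """Load a TOML run configuration file."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return RunConfig(data)
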