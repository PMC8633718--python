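"""Binding-pocket solvation: per-frame water counts N_W.

The pocket is the set of heavy atoms of user-listed residues; a water
molecule (resname HOH/WAT/TIP3, counted once through its designated atom,
by default the oxygen) occupies the pocket in a frame when that atom lies
within ``inclusion_cutoff`` of *any* pocket heavy atom (≤ convention, so a
water exactly at the cutoff counts).  This distance-based operationalisation
of "inside the pocket" is recorded in the series metadata; counts are
monotone non-decreasing in the cutoff by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ParameterError, SelectionError
from .interactions import ResidueSelector, resolve_residue
from .smd_io import FrameSet


@dataclass(frozen=True)
class PocketSpec:
    """The pocket-forming residues and the water-inclusion criterion."""

    residues: tuple  # of ResidueSelector
    inclusion_cutoff: float = 5.0  # Å
    water_atom_name: str = "O"

    def __post_init__(self):
        if len(self.residues) < 1:
            raise ParameterError("pocket needs at least one residue")
        if self.inclusion_cutoff <= 0:
            raise ParameterError("inclusion_cutoff must be > 0")
        object.__setattr__(self, "residues", tuple(self.residues))


@dataclass
class SolvationSeries:
    """Per-frame pocket water counts."""

    times: np.ndarray  # ps
    counts: np.ndarray  # integer N_W
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != self.times.shape:
            raise ParameterError("counts length must match times")
        if np.any(self.counts < 0):
            raise ParameterError("counts must be non-negative")


def count_pocket_waters(frames: FrameSet, pocket: PocketSpec) -> SolvationSeries:
    """N_W per frame: waters within the cutoff of any pocket heavy atom.

    Each water is counted at most once per frame (one designated atom per
    molecule).  A topology without waters yields an all-zero series with a
    warning rather than an error.
    """
    pocket_idx = []
    for sel in pocket.residues:
        hits = resolve_residue(frames, sel)
        heavy = [i for i in hits if not frames.atoms[i].is_hydrogen]
        if not heavy:
            raise SelectionError(f"pocket residue {sel} has no heavy atoms")
        pocket_idx.extend(heavy)
    pocket_idx = sorted(set(pocket_idx))

    water_idx = [
        i
        for i, a in enumerate(frames.atoms)
        if a.is_water and a.name == pocket.water_atom_name
    ]
    meta = {
        "definition": (
            f"water {pocket.water_atom_name} within {pocket.inclusion_cutoff} Å "
            f"of any pocket heavy atom (<= convention)"
        ),
        "n_pocket_atoms": len(pocket_idx),
        "n_waters": len(water_idx),
    }
    if not water_idx:
        warnings.warn("no water molecules in topology; N_W is zero everywhere")
        return SolvationSeries(
            times=frames.times.copy(),
            counts=np.zeros(frames.n_frames, dtype=int),
            metadata=meta,
        )

    pk = frames.coords[:, pocket_idx, :]  # (F, P, 3)
    wa = frames.coords[:, water_idx, :]  # (F, W, 3)
    d = np.linalg.norm(wa[:, :, None, :] - pk[:, None, :, :], axis=-1)  # (F, W, P)
    counts = (d.min(axis=2) <= pocket.inclusion_cutoff).sum(axis=1)
    return SolvationSeries(times=frames.times.copy(), counts=counts, metadata=meta)
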