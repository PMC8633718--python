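"""Nonequilibrium work from pulling traces.

The external work done by the moving spring on the system up to time t is

    W(0→t) = −k·v ∫₀ᵗ (r(t') − λ(t')) dt',      λ(t') = λ0 + v·t',

i.e. the spring constant times the pulling speed times the time integral of
the lag between the scheduled position and the actual reaction coordinate.
The integral is evaluated by trapezoidal quadrature on the native (possibly
non-uniform) time grid, which is second-order accurate and matches typical
SMD output periods.

Replicate work curves are combined on a common reaction-coordinate axis by
re-indexing from time to the *scheduled* position λ(t) — the stiff-spring
convention — and linear interpolation onto a uniform grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import InsufficientDataError, ParameterError
from .smd_io import PullingProtocol, SMDTrace

#: Default grid spacing: pulling velocity 0.00625 Å/ps × 20 ps output period.
DEFAULT_GRID_SPACING = 0.125


@dataclass
class WorkSet:
    """Per-replicate cumulative work aligned on a uniform λ grid."""

    grid: np.ndarray  # Å, uniform, strictly increasing
    works: np.ndarray  # (n_replicas, n_grid), kcal/mol
    protocol: PullingProtocol
    replica_ids: list

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.works = np.atleast_2d(np.asarray(self.works, dtype=float))
        d = np.diff(self.grid)
        if len(self.grid) >= 2 and (
            np.any(d <= 0) or np.ptp(d) > 1e-9 * max(1.0, abs(d[0]))
        ):
            raise ParameterError("grid must be uniform and strictly increasing")
        if self.works.shape != (len(self.replica_ids), len(self.grid)):
            raise ParameterError("works shape must be (n_replicas, n_grid)")

    @property
    def n_replicas(self) -> int:
        return self.works.shape[0]

    @property
    def spacing(self) -> float:
        return float(self.grid[1] - self.grid[0]) if len(self.grid) > 1 else 0.0


def compute_work(trace: SMDTrace, protocol: PullingProtocol) -> np.ndarray:
    """Cumulative external work W(t) at every trace time, kcal/mol.

    Times are shifted so the trace starts at t = 0; W(0) = 0.
    """
    if len(trace) < 2:
        raise InsufficientDataError("work integral needs at least 2 trace points")
    if protocol.velocity < 0:
        raise ParameterError("work integral requires pulling velocity >= 0")
    # v = 0: the schedule never moves and the spring does no net scheduled
    # work; the k·v prefactor makes W identically zero.
    t = trace.times - trace.times[0]
    lag = protocol.schedule(t) - trace.positions  # λ(t) − r(t)
    integral = cumulative_trapezoid(lag, t, initial=0.0)
    return protocol.spring_constant * protocol.velocity * integral


def align_works(
    traces: Sequence[SMDTrace],
    protocol: PullingProtocol,
    grid_spacing: float = DEFAULT_GRID_SPACING,
) -> WorkSet:
    """Re-index replicate work curves from time to λ(t) on a uniform grid.

    The grid spans [λ0, min over replicates of the final λ], so every
    replicate covers every grid point and interpolation never extrapolates.
    """
    if not traces:
        raise InsufficientDataError("need at least one trace")
    if grid_spacing <= 0:
        raise ParameterError("grid_spacing must be > 0")
    lam_end = min(
        protocol.lambda0 + protocol.velocity * (tr.times[-1] - tr.times[0])
        for tr in traces
    )
    n = int(np.floor((lam_end - protocol.lambda0) / grid_spacing + 1e-9))
    if n < 1:
        raise InsufficientDataError(
            "a replicate ends before λ0 + grid_spacing; trace too short"
        )
    grid = protocol.lambda0 + grid_spacing * np.arange(n + 1)
    rows = []
    for tr in traces:
        w = compute_work(tr, protocol)
        lam = protocol.schedule(tr.times - tr.times[0])
        rows.append(np.interp(grid, lam, w))
    works = np.vstack(rows)
    works[:, 0] = 0.0  # W(λ0) = 0 by definition
    return WorkSet(
        grid=grid,
        works=works,
        protocol=protocol,
        replica_ids=[tr.replica_id for tr in traces],
    )
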