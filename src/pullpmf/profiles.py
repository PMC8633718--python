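"""Force-profile averaging and PMF feature analysis.

Averaged unbinding-force profiles are built the same way work curves are:
per-replicate forces are re-indexed from time to the scheduled position
λ(t) and linearly interpolated onto a uniform grid, then averaged
pointwise.  The dissociated state shows up as the force tail converging to
zero, which :func:`tail_zero_test` checks with a 2-standard-error rule.

PMF features — free-energy barriers and metastable intermediates — are read
off the smoothed profile and its first derivative m(λ): a barrier is a
prominent local maximum of ΔG (height reported relative to the initial
state), and a metastable state is a maximal interior interval where
|m| stays below a flatness tolerance for at least a minimum width.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .constants import force_to_pN
from .errors import InsufficientDataError, ParameterError
from .pmf import PMFProfile
from .smd_io import PullingProtocol, SMDTrace
from .work import DEFAULT_GRID_SPACING

#: Default smoothing window, points (≈1.4 Å at the 0.125 Å default spacing).
DEFAULT_WINDOW = 11
#: Default |dG/dλ| tolerance for calling a region flat, kcal/mol/Å.
DEFAULT_FLAT_TOL = 0.5
#: Default minimum width of a metastable interval, Å.
DEFAULT_MIN_FLAT_WIDTH = 0.5
#: Default barrier prominence, kcal/mol.
DEFAULT_PMF_PROMINENCE = 0.5
#: Default force-peak prominence, kcal/mol/Å (≈50 pN).
DEFAULT_FORCE_PROMINENCE = 50.0 / 69.4786


@dataclass
class ForceProfile:
    """Replicate-averaged spring force along the reaction coordinate."""

    grid: np.ndarray  # Å
    mean_force: np.ndarray  # kcal/mol/Å
    sd: np.ndarray  # pointwise population SD (ddof=0)
    n_replicas: int

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.mean_force = np.asarray(self.mean_force, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if not (self.grid.shape == self.mean_force.shape == self.sd.shape):
            raise ParameterError("grid, mean_force and sd must share a shape")
        if np.any(self.sd < 0):
            raise ParameterError("sd must be non-negative")

    @property
    def mean_force_pN(self) -> np.ndarray:
        return force_to_pN(self.mean_force)


@dataclass
class FeatureAnnotation:
    """Barriers, metastable states and force peaks of a dissociation profile."""

    barriers: list = field(default_factory=list)  # (position Å, height kcal/mol)
    metastable_states: list = field(default_factory=list)  # ((a, b) Å, mean ΔG)
    peak_forces: list = field(default_factory=list)  # (position Å, force)


def average_force_profile(
    traces: Sequence[SMDTrace],
    protocol: PullingProtocol,
    grid_spacing: float = DEFAULT_GRID_SPACING,
) -> ForceProfile:
    """Average per-replicate forces on a uniform λ grid.

    Traces without a force column get the reconstructed spring force
    ``k·(λ(t) − r)``.  The pointwise spread is the population standard
    deviation (ddof=0), so two replicates at ±f give sd exactly f.
    """
    if not traces:
        raise InsufficientDataError("need at least one trace")
    if grid_spacing <= 0:
        raise ParameterError("grid_spacing must be > 0")
    traces = [tr.with_forces(protocol) for tr in traces]
    lam_end = min(
        protocol.lambda0 + protocol.velocity * (tr.times[-1] - tr.times[0])
        for tr in traces
    )
    n = int(np.floor((lam_end - protocol.lambda0) / grid_spacing + 1e-9))
    if n < 1:
        raise InsufficientDataError("traces too short for one grid interval")
    grid = protocol.lambda0 + grid_spacing * np.arange(n + 1)
    rows = np.vstack(
        [
            np.interp(grid, protocol.schedule(tr.times - tr.times[0]), tr.forces)
            for tr in traces
        ]
    )
    return ForceProfile(
        grid=grid,
        mean_force=rows.mean(axis=0),
        sd=rows.std(axis=0, ddof=0),
        n_replicas=len(traces),
    )


def tail_zero_test(
    profile: ForceProfile, threshold: float
) -> tuple[float, float, bool]:
    """Has the mean force converged to zero past ``threshold``?

    Returns (tail mean, standard error of the tail mean, verdict).  The
    verdict is true when |mean| ≤ 2·SE, the usual two-standard-error rule
    (~95% nominal coverage for an actually-zero tail).
    """
    mask = profile.grid > threshold
    tail = profile.mean_force[mask]
    if tail.size < 5:
        raise InsufficientDataError(
            f"only {tail.size} grid points beyond {threshold} Å (need >= 5)"
        )
    mean = float(tail.mean())
    se = float(tail.std(ddof=1) / np.sqrt(tail.size))
    return mean, se, bool(abs(mean) <= 2.0 * se)


def smooth_profile(values, window: int) -> np.ndarray:
    """Centered moving average with window truncation at the ends.

    ``window`` must be odd, >= 3 and no longer than the series; output
    length equals input length, and linear series are preserved in the
    interior.
    """
    values = np.asarray(values, dtype=float)
    if window < 3 or window % 2 == 0:
        raise ParameterError("window must be an odd integer >= 3")
    if window > values.size:
        raise ParameterError("window longer than the series")
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(values)))
    n = values.size
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def derivative_profile(pmf: PMFProfile, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """First derivative m(λ) of the smoothed PMF, kcal/mol/Å.

    Central differences in the interior, one-sided at the ends; requires a
    uniform grid with at least 3 points.
    """
    if len(pmf.grid) < 3:
        raise InsufficientDataError("derivative needs at least 3 grid points")
    d = np.diff(pmf.grid)
    if np.ptp(d) > 1e-9 * max(1.0, abs(d[0])):
        raise ParameterError("derivative requires a uniform grid")
    smoothed = smooth_profile(pmf.delta_g, window)
    return np.gradient(smoothed, pmf.grid)


def annotate_features(
    pmf: PMFProfile,
    m: np.ndarray,
    flat_tol: float = DEFAULT_FLAT_TOL,
    min_flat_width: float = DEFAULT_MIN_FLAT_WIDTH,
    prominence: float = DEFAULT_PMF_PROMINENCE,
    window: int = DEFAULT_WINDOW,
) -> FeatureAnnotation:
    """Annotate barriers and metastable states on a PMF.

    Barriers: local maxima of the smoothed ΔG with the given prominence,
    heights relative to the profile's initial state (first grid point).
    Metastable states: maximal runs where |m| ≤ ``flat_tol`` spanning at
    least ``min_flat_width`` Å, excluding runs touching the first or last
    grid point (those are the global bound/dissociated plateaus, not
    intermediates).  Annotations are invariant to adding a constant to ΔG.
    """
    m = np.asarray(m, dtype=float)
    if m.shape != pmf.grid.shape:
        raise ParameterError("derivative m must live on the PMF grid")
    smoothed = smooth_profile(pmf.delta_g, min(window, _largest_odd(len(pmf.delta_g))))
    ref = smoothed[0]

    peak_idx, _ = find_peaks(smoothed, prominence=prominence)
    barriers = [(float(pmf.grid[i]), float(smoothed[i] - ref)) for i in peak_idx]

    flat = np.abs(m) <= flat_tol
    states = []
    for a, b in _runs(flat):  # half-open [a, b)
        if a == 0 or b == len(flat):
            continue  # global initial/final plateau
        width = pmf.grid[b - 1] - pmf.grid[a]
        if width >= min_flat_width:
            states.append(
                (
                    (float(pmf.grid[a]), float(pmf.grid[b - 1])),
                    float(pmf.delta_g[a:b].mean()),
                )
            )
    return FeatureAnnotation(barriers=barriers, metastable_states=states, peak_forces=[])


def detect_force_peaks(
    profile: ForceProfile,
    prominence: float = DEFAULT_FORCE_PROMINENCE,
    window: int = DEFAULT_WINDOW,
) -> list:
    """Prominent local maxima of the smoothed mean force, sorted by position.

    Endpoints are never peaks (interior-only convention): a monotonically
    decreasing profile yields an empty list.  Peak positions are invariant
    to a uniform rescaling of force units provided the prominence threshold
    is rescaled with them.
    """
    if profile.grid.size == 0:
        raise InsufficientDataError("empty force profile")
    w = min(window, _largest_odd(profile.mean_force.size))
    if w < 3:
        return []
    smoothed = smooth_profile(profile.mean_force, w)
    idx, _ = find_peaks(smoothed, prominence=prominence)
    return sorted(
        (float(profile.grid[i]), float(smoothed[i])) for i in idx
    )


def _largest_odd(n: int) -> int:
    return n if n % 2 == 1 else n - 1


def _runs(mask: np.ndarray):
    """Maximal runs of True as half-open index intervals."""
    out = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(mask)))
    return out
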