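"""Synthetic inputs with known ground truth.

This module generates, at desk scale, everything the analysis pipeline
consumes:

* overdamped Langevin constant-velocity pulling on parametric 1-D free-energy
  landscapes whose ΔG between any two points is known in closed form —
  the stand-in for atomistic cv-SMD replicates;
* analytic traces with a prescribed lag (constant or sinusoidal), for which
  the work integral has a closed form;
* toy molecular frame sets with scripted contact distances, and toy water
  boxes with a known number of pocket waters.

The pulling dynamics are the overdamped Langevin equation

    γ dr = [ −U'(r) − k (r − λ0 − v t) ] dt + sqrt(2 γ kT) dW,

integrated by Euler–Maruyama.  The stability condition
``dt · (k + max |U''|) / γ < 0.1`` is enforced before any integration.
Replicas are seeded by spawning ``numpy.random.SeedSequence([master_seed,
replica_index])``, so any single replica is reproducible in isolation.

The default scenario mirrors the pulling protocol of a peptide–RNA
dissociation experiment (75 replicates, k = 12 kcal/mol/Å², T = 310 K) on a
double-Gaussian-bump landscape, with the velocity scaled up so the full
replicate set integrates in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import quad

from .constants import KB_KCAL_MOL_K, kT as thermal_energy
from .errors import ConfigurationError, ConstructionError, NumericalError, ParameterError
from .smd_io import Atom, FrameSet, PullingProtocol, SMDTrace
from .interactions import AtomSelector, ContactSpec

# ---------------------------------------------------------------------------
# Landscapes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Landscape:
    """A 1-D free-energy landscape U(λ) with closed-form ΔG."""

    domain: tuple = (0.0, 10.0)

    def __post_init__(self):
        if not self.domain[1] > self.domain[0]:
            raise ParameterError("domain must be ordered (min, max)")

    def potential(self, x):
        raise NotImplementedError

    def gradient(self, x):
        raise NotImplementedError

    def max_curvature(self) -> float:
        raise NotImplementedError


@dataclass(frozen=True)
class FlatLandscape(Landscape):
    def potential(self, x):
        return np.zeros_like(np.asarray(x, dtype=float))

    def gradient(self, x):
        return np.zeros_like(np.asarray(x, dtype=float))

    def max_curvature(self) -> float:
        return 0.0


@dataclass(frozen=True)
class HarmonicLandscape(Landscape):
    """U(λ) = stiffness · (λ − center)² / 2."""

    stiffness: float = 1.0  # kcal/mol/Å²
    center: float = 0.0

    def __post_init__(self):
        super().__post_init__()
        if self.stiffness <= 0:
            raise ParameterError("stiffness must be > 0")

    def potential(self, x):
        return 0.5 * self.stiffness * (np.asarray(x, dtype=float) - self.center) ** 2

    def gradient(self, x):
        return self.stiffness * (np.asarray(x, dtype=float) - self.center)

    def max_curvature(self) -> float:
        return self.stiffness


@dataclass(frozen=True)
class DoubleGaussianLandscape(Landscape):
    """Two Gaussian bumps: U(λ) = Σ_i h_i exp(−(λ − c_i)²/(2 w_i²))."""

    heights: tuple = (4.0, 2.5)  # kcal/mol
    centers: tuple = (3.0, 7.0)  # Å
    widths: tuple = (0.5, 0.5)  # Å

    def __post_init__(self):
        super().__post_init__()
        if not (len(self.heights) == len(self.centers) == len(self.widths)):
            raise ParameterError("heights/centers/widths must have equal length")
        if any(w <= 0 for w in self.widths):
            raise ParameterError("widths must be > 0")

    def potential(self, x):
        x = np.asarray(x, dtype=float)
        u = np.zeros_like(x)
        for h, c, w in zip(self.heights, self.centers, self.widths):
            u = u + h * np.exp(-((x - c) ** 2) / (2.0 * w * w))
        return u

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        g = np.zeros_like(x)
        for h, c, w in zip(self.heights, self.centers, self.widths):
            g = g - h * (x - c) / (w * w) * np.exp(-((x - c) ** 2) / (2.0 * w * w))
        return g

    def max_curvature(self) -> float:
        # |U''| of a Gaussian bump is maximal at its center: h / w².
        return max(h / (w * w) for h, w in zip(self.heights, self.widths))


def make_landscape(kind: str, domain=(0.0, 10.0), **params) -> Landscape:
    """Factory over the three supported landscape kinds."""
    kinds = {
        "flat": FlatLandscape,
        "harmonic": HarmonicLandscape,
        "double_gaussian_bump": DoubleGaussianLandscape,
    }
    if kind not in kinds:
        raise ParameterError(f"unknown landscape kind {kind!r}")
    if kind == "double_gaussian_bump":
        for k_src, k_dst in (("bump_heights", "heights"), ("bump_centers", "centers"), ("bump_widths", "widths")):
            if k_src in params:
                params[k_dst] = tuple(params.pop(k_src))
        for key in ("heights", "centers", "widths"):
            if key in params:
                params[key] = tuple(params[key])
    return kinds[kind](domain=tuple(domain), **params)


#: The default ground-truth landscape: a high early barrier, a flat valley
#: wide enough to act as a metastable intermediate, and a lower late barrier.
DEFAULT_LANDSCAPE = DoubleGaussianLandscape(
    domain=(0.0, 10.0), heights=(4.0, 2.5), centers=(3.0, 7.0), widths=(0.5, 0.5)
)


# ---------------------------------------------------------------------------
# Langevin pulling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LangevinConfig:
    """Configuration of one batch of overdamped pulling replicas.

    ``kT=None`` derives the thermal energy from the protocol temperature.
    ``output_period`` (ps) sets the trace subsampling; ``n_equil_steps=None``
    equilibrates for 50 spring relaxation times (50·γ/k) before pulling.
    """

    landscape: Landscape
    protocol: PullingProtocol
    friction: float  # γ, kcal·ps/mol/Å²
    dt: float  # ps
    n_steps: int
    n_replicas: int = 75
    seed: int = 0
    kT: Optional[float] = None
    output_period: float = 1.0  # ps
    n_equil_steps: Optional[int] = None

    def __post_init__(self):
        if self.dt <= 0:
            raise ConfigurationError("dt must be > 0")
        if self.friction <= 0:
            raise ConfigurationError("friction must be > 0")
        if self.n_replicas < 1:
            raise ConfigurationError("n_replicas must be >= 1")
        if self.n_steps < 1:
            raise ConfigurationError("n_steps must be >= 1")
        if self.thermal_energy < 0:
            raise ConfigurationError("kT must be >= 0")
        stiff = self.protocol.spring_constant + self.landscape.max_curvature()
        if self.dt * stiff / self.friction >= 0.1:
            raise ConfigurationError(
                f"stability condition violated: dt·(k + max U'')/γ = "
                f"{self.dt * stiff / self.friction:.3g} >= 0.1"
            )

    @property
    def thermal_energy(self) -> float:
        if self.kT is not None:
            return self.kT
        return thermal_energy(self.protocol.temperature)

    @property
    def output_stride(self) -> int:
        return max(1, int(round(self.output_period / self.dt)))


def replica_seed_sequence(master_seed: int, replica: int) -> np.random.SeedSequence:
    """The documented per-replica seed-splitting rule."""
    return np.random.SeedSequence([int(master_seed), int(replica)])


def simulate_pulling(config: LangevinConfig) -> list:
    """Integrate all replicas; returns one SMDTrace per replica.

    All replicas step in lockstep (vectorized over the replica axis) but
    consume independent, deterministically seeded noise streams.  Each trace
    starts at t = 0 with λ = λ0 after an unrecorded equilibration phase with
    the spring held at λ0.
    """
    p = config.protocol
    gamma, dt, kT_val = config.friction, config.dt, config.thermal_energy
    n_rep, n_steps = config.n_replicas, config.n_steps
    n_equil = (
        config.n_equil_steps
        if config.n_equil_steps is not None
        else int(math.ceil(50.0 * gamma / p.spring_constant / dt))
    )
    rngs = [
        np.random.default_rng(replica_seed_sequence(config.seed, i))
        for i in range(n_rep)
    ]
    sigma = math.sqrt(2.0 * gamma * kT_val * dt) / gamma  # noise prefactor on r
    k = p.spring_constant

    r = np.full(n_rep, p.lambda0, dtype=float)

    def advance(r, lam, noise_block):
        # noise_block: (n_rep, n_block) standard normals
        for j in range(noise_block.shape[1]):
            drift = -(config.landscape.gradient(r)) - k * (r - lam[j])
            r = r + dt * drift / gamma + sigma * noise_block[:, j]
        return r

    chunk = 20000
    # --- equilibration at fixed λ0 (not recorded) -------------------------
    done = 0
    while done < n_equil:
        m = min(chunk, n_equil - done)
        noise = np.stack([rng.standard_normal(m) for rng in rngs])
        lam = np.full(m, p.lambda0)
        r = advance(r, lam, noise)
        done += m

    # --- pulling ----------------------------------------------------------
    stride = config.output_stride
    rec_steps = list(range(0, n_steps + 1, stride))
    if rec_steps[-1] != n_steps:
        rec_steps.append(n_steps)
    rec_positions = np.empty((n_rep, len(rec_steps)))
    rec_times = np.array([s * dt for s in rec_steps])
    rec_lambda = p.lambda0 + p.velocity * rec_times

    rec_positions[:, 0] = r
    next_rec = 1
    step = 0
    while step < n_steps:
        m = min(chunk, n_steps - step)
        noise = np.stack([rng.standard_normal(m) for rng in rngs])
        # λ at the *start* of each step in the block (explicit Euler drift)
        lam = p.lambda0 + p.velocity * (step + np.arange(m)) * dt
        for j in range(m):
            drift = -(config.landscape.gradient(r)) - k * (r - lam[j])
            r = r + dt * drift / gamma + sigma * noise[:, j]
            if next_rec < len(rec_steps) and step + j + 1 == rec_steps[next_rec]:
                rec_positions[:, next_rec] = r
                next_rec += 1
        step += m

    traces = []
    for i in range(n_rep):
        forces = k * (rec_lambda - rec_positions[i])
        traces.append(
            SMDTrace(
                replica_id=f"rep{i:03d}",
                times=rec_times.copy(),
                positions=rec_positions[i].copy(),
                forces=forces,
            )
        )
    return traces


def true_delta_g(
    landscape: Landscape,
    a: float,
    b: float,
    kT: Optional[float] = None,
    spring: Optional[float] = None,
) -> float:
    """Ground-truth free-energy difference between reaction coordinates a, b.

    Without a spring this is the bare landscape difference U(b) − U(a).
    With a spring stiffness k it is the difference of the spring-convolved
    free energy

        F(λ) = −kT ln ∫ exp(−[U(r) + k (r − λ)²/2] / kT) dr,

    the quantity a stiff-spring pulling estimate actually converges to.
    """
    lo, hi = landscape.domain
    if not (lo <= a <= hi and lo <= b <= hi):
        raise ParameterError("a and b must lie within the landscape domain")
    if spring is None:
        return float(landscape.potential(b) - landscape.potential(a))
    if kT is None or kT <= 0:
        raise ParameterError("spring-convolved ΔG requires kT > 0")
    width = math.sqrt(kT / spring)

    def free_energy(lam: float) -> float:
        def integrand(r):
            return math.exp(
                -(float(landscape.potential(r)) + 0.5 * spring * (r - lam) ** 2) / kT
            )

        r0, r1 = lam - 12.0 * width, lam + 12.0 * width
        val, err = quad(integrand, r0, r1, limit=200)
        if not np.isfinite(val) or val <= 0 or err > 1e-6 * val:
            raise NumericalError(f"quadrature did not converge at λ={lam}")
        return -kT * math.log(val)

    return free_energy(b) - free_energy(a)


# ---------------------------------------------------------------------------
# Analytic lag traces (closed-form work oracles)
# ---------------------------------------------------------------------------


def constant_lag_trace(
    protocol: PullingProtocol,
    lag: float,
    t_end: float,
    dt: float = 1.0,
    replica_id: str = "const-lag",
) -> SMDTrace:
    """Trace with r(t) = λ(t) − lag; closed-form work W(t) = k·v·lag·t."""
    t = np.arange(0.0, t_end + 0.5 * dt, dt)
    r = protocol.schedule(t) - lag
    return SMDTrace(
        replica_id=replica_id,
        times=t,
        positions=r,
        forces=protocol.spring_constant * lag * np.ones_like(t),
    )


def sinusoidal_lag_trace(
    protocol: PullingProtocol,
    amplitude: float,
    omega: float,
    t_end: float,
    dt: float = 1.0,
    replica_id: str = "sin-lag",
) -> SMDTrace:
    """Trace with lag A·sin(ωt); closed-form W(t) = k·v·A·(1 − cos ωt)/ω."""
    t = np.arange(0.0, t_end + 0.5 * dt, dt)
    lag = amplitude * np.sin(omega * t)
    return SMDTrace(
        replica_id=replica_id,
        times=t,
        positions=protocol.schedule(t) - lag,
        forces=protocol.spring_constant * lag,
    )


# ---------------------------------------------------------------------------
# Toy molecular fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContactScript:
    """Per-frame target distances for one named contact.

    Atom identifiers may be shared across scripts; a shared atom keeps a
    single position per frame, and infeasible combinations raise a
    construction error after verification.
    """

    label: str
    distances: tuple
    atom_a: Optional[str] = None
    atom_b: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "distances", tuple(float(d) for d in self.distances))
        if any(d < 0 for d in self.distances):
            raise ConstructionError("scripted distances must be >= 0")
        if self.atom_a is None:
            object.__setattr__(self, "atom_a", f"{self.label}.a")
        if self.atom_b is None:
            object.__setattr__(self, "atom_b", f"{self.label}.b")


_DIRECTIONS = np.array(
    [
        [1.0, 0.0, 0.0],
        [0.0, 1.0, 0.0],
        [0.0, 0.0, 1.0],
        [1.0, 1.0, 0.0],
        [1.0, 0.0, 1.0],
        [0.0, 1.0, 1.0],
        [1.0, 1.0, 1.0],
    ]
)


def make_toy_frames(
    script: Sequence[ContactScript],
    decoy_atoms: int = 0,
    seed: int = 0,
    frame_interval: float = 1.0,
) -> tuple:
    """Build a FrameSet realizing scripted contact distances exactly.

    Returns ``(frames, specs)`` where ``specs`` maps contact labels to
    ready-made :class:`ContactSpec` objects (cutoff 3.5 Å).  Decoy atoms are
    placed at least 8 Å from every scripted atom in every frame, with
    seeded, reproducible coordinates.
    """
    script = list(script)
    if not script:
        raise ConstructionError("empty contact script")
    n_frames = len(script[0].distances)
    if any(len(c.distances) != n_frames for c in script):
        raise ConstructionError("all contacts must script the same frame count")

    atom_ids = []
    for c in script:
        for aid in (c.atom_a, c.atom_b):
            if aid not in atom_ids:
                atom_ids.append(aid)
    anchors = {aid: np.array([40.0 * i, 0.0, 0.0]) for i, aid in enumerate(atom_ids)}

    coords = np.zeros((n_frames, len(atom_ids), 3))
    index = {aid: i for i, aid in enumerate(atom_ids)}
    for f in range(n_frames):
        placed = {}
        for ci, c in enumerate(script):
            u = _DIRECTIONS[ci % len(_DIRECTIONS)]
            u = u / np.linalg.norm(u)
            if c.atom_a not in placed:
                placed[c.atom_a] = anchors[c.atom_a]
            if c.atom_b not in placed:
                placed[c.atom_b] = placed[c.atom_a] + c.distances[f] * u
        for aid, pos in placed.items():
            coords[f, index[aid]] = pos
        # verify every scripted distance (catches shared-atom contradictions)
        for c in script:
            d = np.linalg.norm(placed[c.atom_a] - placed[c.atom_b])
            if abs(d - c.distances[f]) > 1e-9:
                raise ConstructionError(
                    f"contact {c.label!r} infeasible at frame {f}: realized "
                    f"{d:.6g} Å vs. scripted {c.distances[f]:.6g} Å "
                    f"(shared-atom contradiction?)"
                )

    atoms = [
        Atom(name="CA", resname="CNT", resid=str(i + 1), chain="X", element="C")
        for i in range(len(atom_ids))
    ]
    if decoy_atoms:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 987654321]))
        scripted_pts = coords.reshape(-1, 3)
        decoys = []
        lo = scripted_pts.min(axis=0) - 30.0
        hi = scripted_pts.max(axis=0) + 30.0
        while len(decoys) < decoy_atoms:
            cand = rng.uniform(lo, hi)
            if np.min(np.linalg.norm(scripted_pts - cand, axis=1)) >= 8.0:
                decoys.append(cand)
        decoys = np.array(decoys)
        atoms += [
            Atom(
                name="C",
                resname="DCY",
                resid=str(len(atom_ids) + i + 1),
                chain="D",
                element="C",
            )
            for i in range(decoy_atoms)
        ]
        coords = np.concatenate(
            [coords, np.broadcast_to(decoys, (n_frames, decoy_atoms, 3))], axis=1
        )

    frames = FrameSet(
        atoms=atoms,
        times=np.arange(n_frames, dtype=float) * frame_interval,
        coords=coords,
    )
    specs = {}
    for c in script:
        specs[c.label] = ContactSpec(
            label=c.label,
            atom_a=AtomSelector(resid=str(index[c.atom_a] + 1), name="CA", chain="X"),
            atom_b=AtomSelector(resid=str(index[c.atom_b] + 1), name="CA", chain="X"),
            kind="distance",
        )
    return frames, specs


def make_toy_waterbox(
    pocket_atoms,
    inside: int,
    outside: int,
    cutoff: float = 5.0,
    seed: int = 0,
) -> FrameSet:
    """One-frame box: exactly ``inside`` water oxygens within ``cutoff`` of
    some pocket atom and ``outside`` waters strictly beyond cutoff + 1 Å of
    all pocket atoms."""
    pocket_atoms = np.atleast_2d(np.asarray(pocket_atoms, dtype=float))
    if inside < 0 or outside < 0:
        raise ConstructionError("water counts must be >= 0")
    if cutoff <= 0:
        raise ConstructionError("cutoff must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 24601]))

    waters = []
    for _ in range(inside):
        center = pocket_atoms[rng.integers(len(pocket_atoms))]
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        waters.append(center + u * rng.uniform(0.0, cutoff))
    lo = pocket_atoms.min(axis=0) - (cutoff + 25.0)
    hi = pocket_atoms.max(axis=0) + (cutoff + 25.0)
    attempts = 0
    while len(waters) < inside + outside:
        cand = rng.uniform(lo, hi)
        dmin = np.min(np.linalg.norm(pocket_atoms - cand, axis=1))
        if dmin > cutoff + 1.0:
            waters.append(cand)
        attempts += 1
        if attempts > 10000 * max(1, outside):
            raise ConstructionError("could not place outside waters")

    atoms = [
        Atom(name="C", resname="PCK", resid=str(i + 1), chain="P", element="C")
        for i in range(len(pocket_atoms))
    ]
    atoms += [
        Atom(name="O", resname="HOH", resid=str(i + 1), chain="W", element="O")
        for i in range(inside + outside)
    ]
    coords = np.concatenate(
        [pocket_atoms, np.array(waters).reshape(-1, 3)], axis=0
    )[None, :, :]
    return FrameSet(atoms=atoms, times=np.array([0.0]), coords=coords)


# ---------------------------------------------------------------------------
# Default study scenario
# ---------------------------------------------------------------------------


def default_protocol(velocity: float = 0.005) -> PullingProtocol:
    """k = 12 kcal/mol/Å² at 310 K; velocity defaults to the desk-scale 0.005 Å/ps."""
    return PullingProtocol(
        spring_constant=12.0, velocity=velocity, lambda0=0.0, temperature=310.0
    )


def default_pulling_config(
    seed: int = 0,
    n_replicas: int = 75,
    velocity: float = 0.005,
    friction: float = 5.0,
    dt: float = 0.01,
    output_period: float = 1.0,
    landscape: Optional[Landscape] = None,
) -> LangevinConfig:
    """The package's reference pulling scenario (see docs/methods.md).

    75 replicas, k = 12 kcal/mol/Å², T = 310 K over the default
    double-Gaussian landscape; n_steps spans the whole landscape domain at
    the given velocity.
    """
    landscape = landscape if landscape is not None else DEFAULT_LANDSCAPE
    protocol = default_protocol(velocity)
    span = landscape.domain[1] - landscape.domain[0]
    n_steps = int(round(span / velocity / dt))
    return LangevinConfig(
        landscape=landscape,
        protocol=protocol,
        friction=friction,
        dt=dt,
        n_steps=n_steps,
        n_replicas=n_replicas,
        seed=seed,
        output_period=output_period,
    )
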