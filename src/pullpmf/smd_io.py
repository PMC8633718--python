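"""Reading and writing pulling traces, protocol configs and molecular frames.

Two trace dialects are supported:

``tabular``
    Whitespace- or comma-separated columns ``time  position  [force]`` in
    ps / Å / kcal/mol/Å, with ``#`` comment lines.

``namd``
    One tagged record per SMD output step::

        SMD  <step>  <x> <y> <z>  <fx> <fy> <fz>

    positions and forces are 3-D; the step index is converted to ps through
    a required ``timestep`` (fs per step) and the 3-D vectors are projected
    onto the protocol's pulling direction.

Topologies are fixed-column PDB files (parsed with Biopython); multi-frame
coordinates come either from additional ``MODEL`` blocks or from a simple
per-frame xyz text (``frame <time_ps>`` header followed by one ``x y z``
line per atom).
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import (
    EmptyTraceError,
    ParameterError,
    StructureError,
    TraceOrderingError,
)

logger = logging.getLogger(__name__)

WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3"})

#: PDB v3 phosphate-oxygen names and their legacy aliases.
ATOM_NAME_ALIASES = {"O1P": "OP1", "O2P": "OP2"}


def canonical_atom_name(name: str) -> str:
    """Map legacy PDB atom names (O1P/O2P) onto their v3 equivalents."""
    name = name.strip()
    return ATOM_NAME_ALIASES.get(name, name)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PullingProtocol:
    """Parameters of a constant-velocity pulling experiment.

    Parameters
    ----------
    spring_constant : float
        Harmonic force constant k, kcal/mol/Å².
    velocity : float
        Pulling speed v, Å/ps.  The spring's scheduled position is
        ``λ(t) = λ0 + v·t``.
    lambda0 : float
        Initial scheduled position λ0, Å.
    temperature : float
        Bath temperature, K.
    direction : ndarray or None
        Unit vector of the pulling direction; required to project 3-D
        records onto the reaction coordinate.
    """

    spring_constant: float
    velocity: float
    lambda0: float = 0.0
    temperature: float = 310.0
    direction: Optional[np.ndarray] = None

    def __post_init__(self):
        if not self.spring_constant > 0:
            raise ParameterError("spring_constant must be > 0")
        if self.velocity < 0:
            raise ParameterError("velocity must be >= 0")
        if not self.temperature > 0:
            raise ParameterError("temperature must be > 0")
        if self.direction is not None:
            d = np.asarray(self.direction, dtype=float)
            if d.shape != (3,):
                raise ParameterError("direction must be a 3-vector")
            if abs(np.linalg.norm(d) - 1.0) > 1e-9:
                raise ParameterError("direction must have unit norm (1e-9)")
            object.__setattr__(self, "direction", d)

    def schedule(self, times):
        """Scheduled spring position λ(t) = λ0 + v·t."""
        return self.lambda0 + self.velocity * np.asarray(times, dtype=float)


@dataclass
class SMDTrace:
    """One pulling replicate: time series of position and applied force.

    ``forces`` may be absent; downstream code reconstructs the spring force
    as ``k·(λ(t) − r)`` and ``force_reconstructed`` records that this
    happened, so measured and reconstructed forces stay distinguishable.
    """

    replica_id: str
    times: np.ndarray  # ps, strictly increasing
    positions: np.ndarray  # Å, projection onto the reaction coordinate
    forces: Optional[np.ndarray] = None  # kcal/mol/Å
    force_reconstructed: bool = False

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.forces is not None:
            self.forces = np.asarray(self.forces, dtype=float)
        if self.times.ndim != 1:
            raise ParameterError("times must be 1-D")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            bad = int(np.argmax(np.diff(self.times) <= 0)) + 1
            raise TraceOrderingError(
                f"times not strictly increasing at index {bad}"
            )
        if self.positions.shape != self.times.shape:
            raise ParameterError("positions length must match times")
        if self.forces is not None and self.forces.shape != self.times.shape:
            raise ParameterError("forces length must match times")

    def __len__(self):
        return len(self.times)

    def with_forces(self, protocol: PullingProtocol) -> "SMDTrace":
        """Return a trace that has forces, reconstructing k·(λ−r) if absent."""
        if self.forces is not None:
            return self
        f = protocol.spring_constant * (
            protocol.schedule(self.times) - self.positions
        )
        return replace(self, forces=f, force_reconstructed=True)


@dataclass(frozen=True)
class Atom:
    """One topology atom record."""

    name: str
    resname: str
    resid: str  # residue number with any insertion code appended
    chain: str
    element: str
    epsilon: Optional[float] = None  # LJ well depth, kcal/mol
    rmin_half: Optional[float] = None  # LJ rmin/2, Å

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"

    @property
    def is_water(self) -> bool:
        return self.resname.upper() in WATER_RESNAMES


@dataclass
class FrameSet:
    """Atom metadata joined to a stack of coordinate frames."""

    atoms: list
    times: np.ndarray  # ps, non-decreasing
    coords: np.ndarray  # (n_frames, n_atoms, 3), Å

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise StructureError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] != len(self.times):
            raise StructureError("frame count must match times length")
        if self.coords.shape[1] != len(self.atoms):
            raise StructureError(
                f"coordinate columns ({self.coords.shape[1]}) do not match "
                f"atom count ({len(self.atoms)})"
            )
        if len(self.times) > 1 and np.any(np.diff(self.times) < 0):
            raise StructureError("frame times must be non-decreasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


# ---------------------------------------------------------------------------
# Trace readers / writers
# ---------------------------------------------------------------------------


def read_smd_log(
    path,
    dialect: str = "tabular",
    protocol: Optional[PullingProtocol] = None,
    timestep: Optional[float] = None,
    force_convention: str = "projection",
    replica_id: Optional[str] = None,
) -> SMDTrace:
    """Read one pulling trace.

    Parameters
    ----------
    dialect : {"tabular", "namd"}
    protocol : PullingProtocol, required for the namd dialect
        Its ``direction`` projects 3-D positions/forces onto the reaction
        coordinate.
    timestep : float
        fs per step; required for the namd dialect (the log carries bare
        step indices, no time unit).
    force_convention : {"projection", "magnitude"}
        Whether logged 3-D forces are reduced to their signed projection on
        the pulling direction (default) or to their Euclidean magnitude.
    """
    path = Path(path)
    if dialect not in ("tabular", "namd"):
        raise ParameterError(f"unknown dialect {dialect!r}")
    if force_convention not in ("projection", "magnitude"):
        raise ParameterError(f"unknown force convention {force_convention!r}")
    try:
        text = path.read_text()
    except OSError as exc:
        raise IOError(f"cannot read trace file {path}: {exc}") from exc

    times, positions, forces = [], [], []
    n_skipped = 0
    if dialect == "namd":
        if protocol is None or protocol.direction is None:
            raise ParameterError(
                "namd dialect requires a protocol with a pulling direction"
            )
        if timestep is None or timestep <= 0:
            raise ParameterError("namd dialect requires timestep (fs per step) > 0")
        d = protocol.direction
        for line in text.splitlines():
            parts = line.split()
            if not parts or parts[0] != "SMD":
                continue
            if len(parts) != 8:
                n_skipped += 1
                continue
            try:
                step = float(parts[1])
                vals = [float(x) for x in parts[2:]]
            except ValueError:
                n_skipped += 1
                continue
            pos3 = np.array(vals[:3])
            f3 = np.array(vals[3:])
            times.append(step * timestep / 1000.0)  # fs -> ps
            positions.append(float(pos3 @ d))
            if force_convention == "projection":
                forces.append(float(f3 @ d))
            else:
                forces.append(float(np.linalg.norm(f3)))
    else:
        for lineno, line in enumerate(text.splitlines(), start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.replace(",", " ").split()
            try:
                vals = [float(x) for x in parts]
            except ValueError:
                n_skipped += 1
                continue
            if len(vals) < 2:
                n_skipped += 1
                continue
            times.append(vals[0])
            positions.append(vals[1])
            if len(vals) >= 3:
                forces.append(vals[2])
            else:
                forces.append(math.nan)

    if n_skipped:
        logger.warning("%s: skipped %d malformed line(s)", path, n_skipped)
    if not times:
        raise EmptyTraceError(f"{path}: no parsable trace records")

    t = np.asarray(times)
    if np.any(np.diff(t) <= 0):
        bad = int(np.argmax(np.diff(t) <= 0)) + 1
        raise TraceOrderingError(
            f"{path}: non-monotonic time at record {bad} (t={t[bad]!r})"
        )
    f = np.asarray(forces) if forces else None
    if f is not None and np.all(np.isnan(f)):
        f = None
    return SMDTrace(
        replica_id=replica_id or path.stem,
        times=t,
        positions=np.asarray(positions),
        forces=f,
    )


def write_smd_log(
    trace: SMDTrace,
    path,
    dialect: str = "tabular",
    protocol: Optional[PullingProtocol] = None,
    timestep: Optional[float] = None,
) -> Path:
    """Write a trace; inverse of :func:`read_smd_log` within 1e-6 rel. tol.

    A trace without forces requires a protocol so the spring force
    ``k·(λ(t) − r)`` can be emitted.
    """
    path = Path(path)
    if len(trace) == 0:
        raise EmptyTraceError("refusing to write an empty trace")
    if trace.forces is None:
        if protocol is None:
            raise ParameterError(
                "trace has no forces; a protocol is needed to reconstruct them"
            )
        trace = trace.with_forces(protocol)

    lines = []
    if dialect == "tabular":
        lines.append("# time_ps position_A force_kcal_mol_A")
        for t, r, f in zip(trace.times, trace.positions, trace.forces):
            lines.append(f"{t:.10g} {r:.10g} {f:.10g}")
    elif dialect == "namd":
        if protocol is None or protocol.direction is None:
            raise ParameterError("namd dialect requires a protocol with direction")
        if timestep is None or timestep <= 0:
            raise ParameterError("namd dialect requires timestep (fs per step) > 0")
        d = protocol.direction
        for t, r, f in zip(trace.times, trace.positions, trace.forces):
            step = t * 1000.0 / timestep
            pos3 = r * d
            f3 = f * d
            lines.append(
                "SMD "
                + f"{step:.10g} "
                + " ".join(f"{x:.10g}" for x in pos3)
                + " "
                + " ".join(f"{x:.10g}" for x in f3)
            )
    else:
        raise ParameterError(f"unknown dialect {dialect!r}")
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise IOError(f"cannot write trace file {path}: {exc}") from exc
    return path


# ---------------------------------------------------------------------------
# Protocol configs (YAML / TOML)
# ---------------------------------------------------------------------------


def read_protocol(path) -> tuple[PullingProtocol, Optional[float]]:
    """Read a pulling-protocol config (.yaml/.yml or .toml).

    Recognised keys: spring_constant, velocity, lambda0, temperature,
    direction, timestep.  Returns (protocol, timestep_fs_or_None).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(path.read_text())
    elif suffix == ".toml":
        import tomllib

        data = tomllib.loads(path.read_text())
    else:
        raise ParameterError(f"unsupported protocol config format: {path.name}")
    if not isinstance(data, dict):
        raise ParameterError(f"{path}: protocol config must be a mapping")
    direction = data.get("direction")
    if direction is not None:
        direction = np.asarray(direction, dtype=float)
        n = np.linalg.norm(direction)
        if n == 0:
            raise ParameterError(f"{path}: direction must be non-zero")
        direction = direction / n
    protocol = PullingProtocol(
        spring_constant=float(data["spring_constant"]),
        velocity=float(data["velocity"]),
        lambda0=float(data.get("lambda0", 0.0)),
        temperature=float(data.get("temperature", 310.0)),
        direction=direction,
    )
    timestep = data.get("timestep")
    return protocol, (float(timestep) if timestep is not None else None)


# ---------------------------------------------------------------------------
# Frames (PDB topology + coordinates)
# ---------------------------------------------------------------------------


def _atoms_from_pdb(path) -> tuple[list, list]:
    """Parse a PDB with Biopython; returns (atoms, per-model coordinate arrays).

    Disordered (altloc) positions collapse to the highest-occupancy
    alternative; insertion codes are appended to the residue number.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("top", str(path))
    models = list(structure)
    if not models:
        raise StructureError(f"{path}: no models in PDB file")

    def model_records(model):
        recs = []
        for chain in model:
            for residue in chain:
                _, resseq, icode = residue.id
                resid = f"{resseq}{icode.strip()}"
                for atom in residue:
                    # Bio.PDB exposes the highest-occupancy altloc as the
                    # selected child of a DisorderedAtom.
                    if atom.is_disordered():
                        atom = atom.selected_child
                    recs.append(
                        (
                            Atom(
                                name=canonical_atom_name(atom.get_name()),
                                resname=residue.get_resname().strip(),
                                resid=resid,
                                chain=chain.id.strip() or " ",
                                element=(atom.element or "").strip(),
                            ),
                            atom.get_coord().astype(float),
                        )
                    )
        return recs

    first = model_records(models[0])
    atoms = [a for a, _ in first]
    frames = [np.array([c for _, c in first])]
    for i, model in enumerate(models[1:], start=1):
        recs = model_records(model)
        if len(recs) != len(atoms):
            raise StructureError(
                f"{path}: frame {i} has {len(recs)} atoms, expected {len(atoms)}"
            )
        frames.append(np.array([c for _, c in recs]))
    return atoms, frames


def _read_xyz_frames(path, n_atoms: int):
    """Read the per-frame xyz text dialect.

    Frames are introduced by a ``frame [time_ps]`` header line (or separated
    by blank lines, in which case times default to the frame index); each
    body line is ``x y z``.
    """
    times, frames, current, current_time = [], [], [], None
    idx = 0

    def flush():
        nonlocal current, current_time, idx
        if current:
            if len(current) != n_atoms:
                raise StructureError(
                    f"{path}: frame {len(frames)} has {len(current)} "
                    f"coordinates for {n_atoms} atoms"
                )
            frames.append(np.array(current))
            times.append(current_time if current_time is not None else float(idx))
            idx += 1
        current, current_time = [], None

    for line in Path(path).read_text().splitlines():
        stripped = line.strip()
        if not stripped:
            flush()
            continue
        if stripped.startswith("#"):
            continue
        if stripped.lower().startswith("frame"):
            flush()
            parts = stripped.split()
            current_time = float(parts[1]) if len(parts) > 1 else None
            continue
        vals = stripped.split()
        if len(vals) != 3:
            raise StructureError(f"{path}: bad xyz line: {stripped!r}")
        current.append([float(v) for v in vals])
    flush()
    if not frames:
        raise StructureError(f"{path}: no coordinate frames found")
    return np.asarray(times, dtype=float), np.stack(frames)


def read_frames(topology_path, coords_path=None, frame_interval: float = 1.0) -> FrameSet:
    """Load a FrameSet from a PDB topology plus optional coordinate source.

    With ``coords_path=None`` the topology's own MODEL blocks supply the
    frames (times = model index × ``frame_interval`` ps).  ``coords_path``
    may be another multi-MODEL PDB or the xyz text dialect.
    """
    atoms, pdb_frames = _atoms_from_pdb(topology_path)
    if coords_path is None:
        coords = np.stack(pdb_frames)
        times = np.arange(len(pdb_frames), dtype=float) * frame_interval
    else:
        coords_path = Path(coords_path)
        if coords_path.suffix.lower() in (".pdb", ".ent"):
            _, frames2 = _atoms_from_pdb(coords_path)
            for i, f in enumerate(frames2):
                if f.shape[0] != len(atoms):
                    raise StructureError(
                        f"{coords_path}: frame {i} has {f.shape[0]} atoms, "
                        f"expected {len(atoms)}"
                    )
            coords = np.stack(frames2)
            times = np.arange(len(frames2), dtype=float) * frame_interval
        else:
            times, coords = _read_xyz_frames(coords_path, len(atoms))
    return FrameSet(atoms=atoms, times=times, coords=coords)


def write_frames(frames: FrameSet, path) -> Path:
    """Write a FrameSet as a multi-MODEL PDB (fixed-column ATOM records)."""
    path = Path(path)
    lines = []
    for i in range(frames.n_frames):
        lines.append(f"MODEL     {i + 1:4d}")
        serial = 1
        for atom, xyz in zip(frames.atoms, frames.coords[i]):
            name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {name:<4.4s} {atom.resname:<3.3s} "
                f"{atom.chain:1.1s}{int(''.join(ch for ch in atom.resid if ch.isdigit()) or 0):4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2.2s}"
            )
            serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path
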