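"""Contact timelines and pairwise van der Waals energies.

Hydrogen bonds and salt bridges are classified by a pure distance criterion:
a contact is *bound* in a frame when the donor–acceptor distance is at or
below the cutoff (default 3.5 Å — arginine hydrogen to RNA O/N heavy atom
for hydrogen bonds, arginine side-chain nitrogen to backbone phosphate
oxygen for salt bridges).  No angular term is applied.  Rupture/formation
events mark the state changes of that boolean series; an optional
dual-cutoff hysteresis (form at ≤ cutoff, rupture only above a higher
cutoff) suppresses chatter in the event list while leaving the plain
``bound`` series untouched.

Pairwise van der Waals energies between two residues sum the 12-6
Lennard-Jones term over all atom pairs with Lorentz–Berthelot combination,

    V(r) = ε_ij [ (rmin_ij / r)^12 − 2 (rmin_ij / r)^6 ],
    ε_ij = sqrt(ε_i ε_j),   rmin_ij = rmin_half_i + rmin_half_j,

multiplied by the standard cubic switching function between the switch-on
and cutoff distances (default 8 → 10 Å) and zero beyond the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, ParameterizationError, SelectionError
from .smd_io import FrameSet, canonical_atom_name

#: Distance criterion for hydrogen bonds and salt bridges, Å.
HBOND_CUTOFF = 3.5


@dataclass(frozen=True)
class AtomSelector:
    """Selects exactly one atom by (chain, residue number, atom name)."""

    resid: str
    name: str
    chain: Optional[str] = None
    resname: Optional[str] = None

    def __str__(self):
        chain = f"{self.chain}:" if self.chain else ""
        return f"{chain}{self.resname or '*'}{self.resid}@{self.name}"


@dataclass(frozen=True)
class ResidueSelector:
    """Selects all atoms of one residue."""

    resid: str
    chain: Optional[str] = None
    resname: Optional[str] = None

    def __str__(self):
        chain = f"{self.chain}:" if self.chain else ""
        return f"{chain}{self.resname or '*'}{self.resid}"


@dataclass(frozen=True)
class ContactSpec:
    """A labelled atom-pair contact with its distance criterion."""

    label: str
    atom_a: AtomSelector
    atom_b: AtomSelector
    kind: str = "hbond"  # {"hbond", "saltbridge", "distance"}
    cutoff: float = HBOND_CUTOFF

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ParameterError("cutoff must be > 0")
        if self.kind not in ("hbond", "saltbridge", "distance"):
            raise ParameterError(f"unknown contact kind {self.kind!r}")


@dataclass
class InteractionSeries:
    """Per-frame distance trace of one contact plus its bound/event record."""

    spec: ContactSpec
    times: np.ndarray  # ps
    distances: np.ndarray  # Å
    bound: np.ndarray  # bool, distance <= cutoff
    events: list  # (time ps, "formed" | "ruptured"), time-ordered


@dataclass
class PairEnergySeries:
    """Per-frame van der Waals energy between two residues."""

    residue_a: ResidueSelector
    residue_b: ResidueSelector
    times: np.ndarray  # ps
    energy: np.ndarray  # kcal/mol


def _match_atom(atom, sel: AtomSelector) -> bool:
    if canonical_atom_name(atom.name) != canonical_atom_name(sel.name):
        return False
    if str(atom.resid) != str(sel.resid):
        return False
    if sel.chain is not None and atom.chain != sel.chain:
        return False
    if sel.resname is not None and atom.resname != sel.resname:
        return False
    return True


def resolve_atom(frames: FrameSet, sel: AtomSelector) -> int:
    """Index of the unique atom matching ``sel`` (SelectionError otherwise)."""
    hits = [i for i, a in enumerate(frames.atoms) if _match_atom(a, sel)]
    if len(hits) != 1:
        cand = ", ".join(
            f"{frames.atoms[i].chain}:{frames.atoms[i].resname}"
            f"{frames.atoms[i].resid}@{frames.atoms[i].name}"
            for i in hits
        ) or "none"
        raise SelectionError(
            f"selector {sel} matched {len(hits)} atoms (candidates: {cand})"
        )
    return hits[0]


def resolve_residue(frames: FrameSet, sel: ResidueSelector) -> list:
    """Indices of all atoms in the residue selected by ``sel``."""
    hits = [
        i
        for i, a in enumerate(frames.atoms)
        if str(a.resid) == str(sel.resid)
        and (sel.chain is None or a.chain == sel.chain)
        and (sel.resname is None or a.resname == sel.resname)
    ]
    if not hits:
        raise SelectionError(f"residue selector {sel} matched no atoms")
    return hits


def _events_from_states(times, bound, distances, cutoff, hysteresis):
    """Walk the bound/unbound state machine; events at state changes.

    Without hysteresis the state is the plain cutoff classification.  With
    hysteresis=(form, rupture) a bound contact only ruptures above the
    rupture cutoff and an unbound one only forms at or below the form
    cutoff.
    """
    events = []
    if hysteresis is None:
        state = bool(bound[0])
        for i in range(1, len(bound)):
            if bool(bound[i]) != state:
                state = bool(bound[i])
                events.append((float(times[i]), "formed" if state else "ruptured"))
    else:
        form, rupture = hysteresis
        if not (rupture > form > 0):
            raise ParameterError("hysteresis must satisfy rupture > form > 0")
        state = distances[0] <= form
        for i in range(1, len(distances)):
            if state and distances[i] > rupture:
                state = False
                events.append((float(times[i]), "ruptured"))
            elif not state and distances[i] <= form:
                state = True
                events.append((float(times[i]), "formed"))
    return events


def contact_series(
    frames: FrameSet,
    spec: ContactSpec,
    hysteresis: Optional[tuple] = None,
) -> InteractionSeries:
    """Distance/bound/event series for one contact across all frames.

    ``bound`` always reflects the plain single-cutoff criterion
    (distance ≤ cutoff); ``hysteresis`` only affects the event list.
    Distances are symmetric in the two selectors.
    """
    ia = resolve_atom(frames, spec.atom_a)
    ib = resolve_atom(frames, spec.atom_b)
    diff = frames.coords[:, ia, :] - frames.coords[:, ib, :]
    distances = np.linalg.norm(diff, axis=1)
    bound = distances <= spec.cutoff
    events = _events_from_states(
        frames.times, bound, distances, spec.cutoff, hysteresis
    )
    return InteractionSeries(
        spec=spec,
        times=frames.times.copy(),
        distances=distances,
        bound=bound,
        events=events,
    )


def occupancy(series: InteractionSeries, window: Optional[tuple] = None) -> float:
    """Fraction of frames bound within a (t0, t1) window (default: all)."""
    if window is None:
        mask = np.ones(len(series.times), dtype=bool)
    else:
        t0, t1 = window
        if t1 < t0:
            raise ParameterError("window end before start")
        mask = (series.times >= t0) & (series.times <= t1)
    if not mask.any():
        raise ParameterError("empty occupancy window")
    return float(series.bound[mask].mean())


def switching_function(r, on: float, off: float):
    """Standard cubic (in r²) switching function: 1 below on, 0 beyond off."""
    r = np.asarray(r, dtype=float)
    r2, on2, off2 = r * r, on * on, off * off
    s = (off2 - r2) ** 2 * (off2 + 2.0 * r2 - 3.0 * on2) / (off2 - on2) ** 3
    return np.where(r <= on, 1.0, np.where(r >= off, 0.0, s))


def lj_pair_energy(
    frames: FrameSet,
    residue_a: ResidueSelector,
    residue_b: ResidueSelector,
    params: Optional[dict] = None,
    switch: tuple = (8.0, 10.0),
) -> PairEnergySeries:
    """Summed switched Lennard-Jones energy between two residues, per frame.

    ``params`` maps atom names to ``(epsilon kcal/mol, rmin_half Å)``;
    atoms carrying their own ``epsilon``/``rmin_half`` fields may omit the
    table entry.  Every atom pair is summed explicitly (no neighbour lists
    at this scale).
    """
    on, off = switch
    if not (off > on > 0):
        raise ParameterError("switch must satisfy off > on > 0")
    idx_a = resolve_residue(frames, residue_a)
    idx_b = resolve_residue(frames, residue_b)

    def lookup(i):
        atom = frames.atoms[i]
        if atom.epsilon is not None and atom.rmin_half is not None:
            return atom.epsilon, atom.rmin_half
        if params is not None:
            key = canonical_atom_name(atom.name)
            if key in params:
                return params[key]
        raise ParameterizationError(
            f"no Lennard-Jones parameters for atom "
            f"{atom.chain}:{atom.resname}{atom.resid}@{atom.name}"
        )

    eps_a, rmh_a = map(np.array, zip(*(lookup(i) for i in idx_a)))
    eps_b, rmh_b = map(np.array, zip(*(lookup(i) for i in idx_b)))
    eps_ij = np.sqrt(np.outer(eps_a, eps_b))
    rmin_ij = rmh_a[:, None] + rmh_b[None, :]

    ca = frames.coords[:, idx_a, :]  # (F, A, 3)
    cb = frames.coords[:, idx_b, :]  # (F, B, 3)
    d = np.linalg.norm(ca[:, :, None, :] - cb[:, None, :, :], axis=-1)  # (F, A, B)
    with np.errstate(divide="ignore"):
        ratio6 = (rmin_ij[None] / d) ** 6
    v = eps_ij[None] * (ratio6 * ratio6 - 2.0 * ratio6) * switching_function(d, on, off)
    v = np.where(d >= off, 0.0, v)
    return PairEnergySeries(
        residue_a=residue_a,
        residue_b=residue_b,
        times=frames.times.copy(),
        energy=v.sum(axis=(1, 2)),
    )


def event_sequence(series_list: Sequence[InteractionSeries]) -> pd.DataFrame:
    """Merge contact events into one time-ordered table.

    Columns: time (ps), label, event.  Simultaneous events are ordered by
    contact label (stable, documented tie-break).
    """
    rows = [
        {"time": t, "label": s.spec.label, "event": kind}
        for s in series_list
        for t, kind in s.events
    ]
    df = pd.DataFrame(rows, columns=["time", "label", "event"])
    if len(df):
        df = df.sort_values(["time", "label"], kind="stable").reset_index(drop=True)
    return df
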