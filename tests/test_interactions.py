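import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import pullpmf as pp
from pullpmf.errors import ParameterizationError, SelectionError


@pytest.fixture
def scripted():
    """The 5-frame scripted contact [3.0, 3.0, 4.0, 4.0, 3.0] Å."""
    frames, specs = pp.make_toy_frames(
        [pp.ContactScript("c1", distances=(3.0, 3.0, 4.0, 4.0, 3.0))]
    )
    return frames, specs["c1"]


class TestContactSeries:
    def test_cutoff_classification(self):
        frames, specs = pp.make_toy_frames(
            [pp.ContactScript("near", distances=(3.4,)),
             pp.ContactScript("far", distances=(3.6,)),
             pp.ContactScript("zero", distances=(0.0,))]
        )
        assert pp.contact_series(frames, specs["near"]).bound.all()
        assert not pp.contact_series(frames, specs["far"]).bound.any()
        assert pp.contact_series(frames, specs["zero"]).bound.all()

    def test_constant_bound_distance_has_no_events(self):
        frames, specs = pp.make_toy_frames(
            [pp.ContactScript("c", distances=(3.4,) * 6)]
        )
        s = pp.contact_series(frames, specs["c"])
        assert s.bound.all() and s.events == []

    def test_scripted_rupture_and_reformation(self, scripted):
        frames, spec = scripted
        s = pp.contact_series(frames, spec)
        np.testing.assert_array_equal(s.bound, [True, True, False, False, True])
        assert s.events == [(2.0, "ruptured"), (4.0, "formed")]
        assert pp.occupancy(s) == pytest.approx(0.6)

    def test_hysteresis_suppresses_chatter(self):
        # distances oscillating between 3.4 and 3.7: plain cutoff chatters,
        # dual-cutoff (form 3.5, rupture 4.0) stays bound throughout
        frames, specs = pp.make_toy_frames(
            [pp.ContactScript("c", distances=(3.4, 3.7, 3.4, 3.7, 3.4))]
        )
        plain = pp.contact_series(frames, specs["c"])
        assert len(plain.events) == 4
        damped = pp.contact_series(frames, specs["c"], hysteresis=(3.5, 4.0))
        assert damped.events == []
        # bound is always the single-cutoff classification
        np.testing.assert_array_equal(damped.bound, plain.bound)

    def test_distance_symmetry(self, scripted):
        frames, spec = scripted
        swapped = pp.ContactSpec(
            label=spec.label, atom_a=spec.atom_b, atom_b=spec.atom_a,
            kind=spec.kind, cutoff=spec.cutoff,
        )
        a = pp.contact_series(frames, spec)
        b = pp.contact_series(frames, swapped)
        np.testing.assert_array_equal(a.distances, b.distances)

    def test_ambiguous_selector_errors(self, scripted):
        frames, spec = scripted
        with pytest.raises(SelectionError, match="matched 0"):
            pp.contact_series(
                frames,
                pp.ContactSpec(
                    label="x",
                    atom_a=pp.AtomSelector(resid="99", name="CA"),
                    atom_b=spec.atom_b,
                ),
            )

    def test_rigid_motion_invariance(self, scripted):
        frames, spec = scripted
        rot = Rotation.from_rotvec([0.3, -0.4, 1.1]).as_matrix()
        shift = np.array([5.0, -2.0, 7.0])
        moved = pp.FrameSet(
            atoms=frames.atoms,
            times=frames.times,
            coords=frames.coords @ rot.T + shift,
        )
        a = pp.contact_series(frames, spec)
        b = pp.contact_series(moved, spec)
        np.testing.assert_allclose(a.distances, b.distances, atol=1e-9)


class TestOccupancy:
    def test_extremes(self):
        frames, specs = pp.make_toy_frames(
            [pp.ContactScript("in", distances=(3.0,) * 4),
             pp.ContactScript("out", distances=(9.0,) * 4)]
        )
        assert pp.occupancy(pp.contact_series(frames, specs["in"])) == 1.0
        assert pp.occupancy(pp.contact_series(frames, specs["out"])) == 0.0

    def test_invariant_to_frame_duplication(self, scripted):
        frames, spec = scripted
        dup = pp.FrameSet(
            atoms=frames.atoms,
            times=np.arange(2 * frames.n_frames, dtype=float),
            coords=np.repeat(frames.coords, 2, axis=0),
        )
        assert pp.occupancy(pp.contact_series(dup, spec)) == pytest.approx(
            pp.occupancy(pp.contact_series(frames, spec))
        )

    def test_windowing_and_empty_window(self, scripted):
        frames, spec = scripted
        s = pp.contact_series(frames, spec)
        assert pp.occupancy(s, window=(0.0, 1.0)) == 1.0
        with pytest.raises(pp.ParameterError):
            pp.occupancy(s, window=(100.0, 200.0))


def single_atom_residues(separation):
    """Two one-atom residues a given distance apart, with LJ parameters."""
    atoms = [
        pp.Atom(name="X1", resname="TOY", resid="1", chain="A", element="C",
                epsilon=0.2, rmin_half=1.8),
        pp.Atom(name="X2", resname="TOY", resid="2", chain="A", element="C",
                epsilon=0.45, rmin_half=2.1),
    ]
    coords = np.array([[[0.0, 0.0, 0.0], [separation, 0.0, 0.0]]])
    return pp.FrameSet(atoms=atoms, times=np.array([0.0]), coords=coords)


def lj_bruteforce(frames, idx_a, idx_b, switch=(8.0, 10.0)):
    """Independent O(n²) oracle: explicit double loop, scalar math."""
    import math

    on, off = switch
    energies = []
    for f in range(frames.n_frames):
        e = 0.0
        for i in idx_a:
            for j in idx_b:
                ai, aj = frames.atoms[i], frames.atoms[j]
                r = math.dist(frames.coords[f, i], frames.coords[f, j])
                eps = math.sqrt(ai.epsilon * aj.epsilon)
                rmin = ai.rmin_half + aj.rmin_half
                if r >= off:
                    continue
                v = eps * ((rmin / r) ** 12 - 2.0 * (rmin / r) ** 6)
                if r > on:
                    s = ((off**2 - r**2) ** 2 * (off**2 + 2 * r**2 - 3 * on**2)
                         / (off**2 - on**2) ** 3)
                    v *= s
                e += v
        energies.append(e)
    return np.array(energies)


class TestLJPairEnergy:
    def test_minimum_at_rmin_is_minus_epsilon(self):
        frames = single_atom_residues(1.8 + 2.1)  # r = rmin_ij, inside switch-on
        s = pp.lj_pair_energy(
            frames,
            pp.ResidueSelector(resid="1"),
            pp.ResidueSelector(resid="2"),
        )
        eps_ij = np.sqrt(0.2 * 0.45)
        np.testing.assert_allclose(s.energy, [-eps_ij], rtol=1e-12)

    def test_zero_beyond_cutoff(self):
        frames = single_atom_residues(10.5)
        s = pp.lj_pair_energy(
            frames, pp.ResidueSelector(resid="1"), pp.ResidueSelector(resid="2")
        )
        np.testing.assert_array_equal(s.energy, [0.0])

    def test_switching_region_continuity(self):
        # energy decays continuously from switch-on to exactly 0 at cutoff
        e = []
        for r in (7.999, 8.5, 9.5, 9.999):
            frames = single_atom_residues(r)
            e.append(
                pp.lj_pair_energy(
                    frames, pp.ResidueSelector(resid="1"), pp.ResidueSelector(resid="2")
                ).energy[0]
            )
        assert abs(e[-1]) < 1e-6
        assert abs(e[0]) > abs(e[1]) > abs(e[2]) > abs(e[3])

    def test_matches_bruteforce_oracle_on_toy_residues(self):
        rng = np.random.default_rng(31)
        atoms = []
        # residue 1: three atoms; residue 2: two atoms
        for i, (resid, n) in enumerate([("1", 3), ("2", 2)]):
            for j in range(n):
                atoms.append(
                    pp.Atom(
                        name=f"C{i}{j}", resname="TOY", resid=resid, chain="A",
                        element="C",
                        epsilon=float(rng.uniform(0.05, 0.5)),
                        rmin_half=float(rng.uniform(1.2, 2.2)),
                    )
                )
        coords = np.stack(
            [
                np.concatenate(
                    [
                        rng.uniform(0, 3, size=(3, 3)),
                        rng.uniform(2, 9, size=(2, 3)),
                    ]
                )
                for _ in range(4)
            ]
        )
        frames = pp.FrameSet(atoms=atoms, times=np.arange(4.0), coords=coords)
        s = pp.lj_pair_energy(
            frames, pp.ResidueSelector(resid="1"), pp.ResidueSelector(resid="2")
        )
        oracle = lj_bruteforce(frames, [0, 1, 2], [3, 4])
        np.testing.assert_allclose(s.energy, oracle, rtol=1e-10, atol=1e-12)

    def test_missing_parameters_name_the_atom(self):
        atoms = [
            pp.Atom(name="X1", resname="TOY", resid="1", chain="A", element="C"),
            pp.Atom(name="X2", resname="TOY", resid="2", chain="A", element="C",
                    epsilon=0.1, rmin_half=2.0),
        ]
        frames = pp.FrameSet(
            atoms=atoms, times=np.array([0.0]),
            coords=np.array([[[0, 0, 0], [3.0, 0, 0]]], dtype=float),
        )
        with pytest.raises(ParameterizationError, match="X1"):
            pp.lj_pair_energy(
                frames, pp.ResidueSelector(resid="1"), pp.ResidueSelector(resid="2")
            )
        # a per-atom-type table fills the gap; O1P/OP1 aliasing applies
        s = pp.lj_pair_energy(
            frames,
            pp.ResidueSelector(resid="1"),
            pp.ResidueSelector(resid="2"),
            params={"X1": (0.1, 2.0)},
        )
        assert s.energy.shape == (1,)


class TestEventSequence:
    def test_single_rupture_single_row(self):
        frames, specs = pp.make_toy_frames(
            [pp.ContactScript("a", distances=(3.0, 4.0, 4.0))]
        )
        df = pp.event_sequence([pp.contact_series(frames, specs["a"])])
        assert len(df) == 1
        assert df.loc[0, "event"] == "ruptured"

    def test_simultaneous_events_tie_broken_by_label(self):
        frames, specs = pp.make_toy_frames(
            [
                pp.ContactScript("b_contact", distances=(3.0, 4.0)),  # ruptures @1
                pp.ContactScript("a_contact", distances=(4.0, 3.0)),  # forms @1
            ]
        )
        df = pp.event_sequence(
            [
                pp.contact_series(frames, specs["b_contact"]),
                pp.contact_series(frames, specs["a_contact"]),
            ]
        )
        assert list(df["label"]) == ["a_contact", "b_contact"]
        assert list(df["event"]) == ["formed", "ruptured"]

    def test_empty_input_gives_empty_table(self):
        df = pp.event_sequence([])
        assert len(df) == 0
        assert list(df.columns) == ["time", "label", "event"]
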