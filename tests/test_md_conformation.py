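"""Trajectory observables: ion pairs, salt bridges, helix distances, RMSD."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hsp90kit.md_conformation import (
    ACIDIC_ATOMS,
    BASIC_ATOMS,
    DistanceSeries,
    IonPairDefinition,
    MissingAtomError,
    backbone_rmsd_series,
    classify_open_closed,
    com_distance,
    count_interdomain_salt_bridges,
    helix_pair_com_distances,
    ion_pair_distance_series,
    salt_bridge_series,
)
from hsp90kit.structure_io import (
    AtomRecord,
    SelectionSpec,
    StructureModel,
    Trajectory,
)
from hsp90kit.synthetic_data import (
    TwoStateParams,
    gen_salt_bridge_model,
    gen_toy_trajectory,
    gen_two_state_distance_series,
)

PAIR = IonPairDefinition("A", 590, "CD", "A", 591, "CZ")


def _atom(serial, name, resname, chain, resnum, xyz, element):
    return AtomRecord(
        serial=serial, atom_name=name, residue_name=resname, chain_id=chain,
        residue_number=resnum, coordinates=np.asarray(xyz, float), element=element,
    )


def _rigid_move(model: StructureModel, rotation: np.ndarray, shift: np.ndarray):
    return StructureModel(
        atoms=[
            AtomRecord(
                serial=a.serial, atom_name=a.atom_name, residue_name=a.residue_name,
                chain_id=a.chain_id, residue_number=a.residue_number,
                coordinates=rotation @ a.coordinates + shift, element=a.element,
            )
            for a in model.atoms
        ],
        model_index=model.model_index,
    )


class TestIonPairSeries:
    def test_constant_distance(self):
        traj = gen_toy_trajectory(np.full(5, 4.0))
        series = ion_pair_distance_series(traj, PAIR)
        np.testing.assert_allclose(series.values, 4.0, atol=1e-9)

    def test_matches_per_frame_recomputation(self):
        rng = np.random.default_rng(7)
        distances = rng.uniform(2.5, 9.0, 10)
        traj = gen_toy_trajectory(distances)
        series = ion_pair_distance_series(traj, PAIR)
        # Independent per-frame recomputation.
        for i, frame in enumerate(traj.frames):
            a = frame.find_atom("A", 590, "CD").coordinates
            b = frame.find_atom("A", 591, "CZ").coordinates
            assert np.isclose(series.values[i], float(np.linalg.norm(a - b)))
        np.testing.assert_allclose(series.values, distances, atol=1e-9)

    def test_missing_atom_names_frame(self):
        traj = gen_toy_trajectory(np.array([3.0, 4.0, 6.0, 5.0]))
        # Remove the CZ atom from frame index 3.
        frames = list(traj.frames)
        frames[3] = StructureModel(
            atoms=[a for a in frames[3].atoms if a.atom_name != "CZ"
                   or a.chain_id != "A"],
            model_index=frames[3].model_index,
        )
        bad = Trajectory.__new__(Trajectory)  # bypass identical-atom invariant
        bad.frames = frames
        bad.frame_times = traj.frame_times
        with pytest.raises(MissingAtomError, match="frame 3"):
            ion_pair_distance_series(bad, PAIR)


class TestClassifyOpenClosed:
    def test_small_example(self):
        series = DistanceSeries(times=np.arange(3.0), values=np.array([3.0, 4.0, 6.0]))
        occ = classify_open_closed(series, threshold=5.0)
        assert occ.fraction_closed == pytest.approx(2 / 3)
        assert occ.fraction_open == pytest.approx(1 / 3)
        assert occ.n_transitions == 1
        assert occ.histogram_percent.sum() == pytest.approx(100.0)

    def test_all_open(self):
        series = DistanceSeries(times=np.arange(4.0), values=np.array([6, 7, 8, 9.0]))
        assert classify_open_closed(series).fraction_closed == 0.0

    def test_boundary_value_counts_open(self):
        series = DistanceSeries(times=np.arange(2.0), values=np.array([5.0, 4.9]))
        assert classify_open_closed(series, threshold=5.0).fraction_closed == 0.5

    def test_symmetric_two_state_generator_near_half(self):
        params = TwoStateParams(
            p_close_to_open=0.1, p_open_to_close=0.1, n_steps=10_000, seed=42
        )
        series, _ = gen_two_state_distance_series(params)
        occ = classify_open_closed(series, threshold=5.0)
        # Stationary closed fraction is 1/2; allow 3 SE of the correlated chain.
        se = np.sqrt(0.25 / (10_000 * 0.1))
        assert abs(occ.fraction_closed - 0.5) < 3 * se

    @settings(deadline=None, max_examples=30)
    @given(
        seed=st.integers(0, 1000),
        t1=st.floats(2.0, 10.0),
        t2=st.floats(2.0, 10.0),
    )
    def test_fraction_closed_monotone_in_threshold(self, seed, t1, t2):
        rng = np.random.default_rng(seed)
        series = DistanceSeries(times=np.arange(50.0), values=rng.uniform(1, 12, 50))
        lo, hi = sorted((t1, t2))
        assert (
            classify_open_closed(series, lo).fraction_closed
            <= classify_open_closed(series, hi).fraction_closed
        )

    def test_empty_series_rejected(self):
        series = DistanceSeries(times=np.array([]), values=np.array([]))
        with pytest.raises(ValueError):
            classify_open_closed(series)


def _brute_force_salt_bridges(model, chain_a, chain_b, cutoff):
    """Independent enumeration over all residue pairs and charged atoms."""
    count = 0
    residues: dict = {}
    for a in model.atoms:
        residues.setdefault((a.chain_id, a.residue_number, a.residue_name), []).append(a)
    items = list(residues.items())
    for (ch1, rn1, rname1), atoms1 in items:
        for (ch2, rn2, rname2), atoms2 in items:
            if not (ch1 == chain_a and ch2 == chain_b):
                continue
            for table1, table2 in ((ACIDIC_ATOMS, BASIC_ATOMS), (BASIC_ATOMS, ACIDIC_ATOMS)):
                if rname1 not in table1 or rname2 not in table2:
                    continue
                dmin = np.inf
                for a1 in atoms1:
                    if a1.atom_name not in table1[rname1]:
                        continue
                    for a2 in atoms2:
                        if a2.atom_name not in table2[rname2]:
                            continue
                        dmin = min(dmin, np.linalg.norm(a1.coordinates - a2.coordinates))
                if dmin < cutoff:
                    count += 1
    return count


class TestSaltBridges:
    A = SelectionSpec(chain_id="A")
    B = SelectionSpec(chain_id="B")

    def test_single_bridge_within_cutoff(self):
        model = StructureModel(atoms=[
            _atom(1, "OE1", "GLU", "A", 1, (0, 0, 0), "O"),
            _atom(2, "NZ", "LYS", "B", 1, (3, 0, 0), "N"),
        ])
        assert count_interdomain_salt_bridges(model, self.A, self.B, cutoff=4.0) == 1

    def test_same_geometry_below_cutoff(self):
        model = StructureModel(atoms=[
            _atom(1, "OE1", "GLU", "A", 1, (0, 0, 0), "O"),
            _atom(2, "NZ", "LYS", "B", 1, (3, 0, 0), "N"),
        ])
        assert count_interdomain_salt_bridges(model, self.A, self.B, cutoff=2.5) == 0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_on_random_placement(self, seed):
        rng = np.random.default_rng(seed)
        atoms = []
        serial = 1
        for i in range(5):  # acidic residues, chain A
            resname = ["ASP", "GLU"][rng.integers(2)]
            base = rng.uniform(0, 15, 3)
            for name in ACIDIC_ATOMS[resname]:
                atoms.append(_atom(serial, name, resname, "A", i + 1,
                                   base + rng.uniform(-1, 1, 3), "O"))
                serial += 1
        for j in range(5):  # basic residues, chain B
            resname = ["LYS", "ARG"][rng.integers(2)]
            base = rng.uniform(0, 15, 3)
            for name in BASIC_ATOMS[resname]:
                atoms.append(_atom(serial, name, resname, "B", j + 1,
                                   base + rng.uniform(-1, 1, 3), "N"))
                serial += 1
        model = StructureModel(atoms=atoms)
        expected = _brute_force_salt_bridges(model, "A", "B", 4.0)
        assert count_interdomain_salt_bridges(model, self.A, self.B, 4.0) == expected

    def test_symmetric_in_groups_and_monotone_in_cutoff(self):
        model = gen_salt_bridge_model(n_bridged=3, seed=9)
        for cut_lo, cut_hi in [(2.0, 4.0), (4.0, 8.0)]:
            lo = count_interdomain_salt_bridges(model, self.A, self.B, cut_lo)
            hi = count_interdomain_salt_bridges(model, self.A, self.B, cut_hi)
            assert lo <= hi
        assert count_interdomain_salt_bridges(
            model, self.A, self.B, 4.0
        ) == count_interdomain_salt_bridges(model, self.B, self.A, 4.0)

    def test_fixture_count_matches_construction(self):
        model = gen_salt_bridge_model(n_bridged=2, cutoff=4.0, seed=1)
        assert count_interdomain_salt_bridges(model, self.A, self.B, 4.0) == 2

    def test_empty_group_warns_and_returns_zero(self):
        model = gen_salt_bridge_model(n_bridged=1, seed=0)
        with pytest.warns(UserWarning):
            n = count_interdomain_salt_bridges(
                model, SelectionSpec(chain_id="Z"), self.B, 4.0
            )
        assert n == 0

    def test_series_over_trajectory(self):
        model = gen_salt_bridge_model(n_bridged=2, seed=3)
        traj = Trajectory(frames=[model, model], frame_times=np.array([0.0, 0.1]))
        series = salt_bridge_series(traj, self.A, self.B, cutoff=4.0)
        assert list(series.counts) == [2, 2]


class TestHelixPairDistances:
    def test_single_atom_helices(self):
        model = StructureModel(atoms=[
            _atom(1, "CA", "ALA", "A", 1, (0, 0, 0), "C"),
            _atom(2, "CA", "ALA", "B", 1, (10, 0, 0), "C"),
        ])
        traj = Trajectory(frames=[model], frame_times=np.array([0.0]))
        result = helix_pair_com_distances(
            traj,
            {"H1": (SelectionSpec(chain_id="A"), SelectionSpec(chain_id="B"))},
        )
        np.testing.assert_allclose(result.pairs["H1"].values, [10.0])

    def test_rigid_motion_invariance_and_recomputation(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(12)
        atoms = [
            _atom(i + 1, "CA", "ALA", "AB"[i % 2], i + 1, rng.uniform(-20, 20, 3), "C")
            for i in range(12)
        ]
        model = StructureModel(atoms=atoms)
        rot = Rotation.random(random_state=np.random.RandomState(3)).as_matrix()
        moved = _rigid_move(model, rot, np.array([4.0, -7.0, 2.0]))
        traj = Trajectory(frames=[model, moved], frame_times=np.array([0.0, 0.1]))
        spec_a, spec_b = SelectionSpec(chain_id="A"), SelectionSpec(chain_id="B")
        result = helix_pair_com_distances(traj, {"H": (spec_a, spec_b)})
        # Invariance under rigid motion of the whole frame.
        assert np.isclose(result.pairs["H"].values[0], result.pairs["H"].values[1],
                          atol=1e-8)
        # Independent COM + distance recomputation (unit masses irrelevant:
        # single-element selection).
        coords_a = np.array([a.coordinates for a in atoms if a.chain_id == "A"])
        coords_b = np.array([a.coordinates for a in atoms if a.chain_id == "B"])
        expected = np.linalg.norm(coords_a.mean(axis=0) - coords_b.mean(axis=0))
        assert np.isclose(result.pairs["H"].values[0], expected, atol=1e-9)
        assert np.isclose(com_distance(model, spec_a, spec_b), expected, atol=1e-9)


class TestBackboneRMSD:
    def _backbone_model(self, rng, n_res=10, perturb=None):
        atoms = []
        serial = 1
        coords = rng.uniform(-30, 30, (n_res, 4, 3))
        if perturb is not None:
            coords = coords + perturb
        for i in range(n_res):
            for j, name in enumerate(["N", "CA", "C", "O"]):
                atoms.append(_atom(serial, name, "ALA", "A", i + 1, coords[i, j],
                                   name[0]))
                serial += 1
        return StructureModel(atoms=atoms)

    def test_reference_vs_itself_and_rigid_copy(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(21)
        model = self._backbone_model(rng)
        rot = Rotation.random(random_state=np.random.RandomState(8)).as_matrix()
        moved = _rigid_move(model, rot, np.array([1.0, 2.0, 3.0]))
        traj = Trajectory(frames=[model, moved], frame_times=np.array([0.0, 0.1]))
        series = backbone_rmsd_series(traj, reference_frame=0)
        assert series.values[0] < 1e-10
        assert series.values[1] < 1e-8

    def test_single_displaced_atom_bounded_by_closed_form(self):
        rng = np.random.default_rng(22)
        model = self._backbone_model(rng, n_res=25)
        n_atoms = len(model.atoms)
        d = 2.0
        displaced_atoms = list(model.atoms)
        a = displaced_atoms[7]
        displaced_atoms[7] = _atom(a.serial, a.atom_name, a.residue_name, a.chain_id,
                                   a.residue_number, a.coordinates + [d, 0, 0],
                                   a.element)
        displaced = StructureModel(atoms=displaced_atoms)
        traj = Trajectory(frames=[model, displaced], frame_times=np.array([0.0, 0.1]))
        rmsd = backbone_rmsd_series(traj, reference_frame=0).values[1]
        bound = d / np.sqrt(n_atoms)  # RMSD without superposition
        assert 0 < rmsd <= bound + 1e-12
        assert rmsd > 0.8 * bound  # superposition barely helps for a wide cloud
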