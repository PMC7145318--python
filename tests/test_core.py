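import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import min_image_vector_27
from hydromix import synth
from hydromix.core import (Box, Composition, Frame, Topology, Trajectory,
                           TrajectoryParseError, composition_builder,
                           minimum_image_displacement, read_topology,
                           read_trajectory, select_sites, write_topology,
                           write_trajectory, M_THAL, M_WATER)


class TestMinimumImage:
    def test_wrap_case(self):
        box = Box((10.0, 10.0, 10.0))
        d = minimum_image_displacement([1.0, 0, 0], [9.0, 0, 0], box)
        assert np.linalg.norm(d) == pytest.approx(2.0)

    def test_identity(self):
        box = Box((7.0, 8.0, 9.0))
        a = np.array([3.0, 4.0, 5.0])
        assert np.allclose(minimum_image_displacement(a, a, box), 0.0)

    def test_components_in_half_open_cell(self, rng):
        box = Box((12.0, 20.0, 6.0))
        a = rng.uniform(-50, 50, (200, 3))
        b = rng.uniform(-50, 50, (200, 3))
        d = minimum_image_displacement(a, b, box)
        assert np.all(d >= -box.array / 2)
        assert np.all(d < box.array / 2)

    def test_matches_27_image_brute_force(self, rng):
        box = Box((20.0, 20.0, 20.0))
        for _ in range(1000):
            a = rng.uniform(-30, 50, 3)
            b = rng.uniform(-30, 50, 3)
            got = minimum_image_displacement(a, b, box)
            ref = min_image_vector_27(a, b, box.lengths)
            assert np.linalg.norm(got) == pytest.approx(np.linalg.norm(ref),
                                                        abs=1e-10)

    @given(st.floats(4.0, 100.0), st.floats(4.0, 100.0), st.floats(4.0, 100.0),
           st.lists(st.floats(-200, 200), min_size=6, max_size=6))
    @settings(max_examples=50, deadline=None)
    def test_brute_force_property(self, lx, ly, lz, vals):
        box = Box((lx, ly, lz))
        a, b = np.array(vals[:3]), np.array(vals[3:])
        got = np.linalg.norm(minimum_image_displacement(a, b, box))
        ref = np.linalg.norm(min_image_vector_27(a, b, box.lengths))
        assert got == pytest.approx(ref, abs=1e-8)

    def test_non_finite_rejected(self):
        box = Box((10.0, 10.0, 10.0))
        with pytest.raises(ValueError):
            minimum_image_displacement([np.nan, 0, 0], [0, 0, 0], box)

    def test_invalid_box(self):
        with pytest.raises(ValueError):
            Box((0.0, 10.0, 10.0))
        with pytest.raises(ValueError):
            Box((-1.0, 10.0, 10.0))


class TestComposition:
    def test_pure_water(self):
        comp = composition_builder(1500, 0.0)
        assert comp.n_thal == 0
        assert comp.omega == 0.0

    def test_top_of_grid(self):
        # independent evaluation of the rounding formula
        expected = round(1500 * M_WATER * 0.760 / (M_THAL * (1 - 0.760)))
        comp = composition_builder(1500, 0.760)
        assert comp.n_thal == expected == 250
        recomputed = 250 * M_THAL / (250 * M_THAL + 1500 * M_WATER)
        assert comp.omega == pytest.approx(recomputed)
        assert round(comp.omega, 3) == 0.760

    def test_low_fraction(self):
        assert composition_builder(1500, 0.112).n_thal == 10

    def test_omega_one_rejected(self):
        with pytest.raises(ValueError):
            composition_builder(1500, 1.0)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            composition_builder(0, 0.5)
        with pytest.raises(ValueError):
            composition_builder(1500, -0.1)

    @given(st.lists(st.floats(0.0, 0.99), min_size=2, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_target(self, targets):
        counts = [composition_builder(1500, w).n_thal for w in sorted(targets)]
        assert counts == sorted(counts)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            Composition(n_water=-1, n_thal=0)


class TestTopology:
    def test_thal_multiplicity_enforced(self, thal_tmpl):
        # drop the bridging oxygen -> invariant violation
        keep = [i for i, lab in enumerate(thal_tmpl.labels) if lab != "Ob"]
        with pytest.raises(ValueError, match="label counts"):
            Topology(
                element=[thal_tmpl.elements[i] for i in keep],
                site_label=[thal_tmpl.labels[i] for i in keep],
                molecule_id=[0] * len(keep),
                molecule_type=["THAL"] * len(keep),
                mass=[thal_tmpl.masses[i] for i in keep],
                charge=[0.0] * len(keep),
                lj_sigma=[0.0] * len(keep),
                lj_epsilon=[0.0] * len(keep),
            )

    def test_water_labels_only_on_water(self):
        with pytest.raises(ValueError, match="WATER"):
            Topology(element=["O"], site_label=["Ow"], molecule_id=[0],
                     molecule_type=["THAL"], mass=[16.0], charge=[0.0],
                     lj_sigma=[0.0], lj_epsilon=[0.0])

    def test_positive_mass_required(self):
        with pytest.raises(ValueError):
            Topology(element=["X"], site_label=["X"], molecule_id=[0],
                     molecule_type=["OTHER"], mass=[0.0], charge=[0.0],
                     lj_sigma=[0.0], lj_epsilon=[0.0])

    def test_sidecar_round_trip(self, tmp_path, small_gas_traj):
        path = tmp_path / "top.tsv"
        write_topology(small_gas_traj.topology, path)
        assert read_topology(path) == small_gas_traj.topology


class TestSelectSites:
    def test_one_ow_per_water(self):
        traj = synth.generate_gas_configuration(
            {"WATER": 1500}, Box((120.0, 120.0, 120.0)), seed=1)
        assert len(select_sites(traj.topology, "WATER", {"Ow"})) == 1500

    def test_two_o1_per_thal(self):
        traj = synth.generate_gas_configuration(
            {"THAL": 10}, Box((80.0, 80.0, 80.0)), seed=2)
        idx = select_sites(traj.topology, "THAL", {"O1"})
        assert len(idx) == 20
        assert np.all(np.diff(idx) > 0)

    def test_unknown_label_lists_valid_tokens(self, small_gas_traj):
        with pytest.raises(ValueError, match="valid labels"):
            select_sites(small_gas_traj.topology, "THAL", {"Zz"})

    def test_empty_selection_ok(self, small_gas_traj):
        assert len(select_sites(small_gas_traj.topology, "WATER", {"O1"})) == 0


class TestTrajectoryModel:
    def test_times_strictly_increasing(self, water_tmpl, small_gas_traj):
        frames = [Frame(0.0, small_gas_traj.frames[0].box,
                        small_gas_traj.frames[0].coordinates),
                  Frame(0.0, small_gas_traj.frames[0].box,
                        small_gas_traj.frames[0].coordinates)]
        with pytest.raises(ValueError, match="strictly increasing"):
            Trajectory(topology=small_gas_traj.topology, frames=frames)

    def test_atom_count_mismatch(self, small_gas_traj):
        with pytest.raises(ValueError, match="atoms"):
            Trajectory(topology=small_gas_traj.topology,
                       frames=[Frame(0.0, Box((10, 10, 10)), np.zeros((2, 3)))])


class TestTrajectoryIO:
    def _two_frame_traj(self):
        traj = synth.generate_gas_configuration(
            {"WATER": 5}, Box((15.0, 15.0, 15.0)), seed=3, n_frames=2)
        return traj

    def test_xyz_round_trip_exact(self, tmp_path):
        traj = self._two_frame_traj()
        path = tmp_path / "t.xyz"
        write_trajectory(traj, path, "xyz")
        back = read_trajectory(path, "xyz", traj.topology)
        assert back.n_frames == 2
        for a, b in zip(traj.frames, back.frames):
            assert np.allclose(a.coordinates, b.coordinates, atol=1e-8)
            assert a.box.lengths == b.box.lengths
            assert a.time == pytest.approx(b.time)

    def test_ten_frame_round_trip(self, tmp_path):
        traj = synth.generate_brownian_trajectory(
            {"A": 4}, {"A": 0.1}, 0.5, 9, Box((20, 20, 20)), seed=4)
        path = tmp_path / "b.xyz"
        write_trajectory(traj, path, "xyz")
        back = read_trajectory(path, "xyz", traj.topology)
        assert back.n_frames == 10
        for a, b in zip(traj.frames, back.frames):
            assert np.allclose(a.coordinates, b.coordinates, atol=1e-7)
            assert b.unwrapped is not None
            assert np.allclose(a.unwrapped, b.unwrapped, atol=1e-7)

    def test_pdb_cryst1(self, tmp_path):
        traj = self._two_frame_traj()
        path = tmp_path / "t.pdb"
        write_trajectory(traj, path, "pdb")
        back = read_trajectory(path, "pdb", traj.topology)
        assert back.frames[0].box.lengths == (15.0, 15.0, 15.0)
        assert np.allclose(back.frames[0].coordinates,
                           traj.frames[0].coordinates, atol=1e-3)

    def test_atom_count_mismatch_names_frame(self, tmp_path):
        traj = self._two_frame_traj()
        path = tmp_path / "t.xyz"
        write_trajectory(traj, path, "xyz")
        bigger = synth.generate_gas_configuration(
            {"WATER": 6}, Box((15.0, 15.0, 15.0)), seed=3).topology
        with pytest.raises(TrajectoryParseError, match="frame 0"):
            read_trajectory(path, "xyz", bigger)

    def test_missing_box_record(self, tmp_path, water_tmpl):
        path = tmp_path / "nobox.xyz"
        path.write_text("1\nno box here\nX 0 0 0\n")
        top = Topology(element=["X"], site_label=["X"], molecule_id=[0],
                       molecule_type=["OTHER"], mass=[1.0], charge=[0.0],
                       lj_sigma=[0.0], lj_epsilon=[0.0])
        with pytest.raises(TrajectoryParseError, match="box"):
            read_trajectory(path, "xyz", top)

    def test_malformed_line_reported(self, tmp_path):
        path = tmp_path / "bad.xyz"
        path.write_text('1\nbox="10 10 10"\nX 0 zero 0\n')
        top = Topology(element=["X"], site_label=["X"], molecule_id=[0],
                       molecule_type=["OTHER"], mass=[1.0], charge=[0.0],
                       lj_sigma=[0.0], lj_epsilon=[0.0])
        with pytest.raises(TrajectoryParseError, match="line 3"):
            read_trajectory(path, "xyz", top)

    def test_empty_trajectory(self, tmp_path, small_gas_traj):
        traj = Trajectory(topology=small_gas_traj.topology, frames=[])
        path = tmp_path / "empty.xyz"
        write_trajectory(traj, path, "xyz")
        assert read_trajectory(path, "xyz", traj.topology).n_frames == 0

    def test_single_water_three_atom_lines(self, tmp_path):
        traj = synth.generate_gas_configuration(
            {"WATER": 1}, Box((10, 10, 10)), seed=0)
        path = tmp_path / "w.xyz"
        write_trajectory(traj, path, "xyz")
        lines = path.read_text().splitlines()
        assert lines[0].strip() == "3"
        assert len(lines) == 5

    def test_unwritable_path(self, small_gas_traj):
        with pytest.raises(OSError):
            write_trajectory(small_gas_traj, "/nonexistent-dir/x.xyz", "xyz")

    def test_generator_outputs_round_trip(self, tmp_path, hydrated_traj):
        path = tmp_path / "h.xyz"
        write_trajectory(hydrated_traj, path, "xyz")
        back = read_trajectory(path, "xyz", hydrated_traj.topology)
        assert np.allclose(back.frames[0].coordinates,
                           hydrated_traj.frames[0].coordinates, atol=1e-7)
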