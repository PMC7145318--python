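import numpy as np
import pytest
from scipy import stats

from _oracles import dihedral_textbook, min_image_distance_27
from hydromix import structure, synth
from hydromix.core import Box, Frame, Topology, Trajectory, select_sites


def _point_topology(n, molecule_type="GAS"):
    return Topology(
        element=["X"] * n, site_label=["X"] * n,
        molecule_id=list(range(n)), molecule_type=[molecule_type] * n,
        mass=[1.0] * n, charge=[0.0] * n,
        lj_sigma=[0.0] * n, lj_epsilon=[0.0] * n)


class TestRDF:
    def test_two_particles_single_bin(self):
        top = _point_topology(2)
        frame = Frame(0.0, Box((100, 100, 100)),
                      np.array([[10.0, 10, 10], [15.0, 10, 10]]))
        traj = Trajectory(top, [frame])
        res = structure.compute_rdf(traj, np.array([0]), np.array([1]),
                                    r_max=10.0, bin_width=0.05)
        occupied = np.flatnonzero(res.g > 0)
        assert len(occupied) == 1
        # 5.0 sits on a half-open bin edge; either adjacent bin is acceptable
        assert abs(res.r[occupied[0]] - 5.0) <= 0.5 * res.bin_width + 1e-9

    def test_ideal_gas_flat(self):
        traj = synth.generate_gas_configuration(
            {"GAS": 1000}, Box((60, 60, 60)), seed=1, n_frames=10)
        idx = select_sites(traj.topology, "GAS", {"X"})
        res = structure.compute_rdf(traj, idx, idx, r_max=10.0, bin_width=0.2)
        sel = res.r >= 3.0
        assert np.max(np.abs(res.g[sel] - 1.0)) < 0.05
        # mean within 3 standard errors of 1
        n_eff = res.g[sel].size
        assert abs(res.g[sel].mean() - 1.0) < 3 * res.g[sel].std() / np.sqrt(n_eff)

    def test_running_integral_analytic_ideal_gas(self):
        # clash distance 0: true ideal gas, N(r) = rho * 4/3 pi r^3
        traj = synth.generate_gas_configuration(
            {"GAS": 800}, Box((50, 50, 50)), seed=2, n_frames=10,
            min_distance=0.0)
        idx = select_sites(traj.topology, "GAS", {"X"})
        res = structure.compute_rdf(traj, idx, idx, r_max=8.0, bin_width=0.1)
        for r_cut in (4.0, 6.0):
            expected = res.rho_b * 4.0 / 3.0 * np.pi * r_cut ** 3
            got = structure.compute_running_integral(res, r_cut)
            assert got == pytest.approx(expected, rel=0.05)

    def test_hydrated_fixture_n_is_two(self, hydrated_traj):
        top = hydrated_traj.topology
        ow = select_sites(top, "WATER", {"Ow"})
        for lab in ("O1", "O2", "O3", "O4"):
            oh = select_sites(top, "THAL", {lab})
            res = structure.compute_rdf(hydrated_traj, oh, ow, r_max=6.0)
            n = structure.compute_running_integral(res, 3.5)
            assert n == pytest.approx(2.0, abs=0.01)
            # cross-check against direct neighbour counting
            fr = hydrated_traj.frames[0]
            count = 0
            for i in oh:
                for j in ow:
                    if min_image_distance_27(fr.coordinates[i],
                                             fr.coordinates[j],
                                             fr.box.lengths) <= 3.5:
                        count += 1
            assert n == pytest.approx(count / len(oh), abs=0.01)

    def test_zero_cut_is_zero(self, hydrated_traj):
        top = hydrated_traj.topology
        res = structure.compute_rdf(hydrated_traj,
                                    select_sites(top, "THAL", {"O1"}),
                                    select_sites(top, "WATER", {"Ow"}),
                                    r_max=6.0)
        assert structure.compute_running_integral(res, 0.0) == 0.0
        with pytest.raises(ValueError):
            structure.compute_running_integral(res, 7.0)

    def test_r_max_validation(self, hydrated_traj):
        top = hydrated_traj.topology
        with pytest.raises(ValueError, match="half"):
            structure.compute_rdf(hydrated_traj,
                                  select_sites(top, "THAL", {"O1"}),
                                  select_sites(top, "WATER", {"Ow"}),
                                  r_max=40.0)

    def test_empty_selection_rejected(self, hydrated_traj):
        with pytest.raises(ValueError, match="empty"):
            structure.compute_rdf(hydrated_traj, np.array([], int),
                                  np.array([0]), r_max=6.0)

    def test_n_monotone(self, hydrated_traj):
        top = hydrated_traj.topology
        res = structure.compute_rdf(hydrated_traj,
                                    select_sites(top, "THAL", {"O1"}),
                                    select_sites(top, "WATER", {"Ow"}),
                                    r_max=6.0)
        assert np.all(np.diff(res.n_r) >= -1e-12)
        assert np.all(res.g >= 0)


class TestSDF:
    def test_isotropic_shell(self):
        # one reference molecule, targets on a 2.8 Å sphere around its centroid
        thal = synth.pseudo_trehalose_template()
        rng = np.random.default_rng(3)
        n_t = 400
        v = rng.standard_normal((n_t, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        labels = list(thal.labels)
        align = ["C1@1", "C3@1", "C5@1", "C1@2", "C3@2", "C5@2"]
        align_idx = []
        seen = {}
        for i, lab in enumerate(labels):
            seen.setdefault(lab, []).append(i)
        for a in align:
            base, k = a.split("@")
            align_idx.append(seen[base][int(k) - 1])
        centroid = thal.coords[align_idx].mean(axis=0)
        targets = centroid + 2.8 * v

        top_df_cols = dict(
            element=list(thal.elements) + ["X"] * n_t,
            site_label=list(thal.labels) + ["X"] * n_t,
            molecule_id=[0] * thal.n_atoms + list(range(1, n_t + 1)),
            molecule_type=["THAL"] * thal.n_atoms + ["OTHER"] * n_t,
            mass=list(thal.masses) + [1.0] * n_t,
            charge=list(thal.charges) + [0.0] * n_t,
            lj_sigma=list(thal.lj_sigma) + [0.0] * n_t,
            lj_epsilon=list(thal.lj_epsilon) + [0.0] * n_t)
        top = Topology(**top_df_cols)
        coords = np.vstack([thal.coords, targets]) + 30.0
        traj = Trajectory(top, [Frame(0.0, Box((60, 60, 60)), coords)])
        tgt = np.arange(thal.n_atoms, thal.n_atoms + n_t)
        res = structure.compute_sdf(traj, "THAL", align, tgt,
                                    grid_spacing=0.4, extent=6.0)
        assert res.total_mass == pytest.approx(n_t, rel=0.01)
        # mass concentrated in the shell 2.8 ± spacing
        nz = np.argwhere(res.density > 0)
        centers = res.origin + (nz + 0.5) * res.spacing
        radii = np.linalg.norm(centers, axis=1)
        assert np.all(np.abs(radii - 2.8) < 2.5 * res.spacing)

    def test_targets_near_o1(self, hydrated_traj):
        top = hydrated_traj.topology
        ow = select_sites(top, "WATER", {"Ow"})
        align = ["C1@1", "C3@1", "C5@1", "C1@2", "C3@2", "C5@2"]
        res = structure.compute_sdf(hydrated_traj, "THAL", align, ow,
                                    grid_spacing=0.5, extent=10.0)
        # top-decile voxels must lie within 3.5 Å of a hydroxyl-oxygen body
        # position (waters were constructed 2.8 Å from those sites); the body
        # frame is that of the first reference molecule in the first frame
        fr = hydrated_traj.frames[0]
        labels = top.site_label.astype(str)
        mol0 = np.flatnonzero(top.molecule_id == 0)
        align_idx = []
        for a in align:
            base, k = a.split("@")
            matches = [i for i in mol0 if labels[i] == base]
            align_idx.append(matches[int(k) - 1])
        centroid = fr.coordinates[align_idx].mean(axis=0)
        oh_atoms = [i for i in mol0 if labels[i] in ("O1", "O2", "O3", "O4")]
        oh_body = fr.coordinates[oh_atoms] - centroid
        vals = res.density[res.density > 0]
        thresh = np.quantile(vals, 0.9)
        nz = np.argwhere(res.density >= thresh)
        centers = res.origin + (nz + 0.5) * res.spacing
        d = np.linalg.norm(centers[:, None, :] - oh_body[None, :, :], axis=-1)
        assert np.all(d.min(axis=1) < 3.5)

    def test_empty_targets_zero_grid(self, hydrated_traj):
        align = ["C1@1", "C3@1", "C5@1"]
        res = structure.compute_sdf(hydrated_traj, "THAL", align,
                                    np.array([], int), grid_spacing=0.5,
                                    extent=5.0)
        assert res.density.sum() == 0.0

    def test_collinear_alignment_rejected(self):
        top = _point_topology(3, "ROW")
        # one "molecule" of three collinear atoms
        top = Topology(element=["C", "C", "C"], site_label=["C1", "C2", "C3"],
                       molecule_id=[0, 0, 0], molecule_type=["ROW"] * 3,
                       mass=[12.0] * 3, charge=[0.0] * 3,
                       lj_sigma=[0.0] * 3, lj_epsilon=[0.0] * 3)
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]]) + 10.0
        traj = Trajectory(top, [Frame(0.0, Box((20, 20, 20)), coords)])
        with pytest.raises(ValueError, match="collinear"):
            structure.compute_sdf(traj, "ROW", ["C1", "C2", "C3"],
                                  np.array([], int))


class TestCDF:
    def test_aligned_molecules_zero_angle(self):
        traj = synth.generate_clustered_configuration(
            [6], 6.0, Box((50, 50, 50)), seed=4)   # identical orientations
        res = structure.compute_cdf_distance_angle(
            traj, ("Ob", "Ob"), ("C2@1", "C5@1"), ("C2@1", "C5@1"),
            r_max=24.0, bins=(24, 45), collect_samples=True)
        assert np.all(res.samples[:, 1] < 2.0)

    def test_isotropic_sin_marginal(self):
        traj = synth.generate_gas_configuration(
            {"THAL": 40}, Box((42, 42, 42)), seed=5, n_frames=5,
            min_distance=1.5)
        res = structure.compute_cdf_distance_angle(
            traj, ("Ob", "Ob"), ("C2@1", "C5@1"), ("C2@1", "C5@1"),
            r_max=20.9, bins=(40, 45), collect_samples=True)
        ks = stats.kstest(res.samples[:, 1],
                          lambda x: 1.0 - np.cos(np.radians(x)))
        assert ks.pvalue > 0.01

    def test_marginals_integrate_to_one(self, hydrated_traj):
        res = structure.compute_cdf_distance_angle(
            hydrated_traj, ("Ob", "Ob"), ("C2@1", "C5@1"), ("C2@1", "C5@1"),
            r_max=28.0, bins=(30, 30))
        dr = np.diff(res.r_edges)
        dphi = np.diff(res.phi_edges)
        assert (res.r_marginal * dr).sum() == pytest.approx(1.0, abs=1e-9)
        assert (res.phi_marginal * dphi).sum() == pytest.approx(1.0, abs=1e-9)

    def test_r_marginal_peaks_match_rdf(self):
        traj = synth.generate_clustered_configuration(
            [6], 6.0, Box((50, 50, 50)), seed=4)
        res = structure.compute_cdf_distance_angle(
            traj, ("Ob", "Ob"), ("C2@1", "C5@1"), ("C2@1", "C5@1"),
            r_max=24.0, bins=(96, 18))
        ob = select_sites(traj.topology, "THAL", {"Ob"})
        rdf = structure.compute_rdf(traj, ob, ob, r_max=24.0, bin_width=0.25)
        rc = 0.5 * (res.r_edges[:-1] + res.r_edges[1:])
        cdf_peak = rc[np.argmax(res.r_marginal)]
        rdf_peak = rdf.r[np.argmax(rdf.g)]
        assert abs(cdf_peak - rdf_peak) <= 0.5


class TestDihedral:
    def _traj_with_dihedral(self, angle):
        tmpl = synth.pseudo_trehalose_template(dihedral_deg=angle)
        traj = synth.generate_gas_configuration(
            {"THAL": 8}, Box((60, 60, 60)), seed=6,
            templates={"THAL": tmpl})
        return traj

    def test_planar_cis(self):
        res = structure.compute_dihedral_distribution(
            self._traj_with_dihedral(0.0))
        assert abs(res.circular_mean) < 1.0

    def test_planar_trans(self):
        res = structure.compute_dihedral_distribution(
            self._traj_with_dihedral(180.0))
        assert abs(abs(res.circular_mean) - 180.0) < 1.0

    def test_mode_at_construction_angle(self):
        res = structure.compute_dihedral_distribution(
            self._traj_with_dihedral(140.0), bin_width=2.0)
        mode = res.bin_centers[np.argmax(res.density)]
        assert abs(mode - 140.0) <= 2.0
        assert res.circular_std < 1.0

    def test_matches_textbook_oracle(self, rng):
        for _ in range(50):
            pts = rng.standard_normal((4, 3)) * 3.0
            got = synth.signed_dihedral(*pts)
            ref = dihedral_textbook(*pts)
            assert got == pytest.approx(ref, abs=1e-9)

    def test_ambiguous_label_rejected(self, hydrated_traj):
        with pytest.raises(ValueError, match="qualify"):
            structure.compute_dihedral_distribution(
                hydrated_traj, ("Oe", "C1@1", "Ob", "C1@2"))

    def test_rotation_invariance(self):
        # dihedral is invariant under rigid rotation of the whole molecule
        traj1 = self._traj_with_dihedral(100.0)
        res = structure.compute_dihedral_distribution(traj1)
        assert abs(res.circular_mean - 100.0) < 1.0
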