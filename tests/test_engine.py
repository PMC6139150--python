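import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import ALA_ATOMS, GLY_ATOMS, make_residue_model
from ddflex import engine
from ddflex.engine import (ConstraintSet, aggregate_damper_strength,
                           assemble_dampers, backbone_rmsd,
                           build_sse_constraints, coarse_grain, map_force,
                           overlap_percent, rms_velocity, rmsd, step)
from ddflex.grid_io import DensityMap


class TestCoarseGrain:
    def test_ala_gives_five_pseudo_atoms(self):
        cm = coarse_grain(make_residue_model([("A", 1, "ALA", ALA_ATOMS)]))
        assert cm.n_atoms == 5
        assert sorted(cm.names) == ["C", "CA", "N", "O", "SC"]
        # ALA side chain is CB itself
        sc = cm.positions[cm.names == "SC"][0]
        np.testing.assert_allclose(sc, [2.0, -0.8, 1.2])

    def test_gly_has_no_side_chain(self):
        cm = coarse_grain(make_residue_model([("A", 1, "GLY", GLY_ATOMS)]))
        assert cm.n_atoms == 4

    def test_mass_conservation(self):
        model = make_residue_model([("A", 1, "ALA", ALA_ATOMS)])
        cm = coarse_grain(model)
        assert cm.weights.sum() == pytest.approx(model.atoms["mass"].sum(),
                                                 abs=0.01)

    def test_covalent_pairs_span_consecutive_residues(self, hinge_small):
        cm = coarse_grain(hinge_small.start)
        # N-CA, CA-C, C-O, CA-SC, N-C per residue, plus C-N / CA-N links
        assert len(cm.bonded_pairs) > 5 * (cm.n_atoms // 5)
        d = np.linalg.norm(cm.positions[cm.bonded_pairs[:, 0]]
                           - cm.positions[cm.bonded_pairs[:, 1]], axis=1)
        # local scale only (the idealized fixture has stretched inter-domain
        # junctions; constraints freeze whatever the current geometry is)
        assert d.max() < 7.0


class TestDampers:
    def test_single_edge_strength(self):
        net = assemble_dampers(np.array([[0.0, 0, 0], [4.0, 0, 0]]), d_cut=5.0)
        assert net.n_edges == 1
        assert net.strengths[0] == pytest.approx(0.5)  # 1/sqrt(4)
        assert aggregate_damper_strength(net) == pytest.approx(0.5)

    def test_cutoff_excludes_longer_pairs(self):
        net = assemble_dampers(np.array([[0.0, 0, 0], [5.1, 0, 0]]), d_cut=5.0)
        assert net.n_edges == 0
        assert aggregate_damper_strength(net) == 0.0

    def test_matrix_is_symmetric_psd(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 15, size=(40, 3))
        net = assemble_dampers(pts, d_cut=8.0)
        b = net.matrix
        assert (b - b.T).nnz == 0 or abs(b - b.T).max() < 1e-12
        for x in rng.normal(size=(1000, b.shape[0])):
            assert x @ (b @ x) >= -1e-10

    def test_edge_count_scales_cubically(self):
        rng = np.random.default_rng(42)
        pts = rng.uniform(0, 80.0, size=(4096, 3))
        dcuts = np.array([6.0, 8.0, 10.0, 12.0, 14.0])
        counts = [assemble_dampers(pts, d).n_edges for d in dcuts]
        slope = np.polyfit(np.log(dcuts), np.log(counts), 1)[0]
        assert slope == pytest.approx(3.0, abs=0.3)

    def test_aggregate_strength_scales_as_five_halves(self):
        rng = np.random.default_rng(42)
        pts = rng.uniform(0, 80.0, size=(4096, 3))
        dcuts = np.array([6.0, 8.0, 10.0, 12.0, 14.0])
        aggs = [aggregate_damper_strength(assemble_dampers(pts, d))
                for d in dcuts]
        slope = np.polyfit(np.log(dcuts), np.log(aggs), 1)[0]
        assert slope == pytest.approx(2.5, abs=0.3)


def ramp_map(n=21):
    vals = np.tile(np.arange(n, dtype=float), (n, n, 1))  # increases along x
    return DensityMap(vals, origin=[-(n - 1) / 2] * 3, voxel_size=[1, 1, 1])


class TestMapForce:
    def test_constant_field_gives_zero_force(self):
        m = DensityMap(np.full((9, 9, 9), 2.5), [-4, -4, -4], [1, 1, 1])
        f = map_force(np.zeros((3, 3)), m)
        assert np.all(f == 0)

    def test_linear_ramp_gives_uniform_x_force(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(-5, 5, size=(20, 3))
        f = map_force(pos, ramp_map(), gamma=1.0)
        np.testing.assert_allclose(f, np.tile([1.0, 0.0, 0.0], (20, 1)),
                                   atol=1e-9)

    def test_gaussian_blob_attracts_toward_peak(self):
        n = 31
        ax = np.arange(n) - 15.0
        zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
        blob = np.exp(-(xx**2 + yy**2 + zz**2) / (2 * 16.0))
        m = DensityMap(blob, origin=[-15, -15, -15], voxel_size=[1, 1, 1])
        rng = np.random.default_rng(7)
        offsets = rng.uniform(-8, 8, size=(100, 3))
        forces = map_force(offsets, m)
        inner = (forces * (-offsets)).sum(axis=1)  # toward the peak at 0
        assert np.all(inner > 0)

    def test_outside_atoms_get_zero_force(self):
        f = map_force(np.array([[100.0, 0, 0]]), ramp_map())
        assert np.all(f == 0)


class TestStep:
    def test_free_atom_identity_solve(self):
        pos = np.zeros((1, 3))
        res = step(pos, assemble_dampers(pos, 5.0), ConstraintSet.empty(),
                   np.array([[0.0, 0.0, 2.0]]), epsilon=1.0)
        np.testing.assert_allclose(res.velocities, [[0.0, 0.0, 2.0]])

    def test_two_atom_constrained_kkt(self):
        # equal and opposite pulling forces along the constrained axis:
        # the multiplier takes the load and both velocities vanish
        pos = np.array([[4.0, 0, 0], [0.0, 0, 0]])
        cons = ConstraintSet.from_pairs([[0, 1]], pos)
        forces = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        res = step(pos, assemble_dampers(pos, 3.0), cons, forces, epsilon=1.0)
        assert res.multipliers[0] == pytest.approx(-0.25, abs=1e-12)
        assert np.abs(res.velocities).max() < 1e-12

    def test_dissipativity(self, hinge_small):
        cm = coarse_grain(hinge_small.start)
        cons = ConstraintSet.from_pairs(cm.bonded_pairs, cm.positions)
        rng = np.random.default_rng(2)
        pos = cm.positions
        for _ in range(5):
            forces = rng.normal(size=pos.shape)
            dampers = assemble_dampers(pos, 10.0, exclude_pairs=cons.pairs)
            res = step(pos, dampers, cons, forces, epsilon=0.05)
            assert (res.velocities.ravel() @ forces.ravel()) >= -1e-9
            pos = res.positions

    def test_constraint_rates_vanish(self, hinge_small):
        cm = coarse_grain(hinge_small.start)
        cons = ConstraintSet.from_pairs(cm.bonded_pairs, cm.positions)
        forces = np.random.default_rng(3).normal(size=cm.positions.shape)
        dampers = assemble_dampers(cm.positions, 10.0, exclude_pairs=cons.pairs)
        res = step(cm.positions, dampers, cons, forces, epsilon=0.05,
                   project_constraints=False)
        jac = cons.jacobian(cm.positions)
        rate = np.abs(jac @ res.velocities.ravel()).max()
        assert rate < 1e-9 * np.linalg.norm(res.velocities)

    def test_constraint_preservation_driven_trajectory(self, hinge_small):
        cm = coarse_grain(hinge_small.start)
        cons = ConstraintSet.from_pairs(cm.bonded_pairs, cm.positions)
        rng = np.random.default_rng(0)
        pos = cm.positions.copy()
        for _ in range(1000):
            forces = rng.normal(size=pos.shape)
            dampers = assemble_dampers(pos, 8.0, exclude_pairs=cons.pairs)
            pos = step(pos, dampers, cons, forces, epsilon=0.01).positions
        assert cons.violations(pos).max() < 1e-4

    def test_translation_equivariance(self, hinge_small):
        cm = coarse_grain(hinge_small.start)
        cons = ConstraintSet.from_pairs(cm.bonded_pairs, cm.positions)
        n = 25
        ax = np.arange(n) * 2.0
        zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
        centre = cm.positions.mean(axis=0)
        blob = np.exp(-(((xx - centre[0])**2 + (yy - centre[1])**2
                         + (zz - centre[2])**2)) / 200.0)
        shift = np.array([5.0, -4.0, 3.0])
        out = []
        for dx in (np.zeros(3), shift):
            m = DensityMap(blob, origin=dx, voxel_size=[2, 2, 2])
            pos = cm.positions + dx
            forces = map_force(pos, m)
            dampers = assemble_dampers(pos, 10.0, exclude_pairs=cons.pairs)
            res = step(pos, dampers, cons, forces, epsilon=0.05)
            out.append(res.positions - dx)
        np.testing.assert_allclose(out[0], out[1], atol=1e-6)


class TestObservables:
    @pytest.mark.parametrize("vel,expected", [
        ([[5.0, 0, 0]], 5.0),
        ([[3.0, 0, 0], [0, 4.0, 0]], np.sqrt(12.5)),
        ([[0.0, 0, 0], [0, 0, 0]], 0.0),
    ])
    def test_rms_velocity(self, vel, expected):
        assert rms_velocity(np.array(vel)) == pytest.approx(expected)

    def test_overlap_extremes_and_counting(self):
        em = DensityMap(np.zeros((1, 1, 8)), [0, 0, 0], [1, 1, 1])
        em.values[0, 0, :4] = 1.0
        full = em.like(em.values.copy())
        assert overlap_percent(em, full, 0.5) == pytest.approx(100.0)
        disjoint = em.like(np.roll(em.values, 4))
        assert overlap_percent(em, disjoint, 0.5) == pytest.approx(0.0)
        # EM support 4 voxels, model covers 3 of them -> 75%
        partial = em.like(em.values.copy())
        partial.values[0, 0, 3] = 0.0
        assert overlap_percent(em, partial, 0.5) == pytest.approx(75.0)

    def test_rmsd_identity_and_translation(self, hinge_small):
        cm = coarse_grain(hinge_small.start)
        assert backbone_rmsd(cm, cm) == 0.0
        moved = cm.copy()
        moved.positions = cm.positions + np.array([3.0, 4.0, 0.0])
        assert backbone_rmsd(cm, moved) == pytest.approx(5.0)

    def test_superposed_rmsd_matches_scipy_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(30, 3))
        y = rng.normal(size=(30, 3))
        ours = rmsd(x, y, superpose=True)
        rot, ssd = Rotation.align_vectors(y - y.mean(0), x - x.mean(0),
                                          return_sensitivity=False)[:2]
        oracle = np.sqrt(((rot.apply(x - x.mean(0)) - (y - y.mean(0))) ** 2)
                         .sum(axis=1).mean())
        assert ours == pytest.approx(oracle, abs=1e-8)

    def test_atom_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmsd(np.zeros((3, 3)), np.zeros((4, 3)))


class TestSseConstraints:
    def test_two_strand_sheet_has_four_endpoint_constraints(self):
        from ddflex import make_sheet_fixture
        model, _ = make_sheet_fixture(2, 4)
        cm = coarse_grain(model)
        cs = build_sse_constraints(model, cm, "endpoints")
        assert cs.n_constraints == 4
        assert cs.violations(cm.positions).max() < 1e-9

    def test_no_sse_records_gives_empty_set(self):
        model = make_residue_model([("A", 1, "ALA", ALA_ATOMS)])
        cm = coarse_grain(model)
        assert build_sse_constraints(model, cm, "endpoints").n_constraints == 0
        assert build_sse_constraints(model, cm, "none").n_constraints == 0

    def test_rigidified_helix_stays_rigid_under_forcing(self, hinge_small):
        model = hinge_small.start
        cm = coarse_grain(model)
        cons = ConstraintSet.from_pairs(cm.bonded_pairs, cm.positions)
        cons = cons.merge(build_sse_constraints(model, cm, "rigidify"))
        helix = model.helices[0]
        sel = np.flatnonzero((cm.chains == helix.chain)
                             & (cm.resids >= helix.start)
                             & (cm.resids <= helix.end))
        ref = cm.positions[sel].copy()
        rng = np.random.default_rng(4)
        pos = cm.positions.copy()
        for _ in range(200):
            forces = rng.normal(size=pos.shape)
            dampers = assemble_dampers(pos, 8.0, exclude_pairs=cons.pairs)
            pos = step(pos, dampers, cons, forces, epsilon=0.01).positions
        internal = rmsd(pos[sel], ref, superpose=True)
        assert internal < 0.05
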