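"""Finite-volume Laplace solver: assembly, oracles and invariants."""

import numpy as np
import pytest

from eesim.anatomy import TissueModel
from eesim.field import (
    PotentialField,
    SourceSpec,
    assemble_system,
    sample_along_fiber,
    solve_field,
)


def _add_contact(model, key, ijk):
    flat = np.ravel_multi_index(np.atleast_2d(ijk).T, model.shape)
    model.contacts[key] = np.atleast_1d(flat)


def _center_contact(model, key=("dorsal", "L4")):
    c = tuple(s // 2 for s in model.shape)
    _add_contact(model, key, np.array(c))
    return key


class TestAssembly:
    def test_homogeneous_matrix_is_seven_point_laplacian(self):
        sigma, h = 1.3, 0.5
        model = TissueModel.uniform((5, 5, 5), h, sigma)
        model.grounded = model.default_grounded()
        sys_ = assemble_system(model, SourceSpec(shares=()))
        n = 3  # interior cube
        g = sigma * h * 1e-3
        lap1 = 2 * np.eye(n) - np.eye(n, k=1) - np.eye(n, k=-1)
        eye = np.eye(n)
        expected = g * (
            np.kron(np.kron(lap1, eye), eye)
            + np.kron(np.kron(eye, lap1), eye)
            + np.kron(np.kron(eye, eye), lap1)
        )
        assert np.allclose(sys_.A.toarray(), expected, atol=1e-15)

    def test_interior_row_sums_vanish(self):
        model = TissueModel.uniform((8, 8, 8), 0.2, 2.0)
        model.grounded = model.default_grounded()
        sys_ = assemble_system(model, SourceSpec(shares=()))
        A = sys_.A.toarray()
        # rows whose voxel has no grounded neighbour must conserve current
        ijk = np.array(np.unravel_index(sys_.unknown_index, model.shape)).T
        interior = np.all((ijk >= 2) & (ijk <= 5), axis=1)
        sums = A.sum(axis=1)
        assert np.abs(sums[interior]).max() <= 1e-12 * np.abs(A).max()

    def test_system_size_is_number_of_non_dirichlet_voxels(self):
        model = TissueModel.uniform((6, 7, 8), 0.2, 1.0)
        model.grounded = model.default_grounded()
        sys_ = assemble_system(model, SourceSpec(shares=()))
        assert sys_.A.shape[0] == 4 * 5 * 6

    def test_matrix_is_symmetric(self, fast_model):
        sys_ = assemble_system(
            model=fast_model,
            source=SourceSpec(shares=((("dorsal", "L4"), 1.0),)),
        )
        d = (sys_.A - sys_.A.T).tocoo()
        asym = np.abs(d.data).max() if d.nnz else 0.0
        assert asym <= 1e-15

    def test_unknown_contact_key_rejected(self):
        model = TissueModel.uniform((5, 5, 5), 0.2, 1.0)
        with pytest.raises(KeyError):
            assemble_system(model, SourceSpec(shares=((("dorsal", "L9"), 1.0),)))


class TestSolve:
    def test_zero_current_gives_zero_field(self):
        model = TissueModel.uniform((6, 6, 6), 0.2, 1.0)
        fld = solve_field(assemble_system(model, SourceSpec(shares=())))
        assert np.all(fld.values == 0.0)

    def test_linearity_in_injected_current(self):
        model = TissueModel.uniform((12, 12, 12), 0.2, 1.0)
        key = _center_contact(model)
        f1 = solve_field(assemble_system(model, SourceSpec(((key, 1.0),))))
        f2 = solve_field(assemble_system(model, SourceSpec(((key, 2.0),))))
        assert np.allclose(f2.values, 2 * f1.values, rtol=1e-7, atol=1e-12)

    def test_point_source_matches_grounded_sphere_green_function(self):
        # compact source at the centre of a grounded spherical saline bath:
        # V(r) = I/(4 pi sigma) (1/r - 1/R), the point-source law with the
        # boundary image term; 5% agreement over the mid-range radii
        sigma, h, R = 2.0, 0.2, 6.0
        n = 63
        model = TissueModel.uniform((n, n, n), h, sigma)
        x = model.centers(0)
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        r = np.sqrt(X**2 + Y**2 + Z**2)
        outside = r >= R
        model.sigma_l[outside] = 0.0
        model.sigma_t[outside] = 0.0
        boundary = (r < R) & (r >= R - 2 * h)
        model.grounded = boundary
        key = _center_contact(model)
        fld = solve_field(assemble_system(model, SourceSpec(((key, 1.0),))))
        sel = (r >= 1.0) & (r <= 3.0)
        # the discrete V=0 surface sits mid-shell: centers of the grounded
        # voxels span [R-2h, R), so the effective radius is R - 1.5h
        r_eff = (R - 1.5 * h) * 1e-3
        analytic = 1e-6 / (4 * np.pi * sigma) * (1 / (r[sel] * 1e-3) - 1 / r_eff)
        rel = np.abs(fld.values[sel] * 1e-3 - analytic) / analytic
        assert np.max(rel) < 0.05

    def test_superposition_of_bipole(self):
        model = TissueModel.uniform((16, 16, 16), 0.2, 1.0)
        a = ("dorsal", "L2")
        b = ("dorsal", "L3")
        _add_contact(model, a, np.array([5, 8, 8]))
        _add_contact(model, b, np.array([11, 8, 8]))
        bi = solve_field(assemble_system(model, SourceSpec(((a, 1.0), (b, -1.0)))))
        ma = solve_field(assemble_system(model, SourceSpec(((a, 1.0),))))
        mb = solve_field(assemble_system(model, SourceSpec(((b, 1.0),))))
        assert np.allclose(bi.values, ma.values - mb.values, atol=1e-6)

    def test_anisotropy_elongates_isopotentials_longitudinally(self):
        model = TissueModel.uniform((21, 21, 21), 0.2, 1.0)
        model.sigma_l[:] = 0.6
        model.sigma_t[:] = 0.083  # fibers along z
        key = _center_contact(model)
        fld = solve_field(assemble_system(model, SourceSpec(((key, 1.0),))))
        c = 10
        v_long = fld.values[c, c, c + 6]
        v_trans = fld.values[c + 6, c, c]
        assert v_long > v_trans

    def test_grid_convergence_of_fiber_potentials_on_reference_anatomy(self):
        # halving the voxel size (0.2 -> 0.1 mm) changes the potentials
        # sampled along fibers near a dorsal L4 contact by < 5% RMS
        from eesim.anatomy import (
            ElectrodeConfiguration,
            SpinalCordSpec,
            build_populations,
            build_volume,
        )
        from eesim.field import solve_configuration

        ve = {}
        for h in (0.2, 0.1):
            spec = SpinalCordSpec(voxel_size=h, bath_margin=2.0, z_margin=1.0)
            model = build_volume(spec)
            fld = solve_configuration(
                model, ElectrodeConfiguration("dorsal", "monopolar", "L4"),
                tol=1e-7,
            )
            pop = build_populations(spec, n_per_pool=4, seed=0)
            fibs = [f for f in pop if f.segment == "L4"][:6]
            ve[h] = np.concatenate(
                [sample_along_fiber(fld, f.xyz[::5]) for f in fibs]
            )
        rms = np.sqrt(np.mean((ve[0.2] - ve[0.1]) ** 2))
        assert rms / np.sqrt(np.mean(ve[0.1] ** 2)) < 0.05


class TestSampling:
    def _const_field(self, c):
        vals = np.full((6, 6, 6), c)
        return PotentialField(vals, 0.2, np.zeros(3), 0.0)

    def test_constant_field_sampled_everywhere(self):
        fld = self._const_field(3.7)
        pts = np.array([[0.1, 0.2, 0.3], [0.5, 0.9, 0.4]])
        assert np.allclose(sample_along_fiber(fld, pts), 3.7)

    def test_voxel_center_returns_voxel_value(self):
        vals = np.arange(6 * 6 * 6, dtype=float).reshape(6, 6, 6)
        fld = PotentialField(vals, 0.2, np.zeros(3), 0.0)
        assert sample_along_fiber(fld, [[0.2 * 2, 0.2 * 3, 0.2 * 4]])[0] == vals[2, 3, 4]

    def test_affine_field_interpolated_exactly(self):
        z = np.arange(6) * 0.2
        vals = np.broadcast_to(5.0 * z, (6, 6, 6)).copy()
        fld = PotentialField(vals, 0.2, np.zeros(3), 0.0)
        zq = np.linspace(0.05, 0.95, 17)
        pts = np.c_[np.full_like(zq, 0.5), np.full_like(zq, 0.5), zq]
        assert np.allclose(sample_along_fiber(fld, pts), 5.0 * zq, atol=1e-12)

    def test_out_of_grid_sample_names_fiber_and_compartment(self):
        fld = self._const_field(0.0)
        with pytest.raises(ValueError, match=r"myfiber.*compartment 1"):
            sample_along_fiber(fld, [[0.1, 0.1, 0.1], [9.0, 0.1, 0.1]], "myfiber")
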