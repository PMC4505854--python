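"""Tensor-field construction, normalization and transfer."""

import numpy as np
import pytest

import gbmsim
from gbmsim.tensor_fields import (
    TensorField,
    mean_diffusivity,
    preferential_directions,
    read_tensor_volumes,
    regularize,
    rotate,
    sample_to_mesh,
    synthetic_axis_aligned,
    synthetic_fiber_bundle,
    synthetic_isotropic,
    write_tensor_volumes,
)


def _random_spd(rng, n):
    A = rng.normal(size=(n, 3, 3))
    return np.einsum("nij,nkj->nik", A, A) + 1e-3 * np.eye(3)


class TestMeanDiffusivity:
    def test_diagonal(self):
        f = TensorField(np.array([[1.0, 2.0, 3.0, 0, 0, 0]]))
        assert mean_diffusivity(f)[0] == pytest.approx(2.0)

    def test_degenerate_axis(self):
        f = TensorField(np.array([[86.4, 0, 0, 0, 0, 0]]))
        assert mean_diffusivity(f)[0] == pytest.approx(28.8)

    def test_rotation_invariant(self, rng):
        f = TensorField.from_matrices(_random_spd(rng, 50))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        assert np.allclose(mean_diffusivity(rotate(f, R)), mean_diffusivity(f))


class TestPreferentialDirections:
    def test_isotropic_gives_identity(self):
        f = synthetic_isotropic((3, 3, 3), 7.5)
        T = preferential_directions(f)
        assert np.allclose(T.comps[..., :3], 1.0)
        assert np.allclose(T.comps[..., 3:], 0.0)

    def test_axis_aligned(self):
        f = synthetic_axis_aligned((2, 2, 2), 86.4, axis="x")
        T = preferential_directions(f)
        assert np.allclose(T.comps[..., 0], 3.0)
        assert np.allclose(T.comps[..., 1:], 0.0)

    def test_trace_three_on_random_spd(self, rng):
        f = TensorField.from_matrices(_random_spd(rng, 1000))
        T = preferential_directions(f)
        trace = T.comps[..., :3].sum(axis=-1)
        assert np.allclose(trace, 3.0, rtol=1e-10)

    def test_zero_tensor_masked_not_divided(self):
        comps = np.zeros((2, 6))
        comps[0, :3] = 5.0
        T = preferential_directions(TensorField(comps))
        assert T.mask is not None and T.mask[0] and not T.mask[1]
        # masked location gets the isotropic fallback, never a NaN
        assert np.allclose(T.comps[1, :3], 1.0)
        assert np.all(np.isfinite(T.comps))

    def test_reconstruction_identity(self, rng):
        # D = D_n * T wherever D_n > 0
        f = TensorField.from_matrices(_random_spd(rng, 200))
        md = mean_diffusivity(f)
        T = preferential_directions(f)
        assert np.allclose(md[..., None] * T.comps, f.comps, rtol=1e-12)

    def test_commutes_with_rotation(self, rng):
        f = TensorField.from_matrices(_random_spd(rng, 100))
        # brute-force oracle: rotate first, then normalize
        for _ in range(3):
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            w, x, y, z = q
            R = np.array([
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ])
            a = preferential_directions(rotate(f, R))
            b = rotate(preferential_directions(f), R)
            assert np.allclose(a.comps, b.comps, atol=1e-10)


class TestRegularize:
    def test_spd_unchanged_bit_identical(self, rng):
        f = TensorField.from_matrices(_random_spd(rng, 20))
        out = regularize(f, 1e-9)
        assert np.array_equal(out.comps, f.comps)

    def test_clamps_negative_eigenvalue(self):
        f = TensorField(np.array([[1.0, -0.1, 0.5, 0, 0, 0]]))
        out = regularize(f, 1e-6)
        assert np.allclose(out.comps[0], [1.0, 1e-6, 0.5, 0, 0, 0])

    def test_zero_tensor_floors_to_identity(self):
        out = regularize(TensorField(np.zeros((1, 6))), 1e-6)
        assert np.allclose(out.comps[0], [1e-6, 1e-6, 1e-6, 0, 0, 0])

    def test_clamped_field_is_psd(self, rng):
        mats = rng.normal(size=(100, 3, 3))
        mats = 0.5 * (mats + np.transpose(mats, (0, 2, 1)))  # symmetric, indefinite
        out = regularize(TensorField.from_matrices(mats), 1e-8)
        eig = np.linalg.eigvalsh(out.as_matrices())
        assert eig.min() >= 1e-8 - 1e-12

    def test_nonfinite_reports_location(self):
        comps = np.zeros((2, 6))
        comps[1, 2] = np.nan
        with pytest.raises(ValueError, match=r"\[1\]"):
            regularize(TensorField(comps), 0.0)

    def test_trace_three_after_regularize(self, rng):
        mats = rng.normal(size=(200, 3, 3))
        mats = 0.5 * (mats + np.transpose(mats, (0, 2, 1)))
        reg = regularize(TensorField.from_matrices(mats), 1e-6)
        T = preferential_directions(reg)
        trace = T.comps[T.mask][:, :3].sum(axis=-1)
        assert np.allclose(trace, 3.0, rtol=1e-10)


class TestFiberBundle:
    def test_straight_bundle_uniform_inside(self):
        line = np.array([[-10.0, 0, 0], [10.0, 0, 0]])
        f = synthetic_fiber_bundle((9, 9, 9), line, 3.0, 2.0, 0.5,
                                   spacing=(1.0, 1.0, 1.0), origin=(-4.0, -4.0, -4.0))
        center = f.as_matrices()[4, 4, 4]
        assert np.allclose(center, np.diag([2.0, 0.5, 0.5]))

    def test_equal_eigenvalues_isotropic_everywhere(self):
        line = np.array([[0.0, 0, 0], [5.0, 5.0, 0]])
        f = synthetic_fiber_bundle((5, 5, 5), line, 2.0, 1.3, 1.3)
        assert np.allclose(f.comps[..., :3], 1.3)
        assert np.allclose(f.comps[..., 3:], 0.0, atol=1e-12)

    def test_quarter_circle_tangent(self):
        R = 20.0
        ts = np.linspace(0, np.pi / 2, 361)
        line = np.stack([R * np.sin(ts), R * (1 - np.cos(ts)),
                         np.zeros_like(ts)], axis=1)
        f = synthetic_fiber_bundle((23, 23, 3), line, 4.0, 2.0, 0.5,
                                   spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, -1.0))
        mid = line[180]
        idx = np.round((mid - f.origin) / f.spacing).astype(int)
        D = f.as_matrices()[tuple(idx)]
        _, vecs = np.linalg.eigh(D)
        tangent = np.array([np.cos(ts[180]), np.sin(ts[180]), 0.0])
        angle = np.degrees(np.arccos(abs(vecs[:, 2] @ tangent)))
        assert angle < 1.0

    def test_degenerate_centerline_rejected(self):
        with pytest.raises(ValueError, match="repeated"):
            synthetic_fiber_bundle((4, 4, 4), [[0, 0, 0], [0, 0, 0], [1, 0, 0]],
                                   1.0, 2.0, 1.0)

    def test_everywhere_psd(self):
        ts = np.linspace(0, np.pi / 2, 51)
        line = np.stack([10 * np.sin(ts), 10 * (1 - np.cos(ts)),
                         np.zeros_like(ts)], axis=1)
        f = synthetic_fiber_bundle((8, 8, 8), line, 3.0, 2.5, 0.4,
                                   spacing=(2.0, 2.0, 2.0), origin=(-2, -2, -7))
        assert np.linalg.eigvalsh(f.as_matrices()).min() >= 0.4 - 1e-12


class TestSampleToMesh:
    def test_uniform_field(self, small_mesh):
        f = synthetic_isotropic((4, 4, 4), 5.0, spacing=(2.5,) * 3,
                                origin=(-3.75,) * 3)
        out = sample_to_mesh(f, small_mesh)
        assert np.allclose(out.comps[:, :3], 5.0)
        assert out.fallback_count == 0

    def test_two_valued_split_brute_force(self, small_mesh):
        comps = np.zeros((4, 4, 4, 6))
        comps[..., :3] = 1.0
        comps[2:, ..., 0] = 9.0  # x >= -1.25 plane in world coordinates
        f = TensorField(comps, spacing=(2.5,) * 3, origin=(-3.75,) * 3)
        out = sample_to_mesh(f, small_mesh)
        bary = small_mesh.barycenters()
        # brute-force point-in-voxel: voxel index by rounding
        expected = np.where(np.round((bary[:, 0] + 3.75) / 2.5) >= 2, 9.0, 1.0)
        assert np.array_equal(out.comps[:, 0], expected)

    def test_outside_cells_counted_and_isotropic(self, small_mesh):
        f = synthetic_isotropic((2, 2, 2), 5.0, spacing=(1.0,) * 3,
                                origin=(-0.5,) * 3)  # grid much smaller than mesh
        out = sample_to_mesh(f, small_mesh, eigen_floor=1e-6)
        assert out.fallback_count > 0
        outside = np.all(out.comps == [1e-6, 1e-6, 1e-6, 0, 0, 0], axis=1)
        assert outside.sum() == out.fallback_count

    def test_empty_mesh_rejected(self):
        f = synthetic_isotropic((2, 2, 2), 1.0)
        empty = gbmsim.Mesh(np.zeros((0, 3)), np.zeros((0, 4), dtype=int))
        with pytest.raises(ValueError):
            sample_to_mesh(f, empty)


class TestNiftiIO:
    def test_round_trip_bit_exact(self, tmp_path, rng):
        mats = _random_spd(rng, 3 * 4 * 5).reshape(3, 4, 5, 3, 3)
        f = TensorField.from_matrices(mats, spacing=(2.2, 2.2, 2.2),
                                      origin=(-10.0, 5.0, 0.0))
        paths = write_tensor_volumes(f, tmp_path)
        back = read_tensor_volumes(paths)
        assert np.array_equal(back.comps, f.comps)
        assert np.allclose(back.spacing, f.spacing)
        assert np.allclose(back.origin, f.origin)

    def test_constant_diagonal_volumes(self, tmp_path):
        f = synthetic_isotropic((3, 3, 3), 4.5)
        paths = write_tensor_volumes(f, tmp_path)
        back = read_tensor_volumes([paths[k] for k in
                                    ("xx", "yy", "zz", "xy", "xz", "yz")])
        assert np.allclose(back.comps[..., :3], 4.5)
        assert np.allclose(back.comps[..., 3:], 0.0)

    def test_shape_mismatch_names_file(self, tmp_path):
        f1 = synthetic_isotropic((3, 3, 3), 1.0)
        paths = write_tensor_volumes(f1, tmp_path, prefix="A")
        f2 = synthetic_isotropic((4, 3, 3), 1.0)
        other = write_tensor_volumes(f2, tmp_path, prefix="B")
        paths["yy"] = other["yy"]
        with pytest.raises(ValueError, match="B_yy"):
            read_tensor_volumes(paths)

    def test_missing_component_rejected(self, tmp_path):
        f = synthetic_isotropic((2, 2, 2), 1.0)
        paths = write_tensor_volumes(f, tmp_path)
        del paths["xz"]
        with pytest.raises(ValueError, match="xz"):
            read_tensor_volumes(paths)
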