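"""Voxel-to-element mapping, FA discretization, element orientations."""

import logging

import numpy as np
import pytest

from axonvar import fe_coupling as fc
from axonvar import synthetic_data as sd
from axonvar.tensor_fit import TensorVolume


def uniform_tensor_volume(D, shape=(16, 16, 16), voxel=1.0):
    aff = np.eye(4)
    aff[:3, :3] *= voxel
    aff[:3, 3] = -(np.array(shape) - 1) / 2.0 * voxel
    return TensorVolume(
        D=np.broadcast_to(D, shape + (3, 3)).copy(),
        affine=aff,
        mask=np.ones(shape, dtype=bool),
    )


def prolate(direction, fa=0.6, md=0.7e-3):
    l1, l2, _ = sd.prolate_eigenvalues(fa, md)
    t = np.asarray(direction, dtype=float)
    t /= np.linalg.norm(t)
    return l2 * np.eye(3) + (l1 - l2) * np.outer(t, t)


class TestAssignPart:
    # one FA inside each of the nine intervals with its dispersion value
    @pytest.mark.parametrize(
        "fa,k",
        [
            (0.10, 0.3333), (0.25, 0.2732), (0.35, 0.2500), (0.45, 0.2273),
            (0.55, 0.2000), (0.65, 0.1667), (0.75, 0.1282), (0.85, 0.0769),
            (0.95, 0.0000),
        ],
    )
    def test_interval_lookup(self, fa, k):
        k_got, part = fc.assign_part(fa)
        assert k_got == k
        assert part == int(np.searchsorted([0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9], fa, "right"))

    @pytest.mark.parametrize(
        "fa,k,part", [(0.2, 0.2732, 1), (0.3, 0.2500, 2), (1.0, 0.0000, 8)]
    )
    def test_half_open_boundaries(self, fa, k, part):
        """Boundaries belong to the upper interval; FA = 1 stays in the last."""
        assert fc.assign_part(fa) == (k, part)

    def test_gray_matter_below_threshold(self):
        k, part = fc.assign_part(0.15)
        assert k == 0.3333
        assert part == fc.GRAY_PART

    @pytest.mark.parametrize("fa", [-0.01, 1.01])
    def test_out_of_range_rejected(self, fa):
        with pytest.raises(ValueError):
            fc.assign_part(fa)


class TestVoxelize:
    def test_voxel_count_and_centroid_weight(self):
        vol = uniform_tensor_volume(prolate([0, 0, 1]), shape=(10, 10, 10))
        mesh = sd.make_toy_mesh((10, 10, 10), 5.0)
        assign = fc.voxelize_mesh(mesh, vol)
        counts = [len(v) for v in assign.voxel_indices.values()]
        assert sum(counts) == 1000
        # each 5 mm element holds 125 one-mm voxels
        assert all(c == 125 for c in counts)
        # weights are normalized exponentials of distances in [0, 1]
        for e, w in assign.weights.items():
            d = assign.distances[e]
            assert d.min() >= 0 and d.max() <= 1
            assert np.allclose(w, np.exp(-d))
            assert abs((w / w.sum()).sum() - 1.0) < 1e-12

    def test_no_voxel_double_assigned(self):
        vol = uniform_tensor_volume(prolate([0, 0, 1]), shape=(10, 10, 10))
        mesh = sd.make_toy_mesh((10, 10, 10), 5.0)
        assign = fc.voxelize_mesh(mesh, vol)
        seen = np.vstack([v for v in assign.voxel_indices.values()])
        assert len(np.unique(seen, axis=0)) == len(seen)

    def test_single_voxel_element_distance_zero(self):
        vol = uniform_tensor_volume(prolate([0, 0, 1]), shape=(2, 2, 2), voxel=4.0)
        mesh = sd.make_toy_mesh((8, 8, 8), 4.0)
        assign = fc.voxelize_mesh(mesh, vol)
        for e in assign.voxel_indices:
            assert len(assign.voxel_indices[e]) == 1
            assert assign.distances[e][0] == 0.0
            assert assign.weights[e][0] == 1.0


class TestElementTensor:
    def test_single_voxel_is_exact(self):
        D = prolate([1, 1, 0])
        vol = uniform_tensor_volume(D, shape=(2, 2, 2), voxel=4.0)
        mesh = sd.make_toy_mesh((8, 8, 8), 4.0)
        assign = fc.voxelize_mesh(mesh, vol)
        e = next(iter(assign.voxel_indices))
        assert np.allclose(fc.element_tensor(vol, assign, e), D, atol=1e-18)

    def test_identical_tensors_average_to_themselves(self):
        D = prolate([0, 1, 0])
        vol = uniform_tensor_volume(D, shape=(10, 10, 10))
        mesh = sd.make_toy_mesh((10, 10, 10), 5.0)
        assign = fc.voxelize_mesh(mesh, vol)
        for e in assign.voxel_indices:
            assert np.allclose(fc.element_tensor(vol, assign, e), D, atol=1e-18)

    def test_equal_distances_give_arithmetic_mean(self):
        vol = uniform_tensor_volume(prolate([0, 0, 1]), shape=(2, 1, 1), voxel=1.0)
        Da, Db = prolate([0, 0, 1]), prolate([1, 0, 0])
        vol.D[0, 0, 0] = Da
        vol.D[1, 0, 0] = Db
        assign = fc.VoxelAssignment(
            voxel_indices={0: np.array([[0, 0, 0], [1, 0, 0]])},
            distances={0: np.array([1.0, 1.0])},
            weights={0: np.exp(-np.array([1.0, 1.0]))},
        )
        assert np.allclose(fc.element_tensor(vol, assign, 0), (Da + Db) / 2, atol=1e-18)

    def test_orientation_dispersion_lowers_element_fa(self):
        """Averaging differently oriented voxels smooths anisotropy."""
        vol = uniform_tensor_volume(prolate([0, 0, 1], fa=0.7), shape=(8, 8, 8))
        c = np.radians(30.0)
        tilted = prolate([np.sin(c), 0, np.cos(c)], fa=0.7)
        vol.D[::2] = tilted
        mesh = sd.make_toy_mesh((8, 8, 8), 8.0)
        elems = fc.build_element_anisotropy(mesh, vol)
        assert elems[0].fa <= 0.7
        assert elems[0].fa < 0.7 - 1e-4  # strictly smoothed

    def test_element_fa_matches_voxel_fa_when_uniform(self):
        vol = uniform_tensor_volume(prolate([0, 0, 1], fa=0.65), shape=(8, 8, 8))
        mesh = sd.make_toy_mesh((8, 8, 8), 4.0)
        elems = fc.build_element_anisotropy(mesh, vol)
        for e in elems:
            assert e.fa == pytest.approx(0.65, abs=1e-12)
            assert np.allclose(np.abs(e.P), [0, 0, 1], atol=1e-9)


class TestOrientationAngles:
    @pytest.mark.parametrize(
        "P,theta,phi",
        [((0, 0, 1), 0.0, 0.0), ((np.sqrt(2) / 2, np.sqrt(2) / 2, 0), 90.0, 45.0)],
    )
    def test_reference_vectors(self, P, theta, phi):
        th, ph = fc.element_orientation_angles(np.array(P, dtype=float))
        assert np.degrees(th) == pytest.approx(theta, abs=1e-9)
        assert np.degrees(ph) == pytest.approx(phi, abs=1e-9)

    def test_round_trip_random_vectors(self):
        from axonvar.fiber_descriptors import tangent_from_angles
        from axonvar.tensor_fit import canonical_sign

        rng = np.random.default_rng(9)
        for _ in range(200):
            P = rng.normal(size=3)
            P /= np.linalg.norm(P)
            th, ph = fc.element_orientation_angles(P)
            back = tangent_from_angles(th, ph)
            assert np.abs(back - canonical_sign(P)).max() < 1e-12

    def test_non_unit_rejected(self):
        with pytest.raises(ValueError):
            fc.element_orientation_angles(np.array([1.0, 1.0, 1.0]))


class TestComposition:
    def test_all_low_fa_is_all_gray(self):
        vol = uniform_tensor_volume(prolate([0, 0, 1], fa=0.1), shape=(8, 8, 8))
        mesh = sd.make_toy_mesh((8, 8, 8), 4.0)
        comp = fc.composition_summary(fc.build_element_anisotropy(mesh, vol))
        assert comp.loc[fc.GRAY_PART, "volume_fraction"] == 1.0

    def test_half_gray_half_white_split(self):
        vol = uniform_tensor_volume(prolate([0, 0, 1], fa=0.1), shape=(8, 8, 8))
        vol.D[:4] = prolate([0, 0, 1], fa=0.65)
        mesh = sd.make_toy_mesh((8, 8, 8), 4.0)
        comp = fc.composition_summary(fc.build_element_anisotropy(mesh, vol))
        by_k = comp.set_index("k")["volume_fraction"]
        assert by_k[0.3333] == pytest.approx(0.5)
        assert by_k[0.1667] == pytest.approx(0.5)  # the 0.6-0.7 FA group

    def test_population_composition_spread(self):
        vol_a = uniform_tensor_volume(prolate([0, 0, 1], fa=0.1), shape=(8, 8, 8))
        vol_b = uniform_tensor_volume(prolate([0, 0, 1], fa=0.25), shape=(8, 8, 8))
        mesh = sd.make_toy_mesh((8, 8, 8), 4.0)
        comps = [
            fc.composition_summary(fc.build_element_anisotropy(mesh, v))
            for v in (vol_a, vol_b)
        ]
        pop = fc.population_composition(comps)
        gray = pop.set_index("part").loc[fc.GRAY_PART]
        assert gray["mean_fraction"] == pytest.approx(0.5)
        assert gray["min_fraction"] == 0.0 and gray["max_fraction"] == 1.0
        assert gray["cv_percent"] > 0

    def test_empty_element_inherits_neighbors(self, caplog):
        vol = uniform_tensor_volume(prolate([0, 0, 1], fa=0.5), shape=(8, 8, 4))
        aff = vol.affine.copy()
        aff[2, 3] -= 6.0  # volume covers only the lower half of the mesh
        vol = TensorVolume(D=vol.D, affine=aff, mask=vol.mask)
        mesh = sd.make_toy_mesh((8, 8, 16), 4.0)
        with caplog.at_level(logging.WARNING, logger="axonvar.fe_coupling"):
            elems = fc.build_element_anisotropy(mesh, vol)
        assert "no voxels" in caplog.text
        assert any(e.inherited for e in elems)
        for e in elems:  # inherited elements copy the uniform tensor
            assert e.fa == pytest.approx(0.5, abs=1e-9)


class TestExports:
    def test_orientation_file_round_trip(self, tmp_path):
        from axonvar import io as avio

        vol = uniform_tensor_volume(prolate([1, 0, 1], fa=0.6), shape=(8, 8, 8))
        mesh = sd.make_toy_mesh((8, 8, 8), 4.0)
        elems = fc.build_element_anisotropy(mesh, vol)
        path = tmp_path / "orient.txt"
        avio.write_element_orientation(elems, path)
        rows = np.loadtxt(path, comments="#")
        assert rows.shape == (mesh.n_elements, 8)
        a = rows[:, 2:5]
        d = rows[:, 5:8]
        assert np.abs(np.einsum("ij,ij->i", a, d)).max() < 1e-6
        assert np.allclose(np.linalg.norm(d, axis=1), 1.0, atol=1e-6)
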