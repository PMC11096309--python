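"""Reaction-diffusion segmentation: seeds, evolution, surfaces, shunts."""

import numpy as np
import pytest
from scipy import ndimage

import mrdistort as md
from mrdistort.segmentation import EmptyLabelError
from conftest import dice, oracle_segmentation, rd_masks


class TestSeeds:
    def test_one_seed_per_present_sphere(self, small_spec, small_volume):
        seeds = md.seed_from_grid(small_spec, small_volume)
        assert len(seeds) == small_spec.n_present

    def test_default_spec_yields_338_seeds(self, default_spec_session, full_volume):
        seeds = md.seed_from_grid(default_spec_session, full_volume)
        assert len(seeds) == 338

    def test_seed_centers_coincide_with_spec_centers(self, small_spec, small_volume):
        seeds = md.seed_from_grid(small_spec, small_volume)
        for seed in seeds.seeds:
            assert np.allclose(seed.center, small_spec.center(seed.grid_index))

    def test_all_omitted_spec_gives_empty_segmentation(self, small_volume):
        spec = md.default_spec()
        full = {(i, j, k) for i in range(7) for j in range(7) for k in range(7)}
        empty_spec = spec.with_omitted(full)
        vol = md.rasterize(empty_spec, 4.0)
        seeds = md.seed_from_grid(empty_spec, vol)
        assert len(seeds) == 0
        label_map = md.evolve(vol, seeds)
        assert label_map.labels.max() == 0

    def test_grid_outside_volume_rejected(self, small_spec):
        tiny = md.Volume(np.zeros((5, 5, 5)), spacing=(2, 2, 2), origin=(-4, -4, -4))
        with pytest.raises(ValueError, match="outside"):
            md.seed_from_grid(small_spec, tiny)

    def test_seeds_in_dark_volume_flagged_weak(self, small_spec, small_volume):
        dark = small_volume.copy(data=np.zeros_like(small_volume.data))
        seeds = md.seed_from_grid(small_spec, dark)
        assert all(s.weak for s in seeds.seeds)


class TestEvolve:
    def test_matches_threshold_oracle_on_clean_phantom(
        self, small_spec, small_volume, small_label_map
    ):
        oracle = oracle_segmentation(small_volume, small_spec)
        masks = rd_masks(small_label_map)
        assert set(masks) == set(oracle)
        for gidx in oracle:
            assert dice(oracle[gidx], masks[gidx]) >= 0.99

    def test_volumes_within_3pct_of_closed_form(self, small_spec, small_label_map):
        nominal = md.nominal_water_volume(
            small_spec.sphere_outer_diameter, small_spec.shell_thickness
        )
        voxvol = float(np.prod(small_label_map.spacing))
        for count in small_label_map.counts.values():
            assert count * voxvol == pytest.approx(nominal, rel=0.03)

    def test_deterministic(self, small_spec, small_volume):
        seeds = md.seed_from_grid(small_spec, small_volume)
        a = md.evolve(small_volume, seeds)
        b = md.evolve(small_volume, seeds)
        assert np.array_equal(a.labels, b.labels)

    def test_uniform_background_gives_all_disappeared(self, small_spec):
        spec = small_spec
        vol = md.rasterize(spec, 2.0)
        dark = vol.copy(data=np.zeros_like(vol.data))
        seeds = md.seed_from_grid(spec, dark)
        label_map = md.evolve(dark, seeds)
        assert all(c == 0 for c in label_map.counts.values())
        descs = md.describe_scan(dark, label_map)
        assert all(d.disappeared for d in descs.values())

    def test_labels_connected_and_grid_unique(self, small_label_map):
        structure = ndimage.generate_binary_structure(3, 1)
        seen = set()
        for label, gidx in small_label_map.label_to_index.items():
            assert gidx not in seen
            seen.add(gidx)
            mask = small_label_map.labels == label
            if mask.any():
                _, n = ndimage.label(mask, structure=structure)
                assert n == 1

    def test_unstable_parameters_rejected(self):
        with pytest.raises(ValueError, match="stability"):
            md.RDParameters(diffusion=0.5, step=0.5)


def two_ball_bridge_volume(channel_width: int):
    """Two touching spheres with an artificial bright shunt channel.

    ``channel_width`` is the edge length (voxels) of the square channel
    cross-section drilled along the center-to-center axis; 0 means the
    clean contact.
    """
    spec = md.PhantomSpec(grid_shape=(2, 1, 1), omitted_indices=frozenset())
    vol = md.rasterize(spec, 2.0, supersampling=4)
    if channel_width > 0:
        c0 = vol.world_to_index(spec.center((0, 0, 0)))
        c1 = vol.world_to_index(spec.center((1, 0, 0)))
        j0 = int(round(c0[1]))
        k0 = int(round(c0[2]))
        half = channel_width // 2
        lo_j, hi_j = j0 - half, j0 - half + channel_width
        lo_k, hi_k = k0 - half, k0 - half + channel_width
        vol.data[int(c0[0]) : int(c1[0]) + 1, lo_j:hi_j, lo_k:hi_k] = 1.0
    return spec, vol


class TestShuntRobustness:
    @pytest.mark.parametrize("width", [0, 1, 2, 3])
    def test_bridged_spheres_never_merge(self, width):
        spec, vol = two_ball_bridge_volume(width)
        seeds = md.seed_from_grid(spec, vol)
        label_map = md.evolve(vol, seeds)
        structure = ndimage.generate_binary_structure(3, 1)
        # both labels survive, each connected, and each sphere keeps its own
        # label at its center
        for seed in seeds.seeds:
            mask = label_map.labels == seed.label
            assert mask.any()
            _, n = ndimage.label(mask, structure=structure)
            assert n == 1
            center_vox = tuple(
                np.rint(vol.world_to_index(seed.center)).astype(int)
            )
            assert label_map.labels[center_vox] == seed.label

    @pytest.mark.parametrize("width", [1, 3])
    def test_bridge_does_not_distort_ball_bulk(self, width):
        spec, vol = two_ball_bridge_volume(width)
        seeds = md.seed_from_grid(spec, vol)
        label_map = md.evolve(vol, seeds)
        clean_spec, clean_vol = two_ball_bridge_volume(0)
        oracle = oracle_segmentation(clean_vol, clean_spec)
        masks = rd_masks(label_map)
        for gidx, mask in masks.items():
            # bridged segmentation still overlaps the clean ball almost fully
            inter = np.logical_and(mask, oracle[gidx]).sum()
            assert inter / oracle[gidx].sum() >= 0.95


class TestSurface:
    def test_surface_matches_shift_oracle_on_digital_ball(self):
        # ideal digitized 40 mm ball at 2 mm voxels, built from geometry alone
        ax = (np.arange(25) - 12) * 2.0
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
        ball = x**2 + y**2 + z**2 <= 19.885**2
        # independent oracle: voxels with an exposed axis face, via shifts
        exposed = np.zeros_like(ball)
        for axis in range(3):
            for shift in (1, -1):
                nbr = np.roll(ball, shift, axis=axis)
                edge = np.zeros_like(ball)
                idx = [slice(None)] * 3
                idx[axis] = 0 if shift == 1 else -1
                edge[tuple(idx)] = True
                exposed |= ball & (~nbr | edge)
        lm = md.BallLabelMap(
            labels=ball.astype(np.int32),
            spacing=(2, 2, 2),
            origin=(-24, -24, -24),
            label_to_index={1: (0, 0, 0)},
            counts={1: int(ball.sum())},
        )
        surface = md.extract_surface(lm, 1)
        oracle_idx = {tuple(i) for i in np.argwhere(exposed)}
        assert {tuple(i) for i in surface} == oracle_idx
        # the 6-neighbour boundary is thinner than the face-count continuum
        # estimate (sphere area / voxel face area)
        continuum = 4 * np.pi * 19.885**2 / 2.0**2
        assert surface.shape[0] < continuum

    def test_single_voxel_label_is_its_own_surface(self):
        labels = np.zeros((5, 5, 5), dtype=np.int32)
        labels[2, 2, 2] = 1
        lm = md.BallLabelMap(
            labels=labels,
            spacing=(1, 1, 1),
            origin=(0, 0, 0),
            label_to_index={1: (0, 0, 0)},
            counts={1: 1},
        )
        surface = md.extract_surface(lm, 1)
        assert surface.tolist() == [[2, 2, 2]]

    def test_full_lattice_label_surface_is_boundary_shell(self):
        labels = np.ones((4, 4, 4), dtype=np.int32)
        lm = md.BallLabelMap(
            labels=labels,
            spacing=(1, 1, 1),
            origin=(0, 0, 0),
            label_to_index={1: (0, 0, 0)},
            counts={1: 64},
        )
        surface = md.extract_surface(lm, 1)
        expected = 4**3 - 2**3
        assert surface.shape[0] == expected

    def test_empty_label_raises_distinct_error(self):
        labels = np.zeros((3, 3, 3), dtype=np.int32)
        lm = md.BallLabelMap(
            labels=labels,
            spacing=(1, 1, 1),
            origin=(0, 0, 0),
            label_to_index={1: (0, 0, 0)},
            counts={1: 0},
        )
        with pytest.raises(EmptyLabelError):
            md.extract_surface(lm, 1)
        with pytest.raises(KeyError):
            md.extract_surface(lm, 99)
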