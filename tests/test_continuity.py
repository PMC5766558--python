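"""Vascular continuity: components, diameters, the piecewise weight, re-argmax."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from subsolidseg.classify import ClassWeights, PosteriorStack
from subsolidseg.continuity import (
    ContinuityField,
    apply_continuity,
    compute_continuity_field,
    continuity_weight,
    estimate_diameters,
    find_entering_vessels,
    local_thickness,
    outer_vessel_mask,
    split_components,
)
from subsolidseg.volume import CORE, GROUND_GLASS, VESSEL, LabelMap, Volume

ISO = (0.5, 0.5, 0.5)


def _flood_fill_components(mask, connectivity):
    """Brute-force BFS connected components, independent of scipy labeling."""
    mask = np.asarray(mask) > 0
    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                if connectivity == 6 and abs(dz) + abs(dy) + abs(dx) != 1:
                    continue
                offsets.append((dz, dy, dx))
    seen = np.zeros_like(mask)
    comps = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        queue, comp = [start], set()
        seen[start] = True
        while queue:
            v = queue.pop()
            comp.add(v)
            for off in offsets:
                n = tuple(a + b for a, b in zip(v, off))
                if all(0 <= c < s for c, s in zip(n, mask.shape)) and mask[n] and not seen[n]:
                    seen[n] = True
                    queue.append(n)
        comps.append(comp)
    return comps


class TestContinuityWeight:
    def test_printed_branch_values(self):
        assert continuity_weight(1.0, 1.0, a=3.0) == 1.0  # d_in <= d_out
        assert continuity_weight(0.4, 1.0, a=7.0) == 1.0
        assert continuity_weight(3.0, 1.0, a=3.0) == 0.0  # d_in >= a * d_out
        assert continuity_weight(2.0, 1.0, a=3.0) == 0.5  # linear midpoint

    def test_continuity_at_breakpoints(self):
        for a in (1.5, 3.0, 10.0):
            eps = 1e-13
            assert abs(continuity_weight(1.0 + eps, 1.0, a) - 1.0) < 1e-12
            assert abs(continuity_weight(a - eps, 1.0, a) - 0.0) < 1e-12

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError, match="d_out"):
            continuity_weight(1.0, 0.0)
        with pytest.raises(ValueError, match="a must"):
            continuity_weight(1.0, 1.0, a=1.0)

    @settings(max_examples=100, deadline=None)
    @given(
        ratios=st.lists(st.floats(0.01, 10.0), min_size=2, max_size=6),
        a=st.floats(1.1, 8.0),
    )
    def test_monotone_nonincreasing_in_ratio(self, ratios, a):
        ratios = sorted(ratios)
        w = [continuity_weight(r, 1.0, a) for r in ratios]
        assert all(0.0 <= x <= 1.0 for x in w)
        assert all(x >= y - 1e-12 for x, y in zip(w, w[1:]))


class TestSplitComponents:
    def test_diagonal_tubes_are_separate_under_6_connectivity(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1, 1, :] = True
        mask[2, 2, :] = True  # touches the first only diagonally
        _, comps = split_components(mask)
        assert len(comps) == 2

    def test_single_tube_is_one_component(self):
        mask = np.zeros((4, 4, 8), dtype=bool)
        mask[2, 2, 1:7] = True
        _, comps = split_components(mask)
        assert len(comps) == 1

    def test_random_masks_match_flood_fill_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            mask = rng.random((10, 10, 10)) < 0.2
            lab, comps = split_components(mask)
            oracle = _flood_fill_components(mask, 6)
            assert len(comps) == len(oracle)
            mine = {frozenset(map(tuple, c.voxels)) for c in comps}
            assert mine == {frozenset(c) for c in oracle}

    def test_component_ids_ordered_by_first_voxel(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[4, 4, 4] = True
        mask[0, 0, 0] = True
        lab, comps = split_components(mask)
        assert lab[0, 0, 0] == 1 and lab[4, 4, 4] == 2

    def test_empty_mask_gives_empty_list(self):
        _, comps = split_components(np.zeros((3, 3, 3), dtype=bool))
        assert comps == []


class TestDiameters:
    def test_digital_cylinder_radius_2mm(self, coords40):
        zz, yy, xx = coords40
        mask = (yy - 10.0) ** 2 + (xx - 10.0) ** 2 <= 2.0**2
        d = estimate_diameters(np.array([[20, 20, 20]]), mask, ISO)
        assert 3.5 <= d[0] <= 4.5  # analytic 4 mm

    def test_sphere_radius_3mm(self, coords40):
        zz, yy, xx = coords40
        mask = (zz - 10.0) ** 2 + (yy - 10.0) ** 2 + (xx - 10.0) ** 2 <= 3.0**2
        d = estimate_diameters(np.array([[20, 20, 20]]), mask, ISO)
        assert 5.4 <= d[0] <= 6.6  # analytic 6 mm

    def test_single_voxel_bounded_by_voxel_size(self):
        mask = np.zeros((9, 9, 9), dtype=bool)
        mask[4, 4, 4] = True
        d = estimate_diameters(np.array([[4, 4, 4]]), mask, ISO)
        assert 0.0 < d[0] <= 1.0

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            local_thickness(np.zeros((4, 4, 4), dtype=bool), ISO)

    def test_anisotropic_grid_rejected(self):
        mask = np.ones((4, 4, 4), dtype=bool)
        with pytest.raises(ValueError, match="isotropic"):
            estimate_diameters(np.array([[1, 1, 1]]), mask, (1.0, 0.7, 0.7))


def _tube_mask(shape, axis_point, direction, radius, spacing=0.5):
    grids = np.meshgrid(*[np.arange(n) * spacing for n in shape], indexing="ij")
    p = np.stack(grids, axis=-1) - np.asarray(axis_point)
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    along = p @ d
    radial = p - along[..., None] * d
    return np.linalg.norm(radial, axis=-1) <= radius


class TestEnteringVessels:
    def test_thicker_attached_outer_vessel_wins(self):
        shape = (24, 40, 40)
        nodule = np.zeros(shape, dtype=bool)
        nodule[:, 14:26, 14:26] = True
        inner = _tube_mask(shape, (6.0, 10.0, 10.0), (0, 0, 1), 1.0) & nodule
        thin = _tube_mask(shape, (6.0, 10.0, 10.0), (0, 0, 1), 1.0) & ~nodule
        # 4 mm tube running along y, hugging the nodule face so it touches
        # the inner component across the boundary without being carved by it
        thick = _tube_mask(shape, (6.0, 10.0, 4.9), (0, 1, 0), 2.0) & ~nodule
        outer = thin | thick
        lab, comps = split_components(inner)
        comps = find_entering_vessels(comps, lab, outer, nodule, ISO, tree_min_fraction=0.0)
        assert comps[0].entering_vessel_id is not None
        # the selected entering vessel has ~4 mm calibre, not ~2 mm
        assert comps[0].d_out == pytest.approx(4.0, rel=0.25)

    def test_unattached_inner_blob_has_no_entering_vessel(self):
        shape = (24, 40, 40)
        nodule = np.zeros(shape, dtype=bool)
        nodule[:, 14:26, 14:26] = True
        blob = np.zeros(shape, dtype=bool)
        blob[10:14, 18:22, 18:22] = True
        outer = _tube_mask(shape, (6.0, 10.0, 10.0), (0, 1, 0), 1.25) & ~nodule
        lab, comps = split_components(blob)
        comps = find_entering_vessels(comps, lab, outer, nodule, ISO)
        assert comps[0].entering_vessel_id is None

    def test_crossing_tube_d_out_matches_true_diameter(self):
        # phantom rasterized directly on the isotropic grid so the diameter
        # estimate is compared against clean tube geometry
        from subsolidseg.phantom import PhantomSpec, VesselSpec, generate_phantom

        spec = PhantomSpec(
            shape=(56, 56, 56),
            spacing=(0.5, 0.5, 0.5),
            nodule_center=(14.0, 14.0, 14.0),
            nodule_radii=(6.0, 6.0, 6.0),
            vessels=[VesselSpec(points=[(14, 1, 27), (14, 27, 1)], diameters=[2.5, 2.5])],
            seed=8,
        )
        b = generate_phantom(spec)
        nod = b.nodule.data > 0
        outer = b.outer_vessels.data > 0
        inner = (b.truth.data == VESSEL) & nod
        lab, comps = split_components(inner)
        comps = find_entering_vessels(comps, lab, outer, nod, b.truth.spacing)
        d_outs = [c.d_out for c in comps if c.entering_vessel_id is not None]
        assert d_outs, "the crossing tube should have an entering vessel"
        assert max(d_outs) == pytest.approx(2.5, rel=0.2)  # true tube diameter


class TestOuterVesselMask:
    def test_external_mask_bypasses_default(self, simple_phantom):
        from subsolidseg import pipeline
        from subsolidseg.standardize import resample_labels

        cfg = pipeline.PipelineConfig()
        vol_std = pipeline.standardize_scan(simple_phantom.volume, cfg)
        nod = resample_labels(simple_phantom.nodule, vol_std)
        ext = resample_labels(simple_phantom.outer_vessels, vol_std)
        out = outer_vessel_mask(vol_std, np.ones(vol_std.shape, bool), nod, external_mask=ext)
        np.testing.assert_array_equal(out.data > 0, (ext.data > 0) & ~(nod.data > 0))

    def test_default_segmenter_covers_phantom_tube(self, simple_phantom):
        from subsolidseg import pipeline
        from subsolidseg.standardize import resample_labels

        cfg = pipeline.PipelineConfig()
        vol_std = pipeline.standardize_scan(simple_phantom.volume, cfg)
        nod = resample_labels(simple_phantom.nodule, vol_std)
        true_outer = resample_labels(simple_phantom.outer_vessels, vol_std).data > 0
        out = outer_vessel_mask(vol_std, np.ones(vol_std.shape, bool), nod)
        coverage = (out.data.astype(bool) & true_outer).sum() / true_outer.sum()
        assert coverage >= 0.8

    def test_vessel_free_volume_gives_empty_mask(self):
        rng = np.random.default_rng(1)
        vol = Volume(rng.normal(-900.0, 15.0, (24, 24, 24)), ISO)
        nod = np.zeros((24, 24, 24), dtype=bool)
        nod[10:14, 10:14, 10:14] = True
        out = outer_vessel_mask(vol, np.ones((24, 24, 24), bool), nod)
        assert out.data.sum() == 0

    def test_empty_roi_raises(self):
        vol = Volume(np.zeros((8, 8, 8)), ISO)
        with pytest.raises(ValueError, match="ROI"):
            outer_vessel_mask(vol, np.zeros((8, 8, 8), bool), np.zeros((8, 8, 8), bool))


class TestApplyContinuity:
    def _stack_and_labels(self, seed=0, shape=(8, 8, 8)):
        rng = np.random.default_rng(seed)
        mask = np.ones(shape, dtype=bool)
        p = rng.dirichlet(np.ones(3), size=shape).transpose(3, 0, 1, 2)
        return PosteriorStack(p, mask, ISO), ClassWeights(0.23, 0.13, 0.64)

    def test_unit_field_reproduces_initial_segmentation(self):
        from subsolidseg.classify import initial_segmentation

        stack, w = self._stack_and_labels()
        field = ContinuityField(np.ones(stack.mask.shape), np.zeros(stack.mask.shape))
        final = apply_continuity(stack, w, field, stack.mask)
        initial = initial_segmentation(stack, w, stack.mask)
        np.testing.assert_array_equal(final.data, initial.data)

    def test_zeroed_component_flips_to_core_or_ground_glass(self):
        stack, w = self._stack_and_labels(seed=2)
        field = ContinuityField(np.zeros(stack.mask.shape), np.zeros(stack.mask.shape))
        final = apply_continuity(stack, w, field, stack.mask, smooth=False)
        assert not np.any(final.data == VESSEL)

    def test_bulge_hand_example(self):
        # w_vc = 0.25 (ratio 2.5 at a=3), P=(0.6,0.1,0.3), w=(0.23,0.13,0.64):
        # L_v = 0.23*0.25*0.6 = 0.0345 < L_g = 0.192 -> ground-glass
        p = np.zeros((3, 1, 1, 1))
        p[:, 0, 0, 0] = [0.6, 0.1, 0.3]
        stack = PosteriorStack(p, np.ones((1, 1, 1), bool), ISO)
        assert continuity_weight(2.5, 1.0, 3.0) == pytest.approx(0.25)
        field = ContinuityField(np.full((1, 1, 1), 0.25), np.zeros((1, 1, 1)))
        final = apply_continuity(stack, ClassWeights(0.23, 0.13, 0.64), field, smooth=False)
        assert final.data[0, 0, 0] == GROUND_GLASS

    def test_shrinkage_final_vessels_subset_of_initial(self):
        from subsolidseg.classify import initial_segmentation

        for seed in range(3):
            stack, w = self._stack_and_labels(seed=seed)
            rng = np.random.default_rng(seed + 100)
            field = ContinuityField(
                rng.random(stack.mask.shape), np.zeros(stack.mask.shape)
            )
            initial = initial_segmentation(stack, w, stack.mask, smooth=False)
            final = apply_continuity(stack, w, field, stack.mask, smooth=False)
            assert np.all((final.data == VESSEL) <= (initial.data == VESSEL))

    def test_misaligned_field_raises(self):
        stack, w = self._stack_and_labels()
        field = ContinuityField(np.ones((4, 4, 4)), np.zeros((4, 4, 4)))
        with pytest.raises(ValueError, match="does not match"):
            apply_continuity(stack, w, field)


class TestComputeContinuityField:
    def test_phantom_unattached_blob_weight_zero_and_tube_kept(self, simple_phantom):
        """A blob with no entering vessel gets w_vc 0; a constant-calibre
        crossing tube keeps w_vc >= 0.9 on >= 90% of its voxels."""
        from subsolidseg import pipeline
        from subsolidseg.standardize import resample_labels

        cfg = pipeline.PipelineConfig()
        vol_std = pipeline.standardize_scan(simple_phantom.volume, cfg)
        nod = resample_labels(simple_phantom.nodule, vol_std)
        outer = resample_labels(simple_phantom.outer_vessels, vol_std)
        truth = resample_labels(simple_phantom.truth, vol_std)
        # initial labels = truth vessels plus an artificial unattached blob
        labels = np.where((truth.data == VESSEL) & (nod.data > 0), VESSEL, 0)
        blob = np.zeros(labels.shape, dtype=bool)
        zc, yc, xc = 40, 45, 45  # inside the nodule, clear of tube and core
        blob[zc - 2 : zc + 2, yc - 2 : yc + 2, xc - 2 : xc + 2] = True
        blob &= nod.data > 0
        blob &= labels == 0
        labels[blob] = VESSEL
        lm = LabelMap(labels.astype(np.int16), vol_std.spacing)
        field = compute_continuity_field(lm, nod, outer)
        assert blob.any()
        assert np.all(field.w_vc[blob] == 0.0)
        tube = (truth.data == VESSEL) & (nod.data > 0) & ~blob
        frac = (field.w_vc[tube] >= 0.9).mean()
        assert frac >= 0.9
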