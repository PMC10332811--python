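"""Background thresholding, lipofuscin masking and per-cell quantification."""

import numpy as np
import pytest
from scipy import ndimage

from stpkit import (
    Blob,
    SyntheticVolumeSpec,
    background_threshold,
    depth_profile,
    lipofuscin_mask,
    quantify_cell,
    simulate_mfish_volume,
)
from stpkit.fish import CellExpression

HWHM_GAUSS = np.sqrt(2 * np.log(2))  # = HWHM / sigma


class TestBackgroundThreshold:
    def test_gaussian_matches_analytic_value(self, rng):
        vals = rng.normal(100.0, 10.0, size=300_000)
        bm = background_threshold(vals.reshape(30, 100, 100),
                                  np.ones((30, 100, 100), bool))
        assert bm.threshold == pytest.approx(100 + 3 * 10 * HWHM_GAUSS, rel=0.02)
        assert bm.threshold == bm.median + 3 * bm.hwhm  # exact identity

    def test_constant_background_rejected(self):
        vol = np.full((4, 8, 8), 7.0)
        with pytest.raises(ValueError):
            background_threshold(vol, np.ones_like(vol, bool))

    def test_scale_equivariance(self, rng):
        vals = rng.normal(50.0, 5.0, size=(10, 40, 40))
        mask = np.ones_like(vals, bool)
        t1 = background_threshold(vals, mask).threshold
        t2 = background_threshold(vals * 3.0, mask).threshold
        assert t2 == pytest.approx(3.0 * t1, rel=1e-6)


class TestLipofuscinMask:
    def make_volume(self):
        spec = SyntheticVolumeSpec(
            shape=(16, 64, 64),
            lipofuscin_blobs=[Blob((8, 16, 16), 3.0, 400.0)],
            spots=[Blob((8, 48, 48), 2.0, 400.0, channel=0)],
        )
        stack, truth = simulate_mfish_volume(spec, seed=0)
        noncell = np.ones(stack.shape[1:], bool)
        thr = np.array(
            [background_threshold(stack[c], noncell).threshold
             for c in range(stack.shape[0])]
        )
        return stack, truth, thr

    def test_blob_fully_recalled_within_two_voxel_ring(self):
        stack, truth, thr = self.make_volume()
        mask = lipofuscin_mask(stack, thr)
        blob = truth.lipofuscin_mask
        assert (mask & blob).sum() == blob.sum()  # recall 1.0
        struct = ndimage.generate_binary_structure(3, 1)
        ring = ndimage.binary_dilation(blob, struct, iterations=2)
        assert not (mask & ~ring).any()  # extends at most 2 voxels

    def test_single_channel_spot_not_masked(self):
        stack, truth, thr = self.make_volume()
        mask = lipofuscin_mask(stack, thr)
        assert (mask & truth.spot_masks[0]).sum() == 0

    def test_empty_volume_gives_empty_mask(self, rng):
        stack = rng.normal(100, 10, size=(3, 8, 16, 16))
        mask = lipofuscin_mask(stack, np.full(3, 1e6))
        assert not mask.any()

    def test_requires_two_channels(self, rng):
        with pytest.raises(ValueError):
            lipofuscin_mask(rng.normal(size=(1, 4, 8, 8)), np.array([0.0]))


class TestQuantifyCell:
    def setup_method(self):
        self.shape = (4, 10, 10)
        self.cell = np.zeros(self.shape, bool)
        self.cell[1:3, 2:7, 2:7] = True  # 50 voxels
        self.thr = np.array([100.0])

    def test_uniform_intensity_above_threshold(self):
        stack = np.full((1, *self.shape), 105.0)
        ce = quantify_cell(stack, self.cell, np.zeros(self.shape, bool), self.thr)
        assert ce.expression[0] == pytest.approx(5.0)
        assert ce.cell_volume == 50

    def test_half_masked_halves_sum_but_not_volume(self):
        stack = np.full((1, *self.shape), 105.0)
        lipo = np.zeros(self.shape, bool)
        lipo[1] = True  # masks exactly half the cell
        ce = quantify_cell(stack, self.cell, lipo, self.thr)
        assert ce.expression[0] == pytest.approx(2.5)
        assert ce.masked_voxels == 25

    def test_subthreshold_intensity_gives_zero(self):
        stack = np.full((1, *self.shape), 99.0)
        ce = quantify_cell(stack, self.cell, np.zeros(self.shape, bool), self.thr)
        assert ce.expression[0] == 0.0

    def test_fully_masked_cell_flagged(self):
        stack = np.full((1, *self.shape), 105.0)
        ce = quantify_cell(stack, self.cell, np.ones(self.shape, bool), self.thr)
        assert ce.fully_masked
        assert ce.expression[0] == 0.0

    def test_additive_over_disjoint_submasks(self, rng):
        stack = rng.uniform(90, 130, size=(1, *self.shape))
        lipo = rng.random(self.shape) < 0.2
        half_a = self.cell.copy()
        half_a[2:] = False
        half_b = self.cell & ~half_a
        full = quantify_cell(stack, self.cell, lipo, self.thr)
        a = quantify_cell(stack, half_a, lipo, self.thr)
        b = quantify_cell(stack, half_b, lipo, self.thr)
        total = a.expression * a.cell_volume + b.expression * b.cell_volume
        assert total[0] == pytest.approx(full.expression[0] * full.cell_volume)


class TestDepthProfile:
    def make_cells(self, z_values, expr):
        return [
            CellExpression(f"c{i}", np.array([e]), 0, 10, (z, 5.0, 5.0))
            for i, (z, e) in enumerate(zip(z_values, expr))
        ]

    def test_flat_profile_no_slope(self, rng):
        z = np.linspace(0, 30, 20)
        cells = self.make_cells(z, 5.0 + rng.normal(0, 0.2, 20))
        _, reg = depth_profile(cells)
        assert reg.p_value > 0.05

    def test_attenuation_detected(self, rng):
        z = np.linspace(0, 30, 20)
        cells = self.make_cells(z, 10.0 - 0.2 * z + rng.normal(0, 0.1, 20))
        _, reg = depth_profile(cells)
        assert reg.slope < 0
        assert reg.p_value < 0.01

    def test_single_cell_no_test(self):
        df, reg = depth_profile(self.make_cells([5.0], [2.0]))
        assert len(df) == 1 and reg is None
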