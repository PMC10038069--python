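"""Segmentation: composite channel arithmetic, nucleus detection on known
geometry, the area gate, aggressiveness-controlled splitting, and the
ring-assignment rule checked against a brute-force pixel oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage as ndi

from immunobud import segment
from immunobud.segment import SegmentationParams, composite_nuclear_channel
from immunobud.synthgen import TissueSimParams, simulate_multiplex_image

PX = 0.5  # um per pixel used by the constructed rasters


def disk_image(centers_um, radii_um, shape_px, value=0.9, px=PX):
    img = np.zeros(shape_px)
    yy, xx = np.mgrid[: shape_px[0], : shape_px[1]]
    for (cx, cy), r in zip(centers_um, radii_um):
        d = np.hypot((xx + 0.5) * px - cx, (yy + 0.5) * px - cy)
        img[d <= r] = value
    return img


class TestComposite:
    def test_dapi_only_image_reduces_to_normalized_dapi(self):
        rng = np.random.default_rng(0)
        dapi = rng.uniform(size=(20, 20))
        img = np.zeros((4, 20, 20))
        img[0] = dapi
        out = composite_nuclear_channel(img, (5, 0.15, 0.243, 0.113))
        expected = (dapi - dapi.min()) / (dapi.max() - dapi.min())
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_constant_image_maps_to_zeros(self):
        img = np.full((4, 5, 5), 0.3)
        assert composite_nuclear_channel(img).max() == 0.0

    def test_two_pixel_normalization(self):
        img = np.zeros((4, 1, 2))
        img[1, 0, 1] = 2.0
        out = composite_nuclear_channel(img, (0, 1, 0, 0))
        np.testing.assert_array_equal(out, [[0.0, 1.0]])

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="weight"):
            composite_nuclear_channel(np.zeros((4, 3, 3)), (0, 0, 0, 0))

    def test_nan_pixel_named_in_error(self):
        img = np.zeros((4, 3, 3))
        img[2, 1, 2] = np.nan
        with pytest.raises(ValueError, match="channel=2, y=1, x=2"):
            composite_nuclear_channel(img)


class TestSegmentNuclei:
    def test_recovers_well_separated_blobs_exactly(self):
        centers = [(20 + 30 * i, 20 + 25 * j) for i in range(3) for j in range(3)]
        img = disk_image(centers, [4.0] * 9, (200, 250))
        labels, cells = segment.segment_nuclei(img, SegmentationParams(), PX)
        assert len(cells) == 9
        got = cells[["x", "y"]].to_numpy()
        for cx, cy in centers:
            d = np.hypot(got[:, 0] - cx, got[:, 1] - cy)
            assert d.min() <= PX  # centroid within one pixel of truth

    def test_oversized_blob_filtered_by_area_gate(self):
        # one 500 um^2 blob (r ~ 12.6 um) and one normal nucleus
        img = disk_image([(40, 40), (90, 40)], [12.62, 4.0], (160, 260))
        labels, cells = segment.segment_nuclei(img, SegmentationParams(), PX)
        assert len(cells) == 1
        assert abs(cells.x.iloc[0] - 90) < 1.0
        assert (cells.nucleus_area <= 450).all()

    def test_dumbbell_split_depends_on_aggressiveness(self):
        # two r=4 um disks, centers 7 um apart: one merged foreground blob
        img = disk_image([(40, 40), (47, 40)], [4.0, 4.0], (160, 180))
        hi = SegmentationParams(aggressiveness=0.75)
        lo = SegmentationParams(aggressiveness=0.0)
        _, cells_hi = segment.segment_nuclei(img, hi, PX)
        _, cells_lo = segment.segment_nuclei(img, lo, PX)
        assert len(cells_hi) == 2
        assert len(cells_lo) == 1

    def test_raising_min_intensity_never_adds_cells(self):
        p = TissueSimParams(
            window_width=300, window_height=300, nest_rate=0, bud_rate=80,
            bud_sigma=10, cd8_intensity=100, seed=6,
        )
        img, _ = simulate_multiplex_image(p)
        comp = composite_nuclear_channel(img)
        counts = []
        for thr in (0.01, 0.032, 0.2, 0.5, 0.95):
            _, cells = segment.segment_nuclei(
                comp, SegmentationParams(min_nuclear_intensity=thr), PX
            )
            counts.append(len(cells))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_unnormalized_raster_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            segment.segment_nuclei(np.full((10, 10), 2.0), SegmentationParams(), PX)

    def test_scale_equivariance_of_areas(self):
        img_a = disk_image([(40, 40)], [4.0], (160, 160), px=0.5)
        img_b = disk_image([(40, 40)], [4.0], (320, 320), px=0.25)
        _, ca = segment.segment_nuclei(img_a, SegmentationParams(), 0.5)
        _, cb = segment.segment_nuclei(img_b, SegmentationParams(), 0.25)
        a, b = ca.nucleus_area.iloc[0], cb.nucleus_area.iloc[0]
        assert abs(a - b) / b < 0.05


class TestMeasureCompartments:
    def test_uniform_channel_gives_equal_compartments(self):
        labels = np.zeros((60, 60), dtype=int)
        labels[20:30, 20:30] = 1
        img = np.full((4, 60, 60), 0.42)
        out = segment.measure_compartments(labels, img, SegmentationParams(), PX)
        for comp in ("nucleus", "cytoplasm", "membrane"):
            assert out[f"opal520_{comp}"].iloc[0] == pytest.approx(0.42)

    def test_nuclear_signal_stays_out_of_rings(self):
        labels = np.zeros((60, 60), dtype=int)
        labels[20:30, 20:30] = 1
        img = np.zeros((4, 60, 60))
        img[1][labels == 1] = 0.8
        out = segment.measure_compartments(labels, img, SegmentationParams(), PX)
        assert out["opal520_nucleus"].iloc[0] == pytest.approx(0.8)
        assert out["opal520_cytoplasm"].iloc[0] == pytest.approx(0.0)
        assert out["opal520_membrane"].iloc[0] == pytest.approx(0.0)

    def test_ring_pixels_split_by_nearest_nucleus_oracle(self):
        # two adjacent nuclei: ring ownership must match brute-force
        # per-pixel nearest-nucleus assignment, conserving total ring pixels
        labels = np.zeros((80, 80), dtype=int)
        labels[30:40, 20:30] = 1
        labels[30:40, 33:43] = 2  # 1.5 um gap
        params = SegmentationParams()
        bg = labels == 0
        dist, (iy, ix) = ndi.distance_transform_edt(bg, return_indices=True)
        nearest = labels[iy, ix]
        ring = bg & (dist * PX <= params.membrane_ring_width + params.cytoplasm_ring_width)
        brute = {lbl: int(np.sum(ring & (nearest == lbl))) for lbl in (1, 2)}

        img = np.zeros((4, 80, 80))
        rng = np.random.default_rng(1)
        img[1] = rng.uniform(size=(80, 80))
        out = segment.measure_compartments(labels, img, params, PX)
        # reconstruct implementation ring counts from the same masks
        mem = bg & (dist * PX <= params.membrane_ring_width)
        cyt = bg & (dist * PX > params.membrane_ring_width) & ring
        for lbl in (1, 2):
            impl = int(np.sum((mem | cyt) & (nearest == lbl)))
            assert impl == brute[lbl]
        assert sum(brute.values()) == int(ring.sum())

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError, match="congruent"):
            segment.measure_compartments(
                np.zeros((5, 5), dtype=int), np.zeros((4, 6, 6)), SegmentationParams(), PX
            )
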