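"""Segmentation, per-cell measurement and spot assignment."""

import numpy as np
import pandas as pd
import pytest

import csma
from csma.errors import ConfigurationError, DimensionError
from csma.imaging import LabelMask
from csma.simgen import FieldImage


def disk_image(centers, radius=8, value=500.0, shape=(128, 128), background=0.0):
    img = np.full(shape, background)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for cy, cx in centers:
        img[np.hypot(yy - cy, xx - cx) <= radius] = value
    return img


class TestSegmentNuclei:
    def test_blank_image_gives_zero_labels(self):
        mask = csma.segment_nuclei(np.zeros((64, 64)), pixel_size_um=1.0)
        assert mask.n_labels == 0

    def test_noise_only_image_gives_zero_labels(self):
        rng = np.random.default_rng(0)
        mask = csma.segment_nuclei(100 + rng.normal(0, 5, (128, 128)), pixel_size_um=1.0)
        assert mask.n_labels == 0

    def test_separated_disks_recovered_with_centroids(self):
        centers = [(r, c) for r in (20, 60, 100) for c in (20, 60, 100)][:9]
        img = disk_image(centers, background=50.0)
        mask = csma.segment_nuclei(img, pixel_size_um=1.0)
        assert mask.n_labels == 9
        image = FieldImage(channels={"dapi": img}, pixel_size_um=1.0)
        rec = csma.measure_cells(mask, image, ring_channels=())
        found = rec[["y_um", "x_um"]].to_numpy()
        for cy, cx in centers:
            d = np.hypot(found[:, 0] - cy, found[:, 1] - cx).min()
            assert d <= 1.0

    def test_touching_disks_split_by_watershed(self):
        # centers 1.6 radii apart: substantial overlap, one connected blob
        img = disk_image([(64, 52), (64, 52 + 13)], radius=8, background=20.0)
        mask = csma.segment_nuclei(img, pixel_size_um=1.0)
        assert mask.n_labels == 2

    def test_segmentation_is_deterministic(self):
        t = csma.SpotTruth(spot_id=0)
        img = csma.render_spot_image(csma.simulate_spot_cells(t, seed=2), seed=3)
        a = csma.segment_nuclei(img.channels["dapi"], pixel_size_um=img.pixel_size_um)
        b = csma.segment_nuclei(img.channels["dapi"], pixel_size_um=img.pixel_size_um)
        assert np.array_equal(a.labels, b.labels)

    def test_non_2d_input_rejected(self):
        with pytest.raises(DimensionError):
            csma.segment_nuclei(np.zeros((4, 4, 4)))


class TestMeasureCells:
    def test_uniform_disk_integrated_is_area_times_mean(self):
        img = disk_image([(32, 32)], radius=6, value=123.0, shape=(64, 64))
        labels = (img > 0).astype(np.int32)
        rec = csma.measure_cells(
            LabelMask(labels, 1.0),
            FieldImage(channels={"dapi": img}, pixel_size_um=1.0),
            ring_channels=(),
            background_subtract=False,
        )
        area = labels.sum()
        assert rec.nuclear_area_px.iloc[0] == area
        assert rec.dapi_int.iloc[0] == pytest.approx(area * 123.0)
        assert rec.dapi_mean.iloc[0] == pytest.approx(123.0)

    def test_rings_exclude_neighbor_nuclei(self):
        """Neither ring of two adjacent cells may include nuclear pixels."""
        labels = np.zeros((64, 96), dtype=np.int32)
        yy, xx = np.mgrid[0:64, 0:96]
        labels[np.hypot(yy - 32, xx - 38) <= 8] = 1
        labels[np.hypot(yy - 32, xx - 58) <= 8] = 2
        # distinct nuclear marker values; cytoplasm channel zero everywhere
        chan = np.where(labels == 1, 1000.0, np.where(labels == 2, 2000.0, 0.0))
        img = FieldImage(channels={"tugfp": chan}, pixel_size_um=1.0)
        rec = csma.measure_cells(
            LabelMask(labels, 1.0), img, ring_width_px=15, background_subtract=False
        )
        # rings cover only background pixels (value 0): any nuclear bleed-in
        # from the neighbor would lift the ring mean above zero
        assert rec.tugfp_ring_mean.to_numpy() == pytest.approx([0.0, 0.0])

    def test_integrated_intensity_additive_under_merge(self):
        img = disk_image([(32, 20), (32, 44)], radius=6, value=77.0, shape=(64, 64))
        labels = np.zeros_like(img, dtype=np.int32)
        yy, xx = np.mgrid[0:64, 0:64]
        labels[np.hypot(yy - 32, xx - 20) <= 6] = 1
        labels[np.hypot(yy - 32, xx - 44) <= 6] = 2
        field = FieldImage(channels={"dapi": img}, pixel_size_um=1.0)
        parts = csma.measure_cells(
            LabelMask(labels, 1.0), field, ring_channels=(), background_subtract=False
        )
        merged = csma.measure_cells(
            LabelMask((labels > 0).astype(np.int32), 1.0),
            field,
            ring_channels=(),
            background_subtract=False,
        )
        assert merged.dapi_int.sum() == pytest.approx(parts.dapi_int.sum())

    def test_shape_mismatch_rejected(self):
        with pytest.raises(DimensionError):
            csma.measure_cells(
                LabelMask(np.zeros((8, 8), dtype=np.int32), 1.0),
                FieldImage(channels={"dapi": np.zeros((9, 9))}, pixel_size_um=1.0),
            )


class TestAssignCells:
    @pytest.fixture()
    def layout(self):
        return csma.build_layout(1, 2, pitch_um=500, diameter_um=200)

    def cells_at(self, xy):
        return pd.DataFrame(
            {"x_um": [p[0] for p in xy], "y_um": [p[1] for p in xy], "nuclear_area_um2": 78.5}
        )

    def test_cell_at_center_included(self, layout):
        out = csma.assign_cells_to_spots(self.cells_at([(0.0, 0.0)]), layout)
        assert out.spot_id.iloc[0] == 0 and not out.excluded.iloc[0]

    def test_boundary_cell_excluded(self, layout):
        out = csma.assign_cells_to_spots(self.cells_at([(0.0, 110.01)]), layout, margin_um=10.0)
        assert bool(out.excluded.iloc[0])
        out2 = csma.assign_cells_to_spots(self.cells_at([(0.0, 109.99)]), layout, margin_um=10.0)
        assert not bool(out2.excluded.iloc[0])

    def test_equidistant_tie_goes_to_lower_spot_id(self, layout):
        out = csma.assign_cells_to_spots(self.cells_at([(250.0, 0.0)]), layout)
        assert out.spot_id.iloc[0] == 0

    def test_exclusion_monotone_in_margin(self, layout):
        rng = np.random.default_rng(0)
        cells = self.cells_at(list(zip(rng.uniform(-300, 800, 200), rng.uniform(-300, 300, 200))))
        margins = [0.0, 5.0, 20.0, 80.0]
        excl = [
            csma.assign_cells_to_spots(cells, layout, margin_um=m).excluded.to_numpy()
            for m in margins
        ]
        for a, b in zip(excl, excl[1:]):
            assert not (~a & b).any()  # enlarging the margin never excludes anew

    def test_empty_layout_rejected(self):
        empty = csma.ArrayLayout(spots=[], pitch_um=500, n_wells=1)
        with pytest.raises(ConfigurationError):
            csma.assign_cells_to_spots(self.cells_at([(0, 0)]), empty)


class TestIO:
    def test_field_tiff_round_trip(self, tmp_path):
        t = csma.SpotTruth(mean_cells=5, sd_cells=0)
        img = csma.render_spot_image(csma.simulate_spot_cells(t, seed=1), seed=2, spot_id=7)
        path = tmp_path / "f.tif"
        csma.write_field_tiff(img, path)
        back = csma.read_field_tiff(path)
        assert back.spot_id == 7
        assert back.pixel_size_um == img.pixel_size_um
        assert back.origin_um == pytest.approx(img.origin_um)
        for ch in img.channels:
            np.testing.assert_allclose(back.channels[ch], img.channels[ch], rtol=1e-6)

    def test_cells_csv_round_trip(self, tmp_path, null_spot_cells):
        path = tmp_path / "cells.csv"
        csma.write_cells(null_spot_cells, path)
        back = csma.read_cells(path)
        assert len(back) == len(null_spot_cells)
        np.testing.assert_allclose(back.dapi_int, null_spot_cells.dapi_int)
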