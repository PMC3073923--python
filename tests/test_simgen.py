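"""Synthetic population statistics, image formation and screen simulation."""

import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal
from scipy import ndimage as ndi

import csma
from csma.errors import ConfigurationError, PackingError


class TestSpotPopulations:
    def test_cell_count_matches_reference_mean(self):
        counts = [
            len(csma.simulate_spot_cells(csma.SpotTruth(), seed=s, enforce_spacing=False))
            for s in range(100)
        ]
        assert 50 <= np.mean(counts) <= 52  # 51 +/- 3 per 200 um spot

    def test_zero_sd_gives_exact_count(self):
        t = csma.SpotTruth(mean_cells=20, sd_cells=0)
        assert all(
            len(csma.simulate_spot_cells(t, seed=s, enforce_spacing=False)) == 20
            for s in range(5)
        )

    def test_full_silencing_zeroes_target_channel(self):
        t = csma.SpotTruth(knockdown_frac=1.0, transfection_frac=1.0)
        cells = csma.simulate_spot_cells(t, seed=1, enforce_spacing=False)
        assert (cells.tugfp_mean_true == 0).all()

    def test_marker_mutual_exclusivity(self, big_population):
        cells, _ = big_population
        apo = cells[cells.apoptotic]
        cyc = cells[~cells.apoptotic]
        model = csma.DEFAULT_MODEL
        # apoptotic cells: cPARP elevated, Ki-67 at the negative floor
        assert (apo.cparp_mean_true > model.cparp_baseline_mean).all()
        assert apo.ki67_mean_true.median() < 0.5 * cyc.ki67_mean_true.median()
        # cycling cells stay at cPARP baseline: none reaches the apoptotic range
        assert cyc.cparp_mean_true.max() < 2 * model.cparp_baseline_mean

    def test_dna_content_ratio_between_g2_and_g1(self, big_population):
        cells, _ = big_population
        g1 = cells[cells.phase == "G1S"].dapi_int_true.mean()
        g2 = cells[cells.phase == "G2"].dapi_int_true.mean()
        assert g2 / g1 == pytest.approx(2.0, abs=0.05)

    def test_ki67_monotone_over_phases(self, big_population):
        cells, _ = big_population
        cyc = cells[~cells.apoptotic]
        means = cyc.groupby("phase").ki67_mean_true.mean()
        assert means["G1S"] < means["G2"] < means["M"]

    def test_apoptosis_lowers_spot_index(self):
        """More planted apoptosis must strictly lower the Ki-67/cPARP index."""

        def mean_index(af, seed):
            rows = []
            for i in range(30):
                t = csma.SpotTruth(spot_id=i, apoptosis_frac=af)
                rec = csma.truth_to_records(
                    csma.simulate_spot_cells(t, seed=seed + i, enforce_spacing=False), t
                )
                rows.append(rec)
            spots = csma.spot_index(csma.aggregate_spots(pd.concat(rows)), pseudo=0.0)
            return spots["index"].mean()

        assert mean_index(0.5, 100) < mean_index(0.05, 200)

    def test_packing_error_when_disk_overfull(self):
        t = csma.SpotTruth(mean_cells=400, sd_cells=0, spot_diameter_um=100)
        with pytest.raises(PackingError):
            csma.simulate_spot_cells(t, seed=0, enforce_spacing=True)


class TestRendering:
    def test_empty_field_is_background(self):
        img = csma.render_spot_image(
            csma.simulate_spot_cells(csma.SpotTruth(mean_cells=0, sd_cells=0), seed=0),
            noise_sd=5.0,
            background=100.0,
            seed=1,
        )
        dapi = img.channels["dapi"]
        assert abs(dapi.mean() - 100.0) < 3 * 5.0 / np.sqrt(dapi.size)

    def test_single_cell_single_component(self):
        t = csma.SpotTruth(mean_cells=1, sd_cells=0)
        cells = csma.simulate_spot_cells(t, seed=3)
        img = csma.render_spot_image(cells, noise_sd=0.0, background=10.0, seed=0)
        lab, n = ndi.label(img.channels["dapi"] > 50)
        assert n == 1

    def test_ring_recovers_cytoplasm_value(self):
        t = csma.SpotTruth(mean_cells=1, sd_cells=0, transfection_frac=0.0)
        cells = csma.simulate_spot_cells(t, seed=5)
        v = float(cells.tugfp_mean_true.iloc[0])
        img = csma.render_spot_image(cells, noise_sd=0.0, background=0.0, seed=0)
        mask = csma.segment_nuclei(img.channels["dapi"], pixel_size_um=img.pixel_size_um)
        rec = csma.measure_cells(mask, img, ring_width_px=10, background_subtract=False)
        assert rec.tugfp_ring_mean.iloc[0] == pytest.approx(v, rel=0.02)


class TestScreenSimulation:
    def test_fixed_seed_reproduces_truth_tables(self, small_layout):
        ids = sorted(
            {s.sample_id for s in small_layout.occupied() if s.sample_id != csma.CONTROL_ID}
        )
        eff = csma.null_effects(ids)
        a = csma.simulate_screen(small_layout, eff, n_replicates=2, seed=9)
        b = csma.simulate_screen(small_layout, eff, n_replicates=2, seed=9)
        assert_frame_equal(a.cells, b.cells)
        assert_frame_equal(a.spot_truth, b.spot_truth)
        assert_frame_equal(a.cell_truth, b.cell_truth)

    def test_missing_effect_entry_rejected(self, small_layout):
        eff = csma.null_effects(["not_on_the_array"])
        with pytest.raises(ConfigurationError):
            csma.simulate_screen(small_layout, eff, seed=0)

    def test_null_targets_indistinguishable_from_controls(self):
        """With null effects everywhere, target z and control z agree (KS)."""
        from scipy import stats

        lay = csma.build_layout(24, 20, 500, 200, n_pins=4)
        sheet = csma.SampleSheet.from_gene_list([f"G{i:03d}" for i in range(192)], 2)
        lay = csma.assign_samples(lay, sheet, 0.05, seed=2)  # 384 targets + 20 controls
        ids = sorted({s.sample_id for s in lay.occupied() if s.sample_id != csma.CONTROL_ID})
        sim = csma.simulate_screen(lay, csma.null_effects(ids), n_replicates=2, seed=4)
        out = csma.score_arrays(sim.cells)
        target_z = out["results"]["combined_z"].dropna()
        control_z = out["control_z"].mean(axis=1).dropna()
        assert stats.ks_2samp(target_z, control_z).pvalue > 0.01

    def test_planting_helpers_are_consistent(self):
        # contamination-aware shift exceeds the naive 3 s.d. target
        shift = csma.planted_shift_for_z(-3, 984, 20)
        assert shift < -3
        # the Ki-67 scale compensates the apoptotic floor: stronger than naive
        s = csma.ki67_scale_for_index_shift(-1.0)
        assert 0 < s < 0.5
        assert csma.ki67_scale_for_index_shift(0.0) == pytest.approx(1.0)

    def test_latent_sd_for_correlation_closed_form(self):
        assert csma.latent_sd_for_correlation(0.8, 0.25) == pytest.approx(0.5)
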