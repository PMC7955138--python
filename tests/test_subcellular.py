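"""Region geometry, intensity ratiometry, spot colocalization, trafficking."""

import math

import numpy as np
import pytest

import morphoquant as mq

from conftest import disc


class TestRegionMasks:
    def test_five_px_periphery_area_matches_annulus(self):
        cell = disc((120, 120), 60, 60, 50)
        nuc = disc((120, 120), 60, 60, 10)
        rm = mq.build_region_masks(cell, nuc, mode="five_px_periphery")
        expected = math.pi * (50**2 - 45**2)
        assert rm.peripheral.sum() == pytest.approx(expected, rel=0.05)

    def test_membrane_band_spans_45_to_52(self):
        cell = disc((120, 120), 60, 60, 50)
        nuc = disc((120, 120), 60, 60, 10)
        rm = mq.build_region_masks(cell, nuc, mode="membrane_band")
        yy, xx = np.nonzero(rm.peripheral)
        r = np.hypot(yy - 60, xx - 60)
        assert r.min() >= 44.0 and r.max() <= 52.5
        assert (rm.peripheral & ~cell).any()   # band extends outside the cell

    def test_degenerate_nucleus_equals_cell(self):
        cell = disc((60, 60), 30, 30, 20)
        rm = mq.build_region_masks(cell, cell.copy(), mode="five_px_periphery")
        assert not rm.cytoplasm.any()
        assert not rm.peripheral.any()

    def test_nucleus_outside_cell_rejected(self):
        cell = disc((60, 60), 30, 30, 10)
        nuc = disc((60, 60), 30, 45, 8)
        with pytest.raises(ValueError, match="contained"):
            mq.build_region_masks(cell, nuc)

    @pytest.mark.parametrize("mode", ["membrane_band", "five_px_periphery"])
    def test_partition_invariants(self, mode):
        cell = disc((100, 100), 50, 50, 35)
        nuc = disc((100, 100), 48, 52, 12)
        rm = mq.build_region_masks(cell, nuc, mode=mode)
        rm.validate()
        assert not (rm.peripheral & rm.nucleus).any()
        assert not (rm.cytoplasm & rm.peripheral).any()
        assert not (rm.cytoplasm & rm.nucleus).any()
        from scipy import ndimage as ndi
        dilated = ndi.binary_dilation(cell, iterations=2)
        union = rm.peripheral | rm.nucleus | rm.cytoplasm
        assert not (union & ~dilated).any()
        assert (union & cell).sum() == cell.sum()  # covers the whole cell


class TestRegionIntensity:
    def _rm(self):
        cell = disc((120, 120), 60, 60, 50)
        nuc = disc((120, 120), 60, 60, 12)
        return mq.build_region_masks(cell, nuc, mode="five_px_periphery")

    def test_uniform_image_all_ratios_one(self):
        rm = self._rm()
        out = mq.region_intensity(np.full((120, 120), 3.7), rm)
        assert np.allclose(out["ratio_to_whole_cell"], 1.0, atol=1e-12)

    def test_all_intensity_in_band_closed_form(self):
        rm = self._rm()
        img = np.where(rm.peripheral, 9.0, 0.0)
        out = mq.region_intensity(img, rm).set_index("region")
        expected = rm.cell.sum() / rm.peripheral.sum()
        assert out.loc["peripheral", "ratio_to_whole_cell"] == pytest.approx(expected, rel=1e-9)

    def test_enrichment_sweep_strictly_monotone(self):
        measured = []
        for e in (1.0, 2.0, 4.0):
            scene = mq.generate_cell_scene(
                mq.CellSceneParams(n_cells=6, peripheral_enrichment=e, seed=13, noise_sd=0.0)
            )
            vals = []
            for lab in scene.truth["cell"]:
                cell = scene.labels == lab
                nuc = scene.nuclei_labels == lab
                rm = mq.build_region_masks(cell, nuc, mode="five_px_periphery")
                out = mq.region_intensity(scene.channels["marker"], rm).set_index("region")
                vals.append(out.loc["peripheral", "ratio_to_whole_cell"])
            measured.append(np.mean(vals))
        assert measured[0] < measured[1] < measured[2]

    def test_empty_region_flagged(self):
        cell = disc((60, 60), 30, 30, 20)
        rm = mq.build_region_masks(cell, cell.copy(), mode="five_px_periphery")
        out = mq.region_intensity(np.ones((60, 60)), rm).set_index("region")
        assert out.loc["cytoplasm", "flag"] == "empty"
        assert np.isnan(out.loc["cytoplasm", "ratio_to_whole_cell"])


class TestDetectSpots:
    def test_synthetic_puncta_counted(self):
        rng = np.random.default_rng(0)
        img = np.full((200, 200), 10.0)
        pts = [(20 + 40 * i, 20 + 40 * j) for i in range(5) for j in range(4)]
        for y, x in pts:
            img[disc((200, 200), y, x, 3)] += 150.0
        img += rng.normal(0, 2, img.shape)
        labels, table = mq.detect_spots(img)
        assert abs(len(table) - 20) <= 1

    def test_blank_channel_no_spots(self):
        rng = np.random.default_rng(1)
        img = 10.0 + rng.normal(0, 2, (128, 128))
        labels, table = mq.detect_spots(img)
        assert len(table) == 0

    def test_two_puncta_at_two_radii_apart_not_merged(self):
        img = np.full((80, 80), 5.0)
        img[disc((80, 80), 40, 30, 3)] += 100.0
        img[disc((80, 80), 40, 30 + 12, 3)] += 100.0
        _, table = mq.detect_spots(img)
        assert len(table) == 2


class TestSpotOverlap:
    def test_identical_masks_100(self):
        cells = disc((60, 60), 30, 30, 25).astype(int)
        spots = disc((60, 60), 30, 30, 4)
        out = mq.spot_overlap(spots, spots.copy(), cells)
        assert out["percent_overlap"].iloc[0] == 100.0

    def test_disjoint_masks_0(self):
        cells = disc((60, 60), 30, 30, 25).astype(int)
        g = disc((60, 60), 25, 25, 3)
        r = disc((60, 60), 38, 38, 3)
        out = mq.spot_overlap(g, r, cells)
        assert out["percent_overlap"].iloc[0] == 0.0

    def test_direction_is_green_in_red(self):
        cells = np.ones((60, 60), int)
        g = disc((60, 60), 30, 30, 3)     # small green inside large red
        r = disc((60, 60), 30, 30, 10)
        fwd = mq.spot_overlap(g, r, cells)["percent_overlap"].iloc[0]
        rev = mq.spot_overlap(r, g, cells)["percent_overlap"].iloc[0]
        assert fwd == 100.0
        assert rev < 100.0

    def test_zero_green_area_flagged(self):
        cells = np.ones((20, 20), int)
        out = mq.spot_overlap(np.zeros((20, 20), bool), np.ones((20, 20), bool), cells)
        assert out["flag"].iloc[0] == "no_green_spots"
        assert np.isnan(out["percent_overlap"].iloc[0])

    def test_generator_scene_recovers_true_fraction(self, half_overlap_spot_scene):
        _, scene = half_overlap_spot_scene
        out = mq.spot_overlap(scene.green_spots, scene.red_spots, scene.cells)
        assert out["percent_overlap"].mean() == pytest.approx(50.0, abs=5.0)


class TestTraffickingProfile:
    def test_membrane_to_juxtanuclear_shift_recovered(self):
        p = mq.TraffickingSimParams(n_cells=10, seed=3)
        series = mq.generate_trafficking_series(p)
        prof = mq.trafficking_profile(series, normalise=None)
        agg = prof.groupby(["region", "time_h"])["ratio"].mean()
        memb = agg.loc["peripheral"].to_numpy()
        jn = agg.loc["juxtanuclear"].to_numpy()
        assert (np.diff(memb) < 0).all()
        assert (np.diff(jn) > 0).all()
        # recovered intensity fractions match the generator simplex within 10%
        for k, t in enumerate(p.timepoints):
            sub = prof[(prof["time_h"] == t) & (prof["region"] == "peripheral")]
            whole = prof[(prof["time_h"] == t) & (prof["region"] == "whole_cell")]
            frac = sub["total_intensity"].sum() / whole["total_intensity"].sum()
            assert frac == pytest.approx(p.membrane_fraction[k], abs=0.1)

    def test_static_simulation_ratios_constant(self):
        p = mq.TraffickingSimParams(
            n_cells=6,
            timepoints=(0.0, 0.5, 1.0),
            membrane_fraction=(0.5, 0.5, 0.5),
            cytoplasm_fraction=(0.3, 0.3, 0.3),
            juxtanuclear_fraction=(0.2, 0.2, 0.2),
            seed=5,
        )
        prof = mq.trafficking_profile(mq.generate_trafficking_series(p), normalise=None)
        spread = prof.groupby(["region", "time_h"])["ratio"].mean().groupby("region").agg(np.ptp)
        assert (spread < 0.05).all()

    def test_total_intensity_conserved(self):
        p = mq.TraffickingSimParams(n_cells=6, seed=6)
        prof = mq.trafficking_profile(mq.generate_trafficking_series(p), normalise=None)
        totals = (
            prof[prof["region"] == "whole_cell"].groupby("time_h")["total_intensity"].sum()
        )
        assert totals.max() / totals.min() == pytest.approx(1.0, abs=0.02)

    def test_single_timepoint_rejected(self):
        p = mq.TraffickingSimParams(
            timepoints=(0.0,), membrane_fraction=(1.0,), cytoplasm_fraction=(0.0,),
            juxtanuclear_fraction=(0.0,), n_cells=2,
        )
        with pytest.raises(ValueError, match="two timepoints"):
            mq.trafficking_profile(mq.generate_trafficking_series(p))
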