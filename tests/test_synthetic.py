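"""Ground-truth and reproducibility guarantees of the scene generators."""

import numpy as np
import pandas as pd
import pytest

import morphoquant as mq
from morphoquant.synthetic import _mask_compactness

from conftest import disc


class TestAcinusTimelapse:
    def test_noninvasive_acini_stay_disc_compact(self, small_acinus_timelapse):
        _, (tl, truth) = small_acinus_timelapse
        assert np.allclose(truth["compactness"], 1.0, atol=0.05)

    def test_seeded_determinism_bit_identical(self):
        p = mq.AcinusSimParams(n_acini=4, n_frames=6, seed=42)
        tl1, t1 = mq.generate_acinus_timelapse(p)
        tl2, t2 = mq.generate_acinus_timelapse(p)
        assert np.array_equal(tl1.frames, tl2.frames)
        pd.testing.assert_frame_equal(t1, t2)

    def test_protrusions_grow_feret_strictly(self, invasive_acinus_timelapse):
        _, (tl, truth) = invasive_acinus_timelapse
        for _, g in truth.groupby("acinus"):
            feret = g.sort_values("frame")["feret_max_px"].to_numpy()
            assert np.all(np.diff(feret) > 0)

    def test_overfull_field_rejected(self):
        p = mq.AcinusSimParams(n_acini=50, n_frames=4, field_size=(80, 80))
        with pytest.raises(ValueError, match="cannot place"):
            mq.generate_acinus_timelapse(p)

    @pytest.mark.parametrize("bad", [dict(radius0=0), dict(n_frames=0), dict(protrusion_rate=-1)])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            mq.AcinusSimParams(**bad)


class TestCellScene:
    def test_uniform_marker_gives_unit_enrichment(self):
        p = mq.CellSceneParams(n_cells=10, peripheral_enrichment=1.0, seed=3, noise_sd=0.0)
        scene = mq.generate_cell_scene(p)
        assert np.allclose(scene.truth["enrichment_realised"], 1.0, atol=0.1)

    def test_pure_round_proportions(self):
        p = mq.CellSceneParams(n_cells=50, class_proportions=(1.0, 0.0, 0.0), seed=3)
        scene = mq.generate_cell_scene(p)
        assert (scene.truth["shape_class"] == "round").all()

    def test_enrichment_three_exceeds_one_on_truth_image(self):
        """Recompute the periphery/interior ratio on the noiseless image."""
        ratios = {}
        for e in (1.0, 3.0):
            p = mq.CellSceneParams(n_cells=6, peripheral_enrichment=e, seed=9, noise_sd=0.0)
            scene = mq.generate_cell_scene(p)
            img = scene.channels["marker"]
            vals = []
            for lab in scene.truth["cell"]:
                cell = scene.labels == lab
                from scipy import ndimage as ndi

                din = ndi.distance_transform_edt(cell)
                periph = cell & (din <= 5)
                interior = cell & ~periph
                vals.append(img[periph].mean() / img[interior].mean())
            ratios[e] = np.mean(vals)
        assert ratios[3.0] > ratios[1.0]
        assert ratios[3.0] == pytest.approx(3.0, rel=0.1)

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            mq.CellSceneParams(class_proportions=(0.5, 0.2, 0.2))

    def test_border_fraction_places_cells_on_border(self):
        p = mq.CellSceneParams(n_cells=12, border_fraction=0.25, seed=2)
        scene = mq.generate_cell_scene(p)
        assert scene.truth["touches_border"].sum() >= 2


class TestSpotScene:
    def test_full_overlap_is_100(self):
        p = mq.SpotSceneParams(n_green=8, n_red=8, true_overlap_fraction=1.0, cell_layout=(1, 2), seed=1)
        scene = mq.generate_spot_scene(p)
        assert np.allclose(scene.truth["percent_overlap"], 100.0)

    def test_zero_overlap_is_0(self):
        p = mq.SpotSceneParams(n_green=8, n_red=8, true_overlap_fraction=0.0, cell_layout=(1, 2), seed=1)
        scene = mq.generate_spot_scene(p)
        assert np.allclose(scene.truth["percent_overlap"], 0.0)

    def test_half_overlap_by_pixel_counting(self, half_overlap_spot_scene):
        """Brute-force AND count over the truth masks validates the record."""
        _, scene = half_overlap_spot_scene
        overlap = (scene.green_spots & scene.red_spots).sum() / scene.green_spots.sum()
        assert overlap * 100 == pytest.approx(50.0, abs=5.0)
        pooled = scene.truth["overlap_area_px2"].sum() / scene.truth["green_spot_area_px2"].sum()
        assert pooled == pytest.approx(overlap, abs=1e-12)

    def test_determinism(self):
        p = mq.SpotSceneParams(seed=8)
        a, b = mq.generate_spot_scene(p), mq.generate_spot_scene(p)
        assert np.array_equal(a.green, b.green)
        assert np.array_equal(a.red, b.red)


class TestWoundSeries:
    def test_zero_closure_rate_constant_area(self):
        tl, truth = mq.generate_wound_series(mq.WoundSimParams(closure_rate=0.0, seed=1))
        assert truth["wound_area_px2"].nunique() == 1

    def test_wound_area_non_increasing(self):
        tl, truth = mq.generate_wound_series(mq.WoundSimParams(invasive=True, seed=2))
        assert (np.diff(truth["wound_area_px2"]) <= 0).all()

    def test_full_closure_frame_exists(self):
        # each edge advances 2 px/h: 40 px half-width closes by hour 20 < 24 frames
        p = mq.WoundSimParams(wound_width0=80, closure_rate=2.0, n_frames=24)
        tl, truth = mq.generate_wound_series(p)
        assert (truth["wound_area_px2"] == 0).any()

    def test_wound_inside_field_enforced(self):
        with pytest.raises(ValueError):
            mq.WoundSimParams(field_size=(64, 64), wound_width0=64)


class TestTraffickingSeries:
    def test_all_membrane_fraction_concentrates_in_band(self):
        p = mq.TraffickingSimParams(
            n_cells=4,
            timepoints=(0.0, 1.0),
            membrane_fraction=(1.0, 1.0),
            cytoplasm_fraction=(0.0, 0.0),
            juxtanuclear_fraction=(0.0, 0.0),
            noise_sd=0.0,
            seed=1,
        )
        series = mq.generate_trafficking_series(p)
        img = series.images[0]
        for rm in series.regions[0]:
            assert img[rm.peripheral].sum() >= 0.95 * img[rm.cell].sum()

    def test_all_juxtanuclear_fraction_concentrates_in_ring(self):
        p = mq.TraffickingSimParams(
            n_cells=4,
            timepoints=(0.0, 1.0),
            membrane_fraction=(0.0, 0.0),
            cytoplasm_fraction=(0.0, 0.0),
            juxtanuclear_fraction=(1.0, 1.0),
            noise_sd=0.0,
            seed=1,
        )
        series = mq.generate_trafficking_series(p)
        img = series.images[1]
        for rm in series.regions[1]:
            assert img[rm.juxtanuclear].sum() >= 0.95 * img[rm.cell | rm.peripheral].sum()

    def test_nonsimplex_fractions_rejected(self):
        with pytest.raises(ValueError, match="simplex"):
            mq.TraffickingSimParams(
                timepoints=(0.0,),
                membrane_fraction=(0.5,),
                cytoplasm_fraction=(0.2,),
                juxtanuclear_fraction=(0.2,),
            )


def test_ground_truth_compactness_matches_independent_pixel_sum():
    """The generator's recorded compactness equals a direct pixel-sum oracle."""
    m = disc((64, 64), 32, 32, 20)
    ys, xs = np.nonzero(m)
    oracle = 2 * np.pi * (((ys - ys.mean()) ** 2 + (xs - xs.mean()) ** 2).sum() / len(ys)) / len(ys)
    assert _mask_compactness(m) == pytest.approx(oracle, rel=1e-12)
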