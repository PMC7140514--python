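"""High-content imaging: segmentation, expansion, markers, neurites."""

import math

import numpy as np
import pandas as pd
import pytest
from skimage.draw import disk as draw_disk

from neurophenolab.config import SimConfig, ImagingSimConfig
from neurophenolab.errors import MissingChannelError
from neurophenolab.imaging import (ChannelStack, NucleusSet, segment_nuclei,
                                   expand_regions, score_markers,
                                   measure_neurite_length,
                                   synaptic_area_per_neurite, cellrox_fraction,
                                   skeleton_length_um)
from neurophenolab.simulate import render_synthetic_field


def rect_field(areas_px, px_um=0.25, size=512, intensity=100.0):
    """Rectangular 'nuclei' with exact pixel areas on a clean background."""
    img = np.zeros((size, size))
    col = 40
    shapes = {784: (28, 28), 800: (25, 32), 816: (24, 34)}
    for a in areas_px:
        h, w = shapes[a]
        img[100:100 + h, col:col + w] = intensity
        col += w + 60
    return ChannelStack({"hoechst": img}, px_um)


class TestSegmentNuclei:
    def test_area_cutoff_is_strict(self):
        # 0.25 um/px => 1 px = 0.0625 um^2; 784/800/816 px = 49/50/51 um^2
        stack = rect_field([784, 800, 816])
        nuclei = segment_nuclei(stack)
        assert len(nuclei) == 1
        assert nuclei.table.area_um2.iloc[0] == pytest.approx(51.0)

    def test_empty_field(self):
        stack = ChannelStack({"hoechst": np.zeros((128, 128))}, 0.5)
        assert len(segment_nuclei(stack)) == 0

    def test_missing_hoechst_channel(self):
        stack = ChannelStack({"tubb3": np.zeros((64, 64))}, 0.5)
        with pytest.raises(MissingChannelError):
            segment_nuclei(stack)

    def test_pyknotic_nuclei_excluded(self):
        cfg = SimConfig(seed=21)
        cfg.imaging.n_cells, cfg.imaging.n_neurites = 60, 0
        cfg.imaging.pyknotic_fraction = 0.25
        stack, truth = render_synthetic_field(cfg)
        nuclei = segment_nuclei(stack)
        assert len(nuclei) == int((~truth.cells.pyknotic).sum())

    def test_traced_count_monotone_in_area_min(self):
        cfg = SimConfig(seed=22)
        cfg.imaging.n_cells, cfg.imaging.n_neurites = 40, 0
        stack, _ = render_synthetic_field(cfg)
        counts = [len(segment_nuclei(stack, area_min_um2=a))
                  for a in (30.0, 50.0, 80.0, 120.0)]
        assert counts == sorted(counts, reverse=True)


def circle_nuclei(centres_radii, px_um=1.0, size=256):
    labels = np.zeros((size, size), dtype=int)
    rows = []
    for i, (centre, r) in enumerate(centres_radii, start=1):
        rr, cc = draw_disk(centre, r, shape=(size, size))
        labels[rr, cc] = i
        rows.append((i, rr.size * px_um ** 2, 100.0, centre[0], centre[1]))
    table = pd.DataFrame(rows, columns=["label", "area_um2", "mean_intensity",
                                        "centroid_row", "centroid_col"])
    return NucleusSet(labels, table, px_um)


class TestExpandRegions:
    def test_fifty_percent_area_increase(self):
        nuclei = circle_nuclei([((128, 128), 45.0)])
        regions = expand_regions(nuclei)
        ratio = regions.table.region_area_um2[0] / \
            regions.table.nucleus_area_um2[0]
        assert ratio == pytest.approx(1.50, abs=0.05)

    def test_zero_expansion_is_identity(self):
        nuclei = circle_nuclei([((100, 100), 20.0)])
        regions = expand_regions(nuclei, expansion_fraction=0.0)
        assert np.array_equal(regions.labels, nuclei.labels)

    def test_adjacent_regions_stay_disjoint(self):
        nuclei = circle_nuclei([((100, 80), 20.0), ((100, 130), 20.0)])
        regions = expand_regions(nuclei)
        a = regions.labels == 1
        b = regions.labels == 2
        assert not (a & b).any()
        assert (regions.labels[nuclei.labels == 1] == 1).all()

    def test_radius_mode_close_to_area_mode(self):
        nuclei = circle_nuclei([((128, 128), 40.0)])
        ratio = (expand_regions(nuclei, mode="radius").table.region_area_um2[0]
                 / nuclei.table.area_um2[0])
        assert ratio == pytest.approx(1.50, abs=0.08)


class TestScoreMarkers:
    def test_blank_channels_give_zero_fraction(self):
        cfg = SimConfig(seed=23)
        cfg.imaging.n_cells, cfg.imaging.n_neurites = 30, 0
        cfg.imaging.tubb3_fraction = 0.0
        stack, _ = render_synthetic_field(cfg)
        nuclei = segment_nuclei(stack)
        res = score_markers(expand_regions(nuclei), stack)
        assert res.tubb3_fraction == 0.0
        assert math.isnan(res.map2_fraction)     # no neurons to subset

    def test_saturated_markers_give_one(self):
        cfg = SimConfig(seed=24)
        cfg.imaging.n_cells, cfg.imaging.n_neurites = 30, 0
        cfg.imaging.pyknotic_fraction = 0.0
        cfg.imaging.tubb3_fraction = 1.0
        cfg.imaging.map2_fraction = 1.0
        stack, _ = render_synthetic_field(cfg)
        res = score_markers(expand_regions(segment_nuclei(stack)), stack)
        assert res.tubb3_fraction == 1.0
        assert res.map2_fraction == 1.0

    def test_fraction_recovery_within_3_sigma(self):
        cfg = SimConfig(seed=25)
        cfg.imaging.n_cells, cfg.imaging.n_neurites = 120, 0
        stack, truth = render_synthetic_field(cfg)
        res = score_markers(expand_regions(segment_nuclei(stack)), stack)
        gt = truth.cells[~truth.cells.pyknotic]
        n = len(gt)
        for name, measured, p in [
                ("tubb3", res.tubb3_fraction, gt.tubb3.mean()),
                ("map2", res.map2_fraction, gt[gt.tubb3].map2.mean()),
                ("neun", res.neun_fraction, gt[gt.tubb3].neun.mean())]:
            se = math.sqrt(p * (1 - p) / n)
            assert abs(measured - p) <= max(3 * se, 1e-12), name


class TestNeurites:
    def test_single_straight_neurite_within_5pct(self):
        cfg = SimConfig(seed=26)
        cfg.imaging = ImagingSimConfig(n_cells=0, n_neurites=1,
                                       neurite_length_um=200.0,
                                       puncta_per_channel=0)
        stack, truth = render_synthetic_field(cfg)
        L = measure_neurite_length(stack)
        assert L == pytest.approx(truth.neurite_length_um, rel=0.05)

    def test_blank_field_zero_length(self):
        stack = ChannelStack({"tubb3": np.zeros((256, 256))}, 0.5)
        assert measure_neurite_length(stack) == 0.0

    def test_two_disjoint_neurites_additive(self):
        cfg = SimConfig(seed=27)
        cfg.imaging = ImagingSimConfig(n_cells=0, n_neurites=2,
                                       neurite_length_um=100.0,
                                       puncta_per_channel=0)
        stack, truth = render_synthetic_field(cfg)
        assert truth.neurite_length_um == pytest.approx(200.0, rel=0.1)
        L = measure_neurite_length(stack)
        assert L == pytest.approx(truth.neurite_length_um, rel=0.05)

    def test_skeleton_length_of_straight_digital_line(self):
        s = np.zeros((64, 64), dtype=bool)
        s[32, 10:50] = True                       # 39 steps of 1 px
        assert skeleton_length_um(s, 2.0) == pytest.approx(39 * 2.0, rel=0.03)


class TestSynapticArea:
    def test_on_neurite_puncta_ratio(self):
        cfg = SimConfig(seed=28)
        cfg.imaging = ImagingSimConfig(n_cells=0, n_neurites=6,
                                       neurite_length_um=200.0,
                                       puncta_per_channel=80,
                                       puncta_on_neurite_fraction=1.0)
        stack, truth = render_synthetic_field(cfg)
        v = synaptic_area_per_neurite(stack, "syni")
        expected = truth.puncta["syni"]["on_tubb3_area_um2"] / \
            truth.neurite_length_um
        assert v == pytest.approx(expected, rel=0.05)

    def test_puncta_off_neurites_score_zero(self):
        cfg = SimConfig(seed=29)
        cfg.imaging = ImagingSimConfig(n_cells=0, n_neurites=4,
                                       neurite_length_um=150.0,
                                       puncta_per_channel=60,
                                       puncta_on_neurite_fraction=0.0)
        stack, truth = render_synthetic_field(cfg)
        assert truth.puncta["psd95"]["on_tubb3_area_um2"] == 0.0
        assert synaptic_area_per_neurite(stack, "psd95") == \
            pytest.approx(0.0, abs=1e-6)

    def test_doubling_puncta_doubles_metric(self):
        vals = {}
        for n_puncta in (50, 100):
            cfg = SimConfig(seed=30)
            cfg.imaging = ImagingSimConfig(n_cells=0, n_neurites=8,
                                           neurite_length_um=200.0,
                                           puncta_per_channel=n_puncta)
            stack, _ = render_synthetic_field(cfg)
            vals[n_puncta] = synaptic_area_per_neurite(stack, "syni")
        assert vals[100] == pytest.approx(2 * vals[50], rel=0.05)

    def test_zero_neurite_length_is_nan(self):
        stack = ChannelStack({"tubb3": np.zeros((128, 128)),
                              "syni": np.zeros((128, 128))}, 0.5)
        assert math.isnan(synaptic_area_per_neurite(stack, "syni"))


class TestCellrox:
    def test_fraction_recovery(self):
        cfg = SimConfig(seed=31)
        cfg.imaging.n_cells, cfg.imaging.n_neurites = 100, 0
        cfg.imaging.cellrox_fraction = 0.25
        stack, truth = render_synthetic_field(cfg)
        regions = expand_regions(segment_nuclei(stack))
        frac = cellrox_fraction(regions, stack)
        gt = truth.cells[~truth.cells.pyknotic]
        p = gt[gt.tubb3].cellrox.mean()
        se = math.sqrt(p * (1 - p) / gt.tubb3.sum())
        assert abs(frac - p) <= max(3 * se, 1e-12)

    def test_no_signal_gives_zero(self):
        cfg = SimConfig(seed=32)
        cfg.imaging.n_cells, cfg.imaging.n_neurites = 40, 0
        cfg.imaging.cellrox_fraction = 0.0
        stack, _ = render_synthetic_field(cfg)
        regions = expand_regions(segment_nuclei(stack))
        assert cellrox_fraction(regions, stack) == 0.0

    def test_signal_in_nonneurons_only_gives_zero(self):
        cfg = SimConfig(seed=33)
        cfg.imaging.n_cells, cfg.imaging.n_neurites = 60, 0
        cfg.imaging.tubb3_fraction = 0.5
        cfg.imaging.cellrox_fraction = 0.0
        cfg.imaging.cellrox_tubb3_negative_fraction = 0.8
        stack, truth = render_synthetic_field(cfg)
        regions = expand_regions(segment_nuclei(stack))
        assert cellrox_fraction(regions, stack) == 0.0


def test_identical_image_and_config_identical_outputs():
    cfg = SimConfig(seed=34)
    cfg.imaging.n_cells, cfg.imaging.n_neurites = 25, 2
    stack, _ = render_synthetic_field(cfg)
    a = score_markers(expand_regions(segment_nuclei(stack)), stack)
    b = score_markers(expand_regions(segment_nuclei(stack)), stack)
    assert a.per_cell.equals(b.per_cell)
    assert measure_neurite_length(stack) == measure_neurite_length(stack)
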