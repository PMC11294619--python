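"""Puncta detection, compartment partition, QC and pipeline behaviour."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import histoquant as hq
from histoquant.exceptions import DegenerateHistogramError, DegenerateRegionError
from histoquant.puncta import PipelineConfig

from conftest import make_rect_cell


def _disc_mask(shape, centre, radius):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return ((rr + 0.5) - centre[0]) ** 2 + ((cc + 0.5) - centre[1]) ** 2 <= radius**2


class TestApplyCellMask:
    def test_identity_under_full_mask(self):
        rng = np.random.default_rng(0)
        grid = rng.uniform(0, 10, (16, 16))
        img = hq.AnnotatedImage(channels={"c": grid}, pixel_size_um=1.0,
                                soma_mask=np.ones((16, 16), bool),
                                nucleus_mask=np.zeros((16, 16), bool))
        assert np.array_equal(hq.apply_cell_mask(img, "c"), grid)

    def test_zero_mask_blanks_everything(self):
        img = hq.AnnotatedImage(channels={"c": np.ones((8, 8))},
                                pixel_size_um=1.0,
                                soma_mask=np.zeros((8, 8), bool),
                                nucleus_mask=np.zeros((8, 8), bool))
        assert not hq.apply_cell_mask(img, "c").any()

    def test_unknown_channel_raises(self, noiseless_cell):
        img, _ = noiseless_cell
        with pytest.raises(KeyError, match="unknown channel"):
            hq.apply_cell_mask(img, "nope")

    def test_no_detection_outside_mask(self, noiseless_params):
        # adversarial: bright spots rendered outside the soma must not count
        img, truth = hq.generate_cell_image(noiseless_params)
        outside = img.channels["puncta"].copy()
        outside[0:10, 0:10] = 500.0  # far corner, outside the soma
        img.channels["puncta"] = outside
        masked = hq.apply_cell_mask(img, "puncta")
        labels, recs = hq.detect_puncta(masked, img.pixel_size_um,
                                        mask=img.soma_mask)
        assert len(recs) == len(truth.puncta_catalog)
        assert not labels[~img.soma_mask].any()


class TestDetectPuncta:
    def test_blank_grid_fixed_threshold_finds_nothing(self):
        grid = np.full((32, 32), 5.0)
        _, recs = hq.detect_puncta(grid, 1.0, threshold=10.0,
                                   mask=np.ones((32, 32), bool))
        assert recs == []

    def test_noiseless_counts_and_centroids_match_catalogue(self, noiseless_cell):
        img, truth = noiseless_cell
        masked = hq.apply_cell_mask(img, "puncta")
        _, recs = hq.detect_puncta(masked, img.pixel_size_um,
                                   mask=img.soma_mask)
        assert len(recs) == 15
        cat = np.array(sorted(t.centre_um for t in truth.puncta_catalog))
        det = np.array(sorted(r.centroid_um for r in recs))
        err = np.linalg.norm(cat - det, axis=1)
        assert err.max() <= img.pixel_size_um  # within one pixel

    def test_min_area_floor_removes_specks(self):
        grid = np.zeros((16, 16))
        grid[3, 3] = grid[10, 10] = 100.0
        _, recs = hq.detect_puncta(grid, 1.0, threshold=50.0,
                                   mask=np.ones((16, 16), bool),
                                   min_area_px=2, smooth_sigma_px=0.0)
        assert recs == []

    def test_degenerate_histogram_instructs_fixed_threshold(self):
        grid = np.full((16, 16), 7.0)
        with pytest.raises(DegenerateHistogramError, match="fixed threshold"):
            hq.detect_puncta(grid, 1.0, threshold="auto",
                             mask=np.ones((16, 16), bool))

    def test_labels_contiguous_scan_order(self, noiseless_cell):
        img, _ = noiseless_cell
        labels, recs = hq.detect_puncta(hq.apply_cell_mask(img, "puncta"),
                                        img.pixel_size_um, mask=img.soma_mask)
        present = np.unique(labels)
        assert present[0] == 0
        assert np.array_equal(present[1:], np.arange(1, len(recs) + 1))

    def test_stained_area_monotone_in_fixed_threshold(self, noiseless_cell):
        img, _ = noiseless_cell
        masked = hq.apply_cell_mask(img, "puncta")
        areas = []
        for t in np.linspace(60, 200, 8):
            _, recs = hq.detect_puncta(masked, img.pixel_size_um, threshold=t,
                                       mask=img.soma_mask)
            areas.append(sum(r.area_um2 for r in recs))
        assert all(a >= b for a, b in zip(areas, areas[1:]))


class TestPartitionCompartments:
    def test_partition_tiles_cytoplasm_exactly(self, noiseless_cell):
        img, _ = noiseless_cell
        comps = hq.partition_compartments(img.soma_mask, img.nucleus_mask,
                                          img.pixel_size_um, 2.0)
        assert np.array_equal(comps.perinuclear | comps.cytosolic,
                              comps.cytoplasm)
        assert not (comps.perinuclear & comps.cytosolic).any()

    def test_saturating_band_leaves_no_cytosol(self, noiseless_cell):
        img, _ = noiseless_cell
        comps = hq.partition_compartments(img.soma_mask, img.nucleus_mask,
                                          img.pixel_size_um, 1000.0)
        assert not comps.cytosolic.any()
        assert np.array_equal(comps.perinuclear, comps.cytoplasm)

    def test_one_pixel_band_is_thin_shell(self):
        soma = _disc_mask((64, 64), (32, 32), 25)
        nucleus = _disc_mask((64, 64), (32, 32), 10)
        comps = hq.partition_compartments(soma, nucleus, 1.0, 1.0)
        dist_ring = comps.perinuclear
        # every band pixel touches the nucleus (distance <= 1 px)
        from scipy import ndimage
        grown = ndimage.binary_dilation(nucleus)
        assert np.array_equal(dist_ring, grown & ~nucleus & soma)

    def test_annulus_area_matches_closed_form(self):
        # nucleus r=10 µm, soma r=30 µm, band 5 µm at 0.1 µm/px:
        # perinuclear area ≈ π(15² − 10²)
        px = 0.1
        shape = (700, 700)
        soma = _disc_mask(shape, (350, 350), 30 / px)
        nucleus = _disc_mask(shape, (350, 350), 10 / px)
        comps = hq.partition_compartments(soma, nucleus, px, 5.0)
        area = comps.perinuclear.sum() * px**2
        assert area == pytest.approx(np.pi * (15**2 - 10**2), rel=0.02)

    def test_empty_nucleus_raises(self):
        soma = np.ones((8, 8), bool)
        with pytest.raises(ValueError, match="nucleus"):
            hq.partition_compartments(soma, np.zeros((8, 8), bool), 1.0, 1.0)


class TestQcRatio:
    @pytest.mark.parametrize("ratio,expected_pass",
                             [(1.0, False), (1.5, False), (2.0, True), (3.0, True)])
    def test_threshold_behaviour(self, ratio, expected_pass):
        cell = make_rect_cell(ratio)
        r, ok = hq.qc_ratio_filter(cell.soma_mask, cell.nucleus_mask)
        assert r == pytest.approx(ratio)
        assert ok is expected_pass

    def test_zero_nucleus_area_raises(self):
        with pytest.raises(ValueError):
            hq.qc_ratio_filter(np.ones((4, 4), bool), np.zeros((4, 4), bool))


class TestNucleusEllipse:
    def test_circle_radius_recovered(self):
        mask = _disc_mask((256, 256), (128, 128), 100)
        e = hq.fit_nucleus_ellipse(mask, 0.1)  # radius 10 µm
        assert e.semi_major_um == pytest.approx(10.0, rel=0.02)
        assert e.semi_minor_um == pytest.approx(10.0, rel=0.02)
        assert e.mean_radius_um == pytest.approx(10.0, rel=0.02)

    def test_ellipse_mean_radius(self):
        rr, cc = np.mgrid[0:400, 0:400]
        mask = (((rr + 0.5) - 200) / 200) ** 2 + (((cc + 0.5) - 200) / 100) ** 2 <= 1
        e = hq.fit_nucleus_ellipse(mask, 0.02)  # a=4 µm, b=2 µm
        assert e.semi_major_um == pytest.approx(4.0, rel=0.02)
        assert e.semi_minor_um == pytest.approx(2.0, rel=0.02)
        assert e.mean_radius_um == pytest.approx(3.0, rel=0.02)

    def test_rotation_invariance_of_axes(self):
        from skimage.transform import rotate
        rr, cc = np.mgrid[0:400, 0:400]
        mask = (((rr + 0.5) - 200) / 120) ** 2 + (((cc + 0.5) - 200) / 60) ** 2 <= 1
        rotated = rotate(mask.astype(float), 37.0, order=0) > 0.5
        e0 = hq.fit_nucleus_ellipse(mask, 1.0)
        e1 = hq.fit_nucleus_ellipse(rotated, 1.0)
        assert e1.semi_major_um == pytest.approx(e0.semi_major_um, rel=0.02)
        assert e1.semi_minor_um == pytest.approx(e0.semi_minor_um, rel=0.02)

    def test_degenerate_region_raises(self):
        mask = np.zeros((16, 16), bool)
        mask[8, 2:10] = True  # collinear
        with pytest.raises(DegenerateRegionError):
            hq.fit_nucleus_ellipse(mask, 1.0)


class TestDistanceToNucleus:
    def test_centre_point(self):
        e = hq.puncta.NucleusEllipse(centre_um=(10, 10), semi_major_um=4,
                                     semi_minor_um=2, orientation_rad=0.0)
        d_c, d_b = hq.distance_to_nucleus((10, 10), e)
        assert d_c == 0.0
        assert d_b == -e.mean_radius_um

    @pytest.mark.parametrize("mean_r,dist,expected_border",
                             [(10.0, 15.0, 5.0), (3.0, 5.0, 2.0)])
    def test_border_distance_arithmetic(self, mean_r, dist, expected_border):
        e = hq.puncta.NucleusEllipse(centre_um=(0, 0), semi_major_um=mean_r,
                                     semi_minor_um=mean_r, orientation_rad=0.0)
        d_c, d_b = hq.distance_to_nucleus((0, dist), e)
        assert d_c == pytest.approx(dist)
        assert d_b == pytest.approx(expected_border)


class TestPunctaMetrics:
    def test_no_records_gives_zero_counts_nan_areas(self, noiseless_cell):
        img, _ = noiseless_cell
        comps = hq.partition_compartments(img.soma_mask, img.nucleus_mask,
                                          img.pixel_size_um, 2.0)
        m = hq.puncta_metrics([], comps)
        assert m.counts == {"whole_cell": 0, "perinuclear": 0, "cytosolic": 0}
        assert all(np.isnan(v) for v in m.mean_puncta_area_um2.values())

    def test_synthetic_compartment_counts(self, noiseless_cell):
        img, truth = noiseless_cell
        comps = hq.partition_compartments(img.soma_mask, img.nucleus_mask,
                                          img.pixel_size_um, 2.0)
        _, recs = hq.detect_puncta(hq.apply_cell_mask(img, "puncta"),
                                   img.pixel_size_um, mask=img.soma_mask)
        m = hq.puncta_metrics(recs, comps)
        assert m.counts == {"whole_cell": 15, "perinuclear": 10, "cytosolic": 5}

    def test_constant_area_gives_constant_means(self, noiseless_cell):
        img, _ = noiseless_cell
        comps = hq.partition_compartments(img.soma_mask, img.nucleus_mask,
                                          img.pixel_size_um, 2.0)
        _, recs = hq.detect_puncta(hq.apply_cell_mask(img, "puncta"),
                                   img.pixel_size_um, mask=img.soma_mask)
        for r in recs:
            r.area_um2 = 0.5
        m = hq.puncta_metrics(recs, comps)
        for v in m.mean_puncta_area_um2.values():
            assert v == pytest.approx(0.5)

    def test_centroid_outside_cell_raises(self, noiseless_cell):
        img, _ = noiseless_cell
        comps = hq.partition_compartments(img.soma_mask, img.nucleus_mask,
                                          img.pixel_size_um, 2.0)
        bad = hq.puncta.PunctaRecord(label=1, area_um2=1.0, centroid_um=(0.1, 0.1))
        with pytest.raises(ValueError, match="outside the cell"):
            hq.puncta_metrics([bad], comps)

    @given(seed=st.integers(0, 40))
    def test_count_conservation_under_noise(self, seed):
        """Whole-cell count = perinuclear + cytosolic, for every cell, always."""
        p = hq.CellImageParams(gaussian_noise_sd=25.0, seed=seed)
        img, _ = hq.generate_cell_image(p)
        comps = hq.partition_compartments(img.soma_mask, img.nucleus_mask,
                                          img.pixel_size_um, 2.0)
        _, recs = hq.detect_puncta(hq.apply_cell_mask(img, "puncta"),
                                   img.pixel_size_um, mask=img.soma_mask)
        m = hq.puncta_metrics(recs, comps)
        assert m.counts["whole_cell"] == (m.counts["perinuclear"]
                                          + m.counts["cytosolic"])


class TestPipeline:
    def test_qc_exclusions_logged_and_rows_emitted(self, rect_cell_set):
        cfg = PipelineConfig(threshold=5.0, smooth_sigma_px=0.0)
        cells, _, exclusions = hq.run_puncta_pipeline(rect_cell_set, cfg)
        assert len(cells) == 2
        assert len(exclusions) == 2
        assert all("qc_ratio" in e["reason"] for e in exclusions)

    def test_identical_input_identical_rows(self, noiseless_cell):
        img, _ = noiseless_cell
        cells, _, _ = hq.run_puncta_pipeline({"a": img, "b": img})
        a = cells[cells.cell_id == "a"].drop(columns="cell_id").reset_index(drop=True)
        b = cells[cells.cell_id == "b"].drop(columns="cell_id").reset_index(drop=True)
        assert a.equals(b)

    def test_cohort_recovers_perinuclear_enrichment(self):
        # 25 cells, true perinuclear:cytosolic = 2:1 -> group means within 10%
        images = {}
        for s in range(25):
            p = hq.CellImageParams(n_perinuclear=10, n_cytosolic=5,
                                   gaussian_noise_sd=10.0, seed=100 + s)
            images[f"c{s}"], _ = hq.generate_cell_image(p)
        cells, _, excl = hq.run_puncta_pipeline(images)
        assert not excl
        ratio = cells.n_peri.mean() / cells.n_cyto.mean()
        assert ratio == pytest.approx(2.0, rel=0.10)

    def test_distances_populated_on_punctum_table(self, noiseless_cell):
        img, _ = noiseless_cell
        _, puncta_tbl, _ = hq.run_puncta_pipeline({"a": img})
        assert puncta_tbl.dist_centre_um.notna().all()
        # border distance = centre distance − mean ellipse radius
        ell = hq.fit_nucleus_ellipse(img.nucleus_mask, img.pixel_size_um)
        np.testing.assert_allclose(
            puncta_tbl.dist_border_um,
            puncta_tbl.dist_centre_um - ell.mean_radius_um)
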