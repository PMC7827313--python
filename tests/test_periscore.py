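"""Perivascular ring scoring, lymphocyte blob morphology, CD3 categories,
line profiles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hevscape import AnalysisConfig, Calibration, MultiplexImage
from hevscape.hevseg import VesselRecord
from hevscape.periscore import (CellBlob, categorize, cd3_category,
                                ccl21_morphology, detect_blobs, line_profile,
                                perivascular_ring, score_marker)

CAL = Calibration(0.5)


def annulus_record(r_in_um=15.0, width_um=5.0, field=300, vid=0,
                   center_px=None):
    upp = CAL.um_per_px
    cx, cy = center_px or (field / 2, field / 2)
    yy, xx = np.mgrid[0:field, 0:field]
    rr = np.hypot(xx - cx, yy - cy) * upp
    wall_full = (rr >= r_in_um) & (rr <= r_in_um + width_um)
    lumen_full = rr < r_in_um
    ys, xs = np.nonzero(wall_full)
    bbox = (ys.min(), ys.max() + 1, xs.min(), xs.max() + 1)
    sl = (slice(bbox[0], bbox[1]), slice(bbox[2], bbox[3]))
    return VesselRecord(
        vessel_id=vid, wall_mask=wall_full[sl], lumen_mask=lumen_full[sl],
        bbox=bbox, centroid_um=(cx * upp, cy * upp)), wall_full, lumen_full


class TestRing:
    def test_isolated_annulus_ring_area_is_analytic_band(self, cfg):
        rec, wall, _ = annulus_record()
        ring, _ = perivascular_ring(rec, cfg, CAL,
                                    occupied_labels=np.zeros(wall.shape, np.int32))
        area = ring.sum() * CAL.um2_per_px2()
        r_out = 20.0
        expected = np.pi * ((r_out + cfg.ring_width_um) ** 2 - r_out ** 2)
        assert area == pytest.approx(expected, rel=0.05)

    def test_adjacent_vessel_excluded_from_ring(self, cfg):
        rec1, wall1, lum1 = annulus_record(center_px=(110, 150), vid=0)
        rec2, wall2, lum2 = annulus_record(center_px=(210, 150), vid=1)
        occupied = np.zeros(wall1.shape, np.int32)
        occupied[wall1 | lum1] = 1
        occupied[wall2 | lum2] = 2
        ring, (R0, C0) = perivascular_ring(rec1, cfg, CAL, occupied)
        full = np.zeros(wall1.shape, bool)
        full[R0:R0 + ring.shape[0], C0:C0 + ring.shape[1]] = ring
        assert not (full & (wall2 | lum2)).any()

    def test_zero_ring_width_scores_na(self, cfg):
        rec, wall, _ = annulus_record()
        cfg0 = AnalysisConfig(ring_width_um=1e-9)
        cfg0.ring_width_um = 0.0
        ring, _ = perivascular_ring(rec, cfg0, CAL,
                                    occupied_labels=np.zeros(wall.shape, np.int32))
        score = score_marker(ring, np.zeros(ring.shape), cfg, marker="CCL21")
        assert score.category == "NA" and np.isnan(score.coverage)


class TestScoreMarker:
    def ring_and_positive(self, cfg, coverage):
        rec, wall, _ = annulus_record()
        ring, (R0, C0) = perivascular_ring(
            rec, cfg, CAL, occupied_labels=np.zeros(wall.shape, np.int32))
        h, w = ring.shape
        cy = rec.centroid_um[1] / CAL.um_per_px - R0
        cx = rec.centroid_um[0] / CAL.um_per_px - C0
        yy, xx = np.mgrid[0:h, 0:w]
        ang = np.mod(np.arctan2(yy - cy, xx - cx), 2 * np.pi)
        pos = ring & (ang <= coverage * 2 * np.pi)
        return ring, pos, (cy, cx)

    @pytest.mark.parametrize("coverage,category", [
        (1.0, "CONTINUOUS"), (0.5, "PARTIAL"), (0.0, "NONE")])
    def test_rendered_coverage_maps_to_category(self, cfg, coverage, category):
        ring, pos, center = self.ring_and_positive(cfg, coverage)
        score = score_marker(ring, None, cfg, marker="CCL21",
                             center_rc=center, positive=pos)
        assert score.category == category
        assert score.coverage == pytest.approx(coverage, abs=0.03)

    @settings(max_examples=60, derandomize=True)
    @given(st.floats(min_value=0, max_value=1, allow_nan=False))
    def test_categorize_is_a_monotone_step_function(self, coverage):
        cfg_ = AnalysisConfig()
        cat = categorize(coverage, cfg_)
        if coverage >= cfg_.coverage_continuous_min:
            assert cat == "CONTINUOUS"
        elif coverage <= cfg_.coverage_none_max:
            assert cat == "NONE"
        else:
            assert cat == "PARTIAL"


def blob_scene(n_blobs, mesh=True, asma_pos=False, cd3_frac=1.0, field=700):
    """CCL21 plane with an optional sparse mesh plus rimmed lymphocyte blobs."""
    rng = np.random.default_rng(0)
    ccl21 = np.zeros((field, field), np.float32)
    asma = np.zeros_like(ccl21)
    cd3 = np.zeros_like(ccl21)
    if mesh:
        yy, xx = np.mgrid[0:field, 0:field]
        grid = (np.mod(xx, 300) < 2) | (np.mod(yy, 300) < 2)
        ccl21[grid] = 120
        asma[grid] = 110
    positions = []
    k = int(np.ceil(np.sqrt(n_blobs)))
    step = field // (k + 1)
    r_px = 8  # 4 µm radius
    for i in range(n_blobs):
        cx = (i % k + 1) * step + 20
        cy = (i // k + 1) * step + 20
        positions.append((cx, cy))
        yy, xx = np.mgrid[cy - 12:cy + 12, cx - 12:cx + 12]
        rr = np.hypot(xx - cx, yy - cy)
        disc = rr <= r_px
        interior = rr <= r_px - 2.5
        ccl21[cy - 12:cy + 12, cx - 12:cx + 12][disc & ~interior] = 150
        ccl21[cy - 12:cy + 12, cx - 12:cx + 12][interior] = 100
        if asma_pos:
            asma[cy - 12:cy + 12, cx - 12:cx + 12][interior] = 130
        if i < cd3_frac * n_blobs:
            cd3[cy - 12:cy + 12, cx - 12:cx + 12][interior] = 140
    return ccl21, asma, cd3, positions


class TestMorphology:
    def test_pure_reticular_mesh_has_no_blobs(self, cfg):
        ccl21, asma, cd3, _ = blob_scene(0, mesh=True)
        region = np.ones(ccl21.shape, bool)
        label, blobs = ccl21_morphology(ccl21, asma, region, cfg, CAL,
                                        cd3_plane=cd3)
        assert label == "RETICULAR" and len(blobs) == 0

    def test_blob_dominated_ln_is_immune_cell_with_accurate_count(self, cfg):
        ccl21, asma, cd3, _ = blob_scene(50, mesh=True)
        region = np.ones(ccl21.shape, bool)
        label, blobs = ccl21_morphology(ccl21, asma, region, cfg, CAL,
                                        cd3_plane=cd3)
        candidates = [b for b in blobs if not b.asma_pos]
        assert label == "IMMUNE_CELL"
        assert abs(len(candidates) - 50) <= 2

    def test_asma_positive_blobs_are_not_immune_candidates(self, cfg):
        ccl21, asma, cd3, _ = blob_scene(50, mesh=True, asma_pos=True)
        region = np.ones(ccl21.shape, bool)
        label, blobs = ccl21_morphology(ccl21, asma, region, cfg, CAL,
                                        cd3_plane=cd3)
        assert all(b.asma_pos for b in blobs)
        assert label == "RETICULAR"

    def test_blob_count_invariant_under_rotation(self, cfg):
        ccl21, asma, cd3, _ = blob_scene(20, mesh=False)
        region = np.ones(ccl21.shape, bool)
        blobs0, _, _ = detect_blobs(ccl21, asma, cd3, region, cfg, CAL)
        blobs90, _, _ = detect_blobs(np.rot90(ccl21), np.rot90(asma),
                                     np.rot90(cd3), np.rot90(region), cfg, CAL)
        assert len(blobs0) == len(blobs90) == 20

    def test_blob_count_stable_under_default_noise(self, cfg):
        rng = np.random.default_rng(5)
        ccl21, asma, cd3, _ = blob_scene(20, mesh=False)
        noisy = ccl21 + rng.normal(0, 8.0, ccl21.shape).astype(np.float32)
        region = np.ones(ccl21.shape, bool)
        blobs, _, _ = detect_blobs(np.clip(noisy, 0, 255), asma, cd3, region,
                                   cfg, CAL)
        assert abs(len(blobs) - 20) <= 1


class TestCd3Category:
    def make_blobs(self, n, n_cd3, dist_um=18.0):
        rec, wall, _ = annulus_record()
        cx, cy = rec.centroid_um
        r = 20.0 + dist_um
        out = []
        for i in range(n):
            phi = 2 * np.pi * i / n
            out.append(CellBlob(
                centroid_um=(cx + r * np.cos(phi), cy + r * np.sin(phi)),
                area_um2=50.0, circularity=0.9, cd3_pos=i < n_cd3))
        return rec, out

    @pytest.mark.parametrize("n_cd3,expected", [
        (10, "100"), (6, ">50"), (5, "<50"), (3, "<50"), (0, "0")])
    def test_fraction_categories(self, cfg, n_cd3, expected):
        rec, blobs = self.make_blobs(10, n_cd3)
        assert cd3_category(blobs, rec, cfg, CAL) == expected

    def test_blobs_outside_search_radius_ignored(self, cfg):
        rec, blobs = self.make_blobs(10, 10, dist_um=40.0)
        assert cd3_category(blobs, rec, cfg, CAL) == "NA"

    def test_no_blobs_is_na(self, cfg):
        rec, _ = self.make_blobs(1, 1)
        assert cd3_category([], rec, cfg, CAL) == "NA"


class TestLineProfile:
    def image(self, planes):
        return MultiplexImage(planes=planes, calibration=CAL)

    def test_constant_plane_gives_constant_profile(self):
        img = self.image({"CCL21": np.full((100, 100), 77.0)})
        prof = line_profile(img, (5.0, 5.0), (45.0, 30.0), ["CCL21"])
        np.testing.assert_allclose(prof["CCL21"], 77.0)

    def test_zero_length_segment_is_single_sample(self):
        img = self.image({"CCL21": np.full((50, 50), 3.0)})
        prof = line_profile(img, (10.0, 10.0), (10.0, 10.0), ["CCL21"])
        assert len(prof["CCL21"]) == 1

    def test_endpoint_outside_image_rejected(self):
        img = self.image({"CCL21": np.zeros((50, 50))})
        with pytest.raises(ValueError, match="outside"):
            line_profile(img, (0.0, 0.0), (100.0, 0.0), ["CCL21"])

    def test_ccl21_rim_peaks_flank_cd3_plateau(self):
        """Profile across a CCL21-rimmed CD3+ blob: two CCL21 maxima outside
        the CD3 full-width-half-maximum."""
        ccl21, asma, cd3, positions = blob_scene(1, mesh=False, field=200)
        img = self.image({"CCL21": ccl21, "CD3": cd3})
        cx, cy = positions[0]
        x_um, y_um = cx * CAL.um_per_px, cy * CAL.um_per_px
        prof = line_profile(img, (x_um - 10, y_um), (x_um + 10, y_um),
                            ["CCL21", "CD3"])
        cd3_v, ccl_v = prof["CD3"], prof["CCL21"]
        half = cd3_v.max() / 2
        inside = np.flatnonzero(cd3_v >= half)
        lo, hi = inside.min(), inside.max()
        assert ccl_v[:lo].max() > ccl_v[lo:hi + 1].max() * 0.9
        assert ccl_v[hi + 1:].max() > ccl_v[lo:hi + 1].max() * 0.9
        # the two rim maxima sit strictly outside the CD3 plateau
        assert ccl_v[:lo].argmax() < lo and hi + 1 + ccl_v[hi + 1:].argmax() > hi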