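"""Aggregation arithmetic, the normality-gated battery, Dunn's test oracle,
and pipeline orchestration."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hevscape import Calibration, GroupProfile, load_profile
from hevscape.cohortstats import (aggregate, dunn_test, run_pipeline,
                                  run_tests, _normality_pass)
from hevscape.hevseg import VesselRecord
from hevscape.periscore import CoverageScore
from hevscape.regions import RegionSet
from hevscape.synthcohort import generate_cohort

CAL = Calibration(0.5)


def fake_vessel(vid, zone="PARACORTICAL", cls="NON", thin=False, disc=False,
                ccl21="CONTINUOUS"):
    m = np.ones((2, 2), bool)
    r = VesselRecord(vessel_id=vid, wall_mask=m, lumen_mask=~m, bbox=(0, 2, 0, 2),
                     centroid_um=(1.0, 1.0), zone=zone, dilation_class=cls,
                     thin_flag=thin, pnad_discontinuous=disc)
    r.ring_scores["CCL21"] = CoverageScore("CCL21", 1.0 if ccl21 == "CONTINUOUS"
                                           else 0.0, ccl21)
    return r


def fake_rset(paracortex_px=8_000_000, with_tumor=False):
    """paracortex_px * 0.25 µm² = 2.0 mm² at the default calibration."""
    side = int(np.ceil(np.sqrt(paracortex_px))) if paracortex_px else 10
    para = np.zeros((side, side + 1), bool)
    para.ravel()[:paracortex_px] = True
    tissue = np.ones_like(para)
    tumor = np.zeros_like(para)
    if with_tumor:
        tumor[:2, :2] = True
    return RegionSet(tissue_mask=tissue, tumor_mask=tumor,
                     foci_labels=tumor.astype(np.int32), paracortex_mask=para,
                     calibration=CAL)


class TestAggregate:
    def test_density_is_count_over_area(self):
        recs = [fake_vessel(i) for i in range(5)]
        row = aggregate(recs, fake_rset(), CAL)
        assert row["paracortex_area_mm2"] == pytest.approx(2.0)
        assert row["hev_per_mm2"] == pytest.approx(2.5)

    def test_class_fractions_and_densities(self):
        recs = ([fake_vessel(i, cls="NON") for i in range(5)]
                + [fake_vessel(5 + i, cls="INT") for i in range(3)]
                + [fake_vessel(8 + i, cls="HIGH") for i in range(2)])
        row = aggregate(recs, fake_rset(), CAL)
        assert row["pct_dilated"] == pytest.approx(50.0)
        assert row["high_per_mm2"] == pytest.approx(2 / 2.0)
        # conservation: classes partition the paracortical vessels
        assert row["n_non"] + row["n_int"] + row["n_high"] == row["n_paracortical"]

    def test_excluded_vessels_keep_zone_metrics_alive(self):
        recs = [fake_vessel(0, zone="EXCLUDED"),
                fake_vessel(1, zone="MA", ccl21="NONE"),
                fake_vessel(2, zone="IM", ccl21="NONE")]
        row = aggregate(recs, fake_rset(), CAL)
        assert row["n_paracortical"] == 0
        assert row["hev_per_mm2"] == 0.0
        assert row["pct_ccl21_none_ma"] == 100.0
        assert row["pct_ccl21_none_im"] == 100.0

    def test_zero_paracortex_with_paracortical_vessels_is_error(self):
        recs = [fake_vessel(0)]
        with pytest.raises(ValueError, match="paracort"):
            aggregate(recs, fake_rset(paracortex_px=0), CAL)


class TestNormalityGate:
    def test_gaussian_groups_pass(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(size=15) for _ in range(4)]
        assert _normality_pass(groups)

    def test_exponential_groups_fail(self):
        rng = np.random.default_rng(0)
        groups = [rng.exponential(size=30) for _ in range(2)]
        assert not _normality_pass(groups)


class TestBattery:
    def test_identical_nonnormal_groups_null_mann_whitney(self):
        """Two identical groups: U at its null value n1*n2/2, p ≈ 1."""
        rng = np.random.default_rng(1)
        vals = rng.standard_t(df=2, size=30) ** 3  # strongly non-normal
        table = pd.DataFrame({"y": np.r_[vals, vals],
                              "group": ["a"] * 30 + ["b"] * 30})
        res = run_tests(table, [{"endpoint": "y", "kind": "groups",
                                 "group_col": "group"}])
        assert len(res) == 1
        r = res[0]
        assert r.test == "mann_whitney" and r.branch == "nonparametric"
        assert r.statistic == pytest.approx(30 * 30 / 2)
        assert r.p_value > 0.95

    def test_monotone_pair_has_spearman_rho_one(self):
        table = pd.DataFrame({"x": np.arange(10.0),
                              "y": np.arange(10.0) ** 2 + 1})
        res = run_tests(table, [{"endpoint": "corr", "kind": "correlation",
                                 "x": "x", "y": "y"}])
        assert res[0].test == "spearman"
        assert res[0].statistic == pytest.approx(1.0)

    def test_paired_design_uses_signed_rank_or_paired_t(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=12)
        table = pd.DataFrame({"pre": a, "post": a + rng.normal(1.0, 0.1, 12)})
        res = run_tests(table, [{"endpoint": "shift", "kind": "paired",
                                 "col_a": "pre", "col_b": "post"}])
        assert res[0].test in ("paired_t", "wilcoxon")
        assert res[0].p_value < 0.01

    def test_small_groups_are_skipped(self):
        table = pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0],
                              "group": ["a", "a", "b", "b"]})
        res = run_tests(table, [{"endpoint": "y", "kind": "groups",
                                 "group_col": "group"}])
        assert res == []

    def test_four_group_comparison_reports_omnibus_and_pairs(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame({
            "y": np.r_[[rng.normal(loc, 1, 15) for loc in (0, 0, 0, 2)]].ravel(),
            "group": np.repeat(list("abcd"), 15)})
        res = run_tests(table, [{"endpoint": "y", "kind": "groups",
                                 "group_col": "group"}])
        assert len(res) == 7  # omnibus + 6 pairwise
        assert res[0].comparison == "omnibus"
        shifted = [r for r in res if "d" in r.comparison.split(" vs ")]
        assert all(r.p_value < 0.05 for r in shifted)
        assert all(r.adjustment != "none" for r in res[1:])

    def test_p_values_bounded(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame({"y": rng.normal(size=40),
                              "group": np.repeat(list("ab"), 20)})
        for r in run_tests(table, [{"endpoint": "y", "kind": "groups",
                                    "group_col": "group"}]):
            assert 0.0 <= r.p_value <= 1.0


class TestDunn:
    def test_against_hand_computed_example(self):
        """Three tied-free groups; expected z from the rank-sum formula
        computed by hand: mean ranks 2/5/8, Var = N(N+1)/12 = 7.5."""
        groups = {"a": np.array([1.0, 2, 3]), "b": np.array([4.0, 5, 6]),
                  "c": np.array([7.0, 8, 9])}
        out = {(a, b): (z, p) for a, b, z, p in dunn_test(groups)}
        se = np.sqrt(7.5 * (1 / 3 + 1 / 3))
        z_ab = (2 - 5) / se
        assert out[("a", "b")][0] == pytest.approx(z_ab)
        assert out[("a", "c")][0] == pytest.approx((2 - 8) / se)
        assert out[("a", "b")][1] == pytest.approx(2 * stats.norm.sf(abs(z_ab)))

    def test_tie_correction_changes_variance(self):
        """With heavy ties the z statistic must grow in magnitude relative
        to the uncorrected formula."""
        groups = {"a": np.array([1.0, 1, 1, 2]), "b": np.array([2.0, 2, 3, 3])}
        (_, _, z, _), = dunn_test(groups)
        n_tot = 8
        ranks_a = stats.rankdata(np.r_[groups["a"], groups["b"]])[:4]
        base_uncorr = n_tot * (n_tot + 1) / 12.0
        se_uncorr = np.sqrt(base_uncorr * (1 / 4 + 1 / 4))
        z_uncorr = (ranks_a.mean()
                    - stats.rankdata(np.r_[groups["a"], groups["b"]])[4:].mean()) / se_uncorr
        assert abs(z) > abs(z_uncorr)


@pytest.fixture(scope="module")
def demo_dataset(tmp_path_factory):
    out = tmp_path_factory.mktemp("demo")
    base = load_profile("od").to_dict()
    base.update(name="demo", lns=2, vessels_per_ln=12, image_px=700)
    generate_cohort(GroupProfile.from_dict(base), seed=21, out_dir=out)
    return out


class TestPipeline:
    def manifest(self, dataset):
        with open(dataset / "manifest.json") as fh:
            sim = json.load(fh)
        return {"base_dir": str(dataset), "um_per_px": sim["um_per_px"],
                "channel_map": sim["channel_map"], "images": sim["images"]}

    def test_demo_dataset_completes_with_all_outputs(self, demo_dataset, tmp_path, cfg):
        lns, vessels, _ = run_pipeline(self.manifest(demo_dataset), cfg,
                                       tmp_path / "run")
        assert len(lns) == 2
        assert len(vessels) > 0
        for f in ("vessels.csv", "lns.csv", "run_manifest.json"):
            assert (tmp_path / "run" / f).exists()

    def test_rerun_is_numerically_identical(self, demo_dataset, tmp_path, cfg):
        run_pipeline(self.manifest(demo_dataset), cfg, tmp_path / "r1")
        run_pipeline(self.manifest(demo_dataset), cfg, tmp_path / "r2")
        for f in ("vessels.csv", "lns.csv"):
            a = pd.read_csv(tmp_path / "r1" / f)
            b = pd.read_csv(tmp_path / "r2" / f)
            pd.testing.assert_frame_equal(a.drop(columns="analysis_seconds",
                                                 errors="ignore"),
                                          b.drop(columns="analysis_seconds",
                                                 errors="ignore"))

    def test_corrupted_image_is_skipped_not_fatal(self, demo_dataset, tmp_path, cfg):
        man = self.manifest(demo_dataset)
        man["images"] = man["images"] + [{"path": "missing.tiff", "ln_id": "bad",
                                          "group": "demo"}]
        lns, _, _ = run_pipeline(man, cfg, tmp_path / "run")
        assert len(lns) == 2
        with open(tmp_path / "run" / "run_manifest.json") as fh:
            rm = json.load(fh)
        assert rm["skipped"] and rm["skipped"][0]["ln_id"] == "bad"

    def test_empty_dataset_is_an_error(self, cfg, tmp_path):
        with pytest.raises(ValueError, match="empty"):
            run_pipeline({"images": []}, cfg, tmp_path)
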