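"""Cohort aggregation, the statistical battery, and pipeline orchestration.

Per-vessel records are aggregated into per-LN rows (densities normalized to
paracortical area, class fractions, thin/PNAd frequencies, perivascular
category fractions by zone, metastatic burden, CCL21 morphology label).
Group comparisons are normality-gated: if D'Agostino-Pearson, Shapiro-Wilk
and Lilliefors-corrected KS all pass (alpha = 0.05) in every group, the
parametric branch runs (ANOVA + Holm-Sidak pairwise, or t tests); otherwise
the non-parametric branch (Kruskal-Wallis + Dunn with Holm adjustment,
Mann-Whitney, Wilcoxon signed-rank). Spearman serves correlation endpoints.
Which branch fired is recorded in every result.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__ as _pkg_version
from . import hevseg, morpho, periscore, regions as regions_mod
from .config import AnalysisConfig
from .imgio import (Calibration, ChannelMap, MultiplexImage, read_mask,
                    read_multiplex, to_8bit_scale, vessels_to_frame,
                    write_frame)

log = logging.getLogger(__name__)

POSITIVITY_CHANNELS = ("PNAD", "CLDN5", "CCL21", "ASMA", "HS", "CD3")


# ---------------------------------------------------------------------------
# single-LN analysis


def analyze_ln(image: MultiplexImage, config: AnalysisConfig,
               ln_id: str = "ln", group: str = "",
               fat_mask: Optional[np.ndarray] = None):
    """Full per-LN analysis: regions -> vessels -> morphometry -> scoring.

    Returns (vessel_records, ln_row, region_set).
    """
    t0 = time.perf_counter()
    calib = image.calibration
    rset = regions_mod.build_regions(image, config, fat_mask=fat_mask)

    # one positivity threshold per plane, reused for every vessel
    positive: Dict[str, np.ndarray] = {}
    for ch in POSITIVITY_CHANNELS:
        if ch in image:
            plane = to_8bit_scale(image.plane(ch))
            positive[ch] = plane >= config.positivity_threshold(ch, plane)

    records = hevseg.detect_hevs(image, rset.tissue_mask, config)

    occupied = np.zeros(rset.tissue_mask.shape, np.int32)
    for r in records:
        r0, r1, c0, c1 = r.bbox
        sub = occupied[r0:r1, c0:c1]
        sub[r.wall_mask | r.lumen_mask] = r.vessel_id + 1

    for r in records:
        r0, r1, c0, c1 = r.bbox
        r.diameter_um = morpho.lumen_diameter_um(r.lumen_mask, calib)
        r.dilation_class = morpho.classify_dilation(r.diameter_um, config)
        r.ec_thickness_um, r.thin_flag = morpho.ec_thickness_um(
            r.wall_mask, calib, config)
        r.pnad_coverage, r.pnad_discontinuous = morpho.pnad_coverage(
            r.wall_mask, None, config, calib,
            pnad_positive=positive["PNAD"][r0:r1, c0:c1])
        r.zone = regions_mod.zone_of(r.centroid_um, rset, config)
        ring, (R0, C0) = periscore.perivascular_ring(r, config, calib, occupied)
        cy = r.centroid_um[1] / calib.um_per_px - R0
        cx = r.centroid_um[0] / calib.um_per_px - C0
        for marker, ch in (("CCL21", "CCL21"), ("ASMA", "ASMA"), ("HS", "HS")):
            if ch not in positive:
                continue
            h_, w_ = ring.shape
            pos_crop = positive[ch][R0:R0 + h_, C0:C0 + w_]
            r.ring_scores[marker] = periscore.score_marker(
                ring, None, config, marker=marker, center_rc=(cy, cx),
                positive=pos_crop)

    # LN-level CCL21 morphology and per-vessel CD3 scoring
    morphology, blobs = periscore.ccl21_morphology(
        image.plane("CCL21"), image.plane("ASMA"), rset.paracortex_mask,
        config, calib,
        cd3_plane=image.plane("CD3") if "CD3" in image else None)
    if blobs:
        centers = np.array([b.centroid_um for b in blobs])
        for r in records:
            c = np.array(r.centroid_um)
            rough = np.hypot(centers[:, 0] - c[0], centers[:, 1] - c[1])
            reach = config.cd3_search_um + max(r.bbox[1] - r.bbox[0],
                                               r.bbox[3] - r.bbox[2]) * calib.um_per_px
            cand = [blobs[i] for i in np.flatnonzero(rough <= reach)]
            if r.dilation_class == "HIGH" and cand:
                r.cd3_category = periscore.cd3_category(cand, r, config, calib)
            r.n_blobs = _count_near(cand, r, config, calib)

    ln_row = aggregate(records, rset, calib)
    ln_row.update({"ln_id": ln_id, "group": group,
                   "ccl21_morphology": morphology,
                   "n_blobs_ln": len([b for b in blobs if not b.asma_pos]),
                   "analysis_seconds": round(time.perf_counter() - t0, 2)})
    log.info("analyzed %s: %d vessels in %.1fs", ln_id, len(records),
             ln_row["analysis_seconds"])
    return records, ln_row, rset


def _count_near(blobs, record, config, calib) -> int:
    if not blobs:
        return 0
    ys, xs = np.nonzero(record.wall_mask)
    r0, _, c0, _ = record.bbox
    wx = (xs + c0) * calib.um_per_px
    wy = (ys + r0) * calib.um_per_px
    n = 0
    for b in blobs:
        if b.asma_pos:
            continue
        d = np.min(np.hypot(wx - b.centroid_um[0], wy - b.centroid_um[1]))
        if d <= config.cd3_search_um:
            n += 1
    return n


# ---------------------------------------------------------------------------
# aggregation


def _pct(k: int, n: int) -> float:
    return 100.0 * k / n if n else float("nan")


def aggregate(records: Sequence[hevseg.VesselRecord], rset, calibration) -> dict:
    """One per-LN CohortTable row from vessel records and regions.

    Densities are counts over the paracortical area in mm²; vessels zoned
    EXCLUDED are omitted from paracortical metrics but zone-specific (MA/IM)
    metrics are kept. Border-touching vessels are excluded throughout
    (partial annuli bias the morphometry).
    """
    upp2 = calibration.um2_per_px2()
    area_mm2 = float(rset.paracortex_mask.sum()) * upp2 / 1e6
    usable = [r for r in records if not r.border_touching]
    para = [r for r in usable if r.zone == "PARACORTICAL"]
    if area_mm2 == 0 and para:
        raise ValueError("zero paracortical area but paracortical vessels present")

    def class_n(rows, cls):
        return sum(1 for r in rows if r.dilation_class == cls)

    row = {
        "paracortex_area_mm2": area_mm2,
        "n_vessels": len(usable),
        "n_paracortical": len(para),
        "n_non": class_n(para, "NON"),
        "n_int": class_n(para, "INT"),
        "n_high": class_n(para, "HIGH"),
        "burden_pct": regions_mod.metastatic_burden(rset),
    }
    n_dil = row["n_int"] + row["n_high"]
    row["hev_per_mm2"] = row["n_paracortical"] / area_mm2 if area_mm2 else 0.0
    row["dilated_per_mm2"] = n_dil / area_mm2 if area_mm2 else 0.0
    row["high_per_mm2"] = row["n_high"] / area_mm2 if area_mm2 else 0.0
    row["pct_dilated"] = _pct(n_dil, row["n_paracortical"])
    row["pct_high"] = _pct(row["n_high"], row["n_paracortical"])

    high = [r for r in para if r.dilation_class == "HIGH"]
    rest = [r for r in para if r.dilation_class != "HIGH"]
    row["pct_thin_high"] = _pct(sum(r.thin_flag for r in high), len(high))
    row["pct_thin_nonhigh"] = _pct(sum(r.thin_flag for r in rest), len(rest))
    row["pct_pnad_disc_high"] = _pct(sum(r.pnad_discontinuous for r in high), len(high))
    row["pct_pnad_disc_nonhigh"] = _pct(sum(r.pnad_discontinuous for r in rest), len(rest))

    for zone, rows_z in (("para", para),
                         ("ma", [r for r in usable if r.zone == "MA"]),
                         ("im", [r for r in usable if r.zone == "IM"])):
        row[f"n_{zone}"] = len(rows_z)
        row[f"pct_high_{zone}"] = _pct(class_n(rows_z, "HIGH"), len(rows_z))
        row[f"pct_thin_{zone}"] = _pct(sum(r.thin_flag for r in rows_z), len(rows_z))
        row[f"pct_pnad_disc_{zone}"] = _pct(
            sum(r.pnad_discontinuous for r in rows_z), len(rows_z))
        for marker in ("ccl21", "asma", "hs"):
            scored = [r.ring_scores.get(marker.upper()) for r in rows_z]
            scored = [s for s in scored if s is not None and s.category != "NA"]
            for cat in ("CONTINUOUS", "PARTIAL", "NONE"):
                row[f"pct_{marker}_{cat.lower()}_{zone}"] = _pct(
                    sum(s.category == cat for s in scored), len(scored))

    # HS loss (partial or none) around paracortical HIGH vessels
    hs_high = [r.ring_scores.get("HS") for r in high]
    hs_high = [s for s in hs_high if s is not None and s.category != "NA"]
    row["pct_hs_loss_high"] = _pct(
        sum(s.category in ("PARTIAL", "NONE") for s in hs_high), len(hs_high))

    # CD3 categories among highly dilated vessels with candidate blobs
    cd3 = [r.cd3_category for r in high if r.cd3_category != "NA"]
    for cat, col in (("100", "cd3_100"), (">50", "cd3_gt50"),
                     ("<50", "cd3_lt50"), ("0", "cd3_0")):
        row[f"pct_{col}"] = _pct(sum(c == cat for c in cd3), len(cd3))
    return row


# ---------------------------------------------------------------------------
# statistical battery


@dataclass
class TestResult:
    endpoint: str
    comparison: str
    test: str
    statistic: float
    p_value: float
    adjustment: str
    normality_pass: Optional[bool]
    branch: str
    note: str = ""

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p value outside [0,1]: {self.p_value}")


def _normality_pass(groups: Sequence[np.ndarray], alpha: float = 0.02) -> bool:
    """Normality gate on pooled, group-mean-centered residuals.

    The three tests (Shapiro-Wilk, D'Agostino-Pearson, Lilliefors-corrected
    KS) run once on the residuals of all groups pooled together, each at
    ``alpha`` (default 0.02); the gate passes when all applicable tests
    pass. Pooling the centered residuals instead of testing every group
    separately keeps the false-alarm rate of the combined gate low while
    the three tests together retain high power against heavy tails.
    Tests that cannot run at the available n are skipped rather than failed.
    """
    from statsmodels.stats.diagnostic import lilliefors

    resid = []
    for g in groups:
        g = np.asarray(g, float)
        g = g[~np.isnan(g)]
        if len(g):
            resid.append(g - g.mean())
    if not resid:
        return True
    r = np.concatenate(resid)
    if np.ptp(r) == 0:
        return True
    if len(r) >= 3 and stats.shapiro(r).pvalue < alpha:
        return False
    if len(r) >= 8 and stats.normaltest(r).pvalue < alpha:
        return False
    if len(r) >= 4 and lilliefors(r, dist="norm")[1] < alpha:
        return False
    return True


def dunn_test(groups: Dict[str, np.ndarray]) -> List[Tuple[str, str, float, float]]:
    """Dunn's rank-based post-hoc z tests with tie correction.

    Returns (group_i, group_j, z, raw two-sided p) per pair; adjust the p
    values afterwards (Holm here).
    """
    names = list(groups)
    pooled = np.concatenate([np.asarray(groups[k], float) for k in names])
    ranks = stats.rankdata(pooled)
    n_tot = len(pooled)
    mean_rank = {}
    i = 0
    for k in names:
        n_k = len(groups[k])
        mean_rank[k] = ranks[i:i + n_k].mean()
        i += n_k
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts ** 3 - counts).sum()) / (12.0 * (n_tot - 1)))
    base_var = n_tot * (n_tot + 1) / 12.0 - tie_term
    out = []
    for a, b in combinations(names, 2):
        se = np.sqrt(base_var * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        out.append((a, b, float(z), float(p)))
    return out


def _holm_sidak(pvals: Sequence[float]) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests
    return multipletests(pvals, method="holm-sidak")[1]


def _holm(pvals: Sequence[float]) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests
    return multipletests(pvals, method="holm")[1]


def run_tests(table: pd.DataFrame, design: Sequence[dict],
              alpha: float = 0.05) -> List[TestResult]:
    """Run the normality-gated battery over the endpoints of a design.

    Each design entry is a dict:
      {"endpoint": column, "kind": "groups", "group_col": column}
      {"endpoint": ..., "kind": "paired", "col_a": ..., "col_b": ...}
      {"endpoint": ..., "kind": "correlation", "x": column, "y": column}
    Groups with n < 3 cause the endpoint to be skipped with a logged reason.
    """
    results: List[TestResult] = []
    for spec in design:
        kind = spec.get("kind", "groups")
        name = spec.get("endpoint", "endpoint")
        if kind == "correlation":
            sub = table[[spec["x"], spec["y"]]].dropna()
            if len(sub) < 3:
                log.warning("endpoint %s skipped: n=%d < 3", name, len(sub))
                continue
            rho, p = stats.spearmanr(sub[spec["x"]], sub[spec["y"]])
            results.append(TestResult(
                endpoint=name, comparison=f"{spec['x']} vs {spec['y']}",
                test="spearman", statistic=float(rho), p_value=float(p),
                adjustment="none", normality_pass=None, branch="rank"))
            continue

        if kind == "paired":
            sub = table[[spec["col_a"], spec["col_b"]]].dropna()
            if len(sub) < 3:
                log.warning("endpoint %s skipped: n=%d < 3", name, len(sub))
                continue
            a = sub[spec["col_a"]].to_numpy(float)
            b = sub[spec["col_b"]].to_numpy(float)
            gate = _normality_pass([a - b], alpha)
            if gate:
                st, p = stats.ttest_rel(a, b)
                test, branch = "paired_t", "parametric"
            else:
                if np.allclose(a, b):
                    st, p = 0.0, 1.0
                else:
                    st, p = stats.wilcoxon(a, b)
                test, branch = "wilcoxon", "nonparametric"
            results.append(TestResult(
                endpoint=name, comparison=f"{spec['col_a']} vs {spec['col_b']}",
                test=test, statistic=float(st), p_value=float(p),
                adjustment="none", normality_pass=gate, branch=branch))
            continue

        # independent groups
        gcol = spec.get("group_col", "group")
        sub = table[[name, gcol]].dropna()
        groups = {k: v[name].to_numpy(float) for k, v in sub.groupby(gcol)}
        groups = {k: v for k, v in groups.items() if len(v) >= 3}
        if len(groups) < 2:
            log.warning("endpoint %s skipped: fewer than 2 groups with n >= 3", name)
            continue
        arrays = list(groups.values())
        gate = _normality_pass(arrays, alpha)
        if len(groups) == 2:
            (na, a), (nb, b) = groups.items()
            if gate:
                st, p = stats.ttest_ind(a, b)
                test, branch = "unpaired_t", "parametric"
            else:
                st, p = stats.mannwhitneyu(a, b, alternative="two-sided")
                test, branch = "mann_whitney", "nonparametric"
            results.append(TestResult(
                endpoint=name, comparison=f"{na} vs {nb}", test=test,
                statistic=float(st), p_value=float(p), adjustment="none",
                normality_pass=gate, branch=branch))
            continue
        if gate:
            st, p = stats.f_oneway(*arrays)
            results.append(TestResult(
                endpoint=name, comparison="omnibus", test="anova",
                statistic=float(st), p_value=float(p), adjustment="none",
                normality_pass=gate, branch="parametric"))
            pairs = list(combinations(groups, 2))
            raw = [stats.ttest_ind(groups[a], groups[b]).pvalue for a, b in pairs]
            adj = _holm_sidak(raw)
            stats_ = [stats.ttest_ind(groups[a], groups[b]).statistic for a, b in pairs]
            for (a, b), p_adj, st in zip(pairs, adj, stats_):
                results.append(TestResult(
                    endpoint=name, comparison=f"{a} vs {b}", test="pairwise_t",
                    statistic=float(st), p_value=float(p_adj),
                    adjustment="holm-sidak", normality_pass=gate,
                    branch="parametric"))
        else:
            st, p = stats.kruskal(*arrays)
            results.append(TestResult(
                endpoint=name, comparison="omnibus", test="kruskal_wallis",
                statistic=float(st), p_value=float(p), adjustment="none",
                normality_pass=gate, branch="nonparametric"))
            dunn = dunn_test(groups)
            adj = _holm([d[3] for d in dunn])
            for (a, b, z, _), p_adj in zip(dunn, adj):
                results.append(TestResult(
                    endpoint=name, comparison=f"{a} vs {b}", test="dunn",
                    statistic=float(z), p_value=float(p_adj),
                    adjustment="holm", normality_pass=gate,
                    branch="nonparametric"))
    return results


def results_to_frame(results: Sequence[TestResult]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in results])


# ---------------------------------------------------------------------------
# synthetic-cohort analysis (generation and analysis streamed in memory)


def analyze_synthetic_cohort(profile, seed: int,
                             config: Optional[AnalysisConfig] = None,
                             keep_truth: bool = True):
    """Generate a profile's cohort and run the full pipeline on each LN.

    LNs are rendered, analyzed and discarded one at a time, so a whole
    cohort never resides in memory. Returns (lns, vessels, truth_vessels,
    truth_lns) as DataFrames; the truth frames are empty when
    ``keep_truth`` is False.
    """
    from .synthcohort import iter_cohort

    config = config or AnalysisConfig()
    ln_rows, vessel_rows, truths, ln_truths = [], [], [], []
    for sample in iter_cohort(profile, seed):
        records, ln_row, _ = analyze_ln(sample.image, config,
                                        ln_id=sample.ln_id, group=profile.name)
        ln_rows.append(ln_row)
        vessel_rows.extend(r.to_row(ln_id=sample.ln_id) for r in records)
        if keep_truth:
            truths.append(sample.truth)
            ln_truths.append(sample.ln_truth)
    lns = pd.DataFrame(ln_rows)
    vessels = vessels_to_frame(vessel_rows)
    truth_v = pd.concat(truths, ignore_index=True) if truths else pd.DataFrame()
    truth_l = pd.DataFrame(ln_truths)
    return lns, vessels, truth_v, truth_l


def cohort_summary(lns: pd.DataFrame, vessels: pd.DataFrame) -> dict:
    """Pooled group-level quantities of one cohort.

    ``pct_dilated_pooled`` pools all paracortical vessels; the CCL21-none
    percentages for MA/IM vessels and the immune-cell morphology share are
    per-LN means, matching how the per-patient scoring is reported.
    """
    para = vessels[(vessels.zone == "PARACORTICAL") & (~vessels.border_touching)]
    n_para = len(para)
    dilated = int((para.dilation_class != "NON").sum())
    out = {
        "n_paracortical": n_para,
        "pct_dilated_pooled": _pct(dilated, n_para),
        "pct_high_pooled": _pct(int((para.dilation_class == "HIGH").sum()), n_para),
    }
    for zone in ("im", "ma"):
        col = f"pct_ccl21_none_{zone}"
        vals = lns[col].dropna() if col in lns else pd.Series(dtype=float)
        out[f"mean_{col}"] = float(vals.mean()) if len(vals) else float("nan")
        out[f"n_lns_{zone}"] = int(len(vals))
        out[f"n_vessels_{zone}"] = int(lns[f"n_{zone}"].sum()) if f"n_{zone}" in lns else 0
    morph = lns["ccl21_morphology"] if "ccl21_morphology" in lns else pd.Series(dtype=str)
    out["pct_immune_cell_lns"] = _pct(int((morph == "IMMUNE_CELL").sum()), len(morph))
    out["n_lns"] = int(len(lns))
    return out


# ---------------------------------------------------------------------------
# pipeline orchestration


def run_pipeline(manifest, config: AnalysisConfig, out_dir,
                 design: Optional[Sequence[dict]] = None):
    """Analyze every image of a dataset manifest and write the outputs.

    ``manifest`` is a dict or a YAML path with keys: ``images`` (list of
    {path, ln_id, group, fat_mask?}), ``channel_map`` (list or YAML path)
    and ``um_per_px``. Unreadable images are logged and skipped; an empty
    dataset is an error. Outputs: vessels.csv, lns.csv, tests.csv (when a
    design is given) and run_manifest.json.
    """
    if not isinstance(manifest, dict):
        base = Path(manifest).parent
        with open(manifest) as fh:
            manifest = yaml.safe_load(fh)
    else:
        base = Path(manifest.get("base_dir", "."))
    images = manifest.get("images", [])
    if not images:
        raise ValueError("empty dataset: manifest lists no images")
    cm = manifest.get("channel_map", None)
    if isinstance(cm, (list, tuple)):
        channel_map = ChannelMap(names=tuple(cm))
    elif cm:
        channel_map = ChannelMap.from_yaml(base / cm)
    else:
        channel_map = ChannelMap.default()
    calib = Calibration(um_per_px=float(manifest.get("um_per_px", 0.5)))

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vessel_rows = []
    ln_rows = []
    skipped = []
    for entry in images:
        ln_id = entry.get("ln_id", Path(entry["path"]).stem)
        try:
            image = read_multiplex(base / entry["path"], channel_map, calib)
            fat = read_mask(base / entry["fat_mask"]) if entry.get("fat_mask") else None
            records, ln_row, _ = analyze_ln(image, config, ln_id=ln_id,
                                            group=entry.get("group", ""), fat_mask=fat)
        except Exception as exc:  # partial failure: log and continue
            log.error("skipping %s: %s", ln_id, exc)
            skipped.append({"ln_id": ln_id, "reason": str(exc)})
            continue
        for r in records:
            vessel_rows.append(r.to_row(ln_id=ln_id))
        ln_rows.append(ln_row)

    vessels = vessels_to_frame(vessel_rows)
    lns = pd.DataFrame(ln_rows)
    write_frame(vessels, out / "vessels.csv")
    write_frame(lns, out / "lns.csv")
    results = None
    if design:
        results = run_tests(lns, design)
        write_frame(results_to_frame(results), out / "tests.csv")
    run_manifest = {
        "config": config.to_dict(),
        "hevscape_version": _pkg_version,
        "n_images": len(images),
        "n_analyzed": len(ln_rows),
        "skipped": skipped,
        "um_per_px": calib.um_per_px,
        "channel_map": list(channel_map.names),
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(run_manifest, fh, indent=1, sort_keys=True)
    return lns, vessels, results
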