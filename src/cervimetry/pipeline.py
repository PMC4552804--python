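"""End-to-end orchestration of the synthetic study.

``run_study`` reproduces the whole analysis from one seeded configuration:
simulate the exam table and fibre images, quantify ROI stiffness with QC,
run the longitudinal and reproducibility statistics and the
fibre-directionality comparison, and write every figure-ready table as CSV
plus a JSON report. Deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import elasto, shgtex, stats, synth
from .config import RunConfig

log = logging.getLogger("cervimetry")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and (np.isnan(obj) or np.isinf(obj)):
        return None
    return obj


def _operator_pairs(rois: pd.DataFrame):
    """Replicate-level and operator-level measurement pairs for agreement.

    Intra-operator: first vs second QC-passing replicate of each exam.
    Inter-operator: exam medians of the first two operators per animal x hour.
    """
    ok = rois[rois["qc_pass"]]
    intra_a, intra_b = [], []
    for _, sub in ok.groupby(["animal", "hour", "operator"]):
        vals = sub.sort_values("replicate")["median_kpa"].to_numpy()
        if vals.size >= 2:
            intra_a.append(vals[0])
            intra_b.append(vals[1])
    exam = (ok.groupby(["animal", "hour", "operator"])["median_kpa"]
            .median().reset_index())
    inter_a, inter_b = [], []
    for _, sub in exam.groupby(["animal", "hour"]):
        vals = sub.sort_values("operator")["median_kpa"].to_numpy()
        if vals.size >= 2:
            inter_a.append(vals[0])
            inter_b.append(vals[1])
    return (np.array(intra_a), np.array(intra_b),
            np.array(inter_a), np.array(inter_b))


def analyze_fibre_groups(config: RunConfig, seed: int) -> pd.DataFrame:
    """Generate and analyse the two fibre-morphology groups.

    Renders ``n_fibre_images_per_group`` images per preset (aligned vs
    disordered), extracts ROI windows of ``roi_um`` physical size and
    computes the directionality ratio R and the brightest-10-pixel intensity
    for each.
    """
    seeds = np.random.SeedSequence(seed).generate_state(
        2 * config.n_fibre_images_per_group) % (2**31)
    rows = []
    presets = {"aligned": config.aligned_fibres,
               "disordered": config.disordered_fibres}
    k = 0
    for label, params in presets.items():
        for i in range(config.n_fibre_images_per_group):
            image = synth.simulate_fibre_image(params, seed=int(seeds[k]))
            k += 1
            for roi in shgtex.tile_rois(image, side_um=config.roi_um):
                ell = shgtex.directionality_R(roi, threshold=config.ft_threshold)
                rows.append({
                    "condition": label, "image": i,
                    "roi_row": roi.origin[0], "roi_col": roi.origin[1],
                    "R": ell.R, "major": ell.major_axis,
                    "minor": ell.minor_axis,
                    "orientation_deg": ell.orientation,
                    "max10": shgtex.max10_intensity(roi.pixels),
                })
    return pd.DataFrame(rows)


def run_study(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full synthetic study and write the report bundle.

    Returns the report dictionary; CSV tables and ``report.json`` are written
    under ``out_dir`` (default: ``config.out_dir``).
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": _jsonable(config), "stages": {}}
    master = np.random.SeedSequence(config.seed)
    sub_seeds = master.generate_state(4) % (2**31)

    def stage(name):
        t0 = time.perf_counter()

        def done(**info):
            report["stages"][name] = dict(info)
            log.info("stage %s (%.2fs): %s", name, time.perf_counter() - t0, info)
        return done

    # --- simulate -----------------------------------------------------
    done = stage("simulate")
    design = dataclasses.replace(config.design, seed=int(sub_seeds[0]))
    slot_rng = np.random.default_rng(int(sub_seeds[1]))
    slots = sorted(slot_rng.choice(design.n_records, size=config.n_qc_violations,
                                   replace=False).tolist())
    exams = synth.simulate_swe_dataset(design, config.control_model,
                                       config.treated_model,
                                       qc_violation_slots=slots, rho=config.rho)
    exams.to_csv(out / "exams.csv", index=False)
    done(n_records=len(exams), qc_violation_slots=slots)

    # --- stiffness quantification ------------------------------------
    done = stage("elasto")
    rois = elasto.roi_table(exams, rho=config.rho,
                            qc_threshold=config.qc_threshold)
    per_exam = elasto.quantify_dataset(exams, rho=config.rho,
                                       qc_threshold=config.qc_threshold)
    rois.to_csv(out / "roi_estimates.csv", index=False)
    per_exam.to_csv(out / "exam_estimates.csv", index=False)
    n_missing_exams = int(per_exam["median_kpa"].isna().sum())
    accounting = elasto.account_dataset(
        len(rois),
        missing=0,
        qc_rejected=int((~rois["qc_pass"]).sum()),
    )
    report["accounting"] = _jsonable(accounting)
    done(n_rois=len(rois), n_qc_rejected=accounting.n_rejected_qc,
         n_missing_exams=n_missing_exams)

    # --- longitudinal + reproducibility statistics --------------------
    done = stage("stats")
    per_animal = (per_exam.dropna(subset=["median_kpa"])
                  .groupby(["animal", "group", "hour"])["median_kpa"]
                  .median().reset_index())
    per_hour = stats.ranksum_by_time(per_animal)
    per_hour.to_csv(out / "per_hour_tests.csv", index=False)
    ats = stats.anova_type_statistic(per_animal)
    fits = stats.fit_group_trajectories(per_exam)
    ia, ib, ea, eb = _operator_pairs(rois)
    intra, intra_tab = stats.bland_altman(ia, ib)
    inter, inter_tab = stats.bland_altman(ea, eb)
    intra_tab.to_csv(out / "bland_altman_intra.csv", index=False)
    inter_tab.to_csv(out / "bland_altman_inter.csv", index=False)
    pge2 = synth.simulate_pge2_table(seed=int(sub_seeds[2]))
    pge2.to_csv(out / "pge2.csv", index=False)
    wide = pge2.pivot_table(index=["animal", "group"], columns="sample_time",
                            values="concentration").reset_index()
    ratios = {g: (s["T2"] / s["T1"]).to_numpy() for g, s in wide.groupby("group")}
    kw_h, kw_p = stats.kruskal_wallis(*ratios.values())
    report["stats"] = {
        "ats": _jsonable(ats),
        "per_hour_tests": _jsonable(per_hour.to_dict(orient="records")),
        "trajectory_fits": _jsonable(fits),
        "bland_altman": {"intra_operator": _jsonable(intra),
                         "inter_operator": _jsonable(inter)},
        "pge2_kruskal_wallis": {"H": kw_h, "p": kw_p},
    }
    done(n_hours_tested=len(per_hour), n_intra_pairs=int(ia.size),
         n_inter_pairs=int(ea.size))

    # --- fibre directionality ----------------------------------------
    done = stage("shg")
    fibre = analyze_fibre_groups(config, seed=int(sub_seeds[3]))
    fibre.to_csv(out / "fibre_rois.csv", index=False)
    by_cond = {c: s for c, s in fibre.groupby("condition")}
    f_r, p_r = stats.one_way_anova(*(s["R"].to_numpy() for s in by_cond.values()))
    f_i, p_i = stats.one_way_anova(*(s["max10"].to_numpy()
                                     for s in by_cond.values()))
    report["shg"] = {
        "group_means_R": {c: float(s["R"].mean()) for c, s in by_cond.items()},
        "group_means_max10": {c: float(s["max10"].mean())
                              for c, s in by_cond.items()},
        "anova_R": {"F": f_r, "p": p_r},
        "anova_max10": {"F": f_i, "p": p_i},
    }
    done(n_rois=len(fibre))

    (out / "report.json").write_text(json.dumps(_jsonable(report), indent=2,
                                                sort_keys=True))
    return report
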