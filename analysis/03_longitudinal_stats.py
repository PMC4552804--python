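"""Longitudinal and reproducibility statistics on the per-exam estimates.

Rank-based ANOVA-type statistics for the group x time design, per-hour
rank-sum tests with Benjamini-Hochberg correction, quadratic trajectory
fits on per-hour medians, Bland-Altman intra-/inter-operator agreement,
and the Kruskal-Wallis test on the PGE2 fold changes.
"""

import json
from pathlib import Path

import pandas as pd

from cervimetry import stats
from cervimetry.pipeline import _jsonable, _operator_pairs

RAW = Path("results/raw")
OUT = Path("results")


def main() -> None:
    per_exam = pd.read_csv(OUT / "exam_estimates.csv")
    rois = pd.read_csv(OUT / "roi_estimates.csv")

    per_animal = (per_exam.dropna(subset=["median_kpa"])
                  .groupby(["animal", "group", "hour"])["median_kpa"]
                  .median().reset_index())

    ats = stats.anova_type_statistic(per_animal)
    print("ANOVA-type statistics (mid-ranks, Box approximation):")
    for effect, res in ats.items():
        print(f"  {effect:12s} ATS={res.statistic:8.2f}  "
              f"df=({res.df_num:.2f}, {res.df_den:.1f})  p={res.p_value:.2e}")

    per_hour = stats.ranksum_by_time(per_animal)
    per_hour.to_csv(OUT / "per_hour_tests.csv", index=False)
    sig = per_hour[per_hour["p_adj"] < 0.05]["hour"].tolist()
    print(f"hours with adjusted rank-sum p < 0.05: {sig}")

    fits = stats.fit_group_trajectories(per_exam)
    for group, fit in fits.items():
        print(f"  {group}: E(t) = {fit.a:.4f} t^2 {fit.b:+.4f} t "
              f"{fit.c:+.4f}  (R^2 = {fit.r_squared:.0%})")

    ia, ib, ea, eb = _operator_pairs(rois)
    intra, intra_tab = stats.bland_altman(ia, ib)
    inter, inter_tab = stats.bland_altman(ea, eb)
    intra_tab.to_csv(OUT / "bland_altman_intra.csv", index=False)
    inter_tab.to_csv(OUT / "bland_altman_inter.csv", index=False)
    for name, s in (("intra-operator", intra), ("inter-operator", inter)):
        print(f"  Bland-Altman {name}: bias {s.mean_diff:+.3f} kPa, "
              f"LoA [{s.loa_low:+.2f}, {s.loa_high:+.2f}] kPa (n={s.n})")

    pge2 = pd.read_csv(RAW / "pge2.csv")
    wide = pge2.pivot_table(index=["animal", "group"], columns="sample_time",
                            values="concentration").reset_index()
    ratios = {g: (s["T2"] / s["T1"]).to_numpy()
              for g, s in wide.groupby("group")}
    h, p = stats.kruskal_wallis(*ratios.values())
    print(f"  PGE2 fold-change Kruskal-Wallis: H={h:.2f}, p={p:.4f}")

    (OUT / "stats.json").write_text(json.dumps(_jsonable({
        "ats": ats, "trajectory_fits": fits,
        "bland_altman": {"intra_operator": intra, "inter_operator": inter},
        "pge2_kruskal_wallis": {"H": h, "p": p},
    }), indent=2))


if __name__ == "__main__":
    main()
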