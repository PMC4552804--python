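"""Fibre-directionality contrast between aligned and disordered textures.

Renders ten synthetic SHG-like images per morphology preset, computes the
Fourier-ellipse ratio R and the brightest-10-pixel intensity per 60-um ROI,
and compares the groups with a one-way ANOVA — the synthetic analogue of the
control-vs-ripened collagen comparison.
"""

from pathlib import Path

from cervimetry import stats
from cervimetry.config import validate_config
from cervimetry.pipeline import analyze_fibre_groups

OUT = Path("results")
SEED = 1


def main() -> None:
    cfg = validate_config({"seed": SEED, "n_fibre_images_per_group": 10})
    fibre = analyze_fibre_groups(cfg, seed=SEED)
    fibre.to_csv(OUT / "fibre_rois.csv", index=False)

    groups = {c: s for c, s in fibre.groupby("condition")}
    for cond, sub in groups.items():
        print(f"  {cond:10s} mean R = {sub['R'].mean():.3f} "
              f"(sd {sub['R'].std():.3f}), "
              f"max-10 intensity = {sub['max10'].mean():.0f} counts, "
              f"n = {len(sub)} ROIs")
    f_r, p_r = stats.one_way_anova(*(s["R"].to_numpy()
                                     for s in groups.values()))
    f_i, p_i = stats.one_way_anova(*(s["max10"].to_numpy()
                                     for s in groups.values()))
    print(f"  one-way ANOVA on R:      F = {f_r:.1f}, p = {p_r:.2e}")
    print(f"  one-way ANOVA on max-10: F = {f_i:.1f}, p = {p_i:.2e}")
    print("small R = parallel fibres; R near 1 = disordered texture")


if __name__ == "__main__":
    main()
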