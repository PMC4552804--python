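"""Simulate the synthetic study: exam table, PGE2 assay, example images.

Generates the full 9-animal x 7-timepoint x 2-operator x 3-replicate ROI
table (with two designed QC-violation acquisitions), the paired prostaglandin
table, and one example fibre image per morphology preset, all under
results/raw/.
"""

import dataclasses
from pathlib import Path

import numpy as np

from cervimetry.config import validate_config
from cervimetry.synth import (simulate_swe_dataset, simulate_pge2_table,
                              simulate_fibre_image, write_fibre_image)

OUT = Path("results/raw")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = validate_config({"seed": SEED})
    sub = np.random.SeedSequence(SEED).generate_state(4) % (2**31)

    design = dataclasses.replace(cfg.design, seed=int(sub[0]))
    slots = sorted(np.random.default_rng(int(sub[1]))
                   .choice(design.n_records, size=cfg.n_qc_violations,
                           replace=False).tolist())
    exams = simulate_swe_dataset(design, cfg.control_model, cfg.treated_model,
                                 qc_violation_slots=slots, rho=cfg.rho)
    exams.to_csv(OUT / "exams.csv", index=False)
    print(f"exam table: {len(exams)} ROI records "
          f"({design.n_animals_control} control + "
          f"{design.n_animals_treated} treated animals, "
          f"{len(design.hours)} hours, {design.n_operators} operators, "
          f"{design.n_replicates} replicates); "
          f"QC violations planted at rows {slots}")

    pge2 = simulate_pge2_table(seed=int(sub[2]))
    pge2.to_csv(OUT / "pge2.csv", index=False)
    print(f"PGE2 table: {len(pge2)} samples")

    img_seeds = np.random.SeedSequence(int(sub[3])).generate_state(2) % (2**31)
    for label, preset in (("aligned", cfg.aligned_fibres),
                          ("disordered", cfg.disordered_fibres)):
        image = simulate_fibre_image(preset, seed=int(img_seeds[0]))
        write_fibre_image(image, OUT / f"example_{label}.tif")
    print(f"example fibre images written to {OUT}")


if __name__ == "__main__":
    main()
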