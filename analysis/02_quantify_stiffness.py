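"""Quantify ROI stiffness with QC and report the dataset accounting.

Reads results/raw/exams.csv, converts every per-pixel shear-wave speed to
Young's modulus (E = 3 rho c^2, rho = 1000 kg/m^3), summarises each ROI by
its median +/- SD, rejects acquisitions whose within-ROI SD exceeds 30 % of
the median, and aggregates replicates into per-exam estimates.
"""

import json
from pathlib import Path

import pandas as pd

from cervimetry import elasto
from cervimetry.pipeline import _jsonable

RAW = Path("results/raw")
OUT = Path("results")


def main() -> None:
    exams = pd.read_csv(RAW / "exams.csv")
    rois = elasto.roi_table(exams)
    per_exam = elasto.quantify_dataset(exams)
    rois.to_csv(OUT / "roi_estimates.csv", index=False)
    per_exam.to_csv(OUT / "exam_estimates.csv", index=False)

    acc = elasto.account_dataset(len(rois), missing=0,
                                 qc_rejected=int((~rois["qc_pass"]).sum()))
    (OUT / "accounting.json").write_text(json.dumps(_jsonable(acc), indent=2))

    print(f"{acc.n_total} ROIs analysed; {acc.n_rejected_qc} rejected by the "
          f"30 % dispersion rule ({acc.pct_rejected_qc} % of the total)")
    last = per_exam[per_exam["hour"] == per_exam["hour"].max()]
    for group, sub in last.groupby("group"):
        med = sub["median_kpa"].median()
        print(f"  final stiffness, {group}: median {med:.2f} kPa "
              f"({elasto.modulus_to_sws(med):.3f} m/s)")


if __name__ == "__main__":
    main()
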