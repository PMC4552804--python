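"""ROI-level stiffness quantification for shear-wave elastography exams.

Converts shear-wave speed (SWS, m/s) to Young's modulus E = 3 rho c^2 under
the usual homogeneous/isotropic/incompressible soft-tissue assumptions,
summarises the per-pixel samples of each 5-mm circular ROI (median +/- SD on
the modulus scale), applies the artefact-rejection rule (ROI rejected when the
within-ROI SD exceeds 30 % of the median), aggregates replicate acquisitions,
and keeps the dataset accounting (totals, missing, QC-rejected).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: default tissue density, kg/m^3 (water-like soft tissue)
DEFAULT_RHO = 1000.0

#: within-ROI dispersion threshold: reject when SD/median exceeds this
DEFAULT_QC_THRESHOLD = 0.30


@dataclass(frozen=True)
class ExamRecord:
    """One ROI acquisition within the longitudinal design.

    Parameters
    ----------
    animal : str
        Animal identifier.
    group : str
        ``"control"`` or ``"treated"``.
    hour : float
        Hours since the first examination.
    operator : str
        Operator identifier.
    replicate : int
        Replicate acquisition index (1-based).
    sws_samples : numpy.ndarray
        Per-pixel shear-wave speeds (m/s) inside the ROI; all positive.
    """

    animal: str
    group: str
    hour: float
    operator: str
    replicate: int
    sws_samples: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        samples = np.asarray(self.sws_samples, dtype=float)
        if samples.size == 0:
            raise ValueError("sws_samples must be non-empty")
        if not np.all(samples > 0):
            raise ValueError("all SWS samples must be positive")
        if self.hour < 0:
            raise ValueError("hour must be >= 0")
        object.__setattr__(self, "sws_samples", samples)


@dataclass(frozen=True)
class StiffnessEstimate:
    """ROI summary on the modulus scale."""

    median_sws: float       # m/s, back-converted from the median modulus
    median_modulus: float   # kPa
    modulus_sd: float       # kPa, sample SD (ddof=1); 0 for a single sample
    sd_fraction: float      # SD / median, dimensionless
    qc_pass: bool


@dataclass(frozen=True)
class DatasetAccounting:
    """Totals and rejection percentages for a study dataset."""

    n_total: int
    n_rejected_missing: int
    n_rejected_qc: int
    pct_rejected_missing: str
    pct_rejected_qc: str


def sws_to_modulus(c, rho: float = DEFAULT_RHO):
    """Convert shear-wave speed to Young's modulus, E = 3 rho c^2, in kPa.

    Parameters
    ----------
    c : float or array-like
        Shear-wave speed in m/s; must be >= 0.
    rho : float
        Tissue density in kg/m^3 (default 1000).

    Returns
    -------
    float or numpy.ndarray
        Young's modulus in kPa.
    """
    c_arr = np.asarray(c, dtype=float)
    if rho <= 0:
        raise ValueError("rho must be positive")
    if np.any(c_arr < 0):
        raise ValueError("shear-wave speed must be non-negative")
    e_kpa = 3.0 * rho * c_arr**2 / 1000.0
    return float(e_kpa) if np.isscalar(c) or c_arr.ndim == 0 else e_kpa


def modulus_to_sws(e_kpa, rho: float = DEFAULT_RHO):
    """Inverse conversion: Young's modulus (kPa) to shear-wave speed (m/s)."""
    e_arr = np.asarray(e_kpa, dtype=float)
    if rho <= 0:
        raise ValueError("rho must be positive")
    if np.any(e_arr < 0):
        raise ValueError("modulus must be non-negative")
    c = np.sqrt(e_arr * 1000.0 / (3.0 * rho))
    return float(c) if np.isscalar(e_kpa) or e_arr.ndim == 0 else c


def summarize_roi(
    record: ExamRecord,
    rho: float = DEFAULT_RHO,
    qc_threshold: float = DEFAULT_QC_THRESHOLD,
) -> StiffnessEstimate:
    """Summarise one ROI: median and SD of the per-pixel moduli plus QC flag.

    Statistics are computed on the modulus scale; the summary SWS is the
    back-conversion of the median modulus (consistent with reporting the same
    exam as both an SWS and a kPa figure). The QC rule rejects the acquisition
    when the within-ROI SD strictly exceeds ``qc_threshold`` (default 30 %) of
    the median; equality passes.
    """
    moduli = sws_to_modulus(record.sws_samples, rho=rho)
    median = float(np.median(moduli))
    sd = float(np.std(moduli, ddof=1)) if moduli.size > 1 else 0.0
    if median <= 0:
        raise ValueError("degenerate ROI: non-positive median modulus")
    frac = sd / median
    return StiffnessEstimate(
        median_sws=modulus_to_sws(median, rho=rho),
        median_modulus=median,
        modulus_sd=sd,
        sd_fraction=frac,
        qc_pass=frac <= qc_threshold,
    )


def aggregate_exam(estimates: Sequence[StiffnessEstimate]) -> tuple[float, float]:
    """Aggregate the replicate acquisitions of one animal x hour x operator exam.

    QC-rejected replicates are dropped before aggregation. Returns
    ``(median_kpa, sd_kpa)`` over the surviving replicate medians; with a
    single survivor the SD is undefined and reported as NaN. With zero
    survivors the exam is missing and both values are NaN.
    """
    surviving = [e.median_modulus for e in estimates if e.qc_pass]
    if not surviving:
        return (math.nan, math.nan)
    median = float(np.median(surviving))
    sd = float(np.std(surviving, ddof=1)) if len(surviving) > 1 else math.nan
    return (median, sd)


def format_pct(count: int, total: int) -> str:
    """Percentage formatted to two significant figures (study-report style).

    ``6/378 -> "1.6"``, ``2/378 -> "0.53"``, ``0 -> "0"``.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if count == 0:
        return "0"
    pct = 100.0 * count / total
    digits = 1 - int(math.floor(math.log10(abs(pct))))
    rounded = round(pct, digits)
    if digits <= 0:
        return f"{rounded:.0f}"
    return f"{rounded:.{digits}f}"


def account_dataset(
    n_total: int,
    missing: Iterable | int = (),
    qc_rejected: Iterable | int = (),
) -> DatasetAccounting:
    """Dataset accounting: totals and rejection percentages.

    ``missing`` and ``qc_rejected`` may be counts or collections of rejected
    record identifiers.
    """
    n_missing = missing if isinstance(missing, int) else len(list(missing))
    n_qc = qc_rejected if isinstance(qc_rejected, int) else len(list(qc_rejected))
    if n_missing < 0 or n_qc < 0 or n_missing + n_qc > n_total:
        raise ValueError("rejection counts must be non-negative and <= n_total")
    return DatasetAccounting(
        n_total=n_total,
        n_rejected_missing=n_missing,
        n_rejected_qc=n_qc,
        pct_rejected_missing=format_pct(n_missing, n_total),
        pct_rejected_qc=format_pct(n_qc, n_total),
    )


def records_from_frame(frame: pd.DataFrame) -> list[ExamRecord]:
    """Build :class:`ExamRecord` objects from a tidy exam table.

    The table carries one row per ROI with the design columns
    ``animal,group,hour,operator,replicate`` and the per-pixel SWS samples in
    ``sws_0 .. sws_{n-1}`` columns (the CSV dialect written by the generator).
    """
    sample_cols = sorted(
        (c for c in frame.columns if c.startswith("sws_")),
        key=lambda c: int(c.split("_")[1]),
    )
    if not sample_cols:
        raise ValueError("no sws_* sample columns found")
    records = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        samples = np.array([d[c] for c in sample_cols], dtype=float)
        records.append(
            ExamRecord(
                animal=str(d["animal"]),
                group=str(d["group"]),
                hour=float(d["hour"]),
                operator=str(d["operator"]),
                replicate=int(d["replicate"]),
                sws_samples=samples,
            )
        )
    return records


def roi_table(
    frame: pd.DataFrame,
    rho: float = DEFAULT_RHO,
    qc_threshold: float = DEFAULT_QC_THRESHOLD,
) -> pd.DataFrame:
    """Per-ROI summary table (one row per acquisition, QC flag included)."""
    rows = []
    for rec in records_from_frame(frame):
        est = summarize_roi(rec, rho=rho, qc_threshold=qc_threshold)
        rows.append(
            {
                "animal": rec.animal,
                "group": rec.group,
                "hour": rec.hour,
                "operator": rec.operator,
                "replicate": rec.replicate,
                "median_sws": est.median_sws,
                "median_kpa": est.median_modulus,
                "sd_kpa": est.modulus_sd,
                "sd_fraction": est.sd_fraction,
                "qc_pass": est.qc_pass,
            }
        )
    return pd.DataFrame(rows)


def quantify_dataset(
    frame: pd.DataFrame,
    rho: float = DEFAULT_RHO,
    qc_threshold: float = DEFAULT_QC_THRESHOLD,
) -> pd.DataFrame:
    """Per-exam stiffness table from a raw ROI table.

    Summarises every ROI, drops QC failures, aggregates replicates per
    animal x hour x operator, and returns a tidy frame with columns
    ``animal,group,hour,operator,median_kpa,sd_kpa,qc_n_rejected,n_replicates``.
    Exams whose replicates were all rejected appear with NaN medians.
    """
    records = records_from_frame(frame)
    rows = []
    key = lambda r: (r.animal, r.group, r.hour, r.operator)
    by_exam: dict[tuple, list[StiffnessEstimate]] = {}
    for rec in records:
        by_exam.setdefault(key(rec), []).append(
            summarize_roi(rec, rho=rho, qc_threshold=qc_threshold)
        )
    for (animal, group, hour, operator), ests in sorted(by_exam.items()):
        median, sd = aggregate_exam(ests)
        rows.append(
            {
                "animal": animal,
                "group": group,
                "hour": hour,
                "operator": operator,
                "median_kpa": median,
                "sd_kpa": sd,
                "qc_n_rejected": sum(not e.qc_pass for e in ests),
                "n_replicates": len(ests),
            }
        )
    return pd.DataFrame(rows)
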