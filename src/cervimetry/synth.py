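"""Synthetic study generators.

Emulates the longitudinal elastography design (two groups of ewes examined
every 4 h for 24 h by two operators, three replicate acquisitions each), the
quadratic stiffness trajectories of the two groups, within-ROI pixel
dispersion including designed QC violations, SHG-like fibrous-texture images
with controllable alignment/waviness at the microscope's 100 um / 300 px
sampling, and a paired prostaglandin (PGE2) concentration table. All
generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .elasto import modulus_to_sws, DEFAULT_RHO

DEFAULT_HOURS = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0)

#: pixel dispersion (SD/median of the per-pixel moduli) for clean acquisitions
PIXEL_SD_FRACTION = 0.10
#: engineered dispersion for designed QC-violation slots (rule rejects > 0.30)
QC_VIOLATION_SD_FRACTION = 0.45


@dataclass(frozen=True)
class SWEDesign:
    """Factorial layout of the elastography study.

    Defaults reproduce the study design: 4 control + 5 treated animals,
    7 exam times (every 4 h over 24 h), 2 operators, 3 replicates, i.e.
    9 x 7 x 2 x 3 = 378 ROI acquisitions.
    """

    n_animals_control: int = 4
    n_animals_treated: int = 5
    hours: tuple[float, ...] = DEFAULT_HOURS
    n_operators: int = 2
    n_replicates: int = 3
    pixels_per_roi: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_animals_control + self.n_animals_treated,
               self.n_operators, self.n_replicates, self.pixels_per_roi) < 1:
            raise ValueError("all design counts must be >= 1")
        hours = tuple(float(h) for h in self.hours)
        if any(b <= a for a, b in zip(hours, hours[1:])):
            raise ValueError("hours must be strictly increasing")
        object.__setattr__(self, "hours", hours)

    @property
    def n_records(self) -> int:
        n_animals = self.n_animals_control + self.n_animals_treated
        return n_animals * len(self.hours) * self.n_operators * self.n_replicates


@dataclass(frozen=True)
class TrajectoryModel:
    """Quadratic stiffness trajectory E(t) = a t^2 + b t + c (kPa, t in hours).

    ``noise_sd_exam`` is additive Gaussian exam-to-exam noise on the kPa
    scale; ``noise_sd_pixel_frac`` sets the within-ROI pixel dispersion as a
    fraction of the ROI median modulus.
    """

    a: float
    b: float
    c: float
    noise_sd_exam: float = 0.5
    noise_sd_pixel_frac: float = PIXEL_SD_FRACTION

    def __post_init__(self) -> None:
        if self.noise_sd_exam < 0 or self.noise_sd_pixel_frac < 0:
            raise ValueError("noise SDs must be >= 0")

    def predict(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        out = self.a * t**2 + self.b * t + self.c
        return float(out) if out.ndim == 0 else out

    def validate_over(self, hours: Sequence[float]) -> None:
        pred = self.predict(np.asarray(hours, dtype=float))
        if np.any(pred <= 0):
            bad = np.asarray(hours)[np.asarray(pred) <= 0]
            raise ValueError(
                f"trajectory predicts non-positive stiffness at hours {bad.tolist()}"
            )


#: trajectories reported for the study groups (kPa as a function of hours)
TREATED_TRAJECTORY = TrajectoryModel(a=0.0103, b=-0.3844, c=9.2147)
CONTROL_TRAJECTORY = TrajectoryModel(a=0.0014, b=-0.0648, c=10.7016)


def _roi_pixel_moduli(
    rng: np.random.Generator,
    median_kpa: float,
    sd_fraction: float,
    n_pixels: int,
) -> np.ndarray:
    """Per-pixel moduli with an exact sample median and SD/median fraction.

    Draws lognormal deviates around ``median_kpa`` (keeps moduli positive),
    then pins the sample median exactly by centring the log-deviates on their
    own median, and the sample SD exactly by an affine rescale of the
    deviations about the median. The rescale is order-preserving, so the
    median is untouched; this makes designed QC violations deterministic.
    """
    if n_pixels == 1 or sd_fraction == 0.0:
        return np.full(n_pixels, median_kpa)
    # sigma such that a lognormal's SD/median roughly matches the target
    sigma = math.sqrt(math.log1p(sd_fraction**2))
    z = rng.standard_normal(n_pixels)
    z -= np.median(z)
    moduli = median_kpa * np.exp(sigma * z)
    s = float(np.std(moduli, ddof=1))
    if s > 0:
        moduli = median_kpa + (moduli - median_kpa) * (sd_fraction * median_kpa / s)
    if np.any(moduli <= 0):  # only reachable for extreme sd_fraction
        raise ValueError(
            f"pixel dispersion {sd_fraction} too large for positive moduli"
        )
    return moduli


def simulate_swe_dataset(
    design: SWEDesign,
    control_model: TrajectoryModel = CONTROL_TRAJECTORY,
    treated_model: TrajectoryModel = TREATED_TRAJECTORY,
    qc_violation_slots: Sequence[int] = (),
    rho: float = DEFAULT_RHO,
) -> pd.DataFrame:
    """Simulate the full ROI-level exam table.

    One row per ROI acquisition: design columns ``animal, group, hour,
    operator, replicate`` plus inline per-pixel SWS sample columns
    ``sws_0..``. The ROI median modulus equals the group trajectory at the
    exam hour plus exam-level Gaussian noise; records listed in
    ``qc_violation_slots`` (row indices) get pixel dispersion engineered to
    exceed the 30 % rejection threshold.
    """
    control_model.validate_over(design.hours)
    treated_model.validate_over(design.hours)
    slots = set(int(i) for i in qc_violation_slots)
    if slots and (min(slots) < 0 or max(slots) >= design.n_records):
        raise ValueError("qc_violation_slots out of range for this design")

    rng = np.random.default_rng(np.random.SeedSequence(design.seed))
    animals = [("C%d" % (i + 1), "control", control_model)
               for i in range(design.n_animals_control)]
    animals += [("T%d" % (i + 1), "treated", treated_model)
                for i in range(design.n_animals_treated)]

    rows = []
    idx = 0
    for animal, group, model in animals:
        for hour in design.hours:
            for op in range(1, design.n_operators + 1):
                # one exam = one probe placement; replicates share its noise
                exam_kpa = model.predict(hour) + rng.normal(0.0, model.noise_sd_exam)
                for rep in range(1, design.n_replicates + 1):
                    roi_kpa = exam_kpa + rng.normal(0.0, 0.25 * model.noise_sd_exam)
                    if roi_kpa <= 0:
                        raise ValueError(
                            f"simulated non-positive stiffness ({roi_kpa:.3f} kPa) "
                            f"for {animal} at {hour} h; reduce noise_sd_exam"
                        )
                    frac = (QC_VIOLATION_SD_FRACTION if idx in slots
                            else model.noise_sd_pixel_frac)
                    moduli = _roi_pixel_moduli(rng, roi_kpa, frac,
                                               design.pixels_per_roi)
                    sws = modulus_to_sws(moduli, rho=rho)
                    row = {"animal": animal, "group": group, "hour": hour,
                           "operator": f"op{op}", "replicate": rep}
                    row.update({f"sws_{j}": sws[j] for j in range(sws.size)})
                    rows.append(row)
                    idx += 1
    return pd.DataFrame(rows)


def simulate_exam_stiffness(
    model: TrajectoryModel,
    n_animals: int,
    hours: Sequence[float] = DEFAULT_HOURS,
    n_operators: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Exam-level stiffness values only (no pixel samples): the trajectory
    polynomial evaluated at each hour plus N(0, noise_sd_exam) per
    animal x hour x operator. Used for trajectory-recovery studies."""
    model.validate_over(hours)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for i in range(n_animals):
        for hour in hours:
            for op in range(1, n_operators + 1):
                rows.append({
                    "animal": f"A{i + 1}", "hour": float(hour),
                    "operator": f"op{op}",
                    "median_kpa": model.predict(hour)
                    + rng.normal(0.0, model.noise_sd_exam),
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fibrous-texture images


@dataclass(frozen=True)
class FibreParams:
    """Parameters of the synthetic SHG-like fibrous texture.

    Lengths are in micrometres; the default sampling (1/3 um/px) matches a
    100 um x 100 um field imaged at 300 x 300 px. Fibres are rendered as
    Gaussian-profile ridges in elongated bundles with smooth per-fibre
    amplitude envelopes; ``dispersion_sd`` is the SD of per-fibre orientation
    jitter and is the ground-truth disorder parameter.
    """

    mean_orientation: float = 0.0     # degrees, 0 = horizontal fibres
    dispersion_sd: float = 0.0        # degrees
    waviness_amp: float = 1.0         # um, transverse sinusoidal displacement
    waviness_period: float = 25.0     # um
    fibre_spacing: float = 4.0        # um, mean spacing between fibre axes
    fibre_width: float = 1.5          # um, FWHM of the ridge profile
    intensity_peak: float = 900.0     # counts at the brightest ridge
    background_sd: float = 1.0        # counts, additive detector noise SD
    pixel_size: float = 1.0 / 3.0     # um/px
    image_size: int = 300             # px (square)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.dispersion_sd < 0:
            raise ValueError("dispersion_sd must be >= 0")
        if not (self.intensity_peak > self.background_sd >= 0):
            raise ValueError("need intensity_peak > background_sd >= 0")
        if self.waviness_amp > 0 and self.waviness_period <= 0:
            raise ValueError("waviness_period must be positive")

    @property
    def extent_um(self) -> float:
        return self.image_size * self.pixel_size


@dataclass(frozen=True)
class FibreImage:
    """Grayscale intensity raster with physical pixel size.

    ``provenance`` is ``"synthetic"`` for generated textures (ground truth
    attached) or ``"measured"`` for images read from disk.
    """

    pixels: np.ndarray = field(repr=False)
    pixel_size: float
    provenance: str = "measured"
    ground_truth: FibreParams | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if np.any(px < 0):
            raise ValueError("intensities must be non-negative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "pixels", px)


def _render_fibre(x, y, px, py, theta, params: FibreParams, rng,
                  amp: float, seg_frac: float) -> np.ndarray:
    """One Gaussian-profile ridge through pivot (px, py) at angle theta,
    with sinusoidal waviness and a smooth longitudinal segment envelope."""
    sigma_w = params.fibre_width / 2.355  # FWHM -> SD
    u = (x - px) * math.cos(theta) + (y - py) * math.sin(theta)
    v = -(x - px) * math.sin(theta) + (y - py) * math.cos(theta)
    if params.waviness_amp > 0:
        phase = rng.uniform(0.0, 2.0 * math.pi)
        v = v - params.waviness_amp * np.sin(
            2.0 * math.pi * u / params.waviness_period + phase
        )
    profile = np.exp(-(v**2) / (2.0 * sigma_w**2))
    seg_sigma = seg_frac * params.extent_um / 2.355
    envelope = amp * np.exp(-(u**2) / (2.0 * seg_sigma**2))
    return envelope * profile


def simulate_fibre_image(params: FibreParams, seed: int = 0) -> FibreImage:
    """Render a fibrous texture with known ground truth.

    The texture emulates what SHG sees in fibrillar collagen: a dominant
    bright *bundle* — a few fibres tightly spaced ``fibre_spacing`` apart —
    plus sparse dim background fibres, all rendered as Gaussian-profile
    ridges with smooth longitudinal amplitude envelopes. Each fibre's
    orientation is the mean orientation plus Gaussian jitter of SD
    ``dispersion_sd`` (the ground-truth disorder parameter) and its axis is
    displaced transversely by a random-phase sinusoid
    (``waviness_amp``/``waviness_period``). The noise-free field is scaled so
    its maximum equals ``intensity_peak``; Gaussian detector noise of SD
    ``background_sd`` is added afterwards and negative values clipped.
    """
    extent = params.extent_um
    if extent < params.fibre_spacing:
        raise ValueError("image smaller than one fibre period")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = params.image_size
    # physical coordinates of pixel centres, origin at field centre
    coords = (np.arange(n) + 0.5) * params.pixel_size - extent / 2.0
    x, y = np.meshgrid(coords, coords)
    theta0 = math.radians(params.mean_orientation)
    cos0, sin0 = math.cos(theta0), math.sin(theta0)

    ridge = np.zeros((n, n))
    # dominant bundle: a few bright, near-collinear fibre segments running
    # through a common pivot near the field centre. When aligned they fuse
    # into one coherent filament (the bright SHG bundle); orientation jitter
    # splays them into a fan, which is how disorder reads out spectrally.
    n_bundle = 4
    v_centre = rng.normal(0.0, extent / 24.0)
    pu_bundle = rng.uniform(-extent / 8, extent / 8)
    for _ in range(n_bundle):
        theta = theta0 + math.radians(rng.normal(0.0, params.dispersion_sd))
        v_f = v_centre + rng.normal(0.0, 0.2 * params.fibre_width)
        pu = pu_bundle + rng.normal(0.0, 0.05 * extent)
        px, py = -sin0 * v_f + cos0 * pu, cos0 * v_f + sin0 * pu
        ridge = np.maximum(ridge, _render_fibre(
            x, y, px, py, theta, params, rng,
            amp=rng.uniform(0.7, 1.0), seg_frac=rng.uniform(0.15, 0.30)))
    # sparse dim background fibres spread over the field
    for v0 in np.arange(-extent * 0.7, extent * 0.7, 8.0 * params.fibre_spacing):
        theta = theta0 + math.radians(rng.normal(0.0, params.dispersion_sd))
        v_f = v0 + rng.normal(0.0, params.fibre_spacing)
        pu = rng.uniform(-extent / 4, extent / 4)
        px, py = -sin0 * v_f + cos0 * pu, cos0 * v_f + sin0 * pu
        ridge = np.maximum(ridge, _render_fibre(
            x, y, px, py, theta, params, rng,
            amp=rng.uniform(0.005, 0.015), seg_frac=rng.uniform(0.2, 0.4)))

    peak = ridge.max()
    if peak > 0:
        ridge *= params.intensity_peak / peak
    if params.background_sd > 0:
        ridge = ridge + rng.normal(0.0, params.background_sd, size=ridge.shape)
    pixels = np.clip(ridge, 0.0, None)
    return FibreImage(pixels=pixels, pixel_size=params.pixel_size,
                      provenance="synthetic", ground_truth=params)


#: parameter presets for the two morphologies contrasted in the study:
#: well-aligned parallel collagen (control mucosal chorion) vs disorganised
#: wavy fibres (ripened tissue)
ALIGNED_FIBRES = FibreParams(dispersion_sd=5.0, waviness_amp=0.5)
DISORDERED_FIBRES = FibreParams(dispersion_sd=50.0, waviness_amp=3.0,
                                waviness_period=15.0)


# ---------------------------------------------------------------------------
# prostaglandin table


def simulate_pge2_table(
    n_per_group: int = 5,
    fold_increase_treated: float = 10.0,
    seed: int = 0,
    baseline_pg_ml: float = 40.0,
    cv: float = 0.15,
) -> pd.DataFrame:
    """Paired PGE2-metabolite concentrations (pg/mL) before/after treatment.

    Two samples per animal (T1 at the first exam, T2 at the end); treated T2
    is scaled by ``fold_increase_treated``, control T2 stays near T1.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 animals per group")
    if fold_increase_treated <= 0:
        raise ValueError("fold_increase_treated must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for group, fold, tag in (("control", 1.0, "C"), ("treated",
                                                     fold_increase_treated, "T")):
        for i in range(n_per_group):
            t1 = baseline_pg_ml * math.exp(rng.normal(0.0, cv))
            t2 = t1 * fold * math.exp(rng.normal(0.0, cv))
            animal = f"{tag}{i + 1}"
            rows.append({"animal": animal, "group": group,
                         "sample_time": "T1", "concentration": t1})
            rows.append({"animal": animal, "group": group,
                         "sample_time": "T2", "concentration": t2})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O helpers


def write_fibre_image(image: FibreImage, path: str | Path) -> None:
    """Write a 16-bit single-channel TIFF plus a JSON ground-truth sidecar.

    Physical pixel size is stored in the TIFF resolution tags
    (pixels per centimetre) and echoed in the sidecar.
    """
    import tifffile

    path = Path(path)
    pixels = np.clip(np.round(image.pixels), 0, 65535).astype(np.uint16)
    px_per_cm = 1.0e4 / image.pixel_size
    tifffile.imwrite(path, pixels, resolution=(px_per_cm, px_per_cm),
                     resolutionunit="CENTIMETER")
    sidecar = {"pixel_size_um": image.pixel_size,
               "provenance": image.provenance,
               "ground_truth": asdict(image.ground_truth)
               if image.ground_truth else None}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_fibre_image(path: str | Path) -> FibreImage:
    """Read a TIFF written by :func:`write_fibre_image` (or any greyscale
    TIFF with resolution tags); ground truth is restored from the sidecar if
    present."""
    import tifffile

    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        pixels = page.asarray().astype(float)
        xres = page.tags.get("XResolution")
        unit = page.tags.get("ResolutionUnit")
        pixel_size = 1.0
        if xres is not None:
            num, den = xres.value
            per_unit = num / den
            scale = {2: 2.54e4, 3: 1.0e4}.get(getattr(unit.value, "value", unit.value) if unit else 3, 1.0e4)
            pixel_size = scale / per_unit
    provenance, ground_truth = "measured", None
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        pixel_size = meta.get("pixel_size_um", pixel_size)
        provenance = meta.get("provenance", "measured")
        if meta.get("ground_truth"):
            ground_truth = FibreParams(**meta["ground_truth"])
    return FibreImage(pixels=pixels, pixel_size=pixel_size,
                      provenance=provenance, ground_truth=ground_truth)
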