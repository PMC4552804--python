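# Methods

This note records the models implemented in `cervimetry`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
validation does and does not demonstrate.

## Stiffness quantification (`elasto`)

**Model.** A shear wave of speed *c* in a locally homogeneous, isotropic,
incompressible elastic medium implies a Young's modulus E = 3ρc². The
default tissue density is ρ = 1000 kg/m³; it reproduces the usual
display-unit convention of clinical elastography and is exposed as a
configuration parameter. The package always converts per-pixel speeds first
and computes summary statistics **on the modulus scale**; the summary
shear-wave speed of an ROI is the back-conversion of its median modulus, so
the two reported scales are always consistent with each other.

**ROI summary and quality control.** An ROI is summarised by the median and
the sample (n−1) standard deviation of its per-pixel moduli. Acquisitions
whose SD exceeds 30 % of the median are rejected as artefacts. The boundary
convention is *reject strictly greater than 30 %*: an SD of exactly 30 %
passes. Within one exam (animal × hour × operator) the three replicate
acquisitions are aggregated by the median of the surviving replicate
medians; with a single survivor the exam SD is undefined and reported as
missing (NaN), never as zero; with no survivors the exam itself is missing
and is excluded from all time-point statistics rather than imputed.

**Accounting.** Rejection percentages are formatted to two significant
figures (6/378 → 1.6 %, 2/378 → 0.53 %), the convention used in study-style
reporting.

## Synthetic study generator (`synth`)

The generator emulates the design of a two-group longitudinal ripening
study: 4 control + 5 treated animals, exams at {0, 4, …, 24} h, two
operators, three replicate acquisitions — 378 ROI records in the default
configuration.

**Stiffness trajectories.** Group-level stiffness follows quadratics in
time. The built-in presets are a declining treated-group trajectory
(0.0103 t² − 0.3844 t + 9.2147 kPa) and a near-flat control trajectory
(0.0014 t² − 0.0648 t + 10.7016 kPa). A model that predicts non-positive
stiffness anywhere over the design hours is rejected with a diagnostic.

**Noise model.** No variance decomposition is asserted; each component is a
parameter:

- *exam-level* noise: additive Gaussian on the kPa scale, default SD
  0.5 kPa, chosen to give per-time dispersions of the order observed in
  in-vivo elastography at these stiffnesses (a few tenths to ~1 kPa);
- *replicate-level* noise: additive Gaussian with SD equal to a quarter of
  the exam-level SD, so that replicate acquisitions of one probe placement
  agree much more closely than repeated placements — without it,
  intra-operator agreement would be degenerate;
- *pixel-level* dispersion: per-pixel moduli are drawn lognormal around the
  ROI median (keeping speeds positive), then deviations are affinely
  rescaled about the median so that the *sample* SD/median equals the
  requested fraction exactly (default 0.10). The rescale is order-preserving
  and therefore leaves the sample median untouched. Designated
  QC-violation records use a fraction of 0.45; because the achieved
  dispersion is exact rather than targeted in expectation, the designed
  violations — and only those — are rejected by the downstream 30 % rule,
  deterministically.

**Seeding.** One master seed is split into per-purpose substreams with
`numpy.random.SeedSequence`; a fixed seed reproduces every table and image
byte-for-byte.

**Prostaglandin table.** Two samples per animal (start/end), lognormal
biological scatter (CV 15 %) around a 40 pg/mL baseline; the treated group's
second sample is scaled by a configurable fold change (default 10). This
reproduces only the *structure* needed by the downstream Kruskal–Wallis
comparison, not assay chemistry.

## Fibrous-texture generator (`synth.simulate_fibre_image`)

Textures are rendered at the microscope's sampling (100 µm field, 300 px,
i.e. 1/3 µm/px) as Gaussian-profile ridges with:

- a **dominant bundle**: four bright, near-collinear fibre segments through
  a common pivot near the field centre, each 15–30 % of the field long, with
  per-fibre orientation jitter of SD `dispersion_sd` (the ground-truth
  disorder parameter) and sinusoidal transverse waviness of amplitude
  `waviness_amp` and period `waviness_period` with random phase;
- sparse, much dimmer background fibres with the same orientation
  statistics;
- intensity scaled so the noise-free maximum equals `intensity_peak`, then
  additive Gaussian detector noise of SD `background_sd` (default 1 count,
  photon-counting-like), clipped at zero.

The bundle-dominated structure is deliberate and load-bearing. The
directionality mask keeps only Fourier bins whose magnitude is at least
80 % of the DC value; for any image whose intensity fills the window
uniformly the spectrum near DC is essentially a discrete delta and the mask
degenerates to a single pixel (R = 1 identically). A multi-pixel,
orientation-sensitive mask requires a *spatially concentrated, coherent*
bright structure — which is exactly what SHG produces on discrete collagen
bundles over a dark background. When the bundle fibres are parallel they
fuse into one coherent filament whose spectrum decays slowly perpendicular
to the fibre axis (elongated mask, small R); orientation jitter splays them
into a fan, the coherent structure disappears, and the mask collapses
towards isotropy (R → 1). Segment lengths are kept short (≲30 µm) because a
filament spanning the full window has a spectral ridge thinner than one
frequency bin and is then invisible at oblique orientations — a pure
discretization effect of the thresholded DFT.

What the generator does **not** emulate: wall-to-wall collagen meshes,
pore-scale texture, multi-bundle interference, detector saturation, or the
absolute intensity calibration of any particular instrument. Passing tests
therefore demonstrate that the statistic *orders* alignment correctly and
discriminates group-level differences on bundle-like textures, not that any
particular absolute R value will be reproduced on real tissue.

## Directionality statistic (`shgtex`)

Pipeline per ROI window: centred 2-D DFT magnitude → threshold at 80 % of
the DC bin → 8-connected component containing DC → moment ellipse.

- **Spectrum quantity**: magnitude, not power (thresholding power at 80 %
  would select a different, smaller region); no apodization window is
  applied by default — both choices are visible in the code and the
  threshold is a parameter.
- **Connected component**: disconnected harmonic peaks also exceed the
  threshold for strongly periodic textures; a single ellipse over
  disconnected regions is not meaningful, so the mask is restricted to the
  DC-connected component.
- **Moment ellipse**: axis lengths are 4·√λ for the eigenvalues λ of the
  normalised second-central-moment matrix with the +1/12 per-pixel variance
  correction (each pixel is a unit square). With this correction a
  single-pixel mask is exactly isotropic (R = 1, the degenerate case) and an
  a×b rectangle gives R = b/a exactly; for large regions it agrees with
  scikit-image's `regionprops` axis lengths, which are used as an
  independent cross-check in the tests.
- **ROI tiling**: windows are squares of the requested physical size
  (default 60 µm) rounded to an even pixel count, laid out as a
  non-overlapping grid centred within the image, partial edge windows
  discarded.
- **Stitching**: mosaics assume a fixed fractional overlap (default 10 %);
  overlapping strips are blended by linear feathering and the accumulated
  weights are normalised, so identical data in the overlap reconstructs the
  source exactly.
- **Intensity summary**: mean of the 10 brightest pixels; ties are
  irrelevant to the result.

## Statistics (`stats`)

- **ANOVA-type statistic (ATS)** for the two-factor design (whole-plot:
  group; repeated: time): all observations are jointly mid-ranked, relative
  effects per group×time cell are contrasted through projection matrices
  (P_a ⊗ 1/T, 1/a ⊗ P_T, P_a ⊗ P_T), and the statistic is referred to an F
  distribution with Box-approximation numerator df. The whole-plot effect
  uses an estimated (Satterthwaite-type) denominator df — the formula
  reduces exactly to the Brunner–Munzel df in the two-sample, one-timepoint
  case — while within-subject effects use F(f, ∞). Covariances are the
  per-group empirical covariances of the subjects' rank profiles; missing
  cells are handled by available-case (pairwise-complete) estimation, and
  replicated observations per subject×time (two operators) are averaged on
  the rank scale. Under the generator's null (flat trajectories, exam noise)
  the group-effect size is near-nominal (≈5 % at the 5 % level at the study
  size); with a strong animal-level random effect at n = 4–5 subjects per
  group it becomes mildly liberal (~7 %), a known small-sample property of
  this class of approximation.
- **Rank-sum tests**: exact two-sided p by full enumeration of mid-rank
  assignments for combined n ≤ 12 (correct under ties), tie-corrected normal
  approximation above; two-sided p doubles the smaller tail, capped at 1.
- **Multiplicity**: "step-up" correction across the seven exam hours is
  implemented as Benjamini–Hochberg (the standard reading of
  "Bonferroni-Hochberg"); plain Bonferroni is available behind a flag.
- **Bland–Altman**: bias = mean difference, limits of agreement = bias ±
  1.96·SD of differences (large-sample factor; no small-sample t
  correction). Intra-operator pairs are the first two surviving replicates
  of each exam; inter-operator pairs are the exam medians of the two
  operators. Both are reported, since pairing at replicate vs exam level is
  a genuinely open choice.
- **Trajectory fits**: OLS on {1, t, t²}. The default fit target is the
  per-hour median across animals and operators (7 points per group),
  matching a trajectory-of-medians reading; fitting all raw points is
  available behind a flag. R² = 1 − SS_res/SS_tot, defined as 0 (with a
  warning) when SS_tot = 0.
- **Kruskal–Wallis**: tie-corrected H with a χ² reference; all-identical
  data returns (H = 0, p = 1) instead of raising.

## Validation problem sizes

The test suite validates: the DFT against a direct double-sum oracle on
16×16 images; moment ellipses against analytic disks/rectangles and
`regionprops`; trajectory-coefficient recovery over 200 seeded replicates of
the 5-animal × 7-hour × 2-operator design; ATS type-I error over 200 null
simulations at the study size; Bland–Altman coverage on 1000 paired normal
differences; and the alignment contrast over 20 seeds per dispersion level
and 20 replicate two-group comparisons at 10 ROIs per group. These sizes
give Monte-Carlo error comfortably inside the asserted tolerances while
keeping the whole suite fast.

## Known limitations

- The scanner's internal beamforming and shear-wave tracking are out of
  scope; the pipeline starts from per-pixel speed samples.
- Whether a clinical scanner's kPa display uses exactly ρ = 1000 kg/m³ is an
  inference (the conversion reproduces reported speed/modulus pairs at their
  printed rounding, which is consistent with it).
- Whether the directionality statistic should use axis lengths or squared
  lengths is resolved in favour of axis lengths (the moment-ellipse tool
  convention); absolute R values depend on texture class and cannot be
  transferred between generators and tissue.
- The ATS implementation covers the two-factor layout used here
  (group × time), not general factorial designs; confidence intervals for
  relative treatment effects are not provided.
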