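# Methods

This note documents the models, defaults, and design choices behind
`hcsprotect`, and what the synthetic-data tests do and do not show about
real screens.

## Screen model and plate geometry

A screen is a set of 16×24 plates, three biological replicates deep,
with identical miRNA positions across replicates.  Columns 1–2 hold
dark controls, columns 23–24 light controls; eight wells at the top of
column 24 are transfection controls carrying a red-labelled
non-targeting mimic, leaving 24 light controls per plate.  The 320
interior wells carry one library miRNA each, so 1,268 miRNAs occupy four
plates per replicate.  Control placement is configurable
(`LayoutSpec`); the defaults encode the geometry above.

## Fast-mode generator (well tables)

Each well has a planted dying probability: dark controls sit at the dark
baseline (default 0.05), light-exposed wells at the light baseline
(default 0.40) times the well's miRNA effect (multiplicative; 1 neutral,
<1 protective, >1 deleterious).  The observed percent dying adds a
per-plate batch offset (additive Gaussian, SD 0.02, shared by every well
on the plate — the thing per-plate normalisation exists to remove) and
per-well Gaussian noise (SD 0.05 on the fraction scale), clipped to
[0, 1].  Baselines of 5%/40% are configuration, not biological claims;
they make the QC separation test non-trivial (separation statistic ~7
at the default noise, floor 2).  With these conditions a planted effect
of 0.5 sits near Z ≈ −4 and is recovered essentially always, while the
null tail beyond |Z| = 2.1 matches the scoring structure's Monte-Carlo
tail mass (see below).

## Image-mode generator

Nuclei are 2-D anisotropic Gaussian blobs (minor/major axis ratio drawn
from [0.8, 1]) on a flat background, with Poisson-like shot noise
(Gaussian with variance equal to the signal) and Gaussian read noise
(SD 20), quantised to 16-bit.  Defaults: 300×300 px wells, Poisson(80)
nuclei placed by random sequential adsorption with non-overlapping
effective radii (2.5σ) and a border margin; healthy template amplitude
1200 a.u., σ = 4 px, with 8%/5% per-nucleus amplitude/size jitter.
Dying nuclei are strictly brighter (×2.2) and smaller (σ ×0.5) with
intra-nuclear speckle (CV 0.3) — the condensation contrast the
classifier relies on.  Per-well dying labels are Bernoulli draws from
the well's planted probability, so closed-form binomial expectations are
available for tests.  Transfection controls render a second channel
marking 50% of nuclei by default.

What this emulates: the intensity/morphology contrast between healthy
and pyknotic nuclei, density and packing of a well-seeded plate, photon
and camera noise.  What it does not: optical aberrations and uneven
illumination, clumped or overlapping nuclei, debris, focus drift,
staining variability across wells.  Passing the imaging tests therefore
shows the operator chain is correct and well-calibrated on clean,
non-overlapping nuclei — not that it matches a commercial analyser on
real plates.

## Segmentation and classification

Segmentation is a fixed, auditable chain: Gaussian smoothing (σ = 1 px),
global Otsu threshold with a background-contrast guard (the threshold
must clear the image median by 3 scaled MADs, otherwise the image is
declared empty — this is what keeps pure-noise images from segmenting
their noise), minimum-area filter (30 px²), distance-transform watershed
(peak separation 7 px) to split touching nuclei, and removal of
edge-touching objects (truncated features bias intensity and area).
Smoothing is deliberately light: at σ = 2 the small pyknotic nuclei blur
disproportionately and their segmented-area contrast against healthy
nuclei collapses.

Classification defaults to a two-threshold rule — dying iff mean
intensity ≥ (median + k·MAD_s) AND area ≤ (median − k·MAD_s) of a
reference population, k = 3 — with the reference taken from the plate's
own dark-control wells (almost entirely healthy, and robust statistics
tolerate the ~5% dying contamination).  Fixed thresholds can be supplied
instead; a 2-component k-means mode on (log intensity, log area) exists
behind a flag.  The rule is deterministic, monotone in its thresholds,
and auditable — which is why it is the default over clustering.  Wells
with fewer than 50 nuclei are flagged invalid and excluded from all
plate statistics rather than imputed.

## QC and Z scoring

σ is the sample (n−1) standard deviation of the plate's light controls;
an independent longhand mean/SD recomputation pins this choice in the
tests.  The QC statistic is the light-vs-dark standardised mean
difference over the pooled SD (floor 2, configurable; Z′-factor mode
available).  Z scoring refuses plates that failed QC unless explicitly
overridden, and refuses σ = 0 always.  Normalisation is a single step:
the Z score against same-plate light controls, with no additional
row/column or spatial correction.  Robust (median/MAD) control
statistics exist behind a flag but are off by default since the formula
is defined in terms of mean and SD.

## Hit calling

Mean Z is the arithmetic mean of per-replicate Z scores; miRNAs missing
a replicate (e.g. a failed QC plate) are excluded rather than averaged
over fewer replicates (flag to relax).  The CV filter statistic is
SD/mean of the per-replicate light-normalised dying fractions (x/μ):
positive, scale-free, and stable where CV of Z is ill-behaved near
Z = 0.  CV over |Z| is available behind a flag.  The default selection
policy ranks annotation-surviving candidates by CV ascending and keeps
the top 6; a plain CV-threshold policy is available.  Ties on mean Z
break by lower CV, then lexicographic id — determinism over elegance.
Annotation matching is exact on case-folded names with the species
prefix stripped (`hsa-miR-429` ≡ `miR-429`); no fuzzy matching.
Ranking is computed over all scored miRNAs, with the annotation filter
applied downstream of the cutoff.

The bundled reference table (`synthetic_reference_screen_table`) is a
synthetic stand-in for a published-scale scored library: it encodes only
summary facts (1,268 scored miRNAs; a six-member annotated low-CV
shortlist led by miR-429; protective entries excluded by annotation or
variability; a deleterious tail) and fabricates everything else.
Replicate deviations are standardised before scaling so the planted
means and spreads are exact and the encoded facts hold by construction.

## Secondary assay

The generator seeds 60,000 cells per well, two technical duplicates per
condition, three biological replicates; dead counts are binomial around
the well's dying probability plus additive Gaussian biological jitter
(SD 0.02 on the fraction scale).  The jitter is additive — i.e.
homoskedastic across light and dark cells — deliberately: with
multiplicative noise the light cells' variance dwarfs the dark cells',
the pooled ANOVA error underestimates the light-cell variance, and the
nominal-α F test is genuinely miscalibrated (empirically ~0.06 at
α = 0.05).  Analysing untransformed dead fractions is only exactly
calibrated under homoskedastic noise; for heteroskedastic data the
arcsine-square-root option (`transform='arcsine'`) is the appropriate
mitigation.

The ANOVA is the classical balanced two-factor fixed-effects
decomposition computed explicitly from cell means (type I = II = III in
the balanced case), requiring ≥ 2 observations per cell.  The default
design is treatment × illumination on dead fractions with the
interaction as the protection term: a mimic that changes death *only
under light* is exactly an interaction.  An alternative design —
treatment × replicate on per-duplicate fold changes — is selectable;
note that fold changes divide by the small dark fraction and amplify
its noise, so this design has materially less power at equal settings.
α defaults to 0.05 per miRNA with no multiplicity correction, matching
per-candidate validation practice; a Sidak adjustment over m tests is
available (`sidak_m`).  Which response (fractions vs fold changes)
enters the test is a genuine modelling fork; both are implemented and
the default is documented rather than asserted as the only choice.

## Orchestration and determinism

Every stochastic stage derives its seed as
`(global_seed · 2654435761 + crc32(stage_name)) mod 2³¹`, so runs are
byte-reproducible and stages are independently re-runnable from
persisted artifacts (plate map, well table, QC JSON, Z tables, scored
table, hit list, secondary counts/results, report).  Fast mode is the
default at full library scale; image mode defaults to one rendered
plate per replicate, which keeps a full-plate imaging run around half a
minute at the default image size.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` use: full-scale fast-mode
screens (1,268 miRNAs × 3 replicates × 4 plates) over 20 seeds for null
calibration, with the protective-call rate compared against a 200,000-
draw Monte-Carlo simulation of the same scoring structure (24 light
controls estimating μ and σ, three replicate draws); a single
planted-effect run with 10 protectors and 10 deleterious miRNAs for
recovery; one fully imaged 384-well plate (300×300 px wells) for
segmentation recall/precision, per-well concordance against the planted
binomial envelope, and the transfection estimate; and 1,000 null plus
50 planted-effect simulations for the ANOVA's type-I error and power.

## Known limitations

* The imaging generator omits overlap, debris and illumination
  artifacts; segmentation metrics on it are an upper bound.
* The two-threshold classifier assumes the bright/small contrast; dying
  modes that swell or dim nuclei would need refitted features.
* The CV filter operates on three replicates, where a sample SD is a
  noisy estimator; its ranking is meaningful but coarse.
* The fold-change design divides by small dark-condition fractions;
  wells with near-zero dark death are flagged and excluded rather than
  stabilised.
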