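# Methods

`larvascreen` reimplements, end to end and on fully synthetic data, the
analysis pipeline of a 96-well whole-organism chemical-modifier screen for a
*Drosophila* model of NGLY1 deficiency: mutant (*Pngl*-deficient) homozygote
larvae are small, and the screen looks for compounds that restore their size.
This note records the models, the numerical choices, and what the synthetic
data do and do not establish.

## Assay and plate model

A plate carries 3 larvae per well in the fixed screen format: negative
controls (mutant homozygotes on 0.1% v/v DMSO vehicle) in column 1, 80 test
wells (homozygotes, compound at 10 µM + vehicle) in columns 2–11, positive
control group 1 (heterozygote siblings + vehicle) in A12–F12 and positive
control group 2 (homozygotes without DMSO) in G12–H12. The well readout is
the **total detected larval area in pixels** (the per-component breakdown is
reported, but no attempt is made to split touching larvae into individuals —
the assay statistic is the total).

## Size model (synthetic data)

Per-larva areas are lognormal. Defaults, chosen once:

| parameter | default | meaning |
|---|---|---|
| `het_mean_area` | 280 px | heterozygote mean per-larva area at the default image scale |
| `genotype_ratio` | 0.75 | homozygote/heterozygote mean ratio, untreated |
| `vehicle_genotype_ratio` | 0.50 | the same ratio on 0.1% DMSO (the in-plate condition) |
| `cv` | 0.15 | per-larva coefficient of variation; a 3-larva well total has cv ≈ 0.087 |
| `dmso_onset`, `dmso_mtd`, `dmso_lethal` | 0.025 / 0.1 / 0.4 % v/v | homozygote vehicle dose response |
| `hit_rescue` | 0.5 | default fractional restoration of the size gap by a true hit |

The homozygote DMSO effect is a multiplicative Hill-type decline with
exponent 1.5, zero effect below the onset dose, and its midpoint solved
analytically so that the homozygote/heterozygote ratio equals 0.5 exactly at
the maximum tolerated dose; survival ramps linearly from 1 at the MTD to 0
at the lethal dose. The exact functional form is this package's choice — the
assay it emulates constrains only the onset, the MTD and the two ratio
anchor points. Heterozygotes are treated as insensitive over the screened
range. A rescue `r` moves the homozygote mean a fraction `r` of the way to
the heterozygote mean at the same dose.

`cv = 0.15` was fixed from two constraints that must hold simultaneously:
individual-larva comparisons at n ≈ 20 per genotype must be decisively
significant, and the majority of plates must pass Z′ > 0 quality control
with only 8 negative-control and 6 positive-control wells (the standard
3-sigma Z′ with a half-size negative control is positive only when the
well-level cv is below ~0.11; the 3-larva sum brings cv 0.15 down to 0.087).

## Screen-level processes

Beyond the size model, a simulated screen includes three processes, all
properties of a *compound* and therefore reproducible across replicates
where that is the plausible mechanism:

* **Uneaten-food background.** Wells where larvae do not eat retain food
  that raises the image background and inflates the measured area. Because
  feeding failure follows from the compound, 3% of library compounds are
  "food-prone" and flagged per replicate with probability 0.8; all other
  wells have a 0.5% baseline rate. In rendered images the artifact is a
  broad (σ = 0.45 well radii) grainy darkening at 22% of the background; in
  the area-level fast path it adds ~200 px (about half a control well) of
  apparent area.
* **Low/no DMSO.** A dispensing failure removes the vehicle sensitisation
  and yields larger larvae (area × 1.6). It is a per-dispense accident:
  independent across replicates, rate 1% per well.
* **Toxicity.** 4% of compounds reproducibly stunt larvae (size factor
  drawn once per compound from U(0.35, 0.7)). A bioactive library dosed onto
  vehicle-sensitised mutants is expected to contain such compounds; they
  populate the Z < −2 arm of the extreme-subset replicate correlation.

These three processes, at these rates, reproduce the qualitative replicate
structure of the original screen: most plates pass Z′ QC, the full-set
replicate Z correlation is weak while the |Z| > 2 subset correlates
strongly, and the triage table is dominated by high-background false
positives with a small low-DMSO contingent.

## Image synthesis

Larvae are curved capsules: all pixels within half a body width of a
quadratic Bézier spine, rescaled to a prescribed arc length. In the straight
limit the continuum area is `L·W + πW²/4`, the rasterisation oracle. Larvae
image dark (bromophenol-blue-stained gut) at 35% contrast against a bright
food background (0.75 of full scale) with a gentle illumination gradient,
Gaussian pixel noise (σ = 0.008), and dark well rims. Default geometry: well
radius 65 px, pitch 140 px. Well ground truth is the union pixel count of
the rendered masks; placement is rejection-sampled to keep the three larvae
disjoint, so union and sum coincide in practice. No attempt is made to model
flotation optics, menisci or defoamer — the simulator provides controllable
truth for the detector, not photorealism.

## Detection algorithm

Per located well (rim matched-filtering plus per-well refinement; nominal
pitch known from the plate format):

1. **Exclusion.** Pixels that are probably larvae: local Sobel gradient above
   median + 5 MAD-sigmas, or intensity below median − 4 MAD-sigmas, dilated
   by 3 px. Both rules are relative, making the whole pipeline equivariant
   under global intensity rescaling. The outer 5% of the well radius (rim)
   is masked out entirely; components touching it are kept.
2. **Empty-well estimate.** The excluded gaps are closed by diffusion
   (harmonic) interpolation — solved exactly as a sparse Laplace system with
   Dirichlet data at kept pixels, which reproduces linear backgrounds — and
   the result is smoothed with a masked Gaussian (σ = 2.5).
3. **Segmentation.** Connected components of |observed − estimate| above a
   threshold (default 5 × the MAD-sigma of the difference image), minimum
   area 25 px (~25% of the smallest simulated larva).
4. **Residual metric.** The MAD-sigma of the difference image over the well
   interior excluding strong-difference pixels. Clean wells sit at the
   high-pass noise floor; the soft skirt of a food blob raises the metric
   well clear of it. The default flag cutoff is the 99th percentile of
   clean-well residuals, exceeded strictly.

On synthetic plates the detector recovers per-well areas with a median
relative error below 1% and rank correlation > 0.99, recovers grid centres
exactly, and separates food-blob wells from clean wells with no overlap at
default artifact strength. Those numbers quantify agreement with *this
simulator's* truth; real plate images (meniscus shadows, condensation,
out-of-focus larvae) would degrade them.

## Screen statistics

* **Z′ factor**: the standard `1 − 3(σ_pos + σ_neg)/|μ_pos − μ_neg|` on
  sample moments (ddof = 1); the positive group defaults to control group 1.
  Undefined for equal means (raised as an error).
* **Z-scores**: `(x − μ_NEG)/σ_NEG` against the 8 same-plate negative
  controls. Because σ is a plug-in estimate from n = 8, null Z-scores have
  SD ≈ 1.17, not 1 — the calibration test brackets accordingly. A
  median/MAD variant is available behind a flag but is not the default.
* **Replicate merging** keys rows by library well, never by substance: a
  substance dispensed in two wells stays two rows. Missing replicates stay
  missing (NaN), never imputed.
* **Pairwise R²** is the squared Pearson correlation over matched test
  wells (controls excluded); in extreme mode a pair is kept when *either*
  member has |Z| > 2 (strict). Whether the original analysis required one or
  both members to be extreme is not documented; "either" is the default and
  both modes are implemented.

## Hit calling and triage

A pre-hit has Z > 2 (strict) in at least 2 of 3 replicates. Pre-hits are
partitioned by qualifying replicate pair; a 3-of-3 compound appears in all
three pair rows, so the pair-row total intentionally double-counts it (this
is the screen's own accounting, and is what reconciles a pair-row total with
a smaller unique-compound count). Artifact filtering is subtractive per pair
row — removed as high-background if either qualifying well is flagged, else
as low-DMSO, else clean — so each row satisfies
`clean = prehit − high_bg − low_dmso` exactly. Manual image inspection is
not a computation; the report carries a free-text pass/fail column the
analyst fills (defaults to pass). Substance deduplication is
case-insensitive. Hit rate is `100·n_validated/n_library`, two decimals.

## Validation assays

Cumulative developmental timecourses normalise to surviving animals and must
end at 1; delays are rigid shifts of the event-day distribution.
Fold changes and size ratios use the classical equal-variance two-sample
Student's t-test (per-vial fractions or per-larva areas as replicates); a
Welch variant is behind a flag. Equal groups short-circuit to p = 1 so
zero-variance comparisons are defined. Dose-response curves are 4-parameter
logistic fits (`bottom + (top − bottom)/(1 + (x/IC50)^slope)`) by
least squares, initialised from data quantiles (top from the zero-dose mean,
bottom from the minimum, IC50 from the dose nearest the half-response,
slope 1), with bounds keeping IC50 positive and slope in [0.05, 20]. Fits
are flagged unreliable when the dose-averaged response is flat (range < 10%
of its mean) or rises by more than 15% of its range, and extrapolated when
the IC50 leaves the tested positive-dose range. The genotype sensitisation
experiment fits both genotypes on the standard 0/1/5/10/25 µM ladder
(20 larvae per dose, 5% lognormal noise) and reports the IC50 ratio.

## Determinism and problem sizes

Every simulation is a pure function of its configuration and one master
seed; per-(replicate, plate) substreams are spawned as
`default_rng([seed, replicate, plate])` so any plate can be regenerated in
isolation. Default analysis sizes — a 32-plate triplicate screen for the
statistics, one 96-well plate (48 wells per genotype) for the
image-pipeline ratio experiment, three plates (288 wells) for the
detection-oracle sweep, and 10–20 seeded repetitions for the property
experiments — were chosen so each experiment's sampling error is several
times smaller than the effect it measures.

## Known limitations

* The rendered larvae are binary silhouettes with hard edges; antialiasing,
  motion blur and focus are not modelled, which flatters detection accuracy.
* Overlapping larvae merge into one component; only the total area is
  trustworthy, component counts are not (and are not used as a readout).
* The residual metric is calibrated against clean wells from the same
  simulator; on real images the clean distribution must be re-estimated.
* The area-level fast path draws well totals directly from the size model
  and therefore contains no detection error; conclusions about the
  *statistics* pipeline do not depend on the imaging stage.
* Eclosion denominators: curves normalise to surviving animals; whether
  dead pupae belong in the denominator of a fold change is an assay-design
  choice, so both the survivor count and the dispensed count are carried in
  the event tables.
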