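# Methods

## The volumetric particle model

The pipeline computes molar lipoprotein particle numbers (Lp-P) from
size-fractionated serum by a volume balance: within one AF4 fraction, the
total volume occupied by the measured constituents (core lipids, surface
lipids, apolipoproteins), divided by the volume of one dehydrated
particle at that fraction's hydrodynamic diameter, is the molar particle
concentration.  The model's assumptions, in decreasing order of leverage
on the result:

1. **Every particle in a fraction has the fraction's DLS diameter.**
   Per-particle stoichiometries scale with the cube of the dehydrated
   diameter, so size errors dominate the error budget.
2. **Spherical shape** by default.  Discoidal particles are modelled as
   oblate spheroids with short axis k·d (0 < k ≤ 1); because the volume
   is linear in the short axis, every per-particle stoichiometry scales
   by exactly k relative to the sphere — a useful sensitivity handle.
3. **One bound-water layer** of 0.3 nm (n = 1, w_h = 0.3 nm) separates
   the hydrodynamic from the dehydrated diameter.
4. **Class-average partial molecular volumes**: V_FC = 0.610,
   V_CE = 1.179, V_TG = 1.575, V_PL = 1.307 nm³ per molecule and
   1.212 nm³/kDa for all proteins, regardless of acyl-chain composition
   or protein folding state.  All overridable via configuration.
5. **Free cholesterol partitions** between the polar (surface) and
   non-polar (core) phases with coefficient κ = 5: the core share is
   (CE+TG)/PL / (κ+1).  At (CE+TG)/PL = 1 this puts 5/6 of FC on the
   surface.  When (CE+TG)/PL > κ+1 the surface share would go negative;
   we clamp it to zero (all FC to the core) and flag the fraction rather
   than erroring — this occurs in TG-rich purge fractions and clamping
   preserves mass.
6. **Only the 16 quantified analytes contribute volume.**  Unmeasured
   proteins (albumin and other exchangeable proteins ride HDL-size
   particles) bias Lp-P downward where they are abundant.

### Recovery correction

AF4 loses material (membrane adsorption, losses during
injection/focusing); the per-analyte channel recovery is the summed
fraction amount over the whole-serum amount.  Applying 1/recovery per
analyte per sample makes the conservation identity — recovery-corrected
fraction sums equal whole-serum totals — hold exactly, by construction.
The correction can be disabled (`correct_recovery=False`) for
sensitivity analysis; TG in hypertriglyceridemic samples is the known
over-correction case, because the loss is concentrated in large
particles rather than uniform.  Recoveries outside [0.05, 1.5] are
flagged as suspect.

### Size calibration

One ordinary-least-squares quadratic (diameter vs fraction number) is
fitted per AF4 batch to the per-fraction DLS values, after dropping
flagged points and diameters outside (3, 80) nm — DLS readings outside
the range bracketed by standard size references are treated as
artifacts.  Pipeline diameters are by default the calibration's
predictions at the fraction numbers (`use_fitted_sizes=True`), mirroring
the study pathway that smooths fraction-to-fraction DLS noise and
absorbs batch retention shifts of 1–3 fractions; measured per-fraction
values can be used instead.  A non-monotone fit warns but does not fail.
Fits on fewer than three usable points raise; when that happens inside
the model the batch falls back to measured diameters with a warning.

### Degenerate inputs and numerical guards

* Fractions with missing DLS diameter, or diameter within 1 nm of the
  hydration shell, are excluded from particle math but retained in
  concentration sums (their mass still counts toward recoveries and
  conservation).
* Per-particle stoichiometries are masked (NaN) where Lp-P falls below
  a floor of 1e-12 mol/L, to avoid blow-ups in near-empty fractions.
* Analytes with zero whole-serum totals get no recovery and are excluded
  from corrected quantities, with a flag.

### Geometry

The derived particle geometry uses a sphere-equivalent convention: the
per-particle core volume defines a core diameter d_core = (6v_c/π)^{1/3},
the total per-particle volume defines the outer diameter, and the
surface thickness is half the difference.  The convention (rather than,
say, a shell of uniform thickness over a non-spherical core) is our
choice; only differences and trends across size bins and categories are
interpretable.

### Binning and cohort statistics

Diameters are binned into half-open integer-edge bins: 1 nm wide below
18 nm, 2 nm in [18, 30), 3 nm from 30 nm, with boundary values at 18 and
30 joining the coarser region (a total order is required and the region
definitions leave the boundary open).  Within bins, concentrations and
Lp-P are summed; per-particle quantities are averaged weighted by Lp-P,
which matches their volumetric definition as ratios of summed
concentrations (an unweighted mean is the main alternative; weighting
was chosen for that consistency).  Samples are categorized by whole-serum
Total-C and Total-TG with cutoffs 230/150 mg/dL; values exactly at a
cutoff classify as high.  Group comparisons use the classic
pooled-variance Student's t-test (Welch available by flag), two-tailed,
significant at p < 0.05, with no multiple-testing correction by default
(Benjamini–Hochberg available).  Ratio correlations are Pearson, with
pairwise deletion of missing values.

## Units and conversions

Internally everything is mol/L, nm and nm³; public tables declare units
per row.  mg/dL lipid panels convert with class-average molecular
weights: FC and CE use the cholesterol moiety mass 386.65 g/mol
(cholesterol-equivalent reporting, so Total-C = CE + FC closes in
mg/dL — the clinical convention; ester-mass reporting is supported by
overriding the CE entry), TG uses 885.7 g/mol (the standard clinical
factor 0.01129 mmol/L per mg/dL).  Protein molecular weights default to
mature-chain values from the canonical sequences (apoA-I 28.1, apoA-II
8.7 per monomer, apoA-IV 43.4, apoB-100 512.7, apoC-I 6.6, apoC-II 8.9,
apoC-III 8.8, apoE 34.2 kDa); apoA-II is counted per monomer because the
tryptic-peptide assays quantify monomer-equivalents of the circulating
disulfide dimer.  All of these are configurable.

## The synthetic generator

The generator inverts the model so every pipeline stage can be tested
against known ground truth.

**Species** are defined by a hydrodynamic diameter, protein copy numbers
and lipid-class mole fractions; lipid counts are scaled at construction
so the summed molecular volume closes exactly (within 1%) on the
dehydrated particle volume.  This makes noise-free generator→pipeline
round trips exact: Lp-P equals the species' particle concentration and
each analyte/Lp-P equals its stoichiometry.  apoB-bearing species carry
exactly one apoB-100.

**The default library** spans an albumin-size LPC carrier (6.8 nm),
HDL species at 8–13 nm with 2–4 apoA-I and 1–3 apoA-II, apoE/apoC
species at 14–17 nm, LDL at 20–26 nm, and TG-rich species at 30–36 nm,
each size in cholesteryl-ester-rich / TG-rich compositional variants
bracketing classical compositional analyses of density-isolated classes.
When a sample's serum totals are supplied, the library adapts: the
phospholipid-class split of every species follows the sample's serum PL
pool and the template FC share is rescaled by the sample's FC/CE ratio.

**The forward model** spreads each species' analyte amounts over the
40-fraction schedule by Gaussian band broadening in diameter space
(default σ = 0.75 nm, consistent with ~2 nm base-line peak widths of
monodisperse markers; fraction intervals are half-open with the terminal
intervals extending to ±∞, so out-of-range species pile into the purge
fractions and mass is conserved exactly).  Channel losses attenuate each
analyte uniformly across fractions (defaults: apoA-I 0.52, apoB 0.46,
PC 0.72, FC/CE 0.66, TG 0.33, all others 0.55, matching reported mean
recoveries).  Measurement noise is multiplicative lognormal with unit
mean, by analyte class (non-polar lipids 9%, phospholipids 8%, proteins
18%, apoE 25%, matching inter-day assay CVs); noise is independent per
analyte per fraction.  The per-fraction DLS value is the
particle-number-weighted mean species diameter, which the pipeline's
quadratic re-fit then smooths — deliberately reproducing the real
calibration pathway.  Whole-serum totals are computed loss-free from the
species (with their own noise draw).

**Cohorts** draw whole-serum totals per sample from truncated normal
distributions with the published category-level means/SDs/ranges of the
four lipid phenotypes; Total-C, Total-TG and FC are drawn in mg/dL and
CE is derived as Total-C − FC so the phenotype-defining totals follow
the published distributions exactly.  Species abundances are then fitted
by non-negative least squares on inverse-target-weighted totals, with
priority weights on apoB (the one-per-particle anchor), Total-TG,
apoA-I and an explicit Total-C row.  The emitted serum record is the
species-implied (loss-free) total, keeping the generator and pipeline
mass-consistent; the NNLS residual (typically a few percent on the
prioritized totals, tens of percent on minor analytes such as FC or
apoC-I) is the only deviation from the drawn targets.

**What the generator does not emulate** — and therefore what passing
tests do not show about real data: correlated within-plate measurement
noise, size-dependent channel losses (optional uniform loss only),
unmeasured proteins sharing particle volume, lipase activity during
separation, particle aggregation on storage, and any lipid-species
(acyl-chain) resolution below class level.  Agreement of the pipeline
with the generator's ground truth validates the algebra and the
implementation, not the model's biological assumptions.

## Problem sizes

The test suite and the acceptance script run cohorts of 25 simulated
samples × 40 fractions (seconds on one CPU); that size gives standard
errors comfortably inside the checked windows while keeping the suite
fast enough to run on every change.

## Known limitations

* No uncertainty propagation through the volume equations; dispersion is
  reported only across samples (SD / 95% CI per bin and category).
* Fractions above 30 nm are retained but their particle metrics are
  qualitative at best (purge-phase sizing is unreliable); the >30 nm
  bins should be read as ratios, not particle numbers.
* The core-diameter/surface-thickness formulas are a sphere-equivalent
  convention, not a measured geometry.
* The generator's category realism is limited by the NNLS allocation:
  minor-analyte totals can deviate tens of percent from the drawn
  targets even though the phenotype-defining totals are tightly matched.
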