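# Methods

## Scientific setting

Procyclic *Trypanosoma brucei* fed with oleate (complexed to BSA) build
up cytoplasmic lipid droplets (LDs) that store the fatty acid as
triacylglycerol (TAG). This package implements, as a tested pipeline,
the quantitative analyses that establish (a) how strongly feeding
induces storage, (b) what is stored, and (c) what happens to the store
when the substrate is withdrawn — together with a seed-deterministic
synthetic-data module that emulates every input the pipeline consumes,
because raw measurements of this kind (manual LD counts, cytometer
population means, densitometry areas, summary activity tables) are
routinely not deposited.

## Models and procedures

### Fold-change triangle (droplet_quant)

Three modalities quantify the same induction: mean LDs per cell from
confocal counting, mean whole-cell BODIPY 493/503 fluorescence from
flow cytometry, and the TAG band area from HPTLC densitometry. Each
fold change is the ratio of arithmetic means of replicate-level means
(treated over control), matching the convention of normalizing
replicate values to the control. Concordance is declared when the
largest pairwise ratio of the three point estimates is at most 1.15.

**Confidence intervals.** With the default three replicates per arm, a
plain percentile bootstrap undercovers badly: in our own calibration
runs a nominal 95% interval contained the true fold in only ~85 of 100
seeded simulations. We therefore use a t-calibrated bootstrap: the
bootstrap (1000 joint resamples of both replicate lists, seeded)
estimates the standard error of the log fold change, and the interval
is `point × exp(±t₀.₉₇₅,df · SE)` with `df = (n_treated − 1) +
(n_control − 1)`. The same calibration runs give 94/100 coverage. The
log scale keeps the interval positive and symmetric in ratio space.

### Lipidomics

TAG species labels are parsed as either `C:D` (total acyl carbons :
total double bonds, e.g. `54:3`) or chain-resolved
`c1:d1/c2:d2/c3:d3`; both ASCII `:` and the typographic `∶` are
accepted, output is always ASCII. Intensities are normalized by
dividing every peak by the spiked TAG 17:0/17:0/17:0 internal standard
(exactly one standard row is required; zero-intensity species are
dropped as undetected). Acyl isomers are summed into their C:D class;
class aggregation conserves the species total. Condition comparisons
report per-class fed/unfed ratios, with classes absent from one
condition flagged as missing (NaN), never imputed. "Predominant" is
operationalized as the named classes jointly exceeding 50% of total
normalized intensity.

### Growth kinetics

ln(density) is regressed on time by ordinary least squares — the
maximum-likelihood fit under multiplicative lognormal noise, and
scale-invariant in the density units. μ is the slope (h⁻¹), the
doubling time Td = ln2/μ, and the residual standard error is reported
on the log scale. A non-positive slope is an error ("non-growing
population"), as are fewer than three points. Points after the density
maximum can optionally be excluded (stationary phase); the default
uses all points.

### Turnover model

The central inference. If preformed droplets are partitioned equally
to daughter cells, per-cell stored signal halves each division with no
catabolism at all — the dilution null model

    T(t) = T₀ · 2^(−t/Td),

with Td taken from the growth fit of the same experiment (two-step,
not co-estimated). The kinetic extension adds a basal
synthesis/uptake inflow s and a first-order catabolic rate k:

    dT/dt = s − (μ + k)·T,  s = B·(μ + k)
    ⇒ T(t) = B + (T₀ − B)·e^(−(μ+k)t),

decay at rate μ + k toward the plateau B; with B = 0, k = 0 it nests
the dilution curve exactly. The dilution curve is the assumption-light
prediction; the kinetic form is this package's formalization of
dilution plus basal synthesis plus possible catabolism.

**Fitting.** Signals are normalized so the t = 0 replicate mean is 1.
(B, k) are fitted by bounded weighted least squares (B ≥ 0, k ≥ 0;
weights 1/SEM², falling back to equal weights when any SEM is zero,
e.g. noise-free or single-replicate data), via trust-region
`least_squares` with tolerances 1e-14, initialized at B = last-mean,
k = 0. Estimates within 1e-10 of the non-negativity bound are snapped
to exactly 0 so an inactive catabolic rate is reported as 0, not as a
solver-epsilon. The nested k = 0 fit and both weighted RSS values are
reported (the extra parameter can never increase the weighted RSS).
CIs for B and k are percentile bootstrap (default 1000 seeded
resamples of replicates within timepoints, re-anchored at t = 0);
bootstrap refits reuse the original per-timepoint weights because
resampled SEMs of n = 3 replicates can degenerate to zero.

**Net-catabolism test.** Per timepoint, a one-sided test of
measured-below-predicted using the normal approximation on the
replicate mean, p = Φ((mean − pred)/SEM) (with SEM = 0: p is 0 or 1 by
direct comparison); Holm's procedure controls multiplicity across
timepoints at α = 0.05. "Net catabolism detected" requires at least
one adjusted rejection; measurements sitting *above* the prediction —
the late basal plateau — never trigger it. All timepoints are
evaluated and reported individually, including those after the plateau
is reached.

### Proteome ratios

Proteins quantified by fewer than 2 peptides are removed (boundary
inclusive: 2 peptides is kept). The WT/KO ratio uses a denominator
floor of 1e-3 × the median of all nonzero abundances (both genotypes
pooled) so an ablated protein's residual noise-floor signal gives a
finite, large ratio; floored rows are flagged. Rows zero in both
genotypes are flagged not-quantifiable. Classification against the
2-fold bands is boundary-inclusive (0.5 ≤ r ≤ 2 is "within"). The
unchanged-proteome check passes iff every non-excluded protein is
within; the confidence score is carried through but never used for
filtering.

### Enzyme activities

Only summary statistics (mean ± SEM of n experiments, mU/mg protein)
exist for the subcellular-fractionation enzymology, so contrasts are
ratios of means with independently propagated relative errors
(√(Σ squared relative SEMs)), and "significantly different" is
operationalized as non-overlap of the mean ± 2·SEM intervals — no
named test is possible without raw replicates. Enrichment factor =
glycosome-enriched fraction over whole-cell extract. The stored table
has no glycosomal −glucose rows (none were measured); lookups for
missing keys raise rather than impute.

## Synthetic-data generator

The generator's defaults define the emulated study's conditions; each table has its
own RNG stream derived from the config seed, so generating one table
never perturbs another and fixed seeds give byte-identical CSVs.

- **LD counts**: binomial(n = ld_max = 9, p = mean/9) per cell — a
  bell-shaped, bounded count distribution whose support enforces the
  hard per-cell maximum without truncation. Unfed mean 1.2 LDs/cell is
  a free calibration constant (chosen so
  the fed mean 1.2 × 4.7 = 5.64 stays below 9).
- **Flow cytometry**: intensity = (background + Σ per-droplet
  lognormal emissions, brightness CV 0.25) × lognormal measurement
  noise. The per-droplet mean intensity is solved from (background,
  count means, flow_fold) so the population fed/unfed mean ratio is
  exactly flow_fold = 4.6 in expectation; with positive background
  this requires flow_fold < ld_fold, which the config validates. No
  background subtraction anywhere — the cytometer integrates the
  whole cell.
- **TLC lanes**: five bands at R_F 0 (phospholipids, origin), 0.08
  (DAG), 0.29 (free fatty acids), 0.50 (TAG), 0.90 (esters); the
  unfed TAG area is the normalization anchor (mean 1.0) and the fed
  TAG area is flow_fold-times larger (flow and TLC show the same
  4.6-fold induction), with lognormal replicate noise.
- **Growth / decay**: exponential growth at Td = 12 h (a typical
  procyclic culture doubling time, fixed once), sampled 0–32 h every 4 h with
  3 replicates and CV 5% lognormal noise. Decay follows the kinetic
  model with true k = 0 and B = 0.2 by default.
- **Lipidome**: 96 C:D species (acyl-carbon 44–60 × 0–11 double-bond
  grid) plus the 17:0/17:0/17:0 standard; 54:2/54:3/54:4 carry
  16/30/14% of total intensity, the remainder spread with seed-fixed
  gamma weights shared by both conditions (composition is a property
  of the cells, not of the run); an empty dominance map yields exactly
  uniform shares. Fed total TAG is 4.6× the unfed total relative to
  the fixed standard spike.
- **Proteome**: 80 proteins; reported abundances are means of 3
  CV-5% replicate measurements, true WT/KO ratio 1 for all but the
  ablated protein, whose KO abundance is a residual noise floor at
  WT/140 (finite ratio by construction). 10% of non-ablated rows get
  peptide count 1 to exercise the filter.
- **Activity table**: the summary fixture is stored verbatim (means,
  SEMs, n), not resampled — resampling summaries of unavailable raw
  replicates would add nothing but noise.

**What the generator does not emulate**: cytometer list-mode events
and gating, optical-sectioning artifacts of manual LD counting,
isotope patterns or response factors in the mass spectra,
chromatographic peak shapes, run-to-run normalization of label-free
proteomics, lag or stationary growth phases. Passing tests therefore
demonstrate that the pipeline recovers the quantities it targets from
data with the stated statistical structure — not robustness to those
instrument-level artifacts.

## Problem sizes and runtime choices

Verdict-level checks (net catabolism on k = 0 data) run over 100 seeds
— they need no bootstrap and are cheap. Bootstrap-CI checks
(coverage of k's CI at truth 0, recovery of an injected k = μ) run
over 8 and 5 seeds with 200 resamples; fold-change CI coverage runs
over 100 seeds with 400 resamples. These sizes keep the full suite
under half a minute while leaving the binomial success margins
(≥ 90/100, ≥ 7/8, ≥ 4/5) meaningful.

## Known limitations

- The kinetic model assumes first-order catabolism and a constant
  inflow; mechanistic lipolysis/β-oxidation submodels are out of
  scope, as are per-droplet size dynamics.
- μ is fixed from the growth fit; its uncertainty is not propagated
  into the (B, k) CIs.
- The per-timepoint normal approximation rests on n = 3 replicate
  means; the Holm-adjusted verdict is conservative but the per-test
  p-values are approximate.
- The 2-fold proteome bands are a descriptive classification, not an
  error-controlled differential-abundance test.
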