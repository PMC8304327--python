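# Methods

This note records the models implemented in `hsp90cl`, the defaults and
numerical choices behind them, what the simulators do and do not emulate,
and the design decisions taken where more than one reasonable option
existed.

## Occupancy from ratio triplets

**Model.** A native light sample with per-site occupancy `p_L` is mixed
with a phosphatase-treated heavy reference (residual occupancy `p_H`) at
protein ratio `rho` (heavy/light) before digestion, so both channels share
digestion and ionization. Under two-state mixing the heavy/light ratios
are `x = rho*p_H/p_L` (phosphopeptide), `y = rho*(1-p_H)/(1-p_L)`
(unmodified counterpart) and `z = rho` (whole protein). The inversion
`a = (z-y)/(x-z)`, `occ_light = a/(a+1)` recovers `p_L` exactly;
`b = a*x/y`, `occ_heavy = b/(b+1)` recovers `p_H`. The `b` step follows
from substituting the model into `a`: `a = p_L/(1-p_L)` and
`x/y = p_H(1-p_L)/(p_L(1-p_H))`, so `a*x/y = p_H/(1-p_H)`. `occ_light`
is algebraically identical to `(z-y)/(x-y)`, asserted to 1e-12 in the
tests, and the closed form is cross-checked against an independent
grid-search least-squares inversion of the forward model (coarse 1e-4
grid with the second occupancy profiled out analytically, staged zoom,
parabolic refinement) to 1e-9 on 1,000 random triplets.

**Aggregation and degeneracies.**
- `z` is the *median* of the normalization-peptide H/L ratios per
  replicate — robust to one aberrant peptide; the aggregation statistic
  is a package choice, not dictated by the assay.
- Peptide areas are plain sums of fragment areas per channel (three
  monitored fragments by default); missing channels propagate as flags,
  never imputed. Areas are summed across charge states as well — the
  algebra consumes peptide-level ratios only.
- `|x - z|/z < 1e-6` flags a triplet degenerate (`a` diverges there) and
  invalid.
- Noise can push occupancies outside [0, 1]; estimates are reported
  unclamped with an `out_of_range` flag. Summaries keep flagged values
  with excess <= 0.05 and exclude larger excursions: silent clamping
  would bias group means downward at high occupancy.
- Interference from the neighbouring low-occupancy site on shared
  peptides is ignored (no correction term); it is negligible for the
  panel used.

**Summaries and tests.** Per (site, peptide variant, group): mean and
sample sd (n-1). Between-group comparisons use the two-sided Student
(equal-variance) t-test by default, Welch behind a flag; unpaired, since
no replicate pairing structure is recorded. BH adjustment runs across
the peptide variants tested within one experiment. Variants are reported
separately (not averaged) because the two missed-cleavage forms are
distinct measurements of the same site.

**Co-occupancy and stoichiometry.** With two marginals fixed, the doubly
modified fraction lies in the Fréchet interval
`[max(0, p1+p2-1), min(p1, p2)]`; the independence point `p1*p2` is
reported alongside. Phosphate stoichiometry is the sum of site
occupancies (mol phosphate / mol protein).

## Synthetic data

One RNG stream per simulator, seeded from the caller; the CLI derives
per-table sub-seeds deterministically (seed, seed+1, ...). All truths are
emitted as machine-readable tables.

**PRM/occupancy simulator.** Expected fragment area =
`A_c * w_k * f_k(occ_c) * eps_k * phi_frag` with `A_light = 1`,
`A_heavy = rho`; `w_k` the missed-cleavage species fraction (identical
across channels — channels are mixed before digestion); `eps_k` a
log-normal ionization factor per molecular species shared between
channels (sd 0.5); fixed fragment proportions (0.5/0.3/0.2); observed
areas carry independent multiplicative log-normal noise. Defaults:
occupancy 0.95/0.93 for the two CL sites, heavy residual occupancy
q = 0.01 (dephosphorylation near-complete but not perfect, which
exercises the `occ_heavy != 0` path), `rho = 1`, noise sd 0.1
(0.05 in the recovery checks; the assay itself reports no noise
magnitude, so this is a calibration choice in the plausible 0.05–0.3
log-scale range), 3 replicates. The default panel is the Hsp90β CL
panel: two backbone variants per site plus three normalization peptides.
Not emulated: retention time, m/z, spectral interference, isotope
impurity, digestion chemistry beyond species fractions — so passing
recovery tests demonstrates correctness of the ratio algebra under
multiplicative noise, not robustness to chromatographic artefacts.

**Co-IP simulator.** Label-free: 3 conditions (WT bait, AA bait,
untagged control) x 6 replicates; log2 iBAQ normal around condition
means (baseline 25, sd 0.5); 50 true interactors enriched +4 log2 in
bait conditions with a +0.5 log2 AA excess; interactors missing from
control samples with probability 0.9 (MaxQuant-style 0 cells);
5% of background groups fail one count filter, 5% miss one replicate in
every condition; 8 decoy and 8 contaminant rows injected. SILAC: 4
replicates of one normalized H/L (= WT/AA) ratio per group, noise sd
0.1 per ratio (duplex ratios are far more precise than between-run
label-free intensities, which is why the ratio arm exists), plus a
constant bait offset of 0.7 log2 so bait alignment is exercised. Not
emulated: peptide-level quantification, ratio compression, protein
inference.

**Proteolysis simulator.** Full-length fraction `F(dose)` per genotype
is configured directly; defaults follow the observed dose responses
(WT 1/0.35/0.10 and AA 1/0.22/0.06 at 0/7/14 ng/uL trypsin). Cleaved
molecules split at one dominant site (K607 of the 724-residue protein):
band A keeps `F(d)` of each peptide's base intensity, the N-side
fragment band receives the cleaved share of peptides ending at or
before the site, and the small C-side fragment band receives that of
peptides starting after it. The C-side band is marked *not analyzed* by
default because a ~12 kDa product migrates below the gel range that is
excised and quantified; consequently peptides after the cut show
*higher* band-A/lane ratios than peptides before it. A flag
(`small_fragment_analyzed=True`) includes it for sensitivity analysis.
Peptides spanning the cut are destroyed in cleaved molecules and appear
only in band A. Multiplicative log-normal noise, sd 0.05.

**CWB simulator.** The tagged protein's CM share is
`secreted_fraction + baseline_release`; the actin control's CM share is
`baseline_release` alone; lysate carries the complement. Signals are
scaled by the analyzed fraction of each compartment (defaults CM 0.2,
lysate 0.02) and carry multiplicative noise (sd 0.1). Defaults: WT
secreted fraction 0.016, AA 0.045, baseline 0.03 — the measured levels
for these constructs.

## Interactome analysis

Filters (in order, first failure logged): decoy, contaminant,
only-identified-by-site; < 2 unique peptides, < 4 peptides, < 6 MS/MS
counts in total; presence — label-free: MS/MS-identified in *every*
replicate of at least one condition (control counts as a condition);
SILAC: identified in all replicates. Filters are monotone in the counts.

Missing control intensities are imputed from a per-sample down-shifted
Gaussian, `Normal(mu_s - 1.8*sigma_s, (0.3*sigma_s)^2)` on log2 values —
the de-facto AP-MS convention for left-censored missingness; parameters
configurable; >= 20 observed values are required to estimate moments,
and a control column with no observations falls back to global moments
with a warning. Only (control sample x missing) cells are ever touched.

Label-free calling: two-sample Student t of bait-condition vs control
log2 iBAQ per group, BH across all tested groups per comparison;
*specific* requires adjusted p < 0.05 and |mean log2 difference| >= 3.
The fold-change phrase "3 in log2 scale" is interpreted as a mean log2
difference of 3 (8-fold linear). SILAC calling: each replicate carries
both conditions in one ratio, so an unpaired two-condition test reduces
to a one-sample Student t of bait-normalized log2 H/L vs 0; *regulated*
means adjusted p < 0.05, with 0.4 log2 used only to classify the
direction label. Degenerate zero-variance groups compare with p = 1
when means are equal (p = 0 otherwise) rather than NaN.

Annotation over-representation: one-sided hypergeometric upper tail
P(X >= k) with population = background, BH across terms; the GeneRatio
k/K (hits with the term over background proteins with the term) is
reported for plotting. No ontology structure is used; annotation maps
are caller-supplied.

## Proteolysis readouts

`fraction_full_length` divides each peptide's band-A intensity by its
dose-0 band-A intensity (peptides with zero/missing baseline are
excluded and logged); `band_vs_lane_ratio` divides band A by the summed
intensity of all *analyzed* bands (in [0, 1] by construction). Peptides
are classified before/after/spanning the cleavage site from 1-based
residue spans; spanning peptides are excluded from side statistics
(no principled fractional weights exist). Genotype and side comparisons
use two-sided Welch t-tests on per-peptide ratios with BH across doses,
skipping groups of fewer than 3 peptides. Peptides are pseudo-replicates
of one lane, so these p-values overstate independent evidence; they
mirror how such dose-series data are conventionally compared. Signed
differences are reported without assuming a direction.

## CWB estimators

Absolute ratio: signals scaled to whole samples
(`signal/fraction_analyzed`) before forming
`total_CM/(total_CM + total_lysate)`; invariant to common rescaling;
NaN when both totals vanish. Secreted fraction: HA absolute ratio minus
the mean actin absolute ratio, pooled across constructs by default
(accidental release is a property of the protocol, not the construct;
per-construct baselines behind a flag); negative corrected values are
reported, not clamped, so group means stay unbiased. Construct
comparisons use the Student t-test by default (Welch configurable).
Probe binding: desthiobiotin/HA per replicate; replicates with zero HA
signal are flagged invalid and excluded without affecting others.

## Problem sizes and calibration checks

The repeated-simulation checks in the test suite use 200 simulations per
scenario for interactome calibration (200 background proteins, 50 true
interactors, the default 3x6 design) and 500 seeds for the CWB bias
check; occupancy recovery uses a 40-pair panel at 3 replicates. These
sizes give Monte-Carlo standard errors comfortably below the margins
being asserted while keeping the default test run fast.

## Known limitations

- No raw-spectrum processing: the package consumes tabular exports
  (transition areas, proteinGroups), never mzML/RAW.
- The transition-report dialect is a reconstruction of a typical
  targeted-MS export; column aliases cover common header variants.
- Occupancy assumes exactly two forms per site and shared digestion/
  ionization between channels; multi-site isobaric disambiguation is out
  of scope.
- The proteolysis model has a single dominant cleavage site; secondary
  sites fold into noise.
- Simulator noise magnitudes are calibration choices, not measured
  values; conclusions from passing tests are about estimator
  correctness, not about instrument-level robustness.
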