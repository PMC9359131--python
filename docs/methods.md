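# Methods

## The scoring model

Plan groups are ranked by summed relative deviation from per-item cohort
optima.  For each scored item *j* — a (structure, metric) pair with a
declared direction of merit and weight `P_j` (1 by default) — the
reference `C_j` is the best group-mean value across the compared groups:
the minimum for lower-is-better items, the maximum for higher-is-better
ones.  A group's item score is `S_j = |(M_j − C_j)/C_j · P_j|` and its
overall score `S_D = Σ S_j`, reported with PTV and OAR subtotals.

Key properties (all enforced by tests): every item has at least one group
scoring exactly 0; scores are non-negative, additive, and invariant under
a change of dose units; replacing a group's value by the reference drives
its item score to 0.  The relative form makes items of very different
magnitude (a 0.07 homogeneity index, a 70 Gy near-max dose) commensurable
without explicit normalisation — at the price that `C_j = 0` leaves the
score undefined, which the package treats as an error rather than a
silent skip.

The reference is selected **per item**, not as one global best plan.
With real cohorts different groups hold different per-item optima, so
even the winning group accrues a nonzero subtotal; on the shipped cohort
means the 4 mm group wins overall yet scores 0.079 on the OAR component
because five of the eleven organ optima are held by other groups.  Group
means (not per-patient scores averaged) are scored; rounding to 3
decimals is applied only at reporting, full precision is kept internally.

Direction-of-merit defaults: lower-is-better for every OAR dose metric,
HI and target D2%; higher-is-better for TC and CI.  The scored PTV item
set is configurable (the shipped default scores CI, HI, TC and D2% for
each of the four targets); the PTV subtotal therefore depends on the
chosen item set, unlike the OAR subtotal whose eleven items are fixed by
the cohort tables.

## DVH conventions

The cumulative DVH is binned at 0.05 Gy by default (configurable): at
each edge, the percentage of masked voxels with dose ≥ edge.  `Dx%` is
the largest histogram edge whose cumulative volume still reaches x% —
the empirical inverse of the survival curve.  This is exact when doses
sit on bin edges (a uniform structure has `Dx` equal to its dose for
every x, hence HI exactly 0) and is within one bin width of the
sorted-voxel percentile otherwise; tests quantify the binning error
against brute-force counting and sorting oracles.  `VdGy` interpolates
the curve linearly at d.  Voxel volume is the product of grid spacings;
masks are binary, so partial-volume effects are ignored (a deliberate
desk-scale simplification).  The near-maximum dose reported as "Dmax" in
clinical tables is D2%; the true hottest-voxel dose is exposed separately
as `dmax_true`.

The homogeneity index is implemented in the ICRU-83 difference form
`(D2% − D98%)/D50%`.  Ratio variants of HI circulate in the literature,
but only the difference form is dimensionally consistent with the 0.07–0.29
range the shipped cohort tables report, so it is the only form provided.

`CI ≤ TC/100` always, since `CI = (TC/100)·(TV_PI/V_PI)` and
`TV_PI ≤ V_PI`.  When no voxel reaches the prescription isodose the CI is
defined as 0 with a warning.

## The synthetic cohort

The generator emulates three input kinds, with defaults set to the study
conditions of the shipped cohort (20 patients × 5 beamlet-width groups):

**Phantom.**  A spherical target (70 Gy) in a low-dose bath (5 Gy) on a
48³ grid at 2 mm spacing, convolved with an isotropic Gaussian of width
σ mm.  σ is the penumbra width and the phantom's single link between
fluence-map coarseness and dose spill; the group's beamlet width in mm is
mapped 1:1 to σ.  The default target radius is 30 mm so that the sweep
σ ∈ [0, 10] mm stays non-degenerate (a much smaller sphere is entirely
washed below the prescription by 8–10 mm of 3-D blur).  Coverage in the
sweep is read at the 95% isodose — the standard clinical coverage level —
because the blurred plateau sits strictly below the nominal prescription
for any σ > 0, making coverage at exactly 100% of the prescription a
degenerate measure.  The phantom reproduces the qualitative physics
(finer fluence ⇒ higher TC/CI, lower HI, less OAR spill, monotonically)
but not absolute clinical index values: real head-and-neck plans have
multiple targets, concave boundaries and optimizer-shaped gradients, so
phantom indices are property-test material, not clinical predictions.

**Metric cohort.**  Each (group, structure, metric) cell is drawn
Normal(mean, sd) per patient.  Pairing — the same patient re-planned in
every group — is modelled by a shared per-patient offset with sd
`patient_effect_sd`, carved out of the cell sd (residual sd
`√(sd² − pe²)`), so the configured cell sd is the *total* sd regardless
of pairing strength and the cross-group correlation of a cell is
`pe²/sd²`.  A single absolute `pe` cannot fit cells of very different
scales (a CI sd of 0.05 vs a dose sd of 16 Gy), so the shipped default is
`pe = 0`, which reproduces the configured SDs exactly; set `pe > 0`
(≤ the smallest cell sd) when exercising paired statistics on a
homogeneous metric set.  Values are truncated to physical bounds (doses
≥ 0, percentages in [0, 100], CI in [0, 1]) by resampling, falling back
to clipping only after 100 rounds; for cells within ~2 sd of a bound this
is the upper-truncated normal, whose mean shift the tests check
analytically.  What passing tests show is that the *analysis chain* is
correct under the configured moments — not that real plan metrics are
Normal (bounded indices are mildly skewed in practice).

**Segments.**  Per plan, `n` segment MUs are drawn from a two-component
uniform mixture — a low component entirely below the 5 MU small-segment
threshold and a high component above it — then rescaled to the plan's
total MU.  Plan totals are drawn Normal around the group's configured
mean ± sd.  Group segment counts (57–62) were chosen once so that the
mixture mean × count matches the group total MU (rescale factor ≈ 1,
which keeps the small-segment share at the configured mixture weight) and
are realistic for 9-beam dynamic IMRT; with ~60 segments the binomial
fluctuation of the small-segment share (~6 percentage points) matches the
spread the cohort tables report without any extra noise parameter.
"Small" is strictly `< 5` MU (configurable threshold).

## Statistics

`compare_groups` gates on Shapiro–Wilk at α = 0.05 per sample (on the
differences when paired): normal ⇒ t-test (paired or two-sample),
otherwise Wilcoxon signed-rank / Mann–Whitney U, always two-sided.
Identical paired samples short-circuit to statistic 0, p = 1 (every
rank statistic is degenerate there).  The default Bonferroni family is
the set of comparisons against the reference group per metric (m = 4 for
a five-group cohort).  Under the null the gated test's raw p-values are
approximately uniform; the suite checks a 5% rejection rate within
[0.03, 0.07] over 2000 replicates.  Pairing across groups is joined on
the patient prefix of the canonical `P{nn}-{group}` plan id.  Fisher-LSD
correction is not implemented.

## Constraint checking

Constraints are inclusive upper bounds per (structure, metric); a plan
passes only if every constraint row passes and none is unevaluated.  The
shipped defaults are planning objectives, and two of them are knowingly
inconsistent with the cohort's own reported doses: the parotid bound
"V30 ≤ 5%" (almost certainly intended as ≤ 50%, since the cohort reports
V30 ≈ 48–54%) and the temporal-lobe 65 Gy bound (reported near-max doses
≈ 72 Gy).  They are shipped verbatim as defaults, so the default
constraint report fails every group; users comparing their own plans
should supply their institution's constraint table.

## Numerical and degenerate-input choices

Empty masks, non-positive spacings, structures outside the grid, missing
metric cells, zero references, negative item scores and sub-3-point
samples all raise typed errors rather than propagating NaNs.  Ties in
reference selection list every tied group, all of which score 0; a tie
for the lowest overall score is reported as a tie rather than an
arbitrary winner.  All sampling goes through a single seeded
`numpy.random.Generator` per operation, making every generator
deterministic given its spec; pipeline outputs are byte-identical across
re-runs with the same seed.

## Problem sizes

The test suite runs the oracle sweeps on ≤ 32³ random grids (100 of
them), the null-calibration check on 2000 replicates of n = 20 samples,
moment recovery at n = 1000 patients and mixture recovery at 10⁴
segments; the phantom sweep uses the default 48³ grid at six blur widths.
The full suite completes in well under a minute.

## Known limitations

No DICOM-RT import/export (dose grids and masks are in-memory inputs;
a reader is a natural extension point), no dose calculation or fluence
optimization, no MLC sequencing or deliverability checks, no
partial-volume mask weighting, no per-patient score distributions beyond
group means, and no modelling of measured delivery time (a
hardware-dependent quantity).
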