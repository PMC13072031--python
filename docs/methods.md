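# Methods

## Data model

A sample is a composite specimen with total C, N and P in mg per g dry
mass, strictly positive and below 1000. Needle samples carry a branch
position (apical/basal); soil samples carry one of five fixed depth layers
(0–20 … 80–100 cm). The layer vocabulary is a closed enum: arbitrary
depths are out of scope. Within a dataset the (tree, position) and
(tree, layer) keys are unique — the design analyses exactly one composite
per slot — and every tree with a basal needle sample must also have an
apical one, because resorption is a paired within-branch quantity. Missing
values are rejected, never imputed: the design has no missingness, so a
blank cell is a data error. All concentrations stay mass-based throughout;
no molar conversion is performed anywhere, so ratios are directly
comparable with the mass-based soil survey values used as generator
defaults. CSV I/O uses a single dialect (UTF-8, '.' decimal, ','
separator) and shortest-roundtrip float formatting, making
read(write(D)) = D bit-exact — a property the suite tests over random
datasets. External deposits with different headers are read through an
explicit column-mapping file rather than header guessing.

## Indices

Let x̄ and SD be the mean and *sample* standard deviation (n−1
denominator) of a variable within a group. The n−1 convention is used
everywhere (HI, CV, NSI z-scores, PCA scaling): with 3 trees per group the
denominator choice is material, and the sample form is the standard
unbiased-variance convention for small field designs.

- **HI = x̄/SD = 1/CV.** Requires n ≥ 2 and nonzero mean. A zero-SD group
  returns HI = ∞ with a `degenerate` flag rather than an error: in the
  zero-noise limit of the generator every group is exactly homeostatic.
- **NSI = Z(C:N) + Z(C:P)**, where the z-scores are computed across the
  *entire* needle collection of the run — never per condition — so scores
  are comparable between groups and sum to zero over the run (asserted to
  1e-9). A zero-spread reference ratio is an error naming the ratio.
- **NRE = (C_apical − C_basal)/C_apical × 100 %** is computed per tree
  from that tree's own pair, then summarized per condition. Computing per
  tree rather than from group means preserves between-tree variance for
  the condition-level Welch t-test; with constant inputs the two
  conventions coincide exactly. NRE is always < 100 for positive
  concentrations and may be negative (carbon typically accumulates
  basally). The quantity is a concentration-difference proxy for premature
  stress-induced mobilization, not terminal-senescence resorption; for
  healthy trees the basal needles at comparable positions stand in for the
  senescing tissue.
- **RPI = NRE_N/NRE_P** per tree; the condition RPI is the mean of
  per-tree RPIs. Labels use a band of half-width `coupled_tol` (default
  0.1, configurable) around 1: within it "coupled", within twice it
  "coupled/N-leaning"/"coupled/P-leaning", beyond "N-priority"/
  "P-priority". The intermediate band exists because RPI values a little
  outside the strict band (e.g. 0.89) are conventionally still read as
  near-coupled resorption. RPI is undefined (flagged, not raised) when
  NRE_P = 0.
- **SDI = |needle − soil|/soil** with the soil ratio always the
  denominator (deliberately asymmetric: the soil is the reference). SDI is
  paired within trees: tree i's needle ratio against tree i's soil ratio
  at each layer, the only pairing consistent with one composite soil
  profile per tree. Group-level SDI is reported under two conventions side
  by side — the mean of per-tree SDIs ("group mean", the primary one) and
  the SDI of group-mean needle ratio vs layer-mean soil ratio ("pooled") —
  since published figures do not disambiguate which was used.

## Statistical chain

Group comparisons follow the gated design: Levene's test with **mean**
centring (the original Levene, not the Brown–Forsythe median variant) at
α = 0.05 decides the route; homogeneous variances go to classical one-way
ANOVA with Tukey's HSD, heterogeneous ones to Welch's ANOVA with
Games–Howell pairwise comparisons. Games–Howell is an extension: no post
hoc is conventionally attached to Welch's ANOVA, but letters must be
producible on both routes. All tests are two-sided; α defaults to 0.05
and is configurable. RPI and NRE condition contrasts use Welch's t.

Calibration: over 2000 all-null normal simulations (4 groups, n = 10) the
gated omnibus rejects at ≈ 0.05. Mean-centred Levene itself is mildly
liberal at these sample sizes (empirical type-I ≈ 0.065 at k = 4, n = 10;
the behaviour that motivated the median-centred variant). This is a
property of the chosen test, not of the implementation, and the validation
suite bands it accordingly.

The compact letter display uses the insert-and-absorb algorithm: start
with one column holding all groups; for each significant pair split every
column containing both; absorb subset columns; finally sweep out columns
whose members and non-significant pairs are covered elsewhere. The output
satisfies the contract (two groups share a letter iff non-significant) by
construction, and on designs of ≤ 6 groups the letter count matches an
exhaustive minimum-cover oracle in the test suite.

The needle–soil Pearson grid (4 groups × 5 layers × 3 ratios) reports raw
two-sided p-values as the primary output, matching how such grids are
published; a Benjamini–Hochberg column is emitted alongside as a clearly
labelled extension. Cells with fewer than 3 complete tree pairs are
flagged "insufficient"; n = 3 cells are computed but stamped "low-power";
zero-variance cells are "undefined". PCA standardizes each ratio column to
zero mean and unit sample variance, so the decomposition reflects the
correlation structure; loading signs are fixed by orienting each
component's largest-magnitude entry positive (signs are otherwise
arbitrary and would break run-to-run reproducibility).

HI is reported descriptively per group. An inferential comparison of HI
between groups would need resampling (one HI value exists per group), so
no test is attached to it by default.

## Synthetic generator

The generator emulates the study design: `n_trees_per_condition`
(default 3), one needle composite per position per tree, five soil layers
per tree. Default needle group means are the published field means of the
reference design; default soil means are the regional survey averages for
aeolian sandy soil (C 2.30, N 0.23, P 0.13 mg/g), applied depth-constant
with a per-layer offset hook (published layer contrasts exist only for the
deepest layer, without printed values). Concentrations are drawn from a
normal truncated to the sample model's support (0, 1000) mg/g, with SD =
CV × mean so variance scales with the mean; default CVs are 0.10 (needle)
and 0.15 (soil), chosen as typical within-group variability for composite
field samples — the study's true within-group SDs live in its data
deposit, not its text, so these are explicit placeholders. C is sampled
independently of N and P; no covariance model is attempted because no
covariance information is published. Each tree owns a child random stream
keyed by (condition, tree index) under the root seed, so enlarging the
design never reshuffles existing trees.

Mechanistic mode rebuilds the chlorotic groups from the healthy pools:
apical' = A + f·B and basal' = (1−f)·B for N and P (C is not
reallocated), giving the closed-form expectation
NRE = 100·(1 − (1−f)B/(A + fB)). The default fractions f_N = 0.388 and
f_P = 0.506 are the values whose closed form at the default healthy pools
equals the NRE implied by the published apical/basal contrasts (70.85 %
and 79.75 %), so descriptive and mechanistic defaults describe the same
biology. `ground_truth` returns all noise-free expected indices for any
config and mode.

What passing recovery tests show — and don't: the generator shares the
pipeline's data model and is truncated-normal with independent elements,
so recovery demonstrates correctness of the estimators under the design's
sampling structure, not robustness to real-data features such as
element covariance, non-normal measurement error, spatial structure among
trees, or lab batch effects.

## Validation studies and problem sizes

`needlestoich.validation` packages two studies, also used by the
acceptance script: type-I calibration (2000 null datasets, 4 groups of 10;
the gated omnibus rate and Levene's own rate) and parameter recovery (500
replicate mechanistic studies at 50 trees per condition; mean NRE_N/NRE_P
recovered within 1 percentage point, RPI within 0.03, and the
chlorotic-vs-healthy contrast detected by Welch's t at p < 0.05 in ≥ 95 %
of replicates). These sizes give Monte-Carlo standard errors comfortably
below the asserted bands (binomial SE ≈ 0.005 at 2000 sims) while keeping
the full suite fast.

## Numerical choices

- Levene degenerates (all absolute deviations equal, e.g. constant
  groups) return W = 0, p = 1 with a note; the equality check is relative
  (1e-10 of the data scale) because group means of identical values are
  not exactly representable in binary floating point.
- Classical ANOVA with zero within-group variance everywhere raises
  (F undefined); the pipeline logs and skips that variable — this is the
  zero-noise generator limit.
- Welch's t with two zero-variance equal-mean groups is flagged undefined
  rather than raised.
- Ratio objects enforce n_p × c_n = c_p to 1e-9 relative; reports
  serialize non-finite floats as null with a boolean flag.
- Reports embed no timestamps; re-running the same inputs and config
  yields byte-identical JSON (hash-comparable), with provenance carried
  as a content hash.

## Known limitations

- Variance-derived indices (HI, CV, SDI) at n = 3 are preliminary
  indicators; the correlation grid at n = 3 is stamped low-power.
- The Welch-route identity with classical ANOVA under equal variances
  holds exactly only for two groups; for k > 2 Welch's denominator
  correction is nonzero even at equal sample variances.
- Only C, N, P are modelled; other chlorosis-relevant elements (Mg, Fe)
  are outside the data model.
- The benchmark comparison against an external deposit can only be
  exercised end-to-end on a synthetic stand-in until the deposit is
  downloaded and mapped by the user.
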