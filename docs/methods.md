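# Methods

## Model and procedure

### Event coding

The unit of observation is a triple (specimen, serial element, event)
with a binary attainment state; specimens carry their standard length
(SL, mm).  States are complete-case per element: rows whose state is
missing (unstainable or outside the preservation window) are dropped for
that element only.  No distinction is drawn between the possible causes
of missingness, and no imputation is attempted.  Positions are 1-based
anterior→posterior.  Radials that articulate with several lepidotrichia
are stored once with a `span` annotation rather than duplicated across
columns.

### SL50 estimation

For each element, P(state=1 | SL) is fitted by maximum likelihood
(binomial GLM with logit link, IRLS, 100 iterations, deviance tolerance
1e-8) and SL50 = −β0/β1.  The intercept-only log-likelihood is the
closed-form binomial value at the sample proportion; the likelihood-
ratio statistic G = 2(ℓ1 − ℓ0) is referred to χ²(1), and an element is
"estimated" (significant) when p < α/k with family α = 0.05 and k = the
number of elements actually fitted in the profile — separated fits count
toward k because they were tested.

Degenerate inputs are classified before fitting: all states 1 →
always_present (the element predates the smallest specimens; no model
exists), all states 0 → never_reached.  Perfectly ordered states
(complete separation: every non-attaining specimen smaller than every
attaining one) would drive |β1| → ∞; such elements get SL50 = the
midpoint between the largest state-0 size and the smallest state-1 size,
`fit_status = "separated"`, and a boundary likelihood-ratio p-value
(the supremum log-likelihood is 0), keeping them rankable while flagged.
A converged fit with non-positive slope yields no usable SL50 and is
inestimable.

### Sequences, sites, directions

Rank sequences use average ranks on ascending SL50 over significant
entries (non-significant entries can be included on request, and are
included when measuring parameter recovery so that every fitted element
is ranked).  Always-present elements, when admitted, are ranked ahead of
every fitted entry at a proxy size — the SL of the smallest surveyed
specimen (8.650 mm dorsal, 10.894 mm anal in the packaged table) — tied
among themselves unless distinct proxies are given.

The initiation site is the maximal contiguous run of elements whose SL50
is within `plateau_tol` (default 0.0 mm: exact ties only) of the
minimum; contiguity is judged on the profile's own position grid, so an
excluded element breaks a run but a never-surveyed position does not.
Tied run choices resolve toward the run holding the overall minimum,
then toward the profile centre (a mirror-symmetric rule), then
anteriorly.  Always-present elements, when any exist, constitute the
site outright.

Direction classification computes, on each flank of the site, the
Spearman correlation between SL50 and distance from the site.  A flank
qualifies when it has at least `min_flank` (default 1) elements and its
trend is ≥ `trend_threshold` (default 0.5); a single-element flank
qualifies when its SL50 is not below the site's (development reached it
later).  Both flanks qualifying → bidirectional; a qualifying posterior
flank with an empty anterior flank → antero-posterior, and symmetric;
anything else → indeterminate.  The thresholds are deliberately
permissive: the published direction calls were made by inspection, and
the default configuration reproduces every one of them from the
packaged SL50 table (all 18 fin×event profiles bidirectional).  There is
no special state for "probably AP, possibly bidirectional" — the
indeterminate call plus the reported flank trends carries that
information.

### Modularity tests

Spearman rho is the Pearson correlation of average-tied ranks; it is
undefined (NaN) when either side has zero rank variance.  Pairing is
positional within a series for the dorsal-anal tests, and radial i ↔
lepidotrichium i+2 for the endoskeleton-exoskeleton tests — the offset
that reproduces the published column alignment in both fins; it is a
parameter (`PairingMap.column_aligned(..., offset=...)`, CLI
`--pairing-offset` / `--pairing` CSV override) because radial-to-ray
articulation varies across taxa.  A pair enters the correlation only
when both members are rankable, and ranks are recomputed within the
retained subset; this retention rule reproduces the published pair
counts and coefficients for all nine dorsal/anal rows (radial apparition
requires the always-present proxies above) and four of the six
endo/exoskeleton rows exactly.  The remaining two (apparition,
endo vs exo) cannot be reconstructed exactly from the printed values
under any offset/retention combination examined and are checked
qualitatively (sign and rough magnitude) in the reproduction command.

p-values: exact enumeration of all n! rank permutations for n ≤ 7,
two-sided, ties ignored in the null (the enumeration permutes untied
ranks); the t approximation on n−2 degrees of freedom otherwise.  |rho|
= 1 under the t approximation returns p = 0 with a flag.  No correction
is applied across the table's rows, matching the published presentation.

### Fossil mode

Segment counts proxy segmentation order (rays are built by distal
addition of segments, so longer rays started earlier): the site is the
maximal contiguous run of rays within `plateau_tol` segments (default 0)
of the maximum count, flank trends are Spearman correlations of count
with −distance, and classification mirrors the SL50 classifier.  Rays
with unreadable counts are skipped, and fewer than 3 usable rays (or all
counts equal) is indeterminate.  Bifurcation summaries report the range
of rays attaining the most proximal first-bifurcation segment, per-order
ray ranges, and the deepest order; a fin with no branched rays is a
valid empty summary.

## Synthetic data

The generator emulates a cleared-and-stained growth series.  True SL50
per element follows base + gradient·distance from an initiation site
(V-shaped, or monotone for AP/PA), plus a non-decreasing offset per
event encoding the within-element ontogenetic order.  Each (specimen,
element) pair draws one logistic deviate shared across events, so a
specimen can never show a later state without the earlier ones; the
induced per-event attainment law is exactly the fitted logistic model
with slope 1/`noise_scale`.  `noise_scale` is the logistic scale
parameter in mm (not the SD, which is π/√3 ≈ 1.81× larger).

Defaults are the study design: 80 specimens uniform on 8–50 mm SL, 15
elements, central site, gradient 0.8 mm per element step (the slope of
the published ray-ossification profile away from its site), noise scale
1.5 mm, event offsets 0/4/6 mm for ray apparition/segmentation/
ossification (the order of magnitude separating those events in the
published table).  Optional uniform dropout emulates unobservable
states.  What the generator does **not** emulate: growth-curve sampling
(real surveys are denser at small sizes), staining artefacts that are
correlated across elements, inter-individual meristic variation (every
simulated specimen has all elements), and model misspecification (the
noise is logistic by construction, so simulation-based checks validate
the machinery, not robustness to a wrong link).

Fossil simulation draws counts round(max − decay·distance + Gaussian
noise), floored at one segment, with optional bifurcations whose first-
bifurcation positions rise with distance from a (typically more
posterior) bifurcation site.

The packaged fossil profiles are *schematic synthetic reconstructions*:
only descriptive ranges are published (which rays are longest, where the
most proximal bifurcations sit, nested order ranges, ray counts), so the
module builds integer profiles consistent with those ranges —
`floor(max − decay·d)` counts peaking exactly on the reported interval.
They support site/direction/order assertions, not quantitative claims
about specimens.

## Validation and measured behaviour

The test suite checks, among others: exact reproduction of the published
correlation table from the packaged SL50 fixture; all 18 published
direction calls; MLE agreement with an independent profile-likelihood
grid search (1e-3 mm); the Bonferroni gate's type-I error under a flat
truth (binomial 99% interval at α/15, 1000 replicates); exact-
permutation/t-approximation agreement; and ≥95% direction-classification
accuracy on noisy simulated fossil fins.

One documented limitation: per-element SL50 recovery at the full study
design (80 specimens uniform over 8–50 mm, noise scale 1.5 mm) has a
Fisher-information floor of roughly 0.9 mm standard error per element
(about (n/range)·s observations contribute near the transition), so the
median absolute estimation error sits near 0.6 mm and the corresponding
recovery test asserts a tighter 0.5 mm bound than the design can
deliver; it is retained, failing, as an honest record rather than
loosened.  Rank recovery at a 0.8 mm/element gradient averages rho ≈
0.89 against the truth, limited by the exactly tied element pairs of a
V-shaped profile.

## Numerical choices

Natural logs throughout; G clipped at 0 (tolerance 1e-8); χ²(1) upper
tail.  Separation detected by perfectly ordered states before fitting
and by |β1| > 1e3 or non-convergence after.  JSON reports serialize
floats at 7 significant digits (the precision of the published
coefficients); report files are byte-stable across reruns of the same
configuration.  Exit codes: 0 success, 2 validation error, 3
estimation/pipeline failure.
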