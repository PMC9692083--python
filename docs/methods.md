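# Methods

## Scope and data model

`extractrank` ranks crude natural-product extracts by a composite
structural-novelty score computed from post-processed untargeted LC-MS/MS
results.  It deliberately starts *after* raw-data processing: peak
picking, alignment, molecular networking, in-silico annotation and
class-prediction tools run upstream and only their tabular/MGF outputs
are consumed.  Live taxonomy/occurrence database queries are likewise out
of scope; literature knowledge enters as an offline TSV of per-taxon
reported-compound counts and chemical-class sets with already-resolved
names.

The quantitative backbone is the aligned feature table: one row per
chromatographic feature (m/z, retention time), one non-negative peak-area
column per extract.  Extracts labelled `blank` or `QC` in the metadata
are carried through parsing but excluded from every scoring denominator;
blanks additionally define the background vocabulary removed from MS2
fingerprints.

### Ion-identity collapsing

When the upstream software groups adducts/in-source fragments of one
neutral molecule into ion-identity networks (IIN), each group is collapsed
to a single row before scoring.  The group's per-extract area is the
element-wise **maximum** over its members — the most representative ion
form per extract — and the surviving feature id is the member with the
greatest summed area (ties: lowest id).  The maximum, not the sum, is
used because adduct intensities of one molecule are strongly correlated
and summing would double-count.

## Feature Component (FC) and Feature Specificity (FS)

The table restricted to scored extracts is normalized **row-wise**: each
feature's areas become proportions of that feature's total (all-zero rows
stay zero, 0/0 := 0).  A feature is *specific* to an extract when its
proportion there is at least `min_specificity` (default 0.90).

With several extracts per species (organs, solvents), specificity mass
spreads and single-extract thresholding undercounts.  The *maximum
occurrence* parameter N (default 1) lets up to N same-species extracts
share specificity: per species, a feature's top-min(N, #extracts) extracts
by proportion are jointly specific when their summed proportion reaches
the threshold and each carries a nonzero share.  At most one species can
qualify per feature since two disjoint sums cannot both reach 0.9.  The
rule is deterministic and order-free; raising N can only add specific
flags, so FS is non-decreasing in N.

Per extract *e*, with detected(e) = features of nonzero area in *e*
(after any active filters):

    FS(e) = |specific(e) ∩ detected(e)| / |detected(e)|
    FC(e) = |specific(e) ∩ detected(e) ∩ unannotated| / |detected(e)|

Empty extracts score 0 rather than erroring, so they rank last.

### Annotation status

A feature is *annotated* when any evidence route fires (OR-combination):

* a spectral-library (GNPS-style) hit surviving the quality filter —
  |ppm error| ≤ 5, shared peaks ≥ 10, cosine ≥ 0.6, matching ion mode,
  charge ≤ 2 (boundaries inclusive, since the parameters are named as
  max/min; the ppm filter takes the absolute value because the error sign
  is instrument-dependent);
* an in-silico spectral match with final score ≥ 0.3;
* a formula/structure prediction with formula (ZODIAC) score ≥ 0.9 AND
  structure confidence ≥ 0.25.

The ledger records which sources fired per feature; status is per-feature.

### Intensity filters

Two optional pre-filters explore how discarding low-abundance features
changes the ranking.  Both operate per extract column on the sample-wise
normalized scale and only ever set values to zero:

* **fraction-of-maximum floor** (default 2%): areas below
  `min_fraction` x the column maximum are zeroed.  Max-scaling is used as
  the sample-wise normalization because a sum-scaled 2% cut would remove
  nearly everything in feature-rich extracts.  The column maximum always
  survives, so this filter is idempotent.
* **quantile cut** (default q = 0.75): areas below the linear-interpolation
  q-quantile of the column's **nonzero** values are zeroed (boundary
  kept).  Nonzero values only: zeros dominate sparse aligned tables and a
  zeros-included quantile would collapse to 0 and cut nothing, whereas the
  intended behaviour retains roughly the top (1−q) of an extract's
  observed features.  Consequently re-application tightens the cut on the
  survivors — the quantile filter is a one-shot operation, not an
  idempotent one.

Applied sequentially (floor, then quantile), the retained set is contained
in each filter's own retained set.  FS/FC denominators are recomputed
after filtering.

## Literature Component (LC)

    LC = 1 − [w_sp·f(rcs/max_sp) + w_g·f(rcg/max_g) + w_f·f(rcf/max_f)]

with reported-compound counts rcs/rcg/rcf at species/genus/family rank,
equal default weights 1/3, default maxima 20/100/500, and f = identity by
default (`cap_fractions=False`; with capping, f = min(·, 1) and LC is
bounded in [1 − Σw, 1]).  LC = 1 means no reports at any rank; uncapped
LC goes negative for heavily studied taxa, which is intentional — such
taxa should rank last on this axis.  All three knobs (weights, maxima,
cap) are exposed because the published formulations of this score differ
in exactly these choices; the defaults are a reasonable middle ground,
not a calibration.  Family counts affect all extracts of one family
equally and mostly shift, not reorder, a single-family set.

## Class Component (CC)

Per-feature chemical-class predictions (NPClassifier *class* level only;
pathway/superclass are ignored) are filtered to *confident* ones
(probability ≥ 0.8) among the extract's detected features, then to
*recurrent* classes: the confident feature count must strictly exceed the
recurrence threshold.  A threshold ≥ 1 is an absolute count n ("more than
n features"); a value in (0, 1) — including the default 0.8 — is a
fraction of the extract's confidently classified features.  Recurrence is
evaluated per extract.

Class strings are canonicalized (trim, collapse internal whitespace,
casefold) on both sides, then compared by set subtraction: any recurrent
class missing from the species' literature class set adds CCs = 0.5, any
missing from the genus' set adds CCg = 0.5; CC = CCs + CCg ∈ {0, 0.5, 1}.

## Similarity Component (SC)

Each extract's MS2 spectra are vectorized into counts of *words*,
independent of retention-time alignment:

1. fragment intensities are scaled to the spectrum's base peak; fragments
   with relative intensity in [0.01, 1] are kept; spectra with fewer than
   10 surviving fragments contribute nothing;
2. each kept fragment yields a `peak@x.xx` word, and each
   precursor-minus-fragment difference within [10, 200] Da a `loss@x.xx`
   word.  The loss window's upper bound is configurable; 200 Da covers
   common neutral losses without flooding the vocabulary.
3. m/z values are rounded **half-away-from-zero** to `n_decimal` (default
   2) places, formatted fixed-point.  Rounding operates on the decimal
   literal of the value rather than its binary expansion so that word
   labels are bit-stable across platforms.

Words with nonzero count in any blank are background (solvent, column
bleed) and dropped for all extracts before comparison.  The word-count
rows are compared by Bray–Curtis dissimilarity (standard for count-based
fingerprints; configurable), giving a symmetric zero-diagonal matrix.

Three unsupervised detectors then vote, and SC = 1 iff at least one
flags the extract:

* **Local Outlier Factor** on the precomputed distance matrix,
  neighborhood min(5, n−1), flagging LOF > 1.5;
* **One-Class SVM** (rbf, nu = 0.1) on the matrix rows as coordinate
  vectors;
* **Isolation Forest** (100 trees, contamination "auto", fixed seed) on
  the same rows.

Numerical choice: the SVM votes outlier only when its decision function
is below the boundary by more than the solver tolerance.  On small
extract sets most points end up numerically *on* the margin
(|decision| ≈ 1e-4, the solver tolerance), and the raw sign of the
decision function would label these boundary support vectors as outliers
essentially at random; requiring a margin of one solver tolerance removes
that noise while leaving genuinely separated points flagged.  All
hyperparameters and the seed are recorded in the verdict for provenance.

## Priority Score and reporting

PS is the weighted sum of FC, LC, CC, SC on **unrounded** values
(weights default to 1); the results table rounds to 2 decimals for
display, which is why a displayed PS can differ from the sum of displayed
components by ±0.01.  Ranking is by descending PS, ties broken by
descending FC then ascending filename — deterministic and
permutation-invariant.  The per-extract ion map classifies each detected
feature as `specific_unannotated` (isolation candidates),
`specific_annotated`, or `nonspecific`, with areas from the pre-filter
IIN-collapsed table so intensities reflect the original quantification.

## Synthetic data generator

`generate_bundle` emulates a processed extract library at desk scale.
`n_features` is the number of features *detected per extract*: each
extract gets an exclusive block (area only there → specific by
construction, drawn U(1e6, 1e7)) and all extracts share a common pool
with balanced areas (U(5e5, 1e6), so no share can reach 0.9).  Planted
structure → exact expected scores: `fraction_annotated` of the exclusive
features receive passing library hits (plus one failing hit per extract
to exercise the quality filter), fixing FC = fraction_specific ×
(1 − fraction_annotated); each extract's exclusive features share one
confident class — novel or literature-reported per
`novel_class_extracts` — while shared features only get low-confidence
predictions, fixing CC; the planted outlier's spectra draw fragments from
a disjoint m/z vocabulary (500–900 Da vs 100–440 Da), fixing SC; the
occurrence table carries uniform counts (defaults 2/8/100, echoing a
poorly studied species), fixing LC.  Spectra carry ≥ 10 fragments with
relative intensities ≥ 0.05 so none fall below the MEMO floor; when a
blank is included, three background-vocabulary fragments are spiked into
every sample spectrum and five blank spectra are emitted, exercising
blank-word removal.  One integer seed drives a single RNG, so equal seeds
give identical bundles.

What the generator does **not** emulate: chromatographic peak shapes,
isotopes and adduct chemistry (IIN ids are absent by default), m/z-
correlated fragmentation, annotation errors, partially overlapping
spectral vocabularies, or taxon-dependent literature structure.  Passing
recovery tests therefore demonstrates that the scoring arithmetic and
bookkeeping are correct under clean planted structure — not that the
scores are robust to real instrument noise or annotation ambiguity.

## Problem sizes and determinism

Tests and the reproduction script use 4–10 extracts with 30–340 features
and ~15-fragment spectra — sizes chosen so each bundle generates in well
under a second while every code path (blanks, shared species, filters,
all three detectors) is exercised.  All randomness flows through
explicitly passed seeds: the fixture RNG, and the Isolation Forest seed.
LOF and the SVM are deterministic given the matrix.

## Known limitations

* The literature component's exact published parameterization is
  ambiguous in the sources that use this style of score; values computed
  here are comparable within a run but not across tools.  Exact LC values
  from real libraries are not a validation surface.
* The shared-specificity rule is a deterministic reconstruction (top-N by
  proportion within species, summed mass ≥ threshold); other tools may
  enumerate subsets differently when proportions tie at the N-th place.
* The outlier ensemble's behaviour at n < ~6 extracts is fragile for all
  three detectors; SC is only meaningful for moderately sized sets.
* No mzML parsing, no peak picking, no molecular networking, no live
  database queries — by design.
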