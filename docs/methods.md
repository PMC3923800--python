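# Methods

## Spectral encoding

A compound enters the pipeline as a stick spectrum: peaks of (chemical shift
δ in ppm, proton count).  Each stick is replaced by a triangle centered at δ
with half-width *h* (default 0.1 ppm) and **area** equal to the proton
count, so the apex height is protons / *h*.  Normalizing the *area* rather
than the apex is deliberate: binning then conserves the integral, and the
hydrogen-conservation identity below holds exactly.  The half-width is a
tolerance for shift-prediction error; empirical ¹H predictors have mean
absolute errors around 0.2–0.3 ppm, and the 0.1 ppm default (matching the
bin width) keeps most of a peak's mass within one or two bins while still
letting slightly displaced reactant/product signals overlap and cancel.
`half_width` is exposed as a parameter rather than fixed.

Binning integrates the piecewise-linear fuzzified spectrum analytically over
half-open intervals [k·w, (k+1)·w) on 0–12 ppm with w = 0.1 ppm (120
variables).  The cumulative integral of a triangle is piecewise quadratic
and is evaluated at the bin edges in closed form — no sampling grid is
involved; the fine-grid quadrature in the test suite exists only as an
independent oracle.  A peak sitting exactly on a bin edge needs no
assignment rule: integration splits its mass.  Mass outside 0–12 ppm is
dropped, recorded on the result (`clipped_mass`) and warned about; shifts
outside that window do not occur in the synthetic data and are rare in ¹H
practice.

## Reaction and mixture descriptors

A reaction's descriptor is the *reaction spectrum*: binned product spectrum
minus binned pooled-reactant spectrum, scaled by the conversion *y*:

    after  = (1 − y)·reactants + y·product
    before = reactants          ⇒ difference = y·(product − reactants)

Unreacted material cancels, so conversion acts as an exact scalar on the
full-conversion vector.  Multiple reactants are pooled by concatenating
their shift lists at their stated proton counts (1:1 stoichiometry); no
per-compound normalization is applied — the robustness battery explicitly
varies a global normalization factor, which only makes sense if absolute
integrals are kept.  When total reactant protons equal product protons and
all fuzzified mass lies in range, the descriptor sums to zero at every
yield (asserted to 1e-9 in the tests).

Two-reaction mixtures use MIXTURE = NORM·(RATIO·A + B), with RATIO applied
to the first-listed reaction of the pair (the one whose type comes first in
the registry order).  Six reaction types give C(6,2) = 15 unordered mixture
classes, labeled A–O lexicographically over the type order.

## Partitions

*Mixture-level*: the mixture set itself is split at random (default 2/3
train).  The same reaction appears on both sides in different pairings, so
this measures interpolation among known reactions.  *Reaction-level*: the
reactions are split per type first and mixtures are enumerated within each
side, so no reaction is shared — a genuine generalization test.  The
default held-out counts per type are (4, 8, 4, 17, 2, 6) of
(20, 31, 20, 73, 10, 27); the published per-type partition table is used as
printed even though the accompanying per-class mixture counts imply a
slightly different split for the last type (the two tables are mutually
inconsistent by one reaction; the per-type table governs here, and the
benchmark only reports class A and B training counts, on which both agree).

## Self-organizing map

The map is a rows×cols toroidal grid (default 49×49; every neuron has 8
neighbors; Chebyshev distance with wraparound).  Weights initialize per
variable from Normal(mean, sd) of the training data (a zero-variance
variable initializes constant).  Per cycle t of T:

    lr(t) = lr0·(1 − t/T),  span(t) = round(span0·(1 − t/T))

and every neuron within toroidal distance d ≤ span of the winner updates
with the triangular kernel lr·(1 − d/(span+1))·(x − w).  The kernel form is
chosen so the farthest included neuron still receives a non-zero update.
Defaults: lr0 = 0.1; T = 75 (midpoint of the conventional 50–100 range);
span0 = half the smaller grid dimension (unstated in the original protocol;
configurable).  The span is additionally clipped to (min(rows, cols) − 1)/2
so wrapped neighborhoods never contain duplicate neurons.  Presentation
order is reshuffled every cycle from the run's seed; training is bitwise
reproducible under a fixed seed.  Maps should have at most half as many
neurons as training objects; this is enforced as a warning, not an error.

After training, each neuron is labeled by the training objects mapped onto
it: one class, *conflict* (several classes; the plurality class is kept for
classification, an exact tie stays unresolved), or *empty*.  A new object
takes its winner's label; an empty winner falls back to the nearest decided
neuron on the torus (ties broken by row-major index), and only unresolvable
ties yield *undecided* — chosen so test objects are not silently discarded.
Ensembles of independently seeded maps vote by plurality with undecided
votes excluded; vote ties are undecided.

## Counter-propagation network

The input layer is trained *identically* to the unsupervised map (winners
never see the output layer, so with equal seeds the input layers are
bitwise equal — asserted in the tests).  The output layer has one six-vector
per neuron, initialized at the uninformative midpoint 0.5, updated toward
the object's binary type-indicator target with the same learning rate and
kernel as the input layer (the neighborhood update is the standard
counter-propagation scheme).  Because targets are binary and updates are
convex, output weights remain in [0, 1].  Prediction reads the winner's
output vector; a class is assigned only when exactly two components are
strictly above the threshold (default 0.5) — values equal to the threshold
do not count — otherwise the object is undecided.  Note the rule is not
monotone in the threshold in general: an output with three components above
a low threshold can become decided at a higher one.

## Random forest

The 15-way classification is delegated to a bagged ensemble of unpruned
trees (scikit-learn) with 1000 trees and ⌊√p⌋ = 10 of the 120 variables
per split; out-of-bag accuracy is the internal error estimate.  The target
is the 15-way mixture class directly, not two independent 6-way type calls.
Prediction probabilities are **hard vote fractions** computed from the
individual trees (fraction of trees voting for the winning class), not
averaged leaf probabilities, because the reliability-filtering protocol is
defined on vote shares; exact vote ties are broken by class-label order and
flagged.  Validation utilities: y-randomization (retrain on label-scrambled
data, seeded, fresh permutation per repeat, default 5 repeats) and
stratified 10-fold cross-validation (stratification by class; plain k-fold
would starve the 8-member classes).

## Synthetic data generator

The generator emulates a curated set of 181 photochemical cycloadditions in
six types, which cannot be redistributed.  Each type has a fixed signature:
protons moving from a chemically motivated lost region to a gained region
(e.g. olefinic 5.3–6.3 ppm → cyclobutane 2.3–3.3 ppm for the [2+2]
olefin–olefin type; aldehydic 9.4–10.0 ppm → oxetane O–CH 4.6–5.6 ppm for
the olefin–carbonyl type).  Signature *positions* are drawn per reaction
uniformly within the regions, giving intra-type variability; regions
deliberately overlap between types (most types lose olefinic protons), so
classes are separable but not trivially.  Each reaction also carries 3–10
spectator peaks (1–3 protons each, uniform over 0.5–9.5 ppm) present in
both reactant and product spectra, displaced by Normal(0, drift_sd) with
drift_sd = 0.15 ppm — mirroring the error scale of empirical shift
predictors, so spectators nearly cancel and leave structured residual
noise.  Hydrogen counts are conserved by construction.

What this emulates: type-characteristic difference-spectrum patterns,
near-cancelling background, prediction-error noise, class imbalance, and
the two partition regimes.  What it does not: real within-type shift
*correlations* (real reaction families cluster much more tightly than
uniform sampling over ~1 ppm regions), coupling multiplets, solvent and
overlap artifacts, or classes that are hard for the specific chemical
reason of having no hydrogens near the reaction center.  Consequently the
absolute accuracies on synthetic data — in particular the unsupervised
map's — are not comparable to published values on real data; the package's
benchmark asserts *relative* orderings (forest > map ensemble;
reaction-level < mixture-level; scrambled ≪ true; reliability filtering
monotone; degradation under perturbation), which are properties of the
method rather than of one dataset.  One such ordering is only marginal
under these conditions: with a base accuracy near 95%, amplifying the
first-listed reaction at RATIO = 2 disambiguates confusions between classes
sharing a type about as often as it breaks correct calls, so the accuracy
at RATIO 1 vs 2 is a near-tie (clear degradation resumes by RATIO 5).

## Benchmark problem sizes

The pipeline driver (`rxnmix.pipeline.run_benchmark`, also behind
`scripts/acceptance.py`) runs on the full 181-reaction / 12421-mixture
dataset with: 300-tree forests on the full training splits; a 5-member
25×25 map ensemble (30 cycles) trained on a 2500-mixture subsample and
scored on 1500 test mixtures; y-randomization with 5 repeats at 100 trees.
These sizes keep a complete run at a few minutes on one CPU while leaving
every reported comparison qualitatively unchanged from larger settings
(49×49 maps and 1000-tree forests change individual accuracies by a few
points but no ordering).  All stage seeds derive from the single master
seed via a seed sequence.

## Numerical and degenerate-input conventions

* Bin grids must match exactly (lo, hi, width) for any vector arithmetic;
  mismatches raise.
* Winner search ties break to the smallest row-major neuron index.
* An all-identical training set gives zero per-variable sd, hence all
  neurons initialize identically; the tie rule keeps behavior
  deterministic.
* `enumerate_mixtures` of a single-type dataset returns an empty list (no
  cross-type pairs); classifiers refuse single-class training sets.
* Accuracies are reported both counting undecided predictions as errors
  (`as_error`, the default everywhere) and over assigned objects only
  (`exclude`); confusion tables carry an explicit undecided column so row
  sums always equal truth counts.
* Percentages in report tables are rounded to one decimal only at the
  formatting layer; all comparisons use full precision.
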