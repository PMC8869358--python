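# Methods

This note documents the models and procedures the package implements,
the choices made where the design was genuinely open, and what the
synthetic data does and does not establish about real screening data.

## Plate normalization and curve analysis

Raw fluorescence from a qHTS thallium-flux plate is normalized per plate
to percent activity, `(V − V_DMSO) / (V_DMSO − V_pos) × 100`, using the
*medians* of the DMSO-only and positive-control wells as anchors. The
transform is affine-invariant: rescaling or offsetting a whole plate
leaves normalized values unchanged, and the control anchors map to 0 and
−100 exactly. Controls are required; a plate whose control medians
coincide is rejected rather than silently producing infinities.

Each compound's replicate-averaged series (triplicates are averaged per
concentration before fitting; per-replicate curves are retained on the
`CRCurve`) is fit to the four-parameter Hill model

    y(c) = bottom + (top − bottom) / (1 + (c / IC50)^h)

with `top` the zero-dose asymptote and `bottom` the high-concentration
plateau, by bounded least squares from five starting points spread over
the tested log-concentration range (lowest SSE wins; ties cannot occur
in practice because SSE is compared directly). Convergence tolerances
are 1e-12; on noise-free curves the planted parameters are recovered to
machine precision, which the test suite asserts at the 0.1% level.

Whether a concentration response exists at all is decided by an F-test
of the Hill fit against the constant model (3 vs n−4 degrees of freedom,
α = 0.05). The qHTS curve categorization is then:

* class 1 — significant fit, both asymptotes observed inside the tested
  range (fitted response within 10% of the respective asymptote at the
  range ends);
* class 2 — significant fit, incomplete asymptote coverage;
* class 3 — no significant fit but the top-concentration response
  exceeds the efficacy cutoff (single-point activity);
* class 4 — no significant response; potency fields are reported as NaN.

The signed curve rank in [−9, 9] is |rank| = base(class) + bonus, with
base 7/5/2/0 for classes 1–4 and bonus +2 for efficacy ≥ 80%, +1 for
≥ 50%, capped at 9; the sign follows the response direction (negative =
inhibition). This mapping is a documented surrogate: the upstream
screening literature defines class/rank operationally and only the
range, sign convention and outcome bins are printed; the mapping here is
chosen so that complete, efficacious inhibition curves land in the
antagonist bin (−5…−9) and weak or partial curves do not, and every
threshold is a keyword argument.

Activity outcomes follow the rank bins exactly: 0 inactive, −5…−9 active
antagonist, 5…9 agonist, −4…4 inconclusive. A *reliable* active further
requires efficacy > 30% and a passed curve inspection. Manual curve
review is not implementable in a library, so inspection is automated: a
curve passes if its residual SD is ≤ 15 percentage points (three times
the default plate noise) and it has at most one monotonicity violation
larger than 10 points against the fitted direction. The sequential
filter cascade (antagonist outcome → rank bin → efficacy → inspection →
standardization pass) reports raw counts only; percentages are left to
the caller because denominators are survey-specific.

## Synthetic study conditions

The generator reproduces the screening design: 15-point geometric
concentration series spanning 4 decades down from 100 µM, triplicate
wells, DMSO wells at a raw level of 10000 and positive-control wells at
5000 (arbitrary but fixed so normalization is exercised nontrivially),
Gaussian well noise with SD equal to 5% of the control window by
default. Planted inhibitors draw log-uniform IC50s from 0.1–10 µM, Hill
slopes from 0.8–2.0 and plateaus from −40 to −100% (so most, but not
all, actives clear the 30% efficacy filter); inactives are flat at the
DMSO level. Every generator stream is an independent seeded RNG, and
identical config + seed reproduces identical tables byte for byte.

Molecules combine a hardcoded ~60-structure vocabulary (hERG-liable
drugs, quaternary-ammonium surfactants, pesticides, and low-liability
small organics) with template-sampled structures (alkyl chains,
substituted aromatics, amines, esters). Labels follow a planted
structure-activity rule — tertiary/quaternary nitrogen AND MolLogP ≥ 3 —
mirroring the feature classes that dominate real hERG actives. The
rule's strength is an odds multiplier: the base activity probability is
solved (Brent's method) so the expected active fraction matches the
configured target given the rule's prevalence; a multiplier of 1 removes
all structure-label association. QSAR demonstrations use a multiplier of
100 ("strong rule"), under which the Bayes-optimal classifier's MCC is
roughly 0.7, so the fixed 0.5 pass threshold leaves honest headroom.
Chemotype matrices plant the same odds mechanism into a subset of
chemotype columns (default multiplier 5). Bioactivity records plant
concordant duplicates, >1 log10 patch-clamp conflicts and censored
records at configurable rates.

What the synthetic data does *not* emulate: fluorescence kinetics,
positional plate artifacts (the upstream pattern-correction step is out
of scope), correlated assay interference (e.g. UV absorbers), realistic
descriptor covariance of a 10K-compound library, or class imbalance as
extreme as a real campaign (7–8% actives). Passing tests therefore
demonstrate correctness of the machinery and statistical calibration
under controlled conditions, not field performance on real libraries.

## Curation and descriptor selection

Standardization order: parse + sanitize, strip explicit hydrogens,
reject metal-containing species (any atom outside the organic subset),
sieve salt/solvent fragments (a canonical-SMILES list of common
counterions plus all carbon-free fragments), keep the largest remaining
organic fragment, re-perceive stereochemistry. Two surviving organic
fragments mean a mixture, which is rejected; a chemical that *is* itself
a listed counterion (acetic acid) is kept. Unparseable input yields a
flagged record, never an exception.

Descriptors are RDKit 1D/2D blocks (Crippen logP and MR, topological and
kappa indices, MOE-type VSA, BCUT2D burden eigenvalues, aromatic bond
and atom counts) plus two nitrogen-charge descriptors computed from
Gasteiger charges: QNss (sum of squared N charges) and QNmin (most
negative N charge), both 0 for nitrogen-free molecules. Externally
predicted columns (OPERA-style) merge by id; they are inputs, not
re-implementations. Selection removes null-variance columns and columns
whose modal value covers strictly more than 90% of chemicals, then
clusters the survivors as connected components of the |ρ| > 0.9 graph —
the simplest structure consistent with "one representative per cluster"
— and keeps one per component, chosen by a seeded RNG over
lexicographically sorted names so the retained set is invariant to row
and column order. |ρ| rather than ρ is used because anti-correlated
duplicates are equally redundant.

## Clustering

The SOM is a classic online Kohonen map: 15×15 rectangular grid (225
units) by default, codebook initialized uniformly over the data bounding
box, learning rate decaying linearly 0.5 → 0.01 and Gaussian
neighborhood radius decaying from half the grid diagonal to 1 over 10
epochs of seeded-order presentations. Descriptors are z-scored before
training (and before hierarchical clustering) because Euclidean distance
across heterogeneous units is meaningless unscaled. Assignment is the
argmin over units of Euclidean distance to the codebook, asserted
against brute force in tests. Empty units are permitted; n < 225
chemicals is legal. Hierarchical clustering of actives uses scipy's Ward
linkage on Euclidean distances, with pIC50 and chemical-class leaf
annotations carried for rendering.

## Enrichment statistics

The two-proportion Z-test uses the pooled standard error and Yates
continuity correction, one-tailed for over-representation in actives;
the correction is capped at the observed |p1 − p2| so it can annihilate
but never reverse a difference. Degenerate pooled proportions (0 or 1)
return z = 0, p = 1: no evidence. The implementation agrees with R's
`prop.test` to 1e-10 and is calibrated under the null to within
Monte-Carlo error of α. No multiple-testing adjustment is applied by
default — fidelity to the original analysis — with Benjamini–Hochberg
available behind a flag.

## QSAR protocol

The stratified split assigns round(0.85·n) of each class to training
(549 actives → 467, exactly). Under-sampling builds five inactive
subsets: the training inactives are partitioned into five folds
(guaranteeing their union covers the full training set), each topped up
by seeded sampling from its complement to three times the training
active count — the 75/25 ratio is taken as the primary design rule, and
the per-subset size is configurable. When the active fraction is already
high, under-sampling can be disabled and a single model is trained.

Descriptors are z-scored with training-set statistics only (the test
suite asserts the scaler never sees test rows). Each sub-model runs a
grid search maximizing 10-fold cross-validated MCC; CV confusion metrics
come from cross-validated predictions with the selected
hyperparameters, and fitting (resubstitution) and test metrics complete
the report, each as mean ± SD over sub-models. MCC is defined as 0 when
any denominator factor vanishes. Default grids are deliberately small
(RF trees {100, 500} × features {√p, p/3}; SVM C {0.1, 1, 10}, γ
{scale, 0.01}; CART ccp_alpha {0.001, 0.01}; NN hidden {8, 32}; DNN
64–32 with early stopping; LDA parameter-free) and fully configurable.
The DNN is a feed-forward network — at this input dimensionality a
two-hidden-layer perceptron is the appropriate scale. The decision
threshold on ensemble probability is 0.5, ties calling active; the
consensus model averages the RF and DNN ensemble probabilities.

## Applicability domain

PCA is fit on the z-scored training descriptors; the domain lives in the
smallest leading subspace covering ≥ 80% of variance. Each chemical's
Euclidean distance to the training centroid (the origin, stored
explicitly for external projections) is standardized by the training
distance mean and SD, and zoned at 2 and 4 with the border closed on
both sides. By construction the training-set mean Z is exactly 0 — a
property the tests assert to 1e-10; a reference analysis reporting a
positive mean training Z is therefore describing a variant (plausibly
|Z|), and this package implements the printed formula as stated. Note
that per-column z-scoring is basis-dependent, so the rotation
equivariance of the PCA distance machinery holds for pre-scaled inputs
(`standardize=False`); that is how the invariance is tested.

## Bioactivity integration and potency shift

Integration is per chemical: censored records are dropped; patch-clamp
records, when present, exclude all others; surviving records spanning
more than one log10 drop the chemical; the rest are averaged as
arithmetic mean pAffinity (geometric mean potency — the log-normal
convention for potencies); the active label requires pAffinity ≥ 6.
Chemicals already labeled by the screening assay keep that label. Mixed
endpoints are pooled after the patch-clamp priority step; an
endpoint-priority variant is configurable. The procedure is idempotent.

The potency-shift model is plain OLS of patch-clamp pIC50 on
thallium-flux pIC50 with R², adjusted R² and the slope p-value; its
predict step maps flux potencies to the electrophysiology scale and back
to molar units.

## Problem sizes and numerical choices

Test and demonstration sizes are chosen for a single-CPU desk run:
parameter-recovery suites use ~200 simulated actives, enrichment
calibration 200 null replicates and 100 planted simulations (10 planted
chemotypes of 200, n = 1000), and the QSAR learnability demonstration
2000 molecules with the five-sub-model RF ensemble under the full
10-fold protocol. Tolerances: 0.1% for noiseless recovery (fit
tolerances are orders tighter), 15% median IC50 error at 5% plate noise,
±2 Monte-Carlo SE for test calibration, MCC 0.5 / ±0.1 for the planted
and permuted QSAR checks. Degenerate inputs (flat curves, constant
descriptors, single-class labels, < 3 AD chemicals, < 3 regression
pairs) raise typed errors or return documented conventions rather than
propagating NaNs.

## Known limitations

The curve class/rank mapping is a surrogate with printed-value anchors,
not a re-derivation of the original scheme. The SOM is an online (not
batch) implementation; unit numbering is arbitrary and not comparable
across runs with different seeds. Descriptor coverage is the RDKit 2D
set plus charge descriptors, narrower than a full commercial descriptor
suite. The synthetic bioactivity records sample potencies around the
1 µM cutoff independently of structure, so integration is exercised as a
rules engine, not as a structure-consistent dataset. No probability
calibration is applied to classifier outputs.
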