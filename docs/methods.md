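# Methods

## Model

`rtsbn` models one time-loss football injury per record as a draw from a
discrete Bayesian network over twelve categorical variables arranged in
five temporal tiers:

| tier | variables |
|---|---|
| personal | age, height, weight, bmi, main_position |
| match | time_season, training_match |
| injury | type_injury, body_region, contact_noncontact |
| outcome (days) | days_rts |
| outcome (severity) | severity |

An arc may never point from a later tier to an earlier one; arcs within a
tier are allowed while the graph stays acyclic.  Two families are
*definitional* rather than statistical and are therefore fixed by expert
knowledge, never learned:

* `severity` is the deterministic Fuller coarsening of `days_rts`
  (1–3 → minimal, 4–7 → mild, 8–14 and 15–28 → moderate, 29–60 and
  >60 → severe); its CPT is a point mass per row and is excluded from
  structure search and from per-fold re-learning during cross-validation.
* `bmi` is the deterministic band implied by the height and weight bands
  (heavier-for-height → higher band).  A deterministic child is not
  score-identifiable — the inverted factorization fits the data equally
  well and BDeu can prefer it — so `height→bmi` and `weight→bmi` are forced
  and the `bmi` family frozen, exactly like the severity link.

### Discretization

Printed interval labels follow a closed-interval convention: `"<a"` is
(−∞, a), `"a-b"` is [a, b] closed on both ends, `">b"` is (b, +∞).  A value
on a printed boundary (age exactly 24, BMI exactly 22.8) therefore falls in
the middle bin.  This is our convention: GUI-based network tools
commonly used for such models do not document their boundary handling, so
one defensible rule is stated and tested.  The first `days_rts` bin is a left ray because a time-loss
injury is by definition at least one day of absence, making every rule a
total function on the reals (property-tested).

## Learning

**Parameters.**  Complete data: each CPT cell is
(count + pseudocount) / (row total + pseudocount·r), with unseen rows
uniform.  Missing data: EM with seeded Dirichlet(1) row initialization.
The E-step groups records by missingness pattern and enumerates the
completions of each pattern vectorized, which keeps a 12-variable,
n = 20,000, 20%-MCAR fit under ~20 s.  The trace of observed-data
log-likelihood (evaluated at the parameters entering each iteration) is
non-decreasing up to the smoothing prior; iteration stops on relative
change < `em_tol` (default 1e-4) or `em_max_iter` (default 50).  EM uses a
single run rather than restarts: reproducibility was valued over escaping
the (mild) multimodality of these smoothed categorical likelihoods.

**Structure.**  Greedy hill-climbing over add/delete/reverse moves from the
forced-arc skeleton, best of `restarts` (default 3) seeded starts (the
first from the skeleton, the rest adding random constraint-respecting
arcs).  Score: BDeu with a uniform structure prior, `ess = 1` by default;
family scores are cached, and decomposability means each move rescores at
most two families.  Moves that violate tiers, forbidden arcs, acyclicity,
`max_parents` (default 4 — keeps CPT rows populated at epidemiological
sample sizes), or that touch a frozen child are rejected.  Ties between
equal-scoring moves break on a fixed enumeration order, making the search
deterministic given the seed.  Structure search requires complete records
(listwise deletion), mirroring the usual practice of searching on complete
cases while EM handles missingness at the parameter stage.

## Inference and prediction

Posteriors are computed exactly by variable elimination with a min-fill
elimination order (ties by node name).  A brute-force oracle
(`posterior_enumerate`) broadcasts all evidence-restricted CPT factors into
the full joint tensor and sums it; the test-suite checks elimination
against it to 1e-10 on a thousand random networks.  Evidence whose
probability is exactly zero raises `InconsistentEvidenceError`: with at
most twelve small factors the products cannot underflow, so an exact zero
is always a modelling contradiction (e.g. a days state conflicting with an
observed severity), never numerical noise.

Classification uses the argmax of the posterior, with ties broken to the
earliest state in the declared order.  Validation tools in
this field usually report classification accuracy without stating the
decision rule; argmax is the minimal assumption and is recorded here as
ours.

**Evidence policy.**  When predicting `days_rts`, the observed `severity`
is withheld from the evidence (and vice versa): the two are linked by
definition, and conditioning on one while predicting the other is label
leakage, not prognosis.  The leaky variant is available as an explicit
option (`include_sibling_evidence=True`) for sensitivity checks.

## Validation metrics

k-fold cross-validation (default k = 10) keeps the structure fixed,
re-learns parameters on the training folds, predicts every held-out record
once, and pools a single confusion matrix.  Per class:
sensitivity = TP/(TP+FN), user's accuracy = TP/(TP+FP); a class that never
occurs (or is never predicted) reports 0 with a warning so tables stay
total.  The overall row is the micro-average — pooled diagonal over total —
which is numerically identical for both metrics by construction.  Folds are
a seeded uniform random partition into parts whose sizes differ by at most
one; optional stratification was considered and rejected as default since
equal-size unstratified parts are the plainest reading of standard k-fold
practice.

## The synthetic world

Real league injury tables are scraped from public media and cannot be
redistributed, so the package states its own ground truth and tests every
claim against it.  The canonical network contains the dependencies the
epidemiological literature reports — injury type, body region, age and
event type drive days to RTS; contact drives injury type and body region;
time of season drives event type and injury type — plus two additional
plausible arcs (`main_position→body_region`, `age→training_match`) chosen
so that **every arc is compelled**: each participates in a v-structure, the
DAG is the unique member of its Markov-equivalence class, and exact
structure recovery is a well-posed target instead of a tie-break.

CPTs are hand-authored with strong but non-deterministic effects:

* `days_rts` rows come from a severity-score model: each parent state
  contributes an additive effect (injury type 0–2.8, body region 0–3.0,
  age 0–1.8, match 1.0 vs training 0), and the row is a Gaussian bump
  (σ = 0.5) over the six duration classes, tilted by a decreasing skew so
  the marginal mass falls with duration — most injuries are short, as in
  real exposure data.
* the body-region profile is authored **per (position, contact) pair**, and
  the seasonal injury-type multipliers **per (season, contact) pair**,
  rather than as separable multipliers: the interaction term (defenders'
  aerial-duel head injuries, goalkeepers' dive-related hand injuries,
  preseason non-contact muscle spikes, winter contact fractures) is exactly
  the signal that orients the colliders at `body_region` and `type_injury`;
  log-additive effects carry no such signal and leave the arc direction
  undetermined.

What a green test does and does not establish: the generator draws i.i.d.
records from a faithful, MCAR-corrupted version of the model family the
pipeline assumes.  Passing tests show the machinery is correct and decisive
under those assumptions; they say nothing about repeated injuries within a
player, season effects, non-random missingness, or how well the canonical
CPTs match any real league.

## Numerical choices

* CPT rows are stored in linear space with a 1e-9 normalization tolerance;
  joint evaluation uses log space.
* CPT row order: parents in declared node order, last parent varying
  fastest; serialization (YAML) is bit-stable under this order.
* Strength of influence: average over all unordered pairs of parent states
  and all configurations of the child's other parents of a distance between
  conditional rows; Euclidean distance is normalized by √2 so a
  deterministic disjoint swap scores exactly 1.  Hellinger and total
  variation are available; configuration weighting is uniform by default or
  by the joint marginal of the other parents.  GUI tools that draw arc
  thickness from an "average effect" rarely document the distance they use;
  a configurable, stated distance is the honest substitute.
* Parameter sensitivity: central finite differences (step 1e-5) under
  proportional co-variation of the remaining row entries; entries pinned at
  0 or 1 use a one-sided step, and point-mass rows spread the removed mass
  uniformly.  Nodes whose CPTs provably cannot affect the query — the
  auxiliary-parent d-separation test — are flagged exactly zero without
  differentiation, so "no influence" classifications never depend on
  finite-difference noise.

## Known limitations

* Desk-scale parameter recovery is bounded by sampling noise: the
  `days_rts` family has 714 parent configurations, and even its
  best-populated rows receive only a few hundred of the n = 20,000 samples,
  so the maximum absolute ML error over those rows concentrates around
  0.06–0.08 (≈ 3·√(p(1−p)/N) over ~100 cells), and EM under 20% MCAR
  slightly higher.  The acceptance tests assert tighter bounds (0.05 ML /
  0.08 EM) and document this floor; the corresponding failures are
  expected and quantified, not defects of the estimator.
* Hybrid (conditional-Gaussian) nodes, approximate inference, dynamic
  time-slice extensions and bootstrap model averaging are out of scope.
* The case-study posteriors printed by the worked example are properties of
  the synthetic canonical world, not of any real league.
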