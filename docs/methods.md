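# Methods

`icnet` reconstructs an integrated cellular network — a signed, directed
TF→gene transcription sub-network coupled to an undirected protein–protein
interaction (PPI) sub-network — from an expression time course and candidate
edge pools, by fitting discrete-time dynamic models per target node and
pruning candidate edges statistically.

## The coupled dynamic model

Gene layer. The mRNA level `x_i` of target gene `i` obeys

    x_i[t+1] = Σ_j a_ij z_j[t] + (1 − λ_i) x_i[t] + k_i + ε_i[t]

with `a_ij` the signed regulatory ability of TF `j` (positive = activation,
negative = repression), `λ_i` the degradation effect, `k_i ≥ 0` the basal
transcription level, and `ε_i` additive noise. The regulation function

    z_j[t] = 1 / (1 + exp(−(y_j[t] − μ_j)/σ_j))

is a logistic (Hill-type, saturable) transform of TF `j`'s activity `y_j`;
`μ_j` and `σ_j` are the sample mean and standard deviation (denominator
L−1) of the TF's activity profile on the fitting grid. Estimating them as
profile moments rather than jointly with the regression keeps the
identification linear; the cost is that the sigmoid's midpoint and slope are
fixed by the data distribution, not optimized per edge. TF cooperativity
(products of z's) is deliberately excluded.

Protein layer. The activity `y_n` of protein `n` obeys

    y_n[t+1] = Σ_m b_nm y_n[t] y_m[t] + α_n x_n[t] + (1 − β_n) y_n[t] + h_n + ω_n[t]

with bilinear mass-action interaction terms (collision kinetics, as in
kinase–substrate phosphorylation), `α_n ≥ 0` the translation effect from the
protein's own transcript, `β_n` degradation and `h_n ≥ 0` basal activity.
Interaction edges are undirected and the sign of `b_nm` carries no
activation/repression meaning.

The two layers couple through the TFs: a TF's activity variable drives the
sigmoid regulation functions on the gene side while obeying its own
interaction dynamics on the protein side. Merging the fitted per-target
equations therefore yields one coupled system that can be simulated forward,
including under TF deletion.

## Identification

Each target node yields one linear regression (the bilinear products are
known regressors once activities are observed) with inequality constraints
on the basal (and translation) coefficients. The constrained least-squares
problems are solved by a primal active-set method for convex QP written for
this package: the equality-constrained subproblem over the working set is
solved through its KKT system, blocking constraints are added on partial
steps, and the constraint with the most negative multiplier is dropped at
subproblem optima. The unconstrained optimum is returned directly when
feasible. Tolerances: working-set convergence 1e-10, feasibility check 1e-9,
binding-constraint detection 1e-8. Rank deficiency is detected by pivoted QR
and reported with the offending column labels.

Model structure per target is chosen by bidirectional greedy AIC descent
over the candidate-edge columns only (retention, basal and translation
columns are mandatory). The AIC is the least-squares form
`n ln(rss/n) + 2p`; a numerically perfect fit (rss < 1e-20 per observation)
scores −∞, and at −∞ a drop that keeps the fit perfect counts as an
improvement so that zero-noise searches terminate at a minimal perfect
model. The descent starts from the mandatory-only set; a second descent from
the full column set runs only when needed to guarantee the final AIC is
at most min(full-model AIC, mandatory-only AIC). Ties break toward the
smaller model, then lexicographically — the whole search is deterministic.

Retained edge coefficients are tested with two-sided Student t statistics
using the unconstrained covariance `σ̂²(ΦᵀΦ)⁻¹` on the selected columns,
`σ̂² = rss/((L−1) − P)`. Only edge coefficients are tested; mandatory
coefficients (some of which sit on constraint boundaries) are not. P-values
are Bonferroni-adjusted with the per-target candidate count as the family,
and edges with adjusted p ≤ 0.05 (configurable) survive. An undirected PPI
edge appears in both endpoint regressions; it is preserved if significant in
at least one of the two (union rule — maximizes sensitivity; an intersection
mode is available).

Known statistical caveat: t-tests computed on an AIC-selected model are
post-selection inferences and are anticonservative. Under a global null
(no true edges, 20 candidates, n = 40) the realized fraction of datasets
retaining at least one edge is about 0.25 rather than the nominal 0.05 —
the acceptance script measures this honestly
(`fwer_null_retention_fraction`). Spline densification (below) adds a
further ~√2 inflation of every t statistic because interpolated rows carry
almost no residual while the degrees of freedom count them in full. Both
effects are properties of the procedure itself, faithfully implemented;
consumers who need strict error control should treat the reported adjusted
p-values as rankings, not calibrated error rates.

## Preprocessing

Order: responsive filter (max |log2 ratio| ≥ log2 fold, default fold 3) →
missing-fraction filter (≤ 30%) → natural-cubic-spline imputation on the
log2 scale (imputing before linear conversion avoids positivity artifacts)
→ log2 → linear conversion (`2^v`) → spline densification of the time grid
(default factor 2; each original interval is split into equal sub-intervals,
original points preserved exactly, negative spline excursions clipped to 0).
"Natural" boundary conditions (zero second derivative) were chosen for
reproducibility; leading/trailing missing values are filled by the boundary
cubic's extrapolation. Densification exists to stabilize per-target
regressions whose parameter count approaches the raw number of time points;
it does not add information (see the caveat above).

Because genome-wide protein-activity measurements are rarely available,
activity profiles default to the mRNA-for-activity substitution. Under that
substitution the translation column `x_n[t]` and the retention column
`y_n[t]` of a protein regression are identical; the builder detects this and
merges them into one combined-retention column with coefficient
`α_n + 1 − β_n`, reporting α and β as not separately identifiable. The full
four-block design is used automatically whenever genuinely distinct activity
and mRNA matrices are supplied.

## Synthetic-data generator

The generator emulates a stress-response time course: states are displaced
from rest and relax under the coupled dynamics, simulated synchronously on a
fine grid ((L₀−1)·f + 1 points, default f = 2) and observed on the coarse
L₀-point grid, mimicking dynamics faster than the sampling rate. Additive
Gaussian noise enters every simulation step with a per-node standard
deviation equal to a stated fraction (default 2%) of that node's noise-free
signal range. Negative states clip to zero; clipping events are counted and
scenario defaults keep them below 1% of updates. Candidate pools are the
true networks plus uniformly sampled decoy edges (candidate:true ratio
`decoy_factor`, default 2.5). Everything is deterministic given the seed.

Parameter sampling, chosen once for bounded yet persistently exciting
trajectories:

- Gene layer: `a` uniform on ±[0.3, 1.0] with activator-biased signs per
  gene (keeps expression off the zero floor), retention `1−λ` on [0.3, 0.9],
  `k` on [0, 0.5].
- Protein layer: retention on [0.4, 0.9] for ordinary proteins and
  [0.7, 0.95] for TFs (long-lived regulatory proteins; slower activity
  curves also remain faithful under spline densification), basal
  `h = U(0.4, 0.8)·(1−ρ)` so linear-part fixed points sit near typical
  activity levels. Each undirected interaction acts with opposite signs on
  its two endpoints (activator–inhibitor push–pull), which makes the
  dominant pair dynamics rotational rather than explosive; per-target
  interaction weights have magnitudes U(0.7, 1.0) normalized so
  Σ|b| = 3·(1−ρ). A rejection loop re-simulates with damped b (×0.7) in the
  rare draws whose trajectories exceed an activity ceiling of 10.
- Initial conditions: a random ~40% subset of proteins ("stress sensors")
  start far above rest (U(1.5, 3.5)); the rest start near baseline.

What the generator does not emulate: probe-level measurement error,
missing-not-at-random dropout, unmeasured regulators, chromatin state,
translation delays, or protein activities that deviate from mRNA beyond the
substitution assumption. Passing recovery tests on these scenarios therefore
demonstrates correctness of the estimator under the model's own assumptions,
not performance on real microarray data.

A calibration note on attainable recovery: the bilinear protein model is
stability-limited — the per-target gain `ρ + Σ b⁺ y` must stay below 1, so
the total interaction signal is capped at roughly twice the retention margin
regardless of sign structure. At 2% innovation noise over ~20 independent
time points this caps post-selection |t| values near 2 for typical edges,
and undirected recovery saturates around 60–65% sensitivity at the default
scenario scale, with false-positive rates inflated by the post-selection and
densification effects described above. The acceptance script reports the
measured rates; they are properties of the method at these conditions, not
tunable constants.

## Knockout prediction

A TF deletion clamps the TF's activity to 0. Under the default "clamp"
semantics its regulation function becomes the deletion floor
`f_j(0) = 1/(1+exp(μ_j/σ_j))` — the logistic never reaches exactly zero —
while the alternative "hard_zero" semantics forces `z_j ≡ 0`. The fitted
system (stepwise-selected coefficients of every target) is iterated forward
noise-free from the wild-type initial state. On synthetic round-trips with
candidate = true network the mean per-gene correlation between the predicted
and ground-truth knockout trajectories is ≈ 0.96.

## Integration and comparison

Merging unions the node sets, labels TF-incident transcription edges by
coefficient sign, and flags interface TFs (incident to at least one edge of
each kind). Node degree for hub ranking counts transcription edges at both
endpoints plus interaction edges; ties break lexicographically. Conservation
across conditions is reported for every non-empty subset of conditions
(inclusive intersections by default; an exclusive mode subtracts items
present outside the subset), with conservation fractions computed against
the candidate-pool counts. Preserved-percentage bookkeeping is verifiable by
an independent recount from the serialized edge-TSV (`recount_preserved`).

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run on: 200 random
sign-constrained QPs (40 × ≤6) against a FISTA projected-gradient oracle;
100 random stepwise instances (≤8 candidates) against exhaustive
enumeration; designed 6-gene/4-TF and 5-protein zero-noise systems; ten
replicates of the 30-gene/8-TF/25-protein scenario (L₀ = 21 densified to
41, 2% noise, decoy factor 2.5); 500 global-null replicates for the
family-wise error measurement; and a 10-gene/3-TF/8-protein scenario for the
knockout and bookkeeping checks.
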