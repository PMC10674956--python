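# Methods

This note records the modelling choices behind `routemerit`: what each stage
assumes, which parameters matter, and where the design was genuinely open.

## Quartile binning

Raw network statistics are scaled by their maximum (not min–max): observed
minima of the published weight columns are nonzero while maxima are exactly
1, and only max-scaling preserves that.  Absence from a network layer is the
sentinel −1, which is semantically distinct from a zero statistic.

Bin boundaries are sample quartiles under the `np1` positional convention:
quartile *p* sits at position (n+1)·p in the sorted sample, averaging the two
bracketing order statistics at fractional positions.  Whether the −1
sentinels participate in the quartile computation is not derivable from first
principles, so it was fixed by calibration: a grid search over four quantile
conventions × {include, exclude sentinels} against the published boundary
tables.  Exactly one combination — `np1` with sentinels included — reproduces
every published boundary of both the metabolite-weight and the
pathway-indicator tables; it is frozen in
`src/routemerit/data/fixture_meta.json` and asserted by the test suite.

Category assignment uses right-closed intervals (a value equal to an interior
boundary belongs to the *lower* category; the bottom interval is closed on
both sides).  This is load-bearing: several published weight rows sit exactly
on a boundary.  The sentinel always maps to the lowest-value category.  For
FDR the orientation is reversed: the smallest values carry the best grade.

## Fuzzy merit models

Both models are Mamdani systems: rule activation by the minimum of the
antecedent membership degrees, implication by clipping, aggregation by
pointwise maximum, centroid defuzzification.

**Input membership geometry.**  The published tables give category *ranges*,
not membership functions, and several readings are possible.  Two presets are
implemented:

* `range` (default): each category's triangle spans exactly its own bin
  range, apex at the range midpoint; the two outer categories anchor their
  peaks at the domain ends, so the −1 sentinel carries full Weak membership
  and the column maximum full Excellent membership.  Supports meet only at
  shared boundaries, so a strictly interior input belongs to exactly one
  category.  A value exactly on a boundary (zero membership everywhere)
  falls back to its crisp bin category at membership 1, logged.
* `overlap50`: apexes at bin midpoints, feet at the neighbouring apexes — a
  partition of unity with 50% overlap between adjacent categories.

The preset is selected by calibration residuals over all 55 + 33 published
merits, as a model-selection criterion rather than an assumption; `range`
wins decisively (RMSE 2.54 vs 7.97, 26 vs 2 exact reproductions) and is the
default.

**Output functions and anchoring.**  The output variable on [0, 100] uses
symmetric triangles (model 1) or symmetric trapezoids (model 2) centred on
the four category centroids.  Symmetry is deliberate: the centroid of a
single clipped symmetric function equals its centre at *every* activation
level, which is exactly the behaviour the published tables demand — rows with
very different activation strengths but identical category patterns print
identical merits.  The centroids are therefore free calibration parameters
anchored on the degenerate published rows (all four inputs in one category):
the most frequent printed merit per category, falling back to the median when
no value repeats.  For the metabolite model this yields Weak = 12.357,
Moderate = 37.5, Good = 62.5, Excellent = 90.33333333.  The shared half-width
is the largest value keeping every function symmetric inside [0, 100] with
disjoint adjacent supports; it only influences blended (multi-rule) outputs.

**Defuzzification.**  Because every membership function is piecewise linear,
the centroid of the aggregate is computed exactly by segment-wise integration
between breakpoints (membership vertices, clip corners, pairwise edge
intersections).  A uniform-grid mode exists for cross-checking; at 1001
points its error on off-grid centroids at low activation reaches ~2e-3,
which is why exact integration is the default rather than a grid.

**Rule-consequent calibration.**  The concrete rule consequents are not part
of the published tables.  They are reconstructed by fit: every homogeneous
antecedent (all inputs in category X) is pinned to consequent X; every other
rule activated by at least one example is assigned the consequent minimizing
the squared error of the fitted system (iterated exhaustive per-rule search —
one pass suffices under the `range` preset, where each example activates a
single rule); rules never activated by data fall back to a weighted majority
vote over their antecedent categories.  For the metabolite model the MGDIN
inputs carry twice the vote weight of the MMIN inputs, because the published
examples treat MMIN absence as far less damaging than MGDIN absence (a
metabolite absent from MMIN but Excellent in MGDIN prints the pure Excellent
merit; the converse prints a Weak-range merit).  Calibration reports per-row
residuals and never silently absorbs conflicts: non-monotone centroid anchors
raise a calibration failure listing the conflicting examples.

Residuals of the route model (and of blended metabolite rows) are reported,
not asserted: they reflect rule decisions and membership nuances the source
tables do not print.  One metabolite row is internally inconsistent with its
neighbours — its four weights are category-identical and strictly interior to
the same categories as another row, yet the two printed merits differ by
~1 — so no rule-based system binned by the published ranges can reproduce
both; the residual (0.98) is left standing and the corresponding acceptance
check is expected to stay red.

**Scoring new data.**  Values beyond a variable's calibration domain
saturate into the nearest edge category (`clamp=True` in table scoring);
inference on raw inputs outside the universe otherwise raises a range error
naming the variable.

## Centrality suite

Degree, betweenness, closeness, eigenvector, clustering coefficient and the
shortest-path machinery ride on networkx/numpy; centroid value, stress,
bridging, radiality, eccentricity (as reciprocal maximum distance, so larger
means more central), topological coefficient and neighborhood connectivity
follow the definitions documented in `centrality.py`.  Betweenness and
stress are raw unordered-pair counts.  Disconnected graphs are handled
within components; cross-component distance is undefined (never infinite),
and undefined values carry the −1 sentinel.  Ties at rank *k* in the top-*k*
union are all included (a stable superset) and logged.  All twelve measures
are verified to 1e-9 against a brute-force oracle that enumerates shortest
paths explicitly on graphs of up to 25 nodes.

## LSTM surrogate

Architecture: sequence input → one LSTM layer (default 100 hidden units) →
fully connected → scalar regression output; mean-squared-error loss with
Adam (learning rate 0.0005).  The 55-value merit vector is presented as one
time step with 55 channels by default; `sequence_mode="steps"` gives the
length-55 / one-channel reading.  Inputs and targets are scaled by 1/100
into [0, 1] (merits live on [0, 100]); unscaled mode is available.  The
validation carve-out defaults to 20% of the training routes, seeded, and
training returns the parameter state with the lowest validation loss.  The
desk-scale preset trains for 2000 epochs with early-stopping patience 200;
the long preset (100000 epochs, no early stopping) is selectable.  Forward
and backward passes are implemented in numpy and verified against finite
differences; everything is reproducible from one integer seed.

Repeated-holdout evaluation draws the held-out routes without replacement
within each repeat and re-samples across repeats (the repeat protocol the
source leaves open), reporting per-repeat and mean R².

A capacity caveat drives one experiment-design choice: with only 33 routes
(28 after the test carve-out) in 55 dimensions, even the true *linear*
generating map is underdetermined — no learner can reliably reach held-out
R² ≥ 0.9 at that size.  The planted-linear recovery experiment in the test
suite therefore uses a 200-route synthetic design (same generator, same
55-metabolite panel, exact linear target over 5 planted columns), where the
LSTM reaches held-out R² ≈ 0.98.

## Binary GA

Selection is binary tournament (roulette by option), crossover single-point
(two-point and uniform by option) applied to every selected pair
("crossover proportion 1"), elitism 1 so the best-so-far trace is monotone.
The published "mutation coefficient 0.09" is read as a *per-chromosome*
rate — with probability 0.09 a child has one uniformly chosen bit flipped.
The per-bit reading (also available) implies ~5 flips per 55-bit child, and
measured mutation–selection balance then stalls separable problems around
50/55 ones, making convergence to a global optimum within 300 iterations —
the published behaviour — unreachable; the per-chromosome reading reaches it
reliably.  The number of selected metabolites is an outcome, never a
constraint.  Chromosomes are mapped to surrogate inputs by masking the
merit-weighted column values (bit × merit), matching the route encoding used
in training; a raw-bits mode exists for ablation.

## Synthetic data

The generator emulates the statistical shape of the study inputs: two
preferential-attachment interaction layers whose degree/betweenness columns
are max-normalized (with ~10% −1 sentinels per layer, disjoint between
layers so every metabolite keeps one live pair), pathway indicators with
log-uniform FDRs spanning 1e-27–5e-2 and impacts up to ~0.7, and a Bernoulli
incidence at density 0.15 repaired (seeded, O(cells)) to contain no empty
row or column.  One global seed fans out to fixed-key child streams, so
adding a component never perturbs existing ones and a bundle regenerates
bit-for-bit from its manifest.

What the generator does *not* emulate: real pathway membership structure
(incidence cells are independent), correlations between a metabolite's four
weight columns beyond what the two random graphs induce, and real metabolite
identities.  Tests passing on synthetic bundles therefore demonstrate the
machinery (calibration, training, search, reproducibility), not biological
validity of any particular selection.

Planted-optimum bundles rewrite route merits as effect × (planted-subset
coverage) + Gaussian noise, push the planted metabolites' weights into the
top quartile band, and attach a deterministic additive fitness (positive
weights on the subset, negative elsewhere) whose unique argmax is exactly
the planted subset — the ground truth for GA recovery tests.

## Pipeline

Stages run in dependency order with explicit artifact passing; a disabled
upstream stage surfaces as a dependency error naming what is missing.  The
run report lists every output file with a SHA-256 digest and carries a
content digest over a canonical core that excludes wall-clock timings, so
identical config + seed reproduce an identical digest.  Rule bases are
always calibrated on the packaged worked-example tables; the supplied
weight/indicator tables are what gets scored.  When no incidence file is
given, a seeded synthetic incidence of matching shape is generated and the
report says so.

## Known limitations

* The published rule consequents and the real route×metabolite incidence
  live in a supplementary file outside the printed tables; consequents are
  reconstructed by calibration (blended rows keep residuals of a few merit
  points), and the incidence is synthetic unless supplied by the user.
* The surrogate's published mean holdout R² (~0.64) is tied to that
  supplementary matrix and is not reproducible from the printed tables; the
  package substitutes the planted-linear recovery experiment described
  above.
* The exact 25-metabolite published selection is likewise
  supplementary-dependent and stochastic; the GA reproduces selection
  *behaviour* (optimum recovery, planted-subset Jaccard 1.0 over 20 seeds),
  not that specific list.
* Centrality measures are exact but O(n·m)–O(n³); the suite targets
  curated disease networks (tens to hundreds of nodes), not genome-scale
  graphs.
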