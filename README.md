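# routemerit

Network-driven prioritization of metabolites in disease-associated metabolic
routes, built around a published neovascular age-related macular degeneration
(nAMD) metabolite panel.

## The problem

Multi-layer network studies of a disease end with long candidate lists: which
of 55 metabolites spread over 33 significant metabolic pathways actually
matter?  This package implements a complete prioritization chain for that
question:

1. **Centrality screening** — twelve node centralities (degree, betweenness,
   closeness, centroid value, stress, bridging, radiality, eccentricity,
   eigenvector, clustering coefficient, topological coefficient, neighborhood
   connectivity) with top-*k* union and two-stage merge procedures that
   nominate hub candidates from interaction networks.
2. **Quartile binning** — each metabolite's four max-normalized network
   statistics (degree and betweenness in the metabolite–metabolite layer,
   MMIN, and the metabolite–gene–disease layer, MGDIN) are cut at their
   sample quartiles into Weak / Moderate / Good / Excellent; pathway
   indicators (degree/betweenness/closeness impact, FDR) are graded D–A, with
   FDR reversed (smallest is best).  A value of −1 is a sentinel meaning
   "absent from this network layer".
3. **Fuzzy merit models** — two Mamdani systems (min-AND activation, clipped
   consequents, max aggregation, centroid defuzzification) map the four
   binned indicators to a 0–100 *merit*: model 1 scores metabolites
   (4 inputs × 4 triangular membership functions, 256-rule grid), model 2
   scores routes (betweenness collapsed to 3 functions, trapezoidal output).
   The rule consequents are *calibrated* against the published worked-example
   merits under a homogeneity constraint (all-X inputs ⇒ consequent X).
4. **Route matrix** — the 33 × 55 route×metabolite incidence with each
   presence flag replaced by the metabolite's merit, plus one output merit
   per route.
5. **LSTM surrogate** — a sequence-to-one recurrent regressor (100 hidden
   units, Adam, best-validation checkpoint) predicting route merit from the
   55-value vector, evaluated by repeated 5-route holdout.
6. **Binary GA** — a 55-bit genetic algorithm (300 iterations, population
   100, mutation coefficient 0.09, crossover proportion 1, tournament
   selection, one elite) that searches for the metabolite subset maximizing
   surrogate-predicted route merit.

A synthetic-data module generates statistically matched stand-ins (scale-free
interaction layers, log-uniform FDRs, Bernoulli incidence, planted optima) so
every stage is testable without any download.

## Worked example

Calibrate the metabolite merit model on the packaged fixture tables and score
two metabolites by their printed normalized weights:

```python
from routemerit import fixtures

results = fixtures.metabolite_merit_model().fit()
print(results.summary())
```

```
Merit rule-base calibration
===========================================
examples:            55
rules:               256 (35 activated by data)
membership preset:   range
output centroids:    Weak=12.35708, Moderate=37.5, Good=62.5, Excellent=90.333333
anchored categories: Weak, Moderate, Good, Excellent
RMSE:                2.5387
max |residual|:      8.5091
exact fits (<1e-3):  26
worst residuals:
  L-Histidine                    printed=53.9909      fitted=62.5         resid=+8.5091
  Serotonin                      printed=54.8749      fitted=62.5         resid=+7.6251
  L-Isoleucine                   printed=44.41        fitted=37.5         resid=-6.9100
  Betaine                        printed=42.6383      fitted=37.5         resid=-5.1383
  Urea                           printed=42.4297      fitted=37.5         resid=-4.9297
```

```python
base = results.rule_base
print(base.infer([0.4875, 0.217186109, 0.363636364, 0.259194216]))  # Glycine
print(base.infer([0.153125, 0.021684479, 0.054545455, 0.029713312]))  # Inosine
```

```
90.33333333
37.5
```

Glycine's four weights all fall in the Excellent bins, so the system
defuzzifies to the pure Excellent centroid (90.33333333 — the value the
worked-example table prints for every all-Excellent metabolite); Inosine's
weights are all Moderate and land exactly on 37.5.  The calibration RMSE of
2.54 over all 55 rows, with 26 exact reproductions, is the residual left by
rule consequents that the published tables do not print (see
`docs/methods.md`).

The full pipeline, from fixture tables to a GA-selected metabolite panel:

```bash
frm run --config run.yaml     # seed, output dir and stage toggles in YAML
```

or stage by stage: `frm centrality`, `frm bin`, `frm fuzzy calibrate`,
`frm fuzzy score`, `frm surrogate train`, `frm surrogate eval`, `frm ga run`,
`frm simulate`.

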