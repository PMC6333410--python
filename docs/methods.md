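# Methods

## Scope

`cellfactory` predicts realised cell-factory performance — titer (g/L),
rate (g/L/h) and yield (g/g) — from strain-design records, combining two
information sources: what the metabolic network *can* do (flux balance
analysis under experiment-matched constraints) and what published designs
*did* do (supervised learning over the curated feature template). The
package ships a synthetic-study generator, so every stage is exercised and
validated without the externally hosted curated dataset.

## The strain-design template

Records follow a 45-field template in six blocks: carbon source(s)
(name, molecular weight g/mol, concentration mM, elemental C/H/O),
bioprocess conditions (reactor type, working volume L, media category,
temperature °C, fermentation time h, aeration regime), genetic
modifications (background-strain gene list with insertion/deletion flags;
design gene list with deleted / overexpressed / heterologous / copy-number
/ codon-optimisation / sensor-regulator / enzyme-redesign / scaffold flags,
plus directed-evolution and modular-pathway-optimisation indicators),
product characterisation (elemental composition, molecular weight,
central-metabolism precursor code, enzyme steps, ATP and NADH/NADPH costs),
production metrics (three yield variants, titer, rate, biomass titer and
growth rate — all nullable), and two completeness flags. Gene-parallel
fields are comma-joined inside one delimited cell; a machine-readable copy
of the template ships as `cellfactory/data/template_schema.json`.

Derivable metrics are back-filled from reported ones — yield on substrate
fed = titer / Σ(conc·mw/1000), yield on biomass = titer / biomass titer,
average productivity = titer / time, product mw = 12C + 1H + 16O + 14N
(integer masses reproduce the template's printed values exactly). Derived
values never overwrite reported ones and carry an `estimated` provenance
flag. Because the template's reported rate is a *maximum* productivity
while titer/time is an *average*, estimated values are excluded from model
supervision and scoring by default (`reported_targets_only`); they remain
available for completeness analyses.

Encoding: continuous fields pass through with training-median imputation;
enumerations (reactor type, media, aeration, precursor) expand to 0/1
indicators with a dedicated `unknown` level; variable-length gene lists
collapse to fixed aggregates (counts of modified / deleted / overexpressed
/ heterologous / codon-optimised / sensor-regulated / redesigned /
scaffolded genes, mean plasmid copy number, background-modification
counts); absent carbon sources 2/3 contribute zero blocks. Product-name
indicators are off by default: identity is carried by the numeric product
descriptors, and 25 extra one-hot columns would crowd the 40-component
projection budget (flag `product_name_indicators` restores them).

## Constraint-based features

cobrapy (GLPK backend) supplies model I/O (SBML Level 3 FBC and the cobrapy
JSON dialect), gene–reaction rule evaluation and the LP solver. A record
maps onto the model as: chosen carbon-source exchanges opened at the
configured uptake (default 10 mmol/gDW/h), others closed; aeration regime
bounds O₂ uptake (anaerobic 0, microaerobic 20% of the aerobic default,
aerobic the default, extra-aerobic effectively unbounded); knockouts zero
every reaction whose GPR evaluates false; overexpression raises a
reaction's lower bound to 10% of its theoretical maximum flux, computed on
the environment-constrained model *before* the same spec's genetic
interventions (environment first, then genetics); a measured growth rate
becomes a biomass lower bound in the product-side LPs (capped at the
model's maximal growth so an over-optimistic measurement cannot make the
LP infeasible).

Four LPs (max growth; max product; max growth at product fixed to half its
maximum; max product at growth fixed to half its maximum — the 50%
side-constraints are equalities) give the four yield features, each a
flux-per-carbon-uptake ratio. FBA optima can be degenerate in the uptake
flux, so a secondary LP pins the objective at its optimum (1e-9 slack) and
minimises total carbon uptake, making the features deterministic. An
infeasible growth LP marks the design infeasible with zero-filled features;
later-LP failures are recorded per record, not raised. Solver feasibility
tolerance is fixed at 1e-9; tests compare optima against brute-force vertex
enumeration of the flux polytope at 1e-6.

## Factor analysis

MCA is implemented as correspondence analysis of the complete indicator
matrix (no Burt matrix, no eigenvalue correction): standardised residuals
D_r^{-1/2}(P − rcᵀ)D_c^{-1/2} are decomposed by SVD; principal coordinates,
eigenvalues (squared singular values) and per-category contributions
(mass × squared coordinate / eigenvalue) follow. Total inertia equals
J/Q − 1 for J categories over Q variables, which the tests assert.
Continuous features use standardised PCA with squared-unit-loading
contributions. The default split keeps MCA categorical-only and PCA
continuous-only; a joint MCA can be requested after quartile
discretisation of continuous columns. The factor report ranks features by
their contributions to the first two components and emits a record-level
overlay (coordinates + titer quartile bin 1–4) for plotting.

## Preprocessing, splitting, augmentation

The held-out test split (default 10%) is drawn by record id before any
fitting; imputation medians, standardisation statistics and the PCA basis
(first min(40, rank) components) are learned on training rows only.
Augmentation appends n replicates per training row, multiplying each
non-null target by an independent Uniform(1 − t/100, 1 + t/100) draw —
a hard ±t% bound — with features copied verbatim; inside cross-validation
it is applied to the training part of each fold only, so no
near-duplicates straddle folds. The (n, t) grid search scores each cell by
fold-internal-augmented CV R² with ties broken toward smaller n then t.
A `LeakageAudit` records the ids each stage consumed; the pipeline asserts
no test id appears in any fitting stage on every run.

## The stacked ensemble

Six base learners per metric: SVR, elastic net, random forest,
XGBoost gradient-boosted trees, k-NN, and a numpy feed-forward network
with five hidden layers of 100 units, batch normalisation and dropout
(rate 0.2) between layers, trained by Adam on mean-squared error
(the network recomputes its batch-norm inference statistics exactly over
the training set after training). Each learner is grid-searched over a
compact grid with five-fold CV; every fit sees a per-fit standardised
target (undone at prediction) so scale-sensitive learners behave
comparably across metrics whose magnitudes differ by two orders. Out-of-
fold predictions form the meta-feature matrix; the gradient-boosted-tree
meta-regressor is itself grid-searched (depth 1–3, 50/200 trees) on the
same folds, and the reported CV score of the stack is out-of-fold at the
meta level too. One stack is trained per metric; rows with missing (or
estimate-flagged) targets are dropped for that metric. Evaluation reports
test R² (1 − SSE/SST about the test mean) and Pearson r, optionally also
on per-product max-scaled values; fewer than three test rows yields
undefined metrics. The ablation utility trains identically seeded stacks
with and without the `cobra_` columns (each arm refits its own
standardise+PCA transform); the learning-curve utility reports training
and CV R² (mean ± sd) over seeded subsamples per size.

## Synthetic study generator

The toy network (13 reactions, 8 genes, carbon-balanced by construction)
routes glucose (2 precursors each) or glycerol (1) through a common
precursor to a product branch (isozymes gP1/gP2), a respiratory ATP branch
(2 ATP per precursor, 3 O₂), a fermentative branch (1 ATP) and a biomass
reaction (2 precursors + 2 ATP). Closed forms at uptake 10: max product
flux 20 (yield 2 mol/mol), max aerobic growth 20/3 (yield 2/3), anaerobic
growth 5; the 50%-constrained yields are exactly half the maxima. Gene
rules include AND (glucose PTS) and OR (product synthase) cases.

Records are sampled to emulate a literature-curated database: 1200 records,
25 products (40% native; non-native products carry heterologous genes),
glucose-dominant substrates, a bimodal good/poor design mixture driving
correlated draws of modular-pathway optimisation, directed evolution,
aeration match and media richness. Ground truth (coefficients in
`TRUE_COEFFICIENTS`, all on documented closed forms):

- process quality u = sigmoid(linear score of observable design factors);
- growth factor h = 0.25 + 0.75·min(1, y_b^max / (2/3)) from the design's
  FBA biomass yield — knockout *identity* (e.g. fermentation vs
  respiration genes under a given aeration) acts through h and y_p^max
  while the schema only records knockout counts, which is exactly why the
  flux features carry information the ablation detects;
- yield (g/g) = y_p^max·(mw_p/mw_cs)·u·h;
- titer = 18·tanh(yield·substrate_fed/18) g/L (saturating product
  inhibition);
- rate = 1.0·(titer/8)·exp(1 − titer/8)·q g/L/h — a concave link of titer
  peaking at 8 g/L (the middle of the 6–10 g/L band where curated maximal
  productivities cluster) scaled by an observable process factor q
  (continuous 1.7× / fed-batch 1.3× / batch 1×, rich media e^0.25).

Reported metrics are the truths times log-normal noise (sd 0.1) thinned by
per-metric missingness (titer 3%, rate 35%, yield-on-fed 30%,
yield-on-consumed 90%, yield-on-biomass 45%, biomass fields 40%);
fermentation time is log-normal (median 36 h). A sidecar table carries the
noise-free targets, so attainable ceilings are computable exactly: under
the default noise the reported-versus-true correlation is ≈0.96–0.98 per
metric.

What the generator does *not* emulate: real products' absolute titer
scales, secondary-substrate media effects, by-product secretion, strain
stability, study-level correlation of records from one paper. Passing
recovery tests therefore demonstrates that the pipeline's machinery is
correct and leakage-free under known ground truth, not that comparable
accuracy is attainable on any real curated dataset.

## Problem sizes and numerical choices

Default pipeline runs use the full 1200-record study, the six-learner
stack with compact grids, 25–60 NN epochs equivalents (60 epochs, batch
128) and n = 3 augmentation replicates; n = 50 / t = 0.1% are the tuned
augmentation values and are exercised by the augmentation-contract checks,
while replicate counts beyond ~3 measurably change neither CV nor test
scores on this study (jitter at 0.1% acts as row weighting), so the
smaller count is the package's run-scale choice. Learning curves use a
reduced three-learner set. Held-out performance on the default study is
r ≈ 0.91–0.95 (titer), 0.82–0.86 (rate), 0.91–0.93 (yield) across seeds;
rate is the hardest metric because the concave link makes its
conditional mean most sensitive to titer-model error. In the noise-free
limit the stack reaches R² ≈ 0.94 on titer; the residual is learner bias
on the nonlinear response, not noise.

Determinism: every stochastic component (splits, folds, learner seeds,
augmentation draws, NN initialisation and dropout) derives from explicit
seeds; two runs with the same seeds produce identical reports. LP
determinism additionally relies on the uptake-minimising secondary
objective described above.

## Known limitations

- Overexpression targets whose theoretical maximum flux is zero are left
  unmodified (logged), matching the rule's definition but silently
  dropping impossible interventions.
- yield-on-consumed (g/g consumed) requires substrate-consumption data the
  template rarely carries; it is never derived and stays null when absent.
- Plasmid copy numbers are aggregated as a per-record mean; their
  gene-level resolution is not used further.
- The iML1515-scale SBML path is supported (Level 3 FBC via cobrapy) but
  untested at genome scale in this repository.
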