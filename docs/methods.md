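# Methods

## Problem and model

The package estimates regional type-2-diabetes (T2D) food-access risk from
three data streams: food venues (POIs) with coordinates and a ten-way
food-access category label A1–A10 (low-access stores … direct farm sales),
geotagged check-in posts treated as evidence of venue visits, and
diagnosed-case profiles carrying weekly per-category visit counts.  Space is
partitioned into Web-Mercator slippy tiles; one tile is one training unit.

### Feature splicing

A check-in is joined to a venue in the same tile when both gates pass:

- text similarity `S = 10 · cos(p, n)` between the venue description `p` and
  the post text `n` (term-frequency vectors; tokenization is lowercase,
  split on non-alphanumerics) is **strictly greater than 3.5**, and
- great-circle distance `D = hav(p, n)` with Earth radius `R = 6371 km` is
  **strictly less than 3 km**.

Both inequalities are strict by design.  Among qualifying venues the
highest-similarity one wins; ties break by smaller distance, then
lexicographic venue id, so splicing is one-to-one and deterministic.
Spliced check-ins are binned into weeks (Monday start, week 1 opens
2020-01-06) to give each venue a weekly visit-frequency series `f(P)_t`.
A venue's node feature row at week `t` is
`[scaled lat, scaled lng, one-hot(A1..A10), f_t]` (13 values), with
coordinates min–max scaled to [0, 10] inside the tile's bounding box.

### Per-tile graphs

Within one tile and week, every case contributes one hyperedge per category
it visited that week, spanning the tile's venues of that category.  The
adjacency used by the convolution is the clique expansion of those
hyperedges (binary, symmetric, zero diagonal).  Hyperedge representations
are built by multi-head attention over member venues,

    c_e = (1/K) Σ_k Σ_{j∈e} α_j^k (W_c p_j),
    α^k = softmax_j LeakyReLU( b_k^T [ W_c c_0 ‖ W_k p_j ] ),

where `c_0` is the unweighted member mean.  The attention score needs the
edge vector and vice versa; this cycle is resolved in a single pass by
seeding with `c_0` — the minimal interpretation that makes the definitions
well-founded.  Each node then receives the mean of its incident edge
vectors added onto its features (duplicate case edges over the same member
set weight that mean by their multiplicity), keeping the feature scale
stable regardless of how many cases live in a tile.

### Convolution, fusion, recurrence

The spectral propagation operator is `Â = D̃^{-1/2}(A + I)D̃^{-1/2}`; its
spectral radius is at most 1, and on a k-regular graph it preserves constant
vectors exactly.  Layers stack as `H^{(l+1)} = ReLU(Â H^{(l)} W^{(l)} +
b^{(l)})`; the default is 2 layers with hidden width 32, the output width
returning to 13 so that fusion shapes agree.  Weekly inputs to the
recurrence fuse raw and convolved features,

    X_p^t = δ · X^t + (1 − α) · H^t,    δ = α = 0.5 by default,

and feed a standard LSTM cell (forget/input/output sigmoid gates, tanh
candidate, `C_t = F ⊙ C_{t−1} + I ⊙ g`, `h_t = O ⊙ tanh C_t`) with hidden
size 16, parameters shared across venues and tiles.  The fusion δ and α are
independent mixing hyperparameters; δ weights the raw features and (1 − α)
the convolved ones.  At the final week, venue hidden states are mean-pooled
through an affine + sigmoid head into a tile risk score in (0, 1); the same
head applied before pooling yields per-venue scores.

### Training

Binary cross-entropy against the binary tile label, adaptive-moment (Adam)
updates on gradients averaged over minibatches of 8 tiles, learning rate
0.02 with a 0.97 per-epoch decay, at most 150 epochs.  Batch averaging
matters when labels are noisy: single-tile updates let the optimizer
memorize isolated mislabeled tiles and destroy generalization, while
batched gradients keep the shared frequency signal dominant.  10% of the
training tiles are held out as a validation slice; after a 30-epoch
burn-in (the loss typically sits on a plateau for the first 10–20 epochs),
training stops when the validation loss has not improved by more than 1e-4
for 20 consecutive epochs, and the best-validation snapshot is restored.
All initialization is
uniform ±1/√fan_in from the seeded generator, so a (data, seed) pair fixes
the entire trajectory.  Gradients come from a small reverse-mode autodiff
tape over numpy arrays (`glstm.autograd`); the model is a few thousand
parameters, for which this is entirely adequate and keeps every numerical
step inspectable.

### Metrics

- `rmse(a, f) = sqrt(mean((a_i − f_i)^2))`.  The evaluation report's RMSE
  compares sigmoid risk scores in (0, 1) with planted tile scores measured
  in check-ins/week; the two live on different scales, so this RMSE is a
  dispersion diagnostic, not a calibrated error — read accuracy and recall
  for recovery quality.
- Accuracy: percent of held-out tiles whose thresholded score (0.5) matches
  the true label.
- Recall `= 100 · TP/(TP + FN)` deliberately mixes units, counting true
  positives in check-ins (visits inside correctly flagged risky tiles) and
  false negatives in case profiles (cases inside missed risky tiles).  It is
  a visit-weighted detection rate over the truly risky region.

### Risk surfaces

Local calibration uses a Gaussian distance kernel
`w_i ∝ exp(−(d_i/b)^2)`, bandwidth `b = 3 km` by default — matching the
splicing distance gate, so "local" means the same thing in both places.
The category spatial weight matrix crosses the 10 categories with regions
(tiles by default, queried at their centers): entry (c, r) is the
kernel-weighted mean of category-c venue scores in region r, a convex
combination of member scores, NaN (missing, not zero) where the region has
no such venue.  This is a deliberately simple geographically weighted
aggregation — it keeps the local-calibration idea while remaining fully
auditable; a geographically weighted random forest is out of scope.
Exports are four GeoJSON layers (tile boundaries, check-in points, venue
points, risk polygons) with deterministic feature ordering.

## The synthetic world

The generator emulates the *structure* of a real corpus — venues clustered
in tiles with category labels, posts whose text similarity and distance to
a target venue are controllable, weekly time bins, case profiles — at desk
scale.  Defaults: 60 tiles (zoom 10, a northeastern-US-like bounding box),
20 venues per tile (categories round-robin, so each category appears twice
per tile), 12 weeks, 500 users, 120 cases assigned to tiles uniformly.

The planted signal: half the tiles are risky.  Check-in emission per
tile/category/week is Poisson with rate `2.0 + risky · 10 · w̃_c`, where
`w̃` is the normalized category weight vector, default concentrated on
supercenters (0.3), convenience stores (0.3) and fast food (0.4) — the
venue types that dominate weekly food access in the source populations.
Each tile's true score is `w · (mean weekly per-category spliced
frequency)`, recomputed from the emitted records through the actual
splicing rule, plus optional Gaussian noise; the label thresholds the score
at 3.7, the midpoint between the expected safe (≈ 2.0) and risky (≈ 5.4)
scores.  With `noise_sd = 0` the margin is ≈ 4σ of the Poisson sampling
noise, so labels are cleanly recoverable; `noise_sd = 1.33 =
margin/z_{0.10}` flips an expected 10% of labels, the corrupted-label
regime used in the robustness checks.

Texts come from a closed vocabulary: six tokens per category (pairwise
disjoint) plus a 4-token shared pool.  A venue description is 4 category
tokens + 1 shared token; a "matching" post copies ≥ 60% of them (cosine
≈ 0.77, comfortably above the 0.35 gate), an off-topic post uses a disjoint
chatter vocabulary (cosine 0 against every venue).  Cross-category venue
similarity is bounded by one shared token (cosine ≤ 0.26), so posts cannot
leak across categories; within a category a post may splice onto a sibling
venue of the same category in the same tile, which leaves every tile-level
quantity unchanged.  Matched posts are rejection-sampled inside
(2.9 km disk around the venue) ∩ (the venue's tile); distance violators are
placed at 3.15–6 km.

What the generator does **not** emulate — and what passing tests therefore
do not show: human mobility patterns (no user home locations, trips, or
revisit habits), venue popularity heavy tails, text beyond bag-of-words
token overlap, seasonality, case geolocation error, or any real spatial
correlation between neighboring tiles.  Recovery results on this world
demonstrate that the pipeline's machinery is correct and that the model can
learn a tile-level frequency-composition signal; they say nothing about
effect sizes in real check-in corpora.

## Numerical choices and degenerate inputs

- Strict threshold inequalities throughout (`S > 3.5`, `D < 3`).
- `similarity` returns 0 when either vector is all-zero.
- `normalized_adjacency` divides by `sqrt(d_i d_j)` computed as one square
  root of the product, keeping simple rational entries exact.
- Empty candidate list in matching returns no match (not an error); an
  empty tile, an empty input series, or an empty test set raises.
- A degenerate (single-point) tile bounding box scales coordinates to 0
  with a warning rather than dividing by zero.
- A tile with no case edges in a week propagates features unchanged through
  aggregation (the GCN still mixes via self-loops).
- Attention softmax subtracts the row maximum before exponentiation.
- BCE is clamped with eps = 1e-12; non-finite training loss aborts with the
  offending tile named.
- Checkpoints are flat `.npz` arrays plus a JSON metadata string.

## Problem sizes

Study-scale runs (60 tiles × 20 venues × 12 weeks, ≈ 22k check-ins) were
chosen as the smallest world in which every tile holds all ten categories,
weekly Poisson noise is clearly sub-margin, and a 70/30 split leaves 18
held-out tiles; one full train/evaluate cycle takes a few minutes on one
CPU.  Unit tests use 3–12-tile worlds.

## Known limitations

- The LSTM is unidirectional and single-layer; no GRU/Bi-LSTM variants.
- Graphs are per-tile; no cross-tile message passing, so spatial smoothness
  of risk arises only through the kernel-weighted surface, not the model.
- The attention/edge-aggregation cycle is resolved in one pass, not
  iterated to a fixed point.
- Dense adjacency matrices: fine for tens of venues per tile, wasteful
  beyond ~10³.
- `category_weights_prior` rescales one-hot features multiplicatively; it
  is a soft nudge, not a Bayesian prior.
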