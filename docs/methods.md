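# Methods

This note records the model, the conventions, and the design choices a
maintainer needs; it states nothing the test suite or
`scripts/acceptance.py` does not itself compute.

## Model and inference

One segment (a 10 s audio chunk, in the motivating application) is a
bag of acoustic words per stream.  The generative process: mixture
weights θ ~ Dir(α); one latent activity z_m ~ Cat(θ) per segment; per
activity k and stream, an emission distribution φ_k ~ Dir(β_k) drawn
once; tokens i.i.d. Cat(φ_{z_m}); streams conditionally independent
given z_m.  Streams may have different vocabularies and lengths, so a
stream can be any discretized sensor, not only a beamforming
direction.

Collapsing θ and φ gives a joint over assignments and counts built
from multivariate Beta ratios,

    log P(Z, data) = log B(τ+α) − log B(α)
                   + Σ_streams Σ_k [log B(ω_k+β_k) − log B(β_k)],

with τ_k the cluster sizes and ω_{k,v} the per-cluster word counts.
The Gibbs conditional for one segment multiplies the prior factor
(τ_k^{\m}+α_k)/(M−1+α·) by, per stream, a ratio of rising factorials
over the segment's word counts.  Why collapsing matters: the
per-cluster predictive is then a Dirichlet compound multinomial, whose
count pmf has a power-law tail P(x_v) = O(x_v^{β_v−β·}); clusters
therefore prefer segments that *reuse* words already seen in the
cluster, the bursty structure that codec words (and, e.g., PIR-sensor
events) exhibit.

Numerics.  All probability arithmetic is in log space; the rising
factorial products are evaluated as log-gamma differences
lgamma(ω+β+c) − lgamma(ω+β), which stays finite where direct products
overflow for large vocabularies.  A direct-product implementation
exists only as an enumeration oracle in the tests and acceptance
script, valid at toy sizes.  Per sweep the sampler costs
O(K·L·S) per segment (L streams, S tokens) and the count tables take
O(K·L·V) memory.

Conventions, each documented where exposed:

- Hyperparameter defaults: symmetric α=1.0 and β=0.1 for every stream.
  β<1 puts the emission prior in the sparse regime that rewards bursty
  reuse; both are ordinary parameters of `Hyperparameters` and of the
  CLI.
- Initialization: each z_m uniform from the seeded generator — the
  simplest exchangeable choice.
- The final clustering is the assignment vector after the last sweep
  (no posterior averaging), keeping cluster identities stable; an
  optional per-sweep history (assignments + log joint) supports visual
  convergence inspection.  Default sweep count: 50.
- One named RNG per fit/assign call, seeded explicitly; sampling order
  is segment order; runs are bit-reproducible, and passing the same
  generator object across a save/load boundary reproduces an
  uninterrupted run exactly.
- Argmax ties in `map` assignment resolve to the lowest cluster index.
- Held-out inference: `map` takes the argmax of the held-out
  conditional against the fitted tables; `gibbs` attaches the segment
  and resamples only its assignment for a fixed number of draws.  Both
  are provided because short per-segment inference is underdetermined;
  neither is claimed canonical.
- Empty segments are valid everywhere and are assigned from the
  cluster-size prior alone.  Out-of-vocabulary tokens at assignment
  time are dropped and counted (the model carries no probability for
  them); at corpus *reading* time under an explicit schema they are an
  error instead — silent dropping is reserved for the filter steps
  where it is the documented semantics.

## Tokenization and vocabulary filtering

An acoustic word is the "_"-joined concatenation of the first
`prefix` codes (default 2) of one codec frame; the separator keeps
distinct code tuples distinct.  One word per frame, so a 10 s segment
at the codec's frame rate yields ~750 words per stream.

Two filters, applied per stream in this order:

1. **Noise-word removal.**  Every word type occurring in designated
   noise segments (e.g. 'absence' periods flagged by a presence
   sensor) is removed corpus-wide — including its occurrences in
   genuine activity segments, where many such words are high-frequency
   background — and the noise segments are dropped.
2. **TFR cutoff.**  Words sorted by descending count (ties broken
   lexicographically for reproducibility) are kept up to and including
   the first word at which cumulative relative frequency exceeds r
   (default 0.6); r=1 keeps everything.

Running noise removal first means the TFR budget is spent on
activity-related words only; the alternative order is a one-line
change but is not exposed, since computing the cutoff on a
noise-inflated vocabulary both shrinks and biases the kept set.  Token
order within segments is preserved through tokenization even though
the model ignores it — cheap, and it keeps provenance.

The code-matrix manifest is a TSV with columns
(segment_id, stream, path[, label, fold]) — one row per
(segment, stream) pair, so multi-stream corpora are expressible in one
file.

## Synthetic data

The generator draws from exactly the model above, so recovery tests
are well-posed: θ, z, per-component φ (once per component, never per
segment — burstiness lives at the activity level), then tokens.
`disjoint-support` mode partitions each vocabulary across components
for maximal-separation fixtures.  Fixtures:

- **Recovery** (default): K_true=4, M=400, 3 streams, V=200, length
  100, β=0.05, α=1 — separable but not trivially, generated in well
  under a second, fitted in a few seconds.
- **Burstiness**: single stream, V=500, β=0.05, K_true=30, M=600,
  length 500.  The scale is set so the count-10 tail comparison is
  informative in every frequency group: with many components (about
  the effective activity count daily-life data exhibits) even the most
  frequent words keep mean per-segment counts well below 10, while
  500-token segments let rare words burst into double digits.
- **Crossed factors** (`weak_streams_fixture`): four components on a
  2×2 design; stream "a" sees only the first factor, "b" only the
  second, "c" their XOR.  Any single stream can at best recover a
  two-way split (ARI ≈ 0.5 against the four-cell truth); the three
  streams jointly identify every cell — the cleanest possible
  demonstration of why conditioning several streams on one latent
  activity helps.

What the generator does *not* emulate: within-segment temporal
correlation (real codec words arrive in runs; the model and generator
are exchangeable), codec or beamforming artifacts, label noise, or
segments spanning activity transitions.  Passing recovery tests
therefore show correctness of the inference under the model's own
assumptions, not performance on real recordings.

## Burstiness diagnostic

For each word, the empirical probability of appearing exactly x times
within a counting unit; units are labeled segments by default, or
pooled per-activity blocks (`activity-block`) — the phrase "within an
activity" is ambiguous between the two, so both are implemented.
Words are ranked by total frequency and split into frequent / average
/ rare groups (the average band centered on the median rank; only
group *sizes* are meaningful, boundaries are a convention); per-group
curves are the member-averaged P(x), x ≥ 1.

Slopes and goodness-of-fit are computed on logarithmically binned
points (geometric bins, ratio 1.6): for heavy-tailed pmfs the deep
tail contributes many support points at the empirical resolution
floor, and unbinned least squares would be dominated by that noise.
Raw points are kept for plotting and for tail masses.  The reference
is a matched multinomial: each unit's tokens redrawn i.i.d. from the
global word-frequency distribution (same per-word means, same unit
sizes, no burstiness); its curves are straight on semi-log axes and
carry strictly less tail mass.

One caveat measured and accepted: under component-level burstiness the
*frequent* group alone is not power-law — selecting the top ~30 ranks
conditions on the largest φ draws, producing a binomial-mixture bump —
so log-log linearity (R² ≥ 0.9) is asserted for the vocabulary-wide
curve and the rare group, while all per-group numbers are reported.
Real recordings, which add within-segment burstiness, show cleaner
power laws in every group than the model's own process does.  No
formal tail-index estimation is attempted; the diagnostic is a fit
comparison, as in its visual origins.

## Evaluation protocol

Fold schemes over F folds (default 64), pivot adjacency wrapping
modulo F: **E1V1T62** evaluates on the pivot fold, validates on the
next, trains on the rest (label-rich); **T1V1E62** trains on the
pivot, validates on the next, evaluates on the rest (label-poor).
Clustering is transductive — fit once on all segments; only vote and
score roles change per pivot (a `refit` flag re-runs the sampler per
pivot for the alternative reading).  Majority vote runs over labeled
(train+validation) segments only; vote ties break alphabetically;
clusters with no labeled member are unmapped and their evaluation
segments fall back to 'other'.  This fallback is the measured
mechanism behind the label-poor scheme's degradation: clusters not
represented among two labeled folds predict 'other' for everything.
Scores: accuracy over evaluation segments, and macro-F1 averaged over
the activities present in the evaluation truth with the F1=0
convention for absent classes.  Both are invariant to cluster
relabeling.

## Problem sizes and known limitations

The test suite and acceptance script run at desk scale by design:
recovery at M=400 with K=20 over five seeds (~15 s), the multi-stream
comparison at M=360 over five seeds with four fits each (~25 s),
enumeration oracles at M ≤ 4, K ≤ 3, V ≤ 5.  The sampler is plain
NumPy; ~3 s per 50-sweep fit at the recovery scale, scaling linearly
in K, streams, tokens and sweeps.  Limitations: finite K (no
nonparametric prior — capacity is handled by leaving clusters empty),
no Markov dependence between consecutive segments, no hyperparameter
learning, and no modeling of out-of-vocabulary words at inference
time beyond dropping them.
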