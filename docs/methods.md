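# Methods

## The model

`vegsyntax` treats a vegetation plot as a *sentence*: its species listed in
descending cover-abundance order, lowercase, separated by commas
(`thinopyrum junceum, elymus farctus, pancratium maritimum`).  Species
with equal cover — frequent, because most field data come from ordinal
cover scales — are ordered randomly within the tied group, with a fresh
seeded permutation every training epoch.  Two tokenizations are
supported: **species** (one token per binomial) and **term** (separate
genus and epithet tokens).

A compact bidirectional transformer encoder is trained on these sentences
with the standard masked-token objective: per sentence, each content
token is selected independently with probability 0.15; a selected token
is replaced by `[MASK]` 80% of the time, by a random content token of the
same structural category 10% of the time (genus slots draw genera,
epithet slots draw epithets under the term scheme), and left unchanged
10% of the time; the model must recover the original token at every
selected position.  Commas, `[CLS]` and `[SEP]` are never selected.
Training runs for five epochs by default.

For habitat classification, a softmax head over the observed EUNIS
level-3 codes is attached to the pooled sequence representation and the
whole stack is trained (optionally warm-started from fill-mask weights).
EUNIS codes are hierarchical — broad group (one letter, or `MA2` for
littoral biogenic habitats), group (one more character), type (one more
again) — and group/broad accuracies are computed by projecting the top-1
prediction and the truth upward.

### Encoder implementation

The encoder is a from-scratch numpy implementation of the pre-norm
transformer block (multi-head self-attention, GELU feed-forward,
residuals, layer norm) with an explicit backward pass, Adam (lr 1e-3,
β = 0.9/0.999, global gradient-norm clip 1.0), and a weight-tied token
head.  Gradients are verified against finite differences in the test
suite.  Two deliberate departures from the textbook BERT recipe:

* **Sinusoidal (fixed) position encodings** instead of learned position
  embeddings.  A desk-scale model trained from random initialization must
  generalize to sentence lengths it has not seen — in particular the
  assemblage-completion operation appends mask slots past the training
  lengths — and fixed encodings give that for free.  The table is scaled
  by `pos_scale = 0.1`: unit-amplitude sinusoids are ~50× larger than the
  0.02-std token embeddings and drown the token signal, which empirically
  stalls training at the unigram distribution (held-out perplexity stuck
  near the vocabulary size); at 0.1 the same model learns contextual
  co-occurrence structure readily.
* **Mean pooling** over non-pad positions instead of single-slot `[CLS]`
  pooling for the classification head.  With a 2-layer encoder trained
  from scratch, `[CLS]` pooling must route all evidence through initially
  random attention and stalled on optimization plateaus on a substantial
  fraction of seeds; the masked mean feeds every position's state into
  the head from the first step and converged on every seed tried.

### End-of-assemblage training

Assemblage completion appends a `[MASK]` slot after the observed species
and accepts the argmax species not already present, stopping when `[SEP]`
outranks every candidate species.  Under the literal masking recipe
`[SEP]` is never a prediction target, so a model trained from random
initialization would never learn to emit it and the stopping rule could
not fire.  The collator therefore also masks the final `[SEP]` (label
`[SEP]`) on a configurable fraction of sentences (`sep_mask_prob`,
default 0.1).  The 15% / 80-10-10 procedure over content tokens is
unchanged.  Models fine-tuned from a large pretrained checkpoint can set
`sep_mask_prob = 0`.

## Curation

The filter chain for raw plot archives, in fixed order: drop zero-cover
records; merge within-plot layer duplicates by summing covers (sums may
exceed 100%); snapshot each plot's taxon set and most-abundant taxon;
standardize names against a user-supplied synonym table (genus-only and
unmatched names dropped, subspecies lumped into the parent binomial with
covers summed); drop hybrids and species present in fewer than 10 plots
(single pass, counts frozen before removal; a fixed-point mode is
config-exposed); drop plots that lost more than 25% of their snapshot
taxa or their most abundant taxon; demote habitat labels with fewer than
10 curated plots to unlabelled; split into fill-mask (unlabelled) and
classification (labelled) datasets.  Boundary semantics are strict:
exactly 10 occurrences survive, exactly 25% loss survives.  Rarity is
plot-level presence (layers are already merged).  Subspecies lumping does
not count as taxon loss, since the lumped binomial is still present.

## Spatial cross-validation

Plots are binned into 0.1° (6 arcmin) longitude/latitude cells; a
half-ulp snap guard makes representable multiples of 0.1 land
deterministically.  Whole cells are assigned to k folds by greedy
longest-processing-time: blocks in descending plot count, each to the
currently lightest fold.  This balances fold loads (max/min well within
10% on clustered 10⁴-plot data) while guaranteeing that near-duplicate
plots from one cell never straddle the train/test boundary.

## Baselines

*Naive Bayes on the co-occurrence matrix.*  `C[a,b]` counts plots
containing both species (presence–absence; covers ignored).  A candidate
s is scored against observed assemblage O as

    score(s) = log P(s) + Σ_{o∈O} log P(o | s),
    P(s) = N_s / Σ_t N_t,   P(o|s) = (C[o,s] + α) / (N_s + αV),

with additive smoothing α = 1 and V the species count.  Candidates
exclude observed species; ties break lexicographically.  The
implementation is vectorized and is checked in the tests against an
independent per-candidate loop.

*Masked-retrieval MLP.*  A one-hidden-layer perceptron (scikit-learn
`MLPClassifier`, SGD on log-loss) trained on incomplete assemblages: per
plot per epoch one random species is hidden and must be predicted from
the remaining presence vector.

Both baselines expose the same fill-mask predictor interface as the
encoder, so the rank-wise masking evaluation (mask the ten most abundant
species one by one on plots with more than ten species; score top-1
recovery per rank) runs unchanged across all three methods.

## Synthetic community generator

The generator emulates the statistics of aggregated vegetation-plot
archives that this pipeline is sensitive to, with one seed driving every
draw:

* habitat-specific species pools, disjoint unless a shared generalist
  pool is configured; heavy generalist weighting yields the long-tailed
  species-frequency distribution of real archives;
* plot richness ~ negative binomial (shape 6) around a configurable mean,
  default 19 species per plot;
* species drawn without replacement with probability proportional to
  occurrence weight (Gumbel top-k);
* covers following a geometric rank-abundance series (ratio 0.75 from a
  90% maximum), quantized to an ordinal midpoint grid
  {0.5, 3, 8, 18, 38, 63, 88} — producing the frequent cover ties of
  ordinal field scales;
* coordinates scattered normally (default σ = 0.25°) around per-habitat
  centres, giving the spatial clustering that makes block CV differ from
  random CV;
* an optional motif constraint: any sampled plot containing species A and
  C also contains B (a random non-motif member is swapped out), creating
  a co-occurrence rule invisible to marginal pair counts.

Two staged scenarios are provided.  `make_motif_model` places the motif
pair as moderately frequent cross-habitat species, the partner B as a
species frequent in its home habitat but outside the global frequency
top three, and one strong generalist that is the globally most frequent
species; mean richness is 5, so three-species assemblages (where the
constraint makes the third species deterministic given the pair) are
common, and at 2 500 plots the triple co-occurs well over 100 times.
Under these conditions the trained encoder ranks B in its top 3 for the
context "A, [MASK], C" (with the two observed species excluded from the
candidates, as in the baselines), while naive Bayes — seeing only pair
counts — returns the generalist.  `make_model(dominant_marker=True,
shared_pool=True)` gives every habitat a dedicated always-present
dominant over one shared subdominant pool, so habitat identity is
carried solely by the dominant: removing the first-ranked species
collapses classification to chance while removing the last-ranked one
leaves it intact.

What the generator does **not** emulate: real taxonomic name structure
(names are coined pronounceable binomials), environmental gradients,
dispersal or competition dynamics, observer effort biases, and the
227-type EUNIS label inventory (synthetic codes are valid level-3 codes
over the eight broad groups).  Passing tests therefore demonstrate that
the machinery recovers planted structure at desk scale, not that it
attains any particular accuracy on real archives.

## Problem sizes and numerics

The shipped experiments run on one CPU: habitat classification on a
4-habitat / 200-species / 20 000-plot disjoint-pool corpus (2 encoder
layers, width 64, 4 heads, 5 epochs); motif recovery over 10 generator
seeds at 2 500 plots each (width 64, 20 epochs — from-scratch training
first fits the unigram and rank-position structure and acquires
contextual co-occurrence rules only later, so the small motif corpora
get a longer schedule; context use is verified by the partner species
ranking high in the motif context but far down given an unrelated
context); the dominant-species ablation at 4 000 plots.  Fill-mask
candidate rankings can exclude the query's visible species
(`exclude_observed`), matching the candidate policy of the baselines.  All computation is float32; perplexity and cross-entropy
reductions are float64.  Token ids are dense with specials first;
vocabulary order is lexicographic, so identical corpora give identical
models.  Degenerate inputs are explicit errors: empty plots, empty
corpora, one-class classification, masks absent from a fill-mask query,
sequences beyond `max_len` (default 256, comfortably above the ~40-token
sentences of 19-species plots).

## Known limitations

* Training the encoder on corpora orders of magnitude beyond ~10⁵ plots
  is out of scope for the numpy backend.
* The term scheme's assemblage completion is greedy (genus argmax, then
  epithet), not a joint search over binomials.
* The naive Bayes construction adopts the canonical decomposition from
  the co-occurrence matrix with exposed smoothing α; other smoothing
  conventions would shift scores but not the qualitative behaviour.
* `merge_duplicate_layers` discards layer identity; layer-aware sentences
  are future work.
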