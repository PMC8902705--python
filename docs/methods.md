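# Methods

## Model overview

`impaesim` treats disease similarity as proximity in a learned embedding of
three disease-centric association networks.  The method assumes that
diseases sharing molecular machinery — associated genes, lncRNA targets,
miRNA targets — occupy nearby positions in each network's diffusion
geometry, and that agreement across networks is more trustworthy than any
single network.  Three mechanisms encode this: random-walk-with-restart
(RWR) diffusion turns local edges into global per-disease proximity
profiles; per-network autoencoders compress those profiles; and link
constraints mined from per-network correlations couple the networks when a
final autoencoder re-embeds the concatenated codes.

## Networks and the derived ncRNA tables

Inputs are bipartite edge lists.  Curated disease–lncRNA and disease–miRNA
tables are rare, so by default they are derived by composing the
disease–gene table with gene–ncRNA tables: disease `d` links to ncRNA `r`
iff they share at least one gene, weighted by the shared-gene count.  This
is a modelling choice, not a data fact — users with curated disease–ncRNA
files can pass `ncrna_derivation="direct-file"` to use them verbatim.
Node indices are sorted lexicographically, which fixes matrix row order and
makes every downstream artifact deterministic.  Diseases missing from any
network are dropped (logged with counts): the final embedding concatenates
per-network codes row-wise, so each disease needs a row in all three.

## Diffusion

The walk runs on the full bipartite graph (diseases plus partner nodes)
with transition matrix `B` = row-normalized adjacency, iterating
`p ← (1−u_r) Bᵀ p + u_r e_i` from `p⁰ = e_i` to an L1 tolerance.  Note the
transpose: propagating a distribution through a row-stochastic matrix
requires `Bᵀ`, otherwise mass is not conserved.  Parameters: restart
probability `u_r = 0.5` (a neutral balance between local and global
structure; the stationary vector exists for any `u_r` in (0, 1]), L1
tolerance `1e−6`, at most 100 iterations (the contraction factor is
`1 − u_r`, so 100 is generous at the default).  Stationary vectors are
restricted to the shared diseases and renormalized to sum 1.

**Self-mass exclusion.**  The restart term concentrates most of the
restricted mass on the source disease itself (empirically ~78% at
`u_r = 0.5` on the synthetic data).  That coordinate encodes identity, not
relatedness, and when kept it dominates reconstruction: the autoencoder
bottleneck spends its capacity memorizing which disease each row is,
and embedded similarity collapses to noise (planted-community AUROC ~0.52).
The pipeline therefore zeroes the profile diagonal and renormalizes before
feature learning (`exclude_self=True` by default; the raw restricted
profile remains available by switching it off).  With exclusion the same
configuration reaches AUROC ~0.99.

## Autoencoders

Both stages use exactly one sigmoid hidden layer — `h = σ(Wx + b)`,
`y = σ(W′h + d)` — trained by full-batch Adam (β₁ = 0.9, β₂ = 0.999,
ε = 1e−8) on the summed squared reconstruction error, with Glorot-uniform
weights drawn from a seeded generator and zero biases.  Gradients are
analytic backprop, verified against central finite differences.  Defaults:
learning rate 1e−3, 200 epochs, classic hidden width 128 (shrunk to
`n//4` when the input has fewer than 128 columns), final width 64 (shrunk
to half the concatenated width when that is smaller, e.g. 22 for the
3 × 15-dimensional codes of the default synthetic scale).

The constrained stage adds
`γ (γ₁ Σ_P ‖hᵢ−hⱼ‖² − γ₂ Σ_N min(‖hᵢ−hⱼ‖², m))` to the loss.  Two
numerical choices matter:

- **Margin cap.**  The raw reward term is unbounded below; capping each
  negative pair's squared distance at `m = 1` (configurable, `inf`
  recovers the raw objective) zeroes the repulsion gradient once a pair is
  far enough and keeps the loss bounded.  Within the cap the objective is
  exactly the raw form.
- **Commensurate strengths.**  The reconstruction term sums O(1) errors
  over every coordinate of every disease (≈40 at the default scale),
  while the constraint sums cover a few dozen pairs whose hidden codes the
  reconstruction dynamics drive to near-coincidence (squared distances
  1e−5–1e−3).  With unit-scale weights the constraint gradient is
  numerically invisible.  Defaults are therefore `γ = 1000`, `γ₁ = 100`,
  `γ₂ = 1`: the extra factor on the penalty compensates for the attraction
  force vanishing linearly as positive pairs approach coincidence, whereas
  repulsion keeps acting until the cap binds.  Under these defaults the
  positive-pair mean distance halves and the negative-pair mean distance
  roughly triples relative to a `γ = 0` control (five synthetic cohorts).

With `γ = 0` the constrained trainer takes the identical code path as the
classic trainer, so the reduction is bit-for-bit, not merely approximate.
A non-finite loss aborts with the epoch number; when negative constraints
are present the error suggests reducing `γ₂` or the margin.

## Constraints

Per network, pairwise similarity is the Pearson correlation of the hidden
vectors (`constraint_source="rwr"` correlates raw diffusion profiles
instead).  Zero-variance vectors correlate 0 by convention, with a warning.
Thresholds default to empirical quantiles of the off-diagonal correlation
distribution — positive links above the 99.5th percentile, negative links
below the 0.5th — so set sizes track the data scale; absolute cutoffs are
available.  Pairs are stored as lexicographically sorted tuples, so
constraint sets are invariant to input ordering.  Merging defaults to
`union_drop_conflicts` (pool each polarity, drop pairs claimed by both),
because a strict three-way intersection of small per-network sets is
typically empty; strict intersection is retained as an option.  Under the
default quantiles each per-network set holds ~1% of all pairs and the
merged set ~3% (three nearly disjoint networks).

## Similarity

Cosine similarity of the final hidden vectors, with zero-vector embeddings
scoring 0 (warned) rather than NaN.  Optional normalization min–max
rescales the off-diagonal scores into [0, 1] and pins the diagonal at 1; a
degenerate constant off-diagonal maps to all zeros with a warning.  Top-k
queries break ties lexicographically for determinism.

## Synthetic data

The generator plants `n_communities` disease communities: diseases, genes,
lncRNAs and miRNAs are partitioned into blocks (sizes as equal as integer
division allows, remainders to the first blocks), and a disease (or ncRNA)
links to a gene of its own block with `p_within` and to a foreign gene with
`p_between`; every disease and ncRNA is guaranteed one within-community
edge so no planted node is dropped as isolated.  Defaults — 60 diseases,
150 genes, 12 lncRNAs, 40 miRNAs, 3 communities, `p_within = 0.3`,
`p_between = 0.02` — give dense-enough communities for stable diffusion
while keeping a full pipeline run under a second, which is also the
problem size the verification scripts use.  The generator emulates the
block structure real disease modules induce, but not real data's
heavy-tailed degree distributions, hub genes, annotation noise or
inter-community overlap; recovery of planted communities therefore shows
the machinery is sound, not that the defaults are tuned for any particular
real corpus.

## Known limitations

- The walk always runs on the bipartite graph; a projected
  disease–disease variant is not implemented.
- Only Pearson correlation is offered for constraint mining, and only
  cosine for final scoring.
- The two autoencoders are single-hidden-layer by design; no deep,
  denoising or variational variants.
- Whether real curated corpora are best served by the default γ weights is
  untested here; they were chosen for scale-commensurability of the loss
  terms, and are exposed in the configuration.
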