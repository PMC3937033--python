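# Methods

## Overview

The pipeline extracts a core sub-network from a weighted, undirected PPI
network in four stages: correlation-based link weighting, global-null link
significance, connectivity-constrained filtering, and downstream
robustness/enrichment analysis. All stages are exercised on synthetic
scenarios with planted structure; this note records the models, the
parameter choices, and the limits of what the synthetic results show.

## Link weighting

For genes x, y with n pairwise-complete samples the weight is
`w = |r̄|` with `r̄ = (1/n) Σ r₍₋ᵢ₎`, the plain mean of the leave-one-out
Pearson coefficients (not the bias-corrected `n·r − (n−1)·r̄` form). The
jackknife mean damps the influence of single outlying samples, which
matters when expression series from heterogeneous experiments are merged.
Requirements and conventions:

- at least 4 pairwise-complete samples (each leave-one-out subset needs 3);
- a leave-one-out subset with zero variance makes the pair undefined; such
  links are dropped and counted;
- "expressed" means non-missing; genes observed in < 80% of samples are
  removed before weighting (`min_fraction = 0.8`, boundary inclusive);
- missing values are handled pairwise-complete per gene pair, the rule that
  maximizes usable samples;
- weights are scaled ×100 (`scale = 100`), putting them on a 0–100 range
  where a unit histogram bin is a natural discretization;
- zero-weight links are retained: filtering is by significance, not weight.

## Global-null link significance

The null model fixes the topology and draws every link weight
independently from the empirical weight distribution `P(w)`, discretized
at `bin_width = 1` on the ×100 scale (each weight mapped to the nearest
bin center). Significance of link `e = (i, j)` is the upper tail of the
weight conditional on both endpoint strengths:

    p(w | s_i, s_j) ∝ P(w) · Q_{k_i−1}(s_i − w) · Q_{k_j−1}(s_j − w)
    p_e = Σ_{w ≥ w_e} p(w | s_i, s_j)

with `Q_m` the m-fold self-convolution of `P` (`Q_0` = point mass at 0).
The two stars of a link are edge-disjoint apart from the link itself, so
under the i.i.d. null the factorization is exact, and on the discrete
support the computation is exact too — the test suite checks it against an
exhaustive enumeration oracle to 1e-9 and a Monte-Carlo oracle to three
standard errors.

Numerical choices:

- convolutions are built iteratively with renormalization per step to
  control drift (~1e-12 over the degrees encountered);
- strengths are matched at bin resolution by discretizing each link weight
  first and summing bin indices, so the observed configuration always has
  positive null mass; a nearest-reachable-strength fallback exists but is
  a defensive path, and such links are flagged;
- degenerate conditioning is a property of the model, not a bug: a
  degree-1 endpoint pins the link weight completely (p = 1), so leaf links
  are always removed first; more generally, a link that constitutes most
  of both endpoint strengths is conditionally unsurprising and receives a
  moderate p-value even when its absolute weight is extreme. This matters
  for interpreting planted-backbone results (below).

## Connectivity-constrained filtering

Links are removed in strictly descending p-value order (p-values computed
once, before filtering starts). Ties are broken by ascending weight, then
lexicographic link identity, making runs exactly reproducible. After each
removal every anchor constraint is checked: at least one path must join
the receptor-complex-like anchor set to each downstream anchor set. The
first violating removal is undone and the run stops ("stop semantics":
one violation ends the whole run; a sequential per-constraint mode exists
for comparison but the joint mode is the default). The input network must
satisfy all constraints, otherwise the configuration is rejected.

After every accepted removal the pipeline records: fraction of links
removed, fraction of isolated nodes, diameter (longest shortest path
*within the largest connected component* — the all-pairs definition is
infinite once the network fragments), relative giant size `n_rel = n/N`,
and the mean size of non-giant components `⟨s⟩`, singletons included
(link removal produces them naturally). Both removal fractions are
reported rather than choosing one x-axis.

## Robustness analysis (LWRN)

`round(f·L)` links are selected uniformly and their weights are permuted
among themselves, which conserves the global weight multiset the null
model depends on (a resample-with-replacement mode exists behind a flag).
Significance and filtering are re-run per copy and six statistics compare
the filtered copy with the reference core: mean degree, mean path length
over connected pairs, mean node and link betweenness, mean local
clustering (degree < 2 counts as 0), and the link intersection with the
reference (count and fraction — both, since either normalization is
defensible). Statistics are computed on the subgraph of non-isolated
nodes. Betweenness and path lengths are unweighted (hop count): the
weights are similarity scores, not distances. Per-iteration generators
derive from the master seed and the (fraction, iteration) index, so the
experiment is reproducible and order-independent. Defaults are fractions
0.1–0.9 with 30 iterations.

## Enrichment

One-sided (over-representation) hypergeometric test, identical to the
one-sided Fisher exact test; Benjamini–Hochberg step-up correction across
collections (delegated to statsmodels). The lethality filter keeps genes
whose phenotype contains "lethality" (case-insensitive substring) with an
annotation type containing neither "partial" nor "wean". The universe
defaults to the annotated genes of the weighted network and is
configurable, since the appropriate background (network vs genome-wide)
depends on the question.

## Synthetic scenarios

The generator emulates the statistical structure the pipeline assumes:

- **Network**: preferential-attachment wiring (heavy-tailed degrees, as in
  real interactomes) over all genes, plus a planted path joining one
  representative of each of three anchor sets; link count adjusted exactly,
  backbone links never removed. Default 200 genes / 800 links; planted
  scale 300 genes / 1500 links with a 20-link backbone.
- **Expression**: multivariate normal with block correlation `ρ_in` inside
  planted modules (defaults 0.8/0.6/0.4, 25–30 genes each), background
  `ρ_out = 0.05`, and a first-order autoregressive chain along the
  backbone path (`ρ_bb^d` at path distance d, `ρ_bb = 0.9`). The chain —
  rather than one high-ρ block over all backbone genes — is deliberate: a
  block makes *every* network link between backbone genes near-maximal
  weight and inflates backbone strengths, and under the strength-
  conditioned null those links are not significant; the chain plants a
  heavy *path*, which is the intended structure. Missingness is completely
  at random (default rate 0.1); sample sizes 60 (default) / 100 (planted).
- **Annotations**: Bernoulli essential labels, probability 0.8 on backbone
  genes vs 0.2 elsewhere — a strong planted enrichment detectable by an
  exact test at these set sizes.

One integer seed drives all generators through independent spawned
streams, so whole scenarios are bit-reproducible.

What the synthetic results do **not** show: the generator has no probe
effects, batch structure, platform mixtures, or correlated missingness,
and its degree sequence only qualitatively resembles a curated
interactome. Passing tests demonstrate the pipeline's internal
correctness and its behavior on planted structure, not performance on
real expression compendia.

### A note on backbone recovery

At planted scale the backbone *path* links are retained at 2–3× the
overall retention rate, but their link-level hypergeometric enrichment is
weak (p ≈ 0.01–0.15 across seeds). This is a real property of
strength-conditioned significance: an extreme-weight link whose endpoints
have little other strength is exactly the configuration the conditioning
explains away (in the limit, a leaf link has p = 1). The filter's
multiscale behavior — retaining sub-median-weight links that a
weight threshold at the same size would discard — is robust and is the
property the method is designed for.

## Problem sizes

Default test and acceptance runs use the scales above (≤ 300 genes,
≤ 1500 links, LWRN reduced to ≤ 3 fractions × ≤ 5 iterations where the
full 9 × 30 grid adds nothing to the property under test); the full-size
robustness grid runs from `analysis/06_robustness_lwrn.py` or
`tppin robustness` with the defaults.
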