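# Methods

`seepnet` reimplements, as a tested library, a cross-domain (bacteria –
archaea – fungi) co-occurrence analysis workflow for cold seep sediment
amplicon data: compositional preprocessing, sparse signed network inference
with stability selection, random-attack robustness and information-transfer
efficiency, keystone/core extraction by centrality percentiles, and
cross-validated balance selection of taxa against a discretized methane
response. Because the original amplicon deposit cannot ship with the
package, a synthetic community generator provides every input with known
ground truth, so each stage can be validated by recovery rate rather than
by eyeballing.

## Synthetic community model

Counts are drawn from a logistic-normal-multinomial with independent zero
inflation:

1. a sparse symmetric positive-definite precision matrix Ω (p × p) is drawn
   by sampling off-diagonal support uniformly at a target edge density,
   giving entries uniform magnitudes in [0.25, 0.5] with random signs, and
   inflating the unit diagonal until the minimum eigenvalue reaches a floor
   (0.1 by default). The off-diagonal support of Ω is the ground-truth edge
   set;
2. latent abundances per sample are N(0, Ω⁻¹); a softmax maps them to a
   composition;
3. library depth is log-normal around `depth_mean` (default 20,000 reads)
   with coefficient of variation 0.3, mimicking uneven library sizes so the
   stability subsampling faces heterogeneous depths; counts are multinomial
   at that depth;
4. each count is then zeroed independently with probability
   `zero_inflation` (sampling zeros only; structural zeros are deliberately
   not modeled so the truth stays recoverable).

Domains are apportioned by configurable fractions (default 60% bacteria,
20% archaea, 20% fungi, echoing the roughly 4:1 prokaryote:fungus ratio of
filtered seep tables); fungi carry the 18S marker, prokaryotes 16S.

What the generator does **not** emulate: taxon-specific mean abundances
(all latent means are zero), overdispersion beyond the logistic-normal,
structural absences, chimeras or any read-level artifact. Passing recovery
tests therefore demonstrate correctness of the estimators under the model
the inference method assumes, not performance on raw field data.

Depth-profile metadata places a Gaussian methane bump centred in the
sulfate–methane transition zone (SMTZ, default 10–13 cm below sea floor),
monotonically decreasing sulfate, and a sulfide maximum near the SMTZ; all
noise is seeded log-normal. `plant_balance_signal` multiplies the numerator
group's counts by `exp(effect_size)` in "high" samples and the denominator
group's counts in "low" samples, giving a known log-ratio shift for the
balance screen to find.

## Preprocessing

*Filtering.* A taxon is kept when present in ≥ 30% of samples **and** its
mean (across samples) relative abundance is ≥ 1e-4. "Mean" is the stricter
of the two natural readings of an abundance floor; `abundance_stat="max"`
gives the permissive one. The pipeline applies the filter within each
marker block, since 16S and 18S libraries are sequenced and closed
separately.

*CLR.* Counts are transformed per marker block as
`ln(x + pseudocount) − mean over the block's taxa` with pseudocount 1
(the default of penalized compositional inference tools). Each block row
sums to zero; closure induces a −1/(p−1) correlation between block members,
which is negligible for realistic block sizes but dominates blocks of only
a few taxa — the reason estimator null tests use single-marker communities.

*Methane discretization.* Default rule (`by_depth`): a sample is "high"
iff its depth slice overlaps the SMTZ interval with positive measure.
`by_concentration` instead compares each sample's methane to its site's
surface-slice mean. The SMTZ default is [10, 13] cm; [10, 12] appears in
some descriptions of the same zone and is available via configuration.

## Network inference

The estimator is penalized neighborhood selection: each taxon's
standardized CLR profile is lasso-regressed on all others along a 20-point
log-spaced path from λ_max (the largest absolute empirical correlation)
down to 0.005·λ_max. Neighborhood selection was chosen over the graphical
lasso because edge signs map directly from regression coefficients and the
per-node fits are fast and separable.

*StARS.* Twenty subsamples (without replacement, size ⌊10√n⌋, falling back
to 0.8·n when 10√n ≥ n) refit the path; an edge's selection frequency f
per λ gives the instability D(λ) = mean over pairs of 2f(1−f). D is
monotonized from the sparse end and the smallest λ with D ≤ 0.05 is
selected — the densest graph that is still reproducible under subsampling.
Per-subsample seeds derive deterministically from the master seed.

*Latent adjustment.* Sequencing depth and environmental gradients induce
dense apparent covariance. For candidate ranks r = 0..r_max the top-r
principal components are removed from the column-centered CLR matrix, a
stability-selected network is created on the adjusted matrix, and that
selected model is scored by extended BIC: Gaussian pseudo-likelihood
Σ_j n·log(RSS_j/n) with residuals on the original data scale, plus
|E|·(log n + 4γ·log p) for the graph (γ = 0.5) and r·(n+p−r)·log n for the
rank-r component. Scoring the *selected* model rather than the best point
of the whole path is essential: removing r ≥ 1 components makes the p
columns exactly collinear, so the unpenalized dense-end pseudo-likelihood
is unbounded and would always prefer larger ranks. On planted one-factor
data this procedure picks r = 1 and roughly triples edge-recovery F1; on
factor-free data it picks r = 0. The adjustment is off by default
(`latent_rank_max = 0`) and surfaced in provenance when used.

*Finalization.* The neighborhood lasso is refit on the full (adjusted)
data at the selected λ. The two directed coefficients of a pair are
symmetrized by keeping the larger magnitude (ties toward the
lexicographically smaller source taxon); the kept coefficient is the
signed edge weight ("pseudocorrelation" — only its sign and relative
magnitude are consumed downstream). Isolated nodes are dropped; the
provenance records input and connected taxon counts, the selected λ and
the latent rank. The five domain variants (BAF, BA, BF, B, F) are each
tuned independently.

## Topology

Degree and betweenness are computed on the unweighted topology: no
principled mapping from signed pseudocorrelations to distances exists, so
weights enter only through the mean absolute incident weight. Betweenness
is unnormalized shortest-path betweenness (each unordered pair contributes
its fraction of shortest paths through the node).

Keystone taxa are nodes at or above the 80th percentile
(linear-interpolation quantile) of **both** degree and betweenness; ties at
the threshold are included, so an all-tied network degenerately selects
every node. The core network keeps nodes in the top half of both metrics,
takes the induced subgraph, removes nodes with fewer than three edges in
that subgraph (one pass), and drops whatever that pass isolated — the
order is fixed and documented because the two filters do not commute.

Between-domain contrasts use the two-sample Mann–Whitney U test: the
domain groups are unpaired, so a signed-rank test is not applicable
despite being the conventional label for this comparison. Each report also
gives the domains' shares of the pooled top-20% of the metric, using a
pooled (not per-domain) percentile.

## Random attack and efficiency

For a network of N nodes, one attack iteration removes all nodes in a
uniformly random order; σ(i) is the largest-component size after i
removals relative to the **initial** N, with σ(N) ≡ 0 (the formula's final
term is otherwise undefined; this convention makes the complete-graph
value exact). Robustness R is the mean of σ(1..N) and vulnerability
V = 0.5 − R, so 1/(2N) ≤ V ≤ 0.5 − (N−1)/N² with the complete and edgeless
graphs attaining the bounds. Each iteration is computed in O(N + E) by
adding nodes in reverse order under a union-find. Default 10,000
iterations per network.

Nodal efficiency is Latora–Marchiori: E(i) = mean over j ≠ i of 1/d(i, j)
on unweighted shortest paths, with unreachable pairs contributing zero.

Between-network comparisons use Welch's unequal-variance t-test on the
per-iteration V samples (or per-node efficiencies). At 10,000 iterations
any real difference yields an astronomically small p-value; the reported
percent change in means is the interpretable effect size, and exact-V
networks (zero variance) short-circuit to p ∈ {0, 1} with a degeneracy
flag.

## Balance selection

A balance between disjoint taxon groups of sizes p and q is
`sqrt(pq/(p+q)) · (mean log numerator − mean log denominator)` on
pseudocount-replaced counts (pseudocount 1; Bayesian-multiplicative zero
replacement is not reimplemented). The balance value itself is the
classifier — a threshold-free ranking score — so candidate models are
scored by Mann–Whitney AUC with no inner model fit.

Per cross-validation step (stratified 5-fold, repeated; 100 repeats by
default, 2,000 via configuration for the full 10,000 validation steps),
the forward search finds the best single pair exhaustively, then greedily
adds one taxon to either side while the training AUC improves, recording
the nested sequence up to 8 taxa. Because a parameter-free score gains
nothing from inner refitting, overfitting is controlled at the *size*
level instead: the working balance size is the one maximizing mean
held-out AUC across all steps, and appearance frequencies are counted at
that size. This mirrors how balance-selection tools pick the optimal
number of components by cross-validation, and it is what makes decoy taxa
vanish from the frequency table while a single fixed spurious pair would
otherwise persist across every split of the same data.

Two frequencies are reported per taxon: appearance on the side elevated in
"high" samples (the signature screen's statistic; "high-methane-signature"
taxa are those reaching 30%) and appearance on either side (the bar-chart
statistic). The permutation null re-permutes labels for every repeat; a
single fixed permutation is not a null for appearance frequencies, because
every CV split of the same data rediscovers the same spurious pair.

## Problem sizes and numerical choices

Default experiment sizes — 40 taxa / 400 samples for edge recovery (10
seeds), 30 taxa / 200 samples for the balance screen, 60 taxa / 130
samples for the end-to-end pipeline — are chosen so each validation
experiment represents its estimator's intended regime (n comfortably above
p, study-scale sample counts) while a full run of every experiment
completes on a single CPU in a few minutes. Tolerances: exact closed
forms are asserted to 1e-12; Monte-Carlo means to three standard errors;
CLR row sums to 1e-9 per block. Degenerate inputs (constant CLR columns,
single-class responses, empty filter results, sub-three-node networks) are
rejected with explicit errors rather than propagated.

## Known limitations

- Edge weights are symmetrized lasso coefficients, not rescaled partial
  correlations; magnitudes are comparable within a network, not across
  networks.
- The latent adjustment removes principal components; it approximates, but
  is not, a joint sparse-plus-low-rank decomposition.
- The generator's compositions are exchangeable across taxa apart from the
  dependence structure; abundance-skew-dependent behavior (e.g. filter
  interplay with rare-taxon zero inflation) is only lightly exercised.
- Betweenness on the unweighted topology ignores association strength;
  two networks with identical topology but different weights have
  identical keystones.
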