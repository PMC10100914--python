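# seepnet

Cross-domain co-occurrence network analysis for cold seep sediment
microbiomes.

Cold seeps are deep-sea sediments fueled by methane, where
chemolithoautotrophic bacteria and archaea — and, as is increasingly
recognized, fungi — form tightly coupled communities around the
sulfate–methane transition zone (SMTZ). `seepnet` provides a reusable,
tested pipeline for asking how the fungal fraction shapes such communities
from joint 16S (prokaryotic) and 18S (fungal) amplicon count tables:

- **compositional preprocessing** — prevalence/abundance filtering,
  per-marker centered log-ratio (CLR) transform, domain subsetting into the
  bacteria+archaea+fungi (BAF), BA, BF, bacteria-only and fungi-only
  network variants, and discretization of the methane depth profile into a
  binary high/low response;
- **sparse signed network inference** — penalized neighborhood selection
  with StARS stability selection (nλ = 20, λ_min ratio 0.005, instability
  threshold 0.05, 20 subsamples) and an optional low-rank latent-variable
  adjustment chosen by extended BIC;
- **perturbation analysis** — random-attack robustness
  R = (1/N) Σᵢ σ(i/N) and vulnerability V = 0.5 − R over bootstrap removal
  orders, Latora–Marchiori nodal efficiency, and Welch comparisons between
  network variants;
- **topology** — degree/betweenness centralities, keystone taxa (top 20th
  percentile of both), core-network extraction, and between-domain rank
  tests;
- **balance selection** — repeated cross-validated greedy search for the
  log-contrast balance of taxa that separates high- from low-methane
  samples, with per-taxon appearance frequencies and a 30% signature
  threshold;
- **a synthetic community generator** — zero-inflated
  logistic-normal-multinomial counts from a known sparse precision matrix,
  SMTZ-shaped depth profiles and planted taxon–response signals, so every
  stage is validated by recovery against ground truth.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

```python
import seepnet as sp

# ground-truth community: 40 taxa, 5% of pairs conditionally dependent
truth = sp.make_true_model(p=40, edge_density=0.05, seed=1)
counts = sp.simulate_counts(truth, n_samples=400, seed=101)

# CLR-transform and infer the interaction network
clr = sp.clr_transform(counts)
net = sp.infer_network(clr, sp.NetInferParams(seed=201))
print(f"inferred {net.n_edges} edges over {net.n_nodes} connected taxa "
      f"(lambda = {net.provenance['selected_lambda']:.3f})")

# how much of the planted structure was recovered?
pred = {frozenset(e) for e in net.graph.edges}
tp = len(pred & truth.true_edges)
print(f"precision = {tp / len(pred):.2f}, recall = {tp / len(truth.true_edges):.2f} "
      f"against {len(truth.true_edges)} true edges")

# random-attack vulnerability and information-transfer efficiency
attack = sp.attack_robustness(net, n_iter=10_000, seed=7)
print(f"vulnerability V = {attack.V_mean:.3f} (sd {attack.V_sd:.3f})")
eff = sp.nodal_efficiency(net)
print(f"mean nodal efficiency = {eff.mean:.3f}")

# keystone taxa: top 20th percentile of both degree and betweenness
table = sp.compute_centralities(net)
keystones = sp.keystone_nodes(table, percentile=0.80)
print(f"{len(keystones.keystone_ids)} keystone taxa")
```

Output:

```
inferred 50 edges over 35 connected taxa (lambda = 0.183)
precision = 0.68, recall = 0.97 against 35 true edges
vulnerability V = 0.151 (sd 0.042)
mean nodal efficiency = 0.356
6 keystone taxa
```

The inference recovers essentially all of the planted dependence structure
(recall 0.97) with a modest number of false edges at the stability-selected
penalty. V = 0.151 sits between the complete-graph minimum 1/(2N) ≈ 0.014
and the edgeless maximum ≈ 0.472 for N = 35: the network fragments
gradually, not catastrophically, under random taxon removal. Keystones are
the hubs whose loss would fragment it fastest.

The same stages are available from the shell:

```bash
seepnet simulate --seed 3 --out bundle/
seepnet infer --bundle bundle/ --domains BAF --out baf.graphml
seepnet attack --network baf.graphml --iterations 10000 --seed 1 --out attack.json
seepnet all --seed 3 --out report/        # full pipeline into a report dir
```

Input bundles are plain tab-separated tables (`counts.tsv` with samples as
rows and taxa as columns, `taxonomy.tsv` with per-taxon domain/marker/
lineage, `metadata.tsv` with site, depth interval and porewater
chemistry); networks are written as GraphML, TSV edge lists or JSON with a
provenance sidecar.

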