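# mirmod

Inference of **MRE-mediated miRNA–miRNA modulation networks** from paired
expression data, with bias-control comparators, hub analysis, and
diagnostic/prognostic signature evaluation.

## The problem

miRNAs repress mRNAs by binding response elements (MREs) in their 3′UTRs —
but the traffic runs both ways: an abundant transcript carrying MREs for
several miRNAs acts as a sponge, sequestering them jointly and thereby
*coupling* their free levels (the ceRNA hypothesis). Two miRNAs that share
a target and whose co-expression depends on that target's level are
plausibly co-regulated through it. `mirmod` turns that idea into a tested
statistical pipeline for anyone with a miRNA matrix, an mRNA matrix over
the same samples, and a miRNA→target table (e.g. TargetScan predictions or
a validated-interaction database).

## The statistic

For a miRNA pair (d, r) and candidate modulator transcript m:

```
ΔMI_{d,r|m} = | MI(d, r) − MI(d, r | m) |
```

* MI is plug-in mutual information (nats) on equal-frequency bins
  (B = 3 by default) — rank-based, so invariant to monotone normalization.
* MI(d, r | m) averages within-stratum MI over S = 2 equal-frequency
  strata of m (the high/low sponge dichotomy), weighted by stratum size.
* Significance: permute m (n_perm = 1000), p = (1 + #{ΔMI_perm ≥
  ΔMI_obs}) / (n_perm + 1) — never exactly zero.
* Per unordered miRNA pair, p-values over all mediating targets are pooled
  by Fisher's method, X² = −2 Σ ln p_k ~ χ²(2N); pairs with combined
  p < α (default α = e⁻⁵ ≈ 6.74×10⁻³) become edges of an undirected
  miRNA–miRNA network.

Companion analyses: degree/hub reports; a **shared-target comparator**
(hypergeometric overlap of target sets — built from the target table
alone) and a **correlation comparator** (Spearman + BH), which together
check that hubs are not artifacts of target-count or plain co-expression;
SVM classification of a signature against a random-signature null;
PCA/clustering views; k-means risk groups with Kaplan–Meier, log-rank and
Cox analyses; fold-change differential expression with permutation p and
BH q. A seeded synthetic-cohort generator with planted modulation
structure backs every stage with ground truth.

## Worked example

Generate a 139-sample cohort with 10 planted modulation triplets (a
6-triplet hub plus 4 independent pairs, stratum couplings 0.9 vs 0.0) and
50 planted-null triplets, then infer the network:

```python
import mirmod as mm

cfg = mm.SimulationConfig(n_mirnas=40, n_mrnas=80, n_decoy_edges=40,
                          noise_sd=0.0, class_effect=0.0, risk_effect=0.0,
                          seed=0)
mir, mrna, targets, meta, planted = mm.simulate_dataset(cfg)
net = mm.infer_network(mir, mrna, targets, n_perm=1000, seed=0)
print(f"network: {len(net.nodes)} miRNAs, {net.n_edges} edges")
print("top hubs:", mm.hub_report(net, k=3).top[:3])
```

prints (about two minutes on one core):

```
network: 17 miRNAs, 12 edges
top hubs: [('miR-001', 6), ('miR-006', 2), ('miR-010', 2)]
```

All 10 planted pairs are recovered, none of the 50 planted-null triplets
produces an edge, and the planted hub miR-001 tops the degree ranking with
its 6 partners. A typical edge record shows the evidence trail — for
miR-001–miR-002: X² = 13.82 with 2 degrees of freedom (one mediating
target, GENE-0001), combined p = 9.99×10⁻⁴, i.e. the observed ΔMI beat
all 1000 permutations of the modulator.

The same run from the shell, plus the comparator and signature stages:

```bash
mirmod simulate --config cfg.json --out sim/
mirmod infer --mir sim/mir.tsv --mrna sim/mrna.tsv --targets sim/targets.tsv \
             --n-perm 1000 --seed 0 --out net/
mirmod compare --net-a net/network.graphml --net-b other/network.graphml
mirmod evaluate --expr sim/mir.tsv --meta sim/metadata.tsv \
                --signature sig.txt --log-scale --out eval/
```

`infer` writes `triplets.tsv` (per-triplet MI, conditional MI, ΔMI, p),
`pairs.tsv` (X², dof, combined p, mediating targets), and the network as
Cytoscape-readable `network.sif` and `network.graphml`. Subset reruns
(e.g. primary-tumor samples only) use `--meta ... --sample-class primary`.
Every command takes `--seed`; a repeated run is byte-identical.

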