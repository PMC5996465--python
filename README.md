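# cdrenet

Bipartite miR–gene network inference and **Commodore-miR** analysis.

MicroRNAs (miRs) repress the mRNAs of their target genes, and the joint
pattern of who-regulates-whom is naturally a *bipartite network*: one node
layer of miRs, one of genes, edges only between layers. `cdrenet` is a
pipeline for asking, given paired miR and gene expression matrices from two
conditions (e.g. healthy vs tumor tissue), **which miRs are highly
connected yet nonredundant regulators** — miRs whose removal would strand a
dedicated block of genes that no other miR co-regulates. We call these
*Commodore miRs* (Cdre-miRs). Such miRs are candidate master regulators of
the biological processes their gene neighborhoods carry, and candidate
intervention points.

The pipeline, stage by stage:

1. **Network inference.** For every miR–gene pair, mutual information (MI)
   between the two expression profiles is estimated with an
   equal-frequency-binned plug-in estimator (bits). The all-pairs MI
   distribution is thresholded at a high quantile (default **0.99741**,
   i.e. the top 0.259 % of pairs become edges).
2. **Bipartite topology.** Per node `u`: degree `k_u`; the bipartite
   clustering coefficient
   `cc(u) = Σ_{v∈N(N(u))} |N(u)∩N(v)| / |N(u)∪N(v)| / |N(N(u))|`
   (mean Jaccard overlap with second neighbors); and the redundancy
   coefficient
   `rc(u) = #{ {w₁,w₂} ⊆ N(u) : ∃ u'≠u adjacent to both } / (k_u(k_u−1)/2)`,
   the fraction of neighbor pairs that stay co-connected without `u`
   (undefined for `k_u < 2`). `rc(u) = 1` means deleting `u` changes
   nothing in the one-mode projection of the opposite layer.
3. **Commodore classification.** miRs are partitioned on the
   degree–redundancy plane; a Commodore has degree > 100 and redundancy
   < 0.5 (both thresholds configurable).
4. **Neighborhood characterization.** Each Commodore's gene neighborhood —
   and every pairwise neighborhood intersection — is tested for
   over-representation of annotation categories (GMT catalog) with the
   exact hypergeometric upper tail and Benjamini–Hochberg adjustment
   (category sizes 5–2000, top-10 reporting).

A first-class **synthetic-data generator** plants exactly this structure
(exclusive high-degree regulons for Commodores, shared regulons for
redundant miR groups, noise elsewhere) so the whole pipeline can be
validated against a known ground truth.

## Worked example

```python
import cdrenet as cn

config = cn.PipelineConfig(synthetic=cn.SyntheticConfig(rng_seed=7))
result = cn.run_pipeline(config)
print(result.comparison)
print("Commodores in condition A:", result.condition_a.cdre.commodores)
print("Commodores in condition B:", result.condition_b.cdre.commodores)
```

Output:

```
                                           A       B
Parameter
Nodes, miR                            100.00   65.00
Nodes, gene                           623.00  651.00
Edges                                 914.00  906.00
Average degree, miR                     9.14   13.94
Average degree, gene                    1.47    1.39
Average clustering coefficient, miR     0.09    0.15
Average clustering coefficient, gene    0.84    0.96
Average redundancy coefficient, miR     0.05    0.19
Average redundancy coefficient, gene    0.74    0.90
Connected components                   48.00   46.00

Commodores in condition A: []
Commodores in condition B: ['mir-001', 'mir-002', 'mir-003']
```

The synthetic config planted 3 Commodore miRs (150 exclusive targets each)
in condition B only, plus two redundant miR triplets in both conditions.
The classifier recovers exactly the three planted Commodores in B and —
because the baseline condition contains only redundant regulation — none in
A. The top enrichment hit for `mir-001`'s recovered neighborhood is the
planted annotation category (hypergeometric p ≈ 2.7e-100, 80 of its 100
genes overlapping), with every random category far behind.

The same run from the shell, with all outputs (GML networks, per-node
metric TSVs, Commodore reports, enrichment tables, comparison table)
written to a bundle directory:

```bash
cdrenet -v run-all config.yaml --out bundle/
```

plus stage-wise subcommands `simulate`, `infer`, `metrics`, `classify`,
`enrich` for working with your own expression TSVs and GMT catalogs.

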