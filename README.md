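# synmatch

Ranking cell-surface "matching partner" candidates between layer-5
pyramidal-cell populations and their basket-cell interneuron inputs, from
bulk and single-cell RNA-seq.

## The problem

In neocortical layer 5, intratelencephalic (L5 IT) and extratelencephalic
(L5 ET) pyramidal neurons receive perisomatic inhibition from different
basket-cell types — CCK+ interneurons preferentially target L5 IT cells and
PV+ interneurons L5 ET cells. One candidate mechanism is a transcriptional
program: cell-surface molecules expressed specifically by one pyramidal
population whose binding partners are expressed specifically by the matching
interneuron class. `synmatch` implements the computational route from raw
count matrices to a ranked list of such candidates:

1. **Filtering** — keep genes with ≥ 10 reads in every sample of every study.
2. **Differential expression** per study — a negative-binomial Wald test on
   median-of-ratios-normalized counts; a gene is a DEG when its fold change
   is ≥ 1.5 in either direction and its Bonferroni-adjusted p < 0.05.
3. **Integration** across a primary study, a reference study and an
   early-timepoint study (union of the first two restricted to the third, or
   a plain union), with direction-conflicting genes dropped.
4. **Contamination QC** — per-sample z-scores of a microglial marker panel,
   flagging cross-cell-type contamination.
5. **Interneuron classification** — PV+ cells by high Pvalb, CCK+ cells by
   high Cck with moderate/low Pvalb (quantile rules).
6. **Partner scoring** — for each DEG candidate with annotated
   ligand-receptor partners, the mean log2 enrichment of its positively
   enriched partners in the matching interneuron class (CCK for IT, PV for
   ET), combined with a [0, 1]-scaled L5 fold-change score into a total
   score that ranks the candidates:

   `total = scale01(fold-difference) + scale01(mean log2 partner enrichment)`

A synthetic-data module generates complete ground-truth-labeled input
bundles (NB bulk counts with planted fold changes and optional microglial
contamination, interneuron profiles with planted receptor enrichments, pair
tables with typed decoys) so every stage is testable without any external
download.

## Worked example

Simulate a default scenario (3 bulk studies x 3 replicates per population,
2000 genes, 5 interneuron subpopulations, 50 decoy DEGs per population, the
planted IT candidate *Cdh12* pairing homophilically and enriched in CCK+
cells, the planted ET candidate *Cdh13* enriched in PV+ cells) and run the
pipeline on it:

```sh
synmatch simulate --out demo --seed 2
synmatch run --config demo/pipeline.yaml
```

which prints

```
IT: 5 ranked candidates, top Cdh12
ET: 3 ranked candidates, top Cdh13
```

Both planted candidates emerge at rank 1. Most decoy DEGs are excluded from
ranking because they have no partner in the pair table or no positively
enriched partner; the few that sneak in with weakly positive partner
enrichment score far below the planted candidates on the specificity
component. The same analysis is available in memory:

```python
from synmatch import make_scenario, run_bundle_object

bundle = make_scenario(seed=2)
result = run_bundle_object(bundle)
print(result.ranked["IT"].head().to_string())
```

```
    gene population    fc_raw  fc_score  specificity_raw  specificity_scaled  total_score  rank
0  Cdh12         IT  3.136613  0.926920         1.450647            1.000000     1.926920     1
1  g0353         IT  3.210884  1.000000         0.196475            0.101358     1.101358     2
2  g1417         IT  3.047537  0.839271         0.200504            0.104245     0.943517     3
3  g0668         IT  2.631310  0.429715         0.132070            0.055210     0.484925     4
4  g0831         IT  2.194596  0.000000         0.055017            0.000000     0.000000     5
```

The planted candidate's fold-difference (`fc_raw` ≈ 3.1, its planted ratio
is 4 before sampling noise) is comparable to the strongest decoys', but its
partner specificity (mean log2 enrichment ≈ 1.45 in CCK+ cells) dwarfs the
decoys' near-zero values, and the combined total score puts it first. The
run directory contains per-study DEG tables, the integrated DEG list, QC
reports, partner enrichment tables, the ranked candidate TSVs and a
manifest.

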