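# phylocna

Phylogenetic comparative analysis of gene copy number: weighted
Pagel's-λ PGLS screens of per-orthogroup copy number against life-history
and cancer phenotypes across species, a self-contained aggregate gene-set
copy-number test, simulation-based robustness nulls, a reversed Poisson
phylogenetic GLM, and preranked GSEA / ORA over screen results — together
with a synthetic-data generator so the entire pipeline runs end to end with
known ground truth and no external downloads.

## What's in the box

| Module | Purpose |
| --- | --- |
| `phylocna.tree` | Newick parsing/writing (dendropy-backed), Brownian-motion covariance, Pagel's λ transform, BM simulation, ML ancestral reconstruction |
| `phylocna.pgls` | GLS with fixed covariance, profile-λ PGLS (weighted), per-coefficient t-tests, Poisson phylogenetic GLM (GEE with λ-transformed working correlation) |
| `phylocna.data` | Copy-number TSV / GMT / phenotype-table I/O, the >50%-nonzero orthogroup filter, set→orthogroup mapping, aggregate counts, derived cancer phenotypes (√necropsy weights) |
| `phylocna.screens` | Per-orthogroup and per-gene-set PGLS screens with covariates, BH / Bonferroni / Hommel adjustment, reversed Poisson-PGLM check |
| `phylocna.nulls` | Variance-matched random-set null and BM random-phenotype null, empirical p |
| `phylocna.enrichment` | Ranked-list construction (signed −log10 p), classic (unweighted) GSEA enrichment score with gene-label permutation, hypergeometric ORA |
| `phylocna.synth` | Yule trees, tree-correlated overdispersed copy numbers, phenotypes with planted aggregate effects, bundled worked-example PGLS table |

Weighted PGLS uses the residual covariance
`D^-1/2 · V(λ) · D^-1/2` (weights scale residual variances), with λ
profiled by maximum likelihood on [0, 1] in an eigenbasis so large screens
reuse one decomposition per tree.

## CLI

```sh
# generate a synthetic dataset with a planted gene set
phylocna simulate --config config.yaml --outdir data/

# per-orthogroup and gene-set screens
phylocna screen orthogroups --counts data/counts.tsv --annotation data/annotation.tsv \
    --phenotypes data/phenotypes.tsv --tree data/tree.nwk \
    --phenotype malignancy_rate --out screen_og.tsv
phylocna screen genesets --counts data/counts.tsv --annotation data/annotation.tsv \
    --gmt data/gene_sets.gmt --phenotypes data/phenotypes.tsv --tree data/tree.nwk \
    --phenotype malignancy_rate --out screen_gs.tsv

# robustness nulls for one set
phylocna nulls variance-matched --set planted --reps 1000 --seed 1 \
    --counts data/counts.tsv --annotation data/annotation.tsv --gmt data/gene_sets.gmt \
    --phenotypes data/phenotypes.tsv --tree data/tree.nwk --out null_vm.tsv
phylocna nulls bm-phenotype   --set planted --reps 1000 --seed 1 \
    --counts data/counts.tsv --annotation data/annotation.tsv --gmt data/gene_sets.gmt \
    --phenotypes data/phenotypes.tsv --tree data/tree.nwk --out null_bm.tsv

# enrichment over the per-orthogroup screen
phylocna enrich gsea --screen screen_og.tsv --annotation data/annotation.tsv \
    --gmt data/gene_sets.gmt --out gsea.tsv
phylocna enrich ora  --screen screen_og.tsv --annotation data/annotation.tsv \
    --gmt data/gene_sets.gmt --out ora.tsv
```

An example simulate config:

```yaml
n_species: 94
n_orthogroups: 500
seed: 7
sets:
  - name: planted
    size: 12
    phenotype: malignancy_rate
    effect: -0.1
```

## File formats

Counts: TSV, first column `orthogroup_id`, one column per species.
Annotation: TSV `orthogroup_id<TAB>comma,separated,symbols`. Phenotypes:
TSV with `species`, `body_size_g`, `longevity_months`, `n_necropsies`,
`n_neoplasia`, `n_malignant` (prevalences, malignancy rate and weights are
derived). Gene sets: standard GMT. Trees: newick with branch lengths.
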