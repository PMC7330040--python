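# tmenet

Weighted co-expression network analysis of tumor-microenvironment (TME)
programs in matched primary/metastasis cancer cohorts.

Colorectal cancers that metastasize to the liver often do so without any
distinctive somatic mutation or copy-number change; what separates
metastasizing primaries from non-metastasizing ones is transcriptional —
coordinated stromal, vascular and immune programs (EMT, angiogenesis,
cancer-associated fibroblasts, immune suppression) in the tumor
microenvironment.  `tmenet` implements the analysis used to find and
interpret such programs, for computational biologists working with bulk
expression plus matched variant/copy-number data:

1. **Network construction** — pairwise Pearson correlations raised to a
   soft-threshold power β (default 6, chosen for approximate scale-free
   topology) give a weighted adjacency `a_ij = |cor(x_i, x_j)|^β`, which
   is transformed to the topological overlap measure

       TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)

   Modules are detected by average-linkage clustering on `1 − TOM` and
   merged when their eigengenes are closer than 0.10 in correlation
   dissimilarity.
2. **Eigengenes and traits** — each module is summarized by its eigengene
   (first principal component of member expression, one score per
   sample), correlated with clinical traits (metastasis as 0/1), compared
   across groups (Welch or paired t), and re-scored in external cohorts.
3. **Annotation** — cell-type enrichment of module scores in purified
   reference profiles (one-way ANOVA), size-corrected signature overlap
   `100·|module ∩ signature|/|module|` against a random-signature null,
   hypergeometric over-representation, the ranked minimum-hypergeometric
   (mHG) score, and hub ranking by intramodular connectivity
   `kIM(g) = Σ_{h∈module} TOM_gh`.
4. **Genomic alterations** — gene-level absolute copy-number
   classification (deletion < 1.0 ≤ loss < 1.85 ≤ diploid ≤ 2.15 < gain
   ≤ 4.0 < amplification, most-deviant-from-2 selection, deletion
   precedence), a somatic SNV filter cascade with a per-rule audit,
   BLOSUM80-derived mutation-severity ranking, Fisher tests of per-group
   alteration frequencies, primary/metastasis variant concordance, and
   Jaccard clustering of mutation profiles.
5. **Outcome** — a Welch/paired-t differential-expression stand-in
   (DEG ⇔ FDR < 0.05 and |FC| ≥ 2) and mean-split Kaplan–Meier /
   log-rank survival analysis of module scores.

A synthetic matched-trio cohort generator (adjacent normal AN, primary
without metastasis CNM, primary with metastasis CWM, matched liver
metastasis CLM) plants known module structure, trait effects, cell-type
references, copy-number segments, concordance-controlled variant tables
and module-driven survival, so every stage can be tested against ground
truth.

## Worked example

```python
from tmenet import (SyntheticCohortConfig, generate_cohort, build_network,
                    eigengene_matrix, module_trait_correlation)
from sklearn.metrics import adjusted_rand_score

cohort = generate_cohort(SyntheticCohortConfig(seed=1))   # 2000 genes, 64 samples
tom, partition = build_network(cohort.expression)          # beta=6, merge 0.10
print(partition.value_counts().to_dict())

truth = cohort.truth_partition
mask = truth != "unassigned"
print("ARI:", adjusted_rand_score(truth[mask], partition[mask]))

eig = eigengene_matrix(cohort.expression, partition)
res = module_trait_correlation(eig, cohort.samples["metastasis"])
print(res.sort_values("r", key=abs, ascending=False).head(1))
```

prints

```
{'unassigned': 867, 'GM1': 366, 'GM2': 275, 'GM3': 221, 'GM4': 167, 'GM5': 104}
ARI: 1.0
  module       trait         r             p           fdr
0    GM1  metastasis  0.613055  7.246099e-08  3.623050e-07
```

The five planted modules are recovered exactly on the non-background
genes (adjusted Rand index 1.0); the module carrying the planted CWM/CLM
shift (GM1) tops the metastasis correlation at r = 0.61, p = 7×10⁻⁸.

The same pipeline is available as shell subcommands:

```bash
tmenet simulate --out sim --seed 1
tmenet network  --expr sim/expression.tsv --out net
tmenet traits   --expr sim/expression.tsv --partition net/partition.tsv \
                --pheno sim/phenotype.tsv --out traits
tmenet annotate --tom net/tom.tsv --partition net/partition.tsv \
                --gmt sim/signatures.gmt --refs sim/references.tsv \
                --celltypes sim/celltypes.tsv --seed 1 --out annot
tmenet cnv      --seg sim/segments.tsv --genes sim/gene_models.tsv --out cnv
tmenet variants --maf sim/variants.tsv --pheno sim/phenotype.tsv --out var
tmenet de       --expr sim/expression.tsv --pheno sim/phenotype.tsv --out de
tmenet survival --scores traits/eigengenes.tsv --module GM1 \
                --surv sim/survival.tsv --out surv
```

Every run writes a provenance JSON; identical invocations reproduce their
outputs byte for byte.

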