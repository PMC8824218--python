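# citemo

Single-cell multimodal analysis for CITE-seq / REAP-seq experiments:
integrate the transcriptome and antibody-derived-tag (ADT) modalities of the
same cells with a deliberately linear PCA-of-PCs recipe, cluster each
modality view, and screen ADT pairs for concentrated co-expression patterns
with a four-quadrant entropy statistic.

Intended users are computational biologists analysing paired RNA + surface
protein droplet data who want (a) a multimodal clustering whose cell
subpopulations can be compared one-to-one against the single-modality
clusterings on a shared UMAP, and (b) a high-throughput, threshold-based
screen for double-positive / single-positive / double-negative antibody
combinations (e.g. CD4+CD19+ T–B conjugates, CD4+CD8+ double-positive T
cells) that plain correlation coefficients cannot characterise.

## The method

**Preprocessing.** Genes are screened by two reliability indexes computed
over the *I* × *J* gene-by-cell UMI matrix *M* = (*m*ᵢⱼ): total expression
*T*ᵢ = Σⱼ *m*ᵢⱼ and sparsity *SP*ᵢ = #{ *j* : *m*ᵢⱼ ≠ 0 }; a gene is kept
when *T*ᵢ > *t*·*J* and *SP*ᵢ > *s*·*J* (defaults *t* = 0.01, *s* = 0.05).
RNA is normalized as log(1 + *m*ᵢⱼ); the *K* × *J* ADT count matrix *Q* is
normalized per ADT by the centred log ratio, CLR(*q*ₖ) =
ln((*q*ₖⱼ + c)/g(*q*ₖ + c)) with g the geometric mean across cells
(pseudocount c = 1). Both matrices are then MinMax-rescaled per feature to
[0, 1].

**Integration.** Each scaled matrix is reduced by PCA over cells (features
mean-centred, explained variance with *n*−1 degrees of freedom, component
count by an explained-variance elbow or set explicitly; panels with few
ADTs can pass through un-reduced). The two low-dimensional representations
are MinMax-rescaled per component, stacked row-wise, and reduced by PCA
once more — the multimodal representation. Using one linear algorithm at
every stage avoids mixing artefacts of different reduction methods into
the fusion.

**Downstream.** Leiden community detection on a Jaccard-weighted
k-nearest-neighbour graph clusters each of the three representations (RNA,
ADT, multimodal); one UMAP computed from the multimodal representation is
shared by all three cluster colourings; one-vs-rest Wilcoxon rank-sum tests
with Benjamini–Hochberg correction rank marker genes and ADTs per cluster.

**Co-expression entropy.** Within a cluster, a threshold Θ (default 0.5 on
the [0, 1]-scaled ADT values) splits every two-ADT plane into four
quadrants; with *P*₁..*P*₄ the fractions of the cluster's cells per
quadrant,

&nbsp;&nbsp;&nbsp;&nbsp;S = −Σᵢ *P*ᵢ log₄ *P*ᵢ  (zero *P*ᵢ replaced by ε = 10⁻⁶)

so S ≈ 0 flags one dominant quadrant (a double-positive population when
that quadrant is Q1), S ≈ 0.5 a two-quadrant pattern, and S → 1 a uniform
spread suggesting the cluster is heterogeneous. All (cluster, ADT-pair)
combinations are screened and reported with Pearson/Spearman/Kendall
correlation baselines.

## Worked example

A bundled generator creates paired RNA/ADT counts with known structure.
The `mixed_five` preset has five clusters of 100 cells: two separable only
by RNA markers, two only by ADTs, one by both.

```python
from sklearn.metrics import adjusted_rand_score
from citemo import generate_cite_seq, run_pipeline
from citemo.synthetic import preset

rna, adt, labels = generate_cite_seq(preset("mixed_five"))
bundle = run_pipeline(
    {"preset": "cbmc_like", "qc.drop_adts": [], "output.dir": "out"},
    rna=rna, adt=adt,
)
for m, a in bundle.clusters.items():
    print(f"{m:<11} clusters={a.n_clusters}  "
          f"ARI vs truth={adjusted_rand_score(labels, a.labels):.3f}")
```

prints

```
rna         clusters=4  ARI vs truth=0.781
adt         clusters=4  ARI vs truth=0.781
multimodal  clusters=5  ARI vs truth=1.000
```

— each single modality merges the pair it cannot see (4 clusters,
ARI 0.78), while the multimodal representation recovers all five clusters
exactly. The co-expression table (`bundle.coexpression`, also written to
`out/coexpression.csv`) is sorted by entropy ascending; its head lists the
single-quadrant (concentrated) ADT pairs per cluster:

```
 cluster  adt1  adt2   n  p1  p2  p3  p4  entropy  pearson            band
       0 ADT01 ADT02 100 0.0 0.0 0.0 1.0      0.0    0.061 single-quadrant
       0 ADT01 ADT03 100 0.0 0.0 0.0 1.0      0.0    0.015 single-quadrant
```

Note the near-zero Pearson correlations: a fully concentrated pattern
(here, ADT01-positive / partner-negative, P₄ = 1) is invisible to
correlation but has entropy 0.

The same pipeline runs from the shell:

```bash
citemo simulate --preset mixed_five -o fixture/
citemo run -c config.yaml --set coex.theta=0.5
citemo coex --clusters out/clusters_multimodal.csv --adt fixture/adt.csv
```

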