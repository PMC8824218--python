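# Methods

## Data model and orientation

All matrices are stored features × cells with 0-based indices; readers
transpose cells × features inputs on load (declared via `io.orientation`).
Counts must be nonnegative integers with unique cell barcodes; the RNA and
ADT matrices of one experiment must list the same barcodes in the same
order, and no silent reindexing is ever performed.

## Quality control

* **Gene reliability screen.** With *J* cells, a gene is kept when its
  total expression exceeds `qc.t_frac`·*J* **and** its sparsity (number of
  cells with a nonzero count) exceeds `qc.sp_frac`·*J*. Both inequalities
  are strict. Defaults are 0.01/0.05 (genes expressed in more than 5% of
  cells); the bone-marrow-style preset relaxes sparsity to 0.01. Screening
  is idempotent and errors if it would remove every gene.
* **Species pre-screen.** For experiments with a spiked-in second species,
  the `qc.top_cv_n` (default 100) prefix-matched genes with the largest
  coefficient of variation (sd/mean across cells, ddof = 1) are selected.
  Zero-mean features are excluded; ties break lexicographically on the
  feature id so the selection is deterministic. By default the selected
  genes are retained as a **union** with the reliability-screened set —
  the high-CV spike-in markers survive even if the screen drops them.
* **Contaminated ADTs.** Antibody conjugates known not to bind
  specifically are removed by name (`qc.drop_adts`; the cord-blood-style
  preset drops CCR7, CCR5, CD10). Unknown names warn rather than error
  unless `qc.strict_adt_names` is set. The published cord-blood panel
  counts (11 ADTs, minus 3 contaminated, with 10 analysed) do not
  reconcile arithmetically; the drop list is therefore configuration, not
  code.

## Normalization

* **RNA**: natural log(1 + count). The pseudocount pins zero counts at 0,
  so the global minimum of the log-normalized matrix is 0.
* **ADT**: centred log ratio per ADT across cells,
  ln((q + c)/g(q + c)), pseudocount `norm.clr_pseudocount` = 1 by default
  (required whenever any count is 0). Every ADT row of the output sums to
  zero; this is asserted in the test suite to 1e-9 relative tolerance.
  Centring is across *cells* for each ADT, not across ADTs within a cell.
* **MinMax rescale**: per feature, (x − min)/(max − min); constant
  features map to 0 to avoid a 0/0 deterministically. The transform
  definition also admits adding back the global matrix minimum after
  rescaling (`norm.literal_eq5`). For log-RNA the global minimum is 0 and
  the term is a no-op; for CLR input it is negative and would push values
  below 0, contradicting the intended [0, 1] range, so the default omits
  it and the flag restores the verbatim behaviour. Both paths are tested.

## Dimensionality reduction and integration

PCA treats cells as samples: features are mean-centred across cells, no
unit-variance scaling, full SVD (a seeded randomized solver above
5·10⁶ elements). Explained variance uses *n*−1 degrees of freedom, and the
component-sign ambiguity is resolved by making the largest-|loading| entry
of each component positive, which makes reruns bit-identical. Total
variance equals the sum of per-feature variances (ddof = 1) to 1e-8
relative — a suite invariant.

Component counts may be set explicitly (`reduce.rna_k` etc.) or chosen by
an explained-variance elbow: the elbow is the point of maximum
perpendicular distance to the chord joining the first and last variance
values, and the components strictly before it are kept (curves with no
curvature yield k = 1). The rule is a convenience, not a recommendation —
it is deliberately conservative and can under-select on shallow curves, so
analyses that know their panel (the bundled `cbmc_like` / `hbmc_like`
presets) set k explicitly, exactly as the published analyses chose
10/15 and 30/18 components by inspection. The pipeline floors automatic
choices at 2 components so a 2-D embedding is always defined.

With few ADTs, `reduce.passthrough` uses the scaled ADT matrix itself as
the ADT representation (the cord-blood style, where all 10 ADTs stand in
for components).

Integration: each per-modality representation is MinMax-rescaled per
component to [0, 1] (so neither modality dominates by numeric range),
stacked row-wise, and reduced by a second, centred PCA. The multimodal
component count again comes from config or the elbow.

## Clustering, embedding, differential analysis

Cells are linked to their `cluster.k_neighbors` = 30 nearest neighbours
(euclidean, on the representation scores); edges are weighted by the
Jaccard similarity of the endpoint neighbour sets, the construction used
by PhenoGraph. Leiden (RB-configuration quality, `cluster.resolution` = 1.0,
fixed seed) partitions the graph; labels are renumbered by decreasing
cluster size. Near-duplicate clusters are merged only by an explicit
`cluster.merge` directive, never automatically. A practical note: the
modularity resolution limit can split a single loose blob into
subcommunities when the representation is very low-dimensional or the
panel contains many uninformative dimensions; in the intended regime
(PCA scores, informative panels) partitions are stable and
permutation-invariant up to relabelling, which the suite checks.

One UMAP (`umap.n_neighbors` = 15, `umap.min_dist` = 0.5, fixed seed) is
computed from the multimodal representation and reused for the RNA, ADT
and multimodal cluster colourings, so subpopulations can be compared
across modalities at identical coordinates.

Differential analysis is one-vs-rest per cluster with the two-sided
Mann–Whitney rank-sum test (tie-corrected normal approximation; features
constant across both groups are reported at p = 1), Benjamini–Hochberg
adjusted across features within each cluster. The groups being independent,
the rank-sum form is the default; a signed-rank variant
(`de.test=signedrank`) exists for genuinely paired equal-size groups. Log
fold changes are base-2 on the normalized values with pseudocount 1e-9;
for CLR input the means are taken on the exponentiated
(ratio-to-geometric-mean) scale, since CLR means can be negative.

## Co-expression entropy

For a cluster of N cells and two scaled ADTs, the threshold Θ
(`coex.theta` = 0.5; a value exactly at Θ counts as high) defines marginal
probabilities PH = #(v ≥ Θ)/N, PL = 1 − PH, and four quadrant
probabilities P₁..P₄ numbered anticlockwise from the double-positive
quadrant. **P_i are joint cell proportions**, not the products PH·PH of
the marginals: the two coincide only under independence, and the product
form is available as a diagnostic (`coex.product_form`) whose divergence
from the joint form measures pairwise ADT dependence. The entropy is

S = −Σ P′ᵢ log₄ P′ᵢ, P′ᵢ = max(Pᵢ, ε), ε = `coex.epsilon` = 10⁻⁶.

At ε → 0, 0 ≤ S ≤ 1 with the maximum exactly at the uniform quadrant
distribution; with finite ε the overshoot above 1 is bounded by
4ε·log₄(1/ε) < 5·10⁻⁵, and a fully concentrated cluster scores
3ε·log₄(1/ε) ≈ 3·10⁻⁵, i.e. 0.00 at two decimals. The screen reports
every (cluster, unordered ADT pair) sorted by entropy ascending with
annotation bands (≤ 0.25 single-quadrant, ≤ 0.75 two-quadrant, else
diffuse — patterns above ~0.75 rarely admit a biological reading) and
Pearson/Spearman/Kendall baselines (missing for clusters of < 3 cells or
constant vectors; the entropy is still defined there).

## Synthetic data

The generator emulates the two data characters the pipeline assumes: RNA
counts are negative-binomial (default mean 2, size 2) with multiplicative
marker effects (default fold 16 on 25-gene blocks) and independent dropout
zeroing (rate 0.3) — sparse and over-dispersed; ADT counts are rounded
lognormals (location 3, scale 0.4; marker clusters shifted +2.5 in log
space) — dense, large-range, never sparse. Marker effect sizes are set so
engineered clusters are actually separable in their designated modality
after per-feature MinMax scaling, which grants noise features the same
[0, 1] range as markers; the `adt_only_pair` preset accordingly uses a
panel of only discriminating ADTs, since panel dimensions identical across
clusters act as pure noise that can make graph clustering split the blobs.
Presets carry fixed seeds so fixtures are stable.

What the generator does **not** emulate: library-size variation, batch
effects, ambient contamination, doublets, or mean-variance trends fit to
any real dataset. Passing tests therefore demonstrate the pipeline's
mechanics and its modality-coverage property under clean, well-separated
conditions — not performance on real CITE-seq data.

## Problem sizes and determinism

The test suite and the acceptance script run on desk-scale problems
(≤ 500 cells, ≤ 200 genes, ≤ 10 ADTs; 10,000 simplex draws for the entropy
bound), chosen so the full pipeline exercises every stage in seconds.
Every stochastic step (PCA solver, Leiden, UMAP, the generator) takes an
explicit seed; per-stage seeds default to the global `seed`, and pipeline
outputs are a pure function of (inputs, resolved config, seeds) — reruns
are bit-identical, which the suite asserts on the CSV bundle.

## Known limitations

* The elbow rule under-selects on shallow variance curves; prefer explicit
  k for real analyses.
* CLR depends on the pseudocount when many ADT counts are zero.
* The entropy screen tests marginal thresholding only; Θ = 0.5 presumes
  the MinMax scaling has put the positive/negative boundary near
  mid-range, which can fail for ADTs with extreme outlier cells (the
  threshold is configurable on demand).
* One-vs-rest differential p-values on clusters derived from the same data
  are anti-conservative by construction (double dipping); they rank
  markers, they do not test hypotheses.
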