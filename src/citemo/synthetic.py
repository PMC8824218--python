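"""Synthetic paired RNA/ADT count generator with known cluster structure.

Every pipeline stage is testable without downloading a CITE-seq dataset:
the generator emits a gene-by-cell UMI matrix (negative-binomial counts
with multiplicative marker effects and independent dropout zeroing, giving
the sparse, over-dispersed character of droplet scRNA-seq) and a paired
ADT-by-cell matrix (rounded lognormal counts with cluster-specific shifts
in log space: denser, larger-range, never sparse), plus ground-truth
labels.

Presets mirror the analysis scenarios the pipeline must handle: cluster
pairs separable in only one modality, a five-cluster mix exercising the
integration claim, an engineered double-positive ADT pair, and a
second-species gene spike-in for the coefficient-of-variation pre-screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .io_screening import CountMatrix, ValidationError

PRESETS = ("rna_only_pair", "adt_only_pair", "mixed_five", "double_positive", "species_spikein")


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic CITE-seq experiment.

    ``rna_markers`` / ``adt_markers`` map cluster index -> feature indices
    that are up-shifted in that cluster; clusters sharing a marker set (or
    having none) are indistinguishable in that modality.
    """

    cells_per_cluster: list[int]
    n_genes: int = 200
    n_adts: int = 10
    rna_markers: dict[int, list[int]] = field(default_factory=dict)
    adt_markers: dict[int, list[int]] = field(default_factory=dict)
    rna_base_mean: float = 2.0
    rna_marker_fold: float = 16.0
    rna_dispersion: float = 2.0  # NB size parameter; var = mu + mu^2/size
    dropout: float = 0.3
    adt_base_log: float = 3.0  # lognormal location, ~e^3 = 20 counts
    adt_log_sd: float = 0.4
    adt_marker_shift: float = 2.5  # added to the location in marker clusters
    n_species_genes: int = 0  # spiked-in second-species gene block
    species_prefix: str = "MOUSE-"
    species_cluster: int | None = None  # cluster expressing the spiked block
    double_positive: tuple[int, int, int] | None = None  # (cluster, adt_i, adt_j)
    seed: int = 0

    @property
    def n_clusters(self) -> int:
        return len(self.cells_per_cluster)

    @property
    def n_cells(self) -> int:
        return int(sum(self.cells_per_cluster))


def generate_cite_seq(spec: SyntheticSpec) -> tuple[CountMatrix, CountMatrix, np.ndarray]:
    """Draw one paired (RNA, ADT) experiment; reproducible for a fixed seed.

    Returns the two count matrices (barcodes shared in identical order) and
    the per-cell ground-truth cluster labels.
    """
    if spec.n_clusters == 0 or spec.n_cells == 0:
        raise ValidationError("need at least one cluster with at least one cell")
    rng = np.random.default_rng(spec.seed)
    labels = np.repeat(np.arange(spec.n_clusters), spec.cells_per_cluster)
    n_cells = spec.n_cells
    n_genes_total = spec.n_genes + spec.n_species_genes

    # per-cluster NB mean profiles
    mu = np.full((spec.n_clusters, n_genes_total), spec.rna_base_mean)
    for c, genes in spec.rna_markers.items():
        mu[c, genes] *= spec.rna_marker_fold
    if spec.n_species_genes:
        block = slice(spec.n_genes, n_genes_total)
        mu[:, block] = 0.05  # near-silent in host cells
        if spec.species_cluster is not None:
            mu[spec.species_cluster, block] = spec.rna_base_mean * spec.rna_marker_fold

    size = spec.rna_dispersion
    cell_mu = mu[labels]  # cells x genes
    with np.errstate(divide="ignore"):
        p = size / (size + cell_mu)
    rna = rng.negative_binomial(size, np.clip(p, 1e-12, 1.0), size=cell_mu.shape)
    if spec.dropout > 0:
        rna = rna * (rng.random(rna.shape) >= spec.dropout)

    # per-cluster lognormal ADT locations
    loc = np.full((spec.n_clusters, spec.n_adts), spec.adt_base_log)
    for c, adts in spec.adt_markers.items():
        loc[c, adts] += spec.adt_marker_shift
    if spec.double_positive is not None:
        c, a1, a2 = spec.double_positive
        loc[c, [a1, a2]] = spec.adt_base_log + spec.adt_marker_shift
    adt = np.rint(np.exp(rng.normal(loc[labels], spec.adt_log_sd))).astype(np.int64)

    barcodes = [f"cell-{i:05d}" for i in range(n_cells)]
    gene_ids = [f"G{i:04d}" for i in range(spec.n_genes)] + [
        f"{spec.species_prefix}G{i:04d}" for i in range(spec.n_species_genes)
    ]
    adt_ids = [f"ADT{i:02d}" for i in range(spec.n_adts)]
    rna_m = CountMatrix(rna.T, gene_ids, barcodes, "rna")
    adt_m = CountMatrix(adt.T, adt_ids, barcodes, "adt")
    return rna_m, adt_m, labels


def preset(name: str) -> SyntheticSpec:
    """Fixed-parameter scenario specs (fixed seeds, so fixtures are stable)."""
    if name == "rna_only_pair":
        # two clusters with identical ADT profiles, distinct RNA markers
        return SyntheticSpec(
            cells_per_cluster=[100, 100],
            n_genes=150,
            n_adts=8,
            rna_markers={0: list(range(0, 25)), 1: list(range(25, 50))},
            adt_markers={0: [0, 1], 1: [0, 1]},
            seed=11,
        )
    if name == "adt_only_pair":
        # two clusters with identical RNA profiles, separated by 5 ADTs;
        # the panel holds only discriminating antibodies — MinMax gives every
        # ADT the same [0,1] range, so never-binding panel dimensions would
        # inflate within-cluster spread relative to the cluster gap
        return SyntheticSpec(
            cells_per_cluster=[100, 100],
            n_genes=150,
            n_adts=5,
            rna_markers={},
            adt_markers={0: [0, 1, 2], 1: [3, 4]},
            seed=12,
        )
    if name == "mixed_five":
        # clusters 0/1 separable only in RNA (shared ADT profile),
        # clusters 2/3 separable only in ADT (shared RNA markers),
        # cluster 4 separable in both
        return SyntheticSpec(
            cells_per_cluster=[100] * 5,
            n_genes=200,
            n_adts=10,
            rna_markers={
                0: list(range(0, 25)),
                1: list(range(25, 50)),
                2: list(range(50, 75)),
                3: list(range(50, 75)),
                4: list(range(75, 100)),
            },
            adt_markers={0: [0, 1], 1: [0, 1], 2: [2, 3], 3: [4, 5], 4: [6, 7]},
            seed=1,
        )
    if name == "double_positive":
        return SyntheticSpec(
            cells_per_cluster=[100, 100, 100],
            n_genes=150,
            n_adts=8,
            rna_markers={0: list(range(0, 25)), 1: list(range(25, 50)), 2: list(range(50, 75))},
            adt_markers={1: [4], 2: [5]},
            double_positive=(0, 0, 1),
            seed=13,
        )
    if name == "species_spikein":
        return SyntheticSpec(
            cells_per_cluster=[150, 150, 30],
            n_genes=150,
            n_adts=8,
            rna_markers={0: list(range(0, 25)), 1: list(range(25, 50))},
            adt_markers={0: [0], 1: [1]},
            n_species_genes=30,
            species_cluster=2,
            seed=14,
        )
    raise ValueError(f"unknown preset {name!r}; choose one of {PRESETS}")


def write_fixture(
    out_dir: str,
    spec: SyntheticSpec,
    fmt: str = "mtx_dir",
) -> tuple[CountMatrix, CountMatrix, np.ndarray]:
    """Materialize a spec to disk (MTX trios or dense CSV) plus truth labels."""
    rna, adt, labels = generate_cite_seq(spec)
    os.makedirs(out_dir, exist_ok=True)
    if fmt == "mtx_dir":
        for m, sub in ((rna, "rna"), (adt, "adt")):
            d = os.path.join(out_dir, sub)
            os.makedirs(d, exist_ok=True)
            scipy.io.mmwrite(os.path.join(d, "matrix.mtx"), scipy.sparse.coo_matrix(m.values))
            with open(os.path.join(d, "features.tsv"), "w") as fh:
                fh.writelines(f"{f}\n" for f in m.feature_ids)
            with open(os.path.join(d, "barcodes.tsv"), "w") as fh:
                fh.writelines(f"{b}\n" for b in m.cell_barcodes)
    elif fmt == "csv":
        for m, sub in ((rna, "rna"), (adt, "adt")):
            pd.DataFrame(m.values, index=m.feature_ids, columns=m.cell_barcodes).to_csv(
                os.path.join(out_dir, f"{sub}.csv")
            )
    else:
        raise ValueError(f"unknown fixture format {fmt!r}")
    pd.DataFrame({"barcode": rna.cell_barcodes, "label": labels}).to_csv(
        os.path.join(out_dir, "labels.csv"), index=False
    )
    return rna, adt, labels
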