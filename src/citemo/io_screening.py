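"""Reading paired count matrices and quality-control screening.

CITE-seq experiments yield two count matrices over the same cell barcodes:
a gene-by-cell UMI matrix (RNA) and an antibody-derived-tag-by-cell matrix
(ADT).  This module reads both from 10x-style MTX directories or dense
CSV/TSV, and applies three screens:

* gene reliability screening on total expression ``T`` and sparsity ``SP``
  (keep genes expressed above a fraction of cells),
* a coefficient-of-variation pre-screen for a species-prefixed gene block
  (spiked-in mouse cells),
* removal of contaminated ADTs known not to bind specifically.
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("citemo")

MODALITIES = ("rna", "adt")


class ValidationError(ValueError):
    """Input data violates a structural contract."""


@dataclass
class CountMatrix:
    """Raw nonnegative integer counts, features x cells.

    The canonical in-memory orientation is features on rows, cells on
    columns, 0-based indices; readers transpose cells-by-features inputs.
    """

    values: np.ndarray
    feature_ids: list[str]
    cell_barcodes: list[str]
    modality: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.feature_ids = list(self.feature_ids)
        self.cell_barcodes = list(self.cell_barcodes)
        if self.modality not in MODALITIES:
            raise ValidationError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        if self.values.ndim != 2:
            raise ValidationError("count matrix must be 2-dimensional")
        if self.values.size == 0:
            raise ValidationError("count matrix is empty")
        if not np.issubdtype(self.values.dtype, np.number):
            raise ValidationError("count matrix contains non-numeric entries")
        neg = np.argwhere(self.values < 0)
        if neg.size:
            i, j = neg[0]
            raise ValidationError(f"negative count at feature {i}, cell {j}")
        if not np.allclose(self.values, np.round(self.values)):
            bad = np.argwhere(~np.isclose(self.values, np.round(self.values)))[0]
            raise ValidationError(f"non-integral count at feature {bad[0]}, cell {bad[1]}")
        self.values = self.values.astype(np.int64)
        if len(self.feature_ids) != self.values.shape[0]:
            raise ValidationError(
                f"{len(self.feature_ids)} feature ids for {self.values.shape[0]} rows"
            )
        if len(self.cell_barcodes) != self.values.shape[1]:
            raise ValidationError(
                f"{len(self.cell_barcodes)} barcodes for {self.values.shape[1]} columns"
            )
        if len(set(self.cell_barcodes)) != len(self.cell_barcodes):
            raise ValidationError("duplicate cell barcodes")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_features(self, keep: np.ndarray) -> "CountMatrix":
        """Row-subset by boolean mask or integer index array, order preserved."""
        keep = np.asarray(keep)
        ids = [self.feature_ids[i] for i in np.flatnonzero(keep)] if keep.dtype == bool else [
            self.feature_ids[i] for i in keep
        ]
        return CountMatrix(self.values[keep], ids, self.cell_barcodes, self.modality)


@dataclass
class GeneStats:
    """Per-feature total expression T and sparsity SP (cells with nonzero counts)."""

    total_expression: np.ndarray  # T_i = sum_j m_ij
    sparsity: np.ndarray  # SP_i = #{j : m_ij != 0}
    feature_ids: list[str] = field(default_factory=list)


def _read_lines(path: str) -> list[str]:
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def _find_10x_file(directory: str, stems: tuple[str, ...]) -> str:
    for stem in stems:
        for suffix in ("", ".gz"):
            cand = os.path.join(directory, stem + suffix)
            if os.path.exists(cand):
                return cand
    raise FileNotFoundError(
        f"no file matching {' / '.join(stems)} (optionally .gz) under {directory}"
    )


def read_counts(
    path: str,
    format: str = "mtx_dir",
    modality: str = "rna",
    orientation: str = "features_by_cells",
) -> CountMatrix:
    """Read a count matrix into the canonical features x cells layout.

    Parameters
    ----------
    path
        MTX directory (10x convention: ``matrix.mtx``, ``features.tsv`` or
        ``genes.tsv``, ``barcodes.tsv``, each optionally gzipped) or a dense
        CSV/TSV with a header row of barcodes and feature ids in column 0.
    format
        One of ``mtx_dir``, ``csv``, ``tsv``.
    orientation
        ``features_by_cells`` (default, the 10x convention) or
        ``cells_by_features`` for transposed dense files.
    """
    if format not in ("mtx_dir", "csv", "tsv"):
        raise ValueError(f"unknown format {format!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(f"input path does not exist: {path}")

    if format == "mtx_dir":
        mtx = _find_10x_file(path, ("matrix.mtx",))
        feat = _find_10x_file(path, ("features.tsv", "genes.tsv", "features.txt"))
        barc = _find_10x_file(path, ("barcodes.tsv", "barcodes.txt"))
        values = scipy.io.mmread(mtx)
        if scipy.sparse.issparse(values):
            values = values.toarray()
        feature_ids = [line.split("\t")[0] for line in _read_lines(feat)]
        barcodes = [line.split("\t")[0] for line in _read_lines(barc)]
    else:
        sep = "," if format == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except pd.errors.EmptyDataError as exc:
            raise ValidationError(f"empty matrix file: {path}") from exc
        if df.size == 0:
            raise ValidationError(f"empty matrix file: {path}")
        try:
            df = df.apply(pd.to_numeric)
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"non-numeric entry in {path}: {exc}") from exc
        values = df.to_numpy()
        feature_ids = [str(x) for x in df.index]
        barcodes = [str(x) for x in df.columns]

    if orientation == "cells_by_features":
        values = values.T
        feature_ids, barcodes = barcodes, feature_ids
    elif orientation != "features_by_cells":
        raise ValueError(f"unknown orientation {orientation!r}")

    return CountMatrix(np.asarray(values), feature_ids, barcodes, modality)


def compute_gene_stats(m: CountMatrix) -> GeneStats:
    """Total expression T_i = sum_j m_ij and sparsity SP_i = #{j: m_ij != 0}."""
    total = m.values.sum(axis=1)
    sparsity = np.count_nonzero(m.values, axis=1)
    return GeneStats(total, sparsity, list(m.feature_ids))


def screen_genes(
    m: CountMatrix,
    stats: GeneStats | None = None,
    t_frac: float = 0.01,
    sp_frac: float = 0.05,
) -> CountMatrix:
    """Keep genes with T > t_frac*J and SP > sp_frac*J (strict inequalities).

    The defaults correspond to a cord-blood-style run where kept genes are
    expressed in more than 5% of cells; bone-marrow-style runs use
    ``sp_frac=0.01``.
    """
    if not (0 <= t_frac <= 1 and 0 <= sp_frac <= 1):
        raise ValueError("t_frac and sp_frac must lie in [0, 1]")
    if stats is None:
        stats = compute_gene_stats(m)
    j = m.n_cells
    keep = (stats.total_expression > t_frac * j) & (stats.sparsity > sp_frac * j)
    if not keep.any():
        raise ValidationError(
            "gene screening removed every gene; relax qc.t_frac / qc.sp_frac"
        )
    logger.info("screen_genes: kept %d of %d genes (J=%d)", keep.sum(), m.n_features, j)
    return m.subset_features(keep)


def top_cv_features(m: CountMatrix, prefix: str, n: int = 100) -> list[str]:
    """Feature ids with the largest coefficient of variation among ``prefix``-ids.

    CV = sd/mean across cells (sd with n_samples-1 degrees of freedom);
    zero-mean features are excluded; ties break lexicographically on id.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    idx = [i for i, f in enumerate(m.feature_ids) if f.startswith(prefix)]
    if not idx:
        logger.warning("top_cv_features: no feature matches prefix %r", prefix)
        return []
    sub = m.values[idx].astype(float)
    means = sub.mean(axis=1)
    sds = sub.std(axis=1, ddof=1)
    rows = [
        (-(sds[r] / means[r]), m.feature_ids[idx[r]])
        for r in range(len(idx))
        if means[r] > 0
    ]
    rows.sort()
    return [fid for _, fid in rows[:n]]


def drop_adts(q: CountMatrix, names: list[str], strict: bool = False) -> CountMatrix:
    """Remove the listed (e.g. contaminated, non-binding) ADTs.

    Unknown names warn by default; ``strict=True`` raises instead.
    """
    if q.modality != "adt":
        raise ValidationError("drop_adts expects an ADT matrix")
    if not names:
        return q
    known = set(q.feature_ids)
    unknown = [name for name in names if name not in known]
    if unknown:
        msg = f"drop_adts: unknown ADT name(s) {unknown}"
        if strict:
            raise ValidationError(msg)
        logger.warning(msg)
    dropset = set(names) - set(unknown)
    keep = np.array([f not in dropset for f in q.feature_ids])
    if not keep.any():
        raise ValidationError("dropping these ADTs would remove every ADT")
    if keep.all():
        return q
    return q.subset_features(keep)


#: contaminated antibody conjugates removed in cord-blood-style runs
CBMC_CONTAMINATED_ADTS = ["CCR7", "CCR5", "CD10"]
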