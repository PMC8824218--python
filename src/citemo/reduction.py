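"""Per-modality PCA, elbow-based component selection, and PCA-of-PCs integration.

The integration recipe is deliberately linear and symmetric: each modality
is reduced by PCA on its [0,1]-scaled matrix, the two low-dimensional
representations are themselves MinMax-rescaled per component, stacked
row-wise, and reduced by PCA once more.  Using the same algorithm at every
stage avoids mixing artefacts of different reduction methods into the fused
representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .io_screening import ValidationError
from .normalization import NormalizedMatrix, minmax_rows

#: above this (cells * features) size the randomized SVD solver is used
_RANDOMIZED_THRESHOLD = 5_000_000


@dataclass
class LowDimRep:
    """Components x cells scores with explained variance and loadings.

    ``explained_variance`` uses n_samples-1 degrees of freedom.  ``loadings``
    maps input features to components (features x k); it is the identity for
    the ADT passthrough mode, where the scaled ADT matrix itself serves as
    the representation.
    """

    components: np.ndarray  # k x cells
    explained_variance: np.ndarray  # length k
    modality: str  # rna | adt | multimodal
    cell_barcodes: list[str]
    loadings: np.ndarray | None = None  # features x k
    from_pca: bool = True
    component_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        self.explained_variance = np.asarray(self.explained_variance, dtype=float)
        if not np.all(np.isfinite(self.components)):
            raise ValidationError("non-finite component scores")
        if self.from_pca and np.any(np.diff(self.explained_variance) > 1e-12):
            raise ValidationError("explained variance must be non-increasing")
        if not self.component_ids:
            self.component_ids = [f"PC{i + 1}" for i in range(self.k)]

    @property
    def k(self) -> int:
        return self.components.shape[0]

    @property
    def n_cells(self) -> int:
        return self.components.shape[1]

    def truncate(self, k: int) -> "LowDimRep":
        return LowDimRep(
            self.components[:k],
            self.explained_variance[:k],
            self.modality,
            self.cell_barcodes,
            None if self.loadings is None else self.loadings[:, :k],
            self.from_pca,
            self.component_ids[:k],
        )


def _sign_fix(loadings: np.ndarray, scores: np.ndarray) -> None:
    """Flip each component so its largest-|value| loading is positive (in place)."""
    for c in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[j, c] < 0:
            loadings[:, c] *= -1
            scores[c, :] *= -1


def pca_reduce(
    x: NormalizedMatrix,
    k: int | str = "all",
    seed: int = 0,
    passthrough: bool = False,
) -> LowDimRep:
    """PCA over cells (samples) on a scaled feature x cell matrix.

    Features are mean-centered across cells before decomposition; no
    unit-variance scaling.  Sign ambiguity is resolved by making the loading
    of largest absolute value positive in every component, which makes
    repeated runs bit-identical.  With ``passthrough`` (an ADT matrix with
    few features) the scaled matrix itself is returned unchanged as the
    representation.
    """
    values = x.values
    n_features, n_cells = values.shape
    modality = "multimodal" if x.source_modality == "multimodal_rep" else x.source_modality

    if passthrough:
        if modality != "adt":
            raise ValidationError("passthrough mode is defined for the ADT modality")
        return LowDimRep(
            values.copy(),
            values.var(axis=1, ddof=1),
            modality,
            x.cell_barcodes,
            np.eye(n_features),
            from_pca=False,
            component_ids=list(x.feature_ids),
        )

    if n_cells < 2:
        raise ValidationError("PCA needs at least 2 cells")
    n_comp = min(n_features, n_cells - 1) if k == "all" else int(k)
    if n_comp > n_features:
        raise ValidationError(f"k={n_comp} exceeds the {n_features} available features")
    if values.var(axis=1).max() == 0:
        raise ValidationError("zero-variance input: every feature is constant")

    solver = "randomized" if values.size > _RANDOMIZED_THRESHOLD and n_comp < min(
        n_features, n_cells
    ) // 2 else "full"
    pca = PCA(n_components=n_comp, svd_solver=solver, random_state=seed)
    scores = pca.fit_transform(values.T).T  # k x cells
    loadings = pca.components_.T.copy()  # features x k
    _sign_fix(loadings, scores)
    return LowDimRep(
        scores,
        pca.explained_variance_,
        modality,
        x.cell_barcodes,
        loadings,
    )


def elbow_select(explained_variance: np.ndarray) -> int:
    """Component count at the elbow of the explained-variance curve.

    Kneedle-style rule: the elbow is the point of maximum perpendicular
    distance to the chord joining the first and last variance values;
    components strictly before it are kept.  Degenerate curves with no
    curvature return 1.  The automatic choice is meant as a starting point —
    any configured k overrides it.
    """
    ev = np.asarray(explained_variance, dtype=float)
    if ev.ndim != 1 or len(ev) < 3:
        raise ValidationError(
            "elbow selection needs >= 3 variance values; set k manually"
        )
    n = len(ev)
    x = np.arange(n, dtype=float)
    dx, dy = n - 1.0, ev[-1] - ev[0]
    norm = np.hypot(dx, dy)
    dist = np.abs(dy * x - dx * (ev - ev[0])) / norm
    return max(int(np.argmax(dist)), 1)


def integrate(
    rna_rep: LowDimRep,
    adt_rep: LowDimRep,
    k: int | str = "auto",
    seed: int = 0,
) -> LowDimRep:
    """Fuse two per-modality representations by rescale-stack-PCA.

    Each representation is MinMax-rescaled per component to [0, 1], the two
    are stacked row-wise, and PCA is applied to the stack.  ``k="auto"``
    picks the multimodal component count by the elbow rule.
    """
    if rna_rep.cell_barcodes != adt_rep.cell_barcodes:
        raise ValidationError(
            "cell order differs between the RNA and ADT representations; "
            "no silent reindexing is performed"
        )
    blocks = [
        minmax_rows(rep.components)
        for rep in (rna_rep, adt_rep)
        if rep.k > 0
    ]
    if not blocks:
        raise ValidationError("both representations are empty")
    stacked = np.vstack(blocks)
    ids = [f"RNA_{c}" for c in rna_rep.component_ids] + [
        f"ADT_{c}" for c in adt_rep.component_ids
    ]
    x = NormalizedMatrix(stacked, "scaled", "multimodal_rep", ids, rna_rep.cell_barcodes)
    full = pca_reduce(x, k="all", seed=seed)
    if k == "auto":
        # floor of 2 keeps the representation embeddable in 2-D downstream
        k = max(elbow_select(full.explained_variance), 2) if full.k >= 3 else full.k
    k = min(int(k), full.k)
    return full.truncate(k)
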