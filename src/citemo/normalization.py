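"""Modality-specific normalization and MinMax rescaling.

RNA counts get a log(1+x) transform; ADT counts get a centred log ratio
(CLR) transform per ADT across cells, making the compositional antibody
counts comparable between cells.  Both are then rescaled per feature to
[0, 1] so the two modalities share a data range before PCA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_screening import CountMatrix, ValidationError

STAGES = ("log_rna", "clr_adt", "scaled")


@dataclass
class NormalizedMatrix:
    """Continuous feature x cell values after log / CLR / MinMax transform."""

    values: np.ndarray
    stage: str
    source_modality: str
    feature_ids: list[str]
    cell_barcodes: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.stage not in STAGES:
            raise ValidationError(f"stage must be one of {STAGES}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("normalized matrix contains non-finite values")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


def log_normalize(m: CountMatrix) -> NormalizedMatrix:
    """Natural log(1 + count), elementwise.

    The +1 pseudocount keeps the many zero UMI counts at exactly 0 after the
    transform, which in turn pins the global minimum of the log-normalized
    matrix at 0 — the property the later MinMax step relies on.
    """
    if m.modality != "rna":
        raise ValidationError("log_normalize expects an RNA matrix")
    return NormalizedMatrix(
        np.log1p(m.values.astype(float)), "log_rna", "rna", m.feature_ids, m.cell_barcodes
    )


def clr_transform(q: CountMatrix, pseudocount: float = 1.0) -> NormalizedMatrix:
    """Centred log ratio per ADT across cells: ln((q+c)/g) with g the geometric mean.

    Each ADT row of the output sums to zero over cells.  A pseudocount > 0 is
    required whenever any count is zero, since ln(0) is undefined.
    """
    if q.modality != "adt":
        raise ValidationError("clr_transform expects an ADT matrix")
    shifted = q.values.astype(float) + pseudocount
    if np.any(shifted <= 0):
        raise ValidationError(
            "zero counts with pseudocount 0 make the CLR log undefined; "
            "set norm.clr_pseudocount > 0"
        )
    logs = np.log(shifted)
    centred = logs - logs.mean(axis=1, keepdims=True)  # ln(x/g) = ln x - mean(ln x)
    return NormalizedMatrix(centred, "clr_adt", "adt", q.feature_ids, q.cell_barcodes)


def minmax_rows(values: np.ndarray, literal_shift: bool = False) -> np.ndarray:
    """Per-row rescale (x - min_i)/(max_i - min_i); constant rows map to 0.

    With ``literal_shift`` the global minimum of the whole input matrix is
    added back after rescaling.  When that global minimum is 0 (always true
    for log1p RNA) the term is a no-op and the output lies in [0, 1]; for
    CLR input the global minimum is negative and the shift moves values
    below 0, so the default omits it.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("cannot MinMax-scale an empty matrix")
    lo = values.min(axis=1, keepdims=True)
    hi = values.max(axis=1, keepdims=True)
    span = hi - lo
    constant = span[:, 0] == 0
    span[constant] = 1.0
    out = (values - lo) / span
    out[constant] = 0.0
    if literal_shift:
        out = out + values.min()
    return out


def minmax_scale(x: NormalizedMatrix, literal_shift: bool = False) -> NormalizedMatrix:
    """MinMax rescale each feature across cells to [0, 1] (stage ``scaled``)."""
    return NormalizedMatrix(
        minmax_rows(x.values, literal_shift=literal_shift),
        "scaled",
        x.source_modality,
        x.feature_ids,
        x.cell_barcodes,
    )
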