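"""One-vs-rest Wilcoxon differential analysis of genes and ADTs per cluster.

Each cluster is contrasted against all remaining cells with the rank-sum
(Mann-Whitney) test, normal approximation with tie correction, followed by
Benjamini-Hochberg adjustment across features within the cluster.  Because
the one-vs-rest groups are independent samples, the rank-sum form is the
default; a signed-rank variant is kept for genuinely paired equal-size
groups.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats

from .clustering import ClusterAssignment
from .io_screening import ValidationError
from .normalization import NormalizedMatrix

logger = logging.getLogger("citemo")

_LFC_PSEUDO = 1e-9


def _ranksum_pvalues(xin: np.ndarray, xout: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sided Mann-Whitney U with tie-corrected normal approximation."""
    res = scipy.stats.mannwhitneyu(xin, xout, axis=1, method="asymptotic")
    stat, p = np.asarray(res.statistic, dtype=float), np.asarray(res.pvalue, dtype=float)
    # a feature constant across both groups carries no information: U = n1*n2/2, p = 1
    n1, n2 = xin.shape[1], xout.shape[1]
    flat = (xin.min(axis=1) == xin.max(axis=1)) & (xout.min(axis=1) == xout.max(axis=1)) & (
        xin[:, 0] == xout[:, 0]
    )
    stat[flat] = n1 * n2 / 2.0
    p[flat] = 1.0
    return stat, np.clip(p, 0.0, 1.0)


def _signedrank_pvalues(xin: np.ndarray, xout: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if xin.shape[1] != xout.shape[1]:
        raise ValidationError(
            "signed-rank test needs equal-size paired groups; use de.test=ranksum"
        )
    stats = np.empty(xin.shape[0])
    ps = np.empty(xin.shape[0])
    for i in range(xin.shape[0]):
        d = xin[i] - xout[i]
        if np.all(d == 0):
            stats[i], ps[i] = 0.0, 1.0
        else:
            r = scipy.stats.wilcoxon(xin[i], xout[i], zero_method="wilcox")
            stats[i], ps[i] = r.statistic, r.pvalue
    return stats, ps


def wilcoxon_de(
    x: NormalizedMatrix,
    clusters: ClusterAssignment,
    min_cells: int = 3,
    test: str = "ranksum",
) -> pd.DataFrame:
    """One-vs-rest differential test of every feature in every cluster.

    Returns one row per (cluster, feature) with the U statistic, raw and
    BH-adjusted p-values, base-2 log fold change of the within/without means
    (computed on the normalized pre-scale values), sorted by adjusted p then
    |log fold change| within each cluster.
    """
    if x.n_cells != len(clusters.labels):
        raise ValidationError("matrix and cluster assignment cover different cells")
    n_clusters = clusters.n_clusters
    if n_clusters < 2:
        raise ValidationError("differential analysis needs >= 2 clusters (no rest group)")
    testers = {"ranksum": _ranksum_pvalues, "signedrank": _signedrank_pvalues}
    if test not in testers:
        raise ValueError(f"de.test must be one of {sorted(testers)}")

    frames = []
    for c in range(n_clusters):
        mask = clusters.labels == c
        if mask.sum() < min_cells:
            logger.warning("cluster %d has < %d cells; skipped", c, min_cells)
            continue
        xin, xout = x.values[:, mask], x.values[:, ~mask]
        stat, p = testers[test](xin, xout)
        p_adj = scipy.stats.false_discovery_control(p, method="bh")
        mean_in, mean_out = xin.mean(axis=1), xout.mean(axis=1)
        # CLR values are centred around 0, so fold changes are taken on the
        # exponentiated (ratio-to-geometric-mean) scale, which is positive
        if x.stage == "clr_adt":
            fin, fout = np.exp(xin).mean(axis=1), np.exp(xout).mean(axis=1)
        else:
            fin, fout = mean_in, mean_out
        lfc = np.log2((fin + _LFC_PSEUDO) / (fout + _LFC_PSEUDO))
        df = pd.DataFrame(
            {
                "cluster": c,
                "feature": x.feature_ids,
                "modality": x.source_modality,
                "statistic": stat,
                "pvalue": p,
                "pvalue_adj": p_adj,
                "log2fc": lfc,
                "mean_in": mean_in,
                "mean_out": mean_out,
            }
        )
        df = df.sort_values(
            ["pvalue_adj", "log2fc"],
            key=lambda s: s.abs() if s.name == "log2fc" else s,
            ascending=[True, False],
        )
        frames.append(df)
    if not frames:
        raise ValidationError(f"no cluster reaches min_cells={min_cells}")
    return pd.concat(frames, ignore_index=True)
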