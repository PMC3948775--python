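"""Per-edge group correlations and the Fisher z-difference statistic.

For every edge (gene pair) of the interaction network, the Pearson
correlation of the two genes' log-CPM values is computed separately within
each sample group, variance-stabilized with the Fisher r-to-z transform

    z = 1/2 * ln((1 + r) / (1 - r)) = arctanh(r),

and the group difference z_diff = z_first - z_second is the statistic whose
permutation distribution decides differential co-expression.  Correlations
of exactly +/-1 (possible with five samples per group) are clamped just
inside the open interval so z stays finite and perfect correlations rank
above all others.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .expression import CountMatrix, ExpressionMatrix
from .network import InteractionNetwork

logger = logging.getLogger(__name__)

DEFAULT_CLAMP = 1.0 - 1e-7


def pearson(x, y) -> float:
    """Sample Pearson correlation of two sequences.

    Returns NaN (the explicit "undefined" marker) when either sequence has
    zero variance; raises on length mismatch or fewer than 3 points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("correlation requires at least 3 points")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0.0:
        return float("nan")
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def fisher_z(r: float, clamp: float = DEFAULT_CLAMP):
    """Fisher r-to-z transform, arctanh(r), with |r| clamped to `clamp`."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r[np.isfinite(r)]) > 1.0):
        raise ValueError("correlation outside [-1, 1]")
    out = np.arctanh(np.clip(r, -clamp, clamp))
    if out.ndim == 0:
        return float(out)
    return out


def _group_corr(values: np.ndarray, cols: np.ndarray, ia: np.ndarray, ib: np.ndarray) -> np.ndarray:
    """Pearson r for each edge (ia[k], ib[k]) over the sample columns `cols`.

    Vectorized over edges: rows are centered within the group and the edge
    correlation is the normalized dot product of the two genes' centered
    expression vectors.  Zero-variance genes yield NaN.
    """
    sub = values[:, cols]
    c = sub - sub.mean(axis=1, keepdims=True)
    norms = np.sqrt((c**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.einsum("ij,ij->i", c[ia], c[ib]) / (norms[ia] * norms[ib])
    return np.clip(r, -1.0, 1.0)


def edge_index_arrays(em_genes: list[str], net: InteractionNetwork):
    """Sorted edge list of `net` as row-index arrays into the expression matrix."""
    gene_pos = {g: i for i, g in enumerate(em_genes)}
    edges = sorted(net.edges)
    missing = [e for e in edges if e[0] not in gene_pos or e[1] not in gene_pos]
    if missing:
        raise ValueError(
            f"{len(missing)} network edge(s) reference genes absent from the "
            f"expression matrix (first: {missing[0]}); run trim_to_genes first"
        )
    ia = np.array([gene_pos[a] for a, _ in edges], dtype=np.intp)
    ib = np.array([gene_pos[b] for _, b in edges], dtype=np.intp)
    return edges, ia, ib


def group_columns(em: ExpressionMatrix, cm: CountMatrix) -> dict[str, np.ndarray]:
    sample_pos = {s: i for i, s in enumerate(em.samples)}
    out = {}
    for lab in cm.group_labels:
        cols = np.array([sample_pos[s] for s in cm.samples_in_group(lab)], dtype=np.intp)
        if cols.size < 3:
            raise ValueError(f"group {lab!r} has fewer than 3 samples")
        out[lab] = cols
    return out


def edge_statistics(
    em: ExpressionMatrix,
    cm: CountMatrix,
    net: InteractionNetwork,
    clamp: float = DEFAULT_CLAMP,
) -> pd.DataFrame:
    """Per-edge group correlations, Fisher z-scores, and z-difference.

    Returns one row per network edge with columns gene_a, gene_b,
    r_<first>, r_<second>, z_<first>, z_<second>, z_diff, valid, where
    (first, second) are the two group labels in analysis orientation
    (z_diff = z_first - z_second).  Edges with an undefined correlation in
    either group are flagged valid=False and excluded downstream.
    """
    values = em.values.to_numpy()
    edges, ia, ib = edge_index_arrays(em.genes, net)
    cols = group_columns(em, cm)
    first, second = cm.group_labels

    r1 = _group_corr(values, cols[first], ia, ib)
    r2 = _group_corr(values, cols[second], ia, ib)
    valid = np.isfinite(r1) & np.isfinite(r2)
    z1 = np.where(valid, np.arctanh(np.clip(r1, -clamp, clamp)), np.nan)
    z2 = np.where(valid, np.arctanh(np.clip(r2, -clamp, clamp)), np.nan)
    n_invalid = int((~valid).sum())
    if n_invalid:
        logger.info("%d edge(s) have undefined correlation in a group", n_invalid)

    return pd.DataFrame(
        {
            "gene_a": [a for a, _ in edges],
            "gene_b": [b for _, b in edges],
            f"r_{first}": r1,
            f"r_{second}": r2,
            f"z_{first}": z1,
            f"z_{second}": z2,
            "z_diff": z1 - z2,
            "valid": valid,
        }
    )


def write_edge_statistics(stats: pd.DataFrame, path) -> None:
    stats.to_csv(path, sep="\t", index=False, float_format="%.10g")
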