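"""Permutation null distributions and the two-criterion significance filter.

The null model reshuffles the sample-to-group labels (without replacement,
preserving the two group sizes) on the fixed normalized expression matrix,
recomputing every edge's pseudo-group correlations and z-difference for
each of N reshuffles.  An edge is called significant when

  (i)  its |z_diff| has empirical p < alpha against its own permuted
       z-differences, and
  (ii) at least one of its two group correlations has empirical p < alpha
       against the pooled permuted pseudo-group correlations of that edge.

Empirical p-values are two-sided counts, p = #{|null| >= |observed|} / N
(``count_over_N``); an ``add_one`` mode, (1 + count) / (N + 1), avoids
exact zeros.  Everything is a pure function of (matrix, network, config):
one seeded generator drives the label reshuffles, so results are
bit-reproducible and independent of how the permutations are chunked
across workers.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .edge_stats import _group_corr, edge_index_arrays, group_columns
from .expression import CountMatrix, ExpressionMatrix
from .network import InteractionNetwork

P_MODES = ("count_over_N", "add_one")


@dataclass
class PermutationConfig:
    n_perm: int = 10_000
    seed: int = 0
    alpha: float = 0.05
    p_mode: str = "count_over_N"
    clamp: float = 1.0 - 1e-7
    n_workers: int = 1

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.p_mode not in P_MODES:
            raise ValueError(f"p_mode must be one of {P_MODES}")


@dataclass
class NullDistributions:
    """Per-edge permutation null samples.

    Arrays are edges x n_perm, in the sorted-edge order of the network the
    statistics were computed on; ``r_first``/``r_second`` hold the permuted
    pseudo-group correlations for the two label positions.
    """

    edges: list
    z_diff: np.ndarray
    r_first: np.ndarray
    r_second: np.ndarray
    group_order: tuple[str, str]
    seed: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_perm(self) -> int:
        return self.z_diff.shape[1]


def permute_labels(sample_ids, group_sizes: tuple[int, int], rng: np.random.Generator):
    """One uniformly random partition of samples into groups of the given sizes.

    Returns (group1_ids, group2_ids); every sample appears exactly once.
    """
    n1, n2 = group_sizes
    sample_ids = list(sample_ids)
    if n1 + n2 != len(sample_ids):
        raise ValueError(
            f"group sizes {n1}+{n2} do not sum to the number of samples {len(sample_ids)}"
        )
    perm = rng.permutation(len(sample_ids))
    g1 = [sample_ids[i] for i in perm[:n1]]
    g2 = [sample_ids[i] for i in perm[n1:]]
    return g1, g2


def _assignment_matrix(n_samples: int, n1: int, n_perm: int, seed: int) -> np.ndarray:
    """Precompute all label reshuffles from one seeded stream (n_perm x n_samples)."""
    rng = np.random.default_rng(seed)
    out = np.empty((n_perm, n_samples), dtype=np.intp)
    for i in range(n_perm):
        out[i] = rng.permutation(n_samples)
    return out


def build_null(
    em: ExpressionMatrix,
    cm: CountMatrix,
    net: InteractionNetwork,
    cfg: PermutationConfig,
) -> NullDistributions:
    """Per-edge null samples of z_diff and both pseudo-group correlations.

    Normalization is not redone per permutation: labels are reshuffled on the
    fixed log-CPM matrix.  Fully determined by ``cfg.seed``; the worker count
    only chunks the precomputed reshuffles and cannot change the result.
    """
    values = em.values.to_numpy()
    edges, ia, ib = edge_index_arrays(em.genes, net)
    cols = group_columns(em, cm)
    first, second = cm.group_labels
    # canonical (matrix-order) pooling: with equal group sizes this makes the
    # null — and hence the significant-edge set — exactly invariant under
    # swapping the two group labels
    pooled = np.sort(np.concatenate([cols[first], cols[second]]))
    n1 = cols[first].size
    n_edges = len(edges)

    assign = _assignment_matrix(pooled.size, n1, cfg.n_perm, cfg.seed)

    z_diff = np.empty((n_edges, cfg.n_perm))
    r1_null = np.empty((n_edges, cfg.n_perm))
    r2_null = np.empty((n_edges, cfg.n_perm))

    def run_chunk(lo: int, hi: int) -> None:
        for p in range(lo, hi):
            perm_cols = pooled[assign[p]]
            r1 = _group_corr(values, perm_cols[:n1], ia, ib)
            r2 = _group_corr(values, perm_cols[n1:], ia, ib)
            r1_null[:, p] = r1
            r2_null[:, p] = r2
            z_diff[:, p] = np.arctanh(np.clip(r1, -cfg.clamp, cfg.clamp)) - np.arctanh(
                np.clip(r2, -cfg.clamp, cfg.clamp)
            )

    if cfg.n_workers <= 1:
        run_chunk(0, cfg.n_perm)
    else:
        bounds = np.linspace(0, cfg.n_perm, cfg.n_workers + 1).astype(int)
        with ThreadPoolExecutor(max_workers=cfg.n_workers) as ex:
            futures = [
                ex.submit(run_chunk, int(lo), int(hi))
                for lo, hi in zip(bounds[:-1], bounds[1:])
            ]
            for f in futures:
                f.result()

    return NullDistributions(
        edges=edges,
        z_diff=z_diff,
        r_first=r1_null,
        r_second=r2_null,
        group_order=(first, second),
        seed=cfg.seed,
    )


def empirical_p(observed: float, null_sample, mode: str = "count_over_N") -> float:
    """Two-sided empirical p of `observed` against its permutation null."""
    null_sample = np.asarray(null_sample, dtype=float)
    if null_sample.size == 0:
        raise ValueError("null sample is empty")
    if mode not in P_MODES:
        raise ValueError(f"unknown p mode: {mode!r}")
    count = int(np.sum(np.abs(null_sample) >= abs(observed)))
    if mode == "count_over_N":
        return count / null_sample.size
    return (1 + count) / (null_sample.size + 1)


def _empirical_p_rows(observed: np.ndarray, null_rows: np.ndarray, mode: str) -> np.ndarray:
    """Row-wise two-sided empirical p (one observed value per row of nulls)."""
    counts = np.sum(np.abs(null_rows) >= np.abs(observed)[:, None], axis=1)
    if mode == "count_over_N":
        return counts / null_rows.shape[1]
    return (1 + counts) / (null_rows.shape[1] + 1)


def significant_interactions(
    stats: pd.DataFrame,
    null: NullDistributions,
    cfg: PermutationConfig,
) -> pd.DataFrame:
    """Apply the two-criterion filter and attach empirical p-values.

    The z-difference is tested against the edge's own permuted z-differences;
    each group correlation is tested against the pooled permuted pseudo-group
    correlations of that edge (both label positions pooled, since under
    reshuffling the two pseudo-groups are exchangeable).  Invalid edges
    (undefined correlation) are excluded.
    """
    first, second = null.group_order
    stat_edges = list(zip(stats["gene_a"], stats["gene_b"]))
    if stat_edges != null.edges:
        raise ValueError("statistics and null distributions cover different edges")

    r_pool = np.concatenate([null.r_first, null.r_second], axis=1)
    # permutations can produce undefined pseudo-group correlations for
    # zero-variance genes; those never out-rank a finite observation
    r_pool = np.nan_to_num(r_pool, nan=0.0)
    z_null = np.nan_to_num(null.z_diff, nan=0.0)

    p_zdiff = _empirical_p_rows(stats["z_diff"].to_numpy(), z_null, cfg.p_mode)
    p_r1 = _empirical_p_rows(stats[f"r_{first}"].to_numpy(), r_pool, cfg.p_mode)
    p_r2 = _empirical_p_rows(stats[f"r_{second}"].to_numpy(), r_pool, cfg.p_mode)

    out = stats.copy()
    out["p_zdiff"] = p_zdiff
    out[f"p_r_{first}"] = p_r1
    out[f"p_r_{second}"] = p_r2
    sig = (
        out["valid"]
        & (p_zdiff < cfg.alpha)
        & ((p_r1 < cfg.alpha) | (p_r2 < cfg.alpha))
    )
    out["significant"] = sig
    invalid = ~out["valid"].to_numpy()
    out.loc[invalid, ["p_zdiff", f"p_r_{first}", f"p_r_{second}"]] = np.nan
    return out
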