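"""Hypergeometric pathway over-representation of significant interactions.

The unit of enrichment is the interaction (edge), not the gene: the
universe is the set of pathway-annotated edges of the trimmed network
(size M), of which K belong to a given pathway; drawing the n annotated
significant edges, the pathway's p-value is the upper-tail probability of
seeing at least the observed k pathway members,

    p = P(X >= k),  X ~ Hypergeometric(M, K, n).

A ``paper_compat`` mode instead computes 1 - P(X <= k) = P(X > k),
reproducing the one-minus-lower-tail arithmetic some pipelines apply to R's
``phyper``; it equals the standard tail evaluated at k + 1.  P-values are
Benjamini-Hochberg adjusted across pathways, with p_adj < 0.05 flagged as
enriched, and each record carries the split of its significant edges into
first-group- and second-group-driven interactions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .network import InteractionNetwork, edge_key

MODES = ("standard", "paper_compat")


def hypergeom_upper(k: int, K: int, n: int, M: int, mode: str = "standard") -> float:
    """Upper-tail hypergeometric probability for pathway over-representation.

    Population of M edges, K in the pathway, n drawn (significant);
    standard mode returns P(X >= k), paper_compat returns 1 - P(X <= k).
    """
    if not (0 <= K <= M and 0 <= n <= M and 0 <= k <= min(K, n)):
        raise ValueError(
            f"invalid hypergeometric parameters k={k}, K={K}, n={n}, M={M}"
        )
    if mode == "standard":
        return float(sps.hypergeom.sf(k - 1, M, K, n))
    if mode == "paper_compat":
        return float(sps.hypergeom.sf(k, M, K, n))
    raise ValueError(f"unknown mode: {mode!r} (expected one of {MODES})")


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_pathways(
    classified: pd.DataFrame,
    net: InteractionNetwork,
    mode: str = "standard",
    alpha: float = 0.05,
    group_order: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Per-pathway enrichment of classified significant edges.

    ``classified`` must carry gene_a, gene_b and corr_type columns and its
    edges must be a subset of ``net``'s.  Multi-pathway edges count toward
    every pathway they carry.  Returns one record per pathway with at least
    one universe edge, sorted by k descending then adjusted p.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode: {mode!r}")
    universe = {e: pws for e, pws in net.edge_pathways.items() if pws}
    if not universe:
        raise ValueError("no pathway-annotated edges in the network (empty universe)")
    M = len(universe)

    sig_edges = [edge_key(a, b) for a, b in zip(classified["gene_a"], classified["gene_b"])]
    unknown = [e for e in sig_edges if e not in net.edge_pathways]
    if unknown:
        raise ValueError(f"significant edge {unknown[0]} is not in the network")
    corr_type = dict(zip(sig_edges, classified["corr_type"]))
    # draws: significant edges that carry >= 1 pathway annotation
    drawn = [e for e in sig_edges if e in universe]
    n = len(drawn)

    if group_order is None:
        prefixes = ("LA", "HA")
    else:
        prefixes = group_order

    pathway_edges: dict[str, list] = {}
    for e, pws in universe.items():
        for pw in pws:
            pathway_edges.setdefault(pw, []).append(e)

    records = []
    for pw in sorted(pathway_edges):
        members = pathway_edges[pw]
        K = len(members)
        hits = [e for e in drawn if pw in universe[e]]
        k = len(hits)
        n_first = sum(1 for e in hits if corr_type[e].startswith(prefixes[0]))
        n_second = sum(1 for e in hits if corr_type[e].startswith(prefixes[1]))
        records.append(
            {
                "pathway_id": pw,
                "name": net.pathway_names.get(pw, pw),
                "M": M,
                "K": K,
                "n": n,
                "k": k,
                "p_raw": hypergeom_upper(k, K, n, M, mode=mode),
                f"n_{prefixes[0]}": n_first,
                f"n_{prefixes[1]}": n_second,
            }
        )
    df = pd.DataFrame(records)
    df["p_adj"] = bh_adjust(df["p_raw"].to_numpy())
    df["enriched"] = df["p_adj"] < alpha
    df = df.sort_values(["k", "p_adj", "pathway_id"], ascending=[False, True, True])
    return df.reset_index(drop=True)


def write_enrichment(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
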