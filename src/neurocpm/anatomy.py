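"""Network anatomy of the predictive edge masks.

Because cross-validation selects a slightly different edge set per fold,
the anatomy of a predictive network is summarized — for illustration only —
from a single selection on the full sample: node degree within each mask,
high-degree ("hub") nodes above a degree cutoff, and the canonical-network
membership of the top-N highest-degree nodes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from neurocpm.connectome import edge_pairs, n_edges
from neurocpm.core import EdgeSelection, correlate_edges, correlate_edges_adjusted, select_edges
from neurocpm.errors import InvalidInputError

__all__ = [
    "full_sample_networks",
    "high_degree_nodes",
    "mask_edge_table",
    "node_degree",
    "summarize_canonical",
]


def full_sample_networks(edges, behavior, threshold: float = 0.01,
                         covariates=None) -> EdgeSelection:
    """Edge selection computed once on the entire sample.

    This is the illustrative full-sample network definition, not the
    cross-validated feature set; it must never feed back into prediction.
    """
    if covariates is None:
        r, p = correlate_edges(edges, behavior)
    else:
        r, p = correlate_edges_adjusted(edges, behavior, covariates)
    return select_edges(r, p, threshold)


def _k_for_mask(mask: np.ndarray, k: int | None) -> int:
    e = mask.size
    if k is None:
        k = int(round((1 + np.sqrt(1 + 8 * e)) / 2))
    if n_edges(k) != e:
        raise InvalidInputError(f"mask length {e} does not equal K*(K-1)/2 for K={k}")
    return k


def node_degree(mask: np.ndarray, k: int | None = None) -> np.ndarray:
    """Number of selected edges incident to each node (length-K int vector)."""
    m = np.asarray(mask, dtype=bool)
    k = _k_for_mask(m, k)
    iu = np.triu_indices(k, 1)
    degree = np.zeros(k, dtype=int)
    np.add.at(degree, iu[0][m], 1)
    np.add.at(degree, iu[1][m], 1)
    return degree


def high_degree_nodes(degrees: np.ndarray, min_degree: int) -> list[int]:
    """Nodes with degree >= min_degree, sorted by degree descending then node id."""
    if min_degree < 1:
        raise InvalidInputError(f"min_degree must be >= 1, got {min_degree}")
    d = np.asarray(degrees, dtype=int)
    keep = np.flatnonzero(d >= min_degree)
    order = np.lexsort((keep, -d[keep]))
    return keep[order].tolist()


def _top_nodes(degrees: np.ndarray, top_n: int) -> np.ndarray:
    d = np.asarray(degrees, dtype=int)
    if not 1 <= top_n <= d.size:
        raise InvalidInputError(f"top_n must lie in 1..{d.size}, got {top_n}")
    # Ties at the boundary break toward the lower node id.
    order = np.lexsort((np.arange(d.size), -d))
    return order[:top_n]


def summarize_canonical(degrees: np.ndarray, labels, top_n: int = 20) -> pd.Series:
    """Canonical-network counts of the top-N highest-degree nodes.

    ``labels`` maps node index to a canonical-network name (dict, Series or
    array).  Counts sum to ``top_n``; an unlabeled node among the top N is a
    hard error.
    """
    top = _top_nodes(degrees, top_n)
    if isinstance(labels, pd.Series):
        lookup = labels.to_dict()
    elif isinstance(labels, dict):
        lookup = labels
    else:
        lookup = dict(enumerate(np.asarray(labels).tolist()))
    unlabeled = [int(v) for v in top
                 if v not in lookup or lookup[v] is None or pd.isna(lookup[v])]
    if unlabeled:
        raise InvalidInputError(f"nodes {unlabeled} in the top {top_n} have no canonical label")
    names = [str(lookup[int(v)]) for v in top]
    counts = pd.Series(names, dtype="object").value_counts().sort_index()
    counts.name = "n_nodes"
    return counts


def mask_edge_table(selection: EdgeSelection, tail: str, k: int | None = None) -> pd.DataFrame:
    """Edge list (node_i, node_j, r) for one tail of a selection."""
    mask = selection.mask(tail)
    k = _k_for_mask(np.asarray(mask, bool), k)
    pairs = np.asarray(edge_pairs(k))
    idx = np.flatnonzero(mask)
    return pd.DataFrame(
        {"node_i": pairs[idx, 0], "node_j": pairs[idx, 1], "r": selection.r[idx]}
    )
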