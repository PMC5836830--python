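"""Pair-level network/domain features and per-protein profile lookups.

The 7-dimensional pair feature vector for an edge (i, j) is, in order:

1. the edge weight ``w_ij``;
2. the larger of the maximal neighboring weights of i (excluding j) and of
   j (excluding i);
3. the smaller of the minimal neighboring weights of the two endpoints;
4. the maximum over common neighbors k of ``min(w_ik, w_jk)``;
5. the maximum absolute difference ``|w_ik1 - w_jk2|`` over all k1 != j
   neighboring i and k2 != i neighboring j;
6. the larger total domain count of the two proteins;
7. the smaller total domain count.

Every max/min over an empty index set evaluates to 0, which keeps the map
total on degree-1 endpoints and pairs without common neighbors.
"""

from __future__ import annotations

import numpy as np

from .data_model_io import Pair, ProfileTable, WeightedPPINetwork, canonical_pair

N_PAIR_FEATURES = 7

PAIR_FEATURE_NAMES = (
    "edge_weight",
    "max_neighbor_weight",
    "min_neighbor_weight",
    "max_common_neighbor_min",
    "max_cross_weight_diff",
    "max_domain_count",
    "min_domain_count",
)


def phi(table: ProfileTable, protein: str) -> np.ndarray:
    """Per-protein feature vector from a profile table (zero if unknown)."""
    return table.vector(protein)


def domain_count(table: ProfileTable, protein: str) -> int:
    """Total domain multiplicity of a protein (sum of its count vector)."""
    return int(table.vector(protein).sum())


def psi(network: WeightedPPINetwork, domain_table: ProfileTable, pair: Pair) -> np.ndarray:
    """Compute the 7-dimensional pair feature vector for a network edge."""
    i, j = pair
    key = canonical_pair(i, j)
    if key not in network.weights:
        raise ValueError(f"pair {pair!r} is not a network edge; f1 undefined")
    w_ij = network.weights[key]

    ni = {k: w for k, w in network.neighbors(i).items() if k != j}
    nj = {k: w for k, w in network.neighbors(j).items() if k != i}
    wi = np.fromiter(ni.values(), dtype=float) if ni else np.zeros(0)
    wj = np.fromiter(nj.values(), dtype=float) if nj else np.zeros(0)

    max_i = wi.max() if wi.size else 0.0
    max_j = wj.max() if wj.size else 0.0
    min_i = wi.min() if wi.size else 0.0
    min_j = wj.min() if wj.size else 0.0
    f2 = max(max_i, max_j)
    f3 = min(min_i, min_j)

    common = set(ni) & set(nj)
    f4 = max((min(ni[k], nj[k]) for k in common), default=0.0)

    if wi.size and wj.size:
        # max |u - v| over the cross product reduces to the extreme spreads
        f5 = max(wi.max() - wj.min(), wj.max() - wi.min())
    else:
        f5 = 0.0

    di = domain_count(domain_table, i)
    dj = domain_count(domain_table, j)

    return np.array([w_ij, f2, f3, f4, f5, max(di, dj), min(di, dj)], dtype=float)


def psi_matrix(
    network: WeightedPPINetwork, domain_table: ProfileTable, pairs: list[Pair]
) -> np.ndarray:
    """Stack pair feature vectors into an (n_pairs, 7) matrix."""
    if not pairs:
        return np.zeros((0, N_PAIR_FEATURES))
    return np.vstack([psi(network, domain_table, p) for p in pairs])


def write_psi_matrix(
    network: WeightedPPINetwork,
    domain_table: ProfileTable,
    pairs: list[Pair],
    path,
) -> None:
    """Export pair features as TSV for inspection."""
    mat = psi_matrix(network, domain_table, pairs)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein_a\tprotein_b\t" + "\t".join(f"f{i+1}" for i in range(N_PAIR_FEATURES)) + "\n")
        for (a, b), row in zip(pairs, mat):
            fh.write(f"{a}\t{b}\t" + "\t".join(repr(x) for x in row) + "\n")
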