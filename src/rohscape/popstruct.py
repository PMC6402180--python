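"""Population structure: IBS relationships, PCA, F_ST and k-NN networks.

The genetic relationship matrix G holds pairwise identity-by-state (IBS)
values: for a pair of individuals, the mean over mutually non-missing SNPs
of the fraction of shared alleles (0, 0.5 or 1 per SNP).  Genetic distance
is 1 - IBS.  The high-resolution network connects every individual to its
k nearest neighbors by that distance; node size encodes the individual's
genome-wide ROH coverage (S_ROH), node pie fractions its admixture
membership, and the node border its population of origin.

Between-group differentiation uses the Weir & Cockerham (1984)
variance-components F_ST estimator, combined across loci as a ratio of
sums.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, HET, MISSING


@dataclass
class RelationshipMatrix:
    """Symmetric n x n IBS similarity matrix with its sample order."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match sample count")

    def distance(self) -> np.ndarray:
        """Genetic distance: 1 - relationship."""
        return 1.0 - self.values


def ibs_matrix(g: GenotypeMatrix) -> RelationshipMatrix:
    """Pairwise allele-sharing IBS over mutually non-missing SNPs.

    Raises if any pair (including an individual with itself) has no
    overlapping non-missing SNP.
    """
    if g.n_samples < 2:
        raise ValueError("need at least two samples for an IBS matrix")
    dos = g.b_dosage().astype(np.int16)
    valid = dos >= 0
    n = g.n_samples
    out = np.empty((n, n), dtype=float)
    for i in range(n):
        diff = np.abs(dos - dos[i])  # (n, m)
        both = valid & valid[i]
        overlap = both.sum(axis=1)
        if np.any(overlap == 0):
            j = int(np.flatnonzero(overlap == 0)[0])
            raise ValueError(
                f"no overlapping non-missing SNPs for pair "
                f"({g.sample_ids[i]!r}, {g.sample_ids[j]!r})"
            )
        shared = np.where(both, 1.0 - diff / 2.0, 0.0).sum(axis=1)
        out[i] = shared / overlap
    # enforce exact symmetry against float accumulation order
    out = (out + out.T) / 2.0
    return RelationshipMatrix(values=out, sample_ids=g.sample_ids)


# ---------------------------------------------------------------------------
# PCA on the relationship matrix
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    coordinates: pd.DataFrame           # samples x components
    explained_variance_ratio: np.ndarray
    eigenvalues: np.ndarray
    degenerate: bool


def pca(rel: RelationshipMatrix, n_components: int | None = None) -> PCAResult:
    """Eigendecomposition of the double-centered relationship matrix.

    Components are ordered by decreasing eigenvalue; the variance fraction
    of a component is its eigenvalue over the sum of positive eigenvalues.
    A matrix with no positive eigenvalue (e.g. identical individuals) is
    flagged degenerate with all-zero fractions.
    """
    G = rel.values
    if not np.allclose(G, G.T, atol=1e-8):
        raise ValueError("relationship matrix is not symmetric")
    n = G.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    C = J @ G @ J
    C = (C + C.T) / 2.0
    eigval, eigvec = np.linalg.eigh(C)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    pos_sum = eigval[eigval > 0].sum()
    degenerate = not pos_sum > 1e-12
    ratio = np.where(eigval > 0, eigval, 0.0) / pos_sum if not degenerate else np.zeros(n)
    coords = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
    k = n_components or n
    frame = pd.DataFrame(
        coords[:, :k],
        index=pd.Index(rel.sample_ids, name="sample_id"),
        columns=[f"PC{i + 1}" for i in range(min(k, n))],
    )
    return PCAResult(
        coordinates=frame,
        explained_variance_ratio=ratio[:k],
        eigenvalues=eigval[:k],
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Weir & Cockerham F_ST
# ---------------------------------------------------------------------------

def _wc_components(
    n_i: np.ndarray, p_i: np.ndarray, h_i: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir & Cockerham (1984) variance components a, b, c.

    ``n_i``: individuals sampled per population (r x m), ``p_i``: allele
    frequency per population, ``h_i``: observed heterozygote frequency.
    """
    r = n_i.shape[0]
    n_bar = n_i.mean(axis=0)
    n_c = (r * n_bar - (n_i**2).sum(axis=0) / (r * n_bar)) / (r - 1)
    p_bar = (n_i * p_i).sum(axis=0) / (r * n_bar)
    s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (n_i * h_i).sum(axis=0) / (r * n_bar)

    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar)
        - (r - 1) / r * s2
        - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2.0
    return a, b, c


def _group_locus_stats(
    g: GenotypeMatrix, index: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    calls = g.calls[index]
    dos = g.b_dosage()[index].astype(float)
    nonmiss = calls != MISSING
    n = nonmiss.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, np.where(nonmiss, dos, 0.0).sum(axis=0) / (2 * n), np.nan)
        h = np.where(n > 0, (calls == HET).sum(axis=0) / n, np.nan)
    return n, p, h


def pairwise_fst(
    g: GenotypeMatrix, groups: Mapping[str, str] | pd.Series | None = None
) -> pd.DataFrame:
    """Pairwise Weir–Cockerham F_ST between subpopulations.

    The multi-locus estimate is the ratio of summed ``a`` components to
    summed ``a + b + c``; loci monomorphic across the pair, or with fewer
    than two genotyped individuals in either group, are excluded.
    ``groups`` defaults to the matrix's subpopulation labels.
    """
    labels = (
        g.subpopulations if groups is None else pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    )
    labels = labels.loc[g.sample_ids]
    names = sorted(pd.unique(labels))
    if len(names) < 2:
        raise ValueError("need at least two groups")
    idx = {}
    for name in names:
        sel = np.flatnonzero((labels == name).to_numpy())
        if sel.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 samples")
        idx[name] = sel

    stats = {name: _group_locus_stats(g, sel) for name, sel in idx.items()}
    out = pd.DataFrame(np.zeros((len(names), len(names))), index=names, columns=names)
    for i, gi in enumerate(names):
        for gj in names[i + 1 :]:
            n1, p1, h1 = stats[gi]
            n2, p2, h2 = stats[gj]
            usable = (n1 >= 2) & (n2 >= 2)
            n_i = np.stack([n1, n2])[:, usable]
            p_i = np.stack([p1, p2])[:, usable]
            h_i = np.stack([h1, h2])[:, usable]
            # drop loci monomorphic across both groups
            p_bar = (n_i * p_i).sum(axis=0) / n_i.sum(axis=0)
            poly = (p_bar > 0) & (p_bar < 1)
            a, b, c = _wc_components(n_i[:, poly], p_i[:, poly], h_i[:, poly])
            denom = (a + b + c).sum()
            theta = a.sum() / denom if denom != 0 else np.nan
            out.loc[gi, gj] = out.loc[gj, gi] = theta
    return out


# ---------------------------------------------------------------------------
# admixture Q matrices
# ---------------------------------------------------------------------------

def read_q_matrix(source, n_samples: int, tol: float = 1e-3) -> np.ndarray:
    """Read an ADMIXTURE-style Q matrix (whitespace separated, one row per
    individual, K columns).  Rows must be nonnegative and sum to 1 within
    ``tol``; they are renormalized to sum exactly to 1."""
    text = source.read() if hasattr(source, "read") else Path(source).read_text()
    rows = [line.split() for line in text.splitlines() if line.strip()]
    if len(rows) != n_samples:
        raise ValueError(f"Q matrix has {len(rows)} rows; expected {n_samples} samples")
    q = np.asarray(rows, dtype=float)
    if (q < 0).any():
        raise ValueError("Q matrix contains negative membership coefficients")
    sums = q.sum(axis=1)
    bad = np.flatnonzero(np.abs(sums - 1.0) > tol)
    if bad.size:
        raise ValueError(
            f"Q matrix row {bad[0] + 1} sums to {sums[bad[0]]:.4f}, not 1"
        )
    return q / sums[:, None]


def write_q_matrix(q: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(q, dtype=float), fmt="%.6f")


# ---------------------------------------------------------------------------
# k-NN population network
# ---------------------------------------------------------------------------

def knn_neighbor_lists(rel: RelationshipMatrix, k: int) -> dict[str, list[str]]:
    """Directed k-nearest-neighbor lists by genetic distance.

    Each individual gets exactly ``min(k, n-1)`` neighbors; ties are broken
    by sample order.
    """
    n = len(rel.sample_ids)
    if k <= 0 or k >= n:
        raise ValueError(f"k must satisfy 0 < k < n (got k={k}, n={n})")
    dist = rel.distance().copy()
    np.fill_diagonal(dist, np.inf)
    out = {}
    order_idx = np.arange(n)
    for i in range(n):
        order = np.lexsort((order_idx, dist[i]))
        out[rel.sample_ids[i]] = [rel.sample_ids[j] for j in order[:k]]
    return out


def build_network(
    rel: RelationshipMatrix,
    k: int = 10,
    s_roh: Mapping[str, float] | pd.Series | None = None,
    q: np.ndarray | None = None,
    origins: Mapping[str, str] | pd.Series | None = None,
    mutual: bool = False,
    size_range: tuple[float, float] = (4.0, 20.0),
) -> nx.Graph:
    """Build the high-resolution k-NN population network.

    Edges connect i and j when either is among the other's k nearest
    neighbors (``mutual=True`` requires both directions).  Edge attributes
    carry the genetic distance and the relationship (edge weight); node
    attributes carry the origin label, S_ROH and its affine display size,
    and the admixture fractions as ``q1..qK``.
    """
    neighbors = knn_neighbor_lists(rel, k)
    ids = rel.sample_ids
    pos = {s: i for i, s in enumerate(ids)}

    graph = nx.Graph(k=k, mutual=mutual)
    sizes = None
    if s_roh is not None:
        s_roh = pd.Series(dict(s_roh) if not isinstance(s_roh, pd.Series) else s_roh)
        vals = s_roh.loc[ids].to_numpy(dtype=float)
        lo, hi = float(vals.min()), float(vals.max())
        if hi > lo:
            sizes = size_range[0] + (vals - lo) * (size_range[1] - size_range[0]) / (hi - lo)
        else:
            sizes = np.full(len(ids), (size_range[0] + size_range[1]) / 2.0)
    for i, sid in enumerate(ids):
        attrs: dict = {}
        if origins is not None:
            attrs["origin"] = origins[sid]
        if sizes is not None:
            attrs["s_roh"] = float(s_roh.loc[sid])
            attrs["size"] = float(sizes[i])
        if q is not None:
            if q.shape[0] != len(ids):
                raise ValueError("Q matrix row count does not match samples")
            for kk in range(q.shape[1]):
                attrs[f"q{kk + 1}"] = float(q[i, kk])
        graph.add_node(sid, **attrs)

    dist = rel.distance()
    for sid, nbrs in neighbors.items():
        for other in nbrs:
            if mutual and sid not in neighbors[other]:
                continue
            i, j = pos[sid], pos[other]
            graph.add_edge(
                sid,
                other,
                distance=float(dist[i, j]),
                weight=float(rel.values[i, j]),
            )
    return graph


def network_edge_table(graph: nx.Graph) -> pd.DataFrame:
    rows = [
        {"i": u, "j": v, "distance": d["distance"], "relationship": d["weight"]}
        for u, v, d in graph.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["i", "j", "distance", "relationship"])


def network_node_table(graph: nx.Graph) -> pd.DataFrame:
    rows = []
    for node, d in graph.nodes(data=True):
        rows.append({"sample_id": node, **d})
    return pd.DataFrame(rows)


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def modularity_permutation_test(
    graph: nx.Graph,
    labels: Mapping[str, str] | pd.Series,
    n_permutations: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, np.ndarray]:
    """Modularity of the label partition vs a label-permutation null.

    Returns (observed modularity, permutation p-value, null values).
    """
    rng = rng or np.random.default_rng()
    labels = pd.Series(dict(labels) if not isinstance(labels, pd.Series) else labels)
    nodes = list(graph.nodes)
    lab = labels.loc[nodes].to_numpy()

    def _mod(assignment: np.ndarray) -> float:
        communities = [
            {nodes[i] for i in np.flatnonzero(assignment == name)}
            for name in pd.unique(assignment)
        ]
        return nx.algorithms.community.modularity(graph, communities)

    observed = _mod(lab)
    null = np.empty(n_permutations)
    for t in range(n_permutations):
        null[t] = _mod(rng.permutation(lab))
    p = (1.0 + np.count_nonzero(null >= observed)) / (n_permutations + 1.0)
    return observed, p, null
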