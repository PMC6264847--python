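"""Shared-peak similarity between consensus spectra, the all-pairs similarity
matrix, heat-map rendering and the hierarchical similarity tree.

The score of a query ("inspected") spectrum against a reference is the
percentage of query peaks that find a counterpart in the reference within a
fixed m/z tolerance.  The denominator is the query's own peak count, so the
score is directed: score(A, B) and score(B, A) generally differ.  For tree
building the two directions are averaged into a symmetric distance
d = 100 − (s_ij + s_ji)/2 and clustered agglomeratively (UPGMA by default).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import matplotlib
matplotlib.use("Agg")  # headless rendering
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import LinearSegmentedColormap
from skbio import TreeNode

from .consensus import IdentityError, VirtualSpectrum


@dataclass
class SimilarityMatrix:
    """Directed pairwise scores on [0, 100]; entry (i, j) is sample i's
    virtual spectrum inspected against reference j."""

    sample_ids: list[str]
    directed_scores: np.ndarray
    tol_da: float

    def __post_init__(self) -> None:
        self.directed_scores = np.asarray(self.directed_scores, dtype=float)
        n = len(self.sample_ids)
        if self.directed_scores.shape != (n, n):
            raise ValueError("score grid shape must match sample count")
        if np.any(self.directed_scores < 0) or np.any(self.directed_scores > 100):
            raise ValueError("scores must lie in [0, 100]")

    def symmetric_distance(self) -> np.ndarray:
        """d(i,j) = 100 − mean of the two directed scores; zero diagonal."""
        s = self.directed_scores
        d = 100.0 - (s + s.T) / 2.0
        np.fill_diagonal(d, 0.0)
        return d


def match_peaks(query_mz: np.ndarray, reference_mz: np.ndarray,
                tol_da: float) -> list[tuple[int, int]]:
    """Greedy one-to-one matching of query peaks to reference peaks.

    Candidate pairs with |Δm/z| ≤ tol are certified in order of increasing
    |Δm/z|; ties break toward the lower-m/z query peak (then lower-m/z
    reference peak).  Each reference peak certifies at most one query peak.
    """
    query_mz = np.asarray(query_mz, dtype=float)
    reference_mz = np.asarray(reference_mz, dtype=float)
    pairs = [(abs(q - r), qi, ri)
             for qi, q in enumerate(query_mz)
             for ri, r in enumerate(reference_mz)
             if abs(q - r) <= tol_da]
    pairs.sort()
    used_q: set[int] = set()
    used_r: set[int] = set()
    matches = []
    for _, qi, ri in pairs:
        if qi in used_q or ri in used_r:
            continue
        used_q.add(qi)
        used_r.add(ri)
        matches.append((qi, ri))
    return sorted(matches)


def score(query: VirtualSpectrum, reference: VirtualSpectrum,
          tol_da: float = 2.0) -> float:
    """Percentage of query peaks matched in the reference within ±tol_da."""
    if tol_da <= 0:
        raise ValueError("tol_da must be positive")
    nq = len(query)
    if nq == 0:
        return 0.0
    matched = len(match_peaks(query.mz, reference.mz, tol_da))
    return 100.0 * matched / nq


def similarity_matrix(library: list[VirtualSpectrum],
                      tol_da: float = 2.0) -> SimilarityMatrix:
    """All directed pairwise scores over a consensus library."""
    if len(library) < 2:
        raise ValueError("need at least two samples")
    ids = [vs.sample_id for vs in library]
    if len(set(ids)) != len(ids):
        raise IdentityError("duplicate sample ids in library")
    n = len(library)
    grid = np.zeros((n, n))
    for i, j in itertools.product(range(n), repeat=2):
        grid[i, j] = score(library[i], library[j], tol_da)
    return SimilarityMatrix(sample_ids=ids, directed_scores=grid, tol_da=tol_da)


# ---------------------------------------------------------------------------
# Heat map
# ---------------------------------------------------------------------------

# continuous ramp: red (0) < dark orange < light orange < yellow (50)
# < light green < green < dark green (100)
SIMILARITY_CMAP = LinearSegmentedColormap.from_list(
    "similarity",
    [(0.00, "#d7191c"),   # red
     (0.17, "#e1641e"),   # dark orange
     (0.33, "#f59d3d"),   # light orange
     (0.50, "#ffff66"),   # yellow
     (0.67, "#a6d96a"),   # light green
     (0.83, "#4dac26"),   # green
     (1.00, "#006400")])  # dark green


def render_heatmap(m: SimilarityMatrix, path, show_values: bool = False) -> None:
    """Render the similarity matrix as a heat map anchored at red=0,
    yellow=50, dark green=100, with axes labelled by sample id."""
    n = len(m.sample_ids)
    fig, ax = plt.subplots(figsize=(max(4.0, 0.4 * n + 2),
                                    max(3.5, 0.4 * n + 1.5)))
    im = ax.imshow(m.directed_scores, cmap=SIMILARITY_CMAP, vmin=0, vmax=100)
    ax.set_xticks(range(n), m.sample_ids, rotation=90, fontsize=7)
    ax.set_yticks(range(n), m.sample_ids, fontsize=7)
    ax.set_xlabel("reference spectrum")
    ax.set_ylabel("inspected spectrum")
    if show_values:
        for i in range(n):
            for j in range(n):
                ax.text(j, i, f"{m.directed_scores[i, j]:.0f}",
                        ha="center", va="center", fontsize=6)
    fig.colorbar(im, ax=ax, label="similarity (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Similarity tree
# ---------------------------------------------------------------------------

_LINKAGES = ("upgma", "complete", "single")


def build_tree(m: SimilarityMatrix, linkage: str = "upgma") -> TreeNode:
    """Agglomerative similarity tree over the symmetrised distances.

    Heights are half the merge distance, so tip-to-tip path lengths equal the
    cophenetic distance and the UPGMA tree is ultrametric.  Ties between
    equally distant cluster pairs break toward the pair whose lexicographically
    smallest leaf label is smallest, making the topology deterministic.
    """
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")
    n = len(m.sample_ids)
    if n < 2:
        raise ValueError("need at least two samples to build a tree")

    d = m.symmetric_distance()
    # active clusters: key -> (node, size, member indices, min leaf label)
    nodes = {i: TreeNode(name=m.sample_ids[i]) for i in range(n)}
    heights = {i: 0.0 for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    labels = {i: m.sample_ids[i] for i in range(n)}
    dist = {frozenset((i, j)): d[i, j]
            for i in range(n) for j in range(i + 1, n)}
    next_key = n

    while len(nodes) > 1:
        best = min(
            dist.items(),
            key=lambda kv: (kv[1], *sorted(labels[k] for k in kv[0])))
        (pair, dmin) = best
        a, b = sorted(pair, key=lambda k: labels[k])
        h = dmin / 2.0
        parent = TreeNode(children=[nodes[a], nodes[b]])
        nodes[a].length = max(h - heights[a], 0.0)
        nodes[b].length = max(h - heights[b], 0.0)

        new = next_key
        next_key += 1
        for other in nodes:
            if other in (a, b):
                continue
            da = dist[frozenset((a, other))]
            db = dist[frozenset((b, other))]
            if linkage == "upgma":
                dn = (sizes[a] * da + sizes[b] * db) / (sizes[a] + sizes[b])
            elif linkage == "complete":
                dn = max(da, db)
            else:
                dn = min(da, db)
            dist[frozenset((new, other))] = dn
        for key in list(dist):
            if a in key or b in key:
                del dist[key]
        nodes[new] = parent
        heights[new] = h
        sizes[new] = sizes[a] + sizes[b]
        labels[new] = min(labels[a], labels[b])
        for k in (a, b):
            del nodes[k], heights[k], sizes[k], labels[k]

    root = next(iter(nodes.values()))
    root.length = None
    return root


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")
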