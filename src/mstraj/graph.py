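"""Cell-state graph: consensus of randomized minimum spanning trees.

Each randomized replicate perturbs the cell-cell distance matrix (either
by resampling the gene set with replacement and recomputing distances, or
by multiplicative jitter on the distances), computes the MST with a fully
deterministic Kruskal (ties broken by lexicographic edge order), and the
consensus keeps edges present in at least ``f_min`` of the trees.  If the
thresholded union is disconnected it is repaired deterministically by
adding back the highest-frequency joining edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import rank_transform, spearman_rows
from .matrix import ExpressionMatrix

__all__ = ["CellStateGraph", "cell_distance", "consensus_mst", "kruskal_mst"]


@dataclass
class CellStateGraph:
    """Weighted undirected graph over cells with MST-consensus frequencies."""

    nodes: list[str]
    edges: pd.DataFrame  # columns: a, b, weight, frequency (a < b positionally)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"a", "b", "weight", "frequency"}
        if not required <= set(self.edges.columns):
            raise ValueError(f"edge table must have columns {sorted(required)}")
        f = self.edges["frequency"].to_numpy()
        if len(f) and (np.any(f <= 0) or np.any(f > 1)):
            raise ValueError("edge frequencies must lie in (0, 1]")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def adjacency(self) -> dict[str, list[tuple[str, float]]]:
        adj: dict[str, list[tuple[str, float]]] = {n: [] for n in self.nodes}
        for a, b, w in zip(self.edges["a"], self.edges["b"], self.edges["weight"]):
            adj[a].append((b, float(w)))
            adj[b].append((a, float(w)))
        for n in adj:
            adj[n].sort()
        return adj

    def is_connected(self) -> bool:
        if not self.nodes:
            return True
        adj = self.adjacency()
        seen = {self.nodes[0]}
        stack = [self.nodes[0]]
        while stack:
            for nbr, _ in adj[stack.pop()]:
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        return len(seen) == len(self.nodes)

    def write_edgelist(self, path: str) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_edgelist(cls, path: str) -> "CellStateGraph":
        edges = pd.read_csv(path, sep="\t", dtype={"a": str, "b": str})
        nodes = sorted(set(edges["a"]) | set(edges["b"]))
        return cls(nodes, edges)


def cell_distance(m: ExpressionMatrix, genes: list[str]) -> pd.DataFrame:
    """Distance 1 - Spearman between cell profiles over ``genes``.

    Raises if any cell is constant over the gene set (undefined rank
    correlation), naming the offending cell(s).
    """
    if len(genes) < 2:
        raise ValueError("need at least 2 genes for a rank-based distance")
    idx = m.gene_index(genes)
    sub = m.values[idx]
    corr = spearman_rows(sub.T)
    bad = np.where(np.isnan(np.diag(corr)))[0]
    if bad.size:
        names = [m.cell_ids[i] for i in bad[:5]]
        raise ValueError(f"constant expression over the gene set for cell(s): {names}")
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=m.cell_ids, columns=m.cell_ids)


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        p = self.parent
        root = x
        while p[root] != root:
            root = p[root]
        while p[x] != root:
            p[x], x = root, p[x]
        return root

    def union(self, x: int, y: int) -> bool:
        rx, ry = self.find(x), self.find(y)
        if rx == ry:
            return False
        self.parent[ry] = rx
        return True


def kruskal_mst(dist: np.ndarray) -> list[tuple[int, int]]:
    """MST edge list (i < j) with (weight, i, j) lexicographic tie-break."""
    n = dist.shape[0]
    if n < 2:
        return []
    iu, ju = np.triu_indices(n, 1)
    w = dist[iu, ju]
    order = np.lexsort((ju, iu, w))
    uf = _UnionFind(n)
    edges: list[tuple[int, int]] = []
    for k in order:
        i, j = int(iu[k]), int(ju[k])
        if uf.union(i, j):
            edges.append((i, j))
            if len(edges) == n - 1:
                break
    return edges


def _resampled_distance(values: np.ndarray, gene_idx: np.ndarray) -> np.ndarray:
    # ranks must be recomputed over the resampled gene multiset
    sub = values[gene_idx]
    r = rank_transform(sub, axis=0)  # rank genes within each cell
    r = r - r.mean(axis=0, keepdims=True)
    norm = np.sqrt((r * r).sum(axis=0))
    norm = np.where(norm == 0, 1.0, norm)
    rn = r / norm
    c = np.clip(rn.T @ rn, -1.0, 1.0)
    d = 1.0 - c
    np.fill_diagonal(d, 0.0)
    return d


def consensus_mst(
    d: pd.DataFrame,
    n_trees: int = 1000,
    mode: str = "gene_resample",
    seed: int = 0,
    f_min: float = 0.2,
    epsilon: float = 0.05,
    matrix: ExpressionMatrix | None = None,
    genes: list[str] | None = None,
) -> CellStateGraph:
    """Consensus graph over ``n_trees`` randomized MSTs.

    ``mode="gene_resample"`` (requires ``matrix`` and ``genes``) recomputes
    the distance after resampling genes with replacement; ``mode="jitter"``
    multiplies each distance by iid uniform(1 - eps, 1 + eps).  Edges
    appearing in >= ``f_min`` of the trees are kept (weight = unperturbed
    distance, annotated with frequency); connectivity is repaired by adding
    back joining edges sorted by frequency desc, weight asc, node ids.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    dv = d.to_numpy(dtype=float)
    if dv.shape[0] != dv.shape[1] or not np.allclose(dv, dv.T):
        raise ValueError("distance matrix must be square and symmetric")
    nodes = [str(c) for c in d.columns]
    n = len(nodes)
    if mode not in ("jitter", "gene_resample"):
        raise ValueError(f"unknown randomization mode {mode!r}")
    if mode == "gene_resample" and (matrix is None or genes is None):
        raise ValueError("gene_resample mode requires matrix= and genes=")

    rng = np.random.default_rng(seed)
    counts = np.zeros((n, n), dtype=np.int64)
    if mode == "gene_resample":
        gidx = matrix.gene_index(genes)
        values = matrix.values
    for _ in range(n_trees):
        if mode == "jitter":
            if epsilon > 0:
                factor = rng.uniform(1.0 - epsilon, 1.0 + epsilon, size=(n, n))
                factor = np.triu(factor, 1)
                factor = factor + factor.T
                pert = dv * factor
            else:
                pert = dv
        else:
            sample = rng.choice(gidx, size=len(gidx), replace=True)
            pert = _resampled_distance(values, sample)
        for i, j in kruskal_mst(pert):
            counts[i, j] += 1

    iu, ju = np.triu_indices(n, 1)
    freq = counts[iu, ju] / float(n_trees)
    keep = freq >= max(f_min, 1e-12)
    keep &= counts[iu, ju] > 0

    rows = [
        (nodes[i], nodes[j], float(dv[i, j]), float(f))
        for i, j, f in zip(iu[keep], ju[keep], freq[keep])
    ]

    # deterministic connectivity repair over the remaining observed edges,
    # then (if ever needed) over all untried pairs by weight
    uf = _UnionFind(n)
    for i, j in zip(iu[keep], ju[keep]):
        uf.union(int(i), int(j))
    n_comp = len({uf.find(i) for i in range(n)})
    if n_comp > 1:
        rest = np.where(~keep)[0]
        order = sorted(
            rest,
            key=lambda k: (-freq[k], dv[iu[k], ju[k]], nodes[iu[k]], nodes[ju[k]]),
        )
        for k in order:
            i, j = int(iu[k]), int(ju[k])
            if uf.union(i, j):
                f = freq[k] if freq[k] > 0 else 1.0 / n_trees
                rows.append((nodes[i], nodes[j], float(dv[i, j]), float(f)))
                n_comp -= 1
                if n_comp == 1:
                    break

    edges = pd.DataFrame(rows, columns=["a", "b", "weight", "frequency"])
    edges = edges.sort_values(["a", "b"], kind="mergesort").reset_index(drop=True)
    params = {"n_trees": n_trees, "mode": mode, "seed": seed,
              "f_min": f_min, "epsilon": epsilon}
    return CellStateGraph(nodes, edges, params)
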