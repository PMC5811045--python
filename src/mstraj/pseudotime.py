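"""K-shortest-path trajectory ensembles and pseudotime expression profiles.

The K simple paths of smallest total weight between a start and an end
cell are enumerated with Yen's algorithm (Lawler deviation-index variant,
lazy candidate heap).  Each path is resampled to a fixed grid of L
pseudotime points by linear interpolation in normalized node position,
and the ensemble is averaged into per-gene mean/dispersion profiles.
"""

from __future__ import annotations

import heapq
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph import CellStateGraph
from .matrix import ExpressionMatrix
from .modules import CellStateLabels

__all__ = [
    "PathEnsemble",
    "PseudotimeProfiles",
    "k_shortest_paths",
    "resample_path",
    "ensemble_profiles",
    "pick_endpoints",
    "cell_positions",
]

DEFAULT_K = 9000
DEFAULT_L = 41


@dataclass
class PathEnsemble:
    """Ordered start -> end simple paths with total weights."""

    paths: list[list[str]]
    costs: list[float]
    K: int
    start: str
    end: str
    exhausted: bool = False  # fewer simple paths existed than requested

    def __post_init__(self) -> None:
        for p in self.paths:
            if len(p) != len(set(p)):
                raise ValueError("paths must be simple (no repeated nodes)")
            if p[0] != self.start or p[-1] != self.end:
                raise ValueError("every path must run start -> end")
        if any(self.costs[i] > self.costs[i + 1] + 1e-9
               for i in range(len(self.costs) - 1)):
            raise ValueError("path costs must be non-decreasing")

    def __len__(self) -> int:
        return len(self.paths)

    def edge_usage(self) -> pd.DataFrame:
        """Count of paths traversing each undirected edge."""
        counts: dict[tuple[str, str], int] = {}
        for p in self.paths:
            for u, v in zip(p[:-1], p[1:]):
                key = (u, v) if u <= v else (v, u)
                counts[key] = counts.get(key, 0) + 1
        rows = [(a, b, c) for (a, b), c in sorted(counts.items())]
        return pd.DataFrame(rows, columns=["a", "b", "n_paths"])


@dataclass
class PseudotimeProfiles:
    """Ensemble mean and dispersion of gene expression on the L-point grid."""

    mean_profile: pd.DataFrame      # genes x L
    dispersion: pd.DataFrame        # genes x L (std over paths)
    cell_occupancy: pd.DataFrame    # L x states, rows sum to 1 (if labels given)
    edge_usage: pd.DataFrame
    L: int
    n_paths: int

    def __post_init__(self) -> None:
        if self.mean_profile.shape != self.dispersion.shape:
            raise ValueError("mean and dispersion must share shape")
        if self.mean_profile.shape[1] != self.L:
            raise ValueError("profiles must have exactly L columns")


# ---------------------------------------------------------------------------
# Yen's algorithm
# ---------------------------------------------------------------------------

def _dijkstra_fast(adj, src, dst, banned, banned_next):
    """Shortest path src -> dst avoiding banned nodes / first-hop edges.

    ``adj``: list of lists of (weight, nbr).  Returns (cost, [nodes]) or None.
    """
    n = len(adj)
    dist = [math.inf] * n
    prev = [-1] * n
    done = [False] * n
    dist[src] = 0.0
    heap = [(0.0, src)]
    while heap:
        d, u = heapq.heappop(heap)
        if done[u]:
            continue
        done[u] = True
        if u == dst:
            path = [dst]
            while path[-1] != src:
                path.append(prev[path[-1]])
            path.reverse()
            return d, path
        first_hop = banned_next if u == src else None
        for w, v in adj[u]:
            if banned[v] or done[v]:
                continue
            if first_hop is not None and v in first_hop:
                continue
            nd = d + w
            if nd < dist[v]:
                dist[v] = nd
                prev[v] = u
                heapq.heappush(heap, (nd, v))
    return None


def _dijkstra_lex(adj, src, dst, banned, banned_next):
    """Like :func:`_dijkstra_fast` but returns the lexicographically smallest
    node sequence among minimum-cost paths (used on small graphs so that
    tie-breaking matches brute-force enumeration exactly)."""
    n = len(adj)
    done = [False] * n
    heap = [(0.0, (src,))]
    while heap:
        d, path = heapq.heappop(heap)
        u = path[-1]
        if done[u]:
            continue
        done[u] = True
        if u == dst:
            return d, list(path)
        first_hop = banned_next if u == src else None
        for w, v in adj[u]:
            if banned[v] or done[v]:
                continue
            if first_hop is not None and v in first_hop:
                continue
            heapq.heappush(heap, (d + w, path + (v,)))
    return None


def k_shortest_paths(
    g: CellStateGraph,
    start: str,
    end: str,
    K: int = DEFAULT_K,
    tie_break: str = "auto",
    max_spur_searches: int | None = None,
) -> PathEnsemble:
    """Enumerate the K simple start -> end paths of smallest total weight.

    Ties in total weight are broken by lexicographic node sequence (exact
    on graphs small enough for the lexicographic search; ``tie_break`` may
    be ``"lex"``, ``"fast"`` or ``"auto"``, the latter switching to the
    fast search above 64 nodes where real-valued distances make exact ties
    vanishingly unlikely).  If fewer than K simple paths exist, all are
    returned and ``exhausted`` is set (with a warning).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if start == end:
        raise ValueError("start and end must differ")
    if start not in g.nodes or end not in g.nodes:
        raise KeyError("start/end not in graph")

    # lexicographically sorted nodes => integer order == id order
    nodes = sorted(g.nodes)
    index = {nid: i for i, nid in enumerate(nodes)}
    n = len(nodes)
    adj: list[list[tuple[float, int]]] = [[] for _ in range(n)]
    for a, b, w in zip(g.edges["a"], g.edges["b"], g.edges["weight"]):
        ia, ib, fw = index[a], index[b], float(w)
        adj[ia].append((fw, ib))
        adj[ib].append((fw, ia))
    for lst in adj:
        lst.sort(key=lambda t: t[1])

    if tie_break == "auto":
        tie_break = "lex" if n <= 64 else "fast"
    search = _dijkstra_lex if tie_break == "lex" else _dijkstra_fast

    s, t = index[start], index[end]
    no_ban = [False] * n
    first = search(adj, s, t, no_ban, None)
    if first is None:
        raise ValueError(f"start {start!r} and end {end!r} are disconnected")

    accepted: list[tuple[float, list[int], int]] = [(first[0], first[1], 0)]
    seen: set[tuple[int, ...]] = {tuple(first[1])}
    cand: list[tuple[float, tuple[int, ...], int]] = []
    # root prefix -> set of next nodes taken by already-accepted paths
    root_next: dict[tuple[int, ...], set[int]] = {}
    weight_of: dict[tuple[int, int], float] = {}
    for u in range(n):
        for w, v in adj[u]:
            weight_of[(u, v)] = w
    n_searches = 0

    while len(accepted) < K:
        prev_cost, prev_path, dev_idx = accepted[-1]
        ptuple = tuple(prev_path)
        for i in range(len(prev_path) - 1):
            root_next.setdefault(ptuple[: i + 1], set()).add(prev_path[i + 1])

        root_cost = 0.0
        for i in range(len(prev_path) - 1):
            spur = prev_path[i]
            if i >= dev_idx:
                root = ptuple[: i + 1]
                banned = [False] * n
                for node in prev_path[:i]:
                    banned[node] = True
                banned_next = root_next.get(root, set())
                n_searches += 1
                if max_spur_searches is not None and n_searches > max_spur_searches:
                    raise RuntimeError(
                        "K-shortest-paths spur budget exceeded; lower K, raise "
                        "max_spur_searches, or sparsify the graph")
                res = search(adj, spur, t, banned, banned_next)
                if res is not None:
                    total = root_cost + res[0]
                    full = root[:-1] + tuple(res[1])
                    if full not in seen:
                        seen.add(full)
                        heapq.heappush(cand, (total, full, i))
            root_cost += weight_of[(prev_path[i], prev_path[i + 1])]
        if not cand:
            break
        cost, path, dev = heapq.heappop(cand)
        accepted.append((cost, list(path), dev))

    exhausted = len(accepted) < K
    if exhausted:
        warnings.warn(
            f"only {len(accepted)} simple paths exist between {start!r} and "
            f"{end!r}; requested K={K}")
    return PathEnsemble(
        paths=[[nodes[i] for i in p] for _, p, _ in accepted],
        costs=[c for c, _, _ in accepted],
        K=K, start=start, end=end, exhausted=exhausted,
    )


# ---------------------------------------------------------------------------
# resampling and ensemble statistics
# ---------------------------------------------------------------------------

def resample_path(path_values: np.ndarray, L: int = DEFAULT_L,
                  positions: np.ndarray | None = None) -> np.ndarray:
    """Linearly interpolate a genes x n path onto L equally spaced positions.

    By default node i of an n-node path sits at normalized position
    i / (n - 1); ``positions`` (nondecreasing, arbitrary scale) overrides
    this, e.g. with cumulative edge weights.
    """
    if L < 2:
        raise ValueError("L must be >= 2")
    v = np.asarray(path_values, dtype=float)
    if v.ndim != 2 or v.shape[1] < 2:
        raise ValueError("path must have length >= 2 (genes x nodes)")
    npts = v.shape[1]
    if positions is None:
        x = np.linspace(0.0, npts - 1.0, L)
        pos = np.arange(npts, dtype=float)
    else:
        pos = np.asarray(positions, dtype=float)
        if pos.shape != (npts,) or np.any(np.diff(pos) < 0):
            raise ValueError("positions must be nondecreasing, one per node")
        if pos[-1] == pos[0]:
            pos = np.arange(npts, dtype=float)  # degenerate: fall back to index
        x = np.linspace(pos[0], pos[-1], L)
    i0 = np.searchsorted(pos, x, side="right") - 1
    i0 = np.clip(i0, 0, npts - 2)
    span = pos[i0 + 1] - pos[i0]
    frac = np.where(span > 0, (x - pos[i0]) / np.where(span == 0, 1.0, span), 0.0)
    return v[:, i0] * (1.0 - frac)[None, :] + v[:, i0 + 1] * frac[None, :]


def ensemble_profiles(
    pe: PathEnsemble,
    m: ExpressionMatrix,
    labels: CellStateLabels | None = None,
    L: int = DEFAULT_L,
    resample_mode: str = "index",
) -> PseudotimeProfiles:
    """Mean and standard deviation of resampled expression over all paths.

    ``resample_mode="index"`` places node i at position i/(n-1);
    ``"weight"`` places nodes at cumulative rank-correlation distance along
    the path (duplicated cells then cost zero axis length).
    ``cell_occupancy[j]`` is the distribution over state labels of the node
    mapped nearest to grid point ``j`` across paths (empty when no labels
    are supplied).
    """
    if len(pe) == 0:
        raise ValueError("empty path ensemble")
    if resample_mode not in ("index", "weight"):
        raise ValueError(f"unknown resample_mode {resample_mode!r}")
    cell_idx = {c: i for i, c in enumerate(m.cell_ids)}
    if resample_mode == "weight":
        from ._stats import rank_transform
        r = rank_transform(m.values, axis=0)
        r = r - r.mean(axis=0, keepdims=True)
        norm = np.sqrt((r * r).sum(axis=0))
        r = r / np.where(norm == 0, 1.0, norm)[None, :]
    total = np.zeros((m.n_genes, L))
    total_sq = np.zeros((m.n_genes, L))
    if labels is not None:
        states = sorted(labels.label_of_cell.unique())
        state_pos = {s: i for i, s in enumerate(states)}
        occ = np.zeros((L, len(states)))
    for path in pe.paths:
        idx = np.fromiter((cell_idx[c] for c in path), dtype=int, count=len(path))
        if resample_mode == "weight":
            steps = 1.0 - np.einsum("gi,gi->i", r[:, idx[:-1]], r[:, idx[1:]])
            positions = np.concatenate([[0.0], np.cumsum(np.maximum(steps, 0.0))])
        else:
            positions = None
        res = resample_path(m.values[:, idx], L, positions=positions)
        total += res
        total_sq += res * res
        if labels is not None:
            if positions is not None and positions[-1] > 0:
                grid = np.linspace(0.0, positions[-1], L)
                nearest = np.array([int(np.argmin(np.abs(positions - x)))
                                    for x in grid])
            else:
                nearest = np.rint(np.linspace(0.0, len(path) - 1.0, L)).astype(int)
            for j, node_i in enumerate(nearest):
                occ[j, state_pos[labels.label_of_cell.loc[path[node_i]]]] += 1

    n = float(len(pe))
    mean = total / n
    var = np.maximum(total_sq / n - mean * mean, 0.0)
    grid = [f"t{j}" for j in range(L)]
    mean_df = pd.DataFrame(mean, index=m.gene_ids, columns=grid)
    sd_df = pd.DataFrame(np.sqrt(var), index=m.gene_ids, columns=grid)
    if labels is not None:
        occ_df = pd.DataFrame(occ / occ.sum(axis=1, keepdims=True),
                              index=grid, columns=[str(s) for s in states])
    else:
        occ_df = pd.DataFrame(index=grid)
    return PseudotimeProfiles(
        mean_profile=mean_df, dispersion=sd_df, cell_occupancy=occ_df,
        edge_usage=pe.edge_usage(), L=L, n_paths=len(pe),
    )


def cell_positions(pe: PathEnsemble) -> pd.Series:
    """Mean normalized path position of each cell across the ensemble."""
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for path in pe.paths:
        denom = len(path) - 1.0
        for i, c in enumerate(path):
            sums[c] = sums.get(c, 0.0) + i / denom
            counts[c] = counts.get(c, 0) + 1
    return pd.Series({c: sums[c] / counts[c] for c in sums}, name="mean_position")


def pick_endpoints(
    m: ExpressionMatrix,
    start_markers: list[str],
    end_markers: list[str],
    graph: CellStateGraph | None = None,
    smoothing_rounds: int = 2,
    push_extreme: bool = True,
) -> tuple[str, str]:
    """Cells maximizing mean z-scored expression of the marker sets.

    When a graph is supplied, each cell's marker score is smoothed over its
    graph neighborhood (frequency-weighted mean with its neighbors, repeated
    ``smoothing_rounds`` times) before the argmax, which suppresses
    single-cell noise when locating the trajectory extremes.  Ties resolve
    to the lexicographically smallest cell id; the end cell is chosen among
    cells other than the start cell.
    """
    def _score(markers: list[str]) -> np.ndarray:
        idx = m.gene_index(markers)
        sub = m.values[idx]
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, keepdims=True)
        sd = np.where(sd == 0, 1.0, sd)
        return ((sub - mu) / sd).mean(axis=0)

    def _smooth(score: np.ndarray) -> np.ndarray:
        if graph is None:
            return score
        pos = {c: i for i, c in enumerate(m.cell_ids)}
        out = score.astype(float)
        for _ in range(smoothing_rounds):
            acc = out.copy()
            wsum = np.ones(len(out))
            for a, b, f in zip(graph.edges["a"], graph.edges["b"],
                               graph.edges["frequency"]):
                ia, ib = pos[a], pos[b]
                acc[ia] += f * out[ib]
                acc[ib] += f * out[ia]
                wsum[ia] += f
                wsum[ib] += f
            out = acc / wsum
        return out

    order = np.array(m.cell_ids)
    s_score = _smooth(_score(start_markers))
    e_score = _smooth(_score(end_markers))
    start = min(zip(-s_score, order))[1]
    end_candidates = [(-sc, c) for sc, c in zip(e_score, order) if c != start]
    end = min(end_candidates)[1]
    if graph is None or not push_extreme:
        return start, end

    # push each endpoint to the extreme of its marker-high region: among the
    # top-decile scorers, take the cell graph-farthest from the other endpoint
    dist_from_end = _sp_distances(graph, end)
    start = _extreme(order, s_score, dist_from_end, exclude=end)
    dist_from_start = _sp_distances(graph, start)
    end = _extreme(order, e_score, dist_from_start, exclude=start)
    return start, end


def _sp_distances(graph: CellStateGraph, src: str) -> dict[str, float]:
    adj = graph.adjacency()
    dist = {src: 0.0}
    heap = [(0.0, src)]
    seen: set[str] = set()
    while heap:
        d, u = heapq.heappop(heap)
        if u in seen:
            continue
        seen.add(u)
        for v, w in adj[u]:
            nd = d + w
            if nd < dist.get(v, math.inf):
                dist[v] = nd
                heapq.heappush(heap, (nd, v))
    return dist


def _extreme(order: np.ndarray, score: np.ndarray, dist: dict[str, float],
             exclude: str, quantile: float = 0.9) -> str:
    cutoff = np.quantile(score, quantile)
    best = None
    for c, sc in zip(order, score):
        if c == exclude or sc < cutoff:
            continue
        key = (-dist.get(c, -math.inf), c)
        if best is None or key < best:
            best = key
    return best[1]
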