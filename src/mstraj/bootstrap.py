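"""Bootstrap robustness of pseudotime expression profiles.

Each replicate resamples cells with replacement at the original sample
size, rebuilds the distance matrix, consensus graph and path ensemble
with the supplied parameters, and records the mean expression profile per
gene.  Robustness is the per-gene mean pairwise Spearman correlation of
replicate profiles over the pseudotime grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import rank_transform
from .graph import cell_distance, consensus_mst
from .matrix import ExpressionMatrix
from .pseudotime import ensemble_profiles, k_shortest_paths, pick_endpoints

__all__ = ["BootstrapParams", "BootstrapSummary", "bootstrap_profiles",
           "profile_robustness"]

log = logging.getLogger(__name__)

DEFAULT_N_BOOT = 1000
DEFAULT_BOOT_K = 450  # reduced per-replicate path budget (K / 20)


@dataclass(frozen=True)
class BootstrapParams:
    """Per-replicate reconstruction parameters."""

    n_boot: int = DEFAULT_N_BOOT
    boot_K: int = DEFAULT_BOOT_K
    L: int = 41
    n_trees: int = 50
    mode: str = "jitter"  # duplicate-cell distance ties resolve lexicographically
    f_min: float = 0.2
    resample_mode: str = "weight"  # duplicate cells then cost zero axis length
    epsilon: float = 0.05

    def __post_init__(self) -> None:
        if self.n_boot < 2:
            raise ValueError("n_boot must be >= 2")
        if self.boot_K < 1 or self.L < 2 or self.n_trees < 1:
            raise ValueError("boot_K, L and n_trees must be positive (L >= 2)")


@dataclass
class BootstrapSummary:
    """Replicate profiles and robustness statistics."""

    n_boot: int
    seed: int
    gene_ids: list[str]
    replicate_profiles: np.ndarray  # genes x L x n_successful
    n_failed: int
    params: BootstrapParams
    per_gene_mean_rho: pd.Series | None = None
    n_pairs_used: int | None = None

    @property
    def n_successful(self) -> int:
        return self.replicate_profiles.shape[2]


def _resample_ids(cell_ids: list[str], draw: np.ndarray) -> list[str]:
    """Unique derived ids for a with-replacement draw of cell columns."""
    seen: dict[str, int] = {}
    out = []
    for i in draw:
        cid = cell_ids[i]
        k = seen.get(cid, 0)
        seen[cid] = k + 1
        out.append(cid if k == 0 else f"{cid}.{k}")
    return out


def bootstrap_profiles(
    m: ExpressionMatrix,
    genes: list[str],
    start_markers: list[str],
    end_markers: list[str],
    params: BootstrapParams = BootstrapParams(),
    seed: int = 0,
    start: str | None = None,
    end: str | None = None,
) -> BootstrapSummary:
    """Build ``n_boot`` replicate pseudotime profiles by cell resampling.

    The original ``start``/``end`` cells are reused whenever the resample
    contains them; a replicate that lost them (or when none are supplied)
    re-selects endpoints by the marker rule.  Replicates whose
    reconstruction fails (e.g. endpoints disconnected) are flagged, skipped
    and counted.
    """
    child_seeds = np.random.SeedSequence(seed).spawn(params.n_boot)
    profiles = []
    n_failed = 0
    n = m.n_cells
    for b, ss in enumerate(child_seeds):
        rng = np.random.default_rng(ss)
        draw = rng.integers(0, n, size=n)
        ids = _resample_ids(m.cell_ids, draw)
        meta = m.cell_meta.iloc[draw].set_axis(ids) if m.cell_meta is not None else None
        rep = ExpressionMatrix(
            m.values[:, draw], list(m.gene_ids), ids,
            layer=m.layer, cell_meta=meta, strict=False,
        )
        try:
            d = cell_distance(rep, genes)
            graph = consensus_mst(
                d, n_trees=params.n_trees, mode=params.mode,
                seed=int(rng.integers(2**31)), f_min=params.f_min,
                epsilon=params.epsilon, matrix=rep, genes=genes,
            )
            have = set(ids)
            if start in have and end in have:
                rep_start, rep_end = start, end
            else:
                rep_start, rep_end = pick_endpoints(rep, start_markers,
                                                    end_markers, graph=graph)
            pe = k_shortest_paths(graph, rep_start, rep_end, K=params.boot_K,
                                  tie_break="fast")
            prof = ensemble_profiles(pe, rep, labels=None, L=params.L,
                                     resample_mode=params.resample_mode)
            profiles.append(prof.mean_profile.to_numpy())
        except (ValueError, KeyError) as exc:
            n_failed += 1
            log.warning("bootstrap replicate %d skipped: %s", b, exc)
    if not profiles:
        raise RuntimeError("all bootstrap replicates failed")
    stack = np.stack(profiles, axis=2)
    return BootstrapSummary(
        n_boot=params.n_boot, seed=seed, gene_ids=list(m.gene_ids),
        replicate_profiles=stack, n_failed=n_failed, params=params,
    )


def profile_robustness(
    bs: BootstrapSummary,
    max_pairs: int = 2000,
    seed: int = 0,
) -> pd.Series:
    """Per-gene mean pairwise Spearman correlation across replicates.

    Pairs involving a constant replicate profile contribute 0 (documented
    convention).  When the number of replicate pairs exceeds ``max_pairs``
    a seeded random subsample of pairs is scored instead; the subsample is
    shared across genes.  The result is also stored on ``bs``.
    """
    nb = bs.n_successful
    if nb < 2:
        raise ValueError("need at least 2 successful replicates")
    g_count, L, _ = bs.replicate_profiles.shape
    # rank each profile over the grid; constant profiles become zero vectors
    flat = bs.replicate_profiles.transpose(0, 2, 1).reshape(g_count * nb, L)
    r = rank_transform(flat, axis=1)
    r -= r.mean(axis=1, keepdims=True)
    norm = np.sqrt((r * r).sum(axis=1))
    r = np.where(norm[:, None] > 0, r / np.where(norm == 0, 1.0, norm)[:, None], 0.0)
    r = r.reshape(g_count, nb, L)

    iu, ju = np.triu_indices(nb, 1)
    total_pairs = iu.size
    if total_pairs > max_pairs:
        pick = np.random.default_rng(seed).choice(total_pairs, size=max_pairs,
                                                  replace=False)
        iu, ju = iu[pick], ju[pick]
    rho = np.empty(g_count)
    for g in range(g_count):  # per-gene nb x nb correlation, scored on the pairs
        c = r[g] @ r[g].T
        rho[g] = c[iu, ju].mean()
    result = pd.Series(np.clip(rho, -1.0, 1.0),
                       index=pd.Index(bs.gene_ids, name="gene_id"),
                       name="mean_rho")
    bs.per_gene_mean_rho = result
    bs.n_pairs_used = int(iu.size)
    return result
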