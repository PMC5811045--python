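"""Gene-module detection, module selection and cell-state assignment.

Genes are clustered hierarchically under the distance 1 - Spearman(g, g')
with average linkage.  The cut height is chosen automatically by scanning
the dendrogram's merge heights and maximizing the number of clusters that
pass both retention criteria (minimum size and minimum mean intra-module
correlation).  Module selection is either offline term enrichment
(hypergeometric tail, Benjamini-Hochberg within module) or a marker-gene
rule.  Cell states come from hierarchical clustering of cells on the
selected modules' genes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from ._stats import spearman_rows
from .matrix import ExpressionMatrix

__all__ = [
    "GeneModuleSet",
    "CellStateLabels",
    "detect_modules",
    "select_modules",
    "cluster_cells",
]


@dataclass
class GeneModuleSet:
    """Disjoint gene modules with selection flags and the linkage record."""

    modules: dict[int, list[str]]
    selected: set[int]
    coherence: dict[int, float]
    linkage: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for mid, genes in self.modules.items():
            overlap = seen.intersection(genes)
            if overlap:
                raise ValueError(f"gene(s) {sorted(overlap)[:3]} appear in two modules")
            seen.update(genes)
        if not set(self.selected) <= set(self.modules):
            raise ValueError("selected ids must be a subset of module ids")

    def selected_genes(self) -> list[str]:
        out: list[str] = []
        for mid in sorted(self.selected):
            out.extend(self.modules[mid])
        return out

    def all_genes(self) -> list[str]:
        out: list[str] = []
        for mid in sorted(self.modules):
            out.extend(self.modules[mid])
        return out

    def to_json(self, path: str) -> None:
        payload = {
            "modules": [
                {
                    "id": mid,
                    "genes": self.modules[mid],
                    "coherence": self.coherence.get(mid),
                    "selected": mid in self.selected,
                }
                for mid in sorted(self.modules)
            ],
            "params": self.params,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "GeneModuleSet":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        modules = {int(m["id"]): list(m["genes"]) for m in payload["modules"]}
        selected = {int(m["id"]) for m in payload["modules"] if m.get("selected")}
        coherence = {
            int(m["id"]): m["coherence"]
            for m in payload["modules"]
            if m.get("coherence") is not None
        }
        return cls(modules, selected, coherence,
                   linkage=np.zeros((0, 4)), params=payload.get("params", {}))


@dataclass
class CellStateLabels:
    """Hierarchical cell-state assignment."""

    label_of_cell: pd.Series  # index cell_id -> int state id
    linkage: np.ndarray
    n_states: int

    def __post_init__(self) -> None:
        if self.label_of_cell.isna().any():
            raise ValueError("every cell must receive exactly one label")
        if not (1 <= self.n_states <= len(self.label_of_cell)):
            raise ValueError("n_states out of range")


def _corr_distance(corr: np.ndarray) -> np.ndarray:
    if np.isnan(corr).all():
        raise ValueError("degenerate distance matrix: all correlations undefined")
    d = 1.0 - corr
    d = np.where(np.isnan(d), 2.0, d)  # undefined pairs are maximally distant
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def detect_modules(
    m: ExpressionMatrix,
    genes: list[str] | None = None,
    min_size: int = 5,
    coherence_min: float = 0.3,
    separation_min: float = 0.075,
    method: str = "average",
) -> GeneModuleSet:
    """Detect gene modules by cutting the average-linkage dendrogram.

    The cut is scanned over all merge heights.  A cluster passes when its
    size is >= ``min_size``, its mean intra-cluster pairwise Spearman is
    >= ``coherence_min``, and that coherence exceeds its mean correlation
    to every other cluster by at least ``separation_min`` (fragments of a
    single coherent block fail this, so over-split cuts score zero).  The
    retained cut maximizes the number of passing clusters; ties resolve to
    the highest such cut.  Only passing clusters become modules.
    """
    if m.layer != "lognorm":
        raise ValueError("detect_modules expects a lognorm matrix")
    genes = list(genes) if genes is not None else list(m.gene_ids)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    idx = m.gene_index(genes)
    corr = spearman_rows(m.values[idx])
    dist = _corr_distance(corr)
    link = sch.linkage(squareform(dist, checks=False), method=method)

    heights = np.unique(link[:, 2])
    cuts = np.concatenate([[0.0], (heights[:-1] + heights[1:]) / 2.0,
                           [heights[-1] + 1.0]])

    def _passing(labels: np.ndarray) -> list[tuple[int, float]]:
        groups = {lab: np.where(labels == lab)[0] for lab in np.unique(labels)}
        out = []
        for lab, members in groups.items():
            if members.size < min_size:
                continue
            sub = corr[np.ix_(members, members)]
            iu = np.triu_indices(members.size, 1)
            vals = sub[iu]
            coh = float(np.nanmean(vals)) if not np.isnan(vals).all() else -np.inf
            if coh < coherence_min:
                continue
            max_cross = -np.inf
            for other, omembers in groups.items():
                if other == lab:
                    continue
                cross = np.nanmean(corr[np.ix_(members, omembers)])
                if cross > max_cross:
                    max_cross = cross
            if np.isfinite(max_cross) and coh - max_cross < separation_min:
                continue
            out.append((lab, coh))
        return out

    best_cut, best_count, best = cuts[0], -1, []
    for cut in cuts:
        labels = sch.fcluster(link, t=cut, criterion="distance")
        passing = _passing(labels)
        if len(passing) >= best_count:
            best_cut, best_count, best = cut, len(passing), (labels, passing)

    modules: dict[int, list[str]] = {}
    coherence: dict[int, float] = {}
    if best_count > 0:
        labels, passing = best
        for new_id, (lab, coh) in enumerate(
                sorted(passing, key=lambda x: -len(np.where(labels == x[0])[0]))):
            members = np.where(labels == lab)[0]
            modules[new_id] = [genes[i] for i in members]
            coherence[new_id] = coh
    params = {
        "min_size": min_size, "coherence_min": coherence_min,
        "method": method, "cut_height": float(best_cut),
    }
    return GeneModuleSet(modules, set(), coherence, linkage=link, params=params)


def _enrichment_pvalues(module_genes: set[str], annotation: dict[str, set[str]],
                        background: set[str]) -> pd.Series:
    """Hypergeometric upper-tail p per term for one module."""
    terms: dict[str, set[str]] = {}
    for gene, gene_terms in annotation.items():
        if gene in background:
            for t in gene_terms:
                terms.setdefault(t, set()).add(gene)
    big_n = len(background)
    n_draw = len(module_genes)
    pvals = {}
    for term, carriers in terms.items():
        k = len(module_genes & carriers)
        if k == 0:
            continue
        pvals[term] = float(hypergeom.sf(k - 1, big_n, len(carriers), n_draw))
    return pd.Series(pvals, dtype=float)


def select_modules(
    ms: GeneModuleSet,
    annotation: dict[str, set[str]] | None = None,
    markers: list[str] | None = None,
    alpha: float = 0.05,
    background: list[str] | None = None,
) -> GeneModuleSet:
    """Flag modules as selected by term enrichment or marker membership.

    With ``annotation``: a module is selected iff any term is enriched at
    BH-adjusted hypergeometric p < ``alpha`` against the background (default:
    the union of all module genes).  Without annotation, marker mode: a module
    is selected iff it contains at least one marker gene.  With neither,
    all modules are selected.
    """
    module_gene_union = set(ms.all_genes())
    bg = set(background) if background is not None else module_gene_union
    selected: set[int] = set()

    if annotation:
        unknown = set(annotation) - bg
        if unknown:
            warnings.warn(
                f"{len(unknown)} annotated genes absent from the background are ignored")
        for mid, genes in ms.modules.items():
            pv = _enrichment_pvalues(set(genes), annotation, bg)
            if pv.empty:
                continue
            reject, _, _, _ = multipletests(pv.to_numpy(), alpha=alpha, method="fdr_bh")
            if reject.any():
                selected.add(mid)
    elif markers:
        missing = set(markers) - module_gene_union
        if missing:
            warnings.warn(f"marker genes not found in any module: {sorted(missing)[:5]}")
        for mid, genes in ms.modules.items():
            if set(genes) & set(markers):
                selected.add(mid)
    else:
        selected = set(ms.modules)

    return GeneModuleSet(
        dict(ms.modules), selected, dict(ms.coherence), ms.linkage,
        params={**ms.params, "selection_alpha": alpha},
    )


def _auto_n_states(link: np.ndarray, max_states: int = 10) -> int:
    """Number of clusters at the largest relative gap in top merge heights."""
    heights = link[:, 2]
    n = link.shape[0] + 1
    best_k, best_gap = 2, -np.inf
    upper = min(max_states, n - 1)
    for k in range(2, upper + 1):
        hi = heights[n - k]       # first merge height above the cut
        lo = heights[n - k - 1] if n - k - 1 >= 0 else 0.0
        gap = (hi - lo) / hi if hi > 0 else 0.0
        if gap > best_gap:
            best_k, best_gap = k, gap
    return best_k


def cluster_cells(
    m: ExpressionMatrix,
    ms: GeneModuleSet,
    n_states: int | str = "auto",
    method: str = "average",
) -> tuple[CellStateLabels, pd.DataFrame]:
    """Hierarchically cluster cells on selected-module genes.

    Returns the labels plus a per-state QC summary (cell count, median
    total signal, median genes detected).
    """
    genes = ms.selected_genes()
    if not genes:
        raise ValueError("no selected modules: nothing to cluster on")
    idx = m.gene_index(genes)
    sub = m.values[idx]
    corr = spearman_rows(sub.T)  # correlations between cells over the genes
    bad = np.where(np.isnan(np.diag(corr)))[0]
    if bad.size:
        names = [m.cell_ids[i] for i in bad[:5]]
        raise ValueError(f"cells with constant expression over the gene set: {names}")
    dist = _corr_distance(corr)
    link = sch.linkage(squareform(dist, checks=False), method=method)

    if n_states == "auto":
        n_states = _auto_n_states(link)
    n_states = int(n_states)
    if not (1 <= n_states <= m.n_cells):
        raise ValueError("n_states must be between 1 and the number of cells")
    labels = sch.fcluster(link, t=n_states, criterion="maxclust")
    series = pd.Series(labels, index=pd.Index(m.cell_ids, name="cell_id"), name="state")

    totals = m.values.sum(axis=0)
    detected = (m.values > 0).sum(axis=0)
    summary = (
        pd.DataFrame({"state": labels, "total_signal": totals, "genes_detected": detected})
        .groupby("state")
        .agg(n_cells=("state", "size"),
             median_total=("total_signal", "median"),
             median_genes_detected=("genes_detected", "median"))
    )
    return CellStateLabels(series, link, n_states), summary
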