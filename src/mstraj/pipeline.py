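"""End-to-end pipeline driven by one validated configuration mapping.

Stage order: filter -> modules -> states -> graph -> pseudotime -> phases
(-> bootstrap when enabled).  All randomness derives from one master seed
through named substreams so stages are independently reproducible.  The
machine-readable report records per-stage counts, every effective
parameter and all artifact paths.
"""

from __future__ import annotations

import copy
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bootstrap import BootstrapParams, bootstrap_profiles, profile_robustness
from .graph import cell_distance, consensus_mst
from .matrix import read_matrix, write_matrix
from .modules import cluster_cells, detect_modules, select_modules
from .phases import global_variation, segment_phases
from .preprocess import QcThresholds, correlation_filter_genes, normalize, qc_filter_cells
from .pseudotime import ensemble_profiles, k_shortest_paths, pick_endpoints
from .simulate import TrajectoryConfig, simulate_trajectory

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "DEFAULT_CONFIG"]

log = logging.getLogger("mstraj")

SCHEMA_VERSION = 1

DEFAULT_CONFIG: dict = {
    "schema_version": SCHEMA_VERSION,
    "seed": 0,
    "input_matrix": None,
    "output_dir": "mstraj_out",
    "simulate": None,           # TrajectoryConfig kwargs; replaces input_matrix
    "qc": {
        "min_total_counts": 0.0,
        "min_genes_detected": 0,
        "max_fraction_top_gene": 1.0,
    },
    "filter": {"r_min": 0.4, "min_partners": 2, "iterative": False},
    "modules": {
        "min_size": 5,
        "coherence_min": 0.3,
        "annotation": None,      # path to two-column gene<TAB>term file
        "markers": None,         # marker-gene list for selection fallback
        "n_states": "auto",
    },
    "graph": {"n_trees": 1000, "mode": "gene_resample", "f_min": 0.2,
              "epsilon": 0.05},
    "pseudotime": {
        "K": 9000,
        "L": 41,
        "start": None,
        "end": None,
        "start_markers": None,
        "end_markers": None,
    },
    "phases": {"n_top": 200, "bandwidth": 5, "min_run": 3},
    "bootstrap": {
        "enabled": False,
        "n_boot": 1000,
        "boot_K": 450,
        "n_trees": 50,
        "mode": "jitter",
    },
}


class PipelineError(RuntimeError):
    """Stage failure with stage name and remediation hint."""

    def __init__(self, stage: str, message: str, hint: str = ""):
        self.stage = stage
        suffix = f" (hint: {hint})" if hint else ""
        super().__init__(f"[{stage}] {message}{suffix}")


class RunConfig:
    """Validated pipeline configuration (defaults merged, unknown keys rejected)."""

    def __init__(self, overrides: dict | None = None):
        cfg = copy.deepcopy(DEFAULT_CONFIG)
        if overrides:
            _merge(cfg, overrides, path="")
        self.data = cfg
        self._validate()

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(raw)

    def _validate(self) -> None:
        c = self.data
        if c["schema_version"] != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema_version {c['schema_version']}")
        if c["pseudotime"]["K"] < 1:
            raise ValueError("pseudotime.K must be >= 1")
        if c["pseudotime"]["L"] < 2:
            raise ValueError("pseudotime.L must be >= 2")
        if c["filter"]["min_partners"] < 1:
            raise ValueError("filter.min_partners must be >= 1")
        if c["graph"]["n_trees"] < 1:
            raise ValueError("graph.n_trees must be >= 1")
        if c["bootstrap"]["n_boot"] < 2:
            raise ValueError("bootstrap.n_boot must be >= 2")
        if c["simulate"] is None and c["input_matrix"] is None:
            raise ValueError("either input_matrix or simulate must be given")

    def __getitem__(self, key: str):
        return self.data[key]


def _merge(base: dict, overrides: dict, path: str) -> None:
    for key, value in overrides.items():
        where = f"{path}.{key}" if path else key
        if key not in base:
            raise ValueError(f"unknown configuration key: {where}")
        if isinstance(base[key], dict) and isinstance(value, dict):
            _merge(base[key], value, where)
        else:
            base[key] = value


def stage_seeds(master: int) -> dict[str, int]:
    """Named integer substream seeds derived from the master seed."""
    children = np.random.SeedSequence(master).spawn(3)
    names = ("simulate", "mst", "bootstrap")
    return {name: int(ss.generate_state(1)[0]) for name, ss in zip(names, children)}


def _read_annotation(path: str) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"], dtype=str)
    out: dict[str, set[str]] = {}
    for gene, term in zip(df["gene"], df["term"]):
        out.setdefault(gene, set()).add(term)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; write artifacts and return the report mapping."""
    c = config.data
    outdir = Path(c["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(c["seed"])
    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "effective_config": copy.deepcopy(c),
        "seeds": seeds,
        "stages": {},
        "artifacts": {},
    }

    def _stage(name: str):
        log.info("stage %s ...", name)
        return time.perf_counter()

    def _done(name: str, t0: float, **counts) -> None:
        dt = time.perf_counter() - t0
        report["stages"][name] = {"seconds": round(dt, 3), **counts}
        log.info("stage %s done in %.2fs %s", name, dt, counts)

    # ---- input -------------------------------------------------------
    t0 = _stage("input")
    truth = None
    if c["simulate"] is not None:
        sim_kwargs = dict(c["simulate"])
        sim_kwargs.setdefault("seed", seeds["simulate"])
        if "phase_boundaries" in sim_kwargs:
            sim_kwargs["phase_boundaries"] = tuple(sim_kwargs["phase_boundaries"])
        try:
            matrix, truth = simulate_trajectory(TrajectoryConfig(**sim_kwargs))
        except (TypeError, ValueError) as exc:
            raise PipelineError("input", str(exc), "check the simulate block") from exc
        write_matrix(matrix, str(outdir / "counts.mtx"))
        truth.cells.to_csv(outdir / "truth_cells.tsv", sep="\t")
        truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t")
        report["artifacts"]["counts"] = str(outdir / "counts.mtx")
    else:
        try:
            matrix = read_matrix(c["input_matrix"])
        except (OSError, ValueError) as exc:
            raise PipelineError("input", str(exc), "check input_matrix path/format") from exc
    _done("input", t0, n_genes=matrix.n_genes, n_cells=matrix.n_cells)

    # ---- QC + normalize + gene filter --------------------------------
    t0 = _stage("filter")
    try:
        th = QcThresholds(**c["qc"])
        matrix, qc = qc_filter_cells(matrix, th)
        norm = normalize(matrix)
        kept_genes = correlation_filter_genes(
            norm, r_min=c["filter"]["r_min"],
            min_partners=c["filter"]["min_partners"],
            iterative=c["filter"]["iterative"],
        )
        if not kept_genes:
            raise ValueError("no genes survive the correlation filter")
        filtered = norm.subset_genes(kept_genes)
    except ValueError as exc:
        raise PipelineError("filter", str(exc), "relax QC/filter thresholds") from exc
    qc.to_csv(outdir / "qc_report.tsv", sep="\t")
    write_matrix(filtered, str(outdir / "filtered.tsv"))
    report["artifacts"]["qc_report"] = str(outdir / "qc_report.tsv")
    report["artifacts"]["filtered"] = str(outdir / "filtered.tsv")
    _done("filter", t0, n_cells=filtered.n_cells, n_genes=filtered.n_genes)

    # ---- modules -----------------------------------------------------
    t0 = _stage("modules")
    try:
        ms = detect_modules(filtered, min_size=c["modules"]["min_size"],
                            coherence_min=c["modules"]["coherence_min"])
        annotation = (_read_annotation(c["modules"]["annotation"])
                      if c["modules"]["annotation"] else None)
        ms = select_modules(ms, annotation=annotation,
                            markers=c["modules"]["markers"])
        if not ms.selected:
            raise ValueError("no modules selected")
    except ValueError as exc:
        raise PipelineError("modules", str(exc),
                            "lower coherence_min/min_size or fix annotation") from exc
    ms.to_json(str(outdir / "modules.json"))
    report["artifacts"]["modules"] = str(outdir / "modules.json")
    _done("modules", t0, n_modules=len(ms.modules), n_selected=len(ms.selected))

    # ---- cell states -------------------------------------------------
    t0 = _stage("states")
    try:
        labels, state_summary = cluster_cells(filtered, ms,
                                              n_states=c["modules"]["n_states"])
    except ValueError as exc:
        raise PipelineError("states", str(exc), "check n_states") from exc
    labels.label_of_cell.to_csv(outdir / "states.tsv", sep="\t")
    state_summary.to_csv(outdir / "state_summary.tsv", sep="\t")
    report["artifacts"]["states"] = str(outdir / "states.tsv")
    _done("states", t0, n_states=labels.n_states)

    # ---- graph -------------------------------------------------------
    t0 = _stage("graph")
    try:
        sel_genes = ms.selected_genes()
        dist = cell_distance(filtered, sel_genes)
        graph = consensus_mst(
            dist, n_trees=c["graph"]["n_trees"], mode=c["graph"]["mode"],
            seed=seeds["mst"], f_min=c["graph"]["f_min"],
            epsilon=c["graph"]["epsilon"], matrix=filtered, genes=sel_genes,
        )
    except ValueError as exc:
        raise PipelineError("graph", str(exc), "check selected modules") from exc
    graph.write_edgelist(str(outdir / "graph.edgelist"))
    report["artifacts"]["graph"] = str(outdir / "graph.edgelist")
    _done("graph", t0, n_edges=len(graph.edges))

    # ---- pseudotime --------------------------------------------------
    t0 = _stage("pseudotime")
    pt = c["pseudotime"]
    try:
        if pt["start"] and pt["end"]:
            start, end = pt["start"], pt["end"]
        elif pt["start_markers"] and pt["end_markers"]:
            start, end = pick_endpoints(filtered, pt["start_markers"],
                                        pt["end_markers"], graph=graph)
        else:
            start, end = _diameter_endpoints(graph)
        pe = k_shortest_paths(graph, start, end, K=pt["K"])
        profiles = ensemble_profiles(pe, filtered, labels=labels, L=pt["L"])
    except (ValueError, KeyError) as exc:
        raise PipelineError("pseudotime", str(exc),
                            "check start/end cells and K") from exc
    profiles.mean_profile.to_csv(outdir / "profiles.tsv", sep="\t")
    profiles.dispersion.to_csv(outdir / "profiles_sd.tsv", sep="\t")
    profiles.edge_usage.to_csv(outdir / "edge_usage.tsv", sep="\t", index=False)
    report["artifacts"]["profiles"] = str(outdir / "profiles.tsv")
    report["artifacts"]["edge_usage"] = str(outdir / "edge_usage.tsv")
    _done("pseudotime", t0, n_paths=len(pe), start=start, end=end,
          exhausted=pe.exhausted)

    # ---- phases ------------------------------------------------------
    t0 = _stage("phases")
    try:
        n_top = min(c["phases"]["n_top"], filtered.n_genes)
        curve = global_variation(profiles, n_top=n_top)
        seg = segment_phases(curve, bandwidth=c["phases"]["bandwidth"],
                             min_run=c["phases"]["min_run"])
    except ValueError as exc:
        raise PipelineError("phases", str(exc), "check bandwidth vs L") from exc
    seg.to_frame().to_csv(outdir / "phases.tsv", sep="\t", index=False)
    report["artifacts"]["phases"] = str(outdir / "phases.tsv")
    _done("phases", t0, n_metastable=seg.n_metastable,
          n_transitions=seg.n_transitions)

    # ---- bootstrap (optional) ----------------------------------------
    if c["bootstrap"]["enabled"]:
        t0 = _stage("bootstrap")
        try:
            bp = BootstrapParams(
                n_boot=c["bootstrap"]["n_boot"], boot_K=c["bootstrap"]["boot_K"],
                L=pt["L"], n_trees=c["bootstrap"]["n_trees"],
                mode=c["bootstrap"]["mode"],
            )
            sm = pt["start_markers"] or sel_genes[:5]
            em = pt["end_markers"] or sel_genes[-5:]
            bs = bootstrap_profiles(filtered, sel_genes, sm, em, params=bp,
                                    seed=seeds["bootstrap"])
            rho = profile_robustness(bs)
        except (ValueError, RuntimeError) as exc:
            raise PipelineError("bootstrap", str(exc), "reduce n_boot/boot_K") from exc
        out = pd.DataFrame({
            "mean_rho": rho,
            "n_pairs": bs.n_pairs_used,
            "n_replicates_used": bs.n_successful,
        })
        out.to_csv(outdir / "robustness.tsv", sep="\t")
        report["artifacts"]["robustness"] = str(outdir / "robustness.tsv")
        _done("bootstrap", t0, n_replicates=bs.n_boot,
              n_successful=bs.n_successful, n_failed=bs.n_failed)

    report_path = outdir / "report.json"
    with open(report_path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    report["artifacts"]["report"] = str(report_path)
    return report


def _diameter_endpoints(graph) -> tuple[str, str]:
    """Double-sweep farthest pair on the weighted graph (automatic fallback
    when neither explicit endpoints nor marker lists are configured)."""
    import heapq

    adj = graph.adjacency()

    def _far(src: str) -> tuple[str, float]:
        dist = {src: 0.0}
        heap = [(0.0, src)]
        seen = set()
        while heap:
            d, u = heapq.heappop(heap)
            if u in seen:
                continue
            seen.add(u)
            for v, w in adj[u]:
                nd = d + w
                if nd < dist.get(v, float("inf")):
                    dist[v] = nd
                    heapq.heappush(heap, (nd, v))
        far = max(dist.items(), key=lambda kv: (kv[1], kv[0]))
        return far[0], far[1]

    a, _ = _far(sorted(graph.nodes)[0])
    b, _ = _far(a)
    return (a, b) if a <= b else (b, a)
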