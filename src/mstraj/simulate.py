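"""Synthetic differentiation-trajectory count matrices with ground truth.

Cells are sampled asynchronously along a latent time axis in [0, 1] that
is tiled by metastable plateaus separated by narrow transitions.  Gene
modules follow smooth bounded profiles of latent time (constant within
plateaus, sigmoidal across transitions); one planted regulator follows a
biphasic low -> high -> off profile.  Counts are negative-binomial around
the profile means, scaled by per-cell library factors and thinned by
dropout.  Off-trajectory contaminant populations carry module-free random
expression programs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .matrix import ExpressionMatrix

__all__ = [
    "TrajectoryConfig",
    "SyntheticTruth",
    "profile_value",
    "simulate_trajectory",
]

_PLATEAU_WEIGHT = 0.7  # latent-time mass inside metastable plateaus


@dataclass(frozen=True)
class TrajectoryConfig:
    """Parameters of the synthetic trajectory generator."""

    n_cells: int = 200
    n_genes: int = 300
    n_modules: int = 5
    phase_boundaries: tuple[float, ...] = (1.0 / 3.0, 2.0 / 3.0)
    transition_width: float = 0.1
    noise: float = 0.15          # NB dispersion alpha: var = mu + alpha mu^2
    dropout_rate: float = 0.1
    frac_offtrajectory: float = 0.1
    n_contaminant_pops: int = 2
    frac_noise_genes: float = 0.2
    library_sigma: float = 0.3   # log-normal per-cell scaling; 0 disables
    plateau_drift: float = 0.3   # modest monotone within-plateau expression drift
    low_range: tuple[float, float] = (0.0, 0.0)  # module off-state mean expression
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_genes < 1:
            raise ValueError("n_cells and n_genes must be positive")
        if self.n_modules < 1:
            raise ValueError("n_modules must be positive")
        if self.n_modules > self.n_genes:
            raise ValueError("n_modules cannot exceed n_genes")
        b = self.phase_boundaries
        if any(not (0.0 < x < 1.0) for x in b):
            raise ValueError("phase_boundaries must lie in the open interval (0, 1)")
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("phase_boundaries must be strictly increasing")
        gaps = np.diff([0.0, *b, 1.0])
        if self.transition_width >= gaps.min():
            raise ValueError(
                f"transition_width={self.transition_width} must be smaller than "
                f"the smallest inter-boundary gap ({gaps.min():.4g})"
            )
        if not (0.0 <= self.dropout_rate <= 1.0):
            raise ValueError("dropout_rate must be in [0, 1]")
        if not (0.0 <= self.frac_offtrajectory < 1.0):
            raise ValueError("frac_offtrajectory must be in [0, 1)")
        if self.noise < 0 or self.library_sigma < 0:
            raise ValueError("noise and library_sigma must be nonnegative")

    @property
    def n_phases(self) -> int:
        return len(self.phase_boundaries) + 1


@dataclass
class SyntheticTruth:
    """Planted latent structure backing a simulated matrix."""

    cells: pd.DataFrame   # index cell_id; latent_time, on_trajectory, population
    genes: pd.DataFrame   # index gene_id; module (str id or "noise")
    phase_boundaries: tuple[float, ...]
    transition_width: float
    biphasic_gene_id: str
    gene_profiles: dict[str, tuple[str, dict]] = field(default_factory=dict)

    @property
    def n_phases(self) -> int:
        return len(self.phase_boundaries) + 1

    @property
    def latent_time(self) -> pd.Series:
        return self.cells["latent_time"]

    @property
    def module_of_gene(self) -> pd.Series:
        return self.genes["module"]

    def phase_of_time(self, t):
        """Phase index (0-based) of latent time(s) ``t``."""
        return np.searchsorted(np.asarray(self.phase_boundaries), np.asarray(t), side="right")

    def transition_intervals(self) -> list[tuple[float, float]]:
        w = self.transition_width / 2.0
        return [(b - w, b + w) for b in self.phase_boundaries]

    def segment_kind(self, t) -> np.ndarray:
        """``"transition"`` inside a switching window, else ``"metastable"``."""
        t = np.asarray(t, dtype=float)
        trans = np.zeros(t.shape, dtype=bool)
        for lo, hi in self.transition_intervals():
            trans |= (t >= lo) & (t <= hi)
        return np.where(trans, "transition", "metastable")

    def dynamic_genes(self) -> list[str]:
        """Planted dynamic genes: all module members plus the biphasic gene."""
        in_module = self.genes.index[self.genes["module"] != "noise"].tolist()
        if self.biphasic_gene_id not in in_module:
            in_module.append(self.biphasic_gene_id)
        return in_module


# ---------------------------------------------------------------------------
# parametric profiles
# ---------------------------------------------------------------------------

def _sigmoid_scale(width: float) -> float:
    # the switch runs ~2% -> 98% of its range within `width` latent time
    return max(width, 1e-12) / 8.0


def profile_value(t, kind: str, params: dict):
    """Evaluate a mean-expression profile at latent time(s) ``t`` in [0, 1].

    Kinds: ``plateau`` (constant ``level``), ``sigmoid`` (``low``/``high``
    around ``center`` over ``width``), ``pulse`` (Gaussian bump), ``steps``
    (piecewise plateau ``levels`` switching at ``boundaries``), ``biphasic``
    (``base`` plateau, sharp rise at ``rise``, shutdown at ``fall``).
    """
    t = np.asarray(t, dtype=float)
    if np.any((t < 0) | (t > 1)):
        raise ValueError("latent time must lie in [0, 1]")
    if kind == "plateau":
        return np.full(t.shape, float(params["level"]))
    if kind == "sigmoid":
        s = _sigmoid_scale(params["width"])
        return params["low"] + (params["high"] - params["low"]) * expit(
            (t - params["center"]) / s)
    if kind == "pulse":
        half = max(params["width"], 1e-12) / 2.0
        return params["low"] + (params["high"] - params["low"]) * np.exp(
            -0.5 * ((t - params["center"]) / half) ** 2)
    if kind == "steps":
        levels = np.asarray(params["levels"], dtype=float)
        bounds = np.asarray(params["boundaries"], dtype=float)
        if levels.size != bounds.size + 1:
            raise ValueError("steps profile needs len(levels) == len(boundaries) + 1")
        s = _sigmoid_scale(params["width"])
        out = np.full(t.shape, levels[0])
        for j, b in enumerate(bounds):
            out = out + (levels[j + 1] - levels[j]) * expit((t - b) / s)
        # optional modest monotone drift: metastable expression changes slowly
        # rather than not at all, keeping cells within a plateau orderable
        drift = float(params.get("drift", 0.0))
        if drift != 0.0:
            out = out * (1.0 + drift * (t - 0.5))
        return out
    if kind == "biphasic":
        s = _sigmoid_scale(params["width"])
        rising = params["base"] + (params["peak"] - params["base"]) * expit(
            (t - params["rise"]) / s)
        return rising * (1.0 - expit((t - params["fall"]) / s))
    raise ValueError(f"unknown profile kind {kind!r}")


def _module_patterns(n_modules: int, n_phases: int) -> list[np.ndarray]:
    """Distinct on/off phase patterns, one per module.

    The first pattern is an early-high program that shuts off (repressor-like)
    and a late-onset program is always present, so at least one mutually
    exclusive pair is planted.
    """
    pats: list[np.ndarray] = []
    for p in range(n_phases):          # one-hot: high in exactly one phase
        v = np.zeros(n_phases); v[p] = 1.0
        pats.append(v)
    for p in range(1, n_phases - 1):   # onset: high from phase p onward
        v = np.zeros(n_phases); v[p:] = 1.0
        pats.append(v)
    for p in range(1, n_phases - 1):   # offset: high up to phase p
        v = np.zeros(n_phases); v[: p + 1] = 1.0
        pats.append(v)
    while len(pats) < n_modules:       # cycle if more modules than patterns
        pats.append(pats[len(pats) % max(len(pats), 1)].copy())
    return pats[:n_modules]


def _sample_latent_times(rng: np.random.Generator, n: int,
                         boundaries: tuple[float, ...], width: float) -> np.ndarray:
    w = width / 2.0
    trans = [(b - w, b + w) for b in boundaries]
    edges = [0.0] + [e for iv in trans for e in iv] + [1.0]
    plateaus = [(edges[i], edges[i + 1]) for i in range(0, len(edges) - 1, 2)]

    def _draw_from(segs: list[tuple[float, float]], k: int) -> np.ndarray:
        lens = np.array([hi - lo for lo, hi in segs], dtype=float)
        probs = lens / lens.sum()
        which = rng.choice(len(segs), size=k, p=probs)
        u = rng.random(k)
        lo = np.array([segs[i][0] for i in which])
        hi = np.array([segs[i][1] for i in which])
        return lo + u * (hi - lo)

    in_plateau = rng.random(n) < _PLATEAU_WEIGHT
    t = np.empty(n)
    if in_plateau.any():
        t[in_plateau] = _draw_from(plateaus, int(in_plateau.sum()))
    if (~in_plateau).any():
        t[~in_plateau] = _draw_from(trans, int((~in_plateau).sum()))
    return t


def simulate_trajectory(config: TrajectoryConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate a genes x cells count matrix plus its planted truth.

    ``noise == 0`` is the deterministic limit: the returned values are the
    exact profile means at the sampled latent times (floats, no negative
    binomial sampling) so the matrix equals the noise-free model.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    n_off = int(round(cfg.frac_offtrajectory * cfg.n_cells))
    n_on = cfg.n_cells - n_off
    if n_on < 1:
        raise ValueError("frac_offtrajectory leaves no on-trajectory cells")

    t_on = _sample_latent_times(rng, n_on, cfg.phase_boundaries, cfg.transition_width)

    # --- gene programme assignment ------------------------------------
    n_noise = int(round(cfg.frac_noise_genes * cfg.n_genes))
    n_info = cfg.n_genes - n_noise - 1  # one slot reserved for the biphasic gene
    if n_info < cfg.n_modules:
        raise ValueError("too few genes for the requested module count")
    sizes = np.full(cfg.n_modules, n_info // cfg.n_modules)
    sizes[: n_info % cfg.n_modules] += 1

    gene_ids = [f"g{i:04d}" for i in range(cfg.n_genes)]
    module_of = np.full(cfg.n_genes, "noise", dtype=object)
    pos = 0
    for k, sz in enumerate(sizes):
        module_of[pos: pos + sz] = str(k)
        pos += sz
    biphasic_idx = pos
    module_of[biphasic_idx] = "noise"  # planted regulator, not a module member
    pos += 1

    patterns = _module_patterns(cfg.n_modules, cfg.n_phases)
    bounds = np.asarray(cfg.phase_boundaries)

    # --- mean profiles of on-trajectory cells -------------------------
    means = np.empty((cfg.n_genes, n_on))
    high = rng.uniform(10.0, 50.0, size=cfg.n_genes)
    # module off-state: exactly 0 by default, giving the tied-rank zeros real
    # dropout produces; a positive range yields strictly monotone profiles
    low = rng.uniform(cfg.low_range[0], cfg.low_range[1], size=cfg.n_genes)
    gene_profiles: dict[str, tuple[str, dict]] = {}
    mid_phase = (cfg.n_phases - 1) / 2.0
    pos = 0
    for k, sz in enumerate(sizes):
        pat = patterns[k]
        active_center = float(np.mean(np.where(pat > 0)[0]))
        direction = 1.0 if active_center >= mid_phase else -1.0
        for g in range(pos, pos + sz):
            params = {
                "levels": np.where(pat > 0, high[g], low[g]),
                "boundaries": bounds,
                "width": cfg.transition_width,
                "drift": direction * cfg.plateau_drift,
            }
            means[g] = profile_value(t_on, "steps", params)
            gene_profiles[gene_ids[g]] = ("steps", params)
        pos += sz

    last_b = float(bounds[-1])
    biphasic_params = {
        "base": 6.0, "peak": 40.0,
        "rise": last_b - cfg.transition_width,
        "fall": last_b + cfg.transition_width,
        "width": cfg.transition_width,
    }
    means[biphasic_idx] = profile_value(t_on, "biphasic", biphasic_params)
    gene_profiles[gene_ids[biphasic_idx]] = ("biphasic", biphasic_params)
    for g in range(pos, cfg.n_genes):
        if module_of[g] == "noise" and g != biphasic_idx:
            params = {"level": rng.uniform(0.5, 5.0)}
            means[g] = profile_value(t_on, "plateau", params)
            gene_profiles[gene_ids[g]] = ("plateau", params)

    # --- off-trajectory contaminant populations -----------------------
    if n_off > 0:
        n_pops = min(cfg.n_contaminant_pops, n_off)
        pop_means = rng.gamma(shape=1.5, scale=4.0, size=(n_pops, cfg.n_genes))
        pop_of_cell = np.arange(n_off) % n_pops
        off_means = pop_means[pop_of_cell].T  # genes x n_off
        means = np.concatenate([means, off_means], axis=1)
    else:
        pop_of_cell = np.zeros(0, dtype=int)

    # --- technical noise ----------------------------------------------
    lib = np.ones(cfg.n_cells)
    if cfg.library_sigma > 0:
        lib = rng.lognormal(mean=0.0, sigma=cfg.library_sigma, size=cfg.n_cells)
    mu = means * lib[None, :]
    if cfg.noise > 0:
        r = 1.0 / cfg.noise
        p = 1.0 / (1.0 + cfg.noise * np.maximum(mu, 1e-12))
        values = rng.negative_binomial(r, p).astype(float)
        strict = True
    else:
        values = mu.copy()
        strict = False
    if cfg.dropout_rate > 0:
        keep = rng.random(values.shape) >= cfg.dropout_rate
        values = values * keep

    # --- assemble -----------------------------------------------------
    perm = rng.permutation(cfg.n_cells)
    values = values[:, perm]
    cell_ids = [f"cell_{i:04d}" for i in range(cfg.n_cells)]

    latent = np.concatenate([t_on, np.full(n_off, np.nan)])[perm]
    on_flag = np.concatenate([np.ones(n_on, bool), np.zeros(n_off, bool)])[perm]
    population = np.concatenate([
        np.array(["trajectory"] * n_on, dtype=object),
        np.array([f"contaminant_{p}" for p in pop_of_cell], dtype=object),
    ])[perm]

    cells = pd.DataFrame(
        {"latent_time": latent, "on_trajectory": on_flag, "population": population},
        index=pd.Index(cell_ids, name="cell_id"),
    )
    genes = pd.DataFrame(
        {"module": module_of},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    truth = SyntheticTruth(
        cells=cells, genes=genes,
        phase_boundaries=tuple(cfg.phase_boundaries),
        transition_width=cfg.transition_width,
        biphasic_gene_id=gene_ids[biphasic_idx],
        gene_profiles=gene_profiles,
    )
    meta = cells[["on_trajectory", "population"]].copy()
    matrix = ExpressionMatrix(values, gene_ids, cell_ids, layer="counts",
                              cell_meta=meta, strict=strict)
    return matrix, truth
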