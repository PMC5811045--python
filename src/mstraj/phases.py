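"""Metastable-state / transition-phase segmentation of the pseudotime axis.

The global gene-variation curve is the mean absolute finite-difference
derivative of the min-max-normalized profiles of the most dispersed genes.
After moving-average smoothing, intervals where the discrete second
derivative is negative are transitions; everywhere else (including exact
zero) is metastable.  Runs shorter than ``min_run`` are merged into a
neighbor so the segmentation tiles the grid with alternating kinds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pseudotime import PseudotimeProfiles

__all__ = ["PhaseSegmentation", "global_variation", "segment_phases"]


@dataclass
class PhaseSegmentation:
    """Alternating metastable/transition intervals over grid [0, L-1]."""

    variation_curve: np.ndarray
    smoothed_curve: np.ndarray
    phases: list[tuple[int, int, str]]  # (start, end) inclusive, kind
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        L = len(self.variation_curve)
        if not self.phases:
            raise ValueError("empty segmentation")
        if self.phases[0][0] != 0 or self.phases[-1][1] != L - 1:
            raise ValueError("phases must tile the full grid")
        for (s0, e0, k0), (s1, e1, k1) in zip(self.phases, self.phases[1:]):
            if s1 != e0 + 1:
                raise ValueError("phases must be contiguous and non-overlapping")
            if k0 == k1:
                raise ValueError("phase kinds must alternate")

    @property
    def n_metastable(self) -> int:
        return sum(1 for _, _, k in self.phases if k == "metastable")

    @property
    def n_transitions(self) -> int:
        return sum(1 for _, _, k in self.phases if k == "transition")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.phases, columns=["start", "end", "kind"])


def global_variation(p: PseudotimeProfiles, n_top: int = 200) -> np.ndarray:
    """Mean |derivative| of the min-max-normalized top-dispersion profiles.

    Dispersion of a gene is the variance of its mean profile across the
    grid.  The derivative is the finite-difference gradient (one-sided at
    the endpoints, central inside) at unit grid spacing.
    """
    prof = p.mean_profile.to_numpy(dtype=float)
    if n_top > prof.shape[0]:
        raise ValueError("n_top exceeds the number of genes")
    disp = prof.var(axis=1)
    top = np.argsort(-disp, kind="stable")[:n_top]
    sel = prof[top]
    rng_ = sel.max(axis=1) - sel.min(axis=1)
    dynamic = rng_ > 0
    if not dynamic.any():
        warnings.warn("all selected profiles are constant; variation curve is zero")
        return np.zeros(prof.shape[1])
    sel = sel[dynamic]
    normed = (sel - sel.min(axis=1, keepdims=True)) / rng_[dynamic][:, None]
    deriv = np.abs(np.gradient(normed, axis=1))
    return deriv.mean(axis=0)


def _smooth(curve: np.ndarray, bandwidth: int) -> np.ndarray:
    if bandwidth <= 1:
        return curve.astype(float)
    pad = bandwidth // 2
    padded = np.pad(curve.astype(float), pad, mode="reflect")
    kernel = np.ones(bandwidth) / bandwidth
    out = np.convolve(padded, kernel, mode="same")[pad: pad + len(curve)]
    return out


def _second_derivative(curve: np.ndarray) -> np.ndarray:
    L = len(curve)
    d2 = np.zeros(L)
    d2[1:-1] = curve[2:] - 2.0 * curve[1:-1] + curve[:-2]
    d2[0] = d2[1]
    d2[-1] = d2[-2]
    return d2


def _runs(kinds: np.ndarray) -> list[tuple[int, int, str]]:
    out = []
    start = 0
    for i in range(1, len(kinds) + 1):
        if i == len(kinds) or kinds[i] != kinds[start]:
            out.append((start, i - 1, str(kinds[start])))
            start = i
    return out


def segment_phases(
    curve: np.ndarray,
    bandwidth: int = 5,
    min_run: int = 3,
    prominence_min: float = 0.05,
) -> PhaseSegmentation:
    """Segment the grid by the sign of the smoothed curve's second derivative.

    Negative second derivative -> transition; zero or positive ->
    metastable.  Runs shorter than ``min_run`` are absorbed into the longer
    neighboring run until all runs alternate and meet the minimum length.
    Transition runs whose curve rise is below ``prominence_min`` times the
    smoothed curve's range are treated as numerically-zero curvature and
    reassigned to metastable (the rule stays invariant to rescaling the
    curve's amplitude).
    """
    curve = np.asarray(curve, dtype=float)
    L = len(curve)
    if L < 5:
        raise ValueError("need a grid of at least 5 points")
    if bandwidth >= L:
        raise ValueError("bandwidth must be smaller than the grid length")
    smoothed = _smooth(curve, bandwidth)
    d2 = _second_derivative(smoothed)
    kinds = np.where(d2 < 0, "transition", "metastable").astype(object)

    runs = _runs(kinds)
    # absorb short runs (shortest first) into their longer neighbor
    while True:
        lengths = [(e - s + 1, i) for i, (s, e, _) in enumerate(runs)]
        short = [(ln, i) for ln, i in lengths if ln < min_run]
        if not short or len(runs) == 1:
            break
        _, i = min(short)
        s, e, _ = runs[i]
        left_len = runs[i - 1][1] - runs[i - 1][0] + 1 if i > 0 else -1
        right_len = runs[i + 1][1] - runs[i + 1][0] + 1 if i < len(runs) - 1 else -1
        target = i - 1 if left_len >= right_len else i + 1
        kinds[s: e + 1] = runs[target][2]
        runs = _runs(kinds)

    # drop transitions without a real bump: prominence relative to curve range
    span = float(smoothed.max() - smoothed.min())
    if span > 0:
        for s, e, kind in _runs(kinds):
            if kind != "transition":
                continue
            peak = smoothed[s: e + 1].max()
            outside = []
            if s > 0:
                outside.append(smoothed[s - 1])
            if e < L - 1:
                outside.append(smoothed[e + 1])
            prom = peak - (min(outside) if outside else smoothed.min())
            if prom < prominence_min * span:
                kinds[s: e + 1] = "metastable"

    phases = _runs(kinds)
    return PhaseSegmentation(
        variation_curve=curve, smoothed_curve=smoothed, phases=phases,
        params={"bandwidth": bandwidth, "min_run": min_run,
                "prominence_min": prominence_min},
    )
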