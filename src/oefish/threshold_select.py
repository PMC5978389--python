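"""Kappa-optimal presence thresholds.

Boosted-tree occurrence models emit capture probabilities; turning those into
presence/absence calls needs a per-species threshold.  Because prevalence is
rarely near 50%, a fixed 0.5 cut is a poor choice.  Instead the grid of
thresholds between zero and one (0.005 steps by default, endpoints included)
is searched exhaustively and the threshold maximising Cohen's Kappa against
the training presence/absence labels is selected.  Calls use the inclusive
convention: a species is present where its probability equals or exceeds the
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ThresholdError

__all__ = ["ThresholdResult", "cohens_kappa", "select_threshold", "call_presence"]


@dataclass(frozen=True)
class ThresholdResult:
    species: str
    threshold: float
    kappa: float
    grid_step: float
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def confusion(self) -> tuple[int, int, int, int]:
        return (self.tp, self.fp, self.fn, self.tn)


def cohens_kappa(tp: int, fp: int, fn: int, tn: int) -> float:
    """Chance-corrected agreement from a 2x2 confusion matrix.

    kappa = (p_o - p_e) / (1 - p_e), with observed agreement
    p_o = (tp + tn) / n and chance agreement
    p_e = [(tp+fp)(tp+fn) + (fn+tn)(fp+tn)] / n^2.  When p_e = 1 (both raters
    constant and identical) kappa is returned as 0 by convention.
    """
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    n = tp + fp + fn + tn
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = (tp + tn) / n
    p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
    if p_e >= 1.0:
        return 0.0
    return (p_o - p_e) / (1.0 - p_e)


def _grid(step: float) -> np.ndarray:
    n_steps = int(round(1.0 / step))
    return np.linspace(0.0, 1.0, n_steps + 1)


def select_threshold(
    labels, probs, grid_step: float = 0.005, species: str = ""
) -> ThresholdResult:
    """Exhaustive Kappa maximisation over the threshold grid.

    Every threshold t in {0, step, ..., 1} is evaluated with the inclusive
    call rule (present iff prob >= t); the t with maximal Kappa wins and ties
    break toward the smallest t (favouring sensitivity).
    """
    y = np.asarray(labels).astype(int)
    p = np.asarray(probs, dtype=float)
    if y.shape != p.shape or y.ndim != 1:
        raise ValueError("labels and probs must be 1-D and aligned")
    if y.min() == y.max():
        raise ThresholdError("threshold undefined: labels contain a single class")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")

    grid = _grid(grid_step)
    calls = p[None, :] >= grid[:, None]            # (n_thresholds, n_sites)
    pos = y == 1
    tp = calls[:, pos].sum(axis=1)
    fp = calls[:, ~pos].sum(axis=1)
    fn = pos.sum() - tp
    tn = (~pos).sum() - fp
    n = y.size
    p_o = (tp + tn) / n
    p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(p_e >= 1.0, 0.0, (p_o - p_e) / (1.0 - p_e))
    best = int(np.argmax(kappa))  # first max = smallest threshold on ties
    return ThresholdResult(
        species=species,
        threshold=float(grid[best]),
        kappa=float(kappa[best]),
        grid_step=grid_step,
        tp=int(tp[best]),
        fp=int(fp[best]),
        fn=int(fn[best]),
        tn=int(tn[best]),
    )


def call_presence(probs, threshold: float) -> np.ndarray:
    """Inclusive presence call: 1 where prob >= threshold, else 0."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return (np.asarray(probs, dtype=float) >= threshold).astype(int)
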