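"""Threshold-based classification evaluation for occurrence models.

Predicted probabilities become presence/absence calls at a threshold t
(present iff p >= t); performance is summarized by the 2x2 confusion matrix
(rows predicted, columns observed), the proportion correctly classified
(PCC), sensitivity, specificity, and Cohen's kappa — the chance-corrected
agreement (Po - Pe) / (1 - Pe).  The operating threshold is chosen by
scanning a fine grid and maximizing sensitivity + specificity, averaging
tied grid points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class ThresholdEvaluation:
    """Confusion counts at one threshold, orientation rows=predicted.

    ``tn``: predicted absent & observed absent; ``fn``: predicted absent &
    observed present; ``fp``: predicted present & observed absent; ``tp``:
    predicted present & observed present.
    """

    threshold: float
    tn: int
    fn: int
    fp: int
    tp: int

    def __post_init__(self) -> None:
        for name in ("tn", "fn", "fp", "tp"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer")

    @property
    def n(self) -> int:
        return self.tn + self.fn + self.fp + self.tp

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    def as_dict(self) -> dict:
        kappa, kappa_se = cohen_kappa(self)
        return {
            "threshold": self.threshold, "TN": self.tn, "FN": self.fn,
            "FP": self.fp, "TP": self.tp, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "PCC": percent_correct(self),
            "kappa": kappa, "kappa_SE": kappa_se,
        }


def confusion_matrix(observed, probabilities, threshold: float
                     ) -> ThresholdEvaluation:
    """Classify at ``threshold`` (present iff p >= t) and count the 2x2 cells."""
    obs = np.asarray(observed)
    p = np.asarray(probabilities, dtype=float)
    if obs.shape != p.shape:
        raise ValueError(f"length mismatch: {obs.shape} observed vs {p.shape} predicted")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    pred = p >= threshold
    obs = obs.astype(bool)
    return ThresholdEvaluation(
        threshold=float(threshold),
        tn=int(np.sum(~pred & ~obs)), fn=int(np.sum(~pred & obs)),
        fp=int(np.sum(pred & ~obs)), tp=int(np.sum(pred & obs)))


def optimal_threshold(observed, probabilities, step: float = 0.005) -> float:
    """Threshold maximizing sensitivity + specificity over a regular grid.

    The grid is {0, step, 2*step, ..., 1}.  When several grid points tie at
    the maximum, their mean is returned — which is why optimal thresholds can
    carry more decimals than the grid step.
    """
    obs = np.asarray(observed).astype(bool)
    if obs.all() or not obs.any():
        raise ValueError("optimal threshold needs both classes in the observations")
    n_steps = int(round(1.0 / step))
    grid = np.arange(n_steps + 1) / n_steps
    scores = np.empty(len(grid))
    for i, t in enumerate(grid):
        ev = confusion_matrix(obs, probabilities, t)
        scores[i] = ev.sensitivity + ev.specificity
    best = scores.max()
    return float(grid[scores == best].mean())


def percent_correct(ev: ThresholdEvaluation) -> float:
    """PCC: percentage of observations classified correctly, 100*(TN+TP)/n."""
    if ev.n == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * (ev.tn + ev.tp) / ev.n


def cohen_kappa(ev: ThresholdEvaluation) -> tuple[float, float]:
    """Cohen's kappa and its large-sample standard error.

    kappa = (Po - Pe) / (1 - Pe) with observed agreement Po = (TN+TP)/n and
    chance agreement Pe = [(TN+FN)(TN+FP) + (FP+TP)(FN+TP)] / n^2.  The SE is
    the simple large-sample form sqrt(Po (1-Po) / (n (1-Pe)^2)); it is
    informative only — published SDs for kappa are often computed by other
    (resampling or delta-method) recipes.
    """
    n = ev.n
    if n == 0:
        raise ValueError("empty confusion matrix")
    po = (ev.tn + ev.tp) / n
    pe = ((ev.tn + ev.fn) * (ev.tn + ev.fp)
          + (ev.fp + ev.tp) * (ev.fn + ev.tp)) / n ** 2
    if pe == 1.0:
        warnings.warn("degenerate marginals: chance agreement is 1, kappa undefined")
        return float("nan"), float("nan")
    kappa = (po - pe) / (1.0 - pe)
    se = np.sqrt(po * (1.0 - po) / (n * (1.0 - pe) ** 2))
    return float(kappa), float(se)


def evaluate_at_optimum(observed, probabilities, step: float = 0.005
                        ) -> ThresholdEvaluation:
    """Convenience: find the optimal threshold and evaluate there."""
    t = optimal_threshold(observed, probabilities, step)
    return confusion_matrix(observed, probabilities, t)
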