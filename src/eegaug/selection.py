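"""Selective augmentation integration.

Not every augmentation helps every decoder: some transforms (e.g. reversing
the time axis) destroy exactly the structure a reconstruction model needs.
The search implemented here attaches a trainable importance coefficient
``w_i`` in (0, 1) to every augmentation branch and runs in two stages:

Stage 1 (integration pruning): train the model with the active set A, letting
the coefficients adapt through the weighted contrastive loss.  Any branch
whose coefficient falls below the threshold ``t`` (default 0.4) is dropped
immediately; after each full training period the lowest coefficient is
additionally dropped if it is a low outlier relative to the others.  The loop
ends when the surviving coefficients are evenly distributed.

Stage 2 (single-augmentation probe): because surviving augmentations can
still interfere with one another, each survivor is also trained alone.

The best policy is the argmax over every evaluated candidate — the pruned
integrations, the single augmentations, and the no-augmentation baseline —
with ties broken toward the smaller policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np

from .autodiff import Tensor, stack
from .losses import contrastive_logits, contrastive_loss_pair
from .nn import Module, Parameter

__all__ = [
    "AugmentationWeights",
    "SelectionResult",
    "TrainerInterface",
    "init_weights",
    "weighted_contrastive_loss",
    "prune_below_threshold",
    "detect_low_outlier",
    "stage1_search",
    "stage2_single_eval",
    "select_best",
    "run_selection",
]


class AugmentationWeights(Module):
    """Trainable per-augmentation coefficients w_i = sigmoid(theta_i) in (0, 1).

    The sigmoid parameterization keeps every coefficient strictly inside the
    unit interval under any gradient update; all start at 0.5 (theta = 0).
    """

    def __init__(self, names, threshold: float = 0.4):
        self.names = list(names)
        self.threshold = float(threshold)
        self.theta = Parameter(np.zeros(len(self.names)))

    @property
    def w(self) -> dict[str, float]:
        vals = 1.0 / (1.0 + np.exp(-self.theta.data))
        return dict(zip(self.names, vals.tolist()))

    def w_tensor(self) -> Tensor:
        return self.theta.sigmoid()

    def subset(self, names) -> "AugmentationWeights":
        """Fresh re-initialized weights (0.5 each) for a reduced active set."""
        return AugmentationWeights(names, threshold=self.threshold)


def init_weights(names, threshold: float = 0.4) -> AugmentationWeights:
    """All coefficients initialized to 0.5, ranging over (0, 1)."""
    return AugmentationWeights(names, threshold=threshold)


def weighted_contrastive_loss(pairs, weights: AugmentationWeights) -> Tensor:
    """Coefficient-weighted mean of per-branch contrastive losses.

    Normalizing by the coefficient sum stops a uniform shrink of all w from
    trivially minimizing the loss; gradients reach both the embeddings and
    the coefficients.
    """
    pairs = list(pairs)
    if len(pairs) != len(weights.names):
        raise ValueError(f"{len(pairs)} branches but {len(weights.names)} coefficients")
    w = weights.w_tensor()
    if float(w.data.sum()) == 0:
        raise ValueError("all-zero augmentation coefficients")
    losses = stack([contrastive_loss_pair(contrastive_logits(p)) for p in pairs])
    return (losses * w).sum() / w.sum()


def prune_below_threshold(weights: AugmentationWeights | dict,
                          active: set[str] | None = None) -> set[str]:
    """Names surviving the hard threshold: keep i iff w_i >= t."""
    if isinstance(weights, AugmentationWeights):
        w, t = weights.w, weights.threshold
    else:
        raise TypeError("pass an AugmentationWeights instance")
    active = set(w) if active is None else set(active)
    return {name for name in active if w[name] >= t}


def detect_low_outlier(w: dict[str, float], k: float = 1.5) -> str | None:
    """The minimum-coefficient name, iff it sits significantly below the rest.

    "Significantly lower" is operationalized leave-one-out: the minimum is an
    outlier when ``w_min < mean(others) - k * sd(others)`` (population sd,
    default k = 1.5).  With fewer than 3 coefficients, or an evenly
    distributed vector, there is no outlier and the search loop terminates.
    """
    if len(w) < 3:
        return None
    name_min = min(w, key=w.get)
    others = np.array([v for n, v in w.items() if n != name_min])
    cutoff = others.mean() - k * others.std()
    return name_min if w[name_min] < cutoff else None


@dataclass
class IterationRecord:
    active: tuple[str, ...]
    w: dict[str, float]
    score: float


@dataclass
class SelectionResult:
    best_policy: frozenset[str]
    best_score: float
    trace: list[IterationRecord] = field(default_factory=list)
    stage2_scores: dict[str, float] = field(default_factory=dict)
    candidates: dict[frozenset, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "best_policy": sorted(self.best_policy),
            "best_score": self.best_score,
            "trace": [{"active": list(r.active), "w": r.w, "score": r.score}
                      for r in self.trace],
            "stage2_scores": dict(self.stage2_scores),
            "candidates": {",".join(sorted(k)) or "<none>": v
                           for k, v in self.candidates.items()},
        }


class TrainerInterface(Protocol):
    """What the search engine needs from a trainer.

    ``train`` fits the model from scratch with the given augmentation policy
    and returns an opaque trained-model handle; ``evaluate`` scores it on the
    validation split and returns the coefficient snapshot observed during
    training (higher score = better).  Both must be deterministic under a
    fixed seed.
    """

    def train(self, policy: set[str], seed: int): ...

    def evaluate(self, model) -> tuple[float, dict[str, float]]: ...


def stage1_search(trainer: TrainerInterface, initial: set[str],
                  threshold: float = 0.4, outlier_k: float = 1.5,
                  seed: int = 0, max_iterations: int | None = None
                  ) -> tuple[set[str], list[IterationRecord]]:
    """The outer pruning loop; returns the surviving policy and its trace."""
    active = set(initial)
    trace: list[IterationRecord] = []
    max_iterations = max_iterations or len(initial) + 1
    for iteration in range(max_iterations):
        if not active:
            break
        model = trainer.train(active, seed=seed + iteration)
        score, w_all = trainer.evaluate(model)
        w = {n: w_all[n] for n in active}
        trace.append(IterationRecord(tuple(sorted(active)), dict(w), score))
        active = {n for n in active if w[n] >= threshold}
        outlier = detect_low_outlier({n: w[n] for n in active}, k=outlier_k)
        if outlier is None:
            break  # coefficients evenly distributed: policy fixed
        active = active - {outlier}
    return active, trace


def stage2_single_eval(trainer: TrainerInterface, policy: set[str],
                       seed: int = 0) -> dict[str, float]:
    """Train one model per surviving augmentation alone; return all scores."""
    scores: dict[str, float] = {}
    for i, name in enumerate(sorted(policy)):
        model = trainer.train({name}, seed=seed + 1000 + i)
        scores[name], _ = trainer.evaluate(model)
    return scores


def select_best(trace: list[IterationRecord], stage2_scores: dict[str, float],
                baseline_score: float) -> SelectionResult:
    """Argmax over integrated policies, single augmentations and the baseline.

    Ties break toward the smaller policy, so the no-augmentation baseline
    wins when nothing beats it.
    """
    candidates: dict[frozenset, float] = {frozenset(): baseline_score}
    for rec in trace:
        key = frozenset(rec.active)
        if key not in candidates or rec.score > candidates[key]:
            candidates[key] = rec.score
    for name, score in stage2_scores.items():
        key = frozenset({name})
        if key not in candidates or score > candidates[key]:
            candidates[key] = score
    best = max(candidates, key=lambda k: (candidates[k], -len(k)))
    return SelectionResult(best_policy=best, best_score=candidates[best],
                           trace=list(trace), stage2_scores=dict(stage2_scores),
                           candidates=candidates)


def run_selection(trainer: TrainerInterface, initial: set[str],
                  threshold: float = 0.4, outlier_k: float = 1.5,
                  seed: int = 0) -> SelectionResult:
    """Full two-stage search plus final argmax (the engine's entry point)."""
    baseline_model = trainer.train(set(), seed=seed)
    baseline_score, _ = trainer.evaluate(baseline_model)
    fixed, trace = stage1_search(trainer, initial, threshold=threshold,
                                 outlier_k=outlier_k, seed=seed)
    stage2 = stage2_single_eval(trainer, fixed, seed=seed)
    return select_best(trace, stage2, baseline_score)
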