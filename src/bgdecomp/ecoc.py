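"""Second-level error-correcting output-code (ECOC) multiclass ensemble.

An ordered list of L binary models induces a 5xL codeword matrix C with
C[k][j] = 1 iff class k belongs to model j's positive set; the class-0 row
is all zeros by construction. A case is classified by collecting the L
binary votes into a bit string and choosing the class whose ideal codeword
has minimal Hamming distance. Representing 5 classes requires at least
ceil(log2 5) = 3 classifiers with pairwise-distinct codewords; additional
bits act as error-correcting redundancy.

Distance ties are resolved by clinical severity: hypoglycemia > severe
hyperglycemia > moderate hyperglycemia > nondecompensated > mild
hyperglycemia (mild last to curb false alarms).

The ensemble composition — which candidate binary models to include — is
selected by a genetic algorithm over inclusion bitmasks, maximising the
macro-averaged per-class precision of the decoded predictions on validation
data (a PR-curve-area fitness is available as an alternative reading of
"average precision").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score

from .binary_models import BinaryModelSpec, TrainedBinaryModel

__all__ = [
    "DEFAULT_TIEBREAK_PRIORITY", "N_CLASSES", "EnsembleSpec", "GAConfig",
    "build_codewords", "decode", "decode_matrix", "predict_case",
    "predict_ensemble", "optimize_composition",
]

log = logging.getLogger(__name__)

N_CLASSES = 5

#: Clinical severity order used to break Hamming-distance ties.
DEFAULT_TIEBREAK_PRIORITY: tuple[int, ...] = (1, 4, 3, 0, 2)

MIN_ENSEMBLE_SIZE = 3  # ceil(log2 5)


def _positive_sets(models: Sequence) -> list[frozenset[int]]:
    sets = []
    for m in models:
        if hasattr(m, "spec"):
            sets.append(frozenset(m.spec.positive_set))
        elif hasattr(m, "positive_set"):
            sets.append(frozenset(m.positive_set))
        else:
            sets.append(frozenset(m))
    return sets


def build_codewords(models: Sequence) -> np.ndarray:
    """5 x L codeword matrix from an ordered list of binary model specs.

    Raises when two classes share a codeword (naming them) or when fewer
    than the minimum of 3 classifiers are supplied.
    """
    sets = _positive_sets(models)
    L = len(sets)
    C = np.zeros((N_CLASSES, L), dtype=int)
    for j, pos in enumerate(sets):
        for k in pos:
            C[int(k), j] = 1
    seen: dict[tuple, int] = {}
    collisions = []
    for k in range(N_CLASSES):
        key = tuple(C[k])
        if key in seen:
            collisions.append((seen[key], k))
        else:
            seen[key] = k
    if collisions:
        pairs = ", ".join(f"{a} and {b}" for a, b in collisions)
        raise ValueError(f"codeword collision between classes {pairs}")
    if L < MIN_ENSEMBLE_SIZE:
        raise ValueError(
            f"at least {MIN_ENSEMBLE_SIZE} binary classifiers are required "
            f"for {N_CLASSES} classes, got {L}")
    return C


def decode(bits: Sequence[int], codewords: np.ndarray,
           priority: Sequence[int] = DEFAULT_TIEBREAK_PRIORITY) -> int:
    """Minimal-Hamming-distance class of one vote bit string."""
    bits = np.asarray(bits, dtype=int)
    if bits.shape != (codewords.shape[1],):
        raise ValueError(
            f"bit string length {bits.shape} does not match ensemble "
            f"size {codewords.shape[1]}")
    return int(decode_matrix(bits[None, :], codewords, priority)[0])


def decode_matrix(bits: np.ndarray, codewords: np.ndarray,
                  priority: Sequence[int] = DEFAULT_TIEBREAK_PRIORITY
                  ) -> np.ndarray:
    """Vectorised decoding of an (n, L) vote matrix."""
    priority = tuple(priority)
    if sorted(priority) != list(range(N_CLASSES)):
        raise ValueError("priority must be a permutation of 0..4")
    bits = np.asarray(bits, dtype=int)
    if bits.ndim != 2 or bits.shape[1] != codewords.shape[1]:
        raise ValueError("vote matrix width does not match ensemble size")
    # distances: (n, 5); reorder classes by priority so argmin's first-match
    # tie behaviour realises the clinical tie-break
    dist = (bits[:, None, :] != codewords[None, :, :]).sum(axis=2)
    order = np.asarray(priority)
    winner = order[np.argmin(dist[:, order], axis=1)]
    return winner.astype(int)


@dataclass
class EnsembleSpec:
    """An ordered list of trained binary models plus decoding metadata."""

    models: list[TrainedBinaryModel]
    codewords: np.ndarray = None
    priority: tuple[int, ...] = DEFAULT_TIEBREAK_PRIORITY
    ga_trace: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.codewords is None:
            self.codewords = build_codewords(self.models)

    @property
    def labels(self) -> list[str]:
        return [m.label for m in self.models]

    def votes(self, X: pd.DataFrame) -> np.ndarray:
        return np.column_stack([m.vote(X) for m in self.models])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return decode_matrix(self.votes(X), self.codewords, self.priority)


def predict_case(features_row: pd.DataFrame, ensemble: EnsembleSpec
                 ) -> tuple[int, np.ndarray]:
    """Class and per-model votes for a single feature row (audit trail)."""
    if len(features_row) != 1:
        raise ValueError("predict_case expects exactly one feature row")
    votes = ensemble.votes(features_row)
    return int(decode_matrix(votes, ensemble.codewords,
                             ensemble.priority)[0]), votes[0]


def predict_ensemble(features: pd.DataFrame, ensemble: EnsembleSpec
                     ) -> np.ndarray:
    return ensemble.predict(features)


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings for the composition search."""

    population: int = 50
    generations: int = 30
    crossover_rate: float = 0.5
    mutation_rate: float | None = None  # default 1/L
    tournament: int = 3
    elitism: int = 2


def _macro_precision(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Macro-averaged per-class precision; classes never predicted score 0."""
    precisions = []
    for k in range(N_CLASSES):
        pred_k = y_pred == k
        precisions.append(
            float((y_true[pred_k] == k).mean()) if pred_k.any() else 0.0)
    return float(np.mean(precisions))


def _pr_auc_fitness(y_true: np.ndarray, dist: np.ndarray) -> float:
    """One-vs-rest PR-curve area, macro-averaged, scoring by -distance."""
    scores = []
    for k in range(N_CLASSES):
        yk = (y_true == k).astype(int)
        if yk.sum() == 0:
            continue
        scores.append(average_precision_score(yk, -dist[:, k]))
    return float(np.mean(scores)) if scores else 0.0


def optimize_composition(candidates: Sequence[TrainedBinaryModel],
                         X_val: pd.DataFrame, y_val: np.ndarray,
                         ga: GAConfig | None = None, seed: int = 0,
                         fitness: str = "macro_precision",
                         priority: Sequence[int] = DEFAULT_TIEBREAK_PRIORITY,
                         ) -> tuple[EnsembleSpec, dict]:
    """Select the ensemble composition by a seeded genetic algorithm.

    The GA evolves inclusion bitmasks over the candidate models. Masks whose
    induced codeword matrix is infeasible (collision, or fewer than 3
    members) receive worst fitness. Returns the best feasible ensemble and a
    search report with the per-generation best fitness and every mask
    visited. Deterministic for a fixed seed.
    """
    if fitness not in ("macro_precision", "pr_auc"):
        raise ValueError("fitness must be 'macro_precision' or 'pr_auc'")
    M = len(candidates)
    sets = _positive_sets(candidates)
    if len(set(sets)) != M:
        raise ValueError("candidate models must have distinct positive sets")
    ga = ga or GAConfig()
    rng = np.random.default_rng(seed)
    y_val = np.asarray(y_val, dtype=int)

    # votes of every candidate, computed once
    votes_all = np.column_stack([m.vote(X_val) for m in candidates])

    memo: dict[tuple, float] = {}

    def evaluate(mask: np.ndarray) -> float:
        key = tuple(int(b) for b in mask)
        if key in memo:
            return memo[key]
        idx = np.flatnonzero(mask)
        score = -np.inf
        if len(idx) >= MIN_ENSEMBLE_SIZE:
            try:
                C = build_codewords([sets[i] for i in idx])
            except ValueError:
                C = None
            if C is not None:
                bits = votes_all[:, idx]
                if fitness == "macro_precision":
                    pred = decode_matrix(bits, C, priority)
                    score = _macro_precision(y_val, pred)
                else:
                    dist = (bits[:, None, :] != C[None, :, :]).sum(axis=2)
                    score = _pr_auc_fitness(y_val, dist)
        memo[key] = score
        return score

    mut = ga.mutation_rate if ga.mutation_rate is not None else 1.0 / M
    pop = (rng.random((ga.population, M)) < 0.5).astype(int)
    pop[0] = 1  # ensure the all-candidates mask is explored
    trace = []
    best_mask, best_fit = None, -np.inf
    for gen in range(ga.generations):
        fits = np.array([evaluate(ind) for ind in pop])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best_mask = pop[gen_best].copy()
        trace.append({"generation": gen, "best_fitness": best_fit})
        elite_idx = np.argsort(-fits)[:ga.elitism]
        nxt = [pop[i].copy() for i in elite_idx]
        while len(nxt) < ga.population:
            a = _tournament(pop, fits, ga.tournament, rng)
            b = _tournament(pop, fits, ga.tournament, rng)
            child = np.where(rng.random(M) < ga.crossover_rate, a, b)
            flip = rng.random(M) < mut
            child = np.where(flip, 1 - child, child)
            nxt.append(child)
        pop = np.array(nxt)
    if best_mask is None or not np.isfinite(best_fit):
        raise ValueError("no feasible ensemble composition found")

    idx = np.flatnonzero(best_mask)
    members = [candidates[i] for i in idx]
    ensemble = EnsembleSpec(models=members, priority=tuple(priority),
                            ga_trace=trace)
    report = {
        "mask": best_mask.tolist(),
        "fitness": best_fit,
        "labels": [m.label for m in members],
        "visited": {k: v for k, v in memo.items()},
        "trace": trace,
    }
    log.info("GA selected ensemble %s with %s=%.4f",
             report["labels"], fitness, best_fit)
    return ensemble, report


def _tournament(pop: np.ndarray, fits: np.ndarray, k: int,
                rng: np.random.Generator) -> np.ndarray:
    idx = rng.integers(len(pop), size=k)
    return pop[idx[np.argmax(fits[idx])]]
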