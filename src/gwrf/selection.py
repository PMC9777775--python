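"""Frequency-based important-feature extraction.

A feature's importance is how many of the forest's trees sampled it into
their subset — nothing more. The top candidates by that count feed a
nested-top-j accuracy sweep: for each grid value j, the data are restricted
to the j highest-frequency features, a fresh GWRF is trained and its test
accuracy recorded; the grid point with the best accuracy defines the
important-feature set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forest import EvolutionConfig, GeneticWeightedForest, WeightedForest, subset_size
from .fusion import FusedDataset

__all__ = [
    "FrequencyTable",
    "SweepResult",
    "feature_frequency",
    "top_candidates",
    "sweep_grid",
    "sweep",
]


@dataclass
class FrequencyTable:
    """Per-feature subset-membership counts across a forest's trees."""

    counts: np.ndarray
    source_n_trees: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts < 0).any() or (self.counts > self.source_n_trees).any():
            raise ValueError("counts must lie in [0, n_trees]")


@dataclass
class SweepResult:
    """Accuracy over nested top-j candidate sets."""

    grid: np.ndarray
    accuracies: np.ndarray
    best_count: int

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=int)
        self.accuracies = np.asarray(self.accuracies, dtype=float)


def feature_frequency(forest: WeightedForest) -> FrequencyTable:
    """Count, for every feature, the trees whose subset contains it."""
    counts = np.zeros(forest.num_features, dtype=int)
    for tree in forest.trees:
        counts[tree.feature_subset] += 1
    return FrequencyTable(counts=counts, source_n_trees=forest.n_trees)


def top_candidates(freq: FrequencyTable, limit: int = 1000) -> np.ndarray:
    """Features ranked by descending count (ties: ascending index), truncated."""
    if freq.counts.size < 1:
        raise ValueError("frequency table is empty")
    idx = np.arange(freq.counts.size)
    order = np.lexsort((idx, -freq.counts))
    return order[: int(limit)]


def sweep_grid(
    m: int, n_candidates: int, end: int = 1000, step: int = 10, start: int | None = None
) -> np.ndarray:
    """Grid of candidate counts: multiples of ``step`` in (m, end].

    Starts at the smallest multiple of ``step`` strictly greater than the
    per-tree subset size m (m = 209 starts the grid at 210) and is
    truncated at the number of available candidates. An explicit ``start``
    overrides the computed one.
    """
    if start is None:
        start = (int(m) // step + 1) * step
    stop = min(int(end), int(n_candidates))
    if n_candidates < start:
        raise ValueError(f"need at least {start} candidates for grid start, got {n_candidates}")
    return np.arange(start, stop + 1, step)


def sweep(
    candidates: np.ndarray,
    data: FusedDataset,
    config: EvolutionConfig,
    end: int = 1000,
    step: int = 10,
    start: int | None = None,
) -> SweepResult:
    """Test accuracy over nested top-j candidate feature sets.

    For each grid value j the data are restricted to the j top-ranked
    candidates and a GWRF is trained from scratch with ``config`` (fresh
    stratified 6:2:2 split from the stored seed). ``best_count`` is the
    accuracy argmax, ties resolved toward fewer features.
    """
    candidates = np.asarray(candidates, dtype=int)
    m = subset_size(data.n_features)
    grid = sweep_grid(m, len(candidates), end=end, step=step, start=start)
    accuracies = np.empty(len(grid))
    for gi, j in enumerate(grid):
        sub = data.restrict_features(candidates[:j], name=f"{data.name}:top{j}")
        results = GeneticWeightedForest(sub, config).fit()
        accuracies[gi] = results.evaluate()["accuracy"]
    best = int(grid[int(np.argmax(accuracies))])  # argmax -> first max -> smaller j
    return SweepResult(grid=grid, accuracies=accuracies, best_count=best)
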