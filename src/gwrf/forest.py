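"""The genetic weighted random forest (GWRF).

A random-subspace ensemble of CART trees over a two-class fused dataset,
with three additions to the plain random forest:

* **stratified 6:2:2 split** into train / validation / test sets,
* **genetic evolution** of the forest: per generation the trees are
  randomly partitioned into groups, each group's champion (best validation
  accuracy) survives, and randomly paired champions produce children by
  recombining their feature subsets (child trees are refit on the training
  set) until the population size is restored,
* **weighted voting**: each tree's vote is weighted by its validation
  accuracy, and the ensemble decision is the sign of the weighted vote sum.

Every tree sees a random subset of m = floor(sqrt(num_features)) feature
columns. Two ablation flags (``use_weights``, ``use_evolution``) recover
the plain random forest, the weighted random forest and the
evolution-only random forest as special cases.

The module-level functions implement the individual steps; the
:class:`GeneticWeightedForest` model class orchestrates them and its
:meth:`~GeneticWeightedForest.fit` returns a :class:`GWRFResults` carrying
the fitted forest, its weights and evaluation utilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    precision_recall_fscore_support,
    roc_auc_score,
)
from sklearn.tree import DecisionTreeClassifier

from .fusion import FusedDataset

__all__ = [
    "SplitDataset",
    "TreeSpec",
    "WeightedForest",
    "EvolutionConfig",
    "split_dataset",
    "sample_feature_subset",
    "fit_tree",
    "build_initial_forest",
    "tree_accuracy",
    "select_champions",
    "evolve",
    "compute_weights",
    "predict_weighted",
    "evaluate",
    "GeneticWeightedForest",
    "GWRFResults",
    "forest_to_dict",
    "forest_from_dict",
]

#: train : validation : test proportions.
SPLIT_RATIOS = (0.6, 0.2, 0.2)

_MAX_SEED = 2**31 - 1


@dataclass
class EvolutionConfig:
    """Hyperparameters of the GWRF.

    Defaults are the optimal operating point reported for the AD-HC task:
    320 trees evolved for 50 generations in champion groups of 5. Setting
    ``generations=0`` or ``use_evolution=False`` skips evolution;
    ``use_weights=False`` forces all vote weights to 1. The four
    combinations of the two flags give the plain, weighted, evolution-only
    and full genetic weighted random forests.
    """

    n_trees: int = 320
    group_size: int = 5
    generations: int = 50
    use_weights: bool = True
    use_evolution: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees <= 0:
            raise ValueError("n_trees must be positive")
        if self.group_size <= 0:
            raise ValueError("group_size must be positive")
        if not (0 <= self.generations <= 50):
            raise ValueError("generations must lie in [0, 50]")


@dataclass
class TreeSpec:
    """One ensemble member: a CART tree restricted to a feature subset."""

    feature_subset: np.ndarray
    model: object

    def __post_init__(self) -> None:
        self.feature_subset = np.asarray(self.feature_subset, dtype=int)

    def predict(self, x_rows: np.ndarray) -> np.ndarray:
        return np.asarray(self.model.predict(np.asarray(x_rows)[:, self.feature_subset]), dtype=int)


@dataclass
class SplitDataset:
    """Stratified train / validation / test partition of a fused dataset."""

    train: FusedDataset
    valid: FusedDataset
    test: FusedDataset


@dataclass
class WeightedForest:
    """A forest of subset trees plus (optionally) per-tree vote weights."""

    trees: list[TreeSpec]
    weights: np.ndarray | None
    config: EvolutionConfig
    num_features: int

    @property
    def n_trees(self) -> int:
        return len(self.trees)


def _largest_remainder(n: int, ratios: Sequence[float]) -> np.ndarray:
    """Integer allocation of n items to parts by largest-remainder rounding."""
    quotas = np.asarray(ratios, dtype=float) * n
    base = np.floor(quotas).astype(int)
    short = n - base.sum()
    # Ties broken toward earlier parts (train first).
    order = np.argsort(-(quotas - base), kind="stable")
    base[order[:short]] += 1
    return base


def split_dataset(s: FusedDataset, seed: int) -> SplitDataset:
    """Stratified 6:2:2 split, deterministic given ``seed``.

    Within each label class the per-part counts are assigned by
    largest-remainder rounding, so every part's class count differs from
    the exact proportion by less than one.
    """
    if s.n < 10:
        raise ValueError("dataset too small to split 6:2:2 (need N >= 10)")
    classes = np.unique(s.labels)
    if len(classes) < 2:
        raise ValueError("both label classes must be present")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x5EED)))
    parts: list[list[np.ndarray]] = [[], [], []]
    for c in classes:
        rows = np.flatnonzero(s.labels == c)
        rows = rng.permutation(rows)
        counts = _largest_remainder(len(rows), SPLIT_RATIOS)
        cuts = np.cumsum(counts)[:-1]
        for part, chunk in zip(parts, np.split(rows, cuts)):
            part.append(chunk)
    names = ("train", "valid", "test")
    out = [s.take(np.sort(np.concatenate(chunks)), name=f"{s.name}:{nm}" if s.name else nm)
           for chunks, nm in zip(parts, names)]
    return SplitDataset(*out)


def subset_size(num_features: int) -> int:
    """Per-tree feature-subset size m = floor(sqrt(num_features))."""
    if num_features < 1:
        raise ValueError("num_features must be >= 1")
    return int(math.isqrt(int(num_features)))


def sample_feature_subset(
    num_features: int, seed: int | np.random.Generator
) -> np.ndarray:
    """m = floor(sqrt(num_features)) distinct feature indices, uniform."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = subset_size(num_features)
    return np.sort(rng.choice(num_features, size=m, replace=False))


def fit_tree(
    train: FusedDataset, subset: np.ndarray, seed: int | np.random.Generator = 0
) -> TreeSpec:
    """Fit a CART tree (Gini, unlimited depth, min leaf 1) on a feature subset."""
    if train.n == 0:
        raise ValueError("training set is empty")
    subset = np.asarray(subset, dtype=int)
    if len(np.unique(subset)) != len(subset) or subset.min() < 0 or subset.max() >= train.n_features:
        raise ValueError("invalid feature subset")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    model = DecisionTreeClassifier(
        criterion="gini", random_state=int(rng.integers(_MAX_SEED))
    )
    model.fit(train.features[:, subset], train.labels)
    return TreeSpec(feature_subset=subset, model=model)


def build_initial_forest(
    train: FusedDataset,
    config: EvolutionConfig,
    rng: np.random.Generator | None = None,
) -> WeightedForest:
    """n independent trees, each on its own random feature subset; weights unset."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xF07)))
    trees = [fit_tree(train, sample_feature_subset(train.n_features, rng), rng)
             for _ in range(config.n_trees)]
    return WeightedForest(trees=trees, weights=None, config=config, num_features=train.n_features)


def tree_accuracy(tree: TreeSpec, valid: FusedDataset) -> float:
    """Fraction of validation rows the tree classifies correctly."""
    if valid.n == 0:
        raise ValueError("validation set is empty")
    return float(np.mean(tree.predict(valid.features) == valid.labels))


def select_champions(
    trees: list[TreeSpec],
    valid: FusedDataset,
    group_size: int,
    rng: np.random.Generator,
) -> tuple[list[int], list[np.ndarray]]:
    """Random group partition and per-group champions.

    Returns ``(champion_indices, groups)``: the population is randomly
    partitioned into groups of ``group_size`` (the last group may be
    short); each group's champion is its tree with the best validation
    accuracy, ties resolved to the lowest tree index.
    """
    n = len(trees)
    order = rng.permutation(n)
    groups = [order[s : s + group_size] for s in range(0, n, group_size)]
    champions = []
    for group in groups:
        accs = np.array([tree_accuracy(trees[i], valid) for i in group])
        champions.append(int(group[np.lexsort((group, -accs))[0]]))
    return champions, groups


def _crossover_subset(
    parent_a: TreeSpec, parent_b: TreeSpec, num_features: int, rng: np.random.Generator
) -> np.ndarray:
    """Child subset: half from each parent, deduplicated, refilled uniformly."""
    m = len(parent_a.feature_subset)
    take_a = m // 2
    part_a = rng.choice(parent_a.feature_subset, size=take_a, replace=False)
    part_b = rng.choice(parent_b.feature_subset, size=m - take_a, replace=False)
    child = np.unique(np.concatenate([part_a, part_b]))
    if len(child) < m:
        pool = np.setdiff1d(np.arange(num_features), child, assume_unique=True)
        child = np.concatenate([child, rng.choice(pool, size=m - len(child), replace=False)])
    return np.sort(child)


def evolve(
    forest: WeightedForest,
    train: FusedDataset,
    valid: FusedDataset,
    config: EvolutionConfig | None = None,
    rng: np.random.Generator | None = None,
) -> WeightedForest:
    """Evolve the forest for ``config.generations`` generations.

    Each generation: randomly partition the population into groups of
    ``group_size`` (a short last group is allowed); within each group the
    champion — the tree with the best validation accuracy, ties to the
    lowest index — survives; champions are randomly paired (a lone champion
    pairs with itself) and each pair produces children by subset crossover,
    cycling over the pairs until ``n_trees`` children exist. The children
    replace the population. ``generations == 0`` returns the forest
    unchanged.
    """
    config = config if config is not None else forest.config
    n = forest.n_trees
    if config.group_size > n:
        raise ValueError(f"group_size {config.group_size} exceeds forest size {n}")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xE70)))
    trees = list(forest.trees)
    for _ in range(config.generations):
        champion_idx, _ = select_champions(trees, valid, config.group_size, rng)
        champions = [trees[i] for i in champion_idx]
        pairing = rng.permutation(len(champions))
        pairs: list[tuple[TreeSpec, TreeSpec]] = []
        for k in range(0, len(pairing) - 1, 2):
            pairs.append((champions[pairing[k]], champions[pairing[k + 1]]))
        if len(pairing) % 2:  # lone champion self-pairs
            pairs.append((champions[pairing[-1]], champions[pairing[-1]]))
        children: list[TreeSpec] = []
        while len(children) < n:
            for pa, pb in pairs:
                if len(children) >= n:
                    break
                subset = _crossover_subset(pa, pb, forest.num_features, rng)
                children.append(fit_tree(train, subset, rng))
        trees = children
    return WeightedForest(trees=trees, weights=None, config=config, num_features=forest.num_features)


def compute_weights(
    forest: WeightedForest, valid: FusedDataset, config: EvolutionConfig | None = None
) -> WeightedForest:
    """Set each tree's vote weight to its validation accuracy.

    With ``use_weights=False`` all weights are forced to 1, reducing the
    committee to an unweighted majority vote (the ablation variants).
    """
    config = config if config is not None else forest.config
    if config.use_weights:
        weights = np.array([tree_accuracy(t, valid) for t in forest.trees])
    else:
        weights = np.ones(forest.n_trees)
    return WeightedForest(trees=forest.trees, weights=weights, config=config,
                          num_features=forest.num_features)


def predict_weighted(forest: WeightedForest, x_rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weighted-committee prediction.

    Returns ``(labels, scores)`` where ``score = sum_f W_f * vote_f`` with
    votes in {+1, -1} and ``label = sign(score)``. A tied score falls back
    to the single highest-weight tree's vote (ties to the lowest tree
    index); if every weight is zero the committee reverts to an unweighted
    majority vote.
    """
    if forest.weights is None:
        raise ValueError("forest weights are unset; call compute_weights first")
    x_rows = np.atleast_2d(np.asarray(x_rows, dtype=float))
    votes = np.stack([t.predict(x_rows) for t in forest.trees])  # (n_trees, n_rows)
    weights = forest.weights
    if np.all(weights == 0):
        weights = np.ones(forest.n_trees)
    scores = weights @ votes
    labels = np.sign(scores).astype(int)
    ties = labels == 0
    if ties.any():
        # argmax returns the first (lowest-index) maximal weight.
        best_tree = int(np.argmax(weights))
        labels[ties] = votes[best_tree, ties]
    return labels, scores


def evaluate(forest: WeightedForest, test: FusedDataset) -> dict[str, float]:
    """Accuracy, macro precision / recall / F1 and AUC on a held-out set.

    The AUC uses the continuous weighted vote sum as the ranking score.
    """
    if test.n == 0:
        raise ValueError("test set is empty")
    labels, scores = predict_weighted(forest, test.features)
    accuracy = float(np.mean(labels == test.labels))
    precision, recall, f1, _ = precision_recall_fscore_support(
        test.labels, labels, average="macro", zero_division=0
    )
    if len(np.unique(test.labels)) == 2:
        auc = float(roc_auc_score(test.labels == 1, scores))
    else:
        auc = float("nan")
    return {
        "accuracy": accuracy,
        "precision": float(precision),
        "recall": float(recall),
        "f1": float(f1),
        "auc": auc,
    }


class GeneticWeightedForest:
    """GWRF model over a fused two-class dataset.

    Parameters
    ----------
    data
        The fused dataset (alpha-scaled features, labels in {+1, -1}).
    config
        Ensemble hyperparameters; defaults to :class:`EvolutionConfig`'s
        defaults.

    ``fit()`` performs the stratified 6:2:2 split, builds the initial
    random-subspace forest on the training part, evolves it on the
    validation part, computes the vote weights, and returns a
    :class:`GWRFResults`.
    """

    def __init__(self, data: FusedDataset, config: EvolutionConfig | None = None):
        self.data = data
        self.config = config if config is not None else EvolutionConfig()

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_col: str = "label",
        config: EvolutionConfig | None = None,
        **config_kwargs,
    ) -> "GeneticWeightedForest":
        """Build from a features-plus-label DataFrame (IDs in the index)."""
        if config is None:
            config = EvolutionConfig(**config_kwargs)
        return cls(FusedDataset.from_frame(df, label_col=label_col), config)

    def fit(self) -> "GWRFResults":
        cfg = self.config
        split = split_dataset(self.data, cfg.seed)
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0x6F)))
        forest = build_initial_forest(split.train, cfg, rng=rng)
        if cfg.use_evolution and cfg.generations > 0:
            forest = evolve(forest, split.train, split.valid, cfg, rng=rng)
        elif not cfg.use_evolution:
            forest = replace(forest, config=replace(cfg, generations=0))
        forest = compute_weights(forest, split.valid, cfg)
        return GWRFResults(model=self, forest=forest, split=split)


@dataclass
class GWRFResults:
    """Fitted GWRF: the weighted forest, the data split, and diagnostics."""

    model: GeneticWeightedForest
    forest: WeightedForest
    split: SplitDataset
    _test_metrics: dict | None = field(default=None, repr=False)

    @property
    def config(self) -> EvolutionConfig:
        return self.forest.config

    @property
    def weights(self) -> np.ndarray:
        return self.forest.weights

    def predict(self, x_rows: np.ndarray) -> np.ndarray:
        return predict_weighted(self.forest, x_rows)[0]

    def decision_scores(self, x_rows: np.ndarray) -> np.ndarray:
        return predict_weighted(self.forest, x_rows)[1]

    def evaluate(self, data: FusedDataset | None = None) -> dict[str, float]:
        """Metrics on ``data`` (default: the held-out test part)."""
        if data is None:
            if self._test_metrics is None:
                self._test_metrics = evaluate(self.forest, self.split.test)
            return self._test_metrics
        return evaluate(self.forest, data)

    def feature_frequency(self):
        from .selection import feature_frequency

        return feature_frequency(self.forest)

    def summary(self) -> str:
        cfg = self.config
        m = evaluate(self.forest, self.split.valid)
        t = self.evaluate()
        w = self.forest.weights
        lines = [
            "Genetic Weighted Random Forest",
            "=" * 46,
            f"{'trees':<28}{cfg.n_trees:>18}",
            f"{'generations':<28}{(cfg.generations if cfg.use_evolution else 0):>18}",
            f"{'group size':<28}{cfg.group_size:>18}",
            f"{'weighted voting':<28}{str(cfg.use_weights):>18}",
            f"{'features':<28}{self.forest.num_features:>18}",
            f"{'subset size m':<28}{len(self.forest.trees[0].feature_subset):>18}",
            f"{'split (train/valid/test)':<28}"
            f"{f'{self.split.train.n}/{self.split.valid.n}/{self.split.test.n}':>18}",
            f"{'weights (min/mean/max)':<28}"
            f"{f'{w.min():.3f}/{w.mean():.3f}/{w.max():.3f}':>18}",
            "-" * 46,
            f"{'metric':<14}{'valid':>16}{'test':>16}",
        ]
        for key in ("accuracy", "precision", "recall", "f1", "auc"):
            lines.append(f"{key:<14}{m[key]:>16.4f}{t[key]:>16.4f}")
        return "\n".join(lines)


# --------------------------------------------------------------------------
# JSON-safe (de)serialisation: per-tree feature subset, decision rules and
# weight. Deserialised trees use a numpy rule-traversal predictor, so a model
# written by `gwrf train` can be evaluated without the original fit.


class _RuleTree:
    """Predicts from exported CART arrays (children / feature / threshold)."""

    def __init__(self, rules: dict):
        self.left = np.asarray(rules["children_left"], dtype=int)
        self.right = np.asarray(rules["children_right"], dtype=int)
        self.feature = np.asarray(rules["feature"], dtype=int)
        self.threshold = np.asarray(rules["threshold"], dtype=float)
        self.leaf_label = np.asarray(rules["leaf_label"], dtype=int)

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        out = np.empty(x.shape[0], dtype=int)
        for i, row in enumerate(x):
            node = 0
            while self.left[node] != -1:
                node = self.left[node] if row[self.feature[node]] <= self.threshold[node] else self.right[node]
            out[i] = self.leaf_label[node]
        return out


def _tree_rules(spec: TreeSpec) -> dict:
    t = spec.model.tree_
    classes = np.asarray(spec.model.classes_, dtype=int)
    leaf_label = classes[np.argmax(t.value[:, 0, :], axis=1)]
    return {
        "children_left": t.children_left.tolist(),
        "children_right": t.children_right.tolist(),
        "feature": t.feature.tolist(),
        "threshold": np.round(t.threshold, 12).tolist(),
        "leaf_label": leaf_label.tolist(),
    }


def forest_to_dict(forest: WeightedForest) -> dict:
    """Portable JSON model: per-tree subset, decision rules and weight."""
    return {
        "num_features": forest.num_features,
        "config": {
            "n_trees": forest.config.n_trees,
            "group_size": forest.config.group_size,
            "generations": forest.config.generations,
            "use_weights": forest.config.use_weights,
            "use_evolution": forest.config.use_evolution,
            "seed": forest.config.seed,
        },
        "trees": [
            {
                "feature_subset": t.feature_subset.tolist(),
                "rules": _tree_rules(t) if not isinstance(t.model, _RuleTree) else {
                    "children_left": t.model.left.tolist(),
                    "children_right": t.model.right.tolist(),
                    "feature": t.model.feature.tolist(),
                    "threshold": t.model.threshold.tolist(),
                    "leaf_label": t.model.leaf_label.tolist(),
                },
                "weight": None if forest.weights is None else float(forest.weights[i]),
            }
            for i, t in enumerate(forest.trees)
        ],
    }


def forest_from_dict(payload: dict) -> WeightedForest:
    """Rebuild a weighted forest from :func:`forest_to_dict` output."""
    config = EvolutionConfig(**payload["config"])
    trees = [
        TreeSpec(feature_subset=np.asarray(item["feature_subset"], dtype=int),
                 model=_RuleTree(item["rules"]))
        for item in payload["trees"]
    ]
    weights = None
    if payload["trees"] and payload["trees"][0]["weight"] is not None:
        weights = np.array([item["weight"] for item in payload["trees"]])
    return WeightedForest(trees=trees, weights=weights, config=config,
                          num_features=int(payload["num_features"]))
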