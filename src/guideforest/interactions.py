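"""Random-Intersection-Tree (RIT) mining of feature interactions.

A fitted forest's root-to-leaf decision paths are reduced to feature sets
(order ignored, duplicates collapsed).  RIT looks for feature combinations
that co-occur along those paths more often than independence would predict:
each intersection tree starts from one randomly drawn path set and repeatedly
intersects it with freshly drawn paths down to a fixed depth; the non-empty
survivors are candidate interactions.

For each surviving set the report gives

* observed prevalence  — fraction of paths containing the whole set (RIT);
* expected prevalence  — product of the member features' marginal path
  prevalences (the independence baseline);
* adjusted RIT         — observed minus expected;
* set importance       — observed prevalence times the mean normalized
  importance of the member features;
* samples captured     — leaf-size-weighted fraction of training rows whose
  paths contain the set.

In classification mode paths are stratified by the leaf's predicted class and
RIT runs separately per stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .forest import IRFResult, WeightedRandomForest


class PathExtractionError(ValueError):
    """Forest without retained tree structure."""


@dataclass
class DecisionPathSet:
    """Feature sets of root-to-leaf paths, with leaf sizes and strata."""

    sets: list[frozenset[int]]
    counts: np.ndarray  # training rows reaching each leaf
    strata: np.ndarray  # class/outcome stratum per path (0 in regression)
    tree_ids: np.ndarray
    n_features: int

    def __len__(self) -> int:
        return len(self.sets)

    def select_stratum(self, stratum: int) -> "DecisionPathSet":
        mask = self.strata == stratum
        return DecisionPathSet(
            sets=[s for s, m in zip(self.sets, mask) if m],
            counts=self.counts[mask],
            strata=self.strata[mask],
            tree_ids=self.tree_ids[mask],
            n_features=self.n_features,
        )


def extract_paths(result: IRFResult | WeightedRandomForest) -> DecisionPathSet:
    """One feature set per leaf of every tree in the (final) forest.

    Features repeated along a path collapse to one; empty sets (trees that
    are a single leaf) are dropped.  Leaf counts per tree sum to that tree's
    training-sample count.  In classification mode a path's stratum is its
    leaf's predicted class (probability rounded).
    """
    if isinstance(result, IRFResult):
        forest = result.forest
        classify = result.config.mode == "classification"
    else:
        forest = result
        classify = False
    if not forest.trees_:
        raise PathExtractionError("forest has no retained tree structure")

    sets: list[frozenset[int]] = []
    counts: list[int] = []
    strata: list[int] = []
    tree_ids: list[int] = []
    for t, tree in enumerate(forest.trees_):
        stack = [(0, frozenset())]
        while stack:
            node, feats = stack.pop()
            f = tree.feature[node]
            if f < 0:  # leaf
                if feats:
                    sets.append(feats)
                    counts.append(int(tree.n_node[node]))
                    strata.append(int(round(tree.value[node])) if classify else 0)
                    tree_ids.append(t)
                continue
            feats = feats | {int(f)}
            stack.append((int(tree.left[node]), feats))
            stack.append((int(tree.right[node]), feats))
    return DecisionPathSet(
        sets=sets,
        counts=np.asarray(counts, dtype=np.int64),
        strata=np.asarray(strata, dtype=np.int64),
        tree_ids=np.asarray(tree_ids, dtype=np.int64),
        n_features=forest.n_features_,
    )


def run_rit(
    paths: DecisionPathSet | Sequence[frozenset[int]],
    depth: int = 5,
    n_children: int = 2,
    n_trees: int = 100,
    seed: int = 0,
    weighted: bool = False,
) -> list[frozenset[int]]:
    """Random intersection recursion over decision-path feature sets.

    Each intersection tree starts from the full candidate set (the union of
    all path features) and narrows it: every node draws ``n_children``
    *distinct* path sets and intersects them into its current candidate set,
    then spawns ``n_children`` children that narrow further, down to
    ``depth`` levels.  Paths are drawn uniformly, or proportionally to leaf
    row counts with ``weighted=True``.  Returns the deduplicated non-empty
    depth-level intersections, largest first then lexicographic —
    deterministic under a fixed seed.
    """
    if depth < 1 or n_children < 1:
        raise ValueError("depth and n_children must be >= 1")
    if isinstance(paths, DecisionPathSet):
        sets = paths.sets
        weights = paths.counts.astype(float) if weighted else None
    else:
        sets = list(paths)
        weights = None
    if not sets:
        raise ValueError("no decision paths to intersect")
    probs = None if weights is None else weights / weights.sum()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x817]))
    n_draw = min(n_children, len(sets))

    def narrow(current: frozenset[int]) -> frozenset[int]:
        picks = rng.choice(len(sets), size=n_draw, replace=False, p=probs)
        for i in picks:
            current = current & sets[int(i)]
            if not current:
                break
        return current

    universe = frozenset().union(*sets)
    survivors: set[frozenset[int]] = set()

    def descend(current: frozenset[int], level: int) -> None:
        current = narrow(current)
        if not current:
            return
        if level == depth:
            survivors.add(current)
            return
        for _ in range(n_children):
            descend(current, level + 1)

    for _ in range(n_trees):
        descend(universe, 1)
    return sorted(survivors, key=lambda s: (-len(s), sorted(s)))


def interaction_metrics(
    paths: DecisionPathSet | Sequence[frozenset[int]],
    sets: Iterable[frozenset[int] | Sequence[int]],
    importances: np.ndarray | None = None,
    feature_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Prevalence metrics for candidate interaction sets.

    ``importances`` (final normalized iRF importances) enable the set-
    importance column; without them it is reported as NaN.
    """
    if isinstance(paths, DecisionPathSet):
        path_sets = paths.sets
        counts = paths.counts.astype(float)
        n_features = paths.n_features
    else:
        path_sets = [frozenset(s) for s in paths]
        counts = np.ones(len(path_sets))
        n_features = (max((max(s) for s in path_sets if s), default=-1)) + 1
    n_paths = len(path_sets)
    if n_paths == 0:
        raise ValueError("no decision paths given")

    marginal: dict[int, float] = {}

    def feat_prevalence(f: int) -> float:
        if f not in marginal:
            marginal[f] = sum(1 for s in path_sets if f in s) / n_paths
        return marginal[f]

    total_rows = counts.sum()
    rows = []
    for raw in sets:
        fs = frozenset(int(f) for f in raw)
        for f in fs:
            if f < 0 or f >= max(n_features, 1):
                raise KeyError(f"unknown feature id {f} in interaction set")
        contains = np.fromiter((fs <= s for s in path_sets), dtype=bool, count=n_paths)
        observed = contains.mean()
        expected = float(np.prod([feat_prevalence(f) for f in fs])) if fs else 1.0
        if importances is not None:
            set_imp = observed * float(np.mean([importances[f] for f in fs]))
        else:
            set_imp = float("nan")
        if feature_names is not None:
            label = "+".join(feature_names[f] for f in sorted(fs))
        else:
            label = "+".join(str(f) for f in sorted(fs))
        rows.append(
            {
                "features": label,
                "size": len(fs),
                "observed_prevalence": observed,
                "expected_prevalence": expected,
                "adjusted_rit": observed - expected,
                "set_importance": set_imp,
                "samples_captured": float(counts[contains].sum() / total_rows),
            }
        )
    return pd.DataFrame(rows)


def mine_interactions(
    result: IRFResult,
    depth: int = 5,
    n_children: int = 2,
    n_trees: int = 100,
    seed: int = 0,
    weighted: bool = False,
    min_size: int = 2,
) -> pd.DataFrame:
    """End-to-end mining: extract paths, run RIT per stratum, score survivors."""
    paths = extract_paths(result)
    reports = []
    for stratum in np.unique(paths.strata):
        sub = paths.select_stratum(int(stratum))
        survivors = [
            s
            for s in run_rit(
                sub, depth=depth, n_children=n_children, n_trees=n_trees, seed=seed,
                weighted=weighted,
            )
            if len(s) >= min_size
        ]
        if not survivors:
            continue
        rep = interaction_metrics(
            sub, survivors, importances=result.importances,
            feature_names=result.feature_names,
        )
        rep.insert(0, "stratum", int(stratum))
        reports.append(rep)
    if not reports:
        return pd.DataFrame(
            columns=[
                "stratum", "features", "size", "observed_prevalence",
                "expected_prevalence", "adjusted_rit", "set_importance",
                "samples_captured",
            ]
        )
    return pd.concat(reports, ignore_index=True).sort_values(
        ["stratum", "adjusted_rit"], ascending=[True, False], kind="stable"
    ).reset_index(drop=True)
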