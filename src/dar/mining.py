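"""Candidate rule enumeration, counting, and dynamic-threshold mining.

A candidate rule maps an antecedent itemset of one or two (gene, level)
items to a consequent phenotype class.  For each candidate the miner tallies
(n, n_A, n_B, n_AB), estimates support and confidence, and -- in dynamic
mode -- computes per-rule thresholds from the rule's own marginals
p1 = n_A/n, p2 = n_B/n: the minimum support from the normal bound and the
minimum confidence from the exact null ratio distribution.  A rule is
*meaningful* iff both estimates strictly exceed their thresholds.

No multiple-testing correction is applied; the number of candidates tested
is logged so the user can judge the implied family-wise error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterator, Sequence

import numpy as np

from .core import (
    RuleCounts,
    SupportConfidenceEstimate,
    ThresholdPair,
    back_solve_joint_probability,
    minimum_confidence,
    minimum_support,
    z_quantile,
)
from .discretize import DiscreteDataset

__all__ = ["Item", "Rule", "enumerate_candidates", "count_rule", "mine_rules"]

logger = logging.getLogger(__name__)

_LEVEL_ORDER = (-1, 0, 1)


@dataclass(frozen=True, order=True)
class Item:
    """One antecedent item: a gene at an expression level in {-1, 0, +1}."""

    gene: str
    level: int

    def __post_init__(self) -> None:
        if self.level not in (-1, 0, 1):
            raise ValueError(f"level must be -1, 0 or +1, got {self.level}")

    def __str__(self) -> str:
        prefix = f"{self.level:+d}" if self.level else "0"
        return f"{prefix}:{self.gene}"


@dataclass
class Rule:
    """A mined rule with its tallies, estimates, thresholds and flags."""

    antecedent: tuple[Item, ...]
    consequent: str
    counts: RuleCounts
    estimate: SupportConfidenceEstimate
    thresholds: ThresholdPair | None
    meaningful: bool
    ambiguous: bool = False

    @property
    def support(self) -> float:
        return self.estimate.support

    @property
    def confidence(self) -> float | None:
        return self.estimate.confidence

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(item.gene for item in self.antecedent)

    def antecedent_key(self) -> tuple[Item, ...]:
        return tuple(sorted(self.antecedent))

    def __str__(self) -> str:
        lhs = ",".join(str(i) for i in self.antecedent)
        return f"{lhs} -> {self.consequent}"


def enumerate_candidates(
    dataset: DiscreteDataset,
    classes: Sequence[str] | None = None,
    max_antecedent: int = 1,
    levels: Sequence[int] = (-1, 1),
) -> Iterator[tuple[tuple[Item, ...], str]]:
    """Yield every (antecedent, consequent) candidate in deterministic order.

    ``max_antecedent`` selects the analysis: 1 yields single items, 2 yields
    unordered pairs of items over two distinct genes (the single- and
    double-antecedent analyses are run separately).  Order: gene index, then
    level (-1 < 0 < +1), then class order as given.
    """
    if max_antecedent not in (1, 2):
        raise ValueError("max_antecedent must be 1 or 2")
    if classes is None:
        classes = dataset.groups
    else:
        unknown = set(classes) - set(dataset.groups)
        if unknown:
            raise ValueError(f"classes not observed in the data: {sorted(unknown)}")
    levels = [lv for lv in _LEVEL_ORDER if lv in set(levels)]
    if not levels:
        raise ValueError("levels must be a nonempty subset of {-1, 0, +1}")
    genes = dataset.gene_ids
    if max_antecedent == 1:
        for g in genes:
            for lv in levels:
                for cls in classes:
                    yield (Item(g, lv),), cls
    else:
        for ga, gb in combinations(genes, 2):
            for lva in levels:
                for lvb in levels:
                    for cls in classes:
                        yield (Item(ga, lva), Item(gb, lvb)), cls


def count_rule(
    dataset: DiscreteDataset, antecedent: Sequence[Item], consequent: str
) -> RuleCounts:
    """Tally (n, n_A, n_B, n_AB) for one rule over the dataset's samples."""
    labels = dataset.labels
    for item in antecedent:
        if item.gene not in labels.index:
            raise KeyError(f"unknown gene {item.gene!r}")
    if consequent not in set(dataset.groups):
        raise KeyError(f"unknown class {consequent!r}")
    match = np.ones(labels.shape[1], dtype=bool)
    for item in antecedent:
        match &= labels.loc[item.gene].to_numpy() == item.level
    in_class = (dataset.group_of == consequent).to_numpy()
    return RuleCounts(
        n=labels.shape[1],
        n_A=int(match.sum()),
        n_B=int(in_class.sum()),
        n_AB=int((match & in_class).sum()),
    )


class _ThresholdCache:
    """Per-rule dynamic thresholds depend only on (n_A, n_B) at fixed n, alpha."""

    def __init__(self, n: int, alpha: float, convention: str):
        self.n = n
        self.alpha = alpha
        self.convention = convention
        self.z = z_quantile(alpha)
        self._cache: dict[tuple[int, int], ThresholdPair] = {}

    def get(self, n_A: int, n_B: int) -> ThresholdPair:
        key = (n_A, n_B)
        pair = self._cache.get(key)
        if pair is None:
            p1 = n_A / self.n
            p2 = n_B / self.n
            pair = ThresholdPair(
                s_min=minimum_support(p1, p2, self.n, self.alpha),
                c_min=minimum_confidence(
                    self.n, p1, p2, self.alpha, convention=self.convention
                ),
                alpha=self.alpha,
                z_alpha=self.z,
            )
            self._cache[key] = pair
        return pair


def mine_rules(
    dataset: DiscreteDataset,
    alpha: float = 0.05,
    max_antecedent: int = 1,
    levels: Sequence[int] = (-1, 1),
    mode: str = "dynamic",
    s: float | None = None,
    c: float | None = None,
    classes: Sequence[str] | None = None,
    convention: str = "exact",
    prune_backsolve: bool = False,
) -> list[Rule]:
    """Mine all candidate rules and flag the meaningful ones.

    ``mode="dynamic"`` compares each rule's support and confidence (strictly)
    with its own thresholds; ``mode="fixed"`` compares with the user-supplied
    ``s`` and ``c`` instead.  Candidates whose antecedent matches no sample
    are dropped (their confidence is undefined).

    ``prune_backsolve`` (fixed mode only) skips, before counting the joint
    tally, consequents with p2 < p*/p1 where p* back-solves the minimum-
    support equation at the support floor ``s``: under near-independence such
    rules reach support s with probability below alpha.  A heuristic
    speed-up that leaves the mined set unchanged on null-like data.
    """
    if len(dataset.groups) < 2:
        raise ValueError("mining needs at least 2 classes")
    if mode not in ("dynamic", "fixed"):
        raise ValueError("mode must be 'dynamic' or 'fixed'")
    if mode == "fixed" and (s is None or c is None):
        raise ValueError("fixed mode needs both s and c")
    if prune_backsolve and mode != "fixed":
        raise ValueError("back-solve pruning needs a pre-specified support "
                         "floor: use mode='fixed'")

    labels = dataset.labels.to_numpy()
    gene_index = {g: i for i, g in enumerate(dataset.gene_ids)}
    n = labels.shape[1]
    group_arr = dataset.group_of.to_numpy()
    class_masks = {cls: group_arr == cls for cls in dataset.groups}
    cache = _ThresholdCache(n, alpha, convention) if mode == "dynamic" else None
    p_star = (
        back_solve_joint_probability(n, s, alpha) if prune_backsolve else None
    )

    rules: list[Rule] = []
    n_candidates = 0
    for antecedent, consequent in enumerate_candidates(
        dataset, classes=classes, max_antecedent=max_antecedent, levels=levels
    ):
        n_candidates += 1
        match = labels[gene_index[antecedent[0].gene]] == antecedent[0].level
        for item in antecedent[1:]:
            match = match & (labels[gene_index[item.gene]] == item.level)
        n_A = int(match.sum())
        if n_A == 0:
            continue
        in_class = class_masks[consequent]
        n_B = int(in_class.sum())
        if p_star is not None and n_B / n < p_star / (n_A / n):
            continue
        counts = RuleCounts(n=n, n_A=n_A, n_B=n_B, n_AB=int((match & in_class).sum()))
        est = SupportConfidenceEstimate.from_counts(counts)
        if mode == "dynamic":
            thr = cache.get(n_A, n_B)
            meaningful = est.support > thr.s_min and est.confidence > thr.c_min
        else:
            thr = None
            meaningful = est.support > s and est.confidence > c
        rules.append(
            Rule(
                antecedent=tuple(antecedent),
                consequent=consequent,
                counts=counts,
                estimate=est,
                thresholds=thr,
                meaningful=meaningful,
            )
        )
    logger.warning(
        "tested %d candidate rules at alpha=%.3g with no multiple-testing "
        "correction", n_candidates, alpha,
    )
    return rules
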