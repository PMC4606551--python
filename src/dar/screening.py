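"""Removal of ambiguous (mutually conflicting) meaningful rules.

Two kinds of conflict make meaningful rules uninterpretable:

* consequent conflict: the identical antecedent itemset implies two
  different classes, both significantly;
* level conflict (single-antecedent rules only): the same gene implies the
  same class significantly at both the +1 and the -1 level.

All members of a conflicting group are removed -- no ranking or tie-break
keeps one of them.  Double-antecedent rules are exempt from level conflicts:
a gene genuinely both up- and down-regulated toward a class can still be
captured through interaction rules.  Level-0 items conflict with neither
+1 nor -1.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .mining import Item, Rule

__all__ = ["AmbiguityReport", "find_ambiguous", "screen_rules", "final_gene_set"]


@dataclass
class AmbiguityReport:
    """Indices of conflicting rule groups, and the removed/retained split."""

    consequent_conflicts: list[tuple[int, ...]] = field(default_factory=list)
    level_conflicts: list[tuple[int, ...]] = field(default_factory=list)
    removed: set[int] = field(default_factory=set)
    retained: set[int] = field(default_factory=set)


def find_ambiguous(rules: list[Rule]) -> AmbiguityReport:
    """Locate conflicting groups among meaningful rules.

    All input rules must be flagged meaningful; every member of a conflict
    is marked removed.
    """
    if not all(r.meaningful for r in rules):
        raise ValueError("screening expects meaningful rules only")
    report = AmbiguityReport()

    by_antecedent: dict[tuple[Item, ...], list[int]] = defaultdict(list)
    for i, r in enumerate(rules):
        by_antecedent[r.antecedent_key()].append(i)
    for idxs in by_antecedent.values():
        if len({rules[i].consequent for i in idxs}) > 1:
            report.consequent_conflicts.append(tuple(idxs))
            report.removed.update(idxs)

    # level conflict: single-antecedent, same gene at +1 and -1, same class
    singles: dict[tuple[str, str], dict[int, int]] = defaultdict(dict)
    for i, r in enumerate(rules):
        if len(r.antecedent) == 1 and r.antecedent[0].level != 0:
            item = r.antecedent[0]
            singles[(item.gene, r.consequent)][item.level] = i
    for levels in singles.values():
        if 1 in levels and -1 in levels:
            pair = (levels[-1], levels[1])
            report.level_conflicts.append(pair)
            report.removed.update(pair)

    report.retained = set(range(len(rules))) - report.removed
    return report


def screen_rules(rules: list[Rule]) -> list[Rule]:
    """Return the meaningful rules that survive ambiguity screening.

    Idempotent; rules are returned unchanged apart from the ``ambiguous``
    flag set on removed ones.
    """
    meaningful = [r for r in rules if r.meaningful]
    report = find_ambiguous(meaningful)
    for i in report.removed:
        meaningful[i].ambiguous = True
    return [r for i, r in enumerate(meaningful) if i in report.retained]


def final_gene_set(rules: list[Rule]) -> list[str]:
    """Sorted union of gene ids in the antecedents of surviving rules."""
    genes: set[str] = set()
    for r in rules:
        genes.update(r.genes)
    return sorted(genes)
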