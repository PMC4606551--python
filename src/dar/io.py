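"""Tab-delimited input/output: expression matrices, group maps, rule tables.

Formats (all plain text, no binary):

* expression matrix: TSV, first column gene id, header row of sample ids;
* group file: two columns, ``sample_id<TAB>group``, no header;
* rule table: TSV with a fixed column contract (below), optionally preceded
  by ``#``-prefixed configuration echo lines;
* gene list: one id per line.

Rule-table columns: antecedent, consequent, n, n_A, n_B, n_AB, support,
confidence, s_min, c_min, meaningful, ambiguous, final.  Floats are written
at 6 decimals; the antecedent is serialised as ``+1:geneA,-1:geneB`` with
items sorted by gene id.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .core import RuleCounts, SupportConfidenceEstimate, ThresholdPair
from .discretize import DiscreteDataset, ExpressionMatrix
from .mining import Item, Rule

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_groups",
    "write_groups",
    "write_rule_table",
    "read_rule_table",
    "write_gene_list",
]

RULE_COLUMNS = [
    "antecedent", "consequent", "n", "n_A", "n_B", "n_AB",
    "support", "confidence", "s_min", "c_min",
    "meaningful", "ambiguous", "final",
]

_ITEM_RE = re.compile(r"^([+-]1|0):(.+)$")


def read_expression_matrix(path, groups_path=None) -> ExpressionMatrix | pd.DataFrame:
    """Read a TSV expression matrix; with ``groups_path``, attach groups.

    Returns an ExpressionMatrix when a group file is given, otherwise the
    bare values DataFrame.  Non-numeric cells are reported with the gene and
    sample they occur in; duplicate gene ids are an error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    df.index = df.index.astype(str)
    values = df.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & df.notna()
    if bad.to_numpy().any():
        gi, si = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric value {df.iat[gi, si]!r} for gene "
            f"{df.index[gi]!r}, sample {df.columns[si]!r} in {path}"
        )
    if values.index.has_duplicates:
        dups = values.index[values.index.duplicated()].unique()
        raise ValueError(f"duplicate gene ids in {path}: {list(dups)}")
    if groups_path is None:
        return values
    return ExpressionMatrix(values=values, group_of=read_groups(groups_path))


def write_expression_matrix(matrix: ExpressionMatrix | pd.DataFrame, path) -> None:
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    values.to_csv(path, sep="\t", index_label="gene_id")


def read_groups(path) -> pd.Series:
    """Read a two-column sample_id<TAB>group file into a Series."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "group"],
                     dtype=str, comment="#")
    if df["sample_id"].duplicated().any():
        dups = df["sample_id"][df["sample_id"].duplicated()].tolist()
        raise ValueError(f"duplicate sample ids in {path}: {dups}")
    return pd.Series(df["group"].to_numpy(), index=df["sample_id"].to_numpy())


def write_groups(group_of: pd.Series, path) -> None:
    pd.DataFrame({"sample_id": group_of.index, "group": group_of.to_numpy()}).to_csv(
        path, sep="\t", header=False, index=False
    )


def _serialise_antecedent(rule: Rule) -> str:
    return ",".join(str(item) for item in sorted(rule.antecedent))


def _parse_antecedent(text: str) -> tuple[Item, ...]:
    items = []
    for part in text.split(","):
        m = _ITEM_RE.match(part.strip())
        if not m:
            raise ValueError(f"malformed antecedent item {part!r}")
        items.append(Item(gene=m.group(2), level=int(m.group(1))))
    return tuple(items)


def _fmt(x: float | None) -> str:
    return "NA" if x is None else f"{x:.6f}"


def write_rule_table(rules: list[Rule], path, config: dict | None = None) -> None:
    """Write rules as TSV; ``config`` is echoed as ``# key: value`` lines."""
    path = Path(path)
    with path.open("w") as fh:
        for key, value in (config or {}).items():
            fh.write(f"# {key}: {value}\n")
        fh.write("\t".join(RULE_COLUMNS) + "\n")
        for r in rules:
            thr = r.thresholds
            row = [
                _serialise_antecedent(r),
                r.consequent,
                str(r.counts.n), str(r.counts.n_A),
                str(r.counts.n_B), str(r.counts.n_AB),
                _fmt(r.support), _fmt(r.confidence),
                _fmt(thr.s_min if thr else None),
                _fmt(thr.c_min if thr else None),
                str(int(r.meaningful)), str(int(r.ambiguous)),
                str(int(r.meaningful and not r.ambiguous)),
            ]
            fh.write("\t".join(row) + "\n")


def read_rule_table(path) -> list[Rule]:
    """Read a rule table written by ``write_rule_table``."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in RULE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"rule table {path} lacks columns: {missing}")
    rules = []
    for _, row in df.iterrows():
        counts = RuleCounts(
            n=int(row["n"]), n_A=int(row["n_A"]),
            n_B=int(row["n_B"]), n_AB=int(row["n_AB"]),
        )
        est = SupportConfidenceEstimate(
            support=float(row["support"]),
            confidence=None if row["confidence"] == "NA" else float(row["confidence"]),
        )
        if row["s_min"] == "NA":
            thr = None
        else:
            thr = ThresholdPair(
                s_min=float(row["s_min"]), c_min=float(row["c_min"]),
                alpha=float("nan"), z_alpha=float("nan"),
            )
        rules.append(
            Rule(
                antecedent=_parse_antecedent(row["antecedent"]),
                consequent=str(row["consequent"]),
                counts=counts,
                estimate=est,
                thresholds=thr,
                meaningful=bool(int(row["meaningful"])),
                ambiguous=bool(int(row["ambiguous"])),
            )
        )
    return rules


def write_gene_list(genes: list[str], path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def write_critical_value_table(table: pd.DataFrame, path) -> None:
    """Write a critical-value table (p2 block, level row, p1 columns) as TSV."""
    out = table.copy()
    out.insert(0, "level", [f"{int(round(lv * 100))}%" for _, lv in out.index])
    out.insert(0, "p2", [p2 for p2, _ in out.index])
    out.to_csv(path, sep="\t", index=False, float_format="%.4f")
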