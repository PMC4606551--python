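"""Synthetic fixtures: two-group expression matrices and independent baskets.

The generators stand in for case-study expression datasets so that every
pipeline stage is testable offline.  A single numpy ``default_rng`` PCG64
generator drives all draws; identical seeds give bitwise-identical output.

``simulate_two_group_matrix`` emulates a log-scale expression matrix with
two balanced groups: null genes are Normal(0, noise_sd) everywhere, while
planted genes are shifted by ``+/- effect * noise_sd`` in the case group,
so ``effect`` is the group-mean separation in noise-standard-deviation
units.  Gene ids encode the ground truth (``up_0001``, ``down_0002``,
``null_0003``).

``simulate_independent_baskets`` draws the antecedent and class indicators
as independent Bernoulli(p1) and Bernoulli(p2) -- the null model under
which the dynamic thresholds are derived -- and is the Monte-Carlo oracle
for the exact confidence distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .discretize import DiscreteDataset, ExpressionMatrix

__all__ = ["SimulationSpec", "simulate_two_group_matrix", "simulate_independent_baskets"]

GENERATOR = "numpy.random.default_rng (PCG64)"


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of a planted-signal two-group expression simulation."""

    n_genes: int = 100
    n_per_group: int = 8
    n_planted_up: int = 5
    n_planted_down: int = 5
    effect: float = 4.0
    noise_sd: float = 1.0
    seed: int = 0
    scale: str = "log"  # "log": additive shifts; "linear": 2**values * 100

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_per_group < 1:
            raise ValueError("n_genes and n_per_group must be >= 1")
        if self.n_planted_up < 0 or self.n_planted_down < 0:
            raise ValueError("planted counts must be >= 0")
        if self.n_planted_up + self.n_planted_down > self.n_genes:
            raise ValueError("cannot plant more genes than n_genes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.scale not in ("log", "linear"):
            raise ValueError("scale must be 'log' or 'linear'")


def simulate_two_group_matrix(spec: SimulationSpec) -> ExpressionMatrix:
    """Draw a genes x samples matrix with planted up/down genes in the cases."""
    rng = np.random.default_rng(spec.seed)
    n_up, n_down = spec.n_planted_up, spec.n_planted_down
    n_samples = 2 * spec.n_per_group
    values = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n_samples))
    case = np.s_[spec.n_per_group:]
    shift = spec.effect * spec.noise_sd
    values[:n_up, case] += shift
    values[n_up:n_up + n_down, case] -= shift
    width = len(str(spec.n_genes))
    gene_ids = (
        [f"up_{i + 1:0{width}d}" for i in range(n_up)]
        + [f"down_{i + 1:0{width}d}" for i in range(n_down)]
        + [f"null_{i + 1:0{width}d}" for i in range(spec.n_genes - n_up - n_down)]
    )
    sample_ids = [f"control_{i + 1}" for i in range(spec.n_per_group)] + [
        f"case_{i + 1}" for i in range(spec.n_per_group)
    ]
    if spec.scale == "linear":
        values = 100.0 * np.exp2(values)
    groups = pd.Series(
        ["control"] * spec.n_per_group + ["case"] * spec.n_per_group,
        index=sample_ids,
    )
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        group_of=groups,
    )


def simulate_independent_baskets(
    n: int, p1: float, p2: float, seed: int = 0
) -> DiscreteDataset:
    """Draw n baskets with one antecedent item and one binary class.

    The item is present (label +1) with probability p1, independently of the
    class (``"B"`` with probability p2, else ``"notB"``).
    """
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise ValueError("p1 and p2 must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    has_item = rng.random(n) < p1
    in_class = rng.random(n) < p2
    sample_ids = [f"b{i + 1}" for i in range(n)]
    labels = pd.DataFrame(
        has_item.astype(np.int8)[None, :], index=["item"], columns=sample_ids
    )
    groups = pd.Series(np.where(in_class, "B", "notB"), index=sample_ids)
    return DiscreteDataset(labels=labels, group_of=groups)
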