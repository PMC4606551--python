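"""Normalisation and discretisation of expression matrices to {-1, 0, +1}.

Each case study normalises once and labels once:

================  =============================  =================================
preset            normalisation                  labelling
================  =============================  =================================
``threshold``     MA-plot lowess (two-colour)    value >= +1 -> +1, <= -1 -> -1
``fold2``         none                           ratio to baseline mean > 2 / < 0.5
``fold1.5``       none                           ratio > 1.5 / < 2/3
``maqc-log``      none (values are log ratios)   log difference > +1 / < -1
``tsd``           per-sample median/IQR          per-gene z-score, >= +1 / <= -1
================  =============================  =================================

Boundary conventions follow each scheme's own definition: the threshold and
TSD (Transitional State Discrimination) schemes use inclusive cutoffs, the
fold-change schemes strict ones.  Missing values always label 0 (treated as
not differentially expressed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

__all__ = [
    "ExpressionMatrix",
    "DiscreteDataset",
    "normalize_ma_lowess",
    "normalize_median_iqr",
    "label_by_threshold",
    "label_by_fold_change",
    "label_by_tsd",
    "discretize",
    "PRESETS",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of expression values plus sample group labels.

    ``values``: DataFrame indexed by gene id with sample-id columns.
    ``group_of``: Series mapping sample id -> class label.
    """

    values: pd.DataFrame
    group_of: pd.Series

    def __post_init__(self) -> None:
        self.group_of = self.group_of.astype(str)
        missing = [s for s in self.values.columns if s not in self.group_of.index]
        if missing:
            raise ValueError(f"samples missing from the group map: {missing}")
        extra = [s for s in self.group_of.index if s not in self.values.columns]
        if extra:
            warnings.warn(
                f"group map lists samples absent from the matrix "
                f"(ignored): {extra}",
                stacklevel=3,
            )
            self.group_of = self.group_of.loc[list(self.values.columns)]
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dups)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def groups(self) -> list[str]:
        return sorted(self.group_of.unique())


@dataclass
class DiscreteDataset:
    """Per-gene, per-sample labels in {-1, 0, +1} plus sample group labels."""

    labels: pd.DataFrame
    group_of: pd.Series

    def __post_init__(self) -> None:
        bad = ~self.labels.isin((-1, 0, 1)).to_numpy()
        if bad.any():
            raise ValueError("labels must lie in {-1, 0, +1}")
        self.labels = self.labels.astype(np.int8)
        self.group_of = self.group_of.astype(str).loc[list(self.labels.columns)]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.labels.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.columns)

    @property
    def groups(self) -> list[str]:
        return sorted(self.group_of.unique())


def normalize_ma_lowess(M, A, span: float = 2.0 / 3.0) -> np.ndarray:
    """Two-colour MA-plot normalisation: M -> M - lowess trend of M on A.

    ``M`` are per-spot log2(R/G) ratios and ``A`` per-spot average log
    intensities log2 sqrt(R*G); the locally weighted regression trend c(A)
    absorbs intensity-dependent dye bias.
    """
    M = np.asarray(M, dtype=float)
    A = np.asarray(A, dtype=float)
    if M.shape != A.shape or M.ndim != 1:
        raise ValueError("M and A must be equal-length 1-d arrays")
    if M.size < 10:
        raise ValueError("need at least 10 spots to fit a lowess trend")
    if not (0.0 < span <= 1.0):
        raise ValueError("span must lie in (0, 1]")
    trend = _sm_lowess(M, A, frac=span, return_sorted=False)
    return M - trend


def normalize_median_iqr(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Per-sample scale normalisation: (x - median) / (Q3 - Q1) per column."""
    vals = matrix.values
    med = vals.median(axis=0)
    q3 = vals.quantile(0.75, axis=0)
    q1 = vals.quantile(0.25, axis=0)
    iqr = q3 - q1
    zero = iqr[iqr == 0]
    if len(zero):
        raise ValueError(
            f"zero interquartile range in sample(s): {list(zero.index)}"
        )
    out = (vals - med) / iqr
    return ExpressionMatrix(values=out, group_of=matrix.group_of.copy())


def _labels_from(values: pd.DataFrame, up_mask, down_mask) -> pd.DataFrame:
    lab = np.zeros(values.shape, dtype=np.int8)
    lab[np.asarray(up_mask)] = 1
    lab[np.asarray(down_mask)] = -1
    return pd.DataFrame(lab, index=values.index, columns=values.columns)


def label_by_threshold(
    matrix: ExpressionMatrix, up: float = 1.0, down: float = -1.0
) -> DiscreteDataset:
    """Label normalised values: >= up -> +1, <= down -> -1, else 0.

    Boundaries are inclusive.  NaNs label 0.
    """
    if not up > down:
        raise ValueError("up must exceed down")
    v = matrix.values
    return DiscreteDataset(
        labels=_labels_from(v, v >= up, v <= down),
        group_of=matrix.group_of,
    )


def label_by_fold_change(
    matrix: ExpressionMatrix,
    baseline_group: str,
    up: float = 2.0,
    down: float = 0.5,
    scale: str = "linear",
    on_zero_baseline: str = "error",
) -> DiscreteDataset:
    """Label by fold change against the per-gene mean of a baseline group.

    On the ``linear`` scale a value whose ratio to the baseline mean is
    strictly above ``up`` labels +1 and strictly below ``down`` labels -1.
    On the ``log2`` scale the value minus the baseline mean is compared with
    the same strict cutoffs (``up``/``down`` are then log2 differences, e.g.
    +1/-1 for a two-fold rule on log data).

    ``on_zero_baseline``: ``"error"`` raises when a gene's linear baseline
    mean is 0; ``"skip"`` labels that gene 0 everywhere, with a warning.
    """
    if scale not in ("linear", "log2"):
        raise ValueError("scale must be 'linear' or 'log2'")
    if not up > down or (scale == "linear" and down <= 0):
        raise ValueError("need up > down (> 0 on the linear scale)")
    groups = matrix.group_of
    base_samples = groups.index[groups == str(baseline_group)]
    if len(base_samples) == 0:
        raise ValueError(f"baseline group {baseline_group!r} has no samples")
    baseline = matrix.values[list(base_samples)].mean(axis=1)
    v = matrix.values
    if scale == "log2":
        diff = v.sub(baseline, axis=0)
        return DiscreteDataset(
            labels=_labels_from(v, diff > up, diff < down),
            group_of=matrix.group_of,
        )
    zero = baseline[baseline == 0]
    if len(zero):
        if on_zero_baseline == "error":
            raise ValueError(
                f"zero baseline mean for gene(s): {list(zero.index)[:10]}"
            )
        warnings.warn(
            f"{len(zero)} gene(s) with zero baseline mean labelled 0",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = v.div(baseline, axis=0)
    ratio.loc[zero.index] = 1.0  # neutral: labels 0
    return DiscreteDataset(
        labels=_labels_from(v, ratio > up, ratio < down),
        group_of=matrix.group_of,
    )


def label_by_tsd(matrix: ExpressionMatrix, ddof: int = 1) -> DiscreteDataset:
    """Transitional State Discrimination: per-gene z-scores cut at +/-1.

    Each gene row is centred by its mean and scaled by its standard
    deviation (sample sd, ``ddof=1``, by default); z >= 1 labels +1 and
    z <= -1 labels -1, boundaries inclusive.  Constant rows label 0.
    """
    v = matrix.values
    mu = v.mean(axis=1)
    sd = v.std(axis=1, ddof=ddof)
    safe = sd.replace(0.0, np.nan)
    z = v.sub(mu, axis=0).div(safe, axis=0)
    return DiscreteDataset(
        labels=_labels_from(v, z >= 1.0, z <= -1.0),
        group_of=matrix.group_of,
    )


#: preset name -> callable(ExpressionMatrix, **kwargs) -> DiscreteDataset
PRESETS = {
    "threshold": lambda m, **kw: label_by_threshold(m, **kw),
    "fold2": lambda m, *, baseline_group, **kw: label_by_fold_change(
        m, baseline_group, up=kw.pop("up", 2.0), down=kw.pop("down", 0.5),
        scale="linear", **kw
    ),
    "fold1.5": lambda m, *, baseline_group, **kw: label_by_fold_change(
        m, baseline_group, up=kw.pop("up", 1.5), down=kw.pop("down", 2.0 / 3.0),
        scale="linear", **kw
    ),
    "maqc-log": lambda m, *, baseline_group, **kw: label_by_fold_change(
        m, baseline_group, up=kw.pop("up", 1.0), down=kw.pop("down", -1.0),
        scale="log2", **kw
    ),
    "tsd": lambda m, **kw: label_by_tsd(normalize_median_iqr(m), **kw),
}


def discretize(matrix: ExpressionMatrix, preset: str, **kwargs) -> DiscreteDataset:
    """Apply one of the named normalise-and-label presets."""
    try:
        fn = PRESETS[preset]
    except KeyError:
        raise ValueError(
            f"unknown preset {preset!r}; choose from {sorted(PRESETS)}"
        ) from None
    return fn(matrix, **kwargs)
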