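"""Metabolite statistics: median normalization, log10, Pareto scaling, volcano.

The processing chain is exactly sample-median normalization, then log10
transform, then per-metabolite Pareto scaling (mean-center, divide by
the square root of the standard deviation — intermediate between unit
variance and no scaling).  Median "centering" is implemented as
division by each sample's median intensity, the row-normalization
convention of metabolomics portals; subtraction before a log transform
could produce non-positive values and break the chain.

Selection is volcano-style: a metabolite is significant when its
equal-variance two-sample t-test on the scaled values gives p below the
cutoff AND its raw-intensity group fold change clears the fold cutoff
(default 2, i.e. ratio >= 2 or <= 1/2) — both criteria are required.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .io import MetaboliteMatrix

logger = logging.getLogger("ucptx")


@dataclass
class ScaledMatrix:
    """Samples x metabolites values after the three-step chain.

    Retains the raw intensities (for volcano fold changes), the group
    labels, and each metabolite's pre-scaling mean and sd.
    """

    values: pd.DataFrame
    raw: pd.DataFrame
    groups: pd.Series
    pre_mean: pd.Series
    pre_sd: pd.Series


def median_normalize(m: MetaboliteMatrix) -> MetaboliteMatrix:
    """Divide each sample row by its median intensity (row median becomes 1)."""
    medians = m.intensities.median(axis=1)
    if (medians == 0).any():
        raise ValueError("sample with zero median intensity")
    return MetaboliteMatrix(
        intensities=m.intensities.div(medians, axis=0), groups=m.groups.copy()
    )


def log10_transform(values: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log10; non-positive entries are an error naming the cell."""
    bad = values <= 0
    if bad.to_numpy().any():
        stacked = bad.stack()
        sample, metab = stacked.index[stacked.to_numpy()][0]
        raise ValueError(f"non-positive intensity at sample {sample!r}, metabolite {metab!r}")
    return np.log10(values)


def pareto_scale(values: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Per-metabolite: subtract the mean, divide by sqrt(sample sd).

    Returns ``(scaled, pre_mean, pre_sd)``.  A zero-variance metabolite
    is set to all zeros with a warning.  After scaling each column has
    mean 0 and variance equal to its pre-scaling sd.
    """
    if len(values) < 2:
        raise ValueError("Pareto scaling needs >= 2 samples")
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    centered = values.sub(mean, axis=1)
    # a constant column can carry sd ~ 1e-16 from rounding; treat as zero
    zero = sd <= 100 * np.finfo(float).eps * np.maximum(1.0, mean.abs())
    sd = sd.where(~zero, 0.0)
    if zero.any():
        logger.warning("%d constant metabolite column(s) set to zero", int(zero.sum()))
    scale = np.sqrt(sd.where(~zero, 1.0))
    scaled = centered.div(scale, axis=1)
    scaled.loc[:, zero] = 0.0
    return scaled, mean, sd


def scale_chain(m: MetaboliteMatrix) -> ScaledMatrix:
    """Apply the full chain: median normalize -> log10 -> Pareto scale."""
    normalized = median_normalize(m)
    logged = log10_transform(normalized.intensities)
    scaled, mean, sd = pareto_scale(logged)
    return ScaledMatrix(
        values=scaled,
        raw=m.intensities.copy(),
        groups=m.groups.copy(),
        pre_mean=mean,
        pre_sd=sd,
    )


def volcano_select(
    scaled: ScaledMatrix,
    p_cutoff: float = 0.05,
    fc_cutoff: float = 2.0,
    group_a: str = "OE",
    group_b: str = "WT",
) -> pd.DataFrame:
    """Volcano table: per-metabolite t-test p and raw fold change, with selection.

    The p-value is an unpaired, equal-variance, two-sided t-test on the
    scaled values; the fold change is the ratio of raw-intensity group
    means (``group_a`` over ``group_b``).  ``selected`` requires
    ``p < p_cutoff`` and ``max(fc, 1/fc) >= fc_cutoff``.
    """
    a_idx = scaled.groups[scaled.groups == group_a].index
    b_idx = scaled.groups[scaled.groups == group_b].index
    if len(a_idx) < 2 or len(b_idx) < 2:
        raise ValueError("each group needs >= 2 samples")
    a = scaled.values.loc[a_idx]
    b = scaled.values.loc[b_idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=True)
    p = pd.Series(p, index=scaled.values.columns).fillna(1.0)
    fc = scaled.raw.loc[a_idx].mean(axis=0) / scaled.raw.loc[b_idx].mean(axis=0)
    result = pd.DataFrame(
        {
            "fold_change": fc,
            "log2_fc": np.log2(fc),
            "p": p,
            "selected": (p < p_cutoff) & (np.maximum(fc, 1.0 / fc) >= fc_cutoff),
        }
    )
    result.index.name = "metabolite"
    return result.sort_values("p")


class MetaboliteScaler(TransformerMixin, BaseEstimator):
    """Median -> log10 -> Pareto chain as a transformer.

    ``fit`` learns the per-metabolite means and sds of the training
    matrix after median normalization and log10; ``transform`` applies
    the chain with those parameters (new samples are row-normalized by
    their own median, as in the portal convention).
    """

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        medians = X.median(axis=1)
        logged = log10_transform(X.div(medians, axis=0))
        _, self.mean_, self.sd_ = pareto_scale(logged)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)
        logged = log10_transform(X.div(X.median(axis=1), axis=0))
        zero = self.sd_ == 0
        scale = np.sqrt(self.sd_.where(~zero, 1.0))
        out = logged.sub(self.mean_, axis=1).div(scale, axis=1)
        out.loc[:, zero] = 0.0
        return out


class VolcanoSelector(BaseEstimator):
    """Volcano selection as a fit-style estimator over a MetaboliteMatrix.

    Attributes after ``fit``: ``scaled_`` (:class:`ScaledMatrix`),
    ``results_`` (volcano table), ``selected_`` (metabolite list).
    """

    def __init__(self, p_cutoff: float = 0.05, fc_cutoff: float = 2.0,
                 group_a: str = "OE", group_b: str = "WT"):
        self.p_cutoff = p_cutoff
        self.fc_cutoff = fc_cutoff
        self.group_a = group_a
        self.group_b = group_b

    def fit(self, X: MetaboliteMatrix, y=None):
        self.scaled_ = scale_chain(X)
        self.results_ = volcano_select(
            self.scaled_,
            p_cutoff=self.p_cutoff,
            fc_cutoff=self.fc_cutoff,
            group_a=self.group_a,
            group_b=self.group_b,
        )
        self.selected_ = list(self.results_.index[self.results_["selected"]])
        return self
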