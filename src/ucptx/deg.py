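"""RPKM expression, quantile normalization and replicate-free DEG calling.

The differential test is Kal's proportion Z-test: for a gene with ``x1``
reads out of ``N1`` in one library and ``x2`` of ``N2`` in the other,
the pooled two-proportion statistic

    Z = (p1 - p2) / sqrt(p0 (1 - p0) (1/N1 + 1/N2)),
    p1 = x1/N1, p2 = x2/N2, p0 = (x1 + x2)/(N1 + N2)

is referred to the standard normal.  The test runs on raw count
proportions — the statistic is only defined on proportions — while the
reported fold changes come from quantile-normalized RPKM on the log2
scale, matching the workflow of treating normalization and testing as
separate concerns.  A gene is called differentially expressed when it
clears both a fold-change cutoff (default 2-fold, boundary inclusive)
and a raw p-value cutoff (default 0.001; no multiplicity adjustment at
this stage).  With two overexpressor lines, only genes called in the
same direction in both comparisons enter the common DEG sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .io import CountTable


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


def rpkm(count, length, library_total):
    """Reads per kilobase of transcript per million mapped reads.

    ``count / ((length/1000) * (library_total/1e6))``, vectorized.
    """
    count = np.asarray(count, dtype=float)
    length = np.asarray(length, dtype=float)
    library_total = np.asarray(library_total, dtype=float)
    if (length <= 0).any() if length.ndim else length <= 0:
        raise ValueError("gene length must be positive")
    if (library_total <= 0).any() if library_total.ndim else library_total <= 0:
        raise ValueError("library total must be positive")
    if (count < 0).any() if count.ndim else count < 0:
        raise ValueError("count must be non-negative")
    return count / ((length / 1e3) * (library_total / 1e6))


def rpkm_table(table: CountTable) -> pd.DataFrame:
    """Elementwise RPKM for a whole count table (genes x samples)."""
    values = rpkm(
        table.counts.to_numpy(),
        table.lengths.to_numpy()[:, None],
        table.library_totals.to_numpy()[None, :],
    )
    return pd.DataFrame(values, index=table.counts.index, columns=table.counts.columns)


def quantile_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Force all sample columns onto the mean empirical distribution.

    Each column's sorted values are replaced by the across-sample mean of
    sorted values; within-column ranks are preserved and ties receive the
    mean of their rank positions (linear interpolation at half-ranks).
    """
    if table.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    sorted_vals = np.sort(table.to_numpy(), axis=0)
    mean_sorted = sorted_vals.mean(axis=1)
    n = len(table)
    out = {}
    for col in table.columns:
        ranks = table[col].rank(method="average").to_numpy()
        out[col] = np.interp(ranks, np.arange(1, n + 1), mean_sorted)
    return pd.DataFrame(out, index=table.index)


def kal_z_test(x1, n1, x2, n2):
    """Pooled two-proportion Z-test for a gene's read fraction in two libraries.

    Returns ``(Z, p)`` with a two-sided standard-normal p-value.  Accepts
    scalars or aligned arrays.  Genes with ``x1 == x2 == 0`` have an
    undefined statistic: scalars raise, arrays return NaN so the caller
    can filter.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if (n1 <= 0).any() if n1.ndim else n1 <= 0:
        raise ValueError("library sizes must be positive")
    if (n2 <= 0).any() if n2.ndim else n2 <= 0:
        raise ValueError("library sizes must be positive")
    scalar = x1.ndim == 0 and x2.ndim == 0
    if scalar and x1 + x2 == 0:
        raise ValueError("Z undefined for x1 == x2 == 0; filter or pseudo-count")
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = x1 / n1
        p2 = x2 / n2
        p0 = (x1 + x2) / (n1 + n2)
        se = np.sqrt(p0 * (1.0 - p0) * (1.0 / n1 + 1.0 / n2))
        z = np.where(se > 0, (p1 - p2) / np.where(se > 0, se, 1.0), np.nan)
    p = 2.0 * stats.norm.sf(np.abs(z))
    if scalar:
        return float(z), float(p)
    return z, p


def log2_fold_change(a, b, pseudo: float = 1.0):
    """log2(a/b) with a pseudo-count added to *both* sides only when one is zero."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    needs = (a == 0) | (b == 0)
    a_adj = np.where(needs, a + pseudo, a)
    b_adj = np.where(needs, b + pseudo, b)
    out = np.log2(a_adj / b_adj)
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# per-comparison calling and the two-line intersection
# ---------------------------------------------------------------------------


def call_degs(
    counts: CountTable,
    expr: pd.DataFrame,
    oe_sample: str,
    wt_sample: str,
    fc_cutoff: float = 2.0,
    p_cutoff: float = 0.001,
) -> pd.DataFrame:
    """Call DEGs for one OE-vs-WT comparison.

    ``expr`` is the normalized (linear-scale) expression table used for
    fold changes; the Z-test itself runs on the raw counts and library
    totals.  Genes with zero counts in both compared samples are excluded
    from testing (statistic NaN, call ``none``).  Returns a per-gene
    frame with columns ``z``, ``p``, ``log2fc``, ``call``.
    """
    for s in (oe_sample, wt_sample):
        if s not in counts.counts.columns:
            raise KeyError(f"sample {s!r} not in count table")
        if s not in expr.columns:
            raise KeyError(f"sample {s!r} not in expression table")
    x1 = counts.counts[oe_sample].to_numpy()
    x2 = counts.counts[wt_sample].to_numpy()
    n1 = float(counts.library_totals[oe_sample])
    n2 = float(counts.library_totals[wt_sample])
    z, p = kal_z_test(x1, n1, x2, n2)

    expr = expr.reindex(counts.counts.index)
    fc = log2_fold_change(expr[oe_sample].to_numpy(), expr[wt_sample].to_numpy())

    log2_cut = np.log2(fc_cutoff)
    tested = (x1 + x2) > 0
    up = tested & (p <= p_cutoff) & (fc >= log2_cut)
    down = tested & (p <= p_cutoff) & (fc <= -log2_cut)
    call = np.where(up, "up", np.where(down, "down", "none"))
    return pd.DataFrame(
        {
            "x_oe": x1.astype(np.int64),
            "x_wt": x2.astype(np.int64),
            "z": np.where(tested, z, np.nan),
            "p": np.where(tested, p, np.nan),
            "log2fc": fc,
            "call": call,
        },
        index=counts.counts.index,
    )


def intersect_degs(res_a: pd.DataFrame, res_b: pd.DataFrame) -> tuple[set[str], set[str]]:
    """Genes called in the same direction in both comparisons.

    Returns ``(common_up, common_down)``; genes called in opposite
    directions are excluded from both sets.
    """
    if not res_a.index.equals(res_b.index):
        raise ValueError("comparisons cover different gene universes")
    common_up = set(res_a.index[(res_a["call"] == "up") & (res_b["call"] == "up")])
    common_down = set(res_a.index[(res_a["call"] == "down") & (res_b["call"] == "down")])
    return common_up, common_down


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Quantile normalization as a scikit-learn style transformer.

    ``fit`` learns the mean sorted profile of the training table;
    ``transform`` maps each column of a same-length table onto it.
    """

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        if X.shape[1] < 2:
            raise ValueError("quantile normalization needs >= 2 samples")
        self.mean_quantiles_ = np.sort(X.to_numpy(), axis=0).mean(axis=1)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)
        if len(X) != len(self.mean_quantiles_):
            raise ValueError("row count differs from the fitted profile")
        n = len(X)
        out = {}
        for col in X.columns:
            ranks = X[col].rank(method="average").to_numpy()
            out[col] = np.interp(ranks, np.arange(1, n + 1), self.mean_quantiles_)
        return pd.DataFrame(out, index=X.index)


class KalZDifferentialExpression(BaseEstimator):
    """Full replicate-free DEG pipeline as a fit-style estimator.

    ``fit`` takes a :class:`~ucptx.io.CountTable`, computes RPKM,
    quantile-normalizes it, runs Kal's Z-test for each OE sample against
    the WT sample, applies the fold-change and p-value cutoffs, and
    intersects the two comparisons.

    Attributes
    ----------
    expression_ : DataFrame
        quantile-normalized RPKM (linear scale).
    results_ : dict[str, DataFrame]
        per-OE-sample call tables from :func:`call_degs`.
    common_up_, common_down_ : set[str]
        genes called in the same direction in both comparisons.
    """

    def __init__(
        self,
        wt_sample: str = "WT",
        oe_samples: tuple[str, ...] = ("OE1", "OE2"),
        fc_cutoff: float = 2.0,
        p_cutoff: float = 0.001,
    ):
        self.wt_sample = wt_sample
        self.oe_samples = oe_samples
        self.fc_cutoff = fc_cutoff
        self.p_cutoff = p_cutoff

    def fit(self, X: CountTable, y=None):
        self.rpkm_ = rpkm_table(X)
        self.expression_ = quantile_normalize(self.rpkm_)
        self.results_ = {
            oe: call_degs(
                X,
                self.expression_,
                oe,
                self.wt_sample,
                fc_cutoff=self.fc_cutoff,
                p_cutoff=self.p_cutoff,
            )
            for oe in self.oe_samples
        }
        tables = list(self.results_.values())
        up, down = intersect_degs(tables[0], tables[1]) if len(tables) >= 2 else (
            set(tables[0].index[tables[0]["call"] == "up"]),
            set(tables[0].index[tables[0]["call"] == "down"]),
        )
        self.common_up_ = up
        self.common_down_ = down
        return self

    def predict(self, X=None) -> pd.Series:
        """Per-gene common call: ``up``/``down``/``none`` (fitted universe)."""
        idx = self.expression_.index
        call = pd.Series("none", index=idx, name="call")
        call.loc[sorted(self.common_up_)] = "up"
        call.loc[sorted(self.common_down_)] = "down"
        return call
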