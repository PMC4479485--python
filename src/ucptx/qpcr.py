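"""Comparative-Ct quantification and RNA-seq/qPCR concordance statistics.

Relative expression follows the comparative-Ct method with an assumed
amplification efficiency of 2 (ideal per-cycle doubling):

    ddCt = (Ct_target,sample - Ct_ref,sample)
         - (Ct_target,calibrator - Ct_ref,calibrator)
    relative expression = 2 ** (-ddCt)

so the calibrator sample maps to exactly 1 for every gene.  Concordance
between platforms is the Pearson correlation of log2 RNA-seq fold
changes against log2 relative expression over the validated gene panel,
with the usual t-distribution p-value; inter-line agreement is reported
as R^2, the square of Pearson's r.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import QpcrTable


def ddct(qpcr: QpcrTable, gene: str, sample: str) -> float:
    """Relative expression 2^-ddCt of ``gene`` in ``sample`` vs the calibrator."""
    ct_t_s = qpcr.ct(gene, sample)
    ct_r_s = qpcr.ct(qpcr.reference_gene, sample)
    ct_t_c = qpcr.ct(gene, qpcr.calibrator_sample)
    ct_r_c = qpcr.ct(qpcr.reference_gene, qpcr.calibrator_sample)
    delta_delta = (ct_t_s - ct_r_s) - (ct_t_c - ct_r_c)
    return float(2.0 ** (-delta_delta))


def relative_expression(qpcr: QpcrTable) -> pd.DataFrame:
    """Gene x sample table of 2^-ddCt values (calibrator column all ones)."""
    genes = sorted(set(qpcr.data["gene"]) - {qpcr.reference_gene})
    samples = qpcr.samples
    return pd.DataFrame(
        {s: [ddct(qpcr, g, s) for g in genes] for s in samples}, index=genes
    )


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with its two-sided t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def r_squared(x, y) -> float:
    """Squared Pearson correlation of two paired vectors."""
    r, _ = pearson_r(x, y)
    return r * r


def concordance(
    rnaseq_log2fc: pd.Series, qpcr_rel_expr: pd.Series
) -> tuple[float, float, pd.DataFrame]:
    """Pearson concordance of log2 RNA-seq fold change vs log2 2^-ddCt.

    The two series are aligned on their gene index; genes missing from
    either side are dropped.  Returns ``(r, p, scatter_table)``.
    """
    if (qpcr_rel_expr <= 0).any():
        raise ValueError("relative expression must be positive")
    joined = pd.DataFrame(
        {"rnaseq_log2fc": rnaseq_log2fc, "qpcr_log2": np.log2(qpcr_rel_expr)}
    ).dropna()
    r, p = pearson_r(joined["rnaseq_log2fc"], joined["qpcr_log2"])
    return r, p, joined
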