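"""GO-term enrichment by the hypergeometric test with BH FDR control.

For a universe of M expressed genes of which K carry a term, and a
selected set of n genes of which k carry it, the enrichment p-value is
the exact upper tail P(X >= k) of Hypergeometric(M, K, n).  Raw
p-values over all tested terms are adjusted with the Benjamini-Hochberg
step-up procedure and a term is flagged enriched when its adjusted p is
below alpha (default 0.05).

Enrichment is on literal annotation sets: a gene annotated with a
descendant term does not implicitly carry its ancestors (no ontology
graph propagation), and terms with a single universe gene are still
tested (no minimum-size filter).

The module also provides the descriptive category summary used for
"term (n transcripts — x.yz%)"-style reporting, with percentages
truncated (not rounded) to two decimals.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .io import AnnotationTable


def hypergeom_tail(M: int, K: int, n: int, k: int) -> float:
    """Exact upper-tail P(X >= k) under Hypergeometric(M, K, n)."""
    if not (0 <= k <= n <= M and 0 <= K <= M):
        raise ValueError(f"inconsistent counts M={M}, K={K}, n={n}, k={k}")
    if k > K:
        raise ValueError(f"overlap k={k} exceeds annotated universe K={K}")
    return float(stats.hypergeom.sf(k - 1, M, K, n))


def bh_adjust(pvals) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    pvals = list(pvals)
    if not pvals:
        return []
    if any(not (0 < p <= 1) for p in pvals):
        raise ValueError("p-values must lie in (0, 1]")
    return list(multipletests(pvals, method="fdr_bh")[1])


def enrich(
    selected: set[str],
    annotation: AnnotationTable,
    universe: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of every GO term present in the universe.

    Returns one row per term with universe/annotated/selected/overlap
    counts (``M``, ``K``, ``n``, ``k``), raw and BH-adjusted p, and the
    ``enriched`` flag (adjusted p < alpha), sorted by raw p.
    """
    selected = set(selected)
    universe = set(universe)
    if not selected <= universe:
        raise ValueError("selected set must be a subset of the universe")
    M, n = len(universe), len(selected)
    term_universe_genes: dict[str, set[str]] = {}
    for g in universe:
        for t in annotation.gene_to_go.get(g, ()):
            term_universe_genes.setdefault(t, set()).add(g)
    rows = []
    for term, genes in sorted(term_universe_genes.items()):
        K = len(genes)
        k = len(genes & selected)
        rows.append((term, M, K, n, k, hypergeom_tail(M, K, n, k)))
    result = pd.DataFrame(rows, columns=["term", "M", "K", "n", "k", "p"]).set_index("term")
    result["p_adjusted"] = bh_adjust(result["p"]) if len(result) else []
    result["enriched"] = result["p_adjusted"] < alpha
    return result.sort_values("p")


def truncate_percentage(count: int, total: int) -> float:
    """100*count/total truncated toward zero to 2 decimals (exact, integer math)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return (10000 * count // total) / 100


def summarize_go_categories(
    selected: set[str],
    annotation: AnnotationTable,
    terms: set[str] | None = None,
) -> pd.DataFrame:
    """Per-term transcript counts and truncated percentages of the selected set.

    ``terms`` optionally restricts the summary to one ontology namespace
    (the annotation table itself carries no namespace structure).  Terms
    are sorted by count descending.  The percentage denominator is the
    selected-set size, so a multiply-annotated gene contributes to
    several rows and percentages need not sum to 100.
    """
    selected = set(selected)
    if not selected:
        raise ValueError("selected set is empty")
    counts: dict[str, int] = {}
    for g in selected:
        for t in annotation.gene_to_go.get(g, ()):
            if terms is None or t in terms:
                counts[t] = counts.get(t, 0) + 1
    rows = [
        (t, c, truncate_percentage(c, len(selected)))
        for t, c in sorted(counts.items(), key=lambda item: (-item[1], item[0]))
    ]
    return pd.DataFrame(rows, columns=["term", "count", "percent"]).set_index("term")


class HypergeometricEnrichment(BaseEstimator):
    """Enrichment of a selected gene set as a fit-style estimator.

    Attributes after ``fit(selected, universe)``: ``results_`` (the
    :func:`enrich` table) and ``enriched_terms_``.
    """

    def __init__(self, annotation: AnnotationTable = None, alpha: float = 0.05):
        self.annotation = annotation
        self.alpha = alpha

    def fit(self, X: set[str], y: set[str] = None):
        if self.annotation is None:
            raise ValueError("annotation is required")
        if y is None:
            raise ValueError("pass the expressed-gene universe as y")
        self.results_ = enrich(X, self.annotation, y, alpha=self.alpha)
        self.enriched_terms_ = list(self.results_.index[self.results_["enriched"]])
        return self
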