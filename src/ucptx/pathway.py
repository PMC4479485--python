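"""Pathway-level differential expression by a resampling Z-score.

Transcripts coding for enzymes are mapped to EC numbers; each EC's log2
fold change (overexpressor over wild type) is the unweighted mean over
its coding genes.  Pathways with fewer than five fold-change-bearing ECs
are dropped.  For a retained pathway of k enzymes, the observed mean
fold change is compared against the means of random k-subsets of the
pooled enzyme universe (the distinct fold-change-bearing ECs of all
retained pathways): with null mean m and standard deviation s over the
resampled sets,

    Z = (observed - m) / s

and a two-sided standard-normal p-value is attached.  Positive Z marks
an up-regulated pathway, negative Z a down-regulated one; pathways with
p below alpha (default 0.05) are called in the direction of the sign.

One hundred random sets is the conventional default; an exhaustive null
over all C(pool, k) subsets is available for small pools, and the
empirical rank p-value is reported alongside the normal-theory one for
transparency (100 draws cannot resolve p below about 0.02 empirically).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .deg import log2_fold_change
from .io import AnnotationTable, PathwayMap

logger = logging.getLogger("ucptx")


@dataclass
class PathwayScore:
    """Resampling-null score for one pathway."""

    pathway_id: str
    k: int
    observed: float
    null_mean: float
    null_sd: float
    z: float
    p: float
    p_empirical: float
    direction: str  # up | down | ns


def ec_fold_changes(
    expr: pd.DataFrame,
    annotation: AnnotationTable,
    oe_sample: str,
    wt_sample: str,
    pseudo: float = 1.0,
) -> pd.Series:
    """Per-EC mean log2 fold change over the EC's coding genes.

    Gene fold changes are log2(ExpA/ExpB) on the normalized expression
    table with the pseudo-count policy of the DEG stage (pseudo-count on
    both sides only when one side is zero).  ECs whose coding genes all
    lack expression rows are dropped with a warning.
    """
    gene_fc = pd.Series(
        log2_fold_change(expr[oe_sample].to_numpy(), expr[wt_sample].to_numpy(), pseudo),
        index=expr.index,
    )
    per_ec: dict[str, list[float]] = {}
    for gene, ecs in annotation.gene_to_ec.items():
        if gene not in gene_fc.index:
            continue
        for ec in ecs:
            per_ec.setdefault(ec, []).append(float(gene_fc[gene]))
    all_ecs = set().union(*annotation.gene_to_ec.values()) if annotation.gene_to_ec else set()
    for ec in all_ecs - set(per_ec):
        logger.warning("EC %s has no expressed coding gene; dropped", ec)
    return pd.Series({ec: float(np.mean(v)) for ec, v in per_ec.items()}).sort_index()


def filter_pathways(pmap: PathwayMap, ec_fc: pd.Series, min_ec: int = 5) -> PathwayMap:
    """Keep pathways with at least ``min_ec`` fold-change-bearing ECs."""
    have = set(ec_fc.index)
    keep = [pid for pid in pmap.ecs if len(pmap.ecs[pid] & have) >= min_ec]
    return PathwayMap(
        names={pid: pmap.names[pid] for pid in keep},
        ecs={pid: set(pmap.ecs[pid]) for pid in keep},
    )


def pathway_z(
    pathway_ecs: set[str],
    ec_fc: pd.Series,
    pool: set[str],
    n_sets: int | str = 100,
    seed: int | np.random.Generator | None = None,
    alpha: float = 0.05,
    pathway_id: str = "",
) -> PathwayScore:
    """Score one pathway against random equally sized enzyme sets.

    ``pool`` is the resampling universe (distinct fold-change-bearing
    ECs over all retained pathways).  ``n_sets`` random subsets of size
    k are drawn uniformly without replacement within a set, independent
    across sets; ``n_sets="exhaustive"`` enumerates every k-subset.
    """
    members = sorted(ec for ec in pathway_ecs if ec in ec_fc.index)
    k = len(members)
    pool_list = sorted(ec for ec in pool if ec in ec_fc.index)
    if len(pool_list) <= k:
        raise ValueError(f"resampling pool ({len(pool_list)}) must exceed k ({k})")
    observed = float(ec_fc[members].mean())
    pool_vals = ec_fc[pool_list].to_numpy()

    if n_sets == "exhaustive":
        null_means = np.array([np.mean(c) for c in combinations(pool_vals, k)])
    else:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        null_means = np.array(
            [rng.choice(pool_vals, size=k, replace=False).mean() for _ in range(int(n_sets))]
        )
    null_mean = float(null_means.mean())
    null_sd = float(null_means.std(ddof=1))
    # guard against a numerically degenerate null (all subset means equal)
    if null_sd <= 1e-12 * max(1.0, abs(null_mean)):
        if np.isclose(observed, null_mean):
            z, p = 0.0, 1.0
        else:
            raise ValueError("degenerate resampling pool: null sd is zero")
    else:
        z = (observed - null_mean) / null_sd
        p = float(2.0 * stats.norm.sf(abs(z)))
    p_emp = float(
        (1 + np.sum(np.abs(null_means - null_mean) >= abs(observed - null_mean)))
        / (len(null_means) + 1)
    )
    if p < alpha and z > 0:
        direction = "up"
    elif p < alpha and z < 0:
        direction = "down"
    else:
        direction = "ns"
    return PathwayScore(
        pathway_id=pathway_id,
        k=k,
        observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z=float(z),
        p=p,
        p_empirical=p_emp,
        direction=direction,
    )


def score_pathways(
    pmap: PathwayMap,
    ec_fc: pd.Series,
    n_sets: int | str = 100,
    seed: int | None = None,
    min_ec: int = 5,
    alpha: float = 0.05,
) -> list[PathwayScore]:
    """Filter pathways, build the shared pool, and score each retained pathway."""
    retained = filter_pathways(pmap, ec_fc, min_ec=min_ec)
    pool = set().union(*retained.ecs.values()) if len(retained) else set()
    pool &= set(ec_fc.index)
    rng = np.random.default_rng(seed)
    return [
        pathway_z(
            retained.ecs[pid], ec_fc, pool, n_sets=n_sets, seed=rng, alpha=alpha,
            pathway_id=pid,
        )
        for pid in sorted(retained.ecs)
    ]


def classify_pathways(
    scores: list[PathwayScore], alpha: float = 0.05
) -> tuple[list[str], list[str]]:
    """Partition scored pathways into (up, down) lists by p < alpha and Z sign."""
    up = [s.pathway_id for s in scores if s.p < alpha and s.z > 0]
    down = [s.pathway_id for s in scores if s.p < alpha and s.z < 0]
    return up, down


def scores_to_frame(scores: list[PathwayScore]) -> pd.DataFrame:
    """Tabulate a list of :class:`PathwayScore` (one row per pathway)."""
    return pd.DataFrame(
        [
            {
                "pathway": s.pathway_id,
                "k": s.k,
                "observed_fc": s.observed,
                "null_mean": s.null_mean,
                "null_sd": s.null_sd,
                "z": s.z,
                "p": s.p,
                "p_empirical": s.p_empirical,
                "direction": s.direction,
            }
            for s in scores
        ]
    ).set_index("pathway")


class PathwayZScorer(BaseEstimator):
    """Pathway scoring as a fit-style estimator.

    ``fit(expr)`` computes per-EC fold changes for the configured
    comparison, applies the >=``min_ec`` retention filter and scores
    every retained pathway.  Attributes: ``ec_fold_changes_``,
    ``scores_`` (DataFrame), ``up_``, ``down_``.
    """

    def __init__(
        self,
        annotation: AnnotationTable = None,
        pathways: PathwayMap = None,
        oe_sample: str = "OE1",
        wt_sample: str = "WT",
        n_sets: int | str = 100,
        min_ec: int = 5,
        alpha: float = 0.05,
        random_state: int | None = None,
    ):
        self.annotation = annotation
        self.pathways = pathways
        self.oe_sample = oe_sample
        self.wt_sample = wt_sample
        self.n_sets = n_sets
        self.min_ec = min_ec
        self.alpha = alpha
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None):
        if self.annotation is None or self.pathways is None:
            raise ValueError("annotation and pathways are required")
        self.ec_fold_changes_ = ec_fold_changes(
            X, self.annotation, self.oe_sample, self.wt_sample
        )
        scores = score_pathways(
            self.pathways,
            self.ec_fold_changes_,
            n_sets=self.n_sets,
            seed=self.random_state,
            min_ec=self.min_ec,
            alpha=self.alpha,
        )
        self.scores_ = scores_to_frame(scores)
        self.up_, self.down_ = classify_pathways(scores, alpha=self.alpha)
        return self
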