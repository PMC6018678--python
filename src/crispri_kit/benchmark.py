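"""Essentiality classifiers and ROC-AUC benchmarking.

Three classifiers map screen outputs to a [0, 1] essentiality prediction:

* CRISPRi: ``1 - FPR`` for genes with negative fitness, else 0;
* Tn-seq: genes whose insertion index (unique insertions in the coding
  region / gene length) falls below a bimodality cutoff are "required" and
  scored ``1 - exp(-local_insertion_index * gene_length)`` with the local
  index taken from the 10-kb window around the gene; others score 0;
* genetic footprinting: ``1 - P`` for genes flagged essential, else 0.

Classifiers are compared by ROC against a binary gold standard (e.g. the
Keio-collection essential gene set).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

logger = logging.getLogger(__name__)

TNSEQ_INDEX_CUTOFF = 0.00125
TNSEQ_WINDOW = 10_000


def crispri_prediction(fitness: float, fpr: float) -> float:
    """CRISPRi essentiality score: ``1 - FPR`` if fitness < 0, else 0."""
    return 1.0 - fpr if fitness < 0 else 0.0


def tnseq_prediction(
    start: int,
    end: int,
    insertions,
    cutoff: float = TNSEQ_INDEX_CUTOFF,
    window: int = TNSEQ_WINDOW,
    chromosome_length: int | None = None,
) -> float:
    """Tn-seq essentiality score from unique insertion positions.

    ``insertions`` are 1-based unique genomic positions.  The gene's
    insertion index is the number of insertions within [start, end] divided
    by the gene length; at or above ``cutoff`` the gene is not required and
    scores 0.  Otherwise the local insertion index is N / window, where N
    counts insertions within the ``window``-bp region centered on the gene
    midpoint (truncated at chromosome ends, divisor kept at ``window``), and
    the score is ``1 - exp(-local_index * length)``.
    """
    positions = np.unique(np.asarray(insertions, dtype=int))
    length = end - start + 1
    if length <= 0:
        raise ValueError("gene end must not precede start")
    in_gene = ((positions >= start) & (positions <= end)).sum()
    if in_gene / length >= cutoff:
        return 0.0
    mid = (start + end) / 2
    lo = mid - window / 2
    hi = mid + window / 2
    if chromosome_length is not None:
        lo = max(lo, 1)
        hi = min(hi, chromosome_length)
    n_window = ((positions >= lo) & (positions <= hi)).sum()
    local_index = n_window / window
    return 1.0 - math.exp(-local_index * length)


def footprinting_prediction(essential_flag: bool, p_value: float) -> float:
    """Genetic-footprinting score: ``1 - P`` if flagged essential, else 0."""
    return 1.0 - p_value if essential_flag else 0.0


def roc_auc(scores: pd.Series, gold: pd.Series):
    """ROC curve and AUC of a classifier against binary gold labels.

    ``gold`` maps gene -> True (essential) / False.  Genes absent from the
    gold standard are dropped with a logged count.  Returns
    ``(roc_points: DataFrame[fpr, tpr, threshold], auc: float)``.
    """
    common = scores.index.intersection(gold.index)
    dropped = len(scores) - len(common)
    if dropped:
        logger.info("dropping %d genes absent from the gold standard", dropped)
    y = gold.loc[common].astype(bool).to_numpy()
    s = scores.loc[common].astype(float).to_numpy()
    if y.all() or not y.any():
        raise ValueError("gold standard must contain both classes")
    fpr, tpr, thresholds = _roc_curve(y, s)
    return (
        pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds}),
        float(_trapezoid_auc(fpr, tpr)),
    )
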