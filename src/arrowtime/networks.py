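"""Network assignment and signed aggregation of regional statistics.

Regions are assigned to networks (e.g. the seven canonical resting-state
networks) by majority vote over region/label overlap counts; positive- and
negative-valued contributions of member regions are then summed separately
per network, all regions included regardless of significance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import LabelTable

__all__ = ["majority_vote_labels", "signed_contributions", "NetworkContribution"]

logger = logging.getLogger(__name__)


def majority_vote_labels(overlap_counts: pd.DataFrame) -> LabelTable:
    """Assign each region the label with the largest overlap count.

    ``overlap_counts`` has regions as index and labels as columns.  Ties are
    broken by column (label) order and logged; an all-zero row is an error
    naming the region.
    """
    counts = overlap_counts.to_numpy()
    if (counts < 0).any():
        raise ValueError("overlap counts must be nonnegative")
    zero_rows = np.flatnonzero(counts.sum(axis=1) == 0)
    if zero_rows.size:
        raise ValueError(
            f"region {overlap_counts.index[zero_rows[0]]!r} has no overlap votes"
        )
    winners = counts.argmax(axis=1)  # argmax takes the first label on ties
    ties = (counts == counts.max(axis=1, keepdims=True)).sum(axis=1) > 1
    for i in np.flatnonzero(ties):
        logger.warning(
            "majority-vote tie for region %r; assigned %r by label order",
            overlap_counts.index[i],
            overlap_counts.columns[winners[i]],
        )
    labels = {
        str(region): str(overlap_counts.columns[w])
        for region, w in zip(overlap_counts.index, winners)
    }
    return LabelTable(
        labels,
        label_order=[str(c) for c in overlap_counts.columns],
        overlap_counts=overlap_counts,
    )


@dataclass
class NetworkContribution:
    """Signed per-network sums of a regional statistic.

    ``table`` has one row per label with columns positive_sum (sum of
    positive values over member regions) and negative_sum (sum of absolute
    negative values); ``overall`` is the total signed mass across labels.
    """

    table: pd.DataFrame
    overall: float

    def save(self, path) -> None:
        self.table.to_csv(path, sep="\t")


def signed_contributions(
    tau: np.ndarray, labels: LabelTable, region_ids: Sequence[str]
) -> NetworkContribution:
    """Sum positive and negative statistic mass separately per network.

    Every region must carry a label; the sums over labels partition the
    signed mass exactly: sum over labels of (positive_sum - negative_sum)
    equals sum(tau).
    """
    tau = np.asarray(tau, dtype=float)
    if tau.shape[0] != len(region_ids):
        raise ValueError("tau and region_ids disagree in length")
    assigned = [labels.label_of(r) for r in region_ids]  # KeyError if unlabeled
    order = list(labels.label_order)
    for lab in assigned:
        if lab not in order:
            order.append(lab)
    pos = {lab: 0.0 for lab in order}
    neg = {lab: 0.0 for lab in order}
    for value, lab in zip(tau, assigned):
        if value > 0:
            pos[lab] += value
        else:
            neg[lab] += -value
    table = pd.DataFrame(
        {
            "positive_sum": [pos[lab] for lab in order],
            "negative_sum": [neg[lab] for lab in order],
        },
        index=pd.Index(order, name="label"),
    )
    overall = float(table.positive_sum.sum() + table.negative_sum.sum())
    return NetworkContribution(table, overall)
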