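"""Levins' niche breadth per OTU and community-level Bcom.

``B_j = 1 / Σ_i P_ij²`` where ``P_ij`` is OTU ``j``'s proportion in
community ``i`` of its total across all communities (so Σ_i P_ij = 1).
``B_j`` ranges from 1 (a specialist confined to one community) to the
number of communities (a generalist spread perfectly evenly).  ``Bcom`` of
a sample is the mean ``B`` over the taxa present in it: communities built
from generalists score high, communities of habitat specialists score low.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import OtuTable

logger = logging.getLogger(__name__)


def levins_breadth(table: OtuTable) -> pd.Series:
    """Levins' B per OTU; all-zero OTUs are excluded (logged)."""
    mat = table.matrix.astype(float)
    totals = mat.sum(axis=0)
    empty = totals == 0
    if empty.any():
        logger.info("levins_breadth: excluding %d all-zero OTUs", int(empty.sum()))
    P = mat[:, ~empty] / totals[~empty]
    B = 1.0 / (P**2).sum(axis=0)
    return pd.Series(B, index=np.asarray(table.otu_ids)[~empty], name="B")


def community_breadth(table: OtuTable) -> pd.Series:
    """Bcom per sample: mean B over taxa with nonzero count in the sample."""
    B = levins_breadth(table)
    sub = table.counts[B.index]
    present = sub.to_numpy() > 0
    if not present.any(axis=1).all():
        empty = [s for s, ok in zip(table.sample_ids, present.any(axis=1)) if not ok]
        raise ValueError(f"samples with no taxa present: {empty}")
    b = B.to_numpy()
    bcom = np.array([b[row].mean() for row in present])
    return pd.Series(bcom, index=table.counts.index, name="Bcom")


def breadth_by_group(table: OtuTable, group_of_sample: pd.Series) -> pd.DataFrame:
    """Per-sample Bcom with its group label attached (for zone comparisons)."""
    bcom = community_breadth(table)
    return pd.DataFrame({"Bcom": bcom, "group": group_of_sample.loc[bcom.index]})
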