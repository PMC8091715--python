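"""Phylogenetic and taxonomic null models for community assembly.

Implements the two-step ecological process inference: for every pair of
communities, the beta nearest-taxon index (βNTI) asks whether phylogenetic
turnover (βMNTD) deviates from a tip-shuffle null — deviations beyond ±2
standard deviations indicate selection — and, for pairs without a selection
signal, the Bray–Curtis Raup–Crick metric (RC_Bray) asks whether taxonomic
turnover deviates from a random-assembly null — |RC| > 0.95 indicates a
dispersal process.  Pairwise comparisons are then partitioned into five
processes: variable selection, homogeneous selection, dispersal limitation,
homogenizing dispersal, and the undominated ("drift") remainder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io import OtuTable, patristic_distances

logger = logging.getLogger(__name__)

PROCESSES = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)


@dataclass
class ProcessPartition:
    """Fractions of pairwise comparisons assigned to each assembly process.

    The |βNTI| < 2 & |RC| ≤ 0.95 class is the "undominated" fraction, often
    reported as drift (plus weak selection/dispersal and diversification).
    """

    counts: dict
    n_pairs: int

    @property
    def fractions(self) -> dict:
        if self.n_pairs == 0:
            return {k: np.nan for k in PROCESSES}
        return {k: self.counts[k] / self.n_pairs for k in PROCESSES}

    @property
    def determinism_fraction(self) -> float:
        f = self.fractions
        return f["variable_selection"] + f["homogeneous_selection"]

    @property
    def stochasticity_fraction(self) -> float:
        f = self.fractions
        return (
            f["dispersal_limitation"] + f["homogenizing_dispersal"] + f["undominated"]
        )


def _aligned_distance(table: OtuTable, tree):
    """Patristic distances over the table∩tree OTU set, plus the trimmed matrix."""
    D = patristic_distances(tree, table.otu_ids)
    otus = list(D.index)
    mat = table.counts[otus].to_numpy(dtype=float)
    return mat, D.to_numpy(), otus


def _bmntd_from_arrays(F: np.ndarray, P: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Abundance-weighted βMNTD for all sample pairs.

    F: relative abundances (samples × OTUs); P: presence mask; D: OTU × OTU
    patristic distances.  For each sample ``l``, ``M[:, l]`` holds each
    OTU's distance to its nearest taxon present in ``l`` (zero for taxa also
    present in ``l`` — their nearest neighbour is themselves).
    """
    n_samples = F.shape[0]
    M = np.empty((D.shape[0], n_samples))
    for l in range(n_samples):
        M[:, l] = D[:, P[l]].min(axis=1)
    half = F @ M  # half[k, l] = sum_i f_ik * min-dist(i -> sample l)
    return 0.5 * (half + half.T)


def beta_mntd(table: OtuTable, tree, abundance_weighted: bool = True) -> pd.DataFrame:
    """Observed βMNTD matrix (mean nearest-taxon distance between samples)."""
    mat, D, _ = _aligned_distance(table, tree)
    P = mat > 0
    if abundance_weighted:
        F = mat / mat.sum(axis=1, keepdims=True)
    else:
        F = P / P.sum(axis=1, keepdims=True)
    out = _bmntd_from_arrays(F, P, D)
    np.fill_diagonal(out, 0.0)
    ids = table.sample_ids
    return pd.DataFrame(out, index=ids, columns=ids)


def beta_nti(
    table: OtuTable,
    tree,
    n_null: int = 999,
    seed=None,
    abundance_weighted: bool = True,
) -> pd.DataFrame:
    """βNTI: standardized effect size of βMNTD under a taxa-shuffle null.

    Each of the ``n_null`` randomizations draws one permutation of the OTU
    identities over the tree tips (equivalently, of the distance-matrix
    rows/columns) and recomputes βMNTD for all pairs.  βNTI(k,l) =
    (obs − null mean) / null SD.  Pairs with zero null SD (e.g. identical
    samples) come back as NaN and are excluded downstream.
    """
    mat, D, _ = _aligned_distance(table, tree)
    P = mat > 0
    if abundance_weighted:
        F = mat / mat.sum(axis=1, keepdims=True)
    else:
        F = P.astype(float) / P.sum(axis=1, keepdims=True)
    obs = _bmntd_from_arrays(F, P, D)

    rng = np.random.default_rng(seed)
    n_otus = D.shape[0]
    mean = np.zeros_like(obs)
    m2 = np.zeros_like(obs)
    for r in range(n_null):
        perm = rng.permutation(n_otus)
        null = _bmntd_from_arrays(F, P, D[np.ix_(perm, perm)])
        delta = null - mean
        mean += delta / (r + 1)
        m2 += delta * (null - mean)
    sd = np.sqrt(m2 / max(n_null - 1, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        bnti = (obs - mean) / sd
    bnti[sd == 0] = np.nan
    n_undef = int(np.isnan(bnti[np.triu_indices_from(bnti, k=1)]).sum())
    if n_undef:
        logger.info("beta_nti: %d pairs with zero null SD set to NaN", n_undef)
    ids = table.sample_ids
    return pd.DataFrame(bnti, index=ids, columns=ids)


def raup_crick_bray(table: OtuTable, n_null: int = 999, seed=None) -> pd.DataFrame:
    """Bray–Curtis Raup–Crick matrix in [−1, 1].

    The null assembles each community independently while preserving its
    observed richness and total abundance: species membership is drawn
    without replacement with probability proportional to occupancy across
    all samples; each drawn species gets one individual and the remaining
    individuals are distributed multinomially in proportion to regional
    relative abundance among the drawn species.  RC compares the observed
    Bray–Curtis dissimilarity of a pair against the null distribution:

        RC = 2·[(#(null < obs) + ½·#(null = obs)) / n_null − ½]

    RC > 0.95: more turnover than random assembly (dispersal limitation,
    given no selection signal); RC < −0.95: less turnover (homogenizing
    dispersal).
    """
    mat = table.matrix.astype(float)
    n_samples, n_otus = mat.shape
    occupancy = (mat > 0).sum(axis=0).astype(float)
    gamma = occupancy / occupancy.sum()
    regional = mat.sum(axis=0)
    regional_p = regional / regional.sum()
    richness = (mat > 0).sum(axis=1)
    totals = mat.sum(axis=1).astype(int)

    obs = squareform(pdist(mat, metric="braycurtis"))
    rng = np.random.default_rng(seed)
    less = np.zeros((n_samples, n_samples))
    equal = np.zeros((n_samples, n_samples))
    null_mat = np.zeros((n_samples, n_otus))
    for _ in range(n_null):
        null_mat[:] = 0.0
        for s in range(n_samples):
            k = int(richness[s])
            members = rng.choice(n_otus, size=k, replace=False, p=gamma)
            counts = np.ones(k)
            remaining = totals[s] - k
            if remaining > 0:
                w = regional_p[members]
                counts += rng.multinomial(remaining, w / w.sum())
            null_mat[s, members] = counts
        null_d = squareform(pdist(null_mat, metric="braycurtis"))
        less += null_d < obs
        equal += np.isclose(null_d, obs)
    rc = 2.0 * ((less + 0.5 * equal) / n_null - 0.5)
    np.fill_diagonal(rc, 0.0)
    ids = table.sample_ids
    return pd.DataFrame(rc, index=ids, columns=ids)


def classify_pair(bnti: float, rc: float) -> str | None:
    """Five-process rule for one pairwise comparison (NaN βNTI → None)."""
    if np.isnan(bnti):
        return None
    if bnti > 2:
        return "variable_selection"
    if bnti < -2:
        return "homogeneous_selection"
    if np.isnan(rc):
        return None
    if rc > 0.95:
        return "dispersal_limitation"
    if rc < -0.95:
        return "homogenizing_dispersal"
    return "undominated"


def partition_processes(bnti: pd.DataFrame, rc: pd.DataFrame) -> ProcessPartition:
    """Partition all pairwise comparisons into the five assembly processes.

    |βNTI| > 2 assigns selection (variable if positive, homogeneous if
    negative) regardless of RC; otherwise RC > 0.95 assigns dispersal
    limitation, RC < −0.95 homogenizing dispersal, and the remainder is
    undominated.  Ties at exactly ±2 fall to the stochastic side.  Pairs
    with undefined βNTI are excluded from the denominator.
    """
    if list(bnti.index) != list(rc.index):
        rc = rc.loc[bnti.index, bnti.columns]
    b = bnti.to_numpy()
    r = rc.to_numpy()
    iu = np.triu_indices_from(b, k=1)
    counts = {k: 0 for k in PROCESSES}
    n_pairs = 0
    for bv, rv in zip(b[iu], r[iu]):
        label = classify_pair(bv, rv)
        if label is None:
            continue
        counts[label] += 1
        n_pairs += 1
    return ProcessPartition(counts=counts, n_pairs=n_pairs)
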