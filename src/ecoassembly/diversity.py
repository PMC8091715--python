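"""Alpha diversity, abundance categories, Preston log-normal coverage.

Implements the descriptive layer of the pipeline: per-sample richness and
Shannon–Wiener index, rarefaction curves, the six-way abundant/rare OTU
classification, the truncated Preston log-normal fit used to judge sampling
completeness, and Tukey's HSD for group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import OtuTable

CATEGORIES = ("AAT", "ART", "MT", "CRT", "CAT", "CRAT")


def relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Per-sample proportions; each row sums to 1."""
    sums = table.sample_sums()
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"zero-sum samples: {list(zero.index)}")
    return table.counts.div(sums, axis=0)


def alpha_diversity(table: OtuTable, base: str = "e") -> pd.DataFrame:
    """Richness and Shannon index per sample.

    Shannon is ``−Σ p ln p`` over nonzero proportions (natural log by
    default; ``base="2"`` switches to bits).
    """
    rel = relative_abundance(table).to_numpy()
    richness = (table.matrix > 0).sum(axis=1)
    logf = np.log2 if base == "2" else np.log
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(rel > 0, rel * logf(rel), 0.0)
    shannon = -terms.sum(axis=1)
    return pd.DataFrame(
        {"richness": richness, "shannon": shannon}, index=table.counts.index
    )


def rarefaction_curve(
    table: OtuTable, step_sizes, reps: int = 10, seed=None
) -> pd.DataFrame:
    """Mean subsampled richness per sample at each depth.

    Returns a long-format frame (sample, depth, richness) averaging ``reps``
    random sub-rarefactions per depth; depths exceeding a sample's total are
    skipped for that sample.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sid, row in zip(table.sample_ids, table.matrix):
        total = int(row.sum())
        for depth in step_sizes:
            if depth > total:
                continue
            if depth == total:
                mean_rich = float((row > 0).sum())
            else:
                vals = [
                    (rng.multivariate_hypergeometric(row, depth) > 0).sum()
                    for _ in range(reps)
                ]
                mean_rich = float(np.mean(vals))
            rows.append((sid, depth, mean_rich))
    return pd.DataFrame(rows, columns=["sample", "depth", "richness"])


def classify_abundance_categories(
    rel: pd.DataFrame, rare_cut: float = 0.001, abundant_cut: float = 0.01
) -> pd.Series:
    """Six-way abundant/rare classification of each OTU.

    Using per-sample relative abundances (``rel``: samples × OTUs):

    * AAT  — always abundant: ≥ ``abundant_cut`` in every sample
    * ART  — always rare: < ``rare_cut`` in every sample
    * MT   — moderate: within [``rare_cut``, ``abundant_cut``) in every sample
    * CRT  — conditionally rare: never abundant, rare in at least one sample
    * CAT  — conditionally abundant: never rare, abundant in at least one sample
    * CRAT — spans the full range: rare in some samples, abundant in others

    The boundaries follow the usual convention: "rare" is strictly below
    ``rare_cut``; "abundant" is inclusive at ``abundant_cut``.  The six
    classes partition every OTU present in at least one sample.
    """
    arr = rel.to_numpy()
    present = arr.sum(axis=0) > 0
    rare = arr < rare_cut
    abundant = arr >= abundant_cut
    all_ab = abundant.all(axis=0)
    all_rare = rare.all(axis=0)
    any_rare = rare.any(axis=0)
    any_ab = abundant.any(axis=0)
    out = np.empty(arr.shape[1], dtype=object)
    out[all_ab] = "AAT"
    out[all_rare & ~all_ab] = "ART"
    mid = ~any_rare & ~any_ab
    out[mid] = "MT"
    out[any_rare & any_ab] = "CRAT"
    out[any_rare & ~any_ab & ~all_rare] = "CRT"
    out[any_ab & ~any_rare & ~all_ab] = "CAT"
    assert not any(v is None for v in out[present]), "classification not exhaustive"
    return pd.Series(out, index=rel.columns, name="category")[present]


# ---------------------------------------------------------------------------
# Preston log-normal
# ---------------------------------------------------------------------------

@dataclass
class PrestonFit:
    """Gaussian fit to the octave species-abundance distribution.

    ``S(R) = S0 · exp(−(R − R0)² / (2 σ²))`` over octave index R;
    extrapolated richness is the Gaussian integral ``S0·σ·√(2π)`` and
    coverage is observed / extrapolated (the fraction of the metacommunity's
    species the survey is estimated to have seen — the "unveiled" fraction).
    """

    octave_index: np.ndarray
    observed_octave_counts: np.ndarray
    mode: float  # R0
    width: float  # sigma, in octaves
    height: float  # S0
    observed_richness: int
    extrapolated_richness: float
    coverage: float
    method: str


def preston_octaves(abundances) -> pd.Series:
    """Doubling (log2) abundance classes with boundary ties split.

    Octave ``j`` covers abundances in ``(2^(j−1), 2^j]``; a species whose
    abundance is exactly ``2^j`` contributes half to octave ``j`` and half
    to octave ``j+1``.
    """
    x = np.asarray(abundances, dtype=float)
    x = x[x > 0]
    n_oct = int(np.ceil(np.log2(x.max()))) + 2
    counts = np.zeros(n_oct)
    logx = np.log2(x)
    is_pow = np.isclose(logx, np.round(logx))
    k = np.round(logx).astype(int)
    for kk in k[is_pow]:
        counts[kk] += 0.5
        counts[kk + 1] += 0.5
    j = np.ceil(logx[~is_pow]).astype(int)
    for jj in j:
        counts[jj] += 1.0
    last = np.max(np.nonzero(counts)) if counts.any() else 0
    return pd.Series(counts[: last + 1], index=np.arange(last + 1), name="species")


class PrestonFitError(RuntimeError):
    def __init__(self, msg, octaves=None):
        super().__init__(msg)
        self.octaves = octaves


def preston_fit(otu_total_abundances, method: str = "octave_glm") -> PrestonFit:
    """Fit the truncated Preston log-normal and estimate sampling coverage.

    ``method="octave_glm"`` fits a Poisson GLM (log link, quadratic in the
    octave index) to the octave counts — the quasi-Poisson-on-octaves
    approximation; ``method="log2_mle"`` fits a left-truncated normal to the
    individual log2 abundances by maximum likelihood (truncation at 0, the
    veil line below one individual).
    """
    x = np.asarray(otu_total_abundances, dtype=float)
    x = x[x > 0]
    if len(x) < 10:
        raise ValueError("need at least 10 OTUs with positive abundance")
    oct_counts = preston_octaves(x)
    R = oct_counts.index.to_numpy(dtype=float)
    S = oct_counts.to_numpy()
    # veil line: octaves below the smallest observed abundance are
    # unobservable, not empty — exclude them from the fit so the Gaussian
    # can extend left of the veil
    veil = int(np.floor(np.log2(x.min())))
    visible = R >= veil

    if method == "octave_glm":
        import statsmodels.api as sm

        Rv, Sv = R[visible], S[visible]
        X = np.column_stack([np.ones_like(Rv), Rv, Rv**2])
        try:
            res = sm.GLM(Sv, X, family=sm.families.Poisson()).fit()
            a, b, c = res.params
        except Exception as exc:  # pragma: no cover - statsmodels failure path
            raise PrestonFitError(f"octave GLM failed: {exc}", oct_counts)
        if c >= 0:
            raise PrestonFitError(
                "octave GLM found no interior mode (non-concave quadratic)", oct_counts
            )
        sigma = float(np.sqrt(-1.0 / (2.0 * c)))
        mode = float(-b / (2.0 * c))
        height = float(np.exp(a - b**2 / (4.0 * c)))
        extrap = height * sigma * np.sqrt(2.0 * np.pi)
    elif method == "log2_mle":
        y = np.log2(x)
        trunc = float(np.floor(y.min()))  # veil line in log2 units

        def nll(theta):
            mu, log_sigma = theta
            sigma = np.exp(log_sigma)
            aa = (trunc - mu) / sigma
            return -np.sum(stats.truncnorm.logpdf(y, aa, np.inf, loc=mu, scale=sigma))

        res = optimize.minimize(
            nll, x0=[float(np.mean(y)), float(np.log(np.std(y) + 1e-6))],
            method="Nelder-Mead",
        )
        if not res.success:
            raise PrestonFitError(f"truncated-normal MLE failed: {res.message}", oct_counts)
        mode = float(res.x[0])
        sigma = float(np.exp(res.x[1]))
        seen_frac = float(stats.norm.sf(trunc, loc=mode, scale=sigma))
        extrap = len(x) / max(seen_frac, 1e-12)
        height = extrap / (sigma * np.sqrt(2.0 * np.pi))
    else:
        raise ValueError(f"unknown method {method!r}")

    extrap = max(extrap, float(len(x)))
    return PrestonFit(
        octave_index=R,
        observed_octave_counts=S,
        mode=mode,
        width=sigma,
        height=height,
        observed_richness=len(x),
        extrapolated_richness=float(extrap),
        coverage=float(len(x) / extrap),
        method=method,
    )


def tukey_hsd(values, group_labels) -> pd.DataFrame:
    """All-pairs Tukey HSD on untransformed values.

    Returns a long-format frame (group1, group2, mean_diff, p_adj) with
    p-values from the studentized-range distribution.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    groups = sorted(pd.unique(labels).tolist())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [values[labels == g] for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs at least 2 observations")
    if np.allclose(np.concatenate(arrays), np.concatenate(arrays)[0]):
        raise ValueError("degenerate data: zero variance overall")
    res = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            rows.append(
                (
                    groups[i],
                    groups[j],
                    float(np.mean(arrays[i]) - np.mean(arrays[j])),
                    float(res.pvalue[i, j]),
                )
            )
    return pd.DataFrame(rows, columns=["group1", "group2", "mean_diff", "p_adj"])
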