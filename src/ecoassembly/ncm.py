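"""Sloan neutral community model: occupancy–abundance fit.

The model predicts how often a taxon is detected across local communities
(occupancy) from its mean relative abundance ``p`` in the metacommunity,
assuming purely neutral birth–death dynamics with immigration.  Local
relative abundance follows a beta distribution whose concentration is the
dispersal number ``I`` (written ``N·m`` in the usual parameterisation):

    freq(p) = 1 − BetaCDF(d; I·p, I·(1−p)),    d = 1/N

where ``N`` is the local community size (reads per sample on a rarefied
table) and ``d`` the detection limit.  ``I`` is the single free parameter,
estimated by bounded nonlinear least squares of observed against predicted
occupancy.

The migration rate is reported as the per-death immigration probability
``m = I / (N − 1 + I)``, the exact inversion of the Moran-process dispersal
number ``I = m(N−1)/(1−m)``; this is the probability that a dead individual
is replaced by an immigrant rather than a local birth, and is the quantity
the neutral simulator takes as ground truth.  The classical composite
``I/N`` (which approximates ``m`` only when ``m`` is small) is exposed as
``m_sloan``.  High ``R²`` means the occupancy–abundance cloud is consistent
with neutral assembly; OTUs above (below) the prediction's 95% band are
detected more (less) often than neutrality explains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import OtuTable


@dataclass
class NCMFit:
    m: float  # immigration probability, I/(N-1+I)
    I: float  # dispersal number (the fitted N·m composite)
    N: int
    d: float
    r_squared: float
    m_ci: tuple  # bootstrap 95% interval on m (lo, hi)
    otus: pd.DataFrame  # p, freq, predicted, lower, upper, label
    n_samples: int

    @property
    def m_sloan(self) -> float:
        """Classical ``I/N`` composite (valid approximation of m for small m)."""
        return self.I / self.N

    @property
    def neutral_fraction(self) -> float:
        return float((self.otus["label"] == "neutral").mean())


def predicted_frequency(p, N: int, m: float, d: float | None = None) -> np.ndarray:
    """Neutral occupancy prediction 1 − BetaCDF(d; Nmp, Nm(1−p)).

    ``m`` here is the composite (Sloan) scale, i.e. ``N·m`` is the
    dispersal number.
    """
    p = np.asarray(p, dtype=float)
    if d is None:
        d = 1.0 / N
    a = N * m * p
    b = N * m * (1.0 - p)
    return stats.beta.sf(d, a, b)


def _predicted_from_I(p, I, d):
    p = np.asarray(p, dtype=float)
    return stats.beta.sf(d, I * p, I * (1.0 - p))


def wilson_interval(freq, n: int, alpha: float = 0.05):
    """Wilson score interval for a proportion ``freq`` observed over ``n`` trials."""
    freq = np.asarray(freq, dtype=float)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    denom = 1.0 + z**2 / n
    center = (freq + z**2 / (2 * n)) / denom
    half = z * np.sqrt(freq * (1 - freq) / n + z**2 / (4 * n**2)) / denom
    return np.clip(center - half, 0.0, 1.0), np.clip(center + half, 0.0, 1.0)


def _fit_I(p, freq, d, starts=(10.0, 100.0, 1000.0)):
    """Least-squares fit of the dispersal number, optimised on a log scale."""
    best = None
    for I0 in starts:
        res = optimize.least_squares(
            lambda th: _predicted_from_I(p, np.exp(th[0]), d) - freq,
            x0=[np.log(I0)],
            bounds=([-7.0], [25.0]),
        )
        if best is None or res.cost < best.cost:
            best = res
    return float(np.exp(best.x[0]))


def fit_ncm(table: OtuTable, n_boot: int = 1000, seed=None) -> NCMFit:
    """Fit the neutral model to a rarefied OTU table.

    ``p_i`` is the mean relative abundance of OTU ``i`` across samples and
    ``freq_i`` the fraction of samples where it is detected.  ``N`` is the
    (equal) per-sample read depth; OTUs with ``p_i`` below the detection
    limit ``d = 1/N`` are excluded (the prediction is degenerate there).
    The 95% CI for ``m`` comes from ``n_boot`` bootstrap resamples of OTUs.
    """
    sums = table.sample_sums().to_numpy()
    if not np.all(sums == sums[0]):
        raise ValueError("fit_ncm requires a rarefied table (equal sample sums)")
    if table.n_otus < 20:
        raise ValueError("need at least 20 OTUs")
    N = int(sums[0])
    d = 1.0 / N
    mat = table.matrix
    n_samples = mat.shape[0]
    p = (mat / N).mean(axis=0)
    freq = (mat > 0).mean(axis=0)
    keep = p >= d
    otu_ids = np.asarray(table.otu_ids)[keep]
    p, freq = p[keep], freq[keep]
    if np.allclose(freq, 1.0):
        raise ValueError(
            "all OTUs occur in every sample; no occupancy variation to fit "
            "(use a larger or more uneven species pool)"
        )

    I_hat = _fit_I(p, freq, d)
    m_hat = I_hat / (N - 1 + I_hat)
    pred = _predicted_from_I(p, I_hat, d)
    sse = float(np.sum((freq - pred) ** 2))
    sstot = float(np.sum((freq - freq.mean()) ** 2))
    r2 = 1.0 - sse / sstot

    rng = np.random.default_rng(seed)
    n = len(p)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        I_b = _fit_I(p[idx], freq[idx], d, starts=(I_hat,))
        boots.append(I_b / (N - 1 + I_b))
    lo, hi = (np.quantile(boots, [0.025, 0.975]) if boots else (np.nan, np.nan))

    lower, upper = wilson_interval(pred, n_samples)
    eps = 1e-9  # floating-point guard at the band edges
    label = np.where(
        freq > upper + eps, "above", np.where(freq < lower - eps, "below", "neutral")
    )
    otus = pd.DataFrame(
        {
            "p": p,
            "freq": freq,
            "predicted": pred,
            "lower": lower,
            "upper": upper,
            "label": label,
        },
        index=pd.Index(otu_ids, name="otu_id"),
    )
    return NCMFit(
        m=m_hat,
        I=I_hat,
        N=N,
        d=d,
        r_squared=r2,
        m_ci=(float(lo), float(hi)),
        otus=otus,
        n_samples=n_samples,
    )


def ncm_partition(fit: NCMFit) -> pd.Series:
    """Per-OTU neutrality label (above / neutral / below the 95% band)."""
    return fit.otus["label"]
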