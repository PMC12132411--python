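"""Composition-recovery metrics and naive baseline imputers.

Fifteen metrics in three categories compare an estimated composition
matrix with the ground truth: (i) overall similarity (mean squared error,
mean sample-wise and taxon-wise Euclidean distance); (ii) preservation of
sample-wise summaries (Shannon and Simpson indices, Bray-Curtis, KL,
Jensen-Shannon and Hellinger divergences per sample); (iii) preservation of
taxon-wise summaries (Gini coefficient, per-taxon mean/sd pairs,
coefficient of variation, Kolmogorov-Smirnov and Wasserstein distances of
per-taxon abundance distributions, and the taxon-taxon correlation
structure).  Smaller is better for all fifteen; all are zero when the two
matrices coincide.  The exact aggregation rules (documented per function)
are this package's own fixed definitions.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy import stats
from scipy.spatial.distance import braycurtis, jensenshannon

from .types import BMDDError, Composition, CountTable

_EPS = 1e-12

CATEGORIES = {
    "mse": "similarity",
    "sample_distance": "similarity",
    "taxon_distance": "similarity",
    "shannon": "sample-wise",
    "simpson": "sample-wise",
    "bray_curtis": "sample-wise",
    "kl": "sample-wise",
    "js": "sample-wise",
    "hellinger": "sample-wise",
    "gini": "taxon-wise",
    "mean_sd": "taxon-wise",
    "cv": "taxon-wise",
    "ks": "taxon-wise",
    "wasserstein": "taxon-wise",
    "correlation": "taxon-wise",
}


@dataclass
class MetricReport:
    mse: float
    sample_distance: float
    taxon_distance: float
    shannon: float
    simpson: float
    bray_curtis: float
    kl: float
    js: float
    hellinger: float
    gini: float
    mean_sd: float
    cv: float
    ks: float
    wasserstein: float
    correlation: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def naive_impute(table: CountTable, variant: int) -> Composition:
    """Pseudocount-style baseline imputers.

    variant 1: row-normalised counts, zeros kept (do nothing).
    variant 2: add a pseudocount of 1 to every count, then normalise.
    variant 3: replace zero counts by 0.5, then normalise.
    variant 4: replace a zero count at (i, j) by ``N_i / max{N_k : W_kj = 0}``
    (the sample's depth over the largest depth at which the taxon was still
    missed), then normalise; taxa without zeros are untouched.
    """
    W = table.counts.astype(float)
    N = table.depths.astype(float)
    if variant == 1:
        V = W
    elif variant == 2:
        V = W + 1.0
    elif variant == 3:
        V = np.where(W == 0, 0.5, W)
    elif variant == 4:
        V = W.copy()
        for j in range(table.n_taxa):
            zero = W[:, j] == 0
            if zero.any():
                V[zero, j] = N[zero] / N[zero].max()
    else:
        raise BMDDError("naive variant must be 1, 2, 3 or 4")
    values = V / V.sum(axis=1, keepdims=True)
    return Composition(
        values=values, sample_ids=table.sample_ids, taxon_ids=table.taxon_ids
    )


# --- per-row / per-column summaries ---------------------------------------


def _shannon(rows: np.ndarray) -> np.ndarray:
    from scipy.special import xlogy

    return -xlogy(rows, rows).sum(axis=1)


def _simpson(rows: np.ndarray) -> np.ndarray:
    return 1.0 - (rows**2).sum(axis=1)


def _gini(rows: np.ndarray) -> np.ndarray:
    """Gini coefficient of each row's abundance vector."""
    x = np.sort(rows, axis=1)
    m = x.shape[1]
    ranks = np.arange(1, m + 1)
    total = x.sum(axis=1)
    return (2 * (ranks * x).sum(axis=1) / (m * total)) - (m + 1) / m


def _hellinger(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    return np.sqrt(0.5 * ((np.sqrt(p) - np.sqrt(q)) ** 2).sum(axis=1))


def _kl(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """KL(p || q) per row with a small-epsilon guard on both arguments."""
    p = p + _EPS
    q = q + _EPS
    p = p / p.sum(axis=1, keepdims=True)
    q = q / q.sum(axis=1, keepdims=True)
    return (p * np.log(p / q)).sum(axis=1)


def _ks_stat(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample KS statistic between 1-D arrays (exact, sorted merge)."""
    a = np.sort(a)
    b = np.sort(b)
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, grid, side="right") / a.size
    cdf_b = np.searchsorted(b, grid, side="right") / b.size
    return float(np.abs(cdf_a - cdf_b).max())


def evaluate_all(estimated: Composition, truth: Composition) -> MetricReport:
    """All fifteen recovery metrics between an estimate and the truth.

    Sample-wise divergences are averaged over samples (KL uses the truth as
    the reference distribution; JS is the base-2 divergence, bounded by 1).
    Taxon-wise distribution distances (KS, Wasserstein) compare each
    taxon's abundance values across samples.  ``mean_sd`` is the Euclidean
    distance between the concatenated per-taxon (mean, sd) vectors, and
    ``correlation`` the mean absolute difference between the upper
    triangles of the taxon-taxon Pearson correlation matrices (constant
    taxa contribute correlation 0).
    """
    if estimated.values.shape != truth.values.shape:
        raise BMDDError("estimated and true compositions differ in shape")
    E, T = estimated.values, truth.values
    n, m = E.shape

    mse = float(((E - T) ** 2).mean())
    sample_distance = float(np.linalg.norm(E - T, axis=1).mean())
    taxon_distance = float(np.linalg.norm(E - T, axis=0).mean())

    shannon = float(np.abs(_shannon(E) - _shannon(T)).mean())
    simpson = float(np.abs(_simpson(E) - _simpson(T)).mean())
    bray = float(np.mean([braycurtis(E[i], T[i]) for i in range(n)]))
    kl = float(_kl(T, E).mean())
    js = float(np.mean([jensenshannon(E[i], T[i], base=2) ** 2 for i in range(n)]))
    hell = float(_hellinger(E, T).mean())

    gini = float(np.abs(_gini(E) - _gini(T)).mean())
    mean_sd = float(
        np.linalg.norm(
            np.concatenate([E.mean(axis=0) - T.mean(axis=0),
                            E.std(axis=0) - T.std(axis=0)])
        )
    )
    cv_e = E.std(axis=0) / np.maximum(E.mean(axis=0), _EPS)
    cv_t = T.std(axis=0) / np.maximum(T.mean(axis=0), _EPS)
    cv = float(np.abs(cv_e - cv_t).mean())
    ks = float(np.mean([_ks_stat(E[:, j], T[:, j]) for j in range(m)]))
    wass = float(
        np.mean([stats.wasserstein_distance(E[:, j], T[:, j]) for j in range(m)])
    )

    if m >= 2 and n >= 2:
        iu = np.triu_indices(m, k=1)
        corr = float(
            np.abs(_safe_corr(E)[iu] - _safe_corr(T)[iu]).mean()
        )
    else:
        corr = 0.0

    return MetricReport(
        mse=mse,
        sample_distance=sample_distance,
        taxon_distance=taxon_distance,
        shannon=shannon,
        simpson=simpson,
        bray_curtis=bray,
        kl=kl,
        js=js,
        hellinger=hell,
        gini=gini,
        mean_sd=mean_sd,
        cv=cv,
        ks=ks,
        wasserstein=wass,
        correlation=corr,
    )


def _safe_corr(X: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix with constant columns mapped to 0."""
    sd = X.std(axis=0)
    ok = sd > 0
    C = np.zeros((X.shape[1], X.shape[1]))
    if ok.sum() >= 2:
        C_ok = np.corrcoef(X[:, ok], rowvar=False)
        C[np.ix_(ok, ok)] = C_ok
    np.fill_diagonal(C, 1.0)
    return C
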