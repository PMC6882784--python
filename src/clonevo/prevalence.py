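"""Cancer cell prevalence estimation and mutation clustering.

For a mutation with multiplicity ``m`` (mutated copies per cancer cell) in
a genomic segment with tumor copy number ``CN_T`` and normal copy number
``CN_N``, in a sample of purity ``p``, the expected variant allele
frequency of a mutation carried by a fraction ``C`` of cancer cells is

    v_exp = p * m * C / (p * CN_T + (1 - p) * CN_N)

The variant read count is modeled as Binomial(r_tot, v_exp).  Prevalence is
estimated by evaluating this likelihood on a grid of C values from 0 to 1
in steps of 0.01 and normalizing (a discrete posterior under a flat prior);
the grid argmax is the point estimate and the central 95% mass gives an
interval.  Multiplicity is deduced where possible (m = 1 is the only
option at CN_T in {1, 2}; at higher copy number, values of m whose implied
raw prevalence exceeds 1 are ruled out) and treated as missing otherwise.
Mutations are then clustered across tumor regions by their prevalence
vectors with DBSCAN (silhouette-selected radius), falling back to affinity
propagation when no high-quality density solution exists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import DBSCAN, AffinityPropagation
from sklearn.metrics import silhouette_score

__all__ = [
    "PrevalenceEstimate",
    "MutationCluster",
    "expected_vaf",
    "prevalence_posterior",
    "resolve_multiplicity",
    "exclude_low_vaf_regions",
    "cluster_by_prevalence",
]

GRID = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)


def expected_vaf(p: float, m: int, C: float, cn_t: int, cn_n: int = 2) -> float:
    """Expected variant allele frequency of a subclonal mutation.

    Parameters
    ----------
    p : tumor purity in (0, 1].
    m : multiplicity, number of mutated copies per cancer cell, 1 <= m <= CN_T.
    C : cancer cell prevalence in [0, 1].
    cn_t, cn_n : integer copy number of the locus in tumor and normal cells.
    """
    if not 0 < p <= 1:
        raise ValueError(f"purity must be in (0, 1], got {p}")
    if cn_t == 0:
        raise ValueError("CN_T = 0: a mutation cannot reside in a deleted locus")
    if not 1 <= m <= cn_t:
        raise ValueError(f"multiplicity {m} outside [1, CN_T={cn_t}]")
    if not 0 <= C <= 1:
        raise ValueError(f"prevalence must be in [0, 1], got {C}")
    return p * m * C / (p * cn_t + (1 - p) * cn_n)


@dataclass
class PrevalenceEstimate:
    """Grid posterior over cancer cell prevalence for one mutation/region."""

    grid: np.ndarray
    posterior: np.ndarray
    point: float
    ci_low: float
    ci_high: float
    missing: bool = False
    multiplicity: int | None = None


def prevalence_posterior(
    r_a: int,
    r_tot: int,
    p: float,
    cn_t: int,
    cn_n: int = 2,
    m: int = 1,
    ci_level: float = 0.95,
) -> PrevalenceEstimate:
    """Grid likelihood of cancer cell prevalence given allelic read counts.

    Weights Binomial(r_tot, v_exp(C)) over C in {0, 0.01, ..., 1}, normalizes,
    and reports the argmax and the central ``ci_level`` interval of the
    normalized mass (expanded, if necessary, to contain the point estimate).
    """
    if r_a > r_tot:
        raise ValueError("variant reads exceed total reads")
    v = np.array([expected_vaf(p, m, c, cn_t, cn_n) for c in GRID])
    with np.errstate(divide="ignore"):
        logw = stats.binom.logpmf(r_a, r_tot, v)
    finite = np.isfinite(logw)
    if not finite.any():
        raise ValueError(
            f"all grid weights are zero (r_a={r_a}, r_tot={r_tot}, p={p}, "
            f"CN_T={cn_t}, m={m}); counts incompatible with the model"
        )
    logw = logw - logw[finite].max()
    w = np.where(finite, np.exp(logw), 0.0)
    post = w / w.sum()
    point = float(GRID[int(np.argmax(post))])
    cdf = np.cumsum(post)
    alpha = (1 - ci_level) / 2
    lo = float(GRID[int(np.searchsorted(cdf, alpha))])
    hi = float(GRID[int(np.searchsorted(cdf, 1 - alpha))])
    lo, hi = min(lo, point), max(hi, point)
    return PrevalenceEstimate(GRID.copy(), post, point, lo, hi, multiplicity=m)


def resolve_multiplicity(
    r_a: int,
    r_tot: int,
    p: float,
    cn_t: int,
    cn_n: int = 2,
    tolerance: float = 0.05,
) -> PrevalenceEstimate:
    """Deduce multiplicity where possible and return the prevalence estimate.

    At CN_T in {1, 2} only m = 1 is plausible.  In gained segments every
    m in [1, CN_T] is enumerated and values whose implied raw prevalence
    ``vaf * (p*CN_T + (1-p)*CN_N) / (p*m)`` exceeds ``1 + tolerance`` are
    ruled out; if more than one m survives, the prevalence is reported as
    missing.  A mutation with zero variant reads has prevalence 0 for any m.
    """
    if cn_t < 1:
        raise ValueError("CN_T must be >= 1 to resolve multiplicity")
    if r_a == 0:
        est = prevalence_posterior(0, r_tot, p, cn_t, cn_n, m=1)
        est.multiplicity = None if cn_t > 2 else 1
        return est
    if cn_t <= 2:
        return prevalence_posterior(r_a, r_tot, p, cn_t, cn_n, m=1)

    vaf = r_a / r_tot
    denom = p * cn_t + (1 - p) * cn_n
    plausible = [
        m for m in range(1, cn_t + 1) if vaf * denom / (p * m) <= 1 + tolerance
    ]
    if len(plausible) == 1:
        return prevalence_posterior(r_a, r_tot, p, cn_t, cn_n, m=plausible[0])
    est = PrevalenceEstimate(
        GRID.copy(), np.full_like(GRID, np.nan), np.nan, np.nan, np.nan, missing=True
    )
    return est


def exclude_low_vaf_regions(
    mutations: pd.DataFrame,
    regions: list[str],
    regions_with_cn: set[str] | None = None,
    max_vaf_cut: float = 0.02,
) -> list[str]:
    """Select tumor regions usable for prevalence analysis.

    A region is dropped when the maximum VAF over all mutations is at or
    below ``max_vaf_cut`` (the sample carries too little tumor signal) or
    when it lacks a copy-number profile.  ``mutations`` must carry columns
    ``var_<region>`` and ``tot_<region>``.
    """
    kept = []
    for r in regions:
        if regions_with_cn is not None and r not in regions_with_cn:
            continue
        tot = mutations[f"tot_{r}"].to_numpy(dtype=float)
        var = mutations[f"var_{r}"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            vaf = np.where(tot > 0, var / tot, 0.0)
        if len(vaf) and np.nanmax(vaf) > max_vaf_cut:
            kept.append(r)
    return kept


@dataclass
class MutationCluster:
    """A group of mutations sharing cancer cell prevalence across regions."""

    cluster_id: int
    members: list = field(default_factory=list)
    mean: np.ndarray = None  # per-region mean prevalence
    sd: np.ndarray = None  # per-region prevalence sd


def _dbscan_sweep(X, eps_grid, min_samples, max_noise_frac, min_silhouette):
    best = None
    for eps in eps_grid:
        labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(X)
        core = labels >= 0
        n_clusters = len(set(labels[core]))
        if n_clusters < 2 or (~core).mean() > max_noise_frac:
            continue
        if n_clusters >= core.sum():
            continue
        sil = silhouette_score(X[core], labels[core])
        if sil < min_silhouette:
            continue
        if best is None or sil > best[0] + 1e-12:
            best = (sil, labels)
    return best


def cluster_by_prevalence(
    prevalence: np.ndarray,
    mutation_ids=None,
    seed: int = 0,
    eps_grid=None,
    min_samples: int = 2,
    min_silhouette: float = 0.25,
    max_noise_frac: float = 0.20,
) -> list[MutationCluster]:
    """Cluster mutations by their per-region prevalence vectors.

    DBSCAN is run over a sweep of neighborhood radii (default 0.02-0.30 in
    steps of 0.02) and the radius with the best silhouette coefficient is
    kept, provided the solution passes quality gates (silhouette >= 0.25,
    at most 20% of points labeled noise); residual noise points are
    attached to the nearest cluster centroid.  When no density solution
    qualifies, affinity propagation provides the grouping.  Rows containing
    missing (NaN) prevalence are clustered on the regions shared by all
    mutations if at least one exists, otherwise excluded and returned as
    singleton clusters with id -1.
    """
    X_full = np.asarray(prevalence, dtype=float)
    if X_full.ndim == 1:
        X_full = X_full[:, None]
    n = X_full.shape[0]
    if mutation_ids is None:
        mutation_ids = list(range(n))
    if eps_grid is None:
        eps_grid = np.round(np.arange(0.02, 0.30 + 1e-9, 0.02), 2)

    shared_cols = ~np.isnan(X_full).any(axis=0)
    if shared_cols.any():
        usable = np.ones(n, dtype=bool)
        X = X_full[:, shared_cols]
    else:
        usable = ~np.isnan(X_full).any(axis=1)
        X = X_full[usable]
    idx = np.flatnonzero(usable)

    if usable.sum() < 2:
        warnings.warn("fewer than 2 usable mutations; returning one cluster")
        labels = np.zeros(usable.sum(), dtype=int)
    elif np.allclose(X, X[0], atol=1e-12):
        labels = np.zeros(X.shape[0], dtype=int)
    else:
        best = _dbscan_sweep(X, eps_grid, min_samples, max_noise_frac, min_silhouette)
        if best is not None:
            labels = best[1].copy()
            if (labels < 0).any():
                cents = np.stack(
                    [X[labels == k].mean(axis=0) for k in sorted(set(labels[labels >= 0]))]
                )
                ks = sorted(set(labels[labels >= 0]))
                for i in np.flatnonzero(labels < 0):
                    labels[i] = ks[int(np.argmin(np.linalg.norm(cents - X[i], axis=1)))]
        else:
            ap = AffinityPropagation(random_state=int(seed) % (2**31), damping=0.9)
            labels = ap.fit_predict(X)
            if (labels < 0).any():  # AP failed to converge on all points
                labels = np.zeros(X.shape[0], dtype=int)

    clusters: list[MutationCluster] = []
    for new_id, k in enumerate(sorted(set(labels))):
        sel = idx[labels == k]
        Xi = X_full[sel]
        clusters.append(
            MutationCluster(
                cluster_id=new_id,
                members=[mutation_ids[i] for i in sel],
                mean=np.nanmean(Xi, axis=0),
                sd=np.nanstd(Xi, axis=0, ddof=1) if len(sel) > 1 else np.zeros(X_full.shape[1]),
            )
        )
    for i in np.flatnonzero(~usable):
        clusters.append(
            MutationCluster(
                cluster_id=-1,
                members=[mutation_ids[i]],
                mean=X_full[i],
                sd=np.zeros(X_full.shape[1]),
            )
        )
    return clusters
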