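"""Multiscale bootstrap cluster support (approximately unbiased p-values).

Genes are clustered by correlation dissimilarity (d = 1 - r) with
average linkage.  For each scale r the samples (columns) are resampled
with replacement to round(r * n) columns, the dendrogram is rebuilt, and
every internal-node cluster of the ORIGINAL dendrogram is counted when a
replicate dendrogram contains exactly the same member set.  The
per-scale bootstrap probabilities BP_r = count / n_boot are then probit
transformed, z_r = Phi^-1(1 - BP_r), and fitted against the model

    z_r = v / sigma_r + c * sigma_r,     sigma_r = sqrt(1 / r),

by weighted least squares (weights = inverse delta-method variance of
z_r under binomial counts).  The signed distance v and curvature c give

    AU = 1 - Phi(v - c),        BP(sigma=1) = 1 - Phi(v + c).

AU corrects the naive bootstrap probability for the curvature of the
cluster-hypothesis boundary; clusters with AU >= 0.95 (and at least
min_size genes) are called significant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import norm
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = [
    "BootstrapProfile",
    "MultiscaleBootstrapAU",
    "multiscale_bootstrap",
    "fit_au",
    "significant_modules",
]

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.45, 0.1), 1))  # 0.5 .. 1.4


@dataclass
class BootstrapProfile:
    """Per-cluster multiscale bootstrap record and fitted AU/BP values."""

    cluster_id: int
    members: frozenset
    scales: tuple
    counts: np.ndarray
    n_boot: int
    v: float = np.nan
    c: float = np.nan
    au: float = np.nan
    bp: float = np.nan
    fit_residual: float = np.nan
    saturated: bool = False
    significant: bool = False

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def bp_per_scale(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float) / self.n_boot


def _correlation_condensed(values: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distance between rows, NaN-safe for constant rows."""
    with np.errstate(invalid="ignore", divide="ignore"):
        cor = np.corrcoef(values)
    cor = np.nan_to_num(cor, nan=0.0)
    np.fill_diagonal(cor, 1.0)
    d = 1.0 - np.clip(cor, -1.0, 1.0)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return squareform(d, checks=False)


def _cluster_sets(link: np.ndarray, n_leaves: int) -> list[frozenset]:
    """Member sets of each internal node of a scipy linkage, in merge order."""
    sets: list[frozenset] = []
    lookup: dict[int, frozenset] = {i: frozenset((i,)) for i in range(n_leaves)}
    for step, (a, b, _, _) in enumerate(link):
        merged = lookup[int(a)] | lookup[int(b)]
        lookup[n_leaves + step] = merged
        sets.append(merged)
    return sets


def _dendrogram_sets(values: np.ndarray, method: str = "average") -> set[frozenset]:
    link = linkage(_correlation_condensed(values), method=method)
    return set(_cluster_sets(link, values.shape[0]))


def multiscale_bootstrap(
    dataset: pd.DataFrame,
    scales=DEFAULT_SCALES,
    n_boot: int = 1000,
    seed: int = 0,
    linkage_method: str = "average",
) -> list[BootstrapProfile]:
    """Count original-dendrogram clusters across bootstrap replicates.

    Scales for which round(r * n_samples) < 3 are dropped with a
    warning.  Deterministic given the seed.
    """
    est = MultiscaleBootstrapAU(
        scales=tuple(scales), n_boot=n_boot, random_state=seed, linkage_method=linkage_method
    )
    est.fit(dataset)
    return est.profiles_


def fit_au(
    profile: BootstrapProfile,
    min_usable_scales: int = 2,
    clip_boundary: bool = False,
) -> BootstrapProfile:
    """Fit (v, c) to a profile's BP curve and fill au/bp in place.

    Scales whose count sits on the boundary (0 or n_boot) carry no
    information about the curve's shape and are dropped from the fit by
    default; a cluster left with fewer than ``min_usable_scales``
    non-degenerate scales short-circuits to the majority saturation rule
    (au = 1 when the cluster is present in at least half the replicates
    overall, au = 0 otherwise) with the saturation flag set.  With
    ``clip_boundary`` the boundary counts are instead clipped by
    0.5/n_boot (continuity correction) and kept in the fit.
    """
    counts = np.asarray(profile.counts, dtype=float)
    scales = np.asarray(profile.scales, dtype=float)
    n_boot = profile.n_boot
    degenerate = (counts >= n_boot) | (counts <= 0)
    usable = ~degenerate if not clip_boundary else np.ones_like(degenerate, dtype=bool)
    if degenerate.all() or usable.sum() < min_usable_scales:
        profile.saturated = True
        profile.au = 1.0 if counts.mean() >= n_boot / 2 else 0.0
        profile.bp = profile.au
        profile.v, profile.c, profile.fit_residual = np.nan, np.nan, 0.0
        return profile
    eps = 0.5 / n_boot
    bp = np.clip(counts[usable] / n_boot, eps, 1.0 - eps)
    sigma = np.sqrt(1.0 / scales[usable])
    z = norm.ppf(1.0 - bp)
    # delta-method variance of z under binomial counts: bp(1-bp)/(n * phi(z)^2)
    var_z = bp * (1.0 - bp) / (n_boot * norm.pdf(z) ** 2)
    w = 1.0 / var_z
    design = np.column_stack([1.0 / sigma, sigma])
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(design * sw[:, None], z * sw, rcond=None)
    v, c = float(coef[0]), float(coef[1])
    resid = z - design @ coef
    profile.v, profile.c = v, c
    profile.au = float(1.0 - norm.cdf(v - c))
    profile.bp = float(1.0 - norm.cdf(v + c))
    profile.fit_residual = float(np.sqrt(np.average(resid**2, weights=w)))
    return profile


def significant_modules(
    profiles: list[BootstrapProfile],
    threshold: float = 0.95,
    min_size: int = 3,
    maximal_only: bool = False,
) -> list[BootstrapProfile]:
    """Clusters with au >= threshold and >= min_size members, outermost first.

    By convention nested significant clusters are all reported; with
    ``maximal_only`` clusters contained in another significant cluster
    are dropped.
    """
    hits = [
        p for p in profiles
        if np.isfinite(p.au) and p.au >= threshold and p.size >= min_size
    ]
    hits.sort(key=lambda p: (-p.size, p.cluster_id))
    for p in hits:
        p.significant = True
    if maximal_only:
        kept: list[BootstrapProfile] = []
        for p in hits:
            if not any(p.members < q.members for q in kept):
                kept.append(p)
        hits = kept
    return hits


class MultiscaleBootstrapAU(BaseEstimator):
    """Multiscale bootstrap AU p-values for a gene dendrogram.

    Parameters
    ----------
    scales : tuple of float, default=(0.5, ..., 1.4)
        Resample-size multipliers r; round(r * n_samples) columns are
        drawn with replacement per replicate.
    n_boot : int, default=1000
        Replicates per scale (>= 100 recommended; >= 20 enforced).
    threshold : float, default=0.95
        AU significance threshold.
    min_size : int, default=3
        Minimum member count for a significant module.
    linkage_method : str, default="average"
    random_state : int, default=0

    Attributes
    ----------
    linkage_ : ndarray, scipy linkage of the original dendrogram.
    profiles_ : list of BootstrapProfile, one per internal node.
    report_ : DataFrame summary (size, per-scale BP, v, c, au, bp, flags).
    significant_ : list of significant BootstrapProfile (outermost first).
    """

    def __init__(self, scales=DEFAULT_SCALES, n_boot: int = 1000, threshold: float = 0.95,
                 min_size: int = 3, linkage_method: str = "average", random_state: int = 0):
        self.scales = scales
        self.n_boot = n_boot
        self.threshold = threshold
        self.min_size = min_size
        self.linkage_method = linkage_method
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None):
        if self.n_boot < 20:
            raise ValueError(f"n_boot must be >= 20, got {self.n_boot}")
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        values = np.asarray(X, dtype=float)
        n_genes, n_samples = values.shape
        scales = [float(s) for s in self.scales]
        if any(s <= 0 for s in scales):
            raise ValueError("scales must all be > 0")
        usable = []
        for s in scales:
            if round(s * n_samples) < 3:
                warnings.warn(f"scale {s} yields fewer than 3 samples; dropped")
            else:
                usable.append(s)
        if len(usable) < 2:
            raise ValueError("fewer than 2 usable scales")
        self.gene_ids_ = list(X.index)
        self.linkage_ = linkage(_correlation_condensed(values), method=self.linkage_method)
        original = _cluster_sets(self.linkage_, n_genes)
        counts = np.zeros((len(original), len(usable)), dtype=int)
        rng = np.random.default_rng(self.random_state)
        for j, s in enumerate(usable):
            n_sub = round(s * n_samples)
            for _ in range(self.n_boot):
                cols = rng.integers(0, n_samples, size=n_sub)
                replicate = _dendrogram_sets(values[:, cols], self.linkage_method)
                for i, cl in enumerate(original):
                    if cl in replicate:
                        counts[i, j] += 1
        self.profiles_ = [
            fit_au(BootstrapProfile(
                cluster_id=i,
                members=cl,
                scales=tuple(usable),
                counts=counts[i].copy(),
                n_boot=self.n_boot,
            ))
            for i, cl in enumerate(original)
        ]
        self.significant_ = significant_modules(
            self.profiles_, threshold=self.threshold, min_size=self.min_size
        )
        self.report_ = self._make_report()
        return self

    def _make_report(self) -> pd.DataFrame:
        rows = []
        for p in self.profiles_:
            row = {
                "cluster_id": p.cluster_id,
                "size": p.size,
                "members": ";".join(str(self.gene_ids_[i]) for i in sorted(p.members)),
                "v": p.v,
                "c": p.c,
                "au": p.au,
                "bp": p.bp,
                "fit_residual": p.fit_residual,
                "saturated": p.saturated,
                "significant": p.significant,
            }
            for s, b in zip(p.scales, p.bp_per_scale):
                row[f"bp_r{s:g}"] = b
            rows.append(row)
        return pd.DataFrame(rows).set_index("cluster_id")

    @property
    def n_candidate_modules_(self) -> int:
        """Internal nodes with at least min_size members (the candidate module pool)."""
        return sum(1 for p in self.profiles_ if p.size >= self.min_size)
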