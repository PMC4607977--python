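"""Permutation-based module preservation statistics (Zsummary, medianRank).

Given modules defined on a reference expression dataset, these statistics
quantify whether each module's density and connectivity patterns recur in
an independent test dataset.  Seven observed statistics are used:

density (computed on the test data for the reference-defined membership)
  - mean_cor            mean within-module off-diagonal correlation
  - mean_adj            mean within-module soft-thresholded adjacency
  - prop_var_explained  mean squared correlation with the module eigengene
  - mean_kme            mean eigengene-based connectivity (signed, oriented)

connectivity (agreement of per-gene patterns between reference and test)
  - cor_kim             cor of intramodular connectivity vectors
  - cor_kme             cor of eigengene-based connectivity vectors
  - cor_cor             cor of the vectorized within-module correlations

Each observed statistic is standardised against a permutation null,
Z = (observed - mean_null) / sd_null, built by drawing random gene sets
of the same size from an exchangeability pool.  The default pool is the
tested module's own genes plus the background (gray, unassigned) genes:
under the null hypothesis "this module is background-like" those genes
are exchangeable, and because the pool contains the observed set the
null draws share its conditional, realisation-specific structure (a
pool disjoint from the module under-disperses the null and inflates
|Z| for genuinely background gene sets).  ``null_pool="all"`` instead
draws from every gene, which mixes other modules' genes into the null
sets; their composition gradients (module genes have systematically
higher connectivity than gray genes in both halves) make the null
connectivity correlations structurally positive and can push Z negative
even for a perfectly preserved module.  Zdensity and Zconnectivity are the
medians of their groups and Zsummary their mean.  Zsummary > 10 indicates
strong preservation, 2-10 moderate, < 2 none; a zero-variance null or an
undefined statistic marks the module invalid (no Z can be formed).

The ``adjacency`` mode (for general, sign-free networks) keeps only
mean_adj and cor_kim.

medianRank complements Zsummary: modules are ranked per observed
statistic (rank 1 = most preserved), the density and connectivity ranks
are summarised by their medians, and medianRank is the mean of the two
medians.  Lower = more preserved; unlike Zsummary it is insensitive to
module size.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .partition import ModulePartition

logger = logging.getLogger(__name__)

__all__ = [
    "DENSITY_STATS",
    "CONNECTIVITY_STATS",
    "ModulePreservation",
    "module_preservation",
    "module_statistics",
    "median_rank",
]

DENSITY_STATS = ("mean_cor", "mean_adj", "prop_var_explained", "mean_kme")
CONNECTIVITY_STATS = ("cor_kim", "cor_kme", "cor_cor")
ADJACENCY_DENSITY_STATS = ("mean_adj",)
ADJACENCY_CONNECTIVITY_STATS = ("cor_kim",)

STRONG_THRESHOLD = 10.0
MODERATE_THRESHOLD = 2.0


def _standardize_rows(values: np.ndarray) -> np.ndarray:
    centred = values - values.mean(axis=1, keepdims=True)
    sd = centred.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return centred / sd


def _kme(z_sub: np.ndarray) -> np.ndarray:
    """Correlations of each gene with the module eigengene.

    The eigengene is the first right singular vector of the
    row-standardized module submatrix (= first principal component of the
    module's expression); its sign is oriented so the mean kME is >= 0.
    """
    _, _, vt = np.linalg.svd(z_sub, full_matrices=False)
    e = vt[0]
    ec = e - e.mean()
    norm_e = np.linalg.norm(ec)
    norms = np.linalg.norm(z_sub, axis=1)
    norms[norms == 0] = 1.0
    if norm_e == 0:
        return np.zeros(z_sub.shape[0])
    kme = (z_sub @ ec) / (norms * norm_e)
    if kme.sum() < 0:
        kme = -kme
    return kme


def _safe_cor(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


class _Prepared:
    """Precomputed correlation/adjacency/standardized matrices for speed."""

    def __init__(self, reference: pd.DataFrame, test: pd.DataFrame, beta: int, signed: bool):
        from .network import correlation_matrix, soft_threshold_adjacency

        self.gene_ids = list(reference.index)
        self.cor_ref = np.asarray(correlation_matrix(reference))
        self.cor_test = np.asarray(correlation_matrix(test))
        self.adj_ref = soft_threshold_adjacency(self.cor_ref, beta, signed).adjacency
        self.adj_test = soft_threshold_adjacency(self.cor_test, beta, signed).adjacency
        self.z_ref = _standardize_rows(np.asarray(reference, dtype=float))
        self.z_test = _standardize_rows(np.asarray(test, dtype=float))

    def statistics(self, idx: np.ndarray, mode: str = "correlation") -> dict:
        iu = np.triu_indices(idx.size, k=1)
        sub_cor_t = self.cor_test[np.ix_(idx, idx)]
        sub_adj_t = self.adj_test[np.ix_(idx, idx)]
        kim_ref = self.adj_ref[np.ix_(idx, idx)].sum(axis=0)
        kim_test = sub_adj_t.sum(axis=0)
        stats = {
            "mean_adj": float(sub_adj_t[iu].mean()) if iu[0].size else np.nan,
            "cor_kim": _safe_cor(kim_ref, kim_test),
        }
        if mode == "correlation":
            sub_cor_r = self.cor_ref[np.ix_(idx, idx)]
            kme_test = _kme(self.z_test[idx])
            kme_ref = _kme(self.z_ref[idx])
            stats.update(
                mean_cor=float(sub_cor_t[iu].mean()) if iu[0].size else np.nan,
                prop_var_explained=float(np.mean(kme_test**2)),
                mean_kme=float(np.mean(kme_test)),
                cor_kme=_safe_cor(kme_ref, kme_test),
                cor_cor=_safe_cor(sub_cor_r[iu], sub_cor_t[iu]),
            )
        return stats


def module_statistics(
    reference: pd.DataFrame,
    test: pd.DataFrame,
    genes,
    beta: int = 6,
    signed: bool = False,
    mode: str = "correlation",
) -> dict:
    """Observed preservation statistics for one gene set (no permutation)."""
    prep = _Prepared(reference, test, beta, signed)
    idx = np.array([prep.gene_ids.index(g) for g in genes])
    return prep.statistics(idx, mode=mode)


class ModulePreservation(BaseEstimator):
    """Permutation Zsummary/medianRank module preservation.

    Parameters
    ----------
    n_permutations : int, default=200
        Random same-size gene sets per module for the null (>= 50).
    mode : {"correlation", "adjacency"}, default="correlation"
        "correlation" uses all seven statistics; "adjacency" keeps only
        the sign-free mean_adj and cor_kim (for general networks).
    null_pool : {"gray", "all"}, default="gray"
        Pool the permutation gene sets are drawn from.  "gray" draws
        from the tested module's genes plus the unassigned genes (the
        exchangeability pool of the background-likeness null); "all"
        draws from every gene.
    modules : list of str or None, default=None
        Module labels to evaluate; None evaluates every non-gray module
        of the partition.
    beta, signed
        Soft-thresholding parameters used for the adjacency-based
        statistics; keep them equal to the detection settings.
    random_state : int, default=0
        Seed for the permutation draws; reports are deterministic given it.

    Attributes
    ----------
    report_ : DataFrame
        One row per non-gray module: size, observed statistics, per-
        statistic Z, Zdensity, Zconnectivity, Zsummary, medianRank
        columns, and preservation_class in {strong, moderate, none,
        invalid}.
    """

    def __init__(self, n_permutations: int = 200, mode: str = "correlation",
                 beta: int = 6, signed: bool = False, null_pool: str = "gray",
                 modules: list | None = None, random_state: int = 0):
        self.n_permutations = n_permutations
        self.mode = mode
        self.beta = beta
        self.signed = signed
        self.null_pool = null_pool
        self.modules = modules
        self.random_state = random_state

    def _stat_names(self):
        if self.mode == "adjacency":
            return ADJACENCY_DENSITY_STATS, ADJACENCY_CONNECTIVITY_STATS
        if self.mode == "correlation":
            return DENSITY_STATS, CONNECTIVITY_STATS
        raise ValueError(f"mode must be 'correlation' or 'adjacency', got {self.mode!r}")

    def fit(self, reference: pd.DataFrame, test: pd.DataFrame, partition: ModulePartition):
        if self.n_permutations < 50:
            raise ValueError(f"n_permutations must be >= 50, got {self.n_permutations}")
        if not reference.index.equals(test.index):
            raise ValueError("reference and test datasets must share gene ids in order")
        density_stats, connectivity_stats = self._stat_names()
        all_stats = list(density_stats) + list(connectivity_stats)
        if self.null_pool not in ("gray", "all"):
            raise ValueError(f"null_pool must be 'gray' or 'all', got {self.null_pool!r}")
        prep = _Prepared(reference, test, self.beta, self.signed)
        rng = np.random.default_rng(self.random_state)
        n_genes = len(prep.gene_ids)
        pos = {g: i for i, g in enumerate(prep.gene_ids)}
        gray_idx = np.array(
            [pos[g] for g in partition.gray_genes if g in pos], dtype=int
        )
        small_pool_modules: list[str] = []
        rows = []
        evaluate = partition.module_names if self.modules is None else list(self.modules)
        unknown = [m for m in evaluate if m not in partition.module_names]
        if unknown:
            raise ValueError(f"unknown module label(s): {unknown}")
        for label in evaluate:
            members = partition.members(label)
            idx = np.array([pos[g] for g in members])
            if self.null_pool == "gray":
                pool: np.ndarray | int = np.concatenate([idx, gray_idx])
                if gray_idx.size < idx.size:
                    small_pool_modules.append(label)
            else:
                pool = n_genes
            observed = prep.statistics(idx, mode=self.mode)
            null = {s: np.empty(self.n_permutations) for s in all_stats}
            for p in range(self.n_permutations):
                perm_idx = rng.choice(pool, size=idx.size, replace=False)
                perm_stats = prep.statistics(perm_idx, mode=self.mode)
                for s in all_stats:
                    null[s][p] = perm_stats[s]
            row = {"module": label, "module_size": int(idx.size)}
            invalid = False
            zs = {}
            for s in all_stats:
                obs = observed[s]
                nvals = null[s]
                finite = nvals[np.isfinite(nvals)]
                sd = finite.std(ddof=1) if finite.size > 1 else 0.0
                row[f"obs_{s}"] = obs
                row[f"null_mean_{s}"] = finite.mean() if finite.size else np.nan
                row[f"null_sd_{s}"] = sd
                if not np.isfinite(obs) or sd == 0 or finite.size < 2:
                    zs[s] = np.nan
                    invalid = True
                else:
                    zs[s] = (obs - finite.mean()) / sd
                row[f"Z_{s}"] = zs[s]
            z_density = float(np.median([zs[s] for s in density_stats]))
            z_connectivity = float(np.median([zs[s] for s in connectivity_stats]))
            z_summary = (z_density + z_connectivity) / 2.0
            row["Zdensity"] = z_density
            row["Zconnectivity"] = z_connectivity
            row["Zsummary"] = z_summary
            if invalid or not np.isfinite(z_summary):
                row["preservation_class"] = "invalid"
            elif z_summary > STRONG_THRESHOLD:
                row["preservation_class"] = "strong"
            elif z_summary >= MODERATE_THRESHOLD:
                row["preservation_class"] = "moderate"
            else:
                row["preservation_class"] = "none"
            rows.append(row)
        if small_pool_modules:
            logger.info(
                "gray pool (%d genes) smaller than %d module(s) (%s); "
                "their null sets overlap the module heavily",
                gray_idx.size, len(small_pool_modules), ", ".join(small_pool_modules),
            )
        report = pd.DataFrame(rows)
        if len(report):
            report = report.set_index("module")
            report = median_rank(report, density_stats, connectivity_stats)
        self.report_ = report
        return self

    @property
    def n_valid_(self) -> int:
        """Modules preserved at the moderate cutoff (Zsummary >= 2, valid class)."""
        r = self.report_
        if not len(r):
            return 0
        ok = r["preservation_class"].isin(["strong", "moderate"])
        return int(ok.sum())


def median_rank(report: pd.DataFrame, density_stats=DENSITY_STATS,
                connectivity_stats=CONNECTIVITY_STATS) -> pd.DataFrame:
    """Attach medianRank columns to a preservation report.

    Each observed statistic ranks the modules (rank 1 = largest observed
    value = most preserved; ties share the mean rank).  The density and
    connectivity medians are combined by their mean.  With a single
    module the ranks are defined but uninformative (flagged in a log
    message).
    """
    report = report.copy()
    if len(report) < 2:
        logger.warning("medianRank computed on %d module(s); uninformative", len(report))
    d_ranks = pd.DataFrame(
        {s: report[f"obs_{s}"].rank(ascending=False, method="average") for s in density_stats}
    )
    c_ranks = pd.DataFrame(
        {s: report[f"obs_{s}"].rank(ascending=False, method="average") for s in connectivity_stats}
    )
    report["medianRank_density"] = d_ranks.median(axis=1)
    report["medianRank_connectivity"] = c_ranks.median(axis=1)
    report["medianRank"] = (report["medianRank_density"] + report["medianRank_connectivity"]) / 2.0
    return report


def module_preservation(
    reference: pd.DataFrame,
    test: pd.DataFrame,
    partition: ModulePartition,
    n_perm: int = 200,
    seed: int = 0,
    mode: str = "correlation",
    beta: int = 6,
    signed: bool = False,
    null_pool: str = "gray",
) -> pd.DataFrame:
    """Functional wrapper around :class:`ModulePreservation`."""
    est = ModulePreservation(
        n_permutations=n_perm, mode=mode, beta=beta, signed=signed,
        null_pool=null_pool, random_state=seed,
    )
    return est.fit(reference, test, partition).report_
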