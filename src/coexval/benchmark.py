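"""Benchmark statistics for comparing module-validation approaches.

Three summary statistics compare validation methods across datasets:

- VSR (validation success ratio): the average percentage of valid
  (preserved or significant) modules over all modules, across datasets.
  Datasets on which no valid statistic could be obtained contribute a
  ratio of zero.
- FR (fluctuation ratio): the relative variability of the per-dataset
  valid-module ratio, computed as a coefficient of variation
  (100 * sample sd / mean).  Lower = more stable across datasets.
- VR (variation ratio): the mean relative change of a count (modules,
  gray genes, or valid modules) between a baseline run and perturbed
  re-runs: 100 * mean(|X_i - X0|) / X0.

The gray-area experiment driver perturbs the expression of the genes
left unassigned at baseline by a set of multiplicative levels, re-runs
module detection plus both validation methods with identical seeds, and
records the counts from which VR is computed.  Because Pearson
correlation is scale-invariant, any change must come from nonlinearity
of the clustering cut, not from the data's correlation structure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .bootstrap import MultiscaleBootstrapAU
from .config import RunConfig
from .graph_params import PARAMETER_NAMES, NetworkParameters, compute_network_parameters
from .network import TOMModuleDetector
from .partition import ModulePartition
from .preservation import ModulePreservation
from .simulate import perturb_gray_area, split_reference_test

logger = logging.getLogger(__name__)

__all__ = [
    "DatasetResult",
    "SimulationLevelResult",
    "DatasetAnalysis",
    "GrayAreaResult",
    "vsr",
    "fr",
    "vr",
    "analyze_dataset",
    "gray_area_experiment",
    "parameter_ratio_regression",
    "run_full_benchmark",
]


# ---------------------------------------------------------------------------
# result containers


@dataclass
class DatasetResult:
    """Valid-module count for one dataset under one validation method."""

    dataset_id: str
    method: str  # "zsummary" or "au"
    n_modules: int
    n_valid: int
    invalid_flag: bool = False

    @property
    def ratio(self) -> float:
        """Valid-module ratio R; NaN when no modules were detected."""
        if self.n_modules == 0:
            return math.nan
        return self.n_valid / self.n_modules

    def aggregated_ratio(self) -> float:
        """R as used in aggregation: invalid or empty datasets count as 0."""
        if self.invalid_flag or self.n_modules == 0:
            return 0.0
        return self.n_valid / self.n_modules


@dataclass
class SimulationLevelResult:
    """Counts recorded at one gray-area perturbation level for one method."""

    level: float
    n_modules: int
    n_valid: int
    n_gray: int | None = None  # topology pipeline only
    changed: bool = False


# ---------------------------------------------------------------------------
# the three benchmark statistics


def _ratios(results: list[DatasetResult]) -> np.ndarray:
    return np.array([r.aggregated_ratio() for r in results], dtype=float)


def vsr(results: list[DatasetResult], pooled: bool = False) -> float:
    """Validation success ratio (percent).

    Unweighted mean of per-dataset valid-module ratios, times 100.
    Invalid datasets contribute a ratio of 0.  With ``pooled`` the
    module counts are pooled across datasets instead (a flagged
    alternative reading; the default follows the per-dataset average).
    """
    if not results:
        raise ValueError("vsr requires at least one dataset result")
    if pooled:
        total = sum(r.n_modules for r in results if not r.invalid_flag)
        valid = sum(r.n_valid for r in results if not r.invalid_flag)
        return 100.0 * valid / total if total else math.nan
    return float(100.0 * _ratios(results).mean())


def fr(results: list[DatasetResult], plain_sd: bool = False) -> float:
    """Fluctuation ratio (percent): variability of the valid-module ratio.

    Coefficient of variation, 100 * sd(R) / mean(R), with the sample
    (n-1) standard deviation; invalid datasets contribute R = 0.  NaN
    when the mean ratio is 0.  ``plain_sd`` reports 100 * sd(R) instead.
    """
    if len(results) < 2:
        raise ValueError("fr requires at least two dataset results")
    r = _ratios(results)
    sd = float(np.std(r, ddof=1))
    if plain_sd:
        return 100.0 * sd
    mean = float(r.mean())
    if mean == 0:
        return math.nan
    return 100.0 * sd / mean


def vr(original: int, simulated) -> float:
    """Variation ratio (percent): mean relative change against baseline.

    VR = 100 * (1/n) * sum |X_i - X_original| / X_original.  NaN when
    the original count is 0 (undefined, not zero).
    """
    simulated = list(simulated)
    if not simulated:
        raise ValueError("vr requires at least one simulated count")
    if original == 0:
        return math.nan
    deltas = np.abs(np.asarray(simulated, dtype=float) - float(original))
    return float(100.0 * deltas.mean() / original)


# ---------------------------------------------------------------------------
# per-dataset analysis (detection + both validation methods)


@dataclass
class DatasetAnalysis:
    """Everything one pipeline pass produces for a single dataset."""

    dataset_id: str
    partition: ModulePartition
    preservation: pd.DataFrame
    n_modules_tba: int
    n_valid_tba: int
    n_gray_genes: int
    tba_invalid: bool
    n_modules_sba: int
    n_valid_sba: int
    network_parameters: NetworkParameters
    au_report: pd.DataFrame | None = None

    def dataset_results(self) -> list[DatasetResult]:
        return [
            DatasetResult(self.dataset_id, "zsummary", self.n_modules_tba,
                          self.n_valid_tba, invalid_flag=self.tba_invalid),
            DatasetResult(self.dataset_id, "au", self.n_modules_sba, self.n_valid_sba),
        ]


def analyze_dataset(
    data: pd.DataFrame,
    cfg: RunConfig,
    dataset_id: str = "dataset",
    keep_reports: bool = True,
) -> DatasetAnalysis:
    """Run detection plus both validation methods on one dataset.

    The samples are split into reference and test halves; modules are
    detected on the reference half; Zsummary preservation compares the
    reference-defined modules against the test half; AU support is
    computed on the full dataset's gene dendrogram.
    """
    reference, test = split_reference_test(data, mode=cfg.split_mode, seed=cfg.split_seed)
    detector = TOMModuleDetector(
        beta=cfg.beta, signed=cfg.signed, cut_height=cfg.cut_height, min_size=cfg.min_size
    ).fit(reference)
    partition = detector.partition_

    preserver = ModulePreservation(
        n_permutations=cfg.n_perm, mode=cfg.preservation_mode,
        beta=cfg.beta, signed=cfg.signed, random_state=cfg.permutation_seed,
    ).fit(reference, test, partition)
    report = preserver.report_
    n_modules_tba = partition.n_modules
    if len(report):
        valid_classes = report["preservation_class"].isin(["strong", "moderate"])
        n_valid_tba = int(valid_classes.sum())
        tba_invalid = bool((report["preservation_class"] == "invalid").all())
    else:
        n_valid_tba, tba_invalid = 0, True

    booster = MultiscaleBootstrapAU(
        scales=cfg.scales, n_boot=cfg.n_boot, threshold=cfg.au_threshold,
        min_size=cfg.min_size, random_state=cfg.bootstrap_seed,
    ).fit(data)
    n_modules_sba = booster.n_candidate_modules_
    n_valid_sba = len(booster.significant_)

    params = compute_network_parameters(detector.network_, partition, cfg.edge_threshold)

    return DatasetAnalysis(
        dataset_id=dataset_id,
        partition=partition,
        preservation=report if keep_reports else pd.DataFrame(),
        n_modules_tba=n_modules_tba,
        n_valid_tba=n_valid_tba,
        n_gray_genes=len(partition.gray_genes),
        tba_invalid=tba_invalid,
        n_modules_sba=n_modules_sba,
        n_valid_sba=n_valid_sba,
        network_parameters=params,
        au_report=booster.report_ if keep_reports else None,
    )


# ---------------------------------------------------------------------------
# gray-area perturbation experiment


@dataclass
class GrayAreaResult:
    """Baseline and per-level counts of the gray-area experiment."""

    dataset_id: str
    skipped: bool = False
    baseline_tba: SimulationLevelResult | None = None
    baseline_sba: SimulationLevelResult | None = None
    levels_tba: list = field(default_factory=list)
    levels_sba: list = field(default_factory=list)

    def changed(self, method: str) -> bool:
        levels = self.levels_tba if method == "tba" else self.levels_sba
        return any(lv.changed for lv in levels)

    def vr_summary(self) -> dict:
        """Per-quantity VR of this dataset across the simulated levels."""
        out: dict[str, float] = {}
        if self.skipped:
            return out
        b_t, b_s = self.baseline_tba, self.baseline_sba
        out["tba_modules"] = vr(b_t.n_modules, [lv.n_modules for lv in self.levels_tba]) \
            if b_t.n_modules else math.nan
        out["tba_gray_genes"] = vr(b_t.n_gray, [lv.n_gray for lv in self.levels_tba]) \
            if b_t.n_gray else math.nan
        out["tba_valid"] = vr(b_t.n_valid, [lv.n_valid for lv in self.levels_tba]) \
            if b_t.n_valid else math.nan
        out["sba_modules"] = vr(b_s.n_modules, [lv.n_modules for lv in self.levels_sba]) \
            if b_s.n_modules else math.nan
        out["sba_valid"] = vr(b_s.n_valid, [lv.n_valid for lv in self.levels_sba]) \
            if b_s.n_valid else math.nan
        return out


def gray_area_experiment(
    data: pd.DataFrame,
    cfg: RunConfig,
    dataset_id: str = "dataset",
    levels=None,
    baseline: DatasetAnalysis | None = None,
) -> GrayAreaResult:
    """Perturb baseline gray genes by each level and re-run both pipelines.

    Gray membership is frozen at the baseline partition (perturbing a
    moving target would be circular).  Every re-run uses the identical
    seeds and settings as the baseline, so a count change at level 1.0
    is impossible and a change at any other level can only arise from
    the clustering cut, not from the (scale-invariant) correlations.
    """
    levels = tuple(cfg.perturbation_levels if levels is None else levels)
    if baseline is None:
        baseline = analyze_dataset(data, cfg, dataset_id, keep_reports=False)
    gray_genes = baseline.partition.gray_genes
    if len(gray_genes) == 0:
        logger.warning("dataset %s: no gray genes at baseline; experiment skipped", dataset_id)
        return GrayAreaResult(dataset_id=dataset_id, skipped=True)

    result = GrayAreaResult(
        dataset_id=dataset_id,
        baseline_tba=SimulationLevelResult(
            level=1.0, n_modules=baseline.n_modules_tba,
            n_valid=baseline.n_valid_tba, n_gray=baseline.n_gray_genes),
        baseline_sba=SimulationLevelResult(
            level=1.0, n_modules=baseline.n_modules_sba, n_valid=baseline.n_valid_sba),
    )
    for level in levels:
        perturbed = perturb_gray_area(data, baseline.partition, level)
        run = analyze_dataset(perturbed, cfg, dataset_id, keep_reports=False)
        tba = SimulationLevelResult(
            level=level, n_modules=run.n_modules_tba, n_valid=run.n_valid_tba,
            n_gray=run.n_gray_genes,
            changed=(run.n_modules_tba != baseline.n_modules_tba
                     or run.n_gray_genes != baseline.n_gray_genes
                     or run.n_valid_tba != baseline.n_valid_tba),
        )
        sba = SimulationLevelResult(
            level=level, n_modules=run.n_modules_sba, n_valid=run.n_valid_sba,
            changed=(run.n_modules_sba != baseline.n_modules_sba
                     or run.n_valid_sba != baseline.n_valid_sba),
        )
        result.levels_tba.append(tba)
        result.levels_sba.append(sba)
    return result


def aggregate_vr(
    gray_results: list[GrayAreaResult],
    quantity: str,
    include_unchanged: bool = True,
) -> float:
    """Mean per-dataset VR for one quantity across gray-area experiments.

    ``quantity`` is one of tba_modules, tba_gray_genes, tba_valid,
    sba_modules, sba_valid.  With ``include_unchanged=False`` only
    datasets where the relevant pipeline recorded any change contribute
    (the stricter convention for the topology pipeline).
    """
    method = "tba" if quantity.startswith("tba") else "sba"
    values = []
    for g in gray_results:
        if g.skipped:
            continue
        if not include_unchanged and not g.changed(method):
            continue
        v = g.vr_summary().get(quantity, math.nan)
        if np.isfinite(v):
            values.append(v)
    return float(np.mean(values)) if values else math.nan


# ---------------------------------------------------------------------------
# network-parameter regression


def parameter_ratio_regression(
    params: list[NetworkParameters], ratios: list[float]
) -> pd.DataFrame:
    """OLS of the valid-module ratio on each network parameter separately.

    Returns one row per parameter with slope, Pearson r, and the
    two-sided p-value; a constant parameter gets NaN markers.
    """
    if len(params) < 3:
        raise ValueError("regression requires at least 3 datasets")
    if len(params) != len(ratios):
        raise ValueError("params and ratios must have equal length")
    y = np.asarray(ratios, dtype=float)
    rows = []
    for name in PARAMETER_NAMES:
        x = np.array([getattr(p, name) for p in params], dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or np.ptp(x[ok]) == 0:
            rows.append({"parameter": name, "slope": math.nan,
                         "pearson_r": math.nan, "p_value": math.nan})
            continue
        res = sps.linregress(x[ok], y[ok])
        rows.append({"parameter": name, "slope": res.slope,
                     "pearson_r": res.rvalue, "p_value": res.pvalue})
    return pd.DataFrame(rows).set_index("parameter")


# ---------------------------------------------------------------------------
# the full (paper-shaped) driver


def min_size_sweep(
    data: pd.DataFrame, cfg: RunConfig, dataset_id: str = "dataset"
) -> pd.DataFrame:
    """Percent of preserved modules as the minimum module size is swept.

    Modules are re-detected at each minimum size (not merely
    re-filtered) and re-validated with the same seeds; reports the
    detected/preserved counts and the preserved percentage per setting.
    """
    rows = []
    for ms in cfg.min_size_sweep:
        sub_cfg = RunConfig(**{**cfg.to_dict(), "min_size": int(ms),
                               "scales": cfg.scales,
                               "perturbation_levels": cfg.perturbation_levels,
                               "min_size_sweep": cfg.min_size_sweep})
        run = analyze_dataset(data, sub_cfg, dataset_id, keep_reports=False)
        pct = (100.0 * run.n_valid_tba / run.n_modules_tba) if run.n_modules_tba else math.nan
        rows.append({"min_size": int(ms), "n_modules": run.n_modules_tba,
                     "n_preserved": run.n_valid_tba, "preserved_percent": pct})
    return pd.DataFrame(rows).set_index("min_size")


def run_full_benchmark(
    datasets: dict[str, pd.DataFrame],
    cfg: RunConfig,
    sweep: bool = True,
    gray_levels: bool = True,
) -> dict:
    """Detection + both validations on every dataset, with aggregates.

    Returns a JSON-serialisable report: per-dataset counts and network
    parameters, VSR/FR per method, the min-size sweep, the gray-area
    per-level tables with aggregate VRs, and the parameter-vs-ratio
    regression tables.
    """
    analyses: dict[str, DatasetAnalysis] = {}
    per_dataset = {}
    results_z: list[DatasetResult] = []
    results_au: list[DatasetResult] = []
    for ds_id, data in datasets.items():
        run = analyze_dataset(data, cfg, ds_id, keep_reports=False)
        analyses[ds_id] = run
        rz, rau = run.dataset_results()
        results_z.append(rz)
        results_au.append(rau)
        per_dataset[ds_id] = {
            "n_modules_tba": run.n_modules_tba,
            "n_valid_tba": run.n_valid_tba,
            "tba_invalid": run.tba_invalid,
            "n_gray_genes": run.n_gray_genes,
            "n_modules_sba": run.n_modules_sba,
            "n_valid_sba": run.n_valid_sba,
            "ratio_tba": results_z[-1].aggregated_ratio(),
            "ratio_sba": results_au[-1].aggregated_ratio(),
            "network_parameters": run.network_parameters.as_dict(),
        }

    report: dict = {
        "config_hash": cfg.hash(),
        "per_dataset": per_dataset,
        "vsr": {"zsummary": vsr(results_z), "au": vsr(results_au)},
    }
    if len(datasets) >= 2:
        report["fr"] = {"zsummary": fr(results_z), "au": fr(results_au)}

    if sweep:
        report["min_size_sweep"] = {
            ds_id: min_size_sweep(data, cfg, ds_id).reset_index().to_dict("records")
            for ds_id, data in datasets.items()
        }

    if gray_levels:
        gray_results = [
            gray_area_experiment(data, cfg, ds_id, baseline=analyses[ds_id])
            for ds_id, data in datasets.items()
        ]
        report["gray_area"] = {
            g.dataset_id: {
                "skipped": g.skipped,
                "baseline_tba": asdict(g.baseline_tba) if g.baseline_tba else None,
                "baseline_sba": asdict(g.baseline_sba) if g.baseline_sba else None,
                "levels_tba": [asdict(lv) for lv in g.levels_tba],
                "levels_sba": [asdict(lv) for lv in g.levels_sba],
                "vr": g.vr_summary(),
            }
            for g in gray_results
        }
        report["vr"] = {
            q: aggregate_vr(gray_results, q)
            for q in ("tba_modules", "tba_gray_genes", "tba_valid",
                      "sba_modules", "sba_valid")
        }
        report["vr_changed_only"] = {
            q: aggregate_vr(gray_results, q, include_unchanged=False)
            for q in ("tba_modules", "tba_gray_genes", "tba_valid",
                      "sba_modules", "sba_valid")
        }

    if len(datasets) >= 3:
        params = [analyses[d].network_parameters for d in datasets]
        for method, results in (("zsummary", results_z), ("au", results_au)):
            ratios = [r.aggregated_ratio() for r in results]
            table = parameter_ratio_regression(params, ratios)
            report.setdefault("regression", {})[method] = (
                table.reset_index().to_dict("records")
            )
    return report
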