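"""Benchmark statistics and the gray-area experiment driver."""

import math

import numpy as np
import pytest

from coexval import (DatasetResult, RunConfig, SyntheticSpec, analyze_dataset,
                     fr, gray_area_experiment, make_modular_expression,
                     parameter_ratio_regression, vr, vsr)
from coexval.benchmark import GrayAreaResult, SimulationLevelResult, aggregate_vr
from coexval.graph_params import NetworkParameters


def results(ratios, invalid=()):
    out = []
    for i, r in enumerate(ratios):
        if r is None:
            out.append(DatasetResult(f"d{i}", "zsummary", 10, 0, invalid_flag=True))
        else:
            out.append(DatasetResult(f"d{i}", "zsummary", 10, int(round(10 * r))))
    return out


class TestVSR:
    def test_all_valid_gives_hundred(self):
        assert vsr(results([1, 1, 1])) == pytest.approx(100.0)

    def test_mean_of_ratios(self):
        assert vsr(results([0.2, 0.4])) == pytest.approx(30.0)

    def test_invalid_dataset_counts_as_zero(self):
        assert vsr(results([0.5, None, 0.5])) == pytest.approx(100 / 3)

    def test_pooled_alternative(self):
        rs = [DatasetResult("a", "au", 10, 5), DatasetResult("b", "au", 40, 4)]
        assert vsr(rs) == pytest.approx(100 * (0.5 + 0.1) / 2)
        assert vsr(rs, pooled=True) == pytest.approx(100 * 9 / 50)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            vsr([])


class TestFR:
    def test_constant_ratios_give_zero(self):
        assert fr(results([0.4, 0.4, 0.4])) == pytest.approx(0.0)

    def test_coefficient_of_variation(self):
        # sd([0.2, 0.4]) = 0.141421..., mean = 0.3
        assert fr(results([0.2, 0.4])) == pytest.approx(47.140452, abs=1e-4)

    def test_scale_invariance(self):
        assert fr(results([0.1, 0.3, 0.5])) == pytest.approx(
            fr(results([0.2, 0.6, 1.0])))

    def test_zero_mean_is_undefined(self):
        assert math.isnan(fr(results([0.0, 0.0])))

    def test_plain_sd_alternative(self):
        assert fr(results([0.2, 0.4]), plain_sd=True) == pytest.approx(14.1421, abs=1e-3)

    def test_single_dataset_rejected(self):
        with pytest.raises(ValueError):
            fr(results([0.5]))


class TestVR:
    def test_no_change_gives_zero(self):
        assert vr(10, [10, 10, 10]) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        assert vr(10, [10, 9, 11, 10, 10, 10]) == pytest.approx(100 * (2 / 6) / 10)

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(0)
        original = 9
        sim = rng.integers(5, 15, size=6)
        expected = 100 * np.mean(np.abs(sim - original)) / original
        assert vr(original, sim) == pytest.approx(expected)

    def test_zero_original_is_undefined(self):
        assert math.isnan(vr(0, [1, 2]))

    def test_empty_simulated_rejected(self):
        with pytest.raises(ValueError):
            vr(5, [])


class TestRegression:
    @staticmethod
    def params_from(values, name="density"):
        out = []
        for v in values:
            fields = {n: 0.5 for n in ("modularity", "density", "clustering_coefficient",
                                       "characteristic_path_length", "heterogeneity",
                                       "centralization")}
            fields[name] = v
            out.append(NetworkParameters(**fields))
        return out

    def test_perfect_linear_relation(self):
        x = [0.1, 0.2, 0.3, 0.4]
        y = [1.0, 2.0, 3.0, 4.0]
        table = parameter_ratio_regression(self.params_from(x), y)
        assert table.loc["density", "pearson_r"] == pytest.approx(1.0)
        assert table.loc["density", "p_value"] < 1e-6
        assert table.loc["density", "slope"] == pytest.approx(10.0)

    def test_three_points_match_closed_form_slope(self):
        x = np.array([1.0, 2.0, 4.0])
        y = np.array([3.0, 5.0, 4.0])
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        table = parameter_ratio_regression(self.params_from(x), list(y))
        assert table.loc["density", "slope"] == pytest.approx(slope)

    def test_shuffled_parameter_has_null_mean_r(self):
        rng = np.random.default_rng(1)
        y = rng.uniform(0, 1, 12)
        rs = []
        for _ in range(100):
            x = rng.permutation(np.linspace(0.1, 0.9, 12))
            rs.append(parameter_ratio_regression(self.params_from(x), list(y))
                      .loc["density", "pearson_r"])
        se = np.std(rs, ddof=1) / np.sqrt(len(rs))
        assert abs(np.mean(rs)) < 3 * se + 1e-9

    def test_constant_parameter_gets_undefined_marker(self):
        table = parameter_ratio_regression(self.params_from([0.3, 0.3, 0.3]), [1, 2, 3])
        assert math.isnan(table.loc["density", "slope"])

    def test_too_few_datasets_rejected(self):
        with pytest.raises(ValueError):
            parameter_ratio_regression(self.params_from([0.1, 0.2]), [1, 2])


def fast_config():
    return RunConfig(n_perm=50, n_boot=20, min_size=3)


@pytest.fixture(scope="module")
def gray_dataset():
    spec = SyntheticSpec(n_samples=40, module_sizes=(12, 9, 6),
                         module_strengths=(0.85, 0.8, 0.75), n_gray=40, seed=4)
    return make_modular_expression(spec)[0]


class TestGrayAreaExperiment:
    def test_identity_level_changes_nothing(self, gray_dataset):
        dataset = gray_dataset
        cfg = fast_config()
        result = gray_area_experiment(dataset, cfg, levels=(1.0,))
        assert not result.skipped
        lv = result.levels_tba[0]
        assert not lv.changed
        assert lv.n_modules == result.baseline_tba.n_modules
        assert lv.n_gray == result.baseline_tba.n_gray
        assert not result.levels_sba[0].changed

    def test_no_gray_genes_skips_with_notice(self, caplog):
        spec = SyntheticSpec(n_samples=40, module_sizes=(10, 8),
                             module_strengths=(0.9, 0.9), n_gray=0, seed=0)
        data, _ = make_modular_expression(spec)
        with caplog.at_level("WARNING"):
            result = gray_area_experiment(data, fast_config(), levels=(0.5,))
        assert result.skipped
        assert "skipped" in caplog.text

    def test_vr_summary_from_hand_built_records(self):
        g = GrayAreaResult(
            dataset_id="d",
            baseline_tba=SimulationLevelResult(1.0, n_modules=9, n_valid=5, n_gray=100),
            baseline_sba=SimulationLevelResult(1.0, n_modules=20, n_valid=4),
            levels_tba=[SimulationLevelResult(lv, n_modules=m, n_valid=5, n_gray=100,
                                              changed=(m != 9))
                        for lv, m in zip((0.1, 0.5, 0.9, 1.1, 1.5, 2.0),
                                         (9, 8, 9, 10, 9, 9))],
            levels_sba=[SimulationLevelResult(lv, n_modules=20, n_valid=4)
                        for lv in (0.1, 0.5, 0.9, 1.1, 1.5, 2.0)],
        )
        summary = g.vr_summary()
        assert summary["tba_modules"] == pytest.approx(100 * (2 / 6) / 9)
        assert summary["tba_valid"] == pytest.approx(0.0)
        assert summary["sba_modules"] == pytest.approx(0.0)

    def test_aggregate_vr_changed_only_convention(self):
        changed = GrayAreaResult(
            dataset_id="a",
            baseline_tba=SimulationLevelResult(1.0, 10, 5, 50),
            baseline_sba=SimulationLevelResult(1.0, 10, 5),
            levels_tba=[SimulationLevelResult(0.5, 8, 5, 50, changed=True)],
            levels_sba=[SimulationLevelResult(0.5, 10, 5)],
        )
        unchanged = GrayAreaResult(
            dataset_id="b",
            baseline_tba=SimulationLevelResult(1.0, 10, 5, 50),
            baseline_sba=SimulationLevelResult(1.0, 10, 5),
            levels_tba=[SimulationLevelResult(0.5, 10, 5, 50)],
            levels_sba=[SimulationLevelResult(0.5, 10, 5)],
        )
        both = [changed, unchanged]
        assert aggregate_vr(both, "tba_modules") == pytest.approx((20.0 + 0.0) / 2)
        assert aggregate_vr(both, "tba_modules", include_unchanged=False) == pytest.approx(20.0)


def test_analyze_dataset_counts_are_consistent():
    spec = SyntheticSpec(n_samples=40, module_sizes=(12, 9, 6),
                         module_strengths=(0.85, 0.8, 0.75), n_gray=40, seed=6)
    data, _ = make_modular_expression(spec)
    run = analyze_dataset(data, fast_config(), "ds")
    assert run.n_modules_tba == run.partition.n_modules
    assert 0 <= run.n_valid_tba <= run.n_modules_tba
    assert run.n_valid_sba <= run.n_modules_sba
    assert run.n_gray_genes == len(run.partition.gray_genes)
    rz, rau = run.dataset_results()
    assert rz.method == "zsummary" and rau.method == "au"
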