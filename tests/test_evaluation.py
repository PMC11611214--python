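"""Peak detection, analysis windows, and performance metrics."""

import numpy as np
import pandas as pd
import pytest

from transmix import (
    AnalysisWindowSpec,
    ScenarioEnsembleSpec,
    TransmissionTree,
    UndefinedEstimateError,
    ValidationError,
    clopper_pearson_interval,
    delta_from_pi,
    detect_peak,
    evaluate_replicates,
    onset_incidence,
    peak_asynchronicity,
    run_study,
    sample_ensemble,
    window_end,
)
from conftest import make_scenario


class TestDetectPeak:
    @pytest.mark.parametrize("incidence, expected", [
        ([1, 0, 3, 2, 3], 2),   # earliest day attaining the maximum
        ([5], 0),
        ([0, 0, 2, 7, 1], 3),
    ])
    def test_examples(self, incidence, expected):
        s = pd.Series(incidence, index=range(len(incidence)))
        assert detect_peak(s) == expected

    def test_peak_is_searched_from_the_first_case(self):
        s = pd.Series([0, 0, 4, 1, 4], index=range(5))
        assert detect_peak(s) == 2

    def test_empty_series_is_undefined(self):
        with pytest.raises(UndefinedEstimateError):
            detect_peak(pd.Series([0, 0], index=range(2)))


class TestWindowEnd:
    def test_relative_time_convention(self):
        assert window_end(10, 20, 0.5) == 15

    @pytest.mark.parametrize("first,T", [(0, 7), (3, 12), (5, 5)])
    def test_epsilon_one_ends_at_peak(self, first, T):
        assert window_end(first, T, 1.0) == T

    def test_degenerate_window(self):
        for eps in (0.0, 0.5, 1.0, 3.0):
            assert window_end(4, 4, eps) == 4

    def test_round_half_up(self):
        assert window_end(0, 5, 0.5) == 3   # 2.5 rounds up
        assert window_end(0, 5, 0.3) == 2   # 1.5 rounds up

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            window_end(5, 3, 1.0)
        with pytest.raises(ValidationError):
            window_end(0, 5, -0.1)


class TestPeakAsynchronicity:
    def test_examples(self):
        assert peak_asynchronicity([5, 5, 5]) == 0.0
        assert peak_asynchronicity([0, 10]) == pytest.approx(7.0711, abs=1e-4)
        assert peak_asynchronicity([2, 4, 9]) == pytest.approx(3.6056, abs=1e-4)

    def test_needs_two_defined_peaks(self):
        with pytest.raises(UndefinedEstimateError):
            peak_asynchronicity([3.0, np.nan])


def _chain_tree(n_within, n_between):
    """One g1 import (onset 0) infecting n_within g1 cases and n_between g2
    cases, all with onset day 1 — so every group peaks on day 1 and an
    epsilon = 1 window covers the whole chain."""
    rows = [{"case_id": "root", "group": "g1", "onset_day": 0, "infector_id": None}]
    for i in range(n_within):
        rows.append({"case_id": f"w{i}", "group": "g1",
                     "onset_day": 1, "infector_id": "root"})
    for i in range(n_between):
        rows.append({"case_id": f"b{i}", "group": "g2",
                     "onset_day": 1, "infector_id": "root"})
    return TransmissionTree(pd.DataFrame(rows))


class TestEvaluateReplicates:
    def test_perfect_estimator_gives_zero_bias_full_coverage(self):
        # delta_true = 0 and balanced emissions 5/10 at f=0.5 -> delta_hat = 0
        sc = make_scenario(group_sizes=(50, 50), deltas=(0.0, 0.0))
        trees = [_chain_tree(5, 5) for _ in range(3)]
        rep = evaluate_replicates(trees, sc, AnalysisWindowSpec(epsilons=(1.0,),
                                                                alphas=(0.05,)))
        g1 = rep[rep["group"] == "g1"].iloc[0]
        assert g1["bias"] == pytest.approx(0.0)
        assert g1["coverage"] == 1.0
        assert g1["specificity"] == 1.0
        assert np.isnan(g1["sensitivity"])  # only defined when delta_true != 0

    def test_counts_and_coverage_against_hand_computation(self):
        sc = make_scenario(group_sizes=(50, 50), deltas=(0.8, 0.0))
        tree = _chain_tree(9, 1)
        rep, det = evaluate_replicates([tree], sc,
                                       AnalysisWindowSpec(epsilons=(1.0,), alphas=(0.05,)),
                                       detail=True)
        row = det[det["group"] == "g1"].iloc[0]
        assert (row["tau_within"], row["tau_total"]) == (9, 10)
        assert row["delta_hat"] == pytest.approx(delta_from_pi(0.9, 0.5))
        lo, hi = clopper_pearson_interval(9, 10, 0.05)
        assert row["ci_low"] == pytest.approx(delta_from_pi(lo, 0.5))
        assert row["covered"] == float(row["ci_low"] <= 0.8 <= row["ci_high"])

    def test_sensitivity_counts_ci_excluding_zero(self):
        # strong within-group signal -> CI excludes 0; weak one -> contains 0
        sc = make_scenario(group_sizes=(50, 50), deltas=(0.4, 0.0))
        strong, weak = _chain_tree(30, 1), _chain_tree(6, 4)
        rep = evaluate_replicates([strong, weak], sc,
                                  AnalysisWindowSpec(epsilons=(1.0,), alphas=(0.05,)))
        g1 = rep[rep["group"] == "g1"].iloc[0]
        assert g1["sensitivity"] == pytest.approx(0.5)

    def test_undefined_replicates_excluded_and_counted(self):
        sc = make_scenario(group_sizes=(50, 50), deltas=(0.0, 0.0))
        trees = [_chain_tree(5, 5)] * 2  # g2 never emits
        rep = evaluate_replicates(trees, sc, AnalysisWindowSpec(epsilons=(1.0,),
                                                                alphas=(0.05,)))
        g2 = rep[rep["group"] == "g2"].iloc[0]
        assert g2["status"] == "undefined"
        assert g2["n_valid"] == 0 and g2["n_undefined"] == 2

    def test_tau_sample_size_monotone_in_epsilon(self, scenario_factory):
        sc = scenario_factory(group_sizes=(150, 150), deltas=(0.3, -0.3),
                              initial_imports=(3, 3))
        from transmix import simulate_outbreak
        tree = simulate_outbreak(sc, seed=5)
        _, det = evaluate_replicates(
            [tree], sc,
            AnalysisWindowSpec(epsilons=(0.25, 0.5, 1.0, 2.0), alphas=(0.05,)),
            detail=True,
        )
        for g, cell in det.groupby("group"):
            cell = cell.sort_values("epsilon")
            taus = cell["tau_total"].to_numpy()
            assert (np.diff(taus) >= 0).all()

    def test_metrics_are_deterministic(self, scenario_factory):
        from transmix import simulate_outbreak
        sc = scenario_factory(initial_imports=(2, 2))
        trees = [simulate_outbreak(sc, seed=s) for s in range(3)]
        r1 = evaluate_replicates(trees, sc)
        r2 = evaluate_replicates(trees, sc)
        pd.testing.assert_frame_equal(r1, r2)


class TestRunStudy:
    def test_minimal_study_row_count(self):
        spec = ScenarioEnsembleSpec(n_scenarios=2, n_replicates=2, base_seed=3)
        windows = AnalysisWindowSpec(epsilons=(0.5, 1.0), alphas=(0.05, 0.25))
        result = run_study(spec, windows)
        expected_rows = sum(
            sc.n_groups * len(windows.epsilons) * len(windows.alphas)
            for sc in sample_ensemble(spec)
        )
        assert len(result.report) == expected_rows
        assert len(result.manifest) == 2

    def test_study_is_reproducible(self):
        spec = ScenarioEnsembleSpec(n_scenarios=3, n_replicates=3, base_seed=11)
        windows = AnalysisWindowSpec(epsilons=(1.0,), alphas=(0.05,))
        a = run_study(spec, windows).report
        b = run_study(spec, windows).report
        pd.testing.assert_frame_equal(a, b)

    def test_homogeneous_ensemble_specificity_is_conservative(self):
        """With delta_true = 0 everywhere, the CP-backed CI contains 0 in
        >= 95% of replicates at alpha = 0.05."""
        spec = ScenarioEnsembleSpec(
            n_scenarios=30, n_replicates=20, base_seed=17,
            ranges={"delta": {"p_zero": 1.0}},
        )
        result = run_study(spec, AnalysisWindowSpec(epsilons=(1.0,), alphas=(0.05,)))
        ok = result.report[result.report["status"] == "ok"]
        assert float(ok["specificity"].mean()) >= 0.95
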