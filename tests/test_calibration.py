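import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from voicerisk import (
    CalibratedThreshold,
    CalibrationError,
    ConfigurationError,
    DEFAULT_SPEC,
    STRICT_SPEC,
    ThresholdSpec,
    ValidationError,
    bootstrap_threshold,
    detection_cost,
    eer_threshold,
    min_dcf_threshold,
)
from voicerisk.calibration import _min_dcf_finite

TOY_SCORES = [2.0, 1.0, 0.5, -1.0]
TOY_LABELS = [True, True, False, False]


def grid_min_cost(scores, labels, spec, n=10_000):
    """Exhaustive oracle: cost minimum over an even grid spanning the scores."""
    lo, hi = min(scores) - 1.0, max(scores) + 1.0
    return min(detection_cost(scores, labels, t, spec) for t in np.linspace(lo, hi, n))


class TestDetectionCost:
    def test_perfectly_separated_costs_zero_in_both_modes(self):
        scores, labels = [3.0, 2.5, -1.0, -2.0], [True, True, False, False]
        for mode in ("rates", "counts"):
            spec = ThresholdSpec(mode=mode)
            assert detection_cost(scores, labels, 0.0, spec) == 0.0

    def test_hand_example_default_spec_rates(self):
        # FR = 0, FA = 1/2 -> 1 * 0.5 * 0.99
        assert detection_cost(TOY_SCORES, TOY_LABELS, 0.0, DEFAULT_SPEC) == pytest.approx(0.495)

    def test_hand_example_strict_spec_rates(self):
        # 10 * 0.5 * 0.999
        assert detection_cost(TOY_SCORES, TOY_LABELS, 0.0, STRICT_SPEC) == pytest.approx(4.995)

    def test_counts_mode_uses_raw_counts(self):
        spec = ThresholdSpec(c_fa=1.0, c_fr=1.0, prior_target=0.01, mode="counts")
        # FR count 0, FA count 1 -> 1 * 1 * 0.99
        assert detection_cost(TOY_SCORES, TOY_LABELS, 0.0, spec) == pytest.approx(0.99)

    def test_one_class_input_names_missing_class(self):
        with pytest.raises(ValidationError, match="genuine"):
            detection_cost([1.0, 2.0], [False, False], 0.0, DEFAULT_SPEC)
        with pytest.raises(ValidationError, match="impostor"):
            detection_cost([1.0, 2.0], [True, True], 0.0, DEFAULT_SPEC)

    @pytest.mark.parametrize("bad", [
        dict(c_fa=0.0), dict(c_fr=-1.0), dict(prior_target=0.0), dict(prior_target=1.0),
        dict(mode="other"),
    ])
    def test_invalid_spec_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            ThresholdSpec(**bad)


class TestMinDcf:
    def test_separable_toy_cost_zero_threshold_between_classes(self):
        scores, labels = [3.0, 2.5, -1.0, -2.0], [True, True, False, False]
        thr, cost = min_dcf_threshold(scores, labels, DEFAULT_SPEC)
        assert cost == 0.0
        assert -1.0 < thr < 2.5

    @pytest.mark.parametrize("spec", [DEFAULT_SPEC, STRICT_SPEC], ids=["default", "strict"])
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_grid_oracle(self, spec, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 50))
        labels = np.concatenate([np.ones(n // 2, bool), np.zeros(n - n // 2, bool)])
        scores = np.where(labels, rng.normal(1.0, 1.0, n), rng.normal(-1.0, 1.0, n))
        thr, cost = min_dcf_threshold(scores, labels, spec)
        oracle = grid_min_cost(scores, labels, spec)
        assert cost == pytest.approx(oracle, abs=1e-12)
        assert detection_cost(scores, labels, thr, spec) == pytest.approx(cost, abs=1e-12)

    def test_hand_toy_equals_grid(self):
        thr, cost = min_dcf_threshold(TOY_SCORES, TOY_LABELS, DEFAULT_SPEC)
        assert cost == pytest.approx(grid_min_cost(TOY_SCORES, TOY_LABELS, DEFAULT_SPEC), abs=1e-12)

    def test_infinite_fa_cost_admits_zero_training_false_accepts(self):
        rng = np.random.default_rng(3)
        labels = np.r_[np.ones(20, bool), np.zeros(20, bool)]
        scores = np.where(labels, rng.normal(0.5, 1, 40), rng.normal(-0.5, 1, 40))
        spec = ThresholdSpec(c_fa=1e9, c_fr=1.0, prior_target=0.5)
        thr, _ = min_dcf_threshold(scores, labels, spec)
        impostor = scores[~labels]
        assert (impostor >= thr).sum() == 0

    def test_strictness_monotone_in_cfa(self):
        """Raising C_FA (others fixed) never lowers the selected threshold."""
        rng = np.random.default_rng(8)
        for _ in range(10):
            n = 40
            labels = np.r_[np.ones(20, bool), np.zeros(20, bool)]
            scores = np.where(labels, rng.normal(1, 1, n), rng.normal(-1, 1, n))
            prev = -np.inf
            for c_fa in (0.5, 1.0, 2.0, 10.0, 100.0):
                thr, _ = min_dcf_threshold(
                    scores, labels, ThresholdSpec(c_fa=c_fa, c_fr=1.0, prior_target=0.01)
                )
                assert thr >= prev
                prev = thr


finite_scores = st.lists(
    st.floats(-50, 50, allow_nan=False, allow_infinity=False), min_size=1, max_size=25
)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(genuine=finite_scores, impostor=finite_scores, probe=st.floats(-60, 60))
def test_min_dcf_is_global_minimum_property(genuine, impostor, probe):
    """The selected cost never exceeds the cost at any other threshold."""
    scores = list(genuine) + list(impostor)
    labels = [True] * len(genuine) + [False] * len(impostor)
    for spec in (DEFAULT_SPEC, STRICT_SPEC):
        thr, cost = min_dcf_threshold(scores, labels, spec)
        assert detection_cost(scores, labels, thr, spec) == pytest.approx(cost, abs=1e-12)
        assert cost <= detection_cost(scores, labels, probe, spec) + 1e-12


class TestEer:
    def test_separable_toy_eer_zero(self):
        scores, labels = [3.0, 2.5, -1.0, -2.0], [True, True, False, False]
        thr, eer = eer_threshold(scores, labels)
        assert eer == 0.0
        assert -1.0 < thr < 2.5

    def test_interleaved_toy_matches_enumeration_oracle(self):
        """genuine {1, 3}, impostor {0, 2}: enumerate every cut and pick the
        |FAR-FRR| minimiser (unique at 1.5, where both rates are 1/2)."""
        scores = [1.0, 3.0, 0.0, 2.0]
        labels = [True, True, False, False]
        genuine = np.array([1.0, 3.0])
        impostor = np.array([0.0, 2.0])
        cuts = np.concatenate(([-np.inf], np.sort(np.unique(scores))[:-1] + 0.5, [np.inf]))
        far = [(impostor >= t).mean() for t in cuts]
        frr = [(genuine < t).mean() for t in cuts]
        best = int(np.argmin(np.abs(np.subtract(far, frr))))
        thr, eer = eer_threshold(scores, labels)
        assert thr == pytest.approx(cuts[best])
        assert eer == pytest.approx((far[best] + frr[best]) / 2)
        assert (thr, eer) == (pytest.approx(1.5), pytest.approx(0.5))

    @pytest.mark.parametrize("spec", [DEFAULT_SPEC, STRICT_SPEC])
    def test_eer_cost_never_beats_min_dcf(self, spec):
        rng = np.random.default_rng(12)
        for _ in range(10):
            labels = np.r_[np.ones(15, bool), np.zeros(25, bool)]
            scores = np.where(labels, rng.normal(1, 1, 40), rng.normal(-1, 1, 40))
            thr_eer, _ = eer_threshold(scores, labels)
            _, best_cost = min_dcf_threshold(scores, labels, spec)
            assert detection_cost(scores, labels, thr_eer, spec) >= best_cost - 1e-12


class TestBootstrap:
    def test_single_run_value_equals_that_runs_threshold(self, vox_cohort, vox_model):
        cal = bootstrap_threshold(
            vox_cohort, vox_model, DEFAULT_SPEC, subset_size=80, runs=1, seed=3
        )
        assert cal.runs_attempted == 1
        assert cal.value == cal.per_run_thresholds[0]

    def test_finite_restriction_agrees_with_public_op_when_interior(self):
        rng = np.random.default_rng(5)
        labels = np.r_[np.ones(30, bool), np.zeros(30, bool)]
        scores = np.where(labels, rng.normal(2, 1, 60), rng.normal(-2, 1, 60))
        genuine, impostor = np.sort(scores[labels]), np.sort(scores[~labels])
        thr_pub, _ = min_dcf_threshold(scores, labels, DEFAULT_SPEC)
        assert _min_dcf_finite(genuine, impostor, DEFAULT_SPEC) == pytest.approx(thr_pub)

    def test_disjoint_subset_populations_discard_every_run(self, vox_cohort, vox_model):
        speakers = sorted(vox_cohort.indices_by_speaker())

        def disjoint_halves(rng, pool, size):
            return np.array(speakers[:size], dtype=object), np.array(
                speakers[size : 2 * size], dtype=object
            )

        with pytest.raises(CalibrationError, match="discarded"):
            bootstrap_threshold(
                vox_cohort, vox_model, DEFAULT_SPEC,
                subset_size=50, runs=5, seed=0, _draw_subsets=disjoint_halves,
            )

    def test_discard_accounting_with_tiny_subsets(self, vox_cohort, vox_model):
        # subset_size 2 from 300 speakers: most runs have disjoint subsets
        cal = bootstrap_threshold(
            vox_cohort, vox_model, DEFAULT_SPEC, subset_size=2, runs=400, seed=1
        )
        assert cal.runs_used + cal.runs_discarded == cal.runs_attempted == 400
        assert cal.runs_discarded > 0

    def test_two_seeds_agree_within_three_standard_errors(self, vox_cohort, vox_model):
        cals = [
            bootstrap_threshold(
                vox_cohort, vox_model, STRICT_SPEC, subset_size=80, runs=100, seed=s
            )
            for s in (1, 2)
        ]
        ses = [
            np.std(c.per_run_thresholds, ddof=1) / np.sqrt(c.runs_used) for c in cals
        ]
        pooled = float(np.hypot(*ses))
        assert abs(cals[0].value - cals[1].value) < 3 * pooled

    def test_convergence_stop_uses_fewer_runs(self, vox_cohort, vox_model):
        cal = bootstrap_threshold(
            vox_cohort, vox_model, DEFAULT_SPEC,
            subset_size=80, runs=300, seed=2, converge_tol=1e-2, converge_window=10,
        )
        assert cal.runs_attempted < 300

    def test_subset_larger_than_population_rejected(self, vox_cohort, vox_model):
        with pytest.raises(ConfigurationError):
            bootstrap_threshold(vox_cohort, vox_model, DEFAULT_SPEC, subset_size=10_000, runs=1)

    def test_inconsistent_bookkeeping_rejected(self):
        with pytest.raises(ValidationError):
            CalibratedThreshold(
                value=0.0, method="minDCF", per_run_thresholds=[0.0],
                runs_attempted=2, runs_used=1, runs_discarded=0,
            )
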