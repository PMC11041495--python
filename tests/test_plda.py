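import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.stats import multivariate_normal

from voicerisk import (
    DegenerateDataError,
    EnrollmentTable,
    GeneratorConfig,
    PLDAModel,
    TaskConfig,
    ValidationError,
    enroll,
    fit_plda,
    generate_cohort,
    score_llr,
    score_matrix,
)


def random_model(rng, dim):
    a = rng.standard_normal((dim, dim))
    b = rng.standard_normal((dim, dim))
    return PLDAModel(
        mean=rng.standard_normal(dim),
        between_cov=a @ a.T + 0.1 * np.eye(dim),
        within_cov=b @ b.T + 0.5 * np.eye(dim),
    )


def brute_force_llr(model, enrolled, probe, m):
    """Stacked 2d-dimensional joint-Gaussian evaluation of both hypotheses."""
    d = model.dim
    pb, pw = model.between_cov, model.within_cov
    same = np.block([[pb + pw / m, pb], [pb, pb + pw]])
    diff = np.block([[pb + pw / m, np.zeros((d, d))], [np.zeros((d, d)), pb + pw]])
    z = np.concatenate([enrolled, probe])
    mu = np.concatenate([model.mean, model.mean])
    return multivariate_normal.logpdf(z, mu, same) - multivariate_normal.logpdf(z, mu, diff)


class TestScoring:
    def test_hand_value_1d(self):
        model = PLDAModel(mean=np.zeros(1), between_cov=np.eye(1), within_cov=np.eye(1))
        # joint covariances [[2,1],[1,2]] vs [[2,0],[0,2]] at the origin
        assert score_llr(model, np.zeros(1), np.zeros(1)) == pytest.approx(
            0.5 * np.log(4.0 / 3.0), abs=1e-12
        )

    @pytest.mark.parametrize("dim", [1, 2, 3, 4])
    @pytest.mark.parametrize("m", [1, 2, 5])
    def test_matches_brute_force_joint_gaussian(self, dim, m):
        rng = np.random.default_rng(dim * 10 + m)
        model = random_model(rng, dim)
        for _ in range(8):
            e, p = rng.standard_normal(dim), rng.standard_normal(dim)
            assert score_llr(model, e, p, m) == pytest.approx(
                brute_force_llr(model, e, p, m), abs=1e-8
            )

    def test_symmetric_for_single_recording_enrollment(self):
        rng = np.random.default_rng(4)
        model = random_model(rng, 3)
        e, p = rng.standard_normal(3), rng.standard_normal(3)
        assert score_llr(model, e, p, 1) == pytest.approx(score_llr(model, p, e, 1), abs=1e-10)

    def test_zero_between_covariance_gives_zero_llr(self):
        model = PLDAModel(mean=np.zeros(2), between_cov=np.zeros((2, 2)), within_cov=np.eye(2))
        rng = np.random.default_rng(0)
        for _ in range(5):
            assert score_llr(model, rng.standard_normal(2), rng.standard_normal(2)) == pytest.approx(0.0, abs=1e-12)

    def test_score_matrix_matches_elementwise_llr(self):
        rng = np.random.default_rng(7)
        model = random_model(rng, 3)
        enr = EnrollmentTable(
            speaker_ids=np.array(["a", "b", "c"], dtype=object),
            vectors=rng.standard_normal((3, 3)),
            n_averaged=np.array([1, 4, 2]),
        )
        probes = rng.standard_normal((2, 3))
        mat = score_matrix(model, enr, probes)
        assert mat.shape == (2, 3)
        for i in range(2):
            for j in range(3):
                assert mat[i, j] == pytest.approx(
                    score_llr(model, enr.vectors[j], probes[i], int(enr.n_averaged[j])),
                    abs=1e-10,
                )

    def test_large_matrix_all_finite(self):
        rng = np.random.default_rng(11)
        model = random_model(rng, 8)
        enr = EnrollmentTable(
            speaker_ids=np.array([f"s{i}" for i in range(1000)], dtype=object),
            vectors=rng.standard_normal((1000, 8)),
            n_averaged=rng.integers(1, 6, size=1000),
        )
        mat = score_matrix(model, enr, rng.standard_normal((163, 8)))
        assert mat.shape == (163, 1000)
        assert np.all(np.isfinite(mat))

    def test_dimension_mismatch_raises(self):
        model = PLDAModel(mean=np.zeros(3), between_cov=np.eye(3), within_cov=np.eye(3))
        with pytest.raises(ValidationError):
            score_llr(model, np.zeros(2), np.zeros(3))


class TestFit:
    def test_loglik_monotone_nondecreasing(self, vox_cohort):
        model = fit_plda(vox_cohort.X, vox_cohort.speaker_ids, max_iter=30, tol=1e-10)
        gains = np.diff(model.fit_log)
        assert len(model.fit_log) >= 2
        assert gains.min() > -1e-8 * max(1.0, abs(model.fit_log[0]))

    def test_balanced_1d_fixed_point_matches_numeric_mle(self, anova_toy):
        """EM must land on the maximiser of the exact marginal likelihood
        (mean fixed at the grand mean), found here by direct optimisation."""
        model = fit_plda(anova_toy.X, anova_toy.speaker_ids, max_iter=3000, tol=1e-14)

        x = anova_toy.X.ravel() - anova_toy.X.mean()
        means = np.array([x[:2].mean(), x[2:].mean()])
        ssw = float(((x[:2] - means[0]) ** 2).sum() + ((x[2:] - means[1]) ** 2).sum())

        def nll(params):
            log_w, log_b = params
            w, b = np.exp(log_w), np.exp(log_b)
            v = w + 2 * b
            return 0.5 * (
                2 * np.log(w) + ssw / w + 2 * np.log(v) + 2 * (means**2).sum() / v
            )

        best = min(
            (minimize(nll, s, method="Nelder-Mead") for s in ([0.0, 1.0], [1.0, 3.0])),
            key=lambda r: r.fun,
        )
        w_star, b_star = np.exp(best.x)
        assert model.within_cov[0, 0] == pytest.approx(w_star, rel=1e-4)
        assert model.between_cov[0, 0] == pytest.approx(b_star, rel=1e-4)

    def test_recovers_generator_covariances(self):
        cfg = GeneratorConfig(
            dim=6, n_speakers=400, tasks=(TaskConfig("t", 8),),
            between_cov=1.0, within_cov=0.25, seed=13,
        )
        cohort = generate_cohort(cfg)
        model = fit_plda(cohort.X, cohort.speaker_ids, max_iter=100, tol=1e-6)
        eye = np.eye(6)
        assert np.linalg.norm(model.between_cov - eye) / np.linalg.norm(eye) < 0.2
        assert np.linalg.norm(model.within_cov - 0.25 * eye) / np.linalg.norm(0.25 * eye) < 0.2

    def test_discriminates_genuine_from_impostor_across_seeds(self):
        """With dominant between-speaker covariance, genuine LLRs exceed
        impostor LLRs on average, over 20 independent cohorts."""
        margins = []
        for seed in range(20):
            cfg = GeneratorConfig(
                dim=4, n_speakers=30, tasks=(TaskConfig("t", 3),),
                between_cov=1.0, within_cov=0.3, seed=100 + seed,
            )
            cohort = generate_cohort(cfg)
            model = fit_plda(cohort.X, cohort.speaker_ids, max_iter=30, tol=1e-4)
            enr = enroll(cohort)
            by = cohort.indices_by_speaker()
            probes = np.vstack([cohort.X[idx[0]] for s, idx in sorted(by.items())])
            mat = score_matrix(model, enr, probes)
            genuine = np.eye(len(enr), dtype=bool)
            margins.append(mat[genuine].mean() - mat[~genuine].mean())
        assert np.mean(margins) > 0
        assert np.all(np.asarray(margins) > 0)

    def test_single_speaker_raises(self):
        with pytest.raises(DegenerateDataError):
            fit_plda(np.zeros((3, 2)), ["A", "A", "A"])

    def test_all_singletons_raises(self):
        with pytest.raises(DegenerateDataError):
            fit_plda(np.zeros((3, 2)), ["A", "B", "C"])


class TestEnroll:
    def test_single_recording_equals_itself(self, multitask_cohort):
        sub = multitask_cohort.subset(np.arange(multitask_cohort.n_records))
        one = sub.indices_by_speaker()
        sid = next(iter(one))
        first = one[sid][:1]
        table = enroll(sub.subset(first))
        assert np.allclose(table.vectors[0], sub.X[first[0]])
        assert table.n_averaged[0] == 1

    def test_mean_of_two_recordings(self):
        from voicerisk import EmbeddingCohort

        cohort = EmbeddingCohort(
            recording_ids=np.array(["r1", "r2"], dtype=object),
            speaker_ids=np.array(["S", "S"], dtype=object),
            tasks=np.array(["t", "t"], dtype=object),
            X=np.array([[0.0, 0.0], [2.0, 2.0]]),
        )
        table = enroll(cohort)
        assert np.allclose(table.vectors, [[1.0, 1.0]])
        assert table.n_averaged[0] == 2

    def test_excluded_probe_recording_left_out_of_average(self):
        from voicerisk import EmbeddingCohort

        cohort = EmbeddingCohort(
            recording_ids=np.array(["r1", "r2", "r3"], dtype=object),
            speaker_ids=np.array(["S"] * 3, dtype=object),
            tasks=np.array(["t"] * 3, dtype=object),
            X=np.array([[0.0], [2.0], [100.0]]),
        )
        table = enroll(cohort, exclude_recordings=["r3"])
        assert np.allclose(table.vectors, [[1.0]])
        assert table.n_averaged[0] == 2

    def test_speaker_with_nothing_left_raises(self):
        from voicerisk import EmbeddingCohort

        cohort = EmbeddingCohort(
            recording_ids=np.array(["r1"], dtype=object),
            speaker_ids=np.array(["S"], dtype=object),
            tasks=np.array(["t"], dtype=object),
            X=np.zeros((1, 1)),
        )
        with pytest.raises(DegenerateDataError):
            enroll(cohort, exclude_recordings=["r1"])
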