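"""Component matching, split-half stability, projection cross-validation."""

import numpy as np
import pandas as pd
import pytest

from wmnet.errors import DegenerateInputError
from wmnet.ica import fastica_decompose
from wmnet.stability import (
    bootstrap_stability,
    cross_validate,
    match_components,
    permutation_empirical_p,
)

from conftest import sparse_mixture


def reference_with_planted_ids(X, S_true, k, seed=0):
    """Full-sample reference decomposition plus, per planted component, the
    id of the best-matching reference component (ICA order is arbitrary)."""
    ref = fastica_decompose(X, k, seed=seed)
    C = match_components(S_true, ref.sources).corr  # (ref est rows x true)
    ids = [int(np.abs(C[:, c]).argmax()) for c in range(S_true.shape[0])]
    return ref, ids


def _behavior_frame(A, slope=0.0, component=0, seed=0, measure="d_prime_2back"):
    """Behavior table with an optional planted slope on one component."""
    rng = np.random.default_rng(seed)
    m = A.shape[0]
    zA = (A - A.mean(0)) / A.std(0)
    df = pd.DataFrame(
        {
            "d_prime_2back": rng.normal(size=m),
            "d_prime_0back": rng.normal(size=m),
            "sex": (rng.random(m) < 0.6).astype(int),
            "age": rng.integers(18, 36, m).astype(float),
        }
    )
    if slope:
        df[measure] = slope * zA[:, component] + np.sqrt(1 - slope**2) * rng.normal(size=m)
    return df


class TestMatchComponents:
    def test_permuted_and_negated_rows_recovered(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(size=(4, 300))
        perm = np.array([2, 0, 3, 1])
        est = ref[perm].copy()
        est[0] *= -1
        est[3] *= -1
        match = match_components(ref, est)
        assert np.array_equal(match.mapping, perm)
        assert np.allclose(np.abs(match.r), 1.0)
        assert match.sign_flip.tolist() == [True, False, False, True]

    def test_identity(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(3, 100))
        match = match_components(ref, ref)
        assert np.array_equal(match.mapping, [0, 1, 2])
        assert np.allclose(match.r, 1.0)

    def test_greedy_equals_argmax_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            k_ref, k_est = rng.integers(2, 5), rng.integers(2, 5)
            ref = rng.normal(size=(k_ref, 50))
            est = rng.normal(size=(k_est, 50))
            match = match_components(ref, est)
            for j in range(k_est):
                rs = [abs(np.corrcoef(est[j], ref[i])[0, 1]) for i in range(k_ref)]
                assert match.mapping[j] == int(np.argmax(rs))

    def test_one_to_one_mode_is_a_bijection(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(4, 200))
        est = ref + 0.1 * rng.normal(size=(4, 200))
        match = match_components(ref, est, one_to_one=True)
        assert sorted(match.mapping) == [0, 1, 2, 3]

    def test_zero_variance_row_rejected(self):
        with pytest.raises(DegenerateInputError):
            match_components(np.zeros((2, 50)), np.ones((2, 50)))


class TestBootstrapStability:
    def test_high_snr_components_stable(self):
        X, S, _ = sparse_mixture(3, 240, 1500, 0.2 * np.sqrt(3), seed=4)
        rep = bootstrap_stability(X, k=3, subsample_size=100, n_runs=5, seed=1)
        assert rep.mean_abs_r.min() > 0.9
        assert len(rep.runs) == 15

    def test_pure_noise_components_unstable(self):
        import warnings

        X = np.random.default_rng(5).normal(size=(240, 1500))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = bootstrap_stability(
                X, k=3, subsample_size=100, n_runs=5, seed=1,
                ica_kwargs={"max_iter": 200, "n_restarts": 1},
            )
        assert rep.mean_abs_r.mean() < 0.5

    def test_subsamples_too_large_rejected(self):
        X = np.random.default_rng(6).normal(size=(50, 200))
        with pytest.raises(ValueError):
            bootstrap_stability(X, k=2, subsample_size=30, n_runs=1)

    def test_association_coefficients_aggregated(self):
        X, S, A = sparse_mixture(2, 220, 900, 0.3, seed=7)
        beh = _behavior_frame(A, slope=0.4, component=0, seed=7)
        rep = bootstrap_stability(
            X, k=2, subsample_size=100, n_runs=3, seed=2,
            behavior=beh, predictors=["d_prime_2back", "d_prime_0back"],
            covariates=["sex", "age"],
        )
        coef = rep.coefficients
        assert set(coef.predictor) == {"d_prime_2back", "d_prime_0back"}
        # the planted association must survive aggregation on some component
        planted = coef[coef.predictor == "d_prime_2back"].mean_beta.abs().max()
        assert planted > 0.2
        assert (coef.mean_se > 0).all()


class TestCrossValidation:
    def test_planted_effect_detected_in_most_runs(self):
        # beta = 0.25 at test n = 100 gives ~70% nominal power before
        # projection noise; the detection floor is 40% of runs significant.
        X, S, A = sparse_mixture(3, 300, 1200, 0.3, seed=8)
        beh = _behavior_frame(A, slope=0.25, component=0, seed=8)
        ref, ids = reference_with_planted_ids(X, S, k=3)
        rep = cross_validate(
            X, beh, test_size=100, n_runs=30, seed=3, k=3,
            components=(ids[0],), reference=ref,
        )
        row = rep.summary.query("measure == 'd_prime_2back'")
        assert row.percent_significant.iloc[0] > 40.0

    def test_null_rate_near_alpha(self):
        X, S, A = sparse_mixture(2, 260, 1000, 0.3, seed=9)
        beh = _behavior_frame(A, slope=0.0, seed=9)
        rep = cross_validate(
            X, beh, test_size=100, n_runs=50, seed=4, k=2, components=(0, 1)
        )
        # pooled over 2 components x 2 measures x 50 runs = 200 indicators
        rate = (rep.per_run.p < 0.05).mean()
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 200)

    def test_power_monotone_in_test_size(self):
        rates = {50: [], 200: []}
        for seed in range(20):
            X, S, A = sparse_mixture(2, 330, 800, 0.3, seed=200 + seed)
            beh = _behavior_frame(A, slope=0.3, component=0, seed=seed)
            ref, ids = reference_with_planted_ids(X, S, k=2, seed=seed)
            for ts in (50, 200):
                rep = cross_validate(
                    X, beh, train_size=120, test_size=ts, n_runs=5,
                    seed=seed, k=2, components=(ids[0],), reference=ref,
                )
                row = rep.summary.query("measure == 'd_prime_2back'")
                rates[ts].append(row.percent_significant.iloc[0])
        assert np.mean(rates[200]) >= np.mean(rates[50])

    def test_split_sizes_validated(self):
        X = np.random.default_rng(10).normal(size=(50, 200))
        beh = _behavior_frame(np.zeros((50, 2)) + np.random.default_rng(0).normal(size=(50, 2)))
        with pytest.raises(ValueError):
            cross_validate(X, beh, train_size=40, test_size=20, n_runs=1, k=2)


class TestPermutationEmpiricalP:
    def test_strong_effect_gets_minimum_p(self):
        X, S, A = sparse_mixture(2, 240, 900, 0.2, seed=11)
        beh = _behavior_frame(A, slope=0.5, component=0, seed=11)
        ref, ids = reference_with_planted_ids(X, S, k=2)
        rep = cross_validate(
            X, beh, test_size=80, n_runs=10, seed=5, k=2,
            components=(ids[0],), reference=ref,
        )
        out = permutation_empirical_p(rep, beh, n_outer=19, seed=6)
        row = out.query("measure == 'd_prime_2back'").iloc[0]
        assert row.observed_percent == 100.0
        assert row.empirical_p == pytest.approx(1 / 20)

    def test_null_validity_and_conservatism(self):
        # Under a global null the add-one estimator is valid
        # (P(p <= alpha) <= alpha) and, with a heavily tied discrete statistic,
        # conservative (mean p well above 0.5): checked against a Monte-Carlo
        # oracle of the tied Binomial case.
        X, S, A = sparse_mixture(2, 120, 500, 0.3, seed=12)
        ps = []
        for rep_i in range(40):
            beh = _behavior_frame(A, slope=0.0, seed=rep_i)
            rep = cross_validate(
                X, beh, test_size=50, n_runs=5, seed=rep_i, k=2, components=(0,),
                measures=("d_prime_2back",),
            )
            out = permutation_empirical_p(rep, beh, n_outer=19, seed=1000 + rep_i)
            ps.append(out.empirical_p.iloc[0])
        ps = np.array(ps)
        assert (ps <= 0.05).mean() <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / len(ps))
        assert ps.mean() > 0.5

    def test_reuses_projections_exactly(self):
        # The stored-projection shortcut must equal a naive rerun of the
        # cross-validation on permuted behavior with identical splits/seeds.
        X, S, A = sparse_mixture(2, 150, 600, 0.3, seed=13)
        beh = _behavior_frame(A, slope=0.3, component=0, seed=13)
        rep = cross_validate(X, beh, test_size=60, n_runs=4, seed=7, k=2, components=(0, 1))
        rng = np.random.default_rng(99)
        perm = rng.permutation(len(beh))
        permuted = beh.copy()
        meas = list(rep.measures)
        permuted[meas] = beh[meas].to_numpy()[perm]
        from wmnet.stability import _run_regressions

        naive = []
        for test_idx, proj in rep.runs:
            naive.extend(
                _run_regressions(proj, test_idx, permuted, rep.components, meas, rep.covariates)
            )
        # run the shortcut with the same single permutation
        out = permutation_empirical_p(rep, beh, n_outer=1, seed=99)
        nd = pd.DataFrame(naive)
        for _, row in out.iterrows():
            sel = nd.query("component == @row.component and measure == @row.measure")
            expect = 100.0 * (sel.p < 0.05).mean()
            assert row.null_mean_percent == pytest.approx(expect, abs=1e-12)

    def test_requires_at_least_one_repeat(self):
        X, S, A = sparse_mixture(2, 100, 400, 0.3, seed=14)
        beh = _behavior_frame(A)
        rep = cross_validate(X, beh, test_size=40, n_runs=2, seed=8, k=2, components=(0,))
        with pytest.raises(ValueError):
            permutation_empirical_p(rep, beh, n_outer=0)
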