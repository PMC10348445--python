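"""Pairwise maximum-entropy inference: moments, energies, fitting, KL."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from statescape.binarize import binarize
from statescape.mem import (
    MEMParameters,
    PairwiseMaxEnt,
    boltzmann_distribution,
    compute_empirical_moments,
    compute_model_moments,
    empirical_pattern_distribution,
    fit_accuracy,
    fit_independent_mem,
    fit_pairwise_mem,
    kl_divergence,
    pattern_energy,
)
from statescape.patterns import (
    code_to_pattern,
    pattern_matrix,
    pattern_to_code,
    series_to_codes,
)
from statescape.simulate import make_ising_model, sample_patterns_exact


class TestPatternCodes:
    def test_roundtrip_all_codes(self):
        for n in (2, 3, 5):
            for code in range(2**n):
                assert pattern_to_code(code_to_pattern(code, n)) == code

    def test_series_encoding_matches_rowwise(self, rng):
        values = rng.choice([-1, 1], size=(50, 6))
        codes = series_to_codes(values)
        expected = [pattern_to_code(row) for row in values]
        assert codes.tolist() == expected

    def test_pattern_matrix_rows_are_codes(self):
        S = pattern_matrix(4)
        assert S.shape == (16, 4)
        assert [pattern_to_code(row) for row in S] == list(range(16))


class TestBinarize:
    def test_row_thresholded_at_per_timepoint_mean_with_tie_to_minus(self):
        row = np.array([[1, 2, 3, 4, 5, 6, 7]], dtype=float)  # mean 4, tie at 4
        out = binarize(row)
        assert out.values.tolist() == [[-1, -1, -1, -1, 1, 1, 1]]

    def test_constant_row_is_all_inactive(self):
        out = binarize(np.full((3, 5), 2.0))
        assert (out.values == -1).all()

    def test_per_node_temporal_mean_mode(self):
        sig = np.array([[0.0, 10.0], [2.0, 10.0], [4.0, 10.0]])
        out = binarize(sig, mode="per-node-temporal-mean")
        # node 0 mean 2 -> (-1, -1, +1); node 1 constant -> ties -> -1
        assert out.values[:, 0].tolist() == [-1, -1, 1]
        assert (out.values[:, 1] == -1).all()

    def test_nonfinite_entries_rejected(self):
        sig = np.ones((4, 3))
        sig[1, 2] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            binarize(sig)

    def test_tsv_roundtrip(self, tmp_path, rng):
        from statescape.binarize import BinaryTimeSeries

        series = binarize(rng.normal(size=(20, 4)), node_names=list("wxyz"))
        path = tmp_path / "binary.tsv"
        series.to_tsv(path)
        back = BinaryTimeSeries.from_tsv(path)
        assert (back.values == series.values).all()
        assert back.node_names == series.node_names

    def test_roundtrip_through_noiseless_continuous(self, rng):
        from statescape.simulate import binary_to_continuous

        patterns = rng.choice([-1, 1], size=(200, 7))
        # rows with at least one sign change recover exactly at huge snr
        mixed = patterns[np.abs(patterns.sum(axis=1)) < 7]
        recovered = binarize(binary_to_continuous(mixed, snr=1e6, seed=0))
        assert (recovered.values == mixed).all()


class TestMoments:
    def test_all_active_rows(self):
        m = compute_empirical_moments(np.ones((5, 4)))
        assert np.allclose(m.mean_activity, 1.0)
        assert np.allclose(m.pairwise, 1.0)

    def test_opposite_rows_cancel_means_not_products(self):
        series = np.vstack([np.ones((1, 3)), -np.ones((1, 3))])
        m = compute_empirical_moments(series)
        assert np.allclose(m.mean_activity, 0.0)
        assert np.allclose(m.pairwise, 1.0)

    def test_matches_double_loop_oracle(self, rng):
        values = rng.choice([-1, 1], size=(40, 5)).astype(float)
        m = compute_empirical_moments(values)
        T, N = values.shape
        mean = np.zeros(N)
        pair = np.zeros((N, N))
        for t in range(T):  # independent brute-force computation
            for i in range(N):
                mean[i] += values[t, i] / T
                for j in range(N):
                    pair[i, j] += values[t, i] * values[t, j] / T
        assert np.allclose(m.mean_activity, mean)
        assert np.allclose(m.pairwise, pair)

    def test_concatenation_is_row_stacking(self, rng):
        a = rng.choice([-1, 1], size=(30, 4))
        b = rng.choice([-1, 1], size=(20, 4))
        pooled = compute_empirical_moments([a, b])
        stacked = compute_empirical_moments(np.vstack([a, b]))
        assert np.allclose(pooled.mean_activity, stacked.mean_activity)
        assert pooled.n_samples == 50

    def test_node_count_mismatch_rejected(self, rng):
        a = rng.choice([-1, 1], size=(10, 4))
        b = rng.choice([-1, 1], size=(10, 5))
        with pytest.raises(ValueError, match="node count"):
            compute_empirical_moments([a, b])


class TestEnergy:
    def test_zero_parameters_zero_energy(self):
        params = MEMParameters(h=np.zeros(4), J=np.zeros((4, 4)))
        for code in range(16):
            assert pattern_energy(code_to_pattern(code, 4), params) == 0.0

    def test_hand_computed_two_node_energy(self):
        params = MEMParameters(
            h=np.array([1.0, -1.0]), J=np.array([[0.0, 0.5], [0.5, 0.0]])
        )
        # E = -(1*1 + (-1)*1) - 0.5*1*1 = -0.5 for (+1, +1)
        assert pattern_energy(np.array([1, 1]), params) == pytest.approx(-0.5)

    def test_spin_flip_symmetry_at_zero_field(self, rng):
        J = rng.normal(size=(5, 5)) * 0.3
        J = np.triu(J, 1)
        J = J + J.T
        params = MEMParameters(h=np.zeros(5), J=J)
        for code in range(32):
            v = code_to_pattern(code, 5)
            assert pattern_energy(v, params) == pytest.approx(
                pattern_energy(-v, params)
            )


class TestBoltzmann:
    def test_uniform_at_zero_parameters(self):
        params = MEMParameters(h=np.zeros(7), J=np.zeros((7, 7)))
        dist = boltzmann_distribution(params)
        assert dist.probabilities.shape == (128,)
        assert np.allclose(dist.probabilities, 1 / 128)

    def test_matches_naive_unstabilized_computation(self, small_params):
        dist = boltzmann_distribution(small_params)
        S = pattern_matrix(3).astype(float)
        naive = np.array(
            [
                np.exp(
                    small_params.h @ s + 0.5 * s @ small_params.J @ s
                )
                for s in S
            ]
        )
        naive /= naive.sum()
        assert np.abs(dist.probabilities - naive).max() < 1e-10

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_normalization_for_random_parameters(self, seed):
        model = make_ising_model(5, 1.0, 1.0, seed=seed)
        probs = boltzmann_distribution(model.params()).probabilities
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert (probs >= 0).all()


class TestModelMoments:
    def test_zero_parameters_give_zero_moments(self):
        params = MEMParameters(h=np.zeros(4), J=np.zeros((4, 4)))
        m = compute_model_moments(params)
        assert np.allclose(m.mean_activity, 0.0)
        off = m.pairwise[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 0.0)

    def test_independent_spins_match_tanh(self):
        params = MEMParameters(h=np.full(3, 0.5), J=np.zeros((3, 3)))
        m = compute_model_moments(params)
        assert np.allclose(m.mean_activity, np.tanh(0.5), atol=1e-12)

    def test_matches_monte_carlo_from_exact_sampler(self, seven_node_model):
        m = compute_model_moments(seven_node_model.params())
        samples = sample_patterns_exact(seven_node_model, 200_000, seed=3)
        emp = compute_empirical_moments(samples)
        assert np.abs(emp.mean_activity - m.mean_activity).max() < 0.01
        assert np.abs(emp.pairwise - m.pairwise).max() < 0.01


class TestFitting:
    def test_independent_fit_inverts_tanh(self):
        params = MEMParameters(h=np.full(4, 0.5), J=np.zeros((4, 4)))
        m = compute_model_moments(params)
        fit = fit_independent_mem(m)
        assert np.allclose(fit.h, 0.5, atol=1e-12)
        assert fit.order == "first"
        refit = compute_model_moments(fit)
        assert np.abs(refit.mean_activity - m.mean_activity).max() < 1e-10

    def test_zero_moments_give_zero_parameters(self):
        m = compute_model_moments(MEMParameters(h=np.zeros(3), J=np.zeros((3, 3))))
        params, diag = fit_pairwise_mem(m)
        assert diag.converged and diag.n_iterations == 1
        assert np.allclose(params.h, 0.0) and np.allclose(params.J, 0.0)

    @pytest.mark.parametrize("n_nodes", [3, 5, 7])
    def test_exact_moment_recovery(self, n_nodes):
        truth = make_ising_model(n_nodes, 0.3, 0.3, seed=n_nodes)
        m = compute_model_moments(truth.params())
        params, diag = fit_pairwise_mem(m, tol=1e-8)
        assert diag.converged
        assert np.abs(params.h - truth.h).max() < 1e-4
        assert np.abs(params.J - truth.J).max() < 1e-4

    def test_sampled_moment_recovery_within_sampling_noise(self):
        truth = make_ising_model(7, 0.3, 0.3, seed=11)
        samples = sample_patterns_exact(truth, 50_000, seed=4)
        m = compute_empirical_moments(samples)
        params, diag = fit_pairwise_mem(m)
        assert diag.converged
        assert np.abs(params.h - truth.h).max() < 0.1
        assert np.abs(params.J - truth.J).max() < 0.1

    def test_nonconvergence_reported_not_raised(self):
        truth = make_ising_model(4, 0.3, 0.3, seed=0)
        m = compute_model_moments(truth.params())
        with pytest.warns(RuntimeWarning, match="did not reach"):
            _, diag = fit_pairwise_mem(m, max_iter=3)
        assert not diag.converged
        assert diag.n_iterations == 3


class TestDistributionsAndKL:
    def test_single_row_distribution_is_point_mass(self):
        dist = empirical_pattern_distribution(np.ones((1, 3)))
        assert dist.probabilities[7] == 1.0
        assert dist.probabilities.sum() == 1.0

    def test_matches_hash_count_oracle(self, rng):
        values = rng.choice([-1, 1], size=(500, 4))
        dist = empirical_pattern_distribution(values)
        counts = {}
        for row in values:
            counts[pattern_to_code(row)] = counts.get(pattern_to_code(row), 0) + 1
        for code in range(16):
            assert dist.probabilities[code] == pytest.approx(
                counts.get(code, 0) / 500
            )

    def test_kl_zero_for_identical(self, small_params):
        d = boltzmann_distribution(small_params)
        assert kl_divergence(d, d) == pytest.approx(0.0, abs=1e-14)

    def test_kl_point_mass_vs_fair_coin_is_log2(self):
        from statescape.mem import PatternDistribution

        p = PatternDistribution(probabilities=np.array([1.0, 0.0]), n_nodes=1)
        q = PatternDistribution(probabilities=np.array([0.5, 0.5]), n_nodes=1)
        assert kl_divergence(p, q) == pytest.approx(np.log(2))

    def test_kl_support_violation_raises(self):
        from statescape.mem import PatternDistribution

        p = PatternDistribution(probabilities=np.array([1.0, 0.0]), n_nodes=1)
        q = PatternDistribution(probabilities=np.array([0.0, 1.0]), n_nodes=1)
        with pytest.raises(ValueError, match="support"):
            kl_divergence(p, q)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_kl_nonnegative_gibbs_inequality(self, seed):
        r = np.random.default_rng(seed)
        p = r.dirichlet(np.ones(8))
        q = r.dirichlet(np.ones(8))
        from statescape.mem import PatternDistribution

        kl = kl_divergence(
            PatternDistribution(probabilities=p, n_nodes=3),
            PatternDistribution(probabilities=q, n_nodes=3),
        )
        assert kl >= -1e-12


class TestFitAccuracy:
    def test_accuracy_is_one_when_pairwise_model_realizable(self, small_params):
        emp = boltzmann_distribution(small_params)  # lies in the pairwise family
        m = compute_model_moments(small_params)
        first = fit_independent_mem(m)
        pair, _ = fit_pairwise_mem(m)
        diag = fit_accuracy(emp, first, pair)
        assert not diag.undefined
        assert diag.accuracy == pytest.approx(1.0, abs=1e-4)
        assert diag.d2 <= diag.d1

    def test_uniform_empirical_flags_undefined(self):
        params = MEMParameters(h=np.zeros(3), J=np.zeros((3, 3)))
        emp = boltzmann_distribution(params)
        diag = fit_accuracy(emp, params, params)
        assert diag.undefined
        assert diag.accuracy is None

    def test_pairwise_never_worse_than_independent(self, rng):
        # D2 <= D1 because the pairwise family contains the independent one
        for seed in range(5):
            truth = make_ising_model(4, 0.5, 0.5, seed=seed)
            samples = sample_patterns_exact(truth, 3000, seed=seed)
            emp = empirical_pattern_distribution(samples)
            m = compute_empirical_moments(samples)
            diag = fit_accuracy(emp, fit_independent_mem(m), fit_pairwise_mem(m)[0])
            assert diag.d2 <= diag.d1 + 1e-9


class TestModelObject:
    def test_fit_reports_accuracy_and_summary(self):
        truth = make_ising_model(5, 0.3, 0.3, seed=2)
        samples = sample_patterns_exact(truth, 20_000, seed=2)
        res = PairwiseMaxEnt(samples).fit()
        assert res.diagnostics.converged
        assert res.diagnostics.accuracy is not None
        text = res.summary()
        assert "fit accuracy" in text and "h (basal activity)" in text

    def test_small_sample_warning_threshold(self, rng):
        data = rng.choice([-1, 1], size=(30, 7))  # < 2**6 timepoints
        with pytest.warns(RuntimeWarning, match="2\\*\\*\\(N-1\\)"):
            PairwiseMaxEnt(data)

    def test_json_roundtrip(self, tmp_path):
        truth = make_ising_model(4, 0.3, 0.3, seed=5)
        samples = sample_patterns_exact(truth, 5000, seed=5)
        res = PairwiseMaxEnt(samples).fit()
        path = tmp_path / "model.json"
        res.save(path)
        params, names = res.load_params(path)
        assert np.allclose(params.h, res.h)
        assert np.allclose(params.J, res.J)
        assert names == res.node_names
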