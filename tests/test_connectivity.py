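"""Dependency estimators: correlation, coherence, phase order, SL.

Includes brute-force double-loop oracles for the correlation integral and
synchronization likelihood, and the analytic floors for coherence (1/K
segment bias) and the phase order parameter (mean resultant length of
uniform phases).
"""

import numpy as np
import pytest

from fconnet import (
    EpochSet,
    SLParams,
    correlation_integral,
    critical_radius,
    embed,
    hilbert_phase,
    pearson_matrix,
    phase_order_matrix,
    coherence_matrix,
    subject_connectivity,
    sync_likelihood_matrix,
)
from fconnet.connectivity import (
    coherence_spectrum,
    phase_edge_slice,
    phase_order_pair,
    sl_pair,
)
from fconnet.preproc import ValidationError


def epochset(epochs, fs=500.0):
    epochs = np.asarray(epochs, dtype=float)
    return EpochSet(epochs=epochs, fs_hz=fs, epoch_len_s=epochs.shape[2] / fs)


# ---------------------------------------------------------------------------
# brute-force oracles


def ci_oracle(vectors, r, w_excl):
    """O(N^2) double loop over admissible pairs, strict distance inequality."""
    n = len(vectors)
    count = total = 0
    for t in range(n):
        for s in range(t + 1, n):
            if s - t <= w_excl:
                continue
            total += 1
            if np.linalg.norm(vectors[t] - vectors[s]) < r:
                count += 1
    return count / total


def sl_oracle(vec_i, vec_j, params):
    """Exhaustive SL: quantile radii then conditional counts by double loop."""
    n = len(vec_i)
    w_excl = int(np.ceil(params.theiler_w * n))
    pairs = [
        (t, s) for t in range(n) for s in range(t + 1, n) if s - t > w_excl
    ]
    d_i = np.array([np.linalg.norm(vec_i[t] - vec_i[s]) for t, s in pairs])
    d_j = np.array([np.linalg.norm(vec_j[t] - vec_j[s]) for t, s in pairs])

    def radius(d):
        k = int(round(params.p_ref * len(d)))
        ds = np.sort(d)
        return ds[k] if k < len(d) else ds[-1] * (1 + 1e-12) + 1e-300

    r_i, r_j = radius(d_i), radius(d_j)
    both = int(((d_i < r_i) & (d_j < r_j)).sum())
    return 0.5 * (both / (d_j < r_j).sum() + both / (d_i < r_i).sum())


# ---------------------------------------------------------------------------


class TestPearson:
    def test_identical_channels_fully_correlated(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(200)
        w = pearson_matrix(np.stack([x, x.copy(), rng.standard_normal(200)]))
        assert w[0, 1] == pytest.approx(1.0)

    def test_sign_flip_gives_unit_magnitude(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(200)
        w = pearson_matrix(np.stack([x, -x]))
        assert w[0, 1] == pytest.approx(1.0)
        w_pos = pearson_matrix(np.stack([x, -x]), mode="positive")
        assert w_pos[0, 1] == 0.0

    def test_independent_noise_within_fisher_bound(self):
        rng = np.random.default_rng(2)
        t = 10000
        w = pearson_matrix(rng.standard_normal((2, t)))
        assert w[0, 1] < 3 / np.sqrt(t)

    def test_zero_variance_channel_named_in_error(self):
        data = np.zeros((3, 100))
        data[0] = np.random.default_rng(3).standard_normal(100)
        data[2] = np.random.default_rng(4).standard_normal(100)
        with pytest.raises(ValidationError, match=r"\[1\]"):
            pearson_matrix(data)


class TestCoherence:
    def test_identical_channels_have_unit_coherence(self):
        rng = np.random.default_rng(5)
        eps = rng.standard_normal((10, 1, 500))
        es = epochset(np.concatenate([eps, eps.copy()], axis=1))
        w = coherence_matrix(es, band_hz=(7, 13))
        assert w[0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_independent_noise_near_segment_bias_floor(self):
        rng = np.random.default_rng(6)
        es = epochset(rng.standard_normal((60, 2, 500)))
        w = coherence_matrix(es, band_hz=(7, 13))
        assert w[0, 1] < 0.1
        assert w[0, 1] == pytest.approx(1 / 60, rel=2.0)  # K-segment bias ~ 1/K

    def test_all_values_bounded_by_one(self):
        rng = np.random.default_rng(7)
        es = epochset(rng.standard_normal((5, 4, 128)))
        _, coh = coherence_spectrum(es)
        assert coh.max() <= 1.0

    def test_single_epoch_rejected(self):
        rng = np.random.default_rng(8)
        es = epochset(rng.standard_normal((1, 2, 128)))
        with pytest.raises(ValidationError, match="multiple epochs"):
            coherence_matrix(es)


class TestHilbertPhase:
    def test_instantaneous_frequency_of_sinusoid(self):
        fs, f = 500.0, 10.0
        t = np.arange(500) / fs
        phi = hilbert_phase(np.sin(2 * np.pi * f * t), unwrap=True)
        keep = phase_edge_slice(500)
        inst_freq = np.diff(phi[keep]) * fs / (2 * np.pi)
        assert np.allclose(inst_freq, f, atol=0.5)

    def test_quadrature_pair_offset_by_half_pi(self):
        fs, f = 500.0, 10.0
        t = np.arange(500) / fs
        pc = hilbert_phase(np.cos(2 * np.pi * f * t))
        ps = hilbert_phase(np.sin(2 * np.pi * f * t))
        keep = phase_edge_slice(500)
        diff = np.angle(np.exp(1j * (pc[keep] - ps[keep])))
        assert np.allclose(diff, np.pi / 2, atol=0.05)

    def test_phase_range(self):
        rng = np.random.default_rng(9)
        phi = hilbert_phase(rng.standard_normal(300))
        assert (phi > -np.pi).all() and (phi <= np.pi).all()

    def test_constant_series_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            hilbert_phase(np.ones(100))


class TestPhaseOrder:
    def test_identical_phases_give_unity(self):
        rng = np.random.default_rng(10)
        phi = rng.uniform(-np.pi, np.pi, 500)
        assert phase_order_pair(phi, phi) == pytest.approx(1.0, abs=1e-12)

    def test_constant_phase_lag_still_locked(self):
        rng = np.random.default_rng(11)
        phi = rng.uniform(-np.pi, np.pi, 500)
        assert phase_order_pair(phi, phi - np.pi) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_random_phases_match_resultant_length(self):
        """E[P] for independent uniform phases ~ sqrt(pi)/(2 sqrt(T))."""
        rng = np.random.default_rng(12)
        t_len = 500
        vals = [
            phase_order_pair(
                rng.uniform(-np.pi, np.pi, t_len), rng.uniform(-np.pi, np.pi, t_len)
            )
            for _ in range(400)
        ]
        expected = np.sqrt(np.pi) / (2 * np.sqrt(t_len))
        assert np.mean(vals) == pytest.approx(expected, rel=0.1)

    def test_matrix_on_quadrature_channels(self):
        fs = 500.0
        t = np.arange(1000) / fs
        epochs = np.stack(
            [np.sin(2 * np.pi * 10 * t), np.cos(2 * np.pi * 10 * t)]
        )[None]
        w = phase_order_matrix(epochset(epochs, fs))
        assert w[0, 1] == pytest.approx(1.0, abs=1e-3)


class TestEmbedding:
    def test_vector_count_with_default_parameters(self):
        vecs = embed(np.arange(500.0), SLParams())
        assert vecs.shape == (410, 10)

    def test_degenerate_dimension_one(self):
        x = np.arange(20.0)
        vecs = embed(x, SLParams(embed_e=1, lag_L=3))
        assert vecs.shape == (20, 1)
        assert np.array_equal(vecs[:, 0], x)

    def test_micro_example(self):
        vecs = embed(np.array([1.0, 2.0, 3.0]), SLParams(embed_e=2, lag_L=1))
        assert np.array_equal(vecs, [[1, 2], [2, 3]])

    def test_too_short_series_reports_minimum(self):
        with pytest.raises(ValidationError, match="T >"):
            embed(np.arange(50.0), SLParams())


class TestCorrelationIntegral:
    def test_radius_beyond_diameter_gives_one(self, rng):
        vecs = rng.standard_normal((15, 3))
        params = SLParams(theiler_w=0.1)
        assert correlation_integral(vecs, 1e6, params) == 1.0

    def test_zero_radius_gives_zero(self, rng):
        vecs = rng.standard_normal((15, 3))
        assert correlation_integral(vecs, 0.0, SLParams()) == 0.0

    @pytest.mark.parametrize("r", [0.5, 1.0, 2.0])
    def test_matches_double_loop_oracle(self, rng, r):
        vecs = rng.standard_normal((10, 4))
        params = SLParams(theiler_w=0.1)
        w_excl = int(np.ceil(0.1 * 10))
        assert correlation_integral(vecs, r, params) == ci_oracle(vecs, r, w_excl)

    def test_critical_radius_round_trip(self, rng):
        vecs = rng.standard_normal((40, 3))
        for p_ref in (0.05, 0.25, 0.6):
            params = SLParams(p_ref=p_ref)
            r = critical_radius(vecs, params)
            ci = correlation_integral(vecs, r, params)
            assert abs(ci - p_ref) <= 1.0 / 100  # well within 1/n_pairs slack

    def test_p_ref_one_covers_everything(self, rng):
        vecs = rng.standard_normal((20, 2))
        params = SLParams(p_ref=0.999999)
        r = critical_radius(vecs, params)
        assert correlation_integral(vecs, r, params) == 1.0

    def test_p_ref_below_resolution_warns(self, rng):
        vecs = rng.standard_normal((8, 2))
        with pytest.warns(UserWarning, match="resolution"):
            critical_radius(vecs, SLParams(p_ref=0.001))


class TestSyncLikelihood:
    def test_identical_channels_reach_maximum(self):
        rng = np.random.default_rng(13)
        x = rng.standard_normal(500)
        vecs = embed(x, SLParams())
        assert sl_pair(vecs, vecs.copy(), SLParams()) == 1.0

    def test_independent_noise_near_p_ref(self):
        rng = np.random.default_rng(14)
        params = SLParams()
        vals = []
        for _ in range(30):
            vi = embed(rng.standard_normal(500), params)
            vj = embed(rng.standard_normal(500), params)
            vals.append(sl_pair(vi, vj, params))
        assert np.mean(vals) == pytest.approx(params.p_ref, abs=0.005)

    def test_toy_pair_matches_exhaustive_enumeration(self):
        params = SLParams(p_ref=0.4, lag_L=1, embed_e=2, theiler_w=0.1)
        x = np.array([0.1, 1.2, -0.3, 0.8, 0.05])
        y = np.array([1.0, -0.5, 0.2, 0.9, -1.1])
        vi, vj = embed(x, params), embed(y, params)
        assert sl_pair(vi, vj, params) == pytest.approx(
            sl_oracle(vi, vj, params), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(4))
    def test_random_instances_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        params = SLParams(p_ref=0.1, lag_L=2, embed_e=3, theiler_w=0.1)
        x, y = rng.standard_normal((2, 24))
        vi, vj = embed(x, params), embed(y, params)
        assert sl_pair(vi, vj, params) == pytest.approx(
            sl_oracle(vi, vj, params), abs=1e-12
        )

    def test_matrix_agrees_with_pairwise_computation(self):
        rng = np.random.default_rng(15)
        epochs = rng.standard_normal((1, 4, 200))
        params = SLParams(lag_L=3, embed_e=4)
        w = sync_likelihood_matrix(epochset(epochs), params)
        for i in range(4):
            for j in range(i + 1, 4):
                expected = sl_pair(
                    embed(epochs[0, i], params), embed(epochs[0, j], params), params
                )
                assert w[i, j] == pytest.approx(expected, abs=1e-6)


class TestSubjectConnectivity:
    def test_single_epoch_correlation_equals_pearson(self):
        rng = np.random.default_rng(16)
        epochs = rng.standard_normal((1, 3, 250))
        cm = subject_connectivity(epochset(epochs), "correlation")
        assert np.allclose(cm.weights, pearson_matrix(epochs[0]))
        assert cm.n_epochs_used == 1

    def test_epoch_average_is_elementwise_mean(self):
        rng = np.random.default_rng(17)
        epochs = rng.standard_normal((2, 3, 250))
        cm = subject_connectivity(epochset(epochs), "correlation")
        expected = (pearson_matrix(epochs[0]) + pearson_matrix(epochs[1])) / 2
        assert np.allclose(cm.weights, expected)

    def test_masked_epochs_excluded(self):
        rng = np.random.default_rng(18)
        epochs = rng.standard_normal((4, 3, 250))
        es = epochset(epochs)
        es.artifact_mask[2:] = True
        cm = subject_connectivity(es, "correlation")
        expected = (pearson_matrix(epochs[0]) + pearson_matrix(epochs[1])) / 2
        assert cm.n_epochs_used == 2
        assert np.allclose(cm.weights, expected)

    def test_unknown_estimator_lists_valid_names(self):
        rng = np.random.default_rng(19)
        es = epochset(rng.standard_normal((2, 2, 100)))
        with pytest.raises(ValidationError, match="sync_likelihood"):
            subject_connectivity(es, "granger")


@pytest.fixture(scope="module")
def small_epochs():
    rng = np.random.default_rng(20)
    return epochset(rng.standard_normal((4, 5, 250)))


class TestEstimatorProperties:
    @pytest.mark.parametrize(
        "estimator", ["correlation", "coherence", "phase_order", "sync_likelihood"]
    )
    def test_symmetry_and_range(self, small_epochs, estimator):
        params = SLParams(lag_L=2, embed_e=3)
        cm = subject_connectivity(small_epochs, estimator, params=params)
        w = cm.weights
        assert np.allclose(w, w.T, atol=1e-12)
        assert (np.diag(w) == 0).all()
        assert w.min() >= 0.0 and w.max() <= 1.0

    def test_amplitude_scaling_invariance(self, small_epochs):
        scale = np.array([0.5, 3.0, 10.0, 0.1, 1.0])[None, :, None]
        scaled = epochset(small_epochs.epochs * scale)
        for estimator in ("correlation", "coherence", "phase_order"):
            w0 = subject_connectivity(small_epochs, estimator).weights
            w1 = subject_connectivity(scaled, estimator).weights
            assert np.allclose(w0, w1, atol=1e-9), estimator

    def test_planted_pairs_rank_above_uncoupled(self, paired_epochs):
        """Every estimator separates coupled from uncoupled pairs, AUC > 0.9."""
        es, coupled = paired_epochs
        iu = list(zip(*np.triu_indices(16, 1)))
        for estimator in (
            "correlation",
            "coherence",
            "phase_order",
            "sync_likelihood",
        ):
            w = subject_connectivity(es, estimator).weights
            c = np.array([w[i, j] for i, j in iu if (i, j) in coupled])
            u = np.array([w[i, j] for i, j in iu if (i, j) not in coupled])
            auc = (c[:, None] > u[None, :]).mean()
            assert auc > 0.9, f"{estimator}: AUC={auc}"
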