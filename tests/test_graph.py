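import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from netctrl.graph import (
    Connectome,
    DegenerateInputError,
    DisconnectedGraphError,
    build_consensus,
    effective_resistance_matrix,
    network_variance,
    node_metrics,
    normalize_adjacency,
)
from netctrl.synth import GeneratorConfig, make_dataset

from _oracles import brute_effective_resistance, brute_network_variance


def ring(n, w=1.0):
    a = np.zeros((n, n))
    for i in range(n):
        a[i, (i + 1) % n] = a[(i + 1) % n, i] = w
    return a


class TestNormalization:
    def test_two_node_c_zero(self):
        conn = Connectome(weights=np.array([[0.0, 1.0], [1.0, 0.0]]))
        sys_ = normalize_adjacency(conn, c=0.0)
        assert np.allclose(sys_.a_norm, [[-1, 1], [1, -1]])
        assert np.max(np.linalg.eigvalsh(sys_.a_norm)) == pytest.approx(0.0, abs=1e-12)

    def test_relative_c_shifts_leading_mode(self):
        conn = Connectome(weights=ring(6))
        sys_ = normalize_adjacency(conn, c=0.01, relative=True)
        lead = np.max(np.real(np.linalg.eigvals(sys_.a_norm)))
        assert lead == pytest.approx(1 / 1.01 - 1, abs=1e-12)

    def test_spectral_invariant_random(self, rng):
        a = np.abs(rng.normal(size=(10, 10)))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        conn = Connectome(weights=a)
        for c in (0.0, 0.5, 2.0):
            sys_ = normalize_adjacency(conn, c=c)
            lead = np.max(np.real(np.linalg.eigvals(sys_.a_norm)))
            assert lead == pytest.approx(
                sys_.lambda_max / (sys_.lambda_max + c) - 1, abs=1e-10
            )

    def test_zero_adjacency_rejected(self):
        with pytest.raises(DegenerateInputError):
            normalize_adjacency(Connectome(weights=np.zeros((4, 4))))


class TestEffectiveResistance:
    def test_single_edge_is_inverse_weight(self):
        conn = Connectome(weights=np.array([[0.0, 2.0], [2.0, 0.0]]))
        omega = effective_resistance_matrix(conn).omega
        assert omega[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_path_of_three_resistances_add(self):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = a[1, 2] = a[2, 1] = 1.0
        omega = effective_resistance_matrix(Connectome(weights=a)).omega
        assert omega[0, 2] == pytest.approx(2.0, abs=1e-10)

    def test_complete_graph_closed_form(self):
        for n in (4, 7):
            a = np.ones((n, n)) - np.eye(n)
            omega = effective_resistance_matrix(Connectome(weights=a)).omega
            off = omega[~np.eye(n, dtype=bool)]
            assert np.allclose(off, 2.0 / n, atol=1e-10)

    def test_matches_bruteforce_on_random_small_graphs(self, rng):
        for n in (5, 8, 12):
            a = (rng.random((n, n)) < 0.5) * rng.random((n, n))
            a = np.triu(a, 1)
            a = a + a.T
            # ensure connectivity via a ring backbone
            a += ring(n, 0.3)
            omega = effective_resistance_matrix(Connectome(weights=a)).omega
            assert np.allclose(omega, brute_effective_resistance(a), atol=1e-10)

    def test_triangle_inequality_on_small_graphs(self, rng):
        a = ring(6) + np.triu((rng.random((6, 6)) < 0.4) * rng.random((6, 6)), 1)
        a = np.triu(a, 1) + np.triu(a, 1).T
        omega = effective_resistance_matrix(Connectome(weights=a)).omega
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert omega[i, j] <= omega[i, k] + omega[k, j] + 1e-12

    def test_disconnected_graph_reports_components(self):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 1.0
        a[2, 3] = a[3, 2] = 1.0
        with pytest.raises(DisconnectedGraphError) as exc:
            effective_resistance_matrix(Connectome(weights=a))
        assert len(exc.value.components) == 2


class TestNetworkVariance:
    def test_point_mass_is_zero(self):
        a = np.ones((4, 4)) - np.eye(4)
        dist = effective_resistance_matrix(Connectome(weights=a))
        v = np.array([0.0, 0.0, 5.0, 0.0])
        assert network_variance(dist, v) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_on_k4(self):
        a = np.ones((4, 4)) - np.eye(4)
        dist = effective_resistance_matrix(Connectome(weights=a))
        got = network_variance(dist, np.full(4, 0.25), rescale=False)
        assert got == pytest.approx(3 / 16, abs=1e-12)

    def test_uniform_closed_forms_on_complete_graphs(self):
        # uniform p on K_n has variance (n-1)/n^2
        for n in (2, 4, 6):
            a = np.ones((n, n)) - np.eye(n)
            dist = effective_resistance_matrix(Connectome(weights=a))
            got = network_variance(dist, np.full(n, 1.0 / n), rescale=False)
            assert got == pytest.approx((n - 1) / n**2, abs=1e-10)

    def test_two_node_uniform(self):
        a = np.array([[0.0, 1.0], [1.0, 0.0]])
        dist = effective_resistance_matrix(Connectome(weights=a))
        got = network_variance(dist, np.array([0.5, 0.5]), rescale=False)
        assert got == pytest.approx(0.25, abs=1e-12)

    def test_matches_double_sum_oracle(self, rng):
        for n in (5, 9, 12):
            a = ring(n) + np.triu((rng.random((n, n)) < 0.4) * rng.random((n, n)), 1)
            a = np.triu(a, 1) + np.triu(a, 1).T
            dist = effective_resistance_matrix(Connectome(weights=a))
            v = rng.random(n) * 3
            assert network_variance(dist, v) == pytest.approx(
                brute_network_variance(dist.omega, v), abs=1e-10
            )

    def test_constant_map_rejected(self):
        a = np.ones((3, 3)) - np.eye(3)
        dist = effective_resistance_matrix(Connectome(weights=a))
        with pytest.raises(DegenerateInputError):
            network_variance(dist, np.full(3, 2.5))


class TestNodeMetrics:
    def test_star_center_degree(self):
        n = 6
        a = np.zeros((n, n))
        a[0, 1:] = a[1:, 0] = 1.0
        m = node_metrics(Connectome(weights=a), np.zeros(n))
        assert m.binary_degree[0] == n - 1
        assert m.strength[0] == pytest.approx(n - 1)

    def test_participation_extremes(self):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 2.0  # node 0: all strength in module 0
        a[2, 0] = a[0, 2] = 2.0  # node 0 gains strength in module 1
        part = np.array([0, 0, 1, 1])
        m = node_metrics(Connectome(weights=a), part)
        assert m.participation[0] == pytest.approx(0.5)  # split equally
        assert m.participation[1] == pytest.approx(0.0)  # all in own module
        assert m.participation[3] == 0.0  # isolated node

    def test_partition_must_cover(self):
        a = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(ValueError):
            node_metrics(Connectome(weights=a), [0, 1])


class TestConsensus:
    def test_single_participant_identity(self, small_dataset):
        base = small_dataset.connectome
        cons = build_consensus(
            [base.weights], base.coords3d, base.hemisphere, n_bins=8
        )
        assert np.allclose(cons.weights, base.weights)

    def test_identical_participants_identity(self, small_dataset):
        base = small_dataset.connectome
        cons = build_consensus(
            [base.weights] * 5, base.coords3d, base.hemisphere, n_bins=8
        )
        assert np.allclose(cons.weights, base.weights)

    def test_density_and_length_distribution_preserved(self):
        from scipy.stats import ks_2samp

        from netctrl.synth import make_coordinates, make_connectome, make_participant_ensemble

        coords, hemi, sphere = make_coordinates(40, 5)
        base = make_connectome(coords, 0.25, 40.0, 6, hemisphere=hemi)
        parts = make_participant_ensemble(base, 20, noise_sd=0.3, seed=8)
        cons = build_consensus(
            [p.weights for p in parts], coords, hemi
        )
        mean_density = np.mean([p.density for p in parts])
        assert abs(cons.density - mean_density) < 0.01
        pooled = np.concatenate([p.edge_lengths() for p in parts])
        ks = ks_2samp(cons.edge_lengths(), pooled).statistic
        assert ks < 0.15

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            build_consensus(
                [np.zeros((3, 3)), np.zeros((4, 4))],
                np.zeros((3, 3)),
                ["L", "L", "R"],
            )

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            build_consensus([], np.zeros((0, 3)), [])


class TestConnectomeValidation:
    def test_asymmetry_warns_and_symmetrizes(self):
        a = np.array([[0.0, 1.0], [1.1, 0.0]])
        with pytest.warns(UserWarning, match="asymmetry"):
            conn = Connectome(weights=a)
        assert np.allclose(conn.weights, conn.weights.T)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            Connectome(weights=np.array([[0.0, -1.0], [-1.0, 0.0]]))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_normalization_invariant_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 12))
        a = np.abs(rng.normal(size=(n, n)))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        c = float(rng.uniform(0, 3))
        sys_ = normalize_adjacency(Connectome(weights=a), c=c)
        lead = np.max(np.real(np.linalg.eigvals(sys_.a_norm)))
        assert lead == pytest.approx(sys_.lambda_max / (sys_.lambda_max + c) - 1, abs=1e-9)
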