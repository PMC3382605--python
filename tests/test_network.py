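import numpy as np
import pytest

from demewar import (
    export_network,
    generate_er,
    generate_island,
    generate_scale_free,
    load_network,
    migrate,
)
from conftest import state_from


class TestGenerateER:
    def test_p_equal_one_gives_complete_graph(self, rng):
        net = generate_er(6, 5.0, rng)
        assert (net.degrees() == 5).all()

    def test_z_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError):
            generate_er(10, 0.0, rng)
        with pytest.raises(ValueError):
            generate_er(10, 10.0, rng)

    def test_mean_degree_close_to_z(self):
        # 20 seeds at D=500, z=4: sample mean within 4 SE of 4
        means = [
            generate_er(500, 4.0, np.random.default_rng(s)).degrees().mean()
            for s in range(20)
        ]
        # per-graph variance of mean degree ~ 2z/D; 20 graphs shrink it further
        se = np.sqrt(2 * 4.0 / 500 / 20)
        assert abs(np.mean(means) - 4.0) < 4 * se

    def test_resample_isolated_guarantees_min_degree_one(self):
        net = generate_er(30, 1.5, np.random.default_rng(0), resample_isolated=True)
        assert net.degrees().min() >= 1


class TestGenerateIsland:
    def test_complete_graph_edge_count(self):
        net = generate_island(5)
        assert len(net.edge_set()) == 10
        assert (net.degrees() == 4).all()

    def test_two_demes_single_edge(self):
        net = generate_island(2)
        assert net.edge_set() == {(0, 1)}

    def test_rejects_single_deme(self):
        with pytest.raises(ValueError):
            generate_island(1)


class TestGenerateScaleFree:
    def test_edge_count_and_mean_degree(self, rng):
        # BA with attachment 2: (D - 2) * 2 edges among attached nodes
        net = generate_scale_free(1000, 4.0, rng)
        mean_deg = net.degrees().mean()
        assert 3.5 <= mean_deg <= 4.0

    def test_min_degree_at_least_attachment_count(self, rng):
        net = generate_scale_free(200, 4.0, rng)
        assert net.degrees().min() >= 2

    def test_heavier_tail_than_er(self):
        # degree variance exceeds the matched ER graph's, 10 seeds each
        var_ba = np.mean([
            generate_scale_free(500, 4.0, np.random.default_rng(s)).degrees().var()
            for s in range(10)
        ])
        var_er = np.mean([
            generate_er(500, 4.0, np.random.default_rng(s)).degrees().var()
            for s in range(10)
        ])
        assert var_ba > var_er

    def test_infeasible_attachment_rejected(self, rng):
        with pytest.raises(ValueError):
            generate_scale_free(100, 0.5, rng)


class TestMigrate:
    def test_zero_rate_leaves_state_unchanged(self, rng):
        net = generate_island(2)
        state = state_from([[1, 0], [0, 1]], [[0.1, 0.2], [0.3, 0.4]])
        migrate(state, net, 0.0, rng)
        assert state.deme_sizes().tolist() == [2, 2]
        assert state.fitness[0].tolist() == [0.1, 0.2]

    def test_forced_move_to_only_neighbor(self, rng):
        net = generate_island(2)
        state = state_from([[1] * 10, []], [[0.5] * 10, []])
        migrate(state, net, 1.0, rng)
        assert state.deme_sizes().tolist() == [0, 10]

    def test_isolated_deme_never_emigrates(self, rng):
        # two nodes, no edges: everyone stays even at m = 1
        from demewar.network import MigrationNetwork

        net = MigrationNetwork(n_nodes=2, neighbors=[np.empty(0, np.intp)] * 2)
        state = state_from([[1, 1], [0]], [[0.2, 0.2], [0.9]])
        migrate(state, net, 1.0, rng)
        assert state.deme_sizes().tolist() == [2, 1]

    def test_conserves_individual_multiset(self, rng):
        net = generate_island(4)
        state = state_from(
            [[1, 0, 1], [0, 0], [1], []],
            [[0.1, 0.2, 0.3], [0.4, 0.5], [0.6], []],
        )
        before = sorted(
            zip(
                np.concatenate(state.strategies).tolist(),
                np.concatenate(state.fitness).tolist(),
            )
        )
        migrate(state, net, 0.7, rng)
        after = sorted(
            zip(
                np.concatenate(state.strategies).tolist(),
                np.concatenate(state.fitness).tolist(),
            )
        )
        assert before == after

    def test_migrant_count_is_binomial(self):
        # island D=10, N=200, m=0.3: mean migrant count over 100 generations
        rng = np.random.default_rng(5)
        net = generate_island(10)
        m, N = 0.3, 200
        counts = []
        for _ in range(100):
            # tag each individual's fitness with its home deme id
            state = state_from(
                [[1] * 20 for _ in range(10)], [[float(d)] * 20 for d in range(10)]
            )
            migrate(state, net, m, rng)
            moved = sum(
                int((state.fitness[d] != d).sum()) for d in range(10)
            )
            counts.append(moved)
        se = np.sqrt(N * m * (1 - m))
        assert abs(np.mean(counts) - m * N) < 4 * se / np.sqrt(len(counts))

    def test_invalid_rate_rejected(self, rng):
        net = generate_island(2)
        state = state_from([[1], [0]], [[0.1], [0.2]])
        with pytest.raises(ValueError):
            migrate(state, net, 1.5, rng)

    def test_long_run_island_sizes_hover_at_capacity(self, rng):
        # uniform flow on K_D: inflow balances outflow, sizes stay near N0
        net = generate_island(5)
        state = state_from([[1] * 10] * 5, [[0.5] * 10] * 5)
        sizes = []
        for _ in range(200):
            migrate(state, net, 1.0, rng)
            sizes.append(state.deme_sizes().astype(float))
        assert abs(np.mean(sizes) - 10.0) < 0.5
        assert state.total_size == 50


class TestEdgeListIO:
    def test_path_graph_round_trip(self, tmp_path):
        path = tmp_path / "net.txt"
        path.write_text("0 1\n1 2\n")
        net = load_network(path, D=3)
        assert net.degrees().tolist() == [1, 2, 1]
        out = tmp_path / "out.txt"
        export_network(net, out)
        assert out.read_text() == "0 1\n1 2\n"

    def test_self_loop_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("2 2\n")
        with pytest.raises(ValueError, match="self-loop"):
            load_network(path, D=3)

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("0 1 2\n")
        with pytest.raises(ValueError):
            load_network(path, D=3)

    def test_node_id_out_of_range_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("0 5\n")
        with pytest.raises(ValueError):
            load_network(path, D=3)

    def test_seeded_er_round_trip_identity(self, tmp_path, rng):
        net = generate_er(50, 4.0, rng)
        path = tmp_path / "er.txt"
        export_network(net, path)
        loaded = load_network(path, D=50)
        assert loaded.edge_set() == net.edge_set()
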