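import numpy as np
from scipy import stats

from mitolineage.simulate import (
    CELL_PRIVATE,
    CLONE_SPECIFIC,
    GERMLINE,
    SimConfig,
    assign_cells,
    build_clone_tree,
    read_truth,
    simulate_reads,
    write_truth,
)


class TestCloneTree:
    def test_default_tree_shape_and_edge_mutations(self):
        tree = build_clone_tree(SimConfig(seed=1))
        edges = [n for n, p in tree.parent.items() if p is not None]
        assert len(edges) == 18  # 6 clones x 3 generations
        assert all(len(tree.edge_mutations[e]) >= 1 for e in edges)

    def test_star_topology(self):
        tree = build_clone_tree(SimConfig(seed=1, n_levels=1))
        children = [n for n, p in tree.parent.items() if p == "root"]
        assert len(children) == 6
        assert all(len(tree.edge_mutations[c]) >= 1 for c in children)

    def test_positions_unique_across_tree(self):
        tree = build_clone_tree(SimConfig(seed=2))
        positions = [m.position for muts in tree.edge_mutations.values() for m, _ in muts]
        assert len(positions) == len(set(positions))

    def test_expected_clone_specific_count(self):
        # 18 edges x (1 + lambda) = 36 expected; Monte-Carlo over 200 seeds
        totals = [
            sum(len(v) for v in build_clone_tree(SimConfig(seed=s)).edge_mutations.values())
            for s in range(200)
        ]
        se = np.std(totals) / np.sqrt(len(totals))
        assert abs(np.mean(totals) - 36.0) < 3 * se + 1e-9

    def test_custom_newick_topology(self):
        tree = build_clone_tree(SimConfig(seed=3), newick="((A,B)AB,(C,D)CD)root;")
        assert tree.parent["A"] == "AB" and tree.parent["AB"] == "root"
        assert tree.clone_of["A"] == "AB"


class TestAssignCells:
    def test_cells_at_same_node_share_clone_specific_rows(self):
        cfg = SimConfig(seed=4)
        tree = build_clone_tree(cfg)
        truth = assign_cells(tree, cfg)
        by_node = {}
        cs = [i for i, m in enumerate(truth.mutations) if truth.mutation_class[m] == CLONE_SPECIFIC]
        for ci, c in enumerate(truth.cells):
            by_node.setdefault(truth.cell_node[c], []).append(ci)
        for node, cols in by_node.items():
            block = truth.true_vaf[np.ix_(cs, cols)]
            assert np.all(block == block[:, :1])

    def test_all_positions_globally_unique(self):
        cfg = SimConfig(seed=5)
        truth = assign_cells(build_clone_tree(cfg), cfg)
        positions = [m.position for m in truth.mutations]
        assert len(positions) == len(set(positions))

    def test_germline_count_mean(self):
        # germline count ~ Poisson(10)
        counts = []
        for s in range(100):
            cfg = SimConfig(seed=s)
            truth = assign_cells(build_clone_tree(cfg), cfg)
            counts.append(sum(1 for c in truth.mutation_class.values() if c == GERMLINE))
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - 10.0) < 3 * se + 1e-9

    def test_germline_carrier_fraction(self):
        cfg = SimConfig(seed=6, n_cells=100)
        truth = assign_cells(build_clone_tree(cfg), cfg)
        g_rows = [i for i, m in enumerate(truth.mutations) if truth.mutation_class[m] == GERMLINE]
        carried = np.concatenate([truth.true_vaf[i] > 0 for i in g_rows])
        # pooled binomial CI around 0.8
        n = carried.size
        phat = carried.mean()
        assert abs(phat - 0.8) < 4 * np.sqrt(0.8 * 0.2 / n)

    def test_germline_vaf_range(self):
        cfg = SimConfig(seed=7)
        truth = assign_cells(build_clone_tree(cfg), cfg)
        for i, m in enumerate(truth.mutations):
            if truth.mutation_class[m] == GERMLINE:
                v = truth.true_vaf[i][truth.true_vaf[i] > 0]
                assert np.all((v >= 0.5) & (v <= 1.0))

    def test_cell_private_confined_to_one_cell(self):
        cfg = SimConfig(seed=8, cell_private_lambda=1.0)
        truth = assign_cells(build_clone_tree(cfg), cfg)
        for i, m in enumerate(truth.mutations):
            if truth.mutation_class[m] == CELL_PRIVATE:
                assert (truth.true_vaf[i] > 0).sum() == 1


class TestSimulateReads:
    def test_error_only_mean_alt(self):
        # v = 0: E[alt] = depth * e/3 = 0.01 at defaults
        cfg = SimConfig(seed=9)
        rng_truth = assign_cells(build_clone_tree(cfg), cfg)
        n = 10_000
        from mitolineage.simulate import SimTruth

        truth = SimTruth(
            cell_clone={f"c{i}": "x" for i in range(n)},
            cell_node={f"c{i}": "x" for i in range(n)},
            mutation_class={rng_truth.mutations[0]: CLONE_SPECIFIC},
            true_vaf=np.zeros((1, n)),
            mutations=[rng_truth.mutations[0]],
            cells=[f"c{i}" for i in range(n)],
        )
        ds = simulate_reads(truth, cfg)
        mean = ds.alt.mean()
        se = ds.alt.std() / np.sqrt(n)
        assert abs(mean - 0.01) < 3 * se + 1e-3

    def test_certain_mutation_no_error(self):
        cfg = SimConfig(seed=10, error_rate=1e-12)
        truth = assign_cells(build_clone_tree(cfg), cfg)
        truth.true_vaf[:] = 1.0
        ds = simulate_reads(truth, cfg)
        assert np.all(ds.alt == 30)

    def test_intermediate_heteroplasmy_mean_vaf(self):
        cfg = SimConfig(seed=11)
        e = cfg.error_rate
        n = 10_000
        from mitolineage.simulate import SimTruth
        from mitolineage.io_matrix import MutationId

        m = MutationId.parse("MT_77_A-G")
        truth = SimTruth(
            cell_clone={f"c{i}": "x" for i in range(n)},
            cell_node={f"c{i}": "x" for i in range(n)},
            mutation_class={m: CLONE_SPECIFIC},
            true_vaf=np.full((1, n), 0.2),
            mutations=[m],
            cells=[f"c{i}" for i in range(n)],
        )
        ds = simulate_reads(truth, cfg)
        q = 0.2 * (1 - e) + 0.8 * e / 3
        se = np.nanstd(ds.vaf) / np.sqrt(n)
        assert abs(np.nanmean(ds.vaf) - q) < 3 * se

    def test_alt_counts_follow_binomial(self):
        # chi-square goodness of fit of alt ~ Binom(30, q) at alpha = 0.01
        cfg = SimConfig(seed=12)
        n = 10_000
        from mitolineage.simulate import SimTruth
        from mitolineage.io_matrix import MutationId

        m = MutationId.parse("MT_88_A-G")
        v = 0.3
        truth = SimTruth(
            cell_clone={f"c{i}": "x" for i in range(n)},
            cell_node={f"c{i}": "x" for i in range(n)},
            mutation_class={m: CLONE_SPECIFIC},
            true_vaf=np.full((1, n), v),
            mutations=[m],
            cells=[f"c{i}" for i in range(n)],
        )
        ds = simulate_reads(truth, cfg)
        q = v * (1 - cfg.error_rate) + (1 - v) * cfg.error_rate / 3
        expected = stats.binom.pmf(np.arange(31), 30, q) * n
        observed = np.bincount(ds.alt.ravel(), minlength=31).astype(float)
        # pool bins with expected < 5 into one catch-all bin
        good = expected >= 5
        obs = np.append(observed[good], observed[~good].sum())
        exp = np.append(expected[good], expected[~good].sum())
        chi2 = ((obs - exp) ** 2 / exp).sum()
        assert stats.chi2.sf(chi2, len(obs) - 1) > 0.01

    def test_depth_constant_by_default(self, sim_default):
        ds, _, _ = sim_default
        assert np.all(ds.depth == 30)


class TestTruthIO:
    def test_round_trip(self, tmp_path, sim_default):
        _, truth, _ = sim_default
        write_truth(truth, str(tmp_path / "t"))
        back = read_truth(str(tmp_path / "t"))
        assert back.cell_clone == truth.cell_clone
        assert back.mutation_class == truth.mutation_class
        assert np.allclose(back.true_vaf, truth.true_vaf, atol=1e-12)

    def test_class_vocabulary(self, sim_default):
        _, truth, _ = sim_default
        assert set(truth.mutation_class.values()) <= {CLONE_SPECIFIC, GERMLINE, CELL_PRIVATE}

    def test_one_row_per_cell(self, tmp_path, sim_default):
        import pandas as pd

        _, truth, _ = sim_default
        paths = write_truth(truth, str(tmp_path / "t"))
        cells = pd.read_csv(paths["cells"])
        assert len(cells) == len(truth.cells)


def test_end_to_end_dataset_valid(sim_default):
    ds, truth, tree = sim_default
    assert ds.n_cells == 100
    assert ds.n_mutations == len(truth.mutations)
    assert len(set(truth.cell_clone.values())) == 6
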