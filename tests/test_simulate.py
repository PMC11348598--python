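import json

import numpy as np
import pytest

import polswap as ps
from polswap.align import global_identity
from polswap.simulate import ConfigError, jc_p
from polswap.tree import leaf_depths


class TestSimulateTree:
    def test_three_leaves_forced_shape(self):
        tree = ps.simulate_tree(3, 0.7, 0)
        internal = [n for n in tree.traverse(include_self=True) if not n.is_tip()]
        assert len(internal) == 2
        d = leaf_depths(tree)
        assert all(v == pytest.approx(0.7) for v in d.values())

    def test_same_seed_identical_newick(self):
        assert str(ps.simulate_tree(12, 0.4, 7)) == str(ps.simulate_tree(12, 0.4, 7))

    def test_cherry_count_matches_yule_expectation(self):
        # Yule trees have E[cherries] = n/3 (n = 10 leaves here)
        n, reps = 10, 400
        counts = []
        for seed in range(reps):
            tree = ps.simulate_tree(n, 1.0, seed)
            cherries = sum(
                1
                for node in tree.non_tips()
                if len(node.children) == 2 and all(c.is_tip() for c in node.children)
            )
            counts.append(cherries)
        mean = np.mean(counts)
        se = np.std(counts) / np.sqrt(reps)
        assert abs(mean - n / 3) < 3 * se + 0.05


class TestEvolveGenomes:
    def test_zero_rate_leaves_identical(self):
        cfg = ps.SimConfig(n_leaves=4, n_genes=3, sub_rate=0.0, seed=1)
        tree = ps.simulate_tree(4, 0.4, np.random.default_rng(1))
        leaves = ps.evolve_genomes(tree, cfg)
        seqs = {g.seq for g in leaves.values()}
        assert len(seqs) == 1

    def test_observed_divergence_matches_jc_expectation(self):
        cfg = ps.SimConfig(n_leaves=4, n_genes=10, seed=2, tree_height=0.1)
        tree = ps.simulate_tree(4, cfg.tree_height, np.random.default_rng(2))
        leaves = ps.evolve_genomes(tree, cfg)
        tips = {t.name: t for t in tree.tips()}
        names = sorted(leaves)
        a, b = names[0], names[1]
        t_ab = tips[a].distance(tips[b])
        expected = jc_p(cfg.sub_rate, t_ab)
        sa, sb = leaves[a].seq, leaves[b].seq
        diffs = sum(x != y for x, y in zip(sa, sb))
        n = len(sa)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(diffs / n - expected) < 3 * se + 0.01

    def test_all_genes_remain_intact_orfs(self):
        cfg = ps.SimConfig(n_leaves=6, n_genes=5, seed=3)
        tree, genomes, truth, refs = ps.simulate_dataset(cfg)
        for g in genomes.values():
            orfs = ps.find_orfs(g)
            spans = {(o.start, o.end) for o in orfs}
            for slot in range(cfg.n_genes):
                s, e = cfg.gene_span(slot)
                # the gene's ORF may extend upstream into the spacer if an
                # in-frame start appears there, but must end at the gene stop
                assert any(o.end == e and o.start <= s and o.strand == "+" for o in orfs)


class TestPlantSwaps:
    def test_negative_control_all_root_family(self):
        cfg = ps.SimConfig(n_leaves=6, seed=4)
        tree, genomes, truth, refs = ps.simulate_dataset(cfg)
        fams = {s["family"] for s in truth.leaf_states.values()}
        assert fams == {"PolA"}
        states = {l: s["family"] for l, s in truth.leaf_states.items()}
        assert ps.count_swaps_fitch(tree, states) == 0

    def test_single_swap_marks_descendants_and_fitch_one(self):
        tree0 = ps.simulate_tree(8, 0.4, np.random.default_rng(5))
        branch = ps.choose_swap_branches(tree0, 1)[0]
        cfg = ps.SimConfig(n_leaves=8, seed=5, swap_events=[(branch, "PolB", 1)])
        tree, genomes, truth, refs = ps.simulate_dataset(cfg)
        node = next(n for n in tree.traverse() if n.name == branch)
        below = {t.name for t in node.tips()}
        swapped = {l for l, s in truth.leaf_states.items() if s["family"] == "PolB"}
        assert swapped == below == set(truth.swap_events[0]["leaves"])
        states = {l: s["family"] for l, s in truth.leaf_states.items()}
        assert ps.count_swaps_fitch(tree, states) == 1

    def test_two_disjoint_swaps_fitch_two(self):
        tree0 = ps.simulate_tree(12, 0.4, np.random.default_rng(6))
        b = ps.choose_swap_branches(tree0, 2)
        cfg = ps.SimConfig(
            n_leaves=12, seed=6, swap_events=[(b[0], "PolB", 1), (b[1], "PolC", 1)]
        )
        tree, genomes, truth, refs = ps.simulate_dataset(cfg)
        states = {l: s["family"] for l, s in truth.leaf_states.items()}
        assert ps.count_swaps_fitch(tree, states) == 2

    def test_conflicting_events_on_same_branch_rejected(self):
        with pytest.raises(ConfigError, match="conflicting"):
            ps.SimConfig(
                n_leaves=8, seed=1, swap_events=[("N02", "PolB", 1), ("N02", "PolC", 1)]
            )

    def test_unknown_branch_rejected(self):
        cfg = ps.SimConfig(n_leaves=8, seed=1, swap_events=[("NXX", "PolB", 1)])
        with pytest.raises(ConfigError, match="NXX"):
            ps.simulate_dataset(cfg)

    def test_truth_family_matches_best_identity_reference(self, small_dataset):
        cfg = small_dataset["cfg"]
        genomes = small_dataset["genomes"]
        truth = small_dataset["truth"]
        refs = small_dataset["refs"]
        s, e = cfg.gene_span(cfg.dnap_slot)
        from polswap.orfs import translate_cds

        for leaf, state in truth.leaf_states.items():
            prot = translate_cds(genomes[leaf].seq[s:e])
            best = max(refs.records, key=lambda r: global_identity(prot, r.seq))
            assert best.family == state["family"]

    def test_dual_event_produces_two_dnap_genome(self):
        tree0 = ps.simulate_tree(8, 0.4, np.random.default_rng(7))
        branch = ps.choose_swap_branches(tree0, 1)[0]
        cfg = ps.SimConfig(n_leaves=8, seed=7, dual_dnap_events=[(branch, "PolC", 1)])
        tree, genomes, truth, refs = ps.simulate_dataset(cfg)
        dual = truth.dual_events[0]["leaves"]
        assert dual
        leaf = dual[0]
        orfs = ps.find_orfs(genomes[leaf])
        calls = ps.classify_dnaps(orfs, refs)
        fams = {c.family for c in calls if c.genome_id == leaf}
        assert fams == {"PolA", "PolC"}


class TestEmitDataset:
    def test_round_trip_and_determinism(self, tmp_path):
        cfg = ps.SimConfig(n_leaves=5, n_genes=4, seed=8)
        p1 = ps.emit_dataset(tmp_path / "a", cfg)
        p2 = ps.emit_dataset(tmp_path / "b", cfg)
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()
        genomes = ps.read_genomes_fasta(p1["genomes"])
        assert len(genomes) == cfg.n_leaves
        from polswap.classify import read_reference_fasta
        from polswap.tree import read_newick

        refs = read_reference_fasta(p1["refs"])
        assert len(refs) == 6  # 3 families x 2 subgroups
        tree = read_newick(p1["tree"])
        assert sorted(t.name for t in tree.tips()) == sorted(g.id for g in genomes)
        truth = json.loads(p1["truth"].read_text())
        assert len(truth["leaf_states"]) == cfg.n_leaves
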