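import random
from io import StringIO

import pytest
from skbio import TreeNode

import polswap as ps
from polswap.classify import DnapCall
from polswap.swaps import count_swaps_fitch, group_sister_clades, profile_clades
from polswap.tree import cut_clades, ultrametrize

from .oracles import fitch_brute_force, sankoff_min_changes


def _call(genome, family, subgroup=None, orf="x"):
    return DnapCall(
        genome_id=genome,
        orf_id=f"{genome}|{orf}",
        family=family,
        best_ref_id="r",
        evalue=1e-30,
        bit_score=100.0,
        protein="",
        subgroup=subgroup,
    )


def _partition(nwk, depth=0.15):
    return cut_clades(ultrametrize(TreeNode.read(StringIO(nwk))), depth)


class TestProfileClades:
    def test_homogeneous_clade_not_flagged(self):
        part = _partition("((a:0.05,b:0.05):0.1,(c:0.05,d:0.05):0.1);")
        calls = [_call(g, "PolA") for g in "abcd"]
        profiles = profile_clades(part, calls)
        assert all(not p.het_type_i and not p.het_type_ii for p in profiles)

    def test_mixed_single_copy_families_flag_type_i(self):
        part = _partition("((a:0.05,b:0.05):0.1,(c:0.05,d:0.05):0.1);")
        calls = [_call("a", "PolA"), _call("b", "PolB")]
        profiles = {p.clade_id: p for p in profile_clades(part, calls)}
        flagged = [p for p in profiles.values() if p.het_type_i]
        assert len(flagged) == 1 and not flagged[0].het_type_ii

    def test_two_dnap_genome_flags_type_ii_not_type_i(self):
        part = _partition("((a:0.05,b:0.05):0.1,(c:0.05,d:0.05):0.1);")
        calls = [_call("a", "PolA", orf="x"), _call("a", "PolB", orf="y")]
        profiles = [p for p in profile_clades(part, calls) if "a" in ("a",) and p.het_type_ii]
        assert len(profiles) == 1
        assert not profiles[0].het_type_i

    def test_unknown_genome_rejected(self):
        part = _partition("((a:0.05,b:0.05):0.1,(c:0.05,d:0.05):0.1);")
        with pytest.raises(Exception, match="absent"):
            profile_clades(part, [_call("zz", "PolA")])


class TestGroupSisterClades:
    def test_dnap_free_sister_stops_merging(self):
        nwk = "(((a:0.05,b:0.05):0.25,(c:0.1,d:0.1):0.2):0.2,(e:0.25,f:0.25):0.25);"
        tree = ultrametrize(TreeNode.read(StringIO(nwk)))
        part = cut_clades(tree, 0.15)
        calls = [_call("a", "PolA"), _call("b", "PolB")]
        profiles = profile_clades(part, calls)
        groups = group_sister_clades(tree, part, profiles, calls)
        assert len(groups) == 1
        assert sorted(groups[0].leaves) == ["a", "b"]

    def test_dnap_bearing_sisters_merge(self):
        nwk = "(((a:0.05,b:0.05):0.25,(c:0.1,d:0.1):0.2):0.2,(e:0.25,f:0.25):0.25);"
        tree = ultrametrize(TreeNode.read(StringIO(nwk)))
        part = cut_clades(tree, 0.15)
        calls = [_call("a", "PolA"), _call("b", "PolB"), _call("c", "PolA")]
        profiles = profile_clades(part, calls)
        groups = group_sister_clades(tree, part, profiles, calls)
        assert len(groups) == 1
        assert sorted(groups[0].leaves) == ["a", "b", "c", "d"]

    def test_nested_groups_deduplicated_to_maximal(self):
        nwk = "(((a:0.05,b:0.05):0.25,(c:0.05,d:0.05):0.25):0.2,(e:0.25,f:0.25):0.25);"
        tree = ultrametrize(TreeNode.read(StringIO(nwk)))
        part = cut_clades(tree, 0.15)
        calls = [
            _call("a", "PolA"),
            _call("b", "PolB"),
            _call("c", "PolA"),
            _call("d", "PolC"),
        ]
        profiles = profile_clades(part, calls)
        groups = group_sister_clades(tree, part, profiles, calls)
        assert len(groups) == 1
        assert sorted(groups[0].leaves) == ["a", "b", "c", "d"]


class TestFitch:
    def test_homogeneous_states_zero_changes(self):
        tree = TreeNode.read(StringIO("((w,x),(y,z));"))
        assert count_swaps_fitch(tree, {l: "A" for l in "wxyz"}) == 0

    def test_single_change(self):
        tree = TreeNode.read(StringIO("((w,x),(y,z));"))
        assert count_swaps_fitch(tree, {"w": "A", "x": "A", "y": "A", "z": "B"}) == 1

    def test_wildcards_cost_nothing(self):
        tree = TreeNode.read(StringIO("((w,x),(y,z));"))
        assert count_swaps_fitch(tree, {"w": "A", "z": "B"}) == 1
        assert count_swaps_fitch(tree, {"w": "A"}) == 0

    def test_empty_state_set_rejected(self):
        tree = TreeNode.read(StringIO("((w,x),(y,z));"))
        with pytest.raises(Exception, match="empty"):
            count_swaps_fitch(tree, {"w": frozenset()})

    def test_multi_state_leaf_satisfiable_either_way(self):
        tree = TreeNode.read(StringIO("((w,x),(y,z));"))
        states = {"w": "A", "x": "A", "y": "A", "z": frozenset({"A", "B"})}
        assert count_swaps_fitch(tree, states) == 0

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_exhaustive_minimum(self, seed):
        rng = random.Random(seed)
        n = rng.randrange(4, 9)
        tree = ps.simulate_tree(n, 1.0, seed)
        states = {}
        labels = ["A", "B", "C", "D"][: rng.randrange(2, 5)]
        for tip in tree.tips():
            r = rng.random()
            if r < 0.15:
                continue  # wildcard
            if r < 0.3:
                states[tip.name] = frozenset(rng.sample(labels, min(2, len(labels))))
            else:
                states[tip.name] = rng.choice(labels)
        got = count_swaps_fitch(tree, states)
        assert got == fitch_brute_force(tree, states)
        assert got == sankoff_min_changes(tree, states)

    def test_invariant_under_state_relabeling(self):
        tree = ps.simulate_tree(8, 1.0, 5)
        states = {t.name: random.Random(1).choice("AB") for t in tree.tips()}
        swapped = {k: ("B" if v == "A" else "A") for k, v in states.items()}
        assert count_swaps_fitch(tree, states) == count_swaps_fitch(tree, swapped)


class TestSwapReport:
    def test_negative_control_no_hotspots(self):
        cfg = ps.SimConfig(n_leaves=8, seed=11)
        tree, genomes, truth, refs = ps.simulate_dataset(cfg)
        res = ps.distance_matrix(list(genomes.values()), engine="exact")
        ut = ps.ultrametrize(ps.build_tree(res.matrix))
        part = ps.cut_clades(ut, 0.15)
        orfs = [o for g in genomes for o in res.orfs[g]]
        calls = ps.assign_subgroups(ps.classify_dnaps(orfs, refs))
        profiles = ps.profile_clades(part, calls)
        groups = ps.group_sister_clades(ut, part, profiles, calls)
        rep = ps.swap_report(ut, part, profiles, groups, calls)
        assert rep.n_hotspots_type_i == 0
        assert rep.total_min_swaps_family == 0

    def test_report_counts_conserved(self, small_analysis):
        rep = small_analysis["report"]
        multi = [p for p in rep.profiles if not p.is_singleton]
        hot = sum(1 for p in multi if p.het_type_i)
        homogeneous = sum(
            1 for p in multi if p.families_present and not p.het_type_i
        )
        dnap_free = sum(1 for p in multi if not p.families_present)
        assert hot + homogeneous + dnap_free == rep.n_multi_genome_clades

    def test_type_i_clades_force_at_least_one_swap(self, small_analysis):
        rep = small_analysis["report"]
        ut = small_analysis["ultrametric"]
        calls = small_analysis["calls"]
        fam = {}
        for c in calls:
            fam.setdefault(c.genome_id, set()).add(c.family)
        part = small_analysis["partition"]
        for p in rep.profiles:
            if p.het_type_i:
                clade = next(c for c in part.clades if c.clade_id == p.clade_id)
                sub = {g: frozenset(s) for g, s in fam.items() if g in clade.leaves}
                assert count_swaps_fitch(clade.node, sub) >= 1

    def test_subgroup_refinement_never_below_family(self, small_analysis):
        for sc in small_analysis["report"].swap_clades:
            assert sc.min_swaps_subgroup >= sc.min_swaps_family

    def test_planted_swaps_recovered(self, small_analysis):
        rep = small_analysis["report"]
        truth = small_analysis["truth"]
        # one inter-family + one intra-family event planted
        states_fam = {l: s["family"] for l, s in truth.leaf_states.items()}
        states_sub = {l: s["family"] + ":" + s["subgroup"] for l, s in truth.leaf_states.items()}
        true_tree = small_analysis["tree"]
        assert count_swaps_fitch(true_tree, states_fam) == 1
        assert count_swaps_fitch(true_tree, states_sub) == 2
        tc = rep.truth_comparison
        assert tc["affected_clades_detected"] == tc["affected_clades"]
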