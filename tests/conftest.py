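import json

import numpy as np
import pytest

import polswap as ps


@pytest.fixture(scope="session")
def small_dataset():
    """One deterministic 12-leaf simulated dataset with a planted
    inter-family swap and an intra-family (subgroup) swap, analysed once and
    shared across tests."""
    rng = np.random.default_rng(42)
    tr = ps.simulate_tree(12, 0.4, rng)
    branches = ps.choose_swap_branches(tr, 2)
    cfg = ps.SimConfig(
        n_leaves=12,
        seed=42,
        swap_events=[(branches[0], "PolB", 1), (branches[1], "PolA", 2)],
    )
    tree, genomes, truth, refs = ps.simulate_dataset(cfg)
    return {"cfg": cfg, "tree": tree, "genomes": genomes, "truth": truth, "refs": refs}


@pytest.fixture(scope="session")
def small_analysis(small_dataset):
    """Full pipeline products for the shared dataset (exact SW engine so the
    result is self-contained)."""
    d = small_dataset
    res = ps.distance_matrix(list(d["genomes"].values()), engine="exact")
    ut = ps.ultrametrize(ps.build_tree(res.matrix))
    part = ps.cut_clades(ut, 0.15)
    all_orfs = [o for g in d["genomes"] for o in res.orfs[g]]
    calls = ps.assign_subgroups(ps.classify_dnaps(all_orfs, d["refs"]))
    profiles = ps.profile_clades(part, calls)
    swap_clades = ps.group_sister_clades(ut, part, profiles, calls)
    report = ps.swap_report(
        ut, part, profiles, swap_clades, calls, truth=json.loads(d["truth"].to_json())
    )
    return {
        "result": res,
        "ultrametric": ut,
        "partition": part,
        "calls": calls,
        "profiles": profiles,
        "swap_clades": swap_clades,
        "report": report,
        **d,
    }
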