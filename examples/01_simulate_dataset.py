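"""Generate a synthetic phage-genome dataset with planted DNAP swaps.

Simulates a 12-genome collection (20 genes of 300 nt each, 100-nt spacers)
on a Yule tree of height 0.4 substitutions/site, replaces the DNA-polymerase
gene with a PolB exemplar on one internal branch, and writes the dataset
plus its ground truth to ./scratch/example_dataset/.
"""

import polswap as ps

tree = ps.simulate_tree(12, 0.4, 42)
branch = ps.choose_swap_branches(tree, 1)[0]
cfg = ps.SimConfig(n_leaves=12, seed=42, swap_events=[(branch, "PolB", 1)])
paths = ps.emit_dataset("scratch/example_dataset", cfg)

tree, genomes, truth, refs = ps.simulate_dataset(cfg)
print(f"wrote {len(paths)} files: {', '.join(p.name for p in paths.values())}")
print(f"genomes: {len(genomes)} x {cfg.genome_len} nt")
print(f"swap branch {branch} -> PolB, affecting leaves: "
      f"{truth.swap_events[0]['leaves']}")
print(f"reference proteins: {[r.id for r in refs.records]}")
# Every genome carries one DNAP gene slot; the listed leaves carry the PolB
# exemplar in place of the ancestral PolA, with flanking genes untouched.
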