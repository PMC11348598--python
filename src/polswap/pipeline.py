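"""End-to-end analysis: genomes FASTA -> swap report.

Stages: ORF calling, all-vs-all RBH distances, neighbor-joining tree,
ultrametrization, fixed-depth clade cutting, DNAP classification and
subgrouping, heterogeneity profiling, sister grouping and parsimony swap
counting.  Every intermediate is written to the output directory and a
manifest records parameters and input checksums, so a rerun on identical
inputs reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .classify import assign_subgroups, classify_dnaps, read_reference_fasta, write_calls_tsv
from .orfs import read_genomes_fasta, write_orf_proteins, write_orf_table
from .rbh import distance_matrix, write_matrix_phylip, write_matrix_tsv, write_rbh_tsv
from .swaps import SwapReport, group_sister_clades, profile_clades, swap_report
from .tree import build_tree, cut_clades, ultrametrize, write_clades_tsv, write_newick

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and parameters of one pipeline run.

    Parameter defaults are the analysis' standard operating point: 75-nt
    minimum ORF length, 50% RBH query coverage, classification e-value
    1e-4, clade depth 0.15, subgroup identity 0.5.
    """

    genomes_fasta: str
    reference_fasta: str
    outdir: str
    truth_json: str | None = None
    min_orf_len: int = 75
    rbh_evalue: float = 1e-3
    min_cover: float = 0.5
    classify_evalue: float = 1e-4
    clade_depth: float = 0.15
    subgroup_identity: float = 0.5
    #: all-vs-all search engine for the RBH stage: "blast" or "exact"
    engine: str = "blast"


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> SwapReport:
    """Run all stages, writing every intermediate under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for path in (config.genomes_fasta, config.reference_fasta):
        if not Path(path).exists():
            raise FileNotFoundError(f"input file not found: {path}")
    if config.truth_json and not Path(config.truth_json).exists():
        raise FileNotFoundError(f"input file not found: {config.truth_json}")

    logger.info("[orfs] reading genomes from %s", config.genomes_fasta)
    genomes = read_genomes_fasta(config.genomes_fasta)
    logger.info("[distance] all-vs-all RBH over %d genomes", len(genomes))
    result = distance_matrix(
        genomes,
        min_orf_len=config.min_orf_len,
        evalue_max=config.rbh_evalue,
        min_cover=config.min_cover,
        engine=config.engine,
    )
    all_orfs = [o for g in genomes for o in result.orfs[g.id]]
    write_orf_proteins(all_orfs, outdir / "orfs.faa")
    write_orf_table(all_orfs, outdir / "orfs.tsv")
    write_matrix_tsv(result.matrix, outdir / "distances.tsv")
    write_matrix_phylip(result.matrix, outdir / "distances.phy")
    write_rbh_tsv(result.rbh, outdir / "rbh.tsv")

    logger.info("[tree] neighbor joining + midpoint rooting")
    raw_tree = build_tree(result.matrix)
    write_newick(raw_tree, outdir / "tree_raw.nwk")
    tree = ultrametrize(raw_tree)
    write_newick(tree, outdir / "tree_ultrametric.nwk")

    logger.info("[clades] cutting at depth %.3f", config.clade_depth)
    partition = cut_clades(tree, depth=config.clade_depth)
    write_clades_tsv(partition, outdir / "clades.tsv")

    logger.info("[classify] DNAP search against %s", config.reference_fasta)
    refdb = read_reference_fasta(config.reference_fasta)
    calls = classify_dnaps(all_orfs, refdb, evalue_max=config.classify_evalue)
    calls = assign_subgroups(calls, identity_threshold=config.subgroup_identity)
    write_calls_tsv(calls, outdir / "dnap_calls.tsv")

    logger.info("[detect] heterogeneity profiling and swap counting")
    profiles = profile_clades(partition, calls)
    swap_clades = group_sister_clades(tree, partition, profiles, calls)
    truth = None
    if config.truth_json:
        with open(config.truth_json) as fh:
            truth = json.load(fh)
    report = swap_report(tree, partition, profiles, swap_clades, calls, truth=truth)
    report.write_json(outdir / "swap_report.json")
    report.write_tsv(outdir / "swap_report.tsv")

    manifest = {
        "tool": "polswap",
        "version": __version__,
        "parameters": {
            k: v for k, v in asdict(config).items() if k not in ("genomes_fasta", "reference_fasta", "outdir", "truth_json")
        },
        "inputs": {
            "genomes_fasta": _sha256(config.genomes_fasta),
            "reference_fasta": _sha256(config.reference_fasta),
        },
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("[done] report written to %s", outdir / "swap_report.json")
    return report
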