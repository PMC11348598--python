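import random

import numpy as np
import pytest

import polswap as ps
from polswap.align import align_pair
from polswap.orfs import GenomeRecord, InvariantError, OrfRecord
from polswap.rbh import coverage_term, genome_distance, reciprocal_best_hits

AAS = "ACDEFGHIKLMNPQRSTVWY"


def _random_protein(rng, n):
    return "".join(rng.choice(AAS) for _ in range(n))


def _orf(genome, start, protein):
    end = start + 3 * (len(protein) + 1)
    return OrfRecord(
        genome_id=genome, start=start, end=end, strand="+", frame=0, protein=protein
    )


def _mutate(rng, seq, n_changes):
    out = list(seq)
    for _ in range(n_changes):
        i = rng.randrange(len(out))
        out[i] = rng.choice([c for c in AAS if c != out[i]])
    return "".join(out)


class TestReciprocalBestHits:
    def test_identical_single_gene_proteomes(self):
        rng = random.Random(0)
        prot = _random_protein(rng, 100)
        pairs = reciprocal_best_hits([_orf("A", 0, prot)], [_orf("B", 0, prot)])
        assert len(pairs) == 1
        assert pairs[0].genome_a == "A" and pairs[0].genome_b == "B"

    def test_unrelated_proteins_no_pairs(self):
        rng = random.Random(1)
        pairs = reciprocal_best_hits(
            [_orf("A", 0, _random_protein(rng, 80))],
            [_orf("B", 0, _random_protein(rng, 80))],
        )
        assert pairs == []

    def test_empty_proteome_returns_empty(self):
        rng = random.Random(2)
        assert reciprocal_best_hits([], [_orf("B", 0, _random_protein(rng, 80))]) == []

    def test_planted_orthology_recovered_and_matches_exhaustive_oracle(self):
        """Ten orthologous gene pairs plus one shuffled decoy per side: the
        RBH set must equal the planted orthology, independently confirmed by
        an exhaustive all-vs-all best-hit computation."""
        rng = random.Random(3)
        genes_a, genes_b = [], []
        for i in range(10):
            g = _random_protein(rng, 100)
            genes_a.append(_orf("A", 400 * i, g))
            genes_b.append(_orf("B", 400 * i, _mutate(rng, g, 20)))
        decoy_a = "".join(rng.sample(genes_a[0].protein, 100))
        decoy_b = "".join(rng.sample(genes_b[1].protein, 100))
        pa = genes_a + [_orf("A", 4000, decoy_a)]
        pb = genes_b + [_orf("B", 4000, decoy_b)]
        got = {(p.orf_a, p.orf_b) for p in reciprocal_best_hits(pa, pb)}
        planted = {(a.orf_id, b.orf_id) for a, b in zip(genes_a, genes_b)}

        # exhaustive oracle: full score table via align_pair semantics
        n_a = sum(len(o.protein) for o in pa)
        n_b = sum(len(o.protein) for o in pb)
        def best(query, subjects, space):
            cands = []
            for s in subjects:
                h = align_pair(query.protein, s.protein, search_space=space)
                if h.evalue <= 1e-3 and h.query_cover >= 0.5:
                    cands.append((-h.raw_score, -h.aln_len, s.orf_id))
            return min(cands)[2] if cands else None

        fwd = {a.orf_id: best(a, pb, n_b) for a in pa}
        rev = {b.orf_id: best(b, pa, n_a) for b in pb}
        oracle = {
            (qa, sb)
            for qa, sb in fwd.items()
            if sb is not None and rev.get(sb) == qa
        }
        assert got == oracle == planted


class TestCoverage:
    def test_no_rbh_means_zero(self):
        g = GenomeRecord("A", "ACGT" * 300)
        assert coverage_term(g, [], []) == 0

    def test_overlapping_intervals_counted_once(self):
        g = GenomeRecord("A", "A" * 1000)
        o1 = OrfRecord("A", 0, 300, "+", 0, "X" * 99)
        o2 = OrfRecord("A", 150, 450, "+", 0, "X" * 99)
        rbh = [
            ps.RbhPair("A", o.orf_id, "B", "B|0|300|+", 100.0, 1.0) for o in (o1, o2)
        ]
        assert coverage_term(g, [o1, o2], rbh) == 450

    def test_matches_position_marking_oracle(self):
        rng = random.Random(4)
        g = GenomeRecord("A", "A" * 2000)
        for _ in range(20):
            orfs = []
            for _ in range(rng.randrange(1, 8)):
                s = rng.randrange(0, 1800)
                e = s + 3 * rng.randrange(30, 60)
                orfs.append(OrfRecord("A", s, min(e, 2000), "+", 0, "X"))
            in_rbh = rng.sample(orfs, k=rng.randrange(len(orfs) + 1))
            rbh = [ps.RbhPair("A", o.orf_id, "B", "B|0|90|+", 50.0, 1.0) for o in in_rbh]
            marked = np.zeros(2000, bool)
            for o in in_rbh:
                marked[o.start : o.end] = True
            assert coverage_term(g, orfs, rbh) == int(marked.sum())


class TestGenomeDistance:
    def test_printed_formula_value(self):
        assert genome_distance(600, 500, 1000, 1000) == pytest.approx(0.45)

    def test_full_coverage_limit(self):
        assert genome_distance(1000, 800, 1000, 800) == 0.0

    def test_no_homology_limit(self):
        assert genome_distance(0, 0, 1000, 800) == 1.0

    def test_coverage_above_length_rejected(self):
        with pytest.raises(InvariantError):
            genome_distance(1001, 0, 1000, 800)


class TestDistanceMatrix:
    def test_identical_genomes_distance_is_intergenic_fraction(self):
        rng = np.random.default_rng(0)
        cfg = ps.SimConfig(n_leaves=3, n_genes=4, seed=9, sub_rate=0.0)
        _, genomes, _, _ = ps.simulate_dataset(cfg)
        gl = list(genomes.values())
        res = ps.distance_matrix(gl, engine="exact")
        # identical genomes: every ORF is an RBH, D = 1 - covered fraction
        g = gl[0]
        marked = np.zeros(g.length, bool)
        for o in res.orfs[g.id]:
            marked[o.start : o.end] = True
        expected = 1.0 - marked.sum() / g.length
        off = res.matrix.data[np.triu_indices(3, 1)]
        assert np.allclose(off, expected, atol=1e-12)

    def test_symmetry_bounds_and_zero_diagonal(self, small_analysis):
        D = small_analysis["result"].matrix.data
        assert np.allclose(D, D.T)
        assert np.all(D >= 0) and np.all(D <= 1)
        assert np.all(np.diag(D) == 0)

    def test_blast_engine_agrees_with_exact_on_close_pairs(self, small_analysis):
        genomes = list(small_analysis["genomes"].values())
        d_exact = small_analysis["result"].matrix
        d_blast = ps.distance_matrix(genomes, engine="blast").matrix
        close = d_exact.data < 0.25
        diff = np.abs(d_blast.data - d_exact.data)[close]
        # heuristic seeding may miss a marginal short hit; distances within
        # clades must still agree to a few percent
        assert diff.max() <= 0.06

    def test_duplicate_ids_rejected(self):
        g = GenomeRecord("A", "ACGT" * 100)
        with pytest.raises(Exception, match="duplicate"):
            ps.distance_matrix([g, g, GenomeRecord("B", "ACGT" * 100)], engine="exact")
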