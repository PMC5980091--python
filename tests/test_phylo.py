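"""Alignment optimality, distances, UPGMA trees, indels, 33-mer origin."""

from functools import lru_cache

import numpy as np
import pytest

from glia.core_io import GliaError, NucleotideSeq, back_translate
from glia.epitopes import THIRTY_THREE_MER
from glia.phylo import (
    AlignParams,
    DistanceMatrix,
    PairwiseAlignment,
    distance_matrix,
    epitope_gain_loss,
    extract_clades,
    global_align,
    indel_report,
    jukes_cantor,
    p_distance,
    progressive_msa,
    upgma,
)
from glia.simulate import SimulationConfig, evolve_locus


def nw_bruteforce(a, b, p: AlignParams):
    """Independent optimal-score oracle: exhaustive path enumeration with a
    gap-run state machine (memoized)."""

    @lru_cache(maxsize=None)
    def rec(i, j, state):
        if i == len(a) and j == len(b):
            return 0.0
        best = -1e18
        if i < len(a) and j < len(b):
            s = p.match if a[i] == b[j] and a[i] != "N" else p.mismatch
            best = max(best, s + rec(i + 1, j + 1, 0))
        if i < len(a):
            g = p.gap_extend if state == 1 else p.gap_open
            best = max(best, g + rec(i + 1, j, 1))
        if j < len(b):
            g = p.gap_extend if state == 2 else p.gap_open
            best = max(best, g + rec(i, j + 1, 2))
        return best

    return rec(0, 0, 0)


class TestGlobalAlign:
    def test_self_alignment(self):
        s = NucleotideSeq(id="s", seq="ACGTACGT")
        aln = global_align(s, s)
        assert aln.identity == 1.0
        assert "-" not in aln.aligned_a + aln.aligned_b

    def test_single_gap(self):
        aln = global_align(NucleotideSeq(id="a", seq="ACGT"), NucleotideSeq(id="b", seq="AGT"))
        assert aln.aligned_a == "ACGT" and aln.aligned_b == "A-GT"

    def test_score_matches_bruteforce(self):
        rng = np.random.default_rng(1)
        p = AlignParams()
        for _ in range(300):
            la, lb = int(rng.integers(1, 6)), int(rng.integers(1, 6))
            a = "".join(rng.choice(list("ACGT"), size=la))
            b = "".join(rng.choice(list("ACGT"), size=lb))
            got = global_align(NucleotideSeq(id="a", seq=a), NucleotideSeq(id="b", seq=b), p)
            assert got.score == pytest.approx(nw_bruteforce(a, b, p))

    def test_score_matches_biopython_on_longer_sequences(self):
        # independent implementation cross-check at realistic lengths
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        p = AlignParams()
        aligner.match_score = p.match
        aligner.mismatch_score = p.mismatch
        aligner.open_gap_score = p.gap_open
        aligner.extend_gap_score = p.gap_extend
        rng = np.random.default_rng(23)
        for _ in range(25):
            la, lb = int(rng.integers(20, 90)), int(rng.integers(20, 90))
            a = "".join(rng.choice(list("ACGT"), size=la))
            b = "".join(rng.choice(list("ACGT"), size=lb))
            got = global_align(
                NucleotideSeq(id="a", seq=a), NucleotideSeq(id="b", seq=b), p
            )
            assert got.score == pytest.approx(aligner.score(a, b))

    def test_gapped_strings_recover_inputs(self):
        a = NucleotideSeq(id="a", seq="ACGTTTACGGA")
        b = NucleotideSeq(id="b", seq="ACGACGGATTT")
        aln = global_align(a, b)
        assert aln.aligned_a.replace("-", "") == a.seq
        assert aln.aligned_b.replace("-", "") == b.seq
        assert not any(
            x == y == "-" for x, y in zip(aln.aligned_a, aln.aligned_b)
        )

    def test_empty_input_errors(self):
        with pytest.raises(Exception):
            global_align(NucleotideSeq(id="a", seq="A"), NucleotideSeq(id="b", seq=""))


class TestDistances:
    def test_identical_pair_zero(self):
        s = NucleotideSeq(id="s", seq="ACGT" * 10)
        assert p_distance(global_align(s, s)) == 0.0

    def test_two_mismatches_over_hundred(self):
        a = "A" * 100
        b = "C" * 2 + "A" * 98
        aln = PairwiseAlignment(a, b, 0.0, 0.98)
        assert p_distance(aln) == pytest.approx(0.02)

    def test_hand_counted_toy_alignment(self):
        # 12 columns: 2 gap columns excluded, 3 mismatches in 10 compared
        aln = PairwiseAlignment("ACGTAC-TACGT", "ACCTAAGT-CGA", 0.0, 0.0)
        assert p_distance(aln) == pytest.approx(3 / 10)

    def test_all_gap_columns_error(self):
        with pytest.raises(GliaError):
            p_distance(PairwiseAlignment("A--", "-GG", 0.0, 0.0))

    def test_jukes_cantor_monotone_and_domain(self):
        assert jukes_cantor(0.0) == 0.0
        assert jukes_cantor(0.1) > 0.1
        with pytest.raises(GliaError):
            jukes_cantor(0.8)


class TestUpgma:
    def test_hand_computed_three_taxa(self):
        dm = DistanceMatrix(["A", "B", "C"], np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        tree = upgma(dm)
        assert tree.newick() == "((A:1,B:1):1,C:2);"
        assert tree.is_ultrametric()

    def test_equal_distances_lexicographic_tie_break(self):
        labels = ["d", "b", "c", "a"]
        d = np.full((4, 4), 2.0)
        np.fill_diagonal(d, 0.0)
        tree = upgma(DistanceMatrix(labels, d))
        # first merge joins (a, b); heights all equal
        assert tree.newick() == "(((a:1,b:1):0,c:1):0,d:1);"
        assert tree.is_ultrametric()

    def test_random_matrices_ultrametric_and_leafset(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(2, 9))
            m = rng.uniform(0.01, 2.0, size=(n, n))
            d = (m + m.T) / 2
            np.fill_diagonal(d, 0.0)
            labels = [f"t{i}" for i in range(n)]
            tree = upgma(DistanceMatrix(labels, d))
            assert tree.is_ultrametric(tol=1e-9)
            assert sorted(tree.leaf_names()) == labels

    def test_merge_heights_match_scipy_average_linkage(self):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(3, 9))
            m = rng.uniform(0.1, 2.0, size=(n, n))
            d = (m + m.T) / 2
            np.fill_diagonal(d, 0.0)
            tree = upgma(DistanceMatrix([f"t{i}" for i in range(n)], d))
            heights = []

            def walk(node):
                if not node.is_leaf:
                    heights.append(node.height)
                    for c in node.children:
                        walk(c)

            walk(tree.root)
            expect = sorted(linkage(squareform(d), method="average")[:, 2] / 2)
            assert np.allclose(sorted(heights), expect)

    def test_input_order_invariance(self):
        rng = np.random.default_rng(3)
        n = 6
        m = rng.uniform(0.1, 1.0, size=(n, n))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0.0)
        labels = [f"t{i}" for i in range(n)]
        ref = upgma(DistanceMatrix(labels, d)).newick()
        perm = rng.permutation(n)
        d2 = d[np.ix_(perm, perm)]
        labels2 = [labels[i] for i in perm]
        assert upgma(DistanceMatrix(labels2, d2)).newick() == ref

    def test_invalid_matrix_rejected(self):
        with pytest.raises(GliaError):
            DistanceMatrix(["a", "b"], np.array([[0, -1], [-1, 0]], float))
        with pytest.raises(GliaError):
            upgma(DistanceMatrix(["a"], np.zeros((1, 1))))

    def test_newick_parses_with_dendropy(self):
        import dendropy

        dm = DistanceMatrix(["A", "B", "C"], np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        t = dendropy.Tree.get(data=upgma(dm).newick(), schema="newick")
        assert {l.taxon.label for l in t.leaf_node_iter()} == {"A", "B", "C"}


class TestMsa:
    def test_two_sequences_degenerate_to_pairwise(self):
        a = NucleotideSeq(id="a", seq="ACGTTTACG")
        b = NucleotideSeq(id="b", seq="ACGACG")
        pair = global_align(a, b)
        msa = progressive_msa([a, b])
        assert msa == {"a": pair.aligned_a, "b": pair.aligned_b}

    def test_identical_sequences_gap_free(self):
        seqs = [NucleotideSeq(id=f"s{i}", seq="ACGTACGTAA") for i in range(3)]
        msa = progressive_msa(seqs)
        assert all("-" not in row for row in msa.values())

    def test_planted_substitutions_in_distinct_columns(self):
        base = "ATG" + "ACGTTGCA" * 10 + "TAA"
        seqs = []
        for i in range(4):
            mutated = list(base)
            pos = 10 + 8 * i
            mutated[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[pos]]
            seqs.append(NucleotideSeq(id=f"s{i}", seq="".join(mutated)))
        msa = progressive_msa(seqs)
        rows = list(msa.values())
        assert len({len(r) for r in rows}) == 1
        variable = [
            c for c in range(len(rows[0]))
            if len({r[c] for r in rows}) > 1
        ]
        assert len(variable) == 4

    def test_requires_two_sequences(self):
        with pytest.raises(GliaError):
            progressive_msa([NucleotideSeq(id="a", seq="ACGT")])


class TestClades:
    def test_pure_clades_per_genome(self):
        cfg = SimulationConfig(
            seed=3, p_pseudogenization=0.0, n_genes={"A": 4, "B": 4, "D": 4},
            n_shared_ancestral=0,
        )
        sim = evolve_locus(cfg)
        genes = sim.all_genes()
        tree = upgma(distance_matrix([g.cds for g in genes]))
        clades = extract_clades(tree, {g.gene_id: g.genome for g in genes})
        pure_by_genome = {}
        for c in clades["pure"]:
            pure_by_genome.setdefault(c["genome"], []).append(c["leaves"])
        assert set(pure_by_genome) == {"A", "B", "D"}
        assert max(len(l) for l in pure_by_genome["A"]) == 4

    def test_shared_ancestral_genes_form_mixed_clade(self):
        cfg = SimulationConfig(
            seed=3, p_pseudogenization=0.0, n_genes={"A": 4, "B": 4, "D": 4},
            n_shared_ancestral=1,
        )
        sim = evolve_locus(cfg)
        genes = sim.all_genes()
        tree = upgma(distance_matrix([g.cds for g in genes]))
        clades = extract_clades(tree, {g.gene_id: g.genome for g in genes})
        assert any(len(c["genomes"]) >= 2 for c in clades["mixed"])

    def test_single_genome_star_is_one_pure_clade(self):
        labels = {f"t{i}": "A" for i in range(4)}
        d = np.full((4, 4), 1.0)
        np.fill_diagonal(d, 0.0)
        tree = upgma(DistanceMatrix(list(labels), d))
        clades = extract_clades(tree, labels)
        assert len(clades["pure"]) == 1 and clades["mixed"] == []

    def test_unlabeled_leaf_errors(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0]], float))
        with pytest.raises(GliaError, match="unlabeled"):
            extract_clades(upgma(dm), {"A": "A"})


class TestIndels:
    def test_21nt_deletion_single_in_frame_event(self):
        full = back_translate("MKTA" + THIRTY_THREE_MER + "SPQLVRA", stop=True)
        short_pep = "MKTA" + THIRTY_THREE_MER[:13] + THIRTY_THREE_MER[20:] + "SPQLVRA"
        short = back_translate(short_pep, stop=True)
        events = indel_report(global_align(short, full))
        assert len(events) == 1
        ev = events[0]
        assert (ev.length, ev.in_frame, ev.inserted_in) == (21, True, "b")

    def test_no_gaps_empty(self):
        s = NucleotideSeq(id="s", seq="ACGT" * 5)
        assert indel_report(global_align(s, s)) == []

    def test_runs_match_bruteforce_rle(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            n = int(rng.integers(4, 30))
            cols = []
            prev_both = False
            for _ in range(n):
                choice = rng.choice(["m", "ga", "gb"], p=[0.6, 0.2, 0.2])
                cols.append(choice)
            a = "".join("-" if c == "ga" else "A" for c in cols)
            b = "".join("-" if c == "gb" else "A" for c in cols)
            if all(c != "m" for c in cols):
                continue
            aln = PairwiseAlignment(a, b, 0.0, 0.0)
            events = indel_report(aln)
            # oracle: run-length encode the gap mask of each row
            import itertools

            expect = []
            for row, who in ((a, "b"), (b, "a")):
                pos = 0
                for is_gap, grp in itertools.groupby(row, key=lambda ch: ch == "-"):
                    length = len(list(grp))
                    if is_gap:
                        expect.append((pos, length, who))
                    pos += length
            expect.sort()
            got = sorted((e.position, e.length, e.inserted_in) for e in events)
            assert got == expect


class TestEpitopeGainLoss:
    def _pair(self):
        full = back_translate("MKTA" + THIRTY_THREE_MER + "SPQLVRA", stop=True)
        short_pep = "MKTA" + THIRTY_THREE_MER[:13] + THIRTY_THREE_MER[20:] + "SPQLVRA"
        short = back_translate(short_pep, stop=True)
        return short, full

    def test_33mer_gain_with_associated_indel(self):
        short, full = self._pair()
        report = epitope_gain_loss(short, full)
        assert report["gained_33mer"] and not report["lost_33mer"]
        assert report["epitope_diff"]["DQ2.5-glia-a2"] == 1
        assert len(report["indels"]) == 1 and report["indels"][0].in_frame
        assert report["associated_indels"]

    def test_33mer_loss_in_reverse_direction(self):
        short, full = self._pair()
        report = epitope_gain_loss(full, short)
        assert report["lost_33mer"] and not report["gained_33mer"]

    def test_identical_pair_empty_diff(self):
        _, full = self._pair()
        report = epitope_gain_loss(full, full)
        assert report["epitope_diff"] == {} and report["indels"] == []

    def test_indel_outside_epitope_region_reports_indel_only(self):
        pep = "MKTA" + THIRTY_THREE_MER + "SPQLVRAGSTNIVAGL"
        full = back_translate(pep, stop=True)
        shorter = back_translate(pep[:-6], stop=True)  # trim 6 C-terminal aa
        report = epitope_gain_loss(shorter, full)
        assert report["epitope_diff"] == {}
        assert any(e.length == 18 for e in report["indels"])
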