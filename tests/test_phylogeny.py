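import random

import numpy as np
import pytest

from panortho.alignment import ProteinMSA
from panortho.phylogeny import (DistanceMatrix, MLConfig, external_ml_adapter,
                                nj_tree, p_distances, read_newick,
                                write_newick)

from _oracles import random_additive_matrix, tree_path_distances


def _dm(taxa, rows):
    return DistanceMatrix(taxa=taxa, d=np.array(rows, dtype=float))


class TestPDistances:
    def test_identical_rows_zero(self):
        msa = ProteinMSA(og_id="x", rows={"a": "MKVL", "b": "MKVL"})
        assert p_distances(msa).value("a", "b") == 0.0

    def test_direct_mismatch_count(self):
        msa = ProteinMSA(og_id="x", rows={"a": "AAAA", "b": "AAAT"})
        assert p_distances(msa).value("a", "b") == 0.25

    def test_gapped_overlap_hand_enumerated(self):
        # only column 1 is non-gap in both rows; the residues there agree
        msa = ProteinMSA(og_id="x", rows={"a": "AA--", "b": "A-A-"})
        assert p_distances(msa).value("a", "b") == 0.0

    def test_no_overlap_fatal(self):
        msa = ProteinMSA(og_id="x", rows={"a": "AA--", "b": "--AA"})
        with pytest.raises(ValueError, match="insufficient overlap"):
            p_distances(msa)


class TestNJTree:
    def test_two_taxa_split_evenly(self):
        tree = nj_tree(_dm(["A", "B"], [[0, 0.4], [0.4, 0]]))
        assert write_newick(tree) == "(A:0.2,B:0.2);"

    def test_three_taxa_closed_form(self):
        tree = nj_tree(
            _dm(["A", "B", "C"], [[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]])
        )
        assert write_newick(tree) == "(A:0.1,B:0.3,C:0.5);"

    @pytest.mark.parametrize("trial", range(25))
    def test_recovers_random_additive_trees(self, trial):
        rng = random.Random(6000 + trial)
        n = rng.randint(4, 12)
        taxa = [f"t{i:02d}" for i in range(n)]
        D = random_additive_matrix(rng, n)
        tree = nj_tree(DistanceMatrix(taxa=taxa, d=D))
        D2 = tree_path_distances(tree, taxa)
        assert np.abs(D - D2).max() < 1e-9

    def test_agrees_with_reference_nj_topology(self):
        import dendropy
        from dendropy.calculate import treecompare

        rng = random.Random(71)
        n = 8
        taxa = [f"t{i}" for i in range(n)]
        D = random_additive_matrix(rng, n)
        ours = read_newick(write_newick(nj_tree(DistanceMatrix(taxa=taxa, d=D))))
        csv_rows = ["," + ",".join(taxa)]
        for i, t in enumerate(taxa):
            csv_rows.append(t + "," + ",".join(str(D[i, j]) for j in range(n)))
        import io

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=io.StringIO("\n".join(csv_rows) + "\n"), delimiter=","
        )
        ref = pdm.nj_tree()
        tns = ref.taxon_namespace
        ours_d = dendropy.Tree.get(
            data=write_newick(nj_tree(DistanceMatrix(taxa=taxa, d=D))),
            schema="newick", taxon_namespace=tns,
        )
        ref.encode_bipartitions()
        ours_d.encode_bipartitions()
        assert treecompare.symmetric_difference(ref, ours_d) == 0

    def test_negative_branches_clamped(self):
        # a non-additive matrix that drives a negative NJ branch estimate
        tree = nj_tree(
            _dm(
                ["A", "B", "C", "D"],
                [
                    [0, 0.1, 0.5, 0.5],
                    [0.1, 0, 0.5, 0.5],
                    [0.5, 0.5, 0, 0.05],
                    [0.5, 0.5, 0.05, 0],
                ],
            )
        )

        def lengths(node):
            out = [] if node.length is None else [node.length]
            for c in node.children:
                out.extend(lengths(c))
            return out

        assert all(l >= 0 for l in lengths(tree.root))


class TestNewick:
    def test_round_trip(self):
        rng = random.Random(83)
        taxa = [f"t{i}" for i in range(7)]
        D = random_additive_matrix(rng, 7)
        tree = nj_tree(DistanceMatrix(taxa=taxa, d=D))
        text = write_newick(tree)
        again = write_newick(read_newick(text))
        assert text == again

    def test_structural_recount(self):
        tree = read_newick("((A:1,B:1):1,C:1,D:1);")
        assert tree.leaf_names == ["A", "B", "C", "D"]
        internal = [
            n for n in _walk(tree.root) if n.children and n is not tree.root
        ]
        assert len(internal) == 1

    def test_malformed_raises_with_position(self):
        with pytest.raises(ValueError, match="malformed Newick"):
            read_newick("((A:1,B:1):1,C:1;")

    def test_deterministic_child_order(self):
        t1 = read_newick("(B:1,(D:1,C:1):1,A:1);")
        assert write_newick(t1) == "(A:1,B:1,(C:1,D:1):1);"


def _walk(node):
    yield node
    for c in node.children:
        yield from _walk(c)


class TestExternalMLAdapter:
    def _two_clade_supermatrix(self):
        rng = random.Random(97)
        base1 = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(120))
        base2 = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(120))

        def mutate(s, rate):
            return "".join(
                rng.choice("ACDEFGHIKLMNPQRSTVWY") if rng.random() < rate else c
                for c in s
            )

        rows = {
            "a1": mutate(base1, 0.02), "a2": mutate(base1, 0.02),
            "b1": mutate(base2, 0.02), "b2": mutate(base2, 0.02),
        }
        return ProteinMSA(og_id="sm", rows=rows)

    def test_missing_binary_falls_back_to_nj(self, caplog):
        sm = self._two_clade_supermatrix()
        with caplog.at_level("WARNING"):
            tree = external_ml_adapter(sm, MLConfig(binary="no-such-raxml"))
        assert "FALLING BACK" in caplog.text
        assert tree.leaf_names == ["a1", "a2", "b1", "b2"]
        assert write_newick(tree) == write_newick(nj_tree(p_distances(sm)))

    def test_two_clade_bipartition_recovered(self):
        sm = self._two_clade_supermatrix()
        tree = external_ml_adapter(sm, MLConfig(binary="no-such-raxml"))
        text = write_newick(tree)
        # the (a1,a2)|(b1,b2) split must appear as a clade either way round
        newick = read_newick(text)
        clades = {
            frozenset(lf.name for lf in n.leaves())
            for n in _walk(newick.root) if n.children
        }
        assert frozenset({"a1", "a2"}) in clades or frozenset({"b1", "b2"}) in clades
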