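import random

import pytest
from Bio.Align import substitution_matrices

from panortho.orf import ORFRecord, ProteomeTable
from panortho.search import (PairScore, SearchEngineConfig,
                             all_vs_all_top_hits, bit_score,
                             external_search_adapter, min_score_filter,
                             parse_tabular_hits, score_pair)

from _oracles import sw_local_score

AAS = "ACDEFGHIKLMNPQRSTVWY"
B62 = substitution_matrices.load("BLOSUM62")


def _proteome_from_seqs(seqs_by_genome):
    table = {}
    for genome, seqs in seqs_by_genome.items():
        table[genome] = [
            _make_orf(f"{genome}_{i:03d}", genome, aa) for i, aa in enumerate(seqs, 1)
        ]
    return ProteomeTable(table)


def _make_orf(orf_id, genome, aa):
    # nt_seq is a placeholder of the right length; the search reads only aa_seq
    return ORFRecord(
        orf_id, genome, "c", 0, 3 * len(aa) + 3, "+", "A" * (3 * len(aa)), aa
    )


class TestScorePair:
    def test_self_alignment_equals_diagonal_sum(self):
        s = "MKVLWAALLG"
        assert score_pair(s, s) == sum(B62[c][c] for c in s)

    def test_no_positive_pair_scores_zero(self):
        assert score_pair("WW", "PP") == 0.0

    def test_symmetry(self):
        a, b = "MKVLW", "MKW"
        assert score_pair(a, b) == score_pair(b, a)

    def test_empty_sequence_error(self):
        with pytest.raises(ValueError):
            score_pair("", "MK")

    @pytest.mark.parametrize("trial", range(50))
    def test_matches_exhaustive_dp(self, trial):
        rng = random.Random(4000 + trial)
        a = "".join(rng.choice(AAS) for _ in range(rng.randint(1, 30)))
        b = "".join(rng.choice(AAS) for _ in range(rng.randint(1, 30)))
        assert score_pair(a, b) == sw_local_score(a, b)


class TestMinScoreFilter:
    def _hits(self, scores):
        return [PairScore(f"q{i}", f"t{i}", s) for i, s in enumerate(scores)]

    def test_zero_floor_is_identity(self):
        hits = self._hits([0, 10, 500])
        assert min_score_filter(hits, 0) == hits

    def test_infinite_floor_empties(self):
        assert min_score_filter(self._hits([10, 500]), float("inf")) == []

    def test_negative_floor_rejected(self):
        with pytest.raises(ValueError):
            min_score_filter([], -1)

    def test_floor_separates_homologs_from_shuffled_decoys(self):
        rng = random.Random(8)
        true_pairs, decoy_pairs = [], []
        for _ in range(30):
            a = "".join(rng.choice(AAS) for _ in range(120))
            # homolog: a with 5% substitutions
            b = "".join(
                rng.choice(AAS) if rng.random() < 0.05 else c for c in a
            )
            shuffled = "".join(rng.sample(a, len(a)))
            true_pairs.append(bit_score(score_pair(a, b)))
            decoy_pairs.append(bit_score(score_pair(a, shuffled)))
        kept_true = [s for s in true_pairs if s >= 50]
        kept_decoy = [s for s in decoy_pairs if s >= 50]
        assert len(kept_true) == len(true_pairs)
        assert len(kept_decoy) <= 0.1 * len(decoy_pairs)


class TestAllVsAllTopHits:
    def test_two_genomes_one_orf_each(self):
        prot = _proteome_from_seqs({"a": ["MKVLWAALLGAA"], "b": ["MKVLWAALLGAA"]})
        th = all_vs_all_top_hits(prot, min_score=10)
        assert th.top_hit("a_001", "b").target_orf_id == "b_001"
        assert th.top_hit("b_001", "a").target_orf_id == "a_001"

    def test_below_floor_no_entry(self):
        prot = _proteome_from_seqs({"a": ["WWWWWW"], "b": ["PPPPPP"]})
        th = all_vs_all_top_hits(prot, min_score=50)
        assert th.top_hit("a_001", "b") is None

    def test_never_hits_own_genome(self):
        prot = _proteome_from_seqs(
            {"a": ["MKVLWAALLG", "MKVLWAALLG"], "b": ["MKVLWAALLG"]}
        )
        th = all_vs_all_top_hits(prot, min_score=10)
        genome_of = {o.orf_id: o.genome_id for o in prot.all_orfs()}
        assert all(tg != genome_of[q] for (q, tg) in th.hits)

    def test_matches_bruteforce_and_tiebreak(self):
        rng = random.Random(12)
        seqs = {
            g: ["".join(rng.choice(AAS) for _ in range(40)) for _ in range(3)]
            for g in ("a", "b", "c")
        }
        # plant exact duplicates to force score ties broken by smallest id
        seqs["b"][1] = seqs["b"][0]
        prot = _proteome_from_seqs(seqs)
        th = all_vs_all_top_hits(prot, min_score=0.0)
        orfs = prot.all_orfs()
        for q in orfs:
            for tg in ("a", "b", "c"):
                if tg == q.genome_id:
                    continue
                scored = [
                    (bit_score(score_pair(q.aa_seq, t.aa_seq)), t.orf_id)
                    for t in prot.orfs_by_genome[tg]
                ]
                best_score = max(s for s, _ in scored)
                expected = min(t for s, t in scored if s == best_score)
                got = th.top_hit(q.orf_id, tg)
                assert got is not None and got.target_orf_id == expected

    def test_invariant_under_genome_input_order(self):
        rng = random.Random(13)
        seqs = {
            g: ["".join(rng.choice(AAS) for _ in range(30))] for g in ("a", "b", "c")
        }
        prot_fwd = _proteome_from_seqs(seqs)
        prot_rev = _proteome_from_seqs(dict(reversed(list(seqs.items()))))
        th1 = all_vs_all_top_hits(prot_fwd, min_score=0)
        th2 = all_vs_all_top_hits(prot_rev, min_score=0)
        assert {k: v.target_orf_id for k, v in th1.hits.items()} == {
            k: v.target_orf_id for k, v in th2.hits.items()
        }


class TestExternalSearchAdapter:
    def _tab_line(self, q, t, score):
        return f"{q}\t{t}\t95.0\t40\t2\t0\t1\t40\t1\t40\t1e-20\t{score}"

    def test_parses_tabular_and_applies_tiebreak(self):
        prot = _proteome_from_seqs({"a": ["MKVLW"], "b": ["MKVLW", "MKVLW"]})
        text = "\n".join(
            [
                self._tab_line("a_001", "b_002", 80),
                self._tab_line("a_001", "b_001", 80),  # tie -> b_001
                self._tab_line("b_001", "a_001", 80),
                self._tab_line("a_001", "a_001", 999),  # self-genome: ignored
            ]
        )
        th = parse_tabular_hits(text, prot, min_score=50)
        assert th.top_hit("a_001", "b").target_orf_id == "b_001"
        assert ("a_001", "a") not in th.hits

    def test_malformed_line_names_line(self):
        prot = _proteome_from_seqs({"a": ["MKVLW"], "b": ["MKVLW"]})
        with pytest.raises(ValueError, match="line 1"):
            parse_tabular_hits("a_001\tb_001\tbroken", prot)

    def test_missing_engine_falls_back(self, caplog):
        prot = _proteome_from_seqs({"a": ["MKVLWAALLG"], "b": ["MKVLWAALLG"]})
        with caplog.at_level("WARNING"):
            th = external_search_adapter(
                prot, SearchEngineConfig(binary="no-such-engine"), min_score=10
            )
        assert "falling back" in caplog.text
        assert th.top_hit("a_001", "b").target_orf_id == "b_001"
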