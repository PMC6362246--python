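"""Clustering, merge-parameter selection and overlap-consensus merging."""

import numpy as np
import pytest

from holotrans import reduce as red
from holotrans.orf import revcomp
from holotrans.simulate import SimulationConfig, generate_redundant_transcripts

from oracles import local_alignment_score


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        s = random_dna(np.random.default_rng(0), 100)
        assert red.pairwise_identity(s, s) == (1.0, 100, 1.0)

    def test_exact_substring_containment(self):
        rng = np.random.default_rng(1)
        long = random_dna(rng, 100)
        short = long[25:75]
        ident, ncols, cov = red.pairwise_identity(long, short)
        assert ident == 1.0
        assert ncols == 50
        assert cov == 1.0

    def test_score_matches_dp_oracle_on_random_pairs(self):
        """The aligner's optimal local score equals a hand-rolled Gotoh DP."""
        rng = np.random.default_rng(2)
        for _ in range(5):
            a, b = random_dna(rng, 120), random_dna(rng, 120)
            aln = red._best_local(a, b)
            score = aln.score if aln is not None else 0.0
            assert score == pytest.approx(local_alignment_score(a, b))

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            red.pairwise_identity("", "ACGT")


class TestGreedyCluster:
    def test_identical_sequences_form_one_cluster(self):
        s = random_dna(np.random.default_rng(3), 200)
        clusters = red.greedy_cluster(
            {"a": s, "b": s, "c": s}, red.ClusterParams(0.95, 0.9)
        )
        assert len(clusters) == 1
        assert sorted(clusters[0].members) == ["a", "b", "c"]

    def test_unrelated_sequences_stay_apart(self):
        rng = np.random.default_rng(4)
        a, b = random_dna(rng, 300), random_dna(rng, 300)
        # oracle: the best local alignment cannot reach 80% identity over
        # a meaningful span of two random 300-mers (score stays small)
        assert local_alignment_score(a, b) < 0.8 * 2 * 300
        clusters = red.greedy_cluster({"a": a, "b": b}, red.ClusterParams(0.80, 0.8))
        assert len(clusters) == 2

    def test_contained_fragment_joins_cluster(self):
        rng = np.random.default_rng(5)
        long = random_dna(rng, 1000)
        frag = long[400:500]
        clusters = red.greedy_cluster(
            {"long": long, "frag": frag}, red.ClusterParams(0.95, 0.9)
        )
        assert len(clusters) == 1
        assert clusters[0].representative == "long"

    def test_reverse_complement_member_is_recognized(self):
        rng = np.random.default_rng(6)
        s = random_dna(rng, 400)
        clusters = red.greedy_cluster(
            {"fwd": s, "rev": revcomp(s)}, red.ClusterParams(0.95, 0.9)
        )
        assert len(clusters) == 1

    def test_every_sequence_in_exactly_one_cluster(self):
        rng = np.random.default_rng(7)
        seqs = {f"s{i}": random_dna(rng, 300) for i in range(8)}
        clusters = red.greedy_cluster(seqs, red.ClusterParams(0.9, 0.8))
        members = [m for c in clusters for m in c.members]
        assert sorted(members) == sorted(seqs)


class TestAutoMergeParams:
    def test_short_members_hit_the_overlap_floor(self):
        p = red.auto_merge_params(["A" * 100] * 4, 0.95)
        assert p.min_overlap == 21  # 0.05 * 100 = 5 < 21
        assert p.overlap_identity == 0.95

    def test_kilobase_members_formula(self):
        p = red.auto_merge_params(["A" * 1000] * 4, 0.80)
        assert p.min_overlap == 50
        assert p.max_clip == 20

    def test_single_member_gives_valid_params(self):
        p = red.auto_merge_params(["A" * 500], 0.9)
        assert p.min_overlap >= 21
        assert red.merge_cluster({"only": "ACGT" * 125}, p)[0].seq == "ACGT" * 125


class TestMergeCluster:
    def test_exact_suffix_prefix_overlap_joins(self):
        """100 nt and 80 nt sharing a 30 nt end overlap merge into 150 nt."""
        rng = np.random.default_rng(8)
        s1 = random_dna(rng, 100)
        s2 = s1[70:] + random_dna(rng, 50)
        out = red.merge_cluster(
            {"s1": s1, "s2": s2}, red.MergeParams(21, 0.99)
        )
        assert len(out) == 1
        assert len(out[0].seq) == 150
        assert out[0].seq == s1[:70] + s2
        assert out[0].members == ("s1", "s2")

    def test_overlap_below_min_length_is_rejected(self):
        rng = np.random.default_rng(9)
        s1 = random_dna(rng, 100)
        s2 = s1[85:] + random_dna(rng, 60)  # 15 nt overlap < 21
        out = red.merge_cluster({"s1": s1, "s2": s2}, red.MergeParams(21, 0.99))
        assert len(out) == 2

    def test_identical_sequences_collapse_to_one(self):
        s = random_dna(np.random.default_rng(10), 200)
        out = red.merge_cluster({"a": s, "b": s}, red.MergeParams(21, 0.99))
        assert len(out) == 1
        assert out[0].seq == s

    def test_reverse_complement_overlap_joins(self):
        rng = np.random.default_rng(11)
        s1 = random_dna(rng, 120)
        s2 = revcomp(s1[80:] + random_dna(rng, 40))
        out = red.merge_cluster({"s1": s1, "s2": s2}, red.MergeParams(21, 0.99))
        assert len(out) == 1
        assert len(out[0].seq) == 160


class TestRunSchedule:
    def test_zero_noise_family_collapses_to_one_contig_per_gene(self):
        cfg = SimulationConfig(
            seed=3, n_genes=5, copies_per_gene=3, point_mutation_rate=0.0,
            truncation_fraction=0.0, utr_noise_len=0,
        )
        tset, truth = generate_redundant_transcripts(cfg)
        contigs, genes, _ = red.run_schedule(tset)
        assert len(contigs) == 5
        assert len(genes) == 5
        # no-loss: every input contributes to exactly one output contig
        members = [m for c in contigs for m in c.members]
        assert sorted(members) == sorted(tset)
        # idempotence on the reduced output
        again, genes2, _ = red.run_schedule({c.id: c.seq for c in contigs})
        assert sorted(c.seq for c in again) == sorted(c.seq for c in contigs)
        assert len(genes2) == 5

    def test_divergent_genes_never_merge(self):
        """Two genes at ~60% identity stay apart at every threshold >= 0.80."""
        rng = np.random.default_rng(12)
        a = random_dna(rng, 500)
        b_arr = np.array(list(a))
        mutate = rng.random(500) < 0.4
        for i in np.flatnonzero(mutate):
            b_arr[i] = rng.choice([c for c in "ACGT" if c != b_arr[i]])
        b = "".join(b_arr)
        contigs, genes, _ = red.run_schedule({"a": a, "b": b})
        assert len(contigs) == 2
        assert len(genes) == 2

    def test_single_sequence_passes_through(self):
        s = random_dna(np.random.default_rng(13), 400)
        contigs, genes, _ = red.run_schedule({"solo": s})
        assert len(contigs) == 1
        assert contigs[0].seq == s
        assert genes == {"solo": ["solo"]}

    def test_empty_input(self):
        contigs, genes, log = red.run_schedule({})
        assert contigs == [] and genes == {}

    def test_schedule_requires_non_increasing_identity(self):
        with pytest.raises(ValueError):
            red.ReductionSchedule(
                rounds=[red.ClusterParams(0.8, 0.8), red.ClusterParams(0.9, 0.8)]
            )
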