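"""Synthetic-data generators: determinism, moments, and truth closure."""

import numpy as np
import pytest
from scipy.stats import binom, poisson

from holotrans import simulate as sim
from holotrans.reduce import pairwise_identity


class TestRedundantTranscripts:
    def test_zero_noise_gives_identical_copies(self):
        cfg = sim.SimulationConfig(
            seed=1, n_genes=1, copies_per_gene=1, point_mutation_rate=0.0,
            truncation_fraction=0.0, utr_noise_len=0,
        )
        tset, truth = sim.generate_redundant_transcripts(cfg)
        assert len(tset) == 2
        seqs = list(tset.values())
        assert seqs[0] == seqs[1]
        assert len({gene for gene, _ in truth.values()}) == 1

    def test_within_gene_identity_stays_high_at_low_mutation(self):
        cfg = sim.SimulationConfig(
            seed=7, n_genes=5, copies_per_gene=3, point_mutation_rate=0.01,
            truncation_fraction=0.0, utr_noise_len=0,
        )
        tset, truth = sim.generate_redundant_transcripts(cfg)
        assert len(tset) == 20
        by_gene = {}
        for cid, (gene, _) in truth.items():
            by_gene.setdefault(gene, []).append(cid)
        for gene, ids in by_gene.items():
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    ident, _, _ = pairwise_identity(tset[ids[i]], tset[ids[j]])
                    assert ident >= 0.95

    def test_determinism(self):
        cfg = sim.SimulationConfig(seed=7, n_genes=3)
        assert sim.generate_redundant_transcripts(cfg) == (
            sim.generate_redundant_transcripts(cfg)
        )

    def test_truth_closure(self):
        cfg = sim.SimulationConfig(seed=2, n_genes=4, copies_per_gene=2)
        tset, truth = sim.generate_redundant_transcripts(cfg)
        assert set(tset) == set(truth)
        assert all(role in sim.ROLES for _, role in truth.values())

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            sim.SimulationConfig(point_mutation_rate=1.5)


class TestSpikeContaminants:
    def test_zero_spikes_leave_input_unchanged(self):
        cfg = sim.SimulationConfig(seed=1, n_genes=2)
        tset, _ = sim.generate_redundant_transcripts(cfg)
        out, hits = sim.spike_contaminants(tset, 0, seed=5)
        assert out == tset
        assert all(h.subject_group == "target_clade" for h in hits)

    def test_spiked_rows_flagged_non_target(self):
        cfg = sim.SimulationConfig(seed=1, n_genes=2)
        tset, _ = sim.generate_redundant_transcripts(cfg)
        out, hits = sim.spike_contaminants(tset, 3, seed=5)
        assert len(out) == len(tset) + 3
        others = [h for h in hits if h.subject_group == "other"]
        assert len(others) == 3
        assert all(h.query_coverage > 0.7 and h.percent_identity > 80 for h in others)


class TestStageCounts:
    def test_null_moments_match_nb_formulas(self):
        """Mean ~ mu and variance/mean ~ 1 + phi*mu at 1000 null genes."""
        cfg = sim.SimulationConfig(seed=11, n_genes=1000, de_fraction=0.0)
        cm, truth = sim.simulate_stage_counts(cfg)
        assert truth.empty
        x = cm.counts.to_numpy().ravel().astype(float)
        mu, phi = 100.0, 0.1
        var = mu + phi * mu**2  # 1100
        se_mean = np.sqrt(var / x.size)
        assert abs(x.mean() - mu) < 3 * se_mean
        # variance-to-mean ratio should sit near 1 + phi*mu = 11
        ratio = x.var(ddof=1) / x.mean()
        assert 9.0 < ratio < 13.0

    def test_planted_fold_change_shows_in_sample_means(self):
        cfg = sim.SimulationConfig(
            seed=13, n_genes=2000, de_fraction=0.05, fold_change=8.0
        )
        cm, truth = sim.simulate_stage_counts(cfg)
        ref = cm.reference_stage
        ratios = []
        for row in truth.itertuples():
            if row.direction == "up":
                ratios.append(
                    cm.counts.at[row.gene, row.stage]
                    / max(1, cm.counts.at[row.gene, ref])
                )
        assert np.median(ratios) == pytest.approx(8.0, rel=0.35)

    def test_seed_reproducibility(self):
        cfg = sim.SimulationConfig(seed=3, n_genes=50)
        a, _ = sim.simulate_stage_counts(cfg)
        b, _ = sim.simulate_stage_counts(cfg)
        assert a.counts.equals(b.counts)


class TestVariantSimulation:
    def _contigs(self, total_kb=100, n=100, seed=0):
        rng = np.random.default_rng(seed)
        size = total_kb * 1000 // n
        return {
            f"c{i:03d}": "".join(rng.choice(list("ACGT"), size=size))
            for i in range(n)
        }

    def test_tstv_and_density_within_closed_form_intervals(self):
        """Realized Ts/Tv and per-kb density on 100 kb stay inside 99% bounds."""
        contigs = self._contigs()
        cfg = sim.SimulationConfig(
            seed=11, snv_density=30.0, tstv_ratio=1.5, indel_fraction=0.05
        )
        recs = sim.simulate_variants(contigs, cfg, seed=11)
        n_total = len(recs)
        lam = 30.0 * 100  # density x kb
        assert poisson.ppf(0.005, lam) <= n_total <= poisson.ppf(0.995, lam)
        snvs = [r for r in recs if len(r.ref_allele) == len(r.alt_allele)]
        ts = sum(
            1 for r in snvs if {r.ref_allele, r.alt_allele} in ({"A", "G"}, {"C", "T"})
        )
        p0 = 1.5 / 2.5
        lo, hi = binom.ppf([0.005, 0.995], len(snvs), p0)
        assert lo <= ts <= hi

    def test_zero_density_gives_empty_table(self):
        cfg = sim.SimulationConfig(seed=1, snv_density=0.0)
        assert sim.simulate_variants(self._contigs(total_kb=10, n=10), cfg) == []

    def test_extreme_tstv_suppresses_transversions(self):
        cfg = sim.SimulationConfig(
            seed=2, snv_density=2.0, tstv_ratio=1e6, indel_fraction=0.0
        )
        recs = sim.simulate_variants(self._contigs(total_kb=50, n=50), cfg)
        assert len(recs) >= 50
        assert all(
            {r.ref_allele, r.alt_allele} in ({"A", "G"}, {"C", "T"}) for r in recs
        )

    def test_positions_unique_within_contig(self):
        contigs = self._contigs(total_kb=20, n=5)
        cfg = sim.SimulationConfig(seed=9, snv_density=30.0)
        recs = sim.simulate_variants(contigs, cfg)
        seen = {}
        for r in recs:
            assert r.position not in seen.get(r.contig, set())
            seen.setdefault(r.contig, set()).add(r.position)
            assert 1 <= r.position <= len(contigs[r.contig])


class TestAnnotation:
    def test_planted_term_attached_only_to_planted_genes(self):
        genes = [f"g{i}" for i in range(100)]
        ann, terms = sim.generate_annotation(
            genes, n_terms=30, terms_per_gene=3,
            planted_term="GO:9999999", planted_genes=genes[:10], seed=4,
        )
        with_term = {g for g, ts in ann.items() if "GO:9999999" in ts}
        assert with_term == set(genes[:10])
        assert "GO:9999999" in terms

    def test_no_terms_gives_empty_annotation(self):
        ann, terms = sim.generate_annotation(
            ["a", "b"], n_terms=10, terms_per_gene=0, seed=1
        )
        assert ann == {} and terms == {}

    def test_referential_closure(self):
        ann, terms = sim.generate_annotation(
            [f"g{i}" for i in range(20)], n_terms=15, terms_per_gene=4, seed=2
        )
        used = set().union(*ann.values())
        assert used == set(terms)

    def test_unknown_planted_gene_rejected(self):
        with pytest.raises(ValueError):
            sim.generate_annotation(
                ["a"], 5, 1, planted_term="GO:1", planted_genes=["zzz"], seed=0
            )
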