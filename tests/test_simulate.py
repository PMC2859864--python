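from collections import Counter

import numpy as np
import pytest
from scipy import stats

from flcdna._seq import revcomp
from flcdna.io_formats import FastaRecord
from flcdna.simulate import (ConfigurationError, LengthDist, SimulationConfig,
                             simulate_clone_library, simulate_genome,
                             simulate_transcripts, simulate_variant_genome,
                             simulate_study)


def scaffold_map(genome):
    return {r.id: r.sequence for r in genome}


class TestConfig:
    def test_rates_validated(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(chimera_rate=1.5)
        with pytest.raises(ConfigurationError):
            SimulationConfig(snp_rate=0.5)

    def test_length_dist_validated(self):
        with pytest.raises(ConfigurationError):
            LengthDist(mean=100, median=200)
        with pytest.raises(ConfigurationError):
            LengthDist(mean=100, median=50, minimum=0)

    def test_lognormal_median_survives_clamping(self, rng):
        d = LengthDist(594, 264, minimum=70)
        draws = d.sample(rng, 30000)
        assert np.median(draws) == pytest.approx(264, rel=0.03)
        assert draws.min() >= 70


class TestGenome:
    def test_zero_genes_gives_empty_genome(self):
        genome, truth = simulate_genome(SimulationConfig(n_genes=0))
        assert genome == [] and truth.gene_models == []

    def test_same_seed_byte_identical(self):
        cfg = SimulationConfig(seed=9, n_genes=8)
        g1, t1 = simulate_genome(cfg)
        g2, t2 = simulate_genome(cfg)
        assert [(r.id, r.sequence) for r in g1] == \
            [(r.id, r.sequence) for r in g2]
        assert [g.exons_local for g in t1.gene_models] == \
            [g.exons_local for g in t2.gene_models]

    def test_all_introns_are_gt_ag_and_cds_complete(self):
        """Direct dinucleotide scan over every emitted intron and CDS."""
        genome, truth = simulate_genome(SimulationConfig(seed=1, n_genes=40))
        seqs = scaffold_map(genome)
        for g in truth.gene_models:
            scf = seqs[g.scaffold_id]
            for s, e in g.introns_genome():
                intron = scf[s:e] if g.strand == "+" else revcomp(scf[s:e])
                assert intron.startswith("GT") and intron.endswith("AG")
            cds = g.transcript[g.utr5_len:g.utr5_len + g.cds_len]
            assert cds.startswith("ATG")
            assert cds[-3:] in ("TGA", "TAA", "TAG")

    def test_genes_do_not_overlap(self):
        genome, truth = simulate_genome(SimulationConfig(seed=3, n_genes=25))
        by_scaffold = {}
        for g in truth.gene_models:
            by_scaffold.setdefault(g.scaffold_id, []).append(
                (g.offset, g.offset + g.region_len))
        for ivs in by_scaffold.values():
            ivs.sort()
            assert all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:]))


class TestVariantGenome:
    def test_zero_rate_is_identity(self):
        genome, _ = simulate_genome(SimulationConfig(seed=1, n_genes=3))
        variant, pos = simulate_variant_genome(genome, 0.0, seed=5)
        assert pos == []
        assert [r.sequence for r in variant] == [r.sequence for r in genome]

    def test_realized_count_within_binomial_3_sigma_on_10mb(self, rng):
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 10_000_000)])
        rate = 0.00061
        _, pos = simulate_variant_genome([FastaRecord("s", seq)], rate, seed=2)
        mean = len(seq) * rate
        sigma = (len(seq) * rate * (1 - rate)) ** 0.5
        assert abs(len(pos) - mean) < 3 * sigma

    def test_positions_bookkeeping_exact(self):
        genome, _ = simulate_genome(SimulationConfig(seed=1, n_genes=4))
        variant, pos = simulate_variant_genome(genome, 0.002, seed=7)
        seqs, vseqs = scaffold_map(genome), scaffold_map(variant)
        recorded = {(s, p) for s, p, _, _ in pos}
        for s, p, ref, alt in pos:
            assert seqs[s][p] == ref and vseqs[s][p] == alt and ref != alt
        for sid in seqs:
            diffs = {(sid, i) for i, (a, b)
                     in enumerate(zip(seqs[sid], vseqs[sid])) if a != b}
            assert diffs == {(s, p) for s, p in recorded if s == sid}

    def test_rate_out_of_range(self):
        with pytest.raises(ConfigurationError):
            simulate_variant_genome([], 0.2, seed=1)


class TestTranscripts:
    def test_zero_rates_give_only_reference_isoforms(self):
        genome, truth = simulate_genome(SimulationConfig(seed=2, n_genes=10))
        txs = simulate_transcripts(truth, {}, seed=1)
        assert all(t.event is None for t in txs)
        assert len(txs) == 10

    def test_retained_intron_length_arithmetic(self, study12):
        truth = study12.truth
        for t in truth.transcripts:
            if t.event != "retained_intron":
                continue
            g = truth.gene(t.gene_id)
            ilen = g.intron_lengths()[t.event_info["intron_idx"]]
            assert len(t.body) == len(g.transcript) + ilen

    def test_event_proportions_within_multinomial_99ci(self, big_truth):
        """>1000 planted events split per the configured class rates."""
        cfg, _genome, truth = big_truth
        rates = cfg.isoform_rates
        counts = Counter(t.event for t in truth.transcripts if t.event)
        n = sum(counts.values())
        assert n >= 1000
        total_rate = sum(rates.values())
        for ev, rate in rates.items():
            p = rate / total_rate
            lo, hi = stats.binom.interval(0.99, n, p)
            assert lo <= counts[ev] <= hi, (ev, counts[ev], (lo, hi))

    def test_poly_a_tails_on_all_transcripts(self, study12):
        for t in study12.truth.transcripts:
            assert 15 <= t.polya_len <= 40
            assert t.sequence.endswith("A" * t.polya_len)


class TestCloneLibrary:
    def test_counts_conserved_and_classes_complete(self, study12):
        lib = study12.library
        assert len(lib.reads) == len(lib.clones)
        classes = {c.clone_class for c in lib.clones}
        assert classes <= {"normal", "redundant", "chimera", "ncRNA",
                           "pathogen"}

    def test_no_artifacts_one_clone_per_transcript(self):
        genome, truth = simulate_genome(SimulationConfig(seed=4, n_genes=8))
        txs = simulate_transcripts(truth, {}, seed=1)
        cfg = SimulationConfig(seed=4, n_genes=8, chimera_rate=0,
                               ncrna_rate=0, pathogen_rate=0,
                               redundancy_mean=1.0)
        lib = simulate_clone_library(txs, cfg, seed=2)
        normal = [c for c in lib.clones if c.clone_class == "normal"]
        assert len(normal) == len(txs)

    def test_chimera_junction_carries_enzyme_site(self, study12):
        chimeras = [c for c in study12.truth.clones
                    if c.clone_class == "chimera"]
        assert chimeras
        for c in chimeras:
            j = c.chimera_junction
            assert c.insert[j:j + 6] == c.enzyme_site
            assert c.enzyme_site in ("GGATCC", "CTCGAG")

    def test_redundant_clones_are_5prime_truncations(self, study12):
        truth = study12.truth
        for c in truth.clones:
            if c.clone_class == "redundant":
                src = truth.transcript(c.source_tid).sequence
                assert c.insert == src[c.trunc5:]
                assert c.trunc5 <= 0.15 * len(src)

    def test_planted_polya_recovered_by_stripper(self, study12):
        """Generator self-consistency: the tail-stripping rule recovers the
        planted poly(A) interval exactly."""
        from flcdna.cds_utr import strip_polya
        for t in study12.truth.transcripts:
            body, (s, e) = strip_polya(t.sequence)
            assert body == t.body and e - s == t.polya_len


def test_study_seed_determinism():
    s1 = simulate_study(SimulationConfig(seed=6, n_genes=6))
    s2 = simulate_study(SimulationConfig(seed=6, n_genes=6))
    assert [(c.id, c.insert) for c in s1.truth.clones] == \
        [(c.id, c.insert) for c in s2.truth.clones]
    assert [r.qualities for r in s1.library.reads] == \
        [r.qualities for r in s2.library.reads]
    assert s1.truth.snp_positions == s2.truth.snp_positions
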