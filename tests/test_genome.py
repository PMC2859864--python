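import numpy as np
import pytest

from flcdna._seq import random_seq
from flcdna.cds_utr import strip_polya
from flcdna.genome import (GeneModel, TypedExon, Unmapped,
                           classify_exons, classify_splice_events,
                           estimate_snp_rate, exon_intron_stats,
                           map_to_genome, model_from_truth,
                           utr_intron_occurrence)


@pytest.fixture(scope="module")
def mapped12(study12):
    """All study12 transcripts mapped to their source genome."""
    models = {}
    for t in study12.truth.transcripts:
        body, _ = strip_polya(t.sequence)
        g = study12.truth.gene(t.gene_id)
        cds = (g.utr5_len, g.utr5_len + g.cds_len) if t.event is None else None
        m = map_to_genome(t.id, body, study12.genome_db, cds_interval=cds)
        models[t.id] = m
    return models


class TestMapping:
    def test_exact_exon_boundary_recovery(self, study12, mapped12):
        """Every noiseless transcript maps with exon boundaries equal to the
        truth GFF coordinates (truth-join oracle)."""
        truth = study12.truth
        for t in truth.transcripts:
            m = mapped12[t.id]
            assert not isinstance(m, Unmapped), t.id
            tm = model_from_truth(truth.gene(t.gene_id), t)
            assert sorted(e.genome_interval for e in m.exons) == \
                sorted(e.genome_interval for e in tm.exons), t.id
            assert m.strand == truth.gene(t.gene_id).strand
            m.validate()

    def test_diverged_copy_unmapped_low_identity(self, rng, study12):
        t = study12.truth.transcripts[0]
        body, _ = strip_polya(t.sequence)
        mutated = list(body)
        for pos in rng.choice(len(body), size=int(0.15 * len(body)),
                              replace=False):
            mutated[pos] = "ACGT"[("ACGT".index(mutated[pos]) + 1) % 4]
        m = map_to_genome("mut", "".join(mutated), study12.genome_db)
        assert isinstance(m, Unmapped) and m.reason == "low_identity"

    def test_foreign_3prime_extension_unmapped_low_coverage(self, rng,
                                                            study12):
        t = study12.truth.transcripts[0]
        body, _ = strip_polya(t.sequence)
        m = map_to_genome("ext", body + random_seq(rng, int(0.2 * len(body))),
                          study12.genome_db)
        assert isinstance(m, Unmapped) and m.reason == "low_coverage"

    def test_unrelated_sequence_unmapped_no_hit(self, rng, study12):
        m = map_to_genome("rand", random_seq(rng, 800), study12.genome_db)
        assert isinstance(m, Unmapped) and m.reason == "no_hit"


class TestExonTyping:
    @pytest.mark.parametrize("n,want", [
        (1, ["single"]),
        (3, ["initial", "internal", "terminal"]),
        (5, ["initial", "internal", "internal", "internal", "terminal"]),
    ])
    def test_types_by_count(self, n, want):
        exons = [TypedExon((i * 200, i * 200 + 100), (i * 100, (i + 1) * 100))
                 for i in range(n)]
        introns = [(e.genome_interval[1], f.genome_interval[0])
                   for e, f in zip(exons, exons[1:])]
        m = GeneModel("x", "s", "+", exons, introns,
                      [("GT", "AG")] * len(introns), 1.0, 1.0, 100)
        classify_exons(m)
        assert [e.type for e in m.exons] == want

    def test_typing_totals_invariant(self, study12):
        models = [model_from_truth(g) for g in study12.truth.gene_models]
        multi = sum(1 for m in models if m.n_exons > 1)
        single = sum(1 for m in models if m.n_exons == 1)
        types = [e.type for m in models for e in m.exons]
        assert types.count("initial") == types.count("terminal") == multi
        assert types.count("single") == single

    def test_per_type_medians_match_truth_computation(self, study12):
        models = [model_from_truth(g) for g in study12.truth.gene_models]
        stats = exon_intron_stats(models)
        want = {}
        for g in study12.truth.gene_models:
            lens = g.exon_lengths()
            if len(lens) == 1:
                want.setdefault("single", []).append(lens[0])
            else:
                want.setdefault("initial", []).append(lens[0])
                want.setdefault("terminal", []).append(lens[-1])
                want.setdefault("internal", []).extend(lens[1:-1])
        for t, vals in want.items():
            assert stats[f"exon_{t}_median"] == float(np.median(vals))


class TestStats:
    def test_two_exon_span_identity(self):
        exons = [TypedExon((0, 100), (0, 100)),
                 TypedExon((400, 600), (100, 300))]
        m = GeneModel("x", "s", "+", exons, [(100, 400)], [("GT", "AG")],
                      1.0, 1.0, 300)
        classify_exons(m)
        assert m.gene_length == 600
        assert m.gene_length == sum(m.exon_lengths()) + sum(m.intron_lengths())

    def test_no_models_is_an_error(self):
        with pytest.raises(ValueError):
            exon_intron_stats([])


class TestUtrIntronOccurrence:
    def _model(self, n_exons, start_idx, stop_idx):
        exons = [TypedExon((i * 300, i * 300 + 100), (i * 100, (i + 1) * 100))
                 for i in range(n_exons)]
        introns = [(e.genome_interval[1], f.genome_interval[0])
                   for e, f in zip(exons, exons[1:])]
        m = GeneModel("x", "s", "+", exons, introns,
                      [("GT", "AG")] * len(introns), 1.0, 1.0, 1,
                      start_codon_exon_index=start_idx,
                      stop_codon_exon_index=stop_idx)
        return classify_exons(m)

    def test_single_exon_genes_contribute_zero(self):
        models = [self._model(1, 0, 0) for _ in range(4)]
        assert utr_intron_occurrence(models) == (0.0, 0.0)

    def test_two_exon_gene_cannot_hit_internal(self):
        models = [self._model(2, 0, 1)]
        assert utr_intron_occurrence(models) == (0.0, 0.0)

    def test_planted_internal_start_frequency(self):
        models = [self._model(4, 1, 3) for _ in range(3)] + \
                 [self._model(4, 0, 3) for _ in range(7)]
        start_f, stop_f = utr_intron_occurrence(models)
        assert start_f == pytest.approx(0.3) and stop_f == 0.0


class TestSpliceEvents:
    def test_planted_events_classified_exactly(self, study12, mapped12):
        truth = study12.truth
        for t in truth.transcripts:
            if t.event is None:
                continue
            ref = mapped12[t.gene_id + ".t1"]
            iso = mapped12[t.id]
            events = classify_splice_events(ref, iso)
            assert [e.type for e in events] == [t.event], t.id

    def test_identical_models_yield_no_events(self, study12, mapped12):
        m = mapped12[study12.truth.transcripts[0].id]
        assert classify_splice_events(m, m) == []

    def test_non_overlapping_models_yield_nothing(self, study12, mapped12):
        ids = [t.id for t in study12.truth.transcripts
               if t.event is None]
        a, b = mapped12[ids[0]], mapped12[ids[1]]
        assert classify_splice_events(a, b) == []


class TestSnp:
    def test_rate_zero_on_own_genome(self, study12, mapped12):
        models = [m for m in mapped12.values() if not isinstance(m, Unmapped)]
        est = estimate_snp_rate(models)
        assert est.mismatches == 0 and est.rate == 0.0

    def test_pairs_below_identity_floor_excluded(self):
        good = GeneModel("a", "s", "+",
                         [TypedExon((0, 1000), (0, 1000), "single")], [], [],
                         0.999, 1.0, 1, exon_matches=999, exon_mismatches=1)
        bad = GeneModel("b", "s", "+",
                        [TypedExon((0, 1000), (0, 1000), "single")], [], [],
                        0.994, 1.0, 1, exon_matches=994, exon_mismatches=6)
        est = estimate_snp_rate([good, bad], identity_floor=0.995)
        assert est.pairs_used == 1 and est.mismatches == 1

    def test_no_qualifying_pairs_is_an_error(self):
        with pytest.raises(ZeroDivisionError):
            estimate_snp_rate([])

    def test_variant_genome_rate_recovers_planted_order(self, study12):
        models = []
        for t in study12.truth.transcripts:
            if t.event is not None:
                continue
            body, _ = strip_polya(t.sequence)
            m = map_to_genome(t.id, body, study12.variant_db)
            if not isinstance(m, Unmapped):
                models.append(m)
        est = estimate_snp_rate(models)
        # small sample: just require the right order of magnitude
        assert 0.0 <= est.rate_percent < 0.3
        assert est.aligned_exon_bases > 10_000
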