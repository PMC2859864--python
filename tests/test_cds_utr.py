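import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flcdna._seq import STOP_CODONS, random_seq, translate
from flcdna.cds_utr import (annotate_cdna, classify_completeness, composition,
                            extract_utrs, find_orfs, length_summary,
                            select_cds, stop_codon_usage, strip_polya)
from flcdna.io_formats import ReferenceDb


class TestStripPolya:
    def test_clean_tail(self):
        body, iv = strip_polya("ACGT" + "A" * 20)
        assert body == "ACGT" and iv == (4, 24)

    def test_tail_with_one_non_a_at_90pct(self):
        seq = "CCGG" + "A" * 9 + "G" + "A" * 10
        body, iv = strip_polya(seq)
        assert body == "CCGG" and iv == (4, 24)  # 19/20 A = 95% >= 90%

    def test_no_trailing_a(self):
        body, iv = strip_polya("ACGTT")
        assert body == "ACGTT" and iv == (5, 5)

    def test_short_a_run_not_stripped(self):
        body, iv = strip_polya("ACGT" + "A" * 9)
        assert body == "ACGT" + "A" * 9 and iv[1] - iv[0] == 0

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=60),
           st.integers(min_value=0, max_value=40))
    def test_body_plus_tail_partitions_input(self, prefix, tail_len):
        seq = prefix + "A" * tail_len
        body, (s, e) = strip_polya(seq)
        assert body + seq[s:e] == seq
        frac_a = seq[s:e].count("A") / (e - s) if e > s else 1.0
        assert frac_a >= 0.9


class TestFindOrfs:
    def test_minimal_orf_enumerated(self):
        orfs = find_orfs("ATGAAATAG")
        complete = [o for o in orfs if o.has_start and o.has_stop]
        assert len(complete) == 1 and complete[0].protein == "MK"

    def test_no_atg_no_complete_orfs(self):
        assert all(not o.has_start for o in find_orfs("CCCCCCCCCCCC"))

    def test_exhaustive_scan_oracle_on_random_2kb(self, rng):
        """Complete ORFs equal a direct triplet-walk enumeration."""
        seq = random_seq(rng, 2000)
        got = {(o.interval, o.frame) for o in find_orfs(seq)
               if o.has_start and o.has_stop}
        want = set()
        for frame in range(3):
            for a in range(frame, len(seq) - 2, 3):
                if seq[a:a + 3] != "ATG":
                    continue
                for p in range(a, len(seq) - 2, 3):
                    if seq[p:p + 3] in STOP_CODONS:
                        want.add(((a, p + 3), frame))
                        break
        assert got == want

    def test_sorted_by_protein_length_descending(self, rng):
        orfs = find_orfs(random_seq(rng, 1500))
        lens = [o.aa_len for o in orfs]
        assert lens == sorted(lens, reverse=True)


class TestSelectCds:
    def _db(self, prots):
        return ReferenceDb("p", "protein",
                           {f"p{i}": (p, f"protein {i}")
                            for i, p in enumerate(prots)})

    def test_homology_overrides_longer_hitless_orf(self, rng):
        """A shorter internal ORF with the only database hit wins over a
        longer ORF with no homology (exhaustive candidate x db check)."""
        prot = "M" + "".join(rng.choice(list("ARNDCQEGHILKV"), 60)) + ""
        cds = "ATG" + "".join({  # reverse-translate deterministically
            "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
            "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
            "L": "CTT", "K": "AAA", "V": "GTT"}[a] for a in prot[1:]) + "TAA"
        # embed a longer spurious ORF upstream with no stop codons inside
        long_orf = "ATG" + "GCT" * 100 + "TAA"
        cdna = long_orf + "CCTCC" + cds + "CC"
        db = self._db([prot])
        ann = select_cds("x", cdna, find_orfs(cdna), db)
        assert ann.protein == prot
        assert ann.selection_basis == "homology"

    def test_no_db_falls_back_to_longest_orf(self, rng):
        cdna = "ATG" + "GCA" * 50 + "TGA"
        ann = select_cds("x", cdna, find_orfs(cdna), None)
        assert ann.selection_basis == "longest_orf"
        assert ann.completeness == "full_length"

    def test_sub_10aa_orf_gives_none(self):
        cdna = "ATGAAAAAATAGCCCCCC"  # 2-aa protein only
        ann = select_cds("x", cdna, find_orfs(cdna), None)
        assert ann.completeness == "none" and ann.cds_interval is None

    def test_orf_running_off_3prime_end_is_partial(self):
        cdna = "CCC" + "ATG" + "GCA" * 30  # no stop before the end
        ann = select_cds("x", cdna, find_orfs(cdna), None)
        assert classify_completeness(ann) == "partial"
        assert ann.has_start and not ann.has_stop


class TestUtrs:
    def test_truth_utr_lengths_recovered(self, study12):
        truth = study12.truth
        for t in truth.transcripts:
            if t.event is not None:
                continue
            g = truth.gene(t.gene_id)
            res = annotate_cdna(t.id, t.sequence, study12.protein_db)
            assert res.annotation.cds_interval == (
                g.utr5_len, g.utr5_len + g.cds_len)
            assert (res.utrs.utr5_len, res.utrs.utr3_len) == \
                (g.utr5_len, g.utr3_len)

    def test_cds_at_position_zero_gives_empty_utr5(self):
        cdna = "ATG" + "GCA" * 20 + "TGA" + "CCTT" + "A" * 20
        res = annotate_cdna("x", cdna)
        assert res.utrs.utr5_len == 0 and res.utrs.utr3_len == 4

    def test_partition_identity(self, study12):
        for t in study12.truth.transcripts[:8]:
            res = annotate_cdna(t.id, t.sequence, study12.protein_db)
            if res.utrs is None:
                continue
            s, e = res.annotation.cds_interval
            total = (res.utrs.utr5_len + (e - s) + res.utrs.utr3_len
                     + res.utrs.polya_len)
            assert total == len(t.sequence)

    def test_extract_utrs_requires_full_length(self):
        cdna = "CCC" + "ATG" + "GCA" * 30
        res_ann = select_cds("x", cdna, find_orfs(cdna), None)
        with pytest.raises(ValueError):
            extract_utrs(cdna, res_ann)


class TestComposition:
    def test_pure_a(self):
        assert composition(["AAAA"])["A"] == 100.0

    def test_counts_equal_direct_tally(self, rng):
        seqs = [random_seq(rng, 500) for _ in range(10)]
        comp = composition(seqs)
        joined = "".join(seqs)
        for c in "ATGC":
            assert comp[c] == pytest.approx(
                100 * joined.count(c) / len(joined))
        assert sum(comp[c] for c in "ATGC") == pytest.approx(100.0)

    def test_n_and_x_excluded_from_denominator(self):
        comp = composition(["AANNXX"])
        assert comp["A"] == 100.0 and comp["N"] == 2 and comp["X"] == 2


class TestStopUsage:
    def test_all_tga(self):
        assert stop_codon_usage(["TGA"] * 5) == {"TGA": 100.0, "TAA": 0.0,
                                                 "TAG": 0.0}

    def test_fractions_sum_to_100(self, rng):
        stops = list(rng.choice(STOP_CODONS, 333))
        usage = stop_codon_usage(stops)
        assert sum(usage.values()) == pytest.approx(100.0)

    def test_non_stop_rejected(self):
        with pytest.raises(ValueError):
            stop_codon_usage(["ATG"])


class TestLengthSummary:
    @pytest.mark.parametrize("vals,want", [([1, 2, 3], (2, 2)),
                                           ([1, 2, 3, 4], (2.5, 2.5))])
    def test_mean_median(self, vals, want):
        assert length_summary(vals) == want

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            length_summary([])
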