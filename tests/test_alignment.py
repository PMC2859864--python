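import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flcdna._seq import revcomp
from flcdna.alignment import (CalibrationError, ScoringScheme, calibrate,
                              local_align, search)
from flcdna.io_formats import ReferenceDb
from ._oracles import sw_score


class TestCalibrate:
    def test_lambda_matches_bisection_oracle(self):
        """lambda for +1/-1 uniform solves 0.25 e^l + 0.75 e^-l = 1."""
        def f(lam):
            return 0.25 * math.exp(lam) + 0.75 * math.exp(-lam) - 1.0
        lo, hi = 1e-9, 10.0
        for _ in range(100):
            mid = (lo + hi) / 2
            if f(mid) < 0:
                lo = mid
            else:
                hi = mid
        lam, K = calibrate(ScoringScheme(match=1, mismatch=-1))
        assert lam == pytest.approx((lo + hi) / 2, abs=1e-9)
        assert 0 < K < 1

    def test_scaling_scores_halves_lambda(self):
        lam1, _ = calibrate(ScoringScheme(match=1, mismatch=-3))
        lam2, _ = calibrate(ScoringScheme(match=2, mismatch=-6))
        assert lam2 == pytest.approx(lam1 / 2, rel=1e-9)

    def test_all_match_scheme_is_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate(ScoringScheme(match=1, mismatch=1))

    def test_published_ungapped_constants(self):
        """+1/-3 uniform background: lambda 1.374, K 0.711 (literature)."""
        lam, K = calibrate(ScoringScheme(match=1, mismatch=-3))
        assert lam == pytest.approx(1.374, abs=2e-3)
        assert K == pytest.approx(0.711, rel=0.1)


class TestLocalAlign:
    def test_self_alignment(self):
        hit = local_align("ACGTACGT", "ACGTACGT")
        assert hit.identity == 1.0 and hit.align_len == 8
        assert hit.query_interval == (0, 8) and hit.strand == "+"

    def test_score_equals_independent_dp_on_300nt_pair(self, rng):
        bases = np.array(list("ACGT"))
        a = "".join(rng.choice(bases, 300))
        b = "".join(rng.choice(bases, 300))
        hit = local_align(a, b, strands="+")
        assert hit.score == sw_score(a, b)

    def test_reverse_complement_gives_minus_strand_same_score(self, rng):
        bases = np.array(list("ACGT"))
        a = "".join(rng.choice(bases, 120))
        ctx = "".join(rng.choice(bases, 40))
        subject = ctx + a + ctx[::-1]
        fwd = local_align(a, subject)
        rev = local_align(a, revcomp(subject))
        assert rev.score == fwd.score and rev.strand == "-"
        assert rev.subject_interval == (
            len(subject) - fwd.subject_interval[1],
            len(subject) - fwd.subject_interval[0])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            local_align("", "ACGT")

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=5, max_size=40),
           st.text(alphabet="ACGT", min_size=5, max_size=40))
    def test_score_symmetry(self, a, b):
        assert local_align(a, b).score == local_align(b, a).score

    def test_evalue_strictly_decreases_with_score(self):
        from flcdna.alignment import _evalue_log10, cached_calibration
        lam, K = cached_calibration(ScoringScheme())
        es = [_evalue_log10(s, 500, 500, lam, K) for s in range(10, 200, 10)]
        assert all(x > y for x, y in zip(es, es[1:]))


class TestSearch:
    def _db(self, rng, n=10, length=200):
        bases = np.array(list("ACGT"))
        recs = {f"d{i:02d}": ("".join(rng.choice(bases, length)), f"decoy {i}")
                for i in range(n)}
        return recs

    def test_identical_record_ranks_first(self, rng):
        recs = self._db(rng)
        query = recs["d03"][0]
        db = ReferenceDb("t", "transcript", recs)
        hits = search(query, db, max_evalue=1e-5)
        assert hits[0].subject_id == "d03"
        assert all(h.log10_evalue >= hits[0].log10_evalue for h in hits)

    def test_zero_max_evalue_yields_empty(self, rng):
        db = ReferenceDb("t", "transcript", self._db(rng))
        assert search("ACGTACGTACGT", db, max_evalue=0.0) == []

    def test_planted_homolog_beats_50_decoys(self, rng):
        """A 97%-identity homolog is the top hit over unrelated decoys,
        matching an exhaustive pairwise scan."""
        bases = np.array(list("ACGT"))
        query = "".join(rng.choice(bases, 400))
        hom = list(query)
        for pos in rng.choice(400, size=12, replace=False):
            hom[pos] = "ACGT"[(("ACGT".index(hom[pos])) + 1) % 4]
        recs = self._db(rng, n=50, length=400)
        recs["planted"] = ("".join(hom), "planted homolog")
        db = ReferenceDb("t", "transcript", recs)
        hits = search(query, db, max_evalue=10.0, mode="full")
        assert hits[0].subject_id == "planted"
        # exhaustive oracle: the planted record has the best DP score
        best = max(recs, key=lambda r: sw_score(query, recs[r][0]))
        assert best == "planted"

    def test_seeded_and_full_modes_agree_at_tight_threshold(self, rng):
        recs = self._db(rng, n=8, length=300)
        query = recs["d01"][0]
        db = ReferenceDb("t", "transcript", recs)
        full = search(query, db, max_evalue=1e-50, mode="full")
        seeded = search(query, db, max_evalue=1e-50, mode="seeded")
        assert [h.subject_id for h in full] == [h.subject_id for h in seeded]

    def test_empty_db_is_an_error(self):
        with pytest.raises(ValueError):
            search("ACGT", ReferenceDb("e", "transcript", {}))
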