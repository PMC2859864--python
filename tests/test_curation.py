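import numpy as np

from flcdna._seq import random_seq
from flcdna.curation import (Htc, descriptions_differ,
                             flag_chimera, flag_ncrna, flag_pathogen,
                             flag_retained_intron, remove_redundant,
                             run_curation)
from flcdna.io_formats import ReferenceDb
from flcdna.simulate import expected_dispositions
from ._oracles import sw_score


def mutate(rng, seq, n):
    out = list(seq)
    for pos in rng.choice(len(seq), size=n, replace=False):
        out[pos] = "ACGT"[("ACGT".index(out[pos]) + 1) % 4]
    return "".join(out)


class TestRedundancy:
    def test_identical_pair_collapses_to_one(self, rng):
        s = random_seq(rng, 1000)
        kept, groups = remove_redundant([Htc("a", s), Htc("b", s)])
        assert [h.id for h in kept] == ["a"]
        assert sorted(groups[0]) == ["a", "b"]

    def test_identity_threshold_97_vs_96(self, rng):
        """A planted 97%-identity pair collapses, a 96% pair does not; the
        independent DP oracle confirms the planted identities."""
        base = random_seq(rng, 1000)
        near = mutate(rng, base, 30)    # 97.0% identity
        far = mutate(rng, base, 45)     # 95.5% identity
        for other, expect_n in ((near, 1), (far, 2)):
            kept, _ = remove_redundant([Htc("a", base), Htc("b", other)])
            assert len(kept) == expect_n
        assert sw_score(base, near) == 1000 - 30 * 4  # oracle: 30 mismatches
        assert (1000 - 30) / 1000 >= 0.97 > (1000 - 45) / 1000

    def test_transitive_closure_collapses_chains(self, rng):
        """a~b and b~c link a chain even when a and c alone would not meet
        the pairwise criteria."""
        a = random_seq(rng, 1000)
        b = mutate(rng, a, 20)
        c = mutate(rng, b, 20)  # ~96% to a, ~98% to b
        kept, groups = remove_redundant([Htc("a", a), Htc("b", b),
                                         Htc("c", c)])
        assert len(kept) == 1 and len(groups[0]) == 3

    def test_longest_kept_then_smallest_id(self, rng):
        s = random_seq(rng, 800)
        kept, _ = remove_redundant([Htc("z", s), Htc("m", s + "ACGT"),
                                    Htc("a", s)])
        assert [h.id for h in kept] == ["m"]

    def test_idempotence(self, rng):
        seqs = [random_seq(rng, 600) for _ in range(4)]
        htcs = [Htc(f"h{i}", s) for i, s in enumerate(seqs)]
        kept1, _ = remove_redundant(htcs)
        kept2, _ = remove_redundant([Htc(h.id, h.sequence) for h in kept1])
        assert [h.id for h in kept1] == [h.id for h in kept2]


class TestContaminantFlags:
    def test_ncrna_exact_copy_flagged(self, rng):
        pool = {f"n{i}": (random_seq(rng, 500), "") for i in range(4)}
        db = ReferenceDb("nc", "ncrna", pool)
        assert flag_ncrna(Htc("x", pool["n2"][0]), db) is True
        assert flag_ncrna(Htc("y", random_seq(rng, 500)), db) is False

    def test_empty_ncrna_db_flags_nothing(self, rng):
        db = ReferenceDb("nc", "ncrna", {})
        assert flag_ncrna(Htc("x", random_seq(rng, 500)), db) is False

    def test_pathogen_flagged_unless_rescued_by_host(self, rng):
        pathogen = random_seq(rng, 600)
        pdb = ReferenceDb("p", "pathogen", {"p1": (pathogen, "")})
        host_without = ReferenceDb("h", "transcript",
                                   {"u1": (random_seq(rng, 600), "x 1")})
        host_with = ReferenceDb("h", "transcript",
                                {"u1": (pathogen, "conserved gene")})
        htc = Htc("x", pathogen)
        assert flag_pathogen(htc, pdb, host_without) is True
        # verbatim host copy matches at least as well: rescued
        assert flag_pathogen(Htc("y", pathogen), pdb, host_with) is False

    def test_unrelated_sequence_not_pathogen(self, rng):
        pdb = ReferenceDb("p", "pathogen", {"p1": (random_seq(rng, 600), "")})
        hdb = ReferenceDb("h", "transcript", {"u1": (random_seq(rng, 600), "")})
        assert flag_pathogen(Htc("x", random_seq(rng, 600)), pdb, hdb) is False


class TestChimera:
    def _setup(self, rng, two_scaffolds=True):
        a = random_seq(rng, 700)
        b = random_seq(rng, 700)
        chimera = a[:350] + "GGATCC" + b[350:]
        unigene = ReferenceDb("u", "transcript",
                              {"ua": (a, "kinase g1"), "ub": (b, "receptor g2")})
        if two_scaffolds:
            genome = ReferenceDb("g", "genome", {
                "s1": (random_seq(rng, 200) + a + random_seq(rng, 200), ""),
                "s2": (random_seq(rng, 200) + b + random_seq(rng, 200), "")})
        else:
            genome = ReferenceDb("g", "genome", {
                "s1": (a + random_seq(rng, 300) + b, "")})
        return chimera, a, unigene, genome

    def test_two_scaffold_chimera_fires_scaffold_rule(self, rng):
        chimera, _, unigene, genome = self._setup(rng, two_scaffolds=True)
        flagged, rule = flag_chimera(Htc("c", chimera), unigene, genome)
        assert flagged and rule == "scaffold"

    def test_single_scaffold_genome_falls_back_to_enzyme_site(self, rng):
        chimera, _, unigene, genome = self._setup(rng, two_scaffolds=False)
        flagged, rule = flag_chimera(Htc("c", chimera), unigene, genome)
        assert flagged and rule == "enzyme_site"

    def test_ordinary_transcript_not_flagged(self, rng):
        _, a, unigene, genome = self._setup(rng)
        flagged, rule = flag_chimera(Htc("t", a), unigene, genome)
        assert not flagged and rule == "none"

    def test_description_normalization(self):
        assert not descriptions_differ("putative kinase 1", "KINASE-1 protein")
        assert descriptions_differ("kinase g1", "receptor g2")
        # subset tolerance: fragment vs fuller annotation of the same gene
        assert not descriptions_differ("ribosomal", "ribosomal subunit L3")


class TestRetainedIntron:
    def test_planted_isoform_flagged_spliced_sibling_not(self, study12):
        truth = study12.truth
        unigene = study12.unigene_db
        found = 0
        for t in truth.transcripts:
            if t.event != "retained_intron":
                continue
            found += 1
            iso = Htc(t.id, t.sequence)
            sib = Htc(t.gene_id + ".t1",
                      truth.transcript(t.gene_id + ".t1").sequence)
            assert flag_retained_intron(iso, unigene) is True
            assert flag_retained_intron(sib, unigene) is False
        assert found > 0

    def test_sequence_without_homolog_not_flagged(self, rng, study12):
        htc = Htc("solo", random_seq(rng, 800))
        assert flag_retained_intron(htc, study12.unigene_db) is False


class TestCascade:
    def test_empty_input_all_counts_zero(self, study12):
        res = run_curation([], ncrna_db=study12.ncrna_db,
                           pathogen_db=study12.pathogen_db,
                           host_db=study12.unigene_db,
                           unigene_db=study12.unigene_db,
                           genome_db=study12.genome_db)
        assert res.kept == [] and res.ledger == []

    def test_full_synthetic_library_matches_truth_dispositions(self, study12):
        """Terminal disposition of every clone equals the truth-side
        expectation derived in closed form from planted geometry."""
        htcs = [Htc(c.id, c.insert) for c in study12.truth.clones]
        res = run_curation(htcs, ncrna_db=study12.ncrna_db,
                           pathogen_db=study12.pathogen_db,
                           host_db=study12.unigene_db,
                           unigene_db=study12.unigene_db,
                           genome_db=study12.genome_db)
        got = res.dispositions()
        want = expected_dispositions(study12)
        assert got == want
        for row in res.ledger:
            assert row.n_in == row.n_removed + row.n_kept
        for a, b in zip(res.ledger, res.ledger[1:]):
            assert a.n_kept == b.n_in
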