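import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import brute_force_sites
from sqamp.primers import (DegeneratePrimer, degeneracy, expand_degenerate,
                           find_binding_sites, in_silico_pcr, iupac_consensus,
                           primer_pair_coverage, primer_tm, propose_primers,
                           reverse_complement)


def _fwd(seq, name="F"):
    return DegeneratePrimer(name=name, seq=seq, orientation="forward")


def _rev(seq, name="R"):
    return DegeneratePrimer(name=name, seq=seq, orientation="reverse")


class TestExpansion:
    @pytest.mark.parametrize("seq,expected", [
        ("ATGATGATGA", {"ATGATGATGA"}),
        ("ARCARCARCA", None),   # checked via degeneracy product below
        ("ATGATGATNN", None),
    ])
    def test_size_matches_degeneracy(self, seq, expected):
        exp = expand_degenerate(seq)
        assert len(exp) == degeneracy(seq)
        if expected is not None:
            assert exp == expected

    def test_r_expands_to_a_and_g(self):
        assert expand_degenerate("ARC") == {"AAC", "AGC"}

    def test_nn_expands_to_16(self):
        assert len(expand_degenerate("NN")) == 16

    def test_illegal_character_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            expand_degenerate("ATZ")

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGTRYSWKMBDHVN", min_size=1, max_size=8))
    def test_every_expansion_matches_positionwise(self, seq):
        from sqamp.primers import IUPAC
        for e in expand_degenerate(seq):
            assert all(b in IUPAC[c] for b, c in zip(e, seq))


class TestBindingSites:
    def test_forward_exact_site(self):
        sites = find_binding_sites(_fwd("ATNGGCATNG"), "CCATCGGCATTGCC", 0)
        assert [(s.start, s.mismatches, s.strand) for s in sites] == [(2, 0, "+")]

    def test_reverse_primer_matches_revcomp(self):
        # reverse primer CATCATCATT binds where its revcomp AATGATGATG appears
        sites = find_binding_sites(_rev("CATCATCATT"), "CCAATGATGATGCC", 0)
        assert [(s.start, s.strand) for s in sites] == [(2, "-")]

    def test_primer_longer_than_template_is_empty(self):
        assert find_binding_sites(_fwd("ATGATGATGATG"), "ATG", 0) == []

    def test_template_ambiguity_needs_primer_superset(self):
        # template R: matched by primer N but a mismatch for primer A
        assert find_binding_sites(_fwd("ATGATGATGN"), "ATGATGATGR", 0)
        assert not find_binding_sites(_fwd("ATGATGATGA"), "ATGATGATGR", 0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        primer = "".join(rng.choice(list("ACGTRYN"), size=12))
        template = "".join(rng.choice(list("ACGT"), size=400))
        got = find_binding_sites(_fwd(primer), template, 2)
        expected = brute_force_sites(primer, template, 2,
                                     expand_degenerate(primer))
        assert [(s.start, s.mismatches) for s in got] == expected

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_zero_mismatch_equals_expansion_set_matching(self, seed):
        rng = np.random.default_rng(seed)
        primer = "".join(rng.choice(list("ACGTRY"), size=10))
        template = "".join(rng.choice(list("ACGT"), size=200))
        got = {s.start for s in find_binding_sites(_fwd(primer), template, 0)}
        exp = expand_degenerate(primer)
        want = {i for i in range(len(template) - 9)
                if template[i:i + 10] in exp}
        assert got == want


class TestInSilicoPcr:
    FWD = _fwd("ATGGCGTTAGCGCATG")
    REV = _rev("CCATTGCGCGTATGCA")

    def test_constructed_template_one_product(self):
        rng = np.random.default_rng(1)
        mid = "".join(rng.choice(list("ACGT"), size=300))
        template = self.FWD.seq + mid + reverse_complement(self.REV.seq)
        prods = in_silico_pcr(self.FWD, self.REV, template, 0, (50, 5000))
        assert len(prods) == 1
        amp, fs, rs = prods[0]
        assert len(amp) == 16 + 300 + 16
        assert amp == template

    def test_wrong_mutual_orientation_is_empty(self):
        rng = np.random.default_rng(2)
        mid = "".join(rng.choice(list("ACGT"), size=100))
        # reverse site upstream of forward site: no product
        template = reverse_complement(self.REV.seq) + mid + self.FWD.seq
        assert in_silico_pcr(self.FWD, self.REV, template, 0) == []

    def test_two_forward_sites_two_products(self):
        rng = np.random.default_rng(3)
        a = "".join(rng.choice(list("ACGT"), size=80))
        b = "".join(rng.choice(list("ACGT"), size=80))
        template = (self.FWD.seq + a + self.FWD.seq + b
                    + reverse_complement(self.REV.seq))
        prods = in_silico_pcr(self.FWD, self.REV, template, 0, (50, 5000))
        assert len(prods) == 2
        starts = [fs.start for _, fs, _ in prods]
        assert starts == sorted(starts)

    def test_amplicon_ends_reproduce_primer_sites(self):
        rng = np.random.default_rng(4)
        mid = "".join(rng.choice(list("ACGT"), size=150))
        template = "GG" + self.FWD.seq + mid + reverse_complement(self.REV.seq) + "AA"
        (amp, fs, rs), = in_silico_pcr(self.FWD, self.REV, template, 0)
        assert template[fs.start:fs.start + 16] == self.FWD.seq
        assert amp == template[fs.start:rs.start + 16]


class TestCoverage:
    def test_constructed_db_fraction(self):
        fwd, rev = TestInSilicoPcr.FWD, TestInSilicoPcr.REV
        rng = np.random.default_rng(5)
        db = []
        for i in range(10):
            mid = "".join(rng.choice(list("ACGT"), size=200))
            if i < 8:
                seq = fwd.seq + mid + reverse_complement(rev.seq)
            else:  # broken forward site
                seq = "T" * 16 + mid + reverse_complement(rev.seq)
            db.append((f"t{i}", seq))
        rep = primer_pair_coverage(fwd, rev, db, 0)
        assert rep.n_perfect == 8
        assert rep.fraction_perfect == pytest.approx(0.8)

    def test_empty_db_errors(self):
        with pytest.raises(ValueError):
            primer_pair_coverage(TestInSilicoPcr.FWD, TestInSilicoPcr.REV, [], 0)

    def test_monotone_in_mismatch_budget(self, small_dataset):
        db = [(e.id, e.nt_seq) for e in small_dataset.resource.entries]
        fwd, rev = small_dataset.fwd_primer, small_dataset.rev_primer
        reports = [primer_pair_coverage(fwd, rev, db, mm) for mm in (0, 1, 2)]
        # the perfect-match fraction is budget-independent ...
        assert len({r.fraction_perfect for r in reports}) == 1
        # ... while amplified coverage grows with the budget
        amplified = [r.n_amplified for r in reports]
        assert amplified == sorted(amplified)


class TestTm:
    @pytest.mark.parametrize("seq,expected", [
        ("AAAAAAAAAA", (20.0, 20.0, 20.0)),
        ("GGGGGGGGGG", (40.0, 40.0, 40.0)),
    ])
    def test_homopolymers(self, seq, expected):
        assert primer_tm(_fwd(seq)) == expected

    def test_degenerate_range(self):
        # RRRR plus a fixed AT-tail: R is A (2C) or G (4C) per position
        lo, mean, hi = primer_tm(_fwd("RRRRATATAT"))
        assert (lo, hi) == (2 * 4 + 12, 4 * 4 + 12)
        assert mean == pytest.approx(3 * 4 + 12)  # E[Tm] = 3C per R

    def test_degeneracy_cap(self):
        with pytest.raises(ValueError, match="cap"):
            primer_tm(_fwd("N" * 10), cap=1000)


class TestProposePrimers:
    def test_identical_rows_give_degeneracy_one_full_coverage(self):
        aln = {"a": "ATGGCGTTAGCGCATGCCAT", "b": "ATGGCGTTAGCGCATGCCAT"}
        out = propose_primers(aln, window=15, max_degeneracy=4)
        assert out
        for primer, frac in out:
            assert primer.degeneracy == 1
            assert frac == 1.0

    def test_variable_column_yields_r(self):
        aln = {"a": "ATGGCGTTAGCGCATGCCAT",
               "b": "ATGGCGTTGGCGCATGCCAT"}  # A/G at pos 8
        out = dict()
        for primer, frac in propose_primers(aln, window=20, max_degeneracy=8):
            out[primer.seq] = frac
        assert list(out) == ["ATGGCGTTRGCGCATGCCAT"]
        assert degeneracy("ATGGCGTTRGCGCATGCCAT") == 2

    def test_gapped_windows_skipped(self):
        aln = {"a": "ATG-CGTTAGCGCATGCCAT", "b": "ATGGCGTTAGCGCATGCCAT"}
        out = propose_primers(aln, window=16, max_degeneracy=4)
        assert all(int(p.name[3:]) > 3 for p, _ in out)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_consensus(self, seed):
        rng = np.random.default_rng(seed)
        rows = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(5)]
        aln = {f"r{i}": r for i, r in enumerate(rows)}
        window, cap = 18, 64
        got = {p.name: p.seq for p, _ in propose_primers(aln, window, cap)}
        want = {}
        for s in range(40 - window + 1):
            cons = iupac_consensus([r[s:s + window] for r in rows])
            if degeneracy(cons) <= cap:
                want[f"win{s}"] = cons
        assert got == want
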