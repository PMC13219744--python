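import numpy as np
import pytest

from sqamp.primers import reverse_complement
from sqamp.synth import SynthConfig, simulate_amplicons
from sqamp.verify import (Asv, TranslationResult, VerifyConfig, best_frame,
                          homology_filter, six_frame_translate, verify_asvs)


class TestSixFrameTranslate:
    def test_forward_frame_zero(self):
        assert six_frame_translate("ATGGCC")[0] == "MA"

    def test_stop_rendered_as_star(self):
        assert six_frame_translate("TAA")[0] == "*"

    def test_n_codon_becomes_x(self):
        assert six_frame_translate("ATGNNA")[0] == "MX"

    def test_reverse_strand_recovers_peptide(self):
        nt = "ATGGCCAAATTT"  # MAKF
        frames = six_frame_translate(reverse_complement(nt))
        assert "MAKF" in frames[3:]  # appears on the - strand

    def test_partial_codons_dropped(self):
        assert six_frame_translate("ATGGC")[0] == "M"
        assert six_frame_translate("ATGGC")[1] == "W"  # TGG-C

    def test_invalid_character_rejected(self):
        with pytest.raises(ValueError, match="non-ACGTN"):
            six_frame_translate("ATGU")


class TestBestFrame:
    @pytest.mark.parametrize("offset", [0, 1, 2])
    def test_recovers_frame_of_cds_cut(self, small_reference, offset):
        cds = small_reference.by_id["T000"].nt_seq
        read = cds[offset:offset + 300]
        tr = best_frame(Asv(id="x", nt_seq=read, counts={"s": 1}),
                        small_reference)
        assert tr.strand == "+"
        assert tr.frame == (3 - offset) % 3
        # the recovered peptide is a substring of the source protein
        core = tr.peptide.strip("X*")
        assert core in small_reference.by_id["T000"].protein_seq

    def test_reverse_complement_same_peptide(self, small_reference):
        cds = small_reference.by_id["T001"].nt_seq
        read = cds[60:360]
        fwd = best_frame(Asv(id="x", nt_seq=read, counts={}), small_reference)
        rev = best_frame(Asv(id="x", nt_seq=reverse_complement(read),
                             counts={}), small_reference)
        assert rev.strand == "-"
        assert rev.peptide == fwd.peptide
        assert rev.score == fwd.score

    def test_frame_recovery_under_sequencing_error(self, small_config):
        """>=99% correct frame recovery on simulated reads at 1% nt error."""
        from sqamp.synth import simulate_reference

        cfg = SynthConfig(seed=23, n_target_leaves=8, n_decoy_leaves=4,
                          protein_length=150, amplicon_start=61,
                          n_target_asvs=80, n_decoy_asvs=20,
                          nt_error_rate=0.01)
        resource, _ = simulate_reference(cfg)
        asvs, _, truth = simulate_amplicons(resource, cfg)
        t = truth.asvs.set_index("asv_id")
        correct = 0
        for asv in asvs:
            tr = best_frame(asv, resource)
            row = t.loc[asv.id]
            # the in-frame offset is the same on either strand: translating
            # the emitted read's correct strand starts at frame_offset
            correct += (tr.strand, tr.frame) == (row.strand, row.frame_offset)
        assert correct / len(asvs) >= 0.99


class TestHomologyFilter:
    def test_identical_peptide_is_candidate(self, small_reference):
        pep = small_reference.by_id["T002"].protein_seq
        tr = TranslationResult(frame=0, strand="+", peptide=pep,
                               internal_stops=0, score=0)
        v = homology_filter(tr, small_reference)
        assert v.status == "candidate"
        assert v.best_hit[0] == "T002"
        assert v.best_hit[1] == pytest.approx(1.0)

    def test_random_peptides_excluded(self, small_reference):
        """False-candidate rate below 1% on a random-sequence null."""
        rng = np.random.default_rng(0)
        aas = list("ARNDCQEGHILKMFPSTWYV")
        false = 0
        n = 150
        for _ in range(n):
            pep = "".join(rng.choice(aas, size=113))
            tr = TranslationResult(frame=0, strand="+", peptide=pep,
                                   internal_stops=0, score=0)
            false += homology_filter(tr, small_reference).status == "candidate"
        assert false / n < 0.01

    def test_two_planted_stops_excluded(self, small_reference):
        pep = list(small_reference.by_id["T000"].protein_seq[:120])
        pep[40] = "*"
        pep[80] = "*"
        tr = TranslationResult(frame=0, strand="+", peptide="".join(pep),
                               internal_stops=2, score=0)
        assert homology_filter(tr, small_reference).reason == "internal_stop"

    def test_single_error_stop_tolerated(self, small_reference):
        pep = list(small_reference.by_id["T000"].protein_seq[:120])
        pep[60] = "*"
        tr = TranslationResult(frame=0, strand="+", peptide="".join(pep),
                               internal_stops=1, score=0)
        assert homology_filter(tr, small_reference).status == "candidate"

    def test_short_peptide_excluded_first(self, small_reference):
        tr = TranslationResult(frame=0, strand="+", peptide="MKLV",
                               internal_stops=0, score=0)
        assert homology_filter(tr, small_reference).reason == "too_short"


class TestVerifyAsvs:
    def test_deterministic_and_count_conserving(self, small_dataset):
        res1 = verify_asvs(small_dataset.asvs, small_dataset.resource)
        res2 = verify_asvs(small_dataset.asvs, small_dataset.resource)
        assert [(r.verdict.status, r.verdict.reason) for r in res1] == \
               [(r.verdict.status, r.verdict.reason) for r in res2]
        total_in = sum(a.total_count for a in small_dataset.asvs)
        total_out = sum(r.asv.total_count for r in res1)
        assert total_in == total_out

    def test_sensitivity_and_specificity_on_synthetic_reads(self, small_dataset):
        """Marker-derived reads pass; random non-homologous reads fail."""
        records = verify_asvs(small_dataset.asvs, small_dataset.resource)
        truth = small_dataset.truth.asvs.set_index("asv_id")
        marker = [r for r in records if truth.loc[r.asv.id].is_target]
        sens = np.mean([r.verdict.status == "candidate" for r in marker])
        assert sens >= 0.95
        rng = np.random.default_rng(3)
        junk = [Asv(id=f"j{i}", nt_seq="".join(rng.choice(list("ACGT"), 340)),
                    counts={"s": 1}) for i in range(50)]
        jrec = verify_asvs(junk, small_dataset.resource)
        specificity = np.mean([r.verdict.status == "excluded" for r in jrec])
        assert specificity >= 0.99
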