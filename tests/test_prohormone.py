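"""Prohormone annotation: signal peptide, cleavage rules, mature peptides."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuromine.prohormone import (AnnotationError, RuleConfig, SignalSpan,
                                  annotate_precursor, derive_peptides,
                                  predict_cleavage_sites,
                                  predict_signal_peptide)
from neuromine.seq_io import ProteinRecord

SIGNAL = "MKTLVLLAVLACARA"  # end=15: A at -3/-1, hydrophobic core
AA = "ACDEFGHIKLMNPQRSTVWY"
protein_text = st.text(alphabet=AA, min_size=1, max_size=80)


def oracle_cleavage_positions(seq: str, signal_end,
                              rules: RuleConfig) -> list[int]:
    """Independent predicate-enumeration oracle for the cleavage rules.

    Visits every K/R index, keeps only run ends, and applies each rule
    predicate in isolation.  signal_end=None means no signal exclusion zone.
    """
    n = len(seq)
    out = []
    for i, ch in enumerate(seq):
        if ch not in "KR":
            continue
        if i + 1 < n and seq[i + 1] in "KR":
            continue  # not the run's C-terminal end
        pos = i + 1
        if pos >= n:
            continue  # terminal run: covered by the terminus site
        j = i
        while j >= 0 and seq[j] in "KR":
            j -= 1
        run = seq[j + 1:i + 1]
        if signal_end is not None and pos <= signal_end + rules.signal_margin:
            continue
        if rules.proline_blocks and seq[pos] == "P":
            continue
        L = len(run)
        if L >= 4:
            cleave = True
        elif L >= 2:
            cleave = rules.dibasic_enabled(run[-2:])
        elif run == "K":
            cleave = rules.monobasic_k
        else:
            cleave = rules.monobasic_r and any(
                0 <= pos + o < n and seq[pos + o] in "KR"
                for o in rules.monobasic_context)
        if cleave:
            out.append(pos)
    return out


class TestSignalPeptide:
    def test_canonical_signal_detected_at_boundary(self):
        p = ProteinRecord(id="p", seq=SIGNAL + "SDNEQSTHDFAVNDES")
        span = predict_signal_peptide(p)
        assert span is not None and span.end == 15

    def test_polyserine_n_terminus_rejected(self):
        p = ProteinRecord(id="p", seq="MSSSSSSSSSSSSASA" + "DNEQSTHD")
        assert predict_signal_peptide(p) is None

    def test_truncated_precursor_flags_incomplete(self):
        # no Met, no hydrophobic stretch: N-terminally truncated precursor
        p = ProteinRecord(id="p", seq="DNEQSTHDEDNEQSTHDEDNEQSTHDE")
        model = annotate_precursor(p)
        assert model.signal is None
        assert model.complete_n_terminus is False

    def test_override_channel(self):
        p = ProteinRecord(id="p", seq="DNEQSTHDEDNEQSTHDEDNEQSTHDE")
        span = predict_signal_peptide(p, override=SignalSpan(end=12, score=9.9))
        assert span.end == 12

    def test_span_bounds_enforced(self):
        with pytest.raises(AnnotationError):
            SignalSpan(end=8, score=0.0)


class TestCleavageSites:
    def test_dibasic_kr_site(self):
        p = ProteinRecord(id="p", seq="SDNFMRFGKRAS")
        sites = predict_cleavage_sites(p)
        internal = [s for s in sites if s.kind != "terminus"]
        assert len(internal) == 1
        s = internal[0]
        assert (s.position, s.kind, s.motif, s.basic_run) == \
               (10, "dibasic", "KR", 2)

    def test_no_basics_only_terminus(self):
        p = ProteinRecord(id="p", seq="AAAPAAA")
        sites = predict_cleavage_sites(p)
        assert len(sites) == 1 and sites[0].kind == "terminus"
        assert sites[0].position == 7

    def test_proline_blocks_dibasic(self):
        p = ProteinRecord(id="p", seq="AAAGKRPAAA")
        sites = predict_cleavage_sites(p)
        assert all(s.kind == "terminus" for s in sites)

    def test_monobasic_r_needs_basic_context(self):
        # lone R with K at -8 from the scissile bond -> cleaved
        yes = predict_cleavage_sites(ProteinRecord(id="p", seq="KAAAAAARSDEF"))
        assert any(s.kind == "monobasic" and s.position == 8 for s in yes)
        # same sequence without the upstream K -> not cleaved
        no = predict_cleavage_sites(ProteinRecord(id="p", seq="AAAAAAARSDEF"))
        assert all(s.kind == "terminus" for s in no)

    def test_lone_k_never_cleaved(self):
        p = ProteinRecord(id="p", seq="KAAAAAAKSDEF")
        sites = predict_cleavage_sites(p)
        assert all(s.kind == "terminus" for s in sites)

    def test_tetrabasic_single_site(self):
        p = ProteinRecord(id="p", seq="AAAARKRRSDEF")
        sites = predict_cleavage_sites(p)
        internal = [s for s in sites if s.kind != "terminus"]
        assert len(internal) == 1
        assert internal[0].kind == "tetrabasic"
        assert internal[0].basic_run == 4

    def test_matches_predicate_oracle_on_random_sequences(self):
        rnd = random.Random(42)
        rules = RuleConfig()
        alphabet = AA + "KRKRP"  # enrich rule-relevant residues
        for _ in range(300):
            seq = "".join(rnd.choice(alphabet)
                          for _ in range(rnd.randint(10, 60)))
            p = ProteinRecord(id="p", seq=seq)
            sites = predict_cleavage_sites(p, None, rules)
            got = [s.position for s in sites if s.kind != "terminus"]
            assert got == oracle_cleavage_positions(seq, None, rules), seq


class TestDerivePeptides:
    def test_amidated_fmrf_peptide(self):
        p = ProteinRecord(id="p", seq=SIGNAL + "SDNE" + "KR"
                          + "SDNELDFMRFG" + "KR" + "ASDE")
        model = annotate_precursor(p)
        seqs = {(pep.seq, pep.amidated) for pep in model.peptides}
        assert ("SDNELDFMRF", True) in seqs

    def test_pyroglutamate_and_amide_core(self):
        # adipokinetic-hormone-like layout: core right after the signal
        p = ProteinRecord(id="p", seq=SIGNAL + "QLNFSPGW" + "G" + "KR"
                          + "SDDNELA")
        model = annotate_precursor(p)
        first = model.peptides[0]
        assert first.seq == "QLNFSPGW"
        assert first.amidated and first.pyroglutamate

    def test_no_internal_sites_single_propeptide(self):
        p = ProteinRecord(id="p", seq=SIGNAL + "ADNEQSTHDFAVND")
        model = annotate_precursor(p)
        assert len(model.peptides) == 1
        assert model.peptides[0].seq == "ADNEQSTHDFAVND"
        assert not model.peptides[0].amidated

    def test_inconsistent_sites_rejected(self):
        from neuromine.prohormone import CleavageSite
        p = ProteinRecord(id="p", seq="AAAAKRAAAA")
        bad = [CleavageSite(6, "dibasic", "KR", 2),
               CleavageSite(6, "dibasic", "KR", 2)]
        with pytest.raises(AnnotationError):
            derive_peptides(p, None, bad)

    def test_degenerate_short_input(self):
        model = annotate_precursor(ProteinRecord(id="p", seq="ADNEQST"))
        assert model.signal is None
        assert model.complete_n_terminus is False
        assert len(model.peptides) == 1


class TestInvariants:
    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(protein_text)
    def test_reconstruction_conserves_sequence(self, seq):
        model = annotate_precursor(ProteinRecord(id="p", seq=seq))
        assert model.reconstruct() == seq

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(protein_text)
    def test_amidation_consumes_exactly_one_glycine(self, seq):
        model = annotate_precursor(ProteinRecord(id="p", seq=seq))
        for pep in model.peptides:
            if pep.amidated:
                assert model.core_seq[pep.end] == "G"
            # non-terminal peptides never keep their basic flank
            assert pep.end <= len(model.core_seq)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(protein_text)
    def test_no_internal_peptide_ends_in_basic(self, seq):
        # every peptide upstream of an internal site had its whole basic
        # run trimmed, so only the terminal peptide may end in K/R
        model = annotate_precursor(ProteinRecord(id="p", seq=seq))
        for pep in model.peptides[:-1]:
            assert not pep.seq.endswith(("K", "R"))

    def test_locality_of_downstream_extension(self):
        base = SIGNAL + "SDNE" + "KR" + "SDNELDFMRFG" + "KR"
        m1 = annotate_precursor(ProteinRecord(id="p", seq=base + "ASDE"))
        m2 = annotate_precursor(
            ProteinRecord(id="p", seq=base + "ASDENNNKRQSTW"))
        upstream1 = [(p.seq, p.amidated) for p in m1.peptides[:2]]
        upstream2 = [(p.seq, p.amidated) for p in m2.peptides[:2]]
        assert upstream1 == upstream2

    def test_kk_disabled_by_default_enabled_by_config(self):
        seq = "AAAADEFKKSDEF"
        p = ProteinRecord(id="p", seq=seq)
        default = predict_cleavage_sites(p)
        assert all(s.kind == "terminus" for s in default)
        opened = predict_cleavage_sites(p, None, RuleConfig(cleave_kk=True))
        assert any(s.kind == "dibasic" and s.motif == "KK" for s in opened)
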