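"""Smith-Waterman correctness and mining/orthology behaviour."""

import functools
import random

import numpy as np
import pytest
from Bio import Align

from neuromine.homology import (blosum62, calibrate_min_score, iterate_mine,
                                mine_sequences, rbh_orthologs, sw_align)
from neuromine.seq_io import ProteinRecord, TranscriptRecord
from neuromine.synth import evaluate_mining

AA = "ACDEFGHIKLMNPQRSTVWY"


def oracle_local_score(a: str, b: str, scheme) -> int:
    """Independent local-alignment oracle.

    Enumerates every substring pair and scores each by exhaustive (memoized)
    recursion over alignment columns with affine gap costs: a gap of length L
    costs open + (L-1)*extend.  Feasible for sequences of <= 8 residues.
    """
    go, ge = scheme.gap_open, scheme.gap_extend

    def global_score(x: str, y: str) -> int:
        @functools.lru_cache(maxsize=None)
        def rec(p: int, q: int, last: str) -> float:
            if p == len(x) and q == len(y):
                return 0
            best = -float("inf")
            if p < len(x) and q < len(y):
                best = max(best, scheme.score_pair(x[p], y[q])
                           + rec(p + 1, q + 1, "M"))
            if p < len(x):
                cost = ge if last == "U" else go
                best = max(best, cost + rec(p + 1, q, "U"))
            if q < len(y):
                cost = ge if last == "L" else go
                best = max(best, cost + rec(p, q + 1, "L"))
            return best

        return rec(0, 0, "M")

    best = 0
    for i0 in range(len(a)):
        for i1 in range(i0 + 1, len(a) + 1):
            for j0 in range(len(b)):
                for j1 in range(j0 + 1, len(b) + 1):
                    best = max(best, global_score(a[i0:i1], b[j0:j1]))
    return best


class TestSwAlign:
    def test_identical_pentapeptide_score(self, scheme):
        a = ProteinRecord(id="a", seq="FMRFG")
        h = sw_align(a, ProteinRecord(id="b", seq="FMRFG"), scheme)
        # 6+5+5+6+6 on the BLOSUM62 diagonal
        assert h.score == 28
        assert h.identity == 1.0

    def test_self_alignment_identity_and_diagonal_sum(self, scheme):
        rnd = random.Random(0)
        for _ in range(10):
            s = "".join(rnd.choice(AA) for _ in range(rnd.randint(3, 25)))
            h = sw_align(ProteinRecord(id="a", seq=s),
                         ProteinRecord(id="b", seq=s), scheme)
            assert h.identity == 1.0
            assert h.score == sum(scheme.score_pair(c, c) for c in s)

    def test_no_positive_pair_gives_empty_alignment(self, scheme):
        h = sw_align(ProteinRecord(id="a", seq="WWWW"),
                     ProteinRecord(id="b", seq="PPPP"), scheme)
        assert h.score == 0
        assert h.aligned_query == "" and h.aligned_subject == ""

    def test_empty_input_rejected(self, scheme):
        with pytest.raises(Exception):
            sw_align(ProteinRecord(id="a", seq="A"),
                     ProteinRecord(id="b", seq=""), scheme)

    def test_matches_exhaustive_oracle_short(self, scheme):
        rnd = random.Random(1)
        for _ in range(30):
            a = "".join(rnd.choice(AA) for _ in range(rnd.randint(1, 8)))
            b = "".join(rnd.choice(AA) for _ in range(rnd.randint(1, 8)))
            got = sw_align(ProteinRecord(id="a", seq=a),
                           ProteinRecord(id="b", seq=b), scheme).score
            assert got == oracle_local_score(a, b, scheme), (a, b)

    def test_matches_biopython_on_longer_sequences(self, scheme):
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = Align.substitution_matrices.load(
            "BLOSUM62")
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1
        rnd = random.Random(2)
        for _ in range(15):
            a = "".join(rnd.choice(AA) for _ in range(rnd.randint(10, 60)))
            b = "".join(rnd.choice(AA) for _ in range(rnd.randint(10, 60)))
            got = sw_align(ProteinRecord(id="a", seq=a),
                           ProteinRecord(id="b", seq=b), scheme).score
            assert got == int(aligner.score(a, b))

    def test_score_symmetric_under_swap(self, scheme):
        rnd = random.Random(3)
        for _ in range(10):
            a = "".join(rnd.choice(AA) for _ in range(rnd.randint(2, 30)))
            b = "".join(rnd.choice(AA) for _ in range(rnd.randint(2, 30)))
            ra, rb = ProteinRecord(id="a", seq=a), ProteinRecord(id="b", seq=b)
            assert sw_align(ra, rb, scheme).score == \
                   sw_align(rb, ra, scheme).score

    def test_appending_residues_never_decreases_score(self, scheme):
        rnd = random.Random(4)
        for _ in range(10):
            a = "".join(rnd.choice(AA) for _ in range(rnd.randint(2, 20)))
            b = "".join(rnd.choice(AA) for _ in range(rnd.randint(2, 20)))
            base = sw_align(ProteinRecord(id="a", seq=a),
                            ProteinRecord(id="b", seq=b), scheme).score
            ext = sw_align(
                ProteinRecord(id="a", seq=a + rnd.choice(AA)),
                ProteinRecord(id="b", seq=b + rnd.choice(AA)),
                scheme).score
            assert ext >= base


class TestMining:
    def test_planted_identity_hit(self, scheme):
        from neuromine.synth import embed_in_transcript
        rng = np.random.default_rng(11)
        q = ProteinRecord(id="q", seq="MKTLVLLAVLACARAQDNFMRFGKRSDQE")
        tr, _ = embed_in_transcript(q, rng, transcript_id="tx")
        hits = mine_sequences([tr], {"fam": [q]}, scheme, min_score=40,
                              orf_min_aa=10)
        assert hits
        assert hits[0][0].identity == 1.0

    def test_decoy_only_zero_hits(self, scheme, small_dataset):
        d = small_dataset
        decoys = [t for t in d.transcripts
                  if t.id in set(d.truth.decoy_ids)]
        cut = calibrate_min_score(decoys, d.panel, scheme, seed=5)
        hits = iterate_mine(decoys, d.panel, scheme, min_score=cut)
        assert hits == []

    def test_synthetic_recovery(self, scheme, small_dataset):
        d = small_dataset
        cut = calibrate_min_score(d.transcripts, d.panel, scheme, seed=5)
        hits = iterate_mine(d.transcripts, d.panel, scheme, min_score=cut)
        m = evaluate_mining(hits, d.truth)
        assert m["recall"] == 1.0
        assert m["decoy_hits"] == 0

    def test_recall_non_increasing_in_divergence(self, scheme):
        from neuromine.synth import generate_dataset
        recalls = []
        for div in (0.0, 0.3, 0.6):
            d = generate_dataset(n_precursors=6, divergence=div,
                                 n_decoys=0, seed=17, with_ms=False)
            cut = calibrate_min_score(d.transcripts, d.panel, scheme, seed=17)
            hits = mine_sequences(d.transcripts, d.panel, scheme,
                                  min_score=cut)
            recalls.append(evaluate_mining(hits, d.truth)["recall"])
        assert recalls[0] == 1.0
        assert recalls == sorted(recalls, reverse=True)

    def test_empty_panel_rejected(self, scheme):
        with pytest.raises(ValueError):
            mine_sequences([TranscriptRecord(id="t", seq="ATGAAATAG" * 20)],
                           {}, scheme)


class TestRbh:
    def test_identical_proteomes_all_reciprocal(self, scheme):
        prots = [ProteinRecord(id=f"p{i}", seq=s) for i, s in
                 enumerate(["MKTLVDEFWQNS", "AAWWNDEFHHKL", "GGPLVNSTFYWD"])]
        pairs = rbh_orthologs(prots, prots, scheme)
        assert all(p.reciprocal and p.id_a == p.id_b for p in pairs)

    def test_unrelated_extra_record_left_unpaired(self, scheme):
        p = ProteinRecord(id="p", seq="MKTLVDEFWQNSAAWWNDEFHH")
        q = ProteinRecord(id="q", seq="GGGGGGGGGGGG")
        pairs = rbh_orthologs([p], [p, q], scheme)
        assert len(pairs) == 1
        assert pairs[0].id_b == "p" and pairs[0].reciprocal

    def test_diverged_proteomes_recovered(self, scheme):
        from neuromine.synth import (default_blueprints, generate_precursor,
                                     mutate_protein)
        rng = np.random.default_rng(7)
        bps = default_blueprints()
        A, B = [], []
        for i in range(12):
            prot, truth = generate_precursor(bps[i % len(bps)], rng,
                                             precursor_id=f"p{i:02d}")
            A.append(ProteinRecord(id=f"a{i:02d}", seq=mutate_protein(
                prot.seq, 0.15, truth.critical_positions, rng)))
            B.append(ProteinRecord(id=f"b{i:02d}", seq=mutate_protein(
                prot.seq, 0.15, truth.critical_positions, rng)))
        pairs = rbh_orthologs(A, B, scheme)
        ok = sum(1 for p in pairs
                 if p.reciprocal and p.id_a[1:] == p.id_b[1:])
        assert ok / 12 >= 0.95
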