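"""Translated homology mining and reciprocal-best-hit orthology.

Implements the search the study performed with iterative tBLASTn: every
subject transcript is translated in six frames and scanned against a panel of
reference neuropeptide precursors with affine-gap Smith-Waterman alignment;
hits are extended to their maximal enclosing ORF.  Raw score + identity
thresholds (calibrated on a shuffled null) replace E-values, which are
database-size dependent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from . import _sw
from .seq_io import (OrfCall, ProteinRecord, TranscriptRecord,
                     dinucleotide_shuffle, find_orfs, six_frame_translate)


@dataclass
class ScoringScheme:
    """Substitution matrix plus affine gap penalties (both <= 0)."""

    name: str
    alphabet: str
    matrix: np.ndarray  # (len(alphabet), len(alphabet)) int32, symmetric
    gap_open: int = -11
    gap_extend: int = -1

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int32)
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if self.matrix.shape != (len(self.alphabet),) * 2:
            raise ValueError("matrix shape inconsistent with alphabet")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("substitution matrix must be symmetric")
        self._index = {c: i for i, c in enumerate(self.alphabet)}
        self._x = self._index.get("X")

    def encode(self, seq: str) -> np.ndarray:
        idx = self._index
        x = self._x
        out = np.empty(len(seq), dtype=np.int64)
        for i, c in enumerate(seq):
            j = idx.get(c, x)
            if j is None:
                raise ValueError(f"residue {c!r} not in scoring alphabet")
            out[i] = j
        return out

    def score_pair(self, a: str, b: str) -> int:
        return int(self.matrix[self._index.get(a, self._x),
                               self._index.get(b, self._x)])


def blosum62(gap_open: int = -11, gap_extend: int = -1) -> ScoringScheme:
    """BLOSUM62 with affine gaps; mirrors protein-BLAST defaults."""
    m = substitution_matrices.load("BLOSUM62")
    return ScoringScheme(
        name="BLOSUM62",
        alphabet=str(m.alphabet),
        matrix=np.asarray(m, dtype=np.int32),
        gap_open=gap_open,
        gap_extend=gap_extend,
    )


@dataclass
class AlignmentHit:
    """One local alignment between a panel query and a translated subject."""

    query_id: str
    subject_id: str
    frame: int
    score: int
    identity: float
    query_span: tuple[int, int]
    subject_aa_span: tuple[int, int]
    subject_nt_span: tuple[int, int]
    aligned_query: str
    aligned_subject: str
    family: Optional[str] = None

    @property
    def columns(self) -> int:
        return len(self.aligned_query)


@dataclass
class OrthologPair:
    id_a: str
    id_b: str
    score_ab: int
    score_ba: int
    reciprocal: bool


def _aa_to_nt_span(origin, aa_start: int, aa_end: int) -> tuple[int, int]:
    """Forward-strand nt span of an aa interval within a translation product."""
    if origin is None:
        return (0, 0)
    _, frame, nt_start, nt_end = origin
    if frame > 0:
        return nt_start + 3 * aa_start, nt_start + 3 * aa_end
    return nt_end - 3 * aa_end, nt_end - 3 * aa_start


def sw_align(a: ProteinRecord, b: ProteinRecord, s: ScoringScheme) -> AlignmentHit:
    """Optimal affine-gap Smith-Waterman local alignment of a (query) vs b.

    Deterministic traceback: at each cell ties prefer diagonal over vertical
    over horizontal moves, and among equal-scoring end cells the earliest in
    row-major order is taken.  A score of 0 yields an empty alignment.
    """
    if len(a.seq) == 0 or len(b.seq) == 0:
        raise ValueError("cannot align empty sequences")
    ea, eb = s.encode(a.seq), s.encode(b.seq)
    score, bi, bj, ptrH, ptrE, ptrF = _sw.sw_full(
        ea, eb, s.matrix, np.int32(s.gap_open), np.int32(s.gap_extend))
    score = int(score)
    frame = b.frame or 0
    if score <= 0:
        return AlignmentHit(a.id, b.id, frame, 0, 0.0, (0, 0), (0, 0),
                            _aa_to_nt_span(b.origin, 0, 0), "", "")
    # traceback
    i, j = bi, bj
    qa: list[str] = []
    qb: list[str] = []
    state = "H"
    while True:
        if state == "H":
            p = ptrH[i, j]
            if p == 0:
                break
            if p == 1:
                qa.append(a.seq[i - 1])
                qb.append(b.seq[j - 1])
                i -= 1
                j -= 1
            elif p == 2:
                state = "F"
            else:
                state = "E"
        elif state == "F":  # vertical: gap in subject
            qa.append(a.seq[i - 1])
            qb.append("-")
            ext = ptrF[i, j]
            i -= 1
            state = "F" if ext else "H"
        else:  # horizontal: gap in query
            qa.append("-")
            qb.append(b.seq[j - 1])
            ext = ptrE[i, j]
            j -= 1
            state = "H" if not ext else "E"
    qa.reverse()
    qb.reverse()
    aq, ab_ = "".join(qa), "".join(qb)
    matches = sum(1 for x, y in zip(aq, ab_) if x == y and x != "-")
    identity = matches / len(aq) if aq else 0.0
    return AlignmentHit(
        query_id=a.id, subject_id=b.id, frame=frame, score=score,
        identity=identity, query_span=(i, bi), subject_aa_span=(j, bj),
        subject_nt_span=_aa_to_nt_span(b.origin, j, bj),
        aligned_query=aq, aligned_subject=ab_,
    )


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)
            if "X" not in seq[i:i + k] and "*" not in seq[i:i + k]}


def _as_panel(panel) -> dict[str, list[ProteinRecord]]:
    if isinstance(panel, dict):
        return panel
    return {"unknown": list(panel)}


def mine_sequences(
    subjects: Sequence[TranscriptRecord],
    panel,
    s: Optional[ScoringScheme] = None,
    min_score: int = 60,
    min_identity: float = 0.25,
    orf_min_aa: int = 30,
    word_size: int = 4,
) -> list[tuple[AlignmentHit, OrfCall]]:
    """Six-frame translated search of a query panel against transcripts.

    ``panel`` is a mapping family -> list of ProteinRecord (a bare list is
    treated as one family).  For each (subject, family) only the best-scoring
    hit is kept; hits passing both thresholds are extended to the maximal
    enclosing ORF.  ``word_size`` > 0 enables an exact shared-word prefilter
    (seeding, as in BLAST) before full alignment; 0 disables it.

    Returns (hit, orf) pairs sorted by descending score.
    """
    s = s or blosum62()
    fam_panel = _as_panel(panel)
    if not any(fam_panel.values()):
        raise ValueError("query panel is empty")
    qk: dict[str, set[str]] = {}
    if word_size:
        for recs in fam_panel.values():
            for q in recs:
                qk[q.id] = _kmers(q.seq, word_size)
    results: list[tuple[AlignmentHit, OrfCall]] = []
    for t in subjects:
        if len(t.seq) < 3 * orf_min_aa:
            continue
        frames = six_frame_translate(t)
        fk = [_kmers(f.seq, word_size) if word_size else None for f in frames]
        ef = {}
        orfs: Optional[list[OrfCall]] = None
        for family, recs in fam_panel.items():
            best: Optional[AlignmentHit] = None
            best_key = None
            for q in recs:
                eq = None
                for fi, (f, fks) in enumerate(zip(frames, fk)):
                    if word_size and not (qk[q.id] & fks):
                        continue
                    if eq is None:
                        eq = s.encode(q.seq)
                    if fi not in ef:
                        ef[fi] = s.encode(f.seq)
                    sc = int(_sw.sw_score(eq, ef[fi], s.matrix,
                                          np.int32(s.gap_open),
                                          np.int32(s.gap_extend)))
                    key = (-sc, q.id, f.origin[1])
                    if sc >= min_score and (best_key is None or key < best_key):
                        hit = sw_align(q, f, s)
                        if hit.identity >= min_identity:
                            best, best_key = hit, key
            if best is None:
                continue
            if orfs is None:
                orfs = find_orfs(t, min_aa=orf_min_aa)
            orf = _enclosing_orf(orfs, best)
            if orf is None:
                continue
            best.family = family
            best.subject_id = t.id
            results.append((best, orf))
    results.sort(key=lambda ho: (-ho[0].score, ho[0].subject_id,
                                 ho[0].family or ""))
    return results


def _enclosing_orf(orfs: list[OrfCall], hit: AlignmentHit) -> Optional[OrfCall]:
    """The same-frame ORF overlapping the hit's nt span the most."""
    s, e = hit.subject_nt_span
    best = None
    best_ov = 0
    for o in orfs:
        if o.frame != hit.frame:
            continue
        ov = min(e, o.end) - max(s, o.start)
        if ov > best_ov:
            best, best_ov = o, ov
    return best


def iterate_mine(
    subjects: Sequence[TranscriptRecord],
    panel,
    s: Optional[ScoringScheme] = None,
    max_rounds: int = 5,
    **kwargs,
) -> list[tuple[AlignmentHit, OrfCall]]:
    """Iterative mining: accepted precursor ORFs join the panel and the
    search repeats until no new (subject, family) locus appears (<= max_rounds).
    """
    s = s or blosum62()
    fam_panel = {k: list(v) for k, v in _as_panel(panel).items()}
    accepted: dict[tuple[str, str], tuple[AlignmentHit, OrfCall]] = {}
    augmented: set[str] = set()
    for _ in range(max_rounds):
        hits = mine_sequences(subjects, fam_panel, s, **kwargs)
        new = False
        best_family: dict[str, str] = {}
        for hit, _ in hits:  # sorted by descending score
            best_family.setdefault(hit.subject_id, hit.family or "unknown")
        for hit, orf in hits:
            key = (hit.subject_id, hit.family or "")
            if key not in accepted:
                accepted[key] = (hit, orf)
                new = True
            # panel augmentation is gated on the subject's top-scoring
            # family (inclusion-threshold discipline, as in PSI-BLAST)
            # to keep weak cross-family hits from poisoning the panel
            if (hit.subject_id not in augmented
                    and best_family[hit.subject_id] == (hit.family
                                                        or "unknown")):
                augmented.add(hit.subject_id)
                fam_panel.setdefault(hit.family or "unknown", []).append(
                    orf.protein)
        if not new:
            break
    out = list(accepted.values())
    out.sort(key=lambda ho: (-ho[0].score, ho[0].subject_id,
                             ho[0].family or ""))
    return out


def calibrate_min_score(
    subjects: Sequence[TranscriptRecord],
    panel,
    s: Optional[ScoringScheme] = None,
    seed: int = 0,
    slack: float = 0.5,
    word_size: int = 4,
) -> int:
    """Empirical null calibration of the mining score threshold.

    Dinucleotide-shuffles every subject, scans the shuffled set against the
    panel with no thresholds, and returns ``ceil(null_max * (1 + slack)) + 1``.
    The shuffle preserves composition, so null_max estimates the score a
    biologically empty transcript reaches by chance; the relative slack
    absorbs the extreme-value fluctuation of that maximum between the
    calibration shuffle and the actual search (the best chance score over N
    sequences is Gumbel-distributed, so a fresh draw routinely exceeds a
    single observed maximum by a few points).
    """
    s = s or blosum62()
    rng = np.random.default_rng(seed)
    fam_panel = _as_panel(panel)
    queries = [q for recs in fam_panel.values() for q in recs]
    qk = {q.id: _kmers(q.seq, word_size) for q in queries} if word_size else {}
    eq = {q.id: s.encode(q.seq) for q in queries}
    null_max = 0
    for t in subjects:
        sh = TranscriptRecord(id=t.id + "|shuffled",
                              seq=dinucleotide_shuffle(t.seq, rng))
        for f in six_frame_translate(sh):
            fks = _kmers(f.seq, word_size) if word_size else None
            ef = s.encode(f.seq)
            for q in queries:
                if word_size and not (qk[q.id] & fks):
                    continue
                sc = int(_sw.sw_score(eq[q.id], ef, s.matrix,
                                      np.int32(s.gap_open),
                                      np.int32(s.gap_extend)))
                null_max = max(null_max, sc)
    return int(np.ceil(null_max * (1.0 + slack))) + 1


def rbh_orthologs(
    proteome_a: Sequence[ProteinRecord],
    proteome_b: Sequence[ProteinRecord],
    s: Optional[ScoringScheme] = None,
    min_score: int = 0,
) -> list[OrthologPair]:
    """Reciprocal-best-hit orthology between two proteomes.

    Best hit per query in each direction by alignment score, ties broken by
    lexicographic subject id; a pair is reciprocal iff mutually best.
    Returns one pair per proteome-A record with a best hit >= min_score.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")
    s = s or blosum62()
    ea = [s.encode(p.seq) for p in proteome_a]
    eb = [s.encode(p.seq) for p in proteome_b]
    go, ge = np.int32(s.gap_open), np.int32(s.gap_extend)
    scores = np.zeros((len(proteome_a), len(proteome_b)), dtype=np.int64)
    for i, xa in enumerate(ea):
        for j, xb in enumerate(eb):
            scores[i, j] = _sw.sw_score(xa, xb, s.matrix, go, ge)

    def best_of(row_scores, ids):
        m = row_scores.max()
        cands = sorted(ids[k] for k in np.flatnonzero(row_scores == m))
        return int(m), cands[0]

    ids_a = [p.id for p in proteome_a]
    ids_b = [p.id for p in proteome_b]
    best_b = {}
    for i, pa in enumerate(proteome_a):
        sc, bid = best_of(scores[i], ids_b)
        best_b[pa.id] = (sc, bid)
    best_a = {}
    for j, pb in enumerate(proteome_b):
        sc, aid = best_of(scores[:, j], ids_a)
        best_a[pb.id] = (sc, aid)
    pairs = []
    for pa in proteome_a:
        sc_ab, bid = best_b[pa.id]
        if sc_ab < min_score:
            continue
        sc_ba, back = best_a[bid]
        pairs.append(OrthologPair(
            id_a=pa.id, id_b=bid, score_ab=sc_ab, score_ba=sc_ba,
            reciprocal=(back == pa.id),
        ))
    return pairs


def hits_to_tsv(hits: Iterable[tuple[AlignmentHit, OrfCall]]) -> str:
    """BLAST outfmt-6-like table of mining hits."""
    cols = ["qid", "sid", "pident", "length", "qstart", "qend",
            "sstart", "send", "score", "frame", "family",
            "orf_start", "orf_end"]
    lines = ["\t".join(cols)]
    for h, o in hits:
        lines.append("\t".join(map(str, [
            h.query_id, h.subject_id, f"{100 * h.identity:.1f}", h.columns,
            h.query_span[0], h.query_span[1],
            h.subject_nt_span[0], h.subject_nt_span[1],
            h.score, f"{h.frame:+d}", h.family or "",
            o.start, o.end,
        ])))
    return "\n".join(lines) + "\n"
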