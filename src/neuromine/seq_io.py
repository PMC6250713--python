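"""Sequence I/O, six-frame translation and ORF calling.

All coordinates in this package are 0-based, half-open, and expressed on the
forward strand of the source record; reverse-frame features store the forward
coordinates of the interval they span.  Frames are numbered +1..+3 (forward)
and -1..-3 (reverse complement), as in translated BLAST searches.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NT_ALPHABET = set("ACGTN")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceError(ValueError):
    """Malformed sequence input (bad alphabet, duplicate ids, ...)."""


@dataclass
class TranscriptRecord:
    """A nucleotide sequence (assembled transcript or genome contig)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("transcript id must be non-empty")
        self.seq = self.seq.upper()
        if len(self.seq) < 1:
            raise SequenceError(f"transcript {self.id!r}: empty sequence")
        _check_alphabet(self.id, self.seq, NT_ALPHABET)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ProteinRecord:
    """An amino-acid sequence, optionally with translation provenance.

    ``origin`` is ``(transcript_id, frame, nt_start, nt_end)`` when the protein
    was produced by translation; the nucleotide span is on the forward strand.
    """

    id: str
    seq: str
    description: str = ""
    origin: Optional[tuple[str, int, int, int]] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("protein id must be non-empty")
        self.seq = self.seq.upper()
        if len(self.seq) < 1:
            raise SequenceError(f"protein {self.id!r}: empty sequence")
        _check_alphabet(self.id, self.seq, AA_ALPHABET)

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def frame(self) -> Optional[int]:
        return self.origin[1] if self.origin else None

    def validate(self) -> None:
        """Enforce the strict invariants of ORF/precursor proteins.

        Raw six-frame translation products may contain internal stops and are
        not expected to pass; ORF calls and annotated precursors are.
        """
        if "*" in self.seq[:-1]:
            raise SequenceError(f"protein {self.id!r}: internal stop codon")
        if self.origin is not None:
            _, _, start, end = self.origin
            aa = len(self.seq.rstrip("*"))
            span = end - start
            if not (3 * aa <= span <= 3 * aa + 3):
                raise SequenceError(
                    f"protein {self.id!r}: origin span {span} inconsistent "
                    f"with {aa} residues"
                )


@dataclass
class OrfCall:
    """A maximal open reading frame in one frame of a transcript.

    One call per stop-to-stop region: when the region contains a Met the call
    starts at the first Met (``has_start=True``); otherwise it covers the whole
    region as a partial ORF.  ``end`` includes the stop codon when present.
    """

    transcript_id: str
    frame: int
    start: int
    end: int
    protein: ProteinRecord
    has_start: bool
    has_stop: bool

    @property
    def aa_length(self) -> int:
        return len(self.protein.seq.rstrip("*"))


def _check_alphabet(rec_id: str, seq: str, alphabet: set[str]) -> None:
    for pos, ch in enumerate(seq):
        if ch not in alphabet:
            raise SequenceError(
                f"record {rec_id!r}: illegal character {ch!r} at position {pos}"
            )


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path, alphabet: str = "nt"):
    """Read a FASTA file into Transcript- or ProteinRecords.

    Parameters
    ----------
    path : file path
    alphabet : "nt" for nucleotide records, "aa" for protein records.

    Order is preserved; duplicate ids raise; lowercase is normalized.
    """
    if alphabet not in ("nt", "aa"):
        raise ValueError(f"alphabet must be 'nt' or 'aa', got {alphabet!r}")
    cls = TranscriptRecord if alphabet == "nt" else ProteinRecord
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(cls(id=rec.id, seq=str(rec.seq), description=desc))
    return records


def write_fasta(records: Iterable[TranscriptRecord | ProteinRecord],
                path: str | Path, width: int = 60) -> None:
    """Write records as FASTA (fixed line wrap; round-trips with read_fasta)."""
    bio = []
    for r in records:
        sr = SeqRecord(Seq(r.seq), id=r.id, description=r.description)
        bio.append(sr)
    with open(path, "w") as fh:
        for sr in bio:
            header = sr.id if not sr.description else f"{sr.id} {sr.description}"
            fh.write(f">{header}\n")
            s = str(sr.seq)
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def _codon_maps(table: int = 1) -> tuple[dict[str, str], set[str]]:
    tbl = CodonTable.unambiguous_dna_by_id[table]
    return dict(tbl.forward_table), set(tbl.stop_codons)


def translate_cds(nt: str, table: int = 1) -> str:
    """Translate a nucleotide string codon by codon.

    Trailing partial codons are ignored.  Stops become '*'.  Codons containing
    N (or any ambiguity) translate to X and are never treated as stops.
    """
    fwd, stops = _codon_maps(table)
    out = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        codon = nt[i:i + 3]
        if codon in fwd:
            out.append(fwd[codon])
        elif codon in stops:
            out.append("*")
        else:
            out.append("X")
    return "".join(out)


def six_frame_translate(t: TranscriptRecord, table: int = 1) -> list[ProteinRecord]:
    """Translate a transcript in all six frames with origin maps.

    Returns six ProteinRecords (frames +1,+2,+3,-1,-2,-3).  Every amino-acid
    position of each product is invertible to its codon through the stored
    origin span and frame.
    """
    if len(t.seq) < 3:
        raise SequenceError(f"transcript {t.id!r}: length < 3, cannot translate")
    out = []
    L = len(t.seq)
    rc = revcomp(t.seq)
    for strand, src in ((1, t.seq), (-1, rc)):
        for k in (1, 2, 3):
            offset = k - 1
            aa = translate_cds(src[offset:], table)
            if not aa:
                continue
            nt_len = 3 * len(aa)
            if strand == 1:
                start, end = offset, offset + nt_len
                frame = k
            else:
                start, end = L - (offset + nt_len), L - offset
                frame = -k
            out.append(ProteinRecord(
                id=f"{t.id}|frame{frame:+d}",
                seq=aa,
                origin=(t.id, frame, start, end),
            ))
    return out


def orf_to_forward_coords(L: int, frame: int, aa_start: int, aa_end: int,
                          ) -> tuple[int, int]:
    """Map an aa interval in a translation frame to forward-strand nt coords."""
    k = abs(frame)
    offset = k - 1
    s = offset + 3 * aa_start
    e = offset + 3 * aa_end
    if frame > 0:
        return s, e
    return L - e, L - s


def find_orfs(t: TranscriptRecord, min_aa: int = 1, table: int = 1) -> list[OrfCall]:
    """Find all maximal (stop-to-stop) ORFs of >= min_aa residues in 6 frames.

    Each stop-to-stop region yields at most one call: from the first Met when
    one exists (has_start=True), else the whole region as a partial ORF.
    Sorted by descending aa length, ties by (transcript id, frame, start).
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    calls: list[OrfCall] = []
    if len(t.seq) < 3:
        return calls
    L = len(t.seq)
    for prot in six_frame_translate(t, table):
        frame = prot.origin[1]
        aa = prot.seq
        # split into stop-to-stop regions, tracking aa coordinates
        region_start = 0
        i = 0
        n = len(aa)
        while region_start < n:
            stop_idx = aa.find("*", region_start)
            if stop_idx == -1:
                region_end, has_stop = n, False
            else:
                region_end, has_stop = stop_idx, True
            region = aa[region_start:region_end]
            m = region.find("M")
            if m >= 0:
                call_aa_start, has_start = region_start + m, True
            else:
                call_aa_start, has_start = region_start, False
            pep = aa[call_aa_start:region_end]
            if len(pep) >= min_aa:
                aa_end = region_end + (1 if has_stop else 0)
                s, e = orf_to_forward_coords(L, frame, call_aa_start, aa_end)
                pr = ProteinRecord(
                    id=f"{t.id}|ORF|{frame:+d}|{s}-{e}",
                    seq=pep,
                    origin=(t.id, frame, s, e),
                )
                pr.validate()
                calls.append(OrfCall(
                    transcript_id=t.id, frame=frame, start=s, end=e,
                    protein=pr, has_start=has_start, has_stop=has_stop,
                ))
            region_start = region_end + 1
            i += 1
    calls.sort(key=lambda c: (-c.aa_length, c.transcript_id, c.frame, c.start))
    return calls


def dinucleotide_shuffle(seq: str, rng) -> str:
    """Shuffle a nucleotide string preserving its dinucleotide counts.

    Standard null model for sequence-search calibration: the multigraph whose
    edges are the observed dinucleotides is re-walked along a random Eulerian
    path with the original start symbol (shuffle-and-check with bounded
    retries; falls back to a plain shuffle for degenerate inputs).

    ``rng`` is a numpy Generator.
    """
    s = seq.upper()
    if len(s) < 3:
        return s
    for _attempt in range(200):
        edges: dict[str, list[str]] = {}
        for x, y in zip(s, s[1:]):
            edges.setdefault(x, []).append(y)
        for x in edges:
            perm = rng.permutation(len(edges[x]))
            edges[x] = [edges[x][k] for k in perm]
        out = [s[0]]
        cur = s[0]
        counts = {x: 0 for x in edges}
        total = len(s) - 1
        for _ in range(total):
            lst = edges.get(cur)
            if lst is None or counts[cur] >= len(lst):
                break
            nxt = lst[counts[cur]]
            counts[cur] += 1
            out.append(nxt)
            cur = nxt
        if len(out) == len(s):
            return "".join(out)
    # degenerate composition: plain permutation preserves mononucleotides
    arr = list(s)
    perm = rng.permutation(len(arr))
    return "".join(arr[k] for k in perm)


def orfs_to_gff3(calls: Iterable[OrfCall]) -> str:
    """Render ORF calls as GFF3 (1-based inclusive, type 'ORF')."""
    lines = ["##gff-version 3"]
    for c in calls:
        strand = "+" if c.frame > 0 else "-"
        attrs = (f"ID={c.protein.id};frame={c.frame:+d};"
                 f"has_start={str(c.has_start).lower()};"
                 f"has_stop={str(c.has_stop).lower()}")
        lines.append("\t".join([
            c.transcript_id, "neuromine", "ORF",
            str(c.start + 1), str(c.end), ".", strand, "0", attrs,
        ]))
    return "\n".join(lines) + "\n"


def orfs_to_tsv(calls: Iterable[OrfCall]) -> str:
    lines = ["transcript_id\tframe\tstart\tend\taa_length\thas_start\thas_stop\tprotein"]
    for c in calls:
        lines.append("\t".join([
            c.transcript_id, f"{c.frame:+d}", str(c.start), str(c.end),
            str(c.aa_length), str(c.has_start), str(c.has_stop),
            c.protein.seq,
        ]))
    return "\n".join(lines) + "\n"
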