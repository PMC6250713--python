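"""Prohormone processing prediction: signal peptide, convertase cleavage
sites, and derived mature peptides with post-translational modifications.

A neuropeptide precursor (prepropeptide) is processed by: (1) signal-peptidase
removal of the N-terminal signal peptide; (2) prohormone-convertase cleavage
at mono-/di-/tetra-basic K/R motifs; (3) carboxypeptidase trimming of the
exposed basic residues; (4) amidation of peptides whose trimmed sequence ends
in Gly (the Gly is consumed, leaving a C-terminal amide on the preceding
residue); and (5) cyclization of an N-terminal Gln to pyroglutamate.

The cleavage rule set codified here is the deterministic dibasic/monobasic
rule family standard in insect neuropeptide annotation:

* contiguous K/R runs collapse into a single candidate site at the run's
  C-terminal end;
* dibasic pairs KR, RR and RK are cleaved (KK optional, off by default);
* runs of four or more basics are always cleaved (tetrabasic);
* a lone R is cleaved only when another basic residue sits at position -4,
  -6 or -8 from the scissile bond; a lone K is never cleaved;
* Pro immediately C-terminal to the bond blocks cleavage;
* no site inside, or within 3 residues after, the signal peptide.

Every knob is exposed on :class:`RuleConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from .seq_io import ProteinRecord

BASIC = frozenset("KR")

#: Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2, "X": 0.0,
}

#: Small/neutral residues allowed at the -3 and -1 positions of a
#: signal-peptidase cleavage site (von Heijne's rule).
SMALL_M3_M1 = frozenset("AGSCTV")


class AnnotationError(ValueError):
    pass


@dataclass
class RuleConfig:
    """Tunable convertase-cleavage and PTM rules."""

    cleave_kr: bool = True
    cleave_rr: bool = True
    cleave_rk: bool = True
    cleave_kk: bool = False
    monobasic_r: bool = True
    monobasic_k: bool = False
    monobasic_context: tuple[int, ...] = (-4, -6, -8)
    proline_blocks: bool = True
    signal_margin: int = 3
    min_peptide_len: int = 3  # shorter products flagged as fragments
    pyroglu_q: bool = True
    pyroglu_e: bool = False

    def dibasic_enabled(self, pair: str) -> bool:
        return {
            "KR": self.cleave_kr, "RR": self.cleave_rr,
            "RK": self.cleave_rk, "KK": self.cleave_kk,
        }.get(pair, False)


@dataclass
class SignalSpan:
    """Predicted signal peptide [0, end); cleavage after residue end-1."""

    end: int
    score: float
    start: int = 0

    def __post_init__(self) -> None:
        if not (10 <= self.end <= 45):
            raise AnnotationError(
                f"signal peptide end {self.end} outside plausible 10..45")


@dataclass
class CleavageSite:
    """A convertase cleavage site.

    ``position`` indexes the first residue C-terminal to the scissile bond;
    ``motif`` is the basic run consumed (trimmed off the upstream peptide);
    for kind='terminus' the run may be empty.
    """

    position: int
    kind: str  # dibasic | monobasic | tetrabasic | terminus
    motif: str
    basic_run: int


@dataclass
class MaturePeptide:
    """A processed peptide, with basic flank and amidation Gly removed."""

    seq: str
    start: int
    end: int
    amidated: bool
    pyroglutamate: bool
    copy_index: int
    precursor_id: str
    fragment: bool = False

    def __post_init__(self) -> None:
        if not self.seq:
            raise AnnotationError("mature peptide must be non-empty")


@dataclass
class PrecursorModel:
    """A fully annotated precursor: the object the per-family alignment
    figures of neuropeptidome studies depict."""

    protein: ProteinRecord
    signal: Optional[SignalSpan]
    sites: list[CleavageSite]
    peptides: list[MaturePeptide]
    complete_n_terminus: bool
    complete_c_terminus: bool
    family: Optional[str] = None

    @property
    def core_seq(self) -> str:
        """Precursor sequence without any trailing stop symbol."""
        return self.protein.seq.rstrip("*")

    def reconstruct(self) -> str:
        """Rebuild the precursor from its parts (sequence conservation).

        signal + per-interval [peptide + consumed Gly] + trimmed basic run
        must equal the precursor sequence exactly.
        """
        seq = self.core_seq
        out = [seq[:self.signal.end] if self.signal else ""]
        prev = self.signal.end if self.signal else 0
        pep_iter = iter(self.peptides)
        pep = next(pep_iter, None)
        for site in self.sites:
            if pep is not None and pep.start == prev:
                out.append(pep.seq)
                if pep.amidated:
                    out.append("G")
                pep = next(pep_iter, None)
            out.append(site.motif)
            prev = site.position
        return "".join(out)


def predict_signal_peptide(p: ProteinRecord,
                           override: Optional[SignalSpan] = None,
                           ) -> Optional[SignalSpan]:
    """Heuristic signal-peptide prediction.

    Scans candidate cleavage positions end=15..45 and requires (a) a
    hydrophobic core: best 8-residue mean Kyte-Doolittle hydropathy within
    residues 3..end-4 of at least 1.6, and (b) small residues (A/G/S/C/T/V)
    at the -3 and -1 positions.  Returns the highest-scoring position (score =
    core hydropathy; ties -> shortest), or None.  An externally supplied span
    (e.g. from a dedicated predictor) overrides the heuristic.
    """
    if override is not None:
        return override
    seq = p.seq.rstrip("*")
    if len(seq) < 15:
        return None
    best: Optional[SignalSpan] = None
    for end in range(15, min(45, len(seq) - 1) + 1):
        if seq[end - 3] not in SMALL_M3_M1 or seq[end - 1] not in SMALL_M3_M1:
            continue
        lo, hi = 3, end - 4
        if hi - lo < 8:
            continue
        window_best = max(
            sum(KYTE_DOOLITTLE.get(c, 0.0) for c in seq[i:i + 8]) / 8.0
            for i in range(lo, hi - 8 + 1)
        )
        if window_best < 1.6:
            continue
        if best is None or window_best > best.score:
            best = SignalSpan(end=end, score=window_best)
    return best


def predict_cleavage_sites(p: ProteinRecord,
                           signal: Optional[SignalSpan] = None,
                           rules: Optional[RuleConfig] = None,
                           ) -> list[CleavageSite]:
    """Apply the convertase rule set; always appends a terminus site."""
    rules = rules or RuleConfig()
    seq = p.seq.rstrip("*")
    n = len(seq)
    sites: list[CleavageSite] = []
    guard = (signal.end + rules.signal_margin) if signal else 0
    i = 0
    while i < n:
        if seq[i] not in BASIC:
            i += 1
            continue
        run_start = i
        while i < n and seq[i] in BASIC:
            i += 1
        run_end = i  # position of first residue after the run
        run = seq[run_start:run_end]
        length = len(run)
        if run_end >= n:
            # run reaches the C-terminus; handled by the terminus site below
            terminal_run = run if _run_cleavable(seq, run_start, run_end,
                                                 rules) else ""
            sites.append(CleavageSite(position=n, kind="terminus",
                                      motif=terminal_run,
                                      basic_run=len(terminal_run)))
            return _finalize(sites, n)
        if run_end <= guard:
            continue
        if rules.proline_blocks and seq[run_end] == "P":
            continue
        if not _run_cleavable(seq, run_start, run_end, rules):
            continue
        kind = ("monobasic" if length == 1
                else "tetrabasic" if length >= 4 else "dibasic")
        sites.append(CleavageSite(position=run_end, kind=kind, motif=run,
                                  basic_run=length))
    sites.append(CleavageSite(position=n, kind="terminus", motif="",
                              basic_run=0))
    return _finalize(sites, n)


def _run_cleavable(seq: str, run_start: int, run_end: int,
                   rules: RuleConfig) -> bool:
    length = run_end - run_start
    if length >= 4:
        return True
    if length >= 2:
        return rules.dibasic_enabled(seq[run_end - 2:run_end])
    res = seq[run_start]
    if res == "K":
        return rules.monobasic_k
    if not rules.monobasic_r:
        return False
    for off in rules.monobasic_context:
        idx = run_end + off  # offset from the scissile bond (after run_end-1)
        if 0 <= idx < len(seq) and seq[idx] in BASIC:
            return True
    return False


def _finalize(sites: list[CleavageSite], n: int) -> list[CleavageSite]:
    for a, b in zip(sites, sites[1:]):
        if b.position <= a.position:
            raise AnnotationError("cleavage sites not strictly increasing")
    if not sites or sites[-1].kind != "terminus":
        sites.append(CleavageSite(position=n, kind="terminus", motif="",
                                  basic_run=0))
    return sites


def derive_peptides(p: ProteinRecord,
                    signal: Optional[SignalSpan],
                    sites: list[CleavageSite],
                    rules: Optional[RuleConfig] = None,
                    ) -> list[MaturePeptide]:
    """Cut the precursor at the predicted sites and apply PTM inference.

    Basic flanks are trimmed; a trailing Gly is consumed as the amide donor;
    an N-terminal Gln marks pyroglutamate formation (the unmodified form is
    kept too for downstream mass search, via the flag).  Zero-length segments
    are dropped; sub-``min_peptide_len`` products are kept but flagged
    ``fragment`` (spacer-like segments count as peptides in published
    precursor annotations).
    """
    rules = rules or RuleConfig()
    seq = p.seq.rstrip("*")
    positions = [s.position for s in sites]
    if positions != sorted(set(positions)):
        raise AnnotationError("inconsistent cleavage-site ordering")
    peptides: list[MaturePeptide] = []
    prev = signal.end if signal else 0
    copy_index = 0
    for site in sites:
        seg_end = site.position - site.basic_run
        if seg_end <= prev:
            prev = site.position
            continue
        core = seq[prev:seg_end]
        amidated = False
        if core.endswith("G") and len(core) > 1:
            core = core[:-1]
            amidated = True
        pyro = (core[0] == "Q" and rules.pyroglu_q) or \
               (core[0] == "E" and rules.pyroglu_e)
        peptides.append(MaturePeptide(
            seq=core, start=prev, end=prev + len(core),
            amidated=amidated, pyroglutamate=pyro, copy_index=copy_index,
            precursor_id=p.id,
            fragment=len(core) < rules.min_peptide_len,
        ))
        copy_index += 1
        prev = site.position
    return peptides


def annotate_precursor(p: ProteinRecord,
                       rules: Optional[RuleConfig] = None,
                       signal_override: Optional[SignalSpan] = None,
                       has_stop: Optional[bool] = None,
                       family: Optional[str] = None,
                       ) -> PrecursorModel:
    """Full annotation pipeline: signal -> cleavage sites -> mature peptides.

    ``has_stop`` marks whether the source ORF ended at a stop codon; when
    None it is inferred from a trailing '*' (assumed complete otherwise).
    """
    rules = rules or RuleConfig()
    signal = predict_signal_peptide(p, override=signal_override)
    sites = predict_cleavage_sites(p, signal, rules)
    peptides = derive_peptides(p, signal, sites, rules)
    if has_stop is None:
        # plain protein input: assume the deposited sequence is complete
        has_stop = True
    return PrecursorModel(
        protein=p, signal=signal, sites=sites, peptides=peptides,
        complete_n_terminus=signal is not None,
        complete_c_terminus=bool(has_stop),
        family=family,
    )


def peptides_to_tsv(models: Iterable[PrecursorModel]) -> str:
    cols = ["precursor_id", "family", "copy_index", "seq", "start", "end",
            "amidated", "pyroglutamate", "fragment"]
    lines = ["\t".join(cols)]
    for m in models:
        for pep in m.peptides:
            lines.append("\t".join(map(str, [
                pep.precursor_id, m.family or "", pep.copy_index, pep.seq,
                pep.start, pep.end, pep.amidated, pep.pyroglutamate,
                pep.fragment,
            ])))
    return "\n".join(lines) + "\n"


def precursor_to_gff3(m: PrecursorModel) -> str:
    """Signal/peptide features on the precursor protein (1-based inclusive)."""
    lines = ["##gff-version 3"]
    pid = m.protein.id
    if m.signal:
        lines.append("\t".join([pid, "neuromine", "signal_peptide", "1",
                                str(m.signal.end), f"{m.signal.score:.2f}",
                                "+", ".", "ID=signal"]))
    for pep in m.peptides:
        attrs = (f"ID=peptide{pep.copy_index};amidated="
                 f"{str(pep.amidated).lower()};pyroglutamate="
                 f"{str(pep.pyroglutamate).lower()}")
        lines.append("\t".join([pid, "neuromine", "mature_peptide",
                                str(pep.start + 1), str(pep.end), ".", "+",
                                ".", attrs]))
    return "\n".join(lines) + "\n"
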