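"""Synthetic transcriptomes, precursor panels and MALDI observations with
full ground truth.

The generator emulates the input shape of an insect neuropeptidome study:
transcripts embedding prepropeptides (signal peptide, core peptides flanked
by dibasic cleavage sites, Gly amidation donors, spacer segments), a panel of
sequence-diverged homolog queries, dinucleotide-shuffled decoy transcripts,
and theoretical MALDI masses with parts-per-million jitter.  Every generated
object carries a truth ledger so recovery metrics are exactly defined.

Positions critical to the processing truth (cleavage basics, amidation
donors, motif literals, signal-peptidase determinants) are masked from
divergence mutation, so the ledger stays valid at any divergence rate.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Data import CodonTable

from .homology import ScoringScheme, blosum62
from .motifs import RESIDUES, _parse
from .msmatch import (ModificationState, Observation, PROTON, mh_plus,
                      fragment_ladder, peptide_mass)
from .prohormone import (MaturePeptide, RuleConfig, annotate_precursor)
from .seq_io import (ProteinRecord, TranscriptRecord, dinucleotide_shuffle,
                     revcomp)

#: Residues used for unconstrained fill positions.  Excludes K/R (would
#: create convertase sites), G (amide-donor ambiguity at segment ends),
#: P (blocks cleavage at +1), Q (spurious pyroglutamate at peptide starts),
#: C (disulfide flags), M and W (spurious starts / motif tryptophans).
SAFE_FILL = "ADEFHILNSTVY"
HYDROPHOBIC_CORE = "LVIF"
DIBASIC_FLANKS = ("KR", "RR", "RK")


class GenerationError(RuntimeError):
    pass


@dataclass
class PeptideTemplate:
    """One core-peptide recipe inside a blueprint."""

    pattern: str
    amidated: bool
    count: int = 1
    pyroglu: bool = False


@dataclass
class PrecursorBlueprint:
    """Architecture of a synthetic neuropeptide precursor family."""

    family: str
    templates: list[PeptideTemplate]
    signal_len: tuple[int, int] = (15, 24)
    leading_spacer: bool = True
    spacer_len: tuple[int, int] = (4, 10)
    trailing_spacer: tuple[int, int] = (3, 8)


def default_blueprints() -> list[PrecursorBlueprint]:
    """Shipped blueprints emulating the architectures of published insect
    neuropeptide precursors (paracopy counts included)."""
    return [
        PrecursorBlueprint("MIP", [
            PeptideTemplate("x{2} W x{6} W", amidated=True, count=6),
            PeptideTemplate("x{2} W x{7} W", amidated=True, count=6),
        ]),
        PrecursorBlueprint("AKH", [
            PeptideTemplate("Q x{6} W", amidated=True, count=1, pyroglu=True),
        ], leading_spacer=False,
            # emulates the AKH-precursor-related-peptide region that
            # follows the core in real adipokinetic hormone precursors
            trailing_spacer=(25, 40)),
        PrecursorBlueprint("FMRFamide", [
            # prefixes keep the internal Arg clear of the -4/-6/-8
            # monobasic context of the upstream dibasic flank
            PeptideTemplate("x{6} F M R F", amidated=True, count=4),
            PeptideTemplate("x{6} F I R F", amidated=True, count=1),
        ]),
        PrecursorBlueprint("kinin", [
            PeptideTemplate("x{3} F x{2} W G", amidated=True, count=3),
            PeptideTemplate("x{3} F S x W A", amidated=True, count=2),
        ]),
        PrecursorBlueprint("sulfakinin", [
            PeptideTemplate("x{5} Y x{2} G H M R F", amidated=True, count=1),
            PeptideTemplate("x{5} G Y M R F", amidated=True, count=1),
        ]),
        PrecursorBlueprint("FGL-AST", [
            PeptideTemplate("x{4} L G L", amidated=True, count=1),
            PeptideTemplate("x{4} F G L", amidated=True, count=5),
        ]),
        PrecursorBlueprint("ETH", [
            PeptideTemplate("x{7} P R [LIVM]", amidated=True, count=3),
        ]),
        PrecursorBlueprint("myosuppressin", [
            PeptideTemplate("Q x{5} F L R F", amidated=True, count=1,
                            pyroglu=True),
        ]),
        PrecursorBlueprint("RYamide", [
            PeptideTemplate("x{5} G S R Y", amidated=True, count=1),
            PeptideTemplate("x{2} F Y x{3} R Y", amidated=True, count=1),
        ]),
        PrecursorBlueprint("NPLP", [
            PeptideTemplate("x{10}", amidated=False, count=5),
            PeptideTemplate("x{9}", amidated=True, count=3),
        ]),
    ]


def instantiate_pattern(pattern: str, rng) -> tuple[str, list[bool]]:
    """Sample a concrete peptide from a motif pattern.

    Returns (sequence, literal_mask): mask positions are motif-determining
    (literal residues and class choices) and must survive divergence.
    """
    seq: list[str] = []
    mask: list[bool] = []
    for cls, lo, hi in _parse(pattern):
        n = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        for _ in range(n):
            if cls == RESIDUES:  # wildcard
                seq.append(SAFE_FILL[int(rng.integers(len(SAFE_FILL)))])
                mask.append(False)
            elif len(cls) == 1:
                seq.append(cls)
                mask.append(True)
            else:
                seq.append(cls[int(rng.integers(len(cls)))])
                mask.append(True)
    return "".join(seq), mask


def _make_signal(length: int, rng) -> tuple[str, list[bool]]:
    core_len = length - 5
    core = "".join(HYDROPHOBIC_CORE[int(rng.integers(4))]
                   for _ in range(core_len))
    s1 = "NSTA"[int(rng.integers(4))]
    s2 = "RQNS"[int(rng.integers(4))]
    seq = "M" + s1 + core + "A" + s2 + "A"
    mask = [True] + [False] * (1 + core_len) + [True, False, True]
    return seq, mask


def _spacer(lo: int, hi: int, rng) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(SAFE_FILL[int(rng.integers(len(SAFE_FILL)))]
                   for _ in range(n))


@dataclass
class PeptideTruth:
    seq: str
    start: int
    end: int
    amidated: bool
    pyroglutamate: bool
    is_core: bool  # instantiated from a template (vs spacer segment)


@dataclass
class PrecursorTruth:
    precursor_id: str
    family: str
    protein_seq: str
    signal_end: int
    peptides: list[PeptideTruth]
    critical_positions: list[int]
    transcript_id: str = ""
    orf_start: int = 0
    orf_end: int = 0
    frame: int = 0


def generate_precursor(blueprint: PrecursorBlueprint, rng,
                       precursor_id: str = "precursor",
                       rules: Optional[RuleConfig] = None,
                       max_retries: int = 25,
                       ) -> tuple[ProteinRecord, PrecursorTruth]:
    """Build one precursor whose annotation provably equals its truth.

    The construction is verified by running the annotator on the product;
    on the (rare) spurious-feature collision it is resampled, bounded by
    ``max_retries``.
    """
    rules = rules or RuleConfig()
    last_err = None
    for _ in range(max_retries):
        protein, truth = _build_precursor(blueprint, rng, precursor_id)
        model = annotate_precursor(protein, rules)
        if _truth_matches(model, truth):
            return protein, truth
        last_err = "annotation mismatch"
    raise GenerationError(
        f"could not realize blueprint {blueprint.family!r}: {last_err}")


def _build_precursor(blueprint, rng, precursor_id):
    slen = int(rng.integers(blueprint.signal_len[0],
                            blueprint.signal_len[1] + 1))
    signal, sig_mask = _make_signal(slen, rng)
    parts = [signal]
    mask = list(sig_mask)
    peptides: list[PeptideTruth] = []
    pos = len(signal)

    def add_flank():
        nonlocal pos
        flank = DIBASIC_FLANKS[int(rng.integers(len(DIBASIC_FLANKS)))]
        parts.append(flank)
        mask.extend([True, True])
        pos += len(flank)

    if blueprint.leading_spacer:
        sp = _spacer(*blueprint.spacer_len, rng)
        if sp:
            parts.append(sp)
            mask.extend([False] * len(sp))
            peptides.append(PeptideTruth(sp, pos, pos + len(sp),
                                         False, False, False))
            pos += len(sp)
            add_flank()
    order = [t for t in blueprint.templates for _ in range(t.count)]
    for k, tpl in enumerate(order):
        seq, lit = instantiate_pattern(tpl.pattern, rng)
        parts.append(seq)
        mask.extend(lit)
        peptides.append(PeptideTruth(
            seq, pos, pos + len(seq), tpl.amidated,
            tpl.pyroglu or seq.startswith("Q"), True))
        pos += len(seq)
        if tpl.amidated:
            parts.append("G")
            mask.append(True)
            pos += 1
        add_flank()
    if order or blueprint.leading_spacer:
        sp = _spacer(*blueprint.trailing_spacer, rng)
    else:
        # degenerate blueprint: the whole propeptide is one spacer
        sp = _spacer(max(blueprint.trailing_spacer[0], 1),
                     blueprint.trailing_spacer[1], rng)
    if sp:
        parts.append(sp)
        mask.extend([False] * len(sp))
        peptides.append(PeptideTruth(sp, pos, pos + len(sp),
                                     False, False, False))
        pos += len(sp)
    protein_seq = "".join(parts)
    assert len(protein_seq) == pos == len(mask)
    truth = PrecursorTruth(
        precursor_id=precursor_id, family=blueprint.family,
        protein_seq=protein_seq, signal_end=len(signal),
        peptides=peptides,
        critical_positions=[i for i, m in enumerate(mask) if m],
    )
    return ProteinRecord(id=precursor_id, seq=protein_seq), truth


def _truth_matches(model, truth: PrecursorTruth) -> bool:
    if model.signal is None or model.signal.end != truth.signal_end:
        return False
    got = [(p.seq, p.start, p.end, p.amidated, p.pyroglutamate)
           for p in model.peptides]
    want = [(p.seq, p.start, p.end, p.amidated, p.pyroglutamate)
            for p in truth.peptides]
    return got == want


_CODONS: dict[str, list[str]] = {}


def _codons_by_aa(table: int = 1) -> dict[str, list[str]]:
    if not _CODONS:
        tbl = CodonTable.unambiguous_dna_by_id[table]
        for codon, aa in sorted(tbl.forward_table.items()):
            _CODONS.setdefault(aa, []).append(codon)
        _CODONS["*"] = sorted(tbl.stop_codons)
    return _CODONS


def embed_in_transcript(p: ProteinRecord, rng,
                        utr5: Optional[int] = None,
                        utr3: Optional[int] = None,
                        strand: int = 1,
                        transcript_id: str = "tx",
                        ) -> tuple[TranscriptRecord, tuple[int, int, int]]:
    """Back-translate a protein into a transcript with random UTRs.

    Synonymous codons are chosen uniformly; a stop codon is appended.  When
    the 5' UTR is at least 3 nt its last codon-slot is forced to an in-frame
    stop so the embedded ORF's stop-to-stop region starts exactly at the ATG.
    Returns (transcript, (orf_start, orf_end, frame)) with forward-strand
    coordinates (orf_end includes the stop codon).
    """
    codons = _codons_by_aa()
    if utr5 is None:
        utr5 = int(rng.integers(20, 81))
    if utr3 is None:
        utr3 = int(rng.integers(10, 61))
    nts = "ACGT"
    cds = "".join(codons[aa][int(rng.integers(len(codons[aa])))]
                  for aa in p.seq.rstrip("*"))
    stop = codons["*"][int(rng.integers(3))]
    u5 = "".join(nts[int(rng.integers(4))] for _ in range(utr5))
    if utr5 >= 3:
        guard = codons["*"][int(rng.integers(3))]
        u5 = u5[:utr5 - 3] + guard
    u3 = "".join(nts[int(rng.integers(4))] for _ in range(utr3))
    fwd = u5 + cds + stop + u3
    start = utr5
    end = utr5 + len(cds) + 3
    L = len(fwd)
    if strand >= 0:
        frame = (start % 3) + 1
        seq = fwd
        coords = (start, end, frame)
    else:
        seq = revcomp(fwd)
        frame = -((start % 3) + 1)
        coords = (L - end, L - start, frame)
    return TranscriptRecord(id=transcript_id, seq=seq), coords


_BLOSUM_WEIGHTS: dict = {}


def _substitution_weights(scheme: ScoringScheme):
    """P(b | a) proportional to 2^(score(a,b)/2) over b != a, 20 residues."""
    key = scheme.name
    if key not in _BLOSUM_WEIGHTS:
        aas = RESIDUES
        table = {}
        for a in aas:
            w = np.array([0.0 if b == a else
                          2.0 ** (scheme.score_pair(a, b) / 2.0)
                          for b in aas])
            table[a] = w / w.sum()
        _BLOSUM_WEIGHTS[key] = table
    return _BLOSUM_WEIGHTS[key]


def mutate_protein(seq: str, divergence: float, mask: Sequence[int], rng,
                   scheme: Optional[ScoringScheme] = None) -> str:
    """Substitute residues at the given rate, BLOSUM-weighted, sparing the
    masked (truth-critical) positions."""
    if not 0.0 <= divergence <= 0.6:
        raise ValueError("divergence must be in [0, 0.6]")
    if divergence == 0.0:
        return seq
    scheme = scheme or blosum62()
    weights = _substitution_weights(scheme)
    masked = set(mask)
    out = list(seq)
    aas = RESIDUES
    for i, a in enumerate(seq):
        if i in masked or a not in weights:
            continue
        if rng.random() < divergence:
            out[i] = aas[int(rng.choice(len(aas), p=weights[a]))]
    return "".join(out)


@dataclass
class SyntheticTruth:
    """Ground-truth ledger for a generated dataset."""

    seed: int
    divergence: float
    precursors: list[PrecursorTruth]
    decoy_ids: list[str]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        precursors = []
        for p in d["precursors"]:
            peps = [PeptideTruth(**q) for q in p.pop("peptides")]
            precursors.append(PrecursorTruth(peptides=peps, **p))
        return cls(seed=d["seed"], divergence=d["divergence"],
                   precursors=precursors, decoy_ids=d["decoy_ids"])


@dataclass
class Dataset:
    transcripts: list[TranscriptRecord]
    panel: dict[str, list[ProteinRecord]]
    truth: SyntheticTruth
    observations: list[Observation]
    obs_truth: dict[str, tuple[str, str]]  # obs_id -> (peptide_id, mod label)


def generate_dataset(
    n_precursors: int = 20,
    divergence: float = 0.3,
    n_decoys: int = 200,
    seed: int = 42,
    blueprints: Optional[list[PrecursorBlueprint]] = None,
    with_ms: bool = True,
    n_observations: int = 60,
    ms_jitter_ppm: float = 8.0,
    rules: Optional[RuleConfig] = None,
) -> Dataset:
    """Generate a full synthetic study input with ground truth.

    Embedded precursors are exact; the query panel carries the divergence;
    decoys are dinucleotide-shuffled transcripts; MS observations are
    theoretical masses of a random subset of true mature peptides with
    seeded ppm jitter.  Deterministic (byte-identical) for a fixed seed.
    """
    if not 0.0 <= divergence <= 0.6:
        raise ValueError("divergence must be in [0, 0.6]")
    rng = np.random.default_rng(seed)
    bps = blueprints or default_blueprints()
    rules = rules or RuleConfig()
    transcripts: list[TranscriptRecord] = []
    panel: dict[str, list[ProteinRecord]] = {}
    precursors: list[PrecursorTruth] = []
    all_peptides: list[MaturePeptide] = []
    for i in range(n_precursors):
        bp = bps[i % len(bps)]
        pid = f"{bp.family}_{i:02d}"
        protein, truth = generate_precursor(bp, rng, precursor_id=pid,
                                            rules=rules)
        strand = 1 if rng.random() < 0.5 else -1
        tid = f"tx_{i:03d}"
        tr, (s, e, frame) = embed_in_transcript(
            protein, rng, strand=strand, transcript_id=tid)
        truth.transcript_id, truth.orf_start, truth.orf_end, truth.frame = \
            tid, s, e, frame
        transcripts.append(tr)
        precursors.append(truth)
        qseq = mutate_protein(protein.seq, divergence,
                              truth.critical_positions, rng)
        panel.setdefault(bp.family, []).append(
            ProteinRecord(id=f"q_{pid}", seq=qseq))
        for k, pt in enumerate(truth.peptides):
            all_peptides.append(MaturePeptide(
                seq=pt.seq, start=pt.start, end=pt.end,
                amidated=pt.amidated, pyroglutamate=pt.pyroglutamate,
                copy_index=k, precursor_id=pid,
                fragment=len(pt.seq) < rules.min_peptide_len))
    decoy_ids = []
    n_real = len(transcripts)
    for j in range(n_decoys):
        src = transcripts[j % n_real]
        did = f"decoy_{j:03d}"
        decoy_ids.append(did)
        transcripts.append(TranscriptRecord(
            id=did, seq=dinucleotide_shuffle(src.seq, rng)))
    observations: list[Observation] = []
    obs_truth: dict[str, tuple[str, str]] = {}
    if with_ms:
        observations, obs_truth = _simulate_observations(
            all_peptides, rng, n_observations, ms_jitter_ppm)
    return Dataset(
        transcripts=transcripts, panel=panel,
        truth=SyntheticTruth(seed=seed, divergence=divergence,
                             precursors=precursors, decoy_ids=decoy_ids),
        observations=observations, obs_truth=obs_truth,
    )


def _simulate_observations(peptides: Sequence[MaturePeptide], rng,
                           n_observations: int, jitter_ppm: float,
                           ) -> tuple[list[Observation],
                                      dict[str, tuple[str, str]]]:
    eligible = [p for p in peptides if len(p.seq) >= 5 and not p.fragment]
    if not eligible:
        return [], {}
    k = min(n_observations, len(eligible))
    idx = rng.choice(len(eligible), size=k, replace=False)
    obs: list[Observation] = []
    truth: dict[str, tuple[str, str]] = {}
    for n, i in enumerate(sorted(int(x) for x in idx)):
        pep = eligible[i]
        pyro = bool(pep.pyroglutamate and rng.random() < 0.5)
        trunc = int(rng.random() < 0.15 and len(pep.seq) > 5)
        mods = ModificationState(
            amidated=pep.amidated and trunc == 0,
            pyroglutamate=pyro, sulfation_count=0, c_term_truncation=trunc)
        mz = mh_plus(pep.seq, mods)
        ppm = float(np.clip(rng.normal(0.0, jitter_ppm), -30.0, 30.0))
        mz_obs = mz * (1.0 + ppm * 1e-6)
        b, y = fragment_ladder(pep.seq, mods)
        frags = []
        for f in b + y:
            if rng.random() < 0.8:
                frags.append(round(
                    f + float(np.clip(rng.normal(0.0, 0.05), -0.2, 0.2)), 4))
        oid = f"obs_{n:03d}"
        obs.append(Observation(mz=round(mz_obs, 5), charge=1,
                               fragments=tuple(frags), obs_id=oid))
        truth[oid] = (f"{pep.precursor_id}#{pep.copy_index}", mods.label())
    return obs, truth


# ---------------------------------------------------------------------------
# evaluation against truth

def evaluate_mining(hits, truth: SyntheticTruth) -> dict:
    """Recall/precision of mining results against the truth ledger.

    A true locus counts as recovered when its transcript has a hit with the
    correct family and frame.  Precision is a top-call metric: for every
    subject with hits, its best-scoring hit must name the correct family and
    frame of a true locus.  Any hit on a decoy transcript is a decoy
    acceptance.
    """
    by_tx = {p.transcript_id: p for p in truth.precursors}
    decoys = set(truth.decoy_ids)
    recovered = set()
    decoy_hits = 0
    top: dict[str, object] = {}
    for hit, _orf in hits:  # sorted by descending score
        top.setdefault(hit.subject_id, hit)
        p = by_tx.get(hit.subject_id)
        if p is not None and hit.family == p.family and hit.frame == p.frame:
            recovered.add(hit.subject_id)
        if hit.subject_id in decoys:
            decoy_hits += 1
    correct_calls = 0
    for sid, hit in top.items():
        p = by_tx.get(sid)
        if p is not None and hit.family == p.family and hit.frame == p.frame:
            correct_calls += 1
    n_true = len(by_tx)
    return {
        "n_true_loci": n_true,
        "n_hits": len(hits),
        "n_subjects_called": len(top),
        "recall": len(recovered) / n_true if n_true else 0.0,
        "precision": correct_calls / len(top) if top else 1.0,
        "decoy_hits": decoy_hits,
    }


def evaluate_annotation(truth: SyntheticTruth,
                        rules: Optional[RuleConfig] = None) -> float:
    """Fraction of truth precursors whose fresh annotation equals the ledger."""
    rules = rules or RuleConfig()
    ok = 0
    for p in truth.precursors:
        model = annotate_precursor(
            ProteinRecord(id=p.precursor_id, seq=p.protein_seq), rules)
        ok += _truth_matches(model, p)
    return ok / len(truth.precursors) if truth.precursors else 1.0


def evaluate_ms(matches, obs_truth: dict[str, tuple[str, str]]) -> float:
    """Fraction of observations whose top-ranked match has the correct
    peptide and modification state."""
    top: dict[str, tuple[str, str]] = {}
    for m in matches:
        oid = m.observation.obs_id
        if oid not in top:
            top[oid] = (m.record.peptide_id, m.record.mods.label())
    if not obs_truth:
        return 1.0
    ok = sum(1 for oid, want in obs_truth.items() if top.get(oid) == want)
    return ok / len(obs_truth)


def write_dataset(d: Dataset, out_dir) -> dict[str, Path]:
    """Write transcripts/panel FASTA, truth JSON and observation TSV."""
    from .seq_io import write_fasta
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["transcripts"] = out / "transcripts.fasta"
    write_fasta(d.transcripts, paths["transcripts"])
    panel_records = []
    for fam, recs in sorted(d.panel.items()):
        for r in recs:
            panel_records.append(ProteinRecord(
                id=r.id, seq=r.seq, description=f"family={fam}"))
    paths["panel"] = out / "panel.fasta"
    write_fasta(panel_records, paths["panel"])
    paths["truth"] = out / "truth.json"
    paths["truth"].write_text(d.truth.to_json())
    lines = ["obs_id\tmz\tcharge\tfragments"]
    for ob in d.observations:
        lines.append("\t".join([
            ob.obs_id, f"{ob.mz:.5f}", str(ob.charge),
            ";".join(f"{f:.4f}" for f in ob.fragments)]))
    paths["observations"] = out / "observations.tsv"
    paths["observations"].write_text("\n".join(lines) + "\n")
    return paths
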