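"""Theoretical peptide masses, b/y fragment ladders and MALDI mass matching.

Monoisotopic arithmetic for singly protonated ions, the regime of
MALDI-TOF/TOF neuropeptidomics.  Supported variable modifications: C-terminal
amidation (-0.984016 Da, Gly donor already removed by the annotator),
N-terminal pyroglutamate from Gln (-17.026549 Da; from Glu -18.010565 Da when
enabled), tyrosine sulfation (+79.956815 Da each), and C-terminal truncation
by whole residues (applied before the C-terminal modifications).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from pyteomics import mass as _pmass

from .prohormone import MaturePeptide

WATER = 18.010565
PROTON = 1.007276
AMIDE_DELTA = -0.984016
PYROGLU_Q_DELTA = -17.026549
PYROGLU_E_DELTA = -18.010565
SULFO_DELTA = 79.956815

#: Monoisotopic residue masses for the 20 standard amino acids.
RESIDUE_MASS: dict[str, float] = {
    aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"
}


class MassError(ValueError):
    pass


@dataclass(frozen=True)
class ModificationState:
    amidated: bool = False
    pyroglutamate: bool = False
    sulfation_count: int = 0
    c_term_truncation: int = 0

    def __post_init__(self) -> None:
        if self.sulfation_count < 0 or self.c_term_truncation < 0:
            raise MassError("modification counts must be >= 0")

    def label(self) -> str:
        parts = []
        if self.pyroglutamate:
            parts.append("pyroGlu")
        if self.amidated:
            parts.append("amide")
        if self.sulfation_count:
            parts.append(f"sulfo x{self.sulfation_count}")
        if self.c_term_truncation:
            parts.append(f"-{self.c_term_truncation} C-term")
        return "+".join(parts) or "unmodified"


def _effective_seq(seq: str, mods: ModificationState) -> str:
    if mods.c_term_truncation >= len(seq):
        raise MassError("truncation removes the whole peptide")
    return seq[:len(seq) - mods.c_term_truncation] if mods.c_term_truncation \
        else seq


def peptide_mass(seq: str, mods: ModificationState = ModificationState(),
                 ) -> float:
    """Neutral monoisotopic mass of a (possibly modified) peptide."""
    if not seq:
        raise MassError("empty peptide")
    eff = _effective_seq(seq, mods)
    total = WATER
    for c in eff:
        try:
            total += RESIDUE_MASS[c]
        except KeyError:
            raise MassError(f"nonstandard residue {c!r}") from None
    if mods.amidated:
        total += AMIDE_DELTA
    if mods.pyroglutamate:
        if eff[0] == "Q":
            total += PYROGLU_Q_DELTA
        elif eff[0] == "E":
            total += PYROGLU_E_DELTA
        else:
            raise MassError("pyroglutamate requires N-terminal Q or E")
    if mods.sulfation_count:
        if mods.sulfation_count > eff.count("Y"):
            raise MassError("more sulfations than tyrosines")
        total += SULFO_DELTA * mods.sulfation_count
    return total


def mh_plus(seq: str, mods: ModificationState = ModificationState()) -> float:
    """Singly protonated m/z ([M+H]+)."""
    return peptide_mass(seq, mods) + PROTON


def fragment_ladder(seq: str, mods: ModificationState = ModificationState(),
                    ) -> tuple[list[float], list[float]]:
    """Singly charged b- and y-ion m/z ladders.

    b_i covers residues 1..i (N-terminal mods apply), y_j the last j residues
    (C-terminal mods apply).  Truncation shortens the peptide before ladder
    construction.  Side-chain sulfation has no defined site and is applied to
    the precursor mass only, never to fragments.
    """
    eff = _effective_seq(seq, mods)
    if len(eff) < 2:
        raise MassError("fragment ladder needs >= 2 residues")
    for c in eff:
        if c not in RESIDUE_MASS:
            raise MassError(f"nonstandard residue {c!r}")
    n_delta = 0.0
    if mods.pyroglutamate:
        if eff[0] == "Q":
            n_delta = PYROGLU_Q_DELTA
        elif eff[0] == "E":
            n_delta = PYROGLU_E_DELTA
        else:
            raise MassError("pyroglutamate requires N-terminal Q or E")
    c_delta = AMIDE_DELTA if mods.amidated else 0.0
    b: list[float] = []
    acc = PROTON + n_delta
    for c in eff[:-1]:
        acc += RESIDUE_MASS[c]
        b.append(acc)
    y: list[float] = []
    acc = WATER + PROTON + c_delta
    for c in reversed(eff[1:]):
        acc += RESIDUE_MASS[c]
        y.append(acc)
    return b, y


@dataclass
class PeptideMassRecord:
    peptide_id: str
    seq: str
    mods: ModificationState
    neutral_mass: float
    mz: float


@dataclass
class Observation:
    """One observed MALDI precursor mass, optionally with fragment masses."""

    mz: float
    charge: int = 1
    fragments: tuple[float, ...] = ()
    obs_id: str = ""


@dataclass
class MsMatch:
    observation: Observation
    record: PeptideMassRecord
    ppm: float
    fragments_matched: int
    fragments_total: int


@dataclass
class ModSpaceConfig:
    """Which variable modifications the search expands."""

    max_truncation: int = 1
    allow_sulfation: bool = True
    pyroglu_both_forms: bool = True


def expand_mod_space(pep: MaturePeptide, config: ModSpaceConfig,
                     ) -> list[PeptideMassRecord]:
    """Enumerate the modification states searched for one mature peptide.

    Amidation follows the precursor annotation (it is a processing fact, not
    a search hypothesis); pyroglutamate is searched in both forms when the
    peptide starts with Q; truncation 0..max; sulfation 0..#Y.
    """
    pyro_opts = [False]
    if pep.pyroglutamate and config.pyroglu_both_forms:
        pyro_opts = [False, True]
    elif pep.pyroglutamate:
        pyro_opts = [True]
    trunc_opts = range(0, min(config.max_truncation, len(pep.seq) - 1) + 1)
    records = []
    for trunc, pyro in itertools.product(trunc_opts, pyro_opts):
        eff = pep.seq[:len(pep.seq) - trunc] if trunc else pep.seq
        if pyro and not eff.startswith("Q"):
            continue
        n_y = eff.count("Y") if config.allow_sulfation else 0
        for sulf in range(0, n_y + 1):
            mods = ModificationState(
                amidated=pep.amidated and trunc == 0,
                pyroglutamate=pyro,
                sulfation_count=sulf,
                c_term_truncation=trunc,
            )
            m = peptide_mass(pep.seq, mods)
            records.append(PeptideMassRecord(
                peptide_id=f"{pep.precursor_id}#{pep.copy_index}",
                seq=pep.seq, mods=mods, neutral_mass=m, mz=m + PROTON,
            ))
    return records


def match_observations(
    obs: Sequence[Observation],
    library: Sequence[MaturePeptide],
    tol_ppm: float = 50.0,
    frag_tol_da: float = 0.3,
    mod_space: Optional[ModSpaceConfig] = None,
) -> list[MsMatch]:
    """Match observed MALDI masses against predicted mature peptides.

    Each peptide is expanded over the enabled modification space; every
    precursor match within ``tol_ppm`` is reported, ranked per observation by
    (fragment coverage, |ppm|, peptide id).  Only 1+ ions are modeled.
    """
    if tol_ppm <= 0 or frag_tol_da <= 0:
        raise MassError("tolerances must be > 0")
    mod_space = mod_space or ModSpaceConfig()
    records: list[PeptideMassRecord] = []
    for pep in library:
        records.extend(expand_mod_space(pep, mod_space))
    matches: list[MsMatch] = []
    for ob in obs:
        if ob.charge != 1:
            continue
        cands = []
        for rec in records:
            ppm = (ob.mz - rec.mz) / rec.mz * 1e6
            if abs(ppm) > tol_ppm:
                continue
            n_matched, n_total = 0, 0
            if ob.fragments:
                trunc_mods = rec.mods
                try:
                    b, y = fragment_ladder(rec.seq, trunc_mods)
                except MassError:
                    b, y = [], []
                theo = b + y
                n_total = len(theo)
                used = [False] * len(theo)
                for fmz in ob.fragments:
                    for k, tmz in enumerate(theo):
                        if not used[k] and abs(fmz - tmz) <= frag_tol_da:
                            used[k] = True
                            n_matched += 1
                            break
            cands.append(MsMatch(
                observation=ob, record=rec, ppm=ppm,
                fragments_matched=n_matched, fragments_total=n_total,
            ))
        cands.sort(key=lambda m: (-m.fragments_matched, abs(m.ppm),
                                  m.record.peptide_id, m.record.mods.label()))
        matches.extend(cands)
    return matches


def read_observations_tsv(path) -> list[Observation]:
    """Read observations from TSV: columns mz, charge, fragments (';'-sep)."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for k, line in enumerate(fh):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            frags: tuple[float, ...] = ()
            if "fragments" in idx and len(f) > idx["fragments"] and \
                    f[idx["fragments"]]:
                frags = tuple(float(x) for x in
                              f[idx["fragments"]].split(";") if x)
            out.append(Observation(
                mz=float(f[idx["mz"]]),
                charge=int(f[idx["charge"]]) if "charge" in idx else 1,
                fragments=frags,
                obs_id=f[idx["obs_id"]] if "obs_id" in idx else f"obs{k}",
            ))
    return out


def read_observations_mgf(path) -> list[Observation]:
    """Read observations from an MGF file (PEPMASS dialect)."""
    from pyteomics import mgf
    out = []
    with mgf.MGF(str(path)) as reader:
        for k, spec in enumerate(reader):
            params = spec["params"]
            pep = params["pepmass"]
            mz = pep[0] if isinstance(pep, (tuple, list)) else float(pep)
            charge = 1
            if params.get("charge"):
                charge = int(params["charge"][0])
            out.append(Observation(
                mz=float(mz), charge=charge,
                fragments=tuple(float(x) for x in spec["m/z array"]),
                obs_id=str(params.get("title", f"scan{k}")),
            ))
    return out


def matches_to_tsv(matches: Iterable[MsMatch]) -> str:
    cols = ["obs_id", "obs_mz", "peptide_id", "seq", "mods", "theo_mz",
            "ppm", "fragments_matched", "fragments_total"]
    lines = ["\t".join(cols)]
    for m in matches:
        lines.append("\t".join(map(str, [
            m.observation.obs_id, f"{m.observation.mz:.4f}",
            m.record.peptide_id, m.record.seq, m.record.mods.label(),
            f"{m.record.mz:.4f}", f"{m.ppm:.2f}",
            m.fragments_matched, m.fragments_total,
        ])))
    return "\n".join(lines) + "\n"
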