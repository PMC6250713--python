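"""Neuropeptide-family core-peptide motifs: definition, matching, censuses.

Motifs are written in a restricted pattern language over amino-acid residues:

* a literal residue letter matches itself;
* ``X`` (or ``x``) matches any residue;
* ``[LIVM]`` matches any residue of the class;
* any element may carry a bounded repeat ``{m}`` or ``{m,n}``;
* whitespace is ignored.

Unbounded repeats are deliberately not supported, so matching is decidable in
a single pass.  Anchors tie the match to the peptide's N- and/or C-terminus;
``requires_amide`` restricts a motif to amidated mature peptides (e.g. the
myoinhibitory-peptide core W(6x)W-amide, or the kinin core FXXWG-amide).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

from .prohormone import MaturePeptide, PrecursorModel

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


class MotifError(ValueError):
    pass


_TOKEN = re.compile(
    r"\s*(?:(?P<res>[A-WY])|(?P<any>[Xx])|\[(?P<cls>[A-WYa-wy]+)\])"
    r"(?:\{(?P<m>\d+)(?:,(?P<n>\d+))?\})?"
)


def _parse(pattern: str) -> list[tuple[str, int, int]]:
    """Tokenize to (residue-class string, min-repeat, max-repeat) triples."""
    tokens = []
    pos = 0
    while pos < len(pattern):
        if pattern[pos].isspace():
            pos += 1
            continue
        m = _TOKEN.match(pattern, pos)
        if not m:
            raise MotifError(
                f"cannot parse motif pattern at position {pos}: "
                f"{pattern[pos:]!r}")
        if m.group("res"):
            cls = m.group("res").upper()
        elif m.group("any"):
            cls = RESIDUES
        else:
            cls = "".join(sorted(set(m.group("cls").upper())))
            for c in cls:
                if c not in RESIDUES:
                    raise MotifError(f"unknown residue {c!r} in class")
        lo = int(m.group("m")) if m.group("m") else 1
        hi = int(m.group("n")) if m.group("n") else lo
        if hi < lo:
            raise MotifError(f"repeat bounds {{{lo},{hi}}} out of order")
        tokens.append((cls, lo, hi))
        pos = m.end()
    if not tokens:
        raise MotifError("empty motif pattern")
    return tokens


@dataclass
class MotifSpec:
    """A compiled family motif."""

    name: str
    family: str
    pattern: str
    anchors: frozenset[str] = frozenset()
    requires_amide: bool = False
    note: str = ""
    _regex: re.Pattern = field(init=False, repr=False)

    def __post_init__(self) -> None:
        bad = self.anchors - {"n_terminal", "c_terminal"}
        if bad:
            raise MotifError(f"unknown anchors {sorted(bad)}")
        parts = []
        for cls, lo, hi in _parse(self.pattern):
            atom = cls if len(cls) == 1 else f"[{cls}]"
            if (lo, hi) == (1, 1):
                parts.append(atom)
            elif lo == hi:
                parts.append(f"{atom}{{{lo}}}")
            else:
                parts.append(f"{atom}{{{lo},{hi}}}")
        rex = "".join(parts)
        if "n_terminal" in self.anchors:
            rex = "^" + rex
        if "c_terminal" in self.anchors:
            rex = rex + "$"
        self._regex = re.compile(rex)

    def matches(self, peptide: MaturePeptide) -> bool:
        if self.requires_amide and not peptide.amidated:
            return False
        return self._regex.search(peptide.seq) is not None


def compile_motif(pattern: str, requires_amide: bool = False,
                  anchors: Iterable[str] = ("c_terminal",),
                  name: str = "", family: str = "") -> MotifSpec:
    """Compile a pattern into a deterministic matcher."""
    return MotifSpec(name=name or pattern, family=family or name or pattern,
                     pattern=pattern, anchors=frozenset(anchors),
                     requires_amide=requires_amide)


@dataclass
class CensusRow:
    precursor_id: str
    motif_name: str
    count: int
    copy_indices: list[int]


def count_paracopies(m: PrecursorModel, spec: MotifSpec) -> CensusRow:
    """Count mature peptides of a precursor matching one motif."""
    matched = [p.copy_index for p in m.peptides if spec.matches(p)]
    return CensusRow(precursor_id=m.protein.id, motif_name=spec.name,
                     count=len(matched), copy_indices=matched)


@dataclass
class FamilyCall:
    family: str
    paracopies: int
    score: float


def classify_family(m: PrecursorModel, library: Iterable[MotifSpec],
                    homology_scores: Optional[dict[str, float]] = None,
                    ) -> list[FamilyCall]:
    """Rank candidate family labels for a precursor.

    Families are ranked by (total matched paracopies, best homology score).
    Ties are preserved in the output (adjacent rows with equal keys), never
    broken silently; an empty list means unclassified.
    """
    lib = list(library)
    if not lib:
        raise MotifError("motif library is empty")
    per_family: dict[str, int] = {}
    for spec in lib:
        row = count_paracopies(m, spec)
        if row.count:
            per_family[spec.family] = per_family.get(spec.family, 0) + row.count
    calls = [
        FamilyCall(family=f, paracopies=c,
                   score=(homology_scores or {}).get(f, 0.0))
        for f, c in per_family.items()
    ]
    calls.sort(key=lambda c: (-c.paracopies, -c.score, c.family))
    return calls


def load_motif_library(path) -> list[MotifSpec]:
    """Load a motif library from a TSV file.

    Columns: name, family, pattern, anchors (comma-separated or 'none'),
    requires_amide (true/false), note.
    """
    specs = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            anchors = f[idx["anchors"]]
            anc = frozenset() if anchors in ("none", "") else \
                frozenset(a.strip() for a in anchors.split(","))
            specs.append(MotifSpec(
                name=f[idx["name"]], family=f[idx["family"]],
                pattern=f[idx["pattern"]], anchors=anc,
                requires_amide=f[idx["requires_amide"]].lower() == "true",
                note=f[idx["note"]] if "note" in idx and len(f) > idx["note"]
                else "",
            ))
    return specs


def default_motif_library() -> list[MotifSpec]:
    """The shipped insect neuropeptide motif library."""
    ref = resources.files("neuromine").joinpath("data/motif_library.tsv")
    with resources.as_file(ref) as path:
        return load_motif_library(path)


def census_to_tsv(rows: Iterable[CensusRow]) -> str:
    lines = ["precursor_id\tmotif\tcount\tcopy_indices"]
    for r in rows:
        lines.append("\t".join([
            r.precursor_id, r.motif_name, str(r.count),
            ",".join(map(str, r.copy_indices)),
        ]))
    return "\n".join(lines) + "\n"
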