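# Methods

This note documents the models, rules and numerical choices behind
`neuromine`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Coordinates and sequence conventions

All coordinates are 0-based, half-open, on the forward strand of the source
record; reverse-frame features store the forward coordinates of the interval
they span (GFF3 export converts to 1-based inclusive). Frames are +1..+3
(forward) and −1..−3 (reverse complement). Translation uses the standard
codon table by default (configurable); codons containing N translate to X
and are never treated as stops, a deliberately conservative choice so that
ambiguity cannot terminate an ORF. ORF calling reports one call per
stop-to-stop region: from the first Met when one exists (`has_start=True`),
otherwise the whole region as a partial ORF — partiality flags feed the
precursor completeness flags downstream.

## Translated mining

The search is affine-gap Smith–Waterman (Gotoh) over six-frame translations
against a family-labelled query panel. Defaults are BLOSUM62 with gap open
−11 and extend −1, the substitution regime of protein BLAST; in our gap
accounting a gap of length L costs `open + (L−1)·extend`, i.e. the first
gapped position pays the open penalty (the same convention as Biopython's
`PairwiseAligner`; BLAST's bookkeeping charges one extra extension per gap).
The dynamic program is exact and deterministic: cell ties prefer diagonal
over vertical over horizontal moves, and the traceback starts from the
earliest best cell in row-major order.

Two engineering choices around the core DP:

* a *word prefilter* (default width 4): full alignment runs only when query
  and translated frame share an exact 4-mer, mirroring BLAST's seeding. At
  the divergences the pipeline targets (≤ 0.6) a true precursor of ≥ 40
  residues shares many exact 4-mers with its homolog, so the filter is a
  pure speedup; width 0 disables it.
* a numba-compiled kernel for the inner loops (score-only and full
  traceback variants).

**Threshold calibration.** E-values depend on database size and were not
portable to desk-scale experiments, so acceptance is by raw score plus
fractional identity (default ≥ 0.25). The score cutoff is calibrated per
run on an empirical null: every subject transcript is dinucleotide-shuffled
(composition-preserving Eulerian-walk shuffle) and scanned against the
panel; the cutoff is `ceil(null_max · 1.5) + 1`. The relative headroom
matters: the maximum chance score over hundreds of sequences is
Gumbel-distributed, so a fresh draw (the real decoys) routinely exceeds a
single observed maximum by several points, while true homologs at 30%
divergence score roughly twice the inflated cutoff. The calibration is part
of every run (`min_score: 0` in the config) and is what the shipped
evaluation uses.

**Iteration.** Accepted precursor ORFs are appended to their family's panel
and mining repeats until no new (subject, family) locus appears, at most 5
rounds. Augmentation is gated: a subject's ORF joins only the family of its
*top-scoring* hit. Without the gate, weak cross-family alignments (all
precursors share a hydrophobic signal-peptide architecture) recruit wrong
sequences into panels and the contamination compounds across rounds — the
same inclusion-threshold discipline PSI-BLAST applies.

One hit is reported per (subject, family), which avoids double-counting
splice variants of one assembled cluster; the pipeline's summary keeps, per
subject, the single best family call.

## Prohormone processing rules

The cleavage engine codifies the deterministic mono-/di-basic rule family
standard in insect neuropeptide annotation, every knob exposed on
`RuleConfig`:

| rule | default |
| --- | --- |
| contiguous K/R runs collapse to one site at the run's C-terminal end | always |
| dibasic KR / RR / RK | cleave |
| dibasic KK | do not cleave |
| runs of ≥ 4 basics (tetrabasic) | always cleave |
| lone R with K/R at −4, −6 or −8 from the scissile bond | cleave |
| lone R without that context; lone K | never |
| Pro immediately C-terminal to the bond | blocks |
| exclusion zone | no site within signal peptide + 3 residues |

Runs of length 3 are classified as dibasic and decided by their C-terminal
pair. A run touching the C-terminus is merged into the terminus site (its
basics are trimmed when the run qualifies under the same predicates).

Peptide derivation trims the flanking basic run, then consumes a single
trailing Gly as the amidation donor, then flags an N-terminal Gln (Glu
optional, off by default — only pQ forms are commonly reported) as
pyroglutamate. Note that a mature peptide may legitimately *end* in Gly —
kinins end in amidated Gly (FXXWG-amide) and the consumed donor is a second
Gly; "amidation consumes exactly one G" is the invariant, not "peptides
never end in G". Products shorter than 3 residues are kept but flagged
`fragment`: published precursor annotations count spacer-like segments as
peptides, and dropping them would silently change paracopy counts. The
decomposition is conservative by construction: signal + peptides + consumed
glycines + trimmed basics reconstruct the precursor exactly, and this is
fuzz-tested.

**Signal peptides.** A heuristic stand-in for a dedicated predictor: scan
cleavage positions 15..45, require small residues (A/G/S/C/T/V) at −3 and
−1 (von Heijne's rule) and a hydrophobic core — best 8-mer mean
Kyte–Doolittle hydropathy within residues 3..end−4 of at least 1.6; the
highest-scoring position wins, ties to the shortest. The 1.6 cutoff accepts
genuine leucine/valine-rich cores (mean ≈ 3–4) and rejects mixed polar
stretches. External predictions override via `signal_override`; absence sets
`complete_n_terminus=False`, which is how N-terminally truncated assemblies
present. Machine-learned site scoring is out of scope.

## Motif language and censuses

Family motifs are restricted patterns: literal residues, `X` (any),
`[LIVM]` classes, bounded repeats `{m}`/`{m,n}`, optional N/C anchors, and a
`requires_amide` gate. Unbounded repeats are excluded so matching is a
single deterministic pass; the engine compiles to an anchored regular
expression and is oracle-tested against a naive backtracking matcher. The
shipped library (`data/motif_library.tsv`) encodes the classic insect
cores: MIP W(6×)W/W(7×)W-amide, kinin FXXWG-amide and the heteropteran
FSXWA-amide variant, FMRF/FIRF-amide, myosuppressin FLRF-amide, sulfakinin
GHMRF/GYMRF-amide, FGL/LGL-amide allatostatins, ETH PRX-amide, RY-amide,
AKH (pQ start, Trp at position 8, length 8–10; this one uses both anchors,
a deliberate extension of the single-anchor scheme), CNM-amide, sNPF. The
RYamide entry `FYx{3}RY` encodes an ambiguous prose motif ("FY3(X)RY") and
is marked provisional in its note. Family classification ranks candidate
families by matched paracopies, then homology score, and reports ties
rather than breaking them.

## Mass arithmetic and matching

Monoisotopic residue masses come from pyteomics; water 18.010565, proton
1.007276, amidation −0.984016, pyroGlu −17.026549 (from Gln; −18.010565
from Glu when enabled), sulfation +79.956815. C-terminal truncation removes
whole residues *before* C-terminal modifications apply, and a truncated
peptide is searched as the free acid (the amide cannot survive loss of the
modified terminus). Fragment ladders are singly charged b/y ions (MALDI
regime; multiple charges are out of scope); N-terminal modifications shift
b ions, C-terminal ones y ions, and side-chain sulfation — having no
assigned site — contributes to the precursor mass only. Matching expands
each annotated peptide over the enabled modification space (amidation fixed
by annotation; pyroGlu searched in both forms; truncation 0..1; sulfation
0..#Tyr), accepts precursor matches within 50 ppm (default; MALDI-TOF
regime) and ranks by fragment coverage at 0.3 Da, then |ppm|. All ties are
ranked deterministically.

## Synthetic data: what it emulates, what it does not

Blueprints assemble precursors as signal peptide + spacers + core peptides
instantiated from the family motifs, flanked by dibasic sites, with Gly
donors where amidation is intended; paracopy counts follow the published
family architectures (6+6 MIP copies, 3 ETH cores, 5+1 FGL/LGL-AST, 4+1
FMRF/FIRF, two sulfakinins, one pQ...W AKH core followed by a 25–40 residue
APRP-like region, etc.). Unconstrained fill positions draw from a 12-letter
alphabet that excludes K/R/G/P/Q/C/M/W, so random fills cannot create
cleavage sites, amide donors, pyroGlu starts or spurious motif tryptophans;
template prefixes are sized so that internal arginines of cores (FMRF, ETH,
RYamide) sit clear of the −4/−6/−8 monobasic context of the upstream flank.
Every generated precursor is verified by annotating it and comparing with
the construction ledger (bounded resampling on the rare collision), so
construction equals annotation at divergence 0 by proof, not by luck.

Transcripts are uniform-synonymous back-translations with random UTRs on
either strand; when the 5' UTR has room, an in-frame stop is placed just
before the ATG so the embedded ORF's coordinates are exact. Query panels
are BLOSUM-weighted substitutions of the embedded precursors at the stated
divergence, sparing truth-critical positions (flank basics, donor Gly,
motif literals, signal determinants) so recovery metrics stay well defined.
Decoys are dinucleotide-shuffled transcripts — the standard search null.
MALDI observations are theoretical [M+H]+ of a random peptide subset with
Gaussian ppm jitter (σ = 8, clipped at ±30) plus an 80% subsample of the
b/y ladder jittered at σ = 0.05 Da.

What passing these tests shows: the pipeline's logic — search, thresholds,
processing rules, mass bookkeeping — is internally correct and recovers
planted truth under realistic divergence and noise. What it does not show:
performance on real assemblies, which add fragmented and redundant
transcripts, sequencing error, non-uniform codon usage, splice variants,
genuinely novel precursor architectures, and signal peptides that defeat
the (−3,−1)+hydropathy heuristic. The generator deliberately omits
read-level simulation, expression levels and splice variants.

## Reference problem sizes

The shipped evaluation (tests and `scripts/acceptance.py`) uses 20
precursors over the 10 family blueprints, 200 decoys, 30% query divergence,
60 MALDI observations, and a 15-pair orthology panel at 15% divergence —
large enough for stable recall/precision estimates while keeping the whole
evaluation in seconds on one CPU.

## Known limitations

* No E-value statistics, HSP chaining or nucleotide-level search; raw
  score + identity thresholds stand in, with the calibration above.
* Cleavage prediction is rule-based; no learned scoring (NeuroPred-style),
  no furin-specific typing, no disulfide connectivity (Cys is only part of
  motif literals).
* The signal-peptide heuristic trades sensitivity for determinism; use the
  override channel with a dedicated predictor for production annotation.
* Only 1+ ions and the four listed modifications are modeled; no de novo
  sequencing, isotope envelopes or target-decoy FDR.
* Orthology is plain reciprocal-best-hit; no synteny, no many-to-many
  orthogroups.
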