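"""End-to-end orchestration: mine -> annotate -> census -> ms-match -> rbh.

A single :class:`RunConfig` (YAML round-trippable) drives the stages; every
stage emits machine-readable TSV/GFF3/JSON next to a summary table of
families detected, precursor counts and paracopy censuses.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .homology import (blosum62, calibrate_min_score, hits_to_tsv,
                       iterate_mine, rbh_orthologs)
from .motifs import (census_to_tsv, classify_family, count_paracopies,
                     default_motif_library, load_motif_library)
from .msmatch import (ModSpaceConfig, match_observations, matches_to_tsv,
                      read_observations_mgf, read_observations_tsv)
from .prohormone import RuleConfig, annotate_precursor, peptides_to_tsv
from .seq_io import read_fasta


class ConfigError(ValueError):
    pass


class DataError(ValueError):
    pass


@dataclass
class RunConfig:
    """All knobs of a pipeline run.  Round-trips to/from YAML."""

    transcripts: str = ""
    panel: str = ""
    observations: str = ""        # optional TSV/MGF of observed masses
    rbh_proteome: str = ""        # optional second proteome FASTA for RBH
    motif_library: str = ""       # empty -> shipped default library
    out_dir: str = "neuromine_out"
    seed: int = 0
    min_orf_aa: int = 30
    gap_open: int = -11
    gap_extend: int = -1
    min_score: int = 0            # 0 -> calibrate on a shuffled null
    min_identity: float = 0.25
    word_size: int = 4
    max_rounds: int = 5
    tol_ppm: float = 50.0
    frag_tol_da: float = 0.3
    rules: dict = field(default_factory=dict)  # RuleConfig overrides

    def rule_config(self) -> RuleConfig:
        try:
            return RuleConfig(**self.rules)
        except TypeError as e:
            raise ConfigError(f"bad cleavage-rule option: {e}") from None

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            data = yaml.safe_load(Path(path).read_text()) or {}
        except yaml.YAMLError as e:
            raise ConfigError(f"cannot parse config: {e}") from None
        known = cls.__dataclass_fields__
        bad = set(data) - set(known)
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)


def _load_panel(path: str):
    """Panel FASTA -> mapping family -> records.

    Family is taken from a ``family=...`` token in the description, else
    from the id prefix before the first '|' or '_', else 'unknown'.
    """
    records = read_fasta(path, alphabet="aa")
    panel: dict[str, list] = {}
    for r in records:
        family = None
        for tok in r.description.split():
            if tok.startswith("family="):
                family = tok[len("family="):]
        if family is None:
            sep = "|" if "|" in r.id else "_"
            family = r.id.split(sep)[0] if sep in r.id else "unknown"
        panel.setdefault(family, []).append(r)
    return panel


def run_pipeline(cfg: RunConfig, log=None) -> dict:
    """Execute the configured stages; returns the summary report dict.

    Deterministic and idempotent for fixed inputs + seed.  Stage failures
    raise DataError naming the stage.
    """
    log = log or (lambda msg: print(msg, file=sys.stderr))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for label, p in (("transcripts", cfg.transcripts), ("panel", cfg.panel)):
        if not p:
            raise ConfigError(f"config field {label!r} is required")
        if not Path(p).exists():
            raise ConfigError(f"{label} file not found: {p}")
    scheme = blosum62(cfg.gap_open, cfg.gap_extend)
    rules = cfg.rule_config()
    library = (load_motif_library(cfg.motif_library) if cfg.motif_library
               else default_motif_library())

    t0 = time.perf_counter()
    transcripts = read_fasta(cfg.transcripts, alphabet="nt")
    panel = _load_panel(cfg.panel)
    log(f"[load] {len(transcripts)} transcripts, "
        f"{sum(len(v) for v in panel.values())} panel queries "
        f"({time.perf_counter() - t0:.1f}s)")

    # --- mine ---------------------------------------------------------
    t0 = time.perf_counter()
    min_score = cfg.min_score
    if min_score <= 0:
        min_score = calibrate_min_score(transcripts, panel, scheme,
                                        seed=cfg.seed,
                                        word_size=cfg.word_size)
        log(f"[mine] calibrated min_score={min_score} on shuffled null")
    try:
        hits = iterate_mine(
            transcripts, panel, scheme, max_rounds=cfg.max_rounds,
            min_score=min_score, min_identity=cfg.min_identity,
            orf_min_aa=cfg.min_orf_aa, word_size=cfg.word_size)
    except Exception as e:
        raise DataError(f"stage mine failed: {e}") from e
    (out / "hits.tsv").write_text(hits_to_tsv(hits))
    log(f"[mine] {len(hits)} hits ({time.perf_counter() - t0:.1f}s)")

    # --- annotate + census -------------------------------------------
    # one precursor call per transcript: best-scoring family wins
    t0 = time.perf_counter()
    best: dict[str, tuple] = {}
    for hit, orf in hits:  # sorted by descending score
        best.setdefault(hit.subject_id, (hit, orf))
    calls = sorted(best.values(),
                   key=lambda ho: (-ho[0].score, ho[0].subject_id))
    models = []
    census_rows = []
    for hit, orf in calls:
        try:
            model = annotate_precursor(orf.protein, rules,
                                       has_stop=orf.has_stop,
                                       family=hit.family)
        except Exception as e:
            raise DataError(
                f"stage annotate failed on {orf.protein.id}: {e}") from e
        models.append(model)
        for spec in library:
            row = count_paracopies(model, spec)
            if row.count:
                census_rows.append(row)
    (out / "peptides.tsv").write_text(peptides_to_tsv(models))
    (out / "census.tsv").write_text(census_to_tsv(census_rows))
    log(f"[annotate] {len(models)} precursors, "
        f"{sum(len(m.peptides) for m in models)} peptides "
        f"({time.perf_counter() - t0:.1f}s)")

    # --- ms-match (optional) -----------------------------------------
    ms_summary = None
    if cfg.observations:
        t0 = time.perf_counter()
        try:
            reader = (read_observations_mgf
                      if cfg.observations.endswith(".mgf")
                      else read_observations_tsv)
            obs = reader(cfg.observations)
            peptides = [p for m in models for p in m.peptides]
            matches = match_observations(obs, peptides, cfg.tol_ppm,
                                         cfg.frag_tol_da, ModSpaceConfig())
        except DataError:
            raise
        except Exception as e:
            raise DataError(f"stage ms-match failed: {e}") from e
        (out / "ms_matches.tsv").write_text(matches_to_tsv(matches))
        matched_obs = {m.observation.obs_id for m in matches}
        ms_summary = {"n_observations": len(obs),
                      "n_matched": len(matched_obs)}
        log(f"[ms-match] {len(matched_obs)}/{len(obs)} observations matched "
            f"({time.perf_counter() - t0:.1f}s)")

    # --- rbh (optional) ----------------------------------------------
    rbh_summary = None
    if cfg.rbh_proteome:
        t0 = time.perf_counter()
        try:
            other = read_fasta(cfg.rbh_proteome, alphabet="aa")
            mined = [orf.protein for _, orf in hits]
            pairs = rbh_orthologs(mined, other, scheme) if mined else []
        except Exception as e:
            raise DataError(f"stage rbh failed: {e}") from e
        lines = ["id_a\tid_b\tscore_ab\tscore_ba\treciprocal"]
        for pr in pairs:
            lines.append(f"{pr.id_a}\t{pr.id_b}\t{pr.score_ab}\t"
                         f"{pr.score_ba}\t{pr.reciprocal}")
        (out / "rbh.tsv").write_text("\n".join(lines) + "\n")
        rbh_summary = {"n_pairs": len(pairs),
                       "n_reciprocal": sum(p.reciprocal for p in pairs)}
        log(f"[rbh] {rbh_summary['n_reciprocal']} reciprocal pairs "
            f"({time.perf_counter() - t0:.1f}s)")

    # --- summary ------------------------------------------------------
    family_counts: dict[str, int] = {}
    for m in models:
        fam = m.family or "unknown"
        family_counts[fam] = family_counts.get(fam, 0) + 1
    paracopies: dict[str, dict[str, int]] = {}
    for row in census_rows:
        paracopies.setdefault(row.precursor_id, {})[row.motif_name] = row.count
    summary = {
        "n_transcripts": len(transcripts),
        "n_precursors": len(models),
        "n_families": len(family_counts),
        "families": dict(sorted(family_counts.items())),
        "n_peptides": sum(len(m.peptides) for m in models),
        "n_amidated": sum(1 for m in models for p in m.peptides
                          if p.amidated),
        "min_score": min_score,
        "paracopy_census": paracopies,
        "ms": ms_summary,
        "rbh": rbh_summary,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1,
                                                 sort_keys=True))
    return summary
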