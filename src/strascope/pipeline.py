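"""End-to-end strRNA screen: filters -> PWM scan -> Z-screen -> annotation.

Stage order: strand-specific exonic-overlap filter, median-TPM expression
floor, motif scan of the survivors against a Markov-1 background estimated
from the survivor sequences themselves, per-motif Z-scores for hit number and
density, dual-threshold candidate selection, then class-"u" / longest-ORF /
STR-content / multivalency annotation of every surviving transcript.  The
report lists every input transcript exactly once with the stage that dropped
it, if any.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as sio
from .annotate import (
    ScreenConfig,
    classify_intergenic,
    exonic_overlap_filter,
    expression_filter,
    longest_orf,
    str_fraction,
)
from .motifs import (
    build_log_odds,
    estimate_markov1_background,
    hits_to_rows,
    read_motif_matrices,
    scan_sequence,
    score_pvalue_distribution,
)
from .multivalency import (
    DegeneratePattern,
    count_motif_instances,
    max_nonoverlapping_count,
)
from .screen import compute_z_scores, select_candidates, tally_motif_stats

logger = logging.getLogger(__name__)


class InputError(RuntimeError):
    """A referenced input file is missing or unreadable."""


class ConfigError(RuntimeError):
    """The screen configuration itself is invalid."""


@dataclass
class ScreenReport:
    """Per-transcript outcome of the full screen plus run metadata."""

    table: pd.DataFrame
    hits: pd.DataFrame
    metadata: dict


def _load_config(config_path: str | Path) -> dict:
    config_path = Path(config_path)
    if not config_path.exists():
        raise InputError(f"config file not found: {config_path}")
    try:
        with open(config_path, "rb") as fh:
            return tomllib.load(fh)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"{config_path}: {exc}") from exc


def _resolve(config: dict, config_path: Path) -> tuple[dict, ScreenConfig, list[str]]:
    inputs = config.get("inputs", {})
    required = ("fasta", "bed12", "known_exons", "reference_spans", "strs", "tpm", "motifs")
    missing = [k for k in required if k not in inputs]
    if missing:
        raise ConfigError(f"config [inputs] section missing keys: {missing}")
    base = config_path.parent
    paths = {k: (base / v if not Path(v).is_absolute() else Path(v)) for k, v in inputs.items() if k not in ("motif_format",)}
    for key, p in paths.items():
        if not p.exists():
            raise InputError(f"input {key!r} not found: {p}")
    thr = config.get("thresholds", {})
    try:
        cfg = ScreenConfig(
            tpm_floor=thr.get("tpm_floor", 0.1),
            z_threshold=thr.get("z_threshold", 5.0),
            alpha_p=thr.get("alpha_p", 0.001),
            f_min=thr.get("f_min", 0.85),
            pseudocount=thr.get("pseudocount", 0.1),
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    patterns = config.get("multivalency", {}).get("patterns", ["YUCUYY", "YYUCUY"])
    return {"paths": paths, "motif_format": inputs.get("motif_format", "meme")}, cfg, patterns


def run_screen(config_path: str | Path, outdir: str | Path | None = None) -> ScreenReport:
    """Run the full screen described by a TOML config; optionally write outputs."""
    config_path = Path(config_path)
    config = _load_config(config_path)
    resolved, cfg, pattern_strs = _resolve(config, config_path)
    paths = resolved["paths"]

    sequences = sio.read_fasta(paths["fasta"])
    models = {m.transcript_id: m for m in sio.read_bed12(paths["bed12"])}
    known = sio.read_bed6(paths["known_exons"])
    refspans = sio.read_bed6(paths["reference_spans"])
    strs = sio.read_bed6(paths["strs"])
    tpm = sio.read_tpm_table(paths["tpm"])
    motifs = read_motif_matrices(paths["motifs"], resolved["motif_format"])
    patterns = tuple(DegeneratePattern.from_iupac(p) for p in pattern_strs)

    all_ids = list(sequences)
    dropped: dict[str, str] = {}

    # stage 1: strand-specific exonic overlap with known transcribed sequence
    kept_overlap = []
    for tx in all_ids:
        model = models.get(tx)
        if model is None:
            dropped[tx] = "no_model"
            continue
        if exonic_overlap_filter(model, known):
            kept_overlap.append(tx)
        else:
            dropped[tx] = "overlap_filter"
    logger.info("overlap filter: %d in, %d kept", len(all_ids), len(kept_overlap))

    # stage 2: expression floor
    expressed = expression_filter(tpm.loc[tpm.index.intersection(kept_overlap)], cfg.tpm_floor)
    survivors = []
    for tx in kept_overlap:
        if tx not in tpm.index:
            dropped[tx] = "no_expression_data"
        elif tx in expressed:
            survivors.append(tx)
        else:
            dropped[tx] = "expression_filter"
    logger.info("expression filter: %d in, %d kept", len(kept_overlap), len(survivors))

    # stage 3: motif scan against a survivor-estimated Markov-1 background
    table_rows = []
    hits_df = pd.DataFrame(
        columns=["transcript_id", "motif_id", "start", "end", "score_bits", "p_value", "score_fraction"]
    )
    screen_rows = pd.DataFrame()
    candidates = pd.DataFrame()
    if survivors:
        background = estimate_markov1_background(sequences[tx] for tx in survivors)
        all_hits = []
        for motif in motifs:
            scoring = build_log_odds(motif, background, cfg.pseudocount)
            dist = score_pvalue_distribution(scoring, background)
            for tx in survivors:
                all_hits.extend(
                    scan_sequence(
                        sequences[tx], scoring, dist, cfg.alpha_p, cfg.f_min, transcript_id=tx
                    )
                )
        hits_df = pd.DataFrame(
            hits_to_rows(all_hits),
            columns=["transcript_id", "motif_id", "start", "end", "score_bits", "p_value", "score_fraction"],
        )
        lengths = {tx: len(sequences[tx]) for tx in survivors}

        # stages 4-5: Z-screen and candidate selection
        if len(survivors) >= 2:
            stats = tally_motif_stats(all_hits, lengths, motif_ids=[m.motif_id for m in motifs])
            screen_rows = compute_z_scores(stats)
            candidates = select_candidates(screen_rows, cfg.z_threshold)
        else:
            logger.warning("fewer than 2 surviving transcripts; Z-screen skipped")

    cand_map = (
        candidates.set_index("transcript_id").to_dict("index") if not candidates.empty else {}
    )

    # stage 6: annotation of surviving transcripts
    for tx in all_ids:
        stage = dropped.get(tx)
        row = {
            "transcript_id": tx,
            "kept_overlap": stage not in ("overlap_filter", "no_model"),
            "kept_expression": stage is None,
            "dropped_at": stage or "",
            "class": "",
            "candidate": False,
            "best_motif": "",
            "z_num": np.nan,
            "z_den": np.nan,
            "str_fraction": np.nan,
            "longest_orf_aa": np.nan,
            "motif_instances_total": np.nan,
            "motif_instances_nonoverlapping": np.nan,
        }
        if stage is None:
            model = models[tx]
            seq = sequences[tx]
            cand = cand_map.get(tx)
            total, positions = count_motif_instances(seq, patterns)
            width = len(patterns[0]) if patterns else 6
            row.update(
                {
                    "class": classify_intergenic(model, refspans),
                    "candidate": bool(cand and cand["candidate"]),
                    "best_motif": cand["best_motif"] if cand else "",
                    "z_num": cand["z_num"] if cand else np.nan,
                    "z_den": cand["z_den"] if cand else np.nan,
                    "str_fraction": str_fraction(model, strs),
                    "longest_orf_aa": longest_orf(seq),
                    "motif_instances_total": total,
                    "motif_instances_nonoverlapping": max_nonoverlapping_count(positions, width),
                }
            )
        table_rows.append(row)

    table = pd.DataFrame(table_rows)
    n_candidates = int(table["candidate"].sum())
    n_class_u = int(((table["class"] == "u") & table["candidate"]).sum())
    metadata = {
        "strascope_version": __version__,
        "config_sha256": hashlib.sha256(config_path.read_bytes()).hexdigest(),
        "config": config,
        "n_input": len(all_ids),
        "n_kept_overlap": len(kept_overlap),
        "n_survivors": len(survivors),
        "n_candidates": n_candidates,
        "n_class_u_candidates": n_class_u,
        "stage_drops": {s: sum(1 for v in dropped.values() if v == s) for s in set(dropped.values())},
    }
    if not survivors:
        logger.warning("zero transcripts survived the filters; empty report")

    report = ScreenReport(table=table, hits=hits_df, metadata=metadata)
    if outdir is not None:
        write_report(report, models, outdir)
    return report


def write_report(report: ScreenReport, models: dict, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "report_tsv": outdir / "screen_report.tsv",
        "hits": outdir / "hits.tsv",
        "candidates_bed": outdir / "candidates.bed",
        "report_json": outdir / "report.json",
    }
    report.table.to_csv(paths["report_tsv"], sep="\t", index=False, float_format="%.6g")
    report.hits.to_csv(paths["hits"], sep="\t", index=False, float_format="%.6g")
    with open(paths["candidates_bed"], "w") as fh:
        for tx in report.table.loc[report.table["candidate"], "transcript_id"]:
            m = models.get(tx)
            if m is not None:
                span = m.span
                fh.write(f"{span.chrom}\t{span.start}\t{span.end}\t{tx}\t0\t{m.strand}\n")
    paths["report_json"].write_text(json.dumps(report.metadata, indent=1, sort_keys=True))
    return paths


def validate_inputs(config_path: str | Path) -> list[str]:
    """Diagnostics-only pass over the configured inputs."""
    diagnostics: list[str] = []
    try:
        config = _load_config(config_path)
        resolved, _, _ = _resolve(config, Path(config_path))
    except (InputError, ConfigError) as exc:
        return [str(exc)]
    paths = resolved["paths"]
    chrom_sets = {}
    try:
        sequences = sio.read_fasta(paths["fasta"])
    except Exception as exc:
        diagnostics.append(f"fasta: {exc}")
        sequences = {}
    for key, reader in (
        ("bed12", sio.read_bed12),
        ("known_exons", sio.read_bed6),
        ("reference_spans", sio.read_bed6),
        ("strs", sio.read_bed6),
    ):
        try:
            recs = reader(paths[key])
            chrom_sets[key] = {r.chrom for r in recs}
        except Exception as exc:
            diagnostics.append(f"{key}: {exc}")
    if "bed12" in chrom_sets:
        for key, chroms in chrom_sets.items():
            if key != "bed12" and chroms and not (chroms & chrom_sets["bed12"]):
                diagnostics.append(
                    f"chromosome names in {key} share nothing with bed12 "
                    f"({sorted(chroms)[:3]} vs {sorted(chrom_sets['bed12'])[:3]})"
                )
    try:
        tpm = sio.read_tpm_table(paths["tpm"])
        missing = set(sequences) - set(tpm.index)
        if missing:
            diagnostics.append(f"{len(missing)} FASTA transcripts missing from the TPM table")
    except Exception as exc:
        diagnostics.append(f"tpm: {exc}")
    try:
        read_motif_matrices(paths["motifs"], resolved["motif_format"])
    except Exception as exc:
        diagnostics.append(f"motifs: {exc}")
    return diagnostics
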