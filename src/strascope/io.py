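"""Readers and writers for the plain-text formats the screen consumes.

BED is 0-based half-open; GTF exon coordinates (1-based inclusive) are
converted to the internal BED convention at parse time.  All sequence input
is normalized to RNA (T -> U, unknown letters -> N) on read.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .annotate import GenomicInterval, TranscriptModel
from .motifs import normalize_rna


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: normalized RNA sequence} dict."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = normalize_rna(str(rec.seq))
    if not seqs:
        raise ValueError(f"{path}: no FASTA records")
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, line_width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


def read_bed6(path: str | Path) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{ln}: BED line has fewer than 3 fields")
            strand = f[5] if len(f) >= 6 else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand, name=f[3] if len(f) > 3 else ""))
    return out


def write_bed6(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n")


def read_bed12(path: str | Path) -> list[TranscriptModel]:
    """Read transcript models from BED12 (block fields define the exons)."""
    models: list[TranscriptModel] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{ln}: BED12 requires 12 fields, got {len(f)}")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != int(f[9]) or len(offsets) != int(f[9]):
                raise ValueError(f"{path}:{ln}: block count does not match block lists")
            exons = [
                GenomicInterval(chrom, start + off, start + off + size, strand)
                for off, size in zip(offsets, sizes)
            ]
            models.append(TranscriptModel(name, chrom, strand, exons))
    return models


def write_bed12(models: Iterable[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            start = m.exons[0].start
            end = m.exons[-1].end
            sizes = ",".join(str(e.end - e.start) for e in m.exons)
            offsets = ",".join(str(e.start - start) for e in m.exons)
            fh.write(
                f"{m.chrom}\t{start}\t{end}\t{m.transcript_id}\t0\t{m.strand}"
                f"\t{start}\t{start}\t0\t{len(m.exons)}\t{sizes},\t{offsets},\n"
            )


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read transcript models from a minimal GTF (exon features only)."""
    by_tx: dict[str, dict] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise ValueError(f"{path}:{ln}: GTF requires 9 fields")
            if f[2] != "exon":
                continue
            attrs = f[8]
            tx_id = None
            for chunk in attrs.split(";"):
                chunk = chunk.strip()
                if chunk.startswith("transcript_id"):
                    tx_id = chunk.split(None, 1)[1].strip().strip('"')
                    break
            if tx_id is None:
                raise ValueError(f"{path}:{ln}: exon feature lacks transcript_id")
            rec = by_tx.setdefault(tx_id, {"chrom": f[0], "strand": f[6], "exons": []})
            rec["exons"].append((int(f[3]) - 1, int(f[4])))  # 1-based incl -> 0-based half-open
    models = []
    for tx_id, rec in by_tx.items():
        exons = [
            GenomicInterval(rec["chrom"], s, e, rec["strand"])
            for s, e in sorted(rec["exons"])
        ]
        models.append(TranscriptModel(tx_id, rec["chrom"], rec["strand"], exons))
    return models


def read_tpm_table(path: str | Path) -> pd.DataFrame:
    """Read a transcript x sample TPM matrix (TSV with a header row)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 1:
        raise ValueError(f"{path}: TPM table needs at least one sample column")
    if (df.values < 0).any():
        raise ValueError(f"{path}: negative TPM values")
    return df
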