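"""Synthetic data generation for the strRNA screen and its imaging statistics.

Two generators emulate the statistical structure of the study's inputs:

* :func:`generate_transcriptome` — a background of Markov-1 transcripts plus
  a minority of planted transcripts carrying a dense (UC)n short-tandem-repeat
  array (which embeds YUCUYY/YYUCUY recognition sites), together with all
  matching annotation files (BED12 models, known-exon BED6, reference-span
  BED6 for class-"u" calls, STR BED6, a TPM matrix) and a ground-truth
  manifest.
* :func:`generate_nuclei_images` — nuclei as disks containing one or two
  bright compartment dots plus diffraction-limited single-molecule spots of
  uniform base intensity, with Poisson shot noise and Gaussian read noise,
  alongside a protein channel with a known sequestered fraction.

Every quantity in the manifest is re-derivable from the emitted data, and all
randomness flows from a single seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .annotate import GenomicInterval, TranscriptModel, find_tandem_repeats
from .motifs import ALPHABET, BackgroundModel, MotifMatrix
from .multivalency import PTBP1_PATTERNS, count_motif_instances


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study conditions for the synthetic transcriptome.

    Defaults give 500 background transcripts and 5 planted multivalent
    transcripts carrying a (UC)150 array; background transcripts receive
    sporadic single motif sites at ``contamination_rate`` expected sites per
    transcript, far below the planted arrays.
    """

    n_background: int = 500
    n_planted: int = 5
    length_min: int = 600
    length_max: int = 1500
    planted_unit: str = "UC"
    planted_copies: int = 150
    contamination_rate: float = 0.2
    mutation_rate: float = 0.0
    n_samples: int = 5
    tpm_sigma: float = 1.5
    n_unknown: int = 10
    n_low_expression: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_background < 0 or self.n_planted < 0:
            raise ValueError("transcript counts must be >= 0")
        if self.length_min < 6 or self.length_max < self.length_min:
            raise ValueError("invalid length range")
        array_len = len(self.planted_unit) * self.planted_copies
        if self.n_planted and array_len + 20 > self.length_max:
            raise ValueError(
                f"planted array ({array_len} nt) does not fit in transcripts of "
                f"at most {self.length_max} nt"
            )
        if self.n_unknown + self.n_low_expression > self.n_background:
            raise ValueError("dropout subsets exceed the background count")


def default_background_model() -> BackgroundModel:
    """Mildly structured Markov-1 background (slightly AU-rich, weak stacking)."""
    marginal = np.array([0.28, 0.22, 0.22, 0.28])
    transition = np.array(
        [
            [0.32, 0.20, 0.22, 0.26],
            [0.30, 0.24, 0.18, 0.28],
            [0.26, 0.22, 0.26, 0.26],
            [0.26, 0.24, 0.22, 0.28],
        ]
    )
    return BackgroundModel(marginal, transition, order=1)


def pyrimidine_tract_motif(name: str = "PTBP1_YUCUYY") -> MotifMatrix:
    """A PWM for the YUCUYY recognition element (Y split evenly over C/U)."""
    cols = []
    for ch in "YUCUYY":
        col = np.full(4, 0.025)
        if ch == "Y":
            col[1] = col[3] = 0.475
        else:
            col[ALPHABET.index(ch)] = 0.925
        cols.append(col)
    return MotifMatrix(name, np.column_stack(cols), source="synthetic")


def write_meme_file(motifs: list[MotifMatrix], path: str | Path) -> None:
    """Write motifs in minimal MEME format (RNA alphabet)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGU\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 U 0.25\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.motif_id}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {m.width} nsites= 20 E= 0\n")
            for i in range(m.width):
                fh.write(" ".join(f"{m.probs[b, i]:.6f}" for b in range(4)) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# sequence simulation
# ---------------------------------------------------------------------------

def sample_markov_sequence(
    background: BackgroundModel, length: int, rng: np.random.Generator
) -> str:
    """Draw an RNA string from the Markov-1 background (first base from the
    marginal, subsequent bases from the transition rows)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    marg_cdf = np.cumsum(background.marginal)
    trans_cdf = np.cumsum(background.transition, axis=1)
    u = rng.random(length)
    out = np.empty(length, dtype=np.int8)
    out[0] = np.searchsorted(marg_cdf, u[0], side="right")
    for i in range(1, length):
        out[i] = np.searchsorted(trans_cdf[out[i - 1]], u[i], side="right")
    out = np.minimum(out, 3)
    return "".join(ALPHABET[b] for b in out)


# ---------------------------------------------------------------------------
# transcriptome generation
# ---------------------------------------------------------------------------

@dataclass
class Transcriptome:
    """In-memory synthetic transcriptome plus its ground-truth manifest."""

    sequences: dict[str, str]
    models: list[TranscriptModel]
    known_exons: list[GenomicInterval]
    reference_spans: list[GenomicInterval]
    strs: list[GenomicInterval]
    tpm: pd.DataFrame
    manifest: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "transcripts.fa",
            "bed12": outdir / "transcripts.bed12",
            "known": outdir / "known_exons.bed",
            "refspans": outdir / "reference_spans.bed",
            "strs": outdir / "strs.bed",
            "tpm": outdir / "tpm.tsv",
            "manifest": outdir / "manifest.json",
            "motifs": outdir / "motifs.meme",
        }
        sio.write_fasta(self.sequences, paths["fasta"])
        sio.write_bed12(self.models, paths["bed12"])
        sio.write_bed6(self.known_exons, paths["known"])
        sio.write_bed6(self.reference_spans, paths["refspans"])
        sio.write_bed6(self.strs, paths["strs"])
        self.tpm.to_csv(paths["tpm"], sep="\t")
        paths["manifest"].write_text(json.dumps(self.manifest, indent=1, sort_keys=True))
        write_meme_file([pyrimidine_tract_motif()], paths["motifs"])
        return paths


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = ALPHABET[rng.integers(4)]
    return "".join(chars)


def generate_transcriptome(
    cfg: SimConfig, background: BackgroundModel | None = None
) -> Transcriptome:
    """Simulate the full annotated transcriptome described by ``cfg``."""
    rng = np.random.default_rng(cfg.seed)
    bg = background or default_background_model()
    gap = 1000
    chrom = "chrSim"
    cursor = gap

    sequences: dict[str, str] = {}
    models: list[TranscriptModel] = []
    known: list[GenomicInterval] = []
    refspans: list[GenomicInterval] = []
    strs: list[GenomicInterval] = []
    manifest_tx: dict[str, dict] = {}

    consensus_site = "CUCUCU"  # matches both YUCUYY and YYUCUY

    n_total = cfg.n_background + cfg.n_planted
    planted_idx = set(range(cfg.n_background, n_total))
    unknown_idx = set(range(cfg.n_unknown))
    lowexp_idx = set(range(cfg.n_unknown, cfg.n_unknown + cfg.n_low_expression))

    for k in range(n_total):
        planted = k in planted_idx
        tx_id = f"PLT{k - cfg.n_background + 1:03d}" if planted else f"BKG{k + 1:04d}"
        length = int(rng.integers(cfg.length_min, cfg.length_max + 1))
        if planted:
            array = cfg.planted_unit * cfg.planted_copies
            array = _mutate(array, cfg.mutation_rate, rng)
            flank_total = max(length - len(array), 20)
            left = int(rng.integers(10, flank_total - 9))
            seq = (
                sample_markov_sequence(bg, left, rng)
                + array
                + sample_markov_sequence(bg, flank_total - left, rng)
            )
        else:
            seq = sample_markov_sequence(bg, length, rng)
            n_sites = rng.poisson(cfg.contamination_rate)
            if n_sites and length > 6:
                chars = list(seq)
                for pos in rng.integers(0, length - 6, size=n_sites):
                    chars[pos : pos + 6] = consensus_site
                seq = "".join(chars)
        length = len(seq)
        sequences[tx_id] = seq

        strand = "+" if rng.random() < 0.5 else "-"
        two_exon = (not planted) and k % 5 == 0 and length > 200
        if two_exon:
            split = length // 2
            intron = int(rng.integers(80, 300))
            exons = [
                GenomicInterval(chrom, cursor, cursor + split, strand),
                GenomicInterval(chrom, cursor + split + intron, cursor + length + intron, strand),
            ]
            locus_end = cursor + length + intron
        else:
            exons = [GenomicInterval(chrom, cursor, cursor + length, strand)]
            locus_end = cursor + length
        model = TranscriptModel(tx_id, chrom, strand, exons)
        models.append(model)

        has_known = k not in unknown_idx
        if has_known:
            for e in exons:
                known.append(GenomicInterval(chrom, e.start, e.end, strand, name=f"known_{tx_id}"))
        if not planted:
            refspans.append(
                GenomicInterval(chrom, model.span.start, model.span.end, strand, name=f"ref_{tx_id}")
            )

        # STR track: exact-repeat detection on each exon's sequence, mapped to genome
        tx_strs: list[tuple[int, int]] = []
        offset = 0
        for e in exons:
            sub = seq[offset : offset + e.length]
            for s, t in find_tandem_repeats(sub):
                strs.append(GenomicInterval(chrom, e.start + s, e.start + t, ".", name=f"str_{tx_id}"))
                tx_strs.append((offset + s, offset + t))
            offset += e.length

        motif_count, _ = count_motif_instances(seq, PTBP1_PATTERNS)
        manifest_tx[tx_id] = {
            "planted": planted,
            "length": length,
            "str_intervals": tx_strs,
            "motif_instances": motif_count,
            "class_u": planted,
            "known_overlap": has_known,
            "low_expression": k in lowexp_idx,
        }
        cursor = locus_end + gap

    # TPM matrix: log-normal background, guaranteed-expressed planted rows,
    # near-zero rows for the low-expression subset
    samples = [f"sample{j + 1}" for j in range(cfg.n_samples)]
    tpm_rows = {}
    for k, tx_id in enumerate(sequences):
        if k in lowexp_idx:
            vals = rng.uniform(0.0, 0.05, size=cfg.n_samples)
        elif k in planted_idx:
            vals = np.exp(rng.normal(1.0, 0.5, size=cfg.n_samples))
        else:
            vals = np.exp(rng.normal(0.0, cfg.tpm_sigma, size=cfg.n_samples))
        tpm_rows[tx_id] = np.round(vals, 4)
    tpm = pd.DataFrame.from_dict(tpm_rows, orient="index", columns=samples)
    tpm.index.name = "transcript_id"
    for tx_id, entry in manifest_tx.items():
        entry["tpm_median"] = float(tpm.loc[tx_id].median())

    manifest = {
        "config": asdict(cfg),
        "transcripts": manifest_tx,
        "planted_ids": sorted(t for t, e in manifest_tx.items() if e["planted"]),
    }
    return Transcriptome(sequences, models, known, refspans, strs, tpm, manifest)


# ---------------------------------------------------------------------------
# nuclear image generation
# ---------------------------------------------------------------------------

@dataclass
class ImagingSimConfig:
    """Study conditions for the synthetic smFISH/IF nuclei.

    Compartment dots are modeled as flat-topped disks (lightly blurred), the
    appropriate shape for an extended nuclear body: their segmented footprint
    is then nearly threshold-independent.  Single molecules are Gaussian
    spots of width ``psf_sigma`` and uniform base flux ``unit_intensity``
    with multiplicative noise ``intensity_cv``.
    """

    n_nuclei: int = 50
    image_size: int = 128
    nucleus_radius: int = 52
    n_molecules: int = 40
    molecules_in_dots: int = 8
    n_dots_range: tuple[int, int] = (1, 2)
    psf_sigma: float = 1.5
    dot_radius: float = 6.0
    unit_intensity: float = 2000.0
    intensity_cv: float = 0.10
    rna_background: float = 100.0
    protein_diffuse: float = 50.0
    cyto_background: float = 20.0
    read_noise_sd: float = 3.0
    sequestered_fraction: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.molecules_in_dots > self.n_molecules:
            raise ValueError("molecules_in_dots cannot exceed n_molecules")
        if not (0 <= self.sequestered_fraction < 1):
            raise ValueError("sequestered_fraction must be in [0, 1)")


@dataclass
class SyntheticNucleus:
    """One simulated nucleus: two channels, masks, and ground truth."""

    rna: np.ndarray
    protein: np.ndarray
    nucleus_mask: np.ndarray
    cyto_mask: np.ndarray
    truth: dict


def _gaussian_spot(shape: tuple[int, int], row: float, col: float, sigma: float, flux: float) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    g = np.exp(-((rr - row) ** 2 + (cc - col) ** 2) / (2 * sigma**2))
    return flux * g / (2 * np.pi * sigma**2)


def _disk_body(shape: tuple[int, int], row: float, col: float, radius: float, flux: float) -> np.ndarray:
    """Flat-topped disk of total ``flux`` with a soft 1-px edge."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dist = np.sqrt((rr - row) ** 2 + (cc - col) ** 2)
    profile = np.clip(radius + 0.5 - dist, 0.0, 1.0)
    total = profile.sum()
    return flux * profile / total if total > 0 else profile


def generate_nuclei_images(cfg: ImagingSimConfig) -> list[SyntheticNucleus]:
    """Simulate ``cfg.n_nuclei`` two-channel nuclei with known ground truth.

    The RNA channel carries ``n_molecules`` units of single-molecule flux, of
    which ``molecules_in_dots`` units concentrate in the compartment dots and
    the rest appear as diffraction-limited spots of uniform base intensity
    (multiplicative noise ``intensity_cv``).  The protein channel is diffuse
    nuclear signal over a cytoplasmic haze, plus a sequestered pool placed in
    the dot disks, sized so that the background-corrected fraction of nuclear
    protein lying within the dot footprint equals ``sequestered_fraction``
    exactly before noise (co-localization, the measured quantity, counts all
    protein inside the RNA-dot region, including the diffuse pool there).
    """
    rng = np.random.default_rng(cfg.seed)
    size = cfg.image_size
    center = size / 2
    rr, cc = np.mgrid[0:size, 0:size]
    nucleus_mask = (rr - center) ** 2 + (cc - center) ** 2 <= cfg.nucleus_radius**2
    cyto_mask = ~nucleus_mask
    nuclei = []
    for _ in range(cfg.n_nuclei):
        rna = np.full((size, size), cfg.rna_background, dtype=float)
        n_dots = int(rng.integers(cfg.n_dots_range[0], cfg.n_dots_range[1] + 1))
        dot_centers = []
        for _ in range(n_dots):
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0, 0.5 * cfg.nucleus_radius)
            dot_centers.append((center + rad * np.sin(ang), center + rad * np.cos(ang)))
        dot_flux = cfg.molecules_in_dots * cfg.unit_intensity
        dot_footprint = np.zeros((size, size), dtype=bool)
        for dr, dc in dot_centers:
            if dot_flux > 0:
                rna += _disk_body((size, size), dr, dc, cfg.dot_radius, dot_flux / n_dots)
            dot_footprint |= (rr - dr) ** 2 + (cc - dc) ** 2 <= cfg.dot_radius**2

        n_free = cfg.n_molecules - cfg.molecules_in_dots
        mol_pos = []
        while len(mol_pos) < n_free:
            r = rng.uniform(center - cfg.nucleus_radius, center + cfg.nucleus_radius)
            c = rng.uniform(center - cfg.nucleus_radius, center + cfg.nucleus_radius)
            if (r - center) ** 2 + (c - center) ** 2 <= (cfg.nucleus_radius - 4) ** 2:
                mol_pos.append((r, c))
        fluxes = cfg.unit_intensity * (1 + cfg.intensity_cv * rng.standard_normal(n_free))
        fluxes = np.clip(fluxes, 0.2 * cfg.unit_intensity, None)
        for (r, c), flux in zip(mol_pos, fluxes):
            rna += _gaussian_spot((size, size), r, c, cfg.psf_sigma, flux)

        # protein channel: haze + nuclear diffuse + dot-sequestered pool sized
        # so (dot protein incl. diffuse) / (all nuclear protein above haze) = f
        protein = np.full((size, size), cfg.cyto_background, dtype=float)
        protein[nucleus_mask] += cfg.protein_diffuse
        diffuse_total = cfg.protein_diffuse * nucleus_mask.sum()
        f = cfg.sequestered_fraction
        a_dot = int(dot_footprint.sum())
        extra_total = 0.0
        if f > 0:
            extra_total = (
                cfg.protein_diffuse * (f * nucleus_mask.sum() - a_dot) / (1.0 - f)
            )
            extra_total = max(extra_total, 0.0)
            for dr, dc in dot_centers:
                protein += _disk_body((size, size), dr, dc, cfg.dot_radius, extra_total / n_dots)

        rna = rng.poisson(rna).astype(float) + cfg.read_noise_sd * rng.standard_normal((size, size))
        protein = rng.poisson(protein).astype(float) + cfg.read_noise_sd * rng.standard_normal((size, size))
        rna = np.clip(rna, 0, None)
        protein = np.clip(protein, 0, None)

        nuclei.append(
            SyntheticNucleus(
                rna=rna,
                protein=protein,
                nucleus_mask=nucleus_mask.copy(),
                cyto_mask=cyto_mask.copy(),
                truth={
                    "n_molecules": cfg.n_molecules,
                    "n_free_molecules": n_free,
                    "dot_centers": dot_centers,
                    "molecule_positions": mol_pos,
                    "sequestered_fraction": f,
                },
            )
        )
    return nuclei


def write_nuclei_images(nuclei: list[SyntheticNucleus], outdir: str | Path) -> list[Path]:
    """Write each nucleus as 16-bit TIFFs plus a JSON manifest."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    manifest = []
    for i, nuc in enumerate(nuclei):
        for channel, img in (("rna", nuc.rna), ("protein", nuc.protein)):
            p = outdir / f"nucleus{i:03d}_{channel}.tif"
            tifffile.imwrite(str(p), np.clip(img, 0, 65535).astype(np.uint16))
            paths.append(p)
        m = outdir / f"nucleus{i:03d}_mask.tif"
        tifffile.imwrite(str(m), nuc.nucleus_mask.astype(np.uint8))
        paths.append(m)
        manifest.append(
            {
                "index": i,
                "n_molecules": nuc.truth["n_molecules"],
                "sequestered_fraction": nuc.truth["sequestered_fraction"],
            }
        )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return paths
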