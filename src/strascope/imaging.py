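"""Image-derived statistics: particle analysis of nuclear dots, smFISH
copy-number estimation, sequestered-fraction estimation, and the KS/Pearson
comparisons used on per-nucleus dot measurements.

Images are 2D intensity matrices (maximum projections of confocal Z stacks);
particles are connected components of the thresholded image (8-connectivity,
the ImageJ "Analyze Particles" default).  Copy numbers are estimated as total
spot signal divided by the median intensity of single molecules — the
standard smFISH normalization, robust to the absolute intensity scale.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skimage import filters, measure


def read_image(path: str | Path) -> np.ndarray:
    """Read a 16-bit grayscale TIFF or a whitespace-delimited numeric grid."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        img = tifffile.imread(str(path))
    else:
        img = np.loadtxt(str(path))
    return np.asarray(img, dtype=float)


def max_projection(stack: Sequence[np.ndarray]) -> np.ndarray:
    """Per-pixel maximum across a Z series of equally shaped images."""
    planes = [np.asarray(p, dtype=float) for p in stack]
    if not planes:
        raise ValueError("empty image stack")
    shape = planes[0].shape
    if any(p.shape != shape for p in planes):
        raise ValueError("all planes must share one shape")
    return np.maximum.reduce(planes)


def segment_particles(
    img: np.ndarray,
    threshold: float | str = "otsu",
    connectivity: int = 8,
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Threshold an image and measure connected-component particles.

    Returns a DataFrame with particle_id, area (px), integrated_intensity
    (sum of raw intensities over the particle) and centroid coordinates.
    ``connectivity`` is 4 or 8 (pixel neighbourhood); ``mask`` optionally
    restricts analysis to a region (e.g. one nucleus).
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D image")
    if np.any(~np.isfinite(img)) or np.any(img < 0):
        raise ValueError("image must be finite and non-negative")
    region = img if mask is None else img[mask.astype(bool)]
    if threshold == "otsu":
        thr = float(filters.threshold_otsu(region)) if region.size and region.max() > region.min() else np.inf
    else:
        thr = float(threshold)
    binary = img > thr
    if mask is not None:
        binary &= mask.astype(bool)
    conn = {4: 1, 8: 2}.get(connectivity)
    if conn is None:
        raise ValueError("connectivity must be 4 or 8")
    labels = measure.label(binary, connectivity=conn)
    rows = []
    for rp in measure.regionprops(labels, intensity_image=img):
        rows.append(
            {
                "particle_id": rp.label,
                "area": int(rp.area),
                "integrated_intensity": float(rp.image_intensity[rp.image].sum()),
                "centroid_row": float(rp.centroid[0]),
                "centroid_col": float(rp.centroid[1]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["particle_id", "area", "integrated_intensity", "centroid_row", "centroid_col"],
    )


def quantify_nuclei(
    img: np.ndarray,
    nuclei_labels: np.ndarray,
    threshold: float | str = "otsu",
    connectivity: int = 8,
) -> pd.DataFrame:
    """Per-nucleus particle table (DotTable): one row per segmented dot."""
    rows = []
    for nucleus_id in np.unique(nuclei_labels):
        if nucleus_id == 0:
            continue
        mask = nuclei_labels == nucleus_id
        table = segment_particles(img, threshold=threshold, connectivity=connectivity, mask=mask)
        table.insert(0, "nucleus_id", int(nucleus_id))
        rows.append(table)
    if not rows:
        return pd.DataFrame(
            columns=["nucleus_id", "particle_id", "area", "integrated_intensity", "centroid_row", "centroid_col"]
        )
    return pd.concat(rows, ignore_index=True)


def estimate_copy_number(total_signal: float, singles: Sequence[float]) -> float:
    """Molecules per nucleus = total spot signal / median single-molecule signal."""
    singles = np.asarray(singles, dtype=float)
    if singles.size == 0:
        raise ValueError("need at least one single-molecule intensity")
    if np.any(singles <= 0):
        raise ValueError("single-molecule intensities must be positive")
    return float(total_signal / np.median(singles))


def single_molecule_intensities(
    particles: pd.DataFrame, max_area_factor: float = 1.5
) -> np.ndarray:
    """Select diffraction-limited spots from a particle table.

    Keeps particles with area at most ``max_area_factor`` times the median
    particle area, approximating the manual selection of isolated single
    molecules; returns their integrated intensities.
    """
    if particles.empty:
        return np.empty(0)
    med_area = particles["area"].median()
    sel = particles[particles["area"] <= max_area_factor * med_area]
    return sel["integrated_intensity"].to_numpy(dtype=float)


def sequestered_fraction(
    nuclear_intensity_sum: float,
    coloc_intensity_sum: float,
    cyto_background_per_px: float,
    nuclear_px: int,
    coloc_px: int,
) -> float:
    """Background-corrected fraction of nuclear protein co-localizing with the
    RNA signal, clamped to [0, 1]."""
    if nuclear_px <= 0 or coloc_px <= 0:
        raise ValueError("pixel counts must be positive")
    if nuclear_intensity_sum < 0 or coloc_intensity_sum < 0:
        raise ValueError("intensity sums must be non-negative")
    denom = nuclear_intensity_sum - cyto_background_per_px * nuclear_px
    if denom <= 0:
        raise ValueError("background exceeds nuclear signal; fraction undefined")
    numer = coloc_intensity_sum - cyto_background_per_px * coloc_px
    return float(min(max(numer / denom, 0.0), 1.0))


def analyze_nucleus(
    rna_img: np.ndarray,
    protein_img: np.ndarray,
    nucleus_mask: np.ndarray,
    cyto_mask: np.ndarray,
    threshold: float | str = "otsu",
    min_particle_area: int = 4,
    dot_area_factor: float = 4.0,
    aperture_radius: float = 4.0,
) -> dict:
    """Copy number and sequestered fraction for one two-channel nucleus.

    Spots are segmented in the RNA channel within the nucleus.  Total spot
    signal is integrated over the particle mask dilated by 3 px (so Gaussian
    tails below the threshold are recovered) after subtracting the median
    intensity of the non-spot nuclear pixels.  Single-molecule intensities
    are measured in a circular aperture of ``aperture_radius`` px around the
    centroid of each diffraction-limited particle (area <= 1.5x the median);
    copy number = total signal / median single.  Measuring both through
    background-subtracted apertures makes the ratio insensitive to the exact
    threshold.  Compartment dots (area > ``dot_area_factor`` x median) form
    the co-localization mask for the protein channel.
    """
    from scipy.ndimage import binary_dilation
    from skimage.morphology import disk

    nucleus_mask = nucleus_mask.astype(bool)
    cyto_mask = cyto_mask.astype(bool)
    result = {
        "n_particles": 0,
        "copy_number": 0.0,
        "sequestered_fraction": float("nan"),
        "rna_background": float(np.median(rna_img[nucleus_mask])),
    }
    region = rna_img[nucleus_mask]
    if threshold == "otsu":
        if region.max() <= region.min():
            return result
        thr = float(filters.threshold_otsu(region))
        # a threshold within the noise band means there is no real signal:
        # Otsu always splits the histogram, even of pure noise
        med = float(np.median(region))
        mad_sd = 1.4826 * float(np.median(np.abs(region - med)))
        if thr < med + 3.0 * mad_sd:
            return result
    else:
        thr = float(threshold)
    binary = (rna_img > thr) & nucleus_mask
    labels = measure.label(binary, connectivity=2)
    # drop speckle components below the minimum area
    sizes = np.bincount(labels.ravel())
    keep_ids = np.flatnonzero(sizes >= min_particle_area)
    keep_ids = keep_ids[keep_ids != 0]
    if keep_ids.size == 0:
        return result
    spot_mask = np.isin(labels, keep_ids)
    measure_mask = binary_dilation(spot_mask, structure=disk(3)) & nucleus_mask
    bg = float(np.median(rna_img[nucleus_mask & ~measure_mask]))
    result["rna_background"] = bg
    total_signal = float((rna_img[measure_mask] - bg).sum())

    props = [rp for rp in measure.regionprops(labels) if rp.label in set(keep_ids)]
    areas = np.array([rp.area for rp in props])
    med_area = float(np.median(areas))
    result["n_particles"] = len(props)

    rr, cc = np.mgrid[0 : rna_img.shape[0], 0 : rna_img.shape[1]]
    singles = []
    for rp in props:
        if rp.area <= 1.5 * med_area:
            cy, cx = rp.centroid
            aperture = ((rr - cy) ** 2 + (cc - cx) ** 2 <= aperture_radius**2) & nucleus_mask
            flux = float((rna_img[aperture] - bg).sum())
            if flux > 0:
                singles.append(flux)
    if singles:
        result["copy_number"] = estimate_copy_number(total_signal, singles)

    dot_ids = [rp.label for rp in props if rp.area > dot_area_factor * med_area]
    if dot_ids:
        coloc_mask = np.isin(labels, dot_ids)
        cyto_bg = float(np.median(protein_img[cyto_mask]))
        try:
            result["sequestered_fraction"] = sequestered_fraction(
                float(protein_img[nucleus_mask].sum()),
                float(protein_img[coloc_mask].sum()),
                cyto_bg,
                int(nucleus_mask.sum()),
                int(coloc_mask.sum()),
            )
        except ValueError:
            pass
    return result


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided two-sample KS test (asymptotic p-value)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; errors on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need equal-length samples of size >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)
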