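"""Spectrum preprocessing: TIC normalization, tissue masks, ion images and
binned feature matrices.

TIC (total ion current) normalization divides every spectrum by its summed
intensity, compensating spectrum-to-spectrum variation in desorption and
ionization efficiency; it is the standard normalization for MALDI imaging.
Ion images integrate a narrow mass window around a target ion (a drug or a
structural lipid) per pixel.  Feature matrices bin spectra over the lipid-rich
m/z 750–850 range, which outlines tissue morphology and drives segmentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .io import MSIDataset, Spectrum, ValidationError

__all__ = [
    "MassWindow",
    "IonImage",
    "TissueMask",
    "FeatureMatrix",
    "tic_normalize",
    "extract_ion_image",
    "tissue_mask",
    "build_feature_matrix",
    "EmptyMaskError",
]

#: resolution-matched default mass-window half-widths (Da) per modality:
#: tight for Orbitrap-type DESI data, wider for TOF-type MALDI data
DEFAULT_HALF_WIDTH_DA = {"DESI": 0.01, "MALDI": 0.1}


class EmptyMaskError(ValueError):
    """No pixel survived tissue masking."""


@dataclass(frozen=True)
class MassWindow:
    """Symmetric integration window around ``center_mz``.

    ``half_width`` is in daltons (``width_units='Da'``) or parts-per-million
    (``width_units='ppm'``).
    """

    center_mz: float
    half_width: float
    width_units: str = "Da"

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValidationError("half_width must be positive")
        if self.width_units not in ("Da", "ppm"):
            raise ValidationError("width_units must be 'Da' or 'ppm'")

    def bounds(self) -> Tuple[float, float]:
        """Closed interval [lo, hi] of m/z values inside the window."""
        if self.width_units == "ppm":
            w = self.center_mz * self.half_width * 1e-6
        else:
            w = self.half_width
        return self.center_mz - w, self.center_mz + w


@dataclass
class IonImage:
    """Per-pixel abundance of one mass window.  ``values`` is aligned to the
    source grid, NaN where no spectrum was recorded."""

    values: np.ndarray
    window: MassWindow
    normalized: bool = False

    def masked_values(self, mask: "TissueMask") -> np.ndarray:
        """Abundances of the mask's pixels in row-major order."""
        return self.values[mask.mask]


@dataclass
class TissueMask:
    """Boolean grid separating tissue from slide background."""

    mask: np.ndarray
    method: str = ""

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def pixel_list(self) -> List[Tuple[int, int]]:
        """Masked pixels in row-major order."""
        rows, cols = np.nonzero(self.mask)
        return list(zip(rows.tolist(), cols.tolist()))


@dataclass
class FeatureMatrix:
    """Binned spectra of the masked pixels: one row per pixel (row-major
    mask order), one column per left-closed right-open m/z bin."""

    matrix: np.ndarray
    bin_edges: np.ndarray
    pixel_indices: List[Tuple[int, int]] = field(default_factory=list)

    @property
    def n_pixels(self) -> int:
        return self.matrix.shape[0]


def tic_normalize(dataset: MSIDataset) -> MSIDataset:
    """Divide every spectrum by its total ion current.

    Spectra with zero TIC are left all-zero and recorded in
    ``zero_tic_pixels``.  Normalizing an already-normalized dataset raises,
    since double normalization silently corrupts abundances.
    """
    if not dataset.spectra:
        raise ValidationError("cannot normalize an empty dataset")
    if dataset.normalized:
        raise ValidationError("dataset is already TIC-normalized")
    out: Dict[Tuple[int, int], Spectrum] = {}
    zero_pixels = []
    for px, spec in dataset.spectra.items():
        t = spec.tic
        if t == 0.0:
            out[px] = Spectrum(spec.mz.copy(), spec.intensities.copy())
            zero_pixels.append(px)
        else:
            out[px] = Spectrum(spec.mz.copy(), spec.intensities / t)
    return MSIDataset(
        modality=dataset.modality,
        pixel_size_um=dataset.pixel_size_um,
        grid_shape=dataset.grid_shape,
        spectra=out,
        metadata=dict(dataset.metadata),
        normalized=True,
        zero_tic_pixels=tuple(sorted(zero_pixels)),
    )


def extract_ion_image(dataset: MSIDataset, window: MassWindow) -> IonImage:
    """Sum, per pixel, the intensities whose m/z falls inside ``window``.

    Missing pixels stay NaN.  A window entirely outside the dataset's m/z
    range yields an all-zero image with a warning.
    """
    lo, hi = window.bounds()
    ds_lo, ds_hi = dataset.mz_range()
    if hi < ds_lo or lo > ds_hi:
        warnings.warn(
            f"mass window [{lo:.4f}, {hi:.4f}] lies outside the dataset "
            f"m/z range [{ds_lo:.4f}, {ds_hi:.4f}]; image is all zero"
        )
    values = np.full(dataset.grid_shape, np.nan)
    for (r, c), spec in dataset.spectra.items():
        i0 = np.searchsorted(spec.mz, lo, side="left")
        i1 = np.searchsorted(spec.mz, hi, side="right")
        values[r, c] = spec.intensities[i0:i1].sum()
    return IonImage(values=values, window=window, normalized=dataset.normalized)


def tissue_mask(
    dataset: MSIDataset,
    quantile: float = 0.5,
    keep_largest_component: bool = False,
    method: str = "quantile",
    rel_fraction: float = 0.05,
) -> TissueMask:
    """Threshold the TIC image to separate tissue from slide background.

    ``method='quantile'``: a pixel is kept iff its TIC is >= the ``quantile``
    quantile of the TIC distribution over recorded pixels (ties included) and
    strictly positive — a zero-TIC spectrum carries no signal and would
    otherwise slip through whenever background dominates the grid.  The
    quantile must be matched to the slide's background fraction, which the
    operator knows but the code does not.

    ``method='relative'``: keep pixels whose TIC exceeds ``rel_fraction``
    times the robust tissue level (the 95th-percentile TIC).  Needs no
    knowledge of the background fraction; appropriate whenever background
    TIC sits well below ``rel_fraction`` of the tissue TIC, as it does for
    blank slide regions (``quantile`` is ignored).

    Optionally only the largest 4-connected component is retained.
    """
    if method not in ("quantile", "relative"):
        raise ValidationError("method must be 'quantile' or 'relative'")
    if not (0.0 < quantile < 1.0):
        raise ValidationError("quantile must lie strictly between 0 and 1")
    if not dataset.spectra:
        raise ValidationError("cannot mask an empty dataset")
    tic = dataset.tic_image()
    recorded = ~np.isnan(tic)
    tics = tic[recorded]
    if method == "relative":
        if not (0.0 < rel_fraction < 1.0):
            raise ValidationError("rel_fraction must be in (0, 1)")
        threshold = rel_fraction * float(np.quantile(tics, 0.95))
        keep = (tic > threshold) & (tic > 0)
        descriptor = (
            f"tic_relative(fraction={rel_fraction}, threshold={threshold:.6g})"
        )
    else:
        threshold = float(np.quantile(tics, quantile))
        keep = (tic >= threshold) & (tic > 0)
        descriptor = f"tic_quantile(q={quantile}, threshold={threshold:.6g})"
    mask = recorded & np.where(np.isnan(tic), False, keep)
    if not mask.any():
        raise EmptyMaskError(
            f"no pixel has TIC above {threshold} ({descriptor})"
        )
    if keep_largest_component:
        labeled, n = ndimage.label(mask)
        if n > 1:
            sizes = ndimage.sum_labels(mask, labeled, index=range(1, n + 1))
            mask = labeled == (1 + int(np.argmax(sizes)))
    return TissueMask(mask=mask, method=descriptor)


def build_feature_matrix(
    dataset: MSIDataset,
    mask: TissueMask,
    mz_lo: float = 750.0,
    mz_hi: float = 850.0,
    bin_width: float = 0.1,
) -> FeatureMatrix:
    """Bin each masked pixel's spectrum over [mz_lo, mz_hi).

    Bins are equal-width, left-closed right-open; a peak exactly on an edge
    belongs to the bin to its right.  Row order is the mask's row-major pixel
    enumeration.
    """
    if mz_lo >= mz_hi:
        raise ValidationError("mz_lo must be < mz_hi")
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    pixels = mask.pixel_list()
    if not pixels:
        raise EmptyMaskError("empty mask")
    n_bins = int(np.ceil((mz_hi - mz_lo) / bin_width))
    edges = mz_lo + bin_width * np.arange(n_bins + 1)
    matrix = np.zeros((len(pixels), n_bins))
    for i, px in enumerate(pixels):
        spec = dataset.spectra.get(px)
        if spec is None:
            continue
        mz, inten = spec.mz, spec.intensities
        inside = (mz >= mz_lo) & (mz < edges[-1])
        if not inside.any():
            continue
        idx = np.floor((mz[inside] - mz_lo) / bin_width).astype(int)
        idx = np.clip(idx, 0, n_bins - 1)
        np.add.at(matrix[i], idx, inten[inside])
    return FeatureMatrix(matrix=matrix, bin_edges=edges, pixel_indices=pixels)
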