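"""Reading and writing MSI data (imzML) and tabular inputs.

All stages of the pipeline operate on :class:`MSIDataset`, a pixel grid of
mass spectra with specimen metadata.  Pixel coordinates follow two
conventions that meet only here: imzML files use 1-based (x, y) indices,
while the in-memory grid is 0-based row-major ``(row, col)`` with
``row = y - 1`` and ``col = x - 1``.  Missing pixels (no spectrum recorded)
are represented by absence from ``spectra`` and are excluded from every
downstream statistic, never zero-filled.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterator, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "MSIDataset",
    "ConcentrationTable",
    "read_imzml",
    "write_imzml",
    "read_concentration_table",
    "FormatError",
    "ValidationError",
]

MODALITIES = ("DESI", "MALDI")

#: columns a concentration table must provide
CONCENTRATION_COLUMNS = (
    "specimen_id",
    "animal_id",
    "timepoint_h",
    "drug_name",
    "concentration",
    "replicate_id",
)


class FormatError(ValueError):
    """Raised when a file violates its declared format."""


class ValidationError(ValueError):
    """Raised when data violates a domain invariant."""


@dataclass
class Spectrum:
    """A single mass spectrum: m/z values (Th, strictly increasing) and
    matching non-negative intensities (arbitrary units)."""

    mz: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.mz.ndim != 1 or self.intensities.ndim != 1:
            raise ValidationError("mz and intensities must be 1-D")
        if self.mz.shape != self.intensities.shape:
            raise ValidationError("mz and intensities must have equal length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValidationError("mz values must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValidationError("intensities must be non-negative")

    @property
    def tic(self) -> float:
        """Total ion current: the sum of all intensities."""
        return float(self.intensities.sum())


@dataclass
class MSIDataset:
    """Pixel grid of mass spectra plus acquisition/specimen metadata.

    ``spectra`` maps 0-based ``(row, col)`` to :class:`Spectrum`; pixels
    never acquired are simply absent.
    """

    modality: str
    pixel_size_um: float
    grid_shape: Tuple[int, int]
    spectra: Dict[Tuple[int, int], Spectrum] = field(default_factory=dict)
    metadata: Dict[str, object] = field(default_factory=dict)
    normalized: bool = False
    zero_tic_pixels: Tuple[Tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValidationError(f"modality must be one of {MODALITIES}")
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be positive")
        nrow, ncol = self.grid_shape
        for (r, c) in self.spectra:
            if not (0 <= r < nrow and 0 <= c < ncol):
                raise ValidationError(
                    f"pixel {(r, c)} outside grid {self.grid_shape}"
                )

    def __len__(self) -> int:
        return len(self.spectra)

    def pixels(self) -> Iterator[Tuple[int, int]]:
        """Recorded pixels in row-major order."""
        return iter(sorted(self.spectra))

    def tic_image(self) -> np.ndarray:
        """Grid of per-pixel TIC; NaN where no spectrum was recorded."""
        out = np.full(self.grid_shape, np.nan)
        for (r, c), spec in self.spectra.items():
            out[r, c] = spec.tic
        return out

    def mz_range(self) -> Tuple[float, float]:
        if not self.spectra:
            raise ValidationError("empty dataset has no m/z range")
        lo = min(s.mz[0] for s in self.spectra.values() if s.mz.size)
        hi = max(s.mz[-1] for s in self.spectra.values() if s.mz.size)
        return float(lo), float(hi)


class ConcentrationTable:
    """LC-MS/MS tissue concentrations, one row per
    (specimen, animal, timepoint, drug, replicate).

    Thin wrapper around a :class:`pandas.DataFrame` that enforces the
    non-negativity and key-uniqueness invariants.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in CONCENTRATION_COLUMNS if c not in frame.columns]
        if missing:
            raise FormatError(f"missing required columns: {missing}")
        frame = frame.copy()
        frame["concentration"] = frame["concentration"].astype(float)
        if (frame["concentration"] < 0).any():
            raise ValidationError("concentrations must be non-negative")
        key = ["specimen_id", "drug_name", "replicate_id"]
        if frame.duplicated(subset=key).any():
            dupes = frame[frame.duplicated(subset=key, keep=False)]
            raise ValidationError(
                f"duplicate (specimen, drug, replicate) keys:\n{dupes[key]}"
            )
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def specimen_means(self, drug_name: str) -> pd.Series:
        """Mean concentration per specimen for one drug (technical
        replicates averaged)."""
        sub = self.frame[self.frame["drug_name"] == drug_name]
        return sub.groupby("specimen_id")["concentration"].mean()

    def to_csv(self, path: str) -> None:
        self.frame.to_csv(path, index=False)


def _sidecar_path(path: str) -> str:
    return os.path.splitext(path)[0] + ".meta.json"


def write_imzml(dataset: MSIDataset, path: str) -> None:
    """Write a dataset as an imzML/ibd pair plus a JSON metadata sidecar.

    Continuous mode (one shared m/z axis) is used when every spectrum has an
    identical axis, processed mode otherwise.  Intensities are stored as
    float64 so the round trip is lossless.
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    if not dataset.spectra:
        raise ValidationError("refusing to write an empty dataset")

    axes = [s.mz for s in dataset.spectra.values()]
    continuous = all(
        a.shape == axes[0].shape and np.array_equal(a, axes[0]) for a in axes[1:]
    )
    mode = "continuous" if continuous else "processed"
    with ImzMLWriter(
        path,
        mode=mode,
        mz_dtype=np.float64,
        intensity_dtype=np.float64,
        polarity="positive",
    ) as writer:
        for (r, c) in dataset.pixels():
            spec = dataset.spectra[(r, c)]
            writer.addSpectrum(spec.mz, spec.intensities, (c + 1, r + 1, 1))

    sidecar = {
        "modality": dataset.modality,
        "pixel_size_um": dataset.pixel_size_um,
        "grid_shape": list(dataset.grid_shape),
        "normalized": dataset.normalized,
        "metadata": dataset.metadata,
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=1, default=str)


def read_imzml(path: str, sidecar: Optional[str] = None) -> MSIDataset:
    """Read an imzML/ibd pair into an :class:`MSIDataset`.

    Both continuous and processed binary modes are handled.  Study metadata
    (modality, pixel size, specimen fields) is taken from a JSON sidecar when
    present — imzML itself carries no specimen-level fields — with pixel size
    falling back to the imzML scan-settings entry.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    ibd = os.path.splitext(path)[0] + ".ibd"
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if not os.path.exists(ibd):
        raise IOError(f"missing ibd companion for {path}: {ibd}")

    parser = ImzMLParser(path)
    max_x = parser.imzmldict.get("max count of pixels x")
    max_y = parser.imzmldict.get("max count of pixels y")

    meta: Dict[str, object] = {}
    modality = "MALDI"
    normalized = False
    pixel_size = parser.imzmldict.get("pixel size x") or parser.imzmldict.get(
        "pixel size y"
    )
    sidecar = sidecar or _sidecar_path(path)
    grid_shape = None
    if os.path.exists(sidecar):
        with open(sidecar) as fh:
            side = json.load(fh)
        modality = side.get("modality", modality)
        pixel_size = side.get("pixel_size_um", pixel_size)
        normalized = bool(side.get("normalized", False))
        meta = side.get("metadata", {})
        if side.get("grid_shape"):
            grid_shape = tuple(side["grid_shape"])
    if grid_shape is None:
        grid_shape = (int(max_y), int(max_x))

    spectra: Dict[Tuple[int, int], Spectrum] = {}
    for i, (x, y, _z) in enumerate(parser.coordinates):
        if (max_x and x > max_x) or (max_y and y > max_y):
            raise FormatError(
                f"coordinate ({x}, {y}) exceeds declared max counts "
                f"({max_x}, {max_y})"
            )
        mz, inten = parser.getspectrum(i)
        mz = np.asarray(mz, dtype=np.float64)
        inten = np.asarray(inten, dtype=np.float64)
        order = np.argsort(mz, kind="stable")
        spectra[(int(y) - 1, int(x) - 1)] = Spectrum(mz[order], inten[order])

    if pixel_size is None:
        warnings.warn("pixel size not declared; defaulting to 1 um")
        pixel_size = 1.0
    return MSIDataset(
        modality=modality,
        pixel_size_um=float(pixel_size),
        grid_shape=grid_shape,
        spectra=spectra,
        metadata=meta,
        normalized=normalized,
    )


def read_concentration_table(path: str) -> ConcentrationTable:
    """Read a delimited LC-MS/MS concentration table (CSV/TSV by sniffing).

    Required columns: specimen_id, animal_id, timepoint_h, drug_name,
    concentration, replicate_id.  Unknown columns are preserved.
    """
    frame = pd.read_csv(path, sep=None, engine="python")
    return ConcentrationTable(frame)
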