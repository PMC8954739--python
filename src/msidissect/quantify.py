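"""Per-compartment drug quantification.

Implements the statistics that turn a segmented section into pharmacokinetic
read-outs:

* ``adduct_mz`` — theoretical m/z of the ionized drug ([M+H]+, [M+K]+,
  [M+Na]+) from its molecular formula and monoisotopic atomic masses.
* ``segment_abundances`` — sum/mean/SD of a drug's ion image per
  histological compartment.
* ``absorbed_fraction`` — the share of a drug's total sectional abundance
  found in tissue compartments (mucosa + outer tissue) rather than the
  intestinal lumen; the key read-out distinguishing absorbed drug from
  residue in the bowel content.
* ``detection_limits`` — LOD and LLOQ as 3x and 10x the standard deviation
  of the drug-window abundance across vehicle (undosed) tissue pixels.
* ``time_profile`` — per-compartment abundance-time series across a dosed
  cohort.

Sample standard deviations use the n-1 denominator throughout: cohorts here
are small (three animals per timepoint).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import MSIDataset, ValidationError
from .preprocess import (
    DEFAULT_HALF_WIDTH_DA,
    IonImage,
    MassWindow,
    TissueMask,
    extract_ion_image,
)
from .segmentation import (
    TISSUE_COMPARTMENTS,
    Compartment,
    CompartmentAssignment,
    SegmentMap,
)

__all__ = [
    "MONOISOTOPIC_MASS",
    "ADDUCT_MASS",
    "parse_formula",
    "adduct_mz",
    "DrugDefinition",
    "default_drugs",
    "SegmentAbundance",
    "AbsorbedFractionResult",
    "DetectionLimits",
    "segment_abundances",
    "absorbed_fraction",
    "cohort_fraction_summary",
    "detection_limits",
    "time_profile",
]

#: IUPAC monoisotopic atomic masses (u), 6 decimals; source table cited in
#: docs/methods.md
MONOISOTOPIC_MASS: Dict[str, float] = {
    "C": 12.000000,
    "H": 1.007825,
    "N": 14.003074,
    "O": 15.994915,
    "S": 31.972071,
    "Cl": 34.968853,
    "Br": 78.918338,
    "P": 30.973762,
    "F": 18.998403,
}

#: mass added by each cation adduct (cation mass minus one electron)
ADDUCT_MASS: Dict[str, float] = {
    "[M+H]+": 1.007276,
    "[M+K]+": 38.963158,
    "[M+Na]+": 22.989218,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> Dict[str, int]:
    """Parse a molecular formula like ``C22H23ClN6O`` into element counts."""
    counts: Dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValidationError(f"cannot parse formula {formula!r}")
        if not match.group(0):
            break
        pos = match.end()
        element, num = match.group(1), match.group(2)
        if element not in MONOISOTOPIC_MASS:
            raise ValidationError(
                f"unsupported element {element!r} in {formula!r}"
            )
        counts[element] = counts.get(element, 0) + (int(num) if num else 1)
    if pos != len(formula) or not counts:
        raise ValidationError(f"cannot parse formula {formula!r}")
    return counts


def adduct_mz(formula, adduct: str) -> float:
    """Theoretical m/z of the singly charged adduct of a neutral molecule.

    ``formula`` is a formula string or an element-count mapping.  The result
    is the monoisotopic neutral mass plus the adduct cation mass (proton,
    potassium or sodium, each less one electron).
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    if adduct not in ADDUCT_MASS:
        raise ValidationError(f"unsupported adduct {adduct!r}")
    mass = 0.0
    for element, n in formula.items():
        if element not in MONOISOTOPIC_MASS:
            raise ValidationError(f"unsupported element {element!r}")
        if n < 0:
            raise ValidationError("element counts must be non-negative")
        mass += MONOISOTOPIC_MASS[element] * n
    return mass + ADDUCT_MASS[adduct]


@dataclass
class DrugDefinition:
    """A benchmark compound and how each modality detects it.

    ``adducts`` maps modality to the adduct species; ``expected_mz`` may
    override the theoretical value with the experimentally observed m/z
    (it must stay within 0.02 Th of theory).  ``half_width_da`` holds the
    integration half-window per modality.
    """

    name: str
    formula: str
    adducts: Dict[str, str]
    expected_mz: Dict[str, float] = field(default_factory=dict)
    half_width_da: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HALF_WIDTH_DA)
    )

    def __post_init__(self) -> None:
        self.counts = parse_formula(self.formula)
        for modality, adduct in self.adducts.items():
            theo = adduct_mz(self.counts, adduct)
            observed = self.expected_mz.setdefault(modality, theo)
            if abs(observed - theo) > 0.02:
                raise ValidationError(
                    f"{self.name}/{modality}: expected m/z {observed} is "
                    f"{abs(observed - theo):.4f} Th from theoretical {theo:.4f}"
                )

    def window(self, modality: str) -> MassWindow:
        return MassWindow(
            center_mz=self.expected_mz[modality],
            half_width=self.half_width_da[modality],
            width_units="Da",
        )


def default_drugs() -> List[DrugDefinition]:
    """The four orally co-dosed benchmark compounds.

    Losartan is seen protonated in MALDI but as the potassium adduct in
    DESI (a consequence of dosing the potassium salt); the DESI value is the
    observed one.
    """
    return [
        DrugDefinition(
            name="terfenadine",
            formula="C32H41NO2",
            adducts={"MALDI": "[M+H]+", "DESI": "[M+H]+"},
        ),
        DrugDefinition(
            name="losartan",
            formula="C22H23ClN6O",
            adducts={"MALDI": "[M+H]+", "DESI": "[M+K]+"},
            expected_mz={"DESI": 461.129},
        ),
        DrugDefinition(
            name="dextromethorphan",
            formula="C18H25NO",
            adducts={"MALDI": "[M+H]+", "DESI": "[M+H]+"},
        ),
        DrugDefinition(
            name="diphenhydramine",
            formula="C17H21NO",
            adducts={"MALDI": "[M+H]+", "DESI": "[M+H]+"},
        ),
    ]


@dataclass
class SegmentAbundance:
    """Sum, mean and SD of an ion image over one compartment's pixels."""

    compartment: Compartment
    total: float
    mean: float
    sd: Optional[float]
    pixel_count: int


def segment_abundances(
    image: IonImage,
    segmap: SegmentMap,
    assignment: CompartmentAssignment,
) -> Dict[Compartment, SegmentAbundance]:
    """Aggregate an ion image per histological compartment.

    Compartments with no pixels are absent from the result (never reported
    as zero).  SD is the sample SD (n-1), undefined for single-pixel
    compartments.
    """
    if image.values.shape != segmap.labels.shape:
        raise ValidationError("ion image and segment map grids differ")
    out: Dict[Compartment, SegmentAbundance] = {}
    for compartment in Compartment:
        clusters = assignment.clusters_of(compartment)
        if not clusters:
            continue
        sel = np.isin(segmap.labels, clusters)
        vals = image.values[sel]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            continue
        out[compartment] = SegmentAbundance(
            compartment=compartment,
            total=float(vals.sum()),
            mean=float(vals.mean()),
            sd=float(vals.std(ddof=1)) if vals.size > 1 else None,
            pixel_count=int(vals.size),
        )
    return out


@dataclass
class AbsorbedFractionResult:
    """Absorbed-drug-fraction statistic: per-specimen fractions in [0, 1]
    and their cohort summary (mean, sample SD, min, max)."""

    fractions: List[float]
    mean: float
    sd: Optional[float]
    min: float
    max: float
    n_undefined: int = 0


def absorbed_fraction(
    abundances: Mapping[Compartment, SegmentAbundance],
) -> Tuple[Optional[float], bool]:
    """Fraction of the drug's sectional abundance located in tissue.

    fraction = (mucosa + outer tissue sums) / (all compartments including
    lumen).  Returns ``(fraction, defined)``; a section with zero total
    signal yields ``(None, False)``.
    """
    if Compartment.LUMEN not in abundances:
        raise ValidationError("absorbed fraction needs a lumen compartment")
    if not any(c in abundances for c in TISSUE_COMPARTMENTS):
        raise ValidationError(
            "absorbed fraction needs at least one tissue compartment"
        )
    sums = {c: a.total for c, a in abundances.items()}
    if any(s < 0 for s in sums.values()):
        raise ValidationError("negative compartment sums")
    tissue = sum(sums.get(c, 0.0) for c in TISSUE_COMPARTMENTS)
    total = sum(sums.values())
    if total == 0.0:
        return None, False
    return tissue / total, True


def cohort_fraction_summary(
    fractions: Sequence[Optional[float]],
) -> AbsorbedFractionResult:
    """Mean, sample SD and range of per-specimen absorbed fractions.

    Undefined fractions (``None``) are excluded and counted; at least one
    defined fraction is required.  SD is undefined for a single specimen.
    """
    defined = [f for f in fractions if f is not None]
    n_undefined = len(fractions) - len(defined)
    if not defined:
        raise ValidationError("no defined fractions to summarize")
    for f in defined:
        if not (0.0 <= f <= 1.0):
            raise ValidationError(f"fraction {f} outside [0, 1]")
    arr = np.asarray(defined, dtype=float)
    return AbsorbedFractionResult(
        fractions=list(map(float, arr)),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else None,
        min=float(arr.min()),
        max=float(arr.max()),
        n_undefined=n_undefined,
    )


@dataclass
class DetectionLimits:
    """LOD/LLOQ of one drug in one modality, from vehicle-tissue background.

    lod = 3 x SD and lloq = 10 x SD of the drug-window abundance across
    vehicle tissue pixels, so lloq/lod = 10/3 exactly.
    """

    drug_name: str
    modality: str
    background_sd: float
    lod: float
    lloq: float
    n_background_pixels: int
    pooling: str = "pixels"


def detection_limits(
    vehicle_datasets: Sequence[MSIDataset],
    masks: Sequence[TissueMask],
    drug: DrugDefinition,
    modality: Optional[str] = None,
    pooling: str = "pixels",
) -> DetectionLimits:
    """LOD and LLOQ from the drug-window background on vehicle sections.

    ``pooling='pixels'`` (default) pools the per-pixel abundances of every
    masked vehicle pixel; ``pooling='section_means'`` uses one mean per
    section instead.  Needs at least two pooled values for a sample SD.
    """
    if len(vehicle_datasets) != len(masks) or not vehicle_datasets:
        raise ValidationError("need matched, non-empty datasets and masks")
    if pooling not in ("pixels", "section_means"):
        raise ValidationError("pooling must be 'pixels' or 'section_means'")
    modality = modality or vehicle_datasets[0].modality
    window = drug.window(modality)
    pooled: List[float] = []
    for ds, mask in zip(vehicle_datasets, masks):
        img = extract_ion_image(ds, window)
        vals = img.masked_values(mask)
        vals = vals[~np.isnan(vals)]
        if pooling == "pixels":
            pooled.extend(vals.tolist())
        else:
            if vals.size:
                pooled.append(float(vals.mean()))
    if len(pooled) < 2:
        raise ValidationError(
            "fewer than 2 pooled background values; SD undefined"
        )
    sd = float(np.asarray(pooled).std(ddof=1))
    return DetectionLimits(
        drug_name=drug.name,
        modality=modality,
        background_sd=sd,
        lod=3.0 * sd,
        lloq=10.0 * sd,
        n_background_pixels=len(pooled),
        pooling=pooling,
    )


def time_profile(
    records: Iterable[Mapping[str, object]],
) -> pd.DataFrame:
    """Abundance-time series per compartment across a cohort.

    ``records`` holds one entry per (specimen, compartment) with keys
    ``specimen_id``, ``timepoint_h``, ``compartment`` and ``mean_abundance``.
    Vehicle specimens (``timepoint_h == 'vehicle'``) are reported at t = 0 as
    the background level.  Returns a tidy frame with columns compartment,
    timepoint_h, mean, sd, n; SD is the sample SD over specimens, NaN when a
    timepoint has a single specimen.
    """
    frame = pd.DataFrame(list(records))
    required = {"specimen_id", "timepoint_h", "compartment", "mean_abundance"}
    if not required.issubset(frame.columns):
        raise ValidationError(f"records must provide columns {sorted(required)}")
    frame = frame.copy()
    frame["timepoint_h"] = [
        0.0 if t == "vehicle" else float(t) for t in frame["timepoint_h"]
    ]
    frame["compartment"] = [
        c.value if isinstance(c, Compartment) else str(c)
        for c in frame["compartment"]
    ]
    grouped = frame.groupby(["compartment", "timepoint_h"])["mean_abundance"]
    out = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
    return out.reset_index().sort_values(["compartment", "timepoint_h"]).reset_index(
        drop=True
    )
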