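"""Ground-truthed synthetic MSI phantoms of intestinal cross-sections.

The phantom emulates the geometry and chemistry the pipeline's statistics
depend on, nothing more: a concentric cross-section (intestinal lumen disc,
mucosa ring, outer muscularis/submucosa ring) on an empty slide background,
compartment-specific structural-lipid peaks in m/z 750-850 that drive
segmentation, and drug ions whose abundance follows one-compartment oral
pharmacokinetics — the lumen empties as A0*exp(-ka*t) while tissue follows
the Bateman function A0*ka/(ka-ke)*(exp(-ke*t) - exp(-ka*t)).

Noise model (all seeded, all off at sigma = 0):

* ``tic_sigma`` — per-pixel log-normal factor on the whole spectrum
  (spectrum-to-spectrum TIC variation);
* ``peak_sigma`` — per-channel multiplicative log-normal noise;
* ``baseline_sigma`` — additive half-normal baseline on every channel,
  also the only signal on background pixels and in vehicle drug windows
  (it is what detection limits are estimated from).

Every generated dataset is paired with a :class:`PhantomTruth` carrying the
label grid, noiseless per-compartment drug totals and the true absorbed
fraction — the ground truth the pipeline estimates are validated against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import ConcentrationTable, MSIDataset, Spectrum, ValidationError
from .segmentation import Compartment

__all__ = [
    "PhantomDrug",
    "PhantomConfig",
    "PhantomTruth",
    "pk_profile",
    "generate_phantom",
    "generate_cohort",
    "calibrate_lumen_partition",
    "CohortResult",
    "default_config",
]

#: label codes on the truth grid
LABEL_CODES = {
    Compartment.LUMEN: 1,
    Compartment.MUCOSA: 2,
    Compartment.OUTER_TISSUE: 3,
}

#: compartment-specific structural-lipid peaks (m/z, mean intensity).
#: Each profile totals 100, so compartments share the same lipid load (TIC
#: normalization then rescales all compartments alike).  The two tissue
#: compartments share the phosphatidylcholine [M+K]+ ions (796.53/798.54)
#: that outline tissue in real sections, in different ratios, while the
#: luminal bowel content has a disjoint profile — so under correlation
#: distance the tissues resemble each other more than either resembles the
#: lumen, as in real sections.
DEFAULT_LIPID_PROFILES: Dict[Compartment, Tuple[Tuple[float, float], ...]] = {
    Compartment.LUMEN: ((760.58, 40.0), (786.60, 30.0), (812.55, 30.0)),
    Compartment.MUCOSA: ((796.53, 50.0), (798.54, 30.0), (822.54, 20.0)),
    Compartment.OUTER_TISSUE: (
        (772.53, 20.0),
        (796.53, 35.0),
        (798.54, 35.0),
        (834.53, 10.0),
    ),
}

#: marker ions for automatic compartment assignment (the most abundant lipid
#: of each compartment's profile)
DEFAULT_MARKER_MZ = {
    Compartment.LUMEN: 760.58,
    Compartment.MUCOSA: 796.53,
    Compartment.OUTER_TISSUE: 772.53,
}

#: off-peak channels so the axis has signal-free background positions
BACKGROUND_CHANNELS = (275.0, 350.0, 450.0, 650.0)


@dataclass
class PhantomDrug:
    """One dosed compound: detection m/z per modality, luminal amplitude A0
    (arbitrary intensity units), absorption/elimination rates (1/h), and
    per-pixel partition weights per compartment (lumen >> mucosa > outer,
    matching observed drug distributions)."""

    name: str
    mz: Dict[str, float]
    A0: float = 2.0
    ka: float = 1.2
    ke: float = 0.3
    partition: Dict[Compartment, float] = field(
        default_factory=lambda: {
            Compartment.LUMEN: 6.0,
            Compartment.MUCOSA: 0.6,
            Compartment.OUTER_TISSUE: 0.25,
        }
    )

    def __post_init__(self) -> None:
        if self.A0 < 0:
            raise ValidationError("A0 must be non-negative")
        if self.ka <= 0 or self.ke <= 0:
            raise ValidationError("rates ka, ke must be positive")


def _default_drug_entries() -> List[PhantomDrug]:
    """The four benchmark compounds at their detected m/z values, with
    plausible, compound-specific oral absorption/elimination rates."""
    from .quantify import default_drugs

    rates = {
        "terfenadine": (1.2, 0.25),
        "losartan": (0.9, 0.35),
        "dextromethorphan": (1.5, 0.40),
        "diphenhydramine": (1.8, 0.30),
    }
    out = []
    for d in default_drugs():
        ka, ke = rates[d.name]
        out.append(PhantomDrug(name=d.name, mz=dict(d.expected_mz), ka=ka, ke=ke))
    return out


@dataclass
class PhantomConfig:
    """Everything that defines one phantom section (before seeding)."""

    grid_shape: Tuple[int, int] = (64, 64)
    pixel_size_um: float = 10.0
    modality: str = "MALDI"
    lumen_radius: float = 9.0
    mucosa_radius: float = 18.0
    outer_radius: float = 26.0
    villi_amplitude: float = 0.0
    n_villi: int = 8
    lipid_profiles: Dict[Compartment, Tuple[Tuple[float, float], ...]] = field(
        default_factory=lambda: dict(DEFAULT_LIPID_PROFILES)
    )
    drugs: List[PhantomDrug] = field(default_factory=_default_drug_entries)
    peak_sigma: float = 0.15
    baseline_sigma: float = 0.02
    tic_sigma: float = 0.10
    enterohepatic_amplitude: float = 0.0
    enterohepatic_time_h: float = 3.0

    def __post_init__(self) -> None:
        half = min(self.grid_shape) / 2.0
        if not (0 < self.lumen_radius < self.mucosa_radius < self.outer_radius <= half):
            raise ValidationError(
                "radii must satisfy 0 < lumen < mucosa < outer <= half-extent"
            )
        for s in (self.peak_sigma, self.baseline_sigma, self.tic_sigma):
            if s < 0:
                raise ValidationError("noise sigmas must be non-negative")
        for mz_list in self.lipid_profiles.values():
            for mz, inten in mz_list:
                if not (750.0 <= mz <= 850.0):
                    raise ValidationError("lipid peaks must lie in m/z 750-850")
                if inten < 0:
                    raise ValidationError("lipid intensities must be >= 0")

    def noiseless(self) -> "PhantomConfig":
        return replace(
            self, peak_sigma=0.0, baseline_sigma=0.0, tic_sigma=0.0
        )

    def mz_axis(self) -> np.ndarray:
        """Shared (continuous-mode) m/z axis: the union of lipid, drug and
        background channels."""
        channels = set(BACKGROUND_CHANNELS)
        for peaks in self.lipid_profiles.values():
            channels.update(mz for mz, _ in peaks)
        for drug in self.drugs:
            channels.add(drug.mz[self.modality])
        return np.array(sorted(channels))


@dataclass
class PhantomTruth:
    """Ground truth of one phantom: label grid (0 background, 1 lumen,
    2 mucosa, 3 outer tissue), noiseless per-compartment drug totals, true
    absorbed fractions, and noiseless section means/totals."""

    specimen_id: str
    timepoint_h: object
    labels: np.ndarray
    compartment_totals: Dict[str, Dict[Compartment, float]]
    absorbed_fraction: Dict[str, float]
    section_total: Dict[str, float]
    section_mean: Dict[str, float]
    concentration: Dict[str, float] = field(default_factory=dict)


def pk_profile(
    t: float, A0: float, ka: float, ke: float
) -> Tuple[float, float]:
    """Luminal and tissue drug abundance at time ``t`` hours post dose.

    lumen(t)  = A0 * exp(-ka t)
    tissue(t) = A0 * ka/(ka-ke) * (exp(-ke t) - exp(-ka t))   (Bateman)

    The ka = ke case uses the limit A0 * ka * t * exp(-ka t).  Tissue
    abundance peaks at t_max = ln(ka/ke)/(ka-ke).
    """
    if t < 0:
        raise ValidationError("t must be >= 0")
    if A0 < 0:
        raise ValidationError("A0 must be >= 0")
    if ka <= 0 or ke <= 0:
        raise ValidationError("rates must be positive")
    lumen = A0 * math.exp(-ka * t)
    if ka == ke:
        tissue = A0 * ka * t * math.exp(-ka * t)
    else:
        tissue = A0 * ka / (ka - ke) * (math.exp(-ke * t) - math.exp(-ka * t))
    return lumen, tissue


def _label_grid(config: PhantomConfig) -> np.ndarray:
    nrow, ncol = config.grid_shape
    cy, cx = (nrow - 1) / 2.0, (ncol - 1) / 2.0
    rows, cols = np.mgrid[0:nrow, 0:ncol]
    rr = np.hypot(rows - cy, cols - cx)
    lumen_r = config.lumen_radius
    if config.villi_amplitude > 0:
        theta = np.arctan2(rows - cy, cols - cx)
        lumen_r = config.lumen_radius + config.villi_amplitude * np.sin(
            config.n_villi * theta
        )
    labels = np.zeros(config.grid_shape, dtype=int)
    labels[rr <= config.outer_radius] = LABEL_CODES[Compartment.OUTER_TISSUE]
    labels[rr <= config.mucosa_radius] = LABEL_CODES[Compartment.MUCOSA]
    labels[rr <= lumen_r] = LABEL_CODES[Compartment.LUMEN]
    return labels


def _drug_level(
    drug: PhantomDrug,
    compartment: Compartment,
    timepoint_h: object,
    config: PhantomConfig,
) -> float:
    """Noiseless per-pixel drug intensity in one compartment."""
    if timepoint_h == "vehicle":
        return 0.0
    t = float(timepoint_h)
    lumen, tissue = pk_profile(t, drug.A0, drug.ka, drug.ke)
    if config.enterohepatic_amplitude > 0 and t > config.enterohepatic_time_h:
        # biliary re-entry: a secondary luminal bump after the configured lag
        lumen += (
            drug.A0
            * config.enterohepatic_amplitude
            * math.exp(-drug.ka * (t - config.enterohepatic_time_h))
        )
    base = lumen if compartment == Compartment.LUMEN else tissue
    return base * drug.partition.get(compartment, 0.0)


def _compute_truth(
    config: PhantomConfig,
    labels: np.ndarray,
    timepoint_h: object,
    specimen_id: str,
) -> PhantomTruth:
    counts = {
        comp: int((labels == code).sum()) for comp, code in LABEL_CODES.items()
    }
    n_section = sum(counts.values())
    totals: Dict[str, Dict[Compartment, float]] = {}
    fractions: Dict[str, float] = {}
    section_total: Dict[str, float] = {}
    section_mean: Dict[str, float] = {}
    for drug in config.drugs:
        per_comp = {
            comp: _drug_level(drug, comp, timepoint_h, config) * counts[comp]
            for comp in LABEL_CODES
        }
        totals[drug.name] = per_comp
        tot = sum(per_comp.values())
        section_total[drug.name] = tot
        section_mean[drug.name] = tot / n_section if n_section else 0.0
        tissue = per_comp[Compartment.MUCOSA] + per_comp[Compartment.OUTER_TISSUE]
        fractions[drug.name] = tissue / tot if tot > 0 else float("nan")
    return PhantomTruth(
        specimen_id=specimen_id,
        timepoint_h=timepoint_h,
        labels=labels,
        compartment_totals=totals,
        absorbed_fraction=fractions,
        section_total=section_total,
        section_mean=section_mean,
    )


def calibrate_lumen_partition(
    config: PhantomConfig,
    timepoint_h: float,
    target_fraction: float,
    drug_name: Optional[str] = None,
) -> PhantomConfig:
    """Return a config whose lumen partition weights are rescaled so the true
    absorbed fraction at ``timepoint_h`` equals ``target_fraction`` exactly
    (for one drug, or all drugs when ``drug_name`` is None).

    Solves tissue/(tissue + lumen_pk * w_l * area_l) = f for w_l.
    """
    if not (0 < target_fraction < 1):
        raise ValidationError("target fraction must be in (0, 1)")
    labels = _label_grid(config)
    counts = {
        comp: int((labels == code).sum()) for comp, code in LABEL_CODES.items()
    }
    new_drugs = []
    for drug in config.drugs:
        if drug_name is not None and drug.name != drug_name:
            new_drugs.append(drug)
            continue
        lumen_pk, tissue_pk = pk_profile(
            float(timepoint_h), drug.A0, drug.ka, drug.ke
        )
        tissue_total = tissue_pk * sum(
            drug.partition.get(c, 0.0) * counts[c]
            for c in (Compartment.MUCOSA, Compartment.OUTER_TISSUE)
        )
        if tissue_total <= 0 or lumen_pk <= 0:
            raise ValidationError(
                f"cannot calibrate {drug.name}: no signal at t={timepoint_h}"
            )
        w_l = (
            tissue_total
            * (1.0 - target_fraction)
            / (target_fraction * lumen_pk * counts[Compartment.LUMEN])
        )
        partition = dict(drug.partition)
        partition[Compartment.LUMEN] = w_l
        new_drugs.append(replace(drug, partition=partition))
    return replace(config, drugs=new_drugs)


def generate_phantom(
    config: PhantomConfig,
    timepoint_h: object,
    specimen_id: str,
    seed: Optional[int] = None,
    animal_id: str = "A1",
    dose_group: str = "dosed",
    rng: Optional[np.random.Generator] = None,
) -> Tuple[MSIDataset, PhantomTruth]:
    """Generate one phantom section and its ground truth.

    ``timepoint_h`` is hours post dose, or the string ``"vehicle"`` for an
    undosed control (drug amplitude zero, background noise only).  All noise
    draws come from ``seed`` (or an explicit ``rng``); a fixed seed gives a
    bit-identical dataset.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    labels = _label_grid(config)
    axis = config.mz_axis()
    nch = axis.size
    ch_index = {mz: i for i, mz in enumerate(axis)}

    base_by_code = {0: np.zeros(nch)}
    for comp, code in LABEL_CODES.items():
        base = np.zeros(nch)
        for mz, inten in config.lipid_profiles[comp]:
            base[ch_index[mz]] += inten
        for drug in config.drugs:
            base[ch_index[drug.mz[config.modality]]] += _drug_level(
                drug, comp, timepoint_h, config
            )
        base_by_code[code] = base

    nrow, ncol = config.grid_shape
    base = np.empty((nrow, ncol, nch))
    for code, vec in base_by_code.items():
        base[labels == code] = vec

    intens = base
    if config.peak_sigma > 0:
        intens = intens * rng.lognormal(
            0.0, config.peak_sigma, size=intens.shape
        )
    if config.tic_sigma > 0:
        intens = intens * rng.lognormal(
            0.0, config.tic_sigma, size=(nrow, ncol, 1)
        )
    if config.baseline_sigma > 0:
        intens = intens + np.abs(
            rng.normal(0.0, config.baseline_sigma, size=intens.shape)
        )

    spectra = {
        (r, c): Spectrum(axis, intens[r, c])
        for r in range(nrow)
        for c in range(ncol)
    }
    dataset = MSIDataset(
        modality=config.modality,
        pixel_size_um=config.pixel_size_um,
        grid_shape=config.grid_shape,
        spectra=spectra,
        metadata={
            "specimen_id": specimen_id,
            "animal_id": animal_id,
            "timepoint_h": timepoint_h,
            "dose_group": dose_group,
        },
    )
    truth = _compute_truth(config, labels, timepoint_h, specimen_id)
    return dataset, truth


@dataclass
class CohortResult:
    """A generated study: datasets per modality, per-specimen truths and the
    matched extraction-based concentration table."""

    datasets: Dict[str, List[MSIDataset]]
    truths: List[PhantomTruth]
    table: ConcentrationTable


def generate_cohort(
    config: PhantomConfig,
    timepoints: Sequence[float] = (1.0, 2.0, 4.0, 6.0),
    animals_per_timepoint: int = 3,
    specimens_per_animal: int = 3,
    seed: Optional[int] = None,
    n_vehicle_animals: int = 1,
    a0_jitter_sigma: float = 0.5,
    geometry_jitter: float = 1.0,
    measurement_sigma: float = 0.10,
    calibration_factor: float = 0.05,
    modalities: Sequence[str] = ("MALDI",),
) -> CohortResult:
    """Generate a full dosed study: one phantom per specimen per modality,
    plus vehicle controls and an LC-MS/MS-style concentration table.

    Per-specimen biological variability is a log-normal jitter on each
    drug's A0 (sigma ``a0_jitter_sigma``) and a uniform +/-``geometry_jitter``
    pixel perturbation of the section radii.  Measured concentrations are
    the noiseless section totals times ``calibration_factor`` (mass drug per
    mass tissue per intensity unit) times log-normal measurement noise
    (sigma ``measurement_sigma``).  When several modalities are requested the
    same specimen truth underlies both renderings, with independent noise.
    """
    if not timepoints:
        raise ValidationError("need at least one timepoint")
    master = np.random.default_rng(seed)
    datasets: Dict[str, List[MSIDataset]] = {m: [] for m in modalities}
    truths: List[PhantomTruth] = []
    rows = []

    groups: List[Tuple[object, str]] = []
    for t in timepoints:
        for a in range(animals_per_timepoint):
            groups.append((t, f"A{t}h-{a + 1}"))
    for a in range(n_vehicle_animals):
        groups.append(("vehicle", f"Aveh-{a + 1}"))

    for timepoint, animal in groups:
        for s in range(specimens_per_animal):
            specimen = f"{animal}-S{s + 1}"
            jitter = {
                d.name: float(master.lognormal(0.0, a0_jitter_sigma))
                for d in config.drugs
            }
            dr = (
                master.uniform(-geometry_jitter, geometry_jitter, size=3)
                if geometry_jitter > 0
                else np.zeros(3)
            )
            spec_config = replace(
                config,
                lumen_radius=config.lumen_radius + dr[0],
                mucosa_radius=config.mucosa_radius + dr[1],
                outer_radius=min(
                    config.outer_radius + dr[2], min(config.grid_shape) / 2.0
                ),
                drugs=[
                    replace(d, A0=d.A0 * jitter[d.name]) for d in config.drugs
                ],
            )
            truth: Optional[PhantomTruth] = None
            for modality in modalities:
                ds, tr = generate_phantom(
                    replace(spec_config, modality=modality),
                    timepoint,
                    specimen,
                    rng=np.random.default_rng(master.integers(2**31)),
                    animal_id=animal,
                    dose_group="vehicle" if timepoint == "vehicle" else "dosed",
                )
                datasets[modality].append(ds)
                if truth is None:
                    truth = tr  # totals/fractions are modality-independent
            truths.append(truth)
            for drug in config.drugs:
                true_total = truth.section_total[drug.name]
                noise = (
                    float(master.lognormal(0.0, measurement_sigma))
                    if measurement_sigma > 0
                    else 1.0
                )
                conc = calibration_factor * true_total * noise
                truth.concentration[drug.name] = conc
                rows.append(
                    {
                        "specimen_id": specimen,
                        "animal_id": animal,
                        "timepoint_h": timepoint,
                        "drug_name": drug.name,
                        "concentration": conc,
                        "replicate_id": "r1",
                    }
                )
    table = ConcentrationTable(pd.DataFrame(rows))
    return CohortResult(datasets=datasets, truths=truths, table=table)


def default_config(**overrides) -> PhantomConfig:
    """The study-default phantom configuration (64x64 MALDI section)."""
    return PhantomConfig(**overrides)
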