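"""End-to-end orchestration: mask -> normalize -> segment -> assign ->
quantify -> correlate, with tidy CSV/JSON outputs.

The run produces the study's result artifacts: per-specimen compartment
abundances, absorbed-fraction summaries per drug, abundance-time profiles,
detection limits from vehicle sections, MSI-vs-LC-MS/MS regressions per drug
and modality, and cross-modality regressions.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .correlate import cross_modality, ols_regression
from .io import MSIDataset
from .phantom import DEFAULT_MARKER_MZ, CohortResult
from .preprocess import MassWindow, TissueMask, extract_ion_image, tic_normalize, tissue_mask
from .quantify import (
    Compartment,
    DetectionLimits,
    DrugDefinition,
    absorbed_fraction,
    cohort_fraction_summary,
    default_drugs,
    detection_limits,
    segment_abundances,
    time_profile,
)
from .segmentation import assign_compartments, segment_dataset

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "process_section"]

RESULT_FILES = (
    "segment_abundances.csv",
    "fractions_by_specimen.csv",
    "fraction_summary.csv",
    "time_profiles.csv",
    "detection_limits.csv",
    "regression_msi_vs_lcms.csv",
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the offending section."""


@dataclass
class RunConfig:
    """Parameters of one pipeline run."""

    seed: int = 0
    k: int = 3
    mz_lo: float = 750.0
    mz_hi: float = 850.0
    bin_width: float = 0.1
    #: relative threshold by default: blank-slide background TIC sits orders
    #: of magnitude below tissue TIC, so a cut at 5% of the robust tissue
    #: level separates them without knowing the background fraction, which a
    #: fixed quantile would need to match
    mask_method: str = "relative"
    mask_quantile: float = 0.6
    n_restarts: int = 10
    #: per-modality TIC normalization (MALDI data is normalized, DESI raw)
    normalize: Dict[str, bool] = field(
        default_factory=lambda: {"MALDI": True, "DESI": False}
    )
    #: marker m/z per compartment for automatic cluster assignment
    marker_mz: Dict[str, float] = field(
        default_factory=lambda: {c.value: mz for c, mz in DEFAULT_MARKER_MZ.items()}
    )
    marker_half_width_da: float = 0.1
    output_dir: Optional[str] = None

    def marker_windows(self) -> List[Tuple[MassWindow, Compartment]]:
        return [
            (
                MassWindow(mz, self.marker_half_width_da, "Da"),
                Compartment(name),
            )
            for name, mz in self.marker_mz.items()
        ]


def process_section(
    dataset: MSIDataset,
    config: RunConfig,
    drugs: Sequence[DrugDefinition],
) -> Dict[str, object]:
    """Run the per-section stages on one dataset.

    Returns the section record: mask, segment map, compartment assignment,
    per-drug compartment abundances, absorbed fractions, and the
    whole-section mean abundance per drug (over all masked pixels, lumen
    included, as used for the cross-platform correlation).
    """
    specimen = dataset.metadata.get("specimen_id", "?")
    try:
        mask = tissue_mask(
            dataset, quantile=config.mask_quantile, method=config.mask_method
        )
        ds = dataset
        if config.normalize.get(dataset.modality, False) and not ds.normalized:
            ds = tic_normalize(ds)
        segmap = segment_dataset(
            ds,
            mask,
            k=config.k,
            mz_lo=config.mz_lo,
            mz_hi=config.mz_hi,
            seed=config.seed,
            bin_width=config.bin_width,
            n_restarts=config.n_restarts,
            normalize=False,  # ds already carries the per-modality choice
        )
        assignment = assign_compartments(
            segmap, ds, marker_windows=config.marker_windows()
        )
        record: Dict[str, object] = {
            "specimen_id": specimen,
            "modality": dataset.modality,
            "timepoint_h": dataset.metadata.get("timepoint_h"),
            "mask": mask,
            "segmap": segmap,
            "assignment": assignment,
            "abundances": {},
            "fractions": {},
            "section_mean": {},
        }
        for drug in drugs:
            image = extract_ion_image(ds, drug.window(dataset.modality))
            abund = segment_abundances(image, segmap, assignment)
            record["abundances"][drug.name] = abund
            frac, defined = absorbed_fraction(abund)
            record["fractions"][drug.name] = frac if defined else None
            vals = image.masked_values(mask)
            record["section_mean"][drug.name] = float(np.nanmean(vals))
        return record
    except Exception as exc:  # annotate with the failing section
        raise PipelineError(f"section {specimen!r} failed: {exc}") from exc


def run_pipeline(
    cohort: CohortResult,
    config: RunConfig,
    drugs: Optional[Sequence[DrugDefinition]] = None,
) -> Dict[str, object]:
    """Run the full analysis on a cohort and return (and optionally write)
    the result tables.

    Returns a dict with keys ``segment_abundances``, ``fractions_by_specimen``,
    ``fraction_summary``, ``time_profiles``, ``detection_limits``,
    ``regression_msi_vs_lcms`` (all DataFrames), ``regression_cross_modality``
    (DataFrame or None) and ``provenance``.
    """
    drugs = list(drugs) if drugs is not None else default_drugs()

    abundance_rows = []
    fraction_rows = []
    profile_records = []
    section_means: Dict[str, Dict[str, Dict[str, float]]] = {}
    vehicle: Dict[str, List[Tuple[MSIDataset, TissueMask]]] = {}

    for modality, ds_list in cohort.datasets.items():
        section_means[modality] = {d.name: {} for d in drugs}
        vehicle[modality] = []
        for dataset in ds_list:
            rec = process_section(dataset, config, drugs)
            specimen = rec["specimen_id"]
            is_vehicle = dataset.metadata.get("dose_group") == "vehicle"
            if is_vehicle:
                ds = dataset
                if config.normalize.get(modality, False) and not ds.normalized:
                    ds = tic_normalize(ds)
                vehicle[modality].append((ds, rec["mask"]))
            for drug in drugs:
                for comp, ab in rec["abundances"][drug.name].items():
                    abundance_rows.append(
                        {
                            "specimen_id": specimen,
                            "modality": modality,
                            "timepoint_h": rec["timepoint_h"],
                            "drug_name": drug.name,
                            "compartment": comp.value,
                            "total": ab.total,
                            "mean": ab.mean,
                            "sd": ab.sd,
                            "pixel_count": ab.pixel_count,
                        }
                    )
                    profile_records.append(
                        {
                            "specimen_id": specimen,
                            "timepoint_h": rec["timepoint_h"],
                            "compartment": comp,
                            "mean_abundance": ab.mean,
                            "modality": modality,
                            "drug_name": drug.name,
                        }
                    )
                if not is_vehicle:
                    fraction_rows.append(
                        {
                            "specimen_id": specimen,
                            "modality": modality,
                            "timepoint_h": rec["timepoint_h"],
                            "drug_name": drug.name,
                            "absorbed_fraction": rec["fractions"][drug.name],
                        }
                    )
                section_means[modality][drug.name][specimen] = rec[
                    "section_mean"
                ][drug.name]

    abundances = pd.DataFrame(abundance_rows)
    fractions = pd.DataFrame(fraction_rows)

    summary_rows = []
    for (modality, drug_name), grp in fractions.groupby(
        ["modality", "drug_name"], sort=True
    ):
        res = cohort_fraction_summary(list(grp["absorbed_fraction"]))
        summary_rows.append(
            {
                "modality": modality,
                "drug_name": drug_name,
                "mean": res.mean,
                "sd": res.sd,
                "min": res.min,
                "max": res.max,
                "n": len(res.fractions),
                "n_undefined": res.n_undefined,
            }
        )
    summary = pd.DataFrame(summary_rows)

    profile_frames = []
    for (modality, drug_name), recs in _group_records(profile_records):
        prof = time_profile(recs)
        prof.insert(0, "drug_name", drug_name)
        prof.insert(0, "modality", modality)
        profile_frames.append(prof)
    profiles = (
        pd.concat(profile_frames, ignore_index=True)
        if profile_frames
        else pd.DataFrame()
    )

    limit_rows = []
    limits_by_key: Dict[Tuple[str, str], DetectionLimits] = {}
    for modality, pairs in vehicle.items():
        if not pairs:
            continue
        ds_list, mask_list = zip(*pairs)
        for drug in drugs:
            lim = detection_limits(list(ds_list), list(mask_list), drug, modality)
            limits_by_key[(modality, drug.name)] = lim
            limit_rows.append(
                {
                    "modality": modality,
                    "drug_name": drug.name,
                    "background_sd": lim.background_sd,
                    "lod": lim.lod,
                    "lloq": lim.lloq,
                    "n_background_pixels": lim.n_background_pixels,
                }
            )
    limits = pd.DataFrame(limit_rows)

    # dosed specimens only: vehicle controls inform the detection limits,
    # not the calibration regression
    veh_ids = set(
        cohort.table.frame.loc[
            cohort.table.frame["timepoint_h"].astype(str) == "vehicle",
            "specimen_id",
        ]
    )
    reg_rows = []
    for modality in cohort.datasets:
        for drug in drugs:
            conc = cohort.table.specimen_means(drug.name)
            means = section_means[modality][drug.name]
            dosed = [s for s in conc.index if s in means and s not in veh_ids]
            if len(dosed) < 3:
                continue
            reg = ols_regression(
                [conc[s] for s in dosed], [means[s] for s in dosed]
            )
            reg_rows.append(
                {
                    "modality": modality,
                    "drug_name": drug.name,
                    "slope": reg.slope,
                    "intercept": reg.intercept,
                    "r_squared": reg.r_squared,
                    "n": reg.n,
                }
            )
    regressions = pd.DataFrame(reg_rows)

    cross = None
    mods = list(cohort.datasets)
    if "MALDI" in mods and "DESI" in mods:
        rows = []
        for drug in drugs:
            reg = cross_modality(
                section_means["MALDI"][drug.name],
                section_means["DESI"][drug.name],
            )
            rows.append(
                {
                    "drug_name": drug.name,
                    "slope": reg.slope,
                    "intercept": reg.intercept,
                    "r_squared": reg.r_squared,
                    "n": reg.n,
                }
            )
        cross = pd.DataFrame(rows)

    provenance = {
        "package_version": __version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "config_hash": hashlib.sha256(
            json.dumps(_config_dict(config), sort_keys=True).encode()
        ).hexdigest(),
        "n_sections": {m: len(v) for m, v in cohort.datasets.items()},
    }

    results = {
        "segment_abundances": abundances,
        "fractions_by_specimen": fractions,
        "fraction_summary": summary,
        "time_profiles": profiles,
        "detection_limits": limits,
        "regression_msi_vs_lcms": regressions,
        "regression_cross_modality": cross,
        "provenance": provenance,
    }
    if config.output_dir:
        _write_results(results, config.output_dir)
    return results


def _group_records(records):
    keys = sorted({(r["modality"], r["drug_name"]) for r in records})
    for key in keys:
        yield key, [
            r for r in records if (r["modality"], r["drug_name"]) == key
        ]


def _config_dict(config: RunConfig) -> Dict[str, object]:
    d = asdict(config)
    d.pop("output_dir", None)
    return d


def _write_results(results: Dict[str, object], output_dir: str) -> None:
    os.makedirs(output_dir, exist_ok=True)
    for name in RESULT_FILES:
        frame = results[name.removesuffix(".csv")]
        frame.to_csv(os.path.join(output_dir, name), index=False)
    if results["regression_cross_modality"] is not None:
        results["regression_cross_modality"].to_csv(
            os.path.join(output_dir, "regression_cross_modality.csv"),
            index=False,
        )
    with open(os.path.join(output_dir, "provenance.json"), "w") as fh:
        json.dump(results["provenance"], fh, indent=1, default=str)
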