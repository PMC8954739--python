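"""Adduct masses, per-compartment abundances, absorbed fractions, detection
limits and time profiles."""

import math

import numpy as np
import pytest

from msidissect.io import MSIDataset, Spectrum, ValidationError
from msidissect.preprocess import IonImage, MassWindow, TissueMask
from msidissect.quantify import (
    Compartment,
    DrugDefinition,
    SegmentAbundance,
    absorbed_fraction,
    adduct_mz,
    cohort_fraction_summary,
    default_drugs,
    detection_limits,
    parse_formula,
    segment_abundances,
    time_profile,
)
from msidissect.segmentation import CompartmentAssignment, SegmentMap


class TestAdductMz:
    @pytest.mark.parametrize(
        "formula, expected",
        [
            ("C32H41NO2", 472.32),  # terfenadine
            ("C22H23ClN6O", 423.17),  # losartan
            ("C18H25NO", 272.20),  # dextromethorphan
            ("C17H21NO", 256.17),  # diphenhydramine
        ],
    )
    def test_protonated_benchmark_compounds(self, formula, expected):
        assert adduct_mz(formula, "[M+H]+") == pytest.approx(expected, abs=0.005)

    def test_protonated_water_by_hand(self):
        # 2 x 1.007825 + 15.994915 + 1.007276 summed by hand
        assert adduct_mz("H2O", "[M+H]+") == pytest.approx(19.01784, abs=5e-4)

    def test_potassium_and_sodium_ordering(self):
        m_h = adduct_mz("C17H21NO", "[M+H]+")
        m_na = adduct_mz("C17H21NO", "[M+Na]+")
        m_k = adduct_mz("C17H21NO", "[M+K]+")
        assert m_h < m_na < m_k
        assert m_k - m_h == pytest.approx(38.963158 - 1.007276, abs=1e-9)

    def test_unknown_element_rejected(self):
        with pytest.raises(ValidationError):
            adduct_mz("C2Xe3", "[M+H]+")

    def test_unknown_adduct_rejected(self):
        with pytest.raises(ValidationError):
            adduct_mz("H2O", "[M+NH4]+")

    def test_formula_parsing(self):
        assert parse_formula("C22H23ClN6O") == {
            "C": 22,
            "H": 23,
            "Cl": 1,
            "N": 6,
            "O": 1,
        }
        with pytest.raises(ValidationError):
            parse_formula("C2(H3)2")


class TestDrugDefinition:
    def test_defaults_cover_both_modalities(self):
        drugs = {d.name: d for d in default_drugs()}
        assert drugs["losartan"].adducts == {"MALDI": "[M+H]+", "DESI": "[M+K]+"}
        # observed DESI value kept as override, near the theoretical mass
        assert drugs["losartan"].expected_mz["DESI"] == pytest.approx(461.129)
        window = drugs["terfenadine"].window("DESI")
        assert window.half_width == 0.01

    def test_expected_mz_far_from_theory_rejected(self):
        with pytest.raises(ValidationError):
            DrugDefinition(
                name="bogus",
                formula="H2O",
                adducts={"MALDI": "[M+H]+"},
                expected_mz={"MALDI": 19.1},
            )


def make_segmented_image(values, labels):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    k = int(labels.max())
    segmap = SegmentMap(
        labels=labels,
        k=k,
        metric="correlation",
        seed=0,
        cluster_centroids=np.ones((k, 3)),
    )
    mapping = {1: "lumen", 2: "mucosa", 3: "outer_tissue"}
    assignment = CompartmentAssignment(
        mapping={c: mapping[c] for c in range(1, k + 1)}, provenance="manual"
    )
    image = IonImage(values=values, window=MassWindow(472.32, 0.1))
    return image, segmap, assignment


class TestSegmentAbundances:
    def test_constant_image(self):
        labels = np.concatenate([np.ones(10), np.full(2, 2)]).reshape(2, 6)
        image, segmap, assignment = make_segmented_image(
            np.full((2, 6), 2.0), labels.astype(int)
        )
        out = segment_abundances(image, segmap, assignment)
        lumen = out[Compartment.LUMEN]
        assert lumen.total == pytest.approx(20.0)
        assert lumen.mean == pytest.approx(2.0)
        assert lumen.sd == pytest.approx(0.0)
        assert lumen.pixel_count == 10

    def test_empty_compartment_absent(self):
        image, segmap, assignment = make_segmented_image(
            np.ones((1, 4)), np.array([[1, 1, 2, 2]])
        )
        out = segment_abundances(image, segmap, assignment)
        assert Compartment.OUTER_TISSUE not in out

    def test_grid_mismatch_rejected(self):
        image, segmap, assignment = make_segmented_image(
            np.ones((1, 4)), np.array([[1, 1, 2, 2]])
        )
        image.values = np.ones((2, 2))
        with pytest.raises(ValidationError):
            segment_abundances(image, segmap, assignment)

    def test_sum_equals_mean_times_count(self):
        rng = np.random.default_rng(0)
        image, segmap, assignment = make_segmented_image(
            rng.uniform(size=(3, 4)), rng.integers(1, 4, size=(3, 4))
        )
        for ab in segment_abundances(image, segmap, assignment).values():
            assert ab.total == pytest.approx(ab.mean * ab.pixel_count, rel=1e-9)


class TestAbsorbedFraction:
    def entry(self, comp, total):
        return SegmentAbundance(
            compartment=comp, total=total, mean=total, sd=None, pixel_count=1
        )

    def abundances(self, lumen, mucosa, outer):
        return {
            Compartment.LUMEN: self.entry(Compartment.LUMEN, lumen),
            Compartment.MUCOSA: self.entry(Compartment.MUCOSA, mucosa),
            Compartment.OUTER_TISSUE: self.entry(Compartment.OUTER_TISSUE, outer),
        }

    def test_all_signal_in_tissue(self):
        frac, defined = absorbed_fraction(self.abundances(0.0, 3.0, 2.0))
        assert defined and frac == 1.0

    def test_worked_example(self):
        frac, defined = absorbed_fraction(self.abundances(40.0, 35.0, 25.0))
        assert defined and frac == pytest.approx(0.60)

    def test_zero_total_undefined(self):
        frac, defined = absorbed_fraction(self.abundances(0.0, 0.0, 0.0))
        assert frac is None and not defined

    def test_negative_sum_rejected(self):
        bad = self.abundances(-1.0, 1.0, 1.0)
        with pytest.raises(ValidationError):
            absorbed_fraction(bad)

    def test_lumen_required(self):
        partial = {
            Compartment.MUCOSA: self.entry(Compartment.MUCOSA, 1.0)
        }
        with pytest.raises(ValidationError):
            absorbed_fraction(partial)


class TestCohortSummary:
    def test_constant_fractions(self):
        res = cohort_fraction_summary([0.5, 0.5, 0.5])
        assert (res.mean, res.sd, res.min, res.max) == (0.5, 0.0, 0.5, 0.5)

    def test_two_points_sample_sd(self):
        # hand: mean 0.5, SD = sqrt(((0.3)^2 + (0.3)^2) / 1) = 0.424264...
        res = cohort_fraction_summary([0.2, 0.8])
        assert res.sd == pytest.approx(math.sqrt(0.18), abs=1e-9)
        assert res.sd == pytest.approx(0.4243, abs=1e-4)

    def test_single_fraction_sd_undefined(self):
        res = cohort_fraction_summary([0.6])
        assert res.mean == 0.6 and res.sd is None
        assert (res.min, res.max) == (0.6, 0.6)

    def test_undefined_excluded_and_counted(self):
        res = cohort_fraction_summary([0.4, None, 0.6])
        assert res.mean == pytest.approx(0.5)
        assert res.n_undefined == 1

    def test_all_undefined_rejected(self):
        with pytest.raises(ValidationError):
            cohort_fraction_summary([None, None])


def vehicle_dataset(abundances, drug_mz=472.321005):
    """One-row dataset whose drug-window abundances are given per pixel."""
    n = len(abundances)
    spectra = {
        (0, i): Spectrum([drug_mz], [a]) for i, a in enumerate(abundances)
    }
    ds = MSIDataset(
        modality="MALDI", pixel_size_um=10.0, grid_shape=(1, n), spectra=spectra
    )
    mask = TissueMask(mask=np.ones((1, n), dtype=bool))
    return ds, mask


class TestDetectionLimits:
    def test_hand_computed_fixture(self):
        """Pooled abundances 1..5: sample SD 1.5811, LOD 4.7434, LLOQ
        15.8114 (n-1 denominator)."""
        ds, mask = vehicle_dataset([1.0, 2.0, 3.0, 4.0, 5.0])
        drug = default_drugs()[0]
        lim = detection_limits([ds], [mask], drug)
        assert lim.background_sd == pytest.approx(1.5811, abs=1e-3)
        assert lim.lod == pytest.approx(4.7434, abs=1e-3)
        assert lim.lloq == pytest.approx(15.8114, abs=1e-3)

    def test_lloq_lod_ratio_exact(self):
        ds, mask = vehicle_dataset([0.3, 1.7, 0.2, 2.9])
        lim = detection_limits([ds], [mask], default_drugs()[0])
        assert lim.lloq == lim.lod * (10.0 / 3.0)

    def test_constant_background_gives_zero(self):
        ds, mask = vehicle_dataset([2.0, 2.0, 2.0])
        lim = detection_limits([ds], [mask], default_drugs()[0])
        assert lim.lod == 0.0 and lim.lloq == 0.0

    def test_single_pixel_rejected(self):
        ds, mask = vehicle_dataset([1.0])
        with pytest.raises(ValidationError):
            detection_limits([ds], [mask], default_drugs()[0])

    def test_section_mean_pooling(self):
        ds1, m1 = vehicle_dataset([1.0, 3.0])
        ds2, m2 = vehicle_dataset([5.0, 7.0])
        lim = detection_limits(
            [ds1, ds2], [m1, m2], default_drugs()[0], pooling="section_means"
        )
        # section means 2 and 6 -> SD = sqrt(8)
        assert lim.background_sd == pytest.approx(math.sqrt(8.0), rel=1e-9)
        assert lim.n_background_pixels == 2


class TestTimeProfile:
    def records(self, series, compartment="mucosa"):
        out = []
        for t, values in series.items():
            for i, v in enumerate(values):
                out.append(
                    {
                        "specimen_id": f"S{t}-{i}",
                        "timepoint_h": t,
                        "compartment": compartment,
                        "mean_abundance": v,
                    }
                )
        return out

    def test_single_specimen_sd_undefined(self):
        prof = time_profile(self.records({1.0: [2.0], 2.0: [1.0]}))
        assert prof["mean"].tolist() == [2.0, 1.0]
        assert prof["sd"].isna().all()

    def test_vehicle_reported_at_time_zero(self):
        prof = time_profile(self.records({"vehicle": [0.1, 0.2], 1.0: [2.0]}))
        assert prof["timepoint_h"].tolist() == [0.0, 1.0]
        assert prof.loc[0, "mean"] == pytest.approx(0.15)

    def test_all_zero_images(self):
        prof = time_profile(self.records({1.0: [0.0, 0.0], 2.0: [0.0]}))
        assert (prof["mean"] == 0).all()

    def test_tissue_series_peaks_at_bateman_tmax(self, small_config):
        """Across a dense noiseless time series the tissue-compartment means
        peak at the analytic t_max = ln(ka/ke)/(ka-ke) (within one sampling
        interval)."""
        from msidissect.phantom import generate_phantom

        cfg = small_config.noiseless()
        drug = cfg.drugs[0]
        tmax = math.log(drug.ka / drug.ke) / (drug.ka - drug.ke)
        times = np.arange(0.5, 6.5, 0.5)
        records = []
        for t in times:
            _, truth = generate_phantom(cfg, float(t), f"S{t}", seed=0)
            counts = (truth.labels == 2).sum()
            records.append(
                {
                    "specimen_id": f"S{t}",
                    "timepoint_h": float(t),
                    "compartment": "mucosa",
                    "mean_abundance": truth.compartment_totals[drug.name][
                        Compartment.MUCOSA
                    ]
                    / counts,
                }
            )
        prof = time_profile(records)
        t_peak = prof.loc[prof["mean"].idxmax(), "timepoint_h"]
        assert abs(t_peak - tmax) <= 0.5
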