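"""Model-library loading, validation and covariate relations."""

import math

import pytest
import yaml

from blipta.errors import LibraryError, UnknownPenetrationError
from blipta.library import (
    CovariateRelation,
    IIVSpec,
    PKPDTarget,
    PopPKModel,
    SitePenetration,
    TPREntry,
    covariate_multiplier,
    default_library_path,
    load_model_library,
    write_library,
)


class TestCovariateMultiplier:
    @pytest.mark.parametrize(
        "form,ref,coef,value,expected",
        [
            ("power", 80.0, 1.0, 80.0, 1.0),  # reference case
            ("power", 80.0, 0.75, 200.0, (200.0 / 80.0) ** 0.75),  # ~1.9882
            ("proportional", 100.0, 1.0, 50.0, 0.5),
            ("linear", 100.0, 0.01, 150.0, 1.5),
        ],
    )
    def test_forms(self, form, ref, coef, value, expected):
        rel = CovariateRelation(
            parameter="CL", form=form, reference_value=ref, exponent_or_slope=coef
        )
        assert covariate_multiplier(rel, value) == pytest.approx(expected, rel=1e-12)

    def test_cap_truncates_covariate(self):
        rel = CovariateRelation(
            parameter="CL",
            form="power",
            reference_value=80.0,
            exponent_or_slope=1.0,
            covariate_cap=150.0,
        )
        assert covariate_multiplier(rel, 200.0) == pytest.approx(150.0 / 80.0)

    def test_linear_nonpositive_multiplier_rejected(self):
        rel = CovariateRelation(
            parameter="CL", form="linear", reference_value=100.0, exponent_or_slope=-0.02
        )
        with pytest.raises(LibraryError):
            covariate_multiplier(rel, 200.0)

    def test_power_form_monotone(self):
        rel = CovariateRelation(
            parameter="CL", form="power", reference_value=80.0, exponent_or_slope=0.62
        )
        values = [10.0, 40.0, 80.0, 120.0, 200.0, 400.0]
        mults = [covariate_multiplier(rel, v) for v in values]
        assert all(b > a for a, b in zip(mults, mults[1:]))


class TestValidation:
    def test_tier_magnitudes_must_increase(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            PKPDTarget(
                metric="ft_above_mic",
                tier_magnitudes={"EUCAST": 50.0, "Severe": 40.0, "Aggressive": 100.0},
            )

    def test_non_psd_covariance_rejected(self):
        with pytest.raises(ValueError, match="positive semi-definite"):
            IIVSpec(parameters=["CL", "V1"], matrix=[[0.1, 0.5], [0.5, 0.1]])

    def test_missing_compartment_parameters_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            PopPKModel(
                compound_name="x",
                n_compartments=2,
                typical_params={"CL": 5.0, "V1": 10.0},
            )

    def test_extra_compartment_parameters_rejected(self):
        with pytest.raises(ValueError, match="unexpected"):
            PopPKModel(
                compound_name="x",
                n_compartments=1,
                typical_params={"CL": 5.0, "V1": 10.0, "Q2": 3.0, "V2": 8.0},
            )

    def test_unknown_site_rejected(self):
        with pytest.raises(ValueError):
            SitePenetration(
                compound_name="x", fu=0.5, tpr={"liver": TPREntry(value=0.5)}
            )

    def test_plasma_tpr_fixed_at_one(self):
        pen = SitePenetration(compound_name="x", fu=0.5)
        assert pen.tpr["plasma"].value == 1.0
        with pytest.raises(ValueError, match="definition"):
            SitePenetration(compound_name="x", fu=0.5, tpr={"plasma": TPREntry(value=0.8)})

    def test_tpr_bounds_ordering(self):
        with pytest.raises(ValueError):
            TPREntry(value=0.5, low=0.6, high=0.7)

    def test_iiv_references_declared_parameters(self):
        with pytest.raises(ValueError, match="undeclared"):
            PopPKModel(
                compound_name="x",
                n_compartments=1,
                typical_params={"CL": 5.0, "V1": 10.0},
                iiv=IIVSpec(parameters=["Q2"], matrix=[[0.1]]),
            )

    def test_bad_config_file_reports_source(self, tmp_path, synlib):
        doc = {
            "kind": "compound",
            "compound_name": "bad",
            "model": {"n_compartments": 2, "typical_params": {"CL": 1.0, "V1": 2.0}},
            "target": {
                "metric": "ft_above_mic",
                "tier_magnitudes": {"EUCAST": 10, "Severe": 20, "Aggressive": 30},
            },
        }
        (tmp_path / "bad.yaml").write_text(yaml.safe_dump(doc))
        with pytest.raises(LibraryError) as err:
            load_model_library(tmp_path)
        assert "bad.yaml" in str(err.value)


class TestSyntheticLibrary:
    def test_loads_and_fills_derived_entries(self, synlib):
        combo = synlib.combination("SYN")
        # BL->BLI extrapolation filled the missing peritoneal TPR
        entry = combo.bli.penetration.tpr["peritoneal"]
        assert entry.value == 0.8
        assert entry.provenance == "extrapolated"
        # the compound's own file remains untouched
        assert "peritoneal" not in synlib.compounds["synthebactam"].penetration.tpr
        # prostatitis regimen reuses cUTI
        assert combo.regimens["prostatitis"] == combo.regimens["cUTI"]
        # MIC grid propagated to both component targets
        assert combo.bl.target.mic_grid_mg_per_L == combo.mic_grid_mg_per_L
        assert combo.bli.target.mic_grid_mg_per_L == combo.mic_grid_mg_per_L

    def test_combination_without_cuti_has_no_prostatitis(self, synlib):
        assert "prostatitis" not in synlib.combination("SYN2").regimens

    def test_round_trip_bit_exact(self, synlib, tmp_path):
        write_library(synlib, tmp_path)
        relib = load_model_library(tmp_path)
        for key, entry in synlib.compounds.items():
            assert relib.compounds[key].model.model_dump() == entry.model.model_dump()
            assert (
                relib.compounds[key].penetration.model_dump()
                == entry.penetration.model_dump()
            )
        for name, combo in synlib.combinations.items():
            assert relib.combinations[name].model_dump() == combo.model_dump()


class TestTranscribedLibrary:
    def test_published_penetration_values(self, reallib):
        avi = reallib.compounds["avibactam"]
        assert avi.penetration.fu == 0.92
        assert avi.penetration.tpr["ELF"].value == 0.30
        assert avi.penetration.tpr["ELF"].provenance == "measured"

    def test_bli_inherits_bl_tpr(self, reallib):
        rel = reallib.combination("IMI-REL").bli
        entry = rel.penetration.tpr["peritoneal"]
        assert entry.value == 0.82  # imipenem's value
        assert entry.provenance == "extrapolated"
        vab = reallib.combination("MER-VAB").bli
        assert vab.penetration.tpr["peritoneal"].value == 0.92
        assert vab.penetration.tpr["prostate"].value == 0.15

    def test_unknown_prostate_penetration_raises(self, reallib):
        with pytest.raises(UnknownPenetrationError):
            reallib.compounds["ceftolozane"].penetration.resolve("prostate")

    def test_tazobactam_partner_specific_entries(self, reallib):
        cet = reallib.compounds["tazobactam_cet"]
        pip = reallib.compounds["tazobactam_pip"]
        assert cet.penetration.tpr["ELF"].value == 0.62
        assert pip.penetration.tpr["ELF"].value == 1.21
        assert cet.target.tier_magnitudes["EUCAST"] == 20.0
        assert pip.target.tier_magnitudes["EUCAST"] == 40.0

    def test_tazobactam_tpr_swap_option(self):
        lib = load_model_library(
            default_library_path(),
            swap_tpr_between=("tazobactam_cet", "tazobactam_pip"),
        )
        assert lib.compounds["tazobactam_cet"].penetration.tpr["ELF"].value == 1.21
        assert lib.compounds["tazobactam_pip"].penetration.tpr["peritoneal"].value == 0.95

    def test_five_combinations_present(self, reallib):
        assert set(reallib.combinations) == {
            "CAZ-AVI", "CET-TAZ", "IMI-REL", "MER-VAB", "PIP-TAZ",
        }
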