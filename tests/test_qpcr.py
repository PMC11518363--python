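"""Cq calling, calibration, spike-in QC and delta-Cq normalization."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mirsea as ms
from mirsea.synthetic_data import AmplificationCurve


class TestCallCqSdm:
    def test_noiseless_logistic_recovers_closed_form(self):
        # midpoint m=25, slope k=1 -> SDM at 25 - ln(2+sqrt(3)) = 23.683
        curve = ms.simulate_curve(
            25.0 - math.log(2 + math.sqrt(3)),
            ms.CurveParams(slope=1.0, noise_sd=0.0),
            np.random.default_rng(0),
        )
        assert ms.call_cq_sdm(curve) == pytest.approx(23.683, abs=0.05)

    def test_flat_blank_trace_is_undetermined(self):
        rng = np.random.default_rng(1)
        curve = AmplificationCurve("b", np.arange(1, 46), 0.5 + rng.normal(0, 0.1, 45))
        assert math.isnan(ms.call_cq_sdm(curve))

    def test_noiseless_flat_trace_is_undetermined(self):
        curve = AmplificationCurve("b", np.arange(1, 46), np.full(45, 0.5))
        assert math.isnan(ms.call_cq_sdm(curve))

    def test_translation_equivariance(self):
        params = ms.CurveParams(noise_sd=0.0)
        rng = np.random.default_rng(0)
        c1 = ms.simulate_curve(22.0, params, rng)
        c2 = ms.simulate_curve(24.0, params, rng)
        assert ms.call_cq_sdm(c2) - ms.call_cq_sdm(c1) == pytest.approx(2.0, abs=1e-6)

    def test_non_monotone_cycles_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            AmplificationCurve("x", np.array([1, 2, 2, 4] + list(range(5, 15))), np.zeros(14))

    def test_even_smoothing_window_rejected(self):
        curve = ms.simulate_curve(20.0, ms.CurveParams(), np.random.default_rng(0))
        with pytest.raises(ValueError, match="odd"):
            ms.call_cq_sdm(curve, smoothing_window=4)

    @pytest.mark.parametrize("k", [0.5, 1.0, 2.0])
    @pytest.mark.parametrize("true_cq", [15.0, 25.0, 33.0])
    def test_accuracy_across_slope_grid(self, k, true_cq):
        curve = ms.simulate_curve(
            true_cq, ms.CurveParams(slope=k, noise_sd=0.0), np.random.default_rng(0)
        )
        assert ms.call_cq_sdm(curve) == pytest.approx(true_cq, abs=0.05)


class TestInterplateCalibrate:
    def test_single_plate_unchanged(self, cq_records):
        single = cq_records[cq_records["plate_id"] == "p1"]
        out = ms.interplate_calibrate(single)
        pd.testing.assert_series_equal(out["cq"], single["cq"], check_names=False)

    def test_offset_plate_shifted_back(self, cq_records):
        out = ms.interplate_calibrate(cq_records)
        # calibrator means were 20.0 and 21.0 -> offsets -0.5/+0.5 vs global 20.5
        cal = out[out["well_class"] == "interplate_calibrator"]
        means = cal.groupby("plate_id")["cq"].mean()
        assert means["p1"] == pytest.approx(means["p2"])
        # a miRNA measured 1.0 apart purely from the plate offset converges
        mir = out[out["assay_name"] == "hsa-mir-1"].set_index("sample_id")["cq"]
        assert mir["s1"] == pytest.approx(mir["s2"])

    def test_idempotence(self, cq_records):
        once = ms.interplate_calibrate(cq_records)
        twice = ms.interplate_calibrate(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_plate_without_calibrators_fails_qc(self, cq_records):
        broken = cq_records.copy()
        broken.loc[
            (broken["plate_id"] == "p2") & (broken["well_class"] == "interplate_calibrator"),
            "cq",
        ] = math.nan
        with pytest.raises(ValueError, match="p2"):
            ms.interplate_calibrate(broken)


class TestSpikeInQC:
    @staticmethod
    def _records(values_by_sample):
        rows = []
        for sample, vals in values_by_sample.items():
            for i, v in enumerate(vals):
                rows.append((sample, "p1", f"sp{i}", "spike_in", v))
            rows.append((sample, "p1", "", "blank", math.nan))
        return pd.DataFrame(rows, columns=["sample_id", "plate_id", "assay_name", "well_class", "cq"])

    def test_identical_spikes_all_pass(self):
        rec = self._records({f"s{i}": [21.0, 21.5] for i in range(4)})
        report = ms.qc_spike_ins(rec, tolerance_sd=3.0)
        assert report["passed"].all()

    def test_large_shift_flagged(self):
        values = {f"s{i}": [21.0 + 0.01 * i, 21.5] for i in range(5)}
        values["bad"] = [31.0, 21.5]  # ~10 cycles off, hundreds of leave-one-out SDs
        report = ms.qc_spike_ins(self._records(values), tolerance_sd=3.0).set_index("sample_id")
        assert not report.loc["bad", "passed"]
        assert report.drop(index="bad")["passed"].all()

    def test_blank_records_ignored_and_empty_report_without_spikes(self):
        rec = self._records({"s1": [21.0]})
        only_blanks = rec[rec["well_class"] == "blank"]
        assert ms.qc_spike_ins(only_blanks).empty


class TestNormalizeDeltaCq:
    def test_two_to_the_minus_delta(self, cq_records):
        matrix = ms.normalize_delta_cq(
            cq_records, {"s1": "A", "s2": "B"}, condition_order=("A", "B")
        )
        # sample s1: reference mean 19.0; hsa-mir-1 Cq 25 -> dCq 6 -> 2^-6
        assert matrix.values.loc["hsa-mir-1", "s1"] == pytest.approx(2.0**-6)
        # Cq equal to the reference mean -> expression exactly 1
        rec = cq_records.copy()
        rec.loc[rec["assay_name"] == "hsa-mir-1", "cq"] = rec.groupby("sample_id")[
            "cq"
        ].transform("first")
        rec.loc[(rec["assay_name"] == "hsa-mir-1") & (rec["sample_id"] == "s1"), "cq"] = 19.0
        m2 = ms.normalize_delta_cq(rec, {"s1": "A", "s2": "B"}, condition_order=("A", "B"))
        assert m2.values.loc["hsa-mir-1", "s1"] == pytest.approx(1.0)

    def test_undetermined_propagates_to_missing_not_zero(self, cq_records):
        rec = cq_records.copy()
        rec.loc[(rec["assay_name"] == "hsa-mir-2") & (rec["sample_id"] == "s1"), "cq"] = math.nan
        matrix = ms.normalize_delta_cq(
            rec, {"s1": "A", "s2": "B"}, condition_order=("A", "B"), max_undetermined_frac=None
        )
        assert math.isnan(matrix.values.loc["hsa-mir-2", "s1"])
        assert matrix.values.loc["hsa-mir-2", "s2"] > 0

    def test_sample_without_reference_fails_qc(self, cq_records):
        rec = cq_records.copy()
        rec.loc[(rec["well_class"] == "reference_gene") & (rec["sample_id"] == "s1"), "cq"] = math.nan
        with pytest.raises(ValueError, match="s1"):
            ms.normalize_delta_cq(rec, {"s1": "A", "s2": "B"})

    def test_mostly_undetermined_mirnas_dropped(self, cq_records):
        rec = cq_records.copy()
        rec.loc[rec["assay_name"] == "hsa-mir-2", "cq"] = math.nan
        matrix = ms.normalize_delta_cq(
            rec, {"s1": "A", "s2": "B"}, condition_order=("A", "B"), max_undetermined_frac=0.5
        )
        assert "hsa-mir-2" not in matrix.values.index
        assert "hsa-mir-1" in matrix.values.index

    @given(shift=st.floats(min_value=-5.0, max_value=5.0, allow_nan=False))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_to_constant_cq_shift_within_sample(self, shift):
        """Reference subtraction removes any per-sample additive Cq offset."""
        rows = []
        for sample in ["s1", "s2"]:
            delta = shift if sample == "s1" else 0.0
            rows.append((sample, "p", "ref1", "reference_gene", 19.0 + delta))
            rows.append((sample, "p", "mirA", "mirna_assay", 24.0 + delta))
            rows.append((sample, "p", "mirB", "mirna_assay", 27.0 + delta))
        rec = pd.DataFrame(rows, columns=["sample_id", "plate_id", "assay_name", "well_class", "cq"])
        matrix = ms.normalize_delta_cq(rec, {"s1": "A", "s2": "B"}, condition_order=("A", "B"))
        np.testing.assert_allclose(
            matrix.values["s1"].to_numpy(), matrix.values["s2"].to_numpy(), rtol=1e-9
        )
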