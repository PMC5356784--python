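"""CNV computation, the dual-threshold call, and the mixture-model inverse."""

import numpy as np
import pandas as pd
import pytest

from ddcnv import (
    DuplicationCaller,
    SaturationError,
    Thresholds,
    UndefinedRatioError,
    WellCounts,
    call_samples,
    classify,
    compute_cnv,
    estimate_concentration,
    quantify_wells,
    ratio_for_cnv,
    tumor_fraction,
)
from ddcnv.calling import STATUS_DUPLICATED, STATUS_INCONCLUSIVE, STATUS_NON_DUPLICATED
from ddcnv.simulate import SimSampleConfig, simulate_sample

from conftest import concentration_estimate


class TestComputeCnv:
    def test_equal_channels_are_diploid(self):
        t = concentration_estimate(50.0)
        r = concentration_estimate(50.0, channel="HEX")
        cnv = compute_cnv(t, r)
        assert cnv.cnv == pytest.approx(2.0, rel=1e-6)
        assert cnv.cnv_min < 2.0 < cnv.cnv_max

    @pytest.mark.parametrize("ratio,expected", [(1.125, 2.25), (1.5, 3.0)])
    def test_cnv_is_twice_the_ratio(self, ratio, expected):
        # large wells so the discretized counts reproduce the ratio closely
        t = concentration_estimate(40.0 * ratio, n_total=4_000_000)
        r = concentration_estimate(40.0, n_total=4_000_000, channel="HEX")
        assert compute_cnv(t, r).cnv == pytest.approx(expected, rel=1e-3)

    def test_ratio_for_cnv_inverts_definition(self):
        assert ratio_for_cnv(2.25) == pytest.approx(1.125)
        assert ratio_for_cnv(2.0) == pytest.approx(1.0)

    def test_bound_ratio_is_conservative(self):
        t = concentration_estimate(60.0)
        r = concentration_estimate(40.0, channel="HEX")
        delta = compute_cnv(t, r, ci_method="log_delta")
        ratio = compute_cnv(t, r, ci_method="bound_ratio")
        assert ratio.cnv_min < delta.cnv_min < delta.cnv_max < ratio.cnv_max

    def test_degenerate_inputs_raise(self):
        ok = concentration_estimate(50.0)
        zero = estimate_concentration(WellCounts("w", "s", "HEX", 15000, 0))
        saturated = estimate_concentration(WellCounts("w", "s", "HEX", 1000, 1000))
        with pytest.raises(UndefinedRatioError):
            compute_cnv(ok, zero)
        with pytest.raises(SaturationError):
            compute_cnv(ok, saturated)


class TestTumorFraction:
    @pytest.mark.parametrize(
        "cnv,expected", [(2.25, 0.25), (2.0, 0.0), (3.0, 1.0), (1.5, 0.0), (4.0, 1.0)]
    )
    def test_mixture_inverse_with_clamping(self, cnv, expected):
        est = tumor_fraction(cnv)
        assert est.fraction == pytest.approx(expected)
        assert est.model == "monoallelic_duplication"


def _call(target_conc, ref_conc, n_total=15000):
    t = concentration_estimate(target_conc, n_total=n_total)
    r = concentration_estimate(ref_conc, n_total=n_total, channel="HEX")
    cnv = compute_cnv(t, r)
    return cnv, classify(cnv, t, r, sample_id="s")


class TestClassify:
    def test_clear_duplication(self):
        cnv, result = _call(72.0, 48.0)  # cnv ~ 3 at high concentration
        assert cnv.cnv_min > 2.0
        assert result.status == STATUS_DUPLICATED
        assert not result.flags

    def test_normal_sample(self):
        _, result = _call(50.0, 50.0)
        assert result.status == STATUS_NON_DUPLICATED

    def test_low_target_concentration_is_inconclusive(self):
        _, result = _call(3.0, 50.0)
        assert result.status == STATUS_INCONCLUSIVE
        assert "low_target_conc" in result.flags

    def test_low_reference_concentration_is_inconclusive(self):
        _, result = _call(50.0, 3.0)
        assert result.status == STATUS_INCONCLUSIVE
        assert "low_reference_conc" in result.flags

    def test_split_cutoffs_are_borderline_never_negative(self):
        """CNV above 2.25 but CNVmin below 2 must not be called either way."""
        cnv, result = _call(58.0, 50.0, n_total=6000)  # cnv ~ 2.32, wide interval
        assert cnv.cnv > 2.25 and cnv.cnv_min <= 2.0
        assert result.status == STATUS_INCONCLUSIVE
        assert "borderline" in result.flags

    def test_possible_deletion_flag_needs_adequate_dna(self):
        cnv, result = _call(40.0, 50.0, n_total=60000)  # cnv ~ 1.6, tight
        assert cnv.cnv_max < 2.0
        assert result.status == STATUS_NON_DUPLICATED
        assert "possible_deletion" in result.flags
        # same ratio at sub-threshold DNA: inconclusive, no deletion claim
        _, low = _call(3.2, 4.0, n_total=60000)
        assert low.status == STATUS_INCONCLUSIVE
        assert "possible_deletion" not in low.flags

    def test_artefact_flag_below_1_5(self):
        cnv, result = _call(30.0, 50.0, n_total=60000)  # cnv ~ 1.2
        assert cnv.cnv_max < 1.5
        assert "low_cnv_artefact" in result.flags
        assert result.status == STATUS_NON_DUPLICATED

    def test_saturated_channel_flagged(self):
        t = estimate_concentration(WellCounts("w", "s", "FAM", 1000, 1000))
        r = concentration_estimate(50.0, channel="HEX")
        result = classify(None, t, r, sample_id="s")
        assert result.status == STATUS_INCONCLUSIVE
        assert "saturated_well" in result.flags

    def test_strict_inequalities_at_cutoff(self):
        """A sample sitting exactly on CNV = 2.25 is not duplicated (cutoffs are strict)."""
        from ddcnv import CnvEstimate

        t = concentration_estimate(45.0)
        r = concentration_estimate(40.0, channel="HEX")
        exactly_at_cutoff = CnvEstimate(cnv=2.25, cnv_min=2.2, cnv_max=2.3, ratio=1.125)
        result = classify(exactly_at_cutoff, t, r)
        assert result.status == STATUS_INCONCLUSIVE
        assert "borderline" in result.flags  # cnv_min > 2 passed, cnv > 2.25 did not


class TestCallRates:
    def test_sensitivity_at_half_clonal_duplication(self, rng):
        """f = 0.5 at 50 copies/ul and 15,000 droplets is called duplicated >95%."""
        n, reps = 15000, 300
        p_t = -np.expm1(-0.0625)  # target 62.5 copies/ul
        p_r = -np.expm1(-0.05)
        hits = 0
        for _ in range(reps):
            t = estimate_concentration(WellCounts("w", "s", "FAM", n, int(rng.binomial(n, p_t))))
            r = estimate_concentration(WellCounts("w", "s", "HEX", n, int(rng.binomial(n, p_r))))
            result = classify(compute_cnv(t, r), t, r)
            hits += result.status == STATUS_DUPLICATED
        assert hits / reps > 0.95

    def test_non_duplicated_band(self, rng):
        """Null samples at adequate concentration concentrate in CNV 1.75-2.25."""
        n, reps = 15000, 500
        p = -np.expm1(-0.05)
        cnvs = []
        for _ in range(reps):
            t = estimate_concentration(WellCounts("w", "s", "FAM", n, int(rng.binomial(n, p))))
            r = estimate_concentration(WellCounts("w", "s", "HEX", n, int(rng.binomial(n, p))))
            cnvs.append(compute_cnv(t, r).cnv)
        cnvs = np.array(cnvs)
        assert np.mean((cnvs > 1.75) & (cnvs < 2.25)) > 0.94


class TestCallSamples:
    def test_end_to_end_statuses(self, wells_two_samples):
        calls = call_samples(quantify_wells(wells_two_samples))
        by_id = calls.set_index("sample_id")
        assert by_id.loc["S_dup", "status"] == STATUS_DUPLICATED
        assert by_id.loc["S_dup", "tumor_fraction"] == pytest.approx(1.0, abs=0.15)
        assert by_id.loc["S_norm", "status"] == STATUS_NON_DUPLICATED

    def test_missing_channel_raises(self, wells_two_samples):
        from ddcnv import SchemaError

        broken = wells_two_samples[
            ~((wells_two_samples.sample_id == "S_dup") & (wells_two_samples.channel == "HEX"))
        ]
        with pytest.raises(SchemaError, match="S_dup"):
            call_samples(quantify_wells(broken))


class TestDuplicationCaller:
    def test_predict_matches_call_table(self, wells_two_samples):
        caller = DuplicationCaller().fit(wells_two_samples)
        table = caller.call_table(wells_two_samples)
        assert list(caller.predict(wells_two_samples)) == list(table["status"])
        assert set(caller.classes_) == {
            STATUS_DUPLICATED, STATUS_INCONCLUSIVE, STATUS_NON_DUPLICATED,
        }

    def test_threshold_params_change_calls(self, wells_two_samples):
        lenient = DuplicationCaller(cnv_cutoff=1.2, cnv_min_cutoff=1.1).fit(wells_two_samples)
        statuses = lenient.call_table(wells_two_samples).set_index("sample_id")["status"]
        assert statuses["S_norm"] == STATUS_DUPLICATED  # cnv ~ 2 clears a 1.2 cutoff

    def test_sklearn_clone_roundtrip(self):
        from sklearn.base import clone

        caller = DuplicationCaller(cnv_cutoff=2.5, ci_method="bound_ratio")
        assert clone(caller).get_params() == caller.get_params()

    def test_requires_fit(self, wells_two_samples):
        with pytest.raises(AttributeError):
            DuplicationCaller().predict(wells_two_samples)
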