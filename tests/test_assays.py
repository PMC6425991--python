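import numpy as np
import pytest

from aplkit import (
    ChromiumInput,
    DegenerateFitError,
    FourPLParams,
    KillingInput,
    TitrationSeries,
    chromium_specific_lysis,
    compare_sensitivity,
    effectors_for_dose,
    fit_dose_response,
    flow_killing_percent,
    four_pl,
    simulate_titration,
    stabilization_index,
)

CONCS = tuple(np.logspace(-12, -5, 8))


def clean_series(bottom=0.0, top=10.0, log10_ec50=-9.0, hill=1.0, concs=CONCS):
    readouts = four_pl(np.log10(np.asarray(concs)), bottom, top, log10_ec50, hill)
    return TitrationSeries(
        peptide="x", concentrations=concs, readouts=tuple(readouts)
    )


class TestDoseResponseFit:
    def test_recovers_noise_free_parameters(self):
        fit = fit_dose_response(clean_series())
        assert fit.converged
        assert fit.log10_ec50 == pytest.approx(-9.0, abs=1e-6)
        assert fit.bottom == pytest.approx(0.0, abs=1e-6)
        assert fit.top == pytest.approx(10.0, abs=1e-6)

    def test_flat_readouts_are_degenerate(self):
        series = TitrationSeries(
            peptide="x", concentrations=CONCS, readouts=(3.0,) * len(CONCS)
        )
        with pytest.raises(DegenerateFitError):
            fit_dose_response(series)

    def test_too_few_concentrations(self):
        series = TitrationSeries(
            peptide="x",
            concentrations=(1e-9, 1e-8, 1e-7),
            readouts=(0.0, 5.0, 10.0),
        )
        with pytest.raises(DegenerateFitError):
            fit_dose_response(series)

    def test_ten_fold_concentration_shift_moves_ec50_ten_fold(self):
        base = clean_series()
        fit_lo = fit_dose_response(base)
        shifted = TitrationSeries(
            peptide="x",
            concentrations=tuple(10.0 * c for c in base.concentrations),
            readouts=base.readouts,
        )
        fit_hi = fit_dose_response(shifted)
        assert fit_hi.log10_ec50 - fit_lo.log10_ec50 == pytest.approx(1.0, abs=1e-6)

    def test_background_is_subtracted_before_fit(self):
        base = clean_series()
        raised = TitrationSeries(
            peptide="x",
            concentrations=base.concentrations,
            readouts=tuple(r + 2.5 for r in base.readouts),
            background=2.5,
        )
        fit = fit_dose_response(raised)
        assert fit.log10_ec50 == pytest.approx(-9.0, abs=1e-6)


class TestCompareSensitivity:
    def test_identity_and_hand_value_and_reciprocity(self):
        fit_a = fit_dose_response(clean_series(log10_ec50=-7.0))
        fit_b = fit_dose_response(clean_series(log10_ec50=-9.0))
        assert compare_sensitivity(fit_a, fit_a) == pytest.approx(1.0)
        assert compare_sensitivity(fit_a, fit_b) == pytest.approx(100.0, rel=1e-6)
        assert compare_sensitivity(fit_a, fit_b) * compare_sensitivity(
            fit_b, fit_a
        ) == pytest.approx(1.0, rel=1e-9)


class TestFlowKilling:
    def test_worked_example(self):
        assert flow_killing_percent(KillingInput(200, 1000, 500, 1000)) == 60.0

    def test_equal_ratios_mean_no_killing(self):
        assert flow_killing_percent(KillingInput(500, 1000, 500, 1000)) == 0.0

    def test_zero_surviving_targets_is_complete_killing(self):
        assert flow_killing_percent(KillingInput(0, 1000, 500, 1000)) == 100.0

    def test_invariant_to_common_event_scaling(self):
        base = flow_killing_percent(KillingInput(123, 456, 789, 1011))
        scaled = flow_killing_percent(KillingInput(123 * 7, 456 * 7, 789 * 7, 1011 * 7))
        assert base == pytest.approx(scaled, abs=1e-9)

    def test_outgrowth_is_flagged_not_clipped(self):
        with pytest.warns(UserWarning, match="outgrowth"):
            pct = flow_killing_percent(KillingInput(900, 1000, 500, 1000))
        assert pct < 0

    @pytest.mark.parametrize(
        "counts",
        [(200, 0, 500, 1000), (200, 1000, 500, 0), (200, 1000, 0, 1000)],
    )
    def test_zero_reference_or_control_targets_rejected(self, counts):
        with pytest.raises(ValueError):
            KillingInput(*counts)


class TestChromiumLysis:
    def test_worked_examples(self):
        assert chromium_specific_lysis(ChromiumInput(500, 100, 900)) == 50.0
        assert chromium_specific_lysis(ChromiumInput(100, 100, 900)) == 0.0
        assert chromium_specific_lysis(ChromiumInput(900, 100, 900)) == 100.0

    def test_maximum_must_exceed_spontaneous(self):
        with pytest.raises(ValueError):
            ChromiumInput(500, 900, 900)

    def test_below_spontaneous_is_flagged(self):
        with pytest.warns(UserWarning, match="below zero"):
            assert chromium_specific_lysis(ChromiumInput(50, 100, 900)) < 0

    def test_agrees_with_flow_killing_on_shared_survival_fraction(self):
        # both assays estimate the same surviving-target fraction
        rng = np.random.default_rng(21)
        n = 10_000
        for kill in (0.2, 0.5, 0.8):
            survivors = int(rng.binomial(n, 1.0 - kill))
            flow = flow_killing_percent(
                KillingInput(survivors, 50_000, n, 50_000)
            )
            spont, maxi = 100.0, 1100.0
            experimental = spont + (maxi - spont) * kill
            chromium = chromium_specific_lysis(
                ChromiumInput(experimental, spont, maxi)
            )
            assert abs(flow - chromium) < 2.0


class TestEffectorDosing:
    def test_undiluted_line(self):
        assert effectors_for_dose(1.0, 300) == 200

    def test_low_purity_line_needs_many_cells(self):
        assert effectors_for_dose(0.008, 3000) == 250_000

    def test_patient_line_ratio(self):
        # tetramer+ fractions 0.8% vs 0.06% at the same per-cell dose
        high = effectors_for_dose(0.008, 3000)
        low = effectors_for_dose(0.0006, 3000)
        assert low / high == pytest.approx(0.008 / 0.0006, rel=1e-6)

    def test_zero_fraction_rejected(self):
        with pytest.raises(ValueError):
            effectors_for_dose(0.0, 300)


class TestStabilizationIndex:
    def test_values_and_ordering(self):
        assert stabilization_index(1000.0, 1000.0) == 1.0
        assert stabilization_index(3000.0, 1000.0) == 3.0
        strong = [stabilization_index(m, 800.0) for m in (2000, 3000, 4000)]
        weak = [stabilization_index(m, 800.0) for m in (1000, 1500, 2000)]
        assert all(s > w for s, w in zip(strong, weak))

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError):
            stabilization_index(1000.0, 0.0)


class TestEc50Recovery:
    def test_median_log10_error_under_ten_percent_cv(self):
        """100 noisy 8-point titrations recover EC50 within 0.15 decades (median)."""
        params = FourPLParams(bottom=0.0, top=10.0, log10_ec50=-9.0, hill=1.0)
        errors = []
        for seed in range(100):
            series = simulate_titration(params, CONCS, cv=0.1, seed=seed)
            fit = fit_dose_response(series)
            errors.append(abs(fit.log10_ec50 - params.log10_ec50))
        assert float(np.median(errors)) < 0.15
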