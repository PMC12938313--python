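"""Viability normalization and median-effect / 4PL fitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gbmsynergy.dose_response import (
    DoseResponseError,
    EffectVector,
    dose_for_effect,
    effect_at_dose,
    fit_four_pl,
    fit_median_effect,
    normalize_viability,
)

from .conftest import median_effect_vector


class TestNormalizeViability:
    def test_raw_equal_to_control_gives_zero_effect(self):
        rows = [("M", "c", 0.0, 100.0, 1)] + [
            ("M", "a", d, 100.0, 1) for d in (0.1, 1.0, 10.0)
        ]
        df = pd.DataFrame(rows, columns=["model_id", "agent", "dose_uM",
                                         "luminescence", "replicate"])
        eff = normalize_viability(df, "M", "a")
        assert np.allclose(eff.fa, 0.0)

    def test_zero_luminescence_is_complete_kill(self):
        rows = [("M", "c", 0.0, 100.0, 1)] + [
            ("M", "a", d, lum, 1) for d, lum in [(0.1, 80), (1.0, 40), (10.0, 0.0)]
        ]
        df = pd.DataFrame(rows, columns=["model_id", "agent", "dose_uM",
                                         "luminescence", "replicate"])
        eff = normalize_viability(df, "M", "a")
        assert eff.fa[-1] == 1.0

    def test_replicates_averaged_before_normalization(self, plate_records):
        # four replicates {90,110,95,105} against control mean 200 -> fa 0.5
        rows = [("M", "c", 0.0, 200.0, 1)]
        rows += [("M", "a", 1.0, lum, r) for r, lum in
                 enumerate([90.0, 110.0, 95.0, 105.0], start=1)]
        rows += [("M", "a", d, 10.0, 1) for d in (10.0, 100.0)]
        df = pd.DataFrame(rows, columns=["model_id", "agent", "dose_uM",
                                         "luminescence", "replicate"])
        eff = normalize_viability(df, "M", "a")
        assert eff.fa[0] == pytest.approx(0.5, abs=1e-12)

    def test_invariant_to_replicate_order(self, plate_records):
        shuffled = plate_records.sample(frac=1.0, random_state=1)
        a = normalize_viability(plate_records, "M1", "drugA")
        b = normalize_viability(shuffled, "M1", "drugA")
        np.testing.assert_array_equal(a.fa, b.fa)

    def test_missing_control_raises(self, plate_records):
        no_ctrl = plate_records[plate_records["dose_uM"] > 0]
        with pytest.raises(DoseResponseError, match="no vehicle control") as exc:
            normalize_viability(no_ctrl, "M1", "drugA")
        assert exc.value.code == "no-control"

    def test_too_few_doses_raises(self, plate_records):
        two = plate_records[plate_records["dose_uM"].isin([0.0, 0.1, 1.0])]
        with pytest.raises(DoseResponseError) as exc:
            normalize_viability(two, "M1", "drugA")
        assert exc.value.code == "insufficient-doses"

    def test_stimulation_clipped_with_counter(self, plate_records):
        df = plate_records.copy()
        df.loc[(df["dose_uM"] == 0.1), "luminescence"] = 260.0
        eff = normalize_viability(df, "M1", "drugA")
        assert eff.fa[0] == 0.0
        assert eff.n_clipped_stimulation == 1

    def test_fa_fu_complementarity(self, plate_records):
        eff = normalize_viability(plate_records, "M1", "drugA")
        np.testing.assert_allclose(eff.fa + eff.fu, 1.0)


class TestFitMedianEffect:
    def test_unit_slope_line(self):
        eff = EffectVector(doses=[0.1, 1.0, 10.0],
                           fa=[1 / 11, 0.5, 10 / 11], n_reps=[1, 1, 1])
        fit = fit_median_effect(eff)
        assert fit.m == pytest.approx(1.0, abs=1e-10)
        assert fit.Dm == pytest.approx(1.0, rel=1e-10)
        assert fit.r_linfit == pytest.approx(1.0)

    def test_noiseless_round_trip(self):
        doses = 0.5 * 3.0 ** np.arange(-3, 4)
        fit = fit_median_effect(median_effect_vector(2.0, 0.5, doses))
        assert fit.m == pytest.approx(2.0, rel=1e-6)
        assert fit.Dm == pytest.approx(0.5, rel=1e-6)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        m=st.floats(0.4, 3.0),
        log_dm=st.floats(np.log(0.05), np.log(20.0)),
    )
    def test_noiseless_recovery_is_exact_for_any_parameters(self, m, log_dm):
        Dm = float(np.exp(log_dm))
        doses = Dm * 3.0 ** np.arange(-4, 5)
        fit = fit_median_effect(median_effect_vector(m, Dm, doses))
        assert fit.m == pytest.approx(m, rel=1e-9)
        assert fit.Dm == pytest.approx(Dm, rel=1e-9)

    def test_fit_reproduces_half_effect_at_dm(self):
        doses = np.geomspace(0.01, 10, 9)
        fit = fit_median_effect(median_effect_vector(1.5, 0.8, doses))
        assert effect_at_dose(fit, fit.Dm) == pytest.approx(0.5, abs=1e-9)

    def test_inverted_curve_flagged_non_monotone(self):
        eff = EffectVector(doses=[0.1, 1.0, 10.0],
                           fa=[0.9, 0.5, 0.2], n_reps=[1, 1, 1])
        with pytest.warns(UserWarning, match="non-monotone|m="):
            fit = fit_median_effect(eff)
        assert "non-monotone-fit" in fit.flags

    def test_all_boundary_points_raise(self):
        eff = EffectVector(doses=[0.1, 1.0, 10.0],
                           fa=[0.0, 0.0, 1.0], n_reps=[1, 1, 1])
        with pytest.raises(DoseResponseError) as exc:
            fit_median_effect(eff)
        assert exc.value.code == "insufficient-effect-range"


class TestDoseForEffect:
    def test_median_effect_definition(self):
        fit = fit_median_effect(median_effect_vector(1.3, 2.0, np.geomspace(0.1, 40, 8)))
        assert dose_for_effect(fit, 0.5) == pytest.approx(fit.Dm, rel=1e-12)

    @pytest.mark.parametrize(
        "m,Dm,fa,expected",
        [(1.0, 1.0, 0.9, 9.0), (2.0, 0.5, 0.8, 1.0)],
    )
    def test_closed_form(self, m, Dm, fa, expected):
        fit = fit_median_effect(median_effect_vector(m, Dm, Dm * 3.0 ** np.arange(-3, 4)))
        assert dose_for_effect(fit, fa) == pytest.approx(expected, rel=1e-9)

    def test_exact_inverse_of_effect_curve(self):
        fit = fit_median_effect(median_effect_vector(1.7, 0.3, np.geomspace(0.01, 10, 10)))
        for x in np.linspace(0.01, 0.99, 25):
            assert effect_at_dose(fit, dose_for_effect(fit, x)) == pytest.approx(
                x, abs=1e-10
            )

    def test_monotone_in_effect(self):
        fit = fit_median_effect(median_effect_vector(2.0, 1.0, np.geomspace(0.05, 20, 8)))
        doses = [dose_for_effect(fit, x) for x in np.linspace(0.05, 0.95, 19)]
        assert np.all(np.diff(doses) > 0)

    def test_boundary_effect_rejected(self):
        fit = fit_median_effect(median_effect_vector(1.0, 1.0, [0.1, 1.0, 10.0]))
        for bad in (0.0, 1.0):
            with pytest.raises(DoseResponseError):
                dose_for_effect(fit, bad)


class TestFourPL:
    def test_exact_logistic_recovery(self):
        doses = np.geomspace(0.01, 100, 10)
        fa = doses / (doses + 1.0)  # bottom 0, top 1, hill 1, ec50 1
        fit = fit_four_pl(EffectVector(doses=doses, fa=fa, n_reps=np.ones(10)))
        assert fit.bottom == pytest.approx(0.0, abs=1e-6)
        assert fit.top == pytest.approx(1.0, abs=1e-6)
        assert fit.hill == pytest.approx(1.0, rel=1e-6)
        assert fit.ec50 == pytest.approx(1.0, rel=1e-6)

    def test_noisy_ec50_within_tolerance(self):
        rng = np.random.default_rng(42)
        doses = np.geomspace(0.01, 100, 12)
        v = 1.0 / (1.0 + doses / 1.0) * rng.lognormal(0, 0.05, 12)
        fa = np.clip(1 - v, 0, 1)
        fit = fit_four_pl(EffectVector(doses=doses, fa=fa, n_reps=np.ones(12)))
        assert fit.ec50 == pytest.approx(1.0, rel=0.15)

    def test_rising_viability_fails(self):
        doses = np.geomspace(0.01, 100, 8)
        fa = 1.0 - doses / (doses + 1.0)  # viability increases with dose
        with pytest.raises(DoseResponseError) as exc:
            fit_four_pl(EffectVector(doses=doses, fa=fa, n_reps=np.ones(8)))
        assert exc.value.code == "fit-failed"

    def test_dm_and_ec50_agree_on_logistic_data(self):
        # with bottom 0 / top 1 the 4PL and median-effect curves coincide
        doses = np.geomspace(0.05, 50, 10)
        eff = median_effect_vector(1.0, 2.0, doses)
        me = fit_median_effect(eff)
        pl = fit_four_pl(eff)
        assert abs(pl.ec50 - me.Dm) / me.Dm < 0.10
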