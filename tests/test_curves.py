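import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import leedna as L
from leedna import (EffectiveYieldSet, FluenceResponseCurve, Treatment,
                    UncertainValue, curve_to_yields, effective_yield,
                    enzyme_reveal, fit_zero_fluence_slope, pool_yield_sets,
                    read_curve, write_curve)
from leedna.errors import UsageError

from conftest import linear_curve


def survival_curve(sigma, film, fmax, n=40):
    """Noiseless supercoiled-loss curve from the forward film model."""
    fluence = np.linspace(0.0, fmax, n)
    sc = np.array([L.survival_fraction(phi / film.J, sigma, film) for phi in fluence])
    bands = {"supercoiled": sc, "circular": film.P0 - sc,
             "linear": np.zeros(n), "crosslink": np.zeros(n)}
    return FluenceResponseCurve(energy=10.0, thickness=film.h,
                                treatment=Treatment.NONE, fluence=fluence,
                                bands=bands, J=film.J)


class TestCurveValidation:
    def test_fluence_must_start_at_zero(self):
        with pytest.raises(UsageError, match="start at 0"):
            FluenceResponseCurve(10, 20, "none", [1e12, 2e12],
                                 {b: [50, 50] for b in L.curves.BANDS})

    def test_band_sum_guard(self):
        bands = {"supercoiled": [90, 90], "circular": [20, 20],
                 "linear": [0, 0], "crosslink": [0, 0]}
        with pytest.raises(UsageError, match="sum"):
            FluenceResponseCurve(10, 20, "none", [0, 1e12], bands)


class TestCurveIO:
    def test_round_trip_is_lossless(self, tmp_path):
        curve = linear_curve({"circular": 1.234567890123e-13}, fmax=9.87654e12,
                             J=1.23e11, replicate="gel-7")
        path = tmp_path / "curve.tsv"
        write_curve(curve, path)
        back = read_curve(path)
        assert back.energy == curve.energy
        assert back.treatment is Treatment.NONE
        assert back.replicate == "gel-7"
        np.testing.assert_allclose(back.fluence, curve.fluence, rtol=5e-12)
        for b in L.curves.BANDS:
            np.testing.assert_allclose(back.bands[b], curve.bands[b],
                                       rtol=1e-11, atol=1e-14)

    def test_missing_metadata_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("fluence\tpct_supercoiled\tpct_circular\tpct_linear\tpct_crosslink\n"
                        "0\t100\t0\t0\t0\n")
        with pytest.raises(UsageError, match="metadata"):
            read_curve(path)


class TestZeroFluenceSlope:
    def test_exactly_linear_band_recovered(self):
        curve = linear_curve({"circular": 2e-14})
        est = fit_zero_fluence_slope(curve, "circular")
        assert est.slope == pytest.approx(2e-14, rel=1e-10, abs=0)
        assert est.fit_quality == pytest.approx(1.0)

    def test_two_point_curve_rejected(self):
        fluence = [0.0, 1e12]
        bands = {b: [0.0, 0.0] for b in ("circular", "linear", "crosslink")}
        bands["supercoiled"] = [100.0, 99.0]
        curve = FluenceResponseCurve(10, 20, "none", fluence, bands)
        with pytest.raises(UsageError, match=">= 3"):
            fit_zero_fluence_slope(curve, "supercoiled")

    def test_all_zero_band_gives_zero_slope(self):
        curve = linear_curve({"circular": 1e-14})
        est = fit_zero_fluence_slope(curve, "crosslink")
        assert est.slope == 0.0 and est.stderr == 0.0

    def test_forward_model_slope_matches_initial_slope(self):
        """Fitted |slope| reproduces P'(0)/J when the window stays below 5% loss.

        Uses the no-charging idealization so the fluence axis maps
        one-to-one onto exposure time and only depth attenuation curves
        the response.
        """
        film = L.FilmParameters(h=20.0, lambda_att=12.0, tau=None, J=1e11, P0=100.0)
        sigma = 5e-14
        # fluence span chosen so total loss stays under 5% of P0
        fmax = 0.05 / (sigma * film.f)
        curve = survival_curve(sigma, film, fmax)
        est = fit_zero_fluence_slope(curve, "supercoiled", max_loss_fraction=0.05)
        expected = L.initial_slope(sigma, film) / film.J  # fluence-domain
        assert est.slope == pytest.approx(expected, rel=0.01, abs=0)

    def test_window_shrinks_error_on_curved_response(self, film):
        """Y_eff converges to σ·f as the window tightens on a noiseless curve."""
        sigma = 5e-14
        curve = survival_curve(sigma, film, fmax=0.5 / (sigma * film.f))
        target = sigma * film.f
        errors = []
        for window in (30, 12, 4):
            est = fit_zero_fluence_slope(curve, "supercoiled", window=window)
            y = effective_yield(est, curve.P0)
            errors.append(abs(y.value - target) / target)
        assert errors[0] > errors[1] > errors[2]

    def test_fluence_axis_rescaling_inverts_slope(self):
        """Relabeling fluence units scales the slope inversely; Y_eff bookkeeping follows."""
        curve = linear_curve({"circular": 2e-14})
        scaled = FluenceResponseCurve(
            curve.energy, curve.thickness, curve.treatment,
            curve.fluence * 10.0, curve.bands, curve.replicate)
        est, est10 = (fit_zero_fluence_slope(c, "circular") for c in (curve, scaled))
        assert est10.slope == pytest.approx(est.slope / 10.0, rel=1e-9, abs=0)


class TestEffectiveYield:
    def test_unit_arithmetic(self):
        est = L.SlopeEstimate(slope=-0.5e-13, stderr=0.0, window=3,
                              fit_quality=1.0, channel="LS")
        y = effective_yield(est, 100.0)
        assert y.value == pytest.approx(5e-16, rel=1e-12, abs=0)
        assert y.units == "cm^2"

    def test_zero_slope_preserves_stderr(self):
        est = L.SlopeEstimate(slope=0.0, stderr=2e-15, window=4,
                              fit_quality=0.0, channel="CL")
        y = effective_yield(est, 50.0)
        assert y.value == 0.0
        assert y.sd == pytest.approx(4e-17, rel=1e-12, abs=0)

    def test_non_positive_p0_rejected(self):
        est = L.SlopeEstimate(slope=1.0, stderr=0.0, window=3,
                              fit_quality=1.0, channel="SSB")
        with pytest.raises(UsageError):
            effective_yield(est, 0.0)


def yield_set(energy=10.0, **channels):
    return EffectiveYieldSet(energy=energy, yields={
        k: v if isinstance(v, UncertainValue) else UncertainValue(*v, "cm^2")
        for k, v in channels.items()})


class TestEnzymeReveal:
    def test_identical_sets_reveal_nothing(self):
        s = yield_set(SSB=(1e-14, 1e-15), DSB=(2e-15, 5e-16), CL=(1e-15, 2e-16))
        revealed = enzyme_reveal(s, s)
        assert all(v.value == 0.0 for v in revealed.yields.values())

    def test_difference_with_quadrature_sd(self):
        treated = yield_set(SSB=(10.0, 1.0), DSB=(0.0, 0.0), CL=(0.0, 0.0))
        untreated = yield_set(SSB=(6.0, 1.0), DSB=(0.0, 0.0), CL=(0.0, 0.0))
        revealed = enzyme_reveal(treated, untreated)
        assert revealed["isolated_BD"].value == pytest.approx(4.0)
        assert revealed["isolated_BD"].sd == pytest.approx(math.sqrt(2.0))

    def test_small_negative_clipped_and_flagged(self):
        treated = yield_set(SSB=(5.0, 1.0), DSB=(0, 0), CL=(0, 0))
        untreated = yield_set(SSB=(5.5, 1.0), DSB=(0, 0), CL=(0, 0))
        revealed = enzyme_reveal(treated, untreated)
        assert revealed["isolated_BD"].value == 0.0
        assert revealed.flags["isolated_BD"] == "clipped_negative"

    def test_large_negative_retained_and_flagged(self):
        treated = yield_set(SSB=(5.0, 0.1), DSB=(0, 0), CL=(0, 0))
        untreated = yield_set(SSB=(8.0, 0.1), DSB=(0, 0), CL=(0, 0))
        revealed = enzyme_reveal(treated, untreated)
        assert revealed["isolated_BD"].value == pytest.approx(-3.0)
        assert revealed.flags["isolated_BD"] == "negative"

    def test_energy_mismatch_rejected(self):
        a = yield_set(energy=5.0, SSB=(1, 0), DSB=(1, 0), CL=(1, 0))
        b = yield_set(energy=10.0, SSB=(1, 0), DSB=(1, 0), CL=(1, 0))
        with pytest.raises(UsageError, match="energy"):
            enzyme_reveal(a, b)

    @given(ssb=st.floats(1e-16, 1e-13), dsb=st.floats(0, 1e-14),
           cl=st.floats(0, 1e-14))
    def test_self_difference_always_zero(self, ssb, dsb, cl):
        s = yield_set(SSB=(ssb, ssb / 10), DSB=(dsb, dsb / 10), CL=(cl, cl / 10))
        revealed = enzyme_reveal(s, s)
        assert all(v.value == 0.0 for v in revealed.yields.values())


class TestPooling:
    def test_inverse_variance_weighting(self):
        a = yield_set(SSB=(10.0, 1.0))
        b = yield_set(SSB=(14.0, 2.0))
        pooled = pool_yield_sets([a, b])
        w1, w2 = 1.0, 0.25
        assert pooled["SSB"].value == pytest.approx((10 * w1 + 14 * w2) / (w1 + w2))
        assert pooled["SSB"].sd == pytest.approx(1 / math.sqrt(w1 + w2))

    def test_sum_mode_adds_channels(self):
        a = yield_set(SSB=(10.0, 1.0))
        b = yield_set(SSB=(14.0, 2.0))
        pooled = pool_yield_sets([a, b], mode="sum")
        assert pooled["SSB"].value == pytest.approx(24.0)
        assert pooled["SSB"].sd == pytest.approx(math.hypot(1, 2))

    def test_cross_energy_pooling_rejected(self):
        with pytest.raises(UsageError):
            pool_yield_sets([yield_set(energy=5, SSB=(1, 0)),
                             yield_set(energy=10, SSB=(1, 0))])
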