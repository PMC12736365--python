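"""Structural model: covariate equations, analytic kinetics, AUC."""

import numpy as np
import pytest

from fludapk import (
    Covariates,
    DoseEvent,
    PKParameters,
    ThetaVector,
    allometric_size,
    auc,
    concentration,
    individual_params,
)
from fludapk.pk_core import compartment_amounts

from conftest import (
    ode_concentration,
    ode_states,
    random_pk_parameters,
    random_regimen,
)


class TestAllometricSize:
    @pytest.mark.parametrize(
        "wgt, ref, exponent, expected",
        [
            (70, 70, 0.75, 1.0),
            (70, 70, 1.0, 1.0),
            (140, 70, 0.75, 2**0.75),  # 1.6818
        ],
    )
    def test_values(self, wgt, ref, exponent, expected):
        assert allometric_size(wgt, ref, exponent) == pytest.approx(expected, rel=1e-12)

    def test_rejects_nonpositive_weight(self):
        with pytest.raises(ValueError):
            allometric_size(0.0)
        with pytest.raises(ValueError):
            allometric_size(-50.0)


class TestIndividualParams:
    def test_reference_axicel_clearance(self, theta):
        """70 kg, CRCL 96, axi-cel: typical CL is 6.1 L/h."""
        p = individual_params(theta, Covariates(wgt=70, crcl=96, cart="axi-cel"))
        assert p.cl == pytest.approx(6.1, abs=1e-12)

    def test_reference_tisacel_clearance(self, theta):
        p = individual_params(theta, Covariates(wgt=70, crcl=96, cart="tisa-cel"))
        assert p.cl == pytest.approx(5.6, abs=1e-12)

    def test_reference_volumes(self, theta):
        p = individual_params(theta, Covariates(wgt=70, crcl=96, cart="axi-cel"))
        assert (p.v1, p.v2, p.v3) == pytest.approx((41.2, 14.5, 10.8))
        assert (p.cld2, p.cld3) == pytest.approx((4.8, 3.6))

    def test_half_renal_function(self, theta):
        """CRCL 48 halves the renal component: 3.9 + 1.7*0.5 = 4.75 L/h."""
        p = individual_params(theta, Covariates(wgt=70, crcl=48, cart="tisa-cel"))
        assert p.cl == pytest.approx(4.75, abs=1e-12)

    def test_weight_scaling(self, theta):
        p = individual_params(theta, Covariates(wgt=140, crcl=96, cart="axi-cel"))
        assert p.cl == pytest.approx(6.1 * 2**0.75)
        assert p.v1 == pytest.approx(41.2 * 2.0)
        assert p.cld2 == pytest.approx(4.8 * 2**0.75)

    def test_eta_acts_multiplicatively(self, theta):
        cov = Covariates(wgt=70, crcl=96, cart="axi-cel")
        p = individual_params(theta, cov, eta_cl=0.3, eta_v1=-0.2)
        assert p.cl == pytest.approx(6.1 * np.exp(0.3))
        assert p.v1 == pytest.approx(41.2 * np.exp(-0.2))

    def test_unknown_construct_rejected(self, theta):
        with pytest.raises(ValueError, match="construct"):
            Covariates(wgt=70, crcl=96, cart="liso-cel")


class TestConcentration:
    def test_no_dose_gives_zero(self, typical_axicel):
        assert concentration(typical_axicel, [], 5.0) == 0.0

    def test_causality(self, typical_axicel):
        reg = [DoseEvent(10.0, 44.46, 0.5)]
        assert concentration(typical_axicel, reg, 9.99) == 0.0

    def test_continuity_at_infusion_end(self, typical_axicel):
        reg = [DoseEvent(0.0, 44.46, 0.5)]
        left, right = concentration(typical_axicel, reg, np.array([0.5 - 1e-9, 0.5 + 1e-9]))
        assert left == pytest.approx(right, rel=1e-6)

    def test_matches_ode_oracle_typical(self, typical_axicel):
        reg = [DoseEvent(0.0, 44.46, 0.5)]
        t = np.array([0.25, 0.5, 1.5, 2.0, 7.0, 24.0])
        expected = ode_concentration(typical_axicel, reg, t)
        np.testing.assert_allclose(concentration(typical_axicel, reg, t), expected, rtol=1e-6)

    @pytest.mark.parametrize("case", range(100))
    def test_matches_ode_oracle_randomized(self, case):
        """Analytic solution vs stiff-ODE integration, randomized parameters."""
        rng = np.random.default_rng(1000 + case)
        params = random_pk_parameters(rng)
        reg = random_regimen(rng)
        t = np.sort(rng.uniform(0.0, 80.0, size=5))
        got = concentration(params, reg, t)
        expected = ode_concentration(params, reg, t)
        scale = max(expected.max(), 1e-9)
        np.testing.assert_allclose(got / scale, expected / scale, atol=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_dose_linearity(self, seed):
        rng = np.random.default_rng(seed)
        params = random_pk_parameters(rng)
        reg = random_regimen(rng)
        scaled = [DoseEvent(d.start_time, 3.7 * d.amount, d.duration) for d in reg]
        t = np.linspace(0.1, 70, 40)
        np.testing.assert_allclose(
            concentration(params, scaled, t), 3.7 * concentration(params, reg, t), rtol=1e-10
        )

    @pytest.mark.parametrize("seed", [3, 4])
    def test_mass_balance(self, seed):
        """Compartment amounts + eliminated = administered, via the ODE state."""
        rng = np.random.default_rng(seed)
        params = random_pk_parameters(rng)
        reg = random_regimen(rng)
        t_end = max(d.start_time + d.duration for d in reg)
        times = np.array([t_end / 2, t_end, t_end + 5.0, t_end + 30.0])
        states = ode_states(params, reg, times)
        administered = np.array(
            [sum(d.amount * min(1.0, max(0.0, (t - d.start_time) / d.duration)) for d in reg)
             for t in times]
        )
        np.testing.assert_allclose(states.sum(axis=0), administered, rtol=1e-7)
        # analytic amounts agree with the ODE compartment states
        np.testing.assert_allclose(
            compartment_amounts(params, reg, times), states[:3], rtol=1e-6, atol=1e-9
        )

    def test_two_compartment_limit(self):
        """cld3 = 0 reproduces the two-compartment solution."""
        rng = np.random.default_rng(7)
        p3 = random_pk_parameters(rng)
        p2 = PKParameters(cl=p3.cl, v1=p3.v1, v2=p3.v2, v3=p3.v3, cld2=p3.cld2, cld3=0.0)
        reg = [DoseEvent(0.0, 50.0, 0.5)]
        t = np.linspace(0.25, 48, 30)
        np.testing.assert_allclose(
            concentration(p2, reg, t), ode_concentration(p2, reg, t), rtol=1e-6
        )

    def test_one_compartment_limit(self):
        """cld2 = cld3 = 0 with a bolus-like infusion: D/V1 * exp(-CL/V1 * t)."""
        p = PKParameters(cl=5.0, v1=40.0, v2=10.0, v3=10.0, cld2=0.0, cld3=0.0)
        reg = [DoseEvent(0.0, 10.0, 1e-6)]
        t = np.array([0.5, 2.0, 10.0, 30.0])
        expected = 10.0 / 40.0 * np.exp(-5.0 / 40.0 * t) * 1000.0
        np.testing.assert_allclose(concentration(p, reg, t), expected, rtol=1e-4)


class TestAuc:
    def test_empty_regimen(self, typical_axicel):
        assert auc(typical_axicel, [], 0, 100) == 0.0

    def test_auc_infinity_is_dose_over_cl(self, typical_axicel):
        """AUC(0, inf) = 44.46 mg / 6.1 L/h = 7.289 mg*h/L."""
        reg = [DoseEvent(0.0, 44.46, 0.5)]
        assert auc(typical_axicel, reg, 0, np.inf) == pytest.approx(44.46 / 6.1, rel=1e-10)

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_dose_over_cl_any_parameters(self, seed):
        rng = np.random.default_rng(seed)
        params = random_pk_parameters(rng)
        reg = [DoseEvent(0.0, float(rng.uniform(10, 90)), 0.5)]
        assert auc(params, reg, 0, np.inf) == pytest.approx(reg[0].amount / params.cl, rel=1e-10)

    def test_additive_over_intervals(self, typical_axicel):
        reg = [DoseEvent(0.0, 44.46, 0.5), DoseEvent(24.0, 44.46, 0.5)]
        total = auc(typical_axicel, reg, 0, 60.0)
        assert auc(typical_axicel, reg, 0, 17.3) + auc(typical_axicel, reg, 17.3, 60.0) == pytest.approx(
            total, rel=1e-10
        )

    def test_matches_quadrature(self, typical_axicel):
        from scipy.integrate import quad

        reg = [DoseEvent(0.0, 44.46, 0.5)]
        expected, _ = quad(
            lambda t: concentration(typical_axicel, reg, t) / 1000.0, 0, 30, limit=300
        )
        assert auc(typical_axicel, reg, 0, 30) == pytest.approx(expected, rel=1e-7)

    def test_reversed_interval_rejected(self, typical_axicel):
        with pytest.raises(ValueError):
            auc(typical_axicel, [], 10.0, 5.0)


class TestValidation:
    def test_theta_defaults_are_published_estimates(self, theta):
        assert (
            theta.theta_cart1,
            theta.theta_cart2,
            theta.theta_crcl,
            theta.theta_v1,
            theta.theta_v2,
            theta.theta_v3,
            theta.theta_cld2,
            theta.theta_cld3,
        ) == (4.4, 3.9, 1.7, 41.2, 14.5, 10.8, 4.8, 3.6)
        assert (theta.crcl_ref, theta.wgt_ref) == (96.0, 70.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ThetaVector(theta_v1=-1.0)
        with pytest.raises(ValueError):
            PKParameters(cl=0.0, v1=40, v2=10, v3=10, cld2=4, cld3=3)
        with pytest.raises(ValueError):
            DoseEvent(0.0, -5.0)
        with pytest.raises(ValueError):
            DoseEvent(0.0, 5.0, duration=0.0)

    def test_zero_theta_crcl_allowed(self):
        """The renal-free reduced model needs theta_crcl = 0 exactly."""
        tv = ThetaVector(theta_crcl=0.0)
        p = individual_params(tv, Covariates(wgt=70, crcl=96, cart="axi-cel"))
        assert p.cl == pytest.approx(4.4)
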