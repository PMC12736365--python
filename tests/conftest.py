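"""Shared fixtures: published parameter values and an independent ODE oracle."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from fludapk import (
    Covariates,
    DoseEvent,
    PKParameters,
    RandomEffectsSpec,
    ThetaVector,
    individual_params,
)


@pytest.fixture(scope="session")
def theta():
    return ThetaVector()


@pytest.fixture(scope="session")
def iiv_spec():
    return RandomEffectsSpec()


@pytest.fixture(scope="session")
def typical_axicel(theta):
    """Typical parameters for the 70 kg axi-cel reference patient."""
    return individual_params(theta, Covariates(wgt=70, crcl=96, cart="axi-cel"))


def ode_states(params: PKParameters, regimen, times, rtol=1e-11, atol=1e-13):
    """Stiff-ODE oracle: compartment amounts plus cumulative eliminated amount.

    Independent of the analytic path: integrates the mammillary system with
    zero-order inputs numerically, splitting at infusion breakpoints.
    """
    k10 = params.cl / params.v1
    k12 = params.cld2 / params.v1
    k21 = params.cld2 / params.v2 if params.cld2 > 0 else 0.0
    k13 = params.cld3 / params.v1
    k31 = params.cld3 / params.v3 if params.cld3 > 0 else 0.0

    def rate_in(t):
        total = 0.0
        for d in regimen:
            if d.start_time <= t < d.start_time + d.duration:
                total += d.amount / d.duration
        return total

    def rhs(t, x):
        a1, a2, a3, _ = x
        return [
            rate_in(t) - (k10 + k12 + k13) * a1 + k21 * a2 + k31 * a3,
            k12 * a1 - k21 * a2,
            k13 * a1 - k31 * a3,
            k10 * a1,
        ]

    times = np.atleast_1d(np.asarray(times, dtype=float))
    breaks = sorted(
        {0.0, *times}
        | {d.start_time for d in regimen}
        | {d.start_time + d.duration for d in regimen}
    )
    t_end = max(breaks)
    sol = solve_ivp(
        rhs,
        [0.0, t_end],
        [0.0, 0.0, 0.0, 0.0],
        t_eval=times,
        rtol=rtol,
        atol=atol,
        method="LSODA",
        max_step=0.25,
    )
    assert sol.success
    return sol.y  # rows: A1, A2, A3, eliminated


def ode_concentration(params, regimen, times):
    """ng/mL concentrations from the ODE oracle."""
    return ode_states(params, regimen, times)[0] / params.v1 * 1000.0


def random_pk_parameters(rng):
    """A physiologically spread random parameter draw for property tests."""
    return PKParameters(
        cl=float(rng.uniform(1.0, 15.0)),
        v1=float(rng.uniform(10.0, 80.0)),
        v2=float(rng.uniform(5.0, 60.0)),
        v3=float(rng.uniform(5.0, 60.0)),
        cld2=float(rng.uniform(0.5, 12.0)),
        cld3=float(rng.uniform(0.5, 12.0)),
    )


def random_regimen(rng):
    n = int(rng.integers(1, 4))
    return [
        DoseEvent(
            start_time=float(24.0 * i + rng.uniform(0, 2)),
            amount=float(rng.uniform(10, 80)),
            duration=float(rng.uniform(0.25, 2.0)),
        )
        for i in range(n)
    ]
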