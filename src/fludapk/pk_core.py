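"""Structural three-compartment disposition model for fludarabine (F-ara-A).

Fludarabine is administered as the monophosphate prodrug (f-ara-AMP) by short
intravenous infusion and measured in serum as the circulating nucleoside
F-ara-A.  Serum disposition is described by a linear mammillary
three-compartment model with zero-order input into the central compartment
and first-order elimination from it:

    dA1/dt = R(t) - (k10 + k12 + k13) A1 + k21 A2 + k31 A3
    dA2/dt = k12 A1 - k21 A2
    dA3/dt = k13 A1 - k31 A3

with micro rate constants k10 = CL/V1, k12 = CLD2/V1, k21 = CLD2/V2,
k13 = CLD3/V1, k31 = CLD3/V3.

Units contract (single place for all unit handling):
    time h, amounts mg F-ara-A, volumes L, clearances L/h.
    Serum concentration is reported in ng/mL (= ug/L); 1 mg/L = 1000 ng/mL.
    AUC is reported in mg*h/L.

The covariate model ties individual parameters to body weight (allometry),
creatinine clearance (renal clearance component) and CAR-T construct
(non-renal clearance):

    CL   = [theta_cart(construct) + theta_crcl * CRCL/96] * (WGT/70)^0.75
    V1   = theta_v1 * (WGT/70)          V2, V3 likewise linear in weight
    CLD2 = theta_cld2 * (WGT/70)^0.75   CLD3 likewise

The solution is obtained by eigendecomposition of the rate matrix.  A
mammillary rate matrix is symmetrizable by a diagonal similarity transform,
so the decomposition is computed with a symmetric eigensolver: eigenvalues
are exactly real and the factorization is robust even for (near-)degenerate
parameter draws.  Compartments with zero distributional clearance are
dropped from the system, which also yields the exact two- and
one-compartment limits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "AXI_CEL",
    "TISA_CEL",
    "ThetaVector",
    "PKParameters",
    "DoseEvent",
    "Covariates",
    "allometric_size",
    "individual_params",
    "concentration",
    "compartment_amounts",
    "auc",
]

AXI_CEL = "axi-cel"
TISA_CEL = "tisa-cel"

#: mg/L -> ng/mL
_MGL_TO_NGML = 1000.0


@dataclass(frozen=True)
class ThetaVector:
    """Fixed effects of the final covariate model.

    Defaults are the published population estimates: non-renal clearance by
    CAR-T construct (L/h), renal clearance at the reference creatinine
    clearance of 96 mL/min (L/h), volumes (L) and distributional clearances
    (L/h) at the 70 kg reference weight.
    """

    theta_cart1: float = 4.4  # non-renal CL, axi-cel (L/h)
    theta_cart2: float = 3.9  # non-renal CL, tisa-cel (L/h)
    theta_crcl: float = 1.7   # renal CL at CRCL = 96 mL/min (L/h)
    theta_v1: float = 41.2    # central volume at 70 kg (L)
    theta_v2: float = 14.5    # shallow peripheral volume at 70 kg (L)
    theta_v3: float = 10.8    # deep peripheral volume at 70 kg (L)
    theta_cld2: float = 4.8   # central<->shallow clearance at 70 kg (L/h)
    theta_cld3: float = 3.6   # central<->deep clearance at 70 kg (L/h)
    crcl_ref: float = 96.0    # reference creatinine clearance (mL/min)
    wgt_ref: float = 70.0     # reference body weight (kg)

    def __post_init__(self) -> None:
        strictly_positive = {
            "theta_cart1": self.theta_cart1,
            "theta_cart2": self.theta_cart2,
            "theta_v1": self.theta_v1,
            "theta_v2": self.theta_v2,
            "theta_v3": self.theta_v3,
            "theta_cld2": self.theta_cld2,
            "theta_cld3": self.theta_cld3,
            "crcl_ref": self.crcl_ref,
            "wgt_ref": self.wgt_ref,
        }
        for name, value in strictly_positive.items():
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        # theta_crcl may be exactly zero: the renal-component-free reduced
        # model (nested-model testing) is the final model with theta_crcl = 0.
        if self.theta_crcl < 0:
            raise ValueError(f"theta_crcl must be non-negative, got {self.theta_crcl}")

    def nonrenal_cl(self, cart: str) -> float:
        if cart == AXI_CEL:
            return self.theta_cart1
        if cart == TISA_CEL:
            return self.theta_cart2
        raise ValueError(f"unknown CAR-T construct {cart!r}")


@dataclass(frozen=True)
class PKParameters:
    """Individual disposition parameters after covariates and random effects.

    ``cld2``/``cld3`` may be exactly zero, in which case the corresponding
    peripheral compartment is inert and the model collapses to a two- or
    one-compartment system.
    """

    cl: float
    v1: float
    v2: float
    v3: float
    cld2: float
    cld3: float

    def __post_init__(self) -> None:
        for name in ("cl", "v1", "v2", "v3"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be finite and strictly positive, got {value}")
        for name in ("cld2", "cld3"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value >= 0):
                raise ValueError(f"{name} must be finite and non-negative, got {value}")


@dataclass(frozen=True)
class DoseEvent:
    """One zero-order infusion of F-ara-A equivalents.

    start_time -- h since the start of the first infusion
    amount     -- mg F-ara-A (post prodrug conversion)
    duration   -- infusion length in h (30 min per protocol)
    """

    start_time: float
    amount: float
    duration: float = 0.5

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError(f"dose amount must be non-negative, got {self.amount}")
        if not self.duration > 0:
            raise ValueError(f"infusion duration must be positive, got {self.duration}")


@dataclass(frozen=True)
class Covariates:
    """Subject-level covariates entering (or reported alongside) the model.

    ``wgt`` (kg), ``crcl`` (absolute Cockcroft-Gault creatinine clearance,
    mL/min) and ``cart`` enter the final model; the remainder are clinical
    descriptors used for dosing (BSA) and dataset round-trips.
    """

    wgt: float
    crcl: float
    cart: str
    age: float = float("nan")
    sex: str = ""
    height: float = float("nan")
    scr: float = float("nan")

    def __post_init__(self) -> None:
        if not self.wgt > 0:
            raise ValueError(f"weight must be positive, got {self.wgt}")
        if not self.crcl > 0:
            raise ValueError(f"creatinine clearance must be positive, got {self.crcl}")
        if self.cart not in (AXI_CEL, TISA_CEL):
            raise ValueError(f"unknown CAR-T construct {self.cart!r}")


def allometric_size(wgt: float, ref: float = 70.0, exponent: float = 0.75) -> float:
    """Allometric size factor (wgt/ref)**exponent.

    exponent 0.75 is the fixed allometric exponent used for clearances,
    exponent 1.0 the linear weight scaling used for volumes.
    """
    if not wgt > 0:
        raise ValueError(f"weight must be positive, got {wgt}")
    if not ref > 0:
        raise ValueError(f"reference weight must be positive, got {ref}")
    return float((wgt / ref) ** exponent)


def individual_params(
    theta: ThetaVector,
    cov: Covariates,
    eta_cl: float = 0.0,
    eta_v1: float = 0.0,
) -> PKParameters:
    """Individual PK parameters from fixed effects, covariates and etas.

    CL = [theta_cart + theta_crcl * CRCL/96] * (WGT/70)^0.75 * exp(eta_cl);
    V1 carries exp(eta_v1); V2/V3 scale linearly with weight and CLD2/CLD3
    allometrically; no random effects on peripheral parameters.
    """
    if not (np.isfinite(eta_cl) and np.isfinite(eta_v1)):
        raise ValueError("random effects must be finite")
    f_wgt = allometric_size(cov.wgt, theta.wgt_ref, 0.75)
    g_wgt = allometric_size(cov.wgt, theta.wgt_ref, 1.0)
    cl_typ = theta.nonrenal_cl(cov.cart) + theta.theta_crcl * cov.crcl / theta.crcl_ref
    return PKParameters(
        cl=cl_typ * f_wgt * float(np.exp(eta_cl)),
        v1=theta.theta_v1 * g_wgt * float(np.exp(eta_v1)),
        v2=theta.theta_v2 * g_wgt,
        v3=theta.theta_v3 * g_wgt,
        cld2=theta.theta_cld2 * f_wgt,
        cld3=theta.theta_cld3 * f_wgt,
    )


def _eigensystem(
    cl: float, v1: float, v2: float, v3: float, cld2: float, cld3: float
) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues and squared central eigenvector weights of the rate matrix.

    Fast path used by estimation: because the symmetrizing similarity is
    diagonal with first entry 1, both the projection of a central-compartment
    input and the reconstruction of the central amount use the same first row
    of the orthogonal eigenvector matrix, so the central amount is
    sum_j w_j * f_j(t) with w_j = Q[0, j]^2.
    """
    k10 = cl / v1
    kin, kout = [], []
    for cld, v in ((cld2, v2), (cld3, v3)):
        if cld > 0:
            kin.append(cld / v1)
            kout.append(cld / v)
    n = 1 + len(kin)
    a = np.zeros((n, n))
    d = np.ones(n)
    a[0, 0] = -(k10 + sum(kin))
    for j, (ki, ko) in enumerate(zip(kin, kout), start=1):
        a[0, j] = ko
        a[j, 0] = ki
        a[j, j] = -ko
        d[j] = np.sqrt(ko / ki)
    s = d[:, None] * a / d[None, :]
    s = 0.5 * (s + s.T)
    lam, q = np.linalg.eigh(s)
    return lam, q[0] ** 2


def _eigensystem_batch(
    cl: np.ndarray, v1: np.ndarray, v2: float, v3: float, cld2: float, cld3: float
) -> tuple[np.ndarray, np.ndarray]:
    """Batched :func:`_eigensystem` over K (cl, v1) pairs sharing the
    peripheral parameters; returns lam (K, m) and weights (K, m)."""
    cl = np.asarray(cl, dtype=float)
    v1 = np.asarray(v1, dtype=float)
    kk = cl.shape[0]
    k10 = cl / v1
    kin, kout = [], []
    for cld, v in ((cld2, v2), (cld3, v3)):
        if cld > 0:
            kin.append(cld / v1)   # (K,)
            kout.append(cld / v)   # scalar
    n = 1 + len(kin)
    a = np.zeros((kk, n, n))
    d = np.ones((kk, n))
    a[:, 0, 0] = -(k10 + sum(kin))
    for j, (ki, ko) in enumerate(zip(kin, kout), start=1):
        a[:, 0, j] = ko
        a[:, j, 0] = ki
        a[:, j, j] = -ko
        d[:, j] = np.sqrt(ko / ki)
    s = d[:, :, None] * a / d[:, None, :]
    s = 0.5 * (s + np.swapaxes(s, 1, 2))
    lam, q = np.linalg.eigh(s)
    return lam, q[:, 0, :] ** 2


def _central_amount(
    lam: np.ndarray,
    w: np.ndarray,
    starts: np.ndarray,
    durs: np.ndarray,
    rates: np.ndarray,
    times: np.ndarray,
) -> np.ndarray:
    """Central-compartment amount at `times` for a set of zero-order inputs."""
    tau = times[None, :] - starts[:, None]          # (nd, nt)
    during = (tau >= 0) & (tau <= durs[:, None])
    after = tau > durs[:, None]
    lt = lam[:, None, None]
    td = np.where(during, tau, 0.0)
    term_d = np.expm1(lt * td[None]) / lt
    ta = np.where(after, tau - durs[:, None], 0.0)
    end = np.expm1(lam[:, None] * durs[None, :]) / lam[:, None]   # (m, nd)
    term_a = end[:, :, None] * np.exp(lt * ta[None])
    term = np.where(during[None], term_d, np.where(after[None], term_a, 0.0))
    return np.einsum("m,mdt,d->t", w, term, rates)


class _Disposition:
    """Eigenfactorized linear system for one parameter set.

    Peripheral compartments with zero distributional clearance are excluded,
    so the retained rate matrix is always nonsingular (every state drains to
    elimination) and its diagonal symmetrization D A D^-1 is exact.
    """

    def __init__(self, p: PKParameters) -> None:
        k10 = p.cl / p.v1
        d = [1.0]
        k_in, k_out = [], []  # central->peripheral, peripheral->central
        for cld, v in ((p.cld2, p.v2), (p.cld3, p.v3)):
            if cld > 0:
                k_in.append(cld / p.v1)
                k_out.append(cld / v)
        n = 1 + len(k_in)
        a = np.zeros((n, n))
        a[0, 0] = -(k10 + sum(k_in))
        for j, (kin, kout) in enumerate(zip(k_in, k_out), start=1):
            a[0, j] = kout
            a[j, 0] = kin
            a[j, j] = -kout
            d.append(np.sqrt(kout / kin))
        self.n = n
        self.v1 = p.v1
        self._a = a
        dvec = np.asarray(d)
        s = dvec[:, None] * a / dvec[None, :]
        s = 0.5 * (s + s.T)  # kill rounding asymmetry
        lam, q = np.linalg.eigh(s)
        self._lam = lam            # strictly negative
        self._modes = q / dvec[:, None]      # D^-1 Q, columns are modes
        self._weights = q.T * dvec[None, :]  # Q^T D, rows map state->modes

    def input_vector(self, rate: float) -> np.ndarray:
        b = np.zeros(self.n)
        b[0] = rate
        return b

    def amounts_single_dose(self, dose: DoseEvent, t: np.ndarray) -> np.ndarray:
        """Compartment amounts (n, len(t)) for one infusion, zero initial state."""
        t = np.asarray(t, dtype=float)
        out = np.zeros((self.n, t.size))
        if dose.amount == 0:
            return out
        rate = dose.amount / dose.duration
        bt = self._weights @ self.input_vector(rate)  # input in eigenbasis
        lam = self._lam[:, None]
        tau = (t - dose.start_time).reshape(1, -1)
        during = (tau >= 0) & (tau <= dose.duration)
        after = tau > dose.duration
        coeff = np.zeros_like(out)
        if during.any():
            td = np.where(during, tau, 0.0)
            coeff_d = bt[:, None] * (np.expm1(lam * td)) / lam
            coeff = np.where(during, coeff_d, coeff)
        if after.any():
            end_coeff = bt * np.expm1(self._lam * dose.duration) / self._lam
            ta = np.where(after, tau - dose.duration, 0.0)
            coeff_a = end_coeff[:, None] * np.exp(lam * ta)
            coeff = np.where(after, coeff_a, coeff)
        return self._modes @ coeff

    def amounts(self, regimen: Sequence[DoseEvent], t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros((self.n, t.size))
        for dose in regimen:
            out += self.amounts_single_dose(dose, t)
        return out

    def integral_single_dose(self, dose: DoseEvent, t0: float, t1: float) -> np.ndarray:
        """Exact integral of compartment amounts over [t0, t1]; t1 may be inf.

        Uses int x dt = A^-1 (x(t1) - x(t0) - b*(t1-t0)) on each piecewise
        segment of the forcing, evaluated in the eigenbasis.
        """
        total = np.zeros(self.n)
        if dose.amount == 0:
            return total
        rate = dose.amount / dose.duration
        s, e = dose.start_time, dose.start_time + dose.duration
        bt = self._weights @ self.input_vector(rate)

        def coeffs_at(time: float) -> np.ndarray:
            # eigenbasis coefficients of the state at `time`
            if time <= s:
                return np.zeros(self.n)
            if time <= e:
                return bt * np.expm1(self._lam * (time - s)) / self._lam
            end = bt * np.expm1(self._lam * dose.duration) / self._lam
            return end * np.exp(self._lam * (time - e))

        # infusion segment overlap
        a0, a1 = max(t0, s), min(t1, e)
        if a1 > a0:
            dx = coeffs_at(a1) - coeffs_at(a0)
            total += self._modes @ ((dx - bt * (a1 - a0)) / self._lam)
        # post-infusion segment overlap
        b0 = max(t0, e)
        if t1 > b0:
            x0 = coeffs_at(b0)
            x1 = np.zeros(self.n) if np.isinf(t1) else coeffs_at(t1)
            total += self._modes @ ((x1 - x0) / self._lam)
        return total


def _disposition(params: PKParameters) -> _Disposition:
    return _Disposition(params)


def concentration(
    params: PKParameters,
    regimen: Sequence[DoseEvent],
    t: float | np.ndarray,
) -> float | np.ndarray:
    """Serum F-ara-A concentration (ng/mL) at time(s) t for a dosing regimen.

    Superposition of the analytic single-infusion solutions; continuous in t,
    zero before the first dose starts.
    """
    scalar = np.isscalar(t)
    tv = np.atleast_1d(np.asarray(t, dtype=float))
    if (tv < 0).any():
        raise ValueError("time must be non-negative")
    disp = _disposition(params)
    central = disp.amounts(regimen, tv)[0]
    conc = central / params.v1 * _MGL_TO_NGML
    conc = np.clip(conc, 0.0, None)  # guard tiny negative rounding
    return float(conc[0]) if scalar else conc


def compartment_amounts(
    params: PKParameters,
    regimen: Sequence[DoseEvent],
    t: float | np.ndarray,
) -> np.ndarray:
    """Amounts (mg) in (central, shallow, deep) compartments at time(s) t.

    Compartments disabled by zero distributional clearance are reported as 0.
    """
    tv = np.atleast_1d(np.asarray(t, dtype=float))
    disp = _disposition(params)
    active = disp.amounts(regimen, tv)
    out = np.zeros((3, tv.size))
    idx = [0]
    if params.cld2 > 0:
        idx.append(1)
    if params.cld3 > 0:
        idx.append(2)
    out[idx, :] = active
    return out


def auc(
    params: PKParameters,
    regimen: Sequence[DoseEvent],
    t0: float = 0.0,
    t1: float = np.inf,
) -> float:
    """AUC of the serum concentration on the mg/L scale over [t0, t1] (mg*h/L).

    Computed exactly from the exponential solution (no quadrature); t1 may be
    infinite, giving AUC(0, inf) = dose/CL for a single dose.
    """
    if not t0 < t1:
        raise ValueError(f"need t0 < t1, got [{t0}, {t1}]")
    disp = _disposition(params)
    total = 0.0
    for dose in regimen:
        total += disp.integral_single_dose(dose, t0, t1)[0]
    return float(total / params.v1)
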