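"""Dual-input tracer kinetic models for liver DCE-MRI.

Five models are implemented with a unified parameterization so that their
outputs are directly comparable:

* ``TK``   - Tofts-Kety, one interstitial compartment (v_P ~ 0 limit) with
             the volume transfer constant decomposed as K^Trans = E * F/V_T.
* ``ETK``  - extended Tofts-Kety: instantaneous vascular term v_P * c_in plus
             the interstitial exponential.
* ``2CX``  - two-compartment exchange: coupled plasma/interstitium ODEs,
             biexponential residue from the system eigenvalues.
* ``AATH`` - adiabatic approximation to tissue homogeneity: plug-flow
             capillary of transit time T_c = v_P/f followed by exponential
             interstitial washout, E = 1 - exp(-ps/f).
* ``DP``   - distributed parameter (Sangren-Sheppard): plug-flow capillary
             with distributed back-exchange; the outflow density carries a
             modified-Bessel tail.

All models share a dual vascular input c_in(t) = gamma * c_A(t - t_Lag) +
(1 - gamma) * c_PV(t - t_Lag) in the causal sums-of-exponentials family, so
tissue concentration curves are computed by exact continuous-time
convolution (closed form for exponential/box/delta kernel pieces; adaptive
Gauss-Legendre quadrature for the DP Bessel tail).  A fine-grid discrete
convolution oracle is provided for validation.

Flows are plasma flows per unit tissue volume (mL/min/mL); conversions to
the blood-referred per-100-g units conventional in liver perfusion reporting
are in :func:`derived_parameters`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.interpolate import CubicSpline
from scipy.special import i1e

from .input_functions import ExponentialSumCurve, TracerInputModel

MODEL_IDS = ("TK", "ETK", "2CX", "AATH", "DP")

_GL_NODES, _GL_WEIGHTS = leggauss(32)
_GL5_NODES, _GL5_WEIGHTS = leggauss(5)


class ParameterDomainError(ValueError):
    """Non-physical kinetic parameters."""


@dataclass(frozen=True)
class ConversionConstants:
    """Hematocrit / density constants for unit conversions.

    ``H_LV`` and ``H_SV`` are the large- and small-vessel hematocrits,
    ``rho_T`` the tissue density in g/cm^3 and ``V_T`` the tissue volume in
    mL (``M = rho_T * V_T`` is the tissue mass in g).
    """

    H_LV: float = 0.45
    H_SV: float = 0.25
    rho_T: float = 1.04
    V_T: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.H_SV <= self.H_LV < 1.0:
            raise ValueError("require 0 <= H_SV <= H_LV < 1")
        if self.rho_T <= 0:
            raise ValueError("rho_T must be > 0")

    @property
    def M(self) -> float:
        return self.rho_T * self.V_T


@dataclass(frozen=True)
class KineticParameterSet:
    """Free kinetic parameters of one model for one voxel/ROI.

    Parameters
    ----------
    model_id:
        One of ``TK, ETK, 2CX, AATH, DP``.
    f:
        Total plasma flow per tissue volume F/V_T (mL/min/mL).
    gamma:
        Arterial flow fraction in [0, 1].
    v_P:
        Fractional plasma volume (TK fixes v_P = 0).
    v_I:
        Fractional interstitial volume.
    E:
        Extraction fraction, native free parameter for TK/ETK.
    ps:
        Permeability-surface product per tissue volume PS/V_T (mL/min/mL),
        native free parameter for 2CX/AATH/DP.
    t_Lag_T:
        Bolus-arrival delay of the tissue relative to the dual input (min).
    """

    model_id: str
    f: float
    gamma: float
    v_I: float
    v_P: float = 0.0
    E: float | None = None
    ps: float | None = None
    t_Lag_T: float = 0.0

    def __post_init__(self):
        if self.model_id not in MODEL_IDS:
            raise ParameterDomainError(f"unknown model_id {self.model_id!r}")
        if self.f <= 0:
            raise ParameterDomainError("flow f must be > 0")
        if self.v_I <= 0 or self.v_I >= 1:
            raise ParameterDomainError("v_I must be in (0, 1)")
        if not 0.0 <= self.gamma <= 1.0:
            raise ParameterDomainError("gamma must be in [0, 1]")
        if self.t_Lag_T < 0:
            raise ParameterDomainError("t_Lag_T must be >= 0")
        if self.model_id == "TK":
            if self.v_P != 0.0:
                raise ParameterDomainError("TK assumes v_P = 0 (v_P << v_I limit)")
        elif not 0.0 < self.v_P < 1.0:
            raise ParameterDomainError("v_P must be in (0, 1) for vascular models")
        if self.model_id in ("TK", "ETK"):
            if self.E is None or not 0.0 <= self.E < 1.0:
                raise ParameterDomainError("TK/ETK require extraction E in [0, 1)")
        else:
            if self.ps is None or self.ps < 0:
                raise ParameterDomainError(f"{self.model_id} requires ps >= 0")

    # ---- derived kinetic quantities -------------------------------------

    def extraction(self) -> float:
        """Model-specific extraction fraction E."""
        if self.model_id in ("TK", "ETK"):
            return float(self.E)
        if self.f <= 0:
            raise ParameterDomainError("E undefined for f = 0 with ps > 0")
        if self.model_id == "2CX":
            return self.ps / (self.ps + self.f)
        # AATH and DP share the Crone-Renkin form E = 1 - exp(-(PS/VP)/(F/VP))
        return -math.expm1(-self.ps / self.f)

    def ps_equivalent(self) -> float:
        """PS/V_T implied by E for TK/ETK (Crone-Renkin inversion), else ps."""
        if self.model_id in ("TK", "ETK"):
            return -self.f * math.log1p(-self.E)
        return float(self.ps)

    def kep(self) -> float:
        """Interstitial efflux rate E*f/v_I (1/min)."""
        return self.extraction() * self.f / self.v_I

    def capillary_transit_time(self) -> float:
        """T_c = v_P / f (min); zero in the TK limit."""
        return self.v_P / self.f

    def v_B(self, consts: ConversionConstants) -> float:
        return self.v_P / (1.0 - consts.H_SV)

    def v_C(self, consts: ConversionConstants) -> float:
        if self.model_id == "TK":
            return 1.0 - self.v_I
        return 1.0 - self.v_B(consts) - self.v_I


@dataclass
class CompartmentCurves:
    """Per-compartment impulse responses and concentration curves."""

    times: np.ndarray
    Q_P: np.ndarray
    Q_I: np.ndarray
    Q_T: np.ndarray
    R_T: np.ndarray
    Cbar_P: np.ndarray
    Cbar_I: np.ndarray
    C_T: np.ndarray
    q_p_delta_weight: float = 0.0  # ETK vascular spike (area v_P) not on the grid


# ---------------------------------------------------------------------------
# dual input
# ---------------------------------------------------------------------------


def combined_plasma_input(
    gamma: float,
    t_Lag_T: float,
    aif: TracerInputModel | ExponentialSumCurve,
    pvif: TracerInputModel | ExponentialSumCurve,
) -> ExponentialSumCurve:
    """c_in(t) = gamma*c_A(t - t_Lag) + (1-gamma)*c_PV(t - t_Lag).

    The delay folds into per-term arrival times, so the result stays in the
    sums-of-exponentials family.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must be in [0, 1]")
    a = aif.as_terms() if isinstance(aif, TracerInputModel) else aif
    p = pvif.as_terms() if isinstance(pvif, TracerInputModel) else pvif
    if gamma == 1.0:
        return a.delayed(t_Lag_T)
    if gamma == 0.0:
        return p.delayed(t_Lag_T)
    return a.delayed(t_Lag_T).scaled(gamma) + p.delayed(t_Lag_T).scaled(1.0 - gamma)


# ---------------------------------------------------------------------------
# kernel algebra: exact convolution of exponential-sum inputs with
# exponential / box / delta kernel pieces
# ---------------------------------------------------------------------------


def _conv_exp_terms(cin: ExponentialSumCurve, w: float, m: float, shift: float, t):
    """Convolution of c_in with w*exp(-m*(u-shift))*H(u-shift) at times t."""
    tau = t[..., None] - shift - cin.arrivals  # (..., n_terms)
    tau_c = np.clip(tau, 0.0, None)
    mu = cin.rates
    diff = m - mu
    # (exp(-mu*tau) - exp(-m*tau)) / (m - mu); the direct difference is
    # overflow-free, and a 3-term series handles the near-equal-rate limit
    z = diff * tau_c
    small = np.abs(z) < 1e-4
    safe_diff = np.where(np.abs(diff) > 0, diff, 1.0)
    direct = (np.exp(-mu * tau_c) - np.exp(-m * tau_c)) / safe_diff
    series = np.exp(-m * tau_c) * tau_c * (1.0 + z / 2.0 + z * z / 6.0)
    core = np.where(small, series, direct)
    return np.where(tau >= 0.0, core, 0.0) @ (cin.amplitudes * w)


def _conv_box_terms(cin: ExponentialSumCurve, height: float, Tc: float, t):
    """Convolution of c_in with height * 1_{[0, Tc)} at times t."""
    tau = t[..., None] - cin.arrivals
    tau_c = np.clip(tau, 0.0, None)
    mu = cin.rates
    upper = np.exp(-mu * np.clip(tau_c - Tc, 0.0, None))
    lower = np.exp(-mu * tau_c)
    core = (upper - lower) / mu
    return np.where(tau >= 0.0, core, 0.0) @ (cin.amplitudes * height)


# ---------------------------------------------------------------------------
# DP outflow density and survival tail
# ---------------------------------------------------------------------------


def _dp_outflow_density(s, a: float, k: float):
    """Continuous part of the DP outflow density after the capillary transit.

    phi(s) = e^{-a} e^{-k s} sqrt(a k / s) I_1(2 sqrt(a k s)), written with the
    exponentially scaled Bessel function so the exponent -(sqrt(ks)-sqrt(a))^2
    never overflows.
    """
    s = np.asarray(s, dtype=float)
    if a <= 0.0 or k <= 0.0:
        return np.zeros_like(s)
    s_safe = np.where(s > 1e-14, s, 1.0)
    x = 2.0 * np.sqrt(a * k * s_safe)
    val = (
        np.sqrt(a * k / s_safe)
        * i1e(x)
        * np.exp(-((np.sqrt(k * s_safe) - math.sqrt(a)) ** 2))
    )
    return np.where(s > 1e-14, val, a * k * math.exp(-a))


@lru_cache(maxsize=16)
def _dp_tail_spline(a: float, k: float, w_max: float) -> CubicSpline:
    """Cubic spline of the DP survival tail g(w) = 1 - e^{-a} - int_0^w phi.

    The node grid is refined on the fast scale ~1/k; the cumulative integral
    uses composite 5-point Gauss-Legendre per segment, so spline values are
    accurate to ~1e-10 for physiological rate ranges.
    """
    w_max = max(w_max, 1e-6)
    if a <= 0.0 or k <= 0.0:
        return CubicSpline([0.0, w_max], [0.0, 0.0])
    w_fast = min(max(6.0 / k, 1e-3), w_max)
    grid = np.linspace(0.0, w_fast, 801)
    if w_fast < 0.999 * w_max:
        grid = np.unique(np.concatenate([grid, np.linspace(w_fast, w_max, 501)]))
    lo, hi = grid[:-1], grid[1:]
    mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
    pts = mid[:, None] + half[:, None] * _GL5_NODES
    seg = (_dp_outflow_density(pts, a, k) @ _GL5_WEIGHTS) * half
    g = -math.expm1(-a) - np.concatenate([[0.0], np.cumsum(seg)])
    return CubicSpline(grid, np.clip(g, 0.0, None))


def _conv_tail(cin: ExponentialSumCurve, f: float, Tc: float, g, t: np.ndarray):
    """Convolution of c_in with f * g(u - Tc) H(u - Tc), piecewise GL quadrature."""
    out = np.zeros_like(t, dtype=float)
    for i, ti in enumerate(t):
        end = ti - Tc
        if end <= 0:
            continue
        kinks = ti - Tc - cin.arrivals  # input kinks mapped to the w axis
        breaks = np.unique(
            np.concatenate([[0.0, end], kinks[(kinks > 0) & (kinks < end)]])
        )
        lo, hi = breaks[:-1], breaks[1:]
        mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
        w_pts = mid[:, None] + half[:, None] * _GL_NODES  # (pieces, 32)
        vals = g(w_pts) * cin(ti - Tc - w_pts)
        out[i] = f * float(np.sum((vals @ _GL_WEIGHTS) * half))
    return out


# ---------------------------------------------------------------------------
# residue functions and impulse responses
# ---------------------------------------------------------------------------


def _two_cx_modes(params: KineticParameterSet):
    """Eigen-decomposition of the 2CX plasma/interstitium system.

    Returns (rates m_j, plasma kernel weights alpha_j, interstitial weights
    beta_j) such that Q_P = sum alpha_j e^{-m_j t}, Q_I = sum beta_j e^{-m_j t}.
    """
    f, ps, vP, vI = params.f, params.ps, params.v_P, params.v_I
    if ps == 0.0:  # no leakage: plasma washout only
        return np.array([f / vP, 1.0]), np.array([f, 0.0]), np.array([0.0, 0.0])
    a11, a12 = -(f + ps) / vP, ps / vP
    a21, a22 = ps / vI, -ps / vI
    tr, det = a11 + a22, a11 * a22 - a12 * a21
    disc = math.sqrt(max(tr * tr - 4.0 * det, 0.0))
    disc = max(disc, 1e-12 * max(abs(tr), 1.0))  # guard the degenerate case
    lam = np.array([(tr + disc) / 2.0, (tr - disc) / 2.0])
    # eigenvectors (a12, lam - a11); amplitudes from C_P(0)=f/vP, C_I(0)=0
    V = np.array([[a12, a12], [lam[0] - a11, lam[1] - a11]])
    c = np.linalg.solve(V, np.array([f / vP, 0.0]))
    m = -lam
    alpha = vP * V[0, :] * c
    beta = vI * V[1, :] * c
    return m, alpha, beta


def residue_function(params: KineticParameterSet, t) -> np.ndarray:
    """Tissue residue function R_T(t): fraction of an impulse still in tissue.

    ETK's impulse response contains a vascular delta; for display and
    monotonicity checks it is represented here by the equivalent plug-flow box
    of width T_c = v_P/f (the delta is retained exactly in the concentration
    convolutions).
    """
    t = np.clip(np.asarray(t, dtype=float), 0.0, None)
    mid = params.model_id
    if mid == "TK":
        return np.exp(-params.kep() * t)
    if mid == "ETK":
        Tc = params.capillary_transit_time()
        return np.where(t < Tc, 1.0, params.extraction() * np.exp(-params.kep() * t))
    if mid == "2CX":
        m, alpha, beta = _two_cx_modes(params)
        return (np.exp(-np.multiply.outer(t, m)) @ (alpha + beta)) / params.f
    if mid == "AATH":
        Tc = params.capillary_transit_time()
        E, kep = params.extraction(), params.kep()
        return np.where(t < Tc, 1.0, E * np.exp(-kep * np.clip(t - Tc, 0.0, None)))
    # DP
    Tc = params.capillary_transit_time()
    a, k = params.ps / params.f, params.ps / params.v_I
    if params.ps == 0.0:
        return np.where(t < Tc, 1.0, 0.0)
    g = _dp_tail_spline(a, k, max(float(t.max()) - Tc, 1e-6))
    return np.where(t < Tc, 1.0, g(np.clip(t - Tc, 0.0, None)))


def compartment_impulse_responses(params: KineticParameterSet, t):
    """Per-compartment impulse kernels (Q_P, Q_I) on the time grid (mL/min/mL).

    Their sum is Q_T = f * R_T; the ETK vascular delta (area v_P) cannot be
    represented on a grid and is returned as zero here (see
    :class:`CompartmentCurves.q_p_delta_weight` in the full curves).
    """
    t = np.clip(np.asarray(t, dtype=float), 0.0, None)
    f = params.f
    mid = params.model_id
    if mid == "TK":
        return np.zeros_like(t), params.extraction() * f * np.exp(-params.kep() * t)
    if mid == "ETK":
        return np.zeros_like(t), params.extraction() * f * np.exp(-params.kep() * t)
    if mid == "2CX":
        m, alpha, beta = _two_cx_modes(params)
        ex = np.exp(-np.multiply.outer(t, m))
        return ex @ alpha, ex @ beta
    Tc = params.capillary_transit_time()
    Q_P = np.where(t < Tc, f, 0.0)
    if mid == "AATH":
        E, kep = params.extraction(), params.kep()
        Q_I = np.where(t < Tc, 0.0, E * f * np.exp(-kep * np.clip(t - Tc, 0.0, None)))
        return Q_P, Q_I
    a, k = params.ps / params.f, params.ps / params.v_I
    g = _dp_tail_spline(a, k, max(float(t.max()) - Tc, 1e-6))
    Q_I = np.where(t < Tc, 0.0, f * g(np.clip(t - Tc, 0.0, None)))
    return Q_P, Q_I


def impulse_response_integral(params: KineticParameterSet) -> float:
    """Exact integral of Q_T over [0, inf): tracer distribution volume.

    Equals v_P + v_I for the conservative vascular models and v_I for TK.
    """
    if params.model_id == "TK":
        return params.v_I
    return params.v_P + params.v_I


# ---------------------------------------------------------------------------
# tissue concentration curves
# ---------------------------------------------------------------------------


def tissue_concentration(
    params: KineticParameterSet,
    cin: ExponentialSumCurve | TracerInputModel,
    times,
    method: str = "analytic",
    oracle_dt: float = 5e-4,
) -> CompartmentCurves:
    """Compartment concentration curves for the dual input at given times.

    ``method='analytic'`` uses exact continuous-time convolution (closed form
    for exponential/box/delta pieces, Gauss-Legendre quadrature for the DP
    Bessel tail).  ``method='numeric_oracle'`` uses an independent fine-grid
    composite-trapezoid discrete convolution (step ``oracle_dt`` minutes,
    split at every kernel and input breakpoint) for validation.
    """
    t = np.asarray(times, dtype=float)
    if isinstance(cin, TracerInputModel):
        cin = cin.as_terms()
    if params.t_Lag_T > 0:
        cin = cin.delayed(params.t_Lag_T)
    if method == "analytic":
        vP_CbarP, vI_CbarI, delta_w = _analytic_compartments(params, cin, t)
    elif method == "numeric_oracle":
        vP_CbarP, vI_CbarI, delta_w = _oracle_compartments(params, cin, t, oracle_dt)
    else:
        raise ValueError("method must be 'analytic' or 'numeric_oracle'")

    Q_P, Q_I = compartment_impulse_responses(params, t)
    if params.model_id == "TK":
        Cbar_P = cin(t)  # plasma not modeled; pass-through for reference
        Cbar_I = vI_CbarI / params.v_I
        C_T = vI_CbarI
    else:
        Cbar_P = vP_CbarP / params.v_P
        Cbar_I = vI_CbarI / params.v_I
        C_T = vP_CbarP + vI_CbarI
    return CompartmentCurves(
        times=t,
        Q_P=Q_P,
        Q_I=Q_I,
        Q_T=Q_P + Q_I,
        R_T=residue_function(params, t),
        Cbar_P=Cbar_P,
        Cbar_I=Cbar_I,
        C_T=C_T,
        q_p_delta_weight=delta_w,
    )


def concentration_curves(params, cin, times):
    """Fast analytic path: (Cbar_P, Cbar_I, C_T) only, no impulse/residue arrays.

    Used inside fitting loops where the kernels themselves are not needed.
    """
    t = np.asarray(times, dtype=float)
    if isinstance(cin, TracerInputModel):
        cin = cin.as_terms()
    if params.t_Lag_T > 0:
        cin = cin.delayed(params.t_Lag_T)
    vP_CbarP, vI_CbarI, _ = _analytic_compartments(params, cin, t)
    if params.model_id == "TK":
        return cin(t), vI_CbarI / params.v_I, vI_CbarI
    return (
        vP_CbarP / params.v_P,
        vI_CbarI / params.v_I,
        vP_CbarP + vI_CbarI,
    )


def _analytic_compartments(params, cin, t):
    mid = params.model_id
    f = params.f
    if mid == "TK":
        kep = params.kep()
        vI = _conv_exp_terms(cin, params.extraction() * f, kep, 0.0, t)
        return np.zeros_like(t), vI, 0.0
    if mid == "ETK":
        kep = params.kep()
        vP = params.v_P * cin(t)
        vI = _conv_exp_terms(cin, params.extraction() * f, kep, 0.0, t)
        return vP, vI, params.v_P
    if mid == "2CX":
        m, alpha, beta = _two_cx_modes(params)
        vP = sum(_conv_exp_terms(cin, a_j, m_j, 0.0, t) for a_j, m_j in zip(alpha, m))
        vI = sum(_conv_exp_terms(cin, b_j, m_j, 0.0, t) for b_j, m_j in zip(beta, m))
        return vP, vI, 0.0
    Tc = params.capillary_transit_time()
    vP = _conv_box_terms(cin, f, Tc, t)
    if mid == "AATH":
        vI = _conv_exp_terms(cin, params.extraction() * f, params.kep(), Tc, t)
        return vP, vI, 0.0
    # DP
    a, k = params.ps / f, params.ps / params.v_I
    if params.ps == 0.0:
        return vP, np.zeros_like(t), 0.0
    g = _dp_tail_spline(a, k, max(float(t.max()) - Tc, 1e-6))
    vI = _conv_tail(cin, f, Tc, g, t)
    return vP, vI, 0.0


def _oracle_conv(kernel, breaks_kernel, cin, t, dt):
    """Composite-trapezoid convolution integral, split at all breakpoints."""
    out = np.zeros_like(t, dtype=float)
    for i, ti in enumerate(t):
        if ti <= 0:
            continue
        kinks = ti - cin.arrivals
        pts = np.unique(
            np.concatenate(
                [
                    [0.0, ti],
                    [b for b in breaks_kernel if 0.0 < b < ti],
                    kinks[(kinks > 0) & (kinks < ti)],
                ]
            )
        )
        total = 0.0
        for lo, hi in zip(pts[:-1], pts[1:]):
            n = max(2, int(math.ceil((hi - lo) / dt)) + 1)
            u = np.linspace(lo, hi, n)
            eps = 1e-12 * max(1.0, hi)
            u_eval = np.clip(u, lo + eps, hi - eps)
            total += np.trapezoid(kernel(u_eval) * cin(ti - u_eval), u)
        out[i] = total
    return out


def _oracle_compartments(params, cin, t, dt):
    mid = params.model_id
    f = params.f
    if mid in ("TK", "ETK"):
        kep, E = params.kep(), params.extraction()
        vI = _oracle_conv(lambda u: E * f * np.exp(-kep * u), [], cin, t, dt)
        if mid == "TK":
            return np.zeros_like(t), vI, 0.0
        return params.v_P * cin(t), vI, params.v_P
    if mid == "2CX":
        m, alpha, beta = _two_cx_modes(params)
        vP = _oracle_conv(
            lambda u: np.exp(-np.multiply.outer(u, m)) @ alpha, [], cin, t, dt
        )
        vI = _oracle_conv(
            lambda u: np.exp(-np.multiply.outer(u, m)) @ beta, [], cin, t, dt
        )
        return vP, vI, 0.0
    Tc = params.capillary_transit_time()
    vP = _oracle_conv(lambda u: np.where(u < Tc, f, 0.0), [Tc], cin, t, dt)
    if mid == "AATH":
        E, kep = params.extraction(), params.kep()
        vI = _oracle_conv(
            lambda u: np.where(u < Tc, 0.0, E * f * np.exp(-kep * np.clip(u - Tc, 0, None))),
            [Tc],
            cin,
            t,
            dt,
        )
        return vP, vI, 0.0
    # DP oracle: survival tail from an independent cumulative-trapezoid grid
    a, k = params.ps / f, params.ps / params.v_I
    if params.ps == 0.0:
        return vP, np.zeros_like(t), 0.0
    w_max = max(float(t.max()) - Tc, 1e-6)
    n_g = max(4, int(math.ceil(w_max / min(dt, 2e-4))) + 1)
    w_grid = np.linspace(0.0, w_max, n_g)
    phi = _dp_outflow_density(w_grid, a, k)
    cum = np.concatenate(
        [[0.0], np.cumsum(0.5 * (phi[1:] + phi[:-1]) * np.diff(w_grid))]
    )
    g_vals = np.clip(-math.expm1(-a) - cum, 0.0, None)

    def q_i(u):
        w = np.clip(u - Tc, 0.0, w_max)
        return np.where(u < Tc, 0.0, f * np.interp(w, w_grid, g_vals))

    vI = _oracle_conv(q_i, [Tc], cin, t, dt)
    return vP, vI, 0.0


# ---------------------------------------------------------------------------
# derived hemodynamic report
# ---------------------------------------------------------------------------


def derived_parameters(
    params: KineticParameterSet, consts: ConversionConstants | None = None
) -> dict:
    """Full hemodynamic report in conventional liver-perfusion units.

    Blood flows in mL/min/100 g convert plasma flow through the large-vessel
    hematocrit, BF = f*100/(rho_T*(1-H_LV)); blood volume through the
    small-vessel hematocrit, v_B = v_P/(1-H_SV), BV = v_B*100/rho_T.  PS stays
    plasma-referred, PS = ps*100/rho_T.  MTT follows the central volume
    principle MTT = (v_P + v_I)/f.
    """
    consts = consts or ConversionConstants()
    E = params.extraction()
    ps = params.ps_equivalent()
    if params.model_id == "TK":
        v_B = 0.0
    else:
        v_B = params.v_B(consts)
    BF = params.f * 100.0 / (consts.rho_T * (1.0 - consts.H_LV))
    report = {
        "model_id": params.model_id,
        "f": params.f,
        "gamma": params.gamma,
        "BF": BF,
        "BF_A": params.gamma * BF,
        "BF_PV": (1.0 - params.gamma) * BF,
        "v_P": params.v_P,
        "v_B": v_B,
        "BV": v_B * 100.0 / consts.rho_T,
        "v_I": params.v_I,
        "v_C": params.v_C(consts),
        "MTT": (params.v_P + params.v_I) / params.f,
        "E": E,
        "ps": ps,
        "PS": ps * 100.0 / consts.rho_T,
        "Ktrans": E * params.f,
        "t_Lag_T": params.t_Lag_T,
    }
    return report
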