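"""Parametric vascular input functions and precontrast relaxometry.

The liver receives a dual blood supply, so pharmacokinetic analysis needs two
measured input curves: an arterial input function (AIF) sampled in the aorta
and a portal-venous input function (PVIF) sampled in the main portal vein.
Both are modeled here as causal sums of exponentials,

    c(t) = sum_i A_i * exp(-mu_i * (t - t0)),   t >= t0,

with the amplitude constraint ``sum_i A_i = 0`` so the curve rises
continuously from zero at the bolus arrival time ``t0``.  An optional
recirculation echo adds the same shape delayed and scaled.  This family is
closed under convolution with exponential residue modes, which is what makes
fully analytic tissue concentration curves possible downstream.

The module also provides the plumbing between the MR signal domain and the
concentration domain: spoiled-gradient-echo (SPGR) signal inversion for blood
enhancement curves, and variable-flip-angle (VFA) precontrast T1 estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares


class DegenerateModelError(ValueError):
    """Raised when an input model's rate constants are not distinct."""


class FitError(RuntimeError):
    """Raised when a fit is structurally impossible (degenerate data)."""


# ---------------------------------------------------------------------------
# exponential-sum curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExponentialSumCurve:
    """Causal sum of exponential terms with per-term arrival times.

    Each term contributes ``A * exp(-mu * (t - t0))`` for ``t >= t0`` and 0
    before.  This is the general container that dual-input mixing and delays
    map into; :class:`TracerInputModel` is the constrained user-facing form.
    """

    amplitudes: np.ndarray  # mM
    rates: np.ndarray  # 1/min, all > 0
    arrivals: np.ndarray  # min, per-term bolus arrival

    def __post_init__(self):
        amps = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        rates = np.atleast_1d(np.asarray(self.rates, dtype=float))
        arr = np.atleast_1d(np.asarray(self.arrivals, dtype=float))
        if not (amps.shape == rates.shape == arr.shape):
            raise ValueError("amplitudes, rates and arrivals must have equal length")
        if np.any(rates <= 0):
            raise ValueError("all decay rates mu_i must be > 0")
        object.__setattr__(self, "amplitudes", amps)
        object.__setattr__(self, "rates", rates)
        object.__setattr__(self, "arrivals", arr)

    def __call__(self, times) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        tau = t[..., None] - self.arrivals
        out = np.where(tau >= 0.0, np.exp(-self.rates * np.clip(tau, 0.0, None)), 0.0)
        return out @ self.amplitudes

    @classmethod
    def _unchecked(cls, amplitudes, rates, arrivals) -> "ExponentialSumCurve":
        """Fast constructor for internal arithmetic on already-valid arrays."""
        obj = object.__new__(cls)
        object.__setattr__(obj, "amplitudes", amplitudes)
        object.__setattr__(obj, "rates", rates)
        object.__setattr__(obj, "arrivals", arrivals)
        return obj

    def delayed(self, delay: float) -> "ExponentialSumCurve":
        return self._unchecked(self.amplitudes, self.rates, self.arrivals + delay)

    def scaled(self, factor: float) -> "ExponentialSumCurve":
        return self._unchecked(self.amplitudes * factor, self.rates, self.arrivals)

    def __add__(self, other: "ExponentialSumCurve") -> "ExponentialSumCurve":
        return self._unchecked(
            np.concatenate([self.amplitudes, other.amplitudes]),
            np.concatenate([self.rates, other.rates]),
            np.concatenate([self.arrivals, other.arrivals]),
        )

    def integral(self) -> float:
        """Integral over [0, inf); finite because all rates are positive."""
        return float(np.sum(self.amplitudes / self.rates))


@dataclass(frozen=True)
class TracerInputModel:
    """Parametric AIF/PVIF: causal sums of exponentials starting at zero.

    Parameters
    ----------
    bolus_arrival_t0:
        First-pass bolus arrival time in minutes.
    amplitudes, rates:
        Term amplitudes A_i (mM) and decay constants mu_i (1/min).  Rates must
        be positive and pairwise distinct (closed-form convolutions divide by
        rate differences).  ``sum(A_i)`` must be ~0 so the curve is continuous
        at ``t0``.
    recirculation_delay, recirculation_fraction:
        Optional recirculation echo: the same curve delayed by
        ``recirculation_delay`` minutes and scaled by the fraction.
    """

    bolus_arrival_t0: float
    amplitudes: np.ndarray
    rates: np.ndarray
    recirculation_delay: float | None = None
    recirculation_fraction: float = 0.0

    _RATE_DISTINCT_TOL = 1e-8

    def __post_init__(self):
        amps = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        rates = np.atleast_1d(np.asarray(self.rates, dtype=float))
        if amps.shape != rates.shape:
            raise ValueError("amplitudes and rates must have equal length")
        if np.any(rates <= 0):
            raise ValueError("all decay rates mu_i must be > 0")
        d = np.abs(rates[:, None] - rates[None, :])
        np.fill_diagonal(d, np.inf)
        if d.min() < self._RATE_DISTINCT_TOL:
            raise DegenerateModelError("rate constants mu_i must be distinct")
        if abs(amps.sum()) > 1e-6 * max(1.0, np.abs(amps).max()):
            raise ValueError(
                "amplitudes must sum to 0 so the curve starts continuously at t0"
            )
        if not 0.0 <= self.recirculation_fraction <= 1.0:
            raise ValueError("recirculation_fraction must be in [0, 1]")
        object.__setattr__(self, "amplitudes", amps)
        object.__setattr__(self, "rates", rates)

    @property
    def n_exp(self) -> int:
        return self.amplitudes.size

    def as_terms(self) -> ExponentialSumCurve:
        """Expand to the generic term representation (recirculation folded in)."""
        base = ExponentialSumCurve(
            self.amplitudes,
            self.rates,
            np.full(self.n_exp, float(self.bolus_arrival_t0)),
        )
        if self.recirculation_delay is not None and self.recirculation_fraction > 0:
            echo = base.delayed(self.recirculation_delay).scaled(
                self.recirculation_fraction
            )
            return base + echo
        return base

    def __call__(self, times) -> np.ndarray:
        return self.as_terms()(times)

    def integral(self) -> float:
        return self.as_terms().integral()


def evaluate_input(model, times) -> np.ndarray:
    """Evaluate a tracer input model (mM) at the given times (min).

    Accepts :class:`TracerInputModel` or any :class:`ExponentialSumCurve`;
    exactly zero before bolus arrival, vectorized and order-preserving.
    """
    t = np.asarray(times, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("times must be finite")
    return model(t)


@dataclass(frozen=True)
class MeasuredInputCurve:
    """ROI-mean relative signal enhancement at a vascular site."""

    times: np.ndarray  # min, strictly increasing
    enhancement: np.ndarray  # dimensionless
    site: str  # "aorta" | "portal_vein"

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.enhancement, dtype=float)
        if t.shape != e.shape or t.ndim != 1:
            raise ValueError("times and enhancement must be equal-length 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(e)):
            raise ValueError("enhancement must be finite")
        if self.site not in ("aorta", "portal_vein"):
            raise ValueError("site must be 'aorta' or 'portal_vein'")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "enhancement", e)


def fit_input_model(
    curve: MeasuredInputCurve,
    concentrations: np.ndarray,
    n_exp: int = 3,
    seed: int = 0,
    n_starts: int = 8,
    with_recirculation: bool = False,
) -> tuple[TracerInputModel, float]:
    """Least-squares fit of the sums-of-exponentials input model.

    The start-at-zero constraint is enforced structurally: the last amplitude
    is ``-(A_1 + ... + A_{n-1})``.  Multi-start (seeded) trust-region least
    squares; returns ``(model, ssr)``.  A fit that never converges raises
    :class:`FitError` rather than returning silently.
    """
    t = curve.times
    conc = np.asarray(concentrations, dtype=float)
    if conc.shape != t.shape:
        raise ValueError("concentrations must match curve.times")
    if t.size < 2 * n_exp + 1:
        raise FitError(f"need at least {2 * n_exp + 1} samples for n_exp={n_exp}")
    scale = float(np.abs(conc).max())
    if scale <= 0:
        raise FitError("degenerate input: concentration curve is identically zero")

    rng = np.random.default_rng(seed)
    t_first = float(t[np.argmax(conc > 0.01 * scale)])

    def unpack(x):
        t0 = x[0]
        amps_free = x[1 : n_exp]
        rates = np.sort(np.exp(x[n_exp:]))[::-1]
        amps = np.concatenate([amps_free, [-amps_free.sum()]])
        return t0, amps, rates

    def resid(x):
        t0, amps, rates = unpack(x)
        d = np.abs(rates[:, None] - rates[None, :])
        np.fill_diagonal(d, np.inf)
        if d.min() < 1e-6:
            rates = rates * (1.0 + 1e-5 * np.arange(n_exp))
        esc = ExponentialSumCurve(amps, rates, np.full(n_exp, t0))
        return esc(t) - conc

    best = None
    lo = np.concatenate([[0.0], -50 * scale * np.ones(n_exp - 1), np.full(n_exp, -4.0)])
    hi = np.concatenate(
        [[max(t_first, t[2])], 50 * scale * np.ones(n_exp - 1), np.full(n_exp, 6.0)]
    )
    for _ in range(n_starts):
        x0 = np.concatenate(
            [
                [max(0.0, t_first * rng.uniform(0.3, 1.0))],
                scale * rng.uniform(-2, 2, n_exp - 1),
                rng.uniform(-2, 4, n_exp),
            ]
        )
        try:
            sol = least_squares(resid, x0, bounds=(lo, hi), method="trf")
        except Exception:  # pragma: no cover - optimizer edge cases
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise FitError("input-function fit did not converge from any start")
    t0, amps, rates = unpack(best.x)
    model = TracerInputModel(t0, amps, rates)
    if with_recirculation:
        model = replace(model, recirculation_delay=0.5, recirculation_fraction=0.1)
    return model, float(2.0 * best.cost)


# ---------------------------------------------------------------------------
# SPGR signal model and inversions
# ---------------------------------------------------------------------------


def spgr_signal_scalar(R1, M0: float, TR_ms: float, flip_deg: float) -> np.ndarray:
    """Steady-state SPGR signal  M0 sin(a) (1-E1)/(1-cos(a) E1),  E1=exp(-TR*R1)."""
    R1 = np.asarray(R1, dtype=float)
    a = np.deg2rad(flip_deg)
    E1 = np.exp(-(TR_ms / 1000.0) * R1)
    return M0 * np.sin(a) * (1.0 - E1) / (1.0 - np.cos(a) * E1)


class EnhancementRangeError(ValueError):
    """SPGR inversion requested outside the invertible branch."""


def blood_signal_to_concentration(
    curve: MeasuredInputCurve,
    R10_blood: float,
    r1: float = 4.5,
    TR_ms: float = 5.0,
    flip_deg: float = 15.0,
    H_LV: float = 0.45,
) -> np.ndarray:
    """Convert blood relative enhancement to plasma tracer concentration (mM).

    Inverts the single-pool SPGR equation for R1(t) given the precontrast
    ``R10_blood`` (1/s), then ``C_blood = (R1 - R10)/r1`` and
    ``C_plasma = C_blood / (1 - H_LV)``.
    """
    if not 0.0 <= H_LV < 1.0:
        raise ValueError("H_LV must be in [0, 1)")
    e = curve.enhancement
    if np.any(e <= -1.0):
        raise EnhancementRangeError("enhancement must be > -1")
    TR_s = TR_ms / 1000.0
    cos_a = np.cos(np.deg2rad(flip_deg))
    E10 = np.exp(-TR_s * R10_blood)
    # S(t)/S0 scaling of the saturation factor
    rho = (1.0 + e) * (1.0 - E10) / (1.0 - cos_a * E10)
    E1 = (1.0 - rho) / (1.0 - rho * cos_a)
    bad = (E1 <= 0.0) | (E1 >= 1.0)
    if np.any(bad):
        idx = int(np.flatnonzero(bad)[0])
        raise EnhancementRangeError(
            f"enhancement at sample index {idx} is outside the invertible SPGR "
            f"range for TR={TR_ms} ms, flip={flip_deg} deg"
        )
    R1 = -np.log(E1) / TR_s
    C_blood = (R1 - R10_blood) / r1
    return C_blood / (1.0 - H_LV)


# ---------------------------------------------------------------------------
# variable-flip-angle T1 mapping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VfaSeries:
    """Precontrast SPGR signals at several flip angles, fixed TR (ms)."""

    flip_angles: np.ndarray  # degrees
    signals: np.ndarray  # a.u.
    TR: float  # ms

    def __post_init__(self):
        fa = np.asarray(self.flip_angles, dtype=float)
        s = np.asarray(self.signals, dtype=float)
        if fa.shape != s.shape or fa.ndim != 1:
            raise ValueError("flip_angles and signals must be equal-length 1-D arrays")
        if np.any(s < 0):
            raise ValueError("signals must be >= 0")
        if self.TR <= 0:
            raise ValueError("TR must be > 0")
        object.__setattr__(self, "flip_angles", fa)
        object.__setattr__(self, "signals", s)


def vfa_t1_fit(series: VfaSeries) -> tuple[float, float]:
    """Fit (R10 [1/s], M0) from a variable-flip-angle SPGR series.

    Uses the standard linearization S/sin(a) = E1 * S/tan(a) + M0 (1 - E1)
    followed by a nonlinear refinement of the full SPGR equation.
    """
    fa = series.flip_angles
    if np.unique(fa).size < 2:
        raise FitError("VFA fit is underdetermined with fewer than 2 distinct angles")
    if np.any(series.signals <= 0):
        raise ValueError("VFA signals must be positive for a T1 fit")
    a = np.deg2rad(fa)
    y = series.signals / np.sin(a)
    x = series.signals / np.tan(a)
    slope, intercept = np.polyfit(x, y, 1)
    slope = float(np.clip(slope, 1e-12, 1.0 - 1e-12))
    TR_s = series.TR / 1000.0
    R1_lin = -np.log(slope) / TR_s
    M0_lin = max(float(intercept) / (1.0 - slope), 1e-12)

    def spgr_signal_vec(R1, M0):
        E1 = np.exp(-TR_s * R1)
        return M0 * np.sin(a) * (1.0 - E1) / (1.0 - np.cos(a) * E1)

    def resid(p):
        return spgr_signal_vec(p[0], p[1]) - series.signals

    sol = least_squares(
        resid, x0=np.array([max(R1_lin, 1e-3), M0_lin]),
        bounds=([1e-6, 1e-12], [np.inf, np.inf]),
    )
    R10, M0 = sol.x
    return float(R10), float(M0)
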