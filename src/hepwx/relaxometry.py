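"""Water-exchange-modified SPGR signal models (2SX and 3S2X).

The standard DCE-MRI analysis assumes the fast exchange limit (FXL): water
moves between compartments so quickly, relative to the difference in their
longitudinal relaxation rates, that the tissue relaxes mono-exponentially
with a population-weighted R1.  After a gadolinium bolus the plasma and
interstitium relax much faster than the cells, so the FXL is transiently
violated.  The shutter-speed formalism keeps finite mean water lifetimes:

* 2SX  - two sites, cell <-> interstitium (used with the TK model, where the
  vascular signal fraction is negligible);
* 3S2X - three sites in a chain, blood <-> interstitium <-> cell (used with
  the vascular models ETK/2CX/AATH/DP).

Longitudinal magnetization follows the Bloch-McConnell equations
``dm/dt = -B(t) m + c`` with ``B(t) = diag(R1_j(t)) + X`` where X is the
exchange generator (columns sum to zero; rates obey detailed balance with
the water population fractions).  Under an SPGR pulse train the steady-state
longitudinal magnetization just before each pulse is

    m = (I - cos(a) e^{-B TR})^{-1} (I - e^{-B TR}) B^{-1} c,

with c_j = R1_j p_j M0, and the signal is sin(a) * sum_j m_j.  Because the
tracer concentrations change on a seconds scale while TR is milliseconds,
B is treated as quasi-static within each dynamic frame.

Detailed balance makes B similar to a symmetric matrix through
D = diag(sqrt(p)); all matrix functions are evaluated by a vectorized
symmetric eigen-decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class DegenerateExchangeError(ValueError):
    """Raised when the relaxation-exchange generator is singular/invalid."""


@dataclass(frozen=True)
class WaterExchangeParameters:
    """Mean water lifetimes (seconds) in blood and cell.

    ``tau_C`` is the mean intracellular water lifetime (the cellular biomarker
    of interest, PS_C = V_C/tau_C), ``tau_B`` the mean intravascular lifetime.
    The interstitial lifetime and all four transfer rates follow from
    detailed balance with the water population fractions and are returned by
    :meth:`rates`.
    """

    tau_C: float
    tau_B: float = 0.5

    def __post_init__(self):
        if self.tau_C <= 0 or self.tau_B <= 0:
            raise ValueError("water lifetimes must be > 0")

    def rates(self, p_B: float, p_I: float, p_C: float) -> dict:
        """Water transfer rates (1/s) satisfying detailed balance.

        K_BI = 1/tau_B, K_CI = 1/tau_C, with the reverse rates scaled by the
        population ratio; 1/tau_I = K_IB + K_IC.
        """
        if p_I <= 0:
            raise DegenerateExchangeError("interstitial water fraction must be > 0")
        K_BI = 1.0 / self.tau_B
        K_CI = 1.0 / self.tau_C
        K_IB = p_B * K_BI / p_I
        K_IC = p_C * K_CI / p_I
        return {
            "K_BI": K_BI,
            "K_IB": K_IB,
            "K_CI": K_CI,
            "K_IC": K_IC,
            "tau_I": 1.0 / (K_IB + K_IC) if (K_IB + K_IC) > 0 else np.inf,
        }


@dataclass(frozen=True)
class RelaxationParameters:
    """Precontrast relaxation rates per site and SPGR readout settings.

    R1 rates in 1/s (defaults: blood T1 = 1200 ms, tissue sites 586 ms at
    1.5 T), relaxivity r1 in 1/s/mM, TR in ms, flip in degrees.
    """

    R1B0: float = 1.0 / 1.2
    R1I0: float = 1.0 / 0.586
    R1C0: float = 1.0 / 0.586
    r1: float = 4.5
    TR: float = 5.0
    flip: float = 15.0
    M0: float = 1.0

    def __post_init__(self):
        if min(self.R1B0, self.R1I0, self.R1C0, self.r1, self.TR, self.M0) <= 0:
            raise ValueError("relaxation rates, r1, TR and M0 must be > 0")
        if not 0.0 < self.flip <= 90.0:
            raise ValueError("flip angle must be in (0, 90] degrees")


def spgr_signal(R1, relax: RelaxationParameters):
    """Single-pool SPGR steady-state signal for relaxation rate R1 (1/s)."""
    R1 = np.asarray(R1, dtype=float)
    if np.any(R1 <= 0):
        raise ValueError("R1 must be > 0")
    a = np.deg2rad(relax.flip)
    E1 = np.exp(-(relax.TR / 1000.0) * R1)
    return relax.M0 * np.sin(a) * (1.0 - E1) / (1.0 - np.cos(a) * E1)


def exchange_matrix(p: np.ndarray, wx: WaterExchangeParameters) -> np.ndarray:
    """Exchange generator X for the site chain (columns sum to zero).

    3 sites: order (blood, interstitium, cell), exchange B<->I and I<->C.
    2 sites: order (interstitium, cell).
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0):
        raise DegenerateExchangeError("water population fractions must be > 0")
    p = p / p.sum()
    if p.size == 3:
        r = wx.rates(p[0], p[1], p[2])
        return np.array(
            [
                [r["K_BI"], -r["K_IB"], 0.0],
                [-r["K_BI"], r["K_IB"] + r["K_IC"], -r["K_CI"]],
                [0.0, -r["K_IC"], r["K_CI"]],
            ]
        )
    if p.size == 2:
        r = wx.rates(0.0, p[0], p[1])
        return np.array(
            [[r["K_IC"], -r["K_CI"]], [-r["K_IC"], r["K_CI"]]]
        )
    raise ValueError("exchange chain supports 2 or 3 sites")


def _site_r1(Cbar_P, Cbar_I, relax: RelaxationParameters, H_SV: float, n_sites: int):
    """Per-site R1(t) stacks.  Plasma tracer relaxes all blood water, hence
    the (1 - H_SV) dilution from plasma to whole-blood concentration."""
    Cbar_I = np.asarray(Cbar_I, dtype=float)
    if n_sites == 3:
        Cbar_P = np.asarray(Cbar_P, dtype=float)
        R1B = relax.R1B0 + relax.r1 * (1.0 - H_SV) * Cbar_P
        R1I = relax.R1I0 + relax.r1 * Cbar_I
        R1C = np.full_like(R1I, relax.R1C0)
        return np.stack([R1B, R1I, R1C], axis=-1)
    R1I = relax.R1I0 + relax.r1 * Cbar_I
    R1C = np.full_like(R1I, relax.R1C0)
    return np.stack([R1I, R1C], axis=-1)


def _steady_state_signal(R1_sites: np.ndarray, p: np.ndarray, X: np.ndarray,
                         relax: RelaxationParameters) -> np.ndarray:
    """Pre-pulse steady-state SPGR signal for stacked per-site R1 (T, n)."""
    TR_s = relax.TR / 1000.0
    cos_a = np.cos(np.deg2rad(relax.flip))
    sin_a = np.sin(np.deg2rad(relax.flip))
    sqrt_p = np.sqrt(p)
    S_X = (X * sqrt_p[None, :]) / sqrt_p[:, None]
    S_X = 0.5 * (S_X + S_X.T)  # symmetric by detailed balance; enforce exactly
    n = p.size
    S = np.broadcast_to(S_X, (R1_sites.shape[0], n, n)).copy()
    ii = np.arange(n)
    S[:, ii, ii] += R1_sites
    lam, U = np.linalg.eigh(S)
    if np.any(lam <= 0):
        raise DegenerateExchangeError("relaxation-exchange generator not positive")
    c = R1_sites * p * relax.M0  # (T, n)
    z = np.einsum("tjk,tj->tk", U, c / sqrt_p)
    e = np.exp(-lam * TR_s)
    h = (1.0 - e) / ((1.0 - cos_a * e) * lam)
    m = sqrt_p * np.einsum("tjk,tk->tj", U, h * z)
    return sin_a * m.sum(axis=-1)


def wx_signal(
    Cbar_P,
    Cbar_I,
    fractions,
    wx: WaterExchangeParameters,
    relax: RelaxationParameters,
    n_sites: int = 3,
    H_SV: float = 0.25,
) -> np.ndarray:
    """Water-exchange-modified relative enhancement E_T(t).

    Parameters
    ----------
    Cbar_P, Cbar_I:
        Mean plasma / interstitial tracer concentrations over time (mM).
        ``Cbar_P`` is ignored for ``n_sites=2``.
    fractions:
        Water population fractions, ``(v_B, v_I, v_C)`` for 3S2X or
        ``(v_I, v_C)`` for 2SX (renormalized internally); water density is
        assumed equal across sites.
    """
    if n_sites not in (2, 3):
        raise ValueError("n_sites must be 2 or 3")
    p = np.asarray(fractions, dtype=float)
    if p.size != n_sites:
        raise ValueError(f"need {n_sites} volume fractions, got {p.size}")
    if np.any(p <= 0):
        raise DegenerateExchangeError("volume fractions must be > 0")
    p = p / p.sum()
    X = exchange_matrix(p, wx)
    R1 = _site_r1(Cbar_P, Cbar_I, relax, H_SV, n_sites)
    R1_0 = _site_r1(
        np.zeros(1), np.zeros(1), relax, H_SV, n_sites
    )
    S = _steady_state_signal(R1, p, X, relax)
    S0 = _steady_state_signal(R1_0, p, X, relax)[0]
    return S / S0 - 1.0


def fxl_signal(
    Cbar_P,
    Cbar_I,
    fractions,
    relax: RelaxationParameters,
    n_sites: int = 3,
    H_SV: float = 0.25,
) -> np.ndarray:
    """Fast-exchange-limit enhancement: single pool, population-weighted R1."""
    p = np.asarray(fractions, dtype=float)
    if p.size != n_sites:
        raise ValueError(f"need {n_sites} volume fractions, got {p.size}")
    p = p / p.sum()
    R1 = _site_r1(Cbar_P, Cbar_I, relax, H_SV, n_sites)
    R1_eff = R1 @ p
    R1_eff0 = _site_r1(np.zeros(1), np.zeros(1), relax, H_SV, n_sites)[0] @ p
    return spgr_signal(R1_eff, relax) / spgr_signal(R1_eff0, relax) - 1.0
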