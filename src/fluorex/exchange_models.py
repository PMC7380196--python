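"""Closed-form two-state chemical-exchange models for 19F NMR.

This module collects the analytic expressions that the rest of the package
fits, simulates against, or inverts:

* the constant-time CPMG observable ``R2,eff = -ln(I/I0)/T_CPMG``;
* the Luz-Meiboom fast-exchange dispersion model, in which populations and
  shift difference enter only through the composite ``c = pA*pB*dw**2``;
* the Carver-Richards all-timescale two-state dispersion model;
* the Forsen-Hoffman saturation-transfer intensity decay for slow exchange;
* the slow-exchange thermodynamic identities ``k_s = k_mn + k_nm``,
  ``p_n = k_mn/k_s`` and ``dG = -RT ln(p_n/p_m)``.

Everything here is a pure function of its arguments; fitting lives in
:mod:`fluorex.fitting` and numerical simulation in
:mod:`fluorex.bloch_mcconnell`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import R_KCAL, T_DEFAULT

__all__ = [
    "CPMGPoint",
    "CPMGDataset",
    "TwoStateFastParams",
    "LuzMeiboomParams",
    "SlowExchangeParams",
    "r2_effective",
    "luz_meiboom_r2",
    "carver_richards_r2",
    "slow_exchange_intensity",
    "derive_slow_exchange_thermo",
    "delta_omega_from_ppm",
    "ppm_from_delta_omega",
]

#: Tolerated undershoot of the arccosh argument below 1 before an error is
#: raised; smaller violations are floating-point round-off and are clamped.
ARCCOSH_CLAMP_TOL = 1e-9


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CPMGPoint:
    """One point of a dispersion series.

    ``nu_cpmg`` is the refocusing frequency 0.5/tau_cpmg (s^-1) with
    tau_cpmg the spacing between consecutive 180-degree pulses;
    ``intensity`` the peak intensity at that frequency (a.u.).
    """

    nu_cpmg: float
    intensity: float

    def __post_init__(self) -> None:
        if not self.nu_cpmg > 0:
            raise ValueError(f"nu_cpmg must be positive, got {self.nu_cpmg}")
        if not math.isfinite(self.intensity):
            raise ValueError("intensity must be finite")


@dataclass(frozen=True)
class CPMGDataset:
    """A single-field, single-condition constant-time CPMG dispersion series."""

    spectrometer_freq: float  # 19F Larmor frequency, MHz
    constant_time: float  # T_CPMG, s
    reference_intensity: float  # I0, intensity without the CT block, a.u.
    points: tuple[CPMGPoint, ...]
    condition: str = "apo"  # "apo" | "ligand"
    resonance: str = "active"  # "active" | "inactive"

    def __post_init__(self) -> None:
        if not self.constant_time > 0:
            raise ValueError("constant_time must be positive")
        if not self.reference_intensity > 0:
            raise ValueError("reference_intensity must be positive")
        if len(self.points) < 2:
            raise ValueError("a dispersion series needs at least 2 points")

    @property
    def nu_cpmg(self) -> np.ndarray:
        return np.array([p.nu_cpmg for p in self.points])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([p.intensity for p in self.points])

    def r2_eff(self) -> np.ndarray:
        """Effective transverse rates for every point (vectorised Eq. of
        the constant-time observable)."""
        return r2_effective(
            self.intensities, self.reference_intensity, self.constant_time
        )


@dataclass(frozen=True)
class TwoStateFastParams:
    """Carver-Richards parameters of a millisecond two-state equilibrium.

    ``k_i`` is the total exchange rate (sum of the forward and reverse
    rates); ``p_a``/``p_b`` the state populations; ``delta_delta`` the
    magnitude of the chemical-shift difference in ppm; ``r2_0`` the
    exchange-free transverse rate of the dataset the parameters refer to.
    """

    k_i: float
    p_a: float
    p_b: float
    delta_delta: float
    r2_0: float = 0.0

    def __post_init__(self) -> None:
        if not math.isclose(self.p_a + self.p_b, 1.0, abs_tol=1e-9):
            raise ValueError("populations must sum to 1")
        if self.k_i < 0 or self.r2_0 < 0:
            raise ValueError("rates must be non-negative")
        if self.delta_delta < 0:
            raise ValueError("delta_delta is a magnitude, must be >= 0")


@dataclass(frozen=True)
class LuzMeiboomParams:
    """Fast-exchange dispersion parameters: only the apparent rate ``k_app``
    and the composite ``c = pA*pB*dw**2`` (s^-2) are identifiable."""

    k_app: float
    c: float
    r2_0: float = 0.0

    def __post_init__(self) -> None:
        if self.k_app < 0 or self.c < 0 or self.r2_0 < 0:
            raise ValueError("k_app, c and r2_0 must be non-negative")


@dataclass(frozen=True)
class SlowExchangeParams:
    """Second-timescale two-state exchange with derived thermodynamics.

    ``k_mn`` is the inactive-to-active rate, ``k_nm`` the reverse;
    ``delta_g`` is the free-energy difference in kcal/mol in the direction
    named by ``delta_g_direction`` (default G_active - G_inactive: positive
    when the inactive state is the more populated, hence lower-lying, one).
    """

    k_mn: float
    k_nm: float
    k_s: float
    p_active: float
    p_inactive: float
    delta_g: float
    delta_g_direction: str = "active_minus_inactive"
    temperature: float = T_DEFAULT
    condition: str = "apo"
    uncertainties: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not math.isclose(self.k_s, self.k_mn + self.k_nm, rel_tol=1e-9):
            raise ValueError("k_s must equal k_mn + k_nm")
        if not math.isclose(self.p_active + self.p_inactive, 1.0, abs_tol=1e-9):
            raise ValueError("populations must sum to 1")
        # detailed balance holds by construction of the populations
        if not math.isclose(
            self.p_active * self.k_nm, self.p_inactive * self.k_mn, rel_tol=1e-6
        ):
            raise ValueError("populations violate detailed balance")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def r2_effective(intensity, reference_intensity, constant_time):
    """Effective transverse relaxation rate from constant-time intensities.

    R2,eff = -(1/T_CPMG) * ln(I / I0).  Accepts scalars or arrays for
    ``intensity``.  May legitimately return small negative values when noise
    pushes I above I0.
    """
    intensity = np.asarray(intensity, dtype=float)
    if not constant_time > 0:
        raise ValueError("constant_time must be positive")
    if not reference_intensity > 0:
        raise ValueError("reference_intensity must be positive")
    if np.any(intensity <= 0):
        raise ValueError("intensity must be positive (log undefined otherwise)")
    out = -np.log(intensity / reference_intensity) / constant_time
    return float(out) if out.ndim == 0 else out


def luz_meiboom_r2(nu_cpmg, params: LuzMeiboomParams):
    """Fast-exchange dispersion profile.

    R2,eff(nu) = (c/k_app) * [1 - (4 nu/k_app) tanh(k_app/(4 nu))] + R2,0.
    Monotonically non-increasing in nu; tends to R2,0 as nu -> infinity.
    """
    nu = np.asarray(nu_cpmg, dtype=float)
    if np.any(nu <= 0):
        raise ValueError("nu_cpmg must be positive")
    if params.c == 0:
        out = np.full_like(nu, params.r2_0)
        return float(out) if out.ndim == 0 else out
    if params.k_app == 0:
        raise ValueError("k_app = 0 with c > 0 is undefined")
    x = params.k_app / (4.0 * nu)
    out = (params.c / params.k_app) * (1.0 - np.tanh(x) / x) + params.r2_0
    return float(out) if out.ndim == 0 else out


def _safe_arccosh(arg):
    """arccosh with the documented clamp at 1 for round-off undershoot."""
    arg = np.asarray(arg, dtype=float)
    bad = arg < 1.0 - ARCCOSH_CLAMP_TOL
    if np.any(bad):
        raise FloatingPointError(
            "arccosh argument below 1 beyond numerical tolerance "
            f"(min = {arg.min():.12g}); the parameters are outside the "
            "model's domain of validity"
        )
    return np.arccosh(np.maximum(arg, 1.0))


def carver_richards_r2(nu_cpmg, params: TwoStateFastParams, delta_omega: float):
    """Carver-Richards two-state dispersion profile.

    Valid across slow-to-fast exchange regimes.  With

        psi  = (pB - pA)^2 k^2 - dw^2 + 4 pA pB k^2
        xi   = 2 dw (pB - pA) k
        eta+- = (1/(sqrt(8) nu)) sqrt(+-psi + sqrt(psi^2 + xi^2))
        D+-  = 0.5 [+-1 + (psi + 2 dw^2)/sqrt(psi^2 + xi^2)]

    the profile is

        R2,eff = R2,0 + 0.5 (k - 2 nu arccosh(D+ cosh(eta+) - D- cos(eta-))).

    Symmetric under pA <-> pB and under the sign of ``delta_omega``; returns
    R2,0 for dw = 0 or a vanishing minor population.
    """
    nu = np.asarray(nu_cpmg, dtype=float)
    if np.any(nu <= 0):
        raise ValueError("nu_cpmg must be positive")
    pa, pb, k = params.p_a, params.p_b, params.k_i
    dw = float(delta_omega)
    if not (0.0 <= pb <= 1.0):
        raise ValueError("p_b must lie in [0, 1]")

    psi = (pb - pa) ** 2 * k * k - dw * dw + 4.0 * pb * pa * k * k
    xi = 2.0 * dw * (pb - pa) * k
    root = math.hypot(psi, xi)
    if root == 0.0:  # no exchange broadening at all
        out = np.full_like(nu, params.r2_0)
        return float(out) if out.ndim == 0 else out

    eta_p = np.sqrt(np.maximum(psi + root, 0.0)) / (math.sqrt(8.0) * nu)
    eta_m = np.sqrt(np.maximum(-psi + root, 0.0)) / (math.sqrt(8.0) * nu)
    d_p = 0.5 * (1.0 + (psi + 2.0 * dw * dw) / root)
    d_m = 0.5 * (-1.0 + (psi + 2.0 * dw * dw) / root)

    # cosh overflows for eta+ >~ 700; switch to the asymptotic log form
    # arccosh(z) ~ ln(2 z) with z ~ D+ exp(eta+)/2 well before that.
    eta_p = np.atleast_1d(eta_p)
    eta_m = np.atleast_1d(eta_m)
    big = eta_p > 350.0
    acosh = np.empty_like(eta_p)
    small = ~big
    if np.any(small):
        z = d_p * np.cosh(eta_p[small]) - d_m * np.cos(eta_m[small])
        acosh[small] = _safe_arccosh(z)
    if np.any(big):
        acosh[big] = math.log(d_p) + eta_p[big]
    acosh = acosh.reshape(np.shape(nu)) if np.ndim(nu) else acosh[0]

    out = params.r2_0 + 0.5 * (k - 2.0 * nu * acosh)
    return float(out) if out.ndim == 0 else out


def slow_exchange_intensity(tau, i0: float, k_mn: float, r1_m: float):
    """Residual intensity of the observed resonance under ideal saturation
    of its exchange partner.

    I(tau) = (I0/(k_mn + R1_m)) * [k_mn exp(-tau (k_mn + R1_m)) + R1_m].
    Equals I0 at tau = 0 and decays monotonically to the plateau
    I0 R1_m/(k_mn + R1_m).
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau must be non-negative")
    if not i0 > 0:
        raise ValueError("i0 must be positive")
    if k_mn < 0 or r1_m < 0:
        raise ValueError("rates must be non-negative")
    total = k_mn + r1_m
    if total == 0.0:  # nothing drains the observed magnetization
        out = np.full_like(tau, i0)
        return float(out) if out.ndim == 0 else out
    out = (i0 / total) * (k_mn * np.exp(-tau * total) + r1_m)
    return float(out) if out.ndim == 0 else out


def derive_slow_exchange_thermo(
    k_mn: float,
    k_nm: float,
    temperature: float = T_DEFAULT,
    condition: str = "apo",
    k_mn_err: float = 0.0,
    k_nm_err: float = 0.0,
) -> SlowExchangeParams:
    """Slow-exchange thermodynamics from the two directed rates.

    ``k_mn`` is inactive -> active and ``k_nm`` active -> inactive.  Returns
    k_s = k_mn + k_nm, populations p_active = k_mn/k_s (the population of
    the state the forward rate feeds), and the free-energy difference
    dG = -RT ln(p_active/p_inactive) = G_active - G_inactive, reported with
    the direction tag "active_minus_inactive"; negate for the opposite
    direction (dG is antisymmetric under direction reversal).

    If rate standard errors are supplied, first-order error propagation
    fills the ``uncertainties`` mapping (keys ``k_s``, ``p_active``,
    ``p_inactive``, ``delta_g``).
    """
    if not (k_mn > 0 and k_nm > 0):
        raise ValueError("both rates must be positive")
    if not temperature > 0:
        raise ValueError("temperature must be positive")
    k_s = k_mn + k_nm
    p_active = k_mn / k_s
    p_inactive = k_nm / k_s
    rt = R_KCAL * temperature
    delta_g = -rt * math.log(p_active / p_inactive)

    unc: dict[str, float] = {}
    if k_mn_err or k_nm_err:
        unc["k_s"] = math.hypot(k_mn_err, k_nm_err)
        # d p_active/d k_mn = k_nm/k_s^2 ; d p_active/d k_nm = -k_mn/k_s^2
        dp = math.hypot(k_nm * k_mn_err, k_mn * k_nm_err) / k_s**2
        unc["p_active"] = dp
        unc["p_inactive"] = dp
        # dG = -RT (ln k_mn - ln k_nm)
        unc["delta_g"] = rt * math.hypot(k_mn_err / k_mn, k_nm_err / k_nm)

    return SlowExchangeParams(
        k_mn=k_mn,
        k_nm=k_nm,
        k_s=k_s,
        p_active=p_active,
        p_inactive=p_inactive,
        delta_g=delta_g,
        delta_g_direction="active_minus_inactive",
        temperature=temperature,
        condition=condition,
        uncertainties=unc,
    )


def delta_omega_from_ppm(delta_delta: float, spectrometer_freq: float) -> float:
    """Convert a shift difference in ppm to angular frequency (rad/s).

    With the spectrometer frequency in MHz, ppm * MHz gives Hz directly:
    dw = 2 pi * ddelta * f.
    """
    if not spectrometer_freq > 0:
        raise ValueError("spectrometer_freq must be positive")
    return 2.0 * math.pi * delta_delta * spectrometer_freq


def ppm_from_delta_omega(delta_omega: float, spectrometer_freq: float) -> float:
    """Inverse of :func:`delta_omega_from_ppm`."""
    if not spectrometer_freq > 0:
        raise ValueError("spectrometer_freq must be positive")
    return delta_omega / (2.0 * math.pi * spectrometer_freq)
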