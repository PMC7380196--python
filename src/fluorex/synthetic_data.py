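"""Seeded generators for every input the analysis pipeline consumes.

The generators emulate the acquisition scheme of a constant-time 19F CPMG /
saturation-transfer / inversion-recovery study of a two-resonance protein
system: 14 refocusing frequencies between ~130 and ~6000 s^-1 at two
magnetic fields, 8 saturation times between 25 ms and 1 s, >= 10 inversion
delays between 25 and 800 ms, and two overlapping resonances near -82.7 and
-84.1 ppm whose positions, widths and intensities respond to the exchange
parameters and to ligand binding.

All randomness flows from explicit integer seeds; a generator called twice
with the same (truth, seed) returns identical data.  Noiseless output
inverts exactly through the corresponding closed-form model, which is what
makes every downstream fit testable without experimental data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .bloch_mcconnell import TwoSiteSystem, simulate_cpmg, simulate_spectrum
from .constants import FIELDS_DEFAULT, T_CPMG_DEFAULT
from .exchange_models import (
    CPMGDataset,
    CPMGPoint,
    SlowExchangeParams,
    TwoStateFastParams,
    delta_omega_from_ppm,
    derive_slow_exchange_thermo,
    slow_exchange_intensity,
)
from .fitting import RelaxationSeries, SaturationSeries
from .spectral_tools import Spectrum1D

__all__ = [
    "GroundTruth",
    "default_ground_truth",
    "generate_cpmg_series",
    "generate_saturation_series",
    "generate_inversion_recovery",
    "generate_titration_spectra",
    "realizable_nu_grid",
]


@dataclass(frozen=True)
class GroundTruth:
    """The complete parameter set behind one simulated study.

    ``slow`` maps condition -> slow fold-switch exchange parameters;
    ``fast`` maps (resonance, condition) -> millisecond two-state
    parameters; ``r2_0`` maps (resonance, condition, field) -> intrinsic
    transverse rate (per-field values emulate the field-dependent line
    broadening of 19F); ``r1`` maps (resonance, condition) -> longitudinal
    rate; ``shifts`` maps (resonance, condition) -> resonance center in ppm.
    ``noise_sigma`` is the additive Gaussian noise scale relative to I0.
    """

    slow: dict[str, SlowExchangeParams]
    fast: dict[tuple[str, str], TwoStateFastParams]
    r1: dict[tuple[str, str], float]
    r2_0: dict[tuple[str, str, float], float]
    shifts: dict[tuple[str, str], float]
    fields: tuple[float, ...] = FIELDS_DEFAULT
    constant_time: float = T_CPMG_DEFAULT
    noise_sigma: float = 0.01
    seed: int = 0
    i0: float = 1.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory; no implicit randomness")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


def default_ground_truth(noise_sigma: float = 0.01, seed: int = 0) -> GroundTruth:
    """The reference study conditions.

    Slow fold-switch rates, millisecond exchange rates, populations and
    shift differences are the values the analysis is designed around
    (apo: k_mn = 1.08, k_nm = 1.23 s^-1; ligand-saturated: 4.2 / 8.3 s^-1;
    active resonance k_i = 4300 -> 7300 s^-1 with p = 0.81/0.19 -> 0.70/0.30
    and |ddelta| = 1.2 ppm; inactive resonance k_i = 8000 -> 5100 s^-1 with
    p = 0.009 -> 0.026 and |ddelta| = 2.9 ppm).  Longitudinal rates default
    to 1.5 s^-1; intrinsic R2 to 30 s^-1 at 564 MHz and 40 s^-1 at 659 MHz
    (19F chemical-shift-anisotropy broadening grows with field, emulated
    phenomenologically).
    """
    slow = {
        "apo": derive_slow_exchange_thermo(1.08, 1.23, condition="apo"),
        "ligand": derive_slow_exchange_thermo(4.2, 8.3, condition="ligand"),
    }
    fast = {
        ("active", "apo"): TwoStateFastParams(4300.0, 0.81, 0.19, 1.2),
        ("active", "ligand"): TwoStateFastParams(7300.0, 0.70, 0.30, 1.2),
        ("inactive", "apo"): TwoStateFastParams(8000.0, 0.991, 0.009, 2.9),
        ("inactive", "ligand"): TwoStateFastParams(5100.0, 0.974, 0.026, 2.9),
    }
    r1 = {key: 1.5 for key in fast}
    r2_0 = {}
    for res, cond in fast:
        r2_0[(res, cond, 564.0)] = 30.0
        r2_0[(res, cond, 659.0)] = 40.0
    shifts = {
        ("active", "apo"): -82.7,
        ("active", "ligand"): -82.6,
        ("inactive", "apo"): -84.1,
        ("inactive", "ligand"): -84.3,
    }
    return GroundTruth(
        slow=slow, fast=fast, r1=r1, r2_0=r2_0, shifts=shifts,
        noise_sigma=noise_sigma, seed=seed,
    )


def realizable_nu_grid(
    n_points: int = 14,
    constant_time: float = T_CPMG_DEFAULT,
    n_max: int = 46,
) -> np.ndarray:
    """The default refocusing-frequency grid.

    Only nu = n/(2 T_CPMG) for integer pulse counts n is realizable in a
    constant-time experiment.  The default grid takes the first ``n_max``
    realizable values (130.2 ... 5989.6 s^-1 for T = 3.84 ms) and
    subsamples ``n_points`` of them log-uniformly with both endpoints
    forced, snapping each target to the nearest unused pulse count.
    """
    if n_points < 2 or n_points > n_max:
        raise ValueError("need 2 <= n_points <= n_max")
    targets = np.geomspace(1, n_max, n_points)
    chosen: list[int] = []
    for t in targets:
        n = int(round(t))
        while n in chosen and n < n_max:
            n += 1
        chosen.append(min(n, n_max))
    chosen = sorted(set(chosen))
    # fill from the top if rounding collapsed any targets
    n = n_max
    while len(chosen) < n_points:
        if n not in chosen:
            chosen.append(n)
        n -= 1
    return np.array(sorted(chosen)) / (2.0 * constant_time)


def _system_for(truth: GroundTruth, resonance: str, condition: str,
                field_mhz: float) -> TwoSiteSystem:
    fast = truth.fast[(resonance, condition)]
    dw = delta_omega_from_ppm(fast.delta_delta, field_mhz)
    r2 = truth.r2_0[(resonance, condition, field_mhz)]
    return TwoSiteSystem.from_fast_params(
        k_i=fast.k_i, p_a=fast.p_a, delta_omega=dw, r2_0=r2,
        r1=truth.r1[(resonance, condition)],
    )


def generate_cpmg_series(
    truth: GroundTruth,
    resonance: str,
    condition: str,
    field_mhz: float,
    n_points: int = 14,
    seed: int | None = None,
) -> CPMGDataset:
    """One constant-time dispersion series at one field and condition.

    Intensities are I0 exp(-T_CPMG R2,eff(nu)) with R2,eff from exact
    Bloch-McConnell propagation of the underlying two-site system, plus
    additive Gaussian noise of scale noise_sigma * I0.
    """
    if n_points < 4:
        raise ValueError("n_points must be >= 4")
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    system = _system_for(truth, resonance, condition, field_mhz)
    nus = realizable_nu_grid(n_points, truth.constant_time)
    points = []
    for nu in nus:
        n_pulses = int(round(2.0 * truth.constant_time * nu))
        r2eff = simulate_cpmg(system, n_pulses, truth.constant_time)
        intensity = truth.i0 * math.exp(-truth.constant_time * r2eff)
        intensity += rng.normal(0.0, truth.noise_sigma * truth.i0) if truth.noise_sigma else 0.0
        points.append(CPMGPoint(nu_cpmg=float(nu), intensity=float(intensity)))
    return CPMGDataset(
        spectrometer_freq=field_mhz,
        constant_time=truth.constant_time,
        reference_intensity=truth.i0,
        points=tuple(points),
        condition=condition,
        resonance=resonance,
    )


def generate_saturation_series(
    truth: GroundTruth,
    observed: str,
    condition: str,
    n_points: int = 8,
    tau_range: tuple[float, float] = (0.025, 1.0),
    seed: int | None = None,
) -> SaturationSeries:
    """Saturation-transfer decay of the observed resonance.

    The partner resonance is held saturated; the observed intensity follows
    the closed-form two-state decay with the rate out of the observed state
    (k_IA when observing the inactive resonance, k_AI when observing the
    active one) plus seeded Gaussian noise.  Times are log-spaced over
    ``tau_range`` by default.
    """
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    slow = truth.slow[condition]
    rate_out = slow.k_mn if observed == "inactive" else slow.k_nm
    r1 = truth.r1[(observed, condition)]
    taus = np.geomspace(tau_range[0], tau_range[1], n_points)
    clean = slow_exchange_intensity(taus, truth.i0, rate_out, r1)
    noisy = clean + (rng.normal(0.0, truth.noise_sigma * truth.i0, size=n_points)
                     if truth.noise_sigma else 0.0)
    return SaturationSeries(
        taus=taus,
        intensities=noisy,
        observed=observed,
        saturated="active" if observed == "inactive" else "inactive",
        condition=condition,
        r1=r1,
        r1_provenance="truth",
    )


def generate_inversion_recovery(
    truth: GroundTruth,
    resonance: str,
    condition: str,
    n_points: int = 10,
    tau_range: tuple[float, float] = (0.025, 0.8),
    seed: int | None = None,
) -> RelaxationSeries:
    """Inversion-recovery series I(tau) = A - B exp(-R1 tau).

    Perfect inversion (B = 2A) with A = I0, linear tau spacing over the
    default 25-800 ms window, plus seeded Gaussian noise.
    """
    if n_points < 10:
        raise ValueError("inversion recovery uses at least 10 delays")
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    r1 = truth.r1[(resonance, condition)]
    taus = np.linspace(tau_range[0], tau_range[1], n_points)
    clean = truth.i0 * (1.0 - 2.0 * np.exp(-r1 * taus))
    noisy = clean + (rng.normal(0.0, truth.noise_sigma * truth.i0, size=n_points)
                     if truth.noise_sigma else 0.0)
    return RelaxationSeries(
        taus=taus, intensities=noisy, resonance=resonance, condition=condition
    )


def bound_fraction(ligand_total: float, protein_total: float, kd: float) -> float:
    """Bound protein fraction from the exact two-component binding quadratic."""
    if ligand_total < 0 or protein_total <= 0 or kd < 0:
        raise ValueError("concentrations must be non-negative, protein positive")
    s = protein_total + ligand_total + kd
    disc = s * s - 4.0 * protein_total * ligand_total
    bound = (s - math.sqrt(max(disc, 0.0))) / 2.0
    return bound / protein_total


def _interp_slow(truth: GroundTruth, fb: float) -> SlowExchangeParams:
    apo, lig = truth.slow["apo"], truth.slow["ligand"]
    k_mn = (1 - fb) * apo.k_mn + fb * lig.k_mn
    k_nm = (1 - fb) * apo.k_nm + fb * lig.k_nm
    return derive_slow_exchange_thermo(k_mn, k_nm, condition="mixed")


def generate_titration_spectra(
    truth: GroundTruth,
    ligand_concentrations,
    protein_concentration: float = 100.0,
    kd: float = 0.23,
    ppm_axis: np.ndarray | None = None,
    field_mhz: float | None = None,
    seed: int | None = None,
) -> list[Spectrum1D]:
    """1-D spectra along a ligand titration (concentrations in uM).

    The bound fraction comes from the exact binding quadratic; resonance
    centers and slow-exchange parameters interpolate linearly between the
    apo and ligand-saturated truths with that fraction.  With a
    sub-micromolar dissociation constant the spectra stop changing once the
    ligand exceeds the protein stoichiometry.  Lines carry the per-field
    intrinsic widths; noise is seeded Gaussian on intensities.
    """
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    field_mhz = truth.fields[0] if field_mhz is None else field_mhz
    if ppm_axis is None:
        ppm_axis = np.linspace(-87.0, -80.0, 2048)
    spectra = []
    for lig in ligand_concentrations:
        if lig < 0:
            raise ValueError("ligand concentration must be non-negative")
        fb = bound_fraction(lig, protein_concentration, kd)
        slow = _interp_slow(truth, fb)
        shift = {
            res: (1 - fb) * truth.shifts[(res, "apo")] + fb * truth.shifts[(res, "ligand")]
            for res in ("active", "inactive")
        }
        r2 = {
            res: (1 - fb) * truth.r2_0[(res, "apo", field_mhz)]
            + fb * truth.r2_0[(res, "ligand", field_mhz)]
            for res in ("active", "inactive")
        }
        system = TwoSiteSystem(
            omega_a=delta_omega_from_ppm(shift["active"], field_mhz),
            omega_b=delta_omega_from_ppm(shift["inactive"], field_mhz),
            k_ab=slow.k_nm,
            k_ba=slow.k_mn,
            r2_a=r2["active"],
            r2_b=r2["inactive"],
            p_a=slow.p_active,
            p_b=slow.p_inactive,
        )
        spec = simulate_spectrum(system, ppm_axis, field_mhz)
        noise = (rng.normal(0.0, truth.noise_sigma * spec.intensity.max(),
                            size=len(ppm_axis)) if truth.noise_sigma else 0.0)
        spectra.append(Spectrum1D(ppm=ppm_axis, intensity=spec.intensity + noise,
                                  spectrometer_freq=field_mhz))
    return spectra
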