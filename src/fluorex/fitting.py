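"""Nonlinear estimation for every experiment in the pipeline.

Four fits are provided:

* monoexponential inversion-recovery fit for R1;
* Luz-Meiboom fit of a single-field dispersion series (only the apparent
  rate ``k_app`` and the composite ``c = pA pB dw^2`` are identifiable);
* the global Carver-Richards fit over up to four dispersion series
  (two fields x two ligand conditions) with |ddelta| shared across all
  series of a resonance, (k_i, populations) shared across fields within a
  condition, and R2,0 free per series;
* the saturation-transfer fit for the slow fold-switch rate with R1 fixed
  from an inversion-recovery result.

All fits use bounded trust-region least squares (via lmfit); uncertainties
come from the covariance at the optimum, optionally cross-checked by a
seeded residual bootstrap.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .exchange_models import (
    CPMGDataset,
    LuzMeiboomParams,
    TwoStateFastParams,
    carver_richards_r2,
    delta_omega_from_ppm,
    luz_meiboom_r2,
    slow_exchange_intensity,
)

__all__ = [
    "RelaxationSeries",
    "SaturationSeries",
    "FitOutcome",
    "GlobalFitResult",
    "fit_inversion_recovery",
    "fit_luz_meiboom",
    "fit_carver_richards_global",
    "fit_saturation_transfer",
    "estimate_uncertainties",
]

#: Parameter bounds for all exchange fits.
RATE_MAX = 1e7  # s^-1
DDELTA_MAX = 20.0  # ppm

#: Multi-start grid for the global dispersion fit; the Carver-Richards
#: objective has well-known degenerate valleys (k_i <-> p_minor trade-off),
#: so every fit starts from each point of this grid and the best final
#: objective wins, ties broken toward smaller k_i.
MULTISTART_K = (1e2, 1e3, 3e3, 1e4)
MULTISTART_P = (0.01, 0.05, 0.1, 0.3)


@dataclass(frozen=True)
class RelaxationSeries:
    """Inversion-recovery data: intensities vs delay."""

    taus: np.ndarray
    intensities: np.ndarray
    resonance: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        taus = np.asarray(self.taus, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "taus", taus)
        object.__setattr__(self, "intensities", inten)
        if len(taus) < 5:
            raise ValueError("R1 fits need at least 5 delays")
        if len(taus) != len(inten):
            raise ValueError("taus and intensities must have equal length")
        if np.any(taus < 0) or np.any(np.diff(taus) <= 0):
            raise ValueError("taus must be non-negative and strictly increasing")


@dataclass(frozen=True)
class SaturationSeries:
    """Saturation-transfer data with the fixed R1 and its provenance."""

    taus: np.ndarray
    intensities: np.ndarray
    observed: str
    saturated: str
    condition: str = "apo"
    r1: float | None = None
    r1_provenance: str = "unset"

    def __post_init__(self) -> None:
        taus = np.asarray(self.taus, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "taus", taus)
        object.__setattr__(self, "intensities", inten)
        if len(taus) < 4:
            raise ValueError("saturation series need at least 4 points")
        if len(taus) != len(inten):
            raise ValueError("taus and intensities must have equal length")


@dataclass(frozen=True)
class FitOutcome:
    """A scalar-parameter fit: values, standard errors, and flags."""

    values: dict
    stderr: dict
    converged: bool
    flags: tuple[str, ...] = ()
    redchi: float = math.nan
    result: object = field(default=None, compare=False, repr=False)


@dataclass(frozen=True)
class GlobalFitResult:
    """Result of the shared-parameter Carver-Richards fit of one resonance.

    ``per_condition`` maps condition -> TwoStateFastParams (r2_0 there is
    the first dataset's; per-dataset values live in ``r2_0``, keyed by
    (condition, field)).  ``p_minor`` is reported in [0, 0.5]; which state
    it labels physically is an assignment question outside the fit.
    """

    resonance: str
    delta_delta: float
    per_condition: dict
    r2_0: dict
    stderr: dict
    converged: bool
    flags: tuple[str, ...]
    redchi: float
    n_starts: int
    residuals: np.ndarray = field(default=None, compare=False, repr=False)
    result: object = field(default=None, compare=False, repr=False)


# ---------------------------------------------------------------------------
# Inversion recovery
# ---------------------------------------------------------------------------

def fit_inversion_recovery(series: RelaxationSeries) -> FitOutcome:
    """Monoexponential fit I(tau) = A - B exp(-R1 tau) with A, B, R1 free.

    B is left free rather than pinned at 2A so imperfect inversion does not
    bias R1.  A flat series (no decay) is flagged rather than fitted.
    """
    y = series.intensities
    if np.ptp(y) < 1e-12 * max(1.0, abs(y).max()):
        return FitOutcome(values={}, stderr={}, converged=False,
                          flags=("no_decay",))
    params = lmfit.Parameters()
    a0 = float(y[-1])
    params.add("a", value=a0 if a0 != 0 else 1.0)
    params.add("b", value=float(a0 - y[0]) or 1.0)
    params.add("r1", value=1.0 / max(series.taus.mean(), 1e-6), min=1e-6, max=RATE_MAX)

    def resid(p):
        return p["a"] - p["b"] * np.exp(-p["r1"] * series.taus) - y

    out = lmfit.minimize(resid, params, method="least_squares")
    flags = []
    if not out.success:
        flags.append("non_convergence")
    r1 = out.params["r1"]
    if r1.value <= 1e-5:
        flags.append("r1_nonpositive")
    return FitOutcome(
        values={k: out.params[k].value for k in out.params},
        stderr={k: (out.params[k].stderr or math.nan) for k in out.params},
        converged=out.success and not flags,
        flags=tuple(flags),
        redchi=out.redchi,
        result=out,
    )


# ---------------------------------------------------------------------------
# Luz-Meiboom single-field fit
# ---------------------------------------------------------------------------

def fit_luz_meiboom(dataset: CPMGDataset) -> FitOutcome:
    """Fast-exchange fit of one dispersion series.

    Returns k_app, c and R2,0.  Populations and shift difference cannot be
    separated in this model; only the composite c is reported.  A flat
    dispersion (amplitude indistinguishable from zero) pins c at 0 and
    flags k_app as unidentifiable.
    """
    if len(dataset.points) < 4:
        raise ValueError("need at least 4 dispersion points")
    nu = dataset.nu_cpmg
    r2 = dataset.r2_eff()
    amplitude = float(r2.max() - r2.min())
    if amplitude < 1e-9:
        return FitOutcome(
            values={"k_app": math.nan, "c": 0.0, "r2_0": float(r2.mean())},
            stderr={}, converged=False, flags=("flat_dispersion",),
        )

    params = lmfit.Parameters()
    params.add("k_app", value=2000.0, min=1.0, max=RATE_MAX)
    params.add("c", value=max(amplitude * 2000.0, 1.0), min=0.0, max=1e12)
    params.add("r2_0", value=float(r2.min()), min=0.0, max=1e4)

    def resid(p):
        model = luz_meiboom_r2(
            nu, LuzMeiboomParams(k_app=p["k_app"].value, c=p["c"].value,
                                 r2_0=p["r2_0"].value)
        )
        return model - r2

    best = None
    for k0 in (1e2, 1e3, 1e4):
        params["k_app"].value = k0
        params["c"].value = max(amplitude * k0, 1.0)
        out = lmfit.minimize(resid, params, method="least_squares")
        if best is None or out.chisqr < best.chisqr:
            best = out
    out = best
    flags = []
    if not out.success:
        flags.append("non_convergence")
    if out.params["c"].value <= 1e-6:
        flags.append("exchange_unidentifiable")
    return FitOutcome(
        values={k: out.params[k].value for k in out.params},
        stderr={k: (out.params[k].stderr or math.nan) for k in out.params},
        converged=out.success and not flags,
        flags=tuple(flags),
        redchi=out.redchi,
        result=out,
    )


# ---------------------------------------------------------------------------
# Global Carver-Richards fit
# ---------------------------------------------------------------------------

def _cr_residuals(params, datasets, keys):
    res = []
    for ds, (cond_key, ds_key) in zip(datasets, keys):
        p_minor = params[f"p_{cond_key}"].value
        k_i = params[f"k_{cond_key}"].value
        dd = params["ddelta"].value
        r2_0 = params[f"r2_0_{ds_key}"].value
        dw = delta_omega_from_ppm(dd, ds.spectrometer_freq)
        model = carver_richards_r2(
            ds.nu_cpmg,
            TwoStateFastParams(k_i=k_i, p_a=1.0 - p_minor, p_b=p_minor,
                               delta_delta=dd, r2_0=r2_0),
            dw,
        )
        res.append(model - ds.r2_eff())
    return np.concatenate(res)


def fit_carver_richards_global(
    datasets: list[CPMGDataset],
    n_starts: int | None = None,
) -> GlobalFitResult:
    """Weighted least-squares Carver-Richards fit with parameter sharing.

    All datasets must belong to one resonance.  |ddelta| is shared across
    every dataset; (k_i, p_minor) are shared across fields within a
    condition but free across conditions; R2,0 is free per dataset.  The
    angular shift difference is recomputed per dataset from |ddelta| and
    that dataset's field, which is what couples the fields and breaks the
    fast-exchange degeneracy.

    Initialisation is multi-start over the (k_i, p_minor) grid in
    :data:`MULTISTART_K` x :data:`MULTISTART_P` (16 starts); the best final
    objective wins, ties broken toward smaller k_i.  With a single field
    and condition the fit still runs but the degeneracy warning is recorded.
    """
    if not datasets:
        raise ValueError("no datasets")
    resonance = datasets[0].resonance
    if any(ds.resonance != resonance for ds in datasets):
        raise ValueError("all datasets must share one resonance label")

    conditions = sorted({ds.condition for ds in datasets})
    fields = sorted({ds.spectrometer_freq for ds in datasets})
    flags: list[str] = []
    if len(fields) < 2:
        flags.append("single_field_degenerate")

    keys = []
    for i, ds in enumerate(datasets):
        keys.append((ds.condition, f"{i}_{ds.condition}_{int(ds.spectrometer_freq)}"))

    base = lmfit.Parameters()
    base.add("ddelta", value=1.0, min=0.0, max=DDELTA_MAX)
    for cond in conditions:
        base.add(f"k_{cond}", value=1e3, min=0.0, max=RATE_MAX)
        # restrict to the minor branch; the model is symmetric under
        # p <-> 1-p so nothing is lost
        base.add(f"p_{cond}", value=0.05, min=0.0, max=0.5)
    for ds, (_, ds_key) in zip(datasets, keys):
        base.add(f"r2_0_{ds_key}", value=float(ds.r2_eff().min()), min=0.0, max=1e4)

    starts = list(itertools.product(MULTISTART_K, MULTISTART_P))
    if n_starts is not None:
        starts = starts[: max(1, n_starts)]

    # amplitude-based ddelta seed: dispersion amplitude ~ pA pB dw^2 / k
    amp = max(float(ds.r2_eff().max() - ds.r2_eff().min()) for ds in datasets)

    best = None
    for k0, p0 in starts:
        params = base.copy()
        for cond in conditions:
            params[f"k_{cond}"].value = k0
            params[f"p_{cond}"].value = p0
        dw0 = math.sqrt(max(amp * k0 / max(p0 * (1 - p0), 1e-6), 1.0))
        params["ddelta"].value = min(
            max(dw0 / (2 * math.pi * datasets[0].spectrometer_freq), 0.05), DDELTA_MAX
        )
        out = lmfit.minimize(
            _cr_residuals, params, args=(datasets, keys), method="least_squares"
        )
        if (
            best is None
            or out.chisqr < best.chisqr * (1 - 1e-9)
            or (
                abs(out.chisqr - best.chisqr) <= 1e-9 * max(best.chisqr, 1e-300)
                and out.params[f"k_{conditions[0]}"].value
                < best.params[f"k_{conditions[0]}"].value
            )
        ):
            best = out
    out = best

    if not out.success:
        flags.append("non_convergence")
    for name, par in out.params.items():
        if par.vary and par.value in (par.min, par.max):
            flags.append(f"at_bound:{name}")
    if out.params["ddelta"].value < 1e-3:
        flags.append("exchange_unidentifiable")

    per_condition = {}
    stderr = {k: (out.params[k].stderr or math.nan) for k in out.params}
    r2_0 = {}
    for ds, (_, ds_key) in zip(datasets, keys):
        r2_0[(ds.condition, ds.spectrometer_freq)] = out.params[f"r2_0_{ds_key}"].value
    for cond in conditions:
        p_minor = out.params[f"p_{cond}"].value
        per_condition[cond] = TwoStateFastParams(
            k_i=out.params[f"k_{cond}"].value,
            p_a=1.0 - p_minor,
            p_b=p_minor,
            delta_delta=out.params["ddelta"].value,
            r2_0=next(v for (c, _f), v in r2_0.items() if c == cond),
        )

    return GlobalFitResult(
        resonance=resonance,
        delta_delta=out.params["ddelta"].value,
        per_condition=per_condition,
        r2_0=r2_0,
        stderr=stderr,
        converged=out.success and not any(f.startswith("non_") for f in flags),
        flags=tuple(flags),
        redchi=out.redchi,
        n_starts=len(starts),
        residuals=np.asarray(out.residual),
        result=out,
    )


# ---------------------------------------------------------------------------
# Saturation transfer
# ---------------------------------------------------------------------------

def fit_saturation_transfer(series: SaturationSeries) -> FitOutcome:
    """Fit the two-state saturation-transfer decay for the exchange rate out
    of the observed state, with R1 of the observed resonance held fixed.

    I0 and the rate are free.  A flat trace yields a rate pinned near zero
    and is flagged.
    """
    if series.r1 is None or not series.r1 > 0:
        raise ValueError("a positive fixed r1 is required (fit it first)")
    y = series.intensities
    taus = series.taus

    params = lmfit.Parameters()
    params.add("i0", value=float(abs(y).max()) or 1.0, min=1e-12)
    params.add("k", value=1.0, min=0.0, max=1e4)

    def resid(p):
        return slow_exchange_intensity(taus, p["i0"].value, p["k"].value,
                                       series.r1) - y

    best = None
    for k0 in (0.1, 1.0, 10.0):
        params["k"].value = k0
        out = lmfit.minimize(resid, params, method="least_squares")
        if best is None or out.chisqr < best.chisqr:
            best = out
    out = best
    flags = []
    if not out.success:
        flags.append("non_convergence")
    if out.params["k"].value <= 1e-3:
        flags.append("rate_indistinguishable_from_zero")
    return FitOutcome(
        values={"k_mn": out.params["k"].value, "i0": out.params["i0"].value,
                "r1_fixed": series.r1},
        stderr={"k_mn": out.params["k"].stderr or math.nan,
                "i0": out.params["i0"].stderr or math.nan},
        converged=out.success and not flags,
        flags=tuple(flags),
        redchi=out.redchi,
        result=out,
    )


# ---------------------------------------------------------------------------
# Uncertainties
# ---------------------------------------------------------------------------

def estimate_uncertainties(
    fit_result: lmfit.minimizer.MinimizerResult,
    method: str = "covariance",
    n_boot: int = 200,
    seed: int = 0,
    refit=None,
) -> dict:
    """Per-parameter standard errors by covariance and/or residual bootstrap.

    ``"covariance"`` reads the Jacobian-derived errors at the optimum (NaN
    where the Jacobian is singular).  ``"residual-bootstrap"`` requires
    ``refit``, a callable mapping a synthetic data vector (model prediction
    at the optimum plus resampled residuals) to a dict of parameter values;
    the spread over ``n_boot`` seeded resamples is reported.  ``"both"``
    returns the two side by side.
    """
    if method not in ("covariance", "residual-bootstrap", "both"):
        raise ValueError(f"unknown method {method!r}")
    out: dict[str, dict[str, float]] = {}
    varying = [k for k in fit_result.params if fit_result.params[k].vary]
    if method in ("covariance", "both"):
        for k in varying:
            out.setdefault(k, {})["covariance"] = (
                fit_result.params[k].stderr
                if fit_result.params[k].stderr is not None
                else math.nan
            )
    if method in ("residual-bootstrap", "both"):
        if refit is None:
            raise ValueError("residual bootstrap needs the refit callable")
        residuals = np.asarray(fit_result.residual)
        # model prediction at the optimum: data + residual sign convention
        # is handled by the caller's refit closure, which owns the data.
        rng = np.random.default_rng(seed)
        samples: dict[str, list[float]] = {k: [] for k in varying}
        for _ in range(n_boot):
            resampled = rng.choice(residuals, size=len(residuals), replace=True)
            values = refit(resampled)
            for k in varying:
                if k in values:
                    samples[k].append(values[k])
        for k in varying:
            if samples[k]:
                out.setdefault(k, {})["bootstrap"] = float(np.std(samples[k], ddof=1))
    return out
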