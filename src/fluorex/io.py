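"""File formats, configuration and the pipeline driver.

All data travel as tab-separated text with a ``#``-prefixed ``key: value``
header (the raw experimental formats of the original acquisitions are
vendor-specific and unavailable, so the on-disk format is defined here).
Spectra are two-column (ppm, intensity) files whose header carries the
spectrometer frequency.  Every output embeds the configuration hash and
package version so a run is attributable; all randomness flows from
config-declared seeds, making runs byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .constants import FIELDS_DEFAULT, R_KCAL, T_CPMG_DEFAULT, T_DEFAULT
from .exchange_models import (
    CPMGDataset,
    CPMGPoint,
    derive_slow_exchange_thermo,
)
from .fitting import (
    RelaxationSeries,
    SaturationSeries,
    fit_carver_richards_global,
    fit_inversion_recovery,
    fit_saturation_transfer,
)
from .spectral_tools import Spectrum1D, fit_lorentzians, populations_from_integrals
from .synthetic_data import (
    GroundTruth,
    generate_cpmg_series,
    generate_inversion_recovery,
    generate_saturation_series,
    generate_titration_spectra,
)
from .thermo_report import assemble_four_state_model, render_results_tables

__all__ = [
    "RunConfig",
    "read_intensity_table",
    "write_intensity_table",
    "read_spectrum",
    "write_spectrum",
    "simulate_study",
    "run_pipeline",
]

PIPELINE_STAGES = ("deconvolve", "t1", "st", "cpmg", "report")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration (loadable from YAML)."""

    fields_mhz: tuple[float, ...] = FIELDS_DEFAULT
    constant_time_s: float = T_CPMG_DEFAULT
    temperature_k: float = T_DEFAULT
    gas_constant: float = R_KCAL
    assignments: dict = field(
        default_factory=lambda: {
            "active": {"apo": -82.7, "ligand": -82.6},
            "inactive": {"apo": -84.1, "ligand": -84.3},
        }
    )
    conditions: tuple[str, ...] = ("apo", "ligand")
    seed: int = 0
    noise_sigma: float = 0.01
    input_dir: str = "."
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fields_mhz):
            raise ValueError("spectrometer frequencies must be positive")
        if not self.temperature_k > 0:
            raise ValueError("temperature must be positive")
        for cond in self.conditions:
            for res in ("active", "inactive"):
                if cond not in self.assignments.get(res, {}):
                    raise ValueError(f"no shift assignment for {res}/{cond}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in (
            "constant_time_s", "temperature_k", "gas_constant", "assignments",
            "seed", "noise_sigma", "input_dir", "output_dir",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "fields_mhz" in raw:
            kwargs["fields_mhz"] = tuple(float(f) for f in raw["fields_mhz"])
        if "conditions" in raw:
            kwargs["conditions"] = tuple(raw["conditions"])
        return cls(**kwargs)

    def digest(self) -> str:
        blob = json.dumps(
            {
                "fields_mhz": list(self.fields_mhz),
                "constant_time_s": self.constant_time_s,
                "temperature_k": self.temperature_k,
                "gas_constant": self.gas_constant,
                "assignments": self.assignments,
                "conditions": list(self.conditions),
                "seed": self.seed,
                "noise_sigma": self.noise_sigma,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Delimited-text tables
# ---------------------------------------------------------------------------

def _parse_header(lines: list[str]) -> dict:
    meta = {}
    for ln in lines:
        body = ln.lstrip("#").strip()
        if ":" in body:
            key, _, val = body.partition(":")
            meta[key.strip()] = val.strip()
    return meta


def _provenance_lines(extra: dict | None = None) -> list[str]:
    out = [f"# package_version: {__version__}"]
    for k, v in (extra or {}).items():
        out.append(f"# {k}: {v}")
    return out


def write_intensity_table(dataset, path) -> None:
    """Write a CPMG, saturation or inversion-recovery dataset."""
    path = Path(path)
    lines = _provenance_lines()
    if isinstance(dataset, CPMGDataset):
        lines += [
            "# kind: cpmg",
            f"# field_mhz: {dataset.spectrometer_freq!r}",
            f"# condition: {dataset.condition}",
            f"# resonance: {dataset.resonance}",
            f"# constant_time_s: {dataset.constant_time!r}",
            f"# reference_intensity: {dataset.reference_intensity!r}",
            "nu_cpmg\tintensity",
        ]
        for p in dataset.points:
            lines.append(f"{float(p.nu_cpmg)!r}\t{float(p.intensity)!r}")
    elif isinstance(dataset, SaturationSeries):
        lines += [
            "# kind: saturation",
            f"# condition: {dataset.condition}",
            f"# observed: {dataset.observed}",
            f"# saturated: {dataset.saturated}",
            f"# r1: {dataset.r1!r}",
            f"# r1_provenance: {dataset.r1_provenance}",
            "tau\tintensity",
        ]
        for t, i in zip(dataset.taus, dataset.intensities):
            lines.append(f"{float(t)!r}\t{float(i)!r}")
    elif isinstance(dataset, RelaxationSeries):
        lines += [
            "# kind: inversion",
            f"# condition: {dataset.condition}",
            f"# resonance: {dataset.resonance}",
            "tau\tintensity",
        ]
        for t, i in zip(dataset.taus, dataset.intensities):
            lines.append(f"{float(t)!r}\t{float(i)!r}")
    else:
        raise TypeError(f"cannot serialise {type(dataset).__name__}")
    path.write_text("\n".join(lines) + "\n")


def read_intensity_table(path, kind: str | None = None):
    """Read a typed dataset back; every malformed row is reported at once.

    ``kind`` (cpmg | saturation | inversion) is checked against the file
    header when given.  CPMG refocusing frequencies are checked against the
    realizable grid n/(2 T_CPMG); off-grid values within 1% are accepted
    with a warning in the returned dataset's problems list, larger
    deviations are errors.
    """
    path = Path(path)
    header_lines, data_lines = [], []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        if raw.startswith("#"):
            header_lines.append(raw)
        elif raw.strip():
            data_lines.append((lineno, raw))
    meta = _parse_header(header_lines)
    file_kind = meta.get("kind")
    if file_kind is None:
        raise ValueError(f"{path}: header is missing the 'kind' key")
    if kind is not None and kind != file_kind:
        raise ValueError(f"{path}: expected kind={kind}, file says {file_kind}")

    problems: list[str] = []
    rows: list[tuple[float, float]] = []
    # first non-comment line is the column header
    if not data_lines:
        raise ValueError(f"{path}: no data rows")
    for lineno, raw in data_lines[1:]:
        parts = raw.split("\t")
        if len(parts) != 2:
            problems.append(f"line {lineno}: expected 2 columns, got {len(parts)}")
            continue
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError:
            problems.append(f"line {lineno}: non-numeric cell in {raw!r}")
    xs = [r[0] for r in rows]
    dup = {x for x in xs if xs.count(x) > 1}
    if dup:
        for lineno, raw in data_lines[1:]:
            try:
                if float(raw.split("\t")[0]) in dup:
                    problems.append(f"line {lineno}: duplicated abscissa {raw.split(chr(9))[0]}")
            except (ValueError, IndexError):
                pass

    def need(key):
        if key not in meta:
            problems.append(f"header missing key {key!r}")
            return None
        return meta[key]

    if file_kind == "cpmg":
        f = need("field_mhz")
        ct = need("constant_time_s")
        i0 = need("reference_intensity")
        cond = need("condition")
        res = need("resonance")
        if problems:
            raise ValueError(f"{path}: " + "; ".join(problems))
        ct = float(ct)
        warnings = []
        for nu, _ in rows:
            n = round(2.0 * ct * nu)
            realizable = n / (2.0 * ct) if n >= 1 else None
            if realizable is None or abs(nu - realizable) > 0.01 * nu:
                raise ValueError(
                    f"{path}: nu_cpmg={nu} not on the realizable grid n/(2*{ct})"
                )
            if abs(nu - realizable) > 1e-9 * nu:
                warnings.append(f"nu_cpmg={nu} off-grid by "
                                f"{abs(nu - realizable):.3g} (accepted)")
        ds = CPMGDataset(
            spectrometer_freq=float(f),
            constant_time=ct,
            reference_intensity=float(i0),
            points=tuple(CPMGPoint(nu, inten) for nu, inten in rows),
            condition=cond,
            resonance=res,
        )
        return (ds, warnings) if warnings else (ds, [])
    if file_kind == "saturation":
        cond = need("condition")
        obs = need("observed")
        sat = need("saturated")
        if problems:
            raise ValueError(f"{path}: " + "; ".join(problems))
        r1 = meta.get("r1")
        r1 = None if r1 in (None, "None") else float(r1)
        return (
            SaturationSeries(
                taus=np.array([r[0] for r in rows]),
                intensities=np.array([r[1] for r in rows]),
                observed=obs,
                saturated=sat,
                condition=cond,
                r1=r1,
                r1_provenance=meta.get("r1_provenance", "file"),
            ),
            [],
        )
    if file_kind == "inversion":
        cond = need("condition")
        res = need("resonance")
        if problems:
            raise ValueError(f"{path}: " + "; ".join(problems))
        return (
            RelaxationSeries(
                taus=np.array([r[0] for r in rows]),
                intensities=np.array([r[1] for r in rows]),
                resonance=res,
                condition=cond,
            ),
            [],
        )
    raise ValueError(f"{path}: unknown kind {file_kind!r}")


def write_spectrum(spectrum: Spectrum1D, path) -> None:
    lines = _provenance_lines()
    lines += [
        "# kind: spectrum",
        f"# spectrometer_freq_mhz: {spectrum.spectrometer_freq!r}",
        "ppm\tintensity",
    ]
    for p, i in zip(spectrum.ppm, spectrum.intensity):
        lines.append(f"{float(p)!r}\t{float(i)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_spectrum(path) -> Spectrum1D:
    path = Path(path)
    header_lines, rows = [], []
    for raw in path.read_text().splitlines():
        if raw.startswith("#"):
            header_lines.append(raw)
        elif raw.strip() and not raw.startswith("ppm"):
            a, b = raw.split("\t")
            rows.append((float(a), float(b)))
    meta = _parse_header(header_lines)
    if "spectrometer_freq_mhz" not in meta:
        raise ValueError(f"{path}: header is missing spectrometer_freq_mhz")
    return Spectrum1D(
        ppm=np.array([r[0] for r in rows]),
        intensity=np.array([r[1] for r in rows]),
        spectrometer_freq=float(meta["spectrometer_freq_mhz"]),
    )


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

def _child_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) & 0x7FFFFFFF for s in state]


def simulate_study(truth: GroundTruth, outdir,
                   conditions=("apo", "ligand")) -> dict:
    """Write the full synthetic study a pipeline run consumes.

    Per condition: one CPMG series per resonance per field, one
    saturation series per observed resonance, one inversion-recovery
    series per resonance, and one 1-D spectrum; plus a YAML manifest
    recording the generating truth and every per-dataset seed.
    Returns {relative filename: absolute path}.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}
    manifest = {"seed": truth.seed, "noise_sigma": truth.noise_sigma,
                "datasets": {}}
    jobs = []
    for cond in conditions:
        for res in ("active", "inactive"):
            for fmhz in truth.fields:
                jobs.append(("cpmg", res, cond, fmhz))
            jobs.append(("inversion", res, cond, None))
            jobs.append(("saturation", res, cond, None))
        jobs.append(("spectrum", None, cond, None))
    seeds = _child_seeds(truth.seed, len(jobs))
    for (kind, res, cond, fmhz), seed in zip(jobs, seeds):
        if kind == "cpmg":
            ds = generate_cpmg_series(truth, res, cond, fmhz, seed=seed)
            name = f"cpmg_{res}_{cond}_{int(fmhz)}.tsv"
            write_intensity_table(ds, outdir / name)
        elif kind == "inversion":
            ds = generate_inversion_recovery(truth, res, cond, seed=seed)
            name = f"inversion_{res}_{cond}.tsv"
            write_intensity_table(ds, outdir / name)
        elif kind == "saturation":
            ds = generate_saturation_series(truth, res, cond, seed=seed)
            name = f"saturation_{res}_{cond}.tsv"
            write_intensity_table(ds, outdir / name)
        else:
            # saturating ligand concentration for the ligand condition
            lig = 500.0 if cond == "ligand" else 0.0
            spec = generate_titration_spectra(truth, [lig], seed=seed)[0]
            name = f"spectrum_{cond}.tsv"
            write_spectrum(spec, outdir / name)
        files[name] = str(outdir / name)
        manifest["datasets"][name] = {"seed": seed, "kind": kind,
                                      "resonance": res, "condition": cond,
                                      "field_mhz": fmhz}
    manifest["truth"] = {
        "slow": {c: {"k_mn": truth.slow[c].k_mn, "k_nm": truth.slow[c].k_nm}
                 for c in truth.slow},
        "fast": {f"{res}/{cond}": {
                    "k_i": p.k_i, "p_a": p.p_a, "p_b": p.p_b,
                    "delta_delta": p.delta_delta}
                 for (res, cond), p in truth.fast.items()},
        "r1": {f"{res}/{cond}": v for (res, cond), v in truth.r1.items()},
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    files["manifest.yaml"] = str(outdir / "manifest.yaml")
    return files


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

class PipelineError(RuntimeError):
    pass


def run_pipeline(config: RunConfig, stages=PIPELINE_STAGES) -> dict:
    """Execute the requested stages in dependency order.

    deconvolve -> t1 -> st -> cpmg -> report.  Each stage reads the
    fixture files it needs from ``config.input_dir`` and appends its log
    lines; the report stage writes ``report.tsv`` and ``results.yaml`` in
    ``config.output_dir``.  A stage whose upstream product is missing
    raises :class:`PipelineError` naming the stage to run first.
    """
    requested = set(stages)
    unknown = requested - set(PIPELINE_STAGES)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in PIPELINE_STAGES if s in requested]
    if not stages:
        raise PipelineError("no stages requested")
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"config_digest={config.digest()}",
                      f"package_version={__version__}"]
    state: dict = {"log": log, "config": config}

    if "deconvolve" in stages:
        state["deconvolution"] = {}
        for cond in config.conditions:
            path = indir / f"spectrum_{cond}.tsv"
            if not path.exists():
                raise PipelineError(
                    f"deconvolve: missing {path.name}; generate the fixture "
                    "first (simulate)"
                )
            spec = read_spectrum(path)
            dec = fit_lorentzians(spec, n_peaks=2)
            areas = [p.area for p in dec.peaks]
            pops = populations_from_integrals(*areas)
            state["deconvolution"][cond] = {
                "peaks": dec.peaks,
                "p_active": pops[0],  # peaks sorted by descending ppm;
                "p_inactive": pops[1],  # the active resonance is downfield
                "converged": dec.converged,
            }
            log.append(
                f"deconvolve[{cond}]: centers="
                f"{[round(p.center, 3) for p in dec.peaks]} "
                f"pops=({pops[0]:.3f},{pops[1]:.3f}) converged={dec.converged}"
            )

    if "t1" in stages:
        state["r1"] = {}
        for cond in config.conditions:
            for res in ("active", "inactive"):
                path = indir / f"inversion_{res}_{cond}.tsv"
                if not path.exists():
                    raise PipelineError(f"t1: missing {path.name}")
                series, _ = read_intensity_table(path, "inversion")
                fit = fit_inversion_recovery(series)
                if not fit.converged:
                    raise PipelineError(f"t1: fit failed for {res}/{cond}: "
                                        f"{fit.flags}")
                state["r1"][(res, cond)] = fit
                log.append(f"t1[{res},{cond}]: R1={fit.values['r1']:.4f} "
                           f"+/- {fit.stderr['r1']:.4f}")

    if "st" in stages:
        if "r1" not in state:
            raise PipelineError("st: R1 values missing; run the t1 stage first")
        state["slow"] = {}
        state["st_fits"] = {}
        for cond in config.conditions:
            rates = {}
            for obs in ("inactive", "active"):
                path = indir / f"saturation_{obs}_{cond}.tsv"
                if not path.exists():
                    raise PipelineError(f"st: missing {path.name}")
                series, _ = read_intensity_table(path, "saturation")
                series = SaturationSeries(
                    taus=series.taus, intensities=series.intensities,
                    observed=series.observed, saturated=series.saturated,
                    condition=series.condition,
                    r1=state["r1"][(obs, cond)].values["r1"],
                    r1_provenance="fit_inversion_recovery",
                )
                fit = fit_saturation_transfer(series)
                rates[obs] = fit
                state["st_fits"][(obs, cond)] = fit
                log.append(f"st[{obs},{cond}]: k={fit.values['k_mn']:.4f} "
                           f"+/- {fit.stderr['k_mn']:.4f}")
            # observing the inactive resonance yields k(inactive->active)
            state["slow"][cond] = derive_slow_exchange_thermo(
                k_mn=rates["inactive"].values["k_mn"],
                k_nm=rates["active"].values["k_mn"],
                temperature=config.temperature_k,
                condition=cond,
                k_mn_err=rates["inactive"].stderr.get("k_mn") or 0.0,
                k_nm_err=rates["active"].stderr.get("k_mn") or 0.0,
            )

    if "cpmg" in stages:
        state["global"] = {}
        for res in ("active", "inactive"):
            datasets = []
            for cond in config.conditions:
                for fmhz in config.fields_mhz:
                    path = indir / f"cpmg_{res}_{cond}_{int(fmhz)}.tsv"
                    if not path.exists():
                        raise PipelineError(f"cpmg: missing {path.name}")
                    ds, warn = read_intensity_table(path, "cpmg")
                    for w in warn:
                        log.append(f"cpmg[{res}]: {w}")
                    datasets.append(ds)
            fit = fit_carver_richards_global(datasets)
            state["global"][res] = fit
            log.append(
                f"cpmg[{res}]: |ddelta|={fit.delta_delta:.4f} ppm; "
                + "; ".join(
                    f"{c}: k_i={p.k_i:.1f} p_minor={min(p.p_a, p.p_b):.4f}"
                    for c, p in sorted(fit.per_condition.items())
                )
                + f"; flags={list(fit.flags)}"
            )

    if "report" in stages:
        if "slow" not in state:
            raise PipelineError("report: slow-exchange fits missing; run the "
                                "st stage first")
        if "global" not in state:
            raise PipelineError("report: dispersion fits missing; run the "
                                "cpmg stage first")
        models = {}
        for cond in config.conditions:
            models[cond] = assemble_four_state_model(
                slow=state["slow"][cond],
                fast_inactive=state["global"]["inactive"].per_condition[cond],
                fast_active=state["global"]["active"].per_condition[cond],
                temperature=config.temperature_k,
            )
        state["models"] = models
        shifts = {
            (res, cond): config.assignments[res][cond]
            for res in ("active", "inactive")
            for cond in config.conditions
        }
        report = render_results_tables(
            models=models,
            slow_fits=state["slow"],
            global_fits=state["global"],
            shifts=shifts,
        )
        header = "\n".join(_provenance_lines({"config_digest": config.digest()}))
        (outdir / "report.tsv").write_text(header + "\n" + report)
        machine = {
            "config_digest": config.digest(),
            "package_version": __version__,
            "slow": {
                c: {"k_mn": s.k_mn, "k_nm": s.k_nm, "k_s": s.k_s,
                    "p_active": s.p_active, "p_inactive": s.p_inactive,
                    "delta_g": s.delta_g,
                    "uncertainties": dict(s.uncertainties)}
                for c, s in state["slow"].items()
            },
            "fast": {
                res: {
                    "delta_delta": g.delta_delta,
                    "per_condition": {
                        c: {"k_i": p.k_i, "p_minor": min(p.p_a, p.p_b)}
                        for c, p in g.per_condition.items()
                    },
                    "converged": g.converged,
                    "flags": list(g.flags),
                }
                for res, g in state["global"].items()
            },
            "four_state_populations": {
                c: dict(models[c].populations) for c in models
            },
        }
        with open(outdir / "results.yaml", "w") as fh:
            yaml.safe_dump(machine, fh, sort_keys=True)
        log.append("report: wrote report.tsv and results.yaml")

    (outdir / "pipeline.log").write_text("\n".join(log) + "\n")
    return state
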