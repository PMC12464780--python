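"""End-to-end orchestration of the three analysis stages.

A :class:`RunConfig` names a stage (``synth``, ``isotherm``, ``lpp``,
``surface`` or ``all``), its inputs and parameters; :func:`run_stage`
dispatches, writes machine-readable reports under the output directory,
and returns the in-memory report. Every report carries a provenance
block (config echo, package version, seed) sufficient to regenerate its
numbers exactly; no stage mutates its inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np

from . import io as mio
from . import isotherm as miso
from . import pressure as mpress
from . import surface as msurf
from . import synthetic as msynth
from .datatypes import MixtureSpec
from .errors import ConfigurationError, ValidationError
from .units import DEFAULT_TEMPERATURE

log = logging.getLogger("memcurve")

STAGES = ("synth", "isotherm", "lpp", "surface", "all")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    stage: str
    out_dir: Path
    seed: int = 0
    # isotherm stage
    mixture_path: Optional[Path] = None
    pure_cer_path: Optional[Path] = None
    pure_sm_path: Optional[Path] = None
    n_grid: int = 200
    gibbs_upper: Optional[float] = None
    # lpp stage
    stress_path: Optional[Path] = None
    temperature: float = DEFAULT_TEMPERATURE
    bounds: Optional[tuple[float, float]] = None
    full_box: bool = False
    support_fraction: float = 0.01
    # surface stage
    frame_paths: tuple = ()
    nx: int = 64
    ny: int = 64
    bandwidth: Optional[float] = None
    area_mode: str = "projected"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ConfigurationError(f"unknown stage {self.stage!r}")
        self.out_dir = Path(self.out_dir)
        for name in ("mixture_path", "pure_cer_path", "pure_sm_path",
                     "stress_path"):
            p = getattr(self, name)
            if p is not None:
                p = Path(p)
                if not p.exists():
                    raise ConfigurationError(f"{name}: no such file {p}")
                setattr(self, name, p)
        self.frame_paths = tuple(Path(p) for p in self.frame_paths)
        for p in self.frame_paths:
            if not p.exists():
                raise ConfigurationError(f"frame path does not exist: {p}")

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: (str(v) if isinstance(v, Path) else v) for k, v in d.items()}


@dataclass
class RunReport:
    """In-memory result of a pipeline run."""

    stage: str
    results: dict
    provenance: dict
    warnings: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "stage": self.stage,
            "results": self.results,
            "provenance": self.provenance,
            "warnings": self.warnings,
        }


def _provenance(config: RunConfig) -> dict:
    from . import __version__

    echo = config.echo()
    echo["frame_paths"] = [str(p) for p in config.frame_paths]
    return {"config": echo, "version": __version__, "seed": config.seed}


def _jsonify(obj: Any):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _write_report(report: RunReport, out_dir: Path, name: str) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{name}.json"
    with open(path, "w") as fh:
        json.dump(_jsonify(report.as_dict()), fh, indent=2)
    return path


def _run_isotherm(config: RunConfig) -> RunReport:
    if not (config.mixture_path and config.pure_cer_path and config.pure_sm_path):
        raise ConfigurationError(
            "isotherm stage needs mixture, pure-CER and pure-SM files"
        )
    mixture = mio.read_isotherm_csv(config.mixture_path)
    pure_cer = mio.read_isotherm_csv(config.pure_cer_path)
    pure_sm = mio.read_isotherm_csv(config.pure_sm_path)
    if mixture.composition is None:
        raise ValidationError("mixture file lacks an x_cer metadata line")
    spec = mixture.composition
    curve = miso.excess_area(mixture, pure_cer, pure_sm, spec, n_grid=config.n_grid)
    upper = config.gibbs_upper or float(curve.pressure_grid[-1])
    gibbs = miso.excess_gibbs_curve(curve)
    comp = miso.compressibility_modulus(mixture, n_grid=config.n_grid)
    phases = miso.classify_phase(comp)
    results = {
        "pressure_grid_mN_m": curve.pressure_grid,
        "A_exc_A2": curve.a_exc,
        "A_ideal_A2": curve.a_ideal,
        "A_mix_A2": curve.a_mix,
        "delta_G_exc_J_mol": gibbs.delta_g_exc,
        "delta_G_exc_at_upper_J_mol": miso.excess_gibbs_energy(curve, upper),
        "gibbs_upper_mN_m": upper,
        "Cs_inv_mN_m": comp.cs_inv,
        "Cs_inv_smoothing": comp.smoothing_descriptor,
        "phase_labels": phases["phase"],
        "phase_thresholds": phases["thresholds"],
        "x_cer": spec.fraction_cer,
    }
    return RunReport("isotherm", results, _provenance(config))


def _run_lpp(config: RunConfig) -> RunReport:
    if config.stress_path is None:
        raise ConfigurationError("lpp stage needs a stress profile file")
    stress = mio.read_stress(config.stress_path)
    profile = mpress.compute_lpp(stress)
    profile = mpress.center_midplane(profile)
    if config.bounds is not None:
        bounds = mpress.detect_bounds(profile, explicit=tuple(config.bounds))
    else:
        bounds = mpress.detect_bounds(
            profile,
            support_fraction=config.support_fraction,
            full_box=config.full_box,
        )
    constants = mpress.elastic_constants(profile, bounds, config.temperature)
    results = {
        "d_minus_nm": bounds.d_minus,
        "d_plus_nm": bounds.d_plus,
        "bounds_rule": bounds.detection_rule,
        "midplane_shift_nm": profile.midplane_shift,
        **constants.as_dict(),
    }
    return RunReport("lpp", results, _provenance(config))


def _run_surface(config: RunConfig) -> RunReport:
    if not config.frame_paths:
        raise ConfigurationError("surface stage needs at least one frame file")
    frames = [mio.read_frame(p) for p in config.frame_paths]
    summary = msurf.trajectory_summary(
        frames,
        nx=config.nx,
        ny=config.ny,
        bandwidth=config.bandwidth,
        area_mode=config.area_mode,
    )
    return RunReport("surface", summary.as_dict(), _provenance(config))


def _run_synth(config: RunConfig) -> RunReport:
    """Write one deterministic fixture of each kind under the output dir.

    The fixture parameters echo realistic CER/SM trough and membrane
    scales; downstream stages can be pointed straight at the files.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    # linear stand-ins calibrated to trough scales: pure CER reaches
    # 41 A^2 and pure SM 54 A^2 at 25 mN/m, with CER the stiffer film
    pure_cer = msynth.IsothermModel(
        "linear", (90.6, -1.6), (30.0, 52.0), noise_sd=0.0, seed=seed
    )
    pure_sm = msynth.IsothermModel(
        "linear", (73.6, -0.9), (30.0, 75.0), noise_sd=0.0, seed=seed + 1
    )
    scenario = msynth.MixtureScenario(
        mole_fraction_first=0.5, excess_area_coeffs=(-7.5,), seed=seed + 2
    )
    family = msynth.gen_mixture_family(pure_cer, pure_sm, scenario)
    mio.write_isotherm_csv(family.pure_first, out / "pure_cer.csv")
    mio.write_isotherm_csv(family.pure_second, out / "pure_sm.csv")
    mio.write_isotherm_csv(family.mixture, out / "mixture.csv")

    stress_model = msynth.StressFieldModel(
        bumps=msynth.bilayer_bumps(outer_gain=2.0),
        z_range=(-4.5, 4.5),
        n_points=512,
        seed=seed,
    )
    stress, truth = msynth.gen_stress_profile(stress_model)
    mio.write_stress_xvg(stress, out / "stress.xvg")

    surf_model = msynth.SurfaceModel(
        "sinusoid",
        {"height": 2.0, "amplitude": 0.8, "wavelength": 10.0},
        box=(10.0, 10.0),
        n_lipids_per_leaflet=400,
        seed=seed,
    )
    frame, oracle = msynth.gen_surface_cloud(surf_model)
    mio.write_frame_csv(frame, out / "frame0.csv")
    results = {
        "files": [str(out / n) for n in
                  ("pure_cer.csv", "pure_sm.csv", "mixture.csv",
                   "stress.xvg", "frame0.csv")],
        "stress_truth": truth.as_dict(),
        "surface_oracle_S_C": oracle,
        "declared_excess_area_A2": list(scenario.excess_area_coeffs),
    }
    return RunReport("synth", results, _provenance(config))


def run_stage(config: RunConfig, write: bool = True) -> RunReport:
    """Dispatch one pipeline stage and (optionally) write its report."""
    runners = {
        "synth": _run_synth,
        "isotherm": _run_isotherm,
        "lpp": _run_lpp,
        "surface": _run_surface,
    }
    if config.stage == "all":
        synth_report = _run_synth(config)
        out = config.out_dir
        chained = dataclasses.replace(
            config,
            stage="isotherm",
            mixture_path=out / "mixture.csv",
            pure_cer_path=out / "pure_cer.csv",
            pure_sm_path=out / "pure_sm.csv",
            stress_path=out / "stress.xvg",
            frame_paths=(out / "frame0.csv",),
        )
        reports = {"synth": synth_report}
        for stage in ("isotherm", "lpp", "surface"):
            sub = dataclasses.replace(chained, stage=stage)
            reports[stage] = runners[stage](sub)
        report = RunReport(
            "all",
            {k: r.results for k, r in reports.items()},
            _provenance(config),
            warnings=sum((r.warnings for r in reports.values()), []),
        )
    else:
        log.info("running stage %s", config.stage)
        report = runners[config.stage](config)
    if write:
        _write_report(report, config.out_dir, f"report_{config.stage}")
    return report


def run_comparative(config: RunConfig, scenarios: list[dict],
                    write: bool = True) -> RunReport:
    """Side-by-side comparison across synthetic scenarios.

    Two scenario kinds are understood:

    * ``{"name", "bumps", ...}`` — a stress-field scenario; the report row
      carries the bending moment and Gaussian modulus. A leaflet-
      asymmetric bump set can be compared against its symmetrised control
      (pass ``"symmetrize": True`` to mirror the bumps).
    * ``{"name", "x_cer", "excess_area_coeffs"}`` — a mixture-composition
      scenario; the row carries A_exc at the grid midpoint and ΔG_exc at
      the top of the shared pressure range.
    """
    if len(scenarios) < 2:
        raise ConfigurationError("comparative run needs >= 2 scenarios")
    rows = []
    for sc in scenarios:
        name = sc.get("name")
        if not name:
            raise ConfigurationError(f"scenario missing a name: {sc!r}")
        try:
            if "bumps" in sc:
                bumps = tuple(tuple(b) for b in sc["bumps"])
                if sc.get("symmetrize"):
                    bumps = msynth.mirror_bumps(bumps)
                model = msynth.StressFieldModel(
                    bumps=bumps,
                    z_range=tuple(sc.get("z_range", (-4.5, 4.5))),
                    n_points=int(sc.get("n_points", 512)),
                    noise_sd=float(sc.get("noise_sd", 0.0)),
                    seed=config.seed,
                    temperature=config.temperature,
                )
                stress, truth = msynth.gen_stress_profile(model)
                profile = mpress.center_midplane(mpress.compute_lpp(stress))
                consts = mpress.elastic_constants(
                    profile, temperature=config.temperature
                )
                rows.append({"name": name, "kind": "lpp", **consts.as_dict(),
                             "truth": truth.as_dict()})
            elif "x_cer" in sc:
                pure_cer = msynth.IsothermModel(
                    "linear", (90.6, -1.6), (30.0, 52.0), seed=config.seed
                )
                pure_sm = msynth.IsothermModel(
                    "linear", (73.6, -0.9), (30.0, 75.0), seed=config.seed + 1
                )
                scenario = msynth.MixtureScenario(
                    mole_fraction_first=float(sc["x_cer"]),
                    excess_area_coeffs=tuple(sc.get("excess_area_coeffs", (0.0,))),
                    seed=config.seed,
                )
                family = msynth.gen_mixture_family(pure_cer, pure_sm, scenario)
                curve = miso.excess_area(
                    family.mixture, family.pure_first, family.pure_second,
                    family.spec, n_grid=config.n_grid,
                )
                upper = float(curve.pressure_grid[-1])
                rows.append({
                    "name": name,
                    "kind": "isotherm",
                    "x_cer": float(sc["x_cer"]),
                    "A_exc_mid_A2": float(
                        curve.a_exc[curve.a_exc.size // 2]
                    ),
                    "delta_G_exc_J_mol": miso.excess_gibbs_energy(curve, upper),
                    "upper_mN_m": upper,
                })
            else:
                raise ConfigurationError("scenario kind not recognised")
        except Exception as exc:
            raise type(exc)(f"scenario {name!r}: {exc}") from exc
    report = RunReport("compare", {"rows": rows}, _provenance(config))
    if write:
        _write_report(report, config.out_dir, "report_compare")
    return report
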