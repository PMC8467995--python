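"""End-to-end orchestration: read data, run every requested analysis, emit a
machine-readable JSON report with units and provenance.

A run is described by a :class:`RunConfig` (usually loaded from YAML):

.. code-block:: yaml

    isotherms:
      dopc: data/dopc.csv
    mixtures:
      - mixture: data/mix_211.csv
        components: [[dopc, 0.5], [chol, 0.25], [sm, 0.25]]
        pressures: [5, 10, 15, 20, 25, 30, 35, 40, 45]
    stability:
      mix_112: data/stab.csv
    acv:
      mix_112: data/acv.csv
    eis:
      mix_112: data/eis.csv
    params:
      collapse_threshold: 10.0
      c_bare: 40.0
    seed: 0

Stages run in dependency order (isotherms before mixtures); a failure in one
dataset is recorded in the report without aborting independent stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .acv import ACVAnalyzer
from .datatypes import Isotherm, MixtureSpec
from .eis import CircuitFitter, goodness
from .io import read_acv, read_isotherm, read_spectrum, read_stability, validate_file
from .mixing import excess_sweep
from .monolayer import IsothermAnalyzer, StabilityAnalyzer

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "load_config"]

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Inputs and analysis parameters for one pipeline run."""

    isotherms: dict[str, str] = field(default_factory=dict)
    mixtures: list[dict] = field(default_factory=list)
    stability: dict[str, str] = field(default_factory=dict)
    acv: dict[str, str] = field(default_factory=dict)
    eis: dict[str, str] = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str | None = None


def load_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def validate_inputs(config: RunConfig) -> dict[str, list[str]]:
    """Per-file schema diagnostics; empty lists mean all files are valid."""
    report: dict[str, list[str]] = {}
    for name, path in config.isotherms.items():
        report[f"isotherm:{name}"] = validate_file(path, "isotherm")
    for i, mix in enumerate(config.mixtures):
        report[f"mixture:{i}"] = validate_file(mix.get("mixture", ""), "isotherm")
    for name, path in config.stability.items():
        report[f"stability:{name}"] = validate_file(path, "stability")
    for name, path in config.acv.items():
        report[f"acv:{name}"] = validate_file(path, "acv")
    for name, path in config.eis.items():
        report[f"eis:{name}"] = validate_file(path, "eis")
    return report


def _isotherm_entry(analyzer: IsothermAnalyzer) -> dict:
    f = analyzer.features_
    return {
        "a0_A2": f.a0,
        "a0_post_collapse_A2": f.a0_post_collapse,
        "area_at_30_mN_m_A2": f.a_at_30,
        "cs_inverse_max_mN_m": f.cs_max,
        "pressure_at_cs_max_mN_m": f.pressure_at_cs_max,
        "phase": f.phase,
        "collapse_pressures_mN_m": f.collapse_pressures,
        "kink_pressures_mN_m": f.kink_pressures,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns the report dictionary.

    The report carries a schema version, the package version, the echoed
    config and its hash; every numeric key names its unit.  Per-dataset
    failures appear under ``errors`` while other stages still run.
    """
    p = config.params
    errors: dict[str, str] = {}
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "raftfilm_version": __version__,
        "config": dataclasses.asdict(config),
        "config_sha256": hashlib.sha256(
            json.dumps(dataclasses.asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
    }

    iso_analyzers: dict[str, IsothermAnalyzer] = {}
    isotherms: dict[str, Isotherm] = {}
    out_iso: dict[str, dict] = {}
    for name, path in config.isotherms.items():
        try:
            iso = read_isotherm(path)
            an = IsothermAnalyzer(
                grid_step=p.get("grid_step", 0.1),
                collapse_threshold=p.get("collapse_threshold", 10.0),
                a0_window=tuple(p["a0_window"]) if "a0_window" in p else None,
            ).fit(iso)
            isotherms[name] = an.isotherm_
            iso_analyzers[name] = an
            out_iso[name] = _isotherm_entry(an)
        except Exception as exc:
            errors[f"isotherm:{name}"] = str(exc)
    if out_iso:
        report["isotherms"] = out_iso

    out_mix = []
    for i, mix in enumerate(config.mixtures):
        try:
            mixture = read_isotherm(mix["mixture"])
            comps = []
            for comp_name, fraction in mix["components"]:
                if comp_name not in isotherms:
                    raise KeyError(f"component '{comp_name}' not among analyzed isotherms")
                comps.append((comp_name, isotherms[comp_name], float(fraction)))
            spec = MixtureSpec(components=comps, mixture=mixture)
            pressures = mix.get("pressures", [5, 10, 15, 20, 25, 30, 35, 40, 45])
            results = excess_sweep(spec, pressures, grid=p.get("gibbs_grid", 0.5))
            out_mix.append(
                {
                    "mixture": mix["mixture"],
                    "results": [
                        {
                            "pressure_mN_m": r.pressure,
                            "a_ideal_A2": r.a_ideal,
                            "a_measured_A2": r.a_measured,
                            "a_excess_A2": r.a_excess,
                            "g_excess_J_mol": r.g_excess,
                            "percent_condensation": r.percent_condensation,
                        }
                        for r in results
                    ],
                }
            )
        except Exception as exc:
            errors[f"mixture:{i}"] = str(exc)
    if out_mix:
        report["mixtures"] = out_mix

    out_stab = {}
    for name, path in config.stability.items():
        try:
            an = StabilityAnalyzer(plateau_tol=p.get("plateau_tol", 0.5)).fit(
                read_stability(path)
            )
            out_stab[name] = {
                "plateau_pressure_mN_m": an.plateau_pressure_,
                "drift_rate_mN_m_per_h": an.drift_rate_,
                "time_to_plateau_s": an.time_to_plateau_,
            }
        except Exception as exc:
            errors[f"stability:{name}"] = str(exc)
    if out_stab:
        report["stability"] = out_stab

    out_acv = {}
    for name, path in config.acv.items():
        try:
            an = ACVAnalyzer(
                window=tuple(p.get("acv_window", (-0.3, 0.0))),
                c_bare=p.get("c_bare"),
                anchor_potential=p.get("anchor_potential"),
                anchor_sigma=p.get("anchor_sigma", 0.0),
            ).fit(read_acv(path))
            out_acv[name] = {
                "c_min_uF_cm2": an.estimate_.c_min,
                "e_at_min_V": an.estimate_.e_at_min,
                "e_pzfc_V": an.e_pzfc_,
                "coverage": an.theta_,
            }
        except Exception as exc:
            errors[f"acv:{name}"] = str(exc)
    if out_acv:
        report["acv"] = out_acv

    out_eis = {}
    for name, path in config.eis.items():
        try:
            spec = read_spectrum(path)
            fitter = CircuitFitter(
                weighting=p.get("weighting", "modulus"),
                topology=p.get("topology", "default"),
            ).fit(spec)
            chi2, phase_res = goodness(
                spec, fitter.params_, weighting=fitter.weighting, topology=fitter.topology
            )
            out_eis[name] = {
                "params": {
                    "r_sol_ohm_cm2": fitter.params_.r_sol,
                    "r_m_kohm_cm2": fitter.params_.r_m,
                    "q_m_uF_cm2_s_alpha": fitter.params_.q_m,
                    "alpha_m": fitter.params_.alpha_m,
                    "q_sp_uF_cm2_s_alpha": fitter.params_.q_sp,
                    "alpha_sp": fitter.params_.alpha_sp,
                },
                "stderr": fitter.stderr_,
                "chi_square_per_point": chi2,
                "max_phase_residual_deg": phase_res,
                "topology": fitter.topology,
            }
        except Exception as exc:
            errors[f"eis:{name}"] = str(exc)
    if out_eis:
        report["eis"] = out_eis

    report["errors"] = errors
    n_requested = (
        len(config.isotherms)
        + len(config.mixtures)
        + len(config.stability)
        + len(config.acv)
        + len(config.eis)
    )
    report["status"] = (
        "ok" if not errors else ("failed" if len(errors) == n_requested else "partial")
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, default=_json_default)
    return report


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
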