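"""Configuration-driven orchestration of the analysis stages.

A TOML config selects stages (``afm``, ``pmf``, ``collapse``, ``ftir``,
``seq``), their input paths and parameters, an output directory and a
global seed.  Stages run in order; a failing stage is recorded and the
remaining (independent) stages still run.  The aggregated JSON report
carries per-stage summaries plus provenance: config hash, package version
and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "REPORT_SCHEMA_VERSION"]

REPORT_SCHEMA_VERSION = 1
VALID_STAGES = ("afm", "pmf", "collapse", "ftir", "seq")

_GLOBAL_KEYS = {"stages", "output_dir", "seed", "log_level"}

logger = logging.getLogger("nanospring")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    stages: list[str]
    output_dir: str
    seed: int = 0
    log_level: str = "INFO"
    stage_params: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in VALID_STAGES]
        if unknown:
            raise ValueError(
                f"unknown stage(s) {unknown}; valid stages are {list(VALID_STAGES)}"
            )
        for stage, params in self.stage_params.items():
            if stage not in VALID_STAGES:
                raise ValueError(f"parameters given for unknown stage '{stage}'")
            for key in ("traces", "windows", "manifest", "trajectories", "spectra", "fasta"):
                if key in params and not Path(params[key]).exists():
                    raise ValueError(
                        f"stage '{stage}': input path does not exist: {params[key]}"
                    )


def load_config(path) -> PipelineConfig:
    """Load and validate a TOML pipeline configuration."""
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    stage_params = {k: v for k, v in raw.items() if k not in _GLOBAL_KEYS}
    for key, val in raw.items():
        if key not in _GLOBAL_KEYS and not isinstance(val, dict):
            raise ValueError(f"unknown top-level config key: {key}")
    return PipelineConfig(
        stages=list(raw.get("stages", [])),
        output_dir=str(raw.get("output_dir", ".")),
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
        stage_params=stage_params,
    )


def _stage_afm(params: dict, seed: int) -> dict:
    from . import afm

    traces = afm.read_traces(params["traces"])
    lp_transform = float(params.get("lp_transform", 0.4))
    sep = float(params.get("sep", 8.0))
    tol = float(params.get("tol", 2.0))
    fits, events = [], []
    for trace in traces:
        try:
            corrected = afm.correct_baseline(trace)
            event = afm.detect_specific_event(
                corrected,
                persistence_length_nm=lp_transform,
                expected_separation_nm=sep,
                tolerance_nm=tol,
            )
        except (ValueError, afm.BaselineError) as exc:
            events.append({"trace_id": trace.trace_id, "specific": False, "reason": str(exc)})
            continue
        events.append(
            {
                "trace_id": trace.trace_id,
                "specific": event.specific,
                "delta_Lc_nm": event.delta_Lc_nm,
                "reason": event.reason,
            }
        )
        if event.specific:
            fits.append(afm.analyze_trace(corrected, event))
    summary: dict = {"n_traces": len(traces), "n_specific": len(fits), "events": events}
    if fits:
        pop = afm.summarize_population(fits, n_total=len(traces))
        summary.update(
            contour_mean_nm=pop.contour_mean_nm,
            contour_sd_nm=pop.contour_sd_nm,
            persistence_mean_nm=pop.persistence_mean_nm,
            persistence_sd_nm=pop.persistence_sd_nm,
        )
    return summary


def _stage_pmf(params: dict, seed: int) -> dict:
    from . import pmf as pmf_mod
    from .wlc import fit_wlc

    windows = pmf_mod.read_windows(
        params["windows"], manifest=params.get("manifest")
    )
    stride = int(params.get("stride", 1))
    if stride > 1:
        for w in windows:
            w.samples_nm = w.samples_nm[::stride]
    profile = pmf_mod.wham(
        windows, temperature_K=float(params.get("temp", 300.0))
    )
    out = {
        "converged": profile.converged,
        "n_iterations": profile.n_iterations,
        "n_windows": len(windows),
        "grid_nm": profile.grid_nm.tolist(),
        "free_energy_kJ_mol": np.nan_to_num(profile.free_energy_kJ_mol, nan=-1.0).tolist(),
    }
    if profile.converged and params.get("fit_wlc", True):
        z, f = pmf_mod.mean_force_profile(profile)
        ok = np.isfinite(f) & (f > 0)
        if ok.sum() >= 3:
            fit = fit_wlc(np.column_stack([z[ok], f[ok]]))
            out["wlc_persistence_length_nm"] = fit.params.persistence_length_nm
            out["wlc_contour_length_nm"] = fit.params.contour_length_nm
    return out


def _stage_collapse(params: dict, seed: int) -> dict:
    from . import collapse as col

    trajs = col.read_trajectories(params["trajectories"])
    records = col.first_passage_times(
        trajs, threshold_nm=float(params.get("threshold", 1.5))
    )
    fit = col.fit_lifetime(records, seed=seed)
    return {
        "tau_ns": fit.tau_ns,
        "tau_ci_ns": list(fit.tau_ci_ns),
        "n_events": fit.n_events,
        "n_censored": fit.n_censored,
        "n_total": fit.n_total,
    }


def _stage_ftir(params: dict, seed: int) -> dict:
    from . import ftir

    spectra = ftir.read_plate_csv(params["spectra"])
    kmax = int(params.get("kmax", 13))
    n_starts = int(params.get("starts", 10))
    carriers = sorted({s.carrier_id for s in spectra})
    per_carrier = {}
    best_models = {}
    for carrier in carriers:
        group = [s for s in spectra if s.carrier_id == carrier]
        med = ftir.median_spectrum(ftir.preprocess_spectra(group))
        fits = [
            ftir.fit_gaussian_mixture(med, k, n_starts=n_starts, seed=seed + k)
            for k in range(1, kmax + 1)
        ]
        sel = ftir.select_component_count(fits)
        per_carrier[carrier] = {
            "weighted_mean_k": sel.weighted_mean_k,
            "weighted_sd_k": sel.weighted_sd_k,
            "records": sel.records,
        }
        best_models[carrier] = max(
            zip(fits, [r[2] for r in sel.records]), key=lambda p: p[1]
        )[0]
    summary: dict = {"per_carrier": per_carrier}
    if len(best_models) >= 2:
        report = ftir.peak_width_analysis(best_models)
        summary["peak_width"] = {
            "mean_fwhm_cm1": report.mean_fwhm_cm1,
            "mean_sd_cm1": report.mean_sd_cm1,
            "p_value": report.p_value,
            "excluded": report.excluded_replicates,
        }
    return summary


def _stage_seq(params: dict, seed: int) -> dict:
    from . import sequence as seqmod

    records = seqmod.read_fasta(params["fasta"])
    motif = params.get("motif", "GXGQQ")
    out = {}
    for rec in records:
        metrics = seqmod.uversky_metrics(rec)
        out[rec.id] = {
            "mean_hydropathy": metrics.mean_hydropathy,
            "mean_net_charge": metrics.mean_net_charge,
            "classification": metrics.classification,
            "composition": metrics.composition,
            "motif": motif,
            "motif_positions_1based": seqmod.scan_motif(rec, motif),
        }
    return out


_STAGE_FNS = {
    "afm": _stage_afm,
    "pmf": _stage_pmf,
    "collapse": _stage_collapse,
    "ftir": _stage_ftir,
    "seq": _stage_seq,
}


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(
        {
            "stages": config.stages,
            "seed": config.seed,
            "stage_params": config.stage_params,
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and write the aggregated JSON report.

    Returns the report dict; the report is also written to
    ``<output_dir>/report.json``.  Stage failures are recorded in the report
    and reflected in the ``"failed_stages"`` list; independent later stages
    still run.
    """
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(name)s %(levelname)s %(message)s",
    )
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "nanospring_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
        "failed_stages": [],
    }
    for stage in config.stages:
        log = logging.getLogger(f"nanospring.{stage}")
        params = config.stage_params.get(stage, {})
        try:
            log.info("running stage %s", stage)
            report["stages"][stage] = _STAGE_FNS[stage](params, config.seed)
        except Exception as exc:  # noqa: BLE001 - stage isolation by design
            log.error("stage %s failed: %s", stage, exc)
            report["stages"][stage] = {"error": str(exc)}
            report["failed_stages"].append(stage)
    _validate_report(report)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _validate_report(report: dict) -> None:
    required = {"schema_version", "nanospring_version", "config_hash", "seed", "stages"}
    missing = required - set(report)
    if missing:
        raise RuntimeError(f"malformed report, missing keys: {sorted(missing)}")
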