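"""Config-driven pipeline runner with a provenance manifest.

A pipeline config (YAML) is a mapping with a ``stages`` list; each stage
has a ``stage`` name plus stage-specific keys.  Unknown top-level or stage
keys are rejected, and every stochastic stage must carry an explicit seed.
The runner writes every artifact plus ``manifest.json`` (inputs, outputs,
seeds, package version) into the output directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from . import __version__, io, kinetics, spin_quant, stability_model, synthetic_data
from .chemometrics import fuse_variables, normalize_total_signal, pareto_scale, pca
from .spin_sim import AcquisitionSettings, SpinSystem, simulate_spectrum

log = logging.getLogger("eprstab.pipeline")

_TOP_KEYS = {"stages", "out_dir"}
_STAGE_KEYS: dict[str, set[str]] = {
    "simulate": {"systems", "settings", "seed", "out"},
    "generate-epr": {"scenario", "seed", "out"},
    "generate-features": {"layout", "seed", "out"},
    "fixtures": {"out"},
    "integrate": {"infile", "out"},
    "decompose": {"infile", "systems", "out"},
    "kinetics": {"infile", "out"},
    "predict-auc": {"records", "fit", "out"},
    "pca": {"infile", "fuse", "components", "out"},
}
_STOCHASTIC = {"simulate", "generate-epr", "generate-features"}


@dataclass
class PipelineConfig:
    stages: list[dict[str, Any]] = field(default_factory=list)
    out_dir: Path = Path(".")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_mapping(doc)

    @classmethod
    def from_mapping(cls, doc: Mapping[str, Any]) -> "PipelineConfig":
        unknown = set(doc) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        stages = list(doc.get("stages", []))
        for st in stages:
            name = st.get("stage")
            if name not in _STAGE_KEYS:
                raise ValueError(f"unknown stage {name!r}")
            extra = set(st) - _STAGE_KEYS[name] - {"stage"}
            if extra:
                raise ValueError(f"stage {name!r} has unknown keys: {sorted(extra)}")
            if name in _STOCHASTIC and "seed" not in st:
                raise ValueError(f"stochastic stage {name!r} requires an explicit seed")
        return cls(stages=stages, out_dir=Path(doc.get("out_dir", ".")))


def _systems_from(entry: Any) -> list[SpinSystem]:
    if isinstance(entry, str):
        return io.load_spin_systems(entry)
    return [SpinSystem(**e) for e in entry]


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the configured stages in order; return the manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package": "eprstab",
        "version": __version__,
        "stages": [],
        "status": "ok",
    }
    for st in config.stages:
        name = st["stage"]
        record: dict[str, Any] = {"stage": name, "params": {k: v for k, v in st.items() if k != "stage"}}
        log.info("stage %s: %s", name, record["params"])
        try:
            outputs = _run_stage(name, st, out_dir)
        except Exception as exc:
            record["error"] = str(exc)
            manifest["stages"].append(record)
            manifest["status"] = "failed"
            _write_manifest(manifest, out_dir)
            raise
        record["outputs"] = outputs
        manifest["stages"].append(record)
    _write_manifest(manifest, out_dir)
    return manifest


def _write_manifest(manifest: dict[str, Any], out_dir: Path) -> None:
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")


def _run_stage(name: str, st: Mapping[str, Any], out_dir: Path) -> list[str]:
    out = st.get("out")

    if name == "simulate":
        systems = _systems_from(st["systems"])
        settings = AcquisitionSettings(**(st.get("settings") or {}), seed=st.get("seed"))
        spec = simulate_spectrum(systems, settings)
        path = out_dir / (out or "spectrum.csv")
        io.write_spectrum(spec, path)
        return [str(path)]

    if name == "generate-epr":
        scen_kwargs = dict(st.get("scenario") or {})
        if "systems" in scen_kwargs:
            scen_kwargs["systems"] = tuple(_systems_from(scen_kwargs["systems"]))
        scenario = synthetic_data.KineticScenario(**scen_kwargs, seed=st["seed"])
        spectra, truth = synthetic_data.gen_epr_timeseries(scenario)
        series = kinetics.series_from_spectra(spectra, temperature=scenario.temperature)
        path = out_dir / (out or "series.csv")
        io.write_series(series, path)
        truth_path = path.with_suffix(".truth.json")
        truth_path.write_text(json.dumps(truth, indent=2) + "\n")
        return [str(path), str(truth_path)]

    if name == "generate-features":
        matrix, _ = synthetic_data.gen_feature_table(**(st.get("layout") or {}), seed=st["seed"])
        path = out_dir / (out or "features.csv")
        io.write_feature_matrix(matrix, path)
        return [str(path)]

    if name == "fixtures":
        records = list(synthetic_data.fixtures_table1().values())
        path = out_dir / (out or "oils.csv")
        io.write_oil_records(records, path)
        return [str(path)]

    if name == "integrate":
        spec = io.read_spectrum(st["infile"])
        value = spin_quant.double_integrate(spec)
        path = out_dir / (out or "integral.json")
        path.write_text(json.dumps({"double_integral": value}, indent=2) + "\n")
        return [str(path)]

    if name == "decompose":
        spec = io.read_spectrum(st["infile"])
        result = spin_quant.decompose(spec, _systems_from(st["systems"]))
        path = out_dir / (out or "decomposition.json")
        path.write_text(
            json.dumps(
                {"weights": result.as_dict(), "residual_norm": result.residual_norm},
                indent=2,
            )
            + "\n"
        )
        return [str(path)]

    if name == "kinetics":
        series = io.read_series(st["infile"])
        fit = kinetics.fit_boltzmann(series)
        area = kinetics.auc(series)
        path = out_dir / (out or "kinetics.json")
        path.write_text(
            json.dumps(
                {
                    "I1": fit.I1, "I2": fit.I2, "t0": fit.t0, "dt": fit.dt,
                    "IP": fit.IP, "auc": area, "converged": fit.converged,
                },
                indent=2,
            )
            + "\n"
        )
        return [str(path)]

    if name == "predict-auc":
        records = io.read_oil_records(st["records"])
        if st.get("fit"):
            usable = [r for r in records if r.AUC_measured is not None]
            coef = stability_model.fit_coefficients(usable)
        else:
            coef = stability_model.PUBLISHED_COEFFICIENTS
        table = stability_model.model_residuals(records, coef)
        payload = {
            "coefficients": {"c_PV": coef.c_PV, "c_TPC": coef.c_TPC, "c_FFA": coef.c_FFA},
            "records": table.reset_index().to_dict(orient="records"),
        }
        path = out_dir / (out or "predictions.json")
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return [str(path)]

    if name == "pca":
        matrix = io.read_feature_matrix(st["infile"])
        matrix = normalize_total_signal(matrix)
        if st.get("fuse"):
            import pandas as pd

            assays = pd.read_csv(st["fuse"], index_col=0)
            matrix = fuse_variables(matrix, assays)
        matrix = pareto_scale(matrix)
        model = pca(matrix, int(st.get("components", 2)))
        scores_path = out_dir / "scores.csv"
        loadings_path = out_dir / "loadings.csv"
        r2x_path = out_dir / "r2x.json"
        model.scores.to_csv(scores_path)
        model.loadings.to_csv(loadings_path)
        r2x_path.write_text(json.dumps({"r2x": list(map(float, model.r2x))}, indent=2) + "\n")
        return [str(scores_path), str(loadings_path), str(r2x_path)]

    raise ValueError(f"unknown stage {name!r}")
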