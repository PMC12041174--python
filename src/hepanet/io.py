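"""Serialisation, run configuration and the end-to-end pipeline.

Interchange formats (all plain text, UTF-8, dot-decimal):

* Network JSON -- the documented schema below; reading rejects unknown or
  missing fields with an error naming the field path, and write/read
  round-trips bit-identically for the declared fields.
* Measurements CSV -- columns ``patient_id, scenario, branch, flow_ml_min,
  variability``; unit-labelled column names are mandatory so mislabelled
  files fail loudly.
* Flow solutions -- a flows CSV (``segment_id, name, flow_ml_min``) and a
  pressures CSV (``node_id, pressure_mmHg``), each with the scenario in a
  ``#`` header comment.

The pipeline runs calibrate -> baseline -> clamp_GDA -> clamp_CHA ->
intervals -> validation on one patient's inputs and writes its outputs plus
a key=value run log under the configured directory. Runs are deterministic:
identical inputs and config give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .calibration import (
    CalibrationReport,
    FlowMeasurement,
    calibrate_outlets,
    infer_pha0,
    reconcile_baseline,
)
from .errors import NonphysicalBaselineError, SchemaError
from .evaluation import ValidationRecord, range_accuracy, relative_error
from .network import (
    ArterialNetwork,
    InletBC,
    Variant,
    VesselSegment,
    WindkesselOutlet,
    validate_network,
)
from .scenarios import ScenarioPrediction, predict_scenarios
from .solver import BASELINE, CLAMP_CHA, CLAMP_GDA, FlowSolution

__all__ = [
    "RunConfig",
    "read_network",
    "write_network",
    "read_measurements",
    "write_measurements",
    "measurements_from_frame",
    "write_solution",
    "run_pipeline",
    "PipelineResult",
]

_SEGMENT_FIELDS = {
    "id", "name", "proximal", "distal", "radius_mm", "length_mm",
    "area_reduction", "stenosis_length_mm",
}
_OUTLET_FIELDS = {
    "node", "resistance_mmHg_min_per_ml", "compliance_ml_per_mmHg",
    "reference_pressure_mmHg",
}
_NETWORK_FIELDS = {"variant", "viscosity_pa_s", "inlet", "segments", "outlets",
                   "clamped"}
_MEASUREMENT_COLUMNS = ["patient_id", "scenario", "branch", "flow_ml_min",
                        "variability"]


def _check_fields(obj: dict, allowed: set[str], required: set[str], path: str):
    unknown = set(obj) - allowed
    if unknown:
        raise SchemaError(f"unknown field {path}.{sorted(unknown)[0]}")
    missing = required - set(obj)
    if missing:
        raise SchemaError(f"missing field {path}.{sorted(missing)[0]}")


def network_to_dict(network: ArterialNetwork) -> dict:
    return {
        "variant": network.variant.value,
        "viscosity_pa_s": network.viscosity,
        "inlet": {"node": network.inlet.node,
                  "pressure_mmHg": network.inlet.pressure},
        "segments": [
            {
                "id": s.id,
                "name": s.name,
                "proximal": s.proximal_node,
                "distal": s.distal_node,
                "radius_mm": s.radius,
                "length_mm": s.length,
                "area_reduction": s.area_reduction,
                "stenosis_length_mm": s.stenosis_length,
            }
            for s in network.segments
        ],
        "outlets": [
            {
                "node": o.node,
                "resistance_mmHg_min_per_ml": o.resistance,
                "compliance_ml_per_mmHg": o.compliance,
                "reference_pressure_mmHg": o.reference_pressure,
            }
            for o in network.outlets
        ],
        "clamped": sorted(network.clamped_segments),
    }


def network_from_dict(data: dict) -> ArterialNetwork:
    _check_fields(data, _NETWORK_FIELDS, _NETWORK_FIELDS, "network")
    _check_fields(data["inlet"], {"node", "pressure_mmHg"},
                  {"node", "pressure_mmHg"}, "network.inlet")
    segments = []
    for i, seg in enumerate(data["segments"]):
        _check_fields(seg, _SEGMENT_FIELDS, _SEGMENT_FIELDS,
                      f"network.segments[{i}]")
        segments.append(
            VesselSegment(
                id=seg["id"], name=seg["name"],
                proximal_node=seg["proximal"], distal_node=seg["distal"],
                radius=seg["radius_mm"], length=seg["length_mm"],
                area_reduction=seg["area_reduction"],
                stenosis_length=seg["stenosis_length_mm"],
            )
        )
    outlets = []
    for i, out in enumerate(data["outlets"]):
        _check_fields(out, _OUTLET_FIELDS, _OUTLET_FIELDS,
                      f"network.outlets[{i}]")
        outlets.append(
            WindkesselOutlet(
                node=out["node"],
                resistance=out["resistance_mmHg_min_per_ml"],
                compliance=out["compliance_ml_per_mmHg"],
                reference_pressure=out["reference_pressure_mmHg"],
            )
        )
    network = ArterialNetwork(
        segments=tuple(segments),
        inlet=InletBC(node=data["inlet"]["node"],
                      pressure=data["inlet"]["pressure_mmHg"]),
        outlets=tuple(outlets),
        variant=Variant(data["variant"]),
        viscosity=data["viscosity_pa_s"],
        clamped_segments=frozenset(data["clamped"]),
    )
    known = {s.id for s in network.segments}
    for sid in data["clamped"]:
        if sid not in known:
            raise SchemaError(f"unknown field network.clamped: segment {sid!r}")
    return network


def write_network(network: ArterialNetwork, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(network_to_dict(network), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )


def read_network(path: str | Path) -> ArterialNetwork:
    try:
        data = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise SchemaError(f"invalid JSON in {path}: {exc}") from exc
    return network_from_dict(data)


# -- measurements -----------------------------------------------------------

def write_measurements(
    measurements: dict[str, list[FlowMeasurement]] | list[FlowMeasurement],
    path: str | Path,
    patient_id: str = "P001",
) -> None:
    """Write measurements CSV; accepts a list (one patient) or a dict by id."""
    if isinstance(measurements, list) or isinstance(measurements, tuple):
        measurements = {patient_id: list(measurements)}
    rows = [
        {
            "patient_id": pid,
            "scenario": m.scenario,
            "branch": m.branch,
            "flow_ml_min": m.flow,
            "variability": m.variability,
        }
        for pid, ms in measurements.items()
        for m in ms
    ]
    pd.DataFrame(rows, columns=_MEASUREMENT_COLUMNS).to_csv(path, index=False)


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read a measurements CSV, enforcing the unit-labelled column names."""
    df = pd.read_csv(path)
    if list(df.columns) != _MEASUREMENT_COLUMNS:
        raise SchemaError(
            f"measurements CSV must have columns {_MEASUREMENT_COLUMNS}, "
            f"got {list(df.columns)}"
        )
    return df


def measurements_from_frame(
    df: pd.DataFrame,
    patient_id: str | None = None,
    scenario: str | None = None,
) -> list[FlowMeasurement]:
    if patient_id is not None:
        df = df[df["patient_id"] == patient_id]
    if scenario is not None:
        df = df[df["scenario"] == scenario]
    return [
        FlowMeasurement(
            branch=row.branch,
            flow=float(row.flow_ml_min),
            variability=float(row.variability),
            scenario=row.scenario,
        )
        for row in df.itertuples()
    ]


def write_solution(
    solution: FlowSolution,
    network: ArterialNetwork,
    flows_path: str | Path,
    pressures_path: str | Path,
) -> None:
    """Serialise a solution: flows and pressures CSVs with a scenario header."""
    names = {s.id: s.name for s in network.segments}
    with open(flows_path, "w", encoding="utf-8") as fh:
        fh.write(f"# scenario={solution.scenario}\n")
        fh.write("segment_id,name,flow_ml_min\n")
        for sid in sorted(solution.segment_flows):
            fh.write(f"{sid},{names.get(sid, '')},{solution.segment_flows[sid]:.6f}\n")
    with open(pressures_path, "w", encoding="utf-8") as fh:
        fh.write(f"# scenario={solution.scenario}\n")
        fh.write("node_id,pressure_mmHg\n")
        for node in sorted(solution.node_pressures):
            fh.write(f"{node},{solution.node_pressures[node]:.6f}\n")


# -- run configuration ------------------------------------------------------

@dataclass
class RunConfig:
    """All tunable pipeline parameters, with their physiological defaults."""

    inlet_pressure_mmHg: float = 100.0
    viscosity_pa_s: float = 0.0035
    calibration_tolerance: float = 0.01
    interval_variability: float = 0.15
    habr_gain: float = 0.0
    seed: int = 0
    output_dir: str = "results/run"
    log_level: str = "INFO"

    def __post_init__(self):
        for name in ("inlet_pressure_mmHg", "viscosity_pa_s",
                     "calibration_tolerance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.interval_variability <= 0.5:
            raise ValueError("interval_variability must be in [0, 0.5]")
        if self.habr_gain < 0:
            raise ValueError("habr_gain must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        allowed = {f.name for f in dataclasses.fields(cls)}
        _check_fields(data, allowed, set(), "config")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text(encoding="utf-8")
        if str(path).endswith((".yaml", ".yml")):
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data or {})


# -- pipeline ---------------------------------------------------------------

@dataclass
class PipelineResult:
    network: ArterialNetwork  # calibrated
    report: CalibrationReport
    solutions: dict[str, FlowSolution]
    predictions: list[ScenarioPrediction]
    validation: list[ValidationRecord] = field(default_factory=list)


def run_pipeline(
    config: RunConfig,
    network_path: str | Path,
    measurements_path: str | Path,
    patient_id: str | None = None,
) -> PipelineResult:
    """Calibrate one patient and predict all three scenarios; write outputs.

    Stages: read + validate inputs -> baseline sanity guard -> calibrate
    outlets -> solve baseline/clamp_GDA/clamp_CHA -> prediction intervals ->
    validation against any measured post-clamp flows. Outputs under
    ``config.output_dir``: predictions.csv, calibration_report.json, per-
    scenario flow/pressure CSVs, validation.csv (if post-clamp measurements
    exist) and run_log.txt. Raises a stage-named error on any failure.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"stage=config hepanet_version={_pkg_version}"]
    for key, value in sorted(config.to_dict().items()):
        log_lines.append(f"stage=config {key}={value}")

    network = read_network(network_path)
    diags = validate_network(network)
    if diags:
        raise SchemaError(f"stage=read_network invalid network: {diags}")
    df = read_measurements(measurements_path)
    if patient_id is None:
        ids = df["patient_id"].unique()
        if len(ids) != 1:
            raise ValueError(
                "stage=read_measurements multiple patients in file; pass patient_id"
            )
        patient_id = str(ids[0])
    log_lines.append(f"stage=inputs network={network_path} "
                     f"measurements={measurements_path} patient_id={patient_id}")

    baseline_ms = measurements_from_frame(df, patient_id, BASELINE)
    flows = {m.branch: m.flow for m in baseline_ms}
    if "CHA" in flows and "GDA" in flows and network.variant is Variant.MICHELS_I:
        infer_pha0(flows["CHA"], flows["GDA"])  # raises NonphysicalBaselineError
    calibrated, report = calibrate_outlets(
        network, reconcile_baseline(baseline_ms),
        tolerance=config.calibration_tolerance,
    )
    log_lines.append(
        f"stage=calibrate converged={report.converged} "
        f"iterations={report.iterations} "
        f"max_mismatch={max(report.mismatches.values()):.6f}"
    )
    (out / "calibration_report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )

    solutions, predictions = predict_scenarios(
        calibrated,
        variability=config.interval_variability,
        habr_gain=config.habr_gain,
    )
    for name, sol in solutions.items():
        write_solution(sol, calibrated, out / f"flows_{name}.csv",
                       out / f"pressures_{name}.csv")
        log_lines.append(f"stage=scenario scenario={name} "
                         f"pha_flow_ml_min={sol.flow('PHA'):.6f}")
    with open(out / "predictions.csv", "w", encoding="utf-8") as fh:
        fh.write("scenario,branch,predicted_ml_min,interval_min_ml_min,"
                 "interval_max_ml_min,reversed\n")
        for p in predictions:
            fh.write(f"{p.scenario},{p.branch},{p.predicted_flow:.6f},"
                     f"{p.interval_min:.6f},{p.interval_max:.6f},{p.reversed}\n")

    validation: list[ValidationRecord] = []
    pha0 = infer_pha0(flows["CHA"], flows["GDA"]) \
        if {"CHA", "GDA"} <= set(flows) else flows.get("PHA", float("nan"))
    for scenario in (CLAMP_GDA, CLAMP_CHA):
        post = {m.branch: m.flow
                for m in measurements_from_frame(df, patient_id, scenario)}
        if "PHA" not in post:
            continue
        pred = next(p for p in predictions
                    if p.scenario == scenario and p.branch == "PHA")
        validation.append(
            ValidationRecord(
                patient_id=patient_id, scenario=scenario,
                cha0=flows.get("CHA", float("nan")),
                gda0=flows.get("GDA", float("nan")),
                pha0=pha0,
                real_post=post["PHA"], predicted_post=pred.predicted_flow,
                interval_min=pred.interval_min, interval_max=pred.interval_max,
            )
        )
    if validation:
        with open(out / "validation.csv", "w", encoding="utf-8") as fh:
            fh.write("patient_id,scenario,real_ml_min,predicted_ml_min,"
                     "interval_min_ml_min,interval_max_ml_min,in_range,error_pct\n")
            for r in validation:
                fh.write(
                    f"{r.patient_id},{r.scenario},{r.real_post:.6f},"
                    f"{r.predicted_post:.6f},{r.interval_min:.6f},"
                    f"{r.interval_max:.6f},{r.in_range()},"
                    f"{relative_error(r.predicted_post, r.real_post):.4f}\n"
                )
        log_lines.append(
            f"stage=validation n={len(validation)} "
            f"range_accuracy_pct={range_accuracy(validation):.1f}"
        )

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return PipelineResult(
        network=calibrated,
        report=report,
        solutions=solutions,
        predictions=predictions,
        validation=validation,
    )
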