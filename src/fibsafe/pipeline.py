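"""End-to-end corridor analysis pipeline.

Stages: ingest or generate a cohort -> shape metrics -> per-subject tunnel
simulation -> Procrustes registration (overlay / QC) -> cohort corridors
and summary statistics.  Corridor numbers are computed from the raw
per-subject signed percent locations, which are similarity-invariant;
registration only pools the drawings.

Given an identical configuration and seed the report JSON is
byte-identical across runs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import FibsafeError, ParameterError, PipelineError
from .geometry import CrossSection, SNAP_TOL_MM
from .io import load_cohort, write_cohort
from .registration import register_cohort
from .shape import aspect_ratio, classify_shape
from .stats import (
    CorridorReport,
    cohort_corridor_angulated,
    cohort_corridor_central,
    paired_t_and_pearson,
    summarize,
)
from .synthetic import CohortParams, generate_cohort
from .tunnels import solve_subject

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``cohort`` (synthetic generation parameters) or
    ``input_dir`` (pre-existing cohort files) must be supplied.
    """

    cohort: Optional[CohortParams] = None
    input_dir: Optional[str] = None
    tunnel_diameter_mm: float = 3.5
    reference_policy: str = "mean"
    epsilon: float = 1e-9
    snap_tol_mm: float = SNAP_TOL_MM
    normalization: str = "arc"  # cortical-edge normalization: arc | chord
    corridor_mode: str = "intersection"
    output_dir: Optional[str] = None
    seed: int = 0
    figures: bool = True

    def __post_init__(self) -> None:
        if isinstance(self.cohort, dict):
            self.cohort = CohortParams(**self.cohort)
        if (self.cohort is None) == (self.input_dir is None):
            raise ParameterError(
                "exactly one of cohort params or input_dir must be supplied"
            )
        if self.tunnel_diameter_mm < 0:
            raise ParameterError("tunnel_diameter_mm must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)

    def to_dict(self) -> dict:
        d = {
            "input_dir": self.input_dir,
            "tunnel_diameter_mm": self.tunnel_diameter_mm,
            "reference_policy": self.reference_policy,
            "epsilon": self.epsilon,
            "snap_tol_mm": self.snap_tol_mm,
            "normalization": self.normalization,
            "corridor_mode": self.corridor_mode,
            "seed": self.seed,
            "figures": self.figures,
        }
        d["cohort"] = None if self.cohort is None else self.cohort.to_dict()
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    report: dict
    corridor_report: CorridorReport
    sections: list
    solutions: dict  # subject_id -> orientation -> TunnelSolution
    shape_table: pd.DataFrame
    registration_table: pd.DataFrame
    truth: Optional[pd.DataFrame] = None
    log: list = field(default_factory=list)


def _json_default(o):
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _round_floats(obj, ndigits=10):
    """Round floats recursively so report bytes are stable across platforms."""
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _transform_solutions(sols: dict, t) -> dict:
    """Map solution exit points into the registered frame (values unchanged)."""
    import copy

    from .geometry import ExitLocation, TunnelAxis

    out = {}
    for orientation, sol in sols.items():
        new = copy.copy(sol)
        for attr in ("anterior_border", "posterior_border", "central"):
            loc = getattr(sol, attr)
            if loc is not None:
                setattr(
                    new,
                    attr,
                    ExitLocation(
                        value=loc.value,
                        cortex=loc.cortex,
                        exit_point=t.apply(loc.exit_point.reshape(1, 2)).reshape(2),
                    ),
                )
        new.axes = {
            k: None
            if ax is None
            else TunnelAxis(
                through=t.apply(ax.through.reshape(1, 2)).reshape(2),
                direction=t.matrix @ ax.direction,
            )
            for k, ax in sol.axes.items()
        }
        out[orientation] = new
    return out


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis; see module docstring for the stages."""
    log: list[str] = []
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    # -- stage 1: cohort ----------------------------------------------------
    truth = None
    if config.cohort is not None:
        params = config.cohort
        if params.seed != config.seed:
            params = CohortParams(**{**params.to_dict(), "seed": config.seed})
        sections, truth = generate_cohort(params)
        log.extend(f"{cs.subject_id} generate ok class={cs.shape_class}" for cs in sections)
        if out_dir:
            write_cohort(out_dir / "cohort", sections, truth)
    else:
        sections = load_cohort(config.input_dir, snap_tol=config.snap_tol_mm)
        log.extend(f"{cs.subject_id} ingest ok side={cs.side}" for cs in sections)
    n_subjects = len(sections)

    # -- stage 2: shape metrics ---------------------------------------------
    shape_rows = []
    for cs in sections:
        label = classify_shape(cs)
        rep = aspect_ratio(cs, normalization=config.normalization)
        shape_rows.append(
            {
                "subject_id": cs.subject_id,
                "side": cs.side,
                "shape_class": label,
                "shape_class_generator": cs.shape_class or "",
                "aspect_ratio": rep.aspect_ratio,
                "anterolateral_mm": rep.anterolateral_mm,
                "posterolateral_mm": rep.posterolateral_mm,
            }
        )
        log.append(f"{cs.subject_id} shape ok class={label} ratio={rep.aspect_ratio:.3f}")
    shape_table = pd.DataFrame(shape_rows)

    # -- stage 3: tunnel simulation -----------------------------------------
    solutions: dict[str, dict] = {}
    sol_rows = []
    n_failed = 0
    for cs in sections:
        try:
            sols = solve_subject(
                cs,
                diameter=config.tunnel_diameter_mm,
                eps=config.epsilon,
                normalization=config.normalization,
            )
        except FibsafeError as exc:  # defensive: solve_subject traps per-orientation
            log.append(f"{cs.subject_id} tunnels FAILED {exc}")
            n_failed += 1
            continue
        solutions[cs.subject_id] = sols
        drill_ok = (
            sols["anterior_angulated"].feasible
            or sols["posterior_angulated"].feasible
            or (sols["center_center"].feasible and sols["center_center"].central_feasible)
        )
        if not drill_ok:
            n_failed += 1
        for orientation, sol in sols.items():
            ax = sol.axes.get("central")
            sol_rows.append(
                {
                    "subject_id": cs.subject_id,
                    "orientation": orientation,
                    "feasible": sol.feasible,
                    "border_anterior_pct": None
                    if sol.anterior_border is None
                    else sol.anterior_border.value,
                    "border_posterior_pct": None
                    if sol.posterior_border is None
                    else sol.posterior_border.value,
                    "central_pct": None if sol.central is None else sol.central.value,
                    "central_feasible": sol.central_feasible,
                    "axis_angle_deg": None if ax is None else ax.angle_deg,
                    "note": sol.note,
                }
            )
            log.append(
                f"{cs.subject_id} tunnel {orientation} "
                f"feasible={sol.feasible} interval={sol.interval}"
            )
    if n_failed == n_subjects:
        raise PipelineError(
            f"tunnel simulation infeasible for all {n_subjects} subjects "
            f"(diameter {config.tunnel_diameter_mm} mm); see log"
        )
    solution_table = pd.DataFrame(sol_rows)

    # -- stage 4: registration ----------------------------------------------
    reg_results, reference, transformed = register_cohort(
        sections, reference_policy=config.reference_policy
    )
    registration_table = pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "rotation_deg": float(np.degrees(r.transform.rotation)),
                "scale": r.transform.scale,
                "tx_mm": r.transform.translation[0],
                "ty_mm": r.transform.translation[1],
                "mean_distance_error_mm": r.mean_distance_error,
            }
            for r in reg_results
        ]
    )
    log.extend(
        f"{r.subject_id} register ok err={r.mean_distance_error:.3f}mm"
        for r in reg_results
    )

    # -- stage 5: corridors and cohort statistics ---------------------------
    corridors = {}
    central = {}
    n_infeasible_total = 0
    for orientation in ("anterior_angulated", "posterior_angulated"):
        intervals = []
        centrals = []
        n_inf = 0
        for sid, sols in solutions.items():
            sol = sols.get(orientation)
            if sol is None or not sol.feasible or sol.interval is None:
                n_inf += 1
                continue
            intervals.append(sol.interval)
            if sol.central is not None:
                centrals.append(sol.central.value)
        n_infeasible_total += n_inf
        if intervals:
            corridors[orientation] = cohort_corridor_angulated(
                intervals, orientation, mode=config.corridor_mode, n_infeasible=n_inf
            )
        if len(centrals) >= 2:
            central[orientation] = summarize(centrals)
    cc_values = [
        sols["center_center"].central.value
        for sols in solutions.values()
        if sols.get("center_center") is not None
        and sols["center_center"].feasible
        and sols["center_center"].central is not None
    ]
    if cc_values:
        corridors["center_center"] = cohort_corridor_central(cc_values)
        if len(cc_values) >= 2:
            central["center_center"] = summarize(cc_values)

    corridor_report = CorridorReport(
        corridors=corridors,
        central=central,
        n_subjects=n_subjects,
        n_infeasible=n_infeasible_total,
    )

    # cohort descriptives
    class_counts = shape_table["shape_class"].value_counts().to_dict()
    class_pct = {k: 100.0 * v / n_subjects for k, v in sorted(class_counts.items())}
    report: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_subjects": n_subjects,
        "tunnel_diameter_mm": config.tunnel_diameter_mm,
        "shape_class_pct": class_pct,
        "aspect_ratio": summarize(shape_table["aspect_ratio"]).to_dict(),
        "registration_error_mm": summarize(
            registration_table["mean_distance_error_mm"]
        ).to_dict(),
        "corridors": corridor_report.to_dict(),
    }
    if truth is not None:
        heights = {
            "yc_mm": summarize(truth["height_yc_mm"]).to_dict(),
            "xc_mm": summarize(truth["height_xc_mm"]).to_dict(),
            "yi_mm": summarize(truth["height_yi_mm"]).to_dict(),
            "xi_mm": summarize(truth["height_xi_mm"]).to_dict(),
            "paired_yi_vs_yc": paired_t_and_pearson(
                truth["height_yi_mm"], truth["height_yc_mm"]
            ).to_dict(),
            "pearson_height_vs_yc": paired_t_and_pearson(
                truth["patient_height_cm"], truth["height_yc_mm"]
            ).to_dict(),
            "pearson_height_vs_yi": paired_t_and_pearson(
                truth["patient_height_cm"], truth["height_yi_mm"]
            ).to_dict(),
        }
        report["heights"] = heights

    # -- artifacts -----------------------------------------------------------
    if out_dir:
        shape_table.to_csv(out_dir / "shape_reports.csv", index=False)
        solution_table.to_csv(out_dir / "tunnel_solutions.csv", index=False)
        registration_table.to_csv(out_dir / "registration.csv", index=False)
        (out_dir / "report.json").write_text(
            json.dumps(_round_floats(report), indent=1, sort_keys=True, default=_json_default)
        )
        (out_dir / "run.log").write_text("\n".join(log) + "\n")
        if config.figures:
            from .figures import corridor_figure, overlay_figure

            fig_dir = out_dir / "figures"
            fig_dir.mkdir(exist_ok=True)
            transforms = {r.subject_id: r.transform for r in reg_results}
            sol_reg = {
                sid: _transform_solutions(sols, transforms[sid])
                for sid, sols in solutions.items()
            }
            overlay_figure(
                fig_dir / "overlay.svg",
                sections,
                transformed,
                solutions,
                sol_reg,
            )
            corridor_figure(fig_dir / "corridors.svg", sections[0], corridor_report)

    return PipelineResult(
        report=_round_floats(report),
        corridor_report=corridor_report,
        sections=sections,
        solutions=solutions,
        shape_table=shape_table,
        registration_table=registration_table,
        truth=truth,
        log=log,
    )
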