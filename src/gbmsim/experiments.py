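"""Desk-scale computational experiments and run configuration.

Drivers for the three studies around the model: the (M, k_n) sensitivity
sweep, the (S_n, delta_n) sensitivity sweep, and the paired
anisotropic-versus-isotropic comparison.  Each study runs the full solver
on a structured box domain with a synthetic tensor phantom (or externally
prepared DTI volumes) and reduces every run to the shape-metric summary,
asserting the expected monotone trends:

* larger friction M accumulates cells (phi_max ratio grows) without moving
  the tumor boundary much;
* larger chemotactic coefficient k_n elongates the tumor along the fiber
  axis and grows its total volume;
* larger oxygen supply S_n raises phi_max and shrinks the thresholded
  volume; larger uptake delta_n deepens the nutrient sink and grows it.

A run is described by a single TOML file with sections [domain], [tensors],
[model], [solver], [initial], [output]; configurations re-serialize
losslessly and carry a content digest for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
import tomllib
from dataclasses import dataclass, field as dataclass_field

import numpy as np

from . import metrics, tensor_fields
from .geometry import Mesh, box_mesh, read_mesh, refine_region, write_fields_vtk
from .model_core import ModelParameters
from .solver import Simulator, SolverConfig, gaussian_initial_condition
from .tensor_fields import TensorField

__all__ = [
    "RunConfig",
    "load_config",
    "run_single",
    "sensitivity_M_kn",
    "sensitivity_Sn_deltan",
    "compare_anisotropic_isotropic",
    "TrendViolation",
]

logger = logging.getLogger("gbmsim")


class TrendViolation(AssertionError):
    """A sweep's asserted monotone trend was violated beyond tolerance."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_DEFAULT_DOMAIN = {"kind": "box", "extents": [40.0, 40.0, 40.0],
                   "resolution": [16, 16, 16], "center": [0.0, 0.0, 0.0],
                   "refine_radius": 0.0, "refine_levels": 0}
_DEFAULT_TENSORS = {"kind": "isotropic"}
_DEFAULT_INITIAL = {"center": [0.0, 0.0, 0.0], "sigma_mm": 2.0}
_DEFAULT_OUTPUT = {"directory": "", "write_vtk": False}


@dataclass
class RunConfig:
    """Everything needed for one run; parseable from a single TOML file."""

    domain: dict = dataclass_field(default_factory=lambda: dict(_DEFAULT_DOMAIN))
    tensors: dict = dataclass_field(default_factory=lambda: dict(_DEFAULT_TENSORS))
    model: ModelParameters = dataclass_field(default_factory=ModelParameters)
    solver: SolverConfig = dataclass_field(default_factory=SolverConfig)
    initial: dict = dataclass_field(default_factory=lambda: dict(_DEFAULT_INITIAL))
    output: dict = dataclass_field(default_factory=lambda: dict(_DEFAULT_OUTPUT))

    @property
    def amplitude(self) -> float:
        """Initial peak fraction; defaults to 1.1 * phi_e."""
        return float(self.initial.get("amplitude", 1.1 * self.model.phi_e))

    def to_dict(self) -> dict:
        return {
            "domain": dict(self.domain),
            "tensors": dict(self.tensors),
            "model": self.model.to_dict(),
            "solver": self.solver.to_dict(),
            "initial": dict(self.initial),
            "output": dict(self.output),
        }

    def to_toml(self) -> str:
        return dumps_toml(self.to_dict())

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()

    def with_model(self, **changes) -> "RunConfig":
        return RunConfig(dict(self.domain), dict(self.tensors),
                         self.model.replace(**changes), self.solver,
                         dict(self.initial), dict(self.output))

    def with_solver(self, **changes) -> "RunConfig":
        return RunConfig(dict(self.domain), dict(self.tensors), self.model,
                         self.solver.replace(**changes),
                         dict(self.initial), dict(self.output))


def config_from_dict(data: dict) -> RunConfig:
    domain = {**_DEFAULT_DOMAIN, **data.get("domain", {})}
    tensors = {**_DEFAULT_TENSORS, **data.get("tensors", {})}
    initial = {**_DEFAULT_INITIAL, **data.get("initial", {})}
    output = {**_DEFAULT_OUTPUT, **data.get("output", {})}
    model = ModelParameters(**data.get("model", {}))
    solver = SolverConfig(**data.get("solver", {}))
    return RunConfig(domain, tensors, model, solver, initial, output)


def load_config(path) -> RunConfig:
    with open(str(path), "rb") as fh:
        return config_from_dict(tomllib.load(fh))


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        out = repr(float(v))
        return out if any(c in out for c in ".eE") else out + ".0"
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple, np.ndarray)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v).__name__} to TOML")


def dumps_toml(data: dict) -> str:
    """Serialize a two-level dict (sections of scalars/arrays) as TOML."""
    chunks = []
    for section, table in data.items():
        chunks.append(f"[{section}]")
        for key, value in table.items():
            chunks.append(f"{key} = {_toml_value(value)}")
        chunks.append("")
    return "\n".join(chunks)


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def build_mesh(config: RunConfig) -> Mesh:
    dom = config.domain
    if dom["kind"] == "box":
        extents = np.asarray(dom["extents"], dtype=float)
        center = np.asarray(dom.get("center", [0.0, 0.0, 0.0]), dtype=float)
        mesh = box_mesh(extents, dom["resolution"], origin=center - extents / 2.0)
        if dom.get("refine_levels", 0) and dom.get("refine_radius", 0.0) > 0.0:
            seed = np.asarray(config.initial["center"], dtype=float)
            mesh = refine_region(mesh, seed, float(dom["refine_radius"]),
                                 int(dom["refine_levels"]))
        return mesh
    if dom["kind"] == "file":
        return read_mesh(dom["path"])
    raise ValueError(f"unknown domain kind {dom['kind']!r}")


def build_tensor_fields(config: RunConfig, mesh: Mesh):
    """Construct (D, T) per mesh cell from the [tensors] config section."""
    spec = config.tensors
    kind = spec["kind"]
    D_n = float(spec.get("D_n", config.model.D_n))
    lo, hi = mesh.bounding_box()
    res = np.asarray(config.domain.get("resolution", [16, 16, 16]), dtype=int)
    spacing = (hi - lo) / res
    origin = lo + spacing / 2.0

    if kind == "isotropic":
        field = tensor_fields.synthetic_isotropic(tuple(res), D_n,
                                                  spacing=spacing, origin=origin)
    elif kind == "axis":
        field = tensor_fields.synthetic_axis_aligned(
            tuple(res), D_n, axis=spec.get("axis", "x"),
            spacing=spacing, origin=origin)
    elif kind == "fiber_bundle":
        centerline = np.asarray(spec["centerline"], dtype=float)
        field = tensor_fields.synthetic_fiber_bundle(
            tuple(res), centerline, float(spec["bundle_radius"]),
            float(spec.get("parallel_diffusivity", 2.0 * D_n)),
            float(spec.get("perpendicular_diffusivity", 0.5 * D_n)),
            spacing=spacing, origin=origin)
    elif kind == "nifti":
        field = tensor_fields.read_tensor_volumes(spec["paths"])
        field = tensor_fields.regularize(field, float(spec.get("eigen_floor", 0.0)))
    else:
        raise ValueError(f"unknown tensor kind {kind!r}")

    D_cells = tensor_fields.sample_to_mesh(field, mesh)
    T_cells = tensor_fields.preferential_directions(D_cells)
    return D_cells, T_cells


# ---------------------------------------------------------------------------
# Single run
# ---------------------------------------------------------------------------

def run_single(config: RunConfig, label: str = "run") -> dict:
    """Execute one configured simulation and reduce it to the shape summary.

    Writes (when an output directory is configured) the VTK snapshots, a
    JSON summary, a timestamped log and a manifest entry; always returns the
    in-memory report.
    """
    outdir = config.output.get("directory") or ""
    handler = None
    if outdir:
        os.makedirs(outdir, exist_ok=True)
        handler = logging.FileHandler(os.path.join(outdir, f"{label}.log"))
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
    t_start = time.time()
    try:
        logger.info("run %s: config digest %s", label, config.digest())
        mesh = build_mesh(config)
        D, T = build_tensor_fields(config, mesh)
        sim = Simulator(mesh, D, T, config.model, config.solver)
        phi0 = gaussian_initial_condition(
            mesh, config.initial["center"], float(config.initial["sigma_mm"]),
            config.amplitude, phi_e=config.model.phi_e)
        trajectory = sim.run(phi0)
        summary = metrics.summarize(mesh, trajectory[0], trajectory[-1],
                                    config.solver.eps_t, n_s=config.model.n_s)
        report = {
            "label": label,
            "config_digest": config.digest(),
            "summary": summary,
            "n_snapshots": len(trajectory),
            "t_final": trajectory[-1].t,
            "newton_iterations_total": int(sum(sim.newton_iterations)),
            "dt_halvings": sim.dt_halvings,
            "clip_events": sim.clip_events,
            "wall_seconds": time.time() - t_start,
        }
        if outdir:
            metrics.write_report_json(
                {k: v for k, v in report.items()},
                os.path.join(outdir, f"{label}_summary.json"))
            with open(os.path.join(outdir, f"{label}_config.toml"), "w") as fh:
                fh.write(config.to_toml())
            if config.output.get("write_vtk"):
                _write_snapshots(mesh, trajectory, config, D, T, outdir, label)
        logger.info("run %s finished at t=%g day in %.1f s", label,
                    trajectory[-1].t, report["wall_seconds"])
        report["trajectory"] = trajectory
        report["mesh"] = mesh
        return report
    finally:
        if handler is not None:
            logger.removeHandler(handler)
            handler.close()


def _write_snapshots(mesh, trajectory, config, D, T, outdir, label) -> None:
    index = []
    for i, state in enumerate(trajectory):
        fname = f"{label}_{i:04d}.vtk"
        point_data = {"phi": state.phi, "sigma": state.sigma, "n": state.n,
                      "n_normalized": state.n / config.model.n_s}
        cell_data = {f"D_{name}": D.comps[:, k]
                     for k, name in enumerate(tensor_fields.COMPONENT_ORDER)}
        cell_data.update({f"T_{name}": T.comps[:, k]
                          for k, name in enumerate(tensor_fields.COMPONENT_ORDER)})
        write_fields_vtk(mesh, os.path.join(outdir, fname),
                         point_data=point_data, cell_data=cell_data)
        index.append({"file": fname, "t": state.t})
    with open(os.path.join(outdir, f"{label}_trajectory.json"), "w") as fh:
        json.dump(index, fh, indent=2)


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------

def _check_trend(pairs, values, direction: str, what: str, tol: float):
    """Monotonicity of `values` along consecutive entries, with relative
    tolerance to absorb discretization noise."""
    violations = []
    for i in range(1, len(values)):
        prev, cur = values[i - 1], values[i]
        if direction == "non-decreasing" and cur < prev * (1.0 - tol):
            violations.append(f"{what} decreased from {prev:.6g} at "
                              f"{pairs[i-1]} to {cur:.6g} at {pairs[i]}")
        if direction == "non-increasing" and cur > prev * (1.0 + tol):
            violations.append(f"{what} increased from {prev:.6g} at "
                              f"{pairs[i-1]} to {cur:.6g} at {pairs[i]}")
    return violations


def _sweep(base: RunConfig, grid: list[dict], label: str) -> list[dict]:
    rows = []
    for point in grid:
        config = base.with_model(**point)
        tag = label + "_" + "_".join(f"{k}{v:g}" for k, v in point.items())
        try:
            report = run_single(config, label=tag)
        except Exception:
            logger.error("sweep run failed; failing configuration:\n%s",
                         config.to_toml())
            raise
        row = dict(point)
        row["digest"] = config.digest()
        row["summary"] = report["summary"]
        rows.append(row)
    return rows


def _write_sweep_outputs(base: RunConfig, rows, param_names, label) -> None:
    outdir = base.output.get("directory") or ""
    if not outdir:
        return
    os.makedirs(outdir, exist_ok=True)
    csv_rows = [metrics.report_csv_row(
        row["summary"], extra={k: row[k] for k in param_names})
        for row in rows]
    metrics.write_reports_csv(csv_rows, os.path.join(outdir, f"{label}.csv"))
    manifest = {
        "base_config": base.to_dict(),
        "base_digest": base.digest(),
        "runs": [{k: row[k] for k in (*param_names, "digest")} for row in rows],
    }
    with open(os.path.join(outdir, f"{label}_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def sensitivity_M_kn(base: RunConfig, M_values, kn_values,
                     trend_tol: float = 0.02, strict: bool = True) -> list[dict]:
    """Sweep friction M and chemotactic coefficient k_n on an axis-aligned
    phantom; asserts the monotone trends (phi_max ratio grows with M;
    elongation and volume grow with k_n)."""
    M_values = sorted(float(v) for v in M_values)
    kn_values = sorted(float(v) for v in kn_values)
    grid = [{"M": M, "k_n": kn} for M in M_values for kn in kn_values]
    rows = _sweep(base, grid, "mkn")
    _write_sweep_outputs(base, rows, ("M", "k_n"), "sweep_mkn")

    violations = []
    by = {(r["M"], r["k_n"]): r["summary"] for r in rows}
    for kn in kn_values:
        seq = [(M, kn) for M in M_values]
        violations += _check_trend(
            seq, [by[p]["phi_max_ratio"] for p in seq],
            "non-decreasing", f"phi_max ratio vs M (k_n={kn:g})", trend_tol)
    for M in M_values:
        seq = [(M, kn) for kn in kn_values]
        violations += _check_trend(
            seq, [by[p]["dx_over_dy"] for p in seq],
            "non-decreasing", f"dx/dy vs k_n (M={M:g})", trend_tol)
        violations += _check_trend(
            seq, [by[p]["volume_ratio"] for p in seq],
            "non-decreasing", f"volume ratio vs k_n (M={M:g})", trend_tol)
    if violations and strict:
        raise TrendViolation("; ".join(violations))
    for row in rows:
        row["trend_violations"] = violations
    return rows


def sensitivity_Sn_deltan(base: RunConfig, Sn_values, deltan_values,
                          trend_tol: float = 0.02, strict: bool = True) -> list[dict]:
    """Sweep oxygen supply S_n and uptake delta_n; asserts phi_max grows and
    volume shrinks with S_n, and volume grows with delta_n; records the
    minimum normalized nutrient per run."""
    Sn_values = sorted(float(v) for v in Sn_values)
    deltan_values = sorted(float(v) for v in deltan_values)
    grid = [{"S_n": Sn, "delta_n": dn} for Sn in Sn_values for dn in deltan_values]
    rows = _sweep(base, grid, "sndn")
    _write_sweep_outputs(base, rows, ("S_n", "delta_n"), "sweep_sndn")

    violations = []
    by = {(r["S_n"], r["delta_n"]): r["summary"] for r in rows}
    for dn in deltan_values:
        seq = [(Sn, dn) for Sn in Sn_values]
        violations += _check_trend(
            seq, [by[p]["final"]["phi_max"] for p in seq],
            "non-decreasing", f"phi_max vs S_n (delta_n={dn:g})", trend_tol)
        violations += _check_trend(
            seq, [by[p]["final"]["volume"] for p in seq],
            "non-increasing", f"tumor volume vs S_n (delta_n={dn:g})", trend_tol)
    for Sn in Sn_values:
        seq = [(Sn, dn) for dn in deltan_values]
        violations += _check_trend(
            seq, [by[p]["final"]["volume"] for p in seq],
            "non-decreasing", f"tumor volume vs delta_n (S_n={Sn:g})", trend_tol)
    if violations and strict:
        raise TrendViolation("; ".join(violations))
    for row in rows:
        row["trend_violations"] = violations
    return rows


# ---------------------------------------------------------------------------
# Anisotropic vs isotropic comparison
# ---------------------------------------------------------------------------

def _seed_anisotropy(T: TensorField, mesh: Mesh, seed_center) -> float:
    """Max deviation of the diagonal of T from 1 in the cell nearest the seed."""
    bary = mesh.barycenters()
    c = int(np.argmin(np.linalg.norm(bary - np.asarray(seed_center, dtype=float),
                                     axis=1)))
    return float(np.max(np.abs(T.comps[c, :3] - 1.0)))


def compare_anisotropic_isotropic(base: RunConfig, tensor_field: TensorField | None = None,
                                  strict: bool = True) -> dict:
    """Paired runs differing only in (D, T): configured anisotropy vs the
    isotropic control D = D_n I, T = I.

    When the tumor seed sits in a genuinely anisotropic region, asserts that
    the anisotropic run's major semi-axis exceeds the isotropic one — the
    isotropic model underestimates the invaded volume.
    """
    mesh = build_mesh(base)
    if tensor_field is not None:
        D_aniso = tensor_fields.sample_to_mesh(tensor_field, mesh)
        T_aniso = tensor_fields.preferential_directions(D_aniso)
    else:
        D_aniso, T_aniso = build_tensor_fields(base, mesh)

    seed = base.initial["center"]
    anisotropy = _seed_anisotropy(T_aniso, mesh, seed)

    phi0 = gaussian_initial_condition(mesh, seed, float(base.initial["sigma_mm"]),
                                      base.amplitude, phi_e=base.model.phi_e)

    def _one(D, T, tag):
        sim = Simulator(mesh, D, T, base.model, base.solver)
        traj = sim.run(phi0)
        return metrics.summarize(mesh, traj[0], traj[-1], base.solver.eps_t,
                                 n_s=base.model.n_s)

    sum_aniso = _one(D_aniso, T_aniso, "anisotropic")
    iso_cfg = dict(base.tensors)
    iso = RunConfig(dict(base.domain), {"kind": "isotropic",
                                        "D_n": iso_cfg.get("D_n", base.model.D_n)},
                    base.model, base.solver, dict(base.initial), dict(base.output))
    D_iso, T_iso = build_tensor_fields(iso, mesh)
    sum_iso = _one(D_iso, T_iso, "isotropic")

    major_aniso = max(sum_aniso["final"]["delta_x"], sum_aniso["final"]["delta_y"],
                      sum_aniso["final"]["delta_z"])
    major_iso = max(sum_iso["final"]["delta_x"], sum_iso["final"]["delta_y"],
                    sum_iso["final"]["delta_z"])
    report = {
        "anisotropic": sum_aniso,
        "isotropic": sum_iso,
        "seed_anisotropy": anisotropy,
        "major_axis_anisotropic": major_aniso,
        "major_axis_isotropic": major_iso,
        "volume_difference": sum_aniso["final"]["volume"] - sum_iso["final"]["volume"],
    }
    if anisotropy > 0.3 and strict and major_aniso <= major_iso:
        raise TrendViolation(
            f"anisotropic major semi-axis {major_aniso:.4g} mm does not exceed "
            f"the isotropic one {major_iso:.4g} mm despite seed anisotropy "
            f"{anisotropy:.3g}")
    outdir = base.output.get("directory") or ""
    if outdir:
        os.makedirs(outdir, exist_ok=True)
        metrics.write_report_json(report, os.path.join(outdir, "compare.json"))
    return report
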