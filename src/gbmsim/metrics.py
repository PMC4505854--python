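"""Tumor-shape characterization.

The tumor region at a time t is the thresholded set
Omega_t = { x : phi(x, t) >= eps_t }.  Its size and anisotropy are
summarized by the semi-axes Delta_x, Delta_y, Delta_z — half the extent of
the region along each coordinate axis through its centroid — together with
the region volume and the maximum volume fraction.  The ratios between the
major and minor semi-axes, between final and initial volume, and between
final and initial maximum fraction are the quantities tracked across the
sensitivity sweeps and the anisotropic-versus-isotropic comparison.

Semi-axes are measured along the coordinate axes (not principal-component
axes): phi is interpolated along each axis line through the centroid and
Delta is half the distance between the two outermost crossings of the
eps_t level (linear interpolation between samples).
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass

import numpy as np

from .geometry import Mesh
from .solver import SimulationState

__all__ = ["TumorShape", "tumor_region", "semi_axes", "tumor_shape", "summarize"]


@dataclass(frozen=True)
class TumorShape:
    """Thresholded tumor-region summary (lengths mm, volume mm³)."""

    delta_x: float
    delta_y: float
    delta_z: float
    volume: float
    phi_max: float
    centroid: tuple

    def __post_init__(self) -> None:
        if min(self.delta_x, self.delta_y, self.delta_z) < 0.0 or self.volume < 0.0:
            raise ValueError("semi-axes and volume must be non-negative")
        if not 0.0 <= self.phi_max <= 1.0 + 1e-3:
            raise ValueError(f"phi_max out of range: {self.phi_max!r}")

    @property
    def semi_axes(self) -> tuple:
        return (self.delta_x, self.delta_y, self.delta_z)


def tumor_region(mesh: Mesh, phi: np.ndarray, eps_t: float):
    """Cell mask and volume (mm³) of the region where phi >= eps_t.

    A cell belongs to the region when the vertex-interpolated phi at its
    barycenter (the mean of its four vertex values) reaches the threshold.
    An empty region is not an error: the mask is all-False and the volume 0.
    """
    if not 0.0 < eps_t < 1.0:
        raise ValueError(f"eps_t must lie in (0, 1), got {eps_t!r}")
    phi = np.asarray(phi, dtype=float)
    cell_phi = phi[mesh.cells].mean(axis=1)
    mask = cell_phi >= eps_t
    volume = float(mesh.cell_volumes()[mask].sum())
    return mask, volume


class _CellLocator:
    """Point-in-cell lookup via uniform binning of cell bounding boxes."""

    def __init__(self, mesh: Mesh, bins_per_axis: int = 24):
        self.mesh = mesh
        self.lo, self.hi = mesh.bounding_box()
        span = np.maximum(self.hi - self.lo, 1e-12)
        self.nb = np.minimum(bins_per_axis,
                             np.maximum(1, np.round(span / span.max() * bins_per_axis))
                             ).astype(int)
        self.h = span / self.nb
        verts = mesh.vertices[mesh.cells]
        cell_lo = ((verts.min(axis=1) - self.lo) / self.h).astype(int)
        cell_hi = ((verts.max(axis=1) - self.lo) / self.h).astype(int)
        cell_lo = np.clip(cell_lo, 0, self.nb - 1)
        cell_hi = np.clip(cell_hi, 0, self.nb - 1)
        self.bins: dict[tuple, list] = {}
        for c in range(mesh.n_cells):
            for i in range(cell_lo[c, 0], cell_hi[c, 0] + 1):
                for j in range(cell_lo[c, 1], cell_hi[c, 1] + 1):
                    for k in range(cell_lo[c, 2], cell_hi[c, 2] + 1):
                        self.bins.setdefault((i, j, k), []).append(c)
        # Per-cell affine maps to barycentric coordinates.
        x0 = verts[:, 0]
        E = np.transpose(verts[:, 1:] - verts[:, :1], (0, 2, 1))  # columns=edges
        self.x0 = x0
        self.Einv = np.linalg.inv(E)

    def interpolate(self, points: np.ndarray, nodal: np.ndarray,
                    fill: float = 0.0, tol: float = 1e-10) -> np.ndarray:
        points = np.atleast_2d(points)
        out = np.full(len(points), fill, dtype=float)
        idx = np.floor((points - self.lo) / self.h).astype(int)
        for p, pt in enumerate(points):
            key = tuple(np.clip(idx[p], 0, self.nb - 1))
            for c in self.bins.get(key, ()):
                lam = self.Einv[c] @ (pt - self.x0[c])
                lam0 = 1.0 - lam.sum()
                if lam.min() >= -tol and lam0 >= -tol:
                    w = np.array([lam0, lam[0], lam[1], lam[2]])
                    out[p] = float(w @ nodal[self.mesh.cells[c]])
                    break
        return out


def _region_centroid(mesh: Mesh, mask: np.ndarray) -> np.ndarray:
    vols = mesh.cell_volumes()[mask]
    bary = mesh.barycenters()[mask]
    return (vols[:, None] * bary).sum(axis=0) / vols.sum()


def semi_axes(mesh: Mesh, phi: np.ndarray, eps_t: float,
              samples_per_axis: int = 1601,
              locator: _CellLocator | None = None) -> np.ndarray:
    """Semi-axes (Delta_x, Delta_y, Delta_z) of the thresholded region, mm.

    Raises ValueError if the region is empty.
    """
    phi = np.asarray(phi, dtype=float)
    mask, _ = tumor_region(mesh, phi, eps_t)
    if not mask.any():
        raise ValueError("tumor region is empty; semi-axes undefined")
    centroid = _region_centroid(mesh, mask)
    loc = locator if locator is not None else _CellLocator(mesh)
    lo, hi = mesh.bounding_box()
    deltas = np.empty(3)
    for axis in range(3):
        ts = np.linspace(lo[axis] - centroid[axis], hi[axis] - centroid[axis],
                         samples_per_axis)
        pts = np.tile(centroid, (samples_per_axis, 1))
        pts[:, axis] += ts
        vals = loc.interpolate(pts, phi, fill=0.0)
        above = vals >= eps_t
        if not above.any():
            # Region exists but the axis line through the centroid misses the
            # level set (can happen for very coarse meshes): fall back to the
            # masked cells' extent along this axis.
            bary = mesh.barycenters()[mask]
            deltas[axis] = 0.5 * (bary[:, axis].max() - bary[:, axis].min())
            continue
        crossings = []
        sign = np.flatnonzero(np.diff(above.astype(int)) != 0)
        for i in sign:
            v0, v1 = vals[i], vals[i + 1]
            frac = (eps_t - v0) / (v1 - v0)
            crossings.append(ts[i] + frac * (ts[i + 1] - ts[i]))
        if crossings:
            t_min = min(min(crossings), ts[above][0])
            t_max = max(max(crossings), ts[above][-1])
        else:  # above everywhere along the line
            t_min, t_max = ts[0], ts[-1]
        deltas[axis] = 0.5 * (t_max - t_min)
    return deltas


def tumor_shape(mesh: Mesh, phi: np.ndarray, eps_t: float,
                locator: _CellLocator | None = None) -> TumorShape:
    """Full shape summary of the thresholded tumor region."""
    phi = np.asarray(phi, dtype=float)
    mask, volume = tumor_region(mesh, phi, eps_t)
    if not mask.any():
        raise ValueError("tumor region is empty")
    d = semi_axes(mesh, phi, eps_t, locator=locator)
    centroid = _region_centroid(mesh, mask)
    return TumorShape(delta_x=float(d[0]), delta_y=float(d[1]), delta_z=float(d[2]),
                      volume=volume, phi_max=float(min(np.max(phi), 1.0)),
                      centroid=tuple(centroid.tolist()))


def _phi_of(state) -> np.ndarray:
    return state.phi if isinstance(state, SimulationState) else np.asarray(state, dtype=float)


def summarize(mesh: Mesh, initial, final, eps_t: float, n_s: float | None = None) -> dict:
    """Compare the initial and final tumor: the ratios tracked in the sweeps.

    Returns phi_max_final/phi_max_initial, V_final/V_initial, Delta_x/Delta_y,
    Delta_x/Delta_z, the raw :class:`TumorShape` of both states and (when the
    states carry a nutrient field and ``n_s`` is given) the minimum of n/n_s
    at the final time.
    """
    phi_i, phi_f = _phi_of(initial), _phi_of(final)
    locator = _CellLocator(mesh)
    shape_i = tumor_shape(mesh, phi_i, eps_t, locator=locator)
    shape_f = tumor_shape(mesh, phi_f, eps_t, locator=locator)
    report = {
        "eps_t": eps_t,
        "phi_max_ratio": shape_f.phi_max / shape_i.phi_max,
        "volume_ratio": shape_f.volume / shape_i.volume,
        "dx_over_dy": shape_f.delta_x / shape_f.delta_y,
        "dx_over_dz": shape_f.delta_x / shape_f.delta_z,
        "initial": asdict(shape_i),
        "final": asdict(shape_f),
    }
    if n_s is not None and isinstance(final, SimulationState):
        report["n_min_over_ns"] = float(final.n.min() / n_s)
    return report


_CSV_FIELDS = ["eps_t", "phi_max_ratio", "volume_ratio", "dx_over_dy",
               "dx_over_dz", "final_volume", "final_phi_max",
               "final_dx", "final_dy", "final_dz", "n_min_over_ns"]


def report_csv_fields(extra: list[str] | None = None) -> list[str]:
    return (extra or []) + _CSV_FIELDS


def report_csv_row(report: dict, extra: dict | None = None) -> dict:
    """Flatten a summary report into one CSV row (deterministic formatting)."""
    row = {k: _fmt(v) for k, v in (extra or {}).items()}
    flat = {
        "eps_t": report["eps_t"],
        "phi_max_ratio": report["phi_max_ratio"],
        "volume_ratio": report["volume_ratio"],
        "dx_over_dy": report["dx_over_dy"],
        "dx_over_dz": report["dx_over_dz"],
        "final_volume": report["final"]["volume"],
        "final_phi_max": report["final"]["phi_max"],
        "final_dx": report["final"]["delta_x"],
        "final_dy": report["final"]["delta_y"],
        "final_dz": report["final"]["delta_z"],
        "n_min_over_ns": report.get("n_min_over_ns", ""),
    }
    row.update({k: _fmt(v) for k, v in flat.items()})
    return row


def _fmt(v):
    if isinstance(v, float):
        return f"{v:.12g}"
    return v


def write_report_json(report: dict, path) -> None:
    with open(str(path), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_reports_csv(rows: list[dict], path) -> None:
    if not rows:
        raise ValueError("no rows to write")
    fields = list(rows[0].keys())
    with open(str(path), "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        for row in rows:
            writer.writerow(row)
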