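"""Diffusion tensors and preferential-direction tensors.

DTI measures a symmetric 3x3 water-diffusion tensor D per voxel.  The model
uses D directly as the oxygen diffusion tensor and derives from it the
dimensionless tensor of preferential directions T = D / D_n, where
D_n = tr(D)/3 is the mean diffusivity.  T has trace 3 wherever defined and
encodes the direction — not the magnitude — of the local anisotropy, which
biases the chemotactic motion of tumor cells along white-matter fibers.

Patient DTI volumes are read from six NIfTI component maps; for testing and
desk-scale experiments this module also generates synthetic phantoms:
a uniform isotropic field, the axis-aligned degenerate field used by the
sensitivity analysis (a single non-zero diagonal component), and a curved
fiber-bundle phantom emulating a white-matter tract.

Component storage order is (xx, yy, zz, xy, xz, yz) everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TensorField",
    "COMPONENT_ORDER",
    "mean_diffusivity",
    "preferential_directions",
    "regularize",
    "rotate",
    "synthetic_isotropic",
    "synthetic_axis_aligned",
    "synthetic_fiber_bundle",
    "sample_to_mesh",
    "read_tensor_volumes",
    "write_tensor_volumes",
]

logger = logging.getLogger("gbmsim")

COMPONENT_ORDER = ("xx", "yy", "zz", "xy", "xz", "yz")

# (row, col) index of each stored component in the full 3x3 matrix.
_COMP_IJ = ((0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2))


@dataclass
class TensorField:
    """Symmetric 3x3 tensor field over a voxel grid or over mesh cells.

    ``comps`` has shape ``grid_shape + (6,)`` for a voxel field (with
    ``spacing``/``origin`` giving the axis-aligned world geometry,
    world = origin + index * spacing at the voxel center) or ``(n_cells, 6)``
    for a per-cell field sampled onto a mesh.  ``mask``, if present, marks
    locations where the tensor is defined (background voxels are masked
    out); ``fallback_count`` records how many locations received the
    isotropic fallback during construction or transfer.
    """

    comps: np.ndarray
    spacing: np.ndarray | None = None
    origin: np.ndarray | None = None
    mask: np.ndarray | None = None
    units: str = "mm^2/day"
    fallback_count: int = 0

    def __post_init__(self) -> None:
        self.comps = np.asarray(self.comps, dtype=float)
        if self.comps.shape[-1] != 6:
            raise ValueError("tensor components must have a trailing axis of "
                             f"length 6, got shape {self.comps.shape}")
        if self.spacing is not None:
            self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if self.origin is not None:
            self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.comps.shape[:-1]:
                raise ValueError("mask shape must match the field's location shape")

    @property
    def on_grid(self) -> bool:
        return self.spacing is not None

    @property
    def location_shape(self) -> tuple:
        return self.comps.shape[:-1]

    def as_matrices(self) -> np.ndarray:
        """Full symmetric matrices, shape ``location_shape + (3, 3)``."""
        m = np.empty(self.location_shape + (3, 3), dtype=float)
        for k, (i, j) in enumerate(_COMP_IJ):
            m[..., i, j] = self.comps[..., k]
            m[..., j, i] = self.comps[..., k]
        return m

    @classmethod
    def from_matrices(cls, matrices: np.ndarray, **kwargs) -> "TensorField":
        matrices = np.asarray(matrices, dtype=float)
        comps = np.empty(matrices.shape[:-2] + (6,), dtype=float)
        for k, (i, j) in enumerate(_COMP_IJ):
            comps[..., k] = 0.5 * (matrices[..., i, j] + matrices[..., j, i])
        return cls(comps=comps, **kwargs)

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of voxel centers, shape grid_shape + (3,)."""
        if not self.on_grid:
            raise ValueError("voxel_centers requires a grid-based field")
        axes = [self.origin[a] + self.spacing[a] * np.arange(self.location_shape[a])
                for a in range(3)]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def mean_diffusivity(field: TensorField) -> np.ndarray:
    """Mean diffusivity D_n = tr(D)/3, pointwise (mm²/day).

    A rotation invariant: measures the total amount of diffusion at a
    location, with no information about its directionality.
    """
    c = field.comps
    return (c[..., 0] + c[..., 1] + c[..., 2]) / 3.0


def preferential_directions(field: TensorField,
                            md_floor: float = 0.0) -> TensorField:
    """Tensor of preferential directions T_ij = D_ij / D_n.

    Wherever the mean diffusivity is positive, T has trace exactly 3 and
    equals the identity for isotropic D.  Locations with mean diffusivity
    <= ``md_floor`` (background voxels, fully degenerate tensors) receive
    the isotropic fallback T = I and are masked out — division by zero is
    never performed silently.
    """
    md = mean_diffusivity(field)
    defined = md > md_floor
    n_fallback = int(np.count_nonzero(~defined))
    if n_fallback:
        logger.debug("preferential_directions: %d location(s) with "
                     "non-positive mean diffusivity assigned T = I", n_fallback)
    safe_md = np.where(defined, md, 1.0)
    comps = field.comps / safe_md[..., None]
    identity = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
    comps = np.where(defined[..., None], comps, identity)
    mask = defined if field.mask is None else (defined & field.mask)
    return TensorField(comps=comps, spacing=None if field.spacing is None else field.spacing.copy(),
                       origin=None if field.origin is None else field.origin.copy(),
                       mask=mask, units="dimensionless",
                       fallback_count=n_fallback)


def regularize(field: TensorField, eigen_floor: float) -> TensorField:
    """Clamp tensor eigenvalues to ``>= eigen_floor`` location by location.

    Measured DTI can contain negative or zero eigenvalues (noise, background
    voxels); the clamped field is symmetric positive semi-definite.  Tensors
    already satisfying the floor are passed through bit-identical.
    """
    if eigen_floor < 0.0:
        raise ValueError(f"eigen_floor must be non-negative, got {eigen_floor!r}")
    comps = field.comps
    if not np.all(np.isfinite(comps)):
        bad = np.argwhere(~np.all(np.isfinite(comps), axis=-1))
        raise ValueError("non-finite tensor components at locations "
                         f"{bad[:10].tolist()}{'...' if len(bad) > 10 else ''}")
    mats = field.as_matrices()
    flat = mats.reshape(-1, 3, 3)
    eigvals, eigvecs = np.linalg.eigh(flat)
    needs_fix = eigvals[:, 0] < eigen_floor
    out = comps.reshape(-1, 6).copy()
    if np.any(needs_fix):
        clamped = np.maximum(eigvals[needs_fix], eigen_floor)
        fixed = np.einsum("nij,nj,nkj->nik",
                          eigvecs[needs_fix], clamped, eigvecs[needs_fix])
        for k, (i, j) in enumerate(_COMP_IJ):
            out[needs_fix, k] = fixed[:, i, j]
    return TensorField(comps=out.reshape(comps.shape),
                       spacing=None if field.spacing is None else field.spacing.copy(),
                       origin=None if field.origin is None else field.origin.copy(),
                       mask=None if field.mask is None else field.mask.copy(),
                       units=field.units)


def rotate(field: TensorField, R: np.ndarray) -> TensorField:
    """Apply the rigid rotation R to every tensor: D -> R D Rᵀ."""
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-10):
        raise ValueError("R must be a 3x3 rotation matrix")
    rotated = np.einsum("ab,...bc,dc->...ad", R, field.as_matrices(), R)
    return TensorField.from_matrices(
        rotated,
        spacing=None if field.spacing is None else field.spacing.copy(),
        origin=None if field.origin is None else field.origin.copy(),
        mask=None if field.mask is None else field.mask.copy(),
        units=field.units)


def _grid_comps(grid_shape, spacing, origin):
    grid_shape = tuple(int(s) for s in np.atleast_1d(grid_shape).repeat(
        3 if np.ndim(grid_shape) == 0 else 1))
    if len(grid_shape) != 3:
        raise ValueError("grid shape must have three axes")
    spacing = np.asarray(spacing, dtype=float).reshape(3) if spacing is not None \
        else np.ones(3)
    origin = np.asarray(origin, dtype=float).reshape(3) if origin is not None \
        else np.zeros(3)
    return grid_shape, spacing, origin


def synthetic_isotropic(grid_shape, D_n: float, spacing=None, origin=None) -> TensorField:
    """Uniform isotropic phantom D = D_n · I (the isotropic control field)."""
    if D_n <= 0.0:
        raise ValueError(f"D_n must be strictly positive, got {D_n!r}")
    grid_shape, spacing, origin = _grid_comps(grid_shape, spacing, origin)
    comps = np.zeros(grid_shape + (6,), dtype=float)
    comps[..., :3] = D_n
    return TensorField(comps=comps, spacing=spacing, origin=origin)


def synthetic_axis_aligned(grid_shape, D_n: float, axis="x",
                           spacing=None, origin=None) -> TensorField:
    """Axis-aligned degenerate phantom with a single diagonal component.

    The sensitivity-analysis construction: the chosen axis carries the full
    diffusivity D_n while every other component is zero, so the
    preferential-direction tensor is diag(3, 0, 0) (for axis "x") and the
    mean diffusivity is D_n / 3.
    """
    axes = {"x": 0, "y": 1, "z": 2, 0: 0, 1: 1, 2: 2}
    if axis not in axes:
        raise ValueError(f"axis must be one of x, y, z; got {axis!r}")
    if D_n <= 0.0:
        raise ValueError(f"D_n must be strictly positive, got {D_n!r}")
    grid_shape, spacing, origin = _grid_comps(grid_shape, spacing, origin)
    comps = np.zeros(grid_shape + (6,), dtype=float)
    comps[..., axes[axis]] = D_n
    return TensorField(comps=comps, spacing=spacing, origin=origin)


def synthetic_fiber_bundle(grid_shape, centerline, bundle_radius: float,
                           parallel_diffusivity: float,
                           perpendicular_diffusivity: float,
                           spacing=None, origin=None) -> TensorField:
    """Curved fiber-bundle phantom emulating a white-matter tract.

    Within ``bundle_radius`` of the polyline ``centerline`` the tensor has
    its principal eigenvector tangent to the centerline with eigenvalues
    (parallel, perpendicular, perpendicular); outside, the field is
    isotropic at the mean of the three eigenvalues, so the mean diffusivity
    is uniform and only the directionality varies.
    """
    if not parallel_diffusivity >= perpendicular_diffusivity > 0.0:
        raise ValueError("require parallel_diffusivity >= perpendicular_diffusivity > 0")
    if bundle_radius <= 0.0:
        raise ValueError(f"bundle_radius must be positive, got {bundle_radius!r}")
    pts = np.asarray(centerline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
        raise ValueError("centerline must be an (N, 3) polyline with N >= 2")
    seg = pts[1:] - pts[:-1]
    seg_len = np.linalg.norm(seg, axis=1)
    if np.any(seg_len == 0.0):
        raise ValueError("degenerate centerline: repeated consecutive points")
    tangents = seg / seg_len[:, None]

    grid_shape, spacing, origin = _grid_comps(grid_shape, spacing, origin)
    centers = TensorField(np.zeros(grid_shape + (6,)), spacing=spacing,
                          origin=origin).voxel_centers().reshape(-1, 3)

    # Closest point on the polyline for every voxel center (vectorized over
    # segments; n_voxels x n_segments distance table).
    diff = centers[:, None, :] - pts[None, :-1, :]
    t = np.clip(np.einsum("vsk,sk->vs", diff, seg) / (seg_len**2)[None, :], 0.0, 1.0)
    proj = pts[None, :-1, :] + t[..., None] * seg[None, :, :]
    dist = np.linalg.norm(centers[:, None, :] - proj, axis=2)
    nearest_seg = np.argmin(dist, axis=1)
    min_dist = dist[np.arange(len(centers)), nearest_seg]

    d_par, d_perp = parallel_diffusivity, perpendicular_diffusivity
    iso_value = (d_par + 2.0 * d_perp) / 3.0
    mats = np.empty((len(centers), 3, 3), dtype=float)
    mats[:] = iso_value * np.eye(3)
    inside = min_dist <= bundle_radius
    if np.any(inside):
        tang = tangents[nearest_seg[inside]]
        mats[inside] = d_perp * np.eye(3) + (d_par - d_perp) * \
            np.einsum("ni,nj->nij", tang, tang)
    return TensorField.from_matrices(mats.reshape(grid_shape + (3, 3)),
                                     spacing=spacing, origin=origin)


def sample_to_mesh(field: TensorField, mesh, eigen_floor: float = 1.0e-6) -> TensorField:
    """Transfer a voxel tensor field onto mesh cells, nearest-voxel style.

    Each cell receives the tensor of the voxel containing its barycenter
    (no interpolation), mirroring the voxel-to-tetrahedron assignment used
    when mapping registered DTI onto a computational mesh.  Cells whose
    barycenter falls outside the voxel grid receive the isotropic fallback
    ``eigen_floor * I`` and are counted in ``fallback_count``.
    """
    if not field.on_grid:
        raise ValueError("sample_to_mesh requires a grid-based source field")
    bary = mesh.barycenters()
    if len(bary) == 0:
        raise ValueError("cannot sample onto an empty mesh")
    # Voxel i covers world interval [origin + (i - 1/2) h, origin + (i + 1/2) h).
    idx = np.round((bary - field.origin[None, :]) / field.spacing[None, :]).astype(int)
    shape = np.array(field.location_shape)
    inside = np.all((idx >= 0) & (idx < shape[None, :]), axis=1)
    comps = np.empty((len(bary), 6), dtype=float)
    fallback = np.array([eigen_floor] * 3 + [0.0] * 3)
    comps[~inside] = fallback
    ii = idx[inside]
    comps[inside] = field.comps[ii[:, 0], ii[:, 1], ii[:, 2], :]
    n_out = int(np.count_nonzero(~inside))
    if n_out:
        logger.warning("sample_to_mesh: %d cell barycenter(s) outside the "
                       "voxel grid received the isotropic fallback", n_out)
    mask = None
    if field.mask is not None:
        mask = np.zeros(len(bary), dtype=bool)
        mask[inside] = field.mask[ii[:, 0], ii[:, 1], ii[:, 2]]
    return TensorField(comps=comps, mask=mask, units=field.units,
                       fallback_count=n_out)


def _check_axis_aligned(affine: np.ndarray, path: str) -> tuple[np.ndarray, np.ndarray]:
    lin = affine[:3, :3]
    if not np.allclose(lin, np.diag(np.diag(lin)), atol=1e-8):
        raise ValueError(f"{path}: only axis-aligned (diagonal) affines are "
                         "supported; rotated or sheared volumes must be "
                         "resampled upstream")
    spacing = np.diag(lin).copy()
    if np.any(spacing <= 0.0):
        raise ValueError(f"{path}: affine has non-positive voxel spacing")
    return spacing, affine[:3, 3].copy()


def read_tensor_volumes(paths, units: str = "mm^2/day") -> TensorField:
    """Assemble a TensorField from six NIfTI component volumes.

    ``paths`` maps the component names (xx, yy, zz, xy, xz, yz) to files, or
    is a sequence of six paths in that fixed order.  All volumes must share
    shape and (axis-aligned) affine; grid spacing and origin are taken from
    the headers.
    """
    import nibabel as nib

    if isinstance(paths, dict):
        try:
            ordered = [paths[name] for name in COMPONENT_ORDER]
        except KeyError as exc:
            raise ValueError(f"missing tensor component {exc} in path mapping") from exc
    else:
        ordered = list(paths)
    if len(ordered) != 6:
        raise ValueError(f"expected six component volumes, got {len(ordered)}")

    comps = None
    ref_shape = ref_spacing = ref_origin = None
    for k, path in enumerate(ordered):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim != 3:
            raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
        spacing, origin = _check_axis_aligned(img.affine, str(path))
        if comps is None:
            ref_shape, ref_spacing, ref_origin = data.shape, spacing, origin
            comps = np.empty(ref_shape + (6,), dtype=float)
        else:
            if data.shape != ref_shape:
                raise ValueError(f"{path}: shape {data.shape} does not match "
                                 f"{ref_shape} of {ordered[0]}")
            if not (np.allclose(spacing, ref_spacing) and np.allclose(origin, ref_origin)):
                raise ValueError(f"{path}: affine does not match {ordered[0]}")
        comps[..., k] = data
    return TensorField(comps=comps, spacing=ref_spacing, origin=ref_origin,
                       units=units)


def write_tensor_volumes(field: TensorField, directory, prefix: str = "D") -> dict:
    """Write the six component volumes as NIfTI files; returns the path map."""
    import os

    import nibabel as nib

    if not field.on_grid:
        raise ValueError("write_tensor_volumes requires a grid-based field")
    os.makedirs(directory, exist_ok=True)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(field.spacing)
    affine[:3, 3] = field.origin
    out = {}
    for k, name in enumerate(COMPONENT_ORDER):
        path = os.path.join(str(directory), f"{prefix}_{name}.nii.gz")
        nib.save(nib.Nifti1Image(field.comps[..., k], affine), path)
        out[name] = path
    return out


def write_mask(mask: np.ndarray, spacing, origin, path) -> None:
    """Write a 0/1 voxel mask as NIfTI."""
    import nibabel as nib

    affine = np.eye(4)
    affine[:3, :3] = np.diag(np.asarray(spacing, dtype=float))
    affine[:3, 3] = np.asarray(origin, dtype=float)
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))
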