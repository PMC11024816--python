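"""Host-lattice free-form deformation and surface-driven template fitting.

A regular trilinear control-point lattice wraps the template mesh. Every mesh
node is assigned fixed material coordinates (cell index + local (u, v, w)) in
the undeformed lattice once; displacing control points then carries surface
and internal nodes through the identical deformation, which is what preserves
the relative node arrangement during morphing.

Fitting alternates nearest-point correspondence between the deformed surface
nodes and the target cloud with an exact regularized linear least-squares
solve for the control points (an ICP-style outer loop), so the combined
objective is non-increasing across outer iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial import cKDTree

from .errors import FitError, OutOfDomainError, ValidationError
from .mesh import HexMesh

__all__ = [
    "HostLattice",
    "EmbeddedCoords",
    "FitParams",
    "FitResult",
    "build_host_lattice",
    "embed_points",
    "evaluate",
    "fit_to_point_cloud",
    "rms_error",
    "nearest_cloud_distances",
]

logger = logging.getLogger(__name__)


@dataclass
class HostLattice:
    """Axis-aligned regular lattice of trilinear control points.

    ``control_points`` has shape ``(dims[0]+1, dims[1]+1, dims[2]+1, 3)`` and
    is initialized to the undeformed grid ``origin + index * spacing``.
    """

    origin: np.ndarray
    spacing: np.ndarray
    dims: np.ndarray
    control_points: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.dims = np.asarray(self.dims, dtype=np.int64)
        if self.origin.shape != (3,) or self.spacing.shape != (3,) or self.dims.shape != (3,):
            raise ValidationError("origin, spacing and dims must be length-3")
        if np.any(self.spacing <= 0):
            raise ValidationError("spacing must be strictly positive")
        if np.any(self.dims < 1):
            raise ValidationError("dims must be >= 1 per axis")
        if self.control_points is None:
            self.control_points = self.undeformed_grid()
        self.control_points = np.asarray(self.control_points, dtype=float)
        expected = (*(self.dims + 1), 3)
        if self.control_points.shape != expected:
            raise ValidationError(
                f"control_points shape {self.control_points.shape} != {expected}"
            )

    def undeformed_grid(self) -> np.ndarray:
        axes = [
            self.origin[a] + self.spacing[a] * np.arange(self.dims[a] + 1)
            for a in range(3)
        ]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
        return grid

    @property
    def n_control_points(self) -> int:
        return int(np.prod(self.dims + 1))

    @property
    def box_min(self) -> np.ndarray:
        return self.origin.copy()

    @property
    def box_max(self) -> np.ndarray:
        return self.origin + self.spacing * self.dims

    def copy(self) -> "HostLattice":
        return HostLattice(
            self.origin.copy(), self.spacing.copy(), self.dims.copy(),
            self.control_points.copy(),
        )


@dataclass
class EmbeddedCoords:
    """Material coordinates of points in the undeformed lattice."""

    cells: np.ndarray  # (N, 3) integer cell index per axis
    local: np.ndarray  # (N, 3) local (u, v, w) in [0, 1]

    def __len__(self) -> int:
        return len(self.cells)


@dataclass
class FitParams:
    """Parameters of the surface fit (documented defaults; deterministic)."""

    smoothing_weight: float = 0.01
    max_outer_iters: int = 30
    rmse_tol: float = 1e-3
    correspondence_mode: Literal["nearest", "symmetric"] = "nearest"

    def __post_init__(self) -> None:
        if self.smoothing_weight < 0:
            raise ValidationError("smoothing_weight must be >= 0")
        if self.max_outer_iters < 1:
            raise ValidationError("max_outer_iters must be >= 1")
        if self.rmse_tol <= 0:
            raise ValidationError("rmse_tol must be > 0")
        if self.correspondence_mode not in ("nearest", "symmetric"):
            raise ValidationError(
                f"unknown correspondence_mode {self.correspondence_mode!r}"
            )


@dataclass
class FitResult:
    lattice: HostLattice
    mesh: HexMesh
    rmse: float
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = False
    n_iters: int = 0

    def to_dict(self) -> dict:
        return {
            "rmse_mm": float(self.rmse),
            "iterations": int(self.n_iters),
            "converged": bool(self.converged),
            "objective_trace": [float(v) for v in self.objective_trace],
        }


def build_host_lattice(points: np.ndarray, dims=(4, 4, 4), margin: float = None,
                       ) -> HostLattice:
    """Regular lattice whose box is the point bounding box plus ``margin``.

    ``margin`` defaults to 10% of the largest bounding-box extent (at least
    1 mm), which keeps degenerate (flat or single-point) inputs usable.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.size == 0:
        raise ValidationError("cannot build a host lattice around an empty point set")
    dims = np.asarray(dims, dtype=np.int64)
    if np.any(dims < 1):
        raise ValidationError("lattice dims must be >= 1 per axis")
    lo = points.min(axis=0)
    hi = points.max(axis=0)
    if margin is None:
        margin = max(0.1 * float((hi - lo).max()), 1.0)
    if margin <= 0:
        raise ValidationError("margin must be > 0")
    lo = lo - margin
    hi = hi + margin
    spacing = (hi - lo) / dims
    return HostLattice(lo, spacing, dims)


def embed_points(lattice: HostLattice, points: np.ndarray) -> EmbeddedCoords:
    """Closed-form material coordinates of ``points`` in the undeformed grid."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    rel = (points - lattice.origin) / lattice.spacing
    tol = 1e-9
    outside = np.any((rel < -tol) | (rel > lattice.dims + tol), axis=1)
    if np.any(outside):
        bad = int(np.argmax(outside))
        raise OutOfDomainError(
            f"point {bad} at {points[bad].tolist()} lies outside the lattice box "
            f"[{lattice.box_min.tolist()}, {lattice.box_max.tolist()}]"
        )
    cells = np.clip(np.floor(rel).astype(np.int64), 0, lattice.dims - 1)
    local = rel - cells
    return EmbeddedCoords(cells, np.clip(local, 0.0, 1.0))


def _corner_indices_and_weights(lattice: HostLattice, coords: EmbeddedCoords):
    """Flat control-point indices (N, 8) and trilinear weights (N, 8)."""
    cells, local = coords.cells, coords.local
    if np.any(cells < 0) or np.any(cells >= lattice.dims):
        raise ValidationError("embedded cell index out of range for this lattice")
    shape = tuple(lattice.dims + 1)
    u, v, w = local[:, 0], local[:, 1], local[:, 2]
    wu = np.stack([1 - u, u], axis=1)
    wv = np.stack([1 - v, v], axis=1)
    ww = np.stack([1 - w, w], axis=1)
    idx = np.empty((len(cells), 8), dtype=np.int64)
    wts = np.empty((len(cells), 8))
    corner = 0
    for di in range(2):
        for dj in range(2):
            for dk in range(2):
                idx[:, corner] = np.ravel_multi_index(
                    (cells[:, 0] + di, cells[:, 1] + dj, cells[:, 2] + dk), shape
                )
                wts[:, corner] = wu[:, di] * wv[:, dj] * ww[:, dk]
                corner += 1
    return idx, wts


def evaluate(lattice: HostLattice, coords: EmbeddedCoords) -> np.ndarray:
    """Deformed positions: trilinear blend of each cell's 8 control points."""
    idx, wts = _corner_indices_and_weights(lattice, coords)
    cp = lattice.control_points.reshape(-1, 3)
    return np.einsum("nc,ncx->nx", wts, cp[idx])


def _weight_matrix(lattice: HostLattice, coords: EmbeddedCoords) -> sparse.csr_matrix:
    idx, wts = _corner_indices_and_weights(lattice, coords)
    n = len(coords)
    rows = np.repeat(np.arange(n), 8)
    return sparse.csr_matrix(
        (wts.ravel(), (rows, idx.ravel())), shape=(n, lattice.n_control_points)
    )


def _second_difference_operator(dims: np.ndarray) -> sparse.csr_matrix:
    """Stacked per-axis second differences over the control-point grid.

    The null space contains all per-axis affine displacement fields, so
    regularization never biases the fit away from exact affine reproduction.
    """
    shape = tuple(np.asarray(dims) + 1)
    n = int(np.prod(shape))
    grid = np.arange(n).reshape(shape)
    blocks = []
    for axis in range(3):
        if shape[axis] < 3:
            continue
        centre = np.moveaxis(grid, axis, 0)
        prev_ = centre[:-2].ravel()
        mid = centre[1:-1].ravel()
        next_ = centre[2:].ravel()
        m = len(mid)
        rows = np.repeat(np.arange(m), 3)
        cols = np.stack([prev_, mid, next_], axis=1).ravel()
        vals = np.tile([1.0, -2.0, 1.0], m)
        blocks.append(sparse.csr_matrix((vals, (rows, cols)), shape=(m, n)))
    if not blocks:
        return sparse.csr_matrix((0, n))
    return sparse.vstack(blocks).tocsr()


def nearest_cloud_distances(points: np.ndarray, cloud: np.ndarray) -> np.ndarray:
    """Distance from each point to its nearest cloud point (exact k-d query)."""
    cloud = np.atleast_2d(np.asarray(cloud, dtype=float))
    if cloud.size == 0:
        raise ValidationError("point cloud is empty")
    dists, _ = cKDTree(cloud).query(np.atleast_2d(points))
    return dists


def rms_error(mesh: HexMesh, cloud: np.ndarray) -> float:
    """RMS of surface-node-to-nearest-cloud-point distances, in mm."""
    dists = nearest_cloud_distances(mesh.nodes[mesh.surface_nodes], cloud)
    return float(np.sqrt(np.mean(dists**2)))


def fit_to_point_cloud(
    template: HexMesh,
    cloud: np.ndarray,
    lattice_dims=(4, 4, 4),
    params: FitParams | None = None,
    margin: float | None = None,
) -> FitResult:
    """Morph ``template`` so its surface matches ``cloud``.

    Outer loop: (a) correspond each deformed surface node to its nearest cloud
    point, (b) solve the regularized least squares for all control points,
    (c) move every mesh node (surface and internal) through the updated
    lattice. Stops when the RMSE change drops below ``params.rmse_tol`` or
    after ``params.max_outer_iters`` iterations. Topology is never modified.
    """
    params = params or FitParams()
    cloud = np.atleast_2d(np.asarray(cloud, dtype=float))
    if len(cloud) < 10:
        raise ValidationError(f"point cloud has {len(cloud)} points, need >= 10")

    lattice = build_host_lattice(template.nodes, lattice_dims, margin)
    coords_all = embed_points(lattice, template.nodes)
    surf = template.surface_nodes
    coords_surf = EmbeddedCoords(coords_all.cells[surf], coords_all.local[surf])

    W = _weight_matrix(lattice, coords_surf)
    D2 = _second_difference_operator(lattice.dims)
    n_data = W.shape[0]
    # Scale the penalty with the data term so the default weight behaves the
    # same across cloud densities and lattice resolutions.
    lam = params.smoothing_weight * n_data / max(D2.shape[0], 1)

    P0 = lattice.undeformed_grid().reshape(-1, 3)
    L = (D2.T @ D2).toarray() if lam > 0 else None

    def _factorize(Wmat):
        A = (Wmat.T @ Wmat).toarray()
        if lam > 0:
            A = A + lam * L
            # tiny relative ridge on the displacement for numerical safety
            A = A + 1e-12 * (np.trace(A) / A.shape[0]) * np.eye(A.shape[0])
        try:
            return cho_factor(A)
        except np.linalg.LinAlgError as exc:
            raise FitError(
                "normal system is singular (control points without data support); "
                "set smoothing_weight > 0"
            ) from exc

    factor = _factorize(W)
    tree = cKDTree(cloud)
    delta = np.zeros_like(P0)  # control-point displacements
    trace: list[float] = []
    rmse_prev = None
    converged = False
    n_iters = 0

    for _ in range(params.max_outer_iters):
        n_iters += 1
        P = P0 + delta
        surf_pos = np.asarray(W @ P)
        dists, nearest = tree.query(surf_pos)
        targets = cloud[nearest]
        if params.correspondence_mode == "symmetric":
            # also pull the surface toward each cloud point's nearest node
            d_sym, nearest_node = cKDTree(surf_pos).query(cloud)
            W_it = sparse.vstack([W, W[nearest_node]]).tocsr()
            targets_it = np.vstack([targets, cloud])
            factor_it = _factorize(W_it)
            data_term = float(np.sum(dists**2) + np.sum(d_sym**2))
        else:
            W_it, targets_it, factor_it = W, targets, factor
            data_term = float(np.sum(dists**2))

        obj = data_term
        if lam > 0:
            obj += lam * float(np.sum((D2 @ delta) ** 2))
        trace.append(obj)

        rhs = W_it.T @ (targets_it - np.asarray(W_it @ P0))
        delta = cho_solve(factor_it, rhs)

        rmse = float(
            np.sqrt(np.mean(tree.query(np.asarray(W @ (P0 + delta)))[0] ** 2))
        )
        if rmse_prev is not None and abs(rmse_prev - rmse) < params.rmse_tol:
            converged = True
            rmse_prev = rmse
            break
        rmse_prev = rmse

    fitted = lattice.copy()
    fitted.control_points = (P0 + delta).reshape(fitted.control_points.shape)
    morphed = template.with_nodes(evaluate(fitted, coords_all))
    final_rmse = rms_error(morphed, cloud)
    logger.info(
        "FFD fit: rmse=%.4f mm after %d iterations (converged=%s)",
        final_rmse, n_iters, converged,
    )
    return FitResult(fitted, morphed, final_rmse, trace, converged, n_iters)
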