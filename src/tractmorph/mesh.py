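"""Hexahedral tract meshes and the parametric template generator.

The template is a solid, tube-like structured hexahedral mesh: ``n_w + 1``
elliptical cross-sections swept along a smooth centerline, each cross-section
an ``(n_u + 1) x (n_v + 1)`` grid of nodes. The default resolution is
16 x 16 x 80, i.e. 20 480 elements, which is the fixed feature dimension used
by the cohort statistics.

All coordinates are world millimetres. Hexahedron corners follow the VTK
``VTK_HEXAHEDRON`` convention: the bottom quad (counter-clockwise seen from
above) then the top quad in the same order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import ValidationError

__all__ = [
    "HexMesh",
    "TemplateConfig",
    "build_template_tract_mesh",
    "extract_surface_nodes",
    "element_centroids",
    "element_grid_index",
]

# Corner offsets (di, dj, dk) of a structured-grid hexahedron, VTK order.
_HEX_CORNERS = (
    (0, 0, 0),
    (1, 0, 0),
    (1, 1, 0),
    (0, 1, 0),
    (0, 0, 1),
    (1, 0, 1),
    (1, 1, 1),
    (0, 1, 1),
)

# Local corner ids of the six quad faces of a hexahedron.
_HEX_FACES = (
    (0, 1, 2, 3),
    (4, 5, 6, 7),
    (0, 1, 5, 4),
    (2, 3, 7, 6),
    (0, 3, 7, 4),
    (1, 2, 6, 5),
)


@dataclass
class HexMesh:
    """A fixed-topology hexahedral mesh with optional per-element fields.

    Parameters
    ----------
    nodes : (N, 3) float array
        World coordinates in millimetres.
    elements : (E, 8) int array
        Node indices of each hexahedron, VTK corner order.
    fields : dict of str -> (E,) float array
        Named per-element scalar fields.
    """

    nodes: np.ndarray
    elements: np.ndarray
    fields: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise ValidationError("nodes must be an (N, 3) array")
        if self.elements.ndim != 2 or self.elements.shape[1] != 8:
            raise ValidationError("elements must be an (E, 8) array")
        if self.elements.size:
            if self.elements.min() < 0 or self.elements.max() >= len(self.nodes):
                raise ValidationError("element refers to an out-of-range node index")
            uniq = np.sort(self.elements, axis=1)
            if np.any(uniq[:, 1:] == uniq[:, :-1]):
                raise ValidationError("each element must reference 8 distinct nodes")
        clean = {}
        for name, values in self.fields.items():
            values = np.asarray(values, dtype=float)
            if values.shape != (self.n_elements,):
                raise ValidationError(
                    f"field {name!r} has length {values.shape}, "
                    f"expected ({self.n_elements},)"
                )
            clean[name] = values
        self.fields = clean
        self._surface_nodes: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def surface_nodes(self) -> np.ndarray:
        """Sorted indices of nodes on boundary faces (cached)."""
        if self._surface_nodes is None:
            self._surface_nodes = extract_surface_nodes(self)
        return self._surface_nodes

    def boundary_faces(self) -> np.ndarray:
        """(F, 4) node-index quads of faces belonging to exactly one element."""
        faces = self.elements[:, np.array(_HEX_FACES)].reshape(-1, 4)
        keys = np.sort(faces, axis=1)
        _, inverse, counts = np.unique(
            keys, axis=0, return_inverse=True, return_counts=True
        )
        return faces[counts[inverse] == 1]

    def with_nodes(self, nodes: np.ndarray) -> "HexMesh":
        """Same topology and fields, new node coordinates."""
        return HexMesh(np.asarray(nodes, float).copy(), self.elements.copy(),
                       {k: v.copy() for k, v in self.fields.items()})

    def copy(self) -> "HexMesh":
        return self.with_nodes(self.nodes)


def extract_surface_nodes(mesh: HexMesh) -> np.ndarray:
    """Indices of nodes lying on faces that occur in exactly one element."""
    boundary = mesh.boundary_faces()
    return np.unique(boundary)


def element_centroids(mesh: HexMesh) -> np.ndarray:
    """(E, 3) arithmetic mean of the 8 corner coordinates per element."""
    return mesh.nodes[mesh.elements].mean(axis=1)


def _default_centerline() -> np.ndarray:
    # Gentle S-curve, roughly the course of a corticospinal tract (~115 mm).
    return np.array(
        [
            [0.0, 0.0, 0.0],
            [4.0, 1.0, 28.0],
            [1.0, 6.0, 58.0],
            [-4.0, 3.0, 88.0],
            [0.0, 0.0, 115.0],
        ]
    )


def _default_radii_profile() -> np.ndarray:
    # (station, 2) semi-axes in mm; waist in the middle, flaring at the ends.
    return np.array(
        [
            [9.0, 7.0],
            [7.0, 5.5],
            [6.0, 5.0],
            [7.0, 6.0],
            [9.5, 8.0],
        ]
    )


@dataclass
class TemplateConfig:
    """Resolution and geometry of the parametric template tract mesh."""

    n_u: int = 16
    n_v: int = 16
    n_w: int = 80
    centerline: np.ndarray = field(default_factory=_default_centerline)
    radii_profile: np.ndarray = field(default_factory=_default_radii_profile)

    def __post_init__(self) -> None:
        for name in ("n_u", "n_v", "n_w"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value < 1:
                raise ValidationError(f"{name} must be an integer >= 1, got {value!r}")
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[1] != 3:
            raise ValidationError("centerline must be an (M, 3) array")
        if len(self.centerline) < 2:
            raise ValidationError("centerline needs at least 2 vertices")
        self.radii_profile = np.asarray(self.radii_profile, dtype=float)
        if self.radii_profile.ndim != 2 or self.radii_profile.shape[1] != 2:
            raise ValidationError("radii_profile must be an (S, 2) array")
        if np.any(self.radii_profile <= 0):
            raise ValidationError("radii_profile entries must be strictly positive")

    @property
    def n_elements(self) -> int:
        return self.n_u * self.n_v * self.n_w

    @property
    def n_nodes(self) -> int:
        return (self.n_u + 1) * (self.n_v + 1) * (self.n_w + 1)

    def to_dict(self) -> dict:
        return {
            "n_u": int(self.n_u),
            "n_v": int(self.n_v),
            "n_w": int(self.n_w),
            "centerline": self.centerline.tolist(),
            "radii_profile": self.radii_profile.tolist(),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "TemplateConfig":
        kwargs = {}
        for key in ("n_u", "n_v", "n_w"):
            if key in data:
                kwargs[key] = int(data[key])
        for key in ("centerline", "radii_profile"):
            if key in data:
                kwargs[key] = np.asarray(data[key], dtype=float)
        return cls(**kwargs)


def node_grid_index(config_or_dims, i, j, k):
    """Flat node index of grid position (i, j, k); k runs along the tract."""
    n_u, n_v, _ = _dims_of(config_or_dims)
    return (k * (n_v + 1) + j) * (n_u + 1) + i


def element_grid_index(config_or_dims, i, j, k):
    """Flat element index of element grid position (i, j, k)."""
    n_u, n_v, _ = _dims_of(config_or_dims)
    return (k * n_v + j) * n_u + i


def _dims_of(config_or_dims) -> tuple[int, int, int]:
    if isinstance(config_or_dims, TemplateConfig):
        return config_or_dims.n_u, config_or_dims.n_v, config_or_dims.n_w
    n_u, n_v, n_w = config_or_dims
    return int(n_u), int(n_v), int(n_w)


def structured_hex_connectivity(n_u: int, n_v: int, n_w: int) -> np.ndarray:
    """(n_u*n_v*n_w, 8) connectivity of a structured node grid, VTK order."""
    ii, jj, kk = np.meshgrid(
        np.arange(n_u), np.arange(n_v), np.arange(n_w), indexing="ij"
    )
    # element order: k slowest, then j, then i (matches element_grid_index)
    base = np.stack([ii.ravel(order="F"), jj.ravel(order="F"), kk.ravel(order="F")], 1)
    order = np.lexsort((base[:, 0], base[:, 1], base[:, 2]))
    base = base[order]
    corners = []
    for di, dj, dk in _HEX_CORNERS:
        corners.append(
            node_grid_index((n_u, n_v, n_w), base[:, 0] + di, base[:, 1] + dj,
                            base[:, 2] + dk)
        )
    return np.stack(corners, axis=1)


def _square_to_ellipse(s: np.ndarray, t: np.ndarray, a: float, b: float):
    """Smooth map of [-1, 1]^2 onto the ellipse with semi-axes (a, b).

    The elliptical blend x = s*sqrt(1 - t^2/2), y = t*sqrt(1 - s^2/2) keeps the
    Jacobian positive everywhere, avoiding the degenerate corner elements a
    naive radial clamp would create.
    """
    x = s * np.sqrt(1.0 - 0.5 * t * t)
    y = t * np.sqrt(1.0 - 0.5 * s * s)
    return a * x, b * y


def _parallel_transport_frames(tangents: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation-minimizing normal/binormal fields along a list of unit tangents."""
    n_pts = len(tangents)
    normals = np.zeros((n_pts, 3))
    binormals = np.zeros((n_pts, 3))
    t0 = tangents[0]
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, t0)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    n = ref - np.dot(ref, t0) * t0
    n /= np.linalg.norm(n)
    normals[0] = n
    binormals[0] = np.cross(t0, n)
    for idx in range(1, n_pts):
        t_prev, t_cur = tangents[idx - 1], tangents[idx]
        axis = np.cross(t_prev, t_cur)
        sin_a = np.linalg.norm(axis)
        cos_a = float(np.clip(np.dot(t_prev, t_cur), -1.0, 1.0))
        if sin_a < 1e-12:
            normals[idx] = normals[idx - 1]
        else:
            axis = axis / sin_a
            n_prev = normals[idx - 1]
            # Rodrigues rotation of the previous normal about `axis`.
            normals[idx] = (
                n_prev * cos_a
                + np.cross(axis, n_prev) * sin_a
                + axis * np.dot(axis, n_prev) * (1.0 - cos_a)
            )
        normals[idx] /= np.linalg.norm(normals[idx])
        binormals[idx] = np.cross(t_cur, normals[idx])
    return normals, binormals


def _centroid_jacobians(mesh: HexMesh) -> np.ndarray:
    """Determinant of the trilinear Jacobian at each element centroid."""
    corners = mesh.nodes[mesh.elements]  # (E, 8, 3)
    c = corners
    du = (c[:, 1] - c[:, 0] + c[:, 2] - c[:, 3] + c[:, 5] - c[:, 4] + c[:, 6] - c[:, 7]) / 4
    dv = (c[:, 3] - c[:, 0] + c[:, 2] - c[:, 1] + c[:, 7] - c[:, 4] + c[:, 6] - c[:, 5]) / 4
    dw = (c[:, 4] - c[:, 0] + c[:, 5] - c[:, 1] + c[:, 6] - c[:, 2] + c[:, 7] - c[:, 3]) / 4
    return np.einsum("ij,ij->i", np.cross(du, dv), dw)


def build_template_tract_mesh(config: TemplateConfig | None = None) -> HexMesh:
    """Generate the solid tube-like template mesh described by ``config``.

    Cross-sections are (n_u+1) x (n_v+1) node grids mapped smoothly onto
    ellipses and swept along a cubic-spline interpolation of the centerline
    with rotation-minimizing frames. Deterministic: identical configs yield
    bit-identical node arrays.
    """
    if config is None:
        config = TemplateConfig()

    n_u, n_v, n_w = config.n_u, config.n_v, config.n_w

    # Arc-length-ish parameterization of the centerline control polygon.
    chord = np.linalg.norm(np.diff(config.centerline, axis=0), axis=1)
    params = np.concatenate([[0.0], np.cumsum(chord)])
    if params[-1] <= 0:
        raise ValidationError("centerline has zero length")
    params /= params[-1]
    if len(config.centerline) >= 3:
        spline = CubicSpline(params, config.centerline, axis=0)
    else:
        spline = CubicSpline(params, config.centerline, axis=0, bc_type="natural")

    w_stations = np.linspace(0.0, 1.0, n_w + 1)
    centres = spline(w_stations)
    tangents = spline(w_stations, 1)
    norms = np.linalg.norm(tangents, axis=1, keepdims=True)
    if np.any(norms < 1e-12):
        raise ValidationError("centerline produces a vanishing tangent")
    tangents = tangents / norms
    normals, binormals = _parallel_transport_frames(tangents)

    # Interpolate the semi-axis profile onto the axial stations.
    profile_params = np.linspace(0.0, 1.0, len(config.radii_profile))
    semi_a = np.interp(w_stations, profile_params, config.radii_profile[:, 0])
    semi_b = np.interp(w_stations, profile_params, config.radii_profile[:, 1])

    s = np.linspace(-1.0, 1.0, n_u + 1)
    t = np.linspace(-1.0, 1.0, n_v + 1)
    ss, tt = np.meshgrid(s, t, indexing="ij")  # (n_u+1, n_v+1)

    nodes = np.empty(((n_u + 1) * (n_v + 1) * (n_w + 1), 3))
    for k in range(n_w + 1):
        x, y = _square_to_ellipse(ss, tt, semi_a[k], semi_b[k])
        section = (
            centres[k][None, None, :]
            + x[..., None] * normals[k][None, None, :]
            + y[..., None] * binormals[k][None, None, :]
        )
        # node order within a section: j (v) slow, i (u) fast
        flat = section.transpose(1, 0, 2).reshape(-1, 3)
        start = k * (n_u + 1) * (n_v + 1)
        nodes[start : start + (n_u + 1) * (n_v + 1)] = flat

    elements = structured_hex_connectivity(n_u, n_v, n_w)
    mesh = HexMesh(nodes, elements)

    dets = _centroid_jacobians(mesh)
    if np.any(dets <= 0):
        raise ValidationError(
            f"template has {int(np.sum(dets <= 0))} inverted elements; "
            "check centerline curvature against the radii profile"
        )
    return mesh
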