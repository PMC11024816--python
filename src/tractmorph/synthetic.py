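"""Fully synthetic cohorts: warped tract shapes, metric volumes, ground truth.

Subjects are smooth random warps of the template (perturbed coarse host
lattices). Metric volumes are produced by rasterizing the warped mesh onto a
voxel grid — a voxel is in-mask iff its centre lies inside some element,
decided by Newton inversion of the trilinear map — and filling masked voxels
with a smooth baseline in material coordinates, a per-subject intercept, an
optional group effect inside an axial region, and seeded Gaussian noise.

A single master seed drives a SeedSequence ladder (per subject, per stage),
so every artifact is reproducible in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import nibabel as nib
import numpy as np

from . import vtkio
from .embedding import METRICS, ScalarVolume, SubjectModel, assign_fields
from .errors import ValidationError
from .ffd import FitParams, build_host_lattice, embed_points, evaluate, fit_to_point_cloud
from .mesh import HexMesh, TemplateConfig, build_template_tract_mesh

__all__ = [
    "EffectSpec",
    "SimConfig",
    "generate_subject_shape",
    "generate_metric_volumes",
    "generate_cohort",
    "simulate_cohort_models",
    "rasterize_mesh",
]

logger = logging.getLogger(__name__)

# VTK hexahedron corner offsets as (du, dv, dw) in local coordinates.
_CORNER_OFFSETS = np.array(
    [
        [0, 0, 0],
        [1, 0, 0],
        [1, 1, 0],
        [0, 1, 0],
        [0, 0, 1],
        [1, 0, 1],
        [1, 1, 1],
        [0, 1, 1],
    ],
    dtype=float,
)

DEFAULT_BASELINES = {
    # generator conventions within physiological ranges, not measured values
    "FA": {"core": 0.65, "rim": 0.35},
    "MD": 0.80e-3,
    "AD": 1.20e-3,
    "RD": 0.60e-3,
}

DEFAULT_NOISE_SD = {"FA": 0.03, "MD": 0.04e-3, "AD": 0.06e-3, "RD": 0.04e-3}
DEFAULT_INTERCEPT_SD = {"FA": 0.01, "MD": 0.01e-3, "AD": 0.015e-3, "RD": 0.01e-3}


@dataclass
class EffectSpec:
    """Additive group effect inside an axial material-coordinate interval."""

    deltas: Dict[str, float] = field(default_factory=dict)  # metric -> delta
    region: Tuple[float, float] = (0.35, 0.75)

    def __post_init__(self) -> None:
        w1, w2 = self.region
        if not (0.0 <= w1 < w2 <= 1.0):
            raise ValidationError(
                f"effect region must satisfy 0 <= w1 < w2 <= 1, got {self.region}"
            )
        unknown = set(self.deltas) - set(METRICS)
        if unknown:
            raise ValidationError(f"unknown metrics in effect spec: {sorted(unknown)}")

    @property
    def affected_metrics(self) -> Tuple[str, ...]:
        return tuple(m for m in METRICS if self.deltas.get(m, 0.0) != 0.0)

    def truth_mask(self, template_config: TemplateConfig) -> np.ndarray:
        """Per-element truth: element's axial station centre inside the region."""
        n_u, n_v, n_w = template_config.n_u, template_config.n_v, template_config.n_w
        e = np.arange(n_u * n_v * n_w)
        k = e // (n_u * n_v)
        w_centre = (k + 0.5) / n_w
        w1, w2 = self.region
        return (w_centre >= w1) & (w_centre <= w2)

    def to_dict(self) -> dict:
        return {"deltas": dict(self.deltas), "region": list(self.region)}


@dataclass
class SimConfig:
    """Cohort simulation parameters (defaults mirror a 20-case/12-control study)."""

    n_case: int = 20
    n_control: int = 12
    shape_warp_scale: float = 2.0  # mm, SD of lattice control-point perturbations
    voxel_size: float = 2.0  # mm
    noise_sd: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    baselines: Dict[str, object] = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    subject_intercept_sd: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INTERCEPT_SD)
    )
    seed: int = 0
    template_config: TemplateConfig = field(default_factory=TemplateConfig)
    cloud_factor: int = 10
    warp_lattice_dims: Tuple[int, int, int] = (3, 3, 5)

    def __post_init__(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ValidationError("n_case and n_control must both be >= 2")
        if self.voxel_size <= 0:
            raise ValidationError("voxel_size must be > 0")
        if self.shape_warp_scale < 0:
            raise ValidationError("shape_warp_scale must be >= 0")
        for name, table in (("noise_sd", self.noise_sd),
                            ("subject_intercept_sd", self.subject_intercept_sd)):
            for metric, sd in table.items():
                if sd < 0:
                    raise ValidationError(f"{name}[{metric}] must be >= 0")


def generate_subject_shape(
    template: HexMesh,
    warp_scale: float,
    seed,
    cloud_factor: int = 10,
    lattice_dims: Tuple[int, int, int] = (3, 3, 5),
) -> Tuple[HexMesh, np.ndarray]:
    """Smoothly warp the template and sample a dense surface point cloud.

    The warp displaces the control points of a coarse host lattice by seeded
    i.i.d. Gaussians with SD ``warp_scale`` and maps the template through it.
    The cloud holds >= ``cloud_factor`` x (surface node count) points sampled
    bilinearly on the warped boundary faces. ``warp_scale=0`` returns the
    template unchanged (cloud exactly on its surface).
    """
    if warp_scale < 0:
        raise ValidationError("warp_scale must be >= 0")
    rng = np.random.default_rng(seed)
    if warp_scale > 0:
        lattice = build_host_lattice(template.nodes, lattice_dims)
        coords = embed_points(lattice, template.nodes)
        lattice.control_points = lattice.control_points + rng.normal(
            0.0, warp_scale, size=lattice.control_points.shape
        )
        warped = template.with_nodes(evaluate(lattice, coords))
    else:
        warped = template.copy()

    faces = warped.boundary_faces()  # (F, 4) quads on the warped surface
    n_target = cloud_factor * len(template.surface_nodes)
    per_face = int(np.ceil(n_target / len(faces)))
    a = rng.uniform(size=(len(faces), per_face, 1))
    b = rng.uniform(size=(len(faces), per_face, 1))
    c0, c1, c2, c3 = (warped.nodes[faces[:, i]][:, None, :] for i in range(4))
    pts = (
        (1 - a) * (1 - b) * c0
        + a * (1 - b) * c1
        + a * b * c2
        + (1 - a) * b * c3
    ).reshape(-1, 3)
    return warped, pts


def _trilinear_invert(corners: np.ndarray, points: np.ndarray,
                      n_iter: int = 10) -> Tuple[np.ndarray, np.ndarray]:
    """Batched Newton inversion of the trilinear map; returns (xi, residual).

    ``corners``: (M, 8, 3) hexahedron corners (VTK order); ``points``: (M, 3).
    The 3x3 Newton systems are solved by Cramer's rule (vectorized), which is
    far cheaper than batched LAPACK calls at these sizes.
    """
    m = len(points)
    xi = np.full((m, 3), 0.5)
    off = _CORNER_OFFSETS  # (8, 3)
    su = np.where(off[:, 0] == 1, 1.0, -1.0)
    sv = np.where(off[:, 1] == 1, 1.0, -1.0)
    sw = np.where(off[:, 2] == 1, 1.0, -1.0)
    for _ in range(n_iter):
        u, v, w = xi[:, 0:1], xi[:, 1:2], xi[:, 2:3]
        fu = np.where(off[:, 0] == 1, u, 1 - u)  # (M, 8)
        fv = np.where(off[:, 1] == 1, v, 1 - v)
        fw = np.where(off[:, 2] == 1, w, 1 - w)
        pos = np.einsum("mc,mcx->mx", fu * fv * fw, corners)
        r = pos - points
        a = np.einsum("mc,mcx->mx", su * fv * fw, corners)  # d/du
        b = np.einsum("mc,mcx->mx", fu * sv * fw, corners)  # d/dv
        c = np.einsum("mc,mcx->mx", fu * fv * sw, corners)  # d/dw
        bxc = np.cross(b, c)
        cxa = np.cross(c, a)
        axb = np.cross(a, b)
        det = np.einsum("mx,mx->m", a, bxc)
        safe = np.where(np.abs(det) < 1e-30, 1.0, det)
        step = np.stack(
            [
                np.einsum("mx,mx->m", r, bxc) / safe,
                np.einsum("mx,mx->m", r, cxa) / safe,
                np.einsum("mx,mx->m", r, axb) / safe,
            ],
            axis=1,
        )
        step[np.abs(det) < 1e-30] = 0.0
        xi = np.clip(xi - step, -0.5, 1.5)
    u, v, w = xi[:, 0:1], xi[:, 1:2], xi[:, 2:3]
    fu = np.where(off[:, 0] == 1, u, 1 - u)
    fv = np.where(off[:, 1] == 1, v, 1 - v)
    fw = np.where(off[:, 2] == 1, w, 1 - w)
    pos = np.einsum("mc,mcx->mx", fu * fv * fw, corners)
    return xi, np.linalg.norm(pos - points, axis=1)


def rasterize_mesh(
    mesh: HexMesh, voxel_size: float, tol: float = 1e-9
):
    """Voxelize ``mesh``: a voxel is in-mask iff its centre lies in an element.

    Returns ``(mask, affine, voxel_elem, voxel_local)`` where ``voxel_elem``
    maps each masked voxel (C order) to its containing element (smallest
    element index on shared faces) and ``voxel_local`` holds local (u, v, w).
    """
    if voxel_size <= 0:
        raise ValidationError("voxel_size must be > 0")
    lo = mesh.nodes.min(axis=0) - voxel_size
    hi = mesh.nodes.max(axis=0) + voxel_size
    shape = tuple(np.ceil((hi - lo) / voxel_size).astype(int) + 1)
    affine = np.eye(4)
    affine[:3, :3] *= voxel_size
    affine[:3, 3] = lo

    corners_all = mesh.nodes[mesh.elements]  # (E, 8, 3)
    el_lo = corners_all.min(axis=1)
    el_hi = corners_all.max(axis=1)
    # candidate voxels: centres inside the element's axis-aligned bounding box
    lo_idx = np.maximum(np.ceil((el_lo - lo) / voxel_size - 1e-9).astype(int), 0)
    hi_idx = np.minimum(
        np.floor((el_hi - lo) / voxel_size + 1e-9).astype(int),
        np.array(shape) - 1,
    )
    counts = np.maximum(hi_idx - lo_idx + 1, 0)
    window = counts.max(axis=0)  # uniform per-axis window over all elements
    offs = np.stack(
        np.meshgrid(*(np.arange(c) for c in window), indexing="ij"), axis=-1
    ).reshape(-1, 3)  # (P, 3)
    cand = lo_idx[:, None, :] + offs[None, :, :]  # (E, P, 3)
    valid = np.all(cand <= hi_idx[:, None, :], axis=2) & np.all(
        counts[:, None, :] > 0, axis=2
    )
    els = np.repeat(np.arange(mesh.n_elements, dtype=np.int64), valid.sum(axis=1))
    cand = cand[valid]
    vox = np.ravel_multi_index((cand[:, 0], cand[:, 1], cand[:, 2]), shape)

    vijk = np.stack(np.unravel_index(vox, shape), axis=1).astype(float)
    centres = lo + vijk * voxel_size
    xi, resid = _trilinear_invert(corners_all[els], centres)
    scale = float(np.max(el_hi - el_lo))
    inside = (
        np.all(xi >= -tol, axis=1)
        & np.all(xi <= 1 + tol, axis=1)
        & (resid <= 1e-6 * max(scale, 1.0))
    )
    vox, els, xi = vox[inside], els[inside], xi[inside]
    # duplicates (shared faces / numerically double-counted): smallest element wins
    order = np.lexsort((els, vox))
    vox, els, xi = vox[order], els[order], xi[order]
    uniq_vox, first = np.unique(vox, return_index=True)
    els, xi = els[first], xi[first]

    mask = np.zeros(shape, dtype=bool)
    mask.ravel()[uniq_vox] = True
    return mask, affine, els, np.clip(xi, 0.0, 1.0)


def _material_coords(elem_idx: np.ndarray, local: np.ndarray,
                     config: TemplateConfig) -> np.ndarray:
    """Global material coordinates (u, v, w) in [0,1]^3 per masked voxel."""
    n_u, n_v, n_w = config.n_u, config.n_v, config.n_w
    k = elem_idx // (n_u * n_v)
    j = (elem_idx % (n_u * n_v)) // n_u
    i = elem_idx % n_u
    return np.stack(
        [(i + local[:, 0]) / n_u, (j + local[:, 1]) / n_v, (k + local[:, 2]) / n_w],
        axis=1,
    )


def _baseline_values(metric: str, mat: np.ndarray, baselines: Dict) -> np.ndarray:
    spec = baselines[metric]
    if isinstance(spec, dict):  # core-to-rim radial gradient (FA default)
        rho = np.clip(
            np.hypot(2 * mat[:, 0] - 1, 2 * mat[:, 1] - 1), 0.0, 1.0
        )
        return spec["core"] + (spec["rim"] - spec["core"]) * rho
    return np.full(len(mat), float(spec))


def generate_metric_volumes(
    mesh: HexMesh,
    group: str,
    effect: EffectSpec,
    config: SimConfig,
    seed,
    min_masked_voxels: int = 100,
) -> Dict[str, ScalarVolume]:
    """Rasterize ``mesh`` and fill masked voxels with baseline + effect + noise.

    The group effect (``effect.deltas``) is added only for ``group='case'``
    at voxels whose axial material coordinate falls in ``effect.region``.
    FA is clamped to [0, 1] after noise.
    """
    if group not in ("case", "control"):
        raise ValidationError(f"group must be 'case' or 'control', got {group!r}")
    mask, affine, elem_idx, local = rasterize_mesh(mesh, config.voxel_size)
    n_masked = int(mask.sum())
    if n_masked < min_masked_voxels:
        raise ValidationError(
            f"voxel grid too coarse: only {n_masked} masked voxels "
            f"(need >= {min_masked_voxels}); decrease voxel_size"
        )
    mat = _material_coords(elem_idx, local, config.template_config)
    w1, w2 = effect.region
    in_region = (mat[:, 2] >= w1) & (mat[:, 2] <= w2)

    rng = np.random.default_rng(seed)
    volumes: Dict[str, ScalarVolume] = {}
    for metric in METRICS:
        vals = _baseline_values(metric, mat, config.baselines)
        vals = vals + rng.normal(0.0, config.subject_intercept_sd.get(metric, 0.0))
        if group == "case":
            delta = effect.deltas.get(metric, 0.0)
            if delta:
                vals = vals + delta * in_region
        noise = config.noise_sd.get(metric, 0.0)
        if noise > 0:
            vals = vals + rng.normal(0.0, noise, size=len(vals))
        if metric == "FA":
            vals = np.clip(vals, 0.0, 1.0)
        data = np.zeros(mask.shape)
        data[mask] = vals
        volumes[metric] = ScalarVolume(data, affine, metric, mask.copy())
    return volumes


def _subject_plan(config: SimConfig) -> List[Tuple[str, str]]:
    plan = [("case", f"case{i + 1:02d}") for i in range(config.n_case)]
    plan += [("control", f"control{i + 1:02d}") for i in range(config.n_control)]
    return plan


def simulate_cohort_models(
    config: SimConfig,
    effect: EffectSpec,
    fit: bool = False,
    fit_params: FitParams | None = None,
    fit_lattice_dims: Tuple[int, int, int] = (4, 4, 4),
    group_specific_shape: bool = False,
) -> Tuple[List[SubjectModel], dict]:
    """Run the full synthetic pipeline in memory; returns (models, truth).

    With ``fit=True`` the template is FFD-fitted to each subject's surface
    cloud before embedding (the production path); with ``fit=False`` the
    known warped mesh is used directly, isolating the statistics from fitting
    error. Shapes are drawn from a group-independent distribution unless
    ``group_specific_shape`` adds a systematic axial stretch for cases.
    """
    template = build_template_tract_mesh(config.template_config)
    plan = _subject_plan(config)
    children = np.random.SeedSequence(config.seed).spawn(len(plan))
    models: List[SubjectModel] = []
    rmses: List[float] = []
    for (group, sid), child in zip(plan, children):
        shape_seed, vol_seed = child.spawn(2)
        warped, cloud = generate_subject_shape(
            template, config.shape_warp_scale, shape_seed,
            cloud_factor=config.cloud_factor,
            lattice_dims=config.warp_lattice_dims,
        )
        if group_specific_shape and group == "case":
            centre = warped.nodes.mean(axis=0)
            stretched = warped.nodes.copy()
            stretched[:, 2] = centre[2] + 1.06 * (stretched[:, 2] - centre[2])
            warped = warped.with_nodes(stretched)
            cloud = _resample_surface(warped, shape_seed, config.cloud_factor)
        if fit:
            result = fit_to_point_cloud(
                template, cloud, fit_lattice_dims, fit_params or FitParams()
            )
            mesh_s = result.mesh
            rmses.append(result.rmse)
        else:
            mesh_s = warped
        volumes = generate_metric_volumes(warped, group, effect, config, vol_seed)
        model = assign_fields(
            mesh_s, volumes, subject_id=sid, group_label=group
        )
        models.append(model)
    truth = {
        "effect": effect.to_dict(),
        "truth_mask": effect.truth_mask(config.template_config).tolist(),
        "seed": int(config.seed),
        "fitted": bool(fit),
        "fit_rmse_mm": rmses,
    }
    return models, truth


def _resample_surface(mesh: HexMesh, seed, cloud_factor: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    faces = mesh.boundary_faces()
    n_target = cloud_factor * len(mesh.surface_nodes)
    per_face = int(np.ceil(n_target / len(faces)))
    a = rng.uniform(size=(len(faces), per_face, 1))
    b = rng.uniform(size=(len(faces), per_face, 1))
    c0, c1, c2, c3 = (mesh.nodes[faces[:, i]][:, None, :] for i in range(4))
    return (
        (1 - a) * (1 - b) * c0 + a * (1 - b) * c1 + a * b * c2 + (1 - a) * b * c3
    ).reshape(-1, 3)


def generate_cohort(config: SimConfig, effect: EffectSpec, out_dir) -> dict:
    """Write a full study bundle: clouds, NIfTI volumes, groups CSV, truth JSON.

    Fully reproducible from ``(config, effect)``; returns the manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    template = build_template_tract_mesh(config.template_config)
    plan = _subject_plan(config)
    children = np.random.SeedSequence(config.seed).spawn(len(plan))

    rows = []
    files: List[str] = []
    for (group, sid), child in zip(plan, children):
        shape_seed, vol_seed = child.spawn(2)
        warped, cloud = generate_subject_shape(
            template, config.shape_warp_scale, shape_seed,
            cloud_factor=config.cloud_factor,
            lattice_dims=config.warp_lattice_dims,
        )
        cloud_path = out_dir / f"{sid}.xyz"
        if cloud_path.exists():
            raise ValidationError(f"output collision: {cloud_path} already exists")
        vtkio.write_point_cloud(cloud, cloud_path)
        files.append(cloud_path.name)
        volumes = generate_metric_volumes(warped, group, effect, config, vol_seed)
        for metric, volume in volumes.items():
            nii_path = out_dir / f"{sid}_{metric}.nii"
            if nii_path.exists():
                raise ValidationError(f"output collision: {nii_path} already exists")
            nib.save(nib.Nifti1Image(volume.data, volume.affine), str(nii_path))
            files.append(nii_path.name)
        rows.append(f"{sid},{group}")

    groups_path = out_dir / "groups.csv"
    groups_path.write_text("subject_id,group\n" + "\n".join(rows) + "\n")
    files.append(groups_path.name)

    truth = {
        "effect": effect.to_dict(),
        "truth_mask": effect.truth_mask(config.template_config).tolist(),
        "seed": int(config.seed),
        "n_case": config.n_case,
        "n_control": config.n_control,
        "voxel_size_mm": config.voxel_size,
        "shape_warp_scale_mm": config.shape_warp_scale,
    }
    truth_path = out_dir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=2) + "\n")
    files.append(truth_path.name)

    manifest = {
        name: hashlib.sha256((out_dir / name).read_bytes()).hexdigest()
        for name in sorted(files)
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("wrote cohort bundle with %d files to %s", len(files), out_dir)
    return manifest
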