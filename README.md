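# tractmorph

Whole-volume white-matter tract morphometry on corresponded hexahedral
meshes. A fixed-topology template mesh of a tract is morphed onto each
subject's tract geometry by host-lattice free-form deformation (FFD),
per-voxel diffusion metrics (FA, MD, AD, RD) are embedded into the
corresponded elements by nearest-neighbour lookup, and cohort-level analyses
run on the resulting fixed-dimension feature matrices: centred/scaled PCA
clustering, element-wise t-test fields, and group mean ±1/±2 SD pattern
fields.

Because every subject model is a morph of the *same* template (20 480
elements by default), element *e* corresponds across subjects, which is what
makes the element-wise statistics and subjects × elements PCA well defined.

## Layout

| module | contents |
| --- | --- |
| `tractmorph.mesh` | `HexMesh`, `TemplateConfig`, parametric template generator (elliptical cross-sections swept along a centerline), surface extraction, centroids |
| `tractmorph.vtkio` | ASCII legacy VTK unstructured-grid read/write (hexahedra + per-element fields), XYZ/PLY point clouds |
| `tractmorph.ffd` | `HostLattice` trilinear free-form deformation: embed / evaluate / regularized ICP-style surface fitting, RMSE |
| `tractmorph.embedding` | NIfTI metric volumes (`ScalarVolume`), nearest-masked-voxel field assignment (`SubjectModel`) |
| `tractmorph.cohort_stats` | cohort matrices, standardization, SVD PCA, pooled/Welch/paired element-wise t-tests (BH-FDR optional), pattern fields, PC1/PC2 separation report |
| `tractmorph.synthetic` | synthetic cohorts: seeded smooth shape warps, mesh rasterization (trilinear point-in-hexahedron), metric volumes with a known effect region, ground-truth masks |
| `tractmorph.cli` | `tractmorph` command with `simulate`, `template`, `fit`, `embed`, `analyze` subcommands |

## CLI walkthrough

```bash
# 1. a synthetic study bundle: per-subject surface clouds (.xyz), four NIfTI
#    metric volumes each, groups.csv, truth.json, manifest.json
tractmorph simulate --config study.yaml --out study/

# 2. the template mesh (default 16 x 16 x 80 = 20 480 elements)
tractmorph template -o template.vtk

# 3. per subject: FFD-fit the template to the surface cloud ...
tractmorph fit template.vtk study/case01.xyz -o models/case01_fit.vtk

# 4. ... and embed the metric volumes into the fitted mesh
tractmorph embed models/case01_fit.vtk \
    --fa study/case01_FA.nii --md study/case01_MD.nii \
    --ad study/case01_AD.nii --rd study/case01_RD.nii \
    -o models/case01.vtk --subject-id case01 --group case

# 5. cohort statistics: PCA scores CSV, separation JSON, element-wise t-test
#    p/t fields and per-group mean +/- SD pattern fields on the template VTK
tractmorph analyze models/ study/groups.csv -o results/
```

Example `study.yaml`:

```yaml
sim:
  n_case: 10
  n_control: 10
  seed: 1
  voxel_size: 2.0
  shape_warp_scale: 2.0
effect:
  deltas: {MD: 1.2e-4}
  region: [0.35, 0.75]
```

All mesh outputs are ASCII legacy VTK and open directly in ParaView.
Element-wise p-value maps are **uncorrected** by default; pass `--fdr` to
`analyze` for BH-FDR q-values.

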