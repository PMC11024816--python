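"""Cohort statistics on corresponded meshes.

Because every subject model is a morph of the same template, element e in one
subject corresponds to element e in every other. Stacking subjects gives a
subjects x features matrix per metric (or per flattened node coordinates for
shape), on which we run centred/scaled PCA, element-wise t-test fields, and
group mean +/- SD pattern fields.

PCA is computed from the SVD of the standardized subjects-by-features matrix
directly (the features x features covariance is never formed; with ~20k
features and tens of subjects that would be wasteful). Sign convention: every
loading column is oriented so its largest-magnitude entry is positive, which
makes runs comparable across platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Sequence

import numpy as np
from scipy import stats
from scipy.linalg import svd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from .embedding import METRICS, SubjectModel
from .errors import ValidationError

__all__ = [
    "CohortMatrix",
    "PCAResult",
    "StatField",
    "PatternFields",
    "assemble_cohort_matrix",
    "standardize",
    "run_pca",
    "elementwise_ttest",
    "group_pattern_fields",
    "cluster_report",
]

logger = logging.getLogger(__name__)


@dataclass
class CohortMatrix:
    """Subjects x features matrix with provenance of the retained features."""

    matrix: np.ndarray
    subject_ids: List[str]
    group_labels: List[str]
    metric_name: str  # one of METRICS, "shape", or "combined"
    feature_indices: np.ndarray  # template element (or coordinate) index per column
    dropped_features: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    standardized: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValidationError("cohort matrix must be 2-D")
        if self.matrix.shape[0] != len(self.subject_ids):
            raise ValidationError("row count != number of subjects")
        if len(self.group_labels) != len(self.subject_ids):
            raise ValidationError("group_labels length != subject count")
        self.feature_indices = np.asarray(self.feature_indices, dtype=np.int64)
        if len(self.feature_indices) != self.matrix.shape[1]:
            raise ValidationError("feature_indices length != column count")
        self.dropped_features = np.asarray(self.dropped_features, dtype=np.int64)

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


@dataclass
class PCAResult:
    scores: np.ndarray  # subjects x n_components
    loadings: np.ndarray  # features x n_components
    explained_variance_ratio: np.ndarray
    n_components: int
    subject_ids: List[str] = field(default_factory=list)
    group_labels: List[str] = field(default_factory=list)


@dataclass
class StatField:
    t: np.ndarray
    p: np.ndarray
    test_type: str
    feature_indices: np.ndarray
    degenerate: np.ndarray  # elements where both groups had zero variance
    q: np.ndarray | None = None


@dataclass
class PatternFields:
    """Per group: mean and mean +/- 1,2 SD per-element fields."""

    groups: Dict[str, Dict[str, np.ndarray]]
    metric_name: str
    feature_indices: np.ndarray


def _check_same_topology(models: Sequence[SubjectModel]) -> None:
    ref = models[0].mesh
    bad = [
        m.subject_id or f"#{i}"
        for i, m in enumerate(models)
        if m.mesh.n_nodes != ref.n_nodes
        or m.mesh.n_elements != ref.n_elements
        or not np.array_equal(m.mesh.elements, ref.elements)
    ]
    if bad:
        raise ValidationError(f"template topology mismatch for subjects: {bad}")


def assemble_cohort_matrix(
    models: Sequence[SubjectModel], metric_name: str
) -> CohortMatrix:
    """Stack per-subject fields (or node coordinates for ``"shape"``).

    Metric mode drops every element flagged unassigned in ANY subject, so all
    rows share an identical feature set.
    """
    if len(models) < 3:
        raise ValidationError(f"need >= 3 subjects, got {len(models)}")
    _check_same_topology(models)
    subject_ids = [m.subject_id for m in models]
    group_labels = [m.group_label for m in models]

    if metric_name == "shape":
        rows = np.stack([m.mesh.nodes.ravel() for m in models])
        return CohortMatrix(
            rows, subject_ids, group_labels, "shape",
            np.arange(rows.shape[1]),
        )

    if metric_name not in METRICS:
        raise ValidationError(f"unknown metric {metric_name!r}")
    missing = [m.subject_id or "?" for m in models if metric_name not in m.fields]
    if missing:
        raise ValidationError(f"metric {metric_name!r} missing for subjects {missing}")
    n_el = models[0].mesh.n_elements
    bad_any = np.zeros(n_el, dtype=bool)
    for m in models:
        bad_any |= m.unassigned
    keep = np.flatnonzero(~bad_any)
    rows = np.stack([m.fields[metric_name][keep] for m in models])
    return CohortMatrix(
        rows, subject_ids, group_labels, metric_name, keep,
        dropped_features=np.flatnonzero(bad_any),
    )


def standardize(matrix: CohortMatrix, sd_floor: float = 1e-12) -> CohortMatrix:
    """Centre each column and scale to unit SD (n-1 denominator).

    Columns with SD below ``sd_floor`` carry no between-subject information
    and are dropped (recorded in ``dropped_features``).
    """
    if matrix.n_subjects < 2:
        raise ValidationError("standardization needs >= 2 subjects")
    X = matrix.matrix
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = sd >= sd_floor
    Z = (X[:, keep] - mean[keep]) / sd[keep]
    dropped = np.concatenate(
        [matrix.dropped_features, matrix.feature_indices[~keep]]
    )
    return CohortMatrix(
        Z,
        list(matrix.subject_ids),
        list(matrix.group_labels),
        matrix.metric_name,
        matrix.feature_indices[keep],
        dropped_features=np.unique(dropped),
        standardized=True,
    )


def run_pca(matrix: CohortMatrix, n_components: int = 2) -> PCAResult:
    """PCA of the standardized matrix via thin SVD with a fixed sign rule."""
    n, p = matrix.matrix.shape
    if p == 0:
        raise ValidationError(
            "matrix has no features with nonzero variance (degenerate cohort: "
            "all subjects identical on this feature set); PCA is undefined"
        )
    limit = min(n - 1, p)
    if n_components > limit:
        raise ValidationError(
            f"n_components={n_components} exceeds min(subjects-1, features)={limit}"
        )
    U, S, Vt = svd(matrix.matrix, full_matrices=False)
    total = float(np.sum(S**2))
    evr = (S**2 / total)[:n_components]
    scores = (U * S)[:, :n_components]
    loadings = Vt[:n_components].T
    # orient: largest-|entry| of each loading column positive
    for c in range(n_components):
        col = loadings[:, c]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, c] = -col
            scores[:, c] = -scores[:, c]
    return PCAResult(
        scores, loadings, evr, n_components,
        list(matrix.subject_ids), list(matrix.group_labels),
    )


def elementwise_ttest(
    matrix_a: CohortMatrix,
    matrix_b: CohortMatrix,
    test_type: Literal["pooled", "welch", "paired"] = "pooled",
    fdr: bool = False,
) -> StatField:
    """Two-sided t-test at every retained element across subjects.

    ``pooled`` is the classic equal-variance two-sample t (the default;
    multiple-testing correction is OFF by default — maps are uncorrected
    p-values unless ``fdr=True`` adds BH-FDR q-values). Elements where the
    test statistic is undefined (zero variance in both groups and equal
    means) get t = 0, p = 1 and are flagged ``degenerate``.
    """
    if not np.array_equal(matrix_a.feature_indices, matrix_b.feature_indices):
        raise ValidationError("matrices have different retained feature sets")
    A, B = matrix_a.matrix, matrix_b.matrix
    na, nb = A.shape[0], B.shape[0]
    if na < 2 or nb < 2:
        raise ValidationError("each group needs >= 2 subjects")
    if test_type == "paired":
        if na != nb:
            raise ValidationError("paired test needs equal group sizes in matched order")
        D = A - B
        mean_d = D.mean(axis=0)
        sd_d = D.std(axis=0, ddof=1)
        df = na - 1
        denom = sd_d / np.sqrt(na)
    elif test_type in ("pooled", "welch"):
        mean_d = A.mean(axis=0) - B.mean(axis=0)
        va = A.var(axis=0, ddof=1)
        vb = B.var(axis=0, ddof=1)
        if test_type == "pooled":
            sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
            denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
            df = np.full_like(mean_d, na + nb - 2)
        else:
            denom = np.sqrt(va / na + vb / nb)
            with np.errstate(divide="ignore", invalid="ignore"):
                df = (va / na + vb / nb) ** 2 / (
                    (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
                )
    else:
        raise ValidationError(f"unknown test_type {test_type!r}")

    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_d / denom
    zero_denom = denom == 0
    degenerate = zero_denom & (mean_d == 0)
    t = np.where(degenerate, 0.0, t)
    t = np.where(zero_denom & ~degenerate,
                 np.where(mean_d > 0, np.inf, -np.inf), t)
    df = np.where(zero_denom, 1.0, df) if np.ndim(df) else df
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(degenerate, 1.0, p)
    p = np.clip(p, 0.0, 1.0)

    q = None
    if fdr:
        q = multipletests(p, method="fdr_bh")[1]
    return StatField(t, p, test_type, matrix_a.feature_indices.copy(), degenerate, q)


def group_pattern_fields(
    models: Sequence[SubjectModel], metric_name: str
) -> PatternFields:
    """Per-group mean and mean +/- 1,2 SD per-element fields (ddof=1)."""
    if len(models) < 2:
        raise ValidationError("need >= 2 subjects for pattern fields")
    _check_same_topology(models)
    groups: Dict[str, List[SubjectModel]] = {}
    for m in models:
        groups.setdefault(m.group_label, []).append(m)
    n_el = models[0].mesh.n_elements
    out: Dict[str, Dict[str, np.ndarray]] = {}
    for label, members in groups.items():
        if len(members) < 2:
            raise ValidationError(
                f"group {label!r} has {len(members)} subject(s); need >= 2"
            )
        stackv = np.stack([m.fields[metric_name] for m in members])
        mean = stackv.mean(axis=0)
        sd = stackv.std(axis=0, ddof=1)
        out[label] = {
            "mean": mean,
            "mean_minus_1sd": mean - sd,
            "mean_plus_1sd": mean + sd,
            "mean_minus_2sd": mean - 2 * sd,
            "mean_plus_2sd": mean + 2 * sd,
        }
    return PatternFields(out, metric_name, np.arange(n_el))


def _binary_auc(labels: np.ndarray, scores: np.ndarray, positive) -> float:
    return float(roc_auc_score((labels == positive).astype(int), scores))


def cluster_report(
    pca: PCAResult,
    group_labels: Sequence[str] | None = None,
    positive_label: str | None = None,
) -> dict:
    """Descriptive PC1/PC2 separation summary (no significance claim).

    For each pair of groups reports the raw AUC of PC1 as a ranker of group
    membership (orientation: ``positive_label`` or the lexicographically first
    group), the orientation-free separation max(AUC, 1-AUC), and the AUC of
    the best linear combination of PC1/PC2 (in-sample LDA).
    """
    labels = np.asarray(group_labels if group_labels is not None else pca.group_labels)
    if len(labels) != len(pca.scores):
        raise ValidationError("group_labels length != number of score rows")
    unique = sorted(set(labels.tolist()))
    if len(unique) < 2:
        raise ValidationError("cluster report needs >= 2 groups")

    table = [
        {
            "subject_id": pca.subject_ids[i] if pca.subject_ids else str(i),
            "group": str(labels[i]),
            "pc1": float(pca.scores[i, 0]),
            "pc2": float(pca.scores[i, 1]) if pca.scores.shape[1] > 1 else None,
        }
        for i in range(len(labels))
    ]

    pairs = {}
    for a_idx in range(len(unique)):
        for b_idx in range(a_idx + 1, len(unique)):
            ga, gb = unique[a_idx], unique[b_idx]
            sel = (labels == ga) | (labels == gb)
            pos = positive_label if positive_label in (ga, gb) else ga
            y = labels[sel]
            pc1 = pca.scores[sel, 0]
            auc1 = _binary_auc(y, pc1, pos)
            entry = {
                "positive_label": pos,
                "auc_pc1": auc1,
                "separation_pc1": max(auc1, 1.0 - auc1),
            }
            if pca.scores.shape[1] > 1:
                xy = pca.scores[sel, :2]
                try:
                    lda = LinearDiscriminantAnalysis().fit(xy, (y == pos).astype(int))
                    dec = lda.decision_function(xy)
                    auc_lda = _binary_auc(y, dec, pos)
                except Exception:  # degenerate scores (e.g. zero variance)
                    auc_lda = entry["separation_pc1"]
                entry["auc_pc12_lda"] = max(auc_lda, 1.0 - auc_lda)
            pairs[f"{ga}|{gb}"] = entry

    report = {"scores": table, "pairs": pairs, "n_subjects": len(labels)}
    if len(unique) == 2:
        report.update(pairs[f"{unique[0]}|{unique[1]}"])
    return report
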