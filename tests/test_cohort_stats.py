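import itertools

import numpy as np
import pytest
from scipy import stats

from tractmorph.cohort_stats import (
    CohortMatrix,
    assemble_cohort_matrix,
    cluster_report,
    elementwise_ttest,
    group_pattern_fields,
    run_pca,
    standardize,
)
from tractmorph.embedding import SubjectModel
from tractmorph.errors import ValidationError
from tractmorph.mesh import build_template_tract_mesh, TemplateConfig

from .conftest import make_cohort


def pooled_t_oracle(a, b):
    """Closed-form pooled two-sample t and two-sided p (independent path)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    p = 2 * stats.t.sf(abs(t), df)
    return t, p


@pytest.fixture(scope="module")
def mini_models():
    """Four subjects on a tiny shared template with synthetic fields."""
    mesh = build_template_tract_mesh(TemplateConfig(n_u=2, n_v=2, n_w=3))
    rng = np.random.default_rng(21)
    models = []
    for i in range(4):
        fields = {m: rng.uniform(0.2, 0.8, mesh.n_elements)
                  for m in ("FA", "MD", "AD", "RD")}
        models.append(
            SubjectModel(mesh.copy(), fields, subject_id=f"s{i}",
                         group_label="case" if i < 2 else "control")
        )
    return models


class TestAssemble:
    def test_metric_matrix_shape(self, mini_models):
        mat = assemble_cohort_matrix(mini_models[:3], "FA")
        assert mat.matrix.shape == (3, mini_models[0].mesh.n_elements)

    def test_unassigned_dropped_everywhere(self, mini_models):
        models = [m for m in mini_models]
        flagged = models[0]
        flagged = SubjectModel(
            flagged.mesh.copy(), dict(flagged.fields), flagged.subject_id,
            flagged.group_label,
        )
        flagged.unassigned[[1, 3, 5, 7, 9]] = True
        models = [flagged] + models[1:]
        mat = assemble_cohort_matrix(models, "FA")
        assert mat.matrix.shape[1] == models[0].mesh.n_elements - 5
        assert sorted(mat.dropped_features.tolist()) == [1, 3, 5, 7, 9]

    def test_shape_mode_dimensions(self, mini_models):
        mat = assemble_cohort_matrix(mini_models[:3], "shape")
        assert mat.matrix.shape == (3, mini_models[0].mesh.n_nodes * 3)

    def test_too_few_subjects(self, mini_models):
        with pytest.raises(ValidationError, match=">= 3"):
            assemble_cohort_matrix(mini_models[:2], "FA")

    def test_topology_mismatch_names_subject(self, mini_models):
        other_mesh = build_template_tract_mesh(TemplateConfig(n_u=2, n_v=2, n_w=4))
        bad = SubjectModel(
            other_mesh,
            {m: np.zeros(other_mesh.n_elements) for m in ("FA", "MD", "AD", "RD")},
            subject_id="odd", group_label="case",
        )
        with pytest.raises(ValidationError, match="odd"):
            assemble_cohort_matrix(mini_models[:3] + [bad], "FA")


class TestStandardize:
    def test_simple_column(self):
        mat = make_cohort(np.array([[1.0], [2.0], [3.0]]))
        out = standardize(mat)
        assert np.allclose(out.matrix[:, 0], [-1.0, 0.0, 1.0])

    def test_constant_column_dropped(self):
        mat = make_cohort(np.array([[0.5, 1.0], [0.5, 2.0], [0.5, 3.0]]))
        out = standardize(mat)
        assert out.matrix.shape[1] == 1
        assert 0 in out.dropped_features

    def test_random_matrix_moments(self):
        rng = np.random.default_rng(2)
        out = standardize(make_cohort(rng.normal(2.0, 3.0, size=(5, 10))))
        assert np.abs(out.matrix.mean(axis=0)).max() < 1e-10
        assert np.abs(out.matrix.std(axis=0, ddof=1) - 1).max() < 1e-10

    def test_single_row_rejected(self):
        with pytest.raises(ValidationError):
            standardize(make_cohort(np.ones((1, 4))))


class TestPCA:
    def test_rank1_example(self):
        mat = standardize(make_cohort(np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])))
        pca = run_pca(mat, 2)
        assert pca.explained_variance_ratio[0] == pytest.approx(1.0)
        assert np.allclose(pca.scores[:, 0], [-np.sqrt(2), 0.0, np.sqrt(2)])

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(3)
        mat = standardize(make_cohort(rng.normal(size=(6, 9))))
        pca = run_pca(mat, min(mat.matrix.shape[0] - 1, mat.matrix.shape[1]))
        recon = pca.scores @ pca.loadings.T
        assert np.abs(recon - mat.matrix).max() <= 1e-8

    def test_duplicated_rows_same_scores(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(4, 6))
        X[3] = X[1]
        pca = run_pca(standardize(make_cohort(X)), 2)
        assert np.allclose(pca.scores[1], pca.scores[3], atol=1e-10)

    def test_score_orthogonality(self):
        rng = np.random.default_rng(5)
        pca = run_pca(standardize(make_cohort(rng.normal(size=(8, 20)))), 4)
        gram = pca.scores.T @ pca.scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() <= 1e-8 * np.abs(np.diag(gram)).max()

    def test_evr_nonincreasing_and_bounded(self):
        rng = np.random.default_rng(6)
        pca = run_pca(standardize(make_cohort(rng.normal(size=(8, 20)))), 6)
        evr = pca.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-15)
        assert np.all((evr >= 0) & (evr <= 1))
        assert evr.sum() <= 1 + 1e-12

    def test_too_many_components_rejected(self):
        mat = standardize(make_cohort(np.random.default_rng(7).normal(size=(4, 5))))
        with pytest.raises(ValidationError, match="n_components"):
            run_pca(mat, 4)

    def test_degenerate_zero_variance_reported(self):
        # identical copies of the template: shape matrix has zero variance
        X = np.tile(np.arange(6.0), (4, 1))
        out = standardize(make_cohort(X, metric="shape"))
        assert out.matrix.shape[1] == 0
        with pytest.raises(ValidationError, match="degenerate"):
            run_pca(out, 2)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(5, 7))
        a = run_pca(standardize(make_cohort(X)), 2)
        b = run_pca(standardize(make_cohort(X)), 2)
        assert np.array_equal(a.scores, b.scores)
        for c in range(2):
            col = a.loadings[:, c]
            assert col[np.argmax(np.abs(col))] > 0


class TestTTest:
    def test_identical_groups(self):
        X = np.array([[1.0, 2.0], [3.0, 4.0]])
        a = make_cohort(X)
        b = make_cohort(X.copy())
        sf = elementwise_ttest(a, b)
        assert np.allclose(sf.t, 0.0)
        assert np.allclose(sf.p, 1.0)

    def test_hand_computed_example(self):
        a = make_cohort(np.array([[1.0], [2.0]]))
        b = make_cohort(np.array([[4.0], [6.0]]))
        sf = elementwise_ttest(a, b, "pooled")
        assert sf.t[0] == pytest.approx(-3.1305, abs=1e-3)
        assert sf.p[0] == pytest.approx(0.0888, abs=1e-3)

    def test_pooled_matches_oracle_exhaustive_sizes(self):
        rng = np.random.default_rng(10)
        for na, nb in itertools.product(range(2, 6), repeat=2):
            for _ in range(4):
                a = rng.integers(0, 7, size=na).astype(float)
                b = rng.integers(0, 7, size=nb).astype(float)
                if a.var() == 0 and b.var() == 0:
                    continue
                sf = elementwise_ttest(
                    make_cohort(a[:, None]), make_cohort(b[:, None]), "pooled"
                )
                t_exp, p_exp = pooled_t_oracle(a, b)
                assert sf.t[0] == pytest.approx(t_exp, rel=1e-12, abs=1e-12)
                assert sf.p[0] == pytest.approx(p_exp, rel=1e-12, abs=1e-12)

    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(11)
        A = rng.normal(size=(5, 50))
        B = rng.normal(size=(7, 50)) * 2.0
        sf = elementwise_ttest(make_cohort(A), make_cohort(B), "welch")
        t_exp, p_exp = stats.ttest_ind(A, B, axis=0, equal_var=False)
        assert np.allclose(sf.t, t_exp)
        assert np.allclose(sf.p, p_exp)

    def test_paired_matches_scipy(self):
        rng = np.random.default_rng(12)
        A = rng.normal(size=(6, 30))
        B = A + rng.normal(0.3, 1.0, size=(6, 30))
        sf = elementwise_ttest(make_cohort(A), make_cohort(B), "paired")
        t_exp, p_exp = stats.ttest_rel(A, B, axis=0)
        assert np.allclose(sf.t, t_exp)
        assert np.allclose(sf.p, p_exp)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(13)
        A = rng.normal(size=(10, 2000))
        B = rng.normal(size=(10, 2000))
        sf = elementwise_ttest(make_cohort(A), make_cohort(B))
        ks = stats.kstest(sf.p, "uniform")
        assert ks.pvalue > 0.01

    def test_zero_variance_flagged(self):
        a = make_cohort(np.array([[1.0, 1.0], [1.0, 1.0]]))
        b = make_cohort(np.array([[1.0, 2.0], [1.0, 2.0]]))
        sf = elementwise_ttest(a, b)
        assert sf.degenerate[0] and sf.p[0] == 1.0
        assert not sf.degenerate[1] and sf.p[1] == 0.0  # zero var, unequal means

    def test_group_too_small(self):
        with pytest.raises(ValidationError, match=">= 2"):
            elementwise_ttest(make_cohort(np.ones((1, 3))), make_cohort(np.ones((3, 3))))

    def test_paired_size_mismatch(self):
        with pytest.raises(ValidationError, match="paired"):
            elementwise_ttest(
                make_cohort(np.ones((3, 2))), make_cohort(np.ones((4, 2))), "paired"
            )

    def test_fdr_monotone_and_order_invariant(self):
        rng = np.random.default_rng(14)
        A = rng.normal(size=(6, 300))
        B = rng.normal(size=(6, 300))
        B[:, :40] += 1.5
        sf = elementwise_ttest(make_cohort(A), make_cohort(B), fdr=True)
        order = np.argsort(sf.p)
        assert np.all(np.diff(sf.q[order]) >= -1e-15)
        perm = rng.permutation(300)
        sf_perm = elementwise_ttest(
            make_cohort(A[:, perm], feature_indices=np.arange(300)),
            make_cohort(B[:, perm], feature_indices=np.arange(300)),
            fdr=True,
        )
        assert np.allclose(np.sort(sf_perm.q), np.sort(sf.q))


class TestPatternFields:
    def test_identical_subjects_collapse(self, mini_models):
        base = mini_models[0]
        clones = [
            SubjectModel(base.mesh.copy(), dict(base.fields), f"c{i}", "case")
            for i in range(3)
        ]
        patterns = group_pattern_fields(clones, "FA")
        table = patterns.groups["case"]
        for key in table:
            assert np.allclose(table[key], base.fields["FA"])

    def test_two_subject_sd(self):
        mesh = build_template_tract_mesh(TemplateConfig(n_u=1, n_v=1, n_w=1))
        m1 = SubjectModel(mesh.copy(), {"FA": np.array([0.4])}, "a", "g")
        m2 = SubjectModel(mesh.copy(), {"FA": np.array([0.6])}, "b", "g")
        patterns = group_pattern_fields([m1, m2], "FA")
        table = patterns.groups["g"]
        sd = np.std([0.4, 0.6], ddof=1)
        assert table["mean"][0] == pytest.approx(0.5)
        assert table["mean_plus_1sd"][0] == pytest.approx(0.5 + sd)
        assert sd == pytest.approx(0.1414, abs=1e-4)

    def test_ordering_invariant(self, mini_models):
        patterns = group_pattern_fields(mini_models, "MD")
        for table in patterns.groups.values():
            assert np.all(table["mean_minus_2sd"] <= table["mean_minus_1sd"] + 1e-15)
            assert np.all(table["mean_minus_1sd"] <= table["mean"] + 1e-15)
            assert np.all(table["mean"] <= table["mean_plus_1sd"] + 1e-15)
            assert np.all(table["mean_plus_1sd"] <= table["mean_plus_2sd"] + 1e-15)

    def test_single_subject_group_rejected(self, mini_models):
        lonely = SubjectModel(
            mini_models[0].mesh.copy(), dict(mini_models[0].fields), "solo", "other"
        )
        with pytest.raises(ValidationError, match="other"):
            group_pattern_fields(mini_models + [lonely], "FA")


class TestClusterReport:
    def _pca_like(self, scores, labels):
        from tractmorph.cohort_stats import PCAResult

        scores = np.asarray(scores, float)
        return PCAResult(
            scores, np.zeros((2, scores.shape[1])),
            np.array([0.6, 0.2])[: scores.shape[1]], scores.shape[1],
            [f"s{i}" for i in range(len(scores))], list(labels),
        )

    def test_disjoint_ranges_perfect_auc(self):
        scores = np.array([[0.0, 0], [1.0, 0], [5.0, 0], [6.0, 0]])
        rep = cluster_report(self._pca_like(scores, ["a", "a", "b", "b"]))
        assert rep["separation_pc1"] == 1.0

    def test_table_row_count(self):
        scores = np.random.default_rng(1).normal(size=(7, 2))
        labels = ["a", "a", "a", "b", "b", "b", "b"]
        rep = cluster_report(self._pca_like(scores, labels))
        assert len(rep["scores"]) == 7

    def test_permuted_labels_auc_half_on_average(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=(20, 2))
        aucs = []
        for _ in range(200):
            labels = np.array(["a"] * 10 + ["b"] * 10)
            rng.shuffle(labels)
            rep = cluster_report(self._pca_like(scores, labels))
            aucs.append(rep["auc_pc1"])
        assert abs(np.mean(aucs) - 0.5) < 0.02

    def test_single_group_rejected(self):
        scores = np.zeros((4, 2))
        with pytest.raises(ValidationError, match="2 groups"):
            cluster_report(self._pca_like(scores, ["a"] * 4))


class TestDeterminism:
    def test_pipeline_repeatable(self, mini_models):
        def run():
            mat = assemble_cohort_matrix(mini_models, "FA")
            std = standardize(mat)
            pca = run_pca(std, 2)
            labels = np.array(std.group_labels)
            sub_a = CohortMatrix(
                mat.matrix[labels == "case"], ["a", "b"], ["case"] * 2,
                "FA", mat.feature_indices,
            )
            sub_b = CohortMatrix(
                mat.matrix[labels == "control"], ["c", "d"], ["control"] * 2,
                "FA", mat.feature_indices,
            )
            sf = elementwise_ttest(sub_a, sub_b)
            return pca.scores, sf.t, sf.p

        s1, t1, p1 = run()
        s2, t2, p2 = run()
        assert np.array_equal(s1, s2)
        assert np.array_equal(t1, t2)
        assert np.array_equal(p1, p2)
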