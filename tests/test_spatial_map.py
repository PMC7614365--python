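import numpy as np
import pandas as pd
import pytest

from spheromap import expr_io, simdata, spatial_map as sm
from spheromap.expr_io import PseudoBulkProfile
from spheromap.simdata import SimConfig


def profile(name, values, genes=None):
    genes = genes or [f"g{i}" for i in range(len(values))]
    return PseudoBulkProfile(name, pd.Series(np.asarray(values, float), index=genes), 1)


class TestPearsonSimilarity:
    def test_self_correlation_is_one(self):
        p = profile("p", [1.0, 2.0, 5.0, 3.0])
        assert sm.pearson_similarity(p, p, p.genes) == pytest.approx(1.0)

    def test_known_half_correlation(self):
        x = profile("x", [1.0, 2.0, 3.0])
        y = profile("y", [1.0, 3.0, 2.0])
        assert sm.pearson_similarity(x, y, x.genes) == pytest.approx(0.5)

    def test_perfect_anticorrelation(self):
        x = profile("x", [1.0, 2.0, 3.0, 4.0])
        y = profile("y", [4.0, 3.0, 2.0, 1.0])
        assert sm.pearson_similarity(x, y, x.genes) == pytest.approx(-1.0)

    def test_constant_profile_rejected_by_name(self):
        x = profile("flatliner", [2.0, 2.0, 2.0])
        y = profile("y", [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="flatliner"):
            sm.pearson_similarity(x, y, x.genes)

    def test_spearman_option(self):
        x = profile("x", [1.0, 2.0, 3.0])
        y = profile("y", [10.0, 20.0, 300.0])  # monotone -> rho = 1
        assert sm.pearson_similarity(x, y, x.genes, method="spearman") == pytest.approx(1.0)


class TestProjectSimilarity:
    def test_self_match_scores_one_at_anchor(self, mesh, fields, reference):
        query = reference.profiles[0]
        verts, vals = sm.project_similarity(query, reference, query.genes)
        at = list(verts).index(reference.anchor_idx[0])
        assert vals[at] == pytest.approx(1.0)

    def test_duplicate_anchors_averaged(self, mesh):
        genes = [f"g{i}" for i in range(4)]
        p1 = profile("a", [1.0, 2.0, 3.0, 4.0], genes)
        p2 = profile("b", [1.0, 2.0, 4.0, 3.0], genes)
        p3 = profile("c", [4.0, 3.0, 2.0, 1.0], genes)
        ref = sm.SpatialReference(
            mesh=mesh,
            anchor_idx=np.array([5, 5, 9]),
            lineage=np.array(["Am_distal"] * 3, dtype=object),
            stage=np.array(["CS6"] * 3, dtype=object),
            profiles=[p1, p2, p3],
        )
        query = profile("q", [1.0, 2.0, 3.0, 4.0], genes)
        verts, vals = sm.project_similarity(query, ref, genes)
        r1 = sm.pearson_similarity(query, p1, genes)
        r2 = sm.pearson_similarity(query, p2, genes)
        at = list(verts).index(5)
        assert vals[at] == pytest.approx((r1 + r2) / 2)

    def test_amnion_query_prefers_amnion_anchors(self, mesh, fields, reference):
        cfg = SimConfig(seed=21, cells_per_spheroid=200)
        cells = simdata.sample_spheroid_cells(
            fields, mesh, "Am_distal", "Am_distal", 0.0, cfg
        )
        pb = expr_io.pseudo_bulk(expr_io.normalize(cells), "condition")[0]
        genes = expr_io.select_hvg(expr_io.normalize(reference.counts), 200)
        verts, vals = sm.project_similarity(pb, reference, genes)
        regions = mesh.region_labels[verts]
        am = np.char.startswith(regions.astype(str), "Am")
        assert vals[am].mean() > vals[~am].mean()


class TestGaussianProcess:
    def _toy(self, seed=0, n=10):
        rng = np.random.default_rng(seed)
        X = rng.uniform(-40, 40, size=(n, 3))
        y = 0.7 * np.sin(X[:, 0] / 20.0)
        return X, y

    def test_lml_matches_direct_formula(self):
        X, y = self._toy()
        ell, sf2, sn2 = 15.0, 0.3, 1e-2
        lml, _ = sm.log_marginal_likelihood(X, y - y.mean(), ell, sf2, sn2)
        yc = y - y.mean()
        d2 = ((X[:, None] - X[None, :]) ** 2).sum(-1)
        K = sf2 * np.exp(-0.5 * d2 / ell**2) + sn2 * np.eye(len(X))
        sign, logdet = np.linalg.slogdet(K)
        direct = (
            -0.5 * yc @ np.linalg.solve(K, yc)
            - 0.5 * logdet
            - 0.5 * len(X) * np.log(2 * np.pi)
        )
        assert lml == pytest.approx(direct, abs=1e-8)

    def test_lml_gradient_matches_finite_differences(self):
        X, y = self._toy(3)
        yc = y - y.mean()
        theta = np.log([12.0, 0.2, 5e-3])

        def f(t):
            l_, s_, n_ = np.exp(t)
            return sm.log_marginal_likelihood(X, yc, l_, s_, n_)[0]

        _, grad = sm.log_marginal_likelihood(X, yc, *np.exp(theta))
        for i in range(3):
            e = np.zeros(3)
            e[i] = 1e-6
            fd = (f(theta + e) - f(theta - e)) / 2e-6
            assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-7)

    def test_constant_values_predicted_everywhere(self):
        X, _ = self._toy(1)
        model = sm.fit_gp(
            (X, np.full(len(X), 0.42)),
            init=dict(lengthscale=10.0, signal_var=0.1, noise_var=0.0),
            optimize_hyper=False,
        )
        pred = sm.gp_predict(model, np.array([[100.0, -50.0, 3.0], [0.0, 0.0, 0.0]]))
        np.testing.assert_allclose(pred.values, 0.42, atol=1e-12)

    def test_noise_free_interpolation_reproduces_training_values(self):
        X, y = self._toy(2)
        model = sm.fit_gp(
            (X, y),
            init=dict(lengthscale=20.0, signal_var=0.5, noise_var=0.0),
            optimize_hyper=False,
        )
        pred = sm.gp_predict(model, X, clip=None)
        np.testing.assert_allclose(pred.values, y, atol=1e-8)

    def test_posterior_mean_matches_dense_solver(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(-40, 40, size=(20, 3))
        y = 0.5 * np.tanh(X[:, 1] / 25.0)
        ell, sf2, sn2 = 18.0, 0.25, 1e-3
        model = sm.fit_gp(
            (X, y), init=dict(lengthscale=ell, signal_var=sf2, noise_var=sn2),
            optimize_hyper=False,
        )
        Xs = rng.uniform(-40, 40, size=(30, 3))
        pred = sm.gp_predict(model, Xs, clip=None)

        def k(a, b):
            d2 = ((a[:, None] - b[None, :]) ** 2).sum(-1)
            return sf2 * np.exp(-0.5 * d2 / ell**2)

        oracle = y.mean() + k(Xs, X) @ np.linalg.solve(
            k(X, X) + sn2 * np.eye(20), y - y.mean()
        )
        np.testing.assert_allclose(pred.values, oracle, atol=1e-8)

    def test_matches_sklearn_gpr(self):
        sklearn_gp = pytest.importorskip("sklearn.gaussian_process")
        from sklearn.gaussian_process.kernels import RBF, ConstantKernel

        rng = np.random.default_rng(5)
        X = rng.uniform(-30, 30, size=(15, 3))
        y = 0.6 * np.cos(X[:, 0] / 15.0)
        ell, sf2, sn2 = 12.0, 0.3, 1e-4
        model = sm.fit_gp(
            (X, y), init=dict(lengthscale=ell, signal_var=sf2, noise_var=sn2),
            optimize_hyper=False,
        )
        Xs = rng.uniform(-30, 30, size=(10, 3))
        ours = sm.gp_predict(model, Xs, clip=None).values
        gpr = sklearn_gp.GaussianProcessRegressor(
            kernel=ConstantKernel(sf2, "fixed") * RBF(ell, "fixed"),
            alpha=sn2, optimizer=None, normalize_y=False,
        ).fit(X, y - y.mean())
        theirs = y.mean() + gpr.predict(Xs)
        np.testing.assert_allclose(ours, theirs, atol=1e-8)

    def test_midpoint_between_antisymmetric_anchors_is_zero(self):
        X = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        model = sm.fit_gp(
            (X, np.array([1.0, -1.0])),
            init=dict(lengthscale=0.8, signal_var=1.0, noise_var=0.0),
            optimize_hyper=False,
        )
        pred = sm.gp_predict(model, np.array([[0.5, 0.0, 0.0]]), clip=None)
        assert pred.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_posterior_mean_linear_in_training_values(self):
        X, y = self._toy(6)
        init = dict(lengthscale=15.0, signal_var=0.4, noise_var=1e-3)
        Xs = np.random.default_rng(7).uniform(-40, 40, size=(12, 3))
        p1 = sm.gp_predict(sm.fit_gp((X, y), init=init, optimize_hyper=False), Xs, clip=None)
        p2 = sm.gp_predict(sm.fit_gp((X, -y), init=init, optimize_hyper=False), Xs, clip=None)
        np.testing.assert_allclose(p1.values, -p2.values, atol=1e-10)

    def test_noise_free_posterior_stays_within_training_range(self, mesh):
        # with anchors dense at the evaluated vertices and no noise, the
        # posterior interpolates and cannot leave the training range
        idx = np.arange(mesh.n_vertices)
        y = 0.5 * np.sin(mesh.vertices[:, 2] / 150.0)
        model = sm.fit_gp(
            (idx, y), mesh=mesh,
            init=dict(lengthscale=80.0, signal_var=0.3, noise_var=0.0),
            optimize_hyper=False,
        )
        pred = sm.gp_predict(model, mesh, clip=None)
        assert pred.values.min() >= y.min() - 1e-6
        assert pred.values.max() <= y.max() + 1e-6

    def test_single_anchor_rejected(self):
        with pytest.raises(ValueError, match="two anchors"):
            sm.fit_gp((np.zeros((1, 3)), np.array([1.0])), optimize_hyper=False)

    def test_unfitted_model_rejected(self):
        model = sm.GPModel(1.0, 1.0, 0.0, np.zeros((2, 3)), np.zeros(2))
        with pytest.raises(ValueError, match="not been fitted"):
            sm.gp_predict(model, np.zeros((1, 3)))

    def test_static_field_clipped_to_unit_range(self):
        X = np.array([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
        y = np.array([0.99, -0.99, 0.99])
        model = sm.fit_gp(
            (X, y), init=dict(lengthscale=3.0, signal_var=2.0, noise_var=0.0),
            optimize_hyper=False,
        )
        pred = sm.gp_predict(model, np.linspace([0, 0, 0], [10, 0, 0], 50))
        assert pred.values.min() >= -1.0
        assert pred.values.max() <= 1.0


class TestDynamicMap:
    def _field(self, values, qid="q"):
        return sm.IdentityField(np.asarray(values, float), "static", qid)

    def test_identical_fields_give_zero(self):
        f = self._field([0.1, 0.2, 0.3])
        dyn = sm.dynamic_map(f, f)
        np.testing.assert_array_equal(dyn.values, 0.0)
        assert dyn.kind == "dynamic"

    def test_constant_shift(self):
        c = self._field([0.1, 0.2, 0.3], "ctrl")
        p = self._field([0.2, 0.3, 0.4], "pert")
        np.testing.assert_allclose(sm.dynamic_map(p, c).values, 0.1, atol=1e-15)

    def test_mesh_mismatch_rejected(self):
        a = self._field([0.1, 0.2])
        b = self._field([0.1, 0.2, 0.3])
        with pytest.raises(ValueError, match="different meshes"):
            sm.dynamic_map(a, b)

    def test_metric_mismatch_rejected(self):
        a = self._field([0.1, 0.2])
        b = sm.IdentityField(np.array([0.1, 0.2]), "static", "q", metric="spearman")
        with pytest.raises(ValueError, match="metrics"):
            sm.dynamic_map(a, b)


class TestTernary:
    def test_simple_proportions(self):
        tp = sm.ternary_coords([2.0, 1.0, 1.0])
        np.testing.assert_allclose(tp.p, [0.5, 0.25, 0.25])

    def test_degenerate_corner(self):
        tp = sm.ternary_coords([5.0, 0.0, 0.0])
        np.testing.assert_allclose(tp.p, [1.0, 0.0, 0.0])
        np.testing.assert_allclose(tp.to_cartesian(), [0.0, 0.0])

    def test_random_triples_sum_to_one(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            tp = sm.ternary_coords(rng.uniform(0.01, 10.0, size=3))
            assert tp.p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            sm.ternary_coords([0.0, 0.0, 0.0])

    def test_arrow_between_vertices(self):
        origin, endpoint = sm.ternary_arrow([1.0, 0.0, 0.0], [0.0, 1.0, 0.0])
        np.testing.assert_allclose(origin.p, [1, 0, 0])
        np.testing.assert_allclose(endpoint.p, [0, 1, 0])

    def test_zero_length_arrow_for_identical_markers(self):
        o, e = sm.ternary_arrow([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        np.testing.assert_allclose(o.p, e.p, atol=1e-15)

    def test_amnion_shift_moves_toward_amnion_vertex(self, mesh, fields):
        # BMP4-like lambda shift: endpoint closer to the amnion-marker vertex
        cfg0 = SimConfig(seed=31, cells_per_spheroid=300)
        markers = ("SOX2", "TFAP2A", "VTCN1")
        def marker_means(lam, seed):
            cells = simdata.sample_spheroid_cells(
                fields, mesh, "EmDisc_anterior", "Am_distal", lam,
                SimConfig(seed=seed, cells_per_spheroid=300),
            )
            pb = expr_io.pseudo_bulk(expr_io.normalize(cells), "condition")[0]
            return [float(pb.values[g]) for g in markers]
        origin, endpoint = sm.ternary_arrow(
            marker_means(0.0, 31), marker_means(0.8, 32), markers
        )
        am_vertex = np.array([1.0, 0.0])  # cartesian vertex of the 2nd label
        d0 = np.linalg.norm(origin.to_cartesian() - am_vertex)
        d1 = np.linalg.norm(endpoint.to_cartesian() - am_vertex)
        assert d1 < d0


class TestExport:
    def test_field_csv_roundtrip(self, tmp_path):
        fld = sm.IdentityField(np.array([0.1, -0.2, 0.3]), "static", "q")
        path = tmp_path / "field.csv"
        sm.field_to_csv(fld, path)
        df = pd.read_csv(path)
        np.testing.assert_allclose(df["value"].to_numpy(), fld.values)

    def test_field_ply_written_with_colors(self, tmp_path, mesh):
        import trimesh

        rng = np.random.default_rng(10)
        fld = sm.IdentityField(
            rng.uniform(-1, 1, size=mesh.n_vertices), "static", "q"
        )
        path = tmp_path / "field.ply"
        sm.field_to_ply(fld, mesh, path)
        loaded = trimesh.load(str(path), process=False)
        assert len(loaded.vertices) == mesh.n_vertices
        assert loaded.visual.vertex_colors.shape[0] == mesh.n_vertices
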