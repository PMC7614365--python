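"""Seeded validation experiments and independent oracles.

Every routine here recomputes a headline property of the pipeline from
scratch on synthetic data with known ground truth: Gaussian-process oracle
agreement, region recovery of static spatial identity maps, null/signal
behaviour of dynamic maps, lineage-space correctness, stage assignment,
morphometric ground-truth recovery, preprocessing exactness, and the
statistical-test calibrations.  The analysis drivers, the test suite and
the acceptance script all call these functions.

The brute-force oracles (naive per-entry loops, exhaustive rank-sum
enumeration, dense linear solves) are deliberately written independently of
the library code paths they check.
"""

from __future__ import annotations

import itertools
import math
import zlib

import numpy as np
import pandas as pd
from scipy import stats

from . import expr_io, lineage_space, morphometrics, simdata, spatial_map
from .mesh import REGIONS, STAGES, EmbryoMesh, make_embryo_mesh
from .simdata import SimConfig


def derive_seed(master: int, tag: str) -> int:
    """Stable per-stage seed below 2^31 derived from a master seed."""
    return zlib.crc32(f"{master}:{tag}".encode()) & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# shared synthetic world


def build_world(seed: int, n_vertices: int = 400, radius_um: float = 100.0):
    """Mesh + expression fields used by the mapping experiments."""
    mesh = make_embryo_mesh(n_vertices, radius_um, seed=derive_seed(seed, "mesh"))
    fields = simdata.make_expression_fields(mesh, seed=derive_seed(seed, "fields"))
    return mesh, fields


def _query_pseudobulk(fields, mesh, source, target, lam, seed, n_cells=200, name=None):
    cfg = SimConfig(seed=seed, cells_per_spheroid=n_cells)
    cells = simdata.sample_spheroid_cells(
        fields, mesh, source, target, lam, cfg, condition=name or f"{source}|{lam:g}"
    )
    return expr_io.pseudo_bulk(expr_io.normalize(cells), "condition")[0]


def _reference_and_genes(fields, mesh, seed, n_hvg=500):
    ref = simdata.sample_reference_profiles(fields, mesh, cfg=SimConfig(seed=seed))
    hvg = expr_io.select_hvg(expr_io.normalize(ref.counts), n_hvg)
    return ref, hvg


# ---------------------------------------------------------------------------
# 1. GP oracle equivalence


def gp_oracle_check(seed: int = 0, n_anchors: int = 20) -> dict:
    """Posterior mean vs an independent dense solve, and noise-free
    interpolation of training values, on a small toy anchor set."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(-50.0, 50.0, size=(n_anchors, 3))
    y = 0.8 * np.tanh(X[:, 0] / 30.0) * np.cos(X[:, 1] / 40.0)
    ell, sf2, sn2 = 25.0, 0.4, 1e-3

    model = spatial_map.fit_gp(
        (X, y),
        init=dict(lengthscale=ell, signal_var=sf2, noise_var=sn2),
        optimize_hyper=False,
    )
    Xs = rng.uniform(-50.0, 50.0, size=(40, 3))
    fld = spatial_map.gp_predict(model, Xs, clip=None)

    # independent dense-solve oracle: mean + k*^T (K + sn2 I)^-1 (y - mean)
    def k(a, b):
        d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)
        return sf2 * np.exp(-0.5 * d2 / ell**2)

    oracle = y.mean() + k(Xs, X) @ np.linalg.solve(
        k(X, X) + sn2 * np.eye(n_anchors), y - y.mean()
    )
    posterior_err = float(np.abs(fld.values - oracle).max())

    noise_free = spatial_map.fit_gp(
        (X, y),
        init=dict(lengthscale=ell, signal_var=sf2, noise_var=0.0),
        optimize_hyper=False,
    )
    interp = spatial_map.gp_predict(noise_free, X, clip=None)
    interp_err = float(np.abs(interp.values - y).max())

    lml, _ = spatial_map.log_marginal_likelihood(X, y - y.mean(), ell, sf2, sn2)
    K = k(X, X) + sn2 * np.eye(n_anchors)
    yc = y - y.mean()
    sign, logdet = np.linalg.slogdet(K)
    lml_oracle = -0.5 * yc @ np.linalg.solve(K, yc) - 0.5 * logdet - 0.5 * n_anchors * np.log(
        2 * np.pi
    )
    return {
        "posterior_mean_max_error": posterior_err,
        "interpolation_max_error": interp_err,
        "lml_error": float(abs(lml - lml_oracle)),
    }


def gp_lengthscale_recovery(
    n_runs: int = 100, n_anchors: int = 200, seed: int = 0, rtol: float = 0.25
) -> dict:
    """Hyperparameter optimisation recovers a known length-scale."""
    ell_true, sf2_true, sn2_true = 20.0, 0.5, 1e-3
    hits = 0
    for run in range(n_runs):
        rng = np.random.default_rng(derive_seed(seed, f"gplen{run}"))
        X = rng.uniform(-60.0, 60.0, size=(n_anchors, 3))
        d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
        K = sf2_true * np.exp(-0.5 * d2 / ell_true**2) + sn2_true * np.eye(n_anchors)
        y = np.linalg.cholesky(K + 1e-10 * np.eye(n_anchors)) @ rng.standard_normal(
            n_anchors
        )
        model = spatial_map.fit_gp(
            (X, y),
            optimize_hyper=True,
            n_starts=3,
            seed=derive_seed(seed, f"gpstart{run}"),
            bounds={"lengthscale": (2.0, 200.0)},
        )
        if abs(model.lengthscale - ell_true) <= rtol * ell_true:
            hits += 1
    return {"hits": hits, "n_runs": n_runs}


# ---------------------------------------------------------------------------
# 2. region recovery


def region_recovery(
    n_runs: int = 100, seed: int = 0, n_vertices: int = 400, n_cells: int = 200
) -> pd.DataFrame:
    """Static maps of single-region archetype queries: does the field argmax
    land inside the generating region?

    The similarity gene set is CCA-selected between the reference profiles
    and the run's four query pseudo-bulks (the default gene-set mode).
    """
    mesh, fields = build_world(seed, n_vertices)
    rows = []
    for run in range(n_runs):
        ref = simdata.sample_reference_profiles(
            fields, mesh, cfg=SimConfig(seed=derive_seed(seed, f"ref{run}"))
        )
        pbs = {
            region: _query_pseudobulk(
                fields, mesh, region, region, 0.0,
                derive_seed(seed, f"query{run}:{region}"), n_cells=n_cells,
            )
            for region in REGIONS
        }
        genes, _ = lineage_space.cca_select_genes(
            ref.profiles, list(pbs.values()), n_components=2, top_k=300
        )
        for region, pb in pbs.items():
            fld = spatial_map.static_map(pb, ref, genes, seed=derive_seed(seed, "gp"))
            hit = mesh.region_labels[fld.argmax_vertex()] == region
            rows.append({"run": run, "region": region, "hit": bool(hit)})
    df = pd.DataFrame(rows)
    return df.groupby("region", sort=False)["hit"].agg(hits="sum", n="count").reset_index()


# ---------------------------------------------------------------------------
# 3. dynamic maps: null and signal


def dynamic_null(n_pairs: int = 20, seed: int = 0, n_vertices: int = 400) -> dict:
    """Control-vs-control dynamic maps: mean |delta| against the replicate
    Monte-Carlo standard error of the static field."""
    mesh, fields = build_world(seed, n_vertices)
    ref, hvg = _reference_and_genes(fields, mesh, derive_seed(seed, "nullref"))
    fields_static = []
    deltas = []
    for pair in range(n_pairs):
        maps = []
        for rep in range(2):
            pb = _query_pseudobulk(
                fields, mesh, "EmDisc_anterior", "EmDisc_anterior", 0.0,
                derive_seed(seed, f"null{pair}:{rep}"),
            )
            maps.append(spatial_map.static_map(pb, ref, hvg, seed=derive_seed(seed, "gp")))
        fields_static.extend(maps)
        dyn = spatial_map.dynamic_map(maps[1], maps[0])
        deltas.append(np.abs(dyn.values).mean())
    stack = np.array([f.values for f in fields_static])
    mc_se = float(stack.std(axis=0, ddof=1).mean())
    return {
        "mean_abs_delta": float(np.mean(deltas)),
        "mc_se": mc_se,
        "ratio": float(np.mean(deltas) / mc_se),
    }


def dynamic_signal(
    n_runs: int = 100,
    lam: float = 0.8,
    seed: int = 0,
    n_vertices: int = 400,
    source: str = "EmDisc_anterior",
    target: str = "Am_distal",
) -> dict:
    """A lambda-shift toward the amnion archetype must raise identity over
    amnion vertices and lower it over embryonic-disc vertices."""
    mesh, fields = build_world(seed, n_vertices)
    ref, hvg = _reference_and_genes(fields, mesh, derive_seed(seed, "sigref"))
    am_mask = np.isin(mesh.region_labels, ["Am_proximal", "Am_distal"])
    ed_mask = ~am_mask
    hits = 0
    for run in range(n_runs):
        ctrl = spatial_map.static_map(
            _query_pseudobulk(
                fields, mesh, source, target, 0.0, derive_seed(seed, f"sc{run}")
            ),
            ref, hvg, seed=derive_seed(seed, "gp"),
        )
        pert = spatial_map.static_map(
            _query_pseudobulk(
                fields, mesh, source, target, lam, derive_seed(seed, f"sp{run}")
            ),
            ref, hvg, seed=derive_seed(seed, "gp"),
        )
        dyn = spatial_map.dynamic_map(pert, ctrl)
        if dyn.values[am_mask].mean() > 0 and dyn.values[ed_mask].mean() < 0:
            hits += 1
    return {"hits": hits, "n_runs": n_runs, "lam": lam}


# ---------------------------------------------------------------------------
# 4. lineage space


def lineage_sweep(
    seed: int = 0,
    lams=None,
    n_vertices: int = 400,
    source: str = "EmDisc_anterior",
    target: str = "Am_distal",
) -> dict:
    """Lambda-swept pseudo-bulks projected into the in-vivo lineage space:
    decision values must decrease and cross the boundary exactly once."""
    lams = np.linspace(0.0, 1.0, 11) if lams is None else np.asarray(lams)
    mesh, fields = build_world(seed, n_vertices)
    ref, _ = _reference_and_genes(fields, mesh, derive_seed(seed, "lsref"))
    vivo = ref.profiles
    labels = [
        lineage_space.EMDISC if l.startswith("EmDisc") else lineage_space.AM
        for l in ref.lineage
    ]
    # common random numbers across the sweep: one seed for every lambda so
    # sampling noise is shared and the sweep isolates the lambda effect
    sweep_seed = derive_seed(seed, "sweep")
    vitro = [
        _query_pseudobulk(fields, mesh, source, target, l, sweep_seed, name=f"lam{l:.2f}")
        for l in lams
    ]
    genes, cca = lineage_space.cca_select_genes(vivo, vitro, n_components=2, top_k=300)
    adj = lineage_space.adjust_profiles({"vivo": vivo, "vitro": vitro})
    model = lineage_space.fit_pca(adj["vivo"] + adj["vitro"], genes, n_pcs=2)
    scores = np.array([lineage_space.project(p, model) for p in adj["vivo"]])
    lineage_space.attach_boundary(model, scores, labels)
    train_pred = [
        lineage_space.EMDISC if lineage_space.decision_value(s, model) > 0
        else lineage_space.AM
        for s in scores
    ]
    accuracy = float(np.mean([p == l for p, l in zip(train_pred, labels)]))
    ds = np.array(
        [lineage_space.decision_value(lineage_space.project(p, model), model) for p in adj["vitro"]]
    )
    crossings = int((np.diff(np.sign(ds)) != 0).sum())
    return {
        "lams": lams,
        "decision_values": ds,
        "crossings": crossings,
        "monotone": bool(np.all(np.diff(ds) < 0)),
        "training_accuracy": accuracy,
        "rho": cca.correlations,
        "model": model,
    }


def cca_svd_oracle(seed: int = 0, n_genes: int = 500, n_profiles: int = 10) -> dict:
    """Implementation canonical correlations vs an explicit matrix-square-root
    whitened-cross-covariance SVD on independent random datasets."""
    rng = np.random.default_rng(seed)
    genes = [f"G{i:03d}" for i in range(n_genes)]

    def make(n, tag):
        M = rng.normal(2.0, 1.0, size=(n_genes, n))
        return [
            expr_io.PseudoBulkProfile(f"{tag}{j}", pd.Series(M[:, j], index=genes), 1)
            for j in range(n)
        ]

    A, B = make(n_profiles, "a"), make(n_profiles, "b")
    _, res = lineage_space.cca_select_genes(A, B, n_components=3, top_k=n_genes)

    # oracle: eigendecomposition square roots, same ridge
    X = np.column_stack([p.values.to_numpy() for p in A])
    Y = np.column_stack([p.values.to_numpy() for p in B])
    for M in (X, Y):
        M -= M.mean(axis=1, keepdims=True)
        M /= M.std(axis=1, ddof=1, keepdims=True)
    g = n_genes
    Sxx = X.T @ X / (g - 1) + 1e-3 * np.eye(n_profiles)
    Syy = Y.T @ Y / (g - 1) + 1e-3 * np.eye(n_profiles)
    Sxy = X.T @ Y / (g - 1)

    def inv_sqrt(S):
        w, V = np.linalg.eigh(S)
        return V @ np.diag(1.0 / np.sqrt(w)) @ V.T

    sv = np.linalg.svd(inv_sqrt(Sxx) @ Sxy @ inv_sqrt(Syy), compute_uv=False)
    return {
        "rho": res.correlations,
        "rho_oracle": sv[:3],
        "max_error": float(np.abs(res.correlations - sv[:3]).max()),
    }


def svm_qp_oracle(seed: int = 0, n_points: int = 20, C: float = 1.0) -> dict:
    """Linear SVM (w, b) vs a generic quadratic program on the dual."""
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [rng.normal([-1.5, 0.0], 0.8, size=(n_points // 2, 2)),
         rng.normal([1.5, 0.0], 0.8, size=(n_points - n_points // 2, 2))]
    )
    y = np.array([-1.0] * (n_points // 2) + [1.0] * (n_points - n_points // 2))
    labels = [lineage_space.AM if v < 0 else lineage_space.EMDISC for v in y]
    w, b = lineage_space.fit_decision_boundary(X, labels, C=C)

    # dual QP: max sum a - 1/2 a^T Q a, 0 <= a <= C, sum a_i y_i = 0
    from scipy import optimize as opt

    Q = (y[:, None] * y[None, :]) * (X @ X.T)

    def neg_dual(a):
        return 0.5 * a @ Q @ a - a.sum()

    def grad(a):
        return Q @ a - np.ones_like(a)

    cons = {"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}
    res = opt.minimize(
        neg_dual,
        np.full(n_points, min(C, 1.0) * 0.5),
        jac=grad,
        bounds=[(0.0, C)] * n_points,
        constraints=[cons],
        method="SLSQP",
        options={"maxiter": 2000, "ftol": 1e-16},
    )
    a = res.x
    w_qp = (a * y) @ X
    sv = (a > 1e-6) & (a < C - 1e-6)
    b_qp = float(np.mean(y[sv] - X[sv] @ w_qp)) if sv.any() else float(
        np.mean(y - X @ w_qp)
    )
    return {
        "w": w,
        "b": b,
        "w_qp": w_qp,
        "b_qp": b_qp,
        "max_error": float(max(np.abs(w - w_qp).max(), abs(b - b_qp))),
    }


def stage_recovery(n_runs: int = 100, seed: int = 0, n_vertices: int = 400) -> dict:
    """Global correlation recovers the generating Carnegie stage."""
    mesh, _ = build_world(seed, n_vertices)
    series = simdata.make_stage_series(mesh, SimConfig(seed=derive_seed(seed, "stage")))
    refs = []
    for stage in STAGES:
        cfg = SimConfig(seed=derive_seed(seed, f"ref{stage}"), cells_per_spheroid=100)
        cells = simdata.sample_spheroid_cells(
            series[stage], mesh, "EmDisc_anterior", "EmDisc_anterior", 0.0, cfg,
            condition=stage,
        )
        refs.append(expr_io.pseudo_bulk(expr_io.normalize(cells), "condition")[0])
    hits = 0
    for run in range(n_runs):
        true_stage = STAGES[run % len(STAGES)]
        pb = _query_pseudobulk(
            series[true_stage], mesh, "EmDisc_anterior", "EmDisc_anterior", 0.0,
            derive_seed(seed, f"sq{run}"), n_cells=100,
        )
        called, _ = lineage_space.assign_stage(pb, refs)
        hits += called == true_stage
    return {"hits": hits, "n_runs": n_runs}


# ---------------------------------------------------------------------------
# 5. statistical-test oracles


def exact_mannwhitney_p(a, b) -> float:
    """Exhaustive two-sided rank-sum p-value by enumerating all assignments
    of the pooled values to the two groups (no ties assumed)."""
    a, b = list(a), list(b)
    pooled = a + b
    na = len(a)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:na].sum() - na * (na + 1) / 2.0
    n = len(pooled)
    mid = na * len(b) / 2.0
    count = 0
    total = 0
    for comb in itertools.combinations(range(n), na):
        u = ranks[list(comb)].sum() - na * (na + 1) / 2.0
        if abs(u - mid) >= abs(u_obs - mid) - 1e-12:
            count += 1
        total += 1
    return count / total


def mannwhitney_enumeration_check(max_n: int = 5, seed: int = 0) -> dict:
    """Max |p_impl - p_enumeration| over random ties-free group pairs."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for na in range(2, max_n + 1):
        for nb in range(2, max_n + 1):
            vals = rng.permutation(np.arange(1.0, na + nb + 1))
            a, b = vals[:na], vals[na:]
            res = morphometrics.compare_groups({"a": a, "b": b}, "mann_whitney")
            worst = max(worst, abs(res.p_value - exact_mannwhitney_p(a, b)))
    return {"max_error": worst}


def shapiro_calibration(
    n_reps: int = 10000, n: int = 50, alpha: float = 0.05, seed: int = 0
) -> dict:
    """Type-I error rate of the Shapiro-Wilk test on normal samples."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        res = morphometrics.compare_groups(
            {"g": rng.standard_normal(n)}, "shapiro_wilk"
        )
        rejections += res.p_value < alpha
    return {"rejection_rate": rejections / n_reps, "n_reps": n_reps}


# ---------------------------------------------------------------------------
# 6. morphometrics ground-truth recovery


def morpho_recovery(seed: int = 0) -> dict:
    """Orientation, thickness and intensity recovery on synthetic stacks."""
    out = {}
    for kind in ("epi", "am"):
        stack = simdata.make_spheroid_stack(kind, seed=derive_seed(seed, kind))
        morphs = morphometrics.nuclear_orientation(stack)
        truth = stack.truth["angle_deg"]
        errs = [abs(m.angle_deg - truth.loc[m.nucleus_id]) for m in morphs]
        thickness = morphometrics.epithelial_thickness(stack)
        total = morphometrics.spheroid_intensity(stack, stack.channel_names[1])
        # voxel-loop oracle for the summed intensity (slice-wise accumulation)
        ch = stack.channel(stack.channel_names[1])
        mask = stack.labels > 0
        oracle = 0.0
        for z in range(ch.shape[0]):
            oracle += float(ch[z][mask[z]].astype(np.float64).sum())
        out[kind] = {
            "max_angle_error_deg": float(max(errs)),
            "median_angle_deg": float(np.median([m.angle_deg for m in morphs])),
            "thickness_um": float(np.mean(thickness)),
            "thickness_truth_um": stack.truth_thickness_um,
            "thickness_error_um": float(
                abs(np.mean(thickness) - stack.truth_thickness_um)
            ),
            "voxel_um": float(min(stack.voxel_size_um)),
            "intensity_sum_rel_error": float(abs(total - oracle) / oracle),
        }
    out["thickness_ratio"] = out["epi"]["thickness_um"] / out["am"]["thickness_um"]
    return out


# ---------------------------------------------------------------------------
# 7. preprocessing exactness


def preprocessing_oracle_check(seed: int = 0, n_genes: int = 30, n_cells: int = 12) -> dict:
    """Normalization, HVG, pseudo-bulk, z-scores and BH vs naive loops."""
    rng = np.random.default_rng(seed)
    import anndata as ad

    X = rng.poisson(5.0, size=(n_cells, n_genes)) + 1  # keep totals positive
    genes = [f"g{i:02d}" for i in range(n_genes)]
    cells = [f"c{i:02d}" for i in range(n_cells)]
    adata = ad.AnnData(
        X=X.astype(np.int64),
        obs=pd.DataFrame(
            {"condition": ["A", "B", "C"] * (n_cells // 3)}, index=cells
        ),
        var=pd.DataFrame(index=genes),
    )
    norm = expr_io.normalize(adata)
    L = np.asarray(norm.layers["lognorm"])

    norm_err = 0.0
    for c in range(n_cells):
        tot = X[c].sum()
        for g in range(n_genes):
            norm_err = max(norm_err, abs(L[c, g] - math.log(1 + X[c, g] * 1e4 / tot)))

    k = 7
    hvg = expr_io.select_hvg(norm, k)
    variances = [float(np.var(L[:, g], ddof=1)) for g in range(n_genes)]
    order = sorted(range(n_genes), key=lambda g: (-variances[g], g))
    hvg_match = hvg == [genes[i] for i in order[:k]]

    profiles = expr_io.pseudo_bulk(norm, "condition")
    pb_err = 0.0
    for p in profiles:
        members = [i for i, c in enumerate(norm.obs["condition"]) if c == p.name]
        for g in range(n_genes):
            manual = sum(L[i, g] for i in members) / len(members)
            pb_err = max(pb_err, abs(p.values.iloc[g] - manual))

    z = expr_io.zscore_by_gene(profiles)
    z_err = 0.0
    for g in range(n_genes):
        vals = [p.values.iloc[g] for p in profiles]
        mu = sum(vals) / len(vals)
        sd = math.sqrt(sum((v - mu) ** 2 for v in vals) / (len(vals) - 1))
        for j, p in enumerate(profiles):
            expected = 0.0 if sd == 0 else (vals[j] - mu) / sd
            z_err = max(z_err, abs(z.iloc[g, j] - expected))

    pvals = rng.uniform(size=50)
    from statsmodels.stats.multitest import multipletests

    q_impl = multipletests(pvals, method="fdr_bh")[1]
    # naive BH: step-up with cumulative minimum from the largest p
    order_p = np.argsort(pvals)
    q_manual = np.empty_like(pvals)
    prev = 1.0
    for rank in range(len(pvals), 0, -1):
        i = order_p[rank - 1]
        prev = min(prev, pvals[i] * len(pvals) / rank)
        q_manual[i] = prev
    bh_err = float(np.abs(q_impl - q_manual).max())

    return {
        "normalize_max_error": norm_err,
        "hvg_match": bool(hvg_match),
        "pseudobulk_max_error": float(pb_err),
        "zscore_max_error": float(z_err),
        "bh_max_error": bh_err,
    }
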