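"""Spatial identity mapping onto the embryo surface.

Static mapping: the Pearson correlation between a query pseudo-bulk and
each spatially anchored reference sample is attached to the sample's anchor
vertex and interpolated to every mesh vertex by Gaussian-process regression
with a squared-exponential kernel on 3D vertex coordinates,

    k(u, v) = sigma_f^2 * exp(-||x_u - x_v||^2 / (2 * ell^2)),

optionally maximising the log marginal likelihood over (ell, sigma_f^2,
sigma_n^2).  Dynamic mapping is the signed per-vertex difference between a
perturbed and a control static field, highlighting the embryonic region
whose identity the perturbation shifts.  Ternary coordinates summarise
three-marker proportions with perturbation arrows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .expr_io import PseudoBulkProfile, pseudo_bulk, normalize
from .mesh import REGIONS, EmbryoMesh

JITTER_START = 1e-8
JITTER_MAX = 1e-4


@dataclass
class SpatialReference:
    """Embryo mesh plus anchored reference expression profiles."""

    mesh: EmbryoMesh
    anchor_idx: np.ndarray
    lineage: np.ndarray
    stage: np.ndarray
    profiles: list  # PseudoBulkProfile per sample (normalized scale)
    counts: ad.AnnData | None = None

    def __post_init__(self) -> None:
        self.anchor_idx = np.asarray(self.anchor_idx, int)
        if len(self.anchor_idx) != len(self.profiles):
            raise ValueError("one anchor per reference profile required")
        if self.anchor_idx.size and (
            self.anchor_idx.min() < 0 or self.anchor_idx.max() >= self.mesh.n_vertices
        ):
            raise ValueError("anchor indices outside the mesh")
        if len(np.unique(self.anchor_idx)) < 2:
            raise ValueError("need at least two distinct anchor vertices")
        genes = set(self.profiles[0].genes)
        for p in self.profiles[1:]:
            if set(p.genes) != genes:
                raise ValueError("all reference profiles must share one gene universe")

    @classmethod
    def from_counts(cls, mesh: EmbryoMesh, adata: ad.AnnData) -> "SpatialReference":
        """Build from a samples x genes count AnnData with ``anchor_vertex``,
        ``lineage`` and ``stage`` obs columns; counts are CP10K-log1p
        normalized and each sample becomes one profile."""
        norm = normalize(adata)
        L = np.asarray(norm.layers["lognorm"])
        profiles = [
            PseudoBulkProfile(
                name=str(norm.obs_names[i]),
                values=pd.Series(L[i], index=norm.var_names),
                n_cells=1,
                group_key="sample",
            )
            for i in range(norm.n_obs)
        ]
        return cls(
            mesh=mesh,
            anchor_idx=norm.obs["anchor_vertex"].to_numpy(int),
            lineage=norm.obs["lineage"].to_numpy(object),
            stage=norm.obs["stage"].to_numpy(object),
            profiles=profiles,
            counts=adata,
        )

    @property
    def gene_universe(self) -> pd.Index:
        return self.profiles[0].genes


@dataclass
class GPModel:
    """Fitted squared-exponential GP on anchor coordinates."""

    lengthscale: float
    signal_var: float
    noise_var: float
    X: np.ndarray  # (n, 3) anchor coordinates
    y: np.ndarray  # training values (original scale)
    y_mean: float = 0.0
    _chol: np.ndarray | None = field(default=None, repr=False)
    _alpha: np.ndarray | None = field(default=None, repr=False)
    log_marginal_likelihood: float | None = None

    def __post_init__(self) -> None:
        if self.lengthscale <= 0 or self.signal_var <= 0 or self.noise_var < 0:
            raise ValueError("require ell > 0, sigma_f^2 > 0, sigma_n^2 >= 0")

    @property
    def is_fitted(self) -> bool:
        return self._alpha is not None


@dataclass
class IdentityField:
    """Per-vertex scalar identity field (static correlation or dynamic delta)."""

    values: np.ndarray
    kind: str  # static | dynamic
    query_id: str
    metric: str = "pearson"
    gp_params: dict = field(default_factory=dict)
    posterior_sd: np.ndarray | None = None
    mesh_hash: str = ""
    clipped: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        lim = 1.0 if self.kind == "static" else 2.0
        if np.any(np.abs(self.values) > lim + 1e-9):
            raise ValueError(f"{self.kind} field values exceed [-{lim}, {lim}]")

    def region_means(self, mesh: EmbryoMesh) -> dict:
        return {r: float(self.values[mesh.region_mask(r)].mean()) for r in REGIONS}

    def argmax_vertex(self) -> int:
        return int(np.argmax(self.values))

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"vertex_id": np.arange(len(self.values)), "value": self.values})
        if self.posterior_sd is not None:
            out["posterior_sd"] = self.posterior_sd
        return out


# ---------------------------------------------------------------------------
# similarity


def pearson_similarity(
    query: PseudoBulkProfile,
    reference: PseudoBulkProfile,
    gene_set,
    method: str = "pearson",
) -> float:
    """Sample correlation between two profiles on a gene set (in [-1, 1])."""
    genes = list(gene_set)
    q = query.values.reindex(genes).to_numpy()
    r = reference.values.reindex(genes).to_numpy()
    if np.isnan(q).any():
        raise ValueError(f"query profile {query.name!r} lacks some gene_set genes")
    if np.isnan(r).any():
        raise ValueError(f"reference profile {reference.name!r} lacks some gene_set genes")
    if np.std(q) == 0:
        raise ValueError(f"profile {query.name!r} is constant on the gene set")
    if np.std(r) == 0:
        raise ValueError(f"profile {reference.name!r} is constant on the gene set")
    if method == "pearson":
        return float(stats.pearsonr(q, r).statistic)
    if method == "spearman":
        return float(stats.spearmanr(q, r).statistic)
    raise ValueError(f"unknown similarity method {method!r}")


def project_similarity(
    query: PseudoBulkProfile,
    reference: SpatialReference,
    gene_set,
    method: str = "pearson",
) -> tuple:
    """Correlations attached to anchor vertices (duplicates averaged).

    Returns (vertex_indices, values) with one entry per distinct anchor.
    """
    if not reference.profiles:
        raise ValueError("empty spatial reference")
    rs = np.array(
        [pearson_similarity(query, p, gene_set, method) for p in reference.profiles]
    )
    df = pd.DataFrame({"vertex": reference.anchor_idx, "r": rs})
    agg = df.groupby("vertex", sort=True)["r"].mean()
    return agg.index.to_numpy(), agg.to_numpy()


# ---------------------------------------------------------------------------
# Gaussian process regression


def _sq_dists(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    return ((A[:, None, :] - B[None, :, :]) ** 2).sum(-1)


def _chol_with_jitter(K: np.ndarray):
    jitter = 0.0
    while True:
        try:
            return linalg.cholesky(K + jitter * np.eye(len(K)), lower=True), jitter
        except linalg.LinAlgError:
            jitter = JITTER_START if jitter == 0.0 else jitter * 10.0
            if jitter > JITTER_MAX:
                raise linalg.LinAlgError(
                    "kernel matrix not positive definite even with jitter "
                    f"{JITTER_MAX:g}"
                ) from None


def log_marginal_likelihood(
    anchors: np.ndarray, y_centered: np.ndarray, ell: float, sf2: float, sn2: float
):
    """LML and its gradient with respect to (log ell, log sf2, log sn2)."""
    n = len(y_centered)
    D2 = _sq_dists(anchors, anchors)
    Kf = sf2 * np.exp(-0.5 * D2 / ell**2)
    K = Kf + sn2 * np.eye(n)
    L, _ = _chol_with_jitter(K)
    alpha = linalg.cho_solve((L, True), y_centered)
    lml = (
        -0.5 * y_centered @ alpha
        - np.log(np.diag(L)).sum()
        - 0.5 * n * np.log(2 * np.pi)
    )
    Kinv = linalg.cho_solve((L, True), np.eye(n))
    W = np.outer(alpha, alpha) - Kinv
    dK_dlogell = Kf * (D2 / ell**2)
    grad = np.array(
        [
            0.5 * np.sum(W * dK_dlogell),
            0.5 * np.sum(W * Kf),
            0.5 * np.sum(np.diag(W)) * sn2,
        ]
    )
    return float(lml), grad


def fit_gp(
    anchored: tuple,
    mesh: EmbryoMesh | None = None,
    init: dict | None = None,
    optimize_hyper: bool = True,
    n_starts: int = 5,
    seed: int = 0,
    bounds: dict | None = None,
) -> GPModel:
    """Fit the squared-exponential GP to anchored values.

    ``anchored`` is either ``(vertex_indices, values)`` with a mesh, or
    ``(coordinates, values)`` with coordinates of shape (n, d).  Training
    values are mean-centered internally (so a constant field is reproduced
    exactly).  When ``optimize_hyper``, hyperparameters maximise the log
    marginal likelihood by multi-start L-BFGS-B on log-parameters, with the
    length-scale bounded between the mesh mean edge length and the mesh
    diameter.
    """
    locs, values = anchored
    values = np.asarray(values, float)
    locs = np.asarray(locs)
    if locs.ndim == 1:
        if mesh is None:
            raise ValueError("vertex-index anchors require a mesh")
        X = mesh.vertices[locs.astype(int)]
    else:
        X = locs.astype(float)
    if len(X) < 2:
        raise ValueError("need at least two anchors")
    y_mean = float(values.mean())
    yc = values - y_mean

    extent = float(np.linalg.norm(X.max(0) - X.min(0))) or 1.0
    lo_ell = float(np.mean(mesh.edge_lengths)) if mesh is not None else 0.01 * extent
    hi_ell = mesh.diameter if mesh is not None else extent
    var_y = float(yc.var()) or 1e-4
    defaults = dict(lengthscale=0.3 * hi_ell, signal_var=var_y, noise_var=0.1 * var_y + 1e-6)
    if init:
        defaults.update(init)
    if bounds is None:
        bounds = {}
    b_ell = bounds.get("lengthscale", (lo_ell, hi_ell))
    b_sf2 = bounds.get("signal_var", (1e-8, 1e4))
    b_sn2 = bounds.get("noise_var", (1e-6, 1e2))

    ell, sf2, sn2 = defaults["lengthscale"], defaults["signal_var"], defaults["noise_var"]
    if optimize_hyper:
        log_bounds = [tuple(np.log(b)) for b in (b_ell, b_sf2, b_sn2)]

        def objective(theta):
            l_, s_, n_ = np.exp(theta)
            lml, grad = log_marginal_likelihood(X, yc, l_, s_, n_)
            return -lml, -grad

        rng = np.random.default_rng(seed)
        starts = [np.log([np.clip(ell, *b_ell), np.clip(sf2, *b_sf2), np.clip(sn2, *b_sn2)])]
        for _ in range(max(n_starts - 1, 0)):
            starts.append(np.array([rng.uniform(*lb) for lb in log_bounds]))
        best = None
        for x0 in starts:
            res = optimize.minimize(
                objective, x0, jac=True, method="L-BFGS-B", bounds=log_bounds
            )
            if best is None or res.fun < best.fun:
                best = res
        ell, sf2, sn2 = np.exp(best.x)

    D2 = _sq_dists(X, X)
    K = sf2 * np.exp(-0.5 * D2 / ell**2) + sn2 * np.eye(len(X))
    L, jitter = _chol_with_jitter(K)
    alpha = linalg.cho_solve((L, True), yc)
    lml = float(
        -0.5 * yc @ alpha - np.log(np.diag(L)).sum() - 0.5 * len(yc) * np.log(2 * np.pi)
    )
    return GPModel(
        lengthscale=float(ell),
        signal_var=float(sf2),
        noise_var=float(sn2),
        X=X,
        y=values,
        y_mean=y_mean,
        _chol=L,
        _alpha=alpha,
        log_marginal_likelihood=lml,
    )


def gp_predict(
    model: GPModel,
    mesh: EmbryoMesh | np.ndarray,
    query_id: str = "query",
    metric: str = "pearson",
    clip: tuple | None = (-1.0, 1.0),
    return_sd: bool = False,
) -> IdentityField:
    """Posterior mean (optionally sd) at every mesh vertex as a static field."""
    if not model.is_fitted:
        raise ValueError("GP model has not been fitted")
    Xs = mesh.vertices if isinstance(mesh, EmbryoMesh) else np.asarray(mesh, float)
    Ks = model.signal_var * np.exp(
        -0.5 * _sq_dists(Xs, model.X) / model.lengthscale**2
    )
    mean = model.y_mean + Ks @ model._alpha
    sd = None
    if return_sd:
        v = linalg.solve_triangular(model._chol, Ks.T, lower=True)
        var = np.clip(model.signal_var - (v**2).sum(axis=0), 0.0, None)
        sd = np.sqrt(var)
    clipped = False
    if clip is not None:
        clipped = bool((mean < clip[0]).any() or (mean > clip[1]).any())
        mean = np.clip(mean, clip[0], clip[1])
    mesh_hash = mesh.content_hash() if isinstance(mesh, EmbryoMesh) else ""
    return IdentityField(
        values=mean,
        kind="static",
        query_id=query_id,
        metric=metric,
        gp_params=dict(
            lengthscale=model.lengthscale,
            signal_var=model.signal_var,
            noise_var=model.noise_var,
        ),
        posterior_sd=sd,
        mesh_hash=mesh_hash,
        clipped=clipped,
    )


def static_map(
    query: PseudoBulkProfile,
    reference: SpatialReference,
    gene_set,
    method: str = "pearson",
    optimize_hyper: bool = True,
    init: dict | None = None,
    seed: int = 0,
    return_sd: bool = False,
) -> IdentityField:
    """Static spatial identity mapping: correlate, anchor, interpolate."""
    anchored = project_similarity(query, reference, gene_set, method)
    gp = fit_gp(
        anchored, mesh=reference.mesh, init=init, optimize_hyper=optimize_hyper, seed=seed
    )
    return gp_predict(
        gp, reference.mesh, query_id=query.name, metric=method, return_sd=return_sd
    )


def dynamic_map(perturbed: IdentityField, control: IdentityField) -> IdentityField:
    """Signed per-vertex identity change (perturbed - control)."""
    if perturbed.kind != "static" or control.kind != "static":
        raise ValueError("dynamic maps are differences of two static fields")
    if perturbed.values.shape != control.values.shape or (
        perturbed.mesh_hash != control.mesh_hash
    ):
        raise ValueError("static fields live on different meshes")
    if perturbed.metric != control.metric:
        raise ValueError("static fields use different similarity metrics")
    return IdentityField(
        values=perturbed.values - control.values,
        kind="dynamic",
        query_id=f"{perturbed.query_id} - {control.query_id}",
        metric=perturbed.metric,
        gp_params={"perturbed": perturbed.gp_params, "control": control.gp_params},
        mesh_hash=perturbed.mesh_hash,
    )


# ---------------------------------------------------------------------------
# ternary marker coordinates

_TERNARY_VERTICES = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3.0) / 2.0]])


@dataclass
class TernaryPoint:
    """Barycentric proportions of three marker levels (sum to 1)."""

    labels: tuple
    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, float)
        if self.p.shape != (3,) or (self.p < -1e-12).any():
            raise ValueError("barycentric coordinates must be 3 non-negative values")
        if abs(self.p.sum() - 1.0) > 1e-12:
            raise ValueError("barycentric coordinates must sum to 1")

    def to_cartesian(self) -> np.ndarray:
        return self.p @ _TERNARY_VERTICES


def ternary_coords(marker_means, labels=("EmDisc", "Am", "Am_mature")) -> TernaryPoint:
    """Proportional marker levels as a point in the ternary simplex."""
    m = np.asarray(marker_means, float)
    if m.shape != (3,):
        raise ValueError("exactly three marker means required")
    if (m < 0).any():
        raise ValueError("marker means must be non-negative")
    total = m.sum()
    if total <= 0:
        raise ValueError("all marker means are zero; ternary point undefined")
    return TernaryPoint(tuple(labels), m / total)


def ternary_arrow(
    control_means, perturbed_means, labels=("EmDisc", "Am", "Am_mature")
) -> tuple:
    """Arrow from control marker proportions to perturbed proportions."""
    return (
        ternary_coords(control_means, labels),
        ternary_coords(perturbed_means, labels),
    )


# ---------------------------------------------------------------------------
# export


def field_to_csv(fld: IdentityField, path) -> None:
    fld.to_frame().to_csv(path, index=False)


def field_to_ply(
    fld: IdentityField, mesh: EmbryoMesh, path, cmap: str = "coolwarm"
) -> None:
    """Colored PLY of the field: static on [-1, 1], dynamic symmetric about 0."""
    import matplotlib
    import trimesh
    from matplotlib import colors

    if fld.kind == "static":
        norm = colors.Normalize(vmin=-1.0, vmax=1.0)
    else:
        a = max(float(np.abs(fld.values).max()), 1e-12)
        norm = colors.Normalize(vmin=-a, vmax=a)
    rgba = matplotlib.colormaps[cmap](norm(fld.values))
    m = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
    m.visual.vertex_colors = (rgba * 255).astype(np.uint8)
    data = m.export(file_type="ply", encoding="ascii")
    if isinstance(data, str):
        data = data.encode()
    with open(path, "wb") as fh:
        fh.write(data)
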