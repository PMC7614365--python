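"""The embryonic-disc vs amnion lineage coordinate system.

Cross-dataset gene selection by canonical correlation analysis (genes are
the paired observations shared by the two datasets, profiles the canonical
variables — the convention of cross-dataset single-cell integration), PCA of
the selected genes' expression, a soft-margin linear support-vector boundary
separating the two lineages in the PC1/PC2 plane, and Carnegie-stage
assignment by global Pearson correlation.

Sign conventions are fixed for reproducibility: the largest-magnitude PCA
loading entry is positive, and the SVM decision value d(x) = w.x + b is
positive on the embryonic-disc side.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.svm import SVC

from .expr_io import PseudoBulkProfile
from .mesh import STAGES

EMDISC = "EmDisc"
AM = "Am"
BOUNDARY = "boundary"


@dataclass
class CcaResult:
    """Canonical correlations and per-gene loading magnitudes."""

    correlations: np.ndarray  # rho_1 >= rho_2 >= ..., each in [0, 1]
    gene_loadings: pd.DataFrame  # genes x components, absolute magnitudes

    def __post_init__(self) -> None:
        rho = np.asarray(self.correlations, float)
        if np.any(rho < -1e-9) or np.any(rho > 1 + 1e-9):
            raise ValueError("canonical correlations must lie in [0, 1]")
        if np.any(np.diff(rho) > 1e-9):
            raise ValueError("canonical correlations must be non-increasing")


@dataclass
class LineageSpaceModel:
    """CCA gene set + PCA loadings + linear decision boundary."""

    genes: list
    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray  # (n_pcs, n_genes), rows orthonormal
    explained_variance_ratio: np.ndarray
    w: np.ndarray | None = None  # boundary normal in the PC1/PC2 plane
    b: float | None = None
    svm_C: float | None = None

    @property
    def n_pcs(self) -> int:
        return self.loadings.shape[0]

    @property
    def is_boundary_fitted(self) -> bool:
        return self.w is not None

    def to_json(self, path=None) -> str:
        doc = {
            "genes": list(self.genes),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "loadings_row_major": self.loadings.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "w": None if self.w is None else self.w.tolist(),
            "b": self.b,
            "svm_C": self.svm_C,
            "conventions": {
                "loading_sign": "largest-magnitude entry positive",
                "decision_sign": "d > 0 means EmDisc",
            },
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "LineageSpaceModel":
        text = str(source)
        if text.lstrip().startswith("{"):
            doc = json.loads(text)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        return cls(
            genes=doc["genes"],
            center=np.asarray(doc["center"], float),
            scale=np.asarray(doc["scale"], float),
            loadings=np.asarray(doc["loadings_row_major"], float),
            explained_variance_ratio=np.asarray(
                doc["explained_variance_ratio"], float
            ),
            w=None if doc["w"] is None else np.asarray(doc["w"], float),
            b=doc["b"],
            svm_C=doc["svm_C"],
        )


# ---------------------------------------------------------------------------
# CCA


def _profile_matrix(profiles: list, genes) -> np.ndarray:
    return np.column_stack([p.values.reindex(genes).to_numpy() for p in profiles])


def _standardize_genes(M: np.ndarray) -> np.ndarray:
    """Standardize each gene (row observation) across a dataset's profiles."""
    mu = M.mean(axis=1, keepdims=True)
    sd = M.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (M - mu) / sd


def cca_select_genes(
    in_vivo: list,
    in_vitro: list,
    n_components: int = 2,
    top_k: int = 500,
    ridge: float = 1e-3,
):
    """Select genes carrying correlated structure across two datasets.

    Shared genes are the paired observations; each dataset's profiles are
    the canonical variables (with per-gene standardisation, so the result is
    invariant to per-dataset gene rescalings).  Ridge-regularised canonical
    pairs are computed from the whitened cross-covariance; the per-gene score
    is the maximum absolute canonical-variate loading over the first
    ``n_components`` pairs, and the ``top_k`` genes by score are returned
    (ties break by gene id).
    """
    shared = sorted(set(in_vivo[0].genes) & set(in_vitro[0].genes))
    if not shared:
        raise ValueError("no shared genes between the two datasets")
    if top_k > len(shared):
        raise ValueError(f"top_k={top_k} exceeds {len(shared)} shared genes")
    n1, n2 = len(in_vivo), len(in_vitro)
    if n1 < n_components + 2 or n2 < n_components + 2:
        raise ValueError(
            f"each dataset needs >= n_components + 2 profiles "
            f"(got {n1} and {n2} for n_components={n_components})"
        )
    X = _standardize_genes(_profile_matrix(in_vivo, shared))  # (G, n1)
    Y = _standardize_genes(_profile_matrix(in_vitro, shared))  # (G, n2)
    G = len(shared)

    Sxx = X.T @ X / (G - 1) + ridge * np.eye(n1)
    Syy = Y.T @ Y / (G - 1) + ridge * np.eye(n2)
    Sxy = X.T @ Y / (G - 1)

    # whitened cross-covariance via inverse Cholesky factors
    Lx = linalg.cholesky(Sxx, lower=True)
    Ly = linalg.cholesky(Syy, lower=True)
    M = linalg.solve_triangular(Lx, Sxy, lower=True)
    M = linalg.solve_triangular(Ly, M.T, lower=True).T
    U, s, Vt = np.linalg.svd(M)
    d = min(n_components, len(s))
    rho = np.clip(s[:d], 0.0, 1.0)
    A = linalg.solve_triangular(Lx.T, U[:, :d], lower=False)  # profile weights
    B = linalg.solve_triangular(Ly.T, Vt[:d].T, lower=False)

    loadings = np.zeros((G, d))
    for i in range(d):
        u = X @ A[:, i]
        v = Y @ B[:, i]
        u = u / max(np.linalg.norm(u), 1e-12) * np.sqrt(G)
        v = v / max(np.linalg.norm(v), 1e-12) * np.sqrt(G)
        loadings[:, i] = 0.5 * (np.abs(u) + np.abs(v))
    load_df = pd.DataFrame(
        loadings, index=shared, columns=[f"CC{i + 1}" for i in range(d)]
    )
    score = pd.Series(loadings.max(axis=1), index=shared)
    ranked = score.sort_values(ascending=False, kind="stable")
    # stable sort on descending score; the index (sorted gene ids) breaks ties
    selected = list(ranked.index[:top_k])
    return selected, CcaResult(rho, load_df)


def adjust_profiles(datasets: dict) -> dict:
    """Per-dataset gene-mean centering ("adjusted expression values").

    Removing each dataset's own per-gene mean takes out the systematic
    offset between deeply sequenced reference samples and single-cell
    pseudo-bulks, so profiles from different datasets can share one PCA.
    Returns a dict with the same keys and centered profiles.
    """
    out = {}
    for name, profiles in datasets.items():
        table = pd.DataFrame({p.name: p.values for p in profiles})
        mu = table.mean(axis=1)
        out[name] = [
            PseudoBulkProfile(p.name, p.values - mu, p.n_cells, p.group_key)
            for p in profiles
        ]
    return out


# ---------------------------------------------------------------------------
# PCA


def fit_pca(
    profiles: list,
    genes: list,
    n_pcs: int = 2,
    scale: bool = False,
) -> LineageSpaceModel:
    """PCA of profile expression on the selected genes.

    Genes are centered (optionally unit-scaled) across profiles; loadings
    are the top right-singular vectors with the sign fixed so the
    largest-magnitude entry of each loading is positive.
    """
    if len(profiles) < n_pcs + 1:
        raise ValueError(f"need >= n_pcs + 1 = {n_pcs + 1} profiles")
    P = _profile_matrix(profiles, genes).T  # (n_profiles, n_genes)
    center = P.mean(axis=0)
    sd = P.std(axis=0, ddof=1)
    scl = np.where(sd == 0, 1.0, sd) if scale else np.ones_like(center)
    Z = (P - center) / scl
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size else 0
    if n_pcs > rank:
        raise ValueError(f"n_pcs={n_pcs} exceeds the data rank ({rank})")
    loadings = Vt[:n_pcs]
    for i in range(n_pcs):
        j = np.argmax(np.abs(loadings[i]))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
    total_var = (s**2).sum()
    evr = (s[:n_pcs] ** 2) / total_var if total_var > 0 else np.zeros(n_pcs)
    return LineageSpaceModel(
        genes=list(genes),
        center=center,
        scale=scl,
        loadings=loadings,
        explained_variance_ratio=evr,
    )


def project(profile: PseudoBulkProfile, model: LineageSpaceModel) -> np.ndarray:
    """PC coordinates of a profile; missing genes are an error, never zeros."""
    vals = profile.values.reindex(model.genes)
    missing = list(vals.index[vals.isna()])
    if missing:
        raise ValueError(f"profile {profile.name!r} lacks model genes: {missing[:10]}")
    z = (vals.to_numpy() - model.center) / model.scale
    return model.loadings @ z


# ---------------------------------------------------------------------------
# decision boundary


def fit_decision_boundary(
    scores: np.ndarray, labels, C: float = 1.0
) -> tuple:
    """Soft-margin linear SVM in the PC1/PC2 plane; d > 0 on the EmDisc side."""
    scores = np.asarray(scores, float)[:, :2]
    y = np.asarray([1 if l == EMDISC else -1 for l in labels])
    if len(set(y)) < 2:
        raise ValueError("both classes (EmDisc and Am) must be present")
    svm = SVC(kernel="linear", C=C, tol=1e-8)
    svm.fit(scores, y)
    w = svm.coef_[0].copy()
    b = float(svm.intercept_[0])
    return w, b


def attach_boundary(model: LineageSpaceModel, scores, labels, C: float = 1.0):
    model.w, model.b = fit_decision_boundary(scores, labels, C=C)
    model.svm_C = C
    return model


def decision_value(xy: np.ndarray, model: LineageSpaceModel) -> float:
    if not model.is_boundary_fitted:
        raise ValueError("decision boundary has not been fitted")
    return float(model.w @ np.asarray(xy, float)[:2] + model.b)


def classify(profile: PseudoBulkProfile, model: LineageSpaceModel) -> tuple:
    """Lineage call from the sign of the decision value; |d| is confidence."""
    d = decision_value(project(profile, model), model)
    label = BOUNDARY if d == 0 else (EMDISC if d > 0 else AM)
    return label, d


# ---------------------------------------------------------------------------
# stage assignment

_STAGE_ORDER = {s: i for i, s in enumerate(STAGES)}


def assign_stage(
    query: PseudoBulkProfile, stage_references: list, genes: list | None = None
) -> tuple:
    """Carnegie-stage call by Pearson correlation against stage pseudo-bulks.

    Returns (stage, correlation Series); ties break by fixed stage order
    CS5 < CS6 < CS7 and are flagged via the Series' ``attrs['tie']``.
    """
    if len(stage_references) < 2:
        raise ValueError("need references for at least two stages")
    refs = sorted(stage_references, key=lambda p: _STAGE_ORDER.get(p.name, 99))
    use = list(genes) if genes is not None else list(query.genes)
    q = query.values.reindex(use).to_numpy()
    if np.isnan(q).any():
        raise ValueError("query profile lacks some of the requested genes")
    if np.std(q) == 0:
        raise ValueError(f"query profile {query.name!r} is constant; r undefined")
    rs = {}
    for ref in refs:
        r_vals = ref.values.reindex(use).to_numpy()
        if np.std(r_vals) == 0:
            raise ValueError(f"reference profile {ref.name!r} is constant")
        rs[ref.name] = float(stats.pearsonr(q, r_vals).statistic)
    series = pd.Series(rs)
    best = series.max()
    winners = [s for s in series.index if series[s] == best]
    series.attrs["tie"] = len(winners) > 1
    return winners[0], series
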