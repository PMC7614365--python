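"""Count-matrix I/O and preprocessing.

The in-memory container is :class:`anndata.AnnData` with cells as
observations and genes as variables: raw integer counts in ``X``, the
normalized layer in ``layers['lognorm']`` and cell metadata (condition,
cell line, QC flag) in ``obs``.

Normalization is counts-per-10,000 followed by natural log1p —
``lognorm[c, g] = ln(1 + raw[c, g] * 1e4 / total[c])`` — the documented
default of the Seurat/scanpy normalisation the transcriptome analysis
assumes.  Differential expression uses a two-sided Wilcoxon rank-sum test
per gene with Benjamini-Hochberg adjustment and pseudocounted log2 fold
changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as sio
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

LAYER = "lognorm"
SCALE_FACTOR = 1e4
#: pseudocount on the normalized scale for fold changes
FC_EPS = 0.01


@dataclass
class PseudoBulkProfile:
    """Per-group mean normalized expression profile."""

    name: str
    values: pd.Series  # index: gene ids
    n_cells: int
    group_key: str = "condition"

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")

    @property
    def genes(self) -> pd.Index:
        return self.values.index


def _dense(x) -> np.ndarray:
    return np.asarray(x.todense()) if sparse.issparse(x) else np.asarray(x)


def _check_integer_counts(x: np.ndarray) -> None:
    if x.size == 0:
        raise ValueError("empty count matrix")
    if np.any(x < 0) or not np.allclose(x, np.round(x)):
        raise ValueError("raw counts must be non-negative integers")


# ---------------------------------------------------------------------------
# I/O


def read_counts(path, fmt: str = "mtx") -> ad.AnnData:
    """Read a genes x cells count matrix (MTX triplet dir or dense TSV).

    MTX layout: ``matrix.mtx`` (MatrixMarket, genes as rows), ``genes.tsv``
    and ``barcodes.tsv``.  TSV layout: genes as rows, cells as columns, gene
    ids in the first column.  A sidecar ``metadata.csv`` keyed by cell id is
    joined into ``obs`` when present.
    """
    path = Path(path)
    if fmt == "mtx":
        mat = sio.mmread(path / "matrix.mtx")
        genes = pd.read_csv(path / "genes.tsv", header=None, sep="\t")[0].astype(str)
        cells = pd.read_csv(path / "barcodes.tsv", header=None, sep="\t")[0].astype(str)
        mat = _dense(mat)
        if mat.shape != (len(genes), len(cells)):
            raise ValueError(
                f"matrix shape {mat.shape} does not match "
                f"{len(genes)} genes x {len(cells)} cells"
            )
        X = mat.T
        meta_path = path / "metadata.csv"
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.empty:
            raise ValueError(f"{path}: empty matrix file")
        genes = df.index.astype(str)
        cells = df.columns.astype(str)
        X = df.to_numpy().T
        meta_path = Path(path).with_name("metadata.csv")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    _check_integer_counts(X)
    if genes.duplicated().any() or cells.duplicated().any():
        raise ValueError("gene and cell ids must be unique")
    obs = pd.DataFrame(index=pd.Index(cells, name="cell"))
    if meta_path.exists():
        meta = pd.read_csv(meta_path, index_col=0)
        obs = obs.join(meta, how="left")
    return ad.AnnData(
        X=np.asarray(np.round(X), dtype=np.int64),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )


def write_counts(adata: ad.AnnData, path, fmt: str = "mtx") -> None:
    """Write raw counts (inverse of :func:`read_counts`)."""
    path = Path(path)
    X = _dense(adata.X)
    _check_integer_counts(X)
    if fmt == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        sio.mmwrite(
            path / "matrix.mtx",
            sparse.coo_matrix(X.T.astype(np.int64)),
            field="integer",
        )
        pd.Series(adata.var_names).to_csv(
            path / "genes.tsv", sep="\t", header=False, index=False
        )
        pd.Series(adata.obs_names).to_csv(
            path / "barcodes.tsv", sep="\t", header=False, index=False
        )
        if len(adata.obs.columns):
            adata.obs.to_csv(path / "metadata.csv")
    elif fmt == "tsv":
        pd.DataFrame(
            X.T.astype(np.int64), index=adata.var_names, columns=adata.obs_names
        ).to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# QC / normalization


def qc_filter(
    adata: ad.AnnData, min_genes_detected: int = 2000, min_total_counts: int = 50000
) -> ad.AnnData:
    """Flag cells failing detection/depth thresholds (``obs['qc_pass']``).

    Failing cells stay in the matrix but are excluded from every downstream
    aggregation; the gene set is unchanged.
    """
    if min_genes_detected < 0 or min_total_counts < 0:
        raise ValueError("QC thresholds must be >= 0")
    out = adata.copy()
    X = _dense(out.X)
    _check_integer_counts(X)
    detected = (X > 0).sum(axis=1)
    totals = X.sum(axis=1)
    passed = (detected >= min_genes_detected) & (totals >= min_total_counts)
    if not passed.any():
        raise ValueError(
            f"all {out.n_obs} cells fail QC (min_genes_detected="
            f"{min_genes_detected}, min_total_counts={min_total_counts})"
        )
    out.obs["qc_pass"] = passed
    out.obs["n_genes_detected"] = detected
    out.obs["total_counts"] = totals
    return out


def _qc_mask(adata: ad.AnnData) -> np.ndarray:
    if "qc_pass" in adata.obs:
        return adata.obs["qc_pass"].to_numpy(bool)
    return np.ones(adata.n_obs, dtype=bool)


def normalize(adata: ad.AnnData) -> ad.AnnData:
    """Counts-per-10,000 log1p into ``layers['lognorm']``."""
    out = adata.copy()
    X = _dense(out.X).astype(float)
    _check_integer_counts(X)
    totals = X.sum(axis=1)
    qc = _qc_mask(out)
    if np.any(qc & (totals == 0)):
        bad = list(out.obs_names[qc & (totals == 0)])
        raise ValueError(f"QC-passing cells with zero total counts: {bad}")
    safe = np.where(totals > 0, totals, 1.0)
    out.layers[LAYER] = np.log1p(X * SCALE_FACTOR / safe[:, None])
    return out


def _require_layer(adata: ad.AnnData) -> np.ndarray:
    if LAYER not in adata.layers:
        raise ValueError("normalized layer missing; call normalize() first")
    return np.asarray(adata.layers[LAYER])


def select_hvg(adata: ad.AnnData, k: int) -> list:
    """The k genes with the largest normalized-expression variance.

    Variance (ddof=1) is computed over QC-passing cells; ties break
    deterministically by gene order in the matrix.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > adata.n_vars:
        raise ValueError(f"k={k} exceeds the number of genes ({adata.n_vars})")
    L = _require_layer(adata)[_qc_mask(adata)]
    var = L.var(axis=0, ddof=1) if L.shape[0] > 1 else np.zeros(L.shape[1])
    order = np.argsort(-var, kind="stable")
    return [adata.var_names[i] for i in order[:k]]


def pseudo_bulk(adata: ad.AnnData, group_key: str = "condition") -> list:
    """Per-group arithmetic mean of the normalized layer (QC-passing cells)."""
    L = _require_layer(adata)
    qc = _qc_mask(adata)
    if group_key not in adata.obs:
        raise KeyError(f"obs lacks group key {group_key!r}")
    groups = adata.obs[group_key].astype(str)
    profiles = []
    for name in pd.unique(groups):
        mask = (groups == name).to_numpy() & qc
        if not mask.any():
            raise ValueError(f"group {name!r} has no QC-passing cells")
        profiles.append(
            PseudoBulkProfile(
                name=name,
                values=pd.Series(L[mask].mean(axis=0), index=adata.var_names),
                n_cells=int(mask.sum()),
                group_key=group_key,
            )
        )
    return profiles


def zscore_by_gene(profiles: list) -> pd.DataFrame:
    """Per-gene z-scores across profiles (sample sd; zero-sd genes -> 0)."""
    if len(profiles) < 2:
        raise ValueError("z-scoring needs at least two profiles")
    table = pd.DataFrame({p.name: p.values for p in profiles})
    mu = table.mean(axis=1)
    sd = table.std(axis=1, ddof=1)
    z = table.sub(mu, axis=0).div(sd.replace(0.0, np.inf), axis=0)
    return z.fillna(0.0)


def differential_expression(
    adata: ad.AnnData,
    group_a: str,
    group_b: str,
    group_key: str = "condition",
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum DE with BH adjustment.

    log2FC = log2((mean_a + eps) / (mean_b + eps)) with eps = 0.01 on the
    normalized scale.  The table is sorted by q, then decreasing |log2FC|.
    DE calls downstream use q < 0.05 and |log2FC| > 1.
    """
    L = _require_layer(adata)
    qc = _qc_mask(adata)
    groups = adata.obs[group_key].astype(str).to_numpy()
    ma = (groups == group_a) & qc
    mb = (groups == group_b) & qc
    if ma.sum() < 3 or mb.sum() < 3:
        raise ValueError(
            f"each group needs >= 3 QC-passing cells "
            f"({group_a}: {int(ma.sum())}, {group_b}: {int(mb.sum())})"
        )
    A, B = L[ma], L[mb]
    res = stats.mannwhitneyu(A, B, axis=0, alternative="two-sided", method="auto")
    pvals = np.atleast_1d(res.pvalue)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    mean_a, mean_b = A.mean(axis=0), B.mean(axis=0)
    log2fc = np.log2((mean_a + FC_EPS) / (mean_b + FC_EPS))
    table = pd.DataFrame(
        {
            "gene": adata.var_names,
            "log2fc": log2fc,
            "p": pvals,
            "q": qvals,
            "meanA": mean_a,
            "meanB": mean_b,
            "nA": int(ma.sum()),
            "nB": int(mb.sum()),
        }
    )
    table["_abs"] = -table["log2fc"].abs()
    table = table.sort_values(["q", "_abs"], kind="stable").drop(columns="_abs")
    table.attrs["test"] = "wilcoxon_rank_sum"
    table.attrs["adjustment"] = "benjamini_hochberg"
    table.attrs["fc_pseudocount"] = FC_EPS
    return table.reset_index(drop=True)


def write_de_table(table: pd.DataFrame, path) -> None:
    cols = ["gene", "log2fc", "p", "q", "meanA", "meanB", "nA", "nB"]
    table[cols].to_csv(path, sep="\t", index=False)
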