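"""Synthetic inputs with known ground truth.

Generates every input the analysis consumes: an embryo mesh with regional
expression fields, anchored in-vivo-like reference samples, spheroid
single-cell count matrices under control/perturbed conditions, and 3D
spheroid image stacks.  All generators are pure functions of their
configuration (including the seed).

Count model: negative binomial with Var = m + m^2/theta at mean m, cell
means proportional to the per-vertex expression field scaled to a lognormal
library size (full-length, Smart-seq-like depth).  Perturbations are convex
mixtures of region archetypes with mixing weight lambda.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import anndata as ad
from scipy.special import expit

from .mesh import (
    AMNION_CAP_HEIGHT,
    DISTAL_RHO_FRACTION,
    REGIONS,
    STAGES,
    EmbryoMesh,
    make_embryo_mesh,
)
from .morphometrics import SpheroidStack

__all__ = [
    "SimConfig",
    "MarkerSpec",
    "ExpressionField",
    "FieldSet",
    "DEFAULT_PANEL",
    "make_embryo_mesh",
    "make_expression_fields",
    "sample_reference_profiles",
    "sample_spheroid_cells",
    "make_stage_series",
    "make_spheroid_stack",
    "write_sim_outputs",
]

# regions a marker spec may target (broad lineages or mapped subregions)
MARKER_REGIONS = (
    "EmDisc",
    "EmDisc_anterior",
    "EmDisc_posterior",
    "Am",
    "Am_proximal",
    "Am_distal",
)


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; identical config implies bit-identical output."""

    seed: int = 0
    n_background: int = 1990
    n_smooth: int = 300
    nb_theta: float = 10.0
    library_log_mean: float = 9.2
    library_log_sd: float = 0.3
    archetype_mix: float = 0.0
    cells_per_spheroid: int = 200
    samples_per_region: int = 8
    #: cells pooled per spatial reference sample (microdissected multi-cell
    #: biopsies, not single cells); scales the sample's library size
    reference_pool_cells: int = 20

    def __post_init__(self) -> None:
        if not (0.0 <= self.archetype_mix <= 1.0):
            raise ValueError("archetype_mix (lambda) must lie in [0, 1]")
        if self.nb_theta <= 0:
            raise ValueError("nb_theta must be positive")


@dataclass(frozen=True)
class MarkerSpec:
    """A marker gene expressed as a smooth logistic gradient toward a region."""

    name: str
    region: str
    baseline: float = 0.2
    amplitude: float = 8.0

    def __post_init__(self) -> None:
        if self.region not in MARKER_REGIONS:
            raise ValueError(
                f"marker {self.name!r}: unknown region {self.region!r}; "
                f"expected one of {MARKER_REGIONS}"
            )
        if self.baseline < 0 or self.amplitude < 0:
            raise ValueError(f"marker {self.name!r}: baseline/amplitude must be >= 0")


# panel mirroring the lineage markers mapped on the embryo model: SOX2/POU5F1/
# NANOG (embryonic disc, anterior-biased core pluripotency), TBXT (posterior
# disc / primitive streak), TFAP2A/TFAP2C (pan-amnion), VTCN1/GABRP/HAND1
# (distal, mature amnion), ISL1 (low heterogeneous amnion).
DEFAULT_PANEL = (
    MarkerSpec("SOX2", "EmDisc_anterior", baseline=0.5, amplitude=8.0),
    MarkerSpec("POU5F1", "EmDisc", baseline=1.0, amplitude=6.0),
    MarkerSpec("NANOG", "EmDisc", baseline=0.3, amplitude=6.0),
    MarkerSpec("TBXT", "EmDisc_posterior", baseline=0.2, amplitude=8.0),
    MarkerSpec("TFAP2A", "Am", baseline=0.3, amplitude=8.0),
    MarkerSpec("TFAP2C", "Am", baseline=0.3, amplitude=7.0),
    MarkerSpec("VTCN1", "Am_distal", baseline=0.2, amplitude=8.0),
    MarkerSpec("GABRP", "Am_distal", baseline=0.2, amplitude=6.0),
    MarkerSpec("HAND1", "Am_distal", baseline=0.2, amplitude=5.0),
    MarkerSpec("ISL1", "Am", baseline=0.3, amplitude=1.5),
)

#: amnion maturation markers whose gradient amplitude scales with stage
MATURITY_MARKERS = ("VTCN1", "GABRP", "HAND1")
STAGE_MATURITY = {"CS5": 0.5, "CS6": 1.0, "CS7": 1.6}


@dataclass
class ExpressionField:
    """Per-vertex mean expression of one gene (normalized-scale units >= 0)."""

    gene: str
    values: np.ndarray
    field_kind: str  # marker-gradient | background | random-smooth
    monotone_axis: tuple | None = None  # (axis_name, sign) for pure gradients


@dataclass
class FieldSet:
    """Expression fields for all genes as a dense (genes x vertices) matrix."""

    genes: list
    matrix: np.ndarray  # (G, V), mu_g(v) >= 0
    kinds: np.ndarray
    monotone_axes: list

    @property
    def fields(self) -> list:
        return [
            ExpressionField(g, self.matrix[i], self.kinds[i], self.monotone_axes[i])
            for i, g in enumerate(self.genes)
        ]

    def __len__(self) -> int:
        return len(self.genes)

    def gene_index(self, gene: str) -> int:
        return self.genes.index(gene)

    def archetype(self, mesh: EmbryoMesh, region: str) -> np.ndarray:
        """Mean field over the region's vertices (the region's archetype)."""
        mask = mesh.region_mask(region)
        if not mask.any():
            raise ValueError(f"region {region!r} has no vertices")
        return self.matrix[:, mask].mean(axis=1)


def _amnion_z_split(radius: float) -> float:
    """z (um) of the distal/proximal amnion split at the fixed rho fraction."""
    a = radius
    h = AMNION_CAP_HEIGHT * a
    r2 = (a * a + h * h) / (2.0 * h)
    z0 = h - r2
    return z0 + np.sqrt(r2 * r2 - (DISTAL_RHO_FRACTION * a) ** 2)


def _marker_gate(spec: MarkerSpec, mesh: EmbryoMesh):
    """Logistic gate in [0, 1] over vertices, plus the monotone axis if pure."""
    a = mesh.radius_um
    zn = mesh.vertices[:, 2] / a
    xn = mesh.vertices[:, 0] / a
    zs = _amnion_z_split(a) / a
    disc = expit((-zn - 0.02) / 0.12)
    am = expit((zn + 0.02) / 0.12)
    distal = expit((zn - zs) / 0.04)
    if spec.region == "EmDisc":
        return disc, ("z", -1)
    if spec.region == "Am":
        return am, ("z", +1)
    if spec.region == "Am_distal":
        return distal, ("z", +1)
    if spec.region == "EmDisc_anterior":
        return disc * expit(xn / 0.25), None
    if spec.region == "EmDisc_posterior":
        return disc * expit(-xn / 0.15), None
    if spec.region == "Am_proximal":
        return am * (1.0 - distal), None
    raise ValueError(f"unknown region {spec.region!r}")  # pragma: no cover


def _se_covariance(coords: np.ndarray, lengthscale: float, variance: float) -> np.ndarray:
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    return variance * np.exp(-0.5 * d2 / lengthscale**2)


def make_expression_fields(
    mesh: EmbryoMesh,
    panel=DEFAULT_PANEL,
    n_background: int = 1990,
    n_smooth: int = 300,
    seed: int = 0,
) -> FieldSet:
    """Marker gradients plus background and spatially autocorrelated genes.

    Background genes are region-independent constants (lognormal levels).
    Random-smooth genes are lognormal transforms of a squared-exponential
    Gaussian-process draw (length-scale 0.35 x rim radius), adding realistic
    spatial autocorrelation independent of the mapped regions.
    """
    names = [m.name for m in panel]
    if len(set(names)) != len(names):
        raise ValueError("marker panel names must be unique")
    rng = np.random.default_rng(seed)
    V = mesh.n_vertices

    genes, rows, kinds, axes = [], [], [], []
    for spec in panel:
        gate, axis = _marker_gate(spec, mesh)
        rows.append(spec.baseline + spec.amplitude * gate)
        genes.append(spec.name)
        kinds.append("marker-gradient")
        axes.append(axis)

    bg_levels = rng.lognormal(mean=0.0, sigma=0.8, size=n_background)
    for i in range(n_background):
        genes.append(f"BG{i + 1:04d}")
        rows.append(np.full(V, bg_levels[i]))
        kinds.append("background")
        axes.append(None)

    if n_smooth > 0:
        # GP draw for spatial autocorrelation; hyperparameters deliberately
        # differ from the mapping kernel defaults and use their own stream
        cov = _se_covariance(mesh.vertices, 0.35 * mesh.radius_um, 1.0)
        L = np.linalg.cholesky(cov + 1e-8 * np.eye(V))
        f = rng.standard_normal((n_smooth, V)) @ L.T
        levels = rng.lognormal(mean=-0.5, sigma=0.5, size=n_smooth)
        for i in range(n_smooth):
            genes.append(f"SM{i + 1:04d}")
            rows.append(levels[i] * np.exp(0.6 * f[i] - 0.18))
            kinds.append("random-smooth")
            axes.append(None)

    matrix = np.asarray(rows, dtype=float)
    assert (matrix >= 0).all()
    return FieldSet(genes, matrix, np.asarray(kinds, dtype=object), axes)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """NB draws with Var = m + m^2/theta (Poisson limit for huge theta)."""
    mean = np.clip(mean, 1e-12, None)
    if theta > 1e8:
        return rng.poisson(mean)
    p = theta / (theta + mean)
    return rng.negative_binomial(theta, p)


def _cell_counts(rng, mean_profile, n_cells, cfg: SimConfig):
    """(n_cells, G) NB counts with lognormal library sizes; returns counts, libs."""
    libs = rng.lognormal(cfg.library_log_mean, cfg.library_log_sd, size=n_cells)
    rel = mean_profile / mean_profile.sum()
    means = libs[:, None] * rel[None, :]
    return _nb_counts(rng, means, cfg.nb_theta), libs


def sample_reference_profiles(
    fields: FieldSet,
    mesh: EmbryoMesh,
    samples_per_region: int | None = None,
    cfg: SimConfig = SimConfig(),
):
    """Anchored reference samples emulating spatially resolved embryo biopsies.

    Each sample anchors at one vertex; counts are negative-binomial with
    mean proportional to the field value at the anchor scaled to a lognormal
    library size.  Lineage and stage labels come from the mesh.
    """
    from .spatial_map import SpatialReference

    if len(fields) == 0:
        raise ValueError("empty field list")
    spr = cfg.samples_per_region if samples_per_region is None else samples_per_region
    if spr < 1:
        raise ValueError("samples_per_region must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    anchors, lineages = [], []
    for region in REGIONS:
        verts = mesh.region_vertices(region)
        if spr > len(verts):
            raise ValueError(
                f"region {region!r} has {len(verts)} vertices < "
                f"samples_per_region={spr}"
            )
        anchors.extend(rng.choice(verts, size=spr, replace=False))
        lineages.extend([region] * spr)
    anchors = np.asarray(anchors, dtype=int)

    counts, libs = [], []
    for v in anchors:
        lib = cfg.reference_pool_cells * rng.lognormal(
            cfg.library_log_mean, cfg.library_log_sd
        )
        rel = fields.matrix[:, v] / fields.matrix[:, v].sum()
        counts.append(_nb_counts(rng, lib * rel, cfg.nb_theta))
        libs.append(lib)
    X = np.asarray(counts, dtype=np.int64)
    obs = pd.DataFrame(
        {
            "anchor_vertex": anchors,
            "lineage": lineages,
            "stage": mesh.stage_tag,
            "library_size": libs,
        },
        index=[f"ref_{i:03d}" for i in range(len(anchors))],
    )
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=fields.genes))
    return SpatialReference.from_counts(mesh, adata)


def sample_spheroid_cells(
    fields: FieldSet,
    mesh: EmbryoMesh,
    source_region: str,
    target_region: str,
    lam: float | None = None,
    cfg: SimConfig = SimConfig(),
    condition: str | None = None,
    boost: dict | None = None,
) -> ad.AnnData:
    """Single-cell counts for a spheroid whose identity mixes two archetypes.

    Cell means are (1 - lambda) * archetype(source) + lambda * archetype(target)
    where the archetype is the field mean over the region's vertices.  An
    optional ``boost`` multiplies named genes' means (e.g. a primitive-streak
    marker bump under ACTIVIN stimulation without feeders).
    """
    lam = cfg.archetype_mix if lam is None else float(lam)
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lambda must lie in [0, 1]")
    src = fields.archetype(mesh, source_region)
    tgt = fields.archetype(mesh, target_region)
    mean = (1.0 - lam) * src + lam * tgt
    if boost:
        mean = mean.copy()
        for gene, factor in boost.items():
            mean[fields.gene_index(gene)] *= factor
    rng = np.random.default_rng(cfg.seed)
    X, libs = _cell_counts(rng, mean, cfg.cells_per_spheroid, cfg)
    name = condition or f"{source_region}->{target_region}@{lam:g}"
    obs = pd.DataFrame(
        {
            "condition": name,
            "cell_line": "sim#1",
            "lam": lam,
            "source_region": source_region,
            "target_region": target_region,
            "seed": cfg.seed,
            "library_size": libs,
        },
        index=[f"{name}|c{i:04d}" for i in range(cfg.cells_per_spheroid)],
    )
    return ad.AnnData(X=X.astype(np.int64), obs=obs, var=pd.DataFrame(index=fields.genes))


def make_stage_series(
    mesh: EmbryoMesh,
    cfg: SimConfig = SimConfig(),
    panel=DEFAULT_PANEL,
    n_stage_markers: int = 40,
) -> dict:
    """Stage-graded field sets for CS5/CS6/CS7.

    Amnion maturation markers scale with stage, and each stage carries its
    own block of stage-specific genes (a stage transcriptional program) on
    top of shared background/smooth genes, so global correlation can rank
    stages the way whole-transcriptome comparison does.
    """
    base = make_expression_fields(
        mesh, panel, cfg.n_background, cfg.n_smooth, seed=cfg.seed
    )
    marker_idx = {m.name: base.gene_index(m.name) for m in panel}
    baselines = {m.name: m.baseline for m in panel}
    series = {}
    n_total_extra = n_stage_markers * len(STAGES)
    extra_names = [
        f"{stage}_MRK{j + 1:03d}" for stage in STAGES for j in range(n_stage_markers)
    ]
    for stage in STAGES:
        mat = base.matrix.copy()
        factor = STAGE_MATURITY[stage]
        for name in MATURITY_MARKERS:
            i = marker_idx[name]
            mat[i] = baselines[name] + factor * (mat[i] - baselines[name])
        extra = np.full((n_total_extra, mesh.n_vertices), 0.3)
        block = STAGES.index(stage)
        extra[block * n_stage_markers : (block + 1) * n_stage_markers] *= 8.0
        series[stage] = FieldSet(
            base.genes + extra_names,
            np.vstack([mat, extra]),
            np.concatenate([base.kinds, np.full(n_total_extra, "background", object)]),
            base.monotone_axes + [None] * n_total_extra,
        )
    return series


# ---------------------------------------------------------------------------
# spheroid image stacks


def _fibonacci_directions(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    s = np.sqrt(1.0 - z * z)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def _random_rotation(rng) -> np.ndarray:
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    return q * np.sign(np.diag(r))


def _rotate_towards(v, rng, max_deg):
    """Rotate unit vector v by a random angle <= max_deg about a random axis."""
    axis = np.cross(v, rng.standard_normal(3))
    axis /= np.linalg.norm(axis)
    ang = np.deg2rad(rng.uniform(0.0, max_deg))
    return v * np.cos(ang) + np.cross(axis, v) * np.sin(ang)


DEFAULT_STACK_GEOMETRY = {
    # columnar epithelium: thick shell, radially elongated nuclei
    "epi": dict(outer_radius_um=30.0, inner_radius_um=18.0, n_nuclei=60,
                semi_axes_um=(4.0, 1.6, 1.6)),
    # squamous epithelium: thin shell, tangentially flattened nuclei
    "am": dict(outer_radius_um=36.0, inner_radius_um=34.5, n_nuclei=60,
               semi_axes_um=(4.0, 1.2, 1.2)),
}

DEFAULT_CHANNELS = {
    "epi": {"DAPI": (100.0, 5.0), "SOX2": (80.0, 8.0), "TFAP2C": (5.0, 2.0)},
    "am": {"DAPI": (100.0, 5.0), "SOX2": (5.0, 2.0), "TFAP2C": (80.0, 8.0)},
}


def make_spheroid_stack(
    kind: str,
    outer_radius_um: float | None = None,
    inner_radius_um: float | None = None,
    n_nuclei: int | None = None,
    semi_axes_um: tuple | None = None,
    channel_spec: dict | None = None,
    voxel_size_um: tuple = (0.5, 0.5, 0.5),
    orientation_jitter_deg: float = 2.0,
    seed: int = 0,
) -> SpheroidStack:
    """Voxel stack of an epithelial shell with ellipsoidal nuclei.

    Nuclear major axes are radial for ``kind='epi'`` (columnar, pointing at
    the lumen) and tangential for ``kind='am'`` (squamous).  Ground-truth
    orientation angles, shell thickness and per-nucleus channel intensities
    are stored alongside the voxel data.
    """
    if kind not in ("epi", "am"):
        raise ValueError("kind must be 'epi' or 'am'")
    geo = DEFAULT_STACK_GEOMETRY[kind]
    outer = float(geo["outer_radius_um"] if outer_radius_um is None else outer_radius_um)
    inner = float(geo["inner_radius_um"] if inner_radius_um is None else inner_radius_um)
    n_nuclei = int(geo["n_nuclei"] if n_nuclei is None else n_nuclei)
    semi = np.asarray(geo["semi_axes_um"] if semi_axes_um is None else semi_axes_um, float)
    channel_spec = DEFAULT_CHANNELS[kind] if channel_spec is None else channel_spec
    if inner >= outer:
        raise ValueError("inner radius must be smaller than outer radius")

    shell_volume = 4.0 / 3.0 * np.pi * (outer**3 - inner**3)
    nucleus_volume = 4.0 / 3.0 * np.pi * np.prod(semi)
    if n_nuclei * nucleus_volume > 0.6 * shell_volume:
        raise ValueError(
            f"{n_nuclei} nuclei of volume {nucleus_volume:.0f} um^3 do not fit "
            f"the shell (volume {shell_volume:.0f} um^3)"
        )

    rng = np.random.default_rng(seed)
    vz, vy, vx = (float(v) for v in voxel_size_um)
    margin = outer + max(semi) + 2.0
    shape = tuple(int(np.ceil(2 * margin / v)) | 1 for v in (vz, vy, vx))
    centroid = (np.array(shape, float) - 1.0) / 2.0 * np.array([vz, vy, vx])

    channels = list(channel_spec)
    volume = np.zeros(shape + (len(channels),), dtype=np.float32)
    labels = np.zeros(shape, dtype=np.int32)

    r_mid = 0.5 * (inner + outer)
    dirs = _fibonacci_directions(n_nuclei) @ _random_rotation(rng).T
    truth_rows = []
    grids = np.meshgrid(
        *(np.arange(s) for s in shape), indexing="ij"
    )  # voxel indices, reused per-nucleus via slicing

    for k in range(n_nuclei):
        radial = dirs[k]
        # physical coordinates ordered (z, y, x) to match the voxel layout
        center = centroid + r_mid * radial
        if kind == "epi":
            major = _rotate_towards(radial, rng, orientation_jitter_deg)
        else:
            t = np.cross(radial, rng.standard_normal(3))
            t /= np.linalg.norm(t)
            major = _rotate_towards(t, rng, orientation_jitter_deg)
        e1 = major / np.linalg.norm(major)
        tmp = radial if abs(radial @ e1) < 0.99 else np.array([1.0, 0.0, 0.0])
        e2 = np.cross(e1, tmp)
        e2 /= np.linalg.norm(e2)
        e3 = np.cross(e1, e2)

        lo = np.maximum(
            np.floor((center - semi[0] - 1.0) / (vz, vy, vx)).astype(int), 0
        )
        hi = np.minimum(
            np.ceil((center + semi[0] + 1.0) / (vz, vy, vx)).astype(int) + 1,
            np.array(shape),
        )
        sl = tuple(slice(l, h) for l, h in zip(lo, hi))
        coords = np.stack(
            [grids[0][sl] * vz, grids[1][sl] * vy, grids[2][sl] * vx], axis=-1
        )
        d = coords - center
        q = (
            (d @ e1) ** 2 / semi[0] ** 2
            + (d @ e2) ** 2 / semi[1] ** 2
            + (d @ e3) ** 2 / semi[2] ** 2
        )
        inside = q <= 1.0
        labels[sl][inside] = k + 1

        intensities = {}
        for ci, ch in enumerate(channels):
            mu, sd = channel_spec[ch]
            val = max(float(rng.normal(mu, sd)), 0.0)
            volume[sl + (ci,)][inside] = val
            intensities[ch] = val

        cos_phi = abs(float(e1 @ radial))
        truth_rows.append(
            {
                "nucleus_id": k + 1,
                "z_um": center[0],
                "y_um": center[1],
                "x_um": center[2],
                "angle_deg": float(np.degrees(np.arccos(np.clip(cos_phi, 0, 1)))),
                **{f"intensity_{ch}": intensities[ch] for ch in channels},
            }
        )

    # mild detector noise on top of the nuclear signal
    volume += rng.normal(2.0, 0.3, size=volume.shape).astype(np.float32)
    np.clip(volume, 0.0, None, out=volume)

    # tissue (epithelium) mask: the spherical shell between the two surfaces
    phys = np.stack(
        [grids[0] * vz, grids[1] * vy, grids[2] * vx], axis=-1
    ) - centroid
    radius = np.linalg.norm(phys, axis=-1)
    tissue = (radius >= inner) & (radius <= outer)

    truth = pd.DataFrame(truth_rows).set_index("nucleus_id")
    return SpheroidStack(
        volume=volume,
        channel_names=channels,
        labels=labels,
        voxel_size_um=(vz, vy, vx),
        centroid_um=tuple(centroid),
        tissue_mask=tissue,
        truth=truth,
        truth_thickness_um=outer - inner,
        kind=kind,
    )


# ---------------------------------------------------------------------------
# on-disk outputs


def write_sim_outputs(
    outdir,
    mesh: EmbryoMesh,
    adatas: dict,
    stacks: dict | None = None,
    mesh_encoding: str = "ascii",
) -> dict:
    """Write mesh (PLY), count matrices (MTX triplets), stacks (TIFF) and a
    manifest under one output directory; returns the manifest."""
    from .expr_io import write_counts

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"mesh": "mesh.ply", "counts": {}, "stacks": {}, "ground_truth": {}}
    mesh.save_ply(outdir / "mesh.ply", encoding=mesh_encoding)
    for name, adata in adatas.items():
        d = outdir / f"counts_{name}"
        write_counts(adata, d, fmt="mtx")
        manifest["counts"][name] = str(d.relative_to(outdir))
    if stacks:
        import tifffile

        for name, stack in stacks.items():
            p = outdir / f"stack_{name}.tiff"
            tifffile.imwrite(p, np.moveaxis(stack.volume, -1, 1))  # (Z, C, Y, X)
            tifffile.imwrite(outdir / f"labels_{name}.tiff", stack.labels)
            stack.truth.to_csv(outdir / f"truth_{name}.csv")
            manifest["stacks"][name] = str(p.relative_to(outdir))
            manifest["ground_truth"][name] = f"truth_{name}.csv"
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
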