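"""Triangulated embryo surface meshes.

The virtual embryo is modelled as two opposing spherical caps sharing a
circular rim: a deep (hemispherical) cap for the columnar embryonic disc
and a shallower cap for the squamous amnion.  Every vertex carries exactly
one region label out of the four mapped subregions (anterior/posterior
embryonic disc, proximal/distal amnion).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull

REGIONS = (
    "EmDisc_anterior",
    "EmDisc_posterior",
    "Am_proximal",
    "Am_distal",
)

STAGES = ("CS5", "CS6", "CS7")

#: relative height of the amnion cap (fraction of the rim radius)
AMNION_CAP_HEIGHT = 0.35
#: cylindrical-radius fraction splitting distal from proximal amnion
DISTAL_RHO_FRACTION = 0.6


@dataclass
class EmbryoMesh:
    """Triangulated two-cap embryo surface with per-vertex region labels.

    vertices : (V, 3) float array, coordinates in micrometres.
    faces : (F, 3) int array of vertex indices.
    region_labels : (V,) array of strings drawn from :data:`REGIONS`.
    stage_tag : Carnegie stage of the reference embryo ("CS5"|"CS6"|"CS7").
    """

    vertices: np.ndarray
    faces: np.ndarray
    region_labels: np.ndarray
    stage_tag: str = "CS6"
    radius_um: float = field(default=100.0)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.region_labels = np.asarray(self.region_labels, dtype=object)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("faces reference vertices outside the mesh")
        if len(self.region_labels) != len(self.vertices):
            raise ValueError("one region label per vertex required")
        unknown = set(self.region_labels) - set(REGIONS)
        if unknown:
            raise ValueError(f"unknown region labels: {sorted(unknown)}")
        if self.stage_tag not in STAGES:
            raise ValueError(f"stage_tag must be one of {STAGES}")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def region_mask(self, region: str) -> np.ndarray:
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}; expected one of {REGIONS}")
        return self.region_labels == region

    def region_vertices(self, region: str) -> np.ndarray:
        return np.flatnonzero(self.region_mask(region))

    @property
    def edge_lengths(self) -> np.ndarray:
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        return np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)

    @property
    def diameter(self) -> float:
        lo = self.vertices.min(axis=0)
        hi = self.vertices.max(axis=0)
        return float(np.linalg.norm(hi - lo))

    def content_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.vertices).tobytes())
        h.update(np.ascontiguousarray(self.faces).tobytes())
        return h.hexdigest()

    # -- I/O --------------------------------------------------------------

    def to_trimesh(self):
        import trimesh

        m = trimesh.Trimesh(self.vertices, self.faces, process=False)
        codes = np.array([REGIONS.index(r) for r in self.region_labels], dtype=np.int32)
        m.vertex_attributes["region"] = codes
        return m

    def save_ply(self, path, encoding: str = "ascii") -> None:
        """Write the mesh as PLY with an integer per-vertex ``region`` property."""
        data = self.to_trimesh().export(file_type="ply", encoding=encoding)
        if isinstance(data, str):
            data = data.encode()
        with open(path, "wb") as fh:
            fh.write(data)

    @classmethod
    def load_ply(cls, path, stage_tag: str = "CS6") -> "EmbryoMesh":
        import trimesh

        m = trimesh.load(str(path), file_type="ply", process=False)
        raw = m.metadata.get("_ply_raw", {}).get("vertex", {}).get("data", {})
        if "region" not in raw:
            raise ValueError(f"{path}: PLY lacks the per-vertex 'region' property")
        codes = np.asarray(raw["region"]).ravel().astype(int)
        labels = np.array([REGIONS[c] for c in codes], dtype=object)
        return cls(np.asarray(m.vertices), np.asarray(m.faces), labels, stage_tag)


def _cap_points(rng, n, sphere_radius, center_z, u_lo, u_hi):
    """Uniform-area random points on a spherical cap, u = cos(polar angle)."""
    u = rng.uniform(u_lo, u_hi, size=n)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    s = np.sqrt(np.clip(1.0 - u * u, 0.0, None))
    pts = np.column_stack(
        [
            sphere_radius * s * np.cos(phi),
            sphere_radius * s * np.sin(phi),
            center_z + sphere_radius * u,
        ]
    )
    return pts


def make_embryo_mesh(
    n_vertices: int,
    radius_um: float = 100.0,
    seed: int = 0,
    stage_tag: str = "CS6",
    disc_fraction: float = 0.55,
) -> EmbryoMesh:
    """Construct the two-cap embryo mesh.

    The embryonic-disc cap is the hemisphere below the rim plane (z < 0) of
    radius ``radius_um``; the amnion cap is a shallower spherical cap above
    it with the same rim circle.  The disc is split anterior (x >= 0) vs
    posterior (x < 0); the amnion is split proximal (near the rim) vs distal
    (near the pole) at a fixed cylindrical-radius fraction.  The union of
    the two caps is convex, so the triangulation is the convex hull, which
    is watertight and single-component by construction.
    """
    if n_vertices < 50:
        raise ValueError("n_vertices must be >= 50 to populate all four regions")
    if radius_um <= 0:
        raise ValueError("radius_um must be positive")
    rng = np.random.default_rng(seed)
    a = float(radius_um)
    h = AMNION_CAP_HEIGHT * a
    r2 = (a * a + h * h) / (2.0 * h)  # amnion sphere radius
    z0 = h - r2  # amnion sphere centre (on the z axis)

    n_disc = int(round(disc_fraction * n_vertices))
    n_am = n_vertices - n_disc
    disc = _cap_points(rng, n_disc, a, 0.0, -1.0, 0.0)
    am = _cap_points(rng, n_am, r2, z0, (r2 - h) / r2, 1.0)
    vertices = np.vstack([disc, am])

    hull = ConvexHull(vertices)
    if len(hull.vertices) != n_vertices:
        # points on a strictly convex surface are all extreme; a miss means
        # a numerically degenerate draw, so regenerate with a shifted stream
        return make_embryo_mesh(
            n_vertices, radius_um, seed=seed + 104729, stage_tag=stage_tag,
            disc_fraction=disc_fraction,
        )
    faces = hull.simplices

    labels = np.empty(n_vertices, dtype=object)
    z = vertices[:, 2]
    x = vertices[:, 0]
    rho = np.hypot(vertices[:, 0], vertices[:, 1])
    disc_mask = z < 0
    labels[disc_mask & (x >= 0)] = "EmDisc_anterior"
    labels[disc_mask & (x < 0)] = "EmDisc_posterior"
    am_mask = ~disc_mask
    distal = am_mask & (rho <= DISTAL_RHO_FRACTION * a)
    labels[distal] = "Am_distal"
    labels[am_mask & ~distal] = "Am_proximal"

    for region in REGIONS:
        if not np.any(labels == region):
            raise ValueError(
                f"n_vertices={n_vertices} too small: region {region!r} is empty"
            )
    return EmbryoMesh(vertices, faces, labels, stage_tag, radius_um=a)
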