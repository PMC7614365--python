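"""Image-derived quantifications on label-mask inputs.

Operates on multi-channel 3D stacks with nucleus label volumes: per-frame
channel intensities and ratios on nuclear masks, line intensity profiles,
3D nuclear orientation relative to the spheroid centre, epithelial thickness
by radial ray casting, summed spheroid intensity, DAPI-normalised nuclear
intensities, and the group-comparison statistics used on such measurements
(Shapiro-Wilk, Mann-Whitney, Welch t, Kruskal-Wallis with Dunn post hoc).

All geometric outputs are in physical units (micrometres): voxel coordinates
are scaled by the declared voxel size before any moment or distance is
computed, so anisotropic stacks are handled transparently.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats


@dataclass
class SpheroidStack:
    """Multi-channel 3D image with nucleus labels and physical geometry.

    volume : (Z, Y, X, C) float array of channel intensities.
    labels : (Z, Y, X) int array, 0 = background, k > 0 = nucleus k.
    tissue_mask : optional (Z, Y, X) bool array of the epithelial shell.
    truth : optional per-nucleus ground-truth table (synthetic stacks).
    """

    volume: np.ndarray
    channel_names: list
    labels: np.ndarray
    voxel_size_um: tuple
    centroid_um: tuple
    tissue_mask: np.ndarray | None = None
    lumen_mask: np.ndarray | None = None
    truth: pd.DataFrame | None = None
    truth_thickness_um: float | None = None
    kind: str | None = None

    def __post_init__(self) -> None:
        if self.volume.shape[:3] != self.labels.shape:
            raise ValueError("label volume must be congruent with the voxel array")
        if self.volume.shape[3] != len(self.channel_names):
            raise ValueError("one channel name per volume channel required")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")
        if (self.labels < 0).any():
            raise ValueError("labels must be non-negative integers")

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.volume[..., self.channel_names.index(name)]
        except ValueError:
            raise KeyError(
                f"unknown channel {name!r}; have {self.channel_names}"
            ) from None


@dataclass
class NucleusMorphometry:
    nucleus_id: int
    centroid_um: np.ndarray
    major_axis: np.ndarray  # unit vector, physical (z, y, x) frame
    angle_deg: float  # vs radial direction, folded to [0, 90]
    n_voxels: int
    degenerate: bool
    channel_means: dict
    dapi_normalized: dict = field(default_factory=dict)


@dataclass
class GroupComparisonResult:
    method: str
    statistic: float
    p_value: float
    group_sizes: dict
    posthoc: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# intensities


def frame_intensity(
    stack: SpheroidStack,
    channels: list,
    mask: np.ndarray | None = None,
    ratio: tuple | None = None,
    eps: float = 1e-6,
) -> pd.DataFrame:
    """Per-z-frame mean channel intensity over a nuclear mask (+ ratio).

    Frames with an empty mask are omitted from the table and listed in the
    ``omitted_frames`` attribute of the result.
    """
    mask = (stack.labels > 0) if mask is None else mask.astype(bool)
    if not mask.any():
        raise ValueError("mask is empty on every frame")
    rows, omitted = [], []
    for z in range(stack.labels.shape[0]):
        m = mask[z]
        if not m.any():
            omitted.append(z)
            continue
        row = {"frame": z}
        for ch in channels:
            row[f"mean_{ch}"] = float(stack.channel(ch)[z][m].mean())
        if ratio is not None:
            a, b = ratio
            row[f"ratio_{a}_{b}"] = row[f"mean_{a}"] / (row[f"mean_{b}"] + eps)
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["omitted_frames"] = omitted
    return out


def line_profile(image: np.ndarray, start, end, n_samples: int = 100) -> np.ndarray:
    """Bilinear intensity profile along a line between two (row, col) points."""
    start = np.asarray(start, float)
    end = np.asarray(end, float)
    if np.allclose(start, end):
        raise ValueError("zero-length line")
    for p in (start, end):
        if (p < 0).any() or (p >= np.asarray(image.shape)).any():
            raise ValueError(f"endpoint {tuple(p)} outside the image")
    t = np.linspace(0.0, 1.0, n_samples)
    pts = start[:, None] * (1 - t) + end[:, None] * t
    return ndimage.map_coordinates(np.asarray(image, float), pts, order=1)


def spheroid_intensity(
    stack: SpheroidStack, channel: str, mask: np.ndarray | None = None
) -> float:
    """Total channel intensity over the spheroid mask, summed across slices."""
    mask = (stack.labels > 0) if mask is None else mask.astype(bool)
    if not mask.any():
        raise ValueError("empty spheroid mask")
    return float(stack.channel(channel)[mask].astype(np.float64).sum())


# ---------------------------------------------------------------------------
# nuclear geometry


def nuclear_orientation(
    stack: SpheroidStack,
    min_voxels: int = 5,
    degenerate_ratio: float = 1.1,
) -> list:
    """Per-nucleus major axis and orientation angle relative to the radius.

    The major axis is the principal eigenvector of the nucleus voxel
    second-moment (covariance) matrix in physical coordinates; the angle is
    measured against the nucleus-to-spheroid-centre direction and folded to
    [0, 90] degrees (0 = radial/apicobasal, 90 = tangential).  Nuclei that
    are too small are skipped with a warning; near-isotropic nuclei
    (eigenvalue ratio < ``degenerate_ratio``) are flagged degenerate.
    """
    labels = stack.labels
    n_labels = int(labels.max())
    if n_labels == 0:
        raise ValueError("no nucleus labels in the stack")
    vsize = np.asarray(stack.voxel_size_um)
    center = np.asarray(stack.centroid_um)
    out = []
    objects = ndimage.find_objects(labels)
    for lab in range(1, n_labels + 1):
        sl = objects[lab - 1]
        if sl is None:
            continue
        local = labels[sl] == lab
        n_vox = int(local.sum())
        if n_vox < min_voxels:
            warnings.warn(f"nucleus {lab}: only {n_vox} voxels, skipped")
            continue
        idx = np.argwhere(local) + [s.start for s in sl]
        coords = idx * vsize
        centroid = coords.mean(axis=0)
        cov = np.cov(coords, rowvar=False)
        evals, evecs = np.linalg.eigh(cov)
        major = evecs[:, -1]
        ratio = evals[-1] / max(evals[-2], 1e-12)
        radial = centroid - center
        norm = np.linalg.norm(radial)
        if norm == 0:
            warnings.warn(f"nucleus {lab} at the spheroid centre, skipped")
            continue
        cosphi = abs(float(major @ (radial / norm)))
        angle = math.degrees(math.acos(min(cosphi, 1.0)))
        means = {
            ch: float(stack.channel(ch)[sl][local].mean())
            for ch in stack.channel_names
        }
        out.append(
            NucleusMorphometry(
                nucleus_id=lab,
                centroid_um=centroid,
                major_axis=major,
                angle_deg=angle,
                n_voxels=n_vox,
                degenerate=bool(ratio < degenerate_ratio),
                channel_means=means,
            )
        )
    if not out:
        raise ValueError("all nuclei were skipped (too small or degenerate)")
    return out


def orientation_ratio(morphs: list, threshold_deg: float = 45.0) -> float:
    """Basolateral/apical count ratio: #(angle > thr) / #(angle <= thr).

    Degenerate nuclei are excluded.  Returns ``math.inf`` when no nucleus is
    below the threshold.
    """
    angles = [m.angle_deg for m in morphs if not m.degenerate]
    if not angles:
        raise ValueError("no non-degenerate nuclei")
    tangential = sum(a > threshold_deg for a in angles)
    radial = len(angles) - tangential
    return math.inf if radial == 0 else tangential / radial


def epithelial_thickness(
    stack: SpheroidStack,
    n_sectors: int = 64,
    mask: np.ndarray | None = None,
    step_um: float | None = None,
) -> np.ndarray:
    """Radial epithelial thickness (um) per angular sector.

    Rays are cast from the spheroid centroid along quasi-uniform directions;
    along each ray the tissue mask is sampled in physical space and the
    thickness is the distance between the basal (outer) and apical (inner)
    crossings.  Rays that never cross the tissue are skipped with a warning.
    """
    mask = stack.tissue_mask if mask is None else mask
    if mask is None:
        raise ValueError("no tissue mask available")
    vsize = np.asarray(stack.voxel_size_um)
    center = np.asarray(stack.centroid_um)
    step = 0.5 * float(vsize.min()) if step_um is None else float(step_um)
    max_r = float(np.linalg.norm(np.asarray(mask.shape) * vsize - center))
    radii = np.arange(0.0, max_r, step)

    # quasi-uniform directions on the sphere (golden-spiral lattice)
    i = np.arange(n_sectors) + 0.5
    z = 1.0 - 2.0 * i / n_sectors
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    s = np.sqrt(1.0 - z * z)
    dirs = np.column_stack([z, s * np.cos(phi), s * np.sin(phi)])

    values = []
    skipped = 0
    for d in dirs:
        pts = center[None, :] + radii[:, None] * d[None, :]
        idx = np.round(pts / vsize).astype(int)
        ok = np.all((idx >= 0) & (idx < mask.shape), axis=1)
        hit = np.zeros(len(radii), bool)
        hit[ok] = mask[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
        if not hit.any():
            skipped += 1
            continue
        r_in = radii[hit.argmax()]
        r_out = radii[len(hit) - 1 - hit[::-1].argmax()]
        # midpoint-crossing correction: each surface lies, on average, half a
        # sampling step beyond the first/last detected sample
        values.append(r_out - r_in + step)
    if skipped:
        warnings.warn(f"{skipped}/{n_sectors} rays did not cross the tissue")
    if not values:
        raise ValueError("no ray crossed the tissue mask")
    return np.asarray(values)


def dapi_normalize(
    morphs: list, channel: str, dapi_channel: str = "DAPI"
) -> list:
    """Per-nucleus channel mean divided by the DAPI mean (in place).

    Nuclei with zero DAPI signal are skipped with a warning.
    """
    out = []
    for m in morphs:
        dapi = m.channel_means.get(dapi_channel, 0.0)
        if dapi <= 0:
            warnings.warn(f"nucleus {m.nucleus_id}: zero DAPI mean, skipped")
            continue
        m.dapi_normalized[channel] = m.channel_means[channel] / dapi
        out.append(m)
    return out


# ---------------------------------------------------------------------------
# group statistics


def _dunn_posthoc(groups: dict, alpha_adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's rank-based pairwise z tests after Kruskal-Wallis.

    Uses pooled mid-ranks with the standard tie correction; two-sided normal
    p-values adjusted by Bonferroni across all pairs.
    """
    names = list(groups)
    pooled = np.concatenate([np.asarray(groups[k], float) for k in names])
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    # tie correction term: sum(t^3 - t) over tied groups
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (n - 1)))
    offsets = np.cumsum([0] + [len(groups[k]) for k in names])
    mean_ranks = {
        k: ranks[offsets[i] : offsets[i + 1]].mean() for i, k in enumerate(names)
    }
    rows = []
    m = len(names) * (len(names) - 1) // 2
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            na, nb = len(groups[a]), len(groups[b])
            se = math.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / na + 1.0 / nb))
            z = (mean_ranks[a] - mean_ranks[b]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "z": z,
                    "p": p,
                    "p_adj": min(p * m, 1.0),
                }
            )
    return pd.DataFrame(rows)


def compare_groups(values_by_group: dict, method: str) -> GroupComparisonResult:
    """Caption-level statistical tests on grouped measurements.

    method : 'mann_whitney' | 'welch_t' | 'kruskal_dunn' | 'shapiro_wilk'.
    All p-values are two-sided; 'kruskal_dunn' additionally returns the Dunn
    pairwise table with Bonferroni adjustment.
    """
    groups = {k: np.asarray(v, float) for k, v in values_by_group.items()}
    sizes = {k: len(v) for k, v in groups.items()}

    if method == "shapiro_wilk":
        if len(groups) != 1:
            raise ValueError("shapiro_wilk expects exactly one group")
        (vals,) = groups.values()
        if len(vals) < 3:
            raise ValueError("shapiro_wilk requires n >= 3")
        stat, p = stats.shapiro(vals)
    elif method == "mann_whitney":
        if len(groups) != 2 or any(s < 2 for s in sizes.values()):
            raise ValueError("mann_whitney requires two groups of >= 2 values")
        a, b = groups.values()
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    elif method == "welch_t":
        if len(groups) != 2 or any(s < 3 for s in sizes.values()):
            raise ValueError("welch_t requires two groups of >= 3 values")
        a, b = groups.values()
        stat, p = stats.ttest_ind(a, b, equal_var=False)
    elif method == "kruskal_dunn":
        if len(groups) < 3 or any(s < 3 for s in sizes.values()):
            raise ValueError("kruskal_dunn requires >= 3 groups of >= 3 values")
        stat, p = stats.kruskal(*groups.values())
        return GroupComparisonResult(
            method, float(stat), float(p), sizes, _dunn_posthoc(groups)
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return GroupComparisonResult(method, float(stat), float(p), sizes)
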