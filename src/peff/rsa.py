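"""Root-system-architecture traits from binary root masks.

A scanned root system is represented as a binary mask at a known scan
resolution (dpi); pixels convert to millimetres via 25.4/dpi.  Twelve
traits are computed:

* length — geodesic length of the morphological skeleton (unit steps
  for 4-neighbours, √2 for diagonals);
* area — foreground pixel count × scale²;
* diameter — area/length (projected-area cylinder estimate);
* volume, surface area — cylinder model π(d/2)²·L and π·d·L;
* rooting width/depth — bounding-box extents of the foreground;
* convex hull width/height/area — hull of foreground pixel centres
  (shoelace area, so a filled w×h rectangle gives (w−1)(h−1)·scale²);
* specific root length = length/volume (mm mm⁻³) and specific convex
  hull area = hull area / root area — the efficiency traits that
  summarise how much soil a root system explores per unit carbon.

The cylinder model stands in for the scanning software's internal
formulas: the specific-root-length units (mm mm⁻³) force
SRL = L/V = 1/(π(d/2)²), and published trait means are mutually
consistent with d ≈ 0.5 mm under this model.

``zscore_cluster`` reproduces the multivariate summary: per-column
z-scores over both treatments, then agglomerative complete-linkage
clustering on Euclidean distances of accessions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial import ConvexHull, QhullError
from skimage.morphology import skeletonize

log = logging.getLogger(__name__)

MM_PER_INCH = 25.4


def px_to_mm(dpi: float) -> float:
    """Scale factor mm/px at a scan resolution in dots per inch."""
    if dpi <= 0:
        raise ValueError("dpi must be positive")
    return MM_PER_INCH / dpi


@dataclass
class RootMask:
    mask: np.ndarray
    dpi: float = 600.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask) > 0
        if self.dpi <= 0:
            raise ValueError("dpi must be positive")

    @property
    def mm_per_px(self) -> float:
        return px_to_mm(self.dpi)


@dataclass
class RSATraits:
    length_mm: float
    area_mm2: float
    diameter_mm: float
    volume_mm3: float
    surface_area_mm2: float
    rooting_width_mm: float
    rooting_depth_mm: float
    hull_width_mm: float
    hull_height_mm: float
    hull_area_mm2: float
    specific_root_length: float   # mm / mm^3
    specific_hull_area: float     # mm^2 / mm^2

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def _foreground(mask: RootMask | np.ndarray, dpi: float | None = None) -> RootMask:
    if isinstance(mask, RootMask):
        return mask
    return RootMask(mask, dpi if dpi is not None else 600.0)


def root_length(mask, dpi: float | None = None) -> float:
    """Skeleton length in mm (√2-weighted 8-connectivity steps)."""
    rm = _foreground(mask, dpi)
    if not rm.mask.any():
        raise ValueError("empty mask")
    skel = skeletonize(rm.mask)
    straight = int((skel[:, :-1] & skel[:, 1:]).sum()) + int((skel[:-1] & skel[1:]).sum())
    # diagonal steps; corner-cutting diagonals (the pair already linked
    # through a shared 4-neighbour) would double-count a staircase
    d1 = skel[:-1, :-1] & skel[1:, 1:]
    d1 &= ~(skel[:-1, 1:] | skel[1:, :-1])
    d2 = skel[:-1, 1:] & skel[1:, :-1]
    d2 &= ~(skel[:-1, :-1] | skel[1:, 1:])
    diag = int(d1.sum()) + int(d2.sum())
    return (straight + diag * np.sqrt(2.0)) * rm.mm_per_px


def root_area(mask, dpi: float | None = None) -> float:
    rm = _foreground(mask, dpi)
    if not rm.mask.any():
        raise ValueError("empty mask")
    return float(rm.mask.sum()) * rm.mm_per_px ** 2


def mean_diameter(mask, dpi: float | None = None) -> float:
    """Projected-area diameter estimate d = area / length."""
    length = root_length(mask, dpi)
    if length <= 0:
        raise ValueError("zero skeleton length: diameter undefined")
    return root_area(mask, dpi) / length


def volume(mask, dpi: float | None = None) -> float:
    d = mean_diameter(mask, dpi)
    return np.pi * (d / 2.0) ** 2 * root_length(mask, dpi)


def surface_area(mask, dpi: float | None = None) -> float:
    d = mean_diameter(mask, dpi)
    return np.pi * d * root_length(mask, dpi)


def extents_and_hull(mask, dpi: float | None = None) -> dict[str, float]:
    """Bounding extents and convex hull of the foreground pixel centres.

    Returns rooting_width/depth (x/y extents), hull_width/height (hull
    bounding extents — identical to the foreground extents, as the
    hull of a point set spans the same bounding box) and hull_area.
    Collinear-only foregrounds get hull_area 0 with a warning.
    """
    rm = _foreground(mask, dpi)
    pts = np.argwhere(rm.mask)
    if pts.shape[0] == 0:
        raise ValueError("empty mask")
    s = rm.mm_per_px
    rows, cols = pts[:, 0].astype(float), pts[:, 1].astype(float)
    width = (cols.max() - cols.min()) * s
    depth = (rows.max() - rows.min()) * s
    try:
        hull = ConvexHull(np.column_stack([cols, rows]))
        hull_area = hull.volume * s * s  # 2-D "volume" is the polygon area
    except QhullError:
        warnings.warn("foreground is collinear; hull area set to 0", UserWarning,
                      stacklevel=2)
        hull_area = 0.0
    return {
        "rooting_width_mm": width,
        "rooting_depth_mm": depth,
        "hull_width_mm": width,
        "hull_height_mm": depth,
        "hull_area_mm2": hull_area,
    }


def specific_traits(traits: RSATraits) -> tuple[float, float]:
    """(specific root length, specific convex hull area)."""
    if traits.volume_mm3 <= 0 or traits.area_mm2 <= 0:
        raise ValueError("specific traits need positive volume and area")
    return (traits.length_mm / traits.volume_mm3,
            traits.hull_area_mm2 / traits.area_mm2)


def extract_traits(mask, dpi: float | None = None) -> RSATraits:
    """All twelve RSA traits of one mask."""
    rm = _foreground(mask, dpi)
    length = root_length(rm)
    area = root_area(rm)
    if length <= 0:
        raise ValueError("zero skeleton length: derived traits undefined")
    d = area / length
    vol = np.pi * (d / 2.0) ** 2 * length
    surf = np.pi * d * length
    ext = extents_and_hull(rm)
    traits = RSATraits(
        length_mm=length, area_mm2=area, diameter_mm=d, volume_mm3=vol,
        surface_area_mm2=surf, specific_root_length=length / vol,
        specific_hull_area=ext["hull_area_mm2"] / area, **ext,
    )
    return traits


@dataclass
class ClusterResult:
    zscores: pd.DataFrame
    linkage: np.ndarray
    labels: pd.Series
    leaves: list[str]


def zscore_cluster(
    trait_table: pd.DataFrame,
    n_clusters: int = 2,
    cut_height: float | None = None,
) -> ClusterResult:
    """Z-score columns, then complete-linkage hierarchical clustering of rows.

    Zero-variance columns are dropped with a warning (an all-constant
    table is an error).  Labels come from cutting the tree at
    ``cut_height`` if given, else into ``n_clusters`` groups.
    """
    if len(trait_table) < 2:
        raise ValueError("need at least two accessions")
    sd = trait_table.std(ddof=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all columns are constant")
    if (~keep).any():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance column(s)",
                      UserWarning, stacklevel=2)
    z = (trait_table.loc[:, keep] - trait_table.loc[:, keep].mean()) / sd[keep]
    Z = hierarchy.linkage(z.to_numpy(), method="complete", metric="euclidean")
    if cut_height is not None:
        labels = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    else:
        labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    leaves = [trait_table.index[i] for i in hierarchy.leaves_list(Z)]
    return ClusterResult(
        zscores=z,
        linkage=Z,
        labels=pd.Series(labels, index=trait_table.index, name="cluster"),
        leaves=leaves,
    )


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Export a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(Z)

    def build(node) -> str:
        if node.is_leaf():
            return f"{labels[node.id]}:{0.0:g}"
        left = build(node.left)
        right = build(node.right)
        return f"({left},{right}):{node.dist:g}"

    return build(tree) + ";"
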