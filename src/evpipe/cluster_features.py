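"""Per-cluster shape/intensity descriptors used for filtering and classification.

Twelve descriptors per cluster: radius_of_gyration, num_localisations,
convex_hull_area, distance_birth, skew, discretised_area, distance_depth,
circularity, density, length, ch1_binned_counts, ch2_binned_counts.

Definitions here are chosen to preserve the discriminative intent (antibody
aggregates are small and dense, vesicles larger and annular) without claiming
equivalence to any vendor implementation:

* ``skew`` — Euclidean norm of the per-axis sample skewnesses by default
  (``axis_max`` and ``radial`` alternatives are config-switchable);
* ``discretised_area`` — occupied-pixel area on a 10 nm grid;
* ``distance_birth`` — median single-linkage merge distance of the member
  molecules; ``distance_depth`` — span (max - min) of those merge distances.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from scipy.stats import skew as _sample_skew

from evpipe.localization_io import Channel

DEFAULT_PIXEL_NM = 10.0
DEFAULT_SKEW_RANGE = (1.0, 2.9)
DEFAULT_CIRC_RANGE = (0.43, 1.0)

FEATURE_NAMES = [
    "radius_of_gyration",
    "num_localisations",
    "convex_hull_area",
    "distance_birth",
    "skew",
    "discretised_area",
    "distance_depth",
    "circularity",
    "density",
    "length",
    "ch1_binned_counts",
    "ch2_binned_counts",
]


@dataclass
class ClusterFeatures:
    radius_of_gyration: float
    num_localisations: int
    convex_hull_area: float
    distance_birth: float
    skew: float
    discretised_area: float
    distance_depth: float
    circularity: float
    density: float
    length: float
    ch1_binned_counts: int
    ch2_binned_counts: int
    degenerate: bool = False

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _hull_metrics(xy: np.ndarray) -> tuple[float, float, bool]:
    """(area, perimeter, degenerate) of the 2-D convex hull."""
    if len(xy) < 3:
        return 0.0, 0.0, True
    try:
        hull = ConvexHull(xy)
    except QhullError:  # collinear / coincident
        return 0.0, 0.0, True
    # for 2-D hulls scipy reports area in .volume and perimeter in .area
    return float(hull.volume), float(hull.area), False


def _skew_value(xy: np.ndarray, centroid: np.ndarray, mode: str) -> float:
    if len(xy) < 3:
        return 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        if mode == "radial":
            r = np.linalg.norm(xy - centroid, axis=1)
            val = abs(float(_sample_skew(r)))
        else:
            per_axis = np.abs(_sample_skew(xy, axis=0))
            val = float(np.max(per_axis)) if mode == "axis_max" else float(np.linalg.norm(per_axis))
    return 0.0 if not np.isfinite(val) else val


def _merge_distances(points: np.ndarray) -> np.ndarray:
    if len(points) < 2:
        return np.zeros(0)
    return linkage(points, method="single")[:, 2]


def compute_features(
    loc_xy: np.ndarray,
    loc_channel: np.ndarray,
    mol_xy: np.ndarray | None = None,
    pixel_nm: float = DEFAULT_PIXEL_NM,
    skew_mode: str = "axis_norm",
) -> ClusterFeatures:
    """Compute the 12 descriptors for one cluster.

    Parameters
    ----------
    loc_xy : (n, 2) localization coordinates in nm.
    loc_channel : (n,) channel of each localization (1 or 2).
    mol_xy : molecule positions used for the merge-distance features;
        defaults to ``loc_xy``.
    pixel_nm : grid pitch for the discretised (pixelated support) area.
    skew_mode : ``axis_norm`` (default), ``axis_max`` or ``radial``.

    Degenerate geometry (fewer than 3 points, or collinear) zeroes the
    hull-based features and sets ``degenerate=True``.
    """
    loc_xy = np.asarray(loc_xy, dtype=float)
    loc_channel = np.asarray(loc_channel)
    n = len(loc_xy)
    if n == 0:
        raise ValueError("cluster has no localizations")
    centroid = loc_xy.mean(axis=0)
    rg = float(np.sqrt(((loc_xy - centroid) ** 2).sum(axis=1).mean()))
    length = float(pdist(loc_xy).max()) if n > 1 else 0.0

    area, perimeter, degenerate = _hull_metrics(loc_xy)
    circularity = 0.0
    if not degenerate and perimeter > 0:
        circularity = min(1.0, 4.0 * np.pi * area / perimeter**2)
    density = n / area if area > 0 else 0.0

    pix = np.floor(loc_xy / pixel_nm).astype(np.int64)
    discretised_area = len({(int(a), int(b)) for a, b in pix}) * pixel_nm**2

    md = _merge_distances(loc_xy if mol_xy is None else np.asarray(mol_xy, float))
    distance_birth = float(np.median(md)) if len(md) else 0.0
    distance_depth = float(md.max() - md.min()) if len(md) else 0.0

    return ClusterFeatures(
        radius_of_gyration=rg,
        num_localisations=n,
        convex_hull_area=area,
        distance_birth=distance_birth,
        skew=_skew_value(loc_xy, centroid, skew_mode),
        discretised_area=float(discretised_area),
        distance_depth=distance_depth,
        circularity=circularity,
        density=float(density),
        length=length,
        ch1_binned_counts=int((loc_channel == int(Channel.CH1)).sum()),
        ch2_binned_counts=int((loc_channel == int(Channel.CH2)).sum()),
        degenerate=degenerate,
    )


def shape_filter(
    features: ClusterFeatures,
    skew_range: tuple[float, float] = DEFAULT_SKEW_RANGE,
    circ_range: tuple[float, float] = DEFAULT_CIRC_RANGE,
) -> bool:
    """True iff skew and circularity fall inside the (inclusive) ranges."""
    return (
        skew_range[0] <= features.skew <= skew_range[1]
        and circ_range[0] <= features.circularity <= circ_range[1]
    )
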