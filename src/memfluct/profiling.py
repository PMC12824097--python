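"""Correlative cluster-local tension profiling.

Registers fluorescence frames to tension maps by integer translation,
locates ligand clusters as thresholded local maxima, extracts 11-pixel
center-normalized line scans of tension or SD_time, pools them by distance
from the cluster center, computes the maximal local tension surge within a
fixed radius, and compares distributions with an exact small-sample
Mann-Whitney U test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from skimage.feature import peak_local_max

from .mechanics import TensionMap

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterSet",
    "ClusterScan",
    "ClusterTensionProfile",
    "SurgeStat",
    "register_frames",
    "detect_clusters",
    "line_scan_profiles",
    "radial_average",
    "tension_surge",
    "baseline_backtrace",
    "mann_whitney_u",
]

#: default pixel size of the correlative sets, nm
DEFAULT_PIXEL_SIZE = 65.0


@dataclass
class ClusterSet:
    """Detected cluster centers, ordered by peak value descending."""

    centers: List[Tuple[int, int]]
    peak_values: List[float]
    excluded_edge: int = 0

    def __post_init__(self) -> None:
        if len(self.centers) != len(set(self.centers)):
            raise ValueError("cluster centers must be unique")

    def __len__(self) -> int:
        return len(self.centers)


@dataclass
class ClusterScan:
    """Paired x/y line scans through one cluster center (NaN = filtered)."""

    center: Tuple[int, int]
    x_scan: np.ndarray   # along columns, length 2*half_length+1
    y_scan: np.ndarray   # along rows


@dataclass
class ClusterTensionProfile:
    """Center-normalized mean profile versus distance from cluster center."""

    distance: np.ndarray          # nm, 0 .. half_length*pixel_size
    mean_norm: np.ndarray
    sem: np.ndarray
    n_clusters: int


@dataclass
class SurgeStat:
    max_surge: Optional[float]          # pN/um
    local_mean_norm: Optional[float] = None
    valid: bool = True


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

def register_frames(reference, moving, max_shift: int = 10) -> Tuple[int, int]:
    """Integer shift of ``moving`` relative to ``reference`` maximizing
    normalized cross-correlation over the overlap.

    The returned shift s satisfies moving[i, j] == reference[i - s0, j - s1]
    over the overlap for a pure translation (so ``np.roll(reference, s)``
    reproduces ``moving``).  Ties are broken toward smaller shift magnitude,
    then lexicographically.
    """
    reference = np.asarray(reference, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if reference.shape != moving.shape:
        raise ValueError("images must share one shape")
    h, w = reference.shape
    if max_shift >= min(h, w):
        raise ValueError("max_shift must be smaller than the image size")
    candidates = []
    for dr in range(-max_shift, max_shift + 1):
        for dc in range(-max_shift, max_shift + 1):
            r0, r1 = max(0, dr), min(h, h + dr)
            c0, c1 = max(0, dc), min(w, w + dc)
            ref_part = reference[r0:r1, c0:c1]
            mov_part = moving[r0 - dr:r1 - dr, c0 - dc:c1 - dc]
            a = ref_part - ref_part.mean()
            b = mov_part - mov_part.mean()
            denom = np.sqrt((a * a).sum() * (b * b).sum())
            ncc = (a * b).sum() / denom if denom > 0 else 0.0
            candidates.append((-ncc, abs(dr) + abs(dc), dr, dc))
    candidates.sort()
    _, _, dr, dc = candidates[0]
    return (-dr, -dc)


# ---------------------------------------------------------------------------
# cluster detection
# ---------------------------------------------------------------------------

def detect_clusters(fluor, min_separation: int = 3,
                    threshold: Optional[float] = None,
                    quantile: Optional[float] = None,
                    edge_margin: int = 5,
                    cell_mask=None) -> ClusterSet:
    """Local intensity maxima above threshold, away from the image edge.

    Exactly one of ``threshold`` (absolute) or ``quantile`` must be given.
    Peaks closer than ``edge_margin`` to the border (or outside
    ``cell_mask``) are rejected and counted in ``excluded_edge``.
    """
    fluor = np.asarray(fluor, dtype=float)
    if (threshold is None) == (quantile is None):
        raise ValueError("give exactly one of threshold or quantile")
    if quantile is not None:
        threshold = float(np.quantile(fluor, quantile))
    peaks = peak_local_max(fluor, min_distance=min_separation,
                           threshold_abs=threshold, exclude_border=False)
    h, w = fluor.shape
    centers: List[Tuple[int, int]] = []
    values: List[float] = []
    excluded = 0
    for r, c in peaks:
        inside = (edge_margin <= r < h - edge_margin
                  and edge_margin <= c < w - edge_margin)
        if inside and cell_mask is not None:
            inside = bool(cell_mask[r, c])
        if not inside:
            excluded += 1
            continue
        centers.append((int(r), int(c)))
        values.append(float(fluor[r, c]))
    order = sorted(range(len(centers)), key=lambda i: (-values[i], centers[i]))
    return ClusterSet(centers=[centers[i] for i in order],
                      peak_values=[values[i] for i in order],
                      excluded_edge=excluded)


# ---------------------------------------------------------------------------
# line scans and radial pooling
# ---------------------------------------------------------------------------

def _masked_field(tension_map, field: str) -> np.ndarray:
    if isinstance(tension_map, TensionMap):
        data = getattr(tension_map,
                       "sigma_map" if field == "sigma" else "sd_time_map")
        out = np.where(tension_map.valid_mask, data, np.nan)
        return np.asarray(out, dtype=float)
    return np.asarray(tension_map, dtype=float)


def line_scan_profiles(tension_map, clusters: ClusterSet,
                       half_length: int = 5,
                       field: str = "sigma") -> List[ClusterScan]:
    """11-sample x and y scans through each cluster center.

    ``tension_map`` may be a TensionMap (its validity mask propagates as NaN)
    or a plain 2-D field.  Clusters closer than ``half_length`` to the border
    are skipped with a warning.
    """
    data = _masked_field(tension_map, field)
    h, w = data.shape
    scans: List[ClusterScan] = []
    for r, c in clusters.centers:
        if not (half_length <= r < h - half_length
                and half_length <= c < w - half_length):
            logger.warning("cluster at %s too close to border; skipped", (r, c))
            continue
        x_scan = data[r, c - half_length:c + half_length + 1].copy()
        y_scan = data[r - half_length:r + half_length + 1, c].copy()
        scans.append(ClusterScan(center=(r, c), x_scan=x_scan, y_scan=y_scan))
    return scans


def radial_average(scans: Sequence[ClusterScan], pixel_size: float = DEFAULT_PIXEL_SIZE,
                   normalize_center: bool = True) -> ClusterTensionProfile:
    """Pool scans by absolute offset from the center.

    Each scan is divided by its center value; the up-to-four samples of a
    cluster at the same distance (x+/-, y+/-) contribute jointly as one
    per-cluster value, and mean/SEM are taken across clusters.  Scans with a
    missing or zero center sample are dropped with a warning.
    """
    if not scans:
        raise ValueError("no scans given")
    half = (len(scans[0].x_scan) - 1) // 2
    per_cluster: List[np.ndarray] = []
    for scan in scans:
        center_value = scan.x_scan[half]
        if not np.isfinite(center_value) or center_value == 0:
            logger.warning("scan at %s has invalid center; dropped", scan.center)
            continue
        x = scan.x_scan / center_value
        y = scan.y_scan / center_value
        profile = np.empty(half + 1)
        for d in range(half + 1):
            if d == 0:
                samples = np.array([x[half]])
            else:
                samples = np.array([x[half - d], x[half + d],
                                    y[half - d], y[half + d]])
            finite = samples[np.isfinite(samples)]
            profile[d] = finite.mean() if finite.size else np.nan
        per_cluster.append(profile)
    if not per_cluster:
        raise ValueError("all scans dropped: no valid center samples")
    stacked = np.vstack(per_cluster)
    mean = np.nanmean(stacked, axis=0)
    counts = np.sum(np.isfinite(stacked), axis=0)
    sem = np.zeros(stacked.shape[1])
    for d in range(stacked.shape[1]):
        col = stacked[:, d]
        col = col[np.isfinite(col)]
        if col.size > 1:
            sem[d] = col.std(ddof=1) / np.sqrt(col.size)
    distance = np.arange(half + 1) * pixel_size
    return ClusterTensionProfile(distance=distance, mean_norm=mean, sem=sem,
                                 n_clusters=stacked.shape[0])


# ---------------------------------------------------------------------------
# local tension surge
# ---------------------------------------------------------------------------

def tension_surge(tension_map, center: Tuple[int, int], radius_px: int = 5,
                  baseline_map=None, window: int = 10) -> SurgeStat:
    """Maximal tension increase within ``radius_px`` (325 nm at 65 nm/px).

    ``max_surge`` is the maximum over valid pixels within Euclidean distance
    ``radius_px`` of (sigma_pixel - sigma_center).  With ``baseline_map``
    given, ``local_mean_norm`` is the mean sigma over a ``window`` x
    ``window`` box around the center divided by the same-window baseline
    mean.
    """
    data = _masked_field(tension_map, "sigma")
    h, w = data.shape
    r0, c0 = center
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise ValueError("center outside map")
    center_value = data[r0, c0]
    if not np.isfinite(center_value):
        return SurgeStat(max_surge=None, valid=False)
    rows, cols = np.mgrid[0:h, 0:w]
    within = (rows - r0) ** 2 + (cols - c0) ** 2 <= radius_px ** 2
    values = data[within]
    values = values[np.isfinite(values)]
    if values.size == 0:
        return SurgeStat(max_surge=None, valid=False)
    max_surge = float(values.max() - center_value)
    local_mean_norm = None
    if baseline_map is not None:
        base = _masked_field(baseline_map, "sigma")
        lo_r = max(0, r0 - window // 2)
        lo_c = max(0, c0 - window // 2)
        box = (slice(lo_r, lo_r + window), slice(lo_c, lo_c + window))
        local = data[box]
        local_base = base[box]
        if np.any(np.isfinite(local)) and np.nanmean(local_base) not in (0,):
            local_mean_norm = float(np.nanmean(local) / np.nanmean(local_base))
    return SurgeStat(max_surge=max_surge, local_mean_norm=local_mean_norm,
                     valid=True)


def baseline_backtrace(pre_map, post_fluor, shift: Tuple[int, int],
                       **detect_kwargs) -> Tuple[ClusterSet, int]:
    """Detect clusters on the post-treatment frame and map them into
    pre-treatment coordinates by undoing the registration shift.

    Returns the translated cluster set and the number of centers dropped for
    falling outside the pre-treatment map.
    """
    data = _masked_field(pre_map, "sigma")
    h, w = data.shape
    clusters = detect_clusters(np.asarray(post_fluor, dtype=float),
                               **detect_kwargs)
    dr, dc = shift
    centers: List[Tuple[int, int]] = []
    values: List[float] = []
    dropped = 0
    for (r, c), v in zip(clusters.centers, clusters.peak_values):
        nr, nc = r - dr, c - dc
        if 0 <= nr < h and 0 <= nc < w:
            centers.append((nr, nc))
            values.append(v)
        else:
            dropped += 1
    translated = ClusterSet(centers=centers, peak_values=values,
                            excluded_edge=clusters.excluded_edge)
    return translated, dropped


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _u_distribution(n1: int, n2: int) -> Tuple[int, ...]:
    """Counts of arrangements giving each U value, for tie-free samples.

    Standard recursion: f(n1, n2, u) = f(n1-1, n2, u-n2) + f(n1, n2-1, u).
    """
    max_u = n1 * n2
    # table[i][j] = array over u of counts for sample sizes i, j
    table: Dict[Tuple[int, int], np.ndarray] = {}
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            counts = np.zeros(max_u + 1, dtype=object)
            if i == 0 or j == 0:
                counts[0] = 1
            else:
                prev_i = table[(i - 1, j)]
                prev_j = table[(i, j - 1)]
                for u in range(i * j + 1):
                    total = 0
                    if u - j >= 0 and u - j <= (i - 1) * j:
                        total += prev_i[u - j]
                    if u <= i * (j - 1):
                        total += prev_j[u]
                    counts[u] = total
            table[(i, j)] = counts
    return tuple(int(v) for v in table[(n1, n2)])


def mann_whitney_u(a, b, alternative: str = "two-sided") -> Tuple[float, float]:
    """Mann-Whitney U test of two independent samples.

    U is the statistic of the first sample computed from midrank sums.  The
    p-value is exact (full enumeration of the tie-free permutation
    distribution) when min(n1, n2) <= 8 and there are no ties, and uses the
    normal approximation with tie correction otherwise.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError("alternative must be two-sided, less or greater")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    rank_sum_a = ranks[:n1].sum()
    u1 = rank_sum_a - n1 * (n1 + 1) / 2.0
    has_ties = np.unique(pooled).size < pooled.size
    if min(n1, n2) <= 8 and not has_ties:
        counts = np.array(_u_distribution(n1, n2), dtype=float)
        total = counts.sum()
        u_int = int(round(u1))
        p_less = counts[:u_int + 1].sum() / total       # P(U <= u1)
        p_greater = counts[u_int:].sum() / total        # P(U >= u1)
        if alternative == "less":
            p = p_less
        elif alternative == "greater":
            p = p_greater
        else:
            p = min(1.0, 2.0 * min(p_less, p_greater))
        return float(u1), float(p)
    # normal approximation with tie correction
    mean_u = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var_u <= 0:
        return float(u1), 1.0
    if alternative == "less":
        z = (u1 - mean_u + 0.5) / math.sqrt(var_u)
        p = stats.norm.cdf(z)
    elif alternative == "greater":
        z = (u1 - mean_u - 0.5) / math.sqrt(var_u)
        p = stats.norm.sf(z)
    else:
        z = (u1 - mean_u - np.sign(u1 - mean_u) * 0.5) / math.sqrt(var_u)
        p = 2.0 * stats.norm.sf(abs(z))
    return float(u1), float(min(p, 1.0))
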