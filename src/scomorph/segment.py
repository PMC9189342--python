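"""Compartment and cell segmentation with classical operators.

The original workflow predicts glomerular outlines with a trained UNet and
nuclei with StarDist.  Here classical operators (smoothing, Otsu,
morphology, distance-transform watershed) are the default, and externally
predicted label masks can be loaded as first-class inputs, so the analysis
is self-contained while staying compatible with a deep-learning handoff.

Conventions: 0-based pixel indexing, arrays stored (row=y, col=x); label 0
is background and object labels form a contiguous set {1..K}.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import closing as gray_closing, disk
from skimage.segmentation import expand_labels, watershed

from .io import ChannelStack, DEFAULT_PIXEL_SIZE_UM


@dataclass
class LabelMask:
    """Non-negative integer image; 0 = background, k > 0 = object k."""

    labels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError(f"label image must be 2D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError(f"label image must be integer, got dtype {self.labels.dtype}")
        if self.labels.min(initial=0) < 0:
            raise ValueError("label image contains negative values")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def ids(self) -> np.ndarray:
        """Sorted nonzero label ids present in the mask."""
        u = np.unique(self.labels)
        return u[u > 0]

    @property
    def n_labels(self) -> int:
        return len(self.ids)

    def relabel(self) -> "LabelMask":
        """Map labels onto the contiguous set {1..K}, preserving geometry
        and the relative order of the original ids."""
        ids = self.ids
        lut = np.zeros(int(self.labels.max(initial=0)) + 1, dtype=np.int32)
        lut[ids] = np.arange(1, len(ids) + 1, dtype=np.int32)
        return LabelMask(lut[self.labels], self.pixel_size_um)

    def areas_um2(self) -> dict[int, float]:
        counts = np.bincount(self.labels.ravel())
        px2 = self.pixel_size_um ** 2
        return {int(i): float(counts[i] * px2) for i in self.ids}


# ---------------------------------------------------------------------------
# Glomeruli
# ---------------------------------------------------------------------------

@dataclass
class GlomSegParams:
    """Classical glomerular-tuft segmentation from the IF channel."""

    smooth_sigma_px: float = 2.0
    threshold: float | None = None      # None -> Otsu on the clipped image
    clip_percentile: float = 99.0       # tames rare ultra-bright marker nuclei
    closing_radius_um: float = 1.0
    min_area_um2: float = 700.0         # discards sub-glomerular IF specks


def segment_glomeruli(stack: ChannelStack, if_channel: str = "if",
                      params: GlomSegParams | None = None) -> LabelMask:
    """Segment bright glomerular-tuft regions in the immunofluorescence channel.

    Pipeline: Gaussian smoothing -> global threshold (Otsu unless given) ->
    morphological closing -> hole filling -> minimum-area filter ->
    connected-component labels.  An empty result (no glomeruli in the field)
    is valid and yields a zero mask.
    """
    params = params or GlomSegParams()
    img = np.asarray(stack.channel(if_channel), dtype=np.float64)
    ps = stack.pixel_size_um
    smooth = gaussian(img, sigma=params.smooth_sigma_px, preserve_range=True)
    thr = params.threshold
    if thr is None:
        # the IF channel can carry both the tuft stain and a much brighter
        # but rare nuclear marker; clipping at a high percentile keeps Otsu
        # anchored on the background/tuft transition (a real tuft, given the
        # minimum-area filter, always covers far more than 1% of the field)
        clipped = np.minimum(smooth, np.percentile(smooth, params.clip_percentile))
        if np.ptp(clipped) == 0:
            return LabelMask(np.zeros(img.shape, dtype=np.int32), ps)
        thr = float(threshold_otsu(clipped))
    binary = smooth > thr
    radius_px = max(int(round(params.closing_radius_um / ps)), 1)
    binary = gray_closing(binary, disk(radius_px))
    binary = ndimage.binary_fill_holes(binary)
    labels = cc_label(binary, connectivity=2)
    min_px = params.min_area_um2 / ps**2
    counts = np.bincount(labels.ravel())
    keep = np.flatnonzero(counts >= min_px)
    keep = keep[keep > 0]
    mask = np.isin(labels, keep) * labels
    return LabelMask(mask.astype(np.int32), ps).relabel()


# ---------------------------------------------------------------------------
# Nuclei
# ---------------------------------------------------------------------------

@dataclass
class NucSegParams:
    """Nucleus segmentation from the DAPI channel."""

    smooth_sigma_px: float = 1.0
    threshold: float | None = None      # None -> Otsu
    min_distance_um: float = 3.0        # watershed seed separation
    min_area_um2: float = 10.0


def segment_nuclei(stack: ChannelStack, dapi_channel: str = "dapi",
                   params: NucSegParams | None = None) -> LabelMask:
    """Segment nuclei: smoothing -> threshold -> distance-transform watershed.

    Touching nuclei are split by seeding the watershed at local maxima of
    the Euclidean distance transform; objects below ``min_area_um2`` are
    dropped and the result is relabeled to {1..K}.
    """
    from skimage.feature import peak_local_max

    params = params or NucSegParams()
    img = np.asarray(stack.channel(dapi_channel), dtype=np.float64)
    ps = stack.pixel_size_um
    smooth = gaussian(img, sigma=params.smooth_sigma_px, preserve_range=True)
    thr = params.threshold
    if thr is None:
        if np.ptp(smooth) == 0:
            return LabelMask(np.zeros(img.shape, dtype=np.int32), ps)
        thr = threshold_otsu(smooth)
    binary = smooth > thr
    if not binary.any():
        return LabelMask(np.zeros(img.shape, dtype=np.int32), ps)
    edt = ndimage.distance_transform_edt(binary)
    min_dist_px = max(int(round(params.min_distance_um / ps)), 1)
    peaks = peak_local_max(edt, min_distance=min_dist_px, labels=binary,
                           exclude_border=False)
    markers = np.zeros(img.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-edt, markers, mask=binary)
    min_px = params.min_area_um2 / ps**2
    counts = np.bincount(labels.ravel())
    small = np.flatnonzero(counts < min_px)
    labels[np.isin(labels, small[small > 0])] = 0
    return LabelMask(labels.astype(np.int32), ps).relabel()


# ---------------------------------------------------------------------------
# External masks
# ---------------------------------------------------------------------------

def load_external_mask(path: str | Path, expected_shape: tuple[int, int],
                       pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> LabelMask:
    """Load an externally predicted mask (e.g. a UNet/StarDist prediction).

    Binary masks (one nonzero value) are connected-component labeled;
    already-labeled images are passed through with relabeling to {1..K}.
    """
    path = Path(path)
    data = tifffile.imread(str(path))
    if data.ndim == 3 and data.shape[0] == 1:
        data = data[0]
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel mask, got shape {data.shape}")
    if data.shape != tuple(expected_shape):
        raise ValueError(
            f"{path}: mask shape {data.shape} does not match image shape "
            f"{tuple(expected_shape)}")
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.round(data)
        if not np.allclose(data, rounded):
            raise ValueError(f"{path}: mask has non-integer pixel values")
        data = rounded.astype(np.int64)
    nonzero = np.unique(data[data > 0])
    if len(nonzero) == 1:  # binary mask -> connected components
        labels = cc_label(data > 0, connectivity=2)
        return LabelMask(labels.astype(np.int32), pixel_size_um)
    return LabelMask(data.astype(np.int32), pixel_size_um).relabel()


# ---------------------------------------------------------------------------
# Cell territories
# ---------------------------------------------------------------------------

def expand_cell_territories(nuclei: LabelMask, radius_um: float) -> LabelMask:
    """Grow each nucleus into a cell territory up to ``radius_um``.

    Background pixels within the radius are claimed by the nearest nucleus
    (Euclidean distance to the label's pixel set); growth stops where two
    territories meet.  Every territory is a superset of its nucleus, and
    ``radius_um = 0`` returns the input unchanged.
    """
    if radius_um < 0:
        raise ValueError("radius_um must be non-negative")
    radius_px = radius_um / nuclei.pixel_size_um
    if radius_px == 0:
        return LabelMask(nuclei.labels.copy(), nuclei.pixel_size_um)
    expanded = expand_labels(nuclei.labels, distance=radius_px)
    return LabelMask(expanded.astype(np.int32), nuclei.pixel_size_um)


# ---------------------------------------------------------------------------
# Marker positivity
# ---------------------------------------------------------------------------

@dataclass
class MarkerCalls:
    """Per-nucleus marker (e.g. nuclear WT1) positivity calls."""

    positive: dict[int, bool]
    mean_intensity: dict[int, float]
    threshold: float
    policy: str
    fallback: bool = False  # True when Otsu was undefined and absolute was used

    def __post_init__(self) -> None:
        if set(self.positive) != set(self.mean_intensity):
            raise ValueError("positive and mean_intensity must cover the same labels")


def _exact_otsu(values: np.ndarray) -> float:
    """Otsu's criterion computed exactly on a small sample.

    Histogram-binned Otsu can misplace the cut when a whole cluster falls
    into one bin; with at most a few thousand per-label means, sweeping
    every cut between consecutive sorted values is exact.  The returned
    threshold is the midpoint of the optimal gap.
    """
    v = np.sort(np.asarray(values, dtype=np.float64))
    n = len(v)
    best_var, best_thr = -np.inf, v[0]
    csum = np.cumsum(v)
    total = csum[-1]
    for k in range(1, n):  # lower class = v[:k]
        if v[k] == v[k - 1]:
            continue
        w0 = k / n
        mu0 = csum[k - 1] / k
        mu1 = (total - csum[k - 1]) / (n - k)
        var = w0 * (1 - w0) * (mu0 - mu1) ** 2
        if var > best_var:
            best_var = var
            best_thr = (v[k - 1] + v[k]) / 2
    return float(best_thr)


def classify_marker_positive(nuclei: LabelMask, marker_channel: np.ndarray,
                             policy: str = "otsu",
                             threshold: float | None = None) -> MarkerCalls:
    """Call each nucleus marker-positive from its mean marker intensity.

    ``policy="otsu"`` thresholds the distribution of per-label means
    (the default); ``policy="absolute"`` uses the given ``threshold``.
    With fewer than two labels, or a degenerate mean distribution, Otsu is
    undefined: the call falls back to the absolute threshold (all-negative
    if none was given) and sets ``fallback=True``.
    """
    marker = np.asarray(marker_channel, dtype=np.float64)
    if marker.shape != nuclei.shape:
        raise ValueError(
            f"marker channel shape {marker.shape} does not match mask shape "
            f"{nuclei.shape}")
    if policy not in ("otsu", "absolute"):
        raise ValueError(f"unknown policy {policy!r}")
    ids = nuclei.ids
    if len(ids) == 0:
        return MarkerCalls({}, {}, threshold=np.inf, policy=policy)
    means = ndimage.mean(marker, labels=nuclei.labels, index=ids)
    means_map = {int(i): float(m) for i, m in zip(ids, means)}
    fallback = False
    if policy == "otsu":
        if len(ids) >= 2 and np.ptp(means) > 0:
            thr = _exact_otsu(np.asarray(means))
        else:
            fallback = True
            thr = float(threshold) if threshold is not None else np.inf
    else:
        if threshold is None:
            raise ValueError("absolute policy requires a threshold")
        thr = float(threshold)
    positive = {i: m > thr for i, m in means_map.items()}
    return MarkerCalls(positive, means_map, threshold=thr,
                       policy=policy, fallback=fallback)
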