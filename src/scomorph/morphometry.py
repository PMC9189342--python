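"""Filtration-slit-density (FSD) morphometry from a slit-diaphragm channel.

In super-resolved micrographs the podocin-labelled filtration slit
appears as a curvilinear line pattern.  FSD — total slit length per
region area, in µm⁻¹ — is the standard readout of podocyte foot-process
effacement: effaced foot processes produce fewer, sparser slits and a
lower FSD.  The measurable core implemented here is: binarize the slit
signal, skeletonize it, sum skeleton edge lengths (1 px for orthogonal
steps, √2 px for diagonal steps), and divide by the region area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from skimage.filters import gaussian, threshold_otsu
from skimage.morphology import remove_small_objects, skeletonize


@dataclass
class SlitBinarizeParams:
    smooth_sigma_px: float = 1.0
    threshold: float | None = None   # None -> Otsu
    min_size_px: int = 10


@dataclass
class FSDResult:
    """Filtration slit density of one region."""

    slit_length_um: float
    region_area_um2: float
    fsd_per_um: float
    region_id: int = 1

    def __post_init__(self) -> None:
        if self.slit_length_um < 0 or self.region_area_um2 < 0:
            raise ValueError("lengths and areas must be non-negative")


def binarize_slit(image: np.ndarray,
                  params: SlitBinarizeParams | None = None) -> np.ndarray:
    """Binarize the slit-diaphragm signal: smooth -> threshold -> despeckle."""
    params = params or SlitBinarizeParams()
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError(f"expected a single-channel image, got shape {image.shape}")
    smooth = gaussian(image, sigma=params.smooth_sigma_px, preserve_range=True)
    thr = params.threshold
    if thr is None:
        if np.ptp(smooth) == 0:
            return np.zeros(image.shape, dtype=bool)
        thr = threshold_otsu(smooth)
    mask = smooth > thr
    if params.min_size_px > 1:
        # drop objects with fewer than min_size_px pixels
        mask = remove_small_objects(mask, max_size=params.min_size_px - 1)
    return mask


def skeleton_length(mask: np.ndarray, pixel_size_um: float) -> float:
    """Centerline length of a binary structure in µm.

    The mask is reduced to its topological skeleton; length is the sum
    over 8-connected skeleton edges of 1 (orthogonal) or √2 (diagonal)
    pixel pitches.  Diagonal edges that shortcut an existing orthogonal
    path (i.e. the two pixels share an orthogonal skeleton neighbour) are
    not counted, so a staircase is not double-counted.  An isolated
    skeleton pixel contributes zero length.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 0.0
    skel = skeletonize(mask)
    s = skel.astype(np.int8)
    # orthogonal edges: right and down neighbour pairs
    n_orth = int(np.sum(s[:, :-1] & s[:, 1:]) + np.sum(s[:-1, :] & s[1:, :]))
    # diagonal edges, skipping those bridged by an orthogonal neighbour
    dr = s[:-1, :-1] & s[1:, 1:]          # down-right pairs
    dr_bridge = s[:-1, 1:] | s[1:, :-1]
    dl = s[:-1, 1:] & s[1:, :-1]          # down-left pairs
    dl_bridge = s[:-1, :-1] | s[1:, 1:]
    n_diag = int(np.sum(dr & ~dr_bridge.astype(bool)) +
                 np.sum(dl & ~dl_bridge.astype(bool)))
    return (n_orth + math.sqrt(2) * n_diag) * pixel_size_um


def filtration_slit_density(slit_channel: np.ndarray, region_mask: np.ndarray,
                            pixel_size_um: float,
                            params: SlitBinarizeParams | None = None,
                            region_id: int = 1) -> FSDResult:
    """FSD of the slit signal restricted to one region.

    The slit channel is binarized over the whole field, intersected with
    the region, skeletonized, and its length divided by the region area.
    An empty region is an error naming the region id.
    """
    region = np.asarray(region_mask, dtype=bool)
    if region.shape != np.asarray(slit_channel).shape:
        raise ValueError("region mask shape does not match slit channel")
    n_px = int(region.sum())
    if n_px == 0:
        raise ValueError(f"region {region_id} is empty")
    mask = binarize_slit(slit_channel, params) & region
    length = skeleton_length(mask, pixel_size_um)
    area = n_px * pixel_size_um ** 2
    return FSDResult(slit_length_um=length, region_area_um2=area,
                     fsd_per_um=length / area, region_id=region_id)


def fsd_per_label(slit_channel: np.ndarray, labels: np.ndarray,
                  pixel_size_um: float,
                  params: SlitBinarizeParams | None = None) -> list[FSDResult]:
    """FSD for every nonzero label of a region label image."""
    labels = np.asarray(labels)
    out = []
    for rid in np.unique(labels):
        if rid == 0:
            continue
        out.append(filtration_slit_density(
            slit_channel, labels == rid, pixel_size_um, params, region_id=int(rid)))
    return out
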