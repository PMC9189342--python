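"""Compartment / single-cell transcript quantification and glomerular morphometry.

The core script logic: every detected spot is assigned to a cell
territory and a tissue compartment (intraglomerular vs tubulointerstitial)
by direct label-mask lookup at its rounded pixel; per-cell counts are
tallied and normalized to the on-slide reference transcript as the
per-cell ratio target/reference; podocytes are the marker-positive
intraglomerular cells; per-glomerulus morphometry (tuft area, Feret
diameter, podocyte density) is exported.

Conservation holds exactly by construction: per channel, the summed
per-cell counts plus unassigned spots equal the number of detected
in-bounds spots, and intra- plus extraglomerular area equal the analyzed
tissue area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .segment import LabelMask, MarkerCalls
from .spots import SpotTable

GLOMERULAR = "glomerular"
TUBULOINTERSTITIAL = "tubulointerstitial"


@dataclass
class CellRecord:
    """One segmented cell with compartment, marker status and expression."""

    cell_id: int
    centroid: tuple[float, float]          # (x, y) in px
    nucleus_area_um2: float
    compartment: str                       # glomerular | tubulointerstitial
    glom_id: int | None                    # owning glomerulus, None if extraglomerular
    marker_positive: bool
    raw_counts: dict[str, int] = field(default_factory=dict)
    normalized_expression: float | None = None
    image_id: str = ""

    def __post_init__(self) -> None:
        if (self.compartment == GLOMERULAR) != (self.glom_id is not None):
            raise ValueError(
                f"cell {self.cell_id}: compartment {self.compartment!r} "
                f"inconsistent with glom_id {self.glom_id!r}")
        if any(c < 0 for c in self.raw_counts.values()):
            raise ValueError(f"cell {self.cell_id}: negative raw counts")


@dataclass
class CompartmentSummary:
    """Per-image intra/extraglomerular areas and transcript totals."""

    intra_area_um2: float
    extra_area_um2: float
    intra_counts: dict[str, int]
    extra_counts: dict[str, int]
    unassigned_counts: dict[str, int]      # spots not inside any cell territory
    rejected_spots: int = 0                # out-of-bounds spots


@dataclass
class GlomRecord:
    """Morphometry of one glomerular cross-section."""

    glom_id: int
    tuft_area_um2: float
    feret_diameter_um: float
    podocyte_count: int
    podocyte_density_per_mm2: float


ASSIGNMENT_COLUMNS = ["channel", "x", "y", "cell_id", "glom_id", "compartment"]


def assign_spots(spots: SpotTable, territories: LabelMask,
                 glom: LabelMask) -> pd.DataFrame:
    """Assign each spot to a cell territory and a compartment.

    A spot belongs to the territory label at its rounded pixel (0 = no
    cell) and is intraglomerular iff that pixel lies inside a glomerulus
    label.  Spots whose rounded pixel falls outside the image are
    excluded and tallied in ``result.attrs['n_rejected']``.
    """
    if territories.shape != glom.shape:
        raise ValueError(
            f"territory shape {territories.shape} != glomerulus mask shape "
            f"{glom.shape}")
    H, W = territories.shape
    rows = []
    n_rejected = 0
    for s in spots.spots:
        r = int(np.round(s.y))
        c = int(np.round(s.x))
        if not (0 <= r < H and 0 <= c < W):
            n_rejected += 1
            continue
        gid = int(glom.labels[r, c])
        rows.append({
            "channel": s.channel_role, "x": s.x, "y": s.y,
            "cell_id": int(territories.labels[r, c]),
            "glom_id": gid,
            "compartment": GLOMERULAR if gid > 0 else TUBULOINTERSTITIAL,
        })
    frame = pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)
    frame.attrs["n_rejected"] = n_rejected
    frame.attrs["image_id"] = spots.image_id
    return frame


def build_cell_records(nuclei: LabelMask, territories: LabelMask,
                       glom: LabelMask, marker_calls: MarkerCalls,
                       assignments: pd.DataFrame,
                       channels: tuple[str, ...] = ("fish1", "fish2"),
                       ) -> list[CellRecord]:
    """One record per nucleus, with compartment from the nucleus centroid.

    A cell is glomerular iff the pixel under its nucleus centroid carries
    a glomerulus label (boundary pixels with label > 0 count as inside).
    Raw counts are tallied from the assignment table; an assignment
    referencing an unknown cell id is a hard failure.
    """
    ids = [int(i) for i in nuclei.ids]
    id_set = set(ids)
    if set(marker_calls.positive) != id_set:
        raise ValueError("marker calls do not cover the nucleus label set")
    assigned_ids = set(int(i) for i in assignments["cell_id"].unique()) - {0}
    unknown = assigned_ids - id_set
    if unknown:
        raise ValueError(f"assignments reference unknown cell ids: {sorted(unknown)}")

    counts = {ch: {} for ch in channels}
    if len(assignments):
        tally = assignments[assignments["cell_id"] > 0].groupby(
            ["channel", "cell_id"]).size()
        for (ch, cid), n in tally.items():
            if ch in counts:
                counts[ch][int(cid)] = int(n)

    ps = nuclei.pixel_size_um
    centroids = ndimage.center_of_mass(np.ones(nuclei.shape), nuclei.labels, ids)
    areas = np.bincount(nuclei.labels.ravel())
    records = []
    for cid, (cy, cx) in zip(ids, centroids):
        r, c = int(np.round(cy)), int(np.round(cx))
        r = min(max(r, 0), nuclei.shape[0] - 1)
        c = min(max(c, 0), nuclei.shape[1] - 1)
        gid = int(glom.labels[r, c])
        records.append(CellRecord(
            cell_id=cid,
            centroid=(float(cx), float(cy)),
            nucleus_area_um2=float(areas[cid] * ps**2),
            compartment=GLOMERULAR if gid > 0 else TUBULOINTERSTITIAL,
            glom_id=gid if gid > 0 else None,
            marker_positive=bool(marker_calls.positive[cid]),
            raw_counts={ch: counts[ch].get(cid, 0) for ch in channels},
        ))
    records.sort(key=lambda rec: rec.cell_id)
    return records


def normalize_expression(record: CellRecord, target_channel: str,
                         reference_channel: str) -> float | None:
    """Per-cell normalized expression: target count / reference count.

    Undefined (``None``) when the reference count is zero; such cells are
    excluded from normalized statistics but kept in raw tables.
    """
    for ch in (target_channel, reference_channel):
        if ch not in record.raw_counts:
            raise KeyError(f"channel {ch!r} not in raw_counts of cell {record.cell_id}")
    ref = record.raw_counts[reference_channel]
    if ref == 0:
        return None
    return record.raw_counts[target_channel] / ref


def select_podocytes(records: list[CellRecord]) -> list[CellRecord]:
    """Marker-positive intraglomerular cells (DAPI positivity is implied by
    having a segmented nucleus)."""
    return [r for r in records
            if r.compartment == GLOMERULAR and r.marker_positive]


def compartment_summary(glom: LabelMask, territories: LabelMask,
                        assignments: pd.DataFrame, pixel_size_um: float,
                        channels: tuple[str, ...] = ("fish1", "fish2"),
                        ) -> CompartmentSummary:
    """Areas and per-channel transcript totals by compartment."""
    if glom.shape != territories.shape:
        raise ValueError("mask shapes differ")
    px2 = pixel_size_um ** 2
    n_intra_px = int((glom.labels > 0).sum())
    n_total_px = glom.labels.size
    intra_counts, extra_counts, unassigned = {}, {}, {}
    for ch in channels:
        sel = assignments[assignments["channel"] == ch]
        intra_counts[ch] = int((sel["compartment"] == GLOMERULAR).sum())
        extra_counts[ch] = int((sel["compartment"] == TUBULOINTERSTITIAL).sum())
        unassigned[ch] = int((sel["cell_id"] == 0).sum())
    return CompartmentSummary(
        intra_area_um2=n_intra_px * px2,
        extra_area_um2=(n_total_px - n_intra_px) * px2,
        intra_counts=intra_counts,
        extra_counts=extra_counts,
        unassigned_counts=unassigned,
        rejected_spots=int(assignments.attrs.get("n_rejected", 0)),
    )


def feret_diameter_px(rows: np.ndarray, cols: np.ndarray) -> float:
    """Maximum caliper over pixel centers plus one pixel pitch.

    The +1 accounts for pixel extent, making a single-pixel object one
    pixel wide rather than zero.
    """
    pts = np.column_stack([rows, cols]).astype(np.float64)
    if len(pts) == 0:
        return 0.0
    if len(pts) <= 2:
        d = 0.0 if len(pts) == 1 else float(np.hypot(*(pts[0] - pts[1])))
        return d + 1.0
    try:
        hull = pts[ConvexHull(pts).vertices]
    except QhullError:  # collinear pixel sets
        hull = pts
    diff = hull[:, None, :] - hull[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=-1)).max()
    return float(d) + 1.0


def glomerular_morphometry(glom: LabelMask, podocytes: list[CellRecord],
                           pixel_size_um: float) -> list[GlomRecord]:
    """Per-glomerulus tuft area, Feret diameter and podocyte density.

    Density is podocytes per mm² of tuft cross-section area.
    """
    px2 = pixel_size_um ** 2
    pod_by_glom: dict[int, int] = {}
    for p in podocytes:
        if p.glom_id is not None:
            pod_by_glom[p.glom_id] = pod_by_glom.get(p.glom_id, 0) + 1
    records = []
    for gid in glom.ids:
        rows, cols = np.nonzero(glom.labels == gid)
        area_um2 = len(rows) * px2
        count = pod_by_glom.get(int(gid), 0)
        records.append(GlomRecord(
            glom_id=int(gid),
            tuft_area_um2=area_um2,
            feret_diameter_um=feret_diameter_px(rows, cols) * pixel_size_um,
            podocyte_count=count,
            podocyte_density_per_mm2=count / (area_um2 / 1e6) if area_um2 > 0 else 0.0,
        ))
    return records
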