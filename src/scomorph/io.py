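"""Readers, writers, run configuration and the batch pipeline driver.

The on-disk conventions follow the acquisition layout of multiplexed
smFISH + immunofluorescence kidney micrographs: multichannel TIFFs with
the immunofluorescence channel first (``C1``), two smFISH channels
(``C2``/``C3``) and DAPI last (``C4``).  All tabular output is CSV with a
stable column order so batch runs are byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("scomorph")

#: channel-role convention: IF in C1, smFISH in C2/C3, DAPI in C4
DEFAULT_CHANNEL_MAP: dict[str, int] = {"if": 0, "fish1": 1, "fish2": 2, "dapi": 3}

#: confocal acquisition pixel pitch, µm (189 nm xy voxel size)
DEFAULT_PIXEL_SIZE_UM = 0.189

FISH_CHANNELS = ("fish1", "fish2")

CELL_COLUMNS = [
    "image_id", "cell_id", "x", "y", "nucleus_area_um2", "compartment",
    "glom_id", "marker_positive", "count_fish1", "count_fish2",
    "normalized_expression",
]
SUMMARY_COLUMNS = [
    "image_id", "intra_area_um2", "extra_area_um2",
    "intra_count_fish1", "extra_count_fish1",
    "intra_count_fish2", "extra_count_fish2",
    "unassigned_fish1", "unassigned_fish2", "rejected_spots",
]
GLOM_COLUMNS = [
    "image_id", "glom_id", "tuft_area_um2", "feret_diameter_um",
    "podocyte_count", "podocyte_density_per_mm2",
]


def configure_logging(level: int = logging.INFO) -> None:
    """Attach a simple stderr handler to the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level)


# ---------------------------------------------------------------------------
# ChannelStack
# ---------------------------------------------------------------------------

@dataclass
class ChannelStack:
    """A registered multichannel 2D image with named channel roles.

    Parameters
    ----------
    channels
        Array of shape ``(C, H, W)``.
    channel_roles
        Map from role name (``"if"``, ``"fish1"``, ``"fish2"``, ``"dapi"``)
        to channel index.
    pixel_size_um
        Physical pixel pitch in µm (square pixels).
    image_id
        Identifier carried into all output tables.
    """

    channels: np.ndarray
    channel_roles: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHANNEL_MAP))
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    image_id: str = ""

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels)
        if self.channels.ndim != 3:
            raise ValueError(
                f"channels must be (C, H, W), got shape {self.channels.shape}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        idx = list(self.channel_roles.values())
        if len(set(idx)) != len(idx):
            raise ValueError(f"channel roles map to duplicate indices: {self.channel_roles}")
        n = self.channels.shape[0]
        bad = {r: i for r, i in self.channel_roles.items() if not 0 <= i < n}
        if bad:
            raise ValueError(
                f"channel roles {bad} out of range for a {n}-channel stack")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[1:]

    def channel(self, role: str) -> np.ndarray:
        """Return the 2D image for a channel role."""
        if role not in self.channel_roles:
            raise KeyError(
                f"channel role {role!r} not in stack (available: "
                f"{sorted(self.channel_roles)})")
        return self.channels[self.channel_roles[role]]


# ---------------------------------------------------------------------------
# TIFF IO
# ---------------------------------------------------------------------------

def _ome_pixel_size(tif: tifffile.TiffFile) -> float | None:
    meta = tif.ome_metadata
    if not meta:
        return None
    m = re.search(r'PhysicalSizeX="([0-9.eE+-]+)"', meta)
    return float(m.group(1)) if m else None


def read_multichannel_tiff(
    path: str | Path,
    channel_map: dict[str, int] | None = None,
    pixel_size_um: float | None = None,
    image_id: str | None = None,
) -> ChannelStack:
    """Read a multichannel TIFF into a :class:`ChannelStack`.

    Accepts ``(C, H, W)`` planes or ``(Z, C, H, W)`` stacks; z-stacks are
    reduced by per-pixel maximum projection (the acquisitions span only
    ~2 µm in z).  OME ``PhysicalSizeX`` metadata supplies the pixel size
    when present; an explicit ``pixel_size_um`` argument overrides it.
    """
    path = Path(path)
    channel_map = dict(channel_map or DEFAULT_CHANNEL_MAP)
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            meta_ps = _ome_pixel_size(tif)
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise OSError(f"cannot read TIFF {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None]
    elif data.ndim == 4:  # (Z, C, H, W) -> max projection over z
        data = data.max(axis=0)
    if data.ndim != 3:
        raise ValueError(f"{path}: unsupported TIFF shape {data.shape}")
    n_needed = max(channel_map.values()) + 1
    if data.shape[0] < n_needed:
        raise ValueError(
            f"{path}: channel map {channel_map} needs {n_needed} channels "
            f"but file has {data.shape[0]}")
    ps = pixel_size_um if pixel_size_um is not None else (meta_ps or DEFAULT_PIXEL_SIZE_UM)
    return ChannelStack(
        channels=np.asarray(data, dtype=np.float32),
        channel_roles=channel_map,
        pixel_size_um=ps,
        image_id=image_id if image_id is not None else path.stem,
    )


def write_multichannel_tiff(stack: ChannelStack, path: str | Path) -> None:
    """Write a stack as a (C, H, W) float32 OME-TIFF with pixel-size metadata."""
    tifffile.imwrite(
        str(path),
        np.asarray(stack.channels, dtype=np.float32),
        metadata={
            "axes": "CYX",
            "PhysicalSizeX": stack.pixel_size_um,
            "PhysicalSizeY": stack.pixel_size_um,
        },
        ome=True,
    )


def write_label_tiff(labels: np.ndarray, path: str | Path) -> None:
    """Write a label image as 16-bit single-channel TIFF."""
    labels = np.asarray(labels)
    if labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels do not fit a 16-bit TIFF")
    tifffile.imwrite(str(path), labels.astype(np.uint16))


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Resolved parameters for a batch run; serialized next to outputs."""

    channel_map: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHANNEL_MAP))
    pixel_size_um: float | None = None  # None -> TIFF metadata / default
    # spot detection
    spot_sigma_px: float = 1.5
    spot_threshold: float | None = None  # None -> robust auto threshold
    spot_threshold_nsigma: float = 5.0
    spot_min_distance_px: float = 3.0
    # segmentation
    glom_min_area_um2: float = 700.0
    glom_smooth_sigma_px: float = 2.0
    glom_closing_radius_um: float = 1.0
    nuc_smooth_sigma_px: float = 1.0
    nuc_min_distance_um: float = 3.0
    nuc_min_area_um2: float = 10.0
    # quantification
    territory_radius_um: float = 3.0
    target_channel: str = "fish1"
    reference_channel: str = "fish2"
    marker_policy: str = "otsu"
    marker_threshold: float | None = None
    # misc
    control_group: str | None = None
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.reference_channel not in FISH_CHANNELS:
            raise ValueError(
                f"reference_channel must be one of {FISH_CHANNELS}, "
                f"got {self.reference_channel!r}")
        if self.target_channel not in FISH_CHANNELS:
            raise ValueError(
                f"target_channel must be one of {FISH_CHANNELS}, "
                f"got {self.target_channel!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def cells_to_frame(records, image_id: str = "") -> pd.DataFrame:
    """Flatten CellRecords into the canonical cells table."""
    rows = []
    for r in records:
        norm = r.normalized_expression
        rows.append({
            "image_id": image_id or r.image_id,
            "cell_id": r.cell_id,
            "x": r.centroid[0],
            "y": r.centroid[1],
            "nucleus_area_um2": r.nucleus_area_um2,
            "compartment": r.compartment,
            "glom_id": r.glom_id if r.glom_id is not None else 0,
            "marker_positive": bool(r.marker_positive),
            "count_fish1": r.raw_counts.get("fish1", 0),
            "count_fish2": r.raw_counts.get("fish2", 0),
            "normalized_expression": norm if norm is not None else np.nan,
        })
    return pd.DataFrame(rows, columns=CELL_COLUMNS)


def frame_to_cells(frame: pd.DataFrame):
    """Inverse of :func:`cells_to_frame` (normalized values round-trip)."""
    from .quantify import CellRecord

    records = []
    for row in frame.itertuples(index=False):
        glom_id = int(row.glom_id)
        records.append(CellRecord(
            cell_id=int(row.cell_id),
            centroid=(float(row.x), float(row.y)),
            nucleus_area_um2=float(row.nucleus_area_um2),
            compartment=str(row.compartment),
            glom_id=glom_id if glom_id > 0 else None,
            marker_positive=bool(row.marker_positive),
            raw_counts={"fish1": int(row.count_fish1),
                        "fish2": int(row.count_fish2)},
            normalized_expression=(None if pd.isna(row.normalized_expression)
                                   else float(row.normalized_expression)),
            image_id=str(row.image_id),
        ))
    return records


def write_tables(cells: pd.DataFrame, summaries: pd.DataFrame,
                 gloms: pd.DataFrame, outdir: str | Path) -> dict[str, Path]:
    """Write the accumulated cells/summary/gloms CSVs (idempotent overwrite)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame, cols in (
        ("cells", cells, CELL_COLUMNS),
        ("summary", summaries, SUMMARY_COLUMNS),
        ("gloms", gloms, GLOM_COLUMNS),
    ):
        frame = frame.reindex(columns=cols) if len(frame) else pd.DataFrame(columns=cols)
        path = outdir / f"{name}.csv"
        frame.to_csv(path, index=False)
        paths[name] = path
    return paths


# ---------------------------------------------------------------------------
# Batch pipeline
# ---------------------------------------------------------------------------

_MASK_SUFFIXES = ("_glom", "_nuclei")


def _is_mask_file(path: Path) -> bool:
    return any(path.stem.endswith(s) for s in _MASK_SUFFIXES)


@dataclass
class BatchResult:
    n_processed: int
    n_failed: int
    statuses: dict[str, str]
    tables: dict[str, Path]


def process_image(stack: ChannelStack, config: RunConfig,
                  external_glom: Path | None = None,
                  external_nuclei: Path | None = None):
    """Run the full single-image pipeline; returns (cells, summary, gloms) frames."""
    # imported here so stage modules can import io without a cycle
    from . import quantify, segment, spots

    if external_glom is not None:
        glom = segment.load_external_mask(external_glom, stack.shape,
                                          stack.pixel_size_um)
    else:
        glom = segment.segment_glomeruli(stack, params=segment.GlomSegParams(
            smooth_sigma_px=config.glom_smooth_sigma_px,
            closing_radius_um=config.glom_closing_radius_um,
            min_area_um2=config.glom_min_area_um2))
    if external_nuclei is not None:
        nuclei = segment.load_external_mask(external_nuclei, stack.shape,
                                            stack.pixel_size_um)
    else:
        nuclei = segment.segment_nuclei(stack, params=segment.NucSegParams(
            smooth_sigma_px=config.nuc_smooth_sigma_px,
            min_distance_um=config.nuc_min_distance_um,
            min_area_um2=config.nuc_min_area_um2))
    territories = segment.expand_cell_territories(nuclei, config.territory_radius_um)
    marker = segment.classify_marker_positive(
        nuclei, stack.channel("if"), policy=config.marker_policy,
        threshold=config.marker_threshold)

    spot_params = spots.SpotDetectionParams(
        sigma_small_px=config.spot_sigma_px,
        threshold=config.spot_threshold,
        threshold_nsigma=config.spot_threshold_nsigma,
        min_distance_px=config.spot_min_distance_px)
    table = spots.SpotTable(image_id=stack.image_id, spots=[],
                            params=dataclasses.asdict(spot_params))
    for role in FISH_CHANNELS:
        table.spots.extend(
            spots.detect_spots(stack, role, spot_params).spots)

    assignments = quantify.assign_spots(table, territories, glom)
    records = quantify.build_cell_records(nuclei, territories, glom,
                                          marker, assignments)
    for rec in records:
        rec.image_id = stack.image_id
        rec.normalized_expression = quantify.normalize_expression(
            rec, config.target_channel, config.reference_channel)
    podocytes = quantify.select_podocytes(records)
    summary = quantify.compartment_summary(glom, territories, assignments,
                                           stack.pixel_size_um)
    glom_records = quantify.glomerular_morphometry(glom, podocytes,
                                                   stack.pixel_size_um)

    cells = cells_to_frame(records, image_id=stack.image_id)
    summary_frame = pd.DataFrame([{
        "image_id": stack.image_id,
        "intra_area_um2": summary.intra_area_um2,
        "extra_area_um2": summary.extra_area_um2,
        "intra_count_fish1": summary.intra_counts.get("fish1", 0),
        "extra_count_fish1": summary.extra_counts.get("fish1", 0),
        "intra_count_fish2": summary.intra_counts.get("fish2", 0),
        "extra_count_fish2": summary.extra_counts.get("fish2", 0),
        "unassigned_fish1": summary.unassigned_counts.get("fish1", 0),
        "unassigned_fish2": summary.unassigned_counts.get("fish2", 0),
        "rejected_spots": summary.rejected_spots,
    }], columns=SUMMARY_COLUMNS)
    glom_frame = pd.DataFrame([{
        "image_id": stack.image_id,
        "glom_id": g.glom_id,
        "tuft_area_um2": g.tuft_area_um2,
        "feret_diameter_um": g.feret_diameter_um,
        "podocyte_count": g.podocyte_count,
        "podocyte_density_per_mm2": g.podocyte_density_per_mm2,
    } for g in glom_records], columns=GLOM_COLUMNS)
    return cells, summary_frame, glom_frame


def run_batch(config: RunConfig, indir: str | Path,
              outdir: str | Path | None = None) -> BatchResult:
    """Process every multichannel TIFF in ``indir``.

    Externally predicted masks are auto-discovered by suffix
    (``<stem>_glom.tif``, ``<stem>_nuclei.tif``) and used in place of the
    classical segmenters.  Per-file failures are logged and skipped; the
    batch fails only when no file could be processed.  Accumulated tables
    are sorted by (image_id, cell_id) so output bytes do not depend on
    directory listing order.
    """
    indir = Path(indir)
    outdir = Path(outdir) if outdir is not None else Path(config.output_dir)
    tiffs = sorted(p for p in list(indir.glob("*.tif")) + list(indir.glob("*.tiff"))
                   if not _is_mask_file(p))
    if not tiffs:
        raise FileNotFoundError(f"no processable TIFF files in {indir}")

    all_cells, all_summaries, all_gloms = [], [], []
    statuses: dict[str, str] = {}
    for path in tiffs:
        try:
            stack = read_multichannel_tiff(path, config.channel_map,
                                           config.pixel_size_um)
            ext_glom = path.with_name(path.stem + "_glom.tif")
            ext_nuc = path.with_name(path.stem + "_nuclei.tif")
            cells, summary, gloms = process_image(
                stack, config,
                external_glom=ext_glom if ext_glom.exists() else None,
                external_nuclei=ext_nuc if ext_nuc.exists() else None)
        except Exception as exc:  # per-file failure policy: log and continue
            logger.warning("failed to process %s: %s", path.name, exc)
            statuses[path.name] = f"failed: {exc}"
            continue
        all_cells.append(cells)
        all_summaries.append(summary)
        all_gloms.append(gloms)
        statuses[path.name] = "ok"
        logger.info("processed %s: %d cells", path.name, len(cells))

    n_ok = sum(1 for s in statuses.values() if s == "ok")
    if n_ok == 0:
        raise RuntimeError(f"all {len(tiffs)} files in {indir} failed")

    def _concat(frames, cols):
        if not frames:
            return pd.DataFrame(columns=cols)
        return pd.concat(frames, ignore_index=True)

    cells = _concat(all_cells, CELL_COLUMNS).sort_values(
        ["image_id", "cell_id"], kind="mergesort", ignore_index=True)
    summaries = _concat(all_summaries, SUMMARY_COLUMNS).sort_values(
        "image_id", kind="mergesort", ignore_index=True)
    gloms = _concat(all_gloms, GLOM_COLUMNS).sort_values(
        ["image_id", "glom_id"], kind="mergesort", ignore_index=True)
    tables = write_tables(cells, summaries, gloms, outdir)
    config.to_yaml(Path(outdir) / "resolved_config.yaml")
    return BatchResult(n_processed=n_ok, n_failed=len(tiffs) - n_ok,
                       statuses=statuses, tables=tables)
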