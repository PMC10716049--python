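"""Microscopy quantification: nuclear segmentation, granularity, condensate
counting, nuclear translocation traces, rolling-ball cluster detection and
in vitro droplet partition quantification.

Conventions: pixel-center coordinates, 0-based indices, y increasing
downward. Areas are reported in both px^2 and um^2 using ``pixel_size`` (nm)
squared. All operations accept 8- or 16-bit input.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import median as sk_median
from skimage.filters import threshold_local, threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.morphology import disk
from skimage.registration import phase_cross_correlation

from .datatypes import ImageStack

logger = logging.getLogger(__name__)


def _rolling_ball_background(img: np.ndarray, radius: int) -> np.ndarray:
    """Rolling-ball background: grey opening with a flat disk of the ball
    radius (the ImageJ subtract-background idiom). Removes features
    narrower than the ball while following broad gradients."""
    from skimage.morphology import opening

    return opening(img, disk(radius, decomposition="sequence"))

__all__ = [
    "LabeledRegions",
    "NucleusRecord",
    "segment_nuclei",
    "granularity",
    "detect_condensates",
    "translocation_trace",
    "detect_nuclear_clusters",
    "quantify_droplet_partitioning",
]


@dataclass
class LabeledRegions:
    """Integer label mask (0 = background) plus per-region measurements."""

    labels: np.ndarray
    n_regions: int
    saturated: bool = False
    table: pd.DataFrame | None = None


@dataclass
class NucleusRecord:
    """Per-nucleus granularity measurement: the within-nucleus intensity
    s.d. is the clustering (granularity) statistic."""

    label: int
    mean_intensity: float
    intensity_sd: float
    area: int
    group: str = ""
    replicate: str = ""


def _as_2d(image) -> tuple[np.ndarray, float | None]:
    if isinstance(image, ImageStack):
        return image.frame().astype(np.float64), image.pixel_size
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError("expected a single-channel 2-D frame")
    return arr.astype(np.float64), None


def _sorted_relabel(labels: np.ndarray) -> np.ndarray:
    """Relabel components in raster order of their top-left-most pixel so
    label numbering is deterministic across library versions."""
    out = np.zeros_like(labels)
    props = regionprops(labels)
    order = sorted(props, key=lambda p: (p.bbox[0], p.bbox[1]))
    for new, p in enumerate(order, start=1):
        out[labels == p.label] = new
    return out


def segment_nuclei(
    image,
    median_radius: int = 3,
    bg_radius: int = 50,
    method: str = "otsu",
    min_area: int = 200,
    max_area: int | None = None,
    nucleolus_fraction: float = 0.6,
) -> LabeledRegions:
    """Segment nuclei by median filtering, background subtraction and
    thresholding; dark intranuclear holes (nucleoli) stay excluded.

    ``method`` is ``"otsu"`` (global) or ``"local"`` (adaptive mean, block
    size ~4*bg_radius+1). Holes inside a nucleus are filled only if their
    mean intensity is at least ``nucleolus_fraction`` of the surrounding
    nucleus mean; darker holes are treated as nucleoli and left out of the
    mask. Touching nuclei are not split; use ``max_area`` to drop
    over-merged objects. An all-zero image yields zero labels.
    """
    img, _ = _as_2d(image)
    dtype_max = np.asarray(image.pixels if isinstance(image, ImageStack) else image).max(initial=0)
    saturated = False
    raw = np.asarray(image.pixels if isinstance(image, ImageStack) else image)
    if raw.dtype == np.uint8 and (raw == 255).mean() > 0.001:
        saturated = True
    if raw.dtype == np.uint16 and (raw == 65535).mean() > 0.001:
        saturated = True
    if saturated:
        warnings.warn("image contains saturated pixels", stacklevel=2)

    if img.max() == img.min():
        return LabeledRegions(np.zeros(img.shape, dtype=np.int32), 0, saturated)

    sm = sk_median(img, footprint=disk(median_radius))
    if bg_radius > 0:
        sm = sm - _rolling_ball_background(sm, bg_radius)
    if method == "otsu":
        thr = threshold_otsu(sm)
        binary = sm > thr
    elif method == "local":
        block = 4 * bg_radius + 1 if bg_radius > 0 else 201
        binary = sm > threshold_local(sm, block_size=block | 1, method="mean")
    else:
        raise ValueError("method must be 'otsu' or 'local'")

    # conditional hole filling: refill only bright holes, keep dark nucleoli out
    filled = ndi.binary_fill_holes(binary)
    holes = filled & ~binary
    hole_labels, n_holes = ndi.label(holes)
    labels0 = sk_label(filled)
    for h in range(1, n_holes + 1):
        hole = hole_labels == h
        parent = np.bincount(labels0[hole]).argmax()
        if parent == 0:
            continue
        nucleus_px = (labels0 == parent) & binary
        if nucleus_px.sum() == 0:
            continue
        if img[hole].mean() < nucleolus_fraction * img[nucleus_px].mean():
            filled[hole] = False  # dark hole: nucleolus, excluded

    labels = sk_label(filled)
    # area filtering
    for p in regionprops(labels):
        if p.area < min_area or (max_area is not None and p.area > max_area):
            labels[labels == p.label] = 0
    labels = _sorted_relabel(labels)
    _ = dtype_max
    return LabeledRegions(labels.astype(np.int32), int(labels.max()), saturated)


def granularity(image, mask, group: str = "", replicate: str = "") -> list[NucleusRecord]:
    """Per-nucleus mean and population s.d. of intensity (the granularity
    statistic), computed inside each label of ``mask``.

    Empty labels are excluded with a log entry. Population s.d. (divisor n)
    is used; with thousands of pixels per nucleus the sample/population
    distinction is immaterial but is fixed here for reproducibility.
    """
    img, _ = _as_2d(image)
    labels = mask.labels if isinstance(mask, LabeledRegions) else np.asarray(mask)
    if labels.shape != img.shape:
        raise ValueError("mask shape must match image shape")
    records = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        px = img[labels == lab]
        if px.size == 0:
            logger.info("label %d is empty; excluded from granularity", lab)
            continue
        records.append(
            NucleusRecord(
                label=int(lab),
                mean_intensity=float(px.mean()),
                intensity_sd=float(px.std(ddof=0)),
                area=int(px.size),
                group=group,
                replicate=replicate,
            )
        )
    return records


@dataclass
class CondensateSet:
    """Cytosolic condensate measurements for one timepoint."""

    timepoint: int
    count: int
    areas_px: np.ndarray
    areas_um2: np.ndarray
    cytosol_area_um2: float
    count_density: float  # objects per um^2 of cytosol
    centroids: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))


def detect_condensates(
    stack: ImageStack,
    nuclear_mask: np.ndarray,
    threshold_mode: str | float = "otsu",
    min_area: int = 4,
    cytosol_mask: np.ndarray | None = None,
    channel: int = 0,
) -> list[CondensateSet]:
    """Count and size cytosolic condensates per timepoint.

    Per timepoint: maximum-intensity z-projection -> cytosol mask (supplied,
    or Otsu on the projection) minus the nuclear mask -> threshold
    (``"otsu"`` within the cytosol, or a fixed intensity) -> connected
    components with area >= ``min_area`` px^2. Reports count, areas,
    cytosol area (um^2) and count density (objects per um^2).
    """
    nuclear_mask = np.asarray(nuclear_mask, dtype=bool)
    if nuclear_mask.shape != stack.pixels.shape[2:4]:
        raise ValueError("nuclear mask does not match frame shape")
    um_per_px2 = (stack.pixel_size / 1000.0) ** 2
    out = []
    for t in range(stack.n_timepoints):
        proj = stack.max_project(t, channel).astype(np.float64)
        if cytosol_mask is not None:
            cell = np.asarray(cytosol_mask, dtype=bool)
        else:
            cell = proj > threshold_otsu(proj) if proj.max() > proj.min() else np.zeros_like(proj, bool)
            # the cell mask must cover cytosol, not just bright condensates:
            # use a permissive threshold at half the Otsu level
            cell = proj > 0.5 * threshold_otsu(proj) if proj.max() > proj.min() else cell
            cell = ndi.binary_fill_holes(cell)
        cyto = cell & ~nuclear_mask
        region = proj[cyto]
        if threshold_mode == "otsu":
            thr = threshold_otsu(region) if region.size and region.max() > region.min() else np.inf
        else:
            thr = float(threshold_mode)
        binary = np.zeros_like(cyto)
        binary[cyto] = proj[cyto] > thr
        labels = sk_label(binary)
        areas, cents = [], []
        for p in regionprops(labels):
            if p.area >= min_area:
                areas.append(p.area)
                cents.append(p.centroid)
        areas = np.asarray(areas, dtype=float)
        cyto_area_um2 = float(cyto.sum()) * um_per_px2
        out.append(
            CondensateSet(
                timepoint=t,
                count=len(areas),
                areas_px=areas,
                areas_um2=areas * um_per_px2,
                cytosol_area_um2=cyto_area_um2,
                count_density=len(areas) / cyto_area_um2 if cyto_area_um2 > 0 else np.nan,
                centroids=np.asarray(cents, dtype=float).reshape(-1, 2),
            )
        )
    return out


def translocation_trace(
    stack: ImageStack,
    nuc_mask: np.ndarray,
    cyto_mask: np.ndarray,
    register: bool = True,
    channel: int = 0,
) -> pd.DataFrame:
    """Relative nuclear localization over a time-lapse.

    Per frame: sum z-projection, optional translation-only registration to
    frame 0 (phase correlation), mean intensity per ROI, and
    ``relative_nuclear_localization = I_nuc / (I_nuc + I_cyto)`` in [0, 1].
    If registration fails the unregistered frame is used with a warning.
    """
    nuc = np.asarray(nuc_mask, dtype=bool)
    cyto = np.asarray(cyto_mask, dtype=bool)
    if not nuc.any() or not cyto.any():
        raise ValueError("both ROIs must be non-empty")
    ref = stack.sum_project(0, channel)
    rows = []
    for t in range(stack.n_timepoints):
        proj = stack.sum_project(t, channel)
        if register and t > 0:
            try:
                shift, _, _ = phase_cross_correlation(ref, proj, upsample_factor=1)
                proj = ndi.shift(proj, shift, order=1, mode="nearest")
            except Exception:  # degenerate overlap: fall back unregistered
                warnings.warn(f"registration failed at frame {t}; using unregistered", stacklevel=2)
        i_nuc = float(proj[nuc].mean())
        i_cyto = float(proj[cyto].mean())
        denom = i_nuc + i_cyto
        rows.append(
            {
                "t": t,
                "I_nuc": i_nuc,
                "I_cyto": i_cyto,
                "relative_nuclear_localization": i_nuc / denom if denom > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def detect_nuclear_clusters(
    stack: ImageStack,
    dna_channel: int = 1,
    target_channel: int = 0,
    resolution_limit: float = 48.0,
    ball_multiple: float = 8.0,
    min_area: int = 2,
) -> pd.DataFrame:
    """Detect intranuclear clusters by rolling-ball background subtraction.

    Nuclei are segmented from the DNA counterstain channel (Otsu). In the
    target channel, a rolling-ball background with ball radius
    ``ball_multiple * resolution_limit`` (nm, converted to px) is
    subtracted, the residual is Otsu-thresholded within the nuclei, and
    connected components are reported with mean intensity and size (nm^2).
    Rejects ``resolution_limit`` below the pixel size (sub-pixel ball).
    """
    if resolution_limit < stack.pixel_size:
        raise ValueError(
            f"resolution_limit ({resolution_limit} nm) below pixel size "
            f"({stack.pixel_size} nm)"
        )
    dna = stack.max_project(0, dna_channel).astype(np.float64)
    img = stack.max_project(0, target_channel).astype(np.float64)
    if dna.max() == dna.min():
        return pd.DataFrame(columns=["nucleus", "mean_intensity", "size_nm2", "area_px"])
    nuclei = ndi.binary_fill_holes(dna > threshold_otsu(dna))
    nuc_labels = _sorted_relabel(sk_label(nuclei))

    radius_px = max(1, int(round(ball_multiple * resolution_limit / stack.pixel_size)))
    signal = img - _rolling_ball_background(img, radius_px)
    inside = signal[nuclei]
    if inside.size == 0 or inside.max() <= inside.min():
        return pd.DataFrame(columns=["nucleus", "mean_intensity", "size_nm2", "area_px"])
    thr = threshold_otsu(inside)
    binary = np.zeros_like(nuclei)
    binary[nuclei] = signal[nuclei] > thr
    labels = sk_label(binary)
    rows = []
    for p in regionprops(labels, intensity_image=img):
        if p.area < min_area:
            continue
        cy, cx = (int(round(c)) for c in p.centroid)
        parent = int(nuc_labels[cy, cx])
        if parent == 0:
            continue
        rows.append(
            {
                "nucleus": parent,
                "mean_intensity": float(p.intensity_mean),
                "size_nm2": float(p.area) * stack.pixel_size**2,
                "area_px": int(p.area),
                "y": p.centroid[0],
                "x": p.centroid[1],
            }
        )
    return pd.DataFrame(rows)


def quantify_droplet_partitioning(
    stack: ImageStack,
    channel_of_interest: int = 0,
    threshold: float | None = None,
    min_diameter: float = 0.1,
    profile_droplet: int | None = None,
) -> tuple[pd.DataFrame, np.ndarray | None]:
    """Per-droplet intensity of a probe channel in an in vitro droplet field.

    Droplets are segmented by thresholding the channel-sum image; the
    default threshold is 3 on the 8-bit scale (upper bound 255), rescaled
    proportionally for 16-bit input. Objects with equivalent diameter
    >= ``min_diameter`` (um) are kept and their mean intensity in
    ``channel_of_interest`` reported. Optionally returns the normalized
    horizontal cross-section profile through the centroid of droplet
    ``profile_droplet``.
    """
    if stack.n_channels < 2:
        raise ValueError("need >= 2 registered channels")
    chsum = stack.pixels[0, :, :, :, :].astype(np.float64).sum(axis=(0, 3))
    if threshold is None:
        scale = 65535.0 / 255.0 if stack.bit_depth == 16 else 1.0
        threshold = 3.0 * scale * stack.n_channels
    binary = chsum > threshold
    labels = _sorted_relabel(sk_label(binary))
    coi = stack.max_project(0, channel_of_interest).astype(np.float64)
    um_per_px = stack.pixel_size / 1000.0
    rows = []
    for p in regionprops(labels, intensity_image=coi):
        eq_diam_um = p.equivalent_diameter_area * um_per_px
        if eq_diam_um < min_diameter:
            continue
        rows.append(
            {
                "droplet": int(p.label),
                "mean_intensity": float(p.intensity_mean),
                "area_um2": float(p.area) * um_per_px**2,
                "equivalent_diameter_um": float(eq_diam_um),
                "y": p.centroid[0],
                "x": p.centroid[1],
            }
        )
    table = pd.DataFrame(rows)
    profile = None
    if profile_droplet is not None and not table.empty:
        row = table[table["droplet"] == profile_droplet]
        if not row.empty:
            cy = int(round(row["y"].iloc[0]))
            line = coi[cy, :]
            mx = line.max()
            profile = line / mx if mx > 0 else line
    return table, profile
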