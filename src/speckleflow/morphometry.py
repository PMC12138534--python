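"""Confocal vessel morphometry on maximum intensity projections.

Reproduces a 2-D morphometry chain for lectin-labeled vasculature imaged as
confocal z-stacks: the stack is collapsed into ~70-um maximum intensity
projections (MIPs); a consensus cortical ROI is formed by majority vote over
reader-drawn masks; within the ROI each MIP is binarized with the
iterative-selection (ISODATA/Ridler-Calvard) threshold, small components
(< 51 um^2) are removed, and the remaining mask is skeletonized. The
skeleton is split into branch-free segments; vessel density is total
centerline length over ROI area across the MIPs with the most vasculature,
and per-segment mean diameters (2x the Euclidean distance transform at the
centerline) feed a mode-normalized diameter histogram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt
from skimage.measure import label
from skimage.morphology import skeletonize

from .errors import DegenerateInputError

logger = logging.getLogger(__name__)

__all__ = [
    "ConfocalStack",
    "MIPSeries",
    "ConsensusROI",
    "DiameterHistogram",
    "make_mips",
    "consensus_roi",
    "iterative_threshold",
    "size_filter",
    "skeletonize_mask",
    "segment_skeleton",
    "vessel_diameters",
    "vessel_density",
    "diameter_histogram",
    "analyze_mip",
]

SQRT2 = float(np.sqrt(2.0))


@dataclass
class ConfocalStack:
    """A confocal z-stack with voxel size (z, y, x) in um."""

    volume: np.ndarray  # (z, y, x)
    voxel_size_um: tuple[float, float, float]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume)
        if self.volume.ndim != 3:
            raise ValueError("volume must be 3-D (z, y, x)")
        if min(self.voxel_size_um) <= 0:
            raise ValueError("voxel sizes must be positive")


@dataclass
class MIPSeries:
    """Maximum intensity projections of consecutive z-slabs."""

    mips: list
    slab_um: float
    z_ranges: list  # (first_slice, last_slice_exclusive) per MIP


@dataclass
class ConsensusROI:
    """Majority-vote consensus of reader-drawn ROI masks."""

    mask: np.ndarray
    n_readers: int
    vote_threshold: int


@dataclass
class DiameterHistogram:
    """Mode-normalized histogram of per-segment vessel diameters."""

    bin_centers_um: np.ndarray
    normalized_counts: np.ndarray
    raw_counts: np.ndarray
    bin_width_um: float


def make_mips(stack: ConfocalStack, slab_um: float = 70.0) -> MIPSeries:
    """Collapse a z-stack into MIPs of consecutive ~``slab_um`` slabs.

    The stack is partitioned into blocks of floor(slab_um / z_step) slices
    and each block reduced by a pixelwise maximum. A trailing remainder of
    fewer than half a slab's slices is discarded; a larger remainder is kept
    as a final thin MIP (both logged).
    """
    z_step = stack.voxel_size_um[0]
    if slab_um < z_step:
        raise ValueError(f"slab {slab_um} um is smaller than one slice ({z_step} um)")
    per = int(slab_um // z_step)
    nz = stack.volume.shape[0]
    mips, ranges = [], []
    for start in range(0, nz, per):
        stop = min(start + per, nz)
        if stop - start < per:  # trailing remainder
            if stop - start < per / 2.0:
                logger.info("discarding %d trailing slices (< half a slab)", stop - start)
                break
            logger.info("keeping thin final MIP of %d slices", stop - start)
        mips.append(stack.volume[start:stop].max(axis=0))
        ranges.append((start, stop))
    if not mips:
        raise ValueError("stack produced no MIP")
    return MIPSeries(mips=mips, slab_um=slab_um, z_ranges=ranges)


def consensus_roi(reader_masks: list) -> ConsensusROI:
    """Majority filter over reader ROI masks: a pixel enters the consensus
    iff strictly more than half of the readers included it (2 of 3 for
    three readers). The result always lies between the intersection and the
    union of the reader masks."""
    if len(reader_masks) < 2:
        raise ValueError("need at least two reader masks")
    masks = [np.asarray(m, dtype=bool) for m in reader_masks]
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ValueError("reader masks must share one shape")
    votes = np.sum(masks, axis=0)
    n = len(masks)
    thresh = n // 2 + 1  # strictly more than half
    return ConsensusROI(mask=votes >= thresh, n_readers=n, vote_threshold=thresh)


def iterative_threshold(image: np.ndarray, roi: np.ndarray | ConsensusROI | None = None,
                        max_iter: int = 500) -> float:
    """Iterative-selection (ISODATA/Ridler-Calvard) intensity threshold.

    Starting from the mean intensity of the ROI pixels, iterate
    t <- (mean of pixels below t + mean of pixels at/above t) / 2 until the
    threshold moves by less than 0.5 intensity level (integer images) or a
    relative 1e-6 (float images). The fixed point splits the histogram so
    the threshold sits midway between the two class means.
    """
    if isinstance(roi, ConsensusROI):
        roi = roi.mask
    image = np.asarray(image)
    vals = image[np.asarray(roi, dtype=bool)] if roi is not None else image.ravel()
    if vals.size == 0:
        raise DegenerateInputError("ROI selects no pixels")
    vals = vals.astype(np.float64)
    if np.unique(vals).size < 2:
        raise DegenerateInputError("constant image within the ROI: no threshold exists")
    integer_levels = np.issubdtype(image.dtype, np.integer)
    tol = 0.5 if integer_levels else None
    t = vals.mean()
    for _ in range(max_iter):
        below = vals[vals < t]
        above = vals[vals >= t]
        if below.size == 0 or above.size == 0:
            break
        t_new = 0.5 * (below.mean() + above.mean())
        delta = abs(t_new - t)
        t = t_new
        if tol is not None:
            if delta < tol:
                break
        elif delta < 1e-6 * max(abs(t), 1.0):
            break
    return float(t)


def size_filter(mask: np.ndarray, pixel_area_um2: float, min_area_um2: float = 51.0) -> np.ndarray:
    """Remove connected components (8-connectivity) whose physical area is
    strictly smaller than ``min_area_um2``; components of exactly the
    threshold area are kept. Idempotent; output is a subset of the input."""
    if pixel_area_um2 <= 0:
        raise ValueError("pixel_area_um2 must be positive")
    mask = np.asarray(mask, dtype=bool)
    lab, n = label(mask, connectivity=2, return_num=True)
    if n == 0:
        return mask.copy()
    areas = np.bincount(lab.ravel())[1:] * pixel_area_um2
    keep_labels = np.nonzero(areas >= min_area_um2)[0] + 1
    return np.isin(lab, keep_labels)


def skeletonize_mask(mask: np.ndarray) -> np.ndarray:
    """Topology-preserving thinning to one-pixel-wide centerlines
    (skeleton is a subset of the mask; component count is preserved)."""
    return skeletonize(np.asarray(mask, dtype=bool))


def _neighbor_offsets():
    return [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]


def segment_skeleton(skeleton: np.ndarray) -> list:
    """Split a skeleton into maximal branch-free centerline segments.

    Branch points are skeleton pixels with >= 3 skeleton neighbors
    (8-connectivity). Removing them leaves branch-free paths; each path is
    traced from an endpoint (or around a loop) and its length accumulated
    as 1 per axial step and sqrt(2) per diagonal step, including the final
    step(s) reconnecting the path to its adjacent branch point(s).

    Returns a list of dicts with keys ``points`` (ordered (row, col) list,
    excluding branch points) and ``length_px``.
    """
    skel = np.asarray(skeleton, dtype=bool)
    ys, xs = np.nonzero(skel)
    pixels = set(zip(ys.tolist(), xs.tolist()))
    offs = _neighbor_offsets()

    def neighbors(p, pool):
        y, x = p
        return [(y + dy, x + dx) for dy, dx in offs if (y + dy, x + dx) in pool]

    degree = {p: len(neighbors(p, pixels)) for p in pixels}
    branch = {p for p, d in degree.items() if d >= 3}
    path_pixels = pixels - branch

    def step_len(a, b):
        return SQRT2 if (a[0] != b[0] and a[1] != b[1]) else 1.0

    visited = set()
    segments = []

    def trace(start, first):
        """Walk a branch-free path from start through first until it ends."""
        pts = [start]
        visited.add(start)
        length = 0.0
        prev, cur = start, first
        while cur in path_pixels and cur not in visited:
            length += step_len(prev, cur)
            pts.append(cur)
            visited.add(cur)
            nxt = [q for q in neighbors(cur, path_pixels) if q != prev and q not in visited]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
        return pts, length

    # open paths: start at endpoints (degree within path_pixels <= 1)
    for p in sorted(path_pixels):
        if p in visited:
            continue
        nb = neighbors(p, path_pixels)
        if len(nb) <= 1:
            if nb:
                pts, length = trace(p, nb[0])
            else:
                pts, length = [p], 0.0
                visited.add(p)
            # reconnect to adjacent branch points so junction steps count
            for end in {pts[0], pts[-1]}:
                for q in neighbors(end, branch):
                    length += step_len(end, q)
                    break
            segments.append({"points": pts, "length_px": length})
    # closed loops: remaining unvisited path pixels all have 2 neighbors
    for p in sorted(path_pixels):
        if p in visited:
            continue
        nb = neighbors(p, path_pixels)
        pts, length = trace(p, nb[0])
        length += step_len(pts[-1], pts[0])  # close the loop
        segments.append({"points": pts, "length_px": length})
    return segments


def vessel_diameters(
    mask: np.ndarray,
    segments: list,
    pixel_size_um: float = 1.0,
    mip_index: int = 0,
) -> pd.DataFrame:
    """Per-segment mean vessel diameter via the Euclidean distance transform.

    The local diameter at a centerline point is twice its Euclidean
    distance to the nearest background pixel; a segment's diameter is the
    mean over its points — one value per segment regardless of length, so
    long vessels do not dominate diameter statistics. Also records each
    segment's parent-component area.

    Returns a VesselSegmentTable: DataFrame with columns
    (segment_id, mip_index, length_um, diameter_um, component_area_um2).
    """
    mask = np.asarray(mask, dtype=bool)
    edt = distance_transform_edt(mask)
    lab = label(mask, connectivity=2)
    comp_areas = np.bincount(lab.ravel()) * pixel_size_um**2
    rows = []
    for i, seg in enumerate(segments):
        pts = seg["points"]
        rr = np.array([p[0] for p in pts])
        cc = np.array([p[1] for p in pts])
        if not mask[rr, cc].all():
            raise ValueError(f"segment {i} has centerline points on background")
        diam_px = 2.0 * edt[rr, cc]
        rows.append(
            {
                "segment_id": i,
                "mip_index": mip_index,
                "length_um": seg["length_px"] * pixel_size_um,
                "diameter_um": float(diam_px.mean()) * pixel_size_um,
                "component_area_um2": float(comp_areas[lab[rr[0], cc[0]]]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["segment_id", "mip_index", "length_um", "diameter_um", "component_area_um2"],
    )


def vessel_density(
    segment_tables: list,
    roi_areas_um2: list,
    n_select: int = 5,
) -> float:
    """Vessel density (1/um) over the MIPs with the most vasculature.

    MIPs are ranked by their total centerline length and the top
    ``n_select`` used; density = sum of their lengths / sum of their ROI
    areas. If fewer MIPs exist, all are used (with a warning).
    """
    if len(segment_tables) != len(roi_areas_um2):
        raise ValueError("one ROI area per segment table required")
    if not segment_tables:
        raise ValueError("no MIPs supplied")
    totals = np.array([float(t["length_um"].sum()) for t in segment_tables])
    if len(totals) < n_select:
        logger.warning("only %d MIPs available (wanted %d); using all", len(totals), n_select)
        n_select = len(totals)
    order = np.argsort(-totals, kind="stable")[:n_select]
    area = float(np.sum(np.asarray(roi_areas_um2, dtype=float)[order]))
    if area <= 0:
        raise DegenerateInputError("selected MIPs have zero total ROI area")
    return float(totals[order].sum() / area)


def diameter_histogram(
    tables: list,
    bin_width_um: float = 1.0,
    d_max_um: float = 12.0,
) -> DiameterHistogram:
    """Mode-normalized histogram of per-segment diameters on (0, d_max].

    Counts per-segment diameters into bins of ``bin_width_um``; normalized
    counts divide by the largest bin count, so the modal diameter reads
    exactly 1.
    """
    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    diams = np.concatenate([np.asarray(t["diameter_um"], dtype=float) for t in tables]) \
        if tables else np.array([])
    diams = diams[(diams > 0) & (diams <= d_max_um)]
    if diams.size == 0:
        raise DegenerateInputError("no segment diameters in (0, d_max]")
    n_bins = int(np.ceil(d_max_um / bin_width_um))
    edges = np.arange(n_bins + 1) * bin_width_um
    # right-closed bins (a, b]: a segment of exactly 4 um belongs to the
    # 4-um bin (3, 4]
    idx = np.searchsorted(edges, diams, side="left") - 1
    counts = np.bincount(idx, minlength=n_bins)
    return DiameterHistogram(
        bin_centers_um=0.5 * (edges[:-1] + edges[1:]),
        normalized_counts=counts / counts.max(),
        raw_counts=counts,
        bin_width_um=bin_width_um,
    )


def analyze_mip(
    mip: np.ndarray,
    roi_mask: np.ndarray,
    pixel_size_um: float,
    min_area_um2: float = 51.0,
    mip_index: int = 0,
) -> tuple[pd.DataFrame, float, np.ndarray, np.ndarray]:
    """Full single-MIP chain: threshold within the ROI, binarize, size-filter,
    skeletonize, segment, measure.

    Returns (segment_table, roi_area_um2, vessel_mask, skeleton). Pixels
    outside the ROI are excluded from thresholding and masked out of the
    binary image.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    t = iterative_threshold(mip, roi_mask)
    binary = (np.asarray(mip, dtype=float) >= t) & roi_mask
    pixel_area = pixel_size_um**2
    binary = size_filter(binary, pixel_area, min_area_um2)
    skel = skeletonize_mask(binary)
    segments = segment_skeleton(skel)
    if binary.any():
        table = vessel_diameters(binary, segments, pixel_size_um, mip_index)
    else:
        table = pd.DataFrame(
            columns=["segment_id", "mip_index", "length_um", "diameter_um", "component_area_um2"]
        )
    roi_area = float(roi_mask.sum()) * pixel_area
    return table, roi_area, binary, skel
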