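"""From multi-cycle micrographs to an indexed per-cell expression table.

The pipeline mirrors a CellProfiler-style workflow: maximum projection of
z-stacks, translation registration of imaging cycles using the nuclear stain
as fiducial, nucleus seed detection as maxima of a smoothed DAPI image,
watershed propagation of nuclear boundaries, ~1 um expansion of each nucleus
to define a peri-nuclear sampling area, and per-channel mean intensities over
each sampling area. Cells are indexed by integer label; the label survives
into the expression table and the boundary-index image, so classifications can
be remapped onto the tissue.

Pixel coordinates are 0-based row-major (row, col); physical units enter only
through ``pixel_size_um``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import feature, filters, measure, registration, segmentation

DEFAULT_SMOOTHING_SIGMA_UM = 1.0
DEFAULT_MIN_SEPARATION_UM = 4.0
DEFAULT_EXPANSION_UM = 1.0
NUCLEAR_CHANNEL = "DAPI"


@dataclass
class FieldImage:
    """One imaging cycle of one field of view: channel name -> 2-D image."""

    channels: dict[str, np.ndarray]
    cycle: int
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        shapes = {ch: im.shape for ch, im in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ within one cycle: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


def max_project(zstack: np.ndarray) -> np.ndarray:
    """Per-pixel maximum across the planes of a (planes, rows, cols) stack."""
    arr = np.asarray(zstack)
    if arr.ndim == 2:
        return arr.copy()
    if arr.ndim != 3 or arr.shape[0] < 1:
        raise ValueError(f"expected a (planes, rows, cols) stack, got shape {arr.shape}")
    return arr.max(axis=0)


def register_cycles(
    cycles: Sequence[FieldImage],
    reference_channel: str = NUCLEAR_CHANNEL,
    min_correlation: float = 0.2,
) -> tuple[list[tuple[int, int]], list[FieldImage]]:
    """Align imaging cycles by integer-pixel phase correlation of the nuclear stain.

    The first cycle is the reference. Each later cycle's nuclear channel is
    phase-correlated against it; the correcting (row, col) translation is
    applied to every channel of that cycle. A flat nuclear channel or a
    post-alignment correlation below ``min_correlation`` yields a warning and
    the identity offset. Returns (offsets, aligned cycles); each offset is the
    detected displacement of that cycle relative to the reference (so a cycle
    acquired 3 px down and 2 px left reports (3, -2)), and the applied
    correction is its negative.
    """
    if len(cycles) < 2:
        raise ValueError("need at least two cycles to register")
    for c in cycles:
        if reference_channel not in c.channels:
            raise ValueError(f"cycle {c.cycle} lacks the {reference_channel!r} channel")
    ref = cycles[0].channels[reference_channel].astype(float)
    offsets: list[tuple[int, int]] = [(0, 0)]
    aligned: list[FieldImage] = [cycles[0]]
    for cyc in cycles[1:]:
        mov = cyc.channels[reference_channel].astype(float)
        if mov.std() == 0 or ref.std() == 0:
            warnings.warn(
                f"cycle {cyc.cycle}: blank nuclear channel, using identity offset",
                stacklevel=2,
            )
            offsets.append((0, 0))
            aligned.append(cyc)
            continue
        shift, _, _ = registration.phase_cross_correlation(
            ref, mov, upsample_factor=1, normalization=None
        )
        cy_, cx_ = int(round(shift[0])), int(round(shift[1]))  # correction
        moved = _translate(mov, cy_, cx_)
        corr = _safe_corr(ref, moved)
        if corr < min_correlation:
            warnings.warn(
                f"cycle {cyc.cycle}: registration correlation {corr:.2f} below "
                f"{min_correlation}, using identity offset",
                stacklevel=2,
            )
            cy_ = cx_ = 0
        offsets.append((-cy_, -cx_))
        aligned.append(
            FieldImage(
                channels={ch: _translate(im, cy_, cx_) for ch, im in cyc.channels.items()},
                cycle=cyc.cycle,
                pixel_size_um=cyc.pixel_size_um,
            )
        )
    return offsets, aligned


def _translate(im: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Integer translation padding with zeros (no wrap-around)."""
    out = np.zeros_like(im)
    h, w = im.shape
    ys, yd = (slice(0, h - dy), slice(dy, h)) if dy >= 0 else (slice(-dy, h), slice(0, h + dy))
    xs, xd = (slice(0, w - dx), slice(dx, w)) if dx >= 0 else (slice(-dx, w), slice(0, w + dx))
    out[yd, xd] = im[ys, xs]
    return out


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel().astype(float)
    b = b.ravel().astype(float)
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def detect_nuclei(
    dapi: np.ndarray,
    pixel_size_um: float,
    smoothing_sigma_um: float = DEFAULT_SMOOTHING_SIGMA_UM,
    min_separation_um: float = DEFAULT_MIN_SEPARATION_UM,
) -> np.ndarray:
    """Nucleus seed points as maxima of the smoothed nuclear-stain image.

    The image is Gaussian-smoothed, thresholded automatically (Otsu), and
    local maxima separated by at least ``min_separation_um`` are returned as an
    (n, 2) array of (row, col) coordinates. Two nuclei closer than the
    separation radius merge into one seed. A blank image yields no seeds.
    """
    if smoothing_sigma_um <= 0 or min_separation_um <= 0:
        raise ValueError("smoothing sigma and minimum separation must be positive")
    img = np.asarray(dapi, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if img.max() == img.min():
        return np.empty((0, 2), dtype=int)
    smooth = ndimage.gaussian_filter(img, sigma=smoothing_sigma_um / pixel_size_um)
    thresh = filters.threshold_otsu(smooth)
    min_dist = max(1, int(round(min_separation_um / pixel_size_um)))
    return feature.peak_local_max(
        smooth, min_distance=min_dist, threshold_abs=thresh, exclude_border=False
    )


def segment_nuclei(
    dapi: np.ndarray,
    seeds: np.ndarray,
    pixel_size_um: float,
    smoothing_sigma_um: float = DEFAULT_SMOOTHING_SIGMA_UM,
) -> np.ndarray:
    """Propagate nuclear boundaries from seed points (seeded watershed).

    Region growing runs on the inverted smoothed intensity, constrained to
    above-background (Otsu) pixels, so fronts from neighboring seeds meet at
    intensity valleys. Every seed yields exactly one label, numbered 1..n in
    seed order; a seed falling on background keeps a single flagged pixel.
    """
    img = np.asarray(dapi, dtype=float)
    labels = np.zeros(img.shape, dtype=np.int32)
    seeds = np.asarray(seeds, dtype=int)
    if seeds.size == 0:
        return labels
    smooth = ndimage.gaussian_filter(img, sigma=smoothing_sigma_um / pixel_size_um)
    mask = smooth > filters.threshold_otsu(smooth)
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (r, c) in enumerate(seeds, start=1):
        markers[r, c] = i
        if not mask[r, c]:
            warnings.warn(f"seed {i} at ({r}, {c}) lies on background", stacklevel=2)
            mask[r, c] = True
    return segmentation.watershed(-smooth, markers=markers, mask=mask).astype(np.int32)


def expand_cells(
    labels: np.ndarray,
    pixel_size_um: float,
    radius_um: float = DEFAULT_EXPANSION_UM,
) -> np.ndarray:
    """Dilate every nucleus label by ``radius_um`` to define sampling areas.

    Expansion assigns contested pixels to the nearest nucleus and never
    overwrites an original nucleus pixel, so the result covers nuclear plus
    peri-nuclear regions and remains a partition.
    """
    if radius_um < 0:
        raise ValueError("expansion radius must be non-negative")
    px = int(round(radius_um / pixel_size_um))
    if px == 0:
        return labels.copy()
    return segmentation.expand_labels(labels, distance=px)


def measure_profiles(
    sampling_map: np.ndarray,
    channel_images: Mapping[str, np.ndarray],
    nucleus_labels: np.ndarray | None = None,
    fov: str = "fov0",
) -> pd.DataFrame:
    """Per-cell mean intensities over each sampling area, with shape metrics.

    Returns one row per cell label: ``mean_<gene>`` columns for every channel,
    the sampling-area centroid (row, col), nucleus area/eccentricity (taken
    from ``nucleus_labels`` when given, else from the sampling map), and the
    field-of-view id. Labels with zero area are excluded with a warning.
    """
    sampling_map = np.asarray(sampling_map)
    ids = np.unique(sampling_map)
    ids = ids[ids > 0]
    if ids.size == 0:
        return pd.DataFrame(
            columns=["cell", "fov", "centroid_row", "centroid_col", "area",
                     "eccentricity"] + [f"mean_{g}" for g in channel_images]
        )
    for g, im in channel_images.items():
        if np.asarray(im).shape != sampling_map.shape:
            raise ValueError(f"channel {g!r} shape differs from the sampling map")
    shape_src = sampling_map if nucleus_labels is None else np.asarray(nucleus_labels)
    props = {p.label: p for p in measure.regionprops(shape_src)}
    rows = []
    for lbl in ids:
        area_mask_n = int((sampling_map == lbl).sum())
        if area_mask_n == 0:
            warnings.warn(f"label {lbl} has zero sampling area, excluded", stacklevel=2)
            continue
        p = props.get(int(lbl))
        cy, cx = ndimage.center_of_mass(sampling_map == lbl)
        row: dict[str, object] = dict(
            cell=int(lbl), fov=fov, centroid_row=float(cy), centroid_col=float(cx),
            area=int(p.area) if p is not None else area_mask_n,
            eccentricity=float(p.eccentricity) if p is not None else float("nan"),
        )
        for g, im in channel_images.items():
            row[f"mean_{g}"] = float(ndimage.mean(np.asarray(im, dtype=float),
                                                  labels=sampling_map, index=lbl))
        rows.append(row)
    return pd.DataFrame(rows)


def export_boundary_index_image(labels: np.ndarray) -> np.ndarray:
    """Image that is zero everywhere except nucleus boundary pixels, which
    carry the integer cell index."""
    labels = np.asarray(labels)
    boundaries = segmentation.find_boundaries(labels, mode="inner")
    out = np.zeros_like(labels)
    out[boundaries] = labels[boundaries]
    return out


# ---------------------------------------------------------------------------
# end-to-end convenience


@dataclass
class QuantificationResult:
    profiles: pd.DataFrame
    nucleus_labels: np.ndarray
    sampling_map: np.ndarray
    boundary_index: np.ndarray
    offsets: list[tuple[int, int]]


def quantify_field(
    cycles: Sequence[FieldImage],
    gene_channels: Mapping[str, tuple[int, str]] | None = None,
    smoothing_sigma_um: float = DEFAULT_SMOOTHING_SIGMA_UM,
    min_separation_um: float = DEFAULT_MIN_SEPARATION_UM,
    expansion_um: float = DEFAULT_EXPANSION_UM,
    fov: str = "fov0",
) -> QuantificationResult:
    """Register cycles, segment nuclei, expand, and measure every gene channel.

    ``gene_channels`` maps gene name -> (cycle index into ``cycles``, channel
    name); by default every non-nuclear channel of every cycle is measured
    under its channel name.
    """
    px = cycles[0].pixel_size_um
    if len(cycles) > 1:
        offsets, aligned = register_cycles(cycles)
    else:
        offsets, aligned = [(0, 0)], list(cycles)
    dapi = aligned[0].channels[NUCLEAR_CHANNEL]
    seeds = detect_nuclei(dapi, px, smoothing_sigma_um, min_separation_um)
    nuclei = segment_nuclei(dapi, seeds, px, smoothing_sigma_um)
    sampling = expand_cells(nuclei, px, expansion_um)
    if gene_channels is None:
        gene_channels = {
            ch: (i, ch)
            for i, cyc in enumerate(aligned)
            for ch in cyc.channels
            if ch != NUCLEAR_CHANNEL
        }
    images = {g: aligned[ci].channels[ch] for g, (ci, ch) in gene_channels.items()}
    profiles = measure_profiles(sampling, images, nucleus_labels=nuclei, fov=fov)
    return QuantificationResult(
        profiles=profiles,
        nucleus_labels=nuclei,
        sampling_map=sampling,
        boundary_index=export_boundary_index_image(nuclei),
        offsets=offsets,
    )
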