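"""Cell-of-interest segmentation across z-layers.

The cell is found on the segmentation (green) channel: a per-layer Otsu
threshold, a sum projection of the binary layers, selection of the projected
island with the largest pixel sum as the cell, then per-layer morphological
clean-up and a second Otsu round that removes dark intracellular vacuoles.
The resulting mask is used for both channels downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk, opening

from .stack_model import CellMask


@dataclass
class LayerThresholds:
    """Per-layer Otsu thresholds and the binary masks they produce.

    A degenerate (constant) layer gets ``threshold = nan`` and an empty mask.
    """

    thresholds: np.ndarray  # (z,) float, nan for degenerate layers
    masks: np.ndarray  # (z, y, x) bool


def threshold_layers(channel: np.ndarray) -> LayerThresholds:
    """Apply an Otsu threshold independently to each z-layer.

    Pixels strictly above the layer's threshold are foreground.  A layer
    whose pixels are all equal yields an empty mask (nothing is "above
    threshold" in a constant image).
    """
    channel = np.asarray(channel)
    if channel.ndim != 3 or channel.shape[0] < 1:
        raise ValueError("channel must be a 3D (z, y, x) array with z >= 1")
    nz = channel.shape[0]
    thresholds = np.full(nz, np.nan)
    masks = np.zeros(channel.shape, dtype=bool)
    for z in range(nz):
        layer = channel[z]
        if layer.max() == layer.min():
            continue
        t = threshold_otsu(layer, nbins=256)
        thresholds[z] = t
        masks[z] = layer > t
    return LayerThresholds(thresholds=thresholds, masks=masks)


def select_cell(thresholds: LayerThresholds) -> CellMask:
    """Select the single cell from the per-layer binary masks.

    The binary layers are sum-projected; disjoint islands of the projection
    are found with 4-connectivity; the island with the largest projected
    pixel-value *sum* (a proxy for 3D volume, not 2D area) is the cell.
    Each layer's mask is then restricted to that island's footprint.
    """
    masks = thresholds.masks
    projection = masks.sum(axis=0)  # per-pixel layer count
    if projection.max() == 0:
        raise ValueError("no cell found: all layer masks are empty")
    labels, n = ndi.label(projection > 0, structure=_FOUR_CONN)
    sums = ndi.sum_labels(projection, labels, index=np.arange(1, n + 1))
    cell_label = int(np.argmax(sums)) + 1
    footprint = labels == cell_label
    return CellMask(layers=masks & footprint[np.newaxis])


_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def refine_mask(
    mask: CellMask, channel: np.ndarray, struct_radius: int = 3
) -> CellMask:
    """Clean each layer's mask and remove dark intracellular vacuoles.

    Per layer: morphological closing then opening with a disk of
    ``struct_radius`` removes small noise features and fills small holes;
    then a second Otsu threshold over the layer's in-mask intensity
    histogram removes in-mask pixels below it (vacuoles and organelles with
    much lower fluorophore concentration).  A layer whose in-mask pixels are
    all equal keeps all its pixels (degenerate second threshold).
    """
    channel = np.asarray(channel)
    if channel.shape != mask.layers.shape:
        raise ValueError("channel and mask shapes must match")
    if mask.n_voxels == 0:
        raise ValueError("refine_mask requires a non-empty mask")
    selem = disk(struct_radius)
    out = np.zeros_like(mask.layers)
    for z in range(mask.layers.shape[0]):
        layer_mask = mask.layers[z]
        if not layer_mask.any():
            continue
        cleaned = opening(closing(layer_mask, selem), selem)
        if not cleaned.any():
            continue
        vals = channel[z][cleaned]
        t = _vacuole_threshold(vals)
        if t is None:
            out[z] = cleaned
            continue
        dark = cleaned & (channel[z] < t)
        # only compact dark regions are vacuoles; speckle smaller than the
        # structuring element is noise straddling a unimodal histogram split
        dark = opening(dark, selem)
        out[z] = cleaned & ~dark
    if not out.any():
        raise ValueError("refinement removed the entire mask")
    return CellMask(layers=out)


def _vacuole_threshold(vals: np.ndarray, max_depth: int = 3) -> float | None:
    """Otsu threshold below which in-mask pixels count as vacuole candidates.

    Vacuoles are a *minority* of the cell cross-section with much lower
    intensity, so a valid split must label fewer than half the pixels dark.
    When the first Otsu split instead separates a bright minority (cell rim,
    puncta) from the bulk — i.e. the dark class is the majority — the search
    recurses into the lower class to look for a darker minority there.
    Returns None when no such split exists (near-uniform layer).
    """
    for _ in range(max_depth):
        if vals.size == 0 or vals.max() == vals.min():
            return None
        t = threshold_otsu(vals, nbins=256)
        dark_frac = float((vals < t).mean())
        if dark_frac < 0.5:
            return float(t)
        vals = vals[vals < t]
    return None


def segment_cell(
    channel: np.ndarray, struct_radius: int = 3
) -> tuple[CellMask, LayerThresholds]:
    """Full step-1 pipeline: threshold, select the largest object, refine."""
    thr = threshold_layers(channel)
    cell = select_cell(thr)
    refined = refine_mask(cell, channel, struct_radius=struct_radius)
    return refined, thr
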