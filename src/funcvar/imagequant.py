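"""From three-channel field images to the per-cell feature table.

The pipeline mirrors standard high-content practice: nuclei are
segmented from the nuclear stain by global thresholding with area
bounds; cell regions are approximated by constrained nearest-nucleus
expansion of the nucleus masks (growth stops at a maximum radius or at
the equidistant line between neighboring nuclei); endosome-like
compartments are detected in the DiI channel by local-adaptive
thresholding (local mean over a square window plus an offset) and
clipped to cell regions; and the five phenotypic parameters are
quantified per cell from background-subtracted intensities, with
quality-control filters (edge contact, diameter bounds, nucleus
neighbor distance) removing cells from the output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, segmentation
from skimage.filters import threshold_otsu


@dataclass
class SegmentationConfig:
    #: nuclear-stain threshold; None selects Otsu's method
    nucleus_threshold: Optional[float] = None
    min_nucleus_area: int = 30
    max_nucleus_area: int = 1500
    max_dilation_radius: float = 24.0
    adaptive_window: int = 31
    adaptive_offset: float = 30.0
    min_seg_area: int = 3
    max_seg_area: int = 400
    min_cell_diameter: float = 8.0
    max_cell_diameter: float = 120.0
    min_neighbor_distance: float = 0.0
    edge_margin: int = 2

    def __post_init__(self):
        if self.min_nucleus_area >= self.max_nucleus_area:
            raise ValueError("min_nucleus_area must be below max_nucleus_area")
        if self.min_seg_area >= self.max_seg_area:
            raise ValueError("min_seg_area must be below max_seg_area")
        if self.min_cell_diameter >= self.max_cell_diameter:
            raise ValueError("min_cell_diameter must be below "
                             "max_cell_diameter")
        if self.adaptive_window % 2 == 0 or self.adaptive_window < 3:
            raise ValueError("adaptive_window must be an odd integer >= 3")
        if self.max_dilation_radius <= 0 or self.edge_margin < 0:
            raise ValueError("invalid dilation radius or edge margin")


def _filter_labels_by_area(labels: np.ndarray, min_area: int,
                           max_area: int) -> np.ndarray:
    counts = np.bincount(labels.ravel())
    bad = (counts < min_area) | (counts > max_area)
    bad[0] = False
    out = labels.copy()
    out[bad[labels]] = 0
    return _relabel(out)


def _relabel(labels: np.ndarray) -> np.ndarray:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    lut = np.zeros(labels.max() + 1 if labels.size else 1, dtype=np.int32)
    lut[ids] = np.arange(1, len(ids) + 1, dtype=np.int32)
    return lut[labels]


def segment_nuclei(nuclei_img: np.ndarray,
                   config: SegmentationConfig) -> np.ndarray:
    """Labeled nucleus mask from the nuclear-stain channel."""
    img = np.asarray(nuclei_img, dtype=float)
    if config.nucleus_threshold is not None:
        thr = config.nucleus_threshold
    elif np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=np.int32)
    else:
        thr = threshold_otsu(img)
    labels = measure.label(img > thr, connectivity=2).astype(np.int32)
    return _filter_labels_by_area(labels, config.min_nucleus_area,
                                  config.max_nucleus_area)


def approximate_cells(nucleus_labels: np.ndarray,
                      config: SegmentationConfig) -> np.ndarray:
    """Cell regions by nearest-nucleus expansion up to the maximum
    dilation radius; neighboring regions meet at the equidistant line
    between their nuclei (ties resolved deterministically)."""
    return segmentation.expand_labels(
        nucleus_labels, distance=config.max_dilation_radius).astype(np.int32)


def segment_compartments(dii_img: np.ndarray, cell_labels: np.ndarray,
                         config: SegmentationConfig
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Endosome-like segments by local-adaptive thresholding.

    A pixel is foreground when it exceeds the local mean over a square
    ``adaptive_window`` by more than ``adaptive_offset``; foreground is
    clipped to cell regions.  Connected pieces are split along cell
    boundaries, so every segment belongs to exactly one cell.  Returns
    (segment label image, owner array mapping segment label -> cell
    label).
    """
    img = np.asarray(dii_img, dtype=float)
    if img.shape != cell_labels.shape:
        raise ValueError("DiI channel and cell mask differ in shape")
    local_mean = ndimage.uniform_filter(img, size=config.adaptive_window,
                                        mode="reflect")
    mask = (img > local_mean + config.adaptive_offset) & (cell_labels > 0)
    raw = measure.label(mask, connectivity=2).astype(np.int64)
    # split connected foreground that straddles a cell boundary
    combined = raw * (int(cell_labels.max()) + 1) + cell_labels
    combined[raw == 0] = 0
    keys, segs = np.unique(combined, return_inverse=True)
    segs = segs.reshape(img.shape).astype(np.int32)
    if keys[0] != 0:  # np.unique sorts; key 0 (background) may be absent
        segs += 1
    labels = _filter_labels_by_area(segs, config.min_seg_area,
                                    config.max_seg_area)
    owners = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    flat_lbl = labels.ravel()
    nz = flat_lbl > 0
    owners[flat_lbl[nz]] = cell_labels.ravel()[nz]
    return labels, owners


def _edge_touchers(cell_labels: np.ndarray, margin: int) -> set[int]:
    if margin <= 0:
        border = np.concatenate([cell_labels[0, :], cell_labels[-1, :],
                                 cell_labels[:, 0], cell_labels[:, -1]])
    else:
        m = margin
        border = np.concatenate([
            cell_labels[:m, :].ravel(), cell_labels[-m:, :].ravel(),
            cell_labels[:, :m].ravel(), cell_labels[:, -m:].ravel()])
    return set(np.unique(border[border > 0]).tolist())


def quantify(gfp_img: np.ndarray, dii_img: np.ndarray,
             cell_labels: np.ndarray, seg_labels: np.ndarray,
             seg_owners: np.ndarray, backgrounds: Mapping[str, float],
             config: SegmentationConfig,
             nucleus_labels: Optional[np.ndarray] = None,
             image_id: int = 1) -> pd.DataFrame:
    """Per-cell feature records from background-subtracted intensities.

    ``backgrounds`` must provide 'gfp' and 'dii' levels; the GFP level
    is conventionally measured on the experiment's transfection-control
    sample.  Negative background-subtracted pixels clamp to zero.  Cells
    touching the edge margin, outside the diameter bounds, or closer to
    a neighboring nucleus than ``min_neighbor_distance`` are omitted.
    """
    for ch in ("gfp", "dii"):
        if ch not in backgrounds:
            raise KeyError(f"missing background level for channel {ch!r}")
    gfp = np.clip(np.asarray(gfp_img, dtype=float) - backgrounds["gfp"], 0, None)
    dii = np.clip(np.asarray(dii_img, dtype=float) - backgrounds["dii"], 0, None)

    n_cells = int(cell_labels.max())
    if n_cells == 0:
        return pd.DataFrame(columns=["image_id", "cell_id", "gfp",
                                     "total_ldl", "ldl_concentration",
                                     "seg_number", "seg_area"])
    flat_cells = cell_labels.ravel()
    cell_area = np.bincount(flat_cells, minlength=n_cells + 1)
    gfp_sum = np.bincount(flat_cells, weights=gfp.ravel(),
                          minlength=n_cells + 1)

    n_segs = int(seg_labels.max())
    seg_area_px = np.bincount(seg_labels.ravel(), minlength=n_segs + 1)
    seg_dii = np.bincount(seg_labels.ravel(), weights=dii.ravel(),
                          minlength=n_segs + 1)
    total = np.zeros(n_cells + 1)
    area = np.zeros(n_cells + 1)
    count = np.zeros(n_cells + 1, dtype=int)
    for seg in range(1, n_segs + 1):
        owner = seg_owners[seg]
        if owner > 0:
            total[owner] += seg_dii[seg]
            area[owner] += seg_area_px[seg]
            count[owner] += 1

    dropped = _edge_touchers(cell_labels, config.edge_margin)
    eq_diam = np.sqrt(4.0 * cell_area / np.pi)
    if config.min_neighbor_distance > 0 and nucleus_labels is not None:
        centroids = ndimage.center_of_mass(
            nucleus_labels > 0, nucleus_labels, range(1, n_cells + 1))
        pts = np.array(centroids, dtype=float)
        if len(pts) > 1:
            d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
            np.fill_diagonal(d, np.inf)
            too_close = np.where(d.min(axis=1) < config.min_neighbor_distance)[0]
            dropped |= {int(i) + 1 for i in too_close}

    rows = []
    for cid in range(1, n_cells + 1):
        if cid in dropped or cell_area[cid] == 0:
            continue
        if not (config.min_cell_diameter <= eq_diam[cid]
                <= config.max_cell_diameter):
            continue
        rows.append({
            "image_id": image_id,
            "cell_id": cid,
            "gfp": gfp_sum[cid] / cell_area[cid],
            "total_ldl": total[cid],
            "ldl_concentration": (total[cid] / area[cid]
                                  if area[cid] > 0 else 0.0),
            "seg_number": int(count[cid]),
            "seg_area": float(area[cid]),
        })
    return pd.DataFrame(rows)


def quantify_field(nuclei_img: np.ndarray, gfp_img: np.ndarray,
                   dii_img: np.ndarray, backgrounds: Mapping[str, float],
                   config: SegmentationConfig,
                   image_id: int = 1) -> pd.DataFrame:
    """Full chain on one field: nuclei -> cells -> compartments ->
    per-cell features."""
    nuclei = segment_nuclei(nuclei_img, config)
    cells = approximate_cells(nuclei, config)
    segs, owners = segment_compartments(dii_img, cells, config)
    return quantify(gfp_img, dii_img, cells, segs, owners, backgrounds,
                    config, nucleus_labels=nuclei, image_id=image_id)
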