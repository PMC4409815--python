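"""Synthetic three-channel microscopy fields with ground truth.

Each programmed cell renders as a bright nucleus disk (nuclei channel),
a diffuse cytoplasmic GFP disk (GFP channel) and a set of punctate
endosome-like DiI spots (DiI channel), on a constant background with
additive Gaussian noise, quantized to 16-bit grayscale.  The ground
truth records, per cell, the five phenotypic parameters as actually
rendered (pixel sums of the added DiI signal), so segmentation and
quantification can be validated against exact expectations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.draw import disk


@dataclass
class OpticsConfig:
    shape: tuple[int, int] = (512, 512)
    nuclei_background: float = 200.0
    gfp_background: float = 100.0
    dii_background: float = 120.0
    noise_sd: float = 4.0
    nucleus_radius: int = 7
    cell_radius: int = 24
    gfp_radius: int = 18
    punctum_radius: int = 2
    nucleus_intensity: float = 4000.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0 < self.punctum_radius < self.nucleus_radius
                < self.gfp_radius <= self.cell_radius):
            raise ValueError("radii must satisfy punctum < nucleus < GFP "
                             "<= cell")


@dataclass(frozen=True)
class Punctum:
    dy: float
    dx: float
    total_intensity: float


@dataclass(frozen=True)
class ProgrammedCell:
    y: float
    x: float
    gfp_intensity: float
    puncta: tuple[Punctum, ...] = ()


@dataclass
class FieldRender:
    nuclei: np.ndarray
    gfp: np.ndarray
    dii: np.ndarray
    nucleus_labels: np.ndarray
    cell_labels: np.ndarray
    truth: pd.DataFrame


def _require_inside(cell: ProgrammedCell, optics: OpticsConfig) -> None:
    h, w = optics.shape
    r = optics.cell_radius
    if not (r <= cell.y < h - r and r <= cell.x < w - r):
        raise ValueError(f"cell at ({cell.y:.0f}, {cell.x:.0f}) does not fit "
                         "the field")


def render_fields(cells: Sequence[ProgrammedCell], optics: OpticsConfig,
                  seed: int = 0) -> FieldRender:
    """Render one field of programmed cells into three channels.

    The ground-truth table records per cell: gfp_expression (programmed
    amplitude over background), total_ldl (sum of added DiI intensity),
    ldl_concentration (total over punctum pixel area), seg_number and
    seg_area (pixels), plus the center coordinates.  Label masks give
    the true nucleus disks and the true cell disks (radius
    ``cell_radius``).
    """
    rng = np.random.default_rng(seed)
    h, w = optics.shape
    nuclei = np.full((h, w), optics.nuclei_background, dtype=float)
    gfp = np.full((h, w), optics.gfp_background, dtype=float)
    dii = np.full((h, w), optics.dii_background, dtype=float)
    nucleus_labels = np.zeros((h, w), dtype=np.int32)
    cell_labels = np.zeros((h, w), dtype=np.int32)

    records = []
    for idx, cell in enumerate(cells, start=1):
        _require_inside(cell, optics)
        rr, cc = disk((cell.y, cell.x), optics.nucleus_radius, shape=(h, w))
        nuclei[rr, cc] += optics.nucleus_intensity
        nucleus_labels[rr, cc] = idx
        rr, cc = disk((cell.y, cell.x), optics.cell_radius, shape=(h, w))
        cell_labels[rr, cc] = idx
        rr, cc = disk((cell.y, cell.x), optics.gfp_radius, shape=(h, w))
        gfp[rr, cc] += cell.gfp_intensity

        total = 0.0
        seg_area = 0
        for p in cell.puncta:
            rr, cc = disk((cell.y + p.dy, cell.x + p.dx),
                          optics.punctum_radius, shape=(h, w))
            per_px = p.total_intensity / len(rr)
            dii[rr, cc] += per_px
            total += per_px * len(rr)
            seg_area += len(rr)
        records.append({
            "cell_id": idx,
            "y": cell.y,
            "x": cell.x,
            "gfp_expression": cell.gfp_intensity,
            "total_ldl": total,
            "ldl_concentration": total / seg_area if seg_area else 0.0,
            "seg_number": len(cell.puncta),
            "seg_area": seg_area,
        })

    for channel in (nuclei, gfp, dii):
        if optics.noise_sd > 0:
            channel += rng.normal(0.0, optics.noise_sd, channel.shape)
    as_u16 = [np.clip(np.rint(ch), 0, 65535).astype(np.uint16)
              for ch in (nuclei, gfp, dii)]
    return FieldRender(nuclei=as_u16[0], gfp=as_u16[1], dii=as_u16[2],
                       nucleus_labels=nucleus_labels, cell_labels=cell_labels,
                       truth=pd.DataFrame(records))


def random_cells(n_cells: int, optics: OpticsConfig, rng: np.random.Generator,
                 gfp_median: float = 1500.0, gfp_sigma: float = 0.5,
                 puncta_range: tuple[int, int] = (2, 8),
                 punctum_total_median: float = 4000.0,
                 punctum_total_sigma: float = 0.4) -> list[ProgrammedCell]:
    """Programmed cells on a jittered grid, puncta spread on a ring
    between nucleus and cell boundary with non-overlapping positions."""
    h, w = optics.shape
    jitter = 4
    margin = optics.cell_radius + jitter + 1
    pitch = 2 * optics.cell_radius + 12
    ys = np.arange(margin, h - margin, pitch)
    xs = np.arange(margin, w - margin, pitch)
    sites = [(y, x) for y in ys for x in xs]
    if n_cells > len(sites):
        raise ValueError(f"at most {len(sites)} cells fit this field")
    chosen = rng.permutation(len(sites))[:n_cells]
    cells = []
    for s in chosen:
        y0, x0 = sites[s]
        y = y0 + rng.uniform(-jitter, jitter)
        x = x0 + rng.uniform(-jitter, jitter)
        k = int(rng.integers(puncta_range[0], puncta_range[1] + 1))
        r_lo = optics.nucleus_radius + optics.punctum_radius + 1
        r_hi = optics.cell_radius - optics.punctum_radius - 2
        angles = (np.arange(k) + rng.uniform(0.0, 1.0)) * 2 * np.pi / k
        puncta = []
        for ang in angles:
            rad = rng.uniform(r_lo, r_hi)
            total = float(np.exp(rng.normal(np.log(punctum_total_median),
                                            punctum_total_sigma)))
            puncta.append(Punctum(dy=rad * np.sin(ang), dx=rad * np.cos(ang),
                                  total_intensity=total))
        gfp_level = float(np.exp(rng.normal(np.log(gfp_median), gfp_sigma)))
        cells.append(ProgrammedCell(y=y, x=x, gfp_intensity=gfp_level,
                                    puncta=tuple(puncta)))
    return cells
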