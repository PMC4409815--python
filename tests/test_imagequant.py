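"""Rendering and image quantification: segmentation, cell
approximation, compartment detection, per-cell features."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage
from skimage.draw import disk

from funcvar.imagequant import (SegmentationConfig, approximate_cells,
                                quantify, quantify_field, segment_nuclei,
                                segment_compartments)
from funcvar.render import (OpticsConfig, ProgrammedCell, Punctum,
                            random_cells, render_fields)

CFG = SegmentationConfig()
OPTICS = OpticsConfig()


def _disk_image(centers, radius, value=1000.0, shape=(128, 128), bg=0.0):
    img = np.full(shape, bg)
    for c in centers:
        rr, cc = disk(c, radius, shape=shape)
        img[rr, cc] = value
    return img


# --- nuclei ---------------------------------------------------------------

def test_blank_image_has_no_nuclei():
    assert segment_nuclei(np.zeros((64, 64)), CFG).max() == 0


def test_well_separated_disks_are_counted():
    img = _disk_image([(30, 30), (30, 90), (90, 60)], radius=8)
    labels = segment_nuclei(img, CFG)
    assert labels.max() == 3


def test_small_disk_excluded_by_area_bound():
    img = _disk_image([(30, 30)], radius=8) + _disk_image([(90, 90)], radius=2)
    labels = segment_nuclei(img, CFG)  # min area 30 px excludes r=2 (13 px)
    assert labels.max() == 1


# --- cell approximation ---------------------------------------------------

def test_cell_count_equals_nucleus_count():
    img = _disk_image([(30, 30), (30, 90), (90, 60)], radius=8)
    nuclei = segment_nuclei(img, CFG)
    cells = approximate_cells(nuclei, CFG)
    assert set(np.unique(cells)) == set(np.unique(nuclei))
    # every cell contains its nucleus
    assert (cells[nuclei > 0] == nuclei[nuclei > 0]).all()


def test_single_nucleus_dilated_to_max_radius():
    img = _disk_image([(64, 64)], radius=8, shape=(128, 128))
    nuclei = segment_nuclei(img, CFG)
    cells = approximate_cells(nuclei, CFG)
    dist_out = ndimage.distance_transform_edt(nuclei == 0)
    grown = cells > 0
    assert grown[dist_out <= CFG.max_dilation_radius - 1].all()
    assert not grown[dist_out > CFG.max_dilation_radius + 1].any()


def test_two_nuclei_meet_on_equidistant_line():
    img = _disk_image([(64, 40), (64, 88)], radius=8, shape=(128, 128))
    nuclei = segment_nuclei(img, CFG)
    cells = approximate_cells(nuclei, CFG)
    d1 = ndimage.distance_transform_edt(nuclei != 1)
    d2 = ndimage.distance_transform_edt(nuclei != 2)
    assert (d1[cells == 1] <= d2[cells == 1] + 1e-6).all()
    assert (d2[cells == 2] <= d1[cells == 2] + 1e-6).all()


# --- compartments ---------------------------------------------------------

def test_uniform_dii_yields_no_segments():
    cells = np.ones((64, 64), dtype=np.int32)
    segs, _ = segment_compartments(np.full((64, 64), 500.0), cells, CFG)
    assert segs.max() == 0


def test_puncta_counted_per_cell():
    cells = np.zeros((128, 128), dtype=np.int32)
    rr, cc = disk((64, 64), 30)
    cells[rr, cc] = 1
    dii = _disk_image([(60, 60), (70, 70), (55, 75)], radius=2, value=800.0,
                      bg=100.0)
    segs, owners = segment_compartments(dii, cells, CFG)
    assert segs.max() == 3
    assert (owners[1:] == 1).all()


def test_punctum_outside_cells_is_unassigned():
    cells = np.zeros((128, 128), dtype=np.int32)
    rr, cc = disk((32, 32), 20)
    cells[rr, cc] = 1
    dii = _disk_image([(100, 100)], radius=2, value=800.0, bg=100.0)
    segs, _ = segment_compartments(dii, cells, CFG)
    assert segs.max() == 0


def test_segment_straddling_two_cells_is_split():
    cells = np.zeros((64, 64), dtype=np.int32)
    cells[:, :32] = 1
    cells[:, 32:] = 2
    dii = np.zeros((64, 64)) + 100.0
    rr, cc = disk((32, 32), 3)
    dii[rr, cc] = 900.0
    segs, owners = segment_compartments(dii, cells, CFG)
    assert segs.max() == 2
    assert set(owners[1:]) == {1, 2}


# --- quantification -------------------------------------------------------

def _render_and_quantify(n_cells=16, seed=0, optics=OPTICS, cfg=CFG):
    rng = np.random.default_rng(seed)
    cells = random_cells(n_cells, optics, rng)
    field = render_fields(cells, optics, seed=seed)
    table = quantify_field(field.nuclei, field.gfp, field.dii,
                           {"gfp": optics.gfp_background,
                            "dii": optics.dii_background}, cfg)
    return field, table


def _match_truth(field, table, cfg=CFG):
    nuclei = segment_nuclei(field.nuclei, cfg)
    cent = np.array(ndimage.center_of_mass(nuclei > 0, nuclei,
                                           range(1, nuclei.max() + 1)))
    rows = []
    for _, row in table.iterrows():
        cy, cx = cent[int(row["cell_id"]) - 1]
        d = np.hypot(field.truth["y"] - cy, field.truth["x"] - cx)
        rows.append(field.truth.loc[d.idxmin()])
    return pd.DataFrame(rows).reset_index(drop=True)


def test_background_image_gives_zero_features():
    optics = OpticsConfig(noise_sd=0.0)
    cells = [ProgrammedCell(y=64, x=64, gfp_intensity=0.0, puncta=())]
    field = render_fields(cells, optics, seed=0)
    table = quantify_field(field.nuclei, field.gfp, field.dii,
                           {"gfp": optics.gfp_background,
                            "dii": optics.dii_background}, CFG)
    assert len(table) == 1
    assert table.iloc[0]["gfp"] == 0.0
    assert table.iloc[0]["total_ldl"] == 0.0
    assert table.iloc[0]["seg_number"] == 0
    assert table.iloc[0]["seg_area"] == 0.0


def test_recovered_totals_within_5_percent_of_truth():
    field, table = _render_and_quantify(seed=1)
    truth = _match_truth(field, table)
    assert len(table) >= 10
    rel = np.abs(table["total_ldl"].to_numpy()
                 - truth["total_ldl"].to_numpy()) / truth["total_ldl"]
    assert (rel < 0.05).all()
    assert (table["seg_number"].to_numpy()
            == truth["seg_number"].to_numpy()).all()


def test_concentration_times_area_equals_total():
    _, table = _render_and_quantify(seed=2)
    with_segs = table[table["seg_number"] > 0]
    assert np.allclose(with_segs["ldl_concentration"] * with_segs["seg_area"],
                       with_segs["total_ldl"])


def test_recovery_correlates_with_truth():
    pairs = {"gfp": "gfp_expression", "total_ldl": "total_ldl",
             "ldl_concentration": "ldl_concentration",
             "seg_number": "seg_number", "seg_area": "seg_area"}
    tables, truths = [], []
    for seed in (3, 4):
        field, table = _render_and_quantify(n_cells=20, seed=seed)
        tables.append(table)
        truths.append(_match_truth(field, table))
    table = pd.concat(tables, ignore_index=True)
    truth = pd.concat(truths, ignore_index=True)
    assert len(table) >= 25
    for rec, tru in pairs.items():
        r = np.corrcoef(table[rec], truth[tru])[0, 1]
        assert r > 0.95, f"{rec}: r={r:.3f}"


def test_truth_mask_consistent_with_rendered_dii():
    """Summing rendered, background-subtracted DiI inside the true cell
    mask reproduces the recorded total within quantization error."""
    optics = OpticsConfig(noise_sd=0.0)
    rng = np.random.default_rng(5)
    cells = random_cells(10, optics, rng)
    field = render_fields(cells, optics, seed=5)
    dii = field.dii.astype(float) - optics.dii_background
    for _, row in field.truth.iterrows():
        mask = field.cell_labels == row["cell_id"]
        rendered = dii[mask].sum()
        assert rendered == pytest.approx(row["total_ldl"],
                                         abs=0.5 * mask.sum() + 1)


def test_edge_cell_omitted():
    optics = OpticsConfig(noise_sd=0.0)
    inside = ProgrammedCell(y=64, x=64, gfp_intensity=500.0,
                            puncta=(Punctum(10, 0, 3000.0),))
    field = render_fields([inside], optics, seed=0)
    # force the cell against the image edge by cropping
    y0 = 64 - CFG.edge_margin  # crop so the cell region touches the border
    crop = slice(int(y0 - optics.cell_radius), None)
    table = quantify_field(field.nuclei[crop], field.gfp[crop],
                           field.dii[crop],
                           {"gfp": optics.gfp_background,
                            "dii": optics.dii_background}, CFG)
    assert len(table) == 0


def test_translation_invariance_inside_margin():
    optics = OpticsConfig(noise_sd=0.0)
    puncta = (Punctum(8, 3, 2500.0), Punctum(-9, -2, 1800.0))
    base = ProgrammedCell(y=60, x=60, gfp_intensity=700.0, puncta=puncta)
    shifted = ProgrammedCell(y=65, x=67, gfp_intensity=700.0, puncta=puncta)
    t1 = quantify_field(*[getattr(render_fields([base], optics, seed=0), ch)
                          for ch in ("nuclei", "gfp", "dii")],
                        {"gfp": optics.gfp_background,
                         "dii": optics.dii_background}, CFG)
    t2 = quantify_field(*[getattr(render_fields([shifted], optics, seed=0),
                                  ch) for ch in ("nuclei", "gfp", "dii")],
                        {"gfp": optics.gfp_background,
                         "dii": optics.dii_background}, CFG)
    for col in ("gfp", "total_ldl", "ldl_concentration", "seg_number",
                "seg_area"):
        assert t1.iloc[0][col] == pytest.approx(t2.iloc[0][col], rel=0.02)


def test_quantify_requires_backgrounds():
    field, _ = _render_and_quantify(n_cells=2, seed=6)
    with pytest.raises(KeyError):
        quantify_field(field.nuclei, field.gfp, field.dii, {"gfp": 100.0},
                       CFG)


def test_render_rejects_out_of_field_cells():
    with pytest.raises(ValueError):
        render_fields([ProgrammedCell(y=2, x=2, gfp_intensity=1.0)], OPTICS)


def test_zero_cells_renders_pure_background():
    optics = OpticsConfig(noise_sd=0.0)
    field = render_fields([], optics, seed=0)
    assert (field.nuclei == optics.nuclei_background).all()
    assert (field.gfp == optics.gfp_background).all()
    assert (field.dii == optics.dii_background).all()
    assert len(field.truth) == 0


def test_config_validation():
    with pytest.raises(ValueError):
        SegmentationConfig(adaptive_window=10)
    with pytest.raises(ValueError):
        SegmentationConfig(min_nucleus_area=100, max_nucleus_area=50)
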