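"""Ion-image extraction, registration, ROI quantification, calibration."""

import numpy as np
import pytest

from conftest import make_truth
from spotscreen.chem import AdductSpec, parse_formula
from spotscreen.imaging_io import ImagingDataset
from spotscreen.platemap import (
    ChannelSpec,
    PlateLayout,
    SpeciesEntry,
    SpeciesTable,
    assign_channels,
    build_layout,
)
from spotscreen.quantify import (
    IonImage,
    Registration,
    estimate_conversion,
    extract_ion_image,
    fit_calibration,
    quantify_wells,
    register_grid,
    total_ion_image,
)
from spotscreen.synthetic import simulate_membrane


def empty_dataset(nx=4, ny=4):
    frames = [[(np.empty(0), np.empty(0, dtype=np.float32))] for _ in range(nx * ny)]
    return ImagingDataset(nx=nx, ny=ny, pixel_size_um=500.0, frames=frames)


# ---------------------------------------------------------------- extraction

def test_extract_from_empty_dataset_is_zero():
    ch = ChannelSpec("p", target_mz=208.133, window=0.2, polarity=1)
    img = extract_ion_image(empty_dataset(), ch)
    assert img.data.shape == (4, 4)
    assert np.all(img.data == 0)


def test_extraction_window_is_half_open_and_excludes_outside_peaks():
    """A channel centered between two peaks 0.3 Da apart captures neither."""
    frames = [[(np.array([100.0, 100.3]), np.array([5.0, 7.0], dtype=np.float32))]]
    ds = ImagingDataset(nx=1, ny=1, pixel_size_um=500.0, frames=frames)
    mid = ChannelSpec("mid", target_mz=100.15, window=0.2, polarity=1)
    assert extract_ion_image(ds, mid).data[0, 0] == 0.0
    on_peak = ChannelSpec("on", target_mz=100.0, window=0.2, polarity=1)
    assert extract_ion_image(ds, on_peak).data[0, 0] == 5.0


def test_signal_confined_to_spot_footprints(small_plate):
    layout, species = small_plate
    convs = {w: 1.0 for w in layout.well_labels()}
    ds, _ = simulate_membrane(layout, species, make_truth(layout, convs))
    a = assign_channels(species)
    img = extract_ion_image(ds, a.channel_for_role("product"))
    assert img.data.max() > 0
    # far corners of each cell are dominated by baseline, centers by signal
    center = img.data[5, 5]
    corner = img.data[0, 0]
    assert center > 10 * corner


def test_polarity_mismatch_rejected():
    ds = empty_dataset()
    ch = ChannelSpec("n", target_mz=261.0, window=0.2, polarity=-1)
    with pytest.raises(ValueError, match="polarity"):
        extract_ion_image(ds, ch)


# ---------------------------------------------------------------- registration

def test_registration_null_offset(small_plate):
    layout, species = small_plate
    ds, _ = simulate_membrane(layout, species,
                              make_truth(layout, {w: 0.5 for w in layout.well_labels()}))
    reg = register_grid(total_ion_image(ds), layout)
    px_mm = ds.pixel_size_um / 2000.0
    assert abs(reg.dx_mm) < px_mm and abs(reg.dy_mm) < px_mm
    assert reg.n_spots_used == layout.n_wells


def test_registration_recovers_known_offset(imine_amine):
    sub, _, H = imine_amine
    layout = build_layout(4, 6)
    offset = (0.3, 0.8)
    shifted = PlateLayout(4, 6, 5.0, offset)
    entries = [SpeciesEntry(w, "substrate", sub, H) for w in shifted.well_labels()]
    species = SpeciesTable(entries, shifted)
    ds, _ = simulate_membrane(shifted, species,
                              make_truth(shifted, {w: 0.0 for w in shifted.well_labels()}))
    reg = register_grid(total_ion_image(ds), layout)
    assert reg.dx_mm == pytest.approx(offset[0], abs=0.25)
    assert reg.dy_mm == pytest.approx(offset[1], abs=0.25)


def test_registration_rejects_blank_membrane():
    with pytest.raises(ValueError, match="no spots"):
        register_grid(total_ion_image(empty_dataset(40, 40)), build_layout(2, 2))


# ---------------------------------------------------------------- well sums

def uniform_image(value, ny=10, nx=10, label="u", role="other"):
    ch = ChannelSpec(label, target_mz=100.0, window=0.2, polarity=1,
                     species_role=role)
    return IonImage(data=np.full((ny, nx), float(value)), channel=ch,
                    pixel_size_um=500.0)


def test_uniform_image_roi_sum_is_value_times_pixels():
    layout = build_layout(1, 1)  # one 5 mm cell = 10x10 pixels at 500 um
    img = uniform_image(3.0)
    q = quantify_wells([img], layout, margin=0.1)
    c = q[0].channels["u"]
    assert c.raw == pytest.approx(3.0 * c.n_roi_pixels)
    assert c.background == pytest.approx(3.0)
    assert c.corrected == 0.0  # flat field is all background


def test_summation_linearity_per_well(small_plate):
    layout, species = small_plate
    truth_a = make_truth(layout, {w: 0.3 for w in layout.well_labels()}, seed=1)
    truth_b = make_truth(layout, {w: 0.9 for w in layout.well_labels()}, seed=2)
    a_ds, _ = simulate_membrane(layout, species, truth_a)
    b_ds, _ = simulate_membrane(layout, species, truth_b)
    ch = assign_channels(species).channel_for_role("product")
    img_a = extract_ion_image(a_ds, ch)
    img_b = extract_ion_image(b_ds, ch)
    summed = IonImage(data=img_a.data + img_b.data, channel=ch,
                      pixel_size_um=img_a.pixel_size_um)
    qa = quantify_wells([img_a], layout)
    qb = quantify_wells([img_b], layout)
    qs = quantify_wells([summed], layout)
    for wa, wb, ws in zip(qa, qb, qs):
        assert ws.channels[ch.label].raw == pytest.approx(
            wa.channels[ch.label].raw + wb.channels[ch.label].raw, rel=1e-9)
        assert ws.channels[ch.label].corrected == pytest.approx(
            wa.channels[ch.label].corrected + wb.channels[ch.label].corrected, rel=1e-6,
            abs=1e-6)


def test_blank_wells_flagged_empty(imine_amine):
    sub, prod, H = imine_amine
    layout = build_layout(1, 3)
    entries = [
        SpeciesEntry("A1", "substrate", sub, H),
        SpeciesEntry("A1", "product", prod, H),
        SpeciesEntry("A2", "substrate", sub, H),
        SpeciesEntry("A2", "product", prod, H),
    ]  # A3 carries no species at all
    species = SpeciesTable(entries, layout)
    truth = make_truth(layout, {"A1": 1.0, "A2": 0.0, "A3": 0.0})
    truth.wells["A2"] = type(truth.wells["A2"])(0.0, 0.0)  # declared but empty
    ds, _ = simulate_membrane(layout, species, truth)
    a = assign_channels(species)
    imgs = [extract_ion_image(ds, c) for c in a.channels]
    q = {w.well: w for w in quantify_wells(imgs, layout)}
    assert "empty" not in q["A1"].flags
    assert "empty" in q["A2"].flags
    assert "empty" in q["A3"].flags


def test_large_registration_residual_rejected():
    layout = build_layout(1, 1)
    bad = Registration(0.0, 0.0, residual_mm=3.0, n_spots_used=1)
    with pytest.raises(ValueError, match="residual"):
        quantify_wells([uniform_image(1.0)], layout, bad)


def test_mismatched_image_shapes_rejected():
    layout = build_layout(1, 1)
    with pytest.raises(ValueError, match="dimension"):
        quantify_wells([uniform_image(1.0, 10, 10), uniform_image(1.0, 8, 8, "v")],
                       layout)


# ---------------------------------------------------------------- calibration

def test_perfect_line_gives_r2_one_and_exact_slope():
    x = [0.005, 0.01, 0.025, 0.05, 0.075, 0.1]
    y = [10.0 * c for c in x]
    cal = fit_calibration(x, y)
    assert cal.r_squared == pytest.approx(1.0, abs=1e-12)
    assert cal.slope == pytest.approx(10.0, rel=1e-9)
    assert cal.lod_mM == pytest.approx(0.0, abs=1e-9)
    assert cal.saturated_points == ()


def test_saturated_point_excluded():
    x = np.array([0.005, 0.01, 0.025, 0.05, 0.075, 0.1, 2.0])
    y = 1000.0 * x / (1 + x / 1.0)  # Langmuir with K = 1 mM
    cal = fit_calibration(list(x), list(y))
    assert 6 in cal.saturated_points
    assert cal.linear_range_mM[1] == pytest.approx(0.1)


def test_too_few_points_rejected():
    with pytest.raises(ValueError):
        fit_calibration([0.1, 0.2], [1.0, 2.0])


# ---------------------------------------------------------------- conversion

def make_quant(p, s, noise_floor=0.0):
    from spotscreen.quantify import ChannelQuant, WellQuant
    return WellQuant(well="A1", channels={
        "prod": ChannelQuant(p, 0.0, p, noise_floor, 64, role="product"),
        "sub": ChannelQuant(s, 0.0, s, noise_floor, 64, role="substrate"),
    })


def test_conversion_formula():
    q = make_quant(80.0, 20.0)
    assert estimate_conversion(q, 1.0) == pytest.approx(0.8)


def test_conversion_boundary_zero_product():
    q = make_quant(0.0, 50.0)
    assert estimate_conversion(q, 1.0) == 0.0


def test_conversion_undefined_for_empty_well():
    q = make_quant(0.0, 0.0, noise_floor=10.0)
    assert estimate_conversion(q, 1.0) is None
    assert "empty" in q.flags


def test_conversion_requires_both_channels():
    from spotscreen.quantify import ChannelQuant, WellQuant
    q = WellQuant(well="A1", channels={
        "prod": ChannelQuant(1.0, 0.0, 1.0, 0.0, 64, role="product")})
    with pytest.raises(KeyError):
        estimate_conversion(q)


def test_conversion_monotone_in_true_conversion(imine_amine):
    """Noise-free: increasing true conversion never decreases the estimate."""
    sub, prod, H = imine_amine
    layout = build_layout(1, 6)
    entries = []
    for w in layout.well_labels():
        entries.append(SpeciesEntry(w, "substrate", sub, H))
        entries.append(SpeciesEntry(w, "product", prod, H))
    species = SpeciesTable(entries, layout)
    convs = {layout.label(0, i): c
             for i, c in enumerate([0.0, 0.2, 0.4, 0.6, 0.8, 1.0])}
    ds, _ = simulate_membrane(layout, species, make_truth(layout, convs))
    a = assign_channels(species)
    imgs = [extract_ion_image(ds, c) for c in a.channels]
    q = quantify_wells(imgs, layout)
    est = [estimate_conversion(w) for w in q]
    est = [0.0 if e is None else e for e in est]
    assert all(b >= a_ for a_, b in zip(est, est[1:]))
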