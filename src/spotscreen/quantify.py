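"""Per-well readout: ion images, grid registration, ROI sums, calibration.

The screening readout is deliberately simple: extract a narrow m/z window
as a 2D ion image, find where the spotted grid actually landed on the
raster (translation-only registration against detected spot centroids),
then sum pixel intensities inside each well's region of interest.  The ROI
is the central square of the cell after trimming a margin (default 10% per
side); the trimmed-off border frame of the same cell provides the local
background estimate, which makes the correction robust to slow intensity
drift across the membrane.

Conversion is reported semiquantitatively as P / (P + r*S) from corrected
product and substrate sums.  The response ratio r (product vs substrate
intensity per concentration) defaults to 1; ionization efficiencies differ
between compounds, so cross-compound comparisons at r = 1 rank wells but do
not measure absolute conversion — supply a measured r when one is
available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .imaging_io import ImagingDataset
from .platemap import ChannelSpec, PlateLayout

__all__ = [
    "IonImage",
    "Registration",
    "ChannelQuant",
    "WellQuant",
    "CalibrationResult",
    "extract_ion_image",
    "register_grid",
    "quantify_wells",
    "fit_calibration",
    "estimate_conversion",
    "total_ion_image",
]


@dataclass
class IonImage:
    """2D intensity map of one m/z channel over the raster."""

    data: np.ndarray  # (ny, nx), non-negative
    channel: ChannelSpec
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise ValueError("ion image must be 2D")
        if self.data.size and float(self.data.min()) < 0:
            raise ValueError("ion image intensities must be non-negative")


@dataclass(frozen=True)
class Registration:
    """Translation of the spotted grid relative to its nominal layout position."""

    dx_mm: float
    dy_mm: float
    residual_mm: float  # RMS over matched spot centroids
    n_spots_used: int

    def __post_init__(self) -> None:
        if self.residual_mm < 0:
            raise ValueError("residual must be non-negative")

    @classmethod
    def identity(cls) -> "Registration":
        return cls(0.0, 0.0, 0.0, 0)


@dataclass
class ChannelQuant:
    """One well's readout on one channel."""

    raw: float
    background: float  # per-pixel background level (border-frame median)
    corrected: float  # max(raw - background * n_roi_pixels, 0)
    noise_floor: float  # border-frame MAD * n_roi_pixels
    n_roi_pixels: int
    role: str = "other"

    @property
    def is_empty(self) -> bool:
        return self.corrected <= 3.0 * self.noise_floor


@dataclass
class WellQuant:
    """Per-well quantification across channels, with a conversion estimate."""

    well: str
    channels: dict[str, ChannelQuant]
    conversion_estimate: float | None = None
    flags: set[str] = field(default_factory=set)

    def channel_by_role(self, role: str) -> ChannelQuant:
        matches = [c for c in self.channels.values() if c.role == role]
        if len(matches) != 1:
            raise KeyError(f"well {self.well}: expected exactly one {role!r} channel, "
                           f"found {len(matches)}")
        return matches[0]


@dataclass(frozen=True)
class CalibrationResult:
    """Linear calibration of summed spot intensity against concentration."""

    slope: float  # intensity per mM
    intercept: float
    r_squared: float
    lod_mM: float  # 3.3 * sigma / slope
    linear_range_mM: tuple[float, float]
    saturated_points: tuple[int, ...]  # indices into the input series

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")
        if self.lod_mM < 0:
            raise ValueError("LOD must be non-negative")


def _polarity_sign(polarity: str) -> int:
    return {"positive": 1, "negative": -1}.get(polarity, 0)


def extract_ion_image(ds: ImagingDataset, channel: ChannelSpec) -> IonImage:
    """Sum centroid intensity inside the channel's m/z window, per pixel.

    The window is half-open, ``[target - w/2, target + w/2)``.  A drift
    dimension, if present, is summed over all bins (see
    :mod:`spotscreen.mobility` for gated extraction).
    """
    if channel.polarity != 0 and _polarity_sign(ds.polarity) != channel.polarity:
        raise ValueError(f"channel polarity {channel.polarity:+d} does not match "
                         f"dataset polarity {ds.polarity!r}")
    lo = channel.target_mz - channel.window / 2.0
    hi = channel.target_mz + channel.window / 2.0
    img = np.zeros((ds.ny, ds.nx), dtype=np.float64)
    for y in range(ds.ny):
        for x in range(ds.nx):
            for mz, inten in ds.frames[ds.pixel_index(x, y)]:
                if mz.size == 0:
                    continue
                i0, i1 = np.searchsorted(mz, (lo, hi))
                if i1 > i0:
                    img[y, x] += float(inten[i0:i1].sum())
    return IonImage(data=img, channel=channel, pixel_size_um=ds.pixel_size_um)


def total_ion_image(ds: ImagingDataset) -> IonImage:
    """Total ion current per pixel, for spot detection and registration."""
    img = np.zeros((ds.ny, ds.nx), dtype=np.float64)
    for y in range(ds.ny):
        for x in range(ds.nx):
            for _, inten in ds.frames[ds.pixel_index(x, y)]:
                if inten.size:
                    img[y, x] += float(inten.sum())
    tic_channel = ChannelSpec(label="TIC", target_mz=1.0, window=1e9, polarity=0)
    return IonImage(data=img, channel=tic_channel, pixel_size_um=ds.pixel_size_um)


def _detect_spot_centroids(image: IonImage) -> np.ndarray:
    """Intensity-weighted centroids (mm, (x, y)) of connected bright regions."""
    data = image.data
    positive = data[data > 0]
    if positive.size == 0:
        return np.empty((0, 2))
    try:
        from skimage.filters import threshold_otsu
        thr = threshold_otsu(data) if positive.size > 1 else 0.0
    except ValueError:  # constant image
        thr = 0.0
    mask = data > thr
    if not mask.any():
        return np.empty((0, 2))
    labels, n = ndimage.label(mask)
    coms = ndimage.center_of_mass(data, labels, range(1, n + 1))
    px = image.pixel_size_um / 1000.0
    return np.array([[(c[1] + 0.5) * px, (c[0] + 0.5) * px] for c in coms])


def register_grid(tic: IonImage, layout: PlateLayout, max_shift_mm: float = 2.5) -> Registration:
    """Recover the grid translation from detected spot centroids.

    Bright connected regions of the (typically TIC) image are reduced to
    intensity-weighted centroids; candidate translations are generated from
    centroid/well-center pairs within ``max_shift_mm``, scored by how many
    centroids land near a well center under that shift, and the winner is
    refined by least squares (the optimal translation is the mean residual
    vector of the matched pairs).  Raises when no spots are detected.
    """
    spots = _detect_spot_centroids(tic)
    if spots.shape[0] == 0:
        raise ValueError("no spots detected above threshold; supply a manual offset "
                         "or check the image/channel")
    centers = np.array([layout.well_center(w) for w in layout.well_labels()])
    tree = cKDTree(centers)
    match_radius = layout.cell_size / 3.0

    # candidate shifts from a handful of detected spots against every well
    probes = spots[:: max(1, len(spots) // 8)]
    candidates = [(0.0, 0.0)]
    for s in probes:
        for w in centers:
            d = (float(s[0] - w[0]), float(s[1] - w[1]))
            if abs(d[0]) <= max_shift_mm and abs(d[1]) <= max_shift_mm:
                candidates.append(d)

    def score(shift: tuple[float, float]) -> tuple[int, float]:
        dist, _ = tree.query(spots - np.asarray(shift))
        inliers = dist < match_radius
        n = int(inliers.sum())
        return n, float(dist[inliers].mean()) if n else np.inf

    best = max(candidates, key=lambda c: (score(c)[0], -score(c)[1]))
    shift = np.asarray(best, dtype=float)
    inlier_idx = np.empty(0, dtype=int)
    for _ in range(3):  # ICP refinement: re-match, re-estimate
        dist, idx = tree.query(spots - shift)
        keep = dist < match_radius
        if not keep.any():
            break
        inlier_idx = idx[keep]
        shift = (spots[keep] - centers[inlier_idx]).mean(axis=0)
    shift = np.clip(shift, -max_shift_mm, max_shift_mm)
    dist, idx = tree.query(spots - shift)
    keep = dist < match_radius
    if not keep.any():
        raise ValueError("registration failed: no spot matched a well center; "
                         "supply a manual offset")
    residual = float(np.sqrt((dist[keep] ** 2).mean()))
    return Registration(dx_mm=float(shift[0]), dy_mm=float(shift[1]),
                        residual_mm=residual, n_spots_used=int(keep.sum()))


def _cell_masks(image_shape: tuple[int, int], pixel_size_um: float,
                layout: PlateLayout, registration: Registration, well: str,
                margin: float) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (ROI, border-frame) pixel masks of one well's cell."""
    ny, nx = image_shape
    px = pixel_size_um / 1000.0
    xs = (np.arange(nx) + 0.5) * px - registration.dx_mm
    ys = (np.arange(ny) + 0.5) * px - registration.dy_mm
    x0, y0, x1, y1 = layout.cell_bounds(well)
    in_cell = ((xs >= x0) & (xs < x1))[None, :] & ((ys >= y0) & (ys < y1))[:, None]
    m = margin * layout.cell_size
    in_roi = (((xs >= x0 + m) & (xs < x1 - m))[None, :]
              & ((ys >= y0 + m) & (ys < y1 - m))[:, None])
    return in_roi, in_cell & ~in_roi


def quantify_wells(images: list[IonImage], layout: PlateLayout,
                   registration: Registration | None = None,
                   margin: float = 0.1) -> list[WellQuant]:
    """Sum each channel over every well's ROI with local background correction.

    ``margin`` is the fraction of the cell size trimmed from each side; the
    trimmed border frame supplies the per-cell background (median) and noise
    floor (MAD x ROI size).  A well is flagged ``empty`` when every
    channel's corrected sum is within 3 noise floors of zero.
    """
    if not images:
        raise ValueError("no ion images supplied")
    shapes = {im.data.shape for im in images}
    if len(shapes) != 1:
        raise ValueError(f"ion images have mismatched dimensions: {shapes}")
    if not (0.0 <= margin < 0.5):
        raise ValueError("margin must lie in [0, 0.5)")
    registration = registration or Registration.identity()
    if registration.residual_mm > layout.cell_size / 2.0:
        raise ValueError(f"registration residual {registration.residual_mm:.2f} mm exceeds "
                         f"half the cell size; grid layout mismatch")

    shape = images[0].data.shape
    px_um = images[0].pixel_size_um
    out: list[WellQuant] = []
    for well in layout.well_labels():
        roi, border = _cell_masks(shape, px_um, layout, registration, well, margin)
        n_roi = int(roi.sum())
        channels: dict[str, ChannelQuant] = {}
        for im in images:
            raw = float(im.data[roi].sum())
            border_vals = im.data[border]
            bg = float(np.median(border_vals)) if border_vals.size else 0.0
            mad = float(np.median(np.abs(border_vals - bg))) if border_vals.size else 0.0
            corrected = max(raw - bg * n_roi, 0.0)
            channels[im.channel.label] = ChannelQuant(
                raw=raw, background=bg, corrected=corrected,
                noise_floor=mad * n_roi, n_roi_pixels=n_roi,
                role=im.channel.species_role)
        q = WellQuant(well=well, channels=channels)
        if all(c.is_empty for c in channels.values()):
            q.flags.add("empty")
        out.append(q)
    return out


def fit_calibration(concs_mM: np.ndarray | list[float],
                    sums: np.ndarray | list[float],
                    saturation_cut: float = 0.2) -> CalibrationResult:
    """Ordinary least squares of summed spot intensity on concentration.

    Saturated points — those falling below the linear fit line by more than
    ``saturation_cut`` (20%) of the fitted value — are excluded and refit.
    The linear reference is built from the low-concentration end upward:
    the three lowest concentrations seed the fit, and higher points are
    admitted in ascending order while they stay within the cut (a single
    heavily saturated point would otherwise dominate an all-point fit and
    misclassify the linear points instead).  R^2 is the squared Pearson
    correlation of the retained points; the limit of detection is
    3.3 * sigma / slope with sigma the residual SD of the retained fit
    (ICH-style).
    """
    x = np.asarray(concs_mM, dtype=float)
    y = np.asarray(sums, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("concentration and intensity arrays must be 1D and equal length")
    if x.size < 3:
        raise ValueError("calibration requires at least 3 points")

    order = np.argsort(x, kind="stable")
    included = list(order[:3])
    saturated_idx: list[int] = []
    for i in order[3:]:
        slope_c, icept_c = np.polyfit(x[included], y[included], 1)
        yhat = slope_c * x[i] + icept_c
        if yhat > 0 and (y[i] - yhat) / yhat < -saturation_cut:
            saturated_idx.append(int(i))
        else:
            included.append(int(i))
    saturated = np.zeros(x.size, dtype=bool)
    saturated[saturated_idx] = True
    retained = ~saturated
    if retained.sum() < 3:
        raise ValueError(f"only {int(retained.sum())} unsaturated points; "
                         "calibration requires at least 3")

    xr, yr = x[retained], y[retained]
    slope, intercept = np.polyfit(xr, yr, 1)
    resid = yr - (slope * xr + intercept)
    if np.allclose(yr, yr[0]):
        r2 = 0.0
    else:
        r = np.corrcoef(xr, yr)[0, 1]
        r2 = min(float(r * r), 1.0)
    sigma = float(np.sqrt((resid**2).sum() / max(len(xr) - 2, 1)))
    lod = 3.3 * sigma / slope if slope > 0 else float("inf")
    return CalibrationResult(
        slope=float(slope), intercept=float(intercept), r_squared=r2,
        lod_mM=float(max(lod, 0.0)),
        linear_range_mM=(float(xr.min()), float(xr.max())),
        saturated_points=tuple(int(i) for i in np.flatnonzero(saturated)),
    )


def estimate_conversion(q: WellQuant, response_ratio: float = 1.0,
                        product_label: str | None = None,
                        substrate_label: str | None = None) -> float | None:
    """Semiquantitative conversion P / (P + r*S) from corrected channel sums.

    ``response_ratio`` r is the product-to-substrate response-factor ratio;
    the default r = 1 assumes equal ionization efficiency and should be read
    as a ranking score, not an absolute conversion.  Returns None (and flags
    the well ``empty``) when both channels are at the noise floor.  The
    estimate is stored on the WellQuant.
    """
    if response_ratio <= 0:
        raise ValueError("response ratio must be positive")
    prod = q.channels[product_label] if product_label else q.channel_by_role("product")
    sub = q.channels[substrate_label] if substrate_label else q.channel_by_role("substrate")
    if prod.is_empty and sub.is_empty:
        q.flags.add("empty")
        q.conversion_estimate = None
        return None
    p, s = prod.corrected, sub.corrected
    if p + response_ratio * s == 0:
        q.flags.add("empty")
        q.conversion_estimate = None
        return None
    conv = p / (p + response_ratio * s)
    q.conversion_estimate = float(conv)
    return q.conversion_estimate
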