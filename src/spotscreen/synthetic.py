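"""Synthetic raster-imaging datasets of spotted reaction membranes.

The generator emulates the statistical structure the analysis relies on,
with a ground-truth manifest for every run:

* square grid cells, one reaction spot per cell, deposited as a compact
  isotropic Gaussian (default 2 mm FWHM) centred in the cell and truncated
  at the cell edge;
* per-compound linear-then-saturating response, ``I = rf * c / (1 + c/K)``
  with the saturation level ``K`` defaulting to 1 mM, so the response is
  linear through the low-micromolar screening range and rolls off above a
  millimolar;
* full natural-abundance isotopologue envelopes for every species, so the
  M+2 interference that plagues +2 Da biotransformations is present in the
  data exactly as the chemistry module predicts it;
* optional drift-time dimension: each species' intensity is spread over
  drift bins as a Gaussian at its species-specific drift centre;
* a flat chemical baseline at every species m/z inside each cell, and
  signal-dependent Gaussian noise (SD = noise_scale * sqrt(signal +
  baseline), a Poisson surrogate), clipped at zero.

Identical seeds give bit-identical datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chem import IsotopeEnvelope, isotope_envelope
from .imaging_io import ImagingDataset, Spectrum
from .platemap import PlateLayout, SpeciesEntry, SpeciesTable, build_layout

__all__ = [
    "ResponseModel",
    "InstrumentParams",
    "WellTruth",
    "GroundTruthManifest",
    "simulate_membrane",
    "simulate_calibration_series",
    "saturating_response",
    "noise_scale_for_roi_snr",
    "DEFAULT_CALIBRATION_MM",
]

#: default calibration series, mM (spans the 5-100 uM linear range)
DEFAULT_CALIBRATION_MM = (0.005, 0.010, 0.025, 0.050, 0.075, 0.100)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class ResponseModel:
    """Per-compound intensity response: linear at low concentration, saturating above K.

    ``response_factor`` is the peak-pixel intensity per mM in the linear
    limit; ``saturation_level`` (mM) is the Langmuir-type half-compression
    constant, defaulting to 1 mM.
    """

    response_factor: float = 2.0e4  # intensity per mM at the spot peak
    saturation_level: float = 1.0  # mM
    baseline: float = 20.0  # flat chemical background intensity per centroid
    noise_scale: float = 0.0  # dimensionless; SD = noise_scale*sqrt(I)

    def __post_init__(self) -> None:
        if self.response_factor <= 0:
            raise ValueError("response_factor must be positive")
        if self.saturation_level <= 0:
            raise ValueError("saturation_level must be positive")


def saturating_response(conc_mm: float | np.ndarray, model: ResponseModel) -> float | np.ndarray:
    """Langmuir-type response I = rf * c / (1 + c / K)."""
    c = np.asarray(conc_mm, dtype=float)
    out = model.response_factor * c / (1.0 + c / model.saturation_level)
    return float(out) if np.isscalar(conc_mm) else out


@dataclass(frozen=True)
class InstrumentParams:
    """Raster and mobility parameters of the simulated instrument.

    The raster covers the membrane with square pixels (default 500 um); if
    the cell size is not an integer multiple of the pixel size, the last
    partial pixel row/column of the membrane is truncated.  Stage speed does
    not change the data, only the throughput estimate.
    """

    pixel_size_um: float = 500.0
    stage_speed_um_s: float = 2000.0
    drift_bins: int = 0  # 0 = no mobility dimension
    drift_resolution_ms: float = 1.0  # bin width
    drift_sigma_ms: float = 0.5  # per-species drift peak SD
    mz_jitter_sd: float = 0.01  # Da, centroid position scatter
    spot_fwhm_mm: float = 2.0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.spot_fwhm_mm <= 0:
            raise ValueError("pixel size and spot FWHM must be positive")
        if self.drift_bins < 0:
            raise ValueError("drift_bins must be >= 0")

    def drift_centers(self) -> np.ndarray | None:
        if self.drift_bins <= 0:
            return None
        return (np.arange(self.drift_bins) + 0.5) * self.drift_resolution_ms


@dataclass(frozen=True)
class WellTruth:
    """True per-well reaction state: conversion = product / (substrate + product)."""

    substrate_mM: float
    product_mM: float
    other_mM: float = 0.0

    @property
    def total_mM(self) -> float:
        return self.substrate_mM + self.product_mM

    @property
    def conversion(self) -> float | None:
        tot = self.total_mM
        return None if tot == 0 else self.product_mM / tot

    def concentration(self, role: str) -> float:
        return {"substrate": self.substrate_mM, "product": self.product_mM,
                "other": self.other_mM}[role]


@dataclass
class GroundTruthManifest:
    """Everything needed to reproduce and score a simulated membrane."""

    wells: dict[str, WellTruth]
    responses: dict[str, ResponseModel]  # keyed by species role or formula
    instrument: InstrumentParams
    seed: int
    schema_version: int = 1

    def response_for(self, entry: SpeciesEntry) -> ResponseModel:
        key = entry.composition.hill_formula()
        if key in self.responses:
            return self.responses[key]
        return self.responses[entry.role]

    def to_json(self, path: str | Path) -> None:
        d = {
            "schema_version": self.schema_version,
            "seed": self.seed,
            "instrument": vars(self.instrument) | {},
            "responses": {k: vars(v) | {} for k, v in self.responses.items()},
            "wells": {w: {"substrate_mM": t.substrate_mM, "product_mM": t.product_mM,
                          "other_mM": t.other_mM, "conversion": t.conversion}
                      for w, t in self.wells.items()},
        }
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthManifest":
        d = json.loads(Path(path).read_text())
        return cls(
            wells={w: WellTruth(t["substrate_mM"], t["product_mM"], t.get("other_mM", 0.0))
                   for w, t in d["wells"].items()},
            responses={k: ResponseModel(**v) for k, v in d["responses"].items()},
            instrument=InstrumentParams(**d["instrument"]),
            seed=d["seed"],
            schema_version=d.get("schema_version", 1),
        )

    @classmethod
    def from_conversions(cls, conversions: dict[str, float], total_mM: float = 0.1,
                         responses: dict[str, ResponseModel] | None = None,
                         instrument: InstrumentParams | None = None,
                         seed: int = 0) -> "GroundTruthManifest":
        """Build a manifest from per-well conversion fractions at a fixed total
        substrate+product concentration (default 0.1 mM, inside the linear range)."""
        wells = {}
        for w, conv in conversions.items():
            if not (0.0 <= conv <= 1.0):
                raise ValueError(f"conversion for well {w} outside [0, 1]: {conv}")
            wells[w] = WellTruth(substrate_mM=total_mM * (1.0 - conv),
                                 product_mM=total_mM * conv)
        return cls(
            wells=wells,
            responses=responses or {"substrate": ResponseModel(), "product": ResponseModel(),
                                    "other": ResponseModel()},
            instrument=instrument or InstrumentParams(),
            seed=seed,
        )


def _raster_shape(layout: PlateLayout, instrument: InstrumentParams) -> tuple[int, int]:
    """Raster extent covering the membrane from the scan origin (0, 0) to the
    far edge of the (possibly translated) grid; the last partial pixel
    row/column is truncated."""
    px_mm = instrument.pixel_size_um / 1000.0
    x_extent = layout.origin[0] + layout.width_mm
    y_extent = layout.origin[1] + layout.height_mm
    return int(np.floor(x_extent / px_mm + 1e-9)), int(np.floor(y_extent / px_mm + 1e-9))


def _drift_weights(center_ms: float | None, instrument: InstrumentParams) -> np.ndarray:
    """Normalized per-bin weights of one species' drift peak (all-ones if no mobility)."""
    centers = instrument.drift_centers()
    if centers is None:
        return np.ones(1)
    if center_ms is None:
        return np.full(len(centers), 1.0 / len(centers))
    w = np.exp(-0.5 * ((centers - center_ms) / instrument.drift_sigma_ms) ** 2)
    s = w.sum()
    if s == 0:
        return np.full(len(centers), 1.0 / len(centers))
    return w / s


def simulate_membrane(layout: PlateLayout, species: SpeciesTable,
                      truth: GroundTruthManifest,
                      instrument: InstrumentParams | None = None,
                      seed: int | None = None,
                      ) -> tuple[ImagingDataset, GroundTruthManifest]:
    """Simulate the raster scan of a spotted reaction membrane.

    Every pixel whose centre falls inside a grid cell receives, for each
    species of that cell's well, centroids at the species' isotopologue
    masses with intensity

        spot_profile(pixel) * rf * c / (1 + c/K) * envelope_abundance + baseline

    plus m/z jitter and signal-dependent noise.  Pixels outside any cell are
    empty.  Wells present in the layout but absent from ``truth`` are
    rejected.  Returns the dataset together with the manifest actually used
    (seed updated if overridden).
    """
    instrument = instrument or truth.instrument
    if seed is None:
        seed = truth.seed
    rng = np.random.default_rng(seed)

    missing = [w for w in species.wells() if w not in truth.wells]
    if missing:
        raise ValueError(f"wells missing from ground truth: {sorted(missing)}")

    nx, ny = _raster_shape(layout, instrument)
    px_mm = instrument.pixel_size_um / 1000.0
    sigma_mm = instrument.spot_fwhm_mm * FWHM_TO_SIGMA
    n_bins = max(instrument.drift_bins, 1)
    centers = instrument.drift_centers()

    # precompute per-well species data
    well_species: dict[str, list[tuple[SpeciesEntry, IsotopeEnvelope, ResponseModel, float, np.ndarray]]] = {}
    for w in species.wells():
        rows = []
        t = truth.wells[w]
        for e in species.for_well(w):
            env = isotope_envelope(e.composition, e.adduct)
            model = truth.response_for(e)
            amp = saturating_response(t.concentration(e.role), model)
            rows.append((e, env, model, amp, _drift_weights(e.drift_ms, instrument)))
        well_species[w] = rows

    # map each pixel row/col to a well label (or None)
    frames: list[list[Spectrum]] = []
    for y in range(ny):
        for x in range(nx):
            cx = (x + 0.5) * px_mm
            cy = (y + 0.5) * px_mm
            col = int(np.floor((cx - layout.origin[0]) / layout.cell_size))
            row = int(np.floor((cy - layout.origin[1]) / layout.cell_size))
            well = None
            if 0 <= row < layout.n_rows and 0 <= col < layout.n_cols:
                well = layout.label(row, col)
            rows = well_species.get(well, []) if well else []
            if not rows:
                frames.append([(np.empty(0), np.empty(0, dtype=np.float32))
                               for _ in range(n_bins)])
                continue
            wx, wy = layout.well_center(well)
            g = float(np.exp(-0.5 * (((cx - wx) ** 2 + (cy - wy) ** 2) / sigma_mm**2)))
            bin_mz: list[list[float]] = [[] for _ in range(n_bins)]
            bin_int: list[list[float]] = [[] for _ in range(n_bins)]
            for e, env, model, amp, dw in rows:
                peak_int = g * amp * env.abundances
                jitter = rng.normal(0.0, instrument.mz_jitter_sd, size=len(env))
                mz = env.masses + jitter
                for b in range(n_bins):
                    signal = peak_int * dw[b] + model.baseline / n_bins
                    if model.noise_scale > 0:
                        signal = signal + rng.normal(0.0, model.noise_scale * np.sqrt(signal))
                    signal = np.clip(signal, 0.0, None)
                    bin_mz[b].extend(mz.tolist())
                    bin_int[b].extend(signal.tolist())
            pixel_frames: list[Spectrum] = []
            for b in range(n_bins):
                m = np.asarray(bin_mz[b], dtype=np.float64)
                i = np.asarray(bin_int[b], dtype=np.float32)
                order = np.argsort(m, kind="stable")
                pixel_frames.append((m[order], i[order]))
            frames.append(pixel_frames)

    ds = ImagingDataset(
        nx=nx, ny=ny, pixel_size_um=instrument.pixel_size_um, frames=frames,
        drift_centers=centers,
        polarity="positive" if all(e.adduct.polarity >= 0 for e in species) else "negative",
        metadata={"generator": "spotscreen.synthetic.simulate_membrane", "seed": int(seed)},
    )
    manifest = GroundTruthManifest(wells=truth.wells, responses=truth.responses,
                                   instrument=instrument, seed=int(seed))
    return ds, manifest


def simulate_calibration_series(concentrations_mM: list[float] | tuple[float, ...] = DEFAULT_CALIBRATION_MM,
                                response: ResponseModel | None = None,
                                instrument: InstrumentParams | None = None,
                                seed: int = 0,
                                species: SpeciesEntry | None = None,
                                ) -> tuple[ImagingDataset, GroundTruthManifest, PlateLayout, SpeciesTable]:
    """One spot per concentration on a 1 x N membrane strip.

    The default series (5, 10, 25, 50, 75, 100 uM) spans the screening
    method's linear range; extending it toward the millimolar saturation
    level produces visibly sublinear top points.
    """
    concs = list(concentrations_mM)
    if not concs:
        raise ValueError("concentration list must not be empty")
    if any(c <= 0 for c in concs):
        raise ValueError("concentrations must be positive")
    if len(set(concs)) != len(concs):
        raise ValueError("concentrations must be distinct")

    from .chem import AdductSpec, parse_formula
    response = response or ResponseModel()
    instrument = instrument or InstrumentParams()
    layout = build_layout(1, len(concs))
    if species is None:
        # galactose-1-phosphate-like hexose phosphate, deprotonated
        species = SpeciesEntry(well="A1", role="other",
                               composition=parse_formula("C6H13O9P"),
                               adduct=AdductSpec.deprotonated())
    entries = []
    wells = {}
    for i, c in enumerate(concs):
        label = layout.label(0, i)
        entries.append(SpeciesEntry(well=label, role=species.role,
                                    composition=species.composition,
                                    adduct=species.adduct, drift_ms=species.drift_ms))
        wells[label] = WellTruth(substrate_mM=0.0, product_mM=0.0, other_mM=float(c))
    table = SpeciesTable(entries, layout)
    manifest = GroundTruthManifest(
        wells=wells,
        responses={species.role: response,
                   species.composition.hill_formula(): response},
        instrument=instrument, seed=seed)
    ds, manifest = simulate_membrane(layout, table, manifest, instrument, seed)
    return ds, manifest, layout, table


def expected_spot_total(layout: PlateLayout, instrument: InstrumentParams,
                        peak_intensity: float) -> float:
    """Analytic noise-free total intensity of one spot over its cell.

    Integral of the truncated Gaussian spot profile times the peak
    intensity, expressed as a sum over pixel area: 2*pi*sigma^2 / A_px for a
    spot well inside the cell.  Used to validate discretization error.
    """
    sigma_mm = instrument.spot_fwhm_mm * FWHM_TO_SIGMA
    px_mm = instrument.pixel_size_um / 1000.0
    half = layout.cell_size / 2.0
    from scipy.special import erf
    frac_1d = erf(half / (np.sqrt(2) * sigma_mm))  # mass inside the cell, per axis
    return peak_intensity * 2.0 * np.pi * sigma_mm**2 * frac_1d**2 / px_mm**2


def noise_scale_for_roi_snr(target_snr: float, roi_signal_sum: float,
                            roi_total_sum: float) -> float:
    """Noise scale giving a requested ROI signal-to-noise ratio.

    With per-centroid noise SD = ns*sqrt(I), the SD of a sum over independent
    centroids is ns*sqrt(sum I); the ROI SNR is therefore
    ``roi_signal_sum / (ns * sqrt(roi_total_sum))``.  Given the noise-free
    ROI signal sum and the total (signal+baseline) ROI sum, return ns.
    """
    if target_snr <= 0 or roi_signal_sum <= 0 or roi_total_sum <= 0:
        raise ValueError("SNR and ROI sums must be positive")
    return roi_signal_sum / (target_snr * np.sqrt(roi_total_sum))
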