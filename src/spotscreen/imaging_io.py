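"""imzML reading/writing and the in-memory imaging-dataset container.

A dataset is a rectangular raster of centroid spectra, optionally with a
drift-time (ion mobility) dimension.  Internally pixels are 0-based and
row-major; imzML coordinates are 1-based at the file boundary.

imzML has no standard ion-mobility axis.  The dialect used here stores one
spectrum per (pixel, drift bin) with the bin index carried in the third
(z) imzML coordinate (z = bin + 1), plus informational ``drift_bin`` /
``drift_time_ms`` userParams on each spectrum.  The z coordinate is
authoritative on read; files remain loadable in standard imzML viewers,
which display each drift plane as a z-slice.  Axis metadata that imzML
cannot carry (pixel size, drift-bin centers) is written to a small JSON
sidecar next to the file and restored on read when present.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks

__all__ = ["ImagingDataset", "write_imzml", "read_imzml", "retain_top_n"]

Spectrum = tuple[np.ndarray, np.ndarray]  # (m/z float64 ascending, intensity float32)


def _empty_spectrum() -> Spectrum:
    return (np.empty(0, dtype=np.float64), np.empty(0, dtype=np.float32))


@dataclass
class ImagingDataset:
    """Pixel-indexed centroid spectra with an optional drift-time dimension.

    ``frames[pixel][bin]`` holds the centroid arrays of one drift bin of one
    pixel (row-major pixel index ``y * nx + x``).  Datasets without a
    mobility dimension have exactly one frame per pixel and
    ``drift_centers is None``.
    """

    nx: int
    ny: int
    pixel_size_um: float
    frames: list[list[Spectrum]]
    drift_centers: np.ndarray | None = None  # ms, one per drift bin
    polarity: str = "positive"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.frames) != self.nx * self.ny:
            raise ValueError("frame list length must equal nx * ny")
        n_bins = self.n_drift_bins
        for i, pixel_frames in enumerate(self.frames):
            if len(pixel_frames) != n_bins:
                raise ValueError(f"pixel {i} has {len(pixel_frames)} frames, expected {n_bins}")
            for mz, inten in pixel_frames:
                if mz.shape != inten.shape:
                    raise ValueError(f"pixel {i}: m/z and intensity lengths differ")
                if mz.size and np.any(np.diff(mz) < 0):
                    raise ValueError(f"pixel {i}: m/z array not sorted")
                if inten.size and float(np.min(inten)) < 0:
                    raise ValueError(f"pixel {i}: negative intensity")

    @property
    def n_drift_bins(self) -> int:
        if self.drift_centers is not None:
            return len(self.drift_centers)
        return len(self.frames[0]) if self.frames else 1

    @property
    def has_drift(self) -> bool:
        return self.drift_centers is not None

    def pixel_index(self, x: int, y: int) -> int:
        if not (0 <= x < self.nx and 0 <= y < self.ny):
            raise IndexError(f"pixel ({x}, {y}) outside {self.nx}x{self.ny} raster")
        return y * self.nx + x

    def spectrum(self, x: int, y: int) -> Spectrum:
        """Pixel spectrum summed over the drift dimension (sorted by m/z)."""
        parts = self.frames[self.pixel_index(x, y)]
        if len(parts) == 1:
            return parts[0]
        mz = np.concatenate([p[0] for p in parts])
        inten = np.concatenate([p[1] for p in parts])
        order = np.argsort(mz, kind="stable")
        return mz[order], inten[order]

    def pixel_center_mm(self, x: int, y: int) -> tuple[float, float]:
        px = self.pixel_size_um / 1000.0
        return ((x + 0.5) * px, (y + 0.5) * px)


def retain_top_n(mz: np.ndarray, intensity: np.ndarray, n: int) -> Spectrum:
    """Keep the n most intense centroids, m/z order restored.

    Mirrors the top-N peak retention applied by instrument processing
    software.  Fewer than n peaks is the identity; ties at the cutoff keep
    the lower-m/z peak.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mz = np.asarray(mz, dtype=np.float64)
    intensity = np.asarray(intensity, dtype=np.float32)
    if mz.size <= n:
        return mz, intensity
    order = np.lexsort((mz, -intensity.astype(np.float64)))[:n]
    keep = np.sort(order)
    return mz[keep], intensity[keep]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def _add_spectrum(writer, mz: np.ndarray, inten: np.ndarray, coords, params) -> None:
    """addSpectrum that tolerates empty centroid lists.

    pyimzml's addSpectrum computes min/max/base-peak summaries and fails on
    zero-length arrays, so empty spectra are registered through the writer's
    encoding internals with zeroed summary statistics instead.
    """
    if mz.size:
        writer.addSpectrum(mz, inten, coords, userParams=params)
        return
    from pyimzml.ImzMLWriter import _Spectrum

    mz_offset, mz_len, mz_enc = writer._encode_and_write(
        mz, writer.mz_dtype, writer.mz_compression)
    int_offset, int_len, int_enc = writer._encode_and_write(
        inten, writer.intensity_dtype, writer.intensity_compression)
    writer.spectra.append(_Spectrum(coords, mz_len, mz_offset, mz_enc,
                                    int_len, int_offset, int_enc,
                                    0.0, 0.0, 0.0, 0.0, 0.0, params))


def write_imzml(ds: ImagingDataset, path: str | Path) -> Path:
    """Write a dataset as a processed-mode imzML/ibd pair (+ JSON sidecar).

    m/z is stored as 64-bit, intensity as 32-bit floats; the writer embeds
    the SHA-1 checksum of the binary file, which :func:`read_imzml`
    verifies.  Returns the path of the .imzML file.
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    path = Path(path)
    if path.suffix.lower() != ".imzml":
        path = path.with_suffix(".imzML")
    path.parent.mkdir(parents=True, exist_ok=True)

    with ImzMLWriter(str(path), polarity=ds.polarity, mode="processed") as writer:
        for y in range(ds.ny):
            for x in range(ds.nx):
                for b, (mz, inten) in enumerate(ds.frames[ds.pixel_index(x, y)]):
                    params = [{"name": "drift_bin", "value": str(b)}]
                    if ds.drift_centers is not None:
                        params.append({"name": "drift_time_ms",
                                       "value": repr(float(ds.drift_centers[b]))})
                    _add_spectrum(writer, np.asarray(mz, dtype=np.float64),
                                  np.asarray(inten, dtype=np.float32),
                                  (x + 1, y + 1, b + 1), params)

    sidecar = {
        "pixel_size_um": ds.pixel_size_um,
        "polarity": ds.polarity,
        "drift_centers_ms": None if ds.drift_centers is None else [float(v) for v in ds.drift_centers],
        "metadata": ds.metadata,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def _verify_checksum(parser, imzml_path: Path) -> None:
    try:
        stated = parser.metadata.file_description.param_by_accession["IMS:1000091"]
    except (AttributeError, KeyError):
        return  # no checksum recorded; nothing to verify
    stated = getattr(stated, "value", stated)
    ibd = imzml_path.with_suffix(".ibd")
    actual = hashlib.sha1(ibd.read_bytes()).hexdigest()
    if str(stated).lower() != actual.lower():
        raise IOError(f"ibd SHA-1 mismatch for {ibd}: stated {stated}, actual {actual}")


def _is_continuous(parser) -> bool:
    try:
        return "IMS:1000030" in parser.metadata.file_description.param_by_accession
    except AttributeError:  # pragma: no cover - defensive
        return False


def _centroid_profile(mz: np.ndarray, inten: np.ndarray) -> Spectrum:
    """Reduce a profile spectrum to centroids by local-maximum picking."""
    if mz.size < 3:
        keep = inten > 0
        return mz[keep], inten[keep].astype(np.float32)
    idx, _ = find_peaks(inten)
    return mz[idx], inten[idx].astype(np.float32)


def read_imzml(path: str | Path, pixel_size_um: float | None = None) -> ImagingDataset:
    """Read an imzML file into an :class:`ImagingDataset`.

    Works on both processed (centroid) and continuous (profile) files;
    profile spectra are converted to centroid lists by local-maximum
    picking.  Coordinates are mapped onto a 0-based row-major grid; pixels
    missing from the file are filled with empty spectra, one warning per
    gap.  The drift dimension is reconstructed from the z coordinate.
    Binary-length mismatches and checksum failures are rejected.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    parser = ImzMLParser(str(path))
    try:
        return _read_parsed(parser, path, pixel_size_um)
    finally:
        handle = getattr(parser, "m", None)
        if handle is not None:
            handle.close()


def _read_parsed(parser, path: Path, pixel_size_um: float | None) -> ImagingDataset:
    _verify_checksum(parser, path)
    continuous = _is_continuous(parser)

    coords = parser.coordinates
    if not coords:
        raise IOError(f"{path} contains no spectra")
    xs = [c[0] for c in coords]
    ys = [c[1] for c in coords]
    zs = [c[2] if len(c) > 2 else 1 for c in coords]
    nx, ny, nbins = max(xs), max(ys), max(zs)

    sidecar: dict = {}
    sc_path = _sidecar_path(path)
    if sc_path.exists():
        sidecar = json.loads(sc_path.read_text())

    if pixel_size_um is None:
        pixel_size_um = sidecar.get("pixel_size_um")
    if pixel_size_um is None:
        # imzML scan settings may carry it; fall back to a unit pixel
        pixel_size_um = float(parser.imzmldict.get("pixel size x", 1.0) or 1.0)

    frames: list[list[Spectrum]] = [[_empty_spectrum() for _ in range(nbins)]
                                    for _ in range(nx * ny)]
    seen = np.zeros((nx * ny, nbins), dtype=bool)
    for i, (cx, cy, *rest) in enumerate([(c[0], c[1]) + tuple(c[2:]) for c in coords]):
        cz = rest[0] if rest else 1
        try:
            mz, inten = parser.getspectrum(i)
        except Exception as exc:  # binary offset/length problems
            raise IOError(f"failed to decode spectrum index {i}: {exc}") from exc
        mz = np.asarray(mz, dtype=np.float64)
        inten = np.asarray(inten, dtype=np.float32)
        if mz.shape != inten.shape:
            raise IOError(f"spectrum index {i}: m/z / intensity length mismatch")
        if continuous:
            mz, inten = _centroid_profile(mz, inten)
        elif mz.size and np.any(np.diff(mz) < 0):
            order = np.argsort(mz, kind="stable")
            mz, inten = mz[order], inten[order]
        frames[(cy - 1) * nx + (cx - 1)][cz - 1] = (mz, inten)
        seen[(cy - 1) * nx + (cx - 1), cz - 1] = True

    for flat in np.flatnonzero(~seen.all(axis=1)):
        warnings.warn(f"pixel index {int(flat)} missing from {path.name}; filled with empty spectrum")

    drift_centers = None
    if nbins > 1:
        stated = sidecar.get("drift_centers_ms")
        drift_centers = (np.asarray(stated, dtype=float) if stated is not None
                         else np.arange(nbins, dtype=float))

    polarity = sidecar.get("polarity", "positive")
    return ImagingDataset(nx=nx, ny=ny, pixel_size_um=float(pixel_size_um),
                          frames=frames, drift_centers=drift_centers,
                          polarity=polarity, metadata=sidecar.get("metadata", {}))
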