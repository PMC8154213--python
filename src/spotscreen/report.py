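"""Heat-map rendering, hit calling, and throughput estimation.

The visual readout of a screen is one heat map per channel, optionally
overlaid into a single RGB image (substrate red, product green by
convention) so active wells stand out as bright pixels of the product
color.  Hit calling formalizes the same judgement: either a statistical
threshold against declared blank wells or a simple top-k ranking.
"""

from __future__ import annotations

import importlib.resources
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from .platemap import PlateLayout
from .quantify import IonImage, WellQuant

__all__ = [
    "render_heatmap",
    "call_hits",
    "estimate_throughput",
    "load_pal_conversion_table",
    "write_report",
]

_COLOR_PLANES = {"red": (0,), "green": (1,), "blue": (2,), "gray": (0, 1, 2)}


def render_heatmap(images: list[IonImage], layout: PlateLayout | None = None,
                   normalization: str = "per-channel",
                   path: str | Path | None = None,
                   upscale: int = 10,
                   draw_grid: bool = True) -> tuple[Image.Image, dict]:
    """Render up to three ion images as an RGB heat map.

    Each channel is min-max normalized to its own maximum (``per-channel``)
    or to the maximum across all channels (``global``) and written into the
    RGB plane(s) of its display color; a single gray channel renders as a
    grayscale ramp.  The image is upscaled by nearest-neighbour
    interpolation (default x10) and, when a layout is given, cell grid
    lines and row/column labels are drawn.  Returns the PIL image and a
    legend dict (channel -> color and scale maximum); deterministic
    byte-for-byte for fixed inputs.
    """
    if not 1 <= len(images) <= 3:
        raise ValueError("render_heatmap accepts 1-3 channels")
    colors = [im.channel.display_color for im in images]
    if len(set(colors)) != len(colors):
        raise ValueError(f"channel display colors must be distinct, got {colors}")
    if normalization not in ("per-channel", "global"):
        raise ValueError("normalization must be 'per-channel' or 'global'")

    shape = images[0].data.shape
    if any(im.data.shape != shape for im in images):
        raise ValueError("ion images have mismatched dimensions")
    global_max = max(float(im.data.max()) for im in images)
    rgb = np.zeros(shape + (3,), dtype=np.float64)
    legend: dict[str, dict] = {}
    for im in images:
        scale = float(im.data.max()) if normalization == "per-channel" else global_max
        norm = im.data / scale if scale > 0 else np.zeros(shape)
        for plane in _COLOR_PLANES[im.channel.display_color]:
            rgb[:, :, plane] = np.maximum(rgb[:, :, plane], norm)
        legend[im.channel.label] = {"color": im.channel.display_color,
                                    "scale_max": scale,
                                    "target_mz": im.channel.target_mz}

    img8 = (np.clip(rgb, 0, 1) * 255).round().astype(np.uint8)
    pil = Image.fromarray(img8, mode="RGB")
    if upscale > 1:
        pil = pil.resize((pil.width * upscale, pil.height * upscale), Image.NEAREST)

    if layout is not None and draw_grid:
        draw = ImageDraw.Draw(pil)
        px_mm = images[0].pixel_size_um / 1000.0
        scale = upscale / px_mm  # rendered pixels per mm
        for r in range(layout.n_rows + 1):
            y = round((layout.origin[1] + r * layout.cell_size) * scale)
            draw.line([(0, y), (pil.width, y)], fill=(80, 80, 80), width=1)
        for c in range(layout.n_cols + 1):
            x = round((layout.origin[0] + c * layout.cell_size) * scale)
            draw.line([(x, 0), (x, pil.height)], fill=(80, 80, 80), width=1)
        for well in layout.well_labels():
            x0, y0, _, _ = layout.cell_bounds(well)
            draw.text((round(x0 * scale) + 2, round(y0 * scale) + 1), well,
                      fill=(160, 160, 160))

    if path is not None:
        pil.save(Path(path), format="PNG")
    return pil, legend


def call_hits(quants: list[WellQuant], channel_label: str,
              mode: str = "threshold", param: float | int | None = None,
              blank_wells: list[str] | None = None,
              layout: PlateLayout | None = None) -> pd.DataFrame:
    """Rank wells by corrected channel sum and call hits.

    ``threshold`` mode keeps wells whose corrected sum exceeds
    mean(blanks) + 3 SD(blanks) (or ``param`` as an explicit threshold when
    given) and that carry no ``isotope_false_positive`` flag; blank wells
    are declared, not inferred — pass the labels from
    :meth:`SpeciesTable.blank_wells`.  ``top_k`` mode keeps the ``param``
    highest wells.  Ties break by well label in row-major order; rank 1 is
    the highest.  Returns a HitTable DataFrame (rank, well, channel,
    corrected, conversion, flags).
    """
    if mode not in ("threshold", "top_k"):
        raise ValueError("mode must be 'threshold' or 'top_k'")
    by_well = {q.well: q for q in quants}
    for q in quants:
        if channel_label not in q.channels:
            raise KeyError(f"well {q.well} lacks channel {channel_label!r}")

    def well_order(well: str) -> tuple:
        if layout is not None:
            return layout.well_index(well)
        i = 0
        while i < len(well) and well[i].isalpha():
            i += 1
        return (well[:i], int(well[i:]) if well[i:].isdigit() else 0)

    if mode == "threshold":
        if param is not None:
            cutoff = float(param)
        else:
            if not blank_wells:
                raise ValueError("threshold mode needs declared blank wells (or an "
                                 "explicit threshold); use top_k otherwise")
            blanks = [by_well[w].channels[channel_label].corrected
                      for w in blank_wells if w in by_well]
            if not blanks:
                raise ValueError("no declared blank well was quantified; use top_k")
            cutoff = float(np.mean(blanks) + 3.0 * np.std(blanks))
        selected = [q for q in quants
                    if q.channels[channel_label].corrected > cutoff
                    and "isotope_false_positive" not in q.flags]
    else:
        if param is None or int(param) < 1:
            raise ValueError("top_k mode requires param = k >= 1")
        selected = list(quants)

    ordered = sorted(selected,
                     key=lambda q: (-q.channels[channel_label].corrected,
                                    well_order(q.well)))
    if mode == "top_k":
        ordered = ordered[: int(param)]
    rows = [{"rank": i + 1, "well": q.well, "channel": channel_label,
             "corrected": q.channels[channel_label].corrected,
             "conversion": q.conversion_estimate,
             "flags": ";".join(sorted(q.flags))}
            for i, q in enumerate(ordered)]
    return pd.DataFrame(rows, columns=["rank", "well", "channel", "corrected",
                                       "conversion", "flags"])


def estimate_throughput(cell_size_mm: float = 5.0, pixel_size_um: float = 500.0,
                        stage_speed_um_s: float = 2000.0,
                        per_line_overhead_s: float = 0.0) -> float:
    """Seconds of raster time per sample cell.

    A cell is covered by ``ceil(cell/pixel)`` raster lines, each taking
    ``cell_width / stage_speed`` seconds of scanning plus a per-line
    overhead (fly-back, inter-line moves).  The overhead is instrument- and
    geometry-specific, so it is an explicit parameter with no hidden
    default.
    """
    if min(cell_size_mm, pixel_size_um, stage_speed_um_s) <= 0 or per_line_overhead_s < 0:
        raise ValueError("parameters must be positive (overhead non-negative)")
    cell_um = cell_size_mm * 1000.0
    lines = math.ceil(cell_um / pixel_size_um)
    return lines * (cell_um / stage_speed_um_s + per_line_overhead_s)


def load_pal_conversion_table() -> pd.DataFrame:
    """Published HPLC conversion percentages for two ammonia-lyase enzymes.

    A packaged reference table of per-substrate conversions (%) measured by
    reverse-phase HPLC for a panel of methoxy/halo-substituted cinnamic
    acids — useful for demonstrating :func:`call_hits` in threshold mode on
    real printed numbers.  Values reported as "<1" load as NaN with the
    ``*_censored`` flag set; the verbatim strings are kept alongside.
    """
    with importlib.resources.files("spotscreen.data").joinpath(
            "pal_hplc_conversions.csv").open() as fh:
        df = pd.read_csv(fh, dtype=str)
    for enzyme in ("pbpal", "al11"):
        raw = df[f"{enzyme}_conversion_pct"]
        df[f"{enzyme}_censored"] = raw.str.strip() == "<1"
        df[f"{enzyme}_pct"] = pd.to_numeric(raw.where(~df[f"{enzyme}_censored"]),
                                            errors="coerce")
    return df


def write_report(outdir: str | Path, hit_table: pd.DataFrame,
                 quants: list[WellQuant], legend: dict | None = None,
                 config: dict | None = None) -> Path:
    """Bundle tables and run configuration into a report directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hit_table.to_csv(outdir / "hits.csv", index=False)
    rows = []
    for q in quants:
        for label, c in q.channels.items():
            rows.append({"well": q.well, "channel": label, "raw": c.raw,
                         "background": c.background, "corrected": c.corrected,
                         "conversion": q.conversion_estimate,
                         "flags": ";".join(sorted(q.flags))})
    pd.DataFrame(rows).to_csv(outdir / "wells.csv", index=False)
    meta = {"legend": legend or {}, "config": config or {}}
    (outdir / "report.json").write_text(json.dumps(meta, indent=2, default=str))
    return outdir
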