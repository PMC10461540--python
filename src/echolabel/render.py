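"""Static spectrogram rendering with annotation overlays.

Mirrors the layered-panel structure of the interactive display: the dB
raster is the back layer, bounding-box annotations (border-coloured by class
category) sit on top, and selection guides draw last.  Layers are composited
independently, so adding or removing annotations never changes the base
raster pixels.
"""

from __future__ import annotations

import io
import logging

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Rectangle

from .annotations import Annotation
from .project_config import ClassEntry, classify_label
from .spectrogram import DbSpectrogram
from .tf_filter import BoundingBox

logger = logging.getLogger("echolabel")

__all__ = ["RenderOptions", "render_spectrogram", "render_to_file"]

#: built-in palette family; perceptually-uniform default
PALETTES = ("viridis", "magma", "inferno", "plasma", "cividis", "gray")

from dataclasses import dataclass


@dataclass(frozen=True)
class RenderOptions:
    palette: str = "viridis"
    show_guides: bool = True
    image_width: int = 1200
    image_height: int = 400
    show_bto_codes: bool = False
    dpi: int = 100

    def __post_init__(self) -> None:
        if self.image_width <= 0 or self.image_height <= 0:
            raise ValueError("image dimensions must be positive")


def _box_extent_clipped(box: BoundingBox, dbspec: DbSpectrogram) -> tuple | None:
    t0 = max(box.t_start, dbspec.time_extent[0])
    t1 = min(box.t_end, dbspec.time_extent[1])
    f0 = max(box.f_start, dbspec.freq_extent[0])
    f1 = min(box.f_end, dbspec.freq_extent[1])
    if t0 >= t1 or f0 >= f1:
        return None
    return t0, t1, f0, f1


def render_spectrogram(
    dbspec: DbSpectrogram,
    annotations: list[Annotation] | None = None,
    classes: list[ClassEntry] | None = None,
    selection: BoundingBox | None = None,
    options: RenderOptions | None = None,
) -> bytes:
    """Render a dB spectrogram with overlays to PNG bytes.

    Back to front: palette-mapped raster (0 dB at the palette top), one
    rectangle per annotation with its class text at the upper edge, then the
    selection box with optional time/frequency guide lines.  The time axis is
    seconds, the frequency axis kHz, frequency increasing upward.  Boxes that
    stick out of the spectrogram extent are clipped with a logged warning.
    """
    if options is None:
        options = RenderOptions()
    annotations = annotations or []
    classes = classes or []

    fig = plt.figure(
        figsize=(options.image_width / options.dpi, options.image_height / options.dpi),
        dpi=options.dpi,
    )
    ax = fig.add_axes([0.08, 0.13, 0.9, 0.82])
    extent = (*dbspec.time_extent, *dbspec.freq_extent)
    ax.imshow(
        dbspec.values,
        origin="lower",
        aspect="auto",
        extent=extent,
        cmap=options.palette,
        vmin=float(dbspec.values.min()),
        vmax=0.0,
        interpolation="nearest",
    )
    ax.set_xlabel("Time (s)")
    ax.set_ylabel("Frequency (kHz)")

    for ann in annotations:
        clipped = _box_extent_clipped(ann.box, dbspec)
        if clipped is None:
            logger.warning(
                "annotation %r lies outside the spectrogram extent; not drawn", ann.class_label
            )
            continue
        if clipped != (ann.box.t_start, ann.box.t_end, ann.box.f_start, ann.box.f_end):
            logger.warning("annotation %r clipped to the spectrogram extent", ann.class_label)
        t0, t1, f0, f1 = clipped
        entry = classify_label(ann.class_label, classes)
        ax.add_patch(
            Rectangle(
                (t0, f0), t1 - t0, f1 - f0,
                fill=False, edgecolor=entry.colour, linewidth=1.5,
            )
        )
        text = entry.display_code if options.show_bto_codes else ann.class_label
        ax.text(
            t0, f1, text,
            color=entry.colour, fontsize=8, va="bottom", ha="left", clip_on=True,
        )

    if selection is not None:
        clipped = _box_extent_clipped(selection, dbspec)
        if clipped is not None:
            t0, t1, f0, f1 = clipped
            ax.add_patch(
                Rectangle(
                    (t0, f0), t1 - t0, f1 - f0,
                    fill=False, edgecolor="white", linewidth=1.2, linestyle="--",
                )
            )
            if options.show_guides:
                for t in (t0, t1):
                    ax.axvline(t, color="white", linewidth=0.6, alpha=0.6)
                for f in (f0, f1):
                    ax.axhline(f, color="white", linewidth=0.6, alpha=0.6)

    ax.set_xlim(dbspec.time_extent)
    ax.set_ylim(dbspec.freq_extent)

    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=options.dpi)
    plt.close(fig)
    return buf.getvalue()


def render_to_file(path, *args, **kwargs) -> None:
    data = render_spectrogram(*args, **kwargs)
    with open(path, "wb") as fh:
        fh.write(data)
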