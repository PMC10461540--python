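"""Selection-filtered audio: complex-spectrogram masking and ISTFT reconstruction.

When an annotator draws a time-frequency box around a vocalisation, the audio
they audition is rebuilt from the complex spectrogram with everything outside
the box removed: the selected cells are kept bit-identical, outside cells are
set to zero (or near-zero), and the waveform is reconstructed by inverse STFT.
Collapsing outside magnitudes to exactly zero can sound unnatural, so an
alternative attenuate mode divides outside magnitudes by a factor (100 by
default) instead.  A band filter is the same mask spanning the full clip
duration, and a row-wise noise reducer subtracts each frequency row's median
magnitude — an effective way to suppress stationary backgrounds such as wind
turbine noise while leaving sparse vocalisations mostly intact.

Reconstruction is weighted overlap-add: each frame is inverted, multiplied by
the analysis window a second time, summed at its hop position, and the total
divided by the overlap-added squared window.  For tapers and overlaps
satisfying the nonzero-overlap-add condition this inverts the STFT exactly on
the interior (edge frames lack full window coverage).  The half-spectrum
(bins 0..N/2-1) is extended by conjugate symmetry with a zero Nyquist bin, so
any energy the input had exactly at Nyquist is not representable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy.signal import check_NOLA

from .audio_io import Waveform
from .spectrogram import ComplexSpectrogram

__all__ = [
    "BoundingBox",
    "MaskSpec",
    "apply_box_filter",
    "apply_band_filter",
    "reduce_noise_rowwise",
    "reconstruct",
]


@dataclass(frozen=True)
class BoundingBox:
    """A time (s) x frequency (kHz) rectangle, lower-left to upper-right."""

    t_start: float
    t_end: float
    f_start: float
    f_end: float

    def __post_init__(self) -> None:
        vals = (self.t_start, self.t_end, self.f_start, self.f_end)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"bounding box coordinates must be finite, got {vals}")
        if min(vals) < 0:
            raise ValueError(f"bounding box coordinates must be >= 0, got {vals}")
        if not self.t_start < self.t_end:
            raise ValueError(f"t_start must be < t_end, got [{self.t_start}, {self.t_end}]")
        if not self.f_start < self.f_end:
            raise ValueError(f"f_start must be < f_end, got [{self.f_start}, {self.f_end}]")


@dataclass(frozen=True)
class MaskSpec:
    """How to treat spectrogram cells outside a selection box.

    zero mode multiplies outside cells by ``epsilon`` (exactly 0 by default,
    "near-zero" when a small epsilon is chosen); attenuate mode divides their
    magnitude by ``attenuation_factor`` (default 100).  Phase is preserved
    wherever magnitude stays nonzero, since both are pure scalings.
    """

    box: BoundingBox
    mode: Literal["zero", "attenuate"] = "zero"
    attenuation_factor: float = 100.0
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("zero", "attenuate"):
            raise ValueError(f"mode must be 'zero' or 'attenuate', got {self.mode!r}")
        if not self.attenuation_factor > 1:
            raise ValueError("attenuation_factor must be > 1")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")

    @property
    def outside_scale(self) -> float:
        return self.epsilon if self.mode == "zero" else 1.0 / self.attenuation_factor


def _inside_mask(cspec: ComplexSpectrogram, box: BoundingBox) -> np.ndarray:
    """Boolean (bins x frames) matrix of cells whose centres lie in the closed box."""
    t_in = (cspec.times >= box.t_start) & (cspec.times <= box.t_end)
    f_in = (cspec.freqs_khz >= box.f_start) & (cspec.freqs_khz <= box.f_end)
    return f_in[:, None] & t_in[None, :]


def apply_box_filter(cspec: ComplexSpectrogram, mask: MaskSpec) -> ComplexSpectrogram:
    """Keep the selected area of the complex spectrogram, scale the rest.

    Cells whose centres lie inside the box are bit-identical to the input;
    every outside cell is multiplied by the mask's outside scale.  A box
    containing no cell centres is rejected — nothing would remain.
    """
    inside = _inside_mask(cspec, mask.box)
    if not inside.any():
        raise ValueError(
            f"selection box [{mask.box.t_start}, {mask.box.t_end}] s x "
            f"[{mask.box.f_start}, {mask.box.f_end}] kHz contains no spectrogram cells"
        )
    out = cspec.values.copy()
    out[~inside] *= mask.outside_scale
    return replace(cspec, values=out)


def apply_band_filter(
    cspec: ComplexSpectrogram,
    f_start: float,
    f_end: float,
    mode: Literal["zero", "attenuate"] = "zero",
    attenuation_factor: float = 100.0,
    epsilon: float = 0.0,
) -> ComplexSpectrogram:
    """Band-pass the spectrogram: full duration, only frequencies in [f_start, f_end] kHz."""
    if not f_start < f_end:
        raise ValueError(f"f_start must be < f_end, got [{f_start}, {f_end}]")
    box = BoundingBox(
        t_start=0.0,
        t_end=cspec.time_span_seconds,
        f_start=max(f_start, 0.0),
        f_end=f_end,
    )
    return apply_box_filter(
        cspec,
        MaskSpec(box=box, mode=mode, attenuation_factor=attenuation_factor, epsilon=epsilon),
    )


def reduce_noise_rowwise(cspec: ComplexSpectrogram) -> ComplexSpectrogram:
    """Median spectral subtraction per frequency row, phase preserved.

    For each row the median magnitude over frames estimates the stationary
    noise level there; that estimate is subtracted from every cell's
    magnitude (floored at zero).  Rows that are silent in more than half the
    frames have median zero and pass through untouched, so brief loud events
    survive while persistent backgrounds are removed.
    """
    if cspec.frames < 2:
        raise ValueError("row-wise noise reduction needs at least 2 frames")
    mag = np.abs(cspec.values)
    row_median = np.median(mag, axis=1, keepdims=True)
    new_mag = np.maximum(mag - row_median, 0.0)
    scale = np.divide(new_mag, mag, out=np.zeros_like(mag), where=mag > 0)
    return replace(cspec, values=cspec.values * scale)


def reconstruct(cspec: ComplexSpectrogram) -> Waveform:
    """Inverse STFT by weighted overlap-add with the analysis window.

    Output length is ``(frames - 1) * hop + N`` — the span the analysis
    windows covered; callers needing the original length must pad or truncate.
    The window/overlap pair must satisfy the nonzero-overlap-add condition
    (for the default taper any overlap >= 0.5 qualifies).
    """
    params = cspec.params
    n, hop = params.window_length, params.hop
    window = params.window()
    if params.overlap < 0.5 or not check_NOLA(window, n, n - hop):
        raise ValueError(
            f"(window={params.window_shape!r}, overlap={params.overlap}) does not satisfy "
            "the overlap-add constraint required for reconstruction"
        )
    # Conjugate-symmetric extension: half spectrum + zero Nyquist bin.
    half = np.concatenate([cspec.values, np.zeros((1, cspec.frames))], axis=0)
    frames_time = np.fft.irfft(half, n=n, axis=0).T  # frames x N
    frames_time *= window[None, :]

    length = (cspec.frames - 1) * hop + n
    out = np.zeros(length)
    norm = np.zeros(length)
    win_sq = window**2
    for i in range(cspec.frames):
        start = i * hop
        out[start : start + n] += frames_time[i]
        norm[start : start + n] += win_sq
    np.divide(out, norm, out=out, where=norm > np.finfo(float).tiny)
    return Waveform(samples=out, sample_rate=cspec.sample_rate)
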