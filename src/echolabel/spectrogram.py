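"""Complex STFT and dB spectrograms under explicit windowing conventions.

The conventions are fixed so the matrix dimensions are exactly reproducible:

* analysis windows start at ``i * hop`` with ``hop = round(N * (1 - overlap))``;
  there is no centring and no zero-padding, and a trailing partial window is
  discarded, so ``frames = floor((L - N) / hop) + 1``;
* frequency bins run ``0 .. N/2 - 1`` (DC included, Nyquist excluded), giving
  ``N/2`` rows.

Under these rules a 15 s clip at 24 kHz with the default 256-point window and
75 % overlap yields a 128 x 5622 matrix (719,616 cells).  Cell (k, i) has
centre frequency ``k * sr / N`` Hz and centre time ``(i * hop + N/2) / sr`` s;
all box/zoom geometry is decided by these cell centres.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import TYPE_CHECKING

import numpy as np
from scipy.signal import get_window

from .audio_io import Waveform

if TYPE_CHECKING:  # BoundingBox is defined with the masking ops; no runtime cycle
    from .tf_filter import BoundingBox

__all__ = [
    "StftParams",
    "ComplexSpectrogram",
    "DbSpectrogram",
    "frame_count",
    "compute_stft",
    "to_db",
    "zoom",
]


@dataclass(frozen=True)
class StftParams:
    """STFT windowing parameters: 256-point tapered window, 75 % overlap."""

    window_length: int = 256
    overlap: float = 0.75
    window_shape: str = "hann"

    def __post_init__(self) -> None:
        n = self.window_length
        if not (isinstance(n, (int, np.integer)) and n >= 2 and n % 2 == 0):
            raise ValueError(f"window_length must be an even integer >= 2, got {n!r}")
        if not (0.0 <= self.overlap < 1.0):
            raise ValueError(f"overlap must be in [0, 1), got {self.overlap!r}")
        if self.hop < 1:
            raise ValueError("overlap too high: hop = round(N*(1-overlap)) must be >= 1")
        object.__setattr__(self, "window_length", int(n))

    @property
    def hop(self) -> int:
        return int(round(self.window_length * (1.0 - self.overlap)))

    def window(self) -> np.ndarray:
        # Periodic ("fftbins") taper: the variant with exact constant-overlap-add sums.
        return get_window(self.window_shape, self.window_length, fftbins=True)


def frame_count(n_samples: int, params: StftParams) -> int:
    """Number of full analysis windows fitting in ``n_samples`` samples."""
    n = params.window_length
    if n_samples < n:
        return 0
    return (n_samples - n) // params.hop + 1


@dataclass(frozen=True)
class ComplexSpectrogram:
    """Complex STFT matrix of shape (N/2 bins) x frames with its parameters."""

    values: np.ndarray
    sample_rate: int
    params: StftParams

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2 or not np.iscomplexobj(values):
            raise ValueError("values must be a 2-D complex matrix (bins x frames)")
        if values.shape[0] != self.params.window_length // 2:
            raise ValueError(
                f"expected {self.params.window_length // 2} frequency bins, got {values.shape[0]}"
            )
        object.__setattr__(self, "values", values.astype(np.complex128, copy=False))

    @property
    def bins(self) -> int:
        return self.values.shape[0]

    @property
    def frames(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame-centre times in seconds: (i*hop + N/2) / sample_rate."""
        n, hop = self.params.window_length, self.params.hop
        return (np.arange(self.frames) * hop + n / 2) / self.sample_rate

    @property
    def freqs_khz(self) -> np.ndarray:
        """Bin-centre frequencies in kHz: k * sample_rate / N."""
        return np.arange(self.bins) * self.sample_rate / self.params.window_length / 1000.0

    @property
    def nyquist_khz(self) -> float:
        return self.sample_rate / 2000.0

    @property
    def time_span_seconds(self) -> float:
        """Seconds of input covered by the analysis windows."""
        return ((self.frames - 1) * self.params.hop + self.params.window_length) / self.sample_rate


@dataclass(frozen=True)
class DbSpectrogram:
    """dB-scaled magnitude raster (cells <= 0 dB) with display extents.

    ``times`` / ``freqs_khz`` carry the surviving cell centres so zooming can
    be repeated; extents are what axes should display.
    """

    values: np.ndarray
    sample_rate: int
    params: StftParams
    time_extent: tuple[float, float]
    freq_extent: tuple[float, float]
    times: np.ndarray
    freqs_khz: np.ndarray


def compute_stft(waveform: Waveform, params: StftParams | None = None) -> ComplexSpectrogram:
    """Compute the complex STFT under the fixed windowing conventions.

    Raises a validation error when the input is shorter than one window; the
    message names the minimum length.
    """
    if params is None:
        params = StftParams()
    x = waveform.samples
    n, hop = params.window_length, params.hop
    if x.size < n:
        raise ValueError(
            f"input has {x.size} samples but at least window_length={n} are required"
        )
    frames = frame_count(x.size, params)
    idx = np.arange(frames)[:, None] * hop + np.arange(n)[None, :]
    segments = x[idx] * params.window()[None, :]
    spectrum = np.fft.rfft(segments, axis=1)[:, : n // 2]  # drop the Nyquist row
    return ComplexSpectrogram(values=spectrum.T, sample_rate=waveform.sample_rate, params=params)


def to_db(
    cspec: ComplexSpectrogram, dynamic_range: float = 60.0, contrast: float = 0.0
) -> DbSpectrogram:
    """Convert to a dB raster: 20*log10(|S| / max|S|) + contrast, clamped to [-dynamic_range, 0].

    ``contrast`` is an additive dB offset applied before clamping (a positive
    value pushes more cells to the 0 dB ceiling, brightening the display).
    An all-zero spectrogram maps to a uniform floor.
    """
    if dynamic_range <= 0:
        raise ValueError("dynamic_range must be positive (dB)")
    mag = np.abs(cspec.values)
    peak = mag.max()
    if peak == 0.0:
        db = np.full(mag.shape, -dynamic_range)
    else:
        with np.errstate(divide="ignore"):
            db = 20.0 * np.log10(mag / peak) + contrast
        db = np.clip(db, -dynamic_range, 0.0)
    return DbSpectrogram(
        values=db,
        sample_rate=cspec.sample_rate,
        params=cspec.params,
        time_extent=(0.0, cspec.time_span_seconds),
        freq_extent=(0.0, cspec.nyquist_khz),
        times=cspec.times,
        freqs_khz=cspec.freqs_khz,
    )


def zoom(dbspec: DbSpectrogram, box: "BoundingBox") -> DbSpectrogram:
    """Restrict a dB spectrogram to the cells whose centres fall inside ``box``.

    dB values are untouched (no re-normalisation against the zoomed maximum);
    the display extents become the intersection of the box with the current
    extents.  An empty intersection is an error.
    """
    t_sel = (dbspec.times >= box.t_start) & (dbspec.times <= box.t_end)
    f_sel = (dbspec.freqs_khz >= box.f_start) & (dbspec.freqs_khz <= box.f_end)
    if not (t_sel.any() and f_sel.any()):
        raise ValueError(
            f"zoom box [{box.t_start}, {box.t_end}] s x [{box.f_start}, {box.f_end}] kHz "
            "contains no spectrogram cells"
        )
    return replace(
        dbspec,
        values=dbspec.values[np.ix_(f_sel, t_sel)],
        time_extent=(
            max(dbspec.time_extent[0], box.t_start),
            min(dbspec.time_extent[1], box.t_end),
        ),
        freq_extent=(
            max(dbspec.freq_extent[0], box.f_start),
            min(dbspec.freq_extent[1], box.f_end),
        ),
        times=dbspec.times[t_sel],
        freqs_khz=dbspec.freqs_khz[f_sel],
    )
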