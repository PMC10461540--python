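"""WAV input/output, recorder filename parsing, and waveform preprocessing.

Field recorders deposit mono WAV files named ``RECORDERNAME_YYYYMMDD_HHMMSS.wav``;
recordings split into segments carry an extra ``_start_MM_SS`` suffix giving the
offset of the segment within the parent recording.  This module reads and writes
such files, recovers the recording identity from the name, and provides the
preprocessing chain applied before display: dB gain, peak normalization and
segmentation into fixed-length clips (15 s by default).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path

import numpy as np
from scipy.io import wavfile

logger = logging.getLogger("echolabel")

__all__ = [
    "Waveform",
    "RecordingIdentity",
    "Clip",
    "read_wave",
    "write_wave",
    "parse_filename",
    "format_filename",
    "apply_gain",
    "normalize",
    "segment",
]


@dataclass(frozen=True)
class Waveform:
    """Sampled mono audio with amplitudes nominally in [-1, 1]."""

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("Waveform samples must be one-dimensional (mono)")
        if samples.size < 1:
            raise ValueError("Waveform must contain at least one sample")
        if not (isinstance(self.sample_rate, (int, np.integer)) and self.sample_rate > 0):
            raise ValueError(f"sample_rate must be a positive integer, got {self.sample_rate!r}")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "sample_rate", int(self.sample_rate))

    @property
    def duration_seconds(self) -> float:
        return self.samples.size / self.sample_rate

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Waveform):
            return NotImplemented
        return self.sample_rate == other.sample_rate and np.array_equal(self.samples, other.samples)


# Recorder token: everything before the first "_" that is followed by 8 digits.
_FILENAME_RE = re.compile(
    r"^(?P<recorder>[^_]+)_(?P<date>\d{8})_(?P<time>\d{6})"
    r"(?:_start_(?P<mm>\d{2})_(?P<ss>\d{2}))?\.wav$",
    re.IGNORECASE,
)


@dataclass(frozen=True)
class RecordingIdentity:
    """Identity parsed from a recorder filename.

    ``offset_seconds`` is nonzero only for segment files carrying the
    ``_start_MM_SS`` suffix; the effective clip start is
    ``start_datetime + offset_seconds``.
    """

    recorder: str
    start_datetime: datetime
    offset_seconds: int = 0

    def __post_init__(self) -> None:
        if not self.recorder or "_" in self.recorder:
            raise ValueError("recorder must be a non-empty token without underscores")
        if not (0 <= int(self.offset_seconds) < 3600):
            raise ValueError("offset_seconds must be in [0, 3600): MM_SS cannot encode more")
        object.__setattr__(self, "offset_seconds", int(self.offset_seconds))


@dataclass(frozen=True)
class Clip:
    """A contiguous slice of a source recording."""

    waveform: Waveform
    source_file: str
    clip_offset_seconds: float

    def __post_init__(self) -> None:
        if self.clip_offset_seconds < 0:
            raise ValueError("clip_offset_seconds must be >= 0")


def read_wave(path: str | Path) -> Waveform:
    """Read a WAV file as a mono float waveform scaled to [-1, 1].

    Integer PCM (8/16/24/32-bit) is rescaled by the full-scale value of its
    bit depth; IEEE float files are taken verbatim.  Multi-channel audio is
    mixed down to mono by averaging the channels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"audio file not found: {path}")
    try:
        rate, data = wavfile.read(str(path))
    except ValueError as exc:
        raise ValueError(f"not a readable WAV file: {path} ({exc})") from exc

    if data.dtype == np.uint8:  # 8-bit WAV is unsigned, midpoint 128
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype.kind == "i":
        samples = data.astype(np.float64) / float(2 ** (8 * data.dtype.itemsize - 1))
    else:
        samples = data.astype(np.float64)
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return Waveform(samples=samples, sample_rate=int(rate))


def write_wave(path: str | Path, waveform: Waveform) -> None:
    """Write a waveform as a 32-bit float WAV, clipping to [-1, 1].

    Samples outside [-1, 1] are clamped and a warning is logged; gain staging
    upstream deliberately never clips, so this is the single clipping point.
    """
    if not isinstance(waveform, Waveform):
        raise TypeError("write_wave expects a Waveform")
    samples = waveform.samples
    n_clipped = int(np.count_nonzero((samples < -1.0) | (samples > 1.0)))
    if n_clipped:
        logger.warning("write_wave: clipped %d sample(s) to [-1, 1] in %s", n_clipped, path)
        samples = np.clip(samples, -1.0, 1.0)
    wavfile.write(str(path), waveform.sample_rate, samples.astype(np.float32))


def parse_filename(name: str) -> RecordingIdentity | None:
    """Parse ``RECORDERNAME_YYYYMMDD_HHMMSS[_start_MM_SS].wav``.

    Returns None (with a logged warning) on any mismatch: linking audio files
    to their recording metadata is best-effort, never fatal.
    """
    base = Path(str(name)).name
    m = _FILENAME_RE.match(base)
    if m is None:
        logger.warning("filename does not match recorder convention: %r", base)
        return None
    try:
        start = datetime.strptime(m.group("date") + m.group("time"), "%Y%m%d%H%M%S")
    except ValueError:
        logger.warning("filename has an invalid date/time: %r", base)
        return None
    offset = 0
    if m.group("mm") is not None:
        offset = 60 * int(m.group("mm")) + int(m.group("ss"))
    return RecordingIdentity(recorder=m.group("recorder"), start_datetime=start, offset_seconds=offset)


def format_filename(identity: RecordingIdentity) -> str:
    """Format a RecordingIdentity back to its canonical filename.

    The ``_start_MM_SS`` suffix is omitted when the offset is zero, so
    ``parse_filename(format_filename(i)) == i`` for every valid identity.
    """
    stamp = identity.start_datetime.strftime("%Y%m%d_%H%M%S")
    if identity.offset_seconds == 0:
        return f"{identity.recorder}_{stamp}.wav"
    mm, ss = divmod(identity.offset_seconds, 60)
    return f"{identity.recorder}_{stamp}_start_{mm:02d}_{ss:02d}.wav"


def apply_gain(waveform: Waveform, gain_db: float) -> Waveform:
    """Scale amplitudes by ``10**(gain_db / 20)`` (no clipping at this stage)."""
    if not np.isfinite(gain_db):
        raise ValueError("gain_db must be finite")
    factor = 10.0 ** (gain_db / 20.0)
    return Waveform(samples=waveform.samples * factor, sample_rate=waveform.sample_rate)


def normalize(waveform: Waveform) -> Waveform:
    """Peak-normalize so the maximum absolute amplitude is exactly 1.

    An all-zero waveform is returned unchanged with a warning (there is no
    meaningful scale to apply).
    """
    peak = float(np.max(np.abs(waveform.samples)))
    if peak == 0.0:
        logger.warning("normalize: all-zero waveform left unchanged")
        return waveform
    return Waveform(samples=waveform.samples / peak, sample_rate=waveform.sample_rate)


def segment(waveform: Waveform, clip_seconds: float = 15.0, source_file: str = "") -> list[Clip]:
    """Split a waveform into consecutive clips of ``clip_seconds`` each.

    Clips tile the input without overlap or gap; the final clip may be
    shorter.  The default 15 s matches the display-clip convention.
    """
    if clip_seconds <= 0:
        raise ValueError("clip_seconds must be positive")
    clip_samples = int(round(clip_seconds * waveform.sample_rate))
    if clip_samples < 1:
        raise ValueError("clip_seconds too small for this sample rate")
    clips: list[Clip] = []
    for index, start in enumerate(range(0, waveform.samples.size, clip_samples)):
        chunk = waveform.samples[start : start + clip_samples]
        clips.append(
            Clip(
                waveform=Waveform(samples=chunk, sample_rate=waveform.sample_rate),
                source_file=source_file,
                clip_offset_seconds=index * clip_seconds,
            )
        )
    return clips
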