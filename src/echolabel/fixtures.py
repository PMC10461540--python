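"""Synthetic audio and project scaffolding with known time-frequency ground truth.

Real field recordings cannot ship with the package, so every module is
exercised against synthesized clips: windowed tones, linear chirps and
band-limited noise bursts whose time and frequency extents are known exactly.
Events carry 10 ms raised-cosine amplitude edges so their spectral energy
stays confined to the intended box instead of splattering across the
spectrogram.  ``make_demo_project`` writes a complete miniature annotation
project — WAV files following the recorder filename convention, the three
configuration CSVs and a ground-truth label file — into a chosen directory.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from .audio_io import Waveform, write_wave
from .annotations import AnnotationSet, create_annotation, save_annotations
from .tf_filter import BoundingBox

__all__ = ["SyntheticEvent", "make_signal", "make_demo_project", "DEMO_RECORDERS"]

#: recorder names used by the demo project (real deployment-style tokens)
DEMO_RECORDERS = ("RAHORA", "TEEVURCHER")

_EDGE_SECONDS = 0.010  # raised-cosine fade length at each event edge


@dataclass(frozen=True)
class SyntheticEvent:
    """One synthetic sound event: a tone, linear chirp or noise burst.

    ``f_start == f_end`` for tones; for chirps the instantaneous frequency
    sweeps linearly from f_start to f_end (kHz); a noise burst is white noise
    band-passed to [f_start, f_end].
    """

    kind: str
    t_start: float
    t_end: float
    f_start: float
    f_end: float
    amplitude: float = 0.5
    class_label: str = "Tone"

    def __post_init__(self) -> None:
        if self.kind not in ("tone", "chirp", "noise_burst"):
            raise ValueError(f"kind must be tone/chirp/noise_burst, got {self.kind!r}")
        if not self.t_start < self.t_end:
            raise ValueError("t_start must be < t_end")
        if self.f_start < 0 or self.f_end < 0:
            raise ValueError("frequencies must be >= 0")
        if self.kind == "tone" and self.f_start != self.f_end:
            raise ValueError("a tone must have f_start == f_end")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")

    @property
    def box(self) -> BoundingBox:
        f0, f1 = sorted((self.f_start, self.f_end))
        if f0 == f1:  # tones get a nominal half-kHz band either side
            f0, f1 = max(f0 - 0.5, 0.0), f1 + 0.5
        return BoundingBox(t_start=self.t_start, t_end=self.t_end, f_start=f0, f_end=f1)


def _edge_taper(n: int, edge: int) -> np.ndarray:
    env = np.ones(n)
    if edge > 0 and n >= 2 * edge:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(edge) / edge))
        env[:edge] = ramp
        env[-edge:] = ramp[::-1]
    return env


def make_signal(
    events: list[SyntheticEvent],
    duration: float,
    sample_rate: int,
    noise_floor: float = 0.0,
    seed: int = 0,
) -> Waveform:
    """Synthesize a clip: sum of tapered events plus Gaussian background noise.

    Deterministic for a given seed.  Events must fit inside the clip and
    stay below the Nyquist frequency.
    """
    nyquist_khz = sample_rate / 2000.0
    for ev in events:
        if max(ev.f_start, ev.f_end) >= nyquist_khz:
            raise ValueError(
                f"event at {max(ev.f_start, ev.f_end)} kHz is at or above Nyquist ({nyquist_khz} kHz)"
            )
        if ev.t_start < 0 or ev.t_end > duration:
            raise ValueError(f"event [{ev.t_start}, {ev.t_end}] s does not fit in {duration} s clip")

    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    x = np.zeros(n)
    edge = int(round(_EDGE_SECONDS * sample_rate))
    for ev in events:
        i0, i1 = int(round(ev.t_start * sample_rate)), int(round(ev.t_end * sample_rate))
        t = np.arange(i1 - i0) / sample_rate
        if ev.kind == "tone":
            burst = np.sin(2 * np.pi * ev.f_start * 1000.0 * t)
        elif ev.kind == "chirp":
            sweep_rate = (ev.f_end - ev.f_start) * 1000.0 / (ev.t_end - ev.t_start)
            phase = 2 * np.pi * (ev.f_start * 1000.0 * t + 0.5 * sweep_rate * t**2)
            burst = np.sin(phase)
        else:  # noise_burst: white noise band-passed via FFT brickwall
            white = rng.standard_normal(t.size)
            spectrum = np.fft.rfft(white)
            freqs_khz = np.fft.rfftfreq(t.size, d=1.0 / sample_rate) / 1000.0
            f0, f1 = sorted((ev.f_start, ev.f_end))
            spectrum[(freqs_khz < f0) | (freqs_khz > f1)] = 0.0
            burst = np.fft.irfft(spectrum, n=t.size)
            peak = np.abs(burst).max()
            if peak > 0:
                burst /= peak
        x[i0:i1] += ev.amplitude * burst * _edge_taper(i1 - i0, edge)
    if noise_floor > 0:
        x += noise_floor * rng.standard_normal(n)
    return Waveform(samples=x, sample_rate=sample_rate)


# Demo project ground truth: events per generated file.  Frequencies in kHz.
_DEMO_EVENTS = {
    0: [
        SyntheticEvent("tone", 2.0, 3.0, 4.0, 4.0, amplitude=0.4, class_label="Blackbird"),
        SyntheticEvent("chirp", 6.0, 7.5, 2.0, 5.0, amplitude=0.4, class_label="Robin"),
        SyntheticEvent("tone", 10.0, 11.0, 6.5, 6.5, amplitude=0.3, class_label="Wren"),
    ],
    1: [
        SyntheticEvent("tone", 1.0, 2.5, 3.0, 3.0, amplitude=0.4, class_label="Robin"),
        SyntheticEvent("chirp", 8.0, 9.0, 5.0, 8.0, amplitude=0.35, class_label="Skylark"),
    ],
}

_DEMO_SPECIES = {
    "Rahora": ["Yellowhammer", "Blackbird", "Wren", "Robin", "Skylark"],
    "Teevurcher": ["Robin", "Skylark", "Meadow Pipit"],
}

# Synthetic 5-row stand-in for the full published two-letter code table.
_DEMO_BTO_CODES = [
    ("B.", "Blackbird"),
    ("R.", "Robin"),
    ("WR", "Wren"),
    ("S.", "Skylark"),
    ("MP", "Meadow Pipit"),
]

_DEMO_LOCATIONS = [
    {
        "recorder_name": "RAHORA",
        "lat": "52.57",
        "long": "-7.12",
        "location_name": "Rahora",
        "location_county": "Kilkenny",
        "habitat_type": "Agricultural (inland, arable)",
        "dist_to_coastline": "40",
    },
    {
        "recorder_name": "TEEVURCHER",
        "lat": "53.78",
        "long": "-6.95",
        "location_name": "Teevurcher",
        "location_county": "Meath",
        "habitat_type": "Agricultural (inland, pasture)",
        "dist_to_coastline": "30",
    },
]

DEMO_SAMPLE_RATE = 24_000
DEMO_CLIP_SECONDS = 15.0


def demo_ground_truth() -> dict[str, list[SyntheticEvent]]:
    """File name -> embedded events, as written by make_demo_project."""
    stamps = (datetime(2022, 4, 15, 6, 30), datetime(2022, 5, 1, 22, 0))
    out = {}
    for idx, events in _DEMO_EVENTS.items():
        name = f"{DEMO_RECORDERS[idx]}_{stamps[idx]:%Y%m%d_%H%M%S}.wav"
        out[name] = events
    return out


def make_demo_project(directory: str | Path, seed: int = 0) -> Path:
    """Write a self-consistent miniature annotation project.

    Layout: WAV clips named by the recorder convention, ``species_list.csv``,
    ``location_list.csv``, ``bto_codes.csv`` and ``labels/labels_tmp.csv``
    holding the ground-truth boxes of the embedded events.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    annotations = []
    for name, events in demo_ground_truth().items():
        wave = make_signal(
            events, DEMO_CLIP_SECONDS, DEMO_SAMPLE_RATE, noise_floor=0.01, seed=seed
        )
        write_wave(directory / name, wave)
        for ev in events:
            annotations.append(
                create_annotation(
                    box=ev.box,
                    class_label=ev.class_label,
                    confidence=100,
                    labeller="synthetic",
                    file_name=name,
                    notes="ground truth",
                    clip_duration=DEMO_CLIP_SECONDS,
                    nyquist_khz=DEMO_SAMPLE_RATE / 2000.0,
                    date_time=datetime(2022, 7, 1, 12, 0, tzinfo=timezone.utc),
                )
            )
    save_annotations(AnnotationSet.from_annotations(annotations), directory / "labels", username="")

    def write_csv(name: str, rows: list[list[str]]) -> None:
        with open(directory / name, "w", encoding="utf-8", newline="") as fh:
            csv.writer(fh).writerows(rows)

    sites = list(_DEMO_SPECIES)
    depth = max(len(v) for v in _DEMO_SPECIES.values())
    species_rows = [sites] + [
        [(_DEMO_SPECIES[s][i] if i < len(_DEMO_SPECIES[s]) else "") for s in sites]
        for i in range(depth)
    ]
    write_csv("species_list.csv", species_rows)
    write_csv("bto_codes.csv", [["bto_code", "species_name"], *map(list, _DEMO_BTO_CODES)])
    loc_cols = list(_DEMO_LOCATIONS[0])
    write_csv("location_list.csv", [loc_cols] + [[r[c] for c in loc_cols] for r in _DEMO_LOCATIONS])
    return directory
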