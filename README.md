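# echolabel

A headless Python toolkit for annotating passive-acoustic-monitoring (PAM)
recordings with time-frequency bounding boxes. It is aimed at bioacoustics
projects — bird surveys at wind farms, soundscape monitoring, any workflow
where experts label vocalisations on spectrograms — that need the
computational core of an annotation tool (spectrograms, selection-filtered
audio, label files, per-site species lists) scriptable from Python or a
shell, without an interactive GUI.

## What it computes

**Spectrograms.** The short-time Fourier transform of a mono waveform
*x* with window length *N* (default 256), hop *h* = round(*N*·(1 − overlap))
(default overlap 0.75, so *h* = 64) and a periodic Hann taper *w*:

    S[k, i] = Σ_{n=0}^{N-1} x[i·h + n] · w[n] · e^(−2πi·k·n/N)

Windows start at *i·h* with no centring or padding; a trailing partial
window is discarded, giving `frames = ⌊(L − N)/h⌋ + 1`, and bins run
*k* = 0 … *N*/2 − 1 (DC included, Nyquist excluded). A 15 s clip at 24 kHz
therefore yields exactly 128 × 5622 cells. Display scaling is
`20·log10(|S|/max|S|)` plus an additive contrast offset, clamped to a
dynamic range (default 60 dB).

**Selection filtering.** To audition just the sound inside a drawn box,
cells whose centres lie inside the box are kept bit-identical and all other
cells are either zeroed (default) or divided by an attenuation factor
(default 100, which softens the distortion of hard zeroing). The audio is
then rebuilt by inverse STFT — weighted overlap-add with the analysis
window, normalised by the summed squared window. A band-pass filter is the
same mask spanning the full clip; row-wise noise reduction subtracts each
frequency row's median magnitude (phase preserved), suppressing stationary
backgrounds such as turbine noise.

**Annotations and project files.** Labels are rows of a CSV with columns
`date_time, file_name, start_time, end_time` (s), `start_freq, end_freq`
(kHz), `class_label`, plus optional `confidence` (0–100), `labeller`,
`call_type`, `notes`; files with a UTF-8 BOM are read transparently. Audio
files follow the convention `RECORDERNAME_YYYYMMDD_HHMMSS[_start_MM_SS].wav`.
Per-site species lists, a two-letter species-code lookup (`bto_codes.csv`)
and recorder metadata (`location_list.csv`) configure the class list an
annotator picks from.

## Worked example

```
$ echolabel demo --out proj --seed 1
proj
$ echolabel spectrogram proj/RAHORA_20220415_063000.wav --json
{"file": "RAHORA_20220415_063000.wav", "sample_rate": 24000,
 "duration_seconds": 15.0, "bins": 128, "frames": 5622, "hop": 64,
 "window": 256, "overlap": 0.75}
$ echolabel filter proj/RAHORA_20220415_063000.wav --box 2,3,3.5,4.5 \
      --out filtered.wav
filtered.wav
$ echolabel label add --labels-dir proj/labels --file-name RAHORA_20220415_063000.wav \
      --box 2,3,3.5,4.5 --class Blackbird
added label 6 to proj/labels/labels_tmp.csv
$ echolabel summarize proj
                     file_name  total_labels  Blackbird  Robin  Skylark  Wren
RAHORA_20220415_063000.wav                 4          2      1        0     1
TEEVURCHER_20220501_220000.wav             2          0      1        1     0
```

The demo project embeds synthetic tones and chirps with known boxes; the
`spectrogram` output reports the 128 × 5622 STFT shape for the 15 s / 24 kHz
clip, `filter` writes audio reconstructed from the masked spectrogram
(2–3 s, 3.5–4.5 kHz selection), and `summarize` counts labels per file and
class — here the 5 ground-truth labels plus the one just added.

The same operations are available as library functions
(`compute_stft`, `apply_box_filter`, `reconstruct`, `load_annotations`, …);
see `docs/methods.md` for conventions and parameters.

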