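# Methods

## Spectrogram conventions

The STFT is computed over analysis windows starting at `i * hop`,
`hop = round(N * (1 - overlap))`, with a periodic Hann taper. Three
conventions are fixed deliberately and everything downstream depends on
them:

* **No centring, no padding.** The first window starts at sample 0 and a
  trailing partial window is discarded, so
  `frames = floor((L - N) / hop) + 1`. This is the convention under which a
  15 s clip at 24 kHz (360,000 samples) with the default `N = 256`,
  `overlap = 0.75` (`hop = 64`) produces exactly 5622 frames, and it is
  checked against brute-force enumeration of window start positions in the
  tests.
* **Bins 0 … N/2 − 1.** DC is included and the Nyquist bin is excluded,
  giving 128 rows at the default window. Consequence: signal energy at
  exactly the Nyquist frequency is not representable in the complex
  spectrogram and cannot survive a round trip (see *Reconstruction*).
* **Cell centres decide geometry.** Cell (k, i) has centre frequency
  `k * sr / N` Hz and centre time `(i*hop + N/2) / sr` s. Membership of a
  cell in a selection box, a zoom region or a frequency band is decided by
  whether its centre lies in the closed box — symmetric in both axes and
  free of edge-inclusion ambiguity.

dB scaling is `20*log10(|S| / max|S|) + contrast`, clamped to
`[-dynamic_range, 0]`. The peak therefore sits at 0 dB regardless of input
level (the display is self-normalising and invariant to rescaling the
waveform). `contrast` is an additive dB offset applied before clamping: a
positive value saturates more cells at the ceiling, brightening faint
structure; the default is 0. `dynamic_range` defaults to 60 dB, a common
display floor for birdsong spectrograms. Zooming slices the cell grid
without re-normalising dB values, so zoomed views remain comparable to the
full view.

The default window (256 points, 75 % overlap, Hann) trades time against
frequency resolution at 24 kHz sampling: 93.75 Hz bins and 2.7 ms hops.
Raising `window_length` sharpens frequency at the cost of time resolution.

## Masking and reconstruction

A selection mask keeps inside cells bit-identical and multiplies outside
cells by a scalar: `epsilon` (default exactly 0) in zero mode, or
`1 / attenuation_factor` (default 1/100) in attenuate mode. The attenuation
is applied to the complex value, i.e. to the magnitude with phase
preserved; magnitude (not power) attenuation is the adopted reading of a
"factor of 100". Both modes are pure scalings, so masking is linear, never
increases energy, zero-mode masking is idempotent, and attenuating twice
scales outside cells by the factor squared.

Row-wise noise reduction estimates each frequency row's stationary noise
level by the **median** magnitude over frames and subtracts it from every
cell in the row, floored at zero, with phase preserved. The median is
robust to sparse vocalisations: a call present in fewer than half the
frames of a row does not inflate the row's noise estimate. For
complex-Gaussian noise (Rayleigh magnitudes) the expected mean-magnitude
reduction of pure-noise cells is 1 − E[(R − med R)+]/E[R] ≈ 76 %
(energy reduction ≈ 85 %); the tests pin this closed-form value. Event
cells lose far less (≈ 11 % for the synthetic chirp mixture) because their
magnitudes sit well above the row median.

Reconstruction is weighted overlap-add: each frame's half-spectrum is
extended by conjugate symmetry with a zero Nyquist bin, inverted,
multiplied by the analysis window a second time, summed at its hop
position, and the sum divided by the overlap-added squared window. The
window/hop pair must satisfy the nonzero-overlap-add condition (checked via
`scipy.signal.check_NOLA`; the default Hann at any overlap ≥ 0.5
qualifies). Output length is `(frames - 1)*hop + N` — exactly the span the
analysis covered; callers needing the original length pad or truncate
explicitly. On the interior (edge windows lack full overlap coverage) the
round trip is exact to floating-point for any signal with no energy in the
discarded Nyquist bin; round-trip tests therefore use random multi-tone
signals on exact bin frequencies below 0.8×Nyquist, which the half-spectrum
represents losslessly. Broadband white noise, by contrast, has irreducible
Nyquist-bin energy and reconstructs with errors around 10⁻³ of the noise
amplitude — a representation limit, not an overlap-add defect.

## Audio handling

WAV I/O uses `scipy.io.wavfile`. Integer PCM is scaled by the full-scale
value of its bit depth; multi-channel files are mono-mixed by channel
averaging (deterministic, lossless for identical channels). Output is
32-bit float WAV. Gain (`10^(dB/20)`) never clips; clipping happens only at
write time, clamped to [−1, 1] with a logged warning, so information is
preserved through the processing chain. Normalization is peak
normalization to 1.0. Segmentation tiles a recording into consecutive
clips (default 15 s, the display-clip convention) with a shorter final
clip; concatenating the clips reproduces the input exactly.

Filenames follow `RECORDERNAME_YYYYMMDD_HHMMSS[_start_MM_SS].wav`; the
recorder token is everything before the first underscore followed by eight
digits, and segment offsets are limited to `MM_SS` < 3600 s. Parsing is
best-effort: a non-matching name yields `None` with a warning, never an
exception, because linking audio to metadata is auxiliary.

## Annotations and project configuration

Label timestamps are written as ISO 8601 with a `+HHMM` numeric offset and
parsed offsets are preserved, never silently converted. Confidence is an
integer percent 0–100, defaulting to 100 when the column is absent. Stable
integer ids are assigned in load/creation order and survive edits and
deletions; edit and delete are atomic (any validation failure leaves the
set unchanged) and creation time and source file are immutable. Output CSV
is BOM-less UTF-8; input tolerates a UTF-8 BOM, matching common
spreadsheet exports.

Class-name matching is case-sensitive exact match everywhere (species
lists, label classes, code lookup): exactness avoids silently aliasing
distinct labels. Miscellaneous categories (human/insect/weather noise) are
a global configurable list rather than per-site. Species lists are
deduplicated and sorted alphabetically at load; merging uploaded lists
appends only new site columns, leaving existing sites untouched, and is
idempotent. The species-code lookup only changes an entry's display code;
unmatched names keep their name as the code, so applying a lookup is also
idempotent. The bundled 5-row code table in the demo project is a
synthetic stand-in; a full published table can be dropped in as
`bto_codes.csv`.

## Rendering

Images are composited back-to-front — dB raster, annotation boxes,
selection guides — so overlay changes never touch raster pixels. Box
border colours encode class category: site species green, manually added
blue, miscellaneous orange, unlisted grey. The default palette is viridis
(perceptually uniform); frequency increases upward, axes are seconds and
kHz, and label text sits at the box's upper-left corner. Output dimensions
equal the requested pixel size exactly, and rendering is deterministic for
fixed inputs (tests compare decoded pixel arrays).

## Synthetic data

`make_signal` sums windowed sinusoids, linear chirps and band-limited noise
bursts over an optional Gaussian noise floor, deterministically for a given
seed. Events carry 10 ms raised-cosine amplitude edges so their spectral
energy stays inside the intended time-frequency box (an untapered onset
splatters energy across frequency and would corrupt the box-energy
checks). The demo project (two 15 s clips at 24 kHz, five labelled events,
0.01 noise floor) emulates the file layout of a real deployment:
recorder-convention filenames, the three configuration CSVs and a
ground-truth label file.

What the synthetic fixtures do **not** emulate: real vocalisation
structure (harmonic stacks, amplitude modulation), reverberation,
overlapping calls, wind and rain transients, or recorder frequency
response. Passing tests demonstrate the correctness of the transforms,
masks and file contracts — not detection or labelling performance on field
recordings.

## Problem sizes and numerical choices

Tests and the acceptance script run the reference configuration (15 s at
24 kHz, the sizes the conventions are defined against) plus randomized
checks: 200 frame-count configurations, 20 round-trip signals, 50-row label
sets. Degenerate inputs are handled explicitly: all-zero waveforms pass
through normalization with a warning; all-zero spectrograms map to the
uniform dB floor and reconstruct to digital silence; empty
box-spectrogram intersections, inverted bands, sub-window inputs and
non-overlap-add parameter pairs raise validation errors naming the
offending values.

## Limitations

* No resampling, compressed-audio or ultrasonic (bat) pipeline.
* Nyquist-bin energy is unrepresentable (see above).
* Attenuate-on-magnitude is one reading of the attenuation contract;
  power attenuation would halve the dB reduction.
* No concurrent multi-user label merging; one label file per user.
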