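"""Frequency-domain core: amplitude spectra, surrounding-bin SNR, harmonic
selection, and summed-harmonic z-scores.

A 40 s epoch gives a 0.025 Hz bin resolution, so both tagged frequencies
fall on exact bins (1.2 Hz -> bin 48, 6 Hz -> bin 240). The signal-to-noise
ratio at a bin is its amplitude divided by the mean of 20 surrounding noise
bins; significance of a tagged response is assessed by summing fixed-width
windows centred on each retained harmonic and z-scoring the centre of the
summed segment against the same 20-bin noise set. z > 1.64 (one-tailed
p < .05) flags a significant response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import Epoch

__all__ = [
    "AmplitudeSpectrum",
    "NoiseWindowSpec",
    "HarmonicSet",
    "ZScoreResult",
    "SIGNIFICANCE_Z",
    "amplitude_spectrum",
    "spectral_energy",
    "noise_bin_offsets",
    "snr_spectrum",
    "harmonic_set",
    "deviant_harmonic_set",
    "standard_harmonic_set",
    "summed_harmonic_segments",
    "harmonic_zscore",
]

#: one-tailed 5 % normal criterion (95th percentile of N(0,1), 2 dp)
SIGNIFICANCE_Z = 1.64


@dataclass
class AmplitudeSpectrum:
    """Per-channel one-sided amplitude spectrum on an exact-bin grid.

    Amplitudes are scaled so a unit sinusoid at an exact bin reads 1
    (|X| * 2/N for non-DC, non-Nyquist bins).
    """

    amplitudes: np.ndarray          # (n_channels, n_bins), microvolts
    bin_resolution_hz: float
    channel_labels: list[str] | None = None

    @property
    def n_bins(self) -> int:
        return self.amplitudes.shape[1]

    @property
    def frequencies_hz(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.bin_resolution_hz

    def crop(self, fmax_hz: float) -> "AmplitudeSpectrum":
        """Spectrum restricted to bins at or below ``fmax_hz`` (for display/export)."""
        n = int(fmax_hz / self.bin_resolution_hz) + 1
        return AmplitudeSpectrum(self.amplitudes[:, :n].copy(),
                                 self.bin_resolution_hz, self.channel_labels)

    def bin_of(self, freq_hz: float) -> int:
        """Exact bin index of a frequency; raises if it is off-grid."""
        b = freq_hz / self.bin_resolution_hz
        if abs(b - round(b)) > 1e-6:
            raise ValueError(f"{freq_hz} Hz is not an exact bin "
                             f"(resolution {self.bin_resolution_hz} Hz)")
        k = int(round(b))
        if not (0 <= k < self.n_bins):
            raise ValueError(f"{freq_hz} Hz outside the spectrum")
        return k


@dataclass(frozen=True)
class NoiseWindowSpec:
    """Surrounding-bin noise selections for SNR and z.

    SNR at a bin uses the ``side_bins`` (12) bins on each side, minus the
    ``exclude_adjacent`` (1) immediately adjacent bin per side, minus the
    ``exclude_extremes`` (2) most extreme of the remainder — the local
    maximum and the local minimum — leaving 20 noise bins.

    The z-score noise set is the twenty surrounding bins proper:
    ``z_side_bins`` (10) per side, skipping the adjacent bin, with no
    extreme-value trimming. Trimming would clip the tails of the noise
    sample and bias the sd low, mis-calibrating the null z distribution;
    the untrimmed set leaves z t-distributed with ~20 degrees of freedom.
    """

    side_bins: int = 12
    exclude_adjacent: int = 1
    exclude_extremes: int = 2
    z_side_bins: int = 10

    @property
    def n_noise_bins(self) -> int:
        return 2 * (self.side_bins - self.exclude_adjacent) - self.exclude_extremes

    @property
    def n_z_noise_bins(self) -> int:
        return 2 * self.z_side_bins


def amplitude_spectrum(epoch: Epoch, expected_duration_s: float = 40.0) -> AmplitudeSpectrum:
    """FFT amplitude spectrum of a cropped stimulation epoch.

    No taper (rectangular window): the epoch holds an integer number of
    cycles of every tagged frequency, so their energy is confined to exact
    bins. Requires the epoch to be the cropped stimulation phase.
    """
    n = epoch.n_samples
    if abs(epoch.duration_s - expected_duration_s) > 1e-6:
        raise ValueError(
            f"expected a cropped {expected_duration_s:g} s epoch, got {epoch.duration_s:g} s")
    coef = np.fft.rfft(epoch.data, axis=1)
    amps = np.abs(coef) * (2.0 / n)
    amps[:, 0] /= 2.0                  # DC is not doubled
    if n % 2 == 0:
        amps[:, -1] /= 2.0             # Nyquist bin is not doubled
    labels = epoch.montage.labels if epoch.montage is not None else None
    return AmplitudeSpectrum(amplitudes=amps, bin_resolution_hz=1.0 / epoch.duration_s,
                             channel_labels=list(labels) if labels else None)


def spectral_energy(spec: AmplitudeSpectrum, n_samples: int) -> np.ndarray:
    """Total signal energy per channel reconstructed from the one-sided spectrum.

    Satisfies Parseval: equals ``sum(x**2)`` of the time series.
    """
    a = spec.amplitudes
    # undo the one-sided doubling to recover |X_k|, then sum |X_k|^2 two-sided
    scale = np.full(spec.n_bins, 2.0)
    scale[0] = 1.0
    if n_samples % 2 == 0:
        scale[-1] = 1.0
    power = (a / scale) ** 2 * n_samples ** 2   # |X_k|^2
    # two-sided sum: interior bins appear twice
    two_sided = power * scale
    return two_sided.sum(axis=1) / n_samples


def noise_bin_offsets(win: NoiseWindowSpec = NoiseWindowSpec()) -> np.ndarray:
    """Candidate noise-bin offsets relative to the target bin (before the
    extreme-bin exclusion): +-(exclude_adjacent+1) ... +-side_bins."""
    lo = win.exclude_adjacent + 1
    offs = np.r_[np.arange(-win.side_bins, -lo + 1), np.arange(lo, win.side_bins + 1)]
    return offs


def _select_noise_values(values: np.ndarray, win: NoiseWindowSpec):
    """Drop the extreme values — alternately the maximum and the minimum,
    ``exclude_extremes`` in total (tie-break: lower index first); returns the
    kept values. One-from-each-tail trimming keeps the mean of the remaining
    bins an (almost) unbiased noise estimate, unlike one-sided trimming."""
    keep = np.ones(len(values), dtype=bool)
    for i in range(win.exclude_extremes):
        masked = np.where(keep, values, np.nan)
        idx = np.nanargmax(masked) if i % 2 == 0 else np.nanargmin(masked)
        keep[idx] = False
    return values[keep]


def snr_spectrum(spec: AmplitudeSpectrum,
                 win: NoiseWindowSpec = NoiseWindowSpec()) -> AmplitudeSpectrum:
    """SNR at each bin: amplitude divided by the mean of its 20 noise bins.

    Noise bins for bin k are the bins within +-12, excluding the immediately
    adjacent bin on each side and the 2 bins most deviant from the median of
    the remainder. Edge bins without a full window are set to NaN, as are
    bins whose noise mean is 0.
    """
    amps = spec.amplitudes
    n_ch, n_bins = amps.shape
    offs = noise_bin_offsets(win)
    snr = np.full_like(amps, np.nan, dtype=float)
    lo, hi = win.side_bins, n_bins - win.side_bins - 1
    ks = np.arange(lo, hi + 1)
    vals = amps[:, ks[:, None] + offs[None, :]]      # (n_ch, n_k, n_candidates)
    # drop extremes alternating max/min (ties -> lower offset index, matching
    # _select_noise_values)
    mask = np.ones_like(vals, dtype=bool)
    for i in range(win.exclude_extremes):
        masked = np.where(mask, vals, np.nan)
        idx = (np.nanargmax(masked, axis=-1) if i % 2 == 0
               else np.nanargmin(masked, axis=-1))
        np.put_along_axis(mask, idx[..., None], False, axis=-1)
    kept = np.where(mask, vals, 0.0)
    noise_mean = kept.sum(axis=-1) / mask.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = amps[:, ks] / noise_mean
    ratio[noise_mean <= 0] = np.nan
    snr[:, ks] = ratio
    return AmplitudeSpectrum(amplitudes=snr, bin_resolution_hz=spec.bin_resolution_hz,
                             channel_labels=spec.channel_labels)


@dataclass
class HarmonicSet:
    fundamental_hz: float
    included_hz: tuple[float, ...]
    excluded_hz: tuple[float, ...]
    bin_resolution_hz: float

    @property
    def bins(self) -> np.ndarray:
        return np.array([int(round(f / self.bin_resolution_hz)) for f in self.included_hz])


def harmonic_set(fundamental_hz: float, bin_resolution_hz: float = 0.025,
                 max_harmonics: int = 6,
                 exclude_rate_hz: float | None = None) -> HarmonicSet:
    """Consecutive multiples of a fundamental, skipping multiples of an
    excluded rate, until ``max_harmonics`` frequencies are retained.

    Every retained frequency must fall on an exact spectral bin.
    """
    included, excluded = [], []
    k = 1
    while len(included) < max_harmonics:
        f = round(k * fundamental_hz, 10)
        is_excluded = False
        if exclude_rate_hz:
            ratio = f / exclude_rate_hz
            is_excluded = abs(ratio - round(ratio)) < 1e-9
        if is_excluded:
            excluded.append(f)
        else:
            b = f / bin_resolution_hz
            if abs(b - round(b)) > 1e-6:
                raise ValueError(f"harmonic {f} Hz is not an exact bin at "
                                 f"{bin_resolution_hz} Hz resolution")
            included.append(f)
        k += 1
    return HarmonicSet(fundamental_hz, tuple(included), tuple(excluded),
                       bin_resolution_hz)


def deviant_harmonic_set(deviant_hz: float = 1.2, base_hz: float = 6.0,
                         bin_resolution_hz: float = 0.025, n: int = 6) -> HarmonicSet:
    """The oddball quantification set: {1.2, 2.4, 3.6, 4.8, 7.2, 8.4} Hz by default
    (six harmonics of 1.2 Hz with the 6 Hz base-rate multiple excluded)."""
    return harmonic_set(deviant_hz, bin_resolution_hz, n, exclude_rate_hz=base_hz)


def standard_harmonic_set(base_hz: float = 6.0,
                          bin_resolution_hz: float = 0.025) -> HarmonicSet:
    """The general-visual-response set: the first harmonic (6 Hz) only, which
    carries the strongest steady-state amplitude."""
    return harmonic_set(base_hz, bin_resolution_hz, 1)


def summed_harmonic_segments(spec: AmplitudeSpectrum, hset: HarmonicSet,
                             side_bins: int = 12) -> np.ndarray:
    """Element-wise sum of the (2*side_bins+1)-bin windows centred on each harmonic.

    Returns (n_channels, 25) by default; the centre element (index
    ``side_bins``) holds the summed target amplitude.
    """
    segments = np.zeros((spec.amplitudes.shape[0], 2 * side_bins + 1))
    for f in hset.included_hz:
        k = spec.bin_of(f)
        if k - side_bins < 0 or k + side_bins >= spec.n_bins:
            raise ValueError(f"window around {f} Hz overruns the spectrum")
        segments += spec.amplitudes[:, k - side_bins:k + side_bins + 1]
    return segments


@dataclass
class ZScoreResult:
    """Summed-harmonic z per channel, with noise diagnostics."""

    z: np.ndarray                   # (n_channels,)
    center_amplitude: np.ndarray
    noise_mean: np.ndarray
    noise_sd: np.ndarray
    harmonics: HarmonicSet
    target: str                     # "standard" | "deviant"
    undefined: np.ndarray = field(default=None)  # bool mask where sd == 0
    channel_labels: list[str] | None = None

    @property
    def significant(self) -> np.ndarray:
        return self.z > SIGNIFICANCE_Z


def z_noise_offsets(win: NoiseWindowSpec = NoiseWindowSpec()) -> np.ndarray:
    """The z noise set: ``z_side_bins`` (10) bins per side of the target,
    skipping the immediately adjacent bin, with no further trimming."""
    lo = win.exclude_adjacent + 1
    hi = win.exclude_adjacent + win.z_side_bins
    return np.r_[np.arange(-hi, -lo + 1), np.arange(lo, hi + 1)]


def harmonic_zscore(segments: np.ndarray, hset: HarmonicSet, target: str = "deviant",
                    win: NoiseWindowSpec = NoiseWindowSpec(),
                    channel_labels: list[str] | None = None) -> ZScoreResult:
    """z-score of the summed-segment centre against its twenty surrounding bins.

    ``z = (centre - mean(noise)) / sd(noise)`` with the sample sd (n-1
    denominator) over the 20-bin noise set (10 per side, adjacent bins
    skipped, untrimmed). Channels with zero noise sd are flagged undefined
    (z = NaN). Under pure noise z is t-distributed with 19 degrees of
    freedom (up to the skew of summed spectral amplitudes), so the 1.64
    criterion is mildly anticonservative; see the package docs.
    """
    segments = np.atleast_2d(segments)
    n_ch, seg_len = segments.shape
    center = (seg_len - 1) // 2
    if seg_len != 2 * win.side_bins + 1:
        raise ValueError(f"segment length {seg_len} does not match the "
                         f"+-{win.side_bins}-bin window")
    offs = z_noise_offsets(win)
    if np.max(np.abs(offs)) > center:
        raise ValueError("z noise window exceeds the summed-segment half-width")
    noise = segments[:, center + offs]
    noise_mean = noise.mean(axis=1)
    noise_sd = noise.std(axis=1, ddof=1)
    undefined = noise_sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (segments[:, center] - noise_mean) / noise_sd
    z[undefined] = np.nan
    return ZScoreResult(z=z, center_amplitude=segments[:, center],
                        noise_mean=noise_mean, noise_sd=noise_sd,
                        harmonics=hset, target=target, undefined=undefined,
                        channel_labels=channel_labels)
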