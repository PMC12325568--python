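"""Synthetic multichannel EEG with known frequency-tagged ground truth.

Each simulated recording carries a steady-state response at the base rate
(6 Hz and harmonics), an oddball response at the deviant rate (1.2 Hz and
harmonics, excluding multiples of 6 Hz) for experimental sequences, and
1/f^alpha background noise. Response topographies follow Gaussian profiles
of great-circle distance from a centroid near the target region of
interest, emulating the medial-occipital / occipito-parietal patterns seen
in frequency-tagging studies. The generator exists so every stage of the
analysis pipeline — detection, null calibration, parameter recovery — can
be exercised against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .montage import Montage, ROI_CHANNELS, default_montage
from .paradigm import DesignSpec, StimulusSequence, fade_gain, session_plan, build_sequence

__all__ = [
    "ResponseSpec",
    "NoiseSpec",
    "Recording",
    "topography_weights",
    "simulate_recording",
    "inject_bad_channels",
    "simulate_participant",
    "default_response_for",
    "NOTATION_TOPOGRAPHY",
]

#: which topography profile each mixed-format condition drives
#: (left-lateralised for words-digits, medial for digits-dots, blend for dots-words)
NOTATION_TOPOGRAPHY = {
    "words-digits": "LOP",
    "digits-dots": "MO",
    "dots-words": "LOP+MO",
}

MAX_BAD_CHANNELS = 3  # 5 % of 64 electrodes


@dataclass
class ResponseSpec:
    """Ground-truth neural response parameters for one simulated sequence.

    Amplitudes are in microvolts at the topography's peak channel.
    ``standard_harmonic_decay`` multiplies the 6 Hz amplitude per extra
    harmonic; ``oddball_harmonic_weights`` scale the deviant harmonics
    (1.2 Hz multiples with multiples of 6 Hz skipped).
    """

    standard_amp_uv: float = 2.0
    standard_harmonic_decay: float = 0.25
    n_standard_harmonics: int = 4
    oddball_amp_uv: float = 0.9
    oddball_harmonic_weights: tuple[float, ...] = (1.0, 0.8, 0.6, 0.45, 0.3, 0.2)
    topography_name: str = "MO"
    topography_sigma_rad: float = 0.45
    #: the 6 Hz general visual response is broad and medial-occipital for
    #: every notation; only the oddball response follows the notation topography
    standard_topography_name: str = "MO"
    standard_topography_sigma_rad: float = 0.9
    response_mode: str = "oscillatory"  # "oscillatory" | "event_based"

    def validate(self) -> list[str]:
        v = []
        if self.standard_amp_uv < 0 or self.oddball_amp_uv < 0:
            v.append("amplitudes must be non-negative")
        if any(w < 0 for w in self.oddball_harmonic_weights):
            v.append("oddball harmonic weights must be non-negative")
        if self.response_mode not in ("oscillatory", "event_based"):
            v.append(f"unknown response_mode {self.response_mode!r}")
        if self.topography_sigma_rad <= 0:
            v.append("topography_sigma_rad must be positive")
        return v


@dataclass
class NoiseSpec:
    """Background-noise model: Gaussian 1/f^alpha noise plus optional artifacts."""

    noise_sd_uv: float = 15.0
    spectral_exponent: float = 1.0   # amplitude ~ f^(-alpha/2)
    n_bad_channels: int = 0
    bad_repetition_probability: float = 0.0
    artifact_amp_uv: float = 500.0

    def validate(self) -> list[str]:
        v = []
        if self.noise_sd_uv <= 0:
            v.append("noise_sd_uv must be positive")
        if self.spectral_exponent < 0:
            v.append("spectral_exponent must be >= 0")
        if self.n_bad_channels > MAX_BAD_CHANNELS:
            v.append(f"n_bad_channels exceeds the 5% cap ({MAX_BAD_CHANNELS} of 64)")
        if not (0.0 <= self.bad_repetition_probability <= 1.0):
            v.append("bad_repetition_probability must lie in [0, 1]")
        return v


@dataclass(eq=False)
class Recording:
    """channels x samples EEG in microvolts, with montage, events and provenance."""

    data: np.ndarray
    fs_hz: float
    montage: Montage
    events: list[tuple[float, float, str]]
    ground_truth: ResponseSpec | None = None
    seed: int | None = None
    labels: dict = field(default_factory=dict)  # notation/condition/repetition etc.
    bad_channels: list[str] = field(default_factory=list)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def copy(self) -> "Recording":
        return Recording(self.data.copy(), self.fs_hz, self.montage,
                         list(self.events), self.ground_truth, self.seed,
                         dict(self.labels), list(self.bad_channels))


def _roi_centroid(montage: Montage, name: str) -> np.ndarray:
    pts = np.array([montage.positions[montage.index(ch)] for ch in ROI_CHANNELS[name]])
    c = pts.mean(axis=0)
    return c / np.linalg.norm(c)


def topography_weights(montage: Montage, name: str, sigma_rad: float = 0.45) -> np.ndarray:
    """Per-channel weights in [0, 1] (max 1) for a named response topography.

    ``w = exp(-d^2 / (2 sigma^2))`` with ``d`` the great-circle distance from a
    profile centroid (near Oz for "MO", near P7/PO7 for "LOP", near P8/PO8
    for "ROP"); "LOP+MO" is the renormalised mean of the two profiles.
    """
    if "+" in name:
        parts = [topography_weights(montage, p, sigma_rad) for p in name.split("+")]
        w = np.mean(parts, axis=0)
        return w / w.max()
    if name not in ROI_CHANNELS:
        raise KeyError(f"unknown topography {name!r}")
    d = montage.distances_from_point(_roi_centroid(montage, name))
    w = np.exp(-(d ** 2) / (2.0 * sigma_rad ** 2))
    return w / w.max()


def _oddball_frequencies(deviant_hz: float, base_hz: float, n: int) -> np.ndarray:
    """First ``n`` multiples of the deviant rate, skipping multiples of the base rate."""
    out, k = [], 1
    while len(out) < n:
        f = k * deviant_hz
        if abs(f / base_hz - round(f / base_hz)) > 1e-9:
            out.append(f)
        k += 1
    return np.array(out)


def _one_over_f_noise(rng, n_channels, n_samples, fs_hz, sd_uv, alpha):
    """Gaussian noise with amplitude spectrum ~ f^(-alpha/2), unit sd scaled to sd_uv.

    Built in the frequency domain: Gaussian complex coefficients shaped by the
    power law, inverse-FFT'd, then rescaled so each channel has the requested
    time-domain standard deviation.
    """
    n_freq = n_samples // 2 + 1
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs_hz)
    shape = np.ones(n_freq)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-alpha / 2.0)
    shape[0] = 0.0  # no DC
    coef = (rng.standard_normal((n_channels, n_freq))
            + 1j * rng.standard_normal((n_channels, n_freq))) * shape
    x = np.fft.irfft(coef, n=n_samples, axis=1)
    s = x.std(axis=1, keepdims=True)
    s[s == 0] = 1.0
    return x / s * sd_uv


def _evoked_kernel(fs_hz: float, kind: str) -> np.ndarray:
    """A ~180 ms biphasic evoked-response kernel (Hann-windowed sine cycles)."""
    dur = 0.180 if kind == "standard" else 0.240
    n = int(round(dur * fs_hz))
    t = np.arange(n) / fs_hz
    cycles = 1.5 if kind == "standard" else 2.0
    return np.hanning(n) * np.sin(2 * np.pi * cycles * t / dur)


def simulate_recording(seq: StimulusSequence, resp: ResponseSpec, noise: NoiseSpec,
                       montage: Montage | None = None, fs_hz: float = 2048.0,
                       seed: int = 0) -> Recording:
    """Simulate one 44 s recording for a stimulation sequence.

    In ``oscillatory`` mode the standard response is a sum of sinusoids at
    6 Hz harmonics and the oddball response a sum at 1.2 Hz harmonics
    (multiples of 6 Hz excluded); both are scaled by the channel topography
    and the fade-in/out gain. In ``event_based`` mode every item onset
    contributes a standard evoked kernel and deviant onsets an additional
    deviant kernel, so oddball periodicity emerges at 1.2 Hz without any
    explicit 1.2 Hz sinusoid. 1/f Gaussian noise is added in both modes.
    Deterministic given ``seed``.
    """
    problems = resp.validate() + noise.validate()
    if problems:
        raise ValueError("; ".join(problems))
    montage = montage or default_montage()
    design = seq.design
    max_f = max(design.base_rate_hz * resp.n_standard_harmonics,
                float(np.max(_oddball_frequencies(design.deviant_rate_hz,
                                                  design.base_rate_hz,
                                                  len(resp.oddball_harmonic_weights)))))
    if resp.response_mode == "oscillatory" and fs_hz < 2.0 * max_f:
        raise ValueError(f"fs_hz={fs_hz} aliases synthesized content up to {max_f} Hz")

    rng = np.random.default_rng(seed)
    n_samples = int(round(fs_hz * design.total_duration_s))
    t = np.arange(n_samples) / fs_hz
    gain = fade_gain(t, design)
    odd_topo = topography_weights(montage, resp.topography_name,
                                  resp.topography_sigma_rad)
    std_topo = topography_weights(montage, resp.standard_topography_name,
                                  resp.standard_topography_sigma_rad)

    std_signal = np.zeros(n_samples)
    odd_signal = np.zeros(n_samples)
    if resp.response_mode == "oscillatory":
        for h in range(1, resp.n_standard_harmonics + 1):
            amp = resp.standard_amp_uv * resp.standard_harmonic_decay ** (h - 1)
            std_signal += amp * np.sin(2 * np.pi * design.base_rate_hz * h * t)
        if resp.oddball_amp_uv > 0:
            freqs = _oddball_frequencies(design.deviant_rate_hz, design.base_rate_hz,
                                         len(resp.oddball_harmonic_weights))
            for f, w in zip(freqs, resp.oddball_harmonic_weights):
                odd_signal += resp.oddball_amp_uv * w * np.sin(2 * np.pi * f * t)
    else:
        std_kernel = _evoked_kernel(fs_hz, "standard")
        dev_kernel = _evoked_kernel(fs_hz, "deviant")
        for it in seq.items:
            i0 = int(round(it.onset_s * fs_hz))
            k = std_kernel[: n_samples - i0]
            std_signal[i0:i0 + len(k)] += resp.standard_amp_uv * k
            if it.category == "deviant" and resp.oddball_amp_uv > 0:
                k = dev_kernel[: n_samples - i0]
                odd_signal[i0:i0 + len(k)] += resp.oddball_amp_uv * k

    data = (np.outer(std_topo, std_signal * gain)
            + np.outer(odd_topo, odd_signal * gain))
    data += _one_over_f_noise(rng, len(montage), n_samples, fs_hz,
                              noise.noise_sd_uv, noise.spectral_exponent)

    from .paradigm import sequence_events
    return Recording(data=data, fs_hz=fs_hz, montage=montage,
                     events=sequence_events(seq), ground_truth=resp, seed=int(seed),
                     labels={"notation": design.notation_pair,
                             "condition": design.condition})


def inject_bad_channels(rec: Recording, noise: NoiseSpec, seed: int = 0):
    """Replace up to 3 channels (5 % of 64) with high-variance noise.

    Returns ``(recording, bad_labels)``; the labels let pipeline tests verify
    detection/interpolation. More than 3 channels is refused: a repetition
    that bad should be rejected, not repaired.
    """
    if noise.n_bad_channels > MAX_BAD_CHANNELS:
        raise ValueError(
            f"at most {MAX_BAD_CHANNELS} channels (5% of 64) may be replaced; "
            "reject the repetition instead")
    if noise.n_bad_channels == 0:
        return rec, []
    rng = np.random.default_rng(seed)
    out = rec.copy()
    idx = rng.choice(len(out.montage), size=noise.n_bad_channels, replace=False)
    labels = [out.montage.labels[i] for i in idx]
    out.data[idx] = rng.standard_normal((len(idx), out.n_samples)) * noise.artifact_amp_uv
    out.bad_channels = labels
    return out, labels


def default_response_for(notation: str, condition: str,
                         base: ResponseSpec | None = None) -> ResponseSpec:
    """Ground truth for a notation x condition cell: control sequences carry no oddball."""
    base = base or ResponseSpec()
    d = asdict(base)
    d["oddball_harmonic_weights"] = tuple(d["oddball_harmonic_weights"])
    d["topography_name"] = NOTATION_TOPOGRAPHY[notation]
    if condition == "control":
        d["oddball_amp_uv"] = 0.0
    return ResponseSpec(**d)


def simulate_participant(base_design: DesignSpec, participant_index: int,
                         resp: ResponseSpec | None = None,
                         noise: NoiseSpec | None = None,
                         montage: Montage | None = None, fs_hz: float = 2048.0,
                         seed: int = 0) -> list[Recording]:
    """Simulate one participant's full 24-sequence session.

    Experimental recordings carry the oddball response; control recordings
    have oddball amplitude 0. With ``bad_repetition_probability`` > 0, some
    repetitions receive a large broadband artifact and are labelled
    ``artifact=True`` so rejection can be exercised.
    """
    noise = noise or NoiseSpec()
    montage = montage or default_montage()
    plan = session_plan(base_design, participant_index)
    rng = np.random.default_rng(seed)
    recordings = []
    for i_seq, design in enumerate(plan):
        seq_seed = int(rng.integers(2 ** 31))
        seq = build_sequence(design, seq_seed)
        cell_resp = default_response_for(design.notation_pair, design.condition, resp)
        rec = simulate_recording(seq, cell_resp, noise, montage, fs_hz,
                                 seed=int(rng.integers(2 ** 31)))
        rec.labels["participant"] = participant_index
        rec.labels["repetition"] = i_seq
        if rng.random() < noise.bad_repetition_probability:
            ch = int(rng.integers(rec.n_channels))
            rec.data[ch] += noise.artifact_amp_uv * np.sign(
                np.sin(2 * np.pi * 0.5 * np.arange(rec.n_samples) / fs_hz))
            rec.labels["artifact"] = True
        else:
            rec.labels["artifact"] = False
        recordings.append(rec)
    return recordings
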