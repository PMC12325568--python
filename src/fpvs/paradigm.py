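"""Oddball stimulation-sequence design.

Implements the fast-periodic-visual-stimulation (FPVS) oddball paradigm:
items of a standard magnitude category are presented at a base rate (6 Hz)
and every n-th item (n = 5, i.e. 1.2 Hz) is drawn from a deviant category.
Each 44 s sequence consists of a 2 s fade-in, 40 s of full-contrast
stimulation and a 2 s fade-out.  In the experimental condition the deviant
positions carry large magnitudes (6-9) against small standards (1-4); in the
control condition magnitudes are randomly intermixed with no positional
rule, which removes the periodic category structure while keeping the
visual stimulation identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "NOTATION_PAIRS",
    "DesignSpec",
    "StimulusItem",
    "StimulusSequence",
    "build_sequence",
    "contrast_envelope",
    "fade_gain",
    "session_plan",
    "sequence_events",
    "write_events_tsv",
]

#: The three mixed-format conditions; each value is the (format, format) pair.
NOTATION_PAIRS = {
    "words-digits": ("word", "digit"),
    "dots-words": ("dots", "word"),
    "digits-dots": ("digit", "dots"),
}

_FONT_IDS = (0, 1, 2, 3)        # 4 fonts (the 5th was dropped from the design)
_DOT_CONFIG_IDS = (0, 1, 2, 3, 4)


class ConfigurationError(ValueError):
    """Raised when a design or analysis configuration is internally inconsistent."""


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of one oddball stimulation sequence.

    The deviant frequency is ``base_rate_hz / deviant_period_items``
    (6 / 5 = 1.2 Hz by default).
    """

    base_rate_hz: float = 6.0
    deviant_period_items: int = 5
    fade_in_s: float = 2.0
    stim_s: float = 40.0
    fade_out_s: float = 2.0
    standard_magnitudes: tuple[int, ...] = (1, 2, 3, 4)
    deviant_magnitudes: tuple[int, ...] = (6, 7, 8, 9)
    notation_pair: str = "words-digits"
    condition: str = "experimental"
    n_repetitions_per_condition: int = 4
    color_changes_per_sequence: int = 8
    #: probability that a control-condition item is large-magnitude
    control_large_fraction: float = 0.5

    @property
    def deviant_rate_hz(self) -> float:
        return self.base_rate_hz / self.deviant_period_items

    @property
    def total_duration_s(self) -> float:
        return self.fade_in_s + self.stim_s + self.fade_out_s

    @property
    def n_items(self) -> int:
        return int(round(self.base_rate_hz * self.total_duration_s))

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        v = []
        if self.base_rate_hz <= 0:
            v.append("base_rate_hz must be positive")
        if self.deviant_period_items < 2:
            v.append("deviant_period_items must be >= 2")
        if self.notation_pair not in NOTATION_PAIRS:
            v.append(f"unknown notation_pair {self.notation_pair!r}")
        if self.condition not in ("experimental", "control"):
            v.append(f"condition must be experimental|control, got {self.condition!r}")
        if set(self.standard_magnitudes) & set(self.deviant_magnitudes):
            v.append("standard and deviant magnitude sets must be disjoint")
        if 5 in self.standard_magnitudes or 5 in self.deviant_magnitudes:
            v.append("magnitude 5 is excluded from both categories")
        if not (0.0 <= self.control_large_fraction <= 1.0):
            v.append("control_large_fraction must lie in [0, 1]")
        # the deviant rate must land on an exact analysis bin (1/stim_s resolution)
        if self.stim_s > 0:
            cycles = self.deviant_rate_hz * self.stim_s
            if abs(cycles - round(cycles)) > 1e-9:
                v.append(
                    "deviant rate %.4f Hz is not an integer number of cycles in the "
                    "%.0f s analysis epoch" % (self.deviant_rate_hz, self.stim_s)
                )
        return v

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DesignSpec":
        d = json.loads(text)
        for k in ("standard_magnitudes", "deviant_magnitudes"):
            d[k] = tuple(d[k])
        return cls(**d)


@dataclass(frozen=True)
class StimulusItem:
    onset_s: float
    magnitude: int
    format: str          # "digit" | "word" | "dots"
    category: str        # "standard" | "deviant"
    variant_id: int      # font index or dot-configuration index


@dataclass
class StimulusSequence:
    design: DesignSpec
    items: list[StimulusItem]
    color_change_times_s: np.ndarray
    seed: int

    @property
    def deviant_positions(self) -> np.ndarray:
        """0-based indices of items labelled deviant."""
        return np.array([i for i, it in enumerate(self.items) if it.category == "deviant"])


def _draw_item(rng, design, category, formats):
    mags = design.deviant_magnitudes if category == "deviant" else design.standard_magnitudes
    magnitude = int(rng.choice(mags))
    fmt = formats[rng.integers(len(formats))]
    variant = int(rng.choice(_DOT_CONFIG_IDS if fmt == "dots" else _FONT_IDS))
    return magnitude, fmt, variant


def _draw_color_changes(rng, design, min_gap_s=2.0, edge_s=1.0):
    """8 random fixation-cross colour-change times with a minimum gap (rejection sampled)."""
    lo, hi = edge_s, design.total_duration_s - edge_s
    n = design.color_changes_per_sequence
    for _ in range(10_000):
        t = np.sort(rng.uniform(lo, hi, size=n))
        if n < 2 or np.min(np.diff(t)) >= min_gap_s:
            return t
    raise ConfigurationError(
        f"could not place {n} colour changes with a {min_gap_s} s gap in [{lo}, {hi}] s"
    )


def build_sequence(design: DesignSpec, seed: int) -> StimulusSequence:
    """Generate one timed oddball sequence.

    Experimental condition: items at 1-based positions 5, 10, 15, ... are
    deviants (magnitude > 5) and all other items standards (magnitude < 5).
    Control condition: each item's magnitude is drawn at random from the
    union of both categories (large with probability
    ``control_large_fraction``); the category label merely records which set
    the magnitude fell in, so there is no periodicity to label structure.

    Both formats of the notation pair are guaranteed to occur among the
    standards and among the deviants. Deterministic given ``(design, seed)``.
    """
    problems = design.validate()
    if problems:
        raise ConfigurationError("; ".join(problems))
    rng = np.random.default_rng(seed)
    formats = NOTATION_PAIRS[design.notation_pair]
    period = design.deviant_period_items

    items: list[StimulusItem] = []
    for i in range(design.n_items):
        onset = i / design.base_rate_hz
        if design.condition == "experimental":
            category = "deviant" if (i + 1) % period == 0 else "standard"
        else:
            large = rng.random() < design.control_large_fraction
            category = "deviant" if large else "standard"
        magnitude, fmt, variant = _draw_item(rng, design, category, formats)
        items.append(StimulusItem(onset, magnitude, fmt, category, variant))

    # ensure both formats appear within each category (overwhelmingly likely
    # anyway for 264 items; patch deterministically if a format is missing)
    for category in ("standard", "deviant"):
        idx = [i for i, it in enumerate(items) if it.category == category]
        present = {items[i].format for i in idx}
        for fmt in formats:
            if fmt not in present and len(idx) >= 2:
                j = idx[0] if items[idx[0]].format != fmt else idx[1]
                it = items[j]
                variant = int(rng.choice(_DOT_CONFIG_IDS if fmt == "dots" else _FONT_IDS))
                items[j] = StimulusItem(it.onset_s, it.magnitude, fmt, it.category, variant)

    color_times = _draw_color_changes(rng, design)
    return StimulusSequence(design=design, items=items,
                            color_change_times_s=color_times, seed=int(seed))


def contrast_envelope(t_s, base_rate_hz: float = 6.0):
    """Sinusoidal contrast modulation, 0 to 100 % within each stimulation cycle.

    ``(1 - cos(2 pi f t)) / 2``: each item starts and ends at 0 % contrast and
    peaks half-way through its presentation slot.
    """
    t = np.asarray(t_s, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_s must be non-negative")
    return (1.0 - np.cos(2.0 * np.pi * base_rate_hz * t)) / 2.0


def fade_gain(t_s, design: DesignSpec):
    """Linear fade-in / fade-out gain over one sequence.

    0 at sequence start, ramps to 1 across the fade-in, stays 1 during
    stimulation, ramps back to 0 across the fade-out.
    """
    t = np.asarray(t_s, dtype=float)
    total = design.total_duration_s
    if np.any(t < 0) or np.any(t > total + 1e-9):
        raise ValueError("t_s outside [0, total duration]")
    gain = np.ones_like(t)
    if design.fade_in_s > 0:
        m = t < design.fade_in_s
        gain = np.where(m, t / design.fade_in_s, gain)
    if design.fade_out_s > 0:
        t_out = total - design.fade_out_s
        m = t > t_out
        gain = np.where(m, (total - t) / design.fade_out_s, gain)
    return gain


_LATIN_SQUARE = [  # cyclic 3x3 over the notation pairs
    ["words-digits", "dots-words", "digits-dots"],
    ["dots-words", "digits-dots", "words-digits"],
    ["digits-dots", "words-digits", "dots-words"],
]


def session_plan(base_design: DesignSpec, participant_index: int) -> list[DesignSpec]:
    """Ordered sequence designs for one participant's session (24 sequences).

    Blocked by notation then by condition: all repetitions of one
    notation x condition cell run back to back. Notation order follows the
    3x3 Latin-square row selected by participant index; condition order
    within a notation block alternates with participant parity.
    """
    notations = _LATIN_SQUARE[participant_index % 3]
    conditions = ["experimental", "control"]
    if participant_index % 2 == 1:
        conditions = conditions[::-1]
    plan = []
    for notation in notations:
        for condition in conditions:
            for _rep in range(base_design.n_repetitions_per_condition):
                plan.append(
                    DesignSpec(**{**asdict(base_design),
                                  "standard_magnitudes": base_design.standard_magnitudes,
                                  "deviant_magnitudes": base_design.deviant_magnitudes,
                                  "notation_pair": notation,
                                  "condition": condition})
                )
    return plan


def sequence_events(seq: StimulusSequence) -> list[tuple[float, float, str]]:
    """(onset_s, duration_s, label) triplets for annotation-style export."""
    dur = 1.0 / seq.design.base_rate_hz
    ev = [(0.0, seq.design.total_duration_s, f"sequence/{seq.design.notation_pair}/{seq.design.condition}")]
    ev += [(it.onset_s, dur, f"{it.category}/{it.format}/{it.magnitude}") for it in seq.items]
    ev += [(float(t), 0.0, "color_change") for t in seq.color_change_times_s]
    return ev


def write_events_tsv(seq: StimulusSequence, path) -> None:
    """Write the sequence's events as a 3-column tab-separated file."""
    with open(path, "w") as fh:
        fh.write("onset_s\tduration_s\tlabel\n")
        for onset, dur, label in sequence_events(seq):
            fh.write(f"{onset:.6f}\t{dur:.6f}\t{label}\n")
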