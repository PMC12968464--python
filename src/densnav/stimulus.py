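"""Tone-stack stimulus synthesis along a spectral-density dimension.

The stimulus dimension is the number of concurrent random-frequency pure
tones in a brief "stack".  Sparse stacks (few tones) sound "beepy", dense
stacks (many tones) sound "noisy".  Density takes one of a fixed number of
logarithmically spaced integer tone counts so that successive levels are
roughly equally discriminable (density JNDs grow with density, i.e. the
dimension is Weber-like).

A stack is 190 ms of summed equal-amplitude sinusoids with 2-ms raised
cosine onset/offset ramps, followed by 10 ms of silence, so each stack
occupies exactly 200 ms in a series.  Component frequencies are drawn
log-uniformly between 250 and 4000 Hz, fresh for every stack.  All stacks
are equated for RMS intensity regardless of tone count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = [
    "DensityScale",
    "ToneStack",
    "Waveform",
    "make_density_scale",
    "sample_frequencies",
    "synth_stack",
    "synth_series",
    "write_wav",
]

#: Stack timing defaults (seconds).
STACK_DURATION_S = 0.190
RAMP_S = 0.002
GAP_S = 0.010

#: Frequency range for tone components (Hz).
F_LO = 250.0
F_HI = 4000.0

#: Default audio parameters.  The RMS target is kept well below full scale so
#: that even the highest-crest-factor (densest) stacks stay clear of clipping;
#: a uniform safety rescale is applied at write time if the peak exceeds 0.9.
DEFAULT_SAMPLE_RATE = 44100
DEFAULT_RMS_TARGET = 0.04
PEAK_CEILING = 0.9


@dataclass(frozen=True)
class DensityScale:
    """Ordered integer tone counts defining the density dimension."""

    levels: tuple[int, ...]
    min_tones: int
    max_tones: int

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def __post_init__(self) -> None:
        lv = self.levels
        if len(lv) < 2:
            raise ValueError("a density scale needs at least two levels")
        if any(b <= a for a, b in zip(lv, lv[1:])):
            raise ValueError("density levels must be strictly increasing")
        if lv[0] != self.min_tones or lv[-1] != self.max_tones:
            raise ValueError("scale endpoints must equal min_tones/max_tones")

    def log2_density(self, level_index: int) -> float:
        """log2 tone count at a level; the scale is ~linear in this unit."""
        return float(np.log2(self.levels[level_index]))


@dataclass(frozen=True)
class ToneStack:
    """One tone stack: component frequencies plus envelope timing."""

    n_tones: int
    frequencies: tuple[float, ...]
    duration_s: float = STACK_DURATION_S
    ramp_s: float = RAMP_S
    gap_s: float = GAP_S
    rms_target: float = DEFAULT_RMS_TARGET

    def __post_init__(self) -> None:
        if self.n_tones < 1:
            raise ValueError("n_tones must be >= 1")
        if len(self.frequencies) != self.n_tones:
            raise ValueError("frequencies length must equal n_tones")
        if not all(F_LO <= f <= F_HI for f in self.frequencies):
            raise ValueError(f"frequencies must lie in [{F_LO}, {F_HI}] Hz")
        if min(self.duration_s, self.ramp_s, self.gap_s) <= 0:
            raise ValueError("duration, ramp and gap must be positive")
        if 2 * self.ramp_s >= self.duration_s:
            raise ValueError("ramps must fit inside the stack duration")


@dataclass
class Waveform:
    """A mono waveform with its sample rate."""

    samples: np.ndarray
    sample_rate_hz: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))


def make_density_scale(
    min_tones: int = 2, max_tones: int = 196, n_levels: int = 26
) -> DensityScale:
    """Build a geometric (log-spaced) grid of integer tone counts.

    The exact geometric grid ``min * (max/min)**(i/(n-1))`` is rounded to the
    nearest integer.  At the sparse end rounding can collide (the second
    point of the default 2..196 grid rounds back to 2); collisions are
    resolved by bumping upward to the next unused integer, preserving strict
    monotonicity and both endpoints.
    """
    if not (1 <= min_tones < max_tones):
        raise ValueError("require 1 <= min_tones < max_tones")
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if n_levels > max_tones - min_tones + 1:
        raise ValueError(
            "n_levels exceeds the number of distinct integers in range"
        )
    exact = min_tones * (max_tones / min_tones) ** (
        np.arange(n_levels) / (n_levels - 1)
    )
    levels: list[int] = []
    for x in np.rint(exact).astype(int):
        if levels and x <= levels[-1]:
            x = levels[-1] + 1
        levels.append(int(x))
    if levels[-1] != max_tones:
        # Collisions never propagate to the dense end for any sane grid, but
        # guard anyway: the endpoint is part of the contract.
        raise ValueError("duplicate resolution overran max_tones")
    return DensityScale(tuple(levels), min_tones, max_tones)


def sample_frequencies(
    n_tones: int,
    f_lo: float = F_LO,
    f_hi: float = F_HI,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw ``n_tones`` i.i.d. log-uniform frequencies in [f_lo, f_hi] Hz."""
    if n_tones < 1:
        raise ValueError("n_tones must be >= 1")
    if not (0 < f_lo < f_hi):
        raise ValueError("require 0 < f_lo < f_hi")
    rng = np.random.default_rng(rng)
    return np.exp(rng.uniform(np.log(f_lo), np.log(f_hi), size=n_tones))


def _ramp_envelope(n_samples: int, n_ramp: int) -> np.ndarray:
    """Unit envelope with raised-cosine on/offset ramps of n_ramp samples."""
    env = np.ones(n_samples)
    if n_ramp > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        env[:n_ramp] = ramp
        env[-n_ramp:] = ramp[::-1]
    return env


def synth_stack(
    stack: ToneStack,
    sample_rate_hz: int = DEFAULT_SAMPLE_RATE,
    rng: np.random.Generator | int | None = None,
) -> Waveform:
    """Render one tone stack (without its trailing gap).

    Components are summed at equal amplitude with random phases (uniform in
    [0, 2pi), avoiding onset artifacts), the cosine ramps applied, and the
    result scaled so the RMS over the full 190-ms stack equals
    ``stack.rms_target`` irrespective of tone count.
    """
    if sample_rate_hz < 2 * max(stack.frequencies):
        raise ValueError("sample rate below Nyquist for highest component")
    rng = np.random.default_rng(rng)
    n = int(round(stack.duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    freqs = np.asarray(stack.frequencies)
    phases = rng.uniform(0.0, 2 * np.pi, size=freqs.size)
    wave = np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]).sum(
        axis=0
    )
    wave *= _ramp_envelope(n, int(round(stack.ramp_s * sample_rate_hz)))
    rms = np.sqrt(np.mean(wave**2))
    wave *= stack.rms_target / rms
    return Waveform(wave, sample_rate_hz)


def synth_series(
    level_indices,
    scale: DensityScale,
    sample_rate_hz: int = DEFAULT_SAMPLE_RATE,
    rng: np.random.Generator | int | None = None,
    rms_target: float = DEFAULT_RMS_TARGET,
) -> Waveform:
    """Render a series of stacks, each followed by 10 ms of silence.

    A fresh random set of component frequencies is drawn for every stack
    regardless of whether its density level changed, so the fine spectrum is
    uninformative about density.  Total duration is 0.200 s per stack.
    """
    level_indices = list(level_indices)
    if not level_indices:
        raise ValueError("level_indices must be non-empty")
    if any(not (0 <= i < scale.n_levels) for i in level_indices):
        raise ValueError("level index out of range for scale")
    rng = np.random.default_rng(rng)
    gap = np.zeros(int(round(GAP_S * sample_rate_hz)))
    parts = []
    for idx in level_indices:
        n_tones = scale.levels[idx]
        freqs = tuple(sample_frequencies(n_tones, rng=rng))
        stack = ToneStack(n_tones, freqs, rms_target=rms_target)
        parts.append(synth_stack(stack, sample_rate_hz, rng).samples)
        parts.append(gap)
    return Waveform(np.concatenate(parts), sample_rate_hz)


def write_wav(
    path: str | Path,
    waveform: Waveform,
    sidecar: dict | None = None,
) -> Path:
    """Write a 32-bit float PCM WAV plus an optional JSON sidecar.

    If the peak exceeds the 0.9 safety ceiling the whole waveform is rescaled
    uniformly (preserving relative RMS across stacks).
    """
    path = Path(path)
    samples = waveform.samples
    peak = np.max(np.abs(samples)) if samples.size else 0.0
    if peak > PEAK_CEILING:
        samples = samples * (PEAK_CEILING / peak)
    wavfile.write(path, waveform.sample_rate_hz, samples.astype(np.float32))
    if sidecar is not None:
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path
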