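"""Synthetic multi-view datasets and EEG-like segments for end-to-end testing.

The multi-view generator uses a Gaussian class-center model: per view the
two class means sit at +/- (separation * informativeness_m)/2 along a
random unit direction, with isotropic noise.  Informativeness 0 makes a
view pure noise.  This keeps class separability and per-view information
analytically controllable rather than mimicking real EEG feature
distributions.

The EEG generator emits 1/f-weighted background noise; seizure-like
segments add high-amplitude oscillatory bursts in the 3-12 Hz range with
random onsets, giving them a reliably elevated low-frequency band power.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import DEFAULT_RATE, EEGSegment, MultiViewDataset


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the Gaussian multi-view generator."""

    n_per_class: int = 50
    D: int = 8
    M: int = 2
    informativeness: tuple[float, ...] = (1.0, 1.0)
    class_separation: float = 3.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1 or self.D < 1 or self.M < 1:
            raise ValueError("all counts must be positive")
        if len(self.informativeness) != self.M:
            raise ValueError("informativeness must have one entry per view")
        if any(not 0.0 <= w <= 1.0 for w in self.informativeness):
            raise ValueError("informativeness entries must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def generate_multiview(spec: SynthSpec) -> MultiViewDataset:
    """Two balanced Gaussian classes in M views, deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    n = 2 * spec.n_per_class
    labels = np.concatenate(
        [np.full(spec.n_per_class, 1), np.full(spec.n_per_class, -1)]
    )
    views = []
    for m in range(spec.M):
        u = rng.normal(size=spec.D)
        u /= np.linalg.norm(u)
        shift = 0.5 * spec.class_separation * spec.informativeness[m]
        centers = np.outer(u, shift * labels)  # D x N
        X = centers + rng.normal(scale=spec.noise_sd, size=(spec.D, n))
        views.append((f"view{m + 1}", X))
    return MultiViewDataset(
        views=views, labels=labels, meta={"generator": "gaussian-multiview",
                                          "seed": spec.seed},
    )


def _pink_noise(rng: np.random.Generator, length: int) -> np.ndarray:
    """Noise with an approximately 1/f power spectrum, unit variance."""
    white = rng.normal(size=length)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(length)
    weights = np.ones_like(freqs)
    weights[1:] = 1.0 / np.sqrt(freqs[1:])  # amplitude ~ f^-1/2 => power ~ 1/f
    weights[0] = 0.0
    x = np.fft.irfft(spec * weights, n=length)
    return x / x.std()


def generate_synthetic_eeg(
    n_segments: int,
    length: int = 1024,
    rate: float = DEFAULT_RATE,
    kind: str = "background",
    seed: int = 0,
    burst_amplitude: float = 3.0,
) -> list[EEGSegment]:
    """EEG-like segments: pink-noise background or seizure-like bursts.

    ``kind='seizure'`` adds 1-3 oscillatory bursts per segment, each with a
    random frequency in 3-12 Hz, random onset, and duration 0.5-2 s, at
    ``burst_amplitude`` times the background standard deviation.
    """
    if kind not in ("background", "seizure"):
        raise ValueError("kind must be 'background' or 'seizure'")
    rng = np.random.default_rng(seed)
    segments = []
    for i in range(n_segments):
        x = _pink_noise(rng, length)
        if kind == "seizure":
            for _ in range(rng.integers(1, 4)):
                f = rng.uniform(3.0, 12.0)
                dur = int(rng.uniform(0.5, 2.0) * rate)
                dur = min(dur, length)
                onset = rng.integers(0, max(1, length - dur))
                t = np.arange(dur) / rate
                envelope = np.hanning(dur)
                x[onset:onset + dur] += (
                    burst_amplitude
                    * envelope
                    * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
                )
        segments.append(
            EEGSegment(samples=x, rate=rate, source_id=f"synthetic-{kind}-{i}")
        )
    return segments


def generate_eeg_classification_problem(
    n_per_class: int = 30,
    length: int = 1024,
    rate: float = DEFAULT_RATE,
    seed: int = 0,
    burst_amplitude: float = 3.0,
) -> tuple[list[EEGSegment], np.ndarray]:
    """Balanced seizure-vs-background problem: seizure segments labelled +1."""
    seizure = generate_synthetic_eeg(
        n_per_class, length, rate, kind="seizure", seed=seed,
        burst_amplitude=burst_amplitude,
    )
    background = generate_synthetic_eeg(
        n_per_class, length, rate, kind="background", seed=seed + 1,
    )
    labels = np.concatenate([np.full(n_per_class, 1), np.full(n_per_class, -1)])
    return seizure + background, labels
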