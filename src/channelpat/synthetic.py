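"""Synthetic labelled EEG segments for end-to-end testing.

The generator plants the class signal in the *ordering* of channel
gains, not in absolute amplitude, because the rank transform discards
everything except per-timepoint orderings — a pure mean shift common to
all channels would be invisible downstream.

Class g gives channel c a gain ``1 + effect * delta(g, c)`` where the
fixed patterns are ascending channel gains for the first class and
descending for the second, so with a large effect the two classes
prefer opposite channel orderings.  Each sample is
``gain * |baseline oscillation| + Gaussian noise``: the shared rectified
sinusoid makes the gain ordering dominate when the oscillation is large
relative to the noise, while the noise scrambles orderings near the
zero crossings.  With ``effect = 0`` the classes are exchangeable.

This emulates the one property the pipeline needs from real EEG —
class-dependent channel-amplitude orderings.  It has no 1/f spectrum,
no alpha peaks, no artifacts, and no inter-subject variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import DatasetManifest, EegSegment, save_manifest, save_segment

__all__ = ["SynthParams", "generate_dataset", "write_dataset"]


@dataclass
class SynthParams:
    """Generator settings.

    Defaults give a clearly separable two-class problem at a size the
    full pipeline processes in seconds: 14 channels (the default
    montage), 256 samples per segment, 40 segments per class,
    gain-separation effect 0.8 and noise sd 0.5 (amplitude units; the
    baseline oscillation has unit amplitude).
    """

    n_channels: int = 14
    n_samples: int = 256
    segments_per_class: int = 40
    effect: float = 0.8
    noise_sd: float = 0.5
    seed: int = 0
    class_names: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        if self.n_channels < 2 or self.n_samples < 2 or self.segments_per_class < 1:
            raise ValueError("n_channels, n_samples, segments_per_class must be positive (C, N >= 2)")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if len(self.class_names) != 2 or len(set(self.class_names)) != 2:
            raise ValueError("exactly two distinct class names")


def _gain_patterns(n_channels: int) -> np.ndarray:
    """Fixed per-class gain patterns delta(g, c) in [0, 1]: ascending vs descending."""
    ramp = np.linspace(0.0, 1.0, n_channels)
    return np.stack([ramp, ramp[::-1]])


def generate_dataset(params: SynthParams) -> tuple[list[EegSegment], list[str]]:
    """Deterministic (given seed) labelled segments, class-blocked order."""
    rng = np.random.default_rng(params.seed)
    delta = _gain_patterns(params.n_channels)
    segments: list[EegSegment] = []
    labels: list[str] = []
    names = [f"ch{i + 1}" for i in range(params.n_channels)]
    t = np.arange(params.n_samples)
    for g, cls in enumerate(params.class_names):
        gains = 1.0 + params.effect * delta[g]
        for s in range(params.segments_per_class):
            freq = rng.uniform(4.0, 12.0)  # cycles per segment
            phase = rng.uniform(0.0, 2.0 * np.pi)
            baseline = np.abs(np.sin(2.0 * np.pi * freq * t / params.n_samples + phase))
            noise = rng.normal(0.0, params.noise_sd, size=(params.n_channels, params.n_samples))
            data = gains[:, None] * baseline[None, :] + noise
            segments.append(
                EegSegment(data=data, channel_names=names, segment_id=f"{cls}_{s:03d}")
            )
            labels.append(cls)
    return segments, labels


def write_dataset(params: SynthParams, out_dir) -> DatasetManifest:
    """Write CSV segments plus a (path, label) manifest under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    segments, labels = generate_dataset(params)
    entries = []
    for seg, lab in zip(segments, labels):
        path = out_dir / f"{seg.segment_id}.csv"
        save_segment(seg, path)
        entries.append((path, lab))
    manifest = DatasetManifest(entries=entries, class_names=list(params.class_names))
    save_manifest(manifest, out_dir / "manifest.csv")
    return manifest
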