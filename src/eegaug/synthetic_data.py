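"""Synthetic inputs for the whole pipeline.

Two families:

* band-structured oscillatory EEG — each channel is a sum of band-limited
  Gaussian noise processes whose per-band variances follow an
  emotion-dependent profile, plus a white noise floor. This gives the
  feature pipeline a recoverable ground truth (the band variance, hence the
  DE value) without emulating real emotional physiology.
* low-dimensional toy mixtures (Gaussians on a ring) — the standard
  mode-collapse diagnostic for generative models, scored by how many
  mixture components the generated samples cover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import BandSet, EEGSegment


@dataclass
class EmotionProfile:
    """Target per-band variances (uV^2) per channel for one emotion class."""

    class_index: int
    band_power: np.ndarray          # (n_channels, n_bands)
    noise_floor: float = 0.5        # white-noise variance added everywhere
    smoothness: float = 4.0         # channel-axis correlation length used at build time

    def __post_init__(self):
        self.band_power = np.asarray(self.band_power, dtype=np.float64)
        if (self.band_power <= 0).any():
            raise ValueError("band variances must be positive")


def default_profiles(n_classes: int, n_channels: int = 62,
                     bands: BandSet = BandSet(),
                     contrast: float = 2.5,
                     noise_floor: float = 0.5) -> list[EmotionProfile]:
    """Emotion profiles with class-specific beta/gamma contrasts.

    All classes share a smooth 1/f-flavoured baseline (delta strongest,
    gamma weakest). Class k then scales beta and gamma power in its own
    channel block — a crude stand-in for the frontal/temporal high-band
    asymmetries that distinguish emotional states — strongly enough that
    the classes are separable from true DE features.
    """
    n_bands = len(bands)
    baseline = np.array([8.0, 6.0, 4.0, 3.0, 2.0])[:n_bands]
    ch = np.arange(n_channels)
    profiles = []
    for k in range(n_classes):
        power = np.tile(baseline, (n_channels, 1))
        # smooth channel-block bump for this class, cyclic over the montage
        center = (k + 0.5) * n_channels / n_classes
        dist = np.minimum(np.abs(ch - center), n_channels - np.abs(ch - center))
        bump = np.exp(-0.5 * (dist / (n_channels / 6.0)) ** 2)
        gain = 1.0 + (contrast - 1.0) * bump
        power[:, -2] *= gain            # beta
        power[:, -1] *= gain ** 1.5     # gamma, stronger contrast
        profiles.append(EmotionProfile(class_index=k, band_power=power,
                                       noise_floor=noise_floor))
    return profiles


def _band_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                fs: float, lo: float, hi: float,
                target_var: np.ndarray) -> np.ndarray:
    """Band-limited Gaussian noise via FFT masking, variance-corrected.

    White noise is masked to the band in the frequency domain; the output
    is scaled by the theoretical retained-power fraction so its *expected*
    variance equals the target (sampling noise stays in, as in real data).
    """
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    mask = (freqs >= lo) & (freqs < hi)
    if not mask.any():
        raise ValueError(f"band [{lo}, {hi}) Hz empty at fs={fs}, n={n_samples}")
    spec[:, ~mask] = 0.0
    filtered = np.fft.irfft(spec, n=n_samples, axis=1)
    frac = ((mask[0] * 0.5 if mask.size else 0)  # DC carries half weight
            + mask[1:].sum() - (0.5 * mask[-1] if n_samples % 2 == 0 else 0.0)
            ) / (n_samples / 2.0)
    return filtered * np.sqrt(target_var[:, None] / frac)


def synth_eeg(profile: EmotionProfile, n_segments: int, duration_s: float,
              fs: float, seed: int, bands: BandSet = BandSet(),
              channel_names: tuple[str, ...] | None = None) -> list[EEGSegment]:
    """Segments of band-structured noise matching the profile's variances."""
    if duration_s < 1.0:
        raise ValueError("duration must be >= 1 s")
    if fs <= 2 * bands.highest_edge:
        raise ValueError("fs must exceed twice the highest band edge")
    n_channels = profile.band_power.shape[0]
    n_samples = int(round(duration_s * fs))
    if channel_names is None:
        channel_names = tuple(f"ch{i:02d}" for i in range(n_channels))
    rng = np.random.default_rng(seed)
    segments = []
    for _ in range(n_segments):
        x = rng.standard_normal((n_channels, n_samples)) * np.sqrt(profile.noise_floor)
        for j, (_, lo, hi) in enumerate(bands.bands):
            x += _band_noise(rng, n_channels, n_samples, fs, lo, hi,
                             profile.band_power[:, j])
        segments.append(EEGSegment(data=x, fs=fs, channel_names=channel_names,
                                   label=profile.class_index))
    return segments


# --------------------------------------------------------- toy mixtures

@dataclass
class ToyMixture:
    """K isotropic Gaussians with means on a ring of radius r in 2-D."""

    n_components: int = 8
    radius: float = 2.0
    std: float = 0.05
    weights: np.ndarray | None = None

    def __post_init__(self):
        if self.n_components < 2:
            raise ValueError("need at least two components")
        if self.weights is None:
            self.weights = np.full(self.n_components, 1.0 / self.n_components)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must sum to 1")

    @property
    def means(self) -> np.ndarray:
        angles = 2.0 * np.pi * np.arange(self.n_components) / self.n_components
        return self.radius * np.stack([np.cos(angles), np.sin(angles)], axis=1)


def sample_toy_mixture(mix: ToyMixture, n: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    comp = rng.choice(mix.n_components, size=n, p=mix.weights)
    return mix.means[comp] + mix.std * rng.standard_normal((n, 2))


def mode_coverage(samples: np.ndarray, mix: ToyMixture,
                  radius_multiplier: float = 3.0,
                  min_fraction: float = 0.01) -> int:
    """Number of mixture modes holding >= ``min_fraction`` of the samples
    within ``radius_multiplier * std`` of their mean."""
    samples = np.atleast_2d(np.asarray(samples))
    if samples.shape[0] == 0:
        raise ValueError("empty sample set")
    d = np.linalg.norm(samples[:, None, :] - mix.means[None, :, :], axis=2)
    hits = d <= radius_multiplier * mix.std
    frac = hits.mean(axis=0)
    return int((frac >= min_fraction).sum())
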